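"""Core data model for trio-exome variant analysis.

The central object is the :class:`AnnotatedVariant`: one bi-allelic variant
record (multi-allelic sites are decomposed upstream) carrying the trio
genotypes plus the functional annotations the prioritization cascade
consumes — gene symbol, transcript-consequence terms, the maximum allele
frequency observed across reference populations, and the three missense
deleteriousness scores (SIFT, PolyPhen, Grantham).

Pedigrees are trios extended with a flag for which parent carries the
15q11.2 BP1-BP2 deletion, so that inherited variants can be attributed to
the deleted or the non-deleted parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


MISSING = None  # sentinel spelling used in docstrings; fields use Optional


@dataclass(frozen=True)
class GenotypeCall:
    """A single diploid genotype with its quality annotations.

    ``alleles`` is an ordered pair over {0 (ref), 1 (alt), None (missing)}.
    A call with *any* missing allele is treated as wholly missing by the
    inheritance logic.
    """

    alleles: tuple[Optional[int], Optional[int]]
    dp: Optional[int] = None
    gq: Optional[float] = None

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    @property
    def n_alt(self) -> int:
        """Alt-allele dosage; 0 for missing calls."""
        if self.is_missing:
            return 0
        return sum(1 for a in self.alleles if a == 1)

    @property
    def carries_alt(self) -> bool:
        return self.n_alt > 0

    @property
    def is_hom_alt(self) -> bool:
        return not self.is_missing and self.n_alt == 2

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.n_alt == 1


MISSING_CALL = GenotypeCall(alleles=(None, None))


@dataclass
class AnnotatedVariant:
    """One decomposed (single-alt) variant record with trio genotypes.

    Coordinates follow the VCF convention: ``pos`` is 1-based. The variant
    class is ``"SNV"`` iff ref and alt are both single bases, else
    ``"INDEL"`` with ``indel_length = |len(alt) - len(ref)|``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    biotype_protein_coding: bool = False
    consequence_terms: frozenset[str] = frozenset()
    max_af: Optional[float] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    grantham: Optional[float] = None
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based; got pos={self.pos}")
        if not isinstance(self.consequence_terms, frozenset):
            self.consequence_terms = frozenset(self.consequence_terms)
        if self.max_af is not None and not (0.0 <= self.max_af <= 1.0):
            raise ValueError(f"max_af must lie in [0, 1]; got {self.max_af}")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity used for de-duplication and truth-table joins."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TrioPedigree:
    """A child and its parents, with the deletion-carrier parent flagged.

    Families where parents were not sequenced are representable with both
    parent ids absent; at most one parent per family carries the deletion.
    """

    family_id: str
    child_id: str
    deleted_parent_id: Optional[str] = None
    nondeleted_parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        parents = {p for p in (self.deleted_parent_id, self.nondeleted_parent_id) if p}
        if self.child_id in parents:
            raise ValueError(
                f"family {self.family_id}: child id {self.child_id!r} duplicates a parent id"
            )
        if (
            self.deleted_parent_id is not None
            and self.deleted_parent_id == self.nondeleted_parent_id
        ):
            raise ValueError(f"family {self.family_id}: parent ids must be distinct")

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(
            p for p in (self.deleted_parent_id, self.nondeleted_parent_id) if p is not None
        )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return (self.child_id,) + self.parent_ids


@dataclass(frozen=True)
class GenePanel:
    """A named disease gene panel; symbols are upper-cased and deduplicated."""

    name: str
    genes: frozenset[str]

    @staticmethod
    def from_symbols(name: str, symbols) -> "GenePanel":
        return GenePanel(name=name, genes=frozenset(s.strip().upper() for s in symbols if s.strip()))


VALID_RELATIONS = frozenset({"PP", "C", "CO"})


@dataclass(frozen=True)
class InteractionEdge:
    """One edge of a protein/disease interaction list.

    ``PP`` marks an (undirected) protein–protein interaction; ``C``/``CO``
    mark diseases or functions where variation in the gene is causal or
    correlated.
    """

    gene_a: str
    gene_b: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in VALID_RELATIONS:
            raise ValueError(
                f"unknown relation {self.relation!r}; expected one of {sorted(VALID_RELATIONS)}"
            )
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a!r} is not allowed")

    def touches(self, gene: str) -> bool:
        return gene in (self.gene_a, self.gene_b)

    def partner(self, gene: str) -> str:
        return self.gene_b if gene == self.gene_a else self.gene_a
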