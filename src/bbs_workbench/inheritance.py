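"""Trio inheritance classification of child PDVs.

Each PDV carried by an affected child is assigned exactly one category:
de novo, inherited from the deletion-carrier parent, inherited from the
non-deleted parent, inherited but unattributable (both parents carry the
alt), or one of three "unknown" categories — missing parental data,
improbable homozygous de novo (child hom-alt but a parent lacks the alt),
or an uncharacterized Mendelian violation (a fully observed configuration
that cannot arise by biparental transmission).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import GenotypeCall
from .prioritize import PdvRecord


class InheritanceCategory(Enum):
    DE_NOVO = "DE_NOVO"
    INHERITED_DELETED_PARENT = "INHERITED_DELETED_PARENT"
    INHERITED_NONDELETED_PARENT = "INHERITED_NONDELETED_PARENT"
    INHERITED_AMBIGUOUS = "INHERITED_AMBIGUOUS"
    UNKNOWN_MENDELIAN_VIOLATION = "UNKNOWN_MENDELIAN_VIOLATION"
    UNKNOWN_IMPROBABLE_HOM_DENOVO = "UNKNOWN_IMPROBABLE_HOM_DENOVO"
    UNKNOWN_MISSING_PARENT = "UNKNOWN_MISSING_PARENT"


INHERITED_CATEGORIES = frozenset(
    {
        InheritanceCategory.INHERITED_DELETED_PARENT,
        InheritanceCategory.INHERITED_NONDELETED_PARENT,
        InheritanceCategory.INHERITED_AMBIGUOUS,
    }
)


def _is_missing(call: Optional[GenotypeCall]) -> bool:
    return call is None or call.is_missing


def classify(
    child: GenotypeCall,
    deleted_parent: Optional[GenotypeCall],
    nondeleted_parent: Optional[GenotypeCall],
) -> InheritanceCategory:
    """Assign the inheritance category for one child variant.

    Decision order:

    1. any parent missing (unsequenced, uncalled, or QC-demoted) ->
       UNKNOWN_MISSING_PARENT;
    2. child hom-alt and either parent lacks the alt ->
       UNKNOWN_IMPROBABLE_HOM_DENOVO;
    3. child het, neither parent carries the alt -> DE_NOVO;
    4. exactly one parent carries the alt -> INHERITED from that parent;
    5. both parents carry the alt and the child genotype is attainable by
       biparental transmission -> INHERITED_AMBIGUOUS;
    6. anything else (e.g. child het with both parents hom-alt) ->
       UNKNOWN_MENDELIAN_VIOLATION.

    The child must carry at least one alt allele.
    """
    if _is_missing(child) or not child.carries_alt:
        raise ValueError("classify() requires a present child call carrying >= 1 alt allele")
    if _is_missing(deleted_parent) or _is_missing(nondeleted_parent):
        return InheritanceCategory.UNKNOWN_MISSING_PARENT
    assert deleted_parent is not None and nondeleted_parent is not None

    del_carries = deleted_parent.carries_alt
    nondel_carries = nondeleted_parent.carries_alt

    if child.is_hom_alt and not (del_carries and nondel_carries):
        return InheritanceCategory.UNKNOWN_IMPROBABLE_HOM_DENOVO
    if child.is_het and not del_carries and not nondel_carries:
        return InheritanceCategory.DE_NOVO
    if del_carries != nondel_carries:
        return (
            InheritanceCategory.INHERITED_DELETED_PARENT
            if del_carries
            else InheritanceCategory.INHERITED_NONDELETED_PARENT
        )
    # both parents carry the alt
    if child.is_het and deleted_parent.is_hom_alt and nondeleted_parent.is_hom_alt:
        # each parent must transmit an alt, forcing a hom-alt child
        return InheritanceCategory.UNKNOWN_MENDELIAN_VIOLATION
    return InheritanceCategory.INHERITED_AMBIGUOUS


@dataclass
class ClassifiedPdv:
    """A PDV joined with its inheritance category."""

    pdv: PdvRecord
    category: InheritanceCategory

    @property
    def gene(self) -> Optional[str]:
        return self.pdv.variant.gene

    @property
    def child_id(self) -> str:
        return self.pdv.child_id


def classify_pdvs(pdvs: Iterable[PdvRecord]) -> list[ClassifiedPdv]:
    """Classify every PDV from its QC-demoted trio calls."""
    out = []
    for pdv in pdvs:
        category = classify(
            pdv.child_call, pdv.deleted_parent_call, pdv.nondeleted_parent_call
        )
        out.append(ClassifiedPdv(pdv=pdv, category=category))
    return out


def gene_exclusivity(classified: Sequence[ClassifiedPdv]) -> pd.DataFrame:
    """Per-gene inheritance-exclusivity summary across all children.

    Children whose PDVs are all UNKNOWN_MISSING_PARENT (no parental data)
    contribute nothing to the exclusivity flags but are counted. Returns a
    DataFrame indexed by gene with columns ``n_variants`` (distinct
    sites), ``n_children``, ``exclusively_de_novo`` and
    ``exclusively_from_nondeleted``.
    """
    rows: dict[str, dict] = {}
    # children with no parental data are excluded from exclusivity flags
    informative_children = {
        c.child_id
        for c in classified
        if c.category is not InheritanceCategory.UNKNOWN_MISSING_PARENT
    }
    for c in classified:
        if c.gene is None:
            continue
        entry = rows.setdefault(
            c.gene,
            {"variants": set(), "children": set(), "categories": []},
        )
        entry["variants"].add(c.pdv.variant.key)
        entry["children"].add(c.child_id)
        if c.child_id in informative_children:
            entry["categories"].append(c.category)

    records = []
    for gene in sorted(rows):
        entry = rows[gene]
        cats = entry["categories"]
        records.append(
            {
                "gene": gene,
                "n_variants": len(entry["variants"]),
                "n_children": len(entry["children"]),
                "exclusively_de_novo": bool(cats)
                and all(c is InheritanceCategory.DE_NOVO for c in cats),
                "exclusively_from_nondeleted": bool(cats)
                and all(
                    c is InheritanceCategory.INHERITED_NONDELETED_PARENT for c in cats
                ),
            }
        )
    if not records:
        return pd.DataFrame(
            columns=[
                "n_variants",
                "n_children",
                "exclusively_de_novo",
                "exclusively_from_nondeleted",
            ],
            index=pd.Index([], name="gene"),
        )
    return pd.DataFrame.from_records(records, index="gene")


def category_counts(classified: Sequence[ClassifiedPdv]) -> dict[InheritanceCategory, int]:
    counts = {cat: 0 for cat in InheritanceCategory}
    for c in classified:
        counts[c.category] += 1
    return counts
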