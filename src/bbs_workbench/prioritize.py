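"""Quality/rarity/consequence/deleteriousness cascade selecting PDVs.

The cascade reduces all called variants to "potentially damaging variants"
(PDVs) in the affected child of each trio. Stages, in order:

1. ``protein_coding`` — the variant lies in a protein-coding transcript;
2. ``child_carrier`` — the child's genotype is present and carries the alt;
3. ``genotype_qc`` — the child call passes GQ/depth hard filters (parents
   failing QC are demoted to missing for later inheritance work, the
   variant itself is kept);
4. ``rarity`` — maximum reference-population allele frequency < 0.01%
   (variants unobserved in any reference population count as rare);
5. ``severity`` — a moderately or highly protein-damaging consequence;
6. ``deleterious_triage`` — missense / start-loss SNVs additionally need
   SIFT < 0.05, PolyPhen >= 0.70 and Grantham >= 100.

Depth thresholds differ by variant class: SNVs need DP >= 10; indels need
DP >= 28 when up to 5 bp long and DP >= 42 when 5-200 bp; indels longer
than 200 bp are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from enum import Enum
from typing import Iterable, Optional, Sequence

import yaml

from .model import AnnotatedVariant, GenotypeCall, MISSING_CALL, TrioPedigree


class Severity(Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    NONE = "NONE"


#: Consequence terms considered highly likely to damage the protein product.
HIGH_TERMS = frozenset(
    {"splice_site", "stop_gained", "stop_lost", "start_lost", "frameshift"}
)
#: Consequence terms considered moderately likely to damage the protein product.
MODERATE_TERMS = frozenset(
    {"inframe_insertion", "inframe_deletion", "missense", "protein_altering"}
)
#: Terms that trigger the SIFT/PolyPhen/Grantham triage (SNVs only).
TRIAGE_TERMS = frozenset({"missense", "start_lost"})

CASCADE_STAGES = (
    "protein_coding",
    "child_carrier",
    "genotype_qc",
    "rarity",
    "severity",
    "deleterious_triage",
)


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds of the cascade (defaults are the study's)."""

    gq_min: float = 20.0
    snv_dp_min: int = 10
    indel_dp_min_short: int = 28
    indel_dp_min_long: int = 42
    indel_short_max_len: int = 5
    indel_len_max: int = 200
    max_af_threshold: float = 0.0001  # fraction form of "< 0.01%"
    sift_max: float = 0.05
    polyphen_min: float = 0.70
    grantham_min: float = 100.0

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.indel_short_max_len >= self.indel_len_max:
            raise ValueError("indel_short_max_len must be < indel_len_max")

    @staticmethod
    def from_yaml(path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclass_fields(FilterConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown filter-config fields: {sorted(unknown)}")
        return FilterConfig(**raw)


@dataclass
class PdvRecord:
    """One PDV in one child, with stage provenance and effective trio calls.

    ``deleted_parent_call`` / ``nondeleted_parent_call`` hold the parent
    genotypes *after* QC demotion (a parent call failing GQ/depth filters
    is replaced by a missing call), which is what inheritance
    classification should consume.
    """

    variant: AnnotatedVariant
    child_id: str
    family_id: str
    severity: Severity
    passed_stages: tuple[str, ...]
    child_call: GenotypeCall
    deleted_parent_call: Optional[GenotypeCall]
    nondeleted_parent_call: Optional[GenotypeCall]


def genotype_qc(
    call: GenotypeCall,
    variant_class: str,
    indel_length: int,
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """GQ/depth hard filter for one genotype call (total function).

    Absent DP or GQ fails; indels longer than ``indel_len_max`` fail
    regardless of depth. The boundary at ``indel_short_max_len`` uses the
    laxer short-indel depth requirement.
    """
    if call.gq is None or call.dp is None:
        return False
    if call.gq < cfg.gq_min:
        return False
    if variant_class == "SNV":
        return call.dp >= cfg.snv_dp_min
    if indel_length > cfg.indel_len_max:
        return False
    if indel_length <= cfg.indel_short_max_len:
        return call.dp >= cfg.indel_dp_min_short
    return call.dp >= cfg.indel_dp_min_long


def rarity_pass(max_af: Optional[float], cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff the variant is unobserved in reference populations or rarer
    than the threshold (strict ``<``)."""
    if max_af is None:
        return True
    if not (0.0 <= max_af <= 1.0):
        raise ValueError(f"max_af must lie in [0, 1]; got {max_af}")
    return max_af < cfg.max_af_threshold


def severity_of(consequence_terms: Iterable[str]) -> Severity:
    terms = set(consequence_terms)
    if terms & HIGH_TERMS:
        return Severity.HIGH
    if terms & MODERATE_TERMS:
        return Severity.MODERATE
    return Severity.NONE


def deleterious_triage(variant: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    """Score-based triage of missense / start-loss SNVs.

    Requires SIFT < ``sift_max`` AND PolyPhen >= ``polyphen_min`` AND
    Grantham >= ``grantham_min``; any absent score fails. Variants whose
    qualifying consequences lie outside the triage set pass unconditionally.
    """
    if variant.variant_class != "SNV" or not (variant.consequence_terms & TRIAGE_TERMS):
        return True
    if variant.sift is None or variant.polyphen is None or variant.grantham is None:
        return False
    return (
        variant.sift < cfg.sift_max
        and variant.polyphen >= cfg.polyphen_min
        and variant.grantham >= cfg.grantham_min
    )


def _effective_parent_call(
    variant: AnnotatedVariant, parent_id: Optional[str], cfg: FilterConfig
) -> Optional[GenotypeCall]:
    """Parent call demoted to missing when absent or failing QC."""
    if parent_id is None:
        return None
    call = variant.genotypes.get(parent_id, MISSING_CALL)
    if call.is_missing:
        return MISSING_CALL
    if not genotype_qc(call, variant.variant_class, variant.indel_length, cfg):
        return MISSING_CALL
    return call


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    pedigrees: Sequence[TrioPedigree],
    cfg: FilterConfig = FilterConfig(),
) -> list[PdvRecord]:
    """Apply the full cascade for the child of every pedigree.

    Returns one :class:`PdvRecord` per (child, variant) that survives all
    stages, in input order; the record carries the ordered stage
    provenance and the QC-demoted parental calls.
    """
    out: list[PdvRecord] = []
    for ped in pedigrees:
        for variant in variants:
            record = _evaluate(variant, ped, cfg)
            if record is not None:
                out.append(record)
    return out


def _evaluate(
    variant: AnnotatedVariant, ped: TrioPedigree, cfg: FilterConfig
) -> Optional[PdvRecord]:
    if not variant.biotype_protein_coding:
        return None
    child = variant.genotypes.get(ped.child_id, MISSING_CALL)
    if child.is_missing or not child.carries_alt:
        return None
    if not genotype_qc(child, variant.variant_class, variant.indel_length, cfg):
        return None
    if not rarity_pass(variant.max_af, cfg):
        return None
    severity = severity_of(variant.consequence_terms)
    if severity is Severity.NONE:
        return None
    if not deleterious_triage(variant, cfg):
        return None
    return PdvRecord(
        variant=variant,
        child_id=ped.child_id,
        family_id=ped.family_id,
        severity=severity,
        passed_stages=CASCADE_STAGES,
        child_call=child,
        deleted_parent_call=_effective_parent_call(variant, ped.deleted_parent_id, cfg),
        nondeleted_parent_call=_effective_parent_call(variant, ped.nondeleted_parent_id, cfg),
    )


def stage_counts(
    variants: Sequence[AnnotatedVariant],
    ped: TrioPedigree,
    cfg: FilterConfig = FilterConfig(),
) -> dict[str, int]:
    """Records surviving after each stage for one trio (for run manifests)."""
    counts = {}
    survivors = list(variants)

    def keep(stage, pred):
        nonlocal survivors
        survivors = [v for v in survivors if pred(v)]
        counts[stage] = len(survivors)

    keep("protein_coding", lambda v: v.biotype_protein_coding)
    keep(
        "child_carrier",
        lambda v: (c := v.genotypes.get(ped.child_id, MISSING_CALL)) is not None
        and not c.is_missing
        and c.carries_alt,
    )
    keep(
        "genotype_qc",
        lambda v: genotype_qc(
            v.genotypes.get(ped.child_id, MISSING_CALL), v.variant_class, v.indel_length, cfg
        ),
    )
    keep("rarity", lambda v: rarity_pass(v.max_af, cfg))
    keep("severity", lambda v: severity_of(v.consequence_terms) is not Severity.NONE)
    keep("deleterious_triage", lambda v: deleterious_triage(v, cfg))
    return counts
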