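"""Synthetic trio-exome and force-platform data with recorded ground truth.

The trio generator writes a multi-sample VCF, an extended PED file and a
truth table. Genotypes are constructed to realize the defining trio
configuration of each requested inheritance category, annotations are
drawn from a consequence-class mixture shaped like a trio-exome PDV
spectrum, and "planted failure" variants each violate exactly one cascade
stage so that stage-level diagnostics are testable.

The sway generator emits per-trial CSVs (force/moment channels by
default, obtained by inverting the COP derivation under a constant
vertical load) whose COP paths are Ornstein-Uhlenbeck processes: mean
reverting, Gaussian, with stationary SD = noise / sqrt(2 * rate), which
the truth table records per axis and group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .inheritance import InheritanceCategory
from .model import TrioPedigree

# ---------------------------------------------------------------------------
# Trio exome simulation

#: Defining trio genotype configuration per category:
#: (child, deleted parent, nondeleted parent); None = missing call.
_CATEGORY_CONFIG: dict[InheritanceCategory, tuple] = {
    InheritanceCategory.DE_NOVO: ((0, 1), (0, 0), (0, 0)),
    InheritanceCategory.INHERITED_DELETED_PARENT: ((0, 1), (0, 1), (0, 0)),
    InheritanceCategory.INHERITED_NONDELETED_PARENT: ((0, 1), (0, 0), (0, 1)),
    InheritanceCategory.INHERITED_AMBIGUOUS: ((0, 1), (0, 1), (0, 1)),
    InheritanceCategory.UNKNOWN_MENDELIAN_VIOLATION: ((0, 1), (1, 1), (1, 1)),
    InheritanceCategory.UNKNOWN_IMPROBABLE_HOM_DENOVO: ((1, 1), (0, 0), (0, 1)),
    InheritanceCategory.UNKNOWN_MISSING_PARENT: ((0, 1), None, (0, 1)),
}

#: Cascade stages a planted failure can target (single-fault).
FAILURE_STAGES = (
    "protein_coding",
    "genotype_qc",
    "rarity",
    "severity",
    "deleterious_triage",
)

#: Default consequence-class mixture: a trio-exome PDV spectrum dominated
#: by missense, then frameshifts, inframe indels and splice-site changes.
DEFAULT_CONSEQUENCE_MIX = {
    "missense": 0.407,
    "frameshift": 0.179,
    "inframe_insertion": 0.0886,
    "inframe_deletion": 0.0886,
    "splice_site": 0.1029,
    "stop_gained": 0.0613,
    "stop_lost": 0.0613,
    "start_lost": 0.0037,
    "protein_altering": 0.0076,
}

_SNV_CLASSES = {"missense", "splice_site", "stop_gained", "stop_lost", "start_lost",
                "protein_altering"}


@dataclass
class TrioSimConfig:
    """Configuration of the synthetic annotated trio-exome generator."""

    n_families: int = 5
    category_counts: dict[InheritanceCategory, int] = field(
        default_factory=lambda: {
            InheritanceCategory.DE_NOVO: 25,
            InheritanceCategory.INHERITED_DELETED_PARENT: 20,
            InheritanceCategory.INHERITED_NONDELETED_PARENT: 25,
            InheritanceCategory.INHERITED_AMBIGUOUS: 10,
            InheritanceCategory.UNKNOWN_MENDELIAN_VIOLATION: 5,
            InheritanceCategory.UNKNOWN_IMPROBABLE_HOM_DENOVO: 5,
            InheritanceCategory.UNKNOWN_MISSING_PARENT: 10,
        }
    )
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    fail_counts: dict[str, int] = field(
        default_factory=lambda: {stage: 10 for stage in FAILURE_STAGES}
    )
    dp_mean: float = 60.0
    dp_dispersion: float = 10.0  # negative-binomial shape; larger = tighter
    gq_mean: float = 85.0
    gq_sd: float = 10.0
    af_absent_mass: float = 0.5  # point mass at "not observed in any population"
    n_genes: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if any(n < 0 for n in self.category_counts.values()):
            raise ValueError("category counts must be non-negative")
        total = sum(self.consequence_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"consequence mixture weights must sum to 1 (got {total})")


@dataclass
class TrioSimOutput:
    vcf: Path
    ped: Path
    truth: Path
    pedigrees: list[TrioPedigree]


def _draw_dp(rng, cfg: TrioSimConfig, minimum: int) -> int:
    shape = cfg.dp_dispersion
    p = shape / (shape + cfg.dp_mean)
    return int(max(minimum, rng.negative_binomial(shape, p)))


def _draw_gq(rng, cfg: TrioSimConfig) -> float:
    return float(np.clip(rng.normal(cfg.gq_mean, cfg.gq_sd), 20.0, 99.0))


def _alleles_for_class(cls: str, rng) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    if cls in _SNV_CLASSES:
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        return ref, alt
    ins = "".join(bases[rng.integers(4)] for _ in range(3))
    if cls == "inframe_deletion":
        return ref + ins, ref
    if cls == "frameshift":
        return ref, ref + bases[rng.integers(4)]
    return ref, ref + ins  # inframe_insertion


def _min_dp(ref: str, alt: str) -> int:
    """Depth a passing call needs, by variant class and indel length."""
    indel_len = abs(len(alt) - len(ref))
    if indel_len == 0:
        return 10
    return 28 if indel_len <= 5 else 42


def _format_call(gt, dp: Optional[int], gq: Optional[float]) -> str:
    if gt is None:
        return "./.:.:."
    return f"{gt[0]}/{gt[1]}:{dp}:{gq:.1f}"


def simulate_trios(cfg: TrioSimConfig, out_dir) -> TrioSimOutput:
    """Write ``trios.vcf``, ``trios.ped`` and ``truth.tsv`` under ``out_dir``.

    Planted-category variants are distributed round-robin over families
    and constructed to pass every cascade stage; planted failures violate
    exactly one stage each (on a de novo genotype background). The truth
    table records, per variant row, the family, the planted category, the
    targeted failure stage (empty for passers) and whether the cascade is
    expected to retain it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 1])

    families = [f"F{i + 1}" for i in range(cfg.n_families)]
    pedigrees = []
    for i, fam in enumerate(families):
        # mirror the study design: most carriers are mothers, one a father
        mother, father, child = f"{fam}_MO", f"{fam}_FA", f"{fam}_CH"
        deleted, nondeleted = (mother, father) if i % 5 != 4 else (father, mother)
        pedigrees.append(
            TrioPedigree(
                family_id=fam,
                child_id=child,
                deleted_parent_id=deleted,
                nondeleted_parent_id=nondeleted,
            )
        )
    samples = [s for ped in pedigrees for s in (ped.child_id, *ped.parent_ids)]
    gene_pool = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    classes = sorted(cfg.consequence_mix)
    weights = np.array([cfg.consequence_mix[c] for c in classes])
    weights = weights / weights.sum()

    plan: list[dict] = []  # one entry per variant row
    fam_cycle = 0
    for category in sorted(cfg.category_counts, key=lambda c: c.value):
        for _ in range(cfg.category_counts[category]):
            plan.append(
                {
                    "family": families[fam_cycle % len(families)],
                    "category": category,
                    "fail_stage": "",
                }
            )
            fam_cycle += 1
    for stage in FAILURE_STAGES:
        for _ in range(cfg.fail_counts.get(stage, 0)):
            plan.append(
                {
                    "family": families[fam_cycle % len(families)],
                    "category": InheritanceCategory.DE_NOVO,
                    "fail_stage": stage,
                }
            )
            fam_cycle += 1

    ped_by_family = {p.family_id: p for p in pedigrees}
    records = []
    truth_rows = []
    pos_by_chrom: dict[str, int] = {}
    for item in plan:
        fail = item["fail_stage"]
        cls = str(rng.choice(classes, p=weights))
        if fail == "severity":
            cls = "synonymous"
            ref, alt = _alleles_for_class("missense", rng)
        elif fail == "deleterious_triage":
            cls = "missense"
            ref, alt = _alleles_for_class(cls, rng)
        else:
            ref, alt = _alleles_for_class(cls, rng)
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos_by_chrom[chrom] = pos_by_chrom.get(chrom, 10_000) + int(rng.integers(500, 5_000))
        pos = pos_by_chrom[chrom]
        gene = gene_pool[int(rng.integers(cfg.n_genes))]

        biotype = "protein_coding"
        if rng.random() < cfg.af_absent_mass:
            max_af = None
        else:
            max_af = float(rng.uniform(0.0, 0.0001)) * 0.999  # strictly below 0.01%
        sift = polyphen = grantham = None
        if cls == "missense" or cls == "start_lost":
            sift = float(rng.uniform(0.0, 0.049))
            polyphen = float(rng.uniform(0.70, 1.0))
            grantham = float(rng.uniform(100.0, 215.0))

        min_dp = _min_dp(ref, alt)
        child_dp, child_gq = _draw_dp(rng, cfg, min_dp), _draw_gq(rng, cfg)

        if fail == "protein_coding":
            biotype = "lincRNA"
        elif fail == "genotype_qc":
            if rng.random() < 0.5:
                child_gq = float(rng.uniform(0.0, 19.9))
            else:
                child_dp = int(rng.integers(0, min_dp))
        elif fail == "rarity":
            max_af = float(rng.uniform(0.0001, 0.01))
        elif fail == "deleterious_triage":
            sift = float(rng.uniform(0.05, 1.0))  # benign by SIFT alone

        ped = ped_by_family[item["family"]]
        child_gt, del_gt, nondel_gt = _CATEGORY_CONFIG[item["category"]]
        calls = {}
        for sample in samples:
            if sample == ped.child_id:
                calls[sample] = _format_call(child_gt, child_dp, child_gq)
            elif sample == ped.deleted_parent_id:
                calls[sample] = _format_call(
                    del_gt, _draw_dp(rng, cfg, min_dp), _draw_gq(rng, cfg)
                )
            elif sample == ped.nondeleted_parent_id:
                calls[sample] = _format_call(
                    nondel_gt, _draw_dp(rng, cfg, min_dp), _draw_gq(rng, cfg)
                )
            else:
                calls[sample] = _format_call(
                    (0, 0), _draw_dp(rng, cfg, min_dp), _draw_gq(rng, cfg)
                )

        info = [f"GENE={gene}", f"BIOTYPE={biotype}", f"CSQCLASS={cls}"]
        if max_af is not None:
            info.append(f"MAX_AF={max_af:.10g}")
        if sift is not None:
            info.extend(
                [f"SIFT={sift:.6g}", f"POLYPHEN={polyphen:.6g}", f"GRANTHAM={grantham:.6g}"]
            )
        records.append(
            (chrom, pos, ref, alt, ";".join(info), [calls[s] for s in samples])
        )
        expected_pdv = fail == ""
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": cls,
                "family_id": item["family"],
                "child_id": ped.child_id,
                "planted_category": item["category"].value,
                "fail_stage": fail,
                "expected_pdv": int(expected_pdv),
            }
        )

    def chrom_key(rec):
        return (int(rec[0][3:]), rec[1])

    order = sorted(range(len(records)), key=lambda i: chrom_key(records[i]))
    records = [records[i] for i in order]
    truth_rows = [truth_rows[i] for i in order]

    vcf_path = out_dir / "trios.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for i in range(1, 23):
            fh.write(f"##contig=<ID=chr{i}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=BIOTYPE,Number=1,Type=String,Description="Transcript biotype">\n')
        fh.write('##INFO=<ID=CSQCLASS,Number=A,Type=String,Description="Consequence terms (&-joined)">\n')
        fh.write('##INFO=<ID=MAX_AF,Number=A,Type=Float,Description="Max reference-population AF">\n')
        fh.write('##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT score">\n')
        fh.write('##INFO=<ID=POLYPHEN,Number=A,Type=Float,Description="PolyPhen score">\n')
        fh.write('##INFO=<ID=GRANTHAM,Number=A,Type=Float,Description="Grantham distance">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, info, calls in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DP:GQ\t"
                + "\t".join(calls)
                + "\n"
            )

    ped_path = out_dir / "trios.ped"
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            father = ped.deleted_parent_id if ped.deleted_parent_id.endswith("FA") else ped.nondeleted_parent_id
            mother = ped.deleted_parent_id if ped.deleted_parent_id.endswith("MO") else ped.nondeleted_parent_id
            for sid, fa, mo, sex in (
                (father, "0", "0", "1"),
                (mother, "0", "0", "2"),
                (ped.child_id, father, mother, "0"),
            ):
                carrier = "1" if sid == ped.deleted_parent_id or sid == ped.child_id else "0"
                fh.write(f"{ped.family_id}\t{sid}\t{fa}\t{mo}\t{sex}\t2\t{carrier}\n")

    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return TrioSimOutput(vcf=vcf_path, ped=ped_path, truth=truth_path, pedigrees=pedigrees)


# ---------------------------------------------------------------------------
# Postural-sway simulation


@dataclass
class GroupSwayParams:
    """Per-axis Ornstein-Uhlenbeck parameters for one group.

    ``rate`` is the mean-reversion rate (1/s); ``noise`` the diffusion
    scale (cm/sqrt(s)); the stationary SD per axis is
    noise / sqrt(2 * rate) cm.
    """

    rate_ml: float = 1.0
    rate_ap: float = 1.0
    noise_ml: float = 0.87  # => stationary ML SD ~ 0.61 cm
    noise_ap: float = 1.03  # => stationary AP SD ~ 0.73 cm

    @property
    def stationary_sd_ml(self) -> float:
        return self.noise_ml / math.sqrt(2.0 * self.rate_ml)

    @property
    def stationary_sd_ap(self) -> float:
        return self.noise_ap / math.sqrt(2.0 * self.rate_ap)


@dataclass
class SwaySimConfig:
    """Configuration of the synthetic force-platform generator.

    Defaults emulate quiet standing in a small case/control cohort: three
    30 s trials per participant recorded at 100 Hz, with the affected
    group's sway variability elevated relative to controls.
    """

    n_participants: dict[str, int] = field(
        default_factory=lambda: {"affected": 6, "control": 6}
    )
    trials_per_participant: int = 3
    duration: float = 30.0
    sample_rate: float = 100.0
    groups: dict[str, GroupSwayParams] = field(
        default_factory=lambda: {
            "affected": GroupSwayParams(),
            "control": GroupSwayParams(noise_ml=0.66, noise_ap=0.93),
        }
    )
    unusable_trial_probability: float = 0.05
    cohort: str = "child"
    as_forces: bool = True
    body_weight_n: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 25.0:
            raise ValueError("trials must be at least 25 s (5 s trim + 20 s window)")
        for name, params in self.groups.items():
            for f in ("rate_ml", "rate_ap", "noise_ml", "noise_ap"):
                if getattr(params, f) <= 0:
                    raise ValueError(f"group {name!r}: {f} must be positive")


@dataclass
class SwaySimOutput:
    trial_dir: Path
    groups_tsv: Path
    truth: Path


def ou_series(
    n: int, dt: float, rate: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact discretization of a stationary OU process started at equilibrium."""
    stationary_sd = noise / math.sqrt(2.0 * rate)
    phi = math.exp(-rate * dt)
    innovation_sd = stationary_sd * math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, stationary_sd)
    eps = rng.normal(0.0, innovation_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_sway(cfg: SwaySimConfig, out_dir) -> SwaySimOutput:
    """Write per-trial CSVs, a groups TSV and a truth table under ``out_dir``.

    Unusable trials are realized as truncated recordings (10 s), which
    the pipeline rejects at the duration check. With ``as_forces`` the
    COP path is converted to force/moment channels under a constant
    vertical load (the exact inverse of the COP derivation).
    """
    out_dir = Path(out_dir)
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(parents=True, exist_ok=True)
    dt = 1.0 / cfg.sample_rate
    n_full = int(round(cfg.duration * cfg.sample_rate))

    group_rows = []
    truth_rows = []
    file_index = 0
    for group in sorted(cfg.n_participants):
        params = cfg.groups[group]
        for p in range(cfg.n_participants[group]):
            pid = f"{group.upper()}{p + 1:02d}"
            group_rows.append({"participant_id": pid, "group": group, "cohort": cfg.cohort})
            for trial in range(1, cfg.trials_per_participant + 1):
                file_index += 1
                rng = np.random.default_rng([cfg.seed, 2, file_index])
                unusable = bool(rng.random() < cfg.unusable_trial_probability)
                n = int(round(10.0 * cfg.sample_rate)) if unusable else n_full
                ml = ou_series(n, dt, params.rate_ml, params.noise_ml, rng)
                ap = ou_series(n, dt, params.rate_ap, params.noise_ap, rng)
                t = np.arange(n) * dt
                path = trial_dir / f"{pid}_trial{trial}.csv"
                if cfg.as_forces:
                    fz = np.full(n, cfg.body_weight_n)
                    df = pd.DataFrame(
                        {
                            "t": t,
                            "Fx": np.zeros(n),
                            "Fy": np.zeros(n),
                            "Fz": fz,
                            "Mx": ap / 100.0 * fz,  # cop_ap = Mx / Fz (m -> cm)
                            "My": -ml / 100.0 * fz,  # cop_ml = -My / Fz
                            "Mz": np.zeros(n),
                        }
                    )
                else:
                    df = pd.DataFrame({"t": t, "cop_ml": ml, "cop_ap": ap})
                df.to_csv(path, index=False, float_format="%.10g")
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "trial": trial,
                        "file": path.name,
                        "planted_unusable": int(unusable),
                        "stationary_sd_ml": params.stationary_sd_ml,
                        "stationary_sd_ap": params.stationary_sd_ap,
                    }
                )

    groups_tsv = out_dir / "groups.tsv"
    pd.DataFrame(group_rows).to_csv(groups_tsv, sep="\t", index=False)
    truth_path = out_dir / "sway_truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return SwaySimOutput(trial_dir=trial_dir, groups_tsv=groups_tsv, truth=truth_path)
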