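"""Stage orchestration: run the variant and posture arms, write reports.

Reports are plain TSV/JSON. A run manifest records the configuration, the
record counts entering and surviving each cascade stage, and the category
tallies, so that a rerun on unchanged inputs is verifiable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import genesets, posture, variant_io
from .inheritance import category_counts, classify_pdvs, gene_exclusivity
from .prioritize import FilterConfig, run_cascade, stage_counts


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


def _config_hash(cfg: FilterConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_variant_arm(
    vcf_path,
    ped_path,
    out_dir,
    cfg: FilterConfig = FilterConfig(),
    panels_dir=None,
    edges_path=None,
    keys: Optional[variant_io.AnnotationKeys] = None,
) -> dict:
    """Load -> prioritize -> classify -> summarize; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys = keys or variant_io.AnnotationKeys()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    pedigrees = stage("read_pedigree", variant_io.read_pedigree, ped_path)
    variants = stage("read_trio_vcf", variant_io.read_trio_vcf, vcf_path, pedigrees, keys)
    pdvs = stage("run_cascade", run_cascade, variants, pedigrees, cfg)
    classified = stage("classify", classify_pdvs, pdvs)

    rows = []
    for c in classified:
        v = c.pdv.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence_terms": "&".join(sorted(v.consequence_terms)),
                "family_id": c.pdv.family_id,
                "child_id": c.pdv.child_id,
                "severity": c.pdv.severity.value,
                "category": c.category.value,
                "passed_stages": ",".join(c.pdv.passed_stages),
            }
        )
    pdv_columns = [
        "chrom", "pos", "ref", "alt", "gene", "consequence_terms",
        "family_id", "child_id", "severity", "category", "passed_stages",
    ]
    pd.DataFrame(rows, columns=pdv_columns).to_csv(out_dir / "pdv.tsv", sep="\t", index=False)

    exclusivity = gene_exclusivity(classified)
    exclusivity.to_csv(out_dir / "gene_exclusivity.tsv", sep="\t")

    panels = variant_io.read_panels(panels_dir) if panels_dir else []
    summary = genesets.burden(pdvs, panels)
    summary.per_child.to_csv(out_dir / "burden_per_child.tsv", sep="\t")
    summary.cohort.to_csv(out_dir / "burden_cohort.tsv", sep="\t")
    if pdvs:
        genesets.spectrum(pdvs).to_csv(out_dir / "spectrum.tsv", sep="\t")

    if panels:
        universe = len({v.gene for v in variants if v.gene is not None})
        pdv_genes = {p.variant.gene for p in pdvs if p.variant.gene is not None}
        enrichment = genesets.overrepresentation(pdv_genes, panels, universe_size=universe)
        enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t")

    if edges_path:
        edges = variant_io.read_edges(edges_path)
        pdv_genes = {p.variant.gene for p in pdvs if p.variant.gene is not None}
        flags = genesets.interactor_flags(pdv_genes, edges, exclusivity=exclusivity)
        flags.to_csv(out_dir / "interactors.tsv", sep="\t")

    per_trio_counts = {
        ped.family_id: stage_counts(variants, ped, cfg) for ped in pedigrees
    }
    aggregate = defaultdict(int)
    for counts in per_trio_counts.values():
        for k, v in counts.items():
            aggregate[k] += v
    manifest = {
        "config_hash": _config_hash(cfg),
        "filter_config": asdict(cfg),
        "n_families": len(pedigrees),
        "n_input_variants": len(variants),
        "n_pdvs": len(pdvs),
        "stage_counts_per_trio": per_trio_counts,
        "stage_counts_total": dict(aggregate),
        "category_counts": {k.value: v for k, v in category_counts(classified).items()},
        "n_panels": len(panels),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_posture_arm(trials_dir, groups_tsv, out_dir) -> dict:
    """Process every participant's trials and write the group comparison.

    Trial files are expected as ``<participant_id>_*.csv`` under
    ``trials_dir``; ``groups_tsv`` maps participant -> group (affected or
    control) and cohort (child or adult).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = pd.read_csv(groups_tsv, sep="\t")
    required = {"participant_id", "group", "cohort"}
    if not required <= set(groups.columns):
        raise StageError(f"stage 'read_groups' failed: columns {sorted(required)} required")

    trial_rows = []
    participant_metrics: dict[str, posture.SwayMetrics] = {}
    excluded = {}
    for _, row in groups.iterrows():
        pid = row["participant_id"]
        files = sorted(Path(trials_dir).glob(f"{pid}_*.csv"))
        trials = []
        for path in files:
            trial = posture.read_trial_csv(path, participant_id=pid)
            trial = posture.preprocess(trial)
            metrics = posture.sway_metrics(trial)
            trials.append(trial)
            trial_rows.append(
                {
                    "participant_id": pid,
                    "group": row["group"],
                    "cohort": row["cohort"],
                    "file": path.name,
                    "usable": int(trial.usable),
                    "reason": trial.reason,
                    "cop_length": metrics.cop_length if metrics else float("nan"),
                    "ml_sd_log": metrics.ml_sd_log if metrics else float("nan"),
                    "ap_sd_log": metrics.ap_sd_log if metrics else float("nan"),
                }
            )
        agg = posture.aggregate_participant(trials)
        if agg is None:
            excluded[pid] = "fewer than two usable trials"
        else:
            participant_metrics[pid] = agg

    pd.DataFrame(trial_rows).to_csv(out_dir / "trial_metrics.tsv", sep="\t", index=False)

    comparison_frames = []
    for cohort, sub in groups.groupby("cohort"):
        affected = [
            participant_metrics[p]
            for p in sub.loc[sub["group"] == "affected", "participant_id"]
            if p in participant_metrics
        ]
        control = [
            participant_metrics[p]
            for p in sub.loc[sub["group"] == "control", "participant_id"]
            if p in participant_metrics
        ]
        if len(affected) < 2 or len(control) < 2:
            continue
        cmp = posture.compare_groups(affected, control)
        table = cmp.table.reset_index()
        table.insert(0, "cohort", cohort)
        table["n_affected"] = cmp.n_affected
        table["n_control"] = cmp.n_control
        comparison_frames.append(table)
    if comparison_frames:
        pd.concat(comparison_frames, ignore_index=True).to_csv(
            out_dir / "group_comparison.tsv", sep="\t", index=False
        )

    manifest = {
        "n_participants": int(len(groups)),
        "n_trials": len(trial_rows),
        "n_usable_trials": int(sum(r["usable"] for r in trial_rows)),
        "excluded_participants": excluded,
    }
    with open(out_dir / "posture_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
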