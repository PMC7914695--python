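"""Gene-panel burden, consequence spectrum, overrepresentation, interactors.

Burden summaries count PDVs and distinct affected genes per child and
against disease panels (SFARI ASD list, clinical testing panels), with
cohort means and sample SDs. Overrepresentation of PDV genes in a panel is
scored with a hypergeometric upper tail and Benjamini-Hochberg correction
across panels. Interactor flagging cross-references PDV genes against a
protein-interaction edge list around the four 15q11.2 BP1-BP2 genes
(TUBGCP5, CYFIP1, NIPA1, NIPA2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .inheritance import ClassifiedPdv
from .model import GenePanel, InteractionEdge
from .prioritize import HIGH_TERMS, MODERATE_TERMS, PdvRecord

DEFAULT_INTERACTION_TARGETS = frozenset({"CYFIP1", "TUBGCP5", "NIPA1", "NIPA2"})

#: Display order of consequence classes; a PDV with several qualifying
#: terms is counted once, under its first matching (most severe) class.
CONSEQUENCE_CLASSES = (
    "frameshift",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_site",
    "inframe_insertion",
    "inframe_deletion",
    "missense",
    "protein_altering",
)


@dataclass
class BurdenSummary:
    per_child: pd.DataFrame  # index child_id; n_pdvs, n_genes, panel columns
    cohort: pd.DataFrame  # index quantity; mean, sd (ddof=1)


def burden(pdvs: Sequence[PdvRecord], panels: Sequence[GenePanel]) -> BurdenSummary:
    """Per-child PDV and panel-gene counts with cohort mean/SD (n-1)."""
    children = sorted({p.child_id for p in pdvs})
    rows = []
    for child in children:
        mine = [p for p in pdvs if p.child_id == child]
        genes = {p.variant.gene for p in mine if p.variant.gene is not None}
        row = {"child_id": child, "n_pdvs": len(mine), "n_genes": len(genes)}
        for panel in panels:
            row[panel.name] = len(genes & panel.genes)
        rows.append(row)
    per_child = (
        pd.DataFrame(rows).set_index("child_id")
        if rows
        else pd.DataFrame(
            columns=["n_pdvs", "n_genes", *[p.name for p in panels]],
            index=pd.Index([], name="child_id"),
        )
    )
    cohort = pd.DataFrame(
        {
            "mean": per_child.mean(),
            "sd": per_child.std(ddof=1),
        }
    )
    cohort.index.name = "quantity"
    return BurdenSummary(per_child=per_child, cohort=cohort)


def _primary_class(terms: frozenset[str]) -> Optional[str]:
    for cls in CONSEQUENCE_CLASSES:
        if cls in terms:
            return cls
    return None


def spectrum(pdvs: Sequence[PdvRecord]) -> pd.Series:
    """Proportion of PDVs per predicted-consequence class.

    Proportions are over the total PDV count, so classes outside the
    reported set can leave the sum below 1.
    """
    if not pdvs:
        raise ValueError("spectrum() requires at least one PDV")
    counts = {cls: 0 for cls in CONSEQUENCE_CLASSES}
    for p in pdvs:
        cls = _primary_class(p.variant.consequence_terms)
        if cls is not None:
            counts[cls] += 1
    total = len(pdvs)
    return pd.Series({cls: n / total for cls, n in counts.items()}, name="proportion")


def hypergeom_upper_tail(k: int, universe_size: int, panel_size: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe_size, panel_size, n_drawn)."""
    return float(hypergeom.sf(k - 1, universe_size, panel_size, n_drawn))


def overrepresentation(
    pdv_genes: Iterable[str],
    panels: Sequence[GenePanel],
    universe_size: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric panel overrepresentation with BH correction.

    ``universe_size`` is the number of genes eligible to be drawn (by
    default upstream callers use the count of distinct genes bearing any
    variant pre-cascade). Raises if any panel union with the drawn set
    exceeds the universe.
    """
    genes = {g.upper() for g in pdv_genes}
    rows = []
    for panel in panels:
        if universe_size < len(genes | panel.genes):
            raise ValueError(
                f"universe_size={universe_size} smaller than |drawn ∪ panel| "
                f"for panel {panel.name!r}"
            )
        k = len(genes & panel.genes)
        p_raw = hypergeom_upper_tail(k, universe_size, len(panel.genes), len(genes))
        rows.append(
            {
                "panel": panel.name,
                "panel_size": len(panel.genes),
                "n_drawn": len(genes),
                "overlap": k,
                "p_raw": p_raw,
            }
        )
    df = pd.DataFrame(rows).set_index("panel")
    if len(df):
        _, p_bh, _, _ = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")
        df["p_bh"] = np.minimum(p_bh, 1.0)
        df["significant"] = df["p_bh"] <= alpha
    else:
        df["p_bh"] = []
        df["significant"] = []
    return df


def interactor_flags(
    genes: Iterable[str],
    edges: Sequence[InteractionEdge],
    targets: frozenset[str] = DEFAULT_INTERACTION_TARGETS,
    exclusivity: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Flag genes with a protein-protein edge to a 15q11.2 BP1-BP2 gene.

    ``exclusivity`` may be the per-gene summary from
    :func:`~bbs_workbench.inheritance.gene_exclusivity`; its flags are
    joined onto the output when provided.
    """
    gene_set = {g.upper() for g in genes}
    rows = []
    for edge in edges:
        if edge.relation != "PP":
            continue
        for target in targets:
            if edge.touches(target):
                partner = edge.partner(target)
                if partner in gene_set and partner not in targets:
                    rows.append({"gene": partner, "target": target, "relation": edge.relation})
    if not rows:
        df = pd.DataFrame(columns=["gene", "target", "relation"])
    else:
        df = pd.DataFrame(rows).drop_duplicates().sort_values(["gene", "target"])
    df = df.set_index("gene")
    if exclusivity is not None and len(df):
        df = df.join(
            exclusivity[["exclusively_de_novo", "exclusively_from_nondeleted"]],
            how="left",
        )
    return df
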