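"""RNA-protein concordance: join, correlation, and classification.

Genes quantified at both the RNA and protein level are compared on their
log2(DUX4/Control) fold changes. A gene is called *changed* on an axis
when |log2 FC| >= ``change_threshold`` (default 2, i.e. 4-fold) and
*unchanged* when |log2 FC| <= ``null_band`` (default 1). Crossing the two
axes yields the concordance classes: concordant up/down, RNA-only
("post-transcriptionally buffered"), protein-only ("discordant"),
opposite, unchanged, and an explicit intermediate class for genes between
the null band and the change threshold — the partition is exhaustive and
mutually exclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONCORDANCE_CLASSES",
    "ClassThresholds",
    "merge_rna_protein",
    "pearson_correlation",
    "classify_genes",
    "contingency_counts",
    "concordance_fraction",
    "ConcordanceFractions",
    "plot_scatter",
]

CONCORDANCE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "rna_only_up",
    "rna_only_down",
    "protein_only_up",
    "protein_only_down",
    "opposite",
    "unchanged",
    "intermediate",
)


@dataclass(frozen=True)
class ClassThresholds:
    """Log2-unit thresholds of the concordance classification.

    ``change_threshold`` (t): minimum |log2 FC| for a *changed* call;
    ``null_band`` (b): maximum |log2 FC| for an *unchanged* call.
    Requires b < t.
    """

    change_threshold: float = 2.0
    null_band: float = 1.0

    def __post_init__(self) -> None:
        if self.change_threshold <= 0 or self.null_band <= 0:
            raise ValueError("thresholds must be positive")
        if not self.null_band < self.change_threshold:
            raise ValueError("null_band must be smaller than change_threshold")


def merge_rna_protein(
    proteins: pd.DataFrame, rna: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join protein and RNA fold changes on exact gene symbol.

    ``proteins`` needs ``gene_id`` and ``merged_log2fc`` (renamed to
    ``protein_log2fc``); ``rna`` needs ``gene_id`` and ``rna_log2fc``.
    Returns the paired frame and counts of protein-only / RNA-only genes.
    Duplicate gene ids in either table are an error.
    """
    for name, table in (("protein", proteins), ("rna", rna)):
        dup = table["gene_id"].astype(str).str.strip()
        dupes = sorted(dup[dup.duplicated()].unique())
        if dupes:
            raise ValueError(f"duplicate gene_ids in {name} table: {dupes}")

    prot = proteins[["gene_id", "merged_log2fc"]].copy()
    prot["gene_id"] = prot["gene_id"].astype(str).str.strip()
    prot = prot.rename(columns={"merged_log2fc": "protein_log2fc"})
    rna_t = rna[["gene_id", "rna_log2fc"]].copy()
    rna_t["gene_id"] = rna_t["gene_id"].astype(str).str.strip()

    paired = prot.merge(rna_t, on="gene_id", how="inner")
    counts = {
        "paired": len(paired),
        "protein_only": len(prot) - len(paired),
        "rna_only": len(rna_t) - len(paired),
    }
    if paired.empty:
        warnings.warn("no genes shared between protein and RNA tables")
    return paired, counts


def pearson_correlation(paired: pd.DataFrame) -> tuple[float, float]:
    """Pearson product-moment correlation of RNA vs protein log2 FCs."""
    if len(paired) < 3:
        raise ValueError("need at least 3 paired genes for a correlation")
    x = paired["rna_log2fc"].to_numpy(dtype=float)
    y = paired["protein_log2fc"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in RNA or protein fold changes")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_genes(
    paired: pd.DataFrame, thresholds: ClassThresholds | None = None
) -> pd.DataFrame:
    """Assign each paired gene exactly one concordance class."""
    thresholds = thresholds or ClassThresholds()
    t, b = thresholds.change_threshold, thresholds.null_band

    rna = paired["rna_log2fc"].to_numpy(dtype=float)
    prot = paired["protein_log2fc"].to_numpy(dtype=float)
    conditions = [
        (rna >= t) & (prot >= t),
        (rna <= -t) & (prot <= -t),
        (np.abs(rna) >= t) & (np.abs(prot) >= t),  # remaining: opposite signs
        (rna >= t) & (np.abs(prot) <= b),
        (rna <= -t) & (np.abs(prot) <= b),
        (prot >= t) & (np.abs(rna) <= b),
        (prot <= -t) & (np.abs(rna) <= b),
        (np.abs(rna) <= b) & (np.abs(prot) <= b),
    ]
    choices = [
        "concordant_up",
        "concordant_down",
        "opposite",
        "rna_only_up",
        "rna_only_down",
        "protein_only_up",
        "protein_only_down",
        "unchanged",
    ]
    out = paired.copy()
    out["concordance_class"] = np.select(
        conditions, choices, default="intermediate"
    )
    return out


def _status(values: np.ndarray, t: float) -> np.ndarray:
    return np.select([values >= t, values <= -t], ["up", "down"], "neither")


def contingency_counts(
    paired: pd.DataFrame, thresholds: ClassThresholds | None = None
) -> pd.DataFrame:
    """3x3 table of gene counts by RNA status (rows) x protein status.

    Status is up / down / neither at the change threshold; cells sum to
    the number of paired genes.
    """
    t = (thresholds or ClassThresholds()).change_threshold
    order = ["up", "down", "neither"]
    if paired.empty:
        counts = pd.DataFrame(0, index=order, columns=order)
        counts.index.name = "rna"
        counts.columns.name = "protein"
        return counts
    rna = pd.Categorical(
        _status(paired["rna_log2fc"].to_numpy(dtype=float), t), order
    )
    prot = pd.Categorical(
        _status(paired["protein_log2fc"].to_numpy(dtype=float), t), order
    )
    counts = pd.crosstab(rna, prot, dropna=False)
    counts = counts.reindex(index=order, columns=order, fill_value=0)
    counts.index.name = "rna"
    counts.columns.name = "protein"
    return counts


@dataclass(frozen=True)
class ConcordanceFractions:
    """Directional concordance, conditioned on either axis.

    ``rna_conditioned``: of the genes changed in the given direction at
    the RNA level, the fraction also changed that way at the protein
    level; ``protein_conditioned`` symmetrically. A zero denominator
    yields NaN (undefined), never 0.
    """

    direction: str
    rna_conditioned: float
    protein_conditioned: float


def concordance_fraction(
    counts: pd.DataFrame, direction: str
) -> ConcordanceFractions:
    """Fraction of direction-changed genes concordant across levels."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    both = float(counts.loc[direction, direction])
    rna_total = float(counts.loc[direction].sum())
    prot_total = float(counts[direction].sum())
    return ConcordanceFractions(
        direction=direction,
        rna_conditioned=both / rna_total if rna_total else float("nan"),
        protein_conditioned=both / prot_total if prot_total else float("nan"),
    )


def plot_scatter(
    paired: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    path=None,
):
    """Basic RNA-vs-protein fold-change scatter, colored by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thresholds = thresholds or ClassThresholds()
    table = (
        paired
        if "concordance_class" in paired.columns
        else classify_genes(paired, thresholds)
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, group in table.groupby("concordance_class"):
        ax.scatter(
            group["rna_log2fc"], group["protein_log2fc"], s=6, label=cls
        )
    for v in (thresholds.change_threshold, -thresholds.change_threshold):
        ax.axvline(v, color="grey", lw=0.5, ls="--")
        ax.axhline(v, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("RNA log2 fold change (DUX4/Control)")
    ax.set_ylabel("Protein log2 fold change (DUX4/Control)")
    ax.legend(fontsize=6, markerscale=2)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
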