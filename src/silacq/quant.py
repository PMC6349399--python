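"""Orientation correction, normalization, and peptide-to-protein roll-up.

The quantification model: each filtered PSM carries an H/L abundance ratio.
In a *forward* replicate the heavy channel is the treated (DUX4) sample, so
log2(H/L) estimates log2(DUX4/Control); in a label-*swap* replicate the
assignment is reversed and the sign flips. After per-replicate median
centering, the protein-level log2 fold change within a replicate is the
median of its peptides' log2 ratios, and the final estimate is the median
across label-swap replicates — which pulls the estimate of any
inefficiently-labeled (anticorrelating) protein toward zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "apply_design",
    "read_design",
    "peptide_log_ratios",
    "normalize_ratios",
    "summarize_protein",
    "merge_replicates",
]

ORIENTATIONS = ("forward", "swap")


def read_design(path) -> pd.DataFrame:
    """Read a replicate design table (columns replicate_id, orientation)."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"replicate_id", "orientation"} - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns {sorted(missing)}")
    bad = ~design["orientation"].isin(ORIENTATIONS)
    if bad.any():
        raise ValueError(
            f"unknown orientations: {sorted(design.loc[bad, 'orientation'])}"
        )
    if design["replicate_id"].duplicated().any():
        raise ValueError("duplicate replicate_id in design table")
    return design


def apply_design(psms: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``orientation`` column to a PSM frame via the design table."""
    mapping = dict(zip(design["replicate_id"], design["orientation"]))
    unknown = set(psms["replicate"].unique()) - set(mapping)
    if unknown:
        raise ValueError(
            f"replicates missing from design table: {sorted(map(str, unknown))}"
        )
    out = psms.copy()
    out["orientation"] = psms["replicate"].map(mapping)
    return out


def peptide_log_ratios(psms: pd.DataFrame) -> pd.DataFrame:
    """Orientation-corrected log2(DUX4/Control) ratio per PSM.

    ``log2_ratio = log2(hl_ratio)`` in forward replicates and
    ``-log2(hl_ratio)`` in swap replicates. Requires an ``orientation``
    column (see :func:`apply_design`) and strictly positive ratios.
    """
    if "orientation" not in psms.columns:
        raise ValueError("PSM frame lacks an orientation column")
    bad_orient = ~psms["orientation"].isin(ORIENTATIONS)
    if bad_orient.any():
        raise ValueError(
            f"unknown orientations: {sorted(psms.loc[bad_orient, 'orientation'])}"
        )
    ratio = psms["hl_ratio"].to_numpy(dtype=float)
    if np.any(~(ratio > 0)):
        raise ValueError("hl_ratio must be positive and present")
    sign = np.where(psms["orientation"].to_numpy() == "swap", -1.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": psms["gene"].to_numpy(),
            "replicate_id": psms["replicate"].to_numpy(),
            "log2_ratio": sign * np.log2(ratio),
        }
    )


def normalize_ratios(
    ratios: pd.DataFrame, method: str = "median_center"
) -> pd.DataFrame:
    """Normalize peptide log2 ratios.

    ``median_center`` subtracts, per replicate, the median log2 ratio over
    all peptides in that replicate (post-normalization per-replicate median
    is 0 to machine precision); ``none`` is the identity.
    """
    if method == "none":
        return ratios.copy()
    if method != "median_center":
        raise ValueError(f"unknown normalization method {method!r}")
    if ratios.empty:
        raise ValueError("cannot normalize an empty ratio table")
    out = ratios.copy()
    medians = out.groupby("replicate_id")["log2_ratio"].transform("median")
    out["log2_ratio"] = out["log2_ratio"] - medians
    return out


def summarize_protein(ratios: pd.DataFrame) -> pd.DataFrame:
    """Median peptide log2 ratio per gene per replicate.

    Returns a frame with columns ``gene_id``, ``replicate_id``, ``log2fc``
    (median; midpoint of the two central values for even peptide counts)
    and ``n_peptides``.
    """
    grouped = ratios.groupby(["gene_id", "replicate_id"], sort=True)[
        "log2_ratio"
    ]
    out = grouped.agg(log2fc="median", n_peptides="size").reset_index()
    out["n_peptides"] = out["n_peptides"].astype(int)
    return out


def merge_replicates(
    per_replicate: pd.DataFrame,
    min_replicates: int = 2,
    min_peptides_total: int = 2,
    design_replicates: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-replicate protein estimates into a final log2 fold change.

    The merged value is the median of the per-replicate log2 fold changes.
    Genes observed in fewer than ``min_replicates`` replicates are dropped,
    as are genes whose total peptide count across replicates is below
    ``min_peptides_total``; both are returned in a side table with an
    ``exclusion_reason`` column (``too_few_replicates`` rows report the
    median of whatever replicates were observed, so single-peptide
    single-gene cases remain inspectable).

    Returns ``(merged, excluded)``. ``merged`` has one row per retained
    gene: ``gene_id``, ``merged_log2fc``, ``n_replicates``,
    ``n_peptides_total``, plus per-replicate wide columns
    ``log2fc_<rep>`` and ``n_peptides_<rep>``.
    """
    if design_replicates is not None:
        n_design = len(set(design_replicates))
    else:
        n_design = per_replicate["replicate_id"].nunique()
    if min_replicates > n_design:
        raise ValueError(
            f"min_replicates={min_replicates} exceeds the "
            f"{n_design} replicate(s) in the design"
        )

    gb = per_replicate.groupby("gene_id", sort=True)
    summary = gb.agg(
        merged_log2fc=("log2fc", "median"),
        n_replicates=("replicate_id", "nunique"),
        n_peptides_total=("n_peptides", "sum"),
    ).reset_index()

    wide_fc = per_replicate.pivot(
        index="gene_id", columns="replicate_id", values="log2fc"
    )
    wide_n = per_replicate.pivot(
        index="gene_id", columns="replicate_id", values="n_peptides"
    )
    wide = pd.concat(
        [wide_fc.add_prefix("log2fc_"), wide_n.add_prefix("n_peptides_")],
        axis=1,
    ).reset_index()
    summary = summary.merge(wide, on="gene_id", how="left")

    few_reps = summary["n_replicates"] < min_replicates
    few_peps = ~few_reps & (summary["n_peptides_total"] < min_peptides_total)

    excluded = summary.loc[few_reps | few_peps].copy()
    excluded["exclusion_reason"] = np.where(
        few_reps[few_reps | few_peps], "too_few_replicates", "too_few_peptides"
    )
    merged = summary.loc[~(few_reps | few_peps)].reset_index(drop=True)
    return merged, excluded.reset_index(drop=True)
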