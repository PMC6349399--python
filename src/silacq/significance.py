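"""Peptide-count-matched bootstrap null and two-tailed Z test.

For a protein quantified from n peptides, the null asks: how large a fold
change would the median of n peptides drawn at random from the global pool
of all quantified peptide-level log2 ratios show by chance? Sampling is
with replacement; B resampled medians (default 1000) form the null, whose
mean and standard deviation parameterize a two-tailed Z test of the
observed protein log2 fold change. An empirical-percentile p-value over
the same resampled medians is reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateNullError",
    "NullDistribution",
    "build_null",
    "z_test_pvalue",
    "compute_significance",
]


class DegenerateNullError(ValueError):
    """The null distribution has zero spread; no Z test is possible."""


@dataclass(frozen=True)
class NullDistribution:
    """Bootstrap null of median log2 ratios for a given peptide count.

    ``sd`` uses the sample convention (divisor B-1). A null with sd == 0
    (e.g. a constant pool) is constructible but rejected by the Z test.
    """

    n_peptides: int
    n_reps: int
    medians: np.ndarray
    mean: float
    sd: float

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


def _null_from_medians(medians: np.ndarray, n_peptides: int) -> NullDistribution:
    b = medians.shape[0]
    return NullDistribution(
        n_peptides=int(n_peptides),
        n_reps=int(b),
        medians=medians,
        mean=float(medians.mean()),
        sd=float(medians.std(ddof=1)) if b > 1 else 0.0,
    )


def build_null(
    pool: np.ndarray,
    n_peptides: int,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> NullDistribution:
    """Resample ``n_reps`` medians of ``n_peptides`` pool values each.

    ``pool`` is the flat array of all orientation-corrected, normalized
    peptide-level log2 ratios. Draws are with replacement and seeded.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size < 2:
        raise ValueError("ratio pool must contain at least 2 values")
    if n_peptides < 1 or n_reps < 1:
        raise ValueError("n_peptides and n_reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.choice(pool, size=(n_reps, n_peptides), replace=True)
    medians = np.median(draws, axis=1)
    return _null_from_medians(medians, n_peptides)


def z_test_pvalue(
    observed: float, null: NullDistribution
) -> tuple[float, float]:
    """Two-tailed Z test of an observed log2 FC against a bootstrap null.

    ``z = (observed - mean) / sd`` and ``p = 2 * (1 - Phi(|z|))``. Raises
    :class:`DegenerateNullError` rather than silently returning p = 0 when
    the null has no spread.
    """
    if null.sd <= 0:
        raise DegenerateNullError(
            f"null for n_peptides={null.n_peptides} has sd=0"
        )
    z = (observed - null.mean) / null.sd
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(z), float(p)


def _empirical_pvalue(observed: float, null: NullDistribution) -> float:
    # add-one correction keeps p in (0, 1]
    exceed = np.abs(null.medians - null.mean) >= abs(observed - null.mean)
    return float((1 + exceed.sum()) / (null.n_reps + 1))


def compute_significance(
    proteins: pd.DataFrame,
    ratios: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "none",
) -> pd.DataFrame:
    """Bootstrap significance for every merged protein estimate.

    Parameters
    ----------
    proteins:
        Merged quantification table (from
        :func:`silacq.quant.merge_replicates`): needs ``gene_id``,
        ``merged_log2fc``, ``n_peptides_total``.
    ratios:
        Peptide-level ratio table whose ``log2_ratio`` column forms the
        global resampling pool (every peptide observation surviving the
        filters, pooled across replicates).
    n_reps:
        Bootstrap repetitions B per null (default 1000).
    seed:
        Seed for the resampling RNG; the full result table is
        deterministic given (inputs, n_reps, seed).
    correction:
        ``"none"`` or ``"bh"`` (Benjamini-Hochberg ``q_value`` column).

    Returns a frame sorted by p-value with columns ``gene_id``,
    ``merged_log2fc``, ``n_peptides_total``, ``null_mean``, ``null_sd``,
    ``z``, ``p_value``, ``p_empirical`` and (with correction) ``q_value``.
    Genes whose null is degenerate get NaN statistics and
    ``degenerate=True``; the run fails only if every gene is degenerate.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    required = {"gene_id", "merged_log2fc", "n_peptides_total"}
    missing = required - set(proteins.columns)
    if missing:
        raise ValueError(f"protein table lacks columns {sorted(missing)}")
    pool = ratios["log2_ratio"].to_numpy(dtype=float)
    if pool.size < 2:
        raise ValueError("ratio pool must contain at least 2 values")

    rng = np.random.default_rng(seed)
    rows = []
    # one independent null per gene; genes grouped by peptide count so the
    # resampling vectorizes, iterated in sorted order for determinism
    for n_pep, group in proteins.groupby("n_peptides_total", sort=True):
        g = len(group)
        n_pep = int(n_pep)
        draws = rng.choice(pool, size=(g * n_reps, n_pep), replace=True)
        medians = np.median(draws, axis=1).reshape(g, n_reps)
        for (_, protein), meds in zip(group.iterrows(), medians):
            null = _null_from_medians(meds, n_pep)
            obs = float(protein["merged_log2fc"])
            if null.degenerate:
                z = p = p_emp = np.nan
            else:
                z, p = z_test_pvalue(obs, null)
                p_emp = _empirical_pvalue(obs, null)
            rows.append(
                {
                    "gene_id": protein["gene_id"],
                    "merged_log2fc": obs,
                    "n_peptides_total": n_pep,
                    "null_mean": null.mean,
                    "null_sd": null.sd,
                    "z": z,
                    "p_value": p,
                    "p_empirical": p_emp,
                    "degenerate": null.degenerate,
                }
            )
    result = pd.DataFrame(rows)
    if result["degenerate"].all():
        raise DegenerateNullError("all per-gene null distributions degenerate")
    if correction == "bh":
        ok = result["p_value"].notna()
        q = np.full(len(result), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(
                result.loc[ok, "p_value"], method="fdr_bh"
            )[1]
        result["q_value"] = q
    return result.sort_values(
        ["p_value", "gene_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
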