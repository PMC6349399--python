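"""Synthetic SILAC data generator with known ground truth.

Emulates the statistical structure of a two-condition SILAC experiment
analysed downstream: per-gene peptide-level heavy/light ratios with
multiplicative (log-normal) noise, two label-swap replicates, a small
fraction of inefficiently labeled proteins whose swap-replicate ratios
anticorrelate with the forward replicate, and a matched gene-level RNA
fold-change table drawn from predefined gene classes (concordant up/down,
RNA-only "buffered", protein-only "discordant", null).

Every generated table is a plain :class:`pandas.DataFrame`, and the PSM
table uses the same column dialect that :mod:`silacq.psm` reads, so the
full pipeline can be exercised end to end without any external download.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .psm import DEFAULT_COLUMN_MAP, DEFAULT_FLAGS

__all__ = [
    "GENE_CLASSES",
    "SimulationConfig",
    "generate_gene_truth",
    "generate_psm_table",
    "generate_rna_table",
    "write_simulation",
    "allocate_class_counts",
]

#: Canonical gene-class order; also the tie-break order for the
#: largest-remainder allocation.
GENE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "buffered_rna_up",
    "discordant_protein_down",
    "null",
)

# Class mix calibrated (once, by Monte Carlo) so that the default generator
# yields Pearson r ~ 0.5 between paired RNA and protein estimates at
# n_genes ~ 4000, matching the correlation regime the pipeline is meant to
# operate in.
DEFAULT_CLASS_FRACTIONS: Mapping[str, float] = {
    "concordant_up": 0.036,
    "concordant_down": 0.036,
    "buffered_rna_up": 0.07,
    "discordant_protein_down": 0.05,
    "null": 0.808,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Parameters
    ----------
    n_genes:
        Number of simulated genes.
    class_fractions:
        Mapping gene class -> fraction of genes; must sum to 1 within 1e-9.
        Counts are assigned by deterministic largest-remainder allocation.
    mislabel_fraction:
        Fraction of genes whose protein fails heavy-label incorporation in
        the swap replicate; their swap-replicate corrected log2 ratios are
        sign-flipped, producing apparent anticorrelation between label-swap
        samples. Default 0.026 (the ~2.6% regime typical of incomplete
        SILAC labeling).
    peptide_count_rate:
        Rate of the zero-truncated Poisson peptide-count model (counts are
        drawn per gene per replicate and are always >= 1).
    peptide_noise_sd:
        SD of the additive Gaussian noise on each peptide's log2 ratio
        (i.e. multiplicative log-normal noise on the raw H/L ratio).
    rna_noise_sd:
        SD of the Gaussian noise on the gene-level RNA log2 fold change.
    effect_size_ranges:
        Per-class (low, high) bounds of the uniform distribution of the
        *magnitude* of the true log2 fold change for the changing axis.
    buffer_bound:
        Half-width of the uniform distribution used for the non-changing
        axis of buffered / discordant genes.
    flag_fraction:
        Fraction of PSMs carrying a random quality flag from the blacklist
        vocabulary (these PSMs are later removed by filtering).
    seed:
        Base RNG seed; identical config + seed give byte-identical tables.
    """

    n_genes: int = 4000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    mislabel_fraction: float = 0.026
    peptide_count_rate: float = 5.0
    peptide_noise_sd: float = 0.5
    rna_noise_sd: float = 0.5
    effect_size_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "concordant_up": (2.0, 6.0),
            "concordant_down": (2.0, 6.0),
            "buffered_rna_up": (2.0, 6.0),
            "discordant_protein_down": (2.0, 6.0),
        }
    )
    buffer_bound: float = 0.5
    flag_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_fractions must sum to 1 (got {total!r})"
            )
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigurationError("class fractions must be nonnegative")
        if not 0.0 <= self.mislabel_fraction <= 1.0:
            raise ConfigurationError("mislabel_fraction must lie in [0, 1]")
        for name in ("peptide_noise_sd", "rna_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.peptide_count_rate <= 0:
            raise ConfigurationError("peptide_count_rate must be > 0")
        if not 0.0 <= self.flag_fraction <= 1.0:
            raise ConfigurationError("flag_fraction must lie in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def allocate_class_counts(
    fractions: Mapping[str, float], n: int
) -> dict[str, int]:
    """Deterministic largest-remainder allocation of ``n`` items to classes.

    Floors each ideal count, then hands the remaining items to the classes
    with the largest fractional remainders, breaking ties by the canonical
    class order. The returned counts always sum to ``n``.
    """
    classes = [c for c in GENE_CLASSES if c in fractions]
    ideal = {c: fractions[c] * n for c in classes}
    counts = {c: math.floor(ideal[c]) for c in classes}
    leftover = n - sum(counts.values())
    remainders = sorted(
        classes, key=lambda c: (-(ideal[c] - counts[c]), classes.index(c))
    )
    for c in remainders[:leftover]:
        counts[c] += 1
    return counts


def generate_gene_truth(config: SimulationConfig) -> pd.DataFrame:
    """Generate the ground-truth gene table.

    Returns a frame with columns ``gene_id``, ``gene_class``,
    ``true_protein_log2fc``, ``true_rna_log2fc``, ``mislabeled``.
    """
    rng = np.random.default_rng(config.seed)
    counts = allocate_class_counts(config.class_fractions, config.n_genes)

    classes: list[str] = []
    for c in GENE_CLASSES:
        classes.extend([c] * counts.get(c, 0))

    n = config.n_genes
    protein = np.zeros(n)
    rna = np.zeros(n)
    cls = np.array(classes)
    for c in GENE_CLASSES:
        mask = cls == c
        k = int(mask.sum())
        if k == 0 or c == "null":
            continue
        low, high = config.effect_size_ranges.get(c, (2.0, 6.0))
        effect = rng.uniform(low, high, size=k)
        side = rng.uniform(-config.buffer_bound, config.buffer_bound, size=k)
        if c == "concordant_up":
            protein[mask] = effect
            rna[mask] = rng.uniform(low, high, size=k)
        elif c == "concordant_down":
            protein[mask] = -effect
            rna[mask] = -rng.uniform(low, high, size=k)
        elif c == "buffered_rna_up":
            rna[mask] = effect
            protein[mask] = side
        elif c == "discordant_protein_down":
            protein[mask] = -effect
            rna[mask] = side

    mislabeled = rng.random(n) < config.mislabel_fraction
    width = max(4, len(str(n)))
    gene_ids = [f"GENE{i:0{width}d}" for i in range(n)]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": cls,
            "true_protein_log2fc": protein,
            "true_rna_log2fc": rna,
            "mislabeled": mislabeled,
        }
    )


def _zero_truncated_poisson(
    rng: np.random.Generator, rate: float, size: int
) -> np.ndarray:
    counts = rng.poisson(rate, size=size)
    zeros = counts == 0
    while zeros.any():
        counts[zeros] = rng.poisson(rate, size=int(zeros.sum()))
        zeros = counts == 0
    return counts


DEFAULT_DESIGN: tuple[tuple[str, str], ...] = (
    ("rep1", "forward"),
    ("rep2", "swap"),
)


def generate_psm_table(
    truth: pd.DataFrame,
    config: SimulationConfig,
    replicate_design: Sequence[tuple[str, str]] = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Generate a PSM export table in the dialect read by :mod:`silacq.psm`.

    For every gene x replicate, ``k ~ ZTPoisson(rate)`` peptides are drawn.
    Each peptide's orientation-corrected log2(DUX4/Control) ratio is the
    gene's true protein log2 FC plus Gaussian noise — except for mislabeled
    genes in swap replicates, where the true value enters sign-flipped. The
    stored H/L ratio is back-transformed to the replicate's native
    orientation (heavy = DUX4 in forward replicates, heavy = control in
    swap replicates), and matching heavy/light channel abundances are
    emitted so labeling-efficiency QC can run on simulated data.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    if not replicate_design:
        raise ValueError("replicate_design must be nonempty")
    for rep_id, orientation in replicate_design:
        if orientation not in ("forward", "swap"):
            raise ValueError(f"unknown orientation {orientation!r}")

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    flag_vocab = sorted(DEFAULT_FLAGS)

    frames = []
    for rep_id, orientation in replicate_design:
        k = _zero_truncated_poisson(
            rng, config.peptide_count_rate, len(truth)
        )
        gene = np.repeat(truth["gene_id"].to_numpy(), k)
        true_fc = np.repeat(truth["true_protein_log2fc"].to_numpy(), k)
        mislabeled = np.repeat(truth["mislabeled"].to_numpy(), k)
        n_psm = int(k.sum())

        corrected = true_fc + rng.normal(0.0, config.peptide_noise_sd, n_psm)
        if orientation == "swap":
            flipped = -true_fc + (corrected - true_fc)
            corrected = np.where(mislabeled, flipped, corrected)
            stored_log2 = -corrected
        else:
            stored_log2 = corrected

        # Channel abundances consistent with the stored ratio; the total
        # intensity is log-normal, as peptide intensities typically are.
        log2_total = rng.normal(20.0, 1.0, n_psm)
        heavy = 2.0 ** (log2_total + stored_log2 / 2.0)
        light = 2.0 ** (log2_total - stored_log2 / 2.0)

        flags = np.full(n_psm, "", dtype=object)
        flagged = rng.random(n_psm) < config.flag_fraction
        if flagged.any():
            flags[flagged] = rng.choice(flag_vocab, size=int(flagged.sum()))

        pep_index = np.concatenate([np.arange(c) for c in k])
        frames.append(
            pd.DataFrame(
                {
                    DEFAULT_COLUMN_MAP["peptide"]: [
                        f"PEP.{g}.{i}" for g, i in zip(gene, pep_index)
                    ],
                    DEFAULT_COLUMN_MAP["gene"]: gene,
                    DEFAULT_COLUMN_MAP["flags"]: flags,
                    DEFAULT_COLUMN_MAP["ratio"]: 2.0 ** stored_log2,
                    DEFAULT_COLUMN_MAP["heavy"]: heavy,
                    DEFAULT_COLUMN_MAP["light"]: light,
                    DEFAULT_COLUMN_MAP["replicate"]: rep_id,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_rna_table(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Gene-level RNA log2 fold changes: truth plus Gaussian noise."""
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
    )
    rna = truth["true_rna_log2fc"].to_numpy() + rng.normal(
        0.0, config.rna_noise_sd, len(truth)
    )
    return pd.DataFrame({"gene_id": truth["gene_id"], "rna_log2fc": rna})


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    replicate_design: Sequence[tuple[str, str]] = DEFAULT_DESIGN,
) -> dict[str, Path]:
    """Run the generator and write truth / PSM / RNA / design TSVs.

    Returns a mapping of logical name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_gene_truth(config)
    psms = generate_psm_table(truth, config, replicate_design)
    rna = generate_rna_table(truth, config)
    design = pd.DataFrame(
        replicate_design, columns=["replicate_id", "orientation"]
    )
    paths = {
        "truth": outdir / "truth.tsv",
        "psms": outdir / "psms.tsv",
        "rna": outdir / "rna.tsv",
        "design": outdir / "design.tsv",
    }
    truth.to_csv(paths["truth"], sep="\t", index=False)
    psms.to_csv(paths["psms"], sep="\t", index=False)
    rna.to_csv(paths["rna"], sep="\t", index=False)
    design.to_csv(paths["design"], sep="\t", index=False)
    return paths
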