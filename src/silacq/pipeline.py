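"""End-to-end pipeline: filter -> quantify -> test -> concordance.

A single :class:`PipelineConfig` (constructible from a YAML file) drives
the full analysis over either real PSM exports or the built-in simulator,
producing a :class:`ReportBundle` of result tables plus run metadata
(seed, config echo, and the row count after every filter stage — no PSM
is dropped without an attributable rule), written as TSVs with a manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .concordance import (
    ClassThresholds,
    classify_genes,
    concordance_fraction,
    contingency_counts,
    merge_rna_protein,
    pearson_correlation,
)
from .psm import FlagBlacklist, filter_gene_mapping, filter_psms, read_contaminants, read_psm_table
from .quant import (
    apply_design,
    merge_replicates,
    normalize_ratios,
    peptide_log_ratios,
    read_design,
    summarize_protein,
)
from .significance import compute_significance
from .synthetic import SimulationConfig, generate_gene_truth, generate_psm_table, generate_rna_table

logger = logging.getLogger("silacq")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``psm_path`` or ``simulate`` must be set. ``design``
    is a list of ``(replicate_id, orientation)`` pairs or the path of a
    two-column TSV; it defaults to the simulator's two label-swap
    replicates when simulating.
    """

    psm_path: str | None = None
    simulate: SimulationConfig | None = None
    rna_path: str | None = None
    contaminants_path: str | None = None
    design: Any = None
    column_map: Mapping[str, str] | None = None
    normalization: str = "median_center"
    min_replicates: int = 2
    min_peptides_total: int = 2
    n_reps: int = 1000
    seed: int = 0
    correction: str = "none"
    change_threshold: float = 2.0
    null_band: float = 1.0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat YAML config; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in data and data["simulate"] is not None:
            data["simulate"] = SimulationConfig(**data["simulate"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved_design(self) -> pd.DataFrame:
        from .synthetic import DEFAULT_DESIGN

        design = self.design
        if design is None:
            if self.simulate is None:
                raise ValueError("design required when reading real PSM data")
            design = list(DEFAULT_DESIGN)
        if isinstance(design, (str, Path)):
            return read_design(design)
        return pd.DataFrame(
            [tuple(row) for row in design],
            columns=["replicate_id", "orientation"],
        )

    def validate(self) -> None:
        if (self.psm_path is None) == (self.simulate is None):
            raise ValueError("set exactly one of psm_path or simulate")
        design = self.resolved_design()
        if self.min_replicates > len(design):
            raise ValueError(
                f"min_replicates={self.min_replicates} exceeds the "
                f"{len(design)} replicate(s) in the design"
            )
        ClassThresholds(self.change_threshold, self.null_band)


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus run metadata."""

    quant: pd.DataFrame
    excluded: pd.DataFrame
    significance: pd.DataFrame
    paired: pd.DataFrame
    contingency: pd.DataFrame
    summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _echo_config(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    if config.simulate is not None:
        echo["simulate"] = dataclasses.asdict(config.simulate)
        echo["simulate"]["class_fractions"] = dict(
            config.simulate.class_fractions
        )
    return echo


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``."""
    config.validate()
    design = config.resolved_design()
    stage_counts: dict[str, int] = {}
    removed: dict[str, dict[str, int]] = {}

    if config.simulate is not None:
        sim = config.simulate
        truth = generate_gene_truth(sim)
        psms = generate_psm_table(
            truth, sim, list(design.itertuples(index=False, name=None))
        )
        from .psm import CANONICAL_COLUMNS, DEFAULT_COLUMN_MAP

        psms = psms.rename(
            columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()}
        ).rename(columns={"ratio": "hl_ratio"})
        psms = psms[list(CANONICAL_COLUMNS)]
    else:
        psms = read_psm_table(config.psm_path, config.column_map)
    stage_counts["input_psms"] = len(psms)

    psms, removed["quality_flags"] = filter_psms(psms, FlagBlacklist())
    stage_counts["after_flag_filter"] = len(psms)

    contaminants = (
        read_contaminants(config.contaminants_path)
        if config.contaminants_path
        else frozenset()
    )
    psms, removed["gene_mapping"] = filter_gene_mapping(psms, contaminants)
    stage_counts["after_gene_filter"] = len(psms)

    psms = apply_design(psms, design)
    ratios = peptide_log_ratios(psms)
    ratios = normalize_ratios(ratios, config.normalization)
    stage_counts["peptide_ratios"] = len(ratios)

    per_rep = summarize_protein(ratios)
    merged, excluded = merge_replicates(
        per_rep,
        min_replicates=config.min_replicates,
        min_peptides_total=config.min_peptides_total,
        design_replicates=list(design["replicate_id"]),
    )
    stage_counts["quantified_genes"] = len(merged)
    stage_counts["excluded_genes"] = len(excluded)

    significance = compute_significance(
        merged,
        ratios,
        n_reps=config.n_reps,
        seed=config.seed,
        correction=config.correction,
    )

    if config.rna_path is not None:
        rna = pd.read_csv(config.rna_path, sep="\t")
    elif config.simulate is not None:
        rna = generate_rna_table(truth, sim)
    else:
        rna = pd.DataFrame(columns=["gene_id", "rna_log2fc"])

    thresholds = ClassThresholds(config.change_threshold, config.null_band)
    summary_rows: list[dict] = []
    if len(rna):
        paired, join_counts = merge_rna_protein(merged, rna)
        stage_counts["paired_genes"] = join_counts["paired"]
        paired = classify_genes(paired, thresholds)
        contingency = contingency_counts(paired, thresholds)
        if len(paired) >= 3:
            r, p = pearson_correlation(paired)
            summary_rows.append(
                {"metric": "pearson_r", "value": r}
            )
            summary_rows.append({"metric": "pearson_p", "value": p})
        for direction in ("up", "down"):
            frac = concordance_fraction(contingency, direction)
            summary_rows.append(
                {
                    "metric": f"concordance_{direction}_rna_conditioned",
                    "value": frac.rna_conditioned,
                }
            )
            summary_rows.append(
                {
                    "metric": f"concordance_{direction}_protein_conditioned",
                    "value": frac.protein_conditioned,
                }
            )
        for cls, n in (
            paired["concordance_class"].value_counts().sort_index().items()
        ):
            summary_rows.append({"metric": f"n_class_{cls}", "value": n})
    else:
        paired = pd.DataFrame(
            columns=[
                "gene_id",
                "protein_log2fc",
                "rna_log2fc",
                "concordance_class",
            ]
        )
        contingency = contingency_counts(
            pd.DataFrame({"rna_log2fc": [], "protein_log2fc": []}), thresholds
        )

    summary_rows.append(
        {"metric": "n_quantified_genes", "value": len(merged)}
    )
    summary = pd.DataFrame(summary_rows, columns=["metric", "value"])

    for stage, n in stage_counts.items():
        logger.info("stage %s: %d rows", stage, n)
    metadata = {
        "silacq_version": __version__,
        "seed": config.seed,
        "config": _echo_config(config),
        "stage_counts": stage_counts,
        "removed": removed,
    }
    return ReportBundle(
        quant=merged,
        excluded=excluded,
        significance=significance,
        paired=paired,
        contingency=contingency,
        summary=summary,
        metadata=metadata,
    )


def _atomic_write(write, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        write(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_report(
    bundle: ReportBundle, outdir: str | Path, force: bool = False
) -> pd.DataFrame:
    """Write every bundle table as TSV plus a YAML run-metadata file.

    Refuses to overwrite an existing report unless ``force``. Returns the
    manifest (file name, row count) and writes it as ``manifest.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "quant.tsv": bundle.quant,
        "excluded.tsv": bundle.excluded,
        "significance.tsv": bundle.significance,
        "paired.tsv": bundle.paired,
        "contingency.tsv": bundle.contingency,
        "summary.tsv": bundle.summary,
    }
    existing = [n for n in tables if (outdir / n).exists()]
    if existing and not force:
        raise FileExistsError(
            f"{outdir} already contains {existing}; use force to overwrite"
        )
    manifest_rows = []
    for name, table in tables.items():
        keep_index = name == "contingency.tsv"
        _atomic_write(
            lambda tmp, t=table, ki=keep_index: t.to_csv(
                tmp, sep="\t", index=ki
            ),
            outdir / name,
        )
        manifest_rows.append({"file": name, "n_rows": len(table)})
    _atomic_write(
        lambda tmp: Path(tmp).write_text(
            yaml.safe_dump(bundle.metadata, sort_keys=False)
        ),
        outdir / "run_metadata.yaml",
    )
    manifest_rows.append({"file": "run_metadata.yaml", "n_rows": 1})
    manifest = pd.DataFrame(manifest_rows)
    _atomic_write(
        lambda tmp: manifest.to_csv(tmp, sep="\t", index=False),
        outdir / "manifest.tsv",
    )
    return manifest
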