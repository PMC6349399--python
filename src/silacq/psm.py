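"""Reading and filtering of PSM (peptide-spectrum match) export tables.

Input is a tab-delimited PSM-level export in the style of Proteome
Discoverer 2.1: one row per PSM with a peptide sequence, a gene symbol,
quantification quality flags, a heavy/light abundance ratio (or the two
channel abundances), and the originating replicate. A configurable column
map adapts other dialects.

Filtering follows the standard SILAC quality regime: PSMs carrying any of
seven quality flags are removed, as are PSMs without a quantified ratio,
PSMs that failed to map to a gene, and PSMs mapping to contaminants
(cRAP-style lists) or uncharacterized genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FLAGS",
    "DEFAULT_COLUMN_MAP",
    "CANONICAL_COLUMNS",
    "FlagBlacklist",
    "PsmFormatError",
    "read_psm_table",
    "read_contaminants",
    "filter_psms",
    "filter_gene_mapping",
    "default_uncharacterized",
    "labeling_efficiency",
    "LabelingEfficiency",
]

#: The seven quantification quality flags whose PSMs are removed.
DEFAULT_FLAGS = frozenset(
    {
        "Inconsistently labeled",
        "Indistinguishable channels",
        "No quantitative values",
        "Not unique",
        "Redundant spectra",
        "Single peak spectra",
        "Excluded by method",
    }
)

#: Logical -> Proteome Discoverer 2.1-style column headers.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "peptide": "Annotated Sequence",
    "gene": "Gene Symbol",
    "flags": "Quan Info",
    "ratio": "Abundance Ratio (Heavy)/(Light)",
    "heavy": "Abundance Heavy",
    "light": "Abundance Light",
    "replicate": "Spectrum File",
}

#: Canonical in-memory PSM columns produced by :func:`read_psm_table`.
CANONICAL_COLUMNS = (
    "peptide",
    "gene",
    "flags",
    "hl_ratio",
    "heavy",
    "light",
    "replicate",
)

_FLAG_SEP = ";"


class PsmFormatError(ValueError):
    """A PSM table does not conform to the expected dialect."""


@dataclass(frozen=True)
class FlagBlacklist:
    """Set of quality-flag strings whose PSMs are discarded.

    Matching is exact-string and case-sensitive; flags outside the
    vocabulary are retained (only listed flags are grounds for removal).
    """

    flags: frozenset[str] = field(default_factory=lambda: DEFAULT_FLAGS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))


def _parse_flags(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    parts = [p.strip() for p in str(cell).split(_FLAG_SEP)]
    return frozenset(p for p in parts if p)


def _to_numeric(
    raw: pd.Series, column: str, path: str | Path
) -> pd.Series:
    stripped = raw.astype("string").str.strip()
    values = pd.to_numeric(stripped, errors="coerce")
    bad = values.isna() & stripped.notna() & (stripped != "")
    if bad.any():
        # +2: header line plus 1-based numbering.
        line = int(bad.idxmax()) + 2
        raise PsmFormatError(
            f"{path}: unparsable numeric value {stripped[bad.idxmax()]!r} "
            f"in column {column!r} at line {line}"
        )
    return values.astype(float)


def read_psm_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited PSM export into the canonical PSM frame.

    ``column_map`` maps logical names (``peptide``, ``gene``, ``flags``,
    ``ratio``, ``heavy``, ``light``, ``replicate``) to actual headers;
    unspecified entries fall back to the Proteome Discoverer 2.1 defaults.
    Either the ratio column or both abundance columns must be present; a
    missing ratio is reconstructed as heavy/light. Missing ratios are kept
    as NaN (they are removed later by :func:`filter_psms`).
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)

    # files written by this package use the canonical headers directly
    if column_map is None and {"peptide", "gene", "replicate"} <= set(
        raw.columns
    ):
        colmap = {k: k for k in DEFAULT_COLUMN_MAP}
        colmap["ratio"] = "hl_ratio"

    for logical in ("peptide", "gene", "flags", "replicate"):
        if colmap[logical] not in raw.columns:
            raise PsmFormatError(
                f"{path}: required column {colmap[logical]!r} "
                f"(logical {logical!r}) not found"
            )
    have_ratio = colmap["ratio"] in raw.columns
    have_abund = (
        colmap["heavy"] in raw.columns and colmap["light"] in raw.columns
    )
    if not have_ratio and not have_abund:
        raise PsmFormatError(
            f"{path}: need either ratio column {colmap['ratio']!r} or both "
            f"abundance columns {colmap['heavy']!r}/{colmap['light']!r}"
        )

    out = pd.DataFrame(
        {
            "peptide": raw[colmap["peptide"]].astype("string"),
            "gene": raw[colmap["gene"]].astype("string").str.strip(),
            "flags": raw[colmap["flags"]].map(_parse_flags),
            "replicate": raw[colmap["replicate"]].astype("string"),
        }
    )
    if have_abund:
        out["heavy"] = _to_numeric(raw[colmap["heavy"]], colmap["heavy"], path)
        out["light"] = _to_numeric(raw[colmap["light"]], colmap["light"], path)
    else:
        out["heavy"] = np.nan
        out["light"] = np.nan
    if have_ratio:
        out["hl_ratio"] = _to_numeric(
            raw[colmap["ratio"]], colmap["ratio"], path
        )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = out["heavy"] / out["light"]
        out["hl_ratio"] = ratio.where(np.isfinite(ratio))
    return out[list(CANONICAL_COLUMNS)]


def read_contaminants(path: str | Path) -> frozenset[str]:
    """Read a one-symbol-per-line contaminant list (cRAP-style)."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line)
    return frozenset(symbols)


def filter_psms(
    psms: pd.DataFrame,
    blacklist: FlagBlacklist | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove flagged PSMs and PSMs without a quantified ratio.

    Returns the retained frame (row order preserved) and a removal-count
    mapping: one entry per blacklisted flag observed, plus
    ``"<missing ratio>"`` for rows dropped for lacking a usable ratio.
    A row carrying several blacklisted flags is counted once per flag but
    removed once.
    """
    blacklist = blacklist or FlagBlacklist()
    flags = psms["flags"].map(_parse_flags) if psms["flags"].map(
        lambda f: not isinstance(f, frozenset)
    ).any() else psms["flags"]

    hit = flags.map(lambda f: bool(f & blacklist.flags))
    missing = psms["hl_ratio"].isna() | (psms["hl_ratio"] <= 0)

    counts: dict[str, int] = {}
    for f in sorted(blacklist.flags):
        n = int(flags.map(lambda s, f=f: f in s)[hit].sum())
        if n:
            counts[f] = n
    n_missing = int((missing & ~hit).sum())
    if n_missing:
        counts["<missing ratio>"] = n_missing

    kept = psms.loc[~(hit | missing)].copy()
    return kept, counts


_UNCHAR_RE = re.compile(r"^LOC\d+$")


def default_uncharacterized(symbol: str) -> bool:
    """Default rule for "uncharacterized" gene symbols.

    Accession-like ``LOC#####`` names, or names containing the word
    "uncharacterized", are treated as uncharacterized.
    """
    return bool(_UNCHAR_RE.match(symbol)) or "uncharacterized" in symbol.lower()


def filter_gene_mapping(
    psms: pd.DataFrame,
    contaminant_genes: Iterable[str] = (),
    uncharacterized: Callable[[str], bool] | None = default_uncharacterized,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop PSMs with no gene, contaminant genes, or uncharacterized genes.

    Returns the retained frame and removal counts keyed by reason
    (``unmapped``, ``contaminant``, ``uncharacterized``).
    """
    contaminants = frozenset(contaminant_genes)
    gene = psms["gene"]
    unmapped = gene.isna() | (gene.astype("string").str.len() == 0)
    contaminant = gene.isin(contaminants) & ~unmapped
    if uncharacterized is not None:
        unchar = (
            gene.map(lambda g: bool(uncharacterized(str(g))), na_action="ignore")
            .fillna(False)
            .astype(bool)
            & ~unmapped
            & ~contaminant
        )
    else:
        unchar = pd.Series(False, index=psms.index)

    counts = {
        "unmapped": int(unmapped.sum()),
        "contaminant": int(contaminant.sum()),
        "uncharacterized": int(unchar.sum()),
    }
    counts = {k: v for k, v in counts.items() if v}
    kept = psms.loc[~(unmapped | contaminant | unchar)].copy()
    return kept, counts


@dataclass(frozen=True)
class LabelingEfficiency:
    """Heavy-channel signal fraction plus the per-peptide log2 H/L ratios.

    ``fraction_heavy`` is sum(heavy) / (sum(heavy) + sum(light)) over all
    PSMs with channel abundances; near 1 after complete metabolic labeling,
    and ~0.5 for a 1:1 heavy:light mix, whose log-ratio distribution is
    centered roughly around zero.
    """

    fraction_heavy: float
    log2_ratios: np.ndarray


def labeling_efficiency(psms: pd.DataFrame) -> LabelingEfficiency:
    """Compute labeling-efficiency QC from channel abundances."""
    heavy = psms["heavy"].to_numpy(dtype=float)
    light = psms["light"].to_numpy(dtype=float)
    ok = np.isfinite(heavy) & np.isfinite(light)
    if not ok.any():
        raise ValueError("no PSMs with heavy and light abundances")
    heavy, light = heavy[ok], light[ok]
    total = heavy.sum() + light.sum()
    if total == 0:
        raise ValueError("all channel abundances are zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(heavy / light)
    return LabelingEfficiency(
        fraction_heavy=float(heavy.sum() / total),
        log2_ratios=log2r[np.isfinite(log2r)],
    )
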