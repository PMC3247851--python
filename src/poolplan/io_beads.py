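"""Bead-level I/O, filtering and per-SNP allele-frequency estimation.

Pooled-DNA allelotyping on beadarrays estimates the frequency of one allele
of a SNP as the mean, over the 16-18 beads interrogating that SNP, of the
green-channel share of the total fluorescence::

    p = (1/n) * sum_i  G_i / (G_i + c * R_i)

where ``G_i`` and ``R_i`` are the green and red intensities of bead *i* and
``c`` is an optional red-channel rescaling factor (see :mod:`poolplan.normalize`).
Raw exports may contain beads with negative intensities (background
subtraction artefacts) and failed beads with zero in both channels; these are
dropped before estimation, and SNPs left with fewer than four beads are
excluded as too poorly measured.

Bead tables are plain TSV with a mandatory header
``array_id pool_id strip_id snp_id green red``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import BeadTableParseError, ConfigurationError, ParameterError

__all__ = [
    "BEAD_COLUMNS",
    "FREQ_COLUMNS",
    "MIN_BEADS_PER_SNP",
    "FilterReport",
    "FrequencyTable",
    "read_bead_table",
    "write_bead_table",
    "filter_beads",
    "snp_allele_frequency",
    "build_frequency_table",
    "read_frequency_tables",
    "write_frequency_tables",
]

#: Column order of the bead-level TSV dialect.
BEAD_COLUMNS = ["array_id", "pool_id", "strip_id", "snp_id", "green", "red"]

#: Column order of the SNP-level frequency TSV dialect.
FREQ_COLUMNS = ["array_id", "snp_id", "freq", "n_beads"]

#: SNPs with fewer bead observations than this are excluded.
MIN_BEADS_PER_SNP = 4


@dataclass
class FilterReport:
    """Counts of beads and SNPs removed by the filtering rules."""

    n_dropped_negative: int = 0
    n_dropped_failed: int = 0
    n_snps_excluded_low_beads: int = 0
    n_snps_kept: int = 0

    def __add__(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.n_dropped_negative + other.n_dropped_negative,
            self.n_dropped_failed + other.n_dropped_failed,
            self.n_snps_excluded_low_beads + other.n_snps_excluded_low_beads,
            self.n_snps_kept + other.n_snps_kept,
        )


@dataclass
class FrequencyTable:
    """Per-SNP estimated allele frequencies for one array.

    ``data`` is indexed by ``snp_id`` with columns ``freq`` (estimate in
    [0, 1]) and ``n_beads`` (>= 4). SNPs excluded by the bead-count rule are
    absent rather than carried as missing values, so pairwise comparisons
    downstream operate on SNP-set intersections.
    """

    array_id: str
    data: pd.DataFrame
    pool_id: str | None = None
    report: FilterReport = field(default_factory=FilterReport)

    @property
    def freqs(self) -> pd.Series:
        return self.data["freq"]

    @property
    def snp_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


def read_bead_table(path: str | Path) -> pd.DataFrame:
    """Read a bead-level TSV into a DataFrame (no filtering applied).

    Raises :class:`BeadTableParseError` naming the 1-based line number of the
    first malformed row (wrong column count or non-numeric intensity).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # wrong field count; pandas names the line
        raise BeadTableParseError(str(exc)) from exc
    if not isinstance(df.index, pd.RangeIndex):
        # every data row had extra fields: pandas inferred them as an index
        raise BeadTableParseError("rows have more fields than the header", line=2)
    if list(df.columns) != BEAD_COLUMNS:
        raise BeadTableParseError(
            f"expected header {BEAD_COLUMNS!r}, found {list(df.columns)!r}", line=1
        )
    for col in ("green", "red"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            # +2: 1-based and one header line
            raise BeadTableParseError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column {col!r}",
                line=int(np.flatnonzero(bad)[0]) + 2,
            )
        if values.isna().any():
            raise BeadTableParseError(
                f"missing value in column {col!r}",
                line=int(np.flatnonzero(values.isna())[0]) + 2,
            )
        df[col] = values.astype(float)
    return df


def write_bead_table(beads: pd.DataFrame, path: str | Path) -> None:
    """Write a bead DataFrame in the bead TSV dialect."""
    beads.loc[:, BEAD_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_beads(beads: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop negative-intensity and failed beads.

    A bead with a negative value in either channel is removed as "negative";
    among the remainder, a bead with zero in both channels is removed as
    "failed". The negative rule is applied first, so a bead with one negative
    and one zero channel counts as negative. Row order is preserved and
    ``len(kept) + dropped == len(beads)``.
    """
    green = beads["green"].to_numpy()
    red = beads["red"].to_numpy()
    negative = (green < 0) | (red < 0)
    failed = ~negative & (green == 0) & (red == 0)
    kept = beads.loc[~(negative | failed)]
    report = FilterReport(
        n_dropped_negative=int(negative.sum()),
        n_dropped_failed=int(failed.sum()),
    )
    return kept, report


def snp_allele_frequency(
    beads_for_snp: pd.DataFrame, red_scale: float = 1.0
) -> float | None:
    """Mean green-share frequency for one SNP, or ``None`` if under-observed.

    ``red_scale`` multiplies the red channel (normalization); must be > 0.
    Returns ``None`` (excluded marker) when fewer than four beads remain.
    """
    if red_scale <= 0:
        raise ParameterError(f"red_scale must be > 0, got {red_scale}")
    if len(beads_for_snp) < MIN_BEADS_PER_SNP:
        return None
    g = beads_for_snp["green"].to_numpy(dtype=float)
    r = beads_for_snp["red"].to_numpy(dtype=float)
    return float(np.mean(g / (g + red_scale * r)))


def build_frequency_table(
    array_beads: pd.DataFrame,
    per_strip_scales: Mapping[str, float] | None = None,
) -> FrequencyTable:
    """Assemble a :class:`FrequencyTable` from one array's filtered beads.

    ``per_strip_scales`` maps every strip present in the beads to its red
    scale; ``None`` means raw mode (all scales 1). SNPs with fewer than four
    beads are excluded and counted in the attached :class:`FilterReport`.
    """
    array_ids = array_beads["array_id"].unique()
    if len(array_ids) != 1:
        raise ConfigurationError(
            f"expected beads from exactly one array, found {sorted(array_ids)}"
        )
    array_id = str(array_ids[0])
    pool_ids = array_beads["pool_id"].unique()
    pool_id = str(pool_ids[0]) if len(pool_ids) == 1 else None

    if per_strip_scales is None:
        scale_per_bead = np.ones(len(array_beads))
    else:
        strips = array_beads["strip_id"]
        unknown = set(strips.unique()) - set(per_strip_scales)
        if unknown:
            raise ConfigurationError(f"no red scale for strip(s) {sorted(unknown)}")
        scale_per_bead = strips.map(per_strip_scales).to_numpy(dtype=float)

    g = array_beads["green"].to_numpy(dtype=float)
    r = array_beads["red"].to_numpy(dtype=float)
    ratio = g / (g + scale_per_bead * r)
    per_snp = (
        pd.DataFrame({"snp_id": array_beads["snp_id"].to_numpy(), "ratio": ratio})
        .groupby("snp_id", sort=True)["ratio"]
        .agg(freq="mean", n_beads="size")
    )
    enough = per_snp["n_beads"] >= MIN_BEADS_PER_SNP
    data = per_snp.loc[enough]
    report = FilterReport(
        n_snps_excluded_low_beads=int((~enough).sum()),
        n_snps_kept=int(enough.sum()),
    )
    return FrequencyTable(array_id=array_id, data=data, pool_id=pool_id, report=report)


def write_frequency_tables(tables: list[FrequencyTable], path: str | Path) -> None:
    """Write frequency tables in the frequency TSV dialect (one file, stacked)."""
    frames = []
    for t in tables:
        df = t.data.reset_index()
        df.insert(0, "array_id", t.array_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FREQ_COLUMNS)
    out.loc[:, FREQ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_frequency_tables(path: str | Path) -> list[FrequencyTable]:
    """Read a stacked frequency TSV back into one table per array."""
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "snp_id": str})
    if list(df.columns) != FREQ_COLUMNS:
        raise BeadTableParseError(
            f"expected header {FREQ_COLUMNS!r}, found {list(df.columns)!r}", line=1
        )
    tables = []
    for array_id, grp in df.groupby("array_id", sort=True):
        data = grp.set_index("snp_id")[["freq", "n_beads"]]
        tables.append(FrequencyTable(array_id=str(array_id), data=data))
    return tables
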