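"""Strip-by-strip red-channel normalization.

The red:green intensity balance of a beadarray varies between the physical
strips of an array (and between arrays), which biases pooled allele-frequency
estimates. Each strip is therefore rescaled independently: the red channel is
multiplied by a factor ``c`` chosen so that the mean per-SNP allele-frequency
estimate across the strip equals 0.5.

The strip mean ``m(c) = mean_snp mean_bead G/(G + cR)`` is strictly
decreasing in ``c`` whenever some bead has both channels positive, so the
root is unique; it is found by bisection on log(c) over c in [1e-6, 1e6] to a
tolerance of 1e-9 on the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateStripError, NonNormalizableStripError
from .io_beads import MIN_BEADS_PER_SNP

__all__ = [
    "StripScale",
    "strip_mean_frequency",
    "solve_red_scale",
    "normalize_array",
    "write_strip_scales",
]

_C_LO = 1e-6
_C_HI = 1e6
_TOL = 1e-9
_MAX_ITER = 200


@dataclass
class StripScale:
    """Solved red-channel scale for one strip of one array."""

    array_id: str
    strip_id: str
    red_scale: float
    achieved_mean: float
    iterations: int


class _StripData:
    """Bead intensities of one strip grouped by SNP for fast re-evaluation.

    Bisection re-evaluates the strip mean ~100 times; a pandas groupby per
    evaluation would dominate runtime, so beads are sorted by SNP once and
    per-SNP means are taken with ``np.add.reduceat``.
    """

    def __init__(self, strip_beads: pd.DataFrame, level: str = "snp"):
        if level not in ("snp", "bead"):
            raise ValueError(f"level must be 'snp' or 'bead', got {level!r}")
        self.level = level
        codes, _ = pd.factorize(strip_beads["snp_id"], sort=True)
        order = np.argsort(codes, kind="stable")
        self.green = strip_beads["green"].to_numpy(dtype=float)[order]
        self.red = strip_beads["red"].to_numpy(dtype=float)[order]
        codes = codes[order]
        self.starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self.counts = np.diff(np.r_[self.starts, len(codes)])
        self.included = self.counts >= MIN_BEADS_PER_SNP
        if level == "snp" and not self.included.any():
            raise DegenerateStripError(
                f"no SNP with >= {MIN_BEADS_PER_SNP} beads on this strip"
            )

    def mean_frequency(self, red_scale: float) -> float:
        ratios = self.green / (self.green + red_scale * self.red)
        if self.level == "bead":
            return float(ratios.mean())
        snp_means = np.add.reduceat(ratios, self.starts) / self.counts
        return float(snp_means[self.included].mean())


def strip_mean_frequency(
    strip_beads: pd.DataFrame, red_scale: float = 1.0, level: str = "snp"
) -> float:
    """Mean allele-frequency estimate of a strip at a given red scale.

    With ``level="snp"`` (default) the mean is taken over per-SNP frequency
    estimates (SNPs with fewer than four beads excluded); ``level="bead"``
    averages the raw per-bead green shares instead — the two differ when bead
    counts vary between SNPs.
    """
    return _StripData(strip_beads, level=level).mean_frequency(red_scale)


def solve_red_scale(
    strip_beads: pd.DataFrame,
    array_id: str | None = None,
    strip_id: str | None = None,
    level: str = "snp",
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> StripScale:
    """Find the red-channel scale bringing the strip mean frequency to 0.5.

    Bisection on log(c); raises :class:`NonNormalizableStripError` when the
    mean is bounded away from 0.5 on [1e-6, 1e6] (e.g. every bead has red = 0
    or every bead has green = 0).
    """
    if array_id is None:
        array_id = str(strip_beads["array_id"].iloc[0])
    if strip_id is None:
        strip_id = str(strip_beads["strip_id"].iloc[0])
    data = _StripData(strip_beads, level=level)

    lo, hi = _C_LO, _C_HI
    m_lo = data.mean_frequency(lo)  # mean is decreasing: m(lo) is the sup
    m_hi = data.mean_frequency(hi)
    for c, m in ((lo, m_lo), (hi, m_hi)):
        if abs(m - 0.5) <= tol:
            return StripScale(array_id, strip_id, c, m, 0)
    if m_lo < 0.5 or m_hi > 0.5:
        raise NonNormalizableStripError(
            f"strip {strip_id!r} of array {array_id!r}: mean frequency spans "
            f"[{m_hi:.4g}, {m_lo:.4g}] over the scale range and never reaches 0.5"
        )
    log_lo, log_hi = np.log(lo), np.log(hi)
    c, m = 1.0, data.mean_frequency(1.0)
    for it in range(1, max_iter + 1):
        mid = 0.5 * (log_lo + log_hi)
        c = float(np.exp(mid))
        m = data.mean_frequency(c)
        if abs(m - 0.5) <= tol:
            return StripScale(array_id, strip_id, c, m, it)
        if m > 0.5:
            log_lo = mid
        else:
            log_hi = mid
    return StripScale(array_id, strip_id, c, m, max_iter)


def normalize_array(array_beads: pd.DataFrame, level: str = "snp") -> dict[str, StripScale]:
    """Solve one :class:`StripScale` per strip of a filtered array.

    Degenerate or non-normalizable strips raise, naming the strip.
    """
    scales: dict[str, StripScale] = {}
    for strip_id, strip_beads in array_beads.groupby("strip_id", sort=True):
        scales[str(strip_id)] = solve_red_scale(
            strip_beads, strip_id=str(strip_id), level=level
        )
    return scales


def write_strip_scales(scales: list[StripScale], path) -> None:
    """Write solved scales as TSV (array_id, strip_id, red_scale, achieved_mean, iterations)."""
    pd.DataFrame(
        [
            {
                "array_id": s.array_id,
                "strip_id": s.strip_id,
                "red_scale": s.red_scale,
                "achieved_mean": s.achieved_mean,
                "iterations": s.iterations,
            }
            for s in scales
        ]
    ).to_csv(path, sep="\t", index=False)
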