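"""ROI-based T2* estimation and the AHA-style sector partition.

T2* is estimated per ROI, not per pixel: the ROI-mean signal at each echo
forms a decay curve that is fitted with the three-parameter
offset-exponential model

    S(TE) = So * exp(-TE / T2*) + C

where the constant C absorbs the magnitude-image noise floor (Rician bias),
so no explicit Rician likelihood is needed.  For segmental analysis the
myocardial annulus is partitioned by polar angle into 6 (basal, mid) or 4
(apical) equal sectors following the 16-segment AHA convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from cardioswi.rois import RoiSet

__all__ = ["DecayCurve", "T2StarFit", "fit_t2star", "aha_sectors", "segment_t2star"]

T2_BOUNDS_MS = (0.1, 500.0)


@dataclass
class DecayCurve:
    """ROI-mean signal intensity at each echo time."""

    echo_times: np.ndarray
    mean_signal: np.ndarray
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        if len(self.echo_times) != len(self.mean_signal):
            raise ValueError("echo_times and mean_signal lengths differ")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")


@dataclass
class T2StarFit:
    """Result of the offset-exponential decay fit."""

    t2_star: float
    s_o: float
    c_offset: float
    residual_rms: float
    converged: bool


def _model(te: np.ndarray, s_o: float, t2: float, c: float) -> np.ndarray:
    return s_o * np.exp(-te / t2) + c


def _initial_guess(te: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    c0 = float(s.min())
    so0 = float(s.max() - c0)
    # log-linear slope over the first half of echoes, after offset subtraction
    half = max(2, len(te) // 2)
    y = s[:half] - c0
    pos = y > 0
    t2_0 = 20.0
    if pos.sum() >= 2:
        slope = np.polyfit(te[:half][pos], np.log(y[pos]), 1)[0]
        if slope < 0:
            t2_0 = -1.0 / slope
    t2_0 = float(np.clip(t2_0, T2_BOUNDS_MS[0] * 1.01, T2_BOUNDS_MS[1] * 0.99))
    return so0, t2_0, c0


def fit_t2star(curve: DecayCurve) -> T2StarFit:
    """Bounded nonlinear least-squares fit of S = So exp(-TE/T2*) + C.

    Requires at least 4 echoes (3 free parameters).  Initialization:
    C0 = min(S), So0 = max(S) - C0, T2*0 from a log-linear fit of the first
    half of echoes after offset subtraction.  T2* is constrained to
    (0.1, 500] ms.  Degenerate or non-converging curves are returned with
    ``converged = False`` rather than raising.
    """
    te, s = curve.echo_times, curve.mean_signal
    if len(te) < 4:
        raise ValueError(f"need >= 4 echoes to fit 3 parameters, got {len(te)}")
    span = float(s.max() - s.min())
    if span == 0 or not np.all(np.isfinite(s)):
        return T2StarFit(t2_star=np.nan, s_o=0.0, c_offset=float(s[0]) if np.isfinite(s[0]) else np.nan,
                         residual_rms=0.0, converged=False)
    so0, t2_0, c0 = _initial_guess(te, s)
    scale = max(abs(s).max(), 1e-30)
    lower = [0.0, T2_BOUNDS_MS[0], -10.0 * scale]
    upper = [10.0 * scale, T2_BOUNDS_MS[1], 10.0 * scale]
    x0 = np.clip([max(so0, 1e-12 * scale), t2_0, c0], lower, upper)
    try:
        res = optimize.least_squares(
            lambda p: _model(te, *p) - s, x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
        )
    except Exception:
        return T2StarFit(t2_star=np.nan, s_o=np.nan, c_offset=np.nan, residual_rms=np.nan, converged=False)
    s_o, t2, c = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # a fit pinned to the T2* bounds, or with negligible amplitude, is unidentifiable
    identifiable = (
        res.success
        and s_o > 1e-6 * scale
        and T2_BOUNDS_MS[0] * 1.001 < t2 < T2_BOUNDS_MS[1] * 0.999
    )
    return T2StarFit(t2_star=float(t2), s_o=float(s_o), c_offset=float(c), residual_rms=rms,
                     converged=bool(identifiable))


_SECTOR_COUNT = {"basal": 6, "mid": 6, "apical": 4}


def aha_sectors(annulus_mask: np.ndarray, rv_insertion_angle: float, level: str = "mid") -> RoiSet:
    """Partition a myocardial annulus into equal angular AHA sectors.

    The annulus is divided about its centroid into 6 sectors (basal or mid
    level) or 4 (apical), numbered counterclockwise starting at the
    reference (RV insertion) angle, measured in radians in conventional
    image display orientation (0 = +x/right, counterclockwise positive).
    Sector masks are named ``sector_1`` .. ``sector_n``; they are disjoint
    and their union is exactly the annulus.
    """
    if level not in _SECTOR_COUNT:
        raise ValueError(f"level must be one of {sorted(_SECTOR_COUNT)}, got {level!r}")
    annulus_mask = np.asarray(annulus_mask, dtype=bool)
    if not annulus_mask.any():
        raise ValueError("annulus mask is empty")
    filled = ndimage.binary_fill_holes(annulus_mask)
    if not (filled & ~annulus_mask).any():
        raise ValueError("mask has no enclosed cavity; expected an annular (ring) mask")
    n = _SECTOR_COUNT[level]
    cy, cx = ndimage.center_of_mass(annulus_mask)
    yy, xx = np.mgrid[: annulus_mask.shape[0], : annulus_mask.shape[1]]
    # rows increase downward; negate to get counterclockwise-positive angles
    theta = np.arctan2(-(yy - cy), xx - cx)
    sector_idx = np.floor(((theta - rv_insertion_angle) % (2.0 * np.pi)) / (2.0 * np.pi / n)).astype(int)
    sector_idx = np.clip(sector_idx, 0, n - 1)
    return RoiSet({f"sector_{i + 1}": annulus_mask & (sector_idx == i) for i in range(n)})


def segment_t2star(
    mag_stack: np.ndarray,
    echo_times: np.ndarray,
    sectors: RoiSet,
    min_pixels: int = 5,
) -> pd.DataFrame:
    """Fit the decay model on each sector's ROI-mean curve.

    Returns a table with one row per sector: sector name, pixel count, the
    fitted parameters, residual RMS, convergence flag, and a
    ``low_confidence`` flag for sectors with fewer than ``min_pixels``
    pixels (still fitted).
    """
    mag_stack = np.asarray(mag_stack, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    if mag_stack.shape[1:] != sectors.shape:
        raise ValueError(f"stack grid {mag_stack.shape[1:]} != sector grid {sectors.shape}")
    rows = []
    for name in sectors.names():
        mask = sectors[name]
        n_pix = int(mask.sum())
        means = mag_stack[:, mask].mean(axis=1) if n_pix else np.full(len(echo_times), np.nan)
        fit = fit_t2star(DecayCurve(echo_times, means, roi_name=name))
        rows.append(
            {
                "sector": name,
                "n_pixels": n_pix,
                "t2star_ms": fit.t2_star,
                "so": fit.s_o,
                "c": fit.c_offset,
                "residual_rms": fit.residual_rms,
                "converged": fit.converged,
                "low_confidence": n_pix < min_pixels,
            }
        )
    return pd.DataFrame(rows)
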