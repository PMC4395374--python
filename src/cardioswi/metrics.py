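"""ROI statistics, contrast/SDNR, threshold volumetry and the TE-average sweep.

Operational definitions follow the standard ROI methodology for lesion
conspicuity in magnitude MR images:

    contrast = (S1 - S2) / S1          SDNR = (S1 - S2) / STD

with S1 the reference (adjacent myocardium) mean, S2 the lesion mean, and
STD the raw standard deviation of magnitude values in a signal-free noise
ROI (no Rayleigh correction).  Lesion volumetry uses a half-maximum
threshold over the LV mask, with enclosed hypointense cores (the
microvascular-obstruction pattern) added to the lesion, and is reported as
a percentage of LV myocardial area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from cardioswi.echo_combine import te_average
from cardioswi.rois import RoiSet

__all__ = ["ContrastResult", "VolumeResult", "roi_stats", "contrast_sdnr", "threshold_volume", "sweep_report"]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class ContrastResult:
    s1: float
    s2: float
    contrast: float
    sdnr: float
    noise_std: float
    source_kind: str = "magnitude"
    n_te: int = 1
    n_multiplies: int = 0
    defined: bool = True


@dataclass
class VolumeResult:
    lesion_pixels: int
    lv_pixels: int
    percent_lv: float
    threshold: float
    rule: str


def roi_stats(img: np.ndarray, rois: RoiSet, valid: np.ndarray | None = None) -> pd.DataFrame:
    """Mean/STD/pixel-count per named ROI, over valid pixels only."""
    img = np.asarray(img, dtype=float)
    if img.shape != rois.shape:
        raise ValueError(f"image grid {img.shape} != ROI grid {rois.shape}")
    valid = np.ones(img.shape, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    rows = []
    for name in rois.names():
        sel = rois[name] & valid
        vals = img[sel]
        rows.append(
            {
                "roi": name,
                "n_pixels": int(sel.sum()),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "std": float(vals.std(ddof=0)) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("roi")


def contrast_sdnr(
    img: np.ndarray,
    rois: RoiSet,
    valid: np.ndarray | None = None,
    *,
    source_kind: str = "magnitude",
    n_te: int = 1,
    n_multiplies: int = 0,
) -> ContrastResult:
    """Lesion-vs-adjacent-myocardium contrast and SDNR of one image.

    Requires ROIs named ``lesion``, ``remote_myocardium`` and ``noise``.
    S1 = remote mean, S2 = lesion mean, STD = raw noise-ROI standard
    deviation.  If S1 is zero the contrast is undefined and flagged.
    """
    rois.require("lesion", "remote_myocardium", "noise")
    stats = roi_stats(img, rois, valid=valid)
    s1 = stats.loc["remote_myocardium", "mean"]
    s2 = stats.loc["lesion", "mean"]
    noise_std = stats.loc["noise", "std"]
    noise_mean = stats.loc["noise", "mean"]
    if s1 != 0 and noise_mean > 0.2 * abs(s1):
        warnings.warn(
            f"noise ROI mean ({noise_mean:.3g}) exceeds 20% of reference signal ({s1:.3g}); "
            "the noise region may contain tissue",
            stacklevel=2,
        )
    if s1 == 0:
        return ContrastResult(s1=s1, s2=s2, contrast=np.nan, sdnr=np.nan, noise_std=noise_std,
                              source_kind=source_kind, n_te=n_te, n_multiplies=n_multiplies, defined=False)
    sdnr = (s1 - s2) / noise_std if noise_std > 0 else np.nan
    return ContrastResult(
        s1=float(s1),
        s2=float(s2),
        contrast=float((s1 - s2) / s1),
        sdnr=float(sdnr),
        noise_std=float(noise_std),
        source_kind=source_kind,
        n_te=n_te,
        n_multiplies=n_multiplies,
    )


def _enclosed_holes(above: np.ndarray, lv_mask: np.ndarray) -> np.ndarray:
    """Below-threshold components inside the mask fully surrounded by above-threshold pixels.

    A 4-connected component of non-above pixels counts as an enclosed core
    only if it lies entirely inside the mask and reaches neither the array
    border nor any out-of-mask pixel — i.e. every escape route crosses
    above-threshold tissue.
    """
    labels, n = ndimage.label(~above, structure=_CROSS)
    if n == 0:
        return np.zeros_like(above)
    escaped = np.zeros(n + 1, dtype=bool)
    border = np.zeros_like(above)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    escaped[np.unique(labels[border & ~above])] = True
    escaped[np.unique(labels[~lv_mask & ~above])] = True
    escaped[0] = True
    return ~escaped[labels] & lv_mask


def threshold_volume(img: np.ndarray, lv_mask: np.ndarray, rule: str = "half_max_hyper",
                     threshold: float | None = None) -> VolumeResult:
    """Lesion area under an intensity-threshold rule, as % of the LV mask.

    Rules
    -----
    ``half_max_hyper``
        Pixels >= 50% of the maximum signal over the LV mask (the
        enhancing-infarct convention), plus enclosed hypointense cores
        (4-connected below-threshold components fully surrounded by
        above-threshold pixels), which are counted as part of the lesion.
    ``manual_hypo``
        Pixels <= ``threshold`` (hemorrhage/no-reflow hypointensity with an
        explicit numeric cutoff in image units).
    """
    img = np.asarray(img, dtype=float)
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not lv_mask.any():
        raise ValueError("LV mask is empty")
    if img.shape != lv_mask.shape:
        raise ValueError("image and LV mask shapes differ")
    if rule == "half_max_hyper":
        thr = 0.5 * img[lv_mask].max()
        above = lv_mask & (img >= thr)
        lesion = above | _enclosed_holes(above, lv_mask)
    elif rule == "manual_hypo":
        if threshold is None:
            raise ValueError("manual_hypo rule requires an explicit threshold")
        thr = float(threshold)
        lesion = lv_mask & (img <= thr)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    lesion_pixels = int(lesion.sum())
    lv_pixels = int(lv_mask.sum())
    return VolumeResult(
        lesion_pixels=lesion_pixels,
        lv_pixels=lv_pixels,
        percent_lv=100.0 * lesion_pixels / lv_pixels,
        threshold=float(thr),
        rule=rule,
    )


def sweep_report(
    mag_stack: np.ndarray,
    swi_stacks: dict[str, np.ndarray],
    rois: RoiSet,
    echo_times: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Contrast/SDNR for every (source, n_te) combination of the TE-average sweep.

    ``swi_stacks`` maps a source label (e.g. ``swi3``, ``swi6``) to its
    per-echo SWI stack; the label's trailing integer is recorded as the
    mask-multiplication count when present.  Validity planes, if given, are
    collapsed over the echo axis (a pixel must be valid at every averaged
    echo).
    """
    mag_stack = np.asarray(mag_stack, dtype=float)
    sources: dict[str, tuple[np.ndarray, int]] = {"magnitude": (mag_stack, 0)}
    for label, stack in swi_stacks.items():
        stack = np.asarray(stack, dtype=float)
        if stack.shape != mag_stack.shape:
            raise ValueError(f"stack {label!r} shape {stack.shape} != magnitude shape {mag_stack.shape}")
        digits = "".join(ch for ch in label if ch.isdigit())
        sources[label] = (stack, int(digits) if digits else 0)
    all_valid = None if valid is None else np.asarray(valid, dtype=bool)
    rows = []
    for label, (stack, n_mult) in sources.items():
        for n_te in range(1, stack.shape[0] + 1):
            avg = te_average(stack, n_te, echo_times=echo_times, source_kind=label)
            v = None if all_valid is None else np.all(all_valid[avg.echo_indices], axis=0)
            r = contrast_sdnr(avg.data, rois, valid=v, source_kind=label, n_te=n_te, n_multiplies=n_mult)
            rows.append(
                {
                    "source": label,
                    "n_te": n_te,
                    "n_multiplies": n_mult,
                    "s1": r.s1,
                    "s2": r.s2,
                    "contrast": r.contrast,
                    "sdnr": r.sdnr,
                    "noise_std": r.noise_std,
                }
            )
    return pd.DataFrame(rows)
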