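"""Digital short-axis left-ventricle phantom with multi-coil multi-echo k-space.

The phantom emulates a mid-ventricular short-axis slice acquired with a
multi-echo gradient-echo sequence: an annular myocardium (normal T2* around
34 ms), a signal-suppressed blood pool, air/lung background, and a focal
hemorrhagic lesion inside the annulus with short T2* (around 16 ms) and an
additional locally negative phase offset — the susceptibility signature SWI
exploits.  Each pixel follows the offset-free mono-exponential signal model

    S(TE) = rho * exp(-TE / T2*) * exp(i * (2*pi*df*TE + phi_focal*w(x, y)))

where ``w`` is 1 inside the lesion and 0 elsewhere.  Multi-coil k-space is
the centered orthonormal 2-D FFT of the coil-weighted image plus i.i.d.
circular complex Gaussian noise, deterministic for a given seed.

All downstream stages (reconstruction, phase filtering, SWI, TE-averaging,
T2* fitting, metrics) can therefore be validated against exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from cardioswi.fourier import fft2c
from cardioswi.rois import RoiSet

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "KSpaceSeries",
    "default_echo_times",
    "default_tissues",
    "coil_sensitivities",
    "phantom_rois",
    "ground_truth_image",
    "simulate_kspace",
]


def default_echo_times() -> np.ndarray:
    """12 echo times spanning 2.4-15.5 ms at ~1.2 ms spacing (ms)."""
    return np.linspace(2.4, 15.5, 12)


@dataclass(frozen=True)
class TissueParams:
    """Signal-model parameters of one tissue compartment.

    Parameters
    ----------
    proton_density : float
        Equilibrium signal amplitude, arbitrary units, >= 0.
    t2_star : float
        Effective transverse relaxation time in ms, > 0.
    off_resonance : float
        Global off-resonance in Hz; a spatially smooth (here constant)
        phase source that the homodyne high-pass filter removes.
    focal_phase : float
        Extra phase in radians applied only inside the lesion; negative
        values model hemorrhage (paramagnetic blood products).
    """

    proton_density: float
    t2_star: float
    off_resonance: float = 0.0
    focal_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.proton_density < 0:
            raise ValueError(f"proton_density must be >= 0, got {self.proton_density}")
        if self.t2_star <= 0:
            raise ValueError(f"t2_star must be > 0 ms, got {self.t2_star}")
        if not -np.pi <= self.focal_phase <= np.pi:
            raise ValueError(f"focal_phase must lie in [-pi, pi], got {self.focal_phase}")


def default_tissues() -> dict[str, TissueParams]:
    """Tissue table for the default hemorrhage phantom.

    Normal myocardium uses the healthy segmental T2* (34.1 ms), the lesion
    the hemorrhagic segmental T2* (16.2 ms) with a -1 rad focal phase.
    Blood is given a low proton density to mimic dark-blood preparation;
    background (air/lung) carries no signal, so its magnitude is pure
    Rayleigh noise — the noise ROI.
    """
    return {
        "myocardium": TissueParams(proton_density=1.0, t2_star=34.1, off_resonance=10.0),
        "blood": TissueParams(proton_density=0.3, t2_star=80.0, off_resonance=10.0),
        "lesion": TissueParams(proton_density=1.0, t2_star=16.2, off_resonance=10.0, focal_phase=-1.0),
        "background": TissueParams(proton_density=0.0, t2_star=1000.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Complete ground-truth description of the phantom acquisition.

    Geometry is in pixels on ``grid_shape``; ``lv_center`` and
    ``lesion_center`` default to the grid center and the mid-annulus of the
    inferior wall respectively.  ``noise_sigma`` is the standard deviation
    of each real/imaginary k-space channel, per coil, in signal units.
    """

    grid_shape: tuple[int, int] = (192, 192)
    pixel_size: float = 1.5
    lv_center: tuple[float, float] | None = None
    lv_inner_radius: float = 18.0
    lv_outer_radius: float = 27.0
    lesion_center: tuple[float, float] | None = None
    lesion_radius: float = 4.0
    tissues: dict[str, TissueParams] = field(default_factory=default_tissues)
    echo_times: np.ndarray = field(default_factory=default_echo_times)
    n_coils: int = 4
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "echo_times", np.asarray(self.echo_times, dtype=float))
        if self.lv_inner_radius >= self.lv_outer_radius:
            raise ValueError("lv_inner_radius must be < lv_outer_radius")
        if len(self.echo_times) < 1 or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be non-empty and strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_coils < 1:
            raise ValueError(f"n_coils must be >= 1, got {self.n_coils}")
        for name in ("myocardium", "blood", "lesion", "background"):
            if name not in self.tissues:
                raise ValueError(f"tissues table is missing {name!r}")

    @property
    def center(self) -> tuple[float, float]:
        if self.lv_center is not None:
            return self.lv_center
        return (self.grid_shape[0] / 2.0, self.grid_shape[1] / 2.0)

    @property
    def lesion_centre(self) -> tuple[float, float]:
        if self.lesion_center is not None:
            return self.lesion_center
        cy, cx = self.center
        mid_r = 0.5 * (self.lv_inner_radius + self.lv_outer_radius)
        return (cy + mid_r, cx)  # inferior wall (image rows increase downward)

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass
class KSpaceSeries:
    """DC-centered complex k-space indexed (echo, coil, row, col)."""

    data: np.ndarray
    echo_times: np.ndarray
    coil_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"k-space data must be (echo, coil, row, col), got shape {self.data.shape}")
        if self.data.shape[0] != len(self.echo_times):
            raise ValueError("echo axis length does not match echo_times")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space contains non-finite values")
        if not self.coil_ids:
            self.coil_ids = [f"coil{i}" for i in range(self.data.shape[1])]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _region_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    outer = _disk(spec.grid_shape, spec.center, spec.lv_outer_radius)
    inner = _disk(spec.grid_shape, spec.center, spec.lv_inner_radius)
    annulus = outer & ~inner
    lesion = _disk(spec.grid_shape, spec.lesion_centre, spec.lesion_radius)
    if not np.all(annulus[lesion]):
        raise ValueError(
            "lesion is not contained in the myocardial annulus: "
            f"lesion center {spec.lesion_centre}, radius {spec.lesion_radius}, "
            f"annulus radii ({spec.lv_inner_radius}, {spec.lv_outer_radius}) about {spec.center}"
        )
    return {"annulus": annulus, "blood": inner, "lesion": lesion, "background": ~outer}


def phantom_rois(spec: PhantomSpec) -> RoiSet:
    """Exact analysis masks: lesion, remote myocardium, LV myocardium, noise.

    Remote ("adjacent") myocardium is the annulus minus the lesion dilated by
    a 2-pixel guard ring, so ROI statistics are free of partial-volume mixing
    at the lesion rim.  The noise ROI is a signal-free background block in
    the image corner.
    """
    regions = _region_masks(spec)
    guard = ndimage.binary_dilation(regions["lesion"], iterations=2)
    remote = regions["annulus"] & ~guard
    block = max(8, min(spec.grid_shape) // 8)
    noise = np.zeros(spec.grid_shape, dtype=bool)
    noise[2 : 2 + block, 2 : 2 + block] = True
    if not np.all(regions["background"][noise]):
        raise ValueError("noise ROI block overlaps the LV; enlarge the grid")
    return RoiSet(
        {
            "lesion": regions["lesion"],
            "remote_myocardium": remote,
            "lv_myocardium": regions["annulus"],
            "blood": regions["blood"],
            "noise": noise,
        }
    )


def ground_truth_image(spec: PhantomSpec, echo_index: int) -> tuple[np.ndarray, RoiSet]:
    """Noiseless complex image at one echo, plus the exact ROI masks."""
    te = float(spec.echo_times[echo_index])
    regions = _region_masks(spec)
    image = np.zeros(spec.grid_shape, dtype=complex)
    tissue_of_region = {
        "annulus": "myocardium",
        "blood": "blood",
        "lesion": "lesion",
        "background": "background",
    }
    # lesion overwrites the annulus pixels it occupies
    for region in ("background", "blood", "annulus", "lesion"):
        t = spec.tissues[tissue_of_region[region]]
        mag = t.proton_density * np.exp(-te / t.t2_star)
        phase = 2.0 * np.pi * t.off_resonance * te * 1e-3 + t.focal_phase
        image[regions[region]] = mag * np.exp(1j * phase)
    return image, phantom_rois(spec)


def coil_sensitivities(spec: PhantomSpec) -> np.ndarray:
    """Smooth positive coil profiles (coil, row, col), sum-of-squares == 1.

    ``n_coils`` Gaussian-falloff profiles centered at distinct positions on a
    circle around the image, normalized pixelwise so the sum of squares is
    exactly one — the sum-of-squares combined magnitude then equals the true
    magnitude everywhere, which keeps the phantom's ground truth meaningful
    after coil combination.
    """
    ny, nx = spec.grid_shape
    yy, xx = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ring_r = 0.75 * max(ny, nx)
    sigma = 0.7 * max(ny, nx)
    profiles = np.empty((spec.n_coils, ny, nx))
    for k in range(spec.n_coils):
        ang = 2.0 * np.pi * k / spec.n_coils
        py, px = cy + ring_r * np.sin(ang), cx + ring_r * np.cos(ang)
        profiles[k] = np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2.0 * sigma**2))
    sos = np.sqrt(np.sum(profiles**2, axis=0))
    return profiles / sos


def simulate_kspace(spec: PhantomSpec) -> KSpaceSeries:
    """Multi-coil multi-echo k-space of the phantom with complex Gaussian noise.

    For each echo and coil the k-space is the centered orthonormal forward
    FFT of (ground-truth image x coil sensitivity) plus i.i.d. circular
    complex Gaussian noise of standard deviation ``noise_sigma`` per
    real/imaginary channel.  Bit-reproducible for a fixed ``seed``.
    """
    if spec.n_coils < 1:
        raise ValueError(f"n_coils must be >= 1, got {spec.n_coils}")
    coils = coil_sensitivities(spec)
    ne, nc = len(spec.echo_times), spec.n_coils
    ny, nx = spec.grid_shape
    data = np.empty((ne, nc, ny, nx), dtype=complex)
    for e in range(ne):
        image, _ = ground_truth_image(spec, e)
        data[e] = fft2c(image[None, :, :] * coils)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(scale=spec.noise_sigma, size=(ne, nc, ny, nx, 2))
        data += noise[..., 0] + 1j * noise[..., 1]
    elif spec.noise_sigma == 0:
        pass
    else:  # pragma: no cover - guarded in PhantomSpec
        raise ValueError("noise_sigma must be >= 0")
    if spec.noise_sigma == 0 and not np.all(np.isfinite(data)):
        warnings.warn("non-finite values in simulated k-space", stacklevel=2)
    return KSpaceSeries(data=data, echo_times=spec.echo_times.copy())
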