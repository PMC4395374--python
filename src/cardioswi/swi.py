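"""Negative-phase masking: susceptibility-weighted image construction.

The phase mask maps high-pass-filtered phase to an attenuation factor that
emphasizes negative phase (the hemorrhage signature):

    mask(phi) = (pi + phi) / pi   for -pi < phi < 0
    mask(phi) = 1                 otherwise

The SWI image is the coil-combined magnitude multiplied pixelwise by the
mask raised to the n_multiplies power; more multiplications deepen the
suppression of negative-phase tissue, increasing lesion contrast at the
cost of amplifying phase noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardioswi.recon import EchoSeries  # noqa: F401  (re-exported type context)

__all__ = ["PhaseMask", "SwiImage", "phase_mask", "apply_mask", "swi_series"]

DEFAULT_N_MULTIPLIES = 6


@dataclass
class PhaseMask:
    """Pixelwise attenuation in [0, 1] derived from HPF phase."""

    values: np.ndarray
    valid: np.ndarray
    source_echo: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        v = self.values[self.valid]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("phase mask values must lie in [0, 1]")


@dataclass
class SwiImage:
    """Susceptibility-weighted image with its provenance."""

    data: np.ndarray
    n_multiplies: int
    echo_time: float | None = None
    valid: np.ndarray | None = field(default=None, repr=False)


def phase_mask(phase: np.ndarray, valid: np.ndarray | None = None, source_echo: int | None = None) -> PhaseMask:
    """Build the negative-phase mask from a wrapped phase image.

    Phase must already be wrapped to (-pi, pi].  Negative phase maps
    linearly onto (0, 1); zero or positive phase maps to 1; phi -> -pi
    gives mask -> 0.  Invalid pixels receive mask 1 (no attenuation) and
    stay flagged, so masked-out regions cannot fabricate lesions.
    """
    phase = np.asarray(phase, dtype=float)
    tol = 1e-12
    if np.any(phase > np.pi + tol) or np.any(phase <= -np.pi - tol):
        raise ValueError("phase must be wrapped to (-pi, pi]; wrap upstream before masking")
    values = np.where(phase < 0, (np.pi + phase) / np.pi, 1.0)
    values = np.clip(values, 0.0, 1.0)
    if valid is None:
        valid = np.ones(phase.shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        values = np.where(valid, values, 1.0)
    return PhaseMask(values=values, valid=valid, source_echo=source_echo)


def apply_mask(magnitude: np.ndarray, mask: PhaseMask, n_multiplies: int = DEFAULT_N_MULTIPLIES) -> SwiImage:
    """SWI = magnitude x mask^n, pixelwise.

    ``n_multiplies`` = 0 is the identity on the magnitude; the output is
    bounded above by the magnitude everywhere since the mask is <= 1.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if n_multiplies < 0:
        raise ValueError(f"n_multiplies must be >= 0, got {n_multiplies}")
    if magnitude.shape != mask.values.shape:
        raise ValueError(f"magnitude shape {magnitude.shape} != mask shape {mask.values.shape}")
    return SwiImage(
        data=magnitude * mask.values**n_multiplies,
        n_multiplies=n_multiplies,
        valid=mask.valid,
    )


def swi_series(
    magnitude_stack: np.ndarray,
    phase_stack: np.ndarray,
    n_multiplies: int = DEFAULT_N_MULTIPLIES,
    valid: np.ndarray | None = None,
    echo_times: np.ndarray | None = None,
) -> np.ndarray:
    """Per-echo SWI stack: each echo is masked with its own HPF phase.

    Parameters
    ----------
    magnitude_stack, phase_stack : (n_echo, ny, nx)
        Coil-combined magnitude and HPF phase, co-registered.
    valid : optional (n_echo, ny, nx) boolean
        HPF-phase validity; invalid pixels are not attenuated.
    echo_times : optional, used only for consistency checking.
    """
    magnitude_stack = np.asarray(magnitude_stack, dtype=float)
    phase_stack = np.asarray(phase_stack, dtype=float)
    if magnitude_stack.shape != phase_stack.shape:
        raise ValueError(
            f"magnitude stack {magnitude_stack.shape} and phase stack {phase_stack.shape} disagree"
        )
    if echo_times is not None and len(echo_times) != magnitude_stack.shape[0]:
        raise ValueError("echo_times length does not match the stack's echo axis")
    out = np.empty_like(magnitude_stack)
    for e in range(magnitude_stack.shape[0]):
        v = None if valid is None else valid[e]
        m = phase_mask(phase_stack[e], valid=v, source_echo=e)
        out[e] = apply_mask(magnitude_stack[e], m, n_multiplies).data
    return out
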