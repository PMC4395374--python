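"""TE-averaging of magnitude/SWI stacks and the inverted-grayscale display map.

Averaging the nTE longest-echo images trades lesion contrast (diluted by
the shorter, less T2*-weighted echoes) against noise (the standard
deviation of the mean falls as 1/sqrt(nTE)).  From a 12-echo series this
yields 11 distinct multi-echo averages; nTE = 1 is the longest-TE image
unchanged.  Grayscale inversion is a display-only transform that renders
hemorrhage hyperintense, echoing late-gadolinium-enhancement conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TeAveragedImage", "te_average", "te_average_sweep", "invert_grayscale"]


@dataclass
class TeAveragedImage:
    """Arithmetic mean of the n_te longest-TE images of a stack."""

    data: np.ndarray
    n_te: int
    echo_indices: np.ndarray
    source_kind: str = "magnitude"
    display_only: bool = False


def te_average(
    stack: np.ndarray,
    n_te: int,
    echo_times: np.ndarray | None = None,
    source_kind: str = "magnitude",
) -> TeAveragedImage:
    """Average the ``n_te`` highest-TE images of a (n_echo, ny, nx) stack.

    Echoes are assumed ordered by increasing TE along axis 0 (pass
    ``echo_times`` to have this checked).  ``n_te = 1`` returns the
    longest-TE image unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    n_echoes = stack.shape[0]
    if not 1 <= n_te <= n_echoes:
        raise ValueError(f"n_te must be in [1, {n_echoes}], got {n_te}")
    if echo_times is not None:
        echo_times = np.asarray(echo_times, dtype=float)
        if len(echo_times) != n_echoes:
            raise ValueError("echo_times length does not match stack")
        if np.any(np.diff(echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
    indices = np.arange(n_echoes - n_te, n_echoes)
    return TeAveragedImage(
        data=stack[indices].mean(axis=0),
        n_te=n_te,
        echo_indices=indices,
        source_kind=source_kind,
    )


def te_average_sweep(
    stack: np.ndarray,
    echo_times: np.ndarray | None = None,
    source_kind: str = "magnitude",
) -> list[TeAveragedImage]:
    """All TE-averages of a stack, n_te = 1 .. n_echoes, in that order."""
    stack = np.asarray(stack, dtype=float)
    if stack.size == 0 or stack.shape[0] == 0:
        raise ValueError("empty stack")
    return [te_average(stack, n, echo_times=echo_times, source_kind=source_kind) for n in range(1, stack.shape[0] + 1)]


def invert_grayscale(img: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Clip to [low, high] and map v -> (high - v)/(high - low) in [0, 1].

    Display-only: abnormal (dark) tissue becomes bright.  Never feed the
    result back into quantitative metrics.
    """
    low, high = window
    if not high > low:
        raise ValueError(f"display window must satisfy high > low, got {window}")
    clipped = np.clip(np.asarray(img, dtype=float), low, high)
    return (high - clipped) / (high - low)
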