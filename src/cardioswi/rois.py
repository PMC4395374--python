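"""Named boolean region-of-interest masks on a common image grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiSet"]


@dataclass
class RoiSet:
    """A collection of named boolean masks sharing one image grid.

    Masks may overlap (e.g. ``lesion`` is a subset of ``lv_myocardium``).
    For label-map export, ``to_labels`` assigns integer labels in a stated
    order; overlapping pixels take the label listed last.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks have inconsistent shapes: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, ...]:
        if not self.masks:
            raise ValueError("empty RoiSet has no shape")
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def require(self, *names: str) -> None:
        """Raise KeyError naming the first missing required ROI."""
        for name in names:
            if name not in self.masks:
                raise KeyError(f"required ROI {name!r} is missing (have {sorted(self.masks)})")

    def to_labels(self, order: list[str] | None = None) -> tuple[np.ndarray, dict[str, int]]:
        """Flatten to an integer label image plus a name->label map."""
        order = order if order is not None else sorted(self.masks)
        labels = np.zeros(self.shape, dtype=np.int16)
        name_to_label = {}
        for i, name in enumerate(order, start=1):
            labels[self.masks[name]] = i
            name_to_label[name] = i
        return labels, name_to_label

    @classmethod
    def from_labels(cls, labels: np.ndarray, name_to_label: dict[str, int]) -> "RoiSet":
        return cls({name: labels == lab for name, lab in name_to_label.items()})
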