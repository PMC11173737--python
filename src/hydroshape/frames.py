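"""Per-frame water configurations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FrameValidationError

#: Plausible covalent O–H distance window, Å.
OH_DISTANCE_RANGE = (0.5, 1.5)


@dataclass
class WaterFrame:
    """One time frame of water oxygen/hydrogen coordinates.

    ``oxygen_positions`` has shape (N, 3) and ``hydrogen_positions`` shape
    (N, 2, 3), both in Å: every water carries exactly two hydrogens.  ``box``
    holds orthorhombic box lengths (3,) in Å; ``None`` means no periodicity.
    """

    frame_index: int
    oxygen_positions: np.ndarray
    hydrogen_positions: np.ndarray
    box: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.oxygen_positions = np.asarray(self.oxygen_positions, dtype=float).reshape(-1, 3)
        self.hydrogen_positions = np.asarray(self.hydrogen_positions, dtype=float).reshape(
            -1, 2, 3
        )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_waters(self) -> int:
        return self.oxygen_positions.shape[0]

    def minimum_image(self, disp: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        if self.box is None:
            return disp
        return disp - self.box * np.round(disp / self.box)

    def validate(self) -> None:
        """Check structural invariants; raise FrameValidationError on failure."""
        n = self.n_waters
        if self.hydrogen_positions.shape != (n, 2, 3):
            raise FrameValidationError(
                f"hydrogen_positions shape {self.hydrogen_positions.shape} "
                f"inconsistent with {n} waters"
            )
        if self.box is not None and np.any(self.box <= 0):
            raise FrameValidationError(f"box lengths must be positive, got {self.box}")
        if n == 0:
            return
        oh = self.minimum_image(self.hydrogen_positions - self.oxygen_positions[:, None, :])
        dist = np.linalg.norm(oh, axis=-1)
        lo, hi = OH_DISTANCE_RANGE
        bad = (dist <= lo) | (dist >= hi)
        if np.any(bad):
            i = int(np.argwhere(bad)[0][0])
            raise FrameValidationError(
                f"O–H distance out of {OH_DISTANCE_RANGE} Å for molecule {i}: "
                f"{dist[i]} Å"
            )
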