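"""Machine geometry model for a step-and-shoot MR-linac.

All positions throughout the package are IEC 61217 coordinates projected to
the isocenter plane, in millimetres: X is the cross-plane direction (jaw
travel), Y is the in-plane direction (leaf travel), origin at the isocenter.
The default geometry describes the Elekta Unity treatment head: SAD 143.5 cm,
maximum field 57.4 cm (X) x 22.0 cm (Y), 160 leaves in two opposing banks of
80 travelling in Y.

The leaf width at the isocenter plane is fixed by the field width divided by
the number of leaf pairs (574.0 mm / 80 = 7.175 mm, consistent with published
Unity specifications); other machines can be described by overriding the
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError

__all__ = ["MachineGeometry", "default_geometry", "leaf_index_for_x"]

_EDGE_TOL = 1e-6  # mm


@dataclass(frozen=True)
class MachineGeometry:
    """Immutable description of the treatment head at the isocenter plane.

    Parameters
    ----------
    sad_cm:
        Source-axis distance in centimetres.
    field_x_mm, field_y_mm:
        Maximum field extent at the isocenter plane in the cross-plane (X)
        and in-plane (Y) directions, in millimetres.
    n_leaf_pairs:
        Number of opposing leaf pairs (the machine has ``2 * n_leaf_pairs``
        leaves).
    """

    sad_cm: float = 143.5
    field_x_mm: float = 574.0
    field_y_mm: float = 220.0
    n_leaf_pairs: int = 80
    leaf_width_mm: float = field(init=False)
    leaf_edges_x_mm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_leaf_pairs < 1 or self.field_x_mm <= 0 or self.field_y_mm <= 0:
            raise UsageError("geometry fields must be positive")
        width = self.field_x_mm / self.n_leaf_pairs
        edges = -self.field_x_mm / 2.0 + width * np.arange(self.n_leaf_pairs + 1)
        edges[-1] = self.field_x_mm / 2.0  # exact upper bound
        object.__setattr__(self, "leaf_width_mm", width)
        object.__setattr__(self, "leaf_edges_x_mm", edges)
        self.leaf_edges_x_mm.setflags(write=False)
        assert abs(self.n_leaf_pairs * self.leaf_width_mm - self.field_x_mm) < _EDGE_TOL

    @property
    def half_x_mm(self) -> float:
        return self.field_x_mm / 2.0

    @property
    def half_y_mm(self) -> float:
        return self.field_y_mm / 2.0

    def leaf_index_for_x(self, x_mm: float) -> int:
        """Return the 0-based leaf-pair index whose X interval contains ``x_mm``.

        Leaf intervals are half-open ``[left_edge, right_edge)`` so every
        in-range X maps to exactly one pair; ``x_mm`` must satisfy
        ``-field_x_mm/2 <= x_mm < +field_x_mm/2``.
        """
        if not (-self.half_x_mm <= x_mm < self.half_x_mm):
            raise UsageError(
                f"x={x_mm} mm outside the field [{-self.half_x_mm}, {self.half_x_mm}) mm"
            )
        idx = int(np.searchsorted(self.leaf_edges_x_mm, x_mm, side="right")) - 1
        return min(max(idx, 0), self.n_leaf_pairs - 1)


def default_geometry() -> MachineGeometry:
    """The Elekta Unity defaults (SAD 143.5 cm, 574 x 220 mm, 80 leaf pairs)."""
    return MachineGeometry()


def leaf_index_for_x(geometry: MachineGeometry, x_mm: float) -> int:
    """Functional alias for :meth:`MachineGeometry.leaf_index_for_x`."""
    return geometry.leaf_index_for_x(x_mm)
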