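"""Multi-well plate layouts, well indexing and field-of-view arithmetic.

A plate is a rectangular grid of wells.  Wells are addressed by
``(row, col)`` with row 0 = plate row A (top) and col 0 = column 1
(left), so the origin well A1 is the top-left drop the operator centers
during calibration.  For position prediction a well is reduced to its
normalized grid fraction ``(u, v)`` in the unit square; the calibration
module maps fractions to machine coordinates, so the physical pitches
stored here are informational only.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PlateSpec:
    """Grid shape and physical well pitch of a multi-well plate.

    Pitches follow the ANSI/SLAS microplate standard (9.0 mm for a
    96-well plate).  They document the plate but never drive the stage:
    actual positioning comes from the four-corner calibration, so a
    pitch error cannot corrupt a scan.
    """

    name: str
    n_rows: int
    n_cols: int
    pitch_x: float = 9.0
    pitch_y: float = 9.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate must have at least one row and one column")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("well pitch must be positive")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_label(self, row: int, col: int) -> str:
        """Alphanumeric well name, e.g. (0, 0) -> 'A1', (7, 11) -> 'H12'."""
        self._check_index(row, col)
        if row < 26:
            letter = chr(ord("A") + row)
        else:  # 1536-well style double letters, AA, AB, ...
            letter = chr(ord("A") + row // 26 - 1) + chr(ord("A") + row % 26)
        return f"{letter}{col + 1}"

    def _check_index(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows):
            raise IndexError(f"row {row} out of range for {self.n_rows}-row plate")
        if not (0 <= col < self.n_cols):
            raise IndexError(f"col {col} out of range for {self.n_cols}-col plate")


@dataclass(frozen=True)
class GridFraction:
    """Normalized well position: u along columns, v along rows, in [0, 1]."""

    u: float
    v: float


@dataclass(frozen=True)
class DetectorSpec:
    """Physical size of a camera detector chip in mm."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("detector dimensions must be positive")


#: 1080p HDMI microscope camera chip (5.5 x 3.4 mm).
AMSCOPE_1080P = DetectorSpec(width=5.5, height=3.4)
#: Micro Four Thirds consumer camera chip (21.6 x 13 mm).
MICRO_FOUR_THIRDS = DetectorSpec(width=21.6, height=13.0)


_BUILTIN: dict[str, PlateSpec] = {
    "96": PlateSpec("96", n_rows=8, n_cols=12, pitch_x=9.0, pitch_y=9.0),
    "24": PlateSpec("24", n_rows=4, n_cols=6, pitch_x=19.3, pitch_y=19.3),
    "12": PlateSpec("12", n_rows=3, n_cols=4, pitch_x=26.0, pitch_y=26.0),
}

_REGISTRY: dict[str, PlateSpec] = dict(_BUILTIN)


def builtin_plate(name: str) -> PlateSpec:
    """Look up a plate layout by name.

    Ships with the three standard SBS formats the plate holder accepts
    ("12", "24", "96"); further layouts can be added with
    :func:`register_plate`.

    Raises
    ------
    KeyError
        If ``name`` is not a known plate, with the valid options listed.
    """
    key = str(name)
    try:
        return _REGISTRY[key]
    except KeyError:
        options = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown plate {name!r}; valid plates: {options}") from None


def register_plate(spec: PlateSpec) -> PlateSpec:
    """Register a custom plate layout so builtin_plate can find it by name."""
    _REGISTRY[spec.name] = spec
    return spec


def grid_fraction(spec: PlateSpec, row: int, col: int) -> GridFraction:
    """Normalized grid fraction of a well.

    ``u = col / (n_cols - 1)`` and ``v = row / (n_rows - 1)``; a
    degenerate single-row or single-column axis maps to 0 so a 1xN strip
    (or a 1x1 dish) is still addressable.
    """
    spec._check_index(row, col)
    u = col / (spec.n_cols - 1) if spec.n_cols > 1 else 0.0
    v = row / (spec.n_rows - 1) if spec.n_rows > 1 else 0.0
    return GridFraction(u=u, v=v)


def nearest_well(spec: PlateSpec, g: GridFraction) -> tuple[int, int]:
    """Inverse of grid_fraction: the (row, col) whose fraction is closest."""
    col = round(g.u * (spec.n_cols - 1)) if spec.n_cols > 1 else 0
    row = round(g.v * (spec.n_rows - 1)) if spec.n_rows > 1 else 0
    return int(min(max(row, 0), spec.n_rows - 1)), int(min(max(col, 0), spec.n_cols - 1))


def field_of_view(detector: DetectorSpec, magnification: float) -> tuple[float, float]:
    """Field of view (width, height) in mm at a given magnification.

    At 1x the field of view equals the detector chip; at magnification m
    it shrinks to 1/m of the chip in each dimension.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    return detector.width / magnification, detector.height / magnification
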