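"""G-code scan program generation for the plate imager.

The stage controller runs GRBL, so a scan is just a text program in a
small G-code subset: ``g90``/``g21`` modal setup (absolute coordinates,
mm), ``g0`` rapid moves, ``g4 p<s>`` dwells, and ``m3``/``m5`` which on
this machine close and open the camera relay instead of switching a
cutting tool.  One camera trigger is the sequence m3, pulse dwell, m5.

Per well the program moves to the calibrated xy position, steps through
``n_z`` focus levels centered on the calibrated z (spaced ``dz`` mm,
top to bottom), triggers the camera at each, and finally captures one
deliberately out-of-focus sentinel image well above the stack.  The
sentinel's small JPEG size later marks the end of the well's z-stack in
the image series.  Dwells let the stage settle after each move
(``settle_dwell``) and give the camera time to write each image to its
card (``write_dwell``); without the write dwell the camera skips frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Union

from platescan.calibration import BilinearMap, predict
from platescan.plate_geometry import GridFraction, PlateSpec, grid_fraction

__all__ = [
    "ScanConfig",
    "GCodeProgram",
    "RapidMove",
    "Dwell",
    "RelayClose",
    "RelayOpen",
    "ModalSetup",
    "plan_scan",
    "render_gcode",
    "parse_gcode",
    "count_images",
    "well_order",
    "xy_travel",
]

SCAN_ORDERS = ("row-serpentine", "row-major")


@dataclass(frozen=True)
class ScanConfig:
    """Scan protocol parameters.

    Defaults follow the 2 µl sitting-drop protocol: five images per
    well spaced 0.15 mm in z, a 0.1 s settle dwell after each move and
    0.5 s per image for the camera to finish writing (0.4–0.6 s is the
    workable range), plus one sentinel image 1 mm above the stack top.
    """

    n_z: int = 5
    dz: float = 0.15
    settle_dwell: float = 0.1
    write_dwell: float = 0.5
    pulse_dwell: float = 0.2
    sentinel: bool = True
    sentinel_offset: float = 1.0
    order: str = "row-serpentine"

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise ValueError("n_z must be at least 1")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        for name in ("settle_dwell", "write_dwell", "pulse_dwell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.order not in SCAN_ORDERS:
            raise ValueError(f"order must be one of {SCAN_ORDERS}")
        if self.sentinel and self.sentinel_offset < 3 * self.dz:
            warnings.warn(
                f"sentinel_offset {self.sentinel_offset} mm is less than 3*dz; "
                "the sentinel image may not be obviously out of focus",
                stacklevel=3,
            )

    @property
    def images_per_well(self) -> int:
        return self.n_z + (1 if self.sentinel else 0)

    def z_levels(self, z0: float) -> list[float]:
        """Stack z positions, top to bottom, centered on the focus z0.

        Centering tolerates calibration error in either direction, which
        is the point of capturing a stack rather than one image.
        """
        half = (self.n_z - 1) / 2.0
        return [z0 + self.dz * (half - i) for i in range(self.n_z)]


@dataclass(frozen=True)
class ModalSetup:
    """Absolute-coordinate mode and mm units (g90, g21)."""


@dataclass(frozen=True)
class RapidMove:
    x: float | None = None
    y: float | None = None
    z: float | None = None


@dataclass(frozen=True)
class Dwell:
    seconds: float


@dataclass(frozen=True)
class RelayClose:
    """m3 — closes the camera relay (presses the shutter)."""


@dataclass(frozen=True)
class RelayOpen:
    """m5 — opens the camera relay (releases the shutter)."""


Command = Union[ModalSetup, RapidMove, Dwell, RelayClose, RelayOpen]


@dataclass
class GCodeProgram:
    """Ordered command list plus, per command, the well-visit index.

    ``well_index[i]`` is the 0-based position in scan order of the well
    the i-th command belongs to, or None for the program header.
    """

    commands: list[Command] = field(default_factory=list)
    well_index: list[int | None] = field(default_factory=list)

    def append(self, cmd: Command, well: int | None = None) -> None:
        self.commands.append(cmd)
        self.well_index.append(well)

    def __len__(self) -> int:
        return len(self.commands)

    def __iter__(self) -> Iterator[Command]:
        return iter(self.commands)


def well_order(spec: PlateSpec, order: str = "row-serpentine") -> list[tuple[int, int]]:
    """Well visit order as (row, col) pairs.

    Row-serpentine alternates column direction on each row so that
    consecutive wells are always one grid step apart; row-major rewinds
    to column 0 at each new row.
    """
    if order not in SCAN_ORDERS:
        raise ValueError(f"order must be one of {SCAN_ORDERS}")
    out: list[tuple[int, int]] = []
    for row in range(spec.n_rows):
        cols = range(spec.n_cols)
        if order == "row-serpentine" and row % 2 == 1:
            cols = reversed(cols)
        out.extend((row, col) for col in cols)
    return out


def plan_scan(bmap: BilinearMap, spec: PlateSpec, config: ScanConfig | None = None) -> GCodeProgram:
    """Build the G-code program that scans every well of the plate.

    Per well: one combined move to the well's xy at the stack-top z,
    then for each z level top to bottom a z move (skipped for the top
    level, already reached), settle dwell, camera trigger and write
    dwell; if enabled, the sentinel image is captured last at
    ``sentinel_offset`` mm above the stack top so it delimits the stack.
    """
    config = config or ScanConfig()
    prog = GCodeProgram()
    prog.append(ModalSetup())
    for k, (row, col) in enumerate(well_order(spec, config.order)):
        g = grid_fraction(spec, row, col)
        c = predict(bmap, g)
        levels = config.z_levels(c.z)
        prog.append(RapidMove(x=c.x, y=c.y, z=levels[0]), well=k)
        for i, z in enumerate(levels):
            if i > 0:
                prog.append(RapidMove(z=z), well=k)
            _capture(prog, config, well=k)
        if config.sentinel:
            prog.append(RapidMove(z=levels[0] + config.sentinel_offset), well=k)
            _capture(prog, config, well=k)
    return prog


def _capture(prog: GCodeProgram, config: ScanConfig, well: int) -> None:
    prog.append(Dwell(config.settle_dwell), well=well)
    prog.append(RelayClose(), well=well)
    prog.append(Dwell(config.pulse_dwell), well=well)
    prog.append(RelayOpen(), well=well)
    prog.append(Dwell(config.write_dwell), well=well)


def count_images(program: GCodeProgram) -> int:
    """Number of camera triggers (m3/m5 pairs) in the program."""
    return sum(isinstance(c, RelayClose) for c in program)


def xy_travel(program: GCodeProgram) -> float:
    """Total Euclidean xy path length of the program's rapid moves, mm."""
    total = 0.0
    x = y = 0.0
    for cmd in program:
        if isinstance(cmd, RapidMove):
            nx = cmd.x if cmd.x is not None else x
            ny = cmd.y if cmd.y is not None else y
            total += ((nx - x) ** 2 + (ny - y) ** 2) ** 0.5
            x, y = nx, ny
    return total


def _fmt_seconds(s: float) -> str:
    # g4 dwell: shortest exact-looking decimal, e.g. 0.1, 0.5, 2
    text = f"{s:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def render_gcode(program: GCodeProgram) -> str:
    """Render the program as GRBL-dialect text, one command per line.

    Lowercase mnemonics, coordinates in fixed 3-decimal mm, LF line
    endings; byte-for-byte deterministic for identical programs so
    emitted files can be diffed and versioned.
    """
    lines: list[str] = []
    for cmd in program:
        if isinstance(cmd, ModalSetup):
            lines.append("g90")
            lines.append("g21")
        elif isinstance(cmd, RapidMove):
            parts = ["g0"]
            for axis in ("x", "y", "z"):
                val = getattr(cmd, axis)
                if val is not None:
                    parts.append(f"{axis}{val:.3f}")
            lines.append(" ".join(parts))
        elif isinstance(cmd, Dwell):
            lines.append(f"g4 p{_fmt_seconds(cmd.seconds)}")
        elif isinstance(cmd, RelayClose):
            lines.append("m3")
        elif isinstance(cmd, RelayOpen):
            lines.append("m5")
        else:  # pragma: no cover
            raise TypeError(f"unknown command {cmd!r}")
    return "\n".join(lines) + "\n"


def parse_gcode(text: str) -> GCodeProgram:
    """Parse rendered G-code text back into a command list.

    Accepts the subset this package emits (g90/g21 header, g0, g4 p,
    m3, m5); the header pair collapses back into one ModalSetup.  Well
    indices are not recoverable from text and are left as None.
    """
    prog = GCodeProgram()
    pending_g90 = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip().lower()
        if not line or line.startswith(";"):
            continue
        if pending_g90:
            if line != "g21":
                raise ValueError(f"line {lineno}: expected g21 after g90, got {raw!r}")
            prog.append(ModalSetup())
            pending_g90 = False
            continue
        if line == "g90":
            pending_g90 = True
        elif line == "m3":
            prog.append(RelayClose())
        elif line == "m5":
            prog.append(RelayOpen())
        elif line.startswith("g4"):
            rest = line[2:].strip()
            if not rest.startswith("p"):
                raise ValueError(f"line {lineno}: malformed dwell {raw!r}")
            prog.append(Dwell(float(rest[1:])))
        elif line.startswith("g0"):
            coords: dict[str, float] = {}
            for token in line[2:].split():
                axis, val = token[0], token[1:]
                if axis not in ("x", "y", "z") or axis in coords:
                    raise ValueError(f"line {lineno}: malformed move {raw!r}")
                coords[axis] = float(val)
            prog.append(RapidMove(**coords))
        else:
            raise ValueError(f"line {lineno}: unsupported command {raw!r}")
    if pending_g90:
        raise ValueError("truncated modal setup: g90 without g21")
    return prog
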