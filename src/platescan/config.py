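"""TOML configuration: plate layout, corner calibration and scan protocol.

A minimal control file looks like::

    [plate]
    name = "96"            # or rows/cols for a custom grid

    [calibration]
    c10 = [100.15, -1.34, 0.13]   # top-right corner drop, mm
    c01 = [0.22, -62.81, -0.05]   # bottom-left
    c11 = [100.40, -64.10, 0.21]  # bottom-right

    [scan]
    n_z = 5
    dz = 0.15

``c00`` is fixed at the origin by the zeroing procedure unless
explicitly overridden.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from platescan.calibration import CornerSet, MachineCoord
from platescan.plate_geometry import PlateSpec, builtin_plate
from platescan.scan_planner import ScanConfig

__all__ = ["load_config", "plate_from_config", "corners_from_config", "scan_from_config"]

_SCAN_KEYS = {
    "n_z", "dz", "settle_dwell", "write_dwell", "pulse_dwell",
    "sentinel", "sentinel_offset", "order",
}


def load_config(path: str | Path) -> dict:
    """Parse a control file into plate / corners / scan objects.

    Returns a dict with keys ``plate`` (PlateSpec), ``corners``
    (CornerSet or None if no calibration block) and ``scan``
    (ScanConfig).
    """
    doc = tomllib.loads(Path(path).read_text())
    return {
        "plate": plate_from_config(doc.get("plate", {})),
        "corners": corners_from_config(doc["calibration"]) if "calibration" in doc else None,
        "scan": scan_from_config(doc.get("scan", {})),
    }


def plate_from_config(block: dict) -> PlateSpec:
    if "rows" in block or "cols" in block:
        return PlateSpec(
            name=str(block.get("name", f"{block['rows']}x{block['cols']}")),
            n_rows=int(block["rows"]),
            n_cols=int(block["cols"]),
            pitch_x=float(block.get("pitch_x", 9.0)),
            pitch_y=float(block.get("pitch_y", 9.0)),
        )
    return builtin_plate(str(block.get("name", "96")))


def corners_from_config(block: dict) -> CornerSet:
    def coord(key: str, default=(0.0, 0.0, 0.0)) -> MachineCoord:
        triple = block.get(key, default)
        if len(triple) != 3:
            raise ValueError(f"calibration.{key} must be an [x, y, z] triple")
        return MachineCoord(*map(float, triple))

    known = {"c00", "c10", "c01", "c11"}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown calibration keys: {sorted(unknown)}")
    for key in ("c10", "c01", "c11"):
        if key not in block:
            raise ValueError(f"calibration block must define {key}")
    return CornerSet(
        c00=coord("c00"), c10=coord("c10"), c01=coord("c01"), c11=coord("c11")
    )


def scan_from_config(block: dict) -> ScanConfig:
    unknown = set(block) - _SCAN_KEYS
    if unknown:
        raise ValueError(f"unknown scan keys: {sorted(unknown)}")
    return ScanConfig(**block)
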