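"""File formats: spot lists (CSV/JSON), run configs (YAML/JSON), hologram images.

Coordinate convention in all files: image-space um, x rightward, y downward
(image convention), z positive toward the objective, origin at the
holographic-FOV center.  CSV is comma-separated, UTF-8, '.' decimal, header
required.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from ._exceptions import InvalidParameterError, SchemaError
from .hologram import QuantizedHologram, SpotTarget
from .optics import OpticsConfig
from .zernike import ZernikeSpec

__all__ = [
    "RunConfig",
    "SPOT_COLUMNS",
    "read_spots",
    "write_spots_csv",
    "write_hologram",
    "read_hologram",
    "parse_z_spec",
    "content_hash",
]

SPOT_COLUMNS = ["x_um", "y_um", "z_um", "weight", "L", "active", "phase"]
_REQUIRED_COLUMNS = ["x_um", "y_um", "z_um"]
_DEFAULTS = {"weight": 1.0, "L": 0, "active": True, "phase": 0.0}


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run: optics + aberrations + options."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    zernike: ZernikeSpec | None = None
    options: dict = field(default_factory=dict)

    _KNOWN_OPTIONS = {"weighting", "n_active", "phase_diversity", "seed", "max_gain"}

    def __post_init__(self) -> None:
        unknown = set(self.options) - self._KNOWN_OPTIONS
        if unknown:
            raise InvalidParameterError(
                f"unknown run options: {sorted(unknown)}; known: {sorted(self._KNOWN_OPTIONS)}"
            )

    @classmethod
    def load(cls, path) -> "RunConfig":
        """Read a nested run config, or a flat optics-only config file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} must contain a mapping")
        if "optics" in data:
            extra = set(data) - {"optics", "zernike", "options"}
            if extra:
                raise SchemaError(f"unknown top-level config keys: {sorted(extra)}")
            optics = OpticsConfig.from_dict(data["optics"])
            zspec = (
                ZernikeSpec.from_records(data["zernike"]) if data.get("zernike") else None
            )
            return cls(optics=optics, zernike=zspec, options=dict(data.get("options", {})))
        return cls(optics=OpticsConfig.from_dict(data))

    def to_dict(self) -> dict:
        return {
            "optics": self.optics.to_dict(),
            "zernike": self.zernike.to_records() if self.zernike else [],
            "options": dict(self.options),
        }


def content_hash(*payloads) -> str:
    """sha256 over the canonical JSON of the given payloads."""
    h = hashlib.sha256()
    for p in payloads:
        h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _spots_from_frame(df: pd.DataFrame, source: str) -> list[SpotTarget]:
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{source}: missing required column '{col}'")
    unknown = set(df.columns) - set(SPOT_COLUMNS)
    if unknown:
        raise SchemaError(f"{source}: unknown columns {sorted(unknown)}")
    spots = []
    for idx, row in df.iterrows():
        try:
            spots.append(
                SpotTarget(
                    x=float(row["x_um"]),
                    y=float(row["y_um"]),
                    z=float(row["z_um"]),
                    weight=float(row.get("weight", _DEFAULTS["weight"])),
                    phase=float(row.get("phase", _DEFAULTS["phase"])),
                    vortex_charge=int(row.get("L", _DEFAULTS["L"])),
                    active=bool(row.get("active", _DEFAULTS["active"])),
                )
            )
        except (ValueError, TypeError, InvalidParameterError) as exc:
            raise SchemaError(f"{source}, row {idx}: {exc}") from exc
    return spots


def read_spots(path) -> list[SpotTarget]:
    """Read a spot list from CSV (header ``x_um,y_um,z_um,weight,L,active``) or JSON.

    The JSON form is a list of objects with the same keys; weight, L and
    active are optional (defaults 1, 0, true).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise SchemaError(f"{path}: JSON spot list must be an array of objects")
        df = pd.DataFrame.from_records(records) if records else pd.DataFrame(
            columns=_REQUIRED_COLUMNS
        )
    else:
        df = pd.read_csv(path)
    return _spots_from_frame(df, str(path))


def write_spots_csv(spots: list[SpotTarget], path) -> None:
    df = pd.DataFrame(
        {
            "x_um": [s.x for s in spots],
            "y_um": [s.y for s in spots],
            "z_um": [s.z for s in spots],
            "weight": [s.weight for s in spots],
            "L": [int(s.vortex_charge) for s in spots],
            "active": [bool(s.active) for s in spots],
        }
    )
    if any(s.phase for s in spots):
        df["phase"] = [s.phase for s in spots]
    df.to_csv(path, index=False)


def spots_to_records(spots: list[SpotTarget]) -> list[dict]:
    return [
        {
            "x_um": s.x,
            "y_um": s.y,
            "z_um": s.z,
            "weight": s.weight,
            "L": int(s.vortex_charge),
            "active": bool(s.active),
            "phase": s.phase,
        }
        for s in spots
    ]


def write_hologram(
    holo: QuantizedHologram,
    path,
    *,
    config: OpticsConfig | None = None,
    spots: list[SpotTarget] | None = None,
) -> None:
    """Write the 8-bit hologram as PNG or TIFF plus a JSON sidecar.

    The sidecar records the provenance hash, the resolved optics config and
    the spot list, so a hologram file is fully reproducible.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, holo.levels)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, holo.levels, photometric="minisblack")
    else:
        raise InvalidParameterError(f"unsupported hologram format: {path.suffix}")
    sidecar = {
        "provenance": holo.provenance,
        "config": config.to_dict() if config else None,
        "spots": spots_to_records(spots) if spots is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_hologram(path) -> QuantizedHologram:
    path = Path(path)
    if path.suffix.lower() == ".png":
        levels = np.asarray(iio.imread(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        levels = np.asarray(tifffile.imread(path))
    else:
        raise InvalidParameterError(f"unsupported hologram format: {path.suffix}")
    if levels.ndim == 3:  # grayscale stored with a channel axis
        levels = levels[..., 0]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    provenance = None
    if sidecar_path.exists():
        provenance = json.loads(sidecar_path.read_text()).get("provenance")
    return QuantizedHologram(levels, provenance=provenance)


def parse_z_spec(spec: str) -> list[float]:
    """Parse ``start:stop:step`` (um) into a list of z planes.

    ``start == stop`` yields a single plane; otherwise ``step`` must be > 0
    and ``stop >= start``.
    """
    parts = spec.split(":")
    if len(parts) != 3:
        raise InvalidParameterError(f"z spec must be 'start:stop:step', got {spec!r}")
    try:
        start, stop, step = (float(p) for p in parts)
    except ValueError as exc:
        raise InvalidParameterError(f"z spec values must be numbers, got {spec!r}") from exc
    if start == stop:
        return [start]
    if stop < start:
        raise InvalidParameterError(f"z spec stop must be >= start, got {spec!r}")
    if step <= 0:
        raise InvalidParameterError(f"z spec step must be > 0, got {spec!r}")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return [start + k * step for k in range(n)]
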