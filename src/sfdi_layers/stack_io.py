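"""On-disk formats: multi-page TIFF stacks with JSON sidecars, property
files, CSV tables.

A stack on disk is one multi-page TIFF (page order frequency-major,
phase-minor: f0p0, f0p1, f0p2, f1p0, ...) plus ``<stem>.json`` holding
``frequencies_mm^-1``, ``phases_deg``, ``wavelength_nm`` and
``pixel_size_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DomainError
from .optics_core import OpticalProperties
from .sfd_processing import PHASES_DEG, FrequencyGrid, ReflectanceStack

__all__ = [
    "write_stack", "read_stack",
    "read_properties_json", "write_properties_json",
    "read_properties_csv", "write_properties_csv",
    "write_csv_with_provenance",
]

SIDECAR_KEYS = ("frequencies_mm^-1", "phases_deg")


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_stack(stack: ReflectanceStack, tiff_path) -> None:
    tiff_path = Path(tiff_path)
    pages = [stack.images[i][p]
             for i in range(len(stack.grid))
             for p in range(len(PHASES_DEG))]
    tifffile.imwrite(tiff_path, np.stack(pages).astype(np.float32))
    sidecar = {
        "frequencies_mm^-1": list(stack.grid.frequencies),
        "phases_deg": list(stack.phases_deg),
        "wavelength_nm": stack.wavelength_label,
        "pixel_size_mm": stack.pixel_size_mm,
    }
    _sidecar_path(tiff_path).write_text(json.dumps(sidecar, indent=1))


def read_stack(tiff_path) -> ReflectanceStack:
    tiff_path = Path(tiff_path)
    sidecar_file = _sidecar_path(tiff_path)
    if not sidecar_file.exists():
        raise DomainError(
            f"missing sidecar {sidecar_file.name}: expected a JSON file with keys "
            f"{list(SIDECAR_KEYS)} (plus optional wavelength_nm, pixel_size_mm)")
    meta = json.loads(sidecar_file.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise DomainError(f"sidecar {sidecar_file.name} lacks required keys {missing}")
    grid = FrequencyGrid(tuple(float(f) for f in meta["frequencies_mm^-1"]))
    phases = tuple(float(p) for p in meta["phases_deg"])
    if phases != PHASES_DEG:
        raise DomainError(f"only phase offsets {PHASES_DEG} are supported, got {phases}")
    pages = tifffile.imread(tiff_path)
    n_expected = len(grid) * len(phases)
    if pages.shape[0] != n_expected:
        raise DomainError(f"stack has {pages.shape[0]} pages, sidecar implies {n_expected}")
    images = {i: np.asarray(pages[i * 3:(i + 1) * 3], dtype=float)
              for i in range(len(grid))}
    return ReflectanceStack(
        grid=grid, images=images,
        wavelength_label=str(meta.get("wavelength_nm", "")),
        pixel_size_mm=float(meta.get("pixel_size_mm", 0.4)),
    )


def read_properties_json(path) -> OpticalProperties:
    return OpticalProperties.from_dict(json.loads(Path(path).read_text()))


def write_properties_json(props: OpticalProperties, path) -> None:
    Path(path).write_text(json.dumps(props.to_dict(), indent=1))


def read_properties_csv(path) -> dict[str, OpticalProperties]:
    """CSV rows keyed by wavelength band label -> OpticalProperties."""
    df = pd.read_csv(path, comment="#", dtype={"band": str})
    if "band" not in df.columns:
        raise DomainError("properties CSV needs a 'band' column")
    return {row["band"]: OpticalProperties.from_dict(row.to_dict())
            for _, row in df.iterrows()}


def write_properties_csv(props_by_band: dict[str, OpticalProperties], path) -> None:
    rows = [{"band": band, **p.to_dict()} for band, p in props_by_band.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_csv_with_provenance(df: pd.DataFrame, path, provenance: str) -> None:
    """CSV with a leading '#' provenance comment line and a header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False)
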