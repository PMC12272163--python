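"""Reading and writing masks, sidecars and fibre tables.

Masks travel as single-channel TIFF (uint16 labels) or PNG (8-bit binary)
with a JSON sidecar holding the pixel size and participant id; per-fibre
data travel as CSV with the canonical column names
(``participant_id, axon_area_um2, myelin_area_um2``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import RenderedSection

__all__ = ["save_section", "load_section", "load_area_table"]

REQUIRED_AREA_COLUMNS = ["participant_id", "axon_area_um2", "myelin_area_um2"]


def save_section(section: RenderedSection, stem: str | Path) -> dict[str, Path]:
    """Write image + masks as TIFF and a JSON sidecar next to them."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": stem.with_suffix(".image.tif"),
        "axon_mask": stem.with_suffix(".axon.tif"),
        "myelin_mask": stem.with_suffix(".myelin.tif"),
        "sidecar": stem.with_suffix(".json"),
    }
    tifffile.imwrite(paths["image"], section.image)
    tifffile.imwrite(paths["axon_mask"], section.axon_mask.astype(np.uint16))
    tifffile.imwrite(paths["myelin_mask"], section.myelin_mask.astype(np.uint16))
    paths["sidecar"].write_text(json.dumps({
        "pixel_size_um": section.pixel_size_um,
        "participant_id": section.participant_id,
        "analysed_area_mm2": section.analysed_area_mm2,
    }, indent=2))
    return paths


def load_section(stem: str | Path) -> RenderedSection:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return RenderedSection(
        image=tifffile.imread(stem.with_suffix(".image.tif")),
        axon_mask=tifffile.imread(stem.with_suffix(".axon.tif")),
        myelin_mask=tifffile.imread(stem.with_suffix(".myelin.tif")),
        pixel_size_um=float(meta["pixel_size_um"]),
        analysed_area_mm2=float(meta["analysed_area_mm2"]),
        participant_id=meta.get("participant_id"),
    )


def load_masks(axon_path: str | Path, myelin_path: str | Path,
               pixel_size_um: float,
               participant_id: str | None = None) -> RenderedSection:
    """Build a section from two mask files and an explicit pixel size."""
    axon = tifffile.imread(axon_path)
    myelin = tifffile.imread(myelin_path)
    return RenderedSection(
        image=np.zeros_like(axon, dtype=np.uint8),
        axon_mask=axon, myelin_mask=myelin,
        pixel_size_um=float(pixel_size_um),
        analysed_area_mm2=axon.size * float(pixel_size_um) ** 2 / 1e6,
        participant_id=participant_id,
    )


def load_area_table(path: str | Path) -> pd.DataFrame:
    """Read a user-supplied per-fibre area CSV, checking required columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area table {path} is missing columns: {missing}")
    return df
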