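"""Per-fibre morphometrics from segmentation masks or area tables.

All quantities derive from segmented areas through the equivalent-diameter
construction (diameter of the circle with the same area):

    axon diameter   = 2 sqrt(axon_area / pi)
    fibre diameter  = 2 sqrt((axon_area + myelin_area) / pi)
    g-ratio         = axon diameter / fibre diameter
    myelin thickness = (fibre diameter - axon diameter) / 2

so the identity fibre = axon + 2 * thickness holds to machine precision.
Records with negative myelin thickness, g-ratio > 1, non-finite fields or
non-positive axon area are flagged invalid; g-ratio exactly 1 (zero
myelin) is kept valid by default, mirroring how automated segmentation of
real sections reports thin or missed myelin.

Units are fixed: areas in um^2, diameters/thickness in um, density in
fibres/mm^2.  Pixel size must always be supplied, never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.segmentation import watershed

from .synthetic import RenderedSection

__all__ = [
    "DensityResult",
    "equivalent_diameter",
    "fibre_metrics",
    "validity_filter",
    "extract_from_masks",
    "segment_classical",
    "fibre_density",
    "FIBRE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Canonical column order of a per-fibre metrics table.
FIBRE_COLUMNS = [
    "participant_id", "axon_area_um2", "myelin_area_um2",
    "axon_diameter_um", "fibre_diameter_um", "myelin_thickness_um",
    "g_ratio", "valid",
]


@dataclass
class DensityResult:
    n_fibres: int
    analysed_area_mm2: float
    density_per_mm2: float


def equivalent_diameter(area):
    """Diameter (um) of the circle whose area (um^2) is given.

    Vectorized; negative areas raise ``ValueError``.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a < 0):
        raise ValueError("area must be >= 0")
    out = 2.0 * np.sqrt(a / np.pi)
    return out.item() if np.isscalar(area) else out


def fibre_metrics(axon_area, myelin_area, participant_id=None) -> pd.DataFrame:
    """Apply the four morphometric formulas to paired area columns.

    Non-positive axon areas yield rows marked invalid (NaN derived fields)
    rather than raising: such records occur in real segmentations and are
    handled by :func:`validity_filter`.
    """
    axon_area = np.atleast_1d(np.asarray(axon_area, dtype=float))
    myelin_area = np.atleast_1d(np.asarray(myelin_area, dtype=float))
    if axon_area.shape != myelin_area.shape:
        raise ValueError("axon_area and myelin_area must have equal length")
    n = axon_area.size

    defined = np.isfinite(axon_area) & np.isfinite(myelin_area) & (axon_area > 0)
    axon_d = np.full(n, np.nan)
    fibre_d = np.full(n, np.nan)
    with np.errstate(invalid="ignore"):
        axon_d[defined] = 2.0 * np.sqrt(axon_area[defined] / np.pi)
        total = axon_area[defined] + myelin_area[defined]
        fibre_d[defined] = np.where(total >= 0, 2.0 * np.sqrt(np.abs(total) / np.pi), np.nan)
    thickness = (fibre_d - axon_d) / 2.0
    g = axon_d / fibre_d

    valid = defined & np.isfinite(g) & (g <= 1.0) & (thickness >= 0.0)
    if participant_id is None:
        pid = pd.array([pd.NA] * n)
    else:
        pid = np.broadcast_to(np.asarray(participant_id, dtype=object), (n,))
    return pd.DataFrame({
        "participant_id": pid,
        "axon_area_um2": axon_area,
        "myelin_area_um2": myelin_area,
        "axon_diameter_um": axon_d,
        "fibre_diameter_um": fibre_d,
        "myelin_thickness_um": thickness,
        "g_ratio": g,
        "valid": valid,
    })


def fibre_metrics_table(areas: pd.DataFrame) -> pd.DataFrame:
    """``fibre_metrics`` applied to a table with the canonical area columns."""
    return fibre_metrics(
        areas["axon_area_um2"], areas["myelin_area_um2"],
        areas["participant_id"] if "participant_id" in areas else None)


def validity_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop invalid fibre records; return (kept, n_excluded).

    Invalid means: negative myelin thickness, g-ratio > 1, or non-finite
    derived fields (which covers non-positive axon area).  Order is
    preserved and the operation is idempotent.
    """
    cols = ["axon_diameter_um", "fibre_diameter_um", "myelin_thickness_um", "g_ratio"]
    finite = np.isfinite(records[cols].to_numpy(dtype=float)).all(axis=1)
    with np.errstate(invalid="ignore"):
        ok = (finite
              & (records["myelin_thickness_um"].to_numpy(dtype=float) >= 0)
              & (records["g_ratio"].to_numpy(dtype=float) <= 1.0))
    kept = records.loc[ok].copy()
    if "valid" in kept.columns:
        kept["valid"] = True
    return kept, int((~ok).sum())


def extract_from_masks(section: RenderedSection,
                       *, include_border: bool = False) -> pd.DataFrame:
    """Per-fibre metrics from paired axon/myelin masks.

    Connected components (8-connectivity) of the axon mask define fibres.
    Each myelin pixel is assigned to the nearest axon component by a
    watershed on the distance transform seeded with the axon labels;
    ties resolve deterministically to the lower label.  Myelin components
    touching no axon are dropped (count in ``df.attrs['n_orphan_myelin_px']``).
    Components whose fibre touches the image border have censored areas and
    are excluded unless ``include_border=True``.
    """
    axon_bin = section.axon_mask > 0
    myelin_bin = section.myelin_mask > 0
    if np.any(axon_bin & myelin_bin):
        raise ValueError("axon and myelin masks must be disjoint")
    labels = _cc_label(axon_bin, connectivity=2)
    n = int(labels.max())
    if n == 0:
        empty = fibre_metrics([], [])
        empty.attrs["n_orphan_myelin_px"] = int(myelin_bin.sum())
        return empty

    both = axon_bin | myelin_bin
    # distance from non-axon pixels to the nearest axon pixel
    dist = ndimage.distance_transform_edt(~axon_bin)
    assigned = watershed(dist, markers=labels, mask=both, connectivity=2)
    orphan = int((myelin_bin & (assigned == 0)).sum())
    if orphan:
        logger.warning("dropping %d myelin pixels attached to no axon", orphan)

    px_area = section.pixel_size_um**2
    axon_px = np.bincount(labels[axon_bin], minlength=n + 1)[1:]
    myelin_px = np.bincount(assigned[myelin_bin & (assigned > 0)], minlength=n + 1)[1:]

    if not include_border:
        border = np.zeros_like(assigned, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touching = np.unique(assigned[border & (assigned > 0)])
        keep = ~np.isin(np.arange(1, n + 1), touching)
    else:
        keep = np.ones(n, dtype=bool)

    df = fibre_metrics(axon_px[keep] * px_area, myelin_px[keep] * px_area,
                       participant_id=section.participant_id)
    df.attrs["n_orphan_myelin_px"] = orphan
    df.attrs["n_border_excluded"] = int((~keep).sum())
    return df


def segment_classical(image: np.ndarray,
                      pixel_size_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-based axon/myelin segmentation for synthetic renders.

    Myelin pixels are the dark class under an Otsu threshold; fibre
    regions are the hole-filled myelin annuli and axons the filled
    interiors.  Intended for the renderer's contrast (dark annuli, light
    axoplasm and background); it makes no accuracy claim on real
    histology.  A flat image returns empty masks with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.std() < 1e-12:
        logger.warning("flat image: returning empty masks")
        z = np.zeros(img.shape, dtype=np.uint16)
        return z, z.copy()
    thr = threshold_otsu(img)
    myelin_bin = img < thr
    filled = ndimage.binary_fill_holes(myelin_bin)
    axon_bin = filled & ~myelin_bin
    labels = _cc_label(axon_bin, connectivity=2)
    # myelin label = label of the enclosed axon, via watershed assignment
    dist = ndimage.distance_transform_edt(~axon_bin)
    assigned = watershed(dist, markers=labels, mask=filled, connectivity=2)
    axon_mask = labels.astype(np.uint16)
    myelin_mask = np.where(myelin_bin, assigned, 0).astype(np.uint16)
    return axon_mask, myelin_mask


def fibre_density(n_fibres: int, analysed_area_mm2: float) -> DensityResult:
    """Myelinated-fibre density: count / analysed area (mm^2)."""
    if analysed_area_mm2 <= 0:
        raise ValueError("analysed_area_mm2 must be > 0")
    return DensityResult(
        n_fibres=int(n_fibres),
        analysed_area_mm2=float(analysed_area_mm2),
        density_per_mm2=n_fibres / analysed_area_mm2,
    )
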