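"""Voxel-mask utilities: spectroscopy-voxel / fMRI-cluster overlap,
across-subject density maps, ROI mean extraction, and MRS quality
filtering with CSF-fraction correction.

Masks are boolean 3-D occupancy grids compared in a common, pre-aligned
grid space; registration/resampling is out of scope. The CSF correction
rescales a raw concentration to the tissue water compartment using the
standard water concentrations (GM 43,300 mM, WM 35,880 mM, CSF
55,556 mM), so a voxel with no CSF is returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WATER_GM_MM = 43300.0
WATER_WM_MM = 35880.0
WATER_CSF_MM = 55556.0


@dataclass
class DensityMap:
    grid: np.ndarray        # per-voxel coverage fraction in [0, 1]
    n_subjects: int


@dataclass(frozen=True)
class MrsQC:
    """One metabolite quantification: CRLB (fraction), tissue fractions
    (summing to 1), raw concentration."""

    crlb: float
    fgm: float
    fwm: float
    fcsf: float
    raw_concentration: float

    def __post_init__(self):
        fracs = (self.fgm, self.fwm, self.fcsf)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("tissue fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1")


def _as_bool_grid(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise ValueError("mask must be a 3-D grid")
    return arr.astype(bool)


def density_map(masks) -> DensityMap:
    """Fraction of subjects covering each voxel."""
    grids = [_as_bool_grid(m) for m in masks]
    if not grids:
        raise ValueError("need at least one mask")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("masks must share a common shape")
    counts = np.sum(grids, axis=0)
    return DensityMap(grid=counts / len(grids), n_subjects=len(grids))


def threshold_density(density: DensityMap, cutoff: float = 0.9) -> np.ndarray:
    """Voxels sampled in at least ``cutoff`` of the subjects (boundary
    retained: 'at least 90%')."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    return density.grid >= cutoff


def overlap_stats(mask_a, mask_b) -> dict:
    """Percentage of A inside B and of B inside A, plus voxel counts."""
    a = _as_bool_grid(mask_a)
    b = _as_bool_grid(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share a common shape")
    n_a = int(a.sum())
    n_b = int(b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("masks must be non-empty")
    n_ab = int((a & b).sum())
    return {
        "n_a": n_a, "n_b": n_b, "n_overlap": n_ab,
        "pct_a_in_b": 100.0 * n_ab / n_a,
        "pct_b_in_a": 100.0 * n_ab / n_b,
    }


def roi_mean(activity_grid, mask) -> float:
    """Mean activity over the in-mask voxels."""
    grid = np.asarray(activity_grid, dtype=float)
    m = _as_bool_grid(mask)
    if grid.shape != m.shape:
        raise ValueError("grid and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    return float(grid[m].mean())


def csf_correction_factor(fgm: float, fwm: float, fcsf: float) -> float:
    tissue_water = fgm * WATER_GM_MM + fwm * WATER_WM_MM
    if tissue_water == 0:
        raise ValueError("no tissue water (fGM + fWM = 0)")
    return (tissue_water + fcsf * WATER_CSF_MM) / tissue_water


def mrs_filter_and_correct(records, crlb_cutoff: float = 0.5) -> pd.DataFrame:
    """Apply the CRLB quality filter and the CSF-fraction correction.

    Records with CRLB strictly above ``crlb_cutoff`` are excluded
    ('higher than 50%'); survivors get
    corrected = raw * (fGM*43300 + fWM*35880 + fCSF*55556)
                     / (fGM*43300 + fWM*35880).
    Returns a table with ``corrected`` (NaN where excluded) and an
    ``excluded`` flag.
    """
    recs = [r if isinstance(r, MrsQC) else MrsQC(**r) for r in records]
    rows = []
    for r in recs:
        excluded = r.crlb > crlb_cutoff
        corrected = np.nan if excluded else \
            r.raw_concentration * csf_correction_factor(r.fgm, r.fwm, r.fcsf)
        rows.append({
            "crlb": r.crlb, "fgm": r.fgm, "fwm": r.fwm, "fcsf": r.fcsf,
            "raw": r.raw_concentration, "corrected": corrected,
            "excluded": excluded,
        })
    return pd.DataFrame(rows)


def load_mask(path) -> np.ndarray:
    """Read a boolean mask from a NIfTI file."""
    import nibabel as nib

    return np.asanyarray(nib.load(path).dataobj) > 0


def save_mask(grid, path, affine=None) -> None:
    """Write a boolean mask (or density grid) as NIfTI."""
    import nibabel as nib

    arr = np.asarray(grid)
    data = arr.astype(np.float32) if arr.dtype.kind == "f" \
        else arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine if affine is not None
                             else np.eye(4)), path)
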