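"""Physiology-guided fiber filtering.

Each tractography streamline (polyline in mm space) is weighted, per
patient, by the maximal stimulation E-field magnitude it traverses; each
fiber then receives an R-value from the Spearman correlation between its
per-patient weights and a per-patient target variable (baseline BNST
theta power, coherence, or clinical improvement).  Fibers significant at
unadjusted p < 0.05 are retained, and weighted fiber densities are
accumulated on a 2-mm voxel grid.

Voxel traversal uses an exact 3-D digital differential analyzer
(Amanatides–Woo) on each segment, so scoring is invariant to polyline
re-parameterisation (inserting collinear points changes nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "EFieldMap",
    "FiberSet",
    "traverse_voxels",
    "fiber_weight",
    "fiber_r_values",
    "weighted_density_map",
    "read_trk",
    "write_trk",
    "read_nifti_field",
    "write_nifti_field",
]


@dataclass
class EFieldMap:
    """Voxelized E-field magnitude volume.

    ``data``: nonnegative magnitudes, shape (nx, ny, nz); ``affine``: 4×4
    voxel-index → mm transform (invertible).
    """

    data: np.ndarray
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if (self.data < 0).any():
            raise ValueError("field magnitudes must be nonnegative")

    def mm_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map mm points (n, 3) to continuous voxel-index coordinates."""
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(pts_mm, float)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class FiberSet:
    """List of streamlines; each an (n_points, 3) array of mm coordinates."""

    fibers: list = field(default_factory=list)

    def __post_init__(self):
        clean = []
        for f in self.fibers:
            f = np.asarray(f, float)
            if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 2:
                raise ValueError("each fiber needs >=2 three-dimensional points")
            if not np.isfinite(f).all():
                raise ValueError("fiber coordinates must be finite")
            clean.append(f)
        self.fibers = clean

    def __len__(self):
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)


def _segment_voxels(p0, p1, out: set):
    """Amanatides–Woo traversal of one segment in voxel-index space.

    Voxel (i,j,k) spans the half-open cube [i, i+1) × [j, j+1) × [k, k+1)
    in continuous index coordinates (voxel centres therefore sit at
    i + 0.5).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    cell = np.floor(p0).astype(int)
    end_cell = np.floor(p1).astype(int)
    out.add(tuple(cell))
    if np.all(cell == end_cell):
        return
    step = np.sign(d).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_delta = np.where(d != 0, np.abs(1.0 / d), np.inf)
        next_bound = np.where(step > 0, cell + 1.0, cell)
        t_max = np.where(d != 0, (next_bound - p0) / d, np.inf)
    # guard: t of a zero component stays inf
    for _ in range(int(np.abs(end_cell - cell).sum()) + 3):
        axis = int(np.argmin(t_max))
        if t_max[axis] > 1.0:
            break
        cell[axis] += step[axis]
        t_max[axis] += t_delta[axis]
        out.add(tuple(cell))
        if np.all(cell == end_cell):
            break


def traverse_voxels(fiber_mm: np.ndarray, field: EFieldMap) -> np.ndarray:
    """All grid voxels (i,j,k) intersected by the polyline; in-grid only.

    Returns an (m, 3) integer array (unordered, unique).
    """
    pts = field.mm_to_voxel(fiber_mm)
    vox: set = set()
    for a, b in zip(pts[:-1], pts[1:]):
        _segment_voxels(a, b, vox)
    if not vox:
        return np.empty((0, 3), int)
    arr = np.array(sorted(vox), int)
    shape = field.data.shape
    ok = np.all((arr >= 0) & (arr < shape), axis=1)
    return arr[ok]


def fiber_weight(fiber_mm: np.ndarray, field: EFieldMap,
                 threshold: float = 0.0):
    """Maximal field magnitude along a fiber's voxel passage, or None.

    None ("absent") when the fiber intersects no voxel with magnitude
    strictly above ``threshold`` (default 0) or lies outside the grid.
    """
    vox = traverse_voxels(fiber_mm, field)
    if len(vox) == 0:
        return None
    vals = field.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    peak = float(vals.max()) if len(vals) else 0.0
    return peak if peak > threshold else None


def fiber_r_values(weights: pd.DataFrame, target: pd.Series,
                   alpha: float = 0.05, min_n: int = 4) -> pd.DataFrame:
    """Per-fiber Spearman R of fiber weight vs the per-patient target.

    ``weights``: fibers × patients frame (NaN = weight absent for that
    patient); absent weights are dropped pairwise per fiber.  Fibers with
    fewer than ``min_n`` defined pairs or constant weights are flagged
    undefined (R = NaN).  Significance is the printed rule: unadjusted
    two-sided p < alpha.
    """
    target = target.reindex(weights.columns)
    rows = []
    for fiber_id, w in weights.iterrows():
        ok = w.notna() & target.notna()
        n = int(ok.sum())
        if n < min_n or w[ok].nunique() <= 1 or target[ok].nunique() <= 1:
            rows.append((fiber_id, np.nan, np.nan, False, n))
            continue
        r, p = sstats.spearmanr(w[ok], target[ok])
        rows.append((fiber_id, float(r), float(p), bool(p < alpha), n))
    return pd.DataFrame(
        rows, columns=["fiber", "r", "p", "significant", "n"]
    ).set_index("fiber")


def weighted_density_map(fibers: FiberSet, weights, field_template: EFieldMap
                         ) -> EFieldMap:
    """Accumulate each fiber's weight into every voxel it traverses.

    ``weights``: one weight per fiber (None/NaN skipped).  Returns a map on
    the template's grid holding per-voxel sums of traversing-fiber weights.
    """
    acc = np.zeros_like(field_template.data)
    for fib, w in zip(fibers, weights):
        if w is None or (isinstance(w, float) and np.isnan(w)):
            continue
        vox = traverse_voxels(fib, field_template)
        acc[vox[:, 0], vox[:, 1], vox[:, 2]] += w
    return EFieldMap(data=acc, affine=field_template.affine.copy())


# ------------------------------------------------------------------- I/O

def read_trk(path) -> FiberSet:
    """Read streamlines from a TRK file (coordinates in mm/RAS)."""
    import nibabel as nib

    trk = nib.streamlines.load(str(path))
    return FiberSet(fibers=[np.asarray(s, float) for s in trk.streamlines])


def write_trk(fibers: FiberSet, path, affine=None) -> None:
    import nibabel as nib

    tractogram = nib.streamlines.Tractogram(
        list(fibers), affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram), str(path))


def read_nifti_field(path) -> EFieldMap:
    import nibabel as nib

    img = nib.load(str(path))
    return EFieldMap(data=np.asarray(img.dataobj, float), affine=img.affine)


def write_nifti_field(field: EFieldMap, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(field.data.astype(np.float32), field.affine),
             str(path))
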