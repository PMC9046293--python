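"""Probabilistic cytoarchitectonic maps in a common voxel space.

Per-brain area label volumes (already aligned to a common reference space)
are superimposed into voxelwise probability maps: the value at a voxel is
the fraction of brains in which the area is present there, a direct measure
of intersubject variability.  The maximum probability map (MPM) assigns each
voxel to the area of highest probability, yielding a non-overlapping
parcellation; centers of gravity summarize each map as a probability-
weighted stereotaxic coordinate, and point coordinates (e.g. functional
activation peaks) can be assigned to areas by MPM lookup.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "ProbabilityMap",
    "Mpm",
    "probability_map",
    "maximum_probability_map",
    "center_of_gravity",
    "locate_coordinate",
    "locate_coordinates",
    "save_nifti",
    "load_label_volume",
]

OUT_OF_BOUNDS = "<out-of-bounds>"
BACKGROUND = "<background>"


@dataclass
class LabelVolume:
    """Integer area labels of one brain on a reference grid."""

    data: np.ndarray
    affine: np.ndarray
    brain_id: str
    labels: dict[str, int]  # area name -> integer code

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")


@dataclass
class ProbabilityMap:
    """Voxelwise fraction of brains labeling the voxel as one area."""

    area: str
    data: np.ndarray
    affine: np.ndarray
    n_brains: int


@dataclass
class Mpm:
    """Maximum probability map: argmax-area label per voxel + provenance."""

    data: np.ndarray
    affine: np.ndarray
    labels: dict[str, int]
    winning_prob: np.ndarray = field(default=None)  # type: ignore[assignment]


def _check_common_grid(volumes: Sequence) -> None:
    ref_shape = volumes[0].data.shape
    ref_aff = volumes[0].affine
    for v in volumes[1:]:
        if v.data.shape != ref_shape or not np.allclose(v.affine, ref_aff):
            raise ValueError("all volumes must share grid shape and affine")


def probability_map(volumes: Sequence[LabelVolume], area: str) -> ProbabilityMap:
    """Superimpose per-brain labels: voxel value = labeled brains / n."""
    if not volumes:
        raise ValueError("need at least one label volume")
    _check_common_grid(volumes)
    code = volumes[0].labels[area]
    n = len(volumes)
    acc = np.zeros(volumes[0].data.shape, float)
    for v in volumes:
        acc += v.data == v.labels[area]
    return ProbabilityMap(area=area, data=acc / n,
                          affine=volumes[0].affine.copy(), n_brains=n)


def maximum_probability_map(
    pmaps: Sequence[ProbabilityMap],
    min_prob: float = 0.0,
    label_codes: dict[str, int] | None = None,
) -> Mpm:
    """Assign each voxel to the area of highest probability.

    Voxels where every area has probability 0 (or <= ``min_prob``) stay
    background (label 0).  Exact ties are broken by the larger mean
    probability over the voxel's 26-neighborhood, then by label order.
    """
    if not pmaps:
        raise ValueError("need at least one probability map")
    _check_common_grid(pmaps)
    if label_codes is None:
        label_codes = {pm.area: i + 1 for i, pm in enumerate(pmaps)}
    stack = np.stack([pm.data for pm in pmaps])  # (n_areas, X, Y, Z)
    best = stack.max(axis=0)
    assigned = best > min_prob

    winner = np.argmax(stack, axis=0)
    # tie handling: where >1 area attains the max, use neighborhood means
    n_at_max = (stack == best).sum(axis=0)
    ties = assigned & (n_at_max > 1)
    if np.any(ties):
        k = stack.shape[1:]
        nbh = np.empty_like(stack)
        for i in range(stack.shape[0]):
            s = uniform_filter(stack[i], size=3, mode="constant") * 27.0
            nbh[i] = (s - stack[i]) / 26.0
        tie_scores = np.where(stack == best, nbh, -np.inf)
        winner_t = np.argmax(tie_scores, axis=0)  # argmax takes first = label order
        winner[ties] = winner_t[ties]

    codes = np.array([label_codes[pm.area] for pm in pmaps])
    data = np.where(assigned, codes[winner], 0)
    return Mpm(data=data.astype(np.int32), affine=pmaps[0].affine.copy(),
               labels=dict(label_codes), winning_prob=np.where(assigned, best, 0.0))


def center_of_gravity(pmap: ProbabilityMap) -> np.ndarray:
    """Probability-weighted mean voxel-center coordinate in mm."""
    w = np.asarray(pmap.data, float)
    total = w.sum()
    if total <= 0:
        raise ValueError("probability map has no mass")
    idx = np.indices(w.shape).reshape(3, -1)
    weights = w.reshape(-1)
    vox_cog = (idx * weights).sum(axis=1) / total
    return (pmap.affine @ np.append(vox_cog, 1.0))[:3]


def locate_coordinate(mpm: Mpm, xyz_mm: Sequence[float]) -> str:
    """Area name at a stereotaxic coordinate via nearest-voxel MPM lookup.

    Returns the area name, ``BACKGROUND`` for unassigned voxels, or
    ``OUT_OF_BOUNDS`` when the coordinate falls outside the grid.
    """
    inv = np.linalg.inv(mpm.affine)
    vox = (inv @ np.append(np.asarray(xyz_mm, float), 1.0))[:3]
    ijk = np.round(vox).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(mpm.data.shape)):
        return OUT_OF_BOUNDS
    code = int(mpm.data[tuple(ijk)])
    if code == 0:
        return BACKGROUND
    inv_labels = {v: k for k, v in mpm.labels.items()}
    return inv_labels.get(code, BACKGROUND)


def locate_coordinates(mpm: Mpm, coords_mm: np.ndarray) -> list[str]:
    """Batch :func:`locate_coordinate` over an (n, 3) coordinate table."""
    return [locate_coordinate(mpm, c) for c in np.atleast_2d(coords_mm)]


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path,
               labels: dict[str, int] | None = None) -> None:
    """Write a volume as NIfTI-1; label dictionaries go to a JSON sidecar."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, float))
    nib.save(img, str(path))
    if labels is not None:
        sidecar = Path(str(path)).with_suffix("").with_suffix(".labels.json")
        sidecar.write_text(json.dumps(labels, indent=2))


def load_label_volume(path: str | Path, brain_id: str = "brain",
                      labels: dict[str, int] | None = None) -> LabelVolume:
    """Read a NIfTI label volume (JSON label sidecar is used if present)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    if labels is None:
        sidecar = Path(str(path)).with_suffix("").with_suffix(".labels.json")
        if sidecar.exists():
            labels = json.loads(sidecar.read_text())
        else:
            labels = {f"area{v}": int(v) for v in np.unique(data) if v != 0}
    return LabelVolume(data=data, affine=np.asarray(img.affine, float),
                       brain_id=brain_id, labels=labels)
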