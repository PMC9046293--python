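"""Synthetic histology with planted ground truth.

Real quantitative cytoarchitectonics starts from silver-stained postmortem
sections; those data are not desk-portable.  This module generates the same
kinds of objects with *known* answers so that every downstream stage (GLI,
profiles, border detection, volumetry, clustering, maps) can be validated:

* a curved six-layered cortical ribbon (annulus sector) populated with
  cell-body disks by an inhomogeneous Poisson process whose local intensity
  follows an area's laminar density at the local cortical depth;
* serial section series with a consistent (optionally drifting) border;
* multi-subject label volumes with bounded spatial jitter;
* multivariate-normal profile-feature populations for statistical nulls and
  alternatives.

Depth convention: 0% at the outer contour (layer I/II boundary), 100% at the
inner contour (layer VI / white matter), everywhere in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as _disk

logger = logging.getLogger(__name__)

__all__ = [
    "AreaSpec",
    "SectionGroundTruth",
    "SegmentedSection",
    "RibbonGeometry",
    "make_laminar_density",
    "generate_section",
    "generate_section_series",
    "generate_label_volumes",
    "generate_feature_population",
    "two_area_feature_section",
]


@dataclass(frozen=True)
class AreaSpec:
    """Laminar blueprint of one cortical area.

    ``layer_fractions`` are the relative thicknesses of layers I–VI (sum to
    1); ``layer_densities`` are the target cell-body *area fractions* per
    layer, i.e. the value a GLI measurement inside that layer should return.
    """

    name: str
    layer_fractions: tuple[float, ...]
    layer_densities: tuple[float, ...]
    cell_radius_um: float = 8.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.layer_fractions, float)
        de = np.asarray(self.layer_densities, float)
        if fr.shape != (6,) or de.shape != (6,):
            raise ValueError("six layer fractions and six densities required")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"layer_fractions must sum to 1, got {fr.sum()!r}")
        if np.any(fr < 0):
            raise ValueError("layer_fractions must be nonnegative")
        if np.any((de < 0) | (de > 1)):
            raise ValueError("layer_densities must lie in [0, 1]")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be positive")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative depth boundaries of layers I–VI in [0, 1]."""
        return np.concatenate([[0.0], np.cumsum(self.layer_fractions)])


@dataclass
class SectionGroundTruth:
    """Planted truth for one synthetic section.

    ``border_traverse_indices`` hold positions in distance-function
    convention: border at index ``k`` means traverses ``< k`` belong to the
    left area and traverses ``>= k`` to the right one.
    """

    border_traverse_indices: list[int]
    area_labels_per_traverse: list[str]

    def __post_init__(self) -> None:
        labels = self.area_labels_per_traverse
        changes = [
            i for i in range(1, len(labels)) if labels[i] != labels[i - 1]
        ]
        if changes != sorted(self.border_traverse_indices):
            raise ValueError(
                "labels must change exactly at the planted border indices"
            )


@dataclass
class SegmentedSection:
    """Binary cell-body mask plus the two cortical contours.

    Contours are (N, 2) float arrays of (x, y) pixel coordinates, ordered
    consistently along the ribbon: the outer contour marks the layer I/II
    boundary (depth 0%), the inner one the layer VI/white-matter boundary
    (depth 100%).
    """

    mask: np.ndarray
    pixel_size_um: float
    outer_contour: np.ndarray
    inner_contour: np.ndarray
    section_id: str = "sec0"
    ground_truth: SectionGroundTruth | None = None


@dataclass(frozen=True)
class RibbonGeometry:
    """Annulus-sector ribbon: curvature with analytically exact contours.

    The outer contour sits at ``outer_radius_um`` and the inner contour at
    ``outer_radius_um - thickness_um``; the sector spans ``arc_deg`` degrees.
    ``traverse_spacing_um`` fixes the seed spacing used to express planted
    border positions in traverse indices.
    """

    outer_radius_um: float = 1200.0
    thickness_um: float = 400.0
    arc_deg: float = 92.0
    traverse_spacing_um: float = 16.0

    def __post_init__(self) -> None:
        if self.thickness_um >= self.outer_radius_um:
            raise ValueError("thickness must be smaller than the outer radius")

    @property
    def inner_radius_um(self) -> float:
        return self.outer_radius_um - self.thickness_um

    @property
    def outer_arc_um(self) -> float:
        return self.outer_radius_um * math.radians(self.arc_deg)

    @property
    def n_traverses(self) -> int:
        return int(math.floor(self.outer_arc_um / self.traverse_spacing_um + 1e-9)) + 1


def make_laminar_density(
    spec: AreaSpec, n_samples: int, smooth_sigma: float = 0.0
) -> np.ndarray:
    """Cell-body area fraction as a function of normalized depth 0–100%.

    Returns ``n_samples`` values on an equally spaced depth grid; the value
    within layer k equals ``layer_densities[k]`` (piecewise constant,
    optionally Gaussian-smoothed in depth samples).
    """
    if n_samples < 6:
        raise ValueError("n_samples must be at least 6")
    depths = np.linspace(0.0, 1.0, n_samples)
    bounds = spec.boundaries
    # searchsorted maps depth to its layer; right edge belongs to layer VI
    idx = np.clip(np.searchsorted(bounds, depths, side="right") - 1, 0, 5)
    curve = np.asarray(spec.layer_densities, float)[idx]
    if smooth_sigma > 0:
        curve = gaussian_filter1d(curve, smooth_sigma, mode="nearest")
    return curve


def density_at_depth(spec: AreaSpec, depth: np.ndarray) -> np.ndarray:
    """Laminar density at arbitrary normalized depths in [0, 1]."""
    bounds = spec.boundaries
    idx = np.clip(np.searchsorted(bounds, depth, side="right") - 1, 0, 5)
    return np.asarray(spec.layer_densities, float)[idx]


def _contour_arc(radius_px: float, theta0: float, theta1: float,
                 center: tuple[float, float], step_px: float = 1.0) -> np.ndarray:
    n = max(int(abs(theta1 - theta0) * radius_px / step_px), 8) + 1
    th = np.linspace(theta0, theta1, n)
    cx, cy = center
    return np.column_stack([cx + radius_px * np.cos(th), cy + radius_px * np.sin(th)])


def generate_section(
    area_sequence: Sequence[AreaSpec],
    geometry: RibbonGeometry,
    pixel_size_um: float,
    seed: int,
    section_id: str = "sec0",
    border_arc_fractions: Sequence[float] | None = None,
    noise_salt_pepper: float = 0.0,
) -> tuple[SegmentedSection, SectionGroundTruth]:
    """Draw one synthetic section: mask, contours and planted borders.

    Cells are disks of the area's ``cell_radius_um`` placed by an
    inhomogeneous Poisson process (thinning).  The intensity uses the
    Boolean-model correction ``lam = -log(1 - rho) / (pi r^2)`` so that the
    *observed* cell-area fraction matches the specified laminar density
    despite disk overlap.

    ``border_arc_fractions`` place the borders along the outer arc (defaults
    to equal splits).  Ground truth border indices follow the
    distance-function convention (first traverse of the right-hand area).
    """
    if not area_sequence:
        raise ValueError("at least one area required")
    for spec in area_sequence:
        if pixel_size_um > spec.cell_radius_um:
            raise ValueError(
                "pixel size exceeds the cell radius: cells are unresolvable"
            )
        if geometry.thickness_um < 20 * spec.cell_radius_um:
            raise ValueError("ribbon thickness must be >= 20 cell radii")
    rng = np.random.default_rng(seed)

    n_areas = len(area_sequence)
    if border_arc_fractions is None:
        border_arc_fractions = [i / n_areas for i in range(1, n_areas)]
    border_arc_fractions = list(border_arc_fractions)
    if len(border_arc_fractions) != n_areas - 1:
        raise ValueError("need one border fraction per internal border")

    r_out = geometry.outer_radius_um / pixel_size_um
    r_in = geometry.inner_radius_um / pixel_size_um
    half = math.radians(geometry.arc_deg) / 2.0
    theta0, theta1 = -half, half
    pad = max(s.cell_radius_um for s in area_sequence) / pixel_size_um + 2

    # sector opens along +x; bounding box of the annulus sector
    xs = [r_in * math.cos(theta0), r_out * math.cos(theta0), r_out, r_in]
    ys = [r_out * math.sin(theta0), r_out * math.sin(theta1), r_in * math.sin(theta0), r_in * math.sin(theta1)]
    x_min = min(xs) - pad
    x_max = r_out + pad
    y_min = r_out * math.sin(theta0) - pad
    y_max = r_out * math.sin(theta1) + pad
    width = int(math.ceil(x_max - x_min))
    height = int(math.ceil(y_max - y_min))
    cx, cy = -x_min, -y_min  # sector center in pixel coords

    mask = np.zeros((height, width), dtype=bool)

    # area of the sector in px^2 and max intensity over all layers/areas
    sector_area = half * 2 * 0.5 * (r_out**2 - r_in**2)
    for a_idx, spec in enumerate(area_sequence):
        r_cell = spec.cell_radius_um / pixel_size_um
        dens = np.asarray(spec.layer_densities, float)
        lam_layer = -np.log1p(-np.clip(dens, 0.0, 0.999999)) / (math.pi * r_cell**2)
        lam_max = lam_layer.max()
        # angular span of this area
        f0 = 0.0 if a_idx == 0 else border_arc_fractions[a_idx - 1]
        f1 = 1.0 if a_idx == n_areas - 1 else border_arc_fractions[a_idx]
        th_a = theta0 + f0 * (theta1 - theta0)
        th_b = theta0 + f1 * (theta1 - theta0)
        area_px2 = sector_area * (f1 - f0)
        n_cand = rng.poisson(lam_max * area_px2)
        if n_cand == 0:
            continue
        # uniform points in the annulus wedge: r ~ sqrt(U(r_in^2, r_out^2))
        rr = np.sqrt(rng.uniform(r_in**2, r_out**2, n_cand))
        tt = rng.uniform(th_a, th_b, n_cand)
        depth = (r_out - rr) / (r_out - r_in)
        lam_here = -np.log1p(-np.clip(density_at_depth(spec, depth), 0.0, 0.999999))
        lam_here /= math.pi * r_cell**2
        keep = rng.uniform(0.0, lam_max, n_cand) < lam_here
        xc = cx + rr[keep] * np.cos(tt[keep])
        yc = cy + rr[keep] * np.sin(tt[keep])
        for x, y in zip(xc, yc):
            rr_px, cc_px = _disk((y, x), r_cell, shape=mask.shape)
            mask[rr_px, cc_px] = True

    if noise_salt_pepper > 0:
        flips = rng.random(mask.shape) < noise_salt_pepper
        mask = mask ^ flips

    outer = _contour_arc(r_out, theta0, theta1, (cx, cy))
    inner = _contour_arc(r_in, theta0, theta1, (cx, cy))

    # planted borders in traverse indices (seeds at i * spacing along outer arc)
    spacing_px = geometry.traverse_spacing_um / pixel_size_um
    arc_px = r_out * (theta1 - theta0)
    n_trav = int(math.floor(arc_px / spacing_px + 1e-9)) + 1
    border_idx = [
        int(math.ceil(f * arc_px / spacing_px - 1e-9)) for f in border_arc_fractions
    ]
    labels: list[str] = []
    b_iter = border_idx + [n_trav]
    a = 0
    for i in range(n_trav):
        while a < n_areas - 1 and i >= b_iter[a]:
            a += 1
        labels.append(area_sequence[a].name)
    truth = SectionGroundTruth(border_idx, labels)
    section = SegmentedSection(
        mask=mask,
        pixel_size_um=pixel_size_um,
        outer_contour=outer,
        inner_contour=inner,
        section_id=section_id,
        ground_truth=truth,
    )
    return section, truth


def generate_section_series(
    n_sections: int,
    area_sequence: Sequence[AreaSpec],
    geometry: RibbonGeometry,
    pixel_size_um: float,
    border_drift_traverses: int,
    seed: int,
) -> list[tuple[SegmentedSection, SectionGroundTruth]]:
    """Serial sections sharing a planted border with bounded index drift.

    Each section's border indices are the base positions plus an independent
    uniform integer offset in ``[-drift, +drift]`` traverses, emulating the
    biological requirement that a genuine border appears at comparable
    positions in adjacent sections.
    """
    if n_sections < 3:
        raise ValueError("a series needs at least 3 sections")
    rng = np.random.default_rng(seed)
    spacing_px = geometry.traverse_spacing_um / pixel_size_um
    arc_px = geometry.outer_radius_um / pixel_size_um * math.radians(geometry.arc_deg)
    n_areas = len(area_sequence)
    base_fracs = np.array([i / n_areas for i in range(1, n_areas)])
    out = []
    for s in range(n_sections):
        if border_drift_traverses > 0 and len(base_fracs):
            d = rng.integers(-border_drift_traverses, border_drift_traverses + 1,
                             size=len(base_fracs))
        else:
            d = np.zeros(len(base_fracs), int)
        fracs = base_fracs + d * spacing_px / arc_px
        sec, truth = generate_section(
            area_sequence,
            geometry,
            pixel_size_um,
            seed=int(rng.integers(0, 2**31 - 1)),
            section_id=f"sec{s}",
            border_arc_fractions=fracs.tolist(),
        )
        out.append((sec, truth))
    return out


def generate_label_volumes(
    n_brains: int,
    base_labels: np.ndarray,
    jitter_vox: int,
    seed: int,
    affine: np.ndarray | None = None,
    label_names: dict[str, int] | None = None,
) -> list["LabelVolume"]:
    """Per-brain label volumes: the base parcellation under bounded jitter.

    Each area is translated independently by a uniform integer offset in
    ``[-jitter, +jitter]`` voxels per axis.  Labels stay mutually exclusive
    per brain: voxels are assigned in ascending label order and the first
    assignment wins.  Shapes pushed over the grid edge are clipped (logged).
    """
    from .maps import LabelVolume  # avoid circular import at module load

    base = np.asarray(base_labels)
    if base.ndim != 3:
        raise ValueError("base_labels must be a 3-D integer grid")
    labels = [int(v) for v in np.unique(base) if v != 0]
    if affine is None:
        affine = np.eye(4)
    if label_names is None:
        label_names = {f"area{v}": v for v in labels}
    rng = np.random.default_rng(seed)
    volumes = []
    for b in range(n_brains):
        data = np.zeros_like(base)
        for lab in labels:
            shape_mask = base == lab
            if jitter_vox > 0:
                off = rng.integers(-jitter_vox, jitter_vox + 1, size=3)
            else:
                off = np.zeros(3, int)
            moved = _shift_bool(shape_mask, off)
            if moved.sum() < shape_mask.sum():
                logger.warning(
                    "brain %d label %d clipped at the grid edge (jitter %s)",
                    b, lab, off.tolist(),
                )
            data[(data == 0) & moved] = lab
        volumes.append(
            LabelVolume(data=data, affine=affine.copy(), brain_id=f"brain{b}",
                        labels=dict(label_names))
        )
    return volumes


def _shift_bool(mask: np.ndarray, offset: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for ax, o in enumerate(offset):
        n = mask.shape[ax]
        o = int(o)
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def generate_feature_population(
    group_means: Sequence[np.ndarray],
    covariance: np.ndarray,
    n_per_group: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate-normal feature vectors for two (or more) groups.

    Returns ``(X, y)``: stacked samples (group blocks in order) and integer
    group labels.  The covariance is shared across groups and must be
    symmetric positive definite.
    """
    cov = np.asarray(covariance, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    means = [np.asarray(m, float) for m in group_means]
    p = cov.shape[0]
    for m in means:
        if m.shape != (p,):
            raise ValueError("group means must match the covariance dimension")
    rng = np.random.default_rng(seed)
    if n_per_group == 0:
        return np.empty((0, p)), np.empty(0, int)
    xs, ys = [], []
    for g, m in enumerate(means):
        z = rng.standard_normal((n_per_group, p))
        xs.append(m + z @ chol.T)
        ys.append(np.full(n_per_group, g))
    return np.vstack(xs), np.concatenate(ys)


def two_area_feature_section(
    n_traverses: int,
    border_index: int,
    contrast_sd: float,
    seed: int,
    n_features: int = 10,
) -> tuple[np.ndarray, int]:
    """Feature stream of a two-area section with a planted border.

    Traverse feature vectors are i.i.d. standard normal; vectors at index
    ``>= border_index`` have their first coordinate shifted by
    ``contrast_sd`` pooled standard deviations.  ``contrast_sd = 0`` yields a
    homogeneous (no-border) section.  This is the feature-level counterpart
    of a laminar contrast between abutting areas.
    """
    if not (0 <= border_index <= n_traverses):
        raise ValueError("border_index out of range")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_traverses, n_features))
    x[border_index:, 0] += contrast_sd
    return x, border_index
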