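"""Shrinkage-corrected volumetry and Monte-Carlo permutation tests.

Area volumes are reconstructed from serial sections as

    V = s · T · x · y · ΣNi · F

with s the inter-analysis-section interval (in sections), T the section
thickness (mm), x and y the pixel dimensions (mm), ΣNi the total labeled
pixel count over the investigated sections and F the per-brain shrinkage
factor compensating the volume loss of fixation and histological processing.
Volumes are normalized by the individual whole-brain volume before group
comparisons; hemisphere (paired, sign-flip) and sex (unpaired, relabeling)
differences are tested with a Monte-Carlo permutation test (one million
iterations by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeRecord",
    "area_volume",
    "normalize_volume",
    "permutation_test",
    "PermutationResult",
    "inter_section_distance_mm",
]


@dataclass
class VolumeRecord:
    """One area × hemisphere × brain volumetry entry."""

    brain_id: str
    area: str
    hemisphere: str  # "L" or "R"
    sex: str  # "m" or "f"
    sum_Ni: float  # labeled pixels over the investigated sections
    s: float  # inter-analysis-section interval (sections)
    T_mm: float  # section thickness
    x_mm: float  # pixel width
    y_mm: float  # pixel height
    F: float  # shrinkage factor
    whole_brain_mm3: float | None = None

    @property
    def volume_mm3(self) -> float:
        return area_volume(self.s, self.T_mm, self.x_mm, self.y_mm,
                           self.sum_Ni, self.F)

    @property
    def volume_fraction(self) -> float:
        if self.whole_brain_mm3 is None:
            raise ValueError("whole_brain_mm3 not set")
        return normalize_volume(self.volume_mm3, self.whole_brain_mm3)


def area_volume(s: float, T_mm: float, x_mm: float, y_mm: float,
                sum_Ni: float, F: float) -> float:
    """V = s·T·x·y·ΣNi·F in mm³ (exact product).

    All lengths in mm.  A section thickness above 1 mm almost certainly
    means µm were passed by mistake and is flagged.
    """
    if s <= 0 or T_mm <= 0 or x_mm <= 0 or y_mm <= 0 or F <= 0:
        raise ValueError("all factors must be positive")
    if sum_Ni < 0:
        raise ValueError("sum_Ni must be nonnegative")
    if T_mm > 1.0:
        logger.warning(
            "section thickness %.3g mm is implausibly large; µm given in "
            "error?", T_mm,
        )
    return s * T_mm * x_mm * y_mm * sum_Ni * F


def normalize_volume(v_mm3: float, whole_brain_mm3: float) -> float:
    """Area volume as a fraction of the individual whole-brain volume."""
    if whole_brain_mm3 <= 0:
        raise ValueError("whole-brain volume must be positive")
    if v_mm3 > whole_brain_mm3:
        raise ValueError("area volume exceeds the whole-brain volume")
    return v_mm3 / whole_brain_mm3


def inter_section_distance_mm(section_thickness_mm: float = 0.02,
                              step: int = 60) -> float:
    """Distance between investigated sections: thickness × sampling step.

    Analyzing every 60th section of a 20 µm series gives 1.2 mm.
    """
    if section_thickness_mm <= 0 or step < 1:
        raise ValueError("thickness must be positive and step >= 1")
    return section_thickness_mm * step


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    n_iter: int
    null_mean: float
    null_sd: float


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool = False,
    n_iter: int = 1_000_000,
    seed: int | None = None,
    chunk: int = 100_000,
) -> PermutationResult:
    """Two-sided Monte-Carlo permutation test on the difference of means.

    Paired mode (hemisphere comparisons) randomly sign-flips the within-pair
    differences; unpaired mode (sex comparisons) randomly relabels the
    pooled values.  p = (1 + #{|null| >= |observed|}) / (n_iter + 1), the
    add-one Monte-Carlo estimate, so p is never exactly zero.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    rng = np.random.default_rng(seed)
    count = 0
    s1 = 0.0
    s2 = 0.0
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal, matched lengths")
        d = a - b
        observed = float(d.mean())
        thr = abs(observed) - 1e-12
        done = 0
        while done < n_iter:
            m = min(chunk, n_iter - done)
            signs = rng.integers(0, 2, size=(m, len(d))) * 2 - 1
            null = (signs * d).mean(axis=1)
            count += int(np.count_nonzero(np.abs(null) >= thr))
            s1 += float(null.sum())
            s2 += float((null**2).sum())
            done += m
    else:
        z = np.concatenate([a, b])
        na, n = len(a), len(z)
        observed = float(a.mean() - b.mean())
        thr = abs(observed) - 1e-12
        done = 0
        while done < n_iter:
            m = min(chunk, n_iter - done)
            order = np.argsort(rng.random((m, n)), axis=1)
            za = z[order[:, :na]].mean(axis=1)
            zb = z[order[:, na:]].mean(axis=1)
            null = za - zb
            count += int(np.count_nonzero(np.abs(null) >= thr))
            s1 += float(null.sum())
            s2 += float((null**2).sum())
            done += m
    p = (1 + count) / (n_iter + 1)
    mu = s1 / n_iter
    var = max(s2 / n_iter - mu**2, 0.0)
    return PermutationResult(p_value=p, observed=observed, n_iter=n_iter,
                             null_mean=mu, null_sd=float(np.sqrt(var)))
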