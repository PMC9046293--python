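"""Statistical detection of cytoarchitectonic borders.

A border between two cortical areas shows up as a change in laminar profile
shape.  Along the ribbon, at each position k, the block of ``block_size``
profiles left of k is compared with the block right of k via the Mahalanobis
distance D² between block mean feature vectors (pooled within-block
covariance).  Significance is assessed with the two-sample Hotelling T² test
(F approximation), Bonferroni-corrected over the tested positions of the
section.  Candidate borders are significant strict local maxima of D²; they
must recur (within a small positional tolerance) across at least half of the
block sizes in the 10–24 range, and finally at comparable positions in at
least three adjacent serial sections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceSeries",
    "BorderCall",
    "mahalanobis_d2",
    "hotelling_p",
    "distance_function",
    "detect_borders",
    "confirm_across_sections",
]

#: default sliding-window block sizes (profiles per side)
DEFAULT_BLOCK_SIZES = tuple(range(10, 25))


@dataclass
class DistanceSeries:
    """Mahalanobis D² (and corrected p) per sliding-window position."""

    block_size: int
    positions: np.ndarray
    distances: np.ndarray
    p_values: np.ndarray  # Bonferroni-corrected, capped at 1


@dataclass
class BorderCall:
    """A candidate or accepted border position in one section."""

    section_id: str
    position: int
    block_sizes: tuple[int, ...]
    p_min: float
    accepted: bool = False
    supporting_sections: tuple[str, ...] = field(default_factory=tuple)


def _pooled_covariance(a: np.ndarray, b: np.ndarray,
                       cond_threshold: float = 1e8) -> np.ndarray:
    na, nb = len(a), len(b)
    sa = np.cov(a, rowvar=False, ddof=1)
    sb = np.cov(b, rowvar=False, ddof=1)
    s = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    s = np.atleast_2d(s)
    p = s.shape[0]
    if np.linalg.cond(s) > cond_threshold:
        s = s + (1e-6 * np.trace(s) / p) * np.eye(p)
    return s


def mahalanobis_d2(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Mahalanobis D² between the mean vectors of two blocks.

    ``D² = (m_a - m_b)ᵀ S⁻¹ (m_a - m_b)`` with S the pooled within-block
    covariance, weighted by (n-1) per block and ridge-regularized
    (``1e-6 · trace(S)/p`` on the diagonal) when its condition number
    exceeds 1e8.  Affine-invariant and symmetric in its arguments.
    """
    a = np.atleast_2d(np.asarray(block_a, float))
    b = np.atleast_2d(np.asarray(block_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("blocks must share the feature dimension")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each block needs at least 2 vectors")
    s = _pooled_covariance(a, b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    try:
        sol = np.linalg.solve(s, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance singular even after ridge regularization"
        ) from exc
    return float(max(diff @ sol, 0.0))


def hotelling_p(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Two-sample Hotelling T² p-value via the exact F transformation.

    ``T² = n_a n_b/(n_a+n_b) · D²`` and
    ``F = (n-p-1)/(p(n-2)) · T²  ~  F(p, n-p-1)`` under equal Gaussian
    means, where ``n = n_a + n_b`` and p is the feature dimension.
    """
    a = np.atleast_2d(np.asarray(block_a, float))
    b = np.atleast_2d(np.asarray(block_b, float))
    na, nb = len(a), len(b)
    p = a.shape[1]
    n = na + nb
    dof2 = n - p - 1
    if dof2 < 1:
        raise ValueError(
            f"insufficient degrees of freedom: n_a+n_b-p-1 = {dof2} < 1"
        )
    d2 = mahalanobis_d2(a, b)
    t2 = na * nb / n * d2
    f_stat = dof2 / (p * (n - 2)) * t2
    return float(f_dist.sf(f_stat, p, dof2))


def distance_function(features: np.ndarray, block_size: int,
                      section_id: str = "sec0") -> DistanceSeries:
    """Sliding-window D² and corrected p along one section's profile order.

    At position k the ``block_size`` profiles in ``[k-b, k)`` are compared
    with those in ``[k, k+b)``; the window steps by one profile.  The
    Bonferroni factor is the number of tested positions of this section at
    this block size.  Window statistics are computed from cumulative sums,
    so the cost is linear in the number of positions.
    """
    x = np.asarray(features, float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    b = int(block_size)
    if n < 2 * b:
        logger.warning(
            "only %d profiles for block size %d: empty distance series", n, b
        )
        empty = np.empty(0)
        return DistanceSeries(b, np.empty(0, int), empty, empty)
    dof2 = 2 * b - p - 1
    if dof2 < 1:
        raise ValueError(
            f"block size {b} leaves n_a+n_b-p-1 = {dof2} < 1 dof at p={p}"
        )
    positions = np.arange(b, n - b + 1)
    m = len(positions)

    # cumulative first and second moments over the profile order
    cs = np.vstack([np.zeros(p), np.cumsum(x, axis=0)])  # (n+1, p)
    xx = np.einsum("ni,nj->nij", x, x)
    cxx = np.concatenate([np.zeros((1, p, p)), np.cumsum(xx, axis=0)])

    def block_stats(lo: np.ndarray, hi: np.ndarray):
        s = cs[hi] - cs[lo]
        ss = cxx[hi] - cxx[lo]
        mean = s / b
        cov = (ss - b * np.einsum("ki,kj->kij", mean, mean)) / (b - 1)
        return mean, cov

    m_a, s_a = block_stats(positions - b, positions)
    m_b, s_b = block_stats(positions, positions + b)
    s = ((b - 1) * s_a + (b - 1) * s_b) / (2 * b - 2)
    # ridge-regularize ill-conditioned pooled covariances
    cond = np.linalg.cond(s)
    bad = ~np.isfinite(cond) | (cond > 1e8)
    if np.any(bad):
        tr = np.trace(s[bad], axis1=1, axis2=2)
        s[bad] += (1e-6 * tr / p)[:, None, None] * np.eye(p)
    diff = m_a - m_b
    d2 = np.einsum("ki,ki->k", diff, np.linalg.solve(s, diff[:, :, None])[:, :, 0])
    d2 = np.maximum(d2, 0.0)
    t2 = b * b / (2 * b) * d2
    f_stat = dof2 / (p * (2 * b - 2)) * t2
    praw = f_dist.sf(f_stat, p, dof2)
    return DistanceSeries(b, positions, d2, np.minimum(praw * m, 1.0))


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus take the leftmost index."""
    n = len(values)
    if n < 3:
        return np.empty(0, int)
    out = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, int)


def detect_borders(
    features: np.ndarray,
    block_sizes: Iterable[int] = DEFAULT_BLOCK_SIZES,
    alpha: float = 0.001,
    match_tol: int = 2,
    min_block_fraction: float = 0.5,
    section_id: str = "sec0",
) -> list[BorderCall]:
    """Border candidates of one section, consistent across block sizes.

    Per block size, the strict local maxima of D² are found and thinned by
    non-maximum suppression (maxima closer than one block size share
    profiles and cannot represent distinct borders; the larger wins).  A
    maximum is a *candidate* border when its Bonferroni-corrected p is below
    ``alpha`` for at least one block size; it is *kept* when a local maximum
    of D² occurs within ``match_tol`` positions for at least
    ``min_block_fraction`` of the block sizes — significance and positional
    reproducibility act as separate filters.  Nearby kept positions are
    merged into a single call at their (rounded) median.
    """
    block_sizes = sorted(set(int(b) for b in block_sizes))
    per_bs: dict[int, list[tuple[int, float]]] = {}
    n_valid = 0
    for b in block_sizes:
        series = distance_function(features, b, section_id)
        if series.positions.size == 0:
            continue
        n_valid += 1
        maxima = _local_maxima(series.distances)
        maxima = maxima[np.argsort(series.distances[maxima])[::-1]]
        kept_idx: list[int] = []
        for i in maxima:
            if all(abs(int(series.positions[i]) - int(series.positions[j])) >= b
                   for j in kept_idx):
                kept_idx.append(i)
        per_bs[b] = [
            (int(series.positions[i]), float(series.p_values[i]))
            for i in kept_idx
        ]
    if n_valid == 0:
        raise ValueError("no block size yields a valid distance series")

    need = math.ceil(n_valid * min_block_fraction)
    significant = [
        (pos, p, b) for b, cs in per_bs.items() for pos, p in cs if p < alpha
    ]
    kept = []
    for pos, p, b in significant:
        matched = {
            bb for bb, cs in per_bs.items()
            if any(abs(pp - pos) <= match_tol for pp, _ in cs)
        }
        if len(matched) >= need:
            kept.append((pos, p, tuple(sorted(matched))))
    if not kept:
        return []

    # merge kept candidates within match_tol into single calls
    kept.sort()
    calls: list[BorderCall] = []
    group: list[tuple[int, float, tuple[int, ...]]] = [kept[0]]
    for item in kept[1:]:
        if item[0] - group[-1][0] <= match_tol:
            group.append(item)
        else:
            calls.append(_merge_group(group, section_id))
            group = [item]
    calls.append(_merge_group(group, section_id))
    return calls


def _merge_group(group: list[tuple[int, float, tuple[int, ...]]],
                 section_id: str) -> BorderCall:
    positions = [g[0] for g in group]
    p_min = min(g[1] for g in group)
    support: set[int] = set()
    for g in group:
        support.update(g[2])
    pos = int(round(float(np.median(positions))))
    return BorderCall(section_id=section_id, position=pos,
                      block_sizes=tuple(sorted(support)), p_min=p_min)


def confirm_across_sections(
    calls_per_section: Sequence[Sequence[BorderCall]],
    min_sections: int = 3,
    tol_positions: int = 2,
) -> list[BorderCall]:
    """Accept borders found at comparable positions in adjacent sections.

    ``calls_per_section`` must be ordered by serial section position.  A
    border is accepted iff a chain of calls, each within ``tol_positions``
    of the previous one, spans at least ``min_sections`` *consecutive*
    sections.  Accepted calls are returned with their supporting section
    set; all other calls stay unaccepted.
    """
    n = len(calls_per_section)
    accepted: list[BorderCall] = []
    seen: set[tuple[int, int]] = set()  # (section index, call index) in a chain
    for i in range(n):
        for ci, call in enumerate(calls_per_section[i]):
            if (i, ci) in seen:
                continue
            chain = [(i, ci, call)]
            pos = call.position
            j = i + 1
            while j < n:
                match = None
                for cj, cand in enumerate(calls_per_section[j]):
                    if abs(cand.position - pos) <= tol_positions:
                        if match is None or (
                            abs(cand.position - pos)
                            < abs(calls_per_section[j][match].position - pos)
                        ):
                            match = cj
                if match is None:
                    break
                cand = calls_per_section[j][match]
                chain.append((j, match, cand))
                pos = cand.position
                j += 1
            if len(chain) >= min_sections:
                sections = tuple(c.section_id for _, _, c in chain)
                for si, ci2, c in chain:
                    seen.add((si, ci2))
                    accepted.append(
                        BorderCall(
                            section_id=c.section_id,
                            position=c.position,
                            block_sizes=c.block_sizes,
                            p_min=c.p_min,
                            accepted=True,
                            supporting_sections=sections,
                        )
                    )
    return accepted
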