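"""Cytoarchitectonic similarity via hierarchical Ward clustering.

Area-level feature vectors (means over sampled laminar profiles, classically
~45 profiles per hemisphere: 3 sections × ~15 profiles, over 10 brains = 900
profiles per area) are compared by Euclidean distance — the smaller the
distance, the more similar the cytoarchitectonic pattern — and clustered
agglomeratively with Ward's minimum-variance linkage.  Features are
z-standardized before the distance by default because the ten profile
features live on incommensurate scales.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .profiles import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "AreaFeatureSample",
    "Dendrogram",
    "aggregate_features",
    "ward_cluster",
    "planned_profile_count",
]


@dataclass
class AreaFeatureSample:
    """Sampled profile feature vectors of one area in one hemisphere/brain."""

    area: str
    hemisphere: str
    brain_id: str
    vectors: np.ndarray  # (n_profiles, 10)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, float))
        if self.vectors.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature vectors must be {len(FEATURE_NAMES)}-dimensional"
            )


def planned_profile_count(n_sections: int = 3, profiles_per_section: int = 15,
                          n_hemispheres: int = 2, n_brains: int = 10) -> int:
    """Total profiles entering the cluster analysis per area.

    The classical sampling plan — 3 sections with ~15 profiles per
    hemisphere in each of 10 brains — yields 45 profiles per hemisphere and
    900 in total.
    """
    return n_sections * profiles_per_section * n_hemispheres * n_brains


def aggregate_features(
    samples: Sequence[AreaFeatureSample],
    level: str = "area",
    standardize: bool = False,
) -> pd.DataFrame:
    """Mean feature vector per unit (area or area × hemisphere).

    Units without any vectors are dropped with a warning.  Optional
    z-standardization is applied per feature *across units* after
    aggregation.
    """
    if level not in ("area", "area_hemisphere"):
        raise ValueError("level must be 'area' or 'area_hemisphere'")
    groups: dict[str, list[np.ndarray]] = {}
    for s in samples:
        key = s.area if level == "area" else f"{s.area}_{s.hemisphere}"
        groups.setdefault(key, []).append(s.vectors)
    rows = {}
    for key, vecs in groups.items():
        stacked = np.vstack(vecs)
        if stacked.size == 0:
            logger.warning("unit %s has no profiles: dropped", key)
            continue
        rows[key] = stacked.mean(axis=0)
    if not rows:
        raise ValueError("no unit has any feature vectors")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_NAMES)
    df = df.sort_index()
    if standardize:
        df = _zscore(df)
    return df


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (df - df.mean(axis=0)) / sd


@dataclass
class Dendrogram:
    """Merge table of an agglomerative clustering (scipy linkage format)."""

    merges: np.ndarray  # (n-1, 4): left, right, height, size
    labels: list[str] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        tree = to_tree(self.merges)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id] if self.labels else str(node.id)
            left, right = rec(node.left), rec(node.right)
            bl_l = node.dist - (0 if node.left.is_leaf() else node.left.dist)
            bl_r = node.dist - (0 if node.right.is_leaf() else node.right.dist)
            if node.left.is_leaf():
                bl_l = node.dist
            if node.right.is_leaf():
                bl_r = node.dist
            return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

        return rec(tree) + ";"

    def to_json(self) -> str:
        return json.dumps({
            "labels": self.labels,
            "merges": [
                {"left": int(l), "right": int(r), "height": float(h),
                 "size": int(c)}
                for l, r, h, c in self.merges
            ],
        }, indent=2)


def ward_cluster(matrix: pd.DataFrame | np.ndarray,
                 standardize: bool = True) -> Dendrogram:
    """Agglomerative Ward clustering on Euclidean distances.

    Merge heights are scipy's Ward distances (monotonically non-decreasing).
    Features are z-standardized per column by default.  NaNs are rejected.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        x = matrix.to_numpy(float)
    else:
        x = np.asarray(matrix, float)
        labels = [str(i) for i in range(len(x))]
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains NaN or infinite values")
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    z = linkage(x, method="ward", metric="euclidean")
    return Dendrogram(merges=z, labels=labels)
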