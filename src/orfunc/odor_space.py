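"""Diverse odor-panel selection from a physicochemical descriptor matrix.

The screening panel should tile "odor space": odorants described by a
vector of physicochemical descriptors are partitioned into k clusters by
k-means (k = 42 in the reference design, on 2683 odorants x 20 descriptors)
and one representative is drawn per cluster — preferring, within each
cluster, an odorant already known to activate at least one receptor
(nearest such to the centroid), else simply the odorant nearest the
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class DescriptorMatrix:
    """Odorant ids, an n x d descriptor matrix and known-active flags."""

    ids: tuple[str, ...]
    X: np.ndarray
    active: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        active = np.asarray(self.active, dtype=bool)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("descriptor matrix must be n x d with d >= 2")
        if np.isnan(X).any():
            raise ValueError("descriptor matrix contains missing values")
        if len(self.ids) != X.shape[0] or active.size != X.shape[0]:
            raise ValueError("ids/active length must match matrix rows")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "active", active)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        """Build from a table with columns id, active_flag, d1..dN."""
        desc_cols = [c for c in df.columns if c not in ("id", "active_flag")]
        return cls(tuple(df["id"].astype(str)), df[desc_cols].to_numpy(float),
                   df["active_flag"].to_numpy(bool))

    def standardized(self) -> np.ndarray:
        """Z-score each descriptor column (zero-variance columns pass through)."""
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0)
        sd[sd == 0] = 1.0
        return (self.X - mu) / sd


@dataclass(frozen=True)
class OdorPanel:
    """One selected odorant per cluster, with the rule that chose it."""

    table: pd.DataFrame  # columns: cluster, id, dist_to_centroid, rule_used
    k: int
    labels: np.ndarray   # cluster assignment per input odorant

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])


def select_panel(dm: DescriptorMatrix, k: int = 42, seed: int = 0,
                 standardize: bool = True) -> OdorPanel:
    """Seeded k-means panel selection with known-active preference.

    Descriptors are z-scored per column before clustering (their raw scales
    are heterogeneous); initialization is seeded k-means++, so identical
    inputs yield identical panels. Per cluster the known-active member
    nearest the centroid wins ("active_nearest"); a cluster without actives
    falls back to its overall nearest member ("nearest").
    """
    n = dm.X.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds number of odorants ({n})")
    X = dm.standardized() if standardize else dm.X
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    rows = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # sklearn avoids empty clusters; guard anyway
            continue
        dists = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        actives = dm.active[members]
        if actives.any():
            pool = members[actives]
            pool_d = dists[actives]
            rule = "active_nearest"
        else:
            pool, pool_d, rule = members, dists, "nearest"
        best = pool[np.argmin(pool_d)]
        rows.append({
            "cluster": c,
            "id": dm.ids[best],
            "dist_to_centroid": float(np.min(pool_d)),
            "rule_used": rule,
        })
    table = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    if table["id"].duplicated().any():
        raise RuntimeError("panel selections are not distinct")
    return OdorPanel(table, k, labels)


def pca_projection(dm: DescriptorMatrix, n_components: int = 2) -> pd.DataFrame:
    """2-D principal-component coordinates for display of the odor space."""
    from sklearn.decomposition import PCA

    coords = PCA(n_components=n_components).fit_transform(dm.standardized())
    cols = [f"pc{i + 1}" for i in range(n_components)]
    out = pd.DataFrame(coords, columns=cols)
    out.insert(0, "id", dm.ids)
    return out
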