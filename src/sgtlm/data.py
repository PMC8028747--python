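"""Clustered binary data containers (long format grouped into clusters)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterData", "Panel"]


@dataclass(frozen=True)
class ClusterData:
    """One cluster: binary outcomes y, fixed design X, random design W."""

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    id: object = None

    def __post_init__(self):
        y = np.atleast_1d(np.asarray(self.y))
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if not np.isin(y, (0, 1)).all():
            raise ValueError(f"cluster {self.id}: outcomes must be 0/1")
        if X.shape[0] != y.shape[0] or W.shape[0] != y.shape[0]:
            raise ValueError(f"cluster {self.id}: design row counts disagree")
        if y.shape[0] < 1:
            raise ValueError(f"cluster {self.id}: empty cluster")
        if not (np.isfinite(X).all() and np.isfinite(W).all()):
            raise ValueError(f"cluster {self.id}: non-finite covariates")
        object.__setattr__(self, "y", y.astype(int))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "W", W)

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class Panel:
    """Ordered collection of clusters with shared design dimensions."""

    clusters: list[ClusterData]
    fixed_names: list[str] = field(default_factory=list)
    random_names: list[str] = field(default_factory=list)
    outcome_name: str = "y"
    id_name: str = "id"

    def __post_init__(self):
        if not self.clusters:
            raise ValueError("panel has no clusters")
        p = self.clusters[0].X.shape[1]
        q = self.clusters[0].W.shape[1]
        for c in self.clusters:
            if c.X.shape[1] != p or c.W.shape[1] != q:
                raise ValueError("inconsistent design dimensions across clusters")
        ids = [c.id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValueError("cluster ids are not unique")
        if not self.fixed_names:
            self.fixed_names = [f"x{j}" for j in range(p)]
        if not self.random_names:
            self.random_names = [f"w{j}" for j in range(q)]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_obs(self) -> int:
        return sum(c.n for c in self.clusters)

    @property
    def p(self) -> int:
        return self.clusters[0].X.shape[1]

    @property
    def q(self) -> int:
        return self.clusters[0].W.shape[1]

    def stacked_X(self) -> np.ndarray:
        return np.vstack([c.X for c in self.clusters])

    def stacked_y(self) -> np.ndarray:
        return np.concatenate([c.y for c in self.clusters])

    @staticmethod
    def from_arrays(y, X, W, groups, **names) -> "Panel":
        """Group long-format arrays into contiguous clusters keyed by id.

        Rows keep file order inside each cluster; cluster order follows first
        appearance.
        """
        y = np.asarray(y)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        W = np.atleast_2d(np.asarray(W, dtype=float))
        groups = np.asarray(groups)
        order = {}
        for g in groups:
            if g not in order:
                order[g] = len(order)
        clusters = []
        for g in order:
            m = groups == g
            clusters.append(ClusterData(y=y[m], X=X[m], W=W[m], id=g))
        return Panel(clusters=clusters, **names)
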