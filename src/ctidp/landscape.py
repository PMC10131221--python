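"""Topology-space landscapes: per-frame CT coordinates, Gaussian-mixture
state segmentation, and the evolution score.

Every trajectory frame is reduced to a point in a three-dimensional
*topological space* whose axes are the numbers of series (S), parallel (P)
and cross (X) relations among that frame's contacts.  After min-max scaling
to [0, 1]^3, the point cloud is segmented into transient topological states
with a Gaussian mixture model; the number of components is chosen by the
Bayesian Information Criterion over a candidate range.  Directional
interconversion between the temporally ordered states is quantified by the
evolution score

    E = sum over consecutive states (j -> i) of  d_ij / (s_i + s_j)

where d_ij is the Euclidean distance between state centroids and s_i, s_j
the states' spreads (mean member distance to the centroid).  Wide,
overlapping clusters give low E; narrow, well-separated clusters visited in
sequence give high E.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .contacts import ContactTrajectory
from .topology import topology_counts

__all__ = [
    "TopologyCoordinates",
    "topology_trajectory",
    "scale_minmax",
    "ClusterSummary",
    "TopologyLandscape",
    "LandscapeResults",
    "fit_gmm_bic",
    "temporal_order",
    "evolution_score",
    "ratio_evolution_score",
]


@dataclass(frozen=True)
class TopologyCoordinates:
    """Per-frame (nS, nP, nX) counts plus their min-max scaled image.

    Frames with fewer than two contacts have undefined topology; they are
    kept at (0, 0, 0) and flagged in ``defined``.
    """

    counts: np.ndarray   # (n_frames, 3) integer counts
    scaled: np.ndarray   # (n_frames, 3) in [0, 1]
    defined: np.ndarray  # (n_frames,) bool

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=["nS", "nP", "nX"])
        df.insert(0, "frame", np.arange(len(df)))
        df["defined"] = self.defined
        return df


def topology_trajectory(traj: ContactTrajectory) -> TopologyCoordinates:
    """Map each frame of a contact trajectory to (nS, nP, nX) counts."""
    counts = np.zeros((len(traj), 3), dtype=int)
    defined = np.zeros(len(traj), dtype=bool)
    for f, frame in enumerate(traj.frames):
        if len(frame) >= 2:
            counts[f] = topology_counts(frame)
            defined[f] = True
    return TopologyCoordinates(
        counts=counts, scaled=scale_minmax(counts), defined=defined
    )


def scale_minmax(coords: np.ndarray) -> np.ndarray:
    """Independently map each axis to [0, 1]; constant axes map to 0."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("expected a 2-D (n_frames, n_axes) array")
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    out = np.zeros_like(coords)
    nz = span > 0
    out[:, nz] = (coords[:, nz] - lo[nz]) / span[nz]
    return out


@dataclass(frozen=True)
class ClusterSummary:
    """One topological state: centroid, spread and member frames."""

    id: int
    centroid: np.ndarray
    spread: float
    frames: np.ndarray
    temporal_rank: int

    @property
    def median_frame(self) -> float:
        return float(np.median(self.frames))


def temporal_order(labels: Sequence[int]) -> list[int]:
    """Cluster ids ordered by the median frame index of their members."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    medians = {int(c): float(np.median(np.flatnonzero(labels == c))) for c in ids}
    return sorted((int(c) for c in ids), key=lambda c: (medians[c], c))


def ratio_evolution_score(
    d: float, s_i: float, s_j: float
) -> float:
    """Default per-transition evolution score: d / (s_i + s_j).

    Two coincident point-clusters (zero combined spread) contribute 0.
    """
    if s_i + s_j == 0:
        warnings.warn(
            "two clusters with zero combined spread; contribution set to 0",
            stacklevel=2,
        )
        return 0.0
    return d / (s_i + s_j)


def evolution_score(
    clusters: Sequence[ClusterSummary],
    pair_score: Callable[[float, float, float], float] = ratio_evolution_score,
) -> float:
    """Total evolution score over temporally consecutive cluster pairs.

    A single cluster has no transitions and scores 0.  The per-transition
    functional form is injectable; the default is the ratio of centroid
    distance to combined spread.
    """
    ordered = sorted(clusters, key=lambda c: c.temporal_rank)
    total = 0.0
    for a, b in zip(ordered, ordered[1:]):
        d = float(np.linalg.norm(np.asarray(b.centroid) - np.asarray(a.centroid)))
        total += pair_score(d, a.spread, b.spread)
    return total


class TopologyLandscape:
    """Gaussian-mixture model of a trajectory in topology space.

    Parameters
    ----------
    coords
        Either a :class:`TopologyCoordinates`, a raw ``(n_frames, 3)``
        array of (nS, nP, nX) counts (min-max scaled internally), or a
        :class:`~ctidp.contacts.ContactTrajectory`.

    Examples
    --------
    >>> import numpy as np
    >>> pts = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
    >>> res = TopologyLandscape(pts).fit(k_range=range(1, 3), n_init=2,
    ...                                  seed=0)
    >>> res.k
    2
    """

    def __init__(self, coords):
        if isinstance(coords, ContactTrajectory):
            coords = topology_trajectory(coords)
        if isinstance(coords, TopologyCoordinates):
            self.coordinates = coords
            self.scaled = coords.scaled
        else:
            arr = np.asarray(coords, dtype=float)
            self.coordinates = None
            self.scaled = scale_minmax(arr)
        if len(self.scaled) < 2:
            raise ValueError("need at least 2 frames to fit a landscape")

    def fit(
        self,
        k_range: Iterable[int] = range(1, 11),
        n_init: int = 100,
        tol: float = 1e-4,
        max_iter: int = 10_000,
        reg_covar: float = 1e-6,
        seed: int | None = None,
        bic_direction: str = "min",
        pair_score: Callable[[float, float, float], float] = ratio_evolution_score,
    ) -> "LandscapeResults":
        """Fit mixtures over ``k_range`` and keep the BIC-optimal one.

        ``bic_direction`` selects the winning k as the minimum (standard
        scikit-learn convention, default) or maximum of the criterion.
        Candidate k exceeding the number of frames are skipped with a
        warning.
        """
        if bic_direction not in ("min", "max"):
            raise ValueError("bic_direction must be 'min' or 'max'")
        x = self.scaled
        bic_by_k: dict[int, float] = {}
        fits: dict[int, GaussianMixture] = {}
        for k in k_range:
            if k < 1:
                continue
            if k > len(x):
                warnings.warn(
                    f"k={k} exceeds the number of frames ({len(x)}); skipped",
                    stacklevel=2,
                )
                continue
            gmm = GaussianMixture(
                n_components=k,
                n_init=n_init,
                tol=tol,
                max_iter=max_iter,
                reg_covar=reg_covar,
                random_state=seed,
            )
            gmm.fit(x)
            bic_by_k[k] = float(gmm.bic(x))
            fits[k] = gmm
        if not bic_by_k:
            raise ValueError("no feasible cluster count in k_range")
        pick = min if bic_direction == "min" else max
        k = pick(bic_by_k, key=bic_by_k.__getitem__)
        labels = fits[k].predict(x)

        order = temporal_order(labels)
        clusters = []
        for rank, cid in enumerate(order):
            members = np.flatnonzero(labels == cid)
            pts = x[members]
            centroid = pts.mean(axis=0)
            spread = float(np.linalg.norm(pts - centroid, axis=1).mean())
            clusters.append(
                ClusterSummary(
                    id=int(cid),
                    centroid=centroid,
                    spread=spread,
                    frames=members,
                    temporal_rank=rank,
                )
            )
        return LandscapeResults(
            model=self,
            k=int(k),
            bic_by_k=bic_by_k,
            bic_direction=bic_direction,
            labels=labels,
            clusters=clusters,
            evolution=evolution_score(clusters, pair_score),
            seed=seed,
        )


def fit_gmm_bic(
    scaled_coords: np.ndarray,
    k_range: Iterable[int] = range(1, 11),
    seed: int | None = None,
    **params,
) -> "LandscapeResults":
    """Functional wrapper: fit a landscape on already-scaled coordinates."""
    model = TopologyLandscape.__new__(TopologyLandscape)
    model.coordinates = None
    model.scaled = np.asarray(scaled_coords, dtype=float)
    return model.fit(k_range=k_range, seed=seed, **params)


@dataclass
class LandscapeResults:
    """Fitted topology landscape: states, BIC table, evolution score."""

    model: TopologyLandscape
    k: int
    bic_by_k: dict[int, float]
    bic_direction: str
    labels: np.ndarray
    clusters: list[ClusterSummary]
    evolution: float
    seed: int | None = None

    @property
    def evolution_score(self) -> float:
        return self.evolution

    def ordered_clusters(self) -> list[ClusterSummary]:
        return sorted(self.clusters, key=lambda c: c.temporal_rank)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "bic_direction": self.bic_direction,
            "bic_by_k": {str(k): v for k, v in sorted(self.bic_by_k.items())},
            "evolution_score": self.evolution,
            "seed": self.seed,
            "clusters": [
                {
                    "id": c.id,
                    "temporal_rank": c.temporal_rank,
                    "centroid": np.asarray(c.centroid).tolist(),
                    "spread": c.spread,
                    "n_frames": int(len(c.frames)),
                    "median_frame": c.median_frame,
                }
                for c in self.ordered_clusters()
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def frame_table(self) -> pd.DataFrame:
        """Per-frame TSV-ready table: frame, nS, nP, nX, cluster."""
        if self.model.coordinates is not None:
            df = self.model.coordinates.to_frame()
        else:
            df = pd.DataFrame(self.model.scaled, columns=["nS", "nP", "nX"])
            df.insert(0, "frame", np.arange(len(df)))
        df["cluster"] = self.labels
        return df

    def summary(self) -> str:
        lines = [
            "Topology landscape",
            "------------------",
            f"frames:           {len(self.model.scaled)}",
            f"states (k):       {self.k}  "
            f"[BIC {self.bic_direction} over k={sorted(self.bic_by_k)}]",
            f"evolution score:  {self.evolution:.4f}",
            "",
            "state  rank  n_frames  spread   centroid",
        ]
        for c in self.ordered_clusters():
            cx = ", ".join(f"{v:.3f}" for v in np.asarray(c.centroid))
            lines.append(
                f"{c.id:>5}  {c.temporal_rank:>4}  {len(c.frames):>8}  "
                f"{c.spread:.4f}  ({cx})"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """3-D scatter of the scaled topology coordinates by state."""
        import matplotlib.pyplot as plt

        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        x = self.model.scaled
        ax.scatter(x[:, 0], x[:, 1], x[:, 2], c=self.labels, s=8)
        for c in self.clusters:
            ax.scatter(*np.asarray(c.centroid), marker="x", s=60, color="k")
        ax.set_xlabel("S")
        ax.set_ylabel("P")
        ax.set_zlabel("X")
        return ax
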