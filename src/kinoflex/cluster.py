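"""Activation-loop conformational clustering: pairwise RMSD, k-medoids and
the cluster-transition graph.

The distance between two frames is the RMSD over the activation-loop
selection after least-squares superposition of one frame onto the other over
that same selection (segment fit isolates loop conformation from global
domain motion; a whole-molecule fit is available via ``fit_mask``).
Clustering is the Voronoi-iteration (alternating assignment/update) variant
of k-medoids with deterministic greedy farthest-point seeding, so the
objective — the sum of member-to-medoid distances — is non-increasing every
iteration. Default k = 10 clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from kinoflex.trajectory import Trajectory, kabsch_superpose

__all__ = ["KMedoids", "Clustering", "pairwise_rmsd", "k_medoids", "transition_graph"]


def pairwise_rmsd(
    traj: Trajectory,
    selection: str | Sequence[str] | np.ndarray = "backbone",
    fit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over a selection.

    Entry (i, j) is the RMSD of frame j fit onto frame i over the selected
    atoms. ``selection`` may be a selection string/name-list (see
    ``Trajectory.atom_mask``) or a boolean/index mask; ``fit_mask``
    optionally fits on a different atom set (e.g. the whole molecule) while
    measuring RMSD on the selection — by default fit and measurement use the
    same atoms.
    """
    if isinstance(selection, np.ndarray):
        mask = selection.astype(bool) if selection.dtype == bool else np.isin(
            np.arange(traj.n_atoms), selection
        )
    else:
        mask = traj.atom_mask(selection)
    if not mask.any():
        raise ValueError("selection matches no atoms")
    fit = mask if fit_mask is None else np.asarray(fit_mask, dtype=bool)

    n = traj.n_frames
    coords = traj.coordinates
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, t, _ = kabsch_superpose(coords[j], coords[i], fit)
            moved = coords[j] @ R.T + t
            diff = moved[mask] - coords[i][mask]
            D[i, j] = D[j, i] = float(np.sqrt((diff**2).sum() / mask.sum()))
    return D


def _validate_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


class KMedoids(ClusterMixin, BaseEstimator):
    """k-medoids over a precomputed distance matrix (Voronoi iteration).

    Initialization is greedy farthest-point: the first medoid is chosen by
    the seeded RNG, each further medoid is the point maximizing its distance
    to the nearest already-chosen medoid (ties toward the lower frame
    index). Assignment ties also break toward the lower medoid index, and a
    medoid update picks the lowest-index minimizer, making a run fully
    deterministic given ``random_state``.

    Fitted attributes
    -----------------
    medoid_indices_ : frame index of each cluster's medoid
    labels_ : per-frame cluster assignment
    inertia_ : sum of member-to-medoid distances (the objective)
    objective_history_ : per-iteration objective (non-increasing)
    n_iter_ : iterations until the fixed point (or max_iter)
    """

    def __init__(self, n_clusters: int = 10, max_iter: int = 300, random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        D = _validate_distance(X)
        n = D.shape[0]
        k = self.n_clusters
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds the number of frames {n}")

        rng = np.random.default_rng(self.random_state)
        medoids = [int(rng.integers(n))]
        while len(medoids) < k:
            d_near = D[:, medoids].min(axis=1)
            d_near[medoids] = -1.0
            medoids.append(int(np.argmax(d_near)))  # argmax ties -> lowest index
        medoids = np.array(sorted(medoids))

        def _assign(meds: np.ndarray) -> np.ndarray:
            lab = np.argmin(D[:, meds], axis=1)  # argmin ties -> lowest medoid index
            lab[meds] = np.arange(k)  # a medoid stays in its own cluster on 0-ties
            return lab

        history = []
        labels = _assign(medoids)
        for it in range(self.max_iter):
            obj = float(D[np.arange(n), medoids[labels]].sum())
            if history and obj > history[-1] + 1e-12:
                raise AssertionError("k-medoids objective increased")
            history.append(obj)

            new_medoids = medoids.copy()
            for c in range(k):
                members = np.nonzero(labels == c)[0]
                if len(members) == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = int(members[np.argmin(within)])
            new_labels = _assign(new_medoids)
            if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
                break
            medoids, labels = new_medoids, new_labels

        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = float(D[np.arange(n), medoids[labels]].sum())
        self.objective_history_ = history
        self.n_iter_ = len(history)
        return self

    def to_clustering(self) -> "Clustering":
        return Clustering(
            k=self.n_clusters,
            medoid_indices=self.medoid_indices_,
            assignments=self.labels_,
            objective=self.inertia_,
        )


@dataclass
class Clustering:
    """A k-medoids result: medoids, assignments, objective and cardinalities."""

    k: int
    medoid_indices: np.ndarray
    assignments: np.ndarray
    objective: float

    def __post_init__(self) -> None:
        self.medoid_indices = np.asarray(self.medoid_indices, dtype=int)
        self.assignments = np.asarray(self.assignments, dtype=int)
        for c, m in enumerate(self.medoid_indices):
            if self.assignments[m] != c:
                raise ValueError(f"medoid {m} is not assigned to its own cluster {c}")

    @property
    def cardinalities(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "medoid_indices": self.medoid_indices.tolist(),
            "assignments": self.assignments.tolist(),
            "objective": self.objective,
            "cardinalities": self.cardinalities.tolist(),
        }


def k_medoids(D: np.ndarray, k: int = 10, seed: int = 0, max_iter: int = 300) -> Clustering:
    """Cluster a precomputed distance matrix; thin wrapper over KMedoids."""
    return KMedoids(n_clusters=k, max_iter=max_iter, random_state=seed).fit(D).to_clustering()


def transition_graph(
    assignments: Sequence[int],
    activity: Sequence[float] | None = None,
) -> nx.Graph:
    """Build the cluster-transition graph from a frame assignment sequence.

    Nodes are clusters with attributes ``size`` (cardinality) and, when an
    activity-probability series is given, ``mean_activity`` of the member
    frames. An undirected edge (a, b) carries weight = number of consecutive
    frame pairs switching between a and b (either direction); the graph also
    stores ``persistence`` (count of non-transitions), so total edge weight
    plus persistence equals n - 1.
    """
    a = np.asarray(assignments, dtype=int)
    if activity is not None:
        act = np.asarray(activity, dtype=float)
        if len(act) != len(a):
            raise ValueError("activity series length must equal assignments length")
    G = nx.Graph()
    for c in np.unique(a):
        attrs = {"size": int((a == c).sum())}
        if activity is not None:
            attrs["mean_activity"] = float(act[a == c].mean())
        G.add_node(int(c), **attrs)
    persistence = 0
    for u, v in zip(a[:-1], a[1:]):
        if u == v:
            persistence += 1
            continue
        e = (int(min(u, v)), int(max(u, v)))
        if G.has_edge(*e):
            G.edges[e]["weight"] += 1
        else:
            G.add_edge(*e, weight=1)
    G.graph["persistence"] = persistence
    return G
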