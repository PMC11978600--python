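"""Trajectory clustering: temporal k-means under multivariate dynamic time warping.

Participant trajectories are short (one to three visits) multivariate
sequences of latent cognitive features. Distances use dependent multivariate
DTW: one optimal monotone, boundary-anchored alignment path over the joint
feature vectors, local cost = squared Euclidean distance, returned distance =
square root of the accumulated cost. Centroids are fixed-length "temporal
centroids" updated by DTW barycenter averaging (DBA). The number of clusters
is selected by minimizing the Davies-Bouldin index computed with DTW
distances, and clusters are named by their level/slope archetype.

Ages are not used inside the alignment (visits align ordinally); they only
enter the slope computation used for archetype naming.

Because sequences have at most a handful of points, the k-means inner loops
are vectorized across participants: `_Packed` holds all trajectories in one
padded array and the DP (and its backtracking) runs on whole batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "ClusterModel",
    "trajectories_from_latent",
    "dtw_distance",
    "dba_centroid",
    "temporal_kmeans",
    "davies_bouldin",
    "select_k",
    "label_archetypes",
]


@dataclass(frozen=True)
class Trajectory:
    """Ordered visits of one participant: ages (years) and an (L, d) feature array."""

    participant_id: str
    ages: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "ages", ages)
        if len(ages) != X.shape[0]:
            raise ValueError("ages and feature rows disagree in length")
        if len(ages) == 0:
            raise ValueError("empty trajectory")
        if len(ages) > 1 and not (np.diff(ages) > 0).all():
            raise ValueError("visit ages must be strictly increasing")
        if not np.isfinite(X).all():
            raise ValueError("latent features must be complete (no NaN)")

    def __len__(self) -> int:
        return self.X.shape[0]


def trajectories_from_latent(latent: pd.DataFrame) -> list[Trajectory]:
    """Build per-participant trajectories from a latent table
    (columns participant_id, visit_index, age, latent_*)."""
    feat_cols = [c for c in latent.columns if c.startswith("latent_")]
    if not feat_cols:
        raise ValueError("latent table has no latent_* columns")
    out = []
    for pid, grp in latent.sort_values(["participant_id", "visit_index"]).groupby(
        "participant_id", sort=True
    ):
        out.append(Trajectory(str(pid), grp["age"].to_numpy(), grp[feat_cols].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# pairwise DTW


def _seq(a) -> np.ndarray:
    X = a.X if isinstance(a, Trajectory) else np.atleast_2d(np.asarray(a, dtype=float))
    if X.size == 0:
        raise ValueError("empty trajectory")
    return X


def dtw_sq(a, b) -> float:
    """Accumulated squared-Euclidean cost of the optimal DTW alignment."""
    A, B = _seq(a), _seq(b)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    la, lb = A.shape[0], B.shape[0]
    diff = A[:, None, :] - B[None, :, :]
    cost = np.einsum("abd,abd->ab", diff, diff)
    D = np.full((la, lb), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(1, la):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
    for j in range(1, lb):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, la):
        for j in range(1, lb):
            D[i, j] = cost[i, j] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(D[-1, -1])


def dtw_distance(a, b) -> float:
    """Dependent multivariate DTW distance (square root of accumulated cost).

    Symmetric, non-negative, zero iff the sequences are identical. The
    triangle inequality is not guaranteed (DTW is not a metric).
    """
    return float(np.sqrt(dtw_sq(a, b)))


# ---------------------------------------------------------------------------
# batch engine


class _Packed:
    """All trajectories padded into one (n, Lmax, d) array for vectorized DP."""

    def __init__(self, trajectories: list[Trajectory]):
        if not trajectories:
            raise ValueError("no trajectories")
        self.trajectories = trajectories
        self.lengths = np.array([len(t) for t in trajectories])
        self.n = len(trajectories)
        self.d = trajectories[0].X.shape[1]
        for t in trajectories:
            if t.X.shape[1] != self.d:
                raise ValueError("trajectories have mixed feature dimensions")
        self.Lmax = int(self.lengths.max())
        self.X = np.zeros((self.n, self.Lmax, self.d))
        for i, t in enumerate(trajectories):
            self.X[i, : len(t)] = t.X

    def dp(self, C: np.ndarray, want_decisions: bool = False):
        """Vectorized DP of every packed trajectory against one sequence C.

        Returns (final squared costs (n,), decisions (n, Lmax, Lc) or None).
        Decision codes: 0 diagonal, 1 from (a-1, b), 2 from (a, b-1).
        """
        C = np.atleast_2d(np.asarray(C, dtype=float))
        Lc = C.shape[0]
        diff = self.X[:, :, None, :] - C[None, None, :, :]
        cost = np.einsum("nabd,nabd->nab", diff, diff)
        D = np.full((self.n, self.Lmax, Lc), np.inf)
        dec = np.zeros((self.n, self.Lmax, Lc), dtype=np.int8) if want_decisions else None
        D[:, 0, 0] = cost[:, 0, 0]
        for a in range(1, self.Lmax):
            D[:, a, 0] = D[:, a - 1, 0] + cost[:, a, 0]
            if dec is not None:
                dec[:, a, 0] = 1
        for b in range(1, Lc):
            D[:, 0, b] = D[:, 0, b - 1] + cost[:, 0, b]
            if dec is not None:
                dec[:, 0, b] = 2
        for a in range(1, self.Lmax):
            for b in range(1, Lc):
                options = np.stack(
                    [D[:, a - 1, b - 1], D[:, a - 1, b], D[:, a, b - 1]], axis=0
                )
                choice = options.argmin(axis=0)
                D[:, a, b] = cost[:, a, b] + options[choice, np.arange(self.n)]
                if dec is not None:
                    dec[:, a, b] = choice
        final = D[np.arange(self.n), self.lengths - 1, Lc - 1]
        return final, dec

    def sq_distances(self, C: np.ndarray) -> np.ndarray:
        return self.dp(C)[0]

    def align_sums(self, C: np.ndarray, weights: np.ndarray | None = None):
        """Backtrack optimal paths for all members; return per-centroid-bin
        sums of aligned member points and pair counts (the DBA update), plus
        the squared costs."""
        C = np.atleast_2d(np.asarray(C, dtype=float))
        Lc = C.shape[0]
        final, dec = self.dp(C, want_decisions=True)
        w = np.ones(self.n) if weights is None else np.asarray(weights, dtype=float)
        sums = np.zeros((Lc, self.d))
        counts = np.zeros(Lc)
        a = self.lengths - 1
        b = np.full(self.n, Lc - 1)
        active = np.ones(self.n, dtype=bool)
        for _ in range(self.Lmax + Lc - 1):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            np.add.at(sums, b[idx], self.X[idx, a[idx]] * w[idx, None])
            np.add.at(counts, b[idx], w[idx])
            at_origin = (a[idx] == 0) & (b[idx] == 0)
            active[idx[at_origin]] = False
            move = idx[~at_origin]
            d_ = dec[move, a[move], b[move]]
            a[move] -= (d_ != 2).astype(int)
            b[move] -= (d_ != 1).astype(int)
        return sums, counts, final


def _stretch(X: np.ndarray, L: int) -> np.ndarray:
    """Resample a sequence to length L by linear interpolation in index space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == L:
        return X.copy()
    if X.shape[0] == 1:
        return np.repeat(X, L, axis=0)
    src = np.linspace(0, 1, X.shape[0])
    dst = np.linspace(0, 1, L)
    return np.column_stack([np.interp(dst, src, X[:, j]) for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# DBA


def dba_centroid(
    trajectories: list[Trajectory],
    L: int = 3,
    max_iter: int = 30,
    tol: float = 1e-6,
    seed: int = 0,
    init: np.ndarray | None = None,
    _packed: "_Packed | None" = None,
) -> np.ndarray:
    """DTW barycenter average of length L.

    Iteratively aligns all members to the current centroid and replaces each
    centroid point by the mean of its aligned member points; the summed
    squared-DTW objective is non-increasing. Default initialization: the
    medoid member (on a random subsample of at most 60 members for large
    clusters), stretched to length L.
    """
    packed = _packed if _packed is not None else _Packed(trajectories)
    if init is not None:
        C = np.atleast_2d(np.asarray(init, dtype=float)).copy()
    else:
        rng = np.random.Generator(np.random.PCG64(seed))
        cand = np.arange(packed.n)
        if packed.n > 60:
            cand = rng.choice(packed.n, size=60, replace=False)
        totals = [packed.sq_distances(packed.trajectories[i].X)[cand].sum() for i in cand]
        medoid = cand[int(np.argmin(totals))]
        C = _stretch(packed.trajectories[medoid].X, L)

    prev_obj = np.inf
    for _ in range(max_iter):
        sums, counts, final = packed.align_sums(C)
        obj = final.sum()
        ok = counts > 0
        C_new = C.copy()
        C_new[ok] = sums[ok] / counts[ok, None]
        if prev_obj - obj <= tol * max(prev_obj, 1e-12):
            C = C_new
            break
        C = C_new
        prev_obj = obj
    return C


# ---------------------------------------------------------------------------
# temporal k-means


@dataclass
class ClusterModel:
    k: int
    centroids: list[np.ndarray]
    labels: pd.Series  # participant_id -> cluster index in 1..k
    inertia: float  # sum of squared DTW distances to assigned centroids
    objective_history: list[float]
    iterations_run: int
    seed: int
    db_index: float = float("nan")

    def labels_array(self, trajectories: list[Trajectory]) -> np.ndarray:
        return self.labels.reindex([t.participant_id for t in trajectories]).to_numpy()


def _kpp_seed_centroids(packed: _Packed, k: int, L: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """k-means++-style seeding on DTW distances: member sequences (stretched
    to the centroid length) chosen with probability proportional to the
    squared distance to the nearest already-chosen seed."""
    first = int(rng.integers(packed.n))
    chosen = [first]
    d2 = packed.sq_distances(packed.trajectories[first].X)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            nxt = int(rng.integers(packed.n))
        else:
            nxt = int(rng.choice(packed.n, p=d2 / total))
        chosen.append(nxt)
        d2 = np.minimum(d2, packed.sq_distances(packed.trajectories[nxt].X))
    return [_stretch(packed.trajectories[i].X, L) for i in chosen]


def temporal_kmeans(
    trajectories: list[Trajectory],
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 50,
    centroid_len: int = 3,
    dba_max_iter: int = 10,
) -> ClusterModel:
    """Alternating DTW assignment / DBA centroid update, best of ``n_init``
    random restarts by inertia. Deterministic given the seed; ties in the
    assignment go to the lowest centroid index; an emptied cluster is repaired
    by reassigning the point farthest from its centroid."""
    n = len(trajectories)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available trajectories")
    packed = _Packed(trajectories)

    if n > 1:
        all_equal = bool(np.all(packed.lengths == packed.lengths[0]) and
                         np.allclose(packed.X, packed.X[0]))
        if all_equal and k > 1:
            warnings.warn("all trajectories identical; clustering is degenerate "
                          "(a single effective cluster)")

    best: tuple[float, dict] | None = None
    root = np.random.SeedSequence(seed)
    for init_idx, child in enumerate(root.spawn(n_init)):
        rng = np.random.Generator(np.random.PCG64(child))
        centroids = _kpp_seed_centroids(packed, k, centroid_len, rng)
        labels = np.full(n, -1)
        history: list[float] = []
        iters = 0
        for it in range(max_iter):
            iters = it + 1
            cost = np.column_stack([packed.sq_distances(C) for C in centroids])
            new_labels = cost.argmin(axis=1)  # argmin takes the lowest index on ties
            # empty-cluster repair: give the globally farthest point to the cluster
            assigned_cost = cost[np.arange(n), new_labels]
            for c in range(k):
                if not (new_labels == c).any():
                    far = int(np.argmax(assigned_cost))
                    new_labels[far] = c
                    assigned_cost[far] = 0.0
            history.append(float(cost[np.arange(n), new_labels].sum()))
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = [trajectories[i] for i in np.flatnonzero(labels == c)]
                sub = _Packed(members)
                centroids[c] = dba_centroid(
                    members, L=centroid_len, max_iter=dba_max_iter,
                    init=centroids[c], _packed=sub,
                )
        cost = np.column_stack([packed.sq_distances(C) for C in centroids])
        inertia = float(cost[np.arange(n), labels].sum())
        if best is None or inertia < best[0]:
            best = (inertia, {
                "centroids": [C.copy() for C in centroids],
                "labels": labels.copy(),
                "history": history,
                "iters": iters,
            })

    inertia, payload = best
    labels = pd.Series(
        payload["labels"] + 1,
        index=pd.Index([t.participant_id for t in trajectories], name="participant_id"),
        name="cluster",
    )
    return ClusterModel(
        k=k,
        centroids=payload["centroids"],
        labels=labels,
        inertia=inertia,
        objective_history=payload["history"],
        iterations_run=payload["iters"],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cluster validity


def davies_bouldin(trajectories: list[Trajectory], model: ClusterModel) -> float:
    """Davies-Bouldin index on DTW distances.

    DB = mean over clusters of max_{j != i} (S_i + S_j) / M_ij with S_i the
    mean member-to-centroid DTW distance and M_ij the DTW distance between
    centroids. Lower is better; coincident centroids yield +inf with a warning.
    """
    if model.k < 2:
        raise ValueError("Davies-Bouldin requires k >= 2")
    packed = _Packed(trajectories)
    labels = model.labels_array(trajectories) - 1
    S = np.zeros(model.k)
    for c in range(model.k):
        member_idx = np.flatnonzero(labels == c)
        dists = np.sqrt(packed.sq_distances(model.centroids[c])[member_idx])
        S[c] = dists.mean() if member_idx.size else 0.0
    M = np.zeros((model.k, model.k))
    for i in range(model.k):
        for j in range(i + 1, model.k):
            M[i, j] = M[j, i] = dtw_distance(model.centroids[i], model.centroids[j])
    ratios = np.full((model.k, model.k), -np.inf)
    for i in range(model.k):
        for j in range(model.k):
            if i == j:
                continue
            if M[i, j] == 0:
                warnings.warn("coincident centroids: Davies-Bouldin is infinite")
                return float("inf")
            ratios[i, j] = (S[i] + S[j]) / M[i, j]
    return float(ratios.max(axis=1).mean())


def select_k(
    trajectories: list[Trajectory],
    k_range,
    seed: int = 0,
    **kmeans_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, ClusterModel]]:
    """Fit temporal k-means for each k and pick the Davies-Bouldin minimizer
    (ties go to the smaller k). Returns (k*, DB curve, fitted models)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    n = len(trajectories)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    models: dict[int, ClusterModel] = {}
    rows = []
    for k in ks:
        model = temporal_kmeans(trajectories, k, seed=seed, **kmeans_kwargs)
        model.db_index = davies_bouldin(trajectories, model)
        models[k] = model
        rows.append({"k": k, "db_index": model.db_index, "inertia": model.inertia})
    curve = pd.DataFrame(rows)
    best_k = int(curve.loc[curve["db_index"].idxmin(), "k"])  # idxmin: first minimum
    return best_k, curve, models


# ---------------------------------------------------------------------------
# archetype naming


ARCHETYPE_ORDER = ("low_stable", "low_declining", "high_lower", "high_upper")


def label_archetypes(
    model: ClusterModel,
    composite: pd.DataFrame,
    higher_is_better: bool = True,
) -> dict[int, str]:
    """Name the k=4 clusters by level and slope of a composite cognitive score.

    ``composite`` needs columns participant_id, age, value, one row per visit,
    oriented so that higher = better (set ``higher_is_better=False`` to flip).
    The two clusters with the lowest mean level form the low pair; within each
    pair the cluster with the more negative mean within-participant slope is
    named "declining" (low pair) or "lower" (high pair).

    For k != 4, generic level-rank names are returned instead.
    """
    df = composite.copy()
    if not higher_is_better:
        df["value"] = -df["value"]
    df = df.merge(model.labels.rename("cluster"), left_on="participant_id",
                  right_index=True, how="inner")

    level = df.groupby("cluster")["value"].mean()

    def _slope(grp: pd.DataFrame) -> float:
        if grp["age"].nunique() < 2:
            return np.nan
        return float(np.polyfit(grp["age"], grp["value"], 1)[0])

    slopes = (
        df.groupby(["cluster", "participant_id"])
        .apply(_slope, include_groups=False)
        .groupby("cluster")
        .mean()
    )

    clusters = sorted(level.index)
    if model.k != 4:
        order = level.sort_values(kind="stable").index
        return {int(c): f"level_rank_{r + 1}_of_{model.k}" for r, c in enumerate(order)}

    if level.nunique() < len(clusters):
        warnings.warn("tied cluster levels; breaking ties by cluster index")
    order = level.sort_values(kind="stable").index.tolist()
    low_pair, high_pair = order[:2], order[2:]

    def _pair_names(pair, declining_name, other_name):
        s = slopes.reindex(pair).fillna(0.0)
        declining = s.idxmin() if s.nunique() > 1 else pair[0]
        other = pair[1] if declining == pair[0] else pair[0]
        return {int(declining): declining_name, int(other): other_name}

    mapping = _pair_names(low_pair, "low_declining", "low_stable")
    mapping.update(_pair_names(high_pair, "high_lower", "high_upper"))
    return mapping
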