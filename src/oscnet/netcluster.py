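"""Cluster-based network identification with permutation statistics.

Condition contrasts (paired t across subjects, or the exact t-based F for
2 x 2 within-subject designs) are computed per bin of a 3-D
(frequency x time x location) or 4-D (frequency x time x location-pair)
space, thresholded at a cluster-forming alpha, cleaned with a neighborhood
filter (a significant bin survives only if at least a given ratio of its
possible neighbors is significant), and grouped into connected clusters.
Two bins are neighbors if they match in all dimensions but one and differ
by one step there: one frequency step, one time step, or spatial adjacency
of the location (3-D) / of exactly one endpoint of the pair (4-D).

Cluster mass is the integral of the t or F values over members; inference
uses a permutation null of the per-resample maximum absolute cluster mass
(condition labels shuffled within subject), so the family-wise error over
the whole multi-dimensional search space is controlled at the nominal
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BinSpace",
    "StatMap",
    "ClusterResult",
    "pair_adjacency",
    "stratify_trials",
    "condition_stat_map",
    "binarize_map",
    "neighborhood_filter",
    "extract_clusters",
    "permutation_test",
    "project_cluster",
]


# ---------------------------------------------------------------------------
# bin space and neighbor relation


def _location_adjacency_matrix(neighbors: dict[int, set[int]], n: int) -> sp.csr_matrix:
    rows, cols = [], []
    for i, nb in neighbors.items():
        for j in nb:
            rows.append(i)
            cols.append(j)
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a.data[:] = 1.0
    return a


def pair_adjacency(pairs: np.ndarray, location_neighbors: dict[int, set[int]]) -> sp.csr_matrix:
    """Adjacency between canonical location pairs.

    Pairs (a, b) and (c, d) are neighbors iff they share one endpoint and
    the other endpoints are spatial neighbors (one single-step move of one
    endpoint).
    """
    pairs = np.asarray(pairs, int)
    index = {(int(a), int(b)): k for k, (a, b) in enumerate(pairs)}
    rows, cols = [], []
    for k, (a, b) in enumerate(pairs):
        a, b = int(a), int(b)
        for a2 in location_neighbors.get(a, ()):  # move endpoint a
            if a2 == b:
                continue
            other = index.get((min(a2, b), max(a2, b)))
            if other is not None:
                rows.append(k)
                cols.append(other)
        for b2 in location_neighbors.get(b, ()):  # move endpoint b
            if b2 == a:
                continue
            other = index.get((min(a, b2), max(a, b2)))
            if other is not None:
                rows.append(k)
                cols.append(other)
    a_mat = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(pairs), len(pairs)))
    a_mat.data[:] = 1.0
    return a_mat


@dataclass
class BinSpace:
    """Flattened (frequency, time, unit) bin space with its adjacency.

    ``unit`` is a source location (power maps, 3-D) or a canonical location
    pair (coupling maps, 4-D).  Bins are flattened C-style as
    ``(f * n_times + t) * n_units + u``.
    """

    n_freqs: int
    n_times: int
    n_units: int
    unit_adjacency: sp.csr_matrix
    pairs: np.ndarray | None = None  # (n_units, 2) when units are pairs
    adjacency: sp.csr_matrix = field(init=False)

    def __post_init__(self):
        def band(n):  # symmetric one-step shift
            return sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1], format="csr") if n > 1 else sp.csr_matrix((n, n))

        i_f, i_t, i_u = (sp.identity(k, format="csr") for k in (self.n_freqs, self.n_times, self.n_units))
        a = (
            sp.kron(band(self.n_freqs), sp.kron(i_t, i_u))
            + sp.kron(i_f, sp.kron(band(self.n_times), i_u))
            + sp.kron(i_f, sp.kron(i_t, self.unit_adjacency))
        )
        self.adjacency = a.tocsr()

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_freqs, self.n_times, self.n_units)

    @property
    def n_bins(self) -> int:
        return self.n_freqs * self.n_times * self.n_units

    @classmethod
    def for_power(cls, n_freqs: int, n_times: int, location_neighbors: dict[int, set[int]]) -> "BinSpace":
        n_loc = len(location_neighbors)
        return cls(n_freqs, n_times, n_loc, _location_adjacency_matrix(location_neighbors, n_loc))

    @classmethod
    def for_coupling(
        cls, n_freqs: int, n_times: int, pairs: np.ndarray, location_neighbors: dict[int, set[int]]
    ) -> "BinSpace":
        return cls(n_freqs, n_times, len(pairs), pair_adjacency(pairs, location_neighbors), pairs=np.asarray(pairs, int))


# ---------------------------------------------------------------------------
# statistics across subjects


@dataclass
class StatMap:
    """Per-bin statistic across subjects with effect signs.

    ``values`` is flat over bins; ``kind`` is "t" or "F"; ``sign`` carries
    the direction of the underlying paired t (for F maps the post-hoc sign).
    """

    values: np.ndarray
    kind: str
    sign: np.ndarray
    df: tuple[int, int]  # (df_num, df_den); df_num = 1 for t maps

    def __post_init__(self):
        self.values = np.asarray(self.values, float).ravel()
        self.sign = np.asarray(self.sign, float).ravel()
        if self.kind not in ("t", "F"):
            raise ValueError("kind must be 't' or 'F'")
        if self.kind == "F" and (self.values < 0).any():
            raise ValueError("F values must be nonnegative")


def stratify_trials(labels, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random per-condition subsample down to the minimum condition count.

    Returns sorted trial indices forming a balanced pool; the identity when
    counts are already equal.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or len(uniq) == 0:
        raise ValueError("every condition needs at least one trial")
    n_min = counts.min()
    keep = []
    for u in uniq:
        idx = np.flatnonzero(labels == u)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0; zero-variance bins give t = 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


_CONTRASTS_2X2 = {
    # cells ordered (A1B1, A1B2, A2B1, A2B2)
    "main_a": np.array([0.5, 0.5, -0.5, -0.5]),
    "main_b": np.array([0.5, -0.5, 0.5, -0.5]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


def condition_stat_map(per_subject_measures: np.ndarray, design: str = "paired") -> StatMap:
    """Across-subject statistic map.

    Parameters
    ----------
    per_subject_measures : (n_subjects, n_cells, n_bins) array
        One value per subject, condition cell and bin (bins may be given in
        any trailing shape; they are flattened).
    design : str
        "paired" (2 cells, paired t); or, for a 2 x 2 within-subject design
        with cells ordered (A1B1, A1B2, A2B1, A2B2): "main_a", "main_b" or
        "interaction" — the F statistic is the square of the paired t on the
        corresponding within-subject contrast, which is exact for 2 x 2
        repeated measures.
    """
    x = np.asarray(per_subject_measures, float)
    if x.ndim < 3:
        raise ValueError("expect (subjects, cells, bins...)")
    n_subj, n_cells = x.shape[:2]
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    x = x.reshape(n_subj, n_cells, -1)
    if design == "paired":
        if n_cells != 2:
            raise ValueError("paired design needs exactly 2 cells")
        t = _paired_t(x[:, 0] - x[:, 1])
        return StatMap(t, "t", np.sign(t), (1, n_subj - 1))
    if design in _CONTRASTS_2X2:
        if n_cells != 4:
            raise ValueError("2x2 design needs exactly 4 cells")
        w = _CONTRASTS_2X2[design]
        t = _paired_t(np.einsum("c,scb->sb", w, x))
        return StatMap(t**2, "F", np.sign(t), (1, n_subj - 1))
    raise ValueError(f"unknown design {design!r}")


def binarize_map(stat_map: StatMap, alpha: float = 0.05, tails: int = 2) -> np.ndarray:
    """Significance mask at the cluster-forming alpha.

    t maps are thresholded on |t| at the two-tailed critical value (or
    one-tailed if ``tails == 1``); F maps one-tailed on F.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    dfn, dfd = stat_map.df
    if dfd < 1:
        raise ValueError("denominator df must be >= 1")
    if stat_map.kind == "t":
        crit = stats.t.ppf(1 - alpha / tails, dfd)
        return np.abs(stat_map.values) > crit
    crit = stats.f.ppf(1 - alpha, dfn, dfd)
    return stat_map.values > crit


def neighborhood_filter(binary_map: np.ndarray, adjacency: sp.csr_matrix, ratio: float = 0.3) -> np.ndarray:
    """Drop significant bins with too few significant neighbors.

    Single pass on the input map: a bin survives iff
    (significant neighbors) / (possible neighbors) >= ratio, with neighbor
    counts taken from the pre-filter map.  Bins with no possible neighbors
    survive vacuously.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    b = np.asarray(binary_map, bool).ravel()
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    sig_nb = adjacency @ b.astype(float)
    ok = (deg == 0) | (sig_nb + 1e-9 >= ratio * deg)
    return b & ok


@dataclass
class ClusterResult:
    """One connected cluster of significant bins."""

    members: np.ndarray  # flat bin indices
    mass: float  # integral of the statistic over members (signed for t)
    sign: int  # +1 / -1
    p: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def _components(active: np.ndarray, adjacency: sp.csr_matrix) -> list[np.ndarray]:
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, lab = connected_components(sub, directed=False)
    return [idx[lab == k] for k in range(n_comp)]


def extract_clusters(
    filtered_map: np.ndarray, stat_map: StatMap, space: BinSpace
) -> list[ClusterResult]:
    """Connected components of the surviving bins, split by effect sign.

    For t maps, positive and negative bins are clustered separately.  For F
    maps, components are found on all surviving bins and then split by the
    post-hoc t sign of their members, so each reported cluster carries a
    consistent effect direction.  Mass is the sum of the statistic over
    members (signed for t maps).
    """
    b = np.asarray(filtered_map, bool).ravel()
    if b.size != space.n_bins:
        raise ValueError("map does not match the bin space")
    out: list[ClusterResult] = []
    if stat_map.kind == "t":
        for s in (1, -1):
            for comp in _components(b & (stat_map.sign == s), space.adjacency):
                out.append(ClusterResult(comp, float(stat_map.values[comp].sum()), s))
    else:
        for comp in _components(b, space.adjacency):
            for s in (1, -1):
                part = comp[stat_map.sign[comp] == s]
                if part.size:
                    out.append(ClusterResult(part, float(stat_map.values[part].sum()), s))
    out.sort(key=lambda c: -abs(c.mass))
    return out


def _max_null_mass(binary: np.ndarray, stat_map: StatMap, space: BinSpace, ratio: float) -> float:
    filt = neighborhood_filter(binary, space.adjacency, ratio)
    clusters = extract_clusters(filt, stat_map, space)
    return max((abs(c.mass) for c in clusters), default=0.0)


def permutation_test(
    per_subject_measures: np.ndarray,
    design: str,
    space: BinSpace,
    alpha: float = 0.05,
    ratio: float = 0.3,
    tails: int = 2,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[ClusterResult]:
    """Cluster-mass permutation test with within-subject label shuffling.

    The full map -> threshold -> neighborhood filter -> cluster chain is
    re-run on every permutation (sign flips per subject for paired designs;
    independent random cell relabeling per subject for 2 x 2 factors).  The
    null distribution collects the per-permutation maximum absolute cluster
    mass pooled over effect signs; each observed cluster gets
    ``p = (1 + #{null >= |mass|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(per_subject_measures, float)
    n_subj, n_cells = x.shape[:2]
    x = x.reshape(n_subj, n_cells, -1)
    n_bins = x.shape[2]
    if n_bins != space.n_bins:
        raise ValueError("measures do not match the bin space")

    observed = condition_stat_map(x, design)
    obs_binary = binarize_map(observed, alpha, tails)
    obs_filt = neighborhood_filter(obs_binary, space.adjacency, ratio)
    clusters = extract_clusters(obs_filt, observed, space)

    dfd = n_subj - 1
    null_max = np.empty(n_perm)
    if design == "paired":
        diffs = x[:, 0] - x[:, 1]
        ssq = (diffs**2).sum(axis=0)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
        means = flips @ diffs / n_subj  # (n_perm, n_bins)
        var = (ssq[None, :] - n_subj * means**2) / (dfd)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = np.where(var > 0, means / np.sqrt(var / n_subj), 0.0)
        crit = stats.t.ppf(1 - alpha / tails, dfd)
        for p_i in range(n_perm):
            t = t_all[p_i]
            sm = StatMap(t, "t", np.sign(t), (1, dfd))
            null_max[p_i] = _max_null_mass(np.abs(t) > crit, sm, space, ratio)
    elif design in _CONTRASTS_2X2:
        w = _CONTRASTS_2X2[design]
        crit = stats.f.ppf(1 - alpha, 1, dfd)
        for p_i in range(n_perm):
            idx = np.array([rng.permutation(n_cells) for _ in range(n_subj)])
            perm_x = np.take_along_axis(x, idx[:, :, None], axis=1)
            t = _paired_t(np.einsum("c,scb->sb", w, perm_x))
            sm = StatMap(t**2, "F", np.sign(t), (1, dfd))
            null_max[p_i] = _max_null_mass(t**2 > crit, sm, space, ratio)
    else:
        raise ValueError(f"unknown design {design!r}")

    for c in clusters:
        c.p = float((1 + np.sum(null_max >= abs(c.mass))) / (n_perm + 1))
    return clusters


def project_cluster(cluster: ClusterResult, stat_map: StatMap, space: BinSpace, mode: str) -> np.ndarray:
    """Integrate a cluster's statistic onto a subspace.

    mode "tf": (n_freqs, n_times) map summing over spatial members; mode
    "space": per-location integral over time, frequency and (for pair
    clusters) the partner location — each pair contributes to both of its
    endpoints, so the space projection sums to twice the tf projection.
    """
    if cluster.size == 0:
        raise ValueError("cluster is empty")
    f_idx, t_idx, u_idx = np.unravel_index(cluster.members, space.shape)
    vals = stat_map.values[cluster.members]
    if mode == "tf":
        out = np.zeros((space.n_freqs, space.n_times))
        np.add.at(out, (f_idx, t_idx), vals)
        return out
    if mode == "space":
        if space.pairs is not None:
            n_loc = int(space.pairs.max()) + 1
            out = np.zeros(n_loc)
            np.add.at(out, space.pairs[u_idx, 0], vals)
            np.add.at(out, space.pairs[u_idx, 1], vals)
        else:
            out = np.zeros(space.n_units)
            np.add.at(out, u_idx, vals)
        return out
    raise ValueError("mode must be 'tf' or 'space'")
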