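"""Improved (M-)Chameleon feature clustering and redundancy removal (stage 2).

Filtered features are clustered agglomeratively on a sparse k-nearest-
neighbour similarity graph.  Edge weights are absolute Pearson
correlations between feature columns, so near-collinear features (e.g.
bilateral limb impedances) sit in dense subgraphs.  Sub-cluster pairs are
scored by

* relative interconnectivity  RI = EC{c1,c2} / ((|EC|_c1 + |EC|_c2)/2)
* relative closeness          RC = S̄EC{c1,c2} /
      (|c1|/(|c1|+|c2|) · S̄EC_c1 + |c2|/(|c1|+|c2|) · S̄EC_c2)

where EC{c1,c2} is the total cross-edge weight, S̄EC{c1,c2} the mean
cross-edge weight, and |EC|_c / S̄EC_c come from the balanced minimum
bisection of cluster c.  The "improvement" over classical Chameleon is
that after every merge *all* current cluster pairs — including clusters
created by earlier merges — are re-scored before the next merge.

Redundancy removal then either prunes, within each final cluster, the
features farthest (Euclidean distance between z-scored vectors) from the
target, or keeps one maximum-HSIC representative per cluster.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dataio import FeatureMatrix
from .hsic import HSICScore

log = logging.getLogger("biafs")

EPS = 1e-12
#: clusters up to this size are bisected by exhaustive enumeration
EXHAUSTIVE_LIMIT = 14
#: random restarts of the local-exchange bisection heuristic
N_RESTARTS = 10


# ---------------------------------------------------------------------------
# similarity and graph construction
# ---------------------------------------------------------------------------

def feature_similarity(fm: FeatureMatrix) -> np.ndarray:
    """Pairwise feature similarity: |Pearson r| across samples.

    Symmetric with unit diagonal.  Constant features get similarity 0 to
    every other feature (with a warning).
    """
    if fm.n_features < 2:
        raise ValueError("need at least 2 features")
    if fm.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = fm.values
    sds = X.std(axis=0)
    constant = sds <= EPS
    if constant.any():
        log.warning("constant feature(s) get zero similarity: %s",
                    [n for n, c in zip(fm.feature_names, constant) if c])
    sim = np.zeros((fm.n_features, fm.n_features))
    ok = ~constant
    if ok.sum() >= 2:
        r = np.corrcoef(X[:, ok], rowvar=False)
        sim[np.ix_(ok, ok)] = np.abs(r)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


@dataclass
class FeatureGraph:
    """Sparse weighted feature graph (k-NN construction)."""

    graph: nx.Graph
    names: tuple[str, ...]
    k_neighbors: int

    def weight(self, u: str, v: str) -> float:
        if self.graph.has_edge(u, v):
            return float(self.graph[u][v]["weight"])
        return 0.0

    def incident_mean(self, v: str) -> float:
        """Mean weight of a vertex's incident edges in the full graph."""
        ws = [d["weight"] for _, _, d in self.graph.edges(v, data=True)]
        return float(np.mean(ws)) if ws else 0.0


def build_knn_graph(sim: np.ndarray, names, k_neighbors: int) -> FeatureGraph:
    """Union-symmetrized k-nearest-neighbour graph from a similarity matrix.

    Edge (u, v) is present iff v is among u's k most similar features or
    vice versa; the edge carries the similarity as its weight.  Ties at
    the k-th neighbour are broken toward the lexicographically smaller
    feature name.
    """
    names = tuple(names)
    m = len(names)
    if not (1 <= k_neighbors < m):
        raise ValueError("k_neighbors must be in 1..m-1")
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(m):
        order = sorted((j for j in range(m) if j != i),
                       key=lambda j: (-sim[i, j], names[j]))
        for j in order[:k_neighbors]:
            g.add_edge(names[i], names[j], weight=float(sim[i, j]))
    return FeatureGraph(graph=g, names=names, k_neighbors=k_neighbors)


# ---------------------------------------------------------------------------
# balanced minimum bisection
# ---------------------------------------------------------------------------

@dataclass
class BisectionResult:
    cut_weight: float       # |EC|_f : total cross-weight of the best split
    mean_cut_weight: float  # S̄EC_f : mean weight over the cut's edges (0 if none)
    part_a: tuple[str, ...]
    part_b: tuple[str, ...]


def _submatrices(vertices: list[str], fg: FeatureGraph):
    s = len(vertices)
    W = np.zeros((s, s))
    for a in range(s):
        for b in range(a + 1, s):
            w = fg.weight(vertices[a], vertices[b])
            if w or fg.graph.has_edge(vertices[a], vertices[b]):
                W[a, b] = W[b, a] = w
    E = np.zeros((s, s), dtype=bool)
    for a in range(s):
        for b in range(a + 1, s):
            if fg.graph.has_edge(vertices[a], vertices[b]):
                E[a, b] = E[b, a] = True
    return W, E


def _exhaustive_bisection(vertices, W, E) -> BisectionResult:
    s = len(vertices)
    n_a = (s + 1) // 2
    idx = list(range(s))
    best = None
    if s % 2 == 0:
        # fix vertex 0 in A to skip complement-symmetric duplicates
        combos = (frozenset((0,) + c) for c in itertools.combinations(idx[1:], n_a - 1))
    else:
        combos = (frozenset(c) for c in itertools.combinations(idx, n_a))
    for a_set in combos:
        a = sorted(a_set)
        b = [i for i in idx if i not in a_set]
        cut = W[np.ix_(a, b)].sum()
        if best is None or cut < best[0] - EPS:
            n_edges = int(E[np.ix_(a, b)].sum())
            best = (cut, a, b, n_edges)
    cut, a, b, n_edges = best
    return BisectionResult(
        cut_weight=float(cut),
        mean_cut_weight=float(cut / n_edges) if n_edges else 0.0,
        part_a=tuple(vertices[i] for i in a),
        part_b=tuple(vertices[i] for i in b),
    )


def _local_bisection(vertices, W, E, rng: np.random.Generator,
                     n_restarts: int = N_RESTARTS) -> BisectionResult:
    """Seeded local-exchange (pairwise swap) refinement heuristic."""
    s = len(vertices)
    n_a = (s + 1) // 2
    best = None
    for _ in range(n_restarts):
        perm = rng.permutation(s)
        a = sorted(perm[:n_a]); b = sorted(perm[n_a:])
        while True:
            Wab = W[np.ix_(a, b)]
            cut = Wab.sum()
            # D_i = external - internal attachment; swap gain = D_i + D_j - 2 W[i,j]
            d_a = Wab.sum(axis=1) - W[np.ix_(a, a)].sum(axis=1)
            d_b = Wab.sum(axis=0) - W[np.ix_(b, b)].sum(axis=1)
            gain = d_a[:, None] + d_b[None, :] - 2.0 * Wab
            gi, gj = np.unravel_index(np.argmax(gain), gain.shape)
            if gain[gi, gj] <= EPS:
                break
            ai, bj = a[gi], b[gj]
            a[gi], b[gj] = bj, ai
            a.sort(); b.sort()
        key = (cut, tuple(a))
        if best is None or key < best[0]:
            best = (key, list(a), list(b))
    (cut, _), a, b = best
    n_edges = int(E[np.ix_(a, b)].sum())
    return BisectionResult(
        cut_weight=float(cut),
        mean_cut_weight=float(cut / n_edges) if n_edges else 0.0,
        part_a=tuple(vertices[i] for i in a),
        part_b=tuple(vertices[i] for i in b),
    )


def balanced_min_bisection(
    cluster,
    fg: FeatureGraph,
    rng: np.random.Generator | None = None,
    method: str = "auto",
) -> BisectionResult:
    """Minimum-weight split of a cluster into halves differing by <= 1.

    ``method="auto"`` uses exhaustive enumeration for clusters up to
    ``EXHAUSTIVE_LIMIT`` vertices and the seeded local-exchange heuristic
    above that; ``"exhaustive"``/``"local"`` force one path (the latter is
    used by tests as a cross-check).  Ties go to the lexicographically
    smallest first part.
    """
    vertices = sorted(cluster)
    if len(vertices) < 2:
        raise ValueError("bisection needs at least 2 vertices")
    W, E = _submatrices(vertices, fg)
    if method == "exhaustive" or (method == "auto" and len(vertices) <= EXHAUSTIVE_LIMIT):
        return _exhaustive_bisection(vertices, W, E)
    if rng is None:
        rng = np.random.default_rng(0)
    return _local_bisection(vertices, W, E, rng)


# ---------------------------------------------------------------------------
# cluster state, RI / RC, merging
# ---------------------------------------------------------------------------

@dataclass
class MergeRecord:
    step: int
    cluster_a: tuple[str, ...]
    cluster_b: tuple[str, ...]
    ri: float
    rc: float
    similarity: float
    h_after: int
    rule: str   # "similarity" | "edge-cut-fallback" | "smallest-fallback"


def _cluster_rng(base_seed: int | None, cluster) -> np.random.Generator:
    """Deterministic per-cluster rng: recomputing a cache reproduces it."""
    key = zlib.crc32("|".join(sorted(cluster)).encode())
    base = 0 if base_seed is None else int(base_seed) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([base, key]))


@dataclass
class ClusterState:
    """A partition of the feature graph with cached edge-cut quantities.

    ``internal[c]`` caches (|EC|_c, S̄EC_c) per cluster; singleton
    clusters, for which a bisection is undefined, fall back to the mean
    weight of the vertex's incident edges in the full graph so RI/RC stay
    finite and singletons remain mergeable.
    """

    fg: FeatureGraph
    clusters: list[tuple[str, ...]]
    seed: int | None = None
    internal: dict[tuple[str, ...], tuple[float, float]] = field(default_factory=dict)
    merge_trace: list[MergeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        covered = [v for c in self.clusters for v in c]
        if sorted(covered) != sorted(self.fg.names):
            raise ValueError("clusters must partition the graph's vertex set")
        self.clusters = [tuple(sorted(c)) for c in self.clusters]
        for c in self.clusters:
            if c not in self.internal:
                self.internal[c] = self._internal_stats(c)

    @property
    def h(self) -> int:
        return len(self.clusters)

    def _internal_stats(self, cluster) -> tuple[float, float]:
        if len(cluster) == 1:
            w = self.fg.incident_mean(cluster[0])
            return (w, w)
        res = balanced_min_bisection(cluster, self.fg,
                                     rng=_cluster_rng(self.seed, cluster))
        return (res.cut_weight, res.mean_cut_weight)

    def recompute_internal(self, cluster) -> tuple[float, float]:
        """From-scratch recomputation (cache-consistency checks)."""
        return self._internal_stats(tuple(sorted(cluster)))

    def connectivity(self, c1, c2) -> tuple[float, int, float]:
        """(EC, edge count, S̄EC) between two clusters."""
        total = 0.0
        count = 0
        s2 = set(c2)
        for u in c1:
            for v, d in self.fg.graph[u].items():
                if v in s2:
                    total += d["weight"]
                    count += 1
        return total, count, (total / count if count else 0.0)


def relative_interconnectivity(c1, c2, state: ClusterState) -> float:
    """RI = EC{c1,c2} / ((|EC|_c1 + |EC|_c2)/2); EC>0 over a zero
    denominator is treated as maximal (EC/eps)."""
    c1 = tuple(sorted(c1)); c2 = tuple(sorted(c2))
    ec, _, _ = state.connectivity(c1, c2)
    if ec <= EPS:
        return 0.0
    denom = 0.5 * (state.internal[c1][0] + state.internal[c2][0])
    if denom <= EPS:
        return ec / EPS
    return ec / denom


def relative_closeness(c1, c2, state: ClusterState) -> float:
    """RC = S̄EC{c1,c2} normalized by the size-weighted mean internal
    bisection edge weights of the two clusters."""
    c1 = tuple(sorted(c1)); c2 = tuple(sorted(c2))
    _, _, sbar = state.connectivity(c1, c2)
    if sbar <= EPS:
        return 0.0
    n1, n2 = len(c1), len(c2)
    denom = (n1 * state.internal[c1][1] + n2 * state.internal[c2][1]) / (n1 + n2)
    if denom <= EPS:
        return sbar / EPS
    return sbar / denom


def pair_similarity(ri: float, rc: float, alpha: float = 1.0) -> float:
    """Merge score S = RI * RC^alpha (classical Chameleon combination);
    monotone nondecreasing in both arguments."""
    if ri < 0 or rc < 0:
        raise ValueError("RI and RC must be nonnegative")
    return float(ri * rc ** alpha)


def initial_partition(fg: FeatureGraph, k_init: int, seed: int | None = None) -> ClusterState:
    """Split the graph into ``k_init`` clusters by recursive balanced
    minimum bisection, always splitting the largest cluster next."""
    m = len(fg.names)
    if not (1 <= k_init <= m):
        raise ValueError("k_init must be in 1..m")
    clusters: list[tuple[str, ...]] = [tuple(sorted(fg.names))]
    while len(clusters) < k_init:
        # largest cluster next; ties toward the lexicographically smallest
        target = sorted(clusters, key=lambda c: (-len(c), c))[0]
        res = balanced_min_bisection(target, fg, rng=_cluster_rng(seed, target))
        clusters.remove(target)
        clusters.extend([tuple(sorted(res.part_a)), tuple(sorted(res.part_b))])
    clusters.sort()
    return ClusterState(fg=fg, clusters=clusters, seed=seed)


def mchameleon_merge(
    state: ClusterState,
    k_target: int,
    alpha: float = 1.0,
    merge_rule: str = "max",
) -> ClusterState:
    """Agglomerate until ``k_target`` clusters remain.

    Every step re-evaluates RI/RC/similarity for *all* current cluster
    pairs (clusters produced by earlier merges included) and merges the
    most similar pair (``merge_rule="min"`` keeps the literal smallest-
    similarity reading for auditability).  If every pairwise similarity is
    zero the pair with the largest raw cross-edge weight EC is merged; if
    all EC are zero too, the two smallest clusters are merged (logged).
    """
    if k_target < 1:
        raise ValueError("k_target must be >= 1")
    if state.h < k_target:
        raise ValueError(f"state has {state.h} clusters < k_target={k_target}")
    if merge_rule not in ("max", "min"):
        raise ValueError("merge_rule must be 'max' or 'min'")

    st = ClusterState(fg=state.fg, clusters=list(state.clusters), seed=state.seed,
                      internal=dict(state.internal), merge_trace=list(state.merge_trace))
    step = len(st.merge_trace)
    while st.h > k_target:
        pairs = []
        for i, j in itertools.combinations(range(st.h), 2):
            c1, c2 = st.clusters[i], st.clusters[j]
            ri = relative_interconnectivity(c1, c2, st)
            rc = relative_closeness(c1, c2, st)
            s = pair_similarity(ri, rc, alpha)
            ec, _, _ = st.connectivity(c1, c2)
            pairs.append((c1, c2, ri, rc, s, ec))

        nonzero = [p for p in pairs if p[4] > EPS]
        if nonzero:
            if merge_rule == "max":
                # deterministic tie-break: highest S, then lexicographically
                # smallest (cluster_a, cluster_b)
                top = max(p[4] for p in nonzero)
                tied = [p for p in nonzero if abs(p[4] - top) <= EPS]
                best = min(tied, key=lambda p: tuple(sorted((p[0], p[1]))))
            else:
                low = min(p[4] for p in nonzero)
                tied = [p for p in nonzero if abs(p[4] - low) <= EPS]
                best = min(tied, key=lambda p: tuple(sorted((p[0], p[1]))))
            rule = "similarity"
        else:
            with_ec = [p for p in pairs if p[5] > EPS]
            if with_ec:
                top = max(p[5] for p in with_ec)
                tied = [p for p in with_ec if abs(p[5] - top) <= EPS]
                best = min(tied, key=lambda p: tuple(sorted((p[0], p[1]))))
                rule = "edge-cut-fallback"
            else:
                ordered = sorted(st.clusters, key=lambda c: (len(c), c))
                best = (ordered[0], ordered[1], 0.0, 0.0, 0.0, 0.0)
                rule = "smallest-fallback"
                log.info("merge fallback: no cross edges anywhere; merging two smallest clusters")

        c1, c2, ri, rc, s, _ = best
        merged = tuple(sorted(c1 + c2))
        st.clusters = [c for c in st.clusters if c not in (c1, c2)] + [merged]
        st.clusters.sort()
        st.internal.pop(c1, None)
        st.internal.pop(c2, None)
        st.internal[merged] = st._internal_stats(merged)
        step += 1
        st.merge_trace.append(MergeRecord(step=step, cluster_a=c1, cluster_b=c2,
                                          ri=ri, rc=rc, similarity=s,
                                          h_after=st.h, rule=rule))
    return st


# ---------------------------------------------------------------------------
# redundancy removal
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd <= EPS:
        return v - v.mean()
    return (v - v.mean()) / sd


def target_distances(state: ClusterState, fm: FeatureMatrix, target: np.ndarray) -> dict[str, float]:
    """Euclidean distance between each z-scored feature and the z-scored
    target (the 'distance to the cluster center BFM')."""
    zt = _zscore(np.asarray(target, dtype=float).ravel())
    return {name: float(np.linalg.norm(_zscore(fm.column(name)) - zt))
            for c in state.clusters for name in c}


def prune_far_from_target(
    state: ClusterState,
    fm: FeatureMatrix,
    target: np.ndarray,
    m_remove: int = 1,
) -> tuple[list[str], dict[str, tuple[int, float]]]:
    """Remove, per cluster, the ``m_remove`` features farthest from the
    target; never empties a cluster (at most size-1 removed).

    Returns the survivors in the feature matrix's original column order
    and a mapping removed-name -> (cluster index, distance).
    """
    if m_remove < 0:
        raise ValueError("m_remove must be >= 0")
    dist = target_distances(state, fm, target)
    removed: dict[str, tuple[int, float]] = {}
    col_index = {n: i for i, n in enumerate(fm.feature_names)}
    for ci, cluster in enumerate(state.clusters):
        r = min(m_remove, len(cluster) - 1)
        if r <= 0:
            continue
        # farthest first; ties keep the earlier column (remove the later one)
        ordered = sorted(cluster, key=lambda n: (-dist[n], -col_index[n]))
        for name in ordered[:r]:
            removed[name] = (ci, dist[name])
    survivors = [n for n in fm.feature_names
                 if n in dist and n not in removed]
    return survivors, removed


def select_representatives(
    state: ClusterState,
    scores: dict[str, HSICScore] | list[HSICScore],
) -> list[str]:
    """One maximum-HSIC feature per cluster (ties broken by rank, stable).

    The result is ordered by ascending rank (descending score).
    """
    if not isinstance(scores, dict):
        scores = {s.feature_name: s for s in scores}
    reps: list[HSICScore] = []
    for cluster in state.clusters:
        missing = [n for n in cluster if n not in scores]
        if missing:
            raise KeyError(f"no HSIC score for clustered feature(s): {missing}")
        best = min((scores[n] for n in cluster), key=lambda s: (-s.score, s.rank))
        reps.append(best)
    reps.sort(key=lambda s: s.rank)
    return [s.feature_name for s in reps]
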