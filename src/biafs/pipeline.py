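"""End-to-end hybrid feature selection: HSIC filter, then M-Chameleon
redundancy removal.

``run_selection`` composes the stages in order: expand the bioimpedance
feature set, z-score it, rank and filter by HSIC permutation confidence
(stage 1, survivors F'), build the |r|-weighted k-NN feature graph,
agglomerate with the improved Chameleon merge to ``k_target`` clusters,
and remove redundant features either by pruning the per-cluster features
farthest from the target (the default, matching the source experiment)
or by keeping one maximum-HSIC representative per cluster.

All randomness (permutation tests, bisection restarts) flows from the
single ``seed`` in :class:`SelectionConfig`; identical config + seed
gives byte-identical results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import chameleon, hsic
from .dataio import FeatureMatrix, SampleTable, expand_features, zscore_normalize
from .hsic import KernelSpec

log = logging.getLogger("biafs")


@dataclass
class SelectionConfig:
    """Configuration for one selection run.

    ``alpha`` is the permutation-confidence level (keep p <= alpha; 0.20
    corresponds to an 80 % confidence filter); setting ``top_k`` switches
    stage 1 to a fixed-size ranking cut instead.  ``k_init`` defaults to
    |F'| (agglomeration from singletons); ``k_target`` is the number of
    final clusters.
    """

    target: str = "BFM"
    include_sex: bool = True
    alpha: float = 0.20
    top_k: int | None = None
    n_perm: int = 999
    k_init: int | None = None
    k_target: int = 4
    k_neighbors: int = 3
    alpha_similarity: float = 1.0
    reduction: str = "prune_farthest"      # "prune_farthest" | "representatives"
    m_remove: int = 1
    merge_rule: str = "max"
    feature_kernel: KernelSpec = field(default_factory=KernelSpec)
    target_kernel: KernelSpec = field(default_factory=KernelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k is None and not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.reduction not in ("prune_farthest", "representatives"):
            raise ValueError(f"unknown reduction mode {self.reduction!r}")
        if self.k_target < 1:
            raise ValueError("k_target must be >= 1")
        if self.k_init is not None and self.k_init < self.k_target:
            raise ValueError("k_init must be >= k_target")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_kernel"] = {"kind": self.feature_kernel.kind,
                               "bandwidth": self.feature_kernel.bandwidth}
        d["target_kernel"] = {"kind": self.target_kernel.kind,
                              "bandwidth": self.target_kernel.bandwidth}
        return d

    @classmethod
    def from_file(cls, path) -> "SelectionConfig":
        """Parse a flat ``key: value`` text config (one pair per line,
        ``#`` comments allowed)."""
        kwargs: dict = {}
        casts = {"alpha": float, "alpha_similarity": float,
                 "top_k": int, "n_perm": int, "k_init": int, "k_target": int,
                 "k_neighbors": int, "m_remove": int, "seed": int,
                 "include_sex": lambda s: s.strip().lower() in ("1", "true", "yes")}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if ":" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, value = (s.strip() for s in line.split(":", 1))
                if key in ("feature_kernel", "target_kernel"):
                    kwargs[key] = KernelSpec(kind=value)
                elif key in casts:
                    kwargs[key] = casts[key](value)
                elif key in ("target", "reduction", "merge_rule"):
                    kwargs[key] = value
                else:
                    raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class SelectionResult:
    """Full provenance of one selection run.

    ``removal_reasons`` maps every removed feature to exactly one of
    ``irrelevant@filter`` or ``redundant@cluster``; the counting identity
    |F| − |X| = (#irrelevant) + (#redundant) always holds.
    """

    feature_names: list[str]                # F, expansion order
    scores: list[hsic.HSICScore]            # ranked, descending
    f_prime: list[str]                      # F', descending score
    selected: list[str]                     # X
    removal_reasons: dict[str, str]
    clusters: list[tuple[str, ...]]
    merge_trace: list[chameleon.MergeRecord]
    distances: dict[str, float]             # z-scored distance to target (clustered features)
    config: dict

    def to_json(self) -> str:
        """Deterministic JSON serialization (byte-identical for identical runs)."""
        payload = {
            "config": self.config,
            "feature_names": self.feature_names,
            "scores": [{"feature_name": s.feature_name, "score": s.score,
                        "p_value": s.p_value, "rank": s.rank} for s in self.scores],
            "f_prime": self.f_prime,
            "selected": self.selected,
            "removal_reasons": dict(sorted(self.removal_reasons.items())),
            "clusters": [list(c) for c in self.clusters],
            "merge_trace": [{"step": r.step, "cluster_a": list(r.cluster_a),
                             "cluster_b": list(r.cluster_b), "ri": r.ri, "rc": r.rc,
                             "similarity": r.similarity, "h_after": r.h_after,
                             "rule": r.rule} for r in self.merge_trace],
            "distances": {k: self.distances[k] for k in sorted(self.distances)},
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def write_outputs(self, prefix) -> list[str]:
        """Write scores, clusters and merge-trace CSVs plus a JSON dump;
        returns the written paths."""
        import pandas as pd

        prefix = str(prefix)
        paths = []
        kept = set(self.f_prime)
        sel = set(self.selected)
        sc = pd.DataFrame({
            "feature_name": [s.feature_name for s in self.scores],
            "hsic": [s.score for s in self.scores],
            "p_value": [s.p_value for s in self.scores],
            "rank": [s.rank for s in self.scores],
            "kept": [s.feature_name in kept for s in self.scores],
        })
        sc.to_csv(prefix + "_scores.csv", index=False); paths.append(prefix + "_scores.csv")
        rows = [{"feature": n, "cluster_id": ci,
                 "distance_to_target": self.distances.get(n, float("nan")),
                 "kept": n in sel}
                for ci, c in enumerate(self.clusters) for n in c]
        pd.DataFrame(rows).to_csv(prefix + "_clusters.csv", index=False)
        paths.append(prefix + "_clusters.csv")
        tr = pd.DataFrame([{"step": r.step, "cluster_a": "|".join(r.cluster_a),
                            "cluster_b": "|".join(r.cluster_b), "ri": r.ri, "rc": r.rc,
                            "similarity": r.similarity, "h_after": r.h_after,
                            "rule": r.rule} for r in self.merge_trace])
        tr.to_csv(prefix + "_merge_trace.csv", index=False)
        paths.append(prefix + "_merge_trace.csv")
        with open(prefix + "_result.json", "w") as fh:
            fh.write(self.to_json())
        paths.append(prefix + "_result.json")
        return paths


def _stage_seeds(seed: int) -> tuple[int, int]:
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0]) & 0x7FFFFFFF, int(state[1]) & 0x7FFFFFFF


def run_selection(table: SampleTable, config: SelectionConfig | None = None) -> SelectionResult:
    """Run the full two-stage selection on a sample table."""
    config = config or SelectionConfig()
    filter_seed, cluster_seed = _stage_seeds(config.seed)
    y = table.target(config.target)

    t0 = time.perf_counter()
    fm = expand_features(table, include_sex=config.include_sex)
    fmz = zscore_normalize(fm)
    log.info("expanded %d features from %d samples", fm.n_features, fm.n_samples)

    filt = hsic.rank_and_filter(
        fmz, y, fspec=config.feature_kernel, cspec=config.target_kernel,
        alpha=config.alpha, top_k=config.top_k, n_perm=config.n_perm,
        seed=filter_seed)
    t1 = time.perf_counter()
    log.info("stage 1 (HSIC filter): %d -> %d features in %.2fs",
             fm.n_features, len(filt.kept), t1 - t0)
    if len(filt.kept) < config.k_target:
        raise ValueError(
            f"only {len(filt.kept)} features survive the filter but "
            f"k_target={config.k_target}; decrease k_target or increase alpha")

    sub = fmz.subset(filt.kept)
    sim = chameleon.feature_similarity(sub)
    k_nn = min(config.k_neighbors, sub.n_features - 1)
    fg = chameleon.build_knn_graph(sim, sub.feature_names, k_nn)
    k_init = config.k_init if config.k_init is not None else len(filt.kept)
    state = chameleon.initial_partition(fg, k_init, seed=cluster_seed)
    state = chameleon.mchameleon_merge(state, config.k_target,
                                       alpha=config.alpha_similarity,
                                       merge_rule=config.merge_rule)
    t2 = time.perf_counter()
    log.info("stage 2 (M-Chameleon): %d clusters after %d merges in %.2fs",
             state.h, len(state.merge_trace), t2 - t1)

    distances = chameleon.target_distances(state, sub, y)
    if config.reduction == "prune_farthest":
        selected, _removed = chameleon.prune_far_from_target(
            state, sub, y, m_remove=config.m_remove)
    else:
        selected = chameleon.select_representatives(state, filt.score_map())

    kept = set(filt.kept)
    sel = set(selected)
    reasons = {}
    for name in fm.feature_names:
        if name not in kept:
            reasons[name] = "irrelevant@filter"
        elif name not in sel:
            reasons[name] = "redundant@cluster"
    log.info("selection: |F|=%d, |F'|=%d, |X|=%d", fm.n_features, len(filt.kept), len(selected))

    return SelectionResult(
        feature_names=list(fm.feature_names),
        scores=filt.scores,
        f_prime=list(filt.kept),
        selected=list(selected),
        removal_reasons=reasons,
        clusters=list(state.clusters),
        merge_trace=list(state.merge_trace),
        distances=distances,
        config=config.to_dict(),
    )
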