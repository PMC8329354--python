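"""Paired condition-label permutation inference on network metrics.

In a crossover design every subject is measured under both conditions, so
under the null hypothesis of no condition effect the two labels of each
subject are exchangeable. Each permutation independently swaps every
subject's pair of rows with probability 1/2 and re-runs the *entire*
pipeline — across-subject correlation, FDR thresholding (the edge threshold
is data-dependent, so it is recomputed inside every permutation; freezing it
would understate the null variance) and the requested graph metrics — for
both permuted conditions, recording the between-condition difference.

p-values use the add-one estimator p = (1 + #{null >= observed})/(P + 1)
for the "greater" side (mirrored for "less"; two-sided doubles the smaller
tail, capped at 1), so a p-value is never exactly zero. Nodal metrics are
corrected across ROIs by Benjamini-Hochberg at rate q.

Reference-network seeds inside permutations are derived deterministically
from (master seed, permutation index), so results are reproducible
bit-for-bit without correlating the null draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import MorphometryError, ThicknessTable
from .metrics import (
    MetricUndefinedError,
    betweenness,
    characteristic_path_length,
    distance_matrix,
    global_efficiency,
    local_efficiency,
    mean_clustering,
    nodal_efficiency,
    small_world,
)
from .network import fdr_network_from_values

__all__ = [
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
    "GlobalPermutationResult",
    "NodalPermutationResult",
    "PermutationReport",
    "permute_conditions",
    "stratified_analysis",
]

GLOBAL_METRIC_NAMES = (
    "clustering",
    "path_length",
    "global_efficiency",
    "local_efficiency",
    "gamma",
    "lambda",
    "sigma",
)
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")

DEFAULT_GLOBAL = ("clustering", "path_length", "global_efficiency", "local_efficiency")
DEFAULT_NODAL = NODAL_METRIC_NAMES

_SMALL_WORLD = {"gamma", "lambda", "sigma"}


def _pipeline_metrics(x, atlas, q, global_sel, nodal_sel, n_random, seed):
    """Run correlation -> FDR threshold -> metrics for one condition sample.

    Returns (globals dict, nodal dict of arrays). Metrics undefined for the
    realized network (e.g. path length of an edgeless graph) come back NaN.
    """
    a = fdr_network_from_values(x, q)
    out: dict[str, float] = {}
    nod: dict[str, np.ndarray] = {}
    need_d = bool(
        {"path_length", "global_efficiency"} & set(global_sel)
    ) or "nodal_efficiency" in nodal_sel
    d = distance_matrix(a) if need_d else None
    if "clustering" in global_sel:
        out["clustering"] = mean_clustering(a)
    if "path_length" in global_sel:
        try:
            out["path_length"] = characteristic_path_length(a, d)
        except MetricUndefinedError:
            out["path_length"] = float("nan")
    if "global_efficiency" in global_sel:
        out["global_efficiency"] = global_efficiency(a, d)
    if "local_efficiency" in global_sel:
        _, out["local_efficiency"] = local_efficiency(a)
    if _SMALL_WORLD & set(global_sel):
        try:
            sw = small_world(a, n_random=n_random, seed=seed)
            vals = {"gamma": sw.gamma, "lambda": sw.lambda_, "sigma": sw.sigma}
        except MetricUndefinedError:
            vals = {"gamma": float("nan"), "lambda": float("nan"), "sigma": float("nan")}
        for name in _SMALL_WORLD & set(global_sel):
            out[name] = vals[name]
    if "degree" in nodal_sel:
        nod["degree"] = a.sum(axis=0).astype(float)
    if "nodal_efficiency" in nodal_sel:
        nod["nodal_efficiency"] = nodal_efficiency(a, d)
    if "betweenness" in nodal_sel:
        nod["betweenness"], _ = betweenness(a)
    return out, nod


def _tail_p(null: np.ndarray, observed: float):
    """Add-one permutation p-values (greater, less, two-sided)."""
    if np.isnan(observed):
        return float("nan"), float("nan"), float("nan")
    valid = null[~np.isnan(null)]
    pe = valid.size
    p_greater = (1.0 + float((valid >= observed).sum())) / (pe + 1.0)
    p_less = (1.0 + float((valid <= observed).sum())) / (pe + 1.0)
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return p_greater, p_less, p_two


@dataclass
class GlobalPermutationResult:
    metric: str
    observed_a: float  # first condition (e.g. restricted)
    observed_b: float  # second condition (e.g. full)
    observed_diff: float  # a - b
    null_diffs: np.ndarray
    p_greater: float
    p_less: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed_a": self.observed_a,
            "observed_b": self.observed_b,
            "observed_diff": self.observed_diff,
            "p_greater": self.p_greater,
            "p_less": self.p_less,
            "p_two_sided": self.p_two_sided,
            "null_diffs": [float(v) for v in self.null_diffs],
        }


@dataclass
class NodalPermutationResult:
    metric: str
    observed_a: np.ndarray
    observed_b: np.ndarray
    observed_diff: np.ndarray
    null_diffs: np.ndarray  # (P, n_roi)
    p_greater: np.ndarray
    p_less: np.ndarray
    p_two_sided: np.ndarray
    q: float
    reject: np.ndarray  # BH decision across ROIs on the two-sided p
    reject_greater: np.ndarray  # BH decision on the "increase" one-sided p
    reject_less: np.ndarray  # BH decision on the "decrease" one-sided p

    def to_dict(self, atlas) -> dict:
        return {
            "metric": self.metric,
            "q": self.q,
            # the (P, n_roi) null array is too bulky for the report; its
            # digest still pins bit-level reproducibility of the nulls
            "null_sha256": hashlib.sha256(
                np.ascontiguousarray(self.null_diffs).tobytes()
            ).hexdigest(),
            "rois": {
                name: {
                    "observed_a": float(self.observed_a[i]),
                    "observed_b": float(self.observed_b[i]),
                    "observed_diff": float(self.observed_diff[i]),
                    "p_greater": float(self.p_greater[i]),
                    "p_less": float(self.p_less[i]),
                    "p_two_sided": float(self.p_two_sided[i]),
                    "significant": bool(self.reject[i]),
                    "significant_increase": bool(self.reject_greater[i]),
                    "significant_decrease": bool(self.reject_less[i]),
                }
                for i, name in enumerate(atlas.names)
            },
        }


@dataclass
class PermutationReport:
    conditions: tuple[str, str]
    n_subjects: int
    n_permutations: int
    q_edges: float
    q_nodal: float
    seed: int
    group: str | None
    global_results: dict = field(default_factory=dict)
    nodal_results: dict = field(default_factory=dict)
    n_random: int = 0
    recompute_threshold: bool = True  # FDR edge threshold re-derived per permutation

    def to_dict(self, atlas) -> dict:
        return {
            "conditions": list(self.conditions),
            "n_subjects": self.n_subjects,
            "n_permutations": self.n_permutations,
            "q_edges": self.q_edges,
            "q_nodal": self.q_nodal,
            "seed": self.seed,
            "group": self.group,
            "n_random": self.n_random,
            "recompute_threshold_per_permutation": self.recompute_threshold,
            "global": {k: v.to_dict() for k, v in self.global_results.items()},
            "nodal": {k: v.to_dict(atlas) for k, v in self.nodal_results.items()},
        }


def permute_conditions(
    table: ThicknessTable,
    n_permutations: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    conditions: tuple[str, str] = ("restricted", "full"),
    group: str | None = None,
    global_sel=DEFAULT_GLOBAL,
    nodal_sel=DEFAULT_NODAL,
    n_random: int = 100,
    q_nodal: float | None = None,
) -> PermutationReport:
    """Paired label-permutation test of condition differences in SCN metrics.

    Differences are reported as ``conditions[0] - conditions[1]`` (by
    default restricted minus full). ``q`` is the BH rate for the edge
    threshold inside the pipeline; ``q_nodal`` (default: same) the BH rate
    across ROIs for nodal metrics. ``n_random`` only matters when a
    small-world ratio is among ``global_sel``.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    unknown = set(global_sel) - set(GLOBAL_METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown global metrics: {sorted(unknown)}")
    unknown = set(nodal_sel) - set(NODAL_METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown nodal metrics: {sorted(unknown)}")
    if q_nodal is None:
        q_nodal = q
    atlas = table.atlas
    subjects, xa, xb = table.paired_values(conditions[0], conditions[1], group)
    n = len(subjects)
    if n < 4:
        raise MorphometryError(f"need >= 4 paired subjects, got {n}")

    def run(x0, x1, ref_seed):
        ga, na = _pipeline_metrics(x0, atlas, q, global_sel, nodal_sel, n_random, ref_seed)
        gb, nb = _pipeline_metrics(x1, atlas, q, global_sel, nodal_sel, n_random, ref_seed + 1)
        return ga, na, gb, nb

    obs_seed = _derived_seed(seed, 0)
    ga, na, gb, nb = run(xa, xb, obs_seed)

    p_count = n_permutations
    null_g = {m: np.empty(p_count) for m in global_sel}
    null_n = {m: np.empty((p_count, atlas.n)) for m in nodal_sel}
    for b in range(1, p_count + 1):
        ss = np.random.SeedSequence((seed, b))
        rng = np.random.default_rng(ss)
        swap = rng.random(n) < 0.5
        x0 = np.where(swap[:, None], xb, xa)
        x1 = np.where(swap[:, None], xa, xb)
        pg, pn, pg2, pn2 = run(x0, x1, _derived_seed(seed, b))
        for m in global_sel:
            null_g[m][b - 1] = pg[m] - pg2[m]
        for m in nodal_sel:
            null_n[m][b - 1] = pn[m] - pn2[m]

    report = PermutationReport(
        conditions=conditions,
        n_subjects=n,
        n_permutations=p_count,
        q_edges=q,
        q_nodal=q_nodal,
        seed=seed,
        group=group,
        n_random=n_random if (_SMALL_WORLD & set(global_sel)) else 0,
    )
    for m in global_sel:
        obs = ga[m] - gb[m]
        p_gr, p_le, p_two = _tail_p(null_g[m], obs)
        report.global_results[m] = GlobalPermutationResult(
            metric=m, observed_a=ga[m], observed_b=gb[m], observed_diff=obs,
            null_diffs=null_g[m], p_greater=p_gr, p_less=p_le, p_two_sided=p_two,
        )
    for m in nodal_sel:
        obs = na[m] - nb[m]
        p_gr = np.empty(atlas.n)
        p_le = np.empty(atlas.n)
        p_two = np.empty(atlas.n)
        for i in range(atlas.n):
            p_gr[i], p_le[i], p_two[i] = _tail_p(null_n[m][:, i], obs[i])
        reject, *_ = multipletests(p_two, alpha=q_nodal, method="fdr_bh")
        rej_gr, *_ = multipletests(p_gr, alpha=q_nodal, method="fdr_bh")
        rej_le, *_ = multipletests(p_le, alpha=q_nodal, method="fdr_bh")
        report.nodal_results[m] = NodalPermutationResult(
            metric=m, observed_a=na[m], observed_b=nb[m], observed_diff=obs,
            null_diffs=null_n[m], p_greater=p_gr, p_less=p_le, p_two_sided=p_two,
            q=q_nodal, reject=reject, reject_greater=rej_gr, reject_less=rej_le,
        )
    return report


def _derived_seed(master: int, index: int) -> int:
    """Deterministic 31-bit reference-network seed from (master, index)."""
    ss = np.random.SeedSequence((int(master), int(index), 0x5C17))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def stratified_analysis(table: ThicknessTable, groups=("young", "old"), **kwargs):
    """Run ``permute_conditions`` separately within each age group."""
    out = {}
    for g in groups:
        sub = table.data[table.data["group"] == g]
        n_subj = sub["subject_id"].nunique()
        if n_subj < 4:
            raise MorphometryError(
                f"group {g!r} has {n_subj} subjects; >= 4 required"
            )
        out[g] = permute_conditions(table, group=g, **kwargs)
    return out
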