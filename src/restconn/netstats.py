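"""Edge-wise paired statistics and cluster-based permutation inference.

The multiple-comparison problem over the 91 unique edges of a 14-node
network is handled non-parametrically: edge-wise paired t-values are
thresholded at the two-sided critical t, supra-threshold edges of equal
sign are grouped into clusters (two edges are adjacent iff they share a
node — the network-based-statistic convention), each cluster is scored
by its *mass* ``t_m = Σ t_i``, and observed masses are referred to the
permutation distribution of the maximum cluster mass under random
within-subject pre/post label swaps. Comparing each cluster's |mass|
against the null of the maximum |mass| over both signs keeps the
familywise error rate at alpha for the two-sided test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .connectivity import ThresholdedMatrix

__all__ = [
    "PairedSample",
    "ClusterResult",
    "PermutationConfig",
    "PermutationTestResult",
    "EffectSizeRecord",
    "edgewise_paired_t",
    "critical_t",
    "form_clusters",
    "permutation_test",
    "cohen_d",
    "effect_size_table",
    "results_table",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """Per-subject pre/post thresholded matrices for one contrast."""

    pre: list[ThresholdedMatrix]
    post: list[ThresholdedMatrix]
    session: str = ""
    band: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        if len(self.pre) != len(self.post):
            raise ValueError(
                f"{len(self.pre)} pre vs {len(self.post)} post matrices: need one "
                "pre and one post per subject"
            )
        labels = self.pre[0].labels
        for m in [*self.pre, *self.post]:
            if m.labels != labels:
                raise ValueError("all matrices in a paired sample must share label order")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.pre[0].labels

    @property
    def n_subjects(self) -> int:
        return len(self.pre)

    def edge_stacks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(pre, post) subject x edge value stacks plus the (i, j) edge index."""
        n = len(self.labels)
        iu, ju = np.triu_indices(n, k=1)
        pre = np.stack([m.values[iu, ju] for m in self.pre])
        post = np.stack([m.values[iu, ju] for m in self.post])
        return pre, post, iu, ju


@dataclass
class ClusterResult:
    """A connected set of supra-threshold edges of one sign."""

    edges: tuple[tuple[str, str], ...]
    sign: int                 # +1 increase, -1 decrease
    mass: float               # sum of member edge t-values (t_m)
    size: int                 # number of member edges (b_n)
    p_value: float | None = None

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)


@dataclass
class PermutationConfig:
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    tail: str = "two-sided"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tail != "two-sided":
            raise ValueError("only the two-sided test is implemented")


@dataclass
class PermutationTestResult:
    clusters_pos: list[ClusterResult]
    clusters_neg: list[ClusterResult]
    null_max_mass: np.ndarray       # max |cluster mass| per permutation, both signs
    t_matrix: np.ndarray
    critical_t: float
    config: PermutationConfig
    n_tested_edges: int
    exhaustive: bool = False

    @property
    def clusters(self) -> list[ClusterResult]:
        return [*self.clusters_pos, *self.clusters_neg]

    def significant(self, alpha: float | None = None) -> list[ClusterResult]:
        a = self.config.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value is not None and c.p_value < a]

    @property
    def min_p(self) -> float:
        ps = [c.p_value for c in self.clusters if c.p_value is not None]
        return min(ps) if ps else 1.0


# ---------------------------------------------------------------------------
# edge-wise statistics

def _paired_t_edges(diff: np.ndarray, warn: bool = False) -> np.ndarray:
    """Paired t per edge from the subject x edge difference stack.

    Zero-variance edges get t = 0: an edge retained by no subject (all
    zeros) carries no evidence either way, and a constant non-zero
    difference has no within-sample error estimate.
    """
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    if warn and zero_var.any():
        logger.warning(
            "%d edge(s) with zero-variance paired differences; t set to 0", int(zero_var.sum())
        )
    t = np.zeros_like(mean)
    nz = ~zero_var
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


def edgewise_paired_t(sample: PairedSample) -> np.ndarray:
    """Symmetric matrix of paired t-values of (post − pre) per edge."""
    if sample.n_subjects < 2:
        raise ValueError(
            f"paired t-test needs >= 2 subjects, got {sample.n_subjects}"
        )
    pre, post, iu, ju = sample.edge_stacks()
    t = _paired_t_edges(post - pre, warn=True)
    n = len(sample.labels)
    mat = np.zeros((n, n))
    mat[iu, ju] = t
    mat[ju, iu] = t
    return mat


def critical_t(alpha: float, n_subjects: int) -> float:
    """Two-sided critical t at the given alpha with n−1 degrees of freedom."""
    return float(stats.t.ppf(1 - alpha / 2, df=n_subjects - 1))


# ---------------------------------------------------------------------------
# clustering

def _clusters_from_edges(
    edge_list: Sequence[tuple[int, int]],
    t_values: Sequence[float],
    labels: Sequence[str],
    sign: int,
) -> list[ClusterResult]:
    """Group edges into connected components (edges adjacent iff they
    share a node) and score each by its summed t."""
    if not edge_list:
        return []
    g = nx.Graph()
    for (i, j), t in zip(edge_list, t_values):
        g.add_edge(i, j, t=t)
    out = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        edges = tuple(
            sorted(tuple(sorted((labels[i], labels[j]))) for i, j in sub.edges)
        )
        mass = float(sum(d["t"] for _, _, d in sub.edges(data=True)))
        out.append(ClusterResult(edges=edges, sign=sign, mass=mass, size=sub.number_of_edges()))
    out.sort(key=lambda c: -abs(c.mass))
    return out


def form_clusters(
    t_matrix: np.ndarray, crit: float, sign: int, labels: Sequence[str] | None = None
) -> list[ClusterResult]:
    """Cluster supra-threshold edges of one sign of a symmetric t matrix.

    An edge enters if ``sign * t > crit``; two supra-threshold edges
    belong to the same cluster iff they are connected through shared
    nodes. An empty result is valid (no supra-threshold edges).
    """
    if not crit > 0:
        raise ValueError(f"critical t must be positive, got {crit}")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    t_matrix = np.asarray(t_matrix, dtype=float)
    n = t_matrix.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    t = t_matrix[iu, ju]
    supra = sign * t > crit
    edge_list = list(zip(iu[supra].tolist(), ju[supra].tolist()))
    return _clusters_from_edges(edge_list, t[supra].tolist(), labels, sign)


def _max_abs_mass(t: np.ndarray, crit: float, iu: np.ndarray, ju: np.ndarray) -> float:
    """Largest |cluster mass| over both signs for one edge t vector."""
    best = 0.0
    for sign in (+1, -1):
        supra = sign * t > crit
        if not supra.any():
            continue
        g = nx.Graph()
        for i, j, tv in zip(iu[supra], ju[supra], t[supra]):
            g.add_edge(int(i), int(j), t=float(tv))
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            mass = abs(sum(d["t"] for _, _, d in sub.edges(data=True)))
            if mass > best:
                best = mass
    return best


# ---------------------------------------------------------------------------
# permutation inference

def _sign_matrix(n_subjects: int, config: PermutationConfig) -> tuple[np.ndarray, bool]:
    """Random ±1 sign-flip matrix, or the exhaustive one when cheaper.

    When 2^n <= n_permutations the full enumeration (excluding the
    identity assignment, which is the observed labelling) is used
    instead of Monte-Carlo draws.
    """
    if n_subjects <= 62 and 2 ** n_subjects <= config.n_permutations:
        signs = np.array(list(product((1.0, -1.0), repeat=n_subjects)))
        signs = signs[1:]  # drop the all-+1 identity
        return signs, True
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([1.0, -1.0], size=(config.n_permutations, n_subjects))
    return signs, False


def permutation_test(sample: PairedSample, config: PermutationConfig) -> PermutationTestResult:
    """Cluster-based permutation test of pre-to-post connectivity change.

    Under the paired null the pre/post labels of each subject are
    exchangeable, so the null is sampled by randomly swapping pre and
    post within subjects — equivalently, flipping the sign of each
    subject's difference vector. Per permutation the edge t-vector,
    its supra-threshold clusters, and the maximum |cluster mass| over
    both signs are computed; each observed cluster's p-value is

        p = (1 + #{null max-mass >= |observed mass|}) / (1 + n_permutations)

    (the +1 correction counts the observed labelling itself and avoids
    zero p-values). Significant iff p < alpha. Deterministic given the
    config seed. The minimum attainable p is 1/(1 + n_permutations);
    with few subjects the exhaustive enumeration bounds it at 2^−n.
    """
    n = sample.n_subjects
    if n < 2:
        raise ValueError(f"permutation test needs >= 2 subjects, got {n}")
    pre, post, iu, ju = sample.edge_stacks()
    diff = post - pre
    tested = np.any((pre != 0) | (post != 0), axis=0)
    crit = critical_t(config.alpha, n)

    t_obs = _paired_t_edges(diff)
    labels = list(sample.labels)
    n_nodes = len(labels)
    t_mat = np.zeros((n_nodes, n_nodes))
    t_mat[iu, ju] = t_obs
    t_mat[ju, iu] = t_obs
    clusters_pos = form_clusters(t_mat, crit, +1, labels)
    clusters_neg = form_clusters(t_mat, crit, -1, labels)

    if 2 ** n <= config.n_permutations:
        logger.warning(
            "n=%d subjects supports only 2^%d distinct sign assignments; "
            "using exhaustive enumeration (minimum attainable p = %.3g)",
            n, n, 1.0 / 2 ** n,
        )
    signs, exhaustive = _sign_matrix(n, config)
    n_perm = signs.shape[0]

    # vectorised permuted t: with d_i -> s_i * d_i the per-edge second
    # moment is unchanged, so t follows from the permuted mean alone
    sum_sq = np.sum(diff ** 2, axis=0)
    mean_p = (signs @ diff) / n                                   # (perm, edge)
    var_p = (sum_sq[None, :] - n * mean_p ** 2) / (n - 1)
    var_p = np.maximum(var_p, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(var_p > 0, mean_p / np.sqrt(var_p / n), 0.0)

    null_max = np.empty(n_perm)
    for k in range(n_perm):
        null_max[k] = _max_abs_mass(t_p[k], crit, iu, ju)

    denom = n_perm + 1
    for c in [*clusters_pos, *clusters_neg]:
        exceed = int(np.sum(null_max >= abs(c.mass)))
        c.p_value = (1 + exceed) / denom

    return PermutationTestResult(
        clusters_pos=clusters_pos,
        clusters_neg=clusters_neg,
        null_max_mass=null_max,
        t_matrix=t_mat,
        critical_t=crit,
        config=config,
        n_tested_edges=int(tested.sum()),
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# effect sizes and reporting

@dataclass
class EffectSizeRecord:
    """Cohen's d for one edge: d = (M1 − M2) / s1.

    M1 is the post-condition mean, M2 the pre-condition mean, and s1 the
    standard deviation of the post-condition values. When s1 = 0 the
    effect size is undefined and rendered as "-" in reports.
    """

    edge: tuple[str, str]
    m1: float
    m2: float
    s1: float
    s2: float
    d: float | None

    @property
    def defined(self) -> bool:
        return self.d is not None


def cohen_d(
    pre_values: np.ndarray, post_values: np.ndarray, edge: tuple[str, str] = ("", "")
) -> EffectSizeRecord:
    """Cohen's effect size of a pre-to-post change on one edge."""
    pre_values = np.asarray(pre_values, dtype=float)
    post_values = np.asarray(post_values, dtype=float)
    if pre_values.shape != post_values.shape:
        raise ValueError("pre and post value vectors must have equal length")
    if pre_values.size < 2:
        raise ValueError("effect size needs >= 2 subjects")
    m1 = float(post_values.mean())
    m2 = float(pre_values.mean())
    s1 = float(post_values.std(ddof=1))
    s2 = float(pre_values.std(ddof=1))
    d = (m1 - m2) / s1 if s1 > 0 else None
    return EffectSizeRecord(edge=edge, m1=m1, m2=m2, s1=s1, s2=s2, d=d)


def effect_size_table(sample: PairedSample, clusters: Sequence[ClusterResult]):
    """Per-edge effect sizes for the given (significant) clusters.

    One row per cluster edge with pre/post mean (SD) and Cohen's d;
    undefined d (zero post-SD) renders as "-".
    """
    import pandas as pd

    pre, post, iu, ju = sample.edge_stacks()
    labels = sample.labels
    index = {
        tuple(sorted((labels[i], labels[j]))): k for k, (i, j) in enumerate(zip(iu, ju))
    }
    rows = []
    for c in clusters:
        for edge in c.edges:
            k = index[tuple(sorted(edge))]
            rec = cohen_d(pre[:, k], post[:, k], edge=edge)
            rows.append(
                {
                    "nodes": f"{edge[0]}–{edge[1]}",
                    "pre_mean": rec.m2,
                    "pre_sd": rec.s2,
                    "post_mean": rec.m1,
                    "post_sd": rec.s1,
                    "cohen_d": rec.d if rec.defined else "-",
                }
            )
    return pd.DataFrame(rows)


def results_table(results: dict[tuple[str, str, str], PermutationTestResult]):
    """Summary table over (metric, band, session) contrasts.

    One row per contrast with positive/negative cluster counts, the
    largest cluster mass per sign and its p-value; absent clusters
    render as "-". ``significant`` marks contrasts with any cluster
    p < alpha.
    """
    import pandas as pd

    rows = []
    for (metric, band, session), res in results.items():
        row: dict = {"metric": metric, "band": band, "session": session}
        for name, clusters in (("pos", res.clusters_pos), ("neg", res.clusters_neg)):
            row[f"{name}_clusters"] = len(clusters)
            if clusters:
                top = max(clusters, key=lambda c: abs(c.mass))
                row[f"{name}_t"] = round(top.mass, 4)
                row[f"{name}_p"] = round(top.p_value, 4) if top.p_value is not None else "-"
            else:
                row[f"{name}_t"] = "-"
                row[f"{name}_p"] = "-"
        row["significant"] = bool(res.significant())
        rows.append(row)
    return pd.DataFrame(rows)
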