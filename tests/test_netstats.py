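"""Edge statistics, clustering, permutation inference and effect sizes."""

import numpy as np
import pytest
from scipy import stats

from restconn import (
    ClusterResult,
    PairedSample,
    PermutationConfig,
    ThresholdedMatrix,
    cohen_d,
    critical_t,
    edgewise_paired_t,
    effect_size_table,
    form_clusters,
    permutation_test,
    results_table,
)


def thresholded(values, labels=None, metric="pli", band="alpha"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if labels is None:
        labels = tuple(chr(65 + i) for i in range(n))
    return ThresholdedMatrix(
        labels=tuple(labels), values=values, mask=values != 0,
        proportion=1.0, metric=metric, band=band,
    )


def sample_from_edges(pre_edges, post_edges, labels):
    """Build a PairedSample from per-subject edge-dicts {(i,j): value}."""
    n = len(labels)

    def mats(edge_dicts):
        out = []
        for d in edge_dicts:
            m = np.zeros((n, n))
            for (i, j), v in d.items():
                m[i, j] = m[j, i] = v
            out.append(thresholded(m, labels))
        return out

    return PairedSample(pre=mats(pre_edges), post=mats(post_edges))


def random_sample(rng, n_subjects, n_nodes, shift=None):
    labels = tuple(chr(65 + i) for i in range(n_nodes))
    iu = np.triu_indices(n_nodes, k=1)

    def mat(vec):
        m = np.zeros((n_nodes, n_nodes))
        m[iu] = vec
        return m + m.T

    pre, post = [], []
    for s in range(n_subjects):
        base = rng.uniform(0, 0.3, len(iu[0]))
        delta = rng.normal(0, 0.05, len(iu[0]))
        if shift is not None:
            delta = delta + shift
        pre.append(thresholded(mat(base), labels))
        post.append(thresholded(mat(np.clip(base + delta, 0, 1)), labels))
    return PairedSample(pre=pre, post=post)


class TestEdgewisePairedT:
    def test_no_change_gives_zero_t(self, rng):
        s = random_sample(rng, 6, 5)
        same = PairedSample(pre=s.pre, post=s.pre)
        t = edgewise_paired_t(same)
        assert np.all(t == 0)

    def test_shifted_edge_is_argmax(self, rng):
        n_nodes, target = 6, (1, 3)
        labels = tuple(chr(65 + i) for i in range(n_nodes))
        pre, post = [], []
        for s in range(24):
            m = rng.uniform(0.05, 0.2, (n_nodes, n_nodes))
            m = np.triu(m, 1)
            m = m + m.T
            pre.append(thresholded(m, labels))
            m2 = m.copy()
            m2[target] = m2[target[::-1]] = m[target] + 0.3 + rng.normal(0, 0.02)
            post.append(thresholded(m2, labels))
        t = edgewise_paired_t(PairedSample(pre=pre, post=post))
        iu = np.triu_indices(n_nodes, k=1)
        k = np.argmax(t[iu])
        assert (iu[0][k], iu[1][k]) == target
        assert t[target] > 0

    def test_textbook_three_subject_case(self):
        """Differences {1, 2, 3} on one edge: t = 2 / (1/sqrt(3)) = 2*sqrt(3)."""
        labels = ("A", "B", "C")
        pre = [{(0, 1): 1.0}, {(0, 1): 1.0}, {(0, 1): 1.0}]
        post = [{(0, 1): 2.0}, {(0, 1): 3.0}, {(0, 1): 4.0}]
        s = sample_from_edges(pre, post, labels)
        t = edgewise_paired_t(s)
        assert t[0, 1] == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert t[1, 0] == t[0, 1]

    def test_agrees_with_scipy_on_varying_edges(self, rng):
        s = random_sample(rng, 10, 5, shift=0.02)
        t = edgewise_paired_t(s)
        pre, post, iu, ju = s.edge_stacks()
        ref = stats.ttest_rel(post, pre, axis=0).statistic
        np.testing.assert_allclose(t[iu, ju], ref, atol=1e-10)

    def test_fewer_than_two_subjects_rejected(self, rng):
        s = random_sample(rng, 3, 4)
        with pytest.raises(ValueError, match="2 subjects"):
            edgewise_paired_t(PairedSample(pre=s.pre[:1], post=s.post[:1]))


class TestFormClusters:
    def t_matrix(self, edges, n=5):
        m = np.zeros((n, n))
        for (i, j), t in edges.items():
            m[i, j] = m[j, i] = t
        return m

    def test_edges_sharing_a_node_join(self):
        m = self.t_matrix({(0, 1): 3.0, (1, 2): 4.0})
        clusters = form_clusters(m, 2.0, +1, labels=list("ABCDE"))
        assert len(clusters) == 1
        assert clusters[0].size == 2
        assert clusters[0].mass == pytest.approx(7.0)
        assert clusters[0].edges == (("A", "B"), ("B", "C"))

    def test_disjoint_edges_stay_separate(self):
        m = self.t_matrix({(0, 1): 3.0, (2, 3): 4.0})
        clusters = form_clusters(m, 2.0, +1, labels=list("ABCDE"))
        assert len(clusters) == 2
        assert all(c.size == 1 for c in clusters)

    def test_bilateral_four_edge_pattern_is_one_cluster(self):
        """ParaH x PCC edges interconnect through shared nodes into a
        single 4-edge cluster."""
        labels = ["L ParaH", "R ParaH", "L PCC", "R PCC"]
        m = self.t_matrix({(0, 2): 3.0, (0, 3): 3.5, (1, 2): 4.0, (1, 3): 2.5}, n=4)
        clusters = form_clusters(m, 2.0, +1, labels=labels)
        assert len(clusters) == 1
        assert clusters[0].size == 4
        assert clusters[0].mass == pytest.approx(13.0)
        assert clusters[0].nodes == set(labels)

    def test_sign_separation(self):
        m = self.t_matrix({(0, 1): 3.0, (1, 2): -3.0})
        pos = form_clusters(m, 2.0, +1)
        neg = form_clusters(m, 2.0, -1)
        assert len(pos) == len(neg) == 1
        assert pos[0].mass > 0 > neg[0].mass

    def test_empty_result_allowed(self):
        assert form_clusters(np.zeros((4, 4)), 2.0, +1) == []


def bruteforce_cluster_p(sample, alpha=0.05):
    """Independent oracle: exhaustive sign-flip enumeration with a
    from-scratch t, BFS clustering and max-|mass| null."""
    pre, post, iu, ju = sample.edge_stacks()
    diff = post - pre
    n = diff.shape[0]
    crit = stats.t.ppf(1 - alpha / 2, df=n - 1)

    def t_vec(d):
        out = np.zeros(d.shape[1])
        for e in range(d.shape[1]):
            sd = d[:, e].std(ddof=1)
            if sd > 0:
                out[e] = d[:, e].mean() / (sd / np.sqrt(n))
        return out

    def clusters(t):
        found = []
        for sign in (1, -1):
            supra = [k for k in range(len(t)) if sign * t[k] > crit]
            unvisited = set(supra)
            while unvisited:
                stack = [unvisited.pop()]
                comp = {stack[0]}
                while stack:
                    k = stack.pop()
                    nodes = {iu[k], ju[k]}
                    for other in list(unvisited):
                        if {iu[other], ju[other]} & nodes:
                            unvisited.remove(other)
                            comp.add(other)
                            stack.append(other)
                found.append((sign, sum(t[k] for k in comp), frozenset(comp)))
        return found

    obs = clusters(t_vec(diff))
    null_max = []
    for bits in range(2 ** n):
        signs = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(n)])
        cl = clusters(t_vec(signs[:, None] * diff))
        null_max.append(max((abs(m) for _, m, _ in cl), default=0.0))
    null_max = np.array(null_max)
    return {
        edges: np.mean(null_max >= abs(mass))
        for _, mass, edges in obs
    }


class TestPermutationTest:
    def test_matches_exhaustive_oracle_at_n5(self, rng):
        """Permutation p-values agree with from-scratch exhaustive
        enumeration over all 2^5 sign flips."""
        sample = random_sample(rng, 5, 5, shift=0.06)
        cfg = PermutationConfig(n_permutations=2000, alpha=0.05, seed=0)
        res = permutation_test(sample, cfg)
        assert res.exhaustive  # 2^5 <= 2000: the package enumerates too
        oracle = bruteforce_cluster_p(sample)
        assert res.clusters, "shifted sample should produce clusters"
        pre, post, iu, ju = sample.edge_stacks()
        label_to_idx = {lb: k for k, lb in enumerate(sample.labels)}
        for c in res.clusters:
            edge_keys = frozenset(
                next(
                    k for k in range(len(iu))
                    if {iu[k], ju[k]} == {label_to_idx[a], label_to_idx[b]}
                )
                for a, b in c.edges
            )
            p_oracle = oracle[edge_keys]
            # package p = (1 + exceedances over 31 non-identity flips)/32;
            # the identity flip always exceeds (its max |mass| covers every
            # observed cluster), so the oracle's count over all 32 equals
            # the package numerator and agreement is exact
            assert c.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_monte_carlo_close_to_exhaustive(self, rng):
        """Forcing Monte-Carlo sampling reproduces exhaustive p within
        3 Monte-Carlo standard errors."""
        sample = random_sample(rng, 12, 4, shift=0.04)
        exact = permutation_test(sample, PermutationConfig(n_permutations=4096, seed=0))
        assert exact.exhaustive
        mc = permutation_test(sample, PermutationConfig(n_permutations=1500, seed=42))
        assert not mc.exhaustive
        for c_mc in mc.clusters:
            match = [c for c in exact.clusters if c.edges == c_mc.edges]
            assert match
            p = match[0].p_value
            se = np.sqrt(p * (1 - p) / 1500)
            assert abs(c_mc.p_value - p) <= 3 * se + 2 / 1500

    def test_deterministic_given_seed(self, rng):
        sample = random_sample(rng, 15, 5, shift=0.03)
        cfg = PermutationConfig(n_permutations=500, seed=7)
        a = permutation_test(sample, cfg)
        b = permutation_test(sample, cfg)
        assert [c.p_value for c in a.clusters] == [c.p_value for c in b.clusters]
        np.testing.assert_array_equal(a.null_max_mass, b.null_max_mass)

    def test_label_permutation_equivariance(self, rng):
        sample = random_sample(rng, 10, 5, shift=0.05)
        perm = [2, 0, 4, 1, 3]
        labels = sample.labels
        new_labels = tuple(labels[p] for p in perm)

        def permute(tm):
            inv = np.argsort(perm)
            vals = tm.values[np.ix_(perm, perm)]
            return ThresholdedMatrix(
                labels=new_labels, values=vals, mask=vals != 0,
                proportion=tm.proportion, metric=tm.metric, band=tm.band,
            )

        permuted = PairedSample(
            pre=[permute(m) for m in sample.pre], post=[permute(m) for m in sample.post]
        )
        cfg = PermutationConfig(n_permutations=300, seed=3)
        a = permutation_test(sample, cfg)
        b = permutation_test(permuted, cfg)
        assert {frozenset(c.edges) for c in a.clusters} == {frozenset(c.edges) for c in b.clusters}
        assert sorted(c.p_value for c in a.clusters) == sorted(c.p_value for c in b.clusters)

    def test_minimum_p_is_bounded_by_permutation_count(self, rng):
        sample = random_sample(rng, 20, 4, shift=0.2)
        cfg = PermutationConfig(n_permutations=99, seed=0)
        res = permutation_test(sample, cfg)
        assert res.clusters
        assert min(c.p_value for c in res.clusters) >= 1 / 100


class TestCohenD:
    def test_zero_sd_is_undefined(self):
        rec = cohen_d(np.zeros(5), np.zeros(5))
        assert rec.d is None and not rec.defined

    def test_unit_case(self, rng):
        pre = np.array([-1.0, 0.0, 1.0])          # mean 0
        post = np.array([0.0, 1.0, 2.0])          # mean 1, sd 1
        rec = cohen_d(pre, post)
        assert rec.d == pytest.approx(1.0)
        assert rec.m1 == pytest.approx(1.0) and rec.m2 == pytest.approx(0.0)

    def test_pre_all_zero_edge_renders_dash_when_post_constant(self):
        labels = ("A", "B", "C")
        pre = [{(0, 1): 0.0}] * 4
        post = [{(0, 1): 0.5}] * 4  # constant post -> s1 = 0 -> "-"
        s = sample_from_edges(pre, post, labels)
        cluster = ClusterResult(edges=(("A", "B"),), sign=1, mass=5.0, size=1, p_value=0.01)
        table = effect_size_table(s, [cluster])
        assert table.loc[0, "cohen_d"] == "-"


class TestResultsTable:
    def test_layout_and_dashes(self, rng):
        null = random_sample(rng, 8, 5)
        effect = random_sample(rng, 8, 5, shift=0.15)
        cfg = PermutationConfig(n_permutations=200, seed=1)
        results = {
            ("pli", "alpha", "Ctrl"): permutation_test(null, cfg),
            ("pli", "alpha", "SM"): permutation_test(effect, cfg),
        }
        df = results_table(results)
        assert list(df.columns) == [
            "metric", "band", "session", "pos_clusters", "pos_t", "pos_p",
            "neg_clusters", "neg_t", "neg_p", "significant",
        ]
        sm = df[df.session == "SM"].iloc[0]
        assert sm.pos_clusters >= 1
        for row in df.itertuples():
            if row.pos_clusters == 0:
                assert row.pos_t == "-" and row.pos_p == "-"


class TestMonotonicity:
    def test_cluster_mass_grows_with_coupling_strength(self):
        """Median detected cluster mass is non-decreasing over a
        3-point planted-strength sweep."""
        from restconn.experiments import strength_sweep

        sweep = strength_sweep(strengths=(0.1, 0.3, 0.6), n_runs=3, n_subjects=8,
                               n_permutations=100, base_seed=21)
        masses = [sweep[s] for s in (0.1, 0.3, 0.6)]
        assert masses[0] <= masses[1] <= masses[2]
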