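import numpy as np
import pytest

import fetoconn as fc
from fetoconn.io import node_distances
from fetoconn.templates import (
    DistanceDistribution,
    KernelParams,
    TemplateLossConfig,
    TemplateSet,
    consensus_threshold_template,
    distance_preserved_template,
    distance_weight_histogram,
    fit_templates,
    gaussian_kernel,
    graph_edit_distance,
    histogram_bin_edges,
    init_templates,
    js_divergence,
    template_losses,
)

from conftest import random_connectome


LN2 = np.log(2.0)


class TestGaussianKernel:
    @pytest.mark.parametrize(
        "t1, t2, expected",
        [(28, 28, 1.0), (28, 29, np.exp(-0.5)), (28, 30, np.exp(-2.0))],
    )
    def test_closed_form_values(self, t1, t2, expected):
        assert gaussian_kernel(t1, t2) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a, b = rng.uniform(20, 40, size=2)
            v = gaussian_kernel(a, b, KernelParams(sigma=1.5))
            assert v == gaussian_kernel(b, a, KernelParams(sigma=1.5))
            assert 0 < v <= 1


class TestGraphEditDistance:
    def test_identical_connectomes(self, rng):
        c = random_connectome(rng, d=6, connected=False)
        assert graph_edit_distance(c, c) == 0.0

    def test_three_node_hand_example(self):
        def conn(upper):
            w = np.zeros((3, 3))
            w[np.triu_indices(3, 1)] = upper
            return fc.Connectome(w + w.T, list("abc"))

        assert graph_edit_distance(conn([2, 0, 1]), conn([5, 1, 1])) == 4.0

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = random_connectome(rng, d=5, connected=False)
            b = random_connectome(rng, d=5, connected=False)
            b = fc.Connectome(b.weights, a.node_ids)
            c = random_connectome(rng, d=5, connected=False)
            c = fc.Connectome(c.weights, a.node_ids)
            ab, ba = graph_edit_distance(a, b), graph_edit_distance(b, a)
            assert ab == ba >= 0
            assert graph_edit_distance(a, c) <= ab + graph_edit_distance(b, c) + 1e-12

    def test_node_mismatch_rejected(self, rng):
        a = random_connectome(rng, d=4, connected=False)
        b = fc.Connectome(a.weights, list("wxyz"))
        with pytest.raises(ValueError, match="node sets differ"):
            graph_edit_distance(a, b)


class TestDistanceHistogram:
    def test_single_edge_has_unit_mass(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 2.5
        c = fc.Connectome(w, list("abc"))
        D = np.array([[0, 4.0, 9.0], [4.0, 0, 5.0], [9.0, 5.0, 0]])
        edges = np.linspace(0, 10, 6)
        dist = distance_weight_histogram(c, D, edges)
        assert dist.mass.sum() == pytest.approx(1.0)

    def test_two_equal_edges_in_far_bins_split_mass(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        c = fc.Connectome(w, list("abcd"))
        D = np.full((4, 4), 5.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.5   # below the first bin center -> clamped
        D[2, 3] = D[3, 2] = 9.9   # above the last bin center -> clamped
        edges = np.linspace(0, 10, 11)
        dist = distance_weight_histogram(c, D, edges)
        assert dist.mass[0] == pytest.approx(0.5)
        assert dist.mass[-1] == pytest.approx(0.5)
        assert dist.mass[1:-1].sum() == pytest.approx(0.0)

    def test_soft_binning_matches_hard_at_bin_centers(self, rng):
        c = random_connectome(rng, d=8, connected=False)
        edges = np.linspace(0, 8, 9)
        centers = 0.5 * (edges[:-1] + edges[1:])
        D = np.zeros((8, 8))
        iu = np.triu_indices(8, 1)
        D[iu] = rng.choice(centers, size=iu[0].size)
        D = D + D.T
        soft = distance_weight_histogram(c, D, edges)
        hard = distance_weight_histogram(c, D, edges, hard=True)
        np.testing.assert_allclose(soft.mass, hard.mass, atol=1e-12)

    def test_all_zero_connectome_rejected(self):
        c = fc.Connectome(np.zeros((3, 3)), list("abc"))
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="no mass"):
            distance_weight_histogram(c, D, np.linspace(0, 2, 5))


class TestJSDivergence:
    def _dist(self, mass):
        mass = np.asarray(mass, float)
        return DistanceDistribution(np.arange(len(mass) + 1, dtype=float), mass)

    def test_identical_distributions_are_zero(self):
        p = self._dist([0.2, 0.3, 0.5])
        assert js_divergence(p, p) == 0.0

    def test_disjoint_supports_hit_upper_bound(self):
        p = self._dist([1.0, 0.0])
        q = self._dist([0.0, 1.0])
        assert js_divergence(p, q) == pytest.approx(2 * LN2, abs=1e-12)

    def test_hand_computed_value(self):
        # DKL(p||m) + DKL(q||m) with p=(1,0), q=(.5,.5): 1.5 ln(4/3)
        p = self._dist([1.0, 0.0])
        q = self._dist([0.5, 0.5])
        assert js_divergence(p, q) == pytest.approx(1.5 * np.log(4 / 3), abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(30):
            a = rng.dirichlet(np.ones(10))
            b = rng.dirichlet(np.ones(10))
            p, q = self._dist(a), self._dist(b)
            v = js_divergence(p, q)
            assert v == pytest.approx(js_divergence(q, p), abs=1e-14)
            assert -1e-12 <= v <= 2 * LN2 + 1e-12

    def test_bin_edge_mismatch_rejected(self):
        p = self._dist([0.5, 0.5])
        q = DistanceDistribution(np.array([0.0, 2.0, 4.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="bin edges differ"):
            js_divergence(p, q)


class TestTemplateLosses:
    def test_trivial_identities(self, default_study):
        _, cohort, _ = default_study
        subj = cohort.subjects[30]
        week = round(subj.age_weeks)
        single = fc.Cohort([subj], node_table=cohort.node_table)
        ts = TemplateSet([week], [fc.Connectome(subj.weights, subj.node_ids)])
        D = node_distances(cohort.node_table)
        l_repr, l_cons, l_dist = template_losses(ts, single, D)
        assert l_repr == 0.0
        assert l_cons == 0.0
        assert l_dist == pytest.approx(0.0, abs=1e-12)

    def test_identical_templates_zero_consistency(self, default_study):
        _, cohort, _ = default_study
        c0 = cohort.subjects[0]
        ts = TemplateSet(
            [25, 26, 27],
            [fc.Connectome(c0.weights, c0.node_ids) for _ in range(3)],
        )
        D = node_distances(cohort.node_table)
        _, l_cons, _ = template_losses(ts, cohort, D)
        assert l_cons == 0.0

    def test_one_week_gap_weights_ged_by_kernel(self, default_study):
        _, cohort, _ = default_study
        subj = cohort.subjects[5]
        other = cohort.subjects[40]
        subj_at_int = fc.Connectome(
            subj.weights, subj.node_ids, age_weeks=28.0, subject_id="x"
        )
        single = fc.Cohort([subj_at_int], node_table=cohort.node_table)
        tmpl = fc.Connectome(other.weights, other.node_ids)
        ts = TemplateSet([29], [tmpl])
        D = node_distances(cohort.node_table)
        l_repr, _, _ = template_losses(ts, single, D)
        g = graph_edit_distance(subj_at_int, tmpl)
        assert l_repr == pytest.approx(np.exp(-0.5) * g, rel=1e-12)


class TestInitTemplates:
    def _cohort_at_ages(self, ages, base, node_table, scale=None):
        subs = []
        for i, a in enumerate(ages):
            w = base.copy() * (1.0 if scale is None else scale[i])
            subs.append(fc.Connectome(w, node_table.node_ids, age_weeks=a,
                                      subject_id=f"s{i}"))
        return fc.Cohort(subs, node_table=node_table)

    def test_exact_age_match_copies_subject(self):
        nt = fc.make_node_table(d=6, seed=0)
        base = np.ones((6, 6)) - np.eye(6)
        cohort = self._cohort_at_ages([30.0, 33.0], base, nt)
        ts = init_templates(cohort, [30])
        np.testing.assert_allclose(ts.templates[0].weights, base - np.diag(np.diag(base)))

    def test_window_mean_of_two_subjects(self):
        nt = fc.make_node_table(d=6, seed=0)
        base = np.ones((6, 6)) - np.eye(6)
        cohort = self._cohort_at_ages([29.6, 30.4], base, nt, scale=[2.0, 4.0])
        ts = init_templates(cohort, [30])
        np.testing.assert_allclose(ts.templates[0].weights, 3.0 * base)

    def test_half_open_window_assigns_boundary_up(self):
        nt = fc.make_node_table(d=6, seed=0)
        base = np.ones((6, 6)) - np.eye(6)
        cohort = self._cohort_at_ages([30.5, 29.9], base, nt, scale=[5.0, 1.0])
        ts = init_templates(cohort, [30, 31])
        # 30.5 falls in [30.5, 31.5) -> week 31, not week 30
        np.testing.assert_allclose(ts.templates[0].weights, 1.0 * base)
        np.testing.assert_allclose(ts.templates[1].weights, 5.0 * base)

    def test_empty_week_widens_window(self):
        nt = fc.make_node_table(d=6, seed=0)
        base = np.ones((6, 6)) - np.eye(6)
        cohort = self._cohort_at_ages([24.0, 26.0], base, nt, scale=[1.0, 3.0])
        ts = init_templates(cohort, [30])
        # nearest subjects reached by widening: only the 26-week subject
        np.testing.assert_allclose(ts.templates[0].weights, 3.0 * base)


class TestFitTemplates:
    def test_zero_learning_rate_is_identity(self, default_study):
        _, cohort, _ = default_study
        D = node_distances(cohort.node_table)
        weeks = list(range(22, 38))
        init = init_templates(cohort, weeks)
        out = fit_templates(
            cohort, weeks, D,
            cfg=TemplateLossConfig(learning_rate=0.0, n_epochs=2),
        )
        for a, b in zip(init.templates, out.templates):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_loss_decreases_and_templates_stay_valid(self, fitted_templates):
        tr = fitted_templates.loss_trace
        tot = tr["total"].to_numpy()
        assert tot[-1] < tot[0]
        assert np.diff(tot).max() <= 1e-6 * tot[0]
        for _, t in fitted_templates:
            assert (t.weights >= 0).all()
            np.testing.assert_allclose(t.weights, t.weights.T)
            assert np.diagonal(t.weights).max() == 0.0

    def test_pure_representation_pulls_templates_to_subjects(self):
        # one subject per integer week, lambda_cons = lambda_dist = 0:
        # each template's loss term is driven toward its own-week subject
        nt = fc.make_node_table(d=8, seed=3)
        rng = np.random.default_rng(0)
        subs = []
        for i, a in enumerate(range(25, 30)):
            w = np.zeros((8, 8))
            iu = np.triu_indices(8, 1)
            w[iu] = rng.uniform(0.5, 2.0, iu[0].size)
            subs.append(fc.Connectome(w + w.T, nt.node_ids,
                                      age_weeks=float(a), subject_id=f"s{i}"))
        cohort = fc.Cohort(subs, node_table=nt)
        D = node_distances(nt)
        weeks = list(range(25, 30))
        cfg = TemplateLossConfig(lambda_cons=0, lambda_dist=0, n_epochs=50, seed=1)
        out = fit_templates(cohort, weeks, D, cfg=cfg)
        tr = out.loss_trace
        assert tr["L_repr"].iloc[-1] < tr["L_repr"].iloc[0]

    def test_seeded_runs_are_bit_identical(self, default_study):
        _, cohort, _ = default_study
        D = node_distances(cohort.node_table)
        weeks = list(range(22, 38))
        cfg = TemplateLossConfig(seed=13, n_epochs=3)
        a = fit_templates(cohort, weeks, D, cfg=cfg)
        b = fit_templates(cohort, weeks, D, cfg=cfg)
        for ta, tb in zip(a.templates, b.templates):
            np.testing.assert_array_equal(ta.weights, tb.weights)

    def test_divergence_raises_with_advice(self, default_study):
        _, cohort, _ = default_study
        D = node_distances(cohort.node_table)
        with pytest.raises(RuntimeError, match="learning rate"):
            fit_templates(
                cohort, list(range(22, 38)), D,
                cfg=TemplateLossConfig(learning_rate=50.0, n_epochs=30),
            )

    def test_recovery_beats_initialization(self, default_study, fitted_templates):
        _, cohort, truth = default_study
        init = init_templates(cohort, list(range(22, 38)))
        ged_init = np.mean([
            graph_edit_distance(a, b)
            for a, b in zip(init.templates, truth.templates)
        ])
        ged_fit = np.mean([
            graph_edit_distance(a, b)
            for a, b in zip(fitted_templates.templates, truth.templates)
        ])
        assert ged_fit <= ged_init


class TestBaselineAggregators:
    def test_identical_subjects_reproduce_subject(self, rng):
        c = random_connectome(rng, d=8, connected=False)
        group = [fc.Connectome(c.weights, c.node_ids) for _ in range(4)]
        out = consensus_threshold_template(group)
        np.testing.assert_allclose(out.weights, c.weights)
        nt = fc.make_node_table(d=8, seed=1)
        c2 = fc.Connectome(c.weights, nt.node_ids)
        group2 = [fc.Connectome(c2.weights, nt.node_ids) for _ in range(4)]
        out2 = distance_preserved_template(group2, node_distances(nt))
        np.testing.assert_allclose(out2.weights, c2.weights)

    def test_dense_equal_weight_group_keeps_all_edges(self):
        w = 2.0 * (np.ones((6, 6)) - np.eye(6))
        group = [fc.Connectome(w, [f"n{i}" for i in range(6)]) for _ in range(3)]
        out = consensus_threshold_template(group)
        assert (out.upper_triangle() > 0).all()

    def test_consensus_density_matches_group_mean(self, rng):
        group = [random_connectome(rng, d=10, density=0.5, connected=False)
                 for _ in range(5)]
        ids = group[0].node_ids
        group = [fc.Connectome(g.weights, ids) for g in group]
        out = consensus_threshold_template(group)
        target = np.mean([(g.upper_triangle() > 0).mean() for g in group])
        achieved = (out.upper_triangle() > 0).mean()
        n_pairs = 10 * 9 / 2
        assert abs(achieved - target) <= 1.0 / n_pairs

    def test_distance_preserved_retains_long_range_slots(self):
        # two-bin construction: all subjects share the short edge; long edges
        # each appear in half the subjects.  Global consensus would drop the
        # long-range edges; per-bin thresholding must keep ~half the slots.
        nt = fc.make_node_table(d=6, seed=2)
        D = node_distances(nt)
        iu = np.triu_indices(6, 1)
        order = np.argsort(D[iu])
        short_pair = order[0]
        long_pairs = order[-4:]
        subs = []
        for s in range(4):
            flat = np.zeros(iu[0].size)
            flat[short_pair] = 1.0
            for li, lp in enumerate(long_pairs):
                if (s + li) % 2 == 0:
                    flat[lp] = 1.0
            w = np.zeros((6, 6))
            w[iu] = flat
            subs.append(fc.Connectome(w + w.T, nt.node_ids))
        out = distance_preserved_template(subs, D, n_bins=2)
        flat_out = out.upper_triangle()
        assert flat_out[short_pair] > 0
        n_long_kept = sum(flat_out[lp] > 0 for lp in long_pairs)
        assert n_long_kept == 2  # rounded mean per-bin count = 2 of 4

    def test_per_bin_counts_match_counting_oracle(self, default_study):
        _, cohort, _ = default_study
        D = node_distances(cohort.node_table)
        group = cohort.subjects[:8]
        n_bins = 5
        out = distance_preserved_template(group, D, n_bins=n_bins)
        iu = np.triu_indices(cohort.n_nodes, 1)
        edges = histogram_bin_edges(D, n_bins)
        bins = np.clip(np.digitize(D[iu], edges) - 1, 0, n_bins - 1)
        flat_out = out.upper_triangle()
        for b in range(n_bins):
            members = bins == b
            if not members.any():
                continue
            per_subj = [int(((g.upper_triangle() > 0) & members).sum()) for g in group]
            assert (flat_out[members] > 0).sum() == round(np.mean(per_subj))


class TestModelInterface:
    def test_fit_summary_and_losses(self, default_study):
        _, cohort, _ = default_study
        model = fc.ConnectomeTemplateModel(cohort, weeks=range(22, 38))
        res = model.fit(method="weekly_mean")
        text = res.summary()
        assert "weekly_mean" in text and "L_repr" in text
        l_repr, l_cons, l_dist = res.losses()
        assert l_repr > 0 and l_cons >= 0 and l_dist >= 0

    def test_unknown_method_rejected(self, default_study):
        _, cohort, _ = default_study
        model = fc.ConnectomeTemplateModel(cohort)
        with pytest.raises(ValueError, match="unknown method"):
            model.fit(method="magic")

    def test_baseline_methods_produce_valid_template_sets(self, default_study):
        _, cohort, _ = default_study
        model = fc.ConnectomeTemplateModel(cohort, weeks=range(24, 28))
        for method in ("consensus", "distance_preserved"):
            ts = model.fit(method=method).templates
            assert len(ts) == 4
            for _, t in ts:
                assert (t.weights >= 0).all()
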