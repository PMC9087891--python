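"""Relabeling algorithms: initialization, distances, ML fits, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from mscipost import (
    BetaGammaRelabeler,
    CoGRelabeler,
    beta_gamma_loglik,
    beta_gamma_relabel,
    cog_relabel,
    detect_bdi_events,
    double_bdi_mappings,
    fit_beta_ml,
    fit_gamma_ml,
    init_labels,
    relabel_accuracy,
    relabel_all,
    single_bdi_mapping,
)
from mscipost.relabel import BetaGammaFit, distance
from mscipost.simulate import (
    double_bdi_tower_spec,
    simulate_label_switching_samples,
    single_bdi_tower_spec,
)
from mscipost.towers import apply_mapping, identity_mapping

from model_specs import well_separated_2tower_spec


@pytest.fixture(scope="module")
def maps2(single_event):
    return [identity_mapping(), single_bdi_mapping(single_event)]


@pytest.fixture(scope="module")
def maps4(fig6a_model):
    lo, up = detect_bdi_events(fig6a_model)
    return double_bdi_mappings(lo, up)


def random_table(rng, n=200, double=False):
    cols = {"phi_X": rng.random(n), "phi_Y": rng.random(n),
            "theta_X": rng.gamma(2.0, 0.01, n), "theta_Y": rng.gamma(2.0, 0.01, n)}
    if double:
        cols |= {"phi_Z": rng.random(n), "phi_W": rng.random(n),
                 "theta_Z": rng.gamma(2.0, 0.01, n), "theta_W": rng.gamma(2.0, 0.01, n)}
    return pd.DataFrame(cols)


class TestInitLabels:
    def test_sum_rule(self, maps2):
        table = pd.DataFrame({
            "phi_X": [0.35, 0.65, 0.5], "phi_Y": [0.10, 0.90, 0.5],
            "theta_X": [0.01] * 3, "theta_Y": [0.01] * 3})
        z = init_labels(table, maps2)
        # (0.35, 0.10) -> 0; (0.65, 0.90) -> 1; boundary (0.5, 0.5) -> 1
        assert list(z) == [0, 1, 1]

    def test_double_bdi_prefers_small_phis(self, maps4):
        table = pd.DataFrame({
            "phi_X": [0.9], "phi_Y": [0.8], "theta_X": [0.01], "theta_Y": [0.02],
            "phi_Z": [0.2], "phi_W": [0.1], "theta_Z": [0.01], "theta_W": [0.02]})
        z = init_labels(table, maps4)
        img = apply_mapping(table.iloc[0].to_dict(), maps4[z[0]])
        assert img["phi_X"] + img["phi_Y"] < 1.0
        assert img["phi_Z"] + img["phi_W"] < 1.0


class TestDistance:
    def test_zero_at_center(self):
        assert distance([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_unit_vector(self):
        assert distance([1, 0, 0, 0], [0, 0, 0, 0]) == 1.0

    def test_unit_weights_reduce_to_euclidean(self):
        rng = np.random.default_rng(3)
        p, c = rng.random(4), rng.random(4)
        assert distance(p, c, np.ones(4)) == pytest.approx(distance(p, c))

    def test_errors(self):
        with pytest.raises(ValueError):
            distance([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            distance([1, 2], [1, 2], [1.0, 0.0])


class TestCoG:
    def test_separated_towers_fully_collapsed(self, maps2):
        spec = well_separated_2tower_spec(n=10_000, seed=4)
        table, z_true = simulate_label_switching_samples(spec, maps2)
        res = cog_relabel(table, maps2)
        assert relabel_accuracy(res.labels, z_true) >= 0.99
        # processed marginal is unimodal: all mass on one side of 1/2
        phix = res.table["phi_X"]
        assert min((phix > 0.5).mean(), (phix < 0.5).mean()) < 0.01

    def test_single_tower_table_is_fixed_point(self, maps2):
        rng = np.random.default_rng(5)
        n = 500
        table = pd.DataFrame({
            "phi_X": rng.beta(20, 10, n), "phi_Y": rng.beta(5, 20, n),
            "theta_X": rng.gamma(50, 2e-4, n), "theta_Y": rng.gamma(50, 4e-4, n)})
        res = cog_relabel(table, maps2)
        assert (res.labels == 0).all()
        pd.testing.assert_frame_equal(res.table, table)

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_nonincreasing_cog0(self, maps2, seed):
        rng = np.random.default_rng(seed)
        res = cog_relabel(random_table(rng), maps2)
        path = np.asarray(res.objective_path)
        assert np.all(np.diff(path) <= 1e-9 * np.abs(path).max())

    def test_processed_equals_rowwise_mapping(self, maps2):
        rng = np.random.default_rng(6)
        table = random_table(rng, n=50)
        res = cog_relabel(table, maps2)
        for i in [0, 7, 49]:
            expect = apply_mapping(table.iloc[i].to_dict(), maps2[res.labels[i]])
            assert res.table.iloc[i].to_dict() == pytest.approx(expect)

    def test_cogn_normalizes_scales(self, maps2):
        # theta columns are ~1000x smaller than phi; CoGN still separates
        spec = well_separated_2tower_spec(n=5_000, seed=7)
        table, z_true = simulate_label_switching_samples(spec, maps2)
        res = cog_relabel(table, maps2, normalized=True)
        assert relabel_accuracy(res.labels, z_true) >= 0.99

    def test_sklearn_estimator_api(self, maps2):
        spec = well_separated_2tower_spec(n=2_000, seed=8)
        table, _ = simulate_label_switching_samples(spec, maps2)
        est = CoGRelabeler(mappings=maps2).fit(table)
        assert est.get_params()["normalized"] is False
        assert est.labels_.shape == (2_000,)
        out = est.transform(table)
        assert list(out.columns) == list(table.columns)
        # transform of the training table reproduces the fitted labels
        np.testing.assert_array_equal(est.predict(table), est.labels_)


class TestBetaGammaFits:
    def test_beta_recovery(self):
        rng = np.random.default_rng(9)
        p, q = fit_beta_ml(rng.beta(2.0, 5.0, 100_000))
        assert p == pytest.approx(2.0, rel=0.05)
        assert q == pytest.approx(5.0, rel=0.05)

    def test_beta_symmetric_sample(self):
        rng = np.random.default_rng(10)
        x = rng.beta(3.0, 3.0, 20_000)
        x = np.concatenate([x, 1.0 - x])  # exactly symmetric about 1/2
        p, q = fit_beta_ml(x)
        assert p == pytest.approx(q, rel=1e-6)

    def test_beta_boundary_values_clamped(self):
        x = np.array([0.0, 0.2, 0.5, 0.9, 1.0])
        p, q = fit_beta_ml(x)
        assert np.isfinite([p, q]).all() and p > 0 and q > 0

    def test_beta_constant_sample_errors(self):
        with pytest.raises(ValueError):
            fit_beta_ml(np.full(10, 0.3))

    def test_gamma_recovery(self):
        rng = np.random.default_rng(11)
        a, b = fit_gamma_ml(rng.gamma(3.0, 1.0 / 200.0, 100_000))
        assert a == pytest.approx(3.0, rel=0.05)
        assert b == pytest.approx(200.0, rel=0.05)

    def test_gamma_mean_identity(self):
        rng = np.random.default_rng(12)
        x = rng.gamma(2.0, 0.01, 5_000)
        a, b = fit_gamma_ml(x)
        assert a / b == pytest.approx(x.mean(), abs=1e-8 * x.mean())

    def test_gamma_two_point_sample_matches_grid_search(self):
        x = np.array([1.0, 2.0])
        a, b = fit_gamma_ml(x)
        assert np.isfinite([a, b]).all()

        def negll(u):
            aa, bb = np.exp(u)
            return -np.sum(aa * np.log(bb) - special.gammaln(aa)
                           + (aa - 1.0) * np.log(x) - bb * x)

        ref = optimize.minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        a_ref, b_ref = np.exp(ref.x)
        assert a == pytest.approx(a_ref, rel=1e-4)
        assert b == pytest.approx(b_ref, rel=1e-4)

    def test_gamma_nonpositive_errors(self):
        with pytest.raises(ValueError):
            fit_gamma_ml(np.array([1.0, -1.0]))


class TestBetaGammaLoglik:
    def test_matches_independent_density_sum(self, maps2):
        rng = np.random.default_rng(13)
        table = random_table(rng, n=100)
        labels = rng.integers(0, 2, 100)
        fit = BetaGammaFit(
            beta={"phi_X": (2.0, 3.0), "phi_Y": (1.5, 4.0)},
            gamma={"theta_X": (2.0, 100.0), "theta_Y": (3.0, 150.0)})
        got = beta_gamma_loglik(table, labels, fit, maps2)
        expect = 0.0
        for i in range(100):
            row = apply_mapping(table.iloc[i].to_dict(), maps2[labels[i]])
            for c, (p, q) in fit.beta.items():
                expect += stats.beta.logpdf(np.clip(row[c], 1e-9, 1 - 1e-9), p, q)
            for c, (a, b) in fit.gamma.items():
                expect += stats.gamma.logpdf(max(row[c], 1e-12), a, scale=1.0 / b)
        assert got == pytest.approx(expect, rel=1e-10)

    def test_doubling_table_doubles_loglik(self, maps2):
        rng = np.random.default_rng(14)
        table = random_table(rng, n=60)
        labels = np.zeros(60, dtype=int)
        fit = BetaGammaFit(
            beta={"phi_X": (2.0, 3.0), "phi_Y": (1.5, 4.0)},
            gamma={"theta_X": (2.0, 100.0), "theta_Y": (3.0, 150.0)})
        one = beta_gamma_loglik(table, labels, fit, maps2)
        two = beta_gamma_loglik(pd.concat([table, table], ignore_index=True),
                                np.zeros(120, dtype=int), fit, maps2)
        assert two == pytest.approx(2.0 * one, rel=1e-12)


class TestBetaGammaRelabel:
    @pytest.mark.parametrize("seed", range(20))
    def test_loglik_nondecreasing(self, maps2, seed):
        rng = np.random.default_rng(100 + seed)
        res = beta_gamma_relabel(random_table(rng), maps2)
        path = np.asarray(res.objective_path)
        assert np.all(np.diff(path) >= -1e-8 * np.abs(path).max())

    def test_symmetric_twin_towers_collapse(self, maps2):
        spec = single_bdi_tower_spec(n=20_000, seed=15)
        table, z_true = simulate_label_switching_samples(spec, maps2)
        res = beta_gamma_relabel(table, maps2)
        mean = res.table["phi_X"].mean()
        # unimodal near a tower center (0.7 or its mirror 0.3), not 1/2
        assert min(abs(mean - 0.7), abs(mean - 0.3)) < 0.03
        assert abs(mean - 0.5) > 0.15

    def test_four_tower_accuracy(self, maps4):
        spec = double_bdi_tower_spec(n=10_000, seed=16)
        table, z_true = simulate_label_switching_samples(spec, maps4)
        res = beta_gamma_relabel(table, maps4)
        assert relabel_accuracy(res.labels, z_true) >= 0.99

    def test_equivalent_to_cog0_under_equal_variance_normals(self, maps2):
        """One assignment step with equal-variance normal densities picks
        the image nearest the center, i.e. the CoG0 rule."""
        rng = np.random.default_rng(17)
        table = random_table(rng, n=300)
        from mscipost.relabel import _check_table, _images, _mapping_params

        params = _mapping_params(maps2)
        M = _check_table(table, params)
        imgs = _images(M, maps2, params)
        mu = M.mean(axis=0)
        sigma2 = 1.0
        normal_ll = -((imgs - mu) ** 2).sum(axis=2) / (2 * sigma2)
        d2 = ((imgs - mu) ** 2).sum(axis=2)
        np.testing.assert_array_equal(np.argmax(normal_ll, axis=0),
                                      np.argmin(d2, axis=0))

    def test_idempotent(self, maps2):
        spec = single_bdi_tower_spec(n=5_000, seed=18)
        table, _ = simulate_label_switching_samples(spec, maps2)
        first = beta_gamma_relabel(table, maps2)
        second = beta_gamma_relabel(first.table, maps2)
        assert (second.labels == 0).all()
        pd.testing.assert_frame_equal(second.table, first.table)


class TestRelabelAll:
    def _table_for(self, model, rng, n=2_000):
        events = detect_bdi_events(model)
        cols = {}
        for e in events:
            px, py = e.phi_params
            tx, ty = e.theta_params
            cols[px] = rng.beta(20, 10, n)
            cols[py] = rng.beta(5, 20, n)
            cols[tx] = rng.gamma(50, 2e-4, n)
            cols[ty] = rng.gamma(50, 4e-4, n)
        return pd.DataFrame(cols)

    def test_three_passes_for_three_sister_events(self, fig5a_model):
        rng = np.random.default_rng(19)
        res = relabel_all(self._table_for(fig5a_model, rng), fig5a_model,
                          algorithm="cog0")
        assert len(res.passes) == 3
        assert res.nonsister_events == []

    def test_two_passes_when_one_event_is_nonsister(self, fig5b_model):
        rng = np.random.default_rng(20)
        res = relabel_all(self._table_for(fig5b_model, rng), fig5b_model,
                          algorithm="betagamma")
        assert len(res.passes) == 2
        assert res.nonsister_events == [("X1", "Y1")]

    def test_no_sister_events_returns_table_unchanged(self, s3_model):
        rng = np.random.default_rng(21)
        table = self._table_for(s3_model, rng, n=500)
        res = relabel_all(table, s3_model)
        assert res.passes == []
        pd.testing.assert_frame_equal(res.table, table)

    def test_double_bdi_single_joint_pass(self, fig6a_model):
        spec = double_bdi_tower_spec(n=2_000, seed=22)
        lo, up = detect_bdi_events(fig6a_model)
        table, _ = simulate_label_switching_samples(spec, double_bdi_mappings(lo, up))
        res = relabel_all(table, fig6a_model, algorithm="cogn")
        assert len(res.passes) == 1
        assert res.passes[0][0] == ("X", "Y", "Z", "W")


class TestAccuracy:
    def test_identical(self):
        z = np.array([0, 1, 0, 1])
        assert relabel_accuracy(z, z) == 1.0

    def test_global_flip(self):
        z = np.array([0, 1, 0, 0])
        assert relabel_accuracy(z, 1 - z) == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(23)
        a, b = rng.integers(0, 2, 10_000), rng.integers(0, 2, 10_000)
        acc = relabel_accuracy(a, b)
        assert 0.5 <= acc < 0.53  # 0.5 + O(N^{-1/2})

    def test_klein_translation_counts_as_correct(self):
        z = np.array([0, 1, 2, 3, 2, 1])
        assert relabel_accuracy(z ^ 2, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            relabel_accuracy([0, 1], [0, 1, 0])
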