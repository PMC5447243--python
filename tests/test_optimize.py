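import warnings

import numpy as np
import pytest

import fieldfit as ff
from fieldfit.features import ResponseParams, build_design_matrix
from fieldfit.optimize import (
    FeatureLibrary,
    FitOptions,
    GeneModel,
    GridSpec,
    cluster_fit,
    fit_gene,
    fit_genes,
    grid_search,
    refine_nelder_mead,
    _make_objective,
)
from fieldfit.weather import resample_weather


@pytest.fixture(scope="module")
def env(schedule_4h_mod, weather_mod):
    return schedule_4h_mod, weather_mod


@pytest.fixture(scope="module")
def schedule_4h_mod():
    return ff.sampling_design("4h", 2008)


@pytest.fixture(scope="module")
def weather_mod():
    return resample_weather(ff.benchmark_weather(years=(2008,), step=600, seed=11), 600)


@pytest.fixture(scope="module")
def library(schedule_4h_mod, weather_mod):
    return FeatureLibrary(weather_mod, schedule_4h_mod, GridSpec())


def _nb_log2(rng, log2_mean, dispersion=0.07):
    mu = 2.0**log2_mean
    counts = rng.negative_binomial(1.0 / dispersion, 1.0 / (1.0 + dispersion * mu))
    return np.log2(counts + 0.5)


class TestGridSearch:
    def test_constant_gene_returns_valid_point(self, schedule_4h_mod, weather_mod, library):
        y = np.full(180, 8.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rp, fac, beta, mse = grid_search(
                y, np.ones(180), schedule_4h_mod, weather_mod, library=library
            )
        assert fac in ff.ATTRIBUTES
        assert mse == pytest.approx(0.0, abs=1e-12)
        assert beta[0] == pytest.approx(8.0)

    def test_noiseless_gene_from_grid_point_is_found(self, schedule_4h_mod, weather_mod, library):
        theta = float(library.thresholds["temperature"][6])
        rp_true = ResponseParams("temperature", 6.0, theta, -4.0, 6.0, -1.5, 0.0, 1)
        X = build_design_matrix(
            schedule_4h_mod.times, schedule_4h_mod.ages, schedule_4h_mod.genotypes,
            weather_mod, rp_true,
        )
        y = 5.0 + 2.0 * X.column("response")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rp, fac, _, mse = grid_search(
                y, np.ones(180), schedule_4h_mod, weather_mod, library=library
            )
        assert fac == "temperature"
        assert mse < 1e-6  # the generating setting (or an equivalent) wins

    def test_generating_factor_selected_under_noise(self, schedule_4h_mod, weather_mod, library):
        theta = float(library.thresholds["temperature"][7])
        rp_true = ResponseParams("temperature", 6.0, theta, -4.0, 10.0, -2.0, 0.0, 1)
        X = build_design_matrix(
            schedule_4h_mod.times, schedule_4h_mod.ages, schedule_4h_mod.genotypes,
            weather_mod, rp_true,
        )
        hits = 0
        n_rep = 20
        rng = np.random.default_rng(42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                y = 5.0 + 3.0 * X.column("response") + rng.normal(0, 0.2, 180)
                _, fac, _, _ = grid_search(
                    y, np.ones(180), schedule_4h_mod, weather_mod, library=library
                )
                hits += fac == "temperature"
        assert hits >= 0.95 * n_rep

    def test_too_few_samples_rejected(self, schedule_4h_mod, weather_mod):
        from fieldfit.features import Schedule

        small = Schedule(
            times=schedule_4h_mod.times[:5], ages=schedule_4h_mod.ages[:5],
            genotypes=schedule_4h_mod.genotypes[:5], sample_ids=schedule_4h_mod.sample_ids[:5],
        )
        with pytest.raises(ValueError, match="at least 10"):
            grid_search(np.zeros(5), np.ones(5), small, weather_mod)


class TestRefineNelderMead:
    def test_never_worse_than_init(self, schedule_4h_mod, weather_mod, library, rng):
        y = _nb_log2(rng, np.full(180, 7.0))
        obj = _make_objective(y, np.ones(180), schedule_4h_mod, weather_mod)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rp0, *_ = grid_search(y, np.ones(180), schedule_4h_mod, weather_mod, library=library)
            rp = refine_nelder_mead(rp0, obj)
        assert obj(rp) <= obj(rp0) + 1e-12

    def test_quadratic_bowl_converges(self):
        target = np.array([24.0, 1.0])

        def objective(rp: ResponseParams) -> float:
            return (rp.threshold_theta - target[0]) ** 2 + (rp.gamma_f - target[1]) ** 2

        init = ResponseParams("temperature", 6.0, 23.0, 0.0, 2.0, 0.0, 0.0, 1)
        out = refine_nelder_mead(init, objective)
        assert abs(out.threshold_theta - 24.0) < 1e-3
        assert abs(out.gamma_f - 1.0) < 1e-3

    def test_non_finite_init_rejected(self):
        init = ResponseParams("temperature", 6.0, 23.0, 0.0, 2.0, 0.0, 0.0, 1)
        with pytest.raises(ValueError, match="finite"):
            refine_nelder_mead(init, lambda rp: np.inf)


class TestFitGene:
    def test_pure_noise_gene_mostly_constant(self, schedule_4h_mod, weather_mod, library):
        rng = np.random.default_rng(5)
        n_const = 0
        n_rep = 12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                y = 7.0 + rng.normal(0, 0.4, 180)
                gm = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
                n_const += gm.is_constant
        assert n_const >= 0.8 * n_rep

    def test_noiseless_clock_gene(self, schedule_4h_mod, weather_mod, library):
        t = schedule_4h_mod.times.hour.to_numpy().astype(float)
        y = 6.0 + 1.0 * np.cos(2 * np.pi * (t - 9.0) / 24.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
        assert gm.nonzero_groups() == {"clock"}
        assert gm.factor == "none"
        assert ff.circular_phase_error(ff.phase_of(gm), 9.0) < 0.1

    def test_temperature_response_gene_recovered(self, schedule_4h_mod, weather_mod, library):
        truth = [t for t in ff.truth_library(seed=0) if t.structure == {"response"}][0]
        rng = np.random.default_rng(8)
        y = _nb_log2(rng, ff.true_log2_mean(truth, schedule_4h_mod, weather_mod),
                     truth.dispersion)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
        assert gm.factor == "temperature"
        assert "response" in gm.nonzero_groups()

    def test_fit_beats_constant_model(self, schedule_4h_mod, weather_mod, library, rng):
        t = schedule_4h_mod.times.hour.to_numpy().astype(float)
        y = _nb_log2(rng, 6.0 + 2.0 * np.cos(2 * np.pi * (t - 3.0) / 24.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
        X = build_design_matrix(
            schedule_4h_mod.times, schedule_4h_mod.ages, schedule_4h_mod.genotypes,
            weather_mod, gm.response_params or _any_rp(), scale_specs=gm.scale_specs,
        )
        mse_fit = np.mean((y - X.values @ gm.coefficients) ** 2)
        assert mse_fit <= np.mean((y - y.mean()) ** 2) + 1e-12

    def test_deterministic(self, schedule_4h_mod, weather_mod, library, rng):
        y = _nb_log2(rng, np.full(180, 6.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
            b = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        assert a.selected_lambda == b.selected_lambda

    def test_serialization_roundtrip(self, schedule_4h_mod, weather_mod, library, rng):
        t = schedule_4h_mod.times.hour.to_numpy().astype(float)
        y = _nb_log2(rng, 6.0 + 1.5 * np.cos(2 * np.pi * t / 24.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = fit_gene(y, None, schedule_4h_mod, weather_mod, library=library)
        back = GeneModel.from_dict(gm.to_dict())
        np.testing.assert_array_equal(back.coefficients, gm.coefficients)
        assert back.factor == gm.factor


def _any_rp():
    return ResponseParams("temperature", 1e-9, np.inf, 0.0, 10.0, -2.0, 0.0, 1)


class TestClusterFit:
    def _panel(self, schedule, weather, rng):
        t = schedule.times.hour.to_numpy().astype(float)
        base1 = 6.0 + 2.0 * np.cos(2 * np.pi * (t - 4.0) / 24.0)
        base2 = 7.0 - 2.0 * np.cos(2 * np.pi * (t - 4.0) / 24.0)
        Y = np.vstack(
            [_nb_log2(rng, base1) for _ in range(10)]
            + [_nb_log2(rng, base2) for _ in range(10)]
        )
        return Y

    def test_two_patterns_two_clusters(self, schedule_4h_mod, weather_mod, rng):
        Y = self._panel(schedule_4h_mod, weather_mod, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cluster_fit(Y, None, schedule_4h_mod, weather_mod)
        labels = res.cluster_labels
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_grid_search_runs_only_for_exemplars(self, schedule_4h_mod, weather_mod, rng):
        Y = self._panel(schedule_4h_mod, weather_mod, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cluster_fit(Y, None, schedule_4h_mod, weather_mod)
        assert res.diagnostics["grid_search_calls"] == len(res.exemplars)
        assert len(res.exemplars) < Y.shape[0]

    def test_identical_copies_identical_models(self, schedule_4h_mod, weather_mod, rng):
        t = schedule_4h_mod.times.hour.to_numpy().astype(float)
        y = _nb_log2(rng, 6.0 + 2.0 * np.cos(2 * np.pi * t / 24.0))
        Y = np.vstack([y, y, y])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cluster_fit(Y, None, schedule_4h_mod, weather_mod)
        assert res.diagnostics["n_clusters"] == 1
        # the two warm-started copies are bit-identical; the exemplar's own
        # fit agrees up to Nelder-Mead re-convergence tolerance
        members = [m for m in res.models if m.gene_id not in res.exemplars]
        exemplar = [m for m in res.models if m.gene_id in res.exemplars][0]
        np.testing.assert_array_equal(
            members[0].coefficients, members[1].coefficients
        )
        assert members[0].nonzero_groups() == exemplar.nonzero_groups()
        np.testing.assert_allclose(
            members[0].coefficients, exemplar.coefficients, atol=0.05
        )

    def test_single_gene_rejected(self, schedule_4h_mod, weather_mod):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_fit(np.zeros((1, 180)), None, schedule_4h_mod, weather_mod)
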