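"""Mixed-effects estimation: likelihood kernel, fits, model comparison."""

import numpy as np
import pytest

import dabipkpd as dp
from dabipkpd.dataio import SubjectRecords
from dabipkpd.estimation import ModelSpec, _Problem, compare_models
from dabipkpd.errors import DegenerateErrorModelError


def _single_obs_subject(pop, y_value, time=30.0):
    reg = dp.study_regimen(70.0)
    events = reg.to_array()
    times = np.array([time])
    ch = np.array([1], dtype=np.int64)
    from dabipkpd import _kernels
    from dabipkpd.model import typical_vector
    f = _kernels.predict_obs(times, ch, events,
                             typical_vector(pop.parameter_values(), 70.0))
    y = f if y_value == "model" else np.array([y_value], dtype=float)
    return SubjectRecords(id="s1", weight=70.0, events=events, times=times,
                          y=y, channel=ch), float(f[0])


class TestIndividualNeg2ll:
    def test_exact_fit_unit_additive_gives_log_2pi(self, pop):
        subj, _f = _single_obs_subject(pop, "model")
        val = dp.individual_neg2ll(subj, pop.parameter_values(),
                                   sigma={"add_conc": 1.0})
        assert val == pytest.approx(np.log(2 * np.pi), abs=1e-9)

    def test_doubling_additive_sigma_adds_2log2(self, pop):
        subj, _f = _single_obs_subject(pop, "model")
        v1 = dp.individual_neg2ll(subj, pop.parameter_values(),
                                  sigma={"add_conc": 1.0})
        v2 = dp.individual_neg2ll(subj, pop.parameter_values(),
                                  sigma={"add_conc": 2.0})
        assert v2 - v1 == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_zero_variance_rejected(self, pop):
        subj, _f = _single_obs_subject(pop, "model")
        with pytest.raises(DegenerateErrorModelError):
            dp.individual_neg2ll(subj, pop.parameter_values(), sigma={})

    def test_large_variance_dominated_by_log_term(self, pop):
        subj, f = _single_obs_subject(pop, "model")
        subj.y = subj.y + 5.0
        vals = [dp.individual_neg2ll(subj, pop.parameter_values(),
                                     sigma={"add_conc": s})
                for s in (1e2, 1e4, 1e6)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] - vals[1] == pytest.approx(2 * np.log(1e2), rel=1e-3)


class TestCompareModels:
    @staticmethod
    def _fit_like(obj):
        import pandas as pd
        return dp.FitResult(estimates={}, objective=obj, etas=pd.DataFrame(),
                            spec=None, convergence={})

    def test_threshold_at_3p84(self):
        full, red = self._fit_like(100.0), self._fit_like(104.0)
        assert compare_models(full, red, df=1).significant
        red2 = self._fit_like(103.0)
        assert not compare_models(full, red2, df=1).significant

    def test_df2_threshold(self):
        res = compare_models(self._fit_like(0.0), self._fit_like(0.0), df=2)
        assert res.threshold == pytest.approx(5.991, abs=5e-4)

    def test_negative_delta_warns(self):
        with pytest.warns(RuntimeWarning):
            compare_models(self._fit_like(10.0), self._fit_like(9.0), df=1)


class TestFitPopulation:
    def test_noise_free_naive_recovery(self, noise_free_cohort):
        """Generating parameters are the optimum of a noise-free fit."""
        ds, quiet = noise_free_cohort
        start = quiet.with_values(values={"CL": 0.06, "V1": 2.2, "Q": 0.2,
                                          "V2": 12.0},
                                  sigmas={"add_conc": 0.01})
        spec = ModelSpec(population=start, theta=("CL", "Q", "V1", "V2"),
                         channels=(1,), method="naive")
        fit = dp.fit_population(ds, spec)
        for name, truth in (("CL", 0.0453), ("Q", 0.268), ("V1", 2.94),
                            ("V2", 9.51)):
            assert fit.estimates[name] == pytest.approx(truth, rel=2e-3)

    def test_fit_is_deterministic(self, noise_free_cohort):
        ds, quiet = noise_free_cohort
        start = quiet.with_values(sigmas={"add_conc": 0.01})
        spec = ModelSpec(population=start, theta=("CL", "V1"),
                         channels=(1,), method="naive")
        a = dp.fit_population(ds, spec)
        b = dp.fit_population(ds, spec)
        assert a.objective == b.objective
        assert a.estimates == b.estimates

    def test_focei_agrees_with_laplace_for_small_omega(self, pop):
        """Near-linear random effects: the two approximations coincide."""
        small = pop.with_values(omega={k: 0.0 for k in pop.omega}
                                | {"CL": 0.005, "V1": 0.005})
        ds = dp.generate_cohort(small, dp.paper_design(n_subjects=4, seed=9))
        spec_f = ModelSpec(population=small, theta=("CL", "V1"),
                           channels=(1,), method="focei")
        subjects = ds.subject_records(channels=(1,))
        prob_f = _Problem(subjects, spec_f)
        spec_l = ModelSpec(population=small, theta=("CL", "V1"),
                           channels=(1,), method="laplace")
        prob_l = _Problem(subjects, spec_l)
        x = prob_f.x0
        assert prob_f.objective(x) == pytest.approx(prob_l.objective(x), abs=1.0)

    def test_focei_matches_gauss_hermite_marginal(self, pop):
        """The FOCEI objective approximates the exact marginal -2ll.

        Exact value by 60-point tensor Gauss-Hermite quadrature over the
        two random effects of a single subject.
        """
        from numpy.polynomial.hermite import hermgauss
        from dabipkpd import _kernels
        from dabipkpd.model import PARAM_INDEX, typical_vector

        ds = dp.generate_cohort(pop, dp.paper_design(n_subjects=1, seed=77))
        s = ds.subject_records(channels=(1,))[0]
        p_typ = typical_vector(pop.parameter_values(), s.weight)
        sig = np.array([0.10, 0.1, 0.1, 0.5])
        eta_idx = np.array([PARAM_INDEX["CL"], PARAM_INDEX["V1"]],
                           dtype=np.int64)
        omega = np.array([0.09, 0.09])
        nodes, weights = hermgauss(60)

        def loglik(eta):
            p = p_typ.copy()
            p[eta_idx] *= np.exp(eta)
            f = _kernels.predict_obs(s.times, s.channel, s.events, p)
            v = (f * sig[0]) ** 2 + sig[1] ** 2
            return -0.5 * np.sum(np.log(2 * np.pi * v) + (s.y - f) ** 2 / v)

        lls = np.array([[loglik(np.array([xi, xj]) * np.sqrt(2 * omega))
                         for xj in nodes] for xi in nodes])
        m = lls.max()
        exact = -2 * (m + np.log(
            np.sum(np.outer(weights, weights) * np.exp(lls - m)) / np.pi))
        approx, _eta, _ok = _kernels.foce_subject(
            s.times, s.y, s.channel, s.events, p_typ, eta_idx, omega, sig)
        assert approx == pytest.approx(exact, abs=1.0)

    def test_standard_errors_reported(self, noise_free_cohort):
        ds, quiet = noise_free_cohort
        start = quiet.with_values(sigmas={"add_conc": 0.05})
        spec = ModelSpec(population=start, theta=("CL", "V1"),
                        channels=(1,), method="naive")
        fit = dp.fit_population(ds, spec, compute_se=True)
        assert set(fit.se) == {"CL", "V1"}
        for name in ("CL", "V1"):
            lo, hi = fit.ci[name]
            assert lo < fit.estimates[name] < hi
        table = fit.parameter_table()
        assert {"parameter", "estimate", "SE"} <= set(table.columns)


class TestSequentialPPPD:
    def test_stage1_equals_pk_only_fit(self, pop):
        ds = dp.generate_cohort(pop, dp.paper_design(n_subjects=6, seed=17))
        seq = dp.fit_sequential_pppd(ds, pop, simplex_maxfev=150,
                                     polish_maxiter=30)
        spec = ModelSpec(population=pop, theta=("CL", "Q", "V1", "V2"),
                         omega=("CL", "Q", "V1", "V2"),
                         sigma=("prop_conc", "add_conc"),
                         channels=(1,), method="focei")
        alone = dp.fit_population(ds, spec, simplex_maxfev=150,
                                  polish_maxiter=30)
        assert seq.stages["pk"].objective == pytest.approx(alone.objective)
        assert seq.stages["pk"].estimates == alone.estimates

    def test_noise_free_pd_recovery(self, noise_free_cohort):
        """With exact data and variances pinned small, stage 2 returns the
        generating Emax/Ce50 (fixed-point property of the sequence)."""
        ds, quiet = noise_free_cohort
        start = quiet.with_values(sigmas={"add_conc": 0.01, "add_r": 0.01})
        fit = dp.fit_sequential_pppd(ds, start, pk_omega=(), pd_omega=(),
                                     method="naive")
        assert fit.estimates["Emax"] == pytest.approx(180.0, rel=0.01)
        assert fit.estimates["Ce50"] == pytest.approx(64.2, rel=0.01)
        assert fit.estimates["t_half_keo"] == pytest.approx(1.04, rel=0.02)
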