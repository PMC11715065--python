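"""Nonlinear mixed-effects estimation for the dabigatran PKPD model.

The marginal likelihood is approximated per subject by a Laplace-type
expansion around the empirical Bayes eta.  Three methods are provided:

* ``focei`` — first-order conditional estimation with interaction: the
  inner mode is found by damped Fisher scoring and the curvature term uses
  the Gauss-Newton (Fisher) Hessian including the eta-dependence of the
  residual variance.  This is the default and the fast numba path.
* ``laplace`` — same expansion with a full numeric Hessian of the joint
  -2 log-likelihood (slower; used as a cross-check).
* ``naive`` — naive pooled: no random effects, all data share one
  parameter vector.

Fixed effects, BSV standard deviations and residual components are searched
on the log scale (so estimates stay positive), with a Nelder-Mead start and
an L-BFGS-B polish.  Objective values are -2 log-likelihood including all
2*pi constants, so nested models are directly comparable by chi-square.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from . import _kernels
from .dataio import StudyDataset, SubjectRecords
from .errors import (ConfigurationError, DegenerateErrorModelError,
                     InvalidInputError, NumericError)
from .model import PARAM_INDEX, typical_vector
from .population import SIGMA_NAMES, PopulationModel

__all__ = ["ModelSpec", "FitResult", "LRTResult", "individual_neg2ll",
           "fit_population", "fit_sequential_pppd", "compare_models",
           "heuristic_pk_initials", "PK_THETA", "PD_THETA"]

log = logging.getLogger(__name__)

PK_THETA = ("CL", "Q", "V1", "V2")
PD_THETA = ("E0", "Emax", "Ce50", "t_half_keo")


@dataclass
class ModelSpec:
    """What to estimate, from which starting values, by which method.

    ``population`` supplies both initial values for estimated quantities and
    fixed values for everything else (including omegas fixed at positive
    values, whose etas are still integrated over).
    """

    population: PopulationModel
    theta: tuple[str, ...]
    omega: tuple[str, ...] = ()
    sigma: tuple[str, ...] = ()
    channels: tuple[int, ...] = (1,)
    method: str = "focei"

    def __post_init__(self):
        for name in self.theta:
            if name not in PARAM_INDEX:
                raise ConfigurationError(f"unknown fixed effect {name!r}")
        for name in self.omega:
            if name not in PARAM_INDEX:
                raise ConfigurationError(f"unknown omega term {name!r}")
        for name in self.sigma:
            if name not in SIGMA_NAMES:
                raise ConfigurationError(f"unknown sigma term {name!r}")
        if self.method not in ("focei", "laplace", "naive"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if len(set(self.theta)) != len(self.theta):
            raise ConfigurationError("duplicate theta names")


@dataclass
class LRTResult:
    delta_obj: float
    df: int
    threshold: float
    p_value: float
    significant: bool


@dataclass
class FitResult:
    """Estimates, objective and per-subject random effects from one fit."""

    estimates: dict[str, float]        # theta + omega_* (variances) + sigma_*
    objective: float
    etas: pd.DataFrame                 # subjects x eta terms (EBEs)
    spec: ModelSpec
    convergence: dict
    se: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None
    stages: dict[str, "FitResult"] | None = None

    def to_population(self) -> PopulationModel:
        """Population model with estimated quantities substituted."""
        values = {k: v for k, v in self.estimates.items() if k in PARAM_INDEX}
        omega = {k.removeprefix("omega_"): v for k, v in self.estimates.items()
                 if k.startswith("omega_")}
        sigmas = {k.removeprefix("sigma_"): v for k, v in self.estimates.items()
                  if k.startswith("sigma_")}
        return self.spec.population.with_values(values=values, omega=omega,
                                                sigmas=sigmas)

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / BSV / SE / 95% CI table in the conventional layout."""
        rows = []
        for name in self.spec.theta:
            est = self.estimates[name]
            bsv_var = self.estimates.get(f"omega_{name}",
                                         self.spec.population.omega.get(name))
            row = {"parameter": name, "estimate": est,
                   "BSV_CV%": (100.0 * math.sqrt(bsv_var)
                               if bsv_var else np.nan)}
            if self.se is not None and name in self.se:
                row["SE"] = self.se[name]
                row["CI95_low"], row["CI95_high"] = self.ci[name]
            rows.append(row)
        for name in self.spec.sigma:
            key = f"sigma_{name}"
            row = {"parameter": key, "estimate": self.estimates[key],
                   "BSV_CV%": np.nan}
            if self.se is not None and key in self.se:
                row["SE"] = self.se[key]
                row["CI95_low"], row["CI95_high"] = self.ci[key]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood plumbing


def _sigma_vector(pop: PopulationModel, overrides: dict[str, float]) -> np.ndarray:
    sig = {name: getattr(pop, f"sigma_{name}") for name in SIGMA_NAMES}
    sig.update(overrides)
    return np.array([sig[name] for name in SIGMA_NAMES])


def individual_neg2ll(subject: SubjectRecords, values: dict[str, float],
                      eta: dict[str, float] | None = None,
                      sigma: np.ndarray | dict[str, float] | None = None,
                      ) -> float:
    """-2 log-likelihood of one subject's data at fixed eta.

    ``values`` are 70-kg standardised typical values for all twelve model
    parameters; ``sigma`` the four residual components (prop_conc, add_conc,
    prop_r, add_r).  Returns sum over observations of
    log(2 pi var) + (y - f)^2 / var with var = (f sigma_p)^2 + sigma_a^2.
    """
    if isinstance(sigma, dict):
        sig = np.array([sigma.get(name, 0.0) for name in SIGMA_NAMES])
    else:
        sig = np.asarray(sigma, dtype=float)
    p = typical_vector(values, subject.weight)
    for key, e in (eta or {}).items():
        p[PARAM_INDEX[key]] *= math.exp(e)
    f = _kernels.predict_obs(subject.times, subject.channel, subject.events, p)
    sp = np.where(subject.channel == 1, sig[0], sig[2])
    sa = np.where(subject.channel == 1, sig[1], sig[3])
    var = (f * sp) ** 2 + sa ** 2
    if np.any(var <= 0):
        raise DegenerateErrorModelError(
            "zero residual variance at an observation; check sigma components")
    res = subject.y - f
    return float(np.sum(np.log(2.0 * np.pi * var) + res ** 2 / var))


class _Problem:
    """Packs/unpacks the log-scale search vector and evaluates the objective."""

    def __init__(self, subjects: list[SubjectRecords], spec: ModelSpec):
        self.subjects = subjects
        self.spec = spec
        pop = spec.population
        values = pop.parameter_values()
        self.fixed_values = values
        self.names = (list(spec.theta)
                      + [f"omega_{n}" for n in spec.omega]
                      + [f"sigma_{n}" for n in spec.sigma])
        x0 = []
        for name in spec.theta:
            x0.append(math.log(values[name]))
        for name in spec.omega:
            var0 = pop.omega.get(name, 0.09)
            if var0 <= 0:
                var0 = 0.09
            x0.append(math.log(math.sqrt(var0)))
        for name in spec.sigma:
            s0 = getattr(pop, f"sigma_{name}")
            if s0 <= 0:
                s0 = 0.1
            x0.append(math.log(s0))
        self.x0 = np.array(x0)
        self.n_theta = len(spec.theta)
        self.n_omega = len(spec.omega)
        self.n_obs = int(sum(s.y.size for s in subjects))
        self._last_etas: dict | None = None

    def unpack(self, x: np.ndarray):
        spec = self.spec
        # clip the search vector so simplex excursions cannot underflow a
        # variance to exactly zero (or overflow a fixed effect)
        x = np.clip(x, -40.0, 40.0)
        values = dict(self.fixed_values)
        for i, name in enumerate(spec.theta):
            values[name] = math.exp(x[i])
        omega = dict(spec.population.omega)
        for j, name in enumerate(spec.omega):
            sd = max(math.exp(x[self.n_theta + j]), 1e-6)
            omega[name] = sd * sd
        sig_over = {}
        for k, name in enumerate(spec.sigma):
            sig_over[name] = max(
                math.exp(x[self.n_theta + self.n_omega + k]), 1e-8)
        sig = _sigma_vector(spec.population, sig_over)
        return values, omega, sig

    def eta_layout(self, omega: dict[str, float]):
        names = sorted((k for k, v in omega.items() if v > 0),
                       key=lambda k: PARAM_INDEX[k])
        idx = np.array([PARAM_INDEX[k] for k in names], dtype=np.int64)
        var = np.array([omega[k] for k in names])
        return names, idx, var

    def objective(self, x: np.ndarray) -> float:
        values, omega, sig = self.unpack(x)
        method = self.spec.method
        eta_names, eta_idx, eta_var = self.eta_layout(omega)
        if method == "naive" or eta_idx.size == 0:
            total = 0.0
            for s in self.subjects:
                p = typical_vector(values, s.weight)
                total += _kernels.naive_neg2ll(s.times, s.y, s.channel,
                                               s.events, p, sig)
            self._last_etas = {"names": eta_names, "by_subject": {}}
            return total
        total = 0.0
        etas = {}
        for s in self.subjects:
            p = typical_vector(values, s.weight)
            try:
                if method == "focei":
                    obj_i, eta_hat, _ok = _kernels.foce_subject(
                        s.times, s.y, s.channel, s.events, p, eta_idx,
                        eta_var, sig)
                else:
                    obj_i, eta_hat = _laplace_subject(s, p, eta_idx, eta_var,
                                                      sig)
            except np.linalg.LinAlgError:
                # indefinite curvature in a pathological region of the
                # outer search; treat as a rejected point
                return 1e12
            total += obj_i
            etas[s.id] = eta_hat
        self._last_etas = {"names": eta_names, "by_subject": etas}
        if not np.isfinite(total):
            return 1e12
        return total


def _laplace_subject(s: SubjectRecords, p_typ: np.ndarray,
                     eta_idx: np.ndarray, eta_var: np.ndarray,
                     sig: np.ndarray) -> tuple[float, np.ndarray]:
    """Laplace approximation with a full numeric Hessian of the joint -2ll."""
    q = eta_idx.size

    def joint(eta):
        return _kernels._joint_neg2pen(s.times, s.y, s.channel, s.events,
                                       p_typ, eta_idx, eta_var, sig, eta)

    res = optimize.minimize(joint, np.zeros(q), method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 200})
    eta_hat = res.x
    h = 1e-4
    H = np.zeros((q, q))
    f0 = joint(eta_hat)
    for a in range(q):
        for b in range(a, q):
            ea = np.zeros(q); ea[a] = h
            eb = np.zeros(q); eb[b] = h
            fpp = joint(eta_hat + ea + eb)
            fpm = joint(eta_hat + ea - eb)
            fmp = joint(eta_hat - ea + eb)
            fmm = joint(eta_hat - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    M = H / 2.0
    # guard against indefiniteness far from the optimum
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, 1e-10)
    logdet = float(np.sum(np.log(w)))
    obj = (s.y.size * _kernels.LOG2PI + float(np.sum(np.log(eta_var)))
           + f0 + logdet)
    return obj, eta_hat


# ---------------------------------------------------------------------------
# fitting


def fit_population(dataset: StudyDataset, spec: ModelSpec, *,
                   compute_se: bool = False,
                   simplex_maxfev: int | None = None,
                   polish_maxiter: int = 200) -> FitResult:
    """Maximise the approximate marginal likelihood for ``spec``.

    Deterministic given dataset, spec and optimizer settings.  On
    non-convergence the best-found point is returned with
    ``convergence["converged"] = False``.
    """
    subjects = dataset.subject_records(channels=spec.channels)
    subjects = [s for s in subjects if s.y.size > 0]
    if not subjects:
        raise InvalidInputError("no usable observations for the requested channels")
    prob = _Problem(subjects, spec)
    x0 = prob.x0
    nfev = 0

    def obj(x):
        nonlocal nfev
        nfev += 1
        return prob.objective(x)

    p = x0.size
    if simplex_maxfev is None:
        simplex_maxfev = 100 + 60 * p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nm = optimize.minimize(obj, x0, method="Nelder-Mead",
                               options={"maxfev": simplex_maxfev,
                                        "xatol": 1e-4, "fatol": 1e-4,
                                        "adaptive": True})
        bounds = [(xi - 6.0, xi + 6.0) for xi in x0]
        qn = optimize.minimize(obj, nm.x, method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": polish_maxiter,
                                        "ftol": 1e-10, "gtol": 1e-7,
                                        "eps": 1e-5})
    best = qn if qn.fun <= nm.fun else nm
    x_hat = np.asarray(best.x)
    final_obj = prob.objective(x_hat)  # refresh cached etas at the optimum
    values, omega, sig_vec = prob.unpack(x_hat)
    estimates: dict[str, float] = {}
    for name in spec.theta:
        estimates[name] = values[name]
    for name in spec.omega:
        estimates[f"omega_{name}"] = omega[name]
    for k, name in enumerate(spec.sigma):
        estimates[f"sigma_{name}"] = float(
            math.exp(x_hat[prob.n_theta + prob.n_omega + k]))
    eta_info = prob._last_etas or {"names": [], "by_subject": {}}
    etas = pd.DataFrame(
        {f"eta_{n}": [eta_info["by_subject"].get(s.id, np.zeros(len(eta_info["names"])))[i]
                      for s in subjects]
         for i, n in enumerate(eta_info["names"])},
        index=[s.id for s in subjects])
    convergence = {
        "converged": bool(qn.success or nm.success),
        "nfev": nfev,
        "simplex_obj": float(nm.fun),
        "objective": float(final_obj),
        "message": str(best.message),
        "n_obs": prob.n_obs,
    }
    if not convergence["converged"]:
        log.warning("fit did not formally converge: %s", best.message)
    result = FitResult(estimates=estimates, objective=float(final_obj),
                       etas=etas, spec=spec, convergence=convergence)
    if compute_se:
        _attach_standard_errors(result, prob, x_hat)
    return result


def _attach_standard_errors(result: FitResult, prob: _Problem,
                            x_hat: np.ndarray) -> None:
    """Asymptotic SEs from the numeric Hessian of the -2ll on the log scale."""
    p = x_hat.size
    h = 1e-3
    H = np.zeros((p, p))
    for a in range(p):
        for b in range(a, p):
            ea = np.zeros(p); ea[a] = h
            eb = np.zeros(p); eb[b] = h
            fpp = prob.objective(x_hat + ea + eb)
            fpm = prob.objective(x_hat + ea - eb)
            fmp = prob.objective(x_hat - ea + eb)
            fmm = prob.objective(x_hat - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        log.warning("Hessian singular; standard errors unavailable")
        return
    diag = np.diag(cov)
    if np.any(diag <= 0):
        w, V = np.linalg.eigh(H)
        flat = [prob.names[i] for i in np.argsort(np.abs(V[:, np.argmin(w)]))[::-1][:1]]
        log.warning("objective surface nearly flat along %s; SEs unreliable", flat)
        diag = np.abs(diag)
    se_log = np.sqrt(diag)
    result.se = {}
    result.ci = {}
    for i, name in enumerate(prob.names):
        est = result.estimates[name]
        if name.startswith("omega_"):
            # search scale is log BSV-SD; report SE on the variance scale
            result.se[name] = est * 2.0 * se_log[i]
            lo, hi = est * math.exp(-2 * 1.96 * se_log[i]), est * math.exp(2 * 1.96 * se_log[i])
        else:
            result.se[name] = est * se_log[i]
            lo, hi = est * math.exp(-1.96 * se_log[i]), est * math.exp(1.96 * se_log[i])
        result.ci[name] = (lo, hi)


def fit_sequential_pppd(dataset: StudyDataset,
                        population: PopulationModel | None = None, *,
                        pk_theta: tuple[str, ...] = PK_THETA,
                        pd_theta: tuple[str, ...] = PD_THETA,
                        pk_omega: tuple[str, ...] = ("CL", "Q", "V1", "V2"),
                        pd_omega: tuple[str, ...] = ("Emax", "Ce50"),
                        method: str = "focei",
                        compute_se: bool = False,
                        **fit_kwargs) -> FitResult:
    """Two-stage sequential PPPD estimation.

    Stage 1 fits the population PK to the concentration channel.  Stage 2
    fixes the PK fixed effects and variances at their stage-1 estimates,
    keeps the concentration data in the likelihood (so PK etas stay
    informed), and estimates the PD and equilibration parameters.
    """
    from .population import default_population

    population = population or default_population()
    pk_spec = ModelSpec(population=population, theta=tuple(pk_theta),
                        omega=tuple(pk_omega),
                        sigma=("prop_conc", "add_conc"),
                        channels=(1,), method=method)
    fit_pk = fit_population(dataset, pk_spec, compute_se=compute_se,
                            **fit_kwargs)
    if not np.isfinite(fit_pk.objective):
        raise NumericError(
            f"stage 1 (PK) failed: objective {fit_pk.objective!r}, "
            f"message {fit_pk.convergence['message']!r}; stage 2 aborted")
    if not fit_pk.convergence["converged"]:
        log.warning("stage 1 (PK) did not formally converge; stage 2 "
                    "proceeds from best-found PK estimates")
    pop2 = fit_pk.to_population()
    pd_spec = ModelSpec(population=pop2, theta=tuple(pd_theta),
                        omega=tuple(pd_omega),
                        sigma=("prop_r", "add_r"),
                        channels=(1, 2), method=method)
    fit_pd = fit_population(dataset, pd_spec, compute_se=compute_se,
                            **fit_kwargs)
    estimates = dict(fit_pk.estimates)
    estimates.update(fit_pd.estimates)
    combined = FitResult(
        estimates=estimates,
        objective=fit_pd.objective,
        etas=fit_pd.etas,
        spec=pd_spec,
        convergence={"stage1": fit_pk.convergence,
                     "stage2": fit_pd.convergence,
                     "converged": (fit_pk.convergence["converged"]
                                   and fit_pd.convergence["converged"])},
        se=fit_pd.se,
        ci=fit_pd.ci,
        stages={"pk": fit_pk, "pd": fit_pd},
    )
    return combined


def compare_models(fit_full: FitResult, fit_reduced: FitResult,
                   df: int) -> LRTResult:
    """Likelihood-ratio comparison of nested fits on the same data.

    Significant at alpha = 0.05 when the objective drop exceeds the
    chi-square 95% quantile (3.84 for one degree of freedom).
    """
    if df < 1:
        raise InvalidInputError("df must be >= 1")
    delta = fit_reduced.objective - fit_full.objective
    if delta < -1e-6:
        warnings.warn("reduced model has a better objective than the full "
                      "model; optimisation failure suspected", RuntimeWarning,
                      stacklevel=2)
    threshold = float(chi2.ppf(0.95, df))
    p_value = float(chi2.sf(max(delta, 0.0), df))
    return LRTResult(delta_obj=float(delta), df=df, threshold=threshold,
                     p_value=p_value, significant=bool(delta > threshold))


def heuristic_pk_initials(dataset: StudyDataset) -> dict[str, float]:
    """Data-derived PK starting values for real datasets.

    Noncompartmental sketch per subject: CL = dose / AUC (trapezoid),
    V1 = dose / first-sample concentration, V2 = 3 V1, Q = CL; values are
    medians across subjects, rescaled to 70 kg.
    """
    from .model import ALLOMETRIC_EXPONENTS, W_STD

    cls, v1s = [], []
    for s in dataset.subject_records(channels=(1,)):
        if s.y.size < 2:
            continue
        dose = float(np.sum(s.events[s.events[:, 3] < 0.5, 1]))
        if dose <= 0:
            continue
        auc = float(np.trapezoid(s.y, s.times))
        cmax = float(np.max(s.y))
        if auc > 0:
            cls.append(dose / auc / (s.weight / W_STD) ** 0.75)
        if cmax > 0:
            v1s.append(dose / cmax / (s.weight / W_STD))
    cl = float(np.median(cls)) if cls else 0.05
    v1 = float(np.median(v1s)) if v1s else 3.0
    return {"CL": cl, "Q": cl, "V1": v1, "V2": 3.0 * v1}
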