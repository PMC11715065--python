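"""Structural PKPD model for dabigatran with idarucizumab reversal.

The disposition model is a two-compartment mammillary system (clearance CL,
intercompartment clearance Q, central volume V1, peripheral volume V2) with
zero-order drug inputs into the central compartment.  An effect compartment
is linked to plasma by the first-order constant keo, reported on the
half-time scale (t_half_keo = ln 2 / keo).  Thromboelastographic reaction
time (R-time) follows a sigmoid Emax function of the effect-site
concentration, and idarucizumab contributes an additive, transient R-time
reduction modelled as a unit-normalised input into a reversal compartment
with first-order elimination.

PK parameters are standardised to a 70-kg body weight with allometric
exponents 0.75 (clearances) and 1 (volumes).  Units package-wide: minutes,
litres, milligrams, mg/L, kg.

Two evaluation paths are exposed: a closed-form superposition of infusion
step responses (default, used inside estimation loops) and an adaptive ODE
integration that serves as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .errors import InvalidInputError, ConfigurationError, NumericError

__all__ = [
    "W_STD", "PARAM_NAMES", "PARAM_INDEX", "ALLOMETRIC_EXPONENTS",
    "PKParameters", "PDParameters", "IdarucizumabParameters", "Subject",
    "DoseEvent", "Regimen", "SimulationResult", "IndividualParameters",
    "scale_parameter", "individual_parameters", "simulate_pk", "effect_site",
    "emax_response", "idarucizumab_effect", "predict_r_time",
    "simulate_response",
]

#: standard body weight (kg) to which population parameters refer
W_STD = 70.0

#: canonical parameter ordering used by the numeric kernels
PARAM_NAMES = ("CL", "Q", "V1", "V2", "t_half_keo",
               "E0", "Emax", "Ce50", "hill",
               "k_ida", "dur_ida", "slope_ida")
PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: allometric exponents; parameters not listed are weight-invariant
ALLOMETRIC_EXPONENTS = {"CL": 0.75, "Q": 0.75, "V1": 1.0, "V2": 1.0}

DABIGATRAN = "dabigatran"
IDARUCIZUMAB = "idarucizumab"


def _require_positive(**values) -> None:
    for name, value in values.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment PK parameters standardised to 70 kg.

    CL, Q in L/min/70 kg; V1, V2 in L/70 kg; t_half_keo in minutes.
    """

    CL: float
    Q: float
    V1: float
    V2: float
    t_half_keo: float

    def __post_init__(self):
        _require_positive(CL=self.CL, Q=self.Q, V1=self.V1, V2=self.V2,
                          t_half_keo=self.t_half_keo)

    @property
    def keo(self) -> float:
        """Plasma to effect-site equilibration rate constant, 1/min."""
        return math.log(2.0) / self.t_half_keo


@dataclass(frozen=True)
class PDParameters:
    """Sigmoid Emax response of R-time to the effect-site concentration."""

    E0: float      # baseline reaction time, min
    Emax: float    # maximal drug-induced increase, min
    Ce50: float    # effect-site concentration at half-maximal effect, mg/L
    hill: float = 1.0

    def __post_init__(self):
        if self.E0 < 0 or not math.isfinite(self.E0):
            raise InvalidInputError(f"E0 must be non-negative, got {self.E0!r}")
        _require_positive(Emax=self.Emax, Ce50=self.Ce50, hill=self.hill)


@dataclass(frozen=True)
class IdarucizumabParameters:
    """Empirical reversal model: unit input, first-order washout, linear slope.

    The reversal compartment is unit-normalised (each idarucizumab dose
    contributes a unit amount over ``dur_ida``), so ``slope_ida`` absorbs the
    scale; proportionality across dose levels is not assumed.
    """

    k_ida: float       # 1/min
    dur_ida: float     # min
    slope_ida: float   # min of R-time per unit reversal amount

    def __post_init__(self):
        _require_positive(k_ida=self.k_ida, dur_ida=self.dur_ida,
                          slope_ida=self.slope_ida)


@dataclass
class Subject:
    """A study subject: identifier, weight and log-scale random effects."""

    id: str
    weight: float
    eta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.weight > 0):
            raise InvalidInputError(f"weight must be positive, got {self.weight!r}")
        for key in self.eta:
            if key not in PARAM_INDEX:
                raise ConfigurationError(f"unknown eta key {key!r}")


@dataclass(frozen=True)
class DoseEvent:
    drug: str
    time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self):
        if self.drug not in (DABIGATRAN, IDARUCIZUMAB):
            raise InvalidInputError(f"unknown drug {self.drug!r}")
        if self.time < 0 or self.amount < 0 or self.duration < 0:
            raise InvalidInputError("dose time, amount and duration must be >= 0")


@dataclass
class Regimen:
    """Ordered zero-order dose events; duration 0 means a near-instant input."""

    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time)

    def add(self, drug: str, time: float, amount: float, duration: float = 0.0):
        self.events.append(DoseEvent(drug, time, amount, duration))
        self.events.sort(key=lambda e: e.time)
        return self

    def has_drug(self, drug: str) -> bool:
        return any(e.drug == drug for e in self.events)

    def to_array(self) -> np.ndarray:
        """(n, 4) float array: start, amount, duration, drug flag (0/1)."""
        out = np.zeros((len(self.events), 4))
        for i, e in enumerate(self.events):
            out[i] = (e.time, e.amount, e.duration,
                      0.0 if e.drug == DABIGATRAN else 1.0)
        return out


@dataclass
class SimulationResult:
    """Trajectories on a time grid (concentrations mg/L, amounts mg)."""

    times: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    Ce: np.ndarray
    C_ida: np.ndarray          # unit-normalised reversal-compartment amount
    R: np.ndarray | None = None
    eliminated: np.ndarray | None = None  # cumulative mg cleared (ODE path)

    @property
    def A1(self) -> np.ndarray:
        return self.C1 * self._v1

    @property
    def A2(self) -> np.ndarray:
        return self.C2 * self._v2

    _v1: float = 1.0
    _v2: float = 1.0


@dataclass(frozen=True)
class IndividualParameters:
    """Subject-scale parameter set (allometry and random effects applied)."""

    pk: PKParameters
    pd: PDParameters
    ida: IdarucizumabParameters

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.pk.CL, self.pk.Q, self.pk.V1, self.pk.V2, self.pk.t_half_keo,
            self.pd.E0, self.pd.Emax, self.pd.Ce50, self.pd.hill,
            self.ida.k_ida, self.ida.dur_ida, self.ida.slope_ida,
        ])


def scale_parameter(p_std: float, w: float, exponent: float) -> float:
    """Allometric scaling: p_std * (w / 70)**exponent."""
    if not (p_std > 0):
        raise InvalidInputError(f"standardised parameter must be positive, got {p_std!r}")
    if not (w > 0):
        raise InvalidInputError(f"weight must be positive, got {w!r}")
    return p_std * (w / W_STD) ** exponent


def typical_vector(values: dict[str, float], weight: float) -> np.ndarray:
    """Kernel parameter vector of subject-scale typical values.

    ``values`` maps every name in PARAM_NAMES to its 70-kg standardised
    value; allometry is applied to CL, Q (exp 0.75) and V1, V2 (exp 1).
    """
    p = np.empty(len(PARAM_NAMES))
    for name, i in PARAM_INDEX.items():
        v = values[name]
        exp = ALLOMETRIC_EXPONENTS.get(name)
        p[i] = scale_parameter(v, weight, exp) if exp is not None else v
    return p


def individual_parameters(pop, subject: Subject) -> IndividualParameters:
    """Subject-level parameters: allometric scaling times exp(eta).

    ``pop`` is a PopulationModel (or anything with pk/pd/ida attributes).
    """
    values = {
        "CL": pop.pk.CL, "Q": pop.pk.Q, "V1": pop.pk.V1, "V2": pop.pk.V2,
        "t_half_keo": pop.pk.t_half_keo,
        "E0": pop.pd.E0, "Emax": pop.pd.Emax, "Ce50": pop.pd.Ce50,
        "hill": pop.pd.hill,
        "k_ida": pop.ida.k_ida, "dur_ida": pop.ida.dur_ida,
        "slope_ida": pop.ida.slope_ida,
    }
    p = typical_vector(values, subject.weight)
    for key, eta in subject.eta.items():
        p[PARAM_INDEX[key]] *= math.exp(eta)
    return IndividualParameters(
        pk=PKParameters(*p[0:5]),
        pd=PDParameters(*p[5:9]),
        ida=IdarucizumabParameters(*p[9:12]),
    )


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise InvalidInputError("time grid must be a non-empty 1-D array")
    if np.any(times < 0):
        raise InvalidInputError("time grid must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("time grid must be strictly increasing")
    return times


def simulate_pk(params: PKParameters, regimen: Regimen, times,
                ida: IdarucizumabParameters | None = None,
                method: str = "closed") -> SimulationResult:
    """Simulate concentration channels for one subject-scale parameter set.

    ``method`` is "closed" (bi-exponential superposition, default) or "ode"
    (adaptive LSODA integration, the slower oracle path).  ``ida`` is
    required when the regimen contains idarucizumab events.
    """
    times = _check_times(times)
    if regimen.has_drug(IDARUCIZUMAB) and ida is None:
        raise InvalidInputError(
            "regimen contains idarucizumab events; pass IdarucizumabParameters")
    k_ida = ida.k_ida if ida is not None else 1.0
    dur_ida = ida.dur_ida if ida is not None else 1.0
    events = regimen.to_array()
    if method == "closed":
        C1, A2, Ce, Aida = _kernels.profiles(
            times, events, params.CL, params.Q, params.V1, params.V2,
            params.keo, k_ida, dur_ida)
        res = SimulationResult(times=times, C1=C1, C2=A2 / params.V2, Ce=Ce,
                               C_ida=Aida)
    elif method == "ode":
        res = _simulate_ode(params, events, times, k_ida, dur_ida)
    else:
        raise InvalidInputError(f"unknown simulation method {method!r}")
    res._v1 = params.V1
    res._v2 = params.V2
    return res


def _input_breakpoints(events: np.ndarray, dur_ida: float) -> list[float]:
    pts = set()
    for ts, amt, dur, drug in events:
        if drug < 0.5:
            d = max(dur, _kernels.MIN_DURATION)
        else:
            d = max(dur_ida, _kernels.MIN_DURATION)
        pts.add(float(ts))
        pts.add(float(ts + d))
    return sorted(pts)


def _simulate_ode(params: PKParameters, events: np.ndarray, times: np.ndarray,
                  k_ida: float, dur_ida: float) -> SimulationResult:
    CL, Q, V1, V2 = params.CL, params.Q, params.V1, params.V2
    keo = params.keo

    def rates_at(t: float) -> tuple[float, float]:
        r_dabi = 0.0
        r_ida = 0.0
        for ts, amt, dur, drug in events:
            if drug < 0.5:
                d = max(dur, _kernels.MIN_DURATION)
                if ts <= t < ts + d:
                    r_dabi += amt / d
            else:
                d = max(dur_ida, _kernels.MIN_DURATION)
                if ts <= t < ts + d:
                    r_ida += 1.0 / d
        return r_dabi, r_ida

    def rhs(t, state):
        a1, a2, ce, aida, elim = state
        c1 = a1 / V1
        c2 = a2 / V2
        r_dabi, r_ida = rates_at(t)
        return [
            r_dabi + Q * c2 - (CL + Q) * c1,
            Q * (c1 - c2),
            keo * (c1 - ce),
            r_ida - k_ida * aida,
            CL * c1,
        ]

    # integrate piecewise between input discontinuities for accuracy
    breaks = _input_breakpoints(events, dur_ida)
    edges = sorted(set([0.0, float(times[-1])] + [b for b in breaks
                                                  if 0.0 < b < times[-1]]))
    state = np.zeros(5)
    out = np.zeros((5, times.size))
    for lo, hi in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(rhs, (lo, hi), state, method="LSODA",
                        dense_output=True, rtol=1e-9, atol=1e-11)
        if not sol.success:
            raise NumericError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        mask = (times > lo) & (times <= hi)
        if np.any(mask):
            out[:, mask] = sol.sol(times[mask])
        state = sol.y[:, -1]
    return SimulationResult(times=times, C1=out[0] / V1, C2=out[1] / V2,
                            Ce=out[2], C_ida=out[3], eliminated=out[4])


def effect_site(times, c1_trajectory, keo: float) -> np.ndarray:
    """First-order lag of a plasma trajectory, exact for piecewise-linear C1.

    Solves dCe/dt = keo (C1 - Ce) with Ce(0) = 0, treating ``c1_trajectory``
    as linear between grid points.
    """
    if not (keo > 0):
        raise InvalidInputError(f"keo must be positive, got {keo!r}")
    times = np.asarray(times, dtype=float)
    c1 = np.asarray(c1_trajectory, dtype=float)
    if times.shape != c1.shape:
        raise InvalidInputError("times and c1_trajectory must have equal shape")
    ce = np.zeros_like(c1)
    for j in range(1, c1.size):
        dt = times[j] - times[j - 1]
        slope = (c1[j] - c1[j - 1]) / dt
        ek = math.exp(-keo * dt)
        # exact step for linear input: particular + homogeneous parts
        ce[j] = (c1[j] - slope / keo
                 + (ce[j - 1] - c1[j - 1] + slope / keo) * ek)
    return ce


def emax_response(ce, pd: PDParameters):
    """Sigmoid Emax R-time effect: E0 + Emax ce^N / (Ce50^N + ce^N)."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise InvalidInputError("effect-site concentration must be >= 0")
    cn = np.power(ce_arr, pd.hill, where=ce_arr > 0,
                  out=np.zeros_like(ce_arr, dtype=float))
    out = pd.E0 + pd.Emax * cn / (pd.Ce50 ** pd.hill + cn)
    return float(out) if np.isscalar(ce) else out


def idarucizumab_effect(regimen: Regimen, ida: IdarucizumabParameters,
                        times) -> np.ndarray:
    """Reversal-effect trajectory in minutes of R-time; zero or negative."""
    times = _check_times(times)
    events = regimen.to_array()
    _, _, _, aida = _kernels.profiles(times, events, 1.0, 1.0, 1.0, 1.0, 1.0,
                                      ida.k_ida, ida.dur_ida)
    return -ida.slope_ida * aida


def predict_r_time(sim: SimulationResult, pd: PDParameters,
                   ida: IdarucizumabParameters | None = None) -> np.ndarray:
    """R-time trajectory: sigmoid Emax effect plus reversal, floored at 0."""
    r = emax_response(sim.Ce, pd)
    if ida is not None:
        r = r - ida.slope_ida * sim.C_ida
    elif np.any(sim.C_ida > 0):
        raise InvalidInputError(
            "simulation carries a reversal compartment; pass IdarucizumabParameters")
    return np.maximum(np.asarray(r, dtype=float), 0.0)


def simulate_response(params: IndividualParameters, regimen: Regimen, times,
                      method: str = "closed") -> SimulationResult:
    """Full simulation (concentrations and R-time) for one subject."""
    sim = simulate_pk(params.pk, regimen, times, ida=params.ida, method=method)
    sim.R = predict_r_time(sim, params.pd, params.ida)
    return sim
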