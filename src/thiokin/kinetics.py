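"""Branching sequential rate-equation model of disulfide photolysis.

The reaction scheme describes UV photolysis of an aliphatic disulfide
(L-cystine) in solution: an optically excited parent (population ``N1``)
decays with time constant ``tau1`` into a pair of geminate thiyl radicals
(``N2``).  The thiyl population splits into three sub-ensembles that
recombine with time constants ``tau21``, ``tau22`` or not at all within the
observation window (relative yields ``q21``, ``q22``, ``q23``).
Recombination produces a vibrationally excited parent (``N3``) which either
relaxes back to the cold ground state (yield ``q31``, time constant
``tau31``) or fragments along a C-S bond into a perthiyl radical (``N4``,
yield ``q32 = 1 - q31``, time constant ``tau32``).  Perthiyl radicals in
turn recombine to the cold parent with yield ``q41`` and time constant
``tau41`` or persist (``q42 = 1 - q41``).  ``N0`` is the recovered cold
ground state.

Every sub-chain ``N1 -> N2i -> N3j (-> N4j') -> N0`` is a linear decay
cascade, so its populations are sums of exponentials with partial-fraction
amplitudes (Bateman solutions).  This module represents those solutions
symbolically as sums of ``c * t**m * exp(-k*t)`` terms, which makes the
Gaussian instrument-response convolution exact: each term maps onto a
closed-form exponentially-modified-Gaussian profile.  Nearly degenerate
rates are handled by the confluent ``t*exp`` limit instead of diverging
partial fractions.

Time unit is picoseconds throughout.  A non-decaying sub-ensemble is
expressed with ``tau = math.inf`` (an explicit sentinel, never a huge
float).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import erfc, erfcx

__all__ = [
    "IRFModel",
    "KineticParameters",
    "PopulationTrajectory",
    "quadrature_irf_width",
    "exp_gauss",
    "solve_populations",
    "ode_oracle",
    "recombined_fraction",
    "asymptotic_recovery",
]

#: Two cascade rates closer than this (relative) are treated as equal and
#: solved with the confluent t*exp formula; partial-fraction amplitudes
#: diverge as the rates merge.
RATE_DEGENERACY_RTOL = 1e-9

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


class InvalidInputError(ValueError):
    """Raised for physically or structurally invalid inputs."""


# ---------------------------------------------------------------------------
# IRF
# ---------------------------------------------------------------------------


def quadrature_irf_width(components: Sequence[float]) -> float:
    """Combine independent Gaussian broadening contributions in quadrature.

    Parameters
    ----------
    components
        Individual Gaussian widths (same unit, e.g. ps): pulse durations,
        group-velocity-mismatch broadening, timing jitter.

    Returns
    -------
    float
        ``sqrt(sum(c**2))`` — the standard deviation of the combined
        Gaussian instrument response.
    """
    comps = list(components)
    if not comps:
        raise InvalidInputError("need at least one IRF component")
    if any((not math.isfinite(c)) or c <= 0 for c in comps):
        raise InvalidInputError(f"IRF components must be positive and finite, got {comps}")
    return math.sqrt(math.fsum(c * c for c in comps))


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: standard deviation ``sigma`` and
    zero-delay offset ``t0``, both in ps.

    ``components`` optionally records the individual quadrature
    contributions (label, width) that make up ``sigma``; it is bookkeeping
    only and never enters the convolution.
    """

    sigma: float
    t0: float = 0.0
    components: Optional[Tuple[Tuple[str, float], ...]] = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0) or not math.isfinite(self.sigma):
            raise InvalidInputError(f"IRF sigma must be positive, got {self.sigma}")
        if not math.isfinite(self.t0):
            raise InvalidInputError("IRF t0 must be finite")
        if self.components is not None:
            if any(w <= 0 for _, w in self.components):
                raise InvalidInputError("IRF quadrature components must be positive")

    @classmethod
    def from_components(
        cls, components: Sequence[Tuple[str, float]], t0: float = 0.0
    ) -> "IRFModel":
        comps = tuple(components)
        sigma = quadrature_irf_width([w for _, w in comps])
        return cls(sigma=sigma, t0=t0, components=comps)


# ---------------------------------------------------------------------------
# Kinetic parameters
# ---------------------------------------------------------------------------

_TAU_KEYS = ("tau1", "tau21", "tau22", "tau23", "tau31", "tau32", "tau41", "tau42")
_Q_KEYS = ("q21", "q22", "q31", "q41")


def _check_tau(name: str, value: float) -> None:
    if value == math.inf:
        return
    if not (math.isfinite(value) and value > 0):
        raise InvalidInputError(f"{name} must be > 0 (or math.inf), got {value}")


def _check_q(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise InvalidInputError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class KineticParameters:
    """Time constants (ps) and relative branching yields of the scheme.

    The three thiyl sub-ensembles have yields ``(q21, q22, q23)`` with
    ``q23 = 1 - q21 - q22`` enforced at construction; ``tau23 = inf`` marks
    the non-recombining fraction.  Likewise ``q32 = 1 - q31`` and
    ``q42 = 1 - q41``, with ``tau42 = inf`` for persistent perthiyl
    radicals.
    """

    tau1: float
    q21: float
    tau21: float
    q22: float
    tau22: float
    tau23: float = math.inf
    q31: float = 0.5
    tau31: float = 1.0
    tau32: float = 1.0
    q41: float = 0.5
    tau41: float = 1.0
    tau42: float = math.inf

    def __post_init__(self) -> None:
        for key in _TAU_KEYS:
            _check_tau(key, getattr(self, key))
        for key in _Q_KEYS:
            _check_q(key, getattr(self, key))
        if self.q21 + self.q22 > 1.0 + 1e-12:
            raise InvalidInputError(
                f"q21 + q22 = {self.q21 + self.q22} exceeds 1; thiyl yields must sum to 1"
            )

    # -- derived yields ----------------------------------------------------
    @property
    def q23(self) -> float:
        return 1.0 - self.q21 - self.q22

    @property
    def q32(self) -> float:
        return 1.0 - self.q31

    @property
    def q42(self) -> float:
        return 1.0 - self.q41

    @property
    def thiyl_branches(self) -> List[Tuple[float, float]]:
        """[(q2i, tau2i)] for the three thiyl sub-ensembles."""
        return [(self.q21, self.tau21), (self.q22, self.tau22), (self.q23, self.tau23)]

    @property
    def ves_branches(self) -> List[Tuple[float, float]]:
        return [(self.q31, self.tau31), (self.q32, self.tau32)]

    @property
    def perthiyl_branches(self) -> List[Tuple[float, float]]:
        return [(self.q41, self.tau41), (self.q42, self.tau42)]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> Dict[str, float]:
        d = {key: getattr(self, key) for key in ("tau1",) + _TAU_KEYS[1:]}
        d.update({key: getattr(self, key) for key in _Q_KEYS})
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "KineticParameters":
        known = set(_TAU_KEYS) | set(_Q_KEYS)
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown kinetic parameter keys: {sorted(unknown)}")
        kwargs = {k: float(v) for k, v in d.items()}
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Exponential-polynomial term algebra
# ---------------------------------------------------------------------------
# Each causal signal is a sum of terms  c * t**m * exp(-k*t) * H(t).
# Convolution with a further exponential stage, integration to a sink, and
# convolution with a Gaussian IRF are all closed under this representation.


@dataclass(frozen=True)
class _Term:
    c: float  # coefficient
    m: int  # power of t
    k: float  # decay rate >= 0 (k = 0 encodes a step/constant)


def _rates_equal(a: float, b: float) -> bool:
    scale = max(abs(a), abs(b))
    if scale == 0.0:
        return True
    return abs(a - b) <= RATE_DEGENERACY_RTOL * scale


def _merge(terms: List[_Term]) -> List[_Term]:
    """Combine terms with identical (m, k); keeps the representation small."""
    out: List[_Term] = []
    for t in terms:
        if abs(t.c) == 0.0:
            continue
        for i, u in enumerate(out):
            if u.m == t.m and _rates_equal(u.k, t.k):
                out[i] = _Term(u.c + t.c, u.m, u.k)
                break
        else:
            out.append(t)
    return out


def _convolve_decay(terms: List[_Term], k_next: float) -> List[_Term]:
    """Causal convolution ``exp(-k_next*t)*H(t)  *  f(t)``.

    For a term c*t**m*exp(-a*t) with a nearly equal to k_next the confluent
    limit c*t**(m+1)/(m+1)*exp(-k_next*t) is used.
    """
    out: List[_Term] = []
    for t in terms:
        a, b, c, m = t.k, k_next, t.c, t.m
        if _rates_equal(a, b):
            out.append(_Term(c / (m + 1), m + 1, b))
            continue
        d = a - b
        fact_m = math.factorial(m)
        out.append(_Term(c * fact_m / d ** (m + 1), 0, b))
        for r in range(m + 1):
            out.append(_Term(-c * (fact_m / math.factorial(r)) / d ** (m + 1 - r), r, a))
    return _merge(out)


def _integrate(terms: List[_Term]) -> List[_Term]:
    """Running integral ``int_0^t f(s) ds`` for t >= 0."""
    out: List[_Term] = []
    for t in terms:
        a, c, m = t.k, t.c, t.m
        if _rates_equal(a, 0.0):
            out.append(_Term(c / (m + 1), m + 1, 0.0))
            continue
        fact_m = math.factorial(m)
        out.append(_Term(c * fact_m / a ** (m + 1), 0, 0.0))
        for r in range(m + 1):
            out.append(_Term(-c * (fact_m / math.factorial(r)) / a ** (m + 1 - r), r, a))
    return _merge(out)


def _scale(terms: List[_Term], w: float) -> List[_Term]:
    return [_Term(t.c * w, t.m, t.k) for t in terms]


def _chain_state(rates: Sequence[float], n: int) -> List[_Term]:
    """Population of state ``n`` of the cascade 0 -> 1 -> ... with decay
    rates ``rates[0..n]`` and unit initial population in state 0.

    The influx into state n carries the factor ``rates[n-1]``; a frozen
    upstream state (rate 0) therefore feeds nothing downstream.
    """
    terms: List[_Term] = [_Term(1.0, 0, rates[0])]
    for i in range(1, n + 1):
        if rates[i - 1] == 0.0:
            return []
        terms = _scale(_convolve_decay(terms, rates[i]), rates[i - 1])
    return terms


def _chain_sink(rates: Sequence[float], n: int) -> List[_Term]:
    """Accumulated sink population fed by the decay of state ``n``."""
    if rates[n] == 0.0:
        return []
    return _scale(_integrate(_chain_state(rates, n)), rates[n])


# ---------------------------------------------------------------------------
# Gaussian-convolved exponentials
# ---------------------------------------------------------------------------


def _exp_gauss_basis(u: np.ndarray, k: float, sigma: float, m_max: int) -> List[np.ndarray]:
    """E_m(u) = (t**m exp(-k t) H(t)) convolved with a unit-area Gaussian,
    for m = 0..m_max, evaluated at u = t - t0.

    E_0 uses the scaled complementary error function where the plain
    erfc form would lose precision (large sigma*k); higher orders follow
    the derivative recurrence E_{m+1} = (u - sigma^2 k) E_m + m sigma^2
    E_{m-1}, seeded with E_1 = (u - sigma^2 k) E_0 + sigma^2 g(u).
    """
    u = np.asarray(u, dtype=float)
    gauss = np.exp(-(u * u) / (2.0 * sigma * sigma)) / (sigma * _SQRT2PI)
    if k == 0.0:
        e0 = 0.5 * erfc(-u / (sigma * _SQRT2))
        if m_max > 0:
            raise InvalidInputError("polynomial step terms cannot be IRF-convolved")
        return [e0]
    b = sigma * k - u / sigma
    # b > 0: erfcx form (both factors bounded); b <= 0: direct form, whose
    # exponent k*(sigma^2 k/2 - u) is then <= -sigma^2 k^2 / 2 < 0.
    with np.errstate(over="ignore"):
        direct = 0.5 * np.exp(np.minimum(k * (0.5 * sigma * sigma * k - u), 0.0)) * erfc(
            b / _SQRT2
        )
    scaled = 0.5 * erfcx(np.maximum(b, 0.0) / _SQRT2) * np.exp(-(u * u) / (2.0 * sigma * sigma))
    e0 = np.where(b > 0, scaled, direct)
    basis = [e0]
    if m_max >= 1:
        basis.append((u - sigma * sigma * k) * e0 + sigma * sigma * gauss)
    for m in range(1, m_max):
        basis.append((u - sigma * sigma * k) * basis[m] + m * sigma * sigma * basis[m - 1])
    return basis


def exp_gauss(
    t: np.ndarray, tau: float, sigma: float, t0: float = 0.0
) -> np.ndarray:
    """Causal exponential decay convolved with a unit-area Gaussian IRF.

    Returns ``exp(-(t-t0)/tau) H(t-t0)  *  N(0, sigma^2)`` — the
    exponentially modified Gaussian
    ``0.5 * exp(sigma^2/(2 tau^2) - (t-t0)/tau) * erfc((sigma/tau - (t-t0)/sigma)/sqrt(2))``,
    evaluated through the scaled complementary error function where
    required for stability.  ``tau = math.inf`` yields the Gaussian
    cumulative step; ``sigma = 0`` yields the bare causal exponential.
    """
    t = np.asarray(t, dtype=float)
    if tau != math.inf and not (tau > 0):
        raise InvalidInputError(f"tau must be positive or math.inf, got {tau}")
    if sigma < 0:
        raise InvalidInputError(f"sigma must be >= 0, got {sigma}")
    u = t - t0
    if sigma == 0.0:
        if tau == math.inf:
            return np.where(u >= 0, 1.0, 0.0)
        with np.errstate(over="ignore"):
            return np.where(u >= 0, np.exp(-np.maximum(u, 0.0) / tau), 0.0)
    k = 0.0 if tau == math.inf else 1.0 / tau
    return _exp_gauss_basis(u, k, sigma, 0)[0]


def _evaluate_terms(
    terms: List[_Term], times: np.ndarray, irf: Optional[IRFModel]
) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    if not terms:
        return out
    if irf is None:
        pos = times >= 0
        tp = times[pos]
        acc = np.zeros_like(tp)
        for t in terms:
            with np.errstate(over="ignore"):
                acc += t.c * tp**t.m * np.exp(-t.k * tp)
        out[pos] = acc
        return out
    # group by rate so the E_m recurrence is evaluated once per rate
    u = times - irf.t0
    by_rate: Dict[float, List[_Term]] = {}
    for t in terms:
        for kk in by_rate:
            if _rates_equal(kk, t.k):
                by_rate[kk].append(t)
                break
        else:
            by_rate[t.k] = [t]
    for kk, group in by_rate.items():
        m_max = max(t.m for t in group)
        basis = _exp_gauss_basis(u, kk, irf.sigma, m_max)
        for t in group:
            out += t.c * basis[t.m]
    return out


# ---------------------------------------------------------------------------
# Population solver
# ---------------------------------------------------------------------------


@dataclass
class PopulationTrajectory:
    """Species populations on a time grid, per unit initial excitation.

    ``components`` holds the raw (unweighted) sub-ensemble solutions, keyed
    ``"N21"``, ``"N32^21"``, ``"N41^22"``, ``"N031^21"``, ...; the aggregate
    species arrays apply the branching yields.
    """

    times: np.ndarray
    N1: np.ndarray
    N2: np.ndarray
    N3: np.ndarray
    N4: np.ndarray
    N0: np.ndarray
    components: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.N1 + self.N2 + self.N3 + self.N4 + self.N0

    def to_frame(self):
        """Trajectory as a pandas DataFrame (time + one column per species)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ps": self.times,
                "N1": self.N1,
                "N2": self.N2,
                "N3": self.N3,
                "N4": self.N4,
                "N0": self.N0,
            }
        )


def _species_terms(params: KineticParameters) -> Dict[str, List[_Term]]:
    """Symbolic solutions for every species and sub-ensemble."""
    k1 = 1.0 / params.tau1
    k2 = [0.0 if tau == math.inf else 1.0 / tau for _, tau in params.thiyl_branches]
    k31 = 1.0 / params.tau31
    k32 = 1.0 / params.tau32
    k4 = [
        0.0 if params.tau41 == math.inf else 1.0 / params.tau41,
        0.0 if params.tau42 == math.inf else 1.0 / params.tau42,
    ]
    q2 = [q for q, _ in params.thiyl_branches]
    q3 = [params.q31, params.q32]
    q4 = [params.q41, params.q42]
    k3 = [k31, k32]

    species: Dict[str, List[_Term]] = {"N1": [_Term(1.0, 0, k1)]}
    agg: Dict[str, List[_Term]] = {"N2": [], "N3": [], "N4": [], "N0": []}

    for i in range(3):
        c2 = _chain_state([k1, k2[i]], 1)
        species[f"N2{i + 1}"] = c2
        agg["N2"].extend(_scale(c2, q2[i]))
        for j in range(2):
            c3 = _chain_state([k1, k2[i], k3[j]], 2)
            species[f"N3{j + 1}^2{i + 1}"] = c3
            agg["N3"].extend(_scale(c3, q3[j] * q2[i]))
        s31 = _chain_sink([k1, k2[i], k31], 2)
        species[f"N031^2{i + 1}"] = s31
        agg["N0"].extend(_scale(s31, params.q31 * q2[i]))
        for jp in range(2):
            c4 = _chain_state([k1, k2[i], k32, k4[jp]], 3)
            species[f"N4{jp + 1}^2{i + 1}"] = c4
            agg["N4"].extend(_scale(c4, q4[jp] * params.q32 * q2[i]))
            s4 = _chain_sink([k1, k2[i], k32, k4[jp]], 3)
            species[f"N04{jp + 1}^2{i + 1}"] = s4
            agg["N0"].extend(_scale(s4, q4[jp] * params.q32 * q2[i]))

    for name, terms in agg.items():
        species[name] = _merge(terms)
    return species


def solve_populations(
    params: KineticParameters,
    times: np.ndarray,
    irf: Optional[IRFModel] = None,
) -> PopulationTrajectory:
    """Analytic species populations of the branching cascade.

    Each sub-chain is solved in closed form (sums of exponentials; the
    confluent ``t*exp`` limit for nearly degenerate rates).  When ``irf``
    is given, every exponential term is replaced by its Gaussian-convolved
    counterpart, so the result is the exact convolution of the IRF-free
    solution with the instrument response.

    Initial conditions: ``N1(0) = 1``, all other populations zero.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise InvalidInputError("times must be a 1-D array")
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise InvalidInputError("times must be sorted in increasing order")
    species = _species_terms(params)
    arrays = {name: _evaluate_terms(terms, times, irf) for name, terms in species.items()}
    components = {
        name: arr for name, arr in arrays.items() if name not in ("N1", "N2", "N3", "N4", "N0")
    }
    return PopulationTrajectory(
        times=times,
        N1=arrays["N1"],
        N2=arrays["N2"],
        N3=arrays["N3"],
        N4=arrays["N4"],
        N0=arrays["N0"],
        components=components,
    )


# ---------------------------------------------------------------------------
# ODE verification twin
# ---------------------------------------------------------------------------


def ode_oracle(params: KineticParameters, times: np.ndarray) -> PopulationTrajectory:
    """Direct stiff numerical integration of the rate equations.

    Verification twin of :func:`solve_populations` (IRF-free): integrates
    the full sub-ensemble system with tight tolerances.  Intended for
    testing; orders of magnitude slower than the analytic solver.
    """
    times = np.asarray(times, dtype=float)
    k1 = 1.0 / params.tau1
    k2 = [0.0 if tau == math.inf else 1.0 / tau for _, tau in params.thiyl_branches]
    k3 = [1.0 / params.tau31, 1.0 / params.tau32]
    k4 = [
        0.0 if params.tau41 == math.inf else 1.0 / params.tau41,
        0.0 if params.tau42 == math.inf else 1.0 / params.tau42,
    ]

    # state layout: N1 | N2i (3) | N3j^2i (6) | N4j^2i (6) | N031^2i (3) | N04j^2i (6)
    n_state = 1 + 3 + 6 + 6 + 3 + 6

    def idx_n3(i: int, j: int) -> int:
        return 4 + 2 * i + j

    def idx_n4(i: int, jp: int) -> int:
        return 10 + 2 * i + jp

    def idx_s31(i: int) -> int:
        return 16 + i

    def idx_s4(i: int, jp: int) -> int:
        return 19 + 2 * i + jp

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n_state)
        dy[0] = -k1 * y[0]
        for i in range(3):
            dy[1 + i] = k1 * y[0] - k2[i] * y[1 + i]
            for j in range(2):
                dy[idx_n3(i, j)] = k2[i] * y[1 + i] - k3[j] * y[idx_n3(i, j)]
            dy[idx_s31(i)] = k3[0] * y[idx_n3(i, 0)]
            for jp in range(2):
                dy[idx_n4(i, jp)] = k3[1] * y[idx_n3(i, 1)] - k4[jp] * y[idx_n4(i, jp)]
                dy[idx_s4(i, jp)] = k4[jp] * y[idx_n4(i, jp)]
        return dy

    y0 = np.zeros(n_state)
    y0[0] = 1.0
    t_pos = times[times >= 0]
    t_end = float(t_pos[-1]) if t_pos.size else 1.0
    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-12)),
        y0,
        method="LSODA",
        t_eval=t_pos if t_pos.size else None,
        rtol=1e-11,
        atol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed for parameters {params.to_dict()}: {sol.message}"
        )

    q2 = [q for q, _ in params.thiyl_branches]
    q3 = [params.q31, params.q32]
    q4 = [params.q41, params.q42]

    def full(values_pos: np.ndarray) -> np.ndarray:
        out = np.zeros_like(times)
        out[times >= 0] = values_pos
        return out

    y = sol.y
    N1 = full(y[0])
    N2 = full(sum(q2[i] * y[1 + i] for i in range(3)))
    N3 = full(sum(q3[j] * q2[i] * y[idx_n3(i, j)] for i in range(3) for j in range(2)))
    N4 = full(
        sum(q4[jp] * params.q32 * q2[i] * y[idx_n4(i, jp)] for i in range(3) for jp in range(2))
    )
    N0 = full(
        sum(params.q31 * q2[i] * y[idx_s31(i)] for i in range(3))
        + sum(
            q4[jp] * params.q32 * q2[i] * y[idx_s4(i, jp)]
            for i in range(3)
            for jp in range(2)
        )
    )
    return PopulationTrajectory(times=times, N1=N1, N2=N2, N3=N3, N4=N4, N0=N0)


# ---------------------------------------------------------------------------
# Derived scalar quantities
# ---------------------------------------------------------------------------


def recombined_fraction(params: KineticParameters, t: float) -> float:
    """Fraction of the thiyl radicals formed by time ``t`` that have left
    the thiyl state (recombined), IRF-free.

    Thiyl formed by time t equals ``1 - N1(t)``; of that, ``N2(t)`` still
    resides in the thiyl state, so the recombined fraction is
    ``(1 - N1 - N2) / (1 - N1)`` with the 0/0 limit at t = 0 defined as 0.
    """
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    traj = solve_populations(params, np.array([float(t)]))
    formed = 1.0 - traj.N1[0]
    if formed <= 0.0:
        return 0.0
    return float((formed - traj.N2[0]) / formed)


def asymptotic_recovery(params: KineticParameters) -> float:
    """Closed-form ground-state recovery ``N0(t -> inf)``.

    Only thiyl sub-ensembles with finite recombination time feed the
    vibrationally excited parent; of those, the fraction ``q31`` relaxes
    directly and the fraction ``q32`` forms perthiyl radicals, of which
    only branches with finite ``tau4j`` return to the ground state.
    """
    finite_thiyl = sum(q for q, tau in params.thiyl_branches if tau != math.inf)
    finite_perthiyl = sum(q for q, tau in params.perthiyl_branches if tau != math.inf)
    return finite_thiyl * (params.q31 + params.q32 * finite_perthiyl)
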