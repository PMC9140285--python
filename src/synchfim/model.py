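"""Ternary pairwise maximum-entropy model of multi-neuron activity.

Each neuron occupies one of three states, conventionally the sign of its
activity derivative: down (-1), flat (0), up (+1).  The pairwise model is a
Potts-like Boltzmann distribution

    p(s) = exp(-E(s)) / Z,
    E(s) = - sum_{m<t} J_mt * d(s_m, s_t) - sum_k sum_m h_mk * d(k, s_m),

where d is the Kronecker delta, h_mk biases neuron m toward state k, and the
single agreement coupling J_mt rewards (or penalises, if negative) neurons m
and t occupying the same state.  The sufficient statistics are the per-neuron
state frequencies r_k(s_m) and the pairwise agreement probabilities
<d(s_m, s_t)>.

Because the three state indicators of a neuron sum to one, the fields carry a
gauge freedom: adding a constant to all three h_m* leaves p unchanged.  The
reference gauge fixes h_{m,0} = 0, which makes the parameter count
2N + N(N-1)/2 match the number of independent constraints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: Ternary state values in canonical order; column k of ``h`` and of ``r``
#: refers to STATE_VALUES[k].
STATE_VALUES = (-1, 0, 1)

#: Largest N for which full 3^N enumeration is attempted (3^12 ~ 531k states).
ENUM_LIMIT = 12

#: Tag of the reference gauge h_{m,0} = 0.
GAUGE_REFERENCE = "h0"


class EnumerationLimitError(ValueError):
    """Raised when an exact (enumerated) path is requested for N above the limit.

    Callers should fall back to the Monte Carlo path."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class StateMatrix:
    """T x N matrix of ternary states, one row per (assumed independent) sample."""

    values: np.ndarray
    neuron_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("StateMatrix values must be 2-D (time x neurons)")
        if self.values.shape[0] < 1:
            raise ValueError("StateMatrix needs at least one sample (T >= 1)")
        if not np.isin(self.values, STATE_VALUES).all():
            bad = np.argwhere(~np.isin(self.values, STATE_VALUES))
            locs = [(int(r), int(c)) for r, c in bad[:5]]
            raise ValueError(
                f"StateMatrix cells must be in {{-1, 0, 1}}; offending (row, col): {locs}"
            )
        self.values = self.values.astype(np.int8)
        if self.neuron_ids is None:
            self.neuron_ids = [f"n{m}" for m in range(self.values.shape[1])]
        self.neuron_ids = list(self.neuron_ids)
        if len(self.neuron_ids) != self.values.shape[1]:
            raise ValueError("neuron_ids length must match the number of columns")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]


@dataclass
class PottsModel:
    """Pairwise maximum-entropy model: fields ``h`` (N x 3) and couplings ``J``.

    ``J`` is symmetric with a zero diagonal.  ``gauge`` records the field
    convention; in the reference gauge ``h[:, 1]`` (state 0) is identically 0.
    """

    h: np.ndarray
    J: np.ndarray
    gauge: str = GAUGE_REFERENCE

    def __post_init__(self) -> None:
        self.h = np.array(self.h, dtype=float)
        self.J = np.array(self.J, dtype=float)
        if self.h.ndim != 2 or self.h.shape[1] != 3:
            raise ValueError("h must be N x 3")
        N = self.h.shape[0]
        if self.J.shape != (N, N):
            raise ValueError("J must be N x N")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-12):
            raise ValueError("J must have a zero diagonal")
        self.J = (self.J + self.J.T) / 2.0
        np.fill_diagonal(self.J, 0.0)
        if self.gauge == GAUGE_REFERENCE and not np.allclose(self.h[:, 1], 0.0, atol=1e-12):
            raise ValueError("reference gauge requires h_{m,0} = 0 for all m")

    @property
    def N(self) -> int:
        return self.h.shape[0]

    def to_reference_gauge(self) -> "PottsModel":
        """Return an equivalent model with h_{m,0} = 0 (subtract h_{m,0} row-wise)."""
        h = self.h - self.h[:, 1][:, None]
        return PottsModel(h=h, J=self.J.copy(), gauge=GAUGE_REFERENCE)


@dataclass
class ObservableSet:
    """Sufficient statistics: state frequencies ``r`` and agreement matrix ``agree``.

    ``r[m, k]`` is the probability neuron m is in state STATE_VALUES[k]; rows
    sum to 1.  ``agree[m, t]`` is the probability neurons m and t share a
    state; symmetric with unit diagonal.
    """

    r: np.ndarray
    agree: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.array(self.r, dtype=float)
        self.agree = np.array(self.agree, dtype=float)
        N = self.r.shape[0]
        if self.r.shape != (N, 3):
            raise ValueError("r must be N x 3")
        if self.agree.shape != (N, N):
            raise ValueError("agree must be N x N")
        if not np.allclose(self.r.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of r must sum to 1")
        if (self.r < -1e-15).any() or (self.r > 1 + 1e-15).any():
            raise ValueError("r entries must lie in [0, 1]")
        if (self.agree < -1e-15).any() or (self.agree > 1 + 1e-15).any():
            raise ValueError("agree entries must lie in [0, 1]")
        if not np.allclose(self.agree, self.agree.T, atol=1e-12):
            raise ValueError("agree must be symmetric")
        if not np.allclose(np.diag(self.agree), 1.0, atol=1e-12):
            raise ValueError("agree must have a unit diagonal")

    @property
    def N(self) -> int:
        return self.r.shape[0]

    def copy(self) -> "ObservableSet":
        return ObservableSet(r=self.r.copy(), agree=self.agree.copy())


# ---------------------------------------------------------------------------
# Parameter vector conventions (shared with the fitting and FIM modules)
# ---------------------------------------------------------------------------

def coupling_pairs(N: int) -> list[tuple[int, int]]:
    """Ordered (m, t) with m < t, lexicographic; indexes the coupling block."""
    return [(m, t) for m in range(N) for t in range(m + 1, N)]


def n_params(N: int) -> int:
    """Free parameters in the reference gauge: 2N fields + N(N-1)/2 couplings."""
    return 2 * N + N * (N - 1) // 2


def theta_from_model(model: PottsModel) -> np.ndarray:
    """Flatten a model into the parameter vector theta.

    Ordering: (h_{0,-1}, h_{0,+1}, h_{1,-1}, h_{1,+1}, ...) then couplings
    J_{mt} for m < t lexicographic.  The model is first normalised to the
    reference gauge.
    """
    ref = model if model.gauge == GAUGE_REFERENCE else model.to_reference_gauge()
    N = ref.N
    theta = np.empty(n_params(N))
    theta[: 2 * N : 2] = ref.h[:, 0]
    theta[1 : 2 * N : 2] = ref.h[:, 2]
    theta[2 * N :] = [ref.J[m, t] for m, t in coupling_pairs(N)]
    return theta


def model_from_theta(N: int, theta: np.ndarray) -> PottsModel:
    """Inverse of :func:`theta_from_model` (reference gauge)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_params(N),):
        raise ValueError(f"theta must have length {n_params(N)} for N={N}")
    h = np.zeros((N, 3))
    h[:, 0] = theta[: 2 * N : 2]
    h[:, 2] = theta[1 : 2 * N : 2]
    J = np.zeros((N, N))
    for idx, (m, t) in enumerate(coupling_pairs(N)):
        J[m, t] = J[t, m] = theta[2 * N + idx]
    return PottsModel(h=h, J=J, gauge=GAUGE_REFERENCE)


def observables_to_vector(obs: ObservableSet) -> np.ndarray:
    """Target vector conjugate to theta: (r_{m,-1}, r_{m,+1})_m then agree_{m<t}."""
    N = obs.N
    v = np.empty(n_params(N))
    v[: 2 * N : 2] = obs.r[:, 0]
    v[1 : 2 * N : 2] = obs.r[:, 2]
    v[2 * N :] = [obs.agree[m, t] for m, t in coupling_pairs(N)]
    return v


# ---------------------------------------------------------------------------
# Energies and exact enumeration
# ---------------------------------------------------------------------------

def _check_state_vector(state: np.ndarray, N: int) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (N,):
        raise ValueError(f"state must have length {N}")
    if not np.isin(state, STATE_VALUES).all():
        raise ValueError("state entries must be in {-1, 0, 1}")
    return state.astype(np.int8)


def energy(state: np.ndarray, model: PottsModel) -> float:
    """E(s) = -sum_{m<t} J_mt d(s_m,s_t) - sum_{m,k} h_mk d(k,s_m)."""
    s = _check_state_vector(state, model.N)
    return float(energies(s[None, :], model)[0])


def energies(states: np.ndarray, model: PottsModel) -> np.ndarray:
    """Vectorized energies for a K x N array of ternary states."""
    states = np.asarray(states, dtype=np.int8)
    idx = (states + 1).astype(np.intp)  # state value -> column of h
    E = -model.h[np.arange(model.N)[None, :], idx].sum(axis=1)
    for m, t in coupling_pairs(model.N):
        Jmt = model.J[m, t]
        if Jmt != 0.0:
            E -= Jmt * (states[:, m] == states[:, t])
    return E


def enumerate_states(N: int) -> np.ndarray:
    """All 3^N ternary configurations as a (3^N, N) int8 array, fixed order."""
    if N > ENUM_LIMIT:
        raise EnumerationLimitError(
            f"N={N} exceeds the enumeration limit {ENUM_LIMIT}; use the Monte Carlo path"
        )
    grid = np.indices((3,) * N).reshape(N, -1).T
    return (grid - 1).astype(np.int8)


@dataclass
class ExactDistribution:
    """Enumerated Boltzmann distribution: states, probabilities and log Z."""

    states: np.ndarray
    p: np.ndarray
    log_z: float

    @property
    def N(self) -> int:
        return self.states.shape[1]


def exact_distribution(model: PottsModel) -> ExactDistribution:
    """Enumerate all 3^N states and return their normalized probabilities."""
    states = enumerate_states(model.N)
    E = energies(states, model)
    logw = -E
    log_z = float(np.logaddexp.reduce(logw))
    p = np.exp(logw - log_z)
    return ExactDistribution(states=states, p=p, log_z=log_z)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def observables_from_states(states: StateMatrix) -> ObservableSet:
    """Plug-in state frequencies and agreement fractions from data."""
    vals = states.values
    T, N = vals.shape
    r = np.stack([(vals == k).mean(axis=0) for k in STATE_VALUES], axis=1)
    agree = np.eye(N)
    for m, t in coupling_pairs(N):
        agree[m, t] = agree[t, m] = (vals[:, m] == vals[:, t]).mean()
    return ObservableSet(r=r, agree=agree)


def _observables_from_distribution(dist: ExactDistribution) -> ObservableSet:
    states, p = dist.states, dist.p
    N = dist.N
    r = np.stack([p @ (states == k) for k in STATE_VALUES], axis=1)
    agree = np.eye(N)
    for m, t in coupling_pairs(N):
        agree[m, t] = agree[t, m] = p @ (states[:, m] == states[:, t])
    return ObservableSet(r=np.clip(r, 0, 1), agree=np.clip(agree, 0, 1))


def observables_from_model(
    model: PottsModel,
    method: str = "exact",
    mc_settings: dict | None = None,
) -> ObservableSet:
    """Model expectations of the sufficient statistics.

    ``method='exact'`` marginalizes the enumerated distribution (N <= limit);
    ``method='mc'`` averages over a Metropolis sample (settings: T, seed,
    burn_in, thin).
    """
    if method == "exact":
        return _observables_from_distribution(exact_distribution(model))
    if method == "mc":
        from .synthetic import sample_states  # local import avoids a cycle

        mc = dict(mc_settings or {})
        mc.setdefault("T", 10_000)
        mc.setdefault("seed", 0)
        states = sample_states(model, **mc)
        return observables_from_states(states)
    raise ValueError(f"unknown method {method!r}")


def suff_stats_matrix(states: np.ndarray, N: int) -> np.ndarray:
    """Indicator matrix Phi (K x P): Phi[s, i] = O_i(s) for the theta ordering.

    Field observables are d(k, s_m) for k = -1, +1; coupling observables are
    d(s_m, s_t) for m < t.  p(s) = exp(theta . Phi[s] ) / Z in the reference
    gauge, so gradients of log Z are expectations of these columns.
    """
    K = states.shape[0]
    P = n_params(N)
    phi = np.empty((K, P))
    phi[:, : 2 * N : 2] = states == -1
    phi[:, 1 : 2 * N : 2] = states == 1
    for idx, (m, t) in enumerate(coupling_pairs(N)):
        phi[:, 2 * N + idx] = states[:, m] == states[:, t]
    return phi


# ---------------------------------------------------------------------------
# Higher-order agreement (pairwise-sufficiency check)
# ---------------------------------------------------------------------------

def third_order_agreement(source: StateMatrix | PottsModel) -> dict[tuple[int, int, int], float]:
    """Triple-agreement probabilities p(s_m = s_t = s_u) for all m < t < u.

    A pairwise model is not guaranteed to reproduce these, so comparing the
    fitted model's triples against the data's is a standard adequacy check.
    """
    if isinstance(source, StateMatrix):
        vals = source.values
        N = source.N
        if N < 3:
            raise ValueError("third_order_agreement needs at least 3 neurons")
        out = {}
        for m, t, u in itertools.combinations(range(N), 3):
            out[(m, t, u)] = float(
                ((vals[:, m] == vals[:, t]) & (vals[:, t] == vals[:, u])).mean()
            )
        return out
    if isinstance(source, PottsModel):
        N = source.N
        if N < 3:
            raise ValueError("third_order_agreement needs at least 3 neurons")
        dist = exact_distribution(source)
        states, p = dist.states, dist.p
        out = {}
        for m, t, u in itertools.combinations(range(N), 3):
            out[(m, t, u)] = float(
                p @ ((states[:, m] == states[:, t]) & (states[:, t] == states[:, u]))
            )
        return out
    raise TypeError("source must be a StateMatrix or PottsModel")
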