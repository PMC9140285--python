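"""Matcher-target perturbations and their localized parameter image.

The experimental primitive is a stochastic clamp: with small probability
epsilon the "matcher" neuron m copies the state of a "target" neuron t.  On
the observables this is the replacement rule

    r~_k(s_m) = (1 - eps) r_k(s_m) + eps r_k(s_t),

and the matcher's agreement probabilities with every other neuron j mix the
same way (with the target itself, the clamped fraction agrees by
construction, which is the j = t case of the same mixture since a neuron
always agrees with itself).

For small eps the perturbation maps to a unique *localized* change of model
parameters: only the matcher's fields and couplings move.  That change is
found by linear response: in an exponential family d<O_a>/dtheta_b =
cov(O_a, O_b), so restricting to the matcher's (N+1)-dimensional
observable/parameter block and solving

    chi . dtheta = dO/deps

gives the Jacobian column for direction (m, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ObservableSet,
    PottsModel,
    exact_distribution,
    observables_from_model,
)


@dataclass(frozen=True)
class PerturbationDirection:
    """An ordered matcher-target pair; ``kind`` distinguishes observable-space
    clamps from canonical (single-coupling) parameter perturbations."""

    matcher: int
    target: int
    kind: str = "observable"

    def __post_init__(self) -> None:
        if self.matcher == self.target:
            raise ValueError("matcher and target must differ")
        if self.matcher < 0 or self.target < 0:
            raise ValueError("indices must be nonnegative")


@dataclass
class ParameterDelta:
    """A tangent vector in parameter space: dh (N x 3) and symmetric dJ.

    ``support`` lists the touched parameters as ("h", m, k) / ("J", m, t)
    labels; for localized deltas it stays within the matcher's block.
    """

    dh: np.ndarray
    dJ: np.ndarray
    support: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dh = np.asarray(self.dh, dtype=float)
        self.dJ = np.asarray(self.dJ, dtype=float)
        if not np.allclose(self.dJ, self.dJ.T, atol=1e-12):
            raise ValueError("dJ must be symmetric")
        if not np.allclose(np.diag(self.dJ), 0.0):
            raise ValueError("dJ must have a zero diagonal")
        if not np.allclose(self.dh[:, 1], 0.0):
            raise ValueError("gauge: dh_{m,0} must be 0")

    @property
    def N(self) -> int:
        return self.dh.shape[0]

    def apply(self, model: PottsModel, eps: float = 1.0) -> PottsModel:
        """Return the model with parameters theta + eps * dtheta."""
        ref = model if model.gauge == "h0" else model.to_reference_gauge()
        return PottsModel(h=ref.h + eps * self.dh, J=ref.J + eps * self.dJ)


# ---------------------------------------------------------------------------
# Observable-space picture
# ---------------------------------------------------------------------------

def perturbed_observables(
    obs: ObservableSet, direction: PerturbationDirection, eps: float
) -> ObservableSet:
    """Apply the replacement rule at mixing probability eps.

    The matcher's marginals and agreements mix toward the target's; the
    matcher-target agreement mixes toward 1 because clamped states coincide
    by construction.  All other entries are untouched.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    m, t = direction.matcher, direction.target
    out = obs.copy()
    out.r[m] = (1 - eps) * obs.r[m] + eps * obs.r[t]
    for j in range(obs.N):
        if j == m:
            continue
        new = (1 - eps) * obs.agree[m, j] + eps * (1.0 if j == t else obs.agree[t, j])
        out.agree[m, j] = out.agree[j, m] = new
    return out


def observable_derivative(
    obs: ObservableSet, direction: PerturbationDirection
) -> tuple[np.ndarray, np.ndarray]:
    """d/deps of the matcher's observables at eps = 0.

    Returns ``(dr, dagree)``: dr is the 3-vector r(s_t) - r(s_m) (components
    sum to 0), dagree has entry j = agree_{tj} - agree_{mj} for j not in
    {m, t}, entry t = 1 - agree_{mt}, and a structural 0 at j = m.
    """
    m, t = direction.matcher, direction.target
    dr = obs.r[t] - obs.r[m]
    dagree = np.zeros(obs.N)
    for j in range(obs.N):
        if j == m:
            continue
        dagree[j] = (1.0 if j == t else obs.agree[t, j]) - obs.agree[m, j]
    return dr, dagree


# ---------------------------------------------------------------------------
# Linear response: susceptibility of the matcher block
# ---------------------------------------------------------------------------

def _matcher_indicators(states: np.ndarray, m: int) -> np.ndarray:
    """K x (N+1) matrix of the matcher's observables in parameter order:
    [d(-1, s_m), d(+1, s_m), d(s_m, s_j) for j != m]."""
    N = states.shape[1]
    cols = [states[:, m] == -1, states[:, m] == 1]
    cols += [states[:, m] == states[:, j] for j in range(N) if j != m]
    return np.stack(cols, axis=1).astype(float)


def susceptibility_matrix(
    model: PottsModel,
    matcher: int,
    method: str = "exact",
    mc_settings: dict | None = None,
) -> np.ndarray:
    """Covariance matrix of the matcher's observables under the model.

    Entry (a, b) is cov(O_a, O_b) with O ranging over the matcher's field
    indicators (k = -1, +1) and its agreement indicators with each other
    neuron: the (N+1) x (N+1) linear-response block d<O_a>/dtheta_b in the
    reference gauge.
    """
    if method == "exact":
        dist = exact_distribution(model)
        om = _matcher_indicators(dist.states, matcher)
        w = dist.p
    elif method == "mc":
        from .synthetic import sample_states

        mc = dict(mc_settings or {})
        mc.setdefault("T", 20_000)
        mc.setdefault("seed", 0)
        sample = sample_states(model, **mc)
        om = _matcher_indicators(sample.values, matcher)
        w = np.full(om.shape[0], 1.0 / om.shape[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    mean = w @ om
    centered = om - mean
    return (w[:, None] * centered).T @ centered


def _derivative_vector(
    obs: ObservableSet, direction: PerturbationDirection
) -> np.ndarray:
    """Matcher-block observable derivative in parameter order (length N+1)."""
    m = direction.matcher
    dr, dagree = observable_derivative(obs, direction)
    return np.concatenate(([dr[0], dr[2]], np.delete(dagree, m)))


def localized_jacobian(
    model: PottsModel,
    direction: PerturbationDirection,
    method: str = "exact",
    mc_settings: dict | None = None,
    cond_limit: float = 1e12,
) -> ParameterDelta:
    """Parameter change per unit eps realizing the replacement rule locally.

    Solves chi . dtheta = dO/deps on the matcher's block, touching only
    (dh_{m,-1}, dh_{m,+1}) and dJ_{mj}.  Raises if the susceptibility block
    is ill-conditioned (cond > cond_limit), reporting the condition number.
    """
    m = direction.matcher
    N = model.N
    obs = observables_from_model(model, method=method, mc_settings=mc_settings)
    chi = susceptibility_matrix(model, m, method=method, mc_settings=mc_settings)
    rhs = _derivative_vector(obs, direction)
    cond = np.linalg.cond(chi)
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"susceptibility block for matcher {m} is ill-conditioned "
            f"(cond = {cond:.3e} > {cond_limit:.1e})"
        )
    dtheta = np.linalg.solve(chi, rhs)

    dh = np.zeros((N, 3))
    dh[m, 0], dh[m, 2] = dtheta[0], dtheta[1]
    dJ = np.zeros((N, N))
    others = [j for j in range(N) if j != m]
    for j, v in zip(others, dtheta[2:]):
        dJ[m, j] = dJ[j, m] = v
    support = {("h", m, -1), ("h", m, 1)} | {("J", m, j) for j in others}
    return ParameterDelta(dh=dh, dJ=dJ, support=support)


def canonical_direction(pair: tuple[int, int], N: int) -> ParameterDelta:
    """Unit perturbation of a single coupling: dJ_{mt} = 1, all else 0."""
    m, t = pair
    if m == t:
        raise ValueError("canonical direction needs two distinct neurons")
    dJ = np.zeros((N, N))
    dJ[m, t] = dJ[t, m] = 1.0
    return ParameterDelta(dh=np.zeros((N, 3)), dJ=dJ, support={("J", m, t)})
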