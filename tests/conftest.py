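"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import root

import synchfim as sf
from synchfim.model import exact_distribution
from synchfim.synchrony import synchrony_distribution


def random_model(N: int, seed: int, field_scale: float = 0.4, coupling_scale: float = 0.3) -> sf.PottsModel:
    return sf.generate_ground_truth_model(
        sf.GroundTruthSpec(
            N=N, field_scale=field_scale, coupling_scale=coupling_scale, seed=seed
        )
    )


@pytest.fixture
def model3() -> sf.PottsModel:
    return random_model(3, seed=11)


@pytest.fixture
def model4() -> sf.PottsModel:
    return random_model(4, seed=12)


def zero_model(N: int) -> sf.PottsModel:
    return sf.PottsModel(h=np.zeros((N, 3)), J=np.zeros((N, N)))


def strong_neuron_model(N: int = 8, boost: float = 5.0, seed: int = 4) -> sf.PottsModel:
    """Heterogeneous model with neuron 0 coupled ``boost`` times more strongly."""
    base = random_model(N, seed=seed, field_scale=0.3, coupling_scale=0.15)
    J = base.J.copy()
    J[0, :] *= boost
    J[:, 0] *= boost
    np.fill_diagonal(J, 0.0)
    return sf.PottsModel(h=base.h, J=J)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def kl_quadratic_form(model: sf.PottsModel, delta: sf.ParameterDelta, eps: float = 1e-4,
                      granularity: str = "fine") -> float:
    """Finite-difference KL estimate of the Fisher quadratic form along delta.

    Symmetrized: (D_KL[phi || phi(+eps)] + D_KL[phi || phi(-eps)]) / eps^2,
    which cancels the cubic term of the expansion 2 D_KL ~ eps^2 v' G v.
    Independent of the analytic Gram-form path it checks.
    """
    phi0 = synchrony_distribution(model, granularity=granularity).probs
    phi_p = synchrony_distribution(delta.apply(model, eps), granularity=granularity).probs
    phi_m = synchrony_distribution(delta.apply(model, -eps), granularity=granularity).probs
    return (sf.kl_divergence(phi0, phi_p) + sf.kl_divergence(phi0, phi_m)) / eps**2


def add_deltas(a: sf.ParameterDelta, b: sf.ParameterDelta, sign: float = 1.0) -> sf.ParameterDelta:
    return sf.ParameterDelta(
        dh=a.dh + sign * b.dh, dJ=a.dJ + sign * b.dJ, support=a.support | b.support
    )


def kl_cross_term(model: sf.PottsModel, da: sf.ParameterDelta, db: sf.ParameterDelta,
                  eps: float = 1e-4) -> float:
    """Off-diagonal Fisher entry by the polarization identity:
    F(a, b) = [K(a + b) - K(a - b)] / 4 with K the diagonal KL form."""
    return (
        kl_quadratic_form(model, add_deltas(da, db, +1.0), eps)
        - kl_quadratic_form(model, add_deltas(da, db, -1.0), eps)
    ) / 4.0


def localized_refit_oracle(model: sf.PottsModel, direction: sf.PerturbationDirection,
                           eps: float) -> np.ndarray:
    """Nonlinear inverse-problem oracle for the localized Jacobian.

    Solves, by Newton iteration on exact enumerated observables, for the
    matcher's N+1 parameter offsets that reproduce the replacement rule's
    matcher-block observables at finite eps; dividing by eps approximates the
    linear-response Jacobian independently of the susceptibility solve.
    Returns the offsets (dh_{m,-1}, dh_{m,+1}, dJ_{mj} for j != m).
    """
    m = direction.matcher
    N = model.N
    obs0 = sf.observables_from_model(model)
    target = sf.perturbed_observables(obs0, direction, eps)
    tvec = np.concatenate(
        ([target.r[m, 0], target.r[m, 2]], np.delete(target.agree[m], m))
    )
    others = [j for j in range(N) if j != m]

    def pack(x: np.ndarray) -> sf.PottsModel:
        h = model.h.copy()
        J = model.J.copy()
        h[m, 0] += x[0]
        h[m, 2] += x[1]
        for j, v in zip(others, x[2:]):
            J[m, j] = J[j, m] = model.J[m, j] + v
        return sf.PottsModel(h=h, J=J, gauge=model.gauge)

    def residual(x: np.ndarray) -> np.ndarray:
        o = sf.observables_from_model(pack(x))
        return np.concatenate(
            ([o.r[m, 0], o.r[m, 2]], np.delete(o.agree[m], m))
        ) - tvec

    sol = root(residual, np.zeros(N + 1), method="hybr", tol=1e-13)
    assert sol.success
    return sol.x


def delta_block_vector(delta: sf.ParameterDelta, m: int) -> np.ndarray:
    """Matcher-block components of a ParameterDelta, parameter order."""
    return np.concatenate(
        ([delta.dh[m, 0], delta.dh[m, 2]], np.delete(delta.dJ[m], m))
    )


def entropy_of(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def exact_probs(model: sf.PottsModel) -> np.ndarray:
    return exact_distribution(model).p
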