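"""Inference of model parameters from sufficient statistics.

The pairwise maxent problem is convex: the negative log-likelihood per sample

    L(theta) = log Z(theta) - theta . o_bar

has gradient <O>_theta - o_bar and Hessian cov_theta(O, O), so on the exact
(enumerated) path we use a damped Newton iteration, which converges to the
constraint-error tolerance in a handful of steps at the sizes enumeration
allows.  For larger systems the Monte Carlo path runs Boltzmann learning:
gradient ascent with sampled expectations and a decaying learning rate,
declaring convergence only when the constraint error is resolvable above the
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    GAUGE_REFERENCE,
    ObservableSet,
    PottsModel,
    enumerate_states,
    model_from_theta,
    n_params,
    observables_from_states,
    observables_to_vector,
    suff_stats_matrix,
    theta_from_model,
)


@dataclass
class FitReport:
    """Outcome of a fit: convergence flag, iterations, residual constraint error."""

    converged: bool
    iterations: int
    max_constraint_error: float
    method: str
    mc_error: float | None = None


def _apply_pseudocount(obs: ObservableSet, T: int | None) -> ObservableSet:
    """Additive 1/(2T) smoothing of zero state frequencies (finite-T guard)."""
    if T is None or (obs.r > 0).all():
        return obs
    eps = 1.0 / (2.0 * T)
    r = obs.r + eps
    r /= r.sum(axis=1, keepdims=True)
    return ObservableSet(r=r, agree=obs.agree.copy())


def fit_independent(obs: ObservableSet, T: int | None = None) -> PottsModel:
    """Closed-form independent model: J = 0, h_{m,k} = log(r_k(s_m) / r_0(s_m)).

    The independent model is the maxent solution constraining only the
    single-neuron state frequencies; it reproduces ``obs.r`` exactly but not
    the agreements.  Zero frequencies are smoothed by a 1/(2T) pseudocount
    when a sample count ``T`` is given; otherwise they are rejected.
    """
    obs = _apply_pseudocount(obs, T)
    if (obs.r <= 0).any():
        raise ValueError(
            "zero state frequencies: pass the sample count T to enable the pseudocount rule"
        )
    h = np.log(obs.r / obs.r[:, 1][:, None])
    return PottsModel(h=h, J=np.zeros((obs.N, obs.N)), gauge=GAUGE_REFERENCE)


def fit_pairwise_exact(
    obs: ObservableSet,
    tolerance: float = 1e-6,
    max_iter: int = 200,
    T: int | None = None,
    l2: float = 0.0,
) -> tuple[PottsModel, FitReport]:
    """Fit the pairwise model by damped Newton descent on the exact likelihood.

    Convergence is declared when the maximum absolute difference between the
    model's sufficient statistics and the targets falls below ``tolerance``.
    ``l2`` adds an optional ridge penalty on theta (off by default).  On
    non-convergence the best model found is returned with
    ``report.converged = False``.
    """
    obs = _apply_pseudocount(obs, T)
    N = obs.N
    states = enumerate_states(N)
    phi = suff_stats_matrix(states, N)
    target = observables_to_vector(obs)

    theta = theta_from_model(fit_independent(obs, T))
    P = n_params(N)

    def stats(th: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        logw = phi @ th
        log_z = float(np.logaddexp.reduce(logw))
        p = np.exp(logw - log_z)
        mean = p @ phi
        return p, mean, log_z

    def nll(th: np.ndarray, log_z: float) -> float:
        return log_z - th @ target + 0.5 * l2 * th @ th

    p, mean, log_z = stats(theta)
    best = theta.copy()
    best_err = float(np.abs(mean - target).max())
    it = 0
    for it in range(1, max_iter + 1):
        grad = mean - target + l2 * theta
        err = float(np.abs(mean + l2 * theta - target).max())
        if err < best_err:
            best, best_err = theta.copy(), err
        if err <= tolerance:
            return model_from_theta(N, theta), FitReport(True, it, err, "exact")
        # Hessian = covariance of the sufficient statistics (PSD); small ridge
        # for numerical safety near the boundary of realizable observables.
        centered = phi - mean
        H = (p[:, None] * centered).T @ centered + (l2 + 1e-10) * np.eye(P)
        step = np.linalg.solve(H, grad)
        # backtracking line search on the convex objective
        f0 = nll(theta, log_z)
        alpha = 1.0
        for _ in range(40):
            cand = theta - alpha * step
            p_c, mean_c, log_z_c = stats(cand)
            if nll(cand, log_z_c) <= f0 - 1e-4 * alpha * (grad @ step):
                theta, p, mean, log_z = cand, p_c, mean_c, log_z_c
                break
            alpha /= 2.0
        else:  # no productive step: report best so far
            break
    final_err = float(np.abs(mean + l2 * theta - target).max())
    if final_err <= tolerance:
        return model_from_theta(N, theta), FitReport(True, it, final_err, "exact")
    return model_from_theta(N, best), FitReport(False, it, best_err, "exact")


def fit_pairwise_mc(
    obs: ObservableSet,
    mc_settings: dict | None = None,
    tolerance: float = 1e-2,
    max_iter: int = 300,
    seed: int = 0,
    learning_rate: float = 1.0,
    decay: float = 100.0,
) -> tuple[PottsModel, FitReport]:
    """Boltzmann learning: gradient updates with Metropolis-sampled expectations.

    Each iteration samples the current model, measures its sufficient
    statistics and moves theta along (target - estimate) with learning rate
    ``learning_rate / (1 + it/decay)``.  The Monte Carlo standard error of an
    estimated probability is at most sqrt(0.25/T); iteration stops once the
    constraint error drops below max(tolerance, 3x that noise floor).
    Convergence is certified only when the requested tolerance is itself
    resolvable above the sampling noise (tolerance >= the noise floor) —
    a tolerance unreachable at the given T yields converged = False with the
    best model found.
    """
    from .synthetic import sample_states  # local import avoids a cycle

    mc = dict(mc_settings or {})
    T_mc = int(mc.pop("T", 5000))
    mc_err = float(np.sqrt(0.25 / T_mc))
    threshold = max(tolerance, 3.0 * mc_err)

    N = obs.N
    target = observables_to_vector(obs)
    theta = theta_from_model(fit_independent(obs, T_mc))
    rng = np.random.default_rng(seed)
    best, best_err = theta.copy(), np.inf
    it = 0
    for it in range(1, max_iter + 1):
        model = model_from_theta(N, theta)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sample = sample_states(model, T_mc, seed=sub_seed, **mc)
        est = observables_to_vector(observables_from_states(sample))
        errvec = target - est
        err = float(np.abs(errvec).max())
        if err < best_err:
            best, best_err = theta.copy(), err
        if err <= threshold:
            certified = tolerance >= mc_err
            return model_from_theta(N, theta), FitReport(certified, it, err, "mc", mc_err)
        theta = theta + (learning_rate / (1.0 + it / decay)) * errvec
    return model_from_theta(N, best), FitReport(False, it, best_err, "mc", mc_err)


def parameter_uncertainty(model: PottsModel, T: int) -> np.ndarray:
    """First-order standard errors on theta from T-sample observable noise.

    Propagates independent observable errors of scale sqrt(0.25/T) through
    the inverse Hessian (delta theta = H^-1 delta o_bar); used to compare
    fits across methods on a common scale.
    """
    states = enumerate_states(model.N)
    phi = suff_stats_matrix(states, model.N)
    from .model import exact_distribution

    p = exact_distribution(model).p
    mean = p @ phi
    centered = phi - mean
    H = (p[:, None] * centered).T @ centered + 1e-10 * np.eye(phi.shape[1])
    Hinv = np.linalg.inv(H)
    return np.sqrt(0.25 / T) * np.linalg.norm(Hinv, axis=1)
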