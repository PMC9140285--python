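"""Synthetic ground-truth models, Metropolis sampling and trace ternarization.

The generator emulates the regime of whole-brain Ca2+ imaging in immobilized
C. elegans from which such models are typically inferred: a few dozen neurons
(N ~ 50), short recordings yielding T ~ 80-120 effectively independent ternary
samples, heterogeneous per-neuron biases and a broad coupling distribution
containing both signs.  All randomness is driven by explicit integer seeds;
there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import GAUGE_REFERENCE, PottsModel, StateMatrix, coupling_pairs


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of a synthetic ground-truth model.

    field_scale / coupling_scale are the dispersions (standard deviations) of
    the bias and coupling draws; coupling_sign_fraction is the probability a
    coupling is negative (the data show a signed, broad coupling distribution,
    roughly balanced, so the default is 0.5).
    """

    N: int = 50
    field_scale: float = 0.5
    coupling_scale: float = 0.3
    coupling_sign_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least N = 2 neurons")
        if self.field_scale < 0 or self.coupling_scale < 0:
            raise ValueError("scales must be nonnegative")
        if not 0.0 <= self.coupling_sign_fraction <= 1.0:
            raise ValueError("coupling_sign_fraction must lie in [0, 1]")


def generate_ground_truth_model(spec: GroundTruthSpec) -> PottsModel:
    """Draw a heterogeneous model: centered-normal biases, signed-normal couplings.

    Fields h_{m,k} for k = -1, +1 are N(0, field_scale^2) in the reference
    gauge; each coupling magnitude is |N(0, coupling_scale^2)| with a negative
    sign attached with probability coupling_sign_fraction.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.N
    h = np.zeros((N, 3))
    h[:, 0] = rng.normal(0.0, spec.field_scale, size=N) if spec.field_scale else 0.0
    h[:, 2] = rng.normal(0.0, spec.field_scale, size=N) if spec.field_scale else 0.0
    J = np.zeros((N, N))
    pairs = coupling_pairs(N)
    mags = np.abs(rng.normal(0.0, spec.coupling_scale, size=len(pairs)))
    signs = np.where(rng.random(len(pairs)) < spec.coupling_sign_fraction, -1.0, 1.0)
    for (m, t), v in zip(pairs, mags * signs):
        J[m, t] = J[t, m] = v
    return PottsModel(h=h, J=J, gauge=GAUGE_REFERENCE)


# ---------------------------------------------------------------------------
# Single-site Metropolis sampling of the Boltzmann distribution
# ---------------------------------------------------------------------------

@njit(cache=True)
def _metropolis_kernel(h, J, T, burn_updates, thin_updates, seed):  # pragma: no cover
    np.random.seed(seed)
    N = h.shape[0]
    s = np.empty(N, dtype=np.int8)  # state indices 0, 1, 2 (value = index - 1)
    for m in range(N):
        s[m] = np.random.randint(0, 3)
    out = np.empty((T, N), dtype=np.int8)

    total = burn_updates + T * thin_updates
    taken = 0
    next_sample = burn_updates
    for step in range(total + 1):
        if step == next_sample and taken < T:
            for m in range(N):
                out[taken, m] = s[m] - 1
            taken += 1
            next_sample += thin_updates
        if step == total:
            break
        m = np.random.randint(0, N)
        old = s[m]
        new = (old + 1 + np.random.randint(0, 2)) % 3  # one of the two other states
        dE = h[m, old] - h[m, new]
        for t in range(N):
            if t != m and J[m, t] != 0.0:
                if s[t] == new:
                    dE -= J[m, t]
                elif s[t] == old:
                    dE += J[m, t]
        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            s[m] = new
    return out


def sample_states(
    model: PottsModel,
    T: int,
    seed: int,
    burn_in: int | None = None,
    thin: int | None = None,
) -> StateMatrix:
    """Draw T rows from the model by single-site Metropolis dynamics.

    Parameters
    ----------
    T
        Number of samples (rows).
    seed
        Integer RNG seed; identical seeds give identical output.
    burn_in
        Equilibration sweeps (one sweep = N single-site updates) discarded
        before the first sample.  Default 100*N sweeps, conservative for the
        weakly coupled regimes used here.
    thin
        Single-site updates between retained samples.  Default 10*N.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    N = model.N
    if burn_in is None:
        burn_in = 100 * N
    if thin is None:
        thin = 10 * N
    if burn_in <= 0 or thin <= 0:
        raise ValueError("burn_in and thin must be positive")
    ref = model if model.gauge == GAUGE_REFERENCE else model.to_reference_gauge()
    vals = _metropolis_kernel(
        np.ascontiguousarray(ref.h),
        np.ascontiguousarray(ref.J),
        int(T),
        int(burn_in) * N,
        int(thin),
        int(seed) % (2**32),
    )
    return StateMatrix(values=vals)


# ---------------------------------------------------------------------------
# Ternarization of continuous derivative traces
# ---------------------------------------------------------------------------

def ternarize(
    traces: np.ndarray,
    threshold_rule: tuple[str, float] | float = ("quantile", 1.0 / 3.0),
) -> StateMatrix:
    """Coarse-grain continuous per-neuron derivative traces to {-1, 0, +1}.

    An element above +theta_m maps to +1 ("up"), below -theta_m to -1
    ("down"), otherwise 0 ("flat").  The per-neuron threshold theta_m comes
    from the rule:

    - ``("fixed", theta)`` or a bare float: the same theta for every neuron;
    - ``("quantile", q)``: theta_m is the q-quantile of |trace_m|, so a
      fraction q of each neuron's samples lands in the flat state.  The
      default q = 1/3 keeps all three states populated at roughly equal
      weight, which the pairwise model's ternary alphabet presumes;
    - ``"tercile"``: per-neuron signed terciles (asymmetric thresholds at the
      1/3 and 2/3 quantiles of the trace itself), balancing all three states
      to within one sample.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[:, None]
    if np.isnan(traces).any():
        bad = np.argwhere(np.isnan(traces))
        locs = [(int(r), int(c)) for r, c in bad[:5]]
        raise ValueError(f"traces contain NaN at (row, col): {locs}")
    if not np.isfinite(traces).all():
        raise ValueError("traces must be finite")

    if isinstance(threshold_rule, (int, float)):
        threshold_rule = ("fixed", float(threshold_rule))
    if threshold_rule == "tercile" or threshold_rule == ("tercile",):
        lower = np.quantile(traces, 1.0 / 3.0, axis=0)
        upper = np.quantile(traces, 2.0 / 3.0, axis=0)
        vals = np.zeros(traces.shape, dtype=np.int8)
        vals[traces > upper[None, :]] = 1
        vals[traces < lower[None, :]] = -1
        return StateMatrix(values=vals)
    kind, value = threshold_rule
    if kind == "fixed":
        theta = np.full(traces.shape[1], float(value))
    elif kind == "quantile":
        if not 0.0 <= value < 1.0:
            raise ValueError("quantile must lie in [0, 1)")
        theta = np.quantile(np.abs(traces), value, axis=0)
    else:
        raise ValueError(f"unknown threshold rule {kind!r}")
    if (theta < 0).any():
        raise ValueError("thresholds must be nonnegative")

    vals = np.zeros(traces.shape, dtype=np.int8)
    vals[traces > theta[None, :]] = 1
    vals[traces < -theta[None, :]] = -1
    return StateMatrix(values=vals)
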