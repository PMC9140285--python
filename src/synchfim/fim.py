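"""Fisher information of coarse-grained synchrony under pairwise perturbations.

The sensitivity of the synchrony distribution phi to a perturbation of
strength eps along direction v is measured by the Kullback-Leibler divergence
between perturbed and unperturbed distributions; as eps -> 0,

    F(v, v) = lim 2/eps^2 D_KL[phi || phi~]

is a quadratic form, the Fisher information matrix.  Because phi is a
deterministic coarse-graining of the Boltzmann distribution, its Fisher
matrix over the model parameters theta has the exact Gram form

    G_ij = sum_n phi(n) c_i(n) c_j(n),
    c_i(n) = <O_i | coarse state n> - <O_i>,

where O_i are the sufficient statistics conjugate to theta_i.  The matrix
over matcher-target directions is the congruence F = J^T G J with J the
localized Jacobian columns mapping each observable-space clamp to its
parameter image.

Eigenvectors of F, reshaped onto the (target x matcher) grid as
"eigenmatrices", expose the structure of sensitive perturbations: vertical
striations (high column uniformity) mark single matcher neurons whose
uniform, same-sign coupling changes dominate collective sensitivity — the
pivotal neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    PottsModel,
    coupling_pairs,
    exact_distribution,
    n_params,
    suff_stats_matrix,
)
from .perturb import PerturbationDirection, localized_jacobian
from .synchrony import state_matrix_coarse_labels


def observable_directions(N: int) -> list[tuple[int, int]]:
    """The N(N-1) ordered (matcher, target) pairs, matcher-major."""
    return [(m, t) for m in range(N) for t in range(N) if t != m]


@dataclass
class FisherMatrix:
    """Symmetric sensitivity matrix over an ordered list of directions.

    ``directions`` are (matcher, target) pairs for the observable FIM
    (matcher-major) or unordered (m, t) coupling pairs for the canonical one.
    """

    values: np.ndarray
    directions: list[tuple[int, int]]
    granularity: str
    estimator: str = "exact"
    kind: str = "observable"
    mc_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        D = len(self.directions)
        if self.values.shape != (D, D):
            raise ValueError("values must be square over the directions")
        if self.estimator == "exact" and not np.allclose(
            self.values, self.values.T, atol=1e-8
        ):
            raise ValueError("exact-path Fisher matrix must be symmetric")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def N(self) -> int:
        return 1 + max(max(d) for d in self.directions)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.values)[::-1]


@dataclass
class EigenMode:
    """One FIM eigenmode: rank (1-based, descending eigenvalue) and the
    eigenvector reshaped to a zero-diagonal N x N eigenmatrix with rows
    indexing targets and columns matchers, unit Frobenius norm."""

    rank: int
    eigenvalue: float
    eigenmatrix: np.ndarray

    @property
    def N(self) -> int:
        return self.eigenmatrix.shape[0]


# ---------------------------------------------------------------------------
# Fisher information over the model parameters
# ---------------------------------------------------------------------------

def _coarse_labels(values: np.ndarray, granularity: str) -> np.ndarray:
    labels = state_matrix_coarse_labels(values)
    if granularity == "fine":
        return labels
    if granularity == "coarse":
        # collapse triples sharing the plurality size n1
        from .synchrony import enumerate_synchrony_states

        N = values.shape[1]
        support = enumerate_synchrony_states(N)
        n1s = sorted({s[0] for s in support}, reverse=True)
        remap = np.array([n1s.index(s[0]) for s in support], dtype=np.intp)
        return remap[labels]
    raise ValueError("granularity must be 'fine' or 'coarse'")


def coarse_fisher_theta(
    model: PottsModel,
    granularity: str = "fine",
    method: str = "exact",
    mc_settings: dict | None = None,
) -> np.ndarray:
    """Fisher matrix G of the synchrony distribution over theta (P x P).

    G_ij = sum_n phi(n) c_i(n) c_j(n) with c_i(n) the centered conditional
    mean of sufficient statistic O_i given coarse state n; coarse states with
    phi = 0 contribute nothing.  Symmetric PSD by construction.  The 'mc'
    path replaces exact enumeration with Metropolis samples.
    """
    N = model.N
    if method == "exact":
        dist = exact_distribution(model)
        values, w = dist.states, dist.p
    elif method == "mc":
        from .synthetic import sample_states

        mc = dict(mc_settings or {})
        mc.setdefault("T", 20_000)
        mc.setdefault("seed", 0)
        sample = sample_states(model, **mc)
        values = sample.values
        w = np.full(sample.T, 1.0 / sample.T)
    else:
        raise ValueError(f"unknown method {method!r}")

    phi_states = suff_stats_matrix(values, N)
    labels = _coarse_labels(values, granularity)
    n_coarse = int(labels.max()) + 1
    P = n_params(N)

    phi_n = np.bincount(labels, weights=w, minlength=n_coarse)
    cond_sum = np.zeros((n_coarse, P))
    np.add.at(cond_sum, labels, w[:, None] * phi_states)
    mean = w @ phi_states
    nz = phi_n > 0
    c = cond_sum[nz] / phi_n[nz, None] - mean
    return (phi_n[nz, None] * c).T @ c


# ---------------------------------------------------------------------------
# Observable-space and canonical FIMs
# ---------------------------------------------------------------------------

def _delta_to_theta_vector(delta) -> np.ndarray:
    """Flatten a ParameterDelta onto the theta ordering."""
    N = delta.N
    v = np.empty(n_params(N))
    v[: 2 * N : 2] = delta.dh[:, 0]
    v[1 : 2 * N : 2] = delta.dh[:, 2]
    v[2 * N :] = [delta.dJ[m, t] for m, t in coupling_pairs(N)]
    return v


def observable_fim(
    model: PottsModel,
    granularity: str = "fine",
    method: str = "exact",
    mc_settings: dict | None = None,
) -> FisherMatrix:
    """FIM over the N(N-1) matcher-target clamp directions: F = J^T G J."""
    N = model.N
    G = coarse_fisher_theta(model, granularity, method=method, mc_settings=mc_settings)
    dirs = observable_directions(N)
    Jcols = np.empty((n_params(N), len(dirs)))
    for d, (m, t) in enumerate(dirs):
        delta = localized_jacobian(
            model, PerturbationDirection(m, t), method=method, mc_settings=mc_settings
        )
        Jcols[:, d] = _delta_to_theta_vector(delta)
    F = Jcols.T @ G @ Jcols
    return FisherMatrix(
        values=F,
        directions=dirs,
        granularity=granularity,
        estimator=method,
        kind="observable",
        mc_meta=dict(mc_settings or {}),
    )


def canonical_fim(
    model: PottsModel,
    granularity: str = "fine",
    method: str = "exact",
    mc_settings: dict | None = None,
) -> FisherMatrix:
    """FIM over canonical single-coupling perturbations: the coupling block of G."""
    N = model.N
    G = coarse_fisher_theta(model, granularity, method=method, mc_settings=mc_settings)
    F = G[2 * N :, 2 * N :]
    return FisherMatrix(
        values=F,
        directions=coupling_pairs(N),
        granularity=granularity,
        estimator=method,
        kind="canonical",
        mc_meta=dict(mc_settings or {}),
    )


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------

def eigenmodes(F: FisherMatrix) -> list[EigenMode]:
    """Eigendecomposition, descending; vectors reshaped to eigenmatrices.

    Entry (t, m) of an eigenmatrix is the coefficient of direction (m, t):
    columns collect how matcher m imitates each of its targets.  The sign is
    fixed so the largest-magnitude entry is positive.
    """
    if F.kind != "observable":
        raise ValueError("eigenmatrices are defined for the observable FIM")
    N = F.N
    w, V = np.linalg.eigh(F.values)
    order = np.argsort(w)[::-1]
    modes = []
    for rank, idx in enumerate(order, start=1):
        vec = V[:, idx]
        mat = np.zeros((N, N))
        for d, (m, t) in enumerate(F.directions):
            mat[t, m] = vec[d]
        flat = np.abs(mat).argmax()
        if mat.flat[flat] < 0:
            mat = -mat
        modes.append(EigenMode(rank=rank, eigenvalue=float(w[idx]), eigenmatrix=mat))
    return modes


def uniformity(mode: EigenMode) -> tuple[np.ndarray, np.ndarray]:
    """Row and column uniformities of a unit-norm eigenmatrix.

    U_i = (sum_j v_ij)^2 over row i (targets of matcher j's perturbations),
    V_j = (sum_i v_ij)^2 over column j (matcher j).  High column uniformity
    marks same-sign perturbations concentrated on a single matcher.
    """
    v = mode.eigenmatrix
    U = v.sum(axis=1) ** 2
    V = v.sum(axis=0) ** 2
    return U, V


def pivotal_neurons(
    runs: list[list[EigenMode]] | list[EigenMode],
    percentile: float = 99.0,
) -> np.ndarray:
    """Per-neuron flag fraction: how often a neuron's column uniformity is extreme.

    Column uniformities are pooled over all neurons, modes and runs; the
    cutoff is the given percentile of the pool.  In each run a neuron is
    flagged if any of its column uniformities exceeds the cutoff; the
    returned array is the flag fraction across runs.
    """
    if runs and isinstance(runs[0], EigenMode):
        runs = [runs]  # a single run
    if not runs or not runs[0]:
        raise ValueError("need at least one run with at least one mode")
    N = runs[0][0].N
    per_run = []  # (modes x N) column uniformities per run
    for modes in runs:
        per_run.append(np.stack([uniformity(mode)[1] for mode in modes]))
    pool = np.concatenate([v.ravel() for v in per_run])
    cutoff = np.percentile(pool, percentile)
    flags = np.stack([(v > cutoff).any(axis=0) for v in per_run])
    return flags.mean(axis=0)


def matcher_block_eigenvalues(F: FisherMatrix) -> np.ndarray:
    """Principal eigenvalue of each matcher's (N-1) x (N-1) diagonal block.

    With matcher-major ordering, block m spans directions (m, t) for all t:
    perturbations focused on a single matcher neuron at a time."""
    if F.kind != "observable":
        raise ValueError("matcher blocks are defined for the observable FIM")
    N = F.N
    out = np.empty(N)
    for m in range(N):
        sl = slice(m * (N - 1), (m + 1) * (N - 1))
        out[m] = np.linalg.eigvalsh(F.values[sl, sl])[-1]
    return out


def subsample_sensitivity(
    model: PottsModel,
    subset_sizes: list[int],
    ranking: str = "pivotal",
    M: int = 10,
    seed: int = 0,
    granularity: str = "fine",
    F: FisherMatrix | None = None,
) -> dict:
    """Normalized principal FIM eigenvalue as a function of neuron-subset size.

    The FIM is restricted to directions whose matcher and target both lie in
    the subset.  ``ranking='pivotal'`` grows the subset along neurons ranked
    by matcher-block principal eigenvalue (one deterministic curve);
    ``'random'`` averages over M uniform draws.  Values are normalized by the
    full-model principal eigenvalue.
    """
    if any(s < 2 for s in subset_sizes):
        raise ValueError("subset sizes must be >= 2")
    N = model.N
    if any(s > N for s in subset_sizes):
        raise ValueError("subset sizes cannot exceed N")
    if F is None:
        F = observable_fim(model, granularity=granularity)
    lam_full = float(np.linalg.eigvalsh(F.values)[-1])

    def principal(subset: set[int]) -> float:
        idx = [d for d, (m, t) in enumerate(F.directions) if m in subset and t in subset]
        sub = F.values[np.ix_(idx, idx)]
        return float(np.linalg.eigvalsh(sub)[-1])

    rng = np.random.default_rng(seed)
    means, stds = [], []
    if ranking == "pivotal":
        ranked = list(np.argsort(matcher_block_eigenvalues(F))[::-1])
        for s in subset_sizes:
            means.append(principal(set(ranked[:s])) / lam_full)
            stds.append(0.0)
    elif ranking == "random":
        for s in subset_sizes:
            vals = [
                principal(set(rng.choice(N, size=s, replace=False).tolist()))
                for _ in range(M)
            ]
            means.append(float(np.mean(vals)) / lam_full)
            stds.append(float(np.std(vals)) / lam_full)
    else:
        raise ValueError("ranking must be 'pivotal' or 'random'")
    return {
        "sizes": list(subset_sizes),
        "mean": np.array(means),
        "std": np.array(stds),
        "normalizer": lam_full,
    }


# ---------------------------------------------------------------------------
# Null models and design numbers
# ---------------------------------------------------------------------------

def shuffled_coupling_null(model: PottsModel, seed: int = 0) -> PottsModel:
    """Shuffle the multiset of couplings uniformly over pairs; fields unchanged.

    Preserves the coupling distribution but destroys the interaction
    topology."""
    rng = np.random.default_rng(seed)
    pairs = coupling_pairs(model.N)
    vals = np.array([model.J[m, t] for m, t in pairs])
    vals = vals[rng.permutation(len(vals))]
    J = np.zeros_like(model.J)
    for (m, t), v in zip(pairs, vals):
        J[m, t] = J[t, m] = v
    return PottsModel(h=model.h.copy(), J=J, gauge=model.gauge)


def sample_size_bound(eps: float, fisher_information: float) -> float:
    """Cramer-Rao style lower bound T ~ 1 / (eps^2 F) on the samples needed
    to resolve a perturbation of strength eps along a mode with Fisher
    information F."""
    if eps <= 0 or fisher_information <= 0:
        raise ValueError("eps and Fisher information must be positive")
    return 1.0 / (eps**2 * fisher_information)


def kl_divergence(
    p: np.ndarray, q: np.ndarray, smoothing: float | None = None
) -> float:
    """KL divergence over a shared support; optional additive smoothing for
    empirical distributions (e.g. 1/(2T)).  Terms with p = 0 vanish."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if smoothing:
        p = (p + smoothing) / (p + smoothing).sum()
        q = (q + smoothing) / (q + smoothing).sum()
    mask = p > 0
    if (q[mask] <= 0).any():
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
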