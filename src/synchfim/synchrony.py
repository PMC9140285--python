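"""Coarse-grained collective statistics of ternary activity: synchrony.

A configuration of N ternary neurons is coarse-grained to the sorted
occupation counts (n1, n2, n3), n1 >= n2 >= n3, n1 + n2 + n3 = N: n1 is the
size of the plurality, n3 the smaller minority, with no fixed association to
the up/flat/down labels.  The fine-grained synchrony distribution
phi_fine(n1, n2, n3) is the probability of each such triple; the coarse
variant phi_coarse(n1) keeps only the plurality size.  Synchrony treats
neurons (and state labels) on an equal footing, so it is invariant under
neuron permutations and state relabelings.

The support of phi_fine is the set of partitions of N into at most three
parts; its size is the nearest integer to (N + 3)^2 / 12 (234 for N = 50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PottsModel, StateMatrix, exact_distribution


@dataclass
class SynchronyDistribution:
    """Probability distribution over coarse synchrony states.

    ``support`` lists (n1, n2, n3) triples (fine) or plurality sizes n1
    (coarse) in the fixed enumeration order; ``probs`` matches it.
    """

    granularity: str
    support: list
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.granularity not in ("fine", "coarse"):
            raise ValueError("granularity must be 'fine' or 'coarse'")
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.support) != self.probs.shape[0]:
            raise ValueError("support and probs must have equal length")
        if (self.probs < -1e-15).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def as_dict(self) -> dict:
        return dict(zip(self.support, self.probs))


def synchrony_state(state: np.ndarray) -> tuple[int, int, int]:
    """Sorted occupation counts (n1 >= n2 >= n3) of a ternary configuration."""
    state = np.asarray(state)
    counts = sorted(
        (int((state == k).sum()) for k in (-1, 0, 1)), reverse=True
    )
    return tuple(counts)


def enumerate_synchrony_states(N: int) -> list[tuple[int, int, int]]:
    """All triples n1 >= n2 >= n3 >= 0 with n1 + n2 + n3 = N, descending lex order.

    The length is the number of partitions of N into at most 3 parts,
    equivalently round((N + 3)^2 / 12).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    out = []
    for n1 in range(N, -1, -1):
        for n2 in range(min(n1, N - n1), -1, -1):
            n3 = N - n1 - n2
            if n3 <= n2:
                out.append((n1, n2, n3))
    out.sort(reverse=True)
    return out


def coarse_state_index(N: int) -> dict[tuple[int, int, int], int]:
    """Triple -> rank in the fixed support order."""
    return {s: i for i, s in enumerate(enumerate_synchrony_states(N))}


def state_matrix_coarse_labels(values: np.ndarray) -> np.ndarray:
    """Vectorized coarse-state index per row of a K x N ternary array."""
    N = values.shape[1]
    index = coarse_state_index(N)
    counts = np.stack([(values == k).sum(axis=1) for k in (-1, 0, 1)], axis=1)
    counts = -np.sort(-counts, axis=1)
    lut = {}
    labels = np.empty(values.shape[0], dtype=np.intp)
    for i, row in enumerate(map(tuple, counts)):
        if row not in lut:
            lut[row] = index[row]
        labels[i] = lut[row]
    return labels


def _fine_from_labels(N: int, labels: np.ndarray, weights: np.ndarray) -> SynchronyDistribution:
    support = enumerate_synchrony_states(N)
    probs = np.bincount(labels, weights=weights, minlength=len(support))
    probs = probs / probs.sum()
    return SynchronyDistribution(granularity="fine", support=support, probs=probs)


def synchrony_distribution(
    source: PottsModel | StateMatrix,
    granularity: str = "fine",
    method: str = "exact",
    mc_settings: dict | None = None,
) -> SynchronyDistribution:
    """Synchrony distribution of a model (exact or sampled) or of data.

    The exact model path sums enumerated Boltzmann probabilities over the
    configurations mapping to each coarse state; the data path counts rows.
    Coarse granularity marginalizes fine over (n2, n3).
    """
    if isinstance(source, PottsModel):
        if method == "exact":
            dist = exact_distribution(source)
            labels = state_matrix_coarse_labels(dist.states)
            fine = _fine_from_labels(source.N, labels, dist.p)
        elif method == "mc":
            from .synthetic import sample_states

            mc = dict(mc_settings or {})
            mc.setdefault("T", 10_000)
            mc.setdefault("seed", 0)
            sample = sample_states(source, **mc)
            labels = state_matrix_coarse_labels(sample.values)
            fine = _fine_from_labels(source.N, labels, np.ones(sample.T))
        else:
            raise ValueError(f"unknown method {method!r}")
    elif isinstance(source, StateMatrix):
        labels = state_matrix_coarse_labels(source.values)
        fine = _fine_from_labels(source.N, labels, np.ones(source.T))
    else:
        raise TypeError("source must be a PottsModel or StateMatrix")

    if granularity == "fine":
        return fine
    if granularity == "coarse":
        N = sum(fine.support[0])
        support = [n1 for n1 in range(N, -1, -1) if 3 * n1 >= N]  # feasible pluralities
        pos = {n1: i for i, n1 in enumerate(support)}
        probs = np.zeros(len(support))
        for (n1, _, _), p in zip(fine.support, fine.probs):
            probs[pos[n1]] += p
        return SynchronyDistribution(
            granularity="coarse", support=support, probs=probs / probs.sum()
        )
    raise ValueError("granularity must be 'fine' or 'coarse'")
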