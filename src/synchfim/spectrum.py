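"""Rank-ordered eigenvalue spectra and the truncated power-law (Zipf) fit.

Sloppy sensitivity spectra are summarized by fitting the rank-ordered
eigenvalues with

    lambda_z = A z^-alpha exp(-z / zbar),   z <= Z_cut,

a power law with exponential tail; the pure exponential is the nested
special case alpha = 0.  Taking logs makes the model linear in
(log A, alpha, 1/zbar), so both fits are ordinary least squares on
log lambda_z with equal rank weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpectrumFit:
    """Truncated power-law fit of a rank spectrum, plus the nested alpha = 0 fit."""

    A: float
    alpha: float
    zbar: float
    Z_cut: int
    residual: float
    alternative_residual: float
    alternative_zbar: float = float("nan")

    def predict(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.A * z**-self.alpha * np.exp(-z / self.zbar)


def fit_truncated_power_law(eigenvalues: np.ndarray, Z_cut: int | None = None) -> SpectrumFit:
    """OLS fit of log lambda_z = log A - alpha log z - z / zbar over ranks 1..Z_cut.

    Also fits the restricted exponential (alpha = 0) model; nesting guarantees
    the full model's mean squared log-residual is no larger.  A nonpositive
    fitted decay-rate coefficient is reported as zbar = inf (no exponential
    truncation detected).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if Z_cut is None:
        Z_cut = lam.shape[0]
    if Z_cut < 3:
        raise ValueError("need at least 3 ranks to fit (A, alpha, zbar)")
    if Z_cut > lam.shape[0]:
        raise ValueError("Z_cut exceeds the number of eigenvalues")
    lam = lam[:Z_cut]
    if (lam <= 0).any():
        raise ValueError("eigenvalues up to Z_cut must be positive")
    z = np.arange(1, Z_cut + 1, dtype=float)
    y = np.log(lam)

    X_full = np.column_stack([np.ones_like(z), -np.log(z), -z])
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid_full = float(np.mean((y - X_full @ beta) ** 2))

    X_exp = X_full[:, [0, 2]]
    beta_exp, *_ = np.linalg.lstsq(X_exp, y, rcond=None)
    resid_exp = float(np.mean((y - X_exp @ beta_exp) ** 2))

    def rate_to_zbar(rate: float) -> float:
        return 1.0 / rate if rate > 0 else float("inf")

    return SpectrumFit(
        A=float(np.exp(beta[0])),
        alpha=float(beta[1]),
        zbar=rate_to_zbar(float(beta[2])),
        Z_cut=int(Z_cut),
        residual=resid_full,
        alternative_residual=resid_exp,
        alternative_zbar=rate_to_zbar(float(beta_exp[1])),
    )


def truncation_rank(
    eigenvalues: np.ndarray,
    precision_floor: float = 1e-12,
    n_neurons: int | None = None,
) -> int:
    """Largest rank whose eigenvalue exceeds precision_floor x the principal one.

    The floor marks the double-precision eigensolver noise level.  When the
    neuron count is given, the rank is additionally capped at the synchrony
    dimensionality (the number of partitions of N into at most 3 parts),
    the hard upper limit on the rank of a synchrony FIM.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue list")
    cutoff = precision_floor * lam.max()
    above = np.nonzero(lam > cutoff)[0]
    rank = int(above.max()) + 1 if above.size else 1
    if n_neurons is not None:
        from .synchrony import enumerate_synchrony_states

        rank = min(rank, len(enumerate_synchrony_states(n_neurons)))
    return rank
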