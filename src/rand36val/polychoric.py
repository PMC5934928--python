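"""Polychoric correlation and ordinal (polychoric) alpha.

Internal consistency of Likert-type items is estimated here on the latent
scale: each ordinal item is modelled as a discretised standard normal
variable, pairwise latent correlations are estimated by two-step maximum
likelihood (thresholds fixed from the margins, correlation maximising the
multinomial likelihood with bivariate-normal cell probabilities), and the
Cronbach-type alpha formula is applied to the resulting correlation matrix.
Unlike raw-score alpha this assumes only that the underlying construct is
continuous, not the observed responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

__all__ = [
    "PolychoricEstimate",
    "AlphaResult",
    "thresholds_from_margins",
    "polychoric_rho",
    "ordinal_alpha",
]

RHO_BOUND = 0.999
_TAIL = 8.0  # effective +/- infinity for standard-normal thresholds


@dataclass(frozen=True)
class PolychoricEstimate:
    """Latent correlation of two ordinal items with their thresholds."""

    rho: float
    tau1: np.ndarray
    tau2: np.ndarray
    loglik: float
    converged: bool


@dataclass(frozen=True)
class AlphaResult:
    """Ordinal alpha over k items with the pairwise polychoric matrix."""

    alpha: float
    k: int
    mean_offdiag: float
    rho_matrix: np.ndarray
    n_complete: int


def thresholds_from_margins(proportions) -> np.ndarray:
    """Standard-normal thresholds implied by marginal category proportions.

    ``tau_c = Phi^{-1}(F(c))`` for c = 1..C-1.  Zero-frequency categories
    make adjacent thresholds coincide and are rejected: collapse the empty
    category (or use a continuity correction) first.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p <= 0):
        raise ValueError(
            "zero-frequency category: collapse it into a neighbour (or apply a "
            "continuity correction) before computing thresholds"
        )
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    return norm.ppf(np.cumsum(p)[:-1])


def _cell_probabilities(tau1: np.ndarray, tau2: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for a threshold grid."""
    edges1 = np.concatenate(([-_TAIL], tau1, [_TAIL]))
    edges2 = np.concatenate(([-_TAIL], tau2, [_TAIL]))
    g1, g2 = np.meshgrid(edges1, edges2, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
                              allow_singular=True)
    cdf = np.asarray(mvn.cdf(pts)).reshape(g1.shape)
    probs = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(probs, 1e-12, None)


def polychoric_rho(
    crosstab, zero_correction: float | None = None
) -> PolychoricEstimate:
    """Two-step ML polychoric correlation from a C1 x C2 cross-table.

    Thresholds are fixed at the normal quantiles of the marginal
    distributions; the correlation is found by bounded scalar optimisation
    of the multinomial log-likelihood over [-0.999, 0.999].  All-empty rows
    or columns are dropped (they carry no likelihood).  ``zero_correction``
    adds that amount (typically 0.5) to empty cells before estimation.
    """
    counts = np.asarray(crosstab, dtype=float)
    if counts.ndim != 2:
        raise ValueError("crosstab must be a 2-D count matrix")
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 non-empty categories per margin")
    n = counts.sum()
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n:g}")
    if zero_correction:
        counts = np.where(counts == 0, zero_correction, counts)
    tau1 = thresholds_from_margins(counts.sum(axis=1) / counts.sum())
    tau2 = thresholds_from_margins(counts.sum(axis=0) / counts.sum())

    def negloglik(rho: float) -> float:
        return -float(np.sum(counts * np.log(_cell_probabilities(tau1, tau2, rho))))

    res = minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    converged = bool(res.success)
    if not converged:
        warnings.warn("polychoric optimisation did not converge", stacklevel=2)
    if abs(rho) >= RHO_BOUND - 1e-4:
        warnings.warn(
            f"polychoric correlation at the +/-{RHO_BOUND} bound (near-degenerate "
            "table)",
            stacklevel=2,
        )
    return PolychoricEstimate(
        rho=rho, tau1=tau1, tau2=tau2, loglik=-float(res.fun), converged=converged
    )


def ordinal_alpha(items, zero_correction: float | None = None) -> AlphaResult:
    """Ordinal alpha of an n x k ordinal response matrix.

    Rows with any missing value are dropped (complete-case).  The k x k
    pairwise polychoric matrix (unit diagonal) feeds the alpha identity
    ``alpha = k/(k-1) * (1 - k / sum(R))``.  Empty cells of a pairwise
    cross-table contribute nothing to the multinomial likelihood and need
    no special handling; pass ``zero_correction=0.5`` to reproduce the
    classical continuity-corrected estimates instead.
    """
    df = pd.DataFrame(items)
    k = df.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    df = df.dropna()
    n = len(df)
    R = np.eye(k)
    failures = []
    cols = list(df.columns)
    for a in range(k):
        for b in range(a + 1, k):
            tab = pd.crosstab(df[cols[a]], df[cols[b]]).to_numpy()
            try:
                est = polychoric_rho(tab, zero_correction=zero_correction)
            except Exception as exc:  # noqa: BLE001 - reported collectively below
                failures.append((cols[a], cols[b], str(exc)))
                continue
            R[a, b] = R[b, a] = est.rho
    if failures:
        detail = "; ".join(f"({a!r}, {b!r}): {msg}" for a, b, msg in failures)
        raise RuntimeError(f"polychoric estimation failed for item pairs: {detail}")
    total = R.sum()
    alpha = (k / (k - 1)) * (1.0 - k / total)
    off = R[~np.eye(k, dtype=bool)]
    return AlphaResult(
        alpha=float(alpha),
        k=k,
        mean_offdiag=float(off.mean()),
        rho_matrix=R,
        n_complete=n,
    )
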