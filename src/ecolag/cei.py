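"""Comprehensive ecological index (CEI) by correlation-matrix PCA.

The five indicators (NDVI, LAI, GPP, LST, Wet) are standardized, the
correlation matrix is eigendecomposed, the leading components are kept
until their cumulative variance contribution passes 80%, and the CEI is
the contribution-weighted sum of the retained component scores:

    P = sum_{i<=n} k_i * X_i,

with k_i the variance contribution of component i (applied as a
fraction) and X_i its score.  Eigenvector signs are fixed so each
component's largest-magnitude loading is positive — P is sign-sensitive
and this removes the inherent eigenvector sign ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SELECTION_THRESHOLD = 80.0  # percent cumulative variance


@dataclass
class PCAResult:
    """Correlation-matrix PCA: rows of ``loadings`` are components, columns
    indicators.  ``scaled_loadings`` are eigenvectors scaled by sqrt(λ)
    (the component–indicator correlations)."""

    loadings: np.ndarray
    eigenvalues: np.ndarray
    contribution: np.ndarray      # percent of total variance
    cumulative: np.ndarray        # running sum, percent
    n_selected: int
    scores: np.ndarray            # unit x component
    indicator_names: list[str] | None = None

    @property
    def scaled_loadings(self) -> np.ndarray:
        return self.loadings * np.sqrt(np.maximum(self.eigenvalues, 0))[:, None]


@dataclass
class CEIResult:
    P: np.ndarray                 # per-unit composite score
    weights_used: np.ndarray      # retained k_i as fractions
    year: int | None = None


def standardize(matrix: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Column-wise z-scores with the n-1 (sample) denominator."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 units")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        labels = [names[j] if names else f"column {j}" for j in zero]
        raise ValueError(f"zero-variance indicator(s): {labels}")
    return (X - X.mean(axis=0)) / sd


def pca(matrix: np.ndarray, names: list[str] | None = None) -> PCAResult:
    """Eigendecomposition of the correlation matrix of a standardized
    unit x indicator matrix; components ordered by descending eigenvalue."""
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in PCA input")
    R = np.corrcoef(X, rowvar=False)
    lam, vec = np.linalg.eigh(R)          # ascending
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)         # guard tiny negative roundoff
    loadings = vec.T                       # rows = components
    for k in range(loadings.shape[0]):    # largest-|loading| positive
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
    contribution = 100.0 * lam / lam.sum()
    cumulative = np.cumsum(contribution)
    return PCAResult(
        loadings=loadings,
        eigenvalues=lam,
        contribution=contribution,
        cumulative=cumulative,
        n_selected=select_components(contribution),
        scores=X @ loadings.T,
        indicator_names=list(names) if names else None,
    )


def select_components(contribution, threshold: float = SELECTION_THRESHOLD) -> int:
    """Smallest n whose cumulative contribution reaches ``threshold``
    percent; all components if the threshold is never reached."""
    c = np.asarray(contribution, dtype=float)
    if c.size == 0:
        raise ValueError("empty contribution list")
    cum = np.cumsum(c)
    hit = np.flatnonzero(cum >= threshold)
    return int(hit[0]) + 1 if hit.size else int(c.size)


def composite_score(result: PCAResult, year: int | None = None) -> CEIResult:
    """P = sum over retained components of (k_i / 100) * X_i."""
    n = result.n_selected
    k = result.contribution[:n] / 100.0
    return CEIResult(P=result.scores[:, :n] @ k, weights_used=k, year=year)


def cei_from_panel(matrix: np.ndarray, names: list[str] | None = None,
                   year: int | None = None) -> tuple[CEIResult, PCAResult]:
    """Standardize → PCA → 80% selection → weighted score, in one call."""
    res = pca(standardize(matrix, names), names)
    return composite_score(res, year), res
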