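"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Decomposes a spectral time series D (samples x channels) into
non-negative concentration profiles C (samples x k) and component
spectra S (channels x k) so that D ~ C S^T. Updates alternate
non-negative least squares on C given S and S given C; the residual sum
of squares is non-increasing by construction and iteration stops when
its relative change falls below a tolerance.

Initialization uses purest-variable selection (a SIMPLISMA-style
purity/determinant criterion over channels); additional seeded random
restarts guard against poor local minima and the lowest-residual
restart is returned. The usual rotational/scale ambiguity of bilinear
models is resolved for reporting only, by normalizing each component
spectrum to unit maximum and absorbing the scale into C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import DegenerateInputError
from .synthetic import SpectraMatrix

__all__ = ["MCRResult", "ComponentSelection", "fit_mcr", "explained_variance",
           "select_components"]


@dataclass(frozen=True)
class MCRResult:
    """Best-restart MCR-ALS factorization of one spectra matrix."""

    C: np.ndarray                  # samples x k, >= 0
    S: np.ndarray                  # channels x k, >= 0, unit-max columns
    explained_variance: float      # percent
    n_iter: int
    converged: bool
    k: int
    rss: float
    rss_history: tuple[float, ...]


@dataclass(frozen=True)
class ComponentSelection:
    """Outcome of the explained-variance model-selection scan."""

    k: int
    reached_threshold: bool
    ev_by_k: dict[int, float]
    ev_threshold: float


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, SpectraMatrix):
        D = D.intensities
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise DegenerateInputError("spectra must be a 2-D samples x channels matrix")
    return D


def explained_variance(D, C: np.ndarray, S: np.ndarray) -> float:
    """Percent variance of D captured by the bilinear model C S^T.

    ``100 * (1 - ||D - C S^T||_F^2 / ||D||_F^2)``.
    """
    D = _as_matrix(D)
    denom = float(np.sum(D * D))
    if denom == 0.0:
        raise DegenerateInputError("explained variance undefined for an all-zero matrix")
    resid = D - C @ S.T
    return 100.0 * (1.0 - float(np.sum(resid * resid)) / denom)


def _purest_channels(D: np.ndarray, k: int, offset_frac: float = 0.03) -> list[int]:
    """SIMPLISMA-style purest-variable channel selection.

    Purity of a channel is its relative standard deviation (offset-damped
    to suppress near-zero-mean channels); subsequent picks are weighted by
    the determinant of the Gram matrix of already-selected normalized
    channels, which suppresses channels collinear with earlier picks.
    """
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    offset = offset_frac * float(np.abs(mu).max() or 1.0)
    purity = sd / (np.abs(mu) + offset)
    norm = np.sqrt(np.mean(D * D, axis=0) + offset ** 2)
    Z = D / norm                                   # samples x channels, scaled
    corr = (Z.T @ Z) / D.shape[0]                  # channels x channels
    selected = [int(np.argmax(purity))]
    for _ in range(1, k):
        weights = np.empty(D.shape[1])
        for j in range(D.shape[1]):
            idx = selected + [j]
            weights[j] = np.linalg.det(corr[np.ix_(idx, idx)])
        weights[selected] = 0.0
        scores = purity * np.clip(weights, 0.0, None)
        selected.append(int(np.argmax(scores)))
    return selected


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for each column b of B; returns k x ncols."""
    out = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        out[:, j], _ = nnls(A, B[:, j])
    return out


def fit_mcr(
    D,
    k: int,
    init: str = "purest-variable",
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
    restart_ev_margin: float = 0.01,
) -> MCRResult:
    """Fit a k-component non-negative bilinear model to a spectra matrix.

    Parameters
    ----------
    D:
        :class:`~ecmsom.synthetic.SpectraMatrix` or samples x channels array.
    k:
        Number of components, ``1 <= k <= min(n_samples, n_channels)``.
    init:
        ``"purest-variable"`` (first restart from SIMPLISMA-style channel
        picks, remaining restarts seeded-random) or ``"seeded-random"``
        (all restarts random).
    tol:
        Relative change in residual sum of squares at which ALS stops.
    n_restarts:
        Number of initializations; the lowest-RSS solution is returned,
        except that the purest-variable solution is kept unless a random
        restart improves explained variance by more than
        ``restart_ev_margin`` percentage points. Residual differences at
        the noise floor are typically rotations of the same bilinear fit,
        and the informed initialization is the better representative of
        such a tie.
    """
    D = _as_matrix(D)
    n_samples, n_channels = D.shape
    if not 1 <= k <= min(n_samples, n_channels):
        raise ValueError(
            f"k={k} outside [1, min(samples, channels)={min(n_samples, n_channels)}]")
    if not np.any(D):
        raise DegenerateInputError("all-zero spectra matrix")
    if init not in ("purest-variable", "seeded-random"):
        raise ValueError(f"unknown init {init!r}")
    total = float(np.sum(D * D))
    rng = np.random.default_rng(seed)

    results: list[MCRResult] = []
    for restart in range(max(1, n_restarts)):
        if restart == 0 and init == "purest-variable":
            C = np.clip(D[:, _purest_channels(D, k)], 0.0, None)
            if not np.any(C):          # pathological: purest channels all zero
                C = rng.uniform(0.1, 1.0, size=(n_samples, k))
        else:
            C = rng.uniform(0.1, 1.0, size=(n_samples, k)) * float(D.max())
        history: list[float] = []
        prev = np.inf
        converged = False
        S = np.zeros((n_channels, k))
        for it in range(1, max_iter + 1):
            S = _nnls_columns(C, D).T              # channels x k
            if not np.any(S):
                break                              # dead factorization
            C = _nnls_columns(S, D.T).T            # samples x k
            resid = D - C @ S.T
            rss = float(np.sum(resid * resid))
            history.append(rss)
            if prev < np.inf and prev > 0 and (prev - rss) / prev < tol:
                converged = True
                break
            prev = rss
        rss = history[-1] if history else total
        ev = 100.0 * (1.0 - rss / total)
        # report with unit-max spectra, scale absorbed into C
        scale = S.max(axis=0)
        scale[scale == 0] = 1.0
        result = MCRResult(
            C=C * scale, S=S / scale, explained_variance=ev,
            n_iter=len(history), converged=converged, k=k, rss=rss,
            rss_history=tuple(history))
        results.append(result)
    best = min(results, key=lambda r: r.rss)
    if init == "purest-variable":
        anchored = results[0]
        if best.explained_variance - anchored.explained_variance <= restart_ev_margin:
            return anchored
    return best


def select_components(
    D,
    k_max: int = 6,
    ev_threshold: float = 99.9,
    **fit_kwargs,
) -> ComponentSelection:
    """Smallest component count whose best fit reaches ``ev_threshold`` percent.

    Scans k = 1..k_max; if no fit reaches the threshold the scan returns
    ``k_max`` with ``reached_threshold=False``. Extra keyword arguments
    are passed to :func:`fit_mcr`.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    D = _as_matrix(D)
    ev_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        ev_by_k[k] = fit_mcr(D, k, **fit_kwargs).explained_variance
        if ev_by_k[k] >= ev_threshold:
            return ComponentSelection(k=k, reached_threshold=True,
                                      ev_by_k=ev_by_k, ev_threshold=ev_threshold)
    return ComponentSelection(k=k_max, reached_threshold=False,
                              ev_by_k=ev_by_k, ev_threshold=ev_threshold)
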