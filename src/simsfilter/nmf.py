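"""Non-negative matrix factorization of depth-profile matrices.

Decomposes a non-negative peaks x scans matrix X into endmember
loadings W (peaks x k, the spectral weight of each peak in each
component) and endmember depth profiles H (k x scans), minimizing the
squared Frobenius reconstruction error with Lee-Seung multiplicative
updates. The update rule keeps every entry non-negative and never
increases the objective, which the per-iteration ``objective_trace``
records. Initialization is the elementwise absolute value of seeded
standard normals, so runs are bit-reproducible given a seed.

The factor count is chosen by the endmember-repetition heuristic:
increase k until loadings start duplicating (max pairwise cosine among
loading columns above a threshold), then keep the last k before the
duplication appeared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorModel",
    "nmf",
    "repetition_score",
    "choose_k",
    "match_components",
]

_EPS = 1e-12


@dataclass
class FactorModel:
    """Result of one NMF run.

    ``loadings`` columns are scaled to unit maximum with the scale
    absorbed into ``profiles``, so the product W @ H is unchanged by the
    normalization.
    """

    loadings: np.ndarray  # peaks x k
    profiles: np.ndarray  # k x scans
    k: int
    objective_trace: np.ndarray  # Frobenius reconstruction error per iteration
    seed: int

    def reconstruct(self) -> np.ndarray:
        return self.loadings @ self.profiles

    def relative_error(self, X: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        return float(np.linalg.norm(X - self.reconstruct()) / np.linalg.norm(X))

    def loadings_frame(self, peak_ids=None) -> pd.DataFrame:
        idx = peak_ids if peak_ids is not None else range(self.loadings.shape[0])
        return pd.DataFrame(
            self.loadings, index=idx, columns=[f"factor_{j + 1}" for j in range(self.k)]
        )

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles,
            index=[f"factor_{j + 1}" for j in range(self.k)],
            columns=[f"scan_{i + 1:04d}" for i in range(self.profiles.shape[1])],
        )


def nmf(
    X,
    k: int,
    iters: int = 200,
    seed: int = 0,
    normalize_rows: bool = False,
) -> FactorModel:
    """Factorize ``X`` (peaks x scans, elementwise >= 0) into k components.

    Parameters
    ----------
    X : array-like
        Non-negative depth-profile matrix.
    k : int
        Number of endmembers; must satisfy 1 <= k <= min(X.shape).
    iters : int
        Number of full multiplicative-update sweeps (default 200).
    seed : int
        Seeds the |N(0,1)| initialization of both factors.
    normalize_rows : bool
        Max-normalize each peak row before factorizing. Off by default:
        raw intensities weight the fit, which biases toward intense ions
        but mirrors the unnormalized analysis; switch on to equalize
        peak influence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("X must be elementwise non-negative and finite")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k must be in [1, {min(X.shape)}], got {k}")
    if normalize_rows:
        rowmax = X.max(axis=1, keepdims=True)
        rowmax[rowmax == 0] = 1.0
        X = X / rowmax

    rng = np.random.default_rng(seed)
    W = np.abs(rng.standard_normal((X.shape[0], k)))
    H = np.abs(rng.standard_normal((k, X.shape[1])))

    trace = np.empty(iters)
    for it in range(iters):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        trace[it] = np.linalg.norm(X - W @ H)

    # unit-max loading columns; scale absorbed into the profiles
    scale = W.max(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return FactorModel(loadings=W, profiles=H, k=k, objective_trace=trace, seed=seed)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def repetition_score(model: FactorModel) -> float:
    """Maximum pairwise cosine similarity among loading columns.

    1.0 means two endmembers carry identical spectral loadings — the
    overfitting signature used to stop increasing the factor count.
    Undefined (rejected) for k=1.
    """
    if model.k < 2:
        raise ValueError("repetition score is undefined for k=1")
    W = model.loadings
    best = 0.0
    for i in range(model.k):
        for j in range(i + 1, model.k):
            best = max(best, _cosine(W[:, i], W[:, j]))
    return best


def _duplication_score(model: FactorModel) -> float:
    """Endmember duplication on either side of the factorization: the max
    pairwise cosine among loading columns or among profile rows. On an
    overfitted rank-deficient fit the redundancy can land in either
    factor (two parallel loadings, or two parallel profiles), so both
    are checked."""
    W, H = model.loadings, model.profiles
    best = 0.0
    for i in range(model.k):
        for j in range(i + 1, model.k):
            best = max(best, _cosine(W[:, i], W[:, j]), _cosine(H[i], H[j]))
    return best


def choose_k(
    X,
    k_range=range(1, 5),
    threshold: float = 0.98,
    iters: int = 200,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Recommend the factor count via the endmember-repetition heuristic.

    Runs NMF at every k in ``k_range`` and returns the smallest k whose
    step to k+1 pushes the duplication score (max pairwise cosine among
    loading columns or profile rows) above ``threshold`` — i.e. the
    last k before endmembers start duplicating — together with the full
    diagnostic table so the recommendation can be overruled. If no step
    ever crosses the threshold the maximum of the range is returned
    with a warning.
    """
    ks = sorted(k_range)
    if not ks or ks[0] < 1 or ks[-1] > min(np.asarray(X).shape):
        raise ValueError("k_range must lie within the matrix dimensions")
    rows = []
    scores: dict[int, float] = {}
    for k in ks:
        model = nmf(X, k, iters=iters, seed=seed)
        score = _duplication_score(model) if k >= 2 else float("nan")
        scores[k] = score
        rows.append(
            {
                "k": k,
                "final_error": float(model.objective_trace[-1]),
                "repetition_score": score,
            }
        )
    diagnostics = pd.DataFrame(rows)
    recommended = None
    for k in ks:
        if k + 1 in scores and scores[k + 1] > threshold:
            recommended = k
            break
    if recommended is None:
        recommended = ks[-1]
        warnings.warn(
            f"no k in {ks} showed loading repetition above {threshold}; "
            f"returning the maximum of the range",
            stacklevel=2,
        )
    return recommended, diagnostics


def match_components(truth: np.ndarray, estimated: np.ndarray) -> tuple[list, list]:
    """Match rows of two component matrices by maximum-cosine assignment.

    Used to score recovery of known depth-profile shapes: returns the
    optimal (Hungarian) pairing and the per-pair cosine similarities.
    """
    truth = np.asarray(truth, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    cos = np.zeros((truth.shape[0], estimated.shape[0]))
    for i in range(truth.shape[0]):
        for j in range(estimated.shape[0]):
            cos[i, j] = _cosine(truth[i], estimated[j])
    rows, cols = linear_sum_assignment(-cos)
    return list(zip(rows, cols)), [float(cos[i, j]) for i, j in zip(rows, cols)]
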