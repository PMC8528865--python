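"""Rank-frequency laws: Zipf and the Discrete Generalized Beta Distribution.

Class frequencies in annotated corpora are heavy-tailed. The two-exponent
DGBD,

    f(r) = A * (N + 1 - r)**b / r**a,      r = 1..N,

generalizes Zipf's power law (the b = 0 special case) by letting the tail
bend down when the inventory of classes is finite. Estimation is ordinary
least squares in log space — log f(r) regressed on [1, log(N+1-r), log r] —
which is the standard practice for this family and gives closed-form
diagnostics; the Zipf fit is the same regression with the reversed-rank
column dropped, and the two are compared with a nested-model F test of
b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .stats import FrequencyTable

__all__ = [
    "DGBDFit",
    "DGBDModel",
    "dgbd_expected",
    "fit_dgbd",
    "fit_zipf",
    "compare_zipf_vs_dgbd",
]


@dataclass(frozen=True)
class DGBDFit:
    """Fitted DGBD parameters on a ranked count table."""

    A: float
    a: float
    b: float
    N: int
    r_squared: float
    residuals: np.ndarray  # per-rank log residuals, rank order

    def expected(self, r) -> np.ndarray | float:
        return dgbd_expected(r, self)


def dgbd_expected(r, fit: DGBDFit):
    """Model value A*(N+1-r)**b / r**a at rank(s) r, 1 <= r <= N."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 1) or np.any(r_arr > fit.N):
        raise ValueError(f"rank out of range 1..{fit.N}")
    out = fit.A * (fit.N + 1 - r_arr) ** fit.b / r_arr**fit.a
    return out if out.ndim else float(out)


def _ranked_counts(ft, assume_ranked: bool = False) -> np.ndarray:
    if isinstance(ft, FrequencyTable):
        counts = np.asarray(ft.ranked_counts(), dtype=float)
    else:
        counts = np.asarray(ft, dtype=float)
        counts = counts[counts > 0]
        if not assume_ranked:
            counts = np.sort(counts)[::-1]
    return counts


class DGBDModel(BaseEstimator):
    """Least-squares DGBD fit in log space, sklearn-style.

    Parameters
    ----------
    zipf:
        If True, constrain b = 0 (pure power law).
    assume_ranked:
        Treat a raw count array as already rank-ordered instead of sorting it.
        Sorting noisy counts correlates residuals with rank, which matters for
        significance calibration when noise is comparable to the spacing
        between adjacent expected counts.

    Attributes (after ``fit``)
    --------------------------
    A_, a_, b_ : float
        Scale and the two exponents (``b_`` is 0.0 in Zipf mode).
    n_ranks_ : int
        Number of positive-count ranks used.
    r_squared_ : float
        Coefficient of determination of log count on the design.
    residuals_ : ndarray
        Log-space residuals in rank order.
    """

    def __init__(self, zipf: bool = False, assume_ranked: bool = False):
        self.zipf = zipf
        self.assume_ranked = assume_ranked

    def fit(self, counts, y=None):
        c = _ranked_counts(counts, self.assume_ranked)
        min_n = 2 if self.zipf else 3  # params saturate at these sizes
        if len(c) < min_n:
            raise ValueError(
                f"need >= {min_n} positive-count ranks, got {len(c)}"
            )
        n = len(c)
        r = np.arange(1, n + 1, dtype=float)
        y_log = np.log(c)
        cols = [np.ones(n), np.log(n + 1 - r)]
        if self.zipf:
            cols = [np.ones(n)]
        X = np.column_stack(cols + [np.log(r)])
        beta, _, _, _ = np.linalg.lstsq(X, y_log, rcond=None)
        if self.zipf:
            log_A, neg_a = beta
            b = 0.0
        else:
            log_A, b, neg_a = beta
        self.A_ = float(np.exp(log_A))
        self.a_ = float(-neg_a)
        self.b_ = float(b)
        self.n_ranks_ = n
        fitted = X @ beta
        resid = y_log - fitted
        tss = float(np.sum((y_log - y_log.mean()) ** 2))
        rss = float(np.sum(resid**2))
        self.r_squared_ = 1.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
        self.residuals_ = resid
        self.rss_ = rss
        return self

    def predict(self, r):
        return dgbd_expected(r, self.fit_result_)

    @property
    def fit_result_(self) -> DGBDFit:
        return DGBDFit(
            A=self.A_,
            a=self.a_,
            b=self.b_,
            N=self.n_ranks_,
            r_squared=self.r_squared_,
            residuals=self.residuals_,
        )


def fit_dgbd(ft) -> DGBDFit:
    """Fit the two-exponent DGBD to a frequency table (or count array)."""
    return DGBDModel().fit(ft).fit_result_


def fit_zipf(ft) -> DGBDFit:
    """Fit the pure power law C / r**a (DGBD with b constrained to 0)."""
    return DGBDModel(zipf=True).fit(ft).fit_result_


def compare_zipf_vs_dgbd(ft, alpha: float = 0.05, assume_ranked: bool = False) -> dict:
    """Nested-model F test of b = 0 in log space.

    Returns ``{"F": ..., "p": ..., "preferred": "dgbd"|"zipf"}``; DGBD is
    preferred when p < alpha. Requires >= 4 ranks (one residual degree of
    freedom for the full model).
    """
    c = _ranked_counts(ft, assume_ranked)
    if len(c) < 4:
        raise ValueError("need >= 4 ranks for the nested comparison")
    full = DGBDModel(assume_ranked=True).fit(c)
    restricted = DGBDModel(zipf=True, assume_ranked=True).fit(c)
    df_resid = len(c) - 3
    if full.rss_ <= 0:
        F = np.inf
        p = 0.0
    else:
        F = (restricted.rss_ - full.rss_) / (full.rss_ / df_resid)
        p = float(sps.f.sf(F, 1, df_resid))
    return {"F": float(F), "p": p, "preferred": "dgbd" if p < alpha else "zipf"}
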