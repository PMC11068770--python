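"""Meta-combination of signed t-values across environments.

A SNP tested in ``n`` contexts (environment x treatment combinations for one
trait) yields a vector of signed t-values ``t_i``.  Because the contexts
share accessions, the t-values are correlated even under the null; the
correction estimates the ``n x n`` correlation matrix ``V`` of t-values
across all SNPs and forms::

    chi2_i = t_i' V^{-1} t_i

referred to a chi-square with df equal to the number of contexts the SNP was
actually tested in.  SNPs missing in some contexts are combined over their
present contexts with the matching submatrix of V and reduced df rather than
dropped.  Significance uses a Bonferroni cut (alpha / number of SNPs tested)
and a fixed suggestive cut (p < 1e-4) below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ModelError

logger = logging.getLogger(__name__)

__all__ = [
    "TCorrelation",
    "MetaAnalysis",
    "build_t_matrix",
    "estimate_t_correlation",
    "meta_statistic",
    "combine",
    "bonferroni_threshold",
    "classify",
]

_MIN_EIGENVALUE = 1e-6

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NONE = "none"


@dataclass
class TCorrelation:
    """Estimated cross-context correlation of t-values.

    ``values`` is a labelled square DataFrame with unit diagonal;
    ``pair_counts`` holds the number of SNPs with complete t-values for each
    context pair; ``repaired`` flags a shrinkage-toward-identity repair (by
    factor ``shrinkage``) applied to restore positive definiteness.
    """

    values: pd.DataFrame
    pair_counts: pd.DataFrame
    condition_number: float
    repaired: bool
    shrinkage: float = 0.0

    @property
    def contexts(self) -> list:
        return list(self.values.columns)


def build_t_matrix(assoc_tables: Mapping[object, pd.DataFrame]) -> pd.DataFrame:
    """Assemble SNPs x contexts signed t-values from per-context scan tables."""
    cols = {}
    for ctx, table in assoc_tables.items():
        cols[ctx] = table.set_index("snp_id")["t"]
    T = pd.DataFrame(cols)
    T.columns = list(assoc_tables.keys())
    return T


def estimate_t_correlation(T: pd.DataFrame, min_pairs: int = 100) -> TCorrelation:
    """Pairwise-complete product-moment correlation of t-values across SNPs.

    Raises if any context pair shares fewer than ``min_pairs`` SNPs.  If the
    estimate is not positive definite it is shrunk toward the identity by the
    smallest factor restoring the minimum eigenvalue to 1e-6 (flagged).
    """
    if T.shape[1] < 1:
        raise ModelError("t-matrix has no contexts")
    present = T.notna().astype(float)
    counts = present.T @ present
    ctxs = list(T.columns)
    counts_arr = counts.to_numpy()
    if len(ctxs) >= 2:
        for i, a in enumerate(ctxs):
            for j in range(i + 1, len(ctxs)):
                if counts_arr[i, j] < min_pairs:
                    raise ModelError(
                        f"context pair ({a}, {ctxs[j]}) shares only "
                        f"{int(counts_arr[i, j])} SNPs (< {min_pairs})"
                    )
    V = T.corr(method="pearson", min_periods=2)
    if V.isna().any().any():
        bad = [c for c in ctxs if V[c].isna().any()]
        raise ModelError(f"t-correlation undefined for contexts {bad}")
    np.fill_diagonal(V.values, 1.0)
    eig = np.linalg.eigvalsh(V.to_numpy())
    repaired, gamma = False, 0.0
    if eig[0] < _MIN_EIGENVALUE:
        # eigenvalues of (1-g)V + gI are (1-g)e + g: solve for the smallest g
        gamma = float((_MIN_EIGENVALUE - eig[0]) / (1.0 - eig[0]))
        Vn = (1.0 - gamma) * V.to_numpy() + gamma * np.eye(len(ctxs))
        V = pd.DataFrame(Vn, index=V.index, columns=V.columns)
        eig = np.linalg.eigvalsh(Vn)
        repaired = True
        logger.info("t-correlation repaired by shrinkage %.3g toward identity", gamma)
    cond = float(eig[-1] / eig[0])
    return TCorrelation(V, counts, cond, repaired, gamma)


def meta_statistic(t, V: TCorrelation | pd.DataFrame | np.ndarray):
    """Combine one SNP's signed t-values: returns ``(chi2, df, p)``.

    ``t`` may contain NaN for contexts where the SNP has no result; the
    statistic then uses the corresponding submatrix of V and df equal to the
    number of present entries.
    """
    if isinstance(V, TCorrelation):
        V = V.values
    V = np.asarray(V, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if t.shape[0] != V.shape[0]:
        raise ModelError(f"t has {t.shape[0]} entries but V is {V.shape[0]}x{V.shape[1]}")
    present = ~np.isnan(t)
    m = int(present.sum())
    if m == 0:
        raise ModelError("SNP has no t-value in any context")
    Vsub = V[np.ix_(present, present)]
    tsub = t[present]
    try:
        chi2 = float(tsub @ np.linalg.solve(Vsub, tsub))
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular t-correlation submatrix: {exc}") from exc
    p = float(stats.chi2.sf(chi2, df=m))
    return chi2, m, p


def combine(T: pd.DataFrame, V: TCorrelation | None = None,
            min_pairs: int = 100) -> pd.DataFrame:
    """Meta statistic for every SNP in a t-matrix (vectorised by NA-pattern).

    Returns a DataFrame indexed by snp_id with columns chi2, df, p,
    neglog10p.  ``neglog10p`` is computed on the log scale so it stays finite
    when p underflows.
    """
    if V is None:
        V = estimate_t_correlation(T, min_pairs=min_pairs)
    Vm = V.values.to_numpy() if isinstance(V, TCorrelation) else np.asarray(V)
    tvals = T.to_numpy(dtype=float)
    present = ~np.isnan(tvals)
    chi2 = np.full(len(T), np.nan)
    dfs = np.zeros(len(T), dtype=int)
    # group SNPs by missingness pattern: one solve per pattern
    patterns = {}
    for i, row in enumerate(present):
        patterns.setdefault(row.tobytes(), []).append(i)
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        m = int(mask.sum())
        rows = np.asarray(rows)
        if m == 0:
            continue
        Vsub = Vm[np.ix_(mask, mask)]
        ts = tvals[np.ix_(rows, np.flatnonzero(mask))]
        try:
            sol = np.linalg.solve(Vsub, ts.T)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular t-correlation submatrix: {exc}") from exc
        chi2[rows] = np.einsum("ij,ji->i", ts, sol)
        dfs[rows] = m
    logp = stats.chi2.logsf(np.where(np.isnan(chi2), 0.0, chi2),
                            df=np.where(dfs == 0, 1, dfs))
    out = pd.DataFrame(
        {
            "chi2": chi2,
            "df": dfs,
            "p": np.exp(logp),
            "neglog10p": -logp / np.log(10.0),
        },
        index=T.index,
    )
    out.loc[dfs == 0, ["p", "neglog10p"]] = np.nan
    out.index.name = "snp_id"
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Family-wise threshold ``alpha / n_tests`` and its -log10."""
    if n_tests < 1:
        raise ModelError("n_tests must be >= 1")
    p_thr = alpha / n_tests
    return p_thr, float(-np.log10(p_thr))


def classify(results: pd.DataFrame, n_tests: int, alpha: float = 0.05,
             suggestive_p: float = 1e-4) -> pd.DataFrame:
    """Label each SNP significant / suggestive / none.

    Significant: p <= alpha / n_tests (Bonferroni).  Suggestive: p below
    ``suggestive_p`` but above the Bonferroni cut.
    """
    p_thr, _ = bonferroni_threshold(n_tests, alpha)
    out = results.copy()
    p = out["p"].to_numpy()
    cls = np.where(p <= p_thr, SIGNIFICANT,
                   np.where(p < suggestive_p, SUGGESTIVE, NONE))
    cls = np.where(np.isnan(p), NONE, cls)
    out["class"] = cls
    return out


class MetaAnalysis(BaseEstimator):
    """Estimator wrapper around the t-correlation + combination pipeline.

    ``fit`` estimates the cross-context t-correlation from a t-matrix;
    ``transform`` combines (the same or another) t-matrix into per-SNP meta
    statistics, optionally classifying against a Bonferroni cut.
    """

    def __init__(self, min_pairs: int = 100, alpha: float = 0.05,
                 suggestive_p: float = 1e-4):
        self.min_pairs = min_pairs
        self.alpha = alpha
        self.suggestive_p = suggestive_p

    def fit(self, T: pd.DataFrame, y=None) -> "MetaAnalysis":
        if T.shape[1] >= 2:
            self.corr_ = estimate_t_correlation(T, min_pairs=self.min_pairs)
        else:
            ctx = list(T.columns)
            self.corr_ = TCorrelation(
                pd.DataFrame(np.eye(len(ctx)), index=ctx, columns=ctx),
                pd.DataFrame(T.notna().sum().to_numpy().reshape(1, 1),
                             index=ctx, columns=ctx),
                1.0, False, 0.0,
            )
        return self

    def transform(self, T: pd.DataFrame, n_tests: int | None = None) -> pd.DataFrame:
        results = combine(T, V=self.corr_)
        if n_tests is None:
            n_tests = int(results["p"].notna().sum())
        return classify(results, n_tests, self.alpha, self.suggestive_p)

    def fit_transform(self, T: pd.DataFrame, y=None, **kw) -> pd.DataFrame:
        return self.fit(T).transform(T, **kw)
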