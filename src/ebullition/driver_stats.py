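"""Relating ebullition to its environmental drivers: normality checks,
Spearman correlation matrices (overall and per mixing regime), and PCA.

Ebullition series are zero-inflated and far from normal, so association is
measured with rank correlations throughout.  Conditioning on the mixing
regime (mixed / partial / stratified, from the RWCS classification) exposes
how the strength — and sometimes the sign — of a driver's effect depends on
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool          # True when normality is NOT rejected at alpha
    alpha: float
    n: int


def normality_test(values: np.ndarray, alpha: float = 0.05,
                   min_points: int = 20) -> NormalityResult:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample sd)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < min_points:
        raise ValueError(f"normality_test: need at least {min_points} valid points, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("normality_test: degenerate constant sample")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityResult(statistic=float(stat), p_value=float(p),
                           normal=bool(p >= alpha), alpha=alpha, n=x.size)


@dataclass
class CorrelationMatrix:
    """Spearman rank correlations with per-cell significance."""

    labels: list[str]
    rs: pd.DataFrame          # correlation coefficients
    p_values: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at alpha
    n_pairs: pd.DataFrame      # pairwise-complete sample sizes
    alpha: float = 0.05
    group: str = "all"

    def masked(self) -> pd.DataFrame:
        """rs with non-significant cells set to NaN (diagonal kept)."""
        out = self.rs.where(self.significant)
        np.fill_diagonal(out.values, 1.0)
        return out


def spearman_matrix(table: pd.DataFrame, alpha: float = 0.05,
                    min_pairs: int = 10, group: str = "all") -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix of a variable table."""
    cols = list(table.columns)
    k = len(cols)
    rs = np.eye(k)
    pv = np.zeros((k, k))
    np_pairs = np.full((k, k), len(table))
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            np_pairs[i, j] = np_pairs[j, i] = len(pair)
            if len(pair) < min_pairs:
                rs[i, j] = rs[j, i] = np.nan
                pv[i, j] = pv[j, i] = np.nan
                continue
            r, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rs[i, j] = rs[j, i] = r
            pv[i, j] = pv[j, i] = p
    rs_f = pd.DataFrame(rs, index=cols, columns=cols)
    pv_f = pd.DataFrame(pv, index=cols, columns=cols)
    sig = pv_f < alpha
    np.fill_diagonal(sig.values, True)
    return CorrelationMatrix(labels=cols, rs=rs_f, p_values=pv_f, significant=sig,
                             n_pairs=pd.DataFrame(np_pairs, index=cols, columns=cols),
                             alpha=alpha, group=group)


def regime_conditioned_matrices(
    table: pd.DataFrame,
    regimes: np.ndarray,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> dict[str, CorrelationMatrix]:
    """One correlation matrix per mixing regime, plus the overall one."""
    regimes = np.asarray(regimes, dtype=object)
    if len(regimes) != len(table):
        raise ValueError("regime labels must align with the table rows")
    out = {"all": spearman_matrix(table, alpha, min_pairs, group="all")}
    for regime in ("mixed", "partial", "stratified"):
        sub = table[regimes == regime]
        if len(sub) >= min_pairs:
            out[regime] = spearman_matrix(sub, alpha, min_pairs, group=regime)
    return out


@dataclass
class PCAResult:
    explained_variance_pct: np.ndarray  # per component, sums to 100
    components: pd.DataFrame            # loadings (components x variables)
    scores: pd.DataFrame                # rows x components, with regime column
    n_rows: int
    meta: dict = field(default_factory=dict)


def pca_regimes(table: pd.DataFrame, regimes: np.ndarray | None = None,
                n_components: int | None = None) -> PCAResult:
    """PCA of the standardized variable table (listwise-complete rows).

    Standardizing first makes this a PCA of the correlation matrix, so no
    variable dominates through its units.  Scores carry the mixing-regime
    label of each retained row for grouped plotting.
    """
    keep = table.dropna()
    if regimes is not None:
        regimes = np.asarray(regimes, dtype=object)
        if len(regimes) != len(table):
            raise ValueError("regime labels must align with the table rows")
        regimes = regimes[table.notna().all(axis=1).to_numpy()]
    if len(keep) < len(keep.columns):
        raise ValueError("pca_regimes: fewer complete rows than variables")
    X = StandardScaler().fit_transform(keep.to_numpy(dtype=float))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    scores_df = pd.DataFrame(scores, index=keep.index, columns=comp_names)
    if regimes is not None:
        scores_df["regime"] = regimes
    return PCAResult(
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        components=pd.DataFrame(pca.components_, index=comp_names, columns=keep.columns),
        scores=scores_df,
        n_rows=len(keep),
        meta={"n_variables": len(keep.columns)},
    )
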