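"""Environment association: PCA, representative factors, correlations, clustering.

Climate (BIO1–BIO19) and soil factors carry incommensurable units, so PCA is
performed on the factor *correlation* matrix (factors z-standardised).  One
representative factor per retained component — the factor with the largest
absolute loading — feeds the downstream correlation and variance-partitioning
steps.  Sites are grouped by Ward hierarchical clustering (Ward.D2 on
Euclidean distance) of the standardised, concatenated climate + soil table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io import EnvTable, RunConfig


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # factors × components (unit eigenvectors)
    explained_proportion: pd.Series   # per component, sums to 1
    scores: pd.DataFrame              # sites × components
    block: str

    def representatives(self, n_components: int, per_component: int = 1,
                        ) -> list[str]:
        return select_representatives(self, n_components, per_component)


@dataclass
class SiteClustering:
    linkage_matrix: np.ndarray
    labels: pd.Series          # site → cluster id at the requested k
    k: int
    method: str = "ward.D2/euclidean"


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def pca(env: EnvTable) -> PCAResult:
    """Correlation-matrix PCA via eigendecomposition.

    Constant factors are dropped with a warning.  Each loading column is
    sign-fixed so that its largest-magnitude entry is positive, making the
    result deterministic.
    """
    df = env.values
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 sites and 2 factors")
    const = df.columns[df.std(ddof=1) == 0]
    if len(const):
        warnings.warn(f"constant factor(s) dropped from PCA: {list(const)}",
                      stacklevel=2)
        df = df.drop(columns=const)
    Z = _zscore(df)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=comps)
    explained = pd.Series(eigval / eigval.sum(), index=comps,
                          name="explained_proportion")
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=df.index, columns=comps)
    return PCAResult(loadings, explained, scores, env.block)


def select_representatives(pca_result: PCAResult, n_components: int,
                           per_component: int = 1) -> list[str]:
    """Greedy |loading| selection: for each retained component in order, the
    not-yet-selected factor(s) with the largest absolute loading."""
    if n_components > pca_result.loadings.shape[1]:
        raise ValueError("more components requested than available")
    chosen: list[str] = []
    for comp in pca_result.loadings.columns[:n_components]:
        ranked = pca_result.loadings[comp].abs().sort_values(ascending=False)
        picks = [f for f in ranked.index if f not in chosen][:per_component]
        chosen.extend(picks)
    return chosen


def associate(params: pd.DataFrame, env: EnvTable, factors: list[str],
              cfg: RunConfig | None = None) -> pd.DataFrame:
    """Pearson correlation + OLS line per (network parameter, env factor).

    ``params``: site × parameter table; sites must match the env table.
    Returns one row per pair with r, two-sided p, slope/intercept, and a
    significance flag at ``cfg.alpha``.
    """
    cfg = cfg or RunConfig()
    params = params.drop(index="pooled", errors="ignore")
    env = env.aligned_to(params.index)
    if len(params) < 4:
        raise ValueError("need at least 4 aligned sites")
    rows = []
    for par in params.columns:
        if par in ("N", "E", "n_components"):
            continue
        y = params[par].to_numpy(dtype=float)
        for fac in factors:
            x = env.values[fac].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"zero variance: ({par}, {fac}) skipped",
                              stacklevel=2)
                continue
            fit = stats.linregress(x, y)
            rows.append({
                "parameter": par, "factor": fac,
                "r": fit.rvalue, "p": fit.pvalue,
                "slope": fit.slope, "intercept": fit.intercept,
                "significant": fit.pvalue < cfg.alpha,
            })
    return pd.DataFrame(rows)


def cluster_sites(climate: EnvTable, soil: EnvTable, k: int = 2) -> SiteClustering:
    """Ward clustering of sites on the standardised climate + soil factors."""
    soil = soil.aligned_to(climate.site_ids)
    X = pd.concat([_zscore(climate.values), _zscore(soil.values)], axis=1)
    X = X.dropna(axis=1)  # constant factors z-score to NaN; they carry no signal
    n = len(X)
    if k > n:
        raise ValueError(f"cannot cut {n} sites into {k} clusters")
    lm = linkage(X.to_numpy(), method="ward", metric="euclidean")
    labels = pd.Series(fcluster(lm, t=k, criterion="maxclust"),
                       index=X.index, name="cluster")
    return SiteClustering(lm, labels, k)
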