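"""Correlation-threshold construction of leaf trait networks.

A trait network has one node per trait and an undirected edge between two
traits when the magnitude of their Pearson correlation strictly exceeds a
threshold (default 0.2) *and* the two-sided p-value is strictly below alpha
(default 0.05).  Topology metrics downstream use the binary adjacency; the
signed coefficient is kept as an edge attribute for export and display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import RunConfig, TraitTable


@dataclass
class CorrelationResult:
    """Pairwise Pearson coefficients with two-sided p-values.

    ``r`` and ``p`` are symmetric trait × trait matrices; ``n_eff`` holds the
    pairwise-complete sample size behind each coefficient.  Pairs with a
    zero-variance trait or fewer than 3 complete observations have NaN
    entries and never form edges.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n_eff: pd.DataFrame

    @property
    def trait_names(self) -> list[str]:
        return list(self.r.columns)


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p via the exact t-transform with n − 2 df (NaN where undefined)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        df = n - 2.0
        t = r * np.sqrt(df / (1.0 - r**2))
        p = np.where(df > 0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    # perfect correlation: t is infinite, sf gives 0 — keep, but guard NaN from 1-r^2=0
    p = np.where(np.isclose(np.abs(r), 1.0) & (df > 0), 0.0, p)
    return p


def pairwise_pearson(values: pd.DataFrame) -> CorrelationResult:
    """All-pairs Pearson correlation with pairwise-complete observations.

    Traits that are constant (zero variance) over the complete pairs are
    flagged with a warning; their coefficients are NaN so they stay in the
    node set but never gain edges.
    """
    X = values.to_numpy(dtype=float)
    names = list(values.columns)
    k = X.shape[1]

    if not np.isnan(X).any():
        n = X.shape[0]
        sd = X.std(axis=0, ddof=1)
        const = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(X, rowvar=False)
        r[const, :] = np.nan
        r[:, const] = np.nan
        np.fill_diagonal(r, 1.0)
        n_eff = np.full((k, k), n, dtype=float)
    else:
        r = np.full((k, k), np.nan)
        n_eff = np.zeros((k, k))
        const = np.zeros(k, dtype=bool)
        for i in range(k):
            r[i, i] = 1.0
            n_eff[i, i] = np.sum(~np.isnan(X[:, i]))
            for j in range(i + 1, k):
                ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
                m = int(ok.sum())
                n_eff[i, j] = n_eff[j, i] = m
                if m < 3:
                    continue
                xi, xj = X[ok, i], X[ok, j]
                if xi.std() == 0 or xj.std() == 0:
                    const[i] |= xi.std() == 0
                    const[j] |= xj.std() == 0
                    continue
                r[i, j] = r[j, i] = stats.pearsonr(xi, xj).statistic
    if const.any():
        warnings.warn(
            f"constant trait(s) excluded from edges: "
            f"{[names[i] for i in np.where(const)[0]]}",
            stacklevel=2,
        )
    r = np.clip(r, -1.0, 1.0)
    p = _pearson_p(r, n_eff)
    np.fill_diagonal(p, 0.0)
    wrap = lambda m: pd.DataFrame(m, index=names, columns=names)
    return CorrelationResult(wrap(r), wrap(p), wrap(n_eff))


def build_network(corr: CorrelationResult, cfg: RunConfig | None = None,
                  site_id: str = "pooled") -> nx.Graph:
    """Threshold a correlation result into a trait network.

    Edge rule: |r| > ``cfg.r_threshold`` (strict) and p < ``cfg.alpha``
    (strict).  Isolated traits remain as nodes.  Negative correlations form
    edges exactly like positive ones; the sign is an edge attribute.
    """
    cfg = cfg or RunConfig()
    names = corr.trait_names
    r = corr.r.to_numpy()
    p = corr.p.to_numpy().copy()

    iu = np.triu_indices(len(names), k=1)
    if cfg.p_adjust == "bh":
        flat = p[iu]
        ok = ~np.isnan(flat)
        adj = flat.copy()
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p[iu] = adj
        p.T[iu] = adj

    g = nx.Graph(site_id=site_id, r_threshold=cfg.r_threshold, alpha=cfg.alpha)
    g.add_nodes_from(names)
    with np.errstate(invalid="ignore"):
        keep = (np.abs(r) > cfg.r_threshold) & (p < cfg.alpha)
    keep &= ~np.isnan(r) & ~np.isnan(p)
    for i, j in zip(*iu):
        if keep[i, j]:
            g.add_edge(names[i], names[j], r=float(r[i, j]),
                       weight=float(abs(r[i, j])),
                       sign="+" if r[i, j] > 0 else "-")
    return g


def build_site_networks(traits: TraitTable, cfg: RunConfig | None = None,
                        ) -> tuple[dict[str, nx.Graph], nx.Graph]:
    """One network per site (from that site's trees only) plus a pooled one.

    Sites with fewer than ``cfg.min_site_n`` observations are skipped with a
    warning — too few trees for a meaningful correlation.
    """
    cfg = cfg or RunConfig()
    nets: dict[str, nx.Graph] = {}
    for site in traits.sites:
        sub = traits.site_subset(site)
        if len(sub) < cfg.min_site_n:
            warnings.warn(f"site {site!r}: only {len(sub)} observations, skipped",
                          stacklevel=2)
            continue
        nets[site] = build_network(pairwise_pearson(sub), cfg, site_id=site)
    pooled = build_network(pairwise_pearson(traits.values), cfg, site_id="pooled")
    return nets, pooled
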