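"""Coefficient-of-variation summaries for traits and network parameters.

CV = 100 · sd / mean (percent), sample (n − 1) standard deviation by
default.  Three summaries are produced: per-trait CVs over all trees,
per-category aggregates, and per-parameter spread (max / min / mean / CV)
of the whole-network parameters across sites.

The category-level aggregate has no single canonical definition; two are
reported side by side: the mean of the member-trait CVs (default headline)
and the CV of the member-trait CVs (the between-trait spread).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import TraitTable


def cv(values, convention: str = "sample") -> float:
    """Coefficient of variation in percent: 100 · sd / mean.

    ``convention`` selects the sd denominator: ``sample`` (n − 1, default)
    or ``population`` (n).  Errors on n < 2 or zero mean.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError(f"CV needs at least 2 values, got {len(x)}")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    ddof = 1 if convention == "sample" else 0
    if convention not in ("sample", "population"):
        raise ValueError(f"unknown sd convention {convention!r}")
    return float(100.0 * x.std(ddof=ddof) / mean)


def trait_cvs(traits: TraitTable, convention: str = "sample") -> pd.DataFrame:
    """Per-trait summary over all observations: mean, sd, CV%, min, max, n."""
    rows = []
    for name in traits.trait_names:
        x = traits.values[name].dropna().to_numpy()
        if len(x) >= 2 and x.std() == 0:
            warnings.warn(f"trait {name!r} is constant: CV = 0", stacklevel=2)
        rows.append({
            "trait": name,
            "category": traits.categories[name],
            "mean": x.mean(),
            "sd": x.std(ddof=1 if convention == "sample" else 0),
            "cv_percent": cv(x, convention),
            "min": x.min(),
            "max": x.max(),
            "n": len(x),
        })
    return pd.DataFrame(rows).set_index("trait")


def category_cvs(per_trait: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trait CVs by functional category.

    ``cv_mean_of_traits`` — mean of member-trait CVs (headline);
    ``cv_of_trait_cvs`` — CV of the member-trait CVs (spread between traits;
    NaN for single-trait categories).
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        cvs = g["cv_percent"].to_numpy()
        return pd.Series({
            "n_traits": len(cvs),
            "cv_mean_of_traits": cvs.mean(),
            "cv_of_trait_cvs": cv(cvs) if len(cvs) >= 2 else np.nan,
            "cv_min": cvs.min(),
            "cv_max": cvs.max(),
        })
    return per_trait.groupby("category", sort=True).apply(_agg, include_groups=False)


def network_param_cvs(params: pd.DataFrame,
                      convention: str = "sample") -> pd.DataFrame:
    """Max / min / mean / CV of each whole-network parameter across sites.

    ``params`` is the site × parameter table from ``netmetrics.params_table``
    (a 'pooled' row, if present, is excluded from the spread).
    """
    params = params.drop(index="pooled", errors="ignore")
    if len(params) < 2:
        raise ValueError("need at least 2 sites for a spread summary")
    rows = []
    for col in params.columns:
        if col in ("N", "E", "n_components"):
            continue
        x = params[col].to_numpy(dtype=float)
        rows.append({
            "parameter": col, "max": x.max(), "min": x.min(), "mean": x.mean(),
            "cv_percent": cv(x, convention), "n_sites": len(x),
        })
    return pd.DataFrame(rows).set_index("parameter")
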