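"""Tables, run configuration, and file I/O for the trait-network pipeline.

The pipeline works on two kinds of tables:

* a *trait table*: one row per individual tree, one column per leaf trait,
  plus a ``site`` column (in the motivating study: 15 trees at each of 20
  sites along a river gradient, 27 traits in three functional categories);
* *environment tables*: one row per site, columns are either the 19
  WorldClim bioclimatic factors (BIO1–BIO19) or an 11-factor soil panel.

All files are plain delimited text with a header row.  Networks are written
as GraphML (lossless round-trip) or as a readable weighted edge list.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

TRAIT_CATEGORIES = ("morphological", "stoichiometric", "anatomical")

#: Trait panel of the motivating study: 8 morphological, 7 stoichiometric,
#: 12 anatomical leaf traits (abbreviations as used in the field).
DEFAULT_TRAIT_PANEL: dict[str, str] = {
    # morphological
    "LL": "morphological", "LW": "morphological", "LA": "morphological",
    "LDW": "morphological", "LWC": "morphological", "LDMC": "morphological",
    "SLA": "morphological", "LT": "morphological",
    # stoichiometric
    "LC": "stoichiometric", "LN": "stoichiometric", "LP": "stoichiometric",
    "LK": "stoichiometric", "LC_N": "stoichiometric", "LC_P": "stoichiometric",
    "LN_P": "stoichiometric",
    # anatomical
    "UE": "anatomical", "LE": "anatomical", "PT": "anatomical",
    "ST": "anatomical", "P_S": "anatomical", "SR": "anatomical",
    "CTR": "anatomical", "SC": "anatomical", "MVB": "anatomical",
    "LSC": "anatomical", "USC": "anatomical", "MC": "anatomical",
}

CLIMATE_FACTORS = tuple(f"BIO{i}" for i in range(1, 20))
SOIL_FACTORS = ("SWC", "TS", "SOM", "STN", "STP", "STK",
                "C_N", "C_P", "N_P", "EC", "pH")


class TableValidationError(ValueError):
    """A table violated an invariant (duplicate trait, missing site, ...)."""


@dataclass
class TraitTable:
    """Tree-level trait observations with site labels.

    Parameters
    ----------
    values : DataFrame, observations × traits (numeric; NaN = missing)
    site_ids : per-observation site label, aligned with ``values`` rows
    categories : trait name → functional category
    """

    values: pd.DataFrame
    site_ids: pd.Series
    categories: dict[str, str]

    def __post_init__(self) -> None:
        names = list(self.values.columns)
        dupes = [n for n in set(names) if names.count(n) > 1]
        if dupes:
            raise TableValidationError(f"duplicate trait name(s): {sorted(dupes)}")
        if len(self.site_ids) != len(self.values):
            raise TableValidationError(
                f"{len(self.values)} observations but {len(self.site_ids)} site labels"
            )
        if self.site_ids.isna().any():
            bad = list(self.values.index[self.site_ids.isna()])
            raise TableValidationError(f"observations without a site label: {bad}")
        all_missing = [c for c in names if self.values[c].isna().all()]
        if all_missing:
            raise TableValidationError(f"all-missing trait column(s): {all_missing}")
        for trait in names:
            cat = self.categories.get(trait)
            if cat is None:
                raise TableValidationError(f"trait {trait!r} has no category assignment")
            if cat not in TRAIT_CATEGORIES:
                raise TableValidationError(
                    f"trait {trait!r}: unknown category {cat!r} "
                    f"(expected one of {TRAIT_CATEGORIES})"
                )
        self.site_ids = self.site_ids.astype(str).reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_observations(self) -> int:
        return len(self.values)

    @property
    def sites(self) -> list[str]:
        """Unique site labels in first-appearance order."""
        return list(dict.fromkeys(self.site_ids))

    def site_subset(self, site: str) -> pd.DataFrame:
        return self.values.loc[(self.site_ids == site).to_numpy()]

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "site", self.site_ids.to_numpy())
        return out


@dataclass
class EnvTable:
    """Site-level environmental factors (one row per site)."""

    values: pd.DataFrame  # sites × factors, index = site labels
    block: Literal["climate", "soil"]

    def __post_init__(self) -> None:
        if self.block not in ("climate", "soil"):
            raise TableValidationError(f"unknown block {self.block!r}")
        idx = list(self.values.index.astype(str))
        dupes = [s for s in set(idx) if idx.count(s) > 1]
        if dupes:
            raise TableValidationError(f"duplicate site row(s): {sorted(dupes)}")
        if self.values.isna().any().any():
            cells = [(str(i), c) for i, c in
                     zip(*np.where(self.values.isna().to_numpy()))]
            raise TableValidationError(f"missing cells in env table: {cells[:5]}")
        self.values.index = self.values.index.astype(str)

    @property
    def factor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    def aligned_to(self, sites: Iterable[str]) -> "EnvTable":
        """Reindex rows to ``sites``; raise if any site is missing."""
        sites = list(sites)
        missing = [s for s in sites if s not in self.values.index]
        if missing:
            raise TableValidationError(
                f"{self.block} table is missing site(s) present in traits: {missing}"
            )
        return EnvTable(self.values.loc[sites].copy(), self.block)


@dataclass
class RunConfig:
    """Analysis settings; defaults reproduce the study's stated procedure."""

    r_threshold: float = 0.2       # |r| must strictly exceed this
    alpha: float = 0.05            # two-sided p must be strictly below this
    n_permutations: int = 999
    rng_seed: int = 0
    cv_convention: Literal["sample", "population"] = "sample"
    #: shortest-path statistics over all reachable pairs, or restricted to
    #: the largest connected component
    path_scope: Literal["reachable", "largest_component"] = "reachable"
    #: optional Benjamini–Hochberg correction of the pairwise p-values
    #: before thresholding (the study applied none)
    p_adjust: Literal["none", "bh"] = "none"
    min_site_n: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.r_threshold < 1:
            raise ValueError(f"r_threshold must be in [0, 1): {self.r_threshold}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1): {self.alpha}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers


def read_trait_table(path: str | Path,
                     category_map: Mapping[str, str] | None = None,
                     sep: str = ",") -> TraitTable:
    """Read a trait CSV (``site`` column + one numeric column per trait).

    Rows with missing trait values are retained (correlations are computed
    pairwise-complete downstream); each such row is reported in the returned
    table's values as NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if "site" not in df.columns:
        raise TableValidationError(f"{path.name}: no 'site' column in header")
    site_ids = df["site"].astype(str)
    values = df.drop(columns=["site"])
    for col in values.columns:
        try:
            values[col] = pd.to_numeric(values[col])
        except (ValueError, TypeError) as exc:
            bad = values[pd.to_numeric(values[col], errors="coerce").isna()
                         & values[col].notna()]
            row = int(bad.index[0]) if len(bad) else "?"
            raise TableValidationError(
                f"{path.name}: non-numeric value in column {col!r}, row {row}"
            ) from exc
    if category_map is None:
        category_map = DEFAULT_TRAIT_PANEL
    unknown = [t for t in values.columns if t not in category_map]
    if unknown:
        raise TableValidationError(
            f"{path.name}: trait(s) not in category map: {unknown}"
        )
    cats = {t: category_map[t] for t in values.columns}
    return TraitTable(values, site_ids, cats)


def read_env_table(path: str | Path, block: Literal["climate", "soil"],
                   sep: str = ",") -> EnvTable:
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if "site" not in df.columns:
        raise TableValidationError(f"{path.name}: no 'site' column in header")
    df = df.set_index(df["site"].astype(str)).drop(columns=["site"])
    df.index.name = "site"
    return EnvTable(df.astype(float), block)


# ---------------------------------------------------------------------------
# network writers / readers


def write_network(net: nx.Graph, path: str | Path,
                  format: Literal["graphml", "edgelist"] = "graphml") -> None:
    """Write a trait network; edges carry signed ``r``, ``weight`` = |r| and
    ``sign``; nodes carry ``module`` membership when present."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("u\tv\tr\tsign\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['r']:.10g}\t{d['sign']}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(Path(path))
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
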