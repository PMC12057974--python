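"""Coefficient-of-variation analysis of traits and network parameters.

Computes per-trait CVs over all trees, aggregates them by functional
category (morphological / stoichiometric / anatomical), and summarises the
spread (max, min, mean, CV) of each whole-network parameter across the 20
sites — the study's measures of spatial variability.

Run after 02:  python analysis/03_trait_variability.py
"""

from pathlib import Path

import pandas as pd

from traitnet import category_cvs, network_param_cvs, read_trait_table, trait_cvs


def main(indir: Path = Path("results/study"), outdir: Path = Path("results")) -> None:
    traits = read_trait_table(indir / "traits.csv")
    per_trait = trait_cvs(traits)
    per_cat = category_cvs(per_trait)
    params = pd.read_csv(outdir / "network_params.csv", index_col="site")
    per_param = network_param_cvs(params)

    per_trait.to_csv(outdir / "trait_cvs.csv")
    per_cat.to_csv(outdir / "category_cvs.csv")
    per_param.to_csv(outdir / "param_cvs.csv")

    print("per-category CV aggregates (% — mean of member-trait CVs):")
    print(per_cat["cv_mean_of_traits"].round(2).to_string())
    ordered = per_param["cv_percent"].sort_values(ascending=False)
    print("\nnetwork-parameter variability across sites (CV %):")
    print(ordered.round(2).to_string())
    print(f"\nmost variable parameter: {ordered.index[0]}; "
          f"least variable: {ordered.index[-1]}")


if __name__ == "__main__":
    main()
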