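"""PCA of climate and soil, representative factors, and network correlations.

Runs correlation-matrix PCA on each environment table, picks one
representative factor per leading component (largest |loading|), correlates
every whole-network parameter with the representatives, and clusters the
sites on the standardised climate + soil profile (Ward / Euclidean, k = 2).

Run after 02:  python analysis/04_environment_association.py
"""

from pathlib import Path

import pandas as pd

from traitnet import (RunConfig, associate, cluster_sites, pca, read_env_table,
                      select_representatives)


def main(indir: Path = Path("results/study"), outdir: Path = Path("results")) -> None:
    climate = read_env_table(indir / "climate.csv", "climate")
    soil = read_env_table(indir / "soil.csv", "soil")
    params = pd.read_csv(outdir / "network_params.csv", index_col="site")
    params = params.drop(index="pooled")

    cfg = RunConfig()
    results = {}
    for env, n_comp in ((climate, 3), (soil, 3)):
        res = pca(env)
        reps = select_representatives(res, n_comp)
        res.explained_proportion.to_csv(outdir / f"pca_{env.block}_explained.csv")
        res.loadings.to_csv(outdir / f"pca_{env.block}_loadings.csv")
        results[env.block] = (res, reps)
        top = 100 * res.explained_proportion.iloc[:n_comp]
        print(f"{env.block}: first {n_comp} PCs explain {top.sum():.1f}% "
              f"({', '.join(f'{v:.1f}' for v in top)}); representatives: {reps}")

    assoc = pd.concat(
        [associate(params, env, results[env.block][1], cfg).assign(block=env.block)
         for env in (climate, soil)], ignore_index=True)
    assoc.to_csv(outdir / "associations.csv", index=False)
    sig = assoc[assoc["significant"]]
    print(f"\n{len(sig)}/{len(assoc)} parameter–factor correlations significant "
          f"at p < {cfg.alpha}:")
    if len(sig):
        print(sig[["parameter", "factor", "r", "p", "block"]]
              .round(3).to_string(index=False))

    clusters = cluster_sites(climate, soil, k=2)
    clusters.labels.to_csv(outdir / "clusters.csv")
    counts = clusters.labels.value_counts().sort_index()
    print(f"\nWard clustering splits the sites {counts.iloc[0]} / {counts.iloc[1]}")


if __name__ == "__main__":
    main()
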