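"""Community structure of the simulated cohort: accumulation curves, alpha
diversity per group, Bray-Curtis PCoA, and marginal PERMANOVA of the group
label and covariates (1000 permutations).

Reads results/profile/ + results/data/metadata.tsv, writes results/ecology/.
"""

import argparse
from pathlib import Path

import pandas as pd

from virome import ecology, profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profile", type=Path, default=Path("results/profile"))
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/ecology"))
    ap.add_argument("--perms", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ab = profile.read_feature_table(args.profile / "abundance_votu.tsv")
    meta = pd.read_csv(args.data / "metadata.tsv", sep="\t",
                       index_col=0).loc[ab.index]

    div = ecology.alpha_diversity(ab)
    div.to_csv(args.out / "diversity.tsv", sep="\t")
    by_group = div.join(meta["group"]).groupby("group").mean()
    print("alpha diversity (group means):")
    print(by_group.round(3).to_string())

    curve = ecology.accumulation_curve(ab, meta["group"], seed=args.seed)
    curve.to_csv(args.out / "accumulation.tsv", sep="\t", index=False)

    dist = ecology.bray_curtis(ab)
    dist.to_csv(args.out / "distance.tsv", sep="\t")
    ords = ecology.pcoa(dist, n_axes=10)
    ords.coordinates.to_csv(args.out / "pcoa.tsv", sep="\t")
    print(f"PCoA axis 1+2 variance: "
          f"{100 * ords.variance_ratio[:2].sum():.1f}%")

    perm = ecology.permanova_table(dist, meta, n_permutations=args.perms,
                                   seed=args.seed)
    perm.to_csv(args.out / "permanova.tsv", sep="\t", index=False)
    print("PERMANOVA (marginal, per factor):")
    print(perm.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
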