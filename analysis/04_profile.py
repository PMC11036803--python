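"""Depth-normalize the mapped-read counts (random subsampling without
replacement to a common depth) and compute relative abundances at the vOTU
and family level.

Reads results/data/ + results/catalog/ + results/annotate/, writes
results/profile/.
"""

import argparse
from pathlib import Path

import pandas as pd

from virome import profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--catalog", type=Path, default=Path("results/catalog"))
    ap.add_argument("--annotate", type=Path,
                    default=Path("results/annotate"))
    ap.add_argument("--out", type=Path, default=Path("results/profile"))
    ap.add_argument("--depth", type=int, default=None,
                    help="target depth (default: half the minimum total)")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    counts = profile.read_feature_table(args.data / "counts.tsv")
    clusters = pd.read_csv(args.catalog / "clusters.tsv", sep="\t")
    votu_of_contig = {m: r.votu_id for r in clusters.itertuples()
                      for m in r.members.split(",")}
    counts.columns = [votu_of_contig.get(c, c) for c in counts.columns]

    target = args.depth or int(counts.sum(axis=1).min()) // 2
    sub = profile.subsample(counts, target, seed=args.seed)
    ab = profile.relative_abundance(sub)
    tax = pd.read_csv(args.annotate / "taxonomy.tsv", sep="\t")
    fam = profile.family_rollup(ab, dict(zip(tax["votu_id"],
                                             tax["family"])))

    profile.write_feature_table(sub, args.out / "counts_subsampled.tsv")
    profile.write_feature_table(ab, args.out / "abundance_votu.tsv")
    profile.write_feature_table(fam, args.out / "abundance_family.tsv")

    print(f"subsampled {ab.shape[0]} samples to depth {target}")
    print(f"vOTU table: {ab.shape[1]} features; family table: "
          f"{fam.shape[1]} (incl. unclassified)")
    top = fam.mean().sort_values(ascending=False).head(5)
    print("top mean family abundances:",
          {k: round(v, 3) for k, v in top.items()})


if __name__ == "__main__":
    main()
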