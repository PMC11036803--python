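"""Build group-specific virus-bacterium Spearman networks (|rho| > 0.6)
over the vOTU profiles, compare the two networks (shared vs group-specific
edges), rank hub nodes in the shared network, and score planted-pair
recovery.

Reads results/profile/ + results/data/, writes results/networks/.
"""

import argparse
from pathlib import Path

import pandas as pd

from virome import netassoc, profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profile", type=Path, default=Path("results/profile"))
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--catalog", type=Path, default=Path("results/catalog"))
    ap.add_argument("--out", type=Path, default=Path("results/networks"))
    ap.add_argument("--rho", type=float, default=0.6)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ab = profile.read_feature_table(args.profile / "abundance_votu.tsv")
    bact = profile.read_feature_table(
        args.data / "bacteria_abundance.tsv").loc[ab.index]
    meta = pd.read_csv(args.data / "metadata.tsv", sep="\t",
                       index_col=0).loc[ab.index]
    feats = ab

    ea = netassoc.spearman_edges(feats, bact, meta["group"] == "case",
                                 "case", threshold=args.rho)
    eb = netassoc.spearman_edges(feats, bact, meta["group"] == "control",
                                 "control", threshold=args.rho)
    rep = netassoc.share_networks(ea, eb)

    ea.edges.to_csv(args.out / "edges_case.tsv", sep="\t", index=False)
    eb.edges.to_csv(args.out / "edges_control.tsv", sep="\t", index=False)
    print(f"case network: {len(ea.edges)} edges; control network: "
          f"{len(eb.edges)} edges")
    if len(eb.edges):
        print(f"{len(rep.shared)} of {len(eb.edges)} control edges "
              f"({100 * rep.fraction_of_b_shared:.1f}%) also present in "
              "the case network")
    if rep.shared:
        dv, db = netassoc.degree_ranking(rep.shared, top_k=20)
        dv.to_csv(args.out / "degree_virus.tsv", sep="\t", index=False)
        db.to_csv(args.out / "degree_bacterium.tsv", sep="\t", index=False)
        print("top shared-network hubs:",
              list(dv.head(3)["node"]), "/", list(db.head(3)["node"]))

    truth = pd.read_csv(args.data / "truth" / "edges.tsv", sep="\t")
    clusters = pd.read_csv(args.catalog / "clusters.tsv", sep="\t")
    rep_votu = dict(zip(clusters["representative"], clusters["votu_id"]))
    planted = {(rep_votu.get(r.virus_id, r.virus_id), r.bacterium_id)
               for r in truth.itertuples()}
    hit = len(planted & ea.pairs & eb.pairs)
    print(f"planted correlated pairs present in both networks: "
          f"{hit}/{len(planted)}")


if __name__ == "__main__":
    main()
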