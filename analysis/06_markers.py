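"""Call differentially abundant vOTUs between the two groups (Mann-Whitney
U + Benjamini-Hochberg at q < 0.05, fold change > 1.2) and score the calls
against the planted truth.

Reads results/profile/ + results/data/, writes results/markers/markers.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from virome import markers, profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profile", type=Path, default=Path("results/profile"))
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--catalog", type=Path, default=Path("results/catalog"))
    ap.add_argument("--out", type=Path, default=Path("results/markers"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ab = profile.read_feature_table(args.profile / "abundance_votu.tsv")
    meta = pd.read_csv(args.data / "metadata.tsv", sep="\t",
                       index_col=0).loc[ab.index]
    table = markers.call_markers(ab, meta["group"])
    table.to_csv(args.out / "markers.tsv", sep="\t", index=False)

    hits = table[table["enriched_in"] != ""]
    print(f"{len(hits)} markers of {len(table)} tested vOTUs "
          f"({(hits['enriched_in'] == 'case').sum()} case-enriched, "
          f"{(hits['enriched_in'] == 'control').sum()} control-enriched)")

    truth = pd.read_csv(args.data / "truth" / "markers.tsv", sep="\t")
    clusters = pd.read_csv(args.catalog / "clusters.tsv", sep="\t")
    rep_votu = dict(zip(clusters["representative"], clusters["votu_id"]))
    planted = {rep_votu.get(f, f) for f in truth["feature_id"]}
    called = set(hits["feature_id"])
    print(f"recall {len(called & planted) / len(planted):.2f}, "
          f"precision {len(called & planted) / max(1, len(called)):.2f} "
          "vs planted truth")


if __name__ == "__main__":
    main()
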