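"""Annotate the vOTU catalog: family taxonomy by the quarter-vote over
protein best hits, host prediction by CRISPR-spacer matching and prophage
alignment, and per-protein KO assignment.

Reads results/data/ + results/catalog/, writes results/annotate/ and
scores host-link recovery against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from virome import annotate
from virome.sequtils import read_fasta


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--catalog", type=Path, default=Path("results/catalog"))
    ap.add_argument("--out", type=Path, default=Path("results/annotate"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    clusters = pd.read_csv(args.catalog / "clusters.tsv", sep="\t")
    votu_of_contig = {m: r.votu_id for r in clusters.itertuples()
                      for m in r.members.split(",")}
    votu_seqs = read_fasta(args.catalog / "representatives.fasta")
    hits = pd.read_csv(args.data / "protein_hits.tsv", sep="\t")
    spacers = pd.read_csv(args.data / "spacers.tsv", sep="\t")
    hosts = read_fasta(args.data / "hosts.fasta")

    fams = annotate.assign_families(hits, votu_of_contig)
    links = annotate.predict_hosts(spacers, hosts, votu_seqs)
    kos = annotate.assign_ko(hits)

    pd.DataFrame(sorted(fams.items()),
                 columns=["votu_id", "family"]).to_csv(
        args.out / "taxonomy.tsv", sep="\t", index=False)
    annotate.links_to_frame(links).to_csv(
        args.out / "host_links.tsv", sep="\t", index=False)
    kos.to_csv(args.out / "ko.tsv", sep="\t", index=False)

    classified = sum(1 for f in fams.values() if f != "unclassified")
    print(f"taxonomy: {classified}/{len(fams)} vOTUs classified to family")
    n_crispr = sum(1 for l in links if l.mechanism == "crispr")
    print(f"host links: {n_crispr} CRISPR + {len(links) - n_crispr} "
          "prophage")

    truth = pd.read_csv(args.data / "truth" / "host_links.tsv", sep="\t")
    rep_votu = dict(zip(clusters["representative"], clusters["votu_id"]))
    expected = {(rep_votu[r.virus_id], r.host_id, r.mechanism)
                for r in truth.itertuples()}
    found = {(l.votu_id, l.host_id, l.mechanism) for l in links}
    recall = len(found & expected) / len(expected) if expected else 1.0
    prec = len(found & expected) / len(found) if found else 1.0
    print(f"planted-link recall {recall:.2f}, precision {prec:.2f}")


if __name__ == "__main__":
    main()
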