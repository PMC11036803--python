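"""Evaluate how well the marker vOTUs separate the two groups: random
forest under 5x5-fold stratified cross-validation (AUC with a rank-based
95% CI), permutation importance, and the importance-ordered panel sweep
for a minimal signature.

Reads results/profile/ + results/markers/ + results/data/, writes
results/classify/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from virome import classify, profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profile", type=Path, default=Path("results/profile"))
    ap.add_argument("--markers", type=Path, default=Path("results/markers"))
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/classify"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ab = profile.read_feature_table(args.profile / "abundance_votu.tsv")
    meta = pd.read_csv(args.data / "metadata.tsv", sep="\t",
                       index_col=0).loc[ab.index]
    mk = pd.read_csv(args.markers / "markers.tsv", sep="\t",
                     keep_default_na=False)
    marker_ids = list(mk.loc[mk["enriched_in"] != "", "feature_id"])
    feats = ab[marker_ids] if len(marker_ids) >= 2 else ab

    report = classify.cv_auc(feats, meta["group"], seed=args.seed)
    print(f"marker-panel model ({feats.shape[1]} vOTUs): "
          f"AUC {report.auc:.3f} "
          f"(95% CI {report.ci_low:.3f}-{report.ci_high:.3f}), "
          f"{report.scheme}")

    order = classify.importance_ranking(report)
    report.importance.loc[order].rename_axis("feature_id").reset_index(
        ).to_csv(args.out / "importance.tsv", sep="\t", index=False)
    print("most important vOTUs:", order[:5])

    grid = [k for k in range(5, min(50, len(order)) + 1, 5)] or [len(order)]
    sweep = classify.panel_sweep(feats, meta["group"], order, k_grid=grid,
                                 seed=args.seed)
    sweep.table.to_csv(args.out / "sweep.tsv", sep="\t", index=False)
    print(f"panel sweep: best mean AUC {sweep.best_auc:.3f} at "
          f"k={sweep.best_k} features")

    (args.out / "report.json").write_text(json.dumps({
        "auc": report.auc, "ci_low": report.ci_low,
        "ci_high": report.ci_high, "scheme": report.scheme,
        "n_features": int(feats.shape[1]),
        "best_panel_k": sweep.best_k,
        "best_panel_auc": sweep.best_auc},
        indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
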