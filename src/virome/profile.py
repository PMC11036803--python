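"""Abundance profiling: depth normalization by random subsampling of mapped
reads, relative abundance at the vOTU level, and family-level rollup.

Subsampling draws, per sample, a fixed number of reads without replacement
from the realized read pool (multivariate hypergeometric across features),
mirroring rarefying every sample to the same sequencing amount before
computing relative abundances.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV (first column = feature id) into a
    samples x features DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.T.to_csv(path, sep="\t", index_label="feature_id")


def subsample(
    counts: pd.DataFrame, target_depth: int, seed: int
) -> pd.DataFrame:
    """Rarefy every sample (row) to exactly ``target_depth`` reads.

    Reads are drawn without replacement from the sample's realized pool,
    i.e. a multivariate hypergeometric draw across features.  Fails naming
    the first sample whose total is below ``target_depth``.
    """
    totals = counts.sum(axis=1)
    short = totals[totals < target_depth]
    if not short.empty:
        raise ValueError(
            f"sample {short.index[0]!r} has {int(short.iloc[0])} reads, "
            f"below the target depth {target_depth}")
    rng = np.random.default_rng(seed)
    out = np.empty(counts.shape, dtype=np.int64)
    values = counts.to_numpy().astype(np.int64)
    for i in range(values.shape[0]):
        if totals.iloc[i] == target_depth:
            out[i] = values[i]
        else:
            out[i] = rng.multivariate_hypergeometric(
                values[i], target_depth, method="marginals")
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to fractions; every row must have reads."""
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(
            f"sample {zero.index[0]!r} has zero total reads")
    return counts.div(totals, axis=0)


def family_rollup(
    abundances: pd.DataFrame,
    taxonomy: dict[str, str],
    unclassified_label: str = "unclassified",
) -> pd.DataFrame:
    """Sum vOTU relative abundances per assigned family.

    vOTUs missing from ``taxonomy`` or labelled unclassified are pooled
    into the ``unclassified_label`` column, so family-level rows conserve
    the full mass of the vOTU-level rows.
    """
    fams = pd.Series(
        [taxonomy.get(c, unclassified_label) or unclassified_label
         for c in abundances.columns],
        index=abundances.columns)
    rolled = abundances.T.groupby(fams.values).sum().T
    ordered = sorted(c for c in rolled.columns if c != unclassified_label)
    if unclassified_label in rolled.columns:
        ordered.append(unclassified_label)
    return rolled[ordered]
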