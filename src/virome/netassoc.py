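"""Group-specific virus-bacterium correlation networks.

Within each sample group, every virus-bacterium feature pair is scored by
Spearman's rank correlation (average ranks on ties); pairs with |rho| above
a threshold (default 0.6) become network edges carrying the coefficient and
its sign.  Networks from two groups are compared by set intersection on
unordered (virus, bacterium) pairs — shared versus group-specific edges —
and nodes are ranked by their degree in the shared network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

RHO_THRESHOLD = 0.6


@dataclass
class EdgeList:
    group: str
    threshold: float
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: virus_id, bacterium_id, rho, sign

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["virus_id"], self.edges["bacterium_id"]))


def _rank_columns(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 0, x)


def spearman_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho for every column pair of x (n x p) vs y (n x q)."""
    rx = _rank_columns(x)
    ry = _rank_columns(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx ** 2).sum(axis=0))
    sy = np.sqrt((ry ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / np.outer(sx, sy)
    return rho


def spearman_edges(
    virus: pd.DataFrame,
    bacteria: pd.DataFrame,
    group_mask: pd.Series,
    group_label: str,
    threshold: float = RHO_THRESHOLD,
) -> EdgeList:
    """Edges with |rho| > ``threshold`` among the group's samples only.

    ``virus`` / ``bacteria`` are samples x features; constant features
    within the group are skipped (their rank correlation is undefined).
    Requires at least 5 samples in the group.
    """
    idx = group_mask[group_mask].index
    if len(idx) < 5:
        raise ValueError(f"group {group_label!r} has fewer than 5 samples")
    xv = virus.loc[idx].to_numpy(dtype=float)
    xb = bacteria.loc[idx].to_numpy(dtype=float)
    keep_v = np.ptp(xv, axis=0) > 0
    keep_b = np.ptp(xb, axis=0) > 0
    dropped = (~keep_v).sum() + (~keep_b).sum()
    if dropped:
        log.info("group %s: skipped %d constant features", group_label,
                 int(dropped))
    rho = spearman_matrix(xv[:, keep_v], xb[:, keep_b])
    vi, bi = np.nonzero(np.abs(rho) > threshold)
    vids = virus.columns[keep_v]
    bids = bacteria.columns[keep_b]
    edges = pd.DataFrame({
        "virus_id": vids[vi],
        "bacterium_id": bids[bi],
        "rho": rho[vi, bi],
        "sign": np.where(rho[vi, bi] >= 0, 1, -1),
    }).sort_values(["virus_id", "bacterium_id"],
                   kind="stable").reset_index(drop=True)
    return EdgeList(group=group_label, threshold=threshold, edges=edges)


@dataclass
class SharingReport:
    shared: set[tuple[str, str]]
    only_a: set[tuple[str, str]]
    only_b: set[tuple[str, str]]
    shared_degrees_virus: pd.Series
    shared_degrees_bacterium: pd.Series

    @property
    def fraction_of_b_shared(self) -> float:
        denom = len(self.shared) + len(self.only_b)
        return len(self.shared) / denom if denom else float("nan")


def share_networks(edges_a: EdgeList, edges_b: EdgeList) -> SharingReport:
    """Intersection of two networks on unordered (virus, bacterium) pairs,
    ignoring rho; degrees are computed on the shared set."""
    pa, pb = edges_a.pairs, edges_b.pairs
    shared = pa & pb
    dv = pd.Series([v for v, _ in shared], dtype=str).value_counts()
    db = pd.Series([b for _, b in shared], dtype=str).value_counts()
    return SharingReport(
        shared=shared, only_a=pa - shared, only_b=pb - shared,
        shared_degrees_virus=dv, shared_degrees_bacterium=db)


def degree_ranking(
    edge_pairs: set[tuple[str, str]], top_k: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Virus and bacterium nodes ranked by degree (descending, ties by id),
    truncated to ``top_k``."""
    if not edge_pairs:
        raise ValueError("empty edge set")

    def rank(nodes: list[str]) -> pd.DataFrame:
        counts = pd.Series(nodes, dtype=str).value_counts()
        df = counts.rename("degree").rename_axis("node").reset_index()
        df = df.sort_values(["degree", "node"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
        return df.head(top_k)

    return (rank([v for v, _ in edge_pairs]),
            rank([b for _, b in edge_pairs]))
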