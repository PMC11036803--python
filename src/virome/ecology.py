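"""Community ecology layer: species-accumulation curves, alpha diversity
(observed richness, Shannon, Simpson), Bray-Curtis dissimilarity, principal
coordinate analysis, and permutational multivariate analysis of variance
(PERMANOVA) with adjusted-R2 effect sizes.

PERMANOVA follows the pseudo-F construction on a Gower-centered squared
distance matrix: for a model hat matrix H built from the factor's design
matrix, F = [tr(HGH)/m] / [tr((I-H)G(I-H))/(n-m-1)].  The permutation
p-value includes the observed statistic (p >= 1/(n_permutations+1)), and
the per-factor effect size is reported both as R2 = SS_model/SS_total and
as adjusted R2 = 1 - (1-R2)(n-1)/(n-m-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# accumulation curves
# ---------------------------------------------------------------------------

def accumulation_curve(
    abundances: pd.DataFrame,
    groups: pd.Series,
    n_reps: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-wise vOTU accumulation: for k = 1..group size, the mean and sd
    over ``n_reps`` random (without-replacement) k-subsets of the union
    richness (features present in at least one of the k samples)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in sorted(groups.unique()):
        sub = abundances.loc[groups[groups == g].index]
        present = (sub.to_numpy() > 0)
        n = present.shape[0]
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        for k in range(1, n + 1):
            rich = np.empty(n_reps)
            for r in range(n_reps):
                idx = rng.choice(n, size=k, replace=False)
                rich[r] = present[idx].any(axis=0).sum()
            rows.append({"group": g, "k": k,
                         "mean_richness": rich.mean(),
                         "sd_richness": rich.std(ddof=0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(abundances: pd.DataFrame) -> pd.DataFrame:
    """Observed richness, Shannon (natural log) and Simpson (1 - sum p^2)
    per sample; rows must be relative abundances."""
    x = abundances.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    observed = (x > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(x > 0, x * np.log(x), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (x ** 2).sum(axis=1)
    return pd.DataFrame({
        "observed_votus": observed,
        "shannon": shannon,
        "simpson": simpson,
    }, index=abundances.index)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    d = squareform(pdist(abundances.to_numpy(dtype=float), "braycurtis"))
    return pd.DataFrame(d, index=abundances.index,
                        columns=abundances.index)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # samples x positive axes
    eigenvalues: np.ndarray         # positive eigenvalues, descending
    variance_ratio: np.ndarray      # eigenvalue / sum of positive eigs


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(distances: pd.DataFrame, n_axes: int | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers the squared distances and eigendecomposes; coordinates
    are returned for positive-eigenvalue axes only, with variance ratios
    over the positive part of the spectrum (negative eigenvalues from
    semi-metric distances are dropped, no correction applied).
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if eigvals.size else 0.0
    pos = eigvals > tol
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    if n_axes is not None:
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    coords = eigvecs * np.sqrt(eigvals)[None, :]
    total = eigvals.sum()
    ratio = eigvals / total if total > 0 else eigvals
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=distances.index,
                                 columns=cols),
        eigenvalues=eigvals,
        variance_ratio=ratio)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    f_stat: float
    r2: float
    adjusted_r2: float
    p: float
    n_permutations: int
    df_model: int


def _design_hat(factor: pd.Series) -> tuple[np.ndarray, int]:
    """Hat matrix of [1 | X] for a categorical or continuous factor,
    and the model degrees of freedom m (columns of X)."""
    if factor.isna().any():
        raise ValueError("factor contains missing values")
    if (pd.api.types.is_numeric_dtype(factor)
            and factor.nunique() > max(8, len(factor) // 4)):
        x = np.column_stack([np.ones(len(factor)),
                             factor.to_numpy(dtype=float)])
        m = 1
    else:
        levels = pd.unique(factor)
        if len(levels) < 2:
            raise ValueError(f"factor {factor.name!r} is constant")
        dummies = pd.get_dummies(factor.astype(str), drop_first=True)
        x = np.column_stack([np.ones(len(factor)),
                             dummies.to_numpy(dtype=float)])
        m = dummies.shape[1]
    # hat matrix via pseudo-inverse (robust to balanced designs)
    h = x @ np.linalg.pinv(x)
    return h, m


def permanova(
    distances: pd.DataFrame,
    factor: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA (marginal model per factor).

    ``factor`` is aligned to the distance matrix index.  The permutation
    p-value uses the +1/+1 convention, counting the observed statistic.
    """
    factor = factor.loc[distances.index]
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    g = _gower_center(d)
    h, m = _design_hat(factor)
    if n - m - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")

    ss_total = np.trace(g)
    i_h = np.eye(n) - h

    def stats(gm: np.ndarray) -> tuple[float, float]:
        ss_model = float(np.sum(h * gm))        # tr(H G H) = sum(H * G)
        ss_resid = float(np.sum(i_h * gm))
        f = (ss_model / m) / (ss_resid / (n - m - 1))
        return f, ss_model

    f_obs, ss_model = stats(g)
    r2 = ss_model / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)

    rng = np.random.default_rng(seed)
    exceed = 0
    # permutations reproducing the observed grouping tie F_obs exactly in
    # theory; the tolerance keeps them counted despite roundoff
    tie_tol = 1e-10 * max(1.0, abs(f_obs))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        f_p, _ = stats(gp)
        if f_p >= f_obs - tie_tol:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermanovaResult(
        factor=str(factor.name), f_stat=f_obs, r2=r2,
        adjusted_r2=adj_r2, p=p, n_permutations=n_permutations,
        df_model=m)


def permanova_table(
    distances: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: list[str] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal PERMANOVA per metadata column (one model per factor)."""
    if factors is None:
        factors = list(metadata.columns)
    rows = []
    for i, f in enumerate(factors):
        res = permanova(distances, metadata[f], n_permutations,
                        seed=seed + i)
        rows.append({"factor": f, "f_stat": res.f_stat, "r2": res.r2,
                     "adjusted_r2": res.adjusted_r2, "p": res.p,
                     "n_permutations": res.n_permutations})
    return pd.DataFrame(rows)
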