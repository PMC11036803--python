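"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: alignment identity
comes from Biopython's dynamic-programming aligner, PERMANOVA p-values from
exhaustive label enumeration, and BH q-values from a direct transcription
of the step-up rule.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio import Align


def dp_identity(a: str, b: str) -> float:
    """Global-alignment identity (matches / alignment columns) from a full
    dynamic-programming alignment."""
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-3, extend_gap_score=-1)
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def permanova_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F for a categorical grouping computed from the classic
    within/between sum-of-squares decomposition of squared distances."""
    n = d.shape[0]
    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_p_enumerated(d: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p by enumerating every assignment of the observed
    label multiset to samples (feasible for tiny n)."""
    f_obs = permanova_f(d, labels)
    n = len(labels)
    count = 0
    total = 0
    for perm in set(itertools.permutations(labels)):
        total += 1
        if permanova_f(d, np.array(perm)) >= f_obs - 1e-12:
            count += 1
    return count / total


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up written directly from its definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate_exact(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions."""
    arr = list(seq)
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for i in pos:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)
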