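"""Gut-community comparison from sequencing reads.

Samples are profiled as canonical k-mer frequency vectors (k = 21 by
default; a k-mer and its reverse complement are one key), compared by
cosine distance (euclidean and Bray-Curtis selectable), ordinated by
principal coordinates analysis, and tested for group structure by
PERMANOVA.  Samples whose pathogen taxa exceed half of the community are
flagged unhealthy and excluded before profiling.  Per-taxon abundance
differences between groups use the two-sided Wilcoxon rank-sum test with
an exact enumeration branch for small samples.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .codons import revcomp
from .containers import DistanceMatrix, OrdinationResult

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ sampling

def subsample_reads(reads, n: int, seed: int = 100):
    """Uniform subsample of ``n`` reads without replacement, order-stable.

    If ``n`` is at least the number of reads, all reads are returned (with
    a warning when strictly more were requested).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    reads = list(reads)
    if n >= len(reads):
        if n > len(reads):
            log.warning("requested %d reads but only %d available", n, len(reads))
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in keep]


# ----------------------------------------------------------------- abundance

@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances with per-sample health flags."""

    abundances: pd.DataFrame
    unhealthy: pd.Series | None = None

    def __post_init__(self):
        rows = self.abundances.sum(axis=1)
        if len(rows) and not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("abundance rows must sum to 1")
        if self.unhealthy is None:
            self.unhealthy = pd.Series(False, index=self.abundances.index)

    @property
    def healthy_samples(self) -> list:
        return list(self.abundances.index[~self.unhealthy])


def flag_unhealthy(
    table: AbundanceTable, pathogen_taxa, threshold: float = 0.5
) -> AbundanceTable:
    """Flag samples whose summed pathogen abundance strictly exceeds the
    threshold; flagged samples are meant to be dropped from all downstream
    distance and ordination steps."""
    present = [t for t in pathogen_taxa if t in table.abundances.columns]
    missing = set(pathogen_taxa) - set(present)
    if missing:
        log.warning("pathogen taxa absent from table: %s", sorted(missing))
    mass = (
        table.abundances[present].sum(axis=1)
        if present
        else pd.Series(0.0, index=table.abundances.index)
    )
    return AbundanceTable(table.abundances.copy(), mass > threshold)


def rank_sum_abundance(
    table: AbundanceTable, groups: dict, taxon: str, exact_max_n: int = 20
):
    """Two-sided Wilcoxon rank-sum test on one taxon's abundances.

    ``groups`` maps sample id to one of exactly two group labels.  With
    combined n <= ``exact_max_n`` the null distribution of the rank-sum
    statistic is enumerated exactly over all group assignments (midranks
    for ties); larger samples use the normal approximation with tie and
    continuity corrections.  Returns ``(U, p_value)`` for the first group
    in sorted label order.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("rank-sum test needs exactly two groups")
    x = table.abundances.loc[[s for s in table.abundances.index if groups.get(s) == labels[0]], taxon].to_numpy()
    y = table.abundances.loc[[s for s in table.abundances.index if groups.get(s) == labels[1]], taxon].to_numpy()
    return rank_sum(x, y, exact_max_n=exact_max_n)


def rank_sum(x, y, exact_max_n: int = 20):
    """Two-sided Mann-Whitney U test; see :func:`rank_sum_abundance`."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    if n1 + n2 <= exact_max_n:
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        count = 0
        total = 0
        base = n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mid) >= dev_obs - 1e-9:
                count += 1
        return u_obs, count / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ------------------------------------------------------------------ profiles

@dataclass
class KmerProfile:
    """Canonical k-mer frequency vector for one sample."""

    sample_id: str
    k: int
    counts: dict
    total: int = 0
    freq: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.total:
            self.total = sum(self.counts.values())
        if not self.freq and self.total:
            self.freq = {km: c / self.total for km, c in self.counts.items()}


_VALID = frozenset("ACGT")


def kmer_profile(reads, sample_id: str = "", k: int = 21) -> KmerProfile:
    """Count canonical k-mers over all reads.

    Windows containing characters outside A/C/G/T are skipped; a profile
    with no valid window is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    reads = list(reads)
    if not reads:
        raise ValueError("no reads supplied")
    if all(len(r) < k for r in reads):
        raise ValueError(f"all reads shorter than k={k}")
    counts: dict = {}
    for read in reads:
        read = read.upper()
        L = len(read)
        if L < k:
            continue
        rc = revcomp(read)
        ok = [c in _VALID for c in read]
        valid_prefix = np.cumsum(np.asarray(ok, dtype=np.int32))
        for i in range(L - k + 1):
            n_ok = valid_prefix[i + k - 1] - (valid_prefix[i - 1] if i else 0)
            if n_ok < k:
                continue
            fwd = read[i : i + k]
            rev = rc[L - k - i : L - i]
            key = fwd if fwd <= rev else rev
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError("all windows invalid (non-ACGT characters)")
    return KmerProfile(sample_id=sample_id, k=k, counts=counts)


def kmer_distance(a: KmerProfile, b: KmerProfile, metric: str = "cosine") -> float:
    """Distance between two profiles over the union of their k-mer keys."""
    if a.k != b.k:
        raise ValueError("profiles have different k")
    if not a.counts or not b.counts:
        raise ValueError("empty profile")
    if metric == "cosine":
        dot = sum(fa * b.freq.get(km, 0.0) for km, fa in a.freq.items())
        na = math.sqrt(sum(f * f for f in a.freq.values()))
        nb = math.sqrt(sum(f * f for f in b.freq.values()))
        return 1.0 - dot / (na * nb)
    keys = set(a.freq) | set(b.freq)
    fa = np.array([a.freq.get(km, 0.0) for km in sorted(keys)])
    fb = np.array([b.freq.get(km, 0.0) for km in sorted(keys)])
    if metric == "euclidean":
        return float(np.linalg.norm(fa - fb))
    if metric == "bray-curtis":
        return float(np.abs(fa - fb).sum() / (fa + fb).sum())
    raise ValueError(f"unknown metric {metric!r}")


def profile_distance_matrix(profiles, metric: str = "cosine") -> DistanceMatrix:
    labels = [p.sample_id for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = max(kmer_distance(profiles[i], profiles[j], metric), 0.0)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------- ordination

def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Axes are built from positive eigenvalues only; negative eigenvalues
    (non-Euclidean distances) are reported in ``eigenvalues`` but excluded
    from the explained-variance denominator.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least 2 samples")
    a = -0.5 * d.d**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > 1e-10
    n_pos = int(pos.sum())
    if (eigval < -1e-8).any():
        log.info(
            "distance matrix is non-Euclidean: %d negative eigenvalues",
            int((eigval < -1e-8).sum()),
        )
    n_axes = min(n_axes, n_pos)
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    denom = eigval[pos].sum()
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eigval,
        pct_explained=100.0 * eigval[:n_axes] / denom,
        sample_ids=list(d.labels),
    )


# ----------------------------------------------------------------- permanova

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    seed: int

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _permanova_ss(d2: np.ndarray, group_codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(group_codes == g)
        if len(members) < 1:
            raise ValueError("empty group")
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA with free label permutations.

    ``labels`` is a sequence aligned with ``d.labels`` (or a mapping from
    sample id to group).  The p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if isinstance(labels, dict):
        labels = [labels[s] for s in d.labels]
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n = len(labels)
    a = len(uniq)
    d2 = d.d**2

    def f_stat(codes_):
        ss_total, ss_within = _permanova_ss(d2, codes_, a)
        ss_between = ss_total - ss_within
        return (
            (ss_between / (a - 1)) / (ss_within / (n - a)),
            ss_between / ss_total,
        )

    f_obs, r2 = f_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = f_stat(rng.permutation(codes))
        if f_perm >= f_obs:
            hits += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=(1 + hits) / (1 + n_perm),
        df_between=a - 1,
        df_within=n - a,
        n_permutations=n_perm,
        seed=seed,
    )
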