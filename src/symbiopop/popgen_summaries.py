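"""Population-genetic summaries: windowed nucleotide diversity, linkage
disequilibrium decay, and the LD method for effective population size.

LD is computed as composite (genotype-dosage) correlation, the quantity the
standard tools report for unphased data.  The Ne estimator follows the
Waples bias-corrected LD method for randomly mating populations: the mean
squared dosage correlation across effectively unlinked pairs, scaled by
``(S/(S-1))**2`` (the Burrows composite convention the sampling-expectation
formulas below were calibrated against), minus the no-drift expectation
``1/S + 3.19/S**2`` (S > 29) or ``0.0018 + 0.907/S + 4.44/S**2`` (S <= 29),
inverted to Ne via the quadratic drift relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, PopulationPanel, VariantTable


@dataclass
class PiWindows:
    """Tiling windows with per-window mean pairwise diversity per site."""

    windows: pd.DataFrame  # chrom, start, end, n_variant_sites, pi

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


@dataclass
class LDDecay:
    """Mean r-squared by pairwise-distance bin."""

    bins: pd.DataFrame  # lo, hi, mean_r2, n_pairs

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


@dataclass
class NeEstimate:
    ne: float
    r2_mean: float
    r2_expected: float
    s_harmonic: float
    maf_cutoff: float
    n_pairs: int

    @property
    def is_infinite(self) -> bool:
        return not math.isfinite(self.ne)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "ne": None if self.is_infinite else self.ne,
                    "infinite": self.is_infinite,
                    "r2_mean": self.r2_mean,
                    "r2_expected": self.r2_expected,
                    "s_harmonic": self.s_harmonic,
                    "maf_cutoff": self.maf_cutoff,
                    "n_pairs": self.n_pairs,
                },
                fh,
                indent=1,
            )


def _site_pi(genotypes: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased diversity (n/(n-1)) * 2p(1-p) and allele counts."""
    ok = genotypes != MISSING
    n = ok.sum(axis=1) * ploidy
    alt = np.where(ok, genotypes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        pi = np.where(n > 1, n / np.maximum(n - 1, 1) * 2 * p * (1 - p), 0.0)
    return pi, n


def nucleotide_diversity(
    v: VariantTable,
    pop: str,
    window: int,
    panel: PopulationPanel,
    chrom_lengths: dict | None = None,
) -> PiWindows:
    """Windowed nucleotide diversity for one population.

    Windows of fixed width tile each contig from position 1; window pi is
    the sum of per-site diversity over the window divided by the window
    width, so invariant sites contribute zero.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if pop not in panel.populations:
        raise ValueError(f"unknown population {pop!r}")
    idx = panel.indices_for(pop, v.sample_ids)
    pi_site, n_alleles = _site_pi(v.genotypes[:, idx], v.ploidy)

    rows = []
    chroms = list(dict.fromkeys(v.chrom.tolist()))
    if chrom_lengths:
        for c in chrom_lengths:
            if c not in chroms:
                chroms.append(c)
    for chrom in chroms:
        on = v.chrom == chrom
        pos = v.pos[on]
        length = (chrom_lengths or {}).get(
            chrom, int(pos.max()) if pos.size else window
        )
        n_windows = max(1, -(-length // window))
        widx = (pos - 1) // window
        pi_sum = np.zeros(n_windows)
        n_var = np.zeros(n_windows, dtype=int)
        contrib = pi_site[on]
        seg = contrib > 0
        np.add.at(pi_sum, widx, np.nan_to_num(contrib))
        np.add.at(n_var, widx[seg], 1)
        for w in range(n_windows):
            rows.append(
                (chrom, w * window + 1, (w + 1) * window, int(n_var[w]), pi_sum[w] / window)
            )
    return PiWindows(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variant_sites", "pi"])
    )


def _pair_r2(x: np.ndarray, y: np.ndarray, burrows: bool = False) -> tuple[float, int]:
    """Squared dosage correlation over samples non-missing at both sites.

    Returns (r2, n_used); r2 is NaN for undefined pairs (all-missing or a
    zero-variance site).  With ``burrows`` the (S/(S-1))**2 composite scaling
    used by the Ne estimator is applied.
    """
    ok = (x != MISSING) & (y != MISSING)
    s = int(ok.sum())
    if s < 2:
        return float("nan"), s
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    vx = (xs * xs).sum()
    vy = (ys * ys).sum()
    if vx == 0 or vy == 0:
        return float("nan"), s
    r2 = float((xs * ys).sum() ** 2 / (vx * vy))
    if burrows:
        r2 *= (s / (s - 1)) ** 2
    return r2, s


def ld_r2(
    v: VariantTable,
    pop: str,
    panel: PopulationPanel,
    max_dist: int,
    bins: int = 20,
    maf: float = 0.05,
) -> LDDecay:
    """Distance-binned mean composite r-squared within a population."""
    idx = panel.indices_for(pop, v.sample_ids)
    if len(idx) < 2:
        raise ValueError("need >= 2 samples in the population")
    g = v.genotypes[:, idx]
    freq = v.alt_freq(idx)
    usable = np.isfinite(freq) & (np.minimum(freq, 1 - freq) >= maf)

    edges = np.linspace(0, max_dist, bins + 1)
    r2_sum = np.zeros(bins)
    counts = np.zeros(bins, dtype=int)
    for chrom in dict.fromkeys(v.chrom.tolist()):
        on = np.flatnonzero((v.chrom == chrom) & usable)
        pos = v.pos[on]
        for a in range(len(on)):
            for b in range(a + 1, len(on)):
                dist = pos[b] - pos[a]
                if dist > max_dist:
                    break
                r2, _ = _pair_r2(g[on[a]], g[on[b]])
                if not math.isfinite(r2):
                    continue
                bi = min(int(np.searchsorted(edges, dist, side="right")) - 1, bins - 1)
                r2_sum[bi] += r2
                counts[bi] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, r2_sum / np.maximum(counts, 1), np.nan)
    return LDDecay(
        pd.DataFrame(
            {
                "lo": edges[:-1].astype(int),
                "hi": edges[1:].astype(int),
                "mean_r2": mean_r2,
                "n_pairs": counts,
            }
        )
    )


def expected_r2_sample(s: float) -> float:
    """No-drift expectation of the composite r-squared at sample size S."""
    if s > 29:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _waples_ne(r2_drift: float, s: float) -> float:
    if r2_drift <= 0:
        return float("inf")
    if s > 29:
        disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_drift)
    disc = max(0.308**2 - 2.08 * r2_drift, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2_drift)


def ne_from_ld(
    v: VariantTable,
    pop: str,
    panel: PopulationPanel,
    maf: float = 0.05,
    min_dist: int | None = None,
) -> NeEstimate:
    """LD-based effective population size from effectively unlinked pairs.

    Pairs are taken across different contigs, plus same-contig pairs farther
    apart than ``min_dist`` when given.  Sample size per pair is the number
    of individuals genotyped at both sites; S is summarised across pairs by
    the harmonic mean.
    """
    idx = panel.indices_for(pop, v.sample_ids)
    g = v.genotypes[:, idx]
    freq = v.alt_freq(idx)
    usable = np.flatnonzero(
        np.isfinite(freq) & (np.minimum(freq, 1 - freq) >= maf)
    )

    usable = usable[v.genotypes[usable].std(axis=1) > 0]
    chrom = v.chrom[usable]
    pos = v.pos[usable]
    gm = g[usable]
    no_missing = not (gm == MISSING).any()

    r2_vals = []
    s_vals = []
    if no_missing and len(usable) >= 2:
        # fast path: one correlation matrix, then mask linked pairs
        x = gm.astype(float)
        x -= x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        x /= sd[:, None]
        s = gm.shape[1]
        corr = x @ x.T / s
        r2 = corr**2 * (s / (s - 1)) ** 2
        iu, ju = np.triu_indices(len(usable), 1)
        unlinked = chrom[iu] != chrom[ju]
        if min_dist is not None:
            unlinked |= np.abs(pos[iu] - pos[ju]) > min_dist
        r2_vals = r2[iu[unlinked], ju[unlinked]].tolist()
        s_vals = [s] * len(r2_vals)
    else:
        for a in range(len(usable)):
            for b in range(a + 1, len(usable)):
                linked = chrom[a] == chrom[b] and (
                    min_dist is None or abs(pos[b] - pos[a]) <= min_dist
                )
                if linked:
                    continue
                r2, s = _pair_r2(gm[a], gm[b], burrows=True)
                if math.isfinite(r2):
                    r2_vals.append(r2)
                    s_vals.append(s)

    if len(r2_vals) < 2:
        raise ValueError("fewer than 2 usable unlinked pairs")
    r2_mean = float(np.mean(r2_vals))
    s_harm = len(s_vals) / sum(1.0 / s for s in s_vals)
    expected = expected_r2_sample(s_harm)
    ne = _waples_ne(r2_mean - expected, s_harm)
    return NeEstimate(
        ne=ne,
        r2_mean=r2_mean,
        r2_expected=expected,
        s_harmonic=s_harm,
        maf_cutoff=maf,
        n_pairs=len(r2_vals),
    )
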