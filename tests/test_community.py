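"""k-mer profiles, community distances, PCoA, PERMANOVA and rank-sum tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from symbiopop.community_kmer import (
    AbundanceTable,
    KmerProfile,
    flag_unhealthy,
    kmer_distance,
    kmer_profile,
    pcoa,
    permanova,
    profile_distance_matrix,
    rank_sum,
    subsample_reads,
)
from symbiopop.containers import DistanceMatrix


# ----------------------------------------------------------------- subsample

def test_subsample_identity_and_determinism():
    reads = [f"read{i}" for i in range(50)]
    assert subsample_reads(reads, 50) == reads
    assert subsample_reads(reads, 60) == reads  # warns, returns all
    a = subsample_reads(reads, 10, seed=100)
    b = subsample_reads(reads, 10, seed=100)
    assert a == b and len(a) == 10
    # order-stable: preserved input order
    assert a == [r for r in reads if r in set(a)]
    with pytest.raises(ValueError):
        subsample_reads(reads, -1)


def test_subsample_proportions_within_binomial_noise():
    reads = ["A"] * 7000 + ["B"] * 3000
    picked = subsample_reads(reads, 1000, seed=1)
    n_a = sum(1 for r in picked if r == "A")
    sd = np.sqrt(1000 * 0.7 * 0.3)
    assert abs(n_a - 700) < 3 * sd


# ----------------------------------------------------------------- unhealthy

def test_flag_unhealthy_strict_boundary():
    ab = pd.DataFrame(
        {"good": [0.5, 0.49, 0.6], "bad": [0.5, 0.51, 0.4]},
        index=["at_half", "above", "below"],
    )
    flagged = flag_unhealthy(AbundanceTable(ab), ["bad"])
    assert list(flagged.unhealthy) == [False, True, False]
    assert flagged.healthy_samples == ["at_half", "below"]


def test_flag_unhealthy_empty_pathogen_set_and_missing_taxon():
    ab = pd.DataFrame({"x": [0.7, 0.2], "y": [0.3, 0.8]}, index=["a", "b"])
    assert not flag_unhealthy(AbundanceTable(ab), []).unhealthy.any()
    flagged = flag_unhealthy(AbundanceTable(ab), ["y", "ghost"])
    assert list(flagged.unhealthy) == [False, True]


def test_abundance_rows_must_sum_to_one():
    with pytest.raises(ValueError):
        AbundanceTable(pd.DataFrame({"x": [0.4], "y": [0.4]}, index=["a"]))


# ------------------------------------------------------------------ profiles

def test_kmer_profile_hand_example():
    """'ACGT' with k=3: ACG and CGT are reverse complements -> one key."""
    prof = kmer_profile(["ACGT"], "s", k=3)
    assert prof.total == 2
    assert prof.counts == {"ACG": 2}
    assert prof.freq == {"ACG": 1.0}


def test_kmer_profile_reverse_complement_invariance():
    read = "ACGTACGGTTACGATCGATT"
    rc = read.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    p1 = kmer_profile([read], "a", k=5)
    p2 = kmer_profile([rc], "b", k=5)
    assert p1.counts == p2.counts


def test_kmer_profile_read_order_invariance():
    reads = ["ACGTACGT", "GGGTTTAA", "CCATGCAT"]
    p1 = kmer_profile(reads, "a", k=4)
    p2 = kmer_profile(reads[::-1], "b", k=4)
    assert p1.counts == p2.counts


def test_kmer_profile_skips_invalid_windows():
    prof = kmer_profile(["ACNGT", "ACGT"], "s", k=3)
    # ACNGT contributes no window; ACGT contributes 2
    assert prof.total == 2


def test_kmer_profile_errors():
    with pytest.raises(ValueError):
        kmer_profile([], "s", k=3)
    with pytest.raises(ValueError):
        kmer_profile(["AC"], "s", k=3)
    with pytest.raises(ValueError):
        kmer_profile(["ANNANNA"], "s", k=3)


def test_kmer_profile_frequencies_normalised():
    prof = kmer_profile(["ACGTTGCA", "TTTTTT"], "s", k=4)
    assert sum(prof.freq.values()) == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------- distances

def _profile_from_freq(freqs, k=3):
    scale = 1000
    counts = {km: int(f * scale) for km, f in freqs.items() if f > 0}
    return KmerProfile("p", k, counts)


def test_kmer_distance_identical_zero():
    p = kmer_profile(["ACGTACGTAA"], "s", k=4)
    assert kmer_distance(p, p) == pytest.approx(0.0, abs=1e-12)


def test_kmer_distance_disjoint_one():
    a = _profile_from_freq({"AAA": 1.0})
    b = _profile_from_freq({"ACC": 1.0})
    assert kmer_distance(a, b) == pytest.approx(1.0)


def test_kmer_distance_hand_cosine():
    a = _profile_from_freq({"AAA": 0.5, "AAC": 0.5})
    b = _profile_from_freq({"AAC": 0.5, "ACC": 0.5})
    assert kmer_distance(a, b) == pytest.approx(0.5)


def test_kmer_distance_other_metrics_and_errors():
    a = _profile_from_freq({"AAA": 0.5, "AAC": 0.5})
    b = _profile_from_freq({"AAC": 0.5, "ACC": 0.5})
    assert kmer_distance(a, b, "euclidean") == pytest.approx(np.sqrt(0.5))
    assert kmer_distance(a, b, "bray-curtis") == pytest.approx(0.5)
    with pytest.raises(ValueError):
        kmer_distance(a, KmerProfile("q", 4, {"AAAA": 1}))
    with pytest.raises(ValueError):
        kmer_distance(a, b, "hamming")


def test_profile_distance_matrix_symmetric():
    rng = np.random.default_rng(0)
    reads = [
        ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)] for _ in range(4)
    ]
    profs = [kmer_profile(r, f"s{i}", k=5) for i, r in enumerate(reads)]
    dm = profile_distance_matrix(profs)
    assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)


# ---------------------------------------------------------------------- PCoA

def test_pcoa_line_fixture():
    d = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
    res = pcoa(DistanceMatrix(["a", "b", "c"], d), 2)
    rec = np.abs(np.subtract.outer(res.coordinates[:, 0], res.coordinates[:, 0]))
    assert np.allclose(rec, d, atol=1e-10)
    assert res.pct_explained[0] == pytest.approx(100.0)


def test_pcoa_label_permutation_same_eigenvalues():
    rng = np.random.default_rng(1)
    pts = rng.random((6, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    e1 = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d), 2).eigenvalues
    perm = rng.permutation(6)
    e2 = pcoa(
        DistanceMatrix([f"s{i}" for i in perm], d[np.ix_(perm, perm)]), 2
    ).eigenvalues
    assert np.allclose(np.sort(e1), np.sort(e2), atol=1e-10)


def test_pcoa_matches_skbio():
    import skbio

    rng = np.random.default_rng(2)
    pts = rng.random((8, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ours = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d), 3)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    assert np.allclose(
        ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
    )


def test_pcoa_needs_two_samples():
    with pytest.raises(ValueError):
        pcoa(DistanceMatrix(["a"], np.zeros((1, 1))), 2)


# ------------------------------------------------------------------ permanova

def _euclid_dm(pts, labels=None):
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = labels or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(labels, d)


def test_permanova_single_group_errors():
    dm = _euclid_dm(np.random.default_rng(0).random((6, 2)))
    with pytest.raises(ValueError):
        permanova(dm, ["g"] * 6, n_perm=9)


def test_permanova_label_renaming_invariant():
    rng = np.random.default_rng(3)
    dm = _euclid_dm(rng.random((10, 2)))
    labels = ["x"] * 5 + ["y"] * 5
    r1 = permanova(dm, labels, n_perm=99, seed=5)
    r2 = permanova(dm, ["yy" if l == "x" else "xx" for l in labels], n_perm=99, seed=5)
    assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
    assert r1.p_value == r2.p_value


def test_permanova_matches_skbio_statistic():
    import skbio

    rng = np.random.default_rng(4)
    pts = rng.random((12, 2))
    labels = ["a"] * 6 + ["b"] * 6
    ours = permanova(_euclid_dm(pts), labels, n_perm=49, seed=0)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(_euclid_dm(pts).d), grouping=labels, permutations=49
    )
    assert ours.pseudo_f == pytest.approx(float(theirs["test statistic"]), rel=1e-9)


def test_permanova_detects_separated_clusters():
    rng = np.random.default_rng(5)
    pts = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(5, 0.3, (8, 2))])
    res = permanova(_euclid_dm(pts), ["a"] * 8 + ["b"] * 8, n_perm=199, seed=1)
    assert res.p_value == pytest.approx(1 / 200)
    assert res.r_squared > 0.5


# ------------------------------------------------------------------- rank sum

def rank_sum_enumeration_oracle(x, y):
    """Enumerate group assignments, computing U by pairwise comparison."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mid = n1 * len(y) / 2

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_of(set(range(n1)))
    total = count = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(set(combo)) - mid) >= abs(u_obs - mid) - 1e-9:
            count += 1
    return count / total


def test_rank_sum_identical_groups():
    assert rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])[1] == 1.0


def test_rank_sum_hand_example():
    u, p = rank_sum([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_rank_sum_exact_handles_ties():
    x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
    _, p = rank_sum(x, y)
    assert p == pytest.approx(rank_sum_enumeration_oracle(x, y))


def test_rank_sum_exact_vs_asymptotic_agreement():
    """Both branches agree within 0.02 at n = 10 + 10."""
    rng = np.random.default_rng(6)
    for _ in range(5):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        _, p_exact = rank_sum(x, y, exact_max_n=20)
        _, p_asym = rank_sum(x, y, exact_max_n=0)
        assert abs(p_exact - p_asym) < 0.02


def test_rank_sum_empty_group_errors():
    with pytest.raises(ValueError):
        rank_sum([], [1.0])
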