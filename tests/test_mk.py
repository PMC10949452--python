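"""McDonald-Kreitman scan: codon classification, segregation classes,
2x2 tables, Fisher calls and pooled alpha."""

import math
from fractions import Fraction

import numpy as np
import pytest

from symbiopop.codons import BASES, CODON_TO_AA, SENSE_CODONS, codon_opportunity
from symbiopop.containers import GeneModel, MISSING, PopulationPanel
from symbiopop.mk_scan import (
    FIXED,
    NONSYNONYMOUS,
    POLY_POP1,
    POLY_POP2,
    POLY_SHARED,
    SYNONYMOUS,
    UNINFORMATIVE,
    MKRecord,
    classify_functional,
    classify_segregation,
    mk_table,
    mk_test,
    pooled_alpha,
    run_mk_scan,
)
from symbiopop.synthetic_data import HostSimConfig, simulate_host_populations

from conftest import make_table, two_pop_panel


def fisher_two_sided_exact(fn, fs, pn, ps) -> Fraction:
    """Independent oracle: exact two-sided Fisher p by integer-weight
    enumeration over all tables with the observed margins."""
    n1, n2 = fn + fs, pn + ps
    c1 = fn + pn
    lo, hi = max(0, c1 - n2), min(n1, c1)
    weights = {a: math.comb(n1, a) * math.comb(n2, c1 - a) for a in range(lo, hi + 1)}
    w0 = weights[fn]
    num = sum(w for w in weights.values() if w <= w0)
    return Fraction(num, math.comb(n1 + n2, c1))


# ----------------------------------------------------------------- functional

def _single_codon_gene(codon, strand="+"):
    ref = {"chr1": codon if strand == "+" else _rc(codon)}
    gene = GeneModel("g", "chr1", [(0, 3)], strand=strand)
    return gene, ref


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.mark.parametrize(
    "codon,pos,alt,expected",
    [
        ("GGT", 2, "A", SYNONYMOUS),      # Gly -> Gly, 4-fold third position
        ("AAA", 0, "G", NONSYNONYMOUS),   # Lys -> Glu
        ("TTA", 0, "C", SYNONYMOUS),      # Leu -> Leu across codon blocks
        ("TAC", 2, "A", NONSYNONYMOUS),   # Tyr -> stop, stop is a 21st state
    ],
)
def test_classify_functional_examples(codon, pos, alt, expected):
    gene = GeneModel("g", "chr1", [(0, 3)])
    assert classify_functional(pos, alt, gene, {"chr1": codon}) == expected


def test_tryptophan_has_no_synonymous_changes():
    """All nine single-base variants of TGG change the protein."""
    gene = GeneModel("g", "chr1", [(0, 3)])
    classes = [
        classify_functional(p, b, gene, {"chr1": "TGG"})
        for p in range(3)
        for b in BASES
        if b != "TGG"[p]
    ]
    assert classes.count(NONSYNONYMOUS) == 9


def test_minus_strand_classification_matches_plus():
    """A gene on the minus strand classifies through the reverse complement."""
    for codon in ("GGT", "AAA", "ATG", "CGA"):
        for p in range(3):
            for b in BASES:
                if b == codon[p]:
                    continue
                plus = classify_functional(
                    p, b, GeneModel("g", "chr1", [(0, 3)]), {"chr1": codon}
                )
                # same codon encoded on the minus strand of the contig
                minus_ref = {"chr1": _rc(codon)}
                minus = classify_functional(
                    2 - p,
                    _rc(b),
                    GeneModel("g", "chr1", [(0, 3)], strand="-"),
                    minus_ref,
                )
                assert plus == minus


def test_out_of_cds_site_raises():
    gene = GeneModel("g", "chr1", [(0, 3)])
    with pytest.raises(ValueError):
        classify_functional(7, "A", gene, {"chr1": "ATGAAA"})


def test_frame_offset_shifts_codon_boundaries():
    # frame=1: translation starts at the second CDS base
    gene = GeneModel("g", "chr1", [(0, 7)], frame=1)
    ref = {"chr1": "NGGTAAAC"[:7]}
    # positions 1..3 form GGT; third position change is synonymous
    assert classify_functional(3, "A", gene, ref) == SYNONYMOUS
    assert classify_functional(4, "G", gene, ref) == NONSYNONYMOUS


# ---------------------------------------------------------------- segregation

@pytest.mark.parametrize(
    "pop1,pop2,expected",
    [
        ([2, 2, 2], [0, 0, 0], FIXED),
        ([0, 0, 0], [2, 2, 2], FIXED),
        ([1, 0, 0], [0, 0, 0], POLY_POP1),
        ([2, 2, 2], [1, 2, 2], POLY_POP2),
        ([1, 1, 1], [1, 1, 1], POLY_SHARED),
        ([0, 0, 0], [0, 0, 0], UNINFORMATIVE),
        ([2, 2, 2], [2, 2, 2], UNINFORMATIVE),
    ],
)
def test_classify_segregation_cases(pop1, pop2, expected):
    g = np.array(pop1 + pop2, dtype=np.int8)
    idx1, idx2 = np.arange(3), np.arange(3, 6)
    assert classify_segregation(g, idx1, idx2) == expected


def test_segregation_all_missing_population_uninformative():
    g = np.array([MISSING, MISSING, 1, 1], dtype=np.int8)
    assert classify_segregation(g, np.arange(2), np.arange(2, 4)) == UNINFORMATIVE


def test_maf_cut_demotes_rare_polymorphism():
    # pop1 frequency 0.05 (1/20 alleles): demoted below a 10% cutoff
    g = np.array([1] + [0] * 9 + [2] * 10, dtype=np.int8)
    idx1, idx2 = np.arange(10), np.arange(10, 20)
    assert classify_segregation(g, idx1, idx2) == POLY_POP1
    assert classify_segregation(g, idx1, idx2, maf_cut=0.1) == FIXED


# --------------------------------------------------------------------- tables

def test_mk_table_counts_and_shared_single_count():
    classes = (
        [(NONSYNONYMOUS, FIXED)] * 6
        + [(SYNONYMOUS, FIXED)] * 2
        + [(NONSYNONYMOUS, POLY_POP1)]
        + [(SYNONYMOUS, POLY_POP2)] * 3
        + [(SYNONYMOUS, POLY_SHARED)] * 2
        + [(NONSYNONYMOUS, UNINFORMATIVE)] * 4
    )
    rec = mk_table("g", classes)
    assert (rec.f_n, rec.f_s, rec.p_n, rec.p_s) == (6, 2, 1, 5)
    shared_only = mk_table("g", [(NONSYNONYMOUS, POLY_SHARED)])
    assert shared_only.p_n == 1
    doubled = mk_table("g", [(NONSYNONYMOUS, POLY_SHARED)], count_shared_twice=True)
    assert doubled.p_n == 2


def test_mk_table_empty():
    rec = mk_table("g", [])
    assert (rec.f_n, rec.f_s, rec.p_n, rec.p_s) == (0, 0, 0, 0)


@pytest.mark.parametrize(
    "table,exp_ni,exp_selected",
    [
        ((1, 1, 1, 1), 1.0, False),
        ((0, 5, 0, 7), float("nan"), False),
        ((10, 2, 1, 5), 25.0, True),
    ],
)
def test_mk_test_against_enumeration_oracle(table, exp_ni, exp_selected):
    rec = mk_test(MKRecord("g", *table))
    oracle_p = float(fisher_two_sided_exact(*table))
    assert rec.p_value == pytest.approx(min(oracle_p, 1.0), abs=1e-12)
    if math.isnan(exp_ni):
        assert math.isnan(rec.ni_ratio)
    else:
        assert rec.ni_ratio == pytest.approx(exp_ni)
    assert rec.selected == exp_selected


def test_neutral_table_not_selected():
    rec = mk_test(MKRecord("g", 1, 1, 1, 1))
    assert rec.p_value == pytest.approx(1.0) and not rec.selected


# ---------------------------------------------------------------------- alpha

def test_pooled_alpha_neutral_zero():
    recs = [MKRecord(f"g{i}", 3, 3, 3, 3) for i in range(10)]
    est = pooled_alpha(recs)
    assert est.defined and est.alpha == pytest.approx(0.0)


def test_pooled_alpha_undefined_flags():
    est = pooled_alpha([MKRecord("g", 0, 5, 3, 2)])
    assert not est.defined
    assert pooled_alpha([]).n_genes_used == 0


def test_pooled_alpha_bootstrap_ci_brackets_point():
    rng = np.random.default_rng(0)
    recs = [
        MKRecord(f"g{i}", *rng.poisson([20, 6, 12, 4])) for i in range(60)
    ]
    est = pooled_alpha(recs, n_bootstrap=200, seed=1)
    assert est.ci_low <= est.alpha <= est.ci_high


# ----------------------------------------------------------------------- scan

def test_scan_swapping_population_labels_is_invariant(host_sim):
    v, genes, ref, panel, _ = host_sim
    swapped = PopulationPanel(
        {s: ("pop2" if p == "pop1" else "pop1") for s, p in panel.assignments.items()}
    )
    recs1, alpha1, sel1 = run_mk_scan(v, genes, panel, ref)
    recs2, alpha2, sel2 = run_mk_scan(v, genes, swapped, ref)
    for a, b in zip(recs1, recs2):
        assert (a.f_n, a.f_s, a.p_n, a.p_s) == (b.f_n, b.f_s, b.p_n, b.p_s)
        assert a.p_value == b.p_value
    assert alpha1.alpha == alpha2.alpha and sel1 == sel2


def test_scan_sample_order_invariance(host_sim):
    v, genes, ref, panel, _ = host_sim
    perm = np.random.default_rng(3).permutation(v.n_samples)
    shuffled = v.copy()
    shuffled.genotypes = v.genotypes[:, perm]
    shuffled.depths = v.depths[:, perm]
    shuffled.sample_ids = [v.sample_ids[i] for i in perm]
    recs1, alpha1, _ = run_mk_scan(v, genes, panel, ref)
    recs2, alpha2, _ = run_mk_scan(shuffled, genes, panel, ref)
    for a, b in zip(recs1, recs2):
        assert (a.f_n, a.f_s, a.p_n, a.p_s) == (b.f_n, b.f_s, b.p_n, b.p_s)
    assert alpha1.alpha == alpha2.alpha


def test_scan_recovers_planted_counts(host_sim):
    """Observed MK tables equal the generator's planted per-gene counts."""
    v, genes, ref, panel, truth = host_sim
    recs, _, _ = run_mk_scan(v, genes, panel, ref, min_poly=0)
    for rec in recs:
        assert (rec.f_n, rec.f_s, rec.p_n, rec.p_s) == truth.planted_counts[rec.gene_id]


def test_scan_empty_gene_set(host_sim):
    v, _, ref, panel, _ = host_sim
    recs, alpha, sel = run_mk_scan(v, [], panel, ref)
    assert recs == [] and sel == [] and not alpha.defined


def test_scan_min_poly_excludes_sparse_genes(host_sim):
    v, genes, ref, panel, _ = host_sim
    all_recs, _, _ = run_mk_scan(v, genes, panel, ref, min_poly=0)
    filt_recs, _, _ = run_mk_scan(v, genes, panel, ref, min_poly=3)
    kept = {r.gene_id for r in filt_recs}
    for r in all_recs:
        assert (r.gene_id in kept) == (r.p_n + r.p_s >= 3)


def test_alpha_increases_with_fixation_multiplier():
    """Pooled alpha grows as planted adaptive fixation gets stronger."""
    alphas = []
    for mult in (2.0, 5.0, 10.0):
        cfg = HostSimConfig(
            n_genes=80, gene_len_codons=150, n_samples_pop1=8, n_samples_pop2=8,
            theta=0.008, divergence=0.01, selected_genes=frozenset(range(16)),
            nonsyn_fix_multiplier=mult, seed=5,
        )
        v, genes, ref, panel, _ = simulate_host_populations(cfg)
        _, est, _ = run_mk_scan(v, genes, panel, ref)
        alphas.append(est.alpha)
    assert alphas[0] < alphas[1] < alphas[2]
    assert alphas[2] > 0
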