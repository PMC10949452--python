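"""Synthetic datasets with planted ground truth.

Three generators cover the pipeline's inputs:

``simulate_host_populations``
    A rate-based two-population model: an ancestral coding genome, Poisson
    numbers of fixed differences between the populations (with an inflated
    nonsynonymous fixation rate in a planted set of positively selected
    genes) and per-population polymorphisms whose derived-allele counts
    follow the neutral site-frequency spectrum (P(i copies) proportional to
    1/i).  Rates are tied to codon mutational opportunity, so the expected
    McDonald-Kreitman table of every gene is known in closed form.

``simulate_ld_cohort``
    A forward Wright-Fisher population of unlinked biallelic loci.  Unlike
    the rate-based model (whose sites are independent), finite-population
    mating generates the cross-locus linkage disequilibrium that LD-based
    effective-size estimation measures, so the cohort carries a true Ne.

``simulate_metagenomes``
    Gut-community samples: per-population Dirichlet taxon compositions,
    an exact number of pathogen-dominated ("unhealthy") samples, and reads
    drawn as uniform substrings of per-taxon reference sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, single_base_changes
from .containers import MISSING, GeneModel, PopulationPanel, VariantTable

POP1 = "pop1"
POP2 = "pop2"


def _harmonic(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


@dataclass
class HostSimConfig:
    """Two-population host genome simulation parameters.

    theta is the scaled polymorphism rate per site within each population
    (the neutral expectation of nucleotide diversity pi); divergence is the
    expected number of fixed differences per synonymous site between the
    populations.  Genes listed in selected_genes have their nonsynonymous
    fixation rate multiplied by nonsyn_fix_multiplier.
    """

    n_genes: int = 500
    gene_len_codons: int = 300
    n_samples_pop1: int = 20
    n_samples_pop2: int = 20
    theta: float = 0.01
    divergence: float = 0.015
    selected_genes: frozenset = frozenset(range(20))
    nonsyn_fix_multiplier: float = 10.0
    true_ne_pop1: int = 1065
    true_ne_pop2: int = 69
    mean_depth: float = 30.0
    shared_poly_rate: float = 0.0
    frac_filter_fail: float = 0.0
    haploid: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "gene_len_codons", "n_samples_pop1",
                     "n_samples_pop2", "true_ne_pop1", "true_ne_pop2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.theta < 0 or self.divergence < 0:
            raise ValueError("theta and divergence must be >= 0")
        if self.nonsyn_fix_multiplier < 1:
            raise ValueError("nonsyn_fix_multiplier must be >= 1")
        if not set(self.selected_genes) <= set(range(self.n_genes)):
            raise ValueError("selected_genes outside [0, n_genes)")
        ploidy = 1 if self.haploid else 2
        a1 = _harmonic(max(ploidy * self.n_samples_pop1, 2))
        a2 = _harmonic(max(ploidy * self.n_samples_pop2, 2))
        # conservative worst case: every change nonsynonymous and selected
        per_codon = 3.0 * (
            self.divergence * self.nonsyn_fix_multiplier
            + (self.theta + self.shared_poly_rate) * (a1 + a2)
        )
        if per_codon > 1.0:
            raise ValueError(
                f"expected mutations per codon {per_codon:.2f} > 1; "
                "lower theta/divergence (multi-hit codons would dominate)"
            )


@dataclass
class CommunitySimConfig:
    """Gut-community simulation parameters for two host populations."""

    taxa: tuple = (
        "Gilliamella", "Snodgrassella_1", "Snodgrassella_2",
        "Lactobacillus_1", "Lactobacillus_2", "Bifidobacterium_1",
        "Bifidobacterium_2", "Apibacter", "Crithidia", "Paenibacillus",
    )
    dirichlet_pop1: tuple = (8, 12, 1, 6, 2, 5, 2, 3, 0.4, 0.4)
    dirichlet_pop2: tuple = (4, 1, 12, 2, 6, 2, 5, 3, 0.4, 0.4)
    pathogen_taxa: tuple = ("Crithidia", "Paenibacillus")
    n_samples_per_pop: int = 20
    frac_unhealthy: float = 7 / 40
    reads_per_sample: int = 2000
    read_len: int = 150
    taxon_genome_len: int = 20000
    seed: int = 0

    def validate(self) -> None:
        if len(self.dirichlet_pop1) != len(self.taxa) or len(self.dirichlet_pop2) != len(self.taxa):
            raise ValueError("concentration vectors must match taxa length")
        if min(self.dirichlet_pop1) <= 0 or min(self.dirichlet_pop2) <= 0:
            raise ValueError("concentration parameters must be strictly positive")
        if not 0 <= self.frac_unhealthy <= 1:
            raise ValueError("frac_unhealthy must be in [0, 1]")
        if not set(self.pathogen_taxa) <= set(self.taxa):
            raise ValueError("pathogen_taxa must be a subset of taxa")
        if self.read_len > self.taxon_genome_len:
            raise ValueError("read_len exceeds taxon_genome_len")
        if self.n_samples_per_pop <= 0 or self.reads_per_sample < 0:
            raise ValueError("invalid sample/read counts")


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    selected_genes: set = field(default_factory=set)
    true_ne: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    planted_counts: dict = field(default_factory=dict)
    abundances: pd.DataFrame | None = None
    unhealthy: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        payload = {
            "selected_genes": sorted(self.selected_genes),
            "true_ne": self.true_ne,
            "population": self.population,
            "planted_counts": {k: list(v) for k, v in self.planted_counts.items()},
            "unhealthy": self.unhealthy,
        }
        if self.abundances is not None:
            payload["abundances"] = self.abundances.to_dict(orient="index")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# host populations
# --------------------------------------------------------------------------

def _sfs_counts(rng, n_alleles: int, size: int) -> np.ndarray:
    """Derived-allele copy numbers from the neutral SFS, P(i) ~ 1/i."""
    i = np.arange(1, n_alleles)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def _passing_info(rng) -> dict:
    return {
        "QD": float(rng.uniform(20, 35)),
        "MQ": float(rng.uniform(55, 60)),
        "FS": float(rng.uniform(0, 5)),
        "SOR": float(rng.uniform(0.5, 2.0)),
        "MQRankSum": float(rng.uniform(-2, 2)),
        "ReadPosRankSum": float(rng.uniform(-2, 2)),
    }


_FAIL_DRAWS = {
    "QD": (0.0, 1.99),
    "MQ": (20.0, 39.9),
    "FS": (60.1, 120.0),
    "SOR": (3.1, 6.0),
    "MQRankSum": (-20.0, -12.6),
    "ReadPosRankSum": (-12.0, -8.1),
}


def simulate_host_populations(cfg: HostSimConfig):
    """Simulate two diverged host populations over a coding reference.

    Returns ``(variants, genes, reference, panel, truth)`` where reference
    maps contig name to sequence and truth records the planted selected
    genes and the per-gene planted (F_N, F_S, P_N, P_S) counts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ploidy = 1 if cfg.haploid else 2
    n1, n2 = cfg.n_samples_pop1, cfg.n_samples_pop2
    al1, al2 = ploidy * n1, ploidy * n2
    a1 = _harmonic(al1) if al1 > 1 else 0.0
    a2 = _harmonic(al2) if al2 > 1 else 0.0

    gene_len = 3 * cfg.gene_len_codons
    codon_ids = rng.integers(0, len(SENSE_CODONS), size=(cfg.n_genes, cfg.gene_len_codons))
    gene_seqs = ["".join(SENSE_CODONS[c] for c in row) for row in codon_ids]
    reference = {"chr1": "".join(gene_seqs)}

    genes = [
        GeneModel(
            gene_id=f"gene{g:04d}",
            chrom="chr1",
            cds_intervals=[(g * gene_len, (g + 1) * gene_len)],
        )
        for g in range(cfg.n_genes)
    ]

    sample_ids = [f"{POP1}_s{i:02d}" for i in range(n1)] + [
        f"{POP2}_s{i:02d}" for i in range(n2)
    ]
    panel = PopulationPanel(
        {s: POP1 for s in sample_ids[:n1]} | {s: POP2 for s in sample_ids[n1:]}
    )

    records = []  # (pos, ref, alt, dosage_row)
    truth_counts = {}
    selected = set(cfg.selected_genes)

    for g in range(cfg.n_genes):
        seq = gene_seqs[g]
        start = g * gene_len
        syn_changes, nonsyn_changes = [], []
        for c in range(cfg.gene_len_codons):
            codon = seq[3 * c : 3 * c + 3]
            for p, alt_base, _, is_syn, to_stop in single_base_changes(codon):
                if to_stop:
                    continue
                entry = (start + 3 * c + p, alt_base)
                (syn_changes if is_syn else nonsyn_changes).append(entry)
        syn_opp = len(syn_changes) / 3.0
        nonsyn_opp = len(nonsyn_changes) / 3.0

        mult = cfg.nonsyn_fix_multiplier if g in selected else 1.0
        n_fs = rng.poisson(cfg.divergence * syn_opp)
        n_fn = rng.poisson(cfg.divergence * nonsyn_opp * mult)
        n_ps = rng.poisson(cfg.theta * syn_opp * (a1 + a2))
        n_pn = rng.poisson(cfg.theta * nonsyn_opp * (a1 + a2))
        n_ss = rng.poisson(cfg.shared_poly_rate * syn_opp) if cfg.shared_poly_rate else 0
        n_sn = rng.poisson(cfg.shared_poly_rate * nonsyn_opp) if cfg.shared_poly_rate else 0

        order_s = rng.permutation(len(syn_changes))
        order_n = rng.permutation(len(nonsyn_changes))
        used = set()

        def draw(changes, order, count):
            out = []
            for idx in order:
                if len(out) == count:
                    break
                pos, alt = changes[idx]
                if pos in used:
                    continue
                used.add(pos)
                out.append((pos, alt))
            return out

        fixed_s = draw(syn_changes, order_s, n_fs)
        fixed_n = draw(nonsyn_changes, order_n, n_fn)
        poly_s = draw(syn_changes, order_s, n_ps)
        poly_n = draw(nonsyn_changes, order_n, n_pn)
        shared_s = draw(syn_changes, order_s, n_ss)
        shared_n = draw(nonsyn_changes, order_n, n_sn)
        shared = shared_s + shared_n

        # draws may truncate if a gene exhausts its candidate changes, so
        # record the counts actually placed
        truth_counts[genes[g].gene_id] = (
            len(fixed_n),
            len(fixed_s),
            len(poly_n) + len(shared_n),
            len(poly_s) + len(shared_s),
        )

        for pos, alt in fixed_s + fixed_n:
            row = np.zeros(n1 + n2, dtype=np.int8)
            if rng.random() < 0.5:
                row[:n1] = ploidy
            else:
                row[n1:] = ploidy
            records.append((pos, alt, row))
        for pos, alt in poly_s + poly_n:
            row = np.zeros(n1 + n2, dtype=np.int8)
            if rng.random() < 0.5:
                k = int(_sfs_counts(rng, al1, 1)[0]) if al1 > 1 else 0
                if k == 0:
                    continue
                chroms = rng.choice(al1, size=k, replace=False)
                np.add.at(row, chroms // ploidy, 1)
            else:
                k = int(_sfs_counts(rng, al2, 1)[0]) if al2 > 1 else 0
                if k == 0:
                    continue
                chroms = rng.choice(al2, size=k, replace=False)
                np.add.at(row, n1 + chroms // ploidy, 1)
            records.append((pos, alt, row))
        for pos, alt in shared:
            row = np.zeros(n1 + n2, dtype=np.int8)
            k1 = int(_sfs_counts(rng, al1, 1)[0]) if al1 > 1 else 0
            k2 = int(_sfs_counts(rng, al2, 1)[0]) if al2 > 1 else 0
            if k1 == 0 or k2 == 0:
                continue
            np.add.at(row, rng.choice(al1, size=k1, replace=False) // ploidy, 1)
            np.add.at(row, n1 + rng.choice(al2, size=k2, replace=False) // ploidy, 1)
            records.append((pos, alt, row))

    records.sort(key=lambda r: r[0])
    n_sites = len(records)
    chrom = np.array(["chr1"] * n_sites, dtype=object)
    pos = np.array([r[0] + 1 for r in records], dtype=np.int64)  # 1-based
    ref = np.array([reference["chr1"][r[0]] for r in records], dtype=object)
    alt = np.array([r[1] for r in records], dtype=object)
    geno = (
        np.vstack([r[2] for r in records])
        if n_sites
        else np.empty((0, n1 + n2), dtype=np.int8)
    )
    depths = rng.poisson(cfg.mean_depth, size=geno.shape).astype(np.int32)
    qual = rng.uniform(100, 1000, size=n_sites)
    info = []
    fail_keys = list(_FAIL_DRAWS)
    for _ in range(n_sites):
        d = _passing_info(rng)
        if cfg.frac_filter_fail and rng.random() < cfg.frac_filter_fail:
            key = fail_keys[rng.integers(len(fail_keys))]
            lo, hi = _FAIL_DRAWS[key]
            d[key] = float(rng.uniform(lo, hi))
        info.append(d)

    variants = VariantTable(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        info=info,
        is_indel=np.zeros(n_sites, dtype=bool),
        n_alleles=np.full(n_sites, 2, dtype=np.int32),
        genotypes=geno,
        depths=depths,
        sample_ids=sample_ids,
        ploidy=ploidy,
    )
    truth = SimTruth(
        selected_genes={genes[g].gene_id for g in selected},
        true_ne={POP1: cfg.true_ne_pop1, POP2: cfg.true_ne_pop2},
        population=dict(panel.assignments),
        planted_counts=truth_counts,
    )
    return variants, genes, reference, panel, truth


# --------------------------------------------------------------------------
# Wright-Fisher cohort for LD-based Ne
# --------------------------------------------------------------------------

def simulate_ld_cohort(
    true_ne: int,
    n_loci: int = 250,
    n_samples: int = 50,
    generations: int = 30,
    seed: int = 0,
    population: str = POP1,
):
    """Forward Wright-Fisher simulation of unlinked biallelic loci.

    A population of ``true_ne`` randomly mating diploids is propagated for
    ``generations`` generations (enough for cross-locus LD to equilibrate,
    since disequilibrium between unlinked loci halves each generation);
    ``n_samples`` individuals are then drawn without replacement.  Each
    locus is emitted on its own contig so every pair is unlinked by the
    different-chromosome rule.

    Returns ``(variants, panel, truth)``.
    """
    if true_ne < 2 or n_samples < 2 or n_loci < 2:
        raise ValueError("need true_ne, n_samples and n_loci all >= 2")
    if n_samples > true_ne:
        raise ValueError("cannot sample more individuals than the population holds")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.2, 0.8, n_loci)
    h1 = (rng.random((true_ne, n_loci)) < p0).astype(np.uint8)
    h2 = (rng.random((true_ne, n_loci)) < p0).astype(np.uint8)
    for _ in range(generations):
        mothers = rng.integers(0, true_ne, true_ne)
        fathers = rng.integers(0, true_ne, true_ne)
        g1 = np.where(rng.random((true_ne, n_loci)) < 0.5, h1[mothers], h2[mothers])
        g2 = np.where(rng.random((true_ne, n_loci)) < 0.5, h1[fathers], h2[fathers])
        h1, h2 = g1, g2
    idx = rng.choice(true_ne, n_samples, replace=False)
    dosage = (h1[idx] + h2[idx]).astype(np.int8).T  # loci x samples

    sample_ids = [f"{population}_s{i:02d}" for i in range(n_samples)]
    n_loci_out = dosage.shape[0]
    variants = VariantTable(
        chrom=np.array([f"locus{i:05d}" for i in range(n_loci_out)], dtype=object),
        pos=np.ones(n_loci_out, dtype=np.int64),
        ref=np.array(["A"] * n_loci_out, dtype=object),
        alt=np.array(["G"] * n_loci_out, dtype=object),
        qual=np.full(n_loci_out, 100.0),
        info=[{} for _ in range(n_loci_out)],
        is_indel=np.zeros(n_loci_out, dtype=bool),
        n_alleles=np.full(n_loci_out, 2, dtype=np.int32),
        genotypes=dosage,
        depths=np.full(dosage.shape, 30, dtype=np.int32),
        sample_ids=sample_ids,
        ploidy=2,
    )
    panel = PopulationPanel({s: population for s in sample_ids})
    truth = SimTruth(true_ne={population: true_ne}, population=dict(panel.assignments))
    return variants, panel, truth


# --------------------------------------------------------------------------
# gut communities
# --------------------------------------------------------------------------

def simulate_metagenomes(cfg: CommunitySimConfig):
    """Simulate per-sample gut-community reads with known compositions.

    The number of pathogen-dominated samples is exactly
    ``round(frac_unhealthy * n_samples)`` (chosen at random), so planted
    truth is deterministic in count.  Healthy compositions are redrawn
    until pathogen mass is <= 0.5.

    Returns ``(reads, abundances, references, truth)`` where reads maps
    sample id to a list of read strings and abundances is a samples x taxa
    DataFrame of true compositions.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa = list(cfg.taxa)
    path_idx = [taxa.index(t) for t in cfg.pathogen_taxa]
    other_idx = [i for i in range(len(taxa)) if i not in path_idx]

    references = {
        t: "".join(rng.choice(list("ACGT"), size=cfg.taxon_genome_len))
        for t in taxa
    }

    n_total = 2 * cfg.n_samples_per_pop
    sample_ids = [f"{POP1}_g{i:02d}" for i in range(cfg.n_samples_per_pop)] + [
        f"{POP2}_g{i:02d}" for i in range(cfg.n_samples_per_pop)
    ]
    pops = [POP1] * cfg.n_samples_per_pop + [POP2] * cfg.n_samples_per_pop
    conc = {POP1: np.asarray(cfg.dirichlet_pop1, float),
            POP2: np.asarray(cfg.dirichlet_pop2, float)}

    n_unhealthy = int(round(cfg.frac_unhealthy * n_total))
    unhealthy_ix = set(rng.choice(n_total, size=n_unhealthy, replace=False).tolist())

    comps = np.zeros((n_total, len(taxa)))
    for i, (sid, pop) in enumerate(zip(sample_ids, pops)):
        if i in unhealthy_ix and path_idx:
            mass = rng.uniform(0.55, 0.95)
            pw = rng.dirichlet(np.ones(len(path_idx)))
            ow = rng.dirichlet(conc[pop][other_idx])
            comp = np.zeros(len(taxa))
            comp[path_idx] = mass * pw
            comp[other_idx] = (1 - mass) * ow
        else:
            for _ in range(1000):
                comp = rng.dirichlet(conc[pop])
                if comp[path_idx].sum() <= 0.5:
                    break
            else:
                raise RuntimeError("could not draw a healthy composition")
        comps[i] = comp

    reads = {}
    max_start = cfg.taxon_genome_len - cfg.read_len
    for i, sid in enumerate(sample_ids):
        counts = rng.multinomial(cfg.reads_per_sample, comps[i])
        sample_reads = []
        for t, c in zip(taxa, counts):
            if c == 0:
                continue
            starts = rng.integers(0, max_start + 1, size=c)
            seq = references[t]
            sample_reads.extend(seq[s : s + cfg.read_len] for s in starts)
        rng.shuffle(sample_reads)
        reads[sid] = sample_reads

    abundances = pd.DataFrame(comps, index=sample_ids, columns=taxa)
    truth = SimTruth(
        population=dict(zip(sample_ids, pops)),
        abundances=abundances,
        unhealthy={sid: (i in unhealthy_ix) for i, sid in enumerate(sample_ids)},
    )
    return reads, abundances, references, truth


def write_reads_fasta(reads: dict, directory) -> None:
    """One FASTA per sample under ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, rds in reads.items():
        with open(directory / f"{sid}.fasta", "w") as fh:
            for i, r in enumerate(rds):
                fh.write(f">{sid}_r{i}\n{r}\n")
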