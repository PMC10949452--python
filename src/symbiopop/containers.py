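"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`VariantTable`, a dense sites x samples matrix of
alt-allele dosages plus per-site annotations, read from and written to plain
VCF 4.2.  Genotype dosage is coded 0..ploidy with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: site INFO keys recognised by the QC stage, in canonical output order
INFO_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


@dataclass
class VariantTable:
    """Biallelic SNP matrix with site annotations and genotype depths.

    Attributes
    ----------
    chrom, pos : arrays of contig name and 1-based position, position
        strictly increasing within each contig.
    ref, alt : single-base reference and alternate alleles.
    qual : site quality score (``QUAL`` column).
    info : one dict per site holding any of the keys in :data:`INFO_KEYS`
        (missing keys mean the annotation was absent for that site).
    genotypes : ``(n_sites, n_samples)`` int8 alt-allele dosage,
        0..ploidy or -1 for missing.
    depths : ``(n_sites, n_samples)`` read depth per genotype.
    ploidy : 2 for diploid host data, 1 for haploid symbiont data.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    info: list
    is_indel: np.ndarray
    n_alleles: np.ndarray
    genotypes: np.ndarray
    depths: np.ndarray
    sample_ids: list
    ploidy: int = 2

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            qual=self.qual.copy(),
            info=[dict(d) for d in self.info],
            is_indel=self.is_indel.copy(),
            n_alleles=self.n_alleles.copy(),
            genotypes=self.genotypes.copy(),
            depths=self.depths.copy(),
            sample_ids=list(self.sample_ids),
            ploidy=self.ploidy,
        )

    def take_sites(self, index) -> "VariantTable":
        """New table restricted to the given site mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantTable(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=self.qual[index],
            info=[dict(self.info[i]) for i in index],
            is_indel=self.is_indel[index],
            n_alleles=self.n_alleles[index],
            genotypes=self.genotypes[index],
            depths=self.depths[index],
            sample_ids=list(self.sample_ids),
            ploidy=self.ploidy,
        )

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        """Alt-allele frequency per site over non-missing alleles.

        Returns NaN for sites with no genotyped allele in the selection.
        """
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        ok = g != MISSING
        n_alleles = ok.sum(axis=1) * self.ploidy
        alt = np.where(ok, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    # ------------------------------------------------------------------ VCF
    def to_vcf(self, path, reference_lengths=None) -> None:
        """Write a deterministic, sorted VCF 4.2 text file."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=symbiopop\n')
            if reference_lengths:
                for name, length in reference_lengths.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            else:
                for name in dict.fromkeys(self.chrom.tolist()):
                    fh.write(f"##contig=<ID={name}>\n")
            for key in INFO_KEYS:
                fh.write(
                    f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
                )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            for i in range(self.n_sites):
                info = self.info[i]
                info_str = ";".join(
                    f"{k}={info[k]:.4g}" for k in INFO_KEYS if k in info
                ) or "."
                gts = []
                for j in range(self.n_samples):
                    d = self.genotypes[i, j]
                    if self.ploidy == 1:
                        gt = "." if d == MISSING else str(int(d))
                    else:
                        gt = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                    gts.append(f"{gt}:{int(self.depths[i, j])}")
                fh.write(
                    f"{self.chrom[i]}\t{int(self.pos[i])}\t.\t{self.ref[i]}\t"
                    f"{self.alt[i]}\t{self.qual[i]:.2f}\t.\t{info_str}\tGT:DP\t"
                    + "\t".join(gts)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path, ploidy: int = 2) -> "VariantTable":
        """Read a VCF (plain text or bgzipped) into a dense table.

        Multi-allelic records are kept (``n_alleles`` reflects the ALT list;
        dosage counts the first ALT allele) so the QC stage can drop them.
        """
        import pysam

        vf = pysam.VariantFile(path)
        sample_ids = list(vf.header.samples)
        chrom, pos, ref, alt, qual = [], [], [], [], []
        info_list, is_indel, n_alleles = [], [], []
        geno_rows, depth_rows = [], []
        for rec in vf:
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            first_alt = rec.alts[0] if rec.alts else "."
            alt.append(first_alt)
            qual.append(rec.qual if rec.qual is not None else np.nan)
            info_list.append(
                {k: float(rec.info[k]) for k in INFO_KEYS if k in rec.info}
            )
            alts = rec.alts or ()
            is_indel.append(
                len(rec.ref) != 1 or any(len(a) != 1 for a in alts)
            )
            n_alleles.append(1 + len(alts))
            grow = np.empty(len(sample_ids), dtype=np.int8)
            drow = np.zeros(len(sample_ids), dtype=np.int32)
            for j, s in enumerate(sample_ids):
                call = rec.samples[s]
                alleles = call.get("GT")
                if alleles is None or all(a is None for a in alleles):
                    grow[j] = MISSING
                else:
                    grow[j] = sum(1 for a in alleles if a is not None and a >= 1)
                dp = call.get("DP")
                drow[j] = dp if dp is not None else 0
            geno_rows.append(grow)
            depth_rows.append(drow)
        n = len(pos)
        return cls(
            chrom=np.array(chrom, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            ref=np.array(ref, dtype=object),
            alt=np.array(alt, dtype=object),
            qual=np.array(qual, dtype=float),
            info=info_list,
            is_indel=np.array(is_indel, dtype=bool),
            n_alleles=np.array(n_alleles, dtype=np.int32),
            genotypes=(
                np.vstack(geno_rows)
                if n
                else np.empty((0, len(sample_ids)), dtype=np.int8)
            ),
            depths=(
                np.vstack(depth_rows)
                if n
                else np.empty((0, len(sample_ids)), dtype=np.int32)
            ),
            sample_ids=sample_ids,
            ploidy=ploidy,
        )


@dataclass
class PopulationPanel:
    """Mapping of sample id to population label (two labels for MK stages)."""

    assignments: dict

    @property
    def populations(self) -> list:
        return sorted(set(self.assignments.values()))

    def samples_for(self, population) -> list:
        return [s for s, p in self.assignments.items() if p == population]

    def indices_for(self, population, sample_ids) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(sample_ids) if self.assignments.get(s) == population],
            dtype=int,
        )

    def validate(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")
        for pop in self.populations:
            if not self.samples_for(pop):
                raise ValueError(f"population {pop!r} has no samples")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.assignments), "population": list(self.assignments.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


@dataclass
class GeneModel:
    """CDS coordinates of one gene tied to a reference contig.

    Intervals are 0-based half-open, listed in genomic order; the
    concatenated CDS (reverse-complemented on the - strand) must have
    length divisible by 3 with no internal stop codons.
    """

    gene_id: str
    chrom: str
    cds_intervals: list
    strand: str = "+"
    frame: int = 0

    def cds_positions(self) -> np.ndarray:
        """Genomic positions (0-based) of CDS bases in translation order."""
        pos = np.concatenate(
            [np.arange(s, e, dtype=np.int64) for s, e in self.cds_intervals]
        )
        return pos[::-1] if self.strand == "-" else pos

    @property
    def cds_length(self) -> int:
        return int(sum(e - s for s, e in self.cds_intervals))


def gene_models_to_bed(genes, path) -> None:
    """Write gene models as a BED-like TSV (chrom, start, end, id, strand, frame).

    Multi-interval genes emit one row per interval.
    """
    rows = []
    for g in genes:
        for s, e in g.cds_intervals:
            rows.append((g.chrom, s, e, g.gene_id, g.strand, g.frame))
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "strand", "frame"]
    ).to_csv(path, sep="\t", index=False, header=False)


def gene_models_from_bed(path) -> list:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "strand", "frame"],
    )
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("start")
        genes.append(
            GeneModel(
                gene_id=str(gid),
                chrom=str(sub.iloc[0]["chrom"]),
                cds_intervals=[(int(r.start), int(r.end)) for r in sub.itertuples()],
                strand=str(sub.iloc[0]["strand"]),
                frame=int(sub.iloc[0]["frame"]),
            )
        )
    return genes


def write_fasta(sequences: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()],
        path,
        "fasta",
    )


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distance matrix with labels."""

    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


@dataclass
class OrdinationResult:
    """Sample coordinates on orthogonal axes with explained-variance shares."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_explained: np.ndarray
    sample_ids: list = field(default_factory=list)
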