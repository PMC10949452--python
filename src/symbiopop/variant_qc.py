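"""Two-stage SNP quality control.

Stage one removes sites failing any clause of the hard-filter expression
``QD < 2.0 || MQ < 40.0 || FS > 60.0 || SOR > 3.0 || MQRankSum < -12.5 ||
ReadPosRankSum < -8.0`` (all comparisons strict; a missing annotation never
triggers its clause).  Stage two removes indels, multi-allelic sites and
low-quality sites, and masks individual genotypes below a depth floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import operator

import numpy as np
import pandas as pd

from .containers import MISSING, VariantTable

#: clause name -> (comparison, threshold); a site failing ANY clause is removed
HARD_FILTER_CLAUSES = {
    "QD": (operator.lt, 2.0),
    "MQ": (operator.lt, 40.0),
    "FS": (operator.gt, 60.0),
    "SOR": (operator.gt, 3.0),
    "MQRankSum": (operator.lt, -12.5),
    "ReadPosRankSum": (operator.lt, -8.0),
}


@dataclass
class FilterSummary:
    """Per-clause removal counts for reporting."""

    n_input: int = 0
    n_output: int = 0
    removed_by_clause: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [("input_sites", self.n_input), ("output_sites", self.n_output)]
        rows += sorted(self.removed_by_clause.items())
        pd.DataFrame(rows, columns=["clause", "count"]).to_csv(
            path, sep="\t", index=False
        )


def site_hard_filter(v: VariantTable, summary: FilterSummary | None = None) -> VariantTable:
    """Remove sites failing any hard-filter clause (OR semantics).

    Sites missing an INFO field pass the corresponding clause.  Returns a
    new table; the input is left untouched.
    """
    keep = np.ones(v.n_sites, dtype=bool)
    counts = {name: 0 for name in HARD_FILTER_CLAUSES}
    for i, info in enumerate(v.info):
        for name, (cmp_, thr) in HARD_FILTER_CLAUSES.items():
            val = info.get(name)
            if val is not None and cmp_(val, thr):
                keep[i] = False
                counts[name] += 1
    if summary is not None:
        summary.n_input = v.n_sites
        summary.removed_by_clause = counts
        summary.n_output = int(keep.sum())
    return v.take_sites(keep)


def genotype_site_filter(
    v: VariantTable,
    min_dp: int = 4,
    min_q: float = 70.0,
    drop_monomorphic: bool = False,
) -> VariantTable:
    """Indel/multi-allelic/quality site removal plus per-genotype depth masking.

    Genotypes with depth < ``min_dp`` are set to missing (the site is kept as
    long as any genotype survives); sites with quality < ``min_q``, indels,
    and sites with more than two alleles are removed.  With
    ``drop_monomorphic`` sites left without segregating variation (after
    masking) are removed too.
    """
    out = v.copy()
    mask = out.depths < min_dp
    out.genotypes[mask] = MISSING

    keep = ~out.is_indel
    keep &= out.n_alleles <= 2
    with np.errstate(invalid="ignore"):
        keep &= ~(out.qual < min_q)  # NaN quality passes
    any_called = (out.genotypes != MISSING).any(axis=1)
    keep &= any_called
    if drop_monomorphic:
        freq = out.alt_freq()
        keep &= (freq > 0) & (freq < 1)
    return out.take_sites(keep)


def run_qc(
    v: VariantTable,
    min_dp: int = 4,
    min_q: float = 70.0,
    drop_monomorphic: bool = False,
) -> tuple[VariantTable, FilterSummary]:
    """Hard filter followed by genotype/site filter, with a summary."""
    summary = FilterSummary()
    stage1 = site_hard_filter(v, summary)
    stage2 = genotype_site_filter(
        stage1, min_dp=min_dp, min_q=min_q, drop_monomorphic=drop_monomorphic
    )
    summary.n_output = stage2.n_sites
    return stage2, summary
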