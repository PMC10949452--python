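"""Standard genetic code helpers: codon translation, single-base change
enumeration, and synonymous/nonsynonymous mutational opportunity.

Opportunity for a codon is the count of its nine single-base changes that are
synonymous vs nonsynonymous, excluding changes that create a stop codon
(those are never planted by the simulator, so they are excluded from the
rates symmetrically).  Stop codons encountered during classification are
treated as a 21st amino-acid state ('*').
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

CODON_TO_AA = dict(_STANDARD.forward_table)
for stop in _STANDARD.stop_codons:
    CODON_TO_AA[stop] = "*"

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid for a codon, with '*' for stop."""
    return CODON_TO_AA[codon.upper()]


def is_synonymous(codon: str, pos_in_codon: int, alt_base: str) -> bool:
    """Whether substituting ``alt_base`` at ``pos_in_codon`` preserves the
    amino acid (stop counts as its own state)."""
    alt_codon = codon[:pos_in_codon] + alt_base + codon[pos_in_codon + 1 :]
    return CODON_TO_AA[codon] == CODON_TO_AA[alt_codon]


@lru_cache(maxsize=None)
def single_base_changes(codon: str):
    """All nine single-base changes of a codon.

    Returns tuples ``(pos_in_codon, alt_base, alt_codon, synonymous, to_stop)``.
    """
    out = []
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1 :]
            out.append(
                (p, b, alt, CODON_TO_AA[codon] == CODON_TO_AA[alt], CODON_TO_AA[alt] == "*")
            )
    return tuple(out)


@lru_cache(maxsize=None)
def codon_opportunity(codon: str):
    """(synonymous, nonsynonymous) change counts, excluding to-stop changes."""
    syn = nonsyn = 0
    for _, _, _, is_syn, to_stop in single_base_changes(codon):
        if to_stop:
            continue
        if is_syn:
            syn += 1
        else:
            nonsyn += 1
    return syn, nonsyn


def sequence_opportunity(cds: str):
    """Summed (synonymous, nonsynonymous) opportunity in units of sites.

    Each codon contributes counts/3 so a codon with all nine changes
    non-stop contributes 3 sites total.
    """
    syn = nonsyn = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        s, n = codon_opportunity(cds[i : i + 3])
        syn += s
        nonsyn += n
    return syn / 3.0, nonsyn / 3.0
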