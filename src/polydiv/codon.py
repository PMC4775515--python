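"""Genetic-code helpers shared by the codon-aware statistics.

All functions take an NCBI translation table id (1 = standard, 5 =
invertebrate mitochondrial) and cache per-table lookups.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCS = "ACGT"


@lru_cache(maxsize=None)
def _table(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def stop_codons(table_id: int = 1) -> frozenset[str]:
    return frozenset(_table(table_id).stop_codons)


@lru_cache(maxsize=None)
def translate_codon(codon: str, table_id: int = 1) -> str:
    """One-letter amino acid, or '*' for stop. Codon must be clean ACGT."""
    if codon in stop_codons(table_id):
        return "*"
    return _table(table_id).forward_table[codon]


def is_clean(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCS for b in codon)


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Nei-Gojobori synonymous/nonsynonymous site counts for one codon.

    At each codon position the fraction of single-nucleotide changes that are
    synonymous is computed among changes that do not create a stop codon
    (stop-traversing changes are excluded from both numerator and
    denominator), so the two counts always sum to 3.
    """
    if codon in stop_codons(table_id):
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    aa = translate_codon(codon, table_id)
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in NUCS if b != codon[pos]]
        valid = [a for a in alts if a not in stop_codons(table_id)]
        if not valid:
            continue
        syn += sum(translate_codon(a, table_id) == aa for a in valid) / len(valid)
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """Nei-Gojobori (syn, nonsyn) difference counts between two codons.

    All mutational pathways between the codons are weighted equally; pathways
    passing through a stop codon are excluded from the average. If every
    pathway hits a stop, all observed differences are scored nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_counts: list[int] = []
    for order in permutations(diff_pos):
        cur = c1
        steps_syn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stop_codons(table_id) and nxt != c2:
                ok = False
                break
            if translate_codon(cur, table_id) == translate_codon(nxt, table_id):
                steps_syn += 1
            cur = nxt
        if ok:
            syn_counts.append(steps_syn)
    if not syn_counts:
        return 0.0, float(len(diff_pos))
    sd = sum(syn_counts) / len(syn_counts)
    return sd, len(diff_pos) - sd
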