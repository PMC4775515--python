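"""Coding-alignment I/O and site-level bookkeeping.

The universal input of the pipeline is an :class:`Alignment`: equal-length,
phased coding allele sequences with species/individual/allele metadata parsed
from the FASTA labels. Downstream modules consume either the object or its
``matrix`` (numpy ``(n, L)`` array of single characters).

Coordinates are 0-based internally; report-facing output is 1-based.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import codon as _codon
from ._matrix import (
    MISSING,
    biallelic_encoding,
    column_states,
    incompatible_pairs,
)

#: Default label schema: species prefix (EC/ES/Euc/Eus, case-insensitive),
#: individual number, then the allele number, optionally prefixed by "All".
#: Example labels: "EC01_All1", "Eus78-all2", "ES12_2".
DEFAULT_LABEL_SCHEMA = (
    r"^(?P<species>E(?:uc|us|C|S|c|s))_?(?P<individual>\d+)[-_](?:all)?(?P<allele>\d+)"
)

_SPECIES_CANON = {"ec": "Euc", "euc": "Euc", "es": "Eus", "eus": "Eus"}


class AlignmentError(ValueError):
    """Raised on malformed alignments or labels."""


@dataclass
class Alignment:
    """Equal-length phased coding allele sequences with parsed metadata."""

    labels: list[str]
    species: list[str]
    individuals: list[str]
    alleles: list[int]
    matrix: np.ndarray  # (n, L), dtype '<U1', upper-case
    reading_frame_offset: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (sequences x columns)")
        if len(self.labels) != self.matrix.shape[0]:
            raise AlignmentError("label/sequence count mismatch")
        if len(set(self.labels)) != len(self.labels):
            dupes = [k for k, v in Counter(self.labels).items() if v > 1]
            raise AlignmentError(f"duplicate labels: {dupes}")
        bad = set(np.unique(self.matrix)) - set("ACGTN-")
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(self.matrix[i])

    def subset(self, indices) -> "Alignment":
        idx = np.asarray(indices)
        return replace(
            self,
            labels=[self.labels[i] for i in idx],
            species=[self.species[i] for i in idx],
            individuals=[self.individuals[i] for i in idx],
            alleles=[self.alleles[i] for i in idx],
            matrix=self.matrix[idx].copy(),
        )

    def by_species(self) -> dict[str, "Alignment"]:
        out: dict[str, Alignment] = {}
        for sp in dict.fromkeys(self.species):  # stable order
            idx = [i for i, s in enumerate(self.species) if s == sp]
            out[sp] = self.subset(idx)
        return out

    def codon_at(self, row: int, codon_index: int) -> str:
        off = self.reading_frame_offset
        return "".join(self.matrix[row, off + 3 * codon_index : off + 3 * codon_index + 3])

    @property
    def n_codons(self) -> int:
        return (self.L - self.reading_frame_offset) // 3

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, label in enumerate(self.labels):
                fh.write(f">{label}\n{self.sequence(i)}\n")

    @classmethod
    def from_sequences(
        cls,
        sequences: list[str],
        labels: list[str] | None = None,
        species: list[str] | None = None,
        reading_frame_offset: int = 0,
        name: str = "",
    ) -> "Alignment":
        """Build an alignment from raw strings (metadata optional)."""
        n = len(sequences)
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        labels = labels or [f"seq{i + 1}" for i in range(n)]
        species = species or ["?"] * n
        matrix = np.array([list(s.upper()) for s in sequences], dtype="<U1")
        return cls(
            labels=list(labels),
            species=list(species),
            individuals=[str(i) for i in range(n)],
            alleles=[1] * n,
            matrix=matrix,
            reading_frame_offset=reading_frame_offset,
            name=name,
        )


def _parse_label(label: str, pattern: re.Pattern) -> tuple[str, str, int]:
    m = pattern.search(label)
    if not m:
        raise AlignmentError(
            f"label {label!r} does not match schema {pattern.pattern!r}"
        )
    sp = m.group("species").lower()
    species = _SPECIES_CANON.get(sp, m.group("species"))
    return species, m.group("individual"), int(m.group("allele"))


def read_alignment(
    path,
    label_schema: str = DEFAULT_LABEL_SCHEMA,
    reading_frame_offset: int = 0,
    name: str = "",
    strict_labels: bool = True,
) -> Alignment:
    """Read a FASTA alignment, parsing species/individual/allele from labels.

    Parameters
    ----------
    path:
        FASTA file of equal-length sequences.
    label_schema:
        Regex with named groups ``species``, ``individual``, ``allele``;
        applied case-insensitively. With ``strict_labels=False`` unparseable
        labels get species ``"?"`` instead of raising.
    """
    path = Path(path)
    pattern = re.compile(label_schema, re.IGNORECASE)
    labels, seqs, species, individuals, alleles = [], [], [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append(str(rec.seq).upper())
        try:
            sp, ind, al = _parse_label(rec.id, pattern)
        except AlignmentError:
            if strict_labels:
                raise
            sp, ind, al = "?", rec.id, 1
        species.append(sp)
        individuals.append(ind)
        alleles.append(al)
    if not labels:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        offender = labels[[len(s) for s in seqs].index(max(lengths))]
        raise AlignmentError(
            f"ragged alignment in {path.name}: lengths {sorted(lengths)} "
            f"(e.g. record {offender!r})"
        )
    matrix = np.array([list(s) for s in seqs], dtype="<U1")
    return Alignment(
        labels=labels,
        species=species,
        individuals=individuals,
        alleles=alleles,
        matrix=matrix,
        reading_frame_offset=reading_frame_offset,
        name=name or path.stem,
    )


# ---------------------------------------------------------------------------
# Segregating sites
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Polymorphic columns of an alignment.

    ``S`` (the headline segregating-site count) excludes columns containing
    any gap or N, matching the complete-deletion convention of the classical
    summary tables; ``S_pairwise`` additionally counts polymorphic columns
    that carry missing data.
    """

    positions: list[int] = field(default_factory=list)  # 0-based
    states: list[dict[str, int]] = field(default_factory=list)
    biallelic: list[bool] = field(default_factory=list)
    singleton: list[bool] = field(default_factory=list)
    has_missing: list[bool] = field(default_factory=list)
    syn_class: list[str] = field(default_factory=list)  # synonymous|nonsynonymous|ambiguous

    @property
    def S(self) -> int:
        return sum(not m for m in self.has_missing)

    @property
    def S_pairwise(self) -> int:
        return len(self.positions)

    def complete_positions(self) -> list[int]:
        return [p for p, m in zip(self.positions, self.has_missing) if not m]


def classify_site(aln: Alignment, pos: int, table_id: int = 1) -> str:
    """Synonymous / nonsynonymous / ambiguous classification of one column.

    Builds the majority codon observed for each nucleotide state at the
    column and compares their translations. Columns outside the reading
    frame, or whose state-majority codons are unclean or stops, are
    'ambiguous'.
    """
    off = aln.reading_frame_offset
    if pos < off or pos >= off + 3 * aln.n_codons:
        return "ambiguous"
    ci = (pos - off) // 3
    by_state: dict[str, Counter] = {}
    for i in range(aln.n):
        nuc = aln.matrix[i, pos]
        if nuc in MISSING:
            continue
        cdn = aln.codon_at(i, ci)
        if _codon.is_clean(cdn):
            by_state.setdefault(nuc, Counter())[cdn] += 1
    if len(by_state) < 2:
        return "ambiguous"
    aas = set()
    for cnt in by_state.values():
        cdn = cnt.most_common(1)[0][0]
        if cdn in _codon.stop_codons(table_id):
            return "ambiguous"
        aas.add(_codon.translate_codon(cdn, table_id))
    return "synonymous" if len(aas) == 1 else "nonsynonymous"


def segregating_sites(aln: Alignment, table_id: int = 1) -> SiteTable:
    """Tabulate polymorphic columns (>= 2 observed nucleotide states)."""
    if aln.n < 2:
        raise AlignmentError("need >=2 sequences to find segregating sites")
    table = SiteTable()
    for pos in range(aln.L):
        col = aln.matrix[:, pos]
        states = column_states(col)
        if len(states) < 2:
            continue
        counts = sorted(states.values(), reverse=True)
        table.positions.append(pos)
        table.states.append(states)
        table.biallelic.append(len(states) == 2)
        table.singleton.append(counts[1] == 1 and len(states) == 2)
        table.has_missing.append(bool(np.isin(col, MISSING).any()))
        table.syn_class.append(classify_site(aln, pos, table_id))
    return table


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

def collapse_haplotypes(aln: Alignment, wildcard_n: bool = True) -> list[tuple[str, int]]:
    """Distinct haplotypes with multiplicities, most frequent first.

    With ``wildcard_n`` (default), sequences differing only at positions where
    one of them has an N are merged into one haplotype (ambiguity acts as a
    wildcard); gaps are treated as real states.
    """
    seqs = [aln.sequence(i) for i in range(aln.n)]
    if not wildcard_n:
        counts = Counter(seqs)
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    groups: list[list[str]] = []

    def compatible(a: str, b: str) -> bool:
        return all(x == y or "N" in (x, y) for x, y in zip(a, b))

    def merge(a: str, b: str) -> str:
        return "".join(y if x == "N" else x for x, y in zip(a, b))

    reps: list[str] = []
    for s in seqs:
        for gi, rep in enumerate(reps):
            if compatible(s, rep):
                groups[gi].append(s)
                reps[gi] = merge(rep, s)
                break
        else:
            groups.append([s])
            reps.append(s)
    out = [(rep, len(g)) for rep, g in zip(reps, groups)]
    return sorted(out, key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Lineage partitioning
# ---------------------------------------------------------------------------

@dataclass
class LineagePartition:
    """Assignment of each sequence to an allelic lineage.

    ``assignments[i]`` is the group label for sequence i, or ``None`` when the
    diagnostic states tie. ``mismatch_fraction`` is the fraction of diagnostic
    (sequence, site) observations that disagree with the assigned group.
    """

    assignments: list[str | None]
    diagnostic_sites: dict[int, dict[str, str]]  # pos -> state -> group
    mismatch_fraction: float

    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.assignments):
            if g is not None:
                out.setdefault(g, []).append(i)
        return out


def partition_lineages(
    aln: Alignment, diagnostic_sites: dict[int, dict[str, str]]
) -> LineagePartition:
    """Assign each sequence to the lineage its diagnostic states match best.

    ``diagnostic_sites`` maps 0-based positions to {nucleotide: group-label}.
    Sequences are scored by majority vote over the diagnostic sites; exact
    ties are left unassigned.
    """
    for pos in diagnostic_sites:
        if pos >= aln.L:
            raise AlignmentError(f"diagnostic position {pos} beyond L={aln.L}")
    group_labels = sorted({g for m in diagnostic_sites.values() for g in m.values()})
    assignments: list[str | None] = []
    matches = 0
    observations = 0
    for i in range(aln.n):
        votes = Counter()
        for pos, state_map in diagnostic_sites.items():
            nuc = aln.matrix[i, pos]
            if nuc in state_map:
                votes[state_map[nuc]] += 1
        if not votes:
            assignments.append(None)
            continue
        best = votes.most_common()
        if len(best) > 1 and best[0][1] == best[1][1]:
            assignments.append(None)
            continue
        group = best[0][0]
        assignments.append(group)
        for pos, state_map in diagnostic_sites.items():
            nuc = aln.matrix[i, pos]
            if nuc in MISSING:
                continue
            observations += 1
            if state_map.get(nuc) == group:
                matches += 1
    if all(a is None for a in assignments):
        raise AlignmentError("diagnostics uninformative: no sequence assigned")
    frac = 1.0 - matches / observations if observations else 1.0
    _ = group_labels
    return LineagePartition(
        assignments=assignments,
        diagnostic_sites=diagnostic_sites,
        mismatch_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Infinite-sites filter
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    removed_sites: list[int]  # 0-based column indices masked to N
    removed_sequences: list[str]  # labels
    reasons: list[str]


def _count_incompatibilities(matrix: np.ndarray) -> int:
    _, code = biallelic_encoding(matrix)
    return len(incompatible_pairs(code))


def infinite_sites_filter(
    aln: Alignment,
) -> tuple[Alignment, list[int], list[str]]:
    """Reduce an alignment to perfect-phylogeny (four-gamete) compatibility.

    Columns with three or more nucleotide states are masked first (they
    violate infinite sites outright). Remaining four-gamete conflicts are
    resolved greedily: at each step the single site, or the single sequence,
    whose removal resolves the most incompatible pairs is removed, preferring
    sites over sequences on ties (preserves sample size for the coalescent
    likelihood). Removed sites are masked to 'N'; removed sequences dropped.

    Returns (filtered alignment, removed site positions, removed labels).
    """
    if aln.n < 2:
        raise AlignmentError("need >=2 sequences")
    matrix = aln.matrix.copy()
    removed_sites: list[int] = []
    removed_rows: list[int] = []
    keep_rows = list(range(aln.n))

    # 1) multi-allelic columns are homoplasic under infinite sites
    for pos in range(aln.L):
        if len(column_states(matrix[:, pos])) > 2:
            matrix[:, pos] = "N"
            removed_sites.append(pos)

    # 2) greedy resolution of four-gamete conflicts
    while True:
        sub = matrix[keep_rows]
        positions, code = biallelic_encoding(sub)
        pairs = incompatible_pairs(code)
        if not pairs:
            break
        # benefit of removing each involved site
        site_hits = Counter()
        for i, j in pairs:
            site_hits[i] += 1
            site_hits[j] += 1
        best_site, best_site_gain = site_hits.most_common(1)[0]
        # benefit of removing each sequence (exact, by trial removal)
        best_row, best_row_gain = None, -1
        base = len(pairs)
        for r_idx, row in enumerate(keep_rows):
            trial = [r for r in keep_rows if r != row]
            gain = base - _count_incompatibilities(matrix[trial])
            if gain > best_row_gain:
                best_row, best_row_gain = row, gain
        if best_row_gain > best_site_gain:
            keep_rows.remove(best_row)
            removed_rows.append(best_row)
        else:
            pos = positions[best_site]
            matrix[:, pos] = "N"
            removed_sites.append(pos)

    filtered = aln.subset(keep_rows)
    filtered.matrix[:] = matrix[keep_rows]
    removed_labels = [aln.labels[r] for r in sorted(removed_rows)]
    return filtered, sorted(removed_sites), removed_labels


def passes_four_gamete(aln_or_matrix) -> bool:
    """True when no pair of biallelic columns shows all four gametes."""
    matrix = getattr(aln_or_matrix, "matrix", aln_or_matrix)
    return _count_incompatibilities(matrix) == 0
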