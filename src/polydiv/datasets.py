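"""Loaders for the four-locus two-species krill dataset.

The analyses were designed around four coding alignments (three nuclear
hsp70 paralogs and mitochondrial cox-1) for the sister species
*E. crystallorophias* (Euc) and *E. superba* (Eus). The alignment files are
distributed as journal supplementary material and are not bundled here;
place them under ``data/supplementary/`` (or point ``POLYDIV_DATA`` at a
directory) to enable the deterministic reproduction tests:

    Supp1_Krill_COI_fasta.txt     cox-1   (mitochondrial, code table 5)
    Supp2_Krill_Hsp70A_fasta.txt  paralog A
    Supp3_Krill_Hsp70B_fasta.txt  paralog B
    Supp4_Krill_Hsp70C_fasta.txt  paralog C
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import codon as _codon
from .alignment import Alignment, read_alignment

SUPPLEMENTARY_FILES = {
    "cox1": "Supp1_Krill_COI_fasta.txt",
    "hsp70A": "Supp2_Krill_Hsp70A_fasta.txt",
    "hsp70B": "Supp3_Krill_Hsp70B_fasta.txt",
    "hsp70C": "Supp4_Krill_Hsp70C_fasta.txt",
}

TABLE_IDS = {"cox1": 5, "hsp70A": 1, "hsp70B": 1, "hsp70C": 1}
INHERITANCE = {"cox1": 0.25, "hsp70A": 1.0, "hsp70B": 1.0, "hsp70C": 1.0}


def data_dir(root: Path | None = None) -> Path:
    env = os.environ.get("POLYDIV_DATA")
    if env:
        return Path(env)
    base = root or Path(__file__).resolve().parents[2]
    return base / "data" / "supplementary"


def available(root: Path | None = None) -> bool:
    d = data_dir(root)
    return all((d / f).exists() for f in SUPPLEMENTARY_FILES.values())


def best_frame(aln: Alignment, table_id: int) -> int:
    """Reading-frame offset (0/1/2) minimizing internal stop codons."""
    best, best_stops = 0, None
    for off in range(3):
        stops = 0
        n_codons = (aln.L - off) // 3
        for i in range(aln.n):
            seq = aln.sequence(i)
            for ci in range(n_codons):
                cdn = seq[off + 3 * ci : off + 3 * ci + 3]
                if _codon.is_clean(cdn) and cdn in _codon.stop_codons(table_id):
                    stops += 1
        if best_stops is None or stops < best_stops:
            best, best_stops = off, stops
    return best


@dataclass
class Locus:
    name: str
    alignment: Alignment
    table_id: int
    inheritance: float

    def species(self) -> dict[str, Alignment]:
        return self.alignment.by_species()


def load_locus(name: str, root: Path | None = None) -> Locus:
    path = data_dir(root) / SUPPLEMENTARY_FILES[name]
    table_id = TABLE_IDS[name]
    aln = read_alignment(path, name=name, strict_labels=False)
    unknown = [lbl for lbl, sp in zip(aln.labels, aln.species) if sp == "?"]
    if unknown:
        raise ValueError(
            f"{path.name}: could not parse species from labels, e.g. {unknown[:3]}; "
            "adjust the label schema"
        )
    aln.reading_frame_offset = best_frame(aln, table_id)
    return Locus(name, aln, table_id, INHERITANCE[name])


def load_all(root: Path | None = None) -> dict[str, Locus]:
    return {name: load_locus(name, root) for name in SUPPLEMENTARY_FILES}


def two_lineages(aln: Alignment) -> tuple[Alignment, Alignment]:
    """Split one species' alleles into its two allelic lineages.

    Uses the indel diagnostic when a partially gapped column exists
    (one lineage carries a codon deletion); otherwise splits by 2-group
    average-linkage clustering on pairwise p-distance.
    """
    gap_cols = [
        j
        for j in range(aln.L)
        if 0 < int((aln.matrix[:, j] == "-").sum()) < aln.n
    ]
    if gap_cols:
        has_gap = aln.matrix[:, gap_cols[0]] == "-"
        idx_a = np.nonzero(~has_gap)[0]
        idx_b = np.nonzero(has_gap)[0]
    else:
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        n = aln.n
        dist = np.zeros((n, n))
        good = ~np.isin(aln.matrix, ("N", "-"))
        for i in range(n):
            for j in range(i + 1, n):
                ok = good[i] & good[j]
                d = float((aln.matrix[i, ok] != aln.matrix[j, ok]).mean())
                dist[i, j] = dist[j, i] = d
        labels = fcluster(linkage(squareform(dist), "average"), 2, criterion="maxclust")
        idx_a = np.nonzero(labels == 1)[0]
        idx_b = np.nonzero(labels == 2)[0]
    return aln.subset(idx_a), aln.subset(idx_b)
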