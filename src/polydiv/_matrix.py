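"""Internal helpers on character matrices (n sequences x L columns).

Matrices are numpy arrays of dtype '<U1' with alphabet {A,C,G,T,N,-}.
Missing data means 'N' or '-'.
"""

from __future__ import annotations

import numpy as np

MISSING = ("N", "-")


def column_states(col: np.ndarray) -> dict[str, int]:
    """Counts of observed A/C/G/T states in one column (missing excluded)."""
    vals, counts = np.unique(col, return_counts=True)
    return {v: int(c) for v, c in zip(vals, counts) if v not in MISSING}


def biallelic_encoding(
    matrix: np.ndarray,
    positions: list[int] | None = None,
    min_minor: int = 1,
) -> tuple[list[int], np.ndarray]:
    """0/1/-1 encoding of strictly biallelic columns.

    Returns (positions, code) where code[i, k] is 0 for the major allele, 1
    for the minor allele and -1 for missing data at the k-th retained column.
    Columns with more or fewer than two observed nucleotide states, or with a
    minor-allele count below ``min_minor``, are dropped.
    """
    n, L = matrix.shape
    if positions is None:
        positions = list(range(L))
    keep: list[int] = []
    codes: list[np.ndarray] = []
    for pos in positions:
        col = matrix[:, pos]
        states = column_states(col)
        if len(states) != 2:
            continue
        (a1, c1), (a2, c2) = sorted(states.items(), key=lambda kv: (-kv[1], kv[0]))
        if c2 < min_minor:
            continue
        code = np.full(n, -1, dtype=np.int8)
        code[col == a1] = 0
        code[col == a2] = 1
        keep.append(pos)
        codes.append(code)
    if not codes:
        return [], np.empty((n, 0), dtype=np.int8)
    return keep, np.column_stack(codes)


def four_gamete_incompatible(code_i: np.ndarray, code_j: np.ndarray) -> bool:
    """True if the two 0/1/-1 coded sites show all four gametes."""
    ok = (code_i >= 0) & (code_j >= 0)
    if not ok.any():
        return False
    gametes = {(int(a), int(b)) for a, b in zip(code_i[ok], code_j[ok])}
    return len(gametes) == 4


def incompatible_pairs(code: np.ndarray) -> list[tuple[int, int]]:
    """All column-index pairs (i < j) of ``code`` failing the four-gamete test."""
    m = code.shape[1]
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            if four_gamete_incompatible(code[:, i], code[:, j]):
                out.append((i, j))
    return out
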