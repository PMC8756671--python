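"""Independent brute-force oracles used only by the test suite.

The Gotoh dynamic program here is written from the recurrences (affine
gaps, free terminal gaps on both sequences) and shares no code with the
package's aligner wrappers, so it can serve as an independent check of
optimal alignment scores.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e18


def gotoh_endgap_free_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal score of an end-gap-free global affine-gap alignment.

    ``score_fn(x, y)`` returns the substitution score of residues x, y.
    Terminal gap runs on either sequence cost nothing; internal gaps are
    charged ``gap_open`` for the first and ``gap_extend`` for each further
    gap character.  O(len(a)·len(b)) with row vectorisation over b.
    """
    m, n = len(a), len(b)
    sub = np.array([[score_fn(x, y) for y in b] for x in a], dtype=float)
    # state arrays over columns 0..n for the current/previous row;
    # only a gap run at a sequence's own boundary is free (one free leading
    # run per sequence; a second leading run is internal and charged)
    M_prev = np.full(n + 1, NEG)
    X_prev = np.full(n + 1, NEG)
    Y_prev = np.full(n + 1, NEG)
    M_prev[0] = 0.0
    Y_prev[1:] = 0.0  # row 0: prefix of b skipped in a free leading gap
    best = max(0.0, float(np.max(Y_prev)))  # j == n boundary of row 0
    for i in range(1, m + 1):
        M = np.full(n + 1, NEG)
        X = np.full(n + 1, NEG)
        Y = np.full(n + 1, NEG)
        prev_best = np.maximum.reduce([M_prev, X_prev, Y_prev])
        M[1:] = sub[i - 1] + prev_best[:-1]
        X[0] = 0.0  # column 0: prefix of a skipped in a free leading gap
        X[1:] = np.maximum.reduce(
            [
                M_prev[1:] - gap_open,
                Y_prev[1:] - gap_open,
                X_prev[1:] - gap_extend,
            ]
        )
        # Y depends on Y[j-1] within the row: prefix-max trick
        base = np.maximum(M, X)  # predecessors of a new gap-in-a run
        j = np.arange(n + 1)
        g = base + j * gap_extend
        running = np.maximum.accumulate(g[:-1])
        Y[1:] = running - gap_open - (j[1:] - 1) * gap_extend
        Y[0] = NEG
        # trailing gaps are free only off the last row/column
        last_col = float(np.max([M[n], X[n], Y[n]]))
        best = max(best, last_col)
        M_prev, X_prev, Y_prev = M, X, Y
    best = max(best, float(np.max([M_prev.max(), X_prev.max(), Y_prev.max()])))
    return best


def blosum62_score_fn():
    matrix = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(matrix[x, y])


def nt_score_fn(match: float = 2.0, mismatch: float = -3.0):
    return lambda x, y: match if x == y else mismatch


def protein_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    return gotoh_endgap_free_score(a, b, blosum62_score_fn(), gap_open, gap_extend)


def nucleotide_score(a: str, b: str, gap_open: float = 5.0, gap_extend: float = 2.0) -> float:
    return gotoh_endgap_free_score(a, b, nt_score_fn(), gap_open, gap_extend)


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length ungapped sequences."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
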