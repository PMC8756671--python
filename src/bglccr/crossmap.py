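"""Cross-mapping of metagenome and metatranscriptome gene sets.

DNA- and RNA-derived gene catalogues are matched by reciprocal best hits at
a percent-identity threshold (default ≥95%), so DNA and RNA abundances can
be attributed to the same genes.  Identity is computed on an end-gap-free
global nucleotide alignment; terminal gap columns are excluded, so a
sequence matches its own terminal extension at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

GAP = "-"


class CrossmapError(ValueError):
    pass


@dataclass(frozen=True)
class IdentityParams:
    """Nucleotide alignment scoring (end-gap-free global).

    ``min_coverage`` guards against spurious hits: a candidate match only
    counts when the aligned span covers at least this fraction of the
    shorter sequence (end-gap-free alignments of unrelated sequences can
    otherwise report near-perfect identity over a handful of columns).
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    min_coverage: float = 0.5


@dataclass(frozen=True)
class MatchResult:
    dna_gene_id: str
    rna_gene_id: str
    percent_identity: float
    aligned_columns: int
    reciprocal_best: bool = True


def _make_aligner(params: IdentityParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: PairwiseAligner) -> None:
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


def identity_from_alignment(aligned_a: str, aligned_b: str) -> tuple[float, int]:
    """Percent identity over alignment columns, terminal gap columns excluded.

    Columns = all columns between the first and last column where both
    sequences carry a residue (internal gaps count as non-identical columns).
    """
    nongap = [
        i
        for i, (a, b) in enumerate(zip(aligned_a, aligned_b))
        if a != GAP and b != GAP
    ]
    if not nongap:
        return 0.0, 0
    start, end = nongap[0], nongap[-1] + 1
    columns = end - start
    matches = sum(
        1
        for a, b in zip(aligned_a[start:end], aligned_b[start:end])
        if a == b and a != GAP
    )
    return 100.0 * matches / columns, columns


def pairwise_identity(
    a: str, b: str, params: IdentityParams = IdentityParams()
) -> tuple[float, int]:
    """Percent identity and aligned columns of two nucleotide sequences."""
    if not a or not b:
        raise CrossmapError("empty sequence")
    aligner = _make_aligner(params)
    aln = aligner.align(a.upper(), b.upper())[0]
    return identity_from_alignment(str(aln[0]), str(aln[1]))


def _best_hit(
    query_id: str,
    hits: Mapping[str, tuple[float, int]],
) -> str | None:
    """Deterministic best hit: highest identity, then more aligned columns,
    then lexicographically smallest id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-hits[h][0], -hits[h][1], h))


def reciprocal_match(
    dna_set: Mapping[str, str] | Sequence[tuple[str, str]],
    rna_set: Mapping[str, str] | Sequence[tuple[str, str]],
    threshold: float = 95.0,
    params: IdentityParams = IdentityParams(),
) -> list[MatchResult]:
    """Reciprocal-best-hit matching at ≥``threshold``% identity.

    Each retained pair is the mutual best hit of its two genes, so no gene
    appears in more than one pair.  Sets are mappings (or pair lists) of
    gene id → sequence.  An empty result is valid.
    """
    dna = dict(dna_set)
    rna = dict(rna_set)
    if not dna or not rna:
        raise CrossmapError("empty gene set")
    ident: dict[tuple[str, str], tuple[float, int]] = {}
    for d_id, d_seq in dna.items():
        for r_id, r_seq in rna.items():
            pid, cols = pairwise_identity(d_seq, r_seq, params)
            if cols < params.min_coverage * min(len(d_seq), len(r_seq)):
                continue  # spurious short overlap, not a candidate hit
            ident[(d_id, r_id)] = (pid, cols)
    results = []
    for d_id in sorted(dna):
        best_r = _best_hit(
            d_id, {r: ident[(d_id, r)] for r in rna if (d_id, r) in ident}
        )
        if best_r is None:
            continue
        pid, cols = ident[(d_id, best_r)]
        if pid < threshold:
            continue
        best_d = _best_hit(
            best_r, {d: ident[(d, best_r)] for d in dna if (d, best_r) in ident}
        )
        if best_d == d_id:
            results.append(
                MatchResult(
                    dna_gene_id=d_id,
                    rna_gene_id=best_r,
                    percent_identity=pid,
                    aligned_columns=cols,
                )
            )
    return results


def matches_to_frame(matches: Sequence[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dna_gene_id": m.dna_gene_id,
                "rna_gene_id": m.rna_gene_id,
                "percent_identity": m.percent_identity,
                "aligned_columns": m.aligned_columns,
            }
            for m in matches
        ],
        columns=["dna_gene_id", "rna_gene_id", "percent_identity", "aligned_columns"],
    )
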