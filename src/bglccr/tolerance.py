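"""Residue-based glucose-tolerance classification of GH1 β-glucosidase genes.

Glucose-tolerant GH1 family β-glucosidases carry a conserved tryptophan and
leucine at two positions of the active-site region (Trp168 and Leu173 in the
numbering of the bundled reference protein).  A gene is called
``glucose_tolerant`` when, after translation and global alignment to the
reference, both discriminating positions carry the required residue;
``non_tolerant`` when both positions are covered but at least one residue
differs; and ``indeterminate`` when translation or alignment fails quality
gates or a discriminating position falls in a gap.

The anchoring alignment is an end-gap-free global (semi-global) protein
alignment under BLOSUM62 with affine gap costs, so that amplicon fragments
that cover only part of the reference are not penalised at their ends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

GAP = "-"
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NT_CHARS = set("ACGTUNRYSWKMBDHV")

#: frames reported for nucleotide records, in deterministic preference order
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


class ToleranceError(ValueError):
    """Raised on invalid sequence input (empty record, bad characters...)."""


@dataclass(frozen=True)
class GeneRecord:
    """A single β-glucosidase gene (nucleotide or protein)."""

    gene_id: str
    sequence: str
    moltype: str  # "nt" | "aa"
    taxon: tuple[str, ...] | None = None
    source: str = "metagenome"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ToleranceError(f"record {self.gene_id!r}: empty sequence")
        if self.moltype not in ("nt", "aa"):
            raise ToleranceError(f"record {self.gene_id!r}: moltype must be 'nt' or 'aa'")
        seq = self.sequence.upper()
        if self.moltype == "nt":
            bad = set(seq) - _NT_CHARS
        else:
            bad = set(seq) - STANDARD_AA - set("BZXJUO*-")
        if bad:
            raise ToleranceError(
                f"record {self.gene_id!r}: invalid {self.moltype} characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference glucose-tolerant protein plus the discriminating positions.

    Positions are 1-based on the ungapped reference protein; each must carry
    its own required residue so the reference is its own positive control.
    """

    ref_id: str
    ref_protein: str
    discriminating_positions: tuple[tuple[int, str], ...] = ((168, "W"), (173, "L"))

    def __post_init__(self) -> None:
        prot = self.ref_protein.upper()
        object.__setattr__(self, "ref_protein", prot)
        for pos, res in self.discriminating_positions:
            if not 1 <= pos <= len(prot):
                raise ValueError(f"position {pos} outside reference (len {len(prot)})")
            if prot[pos - 1] != res:
                raise ValueError(
                    f"reference {self.ref_id!r} carries {prot[pos - 1]} at {pos}, "
                    f"expected {res}"
                )


def default_reference() -> ReferenceProfile:
    """Bundled synthetic glucose-tolerant GH1 reference (W168/L173).

    A constructed stand-in protein, not a database sequence; swap in any
    curated reference via :class:`ReferenceProfile` to change the numbering.
    """
    from importlib.resources import files

    path = files("bglccr.data").joinpath("gh1_reference_synthetic.fasta")
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceProfile(ref_id=rec.id, ref_protein=str(rec.seq))


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment scoring and the quality gates guarding residue reads."""

    gap_open: float = 10.0
    gap_extend: float = 1.0
    min_identity: float = 0.30  # fraction of matched residue pairs
    min_columns: int = 150      # residue-pair columns required
    min_segment_aa: int = 100   # stop-free segment length kept per frame
    matrix: str = "BLOSUM62"


@dataclass
class AnchoredAlignment:
    """Best-frame alignment of a gene to the reference with a position map."""

    gene_id: str
    frame: str
    query_protein: str
    aligned_ref: str
    aligned_query: str
    score: float
    position_map: Mapping[int, str]
    identity: float
    aligned_columns: int

    def passes_gates(self, params: AlignmentParams) -> bool:
        return (
            self.aligned_columns >= params.min_columns
            and self.identity >= params.min_identity
        )


@dataclass(frozen=True)
class ToleranceCall:
    gene_id: str
    residue_at_positions: tuple[tuple[int, str], ...]  # (ref position, residue or GAP)
    call: str  # glucose_tolerant | non_tolerant | indeterminate
    frame_used: str | None
    alignment_score: float
    identity: float


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: PairwiseAligner) -> None:
    """End-gap-free semantics: fragments are not charged for terminal
    overhangs on either sequence."""
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


def _sanitize(protein: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X."""
    alphabet = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in alphabet else "X" for c in protein)


def translate_candidates(
    record: GeneRecord, genetic_code: int = 1, min_segment_aa: int = 100
) -> list[tuple[str, str]]:
    """Six-frame translation split at stop codons.

    Returns ``(frame, protein)`` pairs for every stop-free segment of at
    least ``min_segment_aa`` residues; amplicons of the expected 1100–1200 bp
    yield one clean ~370 aa frame.  Raises for sequences shorter than a codon.
    """
    if record.moltype != "nt":
        raise ToleranceError(f"record {record.gene_id!r}: translate_candidates needs nt")
    seq = Seq(record.sequence)
    if len(seq) < 3:
        raise ToleranceError(f"record {record.gene_id!r}: shorter than one codon")
    candidates: list[tuple[str, str]] = []
    for strand, s in (("+", seq), ("-", seq.reverse_complement())):
        for off in range(3):
            frame = f"{strand}{off + 1}"
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) < 3:
                continue
            protein = str(sub.translate(table=genetic_code))
            for segment in protein.split("*"):
                if len(segment) >= min_segment_aa:
                    candidates.append((frame, segment))
    return candidates


def _column_stats(aligned_ref: str, aligned_query: str) -> tuple[float, int]:
    pairs = matches = 0
    for a, b in zip(aligned_ref, aligned_query):
        if a != GAP and b != GAP:
            pairs += 1
            if a == b:
                matches += 1
    identity = matches / pairs if pairs else 0.0
    return identity, pairs


def _position_map(aligned_ref: str, aligned_query: str) -> dict[int, str]:
    pmap: dict[int, str] = {}
    ref_pos = 0
    for a, b in zip(aligned_ref, aligned_query):
        if a != GAP:
            ref_pos += 1
            pmap[ref_pos] = b if b != GAP else GAP
    return pmap


def anchor_to_reference(
    candidates: Sequence[tuple[str, str]],
    profile: ReferenceProfile,
    params: AlignmentParams = AlignmentParams(),
    gene_id: str = "",
) -> AnchoredAlignment:
    """Align every candidate frame against the reference, keep the best score.

    Ties are broken by frame order (+1..+3, -1..-3) then candidate order, so
    the result is deterministic.  Raises if no candidate remains.
    """
    if not candidates:
        raise ToleranceError(f"record {gene_id!r}: no translation candidates")
    aligner = _make_aligner(params)
    scored = []
    for idx, (frame, protein) in enumerate(candidates):
        if not protein:
            continue
        score = aligner.score(profile.ref_protein, _sanitize(protein))
        scored.append((score, idx, frame, protein))
    if not scored:
        raise ToleranceError(f"record {gene_id!r}: all candidates empty")
    score, idx, frame, protein = max(scored, key=lambda t: (t[0], -t[1]))
    aln = aligner.align(profile.ref_protein, _sanitize(protein))[0]
    aligned_ref, aligned_query = str(aln[0]), str(aln[1])
    identity, columns = _column_stats(aligned_ref, aligned_query)
    return AnchoredAlignment(
        gene_id=gene_id,
        frame=frame,
        query_protein=protein,
        aligned_ref=aligned_ref,
        aligned_query=aligned_query,
        score=score,
        position_map=_position_map(aligned_ref, aligned_query),
        identity=identity,
        aligned_columns=columns,
    )


def call_tolerance(
    anchored: AnchoredAlignment,
    profile: ReferenceProfile,
    params: AlignmentParams = AlignmentParams(),
) -> ToleranceCall:
    """Read the discriminating positions off the anchored alignment.

    glucose_tolerant iff every discriminating position carries its required
    residue; indeterminate if the alignment fails the quality gates, a
    position is uncovered/gapped, or an ambiguity character sits there.
    """
    residues = tuple(
        (pos, anchored.position_map.get(pos, GAP))
        for pos, _ in profile.discriminating_positions
    )
    if not anchored.passes_gates(params):
        call = "indeterminate"
    elif any(res == GAP or res not in STANDARD_AA for _, res in residues):
        call = "indeterminate"
    elif all(
        res == required
        for (_, res), (_, required) in zip(residues, profile.discriminating_positions)
    ):
        call = "glucose_tolerant"
    else:
        call = "non_tolerant"
    return ToleranceCall(
        gene_id=anchored.gene_id,
        residue_at_positions=residues,
        call=call,
        frame_used=anchored.frame,
        alignment_score=anchored.score,
        identity=anchored.identity,
    )


def _indeterminate_call(gene_id: str) -> ToleranceCall:
    return ToleranceCall(
        gene_id=gene_id,
        residue_at_positions=(),
        call="indeterminate",
        frame_used=None,
        alignment_score=float("nan"),
        identity=float("nan"),
    )


def classify_record(
    record: GeneRecord,
    profile: ReferenceProfile | None = None,
    params: AlignmentParams = AlignmentParams(),
) -> ToleranceCall:
    profile = profile or default_reference()
    try:
        if record.moltype == "nt":
            candidates = translate_candidates(
                record, min_segment_aa=params.min_segment_aa
            )
        else:
            candidates = [("aa", record.sequence)]
        anchored = anchor_to_reference(candidates, profile, params, record.gene_id)
    except ToleranceError:
        return _indeterminate_call(record.gene_id)
    return call_tolerance(anchored, profile, params)


def read_fasta_records(path: str | Path, moltype: str | None = None) -> list[GeneRecord]:
    """Read FASTA records; taxon lineage may follow a '|' in the header,
    semicolon-separated (phylum;class;...).  Moltype is auto-detected unless
    given.  Duplicate ids are an error naming the offender.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ToleranceError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        taxon = None
        if "|" in rec.description:
            lineage = rec.description.split("|", 1)[1].strip()
            if lineage:
                taxon = tuple(t.strip() for t in lineage.split(";") if t.strip())
        seq = str(rec.seq).upper()
        if moltype is None:
            mt = "nt" if set(seq) <= _NT_CHARS else "aa"
        else:
            mt = moltype
        records.append(GeneRecord(gene_id=rec.id, sequence=seq, moltype=mt, taxon=taxon))
    return records


def classify_records(
    records: Iterable[GeneRecord],
    profile: ReferenceProfile | None = None,
    params: AlignmentParams = AlignmentParams(),
) -> pd.DataFrame:
    """Classify records into a tidy call table (order-stable)."""
    profile = profile or default_reference()
    positions = [pos for pos, _ in profile.discriminating_positions]
    rows = []
    for record in records:
        call = classify_record(record, profile, params)
        resmap = dict(call.residue_at_positions)
        row = {
            "gene_id": call.gene_id,
            "frame": call.frame_used,
            **{f"residue_{p}": resmap.get(p, GAP) for p in positions},
            "call": call.call,
            "identity": call.identity,
            "score": call.alignment_score,
        }
        if record.taxon:
            row["taxon"] = ";".join(record.taxon)
        rows.append(row)
    columns = (
        ["gene_id", "frame"]
        + [f"residue_{p}" for p in positions]
        + ["call", "identity", "score"]
    )
    if any("taxon" in r for r in rows):
        columns.append("taxon")
    return pd.DataFrame(rows, columns=columns)


def classify_fasta(
    path: str | Path,
    profile: ReferenceProfile | None = None,
    params: AlignmentParams = AlignmentParams(),
    moltype: str | None = None,
) -> pd.DataFrame:
    return classify_records(read_fasta_records(path, moltype), profile, params)


def call_summary(calls: pd.DataFrame) -> pd.Series:
    """Counts per call category (and per taxon if lineages are present)."""
    counts = calls["call"].value_counts()
    for cat in ("glucose_tolerant", "non_tolerant", "indeterminate"):
        counts = counts.reindex(
            counts.index.union(["glucose_tolerant", "non_tolerant", "indeterminate"]),
            fill_value=0,
        )
    return counts.sort_index()
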