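"""Ortholog-set curation: identity/length filters, transit-peptide stripping,
and alignment trimming.

The curation stage turns a raw pool of candidate Rca orthologs into the
analysis-ready MSA: candidates below 20% identity to the reference or
shorter than 140 residues are dropped, N-terminal chloroplast transit
peptides (cTPs) are removed so positions are numbered in the mature
protein, and gap-heavy alignment columns/rows are trimmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Protocol

import pandas as pd
from Bio import SeqIO, Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

log = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class Source(str, Enum):
    QUERY = "query"
    HOMOLOG = "homolog"
    METAGENOMIC = "metagenomic"
    SYNTHETIC = "synthetic"


@dataclass
class SequenceRecord:
    """One protein sequence with identity and provenance metadata.

    ``ctp_length`` is the predicted number of N-terminal transit-peptide
    residues (None until a predictor has run). ``mature_offset`` records how
    many residues were removed from the N-terminus, so mature-protein
    coordinates (1-based, e.g. "position 250") map back to the precursor.
    """

    id: str
    residues: str
    source: Source = Source.HOMOLOG
    ctp_length: int | None = None
    mature_offset: int = 0
    round: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - _AA
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues outside the amino-acid alphabet: {sorted(bad)}"
            )
        if self.ctp_length is not None and self.ctp_length >= len(self.residues):
            raise ValueError(f"record {self.id!r}: ctp_length must be shorter than the sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedSet:
    """Fixed-width MSA over the 21-letter alphabet, with a designated wildtype row."""

    ids: list[str]
    rows: list[str]
    wildtype_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal widths: {sorted(widths)}")
        if self.wildtype_id not in self.ids:
            raise ValueError(f"wildtype id {self.wildtype_id!r} not present in the alignment")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @property
    def wildtype_row(self) -> str:
        return self.row(self.wildtype_id)


# ---------------------------------------------------------------------------
# pairwise identity and candidate filtering


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def percent_identity(a: str, b: str, denominator: str = "alignment") -> float:
    """Fraction of identical positions between two unaligned sequences.

    The pair is globally aligned (BLOSUM62, gap open -11 / extend -1) and
    identical aligned positions are counted. ``denominator`` selects the
    normalization: ``"alignment"`` (default) divides by the alignment length
    including gap columns; ``"shorter"`` divides by the shorter sequence
    length. Symmetric in its arguments for either choice.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    if denominator not in ("alignment", "shorter"):
        raise ValueError(f"unknown denominator {denominator!r}")
    aln = _global_aligner().align(a.replace("X", "A"), b.replace("X", "A"))[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # count identities on the original residues via the alignment coordinates
    matches = sum(
        x == y and x != "-" for x, y in zip(_thread(a, s1), _thread(b, s2))
    )
    denom = len(s1) if denominator == "alignment" else min(len(a), len(b))
    return matches / denom


def _thread(original: str, gapped: str) -> str:
    """Re-thread the original residues (with X restored) through a gapped string."""
    it = iter(original)
    return "".join(next(it) if c != "-" else "-" for c in gapped)


def filter_candidates(
    records: list[SequenceRecord],
    reference: SequenceRecord,
    min_identity: float = 0.20,
    min_length: int = 140,
    denominator: str = "alignment",
    report: list[dict] | None = None,
) -> list[SequenceRecord]:
    """Retain candidates with identity > ``min_identity`` to the reference
    AND length >= ``min_length``; order-preserving and idempotent.

    Per-rule rejection counts go to the module logger; pass ``report`` to
    also collect one dict per record (id, decision, reason, identity, length).
    """
    if not reference.residues:
        raise ValueError("reference sequence is empty")
    kept: list[SequenceRecord] = []
    n_len = n_id = 0
    for rec in records:
        length_ok = len(rec) >= min_length
        identity = percent_identity(rec.residues, reference.residues, denominator)
        identity_ok = identity > min_identity
        if length_ok and identity_ok:
            kept.append(rec)
            decision, reason = "keep", ""
        elif not length_ok:
            n_len += 1
            decision, reason = "reject", "length"
        else:
            n_id += 1
            decision, reason = "reject", "identity"
        if report is not None:
            report.append(
                {
                    "id": rec.id,
                    "decision": decision,
                    "reason": reason,
                    "identity": round(identity, 4),
                    "length": len(rec),
                    "ctp_length": rec.ctp_length,
                }
            )
    log.info(
        "filter_candidates: kept %d / %d (rejected %d for length, %d for identity)",
        len(kept), len(records), n_len, n_id,
    )
    return kept


# ---------------------------------------------------------------------------
# chloroplast transit peptide handling


class CtpPredictor(Protocol):
    """Adapter interface for a transit-peptide predictor.

    Implementations return the number of N-terminal residues predicted to be
    a chloroplast transit peptide (0 if none). An external tool (e.g. a
    TargetP-style model) can be wrapped behind this interface; the bundled
    :class:`AnchorCtpPredictor` is a deterministic heuristic stand-in.
    """

    def predict(self, residues: str) -> int: ...


@dataclass
class AnchorCtpPredictor:
    """Heuristic cTP predictor: everything before the first occurrence of a
    conserved anchor motif is called transit peptide.

    The anchor is a short motif from the mature reference protein (for Rca a
    conserved N-domain word works well). If the anchor is absent, no cTP is
    called. ``max_ctp`` caps the call so a spurious late match cannot remove
    most of the protein.
    """

    anchor: str
    max_ctp: int = 120

    def predict(self, residues: str) -> int:
        pos = residues.find(self.anchor)
        if pos <= 0 or pos > self.max_ctp:
            return 0
        return pos


def strip_ctp(record: SequenceRecord, predictor: CtpPredictor | None = None) -> SequenceRecord:
    """Remove the predicted transit peptide, returning the mature sequence.

    The record's ``ctp_length`` must be populated, or a ``predictor`` given
    to populate it. The removed length is recorded in ``mature_offset`` so a
    mature-numbering position p maps back to precursor position
    p + mature_offset.
    """
    ctp = record.ctp_length
    if ctp is None:
        if predictor is None:
            raise ValueError(
                f"record {record.id!r}: prediction required — ctp_length unset and no predictor given"
            )
        ctp = predictor.predict(record.residues)
    if ctp == 0:
        return replace(record, ctp_length=0)
    return replace(
        record,
        residues=record.residues[ctp:],
        ctp_length=ctp,
        mature_offset=record.mature_offset + ctp,
    )


# ---------------------------------------------------------------------------
# alignment trimming


def trim_alignment(
    msa: AlignedSet,
    max_col_gap_frac: float = 0.8,
    max_row_gap_frac: float = 0.5,
) -> AlignedSet:
    """Drop gap-heavy columns, then gap-heavy rows.

    Columns whose gap fraction exceeds ``max_col_gap_frac`` are removed
    first; then rows whose gap fraction over the surviving columns exceeds
    ``max_row_gap_frac`` are removed. The wildtype row is never dropped.
    Row order is preserved; deterministic.

    Raises
    ------
    ValueError
        If the thresholds are outside [0, 1] or trimming would leave no
        columns ("over-trimmed").
    """
    for name, frac in (("max_col_gap_frac", max_col_gap_frac), ("max_row_gap_frac", max_row_gap_frac)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    n, width = msa.n_seqs, msa.column_count
    keep_cols = []
    for j in range(width):
        gaps = sum(row[j] == "-" for row in msa.rows)
        if gaps / n <= max_col_gap_frac:
            keep_cols.append(j)
    if not keep_cols:
        raise ValueError("over-trimmed: no columns survive the gap-fraction threshold")
    new_rows = ["".join(row[j] for j in keep_cols) for row in msa.rows]
    surviving = len(keep_cols)
    ids, rows = [], []
    for seq_id, row in zip(msa.ids, new_rows):
        gap_frac = row.count("-") / surviving
        if gap_frac <= max_row_gap_frac or seq_id == msa.wildtype_id:
            ids.append(seq_id)
            rows.append(row)
    return AlignedSet(ids=ids, rows=rows, wildtype_id=msa.wildtype_id)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, source: Source = Source.HOMOLOG) -> list[SequenceRecord]:
    """Read unaligned protein FASTA into SequenceRecords."""
    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), source=source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_aligned_fasta(path: str | Path, wildtype_id: str) -> AlignedSet:
    """Read an aligned FASTA (gap character ``-``) into an AlignedSet."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return AlignedSet(ids=ids, rows=rows, wildtype_id=wildtype_id)


def write_aligned_fasta(msa: AlignedSet, path: str | Path) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(row), id=seq_id, description="") for seq_id, row in zip(msa.ids, msa.rows)],
        str(path),
        "fasta",
    )


def write_curation_report(report: list[dict], path: str | Path) -> None:
    pd.DataFrame(report).to_csv(path, index=False)
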