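"""Upstream near-cognate start-codon annotation.

Some proteins initiate at a non-AUG codon upstream of the annotated AUG —
CUG being the most efficient near-cognate start — which extends the protein
N-terminally.  Given a transcript with its annotated CDS start, this module
finds in-frame upstream candidates from an allowed near-cognate codon set
(default {CTG}) with no intervening in-frame stop, scores the two Kozak
context positions that matter most (a purine at -3 and a G at +4 relative
to the first codon base), and computes the extended protein length.  A
companion check verifies, on an ortholog alignment of the 5' region, that
the reading frame between the candidate and the annotated start is
conserved: every gap run between the two anchors has a length divisible by
three and no in-frame stop interrupts the extension.

Coordinates are 0-based half-open throughout.  Input sequences are
normalized to the DNA alphabet (U -> T, uppercase) before scanning; the
scanner is strand-naive by contract and expects the sense transcript.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from Bio import AlignIO, SeqIO

__all__ = [
    "AnnotatedTranscript",
    "StartCandidate",
    "KozakContext",
    "FrameVerdict",
    "STOP_CODONS",
    "DEFAULT_ALLOWED_CODONS",
    "EXTENDED_ALLOWED_CODONS",
    "scan_upstream_starts",
    "kozak_context",
    "check_frame_conservation",
    "read_transcripts",
    "candidates_to_rows",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_ALLOWED_CODONS = frozenset({"CTG"})
EXTENDED_ALLOWED_CODONS = frozenset({"CTG", "GTG", "TTG", "ACG", "ATT"})


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class AnnotatedTranscript:
    """A transcript with its annotated CDS start.

    ``cds_start`` is the 0-based offset of the A of the annotated ATG;
    ``orf_len_codons`` counts codons of the annotated ORF excluding the
    stop codon (so it equals the annotated protein length in aa).
    """

    transcript_id: str
    sequence: str
    cds_start: int
    orf_len_codons: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence))
        seq, start, length = self.sequence, self.cds_start, self.orf_len_codons
        if not (0 <= start <= len(seq) - 3):
            raise ValueError(
                f"{self.transcript_id}: CDS start {start} out of range"
            )
        if seq[start : start + 3] != "ATG":
            raise ValueError(
                f"{self.transcript_id}: codon at CDS start is "
                f"{seq[start:start + 3]!r}, not ATG"
            )
        if length < 1:
            raise ValueError(f"{self.transcript_id}: ORF length must be >= 1")
        stop_at = start + 3 * length
        if stop_at + 3 > len(seq) or seq[stop_at : stop_at + 3] not in STOP_CODONS:
            raise ValueError(
                f"{self.transcript_id}: no stop codon at the stated ORF end "
                f"(offset {stop_at})"
            )
        for off in range(start, stop_at, 3):
            if seq[off : off + 3] in STOP_CODONS:
                raise ValueError(
                    f"{self.transcript_id}: premature in-frame stop at {off} "
                    f"inside the annotated ORF"
                )


class KozakContext(NamedTuple):
    """Kozak context of a start codon at the two informative positions.

    Flags are None ("unknown") when the position falls outside the
    sequence (e.g. a candidate fewer than 3 nt from the 5' end).
    """

    minus3: Optional[str]
    plus4: Optional[str]
    minus3_match: Optional[bool]  # base in {A, G}
    plus4_match: Optional[bool]  # base == G
    preferred: Optional[bool]  # both matches


def kozak_context(sequence: str, start_offset: int) -> KozakContext:
    """Kozak -3/+4 bases and match flags for a codon at ``start_offset``."""
    seq = _normalize(sequence)
    minus3 = seq[start_offset - 3] if start_offset >= 3 else None
    plus4_pos = start_offset + 3
    plus4 = seq[plus4_pos] if plus4_pos < len(seq) else None
    minus3_match = (minus3 in ("A", "G")) if minus3 is not None else None
    plus4_match = (plus4 == "G") if plus4 is not None else None
    preferred = (
        (minus3_match and plus4_match)
        if (minus3_match is not None and plus4_match is not None)
        else None
    )
    return KozakContext(minus3, plus4, minus3_match, plus4_match, preferred)


@dataclass(frozen=True)
class StartCandidate:
    """An in-frame upstream near-cognate start candidate."""

    transcript_id: str
    offset: int
    codon: str
    distance_nt: int  # to the annotated ATG; multiple of 3
    kozak: KozakContext
    extension_aa: int  # = distance_nt // 3
    extended_aa: int  # = annotated ORF length + extension


def scan_upstream_starts(
    tx: AnnotatedTranscript,
    allowed_codons: Iterable[str] = DEFAULT_ALLOWED_CODONS,
) -> list[StartCandidate]:
    """Find in-frame upstream start candidates with an open extension.

    Returns, ordered 5'->3', every allowed codon upstream of and in frame
    with the annotated ATG such that no in-frame stop codon lies strictly
    between the candidate and the ATG.  Each candidate carries its Kozak
    context and the extension / extended protein lengths.
    """
    allowed = {_normalize(c) for c in allowed_codons}
    bad = [c for c in allowed if len(c) != 3 or set(c) - set("ACGT")]
    if bad:
        raise ValueError(f"invalid codon(s) in allowed set: {bad}")
    seq = tx.sequence
    candidates: list[StartCandidate] = []
    # walk 5'->3' over in-frame upstream codon positions
    first = tx.cds_start % 3
    for off in range(first, tx.cds_start - 2, 3):
        codon = seq[off : off + 3]
        if codon not in allowed:
            continue
        between = seq[off + 3 : tx.cds_start]
        if any(between[i : i + 3] in STOP_CODONS for i in range(0, len(between), 3)):
            continue
        distance = tx.cds_start - off
        extension = distance // 3
        candidates.append(
            StartCandidate(
                transcript_id=tx.transcript_id,
                offset=off,
                codon=codon,
                distance_nt=distance,
                kozak=kozak_context(seq, off),
                extension_aa=extension,
                extended_aa=tx.orf_len_codons + extension,
            )
        )
    return candidates


@dataclass(frozen=True)
class FrameVerdict:
    """Frame-conservation verdict for one aligned ortholog."""

    record_id: str
    conserved: bool
    reason: str = ""


def check_frame_conservation(
    alignment,
    candidate_col: int,
    atg_col: int,
    gap_char: str = "-",
) -> tuple[list[FrameVerdict], float]:
    """Check reading-frame conservation between two alignment anchors.

    ``candidate_col`` and ``atg_col`` are 0-based alignment columns of the
    first base of the candidate codon and of the annotated ATG.  An
    ortholog is conserved iff every gap run strictly between the two
    anchors has length divisible by 3 and the ungapped sequence from the
    candidate to the ATG contains no in-frame stop codon (frame anchored
    at the candidate).  Returns per-ortholog verdicts and the fraction
    conserved.
    """
    if candidate_col >= atg_col:
        raise ValueError(
            f"candidate column {candidate_col} must be upstream of the ATG "
            f"column {atg_col}"
        )
    length = alignment.get_alignment_length()
    if atg_col >= length:
        raise ValueError(f"ATG column {atg_col} outside alignment of width {length}")

    verdicts: list[FrameVerdict] = []
    for record in alignment:
        row = _normalize(str(record.seq))
        region = row[candidate_col:atg_col]
        if region.startswith(gap_char):
            verdicts.append(
                FrameVerdict(record.id, False, "candidate position gapped")
            )
            continue
        # gap runs strictly between the anchors
        gap_runs = []
        run = 0
        for ch in region:
            if ch == gap_char:
                run += 1
            elif run:
                gap_runs.append(run)
                run = 0
        if run:
            gap_runs.append(run)
        bad_run = next((r for r in gap_runs if r % 3 != 0), None)
        if bad_run is not None:
            verdicts.append(
                FrameVerdict(record.id, False, f"{bad_run}-nt gap shifts the frame")
            )
            continue
        ungapped = region.replace(gap_char, "")
        stop = next(
            (
                ungapped[i : i + 3]
                for i in range(0, len(ungapped) - 2, 3)
                if ungapped[i : i + 3] in STOP_CODONS
            ),
            None,
        )
        if stop is not None:
            verdicts.append(
                FrameVerdict(record.id, False, f"in-frame stop {stop} in extension")
            )
            continue
        verdicts.append(FrameVerdict(record.id, True))
    fraction = (
        sum(v.conserved for v in verdicts) / len(verdicts) if verdicts else 0.0
    )
    return verdicts, fraction


def read_transcripts(fasta_path: str | Path, cds_tsv_path: str | Path) -> list[AnnotatedTranscript]:
    """Load transcripts from FASTA plus a CDS annotation table.

    The TSV has columns transcript_id, cds_start_0based, orf_len_codons.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out: list[AnnotatedTranscript] = []
    with open(cds_tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"transcript_id", "cds_start_0based", "orf_len_codons"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{cds_tsv_path}: expected columns {sorted(required)}"
            )
        for row in reader:
            tid = row["transcript_id"]
            if tid not in seqs:
                raise ValueError(f"{tid}: present in the CDS table but not in the FASTA")
            out.append(
                AnnotatedTranscript(
                    transcript_id=tid,
                    sequence=seqs[tid],
                    cds_start=int(row["cds_start_0based"]),
                    orf_len_codons=int(row["orf_len_codons"]),
                )
            )
    return out


def read_alignment(path: str | Path):
    """Read one aligned-FASTA ortholog alignment."""
    return AlignIO.read(str(path), "fasta")


def candidates_to_rows(candidates: list[StartCandidate]) -> list[dict]:
    """Flatten candidates into TSV-ready rows."""

    def flag(x):
        return "unknown" if x is None else ("1" if x else "0")

    rows = []
    for cand in candidates:
        rows.append(
            {
                "transcript_id": cand.transcript_id,
                "offset": cand.offset,
                "codon": cand.codon,
                "distance_nt": cand.distance_nt,
                "minus3": cand.kozak.minus3 or "unknown",
                "plus4": cand.kozak.plus4 or "unknown",
                "minus3_match": flag(cand.kozak.minus3_match),
                "plus4_match": flag(cand.kozak.plus4_match),
                "kozak_preferred": flag(cand.kozak.preferred),
                "extension_aa": cand.extension_aa,
                "extended_aa": cand.extended_aa,
            }
        )
    return rows
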