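"""FASTA input/output, six-frame translation and ORF extraction.

Downstream stages of the pipeline operate on proteins; this module turns
nucleotide assemblies (transcriptome or genome contigs) into stop-to-stop
ORF proteins so the cassette detector never has to care where a sequence
came from.  Coordinates are 0-based half-open throughout; frames are
numbered +1..+3 on the given strand and -1..-3 on the reverse complement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named residue string with provenance.

    ``frame``/``offset`` are only present on records derived from
    translation: frame +k means translation of the forward strand starting
    at nucleotide k-1, frame -k the same on the reverse complement, and
    ``offset`` is the 0-based start of the ORF on the translated strand.
    """

    id: str
    seq: str
    alphabet: str = PROTEIN
    source: str = ""
    frame: int | None = None
    offset: int | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == NUCLEOTIDE else PROTEIN_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} residues {sorted(bad)}"
            )
        if self.frame is not None and self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"frame must be in +-1..3, got {self.frame}")

    def __len__(self) -> int:
        return len(self.seq)


def _clean_residues(raw: str, alphabet: str, rec_id: str, strict: bool) -> str:
    seq = raw.upper()
    allowed = NUCLEOTIDE_ALPHABET if alphabet == NUCLEOTIDE else PROTEIN_ALPHABET
    bad = set(seq) - allowed
    if not bad:
        return seq
    if strict:
        raise FastaParseError(
            f"record {rec_id!r}: illegal {alphabet} residues {sorted(bad)}"
        )
    placeholder = "N" if alphabet == NUCLEOTIDE else "X"
    log.warning(
        "record %r: replacing illegal residues %s with %s",
        rec_id, sorted(bad), placeholder,
    )
    return "".join(c if c in allowed else placeholder for c in seq)


def read_fasta(
    path: str | Path,
    alphabet: str = PROTEIN,
    source: str = "",
    strict: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Headers are retained up to the first whitespace as the record id and
    input order is preserved.  Residues outside the declared alphabet are
    replaced by N/X with a warning, or rejected when ``strict`` is set.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header line, got {line.strip()[:40]!r}"
                )
            break
        else:
            log.warning("%s: empty FASTA file", path)
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_residues(str(rec.seq), alphabet, rec.id, strict)
        records.append(SequenceRecord(id=rec.id, seq=seq, alphabet=alphabet,
                                      source=source or path.stem))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame of ``seq`` with the standard genetic code.

    Ambiguous codons (containing N) translate to X unless the ambiguity is
    synonymous.  Stops are rendered as ``*``.
    """
    strand = seq if frame > 0 else reverse_complement(seq)
    shift = abs(frame) - 1
    sub = strand[shift:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def six_frame_translate(rec: SequenceRecord, min_orf_aa: int = 60) -> list[SequenceRecord]:
    """Extract stop-to-stop ORFs from all six reading frames.

    ORFs are stop-to-stop rather than ATG-initiated because assembled
    transcripts are frequently 5'-truncated; requiring an initiator
    methionine would silently drop real precursors.  Segments shorter than
    ``min_orf_aa`` are discarded.  ``offset`` on each product is the ORF
    start (in nucleotides) on the translated strand.
    """
    if rec.alphabet != NUCLEOTIDE:
        raise ValueError(f"six_frame_translate requires a nucleotide record, got {rec.alphabet}")
    if min_orf_aa < 1:
        raise ValueError("min_orf_aa must be >= 1")
    if len(rec.seq) < 3:
        return []
    out: list[SequenceRecord] = []
    for frame in (1, 2, 3, -1, -2, -3):
        protein = translate_frame(rec.seq, frame)
        shift = abs(frame) - 1
        pos = 0  # aa index of the current segment start
        ordinal = 0
        for segment in protein.split("*"):
            if len(segment) >= min_orf_aa and "X" * len(segment) != segment:
                out.append(SequenceRecord(
                    id=f"{rec.id}_f{frame:+d}_orf{ordinal}",
                    seq=segment,
                    alphabet=PROTEIN,
                    source=rec.source,
                    frame=frame,
                    offset=shift + 3 * pos,
                ))
                ordinal += 1
            pos += len(segment) + 1  # +1 skips the stop codon
    return out


def six_frame_translate_all(
    records: Sequence[SequenceRecord], min_orf_aa: int = 60
) -> list[SequenceRecord]:
    out: list[SequenceRecord] = []
    for rec in records:
        out.extend(six_frame_translate(rec, min_orf_aa=min_orf_aa))
    return out
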