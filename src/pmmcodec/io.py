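"""FASTA and plain-text sequence I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import AlphabetError
from .model import Alphabet, DNA

__all__ = ["SequenceRecord", "read_fasta", "write_fasta", "read_text"]

logger = logging.getLogger(__name__)


@dataclass
class SequenceRecord:
    identifier: str
    sequence: str
    source: str = "fasta"

    def __post_init__(self):
        if not self.sequence:
            raise AlphabetError(f"record {self.identifier!r} has an empty sequence")


def read_fasta(
    path,
    alphabet: Alphabet = DNA,
    alphabet_policy: str = "strict",
) -> tuple[list[SequenceRecord], Alphabet]:
    """Read (possibly line-wrapped, multi-record) FASTA, lower-casing symbols.

    Policies for characters outside the alphabet: ``strict`` raises naming
    the record and position, ``skip`` drops them (count logged), ``keep``
    extends the alphabet with them in order of first appearance.

    Returns the records and the (possibly extended) alphabet.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlphabetError(f"no FASTA records in {path}")
    symbols = list(alphabet.symbols)
    out = []
    for rec in records:
        seq = str(rec.seq).lower()
        if alphabet_policy == "strict":
            for i, ch in enumerate(seq):
                if ch not in symbols:
                    raise AlphabetError(
                        f"record {rec.id!r}: symbol {ch!r} at position {i} "
                        "outside the alphabet (policy=strict)"
                    )
        elif alphabet_policy == "skip":
            kept = [ch for ch in seq if ch in symbols]
            dropped = len(seq) - len(kept)
            if dropped:
                logger.info(
                    "record %r: dropped %d symbols outside the alphabet",
                    rec.id,
                    dropped,
                )
            seq = "".join(kept)
        elif alphabet_policy == "keep":
            for ch in seq:
                if ch not in symbols:
                    symbols.append(ch)
        else:
            raise AlphabetError(f"unknown alphabet policy {alphabet_policy!r}")
        out.append(SequenceRecord(rec.id, seq, source="fasta"))
    return out, Alphabet(symbols)


def write_fasta(records, path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.identifier, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_text(path, alphabet: Alphabet) -> SequenceRecord:
    """Whole-file plain text over a declared alphabet (newlines stripped)."""
    path = Path(path)
    text = path.read_text().replace("\n", "")
    for i, ch in enumerate(text):
        if ch not in alphabet:
            raise AlphabetError(
                f"symbol {ch!r} at position {i} outside the declared alphabet"
            )
    return SequenceRecord(path.stem, text, source="text")
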