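"""Core sequence record types shared across the pipeline.

A :class:`SeqRecord` is deliberately lighter than Biopython's record: it
carries only what the OTU pipeline needs — an id, a sample tag, the
sequencing technology, the sequence, optional phred qualities, an optional
CCS pass count, and (for merged read pairs) the coordinates of the N
spacer joining the two mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SeqRecord",
    "BarcodeSpec",
    "TECHNOLOGIES",
    "revcomp",
    "iupac_to_regex",
    "DataError",
]

#: Allowed values for :attr:`SeqRecord.technology`.
TECHNOLOGIES = frozenset({"short_merged", "ccs", "reference", "amplicon"})

_IUPAC = set("ACGTURYSWKMBDHVN-")  # "-" admits aligned-FASTA rows

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn-",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn-",
)

#: IUPAC degeneracy expansions used for primer matching.
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class DataError(ValueError):
    """Raised for malformed or inconsistent sequence data."""


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(primer: str) -> str:
    """Translate an IUPAC-degenerate primer into a regex character-class pattern."""
    parts = []
    for base in primer.upper():
        exp = IUPAC_EXPAND.get(base)
        if exp is None:
            raise DataError(f"non-IUPAC symbol {base!r} in primer {primer!r}")
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


@dataclass
class SeqRecord:
    """One read or reference sequence.

    Parameters
    ----------
    id
        Unique identifier within a dataset.
    seq
        IUPAC DNA string, may contain N.  Non-empty.
    sample_id
        Sample of origin; empty string when unknown/unassigned.
    technology
        One of ``short_merged``, ``ccs``, ``reference``, ``amplicon``.
    quals
        Optional per-base phred scores (offset-33 convention, 0..93).
    passes
        Number of polymerase passes for CCS reads (>= 1).
    spacer
        Half-open ``(start, stop)`` interval of an N spacer inserted by
        read-pair merging, if any.  Downstream per-base statistics can
        exclude this interval; the distance stage removes it entirely.
    """

    id: str
    seq: str
    sample_id: str = ""
    technology: str = "reference"
    quals: Optional[list[int]] = None
    passes: Optional[int] = None
    spacer: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise DataError(f"record {self.id!r}: empty sequence")
        if self.technology not in TECHNOLOGIES:
            raise DataError(
                f"record {self.id!r}: unknown technology {self.technology!r}"
            )
        bad = set(self.seq.upper()) - _IUPAC
        if bad:
            raise DataError(
                f"record {self.id!r}: non-IUPAC symbols {sorted(bad)} in sequence"
            )
        if self.quals is not None:
            if len(self.quals) != len(self.seq):
                raise DataError(
                    f"record {self.id!r}: {len(self.quals)} qualities for "
                    f"{len(self.seq)} bases"
                )
            if any(q < 0 or q > 93 for q in self.quals):
                raise DataError(
                    f"record {self.id!r}: phred values outside 0..93 "
                    "(only offset-33 input is supported)"
                )
        if self.passes is not None and self.passes < 1:
            raise DataError(f"record {self.id!r}: passes must be >= 1")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        quals = None if self.quals is None else self.quals[::-1]
        spacer = None
        if self.spacer is not None:
            n = len(self.seq)
            spacer = (n - self.spacer[1], n - self.spacer[0])
        return replace(self, seq=revcomp(self.seq), quals=quals, spacer=spacer)

    def without_spacer(self) -> "SeqRecord":
        """Copy with the recorded N spacer (if any) removed from seq and quals."""
        if self.spacer is None:
            return self
        a, b = self.spacer
        seq = self.seq[:a] + self.seq[b:]
        quals = None if self.quals is None else self.quals[:a] + self.quals[b:]
        return replace(self, seq=seq, quals=quals, spacer=None)


@dataclass(frozen=True)
class BarcodeSpec:
    """A sample barcode, optionally followed by an (IUPAC-degenerate) primer."""

    barcode: str
    sample_id: str
    primer: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.barcode:
            raise DataError("empty barcode")
        bad = set(self.barcode.upper()) - set("ACGT")
        if bad:
            raise DataError(f"barcode {self.barcode!r} must be plain ACGT")
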