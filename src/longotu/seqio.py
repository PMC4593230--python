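"""FASTA/FASTQ I/O and amplicon read preprocessing.

Covers the preprocessing applied to amplicon sequencing runs before
distance computation: merging of read pairs into a single spacer-joined
sequence, quality-fraction filtering, amplicon size filtering, exact-match
barcode demultiplexing and seeded shuffling.

FASTQ is read and written in strict 4-line form with Sanger (offset-33)
qualities; parse failures report the offending line number.  FASTA goes
through Bio.SeqIO (wrapped output).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .records import BarcodeSpec, DataError, SeqRecord, iupac_to_regex, revcomp

__all__ = [
    "ParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_barcode_table",
    "merge_pairs",
    "quality_fraction_filter",
    "length_filter",
    "demultiplex",
    "shuffle_records",
    "subsample_records",
    "score_table_filter",
]

PHRED_OFFSET = 33


class ParseError(DataError):
    """Malformed FASTQ/FASTA input; message names the offending line."""


def read_fastq(path: str | Path, technology: str = "ccs") -> list[SeqRecord]:
    """Read a 4-line FASTQ file into :class:`SeqRecord` objects.

    Qualities are decoded with the Sanger offset-33 convention.  A pass
    count annotated in the header as ``passes=<n>`` (as written by the
    simulator) is picked up, as is ``sample=<s>``.
    """
    records: list[SeqRecord] = []
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"{path}: truncated FASTQ record starting at line {4 * (len(lines) // 4) + 1}"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise ParseError(f"{path}: line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {i + 3}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}: line {i + 4}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        fields = header[1:].split()
        rid = fields[0]
        passes = None
        sample = ""
        for tok in fields[1:]:
            if tok.startswith("passes="):
                passes = int(tok[7:])
            elif tok.startswith("sample="):
                sample = tok[7:]
        quals = [ord(c) - PHRED_OFFSET for c in qual]
        if any(q < 0 or q > 93 for q in quals):
            raise ParseError(
                f"{path}: line {i + 4}: quality characters outside the "
                "offset-33 range (offset-64 input is not supported)"
            )
        try:
            records.append(
                SeqRecord(
                    id=rid, seq=seq, sample_id=sample, technology=technology,
                    quals=quals, passes=passes,
                )
            )
        except DataError as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as 4-line FASTQ; missing qualities are written as Q40."""
    with open(path, "w") as fh:
        for rec in records:
            tags = []
            if rec.sample_id:
                tags.append(f"sample={rec.sample_id}")
            if rec.passes is not None:
                tags.append(f"passes={rec.passes}")
            header = "@" + " ".join([rec.id] + tags)
            quals = rec.quals if rec.quals is not None else [40] * len(rec.seq)
            qstr = "".join(chr(q + PHRED_OFFSET) for q in quals)
            fh.write(f"{header}\n{rec.seq}\n+\n{qstr}\n")


def read_fasta(path: str | Path, technology: str = "reference") -> list[SeqRecord]:
    """Read (possibly wrapped or aligned) FASTA into :class:`SeqRecord` objects."""
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        sample = ""
        for tok in rec.description.split()[1:]:
            if tok.startswith("sample="):
                sample = tok[7:]
        records.append(
            SeqRecord(id=rec.id, seq=str(rec.seq).upper(),
                      sample_id=sample, technology=technology)
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 70) -> None:
    bio = []
    for rec in records:
        desc = f"sample={rec.sample_id}" if rec.sample_id else ""
        bio.append(_BioRecord(Seq(rec.seq), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def read_barcode_table(path: str | Path) -> list[BarcodeSpec]:
    """Read a TSV barcode table with columns sample_id, barcode[, primer]."""
    specs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {ln}: need sample_id<TAB>barcode")
            primer = parts[2] if len(parts) > 2 and parts[2] else None
            specs.append(BarcodeSpec(barcode=parts[1].upper(),
                                     sample_id=parts[0], primer=primer))
    return specs


def merge_pairs(
    r1: SeqRecord,
    r2: SeqRecord,
    trim_tail: int = 0,
    spacer_len: int = 10,
) -> SeqRecord:
    """Join a read pair into one spacer-separated sequence.

    The last ``trim_tail`` bases of the second read are discarded, the
    remainder is reverse-complemented and appended to the first read after
    a run of ``spacer_len`` N characters.  Spacer positions get quality 0
    and the spacer interval is recorded on the result so later per-base
    statistics can exclude it.
    """
    if len(r2.seq) <= trim_tail:
        raise DataError(
            f"read {r2.id!r}: length {len(r2.seq)} <= trim_tail {trim_tail}"
        )
    tail = r2.seq[: len(r2.seq) - trim_tail] if trim_tail else r2.seq
    merged_seq = r1.seq + "N" * spacer_len + revcomp(tail)
    q1 = r1.quals if r1.quals is not None else [40] * len(r1.seq)
    q2 = r2.quals if r2.quals is not None else [40] * len(r2.seq)
    q2 = q2[: len(tail)][::-1]
    quals = q1 + [0] * spacer_len + q2
    spacer = (len(r1.seq), len(r1.seq) + spacer_len) if spacer_len else None
    return SeqRecord(
        id=r1.id, seq=merged_seq, sample_id=r1.sample_id,
        technology="short_merged", quals=quals, spacer=spacer,
    )


def quality_fraction_filter(
    rec: SeqRecord,
    min_q: int,
    min_fraction: float,
    strict: bool = False,
    exclude_spacer: bool = True,
) -> bool:
    """True iff enough of the read meets the per-base quality threshold.

    ``strict`` selects the comparison: q > min_q (long-read convention,
    e.g. ">Q30 across 90 %") versus q >= min_q (short-read convention,
    "Q>=30 over 97 %").  With ``exclude_spacer`` the recorded merge spacer
    does not count toward either the numerator or the denominator.
    """
    if rec.quals is None:
        raise DataError(f"record {rec.id!r}: quality filter needs qualities")
    quals = rec.quals
    if exclude_spacer and rec.spacer is not None:
        a, b = rec.spacer
        quals = quals[:a] + quals[b:]
    if not quals:
        raise DataError(f"record {rec.id!r}: no positions left to assess")
    q = np.asarray(quals)
    good = (q > min_q) if strict else (q >= min_q)
    return bool(good.mean() >= min_fraction)


def length_filter(rec: SeqRecord, expected_len: int, tolerance: int = 100) -> bool:
    """True iff the read length is within ±tolerance of the expected amplicon size."""
    if expected_len <= 0:
        raise DataError("expected_len must be positive")
    return abs(len(rec.seq) - expected_len) <= tolerance


def demultiplex(
    records: Iterable[SeqRecord],
    specs: Sequence[BarcodeSpec],
) -> tuple[dict[str, list[SeqRecord]], list[SeqRecord]]:
    """Assign records to samples by exact 5'-anchored barcode match.

    Zero mismatches are allowed in the barcode.  When a spec carries a
    primer, the primer is matched (IUPAC-degenerate) immediately after
    the barcode and stripped along with it; a read whose barcode matches
    but whose primer does not is still assigned (primer left in place).
    Returns (assigned-by-sample, unassigned).
    """
    specs = list(specs)
    barcodes = [s.barcode for s in specs]
    if len(set(barcodes)) != len(barcodes):
        raise DataError("duplicate barcodes in demultiplexing table")
    if len(set(len(b) for b in barcodes)) > 1:
        raise DataError("all barcodes must have the same length")
    by_barcode = {s.barcode: s for s in specs}
    primer_re = {
        s.barcode: re.compile(iupac_to_regex(s.primer)) if s.primer else None
        for s in specs
    }
    blen = len(barcodes[0]) if barcodes else 0
    assigned: dict[str, list[SeqRecord]] = {s.sample_id: [] for s in specs}
    unassigned: list[SeqRecord] = []
    for rec in records:
        spec = by_barcode.get(rec.seq[:blen]) if blen else None
        if spec is None:
            unassigned.append(rec)
            continue
        cut = blen
        pat = primer_re[spec.barcode]
        if pat is not None:
            m = pat.match(rec.seq, blen)
            if m:
                cut = m.end()
        quals = rec.quals[cut:] if rec.quals is not None else None
        assigned[spec.sample_id].append(
            SeqRecord(
                id=rec.id, seq=rec.seq[cut:], sample_id=spec.sample_id,
                technology=rec.technology, quals=quals, passes=rec.passes,
            )
        )
    return assigned, unassigned


def shuffle_records(records: Sequence[SeqRecord], seed: int) -> list[SeqRecord]:
    """Seeded random permutation (clustering must not depend on input order)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def score_table_filter(
    records: Sequence[SeqRecord],
    scores: dict[str, float],
    threshold: float,
    keep_below: bool = True,
) -> list[SeqRecord]:
    """Filter reads by an externally computed per-read score table.

    Hook for chimera callers and similar external screens: the caller
    supplies scores (e.g. chimera scores) keyed by read id, and reads
    strictly on the wrong side of ``threshold`` are removed
    (``keep_below`` keeps scores <= threshold).  A read missing from the
    table is an error, not a silent pass.
    """
    missing = [r.id for r in records if r.id not in scores]
    if missing:
        raise DataError(f"{len(missing)} reads missing from score table "
                        f"(first: {missing[0]!r})")
    if keep_below:
        return [r for r in records if scores[r.id] <= threshold]
    return [r for r in records if scores[r.id] >= threshold]


def subsample_records(
    records: Sequence[SeqRecord], k: int, seed: int
) -> list[SeqRecord]:
    """Seeded sample of ``k`` records without replacement, input order kept.

    Building block for depth-matched comparisons (e.g. sub-sampling short
    reads to a long-read count, or drawing equal-size bins of CCS reads
    grouped by pass count before clustering each bin separately).
    """
    if k > len(records):
        raise DataError(f"cannot sample {k} from {len(records)} records")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(records), size=k, replace=False)
    return [records[i] for i in sorted(pick)]
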