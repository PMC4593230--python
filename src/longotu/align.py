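"""Pairwise-alignment genetic distances for OTU inference.

The distance between two amplicon reads is computed from an optimal
global (Needleman-Wunsch) alignment with affine gap costs, followed by
two post-processing steps tailored to circular-consensus (CCS) long
reads, whose dominant error mode is the single-base indel:

1. terminal alignment gaps are stripped (they reflect length differences
   of the sequenced fragments, not biology);
2. internal gap runs of length exactly one are deleted from both rows,
   so isolated single-base indels do not contribute to the distance.

The genetic distance is then ``(mismatches + indel_events) /
examined_columns``: each surviving multi-base gap run counts once as an
event and, by default, its columns are collapsed to a single examined
column, making a k-base indel and a single substitution equally
weighted.  Columns containing N in either row are excluded from both the
numerator and denominator.  The resulting dissimilarities lie in [0, 1]
and feed the hierarchical clustering stage.

An alternative distance computed from a multiple sequence alignment
(:func:`msa_distance`) is also provided: the fraction of differing sites
among mutually ungapped, non-N columns for each pair of rows.
"""

from __future__ import annotations

import itertools
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix

from ._nwkernel import gotoh_align
from .records import DataError, SeqRecord

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "nw_align",
    "strip_terminal_gaps",
    "remove_single_base_indels",
    "genetic_distance",
    "pair_distance",
    "distance_matrix",
    "msa_distance",
    "orient",
    "write_distance_tsv",
    "read_distance_tsv",
]

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme (EDNAFULL-style defaults: +5/-4, gap 10/0.5).

    A gap run of length k is penalized ``gap_open + (k - 1) * gap_extend``.
    ``collapse_gap_runs`` selects the denominator convention of the genetic
    distance: collapsed (default; a surviving gap run occupies one examined
    column) or full run length.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    collapse_gap_runs: bool = True


DEFAULT_SCORING = Scoring()


@dataclass
class PairwiseAlignment:
    """Two gapped rows of a pairwise global alignment plus the score."""

    row_a: str
    row_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise DataError("alignment rows differ in length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == "-" and cb == "-":
                raise DataError("alignment column gapped in both rows")

    def __len__(self) -> int:
        return len(self.row_a)

    def counts(self, collapse_gap_runs: bool = True) -> tuple[int, int, int]:
        """(mismatches, indel_events, examined_columns) after N exclusion.

        Columns with N in either row are dropped before gap runs are
        delimited.  With ``collapse_gap_runs`` each gap run contributes a
        single examined column; otherwise its full length counts.
        """
        keep = [
            (ca, cb)
            for ca, cb in zip(self.row_a, self.row_b)
            if ca != "N" and cb != "N"
        ]
        mism = 0
        runs = 0
        run_cols = 0
        in_gap = False
        for ca, cb in keep:
            gap = ca == "-" or cb == "-"
            if gap:
                run_cols += 1
                if not in_gap:
                    runs += 1
                in_gap = True
            else:
                in_gap = False
                if ca != cb:
                    mism += 1
        examined = len(keep)
        if collapse_gap_runs:
            examined -= run_cols - runs
        return mism, runs, examined

    @property
    def mismatches(self) -> int:
        return self.counts()[0]

    @property
    def indel_events(self) -> int:
        return self.counts()[1]

    @property
    def examined_columns(self) -> int:
        return self.counts()[2]


def nw_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
             band: int = -1) -> PairwiseAlignment:
    """Optimal global alignment of two DNA strings under affine-gap scoring.

    Traceback tie-breaking follows a fixed diagonal > up > left priority,
    so the reported alignment is deterministic.  ``band >= 0`` restricts
    the DP to a diagonal band of that half-width beyond the length
    difference (exact whenever the optimal path fits the band, which
    holds for same-locus amplicons; the default is the full matrix).
    """
    if not a or not b:
        raise DataError("cannot align an empty sequence")
    a = a.upper()
    b = b.upper()
    score, path = gotoh_align(
        _encode(a), _encode(b),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        band=band,
    )
    ra: list[str] = []
    rb: list[str] = []
    i = j = 0
    for code in path:
        if code == 0:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif code == 1:
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    return PairwiseAlignment("".join(ra), "".join(rb), float(score))


def strip_terminal_gaps(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Drop leading/trailing columns covered by a terminal gap run in either row."""
    n = len(aln)
    start = 0
    for row in (aln.row_a, aln.row_b):
        k = 0
        while k < n and row[k] == "-":
            k += 1
        start = max(start, k)
    stop = n
    for row in (aln.row_a, aln.row_b):
        k = n
        while k > 0 and row[k - 1] == "-":
            k -= 1
        stop = min(stop, k)
    if start >= stop:
        raise DataError("no aligned overlap after terminal-gap stripping")
    return PairwiseAlignment(aln.row_a[start:stop], aln.row_b[start:stop], aln.score)


def remove_single_base_indels(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Delete columns of internal gap runs of length exactly one.

    Runs of length >= 2 are untouched: they more likely reflect genuine
    indel variation than CCS consensus errors.  Run structure is taken
    from the input alignment in a single pass.
    """
    drop = set()
    for row in (aln.row_a, aln.row_b):
        i = 0
        n = len(row)
        while i < n:
            if row[i] == "-":
                j = i
                while j < n and row[j] == "-":
                    j += 1
                if j - i == 1:
                    drop.add(i)
                i = j
            else:
                i += 1
    if not drop:
        return aln
    ra = "".join(c for k, c in enumerate(aln.row_a) if k not in drop)
    rb = "".join(c for k, c in enumerate(aln.row_b) if k not in drop)
    return PairwiseAlignment(ra, rb, aln.score)


def genetic_distance(aln: PairwiseAlignment, collapse_gap_runs: bool = True) -> float:
    """Distance in [0, 1]: (mismatches + indel events) / examined columns."""
    mism, runs, examined = aln.counts(collapse_gap_runs=collapse_gap_runs)
    if examined == 0:
        raise DataError("zero examined columns; cannot compute distance")
    return min(1.0, (mism + runs) / examined)


def pair_distance(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
                  band: int = -1) -> float:
    """Full pipeline for one pair: align, strip, de-indel, distance."""
    aln = strip_terminal_gaps(nw_align(a, b, scoring, band=band))
    aln = remove_single_base_indels(aln)
    return genetic_distance(aln, collapse_gap_runs=scoring.collapse_gap_runs)


def distance_matrix(
    records: Sequence[SeqRecord],
    scoring: Scoring = DEFAULT_SCORING,
    jobs: int = 1,
    band: int = -1,
) -> DistanceMatrix:
    """All-versus-all genetic distances as a scikit-bio DistanceMatrix.

    Merged-pair spacers are removed before alignment.  The result is
    identical for any ``jobs`` value; with jobs > 1 pairs are computed in
    a thread pool (the alignment kernel releases the GIL).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate record ids in distance computation")
    if len(records) < 2:
        raise DataError("need at least two records")
    seqs = [r.without_spacer().seq for r in records]
    n = len(seqs)
    d = np.zeros((n, n))
    pairs = list(itertools.combinations(range(n), 2))

    def compute(pair):
        i, j = pair
        return i, j, pair_distance(seqs[i], seqs[j], scoring, band=band)

    if jobs > 1:
        with ThreadPoolExecutor(max_workers=jobs) as pool:
            results = list(pool.map(compute, pairs, chunksize=64))
    else:
        results = [compute(p) for p in pairs]
    for i, j, dist in results:
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


def msa_distance(msa: Sequence[SeqRecord]) -> DistanceMatrix:
    """Pairwise distances from a multiple sequence alignment.

    For each pair of rows, the fraction of differing sites among columns
    where both rows carry a plain A/C/G/T base.  (Equivalently the square
    of the square-root distance some toolkits report.)
    """
    ids = [r.id for r in msa]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate record ids in MSA")
    lengths = {len(r.seq) for r in msa}
    if len(lengths) != 1:
        raise DataError("MSA rows have unequal lengths")
    mat = np.vstack([_encode(r.seq.replace("-", "n")) for r in msa])
    valid = mat < 4
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            tot = int(both.sum())
            if tot == 0:
                raise DataError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns"
                )
            diff = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = diff / tot
    return DistanceMatrix(d, ids)


def orient(
    rec: SeqRecord,
    anchors: Sequence[SeqRecord],
    scoring: Scoring = DEFAULT_SCORING,
) -> SeqRecord:
    """Return ``rec`` or its reverse complement, whichever matches the anchor
    panel better (higher best NW score); ties keep the input orientation."""
    if not anchors:
        raise DataError("orientation needs at least one anchor sequence")
    fwd = rec.without_spacer().seq
    rev = rec.reverse_complement().without_spacer().seq
    best_fwd = max(nw_align(fwd, a.seq, scoring).score for a in anchors)
    best_rev = max(nw_align(rev, a.seq, scoring).score for a in anchors)
    if best_rev > best_fwd:
        return rec.reverse_complement()
    return rec


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Write the lower triangle as TSV rows (id_i, id_j, distance)."""
    ids = list(dm.ids)
    with open(path, "w") as fh:
        for i in range(1, len(ids)):
            for j in range(i):
                fh.write(f"{ids[i]}\t{ids[j]}\t{dm[i, j]:.6g}\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Read a lower-triangular (id_i, id_j, distance) TSV back into a matrix."""
    entries: dict[tuple[str, str], float] = {}
    order: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            a, b, v = line.rstrip("\n").split("\t")
            entries[(a, b)] = float(v)
            for x in (b, a):
                if x not in seen:
                    seen.add(x)
                    order.append(x)
    n = len(order)
    idx = {x: k for k, x in enumerate(order)}
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
    return DistanceMatrix(d, order)
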