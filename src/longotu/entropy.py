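"""Shannon-entropy profiling of aligned 16S sequences.

Per-position Shannon entropy H_i = -sum_a f_ai * log2(f_ai), with a
ranging over the four bases, computed on a multiple sequence alignment
projected onto a reference row and averaged in non-overlapping windows.
Entropy peaks along the 16S gene mark the hypervariable regions that
carry the taxonomic signal; profiling reads this way shows how many of
those regions an amplicon actually covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import DataError, SeqRecord

__all__ = [
    "project_to_reference",
    "column_entropies",
    "column_entropy",
    "window_entropy",
    "entropy_profile",
]

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def project_to_reference(
    msa: Sequence[SeqRecord], reference_row_id: str
) -> np.ndarray:
    """Alignment columns on reference coordinates, as a uint8 matrix.

    Columns where the reference row carries a gap (insertions relative
    to the reference) are dropped; the remaining columns are indexed
    1..reference_length.  Bases are encoded 0-3, anything else
    (gap, N, ambiguity) as 4.
    """
    rows = {r.id: r.seq for r in msa}
    if reference_row_id not in rows:
        raise DataError(f"reference row {reference_row_id!r} absent from MSA")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise DataError("MSA rows have unequal lengths")
    mat = np.vstack(
        [_ENC[np.frombuffer(r.seq.encode(), dtype=np.uint8)] for r in msa]
    )
    ref = np.frombuffer(rows[reference_row_id].encode(), dtype=np.uint8)
    keep = ref != ord("-")
    return mat[:, keep]


def column_entropies(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Shannon entropy in bits, plus a low-coverage flag.

    Frequencies are computed over A/C/G/T occurrences only; gaps and N
    are excluded and the frequencies renormalized (0 log 0 = 0).  A
    column with no A/C/G/T at all gets H = 0 and its flag set.
    """
    counts = np.stack([(mat == k).sum(axis=0) for k in range(4)]).astype(float)
    totals = counts.sum(axis=0)
    empty = totals == 0
    safe = np.where(empty, 1.0, totals)
    f = counts / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    h = -terms.sum(axis=0)
    h[empty] = 0.0
    return h, empty


def column_entropy(column: Sequence[str] | str) -> float:
    """Shannon entropy (bits) of one alignment column of symbols."""
    arr = _ENC[np.frombuffer("".join(column).encode(), dtype=np.uint8)]
    h, _ = column_entropies(arr.reshape(-1, 1))
    return float(h[0])


def window_entropy(h: np.ndarray, window: int = 10) -> pd.DataFrame:
    """Average per-position entropy in consecutive non-overlapping windows.

    Returns a frame with 1-based ``window_start`` and ``mean_entropy``.
    A trailing partial window is dropped so all windows average the same
    number of positions.
    """
    if window < 1:
        raise DataError("window must be >= 1")
    h = np.asarray(h, dtype=float)
    n_win = len(h) // window
    if n_win == 0:
        return pd.DataFrame({"window_start": [], "mean_entropy": []})
    means = h[: n_win * window].reshape(n_win, window).mean(axis=1)
    starts = np.arange(n_win) * window + 1
    return pd.DataFrame({"window_start": starts, "mean_entropy": means})


def entropy_profile(
    msa: Sequence[SeqRecord], reference_row_id: str, window: int = 10
) -> pd.DataFrame:
    """Windowed entropy profile of an MSA on reference coordinates."""
    mat = project_to_reference(msa, reference_row_id)
    h, _ = column_entropies(mat)
    return window_entropy(h, window=window)
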