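"""Synthetic 16S-like data: reference databases, mock communities, reads.

The generator reproduces the statistical shape of a curated full-length
16S database — a two-level divergence hierarchy (genera at ~10 %
divergence, genomes within a genus at ~3 %) — so that OTU thresholds of
1-6 % dissimilarity are meaningful, without requiring any download.

Two read simulators are provided:

* ``ccs`` — circular-consensus long reads: per-read accuracy drawn from
  a truncated Normal(0.99, 0.01), errors apportioned
  mismatch:insertion:deletion = 6:21:73 (single-base indels dominate CCS
  consensus error) and placed uniformly along the read;
* ``short_paired`` — paired-end short reads from the two amplicon ends
  with a substitution rate rising from 0.1 % at the 5' end to 1 % at the
  3' end of each mate, merged into one sequence with an N spacer.

Every simulated read is recorded in a truth map (read id -> genome id),
the ground truth for clustering evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import DataError, SeqRecord, iupac_to_regex, revcomp
from .seqio import merge_pairs, shuffle_records

__all__ = [
    "ErrorModel",
    "AmpliconSpec",
    "MockCommunity",
    "BenchmarkConfig",
    "synth_reference_db",
    "filter_reference_db",
    "build_mocks",
    "extract_amplicon",
    "find_primer_product",
    "sim_ccs_reads",
    "sim_short_reads",
    "downsample_per_genome",
    "simulate_community_reads",
    "run_benchmark",
    "TECHNOLOGY_PRESETS",
    "COMPLEXITY_SIZES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

#: Genomes per mock community at each complexity level.
COMPLEXITY_SIZES = {"low": 100, "medium": 250, "high": 500}

#: Amplicon alignment intervals (1-based inclusive) and read setup per
#: simulated technology: V4 for 2x150, V3-V4 for 2x250 and 450 bp CCS,
#: V1-V4 for 750 bp CCS, V1-V6 for 1450 bp CCS.
TECHNOLOGY_PRESETS = {
    "miseq_2x150": {"kind": "short_paired", "interval": (389, 801), "read_len": 150},
    "miseq_2x250": {"kind": "short_paired", "interval": (227, 801), "read_len": 250},
    "ccs_450": {"kind": "ccs", "interval": (227, 801)},
    "ccs_750": {"kind": "ccs", "interval": (4, 801)},
    "ccs_1450": {"kind": "ccs", "interval": (4, 1506)},
}


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error parameters for one of the two simulators."""

    kind: str = "ccs"  # "ccs" or "short_paired"
    accuracy_mean: float = 0.99
    accuracy_sd: float = 0.01
    diff_ratio: tuple[float, float, float] = (6.0, 21.0, 73.0)  # mm:ins:del
    read_len: int = 150
    sub_rate_start: float = 0.001
    sub_rate_end: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("ccs", "short_paired"):
            raise DataError(f"unknown error-model kind {self.kind!r}")
        if any(x <= 0 for x in self.diff_ratio):
            raise DataError("diff_ratio entries must be positive")

    @property
    def diff_probs(self) -> np.ndarray:
        r = np.asarray(self.diff_ratio, dtype=float)
        return r / r.sum()


@dataclass(frozen=True)
class AmpliconSpec:
    """Where an amplicon sits: alignment interval XOR primer pair."""

    interval: Optional[tuple[int, int]] = None  # 1-based inclusive
    primers: Optional[tuple[str, str]] = None  # forward, reverse (IUPAC)
    expected_len: int = 0

    def __post_init__(self) -> None:
        if (self.interval is None) == (self.primers is None):
            raise DataError("set exactly one of interval or primers")


@dataclass
class MockCommunity:
    """Reference genomes plus the read-level ground truth built on top."""

    community_id: str
    genomes: list[SeqRecord]
    complexity: str
    truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate genome ids in mock community")


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = arr.copy()
    hit = np.flatnonzero(rng.random(arr.shape[0]) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def synth_reference_db(
    n_genera: int,
    genomes_per_genus: int,
    genus_divergence: float = 0.10,
    within_genus_divergence: float = 0.03,
    length: int = 1550,
    seed: int = 0,
) -> list[SeqRecord]:
    """Evolve a 16S-like reference database with a genus/species hierarchy.

    A random root sequence is mutated into ``n_genera`` genus ancestors
    (substitution probability ``genus_divergence`` per site), each of
    which yields ``genomes_per_genus`` genomes at
    ``within_genus_divergence``.  Ids encode the genus: ``g003_s007``.
    """
    for name, div in (("genus_divergence", genus_divergence),
                      ("within_genus_divergence", within_genus_divergence)):
        if not (0 < div < 0.5):
            raise DataError(f"{name} must lie in (0, 0.5), got {div}")
    if length <= 1400:
        raise DataError("reference length must exceed 1400 bp")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=length, dtype=np.uint8)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for g in range(n_genera):
        ancestor = _mutate(root, genus_divergence, rng)
        for s in range(genomes_per_genus):
            leaf = _mutate(ancestor, within_genus_divergence, rng)
            seq = _decode(leaf)
            if seq in seen:
                raise DataError(
                    "duplicate genome generated; increase divergence or length"
                )
            seen.add(seq)
            records.append(
                SeqRecord(id=f"g{g:03d}_s{s:03d}", seq=seq, technology="reference")
            )
    return records


def filter_reference_db(
    records: Sequence[SeqRecord], seed: int = 0
) -> list[SeqRecord]:
    """Database hygiene: unique sequences >1400 bp; genera capped at 100.

    Exact duplicate sequences are removed (first occurrence kept), short
    entries dropped, and any genus with more than 1000 genomes is
    down-sampled to 100 (seeded).  The genus is the id prefix before the
    first underscore.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    kept: list[SeqRecord] = []
    for rec in records:
        if len(rec.seq) <= 1400 or rec.seq in seen:
            continue
        seen.add(rec.seq)
        kept.append(rec)
    by_genus: dict[str, list[SeqRecord]] = {}
    for rec in kept:
        by_genus.setdefault(rec.id.split("_")[0], []).append(rec)
    out: list[SeqRecord] = []
    for genus in by_genus:
        members = by_genus[genus]
        if len(members) > 1000:
            pick = rng.choice(len(members), size=100, replace=False)
            members = [members[i] for i in sorted(pick)]
        out.extend(members)
    return out


def build_mocks(
    db: Sequence[SeqRecord],
    complexity: str | int,
    n_replicates: int = 10,
    seed: int = 0,
) -> list[MockCommunity]:
    """Sample mock communities of known genomes from the reference database.

    ``complexity`` is "low"/"medium"/"high" (100/250/500 genomes) or an
    explicit genome count for scaled-down runs.  Genomes are drawn
    without replacement within each community.
    """
    if isinstance(complexity, str):
        if complexity not in COMPLEXITY_SIZES:
            raise DataError(f"unknown complexity {complexity!r}")
        n_genomes = COMPLEXITY_SIZES[complexity]
        label = complexity
    else:
        n_genomes = int(complexity)
        label = f"n{n_genomes}"
    if n_genomes > len(db):
        raise DataError(
            f"database of {len(db)} genomes too small for {n_genomes}-genome mocks"
        )
    rng = np.random.default_rng(seed)
    mocks = []
    for r in range(n_replicates):
        pick = rng.choice(len(db), size=n_genomes, replace=False)
        genomes = [db[i] for i in sorted(pick)]
        mocks.append(
            MockCommunity(community_id=f"{label}_rep{r:02d}",
                          genomes=genomes, complexity=label)
        )
    return mocks


def find_primer_product(seq: str, fwd: str, rev: str) -> Optional[str]:
    """Locate the outermost product of an IUPAC primer pair; plus-strand output.

    The forward primer is matched on the given strand and the reverse
    primer as its reverse complement downstream.  If no product is found,
    the minus strand is scanned and a hit is reported in plus-strand
    coordinates of the amplified region.
    """
    fwd_re = re.compile(iupac_to_regex(fwd))
    rev_re = re.compile(iupac_to_regex(revcomp(rev)))

    def scan(s: str) -> Optional[tuple[int, int]]:
        m = fwd_re.search(s)
        if not m:
            return None
        last = None
        for mm in rev_re.finditer(s, m.start()):
            last = mm
        if last is None:
            return None
        return m.start(), last.end()

    hit = scan(seq)
    if hit is not None:
        return seq[hit[0] : hit[1]]
    rc = revcomp(seq)
    hit = scan(rc)
    if hit is not None:
        a, b = hit
        n = len(seq)
        return seq[n - b : n - a]
    return None


def extract_amplicon(genome: SeqRecord, spec: AmpliconSpec) -> SeqRecord:
    """Cut the amplicon out of a reference genome.

    Interval mode slices 1-based inclusive columns of the reference
    alignment row (gaps removed afterwards); primer mode scans both
    strands with IUPAC-degenerate matching and returns the outermost
    product, primers included, on the plus strand.
    """
    if spec.interval is not None:
        start, end = spec.interval
        if start < 1 or end > len(genome.seq) or start > end:
            raise DataError(
                f"interval {start}-{end} outside genome {genome.id!r} "
                f"of length {len(genome.seq)}"
            )
        sub = genome.seq[start - 1 : end].replace("-", "")
    else:
        fwd, rev = spec.primers  # type: ignore[misc]
        found = find_primer_product(genome.seq.replace("-", ""), fwd, rev)
        if found is None:
            raise DataError(
                f"primer pair {fwd}/{rev} not found in genome {genome.id!r}"
            )
        sub = found
    if not sub:
        raise DataError(f"empty amplicon from genome {genome.id!r}")
    return SeqRecord(id=f"{genome.id}_amp", seq=sub, technology="amplicon",
                     sample_id=genome.sample_id)


def _accuracy_to_passes(acc: float) -> int:
    # synthetic monotone accuracy->passes map, solely so pass-binning
    # recipes are exercisable on simulated data
    return int(np.clip(round(3 + (acc - 0.965) * 480), 3, 153))


def sim_ccs_reads(
    amplicon: SeqRecord,
    n: int,
    model: ErrorModel = ErrorModel(kind="ccs"),
    seed: int = 0,
    truth: Optional[dict[str, str]] = None,
    genome_id: Optional[str] = None,
    sample_id: str = "",
    id_prefix: str = "",
    stats: Optional[dict[str, int]] = None,
) -> list[SeqRecord]:
    """Simulate circular-consensus reads of the amplicon.

    Per read an accuracy is drawn from Normal(accuracy_mean, accuracy_sd)
    truncated to (0, 1]; the error count is Binomial(len, 1 - accuracy)
    and errors are split mismatch:insertion:deletion by ``diff_ratio``
    and placed uniformly.  Qualities are flat at the phred equivalent of
    the drawn accuracy; a synthetic pass count is annotated via a
    monotone map of accuracy.  A ``stats`` dict, when given, accumulates
    the applied error counts under keys mismatch/insertion/deletion.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    template = _ENC[np.frombuffer(amplicon.seq.encode(), dtype=np.uint8)]
    if (template > 3).any():
        raise DataError("amplicon must be plain ACGT for simulation")
    L = template.shape[0]
    gid = genome_id or amplicon.id
    probs = model.diff_probs
    reads: list[SeqRecord] = []
    for k in range(n):
        acc = min(float(rng.normal(model.accuracy_mean, model.accuracy_sd)), 1.0)
        acc = max(acc, 1e-6)
        n_err = int(rng.binomial(L, 1.0 - acc))
        arr = template
        if n_err:
            n_err = min(n_err, L - 1)
            pos = rng.choice(L, size=n_err, replace=False)
            kinds = rng.choice(3, size=n_err, p=probs)  # 0 mm, 1 ins, 2 del
            if stats is not None:
                for key, code in (("mismatch", 0), ("insertion", 1),
                                  ("deletion", 2)):
                    stats[key] = stats.get(key, 0) + int((kinds == code).sum())
            arr = template.copy()
            sub_pos = pos[kinds == 0]
            arr[sub_pos] = (arr[sub_pos] + rng.integers(1, 4, size=sub_pos.size)) % 4
            # apply indels right-to-left so earlier positions stay valid
            lst = list(arr)
            indel = sorted(
                [(p, k) for p, k in zip(pos, kinds) if k > 0], reverse=True
            )
            for p, kind in indel:
                if kind == 2:
                    del lst[p]
                else:
                    lst.insert(p, int(rng.integers(0, 4)))
            arr = np.asarray(lst, dtype=np.uint8)
        q = 93 if acc >= 1.0 else int(np.clip(round(-10 * np.log10(1 - acc)), 1, 93))
        rid = f"{id_prefix}{gid}_ccs{k:04d}"
        rec = SeqRecord(
            id=rid, seq=_decode(arr), sample_id=sample_id, technology="ccs",
            quals=[q] * arr.shape[0], passes=_accuracy_to_passes(acc),
        )
        reads.append(rec)
        if truth is not None:
            truth[rid] = gid
    return reads


def sim_short_reads(
    amplicon: SeqRecord,
    read_len: int,
    n: int,
    model: ErrorModel = ErrorModel(kind="short_paired"),
    spacer_len: int = 10,
    seed: int = 0,
    truth: Optional[dict[str, str]] = None,
    genome_id: Optional[str] = None,
    sample_id: str = "",
    id_prefix: str = "",
) -> list[SeqRecord]:
    """Simulate merged paired-end short reads of the amplicon.

    Each mate carries substitutions at a rate rising linearly from
    ``sub_rate_start`` at its 5' end to ``sub_rate_end`` at its 3' end;
    the pair is merged with an N spacer of ``spacer_len``.  Merged length
    is always ``2 * read_len + spacer_len``.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if len(amplicon.seq) <= read_len:
        raise DataError(
            f"amplicon {amplicon.id!r} ({len(amplicon.seq)} bp) shorter than "
            f"read length {read_len}"
        )
    rng = np.random.default_rng(seed)
    seq = amplicon.seq
    gid = genome_id or amplicon.id
    profile = np.linspace(model.sub_rate_start, model.sub_rate_end, read_len)
    quals = np.clip(np.round(-10 * np.log10(profile)), 1, 93).astype(int).tolist()
    t1 = _ENC[np.frombuffer(seq[:read_len].encode(), dtype=np.uint8)]
    t2 = _ENC[np.frombuffer(revcomp(seq[-read_len:]).encode(), dtype=np.uint8)]
    reads: list[SeqRecord] = []
    for k in range(n):
        mates = []
        for t in (t1, t2):
            arr = t.copy()
            hit = np.flatnonzero(rng.random(read_len) < profile)
            if hit.size:
                arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
            mates.append(_decode(arr))
        rid = f"{id_prefix}{gid}_pe{k:04d}"
        r1 = SeqRecord(id=rid, seq=mates[0], sample_id=sample_id,
                       technology="amplicon", quals=quals)
        r2 = SeqRecord(id=rid + "/2", seq=mates[1], sample_id=sample_id,
                       technology="amplicon", quals=quals)
        merged = merge_pairs(r1, r2, trim_tail=0, spacer_len=spacer_len)
        reads.append(merged)
        if truth is not None:
            truth[rid] = gid
    return reads


def downsample_per_genome(
    reads: Sequence[SeqRecord],
    truth: dict[str, str],
    k: int = 20,
    seed: int = 0,
) -> list[SeqRecord]:
    """Keep exactly ``k`` reads per genome (seeded, without replacement)."""
    by_genome: dict[str, list[int]] = {}
    for i, rec in enumerate(reads):
        gid = truth.get(rec.id)
        if gid is None:
            raise DataError(f"read {rec.id!r} missing from truth map")
        by_genome.setdefault(gid, []).append(i)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for gid in sorted(by_genome):
        idx = by_genome[gid]
        if len(idx) < k:
            raise DataError(f"genome {gid!r} has only {len(idx)} reads (< {k})")
        pick = rng.choice(len(idx), size=k, replace=False)
        keep.extend(idx[i] for i in sorted(pick))
    keep.sort()
    return [reads[i] for i in keep]


def simulate_community_reads(
    mock: MockCommunity,
    technology: str,
    reads_per_genome: int = 20,
    model: Optional[ErrorModel] = None,
    seed: int = 0,
) -> list[SeqRecord]:
    """All reads of one technology for one mock community (shuffled).

    Read ids are prefixed with the community id; the truth map of the
    community is extended in place.
    """
    preset = TECHNOLOGY_PRESETS.get(technology)
    if preset is None:
        raise DataError(f"unknown technology {technology!r}")
    spec = AmpliconSpec(interval=preset["interval"])
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    prefix = f"{mock.community_id}_{technology}_"
    for genome in mock.genomes:
        amp = extract_amplicon(genome, spec)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if preset["kind"] == "ccs":
            m = model or ErrorModel(kind="ccs")
            reads.extend(
                sim_ccs_reads(amp, reads_per_genome, m, seed=sub_seed,
                              truth=mock.truth, genome_id=genome.id,
                              sample_id=mock.community_id, id_prefix=prefix)
            )
        else:
            m = model or ErrorModel(kind="short_paired", read_len=preset["read_len"])
            reads.extend(
                sim_short_reads(amp, preset["read_len"], reads_per_genome, m,
                                seed=sub_seed, truth=mock.truth,
                                genome_id=genome.id,
                                sample_id=mock.community_id, id_prefix=prefix)
            )
    return shuffle_records(reads, seed=int(rng.integers(0, 2**31 - 1)))


@dataclass
class BenchmarkConfig:
    """Configuration of the full simulation benchmark."""

    complexities: tuple = ("low", "medium", "high")
    technologies: tuple = tuple(TECHNOLOGY_PRESETS)
    n_replicates: int = 10
    reads_per_genome: int = 20
    seed: int = 0
    db_genera: int = 60
    db_genomes_per_genus: int = 10
    genus_divergence: float = 0.10
    within_genus_divergence: float = 0.03


def run_benchmark(
    config: BenchmarkConfig,
    sink: Optional[Callable[[str, str, str, list[SeqRecord], dict], None]] = None,
) -> pd.DataFrame:
    """Generate every read set of the benchmark and tally read counts.

    For each (complexity, replicate, technology) the shuffled read set
    and the community truth map are passed to ``sink(complexity,
    community_id, technology, reads, truth)`` if given, then discarded,
    so memory stays bounded.  Returns the bookkeeping table with one row
    per read set; total reads per complexity =
    replicates x genomes x reads_per_genome x technologies.
    """
    ss = np.random.SeedSequence(config.seed)
    db_seed, mock_seed, read_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    ]
    need = max(
        COMPLEXITY_SIZES.get(c, 0) if isinstance(c, str) else int(c)
        for c in config.complexities
    )
    n_genera = max(config.db_genera, (need // config.db_genomes_per_genus) + 1)
    db = filter_reference_db(
        synth_reference_db(
            n_genera, config.db_genomes_per_genus,
            config.genus_divergence, config.within_genus_divergence,
            seed=db_seed,
        )
    )
    rng = np.random.default_rng(read_seed)
    rows = []
    for ci, complexity in enumerate(config.complexities):
        mocks = build_mocks(db, complexity, config.n_replicates,
                            seed=mock_seed + ci)
        for mock in mocks:
            for tech in config.technologies:
                reads = simulate_community_reads(
                    mock, tech, config.reads_per_genome,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                if sink is not None:
                    sink(str(complexity), mock.community_id, tech, reads,
                         dict(mock.truth))
                rows.append(
                    {
                        "complexity": str(complexity),
                        "community_id": mock.community_id,
                        "technology": tech,
                        "n_genomes": len(mock.genomes),
                        "n_reads": len(reads),
                    }
                )
    return pd.DataFrame(rows)
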