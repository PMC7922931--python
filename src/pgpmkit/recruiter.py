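"""Fragment recruitment: q-gram filtered, ungapped read-to-genome alignment.

A metagenome read is "recruited" to a reference genome when some full-length,
ungapped placement of the read (on either strand) matches the genome at an
identity strictly above the configured threshold (default 0.97, i.e. >97%).
Candidate placements are pre-filtered with the q-gram lemma: two length-``n``
strings with at most ``k`` mismatches share at least ``n - q + 1 - k*q``
length-``q`` substrings at corresponding positions, so genome diagonals
sharing fewer q-grams with the read cannot yield a hit and are skipped before
any base-level comparison.  With ``k = floor((1 - t) * n)`` mismatches
tolerated at threshold ``t``, the filter is lossless: every window with
identity > ``t`` survives it.

Alignment is ungapped and full-read-length by design: ``align_len`` equals the
read length, ``identity = matches / align_len``, and any position involving an
``N`` (in read or genome) counts as a mismatch.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Genome, Read

__all__ = [
    "RecruitmentParams",
    "RecruitmentHit",
    "QGramIndex",
    "build_qgram_index",
    "recruit_read",
    "recruit_sample",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)  # everything non-ACGT behaves like N
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T/N (case-insensitive) as uint8 codes 0..4."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


@dataclass(frozen=True)
class RecruitmentParams:
    identity_threshold: float = 0.97
    q: int = 11
    max_reads: int | None = 10_000_000
    min_align_len: int = 30
    strands: str = "both"  # "forward" | "both"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.q < 4:
            raise ValueError("q must be >= 4")
        if self.min_align_len < self.q:
            raise ValueError("min_align_len must be >= q")
        if self.strands not in {"forward", "both"}:
            raise ValueError("strands must be 'forward' or 'both'")
        if self.max_reads is not None and self.max_reads <= 0:
            raise ValueError("max_reads must be positive")


@dataclass(frozen=True)
class RecruitmentHit:
    """One read placed ungapped at one genome locus, above threshold."""

    read_id: str
    genome_id: str
    start: int  # 0-based, forward strand
    end: int  # exclusive
    strand: str  # '+' or '-'
    matches: int
    align_len: int

    @property
    def identity(self) -> float:
        return self.matches / self.align_len


class QGramIndex:
    """Positional q-gram index of one genome.

    Maps every length-``q`` window free of ``N`` to the sorted array of its
    0-based start offsets.  Keys are base-4 integer codes of the window.
    """

    def __init__(self, genome: Genome, q: int):
        if genome.length < q:
            raise ValueError(
                f"genome {genome.id!r} (length {genome.length}) is shorter than q={q}"
            )
        self.genome_id = genome.id
        self.q = q
        self.codes = encode(genome.sequence)
        self.index: dict[int, np.ndarray] = _build_positional_index(self.codes, q)

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.index.values())

    def positions(self, qgram: str) -> np.ndarray:
        codes = encode(qgram)
        if len(codes) != self.q or (codes == 4).any():
            return np.empty(0, dtype=np.int64)
        return self.index.get(_pack(codes), np.empty(0, dtype=np.int64))


def _pack(codes: np.ndarray) -> int:
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def _rolling_codes(codes: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 packed codes for all length-q windows, plus an N-free mask."""
    n = len(codes)
    n_windows = n - q + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    is_n = codes == 4
    # windows containing any N are invalid
    valid = ~(np.convolve(is_n.astype(np.int32), np.ones(q, dtype=np.int32))[q - 1 : n] > 0)
    clean = np.where(is_n, 0, codes).astype(np.int64)
    packed = np.zeros(n_windows, dtype=np.int64)
    for off in range(q):
        packed = (packed << 2) | clean[off : off + n_windows]
    return packed, valid


def _build_positional_index(codes: np.ndarray, q: int) -> dict[int, np.ndarray]:
    packed, valid = _rolling_codes(codes, q)
    positions = np.nonzero(valid)[0]
    keys = packed[positions]
    order = np.argsort(keys, kind="stable")
    keys, positions = keys[order], positions[order]
    index: dict[int, np.ndarray] = {}
    if len(keys):
        bounds = np.nonzero(np.diff(keys))[0] + 1
        for chunk_keys, chunk_pos in zip(
            np.split(keys, bounds), np.split(positions, bounds)
        ):
            index[int(chunk_keys[0])] = chunk_pos
    return index


def build_qgram_index(genome: Genome, q: int = 11) -> QGramIndex:
    """Build the positional q-gram index of ``genome`` (N windows skipped)."""
    return QGramIndex(genome, q)


def min_matches_above(threshold: float, n: int) -> int:
    """Smallest match count with matches/n strictly above ``threshold``.

    ``threshold * n`` is snapped to the nearest integer when within 1e-9 so
    that a decimal threshold like 0.97 behaves exactly: 97 matches in 100 is
    *not* above 97%, 98 is.
    """
    v = threshold * n
    iv = round(v)
    if abs(v - iv) < 1e-9:
        return iv + 1
    return math.ceil(v)


def _candidate_starts(
    read_codes: np.ndarray, index: QGramIndex, min_shared: int
) -> np.ndarray:
    """Genome start offsets whose diagonal shares >= min_shared q-grams."""
    genome_len = len(index.codes)
    n = len(read_codes)
    last_start = genome_len - n
    if last_start < 0:
        return np.empty(0, dtype=np.int64)
    if min_shared <= 0:
        # lemma bound degenerate: every placement is a candidate
        return np.arange(last_start + 1, dtype=np.int64)
    packed, valid = _rolling_codes(read_codes, index.q)
    counts: defaultdict[int, int] = defaultdict(int)
    for i in np.nonzero(valid)[0]:
        hits = index.index.get(int(packed[i]))
        if hits is None:
            continue
        for p in hits:
            counts[int(p) - int(i)] += 1
    starts = [d for d, c in counts.items() if c >= min_shared and 0 <= d <= last_start]
    return np.array(sorted(starts), dtype=np.int64)


def _score_placements(
    read_codes: np.ndarray, genome_codes: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    """Match counts of the read against each candidate genome window."""
    n = len(read_codes)
    read_ok = read_codes != 4
    matches = np.empty(len(starts), dtype=np.int64)
    for j, s in enumerate(starts):
        window = genome_codes[s : s + n]
        matches[j] = np.count_nonzero((window == read_codes) & read_ok)
    return matches


def recruit_read(
    read: Read,
    genome: Genome,
    index: QGramIndex | None = None,
    params: RecruitmentParams = RecruitmentParams(),
) -> list[RecruitmentHit]:
    """All above-threshold ungapped placements of one read on one genome.

    Hits are sorted best identity first (ties: smaller start, then '+' strand).
    Reads shorter than ``params.min_align_len`` yield no hits.
    """
    if index is None:
        index = build_qgram_index(genome, params.q)
    if index.genome_id != genome.id or index.q != params.q:
        raise ValueError("index does not match genome/params")
    n = len(read)
    if n < params.min_align_len:
        return []
    min_matches = min_matches_above(params.identity_threshold, n)
    k = n - min_matches  # max tolerated mismatches; tight, so the filter stays lossless
    min_shared = n - params.q + 1 - k * params.q

    forward = encode(read.sequence)
    searches = [("+", forward)]
    if params.strands == "both":
        searches.append(("-", reverse_complement_codes(forward)))

    hits = []
    for strand, codes in searches:
        starts = _candidate_starts(codes, index, min_shared)
        if not len(starts):
            continue
        matches = _score_placements(codes, index.codes, starts)
        for s, m in zip(starts, matches):
            if m >= min_matches:
                hits.append(
                    RecruitmentHit(
                        read_id=read.id,
                        genome_id=genome.id,
                        start=int(s),
                        end=int(s) + n,
                        strand=strand,
                        matches=int(m),
                        align_len=n,
                    )
                )
    hits.sort(key=lambda h: (-h.identity, h.start, h.strand))
    return hits


@dataclass
class SampleRecruitment:
    """Per-genome best hits for one read set, with stream counters."""

    hits: dict[str, list[RecruitmentHit]]
    n_reads: int = 0
    n_skipped_short: int = 0

    def recruited_count(self, genome_id: str) -> int:
        return len(self.hits.get(genome_id, []))


def recruit_sample(
    reads,
    genomes,
    params: RecruitmentParams = RecruitmentParams(),
) -> SampleRecruitment:
    """Recruit a read stream against every genome independently.

    A read may be recruited to several genomes (genomes are treated as
    independent references, as in per-genome recruitment plots); within one
    genome only its best hit is kept (highest identity, ties to the smallest
    start).  At most ``params.max_reads`` reads are consumed, in stream order.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("at least one reference genome is required")
    indexes = {g.id: build_qgram_index(g, params.q) for g in genomes}
    result = SampleRecruitment(hits={g.id: [] for g in genomes})
    for read in reads:
        if params.max_reads is not None and result.n_reads >= params.max_reads:
            break
        result.n_reads += 1
        if len(read) < params.min_align_len:
            result.n_skipped_short += 1
            continue
        for g in genomes:
            read_hits = recruit_read(read, g, indexes[g.id], params)
            if read_hits:
                result.hits[g.id].append(read_hits[0])
    if result.n_reads == 0:
        warnings.warn("empty read stream: no reads were recruited", stacklevel=2)
    logger.info(
        "recruited sample: %d reads (%d skipped short); hits per genome: %s",
        result.n_reads,
        result.n_skipped_short,
        {gid: len(h) for gid, h in result.hits.items()},
    )
    return result
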