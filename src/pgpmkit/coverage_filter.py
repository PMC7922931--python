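"""Coverage-peak removal of recruited reads (single-pass mean + 2·SD rule).

Conserved repetitive elements — 16S rRNA operons above all — attract reads
from many unrelated taxa, piling abnormally many recruited reads onto a few
loci and inflating a genome's apparent abundance.  The remedy applied here is
deliberately simple: count recruited reads per locus (a locus is a read's
0-based alignment start), compute the mean M and standard deviation SD of the
per-locus counts *over covered loci only*, and drop every read sitting at a
locus whose count exceeds M + 2·SD.

The rule is applied in exactly one pass.  It is not idempotent — removing the
peak loci lowers M and SD, so a second application could remove more — and the
pipeline never re-applies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoverageProfile", "LocusMask", "compute_coverage", "locus_mask", "filter_recruited_reads"]

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Per-locus recruited-read counts with their mean and SD.

    ``counts`` holds only covered loci (count >= 1); ``mean`` and ``sd`` are
    computed over the values of ``counts``.  ``sd`` is the population
    (divide-by-n) standard deviation unless the profile was built with
    ``sample_sd=True``.
    """

    genome_id: str
    counts: dict[int, int] = field(default_factory=dict)
    mean: float = 0.0
    sd: float = 0.0

    @property
    def threshold(self) -> float:
        return self.mean + 2.0 * self.sd

    @property
    def n_hits(self) -> int:
        return sum(self.counts.values())


@dataclass
class LocusMask:
    """Qualified/unqualified verdict per covered locus."""

    genome_id: str
    qualified: dict[int, bool]
    threshold: float


def compute_coverage(hits, genome_id: str | None = None, sample_sd: bool = False) -> CoverageProfile:
    """Tally hits per alignment-start locus and summarize the tally.

    All hits must share one ``genome_id`` (inferred from the first hit when
    not given).  An empty hit set yields an empty profile with M = SD = 0.
    """
    hits = list(hits)
    if not hits:
        return CoverageProfile(genome_id=genome_id or "")
    gid = genome_id or hits[0].genome_id
    counts: dict[int, int] = {}
    for h in hits:
        if h.genome_id != gid:
            raise ValueError(f"hit genome {h.genome_id!r} does not match profile genome {gid!r}")
        counts[h.start] = counts.get(h.start, 0) + 1
    values = np.fromiter(counts.values(), dtype=np.int64)
    mean = float(values.mean())
    sd = float(values.std(ddof=1 if sample_sd else 0)) if len(values) > 1 else 0.0
    return CoverageProfile(genome_id=gid, counts=counts, mean=mean, sd=sd)


def locus_mask(profile: CoverageProfile) -> LocusMask:
    """Partition covered loci: a locus is unqualified iff count > M + 2·SD."""
    threshold = profile.threshold
    qualified = {locus: count <= threshold for locus, count in profile.counts.items()}
    return LocusMask(genome_id=profile.genome_id, qualified=qualified, threshold=threshold)


def filter_recruited_reads(hits, profile: CoverageProfile):
    """Keep hits at qualified loci (count <= M + 2·SD); order preserved.

    The profile must have been computed from the same hit set (checked via
    genome id and total count).  Returns the qualified hits ``Q``; the removed
    complement is ``hits`` minus ``Q`` and its size is logged.
    """
    hits = list(hits)
    if not hits:
        return []
    if any(h.genome_id != profile.genome_id for h in hits):
        raise ValueError("hits and coverage profile refer to different genomes")
    if len(hits) != profile.n_hits:
        raise ValueError(
            f"profile covers {profile.n_hits} hits but {len(hits)} were supplied; "
            "compute the profile from the same hit set"
        )
    mask = locus_mask(profile)
    qualified = [h for h in hits if mask.qualified[h.start]]
    logger.info(
        "%s: removed %d/%d reads at %d peak loci (threshold %.3f)",
        profile.genome_id,
        len(hits) - len(qualified),
        len(hits),
        sum(not q for q in mask.qualified.values()),
        mask.threshold,
    )
    return qualified
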