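"""Synthetic inputs: reference genomes, metagenome read sets, compatibility matrices.

The real inputs to the pipeline are public shotgun metagenomes screened
against a panel of plant-growth-promoting reference genomes — terabyte-scale
archives that cannot ship with a package.  This module generates structurally
faithful stand-ins with known ground truth:

* a set of reference genomes mutated from a common ancestor at a controlled
  per-genome substitution rate, each carrying a few copies of one *shared*
  repeat element that mimics conserved rRNA operons — the exact feature that
  produces cross-genome recruitment and coverage peaks;
* per-sample read sets (soil / root / rhizosphere) drawn uniformly from a
  source genome with a per-base substitution rate, mixed with off-target
  reads from an unrelated genome;
* strain-compatibility matrices with a planted clique, for exercising the
  consortium-design layer.

Every generator is a pure function of its seed; truth records carry enough
labels (read origins, repeat intervals, planted members) to score recruitment
sensitivity/specificity and clique recovery without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .consortium import CompatibilityMatrix
from .io_formats import Genome, Read, SampleMeta

__all__ = [
    "SimulationConfig",
    "ReferenceTruth",
    "SampleTruth",
    "generate_references",
    "generate_sample",
    "generate_compatibility",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated study.

    ``pairwise_divergence`` is the per-genome substitution rate relative to
    the common ancestor; two genomes at rate d share an expected identity of
    (1-d)^2 + d^2/3 (independent substitutions, uniform among the three
    alternative bases).  ``read_divergence`` is the per-base substitution
    rate applied to sampled reads, emulating the divergence between
    environmental strains and their database representatives.
    """

    seed: int = 0
    n_genomes: int = 3
    genome_length: int = 20_000
    pairwise_divergence: float = 0.25
    n_reads: int = 2_000
    read_length: int = 100
    read_divergence: float = 0.02
    repeat_length: int = 1_500
    repeat_copies_per_genome: int = 3
    offtarget_fraction: float = 0.1
    environment_layout: tuple[tuple[str, int], ...] = (
        ("soil", 1),
        ("root", 1),
        ("rhizosphere", 1),
    )

    def __post_init__(self) -> None:
        for name in ("pairwise_divergence", "read_divergence", "offtarget_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class ReferenceTruth:
    """Ground truth of a generated reference set."""

    repeat_sequence: str
    repeat_intervals: dict[str, list[tuple[int, int]]]  # genome id -> [start, end)
    backbone_length: int


@dataclass
class SampleTruth:
    """Per-read ground-truth labels of one generated sample."""

    sample_id: str
    source_genome: str
    labels: list[dict] = field(default_factory=list)  # read_id, origin, start, n_subs, repeat

    def on_target_ids(self) -> set[str]:
        return {r["read_id"] for r in self.labels if r["origin"] == "target"}

    def repeat_ids(self) -> set[str]:
        return {r["read_id"] for r in self.labels if r.get("repeat")}


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Substitute each base with probability ``rate`` (always to another base)."""
    if rate <= 0:
        return seq.copy(), 0
    out = seq.copy()
    sites = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in sites:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out, len(sites)


def _to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def generate_references(config: SimulationConfig) -> tuple[list[Genome], ReferenceTruth]:
    """Generate ``n_genomes`` references from a shared ancestor.

    Each genome is the ancestor mutated at ``pairwise_divergence``, with
    ``repeat_copies_per_genome`` copies of one shared repeat element inserted
    at random positions; the truth record lists the resulting repeat
    intervals.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _random_sequence(rng, config.genome_length)
    repeat = _random_sequence(rng, config.repeat_length)
    if config.n_genomes > 1 and config.pairwise_divergence * config.read_length < 1:
        import warnings

        warnings.warn(
            "pairwise_divergence is too low to distinguish genomes at this read length",
            stacklevel=2,
        )
    genomes = []
    intervals: dict[str, list[tuple[int, int]]] = {}
    for g in range(config.n_genomes):
        backbone, _ = _mutate(rng, ancestor, config.pairwise_divergence)
        pieces = []
        ivals = []
        cuts = [
            int(c)
            for c in np.sort(
                rng.integers(0, len(backbone) + 1, size=config.repeat_copies_per_genome)
            )
        ]
        prev = 0
        offset = 0
        for cut in cuts:
            pieces.append(backbone[prev:cut])
            offset += cut - prev
            ivals.append((offset, offset + config.repeat_length))
            pieces.append(repeat)
            offset += config.repeat_length
            prev = cut
        pieces.append(backbone[prev:])
        gid = f"genome_{g:02d}"
        genomes.append(
            Genome(
                id=gid,
                sequence=_to_str(np.concatenate(pieces)) if pieces else _to_str(backbone),
                description=f"synthetic reference {g} (divergence {config.pairwise_divergence})",
            )
        )
        intervals[gid] = ivals
    truth = ReferenceTruth(
        repeat_sequence=_to_str(repeat),
        repeat_intervals=intervals,
        backbone_length=config.genome_length,
    )
    return genomes, truth


def _overlaps(start: int, end: int, intervals) -> bool:
    return any(start < e and s < end for s, e in intervals)


def generate_sample(
    config: SimulationConfig,
    source_genome: Genome,
    truth: ReferenceTruth,
    sample_id: str,
    environment: str = "soil",
    seed: int | None = None,
) -> tuple[list[Read], SampleMeta, SampleTruth]:
    """Generate one read set from ``source_genome`` plus off-target noise.

    On-target reads start uniformly on the genome and receive per-base
    substitutions at ``read_divergence``; ``offtarget_fraction`` of reads come
    from a freshly drawn unrelated random genome.  Reads overlapping a truth
    repeat interval are labeled ``repeat``.  T is the total generated read
    count.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genome_codes = np.frombuffer(source_genome.sequence.encode("ascii"), dtype=np.uint8)
    n_off = int(round(config.offtarget_fraction * config.n_reads))
    n_on = config.n_reads - n_off
    decoy = _random_sequence(rng, max(config.genome_length, config.read_length))
    reads: list[Read] = []
    labels: list[dict] = []
    repeat_ivals = truth.repeat_intervals.get(source_genome.id, [])
    max_start = len(genome_codes) - config.read_length
    for i in range(n_on):
        start = int(rng.integers(0, max_start + 1))
        window = genome_codes[start : start + config.read_length]
        mutated, n_subs = _mutate(rng, window, config.read_divergence)
        rid = f"{sample_id}_r{i:06d}"
        reads.append(Read(id=rid, sequence=_to_str(mutated), quality="I" * config.read_length))
        labels.append(
            {
                "read_id": rid,
                "origin": "target",
                "start": start,
                "n_subs": n_subs,
                "repeat": _overlaps(start, start + config.read_length, repeat_ivals),
            }
        )
    for i in range(n_off):
        start = int(rng.integers(0, len(decoy) - config.read_length + 1))
        rid = f"{sample_id}_o{i:06d}"
        reads.append(
            Read(
                id=rid,
                sequence=_to_str(decoy[start : start + config.read_length]),
                quality="I" * config.read_length,
            )
        )
        labels.append(
            {"read_id": rid, "origin": "offtarget", "start": start, "n_subs": 0, "repeat": False}
        )
    meta = SampleMeta(sample_id=sample_id, environment=environment, total_reads=len(reads))
    return reads, meta, SampleTruth(sample_id=sample_id, source_genome=source_genome.id, labels=labels)


def generate_compatibility(
    n_strains: int,
    planted_clique_size: int,
    edge_density: float = 0.3,
    nc_rate: float = 0.1,
    seed: int = 0,
) -> tuple[CompatibilityMatrix, list[str]]:
    """Random compatibility matrix with a planted all-``+`` clique.

    Pairs outside the planted clique are ``+`` with probability
    ``edge_density``; the remaining mass is ``nc`` with probability
    ``nc_rate`` and ``-`` otherwise.  Returns the matrix and the planted
    member list (the truth record).
    """
    if planted_clique_size > n_strains:
        raise ValueError("planted clique cannot exceed the strain count")
    rng = np.random.default_rng(seed)
    names = [f"S{i:02d}" for i in range(n_strains)]
    planted = sorted(rng.choice(n_strains, size=planted_clique_size, replace=False))
    planted_names = [names[i] for i in planted]
    planted_set = set(planted_names)
    matrix = CompatibilityMatrix()
    for i in range(n_strains):
        for j in range(i + 1, n_strains):
            a, b = names[i], names[j]
            if a in planted_set and b in planted_set:
                matrix.set(a, b, "+")
            elif rng.random() < edge_density:
                matrix.set(a, b, "+")
            elif rng.random() < nc_rate:
                matrix.set(a, b, "nc")
            else:
                matrix.set(a, b, "-")
    return matrix, planted_names
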