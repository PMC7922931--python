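import numpy as np
import pytest

from pgpmkit.io_formats import Genome, Read
from pgpmkit.recruiter import (
    RecruitmentParams,
    build_qgram_index,
    min_matches_above,
    recruit_read,
    recruit_sample,
)

from ._oracles import brute_force_hits, brute_force_qgram_positions, revcomp
from .conftest import mutate, random_genome


class TestQGramIndex:
    def test_repeated_qgram_positions(self):
        idx = build_qgram_index(Genome("g", "ACGTACGT"), q=4)
        assert list(idx.positions("ACGT")) == [0, 4]

    def test_all_n_genome_empty_index(self):
        idx = build_qgram_index(Genome("g", "N" * 50), q=4)
        assert idx.n_positions == 0

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError, match="shorter than q"):
            build_qgram_index(Genome("g", "ACG"), q=11)

    def test_position_count_matches_window_scan(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=1000))
        idx = build_qgram_index(Genome("g", seq), q=8)
        assert idx.n_positions == brute_force_qgram_positions(seq, 8)


class TestRecruitRead:
    def test_exact_substring_hit(self, rng):
        genome = random_genome(rng, 2000)
        read = Read("r", genome.sequence[37:137])
        (hit,) = recruit_read(read, genome, params=RecruitmentParams())
        assert (hit.start, hit.end, hit.strand, hit.identity) == (37, 137, "+", 1.0)

    def test_two_substitutions_recruited_three_rejected(self, rng):
        genome = random_genome(rng, 2000)
        window = genome.sequence[500:600]
        read2 = Read("r2", mutate(rng, window, [10, 60]))
        (hit,) = recruit_read(read2, genome, params=RecruitmentParams())
        assert hit.identity == pytest.approx(0.98)
        read3 = Read("r3", mutate(rng, window, [10, 60, 90]))
        assert recruit_read(read3, genome, params=RecruitmentParams()) == []

    def test_unrelated_read_gives_no_hits(self, rng):
        genome = random_genome(rng, 2000, "a")
        other = random_genome(rng, 2000, "b")
        assert recruit_read(Read("r", other.sequence[:100]), genome,
                            params=RecruitmentParams()) == []

    def test_reverse_strand_reported_forward(self, rng):
        genome = random_genome(rng, 2000)
        read = Read("r", revcomp(genome.sequence[300:400]))
        (hit,) = recruit_read(read, genome, params=RecruitmentParams())
        assert (hit.start, hit.end, hit.strand) == (300, 400, "-")

    def test_short_read_skipped(self, rng):
        genome = random_genome(rng, 2000)
        read = Read("r", genome.sequence[0:20])
        assert recruit_read(read, genome, params=RecruitmentParams(min_align_len=30)) == []

    def test_strict_threshold_boundary(self):
        assert min_matches_above(0.97, 100) == 98  # 97/100 is not above 97%
        assert min_matches_above(0.97, 150) == 146
        assert min_matches_above(1.0, 80) == 81  # threshold 1.0 admits nothing...
        assert min_matches_above(0.5, 10) == 6


def _hit_tuples(hits):
    return {(h.start, h.strand, h.matches) for h in hits}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        glen = int(rng.integers(200, 3000))
        genome = random_genome(rng, glen, f"g{seed}")
        params = RecruitmentParams(identity_threshold=0.9, q=8, min_align_len=30)
        for i in range(20):
            n = int(rng.integers(30, min(151, glen)))
            if rng.random() < 0.7:
                start = int(rng.integers(0, glen - n + 1))
                seq = genome.sequence[start : start + n]
                n_mut = int(rng.integers(0, max(1, n // 8)))
                seq = mutate(rng, seq, rng.choice(n, size=n_mut, replace=False))
                if rng.random() < 0.5:
                    seq = revcomp(seq)
            else:
                seq = "".join(rng.choice(list("ACGT"), size=n))
            hits = recruit_read(Read(f"r{i}", seq), genome, params=params)
            expected = brute_force_hits(seq, genome.sequence, 0.9, "both")
            assert _hit_tuples(hits) == expected

    def test_filter_keeps_every_low_mismatch_window(self, rng):
        # q-gram lemma safety: every window the full scan accepts must appear
        genome = random_genome(rng, 5000)
        params = RecruitmentParams(identity_threshold=0.97, q=11)
        for start in (0, 1234, 4900):
            seq = genome.sequence[start : start + 100]
            seq = mutate(rng, seq, rng.choice(100, size=2, replace=False))
            hits = recruit_read(Read("r", seq), genome, params=params)
            assert (start, "+", ) in {(h.start, h.strand) for h in hits}

    def test_identity_monotonicity(self, rng):
        genome = random_genome(rng, 3000)
        reads = []
        for i in range(30):
            start = int(rng.integers(0, 2900))
            seq = mutate(rng, genome.sequence[start : start + 100],
                         rng.choice(100, size=int(rng.integers(0, 5)), replace=False))
            reads.append(Read(f"r{i}", seq))
        previous = None
        for threshold in (0.90, 0.95, 0.97, 0.99):
            total = sum(
                len(recruit_read(r, genome,
                                 params=RecruitmentParams(identity_threshold=threshold)))
                for r in reads
            )
            if previous is not None:
                assert total <= previous
            previous = total

    def test_determinism(self, rng):
        genome = random_genome(rng, 2000)
        read = Read("r", mutate(rng, genome.sequence[100:200], [5, 50]))
        first = recruit_read(read, genome, params=RecruitmentParams())
        second = recruit_read(read, genome, params=RecruitmentParams())
        assert first == second


class TestRecruitSample:
    def test_read_recruited_to_identical_genomes(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genomes = [Genome("a", seq), Genome("b", seq)]
        reads = [Read("r", seq[100:200])]
        result = recruit_sample(reads, genomes)
        assert result.recruited_count("a") == result.recruited_count("b") == 1

    def test_all_reads_land_on_their_source_only(self, rng):
        g_a = random_genome(rng, 3000, "A")
        g_b = random_genome(rng, 3000, "B")  # unrelated: ~25% expected identity
        starts = rng.integers(0, 2900, size=200)
        reads = [Read(f"r{i}", g_a.sequence[s : s + 100]) for i, s in enumerate(starts)]
        result = recruit_sample(reads, [g_a, g_b])
        assert result.recruited_count("A") == 200
        assert result.recruited_count("B") == 0

    def test_best_hit_per_genome_is_single(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=100))
        # two perfect copies of the read's template: best-hit keeps leftmost
        genome = Genome("g", core + "".join(rng.choice(list("ACGT"), size=300)) + core)
        result = recruit_sample([Read("r", core)], [genome])
        (hit,) = result.hits["g"]
        assert hit.start == 0

    def test_max_reads_cap(self, rng):
        genome = random_genome(rng, 1000)
        reads = [Read(f"r{i}", genome.sequence[0:100]) for i in range(500)]
        params = RecruitmentParams(max_reads=100)
        result = recruit_sample(reads, [genome], params)
        assert result.n_reads == 100
        assert result.recruited_count(genome.id) == 100

    def test_empty_stream_warns(self, rng):
        genome = random_genome(rng, 1000)
        with pytest.warns(UserWarning, match="empty read stream"):
            result = recruit_sample([], [genome])
        assert result.hits[genome.id] == []
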