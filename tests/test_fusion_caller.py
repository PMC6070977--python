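import numpy as np
import pytest

from segf.aligner import build_index
from segf.fusion_caller import (
    FusionCall,
    Rejection,
    SegmentEvidence,
    call_from_reads,
    call_fusions,
    run_pipeline,
    screen_segment,
    validate_panel,
)
from segf.io_formats import GeneRegion, Read, extract_target_sequences, write_fasta, write_fastq, write_gene_bed
from segf.simulate import FusionSpec, make_genome, simulate_reads

from helpers import random_dna


@pytest.fixture(scope="module")
def screening_world():
    """Hand-built world exercising every screening path.

    chr1 carries genes GA and GB; a 35-mer from inside GA is copied into
    intergenic chr2 sequence to create a genome-multi segment.
    """
    rng = np.random.default_rng(5)
    chr1 = random_dna(rng, 2000)
    chr2 = random_dna(rng, 1000)
    panel = [GeneRegion("chr1", 100, 700, "GA"), GeneRegion("chr1", 1000, 1600, "GB")]
    dup = chr1[200:235]  # inside GA
    chr2 = chr2[:500] + dup + chr2[535:]
    genome = {"chr1": chr1, "chr2": chr2}
    targets = extract_target_sequences(genome, panel)
    return genome, panel, build_index(targets, 35), build_index(genome, 35)


class TestScreenSegment:
    def _screen(self, world, seq):
        genome, panel, target_index, genome_index = world
        by_symbol = {g.symbol: g for g in panel}
        return screen_segment(("r1", "head", seq), target_index, genome_index, by_symbol)

    def test_unique_in_gene_accepted_with_gene_identity(self, screening_world):
        genome = screening_world[0]
        result = self._screen(screening_world, genome["chr1"][300:335])
        assert isinstance(result, SegmentEvidence)
        assert result.gene == "GA" and result.chrom == "chr1" and result.pos == 300

    def test_duplicated_segment_rejected_genome_multi(self, screening_world):
        genome = screening_world[0]
        result = self._screen(screening_world, genome["chr1"][200:235])
        assert isinstance(result, Rejection) and result.reason == "genome_multi"

    def test_unique_outside_panel_rejected(self, screening_world):
        genome = screening_world[0]
        result = self._screen(screening_world, genome["chr1"][800:835])  # intergenic
        assert isinstance(result, Rejection) and result.reason == "no_target_hit"

    def test_absent_segment_rejected_unmapped(self, screening_world):
        result = self._screen(screening_world, "N" * 35)
        assert isinstance(result, Rejection) and result.reason == "genome_unmapped"

    def test_target_hit_at_wrong_genomic_location_rejected(self):
        """Condition (c): the unique genomic hit must fall inside the hit gene."""
        rng = np.random.default_rng(9)
        genome = {"chr1": random_dna(rng, 500)}
        panel = [GeneRegion("chr1", 0, 100, "GX")]
        # target reference content disagrees with the panel region on purpose
        target_index = build_index({"GX": genome["chr1"][300:400]}, 35)
        genome_index = build_index(genome, 35)
        result = screen_segment(
            ("r1", "head", genome["chr1"][310:345]),
            target_index,
            genome_index,
            {"GX": panel[0]},
        )
        assert isinstance(result, Rejection) and result.reason == "location_outside_panel"


def _ev(read_id, end, gene, pos=0):
    return SegmentEvidence(read_id=read_id, end=end, gene=gene, chrom="chr1", pos=pos, strand="+")


def _both_ends(read_id, gene_head, gene_tail):
    return [_ev(read_id, "head", gene_head), _ev(read_id, "tail", gene_tail)]


class TestCallFusions:
    def test_five_supporting_reads_one_call(self):
        evidence = [ev for i in range(5) for ev in _both_ends(f"r{i}", "ALK", "EML4")]
        calls = call_fusions(evidence, min_support=3)
        assert len(calls) == 1
        call = calls[0]
        assert (call.gene_a, call.gene_b, call.support) == ("ALK", "EML4", 5)
        assert call.read_ids == tuple(f"r{i}" for i in range(5))

    def test_two_reads_below_threshold_no_call(self):
        evidence = [ev for i in range(2) for ev in _both_ends(f"r{i}", "ALK", "EML4")]
        assert call_fusions(evidence, min_support=3) == []

    def test_same_gene_both_ends_never_called(self):
        evidence = [ev for i in range(4) for ev in _both_ends(f"r{i}", "ALK", "ALK")]
        assert call_fusions(evidence, min_support=1) == []

    def test_single_surviving_end_contributes_nothing(self):
        evidence = [_ev(f"r{i}", "head", "ALK") for i in range(5)]
        assert call_fusions(evidence, min_support=1) == []

    def test_support_counts_distinct_read_ids(self):
        evidence = [ev for _ in range(3) for ev in _both_ends("r0", "ALK", "EML4")]
        assert call_fusions(evidence, min_support=2) == []

    def test_gene_pair_is_order_insensitive(self):
        evidence = _both_ends("r0", "EML4", "ALK") + _both_ends("r1", "ALK", "EML4") + _both_ends("r2", "ALK", "EML4")
        calls = call_fusions(evidence, min_support=3)
        assert len(calls) == 1 and (calls[0].gene_a, calls[0].gene_b) == ("ALK", "EML4")

    def test_monotonic_in_min_support(self):
        rng = np.random.default_rng(1)
        genes = ["ALK", "EML4", "RET", "CCDC6"]
        evidence = []
        for i in range(60):
            a, b = rng.choice(genes, size=2, replace=False)
            evidence += _both_ends(f"r{i}", a, b)
        previous = None
        for threshold in range(1, 8):
            pairs = {(c.gene_a, c.gene_b) for c in call_fusions(evidence, threshold)}
            if previous is not None:
                assert pairs <= previous
            previous = pairs

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        evidence = [ev for i in range(20) for ev in _both_ends(f"r{i}", "ALK", "EML4")]
        evidence += [ev for i in range(20, 24) for ev in _both_ends(f"r{i}", "RET", "CCDC6")]
        baseline = call_fusions(evidence)
        for _ in range(5):
            shuffled = list(evidence)
            rng.shuffle(shuffled)
            assert call_fusions(shuffled) == baseline

    def test_support_conservation(self):
        evidence = [ev for i in range(10) for ev in _both_ends(f"r{i}", "ALK", "EML4")]
        evidence += [ev for i in range(10, 15) for ev in _both_ends(f"r{i}", "RET", "CCDC6")]
        calls = call_fusions(evidence, min_support=1)
        reads_with_both_ends = 15
        assert sum(c.support for c in calls) <= reads_with_both_ends

    def test_invalid_min_support(self):
        with pytest.raises(ValueError):
            call_fusions([], min_support=0)


class TestValidatePanel:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            validate_panel([GeneRegion("c1", 0, 100, "A"), GeneRegion("c1", 50, 150, "B")])

    def test_disjoint_panel_passes(self, small_panel):
        assert validate_panel(small_panel) == list(small_panel)


class TestPipeline:
    def test_planted_fusion_recovered_exactly(self, small_world):
        genome, panel = small_world
        reads, manifest = simulate_reads(
            genome, panel, [FusionSpec("ALK", "EML4", 0.10)], depth=200, seed=3
        )
        calls, report = call_from_reads(reads, genome, panel)
        assert [(c.gene_a, c.gene_b) for c in calls] == [("ALK", "EML4")]
        assert calls[0].support > 0
        assert report["counters"]["reads_in"] == len(reads)

    def test_wild_type_only_no_calls(self, small_world):
        genome, panel = small_world
        reads, _ = simulate_reads(genome, panel, [], depth=100, seed=4)
        calls, _ = call_from_reads(reads, genome, panel)
        assert calls == []

    def test_file_based_run_matches_in_memory(self, small_world, tmp_path):
        genome, panel = small_world
        reads, _ = simulate_reads(
            genome, panel, [FusionSpec("RET", "CCDC6", 0.08)], depth=150, seed=5
        )
        write_fasta(genome, tmp_path / "genome.fa")
        write_gene_bed(panel, tmp_path / "panel.bed")
        write_fastq(reads, tmp_path / "reads.fq.gz")
        calls_mem, _ = call_from_reads(reads, genome, panel)
        calls_file, report = run_pipeline(
            [tmp_path / "reads.fq.gz"], tmp_path / "genome.fa", tmp_path / "panel.bed"
        )
        assert calls_file == calls_mem
        assert report["counters"]["calls"] == len(calls_file)

    def test_empty_fastq_valid_empty_report(self, small_world, tmp_path):
        genome, panel = small_world
        write_fasta(genome, tmp_path / "genome.fa")
        write_gene_bed(panel, tmp_path / "panel.bed")
        (tmp_path / "empty.fq").write_text("")
        calls, report = run_pipeline(
            [tmp_path / "empty.fq"], tmp_path / "genome.fa", tmp_path / "panel.bed"
        )
        assert calls == [] and report["counters"]["reads_in"] == 0
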