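"""Depth summaries, copy numbers and paired-end class tracks."""

import shutil
import subprocess

import numpy as np
import pytest

from shufflonq import (
    DepthSummary,
    SimConfig,
    copy_number,
    copy_number_report,
    enumerate_arrangements,
    make_locus,
    mean_depth,
    pair_class_coverage,
    sample_population,
    simulate_short_pairs,
)
from shufflonq.locus import write_locus
from shufflonq.seqio import write_sequences


class TestMeanDepth:
    def test_uniform_depth(self):
        records = [("p", i, 10) for i in range(1, 101)]
        s = mean_depth(records, "p")
        assert (s.mean_depth, s.length) == (10.0, 100)

    def test_zero_depth_everywhere(self):
        records = [("p", i, 0) for i in range(1, 51)]
        assert mean_depth(records, "p", length=50).mean_depth == 0.0

    def test_seeded_random_depths_match_brute_force(self):
        rng = np.random.default_rng(17)
        depths = rng.integers(0, 300, 500)
        records = [("chr", i + 1, int(d)) for i, d in enumerate(depths)]
        s = mean_depth(records, "chr")
        assert s.mean_depth == pytest.approx(sum(depths) / 500)

    def test_absent_positions_count_as_zero(self):
        # depth listed for half the replicon only
        records = [("p", i, 8) for i in range(1, 51)]
        assert mean_depth(records, "p", length=100).mean_depth == 4.0

    def test_missing_replicon_rejected(self):
        with pytest.raises(ValueError):
            mean_depth([("p", 1, 5)], "q")


class TestCopyNumber:
    def test_printed_table_values_reproduced(self):
        chrom = DepthSummary("chromosome", 135.41, 4_920_828)
        incI2 = DepthSummary("pIncI2", 219.75, 61_805)
        phage = DepthSummary("pPhage", 298.92, 108_986)
        assert copy_number(incI2, chrom).rounded == 1.6
        assert copy_number(phage, chrom).rounded == 2.2

    def test_self_ratio_is_one(self):
        s = DepthSummary("chr", 123.4, 1000)
        entry = copy_number(s, s)
        assert entry.ratio == pytest.approx(1.0)
        assert entry.rounded == 1.0

    def test_scale_invariance(self):
        a = DepthSummary("p", 50.0, 100)
        b = DepthSummary("c", 20.0, 100)
        a2 = DepthSummary("p", 50.0 * 3.7, 100)
        b2 = DepthSummary("c", 20.0 * 3.7, 100)
        assert copy_number(a, b).ratio == pytest.approx(copy_number(a2, b2).ratio)

    def test_zero_chromosome_depth_rejected(self):
        with pytest.raises(ValueError):
            copy_number(DepthSummary("p", 5.0, 10), DepthSummary("c", 0.0, 10))

    def test_report_pins_chromosome_to_one(self):
        summaries = [
            DepthSummary("chr", 100.0, 1000),
            DepthSummary("p1", 160.0, 100),
        ]
        rep = copy_number_report(summaries, "chr")
        assert rep.set_index("replicon").loc["chr", "copy_number"] == 1.0
        assert rep.set_index("replicon").loc["p1", "copy_number"] == 1.6


@pytest.fixture(scope="module")
def mapped_sam(tmp_path_factory):
    """Short pairs from a rearranged population mapped onto the reference
    arrangement with minimap2, coordinate-sorted SAM."""
    if not (shutil.which("minimap2") and shutil.which("samtools")):
        pytest.fail("minimap2/samtools expected on PATH for this environment")
    tmp = tmp_path_factory.mktemp("pairtrack")
    config = SimConfig(seed=31, n_segments=2, plasmid_len=20_000)
    locus = make_locus(config)
    space = enumerate_arrangements(locus)
    alt = [a for a in space if a != locus.reference_arrangement][5]
    pop = sample_population(locus, [1.0 if a == alt else 0.0 for a in space])
    # keep inserts away from the circular origin so wrap clipping cannot
    # masquerade as broken pairs outside the locus
    r1, r2, _ = simulate_short_pairs(pop, 800, config, region=(500, locus.plasmid_len - 1500))
    write_locus(locus, tmp / "ref.fa", tmp / "ref.gff3")
    write_sequences(r1, tmp / "r1.fq")
    write_sequences(r2, tmp / "r2.fq")
    sam = tmp / "aln.sam"
    with open(sam, "w") as out:
        p1 = subprocess.run(
            ["minimap2", "-ax", "sr", "--secondary=no", "ref.fa", "r1.fq", "r2.fq"],
            cwd=tmp, check=True, capture_output=True,
        )
        sort = subprocess.run(
            ["samtools", "sort", "-O", "sam"], input=p1.stdout, capture_output=True, check=True
        )
        out.write(sort.stdout.decode())
    return sam, locus


class TestPairClassTrack:
    def test_broken_coverage_confined_to_shufflon(self, mapped_sam):
        sam, locus = mapped_sam
        track = pair_class_coverage(sam, locus.plasmid_id)
        pad = 50  # read-length bleed at the locus edges
        outside = np.r_[
            track.broken_cov[: locus.locus_start - pad],
            track.broken_cov[locus.locus_end + pad :],
        ]
        inside = track.broken_cov[locus.locus_start : locus.locus_end]
        assert outside.max() == 0
        assert inside.sum() > 0

    def test_concordant_population_has_no_broken_coverage(self, tmp_path):
        config = SimConfig(seed=32, n_segments=1, plasmid_len=15_000)
        locus = make_locus(config)
        space = enumerate_arrangements(locus)
        ref_only = [1.0 if a == locus.reference_arrangement else 0.0 for a in space]
        pop = sample_population(locus, ref_only)
        r1, r2, _ = simulate_short_pairs(pop, 300, config, region=(500, locus.plasmid_len - 1500))
        write_locus(locus, tmp_path / "ref.fa", tmp_path / "ref.gff3")
        write_sequences(r1, tmp_path / "r1.fq")
        write_sequences(r2, tmp_path / "r2.fq")
        p1 = subprocess.run(
            ["minimap2", "-ax", "sr", "--secondary=no", "ref.fa", "r1.fq", "r2.fq"],
            cwd=tmp_path, check=True, capture_output=True,
        )
        sort = subprocess.run(
            ["samtools", "sort", "-O", "sam"], input=p1.stdout, capture_output=True, check=True
        )
        sam = tmp_path / "aln.sam"
        sam.write_text(sort.stdout.decode())
        track = pair_class_coverage(sam, locus.plasmid_id)
        assert track.broken_cov.max() == 0
        assert track.proper_cov.sum() > 0

    def test_pair_classes_partition_coverage(self, mapped_sam):
        """proper + broken equals total primary paired coverage everywhere."""
        import pysam

        sam, locus = mapped_sam
        track = pair_class_coverage(sam, locus.plasmid_id)
        total = np.zeros(track.length, dtype=int)
        with pysam.AlignmentFile(str(sam)) as fh:
            for read in fh:
                if (
                    read.is_unmapped or read.is_secondary or read.is_supplementary
                    or not read.is_paired or read.reference_name != locus.plasmid_id
                ):
                    continue
                total[read.reference_start : read.reference_end] += 1
        assert np.array_equal(track.proper_cov + track.broken_cov, total)

    def test_unsorted_input_rejected(self, mapped_sam, tmp_path):
        sam, locus = mapped_sam
        lines = sam.read_text().splitlines()
        body = [l for l in lines if not l.startswith("@")]
        header = [l for l in lines if l.startswith("@")]
        shuffled = tmp_path / "unsorted.sam"
        shuffled.write_text("\n".join(header + body[::-1]) + "\n")
        with pytest.raises(ValueError, match="sorted"):
            pair_class_coverage(shuffled, locus.plasmid_id, insert_bounds=(200, 600))
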