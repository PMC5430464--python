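"""Synthetic-data generator: determinism, exactness, frequency convergence."""


import numpy as np
import pytest

from shufflonq import (
    LongReadConfig,
    ShortReadConfig,
    SimConfig,
    build_candidates,
    enumerate_arrangements,
    load_locus,
    make_locus,
    sample_population,
    simulate_long_reads,
    simulate_short_pairs,
    write_locus,
)
from shufflonq.locus import revcomp

ERROR_FREE_LONG = LongReadConfig(sub_rate=0.0, ins_rate=0.0, del_rate=0.0)


def variant_plasmids(population):
    cands = build_candidates(population.locus)
    locus = population.locus
    return {
        locus.label(a): locus.plasmid_seq[: locus.locus_start]
        + cands.sequences[a]
        + locus.plasmid_seq[locus.locus_end :]
        for a in population.space
    }


class TestMakeLocus:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=99, n_segments=2)
        assert make_locus(cfg) == make_locus(cfg)

    def test_different_seed_differs(self):
        a = make_locus(SimConfig(seed=1, n_segments=2))
        b = make_locus(SimConfig(seed=2, n_segments=2))
        assert a.plasmid_seq != b.plasmid_seq

    def test_three_segment_locus_enumerates_48(self, sim_locus):
        assert len(enumerate_arrangements(sim_locus)) == 48

    def test_repeats_differ_from_consensus_only_at_n_positions(self, sim_config, sim_locus):
        cons = sim_config.repeat_consensus
        for rep in sim_locus.junctions:
            assert len(rep) == len(cons)
            for got, want in zip(rep, cons):
                if want != "N":
                    assert got == want

    def test_generated_locus_round_trips_through_gff(self, tmp_path, sim_locus):
        write_locus(sim_locus, tmp_path / "p.fa", tmp_path / "p.gff3")
        assert load_locus(tmp_path / "p.fa", tmp_path / "p.gff3") == sim_locus

    def test_invalid_error_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, long_read=LongReadConfig(ins_rate=1.5))


class TestSamplePopulation:
    def test_degenerate_population_is_monomorphic(self, sim_locus):
        space = enumerate_arrangements(sim_locus)
        freqs = [1.0] + [0.0] * (len(space) - 1)
        pop = sample_population(sim_locus, freqs)
        assert pop.frequencies[0] == 1.0

    def test_uniform_over_two(self, locus1):
        pop = sample_population(locus1, [0.5, 0.5])
        assert pop.frequencies == (0.5, 0.5)

    def test_dirichlet_draw_reproducible(self, sim_locus):
        a = sample_population(sim_locus, seed=5)
        b = sample_population(sim_locus, seed=5)
        assert a.frequencies == b.frequencies
        assert np.isclose(sum(a.frequencies), 1.0)

    def test_bad_frequencies_rejected(self, locus1):
        with pytest.raises(ValueError):
            sample_population(locus1, [0.7, 0.7])
        with pytest.raises(ValueError):
            sample_population(locus1, [1.0])


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self, sim_population):
        cfg = SimConfig(seed=51, long_read=ERROR_FREE_LONG)
        reads, truth = simulate_long_reads(sim_population, 40, cfg)
        plasmids = variant_plasmids(sim_population)
        for rec, row in zip(reads, truth.itertuples()):
            doubled = plasmids[row.arrangement] * 2
            seq = str(rec.seq)
            if row.strand == "-":
                seq = revcomp(seq)
            assert doubled[row.start : row.start + row.length] == seq

    def test_same_seed_byte_identical(self, sim_population, sim_config):
        a, _ = simulate_long_reads(sim_population, 20, sim_config)
        b, _ = simulate_long_reads(sim_population, 20, sim_config)
        assert [(r.id, str(r.seq)) for r in a] == [(r.id, str(r.seq)) for r in b]

    def test_every_read_has_one_truth_record(self, sim_population, sim_config):
        reads, truth = simulate_long_reads(sim_population, 30, sim_config)
        assert truth["read_id"].tolist() == [r.id for r in reads]
        assert truth["read_id"].is_unique

    def test_spanning_only_reads_cover_both_anchors(self, sim_population):
        cfg = SimConfig(seed=52, long_read=ERROR_FREE_LONG)
        locus = sim_population.locus
        reads, truth = simulate_long_reads(sim_population, 25, cfg, spanning_only=True)
        span = locus.locus_end - locus.locus_start
        for row in truth.itertuples():
            offset = (locus.locus_start - row.start) % locus.plasmid_len
            assert offset + span <= row.length

    def test_short_reads_cannot_span(self, sim_population):
        """A read shorter than the pilV-to-rci distance is never spanning."""
        from shufflonq import quantify_structures

        cfg = SimConfig(
            seed=53, long_read=LongReadConfig(mean_len=900, sigma=0.05, min_len=200,
                                              sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        )
        reads, _ = simulate_long_reads(sim_population, 15, cfg)
        table = quantify_structures(reads, sim_population.locus)
        assert table.totals["assigned"] == 0

    def test_truth_frequencies_converge_to_population(self, sim_locus):
        """Empirical arrangement frequencies at n=5000 sit inside 99% CIs."""
        pop = sample_population(sim_locus, seed=8)
        cfg = SimConfig(seed=54, long_read=ERROR_FREE_LONG)
        _, truth = simulate_long_reads(pop, 5000, cfg)
        emp = truth["arrangement"].value_counts(normalize=True)
        ok = 0
        labels = [sim_locus.label(a) for a in pop.space]
        for lab, p in zip(labels, pop.frequencies):
            half = 2.576 * np.sqrt(p * (1 - p) / 5000) + 1e-12
            ok += abs(emp.get(lab, 0.0) - p) <= half
        # ~1% of 48 cells may fall outside a 99% CI by chance
        assert ok >= len(labels) - 3


class TestShortPairs:
    def test_error_free_mates_are_exact_fr_substrings(self, sim_population):
        cfg = SimConfig(seed=61, short_read=ShortReadConfig(sub_rate=0.0))
        r1, r2, truth = simulate_short_pairs(sim_population, 30, cfg)
        plasmids = variant_plasmids(sim_population)
        for m1, m2, row in zip(r1, r2, truth.itertuples()):
            doubled = plasmids[row.arrangement] * 2
            frag = doubled[row.start : row.start + row.insert]
            if row.strand == "-":
                frag = revcomp(frag)
            assert frag.startswith(str(m1.seq))
            assert revcomp(frag).startswith(str(m2.seq))

    def test_same_seed_byte_identical(self, sim_population, sim_config):
        a1, a2, _ = simulate_short_pairs(sim_population, 15, sim_config)
        b1, b2, _ = simulate_short_pairs(sim_population, 15, sim_config)
        assert [str(r.seq) for r in a1 + a2] == [str(r.seq) for r in b1 + b2]

    def test_insert_never_below_read_length(self, sim_population, sim_config):
        _, _, truth = simulate_short_pairs(sim_population, 50, sim_config)
        assert (truth["insert"] >= sim_config.short_read.read_len).all()

    def test_junction_pairs_typed_to_truth_on_error_free_data(self, sim_population):
        """Error-free junction-overlapping pairs type to the variant implied
        by their source arrangement."""
        from shufflonq.pilv import type_read

        locus = sim_population.locus
        cfg = SimConfig(seed=62, short_read=ShortReadConfig(sub_rate=0.0))
        r1, r2, truth = simulate_short_pairs(
            sim_population, 150, cfg, region=(locus.locus_start, locus.locus_end)
        )
        by_label = build_candidates(locus).by_label()
        typed = checked = 0
        for m1, m2, row in zip(r1, r2, truth.itertuples()):
            arr = by_label[row.arrangement]
            seg = locus.segments[arr.order[0] - 1]
            expected = seg.orf_left if arr.orientations[0] == "+" else seg.orf_right
            for mate in (m1, m2):
                call = type_read(mate, locus)
                if call is not None:
                    checked += 1
                    typed += call == expected
        assert checked > 10  # locus-region pairs must yield junction reads
        assert typed == checked
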