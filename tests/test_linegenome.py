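from __future__ import annotations

import numpy as np
import pytest

from _oracles import het_percent_by_grid

from ccstatus.cli import analyze_line
from ccstatus.linegenome import (
    FixedSegment,
    LineGenome,
    SegregatingRegion,
    apply_fixed_override,
    between_ancestor_segregating,
    build_line_genome,
    classify_line,
    merge_segregating_regions,
    read_line_genome,
    residual_heterozygosity,
    within_ancestor_segregating,
    write_line_genome,
)
from ccstatus.reconstruct import DiplotypeMosaic, MarkerPanel, Segment

from test_reconstruct import make_panel


def region(chrom, start, end, founders):
    return SegregatingRegion(chrom, start, end, frozenset(founders))


def mosaic_from(specs, panel=None, animal="anc", sex="female"):
    """Build a mosaic from (chrom, start, end, state) tuples.

    Marker indices are filled in from ``panel`` when given.
    """
    segments = []
    for chrom, start, end, state in specs:
        first = last = -1
        if panel is not None:
            sl = panel.chrom_slice(chrom)
            pos = panel.pos_mb[sl]
            inside = np.where((pos >= start) & (pos < end))[0]
            if len(inside):
                first = sl.start + int(inside[0])
                last = sl.start + int(inside[-1])
        segments.append(
            Segment(chrom, start, end, tuple(sorted(state)), 0, first, last)
        )
    return DiplotypeMosaic(animal=animal, sex=sex, segments=segments)


class TestClassify:
    @pytest.mark.parametrize(
        "het,want",
        [
            (2.0, "complete"),
            (10.0, "distributable"),
            (0.0, "complete"),
            (1.9, "complete"),
            (2.1, "distributable"),
            (10.1, "in_progress"),
            (100.0, "in_progress"),
        ],
    )
    def test_examples(self, het, want):
        assert classify_line(het) == want

    def test_exactly_two_step_breakpoints(self):
        # sweep homozygosity on a 0.1 grid; switches only at 90 and 98
        homs = np.round(np.arange(0, 1001) / 10.0, 1)
        statuses = [classify_line(round(100.0 - h, 1)) for h in homs]
        switches = [
            float(homs[i])
            for i in range(1, len(statuses))
            if statuses[i] != statuses[i - 1]
        ]
        assert switches == [90.0, 98.0]

    @pytest.mark.parametrize("bad", [-0.1, 100.5, 1e9])
    def test_out_of_range_fatal(self, bad):
        with pytest.raises(ValueError):
            classify_line(bad)


class TestResidualHeterozygosity:
    def test_no_regions_zero(self, small_genome):
        assert residual_heterozygosity([], small_genome) == 0.0

    def test_full_chromosome_share(self):
        lengths = {"1": 100.0, "2": 2400.0}
        got = residual_heterozygosity([region("1", 0.0, 100.0, "AB")], lengths)
        assert got == pytest.approx(4.0, abs=1e-12)

    def test_overlaps_unioned_not_double_counted(self):
        lengths = {"1": 100.0}
        regs = [region("1", 10, 30, "AB"), region("1", 20, 40, "BC")]
        assert residual_heterozygosity(regs, lengths) == pytest.approx(30.0)

    def test_out_of_bounds_fatal(self):
        with pytest.raises(ValueError, match="bounds"):
            residual_heterozygosity([region("1", 90.0, 120.0, "AB")], {"1": 100.0})

    def test_untracked_chromosome_fatal(self):
        with pytest.raises(ValueError, match="untracked"):
            residual_heterozygosity([region("5", 0.0, 1.0, "AB")], {"1": 100.0})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_oracle(self, seed, small_genome):
        rng = np.random.default_rng(seed)
        regs = []
        for _ in range(rng.integers(1, 8)):
            chrom = rng.choice(list(small_genome))
            clen = small_genome[chrom]
            # grid-aligned ends so the 0.1-Mb oracle is exact
            a = round(float(rng.uniform(0, clen - 1)), 1)
            b = round(float(rng.uniform(a + 0.2, clen)), 1)
            regs.append(region(chrom, a, b, "ABC"))
        got = residual_heterozygosity(regs, small_genome)
        want = het_percent_by_grid(merge_segregating_regions(regs), small_genome)
        assert got == pytest.approx(want, abs=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_regions(self, seed, small_genome):
        rng = np.random.default_rng(seed)
        regs = []
        prev = 0.0
        for _ in range(6):
            chrom = rng.choice(list(small_genome))
            clen = small_genome[chrom]
            a = float(rng.uniform(0, clen - 0.5))
            b = float(rng.uniform(a + 0.1, clen))
            regs.append(region(chrom, a, b, "AB"))
            cur = residual_heterozygosity(regs, small_genome)
            assert cur >= prev - 1e-12
            prev = cur


class TestMerge:
    def test_union_founder_sets(self):
        merged = merge_segregating_regions(
            [region("1", 0, 10, "AB"), region("1", 5, 15, "CD")]
        )
        assert len(merged) == 1
        assert merged[0].founders == frozenset("ABCD")
        assert (merged[0].start_mb, merged[0].end_mb) == (0, 15)

    def test_disjoint_kept_separate(self):
        merged = merge_segregating_regions(
            [region("1", 0, 10, "AB"), region("1", 20, 30, "AB")]
        )
        assert len(merged) == 2


class TestWithinAncestor:
    def _fh_panel(self):
        # founders F,H differ at every marker
        positions = [20.5, 22.1, 30.0, 37.9, 39.5]
        alleles = [[0, 0, 0, 0, 0, 0, 1, 0]] * len(positions)  # G=1 others 0
        alleles = [[0, 1, 0, 1, 0, 0, 1, 1]] * len(positions)  # F=0, H=1
        return make_panel(positions, alleles)

    def test_boundaries_tighten_to_het_calls(self):
        panel = self._fh_panel()
        mosaic = mosaic_from([("1", 20.0, 40.0, ("F", "H"))], panel)
        calls = np.array([0, 1, 1, 1, 0], dtype=np.int8)
        regs = within_ancestor_segregating(mosaic, calls, panel)
        assert len(regs) == 1
        assert regs[0].founders == frozenset("FH")
        assert (regs[0].start_mb, regs[0].end_mb) == (22.1, 37.9)

    def test_fully_homozygous_empty(self):
        panel = self._fh_panel()
        mosaic = mosaic_from([("1", 0.0, 60.0, ("F", "F"))], panel)
        calls = np.zeros(5, dtype=np.int8)
        assert within_ancestor_segregating(mosaic, calls, panel) == []

    def test_het_segment_without_het_calls_dropped_with_warning(self):
        panel = self._fh_panel()
        mosaic = mosaic_from([("1", 20.0, 40.0, ("F", "H"))], panel)
        calls = np.array([0, 0, 0, 0, 0], dtype=np.int8)
        with pytest.warns(UserWarning, match="dropped"):
            regs = within_ancestor_segregating(mosaic, calls, panel)
        assert regs == []

    def test_true_tracts_recovered_on_simulation(self, sim_line):
        from ccstatus.funnelsim import true_segments
        from ccstatus.reconstruct import HmmParams, estimate_breakpoints, reconstruct_mosaic

        res = sim_line
        cfg = res.config
        params = HmmParams(chrom_lengths=cfg.chrom_lengths, r_per_mb=cfg.recomb_rate_per_mb)
        aid = res.extant_ids[1]  # female: two haplotypes everywhere
        mosaic = estimate_breakpoints(
            reconstruct_mosaic(res.genotypes[aid], res.panel, "female", params),
            res.panel,
            res.genotypes[aid],
        )
        regs = within_ancestor_segregating(mosaic, res.genotypes[aid], res.panel)
        for chrom, clen in cfg.chrom_lengths.items():
            for a, b, labels in true_segments([res.animals[aid]], chrom):
                if len(labels) < 2 or b - a < 3.0:
                    continue
                covered = sum(
                    max(0.0, min(b, r.end_mb) - max(a, r.start_mb))
                    for r in regs
                    if r.chrom == chrom
                )
                assert covered >= 0.8 * (b - a)


class TestBetweenAncestors:
    def _dg_panel(self):
        positions = np.arange(0.5, 100.0, 1.0)
        # D=0, G=1; B=0, E=1 -> informative for both worked examples
        alleles = [[0, 0, 1, 0, 1, 1, 1, 0]] * len(positions)
        return make_panel(positions, alleles)

    def test_both_fixed_for_different_founders(self):
        panel = self._dg_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("D", "D"))], panel, "anc1")
        m2 = mosaic_from(
            [("1", 0.0, 60.0, ("D", "D")), ("1", 60.0, 80.0, ("G", "G")),
             ("1", 80.0, 100.0, ("D", "D"))],
            panel,
            "anc2",
        )
        regs = between_ancestor_segregating([m1, m2], panel, {"1": 100.0})
        assert len(regs) == 1
        assert regs[0].founders == frozenset("DG")
        # snapped outward to the nearest informative markers
        assert regs[0].start_mb == pytest.approx(59.5)
        assert regs[0].end_mb == pytest.approx(80.5)

    def test_one_homozygous_one_segregating(self):
        panel = self._dg_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("B", "B"))], panel, "anc1")
        m2 = mosaic_from(
            [("1", 0.0, 60.0, ("B", "B")), ("1", 60.0, 80.0, ("B", "E")),
             ("1", 80.0, 100.0, ("B", "B"))],
            panel,
            "anc2",
        )
        regs = between_ancestor_segregating([m1, m2], panel, {"1": 100.0})
        assert len(regs) == 1
        assert regs[0].founders == frozenset("BE")

    def test_identical_homozygous_mosaics_empty(self):
        panel = self._dg_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("D", "D"))], panel, "anc1")
        m2 = mosaic_from([("1", 0.0, 100.0, ("D", "D"))], panel, "anc2")
        assert between_ancestor_segregating([m1, m2], panel, {"1": 100.0}) == []

    def test_mismatched_panels_fatal(self):
        panel = self._dg_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("D", "D"))], panel, "anc1")
        m2 = mosaic_from([("2", 0.0, 100.0, ("D", "D"))], None, "anc2")
        with pytest.raises(ValueError, match="mismatched"):
            between_ancestor_segregating([m1, m2], panel)


class TestFixedOverride:
    def _setup(self):
        positions = np.arange(10.5, 20.0, 1.0)
        # D and G share allele 0 here; panel still informative via founder B
        alleles = [[0, 1, 0, 0, 0, 0, 0, 0]] * len(positions)
        panel = make_panel(positions, alleles)
        m1 = mosaic_from([("1", 10.0, 20.0, ("D", "D"))], panel, "anc1")
        m2 = mosaic_from([("1", 10.0, 20.0, ("G", "G"))], panel, "anc2")
        reg = region("1", 10.0, 20.0, "DG")
        return panel, m1, m2, reg

    def test_consistent_discordant_run_removed(self):
        panel, m1, m2, reg = self._setup()
        n = len(panel)
        calls = {  # both ancestors read homozygous 2 where the table says 0
            "anc1": np.full(n, 2, dtype=np.int8),
            "anc2": np.full(n, 2, dtype=np.int8),
        }
        out = apply_fixed_override(
            [reg], calls, panel, k=5, mosaics={"anc1": m1, "anc2": m2}
        )
        assert out == []

    def test_single_ancestor_discordance_retained(self):
        panel, m1, m2, reg = self._setup()
        n = len(panel)
        calls = {
            "anc1": np.full(n, 2, dtype=np.int8),
            "anc2": np.full(n, 0, dtype=np.int8),  # matches its prediction
        }
        out = apply_fixed_override(
            [reg], calls, panel, k=3, mosaics={"anc1": m1, "anc2": m2}
        )
        assert out == [reg]

    def test_k_longer_than_any_run_noop(self):
        panel, m1, m2, reg = self._setup()
        n = len(panel)
        calls = {
            "anc1": np.full(n, 2, dtype=np.int8),
            "anc2": np.full(n, 2, dtype=np.int8),
        }
        out = apply_fixed_override(
            [reg], calls, panel, k=n + 1, mosaics={"anc1": m1, "anc2": m2}
        )
        assert out == [reg]

    def test_k_below_two_fatal(self):
        panel, m1, m2, reg = self._setup()
        with pytest.raises(ValueError):
            apply_fixed_override([reg], {}, panel, k=1)


class TestBuildLineGenome:
    def _bb_panel(self):
        positions = np.arange(0.5, 100.0, 1.0)
        alleles = [[0, 0, 1, 1, 1, 0, 1, 1]] * len(positions)  # B=0, E=1
        return make_panel(positions, alleles)

    def test_two_segregating_regions_remainder_fixed(self):
        panel = self._bb_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("B", "B"))], panel, "anc1")
        m2 = mosaic_from(
            [("1", 0.0, 30.0, ("B", "B")), ("1", 30.0, 50.0, ("B", "E")),
             ("1", 50.0, 70.0, ("B", "B")), ("1", 70.0, 90.0, ("B", "E")),
             ("1", 90.0, 100.0, ("B", "B"))],
            panel,
            "anc2",
        )
        regs = between_ancestor_segregating([m1, m2], panel, {"1": 100.0})
        lg = build_line_genome([m1, m2], regs, {"1": 100.0}, line_id="L")
        assert len(lg.segregating) == 2
        assert all(r.founders == frozenset("BE") for r in lg.segregating)
        assert all(s.founder == "B" for s in lg.fixed)
        assert lg.fixed_length_mb() + lg.segregating_length_mb() == pytest.approx(100.0)

    def test_contradiction_outside_regions_fatal(self):
        panel = self._bb_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("B", "B"))], panel, "anc1")
        m2 = mosaic_from([("1", 0.0, 100.0, ("C", "C"))], panel, "anc2")
        with pytest.raises(ValueError, match="different founders"):
            build_line_genome([m1, m2], [], {"1": 100.0})

    def test_override_piece_labeled_majority_founder(self):
        panel = self._bb_panel()
        m1 = mosaic_from([("1", 0.0, 100.0, ("B", "B"))], panel, "anc1")
        m2 = mosaic_from(
            [("1", 0.0, 40.0, ("B", "B")), ("1", 40.0, 60.0, ("E", "E")),
             ("1", 60.0, 100.0, ("B", "B"))],
            panel,
            "anc2",
        )
        ov = [region("1", 40.0, 60.0, "BE")]
        lg = build_line_genome([m1, m2], [], {"1": 100.0}, override_fixed=ov)
        assert lg.segregating == []
        assert lg.fixed_length_mb() == pytest.approx(100.0)
        assert {s.founder for s in lg.fixed} == {"B"}  # B outweighs E 3:1

    def test_pipeline_output_tiles_genome(self, sim_line):
        res = sim_line
        rep, lg = analyze_line(
            res.pedigree,
            res.genotypes,
            res.extant_ids,
            res.config.chrom_lengths,
            r_per_mb=res.config.recomb_rate_per_mb,
        )
        total = sum(res.config.chrom_lengths.values())
        assert lg.fixed_length_mb() + lg.segregating_length_mb() == pytest.approx(total)
        for chrom, clen in res.config.chrom_lengths.items():
            pieces = sorted(
                [(s.start_mb, s.end_mb) for s in lg.fixed if s.chrom == chrom]
                + [(r.start_mb, r.end_mb) for r in lg.segregating if r.chrom == chrom]
            )
            assert pieces[0][0] == 0.0
            assert pieces[-1][1] == pytest.approx(clen)
            for (a0, a1), (b0, b1) in zip(pieces, pieces[1:]):
                assert a1 == pytest.approx(b0)

    def test_round_trip_tsv(self, tmp_path, small_genome):
        lg = LineGenome(
            line_id="L",
            fixed=[FixedSegment("1", 0.0, 50.0, "B"), FixedSegment("1", 70.0, 100.0, "C")],
            segregating=[region("1", 50.0, 70.0, "BC")],
            chrom_lengths=small_genome,
        )
        path = tmp_path / "lg.tsv"
        write_line_genome(lg, path)
        back = read_line_genome(path, small_genome, line_id="L")
        assert back.fixed == lg.fixed
        assert back.segregating == lg.segregating
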