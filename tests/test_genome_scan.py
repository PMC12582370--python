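"""Genome-wide module scanning, redundancy filtering and quantification."""

import numpy as np
import pytest

from ltrtrace.genome_scan import (
    GenomeHit,
    deduplicate_modules,
    diff_score,
    elimination_rate,
    fpkm,
    merge_hits,
    read_gtf,
    scan_genome,
    write_gtf,
)
from ltrtrace.homology_graph import ModuleDef, Section
from ltrtrace.io_formats import ElementRecord


class TestDiffScore:
    def test_range_of_percentages(self):
        assert diff_score({"A": 1.0, "B": 0.0}) == 1.0
        assert diff_score({"A": 0.9, "B": 0.1, "C": 0.4}) == pytest.approx(0.8)
        assert diff_score({"A": 0.3, "B": 0.3, "C": 0.3}) == 0.0

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            diff_score({"A": 0.5})


def test_median_merge_worked_example():
    intervals = [(100, 200), (110, 190), (105, 210)]
    assert merge_hits(intervals) == (105, 200)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScanGenome:
    def _setup(self, copy_fracs=(1.0, 1.0, 1.0), mod_len=600, genome_len=100_000):
        rng = np.random.default_rng(42)
        mod_seq = _random_seq(rng, mod_len)
        genome = list(_random_seq(rng, genome_len))
        planted = []
        pos = 10_000
        for frac in copy_fracs:
            piece = mod_seq[: int(mod_len * frac)]
            genome[pos : pos + len(piece)] = piece
            planted.append((pos, pos + len(piece)))
            pos += 25_000
        element = ElementRecord("el1", mod_seq)
        module = ModuleDef("b1", [Section("el1", 0, mod_len)], mod_len)
        return module, [element], {"chr1": "".join(genome)}, planted

    def test_planted_copies_recovered(self):
        module, elements, genome, planted = self._setup((1.0, 1.0, 1.0))
        hits = scan_genome(module, elements, genome)
        assert len(hits) == len(planted)
        for h, (start, end) in zip(sorted(hits, key=lambda h: h.start), planted):
            assert abs(h.start - start) <= 30
            assert abs(h.end - end) <= 30
            assert h.source == "truncated"  # no intact annotation supplied

    def test_short_truncation_below_retention_dropped(self):
        module, elements, genome, planted = self._setup((1.0, 0.4))
        hits = scan_genome(module, elements, genome, min_len_frac=0.5)
        assert len(hits) == 1
        assert abs(hits[0].start - planted[0][0]) <= 30

    def test_intact_labeling_from_bed(self):
        module, elements, genome, planted = self._setup((1.0, 1.0))
        bed = [("chr1", planted[0][0] - 100, planted[0][1] + 100, "ltr1")]
        hits = sorted(scan_genome(module, elements, genome, bed), key=lambda h: h.start)
        assert [h.source for h in hits] == ["intact", "truncated"]

    def test_no_extractable_member(self):
        module = ModuleDef("b1", [Section("ghost", 0, 100)], 100)
        with pytest.raises(ValueError, match="extractable"):
            scan_genome(module, [], {"chr1": "ACGT" * 100})


class TestDeduplicateModules:
    def _hits(self, mod, intervals):
        return [GenomeHit(mod, "chr1", s, e) for s, e in intervals]

    def test_identical_hit_sets_drop_shorter(self):
        sets = {
            "b1": self._hits("b1", [(0, 100), (500, 600)]),
            "b2": self._hits("b2", [(0, 100), (500, 600)]),
        }
        kept = deduplicate_modules(sets, {"b1": 100, "b2": 60})
        assert kept == ["b1"]

    def test_disjoint_sets_both_retained(self):
        sets = {
            "b1": self._hits("b1", [(0, 100)]),
            "b2": self._hits("b2", [(1000, 1100)]),
        }
        assert deduplicate_modules(sets, {"b1": 100, "b2": 60}) == ["b1", "b2"]

    def test_boundary_exactly_at_threshold_retained(self):
        # median overlap exactly 0.2 is NOT "greater than 0.2"
        sets = {
            "b1": self._hits("b1", [(0, 100)]),
            "b2": self._hits("b2", [(80, 180)]),  # overlap 20 of 100
        }
        assert deduplicate_modules(sets, {"b1": 100, "b2": 90}, 0.2) == ["b1", "b2"]
        sets["b2"] = self._hits("b2", [(79, 179)])  # overlap 21
        assert deduplicate_modules(sets, {"b1": 100, "b2": 90}, 0.2) == ["b1"]


class TestEliminationRate:
    def test_counting(self):
        hits = [GenomeHit("b1", "c", i * 10, i * 10 + 5,
                          "truncated" if i < 4 else "intact") for i in range(10)]
        assert elimination_rate(hits) == pytest.approx(0.4)

    def test_boundaries_and_complement(self):
        intact = [GenomeHit("b1", "c", 0, 5, "intact")]
        trunc = [GenomeHit("b1", "c", 0, 5, "truncated")]
        assert elimination_rate(intact) == 0.0
        assert elimination_rate(trunc) == 1.0
        assert elimination_rate([]) is None
        mixed = intact * 3 + trunc * 7
        intact_frac = sum(1 for h in mixed if h.source == "intact") / len(mixed)
        assert elimination_rate(mixed) + intact_frac == pytest.approx(1.0)


class TestFpkm:
    def test_printed_formula(self):
        out = fpkm({"b1": 10}, {"b1": 1000.0}, 1_000_000)
        assert out["b1"] == pytest.approx(10.0)

    def test_zero_count_and_scaling(self):
        assert fpkm({"b1": 0}, {"b1": 500.0}, 100)["b1"] == 0.0
        a = fpkm({"b1": 7}, {"b1": 350.0}, 1000)
        b = fpkm({"b1": 7}, {"b1": 350.0}, 2000)
        assert a["b1"] == pytest.approx(2 * b["b1"])

    def test_invalid_totals(self):
        with pytest.raises(ValueError):
            fpkm({"b1": 1}, {"b1": 100.0}, 0)
        with pytest.raises(ValueError):
            fpkm({"b1": 1}, {"b1": 0.0}, 10)


def test_gtf_round_trip(tmp_path):
    hits = [
        GenomeHit("b1", "chr1", 104, 200, "intact", 3),
        GenomeHit("b2", "chr2", 0, 55, "truncated", 1),
    ]
    p = tmp_path / "mods.gtf"
    write_gtf(hits, p)
    back = read_gtf(p)
    assert [(h.module_id, h.chrom, h.start, h.end, h.source, h.seed_support) for h in back] == [
        (h.module_id, h.chrom, h.start, h.end, h.source, h.seed_support) for h in hits
    ]
    # 1-based inclusive on disk
    line = p.read_text().splitlines()[0].split("\t")
    assert (line[3], line[4]) == ("105", "200")
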