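"""Majority-vote genotype calling, matrix assembly and turning-point curation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from sporemap.genotyper import (
    build_matrix,
    call_genotype,
    call_locus,
    scan_turning_point,
    scan_all_turning_points,
    observation_votes,
)
from sporemap.readclass import ReadClass, ReadObservation
from sporemap.report import truth_accuracy


def _obs(read_id, scaffold, start, end, cls, snp=1, a=0, b=0):
    return ReadObservation(read_id, scaffold, start, end, cls, snp, a, b)


def _voter(read_id, scaffold, start, end, vote, snp=1):
    cls = ReadClass.IDENTICAL if vote == "A" else ReadClass.VARIANT
    a, b = (1, 0) if vote == "A" else (0, 1)
    return _obs(read_id, scaffold, start, end, cls, snp, a, b)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "n_a,n_b,code",
        [
            (292, 131, "A"),  # whole-scaffold majority hiding a crossover
            (1, 13, "B"),  # the locus-restricted recount
            (0, 0, "-"),
            (5, 5, "X"),
            (1, 0, "A"),
            (0, 1, "B"),
        ],
    )
    def test_majority_vote(self, n_a, n_b, code):
        assert call_genotype(n_a, n_b) == code

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(-1, 3)


class TestBuildMatrix:
    def test_matrix_matches_truth_at_coverage_1p5(self):
        """Error-free 1.5x simulation genotypes >= 98% of usable cells correctly."""
        import warnings

        from sporemap.simdata import SimConfig, simulate_meiosis, simulate_parents, simulate_reads
        from sporemap.readclass import SnpCatalog, classify_isolate
        from sporemap import io as sio

        # 2 cM genetic span per scaffold, the study's marker-density regime
        cfg = SimConfig(n_chromosomes=2, chrom_genetic_lengths=(60.0, 60.0),
                        n_scaffolds=60, scaffold_lengths=8000, n_isolates=20,
                        coverage=1.5, error_rate=0.0, seed=101)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = simulate_parents(cfg)
            t = simulate_meiosis(cfg, g.scaffold_map)
            reads = simulate_reads(cfg, t, g)
        ref_lens = {n: len(s) for n, s in g.reference.items()}
        catalog = SnpCatalog.from_frame(g.catalog, ref_lens)
        obs_by = {}
        for iso, rs in reads.items():
            from sporemap.io import write_truth_sam
            import tempfile, os

            with tempfile.TemporaryDirectory() as d:
                p = os.path.join(d, "x.sam")
                write_truth_sam(rs, ref_lens, p)
                obs_by[iso], _ = classify_isolate(p, catalog)
        m = build_matrix(obs_by, list(g.scaffold_map.index))
        acc = truth_accuracy(m, t.parent)
        assert acc.n_compared > 300
        assert acc.accuracy_pct >= 98.0
        # success rate is reported per marker and bounded
        sr = m.success_rate()
        assert ((sr >= 0) & (sr <= 1)).all()

    def test_zero_read_isolate_is_all_missing(self):
        obs = {"I1": [_voter("r1", "S1", 0, 100, "A")], "I2": []}
        m = build_matrix(obs, ["S1", "S2"])
        assert (m.codes["I2"] == "-").all()
        assert m.codes.loc["S1", "I1"] == "A"
        assert m.codes.loc["S2", "I1"] == "-"

    def test_duplicate_read_id_rejected(self):
        obs = {"I1": [_voter("r1", "S1", 0, 100, "A"), _voter("r1", "S1", 50, 150, "B")]}
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(obs, ["S1"])

    def test_informative_only_drops_snp_free_votes(self):
        obs = {
            "I1": [
                _voter("r1", "S1", 0, 100, "A", snp=0),
                _voter("r2", "S1", 0, 100, "A", snp=0),
                _voter("r3", "S1", 50, 150, "B", snp=2),
            ]
        }
        full = build_matrix(obs, ["S1"])
        restricted = build_matrix(obs, ["S1"], informative_only=True)
        assert full.codes.loc["S1", "I1"] == "A"
        assert restricted.codes.loc["S1", "I1"] == "B"

    def test_label_swap_flips_calls(self, genotype_matrix):
        swapped = genotype_matrix.swapped_labels()
        flip = {"A": "B", "B": "A", "X": "X", "-": "-"}
        assert (swapped.codes == genotype_matrix.codes.replace(flip)).all().all()


def _brute_force_turning_point(votes, min_segment_reads, min_score):
    """Independent exhaustive oracle over all splits (no prefix sums)."""
    n = len(votes)
    tot_a = votes.count("A")
    base = min(tot_a, n - tot_a)
    best = None
    for k in range(min_segment_reads, n - min_segment_reads + 1):
        la = votes[:k].count("A")
        lb = k - la
        ra = tot_a - la
        rb = (n - k) - (tot_a - la)
        if ("A" if la >= lb else "B") == ("A" if ra >= rb else "B"):
            continue
        total = min(la, lb) + min(ra, rb)
        if best is None or total < best:
            best = total
    if best is None or base - best < min_score:
        return None
    return best


class TestScanTurningPoint:
    def test_perfect_switch(self):
        reads = [(float(i * 100), float(i * 100 + 80), "A" if i < 5 else "B") for i in range(10)]
        tp = scan_turning_point(reads, min_segment_reads=5, min_score=3)
        assert tp is not None
        assert (tp.left_code, tp.right_code) == ("A", "B")
        assert tp.split_index == 5
        assert tp.left_counts == (5, 0) and tp.right_counts == (0, 5)
        assert tp.score == 5  # unsplit call misclassifies the 5 minority reads
        assert 480 <= tp.breakpoint_bp <= 500

    def test_uniform_votes_give_none(self):
        reads = [(float(i), float(i) + 10, "A") for i in range(20)]
        assert scan_turning_point(reads, 5, 3) is None

    def test_unsorted_input_rejected(self):
        reads = [(100.0, 180.0, "A"), (0.0, 80.0, "B")] * 5
        with pytest.raises(ValueError, match="sorted"):
            scan_turning_point(reads, 2, 1)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            votes = ["AB"[v] for v in rng.integers(0, 2, size=n)]
            reads = [(float(i * 50), float(i * 50 + 40), votes[i]) for i in range(n)]
            min_seg = int(rng.integers(2, 6))
            min_score = int(rng.integers(1, 4))
            oracle = _brute_force_turning_point(votes, min_seg, min_score)
            tp = scan_turning_point(reads, min_seg, min_score)
            if oracle is None:
                assert tp is None
            else:
                assert tp is not None
                la, lb = tp.left_counts
                ra, rb = tp.right_counts
                assert min(la, lb) + min(ra, rb) == oracle

    def test_detects_true_simulated_crossovers(self, sim_bundle, obs_by_isolate):
        """Scaffolds spanning a mid-scaffold crossover are flagged near the true breakpoint."""
        _, truth, _ = sim_bundle
        checked = located = 0
        for iso in truth.isolates:
            for scaf, bps in truth.breakpoints[iso].items():
                if len(bps) != 1:
                    continue
                bp_true = bps[0][2]
                if not 2000 <= bp_true <= 6000:  # edge crossovers lack flank support
                    continue
                votes = observation_votes(obs_by_isolate[iso], scaf)
                if len(votes) < 10:
                    continue
                checked += 1
                tp = scan_turning_point(votes, min_segment_reads=3, min_score=2,
                                        scaffold=scaf, isolate=iso)
                if tp is not None and abs(tp.breakpoint_bp - bp_true) <= 800:
                    located += 1
        assert checked >= 3
        assert located / checked >= 0.5


class TestCallLocus:
    def test_matA_style_locus_recount(self):
        """Whole-scaffold A (292:131) but B (1:13) at the locus itself."""
        reads = []
        # 292 A votes upstream of the locus, 118 B votes downstream of it
        reads += [(float(i * 10), float(i * 10 + 300), "A") for i in range(292)]
        reads += [(60_000.0 + i * 10, 60_300.0 + i * 10, "B") for i in range(118)]
        # around the locus [50_000, 52_000): 1 A and 13 B votes
        reads += [(50_100.0, 50_400.0, "A")]
        reads += [(50_000.0 + i * 100, 50_300.0 + i * 100, "B") for i in range(13)]
        reads.sort()
        whole = call_locus(reads, (0.0, 70_000.0))
        assert (whole.n_a, whole.n_b, whole.code) == (293, 131, "A")
        locus = call_locus(reads, (50_000.0, 52_000.0))
        assert (locus.n_a, locus.n_b, locus.code) == (1, 13, "B")

    def test_whole_scaffold_interval_equals_full_call(self):
        reads = [(float(i), float(i + 5), "AB"[i % 2]) for i in range(10)]
        full = call_locus(reads, (0.0, 100.0))
        assert (full.n_a, full.n_b) == (5, 5)
        assert full.code == "X"

    def test_empty_interval_and_no_reads(self):
        with pytest.raises(ValueError, match="empty"):
            call_locus([], (10.0, 10.0))
        assert call_locus([], (0.0, 10.0)).code == "-"
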