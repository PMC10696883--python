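import numpy as np
import pytest

from crnn_tfbs import genome_scan as gs
from crnn_tfbs.datasets import VARIANT_POSITION, grhl1_itc_panel
from crnn_tfbs.errors import AlignmentError, InputError
from crnn_tfbs.seqio import PeakRecord, SequenceRecord


def peak(chrom, start, end, qvalue=6.0, name=None):
    return PeakRecord(
        chrom=chrom, start=start, end=end, name=name or f"{chrom}:{start}",
        qvalue=qvalue, summit_offset=(end - start) // 2,
    )


def count_a_scorer(windows):
    return np.array([w.count("A") for w in windows], dtype=float)


class TestFilterPeaks:
    def test_neglog10_threshold_conversion(self):
        peaks = [peak("c", 0, 10, qvalue=q) for q in (4.0, 6.0, 9.0)]
        kept = gs.filter_peaks(peaks, 1e-5)
        assert [p.qvalue for p in kept] == [6.0, 9.0]

    def test_vacuous_threshold_keeps_all(self):
        peaks = [peak("c", 0, 10, qvalue=q) for q in (0.1, 5.0)]
        assert gs.filter_peaks(peaks, 1.0) == peaks

    def test_empty_input(self):
        assert gs.filter_peaks([], 1e-5) == []

    def test_bad_threshold(self):
        with pytest.raises(InputError):
            gs.filter_peaks([], 0.0)


class TestRemoveOverlapping:
    def test_one_bp_overlap_removed(self):
        survivors, removed = gs.remove_overlapping(
            [peak("chr1", 100, 200)], [peak("chr1", 150, 250)]
        )
        assert survivors == [] and removed == 1

    def test_abutting_kept(self):
        survivors, removed = gs.remove_overlapping(
            [peak("chr1", 100, 200)], [peak("chr1", 200, 300)]
        )
        assert len(survivors) == 1 and removed == 0

    def test_chromosome_separation(self):
        negs = [peak("chr1", 0, 100), peak("chr1", 50, 150)]
        survivors, removed = gs.remove_overlapping(negs, [peak("chr2", 0, 1000)])
        assert survivors == negs and removed == 0

    def test_matches_quadratic_oracle(self, rng):
        negs = [peak("c", int(s), int(s) + int(w), name=f"n{i}")
                for i, (s, w) in enumerate(zip(rng.integers(0, 500, 40),
                                               rng.integers(1, 60, 40)))]
        poss = [peak("c", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 500, 20), rng.integers(1, 60, 20))]
        survivors, removed = gs.remove_overlapping(negs, poss)
        expected = [
            n for n in negs
            if not any(n.start < p.end and p.start < n.end for p in poss)
        ]
        assert survivors == expected
        assert removed == len(negs) - len(expected)


class TestScanSequence:
    def test_degenerate_single_window(self):
        rec = SequenceRecord(id="s", seq="ACGTA")
        res = gs.scan_sequence(count_a_scorer, rec, window=5)
        assert res.best_offset == 0 and res.best_window == "ACGTA"

    def test_enumeration_example(self):
        rec = SequenceRecord(id="s", seq="TTAAAT")
        res = gs.scan_sequence(count_a_scorer, rec, window=3)
        assert (res.best_offset, res.best_window, res.score) == (2, "AAA", 3.0)

    def test_window_count_100nt_peak(self):
        rec = SequenceRecord(id="s", seq="A" * 100)
        calls = []

        def counting_scorer(windows):
            calls.append(len(windows))
            return np.zeros(len(windows))

        gs.scan_sequence(counting_scorer, rec, window=20, stride=1)
        assert calls == [81]

    def test_matches_bruteforce_max(self, rng):
        def scorer(windows):
            # deterministic hash-like score, independent reimplementation below
            return np.array([sum(ord(c) * (i + 1) for i, c in enumerate(w))
                             for w in windows], dtype=float)

        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 60))))
            rec = SequenceRecord(id="s", seq=seq)
            w = int(rng.integers(3, 10))
            res = gs.scan_sequence(scorer, rec, window=w)
            best = max(
                range(len(seq) - w + 1),
                key=lambda o: (scorer([seq[o : o + w]])[0], -o),
            )
            assert res.best_offset == best

    def test_tie_breaks_to_smallest_offset(self):
        rec = SequenceRecord(id="s", seq="AATAA")
        res = gs.scan_sequence(count_a_scorer, rec, window=2)
        assert res.best_offset == 0

    def test_too_short(self):
        with pytest.raises(InputError):
            gs.scan_sequence(count_a_scorer, SequenceRecord(id="s", seq="ACG"), 5)


class TestAssignPercentiles:
    def test_distinct_scores(self):
        results = [
            gs.ScanResult(f"p{i}", 0, "A", s) for i, s in enumerate([0.1, 0.4, 0.2, 0.9])
        ]
        pct = {r.peak_id: r.percentile for r in gs.assign_percentiles(results)}
        assert pct == {"p0": 25.0, "p1": 75.0, "p2": 50.0, "p3": 100.0}

    def test_all_ties_equal(self):
        results = [gs.ScanResult(f"p{i}", 0, "A", 0.5) for i in range(4)]
        pcts = {r.percentile for r in gs.assign_percentiles(results)}
        assert len(pcts) == 1

    def test_singleton_is_100(self):
        (r,) = gs.assign_percentiles([gs.ScanResult("p", 0, "A", 0.3)])
        assert r.percentile == 100.0

    def test_monotone_in_score(self, rng):
        results = [
            gs.ScanResult(f"p{i}", 0, "A", float(s))
            for i, s in enumerate(rng.random(30))
        ]
        ranked = sorted(gs.assign_percentiles(results), key=lambda r: r.score)
        assert all(
            a.percentile <= b.percentile for a, b in zip(ranked, ranked[1:])
        )


class TestDiscoverNoncanonical:
    def res(self, pid, score):
        return gs.ScanResult(pid, 0, "A" * 20, score)

    def test_filter_logic(self):
        rnn = [self.res("a", 0.995), self.res("b", 0.995), self.res("c", 0.5)]
        pwm = [self.res("a", -2.1), self.res("b", 3.0), self.res("c", -5.0)]
        hits = gs.discover_noncanonical(rnn, pwm)
        assert [h.peak_id for h in hits] == ["a"]

    def test_strict_inequalities(self):
        rnn = [self.res("a", 0.99), self.res("b", 0.9901)]
        pwm = [self.res("a", -1.0), self.res("b", 0.0)]
        assert gs.discover_noncanonical(rnn, pwm) == []

    def test_sorted_by_descending_rnn_score(self):
        rnn = [self.res("a", 0.992), self.res("b", 0.999)]
        pwm = [self.res("a", -1.0), self.res("b", -1.0)]
        assert [h.peak_id for h in gs.discover_noncanonical(rnn, pwm)] == ["b", "a"]

    def test_monotone_in_thresholds(self, rng):
        rnn = [self.res(f"p{i}", float(s)) for i, s in enumerate(rng.random(50))]
        pwm = [self.res(f"p{i}", float(s)) for i, s in enumerate(rng.normal(0, 2, 50))]
        base = {h.peak_id for h in gs.discover_noncanonical(rnn, pwm, 0.5, 0.0)}
        stricter_rnn = {h.peak_id for h in gs.discover_noncanonical(rnn, pwm, 0.7, 0.0)}
        stricter_pwm = {h.peak_id for h in gs.discover_noncanonical(rnn, pwm, 0.5, -1.0)}
        assert stricter_rnn <= base and stricter_pwm <= base

    def test_id_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            gs.discover_noncanonical([self.res("a", 1.0)], [self.res("b", 0.0)])


class TestSaturationMutagenesis:
    def test_variant_count_uniqueness_hamming(self):
        rec = SequenceRecord(id="s", seq="ACGTACGTACGTACGTACGT")
        effects = gs.saturation_mutagenesis(rec, count_a_scorer)
        assert len(effects) == 60
        seqs = {e.variant_seq for e in effects}
        assert len(seqs) == 60
        for e in effects:
            diffs = [i for i, (a, b) in enumerate(zip(rec.seq, e.variant_seq)) if a != b]
            assert diffs == [e.position - 1]
            assert e.ref_base != e.alt_base

    def test_position12_variants_reproduce_ligand_panel(self):
        # the bundled calorimetry panel's variant rows are exactly the
        # position-12 substitutions of their parent sequences
        panel = {r.ligand_id: r.sequence for r in grhl1_itc_panel()}
        for parent_id in ("Pos_Ctrl", "Novel"):
            rec = SequenceRecord(id=parent_id, seq=panel[parent_id])
            effects = gs.saturation_mutagenesis(rec, count_a_scorer)
            at12 = {e.variant_seq for e in effects if e.position == VARIANT_POSITION}
            expected = {
                panel[f"{parent_id}_V{i}"] for i in (1, 2, 3)
            }
            assert expected <= at12

    def test_apply_variant_round_trip(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 20))
        rec = SequenceRecord(id="s", seq=seq)
        for e in gs.saturation_mutagenesis(rec, count_a_scorer):
            assert gs.apply_variant(seq, e.position, e.alt_base) == e.variant_seq

    def test_deltas_relative_to_parent(self):
        rec = SequenceRecord(id="s", seq="AAAA")
        effects = gs.saturation_mutagenesis(rec, count_a_scorer)
        for e in effects:
            assert e.delta == e.score - 4.0

    def test_n_rejected(self):
        with pytest.raises(InputError):
            gs.saturation_mutagenesis(
                SequenceRecord(id="s", seq="ACGN"), count_a_scorer
            )


class TestSelectTopVariants:
    def effects(self, deltas):
        return [
            gs.VariantEffect("p", i + 1, "A", "C", "x", 0.0, d)
            for i, d in enumerate(deltas)
        ]

    def test_max_magnitude_selected(self):
        top = gs.select_top_variants(self.effects([-0.8, -0.1, 0.05]), k=1)
        assert top[0].delta == -0.8

    def test_k_equals_all(self):
        eff = self.effects([0.3, -0.5, 0.1])
        assert set(e.delta for e in gs.select_top_variants(eff, 3)) == {0.3, -0.5, 0.1}

    def test_matches_exhaustive_sort_oracle(self, rng):
        deltas = list(rng.normal(0, 1, 40))
        eff = self.effects(deltas)
        top = gs.select_top_variants(eff, 10)
        oracle = sorted(eff, key=lambda e: (-abs(e.delta), e.position, e.alt_base))[:10]
        assert top == oracle

    def test_k_too_large(self):
        with pytest.raises(InputError):
            gs.select_top_variants(self.effects([0.1]), 2)
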