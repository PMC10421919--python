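"""Depth windows, normalization, segment calling and copy-number estimation."""

import numpy as np
import pytest
from scipy import stats

from epspscnv import depthcnv as dc
from epspscnv import maplite as ml
from epspscnv import simulate as sim


def make_track(values, window=5000, normalized=True):
    vals = np.asarray(values, dtype=float)
    return dc.DepthTrack(window=window, values={"Chr1": vals},
                         eff_lengths={"Chr1": np.full(len(vals), float(window))},
                         normalized=normalized)


class TestWindowDepth:
    def test_single_read_covering_one_window(self):
        rec = ml.AlignmentRecord("r", "C", 5000, 10000, "+",
                                 [(5000, 0, 5000)], True)
        tr = dc.window_depth([rec], {"C": 20_000}, window=5000)
        assert list(tr.values["C"]) == [0.0, 1.0, 0.0, 0.0]

    def test_no_alignments_gives_zero_track(self):
        tr = dc.window_depth([], {"C": 12_000}, window=5000)
        assert tr.values["C"].sum() == 0
        assert tr.eff_lengths["C"][-1] == 2000  # trailing partial window

    def test_default_window_is_5kb(self):
        import inspect
        assert inspect.signature(dc.window_depth).parameters["window"].default == 5000

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            dc.window_depth([], {"C": 1000}, window=0)


class TestNormalize:
    def test_constant_track_becomes_unity(self):
        tr = make_track([7.0] * 10, normalized=False)
        out = dc.normalize(tr)
        assert np.allclose(out.all_values(), 1.0)

    def test_scale_invariance_and_unit_mean(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(1, 5, 50)
        a = dc.normalize(make_track(raw, normalized=False))
        b = dc.normalize(make_track(2 * raw, normalized=False))
        assert np.allclose(a.all_values(), b.all_values())
        assert abs(a.all_values().mean() - 1.0) < 1e-9

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError):
            dc.normalize(make_track([0.0] * 5, normalized=False))


class TestCallSegments:
    def test_flat_track_is_single_neutral_segment(self):
        segs = dc.call_segments(make_track([1.0] * 40))
        assert len(segs) == 1 and segs[0].state == "neutral"
        assert (segs[0].start, segs[0].stop) == (0, 40 * 5000)

    def test_high_copy_block_called_with_depth_near_truth(self):
        """A 7-window block at 22x in a long unit background is one
        duplication with mean within 10% of 22 and p <= 0.01."""
        rng = np.random.default_rng(1)
        raw = rng.normal(1.0, 0.03, 3000).clip(0.5)
        raw[1500:1507] = rng.normal(22.0, 0.4, 7)
        track = dc.normalize(make_track(raw, normalized=False))
        dups = [s for s in dc.call_segments(track) if s.state == "duplication"]
        assert len(dups) == 1
        assert abs(dups[0].mean_norm_depth - 22) <= 2.2
        assert dups[0].p_value <= 0.01

    def test_low_block_called_deletion(self):
        vals = np.ones(60)
        vals[20:30] = 0.1
        segs = dc.call_segments(make_track(vals))
        assert [s.state for s in segs] == ["neutral", "deletion", "neutral"]

    def test_threshold_equality_is_neutral(self):
        vals = np.ones(30)
        vals[10:15] = 4.0  # exactly at dup_fold: strict inequality -> neutral
        segs = dc.call_segments(make_track(vals))
        assert all(s.state == "neutral" for s in segs)

    def test_insignificant_calls_demoted_to_neutral(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(1.0, 2.0, 100).clip(0.01)  # huge variance
        vals[50] = 4.5  # single mildly-high window, not significant
        segs = dc.call_segments(make_track(vals), dc.ThresholdConfig(alpha=1e-6))
        covered = [s for s in segs if s.start <= 50 * 5000 < s.stop]
        assert covered[0].state == "neutral"

    def test_segments_tile_chromosome_without_overlap(self):
        rng = np.random.default_rng(2)
        vals = rng.choice([0.1, 1.0, 8.0], size=200)
        segs = sorted(dc.call_segments(make_track(vals)),
                      key=lambda s: s.start)
        assert segs[0].start == 0 and segs[-1].stop == 200 * 5000
        for a, b in zip(segs, segs[1:]):
            assert a.stop == b.start

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            dc.call_segments(make_track([1.0] * 5, normalized=False))

    def test_raising_dup_fold_shrinks_the_duplicated_extent(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.2, 30, 300)
        lo = dc.call_segments(make_track(vals), dc.ThresholdConfig(dup_fold=4.0))
        hi = dc.call_segments(make_track(vals), dc.ThresholdConfig(dup_fold=8.0))
        bases = lambda segs: sum(s.stop - s.start for s in segs
                                 if s.state == "duplication")
        assert bases(hi) <= bases(lo)

    def test_labels_match_brute_force_oracle(self):
        """Differential test: independent per-window classify + run-length
        merge + demote must reproduce call_segments labels."""
        thr = dc.ThresholdConfig()
        rng = np.random.default_rng(5)
        for trial in range(20):
            vals = rng.choice([0.05, 0.8, 1.0, 1.2, 5.0, 22.0], size=rng.integers(5, 200),
                              p=[.05, .15, .4, .2, .1, .1])
            track = make_track(vals)
            got = dc.call_segments(track, thr)
            # oracle: label each window independently, merge runs, test, merge
            allv = track.all_values()
            gv = float(allv.var(ddof=1)) if allv.size > 1 else 0.0
            lab = ["duplication" if v > thr.dup_fold
                   else "deletion" if v < thr.del_fold else "neutral" for v in vals]
            runs = []
            for i, l in enumerate(lab):
                if runs and runs[-1][2] == l:
                    runs[-1][1] = i + 1
                else:
                    runs.append([i, i + 1, l])
            final = []
            for s, e, l in runs:
                if l != "neutral":
                    seg = vals[s:e]
                    if len(seg) >= 2 and np.ptp(seg) > 0:
                        p = stats.ttest_1samp(seg, 1.0).pvalue
                    else:
                        p = 2 * stats.norm.sf(abs(seg.mean() - 1) /
                                              np.sqrt(gv / len(seg))) if gv > 0 else 0.0
                    if p > thr.alpha:
                        l = "neutral"
                final.append((s, e, l))
            merged = []
            for s, e, l in final:
                if merged and merged[-1][2] == l:
                    merged[-1][1] = e
                else:
                    merged.append([s, e, l])
            expect = [(s * 5000, min(e * 5000, len(vals) * 5000), l)
                      for s, e, l in merged]
            assert [(s.start, s.stop, s.state) for s in got] == expect


class TestCopyNumber:
    def _recover(self, multiplicity, het=False, coverage=30.0, seed=21):
        cfg = sim.SimConfig(cassette_palindromic_units=0, chrom_length=60_000,
                            seed=seed)
        base, _, _ = sim.build_genomes(cfg)
        interval = ("Chr2", 30_000, 31_500)
        dup = sim.duplicate_region(base, *interval, n_extra=multiplicity - 1,
                                   dest_chrom="Chr3")
        source = [dup, base] if het else dup
        reads = sim.simulate_reads(source, "short_paired", coverage, seed=seed + 1)
        idx = ml.build_index(base)
        recs = ml.map_reads(reads, idx, seed=seed + 2)
        track = dc.normalize(dc.window_depth(recs, {c: len(s) for c, s in
                                                    base.sequences.items()},
                                             window=500), baseline="median")
        copies, _ = dc.estimate_copy_number(track, interval)
        return copies, track, interval

    def test_neutral_interval_estimates_one_copy(self, small_pair, sus_index,
                                                 short_reads_mapped):
        _, sus, _, _ = small_pair
        _, recs = short_reads_mapped
        track = dc.normalize(dc.window_depth(
            recs, {c: len(s) for c, s in sus.sequences.items()}, 1000),
            baseline="median")
        copies, zyg = dc.estimate_copy_number(track, ("Chr2", 30_000, 50_000))
        assert abs(copies - 1.0) < 0.25
        assert zyg == "na"

    @pytest.mark.parametrize("multiplicity", [2, 5, 22])
    def test_parameter_recovery_within_15_percent(self, multiplicity):
        copies, _, _ = self._recover(multiplicity)
        assert abs(copies - multiplicity) / multiplicity <= 0.15

    def test_heterozygote_estimates_half_of_homozygote_and_is_flagged(self):
        hom, _, _ = self._recover(20, seed=31)
        het, track, interval = self._recover(20, het=True, seed=33)
        assert 0.35 <= het / hom <= 0.65
        cohort = [hom, hom, hom, het]
        _, zyg = dc.estimate_copy_number(track, interval, cohort_copies=cohort)
        assert zyg == "het"

    def test_empty_interval_rejected(self):
        track = make_track([1.0] * 5)
        with pytest.raises(ValueError):
            dc.estimate_copy_number(track, ("Chr1", 100, 100))


def test_segments_tsv_round_trip(tmp_path):
    segs = [dc.CnvSegment("Chr1", 0, 5000, "neutral", 1.0, float("nan")),
            dc.CnvSegment("Chr1", 5000, 20_000, "duplication", 21.5, 1e-9)]
    path = tmp_path / "segs.tsv"
    dc.write_segments_tsv(segs, str(path))
    back = dc.read_segments_tsv(str(path))
    assert [(s.chrom, s.start, s.stop, s.state) for s in back] == \
        [(s.chrom, s.start, s.stop, s.state) for s in segs]
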