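"""Windowed read-depth profiling and per-sample CNV segment calling.

Depth is summarized in fixed windows (default 5 kb) as aligned bases per
window position, normalized to the genome-wide mean so that fold values read
directly as copy-number proxies.  Windows are labeled by fold thresholds
(deletion < 0.25x, duplication > 4x, both strict), adjacent same-state windows
are merged, and each non-neutral segment receives a two-sided one-sample
t-test of its windows' normalized depths against 1.0; calls that fail the
significance level are demoted to neutral.  Segment boundaries are window-
resolution by design — the scan "roughly calls regions" and breakpoint-precise
boundaries are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ThresholdConfig:
    """Fold and significance thresholds used across the pipeline."""

    del_fold: float = 0.25
    dup_fold: float = 4.0
    alpha: float = 0.01
    high_copy_fold: float = 20.0
    de_p: float = 0.01
    de_fc: float = 2.0

    def validate(self) -> None:
        if not (0 < self.del_fold < 1 < self.dup_fold < self.high_copy_fold):
            raise ValueError("need 0 < del_fold < 1 < dup_fold < high_copy_fold")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class DepthTrack:
    """Per-window depth values for a set of reference sequences."""

    window: int
    values: dict                 # ref -> float array (fold units)
    eff_lengths: dict = field(default_factory=dict)  # ref -> window lengths (bp)
    normalized: bool = False

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.values[r] for r in self.values]) \
            if self.values else np.empty(0)


def window_depth(alignments, ref_lengths: dict, window: int = 5000) -> DepthTrack:
    """Aligned bases per window / window size, from mapped alignment records.

    The trailing partial window of each reference is normalized by its actual
    length so its value remains a true fold depth.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    sums = {r: np.zeros((L + window - 1) // window) for r, L in ref_lengths.items()}
    eff = {}
    for r, L in ref_lengths.items():
        n = len(sums[r])
        eff[r] = np.full(n, float(window))
        if L % window:
            eff[r][-1] = L % window
    for rec in alignments:
        if not rec.mapped:
            continue
        bins = sums.get(rec.ref_name)
        if bins is None:
            continue
        for ref_off, _, ln in rec.aligned_blocks:
            start, stop = ref_off, min(ref_off + ln, ref_lengths[rec.ref_name])
            w0, w1 = start // window, (stop - 1) // window
            if w0 == w1:
                bins[w0] += stop - start
            else:
                bins[w0] += (w0 + 1) * window - start
                if w1 > w0 + 1:
                    bins[w0 + 1:w1] += window
                bins[w1] += stop - w1 * window
    values = {r: sums[r] / eff[r] for r in sums}
    return DepthTrack(window=window, values=values, eff_lengths=eff)


def normalize(track: DepthTrack, baseline: str = "mean") -> DepthTrack:
    """Divide every window by a genome-wide baseline depth.

    ``baseline="mean"`` (default) divides by the mean over all windows, so the
    output mean is exactly 1.  ``baseline="median"`` is the robust choice when
    an amplified region is a non-negligible fraction of the genome (as in
    scaled-down simulations): the two coincide when CNVs are rare.
    """
    allv = track.all_values()
    if allv.size == 0 or allv.mean() == 0:
        raise ValueError("cannot normalize an empty or all-zero track")
    m = float(np.median(allv)) if baseline == "median" else allv.mean()
    if m == 0:
        raise ValueError("zero baseline depth; genome mostly uncovered")
    return DepthTrack(window=track.window,
                      values={r: v / m for r, v in track.values.items()},
                      eff_lengths=dict(track.eff_lengths), normalized=True)


@dataclass
class CnvSegment:
    chrom: str
    start: int
    stop: int
    state: str  # deletion | neutral | duplication
    mean_norm_depth: float
    p_value: float = float("nan")


def _runs(labels: np.ndarray):
    """Yield (start_index, stop_index, label) runs of equal adjacent labels."""
    if len(labels) == 0:
        return
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(labels)]))
    for s, e in zip(starts, stops):
        yield int(s), int(e), labels[s]


def _segment_p(vals: np.ndarray, global_var: float) -> float:
    if len(vals) >= 2 and np.ptp(vals) > 0:
        return float(stats.ttest_1samp(vals, 1.0).pvalue)
    # normal approximation using the global window variance
    if global_var <= 0:
        return 0.0 if abs(vals.mean() - 1.0) > 0 else 1.0
    z = (vals.mean() - 1.0) / np.sqrt(global_var / max(len(vals), 1))
    return float(2 * stats.norm.sf(abs(z)))


def call_segments(track: DepthTrack, thresholds: ThresholdConfig | None = None):
    """Threshold, merge and significance-filter windows into CNV segments.

    Fold values exactly at a threshold are neutral (the state definitions are
    strict "below"/"above" inequalities).  Non-neutral segments with
    p > alpha are demoted to neutral and re-merged, so the emitted segments
    tile each reference without overlap.
    """
    if not track.normalized:
        raise ValueError("call_segments requires a normalized track")
    thr = thresholds or ThresholdConfig()
    thr.validate()
    allv = track.all_values()
    global_var = float(allv.var(ddof=1)) if allv.size > 1 else 0.0

    segments = []
    for chrom, vals in track.values.items():
        labels = np.full(len(vals), "neutral", dtype=object)
        labels[vals < thr.del_fold] = "deletion"
        labels[vals > thr.dup_fold] = "duplication"
        # significance demotion, then re-merge
        for s, e, lab in list(_runs(labels)):
            if lab == "neutral":
                continue
            if _segment_p(vals[s:e], global_var) > thr.alpha:
                labels[s:e] = "neutral"
        eff = track.eff_lengths.get(chrom)
        chrom_len = int(eff.sum()) if eff is not None else len(vals) * track.window
        for s, e, lab in _runs(labels):
            start = s * track.window
            stop = min(e * track.window, chrom_len)
            pv = _segment_p(vals[s:e], global_var) if lab != "neutral" else float("nan")
            segments.append(CnvSegment(chrom=chrom, start=start, stop=stop, state=lab,
                                       mean_norm_depth=float(vals[s:e].mean()),
                                       p_value=pv))
    return segments


def estimate_copy_number(track: DepthTrack, interval, background_fold: float = 1.0,
                         cohort_copies=None, het_band: float = 0.25):
    """Mean normalized depth over an interval as a copy-number estimate.

    ``interval`` is (chrom, start, stop), 0-based half-open.  When a cohort of
    copy estimates is supplied, zygosity is called ``hom`` near the cohort
    mode, ``het`` near half the mode, else ``na``; without a cohort it is
    ``na``.  ``background_fold`` rescales when the surrounding baseline is not
    1x.
    """
    chrom, start, stop = interval
    if stop <= start:
        raise ValueError("empty interval")
    if not track.normalized:
        raise ValueError("estimate_copy_number requires a normalized track")
    vals = track.values[chrom]
    w = track.window
    w0, w1 = start // w, (stop - 1) // w + 1
    weights = np.array([min(stop, (i + 1) * w) - max(start, i * w)
                        for i in range(w0, min(w1, len(vals)))], dtype=float)
    sel = vals[w0:min(w1, len(vals))]
    if sel.size == 0:
        raise ValueError("interval not covered by track")
    copies = float(np.average(sel, weights=weights)) / background_fold

    zygosity = "na"
    if cohort_copies is not None and len(cohort_copies) > 0:
        arr = np.asarray(cohort_copies, dtype=float)
        rounded = np.round(arr).astype(int)
        vals_, counts = np.unique(rounded, return_counts=True)
        mode = float(vals_[np.argmax(counts)])
        if mode > 2:  # a real amplification mode, not baseline
            if abs(copies - mode) <= het_band * mode:
                zygosity = "hom"
            elif abs(copies - mode / 2) <= het_band * mode / 2:
                zygosity = "het"
    return copies, zygosity


def write_segments_tsv(segments, path: str) -> None:
    """BED-like TSV, 1-based inclusive start on write (length = stop - start)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tstop\tstate\tmean_norm_depth\tp_value\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start + 1}\t{s.stop}\t{s.state}\t"
                     f"{s.mean_norm_depth:.4f}\t{s.p_value:.4g}\n")


def read_segments_tsv(path: str):
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chrom")
        for line in fh:
            c, a, b, st, d, p = line.rstrip("\n").split("\t")
            out.append(CnvSegment(chrom=c, start=int(a) - 1, stop=int(b), state=st,
                                  mean_norm_depth=float(d), p_value=float(p)))
    return out
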