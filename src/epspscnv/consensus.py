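"""Population-consensus CNV events and the duplication-event catalogue.

A consensus duplication event is a maximal genomic interval in which *every*
resistant sample carries an overlapping duplication segment and *no*
susceptible sample does (per-base semantics; any >= 1 bp overlap counts as
presence, matching the bedtools-intersect default).  Events are numbered
CNV1, CNV2, ... in genomic order and written with the reporting convention of
the published catalogue: 1-based start, inclusive stop, and
``length = stop - start``.  Internal coordinates stay 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .depthcnv import CnvSegment, ThresholdConfig


@dataclass
class CnvEvent:
    """One consensus duplication event, in reporting coordinates.

    ``start`` is 1-based, ``stop`` is the inclusive end position, and the
    catalogue's length column is ``stop - start`` (one less than the spanned
    base count) — the convention reproduced exactly by :func:`event_length`.
    """

    event_id: str
    seq_name: str
    start: int | None
    stop: int
    mean_depth: float
    per_sample_depths: dict = field(default_factory=dict)
    region: str = ""
    seq_class: str = ""
    coords_uncertain: bool = False

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def stop0(self) -> int:
        return self.stop


def event_length(event: CnvEvent) -> int:
    """Catalogue length column: stop - start (NOT stop - start + 1)."""
    if event.start is None:
        raise ValueError(f"{event.event_id} has an uncertain start coordinate")
    if event.stop < event.start:
        raise ValueError("stop must be >= start")
    return event.stop - event.start


DEFAULT_CLASS_PATTERNS = (("pseudomolecule", r"^Chr"), ("scaffold", r"^Scaffold"))


def seq_class_of(name: str, patterns=DEFAULT_CLASS_PATTERNS) -> str:
    for cls, pat in patterns:
        if re.match(pat, name, flags=re.IGNORECASE):
            return cls
    return "scaffold"


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def consensus_events(R_segments, S_segments, thresholds: ThresholdConfig | None = None,
                     min_overlap_frac: float = 0.0,
                     class_patterns=DEFAULT_CLASS_PATTERNS):
    """Group-exclusive duplication intervals across the two panels.

    ``R_segments`` / ``S_segments`` are per-sample lists of
    :class:`~epspscnv.depthcnv.CnvSegment`.  A base belongs to an event iff
    every resistant sample has a duplication segment covering it and no
    susceptible sample does; maximal runs of such bases become events, so each
    event interval is the intersection of the resistant samples' overlapping
    segments clipped by any susceptible duplication.  With
    ``min_overlap_frac > 0``, events where some resistant sample's overlap is
    below that fraction of the event length are additionally dropped.
    """
    if not R_segments or not S_segments:
        raise ValueError("both panels need at least one sample")
    dup = lambda segs: [s for s in segs if s.state == "duplication"]
    chroms = sorted({s.chrom for sample in list(R_segments) + list(S_segments)
                     for s in sample}, key=_natural_key)
    raw = []
    for chrom in chroms:
        r_by_sample = [[(s.start, s.stop, s.mean_norm_depth) for s in dup(sample)
                        if s.chrom == chrom] for sample in R_segments]
        s_ivs = [(s.start, s.stop) for sample in S_segments for s in dup(sample)
                 if s.chrom == chrom]
        if any(len(ivs) == 0 for ivs in r_by_sample):
            continue
        bps = sorted({p for ivs in r_by_sample for a, b, _ in ivs for p in (a, b)}
                     | {p for a, b in s_ivs for p in (a, b)})
        qualifying = []
        for a, b in zip(bps, bps[1:]):
            mid_ok = all(any(x <= a and b <= y for x, y, _ in ivs)
                         for ivs in r_by_sample)
            s_free = not any(x < b and a < y for x, y in s_ivs)
            if mid_ok and s_free:
                qualifying.append((a, b))
        # merge adjacent qualifying elementary intervals
        merged = []
        for a, b in qualifying:
            if merged and merged[-1][1] == a:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            depths = {}
            for si, ivs in enumerate(r_by_sample):
                ws, vs = [], []
                for x, y, d in ivs:
                    ov = min(b, y) - max(a, x)
                    if ov > 0:
                        ws.append(ov)
                        vs.append(d)
                depths[f"R{si + 1}"] = float(np.average(vs, weights=ws)) if vs else float("nan")
            if min_overlap_frac > 0:
                ok = all(sum(min(b, y) - max(a, x) for x, y, _ in ivs
                             if min(b, y) > max(a, x)) >= min_overlap_frac * (b - a)
                         for ivs in r_by_sample)
                if not ok:
                    continue
            raw.append((chrom, a, b, depths))

    raw.sort(key=lambda t: (_natural_key(t[0]), t[1]))
    events = []
    for i, (chrom, a, b, depths) in enumerate(raw, start=1):
        vals = [v for v in depths.values() if not np.isnan(v)]
        events.append(CnvEvent(
            event_id=f"CNV{i}", seq_name=chrom, start=a + 1, stop=b,
            mean_depth=float(np.mean(vals)) if vals else float("nan"),
            per_sample_depths=depths,
            seq_class=seq_class_of(chrom, class_patterns)))
    return events


def classify_and_summarize(events, thresholds: ThresholdConfig | None = None,
                           exclude_regions=("A", "B")) -> dict:
    """Counts by sequence class plus the high-copy subset of the catalogue.

    ``high_copy_other_ids`` lists events above ``high_copy_fold`` that are not
    labeled as a designated region of interest (Region-A/B by default).
    """
    thr = thresholds or ThresholdConfig()
    high = [e for e in events if e.mean_depth > thr.high_copy_fold]
    return {
        "n_total": len(events),
        "n_pseudomolecule": sum(e.seq_class == "pseudomolecule" for e in events),
        "n_scaffold": sum(e.seq_class == "scaffold" for e in events),
        "high_copy_ids": [e.event_id for e in high],
        "high_copy_other_ids": [e.event_id for e in high
                                if e.region not in exclude_regions],
        "region_events": {e.region: e.event_id for e in events if e.region},
    }


# ---------------------------------------------------------------------------
# catalogue I/O

CATALOG_COLUMNS = ("event_id", "seq_name", "start", "stop", "length",
                   "mean_depth_gr", "region", "coords_uncertain")


def write_catalog(events, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for e in events:
            length = "" if e.start is None else str(event_length(e))
            fh.write("\t".join([
                e.event_id, e.seq_name,
                "" if e.start is None else str(e.start), str(e.stop), length,
                f"{e.mean_depth:.2f}", e.region, str(int(e.coords_uncertain)),
            ]) + "\n")


def read_catalog(path_or_handle) -> list:
    """Read a duplication-event catalogue TSV (reporting coordinates)."""
    events = []
    close = False
    fh = path_or_handle
    if isinstance(path_or_handle, str):
        fh = open(path_or_handle)
        close = True
    try:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                continue
            get = lambda c, default="": f[idx[c]] if c in idx and idx[c] < len(f) else default
            start = get("start")
            events.append(CnvEvent(
                event_id=get("event_id"), seq_name=get("seq_name"),
                start=int(start) if start else None, stop=int(get("stop")),
                mean_depth=float(get("mean_depth_gr") or "nan"),
                region=get("region"),
                seq_class=seq_class_of(get("seq_name")),
                coords_uncertain=get("coords_uncertain") in ("1", "True", "true")))
    finally:
        if close:
            fh.close()
    return events


def load_reference_catalog() -> list:
    """The bundled catalogue of duplication events shared by all resistant
    individuals of a glyphosate-resistant goosegrass resequencing panel."""
    ref = resources.files("epspscnv.data").joinpath("gr_cnv_catalog.tsv")
    with ref.open() as fh:
        return read_catalog(fh)


def write_events_bed(events, path: str) -> None:
    with open(path, "w") as fh:
        for e in events:
            if e.start is None:
                continue
            fh.write(f"{e.seq_name}\t{e.start0}\t{e.stop0}\t{e.event_id}\n")
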