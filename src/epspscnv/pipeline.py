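"""End-to-end orchestration: simulate -> map -> depth -> consensus -> cassette
-> repeats -> expression, with a truth-comparison report.

Every stage writes its outputs under the run directory and the final
:class:`RunReport` is serialized as JSON with stable key order, so a fixed
seed yields byte-identical reports.  The top-level seed fans out to per-stage
seeds through a stage-name hash, making each stage independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import cassette as cas
from . import consensus as cons
from . import depthcnv as dc
from . import expression as expr
from . import maplite as ml
from . import repeats as rp
from . import simulate as sim


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed < 2**31 from the master seed and stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    n_resistant: int = 3
    n_susceptible: int = 3
    short_coverage: float = 10.0
    long_coverage: float = 30.0
    window: int = 1000          # finer than the 5 kb analysis default, matching
    min_anchor: int = 100       # the desk-scale region lengths of SimConfig
    depth_baseline: str = "median"
    thresholds: dc.ThresholdConfig = field(default_factory=dc.ThresholdConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        sim_d = d.get("sim", {})
        cfg.sim = sim.SimConfig.from_dict(sim_d)
        thr_d = d.get("thresholds", {})
        known = {f.name for f in dataclasses.fields(dc.ThresholdConfig)}
        cfg.thresholds = dc.ThresholdConfig(**{k: v for k, v in thr_d.items() if k in known})
        for k in ("n_resistant", "n_susceptible", "short_coverage", "long_coverage",
                  "window", "min_anchor", "depth_baseline"):
            if k in d:
                setattr(cfg, k, d[k])
        return cfg

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "thresholds": dataclasses.asdict(self.thresholds),
            "n_resistant": self.n_resistant, "n_susceptible": self.n_susceptible,
            "short_coverage": self.short_coverage, "long_coverage": self.long_coverage,
            "window": self.window, "min_anchor": self.min_anchor,
            "depth_baseline": self.depth_baseline,
        }


@dataclass
class RunReport:
    config: dict
    outputs: dict
    metrics: dict

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "outputs": self.outputs,
                           "metrics": self.metrics}, indent=2, sort_keys=True)


def _reciprocal_overlap(a, b) -> float:
    ov = max(0, min(a[2], b[2]) - max(a[1], b[1]))
    if a[0] != b[0] or ov == 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))


def recall_precision(events, truth_intervals, min_reciprocal: float = 0.5):
    """Event-level precision/recall against truth CNV intervals."""
    truth = [(c, a, b) for c, a, b, _ in truth_intervals]
    ev = [(e.seq_name, e.start0, e.stop0) for e in events if e.start is not None]
    tp_truth = sum(any(_reciprocal_overlap(t, e) >= min_reciprocal for e in ev)
                   for t in truth)
    tp_ev = sum(any(_reciprocal_overlap(t, e) >= min_reciprocal for t in truth)
                for e in ev)
    recall = tp_truth / len(truth) if truth else float("nan")
    precision = tp_ev / len(ev) if ev else float("nan")
    return recall, precision


def run_pipeline(config: PipelineConfig | dict | None = None, seed: int = 0,
                 outdir: str = "run_out", log=print) -> RunReport:
    """Execute all stages on simulated data and score against truth."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    os.makedirs(outdir, exist_ok=True)
    outputs, metrics = {}, {}
    stage = "simulate"
    try:
        cfg = dataclasses.replace(config.sim, seed=stage_seed(seed, "simulate"))
        sus, res, truth = sim.build_genomes(cfg)
        outputs.update(sim.write_outputs(sus, None, truth, outdir))
        sim.write_outputs(res, None, None, outdir)
        log(f"[simulate] susceptible={sus.total_length()} bp "
            f"resistant={res.total_length()} bp junctions={len(truth.junctions)}")

        stage = "map"
        index = ml.build_index(sus)
        ref_lengths = {c: len(s) for c, s in sus.sequences.items()}
        panels = {}
        for group, genome, n in (("R", res, config.n_resistant),
                                 ("S", sus, config.n_susceptible)):
            for i in range(n):
                name = f"{group}{i + 1}"
                haps = [genome, sus] if (group == "R" and config.sim.het) else genome
                reads = sim.simulate_reads(haps, "short_paired", config.short_coverage,
                                           seed=stage_seed(seed, f"reads:{name}"))
                recs = ml.map_reads(reads, index, seed=stage_seed(seed, f"map:{name}"))
                panels[name] = recs
                log(f"[map] {name}: {len(reads.reads)} pairs, "
                    f"{sum(r.mapped for r in recs)} mapped records")

        stage = "depth"
        seg_by_sample = {}
        for name, recs in panels.items():
            track = dc.normalize(dc.window_depth(recs, ref_lengths, config.window),
                                 baseline=config.depth_baseline)
            segs = dc.call_segments(track, config.thresholds)
            seg_by_sample[name] = segs
            dc.write_segments_tsv(segs, os.path.join(outdir, f"segments_{name}.tsv"))
            if name == "R1":
                r1_track = track
        log(f"[depth] {len(panels)} samples segmented")

        stage = "consensus"
        R = [seg_by_sample[n] for n in sorted(seg_by_sample) if n.startswith("R")]
        S = [seg_by_sample[n] for n in sorted(seg_by_sample) if n.startswith("S")]
        events = cons.consensus_events(R, S, config.thresholds)
        cat = os.path.join(outdir, "consensus_events.tsv")
        cons.write_catalog(events, cat)
        outputs["consensus"] = cat
        recall, precision = recall_precision(events, truth.cnv_intervals)
        metrics["consensus_recall"] = recall
        metrics["consensus_precision"] = precision
        metrics["n_consensus_events"] = len(events)
        log(f"[consensus] {len(events)} events, recall={recall} precision={precision}")

        stage = "copy_number"
        copy_errs, copies = [], []
        for chrom, a, b, mult in truth.cnv_intervals:
            cp, _ = dc.estimate_copy_number(r1_track, (chrom, a, b))
            copies.append(cp)
            if mult > 0:
                copy_errs.append(abs(cp - mult) / mult)
        metrics["copy_number_estimates"] = [round(c, 3) for c in copies]
        metrics["copy_number_mean_rel_error"] = (float(np.mean(copy_errs))
                                                 if copy_errs else float("nan"))

        stage = "cassette"
        c = config.sim.cassette_palindromic_units
        if c > 0:
            long_reads = sim.simulate_reads(res, "long", config.long_coverage,
                                            seed=stage_seed(seed, "reads:long"))
            res_index = ml.build_index(res)
            recs = ml.map_reads(long_reads, res_index,
                                seed=stage_seed(seed, "map:long"))
            juncs = [(chrom, nm, pos) for nm, chrom, pos in truth.junctions]
            supports = cas.count_junction_support(recs, juncs,
                                                  min_anchor=config.min_anchor)
            call = cas.infer_architecture(supports)
            metrics["junction_support"] = {s.name: s.n_spanning for s in supports}
        else:
            supports, call = [], "unsupported"
            metrics["junction_support"] = {}
        metrics["architecture_call"] = call
        log(f"[cassette] architecture={call} supports={metrics['junction_support']}")

        stage = "repeats"
        tel = []
        for chrom, s in sus.sequences.items():
            tel += rp.find_motif_arrays(s, config.sim.telomere_motif, chrom=chrom)
        rp.write_arrays_bed(tel, os.path.join(outdir, "telomere_arrays.bed"))
        metrics["n_telomere_arrays"] = len(tel)
        # recover the ST unit from the first native subtelomere array
        st_truth = truth.repeat_arrays[0]
        window = sus.sequences[st_truth[0]][st_truth[1]:st_truth[2]]
        det = rp.detect_unit(window, min_period=4)
        metrics["detected_st_unit_length"] = det[0] if det else None
        units = {f"{chrom}": truth.domains[f"st_unit_{chrom}"]
                 for chrom in sus.sequences}
        if c > 0:
            units["Cassette"] = truth.domains["st_unit_Chr1"]
        dm = rp.identity_distance_matrix(units)
        nwk = rp.nj_tree(dm)
        with open(os.path.join(outdir, "st_units.nwk"), "w") as fh:
            fh.write(nwk + "\n")
        metrics["st_tree"] = nwk
        log(f"[repeats] {len(tel)} telomere arrays, ST unit={metrics['detected_st_unit_length']}")

        stage = "expression"
        de_rows = sim.simulate_de_table({"A": (4, 1), "B": (1, 3)},
                                        seed=stage_seed(seed, "de"))
        de_path = os.path.join(outdir, "de_table.tsv")
        with open(de_path, "w") as fh:
            fh.write("gene_id\tlabel\tregion\tlog2fc\tp_value\n")
            for r in de_rows:
                fh.write(f"{r['gene_id']}\t{r['label']}\t{r['region']}\t"
                         f"{r['log2fc']:.4f}\t{r['p_value']:.4g}\n")
        records = expr.read_de_table(de_path)
        summary = expr.summarize_de(records, config.thresholds)
        expr.write_summary_tsv(summary, os.path.join(outdir, "de_summary.tsv"))
        metrics["de_summary"] = {k: list(v) for k, v in summary.items()}
        log(f"[expression] {metrics['de_summary']}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # paths are reported relative to the run directory so identical seeds give
    # byte-identical reports regardless of where the run lives
    outputs = {k: os.path.relpath(v, outdir) for k, v in outputs.items()}
    report = RunReport(config=config.to_dict(), outputs=outputs, metrics=metrics)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json() + "\n")
    return report
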