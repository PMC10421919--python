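"""Synthetic genomes and read sets with machine-readable ground truth.

This module builds a susceptible/resistant pair of multi-chromosome plant-style
genomes.  Chromosome ends carry Arabidopsis-type telomere arrays (TTTAGGG) and
divergent per-chromosome subtelomeric (ST) tandem-repeat arrays.  One
chromosome holds two interstitial single-copy regions: Region-A (containing a
marker gene standing in for *EPSPS*) and Region-B, separated by a configurable
gap.  The resistant haplotype additionally carries, at one chromosome end, a
tandem array of palindromic "cassette" units

    [A + B(I) forward] + [small ST array: fwd then rev-comp units] + [A + B(I) rev-comp]

flanked (and, by default, separated) by larger ST arrays, where B(I) denotes
Region-B with the short Region-I insert near its 5' end.  Every junction
between adjacent cassette domains, every expected copy-number interval and
every repeat array is recorded in a :class:`Truth` object so downstream CNV
calling, junction counting and repeat detection can be scored against known
answers.

All internal coordinates are 0-based half-open; conversion to the 1-based
reporting convention happens only in report writers.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA sequence of length ``n``."""
    return rng.choice(_BASES, size=n).tobytes().decode()


def mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Apply random substitutions to a fraction of positions (no indels)."""
    if fraction <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = int(round(fraction * len(seq)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class SimConfig:
    """Architecture and size parameters of the simulated genome pair.

    Sequence-architecture constants default to the biological values of the
    system being emulated (telomere motif TTTAGGG, 451 bp subtelomeric unit,
    small ST array of 12 forward + 31 reverse-complement copies, palindromic
    cassette with ~23-fold Region-A/B multiplicity).  Size parameters
    (chromosome and region lengths, flanking-array copy numbers) default to
    desk-scale values so a full simulate/map/call cycle runs in seconds;
    they scale up by configuration only.
    """

    n_chromosomes: int = 3
    chrom_length: int = 150_000
    telomere_motif: str = "TTTAGGG"
    telomere_copies_per_end: int = 100
    st_unit_length: int = 451
    st_native_copies: int = 20
    st_unit_divergence_per_chrom: float = 0.05
    regionA_length: int = 5_000
    regionB_length: int = 4_000
    regionI_length: int = 800
    regionI_offset: int = 400
    regionAB_gap: int = 15_000
    cassette_palindromic_units: int = 11
    st_small_fwd: int = 12
    st_small_rev: int = 31
    st_large_fwd: int = 40
    st_large_rev: int = 60
    arm_capacity_bp: int | None = None
    shared_flanks: bool = True
    het: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "telomere_copies_per_end",
            "st_unit_length", "st_native_copies", "regionA_length",
            "regionB_length", "regionI_length", "regionAB_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.cassette_palindromic_units < 0:
            raise ValueError("cassette_palindromic_units must be >= 0")
        if not (0.0 <= self.st_unit_divergence_per_chrom <= 0.15):
            raise ValueError("st_unit_divergence_per_chrom must lie in [0, 0.15]")
        if not (0 <= self.regionI_offset <= self.regionB_length):
            raise ValueError("regionI_offset must lie within Region-B")
        if not set(self.telomere_motif) <= set("ACGT") or not self.telomere_motif:
            raise ValueError("telomere_motif must be a non-empty ACGT string")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Feature:
    name: str
    chrom: str
    start: int
    stop: int
    orientation: str  # '+' or '-'
    cls: str  # telomere | subtelomere | regionA | regionB | regionI | cassette_unit


@dataclass
class GenomeModel:
    """Named chromosome sequences plus annotated architectural features."""

    sequences: dict
    features: list = field(default_factory=list)
    ploidy_labels: list = field(default_factory=lambda: ["hap1"])
    name: str = "genome"

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def check(self) -> None:
        for f in self.features:
            L = len(self.sequences[f.chrom])
            if not (0 <= f.start <= f.stop <= L):
                raise ValueError(f"feature {f.name} out of bounds on {f.chrom}")


@dataclass
class Truth:
    """Ground truth emitted by the simulator for downstream scoring."""

    cnv_intervals: list = field(default_factory=list)  # (chrom, start, stop, multiplicity)
    junctions: list = field(default_factory=list)      # (name, chrom, position)
    repeat_arrays: list = field(default_factory=list)  # (chrom, start, stop, unit_len, n_fwd, n_rev)
    read_origins: list = field(default_factory=list)   # ReadOrigin
    domains: dict = field(default_factory=dict)        # name -> sequence


@dataclass
class ReadOrigin:
    read_id: str
    haplotype: str
    chrom: str
    start: int
    stop: int
    strand: str


@dataclass
class Read:
    id: str
    sequence: str
    mate: str | None = None


@dataclass
class ReadSet:
    reads: list
    mode: str  # 'long' | 'short_paired'
    coverage: float
    origins: list = field(default_factory=list)

    def n_bases(self) -> int:
        return sum(len(r.sequence) + (len(r.mate) if r.mate else 0) for r in self.reads)


def _st_array(unit: str, n_fwd: int, n_rev: int) -> str:
    return unit * n_fwd + revcomp(unit) * n_rev


def build_genomes(config: SimConfig):
    """Build the susceptible/resistant genome pair and its ground truth.

    Returns ``(susceptible, resistant, truth)``.  The two genomes are
    byte-identical except for the cassette insertion at the subtelomere of the
    carrier chromosome (the chromosome holding the native Region-A/B).  With
    ``cassette_palindromic_units == 0`` the genomes are identical and the
    truth carries no cassette junctions.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    motif = cfg.telomere_motif
    tel_len = len(motif) * cfg.telomere_copies_per_end
    master_unit = random_seq(rng, cfg.st_unit_length)
    st_len = cfg.st_unit_length * cfg.st_native_copies

    region_a = random_seq(rng, cfg.regionA_length)
    region_b = random_seq(rng, cfg.regionB_length)
    region_i = random_seq(rng, cfg.regionI_length)

    interior_len = cfg.chrom_length - 2 * (tel_len + st_len)
    lead, tail = 2_000, 2_000
    carrier_core = lead + cfg.regionA_length + cfg.regionAB_gap + cfg.regionB_length + tail
    if interior_len <= 0:
        raise ValueError("chrom_length too short for telomere + subtelomere ends")
    if carrier_core > interior_len:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} cannot host Region-A, the A-B gap "
            f"and Region-B (needs {carrier_core + 2 * (tel_len + st_len)})"
        )

    sus = GenomeModel(sequences={}, name="susceptible")
    truth = Truth(domains={
        "A": region_a, "B": region_b, "I": region_i,
        "telomere_motif": motif, "st_master_unit": master_unit,
    })
    st_units = {}
    carrier = "Chr1"

    for ci in range(cfg.n_chromosomes):
        chrom = f"Chr{ci + 1}"
        unit = mutate(master_unit, cfg.st_unit_divergence_per_chrom, rng) if ci else master_unit
        st_units[chrom] = unit
        truth.domains[f"st_unit_{chrom}"] = unit

        parts, feats, pos = [], [], 0

        def add(seq, name=None, cls=None, ori="+"):
            nonlocal pos
            parts.append(seq)
            if cls is not None:
                feats.append(Feature(name, chrom, pos, pos + len(seq), ori, cls))
            pos += len(seq)

        add(revcomp(motif) * cfg.telomere_copies_per_end, "telomere_5p", "telomere", ori="-")
        add(unit * cfg.st_native_copies, "subtelomere_5p", "subtelomere")
        truth.repeat_arrays.append((chrom, pos - st_len, pos, cfg.st_unit_length,
                                    cfg.st_native_copies, 0))
        if chrom == carrier:
            add(random_seq(rng, lead))
            add(region_a, "regionA", "regionA")
            a_iv = (feats[-1].start, feats[-1].stop)
            add(random_seq(rng, cfg.regionAB_gap))
            add(region_b, "regionB", "regionB")
            b_iv = (feats[-1].start, feats[-1].stop)
            add(random_seq(rng, interior_len - carrier_core + tail))
        else:
            add(random_seq(rng, interior_len))
        add(unit * cfg.st_native_copies, "subtelomere_3p", "subtelomere")
        truth.repeat_arrays.append((chrom, pos - st_len, pos, cfg.st_unit_length,
                                    cfg.st_native_copies, 0))
        add(motif * cfg.telomere_copies_per_end, "telomere_3p", "telomere")

        sus.sequences[chrom] = "".join(parts)
        sus.features.extend(feats)

    c = cfg.cassette_palindromic_units
    mult = 1 + 2 * c
    truth.cnv_intervals.append((carrier, a_iv[0], a_iv[1], mult))
    truth.cnv_intervals.append((carrier, b_iv[0], b_iv[1], mult))

    res = GenomeModel(sequences=dict(sus.sequences),
                      features=[dataclasses.replace(f) for f in sus.features],
                      name="resistant")

    if c > 0:
        unit = st_units[carrier]
        b1 = region_b[:cfg.regionI_offset]
        b2 = region_b[cfg.regionI_offset:]
        fusion = region_a + b1 + region_i + b2
        small = _st_array(unit, cfg.st_small_fwd, cfg.st_small_rev)
        large = _st_array(unit, cfg.st_large_fwd, cfg.st_large_rev)
        truth.domains["cassette_fusion"] = fusion

        # insertion point: between the 3' native subtelomere array and telomere
        chrom_seq = res.sequences[carrier]
        ins_at = len(chrom_seq) - tel_len
        if cfg.shared_flanks:
            unit_block = fusion + small + revcomp(fusion) + large
            insert = large + unit_block * c
        else:
            unit_block = large + fusion + small + revcomp(fusion) + large
            insert = unit_block * c
        if cfg.arm_capacity_bp is not None and len(insert) > cfg.arm_capacity_bp:
            raise ValueError(
                f"cassette insert ({len(insert)} bp) exceeds the host chromosome "
                f"arm capacity ({cfg.arm_capacity_bp} bp); reduce "
                "cassette_palindromic_units or the ST flank copy numbers"
            )

        la, lb1, li, lb2 = len(region_a), len(b1), len(region_i), len(b2)
        lf, lsm, llg = len(fusion), len(small), len(large)
        sm_flip = cfg.st_small_fwd * cfg.st_unit_length

        def fwd_junctions(p0):
            return [("STs-A", p0), ("A-B", p0 + la), ("B-I", p0 + la + lb1),
                    ("I-B", p0 + la + lb1 + li), ("B-ST", p0 + lf)]

        def rev_junctions(q0):
            # rc(fusion) = rc(b2) + rc(I) + rc(b1) + rc(A)
            return [("B-ST", q0), ("I-B", q0 + lb2), ("B-I", q0 + lb2 + li),
                    ("A-B", q0 + lb2 + li + lb1), ("STs-A", q0 + lf)]

        juncs = []
        for u in range(c):
            if cfg.shared_flanks:
                p0 = ins_at + llg + u * (lf + lsm + lf + llg)
            else:
                p0 = ins_at + llg + u * (llg + lf + lsm + lf + llg)
            juncs += fwd_junctions(p0)
            juncs.append(("INV", p0 + lf + sm_flip))
            juncs += rev_junctions(p0 + lf + lsm)
            res.features.append(Feature("cassette_unit", carrier, p0,
                                        p0 + lf + lsm + lf, "+", "cassette_unit"))
            res.features.append(Feature("regionA", carrier, p0, p0 + la, "+", "regionA"))
            res.features.append(Feature("regionB", carrier, p0 + la,
                                        p0 + lf, "+", "regionB"))
            res.features.append(Feature("regionI", carrier, p0 + la + lb1,
                                        p0 + la + lb1 + li, "+", "regionI"))
            rv0 = p0 + lf + lsm
            res.features.append(Feature("regionB", carrier, rv0, rv0 + lb2 + li + lb1,
                                        "-", "regionB"))
            res.features.append(Feature("regionA", carrier, rv0 + lf - la,
                                        rv0 + lf, "-", "regionA"))
            truth.repeat_arrays.append((carrier, p0 + lf, p0 + lf + lsm,
                                        cfg.st_unit_length, cfg.st_small_fwd,
                                        cfg.st_small_rev))

        n_large = c + 1 if cfg.shared_flanks else 2 * c
        for u in range(n_large):
            if cfg.shared_flanks:
                g0 = ins_at + u * (llg + lf + lsm + lf)
            else:
                g0 = ins_at + (u // 2) * (llg + lf + lsm + lf + llg) + (u % 2) * (llg + lf + lsm + lf)
            res.features.append(Feature("cassette_large_st", carrier, g0, g0 + llg,
                                        "+", "subtelomere"))
            truth.repeat_arrays.append((carrier, g0, g0 + llg, cfg.st_unit_length,
                                        cfg.st_large_fwd, cfg.st_large_rev))

        res.sequences[carrier] = chrom_seq[:ins_at] + insert + chrom_seq[ins_at:]
        # shift pre-existing features located at/after the insertion point
        for f in res.features:
            if f.chrom == carrier and f.cls in ("telomere",) and f.start >= ins_at \
                    and f.name == "telomere_3p":
                f.start += len(insert)
                f.stop += len(insert)
        truth.junctions = [(nm, carrier, p) for nm, p in juncs]

    sus.check()
    res.check()
    return sus, res, truth


# ---------------------------------------------------------------------------
# read simulation

DEFAULT_LONG = {"median": 12_000, "sigma": 0.35, "min_length": 500}
DEFAULT_SHORT = {"read_length": 150, "insert_mean": 400, "insert_sd": 40}


def simulate_reads(genome, mode: str, coverage: float, length_params: dict | None = None,
                   seed: int = 0, error_rate: float = 0.0) -> ReadSet:
    """Draw error-free (by default) reads uniformly from one or more haplotypes.

    ``genome`` may be a single :class:`GenomeModel` or a sequence of haplotype
    models; reads are drawn from haplotypes with equal probability, so a locus
    present on only one of two haplotypes receives half the genome-wide depth
    (the mechanism behind the heterozygote half-depth signal).  ``coverage`` is
    the expected genome-wide fold depth relative to the mean haplotype length.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if mode not in ("long", "short_paired"):
        raise ValueError(f"unknown mode {mode!r}")
    haps = [genome] if isinstance(genome, GenomeModel) else list(genome)
    labels = [f"hap{i + 1}:{g.name}" for i, g in enumerate(haps)]
    rng = np.random.default_rng(seed)
    params = dict(DEFAULT_LONG if mode == "long" else DEFAULT_SHORT)
    params.update(length_params or {})

    target = coverage * (sum(g.total_length() for g in haps) / len(haps))
    reads, origins = [], []
    drawn = 0
    i = 0
    mu = math.log(params.get("median", 12_000)) if mode == "long" else 0.0
    while drawn < target:
        hi = int(rng.integers(len(haps)))
        g = haps[hi]
        chroms = list(g.sequences)
        lens = np.array([len(g.sequences[ch]) for ch in chroms], dtype=float)
        ch = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        seq = g.sequences[ch]
        strand = "+" if rng.integers(2) == 0 else "-"
        rid = f"r{i:07d}"
        if mode == "long":
            rl = int(rng.lognormal(mu, params["sigma"]))
            rl = max(params["min_length"], min(rl, len(seq)))
            start = int(rng.integers(0, len(seq) - rl + 1))
            frag = seq[start:start + rl]
            rd = frag if strand == "+" else revcomp(frag)
            if error_rate > 0:
                rd = mutate(rd, error_rate, rng)
            reads.append(Read(rid, rd))
            origins.append(ReadOrigin(rid, labels[hi], ch, start, start + rl, strand))
            drawn += rl
        else:
            rl = params["read_length"]
            ins = max(2 * rl, int(round(rng.normal(params["insert_mean"],
                                                   params["insert_sd"]))))
            ins = min(ins, len(seq))
            start = int(rng.integers(0, len(seq) - ins + 1))
            frag = seq[start:start + ins]
            if strand == "-":
                frag = revcomp(frag)
            r1, r2 = frag[:rl], revcomp(frag[-rl:])
            if error_rate > 0:
                r1, r2 = mutate(r1, error_rate, rng), mutate(r2, error_rate, rng)
            reads.append(Read(rid, r1, r2))
            if strand == "+":
                origins.append(ReadOrigin(rid + "/1", labels[hi], ch, start, start + rl, "+"))
                origins.append(ReadOrigin(rid + "/2", labels[hi], ch, start + ins - rl,
                                          start + ins, "-"))
            else:
                origins.append(ReadOrigin(rid + "/1", labels[hi], ch, start + ins - rl,
                                          start + ins, "-"))
                origins.append(ReadOrigin(rid + "/2", labels[hi], ch, start, start + rl, "+"))
            drawn += 2 * rl
        i += 1
    return ReadSet(reads=reads, mode=mode, coverage=coverage, origins=origins)


def simulate_de_table(regions: dict, effect_log2fc: float = 5.0, n_null: int = 20,
                      seed: int = 0):
    """Emit a per-gene differential-expression table with configured effects.

    ``regions`` maps region label -> ``(n_overexpressed, n_unchanged)`` gene
    counts; over-expressed genes receive ``effect_log2fc`` with tiny p-values,
    unchanged genes (within the region and the ``n_null`` background genes)
    draw log2 fold-changes around 0 and uniform null p-values.  Returns a
    list of dicts with keys gene_id, label, region, log2fc, p_value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region, (n_up, n_flat) in regions.items():
        for j in range(n_up + n_flat):
            up = j < n_up
            rows.append({
                "gene_id": f"g_{region}{j}", "label": f"{region}{j}", "region": region,
                "log2fc": float(rng.normal(effect_log2fc, 0.5)) if up
                else float(rng.normal(0, 0.3)),
                "p_value": float(10 ** rng.uniform(-14, -8)) if up
                else float(rng.uniform()),
            })
    for j in range(n_null):
        rows.append({
            "gene_id": f"g_null{j}", "label": f"null{j}", "region": "other",
            "log2fc": float(rng.normal(0, 0.3)),
            "p_value": float(rng.uniform()),
        })
    return rows


def duplicate_region(genome: GenomeModel, chrom: str, start: int, stop: int,
                     n_extra: int, dest_chrom: str | None = None) -> GenomeModel:
    """Return a copy of ``genome`` with ``n_extra`` additional copies of a region.

    The extra copies are appended to ``dest_chrom`` (default: the source
    chromosome), modelling a trans-duplication; the source interval itself is
    untouched, so reads from all copies map back to the single reference copy.
    """
    if not (0 <= start < stop <= len(genome.sequences[chrom])):
        raise ValueError("interval out of bounds")
    dest = dest_chrom or chrom
    dup = genome.sequences[chrom][start:stop]
    out = GenomeModel(sequences=dict(genome.sequences),
                      features=list(genome.features), name=genome.name + "_dup")
    out.sequences[dest] = out.sequences[dest] + dup * n_extra
    return out


# ---------------------------------------------------------------------------
# file output / round trip

def _write_fasta(path: str, sequences: dict, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            s = sequences[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path: str) -> dict:
    out, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_outputs(genome: GenomeModel, reads: ReadSet | None, truth: Truth | None,
                  directory: str) -> dict:
    """Write FASTA / FASTQ / BED / TSV outputs; returns a map of written paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {}

    fa = os.path.join(directory, f"{genome.name}.fasta")
    _write_fasta(fa, genome.sequences)
    paths["fasta"] = fa

    if reads is not None:
        fq = os.path.join(directory, f"reads_{reads.mode}.fastq")
        with open(fq, "w") as fh:
            for r in reads.reads:
                if r.mate is None:
                    fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
                else:
                    fh.write(f"@{r.id}/1\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
                    fh.write(f"@{r.id}/2\n{r.mate}\n+\n{'I' * len(r.mate)}\n")
        paths["fastq"] = fq

    if truth is not None:
        bed = os.path.join(directory, "truth_cnv.bed")
        with open(bed, "w") as fh:
            for chrom, start, stop, m in truth.cnv_intervals:
                fh.write(f"{chrom}\t{start}\t{stop}\tmult={m}\n")
        paths["cnv_bed"] = bed

        rbed = os.path.join(directory, "truth_repeats.bed")
        with open(rbed, "w") as fh:
            for chrom, start, stop, ul, nf, nr in truth.repeat_arrays:
                fh.write(f"{chrom}\t{start}\t{stop}\tunit={ul};fwd={nf};rev={nr}\n")
        paths["repeats_bed"] = rbed

        jtsv = os.path.join(directory, "truth_junctions.tsv")
        with open(jtsv, "w") as fh:
            fh.write("name\tchrom\tposition\n")
            for nm, chrom, p in truth.junctions:
                fh.write(f"{nm}\t{chrom}\t{p}\n")
        paths["junctions_tsv"] = jtsv

        otsv = os.path.join(directory, "truth_read_origins.tsv")
        with open(otsv, "w") as fh:
            fh.write("read_id\thaplotype\tchrom\tstart\tstop\tstrand\n")
            for o in truth.read_origins:
                fh.write(f"{o.read_id}\t{o.haplotype}\t{o.chrom}\t{o.start}\t{o.stop}\t{o.strand}\n")
        paths["origins_tsv"] = otsv
    return paths


def read_fastq(path: str) -> list:
    reads = {}
    order = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            rid = h.strip()[1:]
            if rid.endswith("/1"):
                reads[rid[:-2]] = Read(rid[:-2], seq)
                order.append(rid[:-2])
            elif rid.endswith("/2"):
                reads[rid[:-2]].mate = seq
            else:
                reads[rid] = Read(rid, seq)
                order.append(rid)
    return [reads[r] for r in order]
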