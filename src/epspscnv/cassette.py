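"""Cassette junction catalogue, spanning-read counting and architecture calls.

The cassette model is an ordered list of oriented domains (large/small
subtelomeric repeat blocks, Region-A, Region-B split around the Region-I
insert).  Each adjacent domain pair defines a junction; forward and
reverse-complement instances of the same biological junction are pooled under
one canonical name (STs-A, A-B, B-I, I-B, B-ST), and the orientation flip
inside the small subtelomeric block is the inversion point (INV).

The diagnostic for a palindromic tandem array is the ratio law: every
palindromic unit carries *two* copies of each domain junction but only *one*
inversion point, so with uniform read sampling the INV spanning-read count
converges to half the other junctions' counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maplite import build_index, map_reads
from .simulate import revcomp

DOMAIN_JUNCTIONS = ("STs-A", "A-B", "B-I", "I-B", "B-ST")


def canonical_junction(left: str, left_ori: str, right: str, right_ori: str) -> str:
    """Canonical name of the junction between two adjacent oriented domains.

    Reverse-complement instances collapse onto the forward name (a junction
    read right-to-left on the other strand is the same biological breakpoint);
    subtelomeric blocks are treated as orientation-agnostic except that two
    adjacent same-name ST blocks of opposite orientation mark the inversion
    point.
    """
    l_st, r_st = left.startswith("ST"), right.startswith("ST")
    if l_st and r_st:
        return "INV" if left == right and left_ori != right_ori \
            else f"{left}/{right}"
    if left_ori == "-" and right_ori == "-":  # doubly-reversed reading
        left, right = right, left
        l_st, r_st = r_st, l_st
    if l_st or r_st:
        other = right if l_st else left
        if other == "A":
            return "STs-A"
        if other == "B":
            return "B-ST"
        return f"STs-{other}"
    table = {("A", "B"): "A-B", ("B", "A"): "B-A",
             ("B", "I"): "B-I", ("I", "B"): "I-B"}
    key = (left, right)
    if key in table and left_ori == right_ori:
        return table[key]
    return f"{left}{left_ori}/{right}{right_ori}"


@dataclass
class CassetteModel:
    """Concatenation of oriented domains with derived junction catalogue."""

    domains: list            # (name, orientation, sequence as laid out)
    sequence: str
    boundaries: list         # cumulative end position of each domain
    junctions: list          # (canonical name, position)

    def junction_positions(self):
        return [("model", nm, pos) for nm, pos in self.junctions]


def build_cassette_model(domains) -> CassetteModel:
    """Concatenate oriented domains and derive the junction catalogue.

    ``domains`` is a list of ``(name, orientation, sequence)`` where the
    sequence is given in its forward reading; reverse-oriented domains are
    reverse-complemented on concatenation.  Domain names starting with ``ST``
    are subtelomeric blocks; a pair of adjacent same-name ST blocks with
    opposite orientation yields the INV junction.
    """
    if not domains:
        raise ValueError("empty cassette layout")
    parts, boundaries, juncs = [], [], []
    pos = 0
    laid = []
    for name, ori, seq in domains:
        if not seq:
            raise ValueError(f"domain {name} has an empty sequence")
        s = seq if ori == "+" else revcomp(seq)
        laid.append((name, ori, s))
        parts.append(s)
        pos += len(s)
        boundaries.append(pos)
    for (ln, lo, ls), (rn, ro, _), b in zip(laid, laid[1:], boundaries):
        juncs.append((canonical_junction(ln, lo, rn, ro), b))
    return CassetteModel(domains=laid, sequence="".join(parts),
                         boundaries=boundaries, junctions=juncs)


def standard_layout(region_a: str, region_b: str, region_i: str, st_unit: str,
                    small_fwd: int = 12, small_rev: int = 31,
                    large_fwd: int = 40, large_rev: int = 60,
                    i_offset: int = 500) -> list:
    """The palindromic single-unit layout with large ST flanks.

    Returns the oriented domain list for :func:`build_cassette_model`:
    forward A+B(I) and its reverse complement joined by the small ST block
    (forward copies then reverse copies), flanked by large ST arrays.
    """
    b1, b2 = region_b[:i_offset], region_b[i_offset:]
    fwd = [("A", "+", region_a), ("B", "+", b1), ("I", "+", region_i), ("B", "+", b2)]
    rev = [(n, "-", s) for n, _, s in reversed(fwd)]
    return ([("ST_large", "+", st_unit * large_fwd + revcomp(st_unit) * large_rev)]
            + fwd
            + [("ST_small", "+", st_unit * small_fwd),
               ("ST_small", "-", st_unit * small_rev)]
            + rev
            + [("ST_large", "+", st_unit * large_fwd + revcomp(st_unit) * large_rev)])


@dataclass
class JunctionSupport:
    name: str
    position: int
    n_spanning: int
    relative_abundance: float = float("nan")


def count_junction_support(alignments, junctions, min_anchor: int = 100):
    """Spanning-read counts per canonical junction name.

    ``junctions`` is an iterable of ``(ref_name, name, position)`` (e.g. from
    ``CassetteModel.junction_positions()`` or the simulator truth).  A read
    supports a junction iff one of its contiguous aligned blocks covers the
    junction position with at least ``min_anchor`` aligned bases on each side;
    a read is counted at most once per junction name.  Relative abundance is
    reported as fold of the minimum-support junction.
    """
    if min_anchor <= 0:
        raise ValueError("min_anchor must be > 0")
    juncs = [(ref, nm, int(pos)) for ref, nm, pos in junctions]
    by_ref = {}
    for ref, nm, pos in juncs:
        by_ref.setdefault(ref, []).append((pos, nm))
    support = {}
    first_pos = {}
    for ref, nm, pos in juncs:
        support.setdefault(nm, set())
        first_pos.setdefault(nm, pos)
    for rec in alignments:
        if not rec.mapped or rec.ref_name not in by_ref:
            continue
        for ref_off, _, ln in rec.aligned_blocks:
            for pos, nm in by_ref[rec.ref_name]:
                if ref_off + min_anchor <= pos <= ref_off + ln - min_anchor:
                    support[nm].add(rec.read_id)
    counts = {nm: len(ids) for nm, ids in support.items()}
    nonzero = [c for c in counts.values() if c > 0]
    floor = min(nonzero) if nonzero else 0
    return [JunctionSupport(name=nm, position=first_pos[nm], n_spanning=counts[nm],
                            relative_abundance=counts[nm] / floor if floor else float("nan"))
            for nm in counts]


def infer_architecture(supports, palindromic_band=(0.35, 0.65),
                       simple_band=(0.8, 1.25)) -> str:
    """Architecture call from junction spanning-read counts.

    ``palindromic_tandem`` when all five domain junctions are supported and
    the INV/median ratio falls in ``palindromic_band`` (the half-abundance
    signature); ``simple_tandem`` when INV support matches the others (or
    there is no inversion point but all domain junctions are supported);
    ``unsupported`` otherwise.
    """
    if not supports:
        raise ValueError("empty support list")
    counts = {s.name: s.n_spanning for s in supports}
    if any(counts.get(nm, 0) == 0 for nm in DOMAIN_JUNCTIONS):
        return "unsupported"
    others = [counts[nm] for nm in DOMAIN_JUNCTIONS]
    med = float(np.median(others))
    inv = counts.get("INV")
    if inv is None or inv == 0:
        return "simple_tandem" if inv is None else "unsupported"
    r = inv / med
    if palindromic_band[0] <= r <= palindromic_band[1]:
        return "palindromic_tandem"
    if simple_band[0] <= r <= simple_band[1]:
        return "simple_tandem"
    return "unsupported"


def validate_alternatives(candidates: dict, reads, min_anchor: int = 100,
                          k: int = 21, winner_factor: float = 5.0, seed: int = 0,
                          trunc_tol: int = 50) -> dict:
    """Arbitrate alternative local assemblies by spanning-read support.

    ``candidates`` maps candidate name -> ``(sequence, junction_position)``.
    Reads are mapped to each candidate; reads spanning the designated junction
    with ``min_anchor`` on both sides support it, reads whose alignment stops
    within ``trunc_tol`` of the junction while the read continues count as
    truncated (evidence against).  A winner is declared when one candidate's
    spanning count exceeds every other's by ``winner_factor``; otherwise the
    result is inconclusive.
    """
    if not candidates:
        raise ValueError("no candidate sequences")
    report = {}
    for name, (seq, jpos) in candidates.items():
        idx = build_index({name: seq}, k=k)
        recs = map_reads(reads, idx, seed=seed)
        spanning, truncated = set(), set()
        for rec in recs:
            if not rec.mapped:
                continue
            for ref_off, read_off, ln in rec.aligned_blocks:
                a, b = ref_off, ref_off + ln
                if a + min_anchor <= jpos <= b - min_anchor:
                    spanning.add(rec.read_id)
                elif (abs(b - jpos) <= trunc_tol and rec.read_length - (read_off + ln) >= min_anchor) \
                        or (abs(a - jpos) <= trunc_tol and read_off >= min_anchor):
                    truncated.add(rec.read_id)
        report[name] = {"spanning": len(spanning), "truncated": len(truncated)}
    ranked = sorted(report, key=lambda n: -report[n]["spanning"])
    best, rest = ranked[0], ranked[1:]
    best_n = report[best]["spanning"]
    runner_up = max((report[r]["spanning"] for r in rest), default=0)
    if rest and best_n > 0 and best_n >= winner_factor * max(runner_up, 1) \
            and best_n > runner_up:
        report["winner"] = best
    else:
        report["winner"] = None
    return report


def self_dotplot(sequence: str, k: int = 15, min_segment: int = 1):
    """Exact k-mer self-match segments for macrostructure visualization.

    Returns ``(pos1, pos2, length, orientation)`` tuples with ``pos1 < pos2``
    for forward matches, chained along diagonals (forward) and antidiagonals
    (reverse complement).  The trivial main diagonal is excluded.  Lengths are
    in bases (a run of m consecutive matching k-mers spans m + k - 1 bases).
    """
    if len(sequence) < k:
        raise ValueError("sequence shorter than k")
    pos = {}
    for i in range(len(sequence) - k + 1):
        pos.setdefault(sequence[i:i + k], []).append(i)

    fwd = {}
    for hits in pos.values():
        for ai in range(len(hits)):
            for bi in range(ai + 1, len(hits)):
                i, j = hits[ai], hits[bi]
                fwd.setdefault(j - i, []).append(i)
    segs = []
    for d, starts in fwd.items():
        starts.sort()
        run_start, prev = starts[0], starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + k
            if length >= min_segment:
                segs.append((run_start, run_start + d, length, "+"))
            if i is not None:
                run_start = prev = i

    rev = {}
    for i in range(len(sequence) - k + 1):
        rc = revcomp(sequence[i:i + k])
        for j in pos.get(rc, ()):
            if j > i:  # report each pair once
                rev.setdefault(i + j, []).append(i)
    for s, starts in rev.items():
        starts.sort()
        run_start, prev = starts[0], starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + k
            if length >= min_segment:
                segs.append((run_start, s - prev, length, "-"))
            if i is not None:
                run_start = prev = i
    return sorted(segs)


def enumerate_candidate_orders(domains: dict, reads, st_unit: str,
                               min_anchor: int = 100, seed: int = 0):
    """Bounded search over domain orders, scored by junction spanning support.

    Builds a model for each permutation of the non-ST domains (<= 24 orders
    for <= 4 domains) with ST flanks, counts total spanning reads at every
    junction, and returns ``(best_order, scores)``.
    """
    from itertools import permutations

    names = list(domains)
    if len(names) > 4:
        raise ValueError("bounded search supports at most 4 domains")
    scores = {}
    for order in permutations(names):
        layout = [("ST_large", "+", st_unit * 20)] + \
                 [(n, "+", domains[n]) for n in order] + \
                 [("ST_large", "+", st_unit * 20)]
        model = build_cassette_model(layout)
        idx = build_index({"model": model.sequence}, k=21)
        recs = map_reads(reads, idx, seed=seed)
        sup = count_junction_support(recs, model.junction_positions(),
                                     min_anchor=min_anchor)
        scores[order] = sum(s.n_spanning for s in sup)
    best = max(scores, key=lambda o: scores[o])
    return best, scores
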