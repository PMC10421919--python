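"""Telomere and subtelomeric tandem-repeat analysis.

Covers four tasks: scanning chromosome sequences for telomere-motif arrays
(TTTAGGG and its reverse complement), recovering the unit length and consensus
of an unknown tandem repeat by periodicity minimization, counting
forward/reverse-complement unit copies by greedy tiling, and relating repeat
units across chromosomes by global-alignment percent identity and a
neighbor-joining tree on 100 - identity distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .simulate import revcomp


@dataclass
class RepeatArray:
    chrom: str
    start: int
    stop: int
    unit_length: int
    consensus_unit: str
    n_fwd: int
    n_rev: int
    orientation: str = "+"
    terminal: bool = False
    mean_unit_identity: float = float("nan")


def find_motif_arrays(sequence: str, motif: str = "TTTAGGG", min_copies: int = 10,
                      max_mismatch_frac: float = 0.1, terminal_distance: int = 2000,
                      chrom: str = "seq"):
    """Maximal tandem runs of a motif or its reverse complement.

    Each candidate copy may carry up to ``floor(max_mismatch_frac * |motif|)``
    mismatches.  Arrays lying within ``terminal_distance`` of a sequence end
    are flagged terminal.
    """
    if not motif:
        raise ValueError("empty motif")
    m = len(motif)
    max_mm = int(max_mismatch_frac * m)
    out = []
    for unit, ori in ((motif, "+"), (revcomp(motif), "-")):
        if unit == motif and ori == "-":
            continue  # palindromic motif: forward pass already covers it
        uarr = np.frombuffer(unit.encode(), dtype=np.uint8)
        i = 0
        L = len(sequence)
        sarr = np.frombuffer(sequence.encode(), dtype=np.uint8)
        while i + m <= L:
            if (sarr[i:i + m] != uarr).sum() <= max_mm:
                j = i + m
                copies = 1
                while j + m <= L and (sarr[j:j + m] != uarr).sum() <= max_mm:
                    j += m
                    copies += 1
                if copies >= min_copies:
                    seg = sequence[i:j]
                    ident = 100.0 * (1 - sum(a != b for a, b in zip(seg, unit * copies))
                                     / len(seg))
                    out.append(RepeatArray(
                        chrom=chrom, start=i, stop=j, unit_length=m,
                        consensus_unit=unit if ori == "+" else motif,
                        n_fwd=copies if ori == "+" else 0,
                        n_rev=0 if ori == "+" else copies,
                        orientation=ori,
                        terminal=(i <= terminal_distance or L - j <= terminal_distance),
                        mean_unit_identity=ident))
                i = j
            else:
                i += 1
    return sorted(out, key=lambda a: a.start)


def detect_unit(window: str, min_period: int = 2, max_period: int | None = None,
                max_mismatch_frac: float = 0.2, tolerance: float = 0.02):
    """Recover the repeat unit length and consensus of a tandem array.

    The period ``p`` minimizing the mean mismatch fraction between ``s[i]``
    and ``s[i+p]`` wins; among periods within ``tolerance`` of the minimum the
    smallest is taken, so the base period beats its multiples.  Returns
    ``(unit_length, consensus)`` or ``None`` when even the best period
    mismatches more than ``max_mismatch_frac`` (i.e. the window is not a
    tandem array — an i.i.d. random sequence sits near 0.75).
    """
    if len(window) < 2:
        raise ValueError("window shorter than 2 bp")
    s = np.frombuffer(window.encode(), dtype=np.uint8)
    max_p = max_period or len(window) // 2
    if max_p < min_period:
        raise ValueError("window too short for the candidate period range")
    periods = np.arange(min_period, max_p + 1)
    mm = np.array([np.mean(s[p:] != s[:-p]) for p in periods])
    best = mm.min()
    if best > max_mismatch_frac:
        return None
    p = int(periods[np.flatnonzero(mm <= best + tolerance)[0]])
    # per-column majority consensus over the tiling
    n_rows = len(s) // p
    tiles = s[:n_rows * p].reshape(n_rows, p)
    consensus = bytes(
        np.array([np.bincount(tiles[:, c], minlength=256).argmax()
                  for c in range(p)], dtype=np.uint8)
    ).decode()
    return p, consensus


def count_orientations(array_seq: str, unit: str):
    """Greedy left-to-right tiling into forward / reverse-complement copies.

    At each offset the orientation with higher identity to the unit is taken;
    exact ties count as forward (documented tie-break, which also covers
    units equal to their own reverse complement).  Returns ``(n_fwd, n_rev)``
    with ``n_fwd + n_rev = floor(|array| / |unit|)``.
    """
    if len(unit) > len(array_seq):
        raise ValueError("unit longer than array")
    u = np.frombuffer(unit.encode(), dtype=np.uint8)
    ur = np.frombuffer(revcomp(unit).encode(), dtype=np.uint8)
    s = np.frombuffer(array_seq.encode(), dtype=np.uint8)
    p = len(unit)
    n_fwd = n_rev = 0
    for i in range(0, (len(s) // p) * p, p):
        tile = s[i:i + p]
        if (tile == u).sum() >= (tile == ur).sum():
            n_fwd += 1
        else:
            n_rev += 1
    return n_fwd, n_rev


_aligner = None


def _get_aligner(match=1.0, mismatch=-1.0, gap=-2.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, match: float = 1.0,
                      mismatch: float = -1.0, gap: float = -2.0) -> float:
    """Percent identity from a global end-to-end alignment.

    The denominator is the number of alignment columns including gap columns
    (this choice is configurable only through the alignment scores; the
    percent value is symmetric in its arguments).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty input sequence")
    aligner = _get_aligner(match, mismatch, gap)
    aln = aligner.align(seq_a, seq_b)[0]
    c = aln.counts()
    columns = aln.shape[1]
    return 100.0 * c.identities / columns


def region_best_identity(region: str, unit: str, step: int | None = None) -> float:
    """Best identity of ``unit`` against any unit-sized window of ``region``.

    The explicit 'region-vs-unit' mode: a multi-unit repeat region is scanned
    coarsely with stride ``step`` (default: half the unit), then the
    neighborhood of the best coarse window is re-scanned at single-base
    resolution so the unit's phase within the region does not bias the
    result.
    """
    p = len(unit)
    if len(region) <= p:
        return pairwise_identity(region, unit)
    step = step or max(1, p // 2)

    def scan(lo, hi, stride):
        best_v, best_i = -1.0, lo
        for i in range(lo, hi + 1, stride):
            v = pairwise_identity(region[i:i + p], unit)
            if v > best_v:
                best_v, best_i = v, i
            if v == 100.0:
                break
        return best_v, best_i

    coarse_v, coarse_i = scan(0, len(region) - p, step)
    if coarse_v == 100.0 or step == 1:
        return coarse_v
    fine_v, _ = scan(max(0, coarse_i - step), min(len(region) - p, coarse_i + step), 1)
    return max(coarse_v, fine_v)


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v


def identity_distance_matrix(units: dict, **kwargs) -> DistanceMatrix:
    """Distances 100 - percent-identity over a label -> sequence mapping."""
    labels = list(units)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(units[labels[i]], units[labels[j]], **kwargs)
            d[i, j] = d[j, i] = 100.0 - ident
    return DistanceMatrix(labels=labels, values=d)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree in newick form, negative branch lengths clamped to 0."""
    if len(matrix.labels) < 2:
        raise ValueError("need at least 2 labels")
    if len(matrix.labels) == 2:
        d = matrix.values[0, 1] / 2
        return f"({matrix.labels[0]}:{d:g},{matrix.labels[1]}:{d:g});"
    import skbio

    dm = skbio.DistanceMatrix(matrix.values, ids=matrix.labels)
    tree = skbio.tree.nj(dm, neg_as_zero=True)
    return str(tree).strip()


def tree_path_lengths(newick: str) -> dict:
    """Pairwise tip-to-tip path lengths of a newick tree (for additivity checks)."""
    import skbio

    tree = skbio.TreeNode.read([newick])
    tips = [t.name for t in tree.tips()]
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[frozenset((a, b))] = tree.find(a).distance(tree.find(b))
    return out


def write_arrays_bed(arrays, path: str) -> None:
    with open(path, "w") as fh:
        for a in arrays:
            fh.write(f"{a.chrom}\t{a.start}\t{a.stop}\t"
                     f"unit={a.unit_length};fwd={a.n_fwd};rev={a.n_rev};"
                     f"terminal={int(a.terminal)}\n")
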