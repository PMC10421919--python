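"""Region-level summary of a per-gene differential-expression table.

DE statistics are consumed, not fitted: the table provides per-gene log2
fold-changes and p-values from an external test, and this module only applies
the significance filter (p < 0.01 and fold-change > 2, i.e. log2FC > 1, both
strict) and counts significant genes per cassette region.  Genes whose
statistics were filtered out upstream stay in the denominators but can never
be significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

from .depthcnv import ThresholdConfig

KNOWN_REGIONS = ("A", "B", "other")


@dataclass
class DeRecord:
    gene_id: str
    label: str
    region: str
    log2fc: float | None
    p_value: float | None

    @property
    def significant(self) -> bool:
        return self.has_stats and self._sig

    has_stats: bool = True
    _sig: bool = False

    def evaluate(self, thresholds: ThresholdConfig) -> "DeRecord":
        self.has_stats = self.p_value is not None and self.log2fc is not None
        self._sig = bool(
            self.has_stats
            and self.p_value < thresholds.de_p
            and self.log2fc > math.log2(thresholds.de_fc)
        )
        return self


def read_de_table(path_or_handle) -> list:
    """Read a TSV with columns gene_id, label?, region, log2fc, p_value.

    Missing/blank statistics become ``None`` (genes filtered upstream)."""
    rows = []
    fh = open(path_or_handle) if isinstance(path_or_handle, str) else path_or_handle
    try:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c.lower(): i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            get = lambda c: f[idx[c]].strip() if c in idx and idx[c] < len(f) else ""
            rows.append(DeRecord(
                gene_id=get("gene_id"), label=get("label") or get("gene_id"),
                region=get("region"),
                log2fc=float(get("log2fc")) if get("log2fc") else None,
                p_value=float(get("p_value")) if get("p_value") else None))
    finally:
        if isinstance(path_or_handle, str):
            fh.close()
    return rows


def load_reference_de_table() -> list:
    """The bundled per-gene DE table for the genes inside the duplicated
    cassette regions (glyphosate-resistant vs susceptible goosegrass)."""
    ref = resources.files("epspscnv.data").joinpath("cassette_gene_de.tsv")
    with ref.open() as fh:
        return read_de_table(fh)


def summarize_de(records, thresholds: ThresholdConfig | None = None) -> dict:
    """Per-region ``(n_significant, n_total)`` counts under the strict filter.

    Records with an unknown region label are assigned to ``other`` with a
    warning; records lacking statistics count toward totals only.
    """
    thr = thresholds or ThresholdConfig()
    out = {}
    for rec in records:
        region = rec.region if rec.region in KNOWN_REGIONS else None
        if region is None:
            warnings.warn(f"unknown region label {rec.region!r} for "
                          f"{rec.gene_id}; assigning to 'other'")
            region = "other"
        rec.evaluate(thr)
        n_sig, n_tot = out.get(region, (0, 0))
        out[region] = (n_sig + int(rec.significant), n_tot + 1)
    return out


def write_summary_tsv(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("region\tn_significant\tn_total\n")
        for region in sorted(summary):
            n_sig, n_tot = summary[region]
            fh.write(f"{region}\t{n_sig}\t{n_tot}\n")
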