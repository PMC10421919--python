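# Methods

## The system being modeled

The package analyzes (and simulates) a glyphosate-resistance architecture in
which the *EPSPS*-containing Region-A (~35 kb) and the distal Region-B
(~41 kb, carrying the short Region-I insert near its 5' end) are fused and
amplified as a palindromic tandem array at a chromosome end. Each array unit
is

    [A + B(I) forward] + [small ST array: f forward + r reverse-complement 451 bp units] + [A + B(I) reverse-complement]

with large ST arrays flanking (and, in the default layout, separating) the
units. The native single copies of Region-A and Region-B remain in place on
the carrier chromosome, ~1 Mb apart in the real system.

Three signals identify this architecture from sequencing data alone:

1. **Read depth.** With *c* palindromic units, Region-A/B multiplicity on the
   carrier haplotype is 1 + 2*c*; normalized window depth over the native
   regions reads out that multiplicity (halved in a heterozygote, which
   carries the array on one haplotype only).
2. **Group-exclusive consensus.** An interval duplicated in every resistant
   sample and no susceptible sample is a candidate resistance CNV; the
   catalogue convention reports 1-based starts with `length = stop − start`.
3. **Junction spanning reads.** Each unit contributes two copies of every
   domain junction (STs-A, A-B, B-I, I-B, B-ST) but only one inversion point
   (INV, inside the small ST block where unit orientation flips), so
   E[INV support] / E[domain-junction support] → 0.5. A simple tandem has no
   half-abundance signature; a zero-support junction falsifies the model.
   The ratio law is layout-independent (shared or per-unit large ST flanks).

## Simulator

`SimConfig` separates **architecture constants**, kept at the biological
values of the emulated system — telomere motif TTTAGGG, ST unit length 451 bp
(a 472 bp figure also circulates for this repeat; the default is 451 and the
length is configurable), small ST array 12 forward + 31 reverse-complement
units, Region-I inserted a fixed offset into Region-B — from **size
parameters**, which default to desk scale so that a full simulate → map →
call cycle runs in seconds: 3 chromosomes of 150 kb, Region-A/B/I of
5000/4000/800 bp separated by a 15 kb gap, 100 telomere copies and 20 native
ST copies per end, large ST flanks of 40 forward + 60 reverse units
(real flanks are several-fold larger), and c = 11 cassette units
(multiplicity 23, matching the ~22–29× depth regime of the real system).
Paper-scale lengths are one config edit away; none of the inference logic
depends on the scale.

Per-chromosome ST units derive from one master unit with a configurable
substitution fraction (default 5%), reproducing the observed ~86–99.6%
inter-chromosome similarity spread; the cassette's ST unit is the carrier
chromosome's unit. Heterozygotes are simulated mechanistically as two
explicit haplotypes sampled equally. Reads are error-free by default (an
optional uniform substitution rate exists) because junction counting must be
testable without an error model; long-read lengths are log-normal with median
12 kb, short reads are 150 bp pairs with ~400 bp inserts. Ground truth
records CNV intervals with expected multiplicity, every junction position,
every repeat array, and per-read origins.

Coordinates are 0-based half-open everywhere internally; the 1-based
reporting convention appears only in writers. The configured cassette can
exceed a configured `arm_capacity_bp` only by raising an error; by default no
capacity limit is enforced, since a desk-scale chromosome is deliberately
shorter than a realistic cassette.

Deliberately not modeled: sequencing error profiles, chimeric reads, GC bias,
SNP backgrounds beyond ST divergence. Passing tests therefore demonstrate
correctness of the inference logic on clean signals, not robustness to
real-data noise.

## Mapper

`maplite` is a deterministic seed-and-extend mapper for clean synthetic
reads: exact k-mer seeds (k = 21) binned by diagonal, ungapped extension with
an X-drop rule (match +1, mismatch −3, optimal endpoints by cumulative-score
argmax), alignment accepted at ≥ 90% identity over ≥ 30 bp. Multi-mapping
ties — the normal case inside tandem arrays — are broken uniformly at random
under the run seed. A read whose best placement leaves ≥ 100 bp anchored at a
discordant second locus is emitted as two split records; split reads never
span a junction, which is how incompatible candidate assemblies lose support.
There is no gapped alignment, quality-aware scoring, or BAM output; SAM from
a real aligner can be imported instead (pysam), with CIGAR semantics
M/=/X consuming both, I/S the read, D/N the reference.

## Depth, segments, consensus

Window depth is aligned bases per window (default 5 kb; the pipeline's
desk-scale default is 1 kb because the scaled regions are themselves only a
few kb). Normalization divides by the genome-wide mean (output mean exactly
1); a median baseline is available and used by the pipeline because at desk
scale the amplified cassette is a non-negligible fraction of the genome and
would inflate the mean — at realistic genome sizes the two baselines
coincide. Thresholds are strict inequalities (a window exactly at 0.25× or
4× is neutral). Non-neutral runs get a two-sided one-sample t-test of their
windows against 1.0; runs of fewer than two windows (or zero variance) use a
normal approximation with the global window variance. Calls with p > 0.01
are demoted to neutral and runs re-merged, so segments always tile each
reference. No multiple-testing correction is applied, matching the source
analysis. Raising the duplication threshold always shrinks the duplicated
extent; the *number* of duplication segments is monotone only for isolated
CNV blocks, since a higher bar can split one long run.

Copy number over an interval is its coverage-weighted mean normalized depth
divided by a background fold (default 1). Zygosity, when a cohort of copy
estimates is supplied, is `hom` within ±25% of the cohort mode, `het` within
±25% of half the mode, otherwise `na`.

Consensus events use per-base semantics (any ≥ 1 bp overlap counts as
presence, the bedtools default): a base belongs to an event iff every
resistant sample's duplication segments cover it and no susceptible sample's
do; maximal runs become events, ordered genomically and numbered CNV1, CNV2,
… A minimum-overlap fraction is available as a post-filter. Sequence class
(pseudomolecule vs scaffold) is inferred from the name (`Chr*` /
`Scaffold*`, configurable regex). Two rows of the bundled reference
catalogue carry mutually inconsistent printed coordinates; they are flagged
`coords_uncertain`, excluded from length arithmetic, and retained in counts.

## Junction support and architecture

A read supports a junction iff one contiguous aligned block covers the
junction position with ≥ `min_anchor` bases on each side (default 100 bp for
long reads, 30 bp recommended for short reads — anchors must be long enough
that the junction-adjacent unique sequence, not the repeat, carries the
evidence). Forward and reverse-complement instances pool under the canonical
name; a read counts at most once per junction name. Architecture calls:
`palindromic_tandem` when all five domain junctions are supported and
INV/median falls in [0.35, 0.65]; `simple_tandem` when INV ≈ the others (or
no inversion point exists but all domain junctions are supported);
`unsupported` otherwise. Alternative local assemblies are arbitrated by
spanning vs truncated counts, with a 5× default winner factor. The manual
assembly step of the original workflow is reduced to a bounded search:
enumerate ≤ 24 domain orders, score each by total spanning support, keep the
maximum.

## Repeats

Telomere arrays are maximal runs of the motif or its reverse complement with
a per-copy mismatch allowance (10% default) and ≥ 10 copies; arrays within
2 kb of a sequence end are flagged terminal. Unknown units are recovered by
periodicity minimization: the period p minimizing mean mismatch between
s[i] and s[i+p], smallest-p-within-tolerance so the base period beats its
multiples, consensus by per-column majority; windows whose best period still
mismatches > 20% (an i.i.d. sequence sits near 75%) return none. Orientation
counts tile greedily left-to-right, choosing the orientation with higher
identity and counting exact ties as forward (which also covers units equal
to their own reverse complement). Percent identity is computed from a global
end-to-end alignment (match +1, mismatch −1, gap −2; Biopython
PairwiseAligner) with alignment columns — including gap columns — as the
denominator; unit-vs-unit and region-vs-unit best-hit identity are separate
explicit modes. Trees are standard neighbor joining (scikit-bio) on
100 − identity distances, negative branch lengths clamped to zero; NJ
deliberately replaces likelihood phylogenetics here — topology on
well-separated units is the claim under test, not branch support.

## Expression

DE statistics are consumed, not fitted. A gene is significant iff its
p-value and log2 fold-change are present, p < 0.01, and log2FC > 1 — both
strict, so log2FC = 1.0 fails. Genes whose statistics were filtered upstream
stay in denominators. The simulator emits DE tables with configured
per-region (over-expressed, unchanged) gene counts, effect sizes around
log2FC 5, and uniform null p-values.

## Pipeline, seeds, problem sizes

`run_pipeline` executes all stages on simulated data, writes every
intermediate as a file, and scores against truth: consensus precision/recall
at ≥ 50% reciprocal overlap, copy-number relative error, the architecture
call, and the detected ST unit length. The top-level seed fans out to
per-stage seeds via SHA-256 of `"{seed}:{stage}"` (mod 2³¹), so any stage is
independently reproducible and a fixed seed yields byte-identical reports.
Default panels are 3 resistant + 3 susceptible samples at 10× short-read
coverage with 30× long reads for junction validation; the test suite and the
acceptance script run 2 + 2 panels, c = 3, and 6–40× coverages so the full
suite stays within a desktop time budget. These sizes are the package's
validation conditions, not statistical claims about minimal designs.

## Known limitations

- Ungapped alignment only; indel-bearing reads would need imported SAM.
- Window-resolution CNV boundaries (no breakpoint refinement), as intended
  by the "roughly call regions" design.
- The large flanking ST arrays are simulated far smaller than reality and
  the real arrays' internal structure was never resolved; the palindromic
  per-unit layout is one modeling choice consistent with the junction
  evidence, and the ratio law does not depend on it.
- Greedy orientation tiling assumes < 20% unit divergence.
- Exact-match dotplot and k-mer seeding assume clean sequence; highly
  diverged repeats would need a sensitivity-oriented aligner.
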