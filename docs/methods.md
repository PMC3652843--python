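# Methods

## The composite element and its scanner

Forkhead factors bind very short cores; FoxE1's AAACA element occurs by
chance roughly every few hundred bases, so presence of the core alone
carries almost no information. The discriminative signal used here is a
composite arrangement described for the *Tpo* promoter and for forkhead
factors on the serum albumin promoter: an NF1/CTF element (core TTGG)
followed 5'→3' by the forkhead core at a bounded distance,

    5'-TTGG-(N)5–30-AAACA-3'

The scanner treats this as two exact cores with a spacer-length window:

- **Exact matching.** No mismatches, no IUPAC degeneracy and no
  position-weight scoring. `N` in the input is allowed inside a spacer but
  never matches a core position. All matching is case-insensitive after
  normalization to uppercase A/C/G/T/N; other ambiguity codes are rejected
  at read time so matching semantics never depend on them.
- **Spacer convention.** The spacer counts bases *strictly between* the
  two cores, and the bounds 5 and 30 are inclusive. This convention was
  validated against all 30 curated promoter fragments shipped with the
  package: each fragment's reported spacer equals the strictly-between
  count under it.
- **Strands.** A minus-strand occurrence is the same arrangement on the
  reverse complement; on the scanned sequence it reads TGTTT (revcomp of
  the FoxE1 core) first and CCAA (revcomp of the NF1/CTF core) last.
  Only the NF1-then-FoxE1 order per strand is a hit; the opposite order
  is not searched, matching the published pattern.
- **All pairings are reported**, including overlapping and nested ones
  (published tables contain genes with two distinct instances, so no
  deduplication can be assumed at scan time). For *display*, when one
  NF1-core occurrence pairs with several FoxE1 cores —
  which happens in A-rich runs such as the Cdh1 promoter fragment
  `TACTTGGGCTGGAAAACAAACAAAA`, where AAACA occurs at spacer 6 and 10 —
  `select_representative` keeps the longest spacer per NF1 occurrence.
  That is the instance a greedy regular-expression search
  (`TTGG[ACGT]{5,30}AAACA`) yields, and it is the convention under which
  every one of the 30 curated rows is reproduced exactly one-for-one.
- **Core reading.** The forkhead core is configurable. The default AAACA
  is the reading consistent with every curated instance (minus-strand rows
  display TGTTT = revcomp(AAACA)); the literature also prints the permuted
  form ACAAA, which can be supplied via `CompositeMotifConfig` to explore
  that reading.

The scanner is deliberately simple (two `str.find` sweeps plus a bounded
pairing) and is verified against an independent brute-force oracle that
enumerates all core-offset pairs, over thousands of random sequences, as
well as by strand-symmetry and window-monotonicity property tests.

## Coordinates and promoter windows

Internally everything is 0-based half-open; BED6 output follows the same
convention. Promoter windows are anchored on the TSS, default ±1000 bp.
For a plus-strand gene the window is `[tss − upstream, tss + downstream)`.
For a minus-strand gene the *same mirrored genomic interval*
`[tss − downstream, tss + upstream)` is taken and reverse-complemented, so
extracting a window for one strand and reverse-complementing equals
extracting it for the opposite-strand annotation — an invariant the tests
rely on. A consequence of half-open mirroring is that the TSS base sits at
gene-oriented index `upstream` on plus genes and `upstream − 1` on minus
genes. Windows running past a contig edge are clipped with a warning
rather than rejected.

`extract_region` handles literature-style regions quoted with both
endpoints, e.g. an enhancer "between −2495 and −2264 bp": by default both
printed endpoints are included (length 232 nt for that example), since the
phrasing names both boundary bases; a half-open mode is available. Offset
0 is the TSS base itself and negative offsets are upstream on the gene's
orientation.

## Ortholog conservation

For each gene the ortholog promoters are rescanned with the same motif
definition. Reported per gene: `pct_with_motif` (members with ≥1 hit /
members), and mean/min/max spacer. Spacer statistics pool **all** hits
from all members — the simplest estimator consistent with an "average
spacer among orthologs" column; a one-minimal-spacer-per-member mode is
behind a flag because the original aggregation is not specified.
Percentages and means are rounded to one decimal, half away from zero,
matching display precision. When a gene has several reference instances,
each gets its own table row but all rows share the gene's single
ortholog-panel summary; matching panels to individual instances would
require per-instance orthology information that promoter sets do not
carry, and the shared-summary choice is flagged in the table structure
(rows of one gene repeat their conservation columns).

## Differential-expression intersection

Inputs are probe-level tables (`probe gene logfc adj_p`) from an upstream
linear-model fit; p-values arrive already adjusted and are never
re-adjusted here. The rule is strict: `adj_p < 0.005` in *both*
comparisons. Collapse and intersection conventions:

- unannotated probes (empty gene field) count toward probe totals but not
  gene totals — this is what makes significant-probe counts exceed gene
  counts;
- probes annotated to multiple genes are rejected at load with a warning;
- genes whose significant probes disagree in fold-change sign are
  excluded (conservative, logged) rather than majority-voted;
- a gene must have the *same* direction in both comparisons to enter the
  common set, so `total = up + down` always holds.

## Assay quantification

**ChIP / ReChIP.** Technical triplicates are averaged on the Ct scale
first (standard qPCR practice). The input-normalized recovered fraction
of an amplicon is `E^(Ct_input − Ct_IP)` with amplification efficiency
`E = 2.0` by default (perfect doubling; configurable per call, valid range
(1, 2]). Enrichment is the target's fraction divided by a negative-control
locus's fraction, per biological experiment, aggregated as mean ± SEM
(n = 2 experiments in the emulated design). The input dilution factor and
any global Ct shift cancel in the ratio, which the tests assert. When two
negative controls are available (Afm, Gad1) the ratios are computed per
control separately rather than pooled, since the original choice of
printed control is not stated. ReChIP (sequential FoxE1→NF1
immunoprecipitation) is quantified identically; only the antibody label
differs.

**Relative expression.** ΔΔCt against a normalizer gene (Gus in the
emulated design): `(E^(Ct_norm − Ct_target))_treated /
(E^(Ct_norm − Ct_target))_reference`, so the reference condition is 1 by
construction; mean ± SEM over 4 experiments.

**Reporter assays.** Per experiment the luciferase/Renilla ratio is
averaged over replicate wells; fold activation is the mean over paired
experiments of condition/control ratios, reported ± SD (n = 6
experiments). Significance is a two-tailed two-sample t-test on the
per-experiment normalized ratios; the Welch (unequal-variance) form is
used because equal variances cannot be assumed for transfection data.
Stars follow the conventional thresholds (\* p<0.05, \*\* p<0.01,
\*\*\* p<0.001). Note the swap-inversion property (target↔control gives
1/r) is exact per experiment; the mean over noisy experiments inverts
only approximately (Jensen), which is why the property test uses the
noiseless generator.

## Synthetic data: what it emulates, and what it does not

The generators produce every input dialect the pipeline reads, with
planted ground truth, from one top-level seed fanned out through fixed
spawn keys (one stream per generator), so each `gen_*` function is
independently byte-reproducible.

- **Promoters**: 2 kb windows (±1000 bp around a TSS placed mid-contig,
  one contig per gene, genes on either genomic strand) with i.i.d.
  background at GC 0.45 — roughly the GC of rat promoter regions.
  The background is *rejection-scrubbed*: any window matching the
  composite pattern is resampled until none remains (bounded rounds), so
  absence of chance hits is guaranteed rather than merely unlikely, and
  false-positive tests are exact. Motifs are then planted at uniform
  offsets, uniform spacer in 5–30, random strand; planting re-draws until
  the planted instance is the *only* hit in the sequence.
- **Ortholog panels** (default 12 members, conservation rate 0.5): each
  member is scrubbed background, motif-positive with the planted
  probability, spacer jittered ±3 around the reference instance within
  the window.
- **DE tables**: planted to the published screening shape — 74
  significant probes / 64 genes (24 up, 40 down) in silenced-vs-scrambled
  and 211 / 183 (87 up, 96 down) in silenced-vs-wild-type, sharing 55
  genes (17 up, 38 down) with consistent signs; the probe>gene gaps are
  realized as unannotated significant probes. Each table also plants a
  few records at exactly p = 0.005 that a strict rule must exclude, plus
  non-significant filler probes.
- **qPCR tables**: Ct values are back-computed from the planted ratios
  under the efficiency model (so zero-noise tables invert exactly) with
  additive Gaussian Ct noise, default sd 0.1 cycles — a standard error
  model for replicate qPCR. Default planted ChIP ratios are the published
  enrichment values (Tg 22.8, Tpo 3.6, NUE 12.6, Duox2-1 28.1,
  Duox2-2 9.3); since the underlying raw Ct data were never published,
  these serve as recovery targets for the quantification code, not as a
  reproduction of the original measurements. Expression folds emulate a
  strong knockdown (FoxE1 0.15, i.e. >85% silencing) with plausible
  target responses.
- **Reporter tables**: multiplicative lognormal noise (CV 10%) around
  planted folds of 2.0 for each single factor and 4.0 for the
  combination (the published activation is 2-fold per factor and
  additive).

What the generators do **not** emulate: array probe intensities,
normalization artifacts, dye swaps, correlated probe effects, real
promoter composition (CpG islands, repeats), phylogenetic structure among
orthologs, or qPCR efficiency differences between amplicons. Passing the
recovery tests therefore demonstrates that the *computational* pipeline
is correct and well-calibrated under its stated error models — not that
the biological results would replicate on new wet-lab data.

## Problem sizes and numerical choices

Test and driver runs use 20-gene genomes, 12-member panels (200 members
for the binomial-convergence check), 1500-probe DE tables over a
1000-gene universe, and the per-assay replicate structure above; these
sizes exercise every code path while keeping the full suite fast.
Tolerances in recovery tests are derived from the estimator's own
dispersion (3 SEM / 3 SD rules, binomial standard errors at the planted
rate), not tuned constants. Ct values are stored at full precision
because noiseless inversion is asserted to machine precision. Percent and
mean rounding uses decimal half-away-from-zero. Hits are sorted by
leftmost offset with plus-strand first on ties; DE gene calls are sorted
lexicographically for stable output.

## Known limitations

- Exact-core matching cannot represent affinity gradations; a PWM layer
  is explicitly out of scope.
- Conservation summaries treat ortholog panels as unstructured sets; no
  alignment or phylogenetic weighting.
- The DE stage consumes adjusted p-values as given; it cannot detect an
  inconsistent upstream correction.
- Reporter statistics assume per-experiment ratios are approximately
  normal; with n = 6 experiments the Welch test is only as robust as that
  assumption.
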