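# Methods

## Cluster-calling model

Mutations of one sample are assumed to arise from two processes: uniform
scatter across the genome and localized hypermutation of transient ssDNA.
The null model treats every base as mutating independently with
probability π = (collapsed mutation count) / (ploidy × reference length).
Complex events — maximal chains of mutations with consecutive distances
< 10 bp — are collapsed to a single occurrence before anything else,
because they may derive from one lesion; π, the group count *k* and the
candidate chains all use collapsed events, keeping numerator and
denominator consistent.

Candidate groups are maximal chains of events whose consecutive
nearest-edge distances are ≤ 10 kb (the lower bound of 10 bp is implied by
collapsing). For a group of *k* ≥ 2 events spanning *x* bases (last event
end − first event start + 1), the probability of observing k−1 mutations
within x−1 or fewer bases under the null is the negative-binomial tail

    p = Σ_{j=0}^{x−k} C(k+j−2, j) (1−π)^j π^{k−1},

and groups with p ≤ 10⁻⁴ are called clusters. No multiple-testing
correction is applied: the threshold is used as a fixed operating point.
The reported cluster *length* is the distance between the bordering
mutations (no +1), which is the quantity summed into ssDNA estimates; the
statistic's span *x* keeps the +1 so that "k−1 mutations in x−1 bases"
indexes correctly.

Grouping is single-pass maximal chaining. A non-significant group is not
recursively subdivided in search of significant sub-chains; a dense pair
absorbed into a sparse larger chain is therefore not called. This is the
simplest reading of "groups of closely spaced mutations" and is the
documented operating definition here; a sub-window re-testing variant
would call strictly more clusters.

### Numerical evaluation

The sum is evaluated in log space: term *j* is
(k−1)·log π + ln Γ(k+j−1) − ln Γ(j+1) − ln Γ(k−1) + j·log1p(−π),
accumulated with `logsumexp`. This is stable for k in the thousands and
x−k in the hundreds of thousands. For k = 2 the sum is geometric and the
closed form 1 − (1−π)^{x−1} is evaluated directly via
`-expm1((x-1)·log1p(-π))`. The test suite checks both routes against the
negative-binomial CDF (k−1 successes of probability π at ≤ x−k failures)
from an independent library implementation, at 10⁻¹⁰ relative tolerance.

### Null behaviour

The statistic is exact, not conservative, per group: with ~30 mutations on
a 12 Mb haploid genome (π ≈ 2.5×10⁻⁶), an adjacent pair at gap g has
p = 1−(1−π)^g, so pairs at 10–40 bp and compact 3–4-event chains within a
few kb genuinely reach p ≤ 10⁻⁴ under uniform scatter. Summed over the
~29 gaps of such a catalog this admits roughly 5×10⁻³ of null catalogs
(about 2×10⁻³ from pairs, the rest from short k = 3–4 chains) — the value
the acceptance script measures by Monte Carlo. Against dozens of true
clusters per hypermutated genome this false-call mass is negligible, but
it is a property of the fixed 10⁻⁴ threshold worth knowing when screening
sparse catalogs.

## Strand-coordination taxonomy

Cluster patterns are the ref alleles of member mutations in positional
order on the top strand; complex events contribute each member in place.
Any mutated A or T makes the cluster `non_CG` (the taxonomy describes
deamination-driven clusters only); CG clusters need more than 3 mutations
(read strictly as ≥ 4, since a single switch requires a ≥2 C-run next to a
≥2 G-run). The partition is by run structure: one run → coordinated; two
runs with a singleton (necessarily terminal) → coordinated-with-terminal;
two runs of ≥ 2 → single-switch with 5′C-3′G or 5′G-3′C polarity; more
runs → multiple-switch. An internal singleton (e.g. C C G C C) is
multiple-switch, not terminal. A complex event with mixed C and G members
makes a cluster switch-eligible like any other alternation; whether the
original analyses patterned mixed complexes this way is unknowable from
the text, so positional-order expansion is the documented choice.

Terminal-type clusters are ambiguous between a coordinated tract plus a
random colocalized mutation and a genuine switch event. The
terminal-distance analysis quantifies this: per cluster, the distance from
the noncoordinated terminal mutation to its neighbour versus the distance
from the opposite (coordinated) terminal mutation to its neighbour,
compared by a two-sided Mann–Whitney test. Arm geometry of single-switch
clusters (outermost-to-innermost span of each run) feeds the
dispersion-of-log-ratio comparison; Brown–Forsythe (median-centred Levene)
is used for variance equality because log-ratios of small arms are
heavy-tailed and the source analyses name no specific test.

## Motif enrichment

For a mutation set, qualifying sites are all C→T changes plus their G→A
reverse complements. Each site contributes a 41-nt window (±20, truncated
at chromosome ends). Enrichment(motif) =
[mutations(motif) × context(base)] / [mutations(base) × context(motif)],
where context(motif) counts motif occurrences in the windows on both
strands (forward motif plus its reverse complement, overlaps allowed) and
context(base) counts C plus G in the same windows. This pooling makes
every tally invariant under reverse-complementing the genome and catalog,
which the suite property-tests. Site-level motif matching is evaluated on
the mutated strand. N bases never match and windows are never discarded,
only truncated. Significance is a one-sided Fisher exact test of
(motif-mutations vs other mutations) against (motif-context vs other
context); the "APOBEC-enriched" call (default: enrichment > 2 and
p < 0.05) is a configurable decision rule of this package, not a
literature constant, and p-values are reported uncorrected.

## ssDNA metrics

Hypermutable ssDNA per genome = 100 × Σ lengths of CG > 3-mutation
clusters / total bases, with total bases at the sample's ploidy (diploid =
2 × reference length, ignoring LOH). This is a minimum estimate: tracts
with too few deaminations to reach significance, and ssDNA never
deaminated, are invisible. Cluster density is raw mutations × 1000 /
length; because length is the bordering-mutation distance (shorter than
the underlying tract), densities run somewhat above the per-tract
deamination density. Per-chromosome counts are regressed on chromosome
length (proportional spread ⇒ positive slope, intercept near zero);
cohort summaries report incidence of nonselected clusters, per-isolate
counts with pairwise Fisher/rank-sum comparisons, and Pearson correlations
of per-isolate cluster features. These cohort statistics are standard
reporting and delegate to scipy.

## Simulator

The generator emulates a G2 cell that received a burst of radiation-induced
DSBs of which a small fraction repair abnormally, exposing hypermutable
ssDNA; `n_dsb` counts those abnormal events per haploid copy (default 3,
i.e. ~5% of the ~50 breaks a 40-krad haploid exposure produces). Per
event:

* **bidirectional_resection** — two adjacent tracts; the left exposes the
  top strand, the right the bottom strand, so top-strand reading is C
  mutations 5′ of the break and G mutations 3′ of it (5′C-3′G);
* **unidirectional_resection** and **bir** — one tract on a coin-flipped
  side, exposing one strand (all-C or all-G). BIR's resected flank and
  synthesis tail are merged into a single one-strand segment.

Tract lengths are lognormal (median 5 kb, σ = 0.5 by default), truncated
at chromosome ends with the truncation recorded in the truth. Every
deamination is C→T on the exposed strand (G→A in top-strand reading for
bottom-strand exposure). Deamination probability is 0.06 per
motif-matching C (ytCa on the exposed strand by default) and 20-fold lower
at other C's; at GC 0.38 this yields about one mutation per kb of tract,
the density regime of interest. Scattered background SNVs arrive at
2.5×10⁻⁶/bp (~30 per haploid genome) with uniform substitution spectrum.
Diploids are two independent haploid copies merged without phase;
duplicate sites collapse.

Random genomes use the 16-chromosome *S. cerevisiae* length profile at
GC 0.38 with i.i.d. bases. What the generator does **not** emulate:
sequence composition structure (real motif densities are not i.i.d.),
complex joint-molecule events (multiple-switch clusters arise only via
homolog merging or chance adjacency), copy-number changes, selection
through a reporter, and pre-existing polymorphism. Passing
mechanism-recovery tests therefore shows the analysis identifies the
geometries it was built for under clean conditions, not that real catalogs
are free of confounders.

## Problem sizes and seeds

The acceptance script and suite run on: 1,000 random (k, x, π) triples for
the statistic oracle; 10⁴ uniform 30-mutation catalogs for the null rate;
120 events per mechanism (30 isolates × 4 events, tract median 8 kb with
σ = 0.25 so tracts are ≥ 5 kb) for mechanism recovery; a 24-isolate
haploid cohort at defaults for cohort statistics; a 10-isolate cohort for
the clustered-vs-scattered enrichment contrast; and 10⁵ random patterns
for the classifier oracle. These sizes give stable estimates at
single-seed reproducibility; all randomness flows from one seed.

## Known limitations

* Single-pass chaining cannot find a significant sub-cluster inside a
  non-significant chain (rare at yeast-like densities, more relevant at
  very high mutation loads).
* π uses the whole nuclear genome; no masking of repetitive or organellar
  regions.
* The enrichment context uses windows of qualifying mutated sites only, so
  samples with very few C→T/G→A mutations give unstable (small-n) ratios;
  they are flagged undefined rather than extrapolated.
* Diploid ssDNA percentages assume 2× reference length; loss of
  heterozygosity is ignored.
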