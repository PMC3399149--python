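# Methods

This note documents the statistical models, estimators and numerical
choices behind `flaxpopgen`, and what its synthetic-data tests do and do
not demonstrate about real data.

## Data model

The unit of analysis is a **locus alignment**: equal-length aligned
sequences, one per accession, at one genomic region. A study is a set of
unlinked loci sharing one sample set, plus a **panel** assigning each
accession to a group — here the wild progenitor (pale flax, *Linum
bienne*) and four domesticated groups of cultivated flax (*L.
usitatissimum*): dehiscent, fiber, oil and winter. The shipped example
tables describe a 48-accession survey (10 wild + 8/10/10/10 domesticated)
at 24 loci of 184–441 bp (6886 bp concatenated).

Coordinates are 0-based and half-open throughout. IUPAC ambiguity codes
are retained on input but treated as missing data by all statistics.

### Site-deletion policy

All site-based statistics use **complete deletion**: any column containing
a gap, `N`, or an ambiguity code in any sequence is excluded before
counting. This mirrors the common DnaSP convention and makes per-locus
statistics comparable across groups. The analysed length `L_net` (not the
gross locus length) is the denominator of per-site quantities. Published
per-locus π values are printed per site to 4 decimals; converting them to
per-locus totals with gross contig lengths is exact only for gap-free
loci, which is why a few table rows (e.g. gap-affected 712B/A) are not
desk-reproducible from gross lengths.

## Diversity statistics

* **Segregating sites** `S`: analysed columns with ≥ 2 distinct
  nucleotides.
* **Haplotypes** `Nh`: distinct sequence strings, computed both over
  analysed columns (`exclude-gap-sites`) and over raw strings
  (`include-gaps`), because indels can separate otherwise identical
  haplotypes.
* **Nucleotide diversity**: `k` is the unbiased all-pairs mean of
  pairwise difference counts (divide by `C(n,2)`); `pi = k / L_net`. The
  concatenated ("Total") π is the `L_net`-weighted mean of per-locus π,
  identical to π of the concatenation under a shared site policy.
* **Watterson's θ**: `S / a1(n)` with `a1 = Σ_{i<n} 1/i`, total per locus
  and per site.
* **Diversity reduction**: `100·(π_wild − π_dom)/π_wild`, reported to the
  nearest percent.

Internally nothing is rounded; rounding to the printed 4 decimals happens
only at the reporting layer.

## Neutrality tests

Tajima's D is computed from `(n, S, k)` with the standard variance
coefficients; Fu & Li's outgroup-free D* and F* use the corrected
small-sample coefficients, with η (total mutations) counted as distinct
bases minus one per column and singletons as variants carried by exactly
one sequence (derived-allele count 1 or n−1 in simulations, which is the
same folded notion). Statistics are undefined — returned as `None`, never
0 — when `S = 0` (tables print "nd").

**Significance** is simulation-based: neutral standard-coalescent
genealogies conditional on the observed S (exactly S mutations placed
proportionally to branch length), two-tailed. The two-tailed convention
is the *minimum-tail extremeness rank*: the extremeness of a value is its
smaller empirical tail count, and `p = (r+1)/(reps+1)` where `r` counts
null replicates at least as extreme as the observation. This floors at
`1/(reps+1)`, is seed-reproducible, and calibrates to nominal size for D
and F*. D*'s null is a function of the singleton count given S and is
therefore markedly discrete at small S; its exact-test size sits below
nominal there (conservative, never anti-conservative). p-values may
disagree with DnaSP's significance stars in marginal cases; they are
reported raw, with banding left to the consumer.

## Recombination

The four-gamete scan considers only strictly biallelic analysed columns
(triallelic columns violate the infinite-sites premise). `Rm` is the
Hudson–Kaplan bound: the maximum number of pairwise-disjoint open
intervals among incompatible site pairs, found by the greedy
right-endpoint sweep (verified against an exhaustive oracle).

The per-locus population recombination rate `4Nc` is estimated by a
Hudson-style moment method: the observed variance of pairwise difference
counts is matched to `θ + θ²·h(ρ)`, with `θ` estimated by the mean
pairwise difference and `h(ρ)` the average over site pairs of the
classical two-site coalescence-time correlation `(x+18)/(x²+13x+18)`.
`h` decreases from 1 (no recombination) towards 0, so a variance deficit
maps to a positive ρ. The estimate is undefined for monomorphic data or
when the variance falls below the Poisson floor, and is the boundary 0
when the variance is at or above the no-recombination expectation. The
equation is ill-conditioned when the variance sits near that expectation
— estimates can then be arbitrarily large — so pipeline runs cap
per-locus ρ at 100. Hudson's original small-sample correction for the
across-pair sample variance is not reproduced; the estimator is validated
by ordering (simulated ρ=0 vs ρ=20 arms) and determinism, which is all
downstream use requires.

## AMOVA

Single-level analysis of molecular variance on the concatenated
alignment. Squared inter-individual distances are raw pairwise mismatch
counts over analysed columns (no Jukes–Cantor correction — the standard
choice for closely related haplotypic data). Sums of squared deviations
decompose as `SSD_total = SSD_among + SSD_within` (exact by
construction); variance components follow the standard
sums-of-squares-to-components equations with
`n' = (N − Σn_g²/N)/(G−1)`, and `Φst = σ²_a/(σ²_a+σ²_w)`. Significance
permutes individuals among groups, preserving sizes, with add-one
smoothed one-sided p-values. Pairwise group Fst values are two-group
AMOVAs restricted to each pair. The **group-specific Fst** is implemented
as each group contrasted against the pooled remainder in a two-group
AMOVA; the survey's tool does not document its estimator, so this choice
is isolated in one function and its absolute values are not treated as
reproduction targets.

## Bottleneck intensity

The demographic model is a single population of ancestral effective size
`N_a` that dropped instantaneously to `N_p` at `t` generations ago and
stayed there (no expansion, no migration). The intensity is
`α = N_a/N_p ≥ 1`. Calibration follows the survey: `N_a = 30,000`,
`t = 9,000` generations, hence `τ = t/(2N_p) = 0.15·α` in units of
`2N_p` generations — equivalently the change sits at a fixed
`t/(2N_a) = 0.15` in wild-scaled coalescent units, which is the form the
simulator consumes (the α=1 closed-form tests and an msprime
cross-validation at α=2 pin the conversion down). Mutation is scaled to
the wild population: θ_wild = 4·N_a·μ·L per locus; the present-day scaled
mutation rate is θ_wild/α.

Per locus, θ_wild defaults to Watterson's estimate from the wild sample
(the survey says only that it was "obtained" from the wild data; a
π-based alternative is available), and ρ defaults to the wild-group
moment estimate when alignments are available and to 0 for runs driven
by printed summary tables, where per-locus 4Nc was never published.

**Likelihood.** For each α on a 19-point grid (1 to 10, step 0.5) and
each locus, `reps` coalescent replicates are drawn and the locus
likelihood is the proportion of replicates whose simulated per-locus
diversity falls within ±20% of the observed value (a closed band; an
observed 0 accepts only exact zeros). Proportions are floored at
`1/(2·reps)` before logging, so the multilocus log-likelihood — a sum of
logs, never a product — is always finite and ordering-preserving. The
estimate is the grid argmax (ties resolve to the smaller, more
parsimonious α) and the interval collects grid points within 2
log-likelihood units of the maximum. All randomness flows from one
master seed through per-(locus, α) substreams keyed by sorted locus
order, so results are bit-reproducible and invariant to locus ordering.
A surface floored everywhere raises an estimation-failure error rather
than returning a meaningless argmax.

**Replicates.** Library default is 5000 per (locus, α) point; the
shipped reproduction runs and tests use 1000, which parameter-recovery
experiments show is enough for the CI to cover a true α=3 in ≥ 90% of
trials on study-shaped data. The likelihood surface on the real printed
inputs is shallow (see Limitations).

## Synthetic data generator

`generate_study` emulates the survey's shape with known truth: the wild
group is drawn from the neutral coalescent at a configured per-site
θ (default 0.01, the order of the wild group's observed concatenated
diversity), and each domesticated group from the bottleneck model at its
configured α (defaults 1.5/1.5/2.0/1.5 for dehiscent/fiber/oil/winter,
the survey's reported intensities). Mutations are placed on genealogies
under an infinite-sites emulation — each mutation gets a fresh uniform
column while columns remain, then recurrent hits are allowed — and
encoded as substitutions from a uniformly random ancestral sequence. An
optional gap-injection mode plants gap columns to exercise the
site-deletion policy.

What the generator does *not* model: shared ancestry between wild and
domesticated groups (each group's genealogy is independent), migration,
selection, sequencing or alignment error, and ragged sample×locus
coverage. Tests passing on this data therefore validate the estimators
under their own assumptions; they do not show that real flax data meet
those assumptions.

## Numerical and degenerate-input choices

* Undefined statistics are `None` (or NaN for array outputs), never 0.
* π with no analysed sites is NaN; `S = 0 ⟺ π = 0` holds on analysed
  sites.
* Grid ties break toward smaller α; CI endpoints are grid values.
* Permutation and simulation p-values use add-one smoothing; p ∈ (0, 1].
* The ARG path guards against runaway recombination with an event cap.

## Limitations

* The grid likelihood on the survey's *printed* per-locus inputs is very
  shallow for the single groups: for the oil group the surface varies by
  under ~2 log units across α ∈ [2, 5], so the grid MLE wanders in that
  range across seeds while the pooled cultivated sample lands stably at
  1.0–1.5. The four oil loci with printed π = 0 dominate the right tail
  (their exact-zero band favours strong bottlenecks); excluding
  monomorphic loci — a convention the survey does not state — pulls the
  estimate to 2.0–3.0. The reproduction scripts report what the stated
  procedure computes, flatness and all.
* The 2-log-unit interval treats per-locus θ_wild (and ρ) as known. In
  recovery experiments on study-shaped synthetic data at true α=3, the
  interval covers the truth in 19/20 seeded trials when the generating
  θ_wild values are supplied, but only 14/20 when per-locus Watterson
  estimates from the 10-sample wild group are plugged in — the wild
  sample's estimation noise propagates unacknowledged. Survey-style runs
  (which necessarily use estimated θ_wild) should read the interval as
  optimistic.
* Group-specific Fst values depend on an undocumented estimator choice
  (see above) and are compared only qualitatively.
* The rho estimator is a pragmatic moment method for a sensitivity axis,
  not a precision instrument.
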