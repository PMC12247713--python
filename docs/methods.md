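# Methods

This note records the models, defaults and design choices behind
`trnamod`, and what the synthetic validation does and does not establish.

## Misincorporation statistic and null model

The unit of evidence is the per-position misincorporation (MI) frequency:
non-reference base calls (including deletions) divided by total coverage.
Deletions count both as non-reference calls and as coverage, because
heavily modified guanosines (e.g. the trimethylated m²₂Gm) leave
deletion-rich footprints that would otherwise be discarded. A position
with zero coverage yields an explicit `no-coverage` marker, never a silent
MI of 0.

The null model is fitted separately per reference base, per species, on
**unannotated** positions: background misreading is a property of the base
(G and C misread more than A and U) and of the library, not of the
modification. The fit is method-of-moments for a beta distribution; if the
sample variance is degenerate (zero, or at least m(1−m)), the fit falls
back to a configurable floor concentration (default 1000) with a warning.
Canonical positions 1 and 74–76 (the NCCA end) are excluded from fitting
because RT-based protocols accumulate end artifacts there. The same
empirical MI values provide the base-specific 75th-percentile threshold
stored with the null.

Two p-value modes are provided because the role of the 75th-percentile
threshold is genuinely ambiguous:

* `null-tail` (default): p = upper tail of the fitted background beta at
  the observed MI — the probability of a background position misreading at
  least this much.
* `posterior-exceedance`: p = posterior probability that the position's
  latent MI lies **below** the base-specific threshold, treating the
  null's (α, β) as pseudocounts on the observed (mismatch, match) counts.

Both are monotone in MI. Pseudocounts default to the background fit
(`pseudo_source: background`); setting `pseudo_source: known` instead
derives them from the MI moments at known modified positions — supported
because both readings are defensible, but a null intended to calibrate
background tails should itself describe background, hence the default.

Multiple testing is Benjamini-Hochberg within species (the procedure is a
configuration option; BH is the standard choice for a discovery screen).
Confidence classes follow the base-specific rule: high needs adjusted
p < 0.05 **and** MI strictly above 10% (G/C) or 5% (A/U); significant
positions at or below the threshold are moderate. Ties at exactly the
threshold resolve to moderate. Positions under 20 reads (configurable) are
reported but marked `low-coverage` rather than classified.

## Type inference

Different chemistries at the same base and position separate by MI level
and read-identity footprint (m²₂G misreads roughly sixfold more than m²G;
m²₂Gm adds deletions). Profiles per (code, position) store median MI, IQR
and mean composition over annotated instances; fewer than 3 instances
flags the profile low-support. A confident call's candidate codes are
those annotated at the same position/base in related species (same clade
per a user-supplied clade map). Scoring is |MI − median|/max(IQR, 0.05)
plus the total-variation distance between compositions, equally weighted
(both weights configurable); the best candidate needs a margin of 0.5
score units over the runner-up, otherwise the call gets the ambiguity code
`xN`. Deletion-enriched profiles are only assignable to calls with a
deletion fraction above 0.1. The margin and weights are free parameters —
no quantitative separation rule exists in the literature for this — and
the defaults were chosen so that the catalog's six-fold MI separation
assigns cleanly while overlapping profiles abstain to `xN`.

## Homology transfer and concordance

Orthology is operationalised as identity of (isotype, anticodon) — the
community naming scheme — with duplicate isodecoders resolved greedily by
global sequence identity. An annotation transfers only when the target
conserves the reference base at that canonical position and the target's
own call there is high or moderate confidence; every non-transfer is
reported with its failed criterion (`base-mismatch`, `no-signal`,
`no-call`).

Concordance per species pair is the Pearson correlation of (known MI,
predicted MI) over transferred sites. Residuals are taken about the
identity line, not a regression fit, because the question is whether the
two species share the *same* MI, not whether one predicts the other
linearly. Outliers are sites whose residual deviates from the mean
residual by more than twice the residual SD; centring on the mean makes a
common offset (all residuals equal) produce zero outliers, which is the
intended semantics for "discordant site". Fewer than 3 pairs marks a
comparison insufficient rather than reporting an unstable r.

## Pattern analyses

Co-occurrence of modifications at two positions is a 2×2 contingency over
eligible tRNAs — those carrying the modification class's base at **both**
positions (a tRNA with C6 cannot carry m²G6 and is excluded). The package
adds a two-sided Fisher exact test and a Haldane-Anscombe-corrected odds
ratio as the quantitative wrapper around what is usually shown
graphically; descriptive counts are reported alongside. When an
annotation table (known plus predicted records) is supplied, "modified"
means a confident call *at an annotated site*, which makes the analysis
robust to isolated background false positives; without one, any confident
call counts.

Identity-element enrichment tabulates, for each stem pair examined (10:25,
13:22, 12:23, …), the pair identity of every eligible tRNA (`=` for
Watson-Crick, `o` for wobble/other, U rendered for T) against modified
status at the focal position, one Fisher test per identity class versus
the rest. Odds ratios below 1 read as anti-determinants (identity enriched
among unmodified tRNAs).

## Synthetic data: the stated world

The generator mirrors the calling model: latent MI per position is beta
distributed (background means G 0.015, C 0.012, A 0.003, U 0.003,
concentration 300; modification-specific means/concentrations from the
effect catalog), coverage is negative binomial (mean 500, dispersion 10),
non-reference reads split multinomially into a deletion fraction and a
type-characteristic mismatch composition. The effect catalog encodes the
qualitative ordering seen in RT-based profiling: m¹A 0.80, m²₂Gm 0.65,
m²₂G 0.60, m¹G 0.55, m¹I 0.45, m²G 0.10, near-floor marks (t⁶A, cnm⁵U,
Gm) at 0.01–0.015, and a rotation-silent pseudouridine at 0.001. All of
these are configuration, not constants.

The default scenario is 4 species × 40 tRNAs in two clades (tRNA set sizes
in real archaeal genomes run roughly 34–47). Species within a clade share
a tRNA design (orthologous sets and truth table); their latent logit-MI
values at planted sites are drawn from an equicorrelated normal
(correlation 0.9, SD 1.25) whose location is solved numerically so the
marginal mean MI equals the catalog value (plain logit of the mean would
undershoot by convexity). The planting scheme exercises every analysis:
mutually exclusive methylation of the acceptor-stem 6/67 pair in the
"hyperthermophile" clade (plus C6 tRNAs where the modification is
precluded), the G10oU25 determinant of position-10 methylation with weak
D-arm motifs (U13oU22), its anti-determinant relationship with position 26
in one clade and co-occurrence in the other, clade-specific purine-9
methylation, near-universal m¹A58, and Ψ55 everywhere as the negative
control.

A dedicated species-pair simulator draws per-site latent logit-MI from a
bivariate normal with configurable correlation, and can plant discordant
outlier sites by offsetting one species' MI (default 0.2 on the MI scale,
at the sites with most headroom, clipped to [0, 1]).

What a green synthetic test establishes: that the statistics are computed
correctly, the classification implements its definition, and planted
effects of the stated magnitudes are recovered at the stated error rates.
What it does not establish: performance on real libraries with
position-dependent coverage decay, alignment multi-mapping artifacts,
RT-stop signal, shadow signals from neighbouring modifications, or
modification stoichiometries outside the catalog.

## Numerical choices and edge cases

* Beta tails via `scipy.stats.beta.sf`; validated against adaptive
  quadrature of the density to 1e−9.
* BH via `statsmodels.multipletests`; validated against an independently
  written step-up on random vectors.
* Method-of-moments means are clipped to [1e−6, 1−1e−6] before fitting.
* Odds ratios use the Haldane-Anscombe +0.5 correction only when a cell is
  zero, so planted "infinite" associations report large finite values.
* IQR floor 0.05 in type scoring prevents infinite distances for
  degenerate profiles.
* Seeds: every stochastic routine takes its generator from the single
  configured seed through fixed named streams; identical config + seed is
  byte-identical end to end (output files embed a config hash, timestamps
  only ever go to the log).

## Known limitations

* The calling model tests each position independently; modification
  shadows (misincorporation bleeding onto neighbours) are not modelled.
* Ortholog matching is within-clade by (isotype, anticodon); no
  alignment-based ortholog inference across distant clades.
* Type inference abstains (xN) rather than guessing when profiles
  overlap, so heavily overlapping chemistries (position 26's m²G/m²₂G/
  m²₂Gm) will often remain unresolved, as they are in practice without
  mass spectrometry.
* Pooling of replicates happens upstream (counts are summed); replicate-
  aware dispersion estimation is not implemented.
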