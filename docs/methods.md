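# Methods

This note documents the models and procedures `orfunc` implements, the
defaults and why, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Sequence metrics

**Alignment contract.** All pairwise metrics take pre-aligned, codon-aware
sequences; the package does not align. Gaps must occur in whole-codon
units; gap handling is pairwise deletion at the codon level (a codon column
is skipped if either member has a gap there). Orthologous ORs are
near-equal length single-exon ORFs, so codon-aware alignment is a routine
external step.

**Jukes-Cantor.** d = −(3/4) ln(1 − (4/3)p) with p the mismatch proportion
over ungapped sites. The formula's domain ends at p = 3/4; saturation
raises a typed `SaturationError` rather than returning infinity, so
downstream statistics never see non-finite distances.

**Grantham distance.** The residue-pair table is rebuilt at import from
Grantham's (1974) composition, polarity and molecular-volume values with
weights α = 1.833, β = 0.1018, γ = 0.000399 and a scale factor chosen so
the mean over the 190 heterotypic pairs is exactly 100. The published
matrix rounds each entry to an integer and uses a fixed scale (50.723)
whose 190-pair mean is ≈99.97; rebuilt entries therefore differ from the
printed ones by well under 1% (e.g. Ser-Leu 144.3 vs printed 145). The
sequence-level distance is the **mean** per-site table value, not the sum,
so whole-ORF values and binding-site-subset values (e.g. a 22-residue
pocket set supplied as 1-based alignment positions) are on one scale and
directly comparable. No default binding-site position list ships: the
pocket positions are alignment-specific and must be supplied by the user.

**Nei-Gojobori dN/dS.** Per-codon synonymous-site fractions count, at each
position, the synonymous fraction of the three single-base changes;
mutations creating stop codons are excluded from the denominator, which
keeps S + N = 3 × (compared codons). Site counts are averaged over the two
sequences. Codons differing at 2–3 positions are resolved by averaging the
synonymous/nonsynonymous step counts over all orderings of the single-base
steps, excluding orderings that pass through a stop codon; if every
ordering is blocked, all orderings contribute, counting only steps between
sense codons. pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected to dS and
dN; ω = dN/dS carries an explicit undefined flag when dS = 0 and
per-component saturation flags when pS or pN ≥ 3/4. The plain (unweighted)
1986 counting scheme is used throughout; no modified-pathway weighting and
no ML codon models.

**Neighbor-Joining.** Standard NJ via scikit-bio behind the module surface;
the 2-taxon case (below the NJ recursion base) returns a single edge
carrying the full distance. Input matrices must be symmetric and
nonnegative.

## Screen processing

Wells carry firefly (reporter) and Renilla (transfection control)
luminescence. Processing: ratio = firefly/Renilla per well, then min-max
normalization (L_N − L_min)/(L_max − L_min) within a declared scope. The
scope — one plate or a set of plates — is an explicit parameter recorded in
the output (`scope_record`), defaulting to the plate set, because a single
ortholog set is typically screened across plates in one transfection
batch.

Agonist calls: per receptor × odor, a two-tailed two-sample t-test of the
replicate normalized values against the no-odor control at α/n_odors
(α = 0.05, n_odors = 42 in the reference design). Pooled (equal-variance)
variance is the default — with n = 3 per group there is little information
to estimate separate variances — and is switchable to Welch. The tuning
response is the normalized odor mean minus the normalized no-odor mean, so
inhibitory odors are negative and keep both their sign and their
significance flag; display copies zero non-significant cells only.

Tuning curves order odors by the reference receptor's display response,
best ligand at the center index (n−1)//2, subsequent ranks alternating
right, left, right…; the rightward start is arbitrary but deterministic,
and ties break lexicographically by odor label. Every member of an
ortholog set reuses the reference ordering.

## Dose-response analysis

The model is the 3-parameter logistic with Hill slope fixed at 1:
y = bottom + (top − bottom)/(1 + 10^(logEC50 − x)), x = log10 molar.
Fitting is least squares with a multi-start strategy: seven logEC50 starts
spanning the tested concentration range ±1 decade, bottom/top initialized
at the response extremes, best residual sum of squares wins. This guards
against the local minima flat or noisy data induce. Parameter SEs are
asymptotic (from J′J at the optimum scaled by the residual variance); 95%
CIs use the t quantile with df = n − 3. Non-convergence and degeneracy
(overlapping top/bottom CIs) are flags, not exceptions, so batch runs keep
their rows.

The agonist gate requires all three of: (1) top and bottom 95% CIs do not
overlap; (2) SE(logEC50) < 1 log unit — the asymptotic standard error, the
quantity a standard fitting tool reports; (3) the extra-sum-of-squares test
shows the receptor's data need a different curve from the vector-only
control at α = 0.05. Failed criteria are reported by name.

Pair comparison: F = ((SS_pooled − SS_separate)/3)/(SS_separate/(n − 6)),
where the pooled fit constrains one 3PL to both datasets. With the
reference design (2 curves × 7 concentrations × 3 replicates) the
denominator df is 36. A pair with p ≥ α is indistinguishable; with p < α,
receptor A is hyperfunctional if it has both the lower EC50 (more potent)
and the larger span (more efficacious), hypofunctional in the mirror case,
and the pair is undefined when the two shifts disagree in direction.
Separate-SS values that are numerically zero relative to the data scale
(perfect fits) short-circuit to an exact-fit flag. α = 0.05 throughout;
classification requires both members to pass the agonist gate when
controls are supplied (otherwise `not_comparable`). Statistics always run
on the Renilla-normalized responses; `normalize_curve_set` (baseline to the
fitted bottom of the largest-top member and scale by its span, or divide
by a reference member's top) is display-only and never feeds the F test.

## Sequence-vs-function statistics

Functional distance between two receptors is 1 − R, the Pearson
correlation of their full odor-panel display profiles (non-significant
cells zeroed — correlating the zeroed profiles matches how tuning curves
are drawn; raw-profile correlation is available by passing unzeroed
vectors). A pair is excluded when either member responds to fewer than
`min_responsive` odors, default ≥ 3; the stricter "more than three"
reading is one parameter away and both settings are reported in outputs.
Spearman rank correlation (mid-rank ties) relates each sequence metric to
functional distance. Common-ligand rates are responder counts over tested
comparison receptors per stratum (relationship or species pair), with
display rounding to whole percent and exact counts always carried. The
Wilcoxon rank-sum comparison uses the normal approximation with tie
correction and no continuity correction (identical groups give exactly
z = 0); sign convention: z < 0 when the first group is stochastically
smaller. Box-plot summaries report min, 10/25/50/75/90% quantiles
(linear interpolation) and max.

## Odor-panel selection

Descriptors are z-scored per column before clustering — their raw scales
(molecular weight, logP, topological indices…) are incommensurate, and
unstandardized k-means would be dominated by the widest column. Clustering
is seeded k-means++ (scikit-learn, n_init = 10), so a (matrix, flags, k,
seed) tuple determines the panel exactly. Per cluster, the known-active
member nearest the centroid is selected; clusters without actives fall
back to the overall nearest member, and the rule used is recorded per row.
The descriptor matrix itself is an input: computing physicochemical
descriptors from structures is out of scope, and a blob-structured
generator stands in for testing.

## Synthetic data

The generators exist to give every stage inputs with known ground truth.

- **Ortholog pairs**: a random stop-free ORF (first codon ATG) evolves
  along two independent branches; point mutations are proposed uniformly
  (transition/transversion weighting optional) and accepted with
  probability 1 if synonymous, ω if nonsynonymous, never if they create a
  stop; the accepted-substitution count per branch is Poisson with the
  configured mean. ω > 1 is realized by down-weighting synonymous
  acceptance to 1/ω. This acceptance scheme — rather than a full codon
  rate-matrix exponentiation — is simple, auditable, and calibrates well
  at desk scale: realized Nei-Gojobori ω at a 0.3 target, 300 codons, is
  unbiased within ±0.05 over 1000 replicates. It does not model
  codon-usage bias, CpG effects, rate heterogeneity along the sequence, or
  selection that varies by site.
- **Dose-response**: 3PL truth plus Gaussian homoscedastic noise (SD as a
  fraction of span; log-normal multiplicative noise optional), triplicates
  over seven log-spaced concentrations from 10 nM to 10 mM, flat vector
  control.
- **Screens**: per-well firefly/Renilla pairs with configured per-odor
  effects on the ratio scale, including negative (inhibitory) effects,
  plus no-odor and vector wells; Renilla jitters around a common level so
  the ratio step has something to correct. No well-position effects or
  plate drift are modeled.
- **Study**: n ortholog sets whose variant screen profile is the reference
  profile plus Gaussian perturbation with SD proportional to the pair's
  realized nonsynonymous substitution count. Functional divergence is thus
  driven by protein divergence by construction, which is what makes the
  "amino-acid metrics track function more closely than nucleotide
  distance" ordering a recoverable ground truth rather than an assumption.

Because the generators are Gaussian and homoscedastic with independent
wells, passing tests demonstrate correctness of the statistical machinery
under those conditions — not robustness to the heteroscedastic,
batch-structured noise of real plates.

## Problem sizes and determinism

Monte-Carlo suites use seeded generators throughout: 500 replicates for
3PL recovery and extra-SS type-I calibration, 200 for classification
recovery, 1000–2000 screens for family-wise error checks, 1000 replicates
for simulator ω calibration; the end-to-end study uses 12 ortholog sets of
300 codons over a 42-odor panel. These sizes put Monte-Carlo standard
errors comfortably inside the asserted tolerances while keeping the whole
suite to a couple of minutes on one CPU. All simulators are pure functions
of their configurations; reruns are byte-identical.

## Known limitations

- Only the plain NG86 counting method is implemented; no
  modified-pathway weighting, branch or branch-site models.
- The 3PL has a fixed Hill slope; variable-slope or biphasic curves are
  out of scope, as is antagonist quantification.
- SE(logEC50) for the agonist gate is the asymptotic standard error, which
  understates uncertainty for poorly constrained midpoints compared to a
  profile-likelihood width.
- The panel-dispersion advantage of one-per-cluster selection over random
  subsets (measured as mean pairwise distance) is configuration-dependent:
  strong when clusters are balanced and k matches the cluster count,
  weaker when fringe points inflate random-subset dispersion.
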