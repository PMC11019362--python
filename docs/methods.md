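# Methods

This note documents the models implemented in `apohm`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## APOBEC enrichment

For one sample, let `n_mut_c` be its C>T/C>G mutations (pyrimidine
normalized) and `n_mut_tcw` those whose trinucleotide is TCA or TCT.  Around
every such mutation a ±`flank` nt window (default 20) is read from the
reference; `ctx_tcw` counts TCW motifs and `ctx_c` cytosines, both strands.
The fold enrichment is

    E = (n_mut_tcw · ctx_c) / (n_mut_c · ctx_tcw)

so E = 1 when mutations hit TCW exactly as often as the local sequence
content predicts.  Significance is a one-sided Fisher exact test on the 2×2
table `[n_mut_tcw, n_mut_c − n_mut_tcw; ctx_tcw, ctx_c − ctx_tcw]`, BH
corrected across the samples of a cohort.  Classes: high (E ≥ 3), medium
(2 ≤ E < 3), low (1 < E < 2), each requiring adjusted p < 0.01; otherwise
non-APOBEC.  The ±20 nt flank and the Fisher construction are the package's
choices (the class boundaries fix only E and the adjusted-p threshold); both
are parameters.  The same ratio on the tetranucleotide motifs YTCA (Y = C/T)
and RTCA (R = A/G), mutated C third, attributes activity to APOBEC3A vs
APOBEC3B.

## Clonality and cancer cell fraction

Variant copy number: `n_snv = (f_m / p) · [p·C_t + (1 − p)·C_h]`, with `f_m`
the variant allele frequency, `p` tumor purity, `C_t` local tumor copy
number and `C_h` the healthy copy number (2 autosomes, 1 allosomes).
Mutations with `n_snv > 0.75` are clonal.  The CCF is `min(1, n_snv /
n_chr)` where the allelic multiplicity `n_chr` maximizes the binomial
likelihood of the observed read counts at the expected VAF
`n_chr·p / (p·C_t + (1 − p)·C_h)`, over integer candidates 1..round(C_t)
(copies cannot exceed the local total).  Ties go to the smaller multiplicity;
candidates with expected VAF > 1 are infeasible, and a site where every
candidate is infeasible is an error.  The CCF cap at 1 reflects that a
fraction of cells cannot exceed 1.

## Genome tracks

The genome is tiled into 1-Mbp bins (last bin of a contig short).  ChIP-seq
narrowPeak records are q-filtered (q < 0.05; column 9 = −log10 q, −1 treated
as missing and dropped), peak signal mass is apportioned to bins by overlap
length, and a centered moving average with k = 3 is applied per chromosome,
truncating the window at chromosome ends so every bin stays defined for
decile assignment.  Each mark track is z-scored per chromosome (population
sd; constant chromosomes map to 0 — z-scores are used only ordinally
downstream).  Accessibility is the sum of the four mark z-tracks;
high = strictly above the genome-wide median (ties low), and bins are ranked
into genome-wide deciles with boundary ties assigned to the lower decile.
Mutational load is the cohort-mean SNVs per bin (optionally stratified by
TpC context), smoothed the same way.  Expression regions ingest a
precomputed per-bin read-count table; BAM summarization is out of scope.

## Hairpin loops and nearest-neighbor stability

For a mutated site, 50 nt of flank on each side are read (101-nt window);
when the reference base is a purine the window is reverse complemented so
the site reads as a pyrimidine.  All stem-loop configurations whose loop
contains the site are enumerated: loop size 3–10 (the closing pair is not
part of the loop), a stem of ≥ 2 contiguous Watson–Crick pairs growing
outward from the closing pair, and at most one defect — an internal non-WC
pair or a single-nucleotide bulge — never at the closing pair and never as
the outermost pair (either placement would re-parse as a different loop or a
shorter stem).  Maximum stem length is bounded only by the window.

Each configuration's ΔG (kcal/mol, 37 °C) sums: nearest-neighbor stack terms
over adjacent matched pairs; a loop-initiation penalty by loop size, with a
sequence-specific increment for tri-/tetraloops (size ≤ 4, keyed by closing
base + loop + closing base); loop sizes missing from the table extrapolate
logarithmically (Jacobson–Stockmayer) from the nearest tabulated size; a
mismatch increment (the stacks flanking a mismatched pair are not counted);
and a bulge increment (the stack across a 1-nt bulge is retained).  All
parameters live in `src/apohm/data/nn_thermo.tsv`, a versioned TSV that is
the source of truth and can be swapped for an alternative set with the same
layout; the stack and loop-size entries follow the unified DNA
nearest-neighbor ΔG°37 convention, while the mismatch/bulge increments are
single generic values.

"Most stable" means minimum ΔG.  Exact ties break to the longer stem, then
the smaller loop, then the smallest loop start, so the result is unique and
repeated runs agree.  A site counts as *in a loop* only when its best
hairpin is thermodynamically stable (ΔG < 0): a 2-bp stem exists almost
anywhere in a 101-nt window, so bare existence would label essentially every
site in-loop; the threshold is configurable.

## Hotspots, twins, and didymi

A hotspot is a position mutated in ≥ 2 tumors, pooling all substitution
alleles; serial biopsies of one patient count once.  The dominant
substitution at a site is its most frequent pyrimidine-normalized alternate
allele, with ties involving T resolved to C>T.  Twin mutations are two
hotspots inside the loop of a shared stable hairpin; a pair is accepted when
either site's best (centered) hairpin contains both positions, since the two
centered windows can disagree and either is evidence of a shared loop.
Didymi are twins where (a) both dominant substitutions are C>T, (b) the
separation is 1–2 bases, all A/T, and (c) at least one site is TpC —
equivalently the loop matches 101/1001 (1 = G/C, 0 = A/T) with mutated
terminal 1s.

## Driver calling

Hotspots split into two groups: outside loops (tested only in TpC context)
and inside loops (TpC, ApC, CpC, GpC — the didymi partner contexts).  For a
focal site, the recurrence of the *remaining* hotspots is modeled as a
Poisson regression with log link: count ~ accessibility decile outside
loops; count ~ decile + hairpin ΔG + loop-motif flag inside loops.  TpC
sites are stratified by trinucleotide (TCA/TCC/TCG/TCT); a stratum with
fewer than two background sites falls back to the unstratified group model
(flagged).  The accessibility decile enters as a single ordinal numeric
covariate (monotone chromatin effect, fewer parameters in thin strata); ΔG
is continuous in kcal/mol; the loop motif is binary.  Counts are modeled
untruncated even though all catalog entries are ≥ 2.  The focal site's
expected rate λ comes from its own covariates; the exact upper-tail Poisson
test `P(X ≥ n_obs)` is computed with the stable survival function; BH
correction is applied separately within each group, and drivers are sites
with adjusted p < 0.05 (configurable).

Leave-one-out fitting is quadratic if done by refitting.  Strata up to 500
sites refit exactly per focal site; larger strata use the exact closed form
for intercept-only models (`(Σy − y_i)/(m − 1)`) and a one-step Newton
downdate `β_(i) = β − (XᵀWX)⁻¹ x_i (y_i − μ_i)/(1 − h_i)` otherwise, which
agrees with exact refits to ~0.5% in relative rate at a few hundred sites
and tightens as strata grow.  GLM non-convergence (100 IRLS iterations)
falls back to an intercept-only fit with an audit flag; covariate columns
with no variation in a stratum are dropped before fitting.

Model fit is summarized by McFadden's R² = 1 − logLik(model)/logLik(null).

## Synthetic genomes and power

The generator reconstructs the study conditions the driver model assumes:

* 1,000,000 background hotspot positions (scaled preset: 100,000);
* recurrence ~ Poisson(λ = 0.3) truncated to ≥ 2, sampled by inverse CDF
  conditional on the truncation.  λ = 0.3 keeps ~99.3% of background
  positions at ≤ 3 mutations, matching a cohort where nearly all hotspots
  are doubletons; covariate effects on the rate default to zero and can be
  switched on through the config (the parameter-recovery tests do);
* covariates: accessibility decile uniform 1–10; in-loop probability 0.2
  (stable hairpins are a minority of hotspot sites); in-loop ΔG
  ~ −(0.5 + Exp(mean 1.5)) kcal/mol; loop-motif probability 0.15; sequence
  context dominated by TpC (TCA 0.30, TCT 0.25, TCC 0.12, TCG 0.03, ApC
  0.12, CpC 0.10, GpC 0.08), as in an APOBEC-driven cohort;
* 27 spiked drivers with per-cohort prevalence uniform in [0.03, 0.15];
  two-thirds sit in loops (the didymi-like drivers), out-of-loop drivers are
  forced into TpC context (otherwise untestable by design), and in-loop
  drivers carry the loop motif with probability 0.5.

A cohort of n tumors observes Binomial(r, n/115) of each background
position's recurrence r (115 is the reference cohort size; cohorts larger
than the reference superpose the excess rate as Poisson counts so the
expectation stays linear), and Binomial(n, prevalence) for each driver;
positions falling below 2 observed mutations drop out of the catalog.
Power is the fraction of spiked drivers recovered at adjusted p < 0.05 by
the full pipeline, split at 10% prevalence, averaged over replicates with a
Monte-Carlo standard error; the false-positive rate counts background
positions wrongly called.

What the generator does **not** emulate: real sequence (covariates are drawn,
not computed from DNA); linkage between neighboring hotspots (didymi
partners are independent rows); per-sample mutation-burden heterogeneity
(thinning is uniform across positions); and the empirical per-sample ApoHM
count distribution of a real cohort, which is controlled-access — the
truncated-Poisson λ and the thinning reference are documented surrogates
with config hooks for empirical tables.  Passing simulation tests therefore
establish the statistical machinery (calibration, recovery, monotonicity),
not cohort-level numbers on real tumors.

### A structural limit on simulated power

With every one of the 10⁵–10⁶ simulated positions a hotspot by construction,
the thinned per-cohort catalog still contains ~45% of them, and the BH
threshold within a group scales like 0.05·k/m for m tested sites.  At
m ≈ 3×10⁴–4×10⁵ a driver must reach ~10–13 observed tumors against a
fitted background of ~2.1, while a driver at 10–15% prevalence in 75 tumors
averages only 8–11.  The measured power for > 10%-prevalence drivers at
cohort size 75 is therefore ~0.35 under these study conditions, not the
~0.80 that holds when the tested catalog is in the low thousands (the scale
of a real cohort's ApoHM catalog, where the same arithmetic gives a ~9–10
tumor detection threshold).  Equivalently: detection power here is governed
by the multiplicity burden of the simulated catalog size, which is fixed by
the generator's definition, not by the calling machinery.

## Numerical conventions and degenerate inputs

* Coordinates are 1-based inclusive internally (VCF convention); narrowPeak
  converts from 0-based half-open on ingest.
* Enrichment is undefined (error) with no C>T/C>G mutations or no context
  motifs; the exact Poisson test requires λ > 0; BH requires p ∈ [0, 1] and
  enforces adjusted ≥ raw exactly.
* Logistic association (hotspot presence vs continuous E) returns a flagged
  (NaN, NaN) on complete separation or non-convergence rather than a
  misleading Wald p; a degenerate single-class outcome is an error.
* Null-calibration checks of the exact Poisson test are run at a background
  rate of λ = 6: at the catalog-typical rate ~2 the discrete Poisson tail
  cannot produce a rejection fraction near the nominal 0.05 (its largest
  achievable sub-0.05 tail is ~0.02), whereas at λ ≈ 5–8 the support is
  dense enough for the conservative discrete fraction to sit just below
  nominal.
* All simulation outputs are deterministic functions of (config, seed);
  child seeds derive from `numpy.random.SeedSequence.spawn`.
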