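# Methods

## Scope and model

The package analyses three-layer quantitative time courses of adipocyte
differentiation: a global proteome and two PTM-site layers (lysine
acetylome, phosphoproteome) measured at three stages with three
replicates each. All statistics operate on log2 intensities. The
analysis chain is: replicate-presence filtering → normalization →
proteome correction of PTM sites → noise imputation → staged contrasts →
over-representation with pathway directionality → signed weighted
co-abundance network → key drivers.

## Quantification workflow

**Presence filter.** A feature is retained iff it is observed in every
replicate of at least one condition. This is the standard guard against
quantifying features detected only sporadically; it also guarantees each
retained feature has at least one complete condition, which the sporadic
imputation path relies on. The filter is idempotent.

**Normalization.** "Variance stabilization" is implemented as
multiplicative per-sample median alignment (medians over features
observed in every sample, target = geometric mean of the sample medians)
followed by a generalized log, `glog(x) = log2((x + sqrt(x² + a²))/2)`,
with the shift `a` set to the 1st percentile of aligned observed raw
intensities. The transform is monotone per sample, approaches plain log2
for abundant features, and compresses variance near the detection limit;
the contract the tests enforce is that a simulated SD ∝ mean trend
shrinks by at least half. Matrices already delivered on the log2 scale
(e.g. TMT pipelines that transform upstream) skip this stage; the scale
of every input is declared, never guessed, and a raw intensity of 0 is
parsed as missing (not detected).

**Proteome correction.** `corrected = site − parent protein`, per
sample, before any averaging. This ordering makes the algebra exact:
corrected log2FC = raw-site log2FC − protein log2FC for any contrast
computed on fully observed features (the acceptance suite checks this to
1e−12). Sites whose parent protein is not quantified cannot be corrected
and are reported in an unmatched list; the matching key is the protein
accession parsed from the `<protein>_<residue><position>` site ID.
Correction precedes imputation (filter → normalize → correct → impute),
so no synthetic value ever enters the subtraction.

**Imputation.** Missing-not-at-random imputation from a downshifted
Gaussian: per sample, mean = sample mean − 1.8 × sample SD and
SD = 0.3 × sample SD, the de-facto proteomics convention for
left-censored data. Whole condition blocks (0 of n observed) and
sporadic gaps (1–2 of 3) are both imputed, flagged separately, and every
imputed cell is logged. A seed is mandatory; imputation defaults to the
LFQ layers (proteome, acetylome) and off for TMT-style layers, exposed
as a per-layer switch.

## Contrasts

Early/immature-vs-pre, late/mature-vs-immature and complete/mature-vs-
pre contrasts are derived from the ordinal time codes in the design
table. The test is the classic pooled-variance two-sample Student t
(df = n1 + n2 − 2), two-sided; Welch is available behind a flag.
Degenerate zero-variance features follow fixed conventions (equal means
→ p = 1; unequal → p = 0, flagged by an infinite t). BH adjustment runs
per layer × contrast over all testable features; features with fewer
than two observed replicates in either group are excluded from the BH
family and listed as untested. Significance is a strict `adj_p < α`
with α = 0.01 for sites and proteins. Percent-significant tables are
100 × significant / tested. Metabolite-style profiles reuse the same
t machinery against a baseline condition with adjustment deliberately
disabled, attached to z-scored condition-mean profiles (sample SD,
n − 1; constant rows map to zero).

## Enrichment and pathway direction

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with the universe set to the layer's quantified (post-filter)
proteins — the only defensible background for detection-limited PTM
layers. Retention mirrors the cluster-tool convention: overlap ≥ 3,
overlap ≥ 4 % of the term (term-coverage reading), and p < 0.05; raw p
gates retention by default with BH-adjusted p always reported, and the
gate is switchable to the adjusted value. The kappa-based term-grouping
step of the original tooling affects only visualization and is out of
scope. Pathway direction is the median log2FC over *significant* sites
whose parent belongs to the set; sets with no contributing site are
excluded and logged. Cross-dataset comparison is a Pearson correlation
over shared sets (≥ 3 required), with per-set enrichment p-values and a
flag for significance in at least one dataset.

## Co-abundance network

Signed soft-threshold adjacency `((1 + r)/2)^17` is the default: β = 17
is characteristic of signed networks and the analysis distinguishes
positively from negatively trait-correlated modules; unsigned mode is
retained as a flag. The topological overlap matrix uses the standard
formula with connectivity excluding the diagonal. Module detection is
average-linkage clustering of 1 − TOM with a static cut height mapped
from deepsplit (0–4 → 0.99/0.97/0.95/0.93/0.91; the full dynamic-hybrid
algorithm is intentionally not reimplemented, trading its adaptivity for
a deterministic, testable rule). Clusters below the minimum size (50) go
to grey; clusters above the maximum (500) are recursively re-cut at
decreasing heights and kept with a warning if indivisible.

Eigengenes are the unit-norm first right singular vector of the
feature-standardized module submatrix, sign-oriented so the average
correlation with the module's features is non-negative; variance
explained is the first squared singular value over the total. Merging is
closest-pair-first on eigengene dissimilarity 1 − r below the merge cut
0.3, recomputing the eigengene after every merge — the closest-pair rule
makes the final partition independent of input order.

**Membership pruning.** With nine samples, the correlation of an
unrelated feature against a module pattern is heavy-tailed (SD ≈ 0.35),
and the `min(k)` denominator of TOM makes low-connectivity background
features look disproportionately close to large modules, so the static
tree cut accretes background. A final membership step therefore returns
to grey every member whose *signed* kME (correlation with its own
module's eigengene; absolute kME in unsigned mode) falls below 0.9, and
dissolves modules dropping below the minimum size — the stringent end of
the common kME-to-stay practice in weighted correlation network
analysis. True members track their eigengene far more tightly than
chance correlators, so the threshold discriminates independent of module
size.

Module–trait statistics are Pearson r of each eigengene against the
standardized ordinal time code with the two-sided t-transform p
(n − 2 df). Key drivers rank module members by |kME| × |GS| — the
simplest combination monotone in both membership and trait significance,
exposed as a pluggable scorer — with ties broken by feature ID. The
Top-30 network reports TOM among the selected features rescaled by the
module-wide off-diagonal maximum to [0, 1]; edges at or above 0.5 are
emphasized.

## Synthetic data generator

The generator emulates the study design, not mass spectra: log-normal
baseline intensities (Gaussian in log2, mean 25, SD 2), PTM sites riding
additively on their parent protein's realized log2 value with a
site-specific offset (mean −2), Gaussian noise (default SD 0.5 log2
units), and an ordinal trait 0/1/2 across preadipocyte/immature/mature
with three replicates each.

**Planted modules.** Four modules (150/120/90/70 features, 70 %
proteins / 20 % acetyl sites / 10 % phospho sites; module sites ride on
background parents so proteome correction preserves their pattern). Each
module's sample pattern is sign × amplitude × centered time code plus a
condition-level component orthogonal to the trait (scale 0.6 ×
amplitude, anti-aligned between same-signed modules). The orthogonal
part is constant within a condition so it never inflates replicate
variance, and it keeps same-signed eigengene dissimilarity ≈ 0.5, well
above the 0.3 merge cut. The default amplitude of 1.75 log2 per stage
step (≈ 11-fold across the complete process) represents the strongly
differentiation-coupled programs such modules capture — lipogenic
enzymes change by an order of magnitude during adipogenesis — and puts
planted members' kME near 0.95, cleanly separated from chance
correlators at the 0.9 pruning threshold.

**Gene sets.** Twelve disjoint sets of 8–12 proteins drawn outside the
modules; every member carries at least one acetyl site. Each set gets a
direction (±1) per cell line — concordant between the two simulated
lines for a configurable fraction — and a per-set amplitude
(2.0 × U(0.75, 1.25) log2 per stage step, i.e. complete-process
fold changes of 8–32×) applied to its members' acetyl-site offsets, so
the effect survives proteome correction and clears BH at adjusted
p < 0.01 with triplicate df = 4 tests. Each effect site also receives a
site-specific quadratic-in-time component (orthogonal to the linear
trait, constant within condition, zero net effect on the complete
contrast) that decorrelates the direction-planted sites from each other
and from the modules; without it they would form a single spurious
trait-correlated cluster bridging the planted modules.

**Missingness.** Abundance-dependent censoring removes whole condition
blocks of the lowest-intensity features at a rate that decays with the
time code (default 10 % at the first stage, 0 at the last), emulating
the increase in detected sites with maturation, plus a 2 % sporadic
rate. Censoring is rank-based, so raising the censoring fraction never
un-censors a block.

Two cell lines share every structural draw (features, modules, sets,
patterns) and differ in noise, censoring and the discordant subset of
set directions; all randomness flows from one seed through named
sub-streams, so identical configs are bit-identical.

## What the generator does not emulate

Peptide/spectrum-level effects (missed cleavages, TMT reporter
compression, match-between-runs), realistic pathway topology or
correlated gene-set membership, batch effects, and biological variance
heterogeneity across features. Passing tests demonstrate the pipeline's
algebra, calibration and recovery behaviour under the planted model —
they do not certify performance on real acquisitions.

## Numerical and design choices

* Correlations are Pearson throughout; p-values via the t-transform.
* BH adjustment delegates to `statsmodels.multipletests`; the test
  suite checks it against a brute-force threshold search.
* Hierarchical clustering uses `scipy.cluster.hierarchy` average
  linkage; TOM and eigengenes are vectorized in numpy and verified
  against triple-loop and full-SVD oracles.
* Features imputed as whole condition blocks are excluded from the
  network feature space (they remain in the contrasts): their shared
  downshift at censored stages is a synthetic monotone pattern that
  would otherwise seed artifactual trait-correlated modules. Sporadic
  imputations stay.
* Module recovery is scored as the adjusted Rand index over features
  assigned in both the detected and planted labelings: features planted
  with genuine trait-coupled effects outside the modules (the gene-set
  sites) are legitimately co-abundant with module members, so absorbing
  them is not an error of the partition.
* Ties (driver scores, merge candidates, color assignment) break by
  identifier order; all outputs are byte-deterministic given config and
  seed, and result files carry a provenance header (version, seed,
  config hash) with no timestamps.
* Default problem sizes (600 proteins, ≈ 500 sites per PTM layer,
  ≈ 1 600-feature network) give stable module recovery and keep a full
  run in seconds on one CPU.

## Known limitations

The static-height tree cut plus kME pruning approximates, but is not,
the dynamic-hybrid cutting of the reference framework; with very weak
modules it will under-assign rather than adapt. At three conditions the
condition-pattern space is two-dimensional, so strongly trait-coupled
features are intrinsically mutually correlated — distinct biological
programs with the same temporal direction cannot be separated by
co-abundance alone. The empirical null false-positive fraction of the
BH-gated t-test at df = 4 is conservative (near zero) rather than tight
at the nominal level.
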