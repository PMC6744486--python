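# Methods

## The demographic model

`ginkgopop` centres on a four-lineage split-plus-admixture demography for
*Ginkgo biloba* populations in China: the EAST, SOUTH, NORTH and SWEST
lineages.  Backwards in time the model is

* a pulse at **139,260 years** founding NORTH, each NORTH lineage tracing
  to SOUTH with probability **f = 0.7155** and to SWEST with 0.2845;
* a split at **318,120 years** merging SOUTH into the EAST line;
* a split at **515,780 years** merging SWEST into the EAST line, at which
  point the EAST line takes the ancestral size **N_e = 50,514** diploids.

Descendant lineages default to N_e = 28,456 diploids (midpoint of the
inferred 24,819–32,093 range) and are individually overridable.  The size
of the EAST+SOUTH ancestor between the two splits is not separately
estimated anywhere; we use the EAST deme's size for that interval (it is
configurable through the per-deme overrides).

Scaling constants: generation time **g = 20 years** and mutation rate
**μ = 0.67 × 10⁻⁹ per site per year**, giving μ_gen = 1.34 × 10⁻⁸ per
generation and a neutral diversity scale 4Nμ_gen ≈ 2.7 × 10⁻³ per site for
N = 50,514 — the order of magnitude observed in the resequencing data this
package emulates.  Whether μ is per year or per generation is not
decidable from the published constants alone; the per-year reading is the
default because 4 × 50,514 × (20 × 0.67e−9) reproduces the observed π
scale, and a `mu_is_per_generation` flag switches the interpretation.

## Coalescent simulation

The structured coalescent is simulated backwards in time: within a deme of
diploid size N each lineage pair coalesces at rate 1/(2N) per generation;
splits move all child-deme lineages to the parent; pulses move each
recipient lineage independently to a source drawn with the pulse
fractions; size changes are instantaneous.  Simultaneous events apply in a
fixed order (size changes, then pulses, then splits; ties broken by deme
label), and multi-source pulses are compiled to a chain of conditional
moves with renormalized fractions, so event handling is deterministic.
Time is continuous (exponential waiting times); a single seeded generator
drives each run.

Two implementations share this event model:

* an explicit-genealogy simulator (plain Python) used for genotype
  simulation and as a cross-check;
* a flat-array kernel (numba-compiled) that accumulates branch lengths
  directly into the joint SFS lattice — every branch adds its length to
  the cell indexed by its per-deme descendant-leaf counts.  This is the
  engine behind expected-SFS evaluation (50,000 four-deme replicates of
  20 + 20 + 20 + 20 lineages run in under a second).

The two routes are asserted against each other in the tests, and against
msprime and the classical closed forms (E[T₂] = 2N, ξ_i ∝ 1/i,
E[S] = θ a_{n−1} L).

Genotypes are simulated as independent non-recombining loci with free
recombination between loci (matching the SFS composite-likelihood
assumption of unlinked sites), infinite-sites mutations dropped as a
Poisson process over branch lengths, and haploids paired into diploids
within demes.  No migration occurs after splits (none was detected among
the ancient lineages).  The optional sweep injection replaces each site in
a chosen interval, with probability 1 − escape_fraction, by a
high-frequency-derived site (derived count n−1 or n; count n fixes and
removes the site), producing the diversity-depleted, spectrum-distorted
signature a hard sweep leaves.

What the generator does *not* emulate: genotype-likelihood uncertainty,
sequencing error, non-uniform missingness, linked selection, and
recombination within loci.  Tests passing on these simulations therefore
validate the estimators and the inference chain, not robustness to
real-data artefacts.

## Statistics

* π = (1/L) Σ_s [n_s/(n_s−1)] 2p_s(1−p_s) (unbiased per-site correction;
  equals the mean pairwise difference per site), θ_W = S/(a_{n−1}L).
  Table-style SDs are computed across 100-kb windows.
* F_ST: Hudson's estimator as a ratio of averages across sites (numerator
  and denominator summed separately); Weir–Cockerham available behind
  `estimator="wc"`.  Negative estimates are reported as computed.
* IBS distance: d(i,j) = Σ|g_i − g_j| / (2 m_pair) over pairwise-complete
  sites (PLINK `--distance 1-ibs`), with the dispersal classification
  brackets [0, 0.03), [0.03, 0.07), [0.07, 0.09], (0.09, 1].
* Joint SFS by hard-call counting; sites with missing calls in the
  involved populations are excluded (the genotype-likelihood projection
  used upstream of fastsimcoal in the original workflow is out of scope).
* Folding merges each lattice cell with its complement onto the global
  minor side; the tie layer (total count exactly n/2) keeps the
  lexicographically smaller index vector.

## Structure inference

PCA standardizes each polymorphic site as (g − 2p)/√(2p(1−p)), mean-imputes
missing entries, and eigendecomposes XXᵀ/M (PLINK `--pca` convention);
percent variance is eigenvalue/trace.  Neighbor joining follows
Saitou–Nei with the Studier–Keppler Q-criterion; ties are broken by the
lexicographically smallest pair of subtree-minimum leaf labels, making the
output deterministic on degenerate matrices; negative branch lengths are
retained and flagged.  The ancestry model maximizes the binomial
likelihood Σ [g ln(qᵀp) + (2−g) ln(1−qᵀp)] (combinatorial constant
omitted) by EM block relaxation (frappe-type multiplicative updates),
allele frequencies clipped to [10⁻⁶, 1−10⁻⁶], convergence at a loglik
gain below 10⁻⁴, best of R seeded restarts.  Cross-validation masks
random genotype entries (fold partition at the entry level) and scores
them by squared error against the expected genotype 2·qᵀp.

## Demographic fitting

The composite likelihood is multinomial over polymorphic SFS cells,
lnL = Σ m_c ln p_c, with expected probabilities from Monte-Carlo
simulation; zero cells are floored at 1/(10 · n_sims · n_cells) and the
spectrum renormalized so the likelihood stays finite.  Optimization is
cyclic conditional 1-D maximization (ECM-style): per parameter a coarse
13-point scan over the bounds (log-spaced for sizes and times, linear for
fractions) followed by an 11-point refinement between the neighbors of
the coarse optimum.  Every evaluation within a cycle reuses one
simulation seed (common random numbers), so the noisy objective is a
deterministic function of the parameter during a search; a fresh batch is
drawn between cycles.  Invalid parameter combinations encountered at the
bounds (e.g. a split time searched below an event that depends on it)
score −∞ and are counted on the result.

Two likelihood constructions are available.  The default scores the full
joint SFS.  The `sfs_mode="pairwise"` construction sums the composite
log-likelihoods of all folded two-deme marginal (2D) spectra — the same
decomposition the original fastsimcoal workflow used.  At desk-scale
Monte-Carlo sizes the full 4-D lattice (~10⁵ polymorphic cells for 20
haploids per deme) is thinly populated and the ln of noisy cell
probabilities acquires a Jensen-type bias that varies with the parameter,
shifting profiles by up to ~20%; the pairwise spectra concentrate the same
information into ~10³ well-populated cells, where the recovery
experiments are unbiased at the grid resolution.  The recovery protocol
therefore uses the pairwise construction.  Folding is applied per 2D
marginal (folding does not commute with marginalization, so the
observation is simulated unfolded and folded pairwise).

Model comparison uses AIC = 2k − 2 lnL̂ and Akaike weights
w_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC_j/2); shipped templates are the full
admixture model, a bifurcating no-admixture alternative (NORTH as a plain
split from SOUTH), and a single constant-size deme.  Confidence intervals
come from a parametric bootstrap: multinomial draws of n_sites sites from
the fitted expected spectrum, refit per replicate, percentile 2.5/97.5.

Scale: the original workflow ran each model 100 times with 100,000
simulations per likelihood and compared 50 independent runs.  The package
defaults are 3 restarts and 20,000 simulations per evaluation (40,000 in
the recovery experiments), chosen as the point where the recovery
experiments are stable at the search-grid resolution; the full settings
remain reachable through the function arguments and the config file.

## Selection scan

Windowed statistics use 0-based half-open windows (default 100 kb;
50/100/200 kb mirror the robustness grid); VCF's 1-based positions are
shifted down by one before windowing.  Windows with fewer than `min_snps`
(default 10) SNPs are excluded from the genome-wide Z-transformation and
from calling.  A window is called selected when Z(F_ST) ≥ 2.326 and
Z(H_E) ≤ −2.326 (1% normal tails; both configurable — the original
cutoffs live in a supplementary note and are not reproduced here).

The CLR scan implements the SweepFinder/SweeD model on folded spectra (no
outgroup polarization in scope).  At a grid position x with intensity α, a
lineage at distance d escapes the sweep with probability 1 − exp(−αd).
With k of n lineages escaping, the site's configuration is the genome-wide
background spectrum projected (hypergeometric) onto k+1 lineages, with one
uniformly chosen lineage replicated n−k times — the hitchhiking class —
then conditioned on polymorphism across the full mixture over k.  The
folded background is unfolded symmetrically for the projection and the
model probabilities re-folded.  CLR(x) = 2[max_α lnL(α) − lnL(background)]
maximized over 21 log-spaced α values (10⁻⁵–10² per bp) plus the
background-equivalent limit, so CLR ≥ 0 everywhere; likelihood gains below
round-off (10⁻⁸ relative) report CLR = 0 with α̂ = 0.  Projection rows are
cached per k.

The study's real-data counts (7 and 46 selected windows; 910/949 CLR
regions; gene overlaps) depend on the actual genomes and annotation and
are not reproduction targets.

## Numerical and interface conventions

* All stochastic stages require an explicit seed; identical seeds give
  byte-identical outputs (asserted for the simulator's VCF output).
* VCF 4.2 subset with GT only and placeholder REF/ALT (A/T); 1-based
  positions.  Window/BED outputs are 0-based half-open.  The SFS text
  format is a header of per-deme haploid sizes + folded flag + labels,
  then the row-major flattened lattice.
* Undefined statistics (no usable sites, no shared sites for a pair)
  return NaN, never 0.
* Threads may be requested on the CLI; results are independent of the
  thread count (statistics are deterministic given the seed).

## Known limitations

* The coalescent is exact but not recombining; linkage disequilibrium and
  haplotype-based statistics are out of scope.
* The ancestry model's CV error is a masked-entry reconstruction error;
  it tracks ADMIXTURE's CV qualitatively but is not numerically identical
  to that implementation's projection scheme.
* Composite-likelihood standard errors are invalid by construction
  (cells/pairs are not independent); only the parametric bootstrap is
  offered for uncertainty.
* The sweep injection is a spectrum-level stand-in for a hard sweep, not
  a forward simulation; it produces the qualitative signature (diversity
  loss + high-frequency derived excess) the scan is designed to detect.
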