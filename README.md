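# ginkgopop

Population-genomic inference for split-plus-admixture demographies,
built around the evolutionary history of *Ginkgo biloba* — a "living
fossil" whose Chinese populations comprise four ancient lineages (EAST,
SOUTH, NORTH, SWEST) shaped by Pleistocene refugia, a glacial admixture
event, and human-aided dispersal.

The package provides, as one tested pipeline:

* a **structured-coalescent simulator** for demographies with dated
  splits, dated admixture pulses and piecewise-constant sizes — producing
  genealogies, expected site-frequency spectra (SFS), and diploid
  genotype matrices (VCF), with an optional injected selective-sweep
  signature;
* **diversity and differentiation statistics**: nucleotide diversity π,
  Watterson's θ_W, expected heterozygosity H_E, Hudson/Weir–Cockerham
  F_ST, the joint (2D/nD) SFS, and pairwise identity-by-state (IBS)
  distances with the dispersal classification brackets
  (< 0.03 / 0.03–0.07 / 0.07–0.09 / > 0.09);
* **structure inference**: PCA of the variance-standardized relationship
  matrix, neighbor-joining trees, and ADMIXTURE-style ancestry estimation
  (binomial likelihood, EM block relaxation, entry-masking
  cross-validation over K);
* **SFS composite-likelihood demographic fitting** in the fastsimcoal2
  style: multinomial composite likelihood over polymorphic cells (full
  joint or summed pairwise folded 2D spectra), ECM-style 1-D conditional
  maximization with common random numbers, AIC/Akaike-weight model
  comparison, parametric-bootstrap confidence intervals;
* a **two-pronged selection scan**: Z-scored H_E/F_ST in non-overlapping
  windows with a joint-tail caller, and a SweepFinder/SweeD-style
  composite likelihood ratio (CLR) test against the genome-wide folded
  background spectrum.

The shipped demographic model is the study's best-fit scenario: the SWEST
lineage diverged from the EAST+SOUTH ancestor 515,780 years ago, SOUTH
split from EAST 318,120 years ago, and NORTH was founded 139,260 years
ago by an admixture pulse of 71.55% SOUTH + 28.45% SWEST ancestry;
ancestral N_e = 50,514 diploids, descendant lineages ≈ 28,456 (midpoint
of 24,819–32,093), μ = 0.67 × 10⁻⁹ /site/year, generation time 20 years.
The model, statistics and fitting machinery are the core; the simulator
stands in for the resequencing data so every stage runs and is testable
without any downloads.  See `docs/methods.md` for the model details,
estimator definitions, numerical choices and limitations.

## Worked example

```python
from ginkgopop import (build_ginkgo_model, SampleConfig, simulate_genotypes,
                       diversity_summary, simulate_sfs,
                       ginkgo_admixture_template, fit_model)

model = build_ginkgo_model()
samples = SampleConfig({d: 5 for d in model.demes})   # 5 diploids/lineage
data = simulate_genotypes(model, samples, n_loci=40,
                          locus_length_bp=50_000, seed=42)
print(diversity_summary(data, window_bp=50_000).table.round(5))

obs = simulate_sfs(model, samples, 20_000, folded=False, seed=1)
tmpl = ginkgo_admixture_template(free_params={"f_south": (0.0, 1.0)})
fit = fit_model(obs, tmpl, samples=samples, n_restarts=1, n_sims=20_000,
                seed=7, max_cycles=1, sfs_mode="pairwise")
print(f"f_south estimate: {fit.estimates['f_south']:.4f}")
```

prints

```
lineage  n_samples  n_snps      pi   pi_sd  thetaw  thetaw_sd
   EAST          5   14494 0.00288 0.00234 0.00256    0.00179
  SOUTH          5   12882 0.00246 0.00189 0.00228    0.00133
  NORTH          5   16546 0.00302 0.00229 0.00292    0.00181
  SWEST          5   11816 0.00222 0.00213 0.00209    0.00150
f_south estimate: 0.7167
```

Per-lineage diversity sits at the expected few-×10⁻³ per site (4Nμ_gen ≈
2.7 × 10⁻³), NORTH is the most diverse lineage (its admixed origin mixes
two divergent sources), and the NORTH ancestry fraction re-estimated
from a simulated joint SFS lands within half a percentage point of the
generating 0.7155.  SDs are across 50-kb windows.  (IBS distances in
such a small SNP-only panel all exceed the 0.09 deep-divergence cutoff —
the classification brackets are calibrated for dense whole-genome panels;
`ibs_distance_matrix` + `classify_pairs` apply them to any matrix.)

## Command line

```sh
ginkgopop --seed 1 simulate --model ginkgo --diploids 10 --out sim/
ginkgopop stats --vcf sim/sim.vcf --popmap sim/popmap.tsv --out diversity.tsv
ginkgopop dist  --vcf sim/sim.vcf --out ibs.tsv --classify pairs.tsv
ginkgopop nj    --dist ibs.tsv --out tree.nwk
ginkgopop pca   --vcf sim/sim.vcf --out pca
ginkgopop --seed 2 admix --vcf sim/sim.vcf --k 4 --out admix
ginkgopop sfs   --vcf sim/sim.vcf --popmap sim/popmap.tsv \
                --pops EAST,SOUTH,NORTH,SWEST --out obs.sfs
ginkgopop --seed 3 fit --sfs obs.sfs --template ginkgo-admixture \
                --free f_south=0:1 --out fit
ginkgopop scan  --vcf sim/sim.vcf --popmap sim/popmap.tsv \
                --focal EAST --other SWEST --clr --out scan
```

Every stochastic stage requires `--seed` and is bit-reproducible; each
stage writes a `*.runlog.json` with seeds, versions and input digests.

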