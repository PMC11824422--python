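# strainsfs

SFS-based inference of demographic histories and distributions of
fitness effects (DFEs) for recombining bacterial populations sampled as
quasi-phased strain haplotypes across hosts.

The package covers the full analysis chain:

1. **synthetic** — generators for every pipeline input with known ground
   truth (host pileups with two-strain mixtures and read-depth noise,
   Poisson SFS draws, Brownian-motion traits on trees), plus independent
   validation oracles: a forward Wright–Fisher simulator, stationary
   Poisson-Random-Field quadrature, and an msprime coalescent oracle.
2. **phasing** — quasi-phasing of per-host call tables (major allele
   called iff within-host frequency ≥ 0.8 and depth ≥ 20), gene
   copy-number/prevalence filters (core ≥ 95%, accessory 30–70%,
   CN 0.3–3.0), near-clonal lineage exclusion (divergence < 2×10⁻⁴/bp),
   and masking of low-recombination windows (below-median 1 kb tiles)
   and selective sweeps (± 1,000 bp flanks).
3. **sfs** — folded minor-allele spectra from quasi-phased haplotypes,
   with hypergeometric projection to a fixed sample size (default
   n = 14; sites seen in fewer hosts are omitted; fractional projected
   counts retained).
4. **engine / demography** — expected folded SFSs under one-, two- and
   three-epoch histories from a Chang–Cooper finite-volume diffusion
   solver with Richardson extrapolation over three frequency grids;
   multinomial maximum likelihood with θ profiled out, ≥ 25-start
   searches, AIC model selection, 3-log-likelihood-unit confidence
   regions, and conversions N_anc = θs/(4 μ L_syn) (μ = 4.08×10⁻¹⁰) and
   years = τ·2 N_anc·365.
5. **dfe** — gamma and neutral+gamma DFEs over |s| fit by Poisson
   composite likelihood conditional on the fitted demography, with
   θns = 2.31·θs; expected spectra are mixtures of cached selected
   spectra over a log-spaced γ = 2·N_anc·s grid (mass beyond |γ| = 2000
   treated as lethal, i.e. contributing no polymorphism).
6. **compare** — likelihood-ratio tests for DFE equality between two
   datasets on the s or 2·N_anc·s scale (full model: independent
   shape/scale; constrained: shared, grid search plus local refinement),
   Bonferroni-corrected χ²(df=2) critical values (18.30 for m = 471,
   11.77 for m = 18, ≈ 6 for m = 1), and the genus-contrast rank-sum
   test with a species-label permutation control.
7. **phylo** — Pagel's λ by maximum likelihood (upper bound set by
   positive-definiteness, so λ̂ may exceed 1), χ²(1) test against λ = 0,
   and leave-out re-analysis on the pruned tree.
8. **pipeline / cli** — YAML-configured orchestration with per-species
   run directories and plain TSV/JSON artifacts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (engine vs
closed forms and brute-force oracles, CI coverage, DFE parameter
recovery, LRT type-I/power calibration, Pagel's λ calibration); the
full suite takes roughly 15–20 minutes on one CPU.

## CLI

```bash
strainsfs critical --m 471                 # Bonferroni chi-square threshold
strainsfs run-all --config config.yaml     # simulate -> phase -> SFS -> fits
strainsfs phase --calls calls.tsv --out qp.tsv
strainsfs sfs --haplotypes qp.tsv --out-prefix spectra
strainsfs fit-demog --sfs spectra.synonymous.tsv --out demog.json
strainsfs fit-dfe --sfs spectra.nonsynonymous.tsv --demog demog.json \
    --l-syn 1e6 --out dfe.json
strainsfs phylosignal --tree tree.nwk --traits traits.tsv
```

A minimal simulation config:

```yaml
out_dir: run
demog_families: [one, two]
dfe_families: [gamma]
simulate:
  n_hosts: 20
  n_haplotypes_target: 14
  genome_length: 30000
  frac_synonymous: 0.3
  theta_s: 800.0
  depth_mean: 60
  strain_major_fraction: 1.0
  demography: {epochs: [1.0, 0.3], change_times: [0.05]}
  dfe: {family: gamma, shape: 0.3, scale: 0.00333, n_anc_ref: 10000.0}
```

## Conventions

* Time is measured in units of 2·N_anc generations; τ values are times
  before present, oldest first.
* θ = 4·N_anc·μ·L; γ = 2·N_anc·s where s is the selective effect of a
  haploid carrier (deleterious s < 0 handled as gamma-distributed |s|).
* Coordinates are 0-based half-open; mask intervals use union semantics.
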