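# lewontin

Genetic diversity across metazoans spans roughly three orders of magnitude
while census population sizes span more than twelve — the long-standing
puzzle known as **Lewontin's Paradox of Variation**. Under neutral theory,
pairwise nucleotide diversity at equilibrium is π ≈ 4·N·μ, so if the
effective size tracked the census size N_c, diversity should vary across
species nearly as much as abundance does. It does not.

This package provides a tested pipeline for quantifying that discrepancy and
for asking whether linked selection could explain it. It is aimed at
population geneticists and macroecologists who want to:

- **estimate census sizes macroecologically**: range area from α-shapes of
  occurrence coordinates (clipped to landmasses or oceans), population
  density from the Damuth-style abundance–body-size allometry (with body
  mass imputed from length when needed), and N_c = D·R;
- **fit the diversity–census-size relationship**, by OLS with bootstrap
  intervals and by a Bayesian phylogenetic mixed-effects model
  y = α + βx + u + ε with u ~ MVN(0, σ_p²C) on a time-calibrated phylogeny,
  reporting the phylogenetic signal λ = σ_p²/(σ_p² + σ_r²);
- **test for shifts in the rate of trait evolution** with node-height tests:
  robust (Huber) regression of |standardized phylogenetic independent
  contrasts| on node age;
- **predict diversity under linked selection**. The combined background
  selection (BGS) + recurrent hitchhiking model is

  π = θ / (1/B(U, L) + 2·N·S(γ, J, L)),  θ = 4·N·μ,

  with B = exp(−U/L) the BGS factor (U deleterious mutations per diploid
  genome per generation, L map length in Morgans) and S = γ·J/L the sweep
  coalescence rate (γ adaptive substitutions per generation, J the
  probability a sweep traps a lineage pair). Predictions pass through the
  four-alleles mutation model π = θ/(1 + 4θ/3), which caps diversity at 3/4.
  Defaults are strong-selection Drosophila melanogaster estimates
  (U = 1.6, γ = 2.26×10⁻³, J = 4.5×10⁻⁴, μ ∈ [10⁻⁹, 10⁻⁸]);
- **validate census sizes against global biomass**: implied per-phylum
  carbon biomass (wet mass × 0.15) compared with described global biomass.

A synthetic-data module generates chronograms (pure-birth), traits (Brownian
motion with rate shifts), allometries, diversity with a target phylogenetic
signal, and area-uniform occurrence points, so every stage has a
parameter-recovery test with known ground truth and no downloads.

## Worked example

```python
from lewontin import synthetic_data as sd, phylo_comparative as pc, linked_selection as ls

ds = sd.simulate_dataset(sd.SimConfig(n_taxa=166, seed=1))

ols = pc.ols_diversity_nc(ds.taxa["pi"], ds.taxa["N_c"], seed=1)
print(ols.slope, ols.percent_per_decade)     # 0.0570  14.0

mm = pc.fit_phylo_mm_subset(ds.taxa, ds.tree, phylum=None, seed=1)
print(mm.summary.loc["beta", "mean"])        # 0.0617
print(mm.summary.loc["lambda", "mean"])      # 0.737
print(mm.converged)                          # True

R = ls.reduction_factor(1e6, 1.6, 1.05, 2.26e-3, 4.5e-4)
print(R)                                     # 0.1532
```

The synthetic dataset was generated with a diversity slope of 0.0531 per
decade of census size and phylogenetic signal λ = 0.67; the OLS fit
(slope 0.0570, i.e. a 14% increase in diversity per order of magnitude of
N_c) and the mixed-model posterior (β mean 0.0617, λ mean 0.74, Rhat < 1.01)
recover both within their uncertainty. The last line evaluates the combined
BGS + hitchhiking reduction for D. melanogaster parameters (N_e = 10⁶,
L = 1.05 M): R = 0.153, an ~85% predicted reduction in diversity.

The same stages are available from the shell:

```sh
lewontin simulate --n-taxa 166 --seed 1 --out sim/
lewontin run-all --taxa sim/taxa.csv --tree sim/tree.nwk --seed 1 --out run/
```

which writes per-stage CSV/JSON outputs and a JSON run manifest.

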