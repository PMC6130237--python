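# flowerweb

Analysis of quantitative plant–butterfly flower-visitation networks: who
visits whom, how unevenly, and whether the community is organised the way
mutualistic webs usually are. The package is written for community
ecologists who have per-habitat visitation matrices (plants × flower
visitors, integer visit counts) or long-format census records, and want
the standard network battery — assemblage diversity and similarity across
habitats, nestedness with null-model significance, and species-level
roles — as reproducible, seeded computations rather than a collection of
one-off scripts.

## What it computes

With `a_ij` the visits of butterfly *j* on plant *i*, `R`/`C` the guild
richnesses and `m = Σ a_ij`:

- **Assemblages** — Shannon diversity `H' = -Σ p ln p` per habitat
  (presence data gives `H' = ln S`), classic Jaccard similarity
  `J = |A∩B|/|A∪B|`, UPGMA clustering of habitats on `1 - J`, and node
  support from a species bootstrap (columns resampled with replacement;
  support = % of replicates in which a node's exact leaf set reappears).
- **Network level** — web asymmetry `WBAS = (C-R)/(C+R)`,
  interaction-strength asymmetry ISA (mean normalised dependence asymmetry
  over links; positive = visitors depend more on plants), specialization
  asymmetry `SA = mean d'_visitors - mean d'_plants`, and the Shannon
  diversity of interactions `H'_int = -Σ (a_ij/m) ln(a_ij/m)`.
- **Nestedness** — NODF on the binarized web (strict decreasing-fill paired
  overlap, 0–100) tested against 1,000 draws of the probabilistic **Ce**
  null model, `p_ij = (d_i/C + d_j/R)/2`, with an add-one upper-tail
  p-value.
- **Species level** — degree DEG, species strength ST (sum of the
  partners' dependences on the species; conserved guild-wise), interaction
  push/pull IPP in [-1, 1], Blüthgen-style d' specialization in [0, 1],
  and Gc core–periphery (`(k - k̄)/σ_k`, core if Gc > 1).
- **Synthetic data** — a seeded generator of single- and multi-habitat
  censuses (lognormal abundances, multinomial census effort, planted
  habitat clades) so every stage is testable without field data.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

```python
from flowerweb import (SyntheticConfig, generate_web, network_metrics,
                       nestedness_test, species_strength)

web = generate_web(SyntheticConfig(R=20, C=40, n_visits=2000, seed=1))
nm = network_metrics(web)
print(f"size={nm.size} (R={nm.R} plants, C={nm.C} visitors), links={nm.links}")
print(f"WBAS={nm.WBAS:.3f}  ISA={nm.ISA:.3f}  SA={nm.SA:.3f}  H'_int={nm.H_int:.3f}")

res = nestedness_test(web, n_null=1000, seed=0)
print(f"NODF_total={res.NODF_total:.2f}  NODF(Ce)={res.null_mean:.2f}  p={res.p_value:.3f}")

st_plants, st_visitors = species_strength(web)
print(f"top plant strength: {st_plants.idxmax()} ST={st_plants.max():.2f}")
```

prints

```
size=60 (R=20 plants, C=40 visitors), links=542
WBAS=0.333  ISA=0.411  SA=0.021  H'_int=5.865
NODF_total=81.00  NODF(Ce)=71.37  p=0.001
top plant strength: P001 ST=3.77
```

The web has twice as many visitors as plants (`WBAS = 0.333`), visitors
depend on plants far more than the reverse (`ISA > 0`), and the observed
NODF sits well above the Ce null mean with `p = 0.001` at 1,000 draws —
abundance-product sampling makes nestedness the expected outcome.

## Analysis walk-through

Numbered drivers under `analysis/` run the full study design on a
simulated community and write their tables under `results/`:

```sh
python analysis/01_simulate_community.py   # six habitat censuses, planted structure
python analysis/02_assemblage_diversity.py # richness, H', Jaccard, UPGMA + bootstrap
python analysis/03_network_structure.py    # per-habitat + pooled metrics, NODF vs Ce
python analysis/04_species_roles.py        # DEG/ST/IPP/d'/Gc, core species
```

Step 02 merges the two small forest transects into one habitat before any
metric is computed (tiny webs give unstable network statistics) and
recovers the planted open-habitat trio as a 100%-supported clade; step 03
finds every abundance-driven web significantly nested.

The same pipeline is available as a CLI for arbitrary inputs:

```sh
flowerweb simulate --out syn --habitats 3 --seed 1
flowerweb analyze --records syn/records.tsv --merge FOR=FOR-Y+FOR-O \
    --n-null 1000 --bootstrap 9999 --seed 1 --out report
flowerweb nestedness report_input/PDV.tsv --n-null 1000 --seed 1
```

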