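# gaucherflux

Constraint-based modelling of Gaucher-disease (GD) macrophage metabolism.

Gaucher disease is a lysosomal storage disorder: biallelic *GBA1* mutations
cripple glucocerebrosidase, glucosylceramide accumulates, and macrophages —
the cells that clear glycosphingolipid-rich membranes — turn into
lipid-laden Gaucher cells with metabolic disturbances far beyond the
lysosome.  `gaucherflux` is a pipeline for studying that systemic
reprogramming with genome-scale modelling techniques at desk scale:

- **model core** — stoichiometric models with flux bounds, gene–protein–
  reaction (GPR) rules and compartments; JSON and SBML L3+FBC v2 I/O;
  stoichiometric- and flux-consistency checks;
- **flux prediction** — FBA, entropy-regularised FBA (unique
  forward/reverse flux estimates via a dual damped-Newton solver), MOMA,
  and gene knockouts;
- **extraction** — context-specific subnetwork extraction from a generic
  model given expression evidence (FPKM > 10 activity threshold) and
  curated core reactions, with draft-ensemble generation over a parameter
  grid;
- **validation** — predicted vs measured exchange rates (sign accuracy,
  Spearman rank correlation, weighted Euclidean distance) and ensemble
  model selection;
- **disease construction** — differential-expression calling (Welch test)
  and qualitative bound scaling: GBA1 upper bounds to 10%, down-regulated
  to 50%, up-regulated lower bounds to 150%, with t-SNE flux-space
  filtering of paired instances;
- **ensemble analytics** — differential flux (activity log-ratios +
  Mann–Whitney U), subsystem enrichment, GD-specific correlation modules,
  ATP-contribution decomposition (glycolysis / citric-acid-cycle
  substrate-level phosphorylation / oxidative phosphorylation), robustness
  sweeps;
- **reporter metabolites** — transcriptional z-scores aggregated onto
  adjacent metabolites with random-gene-set background correction;
- **modifier genes** — robust metabolic transformation scoring of every
  single-gene knockout (best-case LP / worst-case MOMA), ranking
  perturbations that push a healthy flux state toward the disease state;
- **synthetic data** — a 96-reaction toy macrophage network (glycolysis,
  TCA, oxidative phosphorylation, sphingolipid/ganglioside and cholesterol
  branches, fatty-acid oxidation, `ATPM` / `biomass_maintenance` /
  `ATPS4mi` / `EX_gangliosides[l]` included by name), plus expression and
  exometabolome simulators, so the whole pipeline runs without downloads.

The scientific background, model equations, design decisions and
limitations are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from gaucherflux.synthetic import (make_toy_network, ATP_PATHWAY_TAGS,
                                   default_differential_expression)
from gaucherflux.ensemble import SimulationSetup, atp_contribution_sweep
from gaucherflux.disease import build_disease_model, ScalingScheme
from gaucherflux.optimize import entropic_fba

model, manifest = make_toy_network()
setup = SimulationSetup()              # ATPM >= 44.8, biomass >= 3.45 umol/gDW/hr
de = default_differential_expression(manifest)
gd = build_disease_model(model, de, ScalingScheme(), setup=setup,
                         ganglioside_uptake=1.0)

ctrl = entropic_fba(setup.apply(model, ganglioside_uptake=1.0))
sick = entropic_fba(gd)
print(f"glucocerebrosidase flux: control {ctrl.flux('GBA'):.3f} "
      f"-> GD {sick.flux('GBA'):.3f} umol/gDW/hr")

c = atp_contribution_sweep(model, setup, [44.8], ATP_PATHWAY_TAGS)[0]
g = atp_contribution_sweep(gd, setup, [44.8], ATP_PATHWAY_TAGS)[0]
print(f"ATP from oxphos:     control {c.oxphos:.3f} -> GD {g.oxphos:.3f}")
print(f"ATP from glycolysis: control {c.glycolysis:.3f} -> GD {g.glycolysis:.3f}")
```

prints

```
glucocerebrosidase flux: control 1.136 -> GD 0.200 umol/gDW/hr
ATP from oxphos:     control 0.642 -> GD 0.464
ATP from glycolysis: control 0.310 -> GD 0.503
```

— the disease signature: the GBA1 knockdown caps glucosylceramide
degradation at 10% of capacity, and under the same 44.8 umol/gDW/hr energy
demand the GD model shifts ATP production away from oxidative
phosphorylation onto glycolysis (a Warburg-like pivot driven by the
down-scaled respiratory complexes and ADP/ATP carrier).

Modifier-gene ranking runs the same way in both directions:

```python
from gaucherflux.ensemble import simulate_condition_ensemble
from gaucherflux.mta import rank_modifier_genes

ce = simulate_condition_ensemble(model, setup, 10, seed=101, condition="control")
ge = simulate_condition_ensemble(gd, setup, 10, seed=202, condition="GD")
fwd = rank_modifier_genes(setup.apply(model, ganglioside_uptake=1.0),
                          ce, ge, direction="healthy->disease")
print(fwd.head(3)[["gene", "rTS"]])
```

ranks the acid-ceramidase gene `ASAH1` at the top (its knockout stalls
lysosomal clearance just like the primary deficiency), while the reverse
direction — trying to push the disease state back to health by a knockout —
finds no positive score, because knockouts cannot restore capacity that
the disease constraints removed.

A thin CLI generates the synthetic inputs and checks model files:

```bash
gaucherflux simulate --out synthetic_data --seed 0
gaucherflux model-check synthetic_data/toy_macrophage.xml
```

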