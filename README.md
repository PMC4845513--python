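# phytoflux

Constraint-based analysis of how **biomass composition** and **model
structure** shape flux-balance predictions in stoichiometric metabolic
models, built for the kind of comparison done across plant genome-scale
reconstructions: the same growth simulation run over a matrix of models ×
biomass objective functions, with sensitivity and variability analyses on
top.

## Who this is for

Systems biologists working with stoichiometric (SBML) metabolic models who
want to know how much of a flux prediction is owed to the network itself
and how much to the biomass recipe fed into it — and who need the
surrounding machinery (weight normalization of compositions, producibility
screening, maintenance handling, central-flux tables) in one place.

## The model

Flux balance analysis maximizes the flux *v*<sub>growth</sub> through a
biomass reaction

&nbsp;&nbsp;&nbsp;&nbsp;∑<sub>i</sub> c<sub>i</sub> X<sub>i</sub> + GAM → 1 Biomass

subject to steady-state mass balance **S v = 0** and flux bounds
**v**<sub>min</sub> ≤ **v** ≤ **v**<sub>max</sub>, where c<sub>i</sub> is the
mmol of precursor X<sub>i</sub> per gram dry weight of biomass and GAM/NGAM
are the growth-associated and non-growth-associated ATP maintenance costs.
Because the optimum of such an LP is usually degenerate, all simulations
run in **geometric mode**: flux variability analysis (FVA) ranges over the
optimal face are iteratively contracted around their midpoints, yielding
the unique central flux distribution that shares the plain-FBA optimum.

On top of that engine the package provides:

* `model_io` — SBML L2/L3 reading and writing (fbc or kinetic-law bounds),
  declarative model patches (bound edits, direction flips, added exchange
  reactions), structural validation;
* `biomass` — composition tables, weight normalization (1 flux unit ≡ 1 g),
  producibility screening and cross-model component intersection, biomass
  reaction assembly with a GAM term, class/weight/carbon summaries;
* `lp_core` — FBA, FVA and geometric FBA (scipy HiGHS backend), plus an
  estimator-style `FluxBalanceModel(...).fit()` → `FBAResult` surface;
* `scenarios` — the model × composition matrix, central-flux tables,
  per-reaction SD dispersion summaries, FVA overlap classification;
* `sensitivity` — ±30 % single-component perturbations, four-way
  GAM/NGAM maintenance scans, Pearson correlation of growth responses with
  carbon- or weight-based coefficient fractions;
* `synthetic_models` — toy networks with closed-form optima (parallel
  degenerate pathways, futile cycles, multi-precursor branched networks)
  so every stage is testable without external model downloads.

## Worked example

```python
from phytoflux import FluxBalanceModel
from phytoflux.synthetic_models import ToySpec, make_toy

# substrate uptake <= 10, catabolism yields 3 energy units per substrate,
# maintenance drain fixed at 2, biomass = 0.5 substrate + 1 energy
toy = make_toy(ToySpec(n_pathways=2))
res = FluxBalanceModel(toy.model).fit(method="geometric")
print(res.summary())
```

```
                  Flux balance analysis
==========================================================
method:            geometric_fba
status:            optimal
objective reaction: Biomass
objective value:   11.2
reactions:         6
----------------------------------------------------------
largest |flux|                                       value
Biomass                                               11.2
Biomass_sink                                          11.2
EX_G                                                    10
C2                                                     2.2
C                                                      2.2
NGAM                                                     2
==========================================================
```

The growth optimum 11.2 is the closed form (3·10 − 2)/(3·0.5 + 1): all the
substrate enters, the drain takes its 2 energy units, and the rest goes to
biomass.  The two interchangeable catabolic routes `C` and `C2` individually
range over [0, 4.4] at this optimum; geometric mode settles both at the
central 2.2/2.2 split instead of an arbitrary vertex.

The same objects drive SBML-based workflows from the shell:

```bash
phytoflux fixtures --out fixtures/
phytoflux run-matrix --models fixtures/toy1.xml --models fixtures/toy2.xml \
    --bofs fixtures/toy1_bof.tsv --constraints constraints.yaml --out out/
phytoflux sensitivity --model fixtures/toy1.xml --bof fixtures/toy1_bof.tsv \
    --constraints constraints.yaml --mode maintenance --atp E --out scan.json
```

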