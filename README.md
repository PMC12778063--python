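# spiculate

Ancestral-state estimation for sponge skeletal characters on
time-calibrated phylogenies, using structured Markov models with embedded
dependencies — plus the fossil-calibration prior densities used in
molecular-clock dating designs and a synthetic-data generator that makes
the whole stack testable without any downloads.

## The problem

Whether the earliest sponges carried mineralized skeletons is a question
about ancestral states: given living species (and a few phylogenetically
placed fossils) scored for skeletal characters, what did deep ancestors
such as the poriferan crown node most likely look like?  The characters
are not independent of one another.  Four discrete characters describe a
sponge skeleton:

1. **spicule presence** — absent (0) / present (1)
2. **calcareous biomineralization** — absent (0) / present (1)
3. **siliceous biomineralization** — absent (0) / present (1)
4. **biosilicification pathway** — hexactinellid (0) / demosponge (1) /
   homoscleromorph (2)

Characters 1–3 evolve independently (fossils such as biminerallic taxa
require calcite and silica to be free to co-occur), but character 4 only
*exists* while character 3 is "present": a sponge that deposits no silica
has no silicification pathway.  Such a hierarchy is modeled with an
**embedded dependency**: the joint silica+pathway character lives on the
four states {absent, present·hex, present·demo, present·homo}, with gains
jumping from "absent" into a specific pathway, losses returning to
"absent", and (optional, default off) switching between pathways.

Independent characters are then **amalgamated** into a single
continuous-time Markov chain on the product state space via the Kronecker
sum of their generators,

  Q = Q₁ ⊕ Q₂ ⊕ … = Σᵢ I ⊗ … ⊗ Qᵢ ⊗ … ⊗ I,

which by construction gives rate 0 to simultaneous changes in two
characters.  Four canonical model layouts are built in:

| model | components | states |
|-------|------------|--------|
| A | calcareous × siliceous | 4 |
| B | calcareous × siliceous × spicules | 8 |
| C | calcareous × (siliceous+pathway embedded) | 8 |
| D | calcareous × (siliceous+pathway) × spicules | 16 |

Likelihoods are computed with Felsenstein's pruning algorithm on rooted,
possibly multifurcating timetrees whose tips need not be contemporaneous:
fossil tips sit at positive ages, and partial codings (e.g. a silicified
fossil whose pathway is unknown) enter as indicator sets over the
amalgamated states.  Rates (events/Myr) are fitted by multi-start bounded
maximum likelihood; ancestral states are exact marginal probabilities from
an inside–outside pass, reported both per amalgamated state and collapsed
to display categories (no biomineralization / siliceous / calcareous /
biminerallic, plus spicule presence for models B and D).

The package also implements the node-age calibration densities of the
associated dating design — soft-bounded uniforms and truncated-Cauchy
lower bounds with offset *p* and scale *c* (hard bounds expressed as tail
mass 10⁻³⁰⁰) — with density/CDF/quantile/sampling and quadrature checks.

## Worked example

Simulate a model-D dataset with fossil tips, censor the fossils'
biosilicification pathway the way real fossils are coded, refit and
reconstruct the root:

```python
import spiculate as sp
from spiculate.simulate import (SimulationConfig, simulate_tree,
                                simulate_traits, mask_like_fossils)

rates = {k: 0.002 for k in (
    "calcareous.gain", "calcareous.loss", "siliceous.gain",
    "siliceous.loss", "spicules.gain", "spicules.loss")}
cfg = SimulationConfig(seed=5, birth=0.03, death=0.015, n_extant=64,
                       fossil_rate=0.01, model_id="D", rates=rates,
                       root_state=("0", ("0", None), "0"))  # bare root
tree = simulate_tree(cfg)                  # 76 tips, 12 of them fossils
model = sp.build_model("D", rates)
ds = simulate_traits(tree, model, root_state=cfg.root_state, seed=5)
data = mask_like_fossils(ds, 1.0, 0.0, seed=5)   # fossils: pathway -> "?"

fit = sp.fit_ml(tree, "D", data, seed=5, n_restarts=5)
recon = sp.marginal_ancestral(tree, fit.build(), fit.params, data)
agg = sp.aggregate_display(recon)
print(fit.loglik)
print(agg[agg["node"] == tree.root]
      [["none", "siliceous", "calcareous", "biminerallic", "spicules_present"]])
```

Output (values your machine reproduces exactly — everything is seeded):

```
-79.6261
none = 0.9998, siliceous = 0.0002, calcareous = 0.0000,
biminerallic = 0.0000, spicules_present = 0.0000
```

The fitted rates land close to the generating 0.002/Myr (e.g. siliceous
gain 0.00208, loss 0.00191) and the root is confidently reconstructed as
non-biomineralized and aspiculate — which is the simulated truth.

The same workflow is available from the shell:

```bash
spiculate simulate --config sim.yaml --out-dir runs/sim
spiculate fit --tree runs/sim/tree.nwk --matrix runs/sim/matrix.csv \
          --model D --seed 5 --out fit.json
spiculate ancestral --fit fit.json --out ancestral.csv
spiculate calibration-check --out calibrations.json
spiculate pipeline --config grid.yaml --out-dir runs/grid   # model x tree grid
```

`pipeline` fits every (tree, model, root-prior) combination and writes a
cross-run summary holding, per clade, the *minimum* of each category
probability across runs — the "P ≥ x across all analyses" style of
reporting.

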