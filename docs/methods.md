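# Methods

This note documents the models implemented in `spiculate`, the choices
made where the design was genuinely open, and what the synthetic studies
do and do not demonstrate.

## Characters and state spaces

Four discrete characters describe a sponge skeleton: spicule presence
(binary), calcareous biomineralization (binary), siliceous
biomineralization (binary) and the biosilicification pathway
(three states: hexactinellid, demosponge, homoscleromorph).  The pathway
character is *hierarchically dependent* on siliceous biomineralization: it
has no value while silica deposition is absent.  We embed it in its
controller, producing a four-state component
{absent, present·hex, present·demo, present·homo} whose generator carries

- gain rates, absent → present·p (one shared rate by default, so the
  pathway identity is chosen at the moment of gain with equal probability;
  per-pathway gains are configurable),
- loss rates, present·p → absent (shared by default, per-pathway
  configurable),
- switch rates among the present states (default **0**: the three
  pathways are treated as independent origins with no documented
  transformations between them; the knob is exposed because allowing
  switching changes ancestral estimates).

Inapplicability is handled at the observation level, not with an extra
"inapplicable" symbol: a taxon without silica simply has no pathway
statement, and its allowed-state set collapses onto the absent state.
Positively asserting a pathway while asserting silica absent is a coding
contradiction and is rejected with the taxon named.

## Amalgamation

Independent characters are combined with the Kronecker sum
Q = Σᵢ I ⊗ … ⊗ Qᵢ ⊗ … ⊗ I on the lexicographically ordered product state
space.  This is the structured-Markov-model construction for independent
characters: off-diagonal rates are nonzero only for single-character
changes, and the joint pruning likelihood of per-character data factorizes
exactly into the product of per-character likelihoods — an identity the
test suite checks to 1e-8 and uses as one of two independent oracles.

Model layouts: A = calcareous ⊗ siliceous (4 states); B = A ⊗ spicules
(8); C = calcareous ⊗ embedded silica+pathway (8); D = C ⊗ spicules (16).

Rate parameterization defaults to gain/loss per binary character (the
minimal model that distinguishes acquisition from loss of skeletal
traits); equal-rates and all-rates-different schemes are available through
the same dotted-key parameter interface.

## Likelihood and ancestral states

The likelihood is Felsenstein pruning over rooted, possibly
multifurcating, possibly non-ultrametric trees.  Tip partial likelihoods
are indicators of the tip's allowed amalgamated-state set, so missing
data ("?"), partial codings ("{01}") and fossil-style censoring (silica
present, pathway unknown → three allowed states) all enter through one
mechanism.  Per-node rescaling of partials (log-scalers accumulated
postorder) guards against underflow on deep trees.  Polytomies are hard:
the pruning product simply runs over all children.  Zero-length branches
get identity transition matrices.

Transition matrices P(t) = exp(Qt) are computed by one eigendecomposition
of Q per likelihood evaluation, applied vectorized to all branch lengths;
`scipy.linalg.expm` (scaling-and-squaring with Padé approximation) is the
reference path and the automatic fallback when the eigenbasis fails to
reproduce stochastic rows to 1e-9.  Both paths agree to 1e-10 on random
generators in the tests.

Root priors: **flat** over amalgamated states (default — the least
informative choice), **stationary** (left null vector of Q; falls back to
flat when the chain is reducible or frozen and no unique stationary law
exists) and **FitzJohn conditional** (root weights proportional to the
root partials).  Note a structural consequence of the flat default on
models C/D: because the embedded component has three "present" states,
categories do not receive equal prior mass (e.g. 6 of 16 model-D states
are siliceous but only 2 are unmineralized), which pulls weakly-informed
roots toward silicified categories.  This is a property of flat priors on
amalgamated spaces, not a bug; use the root-prior knob to explore it.

Maximum-likelihood fitting runs bounded L-BFGS-B on log-transformed rates
(bounds 1e-8 to 1e3 events/Myr, convergence tolerance 1e-8), with
multi-start from seeded log-uniform draws over [1e-4, 1] (default 10
restarts; ties broken by lowest restart index so a fixed seed reproduces
the result bit for bit).  All restart endpoints are reported.

Marginal ancestral states are exact inside–outside marginals — the
outside pass propagates the root prior down the tree, combining each
child's transition matrix with the inside messages of its siblings — and
equal re-rooting at every node.  They are verified against brute-force
enumeration over all joint interior assignments (a deliberately
independent oracle, quadratic in nothing but patience) to 1e-9.

Display aggregation collapses state vectors to the four
biomineralization categories (none / siliceous / calcareous /
biminerallic) and, for models B/D, a marginal spicule-presence
probability.  Across-run summaries report the per-clade *minimum* of a
category probability over a declared grid of (tree, model, root prior)
runs, matching the "P ≥ x in all analyses" convention; per-run tables are
always retained because the minimum is only one possible summary.

## Calibration densities

Two families of node-age priors, normalized on age in Myr:

- **uniform_soft(t_L, t_U, p_L, p_U)** — mass 1 − p_L − p_U uniform on
  [t_L, t_U]; exponential tails hold mass p_L below and p_U above,
  matched for density continuity at each bound.
- **cauchy_lower(t_L, p, c, p_L)** — mass 1 − p_L as a Cauchy with
  location t_L(1+p) and scale c·t_L truncated to t > t_L, following the
  offset/scale convention of standard dating software; an exponential
  tail of mass p_L sits below the minimum.  The heavy right tail encodes
  how little a sparse fossil record constrains true clade age from above.

Hard bounds are written as tail mass 1e-300, never exactly 0, so every
density stays strictly positive (log-safe).  Only the tail *masses* and
bound placements are contracts; the tail *shape* is an implementation
choice (different dating programs use different tail dialects), which is
why the quadrature checks target integrals and masses, not tail
pointwise values.  The packaged 12-node YAML
(`data/calibrations_sdn_synthetic.yaml`) carries the three fully
documented calibrations (root uniform 574–609 Ma with soft 2.5% upper
tail; Eumetazoa 561–573 Ma with soft 2.5% lower tail; a Cauchy minimum at
515 Ma with p = 0.5, c = 0.5 on the spiculate demosponges) and nine
representative lower-bound entries whose minimum ages are placeholders —
the file is labelled synthetic and must be replaced with real fossil
minima for any actual dating design.  Sampling is inverse-CDF and fully
seeded.

## Synthetic data

`simulate_tree` grows a forward birth–death process conditioned on a
target extant tip count (stopped at first passage plus a censored final
interval), then applies constant-rate Poisson fossilization along all
branches of the complete tree.  An extinct, otherwise-unsampled lineage
with a fossilization event is truncated at its most recent event and kept
as a fossil tip; events on lineages with sampled descendants are
discarded (no sampled ancestors — the simplest process that yields
non-contemporaneous tips).  `simulate_traits` runs the amalgamated chain
branch by branch with exact exponential waiting times; the complete event
log replays deterministically to the recorded node states, which makes
the simulator its own oracle.  `mask_like_fossils` widens fossil pathway
observations to the full set and optionally blanks whole characters;
masking only ever *widens* sets, so the likelihood of the true parameters
cannot decrease (checked as a property).

Default study conditions: ~64–128 extant tips; birth 0.03/Myr, death
0.006/Myr, fossilization 0.001/Myr (a minority of fossil tips); character
rates 0.001–0.002/Myr, so each character changes on the order of 1–10
times per tree — sparse skeletal evolution, which is the regime the
empirical analyses inhabit.  The parameter-recovery study for model A
uses 128-tip trees with birth 0.3/Myr and death 0.05/Myr, giving ≈500 Myr
of total branch length, and gain = loss = 0.02/Myr — again about ten
changes per character.  We deliberately parameterize this study by
*total* tree length rather than root-to-tip depth: with 0.02/Myr rates on
trees 500 Myr deep, each lineage would see ~10 changes per character and
the root state would be information-theoretically unrecoverable (the
branching rate implied by 128 tips at that depth sits far below the
Kesten–Stigum reconstruction threshold λ > 4q), while also saturating the
tree with ~250 changes — neither sparse nor recoverable.  Under the
chosen conditions 50 seeded replicates give a pooled median
|log₁₀(rate ratio)| around 0.2 and modal root-category recovery of
roughly 70–80%.

What these studies show: the estimator recovers rates and deep states
from data generated *by the model it fits*, at realistic sizes and
sparsity, including under fossil-style censoring.  What they do not
show: robustness to model misspecification (heterotachy, correlated
gains, clade-specific rates), to tree or dating error, or to biased
fossil sampling — none of which the generator emulates.  Passing them is
a correctness statement about the machinery, not a validation of any
empirical conclusion.

## Numerical details worth knowing

- Age convention: Myr before present, larger = older; the oldest
  root-to-tip path pins age 0; ages within 1e-9 Myr of 0 are snapped to 0.
- Tree/matrix taxon matching is case-insensitive and
  whitespace/underscore-equivalent, reports *all* mismatches at once, and
  accepts a user synonym table for the rest.
- The enumeration oracle refuses instances beyond 8 tips / 16 states.
- Impossible data return −inf log-likelihood (not an exception) from
  `pruning_loglik`; `marginal_ancestral` raises, since marginals are then
  undefined.
- `fit_ml` objective replaces −inf with a large finite penalty so L-BFGS-B
  line searches survive impossible corners of rate space.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; reruns are bit-identical.

## Known limitations

- One level of dependency nesting only (pathway under silica); no hidden
  rate categories; no correlated-evolution tests between the two mineral
  characters.
- The flat root prior's category bias on embedded state spaces (above).
- Birth–death conditioning is by first passage to the target extant
  count, which is simple and seedable but does not sample the exact
  conditioned birth–death law; for fixture generation this distinction is
  immaterial, for inference about diversification it would not be.
- Calibration densities are a library (density/CDF/sampling contracts);
  no MCMC dating and no treatment of truncation interactions between
  nested calibrations.
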