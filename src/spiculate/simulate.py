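"""Synthetic timetrees and character histories with known truth.

The generator emulates the statistical structure the ancestral-state
analyses assume: a time-calibrated birth--death tree whose tips are mostly
extant but include a minority of fossil tips at positive ages, and four
skeletal characters evolving sparsely (a handful of gains and losses per
tree) under the amalgamated chain, with fossil-style partial observations
(biosilicification pathway coded unknown, whole characters coded missing).

Fossil tips arise from a constant-rate Poisson sampling process along all
lineages of the complete (extinct-inclusive) tree: an unsampled extinct
lineage bearing a fossilization event is truncated at its most recent
event and retained as a fossil tip; events on lineages with sampled
descendants are discarded (sampled-ancestor configurations are out of
scope).  Character histories are simulated exactly, event by event, with
exponential waiting times on the amalgamated chain, so the event log is an
exact record that replays to the recorded node states.

All randomness flows from the single config seed; equal configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .phylo_io import CharacterMatrix, TimeTree
from .trait_model import AmalgamatedModel, build_model
from . import inference

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_traits",
    "mask_like_fossils",
    "recovery_experiment",
    "state_category",
]

# Default regime: ~100-tip trees a few hundred Myr deep whose characters
# change on the order of 1-10 times each (sparse skeletal evolution).
DEFAULT_BIRTH = 0.03  # /lineage/Myr
DEFAULT_DEATH = 0.006
DEFAULT_FOSSIL_RATE = 0.001
DEFAULT_RATES = {
    "calcareous.gain": 0.001,
    "calcareous.loss": 0.001,
    "siliceous.gain": 0.001,
    "siliceous.loss": 0.001,
    "spicules.gain": 0.001,
    "spicules.loss": 0.001,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulation condition.  ``seed`` is mandatory."""

    seed: int
    birth: float = DEFAULT_BIRTH
    death: float = DEFAULT_DEATH
    n_extant: int = 64
    fossil_rate: float = DEFAULT_FOSSIL_RATE
    model_id: str = "D"
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    root_state: Optional[Union[int, Tuple[object, ...]]] = None  # None = flat draw
    max_tries: int = 1000

    def __post_init__(self) -> None:
        if self.birth < 0 or self.death < 0 or self.fossil_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_extant < 2:
            raise ValueError("need >= 2 extant tips")


@dataclass
class SimulatedDataset:
    """A simulated tree plus full character truth."""

    tree: TimeTree
    matrix: CharacterMatrix
    node_states: np.ndarray  # product-state index per node
    events: pd.DataFrame  # columns: node, time_frac, age_Myr, from_state, to_state
    model: AmalgamatedModel
    config: SimulationConfig


# ---------------------------------------------------------------------------
# birth-death trees with fossil tips
# ---------------------------------------------------------------------------


class _BDNode:
    __slots__ = ("time", "children", "parent", "extant", "fossil_events")

    def __init__(self, time: float, parent: Optional["_BDNode"]) -> None:
        self.time = time
        self.parent = parent
        self.children: List["_BDNode"] = []
        self.extant = False
        self.fossil_events: List[float] = []


def _grow_bd(rng: np.random.Generator, cfg: SimulationConfig):
    """One forward birth-death realization stopped when the extant count
    first reaches the target (plus a censored final interval).

    A node's ``time`` is when its branch *ends* (split, death or present);
    the branch starts at the parent's time.  Returns the root of the
    complete tree and the present time, or None on extinction.
    """
    lam, mu = cfg.birth, cfg.death
    if lam + mu <= 0:
        return None
    root = _BDNode(np.nan, None)
    alive = [root]
    t = 0.0
    while len(alive) < cfg.n_extant:
        t += rng.exponential(1.0 / (len(alive) * (lam + mu)))
        node = alive.pop(int(rng.integers(len(alive))))
        node.time = t
        if rng.random() < lam / (lam + mu):  # split
            node.children = [_BDNode(np.nan, node), _BDNode(np.nan, node)]
            alive.extend(node.children)
        if not alive:
            return None
    # censor: present sits strictly before the next (undrawn) event
    t_present = t + rng.exponential(1.0 / (len(alive) * (lam + mu)))
    for node in alive:
        node.time = t_present
        node.extant = True
    return root, t_present


def _branch_interval(node: _BDNode) -> Tuple[float, float]:
    start = node.parent.time if node.parent is not None else 0.0
    return start, node.time


def simulate_tree(config: SimulationConfig) -> TimeTree:
    """Birth-death timetree conditioned on the target extant tip count,
    with fossil tips from Poisson sampling along all lineages.

    Retries on whole-clade extinction up to ``config.max_tries`` and then
    raises ``RuntimeError``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    for _ in range(config.max_tries):
        grown = _grow_bd(rng, config)
        if grown is None:
            continue
        root, t_present = grown

        # Poisson fossilization events on every branch of the complete tree
        if config.fossil_rate > 0:
            stack = [n for n in root.children]
            while stack:
                node = stack.pop()
                start, end = _branch_interval(node)
                n_ev = rng.poisson(config.fossil_rate * (end - start))
                if n_ev:
                    node.fossil_events = sorted(
                        rng.uniform(start, end, size=n_ev).tolist()
                    )
                stack.extend(node.children)

        kept = _reconstruct(root)
        if kept is None:
            continue
        tree = _to_timetree(kept, t_present)
        if len(tree.tips) >= config.n_extant:
            return tree
    raise RuntimeError(
        f"no surviving clade with {config.n_extant} extant tips in "
        f"{config.max_tries} attempts"
    )


class _OutNode:
    __slots__ = ("time", "children", "extant")

    def __init__(self, time: float, extant: bool = False) -> None:
        self.time = time
        self.children: List["_OutNode"] = []
        self.extant = extant


def _reconstruct(node: _BDNode) -> Optional[_OutNode]:
    """Prune unsampled lineages, truncating at the most recent fossil
    event; suppress unary pass-through nodes."""
    if not node.children:  # terminal lineage
        if node.extant:
            return _OutNode(node.time, extant=True)
        if node.fossil_events:
            return _OutNode(node.fossil_events[-1])
        return None
    kept = [k for k in (_reconstruct(c) for c in node.children) if k is not None]
    if not kept:
        # whole subtree unsampled: a fossil event on this branch truncates it
        if node.fossil_events:
            return _OutNode(node.fossil_events[-1])
        return None
    if len(kept) == 1:
        return kept[0]  # unary: splice out
    out = _OutNode(node.time)
    out.children = kept
    return out


def _to_timetree(root: _OutNode, t_present: float) -> TimeTree:
    order: List[_OutNode] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(v.children))
    index = {id(v): i for i, v in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    labels: List[Optional[str]] = [None] * n
    tip_no = ext_no = 0
    for v in order:
        for c in v.children:
            parent[index[id(c)]] = index[id(v)]
            lengths[index[id(c)]] = c.time - v.time
    for v in order:
        if not v.children:
            if v.extant:
                tip_no += 1
                labels[index[id(v)]] = f"t{tip_no}"
            else:
                ext_no += 1
                labels[index[id(v)]] = f"fossil{ext_no}"
    return TimeTree(parent=parent, branch_lengths=lengths, labels=labels)


# ---------------------------------------------------------------------------
# character histories
# ---------------------------------------------------------------------------


def _state_to_observations(
    model: AmalgamatedModel, idx: int
) -> Dict[str, frozenset]:
    """Decompose a product state into per-character singleton observations;
    an inapplicable dependent character becomes its full (unknown) set."""
    state = model.product_states[idx]
    obs: Dict[str, frozenset] = {}
    for comp, s in zip(model.components, state):
        if comp.enabling is None:
            obs[comp.name] = frozenset([s])
        else:
            ctrl, dep = comp.characters
            obs[ctrl] = frozenset([s[0]])
            dep_space = frozenset(x[1] for x in comp.states if x[1] is not None)
            obs[dep] = frozenset([s[1]]) if s[1] is not None else dep_space
    return obs


def _character_spaces(model: AmalgamatedModel) -> Dict[str, Tuple[str, ...]]:
    spaces: Dict[str, Tuple[str, ...]] = {}
    for comp in model.components:
        if comp.enabling is None:
            spaces[comp.name] = tuple(comp.states)  # type: ignore[arg-type]
        else:
            ctrl, dep = comp.characters
            spaces[ctrl] = (comp.enabling[0], comp.enabling[1])
            spaces[dep] = tuple(s[1] for s in comp.states if s[1] is not None)
    return spaces


def simulate_traits(
    tree: TimeTree,
    model: AmalgamatedModel,
    root_state: Optional[Union[int, Tuple[object, ...]]] = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Exact event-driven CTMC simulation of the amalgamated chain on every
    branch; records all node states and every individual change."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    k = model.n_states
    if root_state is None:
        root_idx = int(rng.integers(k))
    elif isinstance(root_state, int):
        root_idx = root_state
    else:
        root_idx = model.state_index[root_state]
    Q = model.Q
    node_states = np.full(tree.n_nodes, -1, dtype=int)
    node_states[tree.root] = root_idx
    ev_rows = []
    for v in tree.preorder():
        for c in tree.children[v]:
            s = node_states[v]
            L = float(tree.branch_lengths[c])
            tau = 0.0
            while True:
                out = -Q[s, s]
                if out <= 0:
                    break
                tau += rng.exponential(1.0 / out)
                if tau > L:
                    break
                probs = Q[s].clip(min=0.0)
                probs[s] = 0.0
                nxt = int(rng.choice(k, p=probs / probs.sum()))
                ev_rows.append(
                    {
                        "node": c,
                        "time_frac": tau / L if L > 0 else 0.0,
                        "age_Myr": tree.node_ages[v] - tau,
                        "from_state": s,
                        "to_state": nxt,
                    }
                )
                s = nxt
            node_states[c] = s

    spaces = _character_spaces(model)
    characters = list(model.characters)
    taxa = [tree.labels[i] for i in tree.tips]
    observations = {}
    for i in tree.tips:
        obs = _state_to_observations(model, int(node_states[i]))
        for ch in characters:
            observations[(tree.labels[i], ch)] = obs[ch]
    matrix = CharacterMatrix(
        taxa=taxa,  # type: ignore[arg-type]
        characters=characters,
        state_spaces={c: spaces[c] for c in characters},
        observations=observations,
    )
    events = pd.DataFrame(
        ev_rows, columns=["node", "time_frac", "age_Myr", "from_state", "to_state"]
    )
    cfg = SimulationConfig(seed=seed, model_id=model.model_id)
    return SimulatedDataset(
        tree=tree,
        matrix=matrix,
        node_states=node_states,
        events=events,
        model=model,
        config=cfg,
    )


def mask_like_fossils(
    dataset: SimulatedDataset,
    fraction_fossil_pathway_unknown: float = 1.0,
    fraction_missing: float = 0.0,
    seed: int = 0,
) -> CharacterMatrix:
    """Fossil-style censoring of a simulated matrix.

    For each fossil tip (age > 0): with the given probability the
    biosilicification pathway observation is widened to the full pathway
    set (the paper-style "silicified, pathway unknown" coding); whole
    characters are additionally set to missing at rate ``fraction_missing``.
    Masking only ever widens observation sets, so the true state always
    remains allowed.
    """
    for f in (fraction_fossil_pathway_unknown, fraction_missing):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    m = dataset.matrix
    obs = dict(m.observations)
    ages = dataset.tree.tip_ages()
    model = dataset.model
    dep_chars = [
        comp.characters[1] for comp in model.components if comp.enabling is not None
    ]
    for taxon in m.taxa:
        if ages[taxon] <= 0:
            continue
        for dep in dep_chars:
            if rng.random() < fraction_fossil_pathway_unknown:
                obs[(taxon, dep)] = frozenset(m.state_spaces[dep])
        for ch in m.characters:
            if rng.random() < fraction_missing:
                obs[(taxon, ch)] = frozenset(m.state_spaces[ch])
    return CharacterMatrix(
        taxa=list(m.taxa),
        characters=list(m.characters),
        state_spaces=dict(m.state_spaces),
        observations=obs,
    )


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------


def state_category(model: AmalgamatedModel, idx: int) -> str:
    """Biomineralization display category of one product state."""
    calc = model.character_present_mask("calcareous")[idx]
    sil = model.character_present_mask("siliceous")[idx]
    return {
        (False, False): "none",
        (False, True): "siliceous",
        (True, False): "calcareous",
        (True, True): "biminerallic",
    }[(bool(calc), bool(sil))]


def recovery_experiment(
    config_grid: Sequence[SimulationConfig],
    replicates: int,
    seed: int = 0,
    n_restarts: int = 3,
    root_prior: str = "flat",
    mask_fossils: bool = True,
) -> Dict[str, object]:
    """Simulate -> fit -> reconstruct over a grid of conditions.

    For every grid cell and replicate: draw a tree and a character history
    at the true rates, (optionally) censor fossils, fit the model by ML and
    reconstruct the root.  Returns per-replicate rows plus per-cell
    summaries: the distribution of ``|log10(rate_hat / rate_true)|`` over
    free rates and the frequency with which the modal root
    biomineralization category equals the simulated truth.  Per-replicate
    failures are recorded, not fatal.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    rows: List[Dict[str, object]] = []
    for ci, cfg in enumerate(config_grid):
        for r in range(replicates):
            rep_seed = int(
                np.random.SeedSequence([seed, ci, r]).generate_state(1)[0] % (2**31)
            )
            row: Dict[str, object] = {"cell": ci, "replicate": r, "model": cfg.model_id}
            try:
                sim_cfg = replace(cfg, seed=rep_seed)
                tree = simulate_tree(sim_cfg)
                model = build_model(cfg.model_id, cfg.rates)
                ds = simulate_traits(tree, model, root_state=cfg.root_state, seed=rep_seed)
                data = (
                    mask_like_fossils(ds, seed=rep_seed) if mask_fossils else ds.matrix
                )
                fit = inference.fit_ml(
                    tree,
                    cfg.model_id,
                    data,
                    root_prior=root_prior,
                    n_restarts=n_restarts,
                    seed=rep_seed,
                )
                recon = inference.marginal_ancestral(
                    tree, fit.build(), fit.params, data, root_prior=root_prior
                )
                agg = inference.aggregate_display(recon)
                root_row = agg.loc[agg["node"] == tree.root].iloc[0]
                cats = ["none", "siliceous", "calcareous", "biminerallic"]
                modal = max(cats, key=lambda c: float(root_row[c]))
                truth = state_category(model, int(ds.node_states[tree.root]))
                errs = [
                    abs(np.log10(fit.params[name] / cfg.rates[name]))
                    for name in fit.free_names
                    if cfg.rates.get(name, 0) > 0 and fit.params[name] > 0
                ]
                row.update(
                    {
                        "ok": True,
                        "loglik": fit.loglik,
                        "median_abs_log10_err": float(np.median(errs)) if errs else np.nan,
                        "rate_errors": errs,
                        "root_truth": truth,
                        "root_modal": modal,
                        "root_match": modal == truth,
                        "n_fossils": sum(a > 0 for a in tree.tip_ages().values()),
                    }
                )
            except Exception as exc:  # recorded, not fatal
                row.update({"ok": False, "error": f"{type(exc).__name__}: {exc}"})
            rows.append(row)

    table = pd.DataFrame(rows)
    summaries = {}
    for ci in sorted(table["cell"].unique()):
        sub = table[(table["cell"] == ci) & (table["ok"] == True)]  # noqa: E712
        all_errs = [e for lst in sub["rate_errors"] for e in lst]
        summaries[int(ci)] = {
            "n_ok": int(len(sub)),
            "n_fail": int((table["cell"] == ci).sum() - len(sub)),
            "median_abs_log10_rate_error": float(np.median(all_errs))
            if all_errs
            else float("nan"),
            "root_category_recovery": float(sub["root_match"].mean())
            if len(sub)
            else float("nan"),
        }
    return {"replicates": table, "summary": summaries}
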