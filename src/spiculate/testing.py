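"""Random small instances for oracles, property tests and validation runs.

Everything here is deterministic given the supplied generator, so the same
instance stream can be reproduced across the test suite and the
verification scripts.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .phylo_io import CharacterMatrix, TimeTree
from .trait_model import AmalgamatedModel, build_model

__all__ = [
    "CHARSET",
    "make_matrix",
    "random_tree",
    "random_rates",
    "random_observations",
    "random_instance",
]

CHARSET: Dict[str, Tuple[str, ...]] = {
    "spicules": ("0", "1"),
    "calcareous": ("0", "1"),
    "siliceous": ("0", "1"),
    "pathway": ("0", "1", "2"),
}


def make_matrix(cells: Dict[str, Dict[str, object]]) -> CharacterMatrix:
    """Build a CharacterMatrix from ``{taxon: {character: state or set}}``;
    ``"?"`` or a missing character means the full state set."""
    taxa = list(cells)
    characters = sorted({c for row in cells.values() for c in row})
    observations = {}
    for t, row in cells.items():
        for c in characters:
            v = row.get(c, "?")
            if v == "?":
                obs = frozenset(CHARSET[c])
            elif isinstance(v, (set, frozenset, tuple, list)):
                obs = frozenset(str(x) for x in v)
            else:
                obs = frozenset([str(v)])
            observations[(t, c)] = obs
    return CharacterMatrix(
        taxa=taxa,
        characters=characters,
        state_spaces={c: CHARSET[c] for c in characters},
        observations=observations,
    )


def random_tree(rng: np.random.Generator, n_tips: int,
                bl_range: Tuple[float, float] = (0.1, 100.0)) -> TimeTree:
    """Random rooted binary topology by repeatedly splitting a random tip,
    with branch lengths drawn uniformly from ``bl_range`` (Myr)."""
    parent = [-1, 0, 0]
    children: List[List[int]] = [[1, 2], [], []]
    for _ in range(n_tips - 2):
        tips = [i for i, ch in enumerate(children) if not ch and i != 0]
        t = int(rng.choice(tips))
        a, b = len(parent), len(parent) + 1
        parent += [t, t]
        children[t] = [a, b]
        children += [[], []]
    n = len(parent)
    lengths = np.zeros(n)
    lengths[1:] = rng.uniform(*bl_range, size=n - 1)
    labels: List[object] = [None] * n
    k = 0
    for i in range(n):
        if not children[i]:
            labels[i] = f"T{k}"
            k += 1
    return TimeTree(parent=np.array(parent), branch_lengths=lengths, labels=labels)


def random_rates(rng: np.random.Generator, model_id: str) -> Dict[str, float]:
    """Log-uniform rates in [1e-4, 1]/Myr for every parameter a model uses,
    with a pathway-switch rate included half the time for models C/D."""

    def r() -> float:
        return float(np.exp(rng.uniform(np.log(1e-4), np.log(1.0))))

    rates = {
        "calcareous.gain": r(),
        "calcareous.loss": r(),
        "siliceous.gain": r(),
        "siliceous.loss": r(),
    }
    if model_id in ("B", "D"):
        rates.update({"spicules.gain": r(), "spicules.loss": r()})
    if model_id in ("C", "D") and rng.random() < 0.5:
        rates["siliceous.switch"] = r()
    return rates


def random_observations(
    rng: np.random.Generator, model: AmalgamatedModel
) -> Dict[str, object]:
    """Random per-character observation sets that are never contradictory:
    a pathway is only positively asserted when silica is asserted present."""
    obs: Dict[str, object] = {}
    for char in model.characters:
        space = CHARSET[char]
        if char == "pathway":
            continue
        if rng.random() < 0.15:
            obs[char] = set(space)  # missing
        else:
            obs[char] = {str(rng.choice(space))}
    if "pathway" in model.characters:
        sil = obs.get("siliceous", set(CHARSET["siliceous"]))
        if sil == {"1"} and rng.random() < 0.7:
            obs["pathway"] = {str(rng.choice(CHARSET["pathway"]))}
        else:
            obs["pathway"] = set(CHARSET["pathway"])  # unknown / inapplicable
    return obs


def random_instance(rng: np.random.Generator, max_tips: int = 6):
    """A random (tree, model, matrix) triple over models A-D."""
    model_id = str(rng.choice(["A", "B", "C", "D"]))
    model = build_model(model_id, random_rates(rng, model_id))
    n_tips = int(rng.integers(2, max_tips + 1))
    tree = random_tree(rng, n_tips)
    cells = {label: random_observations(rng, model) for label in tree.tip_labels}
    return tree, model, make_matrix(cells)
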