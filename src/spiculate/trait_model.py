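"""Rate-matrix construction for skeletal characters and their amalgamation.

Four discrete characters describe a sponge skeleton:

1. spicule presence        -- absent ``0`` / present ``1``
2. calcareous biomineralization  -- absent ``0`` / present ``1``
3. siliceous biomineralization   -- absent ``0`` / present ``1``
4. biosilicification pathway     -- hexactinellid ``0`` / demosponge ``1`` /
   homoscleromorph ``2``; meaningful only while character 3 is present

Characters 1-3 evolve independently; character 4 is *embedded* in
character 3: pathway states exist only while silica deposition is on, so
the joint silica+pathway character lives on the 4-state space
{absent, present-hex, present-demo, present-homo}.  A gain of
biosilicification jumps from "absent" directly into one of the pathway
states; a loss returns to "absent"; switching between pathways while
silicified is a separate (default 0) rate.

Independent characters are amalgamated into a single Markov chain on the
product state space via the Kronecker sum of their generators, which by
construction assigns rate 0 to any simultaneous change of two characters.
Four canonical model layouts are provided:

====== ============================================== ======
model  components                                     states
====== ============================================== ======
A      calcareous x siliceous                         4
B      calcareous x siliceous x spicules              8
C      calcareous x (siliceous+pathway embedded)      8
D      calcareous x (siliceous+pathway) x spicules    16
====== ============================================== ======
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "CharacterSpec",
    "Component",
    "AmalgamatedModel",
    "SPICULES",
    "CALCAREOUS",
    "SILICEOUS",
    "PATHWAY",
    "MODEL_IDS",
    "build_char_Q",
    "embed_dependent",
    "kronecker_amalgamate",
    "build_model",
    "default_free_params",
    "tip_state_set",
]

ROW_SUM_TOL = 1e-10


@dataclass(frozen=True)
class CharacterSpec:
    """A primitive discrete character, optionally dependent on a controller.

    ``depends_on`` is ``(controller_name, enabling_state)``: the character's
    states exist only while the controller is in the enabling state.
    """

    name: str
    primitive_states: Tuple[str, ...]
    depends_on: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        if len(self.primitive_states) < 2:
            raise ValueError(f"character {self.name!r} needs >=2 states")
        if len(set(self.primitive_states)) != len(self.primitive_states):
            raise ValueError(f"character {self.name!r} has duplicate states")


SPICULES = CharacterSpec("spicules", ("0", "1"))
CALCAREOUS = CharacterSpec("calcareous", ("0", "1"))
SILICEOUS = CharacterSpec("siliceous", ("0", "1"))
PATHWAY = CharacterSpec("pathway", ("0", "1", "2"), depends_on=("siliceous", "1"))

MODEL_IDS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class Component:
    """One factor of the amalgamated chain: a state list and its generator.

    For a simple character the states are its primitive symbols and
    ``characters`` holds one name.  For an embedded pair the states are
    ``(controller_state, dependent_state_or_None)`` tuples and
    ``characters`` holds ``(controller, dependent)``.
    """

    name: str
    states: Tuple[object, ...]
    Q: np.ndarray
    characters: Tuple[str, ...]
    enabling: Optional[Tuple[str, str]] = None  # (disabled symbol, enabled symbol)

    def __post_init__(self) -> None:
        _check_generator(self.Q, len(self.states), self.name)


def _check_generator(Q: np.ndarray, k: int, name: str) -> None:
    if Q.shape != (k, k):
        raise ValueError(f"{name}: generator must be {k}x{k}, got {Q.shape}")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < 0):
        raise ValueError(f"{name}: negative off-diagonal rate")
    if np.max(np.abs(Q.sum(axis=1))) > ROW_SUM_TOL:
        raise ValueError(f"{name}: generator rows do not sum to 0")


def _require_nonneg(value: float, key: str) -> float:
    v = float(value)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"rate {key!r} must be finite and >= 0, got {value}")
    return v


def build_char_Q(
    spec: CharacterSpec,
    rates: Mapping[str, float],
    parameterization: str = "GL",
) -> np.ndarray:
    """Generator for an independent character.

    Parameterizations: ``ER`` (one rate, key ``rate``), ``GL`` (binary only;
    keys ``gain`` for 0->1 and ``loss`` for 1->0) and ``ARD`` (one key
    ``rate_<from>_<to>`` per ordered state pair).
    """
    if spec.depends_on is not None:
        raise ValueError(
            f"{spec.name!r} is dependent; use embed_dependent for its generator"
        )
    k = len(spec.primitive_states)
    Q = np.zeros((k, k))
    if parameterization == "ER":
        q = _require_nonneg(rates["rate"], f"{spec.name}.rate")
        Q[:] = q
    elif parameterization == "GL":
        if k != 2:
            raise ValueError(
                f"GL parameterization needs a binary character; {spec.name!r} has {k} states"
            )
        Q[0, 1] = _require_nonneg(rates["gain"], f"{spec.name}.gain")
        Q[1, 0] = _require_nonneg(rates["loss"], f"{spec.name}.loss")
    elif parameterization == "ARD":
        for i, a in enumerate(spec.primitive_states):
            for j, b in enumerate(spec.primitive_states):
                if i != j:
                    Q[i, j] = _require_nonneg(
                        rates[f"rate_{a}_{b}"], f"{spec.name}.rate_{a}_{b}"
                    )
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def embed_dependent(
    controller: CharacterSpec,
    dependent: CharacterSpec,
    rates: Mapping[str, float],
) -> Component:
    """Embed a dependent character inside its binary controller.

    State space: ``{(off, None)} U {(on, d) for d in dependent states}``.
    Rates (``d`` ranges over dependent states):

    - ``gain`` or ``gain_<d>``: off -> (on, d)
    - ``loss`` or ``loss_<d>``: (on, d) -> off
    - ``switch`` or ``switch_<d1>_<d2>``: (on, d1) -> (on, d2); default 0

    A single shared ``gain`` means pathway identity is chosen at the moment
    of gain with equal rates into each pathway.
    """
    if dependent.depends_on is None or dependent.depends_on[0] != controller.name:
        raise ValueError(
            f"{dependent.name!r} does not declare {controller.name!r} as controller"
        )
    if controller.depends_on is not None:
        raise ValueError("dependency nesting deeper than one level is not supported")
    enabling = dependent.depends_on[1]
    if enabling not in controller.primitive_states or len(controller.primitive_states) != 2:
        raise ValueError(
            f"controller {controller.name!r} must be binary with enabling state "
            f"{enabling!r} in its state space"
        )
    disabled = next(s for s in controller.primitive_states if s != enabling)
    dstates = dependent.primitive_states
    states: Tuple[object, ...] = ((disabled, None),) + tuple((enabling, d) for d in dstates)
    k = len(states)
    Q = np.zeros((k, k))

    def rate(shared_key: str, specific_key: str, default: Optional[float] = None) -> float:
        if specific_key in rates:
            return _require_nonneg(rates[specific_key], specific_key)
        if shared_key in rates:
            return _require_nonneg(rates[shared_key], shared_key)
        if default is not None:
            return default
        raise KeyError(f"missing rate {shared_key!r} (or {specific_key!r})")

    for j, d in enumerate(dstates, start=1):
        Q[0, j] = rate("gain", f"gain_{d}")
        Q[j, 0] = rate("loss", f"loss_{d}")
    for j1, d1 in enumerate(dstates, start=1):
        for j2, d2 in enumerate(dstates, start=1):
            if j1 != j2:
                Q[j1, j2] = rate("switch", f"switch_{d1}_{d2}", default=0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Component(
        name=f"{controller.name}+{dependent.name}",
        states=states,
        Q=Q,
        characters=(controller.name, dependent.name),
        enabling=(disabled, enabling),
    )


@dataclass(frozen=True)
class AmalgamatedModel:
    """Product-space Markov chain over several skeletal characters."""

    components: Tuple[Component, ...]
    model_id: str = "custom"
    product_states: Tuple[Tuple[object, ...], ...] = field(init=False)
    state_index: Dict[Tuple[object, ...], int] = field(init=False)
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        states = tuple(itertools.product(*[c.states for c in self.components]))
        dims = [len(c.states) for c in self.components]
        n = int(np.prod(dims))
        Q = np.zeros((n, n))
        for i, comp in enumerate(self.components):
            left = int(np.prod(dims[:i])) if i else 1
            right = int(np.prod(dims[i + 1 :])) if i + 1 < len(dims) else 1
            Q += np.kron(np.kron(np.eye(left), comp.Q), np.eye(right))
        object.__setattr__(self, "product_states", states)
        object.__setattr__(self, "state_index", {s: i for i, s in enumerate(states)})
        object.__setattr__(self, "Q", Q)
        _check_generator(Q, n, f"amalgamated({self.model_id})")

    @property
    def n_states(self) -> int:
        return len(self.product_states)

    @property
    def characters(self) -> Tuple[str, ...]:
        return tuple(ch for c in self.components for ch in c.characters)

    def component_for(self, character: str) -> Tuple[int, Component]:
        for i, c in enumerate(self.components):
            if character in c.characters:
                return i, c
        raise KeyError(f"model {self.model_id!r} has no character {character!r}")

    # -- masks used for display aggregation -------------------------------

    def _component_mask(self, comp_idx: int, keep) -> np.ndarray:
        return np.array([keep(s[comp_idx]) for s in self.product_states], dtype=bool)

    def character_present_mask(self, character: str) -> np.ndarray:
        """Boolean mask over product states where a binary character is '1'
        (for an embedded controller: where the controller is enabled)."""
        i, comp = self.component_for(character)
        if comp.enabling is not None and character == comp.characters[0]:
            enabled = comp.enabling[1]
            return self._component_mask(i, lambda s: s[0] == enabled)
        if comp.enabling is not None:
            raise KeyError(f"{character!r} is a dependent character, not binary")
        return self._component_mask(i, lambda s: s == "1")


def kronecker_amalgamate(
    components: Sequence[Component], model_id: str = "custom"
) -> AmalgamatedModel:
    """Amalgamate independent components via the Kronecker sum.

    Product states are ordered lexicographically with the first component
    varying slowest, matching ``Q = sum_i I (x) ... Q_i ... (x) I``.
    """
    if not components:
        raise ValueError("at least one component required")
    return AmalgamatedModel(components=tuple(components), model_id=model_id)


def _simple_component(spec: CharacterSpec, params: Mapping[str, float]) -> Component:
    prefix = spec.name + "."
    rates = {k[len(prefix) :]: v for k, v in params.items() if k.startswith(prefix)}
    if "rate" in rates:
        parameterization = "ER"
    elif any(k.startswith("rate_") for k in rates):
        parameterization = "ARD"
    else:
        parameterization = "GL"
    Q = build_char_Q(spec, rates, parameterization)
    return Component(name=spec.name, states=spec.primitive_states, Q=Q, characters=(spec.name,))


def _embedded_silica(params: Mapping[str, float]) -> Component:
    prefix = SILICEOUS.name + "."
    rates = {k[len(prefix) :]: v for k, v in params.items() if k.startswith(prefix)}
    return embed_dependent(SILICEOUS, PATHWAY, rates)


def build_model(model_id: str, params: Mapping[str, float]) -> AmalgamatedModel:
    """Build one of the canonical models A-D from dotted-key rates.

    ``params`` keys are ``<character>.<rate>``, e.g. ``calcareous.gain``,
    ``siliceous.loss``, ``spicules.gain``; for models C/D the siliceous keys
    address the embedded silica+pathway component (``siliceous.gain`` shared
    across pathways or ``siliceous.gain_1`` per pathway, likewise ``loss``
    and ``switch``).
    """
    mid = model_id.upper()
    if mid not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    comps: List[Component] = [_simple_component(CALCAREOUS, params)]
    if mid in ("A", "B"):
        comps.append(_simple_component(SILICEOUS, params))
    else:
        comps.append(_embedded_silica(params))
    if mid in ("B", "D"):
        comps.append(_simple_component(SPICULES, params))
    return kronecker_amalgamate(comps, model_id=mid)


def default_free_params(model_id: str) -> List[str]:
    """Free rate names for a model under the default gain/loss scheme
    (shared pathway gain and loss, pathway switching fixed at 0)."""
    mid = model_id.upper()
    if mid not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    names = ["calcareous.gain", "calcareous.loss", "siliceous.gain", "siliceous.loss"]
    if mid in ("B", "D"):
        names += ["spicules.gain", "spicules.loss"]
    return names


def tip_state_set(
    obs: Mapping[str, Iterable[str]],
    model: AmalgamatedModel,
    taxon: str = "<taxon>",
) -> List[int]:
    """Product-state indices compatible with per-character observation sets.

    Missing characters default to their full state set.  A dependent
    observation is collapsed (ignored) for states where its controller is
    disabled; positively asserting a pathway while asserting silica absent
    is a contradiction and raises.
    """
    per_component: List[List[object]] = []
    obs_sets: Dict[str, Set[str]] = {k: set(v) for k, v in obs.items()}

    def char_obs(spec_name: str, space: Sequence[str]) -> Set[str]:
        got = obs_sets.get(spec_name, set(space))
        bad = got - set(space)
        if bad:
            raise ValueError(
                f"taxon {taxon!r}: states {sorted(bad)} undeclared for {spec_name!r}"
            )
        return got

    for comp in model.components:
        if comp.enabling is None:
            allowed = [s for s in comp.states if s in char_obs(comp.name, comp.states)]
        else:
            ctrl, dep = comp.characters
            disabled, enabled = comp.enabling
            dep_space = [s[1] for s in comp.states if s[1] is not None]
            c_obs = char_obs(ctrl, (disabled, enabled))
            d_obs = char_obs(dep, dep_space)
            if c_obs == {disabled} and d_obs < set(dep_space):
                raise ValueError(
                    f"taxon {taxon!r}: contradictory coding — {ctrl!r} asserted absent "
                    f"but dependent {dep!r} positively asserted as {sorted(d_obs)}"
                )
            allowed = []
            for s in comp.states:
                if s[1] is None:
                    if disabled in c_obs:
                        allowed.append(s)
                elif enabled in c_obs and s[1] in d_obs:
                    allowed.append(s)
        if not allowed:
            raise ValueError(f"taxon {taxon!r}: no state of component {comp.name!r} allowed")
        per_component.append(allowed)

    indices = [
        model.state_index[s] for s in itertools.product(*per_component)
    ]
    if not indices:
        raise ValueError(f"taxon {taxon!r}: contradictory coding yields empty state set")
    return sorted(indices)
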