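"""Reading, validating and writing time-calibrated trees and character matrices.

Trees are rooted phylogenies with branch lengths in Myr.  Tips need not be
contemporaneous: a fossil tip sits at a positive age before present, so the
tree need not be ultrametric.  Ages follow the palaeontological convention
(Myr before present, larger = older); the youngest tip on the longest
root-to-tip path defines age 0.

Character matrices map taxa to *sets* of allowed primitive states per
character: a singleton set is a direct observation, the full state set is
missing data ("?"), and a proper subset is a partial/ambiguous coding such
as a silicified fossil whose biosilicification pathway is unknown.

Parsing of Newick and NEXUS is delegated to dendropy; the containers here
re-expose the results as flat arrays suitable for pruning.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "CharacterMatrix",
    "TreeValidationError",
    "MatrixValidationError",
    "TaxonMatchError",
    "parse_tree",
    "parse_matrix",
    "write_tree",
    "normalize_name",
    "match_taxa",
]

AGE_TOL = 1e-6


class TreeValidationError(ValueError):
    """A parsed tree violates a TimeTree invariant."""


class MatrixValidationError(ValueError):
    """A character matrix cell or header is invalid."""


class TaxonMatchError(ValueError):
    """Tree tips and matrix taxa cannot be matched 1:1."""


@dataclass
class TimeTree:
    """Rooted time-calibrated tree stored as parent-pointer arrays.

    Node 0 is the root.  ``children`` lists allow arbitrary polytomies,
    which the likelihood machinery treats as hard (no resolution).

    Attributes
    ----------
    parent : array of int, -1 for the root
    branch_lengths : array of float, Myr; 0.0 for the root entry
    labels : tip label or None per node
    children : list of child-index lists
    node_ages : Myr before present per node
    """

    parent: np.ndarray
    branch_lengths: np.ndarray
    labels: List[Optional[str]]
    children: List[List[int]] = field(default_factory=list)
    node_ages: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not self.children:
            ch: List[List[int]] = [[] for _ in range(n)]
            for i in range(1, n):
                ch[self.parent[i]].append(i)
            self.children = ch
        if self.node_ages.size == 0:
            depth = np.zeros(n)
            for i in self.preorder()[1:]:
                depth[i] = depth[self.parent[i]] + self.branch_lengths[i]
            ages = depth.max() - depth
            # contemporaneous tips differ from age 0 only by float noise
            ages[np.abs(ages) < 1e-9] = 0.0
            self.node_ages = ages
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tips(self) -> List[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    @property
    def internal_nodes(self) -> List[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def tip_labels(self) -> List[str]:
        return [self.labels[i] for i in self.tips]  # type: ignore[misc]

    def tip_ages(self) -> Dict[str, float]:
        return {self.labels[i]: float(self.node_ages[i]) for i in self.tips}

    def preorder(self) -> List[int]:
        order = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> List[int]:
        return self.preorder()[::-1]

    def clade_tipset(self, i: int) -> FrozenSet[str]:
        """Labels of all tips descending from (or equal to) node ``i``."""
        out = []
        stack = [i]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return frozenset(out)  # type: ignore[arg-type]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths[1:].sum())

    @property
    def height(self) -> float:
        return float(self.node_ages[0])

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise TreeValidationError("empty tree")
        if self.parent[0] != -1:
            raise TreeValidationError("node 0 must be the root (parent -1)")
        if np.sum(self.parent == -1) != 1:
            raise TreeValidationError("exactly one root required")
        if np.any(self.branch_lengths[1:] < 0):
            bad = np.nonzero(self.branch_lengths < 0)[0]
            raise TreeValidationError(f"negative branch length at nodes {bad.tolist()}")
        for i in self.tips:
            if not self.labels[i]:
                raise TreeValidationError(f"unlabeled tip at node {i}")
        seen = self.preorder()
        if len(seen) != n:
            raise TreeValidationError("tree contains a cycle or unreachable node")
        for i in range(1, n):
            p = self.parent[i]
            if abs(self.node_ages[p] - (self.node_ages[i] + self.branch_lengths[i])) > AGE_TOL:
                raise TreeValidationError(f"age/branch-length inconsistency at node {i}")

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        dtree = dtree.clone(depth=1)
        dtree.is_rooted = True
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        labels: List[Optional[str]] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeValidationError(
                        f"missing branch length above node {nd.taxon or i}"
                    )
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeValidationError(f"unlabeled tip at node index {i}")
                labels[i] = nd.taxon.label
            elif nd.taxon is not None:
                labels[i] = nd.taxon.label
        return cls(parent=parent, branch_lengths=lengths, labels=labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        dtree.seed_node = dnodes[0]
        for i in self.preorder()[1:]:
            dnodes[self.parent[i]].add_child(dnodes[i])
            dnodes[i].edge.length = float(self.branch_lengths[i])
        for i in self.tips:
            dnodes[i].taxon = taxa.new_taxon(label=self.labels[i])
        dtree.is_rooted = True
        return dtree


def parse_tree(text: str, units: str = "Myr") -> TimeTree:
    """Parse a rooted Newick or NEXUS tree with branch lengths in Myr.

    Node ages are assigned by placing the tip on the longest root-to-tip
    path at age 0 and measuring every other node back from it, so tips on
    shorter paths come out at positive ages (fossils).

    Raises
    ------
    TreeValidationError
        On malformed syntax, negative branch lengths or unlabeled tips.
    """
    text = text.strip()
    schema = "nexus" if text.upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeValidationError(f"could not parse {schema} tree: {exc}") from exc
    return TimeTree.from_dendropy(dtree)


def write_tree(tree: TimeTree) -> str:
    """Serialize to a Newick string; parse(write(t)) preserves topology and
    branch lengths to well below 1e-9."""
    s = tree.to_dendropy().as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return s.strip() + ("" if s.strip().endswith(";") else ";")


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxon x character observations as allowed-state sets.

    ``state_spaces`` declares the ordered primitive states per character;
    every observation is a non-empty subset of the declared space.
    """

    taxa: List[str]
    characters: List[str]
    state_spaces: Dict[str, Tuple[str, ...]]
    observations: Dict[Tuple[str, str], FrozenSet[str]]

    def __post_init__(self) -> None:
        for (taxon, char), obs in self.observations.items():
            space = set(self.state_spaces[char])
            if not obs:
                raise MatrixValidationError(f"empty observation set for {taxon}/{char}")
            extra = set(obs) - space
            if extra:
                raise MatrixValidationError(
                    f"taxon {taxon!r}, character {char!r}: "
                    f"states {sorted(extra)} not in declared space {sorted(space)}"
                )

    def obs(self, taxon: str, char: str) -> FrozenSet[str]:
        return self.observations[(taxon, char)]

    def subset(self, characters: Sequence[str]) -> "CharacterMatrix":
        chars = list(characters)
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=chars,
            state_spaces={c: self.state_spaces[c] for c in chars},
            observations={
                (t, c): v for (t, c), v in self.observations.items() if c in chars
            },
        )

    def to_frame(self) -> pd.DataFrame:
        def cell(t: str, c: str) -> str:
            v = sorted(self.observations[(t, c)])
            if len(v) == 1:
                return v[0]
            if set(v) == set(self.state_spaces[c]):
                return "?"
            return "{" + "".join(v) + "}"

        return pd.DataFrame(
            {c: [cell(t, c) for t in self.taxa] for c in self.characters},
            index=pd.Index(self.taxa, name="taxon"),
        )


_CELL_SET = re.compile(r"^[{(\[]([^})\]]+)[})\]]$")


def _parse_cell(raw: str, char: str, states: Tuple[str, ...], taxon: str) -> FrozenSet[str]:
    cell = str(raw).strip()
    if cell in {"?", "-", ""} or cell.lower() == "nan":
        return frozenset(states)
    m = _CELL_SET.match(cell)
    if m:
        # {01}, {0,1}, (0 1) all mean the set of single-symbol states
        symbols = list(re.sub(r"[,/\s]+", "", m.group(1)))
    elif "/" in cell:
        symbols = [s for s in cell.split("/") if s]
    else:
        symbols = [cell]
    out = set()
    for sym in symbols:
        if sym not in states:
            raise MatrixValidationError(
                f"taxon {taxon!r}, character {char!r}: undeclared symbol {sym!r} "
                f"(declared: {list(states)})"
            )
        out.add(sym)
    return frozenset(out)


def parse_matrix(
    text: str,
    charset: Mapping[str, Sequence[str]],
    fmt: str = "auto",
) -> CharacterMatrix:
    """Parse a NEXUS or CSV character matrix against declared state spaces.

    ``?`` (and ``-``) expand to the full state set of the character;
    ``{01}``, ``(01)`` or ``0/1`` expand to the declared subset.  Undeclared
    symbols raise :class:`MatrixValidationError` naming taxon, character and
    symbol.
    """
    if fmt == "auto":
        fmt = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "csv"
    state_spaces = {c: tuple(str(s) for s in v) for c, v in charset.items()}
    if fmt == "csv":
        df = pd.read_csv(io.StringIO(text), index_col=0, dtype=str)
        characters = [str(c) for c in df.columns]
        taxa = [str(t) for t in df.index]
    elif fmt == "nexus":
        try:
            dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
        except Exception as exc:
            raise MatrixValidationError(f"could not parse NEXUS matrix: {exc}") from exc
        taxa = [t.label for t in dm.taxon_namespace]
        ncols = max(len(dm[t]) for t in dm.taxon_namespace)
        declared = list(charset)
        if len(declared) != ncols:
            raise MatrixValidationError(
                f"NEXUS matrix has {ncols} characters but charset declares {len(declared)}"
            )
        characters = declared
        cells = {}
        for t in dm.taxon_namespace:
            for j, state in enumerate(dm[t]):
                members = state.member_states or ()
                syms = [str(s.symbol) for s in members] or [str(state.symbol)]
                cells[(t.label, characters[j])] = "?" if set(syms) >= set(
                    state_spaces[characters[j]]
                ) else "{" + "".join(syms) + "}" if len(syms) > 1 else syms[0]
        df = None
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")

    missing = [c for c in characters if c not in state_spaces]
    if missing:
        raise MatrixValidationError(f"characters without declared states: {missing}")

    observations: Dict[Tuple[str, str], FrozenSet[str]] = {}
    for t in taxa:
        for c in characters:
            raw = df.loc[t, c] if df is not None else cells[(t, c)]
            observations[(t, c)] = _parse_cell(raw, c, state_spaces[c], t)
    return CharacterMatrix(
        taxa=taxa,
        characters=characters,
        state_spaces={c: state_spaces[c] for c in characters},
        observations=observations,
    )


# ---------------------------------------------------------------------------
# taxon name matching
# ---------------------------------------------------------------------------


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace/underscore-equivalent canonical form."""
    return re.sub(r"[\s_]+", "_", name.strip()).casefold()


def match_taxa(
    tree: TimeTree,
    matrix: CharacterMatrix,
    synonyms: Optional[Mapping[str, str]] = None,
) -> Dict[str, str]:
    """Match tree tip labels 1:1 to matrix taxa after name normalization.

    ``synonyms`` maps tip labels (raw or normalized) to matrix taxon names
    for cases the default rule cannot resolve.  All mismatches are reported
    together rather than failing at the first one.
    """
    syn = {normalize_name(k): v for k, v in (synonyms or {}).items()}
    by_norm: Dict[str, str] = {}
    for t in matrix.taxa:
        key = normalize_name(t)
        if key in by_norm:
            raise TaxonMatchError(f"matrix taxa {by_norm[key]!r} and {t!r} collide after normalization")
        by_norm[key] = t
    mapping: Dict[str, str] = {}
    unmatched: List[str] = []
    for label in tree.tip_labels:
        key = normalize_name(label)
        if key in syn:
            key = normalize_name(syn[key])
        if key in by_norm:
            mapping[label] = by_norm[key]
        else:
            unmatched.append(label)
    if unmatched:
        raise TaxonMatchError(
            "tree tips with no matrix taxon after normalization: "
            + ", ".join(sorted(unmatched))
        )
    return mapping
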