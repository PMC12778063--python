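"""Likelihoods, ML rate fitting and marginal ancestral states on timetrees.

The likelihood is Felsenstein's pruning algorithm on a rooted, possibly
multifurcating, possibly non-ultrametric tree: tip partial likelihoods are
indicators of the tip's allowed amalgamated-state set (so fossils with
partial codings contribute exactly the information they carry), interior
partials are products over children of ``P(t_child) @ D_child``, and
per-node rescaling guards against underflow.  Marginal ancestral states are
exact inside-outside marginals, equal to re-rooting at every node.

Transition matrices ``P(t) = expm(Q t)`` are computed by eigendecomposition
of the generator, vectorized over all branch lengths of a tree, with
scaling-and-squaring (``scipy.linalg.expm``) as the reference path and as a
fallback when the eigenbasis is ill-conditioned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .phylo_io import CharacterMatrix, TimeTree, match_taxa
from .trait_model import AmalgamatedModel, build_model, default_free_params, tip_state_set

__all__ = [
    "FitResult",
    "MarginalReconstruction",
    "transition_matrix",
    "transition_matrices",
    "tip_partials",
    "pruning_loglik",
    "enumeration_loglik",
    "fit_ml",
    "marginal_ancestral",
    "aggregate_display",
    "minimum_across_runs",
    "ROOT_PRIORS",
]

ROOT_PRIORS = ("flat", "stationary", "fitzjohn")
_EIG_ROWSUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


def transition_matrices(Q: np.ndarray, ts: Sequence[float]) -> np.ndarray:
    """``P(t) = expm(Q t)`` for every ``t`` in ``ts``, shape (len(ts), k, k).

    Uses one eigendecomposition of ``Q`` for all branch lengths; falls back
    to ``scipy.linalg.expm`` per unique ``t`` when the eigenbasis is too
    ill-conditioned to reproduce stochastic rows to 1e-9.
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("branch lengths / times must be >= 0")
    k = Q.shape[0]
    P = np.empty((len(ts), k, k))
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        E = np.exp(np.outer(ts, lam))
        P[:] = np.einsum("ik,tk,kj->tij", U, E, Uinv).real
        ok = (
            np.all(np.isfinite(P))
            and np.max(np.abs(P.sum(axis=2) - 1.0)) < _EIG_ROWSUM_TOL
            and P.min() > -_EIG_ROWSUM_TOL
        )
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        cache: Dict[float, np.ndarray] = {}
        for i, t in enumerate(ts):
            if t not in cache:
                cache[t] = scipy.linalg.expm(Q * t)
            P[i] = cache[t]
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[ts == 0.0] = np.eye(k)
    return P


def transition_matrix(Q: np.ndarray, t: float, method: str = "auto") -> np.ndarray:
    """Single transition matrix ``expm(Q t)``.

    ``method``: ``auto`` (eigendecomposition with expm fallback), ``pade``
    (scipy scaling-and-squaring) or ``eig``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if method == "pade":
        P = scipy.linalg.expm(Q * float(t))
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P
    if method in ("auto", "eig"):
        return transition_matrices(Q, [t])[0]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def tip_partials(
    tree: TimeTree,
    model: AmalgamatedModel,
    data: CharacterMatrix,
    synonyms: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Indicator partial-likelihood vectors for every tip, (n_nodes, k).

    Rows for interior nodes are left at zero; each tip row is 1 on the
    product states compatible with the taxon's observation sets.
    """
    missing = [c for c in model.characters if c not in data.characters]
    if missing:
        raise ValueError(f"character matrix lacks model characters: {missing}")
    mapping = match_taxa(tree, data, synonyms)
    D = np.zeros((tree.n_nodes, model.n_states))
    for i in tree.tips:
        taxon = mapping[tree.labels[i]]
        obs = {c: data.obs(taxon, c) for c in model.characters}
        idx = tip_state_set(obs, model, taxon=taxon)
        D[i, idx] = 1.0
    return D


def _root_prior_vector(
    prior: str, model: AmalgamatedModel, root_partial: np.ndarray
) -> np.ndarray:
    k = model.n_states
    if prior == "flat":
        return np.full(k, 1.0 / k)
    if prior == "stationary":
        ns = scipy.linalg.null_space(model.Q.T)
        if ns.shape[1] != 1:
            # reducible or frozen chain: no unique stationary law
            return np.full(k, 1.0 / k)
        pi = np.abs(ns[:, 0])
        return pi / pi.sum()
    if prior == "fitzjohn":
        s = root_partial.sum()
        if s <= 0:
            return np.full(k, 1.0 / k)
        return root_partial / s
    raise ValueError(f"unknown root prior {prior!r}; expected one of {ROOT_PRIORS}")


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _inside_pass(
    tree: TimeTree, model: AmalgamatedModel, tips: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized inside (subtree) partials, per-node log scalers and the
    per-edge transition matrices (indexed by child node)."""
    P = transition_matrices(model.Q, tree.branch_lengths)
    D = tips.copy()
    logscale = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        part = np.ones(model.n_states)
        for c in tree.children[v]:
            part *= P[c] @ D[c]
        s = part.max()
        if s <= 0.0:
            D[v] = 0.0
            logscale[v] = -np.inf
            continue
        D[v] = part / s
        logscale[v] = np.log(s) + sum(logscale[c] for c in tree.children[v])
    return D, logscale, P


def pruning_loglik(
    tree: TimeTree,
    model: AmalgamatedModel,
    data: CharacterMatrix,
    root_prior: str = "flat",
    synonyms: Optional[Mapping[str, str]] = None,
) -> float:
    """Log-likelihood of the tip data under the amalgamated chain.

    Returns ``-inf`` (no exception) when the data are impossible under the
    model, e.g. a zero-length branch to a tip contradicting its neighbour.
    """
    tips = tip_partials(tree, model, data, synonyms)
    D, logscale, _ = _inside_pass(tree, model, tips)
    root = tree.root
    pi = _root_prior_vector(root_prior, model, D[root])
    L = float(pi @ D[root])
    if L <= 0.0 or not np.isfinite(logscale[root]):
        return -np.inf
    return float(np.log(L) + logscale[root])


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

_ENUM_MAX_ASSIGN = 20_000_000


def enumeration_loglik(
    tree: TimeTree,
    model: AmalgamatedModel,
    data: CharacterMatrix,
    root_prior: str = "flat",
    synonyms: Optional[Mapping[str, str]] = None,
) -> float:
    """Exact log-likelihood by brute-force summation over every joint
    assignment of states to interior nodes (testing oracle).

    Refuses instances with more than 8 tips or 16 states, or whose
    assignment space exceeds an internal guard.
    """
    n_tips = len(tree.tips)
    k = model.n_states
    if n_tips > 8 or k > 16:
        raise ValueError(f"enumeration oracle limited to <=8 tips, <=16 states "
                         f"(got {n_tips} tips, {k} states)")
    interior = tree.internal_nodes
    m = len(interior)
    if k ** m > _ENUM_MAX_ASSIGN:
        raise ValueError("assignment space too large for enumeration")
    tips = tip_partials(tree, model, data, synonyms)
    P = transition_matrices(model.Q, tree.branch_lengths)
    pos = {v: j for j, v in enumerate(interior)}

    grids = np.meshgrid(*([np.arange(k)] * m), indexing="ij") if m else []
    assign = (
        np.stack([g.ravel() for g in grids], axis=1)
        if m
        else np.zeros((1, 0), dtype=int)
    )
    like = np.ones(assign.shape[0])
    for v in interior:
        sv = assign[:, pos[v]]
        for c in tree.children[v]:
            if tree.is_tip(c):
                like *= (P[c] @ tips[c])[sv]
            else:
                like *= P[c][sv, assign[:, pos[c]]]
    if m:
        root_states = assign[:, pos[tree.root]]
        D_root = np.bincount(root_states, weights=like, minlength=k).astype(float)
    else:  # single-tip tree: the root is the tip
        D_root = tips[tree.root].astype(float)
    pi = _root_prior_vector(root_prior, model, D_root)
    L = float(pi @ D_root)
    return float(np.log(L)) if L > 0 else -np.inf


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a multi-start ML fit of per-Myr transition rates."""

    model_id: str
    params: Dict[str, float]
    loglik: float
    root_prior: str
    restarts: List[Dict[str, object]] = field(default_factory=list)
    converged: bool = True
    seed: Optional[int] = None
    free_names: List[str] = field(default_factory=list)
    fixed_params: Dict[str, float] = field(default_factory=dict)

    def build(self) -> AmalgamatedModel:
        return build_model(self.model_id, self.params)


def fit_ml(
    tree: TimeTree,
    model_id: str,
    data: CharacterMatrix,
    root_prior: str = "flat",
    free_params: Optional[Sequence[str]] = None,
    fixed_params: Optional[Mapping[str, float]] = None,
    n_restarts: int = 10,
    seed: int = 0,
    bounds: Tuple[float, float] = (1e-8, 1e3),
    start_range: Tuple[float, float] = (1e-4, 1.0),
    tol: float = 1e-8,
    synonyms: Optional[Mapping[str, str]] = None,
) -> FitResult:
    """Maximize the pruning log-likelihood over log-transformed rates.

    Bounded L-BFGS-B on ``log(rate)`` with ``n_restarts`` seeded log-uniform
    starting points; ties between restarts are broken by the lowest restart
    index, so a fixed seed reproduces the result bit for bit.
    """
    names = list(free_params) if free_params is not None else default_free_params(model_id)
    if not names:
        raise ValueError("at least one free rate parameter required")
    fixed = dict(fixed_params or {})
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    tips_cache: Dict[str, np.ndarray] = {}

    def loglik_of(values: np.ndarray) -> float:
        params = dict(zip(names, np.exp(values)))
        params.update(fixed)
        model = build_model(model_id, params)
        if "tips" not in tips_cache:
            tips_cache["tips"] = tip_partials(tree, model, data, synonyms)
        D, logscale, _ = _inside_pass(tree, model, tips_cache["tips"])
        pi = _root_prior_vector(root_prior, model, D[tree.root])
        L = float(pi @ D[tree.root])
        if L <= 0 or not np.isfinite(logscale[tree.root]):
            return -np.inf
        return float(np.log(L) + logscale[tree.root])

    def objective(values: np.ndarray) -> float:
        ll = loglik_of(values)
        return 1e12 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log(start_range[0]), np.log(start_range[1])
    starts = rng.uniform(log_lo, log_hi, size=(n_restarts, len(names)))

    best = None
    restarts: List[Dict[str, object]] = []
    any_ok = False
    for r in range(n_restarts):
        res = scipy.optimize.minimize(
            objective,
            starts[r],
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(names),
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        ll = -float(res.fun)
        restarts.append(
            {
                "restart": r,
                "loglik": ll,
                "rates": dict(zip(names, np.exp(res.x))),
                "converged": bool(res.success),
                "n_evals": int(res.nfev),
            }
        )
        any_ok = any_ok or bool(res.success)
        if best is None or ll > best[0] + 0.0:
            best = (ll, res.x.copy(), r)
    if best is None or not any_ok:
        raise RuntimeError(f"optimizer failed on all {n_restarts} restarts: {restarts}")
    ll, x, _ = best
    params = dict(zip(names, np.exp(x)))
    params.update(fixed)
    return FitResult(
        model_id=model_id.upper(),
        params=params,
        loglik=float(ll),
        root_prior=root_prior,
        restarts=restarts,
        converged=any_ok,
        seed=seed,
        free_names=names,
        fixed_params=fixed,
    )


# ---------------------------------------------------------------------------
# marginal ancestral states
# ---------------------------------------------------------------------------


@dataclass
class MarginalReconstruction:
    """Per-node marginal state probabilities under plugged-in rates."""

    tree: TimeTree
    model: AmalgamatedModel
    params: Dict[str, float]
    root_prior: str
    probs: np.ndarray  # (n_nodes, n_states), each row sums to 1
    loglik: float

    def node_table(self) -> pd.DataFrame:
        cols = ["|".join("∅" if x is None else str(x) for x in _flatten(s))
                for s in self.model.product_states]
        df = pd.DataFrame(self.probs, columns=cols)
        df.insert(0, "node", np.arange(self.tree.n_nodes))
        df.insert(1, "is_tip", [self.tree.is_tip(i) for i in range(self.tree.n_nodes)])
        df.insert(2, "age_Myr", self.tree.node_ages)
        df.insert(
            3,
            "clade",
            [_clade_hash(self.tree, i) for i in range(self.tree.n_nodes)],
        )
        return df


def _flatten(state: Tuple[object, ...]) -> Tuple[object, ...]:
    out: List[object] = []
    for s in state:
        if isinstance(s, tuple):
            out.extend(s)
        else:
            out.append(s)
    return tuple(out)


def _clade_hash(tree: TimeTree, node: int) -> str:
    import hashlib

    tips = sorted(tree.clade_tipset(node))
    return hashlib.sha1("|".join(tips).encode()).hexdigest()[:12]


def marginal_ancestral(
    tree: TimeTree,
    model: AmalgamatedModel,
    params: Mapping[str, float],
    data: CharacterMatrix,
    root_prior: str = "flat",
    synonyms: Optional[Mapping[str, str]] = None,
) -> MarginalReconstruction:
    """Exact marginal P(node state | data, rates) for every node.

    Inside-outside scheme: the inside pass is pruning; the outside pass
    propagates the root prior down the tree, combining each node's outside
    vector with the inside vectors of its siblings.  Equivalent to
    re-rooting the tree at every node in turn.
    """
    tips = tip_partials(tree, model, data, synonyms)
    D, logscale, P = _inside_pass(tree, model, tips)
    root = tree.root
    pi = _root_prior_vector(root_prior, model, D[root])
    L = float(pi @ D[root])
    if L <= 0 or not np.isfinite(logscale[root]):
        raise ValueError("data impossible under model: zero likelihood at root")
    loglik = float(np.log(L) + logscale[root])

    k = model.n_states
    O = np.zeros((tree.n_nodes, k))
    O[root] = pi
    for v in tree.preorder():
        if tree.is_tip(v):
            continue
        ch = tree.children[v]
        S = [P[c] @ D[c] for c in ch]  # per-child inside message at v
        for i, c in enumerate(ch):
            sib = np.ones(k)
            for j, s in enumerate(S):
                if j != i:
                    sib *= s
            oc = (O[v] * sib) @ P[c]
            tot = oc.sum()
            O[c] = oc / tot if tot > 0 else oc
    probs = O * D
    norm = probs.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise ValueError("zero marginal mass at some node (impossible data)")
    probs /= norm
    return MarginalReconstruction(
        tree=tree,
        model=model,
        params=dict(params),
        root_prior=root_prior,
        probs=probs,
        loglik=loglik,
    )


# ---------------------------------------------------------------------------
# display aggregation (biomineralization category + spicule presence)
# ---------------------------------------------------------------------------

CATEGORIES = ("none", "siliceous", "calcareous", "biminerallic")


def aggregate_display(recon: MarginalReconstruction) -> pd.DataFrame:
    """Collapse per-state marginals to display categories.

    Biomineralization: ``none`` (neither mineral), ``siliceous``,
    ``calcareous``, ``biminerallic`` (both).  For models carrying the
    independent spicule character a ``spicules_present`` column marginalizes
    it out.  Category probabilities sum to 1 by construction.
    """
    model = recon.model
    calc = model.character_present_mask("calcareous")
    sil = model.character_present_mask("siliceous")
    masks = {
        "none": ~calc & ~sil,
        "siliceous": ~calc & sil,
        "calcareous": calc & ~sil,
        "biminerallic": calc & sil,
    }
    out = {cat: recon.probs[:, m].sum(axis=1) for cat, m in masks.items()}
    df = pd.DataFrame(out)
    if "spicules" in model.characters:
        spic = model.character_present_mask("spicules")
        df["spicules_present"] = recon.probs[:, spic].sum(axis=1)
    df.insert(0, "node", np.arange(recon.tree.n_nodes))
    df.insert(1, "is_tip", [recon.tree.is_tip(i) for i in range(recon.tree.n_nodes)])
    df.insert(2, "age_Myr", recon.tree.node_ages)
    df.insert(3, "clade", [_clade_hash(recon.tree, i) for i in range(recon.tree.n_nodes)])
    return df


def minimum_across_runs(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-clade minimum of each category probability across several runs.

    Mirrors "P >= x across all analyses" reporting: clades are matched by
    their descendant-tip-set hash; only clades present in every run are
    kept.  Adds ``n_runs`` for transparency.
    """
    if not tables:
        raise ValueError("no run tables given")
    value_cols = [
        c
        for c in tables[0].columns
        if c in CATEGORIES or c == "spicules_present"
    ]
    common = set(tables[0]["clade"])
    for t in tables[1:]:
        common &= set(t["clade"])
    rows = []
    for clade in sorted(common):
        mins = {
            c: min(float(t.loc[t["clade"] == clade, c].iloc[0]) for t in tables)
            for c in value_cols
        }
        mins["clade"] = clade
        mins["n_runs"] = len(tables)
        rows.append(mins)
    return pd.DataFrame(rows, columns=["clade", *value_cols, "n_runs"])
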