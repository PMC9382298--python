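"""DAG structure learning for discrete Bayesian networks.

Score-based greedy search (add / delete / reverse hill climbing) under
temporal-tier blacklists and prior-knowledge whitelists, structural EM for
categorical data with missing cells, nonparametric bootstrap arc-strength
model averaging with threshold retention, and curated post-hoc arc edits.

Scores are decomposable (BIC by default, BDeu optional), so the search
caches per-family scores and evaluates each candidate move as a local
delta.  All tie-breaking is lexicographic in (parent, child) names so a
run is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import OUTCOME, ROLE_BACKGROUND, CohortTable, VariableSpec

logger = logging.getLogger(__name__)

Arc = tuple[str, str]


# --------------------------------------------------------------------------
# DAG
# --------------------------------------------------------------------------

class Dag:
    """Directed acyclic graph over named variables.

    Arcs are ordered (parent, child) pairs; mutation methods enforce
    acyclicity, no self-loops and no duplicate arcs.
    """

    def __init__(self, nodes: Iterable[str], arcs: Iterable[Arc] = ()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in arcs:
            self.add_arc(u, v)

    # -- queries ------------------------------------------------------------
    @property
    def arcs(self) -> list[Arc]:
        return sorted((u, v) for v, ps in self._parents.items() for u in ps)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._parents[node]))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._children[node]))

    def has_arc(self, u: str, v: str) -> bool:
        return u in self._parents[v]

    def __contains__(self, arc: Arc) -> bool:
        return self.has_arc(*arc)

    def copy(self) -> "Dag":
        return Dag(self.nodes, self.arcs)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Dag) and set(self.nodes) == set(other.nodes)
                and set(self.arcs) == set(other.arcs))

    def __repr__(self) -> str:
        return f"Dag({len(self.nodes)} nodes, {len(self.arcs)} arcs)"

    def _reachable(self, start: str, skip_arc: Arc | None = None) -> set[str]:
        seen, stack = set(), [start]
        while stack:
            u = stack.pop()
            for w in self._children[u]:
                if skip_arc is not None and (u, w) == skip_arc:
                    continue
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    def would_cycle(self, u: str, v: str) -> bool:
        """Would adding u -> v create a directed cycle?"""
        return u == v or u in self._reachable(v)

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises on cycles (cannot occur via the mutators)."""
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        queue = sorted(n for n in self.nodes if indeg[n] == 0)
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in sorted(self._children[n]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
            queue.sort()
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    # -- mutation -----------------------------------------------------------
    def add_arc(self, u: str, v: str) -> None:
        if u not in self._parents or v not in self._parents:
            raise KeyError(f"unknown node in arc ({u}, {v})")
        if self.has_arc(u, v):
            raise ValueError(f"duplicate arc ({u}, {v})")
        if self.would_cycle(u, v):
            raise ValueError(f"arc ({u}, {v}) would create a cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_arc(self, u: str, v: str) -> None:
        if not self.has_arc(u, v):
            raise ValueError(f"arc ({u}, {v}) not present")
        self._parents[v].discard(u)
        self._children[u].discard(v)

    def reverse_arc(self, u: str, v: str) -> None:
        self.remove_arc(u, v)
        try:
            self.add_arc(v, u)
        except ValueError:
            self.add_arc(u, v)  # restore before failing
            cycle = nx.find_cycle(nx.DiGraph(list(self.arcs) + [(v, u)]))
            raise ValueError(f"reversing ({u}, {v}) creates cycle {cycle}")

    # -- serialization ------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def to_edge_list(self, path: str | Path) -> None:
        Path(path).write_text(
            "\n".join(f"{u}\t{v}" for u, v in self.arcs) + ("\n" if self.arcs else ""))

    @classmethod
    def from_edge_list(cls, path: str | Path, nodes: Iterable[str]) -> "Dag":
        arcs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line:
                u, v = line.split("\t")
                arcs.append((u, v))
        return cls(nodes, arcs)

    def to_dot(self, highlight: Iterable[str] = ()) -> str:
        hi = set(highlight)
        lines = ["digraph bn {", "  rankdir=LR;"]
        for n in self.nodes:
            style = ' [style=filled, fillcolor=orange]' if n in hi else ""
            lines.append(f'  "{n}"{style};')
        for u, v in self.arcs:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Constraints and curated edits
# --------------------------------------------------------------------------

@dataclass
class ArcConstraintSet:
    """Forbidden (blacklist) and required (whitelist) directed arcs."""

    blacklist: set[Arc] = field(default_factory=set)
    whitelist: set[Arc] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise ValueError(f"arcs both required and forbidden: {sorted(overlap)}")
        nodes = {n for a in self.whitelist for n in a}
        if self.whitelist:
            Dag(sorted(nodes), sorted(self.whitelist))  # raises if whitelist cyclic

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.blacklist

    def requires(self, u: str, v: str) -> bool:
        return (u, v) in self.whitelist


def tier_blacklist(dictionary: Sequence[VariableSpec],
                   whitelist: Iterable[Arc] = ()) -> ArcConstraintSet:
    """Temporal-ordering blacklist.

    Nothing may point into a background variable (sex, age), and no arc may
    run from a later tier to a strictly earlier one — in particular the
    outcome cannot point at any baseline variable.
    """
    tiers = {v.name: v.tier for v in dictionary}
    background = {v.name for v in dictionary if v.role == ROLE_BACKGROUND}
    bl: set[Arc] = set()
    for u in tiers:
        for v in tiers:
            if u == v:
                continue
            if v in background or tiers[u] > tiers[v]:
                bl.add((u, v))
    return ArcConstraintSet(blacklist=bl - set(whitelist), whitelist=set(whitelist))


#: Prior-knowledge arcs required in the diabetes network search
#: (family history of diabetes raises IFG risk; drinking affects HDL-C;
#: central adiposity raises blood pressure; smoking affects BMI).
GBCS_WHITELIST: tuple[Arc, ...] = (
    ("family_history", "ifg"),
    ("drinking", "hdl"),
    ("wc", "hypertension"),
    ("smoking", "bmi"),
)


def gbcs_constraints(dictionary: Sequence[VariableSpec]) -> ArcConstraintSet:
    """Packaged constraint set: tier blacklist plus the prior-knowledge whitelist."""
    return tier_blacklist(dictionary, whitelist=GBCS_WHITELIST)


@dataclass
class CuratedEditList:
    """Post-hoc expert edits: arc removals and orientation reversals."""

    removals: list[Arc] = field(default_factory=list)
    reversals: list[Arc] = field(default_factory=list)


#: The packaged expert edit list: six substantively illogical arcs removed
#: and the lipid-drug arc re-oriented so that raised triglycerides lead to
#: lipid-lowering treatment rather than the reverse.
GBCS_EDITS = CuratedEditList(
    removals=[
        ("age", "family_history"),
        ("wc", "education"),
        ("education", "family_history"),
        ("ifg", "physical_activity"),
        ("diabetes", "tg"),
        ("drinking", "ldl"),
    ],
    reversals=[("lipid_lowering_drugs", "tg")],
)


def apply_curated_edits(dag: Dag, edits: CuratedEditList) -> Dag:
    """Apply expert removals/reversals; warns on absent arcs, errors on cycles."""
    out = dag.copy()
    nodes = set(out.nodes)
    for u, v in edits.removals:
        if u not in nodes or v not in nodes:
            logger.warning("curated removal %s -> %s: node not in graph, skipped", u, v)
        elif out.has_arc(u, v):
            logger.info("curated edit: removing arc %s -> %s", u, v)
            out.remove_arc(u, v)
        else:
            logger.warning("curated removal %s -> %s: arc not present, skipped", u, v)
    for u, v in edits.reversals:
        if u not in nodes or v not in nodes:
            logger.warning("curated reversal %s -> %s: node not in graph, skipped", u, v)
        elif out.has_arc(u, v):
            logger.info("curated edit: reversing arc %s -> %s", u, v)
            out.reverse_arc(u, v)
        elif out.has_arc(v, u):
            logger.info("curated reversal %s -> %s: already oriented %s -> %s", u, v, v, u)
        else:
            logger.warning("curated reversal %s -> %s: arc not present, skipped", u, v)
    return out


# --------------------------------------------------------------------------
# Decomposable scores
# --------------------------------------------------------------------------

def _family_counts(X: np.ndarray, card: np.ndarray, child: int,
                   parents: tuple[int, ...]) -> np.ndarray:
    """(q, r) count matrix for one family on complete integer-coded data."""
    r = int(card[child])
    idx = X[:, child].astype(np.int64)
    stride = r
    for p in parents:
        idx = idx + X[:, p].astype(np.int64) * stride
        stride *= int(card[p])
    return np.bincount(idx, minlength=stride).reshape(-1, r)


def _bic_family(counts: np.ndarray, n: int) -> float:
    nij = counts.sum(axis=1, keepdims=True)
    nz = counts > 0
    ll = float(np.sum(counts[nz] * np.log(counts[nz] / np.broadcast_to(nij, counts.shape)[nz])))
    q, r = counts.shape
    return ll - 0.5 * math.log(n) * q * (r - 1)


def _bdeu_family(counts: np.ndarray, iss: float) -> float:
    q, r = counts.shape
    a_ij = iss / q
    a_ijk = iss / (q * r)
    nij = counts.sum(axis=1)
    return float(np.sum(gammaln(a_ij) - gammaln(a_ij + nij))
                 + np.sum(gammaln(a_ijk + counts) - gammaln(a_ijk)))


class _Scorer:
    """Cached per-family scorer over an integer-coded complete data matrix."""

    def __init__(self, X: np.ndarray, card: np.ndarray, score: str = "bic",
                 iss: float = 1.0):
        if X.shape[0] == 0:
            raise ValueError("cannot score a zero-row dataset")
        if (X < 0).any():
            raise ValueError("scoring requires complete data (missing codes found)")
        self.X = X
        self.card = card
        self.n = X.shape[0]
        self.score_name = score
        self.iss = iss
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(self, child: int, parents: frozenset | tuple) -> float:
        key = (child, tuple(sorted(parents)))
        got = self._cache.get(key)
        if got is not None:
            return got
        counts = _family_counts(self.X, self.card, child, key[1])
        if self.score_name == "bic":
            val = _bic_family(counts, self.n)
        elif self.score_name == "bdeu":
            val = _bdeu_family(counts, self.iss)
        else:
            raise ValueError(f"unknown score {self.score_name!r}")
        self._cache[key] = val
        return val


def score(dag: Dag, data: CohortTable, score_name: str = "bic",
          iss: float = 1.0) -> float:
    """Decomposable network score (sum of family scores); higher is better."""
    cols = list(dag.nodes)
    scorer = _Scorer(data.codes(cols), data.cardinalities(cols), score_name, iss)
    pos = {n: i for i, n in enumerate(cols)}
    return sum(scorer.family(pos[v], tuple(pos[p] for p in dag.parents(v)))
               for v in dag.nodes)


# --------------------------------------------------------------------------
# Hill climbing
# --------------------------------------------------------------------------

_EPS = 1e-9


def _hill_climb_codes(X: np.ndarray, card: np.ndarray, names: Sequence[str],
                      constraints: ArcConstraintSet | None,
                      score_name: str = "bic", iss: float = 1.0,
                      max_parents: int | None = None,
                      max_iter: int = 10_000) -> Dag:
    names = list(names)
    p = len(names)
    pos = {n: i for i, n in enumerate(names)}
    constraints = constraints or ArcConstraintSet()
    scorer = _Scorer(X, card, score_name, iss)

    dag = Dag(names, sorted(constraints.whitelist))
    parents: list[set[int]] = [set(pos[q] for q in dag.parents(n)) for n in names]
    fam = [scorer.family(v, tuple(parents[v])) for v in range(p)]

    black = {(pos[u], pos[v]) for u, v in constraints.blacklist if u in pos and v in pos}
    white = {(pos[u], pos[v]) for u, v in constraints.whitelist}

    for _ in range(max_iter):
        # descendants via DFS per node, for O(1) cycle checks on adds
        desc: list[set[int]] = []
        children = [set() for _ in range(p)]
        for v in range(p):
            for u in parents[v]:
                children[u].add(v)
        for s in range(p):
            seen: set[int] = set()
            stack = [s]
            while stack:
                u = stack.pop()
                for w in children[u]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            desc.append(seen)

        best = None  # (delta, type_rank, u_name, v_name, apply)
        for u in range(p):
            for v in range(p):
                if u == v:
                    continue
                if u in parents[v]:
                    continue
                if (u, v) in black:
                    continue
                if u in desc[v]:
                    continue  # cycle
                if max_parents is not None and len(parents[v]) >= max_parents:
                    continue
                delta = scorer.family(v, tuple(parents[v] | {u})) - fam[v]
                cand = (delta, 0, names[u], names[v], ("add", u, v))
                if best is None or _better(cand, best):
                    best = cand
        for v in range(p):
            for u in sorted(parents[v]):
                if (u, v) not in white:
                    delta = scorer.family(v, tuple(parents[v] - {u})) - fam[v]
                    cand = (delta, 1, names[u], names[v], ("del", u, v))
                    if best is None or _better(cand, best):
                        best = cand
                # reversal u->v  =>  v->u
                if (u, v) in white or (v, u) in black:
                    continue
                if max_parents is not None and len(parents[u]) >= max_parents:
                    continue
                # reversal adds v -> u: cycle iff u still reaches v
                # via a path avoiding the direct arc (u, v)
                if _reaches(children, u, v, skip=(u, v)):
                    continue
                delta = (scorer.family(v, tuple(parents[v] - {u})) - fam[v]
                         + scorer.family(u, tuple(parents[u] | {v})) - fam[u])
                cand = (delta, 2, names[u], names[v], ("rev", u, v))
                if best is None or _better(cand, best):
                    best = cand

        if best is None or best[0] <= _EPS:
            break
        op, u, v = best[4]
        if op == "add":
            parents[v].add(u)
            fam[v] = scorer.family(v, tuple(parents[v]))
        elif op == "del":
            parents[v].discard(u)
            fam[v] = scorer.family(v, tuple(parents[v]))
        else:
            parents[v].discard(u)
            parents[u].add(v)
            fam[v] = scorer.family(v, tuple(parents[v]))
            fam[u] = scorer.family(u, tuple(parents[u]))

    return Dag(names, [(names[u], names[v]) for v in range(p) for u in parents[v]])


def _better(cand, best) -> bool:
    # higher delta wins; ties by move type then lexicographic (parent, child)
    return (cand[0] > best[0] + _EPS
            or (abs(cand[0] - best[0]) <= _EPS and cand[1:4] < best[1:4]))


def _reaches(children: list[set[int]], start: int, target: int,
             skip: tuple[int, int]) -> bool:
    seen, stack = set(), [start]
    while stack:
        u = stack.pop()
        for w in children[u]:
            if (u, w) == skip:
                continue
            if w == target:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def hill_climb(data: CohortTable, constraints: ArcConstraintSet | None = None,
               seed: int = 0, score_name: str = "bic", iss: float = 1.0,
               max_parents: int | None = None) -> Dag:
    """Greedy add/delete/reverse search from the whitelist-only graph.

    Requires complete data.  Deterministic: candidate moves are scored by
    their cached family-score delta and ties broken lexicographically, so
    ``seed`` is accepted for interface symmetry but unused.
    """
    del seed
    cols = data.variable_names
    X = data.codes(cols)
    if (X < 0).any():
        raise ValueError("hill_climb requires complete data; use structural_em")
    return _hill_climb_codes(X, data.cardinalities(cols), cols, constraints,
                             score_name, iss, max_parents)


# --------------------------------------------------------------------------
# Structural EM
# --------------------------------------------------------------------------

@dataclass
class SemResult:
    dag: Dag
    completed: CohortTable
    converged: bool
    n_iter: int
    score: float


def _fit_cpt_arrays(X: np.ndarray, card: np.ndarray,
                    parents: list[tuple[int, ...]], alpha: float = 1.0
                    ) -> list[np.ndarray]:
    """Dirichlet-smoothed CPTs as (q, r) arrays, parent strides little-endian
    in the given parent order (first parent fastest)."""
    cpts = []
    for v, pa in enumerate(parents):
        counts = _family_counts(X, card, v, pa).astype(float)
        cpts.append((counts + alpha) / (counts.sum(axis=1, keepdims=True)
                                        + alpha * card[v]))
    return cpts


def _config_index(X: np.ndarray, card: np.ndarray, pa: tuple[int, ...],
                  rows: np.ndarray) -> np.ndarray:
    idx = np.zeros(len(rows), dtype=np.int64)
    stride = 1
    for p in pa:
        idx += X[rows, p].astype(np.int64) * stride
        stride *= int(card[p])
    return idx


def structural_em(data: CohortTable, constraints: ArcConstraintSet | None = None,
                  seed: int = 0, max_iter: int = 20, tol: float = 1e-4,
                  score_name: str = "bic", iss: float = 1.0, alpha: float = 1.0,
                  max_parents: int | None = None,
                  em_mode: str = "sample") -> SemResult:
    """Structural EM: alternate imputation and structure search.

    E-step fills each originally-missing cell from its full conditional
    given the row's current other values (posterior sampling by default;
    ``em_mode="map"`` takes the posterior mode instead).  M-step re-runs
    the constrained hill climb on the completed data.  Stops when the
    relative change in network score drops below ``tol``.
    """
    if em_mode not in ("sample", "map"):
        raise ValueError("em_mode must be 'sample' or 'map'")
    cols = data.variable_names
    X = data.codes(cols).copy()
    card = data.cardinalities(cols)
    mask = X < 0
    rng = np.random.default_rng(seed)

    # initial completion from observed per-column marginals
    for j in range(X.shape[1]):
        rows = np.flatnonzero(mask[:, j])
        if len(rows) == 0:
            continue
        obs = X[~mask[:, j], j]
        freq = np.bincount(obs, minlength=card[j]).astype(float)
        if freq.sum() == 0:
            freq[:] = 1.0
        freq /= freq.sum()
        X[rows, j] = rng.choice(card[j], size=len(rows), p=freq)

    prev_score = -np.inf
    converged = False
    dag = Dag(cols)
    total = 0.0
    pos = {n: i for i, n in enumerate(cols)}
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        dag = _hill_climb_codes(X, card, cols, constraints, score_name, iss, max_parents)
        parents = [tuple(pos[q] for q in dag.parents(n)) for n in cols]
        scorer = _Scorer(X, card, score_name, iss)
        total = sum(scorer.family(v, parents[v]) for v in range(len(cols)))
        if np.isfinite(prev_score) and abs(total - prev_score) <= tol * abs(prev_score):
            converged = True
            break
        prev_score = total
        if not mask.any():
            converged = True
            break
        # E-step on the fitted model
        cpts = _fit_cpt_arrays(X, card, parents, alpha)
        children = {v: [] for v in range(len(cols))}
        for v, pa in enumerate(parents):
            for u in pa:
                children[u].append(v)
        for v in range(len(cols)):
            rows = np.flatnonzero(mask[:, v])
            if len(rows) == 0:
                continue
            r = int(card[v])
            logp = np.zeros((len(rows), r))
            pa_v = parents[v]
            for x in range(r):
                X[rows, v] = x
                cfg = _config_index(X, card, pa_v, rows)
                logp[:, x] = np.log(cpts[v][cfg, x])
                for c in children[v]:
                    cfg_c = _config_index(X, card, parents[c], rows)
                    logp[:, x] += np.log(cpts[c][cfg_c, X[rows, c]])
            prob = np.exp(logp - logp.max(axis=1, keepdims=True))
            prob /= prob.sum(axis=1, keepdims=True)
            if em_mode == "map":
                X[rows, v] = prob.argmax(axis=1)
            else:
                u = rng.random(len(rows))
                X[rows, v] = (u[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)
    else:
        logger.warning("structural EM did not converge in %d iterations", max_iter)

    completed = pd.DataFrame(
        {n: np.asarray(data.spec(n).categories, dtype=object)[X[:, j]]
         for j, n in enumerate(cols)})
    return SemResult(dag, CohortTable(completed, data.variables, data.flags),
                     converged, n_iter, total)


# --------------------------------------------------------------------------
# Bootstrap model averaging
# --------------------------------------------------------------------------

@dataclass
class ArcStrengthTable:
    """Per-directed-arc bootstrap frequencies over ``B`` learned networks."""

    table: pd.DataFrame  # columns: from, to, strength
    B: int

    def strength(self, u: str, v: str) -> float:
        hit = self.table[(self.table["from"] == u) & (self.table["to"] == v)]
        return float(hit["strength"].iloc[0]) if len(hit) else 0.0

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, B: int | None = None) -> "ArcStrengthTable":
        df = pd.read_csv(path)
        return cls(df, B if B is not None else -1)


def average_arcs(nodes: Sequence[str], dags: Sequence[Dag],
                 threshold: float = 0.6) -> tuple[Dag, ArcStrengthTable]:
    """Average a collection of bootstrap DAGs into a consensus structure.

    Keeps arcs with frequency strictly above ``threshold``; when both
    orientations pass, the more frequent wins and exact ties drop the edge.
    Any residual cycle is broken by discarding the weakest arc in it.
    """
    B = len(dags)
    freq: dict[Arc, int] = {}
    for d in dags:
        for a in d.arcs:
            freq[a] = freq.get(a, 0) + 1
    strengths = {a: c / B for a, c in freq.items()}
    table = pd.DataFrame(
        [(u, v, s) for (u, v), s in sorted(strengths.items())],
        columns=["from", "to", "strength"])

    kept = {a for a, s in strengths.items() if s > threshold}
    for u, v in sorted(kept):
        if (v, u) in kept:
            su, sv = strengths[(u, v)], strengths[(v, u)]
            if su < sv or (su == sv):
                kept.discard((u, v))
            if sv < su or (su == sv):
                kept.discard((v, u))
            if su == sv:
                logger.warning("direction tie %s - %s: edge dropped", u, v)

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(sorted(kept))
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (strengths[(e[0], e[1])], e))
        logger.warning("averaged graph cyclic; dropping weakest arc %s -> %s",
                       weakest[0], weakest[1])
        g.remove_edge(*weakest[:2])
        kept.discard((weakest[0], weakest[1]))
    return Dag(nodes, sorted(kept)), ArcStrengthTable(table, B)


def bootstrap_average(data: CohortTable, constraints: ArcConstraintSet | None = None,
                      B: int = 200, threshold: float = 0.6, seed: int = 0,
                      score_name: str = "bic", iss: float = 1.0,
                      max_parents: int | None = None,
                      em_mode: str = "sample") -> tuple[Dag, ArcStrengthTable]:
    """Nonparametric-bootstrap arc-strength model averaging.

    Draws ``B`` resamples of size n with replacement, learns one DAG per
    resample (structural EM when the data contain missing cells, plain hill
    climbing otherwise) and retains arcs whose frequency exceeds
    ``threshold`` (default: more than 60% of 200 resamples).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    cols = data.variable_names
    X = data.codes(cols)
    card = data.cardinalities(cols)
    n = X.shape[0]
    missing = bool((X < 0).any())
    rng = np.random.default_rng(seed)
    dags: list[Dag] = []
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        if missing:
            sub = data.iloc_rows(idx)
            res = structural_em(sub, constraints, seed=int(rng.integers(2**31)),
                                score_name=score_name, iss=iss,
                                max_parents=max_parents, em_mode=em_mode)
            dags.append(res.dag)
        else:
            dags.append(_hill_climb_codes(Xb, card, cols, constraints,
                                          score_name, iss, max_parents))
    return average_arcs(cols, dags, threshold)
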