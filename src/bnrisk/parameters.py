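"""Bayesian parameter learning and exact inference for discrete networks.

Given a DAG and a categorical cohort, CPTs are estimated as Dirichlet
posterior means (Laplace ``alpha=1`` by default, so every entry is strictly
positive and exact inference never divides by zero).  Posteriors are
computed by variable elimination with a greedy min-degree ordering; for the
network sizes this package targets (tens of nodes, two to four categories
each) this is exact and fast.

Also here: Markov blankets, the post-test probability table used for risk
stratification (one row per configuration of the outcome's Markov-blanket
variables, with bootstrap or cross-validation confidence intervals), and
monotone arc-sign annotation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec
from .structure import Dag

logger = logging.getLogger(__name__)


class ZeroProbabilityEvidence(ValueError):
    """Raised when conditioning on evidence the model assigns probability 0."""


# --------------------------------------------------------------------------
# CPTs and the model container
# --------------------------------------------------------------------------

@dataclass
class Cpt:
    """Conditional probability table of one node.

    ``table`` and ``counts`` are (q, r) arrays: one row per parent
    configuration, one column per child category.  The flat configuration
    index is little-endian in ``parents`` (the first listed parent varies
    fastest).
    """

    node: str
    parents: tuple[str, ...]
    categories: tuple[str, ...]
    parent_categories: tuple[tuple[str, ...], ...]
    table: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        q = int(np.prod([len(c) for c in self.parent_categories])) if self.parents else 1
        if self.table.shape != (q, len(self.categories)):
            raise ValueError(f"CPT for {self.node!r}: table shape {self.table.shape} "
                             f"!= ({q}, {len(self.categories)})")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT for {self.node!r}: rows do not sum to 1")

    def config_index(self, parent_codes: Sequence[int]) -> int:
        idx, stride = 0, 1
        for code, cats in zip(parent_codes, self.parent_categories):
            idx += code * stride
            stride *= len(cats)
        return idx

    def row(self, assignment: Mapping[str, str]) -> np.ndarray:
        """Probability vector of the node given a parent assignment (labels)."""
        codes = [self.parent_categories[i].index(assignment[p])
                 for i, p in enumerate(self.parents)]
        return self.table[self.config_index(codes)]

    def prob(self, child_label: str, assignment: Mapping[str, str]) -> float:
        return float(self.row(assignment)[self.categories.index(child_label)])

    def as_array(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Factor form: (vars, array) with one axis per parent then the child."""
        shape = tuple(len(c) for c in reversed(self.parent_categories)) + (len(self.categories),)
        return tuple(reversed(self.parents)) + (self.node,), self.table.reshape(shape)


@dataclass
class BayesianNetworkModel:
    """A fitted discrete Bayesian network: DAG plus one CPT per node."""

    dag: Dag
    cpts: dict[str, Cpt]
    alpha: float = 1.0
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for node {node!r}")
            if tuple(self.cpts[node].parents) != tuple(self.dag.parents(node)):
                raise ValueError(f"CPT parents for {node!r} disagree with the DAG")
        if not self.categories:
            self.categories = {n: self.cpts[n].categories for n in self.dag.nodes}

    # -- serialization ------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "nodes": list(self.dag.nodes),
            "arcs": [list(a) for a in self.dag.arcs],
            "alpha": self.alpha,
            "cpts": {
                n: {"parents": list(c.parents),
                    "categories": list(c.categories),
                    "parent_categories": [list(pc) for pc in c.parent_categories],
                    "table": c.table.tolist(),
                    "counts": c.counts.tolist()}
                for n, c in self.cpts.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BayesianNetworkModel":
        dag = Dag(obj["nodes"], [tuple(a) for a in obj["arcs"]])
        cpts = {n: Cpt(n, tuple(e["parents"]), tuple(e["categories"]),
                       tuple(tuple(pc) for pc in e["parent_categories"]),
                       np.asarray(e["table"], dtype=float),
                       np.asarray(e["counts"], dtype=float))
                for n, e in obj["cpts"].items()}
        return cls(dag, cpts, obj.get("alpha", 1.0))

    def cpts_long(self) -> pd.DataFrame:
        """All CPTs in long format (node, parent config, category, probability, count)."""
        rows = []
        for n, c in self.cpts.items():
            for qi, cfg in enumerate(itertools.product(*[range(len(pc)) for pc in
                                                         reversed(c.parent_categories)])):
                cfg = tuple(reversed(cfg))
                labels = {p: c.parent_categories[i][cfg[i]] for i, p in enumerate(c.parents)}
                flat = c.config_index(cfg)
                for k, cat in enumerate(c.categories):
                    rows.append({"node": n, "parents": ";".join(f"{p}={labels[p]}" for p in c.parents),
                                 "category": cat, "probability": c.table[flat, k],
                                 "count": c.counts[flat, k]})
        return pd.DataFrame(rows)


def fit_parameters(dag: Dag, data: CohortTable, prior_pseudocount: float = 1.0) -> BayesianNetworkModel:
    """Bayesian CPT estimation: posterior-mean with a symmetric Dirichlet prior.

    Each entry is ``(count + alpha) / (config total + alpha * r)``.  Families
    are counted over rows fully observed for that family (available-case),
    which is unbiased under MCAR missingness; pass the completed dataset
    from structural EM for full fidelity to the pipeline.
    """
    alpha = float(prior_pseudocount)
    for node in dag.nodes:
        if node not in data.variable_names:
            raise ValueError(f"DAG node {node!r} absent from data")
    cpts: dict[str, Cpt] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        fam = [*parents, node]
        X = data.codes(fam)
        ok = (X >= 0).all(axis=1)
        X = X[ok]
        cards = data.cardinalities(fam)
        r = int(cards[-1])
        q = int(np.prod(cards[:-1])) if parents else 1
        idx = np.zeros(len(X), dtype=np.int64)
        stride = 1
        for j in range(len(parents)):
            idx += X[:, j].astype(np.int64) * stride
            stride *= int(cards[j])
        counts = np.bincount(idx * r + X[:, -1], minlength=q * r).reshape(q, r).astype(float)
        table = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * r)
        if alpha == 0.0:
            empty = counts.sum(axis=1) == 0
            table[empty] = 1.0 / r  # undefined config: fall back to uniform
        cpts[node] = Cpt(node, parents, tuple(data.spec(node).categories),
                         tuple(tuple(data.spec(p).categories) for p in parents),
                         table, counts)
    return BayesianNetworkModel(dag, cpts, alpha)


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------

def joint_probability(model: BayesianNetworkModel, assignment: Mapping[str, str]) -> float:
    """P(full assignment) by the factorization over node families."""
    missing = set(model.dag.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment lacks nodes {sorted(missing)}")
    p = 1.0
    for node in model.dag.nodes:
        cpt = model.cpts[node]
        p *= cpt.prob(assignment[node], assignment)
    return p


def markov_blanket(dag: Dag, node: str) -> set[str]:
    """Parents, children and children's other parents of ``node``."""
    if node not in dag.nodes:
        raise KeyError(node)
    mb = set(dag.parents(node)) | set(dag.children(node))
    for child in dag.children(node):
        mb |= set(dag.parents(child))
    mb.discard(node)
    return mb


def _evidence_codes(model: BayesianNetworkModel, evidence: Mapping[str, str]) -> dict[str, int]:
    out = {}
    for var, label in evidence.items():
        cats = model.categories[var]
        if label not in cats:
            raise ValueError(f"unknown category {label!r} for {var!r}")
        out[var] = cats.index(label)
    return out


def posterior(model: BayesianNetworkModel, target: str,
              evidence: Mapping[str, str] | None = None) -> np.ndarray:
    """Exact P(target | evidence) by variable elimination.

    Returns a probability vector over the target's categories; raises
    :class:`ZeroProbabilityEvidence` when the evidence has probability 0.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError("target cannot also be evidence")
    ev = _evidence_codes(model, evidence)

    # fast path: sink node with all parents observed -> CPT row
    cpt = model.cpts[target]
    if (not model.dag.children(target)
            and all(p in ev for p in cpt.parents)
            and set(ev) >= set(cpt.parents)):
        extra = set(ev) - set(cpt.parents)
        if not extra:
            row = cpt.table[cpt.config_index([ev[p] for p in cpt.parents])]
            return row.copy()

    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for node in model.dag.nodes:
        fvars, arr = model.cpts[node].as_array()
        keep_vars = []
        for ax, var in enumerate(fvars):
            if var in ev:
                arr = np.take(arr, ev[var], axis=len(keep_vars))
            else:
                keep_vars.append(var)
        factors.append((tuple(keep_vars), arr))

    to_eliminate = set(model.dag.nodes) - set(ev) - {target}
    while to_eliminate:
        # min-degree: eliminate the variable appearing with fewest neighbours
        neigh: dict[str, set[str]] = {v: set() for v in to_eliminate}
        for fvars, _ in factors:
            for v in fvars:
                if v in neigh:
                    neigh[v] |= set(fvars) - {v}
        var = min(to_eliminate, key=lambda v: (len(neigh[v]), v))
        group = [f for f in factors if var in f[0]]
        factors = [f for f in factors if var not in f[0]]
        prod_vars, prod = _product(group)
        ax = prod_vars.index(var)
        summed = prod.sum(axis=ax)
        factors.append((prod_vars[:ax] + prod_vars[ax + 1:], summed))
        to_eliminate.discard(var)

    fvars, arr = _product(factors)
    if fvars == ():
        raise ZeroProbabilityEvidence("all query variables observed")
    ax_order = [fvars.index(target)]
    arr = np.transpose(arr, ax_order) if arr.ndim == 1 else np.transpose(arr, ax_order)
    total = arr.sum()
    if total <= 0.0:
        raise ZeroProbabilityEvidence(f"evidence {evidence} has probability 0")
    return arr / total


def _product(factors: list[tuple[tuple[str, ...], np.ndarray]]
             ) -> tuple[tuple[str, ...], np.ndarray]:
    """Multiply labelled factors by broadcasting over the union of variables."""
    all_vars: list[str] = []
    for fvars, _ in factors:
        for v in fvars:
            if v not in all_vars:
                all_vars.append(v)
    out = np.array(1.0)
    for fvars, arr in factors:
        # expand arr to the full variable set
        perm_src = list(fvars)
        shape = [1] * len(all_vars)
        order = sorted(range(len(perm_src)), key=lambda i: all_vars.index(perm_src[i]))
        arr_t = np.transpose(arr, order)
        dims = [all_vars.index(perm_src[i]) for i in order]
        for pos, d in enumerate(dims):
            shape[d] = arr_t.shape[pos]
        out = out * arr_t.reshape(shape)
    return tuple(all_vars), out


def joint_marginal(model: BayesianNetworkModel, variables: Sequence[str]) -> np.ndarray:
    """Exact joint marginal over ``variables`` (axes in the given order)."""
    variables = list(variables)
    factors = [model.cpts[n].as_array() for n in model.dag.nodes]
    to_eliminate = set(model.dag.nodes) - set(variables)
    while to_eliminate:
        neigh: dict[str, set[str]] = {v: set() for v in to_eliminate}
        for fvars, _ in factors:
            for v in fvars:
                if v in neigh:
                    neigh[v] |= set(fvars) - {v}
        var = min(to_eliminate, key=lambda v: (len(neigh[v]), v))
        group = [f for f in factors if var in f[0]]
        factors = [f for f in factors if var not in f[0]]
        prod_vars, prod = _product(group)
        ax = prod_vars.index(var)
        factors.append((prod_vars[:ax] + prod_vars[ax + 1:], prod.sum(axis=ax)))
        to_eliminate.discard(var)
    fvars, arr = _product(factors)
    arr = np.transpose(arr, [fvars.index(v) for v in variables])
    return arr / arr.sum()


def posterior_brute_force(model: BayesianNetworkModel, target: str,
                          evidence: Mapping[str, str] | None = None) -> np.ndarray:
    """Enumeration over the full joint; test oracle for :func:`posterior`.

    Only sensible for networks with a small joint state space.
    """
    evidence = dict(evidence or {})
    cats = model.categories
    nodes = list(model.dag.nodes)
    out = np.zeros(len(cats[target]))
    free = [n for n in nodes if n not in evidence]
    for combo in itertools.product(*[cats[n] for n in free]):
        assignment = dict(zip(free, combo)) | evidence
        out[cats[target].index(assignment[target])] += joint_probability(model, assignment)
    total = out.sum()
    if total <= 0.0:
        raise ZeroProbabilityEvidence(f"evidence {evidence} has probability 0")
    return out / total


# --------------------------------------------------------------------------
# Post-test probability table
# --------------------------------------------------------------------------

@dataclass
class PosttestTable:
    """Post-test risk table over Markov-blanket configurations of a target."""

    target: str
    blanket: tuple[str, ...]
    table: pd.DataFrame  # columns: blanket vars..., probability, ci_low, ci_high
    ci_method: str

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, **config: str) -> float:
        sel = np.ones(len(self.table), dtype=bool)
        for var, label in config.items():
            sel &= self.table[var] == label
        return float(self.table.loc[sel, "probability"].iloc[0])


def posttest_table(model: BayesianNetworkModel, data: CohortTable | None,
                   target: str, ci_method: str = "bootstrap",
                   n_boot: int = 200, seed: int = 0,
                   positive_category: str | None = None) -> PosttestTable:
    """Post-test probability of the target's top category per blanket configuration.

    One row per configuration of the target's Markov-blanket variables;
    the point estimate is the exact posterior under ``model``.  Confidence
    intervals: ``bootstrap`` refits parameters on resampled cohorts with the
    structure fixed (percentile 2.5/97.5), ``cv`` reports the min-max across
    5 cross-validation training folds, ``none`` skips them.
    """
    mb = tuple(sorted(markov_blanket(model.dag, target)))
    if not mb:
        raise ValueError(f"target {target!r} has an empty Markov blanket")
    cats = model.categories
    positive = positive_category or cats[target][-1]
    pos_idx = cats[target].index(positive)

    configs = list(itertools.product(*[cats[v] for v in mb]))
    points = [float(posterior(model, target, dict(zip(mb, cfg)))[pos_idx])
              for cfg in configs]

    lows: list[float] = [np.nan] * len(configs)
    highs: list[float] = [np.nan] * len(configs)
    if ci_method == "bootstrap":
        if data is None:
            raise ValueError("bootstrap CIs require the cohort data")
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, len(configs)))
        n = data.n
        # flat family indices precomputed once; each replicate is then just
        # one bincount per family (rows missing a family member drop out)
        fams = []
        for node in model.dag.nodes:
            parents = model.dag.parents(node)
            famcols = [*parents, node]
            X = data.codes(famcols)
            cards = data.cardinalities(famcols)
            r = int(cards[-1])
            q = int(np.prod(cards[:-1])) if parents else 1
            flat = np.full(n, -1, dtype=np.int64)
            ok = (X >= 0).all(axis=1)
            idx = np.zeros(int(ok.sum()), dtype=np.int64)
            stride = 1
            for j in range(len(parents)):
                idx += X[ok, j].astype(np.int64) * stride
                stride *= int(cards[j])
            flat[ok] = idx * r + X[ok, -1]
            fams.append((node, flat, q, r))
        alpha = model.alpha
        for bi in range(n_boot):
            rows = rng.integers(0, n, size=n)
            cpts_b = {}
            for node, flat, q, r in fams:
                sel = flat[rows]
                counts = np.bincount(sel[sel >= 0], minlength=q * r)
                counts = counts.reshape(q, r).astype(float)
                table = (counts + alpha) / (counts.sum(axis=1, keepdims=True)
                                            + alpha * r)
                if alpha == 0.0:
                    table[counts.sum(axis=1) == 0] = 1.0 / r
                base = model.cpts[node]
                cpts_b[node] = Cpt(node, base.parents, base.categories,
                                   base.parent_categories, table, counts)
            m_b = BayesianNetworkModel(model.dag, cpts_b, alpha)
            reps[bi] = [float(posterior(m_b, target, dict(zip(mb, cfg)))[pos_idx])
                        for cfg in configs]
        lows = np.percentile(reps, 2.5, axis=0).tolist()
        highs = np.percentile(reps, 97.5, axis=0).tolist()
    elif ci_method == "cv":
        if data is None:
            raise ValueError("cv CIs require the cohort data")
        from sklearn.model_selection import KFold
        reps = []
        for train, _ in KFold(5, shuffle=True, random_state=seed).split(np.arange(data.n)):
            m_f = fit_parameters(model.dag, data.iloc_rows(train), model.alpha)
            reps.append([float(posterior(m_f, target, dict(zip(mb, cfg)))[pos_idx])
                         for cfg in configs])
        reps = np.asarray(reps)
        lows = reps.min(axis=0).tolist()
        highs = reps.max(axis=0).tolist()
    elif ci_method != "none":
        raise ValueError(f"unknown ci_method {ci_method!r}")

    rows = []
    for cfg, pt, lo, hi in zip(configs, points, lows, highs):
        row = dict(zip(mb, cfg))
        row.update(probability=pt, ci_low=lo, ci_high=hi)
        rows.append(row)
    return PosttestTable(target, mb, pd.DataFrame(rows), ci_method)


# --------------------------------------------------------------------------
# Arc signs
# --------------------------------------------------------------------------

def arc_sign(model: BayesianNetworkModel, arc: tuple[str, str],
             tol: float = 1e-12) -> str:
    """Classify an arc as positive, negative or non-monotone.

    Computes P(child in its top category | parent level) with the child's
    other parents averaged at their model marginals, then checks strict
    monotonicity across the ordered parent levels.
    """
    u, v = arc
    if not model.dag.has_arc(u, v):
        raise ValueError(f"arc {arc} not in model")
    cpt = model.cpts[v]
    others = [p for p in cpt.parents if p != u]
    marginals = {p: posterior(model, p) for p in others}
    top = len(cpt.categories) - 1
    curve = []
    for lev in range(len(model.categories[u])):
        total = 0.0
        for combo in itertools.product(*[range(len(model.categories[p])) for p in others]):
            w = 1.0
            codes = {}
            for p, c in zip(others, combo):
                w *= float(marginals[p][c])
                codes[p] = c
            codes[u] = lev
            idx = cpt.config_index([codes[p] for p in cpt.parents])
            total += w * float(cpt.table[idx, top])
        curve.append(total)
    diffs = np.diff(curve)
    if np.all(diffs > tol):
        return "positive"
    if np.all(diffs < -tol):
        return "negative"
    return "non-monotone"
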