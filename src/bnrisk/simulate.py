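"""Synthetic cohort generation by ancestral sampling from a DAG + CPT fixture.

The cohort behind the published diabetes network was never deposited, so
this module provides a stated stand-in: a generator whose DAG follows the
published network (expert edits already applied), whose per-node marginal
category frequencies are calibrated to the published baseline table, and
whose outcome CPT equals the published post-test probability table exactly
(new-onset diabetes given hypertension, impaired fasting glucose and raised
waist circumference).

Only marginals, the outcome CPT and qualitative arc signs are published;
every intermediate CPT is therefore built by a documented heuristic —
cumulative-logit (proportional-odds) response curves with monotone shifts
matching the printed arc signs (plus the two explicitly non-monotone
smoking->BMI and BMI->WHR effects), with thresholds solved by 1-D root
finding against the exact parent joint so each node's marginal hits its
published value.  Missingness is MCAR at per-variable rates chosen to
reproduce the published per-variable totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (GBCS_COUNTS, N_BASELINE_DIABETES, N_COHORT, N_INCOMPLETE,
                     N_RETURNED, OUTCOME, CohortTable, VariableSpec,
                     build_variable_dictionary)
from .parameters import BayesianNetworkModel, Cpt, joint_marginal
from .structure import Dag

# ---------------------------------------------------------------------------
# Fixture container
# ---------------------------------------------------------------------------


@dataclass
class GeneratorFixture:
    """A fully specified sampling model: DAG + CPTs + cohort size + missingness."""

    model: BayesianNetworkModel
    variables: list[VariableSpec]
    n: int
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    exclusion_counts: tuple[int, int, int] | None = None  # (n_raw, n_baseline_dm, n_incomplete)

    def __post_init__(self) -> None:
        names = {v.name for v in self.variables}
        if set(self.model.dag.nodes) != names:
            raise ValueError("fixture variables and DAG nodes disagree")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missing rate for {var!r} outside [0, 1)")
        outcome = [v.name for v in self.variables if v.role == "outcome"]
        for o in outcome:
            if self.missing_rates.get(o, 0.0) != 0.0:
                raise ValueError("outcome missing rate must be 0")

    @property
    def dag(self) -> Dag:
        return self.model.dag

    def without_missingness(self) -> "GeneratorFixture":
        return replace(self, missing_rates={})

    # -- serialization ------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "model": self.model.to_json(),
            "variables": [{"name": v.name, "categories": list(v.categories),
                           "role": v.role, "tier": v.tier} for v in self.variables],
            "n": self.n,
            "missing_rates": self.missing_rates,
            "seed": self.seed,
            "exclusion_counts": list(self.exclusion_counts) if self.exclusion_counts else None,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorFixture":
        obj = json.loads(Path(path).read_text())
        return cls(
            BayesianNetworkModel.from_json(obj["model"]),
            [VariableSpec(e["name"], tuple(e["categories"]), e["role"], e["tier"])
             for e in obj["variables"]],
            obj["n"], obj["missing_rates"], obj["seed"],
            tuple(obj["exclusion_counts"]) if obj.get("exclusion_counts") else None,
        )


# ---------------------------------------------------------------------------
# The packaged cohort-emulating fixture
# ---------------------------------------------------------------------------

#: Published post-test probability of new-onset diabetes by the three
#: Markov-blanket factors (hypertension, IFG, waist circumference band).
GBCS_OUTCOME_RISK: dict[tuple[str, str, str], float] = {
    ("no", "no", "normal"): 0.021,
    ("no", "no", "raised"): 0.043,
    ("yes", "no", "normal"): 0.059,
    ("yes", "no", "raised"): 0.102,
    ("no", "yes", "normal"): 0.121,
    ("no", "yes", "raised"): 0.168,
    ("yes", "yes", "normal"): 0.157,
    ("yes", "yes", "raised"): 0.275,
}

# Arcs of the published network recoverable from its description, expert
# edits already applied.  Values: +1 monotone positive, -1 monotone negative
# on the child's ordered categories, or an explicit per-parent-level shift
# vector for the two non-monotone effects.
_DELTA = 0.8  # logit shift across the full parent range for monotone arcs

GBCS_ARC_EFFECTS: dict[tuple[str, str], object] = {
    ("sex", "wc"): -1,
    ("sex", "hdl"): -1,
    ("sex", "ldl"): -1,
    ("sex", "smoking"): +1,
    ("age", "education"): +1,
    ("age", "drinking"): -1,
    ("age", "income"): -1,
    ("age", "hypertension"): +1,
    ("age", "wc"): +1,
    ("education", "smoking"): -1,
    # former smokers shifted toward higher BMI, current smokers toward lower
    ("smoking", "bmi"): (0.0, +0.4, -0.4),
    ("bmi", "wc"): +1,
    ("bmi", "hypertension"): +1,
    # overweight raises, obese lowers the odds of a high waist-to-hip ratio
    ("bmi", "whr"): (0.0, +0.5, -0.5),
    ("wc", "hypertension"): +1,
    ("wc", "ifg"): +1,
    ("family_history", "ifg"): +1,
    ("hypertension", "ifg"): +1,
    ("drinking", "hdl"): -1,
    ("tg", "hdl"): -1,
    ("tg", "ldl"): +1,
    ("tg", "lipid_lowering_drugs"): +1,
    ("hypertension", OUTCOME): None,  # outcome CPT is pinned, no heuristic effect
    ("ifg", OUTCOME): None,
    ("wc", OUTCOME): None,
}


def gbcs_marginals() -> dict[str, np.ndarray]:
    """Published per-variable category frequencies among non-missing rows."""
    out = {}
    for var, cats in GBCS_COUNTS.items():
        totals = np.array([nn + ny for nn, ny in cats.values()], dtype=float)
        out[var] = totals / totals.sum()
    return out


def gbcs_missing_rates() -> dict[str, float]:
    """MCAR rates reproducing the published per-variable total deficits."""
    rates = {}
    for var, cats in GBCS_COUNTS.items():
        total = sum(nn + ny for nn, ny in cats.values())
        rate = 1.0 - total / N_COHORT
        rates[var] = round(max(rate, 0.0), 6)
    rates[OUTCOME] = 0.0
    return rates


def _effect_vector(effect, levels: int) -> np.ndarray:
    if effect is None:
        return np.zeros(levels)
    if isinstance(effect, (int, float)):
        return float(effect) * _DELTA * np.arange(levels) / max(levels - 1, 1)
    vec = np.asarray(effect, dtype=float)
    if len(vec) != levels:
        raise ValueError("effect vector length mismatch")
    return vec


def _calibrated_cpt(node: str, categories: tuple[str, ...],
                    parents: tuple[str, ...],
                    parent_categories: tuple[tuple[str, ...], ...],
                    parent_joint: np.ndarray,
                    effects: Mapping[tuple[str, str], object],
                    target_marginal: np.ndarray) -> np.ndarray:
    """(q, r) CPT from a cumulative-logit response calibrated to a marginal.

    Row shifts t = sum of per-parent effects; thresholds theta_k solved so
    that sum_cfg w_cfg * sigmoid(theta_k - t_cfg) equals the published
    cumulative frequency for every split point k.
    """
    r = len(categories)
    grids = np.meshgrid(*[np.arange(len(pc)) for pc in parent_categories],
                        indexing="ij") if parents else []
    q = int(np.prod([len(pc) for pc in parent_categories])) if parents else 1
    t = np.zeros(q)
    for i, p in enumerate(parents):
        vec = _effect_vector(effects.get((p, node)), len(parent_categories[i]))
        # little-endian flat config index: first parent varies fastest
        t += vec[grids[i]].flatten(order="F")
    w = parent_joint.flatten(order="F") if parents else np.ones(1)

    cum_target = np.cumsum(target_marginal)[:-1]
    thetas = []
    for k, ck in enumerate(cum_target):
        f = lambda th: float(np.sum(w * expit(th - t))) - ck
        thetas.append(brentq(f, -40.0, 40.0, xtol=1e-13))
    cdf = np.column_stack([expit(th - t) for th in thetas] + [np.ones(q)])
    table = np.diff(np.concatenate([np.zeros((q, 1)), cdf], axis=1), axis=1)
    table = np.clip(table, 1e-12, None)
    return table / table.sum(axis=1, keepdims=True)


def gbcs_fixture(n: int = N_COHORT, seed: int = 0,
                 with_missingness: bool = True,
                 with_exclusions: bool = False) -> GeneratorFixture:
    """The packaged cohort-emulating fixture.

    DAG: the published diabetes network (curated edits applied) restricted
    to the arcs recoverable from its description; nodes with no described
    arcs are independent roots.  CPTs: outcome CPT pinned to the published
    risk table; all other nodes calibrated to the published marginals.
    """
    dictionary = build_variable_dictionary()
    names = [v.name for v in dictionary]
    arcs = [a for a in GBCS_ARC_EFFECTS]
    dag = Dag(names, arcs)
    marginals = gbcs_marginals()
    cats = {v.name: tuple(v.categories) for v in dictionary}

    cpts: dict[str, Cpt] = {}
    done: list[str] = []
    for node in dag.topological_order():
        parents = dag.parents(node)
        pcats = tuple(cats[p] for p in parents)
        if node == OUTCOME:
            q = 8
            table = np.zeros((q, 2))
            cpt_stub = Cpt.__new__(Cpt)  # only for config_index arithmetic
            cpt_stub.parents = parents
            cpt_stub.parent_categories = pcats
            for cfg_labels, p_yes in GBCS_OUTCOME_RISK.items():
                by = dict(zip(("hypertension", "ifg", "wc"), cfg_labels))
                codes = [pcats[i].index(by[p]) for i, p in enumerate(parents)]
                idx = cpt_stub.config_index(codes)
                table[idx] = [1.0 - p_yes, p_yes]
        elif not parents:
            table = marginals[node][None, :].copy()
        else:
            partial = BayesianNetworkModel(
                Dag(done, [(u, v) for u, v in dag.arcs if u in done and v in done]),
                {m: cpts[m] for m in done})
            pj = joint_marginal(partial, list(parents))
            table = _calibrated_cpt(node, cats[node], parents, pcats, pj,
                                    GBCS_ARC_EFFECTS, marginals[node])
        cpts[node] = Cpt(node, parents, cats[node], pcats, table,
                         np.zeros_like(table))
        done.append(node)

    model = BayesianNetworkModel(dag, cpts)
    return GeneratorFixture(
        model, dictionary, n,
        gbcs_missing_rates() if with_missingness else {},
        seed,
        (N_RETURNED, N_BASELINE_DIABETES, N_INCOMPLETE) if with_exclusions else None,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_cohort(fixture: GeneratorFixture, n: int | None = None,
                  seed: int | None = None) -> CohortTable:
    """Draw a cohort by ancestral sampling; MCAR masking applied afterwards.

    Identical fixture + seed gives an identical table.
    """
    n = fixture.n if n is None else int(n)
    seed = fixture.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    dag = fixture.dag
    order = dag.topological_order()
    cats = {v.name: tuple(v.categories) for v in fixture.variables}
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = fixture.model.cpts[node]
        if cpt.parents:
            idx = np.zeros(n, dtype=np.int64)
            stride = 1
            for p, pc in zip(cpt.parents, cpt.parent_categories):
                idx += codes[p] * stride
                stride *= len(pc)
        else:
            idx = np.zeros(n, dtype=np.int64)
        cdf = np.cumsum(cpt.table, axis=1)
        u = rng.random(n)
        codes[node] = (u[:, None] > cdf[idx]).sum(axis=1).astype(np.int64)

    data = {}
    names = [v.name for v in fixture.variables]
    for name in names:
        labels = np.asarray(cats[name], dtype=object)[codes[name]]
        data[name] = labels
    df = pd.DataFrame(data, columns=names)
    for name in names:
        rate = fixture.missing_rates.get(name, 0.0)
        if rate > 0.0:
            mask = rng.random(n) < rate
            col = df[name].copy()
            col[mask] = pd.NA
            df[name] = col
    return CohortTable(df, fixture.variables)


def sample_raw_cohort(fixture: GeneratorFixture, seed: int | None = None,
                      overlap: int = 0) -> CohortTable:
    """Emit a raw pre-exclusion cohort with provenance flags.

    ``fixture.exclusion_counts = (n_raw, n_baseline_diabetes, n_incomplete)``
    controls the flag totals; flagged sets are disjoint unless ``overlap``
    rows are shared.  Applying the exclusion filter leaves
    ``n_raw - n_baseline_diabetes - n_incomplete + overlap`` rows.
    """
    if fixture.exclusion_counts is None:
        raise ValueError("fixture has no exclusion_counts")
    n_raw, n_bd, n_inc = fixture.exclusion_counts
    if n_bd + n_inc - overlap > n_raw:
        raise ValueError("flag counts exceed the raw cohort size")
    if overlap > min(n_bd, n_inc):
        raise ValueError("overlap exceeds a flag count")
    seed = fixture.seed if seed is None else int(seed)
    cohort = sample_cohort(fixture, n=n_raw, seed=seed)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n_raw)
    bd_rows = perm[:n_bd]
    inc_rows = np.concatenate([bd_rows[:overlap], perm[n_bd:n_bd + n_inc - overlap]])
    flags = pd.DataFrame(False, index=range(n_raw),
                         columns=["baseline_diabetes", "type1_diabetes", "incomplete"])
    flags.loc[bd_rows, "baseline_diabetes"] = True
    flags.loc[inc_rows, "incomplete"] = True
    cohort.flags = flags
    return cohort
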