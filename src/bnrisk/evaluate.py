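"""Cross-validated performance of the network risk model and logistic baselines.

The risk model is scored the way the field reports it: stratified
five-fold cross-validation (each validation fold is a 20% hold-out, e.g.
3,186 or 3,187 of 15,934 rows), per-fold Youden-index classification
thresholds, and fold-averaged AUC / sensitivity / specificity / accuracy
with normal-approximation confidence intervals across folds.

Comparators: forward/backward stepwise logistic regression selected by
minimum AIC (block entry per categorical variable) and a forced-entry
logistic model on the network's outcome parents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .cohort import OUTCOME, CohortTable
from .parameters import (BayesianNetworkModel, fit_parameters, markov_blanket,
                         posterior)
from .structure import (ArcConstraintSet, CuratedEditList, Dag,
                        apply_curated_edits, bootstrap_average, hill_climb,
                        structural_em)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Stratified k-fold assignment: fold id per row."""

    n: int
    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.assignment, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")

    def validation_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def training_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(n: int, k: int, stratify_labels: Sequence, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold partition; warns if a fold is single-class."""
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and n >= k")
    labels = np.asarray(stratify_labels)
    assignment = np.empty(n, dtype=np.int64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, val) in enumerate(skf.split(np.zeros(n), labels)):
        assignment[val] = fold
    for fold in range(k):
        if len(np.unique(labels[assignment == fold])) < 2:
            logger.warning("fold %d has a single outcome class; AUC undefined", fold)
    return FoldPlan(n, k, assignment, seed)


# ---------------------------------------------------------------------------
# Risk prediction
# ---------------------------------------------------------------------------

def predict_risk(model: BayesianNetworkModel, rows: CohortTable | pd.DataFrame,
                 target: str = OUTCOME,
                 positive_category: str | None = None) -> np.ndarray:
    """Posterior P(target = positive | each row's observed non-target cells).

    Rows with the whole Markov blanket observed use the blanket alone (it
    d-separates the target from everything else); rows with missing blanket
    members fall back to exact inference on all observed cells, which
    marginalizes the missing ones.
    """
    df = rows.data if isinstance(rows, CohortTable) else rows
    cats = model.categories
    positive = positive_category or cats[target][-1]
    pos_idx = cats[target].index(positive)
    mb = sorted(markov_blanket(model.dag, target))
    other = [c for c in df.columns if c != target and c in model.dag.nodes]

    out = np.empty(len(df))
    cache: dict[tuple, float] = {}
    mb_vals = df[mb].to_numpy(dtype=object) if mb else np.empty((len(df), 0))
    for i in range(len(df)):
        row_mb = mb_vals[i]
        if mb and not any(pd.isna(x) for x in row_mb):
            key = ("mb",) + tuple(row_mb)
            if key not in cache:
                cache[key] = float(
                    posterior(model, target, dict(zip(mb, row_mb)))[pos_idx])
            out[i] = cache[key]
        else:
            ev = {c: df.iloc[i][c] for c in other if not pd.isna(df.iloc[i][c])}
            key = ("full",) + tuple(sorted(ev.items()))
            if key not in cache:
                cache[key] = float(posterior(model, target, ev)[pos_idx])
            out[i] = cache[key]
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney concordance probability, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def youden_threshold(scores: Sequence[float], labels: Sequence[int]
                     ) -> tuple[float, float, float]:
    """Threshold among observed scores maximizing Youden's J = sens + spec - 1.

    Classification rule: score >= threshold -> positive.  Ties in J are
    broken toward higher specificity (the larger threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both outcome classes must be present")
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = float((pred & (labels == 1)).sum() / n1)
        spec = float((~pred & (labels == 0)).sum() / n0)
        j = sens + spec - 1.0
        key = (j, spec, thr)
        if best is None or key > best[0]:
            best = (key, (float(thr), sens, spec))
    return best[1]


def confusion_metrics(scores: Sequence[float], labels: Sequence[int],
                      threshold: float) -> dict[str, float]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "accuracy": (tp + tn) / len(labels),
    }


# ---------------------------------------------------------------------------
# Cross-validated evaluation of the network model
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold and fold-averaged metrics with 95% CIs (mean +/- 1.96 SD/sqrt(k))."""

    folds: pd.DataFrame  # columns: fold, auc, sensitivity, specificity, accuracy, threshold
    k: int

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for m in ("auc", "sensitivity", "specificity", "accuracy"):
            vals = self.folds[m].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            half = 1.96 * float(np.std(vals, ddof=1)) / np.sqrt(self.k) if self.k > 1 else np.nan
            out[m] = {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}
        return out

    def to_json(self) -> dict:
        return {"k": self.k, "folds": self.folds.to_dict(orient="records"),
                "summary": self.summary}

    def __str__(self) -> str:
        lines = [self.folds.to_string(index=False), ""]
        for m, s in self.summary.items():
            lines.append(f"{m:12s} {s['mean']:.3f} (95% CI {s['ci_low']:.3f}-{s['ci_high']:.3f})")
        return "\n".join(lines)


def evaluate_bn(data: CohortTable, target: str = OUTCOME, k: int = 5,
                seed: int = 0, B: int = 200, threshold: float = 0.6,
                alpha: float = 1.0,
                constraints: ArcConstraintSet | None = None,
                edits: CuratedEditList | None = None,
                score_name: str = "bic", max_parents: int | None = None,
                fixed_structure: Dag | None = None,
                threshold_from: str = "validation") -> EvaluationReport:
    """k-fold cross-validation of the full learn -> fit -> predict pipeline.

    Per fold: structure is learned on the training 80% (structural EM to
    complete the data when needed, then bootstrap arc averaging and curated
    edits), parameters are fitted on the completed training data, risks are
    predicted for the validation 20%, and the classification threshold is
    set by the Youden index on the fold named by ``threshold_from``
    (``"validation"``, the published procedure, or ``"train"``).
    Pass ``fixed_structure`` to skip structure learning and refit
    parameters only — the cheaper variant.
    """
    labels_raw = data.data[target]
    if labels_raw.isna().any():
        raise ValueError("outcome must be observed for every row")
    positive = data.spec(target).categories[-1]
    y_all = (labels_raw == positive).to_numpy(dtype=int)
    plan = make_folds(data.n, k, y_all, seed)
    rng = np.random.default_rng(seed)

    records = []
    for fold in range(k):
        tr = plan.training_rows(fold)
        va = plan.validation_rows(fold)
        train = data.iloc_rows(tr)
        valid = data.iloc_rows(va)
        fold_seed = int(rng.integers(2**31))

        if train.has_missing():
            sem = structural_em(train, constraints, seed=fold_seed,
                                score_name=score_name, max_parents=max_parents)
            completed = sem.completed
        else:
            completed = train
        if fixed_structure is not None:
            dag = fixed_structure
        else:
            dag, _ = bootstrap_average(completed, constraints, B=B,
                                       threshold=threshold, seed=fold_seed,
                                       score_name=score_name,
                                       max_parents=max_parents)
            if edits is not None:
                dag = apply_curated_edits(dag, edits)
        model = fit_parameters(dag, completed, alpha)

        scores_va = predict_risk(model, valid, target)
        y_va = y_all[va]
        if threshold_from == "train":
            scores_tr = predict_risk(model, completed, target)
            thr, _, _ = youden_threshold(scores_tr, y_all[tr])
        else:
            thr, _, _ = youden_threshold(scores_va, y_va)
        m = confusion_metrics(scores_va, y_va, thr)
        records.append({"fold": fold, "auc": roc_auc(scores_va, y_va),
                        "threshold": thr, **m})
    return EvaluationReport(pd.DataFrame(records), k)


# ---------------------------------------------------------------------------
# Logistic comparators
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, predictors: Sequence[str],
            interactions: bool = False) -> pd.DataFrame:
    if not predictors:
        return pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    X = pd.get_dummies(df[list(predictors)], drop_first=True, dtype=float)
    if interactions and len(predictors) > 1:
        # all products of dummy columns -> a saturated design for binary inputs
        import itertools as it
        base_cols = list(X.columns)
        for order in range(2, len(base_cols) + 1):
            for combo in it.combinations(base_cols, order):
                X[":".join(combo)] = np.prod([X[c] for c in combo], axis=0)
    X.insert(0, "const", 1.0)
    return X


@dataclass
class LogisticFit:
    predictors: tuple[str, ...]
    params: pd.Series
    llf: float
    aic: float
    stabilized: bool
    conf_int: pd.DataFrame | None = None

    @property
    def odds_ratios(self) -> pd.DataFrame:
        out = pd.DataFrame({"OR": np.exp(self.params)})
        if self.conf_int is not None:
            out["ci_low"] = np.exp(self.conf_int[0])
            out["ci_high"] = np.exp(self.conf_int[1])
        return out.drop(index="const", errors="ignore")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = X[self.params.index].to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_logit(X: pd.DataFrame, y: np.ndarray,
               predictors: Sequence[str]) -> LogisticFit:
    """ML logistic fit; falls back to a ridge-stabilized fit under separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
            params = pd.Series(res.params, index=X.columns)
            if np.all(np.isfinite(params)) and np.abs(params).max() < 30:
                ci = pd.DataFrame(res.conf_int(), index=X.columns)
                return LogisticFit(tuple(predictors), params, float(res.llf),
                                   float(res.aic), False, ci)
        except Exception:  # noqa: BLE001 - separation/LinAlg failures
            pass
    logger.warning("logistic fit unstable (separation?); using ridge-stabilized fit")
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression(C=1e3, max_iter=2000)
    lr.fit(X.drop(columns="const").to_numpy(), y)
    params = pd.Series(np.concatenate([lr.intercept_, lr.coef_.ravel()]),
                       index=["const"] + [c for c in X.columns if c != "const"])
    p = 1.0 / (1.0 + np.exp(-(X[params.index].to_numpy() @ params.to_numpy())))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return LogisticFit(tuple(predictors), params, llf, 2 * len(params) - 2 * llf,
                       True, None)


def _outcome_vector(data: CohortTable, outcome: str) -> np.ndarray:
    positive = data.spec(outcome).categories[-1]
    col = data.data[outcome]
    if col.isna().any():
        raise ValueError("outcome must be complete")
    return (col == positive).to_numpy(dtype=int)


def stepwise_logistic(data: CohortTable, candidates: Sequence[str] | None = None,
                      outcome: str = OUTCOME, direction: str = "forward",
                      ) -> tuple[LogisticFit, list[str]]:
    """Stepwise logistic variable selection by minimum AIC.

    Each categorical variable enters or leaves as a full dummy block.
    Forward starts from the intercept-only model and greedily adds the
    block whose inclusion lowers AIC most; backward starts from the full
    model and drops blocks.  Requires complete data (use the structural-EM
    completed dataset).
    """
    if candidates is None:
        candidates = [v for v in data.variable_names if v != outcome]
    candidates = list(candidates)
    df = data.data
    if df[candidates + [outcome]].isna().any().any():
        raise ValueError("stepwise selection requires complete data")
    y = _outcome_vector(data, outcome)

    def aic_of(sel: list[str]) -> tuple[float, LogisticFit]:
        fit = _fit_logit(_design(df, sel), y, sel)
        return fit.aic, fit

    if direction == "forward":
        selected: list[str] = []
        best_aic, best_fit = aic_of(selected)
        improved = True
        while improved and len(selected) < len(candidates):
            improved = False
            for var in candidates:
                if var in selected:
                    continue
                a, f = aic_of(selected + [var])
                if a < best_aic - 1e-9:
                    best_aic, best_fit, best_var = a, f, var
                    improved = True
            if improved:
                selected.append(best_var)
                selected = [v for v in candidates if v in selected]  # stable order
    elif direction == "backward":
        selected = list(candidates)
        best_aic, best_fit = aic_of(selected)
        improved = True
        while improved and selected:
            improved = False
            for var in list(selected):
                a, f = aic_of([v for v in selected if v != var])
                if a < best_aic - 1e-9:
                    best_aic, best_fit, best_var = a, f, var
                    improved = True
            if improved:
                selected = [v for v in selected if v != best_var]
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    return best_fit, selected


def forced_entry_logistic(data: CohortTable, predictors: Sequence[str],
                          outcome: str = OUTCOME, interactions: bool = False,
                          k: int | None = None, seed: int = 0
                          ) -> tuple[LogisticFit, EvaluationReport | None]:
    """Logistic model on exactly the given predictors (e.g. the outcome parents).

    Returns the fit (odds ratios with Wald CIs) and, when ``k`` is given,
    a cross-validated evaluation under the same stratified fold plan and
    Youden thresholding used for the network model.
    """
    predictors = list(predictors)
    sub = data.data[predictors + [outcome]].dropna()
    keep = data.iloc_rows(np.flatnonzero(
        data.data[predictors + [outcome]].notna().all(axis=1).to_numpy()))
    y = _outcome_vector(keep, outcome)
    X = _design(keep.data, predictors, interactions)
    fit = _fit_logit(X, y, predictors)

    report = None
    if k is not None:
        plan = make_folds(keep.n, k, y, seed)
        records = []
        for fold in range(k):
            tr, va = plan.training_rows(fold), plan.validation_rows(fold)
            f = _fit_logit(X.iloc[tr], y[tr], predictors)
            scores = f.predict(X.iloc[va])
            thr, _, _ = youden_threshold(scores, y[va])
            m = confusion_metrics(scores, y[va], thr)
            records.append({"fold": fold, "auc": roc_auc(scores, y[va]),
                            "threshold": thr, **m})
        report = EvaluationReport(pd.DataFrame(records), k)
    return fit, report
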