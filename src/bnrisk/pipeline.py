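"""End-to-end pipeline orchestration: the four-step flow as one call.

Step 1 — structural EM for an initial structure and a completed dataset,
then bootstrap arc-strength averaging under the temporal/prior constraints.
Step 2 — curated expert edits.  Step 3 — Bayesian parameter learning and
the post-test probability table.  Step 4 — cross-validated evaluation.

Every artifact is written to the output directory together with a manifest
recording the configuration, the per-stage seeds (derived deterministically
from one global seed) and a checksum per file, so any stage can be re-run
reproducibly from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import OUTCOME, CohortTable, apply_exclusions, build_variable_dictionary
from .evaluate import evaluate_bn
from .parameters import fit_parameters, posttest_table
from .structure import (ArcConstraintSet, CuratedEditList, GBCS_EDITS,
                        apply_curated_edits, bootstrap_average, gbcs_constraints,
                        structural_em)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed from one global seed (kept below 2^31)."""
    return (int(seed) * 1_000_003 + 7919 * stage) % _SEED_MOD


@dataclass
class PipelineConfig:
    """All tunables of the four-step pipeline."""

    B: int = 200                 # bootstrap resamples for arc averaging
    threshold: float = 0.6       # arc retention frequency (strictly greater)
    alpha: float = 1.0           # Dirichlet pseudo-count for CPTs
    k: int = 5                   # cross-validation folds
    seed: int = 0
    score: str = "bic"
    max_parents: int | None = None
    em_mode: str = "sample"
    n_boot_ci: int = 200         # bootstrap replicates for post-test CIs
    ci_method: str = "bootstrap"
    target: str = OUTCOME
    eval_B: int | None = None    # bootstrap count inside CV (defaults to B)
    threshold_from: str = "validation"

    def __post_init__(self) -> None:
        if self.B < 1 or self.k < 2 or self.alpha < 0 or self.n_boot_ci < 1:
            raise ValueError("numeric pipeline settings must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("arc retention threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, data: CohortTable | str | Path,
                 out_dir: str | Path,
                 constraints: ArcConstraintSet | None = None,
                 edits: CuratedEditList | None = GBCS_EDITS) -> Path:
    """Run the full pipeline and write all artifacts to ``out_dir``.

    Writes, in order: the completed dataset, the arc-strength table, the
    averaged DAG, the edited DAG (edge list and DOT), the CPTs, the
    post-test probability table and the evaluation report, plus a manifest.
    Partial outputs are retained if a stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(data, CohortTable):
        data = CohortTable.from_csv(data)
    if data.flags is not None:
        before = data.n
        data = apply_exclusions(data)
        logger.info("exclusions: %d -> %d rows", before, data.n)
    if constraints is None:
        constraints = gbcs_constraints(data.variables)

    artifacts: list[Path] = []
    seeds = {s: stage_seed(config.seed, i) for i, s in enumerate(
        ("sem", "bootstrap", "posttest", "evaluate"))}
    stage = "structural_em"
    try:
        if data.has_missing():
            sem = structural_em(data, constraints, seed=seeds["sem"],
                                score_name=config.score,
                                max_parents=config.max_parents,
                                em_mode=config.em_mode)
            completed = sem.completed
        else:
            completed = data
        completed.to_csv(out / "completed.csv")
        artifacts.append(out / "completed.csv")

        stage = "bootstrap_average"
        dag, strengths = bootstrap_average(
            completed, constraints, B=config.B, threshold=config.threshold,
            seed=seeds["bootstrap"], score_name=config.score,
            max_parents=config.max_parents)
        strengths.to_csv(out / "arc_strengths.csv")
        dag.to_edge_list(out / "dag_averaged.txt")
        artifacts += [out / "arc_strengths.csv", out / "dag_averaged.txt"]

        stage = "curated_edits"
        if edits is not None:
            dag = apply_curated_edits(dag, edits)
        dag.to_edge_list(out / "dag_edited.txt")
        (out / "dag_edited.dot").write_text(dag.to_dot(highlight=[config.target]))
        artifacts += [out / "dag_edited.txt", out / "dag_edited.dot"]

        stage = "fit_parameters"
        model = fit_parameters(dag, completed, config.alpha)
        (out / "cpts.json").write_text(json.dumps(model.to_json()))
        model.cpts_long().to_csv(out / "cpts.csv", index=False)
        artifacts += [out / "cpts.json", out / "cpts.csv"]

        stage = "posttest_table"
        table = posttest_table(model, completed, config.target,
                               ci_method=config.ci_method,
                               n_boot=config.n_boot_ci, seed=seeds["posttest"])
        table.to_csv(out / "posttest.csv")
        artifacts.append(out / "posttest.csv")

        stage = "evaluate"
        report = evaluate_bn(completed, target=config.target, k=config.k,
                             seed=seeds["evaluate"],
                             B=config.eval_B or config.B,
                             threshold=config.threshold, alpha=config.alpha,
                             constraints=constraints, edits=edits,
                             score_name=config.score,
                             max_parents=config.max_parents,
                             threshold_from=config.threshold_from)
        (out / "evaluation.json").write_text(json.dumps(report.to_json(), indent=1))
        artifacts.append(out / "evaluation.json")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "n_rows": data.n,
        "checksums": {p.name: _checksum(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
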