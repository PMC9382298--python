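"""Study variable dictionary, discretization and cohort-table handling.

The package models new-onset type 2 diabetes over ~4 years of follow-up in
a cohort of older Chinese adults (the Guangzhou Biobank Cohort Study, GBCS:
18,105 returners, of whom 15,934 remain after excluding baseline diabetes
and incomplete records).  All analysis variables are categorical: raw
measurements (fasting plasma glucose in mmol/L, waist circumference in cm,
BMI in kg/m^2, ...) are cut into the published bands before any modelling.

This module defines:

* :class:`VariableSpec` / :class:`CohortTable` — the variable dictionary and
  the person-level categorical table;
* the published per-category outcome cross-tabulation counts
  (:data:`GBCS_COUNTS`) used both as a marginal calibration target for the
  synthetic generator and as the demo input for the cross-tab utilities;
* :func:`discretize` / :func:`define_outcome` — raw measurement -> category
  mapping and the new-onset diabetes rule;
* :func:`apply_exclusions` — removal of baseline-diabetes / type 1 /
  incomplete records by union of provenance flags.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = ""  # canonical missing marker in CSV cells

ROLE_BACKGROUND = "background"
ROLE_BASELINE = "baseline"
ROLE_OUTCOME = "outcome"

OUTCOME = "diabetes"


# --------------------------------------------------------------------------
# Variable dictionary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One categorical study variable.

    Parameters
    ----------
    name
        Identifier used as the column name.
    categories
        Ordered category labels.  The order matters: monotone arc signs are
        defined with respect to it and "top category" means the last label.
    role
        ``background`` (fixed attributes: sex, age), ``baseline`` or
        ``outcome``.
    tier
        Temporal rank used to generate the structural blacklist; background
        < baseline < outcome.
    missing_allowed
        Whether missing cells are tolerated among included participants.
    """

    name: str
    categories: tuple[str, ...]
    role: str = ROLE_BASELINE
    tier: int = 1
    missing_allowed: bool = True

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"variable {self.name!r}: empty category list")
        canon = [_canon(c) for c in self.categories]
        if len(set(canon)) != len(canon):
            raise ValueError(f"variable {self.name!r}: duplicate category labels")
        if self.role not in (ROLE_BACKGROUND, ROLE_BASELINE, ROLE_OUTCOME):
            raise ValueError(f"variable {self.name!r}: unknown role {self.role!r}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def code(self, label: str) -> int:
        """Category index of ``label`` (case-insensitive, trimmed); raises on unknown."""
        target = _canon(label)
        for i, c in enumerate(self.categories):
            if _canon(c) == target:
                return i
        raise ValueError(f"unknown category {label!r} for variable {self.name!r}")


def _canon(label: str) -> str:
    return str(label).strip().lower()


# Published cross-tabulation of every baseline characteristic against the
# new-onset diabetes outcome in the 15,934 analysed participants:
# variable -> {category label: (count without diabetes, count with diabetes)}.
# Per-variable totals fall short of 15,934 where baseline values were missing.
GBCS_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {"women": (10649, 961), "men": (3983, 341)},
    "age": {"<55": (3465, 185), "55-65": (6958, 631), ">=65": (4209, 486)},
    "education": {
        "primary_or_below": (5496, 591),
        "middle_school": (7824, 588),
        "college_or_above": (1308, 123),
    },
    "occupation": {"manual": (8777, 795), "non_manual": (3509, 322), "others": (2261, 176)},
    "income": {"<10k": (724, 67), "10k-50k": (7993, 688), ">=50k": (2700, 216)},
    "smoking": {"never": (11986, 1083), "former": (1197, 109), "current": (1422, 108)},
    "drinking": {"never": (8821, 847), "former": (311, 30), "current": (4344, 347)},
    "physical_activity": {"inactive": (1257, 87), "moderate": (5722, 528), "active": (7653, 687)},
    "insomnia": {"no": (12091, 1085), "yes": (2466, 206)},
    "napping": {"no": (5246, 416), "yes": (9308, 875)},
    "snoring": {"no": (5538, 410), "yes": (6155, 634), "do_not_know": (2862, 247)},
    "health_vs_others": {"good": (3800, 308), "average": (9362, 866), "poor": (1398, 117)},
    "self_rated_health": {
        "better": (209, 23),
        "same": (11812, 1050),
        "poor": (2201, 198),
        "worse": (29, 0),
    },
    "hypertension": {"no": (9199, 524), "yes": (5357, 769)},
    "heart_rate": {"<60": (748, 54), "60-99": (13536, 1192), ">=100": (348, 56)},
    "lipid_lowering_drugs": {"no": (13126, 1132), "yes": (473, 79)},
    "coronary_heart_disease": {"no": (14142, 1246), "yes": (418, 45)},
    "family_history": {"no": (13047, 1095), "yes": (1585, 207)},
    "bmi": {"<25.0": (10251, 651), "25.0-29.9": (3915, 552), ">=30.0": (437, 97)},
    "wc": {"normal": (10283, 642), "raised": (4307, 655)},
    "whr": {"<0.9": (11017, 755), ">=0.9": (3564, 541)},
    "tg": {"<1.7": (10166, 657), ">=1.7": (4441, 644)},
    "hdl": {"<1.0": (326, 57), ">=1.0": (14279, 1244)},
    "ldl": {"<3.4": (8866, 752), ">=3.4": (5707, 546)},
    "ifg": {"no": (10872, 492), "yes": (3675, 772)},
    OUTCOME: {"no": (14632, 0), "yes": (0, 1302)},
}

N_COHORT = 15934          # analysed participants
N_RETURNED = 18105        # returned for follow-up before exclusions
N_BASELINE_DIABETES = 2123
N_INCOMPLETE = 48
N_CASES = 1302            # new-onset diabetes over mean 4.1 y follow-up

_DEFAULT_ROLES = {"sex": ROLE_BACKGROUND, "age": ROLE_BACKGROUND, OUTCOME: ROLE_OUTCOME}
_DEFAULT_TIERS = {"sex": 0, "age": 0, OUTCOME: 2}

# Tabulated at baseline but not entered into the network (the published
# model used 24 categorical predictors plus the outcome).
NON_NETWORK_VARIABLES = ("insomnia",)


def default_dictionary_config() -> dict[str, dict]:
    """Config for :func:`build_variable_dictionary`: the 25 network variables
    (24 background/baseline predictors plus the outcome)."""
    cfg: dict[str, dict] = {}
    for name, cats in GBCS_COUNTS.items():
        if name in NON_NETWORK_VARIABLES:
            continue
        cfg[name] = {
            "categories": list(cats),
            "role": _DEFAULT_ROLES.get(name, ROLE_BASELINE),
            "tier": _DEFAULT_TIERS.get(name, 1),
        }
    return cfg


def build_variable_dictionary(config: Mapping[str, Mapping] | None = None) -> list[VariableSpec]:
    """Build the study variable dictionary from a config mapping.

    ``config`` maps variable name -> {categories, role?, tier?,
    missing_allowed?}.  With no argument the packaged 25-variable dictionary
    (24 background/baseline predictors plus the diabetes outcome) is
    returned, with sex and age in the earliest tier and the outcome in the
    last.
    """
    if config is None:
        config = default_dictionary_config()
    names = list(config)
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable name in dictionary config")
    specs = []
    for name, entry in config.items():
        specs.append(
            VariableSpec(
                name=name,
                categories=tuple(entry["categories"]),
                role=entry.get("role", ROLE_BASELINE),
                tier=int(entry.get("tier", 1)),
                missing_allowed=bool(entry.get("missing_allowed", name != OUTCOME)),
            )
        )
    outcomes = [s for s in specs if s.role == ROLE_OUTCOME]
    if len(outcomes) != 1:
        raise ValueError(f"dictionary must define exactly one outcome variable, found {len(outcomes)}")
    tiers_by_role = {r: [s.tier for s in specs if s.role == r] for r in
                     (ROLE_BACKGROUND, ROLE_BASELINE, ROLE_OUTCOME)}
    if tiers_by_role[ROLE_BACKGROUND] and tiers_by_role[ROLE_BASELINE]:
        if max(tiers_by_role[ROLE_BACKGROUND]) >= min(tiers_by_role[ROLE_BASELINE]):
            raise ValueError("background tier must precede baseline tiers")
    if tiers_by_role[ROLE_BASELINE]:
        if max(tiers_by_role[ROLE_BASELINE]) >= outcomes[0].tier:
            raise ValueError("outcome tier must follow all baseline tiers")
    return specs


# --------------------------------------------------------------------------
# Cohort table
# --------------------------------------------------------------------------

FLAG_COLUMNS = ("baseline_diabetes", "type1_diabetes", "incomplete")


@dataclass
class CohortTable:
    """A person-level categorical table plus its variable dictionary.

    ``data`` holds category labels as strings with ``""``/NaN for missing.
    ``flags`` (optional) is a boolean frame with columns
    ``baseline_diabetes``, ``type1_diabetes``, ``incomplete`` used by
    :func:`apply_exclusions`.
    """

    data: pd.DataFrame
    variables: list[VariableSpec]
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        spec_names = [v.name for v in self.variables]
        missing_cols = [n for n in spec_names if n not in self.data.columns]
        if missing_cols:
            raise ValueError(f"cohort data lacks columns {missing_cols}")
        self.data = self.data[spec_names].copy()
        # canonicalize labels and validate against the dictionary
        for spec in self.variables:
            col = self.data[spec.name]
            mask = col.notna() & (col.astype(str).str.strip() != "")
            vals = col[mask].astype(str).str.strip().str.lower()
            lut = {_canon(c): c for c in spec.categories}
            unknown = set(vals.unique()) - set(lut)
            if unknown:
                raise ValueError(
                    f"unknown categories {sorted(unknown)} for variable {spec.name!r}"
                )
            out = pd.Series(pd.NA, index=col.index, dtype="object")
            out[mask] = vals.map(lut)
            self.data[spec.name] = out
        if self.flags is not None:
            self.flags = self.flags.reindex(columns=list(FLAG_COLUMNS), fill_value=False)
            self.flags = self.flags.fillna(False).astype(bool)
            self.flags.index = self.data.index

    # -- basic queries ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def non_missing_count(self, name: str) -> int:
        return int(self.data[name].notna().sum())

    def category_counts(self, name: str) -> pd.Series:
        spec = self.spec(name)
        counts = self.data[name].value_counts(dropna=True)
        return counts.reindex(list(spec.categories), fill_value=0).astype(int)

    def codes(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Integer code matrix (n x p), −1 for missing; column order as given."""
        cols = list(columns) if columns is not None else self.variable_names
        out = np.empty((self.n, len(cols)), dtype=np.int32)
        for j, name in enumerate(cols):
            spec = self.spec(name)
            cat = pd.Categorical(self.data[name], categories=list(spec.categories))
            out[:, j] = cat.codes
        return out

    def cardinalities(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.variable_names
        return np.array([self.spec(c).n_categories for c in cols], dtype=np.int64)

    def has_missing(self, columns: Sequence[str] | None = None) -> bool:
        cols = list(columns) if columns is not None else self.variable_names
        return bool(self.data[cols].isna().any().any())

    def subset_rows(self, index) -> "CohortTable":
        flags = self.flags.loc[index] if self.flags is not None else None
        return CohortTable(self.data.loc[index].reset_index(drop=True),
                           self.variables,
                           flags.reset_index(drop=True) if flags is not None else None)

    def iloc_rows(self, positions) -> "CohortTable":
        flags = self.flags.iloc[positions] if self.flags is not None else None
        return CohortTable(self.data.iloc[positions].reset_index(drop=True),
                           self.variables,
                           flags.reset_index(drop=True) if flags is not None else None)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path, write_dictionary: bool = True) -> None:
        """Write cohort CSV (empty cell = missing) plus a side-car JSON dictionary."""
        path = Path(path)
        df = self.data.copy()
        if self.flags is not None:
            for c in FLAG_COLUMNS:
                df[c] = self.flags[c].astype(int)
        df.to_csv(path, index=False, na_rep=MISSING)
        if write_dictionary:
            side = path.with_suffix(".dict.json")
            side.write_text(json.dumps(
                [{"name": v.name, "categories": list(v.categories),
                  "role": v.role, "tier": v.tier} for v in self.variables],
                indent=1))

    @classmethod
    def from_csv(cls, path: str | Path,
                 variables: list[VariableSpec] | None = None) -> "CohortTable":
        path = Path(path)
        if variables is None:
            side = path.with_suffix(".dict.json")
            entries = json.loads(side.read_text())
            variables = [VariableSpec(e["name"], tuple(e["categories"]),
                                      e.get("role", ROLE_BASELINE), e.get("tier", 1))
                         for e in entries]
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({MISSING: pd.NA})
        flags = None
        if set(FLAG_COLUMNS) <= set(df.columns):
            flags = df[list(FLAG_COLUMNS)].fillna("0").astype(int).astype(bool)
            df = df.drop(columns=list(FLAG_COLUMNS))
        return cls(df, variables, flags)


# --------------------------------------------------------------------------
# Discretization of raw measurements
# --------------------------------------------------------------------------

IFG_LOW = 5.6    # mmol/L, inclusive
IFG_HIGH = 6.9   # mmol/L, inclusive
DIABETES_FPG = 7.0  # mmol/L, inclusive at follow-up

WC_CUT = {"men": 90.0, "women": 80.0}  # cm, >= cut is "raised"


def _band(value: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    """Half-open bands [edges[i], edges[i+1]) with −inf/+inf implicit ends.

    Upper-band cut-offs take precedence at shared printed boundaries
    (e.g. BMI 30.0 falls in ">=30.0", heart rate 100 in ">=100").
    """
    for i, edge in enumerate(edges):
        if value < edge:
            return labels[i]
    return labels[-1]


def discretize_value(name: str, value: float, sex: str | None = None) -> str:
    """Map one raw measurement to its published category band."""
    if value is not None and not (isinstance(value, float) and math.isnan(value)) and value < 0:
        raise ValueError(f"{name}: negative raw value {value}")
    if name in ("fpg", "fpg_baseline"):
        return "yes" if IFG_LOW <= value <= IFG_HIGH else "no"
    if name == "age":
        return _band(value, [55, 65], ["<55", "55-65", ">=65"])
    if name == "bmi":
        return _band(value, [25.0, 30.0], ["<25.0", "25.0-29.9", ">=30.0"])
    if name == "heart_rate":
        return _band(value, [60, 100], ["<60", "60-99", ">=100"])
    if name == "wc":
        if sex is None:
            raise ValueError("waist circumference requires sex (cut 90 cm men / 80 cm women)")
        cut = WC_CUT[_canon(sex) if _canon(sex) in WC_CUT else ("men" if _canon(sex) in ("m", "male", "man") else "women")]
        return "raised" if value >= cut else "normal"
    if name == "whr":
        return _band(value, [0.9], ["<0.9", ">=0.9"])
    if name == "tg":
        return _band(value, [1.7], ["<1.7", ">=1.7"])
    if name == "hdl":
        return _band(value, [1.0], ["<1.0", ">=1.0"])
    if name == "ldl":
        return _band(value, [3.4], ["<3.4", ">=3.4"])
    raise KeyError(f"no discretization rule for {name!r}")


NUMERIC_FIELDS = ("fpg_baseline", "age", "bmi", "heart_rate", "wc", "whr", "tg", "hdl", "ldl")
_FIELD_TO_VARIABLE = {"fpg_baseline": "ifg", "age": "age", "bmi": "bmi",
                      "heart_rate": "heart_rate", "wc": "wc", "whr": "whr",
                      "tg": "tg", "hdl": "hdl", "ldl": "ldl"}


def discretize(record: Mapping[str, object],
               dictionary: list[VariableSpec] | None = None) -> dict[str, str]:
    """Categorize one raw record (dict of measurements + categorical answers).

    Numeric fields named in :data:`NUMERIC_FIELDS` are cut into bands;
    any other key whose name matches a dictionary variable passes through
    as a category label (validated).  Returns variable -> label.
    """
    if dictionary is None:
        dictionary = build_variable_dictionary()
    by_name = {v.name: v for v in dictionary}
    out: dict[str, str] = {}
    sex = record.get("sex")
    for key, value in record.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        if key in NUMERIC_FIELDS:
            var = _FIELD_TO_VARIABLE[key]
            label = discretize_value(key if key != "fpg_baseline" else "fpg",
                                     float(value), sex=str(sex) if sex is not None else None)
            out[var] = label
        elif key in by_name:
            spec = by_name[key]
            out[key] = spec.categories[spec.code(str(value))]
        # unrecognised keys (follow-up fields, flags) are left to define_outcome
    for var, label in out.items():
        by_name[var].code(label)  # validate
    return out


def define_outcome(record: Mapping[str, object]) -> str | None:
    """New-onset diabetes rule.

    ``yes`` iff follow-up FPG >= 7.0 mmol/L, or self-reported physician
    diagnosis, or initiation of hypoglycemic medication / insulin during
    follow-up.  Returns ``None`` (record incomplete) when all three sources
    are absent.
    """
    fpg = record.get("fpg_followup")
    diag = record.get("diagnosed_diabetes_followup")
    meds = record.get("hypoglycemic_medication_followup")
    has_fpg = fpg is not None and not (isinstance(fpg, float) and math.isnan(fpg))
    if not has_fpg and diag is None and meds is None:
        return None
    if has_fpg and float(fpg) >= DIABETES_FPG:
        return "yes"
    if diag or meds:
        return "yes"
    return "no"


# --------------------------------------------------------------------------
# Exclusions and cross-tabulation
# --------------------------------------------------------------------------

def apply_exclusions(cohort: CohortTable) -> CohortTable:
    """Drop rows flagged baseline-diabetes, type 1 diabetes or incomplete.

    Removal is by union of the provenance flags, so overlapping flags are
    not double-counted; the operation is idempotent.
    """
    if cohort.flags is None:
        return cohort
    keep = ~cohort.flags.any(axis=1)
    return cohort.iloc_rows(np.flatnonzero(keep.to_numpy()))


def crosstab(cohort: CohortTable, variable: str, outcome: str = OUTCOME) -> pd.DataFrame:
    """Cross-tabulate ``variable`` against the outcome with row percentages.

    Returns one row per category of ``variable`` with columns
    ``<outcome cat>`` (count), ``<outcome cat>_pct`` (100*cell/row total,
    2 decimals) and ``total``.  Rows missing either variable are dropped.
    """
    vspec, ospec = cohort.spec(variable), cohort.spec(outcome)
    sub = cohort.data[[variable, outcome]].dropna()
    tab = pd.crosstab(sub[variable], sub[outcome])
    tab = tab.reindex(index=list(vspec.categories), columns=list(ospec.categories),
                      fill_value=0)
    return counts_to_percentages(tab)


def counts_to_percentages(tab: pd.DataFrame) -> pd.DataFrame:
    """Append row totals and row percentages (2 decimals) to a count table."""
    out = tab.copy().astype(int)
    total = out.sum(axis=1)
    for col in tab.columns:
        out[f"{col}_pct"] = (100.0 * tab[col] / total).round(2)
    out["total"] = total
    return out


def gbcs_count_table(variable: str) -> pd.DataFrame:
    """Published count cross-tab of ``variable`` vs the outcome as a DataFrame."""
    entries = GBCS_COUNTS[variable]
    tab = pd.DataFrame(
        {"no": {c: nn for c, (nn, ny) in entries.items()},
         "yes": {c: ny for c, (nn, ny) in entries.items()}}
    )
    tab.index.name = variable
    return tab
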