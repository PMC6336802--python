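"""Synthetic first-episode-psychosis cohort generator.

Draws cohorts with the joint structure the downstream analysis assumes:

* four latent clinical subtypes (C1A, C1B, C2A, C2B) in configurable
  proportions, expressed through sparse PANSS-item signatures on top of a
  shared per-patient severity factor;
* a 43-analyte serum panel of block-correlated log10-normal concentrations
  with subtype-specific standardized mean shifts (Cohen's d targets) and
  LLOD censoring, including designated low-abundance analytes censored in
  well over 10% of samples;
* demographic / serostatus covariates with subtype-specific means and
  prevalences;
* remission outcomes: every subtype has a base remission rate; in the
  high-severity risk subtype (C1A by default) the non-remission probability
  follows a logistic model on configured per-variable odds ratios, with the
  intercept solved numerically so the marginal rate matches the base rate.
  Follow-up criterion items are generated conditionally on the drawn
  remission label so the RSWG rule holds exactly.

Everything is deterministic given the config seed; sub-generators use
sub-seeds spawned from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .analytes import (
    ANALYTE_NAMES,
    DETECTABLE_ANALYTES,
    LOW_ABUNDANCE_ANALYTES,
    AnalytePanel,
)
from .panss import ITEM_NAMES, SUBSCALES, ItemScoreMatrix, RSWG_CRITERION, classify_remission

SUBTYPES: tuple[str, ...] = ("C1A", "C1B", "C2A", "C2B")

# ---------------------------------------------------------------------------
# Default calibration
# ---------------------------------------------------------------------------

# Sub-scale mean totals per subtype (positive / negative / general psychopathology)
_SUBSCALE_TOTALS = {
    "PPANSS": {"C1A": 24.6, "C1B": 17.2, "C2A": 21.3, "C2B": 14.0},
    "NPANSS": {"C1A": 25.7, "C1B": 24.9, "C2A": 14.5, "C2B": 13.5},
    "GPANSS": {"C1A": 47.8, "C1B": 37.5, "C2A": 36.9, "C2B": 27.6},
}

# Sparse informative item subsets per clustering split: the between-subtype
# separation is loaded onto these items only.
DEFAULT_INFORMATIVE_ITEMS: dict[str, tuple[str, ...]] = {
    # first-level split C1 vs C2: five negative + four general items
    "level1": ("N1", "N2", "N4", "N6", "N7", "G5", "G7", "G13", "G16"),
    # C1A vs C1B: four positive + four general items
    "C1": ("P1", "P2", "P3", "P5", "G1", "G2", "G6", "G9"),
    # C2A vs C2B: three positive + four general items
    "C2": ("P1", "P3", "P6", "G3", "G4", "G11", "G14"),
}


def default_item_signature(
    informative: Mapping[str, tuple[str, ...]] | None = None,
    subscale_totals: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-subtype per-item PANSS mean profile (4 x 30 DataFrame).

    The profile is built additively so that every clustering split's
    separation loads on that split's own informative items: the C1-vs-C2
    branch contrast sits on the level-1 items, the within-branch A-vs-B
    contrasts on the respective split items.  Whatever part of a sub-scale
    deviation has no informative item in that sub-scale (e.g. the positive
    sub-scale at level 1) is spread diffusely over all items of the
    sub-scale, so each subtype's sub-scale totals match the configured
    values exactly while between-subtype variance stays concentrated on the
    sparse subsets.
    """
    informative = dict(informative or DEFAULT_INFORMATIVE_ITEMS)
    totals = subscale_totals or _SUBSCALE_TOTALS
    branch_of = {"C1A": "C1", "C1B": "C1", "C2A": "C2", "C2B": "C2"}
    sig = pd.DataFrame(index=list(SUBTYPES), columns=list(ITEM_NAMES), dtype=float)
    for scale, items in SUBSCALES.items():
        items = list(items)
        grand_total = float(np.mean([totals[scale][st] for st in SUBTYPES]))
        base = grand_total / len(items)
        level1_items = [it for it in informative["level1"] if it in items]
        for st in SUBTYPES:
            branch = branch_of[st]
            sibling = [s for s in SUBTYPES if branch_of[s] == branch]
            branch_total = float(np.mean([totals[scale][s] for s in sibling]))
            branch_dev = branch_total - grand_total
            within_dev = totals[scale][st] - branch_total
            split_items = [it for it in informative[branch] if it in items]
            row = pd.Series(base, index=items)
            if level1_items:
                row[level1_items] += branch_dev / len(level1_items)
            else:
                row += branch_dev / len(items)
            if split_items:
                row[split_items] += within_dev / len(split_items)
            else:
                row += within_dev / len(items)
            sig.loc[st, items] = row
    return sig.clip(1.0, 7.0)


def default_analyte_base() -> pd.DataFrame:
    """Per-analyte log10 concentration mean and SD."""
    means = {
        "CCL2": 2.42, "CCL3": 1.18, "CCL4": 1.98, "CCL11": 2.18, "CCL13": 2.09,
        "CCL17": 2.47, "CCL19": 2.76, "CCL20": 1.42, "CCL22": 3.06, "CCL26": 0.81,
        "CCL27": 3.67, "CX3CL1": 4.27, "CXCL10": 2.23, "CXCL11": 2.06, "CXCL12": 3.45,
        "IL-6": 0.16, "IL-7": 1.15, "IL-8": 1.07, "IL-10": 0.12, "IL-12p40": 1.90,
        "IL-15": 0.45, "IL-16": 2.31, "IL-17": 0.40, "IL-18": 2.14, "IL-21": 0.99,
        "IL-23": 1.09, "IL-27": 3.02, "IFN-g": 0.70, "TNF-a": 0.41, "TNF-b": 0.07,
        "VEGF": 2.23, "sICAM-1": 5.59, "sVCAM-1": 5.80, "CRP": 6.03, "SAA": 6.40,
        # low-abundance cytokines near or below the detection limit
        "IL-1a": -0.20, "IL-1b": -0.30, "IL-2": -0.10, "IL-4": -0.60,
        "IL-5": -0.30, "IL-12p70": -0.40, "IL-13": -0.20, "GM-CSF": -0.50,
    }
    base = pd.DataFrame({"mean": pd.Series(means)})
    base["sd"] = 0.30
    return base.loc[list(ANALYTE_NAMES)]


def default_analyte_blocks() -> dict[str, str]:
    """Correlation-block membership: one cytokine block, one chemokine block,
    one vascular/acute-phase block."""
    blocks: dict[str, str] = {}
    for a in ANALYTE_NAMES:
        if a.startswith(("CCL", "CXCL", "CX3CL")):
            blocks[a] = "chemokine"
        elif a in ("VEGF", "sICAM-1", "sVCAM-1", "CRP", "SAA"):
            blocks[a] = "vascular"
        else:
            blocks[a] = "cytokine"
    return blocks


def default_llod_table(
    analyte_base: pd.DataFrame | None = None,
    censored_analytes: tuple[str, ...] = LOW_ABUNDANCE_ANALYTES,
    censored_quantile: float = 0.20,
) -> pd.Series:
    """Per-analyte LLOD on the log10 scale.

    Designated low-abundance analytes get their LLOD at the configured
    quantile of their own distribution (so their censored fraction clearly
    exceeds the 10% screening threshold); all other analytes get an LLOD far
    below their range.
    """
    from scipy.stats import norm

    base = analyte_base if analyte_base is not None else default_analyte_base()
    z = norm.ppf(censored_quantile)
    llod = base["mean"] - 6.0 * base["sd"]
    for a in censored_analytes:
        llod.loc[a] = base.loc[a, "mean"] + z * base.loc[a, "sd"]
    llod.name = "llod_log10"
    return llod


# Subtype-specific analyte effect targets: Cohen's d on the log10 scale for
# the subtype against all remaining patients.
DEFAULT_ANALYTE_EFFECTS: dict[tuple[str, str], float] = {
    ("C1A", "IL-7"): 0.36, ("C1A", "IL-15"): 0.50, ("C1A", "IL-17"): 0.42,
    ("C1A", "IFN-g"): 0.40, ("C1A", "TNF-a"): 0.34,
    ("C1A", "sICAM-1"): 0.37, ("C1A", "sVCAM-1"): 0.30,
    ("C2B", "IL-8"): 0.58, ("C2B", "CXCL12"): -0.36,
}


@dataclass(frozen=True)
class CovariateParams:
    """Per-subtype covariate distribution parameters."""

    male: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    waist_mean: float
    waist_sd: float
    drug_use: float
    toxo: float
    cmv: float
    hsv1: float


DEFAULT_COVARIATE_PARAMS: dict[str, CovariateParams] = {
    "C1A": CovariateParams(0.639, 25.9, 5.9, 23.3, 4.0, 83.2, 11.8, 0.392, 0.309, 0.606, 0.638),
    "C1B": CovariateParams(0.839, 25.6, 5.6, 23.8, 3.8, 85.2, 11.6, 0.387, 0.237, 0.458, 0.441),
    "C2A": CovariateParams(0.634, 27.0, 7.0, 23.2, 4.5, 82.3, 12.2, 0.538, 0.174, 0.609, 0.641),
    "C2B": CovariateParams(0.753, 26.2, 6.0, 23.0, 4.5, 82.8, 10.3, 0.644, 0.224, 0.522, 0.537),
}


@dataclass(frozen=True)
class OutcomeModel:
    """Per-subtype remission process.

    Every subtype has a base remission rate.  Within `risk_subtype` the
    non-remission probability is logistic(intercept + sum beta_j x_j) with
    beta_j = ln(odds_ratios[j]) on standardized continuous predictors and
    0/1 binary predictors; the intercept is solved so the marginal remission
    rate equals the subtype's base rate.  Other subtypes draw outcomes at
    their base rate, independent of biomarkers.
    """

    base_remission_rates: Mapping[str, float] = field(
        default_factory=lambda: {"C1A": 0.577, "C1B": 0.548, "C2A": 0.613, "C2B": 0.904}
    )
    risk_subtype: str = "C1A"
    # odds ratios for NON-remission; keys are analyte or covariate names
    odds_ratios: Mapping[str, float] = field(
        default_factory=lambda: {
            "IL-15": 0.585, "CXCL12": 1.369, "cmv_igg": 1.490,
            "drug_use": 1.393, "age": 0.804,
        }
    )

    BINARY_COVARIATES = ("drug_use", "cmv_igg", "toxo_igg", "hsv1_igg", "male")


@dataclass
class SyntheticCohortConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_patients: int = 325
    subtype_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"C1A": 97 / 325, "C1B": 62 / 325, "C2A": 95 / 325, "C2B": 71 / 325}
    )
    item_signature: pd.DataFrame = field(default_factory=default_item_signature)
    informative_items: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_INFORMATIVE_ITEMS)
    )
    severity_sd: float = 0.4
    item_noise_sd: float = 0.8
    analyte_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_EFFECTS)
    )
    analyte_base: pd.DataFrame = field(default_factory=default_analyte_base)
    analyte_blocks: Mapping[str, str] = field(default_factory=default_analyte_blocks)
    analyte_block_correlation: float = 0.3
    llod_table: pd.Series = field(default_factory=default_llod_table)
    censored_analyte_ids: tuple[str, ...] = LOW_ABUNDANCE_ANALYTES
    covariate_params: Mapping[str, CovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    # follow-up criterion-item generation (conditional on the remission label)
    followup_remitter_mean: float = 2.0
    followup_remitter_sd: float = 0.7
    followup_nonremitter_mean: float = 3.2
    followup_nonremitter_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients: must be non-negative")
        props = np.array([self.subtype_proportions[st] for st in SUBTYPES], dtype=float)
        if (props < 0).any():
            raise ValueError("subtype_proportions: negative fraction")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError(f"subtype_proportions: sum {props.sum()} != 1")
        if self.severity_sd < 0 or self.item_noise_sd < 0:
            raise ValueError("severity_sd/item_noise_sd: must be non-negative")
        if not (0.0 <= self.analyte_block_correlation < 1.0):
            raise ValueError("analyte_block_correlation: must be in [0, 1)")
        if (self.analyte_base["sd"] <= 0).any():
            raise ValueError("analyte_base: all SDs must be > 0")
        for st, rate in self.outcome_model.base_remission_rates.items():
            if not (0.0 < rate < 1.0):
                raise ValueError(f"outcome_model.base_remission_rates[{st}]: must be in (0, 1)")
        for (st, a) in self.analyte_effects:
            if a not in self.analyte_base.index:
                raise ValueError(f"analyte_effects: unknown analyte {a!r}")
            if st not in SUBTYPES:
                raise ValueError(f"analyte_effects: unknown subtype {st!r}")
        missing_llod = [a for a in self.analyte_base.index if a not in self.llod_table.index]
        if missing_llod:
            raise ValueError(f"llod_table: missing analytes {missing_llod}")

    def to_dict(self) -> dict:
        """JSON-serializable echo of the configuration."""
        return {
            "n_patients": self.n_patients,
            "subtype_proportions": dict(self.subtype_proportions),
            "item_signature": {st: self.item_signature.loc[st].to_dict() for st in SUBTYPES},
            "informative_items": {k: list(v) for k, v in self.informative_items.items()},
            "severity_sd": self.severity_sd,
            "item_noise_sd": self.item_noise_sd,
            "analyte_effects": {f"{st}:{a}": d for (st, a), d in self.analyte_effects.items()},
            "analyte_base": {a: [float(r["mean"]), float(r["sd"])] for a, r in self.analyte_base.iterrows()},
            "analyte_blocks": dict(self.analyte_blocks),
            "analyte_block_correlation": self.analyte_block_correlation,
            "llod_table": self.llod_table.to_dict(),
            "censored_analyte_ids": list(self.censored_analyte_ids),
            "covariate_params": {st: vars(p).copy() for st, p in self.covariate_params.items()},
            "outcome_model": {
                "base_remission_rates": dict(self.outcome_model.base_remission_rates),
                "risk_subtype": self.outcome_model.risk_subtype,
                "odds_ratios": dict(self.outcome_model.odds_ratios),
            },
            "followup": [
                self.followup_remitter_mean, self.followup_remitter_sd,
                self.followup_nonremitter_mean, self.followup_nonremitter_sd,
            ],
            "seed": self.seed,
        }


@dataclass
class SyntheticCohort:
    """A generated cohort with ground truth."""

    panss: ItemScoreMatrix
    followup_items: pd.DataFrame
    analytes: AnalytePanel
    covariates: pd.DataFrame
    remission: pd.Series
    true_subtype: pd.Series
    config: SyntheticCohortConfig

    def __post_init__(self) -> None:
        idx = self.panss.patient_ids
        for other in (self.followup_items.index, self.analytes.patient_ids,
                      self.covariates.index, self.remission.index, self.true_subtype.index):
            if not idx.equals(other):
                raise ValueError("cohort tables do not share identical patient identifiers")
        if len(idx):
            derived = classify_remission(self.followup_items)
            if not derived.equals(self.remission.astype(bool)):
                raise ValueError("remission label inconsistent with follow-up items under the RSWG rule")

    @property
    def n(self) -> int:
        return self.panss.m

    def write_csv(self, outdir: str | Path) -> dict[str, Path]:
        """Write panss/analytes/covariates/outcomes CSVs plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = outdir / "panss.csv"
        self.panss.values.rename_axis("patient_id").to_csv(p)
        paths["panss"] = p
        p = outdir / "analytes.csv"
        self.analytes.concentrations.rename_axis("patient_id").to_csv(p, float_format="%.10g")
        paths["analytes"] = p
        p = outdir / "covariates.csv"
        self.covariates.rename_axis("patient_id").to_csv(p, float_format="%.10g")
        paths["covariates"] = p
        p = outdir / "outcomes.csv"
        out = self.followup_items.copy()
        out["remission"] = self.remission.astype(bool)
        out.rename_axis("patient_id").to_csv(p)
        paths["outcomes"] = p
        p = outdir / "cohort.json"
        sidecar = {
            "config": self.config.to_dict(),
            "true_subtype": self.true_subtype.to_dict(),
            "llod": {a: float(10.0 ** v) for a, v in self.config.llod_table.items()},
        }
        p.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        paths["sidecar"] = p
        return paths


# ---------------------------------------------------------------------------
# Sub-generators
# ---------------------------------------------------------------------------


def _patient_index(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:04d}" for i in range(n)], name="patient_id")


def generate_subtypes(config: SyntheticCohortConfig, rng: np.random.Generator) -> pd.Series:
    props = [config.subtype_proportions[st] for st in SUBTYPES]
    labels = rng.choice(SUBTYPES, size=config.n_patients, p=props)
    return pd.Series(labels, index=_patient_index(config.n_patients), name="subtype")


def generate_covariates(
    subtypes: pd.Series, config: SyntheticCohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(subtypes)
    cov = pd.DataFrame(index=subtypes.index)
    cols = {
        "sex": np.empty(n, dtype=object), "age": np.empty(n), "bmi": np.empty(n),
        "waist": np.empty(n),
        "drug_use": np.empty(n, dtype=bool), "toxo_igg": np.empty(n, dtype=bool),
        "cmv_igg": np.empty(n, dtype=bool), "hsv1_igg": np.empty(n, dtype=bool),
    }
    arr = subtypes.to_numpy()
    for st in SUBTYPES:
        mask = arr == st
        k = int(mask.sum())
        if k == 0:
            continue
        p = config.covariate_params[st]
        cols["sex"][mask] = np.where(rng.random(k) < p.male, "male", "female")
        cols["age"][mask] = rng.normal(p.age_mean, p.age_sd, k)
        cols["bmi"][mask] = rng.normal(p.bmi_mean, p.bmi_sd, k)
        cols["waist"][mask] = rng.normal(p.waist_mean, p.waist_sd, k)
        cols["drug_use"][mask] = rng.random(k) < p.drug_use
        cols["toxo_igg"][mask] = rng.random(k) < p.toxo
        cols["cmv_igg"][mask] = rng.random(k) < p.cmv
        cols["hsv1_igg"][mask] = rng.random(k) < p.hsv1
    for name, vals in cols.items():
        cov[name] = vals
    return cov


def generate_analytes(
    subtypes: pd.Series, config: SyntheticCohortConfig, rng: np.random.Generator
) -> AnalytePanel:
    """Block-correlated log10-normal panel with subtype mean shifts and censoring flags."""
    for (st, a) in config.analyte_effects:
        if a not in config.analyte_base.index:
            raise ValueError(f"effect requested for unknown analyte {a!r}")
    n = len(subtypes)
    analyte_names = list(config.analyte_base.index)
    mu = config.analyte_base["mean"].to_numpy()
    sd = config.analyte_base["sd"].to_numpy()
    rho = config.analyte_block_correlation
    blocks = pd.Series({a: config.analyte_blocks.get(a, "_solo") for a in analyte_names})
    block_names = sorted(blocks.unique())
    shared = {b: rng.standard_normal(n) for b in block_names}
    eps = rng.standard_normal((n, len(analyte_names)))
    z = np.empty_like(eps)
    for j, a in enumerate(analyte_names):
        z[:, j] = np.sqrt(rho) * shared[blocks[a]] + np.sqrt(1.0 - rho) * eps[:, j]
    log10 = mu[None, :] + sd[None, :] * z
    # subtype shifts: d * SD added to members of the target subtype
    arr = subtypes.to_numpy()
    for (st, a), d in config.analyte_effects.items():
        j = analyte_names.index(a)
        log10[arr == st, j] += d * sd[j]
    conc = pd.DataFrame(10.0 ** log10, index=subtypes.index, columns=analyte_names)
    llod_raw = pd.Series(
        {a: 10.0 ** config.llod_table[a] for a in analyte_names}, name="llod"
    )
    return AnalytePanel(concentrations=conc, llod=llod_raw)


def _resolve_predictors(
    odds_ratios: Mapping[str, float],
    analytes: AnalytePanel,
    covariates: pd.DataFrame,
    mask: np.ndarray,
    binary_names: tuple[str, ...],
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the risk-subtype outcome model.

    Continuous variables (log10 analytes, age, ...) are standardized within
    the risk subtype; binary covariates enter 0/1.
    """
    cols = []
    names = []
    for var in odds_ratios:
        if var in analytes.concentrations.columns:
            x = np.log10(analytes.concentrations[var].to_numpy()[mask])
            binary = False
        elif var in covariates.columns:
            raw = covariates[var]
            if var in binary_names:
                x = raw.to_numpy()[mask].astype(float)
                binary = True
            elif var == "sex":
                x = (raw.to_numpy()[mask] == "male").astype(float)
                binary = True
            else:
                x = raw.to_numpy()[mask].astype(float)
                binary = False
        else:
            raise ValueError(f"outcome model variable {var!r} is neither an analyte nor a covariate")
        if not binary:
            s = x.std(ddof=0)
            x = (x - x.mean()) / s if s > 0 else x - x.mean()
        cols.append(x)
        names.append(var)
    return np.column_stack(cols) if cols else np.empty((int(mask.sum()), 0)), names


def solve_logistic_intercept(eta: np.ndarray, target_mean: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target_mean, by root bracketing."""
    if not (0.0 < target_mean < 1.0):
        raise ValueError("target rate must be strictly inside (0, 1)")

    def f(c: float) -> float:
        return float(expit(c + eta).mean() - target_mean)

    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def generate_outcomes(
    subtypes: pd.Series,
    analytes: AnalytePanel,
    covariates: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Per-patient remission labels (True = remitter)."""
    model = config.outcome_model
    n = len(subtypes)
    remission = np.zeros(n, dtype=bool)
    arr = subtypes.to_numpy()
    for st in SUBTYPES:
        mask = arr == st
        k = int(mask.sum())
        if k == 0:
            continue
        rate = model.base_remission_rates[st]
        if st == model.risk_subtype and model.odds_ratios:
            X, _ = _resolve_predictors(
                model.odds_ratios, analytes, covariates, mask, model.BINARY_COVARIATES
            )
            beta = np.log(np.array([model.odds_ratios[v] for v in model.odds_ratios]))
            eta = X @ beta
            c = solve_logistic_intercept(eta, 1.0 - rate)  # P(non-remission)
            p_nonrem = expit(c + eta)
            remission[mask] = rng.random(k) >= p_nonrem
        else:
            remission[mask] = rng.random(k) < rate
    return pd.Series(remission, index=subtypes.index, name="remission")


def generate_panss(
    subtypes: pd.Series,
    config: SyntheticCohortConfig,
    remission: pd.Series,
    rng: np.random.Generator,
) -> tuple[ItemScoreMatrix, pd.DataFrame]:
    """Baseline 30-item scores plus follow-up criterion items.

    Baseline: item = clip(round(subtype item mean + shared severity factor +
    item noise), 1, 7).  Follow-up criterion items are drawn conditionally on
    the remission label so the RSWG rule is satisfied exactly.
    """
    unknown = set(subtypes.unique()) - set(config.item_signature.index)
    if unknown:
        raise ValueError(f"subtype labels without item signature: {sorted(unknown)}")
    n = len(subtypes)
    means = config.item_signature.loc[subtypes.to_numpy()].to_numpy()
    severity = rng.normal(0.0, config.severity_sd, size=n) if config.severity_sd > 0 else np.zeros(n)
    noise = (
        rng.normal(0.0, config.item_noise_sd, size=means.shape)
        if config.item_noise_sd > 0
        else np.zeros_like(means)
    )
    scores = np.clip(np.round(means + severity[:, None] + noise), 1, 7).astype(int)
    panss = ItemScoreMatrix(pd.DataFrame(scores, index=subtypes.index, columns=list(ITEM_NAMES)))

    crit = RSWG_CRITERION
    rem = remission.to_numpy().astype(bool)
    fu = np.empty((n, len(crit.items)), dtype=int)
    rem_draw = np.clip(
        np.round(rng.normal(config.followup_remitter_mean, config.followup_remitter_sd, (n, 8))),
        1, crit.cutoff,
    ).astype(int)
    non_draw = np.clip(
        np.round(rng.normal(config.followup_nonremitter_mean, config.followup_nonremitter_sd, (n, 8))),
        1, 7,
    ).astype(int)
    # force at least one item above the cutoff for non-remitters
    needs_fix = ~rem & (non_draw <= crit.cutoff).all(axis=1)
    fix_item = rng.integers(0, 8, size=n)
    fix_value = rng.integers(crit.cutoff + 1, 7, size=n, endpoint=True)
    non_draw[needs_fix, fix_item[needs_fix]] = fix_value[needs_fix]
    fu[rem] = rem_draw[rem]
    fu[~rem] = non_draw[~rem]
    followup = pd.DataFrame(fu, index=subtypes.index, columns=list(crit.items))
    return panss, followup


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Master generator: deterministic given `config.seed`."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_sub, rng_cov, rng_ana, rng_out, rng_panss = (np.random.default_rng(s) for s in ss.spawn(5))
    subtypes = generate_subtypes(config, rng_sub)
    covariates = generate_covariates(subtypes, config, rng_cov)
    analytes = generate_analytes(subtypes, config, rng_ana)
    remission = generate_outcomes(subtypes, analytes, covariates, config, rng_out)
    panss, followup = generate_panss(subtypes, config, remission, rng_panss)
    return SyntheticCohort(
        panss=panss,
        followup_items=followup,
        analytes=analytes,
        covariates=covariates,
        remission=remission,
        true_subtype=subtypes,
        config=config,
    )


def oracle_bayes_auc(
    config: SyntheticCohortConfig, n_mc: int = 1_000_000, seed: int | None = None
) -> float:
    """Monte-Carlo Bayes-optimal AUC of the risk-subtype outcome model.

    Simulates the true linear predictor for non-remission (continuous
    predictors as unit-variance normals, binary predictors at their
    within-subtype prevalence), draws outcomes from the logistic model with
    the intercept solved for the subtype's base rate, and measures the AUC
    of the linear predictor itself.  This is the ceiling any fitted
    classifier can reach on cohorts from this generator.
    """
    from sklearn.metrics import roc_auc_score

    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    model = config.outcome_model
    params = config.covariate_params[model.risk_subtype]
    prevalence = {"drug_use": params.drug_use, "cmv_igg": params.cmv,
                  "toxo_igg": params.toxo, "hsv1_igg": params.hsv1, "male": params.male}
    rng = np.random.default_rng(seed)
    eta = np.zeros(n_mc)
    for var, orr in model.odds_ratios.items():
        beta = np.log(orr)
        if var in model.BINARY_COVARIATES or var == "sex":
            key = "male" if var == "sex" else var
            x = (rng.random(n_mc) < prevalence[key]).astype(float)
        else:
            x = rng.standard_normal(n_mc)
        eta += beta * x
    rate = model.base_remission_rates[model.risk_subtype]
    if np.ptp(eta) == 0:
        return 0.5
    c = solve_logistic_intercept(eta, 1.0 - rate)
    y = rng.random(n_mc) < expit(c + eta)  # 1 = non-remitter
    return float(roc_auc_score(y, eta))
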