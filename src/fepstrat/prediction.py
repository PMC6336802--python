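"""Repeated-cross-validation elastic-net ensemble for remission prediction.

The estimand is the odds of NON-remission (RSWG criterion not met after
treatment) within a patient subtype, as a function of log serum analyte
levels and clinical covariates.  The procedure repeats stratified five-fold
cross-validation over many independent random partitions; per partition the
elastic-net hyper-parameters (mixing alpha, strength lambda) are tuned
among a small set of candidates by cross-validated AUC, and every fold fit
at the tuned pair constitutes one "drawing".  Ensemble summaries are:

* selection proportion - fraction of drawings in which a variable's
  coefficient is nonzero;
* weighted odds ratio - mean of exp(coefficient) over the drawings where
  the variable was selected (its selection proportion is reported
  alongside; an alternative reading that scales the log-OR by the
  proportion is available behind a flag);
* permutation p-values - a single elastic net refit at the mean alpha and
  mean lambda, compared with refits on outcome-permuted data;
* held-out AUC / sensitivity / specificity per drawing.

Penalised logistic fits use scikit-learn's saga solver with the glmnet
parameterisation lambda*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2) mapped to
C = 1/(n*lambda), l1_ratio = alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

BINARY_HINTS = ("drug_use", "cmv_igg", "toxo_igg", "hsv1_igg", "male", "sex")


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Model matrix: standardized continuous columns, 0/1 binaries.

    Stores the centering/scaling used so raw values can be recovered and
    new data mapped consistently.
    """

    X: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    binary_columns: list[str]
    dropped_patients: list = field(default_factory=list)

    @property
    def variable_names(self) -> list[str]:
        return list(self.X.columns)

    def unstandardize(self, column: str) -> pd.Series:
        if column in self.binary_columns:
            return self.X[column]
        return self.X[column] * self.scale[column] + self.center[column]


def build_features(
    log_table: pd.DataFrame | None,
    covariates: pd.DataFrame | None = None,
) -> FeatureTable:
    """Concatenate log analyte levels and covariates into a model matrix.

    Binary covariates are encoded 0/1 ("sex" becomes `male`=1); continuous
    columns are z-scored.  Patients with any missing value are dropped
    (complete-case analysis).
    """
    parts = []
    if log_table is not None:
        parts.append(log_table.copy())
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns:
            cov["male"] = (cov.pop("sex") == "male").astype(float)
        for c in cov.columns:
            if cov[c].dtype == bool:
                cov[c] = cov[c].astype(float)
        parts.append(cov)
    if not parts:
        raise ValueError("no feature sources given")
    common = parts[0].index
    for p in parts[1:]:
        common = common.intersection(p.index)
    if len(common) == 0:
        raise ValueError("no overlapping patient identifiers between feature tables")
    X = pd.concat([p.loc[common] for p in parts], axis=1).astype(float)
    complete = X.notna().all(axis=1)
    dropped = list(X.index[~complete])
    X = X.loc[complete]
    binary_cols = [
        c for c in X.columns
        if c in BINARY_HINTS or set(X[c].dropna().unique()) <= {0.0, 1.0}
    ]
    center = pd.Series(0.0, index=X.columns)
    scale = pd.Series(1.0, index=X.columns)
    for c in X.columns:
        if c in binary_cols:
            continue
        center[c] = X[c].mean()
        s = X[c].std(ddof=0)
        scale[c] = s if s > 0 else 1.0
        X[c] = (X[c] - center[c]) / scale[c]
    return FeatureTable(
        X=X, center=center, scale=scale, binary_columns=binary_cols, dropped_patients=dropped
    )


# ---------------------------------------------------------------------------
# Ensemble configuration
# ---------------------------------------------------------------------------


@dataclass
class EnsembleConfig:
    """Knobs of the repeated-partition elastic-net ensemble.

    Total drawings D = n_partitions * n_folds; the default 400 x 5 = 2000.
    `n_tune` candidate (alpha, lambda) pairs are evaluated per partition:
    alpha from a fixed grid on [0.05, 1], lambda drawn per partition from a
    data-derived log-spaced path below the smallest lambda that zeroes all
    coefficients.
    """

    n_partitions: int = 400
    n_folds: int = 5
    n_tune: int = 10
    alpha_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.05, 1.0, 10), 4))
    lambda_path_length: int = 50
    lambda_min_ratio: float = 1e-3
    permutations: int = 199
    threshold: float = 0.5
    seed: int | None = None
    max_iter: int = 2000
    tol: float = 1e-4

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")

    @property
    def n_drawings(self) -> int:
        return self.n_partitions * self.n_folds


def _penalty_scale(X: np.ndarray) -> np.ndarray:
    """Per-column SD used to put every predictor on the same penalty scale
    (glmnet's internal standardization); constant columns scale by 1."""
    sd = X.std(axis=0, ddof=0)
    return np.where(sd > 0, sd, 1.0)


def _enet_fit(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float, max_iter: int, tol: float
) -> tuple[np.ndarray, float]:
    """One penalised logistic fit in glmnet parameterisation.

    Columns are standardized internally so the penalty treats 0/1 binaries
    and unit-variance continuous predictors alike; the returned
    coefficients are back-transformed to the original column coding.
    """
    n = len(y)
    sd = _penalty_scale(X)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        C=1.0 / (n * lam),
        max_iter=max_iter,
        tol=tol,
        random_state=0,  # saga shuffles internally; pin for reproducibility
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X / sd, y)
    return clf.coef_[0] / sd, float(clf.intercept_[0])


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty zeroing every coefficient (glmnet convention, on
    the internally standardized predictors)."""
    n = len(y)
    resid = y - y.mean()
    return float(np.abs((X / _penalty_scale(X)).T @ resid).max() / (n * max(alpha, 0.05)))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class PerformanceSummary:
    mean_auc: float
    sd_auc: float
    sensitivity: float
    sd_sensitivity: float
    specificity: float
    sd_specificity: float
    threshold: float
    youden_threshold: float
    n_excluded_drawings: int


@dataclass
class EnsembleResults:
    """Fitted ensemble: per-variable selection statistics and per-drawing
    held-out performance."""

    variable_names: list[str]
    coefs: np.ndarray = field(repr=False)  # D x v
    selected: np.ndarray = field(repr=False)  # D x v boolean
    alphas: np.ndarray = field(repr=False)  # per drawing
    lambdas: np.ndarray = field(repr=False)
    heldout: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)  # (y_true, p_hat)
    config: EnsembleConfig = field(repr=False, default=None)
    model: "RemissionEnsemble" = field(repr=False, default=None)
    permutation_p: pd.Series | None = None

    # -- per-variable summaries -------------------------------------------
    @property
    def n_drawings(self) -> int:
        return self.coefs.shape[0]

    @property
    def selection_proportions(self) -> pd.Series:
        return pd.Series(
            self.selected.mean(axis=0), index=self.variable_names, name="selection_proportion"
        )

    @property
    def mean_alpha(self) -> tuple[float, float]:
        return float(self.alphas.mean()), float(self.alphas.std(ddof=0))

    @property
    def mean_lambda(self) -> tuple[float, float]:
        return float(self.lambdas.mean()), float(self.lambdas.std(ddof=0))

    def weighted_odds_ratios(self, mode: str = "selected-mean") -> pd.DataFrame:
        return weighted_odds_ratios(self.coefs, self.selected, self.variable_names, mode=mode)

    def compute_permutation_pvalues(self, B: int | None = None, seed: int | None = None) -> pd.Series:
        if self.model is None:
            raise RuntimeError("results are detached from their model")
        B = self.config.permutations if B is None else B
        a, _ = self.mean_alpha
        l, _ = self.mean_lambda
        self.permutation_p = permutation_pvalues(
            self.model.X, self.model.y, a, l, B=B, seed=seed,
            max_iter=self.config.max_iter, tol=self.config.tol,
            variable_names=self.variable_names,
        )
        return self.permutation_p

    def evaluate_performance(self, threshold: float | None = None) -> PerformanceSummary:
        return evaluate_performance(self.heldout, self.config.threshold if threshold is None else threshold)

    @property
    def heldout_aucs(self) -> np.ndarray:
        aucs = []
        for y, p in self.heldout:
            if len(np.unique(y)) == 2:
                aucs.append(roc_auc_score(y, p))
        return np.asarray(aucs)

    def summary(self) -> str:
        ors = self.weighted_odds_ratios()
        table = pd.DataFrame(
            {
                "selection": self.selection_proportions.round(3),
                "weighted_OR": ors["weighted_or"].round(3),
                "OR_sd": ors["or_sd"].round(3),
            }
        )
        if self.permutation_p is not None:
            table["perm_p"] = self.permutation_p.round(4)
        table = table.sort_values("selection", ascending=False)
        perf = self.evaluate_performance()
        a, asd = self.mean_alpha
        l, lsd = self.mean_lambda
        head = [
            "Elastic-net remission ensemble (outcome: non-remission)",
            f"  drawings: {self.n_drawings}  (partitions x folds)",
            f"  mean alpha: {a:.3f} +/- {asd:.3f}   mean lambda: {l:.3f} +/- {lsd:.3f}",
            f"  held-out AUC: {perf.mean_auc:.3f} +/- {perf.sd_auc:.3f}",
            f"  sensitivity: {perf.sensitivity:.3f} +/- {perf.sd_sensitivity:.3f}  "
            f"specificity: {perf.specificity:.3f} +/- {perf.sd_specificity:.3f} "
            f"(threshold {perf.threshold})",
            "",
        ]
        return "\n".join(head) + table.to_string()


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class RemissionEnsemble:
    """Elastic-net ensemble model for non-remission within a subtype.

    Parameters
    ----------
    features
        FeatureTable or DataFrame (already standardized / encoded).
    outcome
        Boolean per patient, True = NON-remitter (the positive class).
    config
        EnsembleConfig; defaults mirror 400 partitions x 5 folds.
    """

    def __init__(self, features, outcome, config: EnsembleConfig | None = None):
        if isinstance(features, FeatureTable):
            self.feature_table = features
            Xdf = features.X
        else:
            Xdf = pd.DataFrame(features)
            self.feature_table = None
        y = np.asarray(outcome, dtype=bool)
        if y.shape[0] != Xdf.shape[0]:
            raise ValueError("outcome length does not match features")
        if y.all() or not y.any():
            raise ValueError("both outcome classes must be present")
        self.X = Xdf.to_numpy(dtype=float)
        self.Xdf = Xdf
        self.y = y.astype(int)
        self.variable_names = list(Xdf.columns)
        self.config = config or EnsembleConfig()
        self.config.validate()
        if Xdf.shape[0] < self.config.n_folds:
            raise ValueError("fewer patients than folds")

    def _candidates(self, X, y, rng) -> list[tuple[float, float]]:
        cfg = self.config
        alphas = list(cfg.alpha_grid)
        if len(alphas) > cfg.n_tune:
            alphas = list(rng.choice(alphas, size=cfg.n_tune, replace=False))
        pairs = []
        for a in alphas:
            lmax = lambda_max(X, y, a)
            path = np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.lambda_path_length)
            pairs.append((float(a), float(rng.choice(path))))
        return pairs

    def fit(self, seed: int | None = None) -> EnsembleResults:
        """Run the repeated-partition ensemble.

        Per partition: a stratified five-fold split; each candidate
        (alpha, lambda) pair is scored by the mean held-out AUC over the
        folds; the winning pair's five fold-fits become the partition's
        drawings (held-out AUC, nonzero-coefficient indicators and
        coefficients recorded per drawing).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        D = cfg.n_drawings
        v = len(self.variable_names)
        coefs = np.zeros((D, v))
        selected = np.zeros((D, v), dtype=bool)
        alphas = np.zeros(D)
        lambdas = np.zeros(D)
        heldout: list[tuple[np.ndarray, np.ndarray]] = []
        d = 0
        for part, child in enumerate(ss.spawn(cfg.n_partitions)):
            rng = np.random.default_rng(child)
            skf = StratifiedKFold(
                n_splits=cfg.n_folds, shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            folds = list(skf.split(self.X, self.y))
            pairs = self._candidates(self.X, self.y, rng)
            scored = []
            for a, lam in pairs:
                fold_fits = []
                aucs = []
                for tr, te in folds:
                    co, ic = _enet_fit(
                        self.X[tr], self.y[tr], a, lam, cfg.max_iter, cfg.tol
                    )
                    score = self.X[te] @ co + ic
                    if len(np.unique(self.y[te])) == 2:
                        aucs.append(roc_auc_score(self.y[te], score))
                    fold_fits.append((co, ic))
                mean_auc = float(np.mean(aucs)) if aucs else 0.5
                scored.append((mean_auc, a, lam, fold_fits))
            # tuned pair: maximal cross-validated AUC; ties -> first candidate
            best = scored[0]
            for cand in scored[1:]:
                if cand[0] > best[0] + 1e-12:
                    best = cand
            _, a, lam, fold_fits = best
            for (tr, te), (co, ic) in zip(folds, fold_fits):
                coefs[d] = co
                selected[d] = co != 0.0
                alphas[d] = a
                lambdas[d] = lam
                from scipy.special import expit

                p_hat = expit(self.X[te] @ co + ic)
                heldout.append((self.y[te].copy(), p_hat))
                d += 1
        return EnsembleResults(
            variable_names=self.variable_names,
            coefs=coefs,
            selected=selected,
            alphas=alphas,
            lambdas=lambdas,
            heldout=heldout,
            config=cfg,
            model=self,
        )

    def refit_reduced(
        self, variable_subset: list[str], config: EnsembleConfig | None = None,
        seed: int | None = None,
    ) -> EnsembleResults:
        """Identical ensemble restricted to a subset of the variables."""
        unknown = [vn for vn in variable_subset if vn not in self.variable_names]
        if unknown:
            raise ValueError(f"unknown variables: {unknown}")
        if not variable_subset:
            raise ValueError("variable subset is empty")
        sub = RemissionEnsemble(self.Xdf[list(variable_subset)], self.y.astype(bool),
                                config or self.config)
        return sub.fit(seed=seed)


def fit_enet_ensemble(features, outcome, config: EnsembleConfig | None = None,
                      seed: int | None = None) -> EnsembleResults:
    """Functional wrapper around :class:`RemissionEnsemble`."""
    return RemissionEnsemble(features, outcome, config).fit(seed=seed)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def weighted_odds_ratios(
    coefs: np.ndarray, selected: np.ndarray, variable_names: list[str],
    mode: str = "selected-mean",
) -> pd.DataFrame:
    """Frequency-weighted odds ratios across drawings.

    `selected-mean` (default): OR = mean of exp(coefficient) over the
    drawings where the variable was selected, with the SD over those
    drawings; a never-selected variable reports OR 1 with proportion 0.
    `proportion-scaled`: OR = exp(proportion * mean selected coefficient),
    the alternative reading where the selection proportion multiplies the
    log-odds.
    """
    if mode not in ("selected-mean", "proportion-scaled"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    prop = selected.mean(axis=0)
    for j, name in enumerate(variable_names):
        sel = selected[:, j]
        if not sel.any():
            rows.append({"selection_proportion": 0.0, "weighted_or": 1.0, "or_sd": 0.0})
            continue
        ors = np.exp(coefs[sel, j])
        if mode == "selected-mean":
            wor = float(ors.mean())
        else:
            wor = float(np.exp(prop[j] * coefs[sel, j].mean()))
        sd = float(ors.std(ddof=1)) if sel.sum() > 1 else 0.0
        rows.append({"selection_proportion": float(prop[j]), "weighted_or": wor, "or_sd": sd})
    return pd.DataFrame(rows, index=variable_names)


def permutation_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    mean_alpha: float,
    mean_lambda: float,
    B: int = 199,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-4,
    variable_names: list[str] | None = None,
) -> pd.Series:
    """Per-variable permutation p at fixed (mean alpha, mean lambda).

    A single elastic net is fitted on the observed outcome; the outcome is
    then permuted B times and the model refitted.  p = (1 + #{|b_perm| >=
    |b_obs|}) / (B + 1) per variable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    obs, _ = _enet_fit(X, y, mean_alpha, mean_lambda, max_iter, tol)
    rng = np.random.default_rng(seed)
    count = np.zeros(X.shape[1])
    for _ in range(B):
        yp = rng.permutation(y)
        if yp.min() == yp.max():  # cannot happen after class check, kept defensive
            continue
        co, _ = _enet_fit(X, yp, mean_alpha, mean_lambda, max_iter, tol)
        count += np.abs(co) >= np.abs(obs) - 1e-15
    p = (1.0 + count) / (B + 1.0)
    idx = variable_names if variable_names is not None else range(X.shape[1])
    return pd.Series(p, index=idx, name="perm_p")


def evaluate_performance(
    heldout: list[tuple[np.ndarray, np.ndarray]], threshold: float = 0.5
) -> PerformanceSummary:
    """AUC / sensitivity / specificity across held-out drawings.

    Sensitivity and specificity are for predicting non-remission (the
    positive class) at the probability threshold; drawings without held-out
    positives (or negatives) have the undefined quantity excluded.  A
    Youden-optimal threshold (maximizing TPR - FPR on the ROC, averaged
    across drawings) is reported alongside.
    """
    aucs, sens, spec, youden = [], [], [], []
    excluded = 0
    for y, p in heldout:
        y = np.asarray(y).astype(int)
        pos = y == 1
        has_both = pos.any() and (~pos).any()
        if has_both:
            aucs.append(roc_auc_score(y, p))
            fpr, tpr, thr = roc_curve(y, p)
            j = int(np.argmax(tpr - fpr))
            youden.append(thr[j])
        else:
            excluded += 1
        pred = p >= threshold
        if pos.any():
            sens.append(float(pred[pos].mean()))
        if (~pos).any():
            spec.append(float((~pred[~pos]).mean()))

    def ms(vals):
        if not vals:
            return float("nan"), float("nan")
        a = np.asarray(vals, dtype=float)
        return float(a.mean()), float(a.std(ddof=0))

    mean_auc, sd_auc = ms(aucs)
    mean_sens, sd_sens = ms(sens)
    mean_spec, sd_spec = ms(spec)
    finite_youden = [t for t in youden if np.isfinite(t)]
    yt = float(np.mean(finite_youden)) if finite_youden else float("nan")
    return PerformanceSummary(
        mean_auc=mean_auc, sd_auc=sd_auc,
        sensitivity=mean_sens, sd_sensitivity=sd_sens,
        specificity=mean_spec, sd_specificity=sd_spec,
        threshold=threshold, youden_threshold=yt,
        n_excluded_drawings=excluded,
    )
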