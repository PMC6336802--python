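"""End-to-end pipeline: simulate/ingest -> cluster -> validate -> screen -> predict.

A single flat YAML config drives all stages; per-stage seeds are derived
from one master seed through a fixed spawn order (simulate, cluster,
validate, screen, predict), so a run is reproducible bit-for-bit from its
manifest.  Each stage writes plain CSV/JSON artifacts plus one line of
structured logging; the manifest records seeds, config echo, software
version and SHA-256 digests of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytes import ANALYTE_NAMES, AnalytePanel, suggest_analyte_name
from .biomarkers import llod_filter, log_transform, subtype_enrichment, univariate_compare
from .cluster import HierarchicalKSparse
from .panss import ITEM_NAMES, RSWG_CRITERION, ItemScoreMatrix, classify_remission
from .prediction import EnsembleConfig, RemissionEnsemble, build_features
from .simulate import SUBTYPES, SyntheticCohortConfig, generate_cohort
from .validate import crossvalidate_clustering, pca_kmeans, silhouette_report

log = logging.getLogger("fepstrat")

STAGES = ("simulate", "cluster", "validate", "screen", "predict")


@dataclass
class PipelineConfig:
    """Flat configuration of a full run."""

    n_patients: int = 325
    input_dir: str | None = None  # read an existing cohort instead of simulating
    s_level1: int | None = 9
    s_c1: int | None = 8
    s_c2: int | None = 7
    n_starts: int = 20
    stability_drawings: int = 50
    split_fraction: float = 0.8
    enrichment_drawings: int = 10_000
    q_threshold: float = 0.1
    predict_subtype: str = "C1A"
    predict_variables: list[str] | None = None  # None = all features
    n_partitions: int = 20
    n_folds: int = 5
    permutations: int = 199
    threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.predict_subtype not in SUBTYPES:
            raise ValueError(
                f"predict_subtype must be one of {SUBTYPES}, got {self.predict_subtype!r}"
            )
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)
    failure: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seeds(master: int) -> dict[str, int]:
    """Per-stage seeds: fixed-order spawn of the master SeedSequence."""
    ss = np.random.SeedSequence(master)
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, ss.spawn(len(STAGES)))
    }


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------


def read_cohort(indir: str | Path) -> dict[str, Any]:
    """Load and schema-check a cohort directory written by the simulator
    (or assembled by hand in the same layout).

    Expects panss.csv, analytes.csv, covariates.csv, outcomes.csv sharing a
    `patient_id` column, plus cohort.json carrying the per-analyte LLOD.
    """
    indir = Path(indir)
    problems: list[str] = []

    def load(name: str) -> pd.DataFrame:
        path = indir / name
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        df = pd.read_csv(path)
        if "patient_id" not in df.columns:
            raise ValueError(f"{name}: missing patient_id column")
        return df.set_index("patient_id")

    panss_df = load("panss.csv")
    missing_items = [it for it in ITEM_NAMES if it not in panss_df.columns]
    if missing_items:
        problems.append(f"panss.csv: missing items {missing_items}")
    extra = [c for c in panss_df.columns if c not in ITEM_NAMES]
    if extra:
        problems.append(f"panss.csv: unknown columns {extra}")
    if not problems:
        vals = panss_df[list(ITEM_NAMES)]
        bad = (vals < 1) | (vals > 7) | vals.isna()
        if bad.to_numpy().any():
            rows = [
                f"patient {pid} item {item}"
                for pid, row in bad.iterrows() for item, v in row.items() if v
            ]
            problems.append("panss.csv: scores outside 1-7 at " + "; ".join(rows[:10]))

    analytes_df = load("analytes.csv")
    for c in analytes_df.columns:
        if c not in ANALYTE_NAMES:
            hint = suggest_analyte_name(c)
            msg = f"analytes.csv: unknown analyte column {c!r}"
            if hint:
                msg += f" (did you mean {hint!r}?)"
            problems.append(msg)

    covariates_df = load("covariates.csv")
    required_cov = ["sex", "age", "bmi", "waist", "drug_use", "toxo_igg", "cmv_igg", "hsv1_igg"]
    miss = [c for c in required_cov if c not in covariates_df.columns]
    if miss:
        problems.append(f"covariates.csv: missing columns {miss}")

    outcomes_df = load("outcomes.csv")
    miss = [c for c in RSWG_CRITERION.items if c not in outcomes_df.columns]
    if miss:
        problems.append(f"outcomes.csv: missing criterion items {miss}")

    sizes = {len(panss_df), len(analytes_df), len(covariates_df), len(outcomes_df)}
    if len(sizes) != 1:
        problems.append(f"tables have inconsistent patient counts: {sorted(sizes)}")

    if problems:
        raise ValueError("cohort validation failed:\n  " + "\n  ".join(problems))

    sidecar_path = indir / "cohort.json"
    llod = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        llod = pd.Series(sidecar.get("llod", {}), dtype=float)
    if llod is None or llod.empty:
        raise ValueError("cohort.json with per-analyte LLOD values is required")

    panel = AnalytePanel(concentrations=analytes_df.astype(float), llod=llod)
    return {
        "panss": ItemScoreMatrix(panss_df[list(ITEM_NAMES)].astype(int)),
        "analytes": panel,
        "covariates": covariates_df,
        "followup": outcomes_df[list(RSWG_CRITERION.items)].astype(int),
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute all stages, writing artifacts and a run manifest to `outdir`."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    if seed is not None:
        config.seed = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(config=config.__dict__.copy(), seeds=seeds, version=__version__)
    summary_lines: list[str] = []
    written: list[Path] = []
    current_stage = "simulate"
    try:
        # -- stage 1: cohort ------------------------------------------------
        t0 = time.perf_counter()
        if config.input_dir:
            data = read_cohort(config.input_dir)
            panss, panel = data["panss"], data["analytes"]
            covariates, followup = data["covariates"], data["followup"]
        else:
            sim_cfg = SyntheticCohortConfig(n_patients=config.n_patients, seed=seeds["simulate"])
            cohort = generate_cohort(sim_cfg)
            written.extend(cohort.write_csv(outdir).values())
            panss, panel = cohort.panss, cohort.analytes
            covariates, followup = cohort.covariates, cohort.followup_items
        remission = classify_remission(followup)
        log.info("simulate: m=%d analytes=%d elapsed=%.2fs",
                 panss.m, len(panel.analyte_names), time.perf_counter() - t0)
        summary_lines += [
            f"patients: {panss.m}",
            f"remission rate: {remission.mean():.1%} "
            f"(criterion: items {', '.join(RSWG_CRITERION.items)} all <= {RSWG_CRITERION.cutoff})",
        ]

        # -- stage 2: clustering --------------------------------------------
        current_stage = "cluster"
        t0 = time.perf_counter()
        hier = HierarchicalKSparse(
            panss,
            s_level1=config.s_level1,
            s_within={"C1": config.s_c1, "C2": config.s_c2},
            n_starts=config.n_starts,
        ).fit(seed=seeds["cluster"])
        subtype = hier.final_labels
        labels_df = pd.DataFrame(
            {
                "level1": subtype.str[:2],
                "subtype": subtype,
            }
        )
        p = outdir / "labels.csv"
        labels_df.rename_axis("patient_id").to_csv(p)
        written.append(p)
        p = outdir / "weights.csv"
        w1 = pd.DataFrame(
            hier.level1.weights, index=hier.level1.columns,
            columns=[f"level1_{hier.branch_of_cluster[j]}" for j in range(2)],
        )
        parts = [w1]
        for b, res in hier.level2.items():
            if res is not None:
                parts.append(pd.DataFrame(
                    res.weights, index=res.columns,
                    columns=[f"{b}_{j}" for j in range(2)],
                ))
        pd.concat(parts, axis=1).rename_axis("item").to_csv(p, float_format="%.10g")
        written.append(p)
        run_info = {
            "seed": seeds["cluster"],
            "per_split_s": hier.per_split_s,
            "objective": {"level1": hier.level1.objective,
                          **{b: (r.objective if r else None) for b, r in hier.level2.items()}},
            "n_iter": {"level1": hier.level1.n_iter,
                       **{b: (r.n_iter if r else None) for b, r in hier.level2.items()}},
        }
        p = outdir / "clustering.json"
        p.write_text(json.dumps(run_info, indent=1, sort_keys=True))
        written.append(p)
        counts = subtype.value_counts()
        log.info("cluster: sizes=%s elapsed=%.2fs", counts.to_dict(), time.perf_counter() - t0)
        summary_lines.append(
            "subtypes: " + ", ".join(f"{st}={int(counts.get(st, 0))}" for st in SUBTYPES)
        )

        # -- stage 3: validation --------------------------------------------
        current_stage = "validate"
        t0 = time.perf_counter()
        from .cluster import standardize_items
        from .validate import sparse_solution_silhouette

        Z = standardize_items(panss)
        # each method's silhouette is computed in its own working space
        sil = sparse_solution_silhouette(hier.level1, Z)
        pk_labels, pk_scores = pca_kmeans(
            panss, k=2, seed=seeds["validate"], n_starts=config.n_starts, return_scores=True
        )
        sil_pca = silhouette_report(pk_scores, pk_labels, space="principal-components")
        p = outdir / "silhouette.csv"
        sil.to_frame().rename_axis("patient_id").to_csv(p, float_format="%.10g")
        written.append(p)
        stability = crossvalidate_clustering(
            panss,
            n_drawings=config.stability_drawings,
            split_fraction=config.split_fraction,
            seed=seeds["validate"],
            reference=hier,
            s_level1=config.s_level1,
            s_within={"C1": config.s_c1, "C2": config.s_c2},
            n_starts=config.n_starts,
        )
        p = outdir / "stability.json"
        p.write_text(json.dumps(
            {
                "n_drawings": stability.n_drawings,
                "split_fraction": stability.split_fraction,
                "per_cluster_accuracy": stability.per_cluster_accuracy,
            }, indent=1, sort_keys=True))
        written.append(p)
        log.info("validate: silhouette=%.3f pca=%.3f elapsed=%.2fs",
                 sil.mean_value, sil_pca.mean_value, time.perf_counter() - t0)
        summary_lines += [
            f"mean silhouette (sparse clustering): {sil.mean_value:.3f}",
            f"mean silhouette (PCA+k-means): {sil_pca.mean_value:.3f}",
            "assignment stability: " + ", ".join(
                f"{cl}={acc:.1%}" for cl, acc in sorted(stability.per_cluster_accuracy.items())
            ),
        ]

        # -- stage 4: biomarker screen --------------------------------------
        current_stage = "screen"
        t0 = time.perf_counter()
        retained = llod_filter(panel)
        log_table = log_transform(panel, retained)
        summary_lines.append(f"analytes retained by LLOD screen: {len(retained)} of {len(panel.analyte_names)}")
        univ_frames = []
        enrich = {}
        ss_screen = np.random.SeedSequence(seeds["screen"])
        screen_children = ss_screen.spawn(len(SUBTYPES))
        for st, child in zip(SUBTYPES, screen_children):
            mask = (subtype == st).to_numpy()
            if not mask.any() or mask.all():
                continue
            res = univariate_compare(log_table, mask, q_threshold=config.q_threshold)
            tbl = res.table.copy()
            tbl.insert(0, "subtype", st)
            univ_frames.append(tbl)
            er = subtype_enrichment(
                log_table, mask,
                n_drawings=config.enrichment_drawings,
                q_threshold=config.q_threshold,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            enrich[st] = {
                "observed_count": er.observed_count,
                "n_drawings": er.n_drawings,
                "p_empirical": er.p_empirical,
                "p_parametric": er.p_parametric,
            }
            summary_lines.append(
                f"{st}: {er.observed_count} analytes elevated at FDR<{config.q_threshold} "
                f"(enrichment p_emp={er.p_empirical:.2e}, p_poisson={er.p_parametric:.2e})"
            )
        p = outdir / "univariate.csv"
        pd.concat(univ_frames).rename_axis("analyte").to_csv(p, float_format="%.6g")
        written.append(p)
        p = outdir / "enrichment.json"
        p.write_text(json.dumps(enrich, indent=1, sort_keys=True))
        written.append(p)
        log.info("screen: retained=%d elapsed=%.2fs", len(retained), time.perf_counter() - t0)

        # -- stage 5: remission prediction ----------------------------------
        current_stage = "predict"
        t0 = time.perf_counter()
        mask = (subtype == config.predict_subtype).to_numpy()
        if not mask.any():
            summary_lines.append(f"prediction: skipped: no patients in {config.predict_subtype}")
        else:
            feats = build_features(log_table, covariates)
            keep = feats.X.index[mask[panss.patient_ids.get_indexer(feats.X.index)]]
            Xsub = feats.X.loc[keep]
            ysub = ~remission.loc[keep]  # 1 = non-remitter
            if config.predict_variables:
                unknown = [vn for vn in config.predict_variables if vn not in Xsub.columns]
                if unknown:
                    raise ValueError(f"predict_variables not in feature table: {unknown}")
                Xsub = Xsub[config.predict_variables]
            ens_cfg = EnsembleConfig(
                n_partitions=config.n_partitions,
                n_folds=config.n_folds,
                permutations=config.permutations,
                threshold=config.threshold,
            )
            results = RemissionEnsemble(Xsub, ysub, ens_cfg).fit(seed=seeds["predict"])
            results.compute_permutation_pvalues(seed=seeds["predict"] + 1)
            ors = results.weighted_odds_ratios()
            table = pd.DataFrame(
                {
                    "selection_proportion": results.selection_proportions,
                    "weighted_or": ors["weighted_or"],
                    "or_sd": ors["or_sd"],
                    "perm_p": results.permutation_p,
                }
            ).sort_values("selection_proportion", ascending=False)
            p = outdir / "ensemble.csv"
            table.rename_axis("variable").to_csv(p, float_format="%.6g")
            written.append(p)
            perf = results.evaluate_performance()
            a, asd = results.mean_alpha
            l, lsd = results.mean_lambda
            p = outdir / "performance.json"
            p.write_text(json.dumps(
                {
                    "subtype": config.predict_subtype,
                    "n_patients": int(len(Xsub)),
                    "n_drawings": results.n_drawings,
                    "mean_auc": perf.mean_auc, "sd_auc": perf.sd_auc,
                    "sensitivity": perf.sensitivity, "sd_sensitivity": perf.sd_sensitivity,
                    "specificity": perf.specificity, "sd_specificity": perf.sd_specificity,
                    "threshold": perf.threshold,
                    "youden_threshold": perf.youden_threshold,
                    "mean_alpha": a, "sd_alpha": asd,
                    "mean_lambda": l, "sd_lambda": lsd,
                }, indent=1, sort_keys=True))
            written.append(p)
            top = table.head(5)
            summary_lines.append(
                f"{config.predict_subtype} ensemble ({results.n_drawings} drawings): "
                f"AUC {perf.mean_auc:.2f} +/- {perf.sd_auc:.2f}, "
                f"sens {perf.sensitivity:.2f}, spec {perf.specificity:.2f} "
                f"@ threshold {perf.threshold}"
            )
            summary_lines.append("top selected variables:")
            for vn, row in top.iterrows():
                summary_lines.append(
                    f"  {vn}: selected {row['selection_proportion']:.1%}, "
                    f"OR {row['weighted_or']:.3f}, p {row['perm_p']:.3g}"
                )
        log.info("predict: elapsed=%.2fs", time.perf_counter() - t0)
    except Exception as exc:
        manifest.failure = f"{current_stage}: {exc}"
        manifest.write(outdir / "manifest.json")
        raise

    p = outdir / "summary.txt"
    p.write_text("\n".join(summary_lines) + "\n")
    written.append(p)
    for path in written:
        manifest.digests[path.name] = _digest(path)
    manifest.timestamps["completed"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
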