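"""End-to-end pipeline orchestration with provenance.

Stages run in a fixed order — simulate -> preprocess -> associate ->
select -> stratify/discriminate -> network -> clinical course — with any
stage toggleable.  Every output table is tab-separated text carrying the
run's seed and config hash in an accompanying manifest.  One global seed
derives per-stage seeds by stable hashing of the stage name, so toggling a
stage never shifts the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .clinical import default_sojourn_table, fit_cox, summarize_stage_shift
from .models import InsufficientDataError, MonotoneLikelihoodError, fit_adjusted_clogit, fit_clogit
from .preprocess import preprocess_study
from .selection import ResamplingConfig, compare_selections, resample_select, single_split_select
from .simulate import SimConfig, SimulatedStudy, default_config, generate_study
from .strata import delta_auc, stratified_or
from .network import residualize, stable_network

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "stage_seed"]

STAGES = ("simulate", "preprocess", "associate", "select", "stratify", "network", "course")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing; below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Either ``input_dir`` (the three study tables on disk) or ``simulate``
    (a SimConfig) must be provided.  ``stages`` toggles stages on/off.
    """

    output_dir: str
    seed: int = 0
    input_dir: str | None = None
    simulate: SimConfig | None = None
    stages: dict[str, bool] = field(default_factory=dict)
    resampling: ResamplingConfig | None = None
    network_params: dict = field(default_factory=dict)
    baseline_score_column: str = "baseline_score"
    stratum_vars: tuple[str, ...] = ("histology", "stage", "smoking_status", "cohort", "lead_time")
    n_top_proteins: int = 10  # proteins carried into the descriptive stages

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = None
        if "simulate" in raw:
            sim_raw = dict(raw.pop("simulate"))
            scale = sim_raw.pop("scale", 1.0)
            sim = default_config(
                n_proteins=sim_raw.pop("n_proteins", 60),
                scale=scale,
                seed=sim_raw.pop("seed", raw.get("seed", 0)),
                **sim_raw,
            )
        res = ResamplingConfig(**raw.pop("resampling")) if "resampling" in raw else None
        return cls(simulate=sim, resampling=res, **raw)

    def digest(self) -> str:
        def default(o):
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items() if not k.startswith("_") and k != "table"}
            return str(o)

        payload = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_inputs(subjects: pd.DataFrame, matrix: pd.DataFrame, annotations: pd.DataFrame) -> list[dict]:
    """Schema and design checks; returns a machine-readable violation list."""
    violations: list[dict] = []
    required = {"sample_id", "set_id", "cohort", "case", "age", "sex", "smoking_status"}
    for col in sorted(required - set(subjects.columns)):
        violations.append({"kind": "missing_column", "detail": col})
    if violations:
        return violations
    for set_id, grp in subjects.groupby("set_id"):
        if len(grp) != 2 or grp["case"].sum() != 1:
            violations.append({"kind": "bad_set", "detail": f"set {set_id}: needs 1 case + 1 control"})
            continue
        case = grp[grp["case"] == 1].iloc[0]
        ctrl = grp[grp["case"] == 0].iloc[0]
        for attr in ("cohort", "sex", "smoking_status"):
            if case[attr] != ctrl[attr]:
                violations.append({"kind": "matching", "detail": f"set {set_id}: {attr} differs"})
        if abs(case["age"] - ctrl["age"]) > 1.0 + 1e-9:
            violations.append({"kind": "matching", "detail": f"set {set_id}: age difference > 1 year"})
    missing_samples = set(matrix.index) - set(subjects["sample_id"])
    for s in sorted(missing_samples):
        violations.append({"kind": "orphan_sample", "detail": str(s)})
    for assay in matrix.columns:
        if assay not in annotations.index:
            violations.append({"kind": "unannotated_assay", "detail": str(assay)})
            continue
        if "cohorts" in annotations.columns:
            allowed = set(str(annotations.loc[assay, "cohorts"]).split(";"))
            measured = subjects.set_index("sample_id")["cohort"][matrix[assay].notna().to_numpy()]
            stray = set(measured.unique()) - allowed
            for c in sorted(stray):
                violations.append(
                    {"kind": "availability", "detail": f"assay {assay} measured in unlisted cohort {c}"}
                )
    if "lod" in annotations.columns:
        for assay in annotations.index[annotations["lod"].isna()]:
            violations.append({"kind": "missing_lod", "detail": str(assay)})
    return violations


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": {},
        "outputs": {},
    }
    t_all = time.time()

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / f"{name}.tsv"
        io.write_table(df, path, index=index)
        manifest["outputs"][name] = str(path)

    # --- obtain study ------------------------------------------------------
    t0 = time.time()
    if config.simulate is not None and config.enabled("simulate"):
        study = generate_study(config.simulate)
        io.write_study(study, outdir / "study")
    elif config.input_dir:
        study = io.read_study(config.input_dir)
    else:
        raise ValueError("config must provide either simulate or input_dir")
    violations = validate_inputs(study.subjects, study.matrix, study.annotations)
    if violations:
        emit("validation_report", pd.DataFrame(violations))
        raise ValueError(f"input validation failed with {len(violations)} violations; see report")
    manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 3), "n_sets": study.n_sets}

    # --- preprocess --------------------------------------------------------
    t0 = time.time()
    pre = preprocess_study(study.matrix, study.lod_mask, study.annotations, study.subjects)
    matrix = pre.matrix
    emit("qc_report", pre.qc, index=True)
    if len(pre.decisions):
        emit("duplicate_decisions", pre.decisions)
    manifest["stages"]["preprocess"] = {
        "seconds": round(time.time() - t0, 3),
        "n_proteins": matrix.shape[1],
    }

    assoc_table = None
    if config.enabled("associate"):
        t0 = time.time()
        rows = []
        for prot in matrix.columns:
            try:
                crude = fit_clogit(matrix, study.subjects, prot)
                adj = fit_adjusted_clogit(matrix, study.subjects, prot)
            except (MonotoneLikelihoodError, InsufficientDataError) as exc:
                logger.warning("association skipped for %s: %s", prot, exc)
                continue
            row = crude.to_dict()
            row.update({"beta_adj": adj.beta, "se_adj": adj.se, "or_sd_adj": adj.or_sd, "p_adj": adj.p})
            rows.append(row)
        assoc_table = pd.DataFrame(rows).set_index("protein")
        emit("associations", assoc_table, index=True)
        manifest["stages"]["associate"] = {"seconds": round(time.time() - t0, 3), "n_fit": len(assoc_table)}

    selected: list[str] = []
    if config.enabled("select"):
        t0 = time.time()
        rescfg = config.resampling or ResamplingConfig(seed=stage_seed(config.seed, "select"))
        sel = resample_select(matrix, study.subjects, config=rescfg)
        emit("selection", sel.table, index=True)
        selected = sel.selected
        manifest["stages"]["select"] = {
            "seconds": round(time.time() - t0, 3),
            "ent": sel.ent.ent,
            "n_selected": len(selected),
        }
        full_cohorts = [c.name for c in study.config.cohorts] if study.config else list(study.subjects["cohort"].unique())
        disc = rescfg.forced_discovery_cohorts or tuple(full_cohorts[:1])
        try:
            single = single_split_select(matrix, study.subjects, discovery_cohorts=disc)
            overlap = compare_selections(sel, single)
            manifest["stages"]["select"]["single_split_overlap"] = {
                k: overlap[k] for k in ("both", "only_a", "only_b")
            }
            emit("selection_single_split", single.table, index=True)
        except ValueError as exc:
            logger.warning("single-split comparison skipped: %s", exc)

    # descriptive stages need a workable protein set: the selected proteins,
    # topped up with the strongest associations when selection is sparse
    focus = list(selected)
    if len(focus) < 2:
        ranked = (
            list(assoc_table.sort_values("p").index)
            if assoc_table is not None
            else list(matrix.columns)
        )
        focus += [p for p in ranked if p not in focus][: config.n_top_proteins - len(focus)]

    if config.enabled("stratify"):
        t0 = time.time()
        srows, drows = [], []
        for prot in focus:
            for var in config.stratum_vars:
                try:
                    sres = stratified_or(matrix, study.subjects, prot, var)
                except (InsufficientDataError, ValueError):
                    continue
                for level, a in sres.strata.items():
                    srows.append(
                        {
                            "protein": prot,
                            "stratum_var": var,
                            "stratum": level,
                            "or_sd": a.or_sd,
                            "ci_low": a.ci_low,
                            "ci_high": a.ci_high,
                            "n_sets": a.n_sets,
                            "q_stat": sres.q_stat,
                            "p_het": sres.p_het,
                            "p_trend": sres.p_trend,
                        }
                    )
            if config.baseline_score_column in study.subjects.columns:
                try:
                    d = delta_auc(matrix, study.subjects, prot, config.baseline_score_column)
                    drows.append(
                        {
                            "protein": prot,
                            "auc_baseline": d.auc_baseline,
                            "auc_with_protein": d.auc_with_protein,
                            "delta_auc": d.delta_auc,
                        }
                    )
                except ValueError:
                    pass
        if srows:
            emit("stratified", pd.DataFrame(srows))
        if drows:
            emit("discrimination", pd.DataFrame(drows))
        manifest["stages"]["stratify"] = {"seconds": round(time.time() - t0, 3)}

    if config.enabled("network") and len(focus) >= 2:
        t0 = time.time()
        resid = residualize(matrix[focus], study.subjects)
        nets = []
        for group in ("cases", "controls"):
            net = stable_network(
                resid,
                study.subjects,
                group,
                seed=stage_seed(config.seed, f"network:{group}"),
                **config.network_params,
            )
            e = net.edges.copy()
            e.insert(0, "group", group)
            nets.append(e)
        emit("network_edges", pd.concat(nets, ignore_index=True))
        manifest["stages"]["network"] = {"seconds": round(time.time() - t0, 3)}

    if config.enabled("course"):
        t0 = time.time()
        sojourn = default_sojourn_table()
        cases = study.cases().set_index("sample_id")
        try:
            shift = summarize_stage_shift(cases, sojourn)
            emit("stage_at_draw", shift)
            manifest["stages"]["course"] = {
                "seconds": round(time.time() - t0, 3),
                "prop_stage_le_2": shift.attrs["prop_stage_le_2"],
            }
        except ValueError as exc:
            logger.warning("stage back-calculation skipped: %s", exc)
            manifest["stages"]["course"] = {"seconds": round(time.time() - t0, 3)}
        crows = []
        for prot in focus:
            try:
                res = fit_cox(cases.reset_index(), matrix[prot], protein=prot)
                crows.append(vars(res))
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("Cox fit skipped for %s: %s", prot, exc)
        if crows:
            emit("survival", pd.DataFrame(crows))
        manifest["stages"]["course"]["seconds"] = round(time.time() - t0, 3)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
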