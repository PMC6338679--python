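"""Orchestration: phantom generation -> extraction -> QC -> statistics.

`run_pipeline` drives the whole study workflow from a single config and
seed, producing a tidy per-subject records CSV, a QC report, and a
machine-readable statistics JSON validated against a bundled schema.
Everything is deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as tstats
from .extraction import ReferenceSpec, extract_subject
from .imaging import read_mask, read_volume
from .phantom import CohortSpec, TrajectoryParams, generate_cohort

__all__ = [
    "PipelineConfig",
    "QCReport",
    "run_pipeline",
    "qc_filter",
    "extract_cohort",
    "analyze_records",
    "validate_results",
]

log = logging.getLogger("lccr")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: ``phantom`` (simulate a cohort) or
    ``directory`` (read ``<id>_vol.nii[.gz]`` / ``<id>_mask.nii[.gz]``
    pairs plus a cohort CSV from ``input_dir``). The optional
    ``breakpoint_age`` fixes the old/young split used by the subgroup
    analyses; when absent the whole-LC two-lines breakpoint is used.
    """

    mode: str = "phantom"
    out_dir: str = "lccr_out"
    seed: int = 0
    n_subjects: int = 605
    cohort: CohortSpec | None = None
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    breakpoint_age: float | None = None
    input_dir: str | None = None
    cohort_csv: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("phantom", "directory"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "directory" and not self.input_dir:
            raise ValueError("directory mode needs input_dir")


@dataclass
class QCReport:
    """Exclusion accounting for one run."""

    n_input: int
    n_excluded_motion: int
    n_excluded_negative_cr: int
    n_retained: int
    reasons: dict  # subject_id -> reason

    @property
    def retained_pct(self) -> int:
        return int(round(100.0 * self.n_retained / self.n_input))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_motion": self.n_excluded_motion,
            "n_excluded_negative_cr": self.n_excluded_negative_cr,
            "n_retained": self.n_retained,
            "retained_pct": self.retained_pct,
            "reasons": dict(self.reasons),
        }


def qc_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop motion-flagged subjects and any with negative whole-LC mean CR.

    Each excluded subject is counted exactly once; a motion flag takes
    precedence as the exclusion reason when both apply.
    """
    if len(records) == 0:
        raise ValueError("no records to filter")
    reasons: dict[str, str] = {}
    n_motion = n_neg = 0
    keep = []
    for _, row in records.iterrows():
        if row.get("qc_motion_suspect", False):
            reasons[row["subject_id"]] = "motion_suspect"
            n_motion += 1
        elif row["cr_mean_whole"] < 0:
            reasons[row["subject_id"]] = "negative_cr"
            n_neg += 1
        else:
            keep.append(True)
            continue
        keep.append(False)
    retained = records[np.asarray(keep)].reset_index(drop=True)
    if len(retained) == 0:
        raise ValueError("QC excluded every subject")
    report = QCReport(
        n_input=len(records),
        n_excluded_motion=n_motion,
        n_excluded_negative_cr=n_neg,
        n_retained=len(retained),
        reasons=reasons,
    )
    log.info("QC: %d input, %d motion, %d negative-CR, %d retained (%d%%)",
             report.n_input, n_motion, n_neg, report.n_retained, report.retained_pct)
    return retained, report


def extract_cohort(subjects, reference: ReferenceSpec = ReferenceSpec()) -> pd.DataFrame:
    """Run per-subject extraction over phantom subjects -> tidy records."""
    rows = []
    for s in subjects:
        rec = extract_subject(
            s.volume, s.lc_mask_truth, reference,
            subject_id=s.subject_id, age_years=s.age_years, sex=s.sex,
            tr_ms=s.tr_ms, motion_suspect=s.motion_flag,
        )
        rows.append(rec.to_row())
    return pd.DataFrame(rows)


def _safe(analysis_name: str, fn, warnings: list):
    try:
        return fn()
    except (ValueError, RuntimeError) as exc:
        warnings.append(f"{analysis_name}: {exc}")
        return {"skipped": str(exc)}


def _fit_to_dict(fit: tstats.ModelFit) -> dict:
    return {
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "standard_errors": {k: float(v) for k, v in fit.bse.items()},
        "n": fit.n,
        "r2": fit.r2,
        "adjusted_r2": fit.adj_r2,
        "aic": fit.aic,
        "log_likelihood": fit.log_likelihood,
        "f_pvalue": fit.f_pvalue,
        "design": fit.design,
    }


def _two_lines_to_dict(res: tstats.TwoLinesResult) -> dict:
    return {
        "breakpoint_x": res.breakpoint_x,
        "slope_low": res.slope_low, "p_low": res.p_low,
        "slope_high": res.slope_high, "p_high": res.p_high,
        "n_low": res.n_low, "n_high": res.n_high,
        "verdict": res.verdict, "note": res.note,
    }


def _trajectory_block(age, y, breakpoint_age, warnings, name) -> dict:
    out: dict = {}

    def fits():
        lin = tstats.fit_polynomial(age, y, degree=1)
        quad = tstats.fit_polynomial(age, y, degree=2)
        winner, diff = tstats.compare_aic(quad, lin)
        return {
            "linear": _fit_to_dict(lin),
            "quadratic": _fit_to_dict(quad),
            "aic_winner": {"a": "quadratic", "b": "linear", "tie": "tie"}[winner],
            "aic_diff": diff,
        }

    out.update(_safe(f"{name} fits", fits, warnings) or {})
    out["two_lines"] = _safe(
        f"{name} two-lines",
        lambda: _two_lines_to_dict(tstats.two_lines_test(age, y, breakpoint=breakpoint_age)),
        warnings,
    )
    return out


def analyze_records(records: pd.DataFrame, breakpoint_age: float | None = None) -> dict:
    """The full statistical report on QC-retained records.

    Covers: whole/rostral/caudal mean-CR trajectories (linear + quadratic
    fits, AIC, two-lines), sex comparison (Student t, JZS Bayes factor,
    Cohen's d), variance ratio across the age breakpoint, pontine signal vs
    age (raw and TR-adjusted), the covariate-adjusted polynomial regression
    with an age-sex interaction and VIFs, Welch old/young subgroup tests,
    paired left/right comparisons, and voxel-count associations.
    """
    warnings: list[str] = []
    age = records["age_years"].to_numpy(dtype=float)
    results: dict = {"n": int(len(records)), "warnings": warnings}

    trajectories = {}
    for region in ("whole", "rostral", "caudal"):
        y = records[f"cr_mean_{region}"].to_numpy(dtype=float)
        trajectories[region] = _trajectory_block(age, y, None, warnings, region)
    results["trajectories"] = trajectories

    # breakpoint for subgroup splits: config > whole-LC two-lines > median age
    bp = breakpoint_age
    if bp is None:
        tl = trajectories["whole"].get("two_lines", {})
        bp = tl.get("breakpoint_x") if isinstance(tl, dict) else None
    if bp is None or not np.isfinite(bp):
        bp = float(np.median(age))
        warnings.append("breakpoint fell back to median age")
    results["breakpoint_age"] = float(bp)
    older = records[age > bp]
    younger = records[age <= bp]

    def sex_block():
        male = records.loc[records["sex"] == "M", "cr_mean_whole"].to_numpy()
        female = records.loc[records["sex"] == "F", "cr_mean_whole"].to_numpy()
        t, df, p = tstats.student_t(male, female)
        bayes = tstats.jzs_bayes_factor(t, len(male), len(female))
        return {
            "t": t, "df": df, "p": p,
            "n_male": len(male), "n_female": len(female),
            "bf10": bayes.bf10, "bf01": bayes.bf01,
            "cohens_d": bayes.effect_size_d,
            "d_ci95": list(bayes.d_ci95),
            "mean_male": float(male.mean()), "mean_female": float(female.mean()),
        }

    results["sex_comparison"] = _safe("sex comparison", sex_block, warnings)

    def variance_block():
        F, p = tstats.variance_ratio_test(
            older["cr_mean_whole"].to_numpy(), younger["cr_mean_whole"].to_numpy())
        return {"F": F, "p": p, "n_older": len(older), "n_younger": len(younger)}

    results["variance_comparison"] = _safe("variance comparison", variance_block, warnings)

    ref = records["ref_s_mean"].to_numpy(dtype=float)
    results["pons_vs_age"] = _safe(
        "pons vs age", lambda: tstats.association(age, ref), warnings)

    def pons_adjusted():
        tr = pd.DataFrame({"tr50": (records["tr_ms"] == 50).astype(float).to_numpy()})
        fit = tstats.fit_polynomial(age, ref, degree=1, covariates=tr)
        return _fit_to_dict(fit)

    results["pons_vs_age_tr_adjusted"] = _safe(
        "pons vs age TR-adjusted", pons_adjusted, warnings)

    def multiple_regression():
        sex01 = (records["sex"] == "F").astype(float).to_numpy()  # male reference
        tr50 = (records["tr_ms"] == 50).astype(float).to_numpy()
        covs = pd.DataFrame({"sex": sex01, "ref_s_mean": ref, "tr50": tr50})
        inter = pd.DataFrame({"age_x_sex": age * sex01})
        fit = tstats.fit_polynomial(
            age, records["cr_mean_whole"].to_numpy(dtype=float),
            degree=2, covariates=covs, interactions=inter)
        vifs = tstats.vif(pd.DataFrame({"age": age, "ref_s_mean": ref, "tr50": tr50}))
        return {"fit": _fit_to_dict(fit), "vif": {k: float(v) for k, v in vifs.items()}}

    results["adjusted_regression"] = _safe(
        "adjusted regression", multiple_regression, warnings)

    subgroups = {}
    for region in ("rostral", "caudal"):
        for stat in ("mean", "median", "max"):
            col = f"cr_{stat}_{region}"
            subgroups[col] = _safe(
                f"welch {col}",
                lambda c=col: dict(zip(("t", "df", "p"), tstats.welch_t(
                    older[c].to_numpy(), younger[c].to_numpy()))),
                warnings,
            )
    results["old_vs_young_welch"] = subgroups

    paired = {}
    for name, col_l, col_r in (
        ("voxel_count", "voxels_left", "voxels_right"),
        ("cr_max", "cr_max_left", "cr_max_right"),
    ):
        paired[name] = _safe(
            f"paired {name}",
            lambda l=col_l, r=col_r: dict(zip(("t", "df", "p"), tstats.paired_t(
                records[l].to_numpy(dtype=float), records[r].to_numpy(dtype=float)))),
            warnings,
        )
    results["left_vs_right_paired"] = paired

    results["voxels_vs_age"] = _safe(
        "voxels vs age",
        lambda: tstats.association(age, records["voxels_whole"].to_numpy(dtype=float)),
        warnings,
    )
    return results


# ---------------------------------------------------------------------------
# results-JSON schema (minimal structural validation; no external engine)

def _load_schema() -> dict:
    with resources.files("lccr").joinpath("results_schema.json").open() as fh:
        return json.load(fh)


def validate_results(results: dict) -> None:
    """Check the results dict against the bundled structural schema."""
    schema = _load_schema()
    _validate_node(results, schema, path="results")


def _validate_node(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    type_map = {
        "object": dict, "number": (int, float), "integer": int,
        "string": str, "array": list, "boolean": bool,
    }
    if expected and not isinstance(value, type_map[expected]):
        raise ValueError(f"{path}: expected {expected}, got {type(value).__name__}")
    if expected == "object":
        for key, sub in schema.get("required", {}).items():
            if key not in value:
                if isinstance(value, dict) and "skipped" in value:
                    return  # a skipped analysis block is schema-valid
                raise ValueError(f"{path}: missing required key {key!r}")
            _validate_node(value[key], sub, f"{path}.{key}")


# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _load_directory_cohort(config: PipelineConfig) -> pd.DataFrame:
    input_dir = Path(config.input_dir)
    csv = Path(config.cohort_csv) if config.cohort_csv else input_dir / "cohort.csv"
    table = pd.read_csv(csv)
    rows = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        vol_path = next(p for ext in (".nii", ".nii.gz")
                        if (p := input_dir / f"{sid}_vol{ext}").exists())
        mask_path = next(p for ext in (".nii", ".nii.gz")
                         if (p := input_dir / f"{sid}_mask{ext}").exists())
        volume = read_volume(vol_path)
        mask = read_mask(mask_path, volume.grid)
        rec = extract_subject(
            volume, mask, config.reference,
            subject_id=sid, age_years=float(row["age_years"]),
            sex=str(row["sex"]), tr_ms=int(row["tr_ms"]),
            motion_suspect=bool(row.get("motion_flag", False)),
        )
        rows.append(rec.to_row())
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, QCReport, dict]:
    """Run the whole pipeline; writes records CSV, QC report and results JSON.

    Returns (records, qc_report, results). All outputs land in
    ``config.out_dir`` alongside a resolved-config copy carrying the seed.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "phantom":
        spec = config.cohort or CohortSpec(n_subjects=config.n_subjects, seed=config.seed)
        log.info("simulating phantom cohort: n=%d seed=%d", spec.n_subjects, spec.seed)
        subjects, _ = generate_cohort(spec, config.trajectory)
        records = extract_cohort(subjects, config.reference)
    else:
        log.info("reading subjects from %s", config.input_dir)
        records = _load_directory_cohort(config)
    log.info("extraction complete: %d records", len(records))

    retained, qc = qc_filter(records)
    results = analyze_records(retained, breakpoint_age=config.breakpoint_age)
    results["seed"] = int(config.seed)
    results["qc"] = qc.to_dict()
    results = _jsonable(results)
    validate_results(results)

    records_path = out_dir / "records.csv"
    records.to_csv(records_path, index=False, float_format="%.6g")
    with open(out_dir / "qc_report.json", "w") as fh:
        json.dump(_jsonable(qc.to_dict()), fh, indent=2, sort_keys=True)
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    resolved = {"config": _jsonable({
        "mode": config.mode, "seed": config.seed, "n_subjects": config.n_subjects,
        "breakpoint_age": config.breakpoint_age,
        "trajectory": asdict(config.trajectory),
        "reference": asdict(config.reference),
        "cohort": asdict(config.cohort) if config.cohort else None,
        "input_dir": config.input_dir,
    })}
    with open(out_dir / "resolved_config.json", "w") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
    log.info("outputs written to %s", out_dir)
    return records, qc, results
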