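"""End-to-end study orchestration.

Runs the whole validation on a cohort — invasive beat analysis with
stability/arrhythmia exclusions, catheter QC, oscillometric estimation (or
recorded device estimates), agreement statistics, and protocol grading —
and emits a machine-readable study report: cohort summary, exclusion
accounting, per-component agreement and grades, range conformity, and
per-patient detail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import catheterqc, invasive, oscillo
from .types import PairedMeasurement

log = logging.getLogger("cbpval")

COMPONENTS = ("SBP", "MAP", "DBP")
REPORT_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """Everything a study run depends on; YAML-serialisable."""

    manifest: str | None = None
    out_dir: str | None = None
    sd_limits: tuple = invasive.DEFAULT_SD_LIMITS  # (SBP, MAP, DBP) mmHg
    arrhythmia_limit: float = invasive.DEFAULT_ARRHYTHMIA_LIMIT
    outlier_k: float = 3.0
    systolic_ratio: float = oscillo.DEFAULT_SYSTOLIC_RATIO
    diastolic_ratio: float = oscillo.DEFAULT_DIASTOLIC_RATIO
    # "recorded": use device estimates from the sidecar when present,
    # falling back to the surrogate chain; or any registered estimator name
    estimator: str = "recorded"
    estimator_params: dict = field(default_factory=lambda: {"alpha": 0.8})
    fn_range: tuple = catheterqc.DEFAULT_FN_RANGE
    zeta_range: tuple = catheterqc.DEFAULT_ZETA_RANGE
    exclude_on_qc_fail: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sd_limits):
            raise ValueError("SD limits must be positive")
        if (self.estimator != "recorded"
                and self.estimator not in oscillo.ESTIMATORS):
            raise ValueError(f"estimator {self.estimator!r} not registered")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sd_limits", "fn_range", "zeta_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("sd_limits", "fn_range", "zeta_range"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Machine-readable study output mirroring the validation tables."""

    cohort_table: pd.DataFrame
    ledger: pd.DataFrame
    n_recorded: int
    n_analyzed: int
    agreement: dict  # component -> AgreementResult
    grading: dict  # component -> GradingResult
    range_conformity: dict  # component -> (rows, recruitment ratio)
    patients: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "n_recorded": self.n_recorded,
            "n_analyzed": self.n_analyzed,
            "exclusions": self.ledger.to_dict(orient="records"),
            "cohort": self.cohort_table.to_dict(orient="records"),
            "agreement": {c: dataclasses.asdict(a)
                          for c, a in self.agreement.items()},
            "grading": {c: dataclasses.asdict(g)
                        for c, g in self.grading.items()},
            "range_conformity": {
                c: {"rows": rows, "recruitment_ratio_pct": ratio}
                for c, (rows, ratio) in self.range_conformity.items()},
        }

    def write(self, out_dir) -> Path:
        """Write report JSON, tidy CSV tables, and per-component plot data."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, default=_jsonable))
        self.cohort_table.to_csv(out / "cohort_summary.csv", index=False)
        self.ledger.to_csv(out / "exclusions.csv", index=False)
        self.patients.to_csv(out / "patients.csv", index=False)
        for comp in self.agreement:
            df = pd.DataFrame({
                "patient_id": self.patients["patient_id"],
                "invasive": self.patients[f"invasive_{comp.lower()}"],
                "estimated": self.patients[f"estimated_{comp.lower()}"],
            }).dropna()
            df["mean"] = (df["invasive"] + df["estimated"]) / 2.0
            df["diff"] = df["invasive"] - df["estimated"]
            df.to_csv(out / f"bland_altman_{comp.lower()}.csv", index=False)
        return out / "report.json"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# per-patient analysis


def analyze_patient(patient_id: str, site: str, inv_wf, cuff_wf, flush_wf,
                    device_estimate, config: StudyConfig) -> dict:
    """Run every stage on one patient; never raises on bad signals.

    Returns a dict with verdict ('include' or an exclusion reason),
    detail, invasive summary, estimated central pressures, and QC result.
    """
    out = {"patient_id": patient_id, "site": site, "verdict": "include",
           "detail": "", "summary": None, "estimated": None, "qc": None,
           "artifact_flag": False}

    if flush_wf is not None:
        try:
            out["qc"] = catheterqc.analyze_flush(
                flush_wf, fn_range=config.fn_range,
                zeta_range=config.zeta_range)
        except ValueError as exc:
            log.warning("%s: flush QC failed to analyse: %s", patient_id, exc)

    if inv_wf is None:
        out["verdict"], out["detail"] = "exclude_incomplete", "no invasive channel"
        return out
    try:
        beats, summary, verdict, detail = invasive.analyze_recording(
            inv_wf, outlier_policy=(("sbp", "dbp", "duration"), config.outlier_k),
            sd_limits=config.sd_limits,
            arrhythmia_limit=config.arrhythmia_limit)
    except ValueError as exc:
        out["verdict"], out["detail"] = "exclude_corrupt", str(exc)
        return out
    out["summary"] = summary
    out["verdict"], out["detail"] = verdict, detail
    if verdict != "include":
        return out

    if out["qc"] is not None and config.exclude_on_qc_fail and \
            not out["qc"].qc_pass:
        out["verdict"], out["detail"] = "exclude_qc", "catheter QC failed"
        return out

    estimated = None
    if config.estimator == "recorded" and device_estimate is not None:
        estimated = tuple(float(v) for v in device_estimate)
    elif cuff_wf is not None:
        est_name = (config.estimator if config.estimator != "recorded"
                    else "surrogate")
        try:
            _, _, central, artifact = oscillo.process_cuff(
                cuff_wf, systolic_ratio=config.systolic_ratio,
                diastolic_ratio=config.diastolic_ratio,
                estimator=est_name, **config.estimator_params)
            estimated = (central.csbp, central.cmap, central.cdbp)
            out["artifact_flag"] = artifact
        except ValueError as exc:
            out["verdict"], out["detail"] = "exclude_corrupt", \
                f"cuff processing failed: {exc}"
            return out
    if estimated is None:
        out["verdict"], out["detail"] = "exclude_incomplete", \
            "no device estimate and no cuff channel"
        return out
    out["estimated"] = estimated
    return out


def exclusion_ledger(verdicts) -> pd.DataFrame:
    """Accounting table from per-patient (patient_id, verdict, detail) rows.

    Stability exclusions are attributed to a single sub-reason (the SD limit
    tripped first, in the order SBP, MAP, DBP — encoded in the detail).
    Raises on duplicate patient ids.
    """
    ids = [v[0] for v in verdicts]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids in verdicts")
    reasons = []
    for _, verdict, detail in verdicts:
        if verdict == "exclude_stability":
            sub = next((f"stability_{c}" for c in ("sbp", "map", "dbp")
                        if f"sd_{c}" in detail), "stability_other")
            reasons.append(sub)
        elif verdict.startswith("exclude_"):
            reasons.append(verdict.removeprefix("exclude_"))
        else:
            reasons.append("included")
    order = ["stability_sbp", "stability_map", "stability_dbp",
             "arrhythmia", "corrupt", "incomplete", "qc", "included"]
    counts = pd.Series(reasons).value_counts()
    rows = [{"reason": r, "count": int(counts.get(r, 0))}
            for r in order if counts.get(r, 0) > 0 or r == "included"]
    df = pd.DataFrame(rows)
    assert df["count"].sum() == len(verdicts), "ledger does not reconcile"
    return df


# ---------------------------------------------------------------------------
# cohort-level analysis


def analyze_cohort(records, config: StudyConfig) -> StudyReport:
    """Run the study on loaded patient records.

    ``records`` are dicts with keys patient_id, site, invasive, cuff, flush
    (waveforms or None) and optionally device_estimate — the format
    :func:`cbpval.io.read_manifest` produces, or synthetic
    ``PatientRecord`` objects.
    """
    results, verdicts, rows = [], [], []
    for rec in records:
        if not isinstance(rec, dict):
            rec = {"patient_id": rec.patient_id, "site": rec.site,
                   "invasive": rec.invasive, "cuff": rec.cuff,
                   "flush": rec.flush, "device_estimate": rec.device_estimate}
        device_estimate = rec.get("device_estimate")
        if device_estimate is None:
            sidecar = rec.get("sidecars", {}).get("cuff", {})
            device_estimate = sidecar.get("ground_truth", {}).get(
                "device_estimate")
        res = analyze_patient(rec["patient_id"], rec.get("site", ""),
                              rec.get("invasive"), rec.get("cuff"),
                              rec.get("flush"), device_estimate, config)
        results.append(res)
        verdicts.append((res["patient_id"], res["verdict"], res["detail"]))
        log.info("%s: %s %s", res["patient_id"], res["verdict"], res["detail"])

        row = {"patient_id": res["patient_id"], "site": res["site"],
               "verdict": res["verdict"], "detail": res["detail"]}
        if res["summary"] is not None:
            s = res["summary"]
            row.update(invasive_sbp=s.mean_sbp, invasive_map=s.mean_map,
                       invasive_dbp=s.mean_dbp, sd_sbp=s.sd_sbp,
                       sd_map=s.sd_map, sd_dbp=s.sd_dbp,
                       n_beats=s.n_beats_total,
                       n_beats_excluded=s.n_beats_excluded)
        if res["estimated"] is not None:
            row.update(estimated_sbp=res["estimated"][0],
                       estimated_map=res["estimated"][1],
                       estimated_dbp=res["estimated"][2])
        if res["qc"] is not None:
            row.update(flush_fn=res["qc"].natural_frequency,
                       flush_zeta=res["qc"].damping_coefficient,
                       flush_qc_pass=res["qc"].qc_pass)
        rows.append(row)

    patients = pd.DataFrame(rows)
    ledger = exclusion_ledger(verdicts)
    n_analyzed = int(
        ledger.loc[ledger["reason"] == "included", "count"].sum())

    included = [r for r in results if r["verdict"] == "include"]
    pairs = [PairedMeasurement(
        patient_id=r["patient_id"],
        invasive=(r["summary"].mean_sbp, r["summary"].mean_map,
                  r["summary"].mean_dbp),
        estimated=r["estimated"], site=r["site"]) for r in included]

    agreement_results, grading_results, ranges = {}, {}, {}
    if len(pairs) >= 2:
        for i, comp in enumerate(COMPONENTS):
            inv = [p.invasive[i] for p in pairs]
            est = [p.estimated[i] for p in pairs]
            a = agr.bland_altman(inv, est, component=comp)
            agreement_results[comp] = a
            grading_results[comp] = agr.grade(a)
        for comp in ("SBP", "DBP"):
            i = COMPONENTS.index(comp)
            ranges[comp] = agr.range_conformity(
                [p.invasive[i] for p in pairs], comp)

    cohort_table = _cohort_table(pairs)
    provenance = {"config_sha256": config.digest(),
                  "rng_seed": config.rng_seed,
                  "software_version": _version()}
    return StudyReport(
        cohort_table=cohort_table, ledger=ledger,
        n_recorded=len(records), n_analyzed=n_analyzed,
        agreement=agreement_results, grading=grading_results,
        range_conformity=ranges, patients=patients, provenance=provenance)


def _cohort_table(pairs) -> pd.DataFrame:
    rows = [{"variable": "n_patients", "mean": len(pairs),
             "min": None, "max": None, "sd": None}]
    if pairs:
        for i, comp in enumerate(COMPONENTS):
            for src, label in (("invasive", "Invasive central"),
                               ("estimated", "Estimated central")):
                vals = np.array([getattr(p, src)[i] for p in pairs])
                rows.append({
                    "variable": f"{label} {comp} (mmHg)",
                    "mean": round(float(vals.mean()), 1),
                    "min": round(float(vals.min()), 1),
                    "max": round(float(vals.max()), 1),
                    "sd": round(float(vals.std(ddof=1)), 1)
                    if vals.size > 1 else 0.0})
    return pd.DataFrame(rows)


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("cbpval")
    except Exception:  # pragma: no cover
        return "unknown"


def run_study(config: StudyConfig) -> StudyReport:
    """Load the manifest, analyse the cohort, optionally write the report."""
    from . import io as cio
    if config.manifest is None:
        raise ValueError("config.manifest is required")
    records = cio.read_manifest(config.manifest)
    for rec in records:
        if rec["load_errors"]:
            log.warning("%s: %s", rec["patient_id"],
                        "; ".join(rec["load_errors"]))
    report = analyze_cohort(records, config)
    if config.out_dir:
        report.write(config.out_dir)
    return report
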