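"""End-to-end MHC measurement and manual-vs-automatic comparison.

One call chains the stages: canonical orientation -> outer-skin mask ->
maximum-area axial slice -> perimeter in cm -> age-grouped correction
factor -> structured report.  A companion harness reproduces the
bookkeeping used to compare the instrument against manual tape readings
(Diff1 = manual - automatic, New HC = automatic + CF, Diff2 = manual -
corrected, all uncertainties in quadrature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._util import quadrature
from .calibration import CFApplication, Measurement, apply_cf
from .mask import extract_head_mask
from .perimeter import find_mhc_slice
from .presets import cf_preset
from .volume import VoxelVolume, to_canonical

__all__ = [
    "MHCResult",
    "ComparisonRow",
    "PipelineError",
    "DEFAULT_RAW_SD_CM",
    "DEFAULT_MANUAL_SD_CM",
    "measure_mhc",
    "compare_manual",
    "comparison_row",
    "load_manual_csv",
    "render_report",
]

#: Default one-sigma precision of a single automatic reading (cm), the
#: instrument precision established by the phantom calibration.
DEFAULT_RAW_SD_CM = 0.5

#: Default one-sigma precision of a manual tape reading (cm).
DEFAULT_MANUAL_SD_CM = 0.1


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class MHCResult:
    """One subject's automatic maximum-head-circumference measurement."""

    subject_id: str
    raw_cm: Measurement
    corrected_cm: Measurement
    cf_used: object  # CorrectionFactor | None
    cf_applied: bool
    slice_index: int
    z_mm: float
    z_uncertainty_mm: float
    area_mm2: float
    method: str
    spacing: tuple[float, float, float]
    age_months: float | None = None
    sex: str | None = None


@dataclass
class ComparisonRow:
    """Manual vs automatic bookkeeping for one subject (all cm)."""

    subject_id: object
    manual: Measurement
    automatic: Measurement
    diff1: Measurement  # manual - automatic
    corrected: Measurement  # automatic + CF ("New HC")
    diff2: Measurement  # manual - corrected


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


def measure_mhc(
    vol: VoxelVolume,
    age_months: float,
    cf_table=None,
    method: str = "corner_corrected",
    raw_sd_cm: float = DEFAULT_RAW_SD_CM,
    sex: str | None = None,
    average_top_k: int = 1,
) -> MHCResult:
    """Measure the maximum head circumference of one volume.

    ``cf_table`` is a list of :class:`~headcirc.calibration.CorrectionFactor`
    (default: the ``"paper2021"`` preset).  ``raw_sd_cm`` is the instrument
    precision attached to the raw reading; supply the value from a fresh
    calibration run when available.  ``average_top_k > 1`` averages the
    perimeters of the k largest-area slices instead of reading only the
    single maximum (an audit option; the default matches the published
    single-slice protocol).
    """
    if age_months < 0:
        raise ValueError("age_months must be >= 0")
    if cf_table is None:
        cf_table = cf_preset("paper2021")

    canonical = _stage("orientation", to_canonical, vol)
    mask = _stage("mask-extraction", extract_head_mask, canonical)
    best = _stage("slice-selection", find_mhc_slice, mask, method)

    if average_top_k > 1:
        from .perimeter import all_slice_profile

        profile = _stage("slice-selection", all_slice_profile, mask, method)
        top = sorted(profile, key=lambda s: -s.area_mm2)[:average_top_k]
        raw_value = float(np.mean([s.perimeter_cm for s in top]))
    else:
        raw_value = best.perimeter_cm

    raw = Measurement(raw_value, raw_sd_cm)
    application: CFApplication = _stage("correction", apply_cf, raw, cf_table, age_months)

    return MHCResult(
        subject_id=vol.source_id,
        raw_cm=raw,
        corrected_cm=application.corrected,
        cf_used=application.cf,
        cf_applied=application.applied,
        slice_index=best.slice_index,
        z_mm=best.z_mm,
        z_uncertainty_mm=best.z_uncertainty_mm,
        area_mm2=best.area_mm2,
        method=method,
        spacing=canonical.spacing,
        age_months=age_months,
        sex=sex,
    )


def comparison_row(
    subject_id, manual: Measurement, automatic: Measurement, cf: Measurement
) -> ComparisonRow:
    """Build one comparison row from manual, automatic, and CF readings.

    diff1 = manual - automatic; corrected = automatic + cf;
    diff2 = manual - corrected; all sds in quadrature.
    """
    corrected = Measurement(
        automatic.value + cf.value, quadrature(automatic.sd, cf.sd)
    )
    return ComparisonRow(
        subject_id=subject_id,
        manual=manual,
        automatic=automatic,
        diff1=Measurement(
            manual.value - automatic.value, quadrature(manual.sd, automatic.sd)
        ),
        corrected=corrected,
        diff2=Measurement(
            manual.value - corrected.value, quadrature(manual.sd, corrected.sd)
        ),
    )


def load_manual_csv(path):
    """Read a manual-readings table (subject_id, manual_cm[, manual_sd_cm,
    age_months, sex]); '#' comments allowed."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if "subject_id" not in df.columns or "manual_cm" not in df.columns:
        raise ValueError(f"{path}: need columns subject_id and manual_cm")
    if "manual_sd_cm" not in df.columns:
        df["manual_sd_cm"] = DEFAULT_MANUAL_SD_CM
    return df


def compare_manual(results, manual) -> tuple[list, dict]:
    """Join automatic results with manual readings; return rows and a summary.

    ``results`` is a list of :class:`MHCResult`; ``manual`` a DataFrame (or
    CSV path) with subject_id, manual_cm, optional manual_sd_cm and sex.
    The summary reports the mean corrected difference +/- standard error of
    the mean, overall and per sex when a sex column is present.
    """
    import pandas as pd

    if not isinstance(manual, pd.DataFrame):
        manual = load_manual_csv(manual)
    by_id = {str(r.subject_id): r for r in results}
    manual_ids = [str(s) for s in manual["subject_id"]]
    missing = sorted(set(manual_ids) ^ set(by_id))
    if missing:
        raise ValueError(f"unmatched subject ids: {missing}")

    rows = []
    sexes = {}
    for rec in manual.itertuples():
        res = by_id[str(rec.subject_id)]
        man = Measurement(float(rec.manual_cm), float(rec.manual_sd_cm))
        cf = res.cf_used.cf if res.cf_applied else Measurement(0.0, 0.0)
        row = comparison_row(rec.subject_id, man, res.raw_cm, cf)
        rows.append(row)
        if hasattr(rec, "sex"):
            sexes[rec.subject_id] = rec.sex

    def _summary(selected):
        d = np.array([r.diff2.value for r in selected])
        return {
            "n": int(d.size),
            "mean_diff2_cm": float(np.mean(d)),
            "sem_diff2_cm": float(np.std(d, ddof=1) / np.sqrt(d.size))
            if d.size > 1
            else 0.0,
        }

    summary = {"overall": _summary(rows)}
    if sexes:
        for sex in sorted(set(sexes.values())):
            sel = [r for r in rows if sexes.get(r.subject_id) == sex]
            if sel:
                summary[f"sex={sex}"] = _summary(sel)
    return rows, summary


def render_report(result: MHCResult, chart=None, path=None) -> dict:
    """Serialize a measurement as a JSON-ready report.

    When a reference chart is supplied (and the result carries age and sex),
    the percentile and z-score are included; otherwise those fields are
    absent — never null-filled.  ``path`` writes the JSON to disk.
    """
    report = {
        "subject_id": result.subject_id,
        "raw_cm": {"value": result.raw_cm.value, "sd": result.raw_cm.sd},
        "corrected_cm": {
            "value": result.corrected_cm.value,
            "sd": result.corrected_cm.sd,
        },
        "cf_applied": result.cf_applied,
        "slice_index": result.slice_index,
        "z_mm": result.z_mm,
        "z_uncertainty_mm": result.z_uncertainty_mm,
        "area_mm2": result.area_mm2,
        "method": result.method,
        "spacing_mm": list(result.spacing),
        "age_months": result.age_months,
        "sex": result.sex,
    }
    if result.cf_applied and result.cf_used is not None:
        report["cf"] = {
            "group": result.cf_used.group.label,
            "value": result.cf_used.cf.value,
            "sd": result.cf_used.cf.sd,
        }
    if chart is not None and result.age_months is not None and result.sex:
        from .charts import percentile

        z, pct = percentile(
            result.corrected_cm.value, result.age_months, result.sex, chart
        )
        report["z_score"] = z
        report["percentile"] = pct
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
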