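"""Phantom calibration: read summaries, systematic error, correction factors.

The instrument over-reads circumference systematically (digitization bias,
partial volume, mask dilation).  Rather than modeling why, the calibration
protocol measures rings of exactly known circumference (C = D*pi from a
calipered diameter), summarizes the five per-ring reads as mean +/- sample
sd, differences them against truth (Difference = Real - Estimated, so the
value is negative when the instrument over-reads), and pools the
differences per age group into an additive correction factor (CF).
Uncertainties combine in quadrature throughout.  Lengths are cm; values are
kept at full precision internally and rounded to 0.1 cm only at reporting
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._util import quadrature, round_report
from .mask import mask_from_threshold, threshold_value
from .perimeter import trace_boundary, perimeter_estimate
from .volume import VoxelVolume

__all__ = [
    "Measurement",
    "AgeGroup",
    "CorrectionFactor",
    "CalibrationRecord",
    "CFApplication",
    "CalibrationError",
    "summarize_reads",
    "analytic_circumference",
    "ring_difference",
    "derive_cf",
    "apply_cf",
    "run_calibration",
    "load_cf_table",
    "save_cf_table",
    "calibration_report",
]


class CalibrationError(ValueError):
    """Calibration protocol violated (empty ring, mixed groups, ...)."""


@dataclass(frozen=True)
class Measurement:
    """A length in cm with a one-sigma uncertainty."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and math.isfinite(self.sd)):
            raise ValueError(f"non-finite measurement {self.value} +/- {self.sd}")
        if self.sd < 0:
            raise ValueError(f"negative uncertainty {self.sd}")

    def rounded(self, decimals: int = 1) -> "Measurement":
        """Reporting form: value and sd rounded half away from zero."""
        return Measurement(
            round_report(self.value, decimals), round_report(self.sd, decimals)
        )

    def __str__(self) -> str:
        return f"{self.value:.1f} ± {self.sd:.1f}"


@dataclass(frozen=True)
class AgeGroup:
    """Age range in months, inclusive lower bound, exclusive upper."""

    label: str
    min_months: float
    max_months: float

    def __contains__(self, age_months: float) -> bool:
        return self.min_months <= age_months < self.max_months


@dataclass(frozen=True)
class CorrectionFactor:
    """Additive age-grouped correction (cm), mean +/- sd of ring differences."""

    group: AgeGroup
    cf: Measurement


@dataclass
class CalibrationRecord:
    """One ring's calibration row: reads, summary, truth, difference."""

    ring_label: str
    reads: tuple
    est: Measurement
    real: Measurement
    difference: Measurement
    group: str | None = None


@dataclass(frozen=True)
class CFApplication:
    """Result of applying (or failing to apply) a correction factor."""

    corrected: Measurement
    cf: CorrectionFactor | None
    applied: bool


def summarize_reads(reads) -> Measurement:
    """Mean and sample sd (n-1 denominator) of repeated circumference reads.

    The instrument's precision is the variability among its per-slice reads;
    a single read has sd 0.
    """
    reads = np.asarray(list(reads), dtype=float)
    if reads.size == 0:
        raise ValueError("no reads to summarize")
    sd = float(np.std(reads, ddof=1)) if reads.size > 1 else 0.0
    return Measurement(float(np.mean(reads)), sd)


def analytic_circumference(
    diameter_mm: float, diameter_sd_mm: float = 0.1
) -> Measurement:
    """Certified circumference C = D*pi (cm) from a calipered diameter (mm).

    The sd propagates linearly: sd(C) = pi * sd(D).
    """
    if diameter_mm <= 0:
        raise ValueError(f"non-positive diameter {diameter_mm}")
    if diameter_sd_mm < 0:
        raise ValueError("negative diameter sd")
    return Measurement(
        math.pi * diameter_mm / 10.0, math.pi * diameter_sd_mm / 10.0
    )


def ring_difference(est: Measurement, real: Measurement) -> Measurement:
    """Difference = Real - Estimated, sds combined in quadrature.

    Negative when the instrument over-reads (the usual case).
    """
    return Measurement(real.value - est.value, quadrature(est.sd, real.sd))


def derive_cf(records, group: AgeGroup | str) -> CorrectionFactor:
    """Pool a group's ring differences into a correction factor.

    cf = mean of the differences, sd = their sample sd.  Requires at least
    two records; records tagged with a different group are rejected.
    """
    records = list(records)
    if len(records) < 2:
        raise CalibrationError(
            f"need >= 2 calibration records to derive a CF, got {len(records)}"
        )
    if isinstance(group, str):
        group = _default_group(group)
    tags = {r.group for r in records if r.group is not None}
    if len(tags) > 1:
        raise CalibrationError(f"records span multiple groups: {sorted(tags)}")
    diffs = np.array([r.difference.value for r in records], dtype=float)
    return CorrectionFactor(
        group=group,
        cf=Measurement(float(np.mean(diffs)), float(np.std(diffs, ddof=1))),
    )


def _default_group(label: str) -> AgeGroup:
    table = {
        "0-3": AgeGroup("0-3", 0.0, 36.0),
        "3-18": AgeGroup("3-18", 36.0, 216.0),
    }
    try:
        return table[label]
    except KeyError:
        raise CalibrationError(
            f"unknown group label {label!r}; expected one of {sorted(table)}"
        ) from None


def apply_cf(raw: Measurement, cf_table, age_months: float) -> CFApplication:
    """Apply the age-matched correction factor to a raw reading.

    corrected = raw + cf, sd by quadrature.  If no group covers the age,
    the raw measurement is returned unmodified with ``applied=False`` —
    never silently.
    """
    for cf in cf_table:
        if age_months in cf.group:
            corrected = Measurement(
                raw.value + cf.cf.value, quadrature(raw.sd, cf.cf.sd)
            )
            return CFApplication(corrected=corrected, cf=cf, applied=True)
    return CFApplication(corrected=raw, cf=None, applied=False)


def run_calibration(
    phantom_volume: VoxelVolume,
    manifest=None,
    method: str = "corner_corrected",
    real_sd_cm: float = 0.0,
    group: str | None = None,
) -> list:
    """Measure every ring of a rasterized phantom and difference against truth.

    Each occupied slice of a ring yields one circumference read (the
    protocol's five slices per ring at 1 mm spacing), with no resampling
    between reads.  ``real_sd_cm`` is the uncertainty attached to the
    analytic circumference: 0 for a digital phantom whose truth is exact;
    pi * caliper precision when emulating a physical measurement.
    """
    if manifest is None:
        manifest = phantom_volume.meta.get("manifest")
    if manifest is None or not getattr(manifest, "rings", None):
        raise CalibrationError("phantom volume has no ring manifest")

    threshold = threshold_value(phantom_volume)
    mask = mask_from_threshold(phantom_volume, threshold)
    sx, sy, sz = phantom_volume.spacing
    counts = mask.data.sum(axis=(0, 1))
    z_centers = np.arange(mask.data.shape[2]) * sz

    records = []
    for ring in manifest.rings:
        z0, z1 = ring.z_interval_mm
        in_ring = (z_centers > z0 - sz / 2.0) & (z_centers < z1 + sz / 2.0)
        slices = np.nonzero(in_ring & (counts > 0))[0]
        if slices.size == 0:
            raise CalibrationError(f"ring {ring.label!r} has no occupied slices")
        reads = []
        for k in slices:
            chain = trace_boundary(mask.data[:, :, k])
            reads.append(perimeter_estimate(chain, (sx, sy), method) / 10.0)
        est = summarize_reads(reads)
        real = Measurement(ring.circumference_cm, real_sd_cm)
        records.append(
            CalibrationRecord(
                ring_label=ring.label,
                reads=tuple(reads),
                est=est,
                real=real,
                difference=ring_difference(est, real),
                group=group if group is not None else getattr(manifest, "group", None),
            )
        )
    return records


def reported_record(record: CalibrationRecord) -> CalibrationRecord:
    """Reporting form of a record, mirroring the printed-table workflow.

    Values are rounded to 0.1 cm and the difference is recomputed from the
    rounded est/real pair (quadrature of the rounded sds), which is how the
    published calibration tables combine their columns.
    """
    est = record.est.rounded()
    real = record.real.rounded()
    return replace(
        record,
        est=est,
        real=real,
        difference=ring_difference(est, real).rounded(),
    )


def calibration_report(records):
    """Calibration records as a DataFrame mirroring the printed table layout."""
    import pandas as pd

    rows = []
    for rec in records:
        rep = reported_record(rec)
        row = {"ring": rec.ring_label}
        row.update({f"read{i + 1}": r for i, r in enumerate(rec.reads)})
        row.update(
            est=rep.est.value,
            est_sd=rep.est.sd,
            real=rep.real.value,
            real_sd=rep.real.sd,
            diff=rep.difference.value,
            diff_sd=rep.difference.sd,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def load_cf_table(path) -> list:
    """Read a CF table CSV (group_label, age_min_months, age_max_months,
    cf_cm, cf_sd_cm); '#' comments allowed."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"group_label", "age_min_months", "age_max_months", "cf_cm", "cf_sd_cm"}
    missing = required - set(df.columns)
    if missing:
        raise CalibrationError(f"CF file {path} missing columns {sorted(missing)}")
    table = [
        CorrectionFactor(
            group=AgeGroup(
                str(r.group_label), float(r.age_min_months), float(r.age_max_months)
            ),
            cf=Measurement(float(r.cf_cm), float(r.cf_sd_cm)),
        )
        for r in df.itertuples()
    ]
    _check_groups(table)
    return table


def save_cf_table(table, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "group_label": cf.group.label,
                "age_min_months": cf.group.min_months,
                "age_max_months": cf.group.max_months,
                "cf_cm": cf.cf.value,
                "cf_sd_cm": cf.cf.sd,
            }
            for cf in table
        ]
    ).to_csv(path, index=False)


def _check_groups(table) -> None:
    groups = sorted(table, key=lambda cf: cf.group.min_months)
    for a, b in zip(groups, groups[1:]):
        if b.group.min_months < a.group.max_months:
            raise CalibrationError(
                f"overlapping age groups {a.group.label!r} and {b.group.label!r}"
            )
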