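"""Bundled reference data: the 2021 ring-phantom calibration campaign.

The instrument family this package reimplements was calibrated once against
3D-printed ring phantoms; the resulting record (five reads per ring, the
calipered real circumference, and the published per-row summaries) ships
here as data, together with the correction factors that calibration put
into service.  The applied CFs (-2.8 and -3.7 cm) do not equal the mean of
the published per-ring differences (-2.6 and -3.5 cm); the discrepancy is
unexplained in the source record, so both are exposed and neither is
silently preferred: ``"paper2021"`` is the as-applied preset, and
:func:`headcirc.calibration.derive_cf` re-derives the pooled values from
the rows.
"""

from __future__ import annotations

from .calibration import AgeGroup, CorrectionFactor, Measurement

__all__ = [
    "CF_PRESETS",
    "REFERENCE_RING_READS",
    "REFERENCE_COMPARISON_SUBJECTS",
    "cf_preset",
]

#: Correction factors as applied in the 2021 calibration: one per age group,
#: younger than 36 months and 36 months up to 18 years.
CF_PRESETS = {
    "paper2021": [
        CorrectionFactor(AgeGroup("0-3", 0.0, 36.0), Measurement(-2.8, 0.2)),
        CorrectionFactor(AgeGroup("3-18", 36.0, 216.0), Measurement(-3.7, 0.3)),
    ],
}


def cf_preset(name: str = "paper2021") -> list:
    """Return a named CF preset (a list of :class:`CorrectionFactor`)."""
    try:
        return list(CF_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown CF preset {name!r}; available: {sorted(CF_PRESETS)}"
        ) from None


#: The published calibration table: per ring, the five circumference reads
#: (cm), the certified real value with its stated +/- 0.3 cm, and the row
#: summaries as printed (est, est_sd, diff, diff_sd).  Structure 1 covers
#: ages 0-3 years (9 rings), structure 2 covers 3-18 years (4 rings).
REFERENCE_RING_READS = [
    # label, group, reads, real, real_sd, printed est, est_sd, diff, diff_sd
    ("Ring 1", "0-3", (37.88, 38.47, 37.91, 38.14, 38.06), 35.5, 0.3, 38.1, 0.2, -2.6, 0.4),
    ("Ring 2", "0-3", (41.96, 41.27, 42.04, 41.75, 41.15), 39.3, 0.3, 41.6, 0.4, -2.4, 0.5),
    ("Ring 3", "0-3", (44.55, 44.40, 44.75, 44.33, 44.72), 41.8, 0.3, 44.6, 0.2, -2.8, 0.4),
    ("Ring 4", "0-3", (46.68, 46.29, 46.06, 46.34, 45.82), 43.4, 0.3, 46.2, 0.3, -2.9, 0.4),
    ("Ring 5", "0-3", (47.71, 48.17, 48.35, 47.89, 48.16), 45.6, 0.3, 48.1, 0.3, -2.4, 0.4),
    ("Ring 6", "0-3", (48.32, 48.83, 49.24, 48.96, 49.62), 46.5, 0.3, 49.0, 0.5, -2.5, 0.6),
    ("Ring 7", "0-3", (50.55, 50.18, 50.35, 50.64, 49.41), 47.7, 0.3, 50.2, 0.5, -2.5, 0.6),
    ("Ring 8", "0-3", (50.51, 51.48, 50.51, 50.65, 51.07), 48.4, 0.3, 50.9, 0.4, -2.5, 0.5),
    ("Ring 9", "0-3", (52.71, 52.08, 51.89, 51.72, 52.12), 49.3, 0.3, 52.1, 0.4, -2.8, 0.5),
    ("Ring 10", "3-18", (55.28, 54.46, 54.67, 54.34, 54.08), 51.2, 0.3, 54.6, 0.5, -3.2, 0.6),
    ("Ring 11", "3-18", (56.36, 56.58, 55.69, 56.58, 56.70), 52.8, 0.3, 56.4, 0.4, -3.6, 0.5),
    ("Ring 12", "3-18", (58.11, 58.52, 58.11, 58.22, 58.24), 54.7, 0.3, 58.2, 0.2, -3.6, 0.4),
    ("Ring 13", "3-18", (59.48, 58.67, 58.34, 58.52, 59.47), 55.3, 0.3, 58.9, 0.5, -3.6, 0.6),
]

#: The published manual-vs-automatic comparison: per subject, the voxel
#: resolution, manual reading (+/- 0.1 cm), automatic reading (+/- 0.5 cm),
#: applied CF, and the printed derived columns
#: (diff1, diff1_sd, new_hc, new_hc_sd, diff2, diff2_sd).  All cm.
REFERENCE_COMPARISON_SUBJECTS = [
    # id, (sx, sy, sz), manual, man_sd, auto, auto_sd, cf, cf_sd,
    #     diff1, diff1_sd, new_hc, new_hc_sd, diff2, diff2_sd
    (1, (0.58, 0.58, 5.00), 57.1, 0.1, 61.3, 0.5, -3.7, 0.3, -4.2, 0.5, 57.6, 0.6, -0.5, 0.6),
    (2, (0.41, 0.41, 4.00), 44.8, 0.1, 46.7, 0.5, -2.8, 0.2, -1.9, 0.5, 43.9, 0.5, 0.9, 0.5),
    (3, (0.58, 0.58, 5.00), 49.0, 0.1, 53.3, 0.5, -3.7, 0.3, -4.3, 0.5, 49.6, 0.6, -0.6, 0.6),
    (4, (0.85, 0.85, 3.99), 48.5, 0.1, 52.7, 0.5, -3.7, 0.3, -4.2, 0.5, 49.0, 0.6, -0.5, 0.6),
    (5, (0.46, 0.46, 4.99), 57.1, 0.1, 60.1, 0.5, -3.7, 0.3, -3.0, 0.5, 56.4, 0.6, 0.7, 0.6),
    (6, (0.57, 0.57, 4.99), 54.6, 0.1, 57.6, 0.5, -3.7, 0.3, -3.0, 0.5, 53.9, 0.6, 0.7, 0.6),
    (7, (0.79, 0.79, 4.99), 56.0, 0.1, 59.1, 0.5, -3.7, 0.3, -3.1, 0.5, 55.5, 0.6, 0.5, 0.6),
]
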