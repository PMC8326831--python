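"""Head-circumference-for-age reference charts: lookup and plotting.

A reference chart is a table of (age_months, sex, mean_cm, sd_cm) rows —
the mean +/- sd band format of the classic Nellhaus curves.  Lookups
interpolate mean and sd linearly between tabulated ages and convert a
reading to a z-score and normal percentile.  No real chart is bundled:
users supply digitized curves; a clearly-synthetic example generator is
provided for demos and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ReferenceChart",
    "ChartFormatError",
    "AgeRangeError",
    "load_chart",
    "save_chart",
    "percentile",
    "plot_chart",
    "synthetic_example_chart",
]

_COLUMNS = ("age_months", "sex", "mean_cm", "sd_cm")


class ChartFormatError(ValueError):
    """Malformed reference-chart table."""


class AgeRangeError(ValueError):
    """Requested age outside the tabulated range (no extrapolation)."""


@dataclass
class ReferenceChart:
    """Validated reference curves, one row per (sex, age)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ChartFormatError(f"chart missing columns {sorted(missing)}")
        df = df.loc[:, list(_COLUMNS)].copy()
        df["sex"] = df["sex"].astype(str)
        for sex, sub in df.groupby("sex"):
            ages = sub["age_months"].to_numpy(dtype=float)
            if len(ages) < 2:
                raise ChartFormatError(f"sex {sex!r}: need at least 2 ages")
            if np.any(np.diff(ages) <= 0):
                raise ChartFormatError(
                    f"sex {sex!r}: ages must be strictly increasing "
                    "(no duplicates)"
                )
            if np.any(sub["sd_cm"].to_numpy(dtype=float) <= 0):
                raise ChartFormatError(f"sex {sex!r}: sd_cm must be > 0")
        self.table = df

    def sexes(self):
        return sorted(self.table["sex"].unique())

    def age_range(self, sex: str) -> tuple[float, float]:
        sub = self._sub(sex)
        ages = sub["age_months"].to_numpy(dtype=float)
        return float(ages[0]), float(ages[-1])

    def _sub(self, sex: str) -> pd.DataFrame:
        sub = self.table[self.table["sex"] == str(sex)]
        if sub.empty:
            raise ChartFormatError(
                f"chart has no rows for sex {sex!r}; available: {self.sexes()}"
            )
        return sub

    def lookup(self, age_months: float, sex: str) -> tuple[float, float]:
        """Linearly interpolated (mean_cm, sd_cm) at an age; exact at knots."""
        sub = self._sub(sex)
        ages = sub["age_months"].to_numpy(dtype=float)
        if not ages[0] <= age_months <= ages[-1]:
            raise AgeRangeError(
                f"age {age_months} months outside chart range "
                f"[{ages[0]}, {ages[-1]}] for sex {sex!r}"
            )
        mean = float(np.interp(age_months, ages, sub["mean_cm"].to_numpy(float)))
        sd = float(np.interp(age_months, ages, sub["sd_cm"].to_numpy(float)))
        return mean, sd


def load_chart(path) -> ReferenceChart:
    """Read a chart CSV (age_months, sex, mean_cm, sd_cm); '#' comments allowed."""
    df = pd.read_csv(path, comment="#")
    return ReferenceChart(df)


def save_chart(chart: ReferenceChart, path) -> None:
    chart.table.to_csv(path, index=False)


def percentile(hc_cm: float, age_months: float, sex: str, chart: ReferenceChart):
    """z-score and normal percentile of a reading against the chart.

    z = (hc - mean(age)) / sd(age) with interpolated mean and sd; the
    percentile is 100 * Phi(z).
    """
    mean, sd = chart.lookup(age_months, sex)
    z = (hc_cm - mean) / sd
    return float(z), float(100.0 * norm.cdf(z))


def synthetic_example_chart() -> ReferenceChart:
    """A SYNTHETIC demonstration chart (not digitized from any published
    reference).

    Mean curves follow a saturating-growth shape spanning roughly 34 cm at
    birth to 56-57 cm at 18 years, with sd widening from 1.2 to 1.6 cm —
    plausible magnitudes for demos and tests only.
    """
    ages = np.array([0, 3, 6, 9, 12, 18, 24, 36, 48, 72, 108, 144, 216], float)
    rows = []
    for sex, scale in (("m", 1.0), ("f", 0.98)):
        mean = scale * (34.0 + 13.5 * (1.0 - np.exp(-ages / 10.0)) + 0.022 * ages)
        sd = 1.2 + 0.4 * ages / 216.0
        for a, m, s in zip(ages, mean, sd):
            rows.append(
                {
                    "age_months": a,
                    "sex": sex,
                    "mean_cm": round(float(m), 2),
                    "sd_cm": round(float(s), 2),
                }
            )
    return ReferenceChart(pd.DataFrame(rows))


def plot_chart(
    chart: ReferenceChart,
    points=(),
    path=None,
    csv_twin_path=None,
    sex: str | None = None,
):
    """Plot mean and mean +/- 2 sd curves with overlaid readings.

    ``points`` is a sequence of ``(age_months, hc_cm, label)``.  Readings
    outside the tabulated age range are drawn with an out-of-range marker
    and a warning.  The numeric content (curves and points) is also written
    to ``csv_twin_path`` so the plot is testable; returns the twin
    DataFrame.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sexes = [sex] if sex is not None else chart.sexes()
    fig, ax = plt.subplots(figsize=(7, 5))
    twin_rows = []
    for sx in sexes:
        sub = chart._sub(sx)
        ages = sub["age_months"].to_numpy(float)
        mean = sub["mean_cm"].to_numpy(float)
        sd = sub["sd_cm"].to_numpy(float)
        ax.plot(ages, mean, label=f"mean ({sx})")
        ax.plot(ages, mean + 2 * sd, "--", lw=0.8)
        ax.plot(ages, mean - 2 * sd, "--", lw=0.8)
        for a, m, s in zip(ages, mean, sd):
            twin_rows.append(
                {
                    "kind": "curve",
                    "sex": sx,
                    "age_months": a,
                    "mean_cm": m,
                    "upper_cm": m + 2 * s,
                    "lower_cm": m - 2 * s,
                    "hc_cm": np.nan,
                    "label": "",
                }
            )
    for age, hc, label in points:
        in_range = False
        for sx in sexes:
            lo, hi = chart.age_range(sx)
            if lo <= age <= hi:
                in_range = True
        marker = "o" if in_range else "x"
        if not in_range:
            warnings.warn(
                f"point {label!r} at age {age} months is outside the chart "
                "age range",
                stacklevel=2,
            )
        ax.plot([age], [hc], marker, color="k")
        ax.annotate(str(label), (age, hc), fontsize=8)
        twin_rows.append(
            {
                "kind": "point" if in_range else "point-out-of-range",
                "sex": "",
                "age_months": age,
                "mean_cm": np.nan,
                "upper_cm": np.nan,
                "lower_cm": np.nan,
                "hc_cm": hc,
                "label": str(label),
            }
        )
    ax.set_xlabel("age (months)")
    ax.set_ylabel("head circumference (cm)")
    ax.legend()
    twin = pd.DataFrame(twin_rows)
    if path is not None:
        fig.savefig(path, dpi=120)
    plt.close(fig)
    if csv_twin_path is not None:
        twin.to_csv(csv_twin_path, index=False)
    return twin
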