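"""Place a measurement on a head-circumference-for-age reference chart.

Uses the SYNTHETIC example chart bundled with the package (real charts are
user-supplied CSVs with age_months, sex, mean_cm, sd_cm columns), looks up
a reading's z-score and percentile, and writes the chart plot with its
testable CSV twin.
"""

from headcirc.charts import percentile, plot_chart, synthetic_example_chart

chart = synthetic_example_chart()

age, sex, hc_cm = 24.0, "m", 48.0
z, pct = percentile(hc_cm, age, sex, chart)
mean, sd = chart.lookup(age, sex)

print(f"chart at {age:.0f} months ({sex}): mean {mean:.1f} cm, sd {sd:.2f} cm")
print(f"reading {hc_cm:.1f} cm -> z = {z:+.2f}, percentile {pct:.1f}")

twin = plot_chart(
    chart,
    points=[(age, hc_cm, "patient")],
    path="chart.png",
    csv_twin_path="chart_twin.csv",
    sex=sex,
)
print(f"wrote chart.png and chart_twin.csv ({len(twin)} rows)")

# A z-score near +1 places the child toward the upper band of the chart;
# the mean ± 2 sd curves in the plot correspond to roughly the 2.3rd and
# 97.7th percentiles under the per-age normal model.
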