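"""Exercise the statistical decision cascade on simulated operators.

Three simulated clinicians read the same 52-child cohort; one of them
over-reads by half a centimeter.  The cascade screens each operator's
sample for normality (moments + Shapiro-Wilk), certifies equal variances
(Levene), and only then compares locations (one-way ANOVA).
"""

from headcirc.stats import run_cascade, simulate_operators

# operators re-measuring a reference cohort; operator 3 biased +0.5 cm
groups = simulate_operators(
    n_subjects=52,
    n_operators=3,
    operator_bias_cm=(0.0, 0.0, 0.5),
    operator_sd_cm=0.4,
    subject_mean_fn=lambda rng, n: rng.normal(48.0, 0.0, n),
    seed=7,
)

result = run_cascade(groups, alpha=0.05)

for screen in result.screens:
    print(
        f"{screen.label}: skew {screen.skewness:+.2f}, "
        f"kurtosis {screen.kurtosis:+.2f}, Shapiro p = {screen.shapiro.p_value:.3f}"
        f" -> {'normal' if screen.passed else 'NOT normal'}"
    )
print(f"Levene: W = {result.levene.statistic:.3f}, p = {result.levene.p_value:.3f}")
print(f"{result.final.test_name}: statistic = {result.final.statistic:.2f}, "
      f"p = {result.final.p_value:.2g}")
print(result.final.decision_text)

# With a 0.5 cm bias against 0.4 cm operator noise the ANOVA discards the
# null decisively: operator differences of the size seen in clinics are
# detectable, which is the motivation for an automatic instrument.
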