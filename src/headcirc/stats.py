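"""Statistical decision cascade for comparing operators and instruments.

Manual head-circumference readings are operator-dependent; the validation
protocol quantifies that with a fixed cascade: (1) screen each sample for
normality via moment skewness/kurtosis in [-1, 1] plus the Shapiro-Wilk
test, (2) certify equal variances with Levene's test, (3) only then compare
locations — one-way ANOVA for three or more groups, two-sample pooled t-test
for two.  Every decision follows "discard H0 if p <= alpha".  A simulated
clinic (per-operator bias and noise on shared subject truths) exercises the
cascade where real readings are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleSet",
    "StatDecision",
    "NormalityScreen",
    "CascadeResult",
    "normality_screen",
    "variance_homogeneity",
    "compare_groups",
    "run_cascade",
    "simulate_operators",
]


@dataclass
class SampleSet:
    """A labeled sample of readings (cm)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StatDecision:
    """One test's outcome under 'discard H0 if p <= alpha'."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    reject_h0: bool
    decision_text: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class NormalityScreen:
    """Moment screen plus Shapiro-Wilk for one sample."""

    label: str
    kurtosis: float  # excess kurtosis (normal -> 0)
    skewness: float
    range_ok: bool  # both moments within [-1, 1]
    shapiro: StatDecision

    @property
    def passed(self) -> bool:
        return self.range_ok and not self.shapiro.reject_h0


@dataclass
class CascadeResult:
    """Full cascade outcome; ``final`` is None when a screen refused it."""

    screens: list
    levene: StatDecision | None
    final: StatDecision | None
    refused_by: str | None


def _decision(test_name: str, statistic: float, p: float, alpha: float, h0: str) -> StatDecision:
    reject = bool(p <= alpha)
    text = (
        f"discard H0 ({h0}): p = {p:.3g} <= alpha = {alpha:g}"
        if reject
        else f"cannot discard H0 ({h0}): p = {p:.3g} > alpha = {alpha:g}"
    )
    return StatDecision(
        test_name=test_name,
        statistic=float(statistic),
        p_value=float(p),
        alpha=alpha,
        reject_h0=reject,
        decision_text=text,
    )


def _require_varied(s: SampleSet, min_n: int = 3) -> None:
    if s.n < min_n:
        raise ValueError(f"sample {s.label!r} has n = {s.n} < {min_n}")
    if np.ptp(s.values) == 0:
        raise ValueError(f"sample {s.label!r} is constant")


def normality_screen(s: SampleSet, alpha: float = 0.05) -> NormalityScreen:
    """Moment skewness/excess-kurtosis screen plus Shapiro-Wilk.

    Moments use the bias-uncorrected (population-moment) definitions; the
    screen passes when both lie in [-1, 1].  Kurtosis is excess kurtosis
    (a normal sample scatters around 0), the only reading under which
    normal data land inside the band.
    """
    _require_varied(s)
    skew = float(sps.skew(s.values, bias=True))
    kurt = float(sps.kurtosis(s.values, fisher=True, bias=True))
    range_ok = -1.0 <= skew <= 1.0 and -1.0 <= kurt <= 1.0
    w, p = sps.shapiro(s.values)
    return NormalityScreen(
        label=s.label,
        kurtosis=kurt,
        skewness=skew,
        range_ok=range_ok,
        shapiro=_decision("Shapiro-Wilk", w, p, alpha, "data is normal"),
    )


def variance_homogeneity(groups, alpha: float = 0.05) -> StatDecision:
    """Levene's test (mean-centered) for equal variances across groups."""
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        _require_varied(g)
    w, p = sps.levene(*(g.values for g in groups), center="mean")
    return _decision("Levene", w, p, alpha, "equal variances")


def compare_groups(groups, alpha: float = 0.05, welch: bool = False) -> StatDecision:
    """Location comparison: one-way ANOVA (>= 3 groups) or two-sample t-test.

    The two-group test pools variances by default, since the cascade has
    already certified homogeneity; ``welch=True`` opts out.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has n < 2")
    if len(groups) == 2:
        t, p = sps.ttest_ind(
            groups[0].values, groups[1].values, equal_var=not welch
        )
        return _decision("t-test", t, p, alpha, "u1 = u2")
    f, p = sps.f_oneway(*(g.values for g in groups))
    # identical groups: cancellation can leave a tiny negative F and nan p
    if f < 1e-10 and (np.isnan(p) or f < 0):
        f, p = max(float(f), 0.0), 1.0
    h0 = " = ".join(f"u{i + 1}" for i in range(len(groups)))
    return _decision("ANOVA", f, p, alpha, h0)


def run_cascade(groups, alpha: float = 0.05, welch: bool = False) -> CascadeResult:
    """Run the full decision cascade, refusing the final test on any failed screen.

    Order: per-group normality screens, then Levene, then ANOVA/t-test.  If
    a normality screen fails or Levene rejects, the final test is not run and
    ``refused_by`` names the failed screen.
    """
    groups = list(groups)
    screens = [normality_screen(g, alpha) for g in groups]
    for scr in screens:
        if not scr.passed:
            return CascadeResult(
                screens=screens,
                levene=None,
                final=None,
                refused_by=f"normality({scr.label})",
            )
    levene = variance_homogeneity(groups, alpha)
    if levene.reject_h0:
        return CascadeResult(
            screens=screens, levene=levene, final=None, refused_by="Levene"
        )
    final = compare_groups(groups, alpha, welch=welch)
    return CascadeResult(screens=screens, levene=levene, final=final, refused_by=None)


def simulate_operators(
    n_subjects: int,
    n_operators: int,
    operator_bias_cm,
    operator_sd_cm: float,
    subject_mean_fn=None,
    seed: int = 0,
    shared_subjects: bool = True,
) -> list:
    """Simulate a clinic: each operator reads every subject once.

    Per subject a true circumference is drawn from ``subject_mean_fn(rng,
    n)`` (default: normal with mean 48 cm, sd 4 cm, the spread of a mixed-age
    pediatric cohort); operator o's reading is truth + bias_o + Gaussian
    noise of sd ``operator_sd_cm``.  ``operator_bias_cm`` is a scalar or a
    per-operator sequence.  Returns one :class:`SampleSet` per operator.

    ``shared_subjects`` controls the sampling design.  ``True`` mirrors the
    clinic protocol: every operator reads the *same* cohort, so the
    operators' samples are correlated through the subjects and a one-way
    ANOVA across operators is conservative (the shared between-subject
    spread inflates the within-group variance but cancels from the group
    means).  ``False`` draws a fresh cohort per operator, making the groups
    independent — the sampling regime under which the one-way tests attain
    their nominal error rate, used for type-I calibration of the harness.
    """
    if operator_sd_cm < 0:
        raise ValueError("operator_sd_cm must be >= 0")
    rng = np.random.default_rng(seed)
    biases = np.broadcast_to(
        np.asarray(operator_bias_cm, dtype=float), (n_operators,)
    )

    def draw_truths():
        if subject_mean_fn is None:
            return rng.normal(48.0, 4.0, n_subjects)
        return np.asarray(subject_mean_fn(rng, n_subjects), dtype=float)

    truths = draw_truths() if shared_subjects else None
    out = []
    for o in range(n_operators):
        base = truths if shared_subjects else draw_truths()
        noise = (
            rng.normal(0.0, operator_sd_cm, n_subjects)
            if operator_sd_cm > 0
            else np.zeros(n_subjects)
        )
        out.append(
            SampleSet(label=f"operator{o + 1}", values=base + biases[o] + noise)
        )
    return out
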