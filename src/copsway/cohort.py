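"""Cohort-level aggregation and the inferential chain.

Per-record ellipse metrics (eccentricity, long diameter, declination,
lateral component) are aggregated into a condition x trial summary table;
participants whose quiet-stance lateral sway is a box-plot outlier are
excluded by the Tukey 1.5*IQR fence rule; between-trial and
background-vs-stimulus "effects of stimuli" are formed as ratios for
eccentricity and long diameter and as differences for declination and
lateral component; and the headline inference is a paired two-sided t test
of the declination between the array-speakers-only condition and each
headphone condition (first trials), with exact one-sample Kolmogorov-Smirnov
and Shapiro-Wilk normality diagnostics of the paired differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ellipse import fit_probability_ellipse
from .exceptions import ValidationError
from .trajectory import CopTrajectory, HEADPHONE_CONDITIONS

__all__ = [
    "OutlierResult",
    "PairedTestResult",
    "CohortSummary",
    "detect_outliers",
    "effect_of_stimuli",
    "paired_t_test",
    "ci_from_summary",
    "normality_diagnostics",
    "assign_orders",
    "summarize_cohort",
    "metrics_table",
]

#: Per-record ellipse metrics carried through the cohort table.
METRICS = ("eccentricity", "long_diameter", "declination", "lateral_component")

#: Metrics whose effect of stimuli is a ratio (b/a); the rest use b - a.
RATIO_METRICS = frozenset({"eccentricity", "long_diameter"})

_METRIC_ALIASES = {
    "eps": "eccentricity",
    "epsilon": "eccentricity",
    "delta": "long_diameter",
    "theta": "declination",
    "psi": "lateral_component",
}


def _canonical_metric(name: str) -> str:
    metric = _METRIC_ALIASES.get(name.lower(), name.lower())
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {name!r}; expected one of {METRICS}")
    return metric


# ---------------------------------------------------------------------------
# outlier exclusion


@dataclass(frozen=True)
class OutlierResult:
    """Participants excluded by the Tukey fence rule, with the fences used."""

    excluded: frozenset[str]
    lower_fence: float
    upper_fence: float
    q1: float
    q3: float


def detect_outliers(
    per_participant_stat: Mapping[str, float], k: float = 1.5
) -> OutlierResult:
    """Box-plot (Tukey fence) outlier exclusion.

    Excludes participants whose statistic lies strictly above
    ``Q3 + k*IQR`` or strictly below ``Q1 - k*IQR`` (quartiles by linear
    interpolation over all supplied values).  A value exactly at a fence is
    retained.
    """
    if len(per_participant_stat) == 0:
        raise ValidationError("no participants supplied")
    if len(per_participant_stat) < 5:
        raise ValidationError(
            f"need at least 5 participants for fences, got {len(per_participant_stat)}"
        )
    ids = list(per_participant_stat)
    values = np.asarray([per_participant_stat[i] for i in ids], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("outlier statistic contains non-finite values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    excluded = frozenset(
        pid for pid, v in zip(ids, values) if v > upper or v < lower
    )
    return OutlierResult(
        excluded=excluded,
        lower_fence=float(lower),
        upper_fence=float(upper),
        q1=float(q1),
        q3=float(q3),
    )


# ---------------------------------------------------------------------------
# effects of stimuli


def effect_of_stimuli(metric_name: str, value_a: float, value_b: float) -> float:
    """Between-condition or between-trial effect for one metric.

    Ratio ``b/a`` for eccentricity and long diameter; difference ``b - a``
    for declination and lateral component.
    """
    metric = _canonical_metric(metric_name)
    if metric in RATIO_METRICS:
        if value_a == 0:
            raise ValidationError(
                f"ratio effect for {metric} undefined: zero denominator"
            )
        return float(value_b) / float(value_a)
    return float(value_b) - float(value_a)


# ---------------------------------------------------------------------------
# paired inference


@dataclass(frozen=True)
class PairedTestResult:
    """Paired two-sided t test with normality diagnostics of the differences.

    ``mean_difference = mean(a) - mean(b)``; the confidence interval is for
    the mean difference at the requested level.  ``ks_D``/``ks_p`` are the
    exact one-sample Kolmogorov-Smirnov test of the self-standardized
    differences against the standard normal; ``shapiro_W``/``shapiro_p`` the
    Shapiro-Wilk test.  When the differences are constant the test is
    degenerate: diagnostics are NaN, and the p value is 1 (all-zero
    differences) or NaN (constant nonzero offset).
    """

    n: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_difference: float
    t: float
    df: int
    p_two_sided: float
    ci95: tuple[float, float]
    level: float
    ks_D: float
    ks_p: float
    shapiro_W: float
    shapiro_p: float
    degenerate: bool = False


def paired_t_test(a, b, level: float = 0.95) -> PairedTestResult:
    """Paired t test of matched per-participant values ``a`` vs ``b``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and an ``n-1``
    denominator in ``sd``; two-sided p from Student's t with ``n-1`` degrees
    of freedom; CI ``mean(d) +/- t_{1-alpha/2,df} * sd(d)/sqrt(n)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise ValidationError(
            f"paired samples must be 1-d and matched, got {a.shape} vs {b.shape}"
        )
    n = len(a)
    if n < 3:
        raise ValidationError(f"need at least 3 pairs, got {n}")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        degenerate = True
        if md == 0.0:
            t_stat, p, ci = 0.0, 1.0, (0.0, 0.0)
        else:
            t_stat = np.inf if md > 0 else -np.inf
            p, ci = np.nan, (md, md)
        ks_D = ks_p = sw = sw_p = np.nan
    else:
        degenerate = False
        se = sd / np.sqrt(n)
        t_stat = md / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        tc = float(stats.t.ppf(0.5 + level / 2.0, df))
        ci = (md - tc * se, md + tc * se)
        ks_D, ks_p, sw, sw_p = normality_diagnostics(d)
    return PairedTestResult(
        n=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        mean_difference=md,
        t=float(t_stat),
        df=df,
        p_two_sided=p,
        ci95=(float(ci[0]), float(ci[1])),
        level=level,
        ks_D=ks_D,
        ks_p=ks_p,
        shapiro_W=sw,
        shapiro_p=sw_p,
        degenerate=degenerate,
    )


def ci_from_summary(
    mean_difference: float, t: float, df: int, level: float = 0.95
) -> tuple[float, float]:
    """Reconstruct the confidence interval implied by printed summary numbers.

    From a reported mean difference and t statistic the standard error is
    ``|mean_difference / t|``; the interval is
    ``mean_difference +/- t_{1-alpha/2,df} * se``.
    """
    if t == 0:
        raise ValidationError("cannot reconstruct a CI from t = 0")
    if df < 1:
        raise ValidationError("df must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    se = abs(mean_difference / t)
    tc = float(stats.t.ppf(0.5 + level / 2.0, df))
    return (mean_difference - tc * se, mean_difference + tc * se)


def normality_diagnostics(d) -> tuple[float, float, float, float]:
    """Normality diagnostics of a difference sample.

    Returns ``(ks_D, ks_p, shapiro_W, shapiro_p)``: the exact one-sample
    Kolmogorov-Smirnov statistic of the differences standardized by their own
    sample mean and SD against the standard normal, and the Shapiro-Wilk
    statistic.  Because the normal parameters are estimated from the same
    sample, the KS p value is conservative (the Lilliefors correction is not
    applied — this mirrors common practice of reporting the exact KS test on
    standardized residuals).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or len(d) < 3:
        raise ValidationError("need a 1-d sample of at least 3 differences")
    if len(d) > 5000:
        raise ValidationError("Shapiro-Wilk is limited to n <= 5000")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant differences: normality tests undefined")
    z = (d - d.mean()) / sd
    ks = stats.kstest(z, "norm", method="exact")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for near-ties, not errors
        sw = stats.shapiro(d)
    return (
        float(ks.statistic),
        float(ks.pvalue),
        float(sw.statistic),
        float(sw.pvalue),
    )


# ---------------------------------------------------------------------------
# condition-order counterbalancing


def assign_orders(
    participants: Sequence[str],
    conditions: Sequence[str] = HEADPHONE_CONDITIONS,
    seed: int | None = None,
) -> dict[str, tuple[str, ...]]:
    """Assign counterbalanced headphone-condition orders.

    All ``len(conditions)!`` permutations are used; with ``n`` divisible by
    the number of permutations each receives ``n/perms`` participants,
    otherwise assignment is round-robin (some permutations receive one more)
    and a warning is emitted.  With a seed, the permutation list is shuffled
    once before assignment; participants are always taken in the given order,
    so the mapping is deterministic for a given ordering and seed.
    """
    participants = list(participants)
    if not participants:
        raise ValidationError("no participants to assign")
    perms = list(itertools.permutations(conditions))
    if seed is not None:
        rng = np.random.default_rng(seed)
        perms = [perms[i] for i in rng.permutation(len(perms))]
    if len(participants) % len(perms) != 0:
        warnings.warn(
            f"{len(participants)} participants not divisible by {len(perms)} "
            "orders; assigning remainder round-robin",
            stacklevel=2,
        )
    return {
        pid: perms[i % len(perms)] for i, pid in enumerate(participants)
    }


# ---------------------------------------------------------------------------
# whole-cohort summary


@dataclass(frozen=True)
class CohortSummary:
    """Cohort table plus inferential results.

    ``rows`` has one line per fitted record (participant, condition, trial,
    four metrics).  ``condition_means`` averages the retained participants
    per condition x trial.  ``effects`` holds the effects of stimuli:
    between-trial effects per headphone condition and the background
    (silent) vs standard-stimuli (array-only) contrast.  ``tests`` maps
    ``(condition, trial)`` to the paired declination test of array-only vs
    that headphone condition.
    """

    rows: pd.DataFrame
    condition_means: pd.DataFrame
    effects: pd.DataFrame
    tests: dict[tuple[str, int], PairedTestResult]
    holm_adjusted_p: dict[tuple[str, int], float] | None
    outliers: OutlierResult | None
    retained: tuple[str, ...]
    exclusion_log: tuple[str, ...] = field(default_factory=tuple)


def metrics_table(
    dataset: Iterable[CopTrajectory], coverage: float = 0.900
) -> pd.DataFrame:
    """Fit the probability ellipse to every record and tabulate the metrics."""
    rows = []
    for traj in dataset:
        ell = fit_probability_ellipse(traj, coverage=coverage)
        rows.append(
            {
                "participant_id": traj.participant_id,
                "condition": traj.condition,
                "trial": traj.trial_index,
                "eccentricity": ell.eccentricity,
                "long_diameter": ell.long_diameter,
                "declination": ell.declination,
                "lateral_component": ell.lateral_component,
            }
        )
    if not rows:
        raise ValidationError("empty dataset")
    return pd.DataFrame(rows)


def summarize_cohort(
    dataset: Iterable[CopTrajectory],
    coverage: float = 0.900,
    exclude_outliers: bool = True,
    holm: bool = False,
    headline_trial: int = 1,
) -> CohortSummary:
    """Run the full evaluation chain on a cohort of trajectories.

    Ellipses are fitted per record; participants are excluded when their
    quiet-stance (silent-condition) maximum absolute lateral component is a
    Tukey-fence outlier, or when they lack the cells a comparison needs;
    condition means, effects of stimuli and the paired declination tests
    (array-only vs each headphone condition, per trial) are computed on the
    retained participants.
    """
    rows = metrics_table(dataset, coverage=coverage)
    log: list[str] = []

    outliers: OutlierResult | None = None
    retained = sorted(rows["participant_id"].unique())
    if exclude_outliers:
        silent = rows[rows["condition"] == "silent"]
        missing = set(retained) - set(silent["participant_id"])
        for pid in sorted(missing):
            log.append(f"{pid}: no silent-condition record; excluded")
        candidates = {
            pid: float(
                silent.loc[silent["participant_id"] == pid, "lateral_component"]
                .abs()
                .max()
            )
            for pid in retained
            if pid not in missing
        }
        if len(candidates) >= 5:
            outliers = detect_outliers(candidates)
            for pid in sorted(outliers.excluded):
                log.append(
                    f"{pid}: silent |lateral component| "
                    f"{candidates[pid]:.2f} mm outside Tukey fences "
                    f"[{outliers.lower_fence:.2f}, {outliers.upper_fence:.2f}]; excluded"
                )
            retained = [
                pid
                for pid in retained
                if pid not in outliers.excluded and pid not in missing
            ]
        else:
            log.append("fewer than 5 participants with silent records; outlier filter skipped")
            retained = [pid for pid in retained if pid not in missing]

    kept = rows[rows["participant_id"].isin(retained)]
    condition_means = (
        kept.groupby(["condition", "trial"], as_index=False)[list(METRICS)]
        .mean()
        .sort_values(["condition", "trial"], ignore_index=True)
    )

    effects = _effects_table(condition_means)

    tests: dict[tuple[str, int], PairedTestResult] = {}
    array_rows = kept[(kept["condition"] == "array_only")]
    for cond in HEADPHONE_CONDITIONS:
        for trial in sorted(kept.loc[kept["condition"] == cond, "trial"].unique()):
            sub = kept[(kept["condition"] == cond) & (kept["trial"] == trial)]
            ref = array_rows[array_rows["trial"].isin([headline_trial])]
            merged = pd.merge(
                ref[["participant_id", "declination"]],
                sub[["participant_id", "declination"]],
                on="participant_id",
                suffixes=("_array", "_device"),
            )
            if len(merged) < 3:
                log.append(
                    f"array_only vs {cond} (trial {trial}): only {len(merged)} "
                    "matched participants; paired test refused (needs >= 3)"
                )
                continue
            tests[(cond, int(trial))] = paired_t_test(
                merged["declination_array"].to_numpy(),
                merged["declination_device"].to_numpy(),
            )

    holm_adjusted: dict[tuple[str, int], float] | None = None
    if holm and tests:
        headline = [k for k in tests if k[1] == headline_trial]
        if headline:
            raw = [tests[k].p_two_sided for k in headline]
            adj = multipletests(raw, method="holm")[1]
            holm_adjusted = dict(zip(headline, map(float, adj)))

    return CohortSummary(
        rows=rows,
        condition_means=condition_means,
        effects=effects,
        tests=tests,
        holm_adjusted_p=holm_adjusted,
        outliers=outliers,
        retained=tuple(retained),
        exclusion_log=tuple(log),
    )


def _effects_table(condition_means: pd.DataFrame) -> pd.DataFrame:
    """Effects of stimuli from a condition x trial mean table."""
    cm = condition_means.set_index(["condition", "trial"])
    records = []

    def add(label: str, key_a, key_b):
        if key_a in cm.index and key_b in cm.index:
            rec = {"contrast": label}
            for metric in METRICS:
                a = cm.loc[key_a, metric]
                b = cm.loc[key_b, metric]
                try:
                    rec[metric] = effect_of_stimuli(metric, a, b)
                except ValidationError:
                    rec[metric] = np.nan
            records.append(rec)

    # background (silent) vs standard stimuli (array speakers only)
    add("silent_vs_array_only", ("silent", 1), ("array_only", 1))
    # trial 1 vs trial 2 per headphone condition
    for cond in HEADPHONE_CONDITIONS:
        add(f"{cond}_trial1_vs_trial2", (cond, 1), (cond, 2))
    columns = ["contrast", *METRICS]
    return pd.DataFrame(records, columns=columns)
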