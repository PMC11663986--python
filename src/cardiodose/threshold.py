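"""Optimal dose-threshold determination by resampled log-rank splits.

A single optimal split of a continuous dose feature is unstable, so the
procedure subsamples two-thirds of the cohort, finds the cutpoint that
maximizes the two-sample log-rank statistic, repeats (default 100 times)
and takes the median cutpoint.  The cohort is then stratified at the
median cutpoint and Kaplan-Meier median survival is contrasted between
the strata.  Repeating the whole procedure per contour variation and α/β
scenario probes the robustness of the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdResult",
    "optimal_split",
    "logrank_scan",
    "resampled_threshold",
    "km_stratified",
    "robustness_report",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass
class ThresholdResult:
    """Resampled optimal-split result for one model variation."""

    feature_name: str
    cutpoints: list[float]
    median_cutpoint: float
    km_median_below: float
    km_median_above: float
    n_below: int
    n_above: int
    below_median_defined: bool = True
    above_median_defined: bool = True
    variation: str = "original"
    alpha_beta_scenario: str = "standard"
    n_reps_requested: int = 0
    n_reps_successful: int = 0
    seed: int = 0


def logrank_scan(feature, times, events, candidates) -> np.ndarray:
    """Two-sample log-rank chi-square statistic for every candidate cutpoint.

    For cutpoint c the groups are ``feature <= c`` and ``feature > c``.
    Vectorized over candidates: one pass builds per-event-time risk-set
    counts, a candidate-by-patient membership matrix supplies the group
    counts.  Matches the standard (hypergeometric-variance) log-rank test.
    """
    x = np.asarray(feature, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cands = np.asarray(candidates, dtype=float)
    order = np.argsort(t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    uniq, first = np.unique(ts, return_index=True)
    # counts per unique time
    d_tot = np.add.reduceat(es, first)                      # events at time
    n_tot = len(ts) - first                                 # at risk
    member = xs[None, :] <= cands[:, None]                  # (k, n) in group 1
    memf = member.astype(float)
    # at-risk in group 1 at each unique time = suffix sums
    cum = np.cumsum(memf[:, ::-1], axis=1)[:, ::-1]
    n1 = cum[:, first]
    d1 = np.add.reduceat(memf * es[None, :], first, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp1 = d_tot * n1 / n_tot
        var1 = d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / np.maximum(n_tot - 1, 1)
    mask = n_tot > 1
    observed_minus_expected = (d1 - exp1)[:, mask].sum(axis=1)
    variance = var1[:, mask].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(variance > 0, observed_minus_expected**2 / variance, 0.0)
    return chi2


def optimal_split(feature, times, events, *, min_per_side: int = 10,
                  percentile_range: tuple[float, float] = (10.0, 90.0)) -> float:
    """Cutpoint maximizing the two-sample log-rank statistic.

    Candidate cutpoints are the unique observed feature values between the
    10th and 90th percentile with at least ``min_per_side`` patients on
    each side; ties in the statistic break toward the lower cutpoint.
    """
    x = np.asarray(feature, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    lo, hi = np.percentile(x, percentile_range)
    cands = np.unique(x[(x >= lo) & (x <= hi)])
    if cands.size:
        n_below = (x[None, :] <= cands[:, None]).sum(axis=1)
        ok = (n_below >= min_per_side) & (len(x) - n_below >= min_per_side)
        cands = cands[ok]
    if cands.size == 0:
        raise DataError("no admissible candidate cutpoint")
    chi2 = logrank_scan(x, t, e, cands)
    best = int(np.argmax(chi2))  # argmax returns the first = lowest cutpoint
    return float(cands[best])


def resampled_threshold(feature, times, events, *, n_reps: int = 100,
                        frac: float = 2.0 / 3.0, seed: int = 0,
                        min_per_side: int = 10,
                        percentile_range: tuple[float, float] = (10.0, 90.0),
                        feature_name: str = "dose",
                        variation: str = "original",
                        alpha_beta_scenario: str = "standard") -> ThresholdResult:
    """Median optimal split over random two-thirds subsamples.

    Each repetition draws ⌊frac·n⌋ patients without replacement and finds
    its optimal split; failed repetitions (no admissible candidate) are
    skipped with a log entry, and fewer than 50% successful repetitions is
    an error.  The cohort is finally stratified at the median cutpoint.
    """
    x = np.asarray(feature, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.isnan(x).any():
        raise DataError("feature contains missing values")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xC0,)))
    n_sub = int(np.floor(frac * len(x)))
    cutpoints = []
    for rep in range(n_reps):
        idx = rng.choice(len(x), size=n_sub, replace=False)
        try:
            cutpoints.append(optimal_split(
                x[idx], t[idx], e[idx], min_per_side=min_per_side,
                percentile_range=percentile_range))
        except DataError:
            logger.info("resample %d: no admissible cutpoint, skipped", rep)
    if len(cutpoints) < 0.5 * n_reps:
        raise DataError(
            f"only {len(cutpoints)}/{n_reps} resamples produced a cutpoint")
    median_cut = float(np.median(cutpoints))
    med_b, med_a, table = km_stratified(x, median_cut, t, e)
    return ThresholdResult(
        feature_name=feature_name,
        cutpoints=[float(c) for c in cutpoints],
        median_cutpoint=median_cut,
        km_median_below=med_b,
        km_median_above=med_a,
        n_below=int((x <= median_cut).sum()),
        n_above=int((x > median_cut).sum()),
        below_median_defined=bool(np.isfinite(med_b)),
        above_median_defined=bool(np.isfinite(med_a)),
        variation=variation,
        alpha_beta_scenario=alpha_beta_scenario,
        n_reps_requested=n_reps,
        n_reps_successful=len(cutpoints),
        seed=seed,
    )


def km_stratified(feature, cutpoint, times, events):
    """Kaplan-Meier product-limit estimates for the two dose strata.

    Returns the two median survival times in days (the earliest time at
    which the survivor function drops to 0.5 or below; infinity when the
    curve never crosses 0.5 — reported as-is and flagged by the caller)
    and a survival-curve table with one row per observed time.
    """
    x = np.asarray(feature, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    below = x <= cutpoint
    if below.all() or not below.any():
        raise DataError("stratification leaves an empty stratum")
    medians = {}
    curves = {}
    for name, sel in (("below", below), ("above", ~below)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=name)
        medians[name] = float(kmf.median_survival_time_)
        curves[name] = kmf.survival_function_[name]
    table = pd.concat(
        [curves["below"].rename("s_below"), curves["above"].rename("s_above")],
        axis=1).sort_index().ffill()
    table.index.name = "time_days"
    return medians["below"], medians["above"], table


def robustness_report(results: list[ThresholdResult],
                      spread_tolerance: float = 0.25) -> pd.DataFrame:
    """Tabulate cutpoints and KM medians across the model variations.

    Flags the report when the min-max spread of the median cutpoints
    exceeds ``spread_tolerance`` (as a fraction of the original-contour
    run's cutpoint, falling back to the first run).
    """
    if len(results) < 2:
        raise DataError("robustness report needs at least two runs")
    rows = []
    for r in results:
        rows.append({
            "variation": r.variation,
            "alpha_beta_scenario": r.alpha_beta_scenario,
            "feature": r.feature_name,
            "median_cutpoint": r.median_cutpoint,
            "km_median_below_days": r.km_median_below,
            "km_median_above_days": r.km_median_above,
            "km_median_below_months": r.km_median_below / DAYS_PER_MONTH,
            "km_median_above_months": r.km_median_above / DAYS_PER_MONTH,
            "n_below": r.n_below,
            "n_above": r.n_above,
        })
    df = pd.DataFrame(rows)
    ref = df.loc[df["variation"] == "original", "median_cutpoint"]
    ref_cut = float(ref.iloc[0]) if len(ref) else float(df["median_cutpoint"].iloc[0])
    spread = float(df["median_cutpoint"].max() - df["median_cutpoint"].min())
    df.attrs["spread"] = spread
    df.attrs["spread_flag"] = bool(ref_cut > 0 and spread > spread_tolerance * ref_cut)
    return df
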