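"""Ensemble variable selection for dose-survival modelling.

Multivariable Cox regression cannot resolve the strong collinearity between
substructure dose parameters, so two shrinkage/ensemble approaches are run
side by side and only features influential in *both* are carried forward:

* a bootstrapped elastic net for the Cox partial likelihood, with the
  mixing parameter alpha tuned between 0 (ridge) and 1 (lasso) by
  cross-validated partial likelihood on every bootstrap resample, and a
  feature's importance summarized as the percentage of bootstraps in which
  its coefficient is nonzero;
* an ensemble of random survival forests, each contributing one
  permutation-importance (VIMP) draw per feature, summarized by the median
  over forests and thresholded (default 0.01).

The consensus of the two approaches across all contour/α-β model
variations feeds a final multivariable Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ModelRunConfig",
    "CoxResult",
    "SelectionSummary",
    "ImportanceSummary",
    "univariable_cox",
    "screen_confounders",
    "confounder_design",
    "bootstrap_elastic_net",
    "rsf_ensemble",
    "consensus_selection",
    "final_multivariable_cox",
    "cox_log_partial_likelihood",
]


@dataclass
class ModelRunConfig:
    """Configuration of one model run (one cell of the 2 x 4 design).

    Defaults reproduce the full design: 1000 elastic-net bootstraps, 500
    survival forests of 500 trees, importance threshold 0.01, alpha grid
    0, 0.1, ..., 1 with 10-fold cross-validated penalty selection.  Tests
    and reduced studies shrink ``n_boot``/``n_forests``/``n_trees``.
    """

    variation: str = "original"
    alpha_beta_scenario: str = "standard"
    covariate_set: str = "dose_only"
    n_boot: int = 1000
    n_forests: int = 500
    n_trees: int = 500
    importance_threshold: float = 0.01
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    cv_folds: int = 10
    n_penalties: int = 15
    magnitude_floor: float = 0.0
    min_node_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variation not in ("original", "expanded", "contracted"):
            raise ConfigurationError(f"unknown variation {self.variation!r}")
        if self.alpha_beta_scenario not in ("standard", "all3"):
            raise ConfigurationError(
                f"unknown alpha_beta_scenario {self.alpha_beta_scenario!r}")
        if self.covariate_set not in ("dose_only", "complete"):
            raise ConfigurationError(f"unknown covariate_set {self.covariate_set!r}")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ConfigurationError("alpha_grid values must lie in [0, 1]")
        if self.n_forests < 1:
            raise ConfigurationError("n_forests must be >= 1")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")

    @property
    def run_label(self) -> str:
        return f"{self.variation}/{self.alpha_beta_scenario}/{self.covariate_set}"


@dataclass
class CoxResult:
    """Hazard ratio with Wald 95% confidence interval for one covariate."""

    feature: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class SelectionSummary:
    """Elastic-net bootstrap selection percentages for one model run."""

    config: ModelRunConfig
    selection_pct: pd.Series
    mean_tuned_alpha: float


@dataclass
class ImportanceSummary:
    """Median RSF permutation importance (VIMP) for one model run."""

    config: ModelRunConfig
    median_importance: pd.Series
    important: pd.Series


def _check_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise DataError("times and events must have equal length")
    if e.sum() < 2:
        raise DataError("need at least two events")
    return t, e


def univariable_cox(feature, times, events, name: str = "x") -> CoxResult:
    """Univariable proportional-hazards fit (Efron tie handling).

    Standard partial-likelihood estimator with a Wald 95% CI.
    """
    t, e = _check_survival(times, events)
    x = np.asarray(feature, dtype=float)
    if np.isnan(x).any():
        raise DataError(f"feature {name!r} contains missing values")
    if np.std(x) == 0:
        raise DataError(f"feature {name!r} has zero variance: degenerate fit")
    df = pd.DataFrame({name: x, "_t": t, "_e": e})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_t", event_col="_e")
    s = cph.summary.loc[name]
    return CoxResult(name, float(s["exp(coef)"]),
                     float(s["exp(coef) lower 95%"]),
                     float(s["exp(coef) upper 95%"]), float(s["p"]))


def confounder_design(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix and column grouping for the candidate confounders.

    PTV volume enters as log(PTV); categorical covariates as treatment
    contrasts with the largest category as reference (sex: F, pathology:
    proven).  Distance covariates pass through unchanged.
    """
    X = pd.DataFrame(index=cohort.index)
    groups: dict[str, list[str]] = {}
    X["age"] = cohort["age"].astype(float)
    groups["age"] = ["age"]
    X["sex_M"] = (cohort["sex"] == "M").astype(float)
    groups["sex"] = ["sex_M"]
    X["log_ptv"] = np.log(cohort["ptv_cc"].astype(float))
    groups["log_ptv"] = ["log_ptv"]
    X["stage_2"] = (cohort["stage"].astype(int) == 2).astype(float)
    groups["stage"] = ["stage_2"]
    X["laterality_left"] = (cohort["laterality"] == "left").astype(float)
    groups["laterality"] = ["laterality_left"]
    path_cols = []
    for lvl in ("squamous", "adeno", "unknown"):
        col = f"pathology_{lvl}"
        X[col] = (cohort["pathology"] == lvl).astype(float)
        path_cols.append(col)
    groups["pathology"] = path_cols
    for col in ("dist_heart_ptv_cc", "dist_heart_ptv_inplane",
                "dist_heart_gtv_cc", "dist_heart_gtv_inplane"):
        if col in cohort.columns:
            X[col] = cohort[col].astype(float)
            groups[col] = [col]
    return X, groups


def screen_confounders(design: pd.DataFrame, groups: dict[str, list[str]],
                       times, events, alpha: float = 0.05) -> list[str]:
    """Marginal (univariable) Cox screening of candidate confounders.

    Each candidate group (a single column, or the contrast block of a
    categorical covariate) is tested on its own; multi-column groups use
    the likelihood-ratio test of the block against the null model.
    Returns the names of groups with p < ``alpha``.
    """
    t, e = _check_survival(times, events)
    retained = []
    for name, cols in groups.items():
        sub = design[cols]
        if all(np.std(sub[c]) == 0 for c in cols):
            continue
        df = sub.copy()
        df["_t"], df["_e"] = t, e
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="_t", event_col="_e")
            if len(cols) == 1:
                p = float(cph.summary.loc[cols[0], "p"])
            else:
                p = float(cph.log_likelihood_ratio_test().p_value)
        except Exception:  # non-convergent candidate (e.g. separation): drop
            continue
        if p < alpha:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# elastic net


def cox_log_partial_likelihood(X: np.ndarray, times: np.ndarray,
                               events: np.ndarray, beta: np.ndarray) -> float:
    """Breslow log partial likelihood at fixed coefficients.

    Used to score cross-validation folds when tuning the elastic-net
    penalty; it is independent of the solver that produced ``beta``.
    """
    eta = X @ beta
    order = np.argsort(times, kind="stable")
    t, e, eta = times[order], events[order], eta[order]
    # reverse cumulative logsumexp of eta -> log of risk-set sums
    m = float(eta.max()) if eta.size else 0.0
    rev = np.exp(eta[::-1] - m)
    log_risk = (m + np.log(np.cumsum(rev)))[::-1]
    # Breslow: tied event times share the risk set that includes all ties
    first_idx = np.searchsorted(t, t, side="left")
    ll = float(np.sum((eta - log_risk[first_idx])[e == 1]))
    return ll


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _ridge_penalty_grid(n_penalties: int) -> np.ndarray:
    return np.geomspace(100.0, 0.01, n_penalties)


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def _cox_grad_hess(X, t, e, beta):
    """Breslow gradient and Hessian of the log partial likelihood.

    Vectorized over suffix risk-set sums; tied event times share the risk
    set that includes all ties.
    """
    order = np.argsort(t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order].astype(bool)
    eta = Xs @ beta
    shift = float(eta.max())
    w = np.exp(eta - shift)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    wXX = w[:, None, None] * Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    g = np.searchsorted(ts, ts, side="left")[es]
    s0 = S0[g]
    mu = S1[g] / s0[:, None]
    ll = float(eta[es].sum() - (np.log(s0) + shift).sum())
    grad = (Xs[es] - mu).sum(axis=0)
    hess = (S2[g] / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mu, mu)
    return ll, grad, hess


def _fit_ridge(X, y_t, y_e, penalty: float, beta0=None) -> np.ndarray:
    """Ridge-penalized Cox fit by Newton iteration (warm-startable)."""
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    for _ in range(25):
        ll, grad, hess = _cox_grad_hess(X, y_t, y_e, beta)
        g = grad - penalty * beta
        H = hess + penalty * np.eye(p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if float(np.abs(g).max()) < 1e-6:
            break
    return beta


def _tune_one_bootstrap(Xb, tb, eb, config, rng):
    """Pick (l1_ratio, penalty) by CV partial likelihood; return final coef."""
    folds = _fold_indices(len(tb), config.cv_folds, rng)
    best = (-np.inf, None, None)
    for l1 in config.alpha_grid:
        if l1 == 0.0:
            # warm-started Newton fits along the descending penalty path
            penalties = _ridge_penalty_grid(config.n_penalties)
            scores = np.zeros(len(penalties))
            for test in folds:
                train = np.setdiff1d(np.arange(len(tb)), test)
                coef = None
                for j, pen in enumerate(penalties):
                    try:
                        coef = _fit_ridge(Xb[train], tb[train], eb[train], pen,
                                          beta0=coef)
                    except np.linalg.LinAlgError:
                        scores[j] += -np.inf
                        continue
                    scores[j] += cox_log_partial_likelihood(
                        Xb[test], tb[test], eb[test], coef)
            j = int(np.argmax(scores))
            if scores[j] > best[0]:
                best = (scores[j], 0.0, penalties[j])
        else:
            # fix the penalty path on the full resample, then CV over it
            try:
                path = CoxnetSurvivalAnalysis(
                    l1_ratio=l1, n_alphas=config.n_penalties, alpha_min_ratio=0.01)
                path.fit(Xb, Surv.from_arrays(eb.astype(bool), tb))
            except Exception:
                continue
            alphas = path.alphas_
            scores = np.zeros(len(alphas))
            for test in folds:
                train = np.setdiff1d(np.arange(len(tb)), test)
                try:
                    m = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=alphas)
                    m.fit(Xb[train], Surv.from_arrays(eb[train].astype(bool), tb[train]))
                except Exception:
                    scores[:] = -np.inf
                    break
                fitted = np.asarray(m.alphas_)
                for j, a in enumerate(alphas):
                    hit = np.flatnonzero(np.isclose(fitted, a))
                    if hit.size:
                        coef = m.coef_[:, hit[0]]
                        scores[j] += cox_log_partial_likelihood(
                            Xb[test], tb[test], eb[test], coef)
                    else:
                        scores[j] += -np.inf
            j = int(np.argmax(scores))
            if scores[j] > best[0]:
                best = (scores[j], l1, alphas[j])
    _, l1, pen = best
    if l1 is None:
        raise DataError("elastic-net tuning failed on a bootstrap resample")
    if l1 == 0.0:
        coef = _fit_ridge(Xb, tb, eb, pen)
    else:
        # back off to stronger penalties if the solver diverges at the
        # CV-chosen one (can happen on near-separable resamples)
        pen_try = pen
        for _ in range(8):
            try:
                m = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=[pen_try])
                m.fit(Xb, Surv.from_arrays(eb.astype(bool), tb))
                coef = m.coef_[:, 0]
                break
            except ArithmeticError:
                pen_try *= 3.0
        else:
            raise DataError("elastic-net refit failed to converge")
    return l1, coef


def bootstrap_elastic_net(features: pd.DataFrame, times, events,
                          config: ModelRunConfig) -> SelectionSummary:
    """Bootstrapped elastic-net Cox selection.

    Per bootstrap: resample patients with replacement (same n),
    standardize the resample, tune the mixing parameter over
    ``alpha_grid`` and the penalty strength by cross-validated partial
    likelihood, refit at the chosen pair, and record which features have
    nonzero coefficients (ridge, alpha = 0, never zeroes a coefficient;
    an optional ``magnitude_floor`` on |standardized coefficient| is
    exposed because selection of near-zero ridge coefficients is
    otherwise all-or-nothing).

    Returns per-feature selection percentages and the mean tuned alpha.
    """
    t, e = _check_survival(times, events)
    if features.isna().any().any():
        raise DataError("feature matrix contains missing values; apply the "
                        "missing-data rule first")
    if int(e.sum()) < config.cv_folds:
        raise DataError(
            f"fewer events ({int(e.sum())}) than cv_folds ({config.cv_folds})")
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xE7,)))
    counts = np.zeros(p)
    alphas_used = []
    for _ in range(config.n_boot):
        idx = rng.integers(0, n, size=n)
        while e[idx].sum() < max(2, config.cv_folds):
            idx = rng.integers(0, n, size=n)
        Xb, _, _ = _standardize(X[idx])
        l1, coef = _tune_one_bootstrap(Xb, t[idx], e[idx], config, rng)
        alphas_used.append(l1)
        floor = max(config.magnitude_floor, 1e-10)
        if l1 == 0.0 and config.magnitude_floor == 0.0:
            counts += 1
        else:
            counts += (np.abs(coef) > floor).astype(float)
    pct = pd.Series(100.0 * counts / config.n_boot, index=features.columns)
    return SelectionSummary(config, pct, float(np.mean(alphas_used)))


# ---------------------------------------------------------------------------
# random survival forests


def _harrell_pairs(t: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Comparable-pair indices for Harrell's concordance index.

    Pair (i, j) is comparable when the event of i precedes the observed
    time of j, or both occur at the same time with j censored.
    """
    ii, jj = [], []
    idx = np.arange(len(t))
    for i in idx[e == 1]:
        cmp_j = idx[(t > t[i]) | ((t == t[i]) & (e == 0))]
        ii.extend([i] * len(cmp_j))
        jj.extend(cmp_j)
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)


def _cindex_from_pairs(risk: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    ri, rj = risk[ii], risk[jj]
    return float(((ri > rj).sum() + 0.5 * (ri == rj).sum()) / len(ii))


def _vimp_one_forest(model, X, t, e, rng) -> np.ndarray:
    """Tree-level out-of-bag permutation importance (VIMP).

    For every tree: drop its out-of-bag cases down the tree with feature j
    permuted among them and record the drop in that tree's concordance
    index; average the drops over trees.  This is the convention of the
    standard R survival-forest implementations; it attributes importance
    at the tree level, where a correlated twin feature cannot silently
    stand in for the permuted one the way it can with ensemble-level
    permutation.
    """
    from sklearn.ensemble._forest import _generate_unsampled_indices

    n, p = X.shape
    drops = np.zeros(p)
    used = 0
    for tree in model.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n, None)
        if oob.size < 10 or e[oob].sum() < 2:
            continue
        ii, jj = _harrell_pairs(t[oob], e[oob])
        if len(ii) == 0:
            continue
        Xo = np.ascontiguousarray(X[oob], dtype=np.float32)
        ev = tree.is_event_time_

        def risk_of(A):
            return tree.tree_.predict(A)[:, :, 0][:, ev].sum(axis=1)

        base = _cindex_from_pairs(risk_of(Xo), ii, jj)
        perm = rng.permutation(oob.size)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[perm, j]
            drops[j] += base - _cindex_from_pairs(risk_of(Xp), ii, jj)
        used += 1
    return drops / max(used, 1)


def rsf_ensemble(features: pd.DataFrame, times, events,
                 config: ModelRunConfig) -> ImportanceSummary:
    """Ensemble of random survival forests with median permutation VIMP.

    Each forest is a standard random survival forest (log-rank splitting,
    sqrt(p) candidate features per split); it contributes one VIMP draw
    per feature, the tree-level out-of-bag permutation importance under
    the concordance-index loss (see :func:`_vimp_one_forest`).  The
    per-feature median over forests is compared against
    ``importance_threshold``.
    """
    t, e = _check_survival(times, events)
    if features.isna().any().any():
        raise DataError("feature matrix contains missing values")
    X = features.to_numpy(dtype=float)
    y = Surv.from_arrays(e.astype(bool), t)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0x5F,))
    vimps = np.empty((config.n_forests, X.shape[1]))
    for f, child in enumerate(ss.spawn(config.n_forests)):
        rng = np.random.default_rng(child)
        state = int(rng.integers(0, 2**31 - 1))
        # min_node_size follows the R survival-forest convention: nodes
        # smaller than it are not split (sklearn's min_samples_split), with
        # small leaves allowed — deeper trees than a leaf-size constraint
        model = RandomSurvivalForest(
            n_estimators=config.n_trees,
            min_samples_split=config.min_node_size,
            min_samples_leaf=3,
            max_features="sqrt",
            random_state=state,
            n_jobs=1,
        )
        model.fit(X, y)
        vimps[f] = _vimp_one_forest(model, X, t, e, rng)
    med = pd.Series(np.median(vimps, axis=0), index=features.columns)
    return ImportanceSummary(config, med, med > config.importance_threshold)


# ---------------------------------------------------------------------------
# consensus and final model


def consensus_selection(en_summaries, rsf_summaries, dose_features=None,
                        top_tolerance_pct: float = 5.0) -> list[str]:
    """Dose features influential in both approaches across all model runs.

    A dose feature is consensus-influential iff (a) in every elastic-net
    run its selection percentage is within ``top_tolerance_pct`` points of
    that run's top dose feature, and (b) its RSF median importance exceeds
    the threshold in every run.  The result is ranked by mean selection
    percentage; an empty intersection is a valid (reported) outcome.
    """
    if not en_summaries or not rsf_summaries:
        raise ConfigurationError("need at least one summary per approach")
    if dose_features is None:
        dose_features = [c for c in en_summaries[0].selection_pct.index
                         if c.endswith("_eqd2")]
    candidates = set(dose_features)
    for s in en_summaries:
        pct = s.selection_pct.reindex(dose_features)
        top = float(pct.max())
        candidates &= set(pct.index[pct >= top - top_tolerance_pct])
    for s in rsf_summaries:
        flagged = set(s.important.index[s.important]) & set(dose_features)
        candidates &= flagged
    mean_pct = sum(s.selection_pct.reindex(dose_features) for s in en_summaries)
    ranked = sorted(candidates, key=lambda f: -float(mean_pct[f]))
    return ranked


def final_multivariable_cox(data: pd.DataFrame, dose_feature: str,
                            confounder_cols, times, events) -> list[CoxResult]:
    """Joint Cox model of the consensus dose feature and the confounders."""
    t, e = _check_survival(times, events)
    cols = [dose_feature] + list(confounder_cols)
    X = data[cols].astype(float)
    Xs = (X - X.mean()) / X.std().replace(0, 1.0)
    cond = np.linalg.cond(Xs.to_numpy()) if len(cols) > 1 else 1.0
    if cond > 1e8:
        raise DataError(
            f"design is degenerate (condition number {cond:.3g}); "
            "remove collinear covariates")
    df = X.copy()
    df["_t"], df["_e"] = t, e
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_t", event_col="_e")
    out = []
    for c in cols:
        s = cph.summary.loc[c]
        out.append(CoxResult(c, float(s["exp(coef)"]),
                             float(s["exp(coef) lower 95%"]),
                             float(s["exp(coef) upper 95%"]), float(s["p"])))
    return out
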