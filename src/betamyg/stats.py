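"""Statistical models for β incidence and behavior.

The central model is a linear mixed-effects model of per-session β
incidence::

    Y_it = α + β₁·Age_i + β₂·Day_t + β₃·(Age_i × Day_t) + a_i + b_i·Day_t + ε_it

with Gaussian random intercept ``a_i`` and random day slope ``b_i``
per subject and Gaussian residuals. Age is coded 0 (young) / 1 (old),
day is the integer session index starting at 1. Fitting is by maximum
likelihood (not REML) so nested models can be compared with
likelihood-ratio χ² tests.

Also provided: the Win-Stay/Lose-Shift behavioral summary and the
Kruskal-Wallis / correlation utilities used for group comparisons.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

FULL_FORMULA = "incidence ~ age * day"
REQUIRED_COLUMNS = ("subject", "age", "day", "incidence")


@dataclass
class MixedModelFit:
    """Result of the incidence mixed-model fit."""

    params: dict                    # fixed effects
    bse: dict                       # their standard errors
    cov_re: np.ndarray              # random-effects covariance
    resid_var: float
    llf: float
    converged: bool
    formula: str
    n_obs: int
    n_groups: int = 0
    random_slope: bool = True

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Wald interval with t quantiles on between-subject df.

        ML variance estimates run small with a dozen subjects and the
        age and age × day contrasts carry roughly (subjects − 2)
        degrees of freedom, so t quantiles on that df (rather than
        normal ones) are used to keep near-nominal coverage.
        """
        if self.n_groups > 2:
            crit = sps.t.ppf(1 - alpha / 2, self.n_groups - 2)
        else:
            crit = sps.norm.ppf(1 - alpha / 2)
        est, se = self.params[name], self.bse[name]
        return est - crit * se, est + crit * se


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"incidence table missing columns {sorted(missing)}")
    return table


def fit_incidence_model(table: pd.DataFrame, formula: str = FULL_FORMULA,
                        random_slope: bool = True,
                        allow_fallback: bool = True) -> MixedModelFit:
    """ML fit of the incidence mixed model.

    ``table`` needs columns ``subject``, ``age`` (0/1), ``day`` (int,
    from 1) and ``incidence``. A singular random-effects covariance
    triggers a logged refit with a random intercept only (disable with
    ``allow_fallback=False``, e.g. when two fits must share one
    random-effects structure for a likelihood-ratio comparison);
    convergence failures are returned flagged, not raised.
    """
    table = _check_table(table)
    re_formula = "~day" if random_slope else "~1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, table, groups=table["subject"],
                            re_formula=re_formula)
        fit = None
        err = None
        # near-singular random-effects covariances can break a single
        # optimizer; try a short cascade before giving up
        for method in ("lbfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=300)
                break
            except np.linalg.LinAlgError as exc:
                err = exc
        if fit is None:
            if random_slope:
                logger.warning("random-slope fit failed (%s); "
                               "refitting with random intercept only", err)
                return fit_incidence_model(table, formula=formula,
                                           random_slope=False,
                                           allow_fallback=allow_fallback)
            raise err
        if allow_fallback and random_slope and _singular(fit.cov_re.to_numpy()):
            logger.warning("singular random-effects covariance; "
                           "refitting with random intercept only")
            return fit_incidence_model(table, formula=formula,
                                       random_slope=False)
    return MixedModelFit(
        params=dict(fit.fe_params), bse={k: fit.bse[k] for k in fit.fe_params.index},
        cov_re=fit.cov_re.to_numpy(), resid_var=float(fit.scale),
        llf=float(fit.llf), converged=bool(fit.converged),
        formula=formula, n_obs=len(table),
        n_groups=int(table["subject"].nunique()), random_slope=random_slope)


def _singular(cov: np.ndarray, rtol: float = 1e-8) -> bool:
    ev = np.linalg.eigvalsh(cov)
    return bool(ev.min() <= rtol * max(ev.max(), 1e-12))


def lr_test(fit_full: MixedModelFit, fit_reduced: MixedModelFit,
            df: int) -> tuple[float, int, float]:
    """Likelihood-ratio χ² between two nested ML fits."""
    chi2 = 2.0 * (fit_full.llf - fit_reduced.llf)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    if chi2 == 0.0:
        p = 1.0
    return chi2, df, p


def lr_model_selection(table: pd.DataFrame,
                       terms: tuple[str, ...] = ("age", "day", "age:day"),
                       random_slope: bool = True) -> pd.DataFrame:
    """Sequential likelihood-ratio tests over a nested term sequence.

    Models ``incidence ~ 1``, ``~ age``, ``~ age + day``, … are fitted
    by ML in order; each term's χ², df and p compare the model adding
    it to the one before. All fits share one random-effects structure
    (no singular fallback) so the comparisons stay nested; the
    nested-model property (log-likelihood never decreases when a term
    is added) is asserted up to optimizer tolerance.
    """
    table = _check_table(table)
    rhs = ["1"]
    fits = [fit_incidence_model(table, "incidence ~ 1",
                                random_slope=random_slope,
                                allow_fallback=False)]
    rows = []
    for term in terms:
        rhs.append(term)
        formula = "incidence ~ " + " + ".join(rhs[1:])
        fit = fit_incidence_model(table, formula, random_slope=random_slope,
                                  allow_fallback=False)
        assert fit.llf >= fits[-1].llf - 0.05, \
            "log-likelihood decreased when adding a term (non-nested fits?)"
        chi2, df, p = lr_test(fit, fits[-1], df=1)
        rows.append({"term": term, "chi2": chi2, "df": df, "p": p,
                     "llf": fit.llf})
        fits.append(fit)
    return pd.DataFrame(rows)


@dataclass
class WSLSSummary:
    """Win-stay / lose-shift proportions over free-choice trial pairs."""

    win_stay: float | None
    lose_shift: float | None
    n_win_pairs: int
    n_loss_pairs: int


def win_stay_lose_shift(trials: pd.DataFrame) -> WSLSSummary:
    """Win-Stay/Lose-Shift over consecutive free-choice trials.

    A qualifying pair is two free-choice trials with consecutive trial
    indices in the same block (forced trials and block boundaries
    break pairs). ``win_stay`` = P(same lever next | win);
    ``lose_shift`` = P(other lever next | loss). Empty denominators
    yield None with a log entry.
    """
    free = trials[(trials["trial_type"] == "free")
                  & trials["lever"].isin(["small", "large"])
                  & trials["outcome"].isin(["win", "loss"])]
    free = free.sort_values("trial_index")
    stay_w = n_w = shift_l = n_l = 0
    rows = list(free.itertuples())
    for a, b in zip(rows, rows[1:]):
        if b.trial_index != a.trial_index + 1 or b.block_index != a.block_index:
            continue
        same = b.lever == a.lever
        if a.outcome == "win":
            n_w += 1
            stay_w += same
        else:
            n_l += 1
            shift_l += not same
    if n_w == 0:
        logger.info("win-stay undefined: no win pairs")
    if n_l == 0:
        logger.info("lose-shift undefined: no loss pairs")
    return WSLSSummary(win_stay=stay_w / n_w if n_w else None,
                       lose_shift=shift_l / n_l if n_l else None,
                       n_win_pairs=n_w, n_loss_pairs=n_l)


def rank_compare(*groups, pairwise: bool = False):
    """Kruskal-Wallis rank test across groups (tie-corrected).

    Returns ``(H, df, p)``; with ``pairwise=True`` additionally
    returns a list of ``(i, j, H, p_bonferroni)`` over all group
    pairs, Bonferroni-corrected across the comparisons. Identical
    values across all groups give H = 0, p = 1 (flagged via logging).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        logger.warning("all values identical across groups")
        result = (0.0, df, 1.0)
    else:
        h, p = sps.kruskal(*groups)
        result = (float(h), df, float(p))
    if not pairwise:
        return result
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    table = []
    for i, j in pairs:
        if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
            h_ij, p_ij = 0.0, 1.0
        else:
            h_ij, p_ij = sps.kruskal(groups[i], groups[j])
        table.append((i, j, float(h_ij), min(float(p_ij) * m, 1.0)))
    return result, table


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation (r, p) for trial-trend analyses."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def simulate_incidence_table(n_old: int = 7, n_young: int = 6,
                             n_days: int = 20, alpha: float = 0.05,
                             beta_age: float = 0.05, beta_day: float = 0.002,
                             beta_interaction: float = 0.008,
                             sd_intercept: float = 0.03,
                             sd_slope: float = 0.003, sd_resid: float = 0.04,
                             rng: np.random.Generator | None = None,
                             ) -> pd.DataFrame:
    """Simulate a longitudinal incidence table from the mixed model.

    Defaults mirror the study's cohort (7 old + 6 young subjects, 20
    recording days) with effect sizes on the incidence scale
    (events/trial). Used for calibration and coverage experiments.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for i in range(n_old + n_young):
        age = 1 if i < n_old else 0
        a_i = rng.normal(0, sd_intercept)
        b_i = rng.normal(0, sd_slope)
        for day in range(1, n_days + 1):
            y = (alpha + beta_age * age + beta_day * day
                 + beta_interaction * age * day + a_i + b_i * day
                 + rng.normal(0, sd_resid))
            rows.append({"subject": f"s{i:02d}", "age": age, "day": day,
                         "incidence": y})
    return pd.DataFrame(rows)
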