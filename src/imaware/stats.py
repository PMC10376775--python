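"""Mixed-effects inference and simulation-based power.

Feature tables (long format: subject, detection, condition, cluster, window,
measure, value) are analyzed with linear mixed models — experimental factors
fixed, subject as a random intercept, maximum-likelihood estimation — followed
by estimated-marginal-means contrasts (cell means averaged over the remaining
factors) with Bonferroni adjustment.  A Monte-Carlo power calculator fits the
same random-intercept model to simulated replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.formula.api as smf


@dataclass
class ModelSpec:
    response: str = "value"
    fixed: tuple = ("detection", "condition", "cluster")
    interactions: bool = True

    def formula(self) -> str:
        terms = [f"C({f})" for f in self.fixed]
        rhs = " * ".join(terms) if self.interactions else " + ".join(terms)
        return f"{self.response} ~ {rhs}"


def fit_lmm(table: pd.DataFrame, spec: ModelSpec | None = None,
            formula: str | None = None, groups: str = "subject"):
    """ML-fitted random-intercept linear mixed model (statsmodels MixedLM)."""
    if table[groups].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if formula is None:
        formula = (spec or ModelSpec()).formula()
    model = smf.mixedlm(formula, table, groups=table[groups])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Powell handles the variance-component boundary cleanly where
        # gradient methods can stall a step short of it
        result = model.fit(reml=False, method=["powell", "lbfgs"])
    return result


def anova_table(result) -> pd.DataFrame:
    """Wald F-tests of each fixed-effect term.

    Contrast matrices follow the design-info term slices; denominator degrees
    of freedom are the residual count (n observations minus fixed-effect
    rank), adequate at the table sizes used here.
    """
    design_info = result.model.data.design_info
    k_fe = result.k_fe
    cov = result.cov_params().iloc[:k_fe, :k_fe].to_numpy()
    beta = result.fe_params.to_numpy()
    n_obs = result.model.nobs if np.isscalar(result.model.nobs) else len(result.model.endog)
    df_resid = int(n_obs) - k_fe
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        L = np.zeros((len(idx), k_fe))
        L[np.arange(len(idx)), idx] = 1.0
        est = L @ beta
        vc = L @ cov @ L.T
        f = float(est @ np.linalg.solve(vc, est)) / len(idx)
        p = sstats.f.sf(f, len(idx), df_resid)
        rows.append({"term": term, "df1": len(idx), "df2": df_resid,
                     "F": f, "p": p,
                     "partial_eta_sq": partial_eta_squared(f, len(idx), df_resid)})
    return pd.DataFrame(rows)


def _reference_grid(table: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    levels = [sorted(table[f].unique()) for f in factors]
    grid = pd.MultiIndex.from_product(levels, names=factors).to_frame(index=False)
    return grid


def emmeans_contrasts(result, table: pd.DataFrame, by: str | None = "cluster",
                      contrast_factor: str = "detection",
                      pair: tuple = ("hit", "miss"),
                      adjust: str = "bonferroni") -> pd.DataFrame:
    """Pairwise estimated-marginal-means contrasts with Bonferroni adjustment.

    Marginal means are model cell means averaged over the levels of the
    factors not named; the contrast ``pair[0] - pair[1]`` is formed per level
    of ``by`` (or once when ``by`` is None).  SEs come from the fixed-effect
    covariance; p-values are multiplied by the family size and capped at 1.
    """
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    factors = [f for f in ("detection", "condition", "cluster", "window")
               if f in table.columns and table[f].nunique() > 1]
    grid = _reference_grid(table, factors)
    X = np.asarray(build_design_matrices([design_info], grid)[0])
    k_fe = result.k_fe
    cov = result.cov_params().iloc[:k_fe, :k_fe].to_numpy()
    beta = result.fe_params.to_numpy()
    n_obs = len(result.model.endog)
    df = int(n_obs) - k_fe
    strata = sorted(table[by].unique()) if by else [None]
    rows = []
    for stratum in strata:
        sel = np.ones(len(grid), bool) if stratum is None else (grid[by] == stratum).to_numpy()
        l_hi = X[sel & (grid[contrast_factor] == pair[0]).to_numpy()].mean(axis=0)
        l_lo = X[sel & (grid[contrast_factor] == pair[1]).to_numpy()].mean(axis=0)
        L = l_hi - l_lo
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se
        p = 2.0 * sstats.t.sf(abs(t), df)
        rows.append({"stratum": stratum, "pair": f"{pair[0]}-{pair[1]}",
                     "estimate": est, "SE": se, "df": df, "t_ratio": t, "p_raw": p})
    out = pd.DataFrame(rows)
    family = len(out)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p_raw"] * family, 1.0)
    else:
        out["p_adjusted"] = out["p_raw"]
    out["family_size"] = family
    return out


def partial_eta_squared(f_stat: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an F statistic: F df1 / (F df1 + df2)."""
    if f_stat < 0:
        raise ValueError("F must be nonnegative")
    return float(f_stat * df1 / (f_stat * df1 + df2))


def random_intercept_lrt(table: pd.DataFrame, spec: ModelSpec | None = None,
                         groups: str = "subject") -> dict:
    """Likelihood-ratio test of the random intercept against plain OLS.

    The reference chi-square is the usual 0.5/0.5 mixture of chi2(0) and
    chi2(1) for a variance component on the boundary.  Reported, not gated on.
    """
    spec = spec or ModelSpec()
    mixed = fit_lmm(table, spec, groups=groups)
    ols = smf.ols(spec.formula(), table).fit()
    stat = 2.0 * (mixed.llf - ols.llf)
    p = 0.5 * sstats.chi2.sf(max(stat, 0.0), 1)
    return {"lr_stat": float(stat), "p": float(p)}


# -- Monte-Carlo power ---------------------------------------------------------

@dataclass
class PowerDesign:
    n_subjects: int = 15
    blocks: int = 4
    items_per_block: int = 20
    effect_size: float = 0.44   # Cohen's d in total-SD units
    alpha: float = 0.05
    icc: float = 0.5            # share of total variance in subject intercepts
    slope_sd: float = 0.0       # optional subject-by-condition slope SD
    n_reps: int = 1000
    seed: int = 0

    @property
    def obs_per_subject(self) -> int:
        return self.blocks * self.items_per_block

    @property
    def total_obs(self) -> int:
        return self.n_subjects * self.obs_per_subject


def _fit_random_intercept_balanced(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """ML fit of y ~ x + (1 | subject) for a balanced design.

    ``y`` is subjects x m, ``x`` length-m within-subject covariate (identical
    across subjects, centered).  Balance makes the ML solution closed-form:
    the GLS slope equals the within-subject OLS slope, and the variance
    components separate into the within- and between-subject sums of squares.
    Returns (slope, SE(slope)).
    """
    k, m = y.shape
    xc = x - x.mean()
    sxx = k * float(xc @ xc)
    beta = float((y @ xc).sum()) / sxx
    resid = y - beta * xc
    row_means = resid.mean(axis=1)
    grand = row_means.mean()
    ssw = float(((resid - row_means[:, None]) ** 2).sum())
    sigma2 = ssw / (k * (m - 1))            # ML within variance
    # ML between component (boundary at zero)
    ssb = m * float(((row_means - grand) ** 2).sum())
    tau2 = max(ssb / k - sigma2, 0.0) / m
    se = float(np.sqrt(sigma2 / sxx))
    return beta, se, sigma2, tau2


def power_simulation(design: PowerDesign,
                     rng: np.random.Generator | None = None) -> dict:
    """Monte-Carlo power of the within-subject detection effect.

    Per replicate: subject intercepts with variance icc, residuals with
    variance 1 - icc (total 1), an optional subject-by-condition random slope,
    and a two-level within-subject effect of ``effect_size`` total-SD units;
    the random-intercept model is fitted by ML and the effect tested at
    ``alpha`` (Wald, two-sided).  Returns the rejection fraction with a 95%
    binomial (Wilson) interval.
    """
    if design.n_reps < 1:
        raise ValueError("need at least one replicate")
    if not 0.0 <= design.icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    m = design.obs_per_subject
    k = design.n_subjects
    x = np.tile([-0.5, 0.5], m // 2)
    if len(x) < m:
        x = np.append(x, -0.5)
    z_crit = sstats.norm.ppf(1.0 - design.alpha / 2.0)
    rejections = 0
    tau = np.sqrt(design.icc)
    sig = np.sqrt(1.0 - design.icc)
    for _ in range(design.n_reps):
        b = rng.normal(0.0, tau, size=(k, 1))
        slopes = (rng.normal(0.0, design.slope_sd, size=(k, 1))
                  if design.slope_sd > 0 else 0.0)
        y = (b + (design.effect_size + slopes) * x
             + rng.normal(0.0, sig, size=(k, m)))
        beta, se, _, _ = _fit_random_intercept_balanced(y, x)
        if abs(beta / se) > z_crit:
            rejections += 1
    power = rejections / design.n_reps
    lo, hi = _wilson_interval(rejections, design.n_reps)
    return {"power": power, "ci_low": lo, "ci_high": hi,
            "n_reps": design.n_reps, "n_obs": design.total_obs,
            "icc": design.icc, "effect_size": design.effect_size}


def _wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = sstats.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def power_icc_sweep(design: PowerDesign, iccs=(0.3, 0.4, 0.5, 0.6)) -> pd.DataFrame:
    """Power at each candidate intraclass correlation (variance split unknown)."""
    rows = []
    for i, icc in enumerate(iccs):
        d = PowerDesign(**{**design.__dict__, "icc": icc,
                           "seed": design.seed + i})
        rows.append(power_simulation(d))
    return pd.DataFrame(rows)
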