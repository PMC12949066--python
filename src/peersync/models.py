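"""Multilevel models for windowed HRV and dyadic synchrony outcomes.

Random intercepts for the grouping hierarchy (group > subject or
group > dyad), optional random time slopes, an AR(1) residual option,
intraclass correlations, covariate screening, stepwise structure selection
by likelihood-ratio testing, and fixed-effects (marginal) R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "icc",
    "screen_covariates",
    "select_structure",
    "fit_model",
    "marginal_r2",
    "variance_explained_by_level",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``categorical`` maps column name -> reference level (the reference never
    appears as a dummy column); ``interactions`` are pairs of term names
    whose design columns are multiplied.
    """

    outcome: str
    group_col: str
    unit_col: str
    continuous: tuple[str, ...] = ()
    categorical: dict[str, str] = field(default_factory=dict)
    interactions: tuple[tuple[str, str], ...] = ()
    time_col: str | None = None
    random_slope_time: bool = False
    ar1: bool = False


@dataclass
class MixedModelFit:
    spec: ModelSpec
    coefficients: pd.DataFrame      # term, estimate, ci_low, ci_high, p
    variance_components: dict[str, float]
    resid_var: float
    ar1_phi: float
    icc_by_level: dict[str, float]
    marginal_r2: float
    loglik: float
    n_obs: int
    n_units: int
    converged: bool
    fixed_prediction_var: float = np.nan

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[term]


# ---------------------------------------------------------------------------
# design construction

def build_fixed_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code categoricals against their declared reference and assemble
    the fixed-effects columns (no intercept column; patsy adds it)."""
    df = data.copy()
    term_cols: dict[str, list[str]] = {}
    for col, ref in spec.categorical.items():
        levels = [lv for lv in pd.unique(df[col].astype(str)) if lv != ref]
        cols = []
        for lv in sorted(levels):
            name = f"{col}__{lv}"
            df[name] = (df[col].astype(str) == lv).astype(float)
            cols.append(name)
        term_cols[col] = cols
    for col in spec.continuous:
        term_cols[col] = [col]
    if spec.time_col is not None:
        term_cols[spec.time_col] = [spec.time_col]

    names: list[str] = []
    for cols in term_cols.values():
        names.extend(cols)
    for a, b in spec.interactions:
        for ca in term_cols.get(a, [a]):
            for cb in term_cols.get(b, [b]):
                name = f"{ca}:{cb}"
                df[name] = df[ca] * df[cb]
                names.append(name)
    # deduplicate, preserve order
    seen: list[str] = []
    for n in names:
        if n not in seen:
            seen.append(n)
    return df, seen


def _check_rank(df: pd.DataFrame, cols: list[str]) -> None:
    if not cols:
        return
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name aliased columns by greedy elimination
        aliased = []
        keep = [0]
        for j in range(1, X.shape[1]):
            r0 = np.linalg.matrix_rank(X[:, keep + [j]])
            if r0 == len(keep):
                aliased.append(cols[j - 1])
            else:
                keep.append(j)
        raise ValueError(f"rank-deficient fixed design; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# intraclass correlation

def icc(
    data: pd.DataFrame,
    outcome: str,
    group_col: str,
    unit_col: str | None = None,
) -> dict[str, float]:
    """ICC per level (in percent) from a null random-intercept model.

    With ``unit_col`` given, units are treated as nested within groups and
    both variance components are estimated jointly.
    """
    df = data.dropna(subset=[outcome]).copy()
    if df[outcome].var() == 0:
        raise ValueError("outcome has zero variance; ICC undefined")
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 groups")
    vc = {unit_col: f"0 + C({unit_col})"} if unit_col else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            f"{outcome} ~ 1", groups=group_col, re_formula="1",
            vc_formula=vc, data=df,
        )
        res = model.fit(reml=True)
    sig_group = float(np.asarray(res.cov_re)[0, 0])
    sig_unit = float(res.vcomp[0]) if unit_col else 0.0
    sig_res = float(res.scale)
    total = sig_group + sig_unit + sig_res
    out = {group_col: 100.0 * sig_group / total}
    if unit_col:
        out[unit_col] = 100.0 * sig_unit / total
    out["residual"] = 100.0 * sig_res / total
    return out


# ---------------------------------------------------------------------------
# covariate screening

def screen_covariates(
    data: pd.DataFrame,
    outcome: str,
    candidates: dict[str, str],
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates individually associated with the outcome (p < alpha).

    Continuous candidates are tested by Pearson correlation, categorical
    ones by one-way ANOVA across levels. Constant candidates are skipped
    with a warning. Returns the retained names and a decision log.
    """
    rows = []
    included: list[str] = []
    for name, kind in candidates.items():
        sub = data[[outcome, name]].dropna()
        if sub[name].nunique() <= 1:
            logger.warning("covariate %r is constant; skipped", name)
            rows.append({"candidate": name, "test": "skipped (constant)",
                         "statistic": np.nan, "p": np.nan, "included": False})
            continue
        if kind == "continuous":
            r, p = stats.pearsonr(sub[name].astype(float), sub[outcome])
            test, stat = "pearson_r", r
        else:
            groups = [g[outcome].to_numpy() for _, g in sub.groupby(name)]
            f, p = stats.f_oneway(*groups)
            test, stat = "anova_F", f
        keep = bool(p < alpha)
        if keep:
            included.append(name)
        rows.append({"candidate": name, "test": test, "statistic": stat,
                     "p": p, "included": keep})
    return included, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting

def _vc_formula(spec: ModelSpec, random_slope: bool) -> dict[str, str]:
    vc = {spec.unit_col: f"0 + C({spec.unit_col})"}
    if random_slope and spec.time_col is not None:
        vc["unit_time"] = f"0 + C({spec.unit_col}):{spec.time_col}"
    return vc


def _fit_mixedlm(df: pd.DataFrame, outcome: str, fixed: list[str],
                 spec: ModelSpec, reml: bool, random_slope: bool):
    rhs = " + ".join(fixed) if fixed else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            f"{outcome} ~ {rhs}",
            groups=spec.group_col,
            re_formula="1",
            vc_formula=_vc_formula(spec, random_slope),
            data=df,
        )
        res = model.fit(reml=reml, method=["lbfgs", "powell"])
    return res


def _residual_ar1(df: pd.DataFrame, resid: np.ndarray, spec: ModelSpec) -> tuple[float, int]:
    """Lag-1 autocorrelation of residuals within each unit x phase run."""
    work = df.assign(__resid=resid)
    keys = [spec.unit_col]
    if "phase" in work.columns:
        keys.append("phase")
    num = den = 0.0
    m = 0
    lengths = []
    for _, g in work.groupby(keys, sort=False):
        r = g["__resid"].to_numpy()
        if r.size < 2:
            continue
        # demean per run so leftover unit-level variance (compound
        # symmetry) is not mistaken for serial correlation
        r = r - r.mean()
        num += np.sum(r[:-1] * r[1:])
        den += np.sum(r**2)
        m += r.size - 1
        lengths.append(r.size)
    phi = num / den if den > 0 else 0.0
    if lengths:
        # Kendall small-sample correction for the demeaning bias
        phi = phi + (1.0 + 3.0 * phi) / float(np.mean(lengths))
    return float(np.clip(phi, -0.99, 0.99)), m


def _quasi_difference(df: pd.DataFrame, cols: list[str], phi: float,
                      spec: ModelSpec) -> pd.DataFrame:
    """Prais-Winsten transform of outcome and fixed columns within each
    unit x phase run (random-effect indicators left untransformed)."""
    out = df.copy()
    keys = [spec.unit_col] + (["phase"] if "phase" in df.columns else [])
    out["__const"] = 1.0
    tcols = cols + ["__const", spec.outcome]
    for _, idx in out.groupby(keys, sort=False).groups.items():
        idx = list(idx)
        block = out.loc[idx, tcols].to_numpy(float)
        tr = block.copy()
        tr[0] = block[0] * np.sqrt(1.0 - phi**2)
        tr[1:] = block[1:] - phi * block[:-1]
        out.loc[idx, tcols] = tr
    return out


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """REML fit of the specified mixed model.

    Returns Wald estimates, 95% intervals and p-values per fixed term,
    variance components, the residual AR(1) coefficient (estimated from
    within-unit residual runs; when ``spec.ar1`` the fixed part is refit on
    Prais-Winsten-transformed data), ICCs from the null model, and
    marginal R² of the fixed effects.
    """
    df, fixed = build_fixed_design(data, spec)
    needed = [spec.outcome, spec.group_col, spec.unit_col] + fixed
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    _check_rank(df, fixed)

    res = _fit_mixedlm(df, spec.outcome, fixed, spec, reml=True,
                       random_slope=spec.random_slope_time)
    phi, _ = _residual_ar1(df, np.asarray(res.resid), spec)

    if spec.ar1 and abs(phi) > 1e-8:
        dfw = _quasi_difference(df, fixed, phi, spec)
        # refit on whitened data; __const replaces the implicit intercept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                f"{spec.outcome} ~ 0 + __const + " + " + ".join(fixed)
                if fixed else f"{spec.outcome} ~ 0 + __const",
                groups=spec.group_col, re_formula="1",
                vc_formula=_vc_formula(spec, spec.random_slope_time),
                data=dfw,
            )
            res = model.fit(reml=True, method=["lbfgs", "powell"])

    fe = res.fe_params
    ci = res.conf_int().loc[fe.index]
    pvals = res.pvalues.loc[fe.index]
    coef_rows = []
    for name in fe.index:
        pretty = "(Intercept)" if name in ("Intercept", "__const") else name
        coef_rows.append({
            "term": pretty,
            "estimate": float(fe[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "p": float(pvals[name]),
        })
    coefficients = pd.DataFrame(coef_rows)

    vcomp: dict[str, float] = {spec.group_col: float(np.asarray(res.cov_re)[0, 0])}
    vc_names = list(_vc_formula(spec, spec.random_slope_time))
    for i, name in enumerate(vc_names):
        vcomp[name] = float(res.vcomp[i])
    resid_var = float(res.scale)

    # marginal R2 on the original (unwhitened) design
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(float) for c in fixed])
    beta = np.array([fe.get("Intercept", fe.get("__const", 0.0))] +
                    [fe[c] for c in fixed])
    yhat_fixed = X @ beta
    var_fixed = float(np.var(yhat_fixed))
    total = var_fixed + sum(vcomp.values()) + resid_var
    r2_marginal = var_fixed / total if total > 0 else np.nan

    try:
        iccs = icc(df, spec.outcome, spec.group_col, spec.unit_col)
    except Exception:  # degenerate inputs
        iccs = {}

    return MixedModelFit(
        spec=spec,
        coefficients=coefficients,
        variance_components=vcomp,
        resid_var=resid_var,
        ar1_phi=phi,
        icc_by_level=iccs,
        marginal_r2=r2_marginal,
        loglik=float(res.llf),
        n_obs=int(len(df)),
        n_units=int(df[spec.unit_col].nunique()),
        converged=bool(res.converged),
        fixed_prediction_var=var_fixed,
    )


def marginal_r2(fit: MixedModelFit) -> float:
    """Fixed-effects variance over total (fixed + random + residual)."""
    return fit.marginal_r2


def variance_explained_by_level(
    spec: ModelSpec, data: pd.DataFrame
) -> dict[str, float]:
    """Proportional reduction in each random variance component of the full
    model relative to the random-intercept-only model (pseudo-R² per level).
    """
    null_spec = replace(spec, continuous=(), categorical={}, interactions=(),
                        time_col=None, random_slope_time=False, ar1=False)
    full = fit_model(spec, data)
    null = fit_model(null_spec, data)
    out = {}
    for level, v_null in null.variance_components.items():
        v_full = full.variance_components.get(level, np.nan)
        if v_null > 0:
            out[level] = float(np.clip(1.0 - v_full / v_null, 0.0, 1.0))
        else:
            out[level] = np.nan
    return out


# ---------------------------------------------------------------------------
# stepwise structure selection

def _merge_structure(spec: ModelSpec, struct: ModelSpec) -> ModelSpec:
    return replace(spec, time_col=struct.time_col,
                   random_slope_time=struct.random_slope_time, ar1=struct.ar1)


def select_structure(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Stepwise likelihood-ratio structure selection (ML fits).

    Candidate sequence: intercept-only OLS -> + random intercepts
    (group, unit) -> + fixed time -> + random time slope -> + AR(1)
    residuals. Each step is kept while its LRT against the predecessor is
    significant; a rejected component is skipped (components that depend on
    it are skipped too) while later independent components are still tested
    against the current best model. The returned spec carries the selected
    structure flags merged back onto the substantive fixed terms of
    ``spec``.
    """
    df, _fixed = build_fixed_design(data, spec)
    df = df.dropna(subset=[spec.outcome])
    log_rows = []

    ols = sm.OLS(df[spec.outcome].to_numpy(float),
                 np.ones((len(df), 1))).fit()
    ll_prev = float(ols.llf)
    chosen = replace(spec, continuous=(), categorical={}, interactions=(),
                     time_col=None, random_slope_time=False, ar1=False)

    def _step(name, ll_new, df_diff, accept_action):
        nonlocal ll_prev, chosen
        lr = 2.0 * (ll_new - ll_prev)
        p = stats.chi2.sf(max(lr, 0.0), df_diff)
        accepted = bool(p < alpha)
        log_rows.append({"step": name, "lr_stat": lr, "df": df_diff,
                         "p": p, "accepted": accepted})
        if accepted:
            ll_prev = ll_new
            chosen = accept_action()
        return accepted

    # step 1: random intercepts for group and unit
    try:
        res1 = _fit_mixedlm(df, spec.outcome, [], chosen, reml=False,
                            random_slope=False)
    except Exception as exc:  # pragma: no cover - convergence guard
        logger.warning("random-intercept step failed: %s", exc)
        return _merge_structure(spec, chosen), pd.DataFrame(log_rows)
    if not _step("random_intercepts", float(res1.llf), 2, lambda: chosen):
        return _merge_structure(spec, chosen), pd.DataFrame(log_rows)
    res_prev = res1

    # step 2: fixed effect of time
    if spec.time_col is not None:
        try:
            res2 = _fit_mixedlm(df, spec.outcome, [spec.time_col], chosen,
                                reml=False, random_slope=False)
        except Exception as exc:
            logger.warning("fixed-time step failed: %s", exc)
            res2 = None
        time_kept = res2 is not None and _step(
            "fixed_time", float(res2.llf), 1,
            lambda: replace(chosen, time_col=spec.time_col),
        )
        if time_kept:
            res_prev = res2

            # step 3: random slope for time within unit (needs a time term)
            try:
                res3 = _fit_mixedlm(df, spec.outcome, [spec.time_col], chosen,
                                    reml=False, random_slope=True)
            except Exception as exc:
                logger.warning("random-slope step failed: %s", exc)
                res3 = None
            if res3 is not None and _step(
                "random_slope_time", float(res3.llf), 1,
                lambda: replace(chosen, random_slope_time=True),
            ):
                res_prev = res3

    # step 4: AR(1) residual correlation; LRT from the profiled Gaussian
    # likelihood of the within-unit residual runs
    phi, m = _residual_ar1(df, np.asarray(res_prev.resid), chosen)
    if m > 0:
        lr = -m * np.log(max(1.0 - phi**2, 1e-12))
        p = stats.chi2.sf(lr, 1)
        accepted = bool(p < alpha)
        log_rows.append({"step": "ar1", "lr_stat": lr, "df": 1, "p": p,
                         "accepted": accepted})
        if accepted:
            chosen = replace(chosen, ar1=True)

    return _merge_structure(spec, chosen), pd.DataFrame(log_rows)
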