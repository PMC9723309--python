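"""Association of cluster oscillatory power with clinical variables.

Cluster median powers are rank-normalized to a standard normal scale and
entered as fixed effects (alongside age and, for the medication model,
off-state severity and education) in linear mixed models with a
by-participant random intercept, fitted by maximum likelihood. Inference on
the predictor of interest uses the likelihood-ratio test between the models
with and without that predictor, referred to a chi-squared distribution —
so a potential collinearity among predictors does not distort the test.

With exactly one observation per participant the random-intercept variance
is not identifiable; the fit then reports the boundary solution (variance
zero, equivalent to ordinary least squares under maximum likelihood) and
flags it, rather than silently dropping the term.

Descriptive group statistics (pooled two-sample t from summary statistics,
one-way ANOVA on artifact-free trial counts) round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def normalize_to_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform at plotting positions
    (rank - 0.5) / n. Strictly order-preserving; ties share a value."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("inverse-normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)


@dataclass
class PowerFeature:
    """Median cluster power for one subject/state, raw and normalized."""

    subject_id: str
    cluster_id: str
    state: str                 # "off" / "on"
    median_power: float
    normalized: float = np.nan


def cluster_median_power(trial_power: np.ndarray, channel_idx, bin_idx) -> float:
    """Median over trials x cluster electrodes x band bins of the
    (pre-normalization) spectral power. ``trial_power`` is
    (n_trials, n_channels, n_bins)."""
    sel = trial_power[np.ix_(range(trial_power.shape[0]), np.atleast_1d(channel_idx),
                             np.atleast_1d(bin_idx))]
    return float(np.median(sel))


@dataclass
class LMMResult:
    outcome: str
    fixed_terms: tuple
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    conf_int: pd.DataFrame
    llf: float
    re_variance: float
    n_obs: int
    boundary: bool = False       # random intercept at the zero-variance boundary
    converged: bool = True


def _ols_ml(y: np.ndarray, X: np.ndarray):
    """Maximum-likelihood Gaussian linear fit (the boundary solution of the
    mixed model when the random-intercept variance is zero)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    cov = sigma2 * n / (n - p) * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    tcrit = stats.t.ppf(0.975, df=n - p)
    ci = np.column_stack([beta - tcrit * bse, beta + tcrit * bse])
    return beta, bse, tvals, ci, llf


def fit_lmm(data: pd.DataFrame, outcome: str, fixed_terms,
            group: str = "subject_id") -> LMMResult:
    """ML fit of outcome ~ 1 + fixed_terms + (1 | group).

    Complete cases only. Raises on a rank-deficient design, naming the
    collinear columns. Falls back to the flagged boundary (OLS) solution
    when every group has a single row.
    """
    fixed_terms = tuple(fixed_terms)
    cols = [outcome, *fixed_terms, group]
    d = data[cols].dropna()
    n = len(d)
    if n < len(fixed_terms) + 3:
        raise ValueError(f"too few complete rows ({n}) for {outcome} ~ {fixed_terms}")
    X = np.column_stack([np.ones(n)] + [d[t].to_numpy(float) for t in fixed_terms])
    names = ["Intercept", *fixed_terms]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    y = d[outcome].to_numpy(float)
    groups = d[group].to_numpy()
    singleton = pd.Series(groups).value_counts().max() == 1

    if singleton:
        beta, bse, tvals, ci, llf = _ols_ml(y, X)
        return LMMResult(
            outcome=outcome, fixed_terms=fixed_terms,
            params=pd.Series(beta, index=names), bse=pd.Series(bse, index=names),
            tvalues=pd.Series(tvals, index=names),
            conf_int=pd.DataFrame(ci, index=names, columns=["lower", "upper"]),
            llf=llf, re_variance=0.0, n_obs=n, boundary=True,
        )

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        fit = model.fit(reml=False, method=["lbfgs", "powell"])
    params = pd.Series(np.asarray(fit.fe_params), index=names)
    bse = pd.Series(np.asarray(fit.bse_fe), index=names)
    ci_arr = np.column_stack([params - 1.96 * bse, params + 1.96 * bse])
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    return LMMResult(
        outcome=outcome, fixed_terms=fixed_terms, params=params, bse=bse,
        tvalues=params / bse,
        conf_int=pd.DataFrame(ci_arr, index=names, columns=["lower", "upper"]),
        llf=float(fit.llf), re_variance=re_var, n_obs=n,
        boundary=re_var < 1e-8, converged=bool(fit.converged),
    )


def lrt(full: LMMResult, reduced: LMMResult) -> tuple:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p)."""
    if not set(reduced.fixed_terms) <= set(full.fixed_terms):
        raise ValueError("models are not nested")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted on different rows")
    df = len(full.fixed_terms) - len(reduced.fixed_terms)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def lrt_for_predictor(data: pd.DataFrame, outcome: str, fixed_terms,
                      predictor: str, group: str = "subject_id"):
    """Fit the models with and without ``predictor`` on identical rows and
    test it; returns (full LMMResult, chi2, df, p)."""
    fixed_terms = tuple(fixed_terms)
    cols = [outcome, *fixed_terms, group]
    d = data[cols].dropna()
    full = fit_lmm(d, outcome, fixed_terms, group)
    reduced = fit_lmm(d, outcome, tuple(t for t in fixed_terms if t != predictor), group)
    return (full, *lrt(full, reduced))


def association_suite(features: pd.DataFrame, clinical: pd.DataFrame,
                      off_clusters=None, on_theta_cluster: str | None = None,
                      bh_correction: bool = True) -> pd.DataFrame:
    """The full set of power-clinical association models.

    ``features`` has one row per subject x cluster x state with columns
    ``subject_id, cluster_id, state, median_power``; powers are rank-
    normalized within (cluster, state) before modelling.

    Off-medication models: each outcome in {UPDRS motor off, disease
    duration, LEDD} against each off-state cluster power, with age as
    covariate and a by-participant random intercept. On-medication model:
    the on-off change in UPDRS motor against the on-state frontoparietal
    theta power, with age, off-state UPDRS and education as covariates.
    The LRT always targets the power term. Unadjusted p-values are primary;
    a Benjamini-Hochberg column is provided as supplementary output.
    """
    feats = features.copy()
    feats["normalized"] = np.nan
    for (cid, state), idx in feats.groupby(["cluster_id", "state"]).groups.items():
        feats.loc[idx, "normalized"] = normalize_to_normal(
            feats.loc[idx, "median_power"]
        )
    wide = feats.pivot_table(index="subject_id", columns=["cluster_id", "state"],
                             values="normalized")
    wide.columns = [f"power_{c}_{s}" for c, s in wide.columns]
    d = clinical.merge(wide.reset_index(), on="subject_id", how="inner")
    d = d[d.get("cohort", "PD") == "PD"] if "cohort" in d else d
    d = d.copy()
    d["delta_updrs"] = d["updrs_motor_on"] - d["updrs_motor_off"]

    if off_clusters is None:
        off_clusters = sorted({c.split("power_")[1].rsplit("_off", 1)[0]
                               for c in d.columns
                               if c.startswith("power_") and c.endswith("_off")})
    rows = []
    for cid in off_clusters:
        power_col = f"power_{cid}_off"
        if power_col not in d:
            continue
        for outcome in ("updrs_motor_off", "disease_duration", "ledd"):
            try:
                full, chi2, df, p = lrt_for_predictor(
                    d, outcome, ("age", power_col), power_col)
            except ValueError as err:
                rows.append({"outcome": outcome, "cluster": cid, "state": "off",
                             "skipped": str(err)})
                continue
            rows.append({
                "outcome": outcome, "cluster": cid, "state": "off",
                "estimate": full.params[power_col], "se": full.bse[power_col],
                "t": full.tvalues[power_col],
                "ci_lower": full.conf_int.loc[power_col, "lower"],
                "ci_upper": full.conf_int.loc[power_col, "upper"],
                "chi2": chi2, "df": df, "p": p, "n": full.n_obs,
                "boundary": full.boundary, "skipped": "",
            })
    if on_theta_cluster is not None:
        power_col = f"power_{on_theta_cluster}_on"
        if power_col in d:
            try:
                full, chi2, df, p = lrt_for_predictor(
                    d, "delta_updrs",
                    (power_col, "age", "updrs_motor_off", "education"), power_col)
                rows.append({
                    "outcome": "delta_updrs", "cluster": on_theta_cluster,
                    "state": "on",
                    "estimate": full.params[power_col], "se": full.bse[power_col],
                    "t": full.tvalues[power_col],
                    "ci_lower": full.conf_int.loc[power_col, "lower"],
                    "ci_upper": full.conf_int.loc[power_col, "upper"],
                    "chi2": chi2, "df": df, "p": p, "n": full.n_obs,
                    "boundary": full.boundary, "skipped": "",
                })
            except ValueError as err:
                rows.append({"outcome": "delta_updrs", "cluster": on_theta_cluster,
                             "state": "on", "skipped": str(err)})
    report = pd.DataFrame(rows)
    if bh_correction and "p" in report:
        ok = report["p"].notna()
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(report), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(report.loc[ok, "p"], method="fdr_bh")[1]
        report["p_bh_supplementary"] = adj
    return report


def simulate_null_lrt(n_subjects: int = 100, n_replicates: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I calibration of the power-term LRT under the null.

    Each replicate draws an outcome that depends on age only and an
    independent power predictor, fits the association model with and
    without the predictor, and tests it at level ``alpha``. Returns the
    rejection rate and the p-values (which should be uniform on (0, 1)).
    """
    rng = np.random.default_rng(seed)
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        age = rng.standard_normal(n_subjects)
        power = rng.standard_normal(n_subjects)
        y = 0.3 * age + rng.standard_normal(n_subjects)
        d = pd.DataFrame({"y": y, "age": age, "power": power,
                          "subject_id": np.arange(n_subjects)})
        _, _, _, p = lrt_for_predictor(d, "y", ("age", "power"), "power")
        ps[r] = p
    return {"rejection_rate": float((ps < alpha).mean()), "p_values": ps,
            "n_subjects": n_subjects, "n_replicates": n_replicates}


def simulate_sign_recovery(rho: float = -0.6, n_subjects: int = 25,
                           n_replicates: int = 100, measurement_noise: float = 0.3,
                           seed: int = 0) -> dict:
    """Sign recovery of an injected theta -> delta-UPDRS effect.

    Each replicate simulates standardized per-subject theta gains, an
    on-off UPDRS change coupled to them at correlation ``rho`` (via the
    synthetic clinical model), a measured power feature (the gain plus
    measurement noise, rank-normalized), and fits the medication model
    (power + age + off-state UPDRS + education). Returns the fraction of
    replicates whose fitted power effect has the sign of ``rho``.
    """
    from .synth import ClinicalModel, Coupling, simulate_clinical

    model = ClinicalModel(dupdrs=Coupling("fp_theta", "on", rho, -5.0, 4.0))
    rng = np.random.default_rng(seed)
    signs = np.empty(n_replicates, dtype=bool)
    ests = np.empty(n_replicates)
    for r in range(n_replicates):
        z = rng.standard_normal(n_subjects)
        gains = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n_subjects)],
            "z_fp_theta_on": z,
            "z_op_beta_off": rng.standard_normal(n_subjects),
            "z_motor_beta_off": rng.standard_normal(n_subjects),
        })
        clin = simulate_clinical(gains, model, rng)
        clin["delta_updrs"] = clin["updrs_motor_on"] - clin["updrs_motor_off"]
        clin["power"] = normalize_to_normal(z + measurement_noise * rng.standard_normal(n_subjects))
        fit = fit_lmm(clin, "delta_updrs", ("power", "age", "updrs_motor_off", "education"))
        ests[r] = fit.params["power"]
        signs[r] = np.sign(ests[r]) == np.sign(rho)
    return {"sign_recovery_rate": float(signs.mean()), "estimates": ests,
            "rho": rho, "n_subjects": n_subjects}


def summary_t_test(mean1, sd1, n1, mean2, sd2, n2) -> dict:
    """Pooled-variance two-sample t test from summary statistics.

    Student (pooled) convention, df = n1 + n2 - 2; returns the t statistic,
    two-tailed p and the CI for the mean difference.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    t = diff / se if se > 0 else np.sign(diff) * np.inf
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    tcrit = stats.t.ppf(0.975, df)
    return {"t": float(t), "df": int(df), "p": float(p),
            "ci": (float(diff - tcrit * se), float(diff + tcrit * se))}


def oneway_anova(*groups) -> dict:
    """One-way ANOVA across groups of per-subject values."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("within-group variance is zero in every group")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"F": float(f), "df1": df1, "df2": df2, "p": float(p)}
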