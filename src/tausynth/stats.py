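"""Downstream clinical-evaluation statistics for synthetic tau-PET measures.

Linear mixed-effects coupling of synthetic to true longitudinal MetaTempTau
(random intercepts and slopes, REML), univariate logistic diagnosis
classification scored by ROC-AUC, Steiger's Z for dependent correlations
sharing one variable, Benjamini-Hochberg FDR, proportional-odds ordinal
regression of temporal SUVR on Braak group, and tertile-stratified
natural-cubic-spline trajectories of longitudinal cognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices, dmatrix
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# longitudinal coupling
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalFit:
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    p_beta0: float
    p_beta1: float
    re_var_intercept: float
    re_var_slope: float
    re_corr: float
    resid_var: float
    n_subjects: int
    n_obs: int
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None
    degenerate: bool = False


def fit_longitudinal_coupling(true_meta, synth_meta, subject_ids,
                              random_effects: bool = True,
                              lr_test: bool = False) -> LongitudinalFit:
    """REML fit of  true_it = b0 + b1 * synth_it + b0i + b1i * synth_it + e_it.

    With ``random_effects=False`` the model collapses to OLS. The optional
    likelihood-ratio test refits by ML against a null with no fixed or random
    slope (random intercept retained).
    """
    df = pd.DataFrame({"y": np.asarray(true_meta, float),
                       "x": np.asarray(synth_meta, float),
                       "g": np.asarray(subject_ids)})
    if df.isna().any().any():
        raise ValueError("inputs contain missing values")
    n_sub = df["g"].nunique()

    if not random_effects:
        ols = smf.ols("y ~ x", df).fit()
        return LongitudinalFit(
            beta0=float(ols.params["Intercept"]), beta1=float(ols.params["x"]),
            se_beta0=float(ols.bse["Intercept"]), se_beta1=float(ols.bse["x"]),
            p_beta0=float(ols.pvalues["Intercept"]), p_beta1=float(ols.pvalues["x"]),
            re_var_intercept=0.0, re_var_slope=0.0, re_corr=0.0,
            resid_var=float(ols.scale), n_subjects=n_sub, n_obs=len(df))

    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("y ~ x", df, groups=df["g"], re_formula="~x")
        fit = None
        for method in ("lbfgs", "powell", "bfgs"):
            try:
                fit = md.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            # singular random-slope structure: degrade to a random intercept
            degenerate = True
            fit = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
        if not fit.converged or np.any(np.isnan(fit.bse.iloc[:2])):
            degenerate = True
        cov_re = np.asarray(fit.cov_re)
        v0 = float(cov_re[0, 0])
        v1 = float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0
        corr = (float(cov_re[0, 1] / np.sqrt(v0 * v1))
                if cov_re.shape[0] > 1 and v0 > 0 and v1 > 0 else 0.0)

        out = LongitudinalFit(
            beta0=float(fit.params["Intercept"]), beta1=float(fit.params["x"]),
            se_beta0=float(fit.bse["Intercept"]), se_beta1=float(fit.bse["x"]),
            p_beta0=float(fit.pvalues["Intercept"]), p_beta1=float(fit.pvalues["x"]),
            re_var_intercept=v0, re_var_slope=v1, re_corr=corr,
            resid_var=float(fit.scale), n_subjects=n_sub, n_obs=len(df),
            degenerate=degenerate)

        if lr_test:
            try:
                full = smf.mixedlm("y ~ x", df, groups=df["g"],
                                   re_formula="~x").fit(reml=False)
                dfree = 3  # fixed slope + random-slope variance + covariance
            except (np.linalg.LinAlgError, ValueError):
                full = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=False)
                dfree = 1
            null = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=False)
            stat = 2.0 * (full.llf - null.llf)
            out.lr_stat = float(stat)
            out.lr_df = dfree
            out.lr_p = float(sps.chi2.sf(stat, dfree))
    return out


# ---------------------------------------------------------------------------
# diagnosis classification
# ---------------------------------------------------------------------------

def classify_diagnosis(train_values, train_labels, test_values, test_labels) -> dict:
    """Univariate logistic regression on a tau summary; held-out ROC-AUC.

    AUC uses the rank (Mann-Whitney) statistic with midranks for ties, so it
    is invariant to strictly monotone transforms of the scores.
    """
    ytr = np.asarray(train_labels, int)
    yte = np.asarray(test_labels, int)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training labels contain a single class")
    if len(np.unique(yte)) < 2:
        raise ValueError("test labels contain a single class; AUC undefined")
    Xtr = np.asarray(train_values, float).reshape(-1, 1)
    Xte = np.asarray(test_values, float).reshape(-1, 1)
    clf = LogisticRegression().fit(Xtr, ytr)
    prob = clf.predict_proba(Xte)[:, 1]
    return {"model": clf, "auc": float(roc_auc_score(yte, prob)),
            "coef": float(clf.coef_[0, 0]), "intercept": float(clf.intercept_[0])}


# ---------------------------------------------------------------------------
# dependent correlations
# ---------------------------------------------------------------------------

def steiger_z(r_xy: float, r_zy: float, r_xz: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing variable y.

    Fisher-z difference scaled by the shared-variable covariance correction
    (Steiger's case with the pooled correlation r-bar). Returns (Z, two-sided p).
    """
    for name, r in (("r_xy", r_xy), ("r_zy", r_zy), ("r_xz", r_xz)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1, z2 = np.arctanh(r_xy), np.arctanh(r_zy)
    rbar = 0.5 * (r_xy + r_zy)
    psi = r_xz * (1.0 - 2.0 * rbar ** 2) - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r_xz ** 2)
    s = psi / (1.0 - rbar ** 2) ** 2
    denom = 2.0 * (1.0 - s)
    if denom <= 0:
        raise ValueError("degenerate correlation structure")
    z = (z1 - z2) * np.sqrt((n - 3.0) / denom)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (adjusted p-values, boolean rejection set at level q); adjusted
    values are monotone in the raw-p order and never below the raw p.
    """
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# ordinal Braak regression
# ---------------------------------------------------------------------------

@dataclass
class OrdinalFit:
    beta: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    thresholds: list[float]
    levels: list
    separation_flag: bool = False


def ordinal_braak(suvr, braak_group) -> OrdinalFit:
    """Proportional-odds (cumulative logit) regression of SUVR on ordered group."""
    y = pd.Categorical(braak_group, ordered=True)
    if len(y.categories) < 2:
        raise ValueError("need >= 2 populated Braak groups")
    x = pd.DataFrame({"suvr": np.asarray(suvr, float)})
    sep = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = OrderedModel(y, x, distr="logit")
        res = mod.fit(method="bfgs", disp=False, maxiter=2000, gtol=1e-10)
        beta = float(res.params["suvr"])
        se = float(res.bse["suvr"])
        if not np.isfinite(se) or se > 1e3 * max(abs(beta), 1.0):
            sep = True
        zval = beta / se if se > 0 else np.inf
        ci = res.conf_int().loc["suvr"]
        # cumulative thresholds: first raw, subsequent increments exponentiated
        raw = res.params[[c for c in res.params.index if c != "suvr"]].to_numpy()
        thresholds = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
    return OrdinalFit(beta=beta, se=se, z=float(zval), p=float(2 * sps.norm.sf(abs(zval))),
                      ci_low=float(ci[0]), ci_high=float(ci[1]),
                      thresholds=[float(t) for t in thresholds],
                      levels=list(y.categories), separation_flag=sep)


# ---------------------------------------------------------------------------
# tertile spline trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryContrast:
    tertile_of: dict                 # subject id -> 1, 2, 3
    endpoint_time: float
    endpoint_means: dict             # tertile -> fitted endpoint mean
    contrasts: pd.DataFrame          # pair, estimate, se, t, p
    arm: object = None


def assign_tertiles(values, subject_ids) -> dict:
    """Rank-based tertiles: group sizes differ by at most one."""
    ids = list(subject_ids)
    v = np.asarray(values, float)
    order = np.argsort(v, kind="stable")
    n = len(v)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    out = {}
    pos = 0
    for t, sz in enumerate(sizes, start=1):
        for i in order[pos:pos + sz]:
            out[ids[i]] = t
        pos += sz
    return out


def tertile_trajectories(meta_hat: dict, cognition, times, subject_ids,
                         arm_labels=None, n_interior_knots: int = 2,
                         endpoint_time: float | None = None) -> list[TrajectoryContrast]:
    """Mixed model of longitudinal cognition with a natural-cubic-spline time
    basis interacted with MetaTempTau tertile, subject random intercept.

    ``meta_hat`` maps subject id -> synthetic MetaTempTau (baseline);
    tertiles are cut at the empirical 1/3 and 2/3 quantiles within each arm.
    Pairwise tertile differences in fitted means at ``endpoint_time``
    (default: last observed time) are returned with SE, t and p.
    """
    df = pd.DataFrame({"y": np.asarray(cognition, float),
                       "t": np.asarray(times, float),
                       "g": np.asarray(subject_ids)})
    if df["t"].nunique() < 3:
        raise ValueError("need >= 3 distinct time points for the spline basis")
    df["arm"] = (np.asarray(arm_labels) if arm_labels is not None
                 else np.repeat("all", len(df)))
    results = []
    for arm in pd.unique(df["arm"]):
        sub = df[df["arm"] == arm].reset_index(drop=True)
        subj = pd.unique(sub["g"])
        tert_of = assign_tertiles([meta_hat[s] for s in subj], subj)
        sub["tert"] = sub["g"].map(tert_of)

        # the basis (constant + linear + one column per interior knot) must
        # not exceed the number of distinct observation times
        k_eff = min(n_interior_knots, sub["t"].nunique() - 2)
        knots = np.quantile(np.unique(sub["t"]),
                            np.linspace(0, 1, k_eff + 2)[1:-1])
        basis = dmatrix("cr(t, knots=knots) - 1", {"t": sub["t"], "knots": knots},
                        return_type="dataframe")
        dinfo = basis.design_info
        nb = basis.shape[1]

        # fixed effects: per-tertile spline coefficients (the natural cubic
        # basis spans the constant, so no separate intercepts)
        X_parts = []
        for g in (1, 2, 3):
            d = (sub["tert"] == g).to_numpy(float)
            X_parts.append(d[:, None] * basis.to_numpy())
        X = np.hstack(X_parts)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(sub["y"].to_numpy(), X, groups=sub["g"].to_numpy())
            res = None
            for method in ("bfgs", "lbfgs", "powell"):
                try:
                    res = mod.fit(reml=True, method=method)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if res is None:
                raise np.linalg.LinAlgError(
                    "mixed-model fit failed for every optimizer; check that the "
                    "time design spans the spline basis")
        beta = res.fe_params
        cov = res.cov_params()[:len(beta), :len(beta)]

        t_end = float(endpoint_time if endpoint_time is not None else sub["t"].max())
        (b_end,) = build_design_matrices([dinfo], {"t": [t_end], "knots": knots})
        b_end = np.asarray(b_end)[0]

        def row_for(g):
            r = np.zeros(len(beta))
            off = (g - 1) * nb
            r[off: off + nb] = b_end
            return r

        means = {g: float(row_for(g) @ beta) for g in (1, 2, 3)}
        rows = []
        resid_df = len(sub) - len(beta)
        for a, b in ((3, 1), (3, 2), (2, 1)):
            c = row_for(a) - row_for(b)
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            tval = est / se
            rows.append({"pair": f"T{a}-T{b}", "estimate": est, "se": se,
                         "t": tval, "p": float(2 * sps.t.sf(abs(tval), resid_df))})
        results.append(TrajectoryContrast(tert_of, t_end, means,
                                          pd.DataFrame(rows), arm=arm))
    return results
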