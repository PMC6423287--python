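"""Statistical models for incubation rhythms.

The suite mirrors a standard chronobiology workflow:

* circadian rhythm terms enter linear models as sine/cosine pairs of time
  transformed to radians, ``rad = 2 * time * pi / period`` for periods of
  12 and 24 h;
* continuous predictors (except time) are z-transformed;
* models of per-nest or per-day summaries are weighted by the square root
  of monitored time;
* fixed-effect uncertainty is summarized by credible intervals from 5000
  posterior draws (multivariate normal around the estimates with the
  coefficient covariance) — no mixed-model p-values are computed;
* repeatability (ICC) of daily attendance comes from a random-intercept
  REML fit, with a parametric bootstrap for its CI;
* partial compensation is the negated slope of female-on-male attendance.

Mixed models are fitted by REML via statsmodels MixedLM.  When a random
structure fails to converge, the fit falls back down a documented ladder
(random slopes dropped first, then secondary variance components) and the
result records which structure was used.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import FEMALE, MALE

__all__ = [
    "harmonic_design",
    "z_transform",
    "ModelSpec",
    "FitResult",
    "PosteriorSummary",
    "RepeatabilityResult",
    "CompensationResult",
    "fit_model",
    "posterior_ci",
    "sample_one_sex_per_hour",
    "repeatability",
    "compensation",
    "run_model_suite",
]


# ---------------------------------------------------------------------------
# design helpers


def harmonic_design(time_h, periods: Sequence[int] = (12, 24)) -> pd.DataFrame:
    """Sine/cosine rhythm terms for time-of-day in hours.

    For each period p, ``rad_p = 2 * time * pi / p`` and the columns
    ``sin<p>``/``cos<p>`` hold its sine and cosine.
    """
    t = np.asarray(time_h, dtype=float)
    if np.any((t < 0) | (t >= 24)):
        raise ValueError("time_h must lie in [0, 24)")
    out = {}
    for p in periods:
        rad = 2.0 * t * np.pi / p
        out[f"rad{p}"] = rad
        out[f"sin{p}"] = np.sin(rad)
        out[f"cos{p}"] = np.cos(rad)
    return pd.DataFrame(out)


def z_transform(values) -> np.ndarray:
    """Mean-center and scale to sample SD 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-transform a constant column")
    return (x - np.mean(x)) / sd


def _maybe_z(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        df[c + "_z"] = z_transform(df[c].to_numpy())
    return df


# ---------------------------------------------------------------------------
# generic model fitting


@dataclass(frozen=True)
class ModelSpec:
    """A model formula plus its random structure and weighting rule."""

    name: str
    formula: str  # statsmodels formula for the fixed part (incl. response)
    groups: Optional[str] = None  # grouping column for random intercepts
    re_formula: Optional[str] = None  # random-effects design within groups
    vc_formula: Optional[dict] = None  # extra variance components
    weights: Optional[str] = None  # column whose sqrt is the fit weight
    fallbacks: tuple = ()  # ladder of simpler (re_formula, vc_formula)


@dataclass
class FitResult:
    names: list
    estimates: np.ndarray
    cov: np.ndarray
    method: str  # "ols" | "mixed-reml"
    n_obs: int
    converged: bool
    fallback_used: Optional[str] = None
    variance_components: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.estimates, index=self.names)


@dataclass
class PosteriorSummary:
    table: pd.DataFrame  # term, median, ci_low, ci_high
    n_draws: int
    seed: int


def _check_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name columns not contributing independent directions
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        bad = [n for n, d in zip(names, diag) if d < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; aliased terms: {bad}")


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Fit an OLS/WLS model, or a REML mixed model when random terms exist.

    On mixed-model non-convergence the random structure steps down the
    spec's fallback ladder; the structure actually used is recorded.
    """
    df = table.reset_index(drop=True)
    weights = np.sqrt(df[spec.weights].to_numpy(float)) if spec.weights else None

    if spec.groups is None:
        model = smf.wls(
            spec.formula, df, weights=weights if weights is not None else 1.0
        )
        _check_rank(model.exog, model.exog_names)
        if model.exog.shape[0] < model.exog.shape[1] + 2:
            raise ValueError(
                f"{spec.name}: too few rows ({model.exog.shape[0]}) for "
                f"{model.exog.shape[1]} parameters"
            )
        res = model.fit()
        return FitResult(
            names=list(model.exog_names),
            estimates=np.asarray(res.params),
            cov=np.asarray(res.cov_params()),
            method="ols",
            n_obs=int(model.exog.shape[0]),
            converged=True,
        )

    structures = [(spec.re_formula, spec.vc_formula)] + list(spec.fallbacks)
    last_exc: Optional[Exception] = None
    for i, (re_f, vc_f) in enumerate(structures):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    spec.formula,
                    df,
                    groups=df[spec.groups],
                    re_formula=re_f,
                    vc_formula=vc_f,
                )
                _check_rank(model.exog, model.exog_names)
                res = model.fit(reml=True)
            if not res.converged:
                last_exc = RuntimeError(f"{spec.name}: REML did not converge")
                continue
            k = len(model.exog_names)
            cov = np.asarray(res.cov_params())[:k, :k]
            vc = {"group_cov": np.asarray(res.cov_re), "resid": float(res.scale)}
            if getattr(res, "vcomp", None) is not None and len(res.vcomp):
                vc["vcomp"] = np.asarray(res.vcomp)
            return FitResult(
                names=list(model.exog_names),
                estimates=np.asarray(res.fe_params),
                cov=cov,
                method="mixed-reml",
                n_obs=int(model.nobs),
                converged=True,
                fallback_used=None if i == 0 else f"re={re_f!r}, vc={vc_f is not None}",
                variance_components=vc,
            )
        except np.linalg.LinAlgError as exc:
            last_exc = exc
        except ValueError as exc:
            if "aliased" in str(exc):
                raise
            last_exc = exc
    # last rung of the ladder: drop all random terms
    model = smf.wls(spec.formula, df, weights=weights if weights is not None else 1.0)
    _check_rank(model.exog, model.exog_names)
    res = model.fit()
    return FitResult(
        names=list(model.exog_names),
        estimates=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        method="ols",
        n_obs=int(model.exog.shape[0]),
        converged=True,
        fallback_used="no random terms (mixed fits failed)",
    )


def posterior_ci(
    fit: FitResult, n_draws: int = 5000, seed: int = 0
) -> PosteriorSummary:
    """Credible intervals from posterior simulation of the coefficients.

    Draws ``n_draws`` samples from N(estimates, cov) and reports the 2.5,
    50 and 97.5 percentiles per coefficient; reproducible under ``seed``.
    """
    cov = 0.5 * (fit.cov + fit.cov.T)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise ValueError("coefficient covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.estimates, cov, size=n_draws, method="eigh")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame(
        {"term": fit.names, "median": med, "ci_low": lo, "ci_high": hi}
    )
    return PosteriorSummary(table=table, n_draws=n_draws, seed=seed)


def sample_one_sex_per_hour(hourly: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Collapse per-hour rows to a single randomly chosen sex per hour.

    Female and male hourly attendance are strongly inversely correlated, so
    rhythm models use one independent data point per nest-hour: the sex is
    picked uniformly at random (reproducible under ``seed``).
    """
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, size=len(hourly))
    out = hourly.copy().reset_index(drop=True)
    out["sex"] = np.where(pick == 0, FEMALE, MALE)
    out["attendance_sex"] = np.where(
        pick == 0,
        out["attendance_female"].to_numpy(float),
        out["attendance_male"].to_numpy(float),
    )
    return out


# ---------------------------------------------------------------------------
# repeatability (ICC)


@dataclass
class RepeatabilityResult:
    R: float
    ci_low: float
    ci_high: float
    var_between: float
    var_resid: float
    n_bootstrap: int
    grouping: str


def _oneway_reml(y: np.ndarray, groups: np.ndarray):
    """REML variance components for a one-way random-intercept model.

    Profiles the residual variance and the grand mean out of the REML
    criterion, leaving a 1-D search over the variance ratio
    lambda = var_between / var_resid.  O(#groups) per evaluation, which is
    what makes a 5000-draw parametric bootstrap affordable.
    """
    y = np.asarray(y, float)
    codes, _ = pd.factorize(groups)
    k = codes.max() + 1
    n_i = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=y, minlength=k)
    ybar = sums / n_i
    ssw = float(np.sum((y - ybar[codes]) ** 2))
    N = float(len(y))

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = 1.0 + lam * n_i
        w = n_i / denom
        mu = np.sum(w * ybar) / np.sum(w)
        q = ssw + float(np.sum(n_i * (ybar - mu) ** 2 / denom))
        sigma2 = q / (N - 1.0)
        return (N - 1.0) * np.log(sigma2) + float(np.sum(np.log(denom))) + np.log(
            np.sum(w)
        )

    res = scipy.optimize.minimize_scalar(
        neg2_reml, bounds=(-18.0, 18.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    if neg2_reml(-40.0) <= res.fun:  # boundary: no between-group variance
        lam = 0.0
    denom = 1.0 + lam * n_i
    w = n_i / denom
    mu = float(np.sum(w * ybar) / np.sum(w))
    q = ssw + float(np.sum(n_i * (ybar - mu) ** 2 / denom))
    sigma2 = q / (N - 1.0)
    return mu, lam * sigma2, sigma2, codes, n_i


def repeatability(
    daily: pd.DataFrame,
    sex: str,
    n_bootstrap: int = 5000,
    seed: int = 0,
    response: Optional[str] = None,
) -> RepeatabilityResult:
    """Repeatability (ICC) of daily attendance across nests.

    R = var_between / (var_between + var_resid) from a gaussian
    random-intercept REML fit; the CI is a parametric bootstrap (data
    re-simulated from the fitted model, percentile 2.5/97.5).
    """
    col = response or ("attendance_female" if sex == FEMALE else "attendance_male")
    df = daily.dropna(subset=[col])
    counts = df.groupby("nest_id").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("repeatability needs >=2 nests with >=2 days each")
    y = df[col].to_numpy(float)
    mu, vb, ve, codes, n_i = _oneway_reml(y, df["nest_id"].to_numpy())
    R = vb / (vb + ve) if (vb + ve) > 0 else 0.0

    rng = np.random.default_rng(seed)
    k = len(n_i)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        b_i = rng.normal(0.0, np.sqrt(vb), size=k)
        y_star = mu + b_i[codes] + rng.normal(0.0, np.sqrt(ve), size=len(y))
        _, vb_s, ve_s, _, _ = _oneway_reml(y_star, codes)
        boots[b] = vb_s / (vb_s + ve_s) if (vb_s + ve_s) > 0 else 0.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RepeatabilityResult(
        R=float(R),
        ci_low=float(lo),
        ci_high=float(hi),
        var_between=float(vb),
        var_resid=float(ve),
        n_bootstrap=n_bootstrap,
        grouping="nest_id",
    )


# ---------------------------------------------------------------------------
# compensation


@dataclass
class CompensationResult:
    estimate: float  # 1 = full compensation, 0 = none
    ci_low: float
    ci_high: float
    n_nests: int


def compensation(
    nest_summaries: pd.DataFrame,
    n_draws: int = 5000,
    seed: int = 0,
) -> CompensationResult:
    """Partial compensation of female for male attendance shortfall.

    c = -(slope of female attendance on male attendance, WLS weighted by
    sqrt(days)).  c = 1 means the female fully replaces missing male
    incubation; c = 0 means none of it is made up.
    """
    df = nest_summaries
    if "included" in df.columns:
        df = df[df["included"]]
    df = df.dropna(subset=["female_attendance", "male_attendance"])
    if len(df) < 10:
        raise ValueError(f"compensation needs >=10 nests, got {len(df)}")
    male = df["male_attendance"].to_numpy(float)
    if np.ptp(male) == 0:
        raise ValueError("male attendance is constant; slope undefined")
    X = sm.add_constant(male)
    w = np.sqrt(df["n_days_included"].to_numpy(float))
    res = sm.WLS(df["female_attendance"].to_numpy(float), X, weights=w).fit()
    fit = FitResult(
        names=["const", "male_attendance"],
        estimates=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        method="ols",
        n_obs=len(df),
        converged=True,
    )
    post = posterior_ci(fit, n_draws=n_draws, seed=seed)
    slope_row = post.table.set_index("term").loc["male_attendance"]
    return CompensationResult(
        estimate=float(-res.params[1]),
        ci_low=float(-slope_row["ci_high"]),
        ci_high=float(-slope_row["ci_low"]),
        n_nests=len(df),
    )


# ---------------------------------------------------------------------------
# the model suite


def _suite_specs() -> dict:
    """The eight analysis models, keyed by short name.

    Responses: attendance proportions or natural-log durations (seconds).
    ``*_z`` columns are z-transformed continuous predictors; sin/cos terms
    are the untransformed rhythm design.
    """
    return {
        "overall_attendance": ModelSpec(
            name="overall_attendance",
            formula="overall_attendance ~ male_attendance_z",
            weights="n_days_included",
        ),
        "responsibility": ModelSpec(
            name="responsibility",
            formula="attendance ~ sex * responsibility_z",
            groups="nest_id",
            re_formula="1",
        ),
        "daily_attendance": ModelSpec(
            name="daily_attendance",
            formula=(
                "attendance ~ day_of_incubation_z + season_start_day_z "
                "+ male_daily_z"
            ),
            groups="nest_id",
            re_formula="1 + male_daily_z",
            fallbacks=(("1", None),),
        ),
        "hourly_attendance": ModelSpec(
            name="hourly_attendance",
            formula=(
                "attendance_sex ~ sex * (sin12 + cos12) + sex * (sin24 + cos24)"
            ),
            groups="parent_id",
            re_formula="1 + sin24 + cos24",
            vc_formula={"day_in_season": "0 + C(day_in_season)"},
            fallbacks=(("1 + sin24 + cos24", None), ("1", None)),
        ),
        "bout_length": ModelSpec(
            name="bout_length",
            formula=(
                "log_bout ~ sex * (sin24 + cos24) "
                "+ day_of_incubation_z * (sin24 + cos24) "
                "+ season_start_day_z * (sin24 + cos24) + prev_log_bout_z"
            ),
            groups="nest_id",
            re_formula="1 + sin24 + cos24 + day_of_incubation_z",
            vc_formula={"day_in_season": "0 + C(day_in_season)"},
            fallbacks=(
                ("1 + sin24 + cos24", None),
                ("1", None),
            ),
        ),
        "longest_night_bout": ModelSpec(
            name="longest_night_bout",
            formula="log_bout ~ night_length_z",
            groups="nest_id",
            re_formula="1 + night_length_z",
            fallbacks=(("1", None),),
        ),
        "median_bout": ModelSpec(
            name="median_bout",
            formula="log_bout ~ attendance_z * sex",
            groups="nest_id",
            re_formula="1",
        ),
        "gap_length": ModelSpec(
            name="gap_length",
            formula=(
                "log_gap ~ sex * (sin24 + cos24) "
                "+ day_of_incubation_z * (sin24 + cos24) "
                "+ season_start_day_z * (sin24 + cos24)"
            ),
            groups="nest_id",
            re_formula="1 + sin24 + cos24 + day_of_incubation_z",
            fallbacks=(
                ("1 + sin24 + cos24", None),
                ("1", None),
            ),
        ),
    }


def _add_harmonics(df: pd.DataFrame, time_col: str = "time_h") -> pd.DataFrame:
    H = harmonic_design(df[time_col].to_numpy(float) % 24.0)
    return pd.concat([df.reset_index(drop=True), H], axis=1)


def run_model_suite(
    tables: dict,
    n_draws: int = 5000,
    seed: int = 0,
) -> dict:
    """Fit the full analysis suite on aggregation outputs.

    ``tables`` may provide: ``nests`` (nest summaries), ``parents``
    (per-parent attendance/responsibility), ``daily``, ``hourly``
    (included hours with per-sex attendance), ``bouts``, ``night_bouts``,
    ``median_bouts``, ``gaps``.  Models whose inputs are missing or whose
    fit fails are reported as ``{"error": message}`` without aborting the
    rest of the suite.
    """
    specs = _suite_specs()
    out: dict = {}

    def run(key: str, data: Optional[pd.DataFrame]) -> None:
        if data is None or len(data) == 0:
            out[key] = {"error": "no input data"}
            return
        try:
            fit = fit_model(specs[key], data)
            post = posterior_ci(fit, n_draws=n_draws, seed=seed)
            out[key] = {"fit": fit, "posterior": post}
        except Exception as exc:  # propagate per model, keep suite running
            out[key] = {"error": f"{type(exc).__name__}: {exc}"}

    nests = tables.get("nests")
    data = None
    if nests is not None and len(nests):
        data = nests[nests["included"]].copy() if "included" in nests else nests.copy()
        data = _maybe_z(data, ["male_attendance"]).rename(
            columns={"male_attendance_z": "male_attendance_z"}
        )
    run("overall_attendance", data)

    parents = tables.get("parents")
    data = None
    if parents is not None and len(parents):
        data = _maybe_z(parents, ["responsibility"])
    run("responsibility", data)

    daily = tables.get("daily")
    data = None
    if daily is not None and len(daily):
        data = daily[daily["included"]].copy()
        if len(data):
            data["male_daily"] = data["attendance_male"]
            data = _maybe_z(
                data, ["day_of_incubation", "season_start_day", "male_daily"]
            ).rename(columns={"male_daily_z": "male_daily_z"})
    run("daily_attendance", data)

    hourly = tables.get("hourly")
    data = None
    if hourly is not None and len(hourly):
        inc = hourly[hourly["included"]]
        if len(inc):
            data = sample_one_sex_per_hour(inc, seed=seed)
            data["parent_id"] = data["nest_id"].astype(str) + ":" + data["sex"]
            data = _add_harmonics(data)
    run("hourly_attendance", data)

    bouts = tables.get("bouts")
    data = None
    if bouts is not None and len(bouts):
        data = bouts[(bouts["seconds"] > 0) & bouts["prev_seconds"].notna()].copy()
        if len(data):
            data["log_bout"] = np.log(data["seconds"].astype(float))
            data["prev_log_bout"] = np.log(data["prev_seconds"].astype(float))
            data = _maybe_z(
                data, ["day_of_incubation", "season_start_day", "prev_log_bout"]
            )
            data = _add_harmonics(data)
    run("bout_length", data)

    night = tables.get("night_bouts")
    data = None
    if night is not None and len(night):
        data = night.copy()
        data["log_bout"] = np.log(data["longest_female_bout_s"].astype(float))
        data["night_length"] = data["night_length_s"].astype(float)
        data = _maybe_z(data, ["night_length"])
    run("longest_night_bout", data)

    med = tables.get("median_bouts")
    data = None
    if med is not None and len(med):
        data = med.dropna(subset=["median_bout_s"]).copy()
        if len(data):
            data["log_bout"] = np.log(data["median_bout_s"].astype(float))
            data = _maybe_z(data, ["attendance"])
    run("median_bout", data)

    gaps = tables.get("gaps")
    data = None
    if gaps is not None and len(gaps):
        data = gaps[(gaps["seconds"] > 0) & gaps["precedes_sex"].notna()].copy()
        if len(data):
            data["log_gap"] = np.log(data["seconds"].astype(float))
            data["sex"] = data["precedes_sex"]
            data = _maybe_z(data, ["day_of_incubation", "season_start_day"])
            data = _add_harmonics(data)
    run("gap_length", data)

    return out


def suite_report(results: dict) -> pd.DataFrame:
    """Flatten run_model_suite output to a tidy coefficient table."""
    rows = []
    for name, res in results.items():
        if "error" in res:
            rows.append({"model": name, "term": None, "error": res["error"]})
            continue
        fit: FitResult = res["fit"]
        post: PosteriorSummary = res["posterior"]
        for _, r in post.table.iterrows():
            rows.append(
                {
                    "model": name,
                    "term": r["term"],
                    "estimate": fit.as_series()[r["term"]],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "n_obs": fit.n_obs,
                    "method": fit.method,
                    "convergence": fit.converged,
                    "fallback_used": fit.fallback_used or "",
                    "error": "",
                }
            )
    return pd.DataFrame(rows)
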