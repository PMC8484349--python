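"""Statistical battery for the oviposition experiments.

The comparisons mirror the experimental analysis structure: linear
models (LM) for per-dish offspring totals, binomial GLMs (GLM-b) for
parasitism rates, binomial mixed models (GLMM-b) for offspring sex
ratios, and Poisson mixed models with an ``x-1`` response shift
(GLMM-p) or linear mixed models (LMM) for clutch sizes, with the dish
(founder) identity as a random intercept in all mixed models.  Each
factor's effect is assessed by a likelihood-ratio test of the model
with the factor against the nested model without it.

LM, GLM and the Gaussian LMM delegate to statsmodels; the binomial and
Poisson random-intercept likelihoods are maximized here directly, with
the random-effect integral evaluated by Gauss–Hermite quadrature (the
model contract is the marginal likelihood, not any particular fitting
package).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ComparisonResult",
    "fit_model",
    "lrt_compare",
    "run_paper_battery",
    "interval_95",
]

logger = logging.getLogger("flavipes")

RESPONSES = ("total_offspring", "parasitized", "sex", "clutch_size")
FAMILIES = ("gaussian", "binomial", "poisson")

# quadrature nodes for the random-intercept integral; 61 non-adaptive
# nodes reproduce a 101-node reference to <1e-5 log-likelihood units on
# cluster sizes typical here (a dozen eggs per dish)
_GH_NODES = 61


@dataclass(frozen=True)
class ModelSpec:
    """What to model: response, family, fixed factors, random intercept.

    ``transform="shift_minus_1"`` fits the Poisson model to
    ``clutch_size - 1`` (clutch sizes are >= 1 by definition, so the
    shifted response has proper Poisson support); fitted means are
    shifted back (+1) for reporting.
    """

    response: str
    family: str
    fixed: tuple[str, ...] = ()
    random_dish: bool = False
    transform: str | None = None

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.transform not in (None, "shift_minus_1"):
            raise ValueError("transform must be None or 'shift_minus_1'")
        if self.response == "clutch_size" and self.family == "poisson":
            if self.transform != "shift_minus_1":
                object.__setattr__(self, "transform", "shift_minus_1")
        object.__setattr__(self, "fixed", tuple(self.fixed))

    def dropping(self, factor: str) -> "ModelSpec":
        """The nested spec without ``factor`` (for LRT comparisons)."""
        if factor not in self.fixed:
            raise ValueError(f"{factor!r} not among fixed factors {self.fixed}")
        return ModelSpec(
            self.response,
            self.family,
            tuple(f for f in self.fixed if f != factor),
            self.random_dish,
            self.transform,
        )


@dataclass
class FittedModel:
    """A maximum-likelihood fit: log-likelihood, coefficients, diagnostics."""

    spec: ModelSpec
    llf: float
    params: pd.Series
    bse: pd.Series
    n_params: int
    n_obs: int
    converged: bool
    method: str
    sigma_dish: float | None = None
    notes: tuple[str, ...] = ()


@dataclass
class ComparisonResult:
    """Likelihood-ratio comparison of nested fits."""

    statistic: float
    df: int
    p_value: float
    estimates: pd.Series
    bse: pd.Series
    converged: bool
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# modeling frame construction
# ---------------------------------------------------------------------------

def build_frame(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Collapse the tidy per-host-egg table to the response's unit.

    parasitized  -> one row per offered host egg (y binary, trials 1)
    sex          -> one row per parasitized native clutch
                    (y = females, trials = clutch size)
    clutch_size  -> one row per parasitized native clutch
    total_offspring -> one row per founder (sum of native clutch sizes)
    """
    t = table
    if spec.response == "parasitized":
        out = t.assign(y=t["parasitized"].astype(int), trials=1)
    elif spec.response == "sex":
        sub = t[t["parasitized"] & (t["host_species"] == "native")]
        out = sub.assign(
            y=sub["n_females"].astype(int), trials=sub["clutch_size"].astype(int)
        )
    elif spec.response == "clutch_size":
        sub = t[t["parasitized"] & (t["host_species"] == "native")]
        y = sub["clutch_size"].astype(float)
        if spec.transform == "shift_minus_1":
            y = y - 1.0
        out = sub.assign(y=y, trials=1)
    elif spec.response == "total_offspring":
        native = t[t["host_species"] == "native"].copy()
        native["off"] = (
            pd.to_numeric(native["clutch_size"], errors="coerce").fillna(0.0)
            * native["parasitized"].astype(float)
        )
        # per-dish totals; in a within-dish design (choice test) the unit
        # becomes dish x factor level
        keys = ["founder_id"] + [f for f in spec.fixed if f in native.columns]
        agg = {"y": ("off", "sum")}
        for c in ("group",):
            if c not in keys and c in native.columns:
                agg[c] = (c, "first")
        out = native.groupby(keys, sort=False).agg(**agg).reset_index()
        out["trials"] = 1
    else:  # pragma: no cover
        raise AssertionError(spec.response)
    missing = [f for f in spec.fixed if f not in out.columns]
    if missing:
        raise ValueError(f"fixed factor columns missing from table: {missing}")
    return out.reset_index(drop=True)


def _design_matrix(frame: pd.DataFrame, fixed: tuple[str, ...]):
    """Treatment-coded design matrix with intercept; levels sorted."""
    X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    for f in fixed:
        levels = sorted(frame[f].astype(str).unique())
        for lev in levels[1:]:
            X[f"{f}[{lev}]"] = (frame[f].astype(str) == lev).astype(float)
    return X


# ---------------------------------------------------------------------------
# Gauss–Hermite random-intercept GLMM
# ---------------------------------------------------------------------------

def _group_index(groups: pd.Series) -> tuple[np.ndarray, int]:
    codes, _ = pd.factorize(groups, sort=False)
    return codes, int(codes.max()) + 1


def _glmm_loglik(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    trials: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    family: str,
    nodes: np.ndarray,
    log_wts: np.ndarray,
) -> float:
    """Marginal log-likelihood; params = (beta..., sigma)."""
    beta, sigma = params[:-1], params[-1]
    eta0 = X @ beta
    # (n_obs, K) linear predictor per quadrature node
    eta = eta0[:, None] + sigma * nodes[None, :]
    if family == "binomial":
        ll_obs = (
            y[:, None] * eta
            - trials[:, None] * np.logaddexp(0.0, eta)
        )
        const = np.sum(
            special.gammaln(trials + 1)
            - special.gammaln(y + 1)
            - special.gammaln(trials - y + 1)
        )
    elif family == "poisson":
        ll_obs = y[:, None] * eta - np.exp(eta)
        const = -np.sum(special.gammaln(y + 1))
    else:  # pragma: no cover
        raise AssertionError(family)
    # sum observations within each group, per node
    grp = np.zeros((n_groups, ll_obs.shape[1]))
    np.add.at(grp, codes, ll_obs)
    return float(np.sum(special.logsumexp(grp + log_wts[None, :], axis=1)) + const)


def _fit_glmm(
    X: pd.DataFrame,
    y: np.ndarray,
    trials: np.ndarray,
    groups: pd.Series,
    family: str,
    sigma_fixed: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float, bool, list[str]]:
    """ML fit of a random-intercept GLMM by Gauss–Hermite quadrature."""
    codes, n_groups = _group_index(groups)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
    nodes = np.sqrt(2.0) * gh_x
    log_wts = np.log(gh_w) - 0.5 * np.log(np.pi)
    Xv = X.to_numpy()
    notes: list[str] = []

    # start from the marginal GLM
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
    endog = np.column_stack([y, trials - y]) if family == "binomial" else y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.GLM(endog, Xv, family=fam).fit()
    beta0 = np.asarray(start.params)

    if sigma_fixed is not None:
        def nll(b):
            return -_glmm_loglik(
                np.append(b, sigma_fixed), Xv, y, trials, codes, n_groups,
                family, nodes, log_wts,
            )

        res = optimize.minimize(nll, beta0, method="BFGS",
                                options={"gtol": 1e-8})
        params = np.append(res.x, sigma_fixed)
        llf = -res.fun
        hess = approx_hess(res.x, nll)
        bse = _safe_bse(hess)
        return res.x, np.append(bse, np.nan), llf, sigma_fixed, bool(res.success), notes

    def nll(p):
        return -_glmm_loglik(p, Xv, y, trials, codes, n_groups, family, nodes, log_wts)

    p0 = np.append(beta0, 0.5)
    bounds = [(None, None)] * len(beta0) + [(0.0, None)]
    coarse = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
    res = optimize.minimize(nll, coarse.x, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-12, "gtol": 1e-9})
    if coarse.fun < res.fun:
        res = coarse
    # an abnormal line search at an already-converged point is benign
    if not res.success and coarse.success and abs(res.fun - coarse.fun) < 1e-6:
        res.success = True
    llf = -res.fun
    sigma = float(res.x[-1])
    if sigma < 1e-6:
        notes.append("random-intercept variance at boundary (~0)")
    hess = approx_hess(res.x, nll)
    bse = _safe_bse(hess)
    return res.x[:-1], bse, llf, sigma, bool(res.success), notes


def _safe_bse(hess: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.pinv(hess)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(hess.shape[0], np.nan)


# ---------------------------------------------------------------------------
# unified fitting front end
# ---------------------------------------------------------------------------

def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    sigma_fixed: float | None = None,
) -> FittedModel:
    """Maximum-likelihood fit of ``spec`` on a tidy table.

    Gaussian fixed-effect models use OLS, gaussian mixed models use a
    Gaussian random-intercept LMM (ML, not REML, so likelihood-ratio
    comparisons are valid), binomial/Poisson fixed-effect models use
    GLM, and binomial/Poisson mixed models use the quadrature GLMM.
    ``sigma_fixed`` pins the random-intercept standard deviation (0
    recovers the GLM fixed-effect estimates exactly).
    """
    frame = build_frame(table, spec)
    if frame.empty:
        raise ValueError(f"no observations for response {spec.response!r}")
    X = _design_matrix(frame, spec.fixed)
    y = frame["y"].to_numpy(dtype=float)
    trials = frame["trials"].to_numpy(dtype=float)
    notes: list[str] = []

    if spec.family == "gaussian" and not spec.random_dish:
        fit = sm.OLS(y, X.to_numpy()).fit()
        params = pd.Series(fit.params, index=X.columns)
        bse = pd.Series(fit.bse, index=X.columns)
        # +1 for the error variance, a fitted parameter of the likelihood
        return FittedModel(spec, float(fit.llf), params, bse, X.shape[1] + 1,
                           len(frame), True, "ols")

    if spec.family == "gaussian" and spec.random_dish:
        md = sm.MixedLM(y, X.to_numpy(), groups=frame["founder_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=False)
        params = pd.Series(np.asarray(fit.fe_params), index=X.columns)
        bse = pd.Series(np.asarray(fit.bse_fe), index=X.columns)
        conv = bool(getattr(fit, "converged", True))
        sigma = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
        # fixed effects + random-intercept variance + residual variance
        return FittedModel(spec, float(fit.llf), params, bse, X.shape[1] + 2,
                           len(frame), conv, "lmm", sigma_dish=sigma)

    if not spec.random_dish and sigma_fixed is None:
        fam = (
            sm.families.Binomial()
            if spec.family == "binomial"
            else sm.families.Poisson()
        )
        endog = (
            np.column_stack([y, trials - y]) if spec.family == "binomial" else y
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, X.to_numpy(), family=fam).fit()
        params = pd.Series(np.asarray(fit.params), index=X.columns)
        if np.any(np.abs(params.to_numpy()) > 10):
            notes.append("possible complete separation; estimates unstable")
        bse = pd.Series(np.asarray(fit.bse), index=X.columns)
        return FittedModel(spec, float(fit.llf), params, bse, X.shape[1],
                           len(frame), bool(fit.converged), "glm",
                           notes=tuple(notes))

    # binomial / Poisson random-intercept GLMM
    beta, bse_arr, llf, sigma, conv, glmm_notes = _fit_glmm(
        X, y, trials, frame["founder_id"], spec.family, sigma_fixed
    )
    notes.extend(glmm_notes)
    if not conv:
        notes.append("optimizer reported non-convergence")
        logger.warning("GLMM fit did not converge for %s", spec)
    params = pd.Series(beta, index=X.columns)
    bse = pd.Series(bse_arr[: X.shape[1]], index=X.columns)
    n_par = X.shape[1] + (0 if sigma_fixed is not None else 1)
    return FittedModel(spec, llf, params, bse, n_par, len(frame), conv,
                       f"glmm-gh{_GH_NODES}", sigma_dish=sigma,
                       notes=tuple(notes))


def lrt_compare(full: FittedModel, reduced: FittedModel) -> ComparisonResult:
    """Likelihood-ratio test of nested maximum-likelihood fits.

    statistic = 2(l_full − l_reduced), referred to a chi-square with
    df = difference in parameter counts.  Numerically negative
    statistics are clamped to 0 with a warning.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted on different numbers of observations")
    if reduced.n_params > full.n_params:
        raise ValueError("reduced model has more parameters than the full model")
    if set(reduced.params.index) - set(full.params.index):
        raise ValueError("reduced model is not nested in the full model")
    notes = list(full.notes) + list(reduced.notes)
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(
                f"negative LRT statistic ({stat:.3g}) clamped to 0; "
                "check convergence"
            )
            notes.append("negative LR clamped to 0")
        stat = 0.0
    df = full.n_params - reduced.n_params
    p = 1.0 if df == 0 and stat == 0.0 else float(stats.chi2.sf(stat, max(df, 1)))
    return ComparisonResult(
        statistic=float(stat),
        df=df,
        p_value=p,
        estimates=full.params,
        bse=full.bse,
        converged=full.converged and reduced.converged,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def interval_95(values, family: str) -> dict:
    """95% confidence interval for a single group outcome.

    gaussian: t-interval on the mean of ``values``; binomial: exact
    Clopper–Pearson for ``(successes, trials)`` or a 0/1 vector;
    poisson: exact chi-square interval for ``(total_count, exposure)``
    or a vector of counts (exposure = length).
    """
    if family == "gaussian":
        x = np.asarray(values, dtype=float)
        n = x.size
        if n == 0:
            raise ValueError("empty sample")
        mean = float(np.mean(x))
        if n == 1:
            return {"estimate": mean, "ci_95": (None, None),
                    "note": "width undefined for n=1"}
        se = float(np.std(x, ddof=1) / np.sqrt(n))
        t = stats.t.ppf(0.975, n - 1)
        return {"estimate": mean, "ci_95": (mean - t * se, mean + t * se)}
    if family == "binomial":
        if isinstance(values, tuple) and len(values) == 2:
            k, n = int(values[0]), int(values[1])
        else:
            x = np.asarray(values)
            k, n = int(x.sum()), int(x.size)
        if n == 0:
            raise ValueError("zero trials")
        lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
        return {"estimate": k / n, "ci_95": (lo, hi)}
    if family == "poisson":
        if isinstance(values, tuple) and len(values) == 2:
            k, n = int(values[0]), float(values[1])
        else:
            x = np.asarray(values)
            k, n = int(x.sum()), float(x.size)
        if n == 0:
            raise ValueError("zero exposure")
        lo = 0.0 if k == 0 else float(stats.chi2.ppf(0.025, 2 * k) / 2) / n
        hi = float(stats.chi2.ppf(0.975, 2 * k + 2) / 2) / n
        return {"estimate": k / n, "ci_95": (lo, hi)}
    raise ValueError(f"family must be one of {FAMILIES}")


# ---------------------------------------------------------------------------
# the full comparison battery
# ---------------------------------------------------------------------------

#: (contrast name, response, family, random_dish) per analysed variable
_RESPONSE_MODELS = [
    ("parasitism", "parasitized", "binomial", False),   # GLM-b
    ("sex_ratio", "sex", "binomial", True),             # GLMM-b
    ("clutch_size", "clutch_size", "poisson", True),    # GLMM-p, x-1 shift
    ("total_offspring", "total_offspring", "gaussian", False),  # LM
]


def _one_contrast(table: pd.DataFrame, factor: str, name: str) -> dict:
    """All four response models for one fixed factor, as LRT results."""
    out = {}
    for label, response, family, random_dish in _RESPONSE_MODELS:
        try:
            levels = table[factor].nunique()
            if levels < 2:
                out[label] = {"skipped": f"factor {factor!r} has {levels} level(s)"}
                continue
            spec = ModelSpec(response, family, (factor,), random_dish)
            full = fit_model(table, spec)
            reduced = fit_model(table, spec.dropping(factor))
            res = lrt_compare(full, reduced)
            out[label] = {
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "estimates": {k: float(v) for k, v in res.estimates.items()},
                "converged": res.converged,
                "notes": list(res.notes),
            }
        except ValueError as exc:
            out[label] = {"skipped": str(exc)}
            logger.info("contrast %s/%s skipped: %s", name, label, exc)
    return out


def run_paper_battery(tables: dict[str, pd.DataFrame]) -> dict:
    """Run the full grid of experiment contrasts.

    ``tables`` maps experiment names to tidy per-host-egg tables:
    ``no_choice`` (three substrate groups pooled), ``choice``,
    ``fict_host`` (mixed / low-density / high-density groups pooled).
    Any subset may be supplied; missing experiments are skipped with an
    explicit notice.  Each cell is a likelihood-ratio comparison of the
    model with the factor against the nested model without it.
    """
    report: dict = {"alpha": 0.05, "contrasts": {}}

    nc = tables.get("no_choice")
    if nc is not None and not nc.empty:
        report["contrasts"]["no_choice_substrate"] = _one_contrast(
            nc, "substrate", "no_choice_substrate"
        )
        # pairwise substrate contrasts
        subs = sorted(nc["substrate"].unique())
        for i, a in enumerate(subs):
            for b in subs[i + 1:]:
                pair = nc[nc["substrate"].isin([a, b])]
                report["contrasts"][f"no_choice_{a}_vs_{b}"] = _one_contrast(
                    pair, "substrate", f"no_choice_{a}_vs_{b}"
                )
    else:
        report["contrasts"]["no_choice_substrate"] = {
            "skipped": "no_choice table not supplied"
        }

    ch = tables.get("choice")
    if ch is not None and not ch.empty:
        report["contrasts"]["choice_substrate"] = _one_contrast(
            ch, "substrate", "choice_substrate"
        )
    else:
        report["contrasts"]["choice_substrate"] = {
            "skipped": "choice table not supplied"
        }

    if nc is not None and ch is not None and not nc.empty and not ch.empty:
        pooled = pd.concat(
            [nc.assign(test_type="no_choice"), ch.assign(test_type="choice")],
            ignore_index=True,
        )
        report["contrasts"]["choice_vs_no_choice"] = _one_contrast(
            pooled, "test_type", "choice_vs_no_choice"
        )
    else:
        report["contrasts"]["choice_vs_no_choice"] = {
            "skipped": "needs both choice and no_choice tables"
        }

    fh = tables.get("fict_host")
    if fh is not None and not fh.empty:
        groups = sorted(fh["group"].unique())
        if len(groups) >= 2:
            for i, a in enumerate(groups):
                for b in groups[i + 1:]:
                    pair = fh[fh["group"].isin([a, b])]
                    # native hosts only: fictitious eggs never emerge, so
                    # including them would confound every response
                    report["contrasts"][f"fict_host_{a}_vs_{b}"] = _one_contrast(
                        pair[pair["host_species"] == "native"],
                        "group",
                        f"fict_host_{a}_vs_{b}",
                    )
        else:
            report["contrasts"]["fict_host"] = {
                "skipped": f"needs >= 2 groups, found {groups}"
            }
    else:
        report["contrasts"]["fict_host"] = {"skipped": "fict_host table not supplied"}

    return report
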