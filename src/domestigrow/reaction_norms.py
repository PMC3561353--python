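"""Growth reaction norms: REML mixed models, AIC selection, F-tests.

The response is log10 body weight at termination.  Fixed effects are
treatment (control/stress), experimental group ("type": farm/hybrid/wild) and
their interaction; a significant interaction means the groups differ in
phenotypic plasticity, i.e. in the slope of their growth reaction norm.

Family enters as a random effect, in one of four structures:

- ``none``          ordinary least squares;
- ``intercept``     one random elevation per family;
- ``treatment_2x2`` a bivariate (control deviation, stress deviation) random
                    effect per family with an unstructured 2x2 covariance
                    shared across groups — family-by-treatment heterogeneity;
- ``group_6x6``     the same bivariate effect with a separate 2x2 covariance
                    per group (block-diagonal 6x6 across the three groups).

A scalar random tank effect (tanks nested in treatments) can be added to any
structure.  Residual variance is homogeneous; treatment heterogeneity is
carried by the family covariance.

Estimation is REML via the penalized-least-squares profile of the deviance
over the relative Cholesky factor of the family covariance (the same profiling
used by modern mixed-model software), optimized numerically with multiple
starts; the profiled deviance is exact, not approximate, so on balanced
designs the components agree with closed-form ANOVA estimators to numerical
precision.

F statistics use type-II sums of squares from generalized-least-squares
residual sums at the estimated covariance, and the study's own denominator
degree-of-freedom convention: df2 = N - k with N the smallest
group-by-treatment sample size and k the tested factor's level count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .design import GROUPS
from .stats import bonferroni_alpha

TWO_PI = 2.0 * np.pi

RANDOM_STRUCTURES = ("none", "intercept", "treatment_2x2", "group_6x6")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MixedModelSpec:
    """Which fixed terms, family random structure and tank effect to fit."""

    fixed: tuple[str, ...] = ("treatment", "type", "treatment:type")
    random: str = "treatment_2x2"
    tank: bool = False

    def __post_init__(self) -> None:
        allowed = {"treatment", "type", "treatment:type"}
        if not set(self.fixed) <= allowed:
            raise ValueError(f"unknown fixed terms {set(self.fixed) - allowed}")
        if "treatment:type" in self.fixed and not {"treatment", "type"} <= set(self.fixed):
            raise ValueError("interaction requires both main effects")
        if self.random not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown random structure {self.random!r}")

    @property
    def name(self) -> str:
        tank = "+tank" if self.tank else ""
        return f"[{'+'.join(self.fixed) or '1'}|{self.random}{tank}]"


@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    n_obs: int
    fixed_effects: pd.Series
    family_covariance: dict[str, np.ndarray]
    sigma2: float
    theta: np.ndarray
    reml_loglik: float
    aic: float
    n_params: int
    anova: pd.DataFrame
    n_min: int
    converged: bool = True
    boundary: bool = False
    selected: bool = False

    @property
    def tank_variance(self) -> float | None:
        return self.family_covariance.get("tank", None)


@dataclass(frozen=True)
class ReactionNorm:
    family_id: str
    group: str
    control: float  # mean log10 weight, replicate tanks pooled
    stress: float
    slope: float


# ---------------------------------------------------------------------------
# model matrices


def _design_matrices(df: pd.DataFrame, spec: MixedModelSpec):
    """Return y, X (with column names), Z blocks and theta layout."""
    y = np.log10(df["weight_g"].to_numpy(dtype=float))
    treat = (df["treatment"].to_numpy() == "stress").astype(float)
    groups_present = [g for g in GROUPS if g in set(df["group"])]
    ref = groups_present[0]

    cols = {"(Intercept)": np.ones(len(df))}
    if "treatment" in spec.fixed:
        cols["treatment[stress]"] = treat
    if "type" in spec.fixed:
        for g in groups_present[1:]:
            cols[f"type[{g}]"] = (df["group"].to_numpy() == g).astype(float)
    if "treatment:type" in spec.fixed:
        for g in groups_present[1:]:
            cols[f"treatment[stress]:type[{g}]"] = treat * (
                df["group"].to_numpy() == g
            ).astype(float)
    X = np.column_stack(list(cols.values()))

    families = list(dict.fromkeys(df["family"]))
    fam_group = dict(zip(df["family"], df["group"]))
    z_cols: list[np.ndarray] = []
    blocks: list[tuple[int, int, str]] = []  # (col offset, width, group label)
    if spec.random == "intercept":
        for f in families:
            blocks.append((len(z_cols), 1, fam_group[f]))
            z_cols.append((df["family"].to_numpy() == f).astype(float))
    elif spec.random in ("treatment_2x2", "group_6x6"):
        for f in families:
            ind = (df["family"].to_numpy() == f).astype(float)
            blocks.append((len(z_cols), 2, fam_group[f]))
            z_cols.append(ind)
            z_cols.append(ind * treat)
    tank_cols: list[np.ndarray] = []
    if spec.tank:
        for t in dict.fromkeys(df["tank"]):
            tank_cols.append((df["tank"].to_numpy() == t).astype(float))
    Z = np.column_stack(z_cols + tank_cols) if (z_cols or tank_cols) else np.empty((len(df), 0))
    return y, X, list(cols.keys()), Z, blocks, len(tank_cols), groups_present, ref


def _theta_template(spec: MixedModelSpec, groups_present: list[str]):
    """Number of covariance parameters and a map from theta to Lambda blocks."""
    if spec.random == "none":
        n_fam = 0
    elif spec.random == "intercept":
        n_fam = 1
    elif spec.random == "treatment_2x2":
        n_fam = 3
    else:  # group_6x6: one 2x2 factor per group present
        n_fam = 3 * len(groups_present)
    return n_fam + (1 if spec.tank else 0)


def _lambda_matrix(theta: np.ndarray, spec: MixedModelSpec,
                   blocks, n_tank: int, groups_present: list[str], q: int) -> np.ndarray:
    lam = np.zeros((q, q))
    if spec.random == "intercept":
        for off, _w, _g in blocks:
            lam[off, off] = theta[0]
        used = 1
    elif spec.random == "treatment_2x2":
        t0, t1, t2 = theta[0], theta[1], theta[2]
        for off, _w, _g in blocks:
            lam[off, off] = t0
            lam[off + 1, off] = t1
            lam[off + 1, off + 1] = t2
        used = 3
    elif spec.random == "group_6x6":
        idx = {g: i for i, g in enumerate(groups_present)}
        for off, _w, g in blocks:
            t0, t1, t2 = theta[3 * idx[g]: 3 * idx[g] + 3]
            lam[off, off] = t0
            lam[off + 1, off] = t1
            lam[off + 1, off + 1] = t2
        used = 3 * len(groups_present)
    else:
        used = 0
    if n_tank:
        for j in range(q - n_tank, q):
            lam[j, j] = theta[used]
    return lam


class _CrossProducts:
    """Sufficient statistics of the penalized least-squares problem.

    All REML evaluations during optimization work on these q- and
    p-dimensional crossproducts, never on the n-sized data again.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)


def _profiled_deviance(theta, cross: _CrossProducts, spec, blocks, n_tank,
                       groups_present, want_fit: bool = False):
    """-2 REML log-likelihood profiled over beta and sigma^2."""
    n, p, q = cross.n, cross.p, cross.q
    if q:
        lam = _lambda_matrix(np.asarray(theta, float), spec, blocks, n_tank,
                             groups_present, q)
        A11 = lam.T @ cross.ZtZ @ lam + np.eye(q)
        L = cholesky(A11, lower=True, check_finite=False)
        RZX = solve_triangular(L, lam.T @ cross.ZtX, lower=True, check_finite=False)
        cu = solve_triangular(L, lam.T @ cross.Zty, lower=True, check_finite=False)
        XtWX = cross.XtX - RZX.T @ RZX
        logdet_a = 2.0 * np.sum(np.log(np.diag(L)))
    else:
        cu = np.zeros(0)
        XtWX = cross.XtX
        RZX = np.zeros((0, p))
        logdet_a = 0.0
    LX = cholesky(XtWX + 1e-12 * np.eye(p), lower=True, check_finite=False)
    cx = solve_triangular(LX, cross.Xty - RZX.T @ cu, lower=True, check_finite=False)
    r2 = max(cross.yty - cu @ cu - cx @ cx, 1e-300)
    logdet_rx = 2.0 * np.sum(np.log(np.diag(LX)))
    dev = logdet_a + logdet_rx + (n - p) * (1.0 + np.log(TWO_PI * r2 / (n - p)))
    if not want_fit:
        return dev
    beta = solve_triangular(LX.T, cx, lower=False, check_finite=False)
    sigma2 = r2 / (n - p)
    return dev, beta, sigma2


def _gls_rss(theta, cross: _CrossProducts, spec, blocks, n_tank, groups_present) -> float:
    """min_beta (y - X beta)' (I + U U')^{-1} (y - X beta) at fixed theta."""
    q = cross.q
    if q:
        lam = _lambda_matrix(np.asarray(theta, float), spec, blocks, n_tank,
                             groups_present, q)
        A11 = lam.T @ cross.ZtZ @ lam + np.eye(q)
        L = cholesky(A11, lower=True, check_finite=False)
        cu = solve_triangular(L, lam.T @ cross.Zty, lower=True, check_finite=False)
        RZX = solve_triangular(L, lam.T @ cross.ZtX, lower=True, check_finite=False)
        XtWX = cross.XtX - RZX.T @ RZX
        rhs = cross.Xty - RZX.T @ cu
        base = cross.yty - cu @ cu
    else:
        XtWX = cross.XtX
        rhs = cross.Xty
        base = cross.yty
    if cross.p == 0:
        return float(base)
    c, low = cho_factor(XtWX + 1e-12 * np.eye(cross.p), lower=True)
    beta = cho_solve((c, low), rhs)
    return float(base - rhs @ beta)


def _optimize_theta(cross, spec, blocks, n_tank, groups_present, n_theta):
    obj = lambda th: _profiled_deviance(th, cross, spec, blocks, n_tank, groups_present)
    if n_theta == 0:
        return np.zeros(0), obj(np.zeros(0))
    # bounds: diagonal entries >= 0 (variances), off-diagonals free
    diag_mask = np.zeros(n_theta, bool)
    if spec.random == "intercept":
        diag_mask[0] = True
        n_fam = 1
    elif spec.random == "treatment_2x2":
        diag_mask[[0, 2]] = True
        n_fam = 3
    elif spec.random == "group_6x6":
        for i in range(len(groups_present)):
            diag_mask[[3 * i, 3 * i + 2]] = True
        n_fam = 3 * len(groups_present)
    else:
        n_fam = 0
    if spec.tank:
        diag_mask[n_fam] = True
    bounds = [(0.0, 50.0) if d else (-50.0, 50.0) for d in diag_mask]

    starts = []
    for scale in (0.5, 2.0, 0.05):
        th = np.zeros(n_theta)
        th[diag_mask] = scale
        starts.append(th)
    best = None
    for th0 in starts:
        try:
            res = optimize.minimize(obj, th0, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})
        except np.linalg.LinAlgError:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError("REML optimizer failed from every start")
    # Nelder-Mead polish for tight tolerance on the profiled deviance; the
    # single-parameter path is polished hardest (closed-form comparisons)
    polish = optimize.minimize(
        obj, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10 if n_theta == 1 else 1e-8,
                 "fatol": 1e-13,
                 "maxiter": 2000 if n_theta == 1 else 300 * n_theta},
    )
    theta = polish.x if polish.fun <= best.fun else best.x
    theta = np.asarray(theta, float)
    theta[diag_mask] = np.abs(theta[diag_mask])  # sign of diagonal is not identified
    return theta, min(polish.fun, best.fun)


def smallest_cell_size(phenotypes: pd.DataFrame) -> int:
    """Smallest sample size over the group-by-treatment cells."""
    return int(phenotypes.groupby(["group", "treatment"]).size().min())


def ftest_denominator_df(n_min: int, k: int) -> int:
    """The study's denominator-df rule: N - k, N = smallest cell sample size."""
    if k < 2:
        raise ValueError("a tested factor needs at least 2 levels")
    if n_min <= k:
        raise ValueError(f"smallest sample size {n_min} must exceed k={k}")
    return n_min - k


def _anova_type2(theta, y, df, spec, Z, blocks, n_tank, groups_present,
                 sigma2, n_min) -> pd.DataFrame:
    """Type-II F table with the N-k denominator-df convention."""
    present = [t for t in ("treatment", "type", "treatment:type") if t in spec.fixed]

    def rss_for(terms: set[str]) -> float:
        sub = replace(spec, fixed=tuple(t for t in present if t in terms))
        _y, Xr, _c, _z, _b, _nt, _gp, _ref = _design_matrices(df, sub)
        cross = _CrossProducts(y, Xr, Z)
        return _gls_rss(theta, cross, spec, blocks, n_tank, groups_present)

    n_groups = len(groups_present)
    df1_of = {"treatment": 1, "type": n_groups - 1, "treatment:type": n_groups - 1}
    rows = []
    for term in present:
        if term == "treatment":
            reduced = {"type"} & set(present)
        elif term == "type":
            reduced = {"treatment"} & set(present)
        else:
            reduced = {"treatment", "type"}
        ss = rss_for(reduced) - rss_for(reduced | {term})
        ss = max(ss, 0.0)
        df1 = df1_of[term]
        k = df1 + 1
        df2 = ftest_denominator_df(n_min, k)
        fval = (ss / df1) / sigma2
        rows.append(
            {"term": term, "sum_sq": ss, "df1": df1, "df2": df2,
             "F": fval, "p": float(sps.f.sf(fval, df1, df2))}
        )
    return pd.DataFrame(rows)


def fit_growth_model(
    phenotypes: pd.DataFrame,
    spec: MixedModelSpec | None = None,
    n_min: int | None = None,
) -> MixedModelFit:
    """REML fit of the growth mixed model for log10 weight.

    ``n_min`` overrides the smallest group-by-treatment cell size used by the
    denominator-df rule (the study fixes it from the full data set even for
    two-group re-fits).
    """
    spec = spec or MixedModelSpec()
    df = phenotypes.reset_index(drop=True)
    if "type" in spec.fixed and df.groupby("group")["family"].nunique().min() < 2:
        raise ValueError("need >= 2 families per group")
    if "treatment" in spec.fixed and df["treatment"].nunique() < 2:
        raise ValueError("both treatments must be present")
    y, X, col_names, Z, blocks, n_tank, groups_present, _ref = _design_matrices(df, spec)
    n_theta = _theta_template(spec, groups_present)
    cross = _CrossProducts(y, X, Z)
    theta, dev = _optimize_theta(cross, spec, blocks, n_tank, groups_present, n_theta)
    _dev, beta, sigma2 = _profiled_deviance(
        theta, cross, spec, blocks, n_tank, groups_present, want_fit=True
    )
    reml_loglik = -0.5 * dev
    n_params = X.shape[1] + n_theta + 1  # fixed + covariance + residual
    aic = -2.0 * reml_loglik + 2.0 * n_params

    family_cov: dict[str, np.ndarray] = {}
    boundary = False
    if spec.random == "intercept":
        family_cov["shared"] = np.array([[sigma2 * theta[0] ** 2]])
        boundary |= theta[0] < 1e-5
    elif spec.random == "treatment_2x2":
        lam = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
        family_cov["shared"] = sigma2 * lam @ lam.T
        boundary |= min(theta[0], theta[2]) < 1e-5
    elif spec.random == "group_6x6":
        for i, g in enumerate(groups_present):
            t0, t1, t2 = theta[3 * i: 3 * i + 3]
            lam = np.array([[t0, 0.0], [t1, t2]])
            family_cov[g] = sigma2 * lam @ lam.T
            boundary |= min(t0, t2) < 1e-5
    if spec.tank:
        family_cov["tank"] = sigma2 * theta[-1] ** 2

    cell_min = n_min if n_min is not None else smallest_cell_size(df)
    anova = _anova_type2(theta, y, df, spec, Z, blocks, n_tank,
                         groups_present, sigma2, cell_min)
    return MixedModelFit(
        spec=spec, n_obs=len(df),
        fixed_effects=pd.Series(beta, index=col_names),
        family_covariance=family_cov, sigma2=float(sigma2), theta=theta,
        reml_loglik=float(reml_loglik), aic=float(aic), n_params=n_params,
        anova=anova, n_min=cell_min, boundary=bool(boundary),
    )


def default_candidate_specs() -> list[MixedModelSpec]:
    """The simplification ladder from the saturated model downwards."""
    full = ("treatment", "type", "treatment:type")
    return [
        MixedModelSpec(full, "group_6x6", tank=True),
        MixedModelSpec(full, "group_6x6", tank=False),
        MixedModelSpec(full, "treatment_2x2", tank=True),
        MixedModelSpec(full, "treatment_2x2", tank=False),
        MixedModelSpec(("treatment", "type"), "treatment_2x2", tank=False),
        MixedModelSpec(full, "intercept", tank=False),
    ]


def select_model_aic(
    phenotypes: pd.DataFrame,
    specs: list[MixedModelSpec] | None = None,
    n_min: int | None = None,
) -> list[MixedModelFit]:
    """Fit candidates and rank ascending by REML AIC (ties: fewer parameters)."""
    specs = specs if specs is not None else default_candidate_specs()
    if len(specs) < 2:
        raise ValueError("model selection needs at least two candidates")
    fits = []
    for spec in specs:
        try:
            fits.append(fit_growth_model(phenotypes, spec, n_min=n_min))
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {spec.name} excluded: {exc}")
    if not fits:
        raise ConvergenceError("no candidate model converged")
    fits.sort(key=lambda f: (f.aic, f.n_params))
    fits[0].selected = True
    return fits


@dataclass
class PairwiseGroupTests:
    fits: dict[tuple[str, str], MixedModelFit]
    interaction_p: dict[tuple[str, str], float]
    alpha: float
    adjusted_alpha: float


def pairwise_group_tests(
    phenotypes: pd.DataFrame,
    spec: MixedModelSpec | None = None,
    alpha: float = 0.05,
    m: int = 3,
) -> PairwiseGroupTests:
    """Re-fit the final model for each pair of groups, Bonferroni-adjusted.

    The denominator df reuses the smallest group-by-treatment cell size of the
    *full* data set for every pair, matching the study's single N convention.
    """
    groups = sorted(set(phenotypes["group"]))
    if len(groups) != 3:
        raise ValueError(f"expected exactly 3 groups, found {groups}")
    spec = spec or MixedModelSpec()
    n_min = smallest_cell_size(phenotypes)
    fits, pvals = {}, {}
    for dropped in groups:
        pair = tuple(g for g in GROUPS if g in groups and g != dropped)
        sub = phenotypes[phenotypes["group"] != dropped]
        fit = fit_growth_model(sub, spec, n_min=n_min)
        fits[pair] = fit
        inter = fit.anova[fit.anova["term"] == "treatment:type"]
        pvals[pair] = float(inter["p"].iloc[0]) if len(inter) else np.nan
    return PairwiseGroupTests(fits, pvals, alpha, bonferroni_alpha(alpha, m))


def family_reaction_norms(phenotypes: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    """Per-family mean log10 weight per treatment (tanks pooled) and slope."""
    df = phenotypes.copy()
    df["log_w"] = np.log10(df["weight_g"])
    means = df.groupby(["family", "group", "treatment"])["log_w"].mean().unstack()
    rows = []
    for (family, group), r in means.iterrows():
        if r.isna().any():
            if warn:
                warnings.warn(f"family {family}: missing a treatment, excluded")
            continue
        rows.append(
            {"family": family, "group": group, "control": r["control"],
             "stress": r["stress"], "slope": r["stress"] - r["control"]}
        )
    return pd.DataFrame(rows)


def group_reaction_norms(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Group-level reaction norms (mean log10 weight per treatment, slope)."""
    df = phenotypes.copy()
    df["log_w"] = np.log10(df["weight_g"])
    means = df.groupby(["group", "treatment"])["log_w"].mean().unstack()
    out = means.rename(columns=str).reset_index()
    out["slope"] = out["stress"] - out["control"]
    return out
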