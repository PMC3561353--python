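"""Pedigree animal model: Bayesian variance components and heritability.

The animal model treats each individual's breeding value a_i as a random
effect with covariance V_A * A, A being the pedigree-derived additive
relationship matrix.  For log10 body weight y of phenotyped fish,

    y = mu (+ tank) + a + e,   a ~ N(0, V_A A),  e ~ N(0, V_E I),

and narrow-sense heritability is h2 = V_A / V_P with V_P = V_A + V_E
(+ V_tank when a tank effect is fitted).

Estimation is by Gibbs sampling.  All breeding values are updated jointly
from their Gaussian full conditional, exploiting the sparse structure of
A^-1: individuals that are nobody's parent interact with each other only
through their parents, so the precision matrix has a large diagonal block
that is eliminated analytically, leaving a dense Cholesky only on the small
parental block.  Variance components are drawn from scaled-inverse-chi-squared
full conditionals seeded by a weakly informative prior that partitions an
estimate of V_P between the genetic and residual components with a low degree
of belief.  Because the whole breeding-value vector moves in one block, chains
mix far faster than single-site samplers and desk-scale runs (20,000
iterations) give stable posterior summaries; settings can be raised to
production scale (millions of iterations) through :class:`MCMCSettings`.

Model comparison uses DIC (mean deviance plus effective parameter count
p_D, with the deviance conditional on the random effects), and convergence is
checked through lag-k autocorrelations of the thinned chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cholesky, solve_triangular

from .design import GROUPS, TREATMENTS
from .pedigree import Pedigree, build_a_inverse, mendelian_sampling_variances

LOG_2PI = np.log(2.0 * np.pi)


class AnimalModelError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative variance prior.

    ``v_p`` is an estimate of the phenotypic variance (taken from the data
    when None); ``partition`` is the fraction assigned to the genetic
    component, the rest to the residual; ``belief`` is the prior degrees of
    freedom (low = weakly informative).  A fitted tank effect receives a small
    fraction ``tank_fraction`` of V_P as its prior scale.
    """

    v_p: float | None = None
    partition: float = 0.5
    belief: float = 0.002
    tank_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.partition < 1.0:
            raise AnimalModelError("partition must lie in (0, 1)")
        if self.belief <= 0:
            raise AnimalModelError("belief must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise AnimalModelError("iterations must exceed burn_in")
        if self.thin < 1:
            raise AnimalModelError("thin must be >= 1")


@dataclass
class VarianceComponentPosterior:
    samples: pd.DataFrame  # columns v_a, v_e (v_tank), h2, deviance
    h2_mean: float
    h2_mode: float
    h2_hpd: tuple[float, float]
    v_a_mean: float
    v_e_mean: float
    v_tank_mean: float | None
    dic: float
    p_d: float
    autocorr_lag1: float
    settings: MCMCSettings = field(repr=False, default=None)
    prior: PriorSpec = field(repr=False, default=None)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ``mass`` of them."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("hpd_interval needs at least one sample")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    m = max(int(np.ceil(mass * n)), 1)
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def autocorrelation(samples, lag: int) -> float:
    """Lag-k Pearson autocorrelation of a chain."""
    x = np.asarray(samples, dtype=float)
    if lag >= x.size:
        raise ValueError("lag must be smaller than the chain length")
    if np.ptp(x) == 0:
        raise ValueError("autocorrelation undefined for a constant chain")
    if lag == 0:
        return 1.0
    a, b = x[:-lag], x[lag:]
    denom = a.std() * b.std()
    if denom == 0:
        raise ValueError("autocorrelation undefined: constant segment")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / denom)


def dic_components(deviance_samples, deviance_at_mean: float) -> tuple[float, float]:
    """(DIC, p_D): DIC = mean deviance + p_D, p_D = mean deviance - D(posterior mean)."""
    mean_dev = float(np.mean(deviance_samples))
    p_d = mean_dev - float(deviance_at_mean)
    return mean_dev + p_d, p_d


def _scaled_inv_chi2(rng, nu: float, s2: float, ss: float, df: float) -> float:
    return (nu * s2 + ss) / rng.chisquare(nu + df)


def fit_animal_model(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    prior: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    include_tank: bool = False,
) -> VarianceComponentPosterior:
    """Gibbs-sampled variance components and heritability for one data set.

    ``phenotypes`` is normally the subset for one group-by-treatment cell
    (the study fits one model per cell); ``pedigree`` may be the full pedigree
    — it is restricted to the phenotyped fish and their ancestors.
    """
    mcmc = mcmc or MCMCSettings()
    df = phenotypes.reset_index(drop=True)
    ped = pedigree.subset_with_ancestors(df["id"])
    ids = ped.ids
    pos = {ind: i for i, ind in enumerate(ids)}
    missing = set(df["id"]) - set(ids)
    if missing:
        raise AnimalModelError(f"phenotyped individuals missing from pedigree: {sorted(missing)[:5]}")
    y = np.log10(df["weight_g"].to_numpy(dtype=float))
    if np.ptp(y) == 0:
        raise AnimalModelError("response has zero variance")
    n = y.size
    rec_idx = np.array([pos[i] for i in df["id"]], dtype=np.int64)

    prior = prior or PriorSpec()
    v_p = prior.v_p if prior.v_p is not None else float(np.var(y, ddof=1))
    s2_a = prior.partition * v_p
    s2_e = (1.0 - prior.partition) * v_p
    s2_t = prior.tank_fraction * v_p
    nu = prior.belief

    # --- precompute pedigree structure --------------------------------------
    sire, dam = ped.parent_indices()
    n_ped = len(ids)
    two_gen = all(
        (sire[i] < 0 or (sire[sire[i]] < 0 and dam[sire[i]] < 0))
        and (dam[i] < 0 or (sire[dam[i]] < 0 and dam[dam[i]] < 0))
        for i in range(n_ped)
    )
    a_inv = build_a_inverse(ped, assume_noninbred=two_gen).tocsr()
    d_msv = mendelian_sampling_variances(ped) if not two_gen else np.where(
        (sire >= 0) & (dam >= 0), 0.5, np.where((sire >= 0) | (dam >= 0), 0.75, 1.0)
    )
    is_parent = np.zeros(n_ped, dtype=bool)
    is_parent[sire[sire >= 0]] = True
    is_parent[dam[dam >= 0]] = True
    leaves = np.flatnonzero(~is_parent)
    internal = np.flatnonzero(is_parent)
    perm = np.concatenate([leaves, internal])
    inv_perm = np.empty(n_ped, dtype=np.int64)
    inv_perm[perm] = np.arange(n_ped)
    n_leaf = leaves.size

    a_perm = a_inv[perm][:, perm].tocsr()
    a_ll_diag = a_perm.diagonal()[:n_leaf]
    E = a_perm[:n_leaf, n_leaf:].tocoo()  # leaf x internal couplings
    B = a_perm[n_leaf:, n_leaf:].toarray()
    n_int = n_ped - n_leaf
    e_rows = E.row.astype(np.int64)
    e_cols = E.col.astype(np.int64)
    e_vals = E.data.copy()
    # row-wise entry pairs of E for the Schur product E' D^-1 E via bincount
    pair_i, pair_flat, pair_val = [], [], []
    by_row: dict[int, list[int]] = {}
    for k, r_ in enumerate(e_rows):
        by_row.setdefault(int(r_), []).append(k)
    for r_, ks in by_row.items():
        for ka in ks:
            for kb in ks:
                pair_i.append(r_)
                pair_flat.append(e_cols[ka] * n_int + e_cols[kb])
                pair_val.append(e_vals[ka] * e_vals[kb])
    pair_i = np.asarray(pair_i, dtype=np.int64)
    pair_flat = np.asarray(pair_flat, dtype=np.int64)
    pair_val = np.asarray(pair_val, dtype=float)

    n_rec = np.bincount(rec_idx, minlength=n_ped).astype(float)
    n_rec_perm = n_rec[perm]
    nrec_L, nrec_B = n_rec_perm[:n_leaf], n_rec_perm[n_leaf:]
    rec_perm_idx = inv_perm[rec_idx]  # record -> permuted pedigree position

    if include_tank:
        tanks = list(dict.fromkeys(df["tank"]))
        tank_idx = np.array([tanks.index(t) for t in df["tank"]], dtype=np.int64)
        n_tanks = len(tanks)
        tank_counts = np.bincount(tank_idx, minlength=n_tanks).astype(float)
    else:
        n_tanks = 0

    # Mendelian-deviation bookkeeping for a' A^-1 a
    s_idx = np.where(sire >= 0, sire, 0)
    d_idx = np.where(dam >= 0, dam, 0)
    s_w = (sire >= 0) * 0.5
    d_w = (dam >= 0) * 0.5

    rng = np.random.default_rng(mcmc.seed)
    mu = float(np.mean(y))
    a = np.zeros(n_ped)  # natural (unpermuted) order
    tank_eff = np.zeros(max(n_tanks, 1))
    v_a = s2_a if s2_a > 0 else 0.1 * np.var(y, ddof=1)
    v_e = s2_e if s2_e > 0 else 0.9 * np.var(y, ddof=1)
    v_t = s2_t if include_tank else 0.0

    keep = []
    a_sum = np.zeros(n_ped)
    n_keep = 0
    for it in range(mcmc.iterations):
        alpha = 1.0 / v_a
        inv_ve = 1.0 / v_e
        resid_no_a = y - mu - (tank_eff[tank_idx] if include_tank else 0.0)

        # --- breeding values: joint draw from N(C^-1 r, C^-1) ---------------
        r = np.bincount(rec_idx, weights=resid_no_a * inv_ve, minlength=n_ped)
        r_perm = r[perm]
        d_diag = nrec_L * inv_ve + alpha * a_ll_diag
        sq_d = np.sqrt(d_diag)
        # Ew = D^{-1/2} * alpha * E, held as (rows, cols, vals)
        ew_vals = (alpha / sq_d[e_rows]) * e_vals
        m_flat = np.bincount(
            pair_flat,
            weights=pair_val * (alpha * alpha / d_diag)[pair_i],
            minlength=n_int * n_int,
        )
        S = np.diag(nrec_B * inv_ve) + alpha * B - m_flat.reshape(n_int, n_int)
        Ls = cholesky(S, lower=True, check_finite=False)
        v1 = r_perm[:n_leaf] / sq_d
        ew_t_v1 = np.bincount(e_cols, weights=ew_vals * v1[e_rows], minlength=n_int)
        v2 = solve_triangular(Ls, r_perm[n_leaf:] - ew_t_v1, lower=True,
                              check_finite=False)
        z = rng.standard_normal(n_ped)
        xb = solve_triangular(Ls.T, v2 + z[n_leaf:], lower=False, check_finite=False)
        ew_xb = np.bincount(e_rows, weights=ew_vals * xb[e_cols], minlength=n_leaf)
        xl = (v1 + z[:n_leaf] - ew_xb) / sq_d
        a_perm_draw = np.concatenate([xl, xb])
        a = a_perm_draw[inv_perm]

        # --- location effects ----------------------------------------------
        a_rec = a[rec_idx]
        resid_mu = y - a_rec - (tank_eff[tank_idx] if include_tank else 0.0)
        mu = rng.normal(np.mean(resid_mu), np.sqrt(v_e / n))
        if include_tank:
            resid_t = y - mu - a_rec
            sums = np.bincount(tank_idx, weights=resid_t, minlength=n_tanks)
            prec = tank_counts * inv_ve + 1.0 / v_t
            mean_t = (sums * inv_ve) / prec
            tank_eff = rng.normal(mean_t, np.sqrt(1.0 / prec))

        # --- variance components --------------------------------------------
        m = a - s_w * a[s_idx] - d_w * a[d_idx]
        ss_a = float(np.sum(m * m / d_msv))
        v_a = _scaled_inv_chi2(rng, nu, s2_a, ss_a, n_ped)

        # Interweaved non-centered rescaling of (v_a, a).  With one record per
        # individual the centered Gibbs moves can trap the chain on the
        # v_e -> 0 ridge (breeding values absorbing the residual); treating
        # sqrt(v_a) as a regression coefficient on the whitened breeding
        # values, with a Metropolis correction for the prior, restores mixing.
        s_old = np.sqrt(v_a)
        a_norm = a / s_old
        za = a_norm[rec_idx]
        resid_s = y - mu - (tank_eff[tank_idx] if include_tank else 0.0)
        denom = float(za @ za)
        if denom > 0:
            s_hat = float(za @ resid_s) / denom
            s_new = rng.normal(s_hat, np.sqrt(v_e / denom))
            if s_new != 0.0:
                va_new = s_new * s_new

                def _log_prior_s(v, s_abs):
                    return -(nu / 2 + 1) * np.log(v) - nu * s2_a / (2 * v) + np.log(
                        2 * s_abs
                    )

                log_acc = _log_prior_s(va_new, abs(s_new)) - _log_prior_s(v_a, s_old)
                if np.log(rng.random()) < log_acc:
                    v_a = va_new
                    a = abs(s_new) * a_norm * np.sign(s_new)
                    a_rec = a[rec_idx]

        err = y - mu - a_rec - (tank_eff[tank_idx] if include_tank else 0.0)
        sse = float(err @ err)
        v_e = _scaled_inv_chi2(rng, nu, s2_e, sse, n)
        if include_tank:
            v_t = _scaled_inv_chi2(rng, nu, s2_t, float(tank_eff @ tank_eff), n_tanks)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            deviance = n * (LOG_2PI + np.log(v_e)) + sse / v_e
            row = [v_a, v_e, v_t, v_a / (v_a + v_e + (v_t if include_tank else 0.0)),
                   deviance, mu]
            keep.append(row)
            a_sum += a
            n_keep += 1

    cols = ["v_a", "v_e", "v_tank", "h2", "deviance", "mu"]
    samples = pd.DataFrame(keep, columns=cols)
    if not include_tank:
        samples = samples.drop(columns=["v_tank"])

    # deviance at posterior means of (mu, a, tank, v_e) for p_D
    a_bar = a_sum / n_keep
    mu_bar = samples["mu"].mean()
    err_bar = y - mu_bar - a_bar[rec_idx]
    if include_tank:
        # tank effects were not accumulated; refit their conditional mean
        sums = np.bincount(tank_idx, weights=err_bar, minlength=n_tanks)
        t_bar = sums / np.maximum(tank_counts, 1.0)
        err_bar = err_bar - t_bar[tank_idx]
    v_e_bar = samples["v_e"].mean()
    dev_at_mean = n * (LOG_2PI + np.log(v_e_bar)) + float(err_bar @ err_bar) / v_e_bar
    dic, p_d = dic_components(samples["deviance"], dev_at_mean)

    h2 = samples["h2"].to_numpy()
    try:
        from scipy.stats import gaussian_kde

        grid = np.linspace(h2.min(), h2.max(), 512)
        h2_mode = float(grid[np.argmax(gaussian_kde(h2)(grid))])
    except Exception:  # degenerate chains
        h2_mode = float(np.median(h2))
    lag1 = autocorrelation(samples["v_a"], 1) if samples["v_a"].std() > 0 else np.nan
    return VarianceComponentPosterior(
        samples=samples.drop(columns=["mu"]),
        h2_mean=float(h2.mean()),
        h2_mode=h2_mode,
        h2_hpd=hpd_interval(h2, 0.95),
        v_a_mean=float(samples["v_a"].mean()),
        v_e_mean=float(samples["v_e"].mean()),
        v_tank_mean=float(samples["v_tank"].mean()) if include_tank else None,
        dic=float(dic),
        p_d=float(p_d),
        autocorr_lag1=lag1,
        settings=mcmc,
        prior=prior,
    )


def heritability_table(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    prior: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    include_tank: bool = False,
) -> pd.DataFrame:
    """One animal-model fit per group-by-treatment cell, summarised like a
    heritability table: treatment, group, h2, HPD bounds, DIC, lag-1 autocorr."""
    rows = []
    for treatment in TREATMENTS:
        for group in GROUPS:
            sub = phenotypes[
                (phenotypes["group"] == group) & (phenotypes["treatment"] == treatment)
            ]
            if sub.empty:
                continue
            post = fit_animal_model(sub, pedigree, prior, mcmc, include_tank)
            rows.append(
                {
                    "treatment": treatment, "group": group,
                    "h2": post.h2_mean, "h2_mode": post.h2_mode,
                    "hpd_lower": post.h2_hpd[0], "hpd_upper": post.h2_hpd[1],
                    "v_a": post.v_a_mean, "v_e": post.v_e_mean,
                    "dic": post.dic, "autocorr_lag1": post.autocorr_lag1,
                }
            )
    return pd.DataFrame(rows)
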