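"""Family performance ratio under stress and its simulated null distribution.

For each family, the performance ratio is the mean log10 body weight in a
stress tank (x) divided by the mean log10 body weight in a control tank (y).
With two replicate tanks per treatment, each family yields four points: both
stress-tank replicates compared against both control-tank replicates.  The
ratio is plotted/correlated against the family's raw mean weight in the
control tank.

Even with no family effects at all, this correlation is negative: the control
weight enters the denominator of the ratio, so sampling noise in y pushes the
two quantities in opposite directions (d/dy [log x / log y] < 0).  The null
distribution makes that artefact visible by drawing independent control and
stress values around fixed treatment means and correlating ratio with control
weight.  A group whose observed correlation is *positive* therefore carries a
real signal — large families losing relatively less under stress — that
overrides the built-in negative bias.

Weights at or below 1 g would make log10 ratios unstable or flip their sign,
so family means are required to exceed 1 g (hatchery-stage salmon at
termination are well above this).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import CorrelationResult, pearson


class PerformanceRatioError(ValueError):
    pass


@dataclass(frozen=True)
class NullDistribution:
    points: pd.DataFrame  # columns y, ratio
    correlation: CorrelationResult


def _tank_means(phenotypes: pd.DataFrame) -> pd.DataFrame:
    df = phenotypes.copy()
    df["log_w"] = np.log10(df["weight_g"])
    g = df.groupby(["family", "group", "treatment", "tank"], sort=False)
    out = g.agg(mean_weight=("weight_g", "mean"), mean_log_w=("log_w", "mean"))
    return out.reset_index()


def performance_points(
    phenotypes: pd.DataFrame,
    ratio_mode: str = "mean_log",
    warn: bool = True,
) -> pd.DataFrame:
    """All stress-vs-control tank comparisons per family.

    ``ratio_mode`` selects how the per-tank family summary entering the ratio
    is formed: "mean_log" (mean of log10 weights, the default) or "log_mean"
    (log10 of the mean weight).  The y column is always the raw mean weight in
    the control tank.  Families lacking any of the four tanks are skipped.
    """
    if ratio_mode not in ("mean_log", "log_mean"):
        raise PerformanceRatioError(f"unknown ratio_mode {ratio_mode!r}")
    means = _tank_means(phenotypes)
    rows = []
    for (family, group), sub in means.groupby(["family", "group"], sort=False):
        control = sub[sub["treatment"] == "control"]
        stress = sub[sub["treatment"] == "stress"]
        n_tanks = phenotypes[["treatment", "tank"]].drop_duplicates()
        expected_c = (n_tanks["treatment"] == "control").sum()
        expected_s = (n_tanks["treatment"] == "stress").sum()
        if len(control) < expected_c or len(stress) < expected_s:
            if warn:
                import warnings

                warnings.warn(f"family {family}: missing tank mean, skipped")
            continue
        for sr in stress.itertuples(index=False):
            for cr in control.itertuples(index=False):
                if sr.mean_weight <= 1.0 or cr.mean_weight <= 1.0:
                    raise PerformanceRatioError(
                        f"family {family}: tank mean weight <= 1 g, log ratio undefined"
                    )
                if ratio_mode == "mean_log":
                    ratio = sr.mean_log_w / cr.mean_log_w
                else:
                    ratio = np.log10(sr.mean_weight) / np.log10(cr.mean_weight)
                rows.append(
                    {
                        "family": family,
                        "group": group,
                        "control_tank": cr.tank,
                        "stress_tank": sr.tank,
                        "y": cr.mean_weight,
                        "x": sr.mean_weight,
                        "ratio": ratio,
                    }
                )
    return pd.DataFrame(rows)


def group_correlation(points: pd.DataFrame, group: str) -> CorrelationResult:
    """Pearson correlation of (performance ratio, control weight) in one group."""
    sub = points[points["group"] == group]
    if len(sub) < 3:
        raise PerformanceRatioError(f"group {group}: fewer than 3 points")
    return pearson(sub["ratio"].to_numpy(), sub["y"].to_numpy())


def null_distribution(
    mu_control: float,
    mu_stress: float,
    n: int = 120,
    sd_frac: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> NullDistribution:
    """Simulated null: ratio vs control weight with no family structure.

    Draws n independent pairs c ~ N(mu_control, sd_frac*mu_control) and
    s ~ N(mu_stress, sd_frac*mu_stress); draws at or below 1 g are redrawn.
    Returns the (y=c, ratio=log10 s / log10 c) points and their Pearson
    correlation, which is negative under this null.
    """
    if mu_control <= 1.0 or mu_stress <= 1.0:
        raise PerformanceRatioError("treatment means must exceed 1 g")
    if sd_frac < 0:
        raise PerformanceRatioError("sd_frac must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(mu: float) -> np.ndarray:
        out = rng.normal(mu, sd_frac * mu, n)
        while np.any(out <= 1.0):  # redraw non-positive-log weights
            bad = out <= 1.0
            out[bad] = rng.normal(mu, sd_frac * mu, bad.sum())
        return out

    c = draw(mu_control)
    s = draw(mu_stress)
    ratio = np.log10(s) / np.log10(c)
    points = pd.DataFrame({"y": c, "ratio": ratio})
    corr = pearson(ratio, c)  # raises on degenerate sd_frac == 0
    return NullDistribution(points, corr)
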