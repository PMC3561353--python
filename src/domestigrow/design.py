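"""Breeding design and simulation parameters.

The simulator emulates a common-garden experiment in which farmed (domesticated),
wild and F1 hybrid Atlantic salmon families are reared together in replicate
tanks under a control and a stress treatment.  Hybrid families are produced by
crossing farmed dams with wild sires, so hybrid family *h* is a maternal
half-sib family of farmed family *h* and a paternal half-sib family of wild
family *h*.

Default parameter values are calibrated against published group-by-treatment
growth summaries from such an experiment (10 farmed, 10 wild and 9 hybrid
families; two control and two stress tanks; ~550-565 fish sampled per tank),
so that downstream model fitting can be exercised on data with realistic
structure and magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GROUPS = ("farm", "hybrid", "wild")
TREATMENTS = ("control", "stress")

#: Empirical group-by-treatment mean body weight (g) at termination, pooled over
#: replicate tanks, used to calibrate the simulator's mean log10-weights.
REFERENCE_MEAN_WEIGHT_G = {
    ("wild", "control"): 11.98,
    ("wild", "stress"): 8.10,
    ("hybrid", "control"): 22.85,
    ("hybrid", "stress"): 17.19,
    ("farm", "control"): 35.08,
    ("farm", "stress"): 27.77,
}

#: Matching empirical standard deviations of body weight (g).
REFERENCE_SD_WEIGHT_G = {
    ("wild", "control"): 6.07,
    ("wild", "stress"): 4.65,
    ("hybrid", "control"): 7.47,
    ("hybrid", "stress"): 6.39,
    ("farm", "control"): 8.27,
    ("farm", "stress"): 6.16,
}

#: Matching sample sizes per group-by-treatment cell (both replicate tanks pooled).
REFERENCE_N = {
    ("wild", "control"): 425,
    ("wild", "stress"): 435,
    ("hybrid", "control"): 339,
    ("hybrid", "stress"): 351,
    ("farm", "control"): 357,
    ("farm", "stress"): 329,
}

LOG10 = math.log(10.0)


class DesignError(ValueError):
    """Raised when a breeding design or parameter set is internally inconsistent."""


@dataclass(frozen=True)
class BreedingDesign:
    """Family structure and tank layout of the experiment.

    Hybrid family ``h`` reuses the dam of farmed family ``h`` and the sire of
    wild family ``h``, so the number of hybrid families cannot exceed either
    the number of farmed or the number of wild families.
    """

    n_farm_families: int = 10
    n_wild_families: int = 10
    n_hybrid_families: int = 9
    offspring_per_family_per_tank: int = 19
    tanks: tuple[tuple[str, str], ...] = (
        ("T1", "control"),
        ("T2", "control"),
        ("T3", "stress"),
        ("T4", "stress"),
    )

    def __post_init__(self) -> None:
        for name in ("n_farm_families", "n_wild_families", "n_hybrid_families"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.n_hybrid_families > min(self.n_farm_families, self.n_wild_families):
            raise DesignError(
                "hybrid families require a farmed dam and a wild sire each: "
                f"cannot build {self.n_hybrid_families} hybrid families from "
                f"{self.n_farm_families} farmed and {self.n_wild_families} wild families"
            )
        if self.offspring_per_family_per_tank < 0:
            raise DesignError("offspring_per_family_per_tank must be >= 0")
        ids = [t for t, _ in self.tanks]
        if len(set(ids)) != len(ids):
            raise DesignError("tank ids must be unique")
        for _, treatment in self.tanks:
            if treatment not in TREATMENTS:
                raise DesignError(f"unknown treatment {treatment!r}")

    @property
    def n_families(self) -> int:
        return self.n_farm_families + self.n_wild_families + self.n_hybrid_families

    @property
    def family_ids(self) -> list[str]:
        return (
            [f"F{i + 1:02d}" for i in range(self.n_farm_families)]
            + [f"W{i + 1:02d}" for i in range(self.n_wild_families)]
            + [f"H{i + 1:02d}" for i in range(self.n_hybrid_families)]
        )

    def family_group(self, family_id: str) -> str:
        return {"F": "farm", "W": "wild", "H": "hybrid"}[family_id[0]]

    def eggs_per_tray(self, eggs_per_family: int = 50) -> int:
        """Eggs in one mixed incubation tray with equal contributions per family."""
        return self.n_families * eggs_per_family


def _default_allele_freqs(n_loci: int, alleles_per_locus: int) -> tuple[np.ndarray, ...]:
    return tuple(
        np.full(alleles_per_locus, 1.0 / alleles_per_locus) for _ in range(n_loci)
    )


@dataclass
class SimulationParams:
    """All stochastic-model parameters of the simulator.

    ``mu_logw`` are cell means of log10 body weight (log10 grams); ``v_a`` is
    the additive genetic variance per group and ``v_e`` the residual variance
    per treatment, both on the log10 scale (heritability within a cell is
    h2 = V_A / (V_A + V_E + V_tank)); ``v_tank`` is the variance of a shared
    tank effect drawn once per tank.
    """

    mu_logw: dict[tuple[str, str], float] = field(default_factory=dict)
    v_a: dict[str, float] = field(
        default_factory=lambda: {"farm": 0.002, "hybrid": 0.004, "wild": 0.016}
    )
    v_e: dict[str, float] = field(
        default_factory=lambda: {"control": 0.012, "stress": 0.014}
    )
    v_tank: float = 0.0005
    n_loci: int = 6
    alleles_per_locus: int = 10
    allele_freqs: tuple[np.ndarray, ...] | None = None
    genotyping_error_rate: float = 0.001
    trisomy_rate: float = 70 / 2256
    mean_condition_factor: float = 1.28
    sd_condition_factor: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_logw:
            self.mu_logw = {
                cell: math.log10(m) - LOG10 * self.total_variance(*cell) / 2.0
                for cell, m in REFERENCE_MEAN_WEIGHT_G.items()
            }
        if self.allele_freqs is None:
            self.allele_freqs = _default_allele_freqs(self.n_loci, self.alleles_per_locus)
        self.validate()

    def validate(self) -> None:
        if any(v < 0 for v in self.v_a.values()):
            raise DesignError("additive genetic variances must be >= 0")
        if any(v < 0 for v in self.v_e.values()):
            raise DesignError("residual variances must be >= 0")
        if self.v_tank < 0:
            raise DesignError("tank variance must be >= 0")
        for rate_name in ("genotyping_error_rate", "trisomy_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise DesignError(f"{rate_name} must lie in [0, 1]")
        if len(self.allele_freqs) != self.n_loci:
            raise DesignError("allele_freqs must provide one frequency vector per locus")
        for locus, freqs in enumerate(self.allele_freqs):
            freqs = np.asarray(freqs, dtype=float)
            if freqs.size == 0:
                raise DesignError(f"locus {locus}: empty allele frequency vector")
            if np.any(freqs < 0) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-8):
                raise DesignError(f"locus {locus}: allele frequencies must sum to 1")

    def total_variance(self, group: str, treatment: str) -> float:
        """Phenotypic variance of log10 weight in one group-by-treatment cell."""
        return self.v_a[group] + self.v_e[treatment] + self.v_tank

    def expected_mean_weight(self, group: str, treatment: str) -> float:
        """Expected raw-scale mean weight (g) implied by the log-normal model."""
        mu = self.mu_logw[(group, treatment)]
        v = self.total_variance(group, treatment)
        return 10.0**mu * math.exp((LOG10**2) * v / 2.0)

    def to_dict(self) -> dict:
        return {
            "mu_logw": {f"{g}:{t}": float(v) for (g, t), v in self.mu_logw.items()},
            "v_a": {k: float(v) for k, v in self.v_a.items()},
            "v_e": {k: float(v) for k, v in self.v_e.items()},
            "v_tank": float(self.v_tank),
            "n_loci": self.n_loci,
            "alleles_per_locus": self.alleles_per_locus,
            "allele_freqs": [list(map(float, f)) for f in self.allele_freqs],
            "genotyping_error_rate": float(self.genotyping_error_rate),
            "trisomy_rate": float(self.trisomy_rate),
            "mean_condition_factor": float(self.mean_condition_factor),
            "sd_condition_factor": float(self.sd_condition_factor),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "mu_logw" in d:
            d["mu_logw"] = {
                tuple(k.split(":")): float(v) for k, v in d["mu_logw"].items()
            }
        if "allele_freqs" in d and d["allele_freqs"] is not None:
            d["allele_freqs"] = tuple(np.asarray(f, dtype=float) for f in d["allele_freqs"])
        return cls(**d)


def weight_ratio(group_num: str, group_den: str, treatment: str,
                 means: dict[tuple[str, str], float] | None = None) -> float:
    """Ratio of mean body weights between two groups within one treatment.

    Defaults to the reference calibration means; e.g. the farmed/wild ratio in
    the control treatment quantifies the growth gain of domestication.
    """
    means = REFERENCE_MEAN_WEIGHT_G if means is None else means
    return means[(group_num, treatment)] / means[(group_den, treatment)]
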