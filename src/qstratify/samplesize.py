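"""Trial-design arithmetic for phenotype-stratified studies.

Planning a phenotype-stratified trial takes three steps: convert an
anticipated treatment effect into a standardized effect size (Cohen's d for
mean outcomes, w for dichotomous ones); compute the smallest subgroup that
reaches the requested power for that effect under the chosen design; and
inflate the subgroup by the phenotype's frequency in the etiology of
interest to obtain the number of patients who must be screened with QST.

Designs map to test families: PARALLEL to the two-sample t test (the
returned n is per group), CROSSOVER to the paired t test on within-subject
differences (the returned n is total subjects, with d defined on the
difference scale), DICHOTOMOUS to the chi-square test with effect size w.
Power at a given n is evaluated through the noncentral t / noncentral
chi-square machinery of :mod:`statsmodels.stats.power`; the integer-minimal
n is found by direct search, so the result is exactly the smallest integer
achieving the target (no continuous-solution rounding artifacts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.power import (
    GofChisquarePower,
    TTestIndPower,
    TTestPower,
)


class Design(str, Enum):
    PARALLEL = "parallel"
    CROSSOVER = "crossover"
    DICHOTOMOUS = "dichotomous"


class UnattainableError(ValueError):
    """Raised when the required sample size exceeds the configured cap."""


@dataclass(frozen=True)
class PowerSpec:
    """Design and error rates for one sample-size calculation.

    ``effect_size`` is Cohen's d for the t designs (difference-scale d for
    CROSSOVER) and Cohen's w for DICHOTOMOUS.  ``df`` only applies to the
    chi-square family (1 for a 2x2 comparison).  Tests are two-sided by
    default.
    """

    effect_size: float
    design: Design = Design.PARALLEL
    alpha: float = 0.05
    power: float = 0.8
    two_sided: bool = True
    df: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power must lie in (0, 1), got {self.power}")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be > 0, got {self.effect_size}")
        object.__setattr__(self, "design", Design(self.design))


def cohen_d(mean_effect: float, sd_response: float) -> float:
    """Cohen's d: mean treatment effect divided by the response SD.

    E.g. a 2-point mean effect on a 0-10 NRS with SD 4 gives d = 0.5.
    """
    if sd_response <= 0:
        raise ValueError(f"sd_response must be > 0, got {sd_response}")
    return mean_effect / sd_response


def cohen_w(p_alt: Sequence[float], p_null: Sequence[float]) -> float:
    """Cohen's w from alternative vs null cell probabilities.

    w = sqrt(sum((p1_i - p0_i)^2 / p0_i)).  For two proportions pass the
    (p, 1-p) pairs.  Provided because the chi-square family is specified by
    its test, not by a ready-made w.
    """
    p1 = np.asarray(p_alt, dtype=float)
    p0 = np.asarray(p_null, dtype=float)
    if p1.shape != p0.shape:
        raise ValueError("probability vectors must have the same shape")
    if np.any(p0 <= 0) or not (
        math.isclose(p0.sum(), 1.0, abs_tol=1e-9)
        and math.isclose(p1.sum(), 1.0, abs_tol=1e-9)
    ):
        raise ValueError("cell probabilities must be positive and sum to 1")
    return float(np.sqrt(np.sum((p1 - p0) ** 2 / p0)))


def achieved_power(spec: PowerSpec, n: int) -> float:
    """Power of the design's test at sample size ``n``.

    ``n`` is per group for PARALLEL and total subjects otherwise.
    """
    if n < 2:
        return 0.0
    alternative = "two-sided" if spec.two_sided else "larger"
    if spec.design is Design.PARALLEL:
        return float(
            TTestIndPower().power(
                effect_size=spec.effect_size,
                nobs1=n,
                alpha=spec.alpha,
                ratio=1.0,
                alternative=alternative,
            )
        )
    if spec.design is Design.CROSSOVER:
        return float(
            TTestPower().power(
                effect_size=spec.effect_size,
                nobs=n,
                alpha=spec.alpha,
                alternative=alternative,
            )
        )
    # chi-square: inherently two-sided on the contingency scale
    return float(
        GofChisquarePower().power(
            effect_size=spec.effect_size,
            nobs=n,
            n_bins=spec.df + 1,
            alpha=spec.alpha,
        )
    )


def required_n(spec: PowerSpec, cap: int = 10**6) -> int:
    """Smallest integer sample size reaching the requested power.

    Returns subjects per group (PARALLEL) or total subjects (CROSSOVER,
    DICHOTOMOUS).  Searches the integers directly — power is monotone in n
    — and raises :class:`UnattainableError` beyond ``cap``.
    """
    lo, hi = 2, 2
    while achieved_power(spec, hi) < spec.power:
        hi *= 2
        if hi > cap:
            raise UnattainableError(
                f"required n exceeds cap {cap} for effect size "
                f"{spec.effect_size} ({spec.design.value})"
            )
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved_power(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def screening_size(subgroup_n: int, phenotype_frequency: float) -> int:
    """Patients to screen so the target-phenotype subgroup reaches ``subgroup_n``.

    ceiling(subgroup_n / frequency); the frequency is the phenotype's
    prevalence in the etiology of interest under the allocation variant
    that will be used for screening.
    """
    if subgroup_n < 1:
        raise ValueError(f"subgroup_n must be >= 1, got {subgroup_n}")
    if not (0.0 < phenotype_frequency <= 1.0):
        raise ValueError(
            f"phenotype frequency must lie in (0, 1], got {phenotype_frequency}"
        )
    return int(math.ceil(subgroup_n / phenotype_frequency))


@dataclass(frozen=True)
class ScreeningPlan:
    """One fully-resolved screening cell: design x effect size x frequency."""

    spec: PowerSpec
    subgroup_n: int
    phenotype_frequency: float
    screening_n: int
    etiology: str
    phenotype: str
    variant: str = ""

    def __post_init__(self) -> None:
        if self.screening_n < self.subgroup_n:
            raise ValueError("screening_n cannot be smaller than subgroup_n")


def screening_table(
    specs: Sequence[PowerSpec],
    frequencies: Mapping[tuple, float],
) -> tuple[pd.DataFrame, list[str]]:
    """Cross every PowerSpec with every (etiology, phenotype[, variant]) frequency.

    ``frequencies`` maps 2- or 3-tuples (etiology, phenotype) or
    (etiology, phenotype, algorithm-variant) to prevalences in (0, 1].
    Invalid entries are reported in the returned error list; the remaining
    cells are still computed.  For PARALLEL designs the screening size is
    based on the total trial size (2 x per-group n), since both arms are
    recruited from the screened population.
    """
    rows: list[dict] = []
    errors: list[str] = []
    subgroup_cache: dict[PowerSpec, int] = {}
    for key, freq in frequencies.items():
        if len(key) == 2:
            etiology, phenotype = key
            variant = ""
        else:
            etiology, phenotype, variant = key
        for spec in specs:
            cell = f"({etiology}, {phenotype}{', ' + variant if variant else ''}) x d={spec.effect_size} {spec.design.value}"
            try:
                if spec not in subgroup_cache:
                    subgroup_cache[spec] = required_n(spec)
                per_group = subgroup_cache[spec]
                total = 2 * per_group if spec.design is Design.PARALLEL else per_group
                n_screen = screening_size(total, freq)
            except (ValueError, UnattainableError) as exc:
                errors.append(f"{cell}: {exc}")
                continue
            rows.append(
                {
                    "etiology": etiology,
                    "phenotype": phenotype,
                    "variant": variant,
                    "design": spec.design.value,
                    "effect_size": spec.effect_size,
                    "alpha": spec.alpha,
                    "power": spec.power,
                    "subgroup_n": per_group,
                    "subgroup_n_is_per_group": spec.design is Design.PARALLEL,
                    "trial_total_n": total,
                    "frequency": freq,
                    "screening_n": n_screen,
                }
            )
    return pd.DataFrame(rows), errors
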