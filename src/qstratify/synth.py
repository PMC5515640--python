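"""Synthetic QST cohort generation.

There is no deposited patient-level QST dataset, so every cohort-level
operation in this package is exercised on simulated profiles.  The
generator draws each continuous parameter independently from
Normal(mu, (sd_scale * sigma)^2) with (mu, sigma) taken from the centroid
table of the subject's true phenotype — mirroring the approximate normality
of QST z-values that the classification algorithm itself assumes — and
healthy subjects from the standard normal reference.  PHS and DMA have no
published within-cluster distribution; the conformant default
(``thresholded``) samples the same Gaussian and snaps to the nearest legal
code, while ``gaussian`` leaves them continuous for stress testing and
marks the profiles non-conformant.

Parameters are drawn independently (the real battery is intercorrelated;
only per-parameter means and SDs are published), so simulated cohorts are,
if anything, easier to classify than real ones.  ``sd_scale`` exposes the
noise level: 0 puts every subject exactly on its centroid, 1 reproduces the
centroid table's spread, larger values stress the allocator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocator import Allocation
from .profiles import (
    DMA_CODES,
    PARAMETERS,
    PHS_CODES,
    CentroidTable,
    Phenotype,
    QSTParameter,
    QSTProfile,
)
from .stats import cohens_kappa

#: Group order for generation: the three phenotypes, then healthy.
GROUP_ORDER: tuple[Phenotype, ...] = (
    Phenotype.SL,
    Phenotype.TH,
    Phenotype.MH,
    Phenotype.HEALTHY,
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``n_per_group`` maps phenotypes (including HEALTHY) to subject counts.
    ``sd_scale`` multiplies every centroid SD (0 = noise-free).
    ``missing_rate`` is the per-cell probability of a missing value.
    ``discrete_handling`` is ``'thresholded'`` (snap PHS/DMA to legal
    codes) or ``'gaussian'`` (leave continuous; non-conformant stress
    mode).  ``seed`` is mandatory: generation is deterministic given the
    spec (NumPy ``default_rng``, i.e. PCG64).
    """

    n_per_group: Mapping[Phenotype, int]
    seed: int
    centroids: CentroidTable | None = None
    sd_scale: float = 1.0
    missing_rate: float = 0.0
    discrete_handling: str = "thresholded"

    def __post_init__(self) -> None:
        counts = {Phenotype(k): int(v) for k, v in self.n_per_group.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("group counts must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.sd_scale < 0:
            raise ValueError(f"sd_scale must be non-negative, got {self.sd_scale}")
        if self.discrete_handling not in ("thresholded", "gaussian"):
            raise ValueError(f"unknown discrete_handling {self.discrete_handling!r}")
        object.__setattr__(self, "n_per_group", counts)


@dataclass
class SyntheticCohort:
    """Generated profiles plus their ground-truth phenotype labels."""

    profiles: list[QSTProfile]
    truth: dict[str, Phenotype]

    @property
    def truth_labels(self) -> list[Phenotype]:
        return [self.truth[p.subject_id] for p in self.profiles]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in self.profiles],
                "true_phenotype": [t.value for t in self.truth_labels],
            }
        )


def _snap(values: np.ndarray, codes: Sequence[float]) -> np.ndarray:
    codes = np.asarray(codes, dtype=float)
    return codes[np.argmin(np.abs(values[:, None] - codes[None, :]), axis=1)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort according to ``spec``; bit-reproducible for a given seed."""
    centroids = spec.centroids if spec.centroids is not None else CentroidTable.load_default()
    rng = np.random.default_rng(spec.seed)
    conformant = spec.discrete_handling == "thresholded"
    profiles: list[QSTProfile] = []
    truth: dict[str, Phenotype] = {}
    for group in GROUP_ORDER:
        n = spec.n_per_group.get(group, 0)
        if n == 0:
            continue
        mu, sigma = centroids.arrays(group, PARAMETERS)
        draws = rng.normal(mu, spec.sd_scale * sigma, size=(n, len(PARAMETERS)))
        if conformant:
            phs_i = PARAMETERS.index(QSTParameter.PHS)
            dma_i = PARAMETERS.index(QSTParameter.DMA)
            draws[:, phs_i] = _snap(draws[:, phs_i], PHS_CODES)
            draws[:, dma_i] = _snap(draws[:, dma_i], DMA_CODES)
        for k in range(n):
            sid = f"{group.value}-{k:04d}"
            profiles.append(
                QSTProfile(
                    subject_id=sid,
                    values=dict(zip(PARAMETERS, draws[k])),
                    is_patient=group is not Phenotype.HEALTHY,
                    validate=conformant,
                )
            )
            truth[sid] = group
    if not profiles:
        raise ValueError("cohort spec produced no subjects")
    if spec.missing_rate > 0:
        profiles = inject_missing(
            profiles,
            rate=spec.missing_rate,
            pattern="random",
            seed=int(rng.integers(2**31)),
        )
    return SyntheticCohort(profiles=profiles, truth=truth)


def inject_missing(
    profiles: Sequence[QSTProfile],
    rate: float = 0.0,
    pattern: str = "random",
    seed: int | None = None,
    parameters: Sequence[QSTParameter] | None = None,
) -> list[QSTProfile]:
    """Apply a missingness pattern; never removes a profile's last value.

    ``'random'`` drops each cell independently with probability ``rate``
    (a profile whose draw would empty it keeps one randomly chosen value);
    ``'parameter_block'`` blanks the given ``parameters`` in every profile.
    """
    if pattern == "random":
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"rate must lie in [0, 1), got {rate}")
        if rate == 0.0:
            return list(profiles)
        if seed is None:
            raise ValueError("random missingness requires a seed")
        rng = np.random.default_rng(seed)
        out = []
        for prof in profiles:
            present = [p for p in PARAMETERS if p in prof.values]
            drop = rng.random(len(present)) < rate
            if drop.all():
                drop[rng.integers(len(present))] = False
            kept = {
                p: prof.values[p] for p, d in zip(present, drop) if not d
            }
            out.append(prof.with_values(kept))
        return out
    if pattern == "parameter_block":
        if not parameters:
            raise ValueError("parameter_block pattern requires parameters")
        block = {QSTParameter(p) for p in parameters}
        if len(block) >= len(PARAMETERS):
            raise ValueError("cannot blank the entire battery")
        out = []
        for prof in profiles:
            kept = {p: v for p, v in prof.values.items() if p not in block}
            if not kept:
                raise ValueError(
                    f"subject {prof.subject_id!r}: block removes every value"
                )
            out.append(prof.with_values(kept))
        return out
    raise ValueError(f"unknown pattern {pattern!r}")


@dataclass(frozen=True)
class RecoveryReport:
    """How well allocations recover the simulated ground truth."""

    confusion: pd.DataFrame  # rows = truth, columns = allocated
    accuracy: float  # fraction of subjects allocated to their true group
    recall: Mapping[str, float]
    precision: Mapping[str, float]
    kappa: float
    n: int


def truth_recovery_report(
    truth_labels: Sequence[Phenotype],
    allocations: Sequence[Allocation],
) -> RecoveryReport:
    """Confusion table and recovery rates of deterministic allocations vs truth."""
    truth_labels = [Phenotype(t) for t in truth_labels]
    if len(truth_labels) != len(allocations):
        raise ValueError(
            f"truth ({len(truth_labels)}) and allocations ({len(allocations)}) "
            "are misaligned"
        )
    if not truth_labels:
        raise ValueError("empty inputs")
    predicted = []
    for a in allocations:
        if a.label is None:
            raise ValueError(
                f"subject {a.subject_id!r}: recovery needs deterministic labels"
            )
        predicted.append(a.label)
    agreement = cohens_kappa(
        [t.value for t in truth_labels], [p.value for p in predicted]
    )
    confusion = agreement.confusion
    recall: dict[str, float] = {}
    precision: dict[str, float] = {}
    for label in confusion.index:
        row_total = confusion.loc[label].sum()
        col_total = confusion[label].sum()
        hit = confusion.loc[label, label]
        recall[label] = hit / row_total if row_total else np.nan
        precision[label] = hit / col_total if col_total else np.nan
    return RecoveryReport(
        confusion=confusion,
        accuracy=agreement.percent_agreement / 100.0,
        recall=recall,
        precision=precision,
        kappa=agreement.kappa,
        n=agreement.n,
    )
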