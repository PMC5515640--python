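"""Gaussian-similarity phenotype allocation for QST z-profiles.

The stratification algorithm compares a patient's 13-parameter z-profile to
each phenotype centroid through a normalized Gaussian density.  For
parameter i with centroid mean mu_i and SD sigma_i, the per-parameter
similarity is the normal density at the observed z divided by its value at
the mean, expressed as a percentage:

    F_i(z) = 100 * exp(-(z - mu_i)^2 / (2 * sigma_i^2))

so a value exactly at the centroid mean scores 100% regardless of how broad
or narrow the phenotype's distribution is.  The phenotype probability is
the arithmetic mean of F_i over the non-missing parameters — missing values
are simply left out of the average, which is the algorithm's whole reason
for using densities instead of centroid distances (no imputation, no
exclusion of incomplete profiles).  The healthy reference uses mu = 0,
sigma = 1 for every parameter, i.e. the definition of the z-scale.

Two allocation modes are provided.  The deterministic mode assigns the
single phenotype with the highest probability (optionally competing against
the healthy profile).  The probabilistic mode assigns every phenotype whose
probability exceeds a cutoff (default 64%, the Youden-optimal threshold for
separating patients from healthy subjects); a subject none of whose
phenotype probabilities exceeds the cutoff — or whose only exceedance is
the healthy profile — is excluded.

The full protocol averages over all 13 parameters; the simplified protocol
uses only warm detection threshold (WDT) and mechanical pain sensitivity
(MPS), the two parameters that explain most of the between-phenotype
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .profiles import (
    PARAMETERS,
    PATIENT_PHENOTYPES,
    CentroidTable,
    Phenotype,
    QSTParameter,
    QSTProfile,
)

#: Default probability cutoff (percent) for the probabilistic mode: the
#: Youden-optimal threshold on the healthy-profile probability, applied to
#: both the full and the simplified protocol.
DEFAULT_CUTOFF = 64.0


class Protocol(str, Enum):
    FULL = "full"
    SIMPLIFIED = "simplified"


#: The two parameters of the simplified protocol.
SIMPLIFIED_PARAMETERS: tuple[QSTParameter, ...] = (
    QSTParameter.WDT,
    QSTParameter.MPS,
)

#: Minimum non-missing parameters required per protocol.  The full battery
#: tolerates missing values but averaging over very few parameters is
#: fragile; the simplified protocol needs both of its parameters.
DEFAULT_MIN_PARAMS: dict[Protocol, int] = {
    Protocol.FULL: 7,
    Protocol.SIMPLIFIED: 2,
}


class NotComputableError(ValueError):
    """Raised when a profile has too few non-missing parameters."""


class InvalidCentroidError(ValueError):
    """Raised when a centroid SD is non-positive."""


def protocol_parameters(protocol: Protocol) -> tuple[QSTParameter, ...]:
    protocol = Protocol(protocol)
    return PARAMETERS if protocol is Protocol.FULL else SIMPLIFIED_PARAMETERS


def similarity(z, mu, sigma):
    """Normalized Gaussian similarity of z to a centroid, in percent.

    Equals 100 iff z == mu, decays strictly with |z - mu| on the scale of
    sigma; always in (0, 100].  Vectorizes over array inputs.
    """
    z = np.asarray(z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise InvalidCentroidError("sigma must be strictly positive")
    out = 100.0 * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProbabilityVector:
    """Per-subject phenotype probabilities (percent) and parameter counts."""

    subject_id: str
    p: Mapping[Phenotype, float]
    n_used: int
    protocol: Protocol

    def argmax(self, candidates: Sequence[Phenotype]) -> tuple[Phenotype, bool]:
        """Highest-probability candidate; ties broken by candidate order.

        Returns (label, tie_flag); tie_flag is True when another candidate
        attains exactly the same probability.
        """
        best = max(candidates, key=lambda m: self.p[m])
        ties = [m for m in candidates if self.p[m] == self.p[best]]
        return ties[0], len(ties) > 1


def phenotype_probability(
    profile: QSTProfile,
    phenotype: Phenotype,
    centroids: CentroidTable,
    protocol: Protocol = Protocol.FULL,
    min_params: int | None = None,
) -> tuple[float, int]:
    """Probability (percent) that ``profile`` shows ``phenotype``.

    Arithmetic mean of the per-parameter similarities over the non-missing
    parameters of the protocol's set; returns (probability, n_used).
    Raises :class:`NotComputableError` when fewer than ``min_params``
    parameters are available (protocol-dependent default).
    """
    protocol = Protocol(protocol)
    params = [p for p in protocol_parameters(protocol) if profile.z(p) is not None]
    required = DEFAULT_MIN_PARAMS[protocol] if min_params is None else min_params
    if len(params) < max(1, required):
        raise NotComputableError(
            f"subject {profile.subject_id!r}: only {len(params)} of "
            f"{len(protocol_parameters(protocol))} {protocol.value}-protocol "
            f"parameters present (minimum {max(1, required)})"
        )
    z = np.array([profile.z(p) for p in params])
    mu, sigma = centroids.arrays(phenotype, params)
    return float(np.mean(similarity(z, mu, sigma))), len(params)


def probability_vector(
    profile: QSTProfile,
    centroids: CentroidTable,
    protocol: Protocol = Protocol.FULL,
    min_params: int | None = None,
) -> ProbabilityVector:
    """All four phenotype probabilities (SL, TH, MH, healthy) for a subject."""
    p: dict[Phenotype, float] = {}
    n_used = 0
    for pheno in (*PATIENT_PHENOTYPES, Phenotype.HEALTHY):
        p[pheno], n_used = phenotype_probability(
            profile, pheno, centroids, protocol, min_params
        )
    return ProbabilityVector(profile.subject_id, p, n_used, Protocol(protocol))


@dataclass(frozen=True)
class Allocation:
    """Result of allocating one subject.

    Deterministic mode: ``label`` holds the single assigned phenotype and
    ``excluded`` is always False.  Probabilistic mode: ``label_set`` holds
    every patient phenotype above the cutoff, ``healthy_flag`` marks a
    healthy-profile probability above the cutoff, and ``excluded`` is True
    iff ``label_set`` is empty (regardless of the healthy flag).
    """

    subject_id: str
    mode: str  # "deterministic" | "probabilistic"
    probabilities: ProbabilityVector
    label: Phenotype | None = None
    label_set: frozenset[Phenotype] = frozenset()
    healthy_flag: bool = False
    excluded: bool = False
    tie_flag: bool = False
    cutoff_used: float | None = None
    etiology: str | None = None


def allocate_deterministic(
    profile: QSTProfile,
    centroids: CentroidTable,
    protocol: Protocol = Protocol.FULL,
    include_healthy: bool = True,
    min_params: int | None = None,
) -> Allocation:
    """Assign the single phenotype with the highest probability.

    With ``include_healthy`` (the default, matching the final recommended
    algorithm) the healthy profile competes as a fourth label.  Exact ties
    are broken by the fixed order SL > TH > MH > HEALTHY and flagged.
    """
    pv = probability_vector(profile, centroids, protocol, min_params)
    candidates: tuple[Phenotype, ...] = (
        (*PATIENT_PHENOTYPES, Phenotype.HEALTHY) if include_healthy else PATIENT_PHENOTYPES
    )
    label, tie = pv.argmax(candidates)
    return Allocation(
        subject_id=profile.subject_id,
        mode="deterministic",
        probabilities=pv,
        label=label,
        tie_flag=tie,
        etiology=profile.etiology,
    )


def allocate_probabilistic(
    profile: QSTProfile,
    centroids: CentroidTable,
    protocol: Protocol = Protocol.FULL,
    cutoff: float = DEFAULT_CUTOFF,
    min_params: int | None = None,
) -> Allocation:
    """Assign every phenotype whose probability strictly exceeds ``cutoff``.

    A subject whose only exceedance is the healthy profile, or with no
    exceedance at all, is excluded (empty label set).
    """
    if not (0.0 < cutoff < 100.0):
        raise ValueError(f"cutoff must lie strictly between 0 and 100, got {cutoff}")
    pv = probability_vector(profile, centroids, protocol, min_params)
    label_set = frozenset(m for m in PATIENT_PHENOTYPES if pv.p[m] > cutoff)
    return Allocation(
        subject_id=profile.subject_id,
        mode="probabilistic",
        probabilities=pv,
        label_set=label_set,
        healthy_flag=pv.p[Phenotype.HEALTHY] > cutoff,
        excluded=not label_set,
        cutoff_used=cutoff,
        etiology=profile.etiology,
    )


@dataclass
class CohortResult:
    """Batch allocation outcome: results in input order plus an error report."""

    allocations: list[Allocation]
    errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(a.excluded for a in self.allocations)

    @property
    def n_ties(self) -> int:
        return sum(a.tie_flag for a in self.allocations)

    def frame(self):
        """Flat table of probabilities and allocation outcomes."""
        import pandas as pd

        rows = []
        for a in self.allocations:
            rows.append(
                {
                    "subject_id": a.subject_id,
                    "etiology": a.etiology,
                    "p_SL": a.probabilities.p[Phenotype.SL],
                    "p_TH": a.probabilities.p[Phenotype.TH],
                    "p_MH": a.probabilities.p[Phenotype.MH],
                    "p_healthy": a.probabilities.p[Phenotype.HEALTHY],
                    "n_used": a.probabilities.n_used,
                    "mode": a.mode,
                    "protocol": a.probabilities.protocol.value,
                    "cutoff": a.cutoff_used,
                    "label": a.label.value if a.label else None,
                    "label_set": "|".join(
                        sorted(m.value for m in a.label_set)
                    ),
                    "healthy_flag": a.healthy_flag,
                    "excluded": a.excluded,
                    "tie_flag": a.tie_flag,
                }
            )
        return pd.DataFrame(rows)


def allocate_cohort(
    profiles: Sequence[QSTProfile],
    centroids: CentroidTable,
    mode: str = "deterministic",
    protocol: Protocol = Protocol.FULL,
    cutoff: float = DEFAULT_CUTOFF,
    include_healthy: bool = True,
    min_params: int | None = None,
) -> CohortResult:
    """Allocate a whole cohort; subjects failing preconditions are reported.

    Order is preserved; profiles with too few parameters end up in
    ``result.errors`` rather than being silently dropped.
    """
    if len(profiles) == 0:
        raise ValueError("empty profile list")
    if mode not in ("deterministic", "probabilistic"):
        raise ValueError(f"unknown mode {mode!r}")
    result = CohortResult(allocations=[])
    for profile in profiles:
        try:
            if mode == "deterministic":
                alloc = allocate_deterministic(
                    profile, centroids, protocol, include_healthy, min_params
                )
            else:
                alloc = allocate_probabilistic(
                    profile, centroids, protocol, cutoff, min_params
                )
            result.allocations.append(alloc)
        except NotComputableError as exc:
            result.errors.append((profile.subject_id, str(exc)))
    return result
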