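"""ROC/cutoff derivation and agreement statistics.

The healthy-profile probability doubles as a diagnostic score: a subject is
called healthy when the score exceeds a threshold and patient otherwise.
``roc_healthy`` sweeps every observed score, records sensitivity (fraction
of patients correctly called patient, i.e. score <= threshold) against the
false-positive rate (fraction of healthy subjects called patient), and
integrates the empirical curve by the trapezoid rule — which makes the AUC
identical to the Mann-Whitney U statistic scaled to [0, 1], ties counted
one half.  The operating threshold is chosen by the Youden index
J = sensitivity - FPR.

``cohens_kappa`` gives chance-corrected agreement between two categorical
labelings (e.g. deterministic re-sorting vs an original cluster solution),
and ``summarize_cohort`` tabulates phenotype frequencies and overlap the
way stratified-trial planning consumes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .allocator import Allocation
from .profiles import PATIENT_PHENOTYPES, Phenotype


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC of the healthy-probability score.

    ``thresholds`` ascend and include a -inf sentinel; ``sensitivity`` and
    ``false_positive_rate`` are evaluated with the "patient iff score <=
    threshold" rule, so both are non-decreasing along the sweep.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    false_positive_rate: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    youden_cutoff: float
    youden_value: float
    n_patients: int
    n_healthy: int
    ci_method: str


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    """Standard error of the AUC (Hanley & McNeil 1982 approximation)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(patients: np.ndarray, healthy: np.ndarray) -> float:
    """DeLong standard error of the AUC for patient detection.

    AUC = P(patient score < healthy score) + 0.5 P(tie); the variance is
    estimated from the placement values of each group.
    """
    lt = (patients[:, None] < healthy[None, :]).astype(float)
    lt += 0.5 * (patients[:, None] == healthy[None, :])
    v10 = lt.mean(axis=1)  # placements of patients
    v01 = lt.mean(axis=0)  # placements of healthy subjects
    n1, n2 = len(patients), len(healthy)
    var = 0.0
    if n1 > 1:
        var += np.var(v10, ddof=1) / n1
    if n2 > 1:
        var += np.var(v01, ddof=1) / n2
    return float(np.sqrt(var))


def _youden_from_curve(
    thresholds: np.ndarray, sens: np.ndarray, fpr: np.ndarray
) -> tuple[float, float]:
    """Maximize J = sensitivity - FPR over the swept thresholds.

    Ties in J are broken toward the higher specificity (lower FPR) and then
    toward the higher threshold — the more conservative operating point.
    """
    j = sens - fpr
    jmax = float(np.max(j))
    at_max = np.flatnonzero(j >= jmax - 1e-12)
    best_fpr = fpr[at_max].min()
    at_max = at_max[fpr[at_max] <= best_fpr + 1e-12]
    idx = at_max[np.argmax(thresholds[at_max])]
    return float(thresholds[idx]), float(j[idx])


def roc_healthy(
    scores_patients: Sequence[float],
    scores_healthy: Sequence[float],
    ci_method: str = "hanley-mcneil",
    grid: str = "observed",
) -> ROCResult:
    """ROC analysis of healthy-probability scores (percent, in [0, 100]).

    ``grid='observed'`` sweeps all distinct observed scores (exact);
    ``grid='integer'`` sweeps whole percentages 0..100, mimicking a
    step-per-percent presentation.  ``ci_method`` is ``'hanley-mcneil'``
    (default, normal approximation) or ``'delong'``.
    """
    patients = np.asarray(list(scores_patients), dtype=float)
    healthy = np.asarray(list(scores_healthy), dtype=float)
    if patients.size == 0 or healthy.size == 0:
        raise ValueError("both score lists must be non-empty")
    for name, arr in (("patient", patients), ("healthy", healthy)):
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError(f"{name} scores must lie in [0, 100]")

    if grid == "observed":
        thresholds = np.unique(np.concatenate([patients, healthy]))
    elif grid == "integer":
        thresholds = np.arange(0.0, 101.0)
    else:
        raise ValueError(f"unknown grid {grid!r}")
    thresholds = np.concatenate([[-np.inf], thresholds])

    # patient call: score <= t
    sens = np.array([np.mean(patients <= t) for t in thresholds])
    fpr = np.array([np.mean(healthy <= t) for t in thresholds])

    # trapezoid over the empirical curve == Mann-Whitney U / (n1 n2)
    auc = float(np.trapezoid(sens, fpr))

    degenerate = np.unique(patients).size == 1 and np.array_equal(
        np.unique(patients), np.unique(healthy)
    )
    if degenerate:
        warnings.warn(
            "constant identical scores in both groups: no discrimination, AUC = 0.5",
            stacklevel=2,
        )
        auc = 0.5

    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, len(patients), len(healthy))
    elif ci_method == "delong":
        se = _delong_se(patients, healthy)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    zc = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - zc * se), min(1.0, auc + zc * se))

    cutoff, jval = _youden_from_curve(thresholds, sens, fpr)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        false_positive_rate=fpr,
        auc=auc,
        auc_ci95=ci,
        youden_cutoff=cutoff,
        youden_value=jval,
        n_patients=len(patients),
        n_healthy=len(healthy),
        ci_method=ci_method,
    )


def youden_cutoff(roc: ROCResult) -> tuple[float, float]:
    """(threshold, J) maximizing the Youden index on a computed ROC."""
    return _youden_from_curve(
        roc.thresholds, roc.sensitivity, roc.false_positive_rate
    )


def roc_frame(roc: ROCResult) -> pd.DataFrame:
    """ROC curve points as a table (threshold, sensitivity, FPR, J)."""
    return pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "false_positive_rate": roc.false_positive_rate,
            "youden_j": roc.sensitivity - roc.false_positive_rate,
        }
    )


def plot_roc(roc: ROCResult, path=None, ax=None):
    """Plot the ROC curve (FPR vs sensitivity) with the chance diagonal."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.false_positive_rate, roc.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], linestyle=":", color="green")
    ax.set_xlabel("false-positive rate (1 - specificity)")
    ax.set_ylabel("sensitivity (patients detected)")
    ax.set_title(
        f"AUC = {roc.auc:.3f} "
        f"(95% CI {roc.auc_ci95[0]:.3f}-{roc.auc_ci95[1]:.3f}), "
        f"Youden cutoff = {roc.youden_cutoff:.1f}%"
    )
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between two categorical labelings of the same subjects."""

    n: int
    percent_agreement: float  # 0..100
    kappa: float
    kappa_ci95: tuple[float, float]
    confusion: pd.DataFrame  # rows = labels_a, columns = labels_b


def cohens_kappa(
    labels_a: Sequence, labels_b: Sequence
) -> AgreementResult:
    """Cohen's kappa with a large-sample 95% CI and the confusion table.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from the marginals.  When both labelings are
    the same constant (p_e = 1), kappa is defined as 1 with a warning.
    """
    a = [str(x) for x in labels_a]
    b = [str(x) for x in labels_b]
    if len(a) != len(b):
        raise ValueError(f"label lists differ in length ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("label lists must be non-empty")
    labels = sorted(set(a) | set(b))
    confusion = pd.crosstab(
        pd.Categorical(a, categories=labels),
        pd.Categorical(b, categories=labels),
        dropna=False,
    )
    confusion.index = pd.Index(labels, name="labels_a")
    confusion.columns = pd.Index(labels, name="labels_b")
    n = len(a)
    table = confusion.to_numpy(dtype=float)
    p_o = float(np.trace(table)) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0:
        warnings.warn(
            "both labelings are the same constant; kappa defined as 1",
            stacklevel=2,
        )
        kappa, se = 1.0, 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    zc = sps.norm.ppf(0.975)
    ci = (max(-1.0, kappa - zc * se), min(1.0, kappa + zc * se))
    return AgreementResult(
        n=n,
        percent_agreement=100.0 * p_o,
        kappa=kappa,
        kappa_ci95=ci,
        confusion=confusion,
    )


def _det_summary(allocs: list[Allocation], etiology: str) -> list[dict]:
    n = len(allocs)
    labels = [a.label for a in allocs]
    rows = []
    for pheno in (*PATIENT_PHENOTYPES, Phenotype.HEALTHY):
        count = sum(1 for lab in labels if lab is pheno)
        rows.append(
            {
                "etiology": etiology,
                "phenotype": pheno.value,
                "n": n,
                "count": count,
                "percent": 100.0 * count / n,
            }
        )
    return rows


def _prob_summary(allocs: list[Allocation], etiology: str) -> dict:
    n = len(allocs)
    allocable = [a for a in allocs if not a.excluded]
    n_alloc = len(allocable)
    row: dict[str, object] = {
        "etiology": etiology,
        "n": n,
        "n_allocated": n_alloc,
        "n_excluded": n - n_alloc,
        "n_healthy_flag": sum(a.healthy_flag for a in allocs),
    }
    for pheno in PATIENT_PHENOTYPES:
        count = sum(1 for a in allocable if pheno in a.label_set)
        row[f"count_{pheno.value}"] = count
        row[f"percent_{pheno.value}"] = 100.0 * count / n_alloc if n_alloc else np.nan
    for k in (1, 2, 3):
        row[f"n_exactly_{k}"] = sum(1 for a in allocable if len(a.label_set) == k)
    return row


def summarize_cohort(
    allocations: Sequence[Allocation], by_etiology: bool = False
) -> pd.DataFrame:
    """Phenotype frequencies (deterministic) or overlap counts (probabilistic).

    Deterministic mode yields long-format rows whose percentages sum to
    100% within each stratum.  Probabilistic mode yields one wide row per
    stratum: per-phenotype membership percentages of the allocable
    (non-excluded) subjects — deliberately non-additive — plus counts of
    subjects assigned to exactly 1/2/3 phenotypes, flagged healthy, and
    excluded.  Mixing modes is an error.
    """
    allocs = list(allocations)
    if not allocs:
        raise ValueError("no allocations to summarize")
    modes = {a.mode for a in allocs}
    if len(modes) > 1:
        raise ValueError(f"mixed allocation modes: {sorted(modes)}")
    mode = modes.pop()
    if by_etiology:
        strata: dict[str, list[Allocation]] = {}
        for a in allocs:
            strata.setdefault(a.etiology or "unspecified", []).append(a)
    else:
        strata = {"all": allocs}
    if mode == "deterministic":
        rows = [r for et, group in strata.items() for r in _det_summary(group, et)]
    else:
        rows = [_prob_summary(group, et) for et, group in strata.items()]
    return pd.DataFrame(rows)
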