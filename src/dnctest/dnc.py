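"""The diagnostic core of the Dopamine Neuron Challenge Test.

A subject is challenged pharmacologically to evoke dopamine release and
a metabolite readout is measured.  The diagnostic threshold for an
analyte is the midpoint of the two challenged-state group means:

    T = (mean_challenged_control + mean_challenged_PD) / 2

A subject measuring strictly below T is called positive (hypodopaminergic).
Sensitivity is the fraction of PD subjects called positive; specificity
the fraction of controls called negative.  Percentages are reported as
half-up-rounded integers with the unrounded values retained.

:func:`expected_performance` is the closed-form companion: under Normal
populations with SD = SEM * sqrt(n) (the only dispersion reconstructible
from published summaries), the expected sensitivity and specificity are
normal tail probabilities around the midpoint threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .histology import round_half_up

__all__ = [
    "GroupSummary",
    "SubjectCall",
    "DNCResult",
    "summarize_group",
    "compute_threshold",
    "classify_subject",
    "evaluate_dnc",
    "expected_performance",
    "table1",
]

#: CohortTable column schema shared with the synthetic-cohort generator
COHORT_COLUMNS = ("subject_id", "genotype_group", "state", "matrix", "analyte", "value")


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive mean +/- SEM of one (group, state, analyte) cell."""

    group: str
    state: str
    analyte: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class SubjectCall:
    subject_id: str
    group: str
    value: float
    call: str  # "positive" | "negative"


@dataclass(frozen=True)
class DNCResult:
    """Per-analyte diagnostic outcome in the shape of a published table row."""

    analyte: str
    threshold: float
    n_true_pos: int
    n_total_pd: int
    n_true_neg: int
    n_total_control: int
    sensitivity: float  # unrounded %
    specificity: float  # unrounded %
    per_subject_calls: tuple[SubjectCall, ...]

    @property
    def sensitivity_rounded(self) -> int:
        return round_half_up(self.sensitivity)

    @property
    def specificity_rounded(self) -> int:
        return round_half_up(self.specificity)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_subject_calls"] = [asdict(c) for c in self.per_subject_calls]
        d["sensitivity_rounded"] = self.sensitivity_rounded
        d["specificity_rounded"] = self.specificity_rounded
        return d


def summarize_group(
    values,
    group: str = "",
    state: str = "",
    analyte: str = "",
) -> GroupSummary:
    """Mean and SEM (n-1 SD) of one group's measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("group summary requires n >= 2 values")
    sd = float(np.std(arr, ddof=1))
    return GroupSummary(
        group=group,
        state=state,
        analyte=analyte,
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sem=sd / math.sqrt(arr.size),
    )


def compute_threshold(mean_challenged_control: float, mean_challenged_pd: float) -> float:
    """Midpoint diagnostic threshold of the two challenged-state group means."""
    return (mean_challenged_control + mean_challenged_pd) / 2.0


def classify_subject(value: float, threshold: float, direction: str = "low") -> str:
    """Call one subject against the threshold.

    ``direction="low"`` (the DNC convention: a hypodopaminergic state
    lowers challenged metabolite levels): strictly below the threshold is
    positive; a value equal to the threshold is negative.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite measurement {value!r}")
    if direction == "low":
        return "positive" if value < threshold else "negative"
    if direction == "high":
        return "positive" if value > threshold else "negative"
    raise ValueError(f"unknown direction {direction!r}")


def evaluate_dnc(
    cohort: pd.DataFrame,
    analyte: str,
    state: str = "challenged",
    threshold_state: str = "challenged",
    direction: str = "low",
) -> DNCResult:
    """Threshold, per-subject calls and sensitivity/specificity for one analyte.

    The threshold is always derived from the challenged-state group means
    (``threshold_state``), even when classifying resting-state data —
    the challenge is what separates the groups.  ``cohort`` follows the
    CohortTable schema (see ``COHORT_COLUMNS``).
    """
    sub = cohort[(cohort["analyte"] == analyte) & (cohort["state"] == threshold_state)]
    means = {}
    for grp in ("control", "PD"):
        vals = sub.loc[sub["genotype_group"] == grp, "value"]
        if vals.empty:
            raise ValueError(
                f"cohort lacks {grp} subjects for analyte {analyte!r} "
                f"in state {threshold_state!r}"
            )
        means[grp] = float(vals.mean())
    threshold = compute_threshold(means["control"], means["PD"])

    eval_rows = cohort[(cohort["analyte"] == analyte) & (cohort["state"] == state)]
    calls = tuple(
        SubjectCall(
            subject_id=str(r.subject_id),
            group=str(r.genotype_group),
            value=float(r.value),
            call=classify_subject(float(r.value), threshold, direction),
        )
        for r in eval_rows.itertuples()
    )
    n_total_pd = sum(1 for c in calls if c.group == "PD")
    n_total_control = sum(1 for c in calls if c.group == "control")
    if n_total_pd == 0 or n_total_control == 0:
        raise ValueError(f"state {state!r} lacks one of the groups for analyte {analyte!r}")
    n_tp = sum(1 for c in calls if c.group == "PD" and c.call == "positive")
    n_tn = sum(1 for c in calls if c.group == "control" and c.call == "negative")
    return DNCResult(
        analyte=analyte,
        threshold=threshold,
        n_true_pos=n_tp,
        n_total_pd=n_total_pd,
        n_true_neg=n_tn,
        n_total_control=n_total_control,
        sensitivity=n_tp / n_total_pd * 100.0,
        specificity=n_tn / n_total_control * 100.0,
        per_subject_calls=calls,
    )


def expected_performance(
    mean_c: float,
    sem_c: float,
    n_c: int,
    mean_pd: float,
    sem_pd: float,
    n_pd: int,
) -> tuple[float, float]:
    """Closed-form expected sensitivity and specificity (percent).

    Populations are Normal(mean, SEM * sqrt(n)); with the midpoint
    threshold T the expected sensitivity is P(PD value < T) and the
    expected specificity is P(control value > T):

        sensitivity = Phi((T - mean_pd) / (sem_pd * sqrt(n_pd))) * 100
        specificity = Phi((mean_c - T) / (sem_c * sqrt(n_c))) * 100
    """
    if sem_c <= 0 or sem_pd <= 0:
        raise ValueError("SEMs must be positive")
    t = compute_threshold(mean_c, mean_pd)
    sens = norm.cdf((t - mean_pd) / (sem_pd * math.sqrt(n_pd))) * 100.0
    spec = norm.cdf((mean_c - t) / (sem_c * math.sqrt(n_c))) * 100.0
    return float(sens), float(spec)


def table1(cohort: pd.DataFrame, state: str = "challenged") -> pd.DataFrame:
    """Evaluate every analyte in a cohort and return a summary table.

    Columns mirror the published layout: analyte, threshold, sensitivity
    and specificity with the underlying fractions.
    """
    rows = []
    for analyte in sorted(cohort["analyte"].unique()):
        res = evaluate_dnc(cohort, analyte, state=state)
        rows.append(
            {
                "analyte": res.analyte,
                "threshold": res.threshold,
                "sensitivity_pct": res.sensitivity_rounded,
                "sensitivity_fraction": f"{res.n_true_pos}/{res.n_total_pd}",
                "specificity_pct": res.specificity_rounded,
                "specificity_fraction": f"{res.n_true_neg}/{res.n_total_control}",
            }
        )
    return pd.DataFrame(rows)
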