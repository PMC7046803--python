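"""Comparative-CT qPCR quantification with hemolysis QC.

The serum workflow this implements: technical replicates are collapsed by
mean CT; samples are screened for red-blood-cell contamination with the
hemolysis indicator dCT = CT(miR-23a-3p) - CT(miR-451a), excluding samples
with dCT > 7; target expression is quantified relative to a reference
panel as 2^(-dCT) where dCT = CT(target) - mean(CT(references)) -- the
arithmetic mean in CT space equals the geometric mean of the linear-scale
reference quantities; values are log-converted (base 10 by default) for
normality before group testing with one-way ANOVA and unpaired t-tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

HEMOLYSIS_MARKER_NUM = "miR-23a-3p"
HEMOLYSIS_MARKER_DEN = "miR-451a"
HEMOLYSIS_THRESHOLD = 7.0
NEAR_UNDETECTED_CT = 40.0


@dataclass(frozen=True)
class CtRecord:
    """One raw cycle-threshold measurement."""

    sample_id: str
    assay: str
    ct: float
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ct < 50):
            raise ValueError(
                f"CT {self.ct} for {self.sample_id}/{self.assay} outside (0, 50)"
            )
        if self.ct >= NEAR_UNDETECTED_CT:
            log.warning("CT %.2f for %s/%s is near-undetected (>= %.0f); kept, flagged",
                        self.ct, self.sample_id, self.assay, NEAR_UNDETECTED_CT)


@dataclass
class CtTable:
    """All CT measurements of one panel, plus sample -> group labels."""

    records: list[CtRecord] = field(default_factory=list)
    sample_groups: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.sample_id, r.assay, r.replicate) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (sample, assay, replicate) triples in CT table")

    def sample_ids(self) -> list[str]:
        return sorted({r.sample_id for r in self.records})

    def mean_ct(self, sample_id: str, assay: str) -> float | None:
        """Technical replicates collapsed by mean CT; None when absent."""
        cts = [r.ct for r in self.records if r.sample_id == sample_id and r.assay == assay]
        return float(np.mean(cts)) if cts else None


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    delta_ct_hemolysis: float | None
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class RelExpression:
    """Relative expression of one target in one sample (2^-dCT scale)."""

    sample_id: str
    assay: str
    value: float
    log_value: float
    log_base: float = 10.0


def hemolysis_qc(
    ct_mir23a: float | None,
    ct_mir451a: float | None,
    threshold: float = HEMOLYSIS_THRESHOLD,
    sample_id: str = "",
) -> QCResult:
    """Hemolysis screen: dCT = CT(miR-23a-3p) - CT(miR-451a).

    A sample passes iff dCT <= threshold (strictly greater excluded; the
    boundary value itself passes). A missing marker makes the sample
    un-assessable and it is excluded with a logged reason.
    """
    if ct_mir23a is None or ct_mir451a is None:
        log.warning("sample %s: hemolysis marker missing; excluded as un-assessable", sample_id)
        return QCResult(sample_id, None, False, "hemolysis marker missing")
    if ct_mir23a <= 0 or ct_mir451a <= 0:
        raise ValueError(f"sample {sample_id}: non-positive hemolysis marker CT")
    delta = ct_mir23a - ct_mir451a
    passed = delta <= threshold
    return QCResult(sample_id, delta, passed,
                    "" if passed else f"hemolysis dCT {delta:.2f} > {threshold:g}")


def relative_expression(
    ct_target: float,
    ref_cts: Sequence[float],
    sample_id: str = "",
    assay: str = "",
    log_base: float = 10.0,
) -> RelExpression:
    """Comparative-CT relative expression: 2^-(CT_target - mean(CT_refs)).

    Averaging reference CTs arithmetically is exactly geometric-mean
    normalization of the linear-scale reference quantities.
    """
    if len(ref_cts) == 0:
        raise ValueError(f"sample {sample_id}: no reference CT values")
    delta_ct = ct_target - float(np.mean(ref_cts))
    value = 2.0 ** (-delta_ct)
    return RelExpression(sample_id=sample_id, assay=assay, value=value,
                         log_value=math.log(value, log_base), log_base=log_base)


def fold_change(
    group_values: Sequence[RelExpression | float],
    control_values: Sequence[RelExpression | float],
) -> float:
    """Mean linear-scale expression of a group over its control.

    Equals 2^(-ddCT) when the per-sample values come from comparative CT.
    """
    if not len(group_values) or not len(control_values):
        raise ValueError("fold_change requires non-empty group and control")
    g = [v.value if isinstance(v, RelExpression) else float(v) for v in group_values]
    c = [v.value if isinstance(v, RelExpression) else float(v) for v in control_values]
    return float(np.mean(g) / np.mean(c))


@dataclass
class GroupDescriptives:
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float


@dataclass
class GroupComparison:
    """ANOVA / t-test summary over (log-scale) expression values."""

    design: str
    statistic: float
    p_value: float
    descriptives: dict[str, GroupDescriptives]
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "two_group",
) -> GroupComparison:
    """Compare (log-converted) expression across groups.

    two_group: unpaired two-sided t-test. multi_group: one-way ANOVA
    followed by all pairwise unpaired t-tests. Descriptives (mean, SD,
    min-max) support boxplot-style reporting.
    """
    if design not in ("two_group", "multi_group"):
        raise ValueError(f"unknown design {design!r}")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(v.std(ddof=1) == 0 for v in groups.values()):
        raise ValueError("all groups have zero variance; comparison is degenerate")
    names = sorted(groups)
    desc = {g: GroupDescriptives(n=len(v), mean=float(v.mean()),
                                 sd=float(v.std(ddof=1)),
                                 minimum=float(v.min()), maximum=float(v.max()))
            for g, v in groups.items()}
    if design == "two_group":
        if len(groups) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        t, p = stats.ttest_ind(groups[names[0]], groups[names[1]])
        return GroupComparison("two_group", float(t), float(p), desc)
    f, p = stats.f_oneway(*(groups[g] for g in names))
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, tp = stats.ttest_ind(groups[a], groups[b])
            pairwise[(a, b)] = (float(t), float(tp))
    return GroupComparison("multi_group", float(f), float(p), desc, pairwise)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) for covariate checks."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Table-level workflow
# ---------------------------------------------------------------------------


def qc_table(
    table: CtTable,
    threshold: float = HEMOLYSIS_THRESHOLD,
    marker_num: str = HEMOLYSIS_MARKER_NUM,
    marker_den: str = HEMOLYSIS_MARKER_DEN,
) -> list[QCResult]:
    """Hemolysis QC for every sample of a CT table (replicates collapsed)."""
    out = []
    for sid in table.sample_ids():
        out.append(hemolysis_qc(table.mean_ct(sid, marker_num),
                                table.mean_ct(sid, marker_den),
                                threshold=threshold, sample_id=sid))
    return out


def expression_table(
    table: CtTable,
    target: str,
    reference_assays: Sequence[str],
    qc: list[QCResult] | None = None,
    log_base: float = 10.0,
) -> list[RelExpression]:
    """Relative expression of one target for every QC-passing sample.

    Samples failing QC, or missing the target or any reference assay, are
    skipped with a logged reason.
    """
    passed = {r.sample_id for r in qc if r.passed} if qc is not None else None
    out = []
    for sid in table.sample_ids():
        if passed is not None and sid not in passed:
            continue
        ct_t = table.mean_ct(sid, target)
        refs = [table.mean_ct(sid, a) for a in reference_assays]
        if ct_t is None or any(r is None for r in refs):
            log.warning("sample %s: missing target or reference CT; skipped", sid)
            continue
        out.append(relative_expression(ct_t, [r for r in refs if r is not None],
                                       sample_id=sid, assay=target, log_base=log_base))
    return out
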