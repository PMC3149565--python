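"""Shared/exclusive set partitioning and interval-ratio differential calls.

A protein shared by the two strains is called *increased* in the test
strain when the t-test on its per-run emPAI values gives p < alpha AND
the interval ratio test.lower / reference.upper is >= 1.5; *decreased*
when p < alpha AND test.upper / reference.lower is <= 0.67; otherwise
*constant*.  The two thresholds are kept exactly as printed even though
0.67 != 1/1.5, so the rule is not perfectly symmetric under a strain
swap.  Proteins detected in only one strain are never classified; they
are reported in separate exclusive tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from empaiq.quantification import QuantRecord

INCREASED = "increased"
DECREASED = "decreased"
CONSTANT = "constant"


@dataclass(frozen=True)
class SetPartition:
    shared: frozenset[str]
    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_exclusive_a(self) -> int:
        return len(self.exclusive_a)

    @property
    def n_exclusive_b(self) -> int:
        return len(self.exclusive_b)

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_exclusive_a + self.n_exclusive_b


def partition_sets(ids_a, ids_b) -> SetPartition:
    """Split two identification sets into shared and strain-exclusive parts."""
    a, b = set(ids_a), set(ids_b)
    return SetPartition(
        shared=frozenset(a & b),
        exclusive_a=frozenset(a - b),
        exclusive_b=frozenset(b - a),
    )


@dataclass(frozen=True)
class DifferentialCall:
    accession: str
    ratio_up: float
    ratio_down: float
    p_value: float
    call: str


def _ratio(num: float, den: float) -> float:
    """Interval ratio with the degenerate-denominator convention.

    MEP - MSD can be <= 0; a non-positive denominator with a positive
    numerator is treated as +inf (the gate is trivially met or missed),
    and 0/0 as NaN (no evidence either way -> constant).
    """
    if den > 0:
        return num / den
    if num > 0:
        return math.inf
    return math.nan


def classify(
    test: QuantRecord,
    reference: QuantRecord,
    alpha: float = 0.05,
    up: float = 1.5,
    down: float = 0.67,
    equal_var: bool = False,
) -> DifferentialCall:
    """Classify one shared protein as increased / decreased / constant.

    The t-test is Welch's by default (``equal_var=True`` selects the
    pooled-variance test), two-sided, on the per-run emPAI values of the
    two strains.  A NaN p-value (both strains constant) never passes the
    significance gate.
    """
    if test.accession != reference.accession:
        raise ValueError(f"accession mismatch: {test.accession!r} vs {reference.accession!r}")
    with np.errstate(all="ignore"):
        t_res = stats.ttest_ind(test.values, reference.values, equal_var=equal_var)
    p = float(t_res.pvalue)
    ratio_up = _ratio(test.lower, reference.upper)
    ratio_down = _ratio(test.upper, reference.lower)
    significant = (not math.isnan(p)) and p < alpha
    if significant and ratio_up >= up:
        call = INCREASED
    elif significant and not math.isnan(ratio_down) and ratio_down <= down:
        call = DECREASED
    else:
        call = CONSTANT
    return DifferentialCall(
        accession=test.accession, ratio_up=ratio_up, ratio_down=ratio_down, p_value=p, call=call
    )


def call_table(
    quant_test: dict[str, QuantRecord],
    quant_reference: dict[str, QuantRecord],
    partition: SetPartition,
    alpha: float = 0.05,
    up: float = 1.5,
    down: float = 0.67,
    equal_var: bool = False,
) -> tuple[list[DifferentialCall], dict]:
    """One differential call per shared protein plus summary counts.

    The summary reports counts of each class and the percentage of shared
    proteins that changed, (I + D) / shared, rounded to the nearest
    integer percent.
    """
    missing = sorted(
        acc for acc in partition.shared if acc not in quant_test or acc not in quant_reference
    )
    if missing:
        raise KeyError(f"missing quant records for shared accessions: {missing}")
    calls = [
        classify(quant_test[acc], quant_reference[acc], alpha=alpha, up=up, down=down, equal_var=equal_var)
        for acc in sorted(partition.shared)
    ]
    n_inc = sum(c.call == INCREASED for c in calls)
    n_dec = sum(c.call == DECREASED for c in calls)
    n_const = sum(c.call == CONSTANT for c in calls)
    n_shared = len(calls)
    pct_changed = round(100.0 * (n_inc + n_dec) / n_shared) if n_shared else 0
    pct_constant = round(100.0 * n_const / n_shared) if n_shared else 0
    summary = {
        "shared": n_shared,
        "increased": n_inc,
        "decreased": n_dec,
        "constant": n_const,
        "pct_changed": pct_changed,
        "pct_constant": pct_constant,
    }
    return calls, summary
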