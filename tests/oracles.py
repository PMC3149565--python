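"""Independent brute-force reference implementations used by the tests.

Each oracle is deliberately written by a different route than the library
code it checks: regex enumeration for the digest, direct formula
evaluation for emPAI/MEP/MSD/ddCt, and a root-finder on a separately
coded charge equation for pI.
"""

from __future__ import annotations

import math
import re

import numpy as np
from scipy.optimize import brentq


def brute_digest(sequence: str, missed: int, proline_rule: bool) -> set[tuple[int, str]]:
    """Every substring that is a valid tryptic product: both ends on
    termini or cleavage sites, and at most ``missed`` sites strictly inside."""
    pattern = r"[KR](?!P)" if proline_rule else r"[KR]"
    cuts = {m.end() for m in re.finditer(pattern, sequence) if m.end() < len(sequence)}
    ends = cuts | {0, len(sequence)}
    out = set()
    for i in sorted(ends):
        for j in sorted(ends):
            if j <= i:
                continue
            internal = sum(1 for c in cuts if i < c < j)
            if internal <= missed:
                out.add((i, sequence[i:j]))
    return out


def brute_op(sequence: str, missed: int, low: float, high: float, masses: dict[str, float], water: float) -> int:
    """Unique observable peptides by filtering the brute-force digest."""
    peps = {p for _, p in brute_digest(sequence, missed, proline_rule=True)}
    return sum(1 for p in peps if low <= sum(masses[a] for a in p) + water <= high)


def empai_oracle(sc: int, op: int) -> float:
    return math.pow(10.0, sc / op) - 1.0


def mep_msd_oracle(values) -> tuple[float, float]:
    values = list(values)
    n = len(values)
    mep = sum(values) / n
    msd = math.sqrt(sum((v - mep) ** 2 for v in values) / n)
    return mep, msd


def charge_oracle(sequence: str, ph: float, pk: dict[str, float]) -> float:
    pos = sum(
        [1.0 / (1.0 + 10.0 ** (ph - pk["Nterm"]))]
        + [sequence.count(a) / (1.0 + 10.0 ** (ph - pk[a])) for a in "KRH"]
    )
    neg = sum(
        [1.0 / (1.0 + 10.0 ** (pk["Cterm"] - ph))]
        + [sequence.count(a) / (1.0 + 10.0 ** (pk[a] - ph)) for a in "DECY"]
    )
    return pos - neg


def pi_oracle(sequence: str, pk: dict[str, float]) -> float:
    return brentq(lambda ph: charge_oracle(sequence, ph, pk), 0.0, 14.0, xtol=1e-6)


def ddct_oracle(ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal, efficiency=2.0) -> float:
    ddct = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return efficiency ** (-ddct)


def welch_p_oracle(x, y) -> float:
    """Welch two-sample two-sided t-test from the textbook formulas."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
    tstat = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return 2.0 * tdist.sf(abs(tstat), df)
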