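"""Delta-delta-Ct relative quantification for RT-PCR confirmation.

For each sample, the target gene's threshold cycle is normalized against
a reference gene (here the principal sigma factor, sigA):
dCt = Ct_target - Ct_reference.  The test sample is then compared with a
calibrator sample, ddCt = dCt_test - dCt_calibrator, and relative
expression is efficiency**(-ddCt) with the classic assumption of perfect
amplification efficiency (2.0 — one doubling per cycle) unless an
efficiency-corrected value is supplied.  The calibrator's own relative
expression is 1 by construction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


class MissingCtError(KeyError):
    """A required (sample, gene) Ct measurement is absent."""


def _mean_ct(ct_table: pd.DataFrame, sample: str, gene: str) -> float:
    rows = ct_table[(ct_table["sample"] == sample) & (ct_table["gene"] == gene)]
    if rows.empty:
        raise MissingCtError(f"no Ct measurement for sample {sample!r}, gene {gene!r}")
    return float(rows["ct"].mean())


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
    test_sample: str,
    efficiency: float = 2.0,
) -> float:
    """Relative expression of a target gene, test vs calibrator sample.

    Replicate Ct measurements of the same (sample, gene) are averaged
    before the ddCt arithmetic, which on the log scale equals the
    geometric mean of per-replicate fold values.
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must be > 1, got {efficiency}")
    dct_test = _mean_ct(ct_table, test_sample, target_gene) - _mean_ct(ct_table, test_sample, reference_gene)
    dct_cal = _mean_ct(ct_table, calibrator_sample, target_gene) - _mean_ct(
        ct_table, calibrator_sample, reference_gene
    )
    return float(efficiency ** (-(dct_test - dct_cal)))


def ddct_replicates(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
    test_sample: str,
    efficiency: float = 2.0,
) -> list[float]:
    """Per-determination fold values, pairing replicates by order of appearance.

    The calibrator dCt is the replicate-mean (the fixed baseline against
    which each test determination is expressed).
    """
    tgt = ct_table[(ct_table["sample"] == test_sample) & (ct_table["gene"] == target_gene)]["ct"].to_numpy()
    ref = ct_table[(ct_table["sample"] == test_sample) & (ct_table["gene"] == reference_gene)]["ct"].to_numpy()
    if tgt.size == 0 or ref.size == 0:
        raise MissingCtError(f"no Ct replicates for {test_sample!r}/{target_gene!r} or reference")
    if tgt.size != ref.size:
        raise ValueError(f"unequal replicate counts for target ({tgt.size}) and reference ({ref.size})")
    dct_cal = _mean_ct(ct_table, calibrator_sample, target_gene) - _mean_ct(
        ct_table, calibrator_sample, reference_gene
    )
    return [float(efficiency ** (-((t - r) - dct_cal))) for t, r in zip(tgt, ref)]


def replicate_summary(folds, sd: bool = False) -> tuple[float, float]:
    """Mean fold change and its error bar over replicate determinations.

    The error bar is the standard error of the mean by default; ``sd=True``
    reports the sample standard deviation instead.
    """
    arr = np.asarray(list(folds), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 replicate determinations, got {arr.size}")
    mean = float(arr.mean())
    spread = float(arr.std(ddof=1))
    return mean, (spread if sd else spread / math.sqrt(arr.size))
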