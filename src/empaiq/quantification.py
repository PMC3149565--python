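"""emPAI abundance estimates and per-strain MEP/MSD interval summaries.

emPAI (exponentially modified protein abundance index) is computed per
protein per run as ``10**(SC/OP) - 1``, where SC is the spectral count of
the protein in that run and OP its number of observable tryptic peptides.
Per strain, abundance is summarized over the replicate runs as the mean
emPAI (MEP) and its root-mean-square deviation (MSD); the interval
[MEP - MSD, MEP + MSD] drives the differential classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedAbundanceError(ValueError):
    """A protein with no observable peptides has no defined emPAI."""


def empai(sc: float, op: int) -> float:
    """emPAI = 10^(SC/OP) - 1; zero iff SC = 0.

    Parameters
    ----------
    sc : non-negative spectral count of the protein in one run.
    op : number of observable peptides of the protein (>= 1).
    """
    if op < 1:
        raise UndefinedAbundanceError(f"OP must be >= 1, got {op} (no observable peptides)")
    if sc < 0:
        raise ValueError(f"spectral count must be >= 0, got {sc}")
    return 10.0 ** (sc / op) - 1.0


def summarize(values, sample_sd: bool = False) -> tuple[float, float]:
    """Mean emPAI (MEP) and mean-square deviation (MSD) over replicate runs.

    MSD is the population RMS deviation about the mean (divide by n).  With
    ``sample_sd=True`` the n-1 sample standard deviation is used instead.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 replicate values to summarize, got {arr.size}")
    mep = float(arr.mean())
    msd = float(arr.std(ddof=1 if sample_sd else 0))
    return mep, msd


@dataclass(frozen=True)
class QuantRecord:
    """Per-protein per-strain quantification summary."""

    accession: str
    strain: str
    values: tuple[float, ...]
    mep: float
    msd: float

    @property
    def lower(self) -> float:
        return self.mep - self.msd

    @property
    def upper(self) -> float:
        return self.mep + self.msd

    @classmethod
    def from_values(cls, accession: str, strain: str, values, sample_sd: bool = False) -> "QuantRecord":
        mep, msd = summarize(values, sample_sd=sample_sd)
        return cls(accession=accession, strain=strain, values=tuple(float(v) for v in values), mep=mep, msd=msd)


def quantify(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    op: dict[str, int],
    sample_sd: bool = False,
) -> dict[str, dict[str, QuantRecord]]:
    """emPAI quantification of a spectral-count matrix, per strain.

    Parameters
    ----------
    counts : wide matrix of integer spectral counts, index = accession,
        columns = run ids.  A run in which a protein was not detected
        carries SC = 0, which contributes emPAI = 0 (not a missing value).
    design : run annotation with columns ``run_id`` and ``strain``.
    op : observable-peptide count per accession (from the digestion stage).

    Returns
    -------
    {strain: {accession: QuantRecord}}.
    """
    missing = [acc for acc in counts.index if acc not in op]
    if missing:
        raise KeyError(f"no OP entry for accessions: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    out: dict[str, dict[str, QuantRecord]] = {}
    for strain, runs in design.groupby("strain")["run_id"]:
        run_ids = [r for r in counts.columns if r in set(runs)]
        block = counts[run_ids]
        records = {}
        for acc, row in block.iterrows():
            vals = [empai(int(sc), op[acc]) for sc in row]
            records[acc] = QuantRecord.from_values(acc, strain, vals, sample_sd=sample_sd)
        out[strain] = records
    return out


def quant_frame(records: dict[str, QuantRecord]) -> pd.DataFrame:
    """Flatten one strain's QuantRecords into the quant-table layout."""
    rows = [
        {
            "accession": r.accession,
            "strain": r.strain,
            "MEP": r.mep,
            "MSD": r.msd,
            "lower": r.lower,
            "upper": r.upper,
            "run_values": ";".join(format(v, ".6g") for v in r.values),
        }
        for r in records.values()
    ]
    return pd.DataFrame(rows).sort_values("accession").reset_index(drop=True)
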