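"""Functional-category profiling and theoretical pI / Mw computation.

Proteins are binned into ten functional categories via a flat
accession-to-category map (derived from GO biological-process terms);
accessions absent from the map fall into a "no description" category.
Between-strain comparison is by percentage fold change: the percentage
of a category in the test strain's protein set divided by the
percentage of the same category in the reference strain's set.

Theoretical pI is the pH of zero net charge under the
Henderson-Hasselbalch model over the termini and the D, E, C, Y, H, K, R
side chains, solved by bisection; Mw is the sum of average residue
masses plus one water.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from empaiq.digestion import peptide_mass, validate_sequence

DEFAULT_CATEGORIES: tuple[str, ...] = (
    "biosynthetic process",
    "catabolic process",
    "oxidation reduction",
    "transcription",
    "translation",
    "transport",
    "TCA cycle",
    "proteolysis",
    "glycolysis",
    "other",
)

UNMAPPED_CATEGORY = "no description"

# EMBOSS pK scale: widely used defaults for theoretical pI.  pI shifts by
# roughly 0.1-0.3 pH units between published scales; the scale in use is
# echoed into pipeline metadata.
EMBOSS_PK: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


def assign_category(accession: str, go_map: Mapping[str, str]) -> str:
    """Category of one accession, or "no description" when unmapped."""
    return go_map.get(accession, UNMAPPED_CATEGORY)


@dataclass(frozen=True)
class CategoryProfile:
    strain: str
    counts: dict[str, int]
    n_total: int

    @property
    def percentages(self) -> dict[str, float]:
        return {c: 100.0 * n / self.n_total for c, n in self.counts.items()}


def category_profile(
    accessions: Iterable[str],
    go_map: Mapping[str, str],
    strain: str = "",
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> CategoryProfile:
    """Count and percentage per category over a protein set."""
    accs = list(accessions)
    if not accs:
        raise ValueError("cannot profile an empty protein set")
    counts = {c: 0 for c in categories}
    counts[UNMAPPED_CATEGORY] = 0
    for acc in accs:
        cat = assign_category(acc, go_map)
        if cat not in counts:
            counts[cat] = 0
        counts[cat] += 1
    return CategoryProfile(strain=strain, counts=counts, n_total=len(accs))


def category_fold_change(profile_test: CategoryProfile, profile_reference: CategoryProfile) -> dict[str, float | None]:
    """Per-category percentage ratio, test over reference.

    A value > 1 indicates the category is enriched in the test strain's
    set.  A zero reference percentage makes the ratio undefined, flagged
    as None rather than infinity.
    """
    pct_t = profile_test.percentages
    pct_r = profile_reference.percentages
    cats = set(pct_t) | set(pct_r)
    out: dict[str, float | None] = {}
    for c in sorted(cats):
        num, den = pct_t.get(c, 0.0), pct_r.get(c, 0.0)
        out[c] = num / den if den > 0 else None
    return out


def net_charge(sequence: str, ph: float, pk: Mapping[str, float] = EMBOSS_PK) -> float:
    """Net protein charge at a pH (Henderson-Hasselbalch, elementary charges)."""
    charge = 1.0 / (1.0 + 10.0 ** (ph - pk["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pk["Cterm"] - ph))
    for aa in _POSITIVE:
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pk[aa]))
    for aa in _NEGATIVE:
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pk[aa] - ph))
    return charge


def protein_pi(sequence: str, pk: Mapping[str, float] = EMBOSS_PK, tol: float = 0.01) -> float:
    """Theoretical isoelectric point by bisection.

    Net charge is strictly decreasing in pH, so bisection on [0, 14]
    converges unconditionally; the default tolerance is 0.01 pH units.
    """
    validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pk) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_mw(sequence: str) -> float:
    """Average molecular weight in Da."""
    return peptide_mass(sequence, mass_type="average")


def distribution_bins(values, edges) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts and percentages over half-open bins [low, high).

    The last bin is closed on both sides.  Percentages are relative to
    the number of input values (values outside the edges are counted in
    the total but fall in no bin).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a sorted 1-D array of >= 2 values")
    values = np.asarray(list(values), dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    pct = 100.0 * counts / values.size if values.size else np.zeros_like(counts, dtype=float)
    return counts, pct
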