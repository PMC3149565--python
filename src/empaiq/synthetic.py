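"""Synthetic two-strain proteomics data with the structure the analysis assumes.

The generator emulates a label-free comparative experiment on two
bacterial strains: a proteome of a few hundred proteins with realistic
length spread, a 2 strains x 2 biomasses x 3 technical replicates design
(six runs per strain), overdispersed spectral counts with planted
fold-change effects on designated proteins, strain-exclusive proteins,
a flat functional-category map, and a Ct table for the RT-PCR stage.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from empaiq.annotation import DEFAULT_CATEGORIES
from empaiq.digestion import CANONICAL_RESIDUES, DigestParams, observable_peptide_count

STRAIN_A = "SP06081"  # reference (parent) strain
STRAIN_B = "PR2"      # test (derived) strain

ROLE_NULL = "null"
ROLE_UP = "up"
ROLE_DOWN = "down"
ROLE_EXCLUSIVE_A = "exclusive_a"
ROLE_EXCLUSIVE_B = "exclusive_b"


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated two-strain experiment.

    Defaults mirror the design the analysis targets: 288 proteins of
    which 84 and 64 are exclusive to one strain (140 shared), planted
    5-fold effects on 21 up- and 23 down-regulated proteins, and two
    biological x three technical replicates per strain.  Protein lengths
    emulate large multidomain bacterial enzymes (polyketide-synthase
    scale); together with the 28-40 expected spectra per run they keep
    SC/OP in the regime where the emPAI interval classifier has
    near-complete power against 5-fold planted effects under Poisson
    count sampling.
    """

    n_proteins: int = 288
    length_range: tuple[int, int] = (1300, 1900)
    n_up: int = 21
    n_down: int = 23
    effect_fold: float = 5.0
    n_exclusive_a: int = 84
    n_exclusive_b: int = 64
    base_abundance_range: tuple[float, float] = (28.0, 40.0)
    dispersion: float = 0.2
    n_biomass: int = 2
    n_technical: int = 3
    exclusive_mode: str = "absent"  # "absent" (structural zero) or "dropout"
    dropout_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SimulationConfigError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise SimulationConfigError("length_range lower bound must be >= 30 and <= upper bound")
        for name in ("n_up", "n_down", "n_exclusive_a", "n_exclusive_b"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.n_up + self.n_down + self.n_exclusive_a + self.n_exclusive_b > self.n_proteins:
            raise SimulationConfigError(
                "n_up + n_down + n_exclusive_a + n_exclusive_b must be <= n_proteins"
            )
        if not self.effect_fold > 0:
            raise SimulationConfigError("effect_fold must be > 0")
        if self.dispersion < 0:
            raise SimulationConfigError("dispersion must be >= 0")
        blo, bhi = self.base_abundance_range
        if not (0 < blo <= bhi):
            raise SimulationConfigError("base_abundance_range must satisfy 0 < low <= high")
        if self.n_biomass < 1 or self.n_technical < 1:
            raise SimulationConfigError("n_biomass and n_technical must be >= 1")
        if self.exclusive_mode not in ("absent", "dropout"):
            raise SimulationConfigError("exclusive_mode must be 'absent' or 'dropout'")

    @property
    def runs_per_strain(self) -> int:
        return self.n_biomass * self.n_technical


@dataclass(frozen=True)
class ProteinEntry:
    """One database protein: accession, description, sequence, category."""

    accession: str
    description: str
    sequence: str
    category: str


@dataclass
class SpectralCountMatrix:
    """Integer spectral counts per (protein, run) with the run design map."""

    counts: pd.DataFrame  # index accession, columns run_id
    design: pd.DataFrame  # run_id, strain, biomass, replicate
    roles: dict[str, str]  # accession -> planted role

    def strain_runs(self, strain: str) -> list[str]:
        return list(self.design.loc[self.design["strain"] == strain, "run_id"])

    def detected(self, strain: str) -> set[str]:
        """Accessions with at least one spectrum in any run of a strain."""
        block = self.counts[self.strain_runs(strain)]
        return set(block.index[block.sum(axis=1) > 0])


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # Independent deterministic streams per stage so that e.g. regenerating
    # the proteome does not shift the count noise.  crc32 keys the stream
    # name stably across processes (str hash is salted per interpreter).
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def generate_proteome(config: SimulationConfig) -> list[ProteinEntry]:
    """Random protein database over the 20 canonical residues.

    Residues are i.i.d. with a uniform background, which puts K+R at 10%
    of residues — ample tryptic sites for peptides inside the scan
    window.  Any sequence that would still yield zero observable peptides
    is redrawn, so emPAI is defined for every entry.  Categories are
    assigned uniformly over the ten functional categories.
    """
    rng = _rng(config, "proteome")
    residues = np.array(list(CANONICAL_RESIDUES))
    params = DigestParams()
    entries: list[ProteinEntry] = []
    width = max(4, len(str(config.n_proteins)))
    for i in range(config.n_proteins):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        while True:
            seq = "".join(rng.choice(residues, size=length))
            if observable_peptide_count(seq, params) >= 1:
                break
        cat = DEFAULT_CATEGORIES[int(rng.integers(len(DEFAULT_CATEGORIES)))]
        acc = f"SYN{i + 1:0{width}d}"
        entries.append(
            ProteinEntry(
                accession=acc,
                description=f"synthetic protein {i + 1} ({cat})",
                sequence=seq,
                category=cat,
            )
        )
    return entries


def assign_roles(proteome: list[ProteinEntry], config: SimulationConfig) -> dict[str, str]:
    """Planted role per accession, drawn deterministically from the seed."""
    rng = _rng(config, "roles")
    order = rng.permutation(len(proteome))
    roles = {p.accession: ROLE_NULL for p in proteome}
    cursor = 0
    for role, n in (
        (ROLE_UP, config.n_up),
        (ROLE_DOWN, config.n_down),
        (ROLE_EXCLUSIVE_A, config.n_exclusive_a),
        (ROLE_EXCLUSIVE_B, config.n_exclusive_b),
    ):
        for j in order[cursor : cursor + n]:
            roles[proteome[j].accession] = role
        cursor += n
    return roles


def _sample_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(proteome: list[ProteinEntry], config: SimulationConfig) -> SpectralCountMatrix:
    """Overdispersed spectral counts for the 12-run two-strain design.

    Counts are negative binomial with variance mu + dispersion * mu**2
    (Poisson when dispersion = 0).  Up-planted proteins have their mean
    multiplied by ``effect_fold`` in the test strain, down-planted
    divided; exclusive proteins are structurally absent (mean 0) from the
    other strain by default, or sampled at a small residual mean in
    "dropout" mode.
    """
    if not proteome:
        raise ValueError("proteome must be nonempty")
    rng = _rng(config, "counts")
    roles = assign_roles(proteome, config)
    design_rows = []
    for strain in (STRAIN_A, STRAIN_B):
        for b in range(1, config.n_biomass + 1):
            for t in range(1, config.n_technical + 1):
                design_rows.append(
                    {"run_id": f"{strain}_B{b}_T{t}", "strain": strain, "biomass": b, "replicate": t}
                )
    design = pd.DataFrame(design_rows)
    runs_a = [r["run_id"] for r in design_rows if r["strain"] == STRAIN_A]
    runs_b = [r["run_id"] for r in design_rows if r["strain"] == STRAIN_B]

    base = rng.uniform(*config.base_abundance_range, size=len(proteome))
    off_mean = {"absent": 0.0, "dropout": config.dropout_fraction}[config.exclusive_mode]
    data = {}
    for i, prot in enumerate(proteome):
        role = roles[prot.accession]
        mean_a, mean_b = base[i], base[i]
        if role == ROLE_UP:
            mean_b = base[i] * config.effect_fold
        elif role == ROLE_DOWN:
            mean_b = base[i] / config.effect_fold
        elif role == ROLE_EXCLUSIVE_A:
            mean_b = base[i] * off_mean
        elif role == ROLE_EXCLUSIVE_B:
            mean_a = base[i] * off_mean
        row = np.concatenate(
            [
                _sample_counts(rng, mean_a, config.dispersion, len(runs_a)),
                _sample_counts(rng, mean_b, config.dispersion, len(runs_b)),
            ]
        )
        data[prot.accession] = row
    counts = pd.DataFrame.from_dict(data, orient="index", columns=runs_a + runs_b)
    counts.index.name = "accession"
    return SpectralCountMatrix(counts=counts, design=design, roles=roles)


def generate_ct_table(
    fold_changes: Mapping[str, float],
    seed: int = 0,
    reference_gene: str = "sigA",
    calibrator_sample: str = STRAIN_A,
    test_sample: str = STRAIN_B,
    n_replicates: int = 6,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Ct table whose ddCt back-calculation recovers ``fold_changes``.

    The reference gene cycles at Ct 18 in both samples; each target gene
    cycles at a gene-specific baseline in the calibrator and is shifted
    by -log2(fold) cycles in the test sample, so at zero noise the
    delta-delta-Ct arithmetic returns the planted fold exactly.  Optional
    Gaussian noise (cycles) is added per replicate measurement.
    """
    bad = {g: f for g, f in fold_changes.items() if not f > 0}
    if bad:
        raise ValueError(f"fold changes must be positive, got {bad}")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample: str, gene: str, ct: float) -> None:
        for _ in range(n_replicates):
            value = ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"sample": sample, "gene": gene, "ct": value})

    for sample in (calibrator_sample, test_sample):
        emit(sample, reference_gene, 18.0)
    for k, (gene, fold) in enumerate(sorted(fold_changes.items())):
        base_ct = 24.0 + k  # spread targets over realistic Ct values
        emit(calibrator_sample, gene, base_ct)
        emit(test_sample, gene, base_ct - math.log2(fold))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers: plain-text artifacts in the pipeline's exchange formats.

def write_fasta(proteome: list[ProteinEntry], path: Path | str) -> None:
    """Standard FASTA, 60-character wrapped."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.description) for p in proteome
    ]
    seqio_write(records, str(path), "fasta")


def write_counts_tsv(matrix: SpectralCountMatrix, path: Path | str) -> None:
    long = (
        matrix.counts.reset_index()
        .melt(id_vars="accession", var_name="run_id", value_name="spectral_count")
        .sort_values(["accession", "run_id"])
    )
    long.to_csv(path, sep="\t", index=False)


def write_design_tsv(matrix: SpectralCountMatrix, path: Path | str) -> None:
    matrix.design.to_csv(path, sep="\t", index=False)


def write_go_map_tsv(proteome: list[ProteinEntry], path: Path | str) -> None:
    pd.DataFrame(
        [{"accession": p.accession, "category": p.category} for p in proteome]
    ).to_csv(path, sep="\t", index=False)


def write_ct_tsv(ct_table: pd.DataFrame, path: Path | str) -> None:
    ct_table.to_csv(path, sep="\t", index=False)


def write_sidecar(config: SimulationConfig, path: Path | str) -> None:
    """Echo every simulation parameter and the seed to a JSON sidecar."""
    payload = asdict(config)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def generate_dataset(config: SimulationConfig, outdir: Path | str) -> dict[str, Path]:
    """Generate and write the full synthetic bundle; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config)
    matrix = simulate_counts(proteome, config)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "go_map": outdir / "go_map.tsv",
        "sidecar": outdir / "simulation.json",
    }
    write_fasta(proteome, paths["fasta"])
    write_counts_tsv(matrix, paths["counts"])
    write_design_tsv(matrix, paths["design"])
    write_go_map_tsv(proteome, paths["go_map"])
    write_sidecar(config, paths["sidecar"])
    return paths
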