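"""End-to-end orchestration: digestion -> quantification -> differential
calls -> category profiles -> pI/Mw histograms -> optional ddCt table.

The pipeline consumes plain-text exchange formats (FASTA database,
long-format counts TSV, design TSV, accession-to-category TSV, optional
Ct TSV) and emits TSV/JSON artifacts into an output directory, each run
stamped with the configuration hash and seed so reruns are auditable and
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from empaiq import annotation, differential, quantification, rtpcr
from empaiq.digestion import DigestParams, op_table

DEFAULT_PI_EDGES = [2.0, 3.0, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0]
DEFAULT_MW_EDGES_KDA = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 200.0]


@dataclass
class PipelineConfig:
    fasta: str
    counts: str
    design: str
    go_map: str | None = None
    ct_table: str | None = None
    reference_strain: str = "SP06081"
    test_strain: str = "PR2"
    missed_cleavages: int = 0
    mass_window: tuple[float, float] = (600.0, 3500.0)
    mass_type: str = "monoisotopic"
    proline_rule: bool = True
    count_unique_only: bool = True
    alpha: float = 0.05
    up_threshold: float = 1.5
    down_threshold: float = 0.67
    sample_sd: bool = False
    equal_var: bool = False
    reference_gene: str = "sigA"
    pi_edges: list[float] = field(default_factory=lambda: list(DEFAULT_PI_EDGES))
    mw_edges_kda: list[float] = field(default_factory=lambda: list(DEFAULT_MW_EDGES_KDA))
    outdir: str = "empaiq_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.up_threshold > 1.0 > self.down_threshold > 0.0):
            raise ValueError("thresholds must satisfy up > 1 > down > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def digest_params(self) -> DigestParams:
        return DigestParams(
            missed_cleavages=self.missed_cleavages,
            mass_window=tuple(self.mass_window),
            mass_type=self.mass_type,
            proline_rule=self.proline_rule,
            count_unique_only=self.count_unique_only,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_counts(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="accession", columns="run_id", values="spectral_count").fillna(0).astype(int)
    wide.columns.name = None
    return wide.sort_index()


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_go_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"], df["category"]))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns a dict with the differential summary, the partition sizes,
    and the path of every emitted artifact.  On failure all artifacts
    written by this invocation are removed and the error names the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = outdir / name
        _write_tsv(df, path)
        written.append(path)
        return path

    stage = "load-inputs"
    try:
        sequences = read_fasta(config.fasta)
        counts = read_counts(config.counts)
        design = read_design(config.design)
        go_map = read_go_map(config.go_map) if config.go_map else {}
        strains = set(design["strain"])
        for s in (config.reference_strain, config.test_strain):
            if s not in strains:
                raise ValueError(f"strain {s!r} not present in design (has {sorted(strains)})")

        stage = "digestion"
        params = config.digest_params()
        ops = op_table(sequences, params)
        emit("op_table.tsv", pd.DataFrame(sorted(ops.items()), columns=["accession", "OP"]))

        stage = "quantification"
        quant = quantification.quantify(counts, design, ops, sample_sd=config.sample_sd)
        for strain, records in sorted(quant.items()):
            emit(f"quant_{strain}.tsv", quantification.quant_frame(records))

        stage = "partition"
        detected = {
            strain: set(
                counts[list(design.loc[design["strain"] == strain, "run_id"])]
                .pipe(lambda b: b.index[b.sum(axis=1) > 0])
            )
            for strain in (config.reference_strain, config.test_strain)
        }
        part = differential.partition_sets(
            detected[config.reference_strain], detected[config.test_strain]
        )
        emit(
            "partition.tsv",
            pd.DataFrame(
                [
                    {"set": "shared", "size": part.n_shared},
                    {"set": f"exclusive_{config.reference_strain}", "size": part.n_exclusive_a},
                    {"set": f"exclusive_{config.test_strain}", "size": part.n_exclusive_b},
                    {"set": "union", "size": part.n_union},
                ]
            ),
        )
        for label, ids in (
            (config.reference_strain, part.exclusive_a),
            (config.test_strain, part.exclusive_b),
        ):
            emit(f"exclusive_{label}.tsv", pd.DataFrame({"accession": sorted(ids)}))

        stage = "differential"
        calls, summary = differential.call_table(
            quant[config.test_strain],
            quant[config.reference_strain],
            part,
            alpha=config.alpha,
            up=config.up_threshold,
            down=config.down_threshold,
            equal_var=config.equal_var,
        )
        call_rows = []
        for c in calls:
            qt = quant[config.test_strain][c.accession]
            qr = quant[config.reference_strain][c.accession]
            call_rows.append(
                {
                    "accession": c.accession,
                    f"MEP_{config.test_strain}": qt.mep,
                    f"MSD_{config.test_strain}": qt.msd,
                    f"MEP_{config.reference_strain}": qr.mep,
                    f"MSD_{config.reference_strain}": qr.msd,
                    "ratio_up": c.ratio_up,
                    "ratio_down": c.ratio_down,
                    "p_value": c.p_value,
                    "call": c.call,
                }
            )
        emit("calls.tsv", pd.DataFrame(call_rows))
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps({**summary, **stamp}, indent=2, sort_keys=True) + "\n")
        written.append(summary_path)

        stage = "annotation"
        profiles = {}
        for strain in (config.reference_strain, config.test_strain):
            prof = annotation.category_profile(sorted(detected[strain]), go_map, strain=strain)
            profiles[strain] = prof
            emit(
                f"category_profile_{strain}.tsv",
                pd.DataFrame(
                    [
                        {"category": c, "count": n, "percentage": prof.percentages[c]}
                        for c, n in prof.counts.items()
                    ]
                ),
            )
        fold = annotation.category_fold_change(
            profiles[config.test_strain], profiles[config.reference_strain]
        )
        emit(
            "category_fold_change.tsv",
            pd.DataFrame(
                [
                    {"category": c, "fold_change": "" if v is None else format(v, ".6g")}
                    for c, v in fold.items()
                ]
            ),
        )

        stage = "pi-mw"
        pim_rows = [
            {
                "accession": acc,
                "pI": annotation.protein_pi(seq),
                "Mw_kDa": annotation.protein_mw(seq) / 1000.0,
            }
            for acc, seq in sorted(sequences.items())
        ]
        pim = pd.DataFrame(pim_rows)
        emit("pi_mw.tsv", pim)
        for col, edges, name in (
            ("pI", config.pi_edges, "pi_hist.tsv"),
            ("Mw_kDa", config.mw_edges_kda, "mw_hist.tsv"),
        ):
            cnt, pct = annotation.distribution_bins(pim[col], edges)
            emit(
                name,
                pd.DataFrame(
                    {
                        "bin_low": edges[:-1],
                        "bin_high": edges[1:],
                        "count": cnt,
                        "percentage": pct,
                    }
                ),
            )

        if config.ct_table:
            stage = "ddct"
            ct = pd.read_csv(config.ct_table, sep="\t")
            genes = sorted(g for g in ct["gene"].unique() if g != config.reference_gene)
            rows = []
            for gene in genes:
                folds = rtpcr.ddct_replicates(
                    ct,
                    gene,
                    config.reference_gene,
                    calibrator_sample=config.reference_strain,
                    test_sample=config.test_strain,
                )
                mean, err = rtpcr.replicate_summary(folds)
                rows.append(
                    {"gene": gene, "relative_expression": mean, "sem": err, "n": len(folds)}
                )
            emit("ddct.tsv", pd.DataFrame(rows))

        stage = "metadata"
        meta_path = outdir / "run_metadata.json"
        meta_path.write_text(
            json.dumps(
                {
                    **stamp,
                    "config": asdict(config),
                    "n_proteins_db": len(sequences),
                    "n_runs": int(design.shape[0]),
                    "pI_pk_scale": "EMBOSS",
                    "partition": {
                        "shared": part.n_shared,
                        "exclusive_a": part.n_exclusive_a,
                        "exclusive_b": part.n_exclusive_b,
                        "union": part.n_union,
                    },
                    "summary": summary,
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )
        written.append(meta_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "summary": summary,
        "partition": part,
        "calls": calls,
        "outputs": {p.name: p for p in written},
    }
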