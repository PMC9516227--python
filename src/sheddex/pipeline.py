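"""End-to-end orchestration with a single config and an audit manifest.

Stages run in dependency order (simulate -> preprocess -> de -> shed ->
annotate -> corrmap); every output is a TSV/JSON/FASTA/Newick file under
config.out_dir, and a manifest records the config plus a sha256 of every
file written, so a rerun with the same config and inputs is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import cleavage, corrmap, diffexpr, io, preprocess, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths, thresholds, and stage toggles for one pipeline run."""

    out_dir: str = "sheddex_run"
    seed: int = 0

    # inputs (unused when simulation is enabled)
    peptides: str | None = None
    groups: str | None = None
    fasta: str | None = None
    topology: str | None = None
    protease_db: str | None = None

    # simulation design
    simulate: bool = True
    n_proteins: int = 300
    length_min: int = 300
    length_max: int = 900
    n_case: int = 15
    n_control: int = 15
    n_shed: int = 30
    n_secretion: int = 30
    shed_fold: float = 1.0 / 3.0
    secretion_fold: float = 2.0
    cv: float = 0.2
    missing_rate: float = 0.1

    # thresholds
    min_frac: float = 0.75
    peptide_min_frac: float = 0.5
    alpha: float = 0.05
    fc: float = 1.5
    min_sig: int = 2
    b_start: float = 0.05
    b_end: float = 0.95
    b_step: float = 0.01
    k_mad: float = 4.0
    n_min: int = 5
    corr_k: int = 4

    # stage toggles
    run_de: bool = True
    run_shed: bool = True
    run_annotate: bool = True
    run_corrmap: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_frac <= 1 or not 0 < self.peptide_min_frac < 1:
            raise ValueError("completeness fractions out of range")
        if not 0 < self.alpha < 1 or self.fc < 1 or self.min_sig < 2:
            raise ValueError("threshold out of documented range")
        if not 0 < self.b_start < self.b_end < 1 or self.b_step <= 0:
            raise ValueError("invalid boundary grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # name -> sha256
    elapsed_s: float = 0.0
    manifest_path: str = ""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages; returns a report of counts/hashes."""
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    def emit(name: str) -> None:
        report.outputs[name] = _sha256(out_dir / name)

    # ---- stage: simulate or load --------------------------------------
    if config.simulate:
        logger.info("simulate: %d proteins, %d shed, %d secretion",
                    config.n_proteins, config.n_shed, config.n_secretion)
        catalog = simulate.generate_catalog(
            config.n_proteins,
            (config.length_min, config.length_max),
            seed=config.seed,
        )
        truth = simulate.plan_truth(
            catalog,
            n_shed=config.n_shed,
            n_secretion=config.n_secretion,
            shed_fold=config.shed_fold,
            secretion_fold=config.secretion_fold,
            seed=config.seed + 1,
        )
        design = simulate.SimDesign(
            n_case=config.n_case,
            n_control=config.n_control,
            cv=config.cv,
            missing_rate=config.missing_rate,
            seed=config.seed + 2,
        )
        peptides = simulate.simulate_study(catalog, design, truth)
        lengths = catalog.lengths
        io.write_fasta(catalog.sequences(), out_dir / "catalog.fasta")
        simulate.truth_to_frame(truth).to_csv(
            out_dir / "truth.tsv", sep="\t", index=False
        )
        emit("catalog.fasta")
        emit("truth.tsv")
    else:
        if not (config.peptides and config.groups and config.fasta):
            raise ValueError(
                "peptides, groups and fasta paths required when simulation "
                "is disabled"
            )
        peptides = io.read_peptide_table(config.peptides, config.groups)
        seqs = io.read_fasta(config.fasta)
        lengths = {pid: len(s) for pid, s in seqs.items()}
        truth = None

    io.write_peptide_table(peptides, out_dir / "peptides.tsv")
    io.write_group_map(peptides.groups, out_dir / "groups.tsv")
    emit("peptides.tsv")
    emit("groups.tsv")
    report.counts["peptides"] = len(peptides.data)
    report.counts["proteins_input"] = peptides.data["protein_id"].nunique()

    # ---- stage: preprocess --------------------------------------------
    matrix = preprocess.rollup_protein(peptides)
    protein_table = preprocess.normalize_to_reference(
        matrix, peptides.groups, reference_column=peptides.reference_col
    )
    protein_table = preprocess.filter_completeness(
        protein_table, min_frac_per_group=config.min_frac
    )
    report.counts["proteins_filtered"] = len(protein_table.values)
    io.write_protein_table(protein_table, out_dir / "proteins.tsv")
    emit("proteins.tsv")

    qc = preprocess.pca_outliers(protein_table, k_mad=config.k_mad)
    dend = preprocess.hier_cluster(protein_table, axis="samples")
    qc_payload = {
        "protein_counts": qc.protein_counts.to_dict(),
        "explained_variance": [float(v) for v in qc.explained_variance],
        "outliers": qc.outliers,
        "n_proteins_used": qc.n_proteins_used,
        "pca_coords": {
            s: [float(v) for v in row]
            for s, row in qc.pca_coords.iterrows()
        },
    }
    (out_dir / "qc.json").write_text(json.dumps(qc_payload, indent=1, sort_keys=True))
    (out_dir / "samples.nwk").write_text(preprocess.linkage_to_newick(dend) + "\n")
    emit("qc.json")
    emit("samples.nwk")
    report.counts["outlier_samples"] = len(qc.outliers)

    # ---- stage: differential expression -------------------------------
    if config.run_de:
        de = diffexpr.de_analysis(
            protein_table, alpha=config.alpha, fc_min=config.fc
        )
        de.to_csv(out_dir / "de.tsv", sep="\t", na_rep="NA")
        emit("de.tsv")
        report.counts["de_proteins"] = int((de["call"] != "ns").sum())

    # ---- stage: shedding detection ------------------------------------
    calls = pd.DataFrame(columns=cleavage.CALL_COLUMNS)
    if config.run_shed:
        ratios = preprocess.normalize_peptides_to_reference(peptides)
        calls, profiles = cleavage.detect_substrates(
            ratios,
            lengths,
            min_frac=config.peptide_min_frac,
            b_start=config.b_start,
            b_end=config.b_end,
            b_step=config.b_step,
            alpha=config.alpha,
            fc_min=config.fc,
            min_sig=config.min_sig,
            return_profiles=True,
        )
        calls.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
        emit("calls.tsv")
        report.counts["substrate_calls"] = len(calls)
        if config.simulate and truth is not None:
            recovery = simulate.evaluate_calls(calls, truth)
            (out_dir / "recovery.json").write_text(
                json.dumps(
                    {
                        "sensitivity": recovery.sensitivity,
                        "fdr": recovery.fdr,
                        "median_boundary_error_pp":
                            recovery.median_boundary_error_pp,
                        "n_tp": recovery.n_tp,
                        "n_fp": recovery.n_fp,
                    },
                    indent=1, sort_keys=True,
                )
            )
            emit("recovery.json")

    # ---- stage: annotate ----------------------------------------------
    if config.run_annotate and config.run_shed:
        if config.topology:
            topology = io.read_topology_table(config.topology)
        else:
            topology = pd.Series(dtype=object)
        if config.protease_db:
            db = io.read_protease_db(config.protease_db)
        else:
            db = pd.DataFrame(
                columns=["protease_id", "substrate_id", "evidence"]
            )
        annotated = annotate_mod.annotate_substrates(calls, topology, db)
        ranking, incidence = annotate_mod.map_proteases(calls, db)
        annotated.to_csv(out_dir / "annotated.tsv", sep="\t", index=False)
        ranking.to_csv(out_dir / "sheddase_ranking.tsv", sep="\t", index=False)
        incidence.to_csv(out_dir / "incidence.tsv", sep="\t")
        emit("annotated.tsv")
        emit("sheddase_ranking.tsv")
        emit("incidence.tsv")

    # ---- stage: correlation map ---------------------------------------
    if config.run_corrmap:
        cmap = corrmap.correlation_map(
            protein_table, "case", n_min=config.n_min
        )
        k = min(config.corr_k, len(cmap.protein_ids))
        labels, _ = corrmap.extract_clusters(cmap, k=k)
        cmap.corr.to_csv(out_dir / "corr_case.tsv", sep="\t", na_rep="NA")
        labels.to_frame().to_csv(out_dir / "corr_clusters.tsv", sep="\t")
        emit("corr_case.tsv")
        emit("corr_clusters.tsv")
        report.counts["corr_proteins"] = len(cmap.protein_ids)

    # ---- manifest ------------------------------------------------------
    report.elapsed_s = time.monotonic() - t0
    manifest = {
        "config": asdict(config),
        "outputs": dict(sorted(report.outputs.items())),
        "counts": report.counts,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report.manifest_path = str(manifest_path)
    return report
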