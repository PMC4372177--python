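"""End-to-end pipeline: simulate/load -> QC -> cell composition -> EWAS ->
clusters -> differential aging -> enrichment.

One :class:`PipelineConfig` drives every stage; a single seed makes the whole
synthetic run reproducible, and each output file carries a header comment with
the package version, the seed and a hash of the configuration so runs are
auditable. Stage outputs are plain TSVs that the corresponding stage commands
also accept as inputs, so any suffix of the pipeline can be re-run alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import SignificanceConfig, bonferroni_threshold, direction_summary, run_ewas
from .cellcomp import CellTypeReference, covariate_columns, estimate_cell_proportions
from .clusters import ClusterCriteria, call_admcs, clusters_to_bed
from .diffage import candidate_screen, run_differential_aging
from .enrich import GeneSetCollection, enrich_clusters, read_gmt
from .pedigree import kinship_matrix, read_pedigree
from .preprocess import QCConfig, apply_qc, beta_to_m, read_annotation, \
    read_exclusion_list, read_matrix
from .simulate import SimulationConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("kinewas")


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline.

    With ``simulate=True`` (default) the input files are generated by the
    bundled simulator under ``outdir/inputs``; otherwise the ``*_path``
    fields must point at existing files (pedigree, phenotype table, beta
    matrix, probe annotation; optionally detection-P matrix, exclusion list,
    cell reference, GMT gene sets).
    """

    outdir: str = "kinewas_run"
    seed: int = 0
    simulate: bool = True
    # real-data inputs
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    beta_path: str | None = None
    annotation_path: str | None = None
    detection_p_path: str | None = None
    exclusion_list_path: str | None = None
    cell_reference_path: str | None = None
    cell_signal_beta_path: str | None = None
    gene_sets_path: str | None = None
    candidate_genes: list[str] | None = None
    # stage parameters
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    alpha: float = 0.05
    test: str = "lrt"
    drop_celltype: str = "granulocytes"
    clusters: ClusterCriteria = field(default_factory=ClusterCriteria)
    all_pairs_clustering: bool = False
    enrich_method: str = "fdr_bh"

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # analysis parameters only, not output location
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"kinewas {__version__} | seed={self.seed} | config={self.config_hash()}"]


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file with nested stage sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, cls in (("sim", SimulationConfig), ("qc", QCConfig),
                     ("clusters", ClusterCriteria)):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    cfg = PipelineConfig(**raw)
    if not cfg.simulate:
        required = ("pedigree_path", "phenotypes_path", "beta_path", "annotation_path")
        missing = [k for k in required if getattr(cfg, k) is None]
        if missing:
            raise ValueError(f"real-data mode requires config keys: {missing}")
    return cfg


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
           index_label: str = "probe_id") -> None:
    with open(path, "w") as fh:
        for line in cfg.header_lines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _synthetic_gene_sets(annotation: pd.DataFrame, seed: int) -> GeneSetCollection:
    """A small labeled collection over the array's genes for the demo run.

    One set holds the planted-cluster genes (expected enriched in positive
    clusters), the rest are random draws from the background.
    """
    background = frozenset(g for g in annotation["gene"].fillna("") if g)
    rng = np.random.default_rng([9, seed])
    genes = sorted(background)
    sets = {"planted_cluster_genes": frozenset(g for g in genes if g.startswith("CLGENE"))}
    for j in range(1, 6):
        sets[f"random_set_{j}"] = frozenset(
            rng.choice(genes, size=min(20, len(genes)), replace=False)
        )
    sets = {k: v for k, v in sets.items() if v}
    return GeneSetCollection(sets=sets, background=background)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the summary report dictionary.

    Stage order: simulate (optional) -> qc -> cellcomp -> assoc -> cluster ->
    diffage -> enrich. Any stage failure raises with the stage name attached.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "config_hash": cfg.config_hash()}
    stage = "setup"
    try:
        # ------------------------------------------------------ simulate/load
        if cfg.simulate:
            stage = "simulate"
            sim_cfg = cfg.sim
            if sim_cfg.seed != cfg.seed:
                sim_cfg = SimulationConfig(**{**asdict(sim_cfg), "seed": cfg.seed})
            log.info("simulate: %d families, %d probes, seed=%d",
                     sim_cfg.n_families, sim_cfg.n_probes, cfg.seed)
            cohort = simulate_cohort(sim_cfg)
            write_cohort(cohort, out / "inputs")
            beta = cohort.beta_matrix
            annotation = cohort.annotation
            phenotypes = cohort.phenotypes
            K = cohort.kinship
            cell_ref = cohort.cell_reference
            cell_signal = cohort.cell_signal_beta
            detp = None
            exclusion: frozenset[str] = cfg.qc.exclusion_list
        else:
            stage = "load"
            ped = read_pedigree(cfg.pedigree_path)
            phenotypes = pd.read_csv(cfg.phenotypes_path, sep="\t", index_col=0,
                                     comment="#")
            phenotypes.index = phenotypes.index.astype(str)
            beta = read_matrix(cfg.beta_path)
            annotation = read_annotation(cfg.annotation_path)
            K = kinship_matrix(ped, [s for s in beta.columns if s in ped])
            detp = read_matrix(cfg.detection_p_path) if cfg.detection_p_path else None
            exclusion = (read_exclusion_list(cfg.exclusion_list_path)
                         if cfg.exclusion_list_path else cfg.qc.exclusion_list)
            cell_ref = (CellTypeReference.read_tsv(cfg.cell_reference_path)
                        if cfg.cell_reference_path else None)
            cell_signal = (read_matrix(cfg.cell_signal_beta_path)
                           if cfg.cell_signal_beta_path else beta)
        samples = [s for s in beta.columns if s in phenotypes.index]

        # ---------------------------------------------------------------- qc
        stage = "qc"
        qc_cfg = QCConfig(**{**asdict(cfg.qc), "exclusion_list": exclusion})
        log.info("qc: detection P<%g in <=%g of samples, beta range >= %g, "
                 "%d excluded ids", qc_cfg.detection_p_threshold,
                 qc_cfg.max_fail_fraction, qc_cfg.beta_range_min,
                 len(qc_cfg.exclusion_list))
        beta_qc, report = apply_qc(beta[samples], qc_cfg, detp)
        m_qc = pd.DataFrame(beta_to_m(beta_qc.to_numpy()),
                            index=beta_qc.index, columns=beta_qc.columns)
        annotation = annotation.loc[annotation.index.intersection(beta_qc.index,
                                                                  sort=False)]
        _write(report.to_frame().set_index("stage"), out / "qc_report.tsv", cfg,
               index_label="stage")
        _write(m_qc, out / "m_values_qc.tsv", cfg)
        summary["qc"] = {k: int(v) for k, v in vars(report).items()}

        # ---------------------------------------------------------- cellcomp
        stage = "cellcomp"
        if cell_ref is not None:
            props = estimate_cell_proportions(cell_signal[samples], cell_ref)
            cells = covariate_columns(props, drop=cfg.drop_celltype)
            _write(props, out / "cell_proportions.tsv", cfg, index_label="id")
            log.info("cellcomp: estimated 6 proportions, dropped %s",
                     cfg.drop_celltype)
        else:
            props, cells = None, None
            log.info("cellcomp: no reference provided; skipping covariates")

        # ------------------------------------------------------------- assoc
        stage = "assoc"
        sig = SignificanceConfig(alpha=cfg.alpha, n_tests=m_qc.shape[0])
        log.info("assoc: %d probes, %d samples, alpha=%g -> threshold %.3g",
                 m_qc.shape[0], len(samples), cfg.alpha, bonferroni_threshold(sig))
        results = run_ewas(m_qc, phenotypes, K, cell_covariates=cells,
                           annotation=annotation, sig=sig, test=cfg.test)
        _write(results, out / "ewas_results.tsv", cfg)
        summary["assoc"] = direction_summary(results)
        summary["assoc"]["bonferroni_threshold"] = bonferroni_threshold(sig)
        summary["assoc"]["n_tests"] = sig.n_tests
        summary["assoc"]["n_converged"] = int(results["converged"].sum())

        # ----------------------------------------------------------- cluster
        stage = "cluster"
        records = call_admcs(results, annotation, cfg.clusters,
                             all_pairs=cfg.all_pairs_clustering)
        bed = clusters_to_bed(records)
        _write(bed.set_index("cluster_id"), out / "admc.bed.tsv", cfg,
               index_label="cluster_id")
        members = pd.DataFrame(
            [(r.cluster_id, p) for r in records for p in r.member_probe_ids],
            columns=["cluster_id", "probe_id"],
        )
        _write(members.set_index("cluster_id"), out / "admc_members.tsv", cfg,
               index_label="cluster_id")
        by_dir = {d: sum(r.direction == d for r in records)
                  for d in ("positive", "negative", "varying")}
        summary["clusters"] = {"n_clusters": len(records), **by_dir}
        log.info("cluster: %d aDMCs (%s)", len(records), by_dir)

        # ----------------------------------------------------------- diffage
        stage = "diffage"
        cand_genes = cfg.candidate_genes
        if cand_genes is None:
            gene_col = results.get("gene")
            cand_genes = sorted({g for g in (gene_col.fillna("") if gene_col is not None
                                             else []) if g})
        cand = candidate_screen(results, cand_genes, sig=sig) if cand_genes else []
        if cand:
            da = run_differential_aging(m_qc, cand, phenotypes, K,
                                        cell_covariates=cells,
                                        annotation=annotation)
            _write(da, out / "differential_aging.tsv", cfg)
            nominal = da[(da["p_diff_slope"] < 0.05) & da["converged"]]
            summary["diffage"] = {
                "n_candidates": len(cand),
                "n_nominal_slope_diff": int(nominal.shape[0]),
                "n_opposite_signs": int((nominal["opposite_signs"]).sum()),
            }
        else:
            summary["diffage"] = {"n_candidates": 0}
        log.info("diffage: %s", summary["diffage"])

        # ------------------------------------------------------------ enrich
        stage = "enrich"
        if cfg.gene_sets_path:
            background = frozenset(g for g in annotation["gene"].fillna("") if g)
            collection = read_gmt(cfg.gene_sets_path, background)
        elif cfg.simulate:
            collection = _synthetic_gene_sets(annotation, cfg.seed)
        else:
            collection = None
        if collection is not None and collection.sets:
            summary["enrich"] = {}
            for direction in ("positive", "negative"):
                table = enrich_clusters(records, direction, collection,
                                        method=cfg.enrich_method, alpha=cfg.alpha)
                _write(table.set_index("set_name"),
                       out / f"enrichment_{direction}.tsv", cfg,
                       index_label="set_name")
                summary["enrich"][direction] = {
                    "n_sets_tested": int(table.shape[0]),
                    "n_significant": int(table["significant"].sum())
                    if "significant" in table else 0,
                    "top_set": str(table["set_name"].iloc[0])
                    if table.shape[0] else None,
                }
        else:
            summary["enrich"] = {"skipped": "no gene sets provided"}
        log.info("enrich: %s", summary["enrich"])

    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
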