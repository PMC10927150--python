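"""End-to-end pipeline driver with deterministic outputs and a manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, de, enrichment, io, motifs, variance
from .simulate import SimDesign, ac_variance_inflation, simulate_counts

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run.

    With no ``counts_path``, inputs are simulated from the default study
    design (scaled to ``sim_n_genes`` genes) so the pipeline is runnable
    without external data.
    """

    counts_path: str | None = None
    samples_path: str | None = None
    gene_sets_path: str | None = None
    snp_bed_path: str | None = None
    gene_bed_path: str | None = None
    out_dir: str = "results"
    fdr: float = 0.05
    stringent_fdr: float = 0.01
    lenient_fdr: float = 0.05
    posterior_threshold: float = 0.5
    expression_threshold: float = 0.0
    peak_quantile: float = 0.6
    smooth_window: int = 5
    k_min: int = 1
    k_max: int = 6
    seed: int = 1
    sim_n_genes: int = 2000
    sim_variance_inflation: float = 1.5
    em_restarts: int = 5

    def validate(self) -> None:
        for name in ("fdr", "stringent_fdr", "lenient_fdr", "posterior_threshold",
                     "peak_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        for name in ("counts_path", "samples_path", "gene_sets_path",
                     "snp_bed_path", "gene_bed_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Fan the master seed out to a per-stage seed by stable hashing."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _write_csv(df: pd.DataFrame, path: Path, manifest: list, **kwargs) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, **kwargs)
    manifest.append(
        {
            "name": path.name,
            "rows": int(df.shape[0]),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute counts -> DE -> motifs -> variance (-> enrichment/annotation)
    and write CSV/JSON outputs plus a manifest. Returns a result summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_entries: list[dict] = []
    log: dict = {"version": __version__, "seed": config.seed, "config": asdict(config)}

    # --- stage: counts
    if config.counts_path is not None:
        if config.samples_path is None:
            raise ValueError("counts_path requires samples_path")
        experiment = io.read_counts(config.counts_path, config.samples_path)
        truth = None
    else:
        design = SimDesign(
            n_genes=config.sim_n_genes,
            variance_inflation=ac_variance_inflation(config.sim_variance_inflation),
            seed=stage_seed(config.seed, "simulate"),
        )
        experiment, truth = simulate_counts(design)
        io.write_counts_tsv(experiment, out / "counts.tsv", out / "samples.csv")
        manifest_entries.append(
            {"name": "counts.tsv", "rows": experiment.n_genes,
             "sha256": hashlib.sha256((out / "counts.tsv").read_bytes()).hexdigest()}
        )

    # --- stage: differential expression
    lcpm = de.log2_cpm(experiment.counts)
    expressed = de.filter_expressed(lcpm, config.expression_threshold)
    log["n_expressed_genes"] = int(len(expressed))
    tables = de.pairwise_de(experiment, expression_threshold=config.expression_threshold)
    de_counts = {}
    for (drug, time), fit in tables.items():
        key = f"{drug}_{time}"
        _write_csv(fit.table, out / f"de_{key}.csv", manifest_entries, index_label="gene")
        de_counts[key] = int((fit.table["p_adj"] < config.fdr).sum())
    log["de_gene_counts"] = de_counts

    corr, order, _ = de.response_correlation_matrix(tables)
    _write_csv(corr, out / "response_correlation.csv", manifest_entries)
    log["response_correlation_order"] = order

    # --- stage: drug-specific genes per timepoint
    times = sorted(experiment.samples["time"].unique())
    drug_specific = {}
    for tp in times:
        per_drug = {drug: fit for (drug, t), fit in tables.items() if t == tp}
        for drug in per_drug:
            genes = motifs.drug_specific_genes(
                per_drug, drug, strict=config.stringent_fdr, lenient=config.lenient_fdr
            )
            drug_specific[f"{drug}_{tp}"] = list(genes)
    (out / "drug_specific_genes.json").write_text(
        json.dumps(drug_specific, indent=1, sort_keys=True)
    )
    manifest_entries.append(
        {"name": "drug_specific_genes.json",
         "rows": sum(len(v) for v in drug_specific.values()),
         "sha256": hashlib.sha256((out / "drug_specific_genes.json").read_bytes()).hexdigest()}
    )

    # --- stage: correlation motifs
    pairs = list(tables.keys())
    t_matrix, dfs = motifs.condition_statistics(
        experiment, pairs, expression_threshold=config.expression_threshold
    )
    selection = motifs.select_motif_number(
        t_matrix, dfs, k_range=range(config.k_min, config.k_max + 1),
        seed=stage_seed(config.seed, "motifs"), n_restarts=config.em_restarts,
    )
    fit = selection.best_fit
    assignment = motifs.assign_signatures(
        fit, posterior_threshold=config.posterior_threshold
    )
    _write_csv(selection.scores, out / "motif_scores.csv", manifest_entries, index=False)
    _write_csv(fit.gene_posterior, out / "motif_gene_posterior.csv",
               manifest_entries, index_label="gene")
    _write_csv(fit.de_posterior, out / "motif_de_posterior.csv",
               manifest_entries, index_label="gene")
    _write_csv(assignment.labels.to_frame(), out / "signatures.csv",
               manifest_entries, index_label="gene")
    motif_json = {
        "best_k": selection.best_k,
        "pi": fit.pi.tolist(),
        "q": fit.q.tolist(),
        "v": fit.v.tolist(),
        "conditions": list(fit.de_posterior.columns),
        "motif_labels": assignment.motif_labels,
        "assigned_fraction": assignment.assigned_fraction,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "aic": fit.aic,
    }
    (out / "motif_fit.json").write_text(json.dumps(motif_json, indent=1, sort_keys=True))
    manifest_entries.append(
        {"name": "motif_fit.json", "rows": selection.best_k,
         "sha256": hashlib.sha256((out / "motif_fit.json").read_bytes()).hexdigest()}
    )
    log["best_k"] = selection.best_k
    log["assigned_fraction"] = assignment.assigned_fraction
    log["signature_counts"] = assignment.labels.value_counts().to_dict()

    # --- stage: variance analysis
    lcpm_expr = lcpm.loc[expressed]
    vt = variance.group_mean_variance(lcpm_expr, experiment.samples)
    _write_csv(vt.variances, out / "group_variances.csv", manifest_entries,
               index_label="gene")
    vehicle = "VEH"
    shift_rows, f_profiles = [], {}
    for (drug, time) in pairs:
        key = f"{drug}_{time}"
        veh_ids = experiment.group_samples(vehicle, time)
        drug_ids = experiment.group_samples(drug, time)
        ftab = variance.variance_test_per_gene(lcpm_expr[drug_ids], lcpm_expr[veh_ids])
        f_profiles[key] = ftab["F"]
        shift = variance.group_variance_shift_test(
            vt.variances[key], vt.variances[f"{vehicle}_{time}"]
        )
        shift_rows.append({"group": key, **shift})
    shifts = pd.DataFrame(shift_rows).set_index("group")
    _write_csv(shifts, out / "variance_shift_tests.csv", manifest_entries)
    f_matrix = pd.DataFrame(f_profiles)
    rho, v_order, _ = variance.variance_profile_clustering(f_matrix)
    _write_csv(rho, out / "variance_profile_correlation.csv", manifest_entries)
    log["variance_cluster_order"] = v_order

    # --- stage: enrichment / annotation (optional inputs)
    if config.gene_sets_path is not None:
        gene_sets = io.read_gmt(config.gene_sets_path)
        universe = list(expressed)
        rows = []
        for label in sorted(set(assignment.labels) - {"unassigned", "NR"}):
            query = assignment.labels.index[assignment.labels == label]
            ora = enrichment.overrepresentation_test(
                [g for g in query if g in set(universe)], universe, gene_sets,
                fdr=config.fdr,
            )
            ora.insert(0, "signature", label)
            rows.append(ora)
        if rows:
            _write_csv(pd.concat(rows, ignore_index=True), out / "enrichment.csv",
                       manifest_entries, index=False)

    if config.snp_bed_path is not None and config.gene_bed_path is not None:
        snps = io.read_bed_snps(config.snp_bed_path)
        tss = enrichment.tss_from_intervals(io.read_bed_genes(config.gene_bed_path))
        nearest = enrichment.nearest_tss(snps, tss)
        _write_csv(nearest, out / "nearest_tss.csv", manifest_entries, index=False)
        report = enrichment.annotate_gwas_genes(
            nearest["gene_id"].dropna(), [], expressed, tables, assignment.labels,
            fdr=config.fdr,
        )
        _write_csv(report, out / "gwas_locus_report.csv", manifest_entries, index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "motifs")},
        "outputs": sorted(manifest_entries, key=lambda r: r["name"]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return log
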