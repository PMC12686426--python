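"""End-to-end orchestration with a single config and provenance capture.

``run_pipeline`` executes the stages in dependency order on either simulated
or on-disk inputs: variant summarization and threshold filtering, ZIBB
background fitting and cell calling, clone clustering, the calibrated clone
phylogeny, lineage summaries, nuclear-SNV concordance, and clonal
differential expression. Every stage parameter and every convention decision
that fired is echoed into ``provenance.json``; a rerun with the same config
and seed is byte-identical.

Stage defaults are the published analysis parameters (coverage > 5, quality
> 27, AF > 25% in >= 1% of epithelial cells; FDR 0.05 with >= 3 significant
cells; k = 10, resolution = 3; 1000 bootstraps, 100 permutations; 100 DE
iterations). The ``demo`` entry point deliberately scales the bootstrap and
iteration counts down so the whole pipeline runs in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream_seed
from .clonal_de import bootstrapped_de, select_top_overlap, wilcoxon_de
from .clones import (
    SENTINEL_CLUSTER,
    build_heteroplasmy_matrix,
    cluster_clones,
    detect_crossing_lineages,
    lineage_prevalence,
)
from .io_formats import (
    read_allele_matrix,
    read_cell_annotation,
    read_expression_mtx,
    read_snv_table,
    write_allele_matrix,
    write_cell_annotation,
    write_expression_mtx,
    write_newick,
    write_snv_table,
)
from .phylogeny import (
    annotate_significant_edges,
    bootstrap_support,
    permutation_null_threshold,
)
from .simulate import default_config, simulate_all
from .snv_concordance import (
    filter_snvs,
    snv_concordance_test,
    stratified_permutation_null,
)
from .variant_filter import (
    exclude_cross_patient,
    filter_variants,
    flag_homoplasmic,
    summarize_variants,
)
from .zibb import call_cells, fit_zibb_background

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published analysis values."""

    # variant filter
    min_cov: float = 5.0
    min_q: float = 27.0
    af_cut: float = 0.25
    min_frac_epi: float = 0.01
    # ZIBB calling
    fdr: float = 0.05
    min_sig_cells: int = 3
    min_ref_cells: int = 50
    tail_model: str = "zibb"
    fdr_bins: int = 4
    # clone clustering
    k: int = 10
    resolution: float = 3.0
    # phylogeny
    bootstrap: int = 1000
    permutations: int = 100
    null_bootstrap: int = 200
    root_policy: str = "midpoint"
    # SNV concordance
    snv_min_depth: int = 3
    snv_min_cells: int = 4
    snv_permutations: int = 100
    # differential expression
    de_iterations: int = 100
    de_min_pct: float = 0.1
    de_boot_min_pct: float = 0.25
    # global
    seed: int = 7
    input_dir: str | None = None  # None -> simulate the default world

    def __post_init__(self) -> None:
        for name in ("min_cov", "min_q", "af_cut", "min_frac_epi", "fdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "min_sig_cells", "min_ref_cells", "k", "bootstrap", "permutations",
            "null_bootstrap", "snv_min_depth", "snv_min_cells",
            "snv_permutations", "de_iterations", "fdr_bins",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.tail_model not in ("zibb", "zib"):
            raise ValueError(f"unknown tail model {self.tail_model!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: PipelineConfig):
    if config.input_dir is None:
        sim = default_config(seed=config.seed)
        m, ann, truth, snv, expr = simulate_all(sim)
        return m, ann, snv, expr, truth
    d = config.input_dir
    m = read_allele_matrix(os.path.join(d, "allele_matrix.tsv"))
    ann = read_cell_annotation(os.path.join(d, "annotation.tsv"))
    snv_path = os.path.join(d, "snv_counts.tsv")
    snv = read_snv_table(snv_path) if os.path.exists(snv_path) else None
    expr_dir = os.path.join(d, "expression")
    expr = read_expression_mtx(expr_dir) if os.path.isdir(expr_dir) else None
    return m, ann, snv, expr, None


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute all stages; writes TSV outputs plus ``provenance.json``.

    Returns the provenance dictionary.
    """
    os.makedirs(outdir, exist_ok=True)
    provenance: dict = {
        "mtclone_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "decisions": [
            "variant thresholds are strict inequalities",
            "epithelial-fraction denominator: epithelial cells with coverage > 0",
            "homoplasmic variants flagged and excluded from somatic clone calling",
            "variant rule: #significant - ceil(fdr * #significant) >= min_sig_cells",
            "FDR stratified by test-cell coverage quantiles; bins with < 20 null cells merged",
            "heteroplasmy features unscaled (cosine distance is per-cell scale invariant)",
            "all-zero heteroplasmy cells excluded from clustering (sentinel -1), not imputed",
            "support rule: edge and parent edge must both exceed the null 95th percentile",
            "zero-depth cells excluded from SNV contingency tables",
            "Fisher exact test two-sided by point-probability summation",
            "log2FC on library-size-normalized means with pseudocount 1",
            "bootstrap DE subsamples without replacement; normalization recomputed per subsample",
        ],
    }
    seed = config.seed

    m, ann, snv, expr, truth = _load_inputs(config)
    write_allele_matrix(m, os.path.join(outdir, "allele_matrix.tsv"))
    write_cell_annotation(ann, os.path.join(outdir, "annotation.tsv"))
    if snv is not None:
        write_snv_table(snv, os.path.join(outdir, "snv_counts.tsv"))
    if expr is not None:
        write_expression_mtx(expr, os.path.join(outdir, "expression"))

    # --- variant filter -----------------------------------------------------
    stats = summarize_variants(m, ann, af_cut=config.af_cut)
    idx = ann.indexed()
    by_patient: dict[str, list[str]] = {}
    for patient in sorted(idx["patient_id"].unique()):
        cells = idx.index[idx["patient_id"] == patient].tolist()
        rows = [i for i, c in enumerate(m.cell_ids) if c in set(cells)]
        if len(rows) == m.n_cells:
            pstats = stats
        else:
            from .io_formats import AlleleCountMatrix

            sub = AlleleCountMatrix(
                m.variant_ids,
                [m.cell_ids[i] for i in rows],
                m.alt_counts[rows],
                m.coverage[rows],
                m.base_quality[rows],
            )
            pstats = summarize_variants(sub, ann, af_cut=config.af_cut)
        by_patient[patient] = filter_variants(
            pstats,
            min_mean_cov=config.min_cov,
            min_mean_q=config.min_q,
            af_cut=config.af_cut,
            min_frac_epi=config.min_frac_epi,
        )
    by_patient = exclude_cross_patient(by_patient)
    selected = sorted({v for vs in by_patient.values() for v in vs})
    homoplasmic = set(flag_homoplasmic(stats))
    candidates = [v for v in selected if v not in homoplasmic]
    pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in stats],
            "mean_coverage": [s.mean_coverage for s in stats],
            "mean_quality": [s.mean_quality for s in stats],
            "frac_epithelial_above": [s.frac_epithelial_above for s in stats],
            "passed_filter": [s.variant_id in set(selected) for s in stats],
            "homoplasmic": [s.variant_id in homoplasmic for s in stats],
        }
    ).to_csv(os.path.join(outdir, "variant_stats.tsv"), sep="\t", index=False)
    provenance["stages"]["variant_filter"] = {
        "n_selected": len(selected),
        "n_homoplasmic_flagged": len(homoplasmic),
        "candidates": candidates,
    }

    # --- ZIBB calling -------------------------------------------------------
    if not candidates:
        raise RuntimeError("variant_filter: no candidate variants survive the filter")
    from .io_formats import AlleleCountMatrix

    cand_idx = [m.variant_index(v) for v in candidates]
    m_cand = AlleleCountMatrix(
        candidates,
        m.cell_ids,
        m.alt_counts[:, cand_idx],
        m.coverage[:, cand_idx],
        m.base_quality[:, cand_idx],
    )
    params = {
        v: fit_zibb_background(m_cand, ann, v, min_ref_cells=config.min_ref_cells)
        for v in candidates
    }
    calls, significant = call_cells(
        m_cand,
        ann,
        params,
        fdr_level=config.fdr,
        min_sig_cells=config.min_sig_cells,
        tail_model=config.tail_model,
        n_bins=config.fdr_bins,
    )
    calls.to_csv(os.path.join(outdir, "variant_calls.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "significant_variants.txt"), "w") as fh:
        fh.write("".join(v + "\n" for v in significant))
    provenance["stages"]["zibb"] = {
        "n_candidates": len(candidates),
        "n_significant_variants": len(significant),
        "params": {
            v: {"pi": p.pi, "mu": p.mu, "rho": p.rho, "degenerate": p.degenerate}
            for v, p in sorted(params.items())
        },
    }
    if not significant:
        raise RuntimeError("zibb: no variant passes the significant-cell rule")

    # --- clone clustering ---------------------------------------------------
    h = build_heteroplasmy_matrix(m_cand, significant)
    labels = cluster_clones(
        h, k=config.k, resolution=config.resolution, seed=substream_seed(seed, "cluster")
    )
    labels.labels.rename("cluster").to_frame().to_csv(
        os.path.join(outdir, "clone_labels.tsv"), sep="\t"
    )
    cluster_ids = labels.cluster_ids()
    provenance["stages"]["clones"] = {
        "n_clusters": len(cluster_ids),
        "params": labels.params,
        "sizes": {str(c): int((labels.labels == c).sum()) for c in cluster_ids},
    }

    # --- phylogeny ----------------------------------------------------------
    if len(cluster_ids) >= 3:
        tree = bootstrap_support(
            h, labels, n_bootstrap=config.bootstrap, seed=substream_seed(seed, "phylo")
        )
        calib = permutation_null_threshold(
            h,
            labels,
            n_permutations=config.permutations,
            n_bootstrap=config.null_bootstrap,
            seed=substream_seed(seed, "phylo-null"),
        )
        tree = annotate_significant_edges(tree, calib, root_policy=config.root_policy)
        write_newick(tree, os.path.join(outdir, "clone_tree.nwk"))
        pd.DataFrame(
            {
                "permutation": range(calib.n_permutations),
                "max_support": calib.null_max_supports,
            }
        ).to_csv(os.path.join(outdir, "support_calibration.tsv"), sep="\t", index=False)
        provenance["stages"]["phylogeny"] = {
            "threshold": calib.threshold,
            "supports": {"|".join(sorted(k)): v for k, v in sorted(
                tree.supports.items(), key=lambda kv: sorted(kv[0])
            )},
            "n_significant_edges": len(tree.significant_edges()),
        }
    else:
        provenance["stages"]["phylogeny"] = {
            "skipped": f"only {len(cluster_ids)} clusters; need >= 3"
        }

    # --- lineage summaries --------------------------------------------------
    prev = {v: lineage_prevalence(calls, ann, v) for v in significant}
    pd.DataFrame(prev).rename_axis("sample_id").to_csv(
        os.path.join(outdir, "lineage_prevalence.tsv"), sep="\t"
    )
    crossing = detect_crossing_lineages(calls, ann)
    pd.DataFrame(
        [(v, ";".join(ts)) for v, ts in crossing], columns=["variant_id", "tissues"]
    ).to_csv(os.path.join(outdir, "crossing_lineages.tsv"), sep="\t", index=False)
    provenance["stages"]["lineages"] = {"n_crossing": len(crossing)}

    # clone of interest for the validation stages: prefer the cluster whose
    # cells span Barrett's esophagus and dysplasia (the lineage the clonal
    # analyses target); fall back to the largest cluster
    clone_cells: set[str] = set()
    clone_choice = "largest cluster"
    if cluster_ids:
        best, best_score = cluster_ids[0], 0
        for c in cluster_ids:
            members = labels.cells_in(c)
            tiss = idx.loc[members, "tissue"]
            score = min(int((tiss == "BE").sum()), int((tiss == "dysplasia").sum()))
            if score > best_score:
                best, best_score = c, score
        if best_score >= 3:
            clone_choice = "BE/dysplasia-crossing cluster"
        clone_cells = set(labels.cells_in(best))
    provenance["stages"]["clone_of_interest"] = {
        "rule": clone_choice,
        "n_cells": len(clone_cells),
    }

    # --- SNV concordance ----------------------------------------------------
    if snv is not None and len(snv) and clone_cells:
        snv_f = filter_snvs(snv, min_depth=config.snv_min_depth, min_cells=config.snv_min_cells)
        results = snv_concordance_test(snv_f, ann, clone_cells)
        null = stratified_permutation_null(
            snv_f,
            ann,
            clone_cells,
            n_perm=config.snv_permutations,
            seed=substream_seed(seed, "snv"),
        )
        pd.DataFrame(
            {
                "snv_id": [r.snv_id for r in results],
                "otsu_threshold": [r.otsu_threshold for r in results],
                "fisher_p": [r.fisher_p for r in results],
                "bh_q": [r.bh_q for r in results],
                "n_cells_used": [r.n_cells_used for r in results],
                "frac_null_le_obs": [
                    null.frac_null_le_obs.get(r.snv_id, float("nan")) for r in results
                ],
            }
        ).to_csv(os.path.join(outdir, "snv_concordance.tsv"), sep="\t", index=False)
        null.null_p.to_csv(os.path.join(outdir, "snv_null_pvalues.tsv"), sep="\t")
        provenance["stages"]["snv_concordance"] = {
            "n_snvs_tested": len(results),
            "n_concordant": int(sum(r.bh_q <= 0.05 for r in results)),
        }

    # --- clonal differential expression --------------------------------------
    if expr is not None and clone_cells:
        tissues = idx["tissue"]
        dysp = set(idx.index[(tissues == "dysplasia") & idx["is_epithelial"]])
        be = set(idx.index[(tissues == "BE") & idx["is_epithelial"]])
        known = set(expr.cell_ids)
        stage1 = None
        if dysp & known and be & known:
            stage1 = wilcoxon_de(
                expr, sorted(dysp & known), sorted(be & known), min_pct=config.de_min_pct
            )
            stage1.to_csv(os.path.join(outdir, "de_dysplasia_vs_be.tsv"), sep="\t", index=False)
        clone_tissues = set(idx.loc[sorted(clone_cells), "tissue"])
        background = set(
            idx.index[idx["is_epithelial"] & tissues.isin(clone_tissues)]
        ) - clone_cells
        g1 = sorted(clone_cells & known)
        g2 = sorted(background & known)
        if len(g1) >= 3 and len(g2) >= 3:
            clonal = bootstrapped_de(
                expr,
                g1,
                g2,
                n_iter=config.de_iterations,
                min_pct=config.de_boot_min_pct,
                seed=substream_seed(seed, "de"),
            )
            clonal.to_csv(os.path.join(outdir, "de_clonal.tsv"), sep="\t", index=False)
            top = select_top_overlap(stage1, clonal) if stage1 is not None else []
            with open(os.path.join(outdir, "top_overlap_genes.txt"), "w") as fh:
                fh.write("".join(g + "\n" for g in top))
            provenance["stages"]["clonal_de"] = {
                "n_robust": int(clonal["robust"].sum()),
                "top_overlap": top,
            }

    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return provenance


def run_demo(outdir: str, seed: int = 7) -> dict:
    """Full pipeline on the simulated default world at desk scale.

    Two parameter groups are scaled to the demo's size, and only those:
    bootstrap/permutation/iteration counts are reduced from the published
    defaults (1000/100/100 to 200/25/50) so the demo completes in minutes,
    and the clustering resolution is 1.0 instead of 3.0 because modularity
    resolution is graph-scale dependent — 3.0 is calibrated to biopsy-scale
    SNN graphs and shatters the demo's ~600-cell graph into singletons (see
    the clone-clustering module notes). Every other parameter is the
    published value.
    """
    config = PipelineConfig(
        seed=seed,
        resolution=1.0,
        bootstrap=200,
        permutations=25,
        null_bootstrap=100,
        de_iterations=50,
        snv_permutations=100,
    )
    return run_pipeline(config, outdir)
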