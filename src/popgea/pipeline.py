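"""Config-driven orchestration of the full analysis.

A :class:`PipelineConfig` (loadable from YAML) names the inputs and the
stage parameters; :func:`run_pipeline` executes the enabled stages in
dependency order and writes every stage's artifact (TSV/JSON/newick)
plus a line-oriented log into a run directory.  Deterministic stages
reproduce byte-identical artifacts on rerun with the same config.

Stage order and dataset mapping follow low-coverage population-genomics
practice: kinship runs on the LD-pruned dataset *without* a MAF filter
(rare alleles carry the kinship information), while structure, summary
statistics and GEA run on the MAF-filtered, LD-pruned dataset, with
relatives removed before admixture and GEA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diversity, gea, genio, kinship as kin, ld, scan as scan_mod, structure

log = logging.getLogger("popgea")


@dataclass
class PipelineConfig:
    """All stage toggles and parameters, with field defaults matching the
    workflow's standard values."""

    vcf: str = ""
    metadata: str = ""
    env_table: str = ""
    out_dir: str = "popgea_run"
    seed: int = 0

    # stage toggles
    run_filter: bool = True
    run_ld: bool = True
    run_scan: bool = True
    run_structure: bool = True
    run_stats: bool = True
    run_kinship: bool = True
    run_gea: bool = True

    # filtering
    min_mean_depth: float = 5.0
    max_mean_depth: float = 12.0
    min_qual: float = 50.0
    max_missing_frac: float = 0.10
    maf_min: float = 0.05
    ind_min_depth: float = 3.0
    ind_max_missing: float = 0.20

    # LD
    ld_window_kb: float = 50.0
    ld_step_kb: float = 10.0
    ld_r2: float = 0.2
    decay_window_snps: int = 100
    decay_max_dist_kb: float = 1000.0

    # scan
    scan_K: int = 5
    scan_alpha: float = 0.1

    # structure
    pca_axes: int = 20
    kmeans_k_max: int = 20
    kmeans_starts: int = 10
    admixture_K_min: int = 2
    admixture_K_max: int = 12
    admixture_cv_folds: int = 5
    admixture_max_iter: int = 500

    # stats / kinship
    n_boot: int = 1000
    kinship_threshold: float = 0.125

    # GEA
    env_r_max: float = 0.7
    env_vif_max: float = 3.0
    gea_structure_pcs: int = 3
    rda_axes: int = 3
    rda_sd_mult: float = 3.0
    lfmm_K: int = 5
    lfmm_fdr: float = 0.05
    rda_n_perm: int = 99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    log.info("popgea %s seed=%d", __version__, cfg.seed)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)

    gm = genio.read_vcf(cfg.vcf, cfg.metadata or None)
    log.info("loaded %d individuals x %d sites", gm.n_individuals, gm.n_sites)
    pops = gm.individuals["region"].to_numpy()

    if cfg.run_filter:
        site_cfg = genio.SiteFilterConfig(
            min_mean_depth=cfg.min_mean_depth,
            max_mean_depth=cfg.max_mean_depth,
            min_qual=cfg.min_qual,
            max_missing_frac=cfg.max_missing_frac,
            maf_min=0.0,
        )
        gm_maf0, report = genio.filter_dataset(
            gm, site_cfg, cfg.ind_min_depth, cfg.ind_max_missing
        )
        report.to_json(out / "filter_report.json")
        maf = genio.minor_allele_freq(gm_maf0)
        gm_maf = gm_maf0.take_sites(np.flatnonzero(maf >= cfg.maf_min))
        log.info(
            "filtered: %d sites (MAF0.00), %d sites (MAF%.2f)",
            gm_maf0.n_sites, gm_maf.n_sites, cfg.maf_min,
        )
    else:
        gm_maf0 = gm_maf = gm

    if cfg.run_ld:
        prune0 = ld.ld_prune(gm_maf0, cfg.ld_window_kb, cfg.ld_step_kb, cfg.ld_r2)
        prune = ld.ld_prune(gm_maf, cfg.ld_window_kb, cfg.ld_step_kb, cfg.ld_r2)
        ld.write_site_list(prune.removed, out / "ld_removed_sites.txt")
        gm_maf0 = ld.apply_prune(gm_maf0, prune0)
        gm_maf = ld.apply_prune(gm_maf, prune)
        pairs = ld.pairwise_r2(gm_maf, cfg.decay_window_snps, cfg.decay_max_dist_kb)
        if pairs:
            ld.ld_decay(pairs, 25.0).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        log.info("LD pruned to %d sites (MAF-filtered set)", gm_maf.n_sites)

    pops_maf = gm_maf.individuals["region"].to_numpy()

    outlier_ids: np.ndarray | None = None
    if cfg.run_scan:
        sc = scan_mod.outlier_scan(gm_maf, cfg.scan_K, cfg.scan_alpha, seed=cfg.seed)
        sc.to_frame().to_csv(out / "outlier_scan.tsv", sep="\t", index=False)
        ld.write_site_list(list(sc.outliers), out / "outlier_sites.txt")
        outlier_ids = sc.outliers
        log.info("scan: gif=%.3f, %d outliers", sc.gif, len(sc.outliers))

    if cfg.run_structure:
        pca = structure.pca_impute(gm_maf, min(cfg.pca_axes, gm_maf.n_individuals - 1))
        pd.DataFrame(
            pca.scores,
            index=gm_maf.individuals["id"],
            columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        np.savetxt(out / "pca_eigenvalues.tsv", pca.eigenvalues)
        k_max = min(cfg.kmeans_k_max, gm_maf.n_individuals - 1)
        scanres = structure.kmeans_bic(
            pca.scores, k_max, cfg.kmeans_starts, cfg.seed
        )
        pd.DataFrame({"k": scanres.k_values, "bic": scanres.bic}).to_csv(
            out / "kmeans_bic.tsv", sep="\t", index=False
        )
        log.info("k-means chose k=%d", scanres.chosen_k)

    if cfg.run_stats:
        st = diversity.nei_basic_stats(gm_maf, pops_maf)
        theta, f_wc, _ = diversity.wc_stats(gm_maf, pops_maf)
        bs = diversity.beta_fst(gm_maf, pops_maf, cfg.n_boot, cfg.seed)
        pd.DataFrame(
            {
                "statistic": ["Ho", "Hs", "Ht", "Fst_nei", "Fis_nei", "theta_wc", "f_wc"],
                "value": [st.Ho, st.Hs, st.Ht, st.Fst, st.Fis, theta, f_wc],
            }
        ).to_csv(out / "global_stats.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "population": bs.labels,
                "beta_fst": bs.beta,
                "ci_2.5": bs.ci_low,
                "ci_97.5": bs.ci_high,
                "fis": bs.fis,
            }
        ).to_csv(out / "beta_fst.tsv", sep="\t", index=False)
        fst, lo, hi = diversity.pairwise_fst(gm_maf, pops_maf, cfg.n_boot, cfg.seed)
        fst.to_frame().to_csv(out / "pairwise_fst.tsv", sep="\t")
        D = diversity.nei_D(gm_maf, pops_maf)
        D.write_phylip(out / "nei_D.phylip")
        if len(D.labels) >= 3:
            (out / "nj_tree.nwk").write_text(diversity.nj_tree(D) + "\n")
        log.info("stats: Fst(Nei)=%.3f theta(WC)=%.3f", st.Fst, theta)

    removed_rel: list[str] = []
    if cfg.run_kinship:
        K = kin.beta_kinship(gm_maf0)
        K.to_frame().to_csv(out / "kinship_beta.tsv", sep="\t")
        call_rates = 1.0 - gm_maf0.individual_missing_frac()
        removed_rel = kin.prune_relatives(K, cfg.kinship_threshold, call_rates)
        ld.write_site_list(removed_rel, out / "related_removed.txt")
        log.info("kinship: removed %d relatives at >= %.3f", len(removed_rel), cfg.kinship_threshold)

    # analyses that require unrelated individuals
    keep = ~gm_maf.individuals["id"].isin(removed_rel)
    gm_unrel = gm_maf.take_individuals(np.flatnonzero(keep.to_numpy()))

    if cfg.run_structure:
        cv_rows = []
        best = None
        for Kk in range(cfg.admixture_K_min, cfg.admixture_K_max + 1):
            if Kk >= gm_unrel.n_individuals:
                break
            fit = structure.admixture_fit(
                gm_unrel, Kk, seed=cfg.seed,
                max_iter=cfg.admixture_max_iter, cv_folds=cfg.admixture_cv_folds,
            )
            cv_rows.append((Kk, fit.cv_error))
            if best is None or fit.cv_error < best[1]:
                best = (Kk, fit.cv_error, fit)
        if best:
            pd.DataFrame(cv_rows, columns=["K", "cv_error"]).to_csv(
                out / "admixture_cv.tsv", sep="\t", index=False
            )
            structure.write_Q(best[2].Q, out / f"admixture_K{best[0]}.Q")
            log.info("admixture: best K=%d (cv=%.4f)", best[0], best[1])

    if cfg.run_gea:
        if not cfg.env_table:
            raise ValueError("GEA stage enabled but no env_table given")
        if cfg.run_kinship is False and removed_rel == []:
            log.info("GEA running without relatedness pruning (kinship stage off)")
        env = pd.read_csv(cfg.env_table, sep="\t")
        env = env[env["id"].isin(gm_unrel.individuals["id"])]
        env = env.set_index("id").loc[gm_unrel.individuals["id"]].reset_index()
        kept_env, cond_env, envlog = gea.prep_env(env, cfg.env_r_max, cfg.env_vif_max)
        (out / "env_pruning.log").write_text("\n".join(envlog) + "\n")

        gm_gea = gm_unrel
        if outlier_ids is not None:
            gm_noout = gm_gea.take_sites(
                np.flatnonzero(~np.isin(gm_gea.site_ids, outlier_ids))
            )
        else:
            gm_noout = gm_gea
        pca = structure.pca_impute(gm_noout, cfg.gea_structure_pcs)
        Z = pca.scores[:, : cfg.gea_structure_pcs]
        if cond_env.shape[1]:
            Z = np.column_stack([Z, cond_env.to_numpy(float)])

        Y = gea.individual_allele_freq(gm_gea)
        res = gea.prda(Y, kept_env, Z, n_perm=cfg.rda_n_perm, seed=cfg.seed)
        rc = gea.rda_candidates(
            res, gm_gea.site_ids, Y, kept_env,
            min(cfg.rda_axes, res.loadings.shape[1]), cfg.rda_sd_mult,
        )
        lf = gea.lfmm_scan(Y, kept_env, cfg.lfmm_K, fdr=cfg.lfmm_fdr, site_ids=gm_gea.site_ids)
        scan_set = outlier_ids if outlier_ids is not None else gm_gea.site_ids
        final = gea.intersect_candidates(rc, lf, scan_set)
        final.table.to_csv(out / "gea_candidates.tsv", sep="\t", index=False)
        summary = {
            "r2_adj_full": res.r2_adj_full,
            "r2_adj_climate": res.r2_adj_climate,
            "r2_adj_structure": res.r2_adj_structure,
            "n_rda": len(rc),
            "n_lfmm": int(len(lf.significant())),
            "n_final": len(final),
            "per_variable": gea.candidate_summary(final).to_dict("records"),
        }
        with open(out / "gea_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("GEA: %d final candidates", len(final))

    return out
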