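"""End-to-end orchestration: simulate/load -> filter -> PCA -> LD -> trait
correlations -> GWAS -> threshold-GBLUP CV, driven by one YAML config.

Stages communicate only through files in the output directory; a manifest
records parameters, input checksums and per-stage summaries.  One global seed
is fanned out per stage through fixed spawn keys, so toggling a stage never
perturbs another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ordgen import io_formats, ld_analysis, ordinal_gwas, ordinal_stats, popgen, synthetic_data, tgblup

logger = logging.getLogger(__name__)

# fixed per-stage spawn keys for seed fan-out
_STAGE_KEYS = {"simulate": 0, "traits": 1, "gwas": 2, "predict": 3}


@dataclass
class RunConfig:
    """Parameters of a pipeline run (see ``RunConfig.from_yaml``)."""

    seed: int = 0
    output_dir: str = "ordgen_run"
    simulate: dict | None = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)      # vcf/pheno/gff when simulate is off
    maf_threshold: float = 0.05
    pca_components: int = 10
    ld: dict | None = field(default_factory=dict)   # thin_bp, bin_bp, max_dist_bp
    corr: bool = True
    gwas: dict | None = field(default_factory=dict) # traits, threshold, covar_pcs, use_grm, flank_bp
    predict: dict | None = field(default_factory=dict)  # traits, n_iter, burn_in, thin

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.simulate is None and not cfg.inputs.get("vcf"):
            raise ValueError("either a simulate block or inputs.vcf is required")
        for key in ("vcf", "pheno", "gff"):
            p = cfg.inputs.get(key)
            if cfg.simulate is None and p and not Path(p).exists():
                raise FileNotFoundError(f"inputs.{key}: {p} does not exist")
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    logging.getLogger("ordgen").addHandler(log_handler)
    manifest: dict = {"config": _jsonable(config.__dict__), "stages": {}, "files": {}}

    def _record(name: str, **summary):
        manifest["stages"][name] = summary

    def _save_manifest():
        for f in sorted(out.glob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "setup"
    try:
        # ---- obtain panel and phenotypes
        if config.simulate is not None:
            stage = "simulate"
            t0 = time.time()
            sim_kwargs = dict(config.simulate)
            trait_block = sim_kwargs.pop("trait", {})
            sim_kwargs.setdefault("seed", _stage_seed(config.seed, "simulate"))
            sim_cfg = synthetic_data.SimulationConfig(**sim_kwargs)
            panel = synthetic_data.simulate_genotypes(sim_cfg)
            model = synthetic_data.TraitModel(**trait_block)
            table, truths = synthetic_data.simulate_trait_table(
                panel, _stage_seed(config.seed, "traits"), model=model
            )
            io_formats.write_vcf(panel, out / "panel.vcf")
            table.write(out / "phenotypes.tsv")
            truth_wide = pd.concat(
                {name: _strip_attrs(t.set_index("id")[["g_true", "liability"]]) for name, t in truths.items()},
                axis=1,
            )
            truth_wide.to_csv(out / "truth.tsv", sep="\t")
            _record("simulate", n_individuals=panel.n_individuals, n_snps=panel.n_snps,
                    seconds=round(time.time() - t0, 2))
        else:
            stage = "load"
            panel = io_formats.read_vcf(config.inputs["vcf"])
            table = io_formats.read_phenotypes(config.inputs["pheno"]) if config.inputs.get("pheno") else None
            if table is not None:
                sex = table.data.set_index("id")["sex"]
                panel.individuals["sex"] = panel.individuals["id"].map(sex).fillna("unknown")
            _record("load", n_individuals=panel.n_individuals, n_snps=panel.n_snps)

        stage = "filter"
        panel = io_formats.impute_missing_naive(panel)
        filtered = popgen.maf_filter(panel, config.maf_threshold)
        _record("filter", maf_threshold=config.maf_threshold, n_snps_kept=filtered.n_snps)

        stage = "pca"
        pca_res = popgen.pca(filtered, config.pca_components)
        scores = pd.DataFrame(
            pca_res.scores,
            columns=[f"PC{i+1}" for i in range(pca_res.n_components)],
        )
        scores.insert(0, "id", filtered.individuals["id"])
        scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
        _record("pca", pve=[round(float(v), 6) for v in pca_res.pve])

        grm = popgen.vanraden_grm(filtered)
        pd.DataFrame(grm.matrix, index=grm.ids, columns=grm.ids).to_csv(out / "grm.tsv", sep="\t")

        if config.ld is not None:
            stage = "ld"
            t0 = time.time()
            ldc = config.ld
            thinned = ld_analysis.thin_snps(filtered, ldc.get("thin_bp", 50_000))
            pairs = ld_analysis.pairwise_r2(thinned, ldc.get("max_dist_bp", 1_000_000))
            pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
            curves = []
            for chrom, sub in pairs.groupby("chrom"):
                curve = ld_analysis.ld_decay(sub, ldc.get("bin_bp", 10_000))
                curves.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "bin_start": curve.bin_edges[:-1].astype(int),
                            "bin_end": curve.bin_edges[1:].astype(int),
                            "mean_r2": curve.mean_r2,
                            "n_pairs": curve.pair_counts,
                        }
                    )
                )
            if curves:
                pd.concat(curves, ignore_index=True).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
            _record("ld", n_pairs=len(pairs), seconds=round(time.time() - t0, 2))

        if config.corr and table is not None and len(table.trait_names) >= 2:
            stage = "corr"
            cm = ordinal_stats.correlation_matrix(table)
            cm.to_long().to_csv(out / "trait_correlations.tsv", sep="\t", index=False)
            _record("corr", n_traits=len(table.trait_names))

        if config.gwas is not None and table is not None:
            stage = "gwas"
            t0 = time.time()
            gw = config.gwas
            n_pcs = int(gw.get("covar_pcs", 10))
            sex_col = filtered.sex_indicator()
            traits = gw.get("traits") or table.trait_names
            genes = io_formats.read_gff3(config.inputs["gff"]) if config.inputs.get("gff") else None
            n_sig = {}
            for trait in traits:
                y = table.scores(trait)
                keep = ~np.isnan(y)
                sub = _subset_individuals(filtered, keep)
                covar = np.column_stack([sex_col[keep], pca_res.scores[keep, :n_pcs]])
                G_arg = popgen.vanraden_grm(sub) if gw.get("use_grm") else None
                null = ordinal_gwas.fit_null(y[keep], covar, G=G_arg)
                scan = ordinal_gwas.genome_scan(sub, null, threshold=gw.get("threshold", 1e-6))
                scan.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
                n_sig[trait] = int(scan["significant"].sum())
                if genes is not None and n_sig[trait]:
                    hits = scan[scan["significant"]]
                    windows = ordinal_gwas.candidate_gene_window(
                        hits, genes, gw.get("flank_bp", 30_000)
                    )
                    windows.to_csv(out / f"candidate_genes_{trait}.tsv", sep="\t", index=False)
            _record("gwas", significant=n_sig, seconds=round(time.time() - t0, 2))

        if config.predict is not None and table is not None:
            stage = "predict"
            t0 = time.time()
            pr = config.predict
            mcmc = tgblup.McmcSettings(
                n_iter=int(pr.get("n_iter", 6000)),
                burn_in=int(pr.get("burn_in", 1000)),
                thin=int(pr.get("thin", 2)),
                seed=_stage_seed(config.seed, "predict"),
            )
            bs = {}
            for trait in pr.get("traits") or table.trait_names:
                rep = tgblup.loo_cv(
                    table.scores(trait),
                    filtered.individuals["sex"].to_numpy(),
                    popgen.vanraden_grm(filtered),
                    mcmc,
                    n_categories=table.n_categories,
                )
                bs[trait] = round(rep.score, 4)
            pd.Series(bs, name="brier_score").rename_axis("trait").to_csv(
                out / "cv_brier_scores.tsv", sep="\t"
            )
            _record("predict", brier=bs, seconds=round(time.time() - t0, 2))

        _save_manifest()
    except Exception as exc:
        _save_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("ordgen").removeHandler(log_handler)
        log_handler.close()
    return manifest


def _subset_individuals(panel: io_formats.GenotypePanel, keep: np.ndarray) -> io_formats.GenotypePanel:
    return io_formats.GenotypePanel(
        dosages=panel.dosages[keep],
        snp_map=panel.snp_map.copy(),
        individuals=panel.individuals.loc[keep].reset_index(drop=True),
    )


def _strip_attrs(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    out.attrs = {}
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
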