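"""End-to-end orchestration of the decomposition pipeline.

Stages run in a fixed order mirroring the analysis design:
ingest/harmonise → matrix build (threshold, retain, optional region
exclusion, clump, standardise) → SVD and attribution → optional gene-set
enrichment → optional external-GWAS correlations → optional PGS
evaluation (meta-subtraction of overlapping cohorts, group-wise PGS,
case–case GWAS).  Every stage writes its table into the run directory
and logs input/output row counts; optional stages are skipped with a
notice when their inputs are absent so the core decomposition is
runnable from summary statistics alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition as dc
from . import enrichment as en
from . import external as ex
from . import matrix as mx
from . import pgs as pg
from . import sumstats as ss

logger = logging.getLogger(__name__)


class ConfigError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Parameters and input declarations for one pipeline run.

    Defaults reproduce the primary analysis settings (p < 1e-3 zeroing,
    retention in ≥ 2 disorders, 500 kb / r² 0.2 clumping, 50% cumulative
    variance for enrichment queries, 20–500 gene-set sizes, FDR 0.05,
    Bonferroni over three case–case comparisons); sensitivity analyses
    (alpha 1e-5 or 0.05, MHC exclusion, alternative discovery GWAS) are
    pure config changes.
    """

    sumstats: dict[str, str] = field(default_factory=dict)  # trait -> path
    column_maps: dict[str, dict[str, str]] = field(default_factory=dict)
    panel: str | None = None
    ld: str | None = None
    snp_gene_map: str | None = None
    gene_sets: str | None = None          # GMT path
    background_genes: str | None = None   # one gene per line
    externals: dict[str, str] = field(default_factory=dict)
    targets: dict[str, str] = field(default_factory=dict)

    alpha: float = 1e-3
    min_traits: int = 2
    window_bp: int = 500_000
    r2_max: float = 0.2
    cumulative_fraction: float = 0.5
    set_size_min: int = 20
    set_size_max: int = 500
    fdr_alpha: float = 0.05
    exclude_regions: list[tuple[str, int, int]] = field(default_factory=list)
    freq_is: str = "control"
    drop_ambiguous: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.exclude_regions = [
            (str(c), int(s), int(e)) for c, s, e in cfg.exclude_regions
        ]
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violated-invariant messages; empty means valid."""
    errors = []
    if not 0.0 < config.alpha < 1.0:
        errors.append(f"alpha must be in (0,1), got {config.alpha}")
    if config.min_traits < 1:
        errors.append(f"min_traits must be >= 1, got {config.min_traits}")
    if config.window_bp < 0:
        errors.append(f"window_bp must be >= 0, got {config.window_bp}")
    if not 0.0 <= config.r2_max <= 1.0:
        errors.append(f"r2_max must be in [0,1], got {config.r2_max}")
    if not 0.0 < config.cumulative_fraction <= 1.0:
        errors.append(
            f"cumulative_fraction must be in (0,1], got {config.cumulative_fraction}"
        )
    if config.set_size_min > config.set_size_max:
        errors.append("set_size_min must be <= set_size_max")
    if not 0.0 < config.fdr_alpha < 1.0:
        errors.append(f"fdr_alpha must be in (0,1), got {config.fdr_alpha}")
    if config.freq_is not in ("control", "pooled"):
        errors.append(f"freq_is must be 'control' or 'pooled', got {config.freq_is}")
    for region in config.exclude_regions:
        if len(region) != 3 or region[1] >= region[2]:
            errors.append(f"bad exclude_region {region}")
    return errors


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    matrix: mx.ZMatrix
    decomposition: dc.Decomposition
    stats: dc.AttributionStats
    harmonisation: dict[str, ss.HarmonisationReport]
    enrichment: dict[int, list[en.EnrichmentResult]] | None = None
    correlations: list[ex.CorrelationResult] | None = None
    group_pgs: list[pg.GroupPGSResult] | None = None
    outdir: Path | None = None


def _write(df: pd.DataFrame, path: Path, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    logger.info("[%s] wrote %s (%d rows)", stage, path.name, len(df))


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Execute all configured stages; see the module docstring for order."""
    errors = validate_config(config)
    if errors:
        raise ConfigError("invalid config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- ingest & harmonise -------------------------------------------------
    if not config.panel:
        raise ConfigError("a reference panel path is required")
    panel = ss.read_panel(config.panel)
    positions = {
        r.snp_id: (r.chrom, int(r.pos)) for r in panel.itertuples(index=False)
    }
    per_trait: dict[str, pd.DataFrame] = {}
    reports: dict[str, ss.HarmonisationReport] = {}
    default_map = {c: c for c in ss.SUMSTATS_COLUMNS if c != "eaf"} | {
        "eaf": "eaf"
    }
    for trait, path in config.sumstats.items():
        cmap = config.column_maps.get(trait, default_map)
        records = ss.read_sumstats(path, cmap)
        harmonised, report = ss.harmonise(
            records, panel, drop_ambiguous=config.drop_ambiguous
        )
        per_trait[trait] = harmonised
        reports[trait] = report
        logger.info("[ingest] %s: %s", trait, report.summary())
    if len(per_trait) < 2:
        raise ConfigError("at least two sumstats inputs are required")

    # --- matrix build -------------------------------------------------------
    ld = mx.LDSource.read(config.ld) if config.ld else mx.LDSource()
    m = mx.build_matrix(
        per_trait,
        ld,
        positions,
        alpha=config.alpha,
        min_traits=config.min_traits,
        window_bp=config.window_bp,
        r2_max=config.r2_max,
        exclude_regions=config.exclude_regions,
    )
    logger.info("[matrix] %d SNPs × %d traits after clumping", *m.shape)
    _write(
        m.to_frame().reset_index(names="snp_id"), outdir / "z_matrix.tsv", "matrix"
    )

    # --- decomposition ------------------------------------------------------
    d = dc.svd_decompose(m)
    stats = dc.attribution_stats(d)
    _write(
        pd.DataFrame(
            {
                "component": np.arange(1, d.n_components + 1),
                "singular_value": d.singular_values,
                "variance_explained": stats.variance_explained,
            }
        ),
        outdir / "variance_explained.tsv",
        "svd",
    )
    _write(
        pd.DataFrame(
            d.pheno_vectors,
            index=pd.Index(d.trait_ids, name="trait"),
            columns=[f"PC{k + 1}" for k in range(d.n_components)],
        ).reset_index(),
        outdir / "pheno_vectors.tsv",
        "svd",
    )
    _write(
        pd.DataFrame(
            stats.snp_contribution,
            index=pd.Index(d.snp_ids, name="snp_id"),
            columns=[f"PC{k + 1}" for k in range(d.n_components)],
        ).reset_index(),
        outdir / "snp_contributions.tsv",
        "svd",
    )

    result = PipelineResult(
        matrix=m, decomposition=d, stats=stats, harmonisation=reports, outdir=outdir
    )

    # --- enrichment (optional) ----------------------------------------------
    if config.snp_gene_map and config.gene_sets and config.background_genes:
        mapping = en.read_snp_gene_map(config.snp_gene_map)
        background = {
            g.strip()
            for g in Path(config.background_genes).read_text().splitlines()
            if g.strip()
        }
        coll = en.GeneSetCollection(en.read_gmt(config.gene_sets), background)
        coll = en.filter_sets(coll, config.set_size_min, config.set_size_max)
        enrich: dict[int, list[en.EnrichmentResult]] = {}
        frames = []
        for k in range(d.n_components):
            snps = dc.cumulative_top_snps(stats, k, config.cumulative_fraction)
            genes, _ = en.map_snps_to_genes(set(snps), mapping)
            if not genes or not coll.sets:
                logger.info("[enrichment] PC%d: nothing to test", k + 1)
                continue
            res = en.hypergeom_ora(genes, coll)
            enrich[k] = res
            f = en.results_frame(res)
            f.insert(0, "component", k + 1)
            frames.append(f)
        if frames:
            _write(pd.concat(frames), outdir / "enrichment.tsv", "enrichment")
        result.enrichment = enrich
    else:
        logger.info("[enrichment] skipped: annotations not configured")

    # --- external correlations (optional) -----------------------------------
    if config.externals:
        externals = {}
        for trait, path in config.externals.items():
            cmap = config.column_maps.get(trait, default_map)
            records = ss.read_sumstats(path, cmap)
            harmonised, report = ss.harmonise(
                records, panel, drop_ambiguous=config.drop_ambiguous
            )
            logger.info("[external] %s: %s", trait, report.summary())
            externals[trait] = harmonised
        decomp_z = {
            k: dc.loading_zscores(d, k) for k in range(d.n_components)
        }
        grid = ex.correlation_grid(decomp_z, externals)
        _write(ex.grid_frame(grid), outdir / "external_correlations.tsv", "external")
        result.correlations = grid
    else:
        logger.info("[external] skipped: no external GWAS configured")

    # --- PGS evaluation (optional) ------------------------------------------
    if config.targets:
        rows = []
        group_results = []
        for k in range(d.n_components):
            weights = pg.pc_pgs_weights(d, k, panel)
            pg.write_weights(weights, outdir / f"weights_PC{k + 1}.tsv")
            for target_name, path in config.targets.items():
                cmap = config.column_maps.get(target_name, default_map)
                records = ss.read_sumstats(path, cmap)
                harmonised, _ = ss.harmonise(
                    records, panel, drop_ambiguous=config.drop_ambiguous
                )
                res = pg.group_pgs(weights, harmonised, freq_is=config.freq_is)
                group_results.append(res)
                rows.append(
                    {
                        "component": k + 1,
                        "target": target_name,
                        "mean_case": res.mean_a,
                        "mean_control": res.mean_b,
                        "se_mean_case": res.sd_a / np.sqrt(res.n_a),
                        "se_mean_control": res.sd_b / np.sqrt(res.n_b),
                        "t": res.t,
                        "r2": res.r2,
                        "p_value": res.p_value,
                    }
                )
        _write(pd.DataFrame(rows), outdir / "group_pgs.tsv", "pgs")
        result.group_pgs = group_results
    else:
        logger.info("[pgs] skipped: no target GWAS configured")

    # --- manifest -----------------------------------------------------------
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_snps": m.shape[0],
        "n_traits": m.shape[1],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
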