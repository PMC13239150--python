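"""Synthetic multi-trait GWAS summary statistics with planted structure.

The generator emulates the inputs the pipeline consumes in the real
setting — per-disorder case-control summary statistics, a reference
variant panel, an LD table, variant-to-gene annotations and target
cohorts — with a known low-rank latent structure planted in the
association Z-scores so that recovery can be scored exactly.

Model.  K orthonormal phenotype factors and a sparse SNP factor matrix
define a signal matrix ``snp_factors · diag(scales) · pheno_factorsᵀ``;
the observed Z-score of SNP i in trait t is the signal entry plus
independent Gaussian noise with standard deviation ``noise_sd``.  The
null sampling distribution of a GWAS Z-statistic has unit variance, so
``noise_sd = 1`` is the realistic setting and ``scales`` control the
signal-to-noise ratio.  Betas and standard errors are back-derived from
Z via ``se = 1/sqrt(2·f·(1−f)·n_eff)`` with ``n_eff = 4/(1/n_case +
1/n_control)``, the usual effective sample size of a case-control GWAS,
so the written files look like genuine log-odds-ratio statistics.

LD is block-diagonal: consecutive SNPs form blocks with a single
within-block r² and zero across blocks; blocks span less than the
default 500 kb clumping window and distinct blocks are farther apart
than it, so greedy clumping at r² ≤ 0.2 keeps exactly one SNP per block.

Target cohorts for PGS evaluation are generated at the individual level
(genotypes Binomial(2, f) per group under Hardy–Weinberg) and summarised
from the realised counts, so analytic summary-statistics evaluation can
be validated against ground-truth individual scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LDSource
from .pgs import PGSWeightSet
from .sumstats import SUMSTATS_COLUMNS


class SyntheticError(RuntimeError):
    pass


#: Allele pairs that are never strand-ambiguous.
_UNAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class PlantedModel:
    """Ground-truth low-rank structure behind a synthetic study."""

    n_traits: int
    n_snps: int
    n_components: int
    pheno_factors: np.ndarray  # n_traits × K, orthonormal columns
    snp_factors: np.ndarray    # n_snps × K, sparse
    factor_scales: np.ndarray  # K positive
    seed: int

    def signal(self) -> np.ndarray:
        return self.snp_factors @ np.diag(self.factor_scales) @ self.pheno_factors.T


@dataclass
class SyntheticStudy:
    """A complete synthetic multi-trait study plus its generating truth."""

    sumstats: dict[str, pd.DataFrame]
    panel: pd.DataFrame
    ld: LDSource
    ld_table: pd.DataFrame
    positions: dict[str, tuple[str, int]]
    truth: PlantedModel
    z_signal: np.ndarray
    z_observed: np.ndarray
    snp_ids: list[str]
    trait_ids: list[str]


def generate_model(
    n_traits: int = 8,
    n_snps: int = 2000,
    n_components: int = 3,
    sparsity: float = 0.3,
    scales: tuple[float, ...] = (10.0, 7.0, 5.0),
    seed: int = 0,
) -> PlantedModel:
    """Draw a planted factor model; deterministic given the seed."""
    if not (1 <= n_components <= n_traits <= n_snps):
        raise SyntheticError(
            "require n_components <= n_traits <= n_snps, got "
            f"K={n_components}, T={n_traits}, S={n_snps}"
        )
    if not 0.0 < sparsity <= 1.0:
        raise SyntheticError(f"sparsity must be in (0,1], got {sparsity}")
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (n_components,) or np.any(scales <= 0):
        raise SyntheticError("scales must be K positive floats")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_traits, n_components)))
    snp_factors = rng.standard_normal((n_snps, n_components))
    snp_factors *= rng.random((n_snps, n_components)) < sparsity
    return PlantedModel(
        n_traits=n_traits,
        n_snps=n_snps,
        n_components=n_components,
        pheno_factors=q,
        snp_factors=snp_factors,
        factor_scales=scales,
        seed=seed,
    )


def generate_ld_blocks(
    n_snps: int,
    block_size: int = 4,
    r2_within: float = 0.6,
    seed: int = 0,
    chrom: str = "1",
    within_spacing_bp: int = 10_000,
    block_gap_bp: int = 600_000,
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]], list[str]]:
    """Block LD table and positions for ``n_snps`` consecutive SNPs.

    Pairs within a block share ``r2_within``; across blocks r² is zero.
    Default spacing keeps a block inside the 500 kb clumping window and
    separates distinct blocks by more than it.  Returns (ld_table,
    positions, snp_ids).
    """
    if block_size < 1:
        raise SyntheticError("block_size must be >= 1")
    if not 0.0 <= r2_within <= 1.0:
        raise SyntheticError("r2_within must be in [0,1]")
    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    positions: dict[str, tuple[str, int]] = {}
    pairs = []
    pos = 1_000_000
    for start in range(0, n_snps, block_size):
        block = snp_ids[start : start + block_size]
        for j, s in enumerate(block):
            positions[s] = (chrom, pos + j * within_spacing_bp)
        pos += (len(block) - 1) * within_spacing_bp + block_gap_bp
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                pairs.append((block[i], block[j], r2_within))
    ld_table = pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"])
    return ld_table, positions, snp_ids


def _make_panel(
    snp_ids: list[str],
    positions: dict[str, tuple[str, int]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=len(snp_ids))
    rows = []
    for s, pi in zip(snp_ids, pair_idx):
        a1, a2 = _UNAMBIGUOUS_PAIRS[pi]
        chrom, pos = positions[s]
        rows.append((s, a1, a2, chrom, pos))
    return pd.DataFrame(rows, columns=["snp_id", "allele1", "allele2", "chrom", "pos"])


def generate_sumstats(
    model: PlantedModel,
    n_per_trait: dict[str, tuple[int, int]] | None = None,
    noise_sd: float = 1.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 1,
    block_size: int = 4,
    r2_within: float = 0.6,
) -> SyntheticStudy:
    """Full synthetic study from a planted model.

    ``n_per_trait`` maps trait id to (n_case, n_control); the default is
    eight disorders with sample sizes spanning the range typical of
    psychiatric consortium GWAS (tens of thousands to hundreds of
    thousands).  Deterministic given ``seed``.
    """
    if n_per_trait is None:
        n_per_trait = {
            f"trait{j + 1}": (20_000 + 15_000 * j, 50_000 + 40_000 * j)
            for j in range(model.n_traits)
        }
    if len(n_per_trait) != model.n_traits:
        raise SyntheticError(
            f"n_per_trait has {len(n_per_trait)} traits, model has {model.n_traits}"
        )
    rng = np.random.default_rng(seed)
    ld_table, positions, snp_ids = generate_ld_blocks(
        model.n_snps, block_size=block_size, r2_within=r2_within, seed=seed
    )
    panel = _make_panel(snp_ids, positions, rng)
    signal = model.signal()
    observed = signal + noise_sd * rng.standard_normal(signal.shape)
    trait_ids = list(n_per_trait.keys())
    sumstats: dict[str, pd.DataFrame] = {}
    for j, trait in enumerate(trait_ids):
        n_case, n_control = n_per_trait[trait]
        n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
        f = rng.uniform(maf_range[0], maf_range[1], size=model.n_snps)
        se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_eff)
        z = observed[:, j]
        df = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": [positions[s][0] for s in snp_ids],
                "pos": [positions[s][1] for s in snp_ids],
                "effect_allele": panel["allele1"].to_numpy(),
                "other_allele": panel["allele2"].to_numpy(),
                "beta": z * se,
                "se": se,
                "p_value": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
                "eaf": f,
                "n_case": n_case,
                "n_control": n_control,
            }
        )[SUMSTATS_COLUMNS]
        sumstats[trait] = df
    return SyntheticStudy(
        sumstats=sumstats,
        panel=panel,
        ld=LDSource.from_table(ld_table),
        ld_table=ld_table,
        positions=positions,
        truth=model,
        z_signal=signal,
        z_observed=observed,
        snp_ids=snp_ids,
        trait_ids=trait_ids,
    )


def observed_zmatrix(study: SyntheticStudy):
    """The study's observed Z matrix as a :class:`~pleiopc.matrix.ZMatrix`.

    Used by factor-recovery experiments, which decompose the generated
    matrix directly (no thresholding or standardisation) so recovered
    phenotype singular vectors are comparable to the planted orthonormal
    factors.
    """
    from .matrix import ZMatrix

    return ZMatrix(
        list(study.snp_ids),
        list(study.trait_ids),
        study.z_observed,
        np.ones_like(study.z_observed, dtype=bool),
    )


def generate_target_cohort(
    weights: PGSWeightSet,
    n_case: int = 2000,
    n_control: int = 2000,
    effect_shift: float = 0.0,
    seed: int = 0,
    positions: dict[str, tuple[str, int]] | None = None,
    panel: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Individual-level target cohort summarised as a case-control GWAS.

    Control allele frequencies are uniform in (0.2, 0.8); case
    frequencies are shifted by ``effect_shift`` along the sign of each
    SNP's weight (clipped to (0.05, 0.95)), so a positive shift enriches
    cases for score-increasing alleles.  Genotypes are Binomial(2, f) per
    group; the returned summary statistics (log OR, Woolf SE, p, control
    EAF) are computed from the realised genotype counts, so
    count-reconstruction is exact against the returned genotypes.

    Returns ``(sumstats_frame, extras)`` where extras holds
    ``genotypes_case`` / ``genotypes_control`` (individuals × SNPs),
    ``f_case`` / ``f_control`` realised frequencies and ``snp_ids``.
    """
    if len(weights) == 0:
        raise SyntheticError("weight set is empty")
    rng = np.random.default_rng(seed)
    snp_ids = list(weights.entries.keys())
    w = np.array([weights.entries[s][1] for s in snp_ids])
    f_ctrl_true = rng.uniform(0.2, 0.8, size=len(snp_ids))
    f_case_true = np.clip(f_ctrl_true + effect_shift * np.sign(w), 0.05, 0.95)
    g_case = rng.binomial(2, f_case_true, size=(n_case, len(snp_ids)))
    g_ctrl = rng.binomial(2, f_ctrl_true, size=(n_control, len(snp_ids)))
    # realised allele counts; +0.0 keeps everything float
    a = g_case.sum(axis=0).astype(float)
    b = 2.0 * n_case - a
    c = g_ctrl.sum(axis=0).astype(float)
    d = 2.0 * n_control - c
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    if not ok.all():
        raise SyntheticError(
            "monomorphic realised genotypes; increase n or adjust frequencies"
        )
    beta = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    rows = []
    for i, s in enumerate(snp_ids):
        allele = weights.entries[s][0]
        if panel is not None:
            prow = panel.loc[panel["snp_id"] == s]
            other = prow["allele2"].iloc[0] if len(prow) else "G"
            chrom, pos = (
                positions[s] if positions and s in positions else ("1", i + 1)
            )
        else:
            other = "G" if allele != "G" else "C"
            chrom, pos = positions[s] if positions and s in positions else ("1", i + 1)
        rows.append(
            {
                "snp_id": s,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": allele,
                "other_allele": other,
                "beta": beta[i],
                "se": se[i],
                "p_value": float(2.0 * stats.norm.sf(abs(beta[i] / se[i]))),
                "eaf": c[i] / (2.0 * n_control),
                "n_case": n_case,
                "n_control": n_control,
            }
        )
    df = pd.DataFrame(rows)[SUMSTATS_COLUMNS]
    extras = {
        "genotypes_case": g_case,
        "genotypes_control": g_ctrl,
        "f_case": a / (2.0 * n_case),
        "f_control": c / (2.0 * n_control),
        "snp_ids": snp_ids,
    }
    return df, extras


def generate_gene_annotations(
    snp_ids: list[str],
    snps_per_gene: int = 5,
    seed: int = 0,
    enriched_sets: dict[str, list[str]] | None = None,
    n_random_sets: int = 20,
    random_set_size: int = 25,
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    """Interval-based SNP→gene map plus gene-set collections for testing.

    Gene ``GENE{j}`` owns ``snps_per_gene`` consecutive SNPs (top-scoring
    assignment; the neighbouring gene is flagged as within 100 kb for
    every block-boundary SNP).  ``enriched_sets`` maps a set name to the
    SNPs whose owning genes should form that set — built from
    top-contribution SNPs of a planted component, such a set is genuinely
    over-represented in the component's query genes.  Random filler sets
    are drawn from all genes.  Returns (mapping frame, gene sets,
    background genes).
    """
    rng = np.random.default_rng(seed)
    gene_of = {
        s: f"GENE{i // snps_per_gene + 1}" for i, s in enumerate(snp_ids)
    }
    rows = []
    n_genes = (len(snp_ids) - 1) // snps_per_gene + 1
    for i, s in enumerate(snp_ids):
        rows.append((s, gene_of[s], 0.9, True))
        # boundary SNPs also sit near the next gene
        if (i % snps_per_gene) == snps_per_gene - 1 and (i // snps_per_gene + 2) <= n_genes:
            rows.append((s, f"GENE{i // snps_per_gene + 2}", 0.4, True))
    mapping = pd.DataFrame(rows, columns=["snp_id", "gene", "v2g_score", "within_100kb"])
    background = {f"GENE{j + 1}" for j in range(n_genes)}
    sets: dict[str, set[str]] = {}
    for name, set_snps in (enriched_sets or {}).items():
        sets[name] = {gene_of[s] for s in set_snps if s in gene_of}
    all_genes = sorted(background)
    for j in range(n_random_sets):
        size = min(random_set_size, len(all_genes))
        sets[f"RANDOM_SET_{j + 1}"] = set(
            rng.choice(all_genes, size=size, replace=False)
        )
    return mapping, sets, background


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write every study table as delimited text plus a seed manifest."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for trait, df in study.sumstats.items():
        p = outdir / f"sumstats_{trait}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[f"sumstats_{trait}"] = str(p)
    study.panel.to_csv(outdir / "panel.tsv", sep="\t", index=False)
    paths["panel"] = str(outdir / "panel.tsv")
    study.ld_table.to_csv(outdir / "ld.tsv", sep="\t", index=False)
    paths["ld"] = str(outdir / "ld.tsv")
    manifest = {
        "seed": study.truth.seed,
        "n_traits": study.truth.n_traits,
        "n_snps": study.truth.n_snps,
        "n_components": study.truth.n_components,
        "factor_scales": study.truth.factor_scales.tolist(),
        "trait_ids": study.trait_ids,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
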