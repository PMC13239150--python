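"""Component polygenic scores evaluated from summary statistics alone.

A component PGS weights each matrix SNP by its (signed) entry in the
component's SNP singular vector, oriented to the reference panel's
effect allele.  Because no individual-level genotypes are available,
evaluation relies on allelic-count algebra:

* :func:`meta_subtract` removes one cohort from an inverse-variance
  meta-analysis so discovery statistics do not overlap the target.
* :func:`reconstruct_counts` recovers case/control allele counts for a
  SNP from its odds ratio, allele frequency and sample sizes.
* :func:`group_pgs` computes analytic group means and SDs of the PGS in
  cases and controls under Hardy–Weinberg sampling (genotype at SNP i ~
  Binomial(2, f_i) independently across clumped SNPs) and compares them
  with a Welch two-sample t-test; the variance explained is
  R² = t²/(t²+df).
* :func:`cc_gwas` contrasts two case groups directly (case–case GWAS):
  per SNP, the case-frequency odds ratio between groups with a Woolf
  standard error on the reconstructed case counts.

Group means and SDs are reported on a per-SNP-average scale (sums
divided by the number of SNPs used), which cancels in t and R².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import Decomposition

logger = logging.getLogger(__name__)


class PGSError(RuntimeError):
    pass


@dataclass
class PGSWeightSet:
    """Per-SNP signed weights for one component, tied to an effect allele."""

    component: int
    entries: dict[str, tuple[str, float]]  # snp_id -> (effect_allele, weight)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, a, w) for s, (a, w) in self.entries.items()],
            columns=["snp_id", "effect_allele", "weight"],
        )


@dataclass
class GroupPGSResult:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    n_snps: int
    t: float
    df: float
    p_value: float
    r2: float


@dataclass
class CountTable:
    """Reconstructed 2×2 allele counts per SNP (effect/other × case/control)."""

    snp_id: str
    a: float  # effect allele in cases
    b: float  # other allele in cases
    c: float  # effect allele in controls
    d: float  # other allele in controls

    @property
    def f_case(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def f_control(self) -> float:
        return self.c / (self.c + self.d)


def pc_pgs_weights(
    d: Decomposition,
    k: int,
    panel: pd.DataFrame,
    squared: bool = False,
) -> PGSWeightSet:
    """Weights of the component-``k`` PGS.

    The default weight is the signed SNP singular-vector loading, which
    preserves direction of effect; ``squared=True`` instead uses the
    squared loading (the SNP's variance contribution), available for
    comparison but direction-blind.  Effect alleles follow the panel's
    first allele, matching the harmonised record orientation.
    """
    if not 0 <= k < d.n_components:
        raise PGSError(f"component index {k} out of range")
    allele1 = panel.set_index("snp_id")["allele1"]
    missing = [s for s in d.snp_ids if s not in allele1.index]
    if missing:
        raise PGSError(f"panel lacks alleles for SNPs, e.g. {missing[:3]}")
    col = d.snp_vectors[:, k]
    if squared:
        col = col**2
    entries = {
        s: (allele1[s], float(w)) for s, w in zip(d.snp_ids, col)
    }
    return PGSWeightSet(component=k, entries=entries)


def write_weights(weights: PGSWeightSet, path) -> None:
    """Write a 3-column score file (snp_id, effect_allele, weight)."""
    weights.to_frame().to_csv(path, sep="\t", index=False)


def meta_subtract(meta: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Remove one cohort from inverse-variance meta-analysed statistics.

    With weights w = 1/SE², the leave-one-out estimate is
    beta = (w_meta·beta_meta − w_cohort·beta_cohort) / (w_meta − w_cohort)
    and SE = (w_meta − w_cohort)^(−1/2); p is recomputed from beta/SE
    against the standard normal.  SNPs where the cohort's weight is not
    strictly smaller than the meta's are dropped with a warning, as the
    subtraction is degenerate.  Only SNPs present in both frames are
    returned; alleles must already be harmonised to one panel.
    """
    merged = meta.merge(
        cohort[["snp_id", "beta", "se"]], on="snp_id", suffixes=("", "_cohort")
    )
    w_meta = 1.0 / merged["se"] ** 2
    w_cohort = 1.0 / merged["se_cohort"] ** 2
    valid = w_meta > w_cohort
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "meta_subtract: dropping %d SNPs with non-positive residual weight", n_bad
        )
    merged = merged[valid]
    w_meta, w_cohort = w_meta[valid], w_cohort[valid]
    out = merged[[c for c in merged.columns if not c.endswith("_cohort")]].copy()
    out["beta"] = (w_meta * merged["beta"] - w_cohort * merged["beta_cohort"]) / (
        w_meta - w_cohort
    )
    out["se"] = (w_meta - w_cohort) ** -0.5
    out["p_value"] = 2.0 * stats.norm.sf(np.abs(out["beta"] / out["se"]))
    return out.reset_index(drop=True)


def inverse_variance_meta(cohorts: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis over shared SNPs."""
    if not cohorts:
        raise PGSError("no cohorts to meta-analyse")
    base = cohorts[0].copy()
    w_sum = 1.0 / base["se"] ** 2
    bw_sum = base["beta"] * w_sum
    for cohort in cohorts[1:]:
        aligned = base[["snp_id"]].merge(cohort, on="snp_id")
        if len(aligned) != len(base):
            raise PGSError("cohorts do not share an identical SNP set")
        w = 1.0 / aligned["se"].to_numpy() ** 2
        w_sum = w_sum + w
        bw_sum = bw_sum + aligned["beta"].to_numpy() * w
    base["beta"] = bw_sum / w_sum
    base["se"] = w_sum**-0.5
    base["p_value"] = 2.0 * stats.norm.sf(np.abs(base["beta"] / base["se"]))
    return base


def _case_freq_from_or(or_: float, f_ctrl: float) -> float:
    return or_ * f_ctrl / (1.0 - f_ctrl + or_ * f_ctrl)


def reconstruct_counts(
    record: pd.Series, freq_is: str = "control"
) -> CountTable | None:
    """Reconstruct per-group allele counts from one GWAS record.

    ``freq_is`` declares what the record's ``eaf`` measures: the control
    allele frequency (``"control"``) or the pooled case+control frequency
    (``"pooled"``).  In control mode the case frequency follows directly
    from the odds ratio; in pooled mode it is the root of the quadratic
    implied jointly by the odds ratio and the pooled-frequency
    constraint, taking the root with both frequencies in (0, 1).
    Returns None (with a warning) when no admissible root exists.
    """
    if freq_is not in ("control", "pooled"):
        raise PGSError(f"freq_is must be 'control' or 'pooled', got {freq_is!r}")
    eaf = float(record["eaf"])
    n_case = float(record["n_case"])
    n_control = float(record["n_control"])
    if not (0.0 < eaf < 1.0) or not np.isfinite(record["beta"]):
        return None
    if not (n_case > 0 and n_control > 0):
        return None
    or_ = math.exp(float(record["beta"]))
    if freq_is == "control":
        f_ctrl = eaf
        f_case = _case_freq_from_or(or_, f_ctrl)
    else:
        n_total = n_case + n_control
        if abs(or_ - 1.0) < 1e-12:
            f_ctrl = eaf
        else:
            # n_ctrl(OR-1)·f² + [n_case·OR + n_ctrl − N·eaf(OR-1)]·f − N·eaf = 0
            aa = n_control * (or_ - 1.0)
            bb = n_case * or_ + n_control - n_total * eaf * (or_ - 1.0)
            cc = -n_total * eaf
            disc = bb * bb - 4.0 * aa * cc
            if disc < 0:
                logger.warning("no real root for SNP %s", record.get("snp_id"))
                return None
            roots = [(-bb + math.sqrt(disc)) / (2 * aa), (-bb - math.sqrt(disc)) / (2 * aa)]
            admissible = [
                f for f in roots
                if 0.0 < f < 1.0 and 0.0 < _case_freq_from_or(or_, f) < 1.0
            ]
            if not admissible:
                logger.warning("no admissible root for SNP %s", record.get("snp_id"))
                return None
            f_ctrl = admissible[0]
        f_case = _case_freq_from_or(or_, f_ctrl)
    if not (0.0 < f_case < 1.0 and 0.0 < f_ctrl < 1.0):
        return None
    return CountTable(
        snp_id=str(record.get("snp_id", "")),
        a=2.0 * n_case * f_case,
        b=2.0 * n_case * (1.0 - f_case),
        c=2.0 * n_control * f_ctrl,
        d=2.0 * n_control * (1.0 - f_ctrl),
    )


def counts_to_sumstats(table: CountTable) -> dict[str, float]:
    """Summary statistics (beta, SE, p, control EAF) from a 2×2 count table.

    The Woolf standard error sqrt(1/a+1/b+1/c+1/d) is used; this is the
    exact inverse of :func:`reconstruct_counts` in control-frequency mode.
    """
    or_ = (table.a / table.b) / (table.c / table.d)
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    beta = math.log(or_)
    return {
        "beta": beta,
        "se": se,
        "p_value": float(2.0 * stats.norm.sf(abs(beta) / se)),
        "eaf": table.f_control,
        "n_case": (table.a + table.b) / 2.0,
        "n_control": (table.c + table.d) / 2.0,
    }


def welch_t(
    mean_a: float, sd_a: float, n_a: float,
    mean_b: float, sd_b: float, n_b: float,
) -> tuple[float, float, float]:
    """Welch two-sample t, Welch–Satterthwaite df and two-sided p."""
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def r2_from_t(t: float, df: float) -> float:
    """Variance explained by a single predictor from its t-statistic."""
    if df <= 0:
        raise PGSError("df must be positive")
    return t * t / (t * t + df)


def group_pgs(
    weights: PGSWeightSet,
    target: pd.DataFrame,
    freq_is: str = "control",
    group_a: str = "case",
    group_b: str = "control",
) -> GroupPGSResult:
    """Analytic group-wise PGS comparison from target summary statistics.

    Over the intersection of weight SNPs and target records, each group's
    PGS mean is (1/M)·Σ 2·f·w and its SD (1/M)·sqrt(Σ w²·2·f·(1−f)),
    with f the group's reconstructed effect-allele frequency, treating
    post-clumping SNPs as independent under Hardy–Weinberg.  Group sizes
    are taken from the target's n_case / n_control.
    """
    tgt = target.set_index("snp_id")
    shared = [s for s in weights.entries if s in tgt.index]
    if not shared:
        raise PGSError("no overlap between weight SNPs and target GWAS")
    n_missing = len(weights.entries) - len(shared)
    if n_missing:
        logger.info("group_pgs: %d weight SNPs absent from target", n_missing)
    w, fc, ft = [], [], []
    for s in shared:
        rec = tgt.loc[s]
        allele, weight = weights.entries[s]
        if rec["effect_allele"] != allele:
            raise PGSError(
                f"effect-allele mismatch at {s}: weights use {allele}, "
                f"target uses {rec['effect_allele']}; harmonise first"
            )
        table = reconstruct_counts(rec.rename(s), freq_is=freq_is)
        if table is None:
            continue
        w.append(weight)
        fc.append(table.f_case)
        ft.append(table.f_control)
    if not w:
        raise PGSError("no reconstructable SNPs in the intersection")
    w = np.asarray(w)
    fc = np.asarray(fc)
    ft = np.asarray(ft)
    m = len(w)
    mean_a = float(np.sum(2.0 * fc * w) / m)
    mean_b = float(np.sum(2.0 * ft * w) / m)
    sd_a = float(np.sqrt(np.sum(w**2 * 2.0 * fc * (1.0 - fc))) / m)
    sd_b = float(np.sqrt(np.sum(w**2 * 2.0 * ft * (1.0 - ft))) / m)
    n_a = int(tgt.loc[shared[0], "n_case"])
    n_b = int(tgt.loc[shared[0], "n_control"])
    t, df, p = welch_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    return GroupPGSResult(
        group_a=group_a, group_b=group_b,
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
        n_a=n_a, n_b=n_b, n_snps=m,
        t=float(t), df=float(df), p_value=p, r2=r2_from_t(t, df),
    )


def cc_gwas(
    gwas_a: pd.DataFrame,
    gwas_b: pd.DataFrame,
    freq_is: str = "control",
) -> pd.DataFrame:
    """Case–case GWAS reconstructed from two case–control GWAS.

    Per shared SNP, both case allele frequencies are reconstructed; the
    case–case odds ratio is [f_A/(1−f_A)] / [f_B/(1−f_B)], with Woolf SE
    sqrt(1/a_A + 1/b_A + 1/a_B + 1/b_B) on the reconstructed case allele
    counts and a standard-normal p.  The result frame treats group A's
    cases as "cases" and group B's as "controls" (n_case = n_A cases,
    n_control = n_B cases); eaf is group B's case frequency so the output
    is itself consumable by :func:`group_pgs` in control-frequency mode.
    Shared-control covariance between the two source GWAS is not
    corrected for.
    """
    a_idx = gwas_a.set_index("snp_id")
    b_idx = gwas_b.set_index("snp_id")
    shared = [s for s in a_idx.index if s in b_idx.index]
    if not shared:
        raise PGSError("no shared SNPs between the two GWAS")
    rows = []
    for s in shared:
        ra, rb = a_idx.loc[s], b_idx.loc[s]
        if ra["effect_allele"] != rb["effect_allele"]:
            raise PGSError(f"effect-allele mismatch at {s}; harmonise first")
        ta = reconstruct_counts(ra.rename(s), freq_is=freq_is)
        tb = reconstruct_counts(rb.rename(s), freq_is=freq_is)
        if ta is None or tb is None:
            continue
        if min(ta.a, ta.b, tb.a, tb.b) <= 0:
            continue  # monomorphic in one case group
        beta = math.log((ta.f_case / (1 - ta.f_case)) / (tb.f_case / (1 - tb.f_case)))
        se = math.sqrt(1 / ta.a + 1 / ta.b + 1 / tb.a + 1 / tb.b)
        rows.append(
            {
                "snp_id": s,
                "chrom": ra.get("chrom"),
                "pos": ra.get("pos"),
                "effect_allele": ra["effect_allele"],
                "other_allele": ra["other_allele"],
                "beta": beta,
                "se": se,
                "p_value": float(2.0 * stats.norm.sf(abs(beta) / se)),
                "eaf": tb.f_case,
                "n_case": (ta.a + ta.b) / 2.0,
                "n_control": (tb.a + tb.b) / 2.0,
            }
        )
    if not rows:
        raise PGSError("no reconstructable shared SNPs")
    return pd.DataFrame(rows)


def adjust_bonferroni(p_values, m: int) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected level 0.05/m."""
    if m < 1:
        raise PGSError("m must be >= 1")
    return np.asarray(p_values, dtype=float) < 0.05 / m
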