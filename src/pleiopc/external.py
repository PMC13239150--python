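"""Correlation of component SNP loadings with external GWAS Z-scores.

Each component's SNP loadings are standardised to Z-scores and Pearson
correlated with the association Z-scores of the same SNPs from an
external trait's GWAS (harmonised to the same reference panel and allele
orientation as the matrix).  SNPs absent from the external GWAS are
excluded, not zero-filled.  Two-sided p-values come from the usual
t-transform of r with n−2 degrees of freedom; BH FDR is applied across
the full component × trait grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .sumstats import compute_z


class CorrelationError(RuntimeError):
    pass


@dataclass
class CorrelationResult:
    component: int
    trait: str
    n_snps: int
    r: float
    p_value: float
    fdr: float = float("nan")


def correlate_component(
    pc_z: dict[str, float],
    external: pd.DataFrame,
    component: int = 0,
    trait: str = "",
) -> CorrelationResult:
    """Pearson correlation of component loading Z-scores with one external GWAS."""
    ext = external.set_index("snp_id")
    ext_z = compute_z(external).set_axis(ext.index)
    shared = [s for s in pc_z if s in ext_z.index]
    if len(shared) < 3:
        raise CorrelationError(
            f"fewer than 3 shared SNPs with external trait {trait!r}"
        )
    x = np.array([pc_z[s] for s in shared])
    y = ext_z.loc[shared].to_numpy(dtype=float)
    r, p = pearsonr(x, y)
    return CorrelationResult(component, trait, len(shared), float(r), float(p))


def correlation_grid(
    decomp_z: dict[int, dict[str, float]],
    externals: dict[str, pd.DataFrame],
) -> list[CorrelationResult]:
    """All component × external-trait correlations with grid-wide BH FDR."""
    if not decomp_z or not externals:
        raise CorrelationError("need at least one component and one external trait")
    results = [
        correlate_component(pc_z, ext, component=k, trait=trait)
        for k, pc_z in decomp_z.items()
        for trait, ext in externals.items()
    ]
    _, fdr, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for res, q in zip(results, fdr):
        res.fdr = float(q)
    return results


def grid_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
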