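"""SVD of the standardised Z matrix and component attribution statistics.

The matrix ``Z`` (SNPs × traits) is factorised as ``Z = U S Vᵀ`` with
orthonormal SNP singular vectors ``U``, non-increasing singular values
``S`` and orthonormal phenotype singular vectors ``V``.  All components up
to full column rank (K = number of traits) are retained.  Derived
statistics:

* variance explained of component k: ``s_k² / Σ_j s_j²``;
* contribution of a SNP (or phenotype) to component k: the squared entry
  of the unit-norm singular vector, so each column sums to one;
* squared cosine of component k for a trait: the squared
  singular-value-scaled loading ``(V[t,k]·s_k)²`` normalised across
  components, so each trait row sums to one.

Signs of singular vectors are arbitrary; :func:`canonicalise_signs`
orients every component so its largest-magnitude phenotype loading is
positive, which keeps downstream polygenic-score directions reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ZMatrix


class DecompositionError(RuntimeError):
    pass


@dataclass
class Decomposition:
    """Full-rank SVD of a SNP-by-trait matrix."""

    snp_ids: list[str]
    trait_ids: list[str]
    snp_vectors: np.ndarray      # n_snps × K, orthonormal columns (U)
    singular_values: np.ndarray  # K, non-negative, non-increasing
    pheno_vectors: np.ndarray    # n_traits × K, orthonormal columns (V)

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def reconstruct(self) -> np.ndarray:
        return self.snp_vectors @ np.diag(self.singular_values) @ self.pheno_vectors.T


@dataclass
class AttributionStats:
    """Variance shares and per-SNP / per-trait attribution of components."""

    snp_ids: list[str]
    trait_ids: list[str]
    variance_explained: np.ndarray  # K, sums to 1
    snp_contribution: np.ndarray    # n_snps × K, columns sum to 1
    pheno_contribution: np.ndarray  # n_traits × K, columns sum to 1
    squared_cosines: np.ndarray     # n_traits × K, rows sum to 1


def svd_decompose(m: ZMatrix) -> Decomposition:
    """Full-rank SVD with canonical component orientation."""
    n_snps, n_traits = m.shape
    if n_traits < 2 or n_snps < n_traits:
        raise DecompositionError(
            f"need n_snps >= n_traits >= 2, got {n_snps}×{n_traits}"
        )
    if not np.all(np.isfinite(m.z)):
        raise DecompositionError("matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(m.z, full_matrices=False)
    d = Decomposition(list(m.snp_ids), list(m.trait_ids), u, s, vt.T)
    return canonicalise_signs(d)


def canonicalise_signs(d: Decomposition) -> Decomposition:
    """Orient each component so its largest-|loading| phenotype is positive."""
    u = d.snp_vectors.copy()
    v = d.pheno_vectors.copy()
    for k in range(d.n_components):
        lead = np.argmax(np.abs(v[:, k]))
        if v[lead, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return Decomposition(d.snp_ids, d.trait_ids, u, d.singular_values.copy(), v)


def variance_explained(singular_values: np.ndarray) -> np.ndarray:
    """Share of total variance per component: s_k² / Σ s_j²."""
    s2 = np.asarray(singular_values, dtype=float) ** 2
    total = s2.sum()
    if total <= 0:
        raise DecompositionError("all singular values are zero")
    return s2 / total


def contributions(vectors: np.ndarray) -> np.ndarray:
    """Squared entries of unit-norm singular vectors; columns sum to 1."""
    return np.asarray(vectors, dtype=float) ** 2


def squared_cosines(d: Decomposition) -> np.ndarray:
    """Relative contribution of each component to each phenotype.

    Computed on singular-value-scaled loadings (factor scores), so the
    share reflects how much of a trait's representation each component
    carries; each trait row sums to one.
    """
    scores = d.pheno_vectors * d.singular_values[np.newaxis, :]
    sq = scores**2
    row_sums = sq.sum(axis=1)
    dead = np.flatnonzero(row_sums == 0)
    if dead.size:
        raise DecompositionError(
            f"trait {d.trait_ids[dead[0]]!r} has all-zero projections"
        )
    return sq / row_sums[:, np.newaxis]


def attribution_stats(d: Decomposition) -> AttributionStats:
    return AttributionStats(
        snp_ids=list(d.snp_ids),
        trait_ids=list(d.trait_ids),
        variance_explained=variance_explained(d.singular_values),
        snp_contribution=contributions(d.snp_vectors),
        pheno_contribution=contributions(d.pheno_vectors),
        squared_cosines=squared_cosines(d),
    )


def loading_zscores(d: Decomposition, k: int) -> dict[str, float]:
    """SNP loadings of component ``k`` standardised to mean 0, SD 1.

    Used for Pearson correlation against external GWAS Z-scores; the
    correlation is invariant to this affine rescaling, which exists only
    to put loadings on an interpretable Z scale.
    """
    col = d.snp_vectors[:, k]
    sd = col.std()
    if sd == 0:
        raise DecompositionError(f"component {k} has zero-variance loadings")
    z = (col - col.mean()) / sd
    return dict(zip(d.snp_ids, z))


def cumulative_top_snps(
    stats: AttributionStats, k: int, fraction: float = 0.5
) -> list[str]:
    """Smallest prefix of top-contributing SNPs reaching ``fraction`` of component k.

    SNPs are sorted by contribution descending (ties by snp_id) and the
    shortest prefix whose cumulative contribution reaches ``fraction`` is
    returned, in that order.
    """
    if not 0.0 < fraction <= 1.0:
        raise DecompositionError(f"fraction must be in (0,1], got {fraction}")
    contrib = stats.snp_contribution[:, k]
    order = sorted(range(len(stats.snp_ids)), key=lambda i: (-contrib[i], stats.snp_ids[i]))
    out: list[str] = []
    acc = 0.0
    for i in order:
        out.append(stats.snp_ids[i])
        acc += contrib[i]
        if acc >= fraction - 1e-12:
            break
    return out


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruence coefficients between columns of a and b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    return (a.T @ b) / np.outer(na, nb)


def match_components(
    planted: np.ndarray, recovered: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one matching of recovered to planted factor columns.

    Maximises total absolute Tucker congruence via the Hungarian
    algorithm; returns (recovered column index per planted column,
    absolute congruence per planted column).
    """
    from scipy.optimize import linear_sum_assignment

    c = np.abs(tucker_congruence(planted, recovered))
    rows, cols = linear_sum_assignment(-c)
    return cols, c[rows, cols]
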