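"""Construction of the standardised SNP-by-disorder Z-score matrix.

The matrix pipeline follows a fixed order: per-pair significance
thresholding (Z set to zero when p exceeds ``alpha``), assembly over the
union of SNPs, retention of SNPs carried by at least ``min_traits``
disorders, greedy priority LD clumping (500 kb / r-squared 0.2 by default,
prioritising SNPs with non-zero Z in more disorders), and finally
column standardisation to mean zero and unit (population) standard
deviation.  A boolean mask records which cells carried a sub-threshold
association before standardisation so structural zeros remain
distinguishable for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import compute_z


class MatrixError(RuntimeError):
    """Fatal problem during matrix construction."""


@dataclass
class ZMatrix:
    """SNP-by-trait Z-score matrix with a sub-threshold provenance mask."""

    snp_ids: list[str]
    trait_ids: list[str]
    z: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != (len(self.snp_ids), len(self.trait_ids)):
            raise MatrixError("z shape does not match snp/trait ids")
        if self.mask.shape != self.z.shape:
            raise MatrixError("mask shape does not match z")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.snp_ids, columns=self.trait_ids)

    def take_rows(self, idx: np.ndarray) -> "ZMatrix":
        return ZMatrix(
            [self.snp_ids[i] for i in idx],
            list(self.trait_ids),
            self.z[idx],
            self.mask[idx],
        )


class LDSource:
    """Symmetric lookup of pairwise r-squared; absent pairs are r² = 0."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise MatrixError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        if a != b:
            self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "LDSource":
        """Build from a 3-column frame (snp_a, snp_b, r2)."""
        src = cls()
        for a, b, r2 in df.itertuples(index=False):
            src.add(str(a), str(b), float(r2))
        return src

    @classmethod
    def read(cls, path, delimiter: str | None = None) -> "LDSource":
        df = pd.read_csv(path, sep=delimiter if delimiter else r"\s+")
        return cls.from_table(df.iloc[:, :3])


def threshold_z(z: float, p: float, alpha: float) -> tuple[float, bool]:
    """Zero an association whose p-value fails the inclusion threshold.

    Returns ``(z, True)`` when ``p < alpha`` and ``(0.0, False)`` otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise MatrixError(f"alpha must be in (0,1), got {alpha}")
    keep = p < alpha
    return (float(z) if keep else 0.0, bool(keep))


def assemble_matrix(
    per_trait: dict[str, pd.DataFrame], alpha: float
) -> ZMatrix:
    """Assemble the thresholded Z matrix over the union of SNPs.

    ``per_trait`` maps trait id to a harmonised sumstats frame.  Cells for
    SNPs absent from a trait's GWAS are zero with a false mask entry,
    indistinguishable from thresholded cells in ``z`` but not in ``mask``.
    """
    if len(per_trait) < 2:
        raise MatrixError("at least two traits are required")
    if not 0.0 < alpha < 1.0:
        raise MatrixError(f"alpha must be in (0,1), got {alpha}")
    trait_ids = list(per_trait.keys())
    for trait, df in per_trait.items():
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise MatrixError(f"duplicate SNP {dup!r} within trait {trait!r}")
    snp_ids = sorted(set().union(*(df["snp_id"] for df in per_trait.values())))
    row_of = {s: i for i, s in enumerate(snp_ids)}
    z = np.zeros((len(snp_ids), len(trait_ids)))
    mask = np.zeros_like(z, dtype=bool)
    for j, trait in enumerate(trait_ids):
        df = per_trait[trait]
        rows = df["snp_id"].map(row_of).to_numpy()
        keep = (df["p_value"] < alpha).to_numpy()
        zvals = compute_z(df).to_numpy()
        z[rows[keep], j] = zvals[keep]
        mask[rows[keep], j] = True
    return ZMatrix(snp_ids, trait_ids, z, mask)


def filter_min_traits(m: ZMatrix, min_traits: int) -> ZMatrix:
    """Keep SNPs with sub-threshold associations in at least ``min_traits`` traits."""
    if min_traits < 1:
        raise MatrixError(f"min_traits must be >= 1, got {min_traits}")
    keep = np.flatnonzero(m.mask.sum(axis=1) >= min_traits)
    if keep.size == 0:
        raise MatrixError(
            f"no SNP has non-zero Z in at least {min_traits} traits"
        )
    return m.take_rows(keep)


def clump(
    m: ZMatrix,
    ld: LDSource,
    positions: dict[str, tuple[str, int]],
    window_bp: int = 500_000,
    r2_max: float = 0.2,
) -> ZMatrix:
    """Greedy priority clumping to approximately independent index SNPs.

    Candidates are ordered by the number of disorders with non-zero Z
    (descending), then by the largest absolute Z (descending), then by
    snp_id (ascending) for determinism.  The top unclaimed SNP becomes an
    index and claims every unclaimed SNP on the same chromosome within
    ``window_bp`` whose r² with it exceeds ``r2_max``.  Index SNPs are
    returned in the original row order.
    """
    for s in m.snp_ids:
        if s not in positions:
            raise MatrixError(f"missing position for SNP {s!r}")
    counts = m.mask.sum(axis=1)
    maxabs = np.abs(m.z).max(axis=1)
    order = sorted(
        range(len(m.snp_ids)),
        key=lambda i: (-counts[i], -maxabs[i], m.snp_ids[i]),
    )
    claimed = np.zeros(len(m.snp_ids), dtype=bool)
    index_rows: list[int] = []
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        index_rows.append(i)
        chrom_i, pos_i = positions[m.snp_ids[i]]
        for j in order:
            if claimed[j]:
                continue
            chrom_j, pos_j = positions[m.snp_ids[j]]
            if chrom_j != chrom_i or abs(pos_j - pos_i) > window_bp:
                continue
            if ld.r2(m.snp_ids[i], m.snp_ids[j]) > r2_max:
                claimed[j] = True
    return m.take_rows(np.array(sorted(index_rows), dtype=int))


def standardise_columns(m: ZMatrix) -> ZMatrix:
    """Standardise each trait column to mean 0 and SD 1 (denominator n)."""
    mean = m.z.mean(axis=0)
    sd = m.z.std(axis=0)  # population convention; constant cancels in SVD
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise MatrixError(
            f"zero-variance column for trait {m.trait_ids[zero_var[0]]!r}"
        )
    return ZMatrix(list(m.snp_ids), list(m.trait_ids), (m.z - mean) / sd, m.mask)


def exclude_region(
    m: ZMatrix,
    positions: dict[str, tuple[str, int]],
    chrom: str,
    start: int,
    end: int,
) -> ZMatrix:
    """Drop SNPs inside [start, end] (inclusive) on ``chrom``.

    Used to exclude the MHC region (chr6:25,477,797-36,448,354, hg19)
    before clumping in sensitivity analyses.
    """
    if start >= end:
        raise MatrixError("exclude_region requires start < end")
    keep = []
    for i, s in enumerate(m.snp_ids):
        c, p = positions.get(s, (None, None))
        if c == chrom and p is not None and start <= p <= end:
            continue
        keep.append(i)
    return m.take_rows(np.array(keep, dtype=int))


#: hg19 coordinates of the extended MHC region excluded in sensitivity runs.
MHC_REGION = ("6", 25_477_797, 36_448_354)


def build_matrix(
    per_trait: dict[str, pd.DataFrame],
    ld: LDSource,
    positions: dict[str, tuple[str, int]],
    alpha: float = 1e-3,
    min_traits: int = 2,
    window_bp: int = 500_000,
    r2_max: float = 0.2,
    exclude_regions: list[tuple[str, int, int]] | None = None,
) -> ZMatrix:
    """Full fixed-order pipeline: threshold/assemble → retain → (exclude) → clump → standardise."""
    m = assemble_matrix(per_trait, alpha)
    m = filter_min_traits(m, min_traits)
    for chrom, start, end in exclude_regions or []:
        m = exclude_region(m, positions, chrom, start, end)
    m = clump(m, ld, positions, window_bp=window_bp, r2_max=r2_max)
    return standardise_columns(m)
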