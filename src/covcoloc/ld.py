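"""Local linkage-disequilibrium computation from haplotype matrices.

LD is computed from user-supplied or simulated haplotypes only -- no remote
panel queries -- as the Pearson correlation r of 0/1 allele indicators
across haplotypes, with r^2 available as an elementwise square.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .sumstats import VariantKey


@dataclass
class LDMatrix:
    """Signed allele-dosage correlation matrix over an ordered variant list.

    Monomorphic variants have undefined correlations, stored as NaN.
    """

    variants: list[VariantKey]
    r: np.ndarray

    def __post_init__(self):
        q = len(self.variants)
        if self.r.shape != (q, q):
            raise InputError("LD matrix shape does not match variant count")

    @property
    def r2(self) -> np.ndarray:
        return self.r * self.r

    def index_of(self, variant: VariantKey) -> int:
        try:
            return self.variants.index(variant)
        except ValueError:
            raise InputError(f"variant {variant} not present in LD matrix")


def r2_matrix(haplotypes: np.ndarray,
              variants: list[VariantKey] | None = None) -> LDMatrix:
    """Pearson-correlation LD from a haplotype x variant 0/1 matrix.

    Rows are haplotypes, columns variants. Monomorphic columns yield NaN
    rows/columns (their own diagonal entry included). Requires at least two
    haplotypes.
    """
    h = np.asarray(haplotypes, dtype=float)
    if h.ndim != 2 or h.shape[0] < 2:
        raise InputError("need a 2-D matrix with >= 2 haplotype rows")
    q = h.shape[1]
    if variants is None:
        variants = [VariantKey("1", i + 1, "A", "G") for i in range(q)]
    if len(variants) != q:
        raise InputError("variant list length does not match column count")
    sd = h.std(axis=0)
    poly = sd > 0
    r = np.full((q, q), np.nan)
    if poly.any():
        sub = np.corrcoef(h[:, poly], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(poly)
        r[np.ix_(idx, idx)] = sub
    return LDMatrix(list(variants), r)


def ld_to_lead(ld: LDMatrix, lead: VariantKey) -> np.ndarray:
    """Per-variant r^2 relative to a lead variant, aligned to ``ld.variants``."""
    i = ld.index_of(lead)
    return ld.r2[i, :]


def ld_long_format(ld: LDMatrix) -> pd.DataFrame:
    """Long-format (variant_a, variant_b, r, r2) table over the upper triangle."""
    rows = []
    q = len(ld.variants)
    for i in range(q):
        for j in range(i, q):
            rows.append({
                "variant_a": str(ld.variants[i]),
                "variant_b": str(ld.variants[j]),
                "r": ld.r[i, j],
                "r2": ld.r2[i, j],
            })
    return pd.DataFrame(rows)


def read_haplotypes_tsv(path) -> tuple[np.ndarray, list[VariantKey]]:
    """Read a 0/1 haplotype matrix TSV whose header row holds variant keys
    in ``chrom:pos:ref:alt`` form."""
    df = pd.read_csv(path, sep="\t")
    variants = []
    for col in df.columns:
        chrom, pos, ref, alt = str(col).split(":")
        variants.append(VariantKey(chrom, int(pos), ref, alt))
    return df.to_numpy(dtype=np.int8), variants
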