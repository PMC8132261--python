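"""Reading, validation, harmonization and writing of association summary statistics.

GWAS tables follow the COVID-19 Host Genetics Initiative (HGI) release-5
column dialect; eQTL tables follow the GTEx v7 ``all_associations`` dialect.
Both are remappable through a column map. Internally every table is an
:class:`AssocTable`: a study descriptor plus a position-sorted pandas
DataFrame with one row per variant, unique by (chrom, pos, ref, alt).

Coordinates are 1-based (GRCh37-style) throughout; only emitted BED interval
files use 0-based half-open coordinates.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri_exp

from .errors import ConfigError, InputError, NoOverlapError

logger = logging.getLogger(__name__)

PHENOTYPES = ("A2", "B1", "B2", "C2")
ANCESTRIES = ("eur", "multi")
CONTROL_SETS = ("with_ukbb", "without_ukbb")

#: canonical chromosome sort order: 1..22, X, Y
CHROM_ORDER = {str(c): i for i, c in enumerate(list(range(1, 23)) + ["X", "Y"])}

VARIANT_COLS = ["chrom", "pos", "ref", "alt"]
STAT_COLS = ["beta", "se", "p", "eaf", "n"]

#: HGI release-5 column names -> internal names
HGI_COLUMN_MAP = {
    "#CHR": "chrom",
    "POS": "pos",
    "REF": "ref",
    "ALT": "alt",
    "all_inv_var_meta_beta": "beta",
    "all_inv_var_meta_sebeta": "se",
    "all_inv_var_meta_p": "p",
    "all_meta_AF": "eaf",
}

#: GTEx v7 all-associations column names -> internal names
GTEX_COLUMN_MAP = {
    "gene_id": "gene_id",
    "variant_id": "variant_id",
    "maf": "eaf",
    "pval_nominal": "p",
    "slope": "beta",
    "slope_se": "se",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_strand_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref) == alt


def chrom_sort_key(chrom: str) -> int:
    try:
        return CHROM_ORDER[str(chrom)]
    except KeyError:
        raise InputError(f"unrecognised chromosome label {chrom!r}")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, ref and alt allele.

    Ordering is total: canonical chromosome order (1..22, X, Y), then
    position, then ref, then alt. An optional rsID alias may be carried for
    reporting but never participates in identity or ordering.
    """

    sort_index: int = field(init=False, repr=False)
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"invalid allele pair ({self.ref!r}, {self.alt!r})")
        object.__setattr__(self, "sort_index", chrom_sort_key(self.chrom))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class StudyMeta:
    """Descriptor for one GWAS study in an HGI-like panel.

    ``phenotype`` is one of A2 (very severe respiratory confirmed COVID-19
    vs population), B1 (hospitalized vs non-hospitalized patients), B2
    (hospitalized vs population), C2 (all patients vs population).
    ``ancestry`` distinguishes European-only from multi-ethnic meta-analyses
    and ``controls`` whether UK Biobank controls were included.
    """

    study_id: str
    phenotype: str
    ancestry: str
    controls: str
    trait_type: str = "case_control"
    n_total: int = 0
    n_cases: int | None = None
    case_fraction: float | None = None
    sdY: float = 1.0

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ConfigError(f"unknown phenotype {self.phenotype!r}")
        if self.ancestry not in ANCESTRIES:
            raise ConfigError(f"unknown ancestry {self.ancestry!r}")
        if self.controls not in CONTROL_SETS:
            raise ConfigError(f"unknown control set {self.controls!r}")
        if self.trait_type not in ("case_control", "quantitative"):
            raise ConfigError(f"unknown trait type {self.trait_type!r}")
        if self.trait_type == "case_control" and self.n_cases and self.n_total:
            cf = self.n_cases / self.n_total
            if self.case_fraction is None:
                object.__setattr__(self, "case_fraction", cf)
            elif abs(cf - self.case_fraction) > 1e-6:
                raise ConfigError(
                    f"{self.study_id}: case_fraction {self.case_fraction} "
                    f"inconsistent with n_cases/n_total = {cf:.6g}"
                )


@dataclass(frozen=True)
class EqtlDescriptor:
    """One gene x tissue eQTL signal: gene identity, tissue label, sample size."""

    gene_id: str
    gene_name: str = ""
    tissue: str = ""
    n: int = 0
    trait_type: str = "quantitative"
    sdY: float = 1.0

    def __post_init__(self):
        if not self.gene_id:
            raise ConfigError("gene_id must be non-empty")

    @property
    def signal_id(self) -> str:
        return f"{self.gene_id}@{self.tissue}"


class AssocTable:
    """One study's (or one gene-tissue pair's) per-variant association records.

    Wraps a DataFrame with columns chrom, pos, ref, alt, beta, se, p, eaf, n
    (beta/se/eaf/n nullable), sorted by (chrom, pos, ref, alt) and unique by
    variant key.
    """

    def __init__(self, meta: StudyMeta | EqtlDescriptor, df: pd.DataFrame,
                 n_dropped: int = 0, validate: bool = True):
        self.meta = meta
        self.n_dropped = n_dropped
        if validate:
            df = _validate_frame(df, meta)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in self.df.itertuples()
        ]

    def restrict(self, chrom: str, start: int, end: int) -> "AssocTable":
        """Subset to variants on ``chrom`` with start <= pos <= end (1-based)."""
        sub = self.df[
            (self.df["chrom"].astype(str) == str(chrom))
            & (self.df["pos"] >= start)
            & (self.df["pos"] <= end)
        ].reset_index(drop=True)
        return AssocTable(self.meta, sub, validate=False)

    def min_p(self) -> float:
        return float(self.df["p"].min()) if len(self.df) else float("nan")


def _validate_frame(df: pd.DataFrame, meta) -> pd.DataFrame:
    df = df.copy()
    for col in STAT_COLS:
        if col not in df.columns:
            df[col] = np.nan
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["pos"] = df["pos"].astype(np.int64)
    # per-variant n falls back to the study total
    n_total = getattr(meta, "n_total", None) or getattr(meta, "n", None)
    if n_total:
        df["n"] = df["n"].fillna(float(n_total))
    bad_chrom = ~df["chrom"].isin(CHROM_ORDER)
    if bad_chrom.any():
        raise InputError(f"unrecognised chromosome labels: "
                         f"{sorted(df.loc[bad_chrom, 'chrom'].unique())}")
    # p/se z-score consistency check (warn only)
    ok = df["beta"].notna() & df["se"].notna() & df["p"].notna() & (df["se"] > 0)
    if ok.any():
        z_p = -ndtri_exp(np.log(df.loc[ok, "p"].to_numpy()) - np.log(2.0))
        z_b = np.abs(df.loc[ok, "beta"].to_numpy() / df.loc[ok, "se"].to_numpy())
        n_bad = int((np.abs(z_p - z_b) >= 0.1).sum())
        if n_bad:
            logger.warning("%s: %d rows with |z from p| vs |beta/se| differing by >= 0.1",
                           getattr(meta, "study_id", meta), n_bad)
    df["_ck"] = df["chrom"].map(CHROM_ORDER)
    df = df.sort_values(["_ck", "pos", "ref", "alt"], kind="mergesort")
    df = df.drop(columns="_ck").reset_index(drop=True)
    dup = df.duplicated(subset=VARIANT_COLS, keep=False)
    if dup.any():
        # duplicates resolved by keeping the row with the smaller p
        df = (df.sort_values("p", kind="mergesort")
                .drop_duplicates(subset=VARIANT_COLS, keep="first"))
        df["_ck"] = df["chrom"].map(CHROM_ORDER)
        df = df.sort_values(["_ck", "pos", "ref", "alt"], kind="mergesort")
        df = df.drop(columns="_ck").reset_index(drop=True)
    return df


def _numeric_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating numeric domains; return (kept, n_dropped)."""
    n0 = len(df)
    keep = df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1)
    keep &= df["pos"].notna() & (df["pos"] >= 1)
    keep &= df["ref"].notna() & df["alt"].notna() & (df["ref"] != df["alt"])
    if "se" in df.columns:
        keep &= df["se"].isna() | (df["se"] > 0)
    if "eaf" in df.columns:
        keep &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    return df[keep].reset_index(drop=True), n0 - int(keep.sum())


def parse_gwas_sumstats(stream, meta: StudyMeta,
                        column_map: Mapping[str, str] | None = None) -> AssocTable:
    """Parse a delimited GWAS summary-statistics file into an :class:`AssocTable`.

    ``column_map`` maps file column names to the internal names
    (chrom, pos, ref, alt, p required; beta, se, eaf, n optional); defaults
    to the HGI release-5 dialect. Rows failing numeric validation are dropped
    and counted in ``AssocTable.n_dropped``; duplicate variant keys are
    resolved by keeping the record with the smaller p-value.
    """
    column_map = dict(column_map or HGI_COLUMN_MAP)
    raw = pd.read_csv(stream, sep="\t", comment=None, dtype={"#CHR": str},
                      low_memory=False)
    raw = raw.rename(columns=column_map)
    missing = [c for c in VARIANT_COLS + ["p"] if c not in raw.columns]
    if missing:
        raise ConfigError(
            f"column map does not resolve mandatory column(s): {', '.join(missing)}")
    cols = [c for c in VARIANT_COLS + STAT_COLS if c in raw.columns]
    df = raw[cols].copy()
    df["chrom"] = df["chrom"].astype(str)
    for c in ("ref", "alt"):
        df[c] = df[c].astype(str).str.upper()
    df, n_dropped = _numeric_filter(df)
    if len(df) == 0:
        raise InputError(f"{meta.study_id}: no valid rows after filtering")
    return AssocTable(meta, df, n_dropped=n_dropped)


def parse_variant_id(vid: str) -> VariantKey:
    """Parse a GTEx-style ``chrom_pos_ref_alt_build`` variant identifier."""
    parts = str(vid).split("_")
    if len(parts) < 4:
        raise InputError(f"unparseable variant identifier {vid!r}")
    chrom, pos, ref, alt = parts[0], parts[1], parts[2], parts[3]
    return VariantKey(chrom.removeprefix("chr"), int(pos), ref.upper(), alt.upper())


def parse_eqtl_associations(stream, tissue: str, n: int,
                            column_map: Mapping[str, str] | None = None,
                            gene_names: Mapping[str, str] | None = None,
                            ) -> list[tuple[EqtlDescriptor, AssocTable]]:
    """Parse a GTEx-v7-like all-associations table into per-gene tables.

    Returns one ``(EqtlDescriptor, AssocTable)`` pair per gene present.
    The MAF column is stored as ``eaf`` verbatim -- no silent folding onto the
    effect allele is attempted (a value > 0.5 simply means the effect allele
    is the major one at that site). Genes with fewer than 2 variants are
    retained but flagged with a warning.
    """
    column_map = dict(column_map or GTEX_COLUMN_MAP)
    raw = pd.read_csv(stream, sep="\t", low_memory=False).rename(columns=column_map)
    missing = [c for c in ("gene_id", "variant_id", "p", "beta", "se")
               if c not in raw.columns]
    if missing:
        raise ConfigError(
            f"column map does not resolve mandatory column(s): {', '.join(missing)}")
    out: list[tuple[EqtlDescriptor, AssocTable]] = []
    for gene_id, grp in raw.groupby("gene_id", sort=True):
        keys, keep_idx = [], []
        n_bad = 0
        for idx, vid in zip(grp.index, grp["variant_id"]):
            try:
                keys.append(parse_variant_id(vid))
                keep_idx.append(idx)
            except (InputError, ValueError):
                n_bad += 1
        if n_bad:
            logger.warning("%s (%s): dropped %d unparseable variant ids",
                           gene_id, tissue, n_bad)
        grp = grp.loc[keep_idx]
        df = pd.DataFrame({
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "beta": grp["beta"].to_numpy(float),
            "se": grp["se"].to_numpy(float),
            "p": grp["p"].to_numpy(float),
            "eaf": grp["eaf"].to_numpy(float) if "eaf" in grp.columns else np.nan,
        })
        df, n_dropped = _numeric_filter(df)
        desc = EqtlDescriptor(
            gene_id=str(gene_id),
            gene_name=(gene_names or {}).get(str(gene_id), str(gene_id)),
            tissue=tissue, n=n)
        if len(df) < 2:
            logger.warning("%s (%s): fewer than 2 valid variants", gene_id, tissue)
        out.append((desc, AssocTable(desc, df, n_dropped=n_dropped + n_bad)))
    return out


@dataclass
class HarmonizedPair:
    """Variant-aligned pair of association tables.

    ``df`` carries one row per shared variant (order follows table *a*) with
    suffixed statistics columns; ``n_flipped`` counts variants whose alleles
    in *b* were swapped relative to *a* (beta sign flipped, eaf complemented)
    and ``n_dropped`` counts shared positions whose allele sets matched
    neither orientation (including swap-ambiguous A/T and C/G pairs).
    """

    meta_a: object
    meta_b: object
    df: pd.DataFrame
    n_flipped: int = 0
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in self.df.itertuples()
        ]


def harmonize_pair(a: AssocTable, b: AssocTable) -> HarmonizedPair:
    """Align two association tables on shared variants and effect alleles.

    Variants are matched on (chrom, pos). If b's ref/alt equal a's, the record
    is taken as-is; if they are swapped, b's beta sign is flipped and its eaf
    complemented; anything else is dropped and counted. Strand-ambiguous
    (A/T, C/G) pairs are kept only on an exact ref/alt match, since a swap
    cannot be distinguished from a strand flip. Output row order follows *a*.
    """
    m = a.df.merge(b.df, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner")
    if len(m) == 0:
        raise NoOverlapError(
            f"no shared variants between {_label(a.meta)} and {_label(b.meta)}")
    same = (m["ref_a"] == m["ref_b"]) & (m["alt_a"] == m["alt_b"])
    swapped = (m["ref_a"] == m["alt_b"]) & (m["alt_a"] == m["ref_b"])
    ambiguous = m["ref_a"].map(_COMPLEMENT) == m["alt_a"]
    keep = same | (swapped & ~ambiguous)
    n_dropped = int((~keep).sum())
    m = m[keep].copy()
    if len(m) == 0:
        raise NoOverlapError(
            f"no allele-consistent shared variants between "
            f"{_label(a.meta)} and {_label(b.meta)}")
    flip = (swapped & ~ambiguous)[keep]
    n_flipped = int(flip.sum())
    m.loc[flip, "beta_b"] = -m.loc[flip, "beta_b"]
    m.loc[flip, "eaf_b"] = 1.0 - m.loc[flip, "eaf_b"]
    m = m.rename(columns={"ref_a": "ref", "alt_a": "alt"}).drop(
        columns=["ref_b", "alt_b"])
    m["_ck"] = m["chrom"].map(CHROM_ORDER)
    m = (m.sort_values(["_ck", "pos", "ref", "alt"], kind="mergesort")
          .drop(columns="_ck").reset_index(drop=True))
    if n_dropped:
        logger.debug("harmonize %s vs %s: dropped %d allele-inconsistent variants",
                     _label(a.meta), _label(b.meta), n_dropped)
    return HarmonizedPair(a.meta, b.meta, m, n_flipped=n_flipped, n_dropped=n_dropped)


def _label(meta) -> str:
    return getattr(meta, "study_id", None) or getattr(meta, "signal_id", str(meta))


def write_assoc_table(table: AssocTable, path, params: Mapping | None = None) -> None:
    """Write an AssocTable as TSV with a commented provenance header line."""
    from . import __version__
    with open(path, "w") as fh:
        extras = " ".join(f"{k}={v}" for k, v in (params or {}).items())
        fh.write(f"# covcoloc v{__version__} study={_label(table.meta)} {extras}\n".rstrip() + "\n")
        table.df.to_csv(fh, sep="\t", index=False)


def read_assoc_table(path, meta) -> AssocTable:
    """Read a TSV written by :func:`write_assoc_table` (or any internal-dialect TSV)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if len(df) == 0:
        raise InputError(f"{path}: empty table")
    return AssocTable(meta, df)


def default_study_panel(n_large: int = 100_000, case_fraction_large: float = 0.05,
                        n_b1: int = 20_000, case_fraction_b1: float = 0.30,
                        ) -> list[StudyMeta]:
    """The 16-study HGI-like panel: 4 phenotypes x 2 ancestries x 2 control sets.

    A2/B2/C2 studies use population controls (large n, small case fraction);
    B1 compares hospitalized to non-hospitalized patients (much smaller n).
    """
    panel = []
    for ph in PHENOTYPES:
        n = n_b1 if ph == "B1" else n_large
        cf = case_fraction_b1 if ph == "B1" else case_fraction_large
        for anc in ANCESTRIES:
            for ctl in CONTROL_SETS:
                panel.append(StudyMeta(
                    study_id=f"{ph}_{anc}_{ctl}", phenotype=ph, ancestry=anc,
                    controls=ctl, trait_type="case_control",
                    n_total=n, n_cases=int(round(n * cf))))
    return panel


def load_study_panel(path) -> list[StudyMeta]:
    """Load a study panel from a YAML/JSON file with a ``studies`` list."""
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["studies"] if isinstance(doc, dict) else doc
    return [StudyMeta(**e) for e in entries]
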