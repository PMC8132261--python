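"""Locus taxonomy from pairwise colocalization matrices across a study panel.

The taxonomy distinguishes, per locus:

* susceptibility -- two or more C2 (patients vs population) studies
  colocalize with each other (PP-H4 > 0.9); this overrides severity even
  when A2/B2 studies also colocalize, since their population controls
  capture susceptibility as well;
* severity -- no C2 pair colocalizes but a within-phenotype pair in A2, B1
  or B2 does;
* ethnicity-specific -- within one phenotype, colocalization holds within an
  ancestry (or only one ancestry reaches significance) while every
  cross-ancestry pair fails to colocalize;
* two signals -- some pair colocalizes while another pair of
  locus-significant studies shows high PP-H3, indicating two independent
  causal variants.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .coloc import (ColocResult, Priors, coloc_abf, coloc_pair,
                    labf_for_table as coloc_labf_for_table)
from .errors import InputError, NoOverlapError
from .loci import GENOME_WIDE_P, Locus
from .sumstats import AssocTable, StudyMeta, harmonize_pair

logger = logging.getLogger(__name__)

SEVERITY_PHENOTYPES = ("A2", "B1", "B2")
SUSCEPTIBILITY_PHENOTYPE = "C2"


@dataclass
class PPMatrix:
    """Study-by-study PP-H4 / PP-H3 matrices for one locus.

    Matrices are symmetric with NaN on the diagonal and for pairs that could
    not be colocalized (no shared variants). ``sig`` flags studies with a
    variant at p < 1e-7 (strict) inside the locus.
    """

    locus: Locus | None
    studies: list[StudyMeta]
    pph4: np.ndarray
    pph3: np.ndarray
    sig: np.ndarray
    results: dict[tuple[int, int], ColocResult] = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.studies)
        for m in (self.pph4, self.pph3):
            if m.shape != (k, k):
                raise InputError("matrix shape does not match study count")
        with np.errstate(invalid="ignore"):
            for m in (self.pph4, self.pph3):
                if np.nanmax(np.abs(m - m.T), initial=0.0) > 1e-12:
                    raise InputError("PP matrices must be symmetric")

    def pairs(self):
        """Yield (i, j, meta_i, meta_j) over the upper triangle."""
        for i, j in itertools.combinations(range(len(self.studies)), 2):
            yield i, j, self.studies[i], self.studies[j]


@dataclass
class LocusAnnotation:
    """Taxonomy flags for one locus, with supporting pair evidence.

    Flags are True/False, or None when the panel lacks the studies the rule
    needs (degraded mode). ``evidence`` lists
    (study_a, study_b, quantity, value) tuples justifying each raised flag.
    """

    susceptibility: bool | None = False
    severity: bool | None = False
    ethnicity_specific: bool | None = False
    two_signals: bool | None = False
    evidence: list[tuple[str, str, str, float]] = field(default_factory=list)

    @property
    def category(self) -> str:
        """Reporting vocabulary: 'Susceptibility', 'Severity',
        'Two GWAS signals', 'Ethnicity-specific signal', '; '-combined."""
        parts = []
        if self.susceptibility:
            parts.append("Susceptibility")
        elif self.severity:
            parts.append("Severity")
        if self.two_signals:
            parts.append("Two GWAS signals")
        if self.ethnicity_specific:
            parts.append("Ethnicity-specific signal")
        return "; ".join(parts) if parts else "Unassigned"


def pairwise_pp_matrix(locus: Locus | None, tables: Sequence[AssocTable],
                       priors: Priors = Priors(), mode: str = "auto",
                       p_threshold: float = GENOME_WIDE_P) -> PPMatrix:
    """Colocalize every unordered study pair on a locus-restricted panel.

    Tables are restricted to the locus interval (when a locus is given),
    harmonized pairwise and colocalized. Pairs without shared variants are
    recorded as NaN and logged.
    """
    studies = [t.meta for t in tables]
    if locus is not None:
        tables = [t.restrict(locus.chrom, locus.start, locus.end) for t in tables]
    k = len(tables)
    pph4 = np.full((k, k), np.nan)
    pph3 = np.full((k, k), np.nan)
    sig = np.array([len(t) > 0 and t.min_p() < p_threshold for t in tables])
    results: dict[tuple[int, int], ColocResult] = {}
    aligned_labf = _aligned_labfs(tables, mode)
    for i, j in itertools.combinations(range(k), 2):
        try:
            if aligned_labf is not None:
                labfs, variants = aligned_labf
                res = coloc_abf(labfs[i], labfs[j], priors, variants=variants)
            else:
                pair = harmonize_pair(tables[i], tables[j])
                res = coloc_pair(pair, priors=priors, mode=mode)
        except NoOverlapError:
            logger.warning("locus %s: pair %s / %s has no usable overlap",
                           locus.label if locus else "-",
                           studies[i].study_id, studies[j].study_id)
            continue
        results[(i, j)] = res
        pph4[i, j] = pph4[j, i] = res["H4"]
        pph3[i, j] = pph3[j, i] = res["H3"]
    return PPMatrix(locus, list(studies), pph4, pph3, sig, results)


def _aligned_labfs(tables, mode):
    """Fast path: when every table carries the identical variant grid no
    pairwise harmonization is needed, and each study's lABF vector can be
    computed once instead of once per pair. Returns None when tables differ."""
    if not tables or any(len(t) != len(tables[0]) or len(t) < 2 for t in tables):
        return None
    ref = tables[0].df
    key_cols = ["chrom", "pos", "ref", "alt"]
    ref_keys = [ref[c].to_numpy() for c in key_cols]
    for t in tables[1:]:
        for c, rk in zip(key_cols, ref_keys):
            if not np.array_equal(t.df[c].to_numpy(), rk):
                return None
    try:
        labfs = [coloc_labf_for_table(t, mode) for t in tables]
    except InputError:
        return None
    return labfs, tables[0].variants


def _gt(value: float, threshold: float) -> bool:
    return bool(np.isfinite(value) and value > threshold)


def classify_locus(m: PPMatrix, h4_threshold: float = 0.9,
                   h3_threshold: float = 0.5,
                   cross_ancestry_low: float = 0.5) -> LocusAnnotation:
    """Apply the four-way taxonomy to one locus's pairwise matrices."""
    ann = LocusAnnotation()
    phenos = {s.phenotype for s in m.studies}
    by_pheno: dict[str, list[int]] = {}
    for idx, s in enumerate(m.studies):
        by_pheno.setdefault(s.phenotype, []).append(idx)

    if not np.isfinite(m.pph4).any():
        logger.warning("locus %s: all pairwise results missing; no flags assigned",
                       m.locus.label if m.locus else "-")
        return ann

    # susceptibility: any C2-C2 pair colocalizes (strict > threshold)
    c2 = by_pheno.get(SUSCEPTIBILITY_PHENOTYPE, [])
    if len(c2) < 2:
        ann.susceptibility = None
    else:
        for i, j in itertools.combinations(c2, 2):
            if _gt(m.pph4[i, j], h4_threshold):
                ann.susceptibility = True
                ann.evidence.append((m.studies[i].study_id, m.studies[j].study_id,
                                     "PP-H4", float(m.pph4[i, j])))

    # severity: some within-phenotype A2/B1/B2 pair colocalizes, and no C2 pair does
    sev_evaluable = any(len(by_pheno.get(ph, [])) >= 2 for ph in SEVERITY_PHENOTYPES)
    if not sev_evaluable or ann.susceptibility is None:
        # severity needs both a severity phenotype pair and a decidable C2 rule
        ann.severity = None
    elif ann.susceptibility:
        ann.severity = False
    else:
        for ph in SEVERITY_PHENOTYPES:
            for i, j in itertools.combinations(by_pheno.get(ph, []), 2):
                if _gt(m.pph4[i, j], h4_threshold):
                    ann.severity = True
                    ann.evidence.append((m.studies[i].study_id,
                                         m.studies[j].study_id,
                                         "PP-H4", float(m.pph4[i, j])))

    # two signals: some pair colocalizes while a pair of locus-significant
    # studies supports two distinct causal variants
    any_h4 = False
    for i, j, si, sj in m.pairs():
        if _gt(m.pph4[i, j], h4_threshold):
            any_h4 = True
            break
    if any_h4:
        for i, j, si, sj in m.pairs():
            if m.sig[i] and m.sig[j] and _gt(m.pph3[i, j], h3_threshold):
                ann.two_signals = True
                ann.evidence.append((si.study_id, sj.study_id,
                                     "PP-H3", float(m.pph3[i, j])))

    # ethnicity-specific: within one phenotype, within-ancestry colocalization
    # (or single-ancestry-only significance) with no cross-ancestry colocalization
    ancestries = {s.ancestry for s in m.studies}
    if len(ancestries) < 2:
        ann.ethnicity_specific = None
    else:
        for ph, idxs in by_pheno.items():
            sig_idxs = [i for i in idxs if m.sig[i]]
            if not sig_idxs:
                continue
            within_pairs = [(i, j) for i, j in itertools.combinations(idxs, 2)
                            if m.studies[i].ancestry == m.studies[j].ancestry]
            cross_pairs = [(i, j) for i, j in itertools.combinations(idxs, 2)
                           if m.studies[i].ancestry != m.studies[j].ancestry]
            if not cross_pairs:
                continue
            within_hit = [(i, j) for i, j in within_pairs
                          if _gt(m.pph4[i, j], h4_threshold)]
            single_ancestry_sig = len({m.studies[i].ancestry for i in sig_idxs}) == 1
            # a missing cross-ancestry result counts as failure to colocalize
            cross_all_low = all(
                (not np.isfinite(m.pph4[i, j])) or m.pph4[i, j] < cross_ancestry_low
                for i, j in cross_pairs)
            if (within_hit or single_ancestry_sig) and cross_all_low:
                ann.ethnicity_specific = True
                for i, j in within_hit:
                    ann.evidence.append((m.studies[i].study_id,
                                         m.studies[j].study_id,
                                         "PP-H4", float(m.pph4[i, j])))
    return ann


def classify_from_phenotype_maxima(max_pph4: Mapping[str, float],
                                   threshold: float = 0.9) -> str:
    """Reduced classifier from per-phenotype maxima of within-phenotype PP-H4.

    Susceptibility iff max PP-H4 among C2 pairs exceeds the threshold;
    otherwise severity iff the maximum over A2/B1/B2 does; else unassigned.
    """
    missing = [ph for ph in ("A2", "B1", "B2", "C2") if ph not in max_pph4]
    if missing:
        raise InputError(f"missing phenotype maxima: {missing}")
    if max_pph4["C2"] > threshold:
        return "susceptibility"
    if max(max_pph4[ph] for ph in SEVERITY_PHENOTYPES) > threshold:
        return "severity"
    return "unassigned"


def phenotype_maxima(m: PPMatrix) -> dict[str, float]:
    """Max within-phenotype pairwise PP-H4 per phenotype (NaN-ignoring)."""
    out: dict[str, float] = {}
    for ph in ("A2", "B1", "B2", "C2"):
        idxs = [i for i, s in enumerate(m.studies) if s.phenotype == ph]
        vals = [m.pph4[i, j] for i, j in itertools.combinations(idxs, 2)
                if np.isfinite(m.pph4[i, j])]
        out[ph] = max(vals) if vals else float("nan")
    return out


def within_between_phenotype_comparison(matrices: Sequence[PPMatrix]
                                        ) -> tuple[float, float, float]:
    """Compare PP-H4 of same-phenotype vs different-phenotype study pairs.

    Pools pairwise PP-H4 entries across loci into two groups and returns
    (median within-phenotype, median between-phenotype, two-sided
    Mann-Whitney p). Exact enumeration is used when both groups have at
    most 8 entries, else the tie-corrected normal approximation.
    """
    if not matrices:
        raise InputError("need at least one locus matrix")
    within, between = [], []
    for m in matrices:
        for i, j, si, sj in m.pairs():
            v = m.pph4[i, j]
            if not np.isfinite(v):
                continue
            (within if si.phenotype == sj.phenotype else between).append(float(v))
    if not within or not between:
        raise InputError("one comparison group is empty")
    method = "exact" if max(len(within), len(between)) <= 8 else "asymptotic"
    stat = mannwhitneyu(within, between, alternative="two-sided", method=method)
    return float(np.median(within)), float(np.median(between)), float(stat.pvalue)
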