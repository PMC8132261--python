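"""GWAS x eQTL colocalization, eGene calling and locus summary assembly.

eQTL signals are treated as quantitative traits with standardized expression
(sdY = 1), so the effect-size prior SD is 0.15. The eGene decision rule is
non-strict (best PP-H4 >= 0.9), whereas GWAS-pair colocalization uses the
strict > 0.9 rule; both thresholds are exposed.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import LocusAnnotation, PPMatrix, phenotype_maxima
from .coloc import ColocResult, Priors, coloc_pair
from .errors import InputError, NoOverlapError
from .loci import Locus
from .sumstats import AssocTable, EqtlDescriptor, StudyMeta, harmonize_pair

logger = logging.getLogger(__name__)

EGENE_H4 = 0.9         # non-strict (>=) eGene threshold
SUGGESTIVE_H4 = 0.5    # lower bound of the suggestive band

#: GTEx v7 tissue panel (48 tissues with eQTL summary data)
GTEX_V7_TISSUES = (
    "Adipose_Subcutaneous", "Adipose_Visceral_Omentum", "Adrenal_Gland",
    "Artery_Aorta", "Artery_Coronary", "Artery_Tibial", "Brain_Amygdala",
    "Brain_Anterior_cingulate_cortex_BA24", "Brain_Caudate_basal_ganglia",
    "Brain_Cerebellar_Hemisphere", "Brain_Cerebellum", "Brain_Cortex",
    "Brain_Frontal_Cortex_BA9", "Brain_Hippocampus", "Brain_Hypothalamus",
    "Brain_Nucleus_accumbens_basal_ganglia", "Brain_Putamen_basal_ganglia",
    "Brain_Spinal_cord_cervical_c-1", "Brain_Substantia_nigra",
    "Breast_Mammary_Tissue", "Cells_EBV-transformed_lymphocytes",
    "Cells_Transformed_fibroblasts", "Colon_Sigmoid", "Colon_Transverse",
    "Esophagus_Gastroesophageal_Junction", "Esophagus_Mucosa",
    "Esophagus_Muscularis", "Heart_Atrial_Appendage", "Heart_Left_Ventricle",
    "Liver", "Lung", "Minor_Salivary_Gland", "Muscle_Skeletal",
    "Nerve_Tibial", "Ovary", "Pancreas", "Pituitary", "Prostate",
    "Skin_Not_Sun_Exposed_Suprapubic", "Skin_Sun_Exposed_Lower_leg",
    "Small_Intestine_Terminal_Ileum", "Spleen", "Stomach", "Testis",
    "Thyroid", "Uterus", "Vagina", "Whole_Blood",
)


@dataclass
class GeneTissueColocCell:
    """One (gene-tissue eQTL, GWAS study) colocalization result at a locus."""

    locus: Locus
    gene: EqtlDescriptor
    study_id: str
    phenotype: str
    result: ColocResult


@dataclass
class EgeneCall:
    """Per gene x phenotype colocalization call.

    tier 'colocalized' means best PP-H4 >= 0.9 over tissues and the
    phenotype's studies; 'suggestive' means 0.5 <= best PP-H4 < 0.9.
    ``tissues`` lists the tissues reaching the calling tier.
    """

    gene: EqtlDescriptor
    phenotype: str
    tier: str
    best_pph4: float
    tissues: list[str] = field(default_factory=list)


def coloc_locus_eqtls(locus: Locus, gwas: Sequence[AssocTable],
                      eqtls: Sequence[tuple[EqtlDescriptor, AssocTable]],
                      priors: Priors = Priors(), mode: str = "auto",
                      ) -> list[GeneTissueColocCell]:
    """Colocalize every gene-tissue eQTL signal against every GWAS at a locus.

    Pairs with fewer than 2 shared variants are skipped and logged. The eQTL
    side is harmonized as table *b*, so its effect prior follows its
    quantitative descriptor (prior SD 0.15 * sdY).
    """
    gwas_restricted = [t.restrict(locus.chrom, locus.start, locus.end) for t in gwas]
    cells: list[GeneTissueColocCell] = []
    for desc, etab in eqtls:
        etab_r = etab.restrict(locus.chrom, locus.start, locus.end)
        for gtab in gwas_restricted:
            sid = gtab.meta.study_id
            try:
                pair = harmonize_pair(gtab, etab_r)
                res = coloc_pair(pair, priors=priors, mode=mode)
            except NoOverlapError:
                logger.warning("locus %s: %s vs %s lacks usable overlap",
                               locus.label, sid, desc.signal_id)
                continue
            cells.append(GeneTissueColocCell(
                locus=locus, gene=desc, study_id=sid,
                phenotype=gtab.meta.phenotype, result=res))
    return cells


def call_egenes(cells: Sequence[GeneTissueColocCell],
                egene_threshold: float = EGENE_H4,
                suggestive_threshold: float = SUGGESTIVE_H4) -> list[EgeneCall]:
    """Reduce gene-tissue-study cells to per gene x phenotype eGene calls.

    For each gene and phenotype, best_pph4 is the maximum PP-H4 over tissues
    and the phenotype's studies. Tier assignment is >= for the eGene
    threshold and half-open [suggestive, egene) for the suggestive band.
    Invariant to tissue ordering.
    """
    grouped: dict[tuple[str, str], list[GeneTissueColocCell]] = {}
    for c in cells:
        grouped.setdefault((c.gene.gene_id, c.phenotype), []).append(c)
    calls = []
    for (gene_id, pheno), grp in sorted(grouped.items()):
        best = max(c.result["H4"] for c in grp)
        if best >= egene_threshold:
            tier, cut = "colocalized", egene_threshold
        elif best >= suggestive_threshold:
            tier, cut = "suggestive", suggestive_threshold
        else:
            tier, cut = "none", None
        tissues = sorted({c.gene.tissue for c in grp
                          if cut is not None and c.result["H4"] >= cut})
        calls.append(EgeneCall(gene=grp[0].gene, phenotype=pheno, tier=tier,
                               best_pph4=float(best), tissues=tissues))
    return calls


def eqtl_eqtl_coloc(signals: Sequence[tuple[EqtlDescriptor, AssocTable]],
                    priors: Priors = Priors(), mode: str = "auto",
                    ) -> pd.DataFrame:
    """Pairwise colocalization among gene-tissue eQTL signals at one locus.

    High-PP-H4 blocks indicate a single regulatory variant shared across
    genes/tissues; high PP-H3 between signals indicates distinct eQTLs.
    Returns a long-format frame (signal_a, signal_b, pph3, pph4, nsnps).
    """
    if len(signals) < 2:
        raise InputError("need at least 2 gene-tissue signals")
    rows = []
    for (da, ta), (db, tb) in itertools.combinations(signals, 2):
        try:
            pair = harmonize_pair(ta, tb)
            res = coloc_pair(pair, priors=priors, mode=mode)
        except NoOverlapError:
            rows.append({"signal_a": da.signal_id, "signal_b": db.signal_id,
                         "pph3": np.nan, "pph4": np.nan, "nsnps": 0})
            continue
        rows.append({"signal_a": da.signal_id, "signal_b": db.signal_id,
                     "pph3": res["H3"], "pph4": res["H4"], "nsnps": res.nsnps})
    return pd.DataFrame(rows)


def build_locus_summary(locus: Locus, ppm: PPMatrix,
                        annotation: LocusAnnotation,
                        egene_calls: Sequence[EgeneCall],
                        gwas: Sequence[AssocTable],
                        eqtl_cells: Sequence[GeneTissueColocCell] = (),
                        ) -> pd.DataFrame:
    """Assemble the per-locus wide summary: one row per phenotype.

    Columns: locus, category, phenotype, min GWAS p within the locus across
    the phenotype's studies, max within-phenotype pairwise PP-H4, max
    GWAS x eQTL PP-H4 for the phenotype, and semicolon-joined colocalized
    eGene names.
    """
    maxima = phenotype_maxima(ppm)
    eqtl_best: dict[str, float] = {}
    for c in eqtl_cells:
        v = c.result["H4"]
        if not (c.phenotype in eqtl_best and eqtl_best[c.phenotype] >= v):
            eqtl_best[c.phenotype] = float(v)
    egene_by_pheno: dict[str, list[str]] = {}
    for call in egene_calls:
        if call.tier == "colocalized":
            egene_by_pheno.setdefault(call.phenotype, []).append(
                call.gene.gene_name or call.gene.gene_id)
    rows = []
    for ph in ("A2", "B1", "B2", "C2"):
        tabs = [t for t in gwas if t.meta.phenotype == ph]
        pvals = [t.restrict(locus.chrom, locus.start, locus.end).min_p()
                 for t in tabs]
        pvals = [p for p in pvals if np.isfinite(p)]
        rows.append({
            "locus": locus.label,
            "category": annotation.category,
            "phenotype": ph,
            "min_p_gwas": min(pvals) if pvals else np.nan,
            "max_pph4_gwas": maxima.get(ph, np.nan),
            "max_pph4_eqtl": eqtl_best.get(ph, np.nan),
            "egenes": "; ".join(sorted(set(egene_by_pheno.get(ph, [])))),
        })
    return pd.DataFrame(rows)


def cells_long_table(cells: Sequence[GeneTissueColocCell]) -> pd.DataFrame:
    """Long-format gene-tissue-study colocalization table (S3-style layout)."""
    rows = []
    for c in cells:
        rows.append({
            "locus": c.locus.label,
            "gene_id": c.gene.gene_id,
            "gene_name": c.gene.gene_name,
            "tissue": c.gene.tissue,
            "study": c.study_id,
            "lead_snp": str(c.result.lead_variant) if c.result.lead_variant else "",
            "nsnps": c.result.nsnps,
            **c.result.as_dict(),
            "lead_snp_pp_h4": c.result.lead_pp,
        })
    return pd.DataFrame(rows)
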