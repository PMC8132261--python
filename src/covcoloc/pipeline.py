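"""End-to-end orchestration: loci -> pairwise GWAS colocalization ->
taxonomy -> eQTL colocalization -> locus summaries, plus the published-table
replay path.

Artifacts are plain TSVs written atomically (temp file + rename) together
with a JSON manifest recording package version, parameters and input
checksums, so a rerun on identical inputs is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (classify_from_phenotype_maxima, classify_locus,
                       pairwise_pp_matrix, phenotype_maxima,
                       within_between_phenotype_comparison)
from .coloc import Priors
from .eqtl import (build_locus_summary, call_egenes, cells_long_table,
                   coloc_locus_eqtls)
from .errors import ConfigError, InputError
from .loci import (GENOME_WIDE_P, DEFAULT_FLANK, find_loci, loci_to_bed,
                   locus_summary_table)
from .sumstats import (HGI_COLUMN_MAP, AssocTable, parse_eqtl_associations,
                       parse_gwas_sumstats, load_study_panel)

logger = logging.getLogger(__name__)

EGENE_THRESHOLD_DEFAULT = 0.9


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    panel_path: str
    gwas_dir: str
    out_dir: str
    eqtl_paths: dict[str, str] = field(default_factory=dict)  # tissue -> path
    gene_annotation_path: str | None = None
    p_threshold: float = GENOME_WIDE_P
    flank: int = DEFAULT_FLANK
    h4_strict: float = 0.9
    h4_egene: float = EGENE_THRESHOLD_DEFAULT
    h3_high: float = 0.5
    cross_ancestry_low: float = 0.5
    priors: Priors = field(default_factory=Priors)
    evidence_mode: str = "auto"
    eqtl_n: int = 300
    seed: int = 0

    def __post_init__(self):
        for name in ("p_threshold", "h4_strict", "h4_egene", "h3_high",
                     "cross_ancestry_low"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0,1), got {v}")
        if self.flank < 0:
            raise ConfigError("flank must be >= 0")
        if self.evidence_mode not in ("auto", "beta", "pvalue"):
            raise ConfigError(f"unknown evidence mode {self.evidence_mode!r}")


def _atomic_write(df: pd.DataFrame, path: Path, header_comment: str | None = None
                  ) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_gwas_panel(config: RunConfig) -> list[AssocTable]:
    """Read the 16 (or fewer) study tables named ``<study_id>.tsv``."""
    panel = load_study_panel(config.panel_path)
    tables = []
    for meta in panel:
        path = Path(config.gwas_dir) / f"{meta.study_id}.tsv"
        if not path.exists():
            raise InputError(f"missing summary-statistics file {path}")
        tables.append(parse_gwas_sumstats(path, meta, HGI_COLUMN_MAP))
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write artifacts under ``config.out_dir``.

    Returns a result dictionary with the loci, annotations, matrices and
    summary frame. Degrades gracefully on partial panels: taxonomy flags
    whose phenotypes are absent are reported as ``NA`` rather than false.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = load_gwas_panel(config)
    if len(tables) < 2:
        raise InputError("pipeline needs at least 2 studies")
    version_line = f"covcoloc v{__version__}"

    loci = find_loci(tables, p_threshold=config.p_threshold, flank=config.flank)
    _atomic_write(loci_to_bed(loci), out / "loci.bed")
    _atomic_write(locus_summary_table(loci, tables), out / "loci_min_p.tsv",
                  version_line)
    if not loci:
        logger.info("no genome-wide-significant locus found; downstream "
                    "artifacts are empty")
        for name in ("pairwise_pp.tsv", "annotations.tsv", "locus_summary.tsv"):
            _atomic_write(pd.DataFrame(), out / name, version_line)
        _write_manifest(config, out, [])
        return {"loci": [], "annotations": {}, "matrices": {},
                "summary": pd.DataFrame()}

    gene_names: dict[str, str] = {}
    if config.gene_annotation_path:
        genes = pd.read_csv(config.gene_annotation_path, sep="\t",
                            dtype={"chrom": str})
        if "gene_name" in genes.columns:
            gene_names = dict(zip(genes["gene_id"].astype(str),
                                  genes["gene_name"].astype(str)))
    eqtl_signals = []
    for tissue, path in sorted(config.eqtl_paths.items()):
        eqtl_signals.extend(parse_eqtl_associations(
            path, tissue, config.eqtl_n, gene_names=gene_names))

    matrices, annotations, pair_rows, summaries, egene_rows = {}, {}, [], [], []
    all_cells = []
    for locus in loci:
        m = pairwise_pp_matrix(locus, tables, priors=config.priors,
                               mode=config.evidence_mode,
                               p_threshold=config.p_threshold)
        ann = classify_locus(m, h4_threshold=config.h4_strict,
                             h3_threshold=config.h3_high,
                             cross_ancestry_low=config.cross_ancestry_low)
        matrices[locus.label] = m
        annotations[locus.label] = ann
        for i, j, si, sj in m.pairs():
            pair_rows.append({
                "locus": locus.label, "study_a": si.study_id,
                "study_b": sj.study_id, "pph3": m.pph3[i, j],
                "pph4": m.pph4[i, j]})
        cells = coloc_locus_eqtls(locus, tables, eqtl_signals,
                                  priors=config.priors,
                                  mode=config.evidence_mode) if eqtl_signals else []
        all_cells.extend(cells)
        calls = call_egenes(cells, egene_threshold=config.h4_egene) if cells else []
        for call in calls:
            egene_rows.append({
                "locus": locus.label, "gene_id": call.gene.gene_id,
                "gene_name": call.gene.gene_name, "phenotype": call.phenotype,
                "tier": call.tier, "best_pph4": call.best_pph4,
                "tissues": ";".join(call.tissues)})
        summaries.append(build_locus_summary(locus, m, ann, calls, tables,
                                             eqtl_cells=cells))

    ann_rows = []
    for locus in loci:
        a = annotations[locus.label]
        ann_rows.append({
            "locus": locus.label,
            "susceptibility": _flag(a.susceptibility),
            "severity": _flag(a.severity),
            "ethnicity_specific": _flag(a.ethnicity_specific),
            "two_signals": _flag(a.two_signals),
            "category": a.category,
            "evidence": "; ".join(f"{x}|{y}|{q}={v:.3f}"
                                  for x, y, q, v in a.evidence)})
    _atomic_write(pd.DataFrame(pair_rows), out / "pairwise_pp.tsv", version_line)
    _atomic_write(pd.DataFrame(ann_rows), out / "annotations.tsv", version_line)
    summary = (pd.concat(summaries, ignore_index=True)
               if summaries else pd.DataFrame())
    _atomic_write(summary, out / "locus_summary.tsv", version_line)
    _atomic_write(pd.DataFrame(egene_rows), out / "egene_calls.tsv", version_line)
    if all_cells:
        _atomic_write(cells_long_table(all_cells), out / "eqtl_coloc.tsv",
                      version_line)
    try:
        med_w, med_b, p = within_between_phenotype_comparison(list(matrices.values()))
        comparison = {"median_within": med_w, "median_between": med_b, "p": p}
    except InputError:
        comparison = None
    _write_manifest(config, out, loci)
    return {"loci": loci, "annotations": annotations, "matrices": matrices,
            "summary": summary, "within_between": comparison}


def _flag(v) -> str:
    return "NA" if v is None else str(bool(v))


def _write_manifest(config: RunConfig, out: Path, loci) -> None:
    cfg = dataclasses.asdict(config)
    cfg["priors"] = dataclasses.asdict(config.priors)
    inputs = {}
    for p in [config.panel_path, config.gene_annotation_path,
              *config.eqtl_paths.values()]:
        if p and Path(p).exists():
            inputs[str(p)] = _sha256(Path(p))
    gdir = Path(config.gwas_dir)
    if gdir.is_dir():
        for f in sorted(gdir.glob("*.tsv")):
            inputs[str(f)] = _sha256(f)
    manifest = {"version": __version__, "config": cfg,
                "inputs_sha256": inputs,
                "n_loci": len(loci), "loci": [l.label for l in loci]}
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, out / "manifest.json")


# ---------------------------------------------------------------------------
# published-table replay

def packaged_table1_path():
    """Path to the packaged transcription of the published locus table."""
    return resources.files("covcoloc.data") / "table1.tsv"


def load_table1(path=None) -> pd.DataFrame:
    """Load the per-locus per-phenotype table (locus, category, phenotype,
    p_gwas, pph4_gwas, pph4_eqtl, egenes)."""
    src = path if path is not None else packaged_table1_path()
    df = pd.read_csv(src, sep="\t", dtype={"locus": str})
    required = {"locus", "phenotype", "pph4_gwas", "pph4_eqtl"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"table is missing columns: {sorted(missing)}")
    if "egenes" not in df.columns:
        df["egenes"] = ""
    df["egenes"] = df["egenes"].fillna("")
    return df


def replay_table1(path=None, threshold: float = 0.9,
                  egene_threshold: float = EGENE_THRESHOLD_DEFAULT) -> dict:
    """Reduce the published per-locus maxima through the phenotype-level
    classifier and recount the headline quantities.

    Returns per-locus reduced categories plus counts: severity loci,
    susceptibility loci, loci with an eQTL colocalization
    (max PP-H4 >= 0.9 over phenotypes), and distinct eGene names.
    """
    df = load_table1(path)
    per_locus = []
    for locus, grp in df.groupby("locus", sort=False):
        maxima = {}
        for r in grp.itertuples():
            ph = str(r.phenotype)
            if ph not in ("A2", "B1", "B2", "C2"):
                raise InputError(f"{locus}: unknown phenotype {ph!r}")
            maxima[ph] = float(r.pph4_gwas)
        if len(maxima) != 4:
            raise InputError(f"{locus}: expected 4 phenotype rows, got "
                             f"{len(maxima)}")
        category = classify_from_phenotype_maxima(maxima, threshold=threshold)
        eqtl_max = float(grp["pph4_eqtl"].max())
        genes = set()
        for cell in grp["egenes"]:
            genes.update(g.strip() for g in str(cell).split(";") if g.strip())
        per_locus.append({"locus": locus, "reduced_category": category,
                          "max_pph4_eqtl": eqtl_max,
                          "eqtl_colocalized": eqtl_max >= egene_threshold,
                          "egenes": sorted(genes)})
    per_locus_df = pd.DataFrame(
        per_locus, columns=["locus", "reduced_category", "max_pph4_eqtl",
                            "eqtl_colocalized", "egenes"])
    all_genes = sorted({g for row in per_locus for g in row["egenes"]})
    counts = {
        "n_loci": len(per_locus),
        "n_severity": int((per_locus_df["reduced_category"] == "severity").sum()),
        "n_susceptibility": int(
            (per_locus_df["reduced_category"] == "susceptibility").sum()),
        "n_unassigned": int(
            (per_locus_df["reduced_category"] == "unassigned").sum()),
        "n_eqtl_colocalized_loci": int(per_locus_df["eqtl_colocalized"].sum()),
        "n_distinct_egenes": len(all_genes),
    }
    return {"per_locus": per_locus_df, "counts": counts,
            "distinct_egenes": all_genes}
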