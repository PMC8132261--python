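"""Synthetic multi-study GWAS and multi-tissue eQTL summary statistics.

Simulation operates at the z-score level: for a locus of Q variants with
target LD correlation matrix R and per-variant noncentrality vector lambda
(the expected z at each causal variant, zero elsewhere), the marginal
z-vector of one study is drawn as

    z ~ MVN(R @ lambda, R)

which is the standard asymptotic distribution of marginal association
z-scores under a joint causal model. Standard errors follow the allele
frequency / sample-size approximation used by the colocalization engine, so
beta = z * se and p = 2 * Phi(-|z|) complete the summary-statistics table.
Haplotypes (for LD reporting) are generated separately by a per-block
two-state Markov chain whose lag-k allele correlation is exactly rho^k.

Scenario builders encode the study conditions of the benchmark suite:
noncentrality 8 at causal variants, 500 variants per locus in AR(0.95)
blocks of 50, 16 studies with n >= 10,000, and an ethnicity scenario whose
causal variant has frequency 0.25 in multi-ethnic studies but 0.005 in
European-only studies (so those carry essentially no power at it).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coloc import approx_var_beta
from .errors import ConfigError, InputError
from .ld import LDMatrix
from .sumstats import (AssocTable, EqtlDescriptor, StudyMeta, VariantKey,
                       default_study_panel)

logger = logging.getLogger(__name__)

BENCHMARK_LAMBDA = 8.0
BENCHMARK_Q = 500
BENCHMARK_BLOCK = 50
BENCHMARK_RHO = 0.95

#: ethnicity scenario causal-variant frequencies per ancestry
ETHNICITY_MAF = {"multi": 0.25, "eur": 0.005}


@dataclass(frozen=True)
class LDSpec:
    """Block-diagonal AR(rho) LD structure: within a block of size b,
    target correlation between variants i and j is rho^|i-j|; zero across
    blocks."""

    block_size: int = BENCHMARK_BLOCK
    rho: float = BENCHMARK_RHO

    def __post_init__(self):
        if not (-1 < self.rho < 1):
            raise ConfigError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")


def ar_correlation(q: int, ld_spec: LDSpec) -> np.ndarray:
    """Target correlation matrix: block-diagonal with AR(rho) blocks."""
    if q < 1:
        raise InputError("variant count must be >= 1")
    R = np.zeros((q, q))
    b = ld_spec.block_size
    for s in range(0, q, b):
        e = min(s + b, q)
        idx = np.arange(e - s)
        R[s:e, s:e] = ld_spec.rho ** np.abs(idx[:, None] - idx[None, :])
    return R


def _variant_grid(q: int, chrom: str, start: int, spacing: int) -> list[VariantKey]:
    return [VariantKey(chrom, start + i * spacing, "A", "G") for i in range(q)]


def simulate_haplotypes(q: int, ld_spec: LDSpec, n_haplotypes: int,
                        rng: np.random.Generator,
                        block_freqs: np.ndarray | None = None) -> np.ndarray:
    """Draw a haplotype pool whose allele correlation matches the AR target.

    Within each block, alleles follow a stationary two-state Markov chain
    with marginal frequency f (one frequency per block) and transition
    P(1 -> 1) = f + rho (1 - f), P(0 -> 1) = f (1 - rho): the lag-k Pearson
    correlation of such a chain is exactly rho^k. Blocks are independent.
    Requires rho >= 0 (the chain transition probabilities leave [0, 1]
    otherwise).
    """
    rho = ld_spec.rho
    if rho < 0:
        raise ConfigError("haplotype generation requires rho >= 0")
    b = ld_spec.block_size
    n_blocks = (q + b - 1) // b
    if block_freqs is None:
        block_freqs = rng.uniform(0.2, 0.5, size=n_blocks)
    h = np.empty((n_haplotypes, q), dtype=np.int8)
    for k in range(n_blocks):
        s, e = k * b, min((k + 1) * b, q)
        f = float(block_freqs[k])
        x = (rng.random(n_haplotypes) < f).astype(np.int8)
        h[:, s] = x
        for j in range(s + 1, e):
            p_one = f + rho * (x - f)  # f + rho(1-f) if x=1 else f(1-rho)
            x = (rng.random(n_haplotypes) < p_one).astype(np.int8)
            h[:, j] = x
    return h


def simulate_ld(q: int, ld_spec: LDSpec = LDSpec(), seed: int = 0,
                n_haplotypes: int = 0, chrom: str = "1", start: int = 1_000_000,
                spacing: int = 2000) -> tuple[LDMatrix, np.ndarray]:
    """Target LD matrix for a locus, plus an optional matching haplotype pool."""
    rng = np.random.default_rng(seed)
    variants = _variant_grid(q, chrom, start, spacing)
    R = ar_correlation(q, ld_spec)
    haps = (simulate_haplotypes(q, ld_spec, n_haplotypes, rng)
            if n_haplotypes else np.empty((0, q), dtype=np.int8))
    return LDMatrix(variants, R), haps


def _cholesky(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        logger.warning("LD matrix not positive definite; jittering diagonal by 1e-8")
        return np.linalg.cholesky(R + 1e-8 * np.eye(R.shape[0]))


def simulate_study(ld: LDMatrix | np.ndarray, mafs: np.ndarray,
                   causal: dict[int, float] | None, meta: StudyMeta,
                   seed: int | np.random.Generator = 0,
                   variants: list[VariantKey] | None = None,
                   chol: np.ndarray | None = None) -> AssocTable:
    """Simulate one study's summary statistics at a locus.

    ``causal`` maps variant index -> noncentrality lambda (expected z).
    Under lambda = 0 everywhere the z-values are marginally standard normal.
    """
    if isinstance(ld, LDMatrix):
        R = ld.r
        if variants is None:
            variants = ld.variants
    else:
        R = np.asarray(ld, dtype=float)
    q = R.shape[0]
    if variants is None:
        variants = _variant_grid(q, "1", 1_000_000, 2000)
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (q,):
        raise InputError("maf vector length must match variant count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.zeros(q)
    for idx, l in (causal or {}).items():
        if not (0 <= idx < q):
            raise InputError(f"causal index {idx} outside [0, {q})")
        if not np.isfinite(l):
            raise InputError("noncentrality must be finite")
        lam[idx] = l
    L = chol if chol is not None else _cholesky(R)
    z = R @ lam + L @ rng.standard_normal(q)
    se = np.sqrt(approx_var_beta(
        mafs, meta.n_total, meta.trait_type,
        case_fraction=getattr(meta, "case_fraction", None),
        sdY=getattr(meta, "sdY", 1.0)))
    p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    df = pd.DataFrame({
        "chrom": [v.chrom for v in variants],
        "pos": [v.pos for v in variants],
        "ref": [v.ref for v in variants],
        "alt": [v.alt for v in variants],
        "beta": z * se,
        "se": se,
        "p": p,
        "eaf": mafs,
        "n": float(meta.n_total),
    })
    return AssocTable(meta, df, validate=False)


@dataclass
class SimScenario:
    """Ground-truth recipe for one synthetic locus.

    ``causal_map`` maps study_id -> {variant index: lambda}; studies absent
    from the map are null at this locus. ``maf_overrides`` maps
    study_id -> {variant index: frequency} (used by the ethnicity scenario).
    """

    name: str
    chrom: str = "1"
    start: int = 1_000_000
    spacing: int = 2000
    q: int = BENCHMARK_Q
    ld_spec: LDSpec = field(default_factory=LDSpec)
    causal_map: dict[str, dict[int, float]] = field(default_factory=dict)
    maf_overrides: dict[str, dict[int, float]] = field(default_factory=dict)
    expected_flags: dict[str, bool | None] = field(default_factory=dict)

    @property
    def causal_indices(self) -> set[int]:
        return {i for m in self.causal_map.values() for i in m}

    def variants(self) -> list[VariantKey]:
        return _variant_grid(self.q, self.chrom, self.start, self.spacing)


@dataclass
class SimTruth:
    """Ground truth attached to a simulated locus fixture."""

    scenario: SimScenario
    seed: int
    per_study_causal: dict[str, dict[int, float]]
    expected_flags: dict[str, bool | None]


def build_scenario(name: str, panel: list[StudyMeta] | None = None,
                   lam: float = BENCHMARK_LAMBDA, q: int = BENCHMARK_Q,
                   ld_spec: LDSpec = LDSpec()) -> SimScenario:
    """Construct one of the named benchmark scenarios for a 16-study panel.

    Causal variants sit at block centres: index c1 in the middle block and,
    for the two-signal scenario, c2 in a distant block (cross-block target
    LD is zero, so r^2 < 0.1 between the two causal variants).
    """
    panel = panel if panel is not None else default_study_panel()
    ids = {s.study_id: s for s in panel}
    b = ld_spec.block_size
    n_blocks = max(1, q // b)
    c1 = (n_blocks // 2) * b + b // 2
    c2 = (n_blocks - 1) * b + b // 2
    if c2 == c1:
        c2 = min(q - 1, c1 + 1)
    causal: dict[str, dict[int, float]] = {}
    maf_over: dict[str, dict[int, float]] = {}
    if name == "susceptibility":
        sc = SimScenario(name, chrom="3", start=45_000_000, q=q, ld_spec=ld_spec)
        for sid, s in ids.items():
            if s.phenotype == "C2":
                causal[sid] = {c1: lam}
        flags = {"susceptibility": True, "severity": False,
                 "ethnicity_specific": False, "two_signals": False}
    elif name == "severity":
        sc = SimScenario(name, chrom="2", start=166_000_000, q=q, ld_spec=ld_spec)
        for sid, s in ids.items():
            if s.phenotype == "B2":
                causal[sid] = {c1: lam}
        flags = {"susceptibility": False, "severity": True,
                 "ethnicity_specific": False, "two_signals": False}
    elif name == "ethnicity_specific":
        # the causal variant is near-monomorphic in Europeans, so the
        # European-only studies carry no power at it: the variant remains in
        # their tables (frequency 0.005) but contributes no noncentrality
        sc = SimScenario(name, chrom="6", start=40_900_000, q=q, ld_spec=ld_spec)
        for sid, s in ids.items():
            if s.phenotype == "B2":
                if s.ancestry == "multi":
                    causal[sid] = {c1: lam}
                    maf_over[sid] = {c1: ETHNICITY_MAF["multi"]}
                else:
                    maf_over[sid] = {c1: ETHNICITY_MAF["eur"]}
        flags = {"susceptibility": False, "severity": True,
                 "ethnicity_specific": True, "two_signals": False}
    elif name == "two_signal":
        sc = SimScenario(name, chrom="17", start=43_200_000, q=q, ld_spec=ld_spec)
        for sid, s in ids.items():
            if s.phenotype == "C2":
                causal[sid] = {c1: lam}
            elif s.phenotype == "B1":
                causal[sid] = {c2: lam}
        flags = {"susceptibility": True, "severity": False,
                 "ethnicity_specific": False, "two_signals": True}
    elif name == "phenotype_distinct":
        # every phenotype carries its own causal variant in a separate block:
        # within-phenotype pairs colocalize, between-phenotype pairs do not
        sc = SimScenario(name, chrom="9", start=135_600_000, q=q, ld_spec=ld_spec)
        for k, ph in enumerate(("A2", "B1", "B2", "C2")):
            c_ph = min(2 * k, n_blocks - 1) * b + b // 2
            for sid, s in ids.items():
                if s.phenotype == ph:
                    causal[sid] = {c_ph: lam}
        flags = {"susceptibility": True, "severity": False,
                 "ethnicity_specific": False, "two_signals": True}
    elif name == "null":
        sc = SimScenario(name, chrom="11", start=97_000_000, q=q, ld_spec=ld_spec)
        flags = {"susceptibility": False, "severity": False,
                 "ethnicity_specific": False, "two_signals": False}
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    sc.causal_map = causal
    sc.maf_overrides = maf_over
    sc.expected_flags = flags
    return sc


DEFAULT_SUITE = ("susceptibility", "severity", "ethnicity_specific",
                 "two_signal", "null")


def simulate_panel(scenario: SimScenario, panel: list[StudyMeta] | None = None,
                   seed: int = 0) -> tuple[list[AssocTable], SimTruth]:
    """Simulate the full study panel at one scenario locus.

    Baseline allele frequencies are drawn once per locus (shared across
    studies, as studies observe the same population-level frequencies up to
    the scenario's ancestry overrides). Per-study draws use independent
    child seeds of ``seed``, so the fixture is deterministic.
    """
    panel = panel if panel is not None else default_study_panel()
    ss = np.random.SeedSequence(seed)
    rng_maf = np.random.default_rng(ss.spawn(1)[0])
    base_maf = rng_maf.uniform(0.05, 0.5, size=scenario.q)
    R = ar_correlation(scenario.q, scenario.ld_spec)
    L = _cholesky(R)
    variants = scenario.variants()
    child = np.random.SeedSequence(seed, spawn_key=(1,)).spawn(len(panel))
    tables = []
    for meta, cs in zip(panel, child):
        mafs = base_maf.copy()
        for idx, f in scenario.maf_overrides.get(meta.study_id, {}).items():
            mafs[idx] = f
        tables.append(simulate_study(
            R, mafs, scenario.causal_map.get(meta.study_id), meta,
            seed=np.random.default_rng(cs), variants=variants, chol=L))
    truth = SimTruth(scenario=scenario, seed=seed,
                     per_study_causal=dict(scenario.causal_map),
                     expected_flags=dict(scenario.expected_flags))
    return tables, truth


def simulate_eqtl_signals(scenario: SimScenario, seed: int,
                          tissues: tuple[str, ...],
                          n_tissue: int = 300, lam: float = BENCHMARK_LAMBDA,
                          ) -> list[tuple[EqtlDescriptor, AssocTable]]:
    """Two synthetic genes per scenario locus: one sharing the locus's causal
    variant (a true eGene), one with an independent causal variant in a
    different LD block (not an eGene)."""
    R = ar_correlation(scenario.q, scenario.ld_spec)
    L = _cholesky(R)
    variants = scenario.variants()
    causal = sorted(scenario.causal_indices)
    c_shared = causal[0] if causal else scenario.q // 2
    b = scenario.ld_spec.block_size
    c_other = (c_shared + 2 * b) % scenario.q
    out = []
    child = iter(np.random.SeedSequence(seed, spawn_key=(2,)).spawn(2 * len(tissues)))
    for gi, (gname, cidx) in enumerate(
            [("SHARED_EGENE", c_shared), ("INDEP_GENE", c_other)]):
        for tissue in tissues:
            desc = EqtlDescriptor(
                gene_id=f"ENSG{gi:011d}", gene_name=gname, tissue=tissue,
                n=n_tissue)
            meta = StudyMeta(
                study_id=desc.signal_id, phenotype="C2", ancestry="eur",
                controls="without_ukbb", trait_type="quantitative",
                n_total=n_tissue)
            mafs = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(3, gi))
            ).uniform(0.05, 0.5, size=scenario.q)
            tab = simulate_study(R, mafs, {cidx: lam}, meta,
                                 seed=np.random.default_rng(next(child)),
                                 variants=variants, chol=L)
            tab.meta = desc
            out.append((desc, tab))
    return out


# ---------------------------------------------------------------------------
# fixture-directory writer (HGI / GTEx dialects)

HGI_OUT_COLS = {
    "chrom": "#CHR", "pos": "POS", "ref": "REF", "alt": "ALT",
    "beta": "all_inv_var_meta_beta", "se": "all_inv_var_meta_sebeta",
    "p": "all_inv_var_meta_p", "eaf": "all_meta_AF",
}


def write_hgi_tsv(table: AssocTable, path) -> None:
    """Write an AssocTable in the HGI release-5 column dialect."""
    df = table.df.rename(columns=HGI_OUT_COLS)[list(HGI_OUT_COLS.values())].copy()
    meta = table.meta
    n_cases = getattr(meta, "n_cases", None) or 0
    df["all_inv_var_meta_cases"] = n_cases
    df["all_inv_var_meta_controls"] = max(meta.n_total - n_cases, 0)
    df.to_csv(path, sep="\t", index=False)


def write_gtex_tsv(signals: list[tuple[EqtlDescriptor, AssocTable]], path) -> None:
    """Write gene-tissue tables (one tissue) in the GTEx v7 dialect."""
    frames = []
    for desc, tab in signals:
        d = tab.df
        frames.append(pd.DataFrame({
            "gene_id": desc.gene_id,
            "variant_id": [f"{c}_{p}_{r}_{a}_b37" for c, p, r, a in
                           zip(d["chrom"], d["pos"], d["ref"], d["alt"])],
            "tss_distance": 0,
            "ma_samples": (2 * desc.n * d["eaf"]).round().astype(int),
            "ma_count": (2 * desc.n * d["eaf"]).round().astype(int),
            "maf": d["eaf"],
            "pval_nominal": d["p"],
            "slope": d["beta"],
            "slope_se": d["se"],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def simulate_benchmark_suite(out_dir, master_seed: int = 0,
                             scenarios: tuple[str, ...] = DEFAULT_SUITE,
                             panel: list[StudyMeta] | None = None,
                             tissues: tuple[str, ...] = ("Lung", "Whole_Blood"),
                             ) -> dict:
    """Write the default benchmark fixture directory.

    Produces one HGI-dialect TSV per study (all scenario loci concatenated),
    per-tissue GTEx-dialect eQTL tables for the susceptibility locus, a gene
    annotation table, a study-panel YAML and a ``truth.tsv`` with expected
    flags. Deterministic given ``master_seed`` (per-locus child seeds are
    derived by fixed seed-sequence spawning).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel if panel is not None else default_study_panel()
    per_study_frames: dict[str, list[pd.DataFrame]] = {s.study_id: [] for s in panel}
    truth_rows = []
    eqtl_signals: list[tuple[EqtlDescriptor, AssocTable]] = []
    gene_rows = []
    for k, name in enumerate(scenarios):
        sc = build_scenario(name, panel)
        locus_seed = int(np.random.SeedSequence(master_seed, spawn_key=(k,))
                         .generate_state(1)[0] % (2 ** 31))
        tables, truth = simulate_panel(sc, panel, seed=locus_seed)
        for t in tables:
            per_study_frames[t.meta.study_id].append(t.df)
        truth_rows.append({
            "locus": f"{sc.chrom}:{sc.start}–{sc.start + (sc.q - 1) * sc.spacing}",
            "scenario": name, "seed": locus_seed,
            **{f"expect_{k2}": v for k2, v in truth.expected_flags.items()},
        })
        if name == "susceptibility":
            eqtl_signals = simulate_eqtl_signals(sc, locus_seed, tissues)
            span = (sc.q - 1) * sc.spacing
            gene_rows += [
                {"gene_id": "ENSG00000000000", "gene_name": "SHARED_EGENE",
                 "chrom": sc.chrom, "start": sc.start + span // 3,
                 "end": sc.start + span // 2},
                {"gene_id": "ENSG00000000001", "gene_name": "INDEP_GENE",
                 "chrom": sc.chrom, "start": sc.start + span // 2,
                 "end": sc.start + 2 * span // 3},
            ]
    for sid, frames in per_study_frames.items():
        meta = next(s for s in panel if s.study_id == sid)
        cat = pd.concat(frames, ignore_index=True)
        write_hgi_tsv(AssocTable(meta, cat, validate=False), out / f"{sid}.tsv")
    for tissue in tissues:
        sigs = [(d, t) for d, t in eqtl_signals if d.tissue == tissue]
        if sigs:
            write_gtex_tsv(sigs, out / f"eqtl_{tissue}.tsv")
    pd.DataFrame(gene_rows).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    import yaml
    with open(out / "panel.yaml", "w") as fh:
        yaml.safe_dump({"studies": [
            {"study_id": s.study_id, "phenotype": s.phenotype,
             "ancestry": s.ancestry, "controls": s.controls,
             "trait_type": s.trait_type, "n_total": s.n_total,
             "n_cases": s.n_cases} for s in panel]}, fh, sort_keys=False)
    return {
        "out_dir": str(out),
        "studies": sorted(per_study_frames),
        "tissues": list(tissues),
        "truth": pd.DataFrame(truth_rows),
    }
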