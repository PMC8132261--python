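"""Seeded benchmark routines over the synthetic study conditions.

Every routine here regenerates its inputs from scratch at call time under
the benchmark conditions (noncentrality 8, 500 variants per locus in
AR(0.95) blocks of 50, study sizes >= 10,000) and measures the pipeline's
behaviour on them: hypothesis recovery, taxonomy recovery, eGene recovery,
null calibration, engine-vs-oracle agreement and LD accuracy.
"""
from __future__ import annotations

import numpy as np

from .classify import (classify_locus, pairwise_pp_matrix,
                       within_between_phenotype_comparison)
from .coloc import Priors, coloc_abf, coloc_oracle_enumeration, coloc_pair
from .eqtl import call_egenes, coloc_locus_eqtls
from .ld import r2_matrix
from .loci import Locus
from .simulate import (BENCHMARK_LAMBDA, BENCHMARK_Q, LDSpec, ar_correlation,
                       build_scenario, simulate_eqtl_signals,
                       simulate_haplotypes, simulate_panel, simulate_study,
                       _cholesky, _variant_grid)
from .sumstats import StudyMeta, default_study_panel, harmonize_pair


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def oracle_agreement(n_instances: int = 1000, q_max: int = 50,
                     seed: int = 0) -> float:
    """Max absolute per-posterior deviation between the log-space engine and
    the direct enumeration oracle over random log-ABF instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        q = int(rng.integers(1, q_max + 1))
        labf1 = rng.normal(0.0, 10.0, size=q)
        labf2 = rng.normal(0.0, 10.0, size=q)
        a = coloc_abf(labf1, labf2)
        b = coloc_oracle_enumeration(labf1, labf2)
        worst = max(worst, float(np.max(np.abs(a.pp - b.pp))))
        worst = max(worst, float(np.max(np.abs(a.snp_pp_h4 - b.snp_pp_h4))))
    return worst


def _pair_metas() -> tuple[StudyMeta, StudyMeta]:
    panel = default_study_panel()
    return panel[0], panel[4]  # A2_eur_with_ukbb vs B1_eur_with_ukbb


def pair_hypothesis_metrics(scenario: str, n_seeds: int = 100, seed: int = 0,
                            q: int = BENCHMARK_Q, lam: float = BENCHMARK_LAMBDA,
                            ) -> dict[str, np.ndarray]:
    """PP vectors of two-study colocalizations simulated under one hypothesis.

    ``scenario``: 'h4' (shared causal variant), 'h3' (distinct causal
    variants in different LD blocks, target r^2 = 0 between them), or
    'h0' (no causal variant in either study).
    """
    ld = LDSpec()
    R = ar_correlation(q, ld)
    L = _cholesky(R)
    variants = _variant_grid(q, "1", 1_000_000, 2000)
    ma, mb = _pair_metas()
    b = ld.block_size
    c1 = (q // b // 2) * b + b // 2
    c2 = (q // b - 1) * b + b // 2
    causal = {
        "h4": ({c1: lam}, {c1: lam}),
        "h3": ({c1: lam}, {c2: lam}),
        "h0": (None, None),
    }[scenario]
    pph3, pph4 = [], []
    for s in _child_seeds(seed, n_seeds):
        ss = np.random.SeedSequence(s)
        r_m, r_a, r_b = (np.random.default_rng(c) for c in ss.spawn(3))
        mafs = r_m.uniform(0.05, 0.5, size=q)
        ta = simulate_study(R, mafs, causal[0], ma, seed=r_a,
                            variants=variants, chol=L)
        tb = simulate_study(R, mafs, causal[1], mb, seed=r_b,
                            variants=variants, chol=L)
        res = coloc_pair(harmonize_pair(ta, tb), mode="beta")
        pph3.append(res["H3"])
        pph4.append(res["H4"])
    return {"pph3": np.array(pph3), "pph4": np.array(pph4)}


def _scenario_locus(sc) -> Locus:
    return Locus(sc.chrom, sc.start, sc.start + (sc.q - 1) * sc.spacing)


def taxonomy_recovery(scenario_name: str, n_seeds: int = 100, seed: int = 0,
                      ) -> dict:
    """Classify n_seeds replicates of one panel scenario.

    Returns the fraction of replicates in which each expected flag was
    recovered, plus counts of susceptibility/severity assignments (for the
    cross-assignment check).
    """
    panel = default_study_panel()
    sc = build_scenario(scenario_name, panel)
    locus = _scenario_locus(sc)
    hits = {k: 0 for k in sc.expected_flags}
    n_susc = n_sev = 0
    for s in _child_seeds(seed, n_seeds):
        tables, truth = simulate_panel(sc, panel, seed=s)
        m = pairwise_pp_matrix(locus, tables, mode="beta")
        ann = classify_locus(m)
        got = {"susceptibility": ann.susceptibility, "severity": ann.severity,
               "ethnicity_specific": ann.ethnicity_specific,
               "two_signals": ann.two_signals}
        for k, want in truth.expected_flags.items():
            if got[k] == want:
                hits[k] += 1
        n_susc += bool(ann.susceptibility)
        n_sev += bool(ann.severity)
    return {
        "fraction_correct": {k: v / n_seeds for k, v in hits.items()},
        "n_flagged_susceptibility": n_susc,
        "n_flagged_severity": n_sev,
        "n_seeds": n_seeds,
        "expected_flags": dict(sc.expected_flags),
    }


def null_panel_fp_rate(n_seeds: int = 100, seed: int = 0) -> dict:
    """Fraction of study pairs with PP-H4 > 0.9 across null panel replicates."""
    panel = default_study_panel()
    sc = build_scenario("null", panel)
    locus = _scenario_locus(sc)
    n_pairs = n_fp = 0
    for s in _child_seeds(seed, n_seeds):
        tables, _ = simulate_panel(sc, panel, seed=s)
        m = pairwise_pp_matrix(locus, tables, mode="beta")
        finite = np.isfinite(m.pph4)
        iu = np.triu_indices_from(m.pph4, k=1)
        vals = m.pph4[iu][finite[iu]]
        n_pairs += vals.size
        n_fp += int((vals > 0.9).sum())
    return {"n_pairs": n_pairs, "n_fp": n_fp,
            "fp_rate": n_fp / n_pairs if n_pairs else float("nan")}


def egene_recovery(n_seeds: int = 100, seed: int = 0,
                   tissues: tuple[str, ...] = ("Lung", "Whole_Blood")) -> dict:
    """Fractions of replicates where the gene sharing the GWAS causal variant
    is called an eGene and the independent-eQTL gene is not."""
    panel = default_study_panel()
    sc = build_scenario("susceptibility", panel)
    locus = _scenario_locus(sc)
    c2_tables_idx = [i for i, s in enumerate(panel) if s.phenotype == "C2"]
    shared_hit = indep_clean = 0
    for s in _child_seeds(seed, n_seeds):
        tables, _ = simulate_panel(sc, panel, seed=s)
        gwas = [tables[i] for i in c2_tables_idx]
        eqtls = simulate_eqtl_signals(sc, s, tissues)
        cells = coloc_locus_eqtls(locus, gwas, eqtls, mode="beta")
        calls = {(c.gene.gene_name, c.phenotype): c
                 for c in call_egenes(cells)}
        shared = calls.get(("SHARED_EGENE", "C2"))
        indep = calls.get(("INDEP_GENE", "C2"))
        if shared is not None and shared.tier == "colocalized":
            shared_hit += 1
        if indep is None or indep.tier != "colocalized":
            indep_clean += 1
    return {"shared_called": shared_hit / n_seeds,
            "independent_not_called": indep_clean / n_seeds,
            "n_seeds": n_seeds}


def ld_ar_error(n_haplotypes: int = 10_000, q: int = 50, rho: float = 0.9,
                seed: int = 0) -> float:
    """Max |empirical r - rho^|i-j|| within one AR block of a haplotype pool."""
    spec = LDSpec(block_size=q, rho=rho)
    rng = np.random.default_rng(seed)
    haps = simulate_haplotypes(q, spec, n_haplotypes, rng)
    emp = r2_matrix(haps).r
    target = rho ** np.abs(np.subtract.outer(np.arange(q), np.arange(q)))
    return float(np.nanmax(np.abs(emp - target)))


def within_between_metrics(n_loci: int = 6, seed: int = 0) -> dict:
    """Within- vs between-phenotype PP-H4 comparison on synthetic loci where
    each phenotype carries its own causal variant: within-phenotype pairs
    share it, between-phenotype pairs do not."""
    panel = default_study_panel()
    matrices = []
    for s in _child_seeds(seed, n_loci):
        sc = build_scenario("phenotype_distinct", panel)
        tables, _ = simulate_panel(sc, panel, seed=s)
        matrices.append(pairwise_pp_matrix(_scenario_locus(sc), tables, mode="beta"))
    med_w, med_b, p = within_between_phenotype_comparison(matrices)
    return {"median_within": med_w, "median_between": med_b, "p_value": p}
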