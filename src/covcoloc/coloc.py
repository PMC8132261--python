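"""Approximate-Bayes-factor colocalization of two association signals.

For each variant the Wakefield asymptotic approximation summarises the
evidence for association as a natural-log Bayes factor

    lABF = 0.5 * [ ln(1 - r) + z^2 * r ],    r = W / (W + V),

with z = beta/se, V = se^2 and W the prior variance of the true effect.
Under the assumption of at most one causal variant per trait, the posterior
probabilities of the five hypotheses

    H0: neither trait associated        H1/H2: only trait 1 / trait 2
    H3: both associated, different causal variants
    H4: both associated, shared causal variant

follow from per-hypothesis sums of Bayes factors over causal-variant
configurations, weighted by the per-configuration priors p1, p2, p12.
All probability algebra runs in natural-log space with log-sum-exp.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtri_exp

from .errors import ConfigError, InputError, NoOverlapError
from .sumstats import HarmonizedPair, VariantKey

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

#: prior SD of the true effect: log-odds scale for binary traits,
#: per-sd-of-trait scale for quantitative traits (scaled by sdY)
PRIOR_SD_CC = 0.2
PRIOR_SD_QT = 0.15

#: pairs with fewer shared variants than this trigger a warning
MIN_COMFORTABLE_OVERLAP = 50


@dataclass(frozen=True)
class Priors:
    """Per-variant prior probabilities of causal configurations.

    p1 / p2: a given variant is causal for trait 1 / trait 2 only;
    p12: causal for both. Defaults are the conventional single-variant
    colocalization priors (1e-4, 1e-4, 1e-5).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p12 <= self.p1 and self.p12 <= self.p2):
            raise ConfigError(f"require 0 < p12 <= p1 and p12 <= p2, got {self}")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ConfigError(f"p1 + p2 + p12 must be < 1, got {self}")


@dataclass
class ColocResult:
    """Posterior summary of one pairwise colocalization.

    ``pp`` holds (PP-H0..PP-H4), summing to 1; ``snp_pp_h4`` is each shared
    variant's posterior probability of being the shared causal variant
    conditional on H4 (sums to 1); the lead variant maximises it.
    """

    pp: np.ndarray
    nsnps: int
    snp_pp_h4: np.ndarray
    lead_variant: VariantKey | None = None
    lead_pp: float = float("nan")

    def __getitem__(self, h: str) -> float:
        return float(self.pp[HYPOTHESES.index(h)])

    def as_dict(self) -> dict[str, float]:
        return {f"pp_{h.lower()}": float(v) for h, v in zip(HYPOTHESES, self.pp)}


def labf_from_beta(beta, se, prior_sd):
    """Wakefield log-ABF from an effect estimate and its standard error.

    Vectorised over numpy arrays. ``prior_sd`` is W^0.5, the prior SD of the
    true effect; prior_sd = 0 means zero prior variance, hence lABF = 0
    (no evidence either way).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise InputError("standard errors must be finite and > 0")
    if np.any(np.asarray(prior_sd) < 0):
        raise InputError("prior_sd must be >= 0")
    z = beta / se
    V = se ** 2
    W = np.asarray(prior_sd, dtype=float) ** 2
    r = W / (W + V)
    # ln(1 - r) = ln V - ln(W + V), stable as r -> 1
    return 0.5 * (np.log(V) - np.log(W + V) + z * z * r)


def z_from_p(p):
    """Two-sided p-value to |z|, via the log-quantile path so that p-values
    down to the smallest positive double never overflow to infinity."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return -ndtri_exp(np.log(p) - np.log(2.0))


def approx_var_beta(eaf, n, trait_type: str, case_fraction: float | None = None,
                    sdY: float = 1.0):
    """Approximate sampling variance of beta from allele frequency and n.

    Quantitative traits: V = sdY^2 / (2 n f (1-f)).
    Case-control: V = 1 / (2 n f (1-f) s (1-s)) with case fraction s.
    """
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise InputError("allele frequencies must lie in (0, 1)")
    if np.any(n < 2):
        raise InputError("sample size must be >= 2")
    base = 2.0 * n * eaf * (1.0 - eaf)
    if trait_type == "quantitative":
        return sdY ** 2 / base
    if trait_type == "case_control":
        if case_fraction is None or not (0 < case_fraction < 1):
            raise ConfigError("case_control mode needs case_fraction in (0,1)")
        return 1.0 / (base * case_fraction * (1.0 - case_fraction))
    raise ConfigError(f"unknown trait type {trait_type!r}")


def labf_from_p(p, eaf, n, trait_type: str, case_fraction: float | None = None,
                prior_sd: float | None = None, sdY: float = 1.0):
    """Wakefield log-ABF from a p-value, allele frequency and sample size.

    Reconstructs |z| from the two-sided p and approximates V from frequency
    and sample size, then applies the same formula as :func:`labf_from_beta`.
    Symmetric in eaf <-> 1 - eaf.
    """
    if prior_sd is None:
        prior_sd = PRIOR_SD_CC if trait_type == "case_control" else PRIOR_SD_QT * sdY
    z = z_from_p(p)
    V = approx_var_beta(eaf, n, trait_type, case_fraction, sdY)
    W = float(prior_sd) ** 2
    r = W / (W + V)
    return 0.5 * (np.log(V) - np.log(W + V) + z * z * r)


def _finish(lnbf: np.ndarray, labf1: np.ndarray, labf2: np.ndarray,
            variants: list[VariantKey] | None) -> ColocResult:
    """Normalise per-hypothesis log Bayes factors into a ColocResult."""
    pp = np.exp(lnbf - logsumexp(lnbf))
    pp /= pp.sum()
    with np.errstate(over="ignore"):
        joint = labf1 + labf2
    snp_pp = np.exp(joint - logsumexp(joint))
    snp_pp /= snp_pp.sum()
    lead_idx = int(np.argmax(snp_pp))
    if variants is not None:
        # ties broken by smallest genomic position: argmax already returns the
        # first maximum and variants arrive position-sorted
        lead = variants[lead_idx]
    else:
        lead = None
    return ColocResult(pp=pp, nsnps=len(labf1), snp_pp_h4=snp_pp,
                       lead_variant=lead, lead_pp=float(snp_pp[lead_idx]))


def coloc_abf(labf1, labf2, priors: Priors = Priors(),
              variants: list[VariantKey] | None = None) -> ColocResult:
    """Posterior probabilities of H0-H4 from two aligned log-ABF vectors.

    Uses the O(Q) algebraic identity for H3: the sum over ordered pairs of
    distinct variants equals the product of the marginal sums minus the
    diagonal sum, computed stably in log space.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise InputError("labf vectors must be 1-D and of equal length")
    q = labf1.size
    if q == 0:
        raise NoOverlapError("no shared variants to colocalize")
    L1 = logsumexp(labf1)
    L2 = logsumexp(labf2)
    with np.errstate(over="ignore"):
        S = logsumexp(labf1 + labf2)
    if q == 1 or S >= L1 + L2:
        lh3 = -np.inf
    else:
        lh3 = L1 + L2 + np.log1p(-np.exp(S - L1 - L2))
    lnbf = np.array([
        0.0,
        np.log(priors.p1) + L1,
        np.log(priors.p2) + L2,
        np.log(priors.p1) + np.log(priors.p2) + lh3,
        np.log(priors.p12) + S,
    ])
    return _finish(lnbf, labf1, labf2, variants)


def coloc_oracle_enumeration(labf1, labf2, priors: Priors = Priors(),
                             variants: list[VariantKey] | None = None
                             ) -> ColocResult:
    """Reference implementation by direct enumeration of causal configurations.

    Sums Bayes factors over every single-causal-variant configuration per
    hypothesis -- O(Q^2) over the full (i, j) grid for H3, with no algebraic
    shortcut. Identical contract to :func:`coloc_abf`; intended as an
    independent cross-check.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise InputError("labf vectors must be 1-D and of equal length")
    q = labf1.size
    if q == 0:
        raise NoOverlapError("no shared variants to colocalize")
    if q > 2000:
        raise InputError("enumeration oracle limited to 2000 variants")
    grid = labf1[:, None] + labf2[None, :]
    off = ~np.eye(q, dtype=bool)
    lh3 = logsumexp(grid[off]) if q > 1 else -np.inf
    lnbf = np.array([
        0.0,
        np.log(priors.p1) + logsumexp(labf1),
        np.log(priors.p2) + logsumexp(labf2),
        np.log(priors.p1) + np.log(priors.p2) + lh3,
        np.log(priors.p12) + logsumexp(np.diag(grid)),
    ])
    return _finish(lnbf, labf1, labf2, variants)


def is_colocalized(result: ColocResult, threshold: float = 0.9) -> bool:
    """Strict PP-H4 > threshold decision rule for a pair of signals."""
    return result["H4"] > threshold


def _labf_from_stats(beta, se, p, eaf, n, meta, mode: str,
                     prior_sd: float | None):
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    have_beta = np.all(np.isfinite(beta)) and np.all(np.isfinite(se)) and np.all(se > 0)
    trait_type = getattr(meta, "trait_type", "quantitative")
    sdY = getattr(meta, "sdY", 1.0)
    if prior_sd is None:
        prior_sd = PRIOR_SD_CC if trait_type == "case_control" else PRIOR_SD_QT * sdY
    if mode == "beta" or (mode == "auto" and have_beta):
        if not have_beta:
            raise InputError(
                f"beta mode requested but beta/se incomplete for "
                f"{getattr(meta, 'study_id', meta)}")
        return labf_from_beta(beta, se, prior_sd)
    cf = getattr(meta, "case_fraction", None)
    return labf_from_p(np.asarray(p, float), np.asarray(eaf, float),
                       np.asarray(n, float), trait_type, case_fraction=cf,
                       prior_sd=prior_sd, sdY=sdY)


def labf_for_table(table, mode: str = "auto", prior_sd: float | None = None):
    """Per-variant lABF vector for a whole association table."""
    d = table.df
    return _labf_from_stats(d["beta"], d["se"], d["p"], d["eaf"], d["n"],
                            table.meta, mode, prior_sd)


def _side_labf(df, suffix: str, meta, mode: str, prior_sd: float | None):
    """Compute the lABF vector for one side of a harmonized pair."""
    return _labf_from_stats(
        df[f"beta_{suffix}"], df[f"se_{suffix}"], df[f"p_{suffix}"],
        df[f"eaf_{suffix}"], df[f"n_{suffix}"], meta, mode, prior_sd)


def coloc_pair(pair: HarmonizedPair, priors: Priors = Priors(),
               mode: str = "auto", prior_sd_a: float | None = None,
               prior_sd_b: float | None = None, min_nsnps: int = 2
               ) -> ColocResult:
    """Colocalize a harmonized pair of association tables.

    ``mode`` selects the evidence path per side: "beta" forces beta/se,
    "pvalue" forces the p-value approximation, "auto" uses beta/se whenever
    both are complete on that side (sides may differ). Requires at least
    ``min_nsnps`` shared variants; logs a warning under
    ``MIN_COMFORTABLE_OVERLAP``.
    """
    if mode not in ("auto", "beta", "pvalue"):
        raise ConfigError(f"unknown evidence mode {mode!r}")
    q = len(pair)
    if q < min_nsnps:
        raise NoOverlapError(
            f"only {q} shared variants between {_pair_label(pair)}; "
            f"need >= {min_nsnps}")
    if q < MIN_COMFORTABLE_OVERLAP:
        logger.warning("pair %s: only %d shared variants", _pair_label(pair), q)
    labf1 = _side_labf(pair.df, "a", pair.meta_a, mode, prior_sd_a)
    labf2 = _side_labf(pair.df, "b", pair.meta_b, mode, prior_sd_b)
    return coloc_abf(labf1, labf2, priors, variants=pair.variants)


def _pair_label(pair: HarmonizedPair) -> str:
    la = getattr(pair.meta_a, "study_id", None) or getattr(pair.meta_a, "signal_id", "a")
    lb = getattr(pair.meta_b, "study_id", None) or getattr(pair.meta_b, "signal_id", "b")
    return f"{la} vs {lb}"
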