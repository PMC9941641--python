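"""Bayes-factor colocalization under the single-causal-variant assumption.

For two traits measured over the same region, per-SNP approximate Bayes
factors (Wakefield) are combined into posterior probabilities for the
five hypotheses: H0 no causal variant for either trait, H1/H2 a causal
variant for one trait only, H3 two distinct causal variants, and H4 a
single shared causal variant.  A posterior above 0.8 is treated as
decisive; PP.H3 > 0.8 marks an MR signal as LD-confounded (the two traits
are driven by different variants in the same region) and PP.H4 > 0.8 as a
shared causal variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats

from .iv_selection import conditional_select
from .sumstats import harmonize

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PRIORS", "ColocResult", "wakefield_log_abf",
    "abf_from_pval_maf_n", "coloc_region", "extract_region",
    "single_signal_check", "locus_plot_data",
]

#: prior probability that a SNP is causal for trait 1 only / trait 2 only /
#: both (the standard single-variant colocalization defaults)
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")


@dataclass
class ColocResult:
    """Posterior probabilities and the 0.8-rule decision for one region."""

    pp: dict[str, float]
    n_snps: int
    decision: str  # none|shared|distinct|trait1_only|trait2_only|underpowered
    single_snp: bool = False
    assumption_violated: bool = False

    def as_series(self) -> pd.Series:
        s = pd.Series(self.pp)
        s["n_snps"] = self.n_snps
        s["decision"] = self.decision
        return s


def wakefield_log_abf(beta, se, prior_sd: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor in favor of association for each SNP.

    With ``z = beta/se``, sampling variance ``V = se^2`` and prior effect
    variance ``W = prior_sd^2``, the shrinkage is ``r = W/(V+W)`` and
    ``log ABF = 0.5*(log(1-r) + r*z^2)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    z = beta / se
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * (np.log1p(-r) + r * z**2)


def abf_from_pval_maf_n(pval, maf, n, trait_type: str = "quantitative",
                        case_fraction: float | None = None,
                        prior_sd: float = 0.15) -> np.ndarray:
    """Lower-fidelity ABF route when betas/SEs are unavailable: the SE is
    approximated from the additive-variance formula and z recovered from
    the p-value (sign unknown; the ABF depends only on z^2)."""
    pval = np.clip(np.asarray(pval, dtype=float), 1e-300, 1.0)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    z = stats.norm.isf(pval / 2.0)
    var = 2.0 * maf * (1.0 - maf) * n
    if trait_type == "case_control":
        if case_fraction is None:
            raise ValueError("case_fraction required for case_control traits")
        var = var * case_fraction * (1.0 - case_fraction)
    se = 1.0 / np.sqrt(var)
    log.info("abf_from_pval_maf_n: using p/MAF/n approximation (lower fidelity)")
    return wakefield_log_abf(z * se, se, prior_sd)


def _decide(pp: dict[str, float], threshold: float = 0.8) -> str:
    if pp["PP.H4"] > threshold:
        return "shared"
    if pp["PP.H3"] > threshold:
        return "distinct"
    if pp["PP.H1"] > threshold:
        return "trait1_only"
    if pp["PP.H2"] > threshold:
        return "trait2_only"
    if pp["PP.H0"] > threshold:
        return "none"
    return "underpowered"


def coloc_region(labf1, labf2, priors: tuple[float, float, float] = DEFAULT_PRIORS,
                 decision_threshold: float = 0.8) -> ColocResult:
    """Combine per-SNP log-ABFs for two traits into hypothesis posteriors.

    Hypothesis evidence on the log scale (``LSE`` = log-sum-exp over
    SNPs):  H0 = 0;  H1 = log p1 + LSE(L1);  H2 = log p2 + LSE(L2);
    H3 = log(p1 p2) + log(sum_{i != j} exp(L1_i + L2_j)), computed stably
    as the log-difference of LSE(L1)+LSE(L2) and LSE(L1+L2);
    H4 = log p12 + LSE(L1+L2).  Posteriors are the softmax of the five.
    With a single SNP, H3 has no i != j term: PP.H3 = 0, flagged.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or len(l1) < 1:
        raise ValueError("traits must supply aligned 1-D log-ABF arrays")
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
        raise ValueError("priors must be positive with p1+p2+p12 < 1")
    n = len(l1)

    s1, s2, s12 = logsumexp(l1), logsumexp(l2), logsumexp(l1 + l2)
    single_snp = n == 1
    if single_snp:
        lh3 = -np.inf
    else:
        # sum_{i!=j} = (sum_i)(sum_j) - sum_diag; both terms on log scale
        a, b = s1 + s2, s12
        with np.errstate(divide="ignore"):
            lh3 = np.log(p1) + np.log(p2) + a + np.log1p(-np.exp(min(b - a, 0.0)))
    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        lh3,
        np.log(p12) + s12,
    ])
    pp_vec = np.exp(lh - logsumexp(lh))
    pp_vec /= pp_vec.sum()
    pp = dict(zip(HYPOTHESES, pp_vec.astype(float)))
    return ColocResult(pp, n, _decide(pp, decision_threshold),
                       single_snp=single_snp)


def extract_region(trait1: pd.DataFrame, trait2: pd.DataFrame,
                   sentinel: str, half_width: int = 1_000_000,
                   ) -> pd.DataFrame:
    """Slice both traits to the window around a sentinel SNP and align them.

    Keeps SNPs within ``half_width`` bp of the sentinel's position on its
    chromosome, intersects the two traits' SNP lists, and harmonizes the
    second trait's effects to the first's alleles (palindromic SNPs are
    kept: the Bayes factors depend only on z^2).  Returns a harmonized-
    pairs frame (trait1 = ``_exp`` columns, trait2 = ``_out``); empty if
    the intersection is empty (an underpowered region, not an error).
    """
    src = trait1 if (trait1["snp_id"] == sentinel).any() else trait2
    hit = src[src["snp_id"] == sentinel]
    if len(hit) == 0:
        raise KeyError(f"sentinel {sentinel!r} absent from both traits")
    chrom, pos = str(hit["chrom"].iloc[0]), int(hit["pos"].iloc[0])

    def _slice(df: pd.DataFrame) -> pd.DataFrame:
        return df[(df["chrom"].astype(str) == chrom)
                  & ((df["pos"] - pos).abs() <= half_width)]

    return harmonize(_slice(trait1), _slice(trait2), drop_palindromic=False)


def single_signal_check(region: pd.DataFrame, ld: pd.DataFrame,
                        secondary_p_threshold: float = 5e-8,
                        ) -> tuple[bool, dict]:
    """Check the single-causal-variant assumption for both traits.

    Runs conditional selection within the region per trait; the
    assumption fails when either trait carries more than one
    conditionally independent signal at ``secondary_p_threshold``.
    Returns (passes, diagnostic).
    """
    diag: dict[str, int] = {}
    passes = True
    for label, (b, s, n) in {
        "trait1": ("beta_exp", "se_exp", "n_exp"),
        "trait2": ("beta_out", "se_out", "n_out"),
    }.items():
        sub = pd.DataFrame({
            "snp_id": region["snp_id"],
            "beta": region[b], "se": region[s], "n": region[n],
            "pval": 2.0 * stats.norm.sf((region[b] / region[s]).abs()),
        })
        sig = sub[sub["pval"] < secondary_p_threshold]
        if len(sig) == 0:
            diag[label] = 0
            continue
        sel = conditional_select(sig, ld, p_threshold=secondary_p_threshold)
        diag[label] = len(sel)
        if len(sel) > 1:
            passes = False
    return passes, diag


def locus_plot_data(region: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP -log10 p for both traits, keyed by snp_id, for external
    paired locus plots."""
    return pd.DataFrame({
        "snp_id": region["snp_id"],
        "pos": region["pos"],
        "neglog10p_trait1": -np.log10(np.clip(region["pval_exp"], 1e-300, 1)),
        "neglog10p_trait2": -np.log10(np.clip(region["pval_out"], 1e-300, 1)),
    })
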