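"""Two-sample Mendelian randomization estimators and sensitivity suite.

All estimators consume a harmonized-pairs :class:`pandas.DataFrame`
(columns ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out``, ...; see
:func:`protmr.sumstats.harmonize`).  The causal estimate ``beta_mr`` is on
the outcome scale per SD of the exposure — a log odds ratio when the
outcome is a case-control trait — and is reported with its exponentiated
odds ratio and normal-theory 95% confidence interval.

Included: Wald ratio, fixed/multiplicative-random-effects IVW, Egger
regression, weighted median, Cochran's Q, MR-PRESSO global/outlier tests,
the Steiger directionality test, leave-one-out, binary-outcome power (the
mRnd formula), Benjamini-Hochberg FDR, and the discovery-replication
decision rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "MRResult", "PressoResult", "wald_ratio", "ivw", "cochran_q", "egger",
    "weighted_median", "mr_presso", "steiger", "steiger_set",
    "leave_one_out", "mr_power_binary", "bh_fdr", "discover_replicate",
]

Z975 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass
class MRResult:
    """One MR estimate with its diagnostics."""

    method: str
    n_snps: int
    beta_mr: float
    se_mr: float
    pval: float
    protein_id: str | None = None
    group: str | None = None
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    steiger_correct: bool | None = None
    steiger_p: float | None = None
    r2_total: float | None = None
    power: float | None = None
    fdr: float | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_mr))

    @property
    def or_lci(self) -> float:
        return float(np.exp(self.beta_mr - Z975 * self.se_mr))

    @property
    def or_uci(self) -> float:
        return float(np.exp(self.beta_mr + Z975 * self.se_mr))

    def ci_covers(self, theta: float) -> bool:
        return (self.beta_mr - Z975 * self.se_mr
                <= theta <= self.beta_mr + Z975 * self.se_mr)


@dataclass
class PressoResult:
    """MR-PRESSO global test and outlier search."""

    global_rss_obs: float
    global_p: float
    outlier_pvals: dict[str, float]  # Bonferroni-corrected per SNP
    outlier_snps: list[str]
    n_sim: int
    seed: int


def _arrays(pairs: pd.DataFrame):
    return (pairs["beta_exp"].to_numpy(dtype=float),
            pairs["se_exp"].to_numpy(dtype=float),
            pairs["beta_out"].to_numpy(dtype=float),
            pairs["se_out"].to_numpy(dtype=float))


def _pnorm2(z) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def wald_ratio(pair: pd.DataFrame | pd.Series) -> MRResult:
    """Single-instrument MR: ``beta_out / beta_exp`` with the first-order
    delta-method standard error ``se_out / |beta_exp|``."""
    row = pair.iloc[0] if isinstance(pair, pd.DataFrame) else pair
    bx, by, sy = float(row["beta_exp"]), float(row["beta_out"]), float(row["se_out"])
    if bx == 0.0:
        raise ValueError("Wald ratio undefined: exposure beta is zero")
    beta = by / bx
    se = sy / abs(bx)
    return MRResult("wald_ratio", 1, beta, se, _pnorm2(beta / se))


def cochran_q(pairs: pd.DataFrame, beta_mr: float) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic around ``beta_mr``.

    ``Q = sum w_i (theta_i - beta_mr)^2`` with per-SNP Wald ratios
    ``theta_i`` and inverse-variance weights ``w_i = (beta_exp/se_out)^2``;
    p from chi-square with L-1 degrees of freedom.
    """
    bx, _, by, sy = _arrays(pairs)
    theta = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (theta - beta_mr) ** 2))
    p = float(stats.chi2.sf(q, len(bx) - 1))
    return q, p


def ivw(pairs: pd.DataFrame, mode: str = "auto",
        het_alpha: float = 0.05) -> MRResult:
    """Inverse-variance-weighted MR.

    ``beta_mr = sum(bx*by/sy^2) / sum(bx^2/sy^2)``.  Fixed-effects SE is
    ``sum(bx^2/sy^2)^(-1/2)``; the multiplicative-random-effects SE
    multiplies it by ``max(1, sqrt(Q/(L-1)))``.  ``mode="auto"`` selects
    multiplicative iff Cochran's Q has p < ``het_alpha``, else fixed.
    A single pair delegates to :func:`wald_ratio`.
    """
    if mode not in ("fixed", "multiplicative", "auto"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    L = len(pairs)
    if L < 1:
        raise ValueError("ivw requires at least one instrument")
    if L == 1:
        return wald_ratio(pairs)
    bx, _, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    den = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / den
    se_fixed = den ** -0.5
    q, q_pval = cochran_q(pairs, beta)
    infl = max(1.0, np.sqrt(q / (L - 1)))
    if mode == "auto":
        mode = "multiplicative" if q_pval < het_alpha else "fixed"
    if mode == "fixed":
        se, method = se_fixed, "ivw_fe"
    else:
        se, method = se_fixed * infl, "ivw_mre"
    return MRResult(method, L, beta, se, _pnorm2(beta / se),
                    q_stat=q, q_pval=q_pval)


def egger(pairs: pd.DataFrame) -> MRResult:
    """Egger regression: weighted least squares of outcome on exposure
    effects with an intercept (the directional-pleiotropy diagnostic).

    Exposure effects are oriented positive (joint sign flip) first.  The
    residual scale is floored at 1 (multiplicative random effects) and
    p-values use t with L-2 degrees of freedom.
    """
    import statsmodels.api as sm

    L = len(pairs)
    if L < 3:
        raise ValueError(f"Egger regression needs >= 3 instruments, got {L}")
    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    infl = max(1.0, np.sqrt(fit.scale)) / np.sqrt(fit.scale)
    se_int, se_slope = fit.bse[0] * infl, fit.bse[1] * infl
    slope, intercept = fit.params[1], fit.params[0]
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), L - 2))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), L - 2))
    return MRResult("egger", L, float(slope), float(se_slope), p_slope,
                    egger_intercept=float(intercept), egger_intercept_p=p_int)


def _weighted_median_estimate(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    theta, w = theta[order], w[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w  # cumulative midpoint of each weight slab
    return float(np.interp(0.5, s, theta))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted-median MR: consistent when < 50% of instrument weight is
    invalid.

    The SE comes from a seeded model-centered parametric bootstrap:
    exposure betas are redrawn from their normals and outcome betas around
    the fitted values ``est * beta_exp``.  Centering on the fit (rather
    than the raw observations) keeps the bootstrap ratio density near the
    median equal to its sampling-model value; the common observation-
    centered bootstrap dilutes that density and overstates the SE.  Under
    strong violation of instrument validity the SE can be optimistic —
    pair with the heterogeneity and outlier diagnostics.
    """
    L = len(pairs)
    if L < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {L}")
    bx, sx, by, sy = _arrays(pairs)
    theta = by / bx
    w = (bx / sy) ** 2
    est = _weighted_median_estimate(theta, w)

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_boot, L))
    BY = rng.normal(est * bx, sy, size=(n_boot, L))
    TH = BY / BX
    W = (BX / sy) ** 2
    order = np.argsort(TH, axis=1, kind="mergesort")
    TH = np.take_along_axis(TH, order, axis=1)
    W = np.take_along_axis(W, order, axis=1)
    W = W / W.sum(axis=1, keepdims=True)
    S = np.cumsum(W, axis=1) - 0.5 * W
    boots = np.empty(n_boot)
    for b in range(n_boot):  # np.interp is 1-D; loop kept cheap
        boots[b] = np.interp(0.5, S[b], TH[b])
    se = float(boots.std(ddof=1))
    return MRResult("weighted_median", L, est, se, _pnorm2(est / se))


def _loo_ivw_terms(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for all i at once (w = 1/se_out^2)."""
    num = np.sum(w * bx * by, axis=-1, keepdims=True) - w * bx * by
    den = np.sum(w * bx**2, axis=-1, keepdims=True) - w * bx**2
    return num / den


def mr_presso(pairs: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult | None:
    """MR-PRESSO global pleiotropy test and per-SNP outlier search.

    The observed global statistic is the weighted residual sum of squares
    ``RSS = sum_i w_i (by_i - bhat_(-i) * bx_i)^2`` with leave-one-out IVW
    estimates ``bhat_(-i)`` and ``w_i = 1/se_out_i^2``.  Its null
    distribution is simulated by redrawing ``bx* ~ N(bx, se_exp^2)`` and
    ``by*_i ~ N(bhat_(-i) bx_i, se_out_i^2)`` and recomputing the same
    statistic; ``global_p = (1 + #{RSS* >= RSS}) / (n_sim + 1)``.  Per-SNP
    outlier p-values compare each observed squared residual with its
    simulated distribution (Bonferroni-corrected); flagged SNPs should be
    removed before the final MR fit.  Fewer than 4 instruments: skipped
    (returns ``None`` with a logged notice).
    """
    L = len(pairs)
    if L < 4:
        log.info("mr_presso skipped: %d < 4 instruments", L)
        return None
    bx, sx, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    beta_loo = _loo_ivw_terms(bx, by, w)
    resid_obs = by - beta_loo * bx
    rss_obs = float(np.sum(w * resid_obs**2))

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_sim, L))
    BY = rng.normal(beta_loo * bx, sy, size=(n_sim, L))
    BLOO = _loo_ivw_terms(BX, BY, w)
    RESID = BY - BLOO * BX
    rss_sim = np.sum(w * RESID**2, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    if L / (n_sim + 1) >= outlier_alpha:
        log.warning("mr_presso: n_sim=%d too small to flag outliers at "
                    "alpha=%g with %d instruments (needs > %d simulations)",
                    n_sim, outlier_alpha, L, int(L / outlier_alpha))
    snp_ids = list(pairs["snp_id"]) if "snp_id" in pairs.columns \
        else [str(i) for i in range(L)]
    per_snp_p = (1 + np.sum(RESID**2 >= resid_obs**2, axis=0)) / (n_sim + 1)
    corrected = np.minimum(1.0, per_snp_p * L)
    outlier_pvals = dict(zip(snp_ids, corrected.astype(float)))
    outliers = [s for s, p in outlier_pvals.items() if p < outlier_alpha]
    return PressoResult(rss_obs, global_p, outlier_pvals, outliers,
                        n_sim, seed)


def steiger(pair: pd.DataFrame | pd.Series, n_exp: float,
            n_out: float) -> tuple[bool, float]:
    """Steiger directionality test for one instrument.

    Variance explained on each side from ``r2 = z^2/(z^2 + n)``; the
    direction is correct when the instrument explains more variance in the
    exposure than in the outcome.  p from Fisher's z comparison of the two
    correlations.
    """
    row = pair.iloc[0] if isinstance(pair, pd.DataFrame) else pair
    zx = float(row["beta_exp"]) / float(row["se_exp"])
    zy = float(row["beta_out"]) / float(row["se_out"])
    r2x = zx**2 / (zx**2 + n_exp)
    r2y = zy**2 / (zy**2 + n_out)
    return _steiger_from_r2(r2x, r2y, n_exp, n_out)


def _steiger_from_r2(r2x: float, r2y: float, n_exp: float,
                     n_out: float) -> tuple[bool, float]:
    rx, ry = np.sqrt(r2x), np.sqrt(r2y)
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (np.arctanh(min(rx, 0.999999)) - np.arctanh(min(ry, 0.999999))) / denom
    return bool(r2x > r2y), _pnorm2(z)


def steiger_set(pairs: pd.DataFrame, n_exp: float,
                n_out: float) -> tuple[bool, float]:
    """Set-level Steiger test: per-SNP r2 summed within each trait."""
    bx, sx, by, sy = _arrays(pairs)
    zx, zy = bx / sx, by / sy
    r2x = float(np.sum(zx**2 / (zx**2 + n_exp)))
    r2y = float(np.sum(zy**2 / (zy**2 + n_out)))
    return _steiger_from_r2(min(r2x, 0.999), min(r2y, 0.999), n_exp, n_out)


def leave_one_out(pairs: pd.DataFrame,
                  mode: str = "auto") -> list[tuple[str, MRResult]]:
    """Re-fit IVW excluding each SNP in turn."""
    if len(pairs) < 2:
        raise ValueError("leave-one-out requires >= 2 instruments")
    out = []
    for i in range(len(pairs)):
        sub = pairs.drop(pairs.index[i])
        snp = pairs.iloc[i].get("snp_id", str(i))
        out.append((snp, ivw(sub, mode=mode)))
    return out


def mr_power_binary(r2: float, or_alt: float, n: int,
                    case_fraction: float, alpha: float = 0.05) -> float:
    """Statistical power of MR with a binary outcome (the mRnd formula).

    Uses the attenuated effect of the exposure on the observed binary
    scale, ``b = K*(OR/(1 + K*(OR-1)) - 1)`` with case fraction ``K``,
    variance ``v = (K*(1-K) - b^2)/(n*r2)`` where ``r2`` is the exposure
    variance explained by the instruments, and a two-sided chi-square test
    with noncentrality ``b^2/v``.  At OR=1 the power equals ``alpha``.
    """
    if not (0 < r2 < 1):
        raise ValueError("r2 must be in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must be in (0, 1)")
    K = case_fraction
    b = K * (or_alt / (1.0 + K * (or_alt - 1.0)) - 1.0)
    v = (K * (1.0 - K) - b * b) / (n * r2)
    ncp = b * b / v
    thresh = stats.chi2.ppf(1.0 - alpha, 1)
    return float(stats.ncx2.sf(thresh, 1, ncp))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def discover_replicate(discovery: Sequence[MRResult],
                       replication: Sequence[MRResult],
                       fdr_threshold: float = 0.05,
                       rep_alpha: float = 0.05) -> dict:
    """Two-cohort decision rule.

    FDR is computed within each instrument group over that group's tested
    proteins (stored on each discovery result).  A protein passes iff its
    discovery FDR < ``fdr_threshold``, its replication p < ``rep_alpha``,
    and the effect direction agrees in both cohorts.  Proteins absent from
    the replication set are recorded as untestable, never passed.

    Returns ``{"passing": [...], "untestable": [...], "table": DataFrame}``.
    """
    disc = list(discovery)
    rep_by_key = {(r.protein_id, r.group): r for r in replication}

    by_group: dict[str, list[MRResult]] = {}
    for r in disc:
        by_group.setdefault(r.group, []).append(r)
    for results in by_group.values():
        adj = bh_fdr([r.pval for r in results])
        for r, a in zip(results, adj):
            r.fdr = float(a)

    rows, passing, untestable = [], [], []
    for r in disc:
        rep = rep_by_key.get((r.protein_id, r.group))
        sig = r.fdr is not None and r.fdr < fdr_threshold
        status = "not_significant"
        rep_p = rep_beta = np.nan
        if sig:
            if rep is None:
                status = "untestable"
                untestable.append(r.protein_id)
            else:
                rep_p, rep_beta = rep.pval, rep.beta_mr
                concordant = np.sign(rep.beta_mr) == np.sign(r.beta_mr)
                if rep.pval < rep_alpha and concordant:
                    status = "replicated"
                    passing.append(r.protein_id)
                else:
                    status = "discovery_only"
        rows.append({"protein_id": r.protein_id, "group": r.group,
                     "beta_disc": r.beta_mr, "pval_disc": r.pval,
                     "fdr_disc": r.fdr, "beta_rep": rep_beta,
                     "pval_rep": rep_p, "status": status})
    return {"passing": sorted(set(passing)),
            "untestable": sorted(set(untestable)),
            "table": pd.DataFrame(rows)}
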