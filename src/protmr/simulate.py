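"""Synthetic GWAS summary statistics with known ground truth.

Emulates the statistical structure of the study inputs — regional LD,
cis/trans pQTL architectures, a large-case-count discovery outcome cohort
and a small-case-count replication cohort, shared vs. distinct causal
variants, and pleiotropic instruments — so that every pipeline stage can
be tested without external data.

Summary statistics are generated on the standardized scale: a region's
marginal effects are ``b_marg = R b_true + e`` with LD correlation ``R``
and sampling noise ``e ~ MVN(0, R/n_eff)`` (per-SNP sd ``1/sqrt(n_eff)``),
where the effective sample size is ``n`` for quantitative traits and
``n K (1-K)`` for case-control traits with case fraction ``K``.  Allelic
betas and SEs follow from the minor-allele frequency; binary-outcome
effects are on the log-odds-ratio scale.

The emitted :class:`SyntheticTruth` is sufficient to score every pipeline
decision but is never consumed by the analysis code (firewall).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig", "SyntheticTruth", "RegionSim", "ProteomeSim",
    "ar1_corr", "block_corr", "simulate_region",
    "simulate_mr_instruments", "simulate_proteome",
]

#: non-palindromic allele pairs assigned cyclically to simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generators.

    Cohort shapes follow the study design: a quantitative exposure GWAS
    (pooled plasma-proteome scale), a large discovery case-control cohort
    (8021 cases / 16,489 controls) and a small replication cohort
    (346 cases / 207,748 controls).
    """

    seed: int = 20230207
    n_snps_per_region: int = 200
    snp_spacing: int = 5_000
    ld_model: str = "ar1"           # "ar1" | "block"
    rho: float = 0.9                # AR1 decay / within-block r
    block_size: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_n: int = 35_000
    outcome_n: tuple[int, int] = (24_510, 208_094)
    outcome_cases: tuple[int, int] = (8_021, 346)
    true_theta: float = -0.2        # causal log-OR per SD of exposure
    n_instruments: int = 50
    instrument_beta_range: tuple[float, float] = (0.05, 0.20)
    pleiotropy_frac: float = 0.0
    pleiotropy_shift: float = 0.0
    coloc_scenario: str = "shared"  # shared|distinct|trait1_only|null
    causal_z1: float = 12.0         # target |z| at trait 1's causal SNP
    causal_z2: float = 12.0
    causal_r2: float = 0.25         # r^2 between the two causal SNPs (distinct)
    causal_index: int | None = None  # fix trait 1's causal SNP (else random)
    chrom: str = "1"
    region_start: int = 5_000_000

    def __post_init__(self) -> None:
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        for v in (self.n_snps_per_region, self.exposure_n, self.n_instruments,
                  *self.outcome_n, *self.outcome_cases):
            if v <= 0:
                raise ValueError("all counts must be positive")
        if self.coloc_scenario not in ("shared", "distinct", "trait1_only", "null"):
            raise ValueError(f"unknown coloc_scenario {self.coloc_scenario!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each simulated dataset."""

    causal_idx_trait1: list[int] = field(default_factory=list)
    causal_idx_trait2: list[int] = field(default_factory=list)
    b_true_trait1: np.ndarray | None = None
    b_true_trait2: np.ndarray | None = None
    theta: float | None = None
    invalid_iv: np.ndarray | None = None
    scenario: str | None = None


@dataclass
class RegionSim:
    trait1: pd.DataFrame
    trait2: pd.DataFrame
    ld: pd.DataFrame
    truth: SyntheticTruth


def ar1_corr(p: int, rho: float) -> np.ndarray:
    """AR(1) correlation, R_ij = rho^|i-j| (positive definite for |rho|<1)."""
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def block_corr(p: int, block_size: int, r: float) -> np.ndarray:
    """Block-diagonal constant-correlation LD."""
    if not (0 <= r < 1):
        raise ValueError(f"block correlation r={r} is not positive definite")
    R = np.eye(p)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        R[start:stop, start:stop] = r
    np.fill_diagonal(R, 1.0)
    return R


def _n_eff(n: float, n_cases: float | None) -> float:
    if n_cases is None:
        return float(n)
    K = n_cases / n
    return float(n * K * (1.0 - K))


def _chol(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"requested LD matrix is not positive definite: {err}")


def _sumstats_frame(z: np.ndarray, maf: np.ndarray, pos: np.ndarray,
                    snp_ids: Sequence[str], alleles: list[tuple[str, str]],
                    chrom: str, n: int, n_cases: int | None) -> pd.DataFrame:
    """Convert standardized z-scores to an allelic-scale summary table."""
    n_eff = _n_eff(n, n_cases)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)
    beta = z * se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    ea, oa = zip(*alleles)
    return pd.DataFrame({
        "snp_id": list(snp_ids), "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "beta": beta, "se": se, "pval": pval, "n": n,
        "n_cases": np.nan if n_cases is None else n_cases,
    })


def _distinct_index(i0: int, p: int, rho: float, target_r2: float) -> int:
    """Index whose AR1 correlation with i0 is closest to sqrt(target_r2)."""
    if rho == 0:
        return min(i0 + 1, p - 1) if i0 + 1 < p else i0 - 1
    d = max(1, round(np.log(np.sqrt(target_r2)) / np.log(rho)))
    cand = i0 + d if i0 + d < p else i0 - d
    return int(np.clip(cand, 0, p - 1))


def simulate_region(config: SimConfig,
                    rng: np.random.Generator | None = None) -> RegionSim:
    """Simulate two traits' summary statistics over one LD region.

    Trait 1 is the quantitative exposure (protein), trait 2 the binary
    discovery outcome.  Under ``shared`` both traits load on one causal
    SNP; ``distinct`` places trait 2's causal SNP at ``causal_r2`` from
    trait 1's; ``trait1_only`` and ``null`` zero out the respective
    signals.
    """
    rng = rng or np.random.default_rng(config.seed)
    p = config.n_snps_per_region
    if config.ld_model == "ar1":
        R = ar1_corr(p, config.rho)
    elif config.ld_model == "block":
        R = block_corr(p, config.block_size, config.rho)
    else:
        raise ValueError(f"unknown ld_model {config.ld_model!r}")
    Lc = _chol(R)

    n1 = config.exposure_n
    n2, cases2 = config.outcome_n[0], config.outcome_cases[0]
    neff1, neff2 = _n_eff(n1, None), _n_eff(n2, cases2)

    g1 = np.zeros(p)
    g2 = np.zeros(p)
    truth = SyntheticTruth(scenario=config.coloc_scenario)
    if config.coloc_scenario != "null":
        i0 = config.causal_index if config.causal_index is not None \
            else int(rng.integers(p // 4, 3 * p // 4))
        g1[i0] = config.causal_z1 / np.sqrt(neff1)
        truth.causal_idx_trait1 = [i0]
        if config.coloc_scenario == "shared":
            g2[i0] = config.causal_z2 / np.sqrt(neff2)
            truth.causal_idx_trait2 = [i0]
        elif config.coloc_scenario == "distinct":
            i1 = _distinct_index(i0, p, config.rho, config.causal_r2)
            g2[i1] = config.causal_z2 / np.sqrt(neff2)
            truth.causal_idx_trait2 = [i1]
    truth.b_true_trait1, truth.b_true_trait2 = g1, g2

    z1 = np.sqrt(neff1) * (R @ g1) + Lc @ rng.standard_normal(p)
    z2 = np.sqrt(neff2) * (R @ g2) + Lc @ rng.standard_normal(p)

    maf = rng.uniform(*config.maf_range, size=p)
    pos = config.region_start + config.snp_spacing * np.arange(p)
    ids = [f"rs{config.chrom}_{q}" for q in pos]
    alleles = [_ALLELE_PAIRS[int(k)] for k in rng.integers(0, 4, size=p)]
    trait1 = _sumstats_frame(z1, maf, pos, ids, alleles, config.chrom, n1, None)
    trait2 = _sumstats_frame(z2, maf, pos, ids, alleles, config.chrom, n2, cases2)
    ld = pd.DataFrame(R, index=ids, columns=ids)
    return RegionSim(trait1, trait2, ld, truth)


def simulate_mr_instruments(config: SimConfig,
                            rng: np.random.Generator | None = None) -> dict:
    """Draw L independent instruments with exposure and two-cohort outcome
    effects.

    Exposure effects (standardized) have magnitudes uniform on
    ``instrument_beta_range`` with random sign.  True outcome effects are
    ``theta * b_exp`` plus a directional ``pleiotropy_shift`` on the
    invalid fraction; the two outcome cohorts share theta but have
    independent sampling noise at their own effective sample sizes.

    Returns ``{"discovery": pairs, "replication": pairs, "truth": ...}``
    where each ``pairs`` frame is directly consumable by the estimators.
    """
    rng = rng or np.random.default_rng(config.seed)
    L = config.n_instruments
    mag = rng.uniform(*config.instrument_beta_range, size=L)
    sign = rng.choice([-1.0, 1.0], size=L)
    bx = mag * sign

    invalid = np.zeros(L, dtype=bool)
    n_invalid = int(round(config.pleiotropy_frac * L))
    if n_invalid:
        invalid[rng.choice(L, size=n_invalid, replace=False)] = True

    sx = np.full(L, 1.0 / np.sqrt(config.exposure_n))
    bx_hat = bx + sx * rng.standard_normal(L)

    # directional pleiotropy is applied in the frame where the exposure
    # effect is positive (the Egger orientation), so a constant shift is
    # genuinely directional rather than cancelling across random signs
    by_true = config.true_theta * bx + config.pleiotropy_shift * invalid * sign
    out = {}
    for label, n, cases in [
        ("discovery", config.outcome_n[0], config.outcome_cases[0]),
        ("replication", config.outcome_n[1], config.outcome_cases[1]),
    ]:
        sy = np.full(L, 1.0 / np.sqrt(_n_eff(n, cases)))
        by_hat = by_true + sy * rng.standard_normal(L)
        out[label] = pd.DataFrame({
            "snp_id": [f"iv{i}" for i in range(L)],
            "beta_exp": bx_hat, "se_exp": sx,
            "pval_exp": np.clip(2 * stats.norm.sf(np.abs(bx_hat / sx)), 1e-300, 1),
            "beta_out": by_hat, "se_out": sy,
            "pval_out": np.clip(2 * stats.norm.sf(np.abs(by_hat / sy)), 1e-300, 1),
            "n_exp": config.exposure_n, "n_out": n,
        })
    out["truth"] = SyntheticTruth(
        b_true_trait1=bx, theta=config.true_theta, invalid_iv=invalid,
        scenario="instruments")
    return out


# ---------------------------------------------------------------------------
# full-proteome bundle


@dataclass
class ProteomeSim:
    """Everything the pipeline needs, plus the truth to score it against."""

    pqtls: pd.DataFrame          # pooled pQTL table with protein_id column
    annotations: pd.DataFrame    # protein_id, uniprot_id, gene, chrom, tss
    outcome_discovery: pd.DataFrame
    outcome_replication: pd.DataFrame
    ld: dict[str, pd.DataFrame]  # per-protein LD over that protein's SNPs
    truth: pd.DataFrame          # per-protein ground truth
    config: SimConfig


def _protein_slot(k: int) -> tuple[str, int]:
    """Disjoint genomic slot per protein (avoids the chr6 MHC window)."""
    chrom = str((k % 22) + 1)
    start = 5_000_000 + (k // 22) * 20_000_000
    return chrom, start


def simulate_proteome(config: SimConfig, n_proteins: int = 100,
                      n_causal: int = 5, n_confounded: int = 2,
                      causal_thetas: Sequence[float] = (-1.2, -1.0, 0.9, -0.35, 0.3),
                      confounded_effect_z: float = 26.0,
                      confounded_r2: float = 0.6,
                      n_snps_cis: int = 60,
                      cis_beta_range: tuple[float, float] = (0.10, 0.18),
                      rng: np.random.Generator | None = None) -> ProteomeSim:
    """Generate a multi-protein pQTL study with two outcome cohorts.

    Every protein receives a cis signal (plasma protein levels are
    heritable); ``n_causal`` proteins causally affect the outcome with
    effects from ``causal_thetas`` (strong ones should replicate, weak
    ones remain discovery-only); ``n_confounded`` proteins have an
    LD-confounded architecture — the outcome's causal variant is distinct
    from the pQTL (r^2 ~ ``confounded_r2``) with no causal protein effect,
    producing a spurious MR hit that colocalization should exclude.  A
    minority of proteins carry extra architecture: a secondary independent
    cis signal, trans SNPs (one shared pleiotropic trans SNP across six
    proteins, some trans SNPs inside the MHC, some coding variants) to
    exercise the filters.
    """
    if n_causal + n_confounded > n_proteins:
        raise ValueError("more special proteins than proteins")
    rng = rng or np.random.default_rng(config.seed)
    cfg = replace(config, n_snps_per_region=n_snps_cis)
    p = n_snps_cis

    roles = ["null"] * n_proteins
    specials = rng.choice(n_proteins, size=n_causal + n_confounded, replace=False)
    thetas = {}
    for j, k in enumerate(specials[:n_causal]):
        roles[k] = "causal"
        thetas[k] = float(causal_thetas[j % len(causal_thetas)])
    for k in specials[n_causal:]:
        roles[k] = "confounded"

    neff_x = _n_eff(cfg.exposure_n, None)
    neff_d = _n_eff(cfg.outcome_n[0], cfg.outcome_cases[0])
    neff_r = _n_eff(cfg.outcome_n[1], cfg.outcome_cases[1])

    R = ar1_corr(p, cfg.rho)
    Lc = _chol(R)

    pleio_snp = ("22", 40_000_000, "rs_pleio_shared")
    pleio_targets = set(rng.choice(n_proteins, size=min(6, n_proteins),
                                   replace=False).tolist())

    pqtl_frames, ann_rows, truth_rows = [], [], []
    out_disc_frames, out_rep_frames = [], []
    ld_by_protein: dict[str, pd.DataFrame] = {}

    for k in range(n_proteins):
        pid = f"P{k:04d}"
        chrom, start = _protein_slot(k)
        tss = start + (p // 2) * cfg.snp_spacing
        pos = start + cfg.snp_spacing * np.arange(p)
        ids = [f"rs{k}_{i}" for i in range(p)]
        maf = rng.uniform(*cfg.maf_range, size=p)
        alleles = [_ALLELE_PAIRS[int(a)] for a in rng.integers(0, 4, size=p)]

        # exposure architecture: always one cis signal; ~15% get a second
        b_exp = np.zeros(p)
        i0 = int(rng.integers(p // 3, 2 * p // 3))
        b_exp[i0] = rng.uniform(*cis_beta_range) * rng.choice([-1, 1])
        two_signal = rng.random() < 0.15 and roles[k] == "null"
        if two_signal:
            i2 = (i0 + p // 3) % p  # far from i0: conditionally independent
            b_exp[i2] = rng.uniform(*cis_beta_range) * rng.choice([-1, 1])

        # outcome architecture
        g_out = np.zeros(p)
        theta = 0.0
        conf_idx = None
        if roles[k] == "causal":
            theta = thetas[k]
            g_out = theta * b_exp
        elif roles[k] == "confounded":
            conf_idx = _distinct_index(i0, p, cfg.rho, confounded_r2)
            g_out[conf_idx] = confounded_effect_z / np.sqrt(neff_d)

        # same standardized effects in both cohorts, each at its own n_eff
        zx = np.sqrt(neff_x) * (R @ b_exp) + Lc @ rng.standard_normal(p)
        zd = np.sqrt(neff_d) * (R @ g_out) + Lc @ rng.standard_normal(p)
        zr = np.sqrt(neff_r) * (R @ g_out) + Lc @ rng.standard_normal(p)

        pq = _sumstats_frame(zx, maf, pos, ids, alleles, chrom,
                             cfg.exposure_n, None)
        pq["protein_id"] = pid
        # consequence annotations: a few non-causal coding variants
        cons = np.array(["intron_variant"] * p, dtype=object)
        n_coding = int(rng.integers(0, 3))
        for i in rng.choice(p, size=n_coding, replace=False):
            if i != i0:
                cons[i] = "missense_variant"
        pq["consequence"] = cons

        od = _sumstats_frame(zd, maf, pos, ids, alleles, chrom,
                             cfg.outcome_n[0], cfg.outcome_cases[0])
        orp = _sumstats_frame(zr, maf, pos, ids, alleles, chrom,
                              cfg.outcome_n[1], cfg.outcome_cases[1])

        ld = pd.DataFrame(R.copy(), index=ids, columns=ids)

        # trans architecture for ~15% of proteins + the shared pleiotropic SNP
        trans_rows = []
        if rng.random() < 0.15 or k in pleio_targets:
            t_chrom = str(((k + 7) % 22) + 1)
            t_pos = 90_000_000 + k * 10_000
            t_id = f"rs{k}_trans"
            bz = rng.uniform(*cis_beta_range) * rng.choice([-1, 1])
            z_t = bz * np.sqrt(neff_x) + rng.standard_normal()
            trans_rows.append((t_id, t_chrom, t_pos, z_t, "intron_variant"))
            if rng.random() < 0.3:  # some trans SNPs inside the MHC
                m_id = f"rs{k}_mhc"
                z_m = (rng.uniform(*cis_beta_range)
                       * rng.choice([-1, 1]) * np.sqrt(neff_x)
                       + rng.standard_normal())
                trans_rows.append((m_id, "6", 30_000_000 + k * 1_000, z_m,
                                   "intron_variant"))
        if k in pleio_targets:
            z_p = (rng.uniform(*cis_beta_range) * rng.choice([-1, 1])
                   * np.sqrt(neff_x) + rng.standard_normal())
            trans_rows.append((pleio_snp[2], pleio_snp[0], pleio_snp[1], z_p,
                               "intron_variant"))
        if trans_rows:
            t_ids = [r[0] for r in trans_rows]
            t_maf = rng.uniform(*cfg.maf_range, size=len(trans_rows))
            t_alleles = [_ALLELE_PAIRS[0]] * len(trans_rows)
            tq = _sumstats_frame(np.array([r[3] for r in trans_rows]), t_maf,
                                 np.array([r[2] for r in trans_rows]), t_ids,
                                 t_alleles, "NA", cfg.exposure_n, None)
            tq["chrom"] = [r[1] for r in trans_rows]
            tq["protein_id"] = pid
            tq["consequence"] = [r[4] for r in trans_rows]
            pq = pd.concat([pq, tq], ignore_index=True)
            # trans SNPs: independent of the cis region and each other
            all_ids = ids + t_ids
            big = np.eye(len(all_ids))
            big[:p, :p] = R
            ld = pd.DataFrame(big, index=all_ids, columns=all_ids)
            # null outcome entries for the trans SNPs in both cohorts
            for frame, n, cases, lbl in ((od, cfg.outcome_n[0], cfg.outcome_cases[0], 0),
                                         (orp, cfg.outcome_n[1], cfg.outcome_cases[1], 1)):
                tz = rng.standard_normal(len(trans_rows))
                to = _sumstats_frame(tz, t_maf,
                                     np.array([r[2] for r in trans_rows]),
                                     t_ids, t_alleles, "NA", n, cases)
                to["chrom"] = [r[1] for r in trans_rows]
                if lbl == 0:
                    out_disc_frames.append(to)
                else:
                    out_rep_frames.append(to)

        pqtl_frames.append(pq)
        out_disc_frames.append(od)
        out_rep_frames.append(orp)
        ld_by_protein[pid] = ld
        ann_rows.append({"protein_id": pid, "uniprot_id": f"U{k:05d}",
                         "gene": f"GENE{k}", "gene_chrom": chrom,
                         "gene_tss": tss})
        truth_rows.append({"protein_id": pid, "role": roles[k],
                           "theta": theta, "causal_idx": i0,
                           "confounded_idx": conf_idx,
                           "two_signal": two_signal})

    def _dedup(frames: list[pd.DataFrame]) -> pd.DataFrame:
        df = pd.concat(frames, ignore_index=True)
        return df.drop_duplicates("snp_id", keep="first").reset_index(drop=True)

    return ProteomeSim(
        pqtls=pd.concat(pqtl_frames, ignore_index=True),
        annotations=pd.DataFrame(ann_rows),
        outcome_discovery=_dedup(out_disc_frames),
        outcome_replication=_dedup(out_rep_frames),
        ld=ld_by_protein,
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )
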