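"""Discovery -> replication -> colocalization orchestration and reporting.

Runs, in order: instrument filtering, group construction (A/B/C/D),
per-group MR on the discovery cohort, Benjamini-Hochberg FDR within each
group, replication MR for FDR-passing proteins, MR-PRESSO where an
instrument set has at least four SNPs, and colocalization of each
surviving protein's cis region against the discovery outcome.  A protein
whose coloc verdict is *distinct* (PP.H3 > 0.8) is excluded as
LD-confounded; *shared* (PP.H4 > 0.8) upgrades it to
``replicated_colocalized``.  When a protein is significant in several
groups the reporting preference is A > B > D > C.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import (DEFAULT_PRIORS, ColocResult, coloc_region, extract_region,
                    single_signal_check, wakefield_log_abf)
from .iv_selection import (MHC_REGION, InstrumentSet, assign_cis_trans,
                           build_groups, f_statistic, filter_instruments,
                           variance_explained)
from .mr import (MRResult, PressoResult, bh_fdr, ivw, mr_power_binary,
                 mr_presso, steiger_set, wald_ratio)
from .sumstats import Region, harmonize

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ProteinVerdict", "run_pipeline",
           "verdict_report", "write_reports"]

GROUP_PREFERENCE = ("A", "B", "D", "C")


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with the study's defaults."""

    p_threshold: float = 5e-8
    f_min: float = 10.0
    clump_r2: float = 0.1
    conditional_p: float = 5e-8
    cis_window: int = 1_000_000
    region_span: int = 1_000_000
    max_pleiotropy: int = 5
    fdr_threshold: float = 0.05
    rep_alpha: float = 0.05
    coloc_pp_threshold: float = 0.8
    coloc_half_width: int = 1_000_000
    coloc_priors: tuple[float, float, float] = DEFAULT_PRIORS
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2
    presso_n_sim: int = 1000
    mhc: Region = field(default_factory=lambda: MHC_REGION)
    groups: tuple[str, ...] = ("A", "B", "C", "D")
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_threshold", "f_min", "clump_r2", "fdr_threshold",
                     "rep_alpha", "coloc_pp_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mhc"] = (self.mhc.chrom, self.mhc.start, self.mhc.end)
        return d


@dataclass
class ProteinVerdict:
    """The pipeline's complete judgement for one protein."""

    protein_id: str
    final_status: str = "not_significant"
    reported_group: str | None = None
    discovery: dict[str, MRResult] = field(default_factory=dict)
    replication: dict[str, MRResult] = field(default_factory=dict)
    presso: PressoResult | None = None
    coloc_outcome: ColocResult | None = None
    coloc_eqtl: ColocResult | None = None

    def reported_result(self) -> MRResult | None:
        if self.reported_group is None:
            return None
        return self.discovery[self.reported_group]


def _mr_for_set(iset: InstrumentSet, outcome: pd.DataFrame,
                config: PipelineConfig) -> tuple[MRResult, pd.DataFrame] | None:
    """Harmonize one instrument set against an outcome and fit MR."""
    if iset.n_snps == 0:
        return None
    pairs = harmonize(iset.records, outcome, drop_palindromic=True)
    if len(pairs) == 0:
        return None
    res = wald_ratio(pairs) if len(pairs) == 1 else ivw(pairs, mode="auto")
    res.protein_id = iset.protein_id
    res.group = iset.group
    f = f_statistic(pairs["beta_exp"], pairs["se_exp"])
    res.r2_total = float(np.sum(variance_explained(f, pairs["n_exp"])))
    correct, p_st = steiger_set(pairs, float(pairs["n_exp"].iloc[0]),
                                float(pairs["n_out"].iloc[0]))
    res.steiger_correct, res.steiger_p = correct, p_st
    return res, pairs


def run_pipeline(bundle, config: PipelineConfig | None = None
                 ) -> list[ProteinVerdict]:
    """Execute the full workflow on an input bundle.

    ``bundle`` provides ``pqtls`` (pooled pQTL table with ``protein_id``
    and ``consequence`` columns), ``annotations`` (gene coordinates per
    protein), ``outcome_discovery``/``outcome_replication`` summary
    statistics, and ``ld`` (per-protein LD frames) — the shape produced by
    :func:`protmr.simulate.simulate_proteome` or loaded from files.
    """
    config = config or PipelineConfig()
    pqtls = bundle.pqtls.copy()
    ann = bundle.annotations.set_index("protein_id")
    pqtls["f_stat"] = f_statistic(pqtls["beta"], pqtls["se"])

    # pleiotropy counted over genome-wide-significant associations
    sig = pqtls[pqtls["pval"] < config.p_threshold]
    pleiotropy_counts = sig.groupby("snp_id")["protein_id"].nunique().to_dict()

    verdicts: dict[str, ProteinVerdict] = {}
    discovery_results: list[MRResult] = []
    groups_by_protein: dict[str, dict[str, InstrumentSet]] = {}
    sentinel_by_protein: dict[str, str] = {}

    for pid, prot in pqtls.groupby("protein_id", sort=True):
        verdicts[pid] = ProteinVerdict(pid)
        kept, _ = filter_instruments(
            prot, pleiotropy_counts, p_threshold=config.p_threshold,
            f_min=config.f_min, max_proteins=config.max_pleiotropy,
            mhc=config.mhc)
        if len(kept) == 0:
            continue
        meta = ann.loc[pid] if pid in ann.index else None
        kept = assign_cis_trans(
            kept,
            None if meta is None else meta["gene_chrom"],
            None if meta is None else meta["gene_tss"],
            window=config.cis_window)
        groups = build_groups(kept, bundle.ld[pid], protein_id=pid,
                              clump_r2=config.clump_r2,
                              conditional_p=config.conditional_p,
                              region_span=config.region_span)
        groups_by_protein[pid] = groups
        if len(groups["A"].records):
            sentinel_by_protein[pid] = groups["A"].records["snp_id"].iloc[0]
        for g in config.groups:
            fit = _mr_for_set(groups[g], bundle.outcome_discovery, config)
            if fit is None:
                continue
            res, _ = fit
            verdicts[pid].discovery[g] = res
            discovery_results.append(res)

    # BH-FDR within each group over that group's tested proteins
    by_group: dict[str, list[MRResult]] = {}
    for r in discovery_results:
        by_group.setdefault(r.group, []).append(r)
    for results in by_group.values():
        for r, a in zip(results, bh_fdr([r.pval for r in results])):
            r.fdr = float(a)

    # replication, PRESSO, coloc — only for FDR-passing (protein, group)
    for pid, verdict in verdicts.items():
        passing_groups = [g for g, r in verdict.discovery.items()
                          if r.fdr is not None and r.fdr < config.fdr_threshold]
        if not passing_groups:
            continue
        replicated_groups = []
        for g in passing_groups:
            iset = groups_by_protein[pid][g]
            fit = _mr_for_set(iset, bundle.outcome_replication, config)
            if fit is None:
                continue
            rep, rep_pairs = fit
            verdict.replication[g] = rep
            disc = verdict.discovery[g]
            if rep.pval < config.rep_alpha and \
                    np.sign(rep.beta_mr) == np.sign(disc.beta_mr):
                replicated_groups.append(g)
            # MR-PRESSO on sets with >= 4 instruments; outliers removed,
            # the discovery fit refreshed
            disc_pairs = harmonize(iset.records, bundle.outcome_discovery,
                                   drop_palindromic=True)
            if len(disc_pairs) >= 4:
                presso = mr_presso(disc_pairs, n_sim=config.presso_n_sim,
                                   seed=config.seed)
                if presso is not None:
                    verdict.presso = presso
                    if presso.outlier_snps:
                        clean = disc_pairs[~disc_pairs["snp_id"]
                                           .isin(presso.outlier_snps)]
                        if len(clean) >= 2:
                            refit = ivw(clean, mode="auto")
                            refit.protein_id, refit.group = pid, g
                            refit.fdr = disc.fdr
                            refit.r2_total = disc.r2_total
                            verdict.discovery[g] = refit

        if not replicated_groups:
            verdict.final_status = "discovery_only"
            verdict.reported_group = _preferred(passing_groups)
            continue

        verdict.final_status = "replicated"
        verdict.reported_group = _preferred(replicated_groups)

        # colocalization of the cis region vs the discovery outcome
        sentinel = sentinel_by_protein.get(pid)
        if sentinel is None:
            continue
        prot_all = pqtls[pqtls["protein_id"] == pid]
        region = extract_region(prot_all, bundle.outcome_discovery, sentinel,
                                half_width=config.coloc_half_width)
        if len(region) == 0:
            verdict.coloc_outcome = ColocResult(
                dict.fromkeys(["PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4"],
                              np.nan), 0, "underpowered")
            continue
        l1 = wakefield_log_abf(region["beta_exp"], region["se_exp"],
                               config.prior_sd_quant)
        l2 = wakefield_log_abf(region["beta_out"], region["se_out"],
                               config.prior_sd_cc)
        cres = coloc_region(l1, l2, priors=config.coloc_priors,
                            decision_threshold=config.coloc_pp_threshold)
        ids = [s for s in region["snp_id"] if s in bundle.ld[pid].index]
        if len(ids) >= 2:
            sub_ld = bundle.ld[pid].loc[ids, ids]
            ok, _ = single_signal_check(
                region[region["snp_id"].isin(ids)], sub_ld,
                secondary_p_threshold=config.p_threshold)
            cres.assumption_violated = not ok
        verdict.coloc_outcome = cres
        if cres.decision == "distinct":
            verdict.final_status = "excluded_LD_confounded"
        elif cres.decision == "shared":
            verdict.final_status = "replicated_colocalized"

    # fill power column for reported results
    n_disc = int(bundle.outcome_discovery["n"].iloc[0])
    cases = bundle.outcome_discovery["n_cases"].iloc[0]
    K = float(cases) / n_disc if pd.notna(cases) else None
    for verdict in verdicts.values():
        res = verdict.reported_result()
        if res is not None and K is not None and res.r2_total \
                and 0 < res.r2_total < 1:
            res.power = mr_power_binary(res.r2_total, res.or_, n_disc, K)

    return list(verdicts.values())


def _preferred(groups: list[str]) -> str:
    for g in GROUP_PREFERENCE:
        if g in groups:
            return g
    return groups[0]


def verdict_report(verdicts: list[ProteinVerdict],
                   annotations: pd.DataFrame | None = None
                   ) -> dict[str, object]:
    """Build the MR-results and colocalization report tables plus a
    human-readable summary of counts per final status."""
    uniprot = {}
    if annotations is not None:
        uniprot = annotations.set_index("protein_id")["uniprot_id"].to_dict()

    mr_rows, coloc_rows = [], []
    for v in verdicts:
        res = v.reported_result()
        if res is not None and v.final_status != "not_significant":
            groups = sorted(g for g, r in v.discovery.items()
                            if r.fdr is not None and r.fdr < 0.05)
            mr_rows.append({
                "protein": v.protein_id,
                "UniprotID": uniprot.get(v.protein_id, ""),
                "method": res.method, "pval": res.pval, "FDR": res.fdr,
                "OR": res.or_, "lower": res.or_lci, "upper": res.or_uci,
                "r2": res.r2_total, "power": res.power,
                "group": " and ".join(f"group {g}" for g in groups),
                "final_status": v.final_status,
            })
        if v.coloc_outcome is not None and v.coloc_outcome.n_snps > 0:
            row = {"protein": v.protein_id,
                   "UniprotID": uniprot.get(v.protein_id, ""),
                   "N": v.coloc_outcome.n_snps}
            row.update({k: v.coloc_outcome.pp[k] for k in
                        ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")})
            row["decision"] = v.coloc_outcome.decision
            coloc_rows.append(row)

    mr_table = pd.DataFrame(mr_rows, columns=[
        "protein", "UniprotID", "method", "pval", "FDR", "OR", "lower",
        "upper", "r2", "power", "group", "final_status"])
    coloc_table = pd.DataFrame(coloc_rows, columns=[
        "protein", "UniprotID", "N", "PP.H0", "PP.H1", "PP.H2", "PP.H3",
        "PP.H4", "decision"])

    counts = pd.Series([v.final_status for v in verdicts]).value_counts()
    n_final = int(counts.get("replicated", 0)
                  + counts.get("replicated_colocalized", 0))
    lines = [f"{len(verdicts)} proteins analyzed"]
    for status in ("discovery_only", "replicated", "replicated_colocalized",
                   "excluded_LD_confounded"):
        lines.append(f"{status}: {int(counts.get(status, 0))}")
    lines.append(f"final causal candidates: {n_final}")
    return {"mr_table": mr_table, "coloc_table": coloc_table,
            "summary": "\n".join(lines)}


def write_reports(verdicts: list[ProteinVerdict], config: PipelineConfig,
                  out_dir, annotations: pd.DataFrame | None = None,
                  input_checksums: dict | None = None) -> dict:
    """Write the report TSVs, summary, and a provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = verdict_report(verdicts, annotations)
    rep["mr_table"].to_csv(out / "mr_results.tsv", sep="\t", index=False)
    rep["coloc_table"].to_csv(out / "coloc_results.tsv", sep="\t", index=False)
    (out / "summary.txt").write_text(rep["summary"] + "\n")
    prov = {
        "package": "protmr", "version": __version__,
        "seed": config.seed, "config": config.to_dict(),
        "input_checksums": input_checksums or {},
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
    return rep


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
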