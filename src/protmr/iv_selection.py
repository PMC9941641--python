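"""Instrument selection for protein quantitative trait loci (pQTLs).

Implements the filtering and grouping scheme used for proteome-wide MR:
genome-wide significance, weak-instrument (F statistic) exclusion, MHC
exclusion, pleiotropy and protein-coding-variant exclusion, cis/trans
assignment, sentinel selection, greedy LD clumping, approximate
conditional (joint) analysis from summary statistics, and construction of
the four instrument groups:

* **A** — sentinel cis-pQTL only (never clumped; one SNP per gene region),
* **B** — sentinel plus conditionally independent cis-pQTLs, clumped,
* **C** — trans-pQTLs only, clumped,
* **D** — all pQTLs, clumped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import Region

log = logging.getLogger(__name__)

__all__ = [
    "MHC_REGION", "CODING_CONSEQUENCES", "InstrumentSet",
    "f_statistic", "variance_explained", "filter_instruments",
    "assign_cis_trans", "select_sentinel", "ld_clump",
    "conditional_select", "build_groups", "ld_from_dosages",
]

#: extended MHC region, GRCh37 (hg19)
MHC_REGION = Region("6", 27_477_797, 34_448_354)

#: protein-coding-altering consequences excluded as instruments, since they
#: can distort the aptamer/antibody measurement of the protein itself
CODING_CONSEQUENCES = frozenset({
    "missense_variant", "stop_gained", "stop_lost", "start_lost",
    "frameshift_variant", "inframe_insertion", "inframe_deletion",
})


@dataclass
class InstrumentSet:
    """Instruments for one protein in one group, with their LD matrix (r)."""

    protein_id: str
    group: str  # "A" | "B" | "C" | "D"
    records: pd.DataFrame
    ld: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ld is None:
            ids = list(self.records["snp_id"])
            self.ld = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)

    @property
    def n_snps(self) -> int:
        return len(self.records)


def f_statistic(beta, se) -> np.ndarray:
    """Per-SNP instrument-strength F statistic, (beta/se)^2."""
    return (np.asarray(beta) / np.asarray(se)) ** 2


def variance_explained(f_stat, n) -> np.ndarray:
    """Per-SNP exposure variance explained, r2 = F / (F + n - 2)."""
    f_stat = np.asarray(f_stat, dtype=float)
    return f_stat / (f_stat + np.asarray(n, dtype=float) - 2.0)


def filter_instruments(records: pd.DataFrame,
                       pleiotropy_counts: Mapping[str, int] | None = None,
                       *, p_threshold: float = 5e-8, f_min: float = 10.0,
                       max_proteins: int = 5, mhc: Region = MHC_REGION,
                       coding: frozenset = CODING_CONSEQUENCES,
                       strict_consequence: bool = False,
                       ) -> tuple[pd.DataFrame, dict]:
    """Apply the instrument exclusion rules; returns (kept, removal counts).

    A record is kept iff it is genome-wide significant
    (``pval < p_threshold``), not a weak instrument (``f_stat >= f_min``),
    outside the MHC region, associated with at most ``max_proteins``
    proteins, and not a protein-coding-altering variant.  Removal counts
    are attributed to the first failing rule, in that order.  Rows lacking
    a consequence annotation raise in strict mode and are kept (flagged)
    otherwise.
    """
    df = records.copy()
    if "f_stat" not in df.columns:
        df["f_stat"] = f_statistic(df["beta"], df["se"])
    cons = df.get("consequence")
    if cons is None:
        cons = pd.Series([None] * len(df), index=df.index)
    missing_cons = cons.isna()
    if strict_consequence and missing_cons.any():
        raise ValueError(
            f"{int(missing_cons.sum())} record(s) lack a consequence annotation"
        )

    fail_sig = ~(df["pval"] < p_threshold)
    fail_weak = ~(df["f_stat"] >= f_min)
    fail_mhc = pd.Series(mhc.contains(df["chrom"], df["pos"]), index=df.index)
    if pleiotropy_counts is not None:
        counts = df["snp_id"].map(lambda s: pleiotropy_counts.get(s, 1))
        fail_pleio = counts > max_proteins
    else:
        fail_pleio = pd.Series(False, index=df.index)
    fail_coding = cons.isin(coding)

    reason = pd.Series("kept", index=df.index)
    for name, mask in [("not_significant", fail_sig), ("weak_iv", fail_weak),
                       ("mhc", fail_mhc), ("pleiotropic", fail_pleio),
                       ("coding_variant", fail_coding)]:
        reason = reason.mask((reason == "kept") & mask, name)

    removal_counts = reason[reason != "kept"].value_counts().to_dict()
    kept = df[reason == "kept"].copy()
    kept["consequence_missing"] = missing_cons[reason == "kept"]
    if removal_counts:
        log.info("filter_instruments: removed %s", removal_counts)
    return kept.reset_index(drop=True), removal_counts


def assign_cis_trans(records: pd.DataFrame, gene_chrom: str | None,
                     gene_tss: int | None,
                     window: int = 1_000_000) -> pd.DataFrame:
    """Flag each pQTL cis/trans relative to the protein's gene TSS.

    A SNP is *cis* iff it lies on the gene's chromosome within ``window``
    bp of the TSS (boundary inclusive).  When gene coordinates are
    unknown every SNP is labeled trans and the frame is flagged.
    """
    df = records.copy()
    if gene_chrom is None or gene_tss is None:
        log.warning("assign_cis_trans: missing gene coordinates; "
                    "all SNPs labeled trans")
        df["is_cis"] = False
        df.attrs["gene_coords_missing"] = True
        return df
    df["is_cis"] = (df["chrom"].astype(str) == str(gene_chrom)) & \
                   ((df["pos"] - int(gene_tss)).abs() <= window)
    df.attrs["gene_coords_missing"] = False
    return df


def _priority_order(df: pd.DataFrame) -> pd.DataFrame:
    """Ascending p; ties by larger F, then lexicographic snp_id."""
    d = df.copy()
    if "f_stat" not in d.columns:
        d["f_stat"] = f_statistic(d["beta"], d["se"])
    return d.sort_values(["pval", "f_stat", "snp_id"],
                         ascending=[True, False, True], kind="mergesort")


def select_sentinel(records: pd.DataFrame,
                    region_span: int = 1_000_000) -> pd.DataFrame:
    """Greedy sentinel selection: repeatedly take the lowest-p SNP and mask
    all SNPs within ``region_span`` bp of it on the same chromosome."""
    if len(records) == 0:
        return records.copy()
    ordered = _priority_order(records)
    taken: list[int] = []
    masked = np.zeros(len(ordered), dtype=bool)
    chrom = ordered["chrom"].astype(str).to_numpy()
    pos = ordered["pos"].to_numpy()
    for i in range(len(ordered)):
        if masked[i]:
            continue
        taken.append(i)
        masked |= (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= region_span)
    return ordered.iloc[taken].reset_index(drop=True)


def _r2_sub(ld: pd.DataFrame, rows, cols) -> np.ndarray:
    return np.asarray(ld.loc[rows, cols], dtype=float) ** 2


def ld_clump(records: pd.DataFrame, ld: pd.DataFrame,
             r2_threshold: float = 0.1, strict: bool = True) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    Retain the best remaining SNP; discard every remaining SNP with
    ``r^2 >= r2_threshold`` against any retained SNP.  The output is
    pairwise ``r^2 < r2_threshold``.
    """
    if len(records) == 0:
        return records.copy()
    missing = [s for s in records["snp_id"] if s not in ld.index]
    if missing:
        if strict:
            raise KeyError(f"SNP(s) missing from LD matrix: {missing[:5]}")
        records = records[records["snp_id"].isin(ld.index)]
    ordered = _priority_order(records)
    kept: list[str] = []
    for snp in ordered["snp_id"]:
        if not kept or (_r2_sub(ld, [snp], kept) < r2_threshold).all():
            kept.append(snp)
    return ordered[ordered["snp_id"].isin(kept)].reset_index(drop=True)


def conditional_select(records: pd.DataFrame, ld: pd.DataFrame,
                       p_threshold: float = 5e-8,
                       collinear_r2: float = 0.9) -> pd.DataFrame:
    """Stepwise forward selection of conditionally independent SNPs from
    summary statistics (approximate conditional & joint analysis).

    Starting from the sentinel (lowest marginal p), each step evaluates
    every remaining SNP jointly with the selected set on the standardized
    scale (joint effects ``R^{-1} b``, per-SNP joint variance
    ``(R^{-1})_jj / n``) and adds the SNP with the smallest conditional p
    if it is below ``p_threshold``.  Candidates with ``r^2 >
    collinear_r2`` against the selected set are skipped; a numerically
    singular ``R`` aborts the step with a diagnostic.
    """
    if len(records) == 0:
        return records.copy()
    ordered = _priority_order(records)
    ids = list(ordered["snp_id"])
    z = (ordered["beta"] / ordered["se"]).to_numpy()
    n = ordered["n"].to_numpy(dtype=float)
    b_std = z / np.sqrt(n)  # standardized marginal effects
    idx = {s: i for i, s in enumerate(ids)}

    selected = [ids[0]]
    cond_p = {ids[0]: float(ordered["pval"].iloc[0])}
    while True:
        remaining = [s for s in ids if s not in selected]
        best: tuple[float, str] | None = None
        for s in remaining:
            r2_with_sel = _r2_sub(ld, [s], selected)
            if (r2_with_sel > collinear_r2).any():
                continue
            trial = selected + [s]
            R = np.asarray(ld.loc[trial, trial], dtype=float)
            try:
                Rinv = np.linalg.inv(R)
            except np.linalg.LinAlgError:
                log.warning("conditional_select: singular LD for %s; "
                            "step aborted", trial)
                continue
            if np.linalg.cond(R) > 1e8:
                continue
            b = np.array([b_std[idx[t]] for t in trial])
            b_joint = Rinv @ b
            var_j = Rinv[-1, -1] / n[idx[s]]
            z_cond = b_joint[-1] / np.sqrt(var_j)
            p_cond = 2.0 * stats.norm.sf(abs(z_cond))
            if best is None or p_cond < best[0]:
                best = (p_cond, s)
        if best is None or best[0] >= p_threshold:
            break
        cond_p[best[1]] = best[0]
        selected.append(best[1])

    out = ordered[ordered["snp_id"].isin(selected)].copy()
    out["conditional_pval"] = out["snp_id"].map(cond_p)
    return out.reset_index(drop=True)


def build_groups(records: pd.DataFrame, ld: pd.DataFrame, *,
                 protein_id: str | None = None, clump_r2: float = 0.1,
                 conditional_p: float = 5e-8,
                 region_span: int = 1_000_000) -> dict[str, InstrumentSet]:
    """Construct the four instrument groups for one protein.

    ``records`` must already be filtered (see :func:`filter_instruments`)
    and carry an ``is_cis`` flag.  Group A keeps only the sentinel
    cis-pQTL (no clumping); B adds conditionally independent cis-pQTLs
    and is clumped at ``clump_r2``; C is the clumped trans set; D is the
    clumped union of all instruments.
    """
    pid = protein_id or (records["protein_id"].iloc[0]
                         if "protein_id" in records.columns and len(records)
                         else "?")
    cis = records[records["is_cis"]]
    trans = records[~records["is_cis"]]

    sentinel = select_sentinel(cis, region_span=region_span).head(1)
    if len(cis):
        indep = conditional_select(cis, ld, p_threshold=conditional_p)
        group_b = ld_clump(indep, ld, r2_threshold=clump_r2)
    else:
        group_b = cis.copy()
    group_c = ld_clump(trans, ld, r2_threshold=clump_r2) if len(trans) else trans.copy()
    group_d = ld_clump(records, ld, r2_threshold=clump_r2) if len(records) else records.copy()

    def _mk(group: str, df: pd.DataFrame) -> InstrumentSet:
        ids = list(df["snp_id"])
        sub = ld.loc[ids, ids] if ids else pd.DataFrame()
        return InstrumentSet(pid, group, df.reset_index(drop=True), sub)

    return {"A": _mk("A", sentinel), "B": _mk("B", group_b),
            "C": _mk("C", group_c), "D": _mk("D", group_d)}


def ld_from_dosages(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation (r) matrix from a samples x SNPs dosage table."""
    r = np.corrcoef(dosages.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(r, index=dosages.columns, columns=dosages.columns)
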