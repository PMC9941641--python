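"""GWAS summary-statistics data model, I/O, allele harmonization, and
fixed-effect inverse-variance meta-analysis.

Summary statistics are held as :class:`pandas.DataFrame` objects with the
canonical columns in :data:`CANONICAL_COLUMNS`; one row is one SNP's
association with one trait (alleles, effect-allele frequency, additive
per-allele effect ``beta`` — a log odds ratio for case-control traits —
its standard error, p-value and sample size).  All genomic coordinates are
GRCh37, 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "ConfigurationError",
    "InputError",
    "TraitMeta",
    "Region",
    "read_sumstats",
    "validate_sumstats",
    "write_sumstats",
    "is_palindromic",
    "harmonize",
    "meta_analyze",
]

#: canonical in-memory column order
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_cases",
]

#: default source-file column names (configurable via ``column_map``)
DEFAULT_COLUMN_MAP = {
    "SNP": "snp_id", "CHR": "chrom", "POS": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pval", "N": "n",
}

_MANDATORY = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pval", "n"]

_ALLELES = frozenset("ACGT")

#: z beyond which the two-sided normal p-value underflows double precision,
#: making a z-vs-p cross-check meaningless
_Z_SATURATION = 37.0


class ConfigurationError(ValueError):
    """A column mapping or configuration problem."""


class InputError(ValueError):
    """Input data that cannot be analyzed."""


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one trait's GWAS (and, for proteins, its gene)."""

    trait_id: str
    trait_type: str = "quantitative"  # "quantitative" | "case_control"
    n: int | None = None
    n_cases: int | None = None
    uniprot_id: str | None = None
    gene: str | None = None
    gene_chrom: str | None = None
    gene_tss: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control":
            if self.n_cases is None or self.n is None or not (0 < self.n_cases < self.n):
                raise ConfigurationError(
                    "case_control traits require 0 < n_cases < n "
                    f"(got n_cases={self.n_cases}, n={self.n})"
                )

    @property
    def case_fraction(self) -> float | None:
        if self.trait_type == "case_control":
            return self.n_cases / self.n
        return None


@dataclass(frozen=True)
class Region:
    """Closed genomic interval, GRCh37, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> np.ndarray | bool:
        """Vectorized membership test for ``chrom``/``pos`` arrays."""
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)


def _normalize_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def validate_sumstats(df: pd.DataFrame, z_p_rtol: float = 0.1,
                      z_abs_tol: float = 0.2) -> tuple[pd.DataFrame, dict]:
    """Apply row-level validity rules; return (valid rows, drop counts).

    Rules: alleles are single A/C/G/T bases and differ; ``se > 0``;
    ``0 < pval <= 1``; ``eaf`` (if present) strictly inside (0, 1);
    ``n > 0``; and ``|beta/se|`` must be consistent with the reported
    p-value under a two-sided normal, within ``z_p_rtol`` relative on the
    z scale (with an absolute floor of ``z_abs_tol`` so that rounded
    near-null p-values are not rejected).  The z/p check is skipped where
    the p-value saturates double precision.
    """
    counts: dict[str, int] = {}
    n0 = len(df)
    df = df.copy()
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    ea, oa = df["effect_allele"], df["other_allele"]
    ok = ea.isin(_ALLELES) & oa.isin(_ALLELES) & (ea != oa)
    counts["bad_alleles"] = int((~ok).sum())
    df = df[ok]

    num_ok = (
        (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["n"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
        & df["beta"].notna()
    )
    counts["bad_numeric"] = int((~num_ok).sum())
    df = df[num_ok]

    z_obs = (df["beta"].abs() / df["se"]).to_numpy()
    z_p = stats.norm.isf(np.clip(df["pval"].to_numpy(), 1e-300, 1.0) / 2.0)
    scale = np.maximum(z_obs, z_p)
    tol = np.maximum(z_p_rtol * scale, z_abs_tol)
    consistent = (np.abs(z_obs - z_p) <= tol) | (scale > _Z_SATURATION)
    counts["zp_inconsistent"] = int((~consistent).sum())
    df = df[consistent]

    counts["total_dropped"] = n0 - len(df)
    return df.reset_index(drop=True), counts


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_meta: TraitMeta | None = None,
                  z_p_rtol: float = 0.1) -> pd.DataFrame:
    """Read a delimited summary-statistics table into canonical form.

    ``column_map`` maps source column names to canonical field names
    (default :data:`DEFAULT_COLUMN_MAP`).  Rows violating record
    invariants are dropped; per-rule counts are logged and stored in
    ``df.attrs["drop_counts"]``.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    missing = [src for src, dst in column_map.items()
               if dst in _MANDATORY and src not in raw.columns]
    # n may instead come from trait_meta
    missing = [m for m in missing
               if not (column_map[m] == "n" and trait_meta and trait_meta.n)]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")

    df = raw.rename(columns=column_map)
    if "n" not in df.columns and trait_meta and trait_meta.n:
        df["n"] = trait_meta.n
    for opt in ("eaf", "n_cases"):
        if opt not in df.columns:
            df[opt] = np.nan
    if "n_cases" in df.columns and df["n_cases"].isna().all() and trait_meta \
            and trait_meta.n_cases:
        df["n_cases"] = trait_meta.n_cases
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]

    df, counts = validate_sumstats(df, z_p_rtol=z_p_rtol)
    if len(df) == 0:
        raise InputError(f"no valid rows in {path}")
    if counts["total_dropped"]:
        log.info("read_sumstats(%s): dropped %d rows (%s)", path,
                 counts["total_dropped"], counts)
    df.attrs["drop_counts"] = counts
    if trait_meta is not None:
        df.attrs["trait_meta"] = trait_meta
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write canonical TSV plus a JSON sidecar with drop counts."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    counts = df.attrs.get("drop_counts", {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(counts, indent=1))


def is_palindromic(ea, oa) -> np.ndarray:
    """A/T or C/G allele pairs — strand cannot be resolved from alleles."""
    ea = np.asarray(ea, dtype=str)
    oa = np.asarray(oa, dtype=str)
    return ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | \
           ((ea == "C") & (oa == "G")) | ((ea == "G") & (oa == "C"))


def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise InputError(
            f"duplicate snp_id in {label}: {sorted(df.loc[dup, 'snp_id'].unique())[:5]}"
        )


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_palindromic: bool = True) -> pd.DataFrame:
    """Match exposure and outcome records by SNP and align outcome effects
    to the exposure's effect allele.

    When the outcome's effect/other alleles are swapped relative to the
    exposure, the outcome beta is negated and its frequency replaced by
    ``1 - eaf`` (action ``flipped``).  Allele sets that cannot be
    reconciled are dropped, as are palindromic (A/T, C/G) SNPs when
    ``drop_palindromic`` is true; dropped pairs never reach downstream
    estimators.  Returns one row per retained pair with ``_exp``/``_out``
    suffixed statistics, a ``palindromic`` flag and the ``action`` taken.
    """
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    m = exposure.merge(outcome, on="snp_id", suffixes=("_exp", "_out"), how="inner")
    if len(m) == 0:
        return _empty_pairs()

    same = (m["effect_allele_exp"] == m["effect_allele_out"]) & \
           (m["other_allele_exp"] == m["other_allele_out"])
    swapped = (m["effect_allele_exp"] == m["other_allele_out"]) & \
              (m["other_allele_exp"] == m["effect_allele_out"])
    pal = is_palindromic(m["effect_allele_exp"], m["other_allele_exp"])

    action = np.where(same, "none", np.where(swapped, "flipped", "dropped"))
    if drop_palindromic:
        action = np.where(pal, "dropped", action)

    beta_out = np.where(swapped, -m["beta_out"], m["beta_out"])
    eaf_out = np.where(swapped, 1.0 - m["eaf_out"], m["eaf_out"])

    out = pd.DataFrame({
        "snp_id": m["snp_id"],
        "chrom": m["chrom_exp"],
        "pos": m["pos_exp"],
        "effect_allele": m["effect_allele_exp"],
        "other_allele": m["other_allele_exp"],
        "beta_exp": m["beta_exp"], "se_exp": m["se_exp"],
        "pval_exp": m["pval_exp"], "eaf_exp": m["eaf_exp"],
        "beta_out": beta_out, "se_out": m["se_out"],
        "pval_out": m["pval_out"], "eaf_out": eaf_out,
        "n_exp": m["n_exp"], "n_out": m["n_out"],
        "palindromic": pal, "action": action,
    })
    n_dropped = int((action == "dropped").sum())
    out = out[out["action"] != "dropped"].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def _empty_pairs() -> pd.DataFrame:
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "pval_exp", "eaf_exp",
            "beta_out", "se_out", "pval_out", "eaf_out",
            "n_exp", "n_out", "palindromic", "action"]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    df.attrs["n_dropped"] = 0
    return df


def meta_analyze(records_per_study: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance pooling of per-study summary statistics.

    Per SNP: ``beta* = sum(b_i/se_i^2) / sum(1/se_i^2)``,
    ``se* = sum(1/se_i^2)^(-1/2)``; sample sizes summed; p-value from
    ``z = beta*/se*``.  Alleles are assumed harmonized to the first
    study's orientation.  SNPs present in only one study are passed
    through unchanged and flagged ``single_study``.
    """
    if len(records_per_study) < 1:
        raise InputError("meta_analyze requires at least one study")
    stacked = pd.concat(records_per_study, keys=range(len(records_per_study)),
                        names=["study"]).reset_index(level=0)
    w = 1.0 / stacked["se"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["beta"])
    agg = stacked.groupby("snp_id", sort=False).agg(
        _w=("_w", "sum"), _wb=("_wb", "sum"), n=("n", "sum"),
        k=("beta", "size"),
    )
    beta = agg["_wb"] / agg["_w"]
    se = 1.0 / np.sqrt(agg["_w"])
    z = beta / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    # carry positional/allele metadata from the first study seen per SNP
    meta_cols = stacked.drop_duplicates("snp_id").set_index("snp_id")
    out = pd.DataFrame({
        "snp_id": agg.index,
        "chrom": meta_cols.loc[agg.index, "chrom"].values,
        "pos": meta_cols.loc[agg.index, "pos"].values,
        "effect_allele": meta_cols.loc[agg.index, "effect_allele"].values,
        "other_allele": meta_cols.loc[agg.index, "other_allele"].values,
        "eaf": meta_cols.loc[agg.index, "eaf"].values,
        "beta": beta.values, "se": se.values, "pval": pval,
        "n": agg["n"].values,
        "single_study": (agg["k"] == 1).values,
    })
    # pass single-study SNPs through untouched (no pooling artifacts)
    single = out["single_study"].to_numpy()
    if single.any():
        orig = meta_cols.loc[out.loc[single, "snp_id"]]
        for col in ("beta", "se", "pval", "n"):
            out.loc[single, col] = orig[col].values
    return out.reset_index(drop=True)
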