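"""Plain-text round-trip of a full pipeline input bundle.

A bundle directory holds ``pqtls.tsv``, ``annotations.tsv``,
``outcome_discovery.tsv``, ``outcome_replication.tsv``, one dense LD
matrix per protein under ``ld/``, and (for simulated bundles) the
``truth.tsv`` ground-truth table, which the analysis never reads.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import ProteomeSim, SimConfig

__all__ = ["save_bundle", "load_bundle"]

_TABLES = ("pqtls", "annotations", "outcome_discovery", "outcome_replication")


def save_bundle(sim: ProteomeSim, out_dir) -> Path:
    out = Path(out_dir)
    (out / "ld").mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(sim, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for pid, ld in sim.ld.items():
        ld.to_csv(out / "ld" / f"{pid}.tsv", sep="\t")
    return out


def load_bundle(in_dir) -> ProteomeSim:
    src = Path(in_dir)
    tables = {}
    for name in _TABLES:
        df = pd.read_csv(src / f"{name}.tsv", sep="\t",
                         dtype={"chrom": str, "gene_chrom": str})
        tables[name] = df
    ld = {}
    for path in sorted((src / "ld").glob("*.tsv")):
        ld[path.stem] = pd.read_csv(path, sep="\t", index_col=0)
    truth_path = src / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() \
        else pd.DataFrame()
    return ProteomeSim(pqtls=tables["pqtls"], annotations=tables["annotations"],
                       outcome_discovery=tables["outcome_discovery"],
                       outcome_replication=tables["outcome_replication"],
                       ld=ld, truth=truth, config=SimConfig())
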