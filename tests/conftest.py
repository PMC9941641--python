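import numpy as np
import pandas as pd
import pytest


def make_sumstats(rows, **common):
    """Build a canonical summary-statistics frame from terse row tuples:
    (snp_id, chrom, pos, ea, oa, beta, se) with consistent p-values."""
    from scipy import stats

    recs = []
    for snp, chrom, pos, ea, oa, beta, se in rows:
        rec = {
            "snp_id": snp, "chrom": str(chrom), "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": 0.3,
            "beta": beta, "se": se,
            "pval": max(2 * stats.norm.sf(abs(beta / se)), 1e-300),
            "n": 10_000, "n_cases": np.nan,
        }
        rec.update(common)
        recs.append(rec)
    return pd.DataFrame(recs)


def make_pairs(bx, sx, by, sy, snp_ids=None):
    """Harmonized-pairs frame straight from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    L = len(bx)
    return pd.DataFrame({
        "snp_id": snp_ids or [f"s{i}" for i in range(L)],
        "beta_exp": bx, "se_exp": np.broadcast_to(np.asarray(sx, float), (L,)),
        "beta_out": np.asarray(by, dtype=float),
        "se_out": np.broadcast_to(np.asarray(sy, float), (L,)),
        "n_exp": 30_000, "n_out": 20_000,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20230207)


@pytest.fixture(scope="session")
def proteome_sim():
    """One moderate synthetic proteome shared by pipeline-level tests."""
    import protmr as pm

    return pm.simulate_proteome(pm.SimConfig(seed=11), n_proteins=40,
                                n_causal=3, n_confounded=1,
                                causal_thetas=(-1.2, -1.0, 0.9))
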