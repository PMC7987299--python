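"""Shared fixtures: small simulated loci reused across test modules."""

import numpy as np
import pytest

from twaskit import (GwasSummary, LdMatrix, SimulationConfig, simulate_locus)

import pandas as pd


@pytest.fixture(scope="session")
def mediated_locus():
    """A mediated-architecture locus with a clear ER+ signal."""
    cfg = SimulationConfig(
        n_ref_individuals=400, n_snps=60, n_causal_eqtl=4, h2_cis=0.4,
        ld_rho=0.6, alpha_pos=0.15, alpha_neg=0.0, architecture="mediated",
        seed=11)
    panel, expr, truth, scans = simulate_locus(cfg)
    return cfg, panel, expr, truth, scans


@pytest.fixture(scope="session")
def null_locus():
    """A null-architecture locus (no SNP-disease effects anywhere)."""
    cfg = SimulationConfig(
        n_ref_individuals=300, n_snps=40, n_causal_eqtl=3, h2_cis=0.3,
        ld_rho=0.5, alpha_pos=0.0, alpha_neg=0.0, architecture="null", seed=7)
    panel, expr, truth, scans = simulate_locus(cfg)
    return cfg, panel, expr, truth, scans


def make_gwas(snp_ids, z, scan_label="overall", a1=None, a2=None, n=10000,
              chrom="1", bp=None):
    """Construct a GwasSummary directly from arrays (test helper)."""
    m = len(snp_ids)
    t = pd.DataFrame({
        "SNP": list(snp_ids),
        "CHR": [chrom] * m,
        "BP": bp if bp is not None else np.arange(1, m + 1) * 1000,
        "A1": a1 if a1 is not None else ["A"] * m,
        "A2": a2 if a2 is not None else ["G"] * m,
        "Z": np.asarray(z, dtype=float),
        "N": n,
    })
    return GwasSummary(table=t, scan_label=scan_label)


def make_ld(snp_ids, values, lam=0.0):
    return LdMatrix(snp_ids=list(snp_ids), values=np.asarray(values, float), lam=lam)
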