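"""Synthetic genotype panels, cis-heritable expression and subtype GWAS scans.

Every downstream stage of the toolkit (heritability screening, weight
training, TWAS, case-only and conditional analyses) is exercised against
data generated here with known truth: which SNPs are causal for expression,
what the cis-heritability is, and what each scan's expected z-scores are.

The generative model:

* Diploid genotypes arise from two haplotypes per individual.  Each
  haplotype is a latent first-order autoregressive Gaussian process along
  the chromosome, thresholded at the per-SNP minor-allele-frequency
  quantile, so adjacent SNPs show tunable linkage disequilibrium that
  decays geometrically with distance (in SNP index).
* Expression is a linear function of standardized causal dosages plus
  Gaussian noise, with the genetic/noise variance split fixed at
  ``h2_cis`` / ``1 - h2_cis`` in the generated sample.
* GWAS summary statistics are simulated directly at the z-score level:
  each scan's z-vector is multivariate normal with covariance equal to the
  panel LD matrix and mean ``sqrt(N_eff) * Sigma @ b``, where ``b`` are the
  joint standardized SNP effects implied by the genetic architecture.

Four scans are produced per locus: overall case-control, ER+ vs controls,
ER- vs controls, and the case-only ER+ vs ER- contrast.  The case-only
z is oriented so the effect allele increases the odds of ER- relative to
ER+ disease; its mean is therefore proportional to ``alpha_neg -
alpha_pos`` projected through the SNP-expression correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io import GenotypePanel, GwasSummary

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotype_panel",
    "simulate_expression",
    "simulate_subtype_gwas",
    "simulate_locus",
]

ARCHITECTURES = ("mediated", "pleiotropic", "colocalized", "null")

#: substreams of the master seed, one per generation stage
_PANEL_STREAM, _EXPR_STREAM, _GWAS_STREAM = 0, 1, 2

# non strand-ambiguous allele pairs (ambiguous = A/T or C/G)
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cis locus.

    Defaults emulate a desk-scale version of the design the toolkit
    targets: a small expression reference panel (tens to hundreds of
    individuals), a cis window of a few hundred SNPs, moderate
    cis-heritability, and subtype case counts with the ER+ subtype about
    three times the size of ER-.
    """

    n_ref_individuals: int = 500
    n_gwas_cases_pos: int = 69501
    n_gwas_cases_neg: int = 21468
    n_gwas_controls: int = 105974
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.7
    n_causal_eqtl: int = 5
    h2_cis: float = 0.3
    alpha_pos: float = 0.0
    alpha_neg: float = 0.0
    architecture: str = "mediated"
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.h2_cis <= 1.0:
            raise ValueError(f"h2_cis must lie in [0, 1], got {self.h2_cis}")
        for name in ("n_ref_individuals", "n_gwas_cases_pos", "n_gwas_cases_neg",
                     "n_gwas_controls", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.n_causal_eqtl > self.n_snps:
            raise ValueError("n_causal_eqtl cannot exceed n_snps")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}")
        if self.architecture == "null" and (self.alpha_pos != 0.0 or self.alpha_neg != 0.0):
            raise ValueError("architecture='null' requires alpha_pos = alpha_neg = 0")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    @property
    def n_eff(self) -> dict[str, float]:
        """Effective sample size per scan (harmonic 4/(1/n1 + 1/n2))."""
        ncase = self.n_gwas_cases_pos + self.n_gwas_cases_neg

        def eff(a: int, b: int) -> float:
            return 4.0 / (1.0 / a + 1.0 / b)

        return {
            "overall": eff(ncase, self.n_gwas_controls),
            "er_pos": eff(self.n_gwas_cases_pos, self.n_gwas_controls),
            "er_neg": eff(self.n_gwas_cases_neg, self.n_gwas_controls),
            "case_only": eff(self.n_gwas_cases_pos, self.n_gwas_cases_neg),
        }


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated locus."""

    causal_snp_indices: np.ndarray
    true_weights: np.ndarray          # per-SNP effect on expression, standardized scale
    realized_h2: float
    expected_z: dict[str, np.ndarray] = field(default_factory=dict)
    direct_snp_index: int | None = None   # pleiotropic/colocalized direct-effect SNP


def simulate_genotype_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw a diploid reference genotype panel with AR(1)-style LD.

    Haplotypes are thresholded latent Gaussian AR(1) series: the latent
    correlation between SNPs ``j`` and ``k`` is ``ld_rho ** |j - k|``, so
    allelic correlation decays geometrically along the chromosome.
    Positions increase strictly on a single chromosome.
    """
    rng = config._rng(_PANEL_STREAM)
    n, m = config.n_ref_individuals, config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(maf)

    rho = config.ld_rho
    eps = rng.standard_normal((2 * n, m))
    latent = np.empty_like(eps)
    latent[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        latent[:, j] = rho * latent[:, j - 1] + scale * eps[:, j]
    alleles = (latent < thresh).astype(np.int8)   # 1 = minor allele
    dosages = alleles[:n] + alleles[n:]

    positions = 1_000_000 + np.cumsum(rng.integers(100, 2000, size=m))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    freq = dosages.mean(axis=0) / 2.0
    emp_maf = np.minimum(freq, 1.0 - freq)
    snp_ids = [f"rs{config.seed}_{j}" for j in range(m)]
    ind_ids = [f"ind{i}" for i in range(n)]
    return GenotypePanel.from_arrays(
        individual_ids=ind_ids,
        snp_ids=snp_ids,
        chrom=config.chrom,
        positions=positions,
        effect_alleles=a1,
        other_alleles=a2,
        maf=emp_maf,
        dosages=dosages.astype(np.int8),
    )


def _standardize(dosages: np.ndarray) -> np.ndarray:
    z = dosages.astype(float)
    z -= z.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    return z / sd


def simulate_expression(
    panel: GenotypePanel, config: SimulationConfig
) -> tuple[np.ndarray, SimulationTruth]:
    """Simulate a gene's expression with a cis-genetic component.

    The linear predictor over standardized causal dosages is rescaled so
    that its sample variance is exactly ``h2_cis`` and Gaussian noise with
    variance ``1 - h2_cis`` is added; the variance fractions therefore
    equal the configured split up to the noise draw.
    """
    rng = config._rng(_EXPR_STREAM)
    m = panel.n_snps
    if config.n_causal_eqtl > m:
        raise ValueError("n_causal_eqtl exceeds the panel's SNP count")
    causal = np.sort(rng.choice(m, size=config.n_causal_eqtl, replace=False))
    weights = np.zeros(m)
    h2 = config.h2_cis

    Z = _standardize(panel.dosages)
    if h2 > 0:
        raw = rng.standard_normal(config.n_causal_eqtl)
        g = Z[:, causal] @ raw
        gvar = g.var()
        if gvar <= 0:
            raise ValueError("degenerate genetic component (monomorphic causal SNPs?)")
        raw *= np.sqrt(h2 / gvar)
        weights[causal] = raw
        g = Z[:, causal] @ raw
    else:
        g = np.zeros(panel.n_individuals)

    noise = rng.standard_normal(panel.n_individuals) * np.sqrt(max(1.0 - h2, 0.0)) \
        if h2 < 1.0 else np.zeros(panel.n_individuals)
    expr = g + noise

    tot = expr.var()
    realized = float(g.var() / tot) if tot > 0 else 0.0
    truth = SimulationTruth(
        causal_snp_indices=causal,
        true_weights=weights,
        realized_h2=realized,
    )
    _attach_expected_z(panel, truth, config)
    return expr, truth


def _joint_disease_effects(
    panel: GenotypePanel, truth: SimulationTruth, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Joint (not marginal) standardized SNP effects on each scan's trait."""
    m = panel.n_snps
    w = truth.true_weights
    arch = config.architecture
    a_pos, a_neg = config.alpha_pos, config.alpha_neg
    ncase = config.n_gwas_cases_pos + config.n_gwas_cases_neg
    a_all = (config.n_gwas_cases_pos * a_pos + config.n_gwas_cases_neg * a_neg) / ncase

    base = {"overall": a_all * w, "er_pos": a_pos * w, "er_neg": a_neg * w,
            "case_only": (a_neg - a_pos) * w}
    if arch == "null":
        return {k: np.zeros(m) for k in base}
    if arch == "mediated":
        return base

    # direct (non-expression-mediated) effect for pleiotropic/colocalized loci
    direct = np.zeros(m)
    scale = np.sqrt(config.h2_cis) if config.h2_cis > 0 else 1.0
    if arch == "pleiotropic":
        noncausal = np.setdiff1d(np.arange(m), truth.causal_snp_indices)
        idx = int(noncausal[len(noncausal) // 2]) if noncausal.size else 0
    else:  # colocalized: independent causal SNP adjacent to (in LD with) an eQTL
        lead = int(truth.causal_snp_indices[0]) if truth.causal_snp_indices.size else 0
        idx = lead + 1 if lead + 1 < m else lead - 1
    truth.direct_snp_index = idx
    direct[idx] = 1.0
    if arch == "colocalized":
        # all SNP-disease signal routed through the colocalized SNP, none
        # through expression
        return {
            "overall": a_all * scale * direct,
            "er_pos": a_pos * scale * direct,
            "er_neg": a_neg * scale * direct,
            "case_only": (a_neg - a_pos) * scale * direct,
        }
    return {
        "overall": base["overall"] + a_all * scale * direct,
        "er_pos": base["er_pos"] + a_pos * scale * direct,
        "er_neg": base["er_neg"] + a_neg * scale * direct,
        "case_only": base["case_only"] + (a_neg - a_pos) * scale * direct,
    }


def _attach_expected_z(
    panel: GenotypePanel, truth: SimulationTruth, config: SimulationConfig
) -> None:
    sigma = np.corrcoef(_standardize(panel.dosages), rowvar=False)
    sigma = np.atleast_2d(sigma)
    effects = _joint_disease_effects(panel, truth, config)
    n_eff = config.n_eff
    truth.expected_z = {
        scan: np.sqrt(n_eff[scan]) * sigma @ b for scan, b in effects.items()
    }


def simulate_subtype_gwas(
    panel: GenotypePanel, truth: SimulationTruth, config: SimulationConfig
) -> dict[str, GwasSummary]:
    """Draw the four GWAS scans (overall, ER+, ER-, case-only) at z level.

    Each scan's z-vector is multivariate normal with mean recorded in
    ``truth.expected_z`` and covariance equal to the panel LD matrix; the
    scans are drawn independently given the LD.
    """
    if config.architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {config.architecture!r}")
    if truth.true_weights.shape[0] != panel.n_snps:
        raise ValueError("truth is inconsistent with the panel")
    rng = config._rng(_GWAS_STREAM)
    sigma = np.corrcoef(_standardize(panel.dosages), rowvar=False)
    sigma = np.atleast_2d(sigma)
    # tiny ridge keeps the factorization stable for near-singular LD
    chol = np.linalg.cholesky(sigma + 1e-8 * np.eye(panel.n_snps))

    # (re)compute the expected means for this config's alphas and N_eff
    _attach_expected_z(panel, truth, config)

    n_eff = config.n_eff
    sample_n = {
        "overall": config.n_gwas_cases_pos + config.n_gwas_cases_neg + config.n_gwas_controls,
        "er_pos": config.n_gwas_cases_pos + config.n_gwas_controls,
        "er_neg": config.n_gwas_cases_neg + config.n_gwas_controls,
        "case_only": config.n_gwas_cases_pos + config.n_gwas_cases_neg,
    }
    scans = {}
    for scan in ("overall", "er_pos", "er_neg", "case_only"):
        z = truth.expected_z[scan] + chol @ rng.standard_normal(panel.n_snps)
        scans[scan] = GwasSummary.from_panel(panel, z=z, n=sample_n[scan], scan_label=scan)
    return scans


def simulate_locus(
    config: SimulationConfig,
) -> tuple[GenotypePanel, np.ndarray, SimulationTruth, dict[str, GwasSummary]]:
    """Convenience wrapper: panel, expression, truth and all four scans."""
    panel = simulate_genotype_panel(config)
    expr, truth = simulate_expression(panel, config)
    scans = simulate_subtype_gwas(panel, truth, config)
    return panel, expr, truth, scans


def replicate(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
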