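"""Conditional and joint analyses of TWAS genes and regional GWAS SNPs.

All algebra is carried out at the z-score level using the standard
summary-statistics identities for standardized variables:

* a *feature* is a linear combination of SNPs (a gene's predicted
  expression); the correlation between two features j, k with weight
  vectors embedded over the union SNP set is
  ``r_jk = w_j Sigma w_k' / sqrt((w_j Sigma w_j')(w_k Sigma w_k'))``;
* jointly modelling several features with marginal z-vector ``z`` and
  feature-correlation matrix ``R`` gives joint effects ``b = R^-1 z``
  and per-feature joint z ``b_i / sqrt((R^-1)_ii)``;
* a SNP's z conditional on a set of features is
  ``(z_snp - rho' R^-1 z_genes) / sqrt(1 - rho' R^-1 rho)`` where
  ``rho_s = (Sigma w)_s / sqrt(w Sigma w')`` is the SNP-feature
  correlation.

Regions group TWAS genes by transitive closure of a pairwise distance
window (default 500 kb).  Region summaries count genome-wide-significant
SNPs before/after conditioning and report the ratio explained and the
magnitude of change of the minimum p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import LdMatrix, zscore_to_p
from .io import GenotypePanel, GwasSummary
from .weights import WeightModel

__all__ = [
    "Region", "ConditionalSummary", "JointResult",
    "group_regions", "feature_correlation", "joint_gene_analysis",
    "conditional_snp_z", "conditional_region_summary", "conditional_arithmetic",
]


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    gene_ids: list[str]
    snp_ids: list[str] = field(default_factory=list)
    index_snp: str | None = None
    index_p: float = np.nan


@dataclass
class ConditionalSummary:
    gene_id: str
    n_snps: int
    n_sig_before: int
    index_p: float
    n_sig_after: int
    min_conditional_p: float
    ratio: float = np.nan
    magnitude: float = np.nan
    index_snp: str | None = None
    nothing_significant: bool = False

    def __post_init__(self) -> None:
        if np.isnan(self.ratio) or np.isnan(self.magnitude):
            r, m, flag = conditional_arithmetic(
                self.n_sig_before, self.n_sig_after,
                self.index_p, self.min_conditional_p)
            if np.isnan(self.ratio):
                self.ratio = r
            if np.isnan(self.magnitude):
                self.magnitude = m
            self.nothing_significant = flag


def conditional_arithmetic(
    n_sig_before: int, n_sig_after: int, index_p: float, min_conditional_p: float
) -> tuple[float, float, bool]:
    """Ratio explained and p-value change magnitude for one region.

    ratio = (n_sig_before - n_sig_after) / n_sig_before — the proportion
    of marginally genome-wide-significant SNPs that are no longer
    significant after conditioning; when nothing was significant to
    begin with the ratio is reported as 1.0 by convention and flagged.
    magnitude = index_p / min_conditional_p; exactly 1 when the index
    SNP's p-value is unchanged.
    """
    if n_sig_before > 0:
        ratio = (n_sig_before - n_sig_after) / n_sig_before
        flag = False
    else:
        ratio = 1.0
        flag = True
    magnitude = index_p / min_conditional_p
    return float(ratio), float(magnitude), flag


@dataclass
class JointResult:
    gene_ids: list[str]
    marginal_z: np.ndarray
    marginal_p: np.ndarray
    joint_z: np.ndarray
    joint_p: np.ndarray
    retained: np.ndarray            # joint p < retain threshold
    pruned: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids, "marginal_z": self.marginal_z,
            "marginal_p": self.marginal_p, "joint_z": self.joint_z,
            "joint_p": self.joint_p, "retained": self.retained})


def group_regions(
    genes: pd.DataFrame, window: int = 500_000
) -> list[Region]:
    """Merge genes into regions by transitive closure of the distance window.

    ``genes`` needs columns gene_id, chrom, start, end (1-based,
    inclusive).  Two genes chain into one region when their interval
    distance is at most ``window``; chromosomes never merge.  Regions are
    returned sorted by (chromosome, start).
    """
    regions: list[Region] = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur: Region | None = None
        cur_end = -np.inf
        for rec in sub.itertuples(index=False):
            if cur is not None and rec.start - cur_end <= window:
                cur.gene_ids.append(rec.gene_id)
                cur.end = max(cur.end, int(rec.end))
                cur_end = max(cur_end, rec.end)
            else:
                cur = Region(chrom=str(chrom), start=int(rec.start),
                             end=int(rec.end), gene_ids=[rec.gene_id])
                regions.append(cur)
                cur_end = rec.end
        # (sweep over sorted starts realizes the transitive closure)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _embed(weights: WeightModel, union_snps: list[str]) -> np.ndarray:
    w = np.zeros(len(union_snps))
    lookup = {s: x for s, x in zip(weights.snp_ids, weights.weights)}
    for i, s in enumerate(union_snps):
        if s in lookup:
            w[i] = lookup[s]
    return w


def feature_correlation(
    w_j: np.ndarray, w_k: np.ndarray, ld: LdMatrix
) -> float:
    """Correlation of two predicted-expression features under the LD matrix."""
    S = ld.values
    vj = float(w_j @ S @ w_j)
    vk = float(w_k @ S @ w_k)
    if vj <= 0 or vk <= 0:
        raise ValueError("zero-variance feature")
    return float(w_j @ S @ w_k / np.sqrt(vj * vk))


def feature_correlation_matrix(
    weight_models: list[WeightModel], ld: LdMatrix
) -> np.ndarray:
    union = ld.snp_ids
    W = np.column_stack([_embed(wm, union) for wm in weight_models])
    S = ld.values
    cov = W.T @ S @ W
    sd = np.sqrt(np.diag(cov))
    if (sd <= 0).any():
        raise ValueError("zero-variance feature")
    R = cov / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def joint_gene_analysis(
    marginal_z: np.ndarray,
    R: np.ndarray,
    gene_ids: list[str] | None = None,
    prune_r: float = 0.95,
    retain_p: float = 0.05,
    ridge_eps: float = 1e-6,
) -> JointResult:
    """Jointly model several TWAS genes from their marginal z-scores.

    Near-collinear features (|r| > ``prune_r``) are collapsed, keeping
    the smallest marginal p per collinear group; joint effects solve the
    normal equations ``b = R^-1 z`` and each gene's joint z is
    ``b_i / sqrt((R^-1)_ii)``.  Pruned genes carry NaN joint values.  If
    R is singular after pruning it is ridge-stabilized and a warning
    issued.  ``retained`` flags joint p < ``retain_p``.
    """
    z = np.asarray(marginal_z, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    g = z.shape[0]
    if R.shape != (g, g):
        raise ValueError("R must be square and match the z vector")
    if not np.allclose(R, R.T, atol=1e-8) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must be symmetric with unit diagonal")
    ids = list(gene_ids) if gene_ids is not None else [f"gene{i}" for i in range(g)]

    # collapse collinear features: greedy by ascending marginal p
    order = np.argsort(zscore_to_p(z))
    keep: list[int] = []
    for i in order:
        if all(abs(R[i, j]) <= prune_r for j in keep):
            keep.append(int(i))
    keep = sorted(keep)
    pruned = [ids[i] for i in range(g) if i not in keep]

    Rk = R[np.ix_(keep, keep)]
    zk = z[keep]
    try:
        Ri = np.linalg.inv(Rk)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn(
            f"feature-correlation matrix singular after pruning; "
            f"ridge-stabilizing with eps={ridge_eps}")
        Ri = np.linalg.inv(Rk + ridge_eps * np.eye(len(keep)))
    b = Ri @ zk
    jz = b / np.sqrt(np.diag(Ri))

    joint_z = np.full(g, np.nan)
    joint_p = np.full(g, np.nan)
    retained = np.zeros(g, dtype=bool)
    for pos, i in enumerate(keep):
        joint_z[i] = jz[pos]
        joint_p[i] = zscore_to_p(jz[pos])
        retained[i] = joint_p[i] < retain_p
    return JointResult(gene_ids=ids, marginal_z=z,
                       marginal_p=np.asarray(zscore_to_p(z)),
                       joint_z=joint_z, joint_p=joint_p,
                       retained=retained, pruned=pruned)


def conditional_snp_z(
    z_snp: float,
    rho: np.ndarray,
    R: np.ndarray,
    z_genes: np.ndarray,
) -> tuple[float, bool]:
    """A SNP's z-score conditional on a set of predicted-expression features.

    Returns ``(z_cond, fully_explained)``; when the SNP is (numerically)
    a linear combination of the features — ``1 - rho' R^-1 rho <= 0`` —
    the conditional z is undefined, the flag is set and 0 is returned
    (conditional p = 1).
    """
    rho = np.asarray(rho, dtype=float).ravel()
    R = np.atleast_2d(np.asarray(R, dtype=float))
    zg = np.asarray(z_genes, dtype=float).ravel()
    if np.abs(rho).max(initial=0.0) > 1.0 + 1e-8:
        raise ValueError("SNP-feature correlations must lie in [-1, 1]")
    Ri = np.linalg.inv(R)
    denom = 1.0 - float(rho @ Ri @ rho)
    if denom <= 1e-12:
        return 0.0, True
    return float((z_snp - rho @ Ri @ zg) / np.sqrt(denom)), False


def snp_feature_correlations(
    weight_models: list[WeightModel], ld: LdMatrix
) -> np.ndarray:
    """Per-SNP correlation with each gene feature: (Sigma w)_s / sqrt(w Sigma w')."""
    union = ld.snp_ids
    S = ld.values
    cols = []
    for wm in weight_models:
        w = _embed(wm, union)
        var = float(w @ S @ w)
        if var <= 0:
            raise ValueError(f"zero-variance feature for gene {wm.gene_id}")
        cols.append(S @ w / np.sqrt(var))
    return np.column_stack(cols)


def conditional_region_summary(
    region: Region,
    gwas: GwasSummary,
    weight_models: list[WeightModel],
    panel: GenotypePanel,
    ld: LdMatrix,
    gw_threshold: float = 5e-8,
) -> tuple[ConditionalSummary, pd.DataFrame]:
    """Condition every region SNP on the region's gene(s) and summarize.

    Returns the summary plus a per-SNP track (marginal and conditional z
    and p) suitable for BED-style output.  The index SNP is the smallest
    marginal p in the region.
    """
    snps = [s for s in ld.snp_ids if s in set(gwas.table["SNP"])]
    if not snps:
        raise ValueError("no harmonized region SNPs available")
    z = gwas.z_for(snps)
    p_marg = np.asarray(zscore_to_p(z))

    R = feature_correlation_matrix(weight_models, ld)
    rho_all = snp_feature_correlations(weight_models, ld)
    idx_of = {s: i for i, s in enumerate(ld.snp_ids)}

    z_genes = np.empty(len(weight_models))
    for k, wm in enumerate(weight_models):
        w = _embed(wm, ld.snp_ids)
        z_genes[k] = float(w @ gwas.z_for(ld.snp_ids)) / np.sqrt(float(w @ ld.values @ w))

    z_cond = np.empty(len(snps))
    p_cond = np.empty(len(snps))
    for i, s in enumerate(snps):
        zc, explained = conditional_snp_z(z[i], rho_all[idx_of[s]], R, z_genes)
        z_cond[i] = zc
        p_cond[i] = 1.0 if explained else float(zscore_to_p(zc))

    i_index = int(np.argmin(p_marg))
    n_before = int((p_marg < gw_threshold).sum())
    n_after = int((p_cond < gw_threshold).sum())
    summary = ConditionalSummary(
        gene_id=",".join(wm.gene_id for wm in weight_models),
        n_snps=len(snps), n_sig_before=n_before,
        index_p=float(p_marg[i_index]), n_sig_after=n_after,
        min_conditional_p=float(p_cond.min()), index_snp=snps[i_index])
    pos = gwas.table.set_index("SNP").loc[snps]
    track = pd.DataFrame({
        "chrom": pos["CHR"].to_numpy(), "start": pos["BP"].to_numpy() - 1,
        "end": pos["BP"].to_numpy(), "snp": snps,
        "z_marginal": z, "z_conditional": z_cond,
        "p_marginal": p_marg, "p_conditional": p_cond})
    return summary, track
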