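"""Case-only TWAS: subtype-heterogeneity testing and gene classification.

Applying the TWAS statistic to a case-only GWAS (ER+ cases contrasted
directly with ER- cases) tests the null that the expression log-odds
effects on the two subtypes are equal, H0: beta_neg - beta_pos = 0 — the
same contrast a multinomial subtype-risk model would estimate.  The
case-only z is oriented so a positive value means the effect allele
raises the odds of ER- relative to ER+ disease.

Genes are then classified from the four scan p-values: a gene is
subtype-specific when the case-only heterogeneity test and exactly one
subtype scan are significant; shared when both subtype scans are
significant without heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

from .association import LdMatrix, TwasResult, twas_z
from .io import GwasSummary
from .weights import WeightModel

__all__ = ["SubtypeCall", "case_only_test", "classify_subtype", "SUBTYPE_LABELS"]

SUBTYPE_LABELS = ("er_pos_specific", "er_neg_specific", "shared",
                  "heterogeneous_only", "not_significant")


@dataclass
class SubtypeCall:
    gene_id: str
    p_overall: float
    p_pos: float
    p_neg: float
    p_caseonly: float
    label: str


def case_only_test(
    weights: WeightModel, gwas_caseonly: GwasSummary, ld: LdMatrix,
    alpha: float | None = None, n_tests: int = 1,
) -> TwasResult:
    """TWAS statistic on the case-only scan (identical contracts to twas_z)."""
    if gwas_caseonly.scan_label != "case_only":
        raise ValueError("case_only_test expects a case-only scan")
    return twas_z(weights, gwas_caseonly, ld, alpha=alpha, n_tests=n_tests)


def classify_subtype(
    gene_id: str,
    p_overall: float,
    p_pos: float,
    p_neg: float,
    p_caseonly: float,
    threshold: float,
    threshold_pos: float | None = None,
    threshold_neg: float | None = None,
    threshold_caseonly: float | None = None,
) -> SubtypeCall:
    """Deterministic subtype label from the four scan p-values.

    ``er_pos_specific``: heterogeneity and the ER+ scan significant, the
    ER- scan not (``er_neg_specific`` symmetric); ``shared``: both
    subtype scans significant, no heterogeneity; ``heterogeneous_only``:
    only the case-only test significant.  Scan-specific thresholds
    default to the shared one.
    """
    pvals = (p_overall, p_pos, p_neg, p_caseonly)
    if any(p is None or isnan(p) for p in pvals):
        raise ValueError("all four p-values are required")
    t_pos = threshold_pos if threshold_pos is not None else threshold
    t_neg = threshold_neg if threshold_neg is not None else threshold
    t_co = threshold_caseonly if threshold_caseonly is not None else threshold
    sig_pos, sig_neg, sig_co = p_pos < t_pos, p_neg < t_neg, p_caseonly < t_co
    if sig_co and sig_pos and not sig_neg:
        label = "er_pos_specific"
    elif sig_co and sig_neg and not sig_pos:
        label = "er_neg_specific"
    elif sig_pos and sig_neg and not sig_co:
        label = "shared"
    elif sig_co and not sig_pos and not sig_neg:
        label = "heterogeneous_only"
    else:
        label = "not_significant"
    return SubtypeCall(gene_id=gene_id, p_overall=p_overall, p_pos=p_pos,
                       p_neg=p_neg, p_caseonly=p_caseonly, label=label)
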