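"""Classical comparison arm: per-SNP univariate logistic association.

Each panel SNP is tested one at a time with an additive-coding logistic
regression of case status on dosage (Wald two-sided p on the slope), with
family-wise control by Bonferroni across the J tests.  This is the
standard single-marker validation the reconstruction-error method is
compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "fit_univariate",
    "fit_panel",
    "bonferroni_threshold",
    "format_threshold",
    "association_table",
]


@dataclass
class AssociationResult:
    rsid: str
    log_or: float | None
    se: float | None
    p_value: float | None
    significant_nominal: bool
    significant_bonferroni: bool
    flag: str | None = None  # "monomorphic" | "separation" | None


def fit_univariate(
    dosage: np.ndarray,
    labels: np.ndarray,
    rsid: str = "",
    alpha: float = 0.05,
    bonferroni: float | None = None,
) -> AssociationResult:
    """Additive logistic fit of one SNP; Wald two-sided p.

    Monomorphic columns and complete separation are flagged unestimable
    rather than raising, so panel-wide scans always complete.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    if np.ptp(x) == 0:
        return AssociationResult(rsid, None, None, None, False, False, "monomorphic")
    design = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(fit.pvalues[1])
        if not (math.isfinite(beta) and math.isfinite(se) and math.isfinite(p)):
            raise PerfectSeparationError
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssociationResult(rsid, None, None, None, False, False, "separation")
    thr = alpha if bonferroni is None else bonferroni
    return AssociationResult(
        rsid=rsid,
        log_or=beta,
        se=se,
        p_value=p,
        significant_nominal=p < alpha,
        significant_bonferroni=p < thr,
    )


def bonferroni_threshold(alpha: float, j: int) -> float:
    """Per-test threshold alpha / J for J simultaneous tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if j < 1:
        raise ValueError("need at least one test")
    return alpha / j


def format_threshold(threshold: float, decimals: int = 4) -> str:
    """Truncate (not round) for display: 0.05/43 -> '0.0011'."""
    scale = 10**decimals
    return f"{math.floor(threshold * scale) / scale:.{decimals}f}"


def fit_panel(
    X: np.ndarray,
    labels: np.ndarray,
    rsids: Sequence[str],
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Univariate scan over all panel SNPs with Bonferroni control."""
    thr = bonferroni_threshold(alpha, len(rsids))
    return [
        fit_univariate(X[:, k], labels, rsid=rsid, alpha=alpha, bonferroni=thr)
        for k, rsid in enumerate(rsids)
    ]


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in results],
            "logOR": [r.log_or for r in results],
            "SE": [r.se for r in results],
            "p": [r.p_value for r in results],
            "nominal": [r.significant_nominal for r in results],
            "bonferroni": [r.significant_bonferroni for r in results],
            "flag": [r.flag or "" for r in results],
        }
    ).set_index("rsid")


def write_association_tsv(
    results: Sequence[AssociationResult], path: str | Path
) -> None:
    association_table(results).reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
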