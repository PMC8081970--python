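"""Causal-effect estimators on harmonized summary statistics.

Per-variant Wald ratios, fixed-effect inverse-variance-weighted (IVW)
pooling, Cochran's Q heterogeneity, and a multiplicative over-dispersion
variant of IVW. For instrument k with exposure effect X_k (SE sigma_Xk) and
outcome effect Y_k (SE sigma_Yk), the Wald ratio is Y_k/X_k with first-order
SE sigma_Yk/|X_k|; the fixed-effect IVW pooled estimate is

    beta = sum(X_k * Y_k / sigma_Yk^2) / sum(X_k^2 / sigma_Yk^2)
    se   = 1 / sqrt(sum(X_k^2 / sigma_Yk^2))

which is identical to precision-weighting the Wald ratios by 1/se_k^2, and
to an origin-constrained weighted least-squares regression of Y on X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .errors import EstimationError

WALD_SINGLE = "wald_single"
IVW_FIXED = "ivw_fixed"
IVW_SCALED = "ivw_scaled"


@dataclass(frozen=True)
class WaldEstimate:
    """Per-variant causal-effect ratio (log-odds per SD of exposure)."""

    variant_id: str
    ratio: float
    se: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: Wald SE must be positive")


def wald_ratio(pair) -> WaldEstimate:
    """Wald ratio y/x with first-order SE sigma_y/|x|.

    The exposure-side uncertainty is ignored (first-order delta method), so
    the SE understates the truth for weak instruments.
    """
    if pair.x == 0:
        raise EstimationError(f"{pair.variant_id}: exposure effect is 0; Wald ratio undefined")
    return WaldEstimate(
        variant_id=pair.variant_id,
        ratio=pair.y / pair.x,
        se=pair.sigma_y / abs(pair.x),
    )


def or_ci(beta: float, se: float, level: float = 0.95):
    """Odds ratio, normal confidence interval, and two-sided p for a log-odds beta.

    Returns ``(or_point, ci_low, ci_high, p_value)``.
    """
    if not 0 < level < 1:
        raise EstimationError(f"confidence level must be in (0, 1), got {level}")
    if se <= 0:
        raise EstimationError(f"se must be positive, got {se}")
    z = norm.ppf((1 + level) / 2)
    p = 2 * float(norm.sf(abs(beta) / se))
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se), min(p, 1.0)


def cochran_q(estimates, pooled_beta: float):
    """Cochran's Q over Wald ratios around the pooled estimate.

    Q = sum w_k (ratio_k - pooled)^2 with w_k = 1/se_k^2 (equivalently
    X_k^2/sigma_Yk^2); chi-square with k-1 df under homogeneity.
    Returns ``(q, q_df, q_p)``.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    ratios = np.array([e.ratio for e in estimates])
    weights = np.array([1 / e.se**2 for e in estimates])
    q = float(np.sum(weights * (ratios - pooled_beta) ** 2))
    q_df = len(estimates) - 1
    return q, q_df, float(chi2.sf(q, q_df))


@dataclass
class MRResult:
    """Pooled causal estimate for one exposure.

    ``beta``/``se`` are on the log-odds-per-SD scale; ``or_point`` and the
    confidence bounds are exponentiated. ``q``/``q_df``/``q_p`` are None for
    single-instrument results, where heterogeneity is undefined.
    """

    exposure_id: str
    method: str
    n_snp: int
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    significant_bonferroni: bool | None = None

    def __post_init__(self):
        if not (self.ci_low < self.or_point < self.ci_high):
            raise ValueError("confidence bounds must bracket the point estimate")
        if self.q is not None and self.q < -1e-12:
            raise ValueError("Q must be non-negative")

    def conf_int(self):
        return (self.ci_low, self.ci_high)

    def as_dict(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "q": self.q,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "bonferroni_significant": self.significant_bonferroni,
        }

    def summary(self) -> str:
        """Human-readable block, OR/CI rounded to 2 decimals."""
        lines = [
            f"MR estimate: {self.exposure_id or '(unnamed exposure)'}",
            "=" * 46,
            f"method          {self.method}",
            f"n_snp           {self.n_snp}",
            f"beta (log-odds) {self.beta:.4f}",
            f"se              {self.se:.4f}",
            f"OR              {self.or_point:.2f}",
            f"{self.level:.0%} CI          {self.ci_low:.2f}–{self.ci_high:.2f}",
            f"p               {self.p_value:.3g}",
        ]
        if self.q is not None:
            lines.append(f"Q               {self.q:.2f} (df {self.q_df}, p {self.q_p:.3g})")
        if self.significant_bonferroni is not None:
            lines.append(f"Bonferroni sig. {self.significant_bonferroni}")
        return "\n".join(lines)


def ivw_fixed(estimates, exposure_id: str = "", level: float = 0.95) -> MRResult:
    """Fixed-effect IVW pooling of Wald estimates.

    With a single estimate this reduces exactly to the Wald ratio.
    Heterogeneity (Q) is reported for two or more instruments.
    """
    estimates = list(estimates)
    if not estimates:
        raise EstimationError("IVW needs at least 1 instrument")
    if len(estimates) == 1:  # exact k=1 reduction to the Wald ratio
        beta, se = estimates[0].ratio, estimates[0].se
    else:
        weights = np.array([1 / e.se**2 for e in estimates])
        ratios = np.array([e.ratio for e in estimates])
        beta = float(np.sum(weights * ratios) / np.sum(weights))
        se = float(1 / math.sqrt(np.sum(weights)))
    orp, lo, hi, p = or_ci(beta, se, level)
    q = q_df = q_p = None
    if len(estimates) >= 2:
        q, q_df, q_p = cochran_q(estimates, beta)
    return MRResult(
        exposure_id=exposure_id,
        method=IVW_FIXED,
        n_snp=len(estimates),
        beta=beta,
        se=se,
        or_point=orp,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        level=level,
        q=q,
        q_df=q_df,
        q_p=q_p,
    )


def ivw_scaled(estimates, exposure_id: str = "", level: float = 0.95) -> MRResult:
    """IVW with multiplicative over-dispersion scaling of the SE.

    The fixed-effect SE is inflated by max(1, sqrt(Q/df)), the behaviour of
    weighted regression with a residual variance floored at 1; identical to
    :func:`ivw_fixed` whenever Q/df <= 1.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise EstimationError("over-dispersion scaling needs at least 2 instruments")
    fixed = ivw_fixed(estimates, exposure_id=exposure_id, level=level)
    inflation = max(1.0, math.sqrt(fixed.q / fixed.q_df))
    se = fixed.se * inflation
    orp, lo, hi, p = or_ci(fixed.beta, se, level)
    return MRResult(
        exposure_id=exposure_id,
        method=IVW_SCALED,
        n_snp=fixed.n_snp,
        beta=fixed.beta,
        se=se,
        or_point=orp,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        level=level,
        q=fixed.q,
        q_df=fixed.q_df,
        q_p=fixed.q_p,
    )


def bonferroni_flag(p_values, family_size: int = 6, alpha: float = 0.05) -> list[bool]:
    """Flag i is True iff p_i < alpha/family_size (strict)."""
    if family_size < 1:
        raise EstimationError(f"family_size must be >= 1, got {family_size}")
    threshold = alpha / family_size
    return [p < threshold for p in p_values]
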