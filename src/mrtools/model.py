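"""The statsmodels-style model object for two-sample MR.

Build an :class:`MRModel` from harmonized pairs (or directly from exposure
and outcome records, which are harmonized on the way in); ``fit`` returns an
:class:`~mrtools.estimators.MRResult` carrying the pooled estimate, its
uncertainty, and heterogeneity diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

import pandas as pd

from .errors import EstimationError
from .estimators import (
    IVW_FIXED,
    IVW_SCALED,
    WALD_SINGLE,
    MRResult,
    ivw_fixed,
    ivw_scaled,
    wald_ratio,
)
from .harmonize import HarmonizedPair, harmonize_set
from .records import InstrumentSet


class MRModel:
    """Two-sample Mendelian randomization model over harmonized variant pairs.

    Parameters
    ----------
    pairs : sequence of HarmonizedPair
        Aligned exposure/outcome effects; dropped pairs are filtered out.
    exposure_id : str
        Label used in results and summaries.

    Examples
    --------
    >>> from mrtools import load_table1_fixture, MRModel
    >>> iset = load_table1_fixture()["IL-1Ra"]
    >>> res = MRModel.from_instrument_set(iset).fit()
    >>> round(res.or_point, 2)
    0.93
    """

    def __init__(self, pairs, exposure_id: str = ""):
        self.pairs: list[HarmonizedPair] = [p for p in pairs if p.kept]
        self.dropped: list[HarmonizedPair] = [p for p in pairs if not p.kept]
        self.exposure_id = exposure_id

    @classmethod
    def from_instrument_set(cls, iset: InstrumentSet, **harmonize_kwargs) -> "MRModel":
        """Harmonize an instrument set and build the model from the kept pairs."""
        result = harmonize_set(iset, **harmonize_kwargs)
        model = cls(result.pairs + result.dropped, exposure_id=iset.exposure_id)
        model.harmonization_log = result.log
        return model

    @classmethod
    def from_records(cls, exposure_records, outcome_records, exposure_id: str = "",
                     **harmonize_kwargs) -> "MRModel":
        """Build from parallel exposure/outcome record collections."""
        iset = InstrumentSet(
            exposure_id=exposure_id,
            records=list(exposure_records),
            outcome_records=list(outcome_records),
        )
        return cls.from_instrument_set(iset, **harmonize_kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure_id: str = "") -> "MRModel":
        """Build from an already-harmonized table.

        Expects columns ``variant_id``, ``x``, ``sigma_x``, ``y``,
        ``sigma_y`` and optionally ``effect_allele``.
        """
        pairs = [
            HarmonizedPair(
                variant_id=str(row["variant_id"]),
                x=float(row["x"]),
                sigma_x=float(row["sigma_x"]),
                y=float(row["y"]),
                sigma_y=float(row["sigma_y"]),
                effect_allele=str(row.get("effect_allele", "A")),
                palindromic=bool(row.get("palindromic", False)),
                action=str(row.get("action", "unchanged")),
            )
            for _, row in df.iterrows()
        ]
        return cls(pairs, exposure_id=exposure_id)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    @property
    def wald_estimates(self):
        return [wald_ratio(p) for p in self.pairs]

    def fit(self, method: str = "auto", level: float = 0.95) -> MRResult:
        """Estimate the causal effect.

        method : {"auto", "ivw_fixed", "ivw_scaled", "wald_single"}
            "auto" uses the single-variant Wald ratio when one instrument
            survives and fixed-effect IVW otherwise.
        """
        if not self.pairs:
            raise EstimationError(
                f"{self.exposure_id or 'exposure'}: no surviving instruments "
                f"({len(self.dropped)} dropped)"
            )
        estimates = self.wald_estimates
        if method == "auto":
            method = WALD_SINGLE if len(estimates) == 1 else IVW_FIXED
        if method == WALD_SINGLE:
            if len(estimates) != 1:
                raise EstimationError("wald_single requires exactly one instrument")
            res = ivw_fixed(estimates, exposure_id=self.exposure_id, level=level)
            res.method = WALD_SINGLE
            return res
        if method == IVW_FIXED:
            return ivw_fixed(estimates, exposure_id=self.exposure_id, level=level)
        if method == IVW_SCALED:
            return ivw_scaled(estimates, exposure_id=self.exposure_id, level=level)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, level: float = 0.95) -> list[MRResult]:
        """The auto-selected result, plus the over-dispersion-scaled IVW when k >= 2."""
        results = [self.fit(method="auto", level=level)]
        if self.n_snp >= 2:
            results.append(self.fit(method=IVW_SCALED, level=level))
        return results

    def wald_table(self) -> pd.DataFrame:
        """Per-variant Wald ratios with ORs and IVW weights (percent)."""
        estimates = self.wald_estimates
        total_w = sum(1 / e.se**2 for e in estimates) if estimates else float("nan")
        rows = []
        for p, e in zip(self.pairs, estimates):
            from .estimators import or_ci

            orp, lo, hi, pv = or_ci(e.ratio, e.se)
            rows.append(
                {
                    "variant_id": e.variant_id,
                    "x": p.x,
                    "sigma_x": p.sigma_x,
                    "y": p.y,
                    "sigma_y": p.sigma_y,
                    "ratio": e.ratio,
                    "se": e.se,
                    "or": orp,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": pv,
                    "weight_pct": 100 * (1 / e.se**2) / total_w,
                    "action": p.action,
                }
            )
        return pd.DataFrame(rows)
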