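"""Align exposure and outcome records to a common effect allele.

Harmonization guarantees that each variant's exposure effect ``x`` and
outcome effect ``y`` refer to the same allele. Non-palindromic pairs are
aligned by allele matching, complementing the outcome alleles when the two
files report opposite strands. Palindromic variants (A/T or C/G) carry no
strand information in the alleles, so orientation is inferred from allele
frequency; when the exposure-side minor-allele frequency is too close to
0.5 the variant is dropped as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import HarmonizationError, HarmonizationWarning
from .records import COMPLEMENT, AssociationRecord, InstrumentSet

MAF_AMBIGUITY_THRESHOLD = 0.45
EAF_TOLERANCE = 0.2

UNCHANGED = "unchanged"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
STRAND_AND_SIGN_FLIPPED = "strand_flipped_and_sign_flipped"
DROPPED = "dropped"

ACTIONS = (UNCHANGED, SIGN_FLIPPED, STRAND_FLIPPED, STRAND_AND_SIGN_FLIPPED, DROPPED)


@dataclass(frozen=True)
class HarmonizedPair:
    """A variant's aligned exposure and outcome effects.

    ``x``/``sigma_x`` are the exposure beta and SE, ``y``/``sigma_y`` the
    outcome beta and SE, all referring to ``effect_allele``. ``action``
    records what harmonization did to the outcome record.
    """

    variant_id: str
    x: float
    sigma_x: float
    y: float
    sigma_y: float
    effect_allele: str
    palindromic: bool
    action: str
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action != DROPPED and (self.sigma_x <= 0 or self.sigma_y <= 0):
            raise ValueError(f"{self.variant_id}: standard errors must be positive")

    @property
    def kept(self) -> bool:
        return self.action != DROPPED


def _flip(outcome_beta: float, outcome_eaf: float | None):
    return -outcome_beta, None if outcome_eaf is None else 1 - outcome_eaf


def harmonize_pair(
    exposure: AssociationRecord,
    outcome: AssociationRecord,
    maf_ambiguity_threshold: float = MAF_AMBIGUITY_THRESHOLD,
    eaf_tolerance: float = EAF_TOLERANCE,
) -> HarmonizedPair:
    """Harmonize one exposure/outcome record pair to the exposure's effect allele.

    Palindromic variants with exposure-side MAF > ``maf_ambiguity_threshold``
    are returned with ``action='dropped'``; otherwise their orientation is
    inferred by comparing which side of 0.5 the two EAFs fall on
    (``eaf_tolerance`` bounds the post-alignment EAF disagreement that is
    accepted silently). Raises :class:`HarmonizationError` when the two
    records cannot refer to the same variant.
    """
    if exposure.variant_id != outcome.variant_id:
        raise HarmonizationError(
            f"variant_id mismatch: {exposure.variant_id!r} vs {outcome.variant_id!r}"
        )
    vid = exposure.variant_id
    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    ea_o, oa_o = outcome.effect_allele, outcome.other_allele

    palindromic = oa_x is not None and oa_x == COMPLEMENT[ea_x]
    if oa_x is None:
        warnings.warn(
            f"{vid}: exposure other_allele missing; palindrome status unknown, "
            "matching on effect allele only",
            HarmonizationWarning,
            stacklevel=2,
        )

    if palindromic:
        if exposure.eaf is None or outcome.eaf is None:
            raise HarmonizationError(
                f"{vid}: palindromic variant with missing EAF; strand not inferable"
            )
        if {ea_o, oa_o} - {ea_x, oa_x, None}:
            raise HarmonizationError(
                f"{vid}: outcome alleles {ea_o}/{oa_o} irreconcilable with "
                f"palindromic exposure {ea_x}/{oa_x}"
            )
        if min(exposure.eaf, 1 - exposure.eaf) > maf_ambiguity_threshold:
            return HarmonizedPair(
                variant_id=vid,
                x=exposure.beta,
                sigma_x=exposure.se,
                y=outcome.beta,
                sigma_y=outcome.se,
                effect_allele=ea_x,
                palindromic=True,
                action=DROPPED,
                eaf_exposure=exposure.eaf,
                eaf_outcome=outcome.eaf,
            )
        # Orientation from EAF: outcome EAF refers to its stated effect allele;
        # if that sits on the opposite side of 0.5 from the exposure EAF, the
        # outcome is coded for the other allele (possibly other strand) and
        # the sign flips.
        same_side = (exposure.eaf - 0.5) * (outcome.eaf - 0.5) >= 0
        if same_side:
            y, eaf_o, action = outcome.beta, outcome.eaf, UNCHANGED
        else:
            (y, eaf_o), action = _flip(outcome.beta, outcome.eaf), SIGN_FLIPPED
        if abs(exposure.eaf - eaf_o) > eaf_tolerance:
            warnings.warn(
                f"{vid}: palindromic orientation inferred but EAFs disagree by "
                f"{abs(exposure.eaf - eaf_o):.2f} (> {eaf_tolerance})",
                HarmonizationWarning,
                stacklevel=2,
            )
        return HarmonizedPair(
            variant_id=vid,
            x=exposure.beta,
            sigma_x=exposure.se,
            y=y,
            sigma_y=outcome.se,
            effect_allele=ea_x,
            palindromic=True,
            action=action,
            eaf_exposure=exposure.eaf,
            eaf_outcome=eaf_o,
        )

    # Non-palindromic (or palindrome status unknowable): align by alleles.
    y, eaf_o = outcome.beta, outcome.eaf
    if oa_o is None or oa_x is None:
        # Partial allele information: match on the effect allele, taking the
        # complement as the same allele read from the other strand.
        if ea_o == ea_x:
            action = UNCHANGED
        elif ea_o == COMPLEMENT[ea_x]:
            action = STRAND_FLIPPED
        elif oa_x is not None and ea_o == oa_x:
            (y, eaf_o), action = _flip(y, eaf_o), SIGN_FLIPPED
        elif oa_x is not None and ea_o == COMPLEMENT[oa_x]:
            (y, eaf_o), action = _flip(y, eaf_o), STRAND_AND_SIGN_FLIPPED
        else:
            raise HarmonizationError(
                f"{vid}: alleles irreconcilable ({ea_x}/{oa_x} vs {ea_o}/{oa_o})"
            )
        warnings.warn(
            f"{vid}: other allele missing on one side; harmonized on effect-allele match only",
            HarmonizationWarning,
            stacklevel=2,
        )
    else:
        if (ea_o, oa_o) == (ea_x, oa_x):
            action = UNCHANGED
        elif (ea_o, oa_o) == (oa_x, ea_x):
            (y, eaf_o), action = _flip(y, eaf_o), SIGN_FLIPPED
        elif (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) == (ea_x, oa_x):
            action = STRAND_FLIPPED
        elif (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) == (oa_x, ea_x):
            (y, eaf_o), action = _flip(y, eaf_o), STRAND_AND_SIGN_FLIPPED
        else:
            raise HarmonizationError(
                f"{vid}: alleles irreconcilable ({ea_x}/{oa_x} vs {ea_o}/{oa_o})"
            )
    return HarmonizedPair(
        variant_id=vid,
        x=exposure.beta,
        sigma_x=exposure.se,
        y=y,
        sigma_y=outcome.se,
        effect_allele=ea_x,
        palindromic=False,
        action=action,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_o,
    )


@dataclass
class HarmonizationResult:
    """Kept pairs, dropped pairs, and a human-readable log."""

    pairs: list[HarmonizedPair] = field(default_factory=list)
    dropped: list[HarmonizedPair] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def harmonize_set(
    iset: InstrumentSet,
    maf_ambiguity_threshold: float = MAF_AMBIGUITY_THRESHOLD,
    eaf_tolerance: float = EAF_TOLERANCE,
) -> HarmonizationResult:
    """Harmonize every exposure/outcome pair of an instrument set.

    Dropped (ambiguous palindromic) pairs and variants with no outcome
    record are excluded from the estimation set but logged with the reason;
    output order follows the exposure record order.
    """
    result = HarmonizationResult()
    for exp_rec, out_rec in zip(iset.records, iset.outcome_records):
        if out_rec is None:
            result.log.append(f"{exp_rec.variant_id}: no outcome record; excluded")
            continue
        pair = harmonize_pair(
            exp_rec,
            out_rec,
            maf_ambiguity_threshold=maf_ambiguity_threshold,
            eaf_tolerance=eaf_tolerance,
        )
        if pair.kept:
            result.pairs.append(pair)
            result.log.append(f"{pair.variant_id}: kept ({pair.action})")
        else:
            result.dropped.append(pair)
            result.log.append(
                f"{pair.variant_id}: dropped (palindromic, exposure MAF "
                f"{min(pair.eaf_exposure, 1 - pair.eaf_exposure):.2f} > "
                f"{maf_ambiguity_threshold})"
            )
    return result
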