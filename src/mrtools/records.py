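"""Domain containers for GWAS summary associations and LD.

An :class:`AssociationRecord` is one variant's marginal association with one
trait, on the scale GWAS report it: log-odds per effect allele for binary
traits, SD units for continuous traits. An :class:`InstrumentSet` pairs the
exposure-side records of one exposure with the (possibly gappy) outcome-side
records. An :class:`LDMatrix` holds pairwise r-squared between variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import LDError, ValueWarning

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _check_allele(allele: str, name: str) -> str:
    allele = str(allele).upper()
    if len(allele) != 1 or allele not in VALID_ALLELES:
        raise ValueError(
            f"{name} must be a single base A/C/G/T, got {allele!r} "
            "(indels and multi-allelic sites are not supported)"
        )
    return allele


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's summary association with one trait.

    Parameters
    ----------
    variant_id : str
        rsID (or any unique label).
    effect_allele : str
        The allele ``beta`` refers to; one of A/C/G/T.
    beta : float
        Per-allele effect estimate (log-odds for binary traits, SD units
        for continuous traits).
    se : float
        Standard error of ``beta``; must be positive.
    p_value : float
        Two-sided association p-value in (0, 1].
    other_allele : str, optional
        The non-effect allele; may be missing (some published tables omit it).
    eaf : float, optional
        Effect-allele frequency in [0, 1].
    chromosome : str, optional
        Chromosome label (kept as a string to admit "X").
    position : int, optional
        1-based base-pair position.
    trait_id : str
        Label for the trait the association refers to.
    """

    variant_id: str
    effect_allele: str
    beta: float
    se: float
    p_value: float
    other_allele: str | None = None
    eaf: float | None = None
    chromosome: str | None = None
    position: int | None = None
    trait_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        if self.other_allele is not None:
            object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
            if self.other_allele == self.effect_allele:
                raise ValueError(f"{self.variant_id}: effect_allele == other_allele ({self.effect_allele})")
        for name in ("beta", "se", "p_value"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"{self.variant_id}: {name} must be a finite number, got {v!r}")
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.variant_id}: p_value must be in (0, 1], got {self.p_value}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.position is not None:
            object.__setattr__(self, "position", int(self.position))
        self._check_p_consistency()

    def _check_p_consistency(self):
        # Sanity check, warn not fail: compare on the normal-quantile scale,
        # which is robust to the huge relative rounding error in extreme tails.
        if self.p_value <= 1e-300:  # tail saturated in double precision
            return
        z = abs(self.beta) / self.se
        z_implied = float(norm.isf(self.p_value / 2))
        if max(z, z_implied) > 1.0 and not (0.5 * z <= z_implied <= 2 * z):
            warnings.warn(
                f"{self.variant_id}: p_value {self.p_value:g} implies |z|≈{z_implied:.2f} "
                f"but beta/se gives |z|≈{z:.2f}",
                ValueWarning,
                stacklevel=3,
            )

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, if the EAF is known."""
        return None if self.eaf is None else min(self.eaf, 1 - self.eaf)

    @property
    def is_palindromic(self) -> bool | None:
        """True for A/T or C/G pairs; None when the other allele is unknown."""
        if self.other_allele is None:
            return None
        return self.other_allele == COMPLEMENT[self.effect_allele]

    def flip_coding(self) -> "AssociationRecord":
        """Recode to the opposite effect allele (beta -> -beta, eaf -> 1-eaf)."""
        if self.other_allele is None:
            raise ValueError(f"{self.variant_id}: cannot flip coding without the other allele")
        return AssociationRecord(
            variant_id=self.variant_id,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            se=self.se,
            p_value=self.p_value,
            eaf=None if self.eaf is None else 1 - self.eaf,
            chromosome=self.chromosome,
            position=self.position,
            trait_id=self.trait_id,
        )


@dataclass
class InstrumentSet:
    """The instruments for one exposure, with matched outcome associations.

    ``outcome_records`` is parallel to ``records``; ``None`` marks a variant
    not (yet) found in the outcome data, to be filled by proxy search.
    """

    exposure_id: str
    records: list[AssociationRecord]
    outcome_records: list[AssociationRecord | None] = field(default_factory=list)

    def __post_init__(self):
        self.records = list(self.records)
        if not self.outcome_records:
            self.outcome_records = [None] * len(self.records)
        self.outcome_records = list(self.outcome_records)
        if len(self.outcome_records) != len(self.records):
            raise ValueError(
                f"{self.exposure_id}: {len(self.records)} exposure records but "
                f"{len(self.outcome_records)} outcome slots"
            )
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.exposure_id}: duplicate variant_ids in exposure records")
        out_ids = [r.variant_id for r in self.outcome_records if r is not None]
        if len(set(out_ids)) != len(out_ids):
            raise ValueError(f"{self.exposure_id}: duplicate variant_ids in outcome records")

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LDMatrix:
    """Pairwise r-squared between variants; symmetric, unit diagonal."""

    variant_ids: tuple[str, ...]
    r2: np.ndarray
    positions: tuple[int, ...] | None = None
    chromosomes: tuple[str, ...] | None = None

    def __post_init__(self):
        self.variant_ids = tuple(str(v) for v in self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise LDError(f"r2 matrix shape {self.r2.shape} does not match {n} variant ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise LDError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise LDError("r2 matrix diagonal must be 1")
        if self.r2.min() < -1e-8 or self.r2.max() > 1 + 1e-8:
            raise LDError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != n:
            raise LDError("duplicate variant ids in LD matrix")
        if self.positions is not None:
            self.positions = tuple(int(p) for p in self.positions)
            if len(self.positions) != n:
                raise LDError("positions length does not match variant ids")
        if self.chromosomes is not None:
            self.chromosomes = tuple(str(c) for c in self.chromosomes)
            if len(self.chromosomes) != n:
                raise LDError("chromosomes length does not match variant ids")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise LDError(f"variant {variant_id!r} is not in the LD matrix") from None

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index(a), self.index(b)])
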