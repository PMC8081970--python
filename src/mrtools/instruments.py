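"""Instrument selection: significance filter, greedy LD clumping, proxy lookup."""

from __future__ import annotations

from .errors import LDError
from .records import AssociationRecord, LDMatrix

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.01
CLUMP_WINDOW_BP = 1_000_000
PROXY_R2 = 0.8


def select_genomewide(records, p_threshold: float = GENOME_WIDE_P) -> list[AssociationRecord]:
    """Keep records with p strictly below the genome-wide threshold; order preserved."""
    return [r for r in records if r.p_value < p_threshold]


def ld_clump(
    records,
    ld: LDMatrix,
    r2_threshold: float = CLUMP_R2,
    window: int = CLUMP_WINDOW_BP,
) -> list[AssociationRecord]:
    """Greedy LD clumping: keep the lowest-p variant per locus.

    Repeatedly takes the unprocessed record with the lowest p-value (ties
    broken by variant_id), retains it, and removes every unprocessed record
    on the same chromosome within ±``window`` bp whose r² with it exceeds
    ``r2_threshold``. The result is ordered by the greedy retention order
    (p, then id), so it does not depend on input order.
    """
    records = list(records)
    for r in records:
        if r.variant_id not in ld:
            raise LDError(f"variant {r.variant_id!r} is not in the LD matrix")
        if r.position is None:
            raise LDError(f"variant {r.variant_id!r} has no position; clumping needs positions")
    order = sorted(records, key=lambda r: (r.p_value, r.variant_id))
    removed: set[str] = set()
    kept: list[AssociationRecord] = []
    for r in order:
        if r.variant_id in removed:
            continue
        kept.append(r)
        for s in order:
            if s.variant_id == r.variant_id or s.variant_id in removed:
                continue
            if (
                s.chromosome == r.chromosome
                and abs(s.position - r.position) <= window
                and ld.r2_between(r.variant_id, s.variant_id) > r2_threshold
            ):
                removed.add(s.variant_id)
    return kept


def find_proxy(
    target: str,
    available,
    ld: LDMatrix,
    r2_min: float = PROXY_R2,
    window: int = CLUMP_WINDOW_BP,
) -> str | None:
    """Best available proxy for ``target``: highest r² strictly above ``r2_min``.

    Candidates must be present in the LD matrix; when the matrix carries
    chromosomes/positions they must share the target's chromosome and lie
    within ±``window`` bp. Ties are broken by variant_id; returns None when
    no candidate qualifies. The target itself, if available, wins (r² = 1).
    """
    ti = ld.index(target)  # raises LDError for unknown targets
    best_id, best_r2 = None, r2_min
    for cand in sorted(set(available)):
        if cand not in ld:
            continue
        ci = ld.index(cand)
        if ld.chromosomes is not None and ld.chromosomes[ci] != ld.chromosomes[ti]:
            continue
        if ld.positions is not None and abs(ld.positions[ci] - ld.positions[ti]) > window:
            continue
        r2 = float(ld.r2[ti, ci])
        if r2 > best_r2:
            best_id, best_r2 = cand, r2
    return best_id
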