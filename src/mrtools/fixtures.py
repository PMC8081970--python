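"""Packaged 9-SNP instrument table for six circulating interleukins vs MS.

The table carries, per variant, the exposure-side association (per-SD effect
on the circulating interleukin) and the outcome-side association (log-odds
of multiple sclerosis) to two decimals, as published. The source table does
not report the non-effect alleles or positions, so ``other_allele`` and
``position`` are missing; harmonization falls back to effect-allele matching
for such records.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import parse_number
from .records import AssociationRecord, InstrumentSet

OUTCOME_ID = "MS"

#: exposures in table order; IL-1Ra and IL-18 have two instruments each
EXPOSURE_ORDER = ("IL-1Ra", "sIL-2Rα", "IL-6", "IL-16", "IL-17", "IL-18")


def fixture_path():
    """Filesystem path of the packaged instrument table."""
    return resources.files("mrtools") / "data" / "il_ms_instruments.tsv"


def load_table1_fixture() -> dict[str, InstrumentSet]:
    """Load the packaged table as one :class:`InstrumentSet` per exposure.

    Returns a dict keyed by exposure label, in table order, each holding the
    exposure-side records and the matched MS outcome records.
    """
    with resources.as_file(fixture_path()) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    sets: dict[str, InstrumentSet] = {}
    groups: dict[str, tuple[list, list]] = {}
    for _, row in df.iterrows():
        exposure = row["exposure"]
        exp_rec = AssociationRecord(
            variant_id=row["SNP"],
            chromosome=row["Chr"],
            effect_allele=row["EA"],
            eaf=parse_number(row["EAF"]),
            beta=parse_number(row["beta_exposure"]),
            se=parse_number(row["se_exposure"]),
            p_value=parse_number(row["p_exposure"]),
            trait_id=exposure,
        )
        out_rec = AssociationRecord(
            variant_id=row["SNP"],
            chromosome=row["Chr"],
            effect_allele=row["EA"],
            eaf=parse_number(row["EAF"]),
            beta=parse_number(row["beta_outcome"]),
            se=parse_number(row["se_outcome"]),
            p_value=parse_number(row["p_outcome"]),
            trait_id=OUTCOME_ID,
        )
        groups.setdefault(exposure, ([], []))
        groups[exposure][0].append(exp_rec)
        groups[exposure][1].append(out_rec)
    for exposure, (recs, outs) in groups.items():
        sets[exposure] = InstrumentSet(exposure_id=exposure, records=recs, outcome_records=outs)
    return sets
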