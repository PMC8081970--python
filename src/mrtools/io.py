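"""Tab-separated readers/writers for summary statistics, LD matrices and results.

GWAS summary dialects vary, so column names are configurable through a
``column_map`` (field name -> column header); defaults follow the packaged
instrument table. Publisher-style scientific notation ("2.1 × 10^−12^",
unicode minus) is normalized to plain floats on ingest.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MRToolsError, SummaryTableError
from .records import AssociationRecord, LDMatrix

DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chromosome": "Chr",
    "position": "Position",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "Beta",
    "se": "SE",
    "p_value": "P-value",
}

REQUIRED_FIELDS = ("variant_id", "effect_allele", "beta", "se", "p_value")

_SCI_RE = re.compile(r"^\s*([+\-−]?[0-9.]+)\s*[×x*]\s*10\s*\^?\s*([+\-−]?[0-9]+)\s*\^?\s*$")


def parse_number(text) -> float:
    """Parse a number, accepting publisher forms like '2.1 × 10^−12^'."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        raise ValueError("missing value")
    s = str(text).strip().replace("−", "-")
    if s == "" or s.upper() in {"NA", "NAN", "."}:
        raise ValueError("missing value")
    m = _SCI_RE.match(s)
    if m:
        s = f"{m.group(1)}e{m.group(2)}"
    return float(s)


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN", "."}:
        return None
    return s


def read_summary_table(path, column_map=None, trait_id: str = "") -> list[AssociationRecord]:
    """Read a tab-separated GWAS summary-statistic table.

    Missing optional columns (other allele, EAF, chromosome, position) are
    tolerated; malformed numeric cells raise :class:`SummaryTableError`
    naming the offending lines (the header is line 1).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in REQUIRED_FIELDS:
        if cmap[field] not in df.columns:
            raise SummaryTableError(f"{path}: required column {cmap[field]!r} not found")

    def col(row, field):
        name = cmap.get(field)
        return row[name] if name in df.columns else None

    records, errors = [], []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            eaf = _opt(col(row, "eaf"))
            pos = _opt(col(row, "position"))
            records.append(
                AssociationRecord(
                    variant_id=str(row[cmap["variant_id"]]).strip(),
                    effect_allele=str(row[cmap["effect_allele"]]).strip(),
                    other_allele=_opt(col(row, "other_allele")),
                    eaf=None if eaf is None else parse_number(eaf),
                    beta=parse_number(col(row, "beta")),
                    se=parse_number(col(row, "se")),
                    p_value=parse_number(col(row, "p_value")),
                    chromosome=_opt(col(row, "chromosome")),
                    position=None if pos is None else int(float(pos)),
                    trait_id=trait_id,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((line_no, str(exc)))
    if errors:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in errors)
        raise SummaryTableError(f"{path}: {len(errors)} malformed row(s): {detail}", errors)
    return records


def write_summary_table(records, path, column_map=None) -> None:
    """Write association records as a tab-separated table with header."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rows = []
    for r in records:
        rows.append(
            {
                cmap["variant_id"]: r.variant_id,
                cmap["chromosome"]: r.chromosome if r.chromosome is not None else "NA",
                cmap["position"]: r.position if r.position is not None else "NA",
                cmap["effect_allele"]: r.effect_allele,
                cmap["other_allele"]: r.other_allele if r.other_allele is not None else "NA",
                cmap["eaf"]: _fmt(r.eaf),
                cmap["beta"]: _fmt(r.beta),
                cmap["se"]: _fmt(r.se),
                cmap["p_value"]: _fmt(r.p_value),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    return f"{x:.10g}"


def read_ld_matrix(path) -> LDMatrix:
    """Read a square tab-separated r² matrix with variant ids as first row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise MRToolsError(f"{path}: LD matrix row and column ids differ")
    return LDMatrix(variant_ids=tuple(str(v) for v in df.columns), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


RESULT_COLUMNS = [
    "exposure",
    "method",
    "n_snp",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "p_value",
    "q",
    "q_df",
    "q_p",
    "bonferroni_significant",
]


def write_result_table(results, path) -> None:
    """Write pooled MR results (full machine precision, tab-separated)."""
    results = list(results)
    if not results:
        raise MRToolsError("cannot write an empty result table")
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_id,
                "method": r.method,
                "n_snp": r.n_snp,
                "beta": _fmt(r.beta),
                "se": _fmt(r.se),
                "or": _fmt(r.or_point),
                "ci_low": _fmt(r.ci_low),
                "ci_high": _fmt(r.ci_high),
                "p_value": _fmt(r.p_value),
                "q": _fmt(r.q),
                "q_df": r.q_df if r.q_df is not None else "NA",
                "q_p": _fmt(r.q_p),
                "bonferroni_significant": (
                    "NA" if r.significant_bonferroni is None else str(r.significant_bonferroni)
                ),
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_result_table(path) -> pd.DataFrame:
    """Read a result table back into a DataFrame with numeric columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for c in ("beta", "se", "or", "ci_low", "ci_high", "p_value", "q", "q_p"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
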