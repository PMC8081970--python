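"""End-to-end analysis: select -> clump -> proxy -> harmonize -> estimate -> report.

All tabular outputs are tab-separated with headers and fully deterministic
given the inputs and thresholds; the run log records every threshold used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import EstimationError, MRToolsError
from .estimators import MRResult, bonferroni_flag
from .fixtures import load_table1_fixture
from .harmonize import EAF_TOLERANCE, MAF_AMBIGUITY_THRESHOLD
from .instruments import (
    CLUMP_R2,
    CLUMP_WINDOW_BP,
    GENOME_WIDE_P,
    PROXY_R2,
    find_proxy,
    ld_clump,
    select_genomewide,
)
from .io import write_result_table
from .model import MRModel
from .records import AssociationRecord, InstrumentSet, LDMatrix


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for the full pipeline, defaulting to the standard values."""

    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = CLUMP_R2
    clump_window: int = CLUMP_WINDOW_BP
    proxy_r2: float = PROXY_R2
    maf_ambiguity_threshold: float = MAF_AMBIGUITY_THRESHOLD
    eaf_tolerance: float = EAF_TOLERANCE
    alpha: float = 0.05
    family_size: int | None = None  # None -> number of exposures analyzed
    ci_level: float = 0.95

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat key=value config file (lines starting with # ignored)."""
        kwargs = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise MRToolsError(f"config line not of form key=value: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise MRToolsError(f"unknown config key {key!r}")
            if key in ("clump_window", "family_size"):
                kwargs[key] = None if value.lower() == "none" else int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class ExposureAnalysis:
    """Everything computed for one exposure: model, results, plot-data tables."""

    exposure_id: str
    model: MRModel
    results: list[MRResult]
    wald_table: pd.DataFrame
    scatter: pd.DataFrame
    funnel: pd.DataFrame
    forest: pd.DataFrame
    drop_log: list[str] = field(default_factory=list)


def resolve_outcome(
    records,
    outcome_lookup: dict[str, AssociationRecord],
    ld: LDMatrix | None = None,
    exposure_lookup: dict[str, AssociationRecord] | None = None,
    proxy_r2: float = PROXY_R2,
    window: int = CLUMP_WINDOW_BP,
):
    """Match outcome records to exposure instruments, substituting proxies.

    When a variant is absent from the outcome data and an LD matrix is
    given, the best proxy (r² > ``proxy_r2``) present in the outcome data is
    substituted — on *both* sides, using the proxy's own exposure record
    and alleles (no allele translation between target and proxy is
    attempted, since it would require phase information). Targets without a
    usable proxy are logged and excluded.

    Returns ``(exposure_records, outcome_records, log)``.
    """
    kept_exp, kept_out, log = [], [], []
    for rec in records:
        if rec.variant_id in outcome_lookup:
            kept_exp.append(rec)
            kept_out.append(outcome_lookup[rec.variant_id])
            continue
        if ld is None or rec.variant_id not in ld:
            log.append(f"{rec.variant_id}: absent from outcome data, no LD for proxy search")
            continue
        proxy = find_proxy(rec.variant_id, outcome_lookup.keys(), ld, r2_min=proxy_r2, window=window)
        if proxy is None:
            log.append(f"{rec.variant_id}: absent from outcome data, no proxy with r2 > {proxy_r2}")
            continue
        if exposure_lookup is None or proxy not in exposure_lookup:
            log.append(
                f"{rec.variant_id}: proxy {proxy} found but has no exposure record; excluded"
            )
            continue
        log.append(f"{rec.variant_id}: proxied by {proxy}")
        kept_exp.append(exposure_lookup[proxy])
        kept_out.append(outcome_lookup[proxy])
    return kept_exp, kept_out, log


def analyze_exposure(
    iset: InstrumentSet,
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
) -> ExposureAnalysis:
    """Run the full pipeline for one exposure and assemble all tables.

    Selection and (when an LD matrix is supplied) clumping are applied to
    the exposure records; surviving variants are harmonized against their
    outcome records and pooled. Raises :class:`EstimationError` with the
    drop log attached when no instrument survives.
    """
    cfg = config or PipelineConfig()
    drop_log: list[str] = []

    selected = select_genomewide(iset.records, p_threshold=cfg.p_threshold)
    for r in iset.records:
        if r not in selected:
            drop_log.append(f"{r.variant_id}: p {r.p_value:g} >= {cfg.p_threshold:g}")
    if ld is not None and selected:
        clumped = ld_clump(selected, ld, r2_threshold=cfg.clump_r2, window=cfg.clump_window)
        kept_ids = {r.variant_id for r in clumped}
        for r in selected:
            if r.variant_id not in kept_ids:
                drop_log.append(f"{r.variant_id}: removed by LD clumping")
        selected = clumped

    outcome_by_id = {
        r.variant_id: r for r in iset.outcome_records if r is not None
    }
    sub = InstrumentSet(
        exposure_id=iset.exposure_id,
        records=selected,
        outcome_records=[outcome_by_id.get(r.variant_id) for r in selected],
    )
    model = MRModel.from_instrument_set(
        sub,
        maf_ambiguity_threshold=cfg.maf_ambiguity_threshold,
        eaf_tolerance=cfg.eaf_tolerance,
    )
    drop_log.extend(
        line for line in getattr(model, "harmonization_log", []) if "kept" not in line
    )
    if model.n_snp == 0:
        raise EstimationError(
            f"{iset.exposure_id}: no surviving instruments; drop log: {'; '.join(drop_log)}"
        )
    results = model.fit_all(level=cfg.ci_level)
    wald = model.wald_table()
    wald.insert(0, "exposure", iset.exposure_id)

    pooled = results[0]
    scatter = wald[["exposure", "variant_id", "x", "sigma_x", "y", "sigma_y"]].copy()
    scatter["fitted_slope"] = pooled.beta
    funnel = wald[["exposure", "variant_id", "ratio", "se"]].copy()
    funnel["precision"] = 1 / funnel["se"]
    funnel["pooled_beta"] = pooled.beta
    forest_rows = [
        {
            "exposure": iset.exposure_id,
            "label": row["variant_id"],
            "kind": "snp",
            "method": "wald",
            "or": row["or"],
            "ci_low": row["ci_low"],
            "ci_high": row["ci_high"],
            "weight_pct": row["weight_pct"],
        }
        for _, row in wald.iterrows()
    ] + [
        {
            "exposure": iset.exposure_id,
            "label": f"pooled ({res.method})",
            "kind": "pooled",
            "method": res.method,
            "or": res.or_point,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "weight_pct": 100.0,
        }
        for res in results
    ]
    return ExposureAnalysis(
        exposure_id=iset.exposure_id,
        model=model,
        results=results,
        wald_table=wald,
        scatter=scatter,
        funnel=funnel,
        forest=pd.DataFrame(forest_rows),
        drop_log=drop_log,
    )


def render_forest_table(results, order=None) -> str:
    """Human-readable forest listing, OR/CI to 2 decimals.

    Rows are sorted by exposure name unless ``order`` gives an explicit
    sequence of exposure labels.
    """
    results = list(results)
    if not results:
        raise MRToolsError("no results to render")
    if order is None:
        results = sorted(results, key=lambda r: (r.exposure_id, r.method))
    else:
        rank = {name: i for i, name in enumerate(order)}
        results = sorted(results, key=lambda r: (rank.get(r.exposure_id, len(rank)), r.method))
    header = f"{'Exposure':<12}{'Method':<12}{'nSNP':>5}  {'OR (95% CI)':<22}{'P':>9}{'Q':>7}{'Q_P':>8}"
    lines = [header, "-" * len(header)]
    for r in results:
        q = f"{r.q:.2f}" if r.q is not None else "."
        qp = f"{r.q_p:.3f}" if r.q_p is not None else "."
        lines.append(
            f"{r.exposure_id:<12}{r.method:<12}{r.n_snp:>5}  "
            f"{r.or_point:.2f} ({r.ci_low:.2f}–{r.ci_high:.2f})   "
            f"{r.p_value:>8.3g}{q:>7}{qp:>8}"
        )
    return "\n".join(lines)


def run_pipeline(
    outdir,
    exposures: dict[str, InstrumentSet] | None = None,
    fixture: str | None = None,
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
    exposure_order=None,
) -> dict:
    """Analyze every exposure and write the full result bundle to ``outdir``.

    ``fixture='table1'`` loads the packaged interleukin/MS instrument table.
    Writes results.tsv, wald_ratios.tsv, scatter_data.tsv, funnel_data.tsv,
    forest_data.tsv, forest.txt, drop_log.txt and run_log.txt; output is
    byte-identical across reruns with the same inputs.
    """
    cfg = config or PipelineConfig()
    if exposures is None:
        if fixture != "table1":
            raise MRToolsError("either exposures or fixture='table1' must be given")
        exposures = load_table1_fixture()
    if not exposures:
        raise MRToolsError("no exposures to analyze")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    analyses = [analyze_exposure(iset, ld=ld, config=cfg) for iset in exposures.values()]
    family = cfg.family_size if cfg.family_size is not None else len(exposures)

    all_results: list[MRResult] = []
    for a in analyses:
        all_results.extend(a.results)
    flags = bonferroni_flag([r.p_value for r in all_results], family_size=family, alpha=cfg.alpha)
    for r, f in zip(all_results, flags):
        r.significant_bonferroni = f

    write_result_table(all_results, outdir / "results.tsv")
    for name, attr in (
        ("wald_ratios", "wald_table"),
        ("scatter_data", "scatter"),
        ("funnel_data", "funnel"),
        ("forest_data", "forest"),
    ):
        pd.concat([getattr(a, attr) for a in analyses], ignore_index=True).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    (outdir / "forest.txt").write_text(
        render_forest_table(all_results, order=exposure_order or list(exposures)) + "\n",
        encoding="utf-8",
    )
    (outdir / "drop_log.txt").write_text(
        "\n".join(line for a in analyses for line in a.drop_log) + "\n", encoding="utf-8"
    )
    (outdir / "run_log.txt").write_text(_run_log(cfg, family, list(exposures)), encoding="utf-8")
    return {
        "outdir": outdir,
        "analyses": analyses,
        "results": all_results,
        "family_size": family,
    }


def _run_log(cfg: PipelineConfig, family: int, exposure_names) -> str:
    return (
        "two-sample MR pipeline run\n"
        f"genome-wide significance threshold: p < {cfg.p_threshold:g}\n"
        f"LD clumping: remove r2 > {cfg.clump_r2:g} within {cfg.clump_window} bp window\n"
        f"proxy search: r2 > {cfg.proxy_r2:g}\n"
        f"palindromic drop rule: MAF > {cfg.maf_ambiguity_threshold:g}\n"
        f"EAF orientation tolerance: {cfg.eaf_tolerance:g}\n"
        f"significance: p < {cfg.alpha:g}/{family} (Bonferroni)\n"
        f"confidence level: {cfg.ci_level:g}\n"
        f"exposures: {', '.join(exposure_names)}\n"
    )
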