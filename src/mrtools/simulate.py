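"""Synthetic paired GWAS summary statistics with known causal ground truth.

Binary-outcome GWAS effects are simulated directly on the log-odds scale
with normal noise (no individual-level logistic simulation): for variant k
with minor-allele frequency p_k and exposure sample size N_X, the exposure
SE uses the standard approximation 1/sqrt(2 p_k (1-p_k) N_X); the observed
exposure beta is the true per-SD effect x*_k plus noise. The true outcome
effect is causal_effect * x*_k plus an optional direct (pleiotropic) effect;
the outcome side is generated analogously with N_Y. Outcome records are
re-coded to the opposite allele with probability 1/2 so that harmonization
is exercised end to end. All randomness flows from one
``numpy.random.default_rng`` (PCG64) seeded by the scenario seed, so output
is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .errors import MRToolsError
from .harmonize import harmonize_set
from .model import MRModel
from .records import AssociationRecord, InstrumentSet, LDMatrix

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one paired exposure/outcome summary data set.

    ``exposure_betas`` is either a ``(low, high)`` tuple, drawn uniformly
    per variant, or an explicit list of per-variant SD-unit effects.
    ``ld_blocks`` is ``None`` (independent variants on well-separated loci)
    or ``(block_sizes, within_r2)``.
    """

    n_variants: int = 5
    causal_effect: float = 0.0
    exposure_betas: tuple = (0.1, 0.6)
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    maf_range: tuple = (0.1, 0.5)
    palindromic_fraction: float = 0.2
    pleiotropy_sd: float = 0.0
    ld_blocks: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise MRToolsError("n_variants must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise MRToolsError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise MRToolsError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.palindromic_fraction <= 1:
            raise MRToolsError("palindromic_fraction must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise MRToolsError("pleiotropy_sd must be >= 0")


def _draw_exposure_betas(scenario: SyntheticScenario, rng) -> np.ndarray:
    spec = scenario.exposure_betas
    if isinstance(spec, tuple) and len(spec) == 2:
        return rng.uniform(spec[0], spec[1], scenario.n_variants)
    arr = np.asarray(list(spec), dtype=float)
    if arr.shape != (scenario.n_variants,):
        raise MRToolsError(
            f"exposure_betas: expected a (low, high) tuple or {scenario.n_variants} values"
        )
    return arr


def _positions(scenario: SyntheticScenario) -> tuple[np.ndarray, list[str]]:
    # Independent variants sit 2 Mb apart (outside any clumping window);
    # variants within an LD block sit 10 kb apart.
    if scenario.ld_blocks is None:
        pos = 1 + 2_000_000 * np.arange(scenario.n_variants)
        return pos, ["1"] * scenario.n_variants
    block_sizes, _ = scenario.ld_blocks
    pos, chroms, cursor = [], [], 1
    for b, size in enumerate(block_sizes):
        for j in range(size):
            pos.append(cursor + 10_000 * j)
            chroms.append("1")
        cursor += 2_000_000
    if len(pos) != scenario.n_variants:
        raise MRToolsError("ld_blocks sizes must sum to n_variants")
    return np.array(pos), chroms


def _p_from_z(beta, se):
    p = 2 * norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_two_sample(scenario: SyntheticScenario):
    """Generate one paired exposure/outcome summary data set.

    Returns ``(exposure_records, outcome_records, truth)`` where ``truth``
    holds the causal effect, the per-variant true exposure effects, the
    pleiotropy draws, and bookkeeping (MAFs, palindromic flags, which
    outcome records were re-coded).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_variants
    maf = rng.uniform(scenario.maf_range[0], scenario.maf_range[1], n)
    x_star = _draw_exposure_betas(scenario, rng)
    se_x = 1 / np.sqrt(2 * maf * (1 - maf) * scenario.n_exposure)
    se_y = 1 / np.sqrt(2 * maf * (1 - maf) * scenario.n_outcome)
    beta_x = x_star + rng.normal(0, se_x)
    pleio = rng.normal(0, scenario.pleiotropy_sd, n) if scenario.pleiotropy_sd > 0 else np.zeros(n)
    y_star = scenario.causal_effect * x_star + pleio
    beta_y = y_star + rng.normal(0, se_y)
    eaf_x = np.clip(maf + rng.normal(0, np.sqrt(maf * (1 - maf) / (2 * scenario.n_exposure))), 1e-4, 1 - 1e-4)
    eaf_y = np.clip(maf + rng.normal(0, np.sqrt(maf * (1 - maf) / (2 * scenario.n_outcome))), 1e-4, 1 - 1e-4)
    is_palin = rng.random(n) < scenario.palindromic_fraction
    swap = rng.random(n) < 0.5
    positions, chroms = _positions(scenario)
    p_x = _p_from_z(beta_x, se_x)
    p_y = _p_from_z(beta_y, se_y)

    exposure_records, outcome_records = [], []
    for k in range(n):
        if is_palin[k]:
            ea, oa = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        vid = f"rs{1000001 + k}"
        exposure_records.append(
            AssociationRecord(
                variant_id=vid, chromosome=chroms[k], position=int(positions[k]),
                effect_allele=ea, other_allele=oa, eaf=float(eaf_x[k]),
                beta=float(beta_x[k]), se=float(se_x[k]), p_value=float(p_x[k]),
                trait_id="exposure",
            )
        )
        out = AssociationRecord(
            variant_id=vid, chromosome=chroms[k], position=int(positions[k]),
            effect_allele=ea, other_allele=oa, eaf=float(eaf_y[k]),
            beta=float(beta_y[k]), se=float(se_y[k]), p_value=float(p_y[k]),
            trait_id="outcome",
        )
        if swap[k]:
            out = out.flip_coding()
        outcome_records.append(out)

    truth = {
        "causal_effect": scenario.causal_effect,
        "x_star": x_star,
        "pleiotropy": pleio,
        "maf": maf,
        "palindromic": is_palin,
        "outcome_recoded": swap,
    }
    return exposure_records, outcome_records, truth


def simulate_ld_block(block_sizes, within_r2: float, positions=None, seed=None) -> LDMatrix:
    """Block-diagonal r² matrix: ``within_r2`` inside blocks, 0 between.

    ``positions`` defaults to the same layout :func:`simulate_two_sample`
    uses (10 kb within a block, 2 Mb between blocks). The construction is
    exact and deterministic; ``seed`` is accepted for interface symmetry
    and unused.
    """
    if not 0 <= within_r2 <= 1:
        raise MRToolsError("within_r2 must be in [0, 1]")
    n = int(sum(block_sizes))
    r2 = np.zeros((n, n))
    start = 0
    for size in block_sizes:
        r2[start : start + size, start : start + size] = within_r2
        start += size
    np.fill_diagonal(r2, 1.0)
    if positions is None:
        scenario = SyntheticScenario(n_variants=n, ld_blocks=(tuple(block_sizes), within_r2))
        positions, chroms = _positions(scenario)
    else:
        chroms = ["1"] * n
    ids = tuple(f"rs{1000001 + k}" for k in range(n))
    return LDMatrix(
        variant_ids=ids, r2=r2, positions=tuple(int(p) for p in positions),
        chromosomes=tuple(chroms),
    )


def recovery_study(scenario: SyntheticScenario, n_reps: int, alpha: float = 0.05) -> dict:
    """Monte-Carlo calibration of the IVW estimator under a known scenario.

    Per replicate: simulate, harmonize, fit (auto: Wald for one surviving
    instrument, fixed-effect IVW otherwise), then summarize bias, empirical
    SE, CI coverage of the true effect, and the rejection rate at ``alpha``.
    Intended for n_reps in the hundreds; rejects n_reps < 1.
    """
    if n_reps < 1:
        raise MRToolsError(f"n_reps must be >= 1, got {n_reps}")
    child_seeds = np.random.SeedSequence(scenario.seed).generate_state(n_reps, dtype=np.uint32)
    estimates, ses, covered, rejected = [], [], 0, 0
    truth_beta = scenario.causal_effect
    n_used = 0
    for s in child_seeds:
        reps = replace(scenario, seed=int(s))
        exp_recs, out_recs, _ = simulate_two_sample(reps)
        iset = InstrumentSet(exposure_id="sim", records=exp_recs, outcome_records=out_recs)
        hres = harmonize_set(iset)
        if not hres.pairs:
            continue
        res = MRModel(hres.pairs, exposure_id="sim").fit(method="auto")
        n_used += 1
        estimates.append(res.beta)
        ses.append(res.se)
        lo, hi = np.log(res.ci_low), np.log(res.ci_high)
        covered += int(lo <= truth_beta <= hi)
        rejected += int(res.p_value < alpha)
    estimates = np.array(estimates)
    return {
        "n_reps": n_used,
        "mean_estimate": float(np.mean(estimates)),
        "bias": float(np.mean(estimates) - truth_beta),
        "empirical_se": float(np.std(estimates, ddof=1)) if n_used > 1 else float("nan"),
        "mean_model_se": float(np.mean(ses)),
        "coverage": covered / n_used,
        "rejection_rate": rejected / n_used,
        "mc_se_mean": float(np.std(estimates, ddof=1) / np.sqrt(n_used)) if n_used > 1 else float("nan"),
    }
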