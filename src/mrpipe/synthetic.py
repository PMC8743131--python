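"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical structure of real GWAS summary
data: per-SNP effects on one or two exposures, outcome effects composed of
causal transmission plus optional pleiotropy, standard errors scaled by
GWAS sample size (se ~ 1/sqrt(2 n maf (1-maf))), p-values consistent with
the z-scores, allele pairs with a configurable palindromic fraction, and a
block LD table so that clumping and proxy lookup have real work to do.
Every draw is governed by a single seed; a fixed seed gives byte-identical
written files.

It does *not* simulate individual-level genotypes, genome-wide LD maps, or
dynastic/assortative-mating structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import json

import numpy as np
import pandas as pd
from scipy import stats

from mrpipe.errors import ConfigurationError
from mrpipe.sumstats import CANONICAL_COLUMNS, LDTable, SummaryStats, write_sumstats

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_PLAIN_PAIRS = [("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
                ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T")]

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violating")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative description of a synthetic two-sample MR dataset.

    ``theta`` is the true causal effect (scalar, or length-2 for two
    exposures).  Exposure effects are drawn from normal(0, bx_sd^2);
    with ``significant_only`` the magnitudes are truncated so every
    variant passes ``p_threshold`` in the exposure GWAS (instrument-grade
    effects).  ``pleiotropy`` adds a direct variant-outcome effect alpha:
    ``balanced`` is mean-zero, ``directional`` has mean
    ``pleiotropy_magnitude``, and ``inside_violating`` correlates alpha
    with the exposure effect (breaking the InSIDE assumption).
    """

    n_snps: int = 50
    theta: float | tuple[float, float] = 0.2
    bx_sd: float = 0.02
    significant_only: bool = True
    p_threshold: float = 5e-8
    pleiotropy: str = "none"
    pleiotropy_magnitude: float = 0.0
    pleiotropy_fraction: float = 1.0
    n_exp: int = 50_000
    n_out: int = 300_000
    exposure_binary: bool = False
    exposure_correlation: float = 0.0
    ld_blocks: Optional[tuple[int, tuple[float, float]]] = None
    palindromic_fraction: float = 0.0
    flip_fraction: float = 0.0
    with_eaf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.pleiotropy_magnitude < 0:
            raise ConfigurationError("pleiotropy_magnitude must be >= 0")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigurationError("palindromic_fraction must lie in [0, 1]")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ConfigurationError("pleiotropy_fraction must lie in [0, 1]")
        if not (-1.0 < self.exposure_correlation < 1.0):
            raise ConfigurationError("exposure_correlation must lie in (-1, 1)")
        if self.n_exp <= 3 or self.n_out <= 3:
            raise ConfigurationError("sample sizes must exceed 3")


def _se_scale(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _truncated_effects(rng: np.random.Generator, n: int, sd: float,
                       threshold: np.ndarray) -> np.ndarray:
    """|effect| ~ half-normal(sd) truncated above per-variant thresholds, random sign."""
    frac = 2.0 * stats.norm.cdf(threshold / sd) - 1.0  # P(|X| <= threshold)
    v = frac + rng.uniform(size=n) * (1.0 - frac)
    mag = sd * stats.norm.ppf((v + 1.0) / 2.0)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


def _alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.uniform(size=n) < palindromic_fraction
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    plain_idx = rng.integers(0, len(_PLAIN_PAIRS), size=n)
    for i in range(n):
        ea[i], oa[i] = (_PALINDROMIC_PAIRS[pal_idx[i]] if pal[i]
                        else _PLAIN_PAIRS[plain_idx[i]])
    return ea, oa, pal


def _positions(rng: np.random.Generator, n: int,
               ld_blocks: Optional[tuple[int, tuple[float, float]]]):
    """Chromosome/position assignment and the block LD structure.

    Without blocks every variant sits alone (1 Mb spacing, chromosomes
    cycling 1..22, zero LD).  With blocks, variants are packed into the
    requested number of blocks, 10 kb apart within a block, one block per
    chromosome slot; within-block r2 is exchangeable (one draw per block
    from the configured range), across blocks zero.
    """
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=int)
    ld = LDTable()
    if ld_blocks is None:
        for i in range(n):
            chroms[i] = str(i % 22 + 1)
            pos[i] = 1_000_000 * (i // 22 + 1)
        return chroms, pos, ld, np.arange(n)
    n_blocks, (r2_lo, r2_hi) = ld_blocks
    if n_blocks < 1 or not (0.0 <= r2_lo <= r2_hi <= 1.0):
        raise ConfigurationError("ld_blocks must be (count >= 1, (r2_lo <= r2_hi) in [0,1])")
    block_of = np.arange(n) % n_blocks
    within = np.arange(n) // n_blocks
    block_r2 = rng.uniform(r2_lo, r2_hi, size=n_blocks)
    for i in range(n):
        chroms[i] = str(block_of[i] % 22 + 1)
        pos[i] = 1_000_000 * (block_of[i] // 22 + 1) + 10_000 * within[i]
    ids = [f"rs{i + 1}" for i in range(n)]
    for b in range(n_blocks):
        members = np.flatnonzero(block_of == b)
        for j in range(len(members)):
            for k in range(j + 1, len(members)):
                ld.set(ids[members[j]], ids[members[k]], block_r2[b])
    return chroms, pos, ld, block_of


def _pleiotropy(rng: np.random.Generator, cfg: SimulationConfig,
                bx: np.ndarray) -> np.ndarray:
    mag = cfg.pleiotropy_magnitude
    n = len(bx)
    if cfg.pleiotropy == "none" or mag == 0.0:
        return np.zeros(n)
    if cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, mag, size=n)
    elif cfg.pleiotropy == "directional":
        # directional per exposure-increasing allele: the pleiotropic effect
        # shares a sign once variants are oriented so that bx > 0
        alpha = np.sign(bx) * rng.normal(mag, mag / 2.0, size=n)
    else:  # inside_violating: alpha correlated with the instrument strength
        rms = np.sqrt(np.mean(bx**2))
        alpha = mag * bx / rms + rng.normal(0.0, mag / 2.0, size=n)
    if cfg.pleiotropy_fraction < 1.0:
        alpha = alpha * (rng.uniform(size=n) < cfg.pleiotropy_fraction)
    return alpha


def _assemble(trait_id, ids, chroms, pos, ea, oa, eaf, beta, se, n) -> SummaryStats:
    z = np.abs(beta / se)
    table = pd.DataFrame({
        "variant_id": ids, "chromosome": chroms, "position": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": 2.0 * stats.norm.sf(z),
        "n": n,
    })[CANONICAL_COLUMNS]
    return SummaryStats(trait_id, table)


def _flip_records(rng: np.random.Generator, ss: SummaryStats,
                  fraction: float) -> SummaryStats:
    """Store a fraction of records with swapped allele labels and negated beta.

    Harmonization must undo this; round-tripping through a flip is how the
    generator exercises the sign-fix path.
    """
    if fraction <= 0:
        return ss
    t = ss.table.copy()
    flip = rng.uniform(size=len(t)) < fraction
    ea = t.loc[flip, "effect_allele"].copy()
    t.loc[flip, "effect_allele"] = t.loc[flip, "other_allele"].values
    t.loc[flip, "other_allele"] = ea.values
    t.loc[flip, "beta"] = -t.loc[flip, "beta"]
    if t["eaf"].notna().any():
        t.loc[flip, "eaf"] = 1.0 - t.loc[flip, "eaf"]
    return SummaryStats(ss.trait_id, t)


def simulate_pair(cfg: SimulationConfig):
    """One exposure, one outcome, an LD table, and the generating truth.

    Per variant j: draw the true exposure effect bx_j, set the true outcome
    effect to theta * bx_j + alpha_j, then add estimation noise at the
    scale implied by the GWAS sample sizes.  Returns
    ``(exposure, outcome, ld, truth)`` where ``truth`` records theta, the
    alpha vector, and per-variant validity labels (alpha_j == 0).
    """
    if not np.isscalar(cfg.theta):
        raise ConfigurationError("simulate_pair expects scalar theta; use simulate_mvmr")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    ids = [f"rs{i + 1}" for i in range(n)]
    maf = rng.uniform(0.05, 0.5, size=n) if cfg.with_eaf else np.full(n, 0.3)
    se_x = _se_scale(cfg.n_exp, maf)
    se_y = _se_scale(cfg.n_out, maf)
    if cfg.significant_only:
        z_sig = stats.norm.isf(cfg.p_threshold / 2.0)
        bx = _truncated_effects(rng, n, cfg.bx_sd, z_sig * se_x)
    else:
        bx = rng.normal(0.0, cfg.bx_sd, size=n)
    alpha = _pleiotropy(rng, cfg, bx)
    by = cfg.theta * bx + alpha
    bx_hat = bx + se_x * rng.standard_normal(n)
    by_hat = by + se_y * rng.standard_normal(n)
    ea, oa, pal = _alleles(rng, n, cfg.palindromic_fraction)
    chroms, pos, ld, _blocks = _positions(rng, n, cfg.ld_blocks)
    eaf = maf if cfg.with_eaf else np.full(n, np.nan)
    exposure = _assemble("exposure", ids, chroms, pos, ea, oa, eaf,
                         bx_hat, se_x, cfg.n_exp)
    outcome = _assemble("outcome", ids, chroms, pos, ea, oa, eaf,
                        by_hat, se_y, cfg.n_out)
    outcome = _flip_records(rng, outcome, cfg.flip_fraction)
    truth = {
        "theta": float(cfg.theta),
        "alpha": alpha.tolist(),
        "valid": (alpha == 0.0).tolist(),
        "bx_true": bx.tolist(),
        "palindromic": pal.tolist(),
        "variant_ids": ids,
    }
    return exposure, outcome, ld, truth


def simulate_mvmr(cfg: SimulationConfig):
    """Two correlated exposures and an outcome: by = theta1 bx1 + theta2 bx2 + alpha.

    Both exposures' effects are drawn at instrument-grade magnitude; the
    second is mixed with the first at ``cfg.exposure_correlation``.
    Returns ``(exposure1, exposure2, outcome, ld, truth)``.
    """
    theta = np.asarray(cfg.theta, dtype=float).ravel()
    if theta.size != 2:
        raise ConfigurationError("simulate_mvmr expects theta of length 2")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    ids = [f"rs{i + 1}" for i in range(n)]
    maf = rng.uniform(0.05, 0.5, size=n) if cfg.with_eaf else np.full(n, 0.3)
    se_x = _se_scale(cfg.n_exp, maf)
    se_y = _se_scale(cfg.n_out, maf)
    if cfg.significant_only:
        z_sig = stats.norm.isf(cfg.p_threshold / 2.0)
        bx1 = _truncated_effects(rng, n, cfg.bx_sd, z_sig * se_x)
        raw2 = _truncated_effects(rng, n, cfg.bx_sd, z_sig * se_x)
    else:
        bx1 = rng.normal(0.0, cfg.bx_sd, size=n)
        raw2 = rng.normal(0.0, cfg.bx_sd, size=n)
    rho = cfg.exposure_correlation
    bx2 = rho * bx1 + np.sqrt(1.0 - rho**2) * raw2
    alpha = _pleiotropy(rng, cfg, bx1)
    by = theta[0] * bx1 + theta[1] * bx2 + alpha
    bx1_hat = bx1 + se_x * rng.standard_normal(n)
    bx2_hat = bx2 + se_x * rng.standard_normal(n)
    by_hat = by + se_y * rng.standard_normal(n)
    ea, oa, pal = _alleles(rng, n, cfg.palindromic_fraction)
    chroms, pos, ld, _blocks = _positions(rng, n, cfg.ld_blocks)
    eaf = maf if cfg.with_eaf else np.full(n, np.nan)
    exposure1 = _assemble("exposure1", ids, chroms, pos, ea, oa, eaf,
                          bx1_hat, se_x, cfg.n_exp)
    exposure2 = _assemble("exposure2", ids, chroms, pos, ea, oa, eaf,
                          bx2_hat, se_x, cfg.n_exp)
    outcome = _assemble("outcome", ids, chroms, pos, ea, oa, eaf,
                        by_hat, se_y, cfg.n_out)
    outcome = _flip_records(rng, outcome, cfg.flip_fraction)
    truth = {
        "theta": theta.tolist(),
        "alpha": alpha.tolist(),
        "valid": (alpha == 0.0).tolist(),
        "bx1_true": bx1.tolist(),
        "bx2_true": bx2.tolist(),
        "palindromic": pal.tolist(),
        "variant_ids": ids,
    }
    return exposure1, exposure2, outcome, ld, truth


@dataclass
class FixtureBundle:
    """A study-shaped synthetic dataset, writable as the pipeline's input files."""

    name: str
    exposure: SummaryStats
    outcome: SummaryStats
    second_exposure: SummaryStats
    ld: LDTable
    truth: dict
    p_threshold: float

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "exposure": directory / f"{self.exposure.trait_id}.tsv",
            "outcome": directory / f"{self.outcome.trait_id}.tsv",
            "second_exposure": directory / f"{self.second_exposure.trait_id}.tsv",
            "ld": directory / "ld.tsv",
            "truth": directory / "truth.json",
        }
        write_sumstats(self.exposure, paths["exposure"])
        write_sumstats(self.outcome, paths["outcome"])
        write_sumstats(self.second_exposure, paths["second_exposure"])
        self.ld.write(paths["ld"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


#: per-fixture design: (n_instruments, F range, true effect, exposure binary,
#: outcome binary, p threshold)
_FIXTURES = {
    "adhd_to_ea": dict(n_instruments=11, f_range=(30.0, 51.0), theta=-0.103,
                       exposure_binary=True, outcome_binary=False, p_threshold=5e-8,
                       n_exp=55_000, n_out=766_000),
    "asd_to_ea": dict(n_instruments=10, f_range=(26.0, 36.0), theta=0.004,
                      exposure_binary=True, outcome_binary=False, p_threshold=5e-7,
                      n_exp=46_000, n_out=766_000),
    "ea_to_adhd": dict(n_instruments=481, f_range=(30.0, 240.0), theta=-1.204,
                       exposure_binary=False, outcome_binary=True, p_threshold=5e-8,
                       n_exp=766_000, n_out=55_000),
    "ea_to_asd": dict(n_instruments=481, f_range=(30.0, 240.0), theta=0.412,
                      exposure_binary=False, outcome_binary=True, p_threshold=5e-8,
                      n_exp=766_000, n_out=46_000),
}

_N_COGNITIVE = 212
_N_FILLER = 20


def _instrument_grade(rng, n, f_range, se):
    """Observed effects whose F = (beta/se)^2 lies exactly in the target range."""
    f = rng.uniform(f_range[0], f_range[1], size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * np.sqrt(f) * se


def study_shaped_fixture(name: str, seed: int = 0) -> FixtureBundle:
    """Synthetic bundle sized like one of four reference analysis designs.

    ``adhd_to_ea``: 11 instruments with per-SNP F in [30, 51] at p <= 5e-8;
    ``asd_to_ea``: 10 instruments (F in [26, 36]) at the relaxed 5e-7
    threshold; ``ea_to_adhd`` / ``ea_to_asd``: 481 instruments with F in
    [30, 240].  Every bundle carries a 212-instrument second exposure
    (cognitive-ability-like) for multivariable runs, one high-LD satellite
    per lead instrument (removed by clumping, usable as a proxy), and
    non-significant filler variants.  All data are synthetic; only the
    shapes (instrument counts, F ranges, binary/continuous scales) follow
    the study design.
    """
    if name not in _FIXTURES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    spec = _FIXTURES[name]
    rng = np.random.default_rng(seed)
    n_lead = spec["n_instruments"]
    maf = 0.3
    se_x = float(_se_scale(spec["n_exp"], np.array([maf]))[0])
    se_y = float(_se_scale(spec["n_out"], np.array([maf]))[0])

    # lead instruments with F in range, one satellite each (r2 = 0.95, weaker p)
    lead_beta = _instrument_grade(rng, n_lead, spec["f_range"], se_x)
    sat_beta = np.sign(lead_beta) * (np.abs(lead_beta) - 0.05 * se_x)
    # cognitive-ability-like second exposure: its own 212 leads
    se_c = float(_se_scale(280_000, np.array([maf]))[0])
    cog_beta = _instrument_grade(rng, _N_COGNITIVE, (30.0, 240.0), se_c)
    filler_z = rng.uniform(-1.5, 1.5, size=_N_FILLER)

    theta = spec["theta"]
    theta_cog = 0.3 if not spec["outcome_binary"] else -0.5
    records = []
    vid = 0

    def add(role, beta_exp, se_exp, beta_cog, se_cog, chrom, pos):
        nonlocal vid
        vid += 1
        records.append(dict(variant_id=f"rs{vid}", chromosome=str(chrom), position=pos,
                            role=role, beta_exp=beta_exp, se_exp=se_exp,
                            beta_cog=beta_cog, se_cog=se_cog))

    for i in range(n_lead):
        chrom = i % 22 + 1
        base = 1_000_000 * (i // 22 + 1)
        add("lead", lead_beta[i], se_x, rng.normal(0.0, se_c), se_c, chrom, base)
        add("satellite", sat_beta[i], se_x, rng.normal(0.0, se_c), se_c, chrom, base + 10_000)
    for i in range(_N_COGNITIVE):
        chrom = i % 22 + 1
        base = 500_000_000 + 1_000_000 * (i // 22 + 1)
        add("cognitive", rng.normal(0.0, se_x), se_x, cog_beta[i], se_c, chrom, base)
    for i in range(_N_FILLER):
        chrom = i % 22 + 1
        base = 900_000_000 + 1_000_000 * (i // 22 + 1)
        add("filler", filler_z[i] * se_x, se_x, rng.normal(0.0, se_c), se_c, chrom, base)

    n = len(records)
    ea, oa, _pal = _alleles(rng, n, 0.0)
    ids = [r["variant_id"] for r in records]
    chroms = [r["chromosome"] for r in records]
    pos = [r["position"] for r in records]
    beta_exp = np.array([r["beta_exp"] for r in records])
    beta_cog = np.array([r["beta_cog"] for r in records])
    by = theta * beta_exp + theta_cog * beta_cog + se_y * rng.standard_normal(n)
    nan = np.full(n, np.nan)

    exposure = _assemble(name.split("_to_")[0], ids, chroms, pos, ea, oa, nan,
                         beta_exp, np.full(n, se_x), spec["n_exp"])
    cognitive = _assemble("cognitive", ids, chroms, pos, ea, oa, nan,
                          beta_cog, np.full(n, se_c), 280_000)
    outcome = _assemble(name.split("_to_")[1], ids, chroms, pos, ea, oa, nan,
                        by, np.full(n, se_y), spec["n_out"])

    ld = LDTable()
    for i in range(n_lead):
        ld.set(f"rs{2 * i + 1}", f"rs{2 * i + 2}", 0.95)

    truth = {
        "name": name,
        "theta": theta,
        "theta_cognitive": theta_cog,
        "n_instruments": n_lead,
        "f_range": list(spec["f_range"]),
        "lead_ids": [r["variant_id"] for r in records if r["role"] == "lead"],
        "exposure_binary": spec["exposure_binary"],
        "outcome_binary": spec["outcome_binary"],
        "n_exp": spec["n_exp"],
        "n_out": spec["n_out"],
    }
    return FixtureBundle(name, exposure, outcome, cognitive, ld, truth,
                         spec["p_threshold"])
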