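"""Synthetic hotspot genomes, cohort simulation, and statistical power.

The generator reconstructs a synthetic genome of hotspot positions with the
statistical structure the driver model assumes: every background position
carries a recurrence count drawn from a Poisson distribution truncated to
>= 2 (every simulated position is a hotspot by definition), covariates
(accessibility decile, sequence context, hairpin stability, didymi loop
motif) drawn from configurable generators, and a set of spiked driver
positions whose per-cohort prevalence is drawn uniformly from a 3%-15%
range.  Simulated cohorts thin the genome counts binomially to the cohort
size relative to the reference cohort; positions falling below two observed
mutations drop out of the observed catalog.  Statistical power is the
fraction of spiked drivers recovered by the full driver-calling pipeline at
BH-adjusted p < alpha, split by driver prevalence (<= 10% vs > 10%).

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .drivers import DRIVER_ALPHA, call_drivers

# Sequence-context frequencies of hotspot positions (pyrimidine-normalized
# 5' neighbor; TpC split by trinucleotide).  Chosen to reflect an
# APOBEC-dominated cohort where TpC contexts carry most hotspots.
DEFAULT_CONTEXT_PROBS: dict[str, float] = {
    "TCA": 0.30, "TCT": 0.25, "TCC": 0.12, "TCG": 0.03,
    "ApC": 0.12, "CpC": 0.10, "GpC": 0.08,
}


@dataclass(frozen=True)
class CovariateEffects:
    """Log-linear effects of covariates on the background recurrence rate.

    Defaults are zero: recurrence is then drawn from the truncated Poisson at
    ``background_lambda`` independent of covariates.
    """

    accessibility_decile: float = 0.0
    delta_g: float = 0.0
    loop_pattern: float = 0.0


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Study conditions for the synthetic genome.

    ``background_lambda`` is the rate of the underlying Poisson before
    truncation to >= 2, calibrated so that ~99% of background hotspot
    positions carry at most 3 mutations at the reference cohort size.
    ``reference_cohort_size`` is the cohort the genome counts represent;
    simulated cohorts are binomially thinned relative to it.
    """

    n_hotspot_positions: int = 1_000_000
    background_lambda: float = 0.3
    n_drivers: int = 27
    driver_prevalence_range: tuple[float, float] = (0.03, 0.15)
    reference_cohort_size: int = 115
    p_in_loop: float = 0.2
    p_loop_pattern: float = 0.15
    driver_in_loop_fraction: float = 2.0 / 3.0
    driver_loop_pattern_p: float = 0.5
    context_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_PROBS)
    )
    covariate_effects: CovariateEffects = CovariateEffects()

    def __post_init__(self):
        lo, hi = self.driver_prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("prevalence range must lie in (0, 1]")
        if self.n_drivers >= self.n_hotspot_positions:
            raise ValueError("n_drivers must be smaller than n_hotspot_positions")


def scaled_config(**overrides) -> SyntheticGenomeConfig:
    """The scaled-down preset: 100,000 background positions."""
    defaults = dict(n_hotspot_positions=100_000)
    defaults.update(overrides)
    return SyntheticGenomeConfig(**defaults)


@dataclass
class SyntheticGenome:
    positions: pd.DataFrame
    config: SyntheticGenomeConfig
    seed: int


@dataclass(frozen=True)
class PowerResult:
    cohort_size: int
    prevalence_bin: str  # "<=10%" or ">10%"
    n_replicates: int
    power: float
    power_se: float
    false_positive_rate: float


def _sample_truncated_poisson(rng: np.random.Generator, lam: np.ndarray, minimum: int = 2) -> np.ndarray:
    """Vectorized Poisson sampling conditioned on >= minimum via inverse CDF."""
    lam = np.asarray(lam, float)
    f_below = stats.poisson.cdf(minimum - 1, lam)
    if np.any(1 - f_below < 1e-12):
        raise ValueError(
            "truncation infeasible: P(X >= 2) vanishes at the configured lambda"
        )
    u = f_below + rng.random(lam.shape) * (1 - f_below)
    # guard against u == 1 rounding past the support
    u = np.minimum(u, 1 - 1e-16)
    return stats.poisson.ppf(u, lam).astype(int)


def _sample_contexts(rng: np.random.Generator, probs: Mapping[str, float], n: int,
                     allowed: Optional[Sequence[str]] = None):
    labels = list(probs)
    p = np.array([probs[k] for k in labels], float)
    if allowed is not None:
        mask = np.array([k in allowed for k in labels])
        labels = [k for k, m in zip(labels, mask) if m]
        p = p[mask]
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    strata = np.array(labels, object)[idx]
    trinuc = np.where(np.char.startswith(strata.astype(str), "TC"), strata, "NCN")
    group = np.where(
        np.char.startswith(strata.astype(str), "TC"), "TpC", strata
    )
    return trinuc.astype(object), group.astype(object)


def generate_synthetic_genome(
    config: SyntheticGenomeConfig = SyntheticGenomeConfig(), seed: int = 0
) -> SyntheticGenome:
    """Synthetic catalog of background hotspot positions plus spiked drivers.

    Exactly ``n_hotspot_positions`` background positions receive recurrence
    counts from the truncated Poisson; ``n_drivers`` extra positions are
    flagged as true drivers with a target prevalence drawn uniformly from the
    configured range.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_hotspot_positions
    eff = config.covariate_effects

    decile = rng.integers(1, 11, size=n)
    in_loop = rng.random(n) < config.p_in_loop
    delta_g = np.where(in_loop, -(0.5 + rng.exponential(1.5, size=n)), np.nan)
    loop_pattern = in_loop & (rng.random(n) < config.p_loop_pattern)
    trinuc, group = _sample_contexts(rng, config.context_probs, n)

    log_rate = np.log(config.background_lambda) + eff.accessibility_decile * (decile - 5.5)
    log_rate = log_rate + np.where(in_loop, eff.delta_g * np.nan_to_num(delta_g), 0.0)
    log_rate = log_rate + eff.loop_pattern * loop_pattern
    recurrence = _sample_truncated_poisson(rng, np.exp(log_rate))

    background = pd.DataFrame(
        {
            "chrom": "sim",
            "pos": np.arange(1, n + 1),
            "n_mut": recurrence,
            "trinucleotide": trinuc,
            "context_group": group,
            "in_loop": in_loop,
            "delta_g": delta_g,
            "loop_pattern": loop_pattern,
            "accessibility_decile": decile,
            "is_driver": False,
            "prevalence": 0.0,
        }
    )

    d = config.n_drivers
    lo, hi = config.driver_prevalence_range
    prevalence = rng.uniform(lo, hi, size=d)
    drv_in_loop = rng.random(d) < config.driver_in_loop_fraction
    drv_tri_out, drv_grp_out = _sample_contexts(
        rng, config.context_probs, d, allowed=["TCA", "TCT", "TCC", "TCG"]
    )
    drv_tri_any, drv_grp_any = _sample_contexts(rng, config.context_probs, d)
    drv_tri = np.where(drv_in_loop, drv_tri_any, drv_tri_out)
    drv_grp = np.where(drv_in_loop, drv_grp_any, drv_grp_out)
    drivers = pd.DataFrame(
        {
            "chrom": "sim",
            "pos": np.arange(n + 1, n + d + 1),
            "n_mut": stats.binom.ppf(
                rng.random(d), config.reference_cohort_size, prevalence
            ).astype(int),
            "trinucleotide": drv_tri,
            "context_group": drv_grp,
            "in_loop": drv_in_loop,
            "delta_g": np.where(
                drv_in_loop, -(0.5 + rng.exponential(1.5, size=d)), np.nan
            ),
            "loop_pattern": drv_in_loop & (rng.random(d) < config.driver_loop_pattern_p),
            "accessibility_decile": rng.integers(1, 11, size=d),
            "is_driver": True,
            "prevalence": prevalence,
        }
    )
    positions = pd.concat([background, drivers], ignore_index=True)
    return SyntheticGenome(positions=positions, config=config, seed=seed)


def simulate_cohort(
    genome: SyntheticGenome, n_samples: int, seed: int = 0
) -> pd.DataFrame:
    """Observed hotspot catalog for a cohort of ``n_samples`` tumors.

    Background counts are binomially thinned by n_samples / reference size
    (cohorts larger than the reference superpose the excess rate as Poisson
    counts, keeping the expectation linear in cohort size); driver counts are
    Binomial(n_samples, prevalence).  Positions with fewer than two observed
    mutations drop out.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    df = genome.positions
    ref = genome.config.reference_cohort_size
    f = n_samples / ref
    r = df["n_mut"].to_numpy(int)
    obs = rng.binomial(r, min(f, 1.0))
    if f > 1:
        obs = obs + rng.poisson(r * (f - 1))
    is_driver = df["is_driver"].to_numpy(bool)
    obs = np.where(
        is_driver,
        rng.binomial(n_samples, df["prevalence"].to_numpy(float).clip(0, 1)),
        obs,
    )
    out = df.copy()
    out["n_mut"] = obs
    return out[obs >= 2]


def power_analysis(
    config: SyntheticGenomeConfig = SyntheticGenomeConfig(),
    cohort_sizes: Sequence[int] = (75,),
    n_replicates: int = 100,
    alpha: float = DRIVER_ALPHA,
    seed: int = 0,
    prevalence_split: float = 0.10,
) -> pd.DataFrame:
    """Detection power of the driver pipeline on simulated cohorts.

    For each cohort size, ``n_replicates`` cohorts are simulated from one
    synthetic genome and run through the full pipeline (leave-one-out Poisson
    background, exact Poisson test, per-group BH).  Power is the fraction of
    true drivers called at adjusted p < ``alpha``, reported separately for
    drivers with prevalence <= / > ``prevalence_split`` together with a
    Monte-Carlo standard error and the background false-positive rate.
    """
    ss = np.random.SeedSequence(seed)
    genome_seed, cohort_entropy = ss.spawn(2)
    genome = generate_synthetic_genome(config, seed=genome_seed.generate_state(1)[0] % (2**31))
    truth = genome.positions
    driver_idx = truth.index[truth["is_driver"]]
    prev = truth.loc[driver_idx, "prevalence"]
    bins = {
        "<=10%": driver_idx[prev <= prevalence_split],
        ">10%": driver_idx[prev > prevalence_split],
    }
    rows = []
    rep_seeds = cohort_entropy.spawn(len(cohort_sizes) * n_replicates)
    k = 0
    for size in cohort_sizes:
        hits = {b: [] for b in bins}
        fprs = []
        for _ in range(n_replicates):
            cohort = simulate_cohort(
                genome, size, seed=rep_seeds[k].generate_state(1)[0] % (2**31)
            )
            k += 1
            calls = call_drivers(cohort, alpha=alpha)
            called = set(calls.index[calls["is_driver"]])
            for b, idx in bins.items():
                if len(idx):
                    hits[b].append(np.mean([i in called for i in idx]))
            n_bg_catalog = int((~cohort["is_driver"]).sum())
            n_bg_called = len(called - set(driver_idx))
            fprs.append(n_bg_called / n_bg_catalog if n_bg_catalog else 0.0)
        for b, idx in bins.items():
            if not len(idx):
                continue
            h = np.array(hits[b])
            rows.append(
                PowerResult(
                    cohort_size=size,
                    prevalence_bin=b,
                    n_replicates=n_replicates,
                    power=float(h.mean()),
                    power_se=float(h.std(ddof=1) / np.sqrt(len(h))) if len(h) > 1 else 0.0,
                    false_positive_rate=float(np.mean(fprs)),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
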