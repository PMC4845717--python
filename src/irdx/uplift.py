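"""Stratified weighted diagnostic-yield uplift with simulated confidence bands.

The referral population of size ``N`` contains ``N_s`` patients in each
outcome stratum ``s``; a stratified subsample of ``n_s`` patients per stratum
is re-sequenced on the new assay and ``k_s`` of them gain a diagnosis.  The
projected number of new diagnoses is the stratum-weighted plug-in estimate

    E[new] = sum_s N_s * (k_s / n_s)

and the relative uplift is ``100 * E[new] / D`` where ``D`` is the baseline
number of diagnoses (an ``absolute`` switch reports percentage points of the
population instead).  The confidence interval is a parametric bootstrap:
each replicate redraws ``k_s* ~ Binomial(n_s, k_s/n_s)`` per stratum and,
unless disabled, the population composition ``N_s* ~ Binomial(N, N_s/N)`` and
baseline ``D* ~ Binomial(N, D/N)``; empirical percentiles (linear
interpolation) of the replicate uplifts give the interval.  A fixed seed
makes the output bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .types import IrdxError, StratumSpec


class UpliftError(IrdxError):
    pass


@dataclass
class UpliftConfig:
    n_sims: int = 10_000
    ci_lo: float = 2.5
    ci_hi: float = 97.5
    seed: Optional[int] = None
    simulate_prevalence: bool = True
    absolute: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.ci_lo < self.ci_hi <= 100):
            raise UpliftError(f"invalid percentile bounds [{self.ci_lo}, {self.ci_hi}]")
        if self.n_sims < 1:
            raise UpliftError("n_sims must be >= 1")


@dataclass
class UpliftEstimate:
    point: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    expected_new_diagnoses: float
    n_sims: int = 0
    seed: Optional[int] = None
    absolute: bool = False

    def to_report(self) -> dict:
        return {
            "point": round(self.point, 2),
            "ci_low": None if self.ci_low is None else round(self.ci_low, 2),
            "ci_high": None if self.ci_high is None else round(self.ci_high, 2),
            "expected_new_diagnoses": round(self.expected_new_diagnoses, 2),
            "n_sims": self.n_sims,
            "seed": self.seed,
            "scale": "percentage_points_of_population" if self.absolute
                     else "percent_of_baseline_diagnoses",
        }


def _validate(strata: Sequence[StratumSpec], baseline_diagnosed: int, pop_total: int):
    if baseline_diagnosed <= 0:
        raise UpliftError("baseline diagnoses D must be > 0 (relative uplift undefined)")
    if pop_total <= 0:
        raise UpliftError("population total N must be > 0")
    for s in strata:
        if s.sample_size == 0 and s.pop_count > 0:
            raise UpliftError(
                f"stratum {s.label}: population weight without any sampled patients"
            )


def point_uplift(
    strata: Sequence[StratumSpec],
    baseline_diagnosed: int,
    pop_total: int,
    absolute: bool = False,
) -> UpliftEstimate:
    """Plug-in stratum-weighted uplift estimate (no interval)."""
    _validate(strata, baseline_diagnosed, pop_total)
    expected_new = sum(
        s.pop_count * (s.new_diag / s.sample_size) for s in strata if s.sample_size
    )
    denom = pop_total if absolute else baseline_diagnosed
    return UpliftEstimate(
        point=100.0 * expected_new / denom,
        ci_low=None,
        ci_high=None,
        expected_new_diagnoses=expected_new,
        absolute=absolute,
    )


def simulate_ci(
    strata: Sequence[StratumSpec],
    baseline_diagnosed: int,
    pop_total: int,
    config: Optional[UpliftConfig] = None,
) -> UpliftEstimate:
    """Parametric-bootstrap percentile interval around the plug-in estimate.

    Replicate draws are consumed in stratum order from a single seeded
    generator, so a fixed seed yields bit-identical results.
    """
    config = config or UpliftConfig()
    if config.n_sims < 2:
        raise UpliftError("confidence interval undefined for n_sims < 2")
    base = point_uplift(strata, baseline_diagnosed, pop_total, config.absolute)
    rng = np.random.default_rng(config.seed)

    n_sims = config.n_sims
    new = np.zeros(n_sims)
    for s in strata:
        if s.sample_size == 0:
            continue
        if s.sample_size >= s.pop_count:
            # census limit: the whole stratum was observed, so its
            # contribution carries no sampling uncertainty
            new = new + s.pop_count * (s.new_diag / s.sample_size)
            continue
        p = s.new_diag / s.sample_size
        k_star = rng.binomial(s.sample_size, p, size=n_sims)
        if config.simulate_prevalence:
            n_star = rng.binomial(pop_total, s.pop_count / pop_total, size=n_sims)
        else:
            n_star = s.pop_count
        new = new + n_star * (k_star / s.sample_size)

    if config.absolute:
        denom = np.full(n_sims, float(pop_total))
    elif config.simulate_prevalence:
        denom = rng.binomial(pop_total, baseline_diagnosed / pop_total,
                             size=n_sims).astype(float)
        # a zero baseline draw leaves the replicate uplift undefined; redraw
        while (denom == 0).any():
            mask = denom == 0
            denom[mask] = rng.binomial(pop_total, baseline_diagnosed / pop_total,
                                       size=int(mask.sum()))
    else:
        denom = np.full(n_sims, float(baseline_diagnosed))

    uplifts = 100.0 * new / denom
    lo, hi = np.percentile(uplifts, [config.ci_lo, config.ci_hi])
    return UpliftEstimate(
        point=base.point,
        ci_low=float(lo),
        ci_high=float(hi),
        expected_new_diagnoses=base.expected_new_diagnoses,
        n_sims=n_sims,
        seed=config.seed,
        absolute=config.absolute,
    )


@dataclass(frozen=True)
class StratumTruth:
    """Generating truth for one stratum in a coverage experiment."""

    label: str
    pop_count: int
    sample_size: int
    yield_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.yield_prob <= 1.0:
            raise UpliftError(f"stratum {self.label}: yield probability outside [0, 1]")


def coverage_check(
    truth: Sequence[StratumTruth],
    baseline_diagnosed: int,
    pop_total: int,
    config: Optional[UpliftConfig] = None,
    n_experiments: int = 200,
    seed: Optional[int] = None,
) -> float:
    """Empirical coverage of the simulated interval on a known truth.

    Repeatedly draws stratified samples ``k_s ~ Binomial(n_s, q_s)`` from the
    generating yields, computes :func:`simulate_ci` on each sample, and
    returns the fraction of experiments whose interval contains the true
    uplift ``100 * sum_s N_s q_s / D``.
    """
    config = config or UpliftConfig(simulate_prevalence=False)
    rng = np.random.default_rng(seed)
    true_new = sum(t.pop_count * t.yield_prob for t in truth)
    denom = pop_total if config.absolute else baseline_diagnosed
    true_uplift = 100.0 * true_new / denom
    covered = 0
    for _ in range(n_experiments):
        strata = [
            StratumSpec(t.label, t.pop_count, t.sample_size,
                        int(rng.binomial(t.sample_size, t.yield_prob)))
            for t in truth
        ]
        ci_seed = int(rng.integers(0, 2**31 - 1))
        est = simulate_ci(
            strata, baseline_diagnosed, pop_total,
            UpliftConfig(
                n_sims=config.n_sims, ci_lo=config.ci_lo, ci_hi=config.ci_hi,
                seed=ci_seed, simulate_prevalence=config.simulate_prevalence,
                absolute=config.absolute,
            ),
        )
        if est.ci_low <= true_uplift <= est.ci_high:
            covered += 1
    return covered / n_experiments
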