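"""Aggregated Poisson detection of ctDNA signal.

Per-target unique-molecule observations are summed across the bespoke panel:
k alt-supporting molecules out of M total unique molecules, with an expected
background of lambda = sum(e_t * M_t) molecules under the substitution error
model. Detection is a one-tailed Poisson test of k against lambda; the sample
is called ctDNA-positive when P(X >= k) <= 0.001, a threshold chosen to hold
analytical specificity above 99.9%. Tumor burden is reported in ppm
(10^6 * k / M) and optionally as tumor molecules per ml plasma. The module
also predicts the panel's 95% limit of detection and stratifies a cohort of
results around the median detected level.
"""
from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import poisson


@dataclass(frozen=True)
class TargetObservation:
    """Unique-molecule counts at one panel target in one plasma sample."""

    target_id: str
    total_molecules: int
    alt_molecules: int
    noise_rate: float
    active: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.alt_molecules <= self.total_molecules:
            raise ValueError(
                f"{self.target_id}: need 0 <= alt <= total, got "
                f"{self.alt_molecules}/{self.total_molecules}"
            )
        if not self.noise_rate > 0:
            raise ValueError(f"{self.target_id}: noise_rate must be > 0")


@dataclass
class SampleDetectionResult:
    """Aggregated detection call for one plasma sample."""

    k: int
    M: int
    lambda_noise: float
    ppm: float
    p_value: float
    detected: bool
    sample_id: str | None = None
    tumor_molecules_per_ml: float | None = None


@dataclass(frozen=True)
class LodEstimate:
    """Predicted 95% limit of detection for a panel configuration."""

    lod95_ppm: float
    p_threshold: float
    sensitivity_target: float
    assumed_M: float
    assumed_lambda: float
    k_crit: int
    method: Literal["analytic", "monte_carlo"]


@dataclass
class CohortStratification:
    """negative / low / high grouping of a cohort around the detected median."""

    groups: dict[str, Literal["negative", "low", "high"]]
    median_ppm_of_detected: float | None


def aggregate_panel_signal(
    observations: Sequence[TargetObservation], active_only: bool = True
) -> tuple[int, int, float]:
    """Sum signal, molecules, and expected noise across (active) targets.

    Returns (k, M, lambda_noise). Deactivated targets contribute nothing.
    """
    obs = [o for o in observations if o.active] if active_only else list(observations)
    if not obs:
        raise ValueError("no active target observations to aggregate")
    k = sum(o.alt_molecules for o in obs)
    M = sum(o.total_molecules for o in obs)
    lam = sum(o.noise_rate * o.total_molecules for o in obs)
    return k, M, lam


def compute_ppm(k: int, M: int) -> float:
    """Tumor fraction in parts per million of total unique molecules."""
    if M <= 0:
        raise ValueError("total unique molecule count M must be > 0")
    return 1e6 * k / M


def poisson_detection_test(k: int, lambda_noise: float) -> float:
    """One-tailed Poisson p-value P(X >= k) under noise mean lambda."""
    if lambda_noise <= 0:
        raise ValueError("lambda_noise must be > 0 (floor noise rates upstream)")
    if k < 0 or k != int(k):
        raise ValueError("k must be a non-negative integer")
    # inclusive upper tail: survival function evaluated at k - 1; overwhelming
    # signal can underflow double precision, so clamp to a tiny positive p
    # rather than reporting an impossible zero
    return max(float(poisson.sf(k - 1, lambda_noise)), 5e-324)


def call_detection_status(p_value: float, p_threshold: float = 0.001) -> bool:
    """ctDNA-positive iff the signal is significantly above noise."""
    if not 0 < p_value <= 1:
        raise ValueError("p_value must lie in (0, 1]")
    return p_value <= p_threshold


def tumor_molecules_per_ml(k: int, plasma_volume_ml: float) -> float:
    """Tumor-derived unique molecules per ml of input plasma."""
    if plasma_volume_ml <= 0:
        raise ValueError("plasma volume must be > 0 ml")
    return k / plasma_volume_ml


def detect_sample(
    observations: Sequence[TargetObservation],
    p_threshold: float = 0.001,
    plasma_volume_ml: float | None = None,
    sample_id: str | None = None,
) -> SampleDetectionResult:
    """Aggregate a sample's target observations and call detection status."""
    k, M, lam = aggregate_panel_signal(observations)
    p = poisson_detection_test(k, lam)
    return SampleDetectionResult(
        k=k,
        M=M,
        lambda_noise=lam,
        ppm=compute_ppm(k, M),
        p_value=p,
        detected=call_detection_status(p, p_threshold),
        sample_id=sample_id,
        tumor_molecules_per_ml=(
            tumor_molecules_per_ml(k, plasma_volume_ml)
            if plasma_volume_ml is not None
            else None
        ),
    )


def critical_signal_count(lambda_noise: float, p_threshold: float = 0.001) -> int:
    """Smallest k whose one-tailed Poisson p-value reaches significance."""
    if lambda_noise <= 0:
        raise ValueError("lambda_noise must be > 0")
    k = 0
    while poisson_detection_test(k, lambda_noise) > p_threshold:
        k += 1
    return k


def predict_panel_lod(
    assumed_M: float,
    assumed_lambda: float,
    p_threshold: float = 0.001,
    sensitivity_target: float = 0.95,
    method: Literal["analytic", "monte_carlo"] = "analytic",
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> LodEstimate:
    """Predict the tumor fraction detectable with 95% sensitivity.

    The detection decision reduces to k >= k_crit, the smallest count
    significant against the noise mean. Analytically, the LOD is the signal
    mean mu* at which P(Poisson(mu*) >= k_crit) reaches the sensitivity
    target, converted to ppm as 10^6 * (mu* - lambda) / M (tumor molecules in
    excess of noise). The Monte-Carlo variant instead simulates detection
    across a tumor-fraction grid and returns the first grid point reaching
    the target sensitivity; the two agree within Monte-Carlo error.
    """
    if assumed_M <= 0:
        raise ValueError("assumed_M must be > 0")
    if assumed_lambda <= 0:
        raise ValueError("assumed_lambda must be > 0")
    if not 0 < sensitivity_target < 1:
        raise ValueError("sensitivity_target must lie in (0, 1)")
    k_crit = critical_signal_count(assumed_lambda, p_threshold)

    def sensitivity(mu: float) -> float:
        return float(poisson.sf(k_crit - 1, mu))

    if method == "analytic":
        lo, hi = 0.0, max(float(k_crit), 1.0)
        while sensitivity(hi) < sensitivity_target:
            hi *= 2.0
            if hi > 1e12:
                raise ValueError("sensitivity target unreachable")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if sensitivity(mid) >= sensitivity_target:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-9 * max(hi, 1.0):
                break
        mu_star = hi
        lod_ppm = 1e6 * (mu_star - assumed_lambda) / assumed_M
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)

        def empirical_sensitivity(f_ppm: float) -> float:
            mu = assumed_lambda + f_ppm * 1e-6 * assumed_M
            k = rng.poisson(mu, size=n_replicates)
            return float(np.mean(k >= k_crit))

        f_hi = 1e6 / assumed_M  # one expected tumor molecule
        while empirical_sensitivity(f_hi) < sensitivity_target:
            f_hi *= 2.0
            if f_hi > 1e6:
                raise ValueError("sensitivity target unreachable")
        grid = np.linspace(f_hi / 2.0, f_hi, 64)
        lod_ppm = float(f_hi)
        for f in grid:
            if empirical_sensitivity(float(f)) >= sensitivity_target:
                lod_ppm = float(f)
                break
    else:
        raise ValueError(f"unknown method {method!r}")

    if not lod_ppm > 0 or not math.isfinite(lod_ppm):
        raise ValueError("LOD estimate is not a positive finite ppm value")
    return LodEstimate(
        lod95_ppm=lod_ppm,
        p_threshold=p_threshold,
        sensitivity_target=sensitivity_target,
        assumed_M=assumed_M,
        assumed_lambda=assumed_lambda,
        k_crit=k_crit,
        method=method,
    )


def stratify_cohort_by_median(
    results: Sequence[SampleDetectionResult],
) -> CohortStratification:
    """Assign each sample to negative / low / high ctDNA groups.

    Undetected samples are negative. Detected samples at or below the median
    detected ppm are low, above it high (ties go to low). With no detected
    samples every sample is negative and the median is unset.
    """
    groups: dict[str, str] = {}
    detected = [r for r in results if r.detected]
    median: float | None = None
    if detected:
        median = float(statistics.median(r.ppm for r in detected))
    for i, r in enumerate(results):
        key = r.sample_id if r.sample_id is not None else f"sample_{i}"
        if not r.detected:
            groups[key] = "negative"
        elif r.ppm <= median:
            groups[key] = "low"
        else:
            groups[key] = "high"
    return CohortStratification(groups=groups, median_ppm_of_detected=median)
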