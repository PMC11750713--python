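"""Synthetic data generation for the whole pipeline.

Patient plasma for this assay is controlled-access, so every stage is
exercised against simulated data with known truth:

- tumor/normal somatic SNV call sets plus genomic exclusion intervals
  (fixtures for panel design);
- healthy-plasma background cohorts of per-substitution-class molecule
  counts (input to the error-model estimator);
- duplex cfDNA read families per panel target at a controlled tumor
  fraction, with Poisson molecule yields, zero-truncated Poisson family
  sizes per strand, per-base sequencing error, and a discrete Phred quality
  profile (input to consensus and detection);
- fast count-level draws of the aggregated panel signal (for specificity
  and limit-of-detection studies at realistic panel scale).

All generators are reproducible bit-for-bit from their seed.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .consensus import (
    BOTTOM,
    TOP,
    AlignedReadPair,
    consensus_pipeline,
    genotype_molecule_at_target,
)
from .detection import (
    SampleDetectionResult,
    TargetObservation,
    detect_sample,
)
from .panel_design import (
    SUBSTITUTION_CLASSES,
    BespokePanel,
    GenomicExclusionSet,
    QaSnv,
    SomaticVariantCall,
)

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default per-molecule background error rates after duplex consensus.
#: Deamination-driven transitions dominate; transversions are rarest.
DEFAULT_CLASS_ERROR_RATES: dict[str, float] = {
    "C>T": 5e-6,
    "G>A": 5e-6,
    "A>G": 1e-6,
    "T>C": 1e-6,
    **{c: 1e-7 for c in SUBSTITUTION_CLASSES
       if c not in ("C>T", "G>A", "A>G", "T>C")},
}

#: Smoking-associated tumor mutation spectrum (C>A transversion heavy),
#: used when drawing substitution classes for simulated somatic variants.
SMOKING_SPECTRUM: dict[str, float] = {
    "C>A": 0.25,
    "G>T": 0.25,
    "C>T": 0.06,
    "G>A": 0.06,
    **{c: 0.0475 for c in SUBSTITUTION_CLASSES
       if c not in ("C>A", "G>T", "C>T", "G>A")},
}

DEFAULT_CONTIGS: dict[str, int] = {
    "1": 40_000_000,
    "2": 35_000_000,
    "3": 30_000_000,
    "4": 25_000_000,
}


@dataclass(frozen=True)
class SimulationTruth:
    """The data-generating conditions for one simulated plasma sample."""

    tumor_fraction: float  # fraction of molecules that are tumor-derived
    mean_molecules_per_target: float = 1666.0
    family_size_mean: float = 2.0  # per-strand, zero-truncated Poisson
    min_reads_per_strand: int = 1  # floor applied to each family-size draw
    per_base_error_rate: float = 1e-3
    fragment_length: int = 166  # mononucleosomal cfDNA; +/-10 bp jitter
    quality_values: tuple[int, ...] = (37, 25, 11)
    quality_probs: tuple[float, ...] = (0.94, 0.05, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.mean_molecules_per_target <= 0:
            raise ValueError("mean molecule yield must be > 0")
        if self.family_size_mean <= 0:
            raise ValueError("family_size_mean must be > 0")
        if self.min_reads_per_strand < 1:
            raise ValueError("min_reads_per_strand must be >= 1")
        if not 0.0 <= self.per_base_error_rate < 0.5:
            raise ValueError("per_base_error_rate must lie in [0, 0.5)")
        if self.fragment_length < 30:
            raise ValueError("fragment_length too short")
        if len(self.quality_values) != len(self.quality_probs):
            raise ValueError("quality profile values/probs length mismatch")
        if abs(sum(self.quality_probs) - 1.0) > 1e-9:
            raise ValueError("quality profile probabilities must sum to 1")


@dataclass
class SimulatedPlasmaSample:
    """Read pairs plus the exact per-target and per-molecule truth."""

    pairs: list[AlignedReadPair]
    per_target: dict[str, dict[str, int]]
    # fragment_key -> list of (target_id, true base at the target locus)
    molecule_truth: dict[tuple[str, int, int], list[tuple[str, str]]]

    @property
    def true_alt_molecules(self) -> int:
        return sum(t["n_tumor_alt"] for t in self.per_target.values())


def _draw_af(af_distribution, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(af_distribution):
        afs = np.asarray(af_distribution(rng, n), dtype=float)
    else:
        a, b = af_distribution
        if not (a > 0 and b > 0):
            raise ValueError("Beta parameters must be positive")
        afs = rng.beta(a, b, size=n)
    if afs.shape != (n,) or np.any(afs < 0) or np.any(afs > 1):
        raise ValueError("allele frequencies must be n values in [0, 1]")
    return afs


def simulate_tumor_normal_variants(
    n_variants: int,
    af_distribution: tuple[float, float] | Callable = (5.0, 5.0),
    exclusion_fraction: float = 0.10,
    seed: int = 0,
    contigs: Mapping[str, int] = DEFAULT_CONTIGS,
    spectrum: Mapping[str, float] = SMOKING_SPECTRUM,
) -> tuple[list[SomaticVariantCall], list[GenomicExclusionSet], list[dict]]:
    """Generate a somatic SNV call set with truth labels.

    A stated fraction of the calls is placed inside generated exclusion
    intervals (cycling through the exclusion categories). Returns
    (calls, exclusion_sets, truth) where each truth record carries the
    call's coordinates, its AF, whether it sits in an exclusion interval,
    and whether it is designable (AF > 0.10 and not excluded).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 <= exclusion_fraction <= 1.0:
        raise ValueError("exclusion_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chrom_names = sorted(contigs)
    lengths = np.array([contigs[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    afs = _draw_af(af_distribution, rng, n_variants)
    classes = list(spectrum)
    class_probs = np.array([spectrum[c] for c in classes])
    class_probs = class_probs / class_probs.sum()
    drawn = rng.choice(len(classes), size=n_variants, p=class_probs)
    excluded = rng.random(n_variants) < exclusion_fraction

    categories = sorted(c for c in
                        {"germline_snp", "chip_region", "polymorphic",
                         "mapping_difficulty", "short_tandem_repeat",
                         "low_complexity"})
    excl_intervals: dict[str, list[tuple[str, int, int]]] = {c: [] for c in categories}
    calls: list[SomaticVariantCall] = []
    truth: list[dict] = []
    seen: set[tuple[str, int]] = set()
    cat_i = 0
    for i in range(n_variants):
        ci = rng.choice(len(chrom_names), p=probs)
        chrom = chrom_names[ci]
        while True:
            pos = int(rng.integers(2_000, contigs[chrom] - 2_000))
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                break
        ref, alt = classes[drawn[i]].split(">")
        call = SomaticVariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                  tumor_af=float(afs[i]),
                                  tumor_depth=int(rng.integers(20, 80)))
        calls.append(call)
        if excluded[i]:
            half = int(rng.integers(10, 60))
            excl_intervals[categories[cat_i % len(categories)]].append(
                (chrom, max(pos - 1 - half, 0), pos + half)
            )
            cat_i += 1
        truth.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "tumor_af": float(afs[i]),
                "in_exclusion": bool(excluded[i]),
                "designable": bool(not excluded[i] and afs[i] > 0.10),
            }
        )
    exclusion_sets = [
        GenomicExclusionSet(category=c, intervals=tuple(ivs))
        for c, ivs in excl_intervals.items()
        if ivs
    ]
    return calls, exclusion_sets, truth


def simulate_background_cohort(
    n_samples: int = 200,
    true_class_rates: Mapping[str, float] | None = None,
    molecules_per_sample: int = 1_000_000,
    seed: int = 0,
) -> dict[str, list[tuple[int, int]]]:
    """Draw a healthy-plasma background cohort of per-class molecule counts.

    Each sample contributes ``molecules_per_sample`` molecules per class and a
    binomial alt-supporting count at the class's true error rate. The output
    feeds :func:`ctdna_mrd.panel_design.estimate_substitution_error_model`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rates = dict(true_class_rates or DEFAULT_CLASS_ERROR_RATES)
    missing = set(SUBSTITUTION_CLASSES) - set(rates)
    if missing:
        raise ValueError(f"true_class_rates missing classes: {sorted(missing)}")
    for cls, r in rates.items():
        if not 0 < r <= 1e-3:
            raise ValueError(f"rate for {cls} must lie in (0, 1e-3], got {r}")
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[tuple[int, int]]] = {}
    for cls in SUBSTITUTION_CLASSES:
        alts = rng.binomial(molecules_per_sample, rates[cls], size=n_samples)
        cohort[cls] = [(int(a), molecules_per_sample) for a in alts]
    return cohort


def simulate_qa_snv_catalog(
    n: int = 120,
    seed: int = 0,
    subpopulations: Sequence[str] = ("afr", "amr", "eas", "eur", "sas"),
    contigs: Mapping[str, int] = DEFAULT_CONTIGS,
) -> list[QaSnv]:
    """A synthetic population SNP catalog with subpopulation frequencies."""
    rng = np.random.default_rng(seed)
    chrom_names = sorted(contigs)
    catalog = []
    for i in range(n):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(2_000, contigs[chrom] - 2_000))
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        freq = float(rng.uniform(0.05, 0.55))
        spread = float(rng.uniform(0.0, 0.25))
        subs = {
            p: float(np.clip(freq + rng.uniform(-spread / 2, spread / 2), 0, 1))
            for p in subpopulations
        }
        catalog.append(
            QaSnv(
                chrom=chrom,
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                population_frequency=freq,
                hwe_pass=bool(rng.random() > 0.05),
                subpopulation_frequencies=subs,
            )
        )
    return catalog


def _zero_truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    k = 0
    while k == 0:
        k = int(rng.poisson(mean))
    return k


def simulate_plasma_sample(
    panel: BespokePanel, truth: SimulationTruth
) -> SimulatedPlasmaSample:
    """Simulate duplex cfDNA read families over a panel.

    Per target: unique molecule count ~ Poisson(mean yield); each molecule is
    tumor-derived (alt) with probability f, otherwise converted to alt by
    background error at the target's class rate; each molecule emits a
    zero-truncated-Poisson number of read pairs from each strand; per-base
    sequencing errors and quality scores are injected per read. Fragments are
    mononucleosome-sized with +/-10 bp length jitter and a random offset over
    the target, so distinct molecules usually (not always) have distinct
    positional keys -- positional collisions are part of what the consensus
    splitter must handle.
    """
    if not panel.targets:
        raise ValueError("cannot simulate plasma for an empty panel")
    rng = np.random.default_rng(truth.seed)
    qual_cum = np.cumsum(np.asarray(truth.quality_probs, dtype=float))
    qual_vals = np.asarray(truth.quality_values, dtype=np.int16)
    f = truth.tumor_fraction
    l_lo = truth.fragment_length - 10
    l_hi = truth.fragment_length + 10

    pairs: list[AlignedReadPair] = []
    per_target: dict[str, dict[str, int]] = {}
    molecule_truth: dict[tuple[str, int, int], list[tuple[str, str]]] = {}

    for target in panel.targets:
        # deterministic local reference window around the target
        window_start = target.pos - 1 - (l_hi + 5)
        window_len = 2 * (l_hi + 5) + 1
        window = _BASE_CODES[rng.integers(0, 4, size=window_len)]
        window[target.pos - 1 - window_start] = ord(target.ref)

        n_molecules = int(rng.poisson(truth.mean_molecules_per_target))
        n_tumor_alt = 0
        n_noise_alt = 0
        for mi in range(n_molecules):
            frag_len = int(rng.integers(l_lo, l_hi + 1))
            offset = int(rng.integers(0, frag_len))
            start = target.pos - 1 - offset
            end = start + frag_len
            key = (target.chrom, start, end)
            mol = window[start - window_start:end - window_start].copy()
            is_tumor = rng.random() < f
            is_noise_alt = (not is_tumor) and rng.random() < target.error_rate
            if is_tumor or is_noise_alt:
                mol[offset] = ord(target.alt)
            n_tumor_alt += is_tumor
            n_noise_alt += is_noise_alt
            true_base = target.alt if (is_tumor or is_noise_alt) else target.ref
            molecule_truth.setdefault(key, []).append((target.target_id, true_base))

            for strand in (TOP, BOTTOM):
                n_reads = max(
                    _zero_truncated_poisson(rng, truth.family_size_mean),
                    truth.min_reads_per_strand,
                )
                for ri in range(n_reads):
                    read = mol.copy()
                    if truth.per_base_error_rate > 0:
                        err = rng.random(frag_len) < truth.per_base_error_rate
                        n_err = int(err.sum())
                        if n_err:
                            idx = np.nonzero(err)[0]
                            shift = rng.integers(1, 4, size=n_err)
                            cur = np.searchsorted(_BASE_CODES, read[idx])
                            read[idx] = _BASE_CODES[(cur + shift) % 4]
                    quals = qual_vals[np.searchsorted(qual_cum, rng.random(frag_len))]
                    pairs.append(
                        AlignedReadPair(
                            fragment_key=key,
                            strand_tag=strand,
                            bases=read.tobytes().decode("ascii"),
                            quals=quals,
                            read_id=f"{target.target_id}|m{mi}|{strand}{ri}",
                        )
                    )
        per_target[target.target_id] = {
            "n_molecules": n_molecules,
            "n_tumor_alt": n_tumor_alt,
            "n_noise_alt": n_noise_alt,
        }
    return SimulatedPlasmaSample(
        pairs=pairs, per_target=per_target, molecule_truth=molecule_truth
    )


def run_end_to_end(
    panel: BespokePanel,
    truth: SimulationTruth,
    p_threshold: float = 0.001,
    plasma_volume_ml: float | None = None,
    **consensus_kwargs,
) -> tuple[SampleDetectionResult, dict]:
    """simulate -> consensus -> detect in one call, with truth comparison."""
    sample = simulate_plasma_sample(panel, truth)
    molecules, qc = consensus_pipeline(sample.pairs, **consensus_kwargs)

    by_chrom: dict[str, list] = {}
    for t in panel.active_targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    positions = {c: sorted(ts, key=lambda t: t.pos) for c, ts in by_chrom.items()}
    pos_lists = {c: [t.pos for t in ts] for c, ts in positions.items()}

    counts = {t.target_id: {"M": 0, "k": 0} for t in panel.active_targets}
    for mol in molecules:
        chrom, start, end = mol.fragment_key
        if chrom not in pos_lists:
            continue
        plist = pos_lists[chrom]
        lo = bisect.bisect_right(plist, start)
        hi = bisect.bisect_right(plist, end)
        for t in positions[chrom][lo:hi]:
            call = genotype_molecule_at_target(mol, t)
            if call == "alt":
                counts[t.target_id]["M"] += 1
                counts[t.target_id]["k"] += 1
            elif call == "ref":
                counts[t.target_id]["M"] += 1

    observations = [
        TargetObservation(
            target_id=t.target_id,
            total_molecules=counts[t.target_id]["M"],
            alt_molecules=counts[t.target_id]["k"],
            noise_rate=t.error_rate,
            active=t.active,
        )
        for t in panel.active_targets
    ]
    result = detect_sample(observations, p_threshold=p_threshold,
                           plasma_volume_ml=plasma_volume_ml)
    comparison = {
        "true_tumor_fraction_ppm": truth.tumor_fraction * 1e6,
        "estimated_ppm": result.ppm,
        "detected": result.detected,
        "true_tumor_alt_molecules": sample.true_alt_molecules,
        "observed_alt_molecules": result.k,
        "qc": qc,
    }
    return result, comparison


# ---------------------------------------------------------------------------
# fast count-level simulation at full panel scale


def simulate_aggregate_counts(
    lambda_noise: float,
    assumed_M: float,
    tumor_fraction_ppm: float,
    n_replicates: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw the aggregated panel signal k for replicate plasma samples.

    Noise and tumor signal are independent Poisson contributions, so
    k ~ Poisson(lambda + f * M) with f in fractional units; detection
    efficiency is 1 (every tumor molecule at a target is countable).
    """
    if lambda_noise < 0 or tumor_fraction_ppm < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    mu = lambda_noise + tumor_fraction_ppm * 1e-6 * assumed_M
    return rng.poisson(mu, size=n_replicates)


def measure_specificity(
    lambda_noise: float,
    n_samples: int,
    seed: int | None = None,
    p_threshold: float = 0.001,
) -> float:
    """Fraction of simulated tumor-free samples NOT called ctDNA-positive.

    Each null sample's signal is a Poisson draw at the panel noise mean; the
    one-tailed Poisson test is applied to every draw exactly as in
    :func:`ctdna_mrd.detection.detect_sample`.
    """
    k = simulate_aggregate_counts(lambda_noise, 0.0, 0.0, n_samples, seed=seed)
    p_values = poisson.sf(k - 1, lambda_noise)
    detected = p_values <= p_threshold
    return 1.0 - float(np.mean(detected))
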