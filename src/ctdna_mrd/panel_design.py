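"""Bespoke MRD panel design.

A tumor-informed ctDNA assay tracks a patient-specific set of somatic SNVs
("MRD targets") selected from tumor/normal whole-genome sequencing. This
module covers the design steps:

1. estimate a per-substitution-class background error model from a cohort of
   healthy plasma samples (the noise floor of the assay);
2. filter somatic SNV candidates on allele frequency, genomic exclusion
   regions (germline SNPs, CHIP hotspots, repeats, ...) and local GC content;
3. rank candidates by signal-to-noise (tumor AF over the class error rate)
   and select up to a panel cap of targets;
4. add a fixed number of common population SNVs for quality assurance
   (sample-swap and contamination detection);
5. qualify the panel against one unrelated healthy plasma screen, deactivating
   any target that shows non-reference signal there.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

BASES = "ACGT"

#: The 12 ordered substitution classes ref>alt, e.g. "C>T".
SUBSTITUTION_CLASSES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)

EXCLUSION_CATEGORIES = frozenset(
    {
        "germline_snp",
        "chip_region",
        "high_gc",
        "polymorphic",
        "mapping_difficulty",
        "systematic_bias",
        "short_tandem_repeat",
        "low_complexity",
        "hla",
    }
)


def substitution_class(ref: str, alt: str) -> str:
    """Return the ordered substitution class label for a ref/alt base pair."""
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"not a substitution: {ref!r}>{alt!r}")
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SomaticVariantCall:
    """One somatic SNV candidate from tumor/normal WGS."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_af: float
    tumor_depth: int = 0
    passed_caller_filters: bool = True

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-SNV record at {self.chrom}:{self.pos}: "
                             f"{self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.tumor_af <= 1.0:
            raise ValueError(f"tumor_af {self.tumor_af} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def substitution(self) -> str:
        return substitution_class(self.ref, self.alt)


@dataclass(frozen=True)
class SubstitutionErrorModel:
    """Per-substitution-class background error rate per unique molecule.

    Rates are pooled ratios (alt-supporting molecules / total molecules)
    across a healthy-plasma background cohort, floored at ``rate_floor`` so
    that downstream Poisson noise means never degenerate to zero.
    """

    rates: Mapping[str, float]
    n_background_samples: int
    rate_floor: float = 1e-8

    def __post_init__(self) -> None:
        missing = set(SUBSTITUTION_CLASSES) - set(self.rates)
        extra = set(self.rates) - set(SUBSTITUTION_CLASSES)
        if missing or extra:
            raise ValueError(
                f"error model must cover exactly the 12 substitution classes; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if not self.rate_floor > 0:
            raise ValueError("rate_floor must be > 0")
        for cls, rate in self.rates.items():
            if rate < self.rate_floor:
                raise ValueError(f"rate for {cls} below floor: {rate}")
            if rate >= 0.01:
                raise ValueError(f"rate for {cls} implausibly high: {rate}")

    def rate(self, ref: str, alt: str) -> float:
        return self.rates[substitution_class(ref, alt)]


@dataclass(frozen=True)
class GenomicExclusionSet:
    """A category of genomic intervals barred from panel design.

    Intervals are 0-based half-open (chrom, start, end).
    """

    category: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.category not in EXCLUSION_CATEGORIES:
            raise ValueError(f"unknown exclusion category {self.category!r}")
        object.__setattr__(self, "intervals", tuple(self.intervals))
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")


class ExclusionIndex:
    """Point-overlap queries against one or more exclusion sets."""

    def __init__(self, exclusions: Iterable[GenomicExclusionSet] |
                 Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for item in exclusions:
            ivs = item.intervals if isinstance(item, GenomicExclusionSet) else [item]
            for chrom, start, end in ivs:
                self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps_locus(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position falls inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos - 1])


@dataclass
class PanelTarget:
    """One qualified MRD target locus in a bespoke panel."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_af: float
    error_rate: float
    rank_score: float
    active: bool = True

    @property
    def target_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def substitution(self) -> str:
        return substitution_class(self.ref, self.alt)


@dataclass(frozen=True)
class QaSnv:
    """A common population SNV carried for quality assurance."""

    chrom: str
    pos: int
    ref: str
    alt: str
    population_frequency: float
    hwe_pass: bool = True
    subpopulation_frequencies: Mapping[str, float] = field(default_factory=dict)

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def subpopulation_spread(self) -> float:
        """max - min subpopulation frequency; 0 when none are annotated."""
        freqs = list(self.subpopulation_frequencies.values())
        if not freqs:
            return 0.0
        return max(freqs) - min(freqs)


@dataclass
class BespokePanel:
    """The designed panel: ranked MRD targets plus QA population SNVs."""

    patient_id: str
    targets: list[PanelTarget]
    qa_snvs: list[QaSnv]
    predicted_lod_ppm: float | None = None

    @property
    def active_targets(self) -> list[PanelTarget]:
        return [t for t in self.targets if t.active]

    def aggregate_noise_rate(self, molecules_per_target: float) -> float:
        """Expected background molecules across active targets at a given
        per-target unique-molecule yield."""
        return sum(t.error_rate * molecules_per_target for t in self.active_targets)


# ---------------------------------------------------------------------------
# operations


def estimate_substitution_error_model(
    background_observations: Mapping[str, Sequence[tuple[int, int]]],
    rate_floor: float = 1e-8,
) -> SubstitutionErrorModel:
    """Pool per-class background observations into an error model.

    ``background_observations`` maps each of the 12 substitution classes to a
    sequence of (alt_supporting_molecules, total_molecules) pairs, one per
    background plasma sample. The class rate is the pooled ratio
    sum(alt)/sum(total), floored at ``rate_floor``.
    """
    missing = set(SUBSTITUTION_CLASSES) - set(background_observations)
    if missing:
        raise ValueError(f"background observations missing classes: {sorted(missing)}")
    rates: dict[str, float] = {}
    n_samples = 0
    for cls in SUBSTITUTION_CLASSES:
        obs = list(background_observations[cls])
        if not obs:
            raise ValueError(f"no background samples for class {cls}")
        total = sum(t for _, t in obs)
        if total <= 0:
            raise ValueError(f"zero total molecules for class {cls}")
        alt = sum(a for a, _ in obs)
        rates[cls] = max(alt / total, rate_floor)
        n_samples = max(n_samples, len(obs))
    return SubstitutionErrorModel(rates=rates, n_background_samples=n_samples,
                                  rate_floor=rate_floor)


def _gc_fraction(reference, chrom: str, pos: int, window_bp: int) -> float:
    # window is centered on the 1-based position, clipped at contig bounds
    if chrom not in reference:
        raise KeyError(f"reference contig {chrom!r} not found")
    contig = reference[chrom]
    half = window_bp // 2
    start = max(pos - 1 - half, 0)
    end = pos - 1 + half + 1
    seq = contig[start:end]
    seq = getattr(seq, "seq", seq)  # pyfaidx returns a Sequence object
    seq = str(seq).upper()
    if not seq:
        raise KeyError(f"position {pos} outside reference contig {chrom!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def filter_candidate_variants(
    calls: Sequence[SomaticVariantCall],
    exclusions: Sequence[GenomicExclusionSet],
    af_threshold: float = 0.10,
    gc_window_bp: int = 121,
    reference=None,
    gc_threshold: float = 0.80,
) -> list[SomaticVariantCall]:
    """Apply the panel-design eligibility filters, preserving input order.

    A call is retained iff it passed the somatic caller's filters, its tumor
    allele frequency exceeds ``af_threshold``, it overlaps no exclusion
    interval, and the GC fraction of the ``gc_window_bp`` window centered on
    it is below ``gc_threshold``. ``reference`` may be a pyfaidx ``Fasta`` or
    a plain mapping of contig name to sequence string; when ``None`` the GC
    filter is skipped (callers may supply a pre-made ``high_gc`` exclusion
    set instead).
    """
    index = ExclusionIndex(exclusions)
    kept: list[SomaticVariantCall] = []
    for call in calls:
        if not call.passed_caller_filters:
            continue
        if call.tumor_af <= af_threshold:
            continue
        if index.overlaps_locus(call.chrom, call.pos):
            continue
        if reference is not None:
            if _gc_fraction(reference, call.chrom, call.pos, gc_window_bp) >= gc_threshold:
                continue
        kept.append(call)
    return kept


def rank_and_select_targets(
    eligible: Sequence[SomaticVariantCall],
    error_model: SubstitutionErrorModel,
    panel_cap: int = 1800,
) -> list[PanelTarget]:
    """Rank eligible SNVs by signal-to-noise and keep the top ``panel_cap``.

    rank_score = tumor_af / class error rate, sorted descending. Ties break
    deterministically by (lower error rate, higher AF, chrom, pos).
    """
    if not eligible:
        raise ValueError("no designable targets")
    targets = []
    for call in eligible:
        e = error_model.rate(call.ref, call.alt)
        targets.append(
            PanelTarget(
                chrom=call.chrom,
                pos=call.pos,
                ref=call.ref,
                alt=call.alt,
                tumor_af=call.tumor_af,
                error_rate=e,
                rank_score=call.tumor_af / e,
            )
        )
    targets.sort(key=lambda t: (-t.rank_score, t.error_rate, -t.tumor_af,
                                t.chrom, t.pos))
    return targets[:panel_cap]


def select_qa_snvs(
    catalog: Sequence[QaSnv],
    hla_intervals: Iterable[tuple[str, int, int]] = (),
    n: int = 43,
    seed: int = 0,
) -> list[QaSnv]:
    """Choose ``n`` QA population SNVs from a catalog.

    Eligibility: population frequency >= 0.20, Hardy-Weinberg pass, and the
    locus outside the HLA region. Among eligible SNVs the ``n`` with the
    smallest max-min spread of subpopulation frequencies are taken, so the
    chosen set is roughly equally informative across ancestries; ties break
    by a seed-derived shuffle then genomic coordinate, making the selection
    deterministic for a given seed.
    """
    hla_index = ExclusionIndex(list(hla_intervals))
    eligible = [
        s
        for s in catalog
        if s.population_frequency >= 0.20
        and s.hwe_pass
        and not hla_index.overlaps_locus(s.chrom, s.pos)
    ]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible QA SNVs in catalog; "
            f"need {n} (shortfall {n - len(eligible)})"
        )
    rng = random.Random(seed)
    tie = [rng.random() for _ in eligible]
    order = sorted(
        range(len(eligible)),
        key=lambda i: (eligible[i].subpopulation_spread, tie[i],
                       eligible[i].chrom, eligible[i].pos),
    )
    return [eligible[i] for i in order[:n]]


def qualify_panel_against_background(
    panel: BespokePanel,
    screen: Mapping[str, int],
) -> BespokePanel:
    """Deactivate targets showing any non-reference signal in a healthy screen.

    ``screen`` maps target_id to the count of alt-supporting unique molecules
    observed in targeted sequencing of one unrelated healthy plasma sample.
    Every target must be covered (a zero count is a valid observation).
    """
    missing = [t.target_id for t in panel.targets if t.target_id not in screen]
    if missing:
        raise ValueError(f"background screen missing {len(missing)} targets, "
                         f"first: {missing[0]}")
    new_targets = []
    for t in panel.targets:
        if screen[t.target_id] >= 1:
            new_targets.append(replace(t, active=False))
        else:
            new_targets.append(replace(t))
    return BespokePanel(
        patient_id=panel.patient_id,
        targets=new_targets,
        qa_snvs=list(panel.qa_snvs),
        predicted_lod_ppm=panel.predicted_lod_ppm,
    )


def design_panel(
    patient_id: str,
    calls: Sequence[SomaticVariantCall],
    exclusions: Sequence[GenomicExclusionSet],
    error_model: SubstitutionErrorModel,
    snp_catalog: Sequence[QaSnv],
    *,
    reference=None,
    panel_cap: int = 1800,
    af_threshold: float = 0.10,
    gc_window_bp: int = 121,
    n_qa: int = 43,
    seed: int = 0,
) -> BespokePanel:
    """Run the full design: filter, rank/select, and attach QA SNVs."""
    eligible = filter_candidate_variants(
        calls, exclusions, af_threshold=af_threshold,
        gc_window_bp=gc_window_bp, reference=reference,
    )
    targets = rank_and_select_targets(eligible, error_model, panel_cap=panel_cap)
    hla = [iv for s in exclusions if s.category == "hla" for iv in s.intervals]
    qa = select_qa_snvs(snp_catalog, hla, n=n_qa, seed=seed)
    return BespokePanel(patient_id=patient_id, targets=targets, qa_snvs=qa)
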