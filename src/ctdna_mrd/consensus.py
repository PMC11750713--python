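"""Positional duplex consensus for cfDNA read pairs.

cfDNA libraries here carry no UMIs: read pairs deriving from the same original
plasma molecule are identified purely by their paired mapped positions. Each
positional group is collapsed into a single consensus molecule under a fixed
rule order:

1. mask bases below the quality threshold (Q < 29 by default);
2. drop reads with more than 20% of their bases masked;
3. form a provisional majority consensus;
4. drop reads diverging from it by more than 2.5% of comparable bases;
5. recompute the consensus, masking positions with <90% agreement;
6. require read support from both original DNA strands (duplex rule).

Positional grouping can merge distinct molecules that happen to share both
fragment endpoints; groups are therefore split when a non-reference allele is
carried by a strict subset of the group's reads and is independently seen in
at least two other groups.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .panel_design import PanelTarget

MASK_BASE = "N"
_MASK_CODE = ord(MASK_BASE)
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

TOP = "top"
BOTTOM = "bottom"

GenotypeCall = Literal["alt", "ref", "no_call"]


@dataclass
class AlignedReadPair:
    """One sequenced read pair, merged over its fragment span.

    ``fragment_key`` holds the 0-based half-open outer coordinates of the
    pair; ``bases``/``quals`` cover the full fragment (positions covered by
    neither mate are 'N' with quality 0). ``strand_tag`` records which
    original DNA strand the pair derives from (read1-forward pairs are "top",
    read1-reverse pairs are "bottom").
    """

    fragment_key: tuple[str, int, int]
    strand_tag: str
    bases: str
    quals: np.ndarray
    read_id: str

    def __post_init__(self) -> None:
        chrom, start, end = self.fragment_key
        if not 0 <= start < end:
            raise ValueError(f"bad fragment coordinates {chrom}:{start}-{end}")
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != end - start or len(self.quals) != end - start:
            raise ValueError(
                f"read {self.read_id}: bases/quals length must equal fragment "
                f"span {end - start}"
            )
        if self.strand_tag not in (TOP, BOTTOM):
            raise ValueError(f"strand_tag must be '{TOP}' or '{BOTTOM}'")

    @property
    def base_codes(self) -> np.ndarray:
        return np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)


@dataclass
class ConsensusGroup:
    """Read pairs sharing identical paired mapped positions."""

    fragment_key: tuple[str, int, int]
    members: list[AlignedReadPair]
    split_index: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("consensus group must be non-empty")
        for m in self.members:
            if m.fragment_key != self.fragment_key:
                raise ValueError("all members must share the group fragment_key")


@dataclass
class ConsensusMolecule:
    """One deduplicated, strand-confirmed unique cfDNA molecule."""

    fragment_key: tuple[str, int, int]
    sequence: str  # 'N' marks masked positions
    n_members: int
    strand_support: tuple[int, int]  # (n_top, n_bottom)

    def __post_init__(self) -> None:
        n_top, n_bottom = self.strand_support
        if n_top < 1 or n_bottom < 1:
            raise ValueError("consensus molecule requires both strands")
        if self.n_members != n_top + n_bottom:
            raise ValueError("n_members must equal n_top + n_bottom")

    @property
    def masked_fraction(self) -> float:
        return self.sequence.count(MASK_BASE) / len(self.sequence)


@dataclass(frozen=True)
class ConsensusRejection:
    """Why a positional group produced no molecule."""

    fragment_key: tuple[str, int, int]
    reason: Literal["single_strand", "all_reads_removed"]


def group_read_pairs_by_position(
    pairs: Sequence[AlignedReadPair],
) -> list[ConsensusGroup]:
    """Partition read pairs into groups with identical fragment coordinates.

    Output order (and member order within a group) is deterministic and
    independent of input order.
    """
    buckets: dict[tuple[str, int, int], list[AlignedReadPair]] = defaultdict(list)
    for pair in pairs:
        buckets[pair.fragment_key].append(pair)
    groups = []
    for key in sorted(buckets):
        members = sorted(buckets[key], key=lambda r: r.read_id)
        groups.append(ConsensusGroup(fragment_key=key, members=members))
    return groups


def _group_matrix(group: ConsensusGroup) -> tuple[np.ndarray, np.ndarray]:
    bases = np.vstack([m.base_codes for m in group.members])
    quals = np.vstack([m.quals for m in group.members])
    return bases, quals


def _base_counts(bases: np.ndarray, masked: np.ndarray) -> np.ndarray:
    """(4, L) counts of unmasked A/C/G/T per column."""
    valid = ~masked
    return np.stack([((bases == c) & valid).sum(axis=0) for c in _BASE_CODES])


def _majority(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column majority base code; ties resolve alphabetically.

    Returns (codes, covered) where covered marks columns with >=1 unmasked base.
    """
    covered = counts.sum(axis=0) > 0
    codes = _BASE_CODES[np.argmax(counts, axis=0)]
    codes = np.where(covered, codes, np.uint8(_MASK_CODE))
    return codes.astype(np.uint8), covered


def _group_reference(group: ConsensusGroup, reference) -> np.ndarray | None:
    """Reference base codes over the group's span, or None for majority proxy."""
    if reference is None:
        return None
    chrom, start, end = group.fragment_key
    if chrom not in reference:
        raise KeyError(f"reference contig {chrom!r} not found")
    seq = reference[chrom][start:end]
    seq = str(getattr(seq, "seq", seq)).upper()
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def split_groups_on_shared_alleles(
    groups: Sequence[ConsensusGroup],
    min_other_groups: int = 2,
    reference=None,
) -> list[ConsensusGroup]:
    """Split positional groups that mix distinct molecules.

    A group is split at a (position, allele) where the non-reference allele is
    carried by a strict subset of the group's reads and the same allele is
    observed in at least ``min_other_groups`` other groups (independent
    evidence that the allele is real rather than a sequencing error). One
    split per group per pass, taking the allele carried by the most reads
    first; passes repeat until no group changes. Total read count is
    conserved. Without a ``reference`` the per-group majority base stands in
    for the reference allele.
    """
    import bisect

    current = list(groups)
    while True:
        # phase 1: per-group base counts and candidate (pos, allele) pairs --
        # non-reference alleles carried by a strict subset of the group's reads
        counts_list: list[np.ndarray] = []
        group_candidates: list[dict[tuple[str, int, int], int]] = []
        for group in current:
            bases, _ = _group_matrix(group)
            masked = bases == _MASK_CODE
            counts = _base_counts(bases, masked)
            ref_codes = _group_reference(group, reference)
            if ref_codes is None:
                ref_codes, _ = _majority(counts)
            chrom, start, _ = group.fragment_key
            n = len(group.members)
            cands: dict[tuple[str, int, int], int] = {}
            for bi, code in enumerate(_BASE_CODES):
                cols = np.nonzero(
                    (counts[bi] > 0) & (counts[bi] < n) & (ref_codes != code)
                )[0]
                for col in cols:
                    cands[(chrom, start + int(col), int(code))] = int(counts[bi, col])
            counts_list.append(counts.astype(np.int32))
            group_candidates.append(cands)

        # phase 2: which groups observe each candidate allele at all
        # (homogeneous groups count as support -- presence, not minority status)
        cand_bases: dict[tuple[str, int], list[int]] = defaultdict(list)
        for cands in group_candidates:
            for chrom, pos, code in cands:
                if code not in cand_bases[(chrom, pos)]:
                    cand_bases[(chrom, pos)].append(code)
        pos_by_chrom: dict[str, list[int]] = defaultdict(list)
        for chrom, pos in cand_bases:
            pos_by_chrom[chrom].append(pos)
        for plist in pos_by_chrom.values():
            plist.sort()
        code_index = {int(c): i for i, c in enumerate(_BASE_CODES)}
        support: dict[tuple[str, int, int], set[int]] = defaultdict(set)
        for gi, group in enumerate(current):
            chrom, start, end = group.fragment_key
            plist = pos_by_chrom.get(chrom, [])
            counts = counts_list[gi]
            lo = bisect.bisect_left(plist, start)
            hi = bisect.bisect_left(plist, end)
            for pos in plist[lo:hi]:
                col = pos - start
                for code in cand_bases[(chrom, pos)]:
                    if counts[code_index[code], col] > 0:
                        support[(chrom, pos, code)].add(gi)

        new_groups: list[ConsensusGroup] = []
        changed = False
        for gi, group in enumerate(current):
            candidates = [
                (count, key)
                for key, count in group_candidates[gi].items()
                if len(support[key] - {gi}) >= min_other_groups
            ]
            if not candidates:
                new_groups.append(group)
                continue
            # most-supported allele first; deterministic tie-break
            candidates.sort(key=lambda c: (-c[0], c[1][1], c[1][2]))
            _, (chrom, pos, code) = candidates[0]
            col = pos - group.fragment_key[1]
            carriers = [m for m in group.members if m.base_codes[col] == code]
            rest = [m for m in group.members if m.base_codes[col] != code]
            changed = True
            for part in (carriers, rest):
                new_groups.append(
                    ConsensusGroup(
                        fragment_key=group.fragment_key,
                        members=part,
                        split_index=group.split_index + 1,
                    )
                )
        current = new_groups
        if not changed:
            return current


def build_consensus_molecule(
    group: ConsensusGroup,
    q_mask: int = 29,
    max_divergence: float = 0.025,
    agreement: float = 0.90,
    max_masked_fraction: float = 0.20,
) -> ConsensusMolecule | ConsensusRejection:
    """Collapse one positional group into a consensus molecule.

    Returns a :class:`ConsensusMolecule`, or a :class:`ConsensusRejection`
    with reason ``all_reads_removed`` (every read failed the masking or
    divergence filters) or ``single_strand`` (surviving reads do not cover
    both original DNA strands).
    """
    if not group.members:
        raise ValueError("empty consensus group")
    bases, quals = _group_matrix(group)
    masked = (quals < q_mask) | (bases == _MASK_CODE)

    # reads dominated by masked bases carry too little information
    keep = masked.mean(axis=1) <= max_masked_fraction
    if not keep.any():
        return ConsensusRejection(group.fragment_key, "all_reads_removed")
    bases, masked = bases[keep], masked[keep]
    members = [m for m, k in zip(group.members, keep) if k]

    # provisional consensus, then divergence filter against it
    counts = _base_counts(bases, masked)
    prov, covered = _majority(counts)
    comparable = (~masked) & covered[None, :]
    denom = comparable.sum(axis=1)
    mismatches = ((bases != prov[None, :]) & comparable).sum(axis=1)
    divergence = np.divide(mismatches, np.maximum(denom, 1), dtype=float)
    keep2 = divergence <= max_divergence
    if not keep2.any():
        return ConsensusRejection(group.fragment_key, "all_reads_removed")
    bases, masked = bases[keep2], masked[keep2]
    members = [m for m, k in zip(members, keep2) if k]

    n_top = sum(1 for m in members if m.strand_tag == TOP)
    n_bottom = len(members) - n_top
    if n_top < 1 or n_bottom < 1:
        return ConsensusRejection(group.fragment_key, "single_strand")

    # final consensus with the agreement mask
    counts = _base_counts(bases, masked)
    total = counts.sum(axis=0)
    top_count = counts.max(axis=0)
    codes = _BASE_CODES[np.argmax(counts, axis=0)]
    ok = (total > 0) & (top_count >= agreement * total)
    sequence_codes = np.where(ok, codes, np.uint8(_MASK_CODE))
    sequence = sequence_codes.astype(np.uint8).tobytes().decode("ascii")

    return ConsensusMolecule(
        fragment_key=group.fragment_key,
        sequence=sequence,
        n_members=len(members),
        strand_support=(n_top, n_bottom),
    )


def genotype_molecule_at_target(
    molecule: ConsensusMolecule, target: PanelTarget
) -> GenotypeCall:
    """Call one consensus molecule at a panel target locus."""
    chrom, start, end = molecule.fragment_key
    if target.chrom != chrom or not start < target.pos <= end:
        raise ValueError(
            f"target {target.target_id} outside molecule span {chrom}:{start}-{end}"
        )
    base = molecule.sequence[target.pos - 1 - start]
    if base == target.alt:
        return "alt"
    if base == target.ref:
        return "ref"
    return "no_call"


def consensus_pipeline(
    pairs: Sequence[AlignedReadPair],
    reference=None,
    min_other_groups: int = 2,
    **consensus_kwargs,
) -> tuple[list[ConsensusMolecule], dict[str, int]]:
    """Group, split, and collapse read pairs; returns molecules plus QC counts."""
    groups = group_read_pairs_by_position(pairs)
    n_groups_initial = len(groups)
    groups = split_groups_on_shared_alleles(
        groups, min_other_groups=min_other_groups, reference=reference
    )
    molecules: list[ConsensusMolecule] = []
    rejections = {"single_strand": 0, "all_reads_removed": 0}
    for group in groups:
        result = build_consensus_molecule(group, **consensus_kwargs)
        if isinstance(result, ConsensusMolecule):
            molecules.append(result)
        else:
            rejections[result.reason] += 1
    qc = {
        "read_pairs_in": len(pairs),
        "groups_initial": n_groups_initial,
        "groups_after_split": len(groups),
        "splits": len(groups) - n_groups_initial,
        "molecules": len(molecules),
        "rejected_single_strand": rejections["single_strand"],
        "rejected_all_reads_removed": rejections["all_reads_removed"],
    }
    return molecules, qc
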