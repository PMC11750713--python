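"""Positional grouping, group splitting, and duplex consensus rules."""
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_mrd import (
    ConsensusGroup,
    ConsensusMolecule,
    ConsensusRejection,
    PanelTarget,
    build_consensus_molecule,
    consensus_pipeline,
    genotype_molecule_at_target,
    group_read_pairs_by_position,
    split_groups_on_shared_alleles,
)
from conftest import make_pair

KEY = ("1", 100, 110)


class TestGrouping:
    def test_identical_fragment_keys_share_a_group(self):
        pairs = [make_pair(KEY, "top", read_id="a"),
                 make_pair(KEY, "bottom", read_id="b")]
        groups = group_read_pairs_by_position(pairs)
        assert len(groups) == 1 and len(groups[0].members) == 2

    def test_one_bp_start_shift_separates_groups(self):
        pairs = [
            make_pair(("1", 100, 110), read_id="a"),
            make_pair(("1", 101, 110), bases="A" * 9,
                      quals=np.full(9, 37), read_id="b"),
        ]
        assert len(group_read_pairs_by_position(pairs)) == 2

    def test_empty_input(self):
        assert group_read_pairs_by_position([]) == []

    def test_grouping_is_order_independent(self):
        rng = random.Random(5)
        pairs = [
            make_pair(("1", 100 + rng.randrange(3), 110 + rng.randrange(2)),
                      bases=None, quals=None, read_id=f"r{i}")
            for i in range(20)
        ]
        # regenerate with matching lengths
        pairs = []
        for i in range(20):
            s, e = 100 + rng.randrange(3), 115 + rng.randrange(2)
            pairs.append(make_pair(("1", s, e), bases="C" * (e - s),
                                   quals=np.full(e - s, 37), read_id=f"r{i}"))
        a = group_read_pairs_by_position(pairs)
        shuffled = pairs[:]
        rng.shuffle(shuffled)
        b = group_read_pairs_by_position(shuffled)
        assert [(g.fragment_key, [m.read_id for m in g.members]) for g in a] == [
            (g.fragment_key, [m.read_id for m in g.members]) for g in b
        ]


def mixed_group(n_alt=3, n_ref=3, key=KEY, alt_col=4):
    """A positional group whose reads disagree at one column (A ref, T alt)."""
    length = key[2] - key[1]
    members = []
    for i in range(n_ref):
        members.append(make_pair(key, "top" if i % 2 else "bottom",
                                 read_id=f"ref{i}"))
    alt_bases = "A" * alt_col + "T" + "A" * (length - alt_col - 1)
    for i in range(n_alt):
        members.append(make_pair(key, "top" if i % 2 else "bottom",
                                 bases=alt_bases, read_id=f"alt{i}"))
    return ConsensusGroup(fragment_key=key, members=members)


def alt_supporting_group(key, alt_col=4):
    """A homogeneous group carrying the T allele at the same genomic position."""
    length = key[2] - key[1]
    bases = "A" * alt_col + "T" + "A" * (length - alt_col - 1)
    return ConsensusGroup(
        fragment_key=key,
        members=[make_pair(key, s, bases=bases, read_id=f"{key[1]}{s}")
                 for s in ("top", "bottom")],
    )


class TestGroupSplitting:
    def test_subset_allele_with_two_other_groups_splits(self):
        # alt at genomic pos 104; supported by 2 other groups spanning it
        groups = [
            mixed_group(3, 3),
            alt_supporting_group(("1", 98, 112), alt_col=6),
            alt_supporting_group(("1", 102, 115), alt_col=2),
        ]
        out = split_groups_on_shared_alleles(groups, min_other_groups=2)
        sizes = sorted(len(g.members) for g in out if g.fragment_key == KEY)
        assert sizes == [3, 3]

    def test_single_other_group_does_not_split(self):
        groups = [mixed_group(3, 3), alt_supporting_group(("1", 98, 112), 6)]
        out = split_groups_on_shared_alleles(groups, min_other_groups=2)
        assert sorted(len(g.members) for g in out if g.fragment_key == KEY) == [6]

    def test_allele_in_every_read_is_not_a_split_candidate(self):
        groups = [
            mixed_group(6, 0),
            alt_supporting_group(("1", 98, 112), 6),
            alt_supporting_group(("1", 102, 115), 2),
        ]
        out = split_groups_on_shared_alleles(groups, min_other_groups=2)
        assert sorted(len(g.members) for g in out if g.fragment_key == KEY) == [6]

    def test_read_count_conserved(self):
        groups = [
            mixed_group(2, 4),
            alt_supporting_group(("1", 98, 112), 6),
            alt_supporting_group(("1", 102, 115), 2),
            alt_supporting_group(("1", 99, 111), 5),
        ]
        n_in = sum(len(g.members) for g in groups)
        out = split_groups_on_shared_alleles(groups)
        assert sum(len(g.members) for g in out) == n_in

    def test_explicit_reference_defines_nonreference(self):
        # all-alt group vs reference: T is non-ref even when unanimous locally,
        # but a unanimous allele is not a strict subset, so no split happens
        reference = {"1": "A" * 200}
        groups = [
            mixed_group(3, 3),
            alt_supporting_group(("1", 98, 112), 6),
            alt_supporting_group(("1", 102, 115), 2),
        ]
        out = split_groups_on_shared_alleles(groups, reference=reference)
        sizes = sorted(len(g.members) for g in out if g.fragment_key == KEY)
        assert sizes == [3, 3]


class TestConsensusMolecule:
    def test_duplex_pair_yields_clean_molecule(self):
        group = ConsensusGroup(KEY, [
            make_pair(KEY, "top", read_id="t"),
            make_pair(KEY, "bottom", read_id="b"),
        ])
        mol = build_consensus_molecule(group)
        assert isinstance(mol, ConsensusMolecule)
        assert mol.strand_support == (1, 1)
        assert mol.sequence == "A" * 10
        assert mol.masked_fraction == 0.0

    def test_single_strand_group_rejected(self):
        group = ConsensusGroup(KEY, [
            make_pair(KEY, "top", read_id=f"t{i}") for i in range(3)
        ])
        out = build_consensus_molecule(group)
        assert isinstance(out, ConsensusRejection)
        assert out.reason == "single_strand"

    def test_divergent_read_excluded(self):
        key = ("1", 0, 200)
        clean = "A" * 200
        # 6 mismatches of 200 = 3% > 2.5%
        divergent = "T" * 6 + "A" * 194
        group = ConsensusGroup(key, [
            make_pair(key, "top", bases=clean, quals=np.full(200, 37), read_id="t1"),
            make_pair(key, "top", bases=clean, quals=np.full(200, 37), read_id="t2"),
            make_pair(key, "bottom", bases=clean, quals=np.full(200, 37), read_id="b1"),
            make_pair(key, "bottom", bases=divergent, quals=np.full(200, 37),
                      read_id="b2"),
        ])
        mol = build_consensus_molecule(group)
        assert isinstance(mol, ConsensusMolecule)
        assert mol.n_members == 3  # divergent read dropped
        assert mol.sequence == clean

    def test_low_agreement_position_masked(self):
        # 6 unmasked bases, 5 agree: 83% < 90% -> masked; the fragment is long
        # enough that the odd read stays under the 2.5% divergence cut
        key = ("1", 0, 50)
        disagree = "G" + "A" * 49
        members = [
            make_pair(key, "top" if i % 2 else "bottom", bases="A" * 50,
                      quals=np.full(50, 37), read_id=f"r{i}")
            for i in range(5)
        ] + [make_pair(key, "top", bases=disagree, quals=np.full(50, 37),
                       read_id="odd")]
        mol = build_consensus_molecule(ConsensusGroup(key, members))
        assert mol.n_members == 6
        assert mol.sequence[0] == "N"
        assert mol.sequence[1:] == "A" * 49

    def test_read_with_many_low_quality_bases_removed(self):
        key = ("1", 0, 100)
        bad_quals = np.full(100, 37)
        bad_quals[:25] = 20  # 25% of bases below Q29
        group = ConsensusGroup(key, [
            make_pair(key, "top", bases="A" * 100, quals=np.full(100, 37),
                      read_id="t"),
            make_pair(key, "bottom", bases="A" * 100, quals=np.full(100, 37),
                      read_id="b"),
            make_pair(key, "bottom", bases="A" * 100, quals=bad_quals,
                      read_id="bad"),
        ])
        mol = build_consensus_molecule(group)
        assert mol.n_members == 2

    def test_all_reads_removed_rejection(self):
        key = ("1", 0, 10)
        group = ConsensusGroup(key, [
            make_pair(key, "top", quals=np.full(10, 10), read_id="t"),
        ])
        out = build_consensus_molecule(group)
        assert isinstance(out, ConsensusRejection)
        assert out.reason == "all_reads_removed"

    def test_quality_mask_below_29(self):
        key = ("1", 0, 10)
        quals = np.full(10, 37)
        quals[3] = 28  # just below threshold
        group = ConsensusGroup(key, [
            make_pair(key, "top", quals=quals, read_id="t"),
            make_pair(key, "bottom", quals=quals, read_id="b"),
        ])
        mol = build_consensus_molecule(group)
        assert mol.sequence[3] == "N"

    def test_consensus_is_order_independent(self):
        rng = random.Random(9)
        key = ("1", 0, 50)
        members = []
        for i in range(8):
            bases = "".join(
                "C" if rng.random() < 0.01 else "A" for _ in range(50)
            )
            members.append(make_pair(key, "top" if i % 2 else "bottom",
                                     bases=bases, quals=np.full(50, 37),
                                     read_id=f"r{i}"))
        ref_out = build_consensus_molecule(ConsensusGroup(key, members))
        assert isinstance(ref_out, ConsensusMolecule)
        for _ in range(5):
            shuffled = members[:]
            rng.shuffle(shuffled)
            out = build_consensus_molecule(ConsensusGroup(key, shuffled))
            assert out == ref_out

    def test_consensus_idempotent_on_own_output(self):
        key = ("1", 0, 20)
        bases = "ACGT" * 5
        group = ConsensusGroup(key, [
            make_pair(key, "top", bases=bases, quals=np.full(20, 37), read_id="t"),
            make_pair(key, "bottom", bases=bases, quals=np.full(20, 37), read_id="b"),
        ])
        mol = build_consensus_molecule(group)
        regroup = ConsensusGroup(key, [
            make_pair(key, "top", bases=mol.sequence, quals=np.full(20, 37),
                      read_id="t2"),
            make_pair(key, "bottom", bases=mol.sequence, quals=np.full(20, 37),
                      read_id="b2"),
        ])
        again = build_consensus_molecule(regroup)
        assert again.sequence == mol.sequence


class TestGenotyping:
    TARGET = PanelTarget("1", 105, "A", "T", tumor_af=0.5,
                         error_rate=1e-6, rank_score=5e5)

    def _molecule(self, sequence):
        return ConsensusMolecule(KEY, sequence, 2, (1, 1))

    def test_alt_ref_and_no_call(self):
        base = ["A"] * 10
        assert genotype_molecule_at_target(
            self._molecule("".join(base)), self.TARGET) == "ref"
        base[4] = "T"
        assert genotype_molecule_at_target(
            self._molecule("".join(base)), self.TARGET) == "alt"
        base[4] = "N"
        assert genotype_molecule_at_target(
            self._molecule("".join(base)), self.TARGET) == "no_call"
        base[4] = "G"  # third allele
        assert genotype_molecule_at_target(
            self._molecule("".join(base)), self.TARGET) == "no_call"

    def test_target_outside_span_raises(self):
        target = PanelTarget("1", 500, "A", "T", 0.5, 1e-6, 5e5)
        with pytest.raises(ValueError, match="outside"):
            genotype_molecule_at_target(self._molecule("A" * 10), target)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 3)), min_size=1,
                max_size=12))
def test_molecule_count_bounded_by_groups_and_pairs(layout):
    """molecules <= groups <= read pairs, for arbitrary duplex layouts."""
    pairs = []
    for i, (start_shift, extra_reads) in enumerate(layout):
        key = ("1", 100 + start_shift, 120 + start_shift)
        for j in range(1 + extra_reads):
            pairs.append(make_pair(
                key, "top" if j % 2 else "bottom",
                bases="A" * 20, quals=np.full(20, 37), read_id=f"g{i}r{j}"))
    molecules, qc = consensus_pipeline(pairs)
    assert len(molecules) <= qc["groups_after_split"]
    assert qc["groups_after_split"] >= qc["groups_initial"]
    assert qc["groups_initial"] <= len(pairs)
    assert qc["read_pairs_in"] == len(pairs)
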