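"""Window solver: Procedure P1, Clark solving, sharing pairs, Algorithm 1."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutregion.mrhip import (
    STAR,
    CenterConflict,
    MrhipInstance,
    MrhipStatus,
    PhaseState,
    TypeIIFailure,
    can_solve,
    complement_pair,
    compute_center,
    hap_str,
    infer_shared_pair,
    merge_compatible,
    parse_genotype,
    parse_hap,
    run_mrhip,
)

from conftest import assert_valid_true_state, diseased_conflict_scan, random_instance

G = parse_genotype
H = parse_hap


# ---------------------------------------------------------------------------
# Procedure P1

@pytest.mark.parametrize("diseased, expected", [
    (["10211", "12221", "10221"], "10*11"),
    (["111", "121"], "111"),
    (["12110", "11210"], "11110"),
    (["222"], "***"),
])
def test_compute_center(diseased, expected):
    assert hap_str(compute_center([G(s) for s in diseased])) == expected


def test_compute_center_conflict_position():
    with pytest.raises(CenterConflict) as exc:
        compute_center([G("02"), G("12")])
    assert exc.value.position == 1  # 1-based, first position

    with pytest.raises(ValueError):
        compute_center([])


# ---------------------------------------------------------------------------
# pairing rules

@pytest.mark.parametrize("g, h, expected", [
    ("10211", "10*11", "10*11"),
    ("12221", "10*11", "11*01"),
    ("000", "000", "000"),
])
def test_complement_pair(g, h, expected):
    assert hap_str(complement_pair(G(g), H(h))) == expected


def test_complement_pair_inconsistent():
    with pytest.raises(ValueError):
        complement_pair(G("01"), H("00"))


@pytest.mark.parametrize("h, g, expected", [
    ("10*11", "10121", True),
    ("111", "102", False),
    ("***", "012", True),
])
def test_can_solve(h, g, expected):
    assert can_solve(H(h), G(g)) is expected


@pytest.mark.parametrize("h1, h2, expected", [
    ("10101", "10101", "10101"),
    ("1*0", "*10", "110"),
    ("10", "01", None),
])
def test_merge_compatible(h1, h2, expected):
    got = merge_compatible(H(h1), H(h2))
    assert got == (None if expected is None else H(expected))


@pytest.mark.parametrize("g1, g2, shared, o1, o2", [
    ("21111", "11121", "11111", "01111", "11101"),
    ("00", "00", "00", "00", "00"),  # identical homozygotes share themselves
])
def test_infer_shared_pair(g1, g2, shared, o1, o2):
    got = infer_shared_pair(G(g1), G(g2))
    assert got == (H(shared), H(o1), H(o2))


def test_infer_shared_pair_conflict():
    assert infer_shared_pair(G("012"), G("112")) is None


# ---------------------------------------------------------------------------
# Algorithm 1 on the worked examples

def test_example1_full_solution(example1):
    out = run_mrhip(example1)
    assert out.is_true
    assert out.center == H("10011")
    distinct = {h for pair in out.pairs for h in pair}
    assert distinct == {H("10011"), H("10111"), H("11101"), H("10101")}
    assert out.dh == 4
    # the normal's first haplotype was solved with (and equals) h_{1,2}
    assert out.pairs[3] == (H("10111"), H("10101"))
    assert_valid_true_state(example1, out)


def test_example1_intermediate_queue(example1):
    state = PhaseState.from_center(example1.diseased, example1.normal,
                                   compute_center(example1.diseased))
    intq = [tuple(state.class_values[c]) for c in state.queue]
    assert intq == [H("10*11"), H("11*01"), H("10*01")]


def test_example2_sharing_pair(example2):
    out = run_mrhip(example2)
    assert out.is_true
    assert out.center == H("11110")
    # the two normals share 11111; mates are 01111 and 11101
    assert out.pairs[2] == (H("11111"), H("01111"))
    assert out.pairs[3] == (H("11111"), H("11101"))
    assert_valid_true_state(example2, out)


def test_example2_intermediate_queue(example2):
    state = PhaseState.from_center(example2.diseased, example2.normal,
                                   compute_center(example2.diseased))
    intq = {tuple(state.class_values[c]) for c in state.queue}
    assert intq == {H("10110"), H("11010")}


def test_type_ii_false(type2_instance):
    assert run_mrhip(type2_instance).status is MrhipStatus.TYPE_II_FALSE


def test_type_i_false_reports_position():
    out = run_mrhip(MrhipInstance.from_strings(["021", "120"], ["222"]))
    assert out.status is MrhipStatus.TYPE_I_FALSE
    assert out.conflict_position == 1


# ---------------------------------------------------------------------------
# instance hygiene

def test_instance_rejects_within_set_duplicates():
    with pytest.raises(ValueError):
        MrhipInstance.from_strings(["11", "11"], ["02"])
    # the same segment may appear in both sets
    MrhipInstance.from_strings(["12"], ["12"])


def test_intq_deduplicates_identical_complements():
    # both diseased genotypes are explained by identical complements
    inst = MrhipInstance.from_strings(["210", "212"], [])
    state = PhaseState.from_center(inst.diseased, inst.normal,
                                   compute_center(inst.diseased))
    assert len(state.queue) <= len(inst.diseased)
    vals = [tuple(state.class_values[c]) for c in state.queue]
    assert len(vals) == len(set(vals))


# ---------------------------------------------------------------------------
# finalization of unsolvable normals

def test_finalize_homozygous_mismatch_is_trivially_fixed():
    # the normal cannot be solved by the queue (homozygous conflict) and is
    # finalized against the center via its homozygous mismatch
    inst = MrhipInstance.from_strings(["00"], ["12"])
    out = run_mrhip(inst)
    assert out.is_true
    assert_valid_true_state(inst, out)


def test_finalize_impossible_phasing_raises():
    # g=12 phases only to (11,10) or (10,11); one side always equals the
    # fully determined center 10
    state = PhaseState.from_center((G("10"),), (G("12"),),
                                   compute_center([G("10")]))
    with pytest.raises(TypeIIFailure):
        state.finalize_unsolved()


def test_finalize_fixes_trivial_and_leaves_empty_p_alone():
    state = PhaseState.from_center((G("00"),), (G("11"),),
                                   compute_center([G("00")]))
    state.finalize_unsolved()
    assert not state.unsolved
    state.finalize_unsolved()  # empty P: no-op


def test_unavoidable_center_carrier_is_type_ii():
    # every phasing of the normal 012 contains 010 or 011, and the center is
    # 01x for either wild-card choice: condition (2) cannot hold
    out = run_mrhip(MrhipInstance.from_strings(["012", "212"], ["012"]))
    assert out.status is MrhipStatus.TYPE_II_FALSE


def test_finalize_empty_unsolved_is_noop(example1):
    out = run_mrhip(example1)
    assert not out.state.unsolved


# ---------------------------------------------------------------------------
# DH counting

def test_dh_identical_homozygous_diseased():
    out = run_mrhip(MrhipInstance.from_strings(["0000"], []))
    assert out.is_true and out.dh == 1


def test_dh_bounded_by_slots(example2):
    out = run_mrhip(example2)
    assert out.dh <= 2 * (len(example2.diseased) + len(example2.normal))


# ---------------------------------------------------------------------------
# properties

def test_type_i_matches_direct_scan_small():
    """run_mrhip returns Type I iff the diseased segments carry a 0/1
    conflict (reduced sweep; the exhaustive one runs in the acceptance
    suite)."""
    rng = np.random.default_rng(11)
    for _ in range(2000):
        inst = random_instance(rng, max_len=4, max_n=3)
        out = run_mrhip(inst)
        assert (out.status is MrhipStatus.TYPE_I_FALSE) == \
            diseased_conflict_scan(inst.diseased)


def test_true_outcomes_satisfy_invariants_fuzz():
    rng = np.random.default_rng(13)
    n_true = 0
    for _ in range(1500):
        inst = random_instance(rng, max_len=6, max_n=4)
        out = run_mrhip(inst)
        if out.is_true:
            n_true += 1
            assert_valid_true_state(inst, out)
    assert n_true > 100  # the sweep must actually exercise TRUE outcomes


def test_determinism(example1, example2):
    for inst in (example1, example2):
        a, b = run_mrhip(inst), run_mrhip(inst)
        assert a.status == b.status and a.pairs == b.pairs and a.dh == b.dh


# hypothesis: pairing-rule algebra

genotypes = st.lists(st.integers(0, 2), min_size=1, max_size=8).map(tuple)


@settings(max_examples=200, derandomize=True)
@given(genotypes)
def test_phasing_roundtrip_explains_genotype(g):
    """Complementing any consistent haplotype of g yields a pair that
    explains g under C1/C2."""
    h = tuple(v if v != 2 else 0 for v in g)
    mate = complement_pair(g, h)
    for gv, a, b in zip(g, h, mate):
        if gv == 2:
            assert {a, b} == {0, 1}
        else:
            assert a == b == gv
    assert can_solve(h, g) and can_solve(mate, g)


@settings(max_examples=200, derandomize=True)
@given(genotypes, genotypes)
def test_shared_pair_symmetric_and_explains(g1, g2):
    if len(g1) != len(g2):
        return
    res = infer_shared_pair(g1, g2)
    sym = infer_shared_pair(g2, g1)
    assert (res is None) == (sym is None)
    if res is not None:
        shared, o1, o2 = res
        assert sym[0] == shared
        assert can_solve(shared, g1) and can_solve(shared, g2)
        assert o1 == complement_pair(g1, shared)
        assert o2 == complement_pair(g2, shared)
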