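"""Gene-dropping simulator: founders, recombination, forced transmission,
truth regions."""

import numpy as np
import pytest

from mutregion.pedigrees import five_generation_pedigree
from mutregion.simulate import (
    GeneticMap,
    Member,
    Pedigree,
    PedigreeError,
    SimulationConfig,
    SimulationError,
    TruthSet,
    drop_pedigree,
    generate_founders,
    make_gamete,
    read_map_tsv,
    read_pedigree_tsv,
    shared_regions_from_haplotypes,
    simulate_crossovers,
    true_and_shared_regions,
    write_pedigree_tsv,
)

from conftest import brute_force_shared_regions


# ---------------------------------------------------------------------------
# pedigree validation

def test_pedigree_carrier_chain_validation():
    ok = five_generation_pedigree(2)
    assert ok.carrier_origin == "g1a"
    # a second diseased member without a diseased parent breaks the single
    # origin assumption
    bad = [Member("a", None, None, "M", True),
           Member("b", None, None, "F", True),
           Member("c", "a", "b", "M", False, True)]
    with pytest.raises(PedigreeError, match="exactly one"):
        Pedigree(bad)
    with pytest.raises(PedigreeError, match="precede"):
        Pedigree([Member("c", "a", "b", "M", True, True),
                  Member("a", None, None, "M", True),
                  Member("b", None, None, "F", False)])
    with pytest.raises(PedigreeError, match="both parents"):
        Pedigree([Member("a", None, None, "M", True),
                  Member("c", "a", None, "M", True, True)])


def test_pedigree_tsv_roundtrip(tmp_path):
    ped = five_generation_pedigree(3)
    p = tmp_path / "ped.tsv"
    write_pedigree_tsv(ped, p)
    back = read_pedigree_tsv(p)
    assert [m.id for m in back.members] == [m.id for m in ped.members]
    assert [m.diseased for m in back.members] == [m.diseased for m in ped.members]
    assert [m.in_output for m in back.members] == [m.in_output for m in ped.members]


def test_genetic_map_validation(tmp_path):
    with pytest.raises(ValueError, match="nondecreasing"):
        GeneticMap([0.0, 1.0, 0.5])
    with pytest.raises(ValueError, match="> 0"):
        GeneticMap([1.0, 1.0, 1.0])
    gmap = GeneticMap.uniform(2000)
    assert gmap.total_morgans == pytest.approx(1999 * 0.001 / 100)
    p = tmp_path / "map.tsv"
    p.write_text("".join(f"snp{i}\t{i * 0.01}\n" for i in range(100)))
    assert read_map_tsv(p).n_sites == 100


# ---------------------------------------------------------------------------
# founder haplotypes

def test_degenerate_pool_single_member():
    cfg = SimulationConfig(pool_size=1)
    haps, pool = generate_founders(300, 6, cfg, np.random.default_rng(0))
    assert (haps == pool[0]).all()  # every founder is the single pool member


def test_zero_switch_rate_copies_pool_members():
    cfg = SimulationConfig(switch_rate=0.0)
    haps, pool = generate_founders(200, 10, cfg, np.random.default_rng(1))
    pool_rows = {r.tobytes() for r in pool}
    assert all(h.tobytes() in pool_rows for h in haps)


def test_founder_allele_frequency_tracks_pool_mean():
    cfg = SimulationConfig()
    rng = np.random.default_rng(2)
    haps, pool = generate_founders(150, 2000, cfg, rng)
    emp = haps.mean(axis=0)
    assert np.abs(emp - pool.mean(axis=0)).max() <= 0.05


# ---------------------------------------------------------------------------
# recombination

def test_haldane_limit_mean_crossovers():
    """m=0: the retained process is Poisson with intensity 1 per Morgan."""
    gmap = GeneticMap.uniform(2001, cm_per_site=0.1)  # 2 Morgans
    rng = np.random.default_rng(3)
    counts = [len(simulate_crossovers(gmap, 0, rng)) for _ in range(4000)]
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - 2.0) <= 3 * se + 1e-9


def test_map_length_conservation_any_m():
    gmap = GeneticMap.uniform(1501, cm_per_site=0.2)  # 3 Morgans
    rng = np.random.default_rng(4)
    for m in (0, 2, 4):
        counts = [len(simulate_crossovers(gmap, m, rng)) for _ in range(4000)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 3.0) <= 3 * se + 1e-9


def test_interference_underdispersion():
    """m=4 chiasma interference makes crossover counts underdispersed
    relative to Poisson."""
    gmap = GeneticMap.uniform(2001, cm_per_site=0.1)
    rng = np.random.default_rng(5)
    v0 = np.var([len(simulate_crossovers(gmap, 0, rng)) for _ in range(4000)])
    v4 = np.var([len(simulate_crossovers(gmap, 4, rng)) for _ in range(4000)])
    assert v4 < v0


def test_make_gamete_basic():
    gmap = GeneticMap.uniform(10, cm_per_site=1.0)
    parent = np.array([[0] * 10, [1] * 10], dtype=np.int8)
    assert (make_gamete(parent, np.array([]), gmap, 0) == 0).all()
    g = make_gamete(parent, np.array([4.5]), gmap, 0)
    assert list(g) == [0] * 5 + [1] * 5  # switch between sites 4 and 5


def test_gamete_alleles_come_from_parent():
    gmap = GeneticMap.uniform(500, cm_per_site=0.05)
    rng = np.random.default_rng(6)
    for _ in range(50):
        parent = rng.integers(0, 2, (2, 500)).astype(np.int8)
        xo = simulate_crossovers(gmap, 4, rng)
        g = make_gamete(parent, xo, gmap, int(rng.integers(0, 2)))
        assert ((g == parent[0]) | (g == parent[1])).all()


# ---------------------------------------------------------------------------
# gene dropping

def test_all_diseased_chain_is_ibd_at_mutation():
    members = [Member("f0", None, None, "M", True),
               Member("f0b", None, None, "F", False)]
    prev = ("f0", "f0b")
    for gen in range(1, 4):
        members.append(Member(f"c{gen}", prev[0], prev[1], "M", True, gen == 3))
        members.append(Member(f"s{gen}", None, None, "F", False, gen == 3))
        prev = (f"c{gen}", f"s{gen}")
    members.append(Member("n3", "c2", "s2", "F", False, True))
    ped = Pedigree(members)
    gmap = GeneticMap.uniform(2000)
    truth, _ = drop_pedigree(ped, gmap, SimulationConfig(), np.random.default_rng(7))
    mut = truth.mutation_site
    origin_allele = truth.haplotypes["f0"][0][mut]
    for gen in range(1, 4):
        hid = truth.mutant[f"c{gen}"]
        assert hid[0] or hid[1]
        carried = truth.haplotypes[f"c{gen}"][0 if hid[0] else 1][mut]
        assert carried == origin_allele  # descended, not re-drawn


def test_truthset_invariants_over_replicates():
    ped = five_generation_pedigree(2)
    gmap = GeneticMap.uniform(800)
    cfg = SimulationConfig()
    for seed in range(60):
        rng = np.random.default_rng(seed)
        try:
            truth, matrix = drop_pedigree(ped, gmap, cfg, rng)
        except SimulationError:
            continue  # identical-by-state coincidence; detected and refused
        mut = truth.mutation_site
        for mid, dis in zip(truth.output_ids, truth.output_diseased):
            flags = truth.mutant[mid]
            assert (flags[0] or flags[1]) == bool(dis)
        a, b = truth.true_region
        assert a <= mut <= b
        assert (a, b) in [tuple(r) for r in truth.shared_regions]
        # genotype coding matches the haplotypes
        for r, mid in enumerate(truth.output_ids):
            h = truth.haplotypes[mid]
            s = h[0].astype(int) + h[1]
            expect = np.where(s == 1, 2, np.where(s == 2, 1, 0))
            assert (matrix.codes[r] == expect).all()


def test_figure_pedigree_output_shape():
    ped = five_generation_pedigree(2)
    truth, matrix = drop_pedigree(ped, GeneticMap.uniform(500),
                                  SimulationConfig(), np.random.default_rng(8))
    assert matrix.n_individuals == 10
    assert int(matrix.diseased.sum()) == 2


def test_mendelian_consistency():
    ped = five_generation_pedigree(2)
    gmap = GeneticMap.uniform(1000)
    truth, _ = drop_pedigree(ped, gmap, SimulationConfig(), np.random.default_rng(9))
    for m in ped.members:
        if m.father is None:
            continue
        child = truth.haplotypes[m.id]
        for slot, parent in enumerate((m.father, m.mother)):
            ph = truth.haplotypes[parent]
            assert ((child[slot] == ph[0]) | (child[slot] == ph[1])).all()


# ---------------------------------------------------------------------------
# shared mutation regions

def _mk_truth(d_haps, n_haps, mut_site):
    haplotypes = {}
    ids, dis = [], []
    for i, h in enumerate(d_haps):
        haplotypes[f"d{i}"] = np.asarray(h, dtype=np.int8)
        ids.append(f"d{i}")
        dis.append(True)
    for i, h in enumerate(n_haps):
        haplotypes[f"n{i}"] = np.asarray(h, dtype=np.int8)
        ids.append(f"n{i}")
        dis.append(False)
    return TruthSet(haplotypes, {}, mut_site, {}, (0, 0), [], ids, np.array(dis))


def test_shared_regions_match_bruteforce_oracle():
    rng = np.random.default_rng(10)
    for _ in range(150):
        k = int(rng.integers(1, 4))
        nn = int(rng.integers(0, 3))
        S = int(rng.integers(2, 11))
        d = [rng.integers(0, 2, (2, S)).astype(np.int8) for _ in range(k)]
        n = [rng.integers(0, 2, S).astype(np.int8) for _ in range(nn)]
        got = shared_regions_from_haplotypes(d, n)
        assert got == brute_force_shared_regions(d, n)


def test_no_shared_region_when_normal_has_the_haplotype():
    h = np.zeros(6, dtype=np.int8)
    truth = _mk_truth([(h, h), (h, h)], [(h, h)], mut_site=3)
    with pytest.raises(SimulationError):
        true_and_shared_regions(truth)


def test_single_diseased_unique_haplotype_whole_chromosome():
    d = (np.zeros(8, dtype=np.int8), np.ones(8, dtype=np.int8))
    n = np.array([0, 1] * 4, dtype=np.int8)
    truth = _mk_truth([d], [(n, n)], mut_site=2)
    tr, shared = true_and_shared_regions(truth)
    assert tr == (0, 7) and shared == [(0, 7)]
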