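"""Shared fixtures and oracle helpers."""

import itertools

import numpy as np
import pytest

from mutregion.mrhip import (
    STAR,
    MrhipInstance,
    MrhipStatus,
)


@pytest.fixture
def example1():
    """Three diseased, one normal; solvable with DH = 4."""
    return MrhipInstance.from_strings(["10211", "12221", "10221"], ["10121"])


@pytest.fixture
def example2():
    """Two diseased, two normals solvable only through a sharing pair."""
    return MrhipInstance.from_strings(["12110", "11210"], ["21111", "11121"])


@pytest.fixture
def type2_instance():
    """A normal genotype that forces a haplotype equal to the center."""
    return MrhipInstance.from_strings(["111", "121"], ["112", "102"])


# ---------------------------------------------------------------------------
# oracles

def diseased_conflict_scan(diseased) -> bool:
    """Direct scan: some position carries both a homozygous 0 and a
    homozygous 1 among the diseased genotypes."""
    for p in range(len(diseased[0])):
        vals = {g[p] for g in diseased}
        if 0 in vals and 1 in vals:
            return True
    return False


def assert_valid_true_state(inst, out):
    """All MRHIP invariants on a TRUE outcome's resolved state."""
    assert out.status is MrhipStatus.TRUE
    L = inst.length
    center = out.center
    assert len(center) == L and STAR not in center
    k = len(inst.diseased)
    segs = inst.diseased + inst.normal
    assert len(out.pairs) == len(segs)
    for i, (g, (h1, h2)) in enumerate(zip(segs, out.pairs)):
        assert STAR not in h1 and STAR not in h2
        for p in range(L):
            if g[p] != 2:  # rule C1
                assert h1[p] == g[p] and h2[p] == g[p], (i, p)
            else:  # rule C2
                assert {h1[p], h2[p]} == {0, 1}, (i, p)
        if i < k:  # condition (1)
            assert h1 == center, i
        else:  # condition (2)
            assert h1 != center and h2 != center, i
    distinct = {h for pair in out.pairs for h in pair}
    assert out.dh == len(distinct)
    assert out.dh <= 2 * len(segs)


def all_phasings(g):
    """Every unordered haplotype pair explaining genotype ``g``."""
    hets = [p for p in range(len(g)) if g[p] == 2]
    for fill in itertools.product((0, 1), repeat=len(hets)):
        h1 = list(g)
        for p, v in zip(hets, fill):
            h1[p] = v
        h2 = [v if v != 2 else 1 - a for v, a in zip(g, h1)]
        yield tuple(h1), tuple(h2)


def exact_min_distinct(inst):
    """Brute-force minimum number of distinct haplotypes over all phasings
    satisfying MRHIP conditions (1) and (2); None when infeasible."""
    L = inst.length
    base = []
    for p in range(L):
        vals = {g[p] for g in inst.diseased}
        if 0 in vals and 1 in vals:
            return None
        base.append(0 if 0 in vals else 1 if 1 in vals else None)
    wild = [p for p in range(L) if base[p] is None]
    best = None
    for fill in itertools.product((0, 1), repeat=len(wild)):
        center = list(base)
        for p, v in zip(wild, fill):
            center[p] = v
        center = tuple(center)
        fixed = {center}
        for g in inst.diseased:
            fixed.add(tuple(v if v != 2 else 1 - center[p]
                            for p, v in enumerate(g)))
        options = []
        feasible = True
        for g in inst.normal:
            opts = [(h1, h2) for h1, h2 in all_phasings(g)
                    if h1 != center and h2 != center]
            if not opts:
                feasible = False
                break
            options.append(opts)
        if not feasible:
            continue
        for combo in itertools.product(*options):
            size = len(fixed | {h for pair in combo for h in pair})
            if best is None or size < best:
                best = size
    return best


def random_instance(rng, max_len, max_n):
    """A random MRHIP instance with distinct within-set segments."""
    while True:
        L = int(rng.integers(1, max_len + 1))
        n = int(rng.integers(2, max_n + 1))
        k = int(rng.integers(1, n))
        if 3 ** L >= k and 3 ** L >= n - k:  # distinctness must be possible
            break
    while True:
        segs = [tuple(int(v) for v in rng.integers(0, 3, L)) for _ in range(n)]
        d, nrm = segs[:k], segs[k:]
        if len(set(d)) == k and len(set(nrm)) == n - k:
            return MrhipInstance(tuple(d), tuple(nrm))


def brute_force_shared_regions(d_haps, n_haps):
    """Enumerate every interval; keep those on which some diseased-haplotype
    choice agrees and every normal haplotype mismatches; return the
    inclusion-maximal set.  Exponential; for tiny inputs only."""
    k = len(d_haps)
    S = len(d_haps[0][0])
    good = set()
    for i in range(S):
        for j in range(i, S):
            for choice in itertools.product((0, 1), repeat=k):
                seqs = [tuple(d_haps[t][c][i:j + 1]) for t, c in enumerate(choice)]
                if len(set(seqs)) != 1:
                    continue
                seq = seqs[0]
                if all(tuple(h[i:j + 1]) != seq for h in n_haps):
                    good.add((i, j))
                    break
    return sorted(c for c in good
                  if not any(o != c and o[0] <= c[0] and c[1] <= o[1] for o in good))
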