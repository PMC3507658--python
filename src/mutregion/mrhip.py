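"""Parsimony haplotype inference on a fixed window.

Given the genotype segments of diseased and normal individuals on a short
region, infer a *center* haplotype carried by every diseased individual plus a
haplotype pair per individual such that

1. every diseased individual carries the center haplotype,
2. no normal individual carries it, and
3. the number of distinct haplotype segments is (heuristically) minimized.

Genotypes are coded per site as 0 (homozygous 0), 1 (homozygous 1) or
2 (heterozygous).  A haplotype pair ``(h, h')`` *explains* a genotype ``g``
when ``g`` in {0,1} forces both haplotypes to that allele (rule C1) and
``g == 2`` forces the two haplotypes to complementary alleles (rule C2).

The solver is Clark-style: complements of the diseased genotypes seed a queue
of known haplotypes; each known haplotype is used to phase normal genotypes,
whose complements become new known material.  Undetermined positions are wild
cards (``*``), fixed lazily by constraint propagation.  An instance is
classified TRUE, Type I false (two diseased genotypes are homozygous for
opposite alleles at some site, so no center exists) or Type II false (a center
exists but some normal individual unavoidably carries it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

#: wild card ("undetermined") haplotype value
STAR = -1

Hap = tuple  # tuple of int over {0, 1, STAR}
Geno = tuple  # tuple of int over {0, 1, 2}


class MrhipStatus(Enum):
    TRUE = "true"
    TYPE_I_FALSE = "type_i_false"
    TYPE_II_FALSE = "type_ii_false"


class Contradiction(Exception):
    """Constraint propagation produced conflicting allele assignments."""


class TypeIIFailure(Exception):
    """A normal individual cannot avoid carrying the center haplotype."""


class CenterConflict(Exception):
    """Two diseased genotypes are homozygous for opposite alleles."""

    def __init__(self, index: int):
        self.index = index  # 0-based site offset within the window
        super().__init__(f"conflicting diseased alleles at window offset {index}")

    @property
    def position(self) -> int:
        """1-based position of the conflict inside the window."""
        return self.index + 1


# ---------------------------------------------------------------------------
# string helpers

def parse_hap(s: str) -> Hap:
    """Parse ``"10*11"`` (``*`` or ``∗`` = wild card) into a value tuple."""
    return tuple(STAR if ch in "*∗" else int(ch) for ch in s)


def hap_str(h: Sequence[int]) -> str:
    return "".join("*" if v == STAR else str(v) for v in h)


def parse_genotype(s: str) -> Geno:
    g = tuple(int(ch) for ch in s)
    if any(v not in (0, 1, 2) for v in g):
        raise ValueError(f"genotype codes must be 0/1/2: {s!r}")
    return g


# ---------------------------------------------------------------------------
# elementary operations

def compute_center(diseased_segs: Sequence[Geno]) -> Hap:
    """Procedure P1: the haplotype every diseased individual must carry.

    Position-wise: 0 if any diseased genotype is 0 (and none is 1); 1 if any
    is 1 (and none is 0); ``*`` if all are heterozygous.  Raises
    :class:`CenterConflict` at the first position carrying both a homozygous 0
    and a homozygous 1.
    """
    if not diseased_segs:
        raise ValueError("at least one diseased genotype segment is required")
    length = len(diseased_segs[0])
    out = []
    for p in range(length):
        has0 = has1 = False
        for g in diseased_segs:
            v = g[p]
            if v == 0:
                has0 = True
            elif v == 1:
                has1 = True
        if has0 and has1:
            raise CenterConflict(p)
        out.append(0 if has0 else 1 if has1 else STAR)
    return tuple(out)


def complement_pair(g: Sequence[int], h: Sequence[int]) -> Hap:
    """The mate ``h'`` of ``h`` in a pair explaining ``g`` (rules C1/C2)."""
    out = []
    for gv, hv in zip(g, h):
        if gv == 2:
            out.append(STAR if hv == STAR else 1 - hv)
        else:
            if hv != STAR and hv != gv:
                raise ValueError("haplotype inconsistent with genotype")
            out.append(gv)
    return tuple(out)


def can_solve(h: Sequence[int], g: Sequence[int]) -> bool:
    """True iff ``h`` could be one haplotype of a pair explaining ``g``."""
    for hv, gv in zip(h, g):
        if hv != STAR and gv != 2 and gv != hv:
            return False
    return True


def merge_compatible(h1: Sequence[int], h2: Sequence[int]) -> Optional[Hap]:
    """Pointwise merge of two haplotypes, or None if they conflict.

    Two haplotypes are compatible when no position carries a determined 0 in
    one and a determined 1 in the other; the merge keeps the determined value
    wherever either side has one.
    """
    out = []
    for a, b in zip(h1, h2):
        if a == STAR:
            out.append(b)
        elif b == STAR or a == b:
            out.append(a)
        else:
            return None
    return tuple(out)


def infer_shared_pair(g1: Sequence[int], g2: Sequence[int]):
    """Haplotype shared by two genotypes, plus their two mates.

    Returns ``(shared, mate1, mate2)`` or ``None`` when some position carries
    a homozygous 0 in one genotype and a homozygous 1 in the other.
    """
    shared = []
    for a, b in zip(g1, g2):
        if 0 in (a, b) and 1 in (a, b):
            return None
        if a == 0 or b == 0:
            shared.append(0)
        elif a == 1 or b == 1:
            shared.append(1)
        else:
            shared.append(STAR)
    shared = tuple(shared)
    return shared, complement_pair(g1, shared), complement_pair(g2, shared)


# ---------------------------------------------------------------------------
# instance / outcome containers

@dataclass(frozen=True)
class MrhipInstance:
    """One window's genotype segments, diseased first.

    Segments within each set must be pairwise distinct (identical genotypes
    within a set can always be phased identically, so duplicates carry no
    information); the same segment may appear in both sets.
    """

    diseased: tuple
    normal: tuple

    def __post_init__(self):
        d = tuple(tuple(g) for g in self.diseased)
        n = tuple(tuple(g) for g in self.normal)
        object.__setattr__(self, "diseased", d)
        object.__setattr__(self, "normal", n)
        if not d:
            raise ValueError("need at least one diseased segment")
        length = len(d[0])
        for g in d + n:
            if len(g) != length:
                raise ValueError("all segments must have equal length")
            if any(v not in (0, 1, 2) for v in g):
                raise ValueError("genotype codes must be in {0,1,2}")
        if len(set(d)) != len(d) or len(set(n)) != len(n):
            raise ValueError("segments within a set must be pairwise distinct")

    @classmethod
    def from_strings(cls, diseased, normal):
        return cls(tuple(parse_genotype(s) for s in diseased),
                   tuple(parse_genotype(s) for s in normal))

    @property
    def length(self) -> int:
        return len(self.diseased[0])


@dataclass
class MrhipOutcome:
    status: MrhipStatus
    conflict_position: Optional[int] = None  # 1-based, Type I only
    state: Optional["PhaseState"] = None
    dh: Optional[int] = None
    center: Optional[Hap] = None
    pairs: Optional[list] = None  # [(h1, h2)] per segment, diseased first

    @property
    def is_true(self) -> bool:
        return self.status is MrhipStatus.TRUE


# ---------------------------------------------------------------------------
# the evolving solution

class PhaseState:
    """Partially phased window: identity classes of haplotype slots.

    Each input segment owns two *slots* (``2*i`` and ``2*i+1``).  Slots
    constrained to carry identical haplotypes live in one identity class with
    a single shared value list.  Rules C1/C2 link the two slots of a segment:
    whenever a class becomes determined at a heterozygous position of a member
    segment, the mate's class is eagerly set to the complementary allele.
    """

    def __init__(self, diseased: Sequence[Geno], normal: Sequence[Geno]):
        self.segs = list(diseased) + list(normal)
        self.k = len(diseased)
        self.L = len(self.segs[0])
        self._next_cid = 0
        self.class_values: dict[int, list] = {}
        self.class_slots: dict[int, list] = {}
        self.slot_cid: list = [None] * (2 * len(self.segs))
        self.queue: list = []  # FIFO of class ids awaiting use as solvers
        self.unsolved: list = list(range(self.k, len(self.segs)))
        self.center_cid: Optional[int] = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_center(cls, diseased, normal, center) -> "PhaseState":
        st = cls(diseased, normal)
        st.center_cid = st._new_class(list(center), [2 * i for i in range(st.k)])
        # complements of the diseased genotypes seed the queue (intQ),
        # deduplicating identical segments into one identity class
        for i in range(st.k):
            mate = list(complement_pair(st.segs[i], center))
            for cid in st.queue:
                if st.class_values[cid] == mate:
                    st._attach(2 * i + 1, cid)
                    break
            else:
                st.queue.append(st._new_class(mate, [2 * i + 1]))
        return st

    def _new_class(self, values: list, slots: list) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.class_values[cid] = list(values)
        self.class_slots[cid] = []
        for s in slots:
            self._attach(s, cid)
        return cid

    def _attach(self, slot: int, cid: int) -> None:
        self.slot_cid[slot] = cid
        self.class_slots[cid].append(slot)

    def copy(self) -> "PhaseState":
        new = object.__new__(PhaseState)
        new.segs = self.segs  # immutable tuples, shared
        new.k = self.k
        new.L = self.L
        new._next_cid = self._next_cid
        new.class_values = {c: list(v) for c, v in self.class_values.items()}
        new.class_slots = {c: list(s) for c, s in self.class_slots.items()}
        new.slot_cid = list(self.slot_cid)
        new.queue = list(self.queue)
        new.unsolved = list(self.unsolved)
        new.center_cid = self.center_cid
        return new

    def _adopt(self, other: "PhaseState") -> None:
        self.__dict__.update(other.__dict__)

    # -- constraint propagation ---------------------------------------------

    def _set(self, cid: int, p: int, v: int) -> None:
        vals = self.class_values[cid]
        cur = vals[p]
        if cur == v:
            return
        if cur != STAR:
            raise Contradiction
        vals[p] = v
        for s in list(self.class_slots[cid]):
            self._propagate_slot(s, p, v)

    def _propagate_slot(self, s: int, p: int, v: int) -> None:
        g = self.segs[s >> 1][p]
        if g == 2:
            mate_cid = self.slot_cid[s ^ 1]
            if mate_cid is not None:
                self._set(mate_cid, p, 1 - v)
        elif g != v:
            raise Contradiction

    def merge_classes(self, keep: int, drop: int) -> None:
        """Union two compatible classes, propagating newly fixed values."""
        if keep == drop:
            return
        va = self.class_values[keep]
        vb = self.class_values.pop(drop)
        det_keep = [x != STAR for x in va]
        drop_slots = self.class_slots.pop(drop)
        for s in drop_slots:
            self.slot_cid[s] = keep
        self.class_slots[keep].extend(drop_slots)
        if drop in self.queue:
            self.queue.remove(drop)
        for p in range(self.L):
            a_det, b = det_keep[p], vb[p]
            if a_det and b != STAR and va[p] != b:
                raise Contradiction  # incompatible
            if not a_det and b != STAR:
                self._set(keep, p, b)
            elif a_det and b == STAR:
                for s in drop_slots:
                    self._propagate_slot(s, p, va[p])

    # -- Clark solving -------------------------------------------------------

    def solve_with(self, cid: int, j: int) -> None:
        """Phase unsolved segment ``j`` using the haplotype of class ``cid``.

        The segment's first slot joins the class; determined alleles of the
        genotype fill the class's wild cards (propagating through complements
        of previously solved segments and the center); the mate haplotype is
        merged into the earliest compatible class still queued, or queued
        fresh.
        """
        g = self.segs[j]
        if not can_solve(self.class_values[cid], g):
            raise ValueError("class cannot solve this genotype")
        self._attach(2 * j, cid)
        vals = self.class_values[cid]
        for p in range(self.L):
            if vals[p] == STAR and g[p] != 2:
                self._set(cid, p, g[p])
        mate = complement_pair(g, self.class_values[cid])
        mate_cid = self._new_class(list(mate), [2 * j + 1])
        self.unsolved.remove(j)
        self.insert_into_queue(mate_cid)

    def _forbidden_pairing(self, a: int, b: int) -> bool:
        # the two slots of a segment with >=1 heterozygous site must end up in
        # different classes (they must differ there); refuse such a union
        slots_a = set(self.class_slots[a])
        for s in self.class_slots[b]:
            if (s ^ 1) in slots_a and any(v == 2 for v in self.segs[s >> 1]):
                return True
        return False

    def insert_into_queue(self, cid: int) -> None:
        """Queue a new haplotype class, merging into the earliest compatible
        queued class (transactionally: a propagation contradiction just skips
        that merge candidate)."""
        for q in list(self.queue):
            if q == cid:
                return
            if self._forbidden_pairing(q, cid):
                continue
            if merge_compatible(self.class_values[q], self.class_values[cid]) is None:
                continue
            trial = self.copy()
            try:
                trial.merge_classes(q, cid)
            except Contradiction:
                continue
            self._adopt(trial)
            return
        self.queue.append(cid)

    # -- sharing pairs -------------------------------------------------------

    def iter_sharing_pairs(self):
        """Unsolved pairs (input order) that can share a haplotype."""
        for a in range(len(self.unsolved)):
            for b in range(a + 1, len(self.unsolved)):
                j1, j2 = self.unsolved[a], self.unsolved[b]
                if infer_shared_pair(self.segs[j1], self.segs[j2]) is not None:
                    yield j1, j2

    def apply_shared_pair(self, j1: int, j2: int) -> None:
        shared, mate1, mate2 = infer_shared_pair(self.segs[j1], self.segs[j2])
        cid_sh = self._new_class(list(shared), [2 * j1, 2 * j2])
        cid1 = self._new_class(list(mate1), [2 * j1 + 1])
        cid2 = self._new_class(list(mate2), [2 * j2 + 1])
        self.unsolved.remove(j1)
        self.unsolved.remove(j2)
        for c in (cid_sh, cid1, cid2):
            self.insert_into_queue(c)

    # -- end-game ------------------------------------------------------------

    def _normal_slots(self, cid: int):
        return [s for s in self.class_slots[cid] if (s >> 1) >= self.k]

    def normal_identical_to_center(self) -> bool:
        """Line-18 check: a solved normal haplotype identical to the center
        (same identity class, or fully determined and value-equal)."""
        cvals = self.class_values[self.center_cid]
        center_det = STAR not in cvals
        for j in range(self.k, len(self.segs)):
            for s in (2 * j, 2 * j + 1):
                cid = self.slot_cid[s]
                if cid is None:
                    continue
                if cid == self.center_cid:
                    return True
                if center_det and self.class_values[cid] == cvals:
                    return True
        return False

    def finalize_unsolved(self) -> None:
        """Phase each remaining normal genotype so neither haplotype can equal
        the center.

        Greedy site-by-site: mismatches with the determined part of the center
        are created as early as possible — a homozygous mismatch covers both
        haplotypes, a heterozygous site with determined center covers one.
        Raises :class:`TypeIIFailure` when no phasing can guarantee both
        mismatches.
        """
        center = self.class_values[self.center_cid]
        for j in list(self.unsolved):
            g = self.segs[j]
            h1, h2 = [], []
            m1 = m2 = False
            for p in range(self.L):
                c = center[p]
                if g[p] != 2:
                    h1.append(g[p])
                    h2.append(g[p])
                    if c != STAR and c != g[p]:
                        m1 = m2 = True
                elif c == STAR:
                    h1.append(0)
                    h2.append(1)
                else:
                    if not m1:
                        h1.append(1 - c)
                        h2.append(c)
                        m1 = True
                    elif not m2:
                        h1.append(c)
                        h2.append(1 - c)
                        m2 = True
                    else:
                        h1.append(0)
                        h2.append(1)
            if not (m1 and m2):
                raise TypeIIFailure
            self._new_class(h1, [2 * j])
            self._new_class(h2, [2 * j + 1])
            self.unsolved.remove(j)

    def _majority(self, p: int) -> int:
        c0 = c1 = 0
        for cid in self.slot_cid:
            if cid is None:
                continue
            v = self.class_values[cid][p]
            if v == 0:
                c0 += 1
            elif v == 1:
                c1 += 1
        return 1 if c1 > c0 else 0

    def resolve_and_count(self):
        """Fix all remaining wild cards and count distinct haplotypes.

        The center class resolves first; every other class follows in creation
        order.  A wild card takes the majority determined allele at its
        position over all slots (ties -> 0), except that a class containing a
        normal slot must end up different from the resolved center: while it
        still matches the center everywhere determined, its first free wild
        card takes the opposite of the center's allele.  If such a class
        nevertheless resolves identical to the center, the window is a Type II
        false (condition (2) cannot be met).

        Returns ``(pairs, dh)`` where ``pairs[i]`` is the fully determined
        haplotype pair of segment ``i`` and ``dh`` the number of distinct
        haplotypes over all slots.
        """
        order = [self.center_cid] + [c for c in sorted(self.class_values)
                                     if c != self.center_cid]
        center = self.class_values[self.center_cid]
        for cid in order:
            if cid not in self.class_values:  # merged away (cannot happen now)
                continue
            vals = self.class_values[cid]
            guard = cid != self.center_cid and self._normal_slots(cid)
            for p in range(self.L):
                if vals[p] != STAR:
                    continue
                if guard and not any(
                        v != STAR and v != c
                        for v, c in zip(vals, center)):
                    v = 1 - center[p]  # force a mismatch with the center
                else:
                    v = self._majority(p)
                snapshot = {c: list(x) for c, x in self.class_values.items()}
                try:
                    self._set(cid, p, v)
                except Contradiction:
                    # heuristic merges can commit the classes to an
                    # odd-parity complement cycle with no consistent
                    # assignment; try the other allele, else give up on
                    # this window (no valid phasing was found)
                    for c, x in snapshot.items():
                        self.class_values[c][:] = x
                    try:
                        self._set(cid, p, 1 - v)
                    except Contradiction:
                        raise TypeIIFailure from None
            if guard and vals == center:
                raise TypeIIFailure
        pairs = []
        for i in range(len(self.segs)):
            h1 = tuple(self.class_values[self.slot_cid[2 * i]])
            h2 = tuple(self.class_values[self.slot_cid[2 * i + 1]])
            pairs.append((h1, h2))
        distinct = {h for pair in pairs for h in pair}
        return pairs, len(distinct)

    @property
    def center(self) -> Hap:
        return tuple(self.class_values[self.center_cid])


# ---------------------------------------------------------------------------
# Algorithm 1

def run_mrhip(inst: MrhipInstance) -> MrhipOutcome:
    """Classify one window and, when feasible, phase it.

    Returns TRUE with a fully resolved :class:`PhaseState`, Type I false with
    the first conflicting position, or Type II false.
    """
    try:
        center0 = compute_center(inst.diseased)
    except CenterConflict as e:
        return MrhipOutcome(MrhipStatus.TYPE_I_FALSE, conflict_position=e.position)

    state = PhaseState.from_center(inst.diseased, inst.normal, center0)

    while True:
        while state.queue and state.unsolved:
            cid = state.queue.pop(0)
            for j in list(state.unsolved):
                if j not in state.unsolved:
                    continue
                if not can_solve(state.class_values[cid], state.segs[j]):
                    continue
                trial = state.copy()
                try:
                    trial.solve_with(cid, j)
                except Contradiction:
                    continue  # treated as "cid cannot solve j"
                state = trial
        if not state.unsolved:
            break
        applied = False
        if len(state.unsolved) >= 2:
            for j1, j2 in state.iter_sharing_pairs():
                trial = state.copy()
                try:
                    trial.apply_shared_pair(j1, j2)
                except Contradiction:
                    continue
                state = trial
                applied = True
                break
        if not applied:
            break

    if state.normal_identical_to_center():
        return MrhipOutcome(MrhipStatus.TYPE_II_FALSE)
    try:
        state.finalize_unsolved()
        pairs, dh = state.resolve_and_count()
    except TypeIIFailure:
        return MrhipOutcome(MrhipStatus.TYPE_II_FALSE)
    return MrhipOutcome(MrhipStatus.TRUE, state=state, dh=dh,
                        center=state.center, pairs=pairs)
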