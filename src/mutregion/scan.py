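"""Whole-chromosome mutation-region detection.

The chromosome is tiled into length-``L`` windows (default 500 SNPs), each
classified by the window solver as VALID (a consistent phasing exists),
Type I (conflicting diseased homozygotes) or Type II (a normal individual
unavoidably carries the center haplotype).  Valid windows separated by at
most ``2L`` SNPs of exclusively Type II windows merge into longer spans;
each span's boundaries are refined by re-solving three candidate widenings
(+-0.5L, +-0.2L, exact); the surviving span is extended site by site in both
directions by constraint propagation over the identity classes of inferred
haplotypes until a conflicting position stops it.  Every region is scored
``SCORE = (2n - DH) * LENGTH`` and all regions are reported, highest score
first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, RegionRecord, to_report_coords
from .mrhip import MrhipInstance, MrhipOutcome, MrhipStatus, run_mrhip

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 500


class WindowStatus(Enum):
    VALID = "valid"
    TYPE_I = "type_i"
    TYPE_II = "type_ii"


@dataclass
class Window:
    start: int  # 0-based half-open
    end: int
    status: WindowStatus
    outcome: Optional[MrhipOutcome] = None
    pairs: Optional[list] = None  # per-individual haplotype pair (VALID only)


@dataclass
class WindowGrid:
    window_length: int
    windows: list

    def gap_windows(self, lo: int, hi: int) -> list:
        """Windows lying wholly inside the 0-based half-open span [lo, hi)."""
        return [w for w in self.windows if w.start >= lo and w.end <= hi]


@dataclass
class CandidateRegion:
    """A detected region: merged, refined and extended bounds plus score.

    ``start``/``end`` are the 0-based *closed* extended bounds [rb, re];
    ``record()`` converts to the 1-based inclusive reporting frame.
    """

    merged: tuple  # (sb, se) 0-based half-open
    refined: tuple  # (b, e) 0-based half-open
    start: int  # rb, 0-based closed
    end: int  # re, 0-based closed
    dh: int
    score: int
    n: int
    normal_matches_center_in_extension: bool = False

    def record(self) -> RegionRecord:
        s1, e1 = to_report_coords(self.start, self.end)
        return RegionRecord(s1, e1, self.dh, self.score)


# ---------------------------------------------------------------------------
# window solving with per-individual bookkeeping

def solve_span(m: GenotypeMatrix, start: int, end: int):
    """Run the window solver on [start, end), deduplicating identical
    genotype segments within each status group.

    Returns ``(outcome, pairs)`` where ``pairs`` maps each individual to its
    inferred haplotype pair (None unless the outcome is TRUE).
    """
    sub = m.codes[:, start:end]
    d_idx = np.flatnonzero(m.diseased)
    n_idx = np.flatnonzero(~m.diseased)
    d_segs, d_map = _dedup([tuple(int(v) for v in sub[i]) for i in d_idx])
    n_segs, n_map = _dedup([tuple(int(v) for v in sub[i]) for i in n_idx])
    outcome = run_mrhip(MrhipInstance(tuple(d_segs), tuple(n_segs)))
    pairs = None
    if outcome.is_true:
        pairs = [None] * m.n_individuals
        for pos, i in enumerate(d_idx):
            pairs[i] = outcome.pairs[d_map[pos]]
        for pos, i in enumerate(n_idx):
            pairs[i] = outcome.pairs[len(d_segs) + n_map[pos]]
    return outcome, pairs


def _dedup(segs):
    uniq, index, mapping = [], {}, []
    for s in segs:
        if s not in index:
            index[s] = len(uniq)
            uniq.append(s)
        mapping.append(index[s])
    return uniq, mapping


# ---------------------------------------------------------------------------
# Algorithm 2 steps

def scan_windows(m: GenotypeMatrix, L: int = DEFAULT_WINDOW) -> WindowGrid:
    """Tile the chromosome and classify every window.

    The final window may be shorter than ``L``; it is scanned like any other
    (discarding it could lose telomeric regions).
    """
    if L < 2:
        raise ValueError("window length must be >= 2")
    if m.has_missing:
        raise ValueError("matrix contains missing calls; run drop_missing_sites first")
    windows = []
    for start in range(0, m.n_sites, L):
        end = min(start + L, m.n_sites)
        outcome, pairs = solve_span(m, start, end)
        status = {
            MrhipStatus.TRUE: WindowStatus.VALID,
            MrhipStatus.TYPE_I_FALSE: WindowStatus.TYPE_I,
            MrhipStatus.TYPE_II_FALSE: WindowStatus.TYPE_II,
        }[outcome.status]
        log.debug("window [%d,%d): %s", start, end, status.value)
        windows.append(Window(start, end, status, outcome, pairs))
    return WindowGrid(L, windows)


def merge_valid(grid: WindowGrid) -> list:
    """Merge valid windows into maximal spans.

    Two valid/merged spans merge when their gap is at most ``2L`` SNPs and
    every tiling window inside the gap is Type II (a center exists throughout,
    it is just shared with normals — the signature of a region continuing
    across the gap).  Left-to-right to fixpoint.
    """
    L = grid.window_length
    spans = []
    for w in grid.windows:
        if w.status is not WindowStatus.VALID:
            continue
        if spans:
            sb, se = spans[-1]
            gap = w.start - se
            if gap <= 2 * L and all(
                    gw.status is WindowStatus.TYPE_II
                    for gw in grid.gap_windows(se, w.start)):
                spans[-1] = (sb, w.end)
                continue
        spans.append((w.start, w.end))
    return spans


def refine_boundaries(span: tuple, m: GenotypeMatrix, L: int):
    """Re-solve the three candidate widenings of a merged span.

    Candidates [sb-0.5L, se+0.5L), [sb-0.2L, se+0.2L) and [sb, se) (clamped
    to the chromosome) are tried longest first; the first that solves TRUE is
    returned as ``(b, e, outcome, pairs)``.  None if all three fail — the
    span is dropped as spurious with a warning (the merged span itself is
    expected to re-validate, but merging is order-dependent).
    """
    sb, se = span
    widenings = (L // 2, L // 5, 0)
    cands = []
    for w in widenings:
        b = max(0, sb - w)
        e = min(m.n_sites, se + w)
        if (b, e) not in cands:
            cands.append((b, e))
    cands.sort(key=lambda be: -(be[1] - be[0]))
    for b, e in cands:
        outcome, pairs = solve_span(m, b, e)
        if outcome.is_true:
            return b, e, outcome, pairs
    log.warning("merged span [%d,%d) failed to re-validate; dropped", sb, se)
    return None


class _ExtConflict(Exception):
    pass


def extend_region(b_e: tuple, pairs: Sequence, m: GenotypeMatrix) -> tuple:
    """Extend a refined span outwards one site at a time.

    The inferred haplotypes on [b, e) are grouped into identity classes of
    identical sequences.  At each flanking position, a class member whose
    genotype is homozygous forces the allele of the whole class; forced
    alleles propagate to complementary haplotypes through heterozygous
    genotypes (rules C1/C2) until fixpoint.  A contradiction marks a
    conflicting position and stops extension in that direction (the position
    is excluded).  Classes whose members are all heterozygous stay
    undetermined.  Returns ``(rb, re, flag)`` with 0-based closed bounds and
    a flag marking that some normal-carrying class matched the center class
    at every annexed position.
    """
    b, e = b_e
    codes = m.codes
    # identity classes of identical haplotypes on [b, e)
    cls_of = {}
    members = []
    seq_to_cid = {}
    for i, (h1, h2) in enumerate(pairs):
        for j, h in enumerate((h1, h2)):
            cid = seq_to_cid.setdefault(h, len(members))
            if cid == len(members):
                members.append([])
            members[cid].append((i, j))
            cls_of[(i, j)] = cid
    d0 = int(np.flatnonzero(m.diseased)[0])
    center_cid = cls_of[(d0, 0)]
    n_cls = len(members)
    normal_cids = {cls_of[(i, j)] for i in np.flatnonzero(~m.diseased) for j in (0, 1)}

    track: dict[int, list] = {c: [] for c in range(n_cls)}  # annexed values per class

    def annex(p: int) -> dict:
        assign: dict[int, int] = {}

        def setv(cid, v):
            if cid in assign:
                if assign[cid] != v:
                    raise _ExtConflict
                return
            assign[cid] = v
            for (i, j) in members[cid]:
                g = codes[i, p]
                if g == 2:
                    setv(cls_of[(i, 1 - j)], 1 - v)
                elif g != v:
                    raise _ExtConflict

        for cid in range(n_cls):
            gs = {int(codes[i, p]) for (i, j) in members[cid]}
            if 0 in gs and 1 in gs:
                raise _ExtConflict
            if 0 in gs:
                setv(cid, 0)
            elif 1 in gs:
                setv(cid, 1)
        return assign

    rb = b
    for p in range(b - 1, -1, -1):
        try:
            assign = annex(p)
        except _ExtConflict:
            break
        rb = p
        for c in range(n_cls):
            track[c].append(assign.get(c))
    re_ = e - 1
    for p in range(e, m.n_sites):
        try:
            assign = annex(p)
        except _ExtConflict:
            break
        re_ = p
        for c in range(n_cls):
            track[c].append(assign.get(c))

    flag = False
    n_annexed = (b - rb) + (re_ - (e - 1))
    if n_annexed:
        for c in normal_cids:
            if c != center_cid and track[c] == track[center_cid]:
                flag = True
                break
        if center_cid in normal_cids:
            flag = True
    return rb, re_, flag


def score_region(n: int, dh: int, rb: int, re: int) -> int:
    """``SCORE = (2n - DH) * LENGTH`` for a 1-based inclusive region [rb, re].

    ``n`` is the total number of input genotypes; a longer region with fewer
    distinct haplotypes scores higher.
    """
    if not 1 <= dh <= 2 * n:
        raise ValueError(f"dh={dh} outside [1, 2n={2 * n}]")
    if rb > re:
        raise ValueError("rb must be <= re")
    return (2 * n - dh) * (re - rb + 1)


# ---------------------------------------------------------------------------
# full pipeline

def detect_regions(m: GenotypeMatrix, L: int = DEFAULT_WINDOW,
                   bridge_gap: int = 0) -> list:
    """Scan -> merge -> refine -> extend -> score; all regions reported,
    sorted by descending score (stable).

    DH for scoring is recomputed on the extended region when it solves TRUE;
    otherwise the refined window's DH is used (extension applies only
    conflict checks, so the extended span may not re-validate).  With
    ``bridge_gap = B > 0``, reported regions separated by at most B sites are
    merged afterwards — mirroring the manual step of reading a single
    conflicting site inside an otherwise shared region as a genotyping error.
    """
    n = m.n_individuals
    grid = scan_windows(m, L)
    regions = []
    for span in merge_valid(grid):
        refined = refine_boundaries(span, m, L)
        if refined is None:
            continue
        b, e, outcome, pairs = refined
        rb, re_, flag = extend_region((b, e), pairs, m)
        dh = outcome.dh
        if (rb, re_) != (b, e - 1):
            ext_outcome, _ = solve_span(m, rb, re_ + 1)
            if ext_outcome.is_true:
                dh = ext_outcome.dh
            else:
                log.debug("extended span [%d,%d] not TRUE; keeping refined DH", rb, re_)
        score = score_region(n, dh, *to_report_coords(rb, re_))
        regions.append(CandidateRegion(span, (b, e), rb, re_, dh, score, n, flag))
    if bridge_gap > 0:
        regions = _bridge(regions, m, bridge_gap)
    regions.sort(key=lambda r: -r.score)
    return regions


def _bridge(regions: list, m: GenotypeMatrix, max_gap: int) -> list:
    """Merge reported regions separated by <= max_gap sites (error bridging)."""
    by_start = sorted(regions, key=lambda r: r.start)
    out = []
    for r in by_start:
        if out and r.start - out[-1].end - 1 <= max_gap:
            prev = out[-1]
            rb, re_ = prev.start, r.end
            outcome, _ = solve_span(m, rb, re_ + 1)
            dh = outcome.dh if outcome.is_true else max(prev.dh, r.dh)
            score = score_region(prev.n, dh, *to_report_coords(rb, re_))
            out[-1] = CandidateRegion(
                (min(prev.merged[0], r.merged[0]), max(prev.merged[1], r.merged[1])),
                (prev.refined[0], r.refined[1]), rb, re_, dh, score, prev.n,
                prev.normal_matches_center_in_extension or r.normal_matches_center_in_extension)
        else:
            out.append(r)
    return out
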