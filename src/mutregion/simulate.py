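"""Gene-dropping pedigree simulator with chi-square crossover interference.

Generates genotype data with known ground truth: founder haplotypes with
local LD are dropped through a user-specified pedigree; recombination follows
the chi-square interference model (chiasmata are every (m+1)-th event of a
Poisson process on the four-strand bundle, each retained on the sampled
gamete with probability 1/2; m = 4 by default, m = 0 recovers the Haldane
model); one SNP site is chosen uniformly as the mutation point and, for a
dominant trait, transmission from every carrier parent is forced so that
diseased children inherit the mutant strand and normal children do not.  The
forcing only relabels which strand the gamete starts on — the crossover
pattern itself is never conditioned — so the recombination law is exact
everywhere and the conditioning at the mutation site is exact too.

The output is the genotype matrix of the designated input individuals plus a
:class:`TruthSet` with all haplotypes, the mutation site, the true mutation
region and all shared mutation regions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

log = logging.getLogger(__name__)


class PedigreeError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pedigree

@dataclass(frozen=True)
class Member:
    id: str
    father: Optional[str]  # None = founder
    mother: Optional[str]
    sex: str  # 'M' / 'F'
    diseased: bool
    in_output: bool = False


@dataclass
class Pedigree:
    """An acyclic pedigree in topological order (parents precede children).

    Validated for single-origin dominant transmission: exactly one diseased
    member has no diseased parent (the carrier origin); every other diseased
    member has at least one diseased parent.
    """

    members: list

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("member ids must be unique")
        by_id = {m.id: m for m in self.members}
        seen = set()
        for m in self.members:
            if (m.father is None) != (m.mother is None):
                raise PedigreeError(f"{m.id}: both parents or neither")
            for p in (m.father, m.mother):
                if p is not None:
                    if p not in by_id:
                        raise PedigreeError(f"{m.id}: unknown parent {p}")
                    if p not in seen:
                        raise PedigreeError(f"{m.id}: parent {p} must precede child")
            seen.add(m.id)
        roots = [m for m in self.members if m.diseased and not self._has_diseased_parent(m, by_id)]
        if len([m for m in self.members if m.diseased]) == 0:
            raise PedigreeError("pedigree has no diseased member")
        if len(roots) != 1:
            raise PedigreeError(
                f"dominant single-origin transmission needs exactly one diseased "
                f"member without a diseased parent; found {[m.id for m in roots]}")
        self.by_id = by_id
        self.carrier_origin = roots[0].id

    @staticmethod
    def _has_diseased_parent(m: Member, by_id) -> bool:
        return any(p is not None and by_id[p].diseased for p in (m.father, m.mother))

    @property
    def founders(self) -> list:
        return [m for m in self.members if m.father is None]

    @property
    def output_members(self) -> list:
        return [m for m in self.members if m.in_output]


def read_pedigree_tsv(path) -> Pedigree:
    """Pedigree TSV: ``id father mother sex status in_output``; founder
    parents are '0'; status D/U; in_output 1/0."""
    members = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns")
            mid, fa, mo, sex, status, out = parts
            members.append(Member(
                mid, None if fa == "0" else fa, None if mo == "0" else mo,
                sex, status == "D", out == "1"))
    return Pedigree(members)


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in ped.members:
            fh.write("\t".join([m.id, m.father or "0", m.mother or "0", m.sex,
                                "D" if m.diseased else "U",
                                "1" if m.in_output else "0"]) + "\n")


# ---------------------------------------------------------------------------
# genetic map

@dataclass
class GeneticMap:
    """Per-site genetic position in centimorgans, nondecreasing."""

    cm: np.ndarray

    def __post_init__(self):
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.cm) < 2:
            raise ValueError("map needs >= 2 sites")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic positions must be nondecreasing")
        if self.total_morgans <= 0:
            raise ValueError("total map length must be > 0 Morgans")

    @property
    def n_sites(self) -> int:
        return len(self.cm)

    @property
    def total_morgans(self) -> float:
        return float(self.cm[-1] - self.cm[0]) / 100.0

    @classmethod
    def uniform(cls, n_sites: int, cm_per_site: float = 0.001) -> "GeneticMap":
        """Uniform map; the default density of 1 cM per 1,000 sites is a
        neutral stand-in for a human high-density SNP map."""
        return cls(np.arange(n_sites) * cm_per_site)


def read_map_tsv(path) -> GeneticMap:
    """Genetic map TSV: ``snp_id`` <tab> ``cM`` per line."""
    cm = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cm.append(float(line.split("\t")[1]))
    return GeneticMap(np.array(cm))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Tunable parameters of the generator.

    m: interference parameter of the chi-square model (degrees of freedom
       divided by two); 4 matches human data, 0 is Haldane.
    pool_size / switch_rate / freq_low..freq_high: founder haplotypes are
       mosaics over an ancestral pool of ``pool_size`` haplotypes whose
       per-site allele frequencies are Uniform(freq_low, freq_high); the
       mosaic jumps to a random pool member with probability ``switch_rate``
       per site, giving HapMap-like local LD (expected segment ~1/switch_rate
       sites).
    mutation_site: 0-based site ordinal, or "uniform" to draw uniformly.
    """

    m: int = 4
    pool_size: int = 24
    switch_rate: float = 0.002
    freq_low: float = 0.05
    freq_high: float = 0.95
    mutation_site: object = "uniform"

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


# ---------------------------------------------------------------------------
# founder haplotypes

def generate_founders(S: int, n_haplotypes: int, cfg: SimulationConfig,
                      rng: np.random.Generator):
    """Mosaic founder haplotypes over a shared ancestral pool.

    Returns ``(haps, pool)`` with ``haps`` of shape (n_haplotypes, S).
    """
    freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=S)
    pool = (rng.random((cfg.pool_size, S)) < freqs).astype(np.int8)
    haps = np.empty((n_haplotypes, S), dtype=np.int8)
    for h in range(n_haplotypes):
        switches = rng.random(S) < cfg.switch_rate
        switches[0] = True
        seg_id = np.cumsum(switches) - 1
        donors = rng.integers(0, cfg.pool_size, size=seg_id[-1] + 1)
        haps[h] = pool[donors[seg_id], np.arange(S)]
    return haps, pool


# ---------------------------------------------------------------------------
# recombination

def simulate_crossovers(gmap: GeneticMap, m: int, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions (cM) on one gamete under the chi-square model.

    A stationary renewal chiasma process: events arrive as a Poisson process
    of rate 2(m+1) per Morgan on the four-strand bundle and every (m+1)-th
    event is a chiasma (stationarity via a uniformly random initial phase);
    each chiasma is retained on the sampled gamete independently with
    probability 1/2.  The retained intensity is 1 per Morgan for every m
    (map-length conservation); m = 0 gives the Haldane (Poisson) model.
    """
    total = gmap.total_morgans
    n_events = rng.poisson(2 * (m + 1) * total)
    if n_events == 0:
        return np.empty(0)
    events = np.sort(rng.uniform(0.0, total, size=n_events))
    phase = rng.integers(0, m + 1)
    idx = np.arange(n_events)
    chiasmata = events[(idx + phase) % (m + 1) == m]
    kept = chiasmata[rng.random(len(chiasmata)) < 0.5]
    return float(gmap.cm[0]) + kept * 100.0


def make_gamete(parent_haps: np.ndarray, crossovers_cm: np.ndarray,
                gmap: GeneticMap, start_strand: int) -> np.ndarray:
    """Alternate between the two parental haplotypes at each crossover."""
    n_switch = np.searchsorted(np.sort(np.asarray(crossovers_cm)), gmap.cm, side="left")
    strand = (start_strand + n_switch) % 2
    return parent_haps[strand, np.arange(gmap.n_sites)].astype(np.int8)


def _strand_at(site: int, crossovers_cm: np.ndarray, gmap: GeneticMap,
               start_strand: int) -> int:
    n = int(np.searchsorted(np.sort(np.asarray(crossovers_cm)), gmap.cm[site], side="left"))
    return (start_strand + n) % 2


# ---------------------------------------------------------------------------
# truth container

@dataclass
class TruthSet:
    """Everything the simulator knows that the detector must rediscover."""

    haplotypes: dict  # member id -> (2, S) int8
    mutant: dict  # member id -> (bool, bool): haplotype carries the mutant site
    mutation_site: int  # 0-based
    carrier_haplotype: dict  # diseased output member id -> 0/1
    true_region: tuple  # (start, end) 0-based closed
    shared_regions: list  # [(start, end)] 0-based closed
    output_ids: list
    output_diseased: np.ndarray

    @property
    def mutation_site_1based(self) -> int:
        return self.mutation_site + 1


# ---------------------------------------------------------------------------
# gene dropping

def drop_pedigree(ped: Pedigree, gmap: GeneticMap, cfg: SimulationConfig,
                  rng: np.random.Generator):
    """Drop founder haplotypes through the pedigree.

    Returns ``(truth, matrix)``.  The carrier origin's first haplotype is the
    mutant lineage; at every transmission from a carrier parent the gamete's
    start strand is flipped, if necessary, so that the allele transmitted at
    the mutation site descends from the mutant strand iff the child is
    diseased.
    """
    S = gmap.n_sites
    out_members = ped.output_members
    if not out_members:
        raise PedigreeError("pedigree designates no output individuals")
    if cfg.mutation_site == "uniform":
        mut_site = int(rng.integers(0, S))
    else:
        mut_site = int(cfg.mutation_site)
        if not 0 <= mut_site < S:
            raise ValueError("mutation_site out of range")

    founders = ped.founders
    fhaps, _ = generate_founders(S, 2 * len(founders), cfg, rng)
    haps: dict[str, np.ndarray] = {}
    mutant: dict[str, list] = {}
    for i, f in enumerate(founders):
        haps[f.id] = fhaps[2 * i:2 * i + 2].copy()
        mutant[f.id] = [False, False]

    origin = ped.carrier_origin
    for member in ped.members:
        if member.father is not None:
            child = np.empty((2, S), dtype=np.int8)
            flags = [False, False]
            for slot, parent_id in enumerate((member.father, member.mother)):
                xo = simulate_crossovers(gmap, cfg.m, rng)
                start = int(rng.integers(0, 2))
                pm = mutant[parent_id]
                if pm[0] or pm[1]:
                    if pm[0] and pm[1]:
                        raise PedigreeError(
                            f"parent {parent_id} carries two mutant haplotypes; "
                            "forced transmission is ill-defined")
                    mut_idx = 0 if pm[0] else 1
                    desired = mut_idx if member.diseased else 1 - mut_idx
                    if _strand_at(mut_site, xo, gmap, start) != desired:
                        start ^= 1
                    flags[slot] = member.diseased
                child[slot] = make_gamete(haps[parent_id], xo, gmap, start)
            haps[member.id] = child
            mutant[member.id] = flags
        if member.id == origin:
            mutant[member.id] = [True, False]

    # genotype matrix of the output individuals
    ids = [m.id for m in out_members]
    diseased = np.array([m.diseased for m in out_members])
    codes = np.empty((len(ids), S), dtype=np.int8)
    for r, m in enumerate(out_members):
        s = haps[m.id][0].astype(np.int16) + haps[m.id][1]
        codes[r] = np.where(s == 1, 2, np.where(s == 2, 1, 0)).astype(np.int8)
    matrix = GenotypeMatrix(ids, diseased, [f"snp{j + 1}" for j in range(S)], codes)

    carrier_hap = {}
    for m in out_members:
        if m.diseased:
            f = mutant[m.id]
            if not (f[0] or f[1]):
                raise SimulationError(f"diseased output member {m.id} lost the mutant strand")
            carrier_hap[m.id] = 0 if f[0] else 1
        elif mutant[m.id][0] or mutant[m.id][1]:
            raise SimulationError(f"normal output member {m.id} carries the mutant strand")

    truth = TruthSet(haps, {k: tuple(v) for k, v in mutant.items()}, mut_site,
                     carrier_hap, (0, 0), [], ids, diseased)
    truth.true_region, truth.shared_regions = true_and_shared_regions(truth)
    return truth, matrix


# ---------------------------------------------------------------------------
# shared mutation regions from the truth

def shared_regions_from_haplotypes(d_haps, n_haps) -> list:
    """Maximal 0-based closed intervals on which some per-diseased choice of
    one haplotype is identical across all diseased individuals and no normal
    haplotype equals the shared sequence.

    ``d_haps``: one (2, S) array per diseased individual; ``n_haps``: flat
    list of normal haplotype arrays.  For a fixed choice the candidates are
    exactly its maximal agreement runs on which every normal haplotype
    mismatches at least once (a mismatch inside a run persists in any
    super-interval within the run); the result is the inclusion-maximal
    candidate set over all choices.
    """
    k = len(d_haps)
    if k == 0:
        raise ValueError("no diseased individuals")
    if k > 12:
        raise ValueError("too many diseased individuals for exhaustive choice sweep")
    d_haps = np.stack(d_haps)  # (k, 2, S)

    candidates = set()
    for choice in itertools.product((0, 1), repeat=k):
        chosen = np.stack([d_haps[i, c] for i, c in enumerate(choice)])
        agree = (chosen == chosen[0]).all(axis=0)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], agree.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2] - 1):
            seq = chosen[0, a:b + 1]
            if all(not np.array_equal(h[a:b + 1], seq) for h in n_haps):
                candidates.add((int(a), int(b)))

    regions = [c for c in candidates
               if not any(o != c and o[0] <= c[0] and c[1] <= o[1] for o in candidates)]
    regions.sort()
    return regions


def true_and_shared_regions(truth: TruthSet):
    """Maximal intervals shared by all diseased and by no normal individual.

    An interval is *shared* when some per-diseased choice of one haplotype is
    identical across all diseased individuals on it and no normal haplotype
    equals that sequence on the whole interval.  For a fixed choice the
    candidate intervals are exactly its maximal agreement runs that every
    normal haplotype mismatches at least once; the shared regions are the
    inclusion-maximal candidates over all choices.  The true region is the
    shared region containing the mutation site.
    """
    d_ids = [i for i, dis in zip(truth.output_ids, truth.output_diseased) if dis]
    n_ids = [i for i, dis in zip(truth.output_ids, truth.output_diseased) if not dis]
    d_haps = [truth.haplotypes[i] for i in d_ids]
    n_haps = [truth.haplotypes[i][j] for i in n_ids for j in (0, 1)]
    regions = shared_regions_from_haplotypes(d_haps, n_haps)
    containing = [r for r in regions if r[0] <= truth.mutation_site <= r[1]]
    if not containing:
        raise SimulationError(
            "no shared region contains the mutation site (a normal individual "
            "carries an identical-by-state copy of the mutant segment)")
    # the true region: the largest shared region around the mutation site
    true_region = max(containing, key=lambda r: (r[1] - r[0], -r[0]))
    return true_region, regions


# ---------------------------------------------------------------------------
# truth writers (plain TSV)

def write_truth_haplotypes(truth: TruthSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("member\thap\tmutant\tsequence\n")
        for mid in truth.output_ids:
            h = truth.haplotypes[mid]
            for j in (0, 1):
                seq = "".join(str(int(v)) for v in h[j])
                fh.write(f"{mid}\t{j}\t{int(truth.mutant[mid][j])}\t{seq}\n")


def write_truth_regions(truth: TruthSet, path) -> None:
    """1-based inclusive true/shared regions plus the mutation site."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tstart\tend\n")
        fh.write(f"mutation_site\t{truth.mutation_site_1based}\t{truth.mutation_site_1based}\n")
        tr = truth.true_region
        fh.write(f"true\t{tr[0] + 1}\t{tr[1] + 1}\n")
        for a, b in truth.shared_regions:
            fh.write(f"shared\t{a + 1}\t{b + 1}\n")


def read_truth_regions(path):
    """Returns ``(mutation_site_1based, true_region, shared_regions)`` with
    1-based inclusive interval tuples."""
    mut = true_region = None
    shared = []
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            kind, a, b = line.rstrip("\n").split("\t")
            if kind == "mutation_site":
                mut = int(a)
            elif kind == "true":
                true_region = (int(a), int(b))
            else:
                shared.append((int(a), int(b)))
    return mut, true_region, shared
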