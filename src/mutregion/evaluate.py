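"""Precision/recall of reported regions against simulator truth.

All four metrics are SNP-count overlaps of the top-k reported regions with
the truth: *precision* divides the correctly detected SNPs by the reported
SNPs, *recall* by the SNPs of the true mutation region; the primed variants
replace the true region with the union of all shared mutation regions (a
superset of the true region, so precision' >= precision always).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import scan as _scan
from . import simulate as _sim
from .genotype_io import GenotypeMatrix


@dataclass
class EvalResult:
    precision: float
    recall: float
    precision_shared: float
    recall_shared: float
    k_used: int
    empty_report: bool = False


def _interval_set(intervals):
    """Merge 1-based inclusive intervals into disjoint sorted form."""
    ivs = sorted(intervals)
    out = []
    for a, b in ivs:
        if a > b:
            raise ValueError("interval start > end")
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _size(intervals) -> int:
    return sum(b - a + 1 for a, b in intervals)


def _overlap(xs, ys) -> int:
    total = 0
    for a, b in xs:
        for c, d in ys:
            lo, hi = max(a, c), min(b, d)
            if lo <= hi:
                total += hi - lo + 1
    return total


def evaluate(reported: Sequence[tuple], true_region: tuple,
             shared: Sequence[tuple], k_used: int = 1) -> EvalResult:
    """Score top-k reported regions (1-based inclusive intervals).

    An empty report yields 0/0/0/0 with ``empty_report`` set; the true region
    must be nonempty.
    """
    if true_region is None or true_region[0] > true_region[1]:
        raise ValueError("true region must be a nonempty interval")
    if not reported:
        return EvalResult(0.0, 0.0, 0.0, 0.0, k_used, empty_report=True)
    rep = _interval_set(reported)
    truth = [tuple(true_region)]
    shared_u = _interval_set(shared) if shared else truth
    correct = _overlap(rep, truth)
    correct_shared = _overlap(rep, shared_u)
    return EvalResult(
        precision=correct / _size(rep),
        recall=correct / _size(truth),
        precision_shared=correct_shared / _size(rep),
        recall_shared=correct_shared / _size(shared_u),
        k_used=k_used,
    )


def top_k_intervals(regions: Sequence, k: int) -> list:
    """1-based inclusive intervals of the k highest-scoring regions.

    Ties in score are broken by leftmost start (deterministic).
    """
    ordered = sorted(regions, key=lambda r: (-r.score, r.start))
    return [(r.start + 1, r.end + 1) for r in ordered[:k]]


# ---------------------------------------------------------------------------
# replicated simulate -> detect -> evaluate

@dataclass
class BatchResult:
    per_replicate: list  # [(EvalResult top1, EvalResult top3, hit_top3)]
    n_failed: int
    n_reps: int

    def _means(self, which: int, include_empty: bool) -> dict:
        rows = [r[which] for r in self.per_replicate]
        if not include_empty:
            rows = [r for r in rows if not r.empty_report]
        if not rows:
            return {k: float("nan") for k in
                    ("precision", "recall", "precision_shared", "recall_shared")}
        return {
            "precision": float(np.mean([r.precision for r in rows])),
            "recall": float(np.mean([r.recall for r in rows])),
            "precision_shared": float(np.mean([r.precision_shared for r in rows])),
            "recall_shared": float(np.mean([r.recall_shared for r in rows])),
        }

    def means(self, k: int = 1, include_empty: bool = True) -> dict:
        """Mean metrics over replicates for top-1 (k=1) or top-3 (k=3);
        ``include_empty`` counts empty reports as zeros (the alternative
        excludes them)."""
        return self._means(0 if k == 1 else 1, include_empty)

    @property
    def hit_rate_top3(self) -> float:
        """Fraction of replicates whose top-3 report contains the mutation site."""
        if not self.per_replicate:
            return float("nan")
        return float(np.mean([r[2] for r in self.per_replicate]))


def run_replicate(ped: _sim.Pedigree, gmap: _sim.GeneticMap,
                  cfg: _sim.SimulationConfig, rng: np.random.Generator,
                  L: int = _scan.DEFAULT_WINDOW, bridge_gap: int = 0):
    """One simulate -> detect -> evaluate pass.

    Returns ``(top1 EvalResult, top3 EvalResult, mutation site in top-3)``.
    """
    truth, matrix = _sim.drop_pedigree(ped, gmap, cfg, rng)
    regions = _scan.detect_regions(matrix, L=L, bridge_gap=bridge_gap)
    tr = (truth.true_region[0] + 1, truth.true_region[1] + 1)
    shared = [(a + 1, b + 1) for a, b in truth.shared_regions]
    res = []
    for k in (1, 3):
        res.append(evaluate(top_k_intervals(regions, k), tr, shared, k_used=k))
    mut1 = truth.mutation_site_1based
    hit = any(a <= mut1 <= b for a, b in top_k_intervals(regions, 3))
    return res[0], res[1], hit


def batch_evaluate(ped: _sim.Pedigree, gmap: _sim.GeneticMap,
                   cfg: _sim.SimulationConfig, n_reps: int, master_seed: int,
                   L: int = _scan.DEFAULT_WINDOW, bridge_gap: int = 0) -> BatchResult:
    """Replicated evaluation with per-replicate seeds derived from one master
    seed; a crashed replicate is recorded and excluded."""
    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    rows = []
    failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            rows.append(run_replicate(ped, gmap, cfg, rng, L=L, bridge_gap=bridge_gap))
        except (_sim.SimulationError, ValueError) as e:
            failed += 1
            import logging
            logging.getLogger(__name__).warning("replicate failed: %s", e)
    return BatchResult(rows, failed, n_reps)
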