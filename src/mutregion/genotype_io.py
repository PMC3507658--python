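"""File formats and the genotype data model.

The program's sole real input is a matrix of unphased genotypes on one
chromosome for ``n`` individuals, coded per site as 0 (homozygous 0),
1 (homozygous 1) or 2 (heterozygous), each individual labelled diseased or
normal.  Two readers are provided: a simple TSV format (documented in the
README) and biallelic VCF via cyvcf2.

All user-facing coordinates are 1-based inclusive SNP ordinals (the field's
convention of "the 124561-th SNP site"); internal computation uses 0-based
half-open spans.  :func:`to_report_coords` / :func:`from_report_coords` are
the single audited converters between the two frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: internal marker for a missing genotype call
MISSING = np.int8(-9)

#: literal used for missing calls in the genotype TSV
MISSING_TOKEN = "N"

DISEASED, NORMAL = "D", "U"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# coordinate conversion (the single audited converter)

def to_report_coords(start0: int, end0_closed: int) -> tuple[int, int]:
    """0-based closed interval -> 1-based inclusive SNP ordinals."""
    return start0 + 1, end0_closed + 1


def from_report_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive SNP ordinals -> 0-based closed interval."""
    return start1 - 1, end1 - 1


def inclusive_length(start1: int, end1: int) -> int:
    """Number of SNP sites in a 1-based inclusive interval."""
    if start1 > end1:
        raise ValueError(f"start {start1} > end {end1}")
    return end1 - start1 + 1


# ---------------------------------------------------------------------------
# data model

@dataclass
class GenotypeMatrix:
    """n individuals x S SNP sites of ternary genotype codes.

    ``codes`` has shape (n, S) over {0, 1, 2, MISSING}; ``snp_index`` keeps the
    1-based ordinal of each surviving site in whichever frame the matrix is
    reported in (it is rewritten by :func:`drop_missing_sites` unless the
    original frame is requested).
    """

    individual_ids: list
    diseased: np.ndarray  # bool per individual
    snp_ids: list
    codes: np.ndarray  # int8 (n, S)
    snp_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.diseased = np.asarray(self.diseased, dtype=bool)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, S = self.codes.shape
        if len(self.individual_ids) != n or len(self.diseased) != n:
            raise ValueError("individual annotations do not match matrix shape")
        if len(self.snp_ids) != S:
            raise ValueError("snp_ids length does not match matrix shape")
        if S < 1:
            raise ValueError("need at least one SNP site")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.snp_ids)) != S:
            raise ValueError("snp ids must be unique")
        if not self.diseased.any() or self.diseased.all():
            raise ValueError("need at least one diseased and one normal individual")
        ok = np.isin(self.codes, [0, 1, 2, MISSING])
        if not ok.all():
            bad = self.codes[~ok][0]
            raise ValueError(f"invalid genotype code {bad}")
        if self.snp_index is None:
            self.snp_index = np.arange(1, S + 1, dtype=np.int64)
        else:
            self.snp_index = np.asarray(self.snp_index, dtype=np.int64)
            if len(self.snp_index) != S:
                raise ValueError("snp_index length does not match matrix shape")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def statuses(self) -> list:
        return [DISEASED if d else NORMAL for d in self.diseased]


@dataclass(frozen=True)
class RegionRecord:
    """A reported mutation region in 1-based inclusive SNP ordinals."""

    start: int
    end: int
    dh: int
    score: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.dh < 1:
            raise ValueError("dh must be >= 1")

    @property
    def length(self) -> int:
        return inclusive_length(self.start, self.end)


# ---------------------------------------------------------------------------
# genotype TSV

def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the genotype TSV format.

    Line 1: ``#STATUS`` then one ``D``/``U`` per individual.
    Line 2: ``snp_id`` then the individual ids.
    Then one row per SNP: id followed by one code per individual in
    {0, 1, 2, N}.  Missing calls survive as :data:`MISSING` (run
    :func:`drop_missing_sites` before analysis).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: need a #STATUS line, a header and >=1 SNP row")
    status_row = lines[0].split("\t")
    if status_row[0] != "#STATUS":
        raise ParseError(f"{path}:1: first line must start with '#STATUS'")
    header = lines[1].split("\t")
    ids = header[1:]
    statuses = status_row[1:]
    if len(statuses) != len(ids):
        raise ParseError(f"{path}:1: {len(statuses)} statuses for {len(ids)} individuals")
    bad = [s for s in statuses if s not in (DISEASED, NORMAL)]
    if bad:
        raise ParseError(f"{path}:1: unknown status {bad[0]!r} (use D or U)")
    snp_ids, rows = [], []
    seen = set()
    code_map = {"0": 0, "1": 1, "2": 2, MISSING_TOKEN: int(MISSING)}
    for lineno, line in enumerate(lines[2:], start=3):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(ids) + 1:
            raise ParseError(f"{path}:{lineno}: expected {len(ids) + 1} columns, got {len(parts)}")
        if parts[0] in seen:
            raise ParseError(f"{path}:{lineno}: duplicate snp_id {parts[0]!r}")
        seen.add(parts[0])
        snp_ids.append(parts[0])
        try:
            rows.append([code_map[tok] for tok in parts[1:]])
        except KeyError as e:
            raise ParseError(f"{path}:{lineno}: invalid genotype code {e.args[0]!r}") from None
    if not rows:
        raise ParseError(f"{path}: no SNP rows")
    codes = np.array(rows, dtype=np.int8).T  # (n, S)
    return GenotypeMatrix(ids, [s == DISEASED for s in statuses], snp_ids, codes)


def write_genotype_tsv(m: GenotypeMatrix, path) -> None:
    """Inverse of :func:`read_genotype_tsv` (byte-identical round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#STATUS\t" + "\t".join(m.statuses()) + "\n")
        fh.write("snp_id\t" + "\t".join(m.individual_ids) + "\n")
        inv = {0: "0", 1: "1", 2: "2", int(MISSING): MISSING_TOKEN}
        for s in range(m.n_sites):
            toks = [inv[int(v)] for v in m.codes[:, s]]
            fh.write(m.snp_ids[s] + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, sample_status: Mapping[str, str]) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF.

    ``sample_status`` maps sample id -> 'D' (diseased) or 'U' (normal); only
    mapped samples are loaded.  GT 0/0 -> 0, 1/1 -> 1, 0/1 or 1/0 -> 2 (phase
    is ignored), missing -> :data:`MISSING`.  Multi-allelic records are
    skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    missing_samples = [s for s in sample_status if s not in vcf.samples]
    if missing_samples:
        raise ValueError(f"samples not in VCF: {missing_samples}")
    ids = [s for s in vcf.samples if s in sample_status]
    idx = [vcf.samples.index(s) for s in ids]
    snp_ids, cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        col = []
        for i in idx:
            a, b = rec.genotypes[i][0], rec.genotypes[i][1]
            if a < 0 or b < 0:
                col.append(int(MISSING))
            elif a == b:
                col.append(a)
            else:
                col.append(2)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(col)
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    if not cols:
        raise ValueError("no biallelic SNP records in VCF")
    codes = np.array(cols, dtype=np.int8).T
    statuses = [sample_status[s] for s in ids]
    bad = [s for s in statuses if s not in (DISEASED, NORMAL)]
    if bad:
        raise ValueError(f"unknown status {bad[0]!r} (use D or U)")
    return GenotypeMatrix(ids, [s == DISEASED for s in statuses], snp_ids, codes)


# ---------------------------------------------------------------------------
# missing-data pre-processing

def drop_missing_sites(m: GenotypeMatrix, report_original_index: bool = False) -> GenotypeMatrix:
    """Delete every SNP site at which any individual has a missing call.

    By default surviving sites are re-indexed 1..S' (coordinates are then
    reported in the filtered frame, matching the convention of indexing sites
    after elimination of unknown genotypes); with ``report_original_index``
    the pre-filter ordinals are retained instead.
    """
    keep = ~(m.codes == MISSING).any(axis=0)
    if not keep.any():
        raise ValueError("no usable sites: every SNP has a missing call")
    if keep.all():
        idx = m.snp_index if report_original_index else None
        return GenotypeMatrix(list(m.individual_ids), m.diseased.copy(),
                              list(m.snp_ids), m.codes.copy(), idx)
    snp_ids = [sid for sid, k in zip(m.snp_ids, keep) if k]
    idx = m.snp_index[keep] if report_original_index else None
    return GenotypeMatrix(list(m.individual_ids), m.diseased.copy(),
                          snp_ids, m.codes[:, keep], idx)


# ---------------------------------------------------------------------------
# region report

REGION_COLUMNS = ["start", "end", "length", "dh", "score"]


def write_regions(regions: Sequence[RegionRecord], path) -> None:
    """TSV region report (1-based inclusive bounds, input order preserved)."""
    df = pd.DataFrame(
        [(r.start, r.end, r.length, r.dh, r.score) for r in regions],
        columns=REGION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [RegionRecord(int(r.start), int(r.end), int(r.dh), int(r.score))
            for r in df.itertuples()]
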