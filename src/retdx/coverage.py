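"""Per-base coverage QC over the clinically analysed region.

Targeted panels occasionally leave contiguous stretches of a coding exon
under-covered (classically GC-rich exons; the service's exemplar is a
460-base stretch of a GUCY2D coding exon below 50×, 76.2% GC).  Such runs
are flagged for capillary-sequencing fallback.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .regions import GenomicInterval, merge_intervals


@dataclass(slots=True)
class DepthProfile:
    """Dense per-base depths starting at 0-based ``start`` on ``chrom``."""

    chrom: str
    start: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or len(self.depths) < 1:
            raise ValueError("depths must be a non-empty 1-D array")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.depths)

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        if iv.chrom != self.chrom or iv.start < self.start or iv.end > self.end:
            raise ValueError(f"region {iv} outside profile span [{self.start},{self.end})")
        return self.depths[iv.start - self.start : iv.end - self.start]


def load_depth_tsv(path: str | Path) -> list[DepthProfile]:
    """Three-column TSV (chrom, 1-based pos, depth); contiguous runs per
    chromosome become one dense profile each."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            rows.setdefault(row[0], []).append((int(row[1]) - 1, int(row[2])))
    profiles = []
    for chrom in sorted(rows):
        entries = sorted(rows[chrom])
        run: list[tuple[int, int]] = []
        for pos, depth in entries:
            if run and pos != run[-1][0] + 1:
                profiles.append(DepthProfile(chrom, run[0][0], np.array([d for _, d in run])))
                run = []
            run.append((pos, depth))
        if run:
            profiles.append(DepthProfile(chrom, run[0][0], np.array([d for _, d in run])))
    return profiles


def region_fraction(
    profile: DepthProfile,
    region: Sequence[GenomicInterval],
    threshold: int,
) -> float:
    """Fraction of region bases covered at ≥ ``threshold``×."""
    region = merge_intervals(region)
    if not region:
        raise ValueError("empty region")
    total = 0
    covered = 0
    for iv in region:
        d = profile.slice(iv)
        total += len(d)
        covered += int((d >= threshold).sum())
    return covered / total


def low_coverage_runs(
    profile: DepthProfile,
    region: Sequence[GenomicInterval],
    threshold: int,
    min_len: int = 1,
) -> list[GenomicInterval]:
    """Maximal runs of consecutive region bases below ``threshold`` with
    length ≥ ``min_len`` — the capillary-fallback candidates."""
    out: list[GenomicInterval] = []
    for iv in merge_intervals(region):
        d = profile.slice(iv)
        below = d < threshold
        i = 0
        n = len(below)
        while i < n:
            if below[i]:
                j = i
                while j < n and below[j]:
                    j += 1
                if j - i >= min_len:
                    out.append(GenomicInterval(iv.chrom, iv.start + i, iv.start + j))
                i = j
            else:
                i += 1
    return out


def gc_content(seq: str) -> float:
    """(G+C) / (non-N length) of a nucleotide string."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    denom = sum(1 for c in s if c != "N")
    if denom == 0:
        raise ValueError("sequence is all N")
    return sum(1 for c in s if c in "GC") / denom


def coverage_report(
    profiles: Iterable[DepthProfile],
    regions: dict[str, list[GenomicInterval]],
    thresholds: Sequence[int] = (20, 50),
    run_threshold: int = 50,
    run_min_len: int = 100,
) -> dict:
    """Per-gene and pooled coverage fractions plus flagged fallback runs.

    Emits both the pooled (all bases together) and the per-gene-mean view of
    each threshold fraction, since cohort summaries are quoted both ways.
    """
    by_chrom = {p.chrom: p for p in profiles}
    per_gene: dict[str, dict] = {}
    pooled_total = 0
    pooled_covered = {t: 0 for t in thresholds}
    flagged: list[GenomicInterval] = []
    for gene in sorted(regions):
        ivs = merge_intervals(regions[gene])
        if not ivs:
            continue
        profile = by_chrom.get(ivs[0].chrom)
        if profile is None:
            continue
        entry = {}
        n_bases = sum(len(iv) for iv in ivs)
        pooled_total += n_bases
        for t in thresholds:
            frac = region_fraction(profile, ivs, t)
            entry[f"frac_ge_{t}x"] = frac
            pooled_covered[t] += round(frac * n_bases)
        runs = low_coverage_runs(profile, ivs, run_threshold, run_min_len)
        entry["fallback_runs"] = [(r.chrom, r.start, r.end) for r in runs]
        flagged.extend(runs)
        per_gene[gene] = entry
    report = {
        "per_gene": per_gene,
        "pooled": {
            f"frac_ge_{t}x": (pooled_covered[t] / pooled_total if pooled_total else 0.0)
            for t in thresholds
        },
        "per_gene_mean": {
            f"frac_ge_{t}x": (
                float(np.mean([g[f"frac_ge_{t}x"] for g in per_gene.values()]))
                if per_gene
                else 0.0
            )
            for t in thresholds
        },
        "n_fallback_runs": len(flagged),
    }
    return report
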