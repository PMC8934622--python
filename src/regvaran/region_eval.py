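"""Evaluation of a region set against functional features and score tracks.

Provides size-matched random control sampling (per chromosome, avoiding
excluded intervals), Fisher-exact enrichment of regions over controls for
overlap with functional feature sets, per-region conservation summaries
over partially covered per-position score tracks, and Mann-Whitney U
comparisons between region and control summary distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from regvaran.genome import GenomeModel, merge_intervals, read_bed3
from regvaran.regiondb import RegulatoryRegion


@dataclass
class EnrichmentResult:
    feature: str
    a: int  # regions hitting the feature
    b: int  # regions not hitting
    c: int  # controls hitting
    d: int  # controls not hitting
    odds_ratio: float
    p_value: float
    haldane_corrected: bool
    side: str = "two-sided"


@dataclass
class ConservationSummary:
    """Per-region track summaries over covered bases only."""

    region_ids: list[str]
    thresholds: tuple[float, ...]
    fraction_above: np.ndarray  # shape (n_regions, n_thresholds); NaN if uncovered
    median: np.ndarray  # NaN if uncovered
    maximum: np.ndarray
    n_uncovered: int


# ---------------------------------------------------------------------------
# Control sampling


def sample_controls(
    genome: GenomeModel,
    regions: Sequence[RegulatoryRegion],
    seed: int,
    max_tries: int = 1000,
) -> list[RegulatoryRegion]:
    """Sample size-matched random control regions per chromosome.

    For every chromosome the control count equals the source count and the
    control size multiset equals the source size multiset exactly; controls
    never overlap the genome's excluded intervals. Identical seeds give
    identical output. Raises if a size cannot be placed within
    ``max_tries`` draws on its chromosome.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r.length)

    controls: list[RegulatoryRegion] = []
    idx = 0
    for chrom in sorted(by_chrom):
        sizes = sorted(by_chrom[chrom])
        usable = genome.usable_intervals(chrom)
        for size in sizes:
            slots = [(s, e) for s, e in usable if e - s >= size]
            if not slots:
                raise RuntimeError(f"no usable interval on {chrom} can host a {size}-bp control")
            # placement inside a usable slot cannot overlap an excluded
            # interval, so a single weighted draw always succeeds
            weights = np.array([e - s - size + 1 for s, e in slots], dtype=float)
            slot = slots[rng.choice(len(slots), p=weights / weights.sum())]
            start = int(rng.integers(slot[0], slot[1] - size + 1))
            controls.append(
                RegulatoryRegion(
                    region_id=f"control_{idx:06d}",
                    chrom=chrom,
                    start=start,
                    end=start + size,
                    region_type="enhancer",
                    sources={"control"},
                )
            )
            idx += 1
    return controls


# ---------------------------------------------------------------------------
# Fisher enrichment


def _hits(regions: Sequence[RegulatoryRegion], feature: dict[str, list[tuple[int, int]]]) -> int:
    n = 0
    for r in regions:
        for s, e in feature.get(r.chrom, []):
            if s < r.end and e > r.start:
                n += 1
                break
    return n


def load_feature_bed(
    bed: str | Path | Iterable[tuple[str, int, int]],
) -> dict[str, list[tuple[int, int]]]:
    ivs = read_bed3(bed) if isinstance(bed, (str, Path)) else bed
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in ivs:
        by_chrom.setdefault(chrom, []).append((s, e))
    return {c: merge_intervals(v) for c, v in by_chrom.items()}


def fisher_enrichment(
    regions: Sequence[RegulatoryRegion],
    controls: Sequence[RegulatoryRegion],
    feature_bed: str | Path | Iterable[tuple[str, int, int]],
    feature_name: str = "feature",
) -> EnrichmentResult:
    """Two-sided Fisher exact test: regions vs controls hitting the feature.

    A region "hits" if it overlaps at least one feature base. The odds
    ratio is (a*d)/(b*c); when any cell is zero the Haldane correction
    (+0.5 to every cell) is applied to the OR only, and the result is
    flagged. The p-value is the exact two-sided hypergeometric probability.
    """
    if not controls:
        raise ValueError("empty control set")
    feature = load_feature_bed(feature_bed)
    a = _hits(regions, feature)
    b = len(regions) - a
    c = _hits(controls, feature)
    d = len(controls) - c
    haldane = 0 in (a, b, c, d)
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(feature_name, a, b, c, d, odds, float(p), haldane)


# ---------------------------------------------------------------------------
# Conservation / score summaries


class PositionTrack:
    """Per-position score track (chrom, 1-based pos, value), possibly partial."""

    def __init__(self, positions: dict[str, np.ndarray], values: dict[str, np.ndarray]):
        self.positions = positions  # sorted 0-based positions per chromosome
        self.values = values

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, float]]) -> "PositionTrack":
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for chrom, pos, val in records:
            by_chrom.setdefault(chrom, []).append((pos - 1, float(val)))
        positions, values = {}, {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            positions[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            values[chrom] = np.array([v for _, v in pairs])
        return cls(positions, values)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionTrack":
        """Read a 3-column TSV: chrom, pos (1-based), value; '#' lines skipped."""
        recs = []
        import gzip

        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                chrom, pos, val = line.split("\t")[:3]
                recs.append((chrom, int(pos), float(val)))
        return cls.from_records(recs)

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values at covered bases within the half-open interval."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.empty(0)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return self.values[chrom][lo:hi]

    def n_covered(self) -> int:
        return sum(len(p) for p in self.positions.values())


def conservation_summary(
    regions: Sequence[RegulatoryRegion],
    track: PositionTrack,
    thresholds: Sequence[float] = (1.0, 1.5, 2.0),
) -> ConservationSummary:
    """Per-region fraction of covered bases strictly above each threshold,
    plus median and maximum; regions with no covered base get NaN summaries
    and are counted as uncovered."""
    n = len(regions)
    frac = np.full((n, len(thresholds)), np.nan)
    med = np.full(n, np.nan)
    mx = np.full(n, np.nan)
    n_uncovered = 0
    for i, r in enumerate(regions):
        vals = track.region_values(r.chrom, r.start, r.end)
        if len(vals) == 0:
            n_uncovered += 1
            continue
        for j, t in enumerate(thresholds):
            frac[i, j] = np.mean(vals > t)
        med[i] = np.median(vals)
        mx[i] = np.max(vals)
    return ConservationSummary(
        region_ids=[r.region_id for r in regions],
        thresholds=tuple(thresholds),
        fraction_above=frac,
        median=med,
        maximum=mx,
        n_uncovered=n_uncovered,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for sample ``a``) and two-sided p.

    Uses exact enumeration when both samples have n <= 8 and no ties span
    the groups; otherwise the normal approximation with tie correction.
    Returns p = 1 when all values in both samples are identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and len(np.unique(pooled)) == len(pooled)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
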