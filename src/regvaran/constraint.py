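"""Per-region variation constraint from observed variant counts.

The expected number of variants in each region is modeled by ordinary
least squares on five covariates — region length, GC fraction, and the
fractions of the region overlapped by segmental duplications,
low-complexity regions and exons. The constraint value is the mid-rank
empirical CDF of the residual (expected − observed), so it lies in [0, 1]
and regions with higher values harbour fewer variants than expected.
Regions whose constraint exceeds the 99th percentile of the distribution
are flagged as constrained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from regvaran.genome import merge_intervals, read_bed3
from regvaran.regiondb import RegulatoryRegion

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ("length", "gc", "segdup", "lcr", "exonic")


@dataclass
class RegionCovariates:
    region_id: str
    length: int
    gc_fraction: float
    segdup_fraction: float
    lcr_fraction: float
    exonic_fraction: float
    observed_variants: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.region_id}: non-positive length")
        for name in ("gc_fraction", "segdup_fraction", "lcr_fraction", "exonic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.region_id}: {name}={v} outside [0,1]")
        if self.observed_variants < 0:
            raise ValueError(f"{self.region_id}: negative variant count")


@dataclass
class ConstraintFit:
    """OLS expectation model plus per-region residuals and constraint values."""

    region_ids: list[str]
    intercept: float
    coefficients: dict[str, float]  # keyed by COVARIATE_NAMES
    expected: np.ndarray
    observed: np.ndarray
    residuals: np.ndarray  # expected - observed; positive = fewer variants than expected
    constraint: np.ndarray = field(default=None)  # type: ignore[assignment]
    constrained: np.ndarray = field(default=None)  # type: ignore[assignment]
    flag_percentile: float = 99.0
    design: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def as_dict(self) -> dict[str, float]:
        """region_id -> constraint value."""
        return dict(zip(self.region_ids, self.constraint.tolist()))


# ---------------------------------------------------------------------------
# Counting and covariates


def count_observed(
    regions: Sequence[RegulatoryRegion],
    sites: "str | Path | Iterable[tuple[str, int]]",
    genome=None,
) -> dict[str, int]:
    """Count variant sites per region.

    ``sites`` is a VCF path or an iterable of (chrom, pos) with 1-based VCF
    positions; each site counts once regardless of the number of ALT
    alleles. A site's internal position pos-1 is counted when it falls in
    [start, end). Sites on chromosomes absent from ``genome`` (when given)
    are skipped with a warning.
    """
    if isinstance(sites, (str, Path)):
        import pysam

        with pysam.VariantFile(str(sites)) as vf:
            site_list = [(rec.chrom, rec.pos) for rec in vf]
    else:
        site_list = list(sites)

    positions: dict[str, list[int]] = {}
    n_skipped = 0
    seen: set[tuple[str, int]] = set()
    for chrom, pos in site_list:
        if (chrom, pos) in seen:  # multi-allelic records split across lines
            continue
        seen.add((chrom, pos))
        if genome is not None and chrom not in genome:
            n_skipped += 1
            continue
        positions.setdefault(chrom, []).append(pos - 1)
    if n_skipped:
        logger.warning("%d variant sites on chromosomes absent from the genome", n_skipped)
    for chrom in positions:
        positions[chrom] = sorted(positions[chrom])

    counts: dict[str, int] = {}
    for r in regions:
        pos = positions.get(r.chrom)
        if not pos:
            counts[r.region_id] = 0
            continue
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end - 1, side="right")
        counts[r.region_id] = int(hi - lo)
    return counts


def _overlap_fraction(region: RegulatoryRegion, merged: dict[str, list[tuple[int, int]]]) -> float:
    total = 0
    for s, e in merged.get(region.chrom, []):
        ov = min(e, region.end) - max(s, region.start)
        if ov > 0:
            total += ov
    return total / region.length


def gc_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    gc = sum(1 for b in sequence.upper() if b in "GC")
    return gc / len(sequence)


def compute_covariates(
    regions: Sequence[RegulatoryRegion],
    observed: dict[str, int],
    segdup_bed: str | Path | Iterable[tuple[str, int, int]] = (),
    lcr_bed: str | Path | Iterable[tuple[str, int, int]] = (),
    exon_bed: str | Path | Iterable[tuple[str, int, int]] = (),
    sequences: "dict[str, str] | None" = None,
    gc_table: "dict[str, float] | None" = None,
) -> list[RegionCovariates]:
    """Assemble the covariate table for the expectation model.

    Overlap fractions are computed against merged feature intervals.
    GC comes either from per-chromosome sequences or a precomputed
    region_id -> gc table; absent both, GC is set to 0.5 for all regions.
    """

    def load(bed) -> dict[str, list[tuple[int, int]]]:
        ivs = read_bed3(bed) if isinstance(bed, (str, Path)) else bed
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            by_chrom.setdefault(chrom, []).append((s, e))
        return {c: merge_intervals(v) for c, v in by_chrom.items()}

    segdup = load(segdup_bed)
    lcr = load(lcr_bed)
    exon = load(exon_bed)

    out = []
    for r in regions:
        if gc_table is not None:
            gc = gc_table.get(r.region_id, 0.5)
        elif sequences is not None and r.chrom in sequences:
            gc = gc_fraction(sequences[r.chrom][r.start : r.end])
        else:
            gc = 0.5
        out.append(
            RegionCovariates(
                region_id=r.region_id,
                length=r.length,
                gc_fraction=gc,
                segdup_fraction=_overlap_fraction(r, segdup),
                lcr_fraction=_overlap_fraction(r, lcr),
                exonic_fraction=_overlap_fraction(r, exon),
                observed_variants=observed.get(r.region_id, 0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expectation model


def _design_matrix(covariates: Sequence[RegionCovariates]) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [
            np.ones(len(covariates)),
            [c.length for c in covariates],
            [c.gc_fraction for c in covariates],
            [c.segdup_fraction for c in covariates],
            [c.lcr_fraction for c in covariates],
            [c.exonic_fraction for c in covariates],
        ]
    )
    y = np.array([c.observed_variants for c in covariates], dtype=float)
    return X, y


def fit_expectation(covariates: Sequence[RegionCovariates]) -> ConstraintFit:
    """OLS of observed count on the five covariates plus intercept.

    Requires n >= 10 x number of coefficients and a full-rank design; a
    rank-deficient design raises with the names of collinear columns.
    """
    n_coef = len(COVARIATE_NAMES) + 1
    if len(covariates) < 10 * n_coef:
        raise ValueError(
            f"need at least {10 * n_coef} regions to fit {n_coef} coefficients, "
            f"got {len(covariates)}"
        )
    X, y = _design_matrix(covariates)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite covariate or count values")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ("intercept",) + COVARIATE_NAMES
        collinear = []
        centered = X - X.mean(axis=0)
        norms = np.linalg.norm(centered, axis=0)
        for i in range(1, X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                if norms[i] == 0 or norms[j] == 0:
                    continue
                corr = centered[:, i] @ centered[:, j] / (norms[i] * norms[j])
                if abs(corr) > 1 - 1e-10:
                    collinear.append((names[i], names[j]))
        constant = [names[i] for i in range(1, X.shape[1]) if norms[i] == 0]
        raise ValueError(
            f"rank-deficient design (rank {rank} of {X.shape[1]}); "
            f"collinear column pairs: {collinear or 'n/a'}; constant columns: {constant or 'n/a'}"
        )

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    expected = X @ beta
    return ConstraintFit(
        region_ids=[c.region_id for c in covariates],
        intercept=float(beta[0]),
        coefficients=dict(zip(COVARIATE_NAMES, beta[1:].tolist())),
        expected=expected,
        observed=y,
        residuals=expected - y,
        design=X,
    )


def _midrank_ecdf(values: np.ndarray) -> np.ndarray:
    """Mid-rank empirical CDF: P(X < x) + P(X == x)/2, in [0, 1]."""
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    sorted_v = values[order]
    less = np.searchsorted(sorted_v, values, side="left")
    leq = np.searchsorted(sorted_v, values, side="right")
    return (less + 0.5 * (leq - less)) / n


def constraint_values(fit: ConstraintFit, studentized: bool = False) -> np.ndarray:
    """Map residuals to [0, 1] by the mid-rank empirical CDF.

    With ``studentized=True`` the residuals are first divided by their
    leverage-adjusted standard errors (internally studentized); the default
    ranks the raw residuals, which the mid-rank ECDF makes scale-free.
    """
    residuals = fit.residuals
    if studentized:
        X = fit.design
        lev = np.clip(
            np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X), 0, 1 - 1e-12
        )
        sigma = math.sqrt(float(np.sum(residuals**2)) / max(len(residuals) - X.shape[1], 1))
        if sigma > 0:
            residuals = residuals / (sigma * np.sqrt(1 - lev))
    fit.constraint = _midrank_ecdf(residuals)
    return fit.constraint


def flag_constrained(constraints: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Flag values strictly above the nearest-rank percentile of the set.

    The nearest-rank definition (q = sorted[ceil(p/100 * n) - 1]) keeps the
    flagged fraction at (100 - p)% up to integer rounding when values are
    distinct, and flags nothing when n is too small for the tail to exist.
    """
    constraints = np.asarray(constraints, dtype=float)
    n = len(constraints)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if not (0.0 <= percentile <= 100.0):
        raise ValueError("percentile must be in [0, 100]")
    k = max(int(math.ceil(percentile / 100.0 * n)), 1)
    q = np.sort(constraints)[k - 1]
    return constraints > q


def compute_constraint(
    covariates: Sequence[RegionCovariates],
    percentile: float = 99.0,
    studentized: bool = False,
) -> ConstraintFit:
    """Fit the expectation model, compute constraint values and flags."""
    fit = fit_expectation(covariates)
    constraint_values(fit, studentized=studentized)
    fit.constrained = flag_constrained(fit.constraint, percentile)
    fit.flag_percentile = percentile
    return fit


def write_constraint_tsv(fit: ConstraintFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tobserved\texpected\tresidual\tconstraint\tconstrained\n")
        for i, rid in enumerate(fit.region_ids):
            fh.write(
                f"{rid}\t{int(fit.observed[i])}\t{fit.expected[i]:.6g}\t"
                f"{fit.residuals[i]:.6g}\t{fit.constraint[i]:.6g}\t"
                f"{int(bool(fit.constrained[i]))}\n"
            )
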