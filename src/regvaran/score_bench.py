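"""Benchmarking of non-coding impact prediction scores.

Given a labeled variant set (disease-causing positives vs matched
negatives) and per-score value tracks, computes ROC AUC by concordant-pair
counting and calibrates three operating thresholds per score: the most
stringent cutoff retaining TPR >= 0.9, the most sensitive cutoff with
FDR <= 0.5, and the maximum-accuracy cutoff. Variants missing a score are
excluded per score and the exclusion counted; scores are oriented so that
higher means more likely pathogenic, and a variant is called positive when
its score is >= the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regvaran.genome import GenomeModel
from regvaran.region_eval import PositionTrack


@dataclass
class ScoreThresholds:
    score: str
    auc: float
    threshold_tpr90: float  # largest threshold with TPR >= 0.9
    fdr_at_tpr90: float
    threshold_fdr50: float | None  # smallest threshold with FDR <= 0.5; None if unattainable
    tpr_at_fdr50: float | None
    threshold_max_accuracy: float
    max_accuracy: float
    n_used: int
    n_missing: int
    coverage: float | None = None

    @property
    def fdr50_attainable(self) -> bool:
        return self.threshold_fdr50 is not None


def _check_labels(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative example")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney probability (concordant + 0.5*ties)/(n1*n0).

    Missing scores (NaN) are excluded together with their labels.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep].astype(bool)
    _check_labels(y)
    ranks = stats.rankdata(s)  # mid-ranks handle ties
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _confusion(s: np.ndarray, y: np.ndarray, t: float) -> tuple[int, int, int, int]:
    call = s >= t
    tp = int((call & y).sum())
    fp = int((call & ~y).sum())
    fn = int((~call & y).sum())
    tn = int((~call & ~y).sum())
    return tp, fp, fn, tn


def calibrate_thresholds(
    scores: Sequence[float], labels: Sequence[int], name: str = "score"
) -> ScoreThresholds:
    """Calibrate operating thresholds over the observed score values.

    threshold_tpr90: the largest observed value t with TPR(t) >= 0.9
    (the most specific cutoff that keeps sensitivity at 0.9).
    threshold_fdr50: the smallest observed value t with FDR(t) <= 0.5;
    None (flagged) when no cutoff attains it.
    threshold_max_accuracy: maximises accuracy; ties toward the higher
    threshold.
    """
    s_all = np.asarray(scores, dtype=float)
    y_all = np.asarray(labels, dtype=int)
    keep = ~np.isnan(s_all)
    s, y = s_all[keep], y_all[keep].astype(bool)
    n_missing = int((~keep).sum())
    _check_labels(y)

    candidates = np.unique(s)
    t_tpr90 = None
    fdr_at = None
    t_fdr50 = None
    tpr_at = None
    t_acc = None
    best_acc = -1.0
    for t in candidates:  # ascending
        tp, fp, fn, tn = _confusion(s, y, t)
        tpr = tp / (tp + fn)
        fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
        acc = (tp + tn) / len(y)
        if tpr >= 0.9:
            t_tpr90, fdr_at = float(t), fdr  # keeps the largest qualifying t
        if fdr <= 0.5 and t_fdr50 is None:
            t_fdr50, tpr_at = float(t), tpr
        if acc >= best_acc:  # >= keeps the higher threshold on ties
            best_acc, t_acc = acc, float(t)

    if t_tpr90 is None:
        # TPR(min observed score) is always 1 under the >= convention
        raise AssertionError("unreachable: minimum threshold always has TPR 1")
    return ScoreThresholds(
        score=name,
        auc=roc_auc(s_all, y_all),
        threshold_tpr90=t_tpr90,
        fdr_at_tpr90=fdr_at,
        threshold_fdr50=t_fdr50,
        tpr_at_fdr50=tpr_at,
        threshold_max_accuracy=t_acc,
        max_accuracy=best_acc,
        n_used=len(s),
        n_missing=n_missing,
    )


def coverage_fraction(track: PositionTrack, genome: GenomeModel) -> float:
    """Fraction of genome positions with a precomputed score value."""
    return track.n_covered() / genome.total_length


def composite_metric(thresholds: ScoreThresholds) -> float:
    """Optional composite performance summary: mean of AUC and max accuracy.

    A single-number convenience for ranking scores; not a published metric.
    """
    return 0.5 * (thresholds.auc + thresholds.max_accuracy)


def benchmark_scores(
    labeled: pd.DataFrame,
    tracks: dict[str, PositionTrack],
    genome: GenomeModel | None = None,
) -> pd.DataFrame:
    """Benchmark several score tracks against one labeled variant table.

    ``labeled`` needs columns chrom, pos (1-based), label (1 positive /
    0 negative). Each variant's score is looked up at its position;
    variants without a value are excluded for that score only.
    """
    rows = []
    for name, track in tracks.items():
        vals = []
        for chrom, pos in zip(labeled["chrom"], labeled["pos"]):
            v = track.region_values(str(chrom), int(pos) - 1, int(pos))
            vals.append(float(v[0]) if len(v) else np.nan)
        th = calibrate_thresholds(vals, labeled["label"].to_numpy(), name=name)
        if genome is not None:
            th.coverage = coverage_fraction(track, genome)
        rows.append(
            {
                "score": th.score,
                "auc": th.auc,
                "threshold_tpr90": th.threshold_tpr90,
                "fdr_at_tpr90": th.fdr_at_tpr90,
                "threshold_fdr50": th.threshold_fdr50,
                "tpr_at_fdr50": th.tpr_at_fdr50,
                "threshold_max_accuracy": th.threshold_max_accuracy,
                "max_accuracy": th.max_accuracy,
                "n_used": th.n_used,
                "n_missing": th.n_missing,
                "coverage": th.coverage,
            }
        )
    return pd.DataFrame(rows)


def read_labeled_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeled variant TSV (chrom, pos, ref, alt, label)."""
    df = pd.read_csv(path, sep="\t")
    if df["label"].dtype == object:
        df["label"] = (df["label"].str.lower() == "positive").astype(int)
    return df
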