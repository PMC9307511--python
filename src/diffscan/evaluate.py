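"""Interval-level evaluation of predicted SVRs against ground truth.

Metrics (all at nucleotide-position resolution):

- Jaccard index |A ∩ B| / |A ∪ B| between predicted and true position sets;
- average distance: for each predicted nucleotide, the number of nucleotides
  between it and the nearest true-SVR nucleotide (0 inside truth), averaged
  per predicted region and over all predicted nucleotides;
- precision / recall of the top-k ranked positions at varying cutoffs k;
- specificity = correctly non-predicted / all true non-SVR positions; and
- the negative-control position-level false positive rate
  |predicted| / transcript length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "AnnotationSet",
    "DistanceReport",
    "jaccard_index",
    "average_distance",
    "precision_recall",
    "specificity_and_fpr",
    "load_flu_annotation",
    "read_annotation_table",
    "intervals_to_positions",
    "default_cutoffs",
]


@dataclass
class AnnotationSet:
    """True-SVR intervals (1-based inclusive, merged) on one transcript."""

    transcript_id: str
    intervals: list[tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        merged: list[tuple[int, int]] = []
        for s, e in sorted((int(s), int(e)) for s, e in self.intervals):
            if s < 1 or e > self.length or e < s:
                raise ValidationError(
                    f"interval ({s}, {e}) invalid for transcript of length {self.length}"
                )
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.intervals = merged

    def positions(self) -> set[int]:
        return intervals_to_positions(self.intervals)

    @property
    def n_positions(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


def intervals_to_positions(intervals: Iterable[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out.update(range(int(s), int(e) + 1))
    return out


def jaccard_index(predicted: set[int] | Sequence[int], truth: set[int] | Sequence[int]) -> float:
    """|A ∩ B| / |A ∪ B| over nucleotide position sets; 0 when both empty."""
    a, b = set(predicted), set(truth)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class DistanceReport:
    """Average distance of predicted SVRs to truth; ``applicable`` is False
    when there are no predicted regions (no distance to report)."""

    applicable: bool
    per_nucleotide: float = float("nan")  # headline: mean over all predicted nt
    per_region: list[float] = field(default_factory=list)
    per_region_mean: float = float("nan")


def average_distance(
    predicted_svrs: Sequence[tuple[int, int]], truth: AnnotationSet
) -> DistanceReport:
    """Mean nucleotide distance from predicted SVRs to the nearest truth position.

    A nucleotide inside a true SVR contributes 0; otherwise it contributes the
    gap (in nucleotides) to the nearest truth nucleotide. Reported per
    predicted region and aggregated over all predicted nucleotides
    (the headline number, length-weighted across regions).
    """
    if not truth.intervals:
        raise ValidationError("average distance is undefined for empty truth")
    if not predicted_svrs:
        return DistanceReport(applicable=False)
    truth_pos = np.array(sorted(truth.positions()))
    per_region: list[float] = []
    all_d: list[np.ndarray] = []
    for s, e in predicted_svrs:
        pos = np.arange(int(s), int(e) + 1)
        idx = np.searchsorted(truth_pos, pos)
        left = np.where(idx > 0, pos - truth_pos[np.maximum(idx - 1, 0)], np.inf)
        right = np.where(idx < truth_pos.size, truth_pos[np.minimum(idx, truth_pos.size - 1)] - pos, np.inf)
        d = np.minimum(left, right).astype(float)
        per_region.append(float(d.mean()))
        all_d.append(d)
    flat = np.concatenate(all_d)
    return DistanceReport(
        applicable=True,
        per_nucleotide=float(flat.mean()),
        per_region=per_region,
        per_region_mean=float(np.mean(per_region)),
    )


def default_cutoffs(n_truth: int) -> list[int]:
    """Doubling top-k grid 5, 10, 20, 40, ... capped at 3x the truth size."""
    cap = max(5, 3 * n_truth)
    out = []
    k = 5
    while k <= cap:
        out.append(k)
        k *= 2
    if out and out[-1] != cap:
        out.append(cap)
    return out


def precision_recall(
    ranked_positions: Sequence[int],
    truth: set[int] | Sequence[int],
    cutoffs: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Precision and recall of top-k ranked positions at each cutoff k.

    precision = |top-k ∩ truth| / k, recall = |top-k ∩ truth| / |truth|.
    """
    truth_set = set(truth)
    if not truth_set:
        raise ValidationError("precision/recall need nonempty truth")
    if cutoffs is None:
        cutoffs = default_cutoffs(len(truth_set))
    ranked = list(ranked_positions)
    rows = []
    for k in cutoffs:
        k_eff = min(int(k), len(ranked))
        if k_eff == 0:
            continue
        hits = len(set(ranked[:k_eff]) & truth_set)
        rows.append((int(k), k_eff, hits / k_eff, hits / len(truth_set)))
    return pd.DataFrame(rows, columns=["cutoff", "k", "precision", "recall"])


def specificity_and_fpr(
    predicted_positions: set[int] | Sequence[int],
    truth: set[int] | Sequence[int],
    n: int,
) -> tuple[float, float]:
    """(specificity, position-level FPR) on a transcript of length n.

    Specificity is the fraction of true non-SVR positions not predicted;
    the FPR — the negative-control metric, where truth is empty — is the
    number of predicted positions divided by the transcript length.
    """
    if n < 1:
        raise ValidationError("transcript length must be >= 1")
    pred = set(predicted_positions)
    truth_set = set(truth)
    non_truth = n - len(truth_set)
    if non_truth > 0:
        spec = (non_truth - len(pred - truth_set)) / non_truth
    else:
        spec = float("nan")
    fpr = len(pred) / n
    return spec, fpr


def load_flu_annotation() -> AnnotationSet:
    """Curated SVR annotation of the B. cereus crcB fluoride riboswitch.

    The 100-nt transcript probed with and without fluoride has five annotated
    SVRs: positions 12-17, 22-27, 38-40, the singleton 48, and 67-74
    (24 nucleotides in total).
    """
    return AnnotationSet(
        transcript_id="flu_crcB_riboswitch",
        intervals=[(12, 17), (22, 27), (38, 40), (48, 48), (67, 74)],
        length=100,
    )


def read_annotation_table(path: str | Path, lengths: dict[str, int]) -> dict[str, AnnotationSet]:
    """Read truth intervals TSV (transcript_id, start, end) into AnnotationSets."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for col in ("transcript_id", "start", "end"):
        if col not in df.columns:
            raise ValidationError(f"{path}: annotation file needs column {col!r}")
    out = {}
    for tx, sub in df.groupby("transcript_id", sort=False):
        tx = str(tx)
        if tx not in lengths:
            raise ValidationError(f"{path}: no length known for transcript {tx!r}")
        out[tx] = AnnotationSet(
            tx, list(zip(sub["start"].astype(int), sub["end"].astype(int))), lengths[tx]
        )
    return out
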