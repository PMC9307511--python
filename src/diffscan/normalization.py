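"""Normalization of structure-probing reactivities across conditions.

Reactivities from two cellular conditions are made comparable in three steps:

1. per-replicate 90% winsorization followed by min-max rescaling to [0, 1],
   taming outliers and unit differences between platforms;
2. quantile normalization of within-condition replicates, so replicates of a
   condition share a value distribution;
3. a between-condition transform anchored on a "pivot" set S of nucleotide
   positions assumed structurally invariant: regressing log mean reactivity
   of the reference condition A on that of condition B over S,

       log r̄_A(j) ~ log α + β · log r̄_B(j),   j ∈ S,

   with Huber M-estimation (iterated reweighted least squares). log α
   absorbs the sequencing-depth difference, β the signal-to-noise
   difference. The fitted transform is extrapolated to every position:
   A is left unchanged, B becomes exp(log α̂ + β̂ · log r_B).

When no pivot is supplied, S is found by an iterative screen: positions are
tested for differential reactivity with the positional rank-sum test,
clearly flagged positions (p below ``screen_p``) are excluded, the transform
is refitted on the remainder, and the screen repeats on transformed data
until the set stabilizes. The screen is deliberately strict (default
``screen_p`` 0.05): it only needs to catch strongly differential positions,
because the Huber loss already downweights moderate contamination of S, and
excluding too many positions biases the extrapolated fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .io import (
    ReactivityDataset,
    ReactivityProfile,
    ValidationError,
)

__all__ = [
    "PivotSet",
    "NormalizationModel",
    "winsorize_rescale",
    "quantile_normalize",
    "select_pivot_set",
    "fit_between_condition_model",
    "normalize_dataset",
    "read_pivot_table",
    "write_pivot_table",
]

logger = logging.getLogger(__name__)

# floor applied before taking logs; reactivities are in [0,1] after Step 1
LOG_FLOOR = 1e-3
# Huber tuning constant (95% Gaussian efficiency) and IRLS controls
HUBER_T = 1.345
IRLS_TOL = 1e-8
IRLS_MAXITER = 50


@dataclass
class PivotSet:
    """Structurally invariant positions anchoring between-condition fitting.

    ``positions`` maps transcript_id to a sorted 1-based position array.
    """

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = {
            tx: np.unique(np.asarray(pos, dtype=np.int64))
            for tx, pos in self.positions.items()
        }
        for tx, pos in self.positions.items():
            if pos.size and pos.min() < 1:
                raise ValidationError(f"pivot positions for {tx!r} must be >= 1")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.positions)

    def size(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def __contains__(self, tx: str) -> bool:
        return tx in self.positions


@dataclass
class NormalizationModel:
    """Fitted between-condition transform (B is mapped toward reference A)."""

    log_alpha: float
    beta: float
    pivot: PivotSet
    reference_condition: str
    other_condition: str
    n_pivot_used: int = 0
    iterations: int = 0
    converged: bool = True
    scale: float = float("nan")

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Apply exp(log α + β log r) elementwise; NaN passes through.

        Below the positivity floor the log-linear map is extended linearly
        through the origin (slope matching the map at the floor), so zeros
        stay zero, the map stays monotone, and the identity fit
        (log α = 0, β = 1) is exactly the identity.
        """
        v = np.asarray(values, dtype=float)
        out = np.empty_like(v)
        big = v > LOG_FLOOR
        with np.errstate(invalid="ignore"):
            out[big] = np.exp(self.log_alpha + self.beta * np.log(v[big]))
        factor = math.exp(self.log_alpha + self.beta * math.log(LOG_FLOOR)) / LOG_FLOOR
        out[~big] = v[~big] * factor
        out[np.isnan(v)] = np.nan
        return out

    def to_text(self, path: str | Path) -> None:
        lines = [
            f"log_alpha\t{self.log_alpha:.10g}",
            f"beta\t{self.beta:.10g}",
            f"reference_condition\t{self.reference_condition}",
            f"other_condition\t{self.other_condition}",
            f"n_pivot_used\t{self.n_pivot_used}",
            f"iterations\t{self.iterations}",
            f"converged\t{self.converged}",
            f"scale\t{self.scale:.10g}",
        ]
        for tx, pos in self.pivot.positions.items():
            lines.append(f"pivot\t{tx}\t{','.join(map(str, pos))}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Step 1: winsorize and rescale
# ---------------------------------------------------------------------------


def winsorize_rescale(
    profile: ReactivityProfile, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> ReactivityProfile:
    """90% winsorization then min-max rescale to [0, 1], per replicate.

    Values below the ``lower_pct`` empirical percentile (linear-interpolation
    quantiles) are set to it, values above ``upper_pct`` likewise; the
    clipped values are then shifted and scaled onto [0, 1]. A constant
    profile (max == min after clipping) maps to all zeros.
    """
    values = profile.reactivity
    finite = ~np.isnan(values)
    if not finite.any():
        raise ValidationError(
            f"profile {profile.transcript_id}/{profile.replicate_id} is all-missing"
        )
    lo, hi = np.nanpercentile(values, [lower_pct, upper_pct])
    clipped = np.clip(values, lo, hi)
    rng = hi - lo
    if rng <= 0:
        out = np.where(finite, 0.0, np.nan)
    else:
        out = (clipped - lo) / rng
    return profile.with_values(out)


# ---------------------------------------------------------------------------
# Step 2: within-condition quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(profiles: Sequence[ReactivityProfile]) -> list[ReactivityProfile]:
    """Match value distributions of within-condition replicates.

    Each replicate's k-th order statistic is replaced by the mean of the
    order statistics across replicates, preserving ranks within replicates.
    Missing positions are excluded and restored as missing. With unequal
    non-missing counts, each replicate's empirical quantile function is
    evaluated on its own plotting positions against the mean quantile
    function of all replicates (for equal counts this reduces to columnwise
    means of the sorted values). A single replicate is returned unchanged.
    """
    if not profiles:
        return []
    tx_ids = {p.transcript_id for p in profiles}
    if len(tx_ids) != 1:
        raise ValidationError(f"cannot quantile-normalize across transcripts {sorted(tx_ids)}")
    if len(profiles) == 1:
        return [profiles[0].with_values(profiles[0].reactivity)]

    sorted_vals = []
    for p in profiles:
        v = p.reactivity[~np.isnan(p.reactivity)]
        if v.size == 0:
            raise ValidationError(
                f"profile {p.transcript_id}/{p.replicate_id} is all-missing"
            )
        sorted_vals.append(np.sort(v))

    def mean_quantile(q: np.ndarray) -> np.ndarray:
        return np.mean([np.quantile(v, q) for v in sorted_vals], axis=0)

    out = []
    for p, v_sorted in zip(profiles, sorted_vals):
        m = v_sorted.size
        pp = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        target = mean_quantile(pp)
        new = np.full_like(p.reactivity, np.nan)
        idx = np.flatnonzero(~np.isnan(p.reactivity))
        order = np.argsort(p.reactivity[idx], kind="stable")
        new[idx[order]] = target
        out.append(p.with_values(new))
    return out


def _steps12(dataset: ReactivityDataset) -> ReactivityDataset:
    """Apply Step 1 to every profile and Step 2 within each condition."""
    profiles: list[ReactivityProfile] = []
    for tx in dataset.transcript_ids:
        for cond in dataset.conditions(tx):
            reps = [winsorize_rescale(p) for p in dataset.profiles(tx, cond)]
            profiles.extend(quantile_normalize(reps))
    return ReactivityDataset(profiles)


# ---------------------------------------------------------------------------
# Step 3: pivot selection and between-condition fit
# ---------------------------------------------------------------------------


def _condition_means(
    dataset: ReactivityDataset, tx: str, cond: str
) -> np.ndarray:
    mat = dataset.matrix(tx, cond)
    with np.errstate(invalid="ignore"):
        return np.nanmean(mat, axis=0)


def fit_between_condition_model(
    dataset: ReactivityDataset,
    pivot: PivotSet,
    reference: str | None = None,
) -> NormalizationModel:
    """Fit log r̄_A ~ log α + β log r̄_B over pivot positions (Huber IRLS).

    ``dataset`` must already be winsorized/quantile-normalized (Steps 1-2).
    Pivot positions where either condition mean is at or below the log floor
    are dropped from the fit; fewer than 3 usable points is an error.
    """
    cond_a, cond_b = dataset.condition_pair()
    if reference is not None:
        if reference not in (cond_a, cond_b):
            raise ValidationError(f"reference {reference!r} not among conditions")
        if reference == cond_b:
            cond_a, cond_b = cond_b, cond_a
    xs, ys = [], []
    for tx in dataset.transcript_ids:
        if tx not in pivot:
            continue
        pos = pivot.positions[tx]
        pos = pos[pos <= dataset.length(tx)]
        if pos.size == 0:
            continue
        mean_a = _condition_means(dataset, tx, cond_a)[pos - 1]
        mean_b = _condition_means(dataset, tx, cond_b)[pos - 1]
        ok = (mean_a > LOG_FLOOR) & (mean_b > LOG_FLOOR)
        xs.append(np.log(mean_b[ok]))
        ys.append(np.log(mean_a[ok]))
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if x.size < 3:
        raise ValidationError(
            f"only {x.size} usable pivot positions (>= 3 required); "
            "supply a larger pivot set"
        )
    if np.ptp(x) == 0:  # degenerate predictor: depth-only offset
        return NormalizationModel(
            log_alpha=float(np.median(y) - np.median(x)),
            beta=1.0,
            pivot=pivot,
            reference_condition=cond_a,
            other_condition=cond_b,
            n_pivot_used=int(x.size),
            iterations=0,
            converged=True,
        )
    model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT(t=HUBER_T))
    res = model.fit(conv="coefs", tol=IRLS_TOL, maxiter=IRLS_MAXITER, scale_est="mad")
    return NormalizationModel(
        log_alpha=float(res.params[0]),
        beta=float(res.params[1]),
        pivot=pivot,
        reference_condition=cond_a,
        other_condition=cond_b,
        n_pivot_used=int(x.size),
        iterations=int(res.fit_history.get("iteration", 0) or 0),
        converged=bool(res.converged) if hasattr(res, "converged") else True,
        scale=float(res.scale),
    )


def select_pivot_set(
    dataset: ReactivityDataset,
    screen_p: float = 0.05,
    max_iter: int = 5,
    radius: int = 2,
    reference: str | None = None,
) -> PivotSet:
    """Data-driven structurally invariant set via an iterative loose screen.

    On Steps-1-2 data, positional rank-sum p-values are computed; testable
    positions with p >= ``screen_p`` form the candidate set S. The
    between-condition model is fitted on S, condition B is transformed, the
    screen is repeated on transformed data, and S is refitted — iterating
    until S changes by at most 1% of testable positions or ``max_iter``
    rounds. Deterministic given the input.
    """
    from .scan import positional_pvalues  # deferred: scan depends on io only

    dataset.condition_pair()

    def screen(ds: ReactivityDataset) -> tuple[dict[str, np.ndarray], int]:
        positions: dict[str, np.ndarray] = {}
        n_testable = 0
        for tx, pv in positional_pvalues(ds, radius=radius).items():
            testable = ~np.isnan(pv.p)
            n_testable += int(testable.sum())
            keep = testable & (pv.p >= screen_p)
            positions[tx] = np.flatnonzero(keep) + 1
        return positions, n_testable

    positions, n_testable = screen(dataset)
    pivot = PivotSet(positions)
    if pivot.size() == 0:
        raise ValidationError(
            "pivot screening excluded every position; supply a pivot set explicitly"
        )
    for _ in range(max_iter):
        model = fit_between_condition_model(dataset, pivot, reference=reference)
        transformed = apply_model(dataset, model)
        new_positions, _ = screen(transformed)
        new_pivot = PivotSet(new_positions)
        if new_pivot.size() == 0:
            break
        delta = sum(
            np.setxor1d(
                pivot.positions.get(tx, np.empty(0, dtype=np.int64)),
                new_pivot.positions.get(tx, np.empty(0, dtype=np.int64)),
            ).size
            for tx in set(pivot.positions) | set(new_pivot.positions)
        )
        stable = n_testable > 0 and delta / n_testable <= 0.01
        pivot = new_pivot
        if stable:
            break
    return pivot


def apply_model(dataset: ReactivityDataset, model: NormalizationModel) -> ReactivityDataset:
    """Transform every condition-B profile through the fitted model."""
    profiles = []
    for p in dataset.all_profiles():
        if p.condition == model.other_condition:
            profiles.append(p.with_values(model.transform(p.reactivity)))
        else:
            profiles.append(p.with_values(p.reactivity))
    return ReactivityDataset(profiles)


def normalize_dataset(
    dataset: ReactivityDataset,
    pivot: PivotSet | None = None,
    screen_p: float = 0.05,
    max_iter: int = 5,
    radius: int = 2,
    reference: str | None = None,
) -> tuple[ReactivityDataset, NormalizationModel]:
    """Run the full normalization: Steps 1-2, pivot selection, Step 3.

    Returns the normalized dataset (reference condition unchanged after
    Steps 1-2, the other condition transformed through the fitted model at
    every position) together with the fitted :class:`NormalizationModel`.
    """
    dataset.condition_pair()
    prepped = _steps12(dataset)
    if pivot is None:
        pivot = select_pivot_set(
            prepped, screen_p=screen_p, max_iter=max_iter, radius=radius,
            reference=reference,
        )
        logger.info("pivot screening kept %d positions", pivot.size())
    model = fit_between_condition_model(prepped, pivot, reference=reference)
    logger.info(
        "between-condition fit: log_alpha=%.4f beta=%.4f on %d pivot positions",
        model.log_alpha, model.beta, model.n_pivot_used,
    )
    return apply_model(prepped, model), model


# ---------------------------------------------------------------------------
# Pivot file I/O (TSV: transcript_id, position)
# ---------------------------------------------------------------------------


def read_pivot_table(path: str | Path) -> PivotSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if "transcript_id" not in df.columns or "position" not in df.columns:
        raise ValidationError(f"{path}: pivot file needs columns transcript_id, position")
    positions = {
        str(tx): sub["position"].to_numpy(dtype=np.int64)
        for tx, sub in df.groupby("transcript_id", sort=False)
    }
    return PivotSet(positions)


def write_pivot_table(pivot: PivotSet, path: str | Path) -> None:
    import pandas as pd

    rows = [
        (tx, int(pos))
        for tx, positions in pivot.positions.items()
        for pos in positions
    ]
    pd.DataFrame(rows, columns=["transcript_id", "position"]).to_csv(
        path, sep="\t", index=False
    )
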