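"""Conformation-mixture simulation of two-condition structure-probing data.

An RNA in a cell is a mixture of secondary-structure conformations, and a
structurally variable region (SVR) between two conditions reflects a shift
in the mixture proportions. The simulator mirrors that picture:

1. K conformations (default 10) are drawn for a transcript, each a binary
   pairing-status vector. Here they come from a synthetic two-state Markov
   chain along the sequence (mean run length ``mean_run``), which reproduces
   the helix-like blocky pairing of thermodynamic-ensemble samples without
   requiring an external folding engine.
2. Conditional on pairing status, per-nucleotide reactivities are drawn from
   platform-style distributions (SHAPE-like gammas or an icSHAPE-like
   zero-inflated beta). These built-ins are parameterized stand-ins chosen
   so that unpaired nucleotides are stochastically more reactive than paired
   ones; the framework accepts any other parameterization.
3. Conditions A and B weight the conformations differently. 90% of the
   weight goes to the first two conformations and the remaining 10% is split
   uniformly at random over the rest (shared between conditions). The three
   signal levels move the (w1, w2) pair: low (0.4, 0.5) vs (0.5, 0.4),
   medium (0.3, 0.6) vs (0.6, 0.3), high (0, 0.9) vs (0.9, 0); the "null"
   level gives both conditions identical weights. Replicates perturb
   (w1, w2) with N(0, 0.1^2) noise. Observed reactivities are the
   weight-mixed conformation draws, so positions where conformations 1 and
   2 disagree in pairing status are the true SVRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ReactivityDataset, ReactivityProfile, ValidationError

__all__ = [
    "ConformationEnsemble",
    "ReactivityModel",
    "SimulatedDataset",
    "REACTIVITY_MODELS",
    "SIGNAL_WEIGHTS",
    "sample_conformation_ensemble",
    "assign_weights",
    "draw_reactivity",
    "simulate_dataset",
    "true_svrs_from_ensemble",
    "make_negative_control",
]

# base (w1, w2) per condition at each signal level
SIGNAL_WEIGHTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "low": ((0.4, 0.5), (0.5, 0.4)),
    "medium": ((0.3, 0.6), (0.6, 0.3)),
    "high": ((0.0, 0.9), (0.9, 0.0)),
    # both conditions identical: no SVR signal, for negative controls
    "null": ((0.45, 0.45), (0.45, 0.45)),
}

DEFAULT_K = 10
DEFAULT_MEAN_RUN = 6.0
DEFAULT_NOISE_SD = 0.1
# stationary fraction of positions at which a non-reference conformation
# deviates from the reference; sets expected true-SVR coverage (~20%)
DEFAULT_DEVIATION_DENSITY = 0.2


@dataclass
class ConformationEnsemble:
    """K pairing-status vectors with per-condition base mixture weights."""

    transcript_id: str
    conformations: np.ndarray  # (K, n) of {0, 1}; 1 = paired
    weights_a: np.ndarray | None = None  # base K-vector for condition A
    weights_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conformations = np.asarray(self.conformations, dtype=np.int8)
        if self.conformations.ndim != 2 or self.conformations.shape[0] < 2:
            raise ValidationError("ensemble needs K >= 2 conformations as a (K, n) array")

    @property
    def K(self) -> int:
        return int(self.conformations.shape[0])

    @property
    def n(self) -> int:
        return int(self.conformations.shape[1])


@dataclass(frozen=True)
class ReactivityModel:
    """Status-conditional reactivity distributions for one SP platform style.

    ``paired`` / ``unpaired`` are ("gamma", shape, scale),
    ("zib", p_zero, a, b) — a zero-inflated Beta on [0, 1] — or
    ("const", value). Parameters of the built-ins are documented stand-ins
    styled after the named platforms, not fitted values.
    """

    name: str
    paired: tuple
    unpaired: tuple

    def _draw(self, spec: tuple, size, rng: np.random.Generator) -> np.ndarray:
        kind = spec[0]
        if kind == "const":  # degenerate point mass, for closed-form checks
            return np.full(size, float(spec[1]))
        if kind == "gamma":
            _, shape, scale = spec
            return rng.gamma(shape, scale, size=size)
        if kind == "zib":
            _, p_zero, a, b = spec
            x = rng.beta(a, b, size=size)
            x[rng.random(size=size) < p_zero] = 0.0
            return x
        raise ValidationError(f"unknown distribution family {kind!r}")

    def draw(self, pairing_status: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One reactivity draw per element of ``pairing_status`` (1 = paired)."""
        status = np.atleast_1d(np.asarray(pairing_status))
        out = np.empty(status.shape, dtype=float)
        paired_mask = status == 1
        out[paired_mask] = self._draw(self.paired, int(paired_mask.sum()), rng)
        out[~paired_mask] = self._draw(self.unpaired, int((~paired_mask).sum()), rng)
        return out


REACTIVITY_MODELS: dict[str, ReactivityModel] = {
    # SHAPE-style nonnegative reactivities: low-mean paired, high-mean unpaired
    "shape-cordero-like": ReactivityModel(
        "shape-cordero-like", paired=("gamma", 0.8, 0.11), unpaired=("gamma", 1.1, 0.87)
    ),
    "shape-sukosd-like": ReactivityModel(
        "shape-sukosd-like", paired=("gamma", 1.0, 0.07), unpaired=("gamma", 1.5, 0.60)
    ),
    # icSHAPE-style scores on [0, 1] with excess zeros
    "icshape-like": ReactivityModel(
        "icshape-like", paired=("zib", 0.55, 1.5, 7.0), unpaired=("zib", 0.15, 4.0, 2.5)
    ),
}


@dataclass
class SimulatedDataset:
    """A two-condition dataset with its ground-truth SVR intervals."""

    dataset: ReactivityDataset
    truth: dict[str, list[tuple[int, int]]]
    ensembles: dict[str, ConformationEnsemble]
    provenance: dict


# ---------------------------------------------------------------------------


def _markov_chain(
    rng: np.random.Generator, shape: tuple[int, int], p_state1: float, mean_run1: float
) -> np.ndarray:
    """Rows of a stationary two-state chain with P(state 1) = p_state1 and
    mean run length ``mean_run1`` in state 1."""
    rows, n = shape
    exit1 = 1.0 / mean_run1
    enter1 = min(1.0, p_state1 * exit1 / max(1e-12, 1.0 - p_state1))
    states = np.empty((rows, n), dtype=np.int8)
    u = rng.random((rows, n))
    states[:, 0] = u[:, 0] < p_state1
    for j in range(1, n):  # per-position loop; n is a few hundred
        prev = states[:, j - 1].astype(bool)
        stay = u[:, j] >= np.where(prev, exit1, enter1)
        states[:, j] = np.where(stay, prev, ~prev)
    return states


def sample_conformation_ensemble(
    n: int,
    K: int = DEFAULT_K,
    seed: int | np.random.Generator | None = None,
    mean_run: float = DEFAULT_MEAN_RUN,
    deviation_density: float = DEFAULT_DEVIATION_DENSITY,
    transcript_id: str = "tx",
) -> ConformationEnsemble:
    """Draw K similar pairing-status vectors with helix-like blocks.

    Conformation 1 (the reference) is a symmetric two-state Markov chain
    along the sequence with mean run length ``mean_run``, giving geometric
    paired/unpaired blocks with about half of positions paired. Each further
    conformation copies the reference and flips its status inside an
    independent sparse set of deviation blocks — geometric runs of mean
    length ``mean_run`` covering a ``deviation_density`` fraction of
    positions in expectation. This mimics a thermodynamic ensemble: members
    share most helices and disagree in localized stretches, so true SVRs
    (where conformations 1 and 2 differ) cover roughly 20% of positions at
    the defaults.
    """
    if n < 10:
        raise ValidationError("transcript length must be >= 10")
    if K < 2:
        raise ValidationError("K must be >= 2")
    if mean_run < 1:
        raise ValidationError("mean_run must be >= 1")
    if not 0 < deviation_density < 1:
        raise ValidationError("deviation_density must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reference = _markov_chain(rng, (1, n), 0.5, mean_run)[0]
    masks = _markov_chain(rng, (K - 1, n), deviation_density, mean_run).astype(bool)
    states = np.vstack([reference, np.where(masks, 1 - reference, reference)])
    return ConformationEnsemble(transcript_id, states.astype(np.int8))


def assign_weights(
    ensemble: ConformationEnsemble,
    signal: str,
    n_reps: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate mixture weight vectors for both conditions.

    Base weights put (w1, w2) at the printed values for ``signal`` and split
    the remaining mass uniformly at random over conformations 3..K (one draw,
    shared by both conditions); these bases are stored on the ensemble. Each
    replicate then adds N(0, noise_sd^2) noise to (w1, w2), clips the vector
    to [0, 1], and renormalizes it to sum 1. Returns (n_reps, K) arrays for
    conditions A and B.
    """
    if signal not in SIGNAL_WEIGHTS:
        raise ValidationError(f"signal must be one of {sorted(SIGNAL_WEIGHTS)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = ensemble.K
    (w1a, w2a), (w1b, w2b) = SIGNAL_WEIGHTS[signal]
    rest_mass = 1.0 - (w1a + w2a)
    if K > 2:
        rest = rng.dirichlet(np.ones(K - 2)) * rest_mass
    else:
        rest = np.empty(0)
    base_a = np.concatenate([[w1a, w2a], rest])
    base_b = np.concatenate([[w1b, w2b], rest])
    ensemble.weights_a = base_a
    ensemble.weights_b = base_b

    def perturb(base: np.ndarray) -> np.ndarray:
        out = np.empty((n_reps, K))
        for i in range(n_reps):
            w = base.copy()
            if noise_sd > 0:
                w[:2] += rng.normal(0.0, noise_sd, size=2)
            w = np.clip(w, 0.0, 1.0)
            total = w.sum()
            if total <= 0:
                w = np.full(K, 1.0 / K)
            else:
                w = w / total
            out[i] = w
        return out

    return perturb(base_a), perturb(base_b)


def draw_reactivity(
    pairing_status, model: ReactivityModel, rng: np.random.Generator
):
    """Status-conditional reactivity draw(s); scalar in, scalar out."""
    out = model.draw(pairing_status, rng)
    return float(out[0]) if np.isscalar(pairing_status) else out


def true_svrs_from_ensemble(ensemble: ConformationEnsemble) -> list[tuple[int, int]]:
    """Maximal runs where conformations 1 and 2 differ, as 1-based intervals."""
    diff = ensemble.conformations[0] != ensemble.conformations[1]
    intervals: list[tuple[int, int]] = []
    start = None
    for j, d in enumerate(diff):
        if d and start is None:
            start = j
        elif not d and start is not None:
            intervals.append((start + 1, j))
            start = None
    if start is not None:
        intervals.append((start + 1, int(diff.size)))
    return intervals


def simulate_dataset(
    n_transcripts: int = 1,
    length_range: tuple[int, int] = (60, 400),
    signal: str = "medium",
    model: str | ReactivityModel = "shape-sukosd-like",
    n_reps_per_condition: int = 4,
    seed: int | None = None,
    K: int = DEFAULT_K,
    mean_run: float = DEFAULT_MEAN_RUN,
    noise_sd: float = DEFAULT_NOISE_SD,
    deviation_density: float = DEFAULT_DEVIATION_DENSITY,
    conditions: tuple[str, str] = ("A", "B"),
) -> SimulatedDataset:
    """Simulate a two-condition dataset with known SVR ground truth.

    Per replicate and position, the observed reactivity is
    sum_c w_c * x_cj with fresh status-conditional draws x_cj for every
    (replicate, conformation, position) — independent draws avoid artificial
    replicate correlation. Byte-identical output is guaranteed for a fixed
    seed.
    """
    if isinstance(model, str):
        try:
            model = REACTIVITY_MODELS[model]
        except KeyError:
            raise ValidationError(
                f"unknown reactivity model {model!r}; available: {sorted(REACTIVITY_MODELS)}"
            ) from None
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    profiles: list[ReactivityProfile] = []
    truth: dict[str, list[tuple[int, int]]] = {}
    ensembles: dict[str, ConformationEnsemble] = {}
    for t in range(n_transcripts):
        tx = f"tx{t + 1}"
        n = int(rng.integers(lo, hi + 1))
        ensemble = sample_conformation_ensemble(
            n, K=K, seed=rng, mean_run=mean_run,
            deviation_density=deviation_density, transcript_id=tx,
        )
        w_a, w_b = assign_weights(ensemble, signal, n_reps_per_condition,
                                  noise_sd=noise_sd, seed=rng)
        for cond, weights in zip(conditions, (w_a, w_b)):
            for i in range(n_reps_per_condition):
                draws = model.draw(ensemble.conformations, rng)  # (K, n)
                r = weights[i] @ draws
                profiles.append(ReactivityProfile(tx, cond, f"rep{i + 1}", r))
        truth[tx] = true_svrs_from_ensemble(ensemble)
        ensembles[tx] = ensemble
    return SimulatedDataset(
        dataset=ReactivityDataset(profiles),
        truth=truth,
        ensembles=ensembles,
        provenance={
            "seed": seed,
            "signal": signal,
            "model": model.name,
            "n_transcripts": n_transcripts,
            "length_range": list(length_range),
            "n_reps_per_condition": n_reps_per_condition,
            "K": K,
            "mean_run": mean_run,
            "noise_sd": noise_sd,
        },
    )


def make_negative_control(
    profiles: Sequence[ReactivityProfile],
    seed: int | None = None,
    conditions: tuple[str, str] = ("pseudoA", "pseudoB"),
) -> ReactivityDataset:
    """Split same-condition replicates into two pseudo-conditions.

    The m replicates are randomly split into groups of ceil(m/2) and
    floor(m/2); any SVR found by contrasting the groups is a false positive
    by construction.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValidationError("negative control needs >= 2 replicates")
    if len({p.transcript_id for p in profiles}) != 1:
        raise ValidationError("negative control replicates must share one transcript")
    rng = np.random.default_rng(seed)
    m = len(profiles)
    order = rng.permutation(m)
    half = math.ceil(m / 2)
    relabeled = []
    for rank, idx in enumerate(order):
        cond = conditions[0] if rank < half else conditions[1]
        p = profiles[idx]
        relabeled.append(ReactivityProfile(p.transcript_id, cond, p.replicate_id,
                                           p.reactivity.copy()))
    return ReactivityDataset(relabeled)


def write_truth_table(truth: dict[str, list[tuple[int, int]]], path) -> None:
    """True SVR intervals as TSV: transcript_id, start, end (1-based inclusive)."""
    from pathlib import Path

    lines = ["transcript_id\tstart\tend"]
    for tx, intervals in truth.items():
        for s, e in intervals:
            lines.append(f"{tx}\t{s}\t{e}")
    Path(path).write_text("\n".join(lines) + "\n")
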