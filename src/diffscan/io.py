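"""Data model and tabular I/O for structure-probing (SP) experiments.

The central container is :class:`ReactivityDataset`: per-transcript collections
of per-nucleotide reactivity profiles, indexed by (condition, replicate).
Reactivities may also be computed from raw counts (RT stops from a probed
"case" experiment over coverage from an unprobed "control" experiment).

All positions exposed at interfaces are 1-based and inclusive; internally
arrays are 0-indexed. Missing values are ``NaN`` in memory and the literal
string ``NA`` on disk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiffScanError",
    "FormatError",
    "ValidationError",
    "CountProfile",
    "ReactivityProfile",
    "ReactivityDataset",
    "read_reactivity_table",
    "write_reactivity_table",
    "read_count_table",
    "read_lengths",
    "reactivity_from_counts",
    "pair_count_replicates",
    "apply_coverage_filters",
]


class DiffScanError(Exception):
    """Base class for errors raised by this package."""


class FormatError(DiffScanError):
    """A file does not conform to the expected tabular format."""


class ValidationError(DiffScanError):
    """Input data violate a documented contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountProfile:
    """Raw per-position counts for one sequencing replicate.

    ``rt_stop`` carries reverse-transcription truncation counts (the probing
    signal of a *case* experiment); ``coverage`` carries read-through depth
    (used as the exposure proxy from a *control* experiment). Both arrays are
    kept for every replicate; ``experiment`` says which role the replicate
    plays.
    """

    transcript_id: str
    experiment: str  # "case" or "control"
    replicate_id: str
    rt_stop: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.rt_stop = np.asarray(self.rt_stop, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.experiment not in ("case", "control"):
            raise ValidationError(
                f"experiment must be 'case' or 'control', got {self.experiment!r}"
            )
        if self.rt_stop.shape != self.coverage.shape or self.rt_stop.ndim != 1:
            raise ValidationError("rt_stop and coverage must be 1-D arrays of equal length")
        if (self.rt_stop < 0).any() or (self.coverage < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def length(self) -> int:
        return int(self.rt_stop.size)


@dataclass
class ReactivityProfile:
    """Per-nucleotide reactivities of one replicate in one condition.

    ``reactivity`` is a float array of transcript length; NaN marks missing
    positions (no data, or removed by a coverage filter).
    """

    transcript_id: str
    condition: str
    replicate_id: str
    reactivity: np.ndarray

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        if self.reactivity.ndim != 1:
            raise ValidationError("reactivity must be a 1-D array")

    @property
    def length(self) -> int:
        return int(self.reactivity.size)

    def with_values(self, values: np.ndarray) -> "ReactivityProfile":
        return replace(self, reactivity=np.asarray(values, dtype=float))


class ReactivityDataset:
    """Profiles of one or more transcripts, grouped by transcript.

    All profiles of a transcript must share one length (a common coordinate
    system). Condition labels are arbitrary strings; most analyses require
    exactly two conditions, which is checked at their entry points rather
    than here so that single-condition data (e.g. inputs to negative-control
    construction) remain representable.
    """

    def __init__(self, profiles: Iterable[ReactivityProfile]):
        self._by_tx: dict[str, list[ReactivityProfile]] = {}
        for p in profiles:
            self._by_tx.setdefault(p.transcript_id, []).append(p)
        for tx, plist in self._by_tx.items():
            lengths = {p.length for p in plist}
            if len(lengths) != 1:
                raise ValidationError(
                    f"transcript {tx!r} has profiles of differing lengths {sorted(lengths)}"
                )
            seen = set()
            for p in plist:
                key = (p.condition, p.replicate_id)
                if key in seen:
                    raise ValidationError(
                        f"duplicate profile for transcript {tx!r}, "
                        f"condition {p.condition!r}, replicate {p.replicate_id!r}"
                    )
                seen.add(key)

    # -- introspection ------------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._by_tx)

    def __len__(self) -> int:
        return len(self._by_tx)

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_tx)

    def length(self, transcript_id: str) -> int:
        return self._by_tx[transcript_id][0].length

    def conditions(self, transcript_id: str | None = None) -> list[str]:
        txs = [transcript_id] if transcript_id is not None else self.transcript_ids
        out: list[str] = []
        for tx in txs:
            for p in self._by_tx[tx]:
                if p.condition not in out:
                    out.append(p.condition)
        return out

    def profiles(
        self, transcript_id: str, condition: str | None = None
    ) -> list[ReactivityProfile]:
        plist = self._by_tx[transcript_id]
        if condition is None:
            return list(plist)
        return [p for p in plist if p.condition == condition]

    def matrix(self, transcript_id: str, condition: str) -> np.ndarray:
        """Replicate-by-position reactivity matrix for one condition."""
        plist = self.profiles(transcript_id, condition)
        if not plist:
            raise ValidationError(
                f"transcript {transcript_id!r} has no profiles in condition {condition!r}"
            )
        return np.vstack([p.reactivity for p in plist])

    def all_profiles(self) -> list[ReactivityProfile]:
        return [p for plist in self._by_tx.values() for p in plist]

    def condition_pair(self) -> tuple[str, str]:
        """The (reference, other) condition pair; errors unless exactly two."""
        conds = self.conditions()
        if len(conds) != 2:
            raise ValidationError(
                f"expected exactly two conditions, found {conds!r}"
            )
        return conds[0], conds[1]

    def subset(self, transcript_ids: Sequence[str]) -> "ReactivityDataset":
        keep = set(transcript_ids)
        return ReactivityDataset(p for p in self.all_profiles() if p.transcript_id in keep)


# ---------------------------------------------------------------------------
# Long-format TSV readers / writers
# ---------------------------------------------------------------------------

_REACTIVITY_COLUMNS = ["transcript_id", "position", "condition", "replicate", "reactivity"]
_COUNT_COLUMNS = ["transcript_id", "position", "rt_stop", "coverage", "experiment", "replicate"]


def read_lengths(path: str | Path) -> dict[str, int]:
    """Read a lengths sidecar TSV (columns transcript_id, length)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if list(df.columns)[:2] != ["transcript_id", "length"]:
        raise FormatError(
            f"lengths sidecar must have columns transcript_id, length; got {list(df.columns)}"
        )
    return {str(t): int(n) for t, n in zip(df["transcript_id"], df["length"])}


def _validate_positions(df: pd.DataFrame, path: str | Path) -> None:
    if not np.issubdtype(df["position"].dtype, np.integer):
        raise FormatError(f"{path}: position column must be integer")
    if (df["position"] < 1).any():
        bad = df.loc[df["position"] < 1].iloc[0]
        raise ValidationError(
            f"{path}: non-positive position {bad['position']} for {bad['transcript_id']}"
        )


def read_reactivity_table(
    path: str | Path, lengths: Mapping[str, int] | str | Path | None = None
) -> ReactivityDataset:
    """Read a long-format reactivity TSV into a :class:`ReactivityDataset`.

    Columns: transcript_id, position (1-based), condition, replicate,
    reactivity (``NA`` for missing). Transcript length is taken from the
    ``lengths`` sidecar (mapping or path) when given, otherwise from the
    maximum observed position. Positions without a row become missing.
    """
    if lengths is not None and not isinstance(lengths, Mapping):
        lengths = read_lengths(lengths)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "condition": str, "replicate": str},
        na_values=["NA"],
        keep_default_na=False,
    )
    missing_cols = [c for c in _REACTIVITY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    _validate_positions(df, path)
    dup = df.duplicated(subset=["transcript_id", "position", "condition", "replicate"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate row for ({row['transcript_id']}, {row['position']}, "
            f"{row['condition']}, {row['replicate']})"
        )
    profiles: list[ReactivityProfile] = []
    for tx, tx_df in df.groupby("transcript_id", sort=False):
        n = int(lengths[str(tx)]) if lengths and str(tx) in lengths else int(tx_df["position"].max())
        if (tx_df["position"] > n).any():
            raise ValidationError(f"{path}: position beyond declared length {n} for {tx}")
        for (cond, rep), sub in tx_df.groupby(["condition", "replicate"], sort=False):
            values = np.full(n, np.nan)
            values[sub["position"].to_numpy() - 1] = sub["reactivity"].to_numpy(dtype=float)
            profiles.append(ReactivityProfile(str(tx), str(cond), str(rep), values))
    return ReactivityDataset(profiles)


def write_reactivity_table(dataset: ReactivityDataset, path: str | Path) -> None:
    """Write a dataset as long-format TSV; every position gets a row (NA if missing)."""
    rows = []
    for tx in dataset.transcript_ids:
        for p in dataset.profiles(tx):
            for j, v in enumerate(p.reactivity, start=1):
                rows.append((tx, j, p.condition, p.replicate_id, v))
    df = pd.DataFrame(rows, columns=_REACTIVITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_count_table(path: str | Path) -> list[CountProfile]:
    """Read a long-format count TSV into :class:`CountProfile` objects.

    Columns: transcript_id, position (1-based), rt_stop, coverage,
    experiment ({case, control}), replicate. Positions without a row get
    zero counts.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"transcript_id": str, "experiment": str, "replicate": str}
    )
    missing_cols = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    _validate_positions(df, path)
    dup = df.duplicated(subset=["transcript_id", "position", "experiment", "replicate"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate (transcript, position, experiment, replicate)")
    out: list[CountProfile] = []
    for tx, tx_df in df.groupby("transcript_id", sort=False):
        n = int(tx_df["position"].max())
        for (exp, rep), sub in tx_df.groupby(["experiment", "replicate"], sort=False):
            rt = np.zeros(n, dtype=np.int64)
            cov = np.zeros(n, dtype=np.int64)
            idx = sub["position"].to_numpy() - 1
            rt[idx] = sub["rt_stop"].to_numpy(dtype=np.int64)
            cov[idx] = sub["coverage"].to_numpy(dtype=np.int64)
            out.append(CountProfile(str(tx), str(exp), str(rep), rt, cov))
    return out


# ---------------------------------------------------------------------------
# Reactivity computation from raw counts
# ---------------------------------------------------------------------------


def reactivity_from_counts(case: CountProfile, control: CountProfile) -> ReactivityProfile:
    """Reactivity r_j = RT_j(case) / coverage_j(control).

    The control coverage proxies the number of times position j was exposed
    to the probe, so the ratio estimates the per-exposure modification rate.
    Positions with zero control coverage carry no exposure information and
    become missing.
    """
    if case.transcript_id != control.transcript_id:
        raise ValidationError(
            f"case transcript {case.transcript_id!r} != control {control.transcript_id!r}"
        )
    if case.length != control.length:
        raise ValidationError(
            f"case length {case.length} != control length {control.length}"
        )
    cov = control.coverage.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = case.rt_stop / cov
    r[control.coverage == 0] = np.nan
    return ReactivityProfile(
        transcript_id=case.transcript_id,
        condition="",
        replicate_id=f"{case.replicate_id}.{control.replicate_id}",
        reactivity=r,
    )


def pair_count_replicates(
    case_reps: Sequence[CountProfile],
    control_reps: Sequence[CountProfile],
    condition: str = "",
) -> list[ReactivityProfile]:
    """All case x control pairings, each converted to a reactivity replicate.

    With two case and two control replicates this yields the four reactivity
    replicates per condition used for icSHAPE data. The replicate id encodes
    the pairing, e.g. ``"case1.control2"``.
    """
    if not case_reps or not control_reps:
        raise ValidationError("need at least one case and one control replicate")
    out = []
    for case, control in itertools.product(case_reps, control_reps):
        prof = reactivity_from_counts(case, control)
        out.append(replace(prof, condition=condition))
    return out


def apply_coverage_filters(
    dataset: ReactivityDataset,
    counts: Mapping[str, Sequence[CountProfile]],
    min_coverage: int = 10,
    min_rt: int = 2,
) -> ReactivityDataset:
    """Mask low-coverage positions and drop transcripts with no RT signal.

    A transcript is dropped when every case replicate has RT stop below
    ``min_rt`` at every position. A position is masked (set missing in all
    profiles) when the minimum control coverage across control replicates is
    below ``min_coverage``. ``counts`` maps transcript_id to its
    :class:`CountProfile` list.
    """
    profiles: list[ReactivityProfile] = []
    for tx in dataset.transcript_ids:
        tx_counts = list(counts.get(tx, []))
        case = [c for c in tx_counts if c.experiment == "case"]
        control = [c for c in tx_counts if c.experiment == "control"]
        if min_rt > 0 and case:
            max_rt = max(int(c.rt_stop.max(initial=0)) for c in case)
            if max_rt < min_rt:
                continue
        mask = None
        if min_coverage > 0 and control:
            cov = np.min(np.vstack([c.coverage for c in control]), axis=0)
            mask = cov < min_coverage
        for p in dataset.profiles(tx):
            values = p.reactivity.copy()
            if mask is not None:
                values[mask] = np.nan
            profiles.append(p.with_values(values))
    return ReactivityDataset(profiles)
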