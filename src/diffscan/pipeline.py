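"""End-to-end orchestration: configuration, the full normalize+scan run, and
the simulation study that exercises the whole method against known truth.

Every run writes its resolved configuration and a log next to its outputs,
so a run is reproducible from the output directory alone. All randomness
descends from the single ``seed`` in the configuration; each stochastic
stage derives its own stream from (seed, stage name), so adding or removing
a stage does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluate, io, normalization, scan, simulate
from .io import DiffScanError, ReactivityDataset, ValidationError

__all__ = ["RunConfig", "run_diffscan", "run_simulation_study", "stage_seed"]

logger = logging.getLogger(__name__)

LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"  # no timestamps: outputs stay byte-identical


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(stage.encode()))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Flat bag of every tunable, with the package defaults."""

    # normalization
    screen_p: float = 0.05
    max_iter: int = 5
    # positional test & scan
    radius: int = 2
    l_min: int = 1
    l_max: int = 100
    alpha: float = 0.05
    mc_samples: int = 1000
    min_obs: int = 3
    global_fwer: bool = False
    null_mode: str = "windowed"
    # count-to-reactivity filters
    min_coverage: int = 10
    min_rt: int = 2
    # simulation
    n_transcripts: int = 1
    length_min: int = 60
    length_max: int = 400
    signal: str = "medium"
    model: str = "shape-sukosd-like"
    n_reps: int = 4
    noise_sd: float = 0.1
    conformations: int = 10
    mean_run: float = 6.0
    # reproducibility
    seed: int = 7

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _setup_run_dir(out_dir: str | Path, config: RunConfig) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(LOG_FORMAT))
    root = logging.getLogger("diffscan")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return out


def _teardown_logging() -> None:
    root = logging.getLogger("diffscan")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()


def run_diffscan(
    config: RunConfig,
    dataset: ReactivityDataset | None = None,
    reactivity_path: str | Path | None = None,
    count_path: str | Path | None = None,
    lengths_path: str | Path | None = None,
    pivot: normalization.PivotSet | None = None,
    out_dir: str | Path = "diffscan_out",
) -> dict[str, scan.ScanResult]:
    """Counts→reactivities (if needed) → filters → normalize → scan → write.

    Accepts either an in-memory :class:`ReactivityDataset`, a long-format
    reactivity TSV, or a count TSV (converted via the case x control
    replicate pairings and coverage filters). Outputs: ``svrs.tsv``,
    ``positions.tsv``, ``normalization_model.txt``, ``config.yaml`` and
    ``run.log`` in ``out_dir``.
    """
    out = _setup_run_dir(out_dir, config)
    try:
        if dataset is None:
            if reactivity_path is not None:
                dataset = io.read_reactivity_table(reactivity_path, lengths=lengths_path)
            elif count_path is not None:
                dataset = _dataset_from_counts(config, count_path)
            else:
                raise ValidationError("run_diffscan needs a dataset, reactivity file, or count file")
        logger.info("input: %d transcripts", len(dataset))
        dataset.condition_pair()

        norm, model = normalization.normalize_dataset(
            dataset, pivot=pivot, screen_p=config.screen_p,
            max_iter=config.max_iter, radius=config.radius,
        )
        model.to_text(out / "normalization_model.txt")

        results = scan.scan_dataset(
            norm,
            radius=config.radius, L_min=config.l_min, L_max=config.l_max,
            alpha=config.alpha, B=config.mc_samples,
            seed=stage_seed(config.seed, "scan-null"),
            global_fwer=config.global_fwer, null_mode=config.null_mode,
            min_obs=config.min_obs,
        )
        scan.write_svr_table(results, out / "svrs.tsv")
        scan.write_position_table(results, out / "positions.tsv")
        n_svrs = sum(len(r.svrs) for r in results.values())
        logger.info("called %d SVRs across %d transcripts", n_svrs, len(results))
        return results
    except DiffScanError:
        raise
    finally:
        _teardown_logging()


def _dataset_from_counts(config: RunConfig, count_path: str | Path) -> ReactivityDataset:
    """Count TSV → reactivity replicates per condition → coverage filters.

    The count file's ``replicate`` column must be ``<condition>:<rep>`` so
    that case/control replicates can be grouped per condition.
    """
    counts = io.read_count_table(count_path)
    by_tx_cond: dict[tuple[str, str], dict[str, list[io.CountProfile]]] = {}
    for c in counts:
        if ":" not in c.replicate_id:
            raise ValidationError(
                "count replicate ids must be '<condition>:<replicate>' "
                f"(got {c.replicate_id!r})"
            )
        cond, rep = c.replicate_id.split(":", 1)
        slot = by_tx_cond.setdefault((c.transcript_id, cond), {"case": [], "control": []})
        slot[c.experiment].append(dataclasses.replace(c, replicate_id=rep))
    profiles = []
    counts_by_tx: dict[str, list[io.CountProfile]] = {}
    for (tx, cond), slot in by_tx_cond.items():
        profiles.extend(io.pair_count_replicates(slot["case"], slot["control"], condition=cond))
        counts_by_tx.setdefault(tx, []).extend(slot["case"] + slot["control"])
    dataset = ReactivityDataset(profiles)
    return io.apply_coverage_filters(
        dataset, counts_by_tx, min_coverage=config.min_coverage, min_rt=config.min_rt
    )


# ---------------------------------------------------------------------------
# Simulation study
# ---------------------------------------------------------------------------


def _evaluate_run(
    results: Mapping[str, scan.ScanResult],
    truth: Mapping[str, list[tuple[int, int]]],
) -> dict[str, float]:
    """Position-level metrics of one simulated run, pooled over transcripts."""
    pred_all: set[tuple[str, int]] = set()
    truth_all: set[tuple[str, int]] = set()
    n_total = 0
    dists = []
    for tx, res in results.items():
        n_total += res.n
        pred = {int(p) for p in res.svr_positions()}
        tset = evaluate.intervals_to_positions(truth.get(tx, []))
        pred_all |= {(tx, p) for p in pred}
        truth_all |= {(tx, p) for p in tset}
        if truth.get(tx) and res.svrs:
            ann = evaluate.AnnotationSet(tx, list(truth[tx]), res.n)
            rep = evaluate.average_distance([(r.start, r.end) for r in res.svrs], ann)
            if rep.applicable:
                dists.append(rep.per_nucleotide)
    jac = evaluate.jaccard_index(pred_all, truth_all)
    hits = len(pred_all & truth_all)
    precision = hits / len(pred_all) if pred_all else float("nan")
    recall = hits / len(truth_all) if truth_all else float("nan")
    non_truth = n_total - len(truth_all)
    spec = (non_truth - len(pred_all - truth_all)) / non_truth if non_truth else float("nan")
    return {
        "jaccard": jac,
        "precision": precision,
        "recall": recall,
        "specificity": spec,
        "fpr": len(pred_all) / n_total if n_total else float("nan"),
        "any_svr": float(bool(pred_all)),
        "avg_distance": float(np.mean(dists)) if dists else float("nan"),
    }


def run_simulation_study(
    config: RunConfig,
    signals: Sequence[str] = ("low", "medium", "high"),
    n_seeds: int = 20,
    out_dir: str | Path = "study_out",
    null_runs: int = 0,
) -> pd.DataFrame:
    """simulate → normalize+scan → evaluate over a signal x seed grid.

    Emits per-run and aggregate metric tables under ``out_dir``. When
    ``null_runs`` > 0, that many additional negative-control runs (identical
    mixture weights in both pseudo-conditions) are executed and summarized
    as an FWER estimate with a 95% Wilson confidence interval.
    """
    out = _setup_run_dir(out_dir, config)
    try:
        rows = []
        null_cache = None
        if config.null_mode != "permutation":
            null_cache = scan.NullCache(
                config.l_min, config.l_max, config.mc_samples,
                stage_seed(config.seed, "scan-null"), alpha=config.alpha,
                mode=config.null_mode, radius=config.radius, min_obs=config.min_obs,
            )
        grid = [(sig, s) for sig in signals for s in range(n_seeds)]
        grid += [("null", s) for s in range(null_runs)]
        for sig, s in grid:
            run_seed = stage_seed(config.seed, f"study-{sig}-{s}")
            sim = simulate.simulate_dataset(
                n_transcripts=config.n_transcripts,
                length_range=(config.length_min, config.length_max),
                signal=sig, model=config.model,
                n_reps_per_condition=config.n_reps, seed=run_seed,
                K=config.conformations, mean_run=config.mean_run,
                noise_sd=config.noise_sd,
            )
            norm, _ = normalization.normalize_dataset(
                sim.dataset, screen_p=config.screen_p,
                max_iter=config.max_iter, radius=config.radius,
            )
            results = scan.scan_dataset(
                norm, radius=config.radius, L_min=config.l_min,
                L_max=config.l_max, alpha=config.alpha, B=config.mc_samples,
                seed=stage_seed(config.seed, "scan-null"),
                null_mode=config.null_mode, null_cache=null_cache,
                min_obs=config.min_obs,
            )
            truth = sim.truth if sig != "null" else {tx: [] for tx in sim.truth}
            metrics = _evaluate_run(results, truth)
            rows.append({"signal": sig, "seed": s, **metrics})
            logger.info("study %s seed %d: jaccard=%.3f fpr=%.4f",
                        sig, s, metrics["jaccard"], metrics["fpr"])
        per_run = pd.DataFrame(rows)
        per_run.to_csv(out / "per_run_metrics.tsv", sep="\t", index=False, na_rep="NA")
        agg = per_run.groupby("signal", sort=False).mean(numeric_only=True).drop(columns="seed")
        agg.to_csv(out / "aggregate_metrics.tsv", sep="\t", na_rep="NA")
        if null_runs:
            null_rows = per_run[per_run["signal"] == "null"]
            k = int(null_rows["any_svr"].sum())
            lo, hi = _wilson_ci(k, null_runs)
            pd.DataFrame(
                [{"null_runs": null_runs, "runs_with_svr": k,
                  "fwer_estimate": k / null_runs, "wilson_lo": lo, "wilson_hi": hi,
                  "mean_position_fpr": float(null_rows["fpr"].mean())}]
            ).to_csv(out / "fwer_estimate.tsv", sep="\t", index=False)
        return per_run
    finally:
        _teardown_logging()


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))
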