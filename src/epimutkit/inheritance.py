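"""Epimutation runs, inheritance statistics and simulation nulls.

A *run* is one directed epimutation episode at a locus: a maximal stretch of
consecutive measured generations carrying the same nonzero call.  Because
lineages are sampled only at even generations (and occasionally miss one),
unmeasured generations between two same-direction measured calls are imputed
as epimutated and the run's ``length`` counts them
(``length = offset - onset + 1``).  A measured zero, or a sign flip,
terminates the run: the molecular processes that establish and dismantle a
chromatin state are antagonistic, so direction is part of a run's identity.

A run is *inherited* when it spans at least two measured generations (the
conservative definition: the state was seen transmitted at least once), and
*censored* when it is still active at the final measured generation.

Two simulation nulls are provided:

* :func:`reassortment_null` -- permutes each generation column's calls
  across "epimutable" loci (those with at least one call), preserving
  per-generation call counts and signs exactly, to ask whether consecutive-
  generation co-occurrence exceeds chance.
* :func:`fixed_rate_null` -- populates a fresh table with independent calls
  at a fixed per-cell rate, for class-level comparisons of the inherited
  proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .core_io import StatusTable


@dataclass(frozen=True)
class Run:
    """One directed epimutation episode."""

    locus_id: str
    lineage_id: str
    assay: str
    direction: int
    onset_gen: int
    offset_gen: int
    length: int
    inherited: bool
    censored: bool
    measured_covered: tuple[int, ...]

    @property
    def n_measured(self) -> int:
        return len(self.measured_covered)


def detect_runs(
    statuses: Sequence[int],
    measured_gens: Sequence[int],
    locus_id: str = "",
    lineage_id: str = "",
    assay: str = "",
) -> list[Run]:
    """Segment a ternary status vector into directed runs.

    ``statuses`` holds one call per *measured* generation.  Gaps between
    consecutive measured generations (odd generations, or missing even ones)
    are bridged when the flanking calls share direction and contribute to
    ``length``; they never break a run on their own.
    """
    gens = list(measured_gens)
    if len(statuses) != len(gens):
        raise ValueError("statuses and measured_gens must have equal length")
    if any(b <= a for a, b in zip(gens, gens[1:])):
        raise ValueError(f"measured generations must be sorted: {gens}")
    vals = np.asarray(statuses, dtype=int)
    if not np.isin(vals, (-1, 0, 1)).all():
        raise ValueError("statuses must be in {-1, 0, +1}")

    runs: list[Run] = []
    start = None  # index of current run start
    for i, s in enumerate(vals):
        if start is not None and (s == 0 or s != vals[start]):
            runs.append(_make_run(vals, gens, start, i - 1, locus_id, lineage_id, assay))
            start = None
        if s != 0 and start is None:
            start = i
    if start is not None:
        runs.append(
            _make_run(vals, gens, start, len(vals) - 1, locus_id, lineage_id, assay)
        )
    return runs


def _make_run(vals, gens, i0, i1, locus_id, lineage_id, assay) -> Run:
    onset, offset = gens[i0], gens[i1]
    return Run(
        locus_id=locus_id,
        lineage_id=lineage_id,
        assay=assay,
        direction=int(vals[i0]),
        onset_gen=onset,
        offset_gen=offset,
        length=offset - onset + 1,
        inherited=i1 > i0,
        censored=offset == gens[-1],
        measured_covered=tuple(gens[i0 : i1 + 1]),
    )


def detect_runs_table(status: StatusTable) -> list[Run]:
    """Detect runs for every locus of a status table."""
    gens = status.generations
    out: list[Run] = []
    mat = status.statuses.to_numpy()
    for locus, row in zip(status.locus_ids, mat):
        if not row.any():
            continue
        out.extend(
            detect_runs(row, gens, str(locus), status.lineage_id, status.assay)
        )
    return out


def runs_to_frame(runs: Iterable[Run]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": r.locus_id,
            "lineage_id": r.lineage_id,
            "assay": r.assay,
            "direction": r.direction,
            "onset_gen": r.onset_gen,
            "offset_gen": r.offset_gen,
            "length": r.length,
            "inherited": r.inherited,
            "censored": r.censored,
        }
        for r in runs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "lineage_id",
            "assay",
            "direction",
            "onset_gen",
            "offset_gen",
            "length",
            "inherited",
            "censored",
        ],
    )


def runs_to_status(
    runs: Iterable[Run], locus_ids: Sequence[str], measured_gens: Sequence[int]
) -> pd.DataFrame:
    """Rebuild the ternary matrix from runs (measured cells only)."""
    df = pd.DataFrame(0, index=pd.Index(locus_ids, name="locus_id"),
                      columns=list(measured_gens), dtype=int)
    for r in runs:
        df.loc[r.locus_id, list(r.measured_covered)] = r.direction
    return df


# ---------------------------------------------------------------------------
# vectorized run counting (used by the simulation nulls; equivalence with
# detect_runs is asserted by a property test)


def count_runs_matrix(status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Count (inherited runs, all runs) for a 2-D or batched 3-D status matrix.

    A run starts wherever a nonzero cell follows a zero, a different sign, or
    the table edge; it is inherited when the next column repeats its sign.
    Returns arrays of shape ``()`` for 2-D input or ``(batch,)`` for 3-D.
    """
    s = np.asarray(status)
    squeeze = s.ndim == 2
    if squeeze:
        s = s[None]
    nz = s != 0
    prev_differs = np.ones_like(nz)
    prev_differs[:, :, 1:] = s[:, :, 1:] != s[:, :, :-1]
    starts = nz & prev_differs
    cont = np.zeros_like(nz)
    cont[:, :, :-1] = nz[:, :, :-1] & (s[:, :, 1:] == s[:, :, :-1])
    n_runs = starts.sum(axis=(1, 2))
    n_inherited = (starts[:, :, :-1] & cont[:, :, :-1]).sum(axis=(1, 2))
    if squeeze:
        return n_inherited[0], n_runs[0]
    return n_inherited, n_runs


def inherited_cells_matrix(status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero cells belonging to inherited runs, and all nonzero cells."""
    s = np.asarray(status)
    squeeze = s.ndim == 2
    if squeeze:
        s = s[None]
    nz = s != 0
    same_next = np.zeros_like(nz)
    same_next[:, :, :-1] = nz[:, :, :-1] & (s[:, :, 1:] == s[:, :, :-1])
    same_prev = np.zeros_like(nz)
    same_prev[:, :, 1:] = same_next[:, :, :-1]
    in_inherited = same_next | same_prev
    a, b = in_inherited.sum(axis=(1, 2)), nz.sum(axis=(1, 2))
    if squeeze:
        return a[0], b[0]
    return a, b


def inherited_percent(status: np.ndarray, unit: str = "runs") -> float:
    """Percentage of runs (or called cells) that are inherited; NaN if no calls."""
    if unit == "runs":
        inh, tot = count_runs_matrix(status)
    elif unit == "cells":
        inh, tot = inherited_cells_matrix(status)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, 100.0 * inh / np.maximum(tot, 1), np.nan)


# ---------------------------------------------------------------------------
# Survival analysis


@dataclass
class SurvivalResult:
    groups: list[str]
    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    statistic: float
    p: float


def survival_analysis(runs_by_group: Mapping[str, Sequence[Run]]) -> SurvivalResult:
    """Kaplan-Meier duration curves per group plus a log-rank test across groups.

    Runs still active at the last measured generation enter as right-censored
    observations at their observed length.
    """
    groups = list(runs_by_group)
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    durations, events, labels = [], [], []
    for g in groups:
        runs = list(runs_by_group[g])
        if not runs:
            raise ValueError(f"empty run group {g!r}")
        d = np.array([r.length for r in runs], dtype=float)
        e = np.array([not r.censored for r in runs], dtype=bool)
        kmf = KaplanMeierFitter()
        kmf.fit(d, event_observed=e, label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        medians[g] = float(kmf.median_survival_time_)
        durations.append(d)
        events.append(e)
        labels.append(np.repeat(g, len(d)))
    if len(groups) > 1:
        res = multivariate_logrank_test(
            np.concatenate(durations),
            np.concatenate(labels),
            np.concatenate(events),
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        stat, p = float("nan"), float("nan")
    return SurvivalResult(groups, curves, medians, stat, p)


# ---------------------------------------------------------------------------
# Simulation nulls


def _spawn_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _reassort_counts(
    status: StatusTable | pd.DataFrame,
    n_sim: int,
    rng: np.random.Generator,
    unit: str = "runs",
    batch: int = 64,
    epimutable: str | Sequence[str] = "observed",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-simulation (inherited, total) counts under column reassortment."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    df = status.statuses if isinstance(status, StatusTable) else status
    mat = df.to_numpy(dtype=np.int8)
    if isinstance(epimutable, str):
        if epimutable == "observed":
            mask = mat.any(axis=1)
        elif epimutable == "all":
            mask = np.ones(mat.shape[0], dtype=bool)
        else:
            raise ValueError(f"unknown epimutable spec {epimutable!r}")
    else:
        mask = df.index.isin(set(epimutable))
    sub = mat[mask]
    max_calls = int((sub != 0).sum(axis=0).max(initial=0))
    if sub.shape[0] < max_calls:
        raise ValueError("fewer epimutable loci than the largest per-column call count")
    counter = count_runs_matrix if unit == "runs" else inherited_cells_matrix
    inh = np.empty(n_sim, dtype=np.int64)
    tot = np.empty(n_sim, dtype=np.int64)
    for lo in range(0, n_sim, batch):
        b = min(batch, n_sim - lo)
        tiled = np.broadcast_to(sub, (b, *sub.shape))
        perm = rng.permuted(tiled, axis=1)  # independent row-permutation per column
        inh[lo : lo + b], tot[lo : lo + b] = counter(perm)
    return inh, tot


def reassortment_null(
    status: StatusTable | pd.DataFrame,
    n_sim: int,
    seed: int | np.random.Generator,
    unit: str = "runs",
    batch: int = 64,
    epimutable: str | Sequence[str] = "observed",
) -> np.ndarray:
    """Inherited-percentage distribution under random reassortment of calls.

    Each simulation permutes every generation column's entries independently
    across the epimutable loci, so per-column call counts and their sign
    multisets are preserved exactly while any across-generation memory is
    destroyed.  ``epimutable`` picks the reassortment universe: "observed"
    (loci with at least one call -- the operational proxy used on real data,
    where structurally non-epimutable loci would otherwise dilute the null),
    "all" (every locus; exact when the whole universe is genuinely
    epimutable, e.g. in calibration simulations), or an explicit locus list.
    Note the "observed" proxy conditions on having a call, which inflates
    the null's coincidence rate for sparse tables and hence makes the
    inheritance excess conservative.
    """
    rng = _spawn_rng(seed)
    inh, tot = _reassort_counts(status, n_sim, rng, unit=unit, batch=batch,
                                epimutable=epimutable)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, 100.0 * inh / np.maximum(tot, 1), np.nan)


@dataclass
class ExcessResult:
    """Observed-vs-simulated inheritance excess over a grid of Z cutoffs."""

    table: pd.DataFrame  # cutoff, n_calls, observed, sim_mean, sim_sd, excess, p
    argmax_cutoff: float


def optimize_threshold(
    z_tables: Sequence,
    grid: Sequence[float] | None = None,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    unit: str = "runs",
    epimutable: str | Sequence[str] = "observed",
) -> ExcessResult:
    """Scan Z cutoffs for the largest inheritance excess over the reassortment null.

    At each cutoff every Z table is binarized, the observed inherited
    percentage is pooled across tables, and compared with the mean of the
    reassortment null; the empirical p uses the add-one permutation
    convention.  Cutoffs yielding zero calls are recorded as missing.
    """
    from .calling import CallParams, call_epimutations  # local import, no cycle

    if grid is None:
        grid = np.arange(1.0, 3.0 + 1e-9, 0.25)
    grid = np.asarray(list(grid), dtype=float)
    if (grid <= 0).any():
        raise ValueError("cutoff grid must be positive")
    rng = _spawn_rng(seed)
    rows = []
    for cutoff in grid:
        statuses = [
            call_epimutations(zt, CallParams(z_threshold=float(cutoff))) for zt in z_tables
        ]
        mats = [st.statuses.to_numpy(dtype=np.int8) for st in statuses]
        if unit == "runs":
            counts = [count_runs_matrix(m) for m in mats]
        else:
            counts = [inherited_cells_matrix(m) for m in mats]
        tot = sum(int(t) for _, t in counts)
        if tot == 0:
            rows.append(
                dict(cutoff=cutoff, n_calls=0, observed=np.nan, sim_mean=np.nan,
                     sim_sd=np.nan, excess=np.nan, p=np.nan)
            )
            continue
        observed = 100.0 * sum(int(i) for i, _ in counts) / tot
        sim_inh = np.zeros(n_sim)
        sim_tot = np.zeros(n_sim)
        for st in statuses:
            if not st.statuses.to_numpy().any():
                continue
            i, t = _reassort_counts(st, n_sim, rng, unit=unit, epimutable=epimutable)
            sim_inh += i
            sim_tot += t
        pooled = 100.0 * sim_inh / np.maximum(sim_tot, 1)
        n_calls = int(sum((m != 0).sum() for m in mats))
        excess = observed - float(pooled.mean())
        p = (1.0 + float((pooled >= observed).sum())) / (1.0 + n_sim)
        rows.append(
            dict(cutoff=cutoff, n_calls=n_calls, observed=observed,
                 sim_mean=float(pooled.mean()), sim_sd=float(pooled.std(ddof=0)),
                 excess=excess, p=p)
        )
    table = pd.DataFrame(rows)
    if table["excess"].notna().any():
        argmax = float(table.loc[table["excess"].idxmax(), "cutoff"])
    else:
        argmax = float("nan")
    return ExcessResult(table=table, argmax_cutoff=argmax)


def fixed_rate_null(
    observed_rate: float,
    shape: tuple[int, int],
    n_sim: int = 10000,
    seed: int | np.random.Generator = 0,
    batch: int = 256,
) -> np.ndarray:
    """Inherited-proportion distribution under independent fixed-rate calls.

    Each cell is nonzero with probability ``observed_rate`` (sign +/- with
    equal probability, independently); per simulation the proportion of runs
    spanning at least two columns is returned (0 when no runs arise).
    """
    if not 0.0 <= observed_rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {observed_rate}")
    rng = _spawn_rng(seed)
    n_loci, n_gens = shape
    out = np.empty(n_sim, dtype=float)
    for lo in range(0, n_sim, batch):
        b = min(batch, n_sim - lo)
        u = rng.random((b, n_loci, n_gens))
        sign = rng.integers(0, 2, size=(b, n_loci, n_gens)) * 2 - 1
        status = np.where(u < observed_rate, sign, 0).astype(np.int8)
        inh, tot = count_runs_matrix(status)
        out[lo : lo + b] = np.where(tot > 0, inh / np.maximum(tot, 1), 0.0)
    return out
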