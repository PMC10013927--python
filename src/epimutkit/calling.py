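"""Normalization, MA-plot residual Z-scores and epimutation calling.

Counts are first normalized with median-of-ratios size factors (the standard
sequencing-depth correction: each generation column is divided by the median,
over reference loci, of its ratio to the per-locus geometric mean).  For each
post-founder generation *g* a simple MA-plot linear model is fitted against
the founder (PMA, generation 0): the per-locus log2 fold change
``y_i = log2((c_{i,g}+pc) / (c_{i,0}+pc))`` is regressed by ordinary least
squares on the log2 mean count ``x_i``, which removes the systematic
mean-dependence of fold-change variability.  Residuals are standardized into
Z-scores (mean 0, population SD 1 per comparison), and cells with
``Z > t`` / ``Z < -t`` become Up (+1) / Down (-1) epimutation calls.  The
default threshold ``t = 2.25`` is the cutoff at which the inheritance excess
over a reassortment null peaks (see :mod:`epimutkit.inheritance`).

Putatively environmentally induced events -- runs with the same locus,
direction, onset and duration in *all* lineages, which a shared external
stimulus rather than spontaneous change would produce -- can be erased with
:func:`filter_environmental`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnnotationTable, CountTable, StatusTable, ZTable


class DegenerateFitError(ValueError):
    """Raised when a generation's residuals carry no spread (SD = 0)."""


@dataclass
class SizeFactors:
    lineage_id: str
    assay: str
    factors: pd.Series  # indexed by generation, all > 0


@dataclass
class MAFit:
    """One fitted MA-plot comparison (generation g versus PMA)."""

    lineage_id: str
    assay: str
    generation: int
    slope: float
    intercept: float
    residuals: pd.Series  # indexed by included locus ids
    resid_mean: float
    resid_sd: float


@dataclass
class CallParams:
    """Tunables for Z-score derivation and thresholding.

    z_threshold : calls require |Z| strictly greater than this (default 2.25).
    pseudocount : added to counts before every log2 (default 1.0).
    min_mean    : loci with normalized counts below this in *both* compared
                  samples are excluded from the fit and assigned Z = 0.
    subset_chromosome : restrict the fit and standardization to loci on one
                  chromosome (requires an annotation), e.g. for
                  X-chromosome-specific Z-scores.
    ma_mean_mode : "pairwise" (mean of the two compared samples, the MA-plot
                  convention) or "all_samples".
    """

    z_threshold: float = 2.25
    pseudocount: float = 1.0
    min_mean: float = 1.0
    subset_chromosome: str | None = None
    ma_mean_mode: str = "pairwise"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.min_mean < 0:
            raise ValueError("min_mean must be non-negative")
        if self.ma_mean_mode not in ("pairwise", "all_samples"):
            raise ValueError(f"unknown ma_mean_mode {self.ma_mean_mode!r}")


def compute_size_factors(raw: CountTable) -> SizeFactors:
    """Median-of-ratios size factors (reference = loci nonzero in every column)."""
    mat = raw.counts.to_numpy(dtype=float)
    reference = (mat > 0).all(axis=1)
    if not reference.any():
        raise ValueError("no locus has nonzero counts in every generation column")
    ref = mat[reference]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return SizeFactors(
        raw.lineage_id,
        raw.assay,
        pd.Series(factors, index=raw.counts.columns, name="size_factor"),
    )


def normalize_counts(raw: CountTable, size_factors: SizeFactors | None = None) -> CountTable:
    """Divide each generation column by its size factor."""
    if size_factors is None:
        size_factors = compute_size_factors(raw)
    norm = raw.counts.astype(float).div(size_factors.factors, axis=1)
    return CountTable(raw.lineage_id, raw.assay, norm)


def ma_zscores(
    norm: CountTable,
    params: CallParams | None = None,
    annotation: AnnotationTable | None = None,
) -> tuple[ZTable, dict[int, MAFit]]:
    """Residual Z-scores for every generation versus the PMA founder.

    One OLS fit per (lineage, generation) comparison; residuals are centred
    and scaled by their population SD so every non-degenerate column has
    mean 0 and SD 1 over the fitted loci.  Excluded loci (below ``min_mean``
    in both samples, or off the requested chromosome subset) get Z = 0.
    """
    params = params or CallParams()
    df = norm.counts.astype(float)
    if params.subset_chromosome is not None:
        if annotation is None:
            raise ValueError("subset_chromosome requires an annotation")
        chrom = annotation.table["chromosome"]
        keep = [
            loc
            for loc in df.index
            if loc in chrom.index and chrom[loc] == params.subset_chromosome
        ]
        df = df.loc[keep]
    gens = [g for g in df.columns if g != 0]
    pc = params.pseudocount
    c0 = df[0].to_numpy()
    if params.ma_mean_mode == "all_samples":
        all_mean = df.to_numpy().mean(axis=1)
    zmat = pd.DataFrame(0.0, index=df.index, columns=gens)
    fits: dict[int, MAFit] = {}
    for g in gens:
        cg = df[g].to_numpy()
        include = (c0 >= params.min_mean) | (cg >= params.min_mean)
        if include.sum() < 3:
            raise DegenerateFitError(
                f"generation {g}: fewer than 3 loci pass the min_mean filter"
            )
        y = np.log2(cg[include] + pc) - np.log2(c0[include] + pc)
        if params.ma_mean_mode == "pairwise":
            x = np.log2((c0[include] + cg[include]) / 2.0 + pc)
        else:
            x = np.log2(all_mean[include] + pc)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        mu = float(resid.mean())
        sd = float(resid.std(ddof=0))
        if sd < 1e-12:
            raise DegenerateFitError(
                f"generation {g}: residual SD is zero (column identical to PMA?)"
            )
        z = (resid - mu) / sd
        col = np.zeros(len(df))
        col[include] = z
        zmat[g] = col
        fits[g] = MAFit(
            norm.lineage_id, norm.assay, int(g), float(slope), float(intercept),
            pd.Series(resid, index=df.index[include]), mu, sd,
        )
    return ZTable(norm.lineage_id, norm.assay, zmat), fits


def call_epimutations(z: ZTable, params: CallParams | None = None) -> StatusTable:
    """Threshold Z-scores into ternary calls (strict inequalities)."""
    params = params or CallParams()
    t = params.z_threshold
    vals = z.z.to_numpy()
    status = np.where(vals > t, 1, np.where(vals < -t, -1, 0))
    return StatusTable(
        z.lineage_id, z.assay, pd.DataFrame(status, index=z.z.index, columns=z.z.columns)
    )


def filter_environmental(
    statuses: Mapping[str, StatusTable],
) -> tuple[dict[str, StatusTable], pd.DataFrame]:
    """Erase runs identical in every lineage (putatively induced, not spontaneous).

    A run is erased when its (locus, direction, onset, duration) signature
    occurs in *all* supplied lineages; erased cells are set to 0 in every
    lineage and listed in the removal log.
    """
    from .inheritance import detect_runs_table

    if len(statuses) < 2:
        raise ValueError("filter_environmental needs at least 2 lineages")
    lineages = list(statuses)
    locus_sets = [frozenset(st.locus_ids) for st in statuses.values()]
    if len(set(locus_sets)) != 1:
        raise ValueError("lineages have non-matching locus universes")

    runs_by_lineage = {lin: detect_runs_table(st) for lin, st in statuses.items()}
    signatures = [
        {(r.locus_id, r.direction, r.onset_gen, r.length) for r in runs}
        for runs in runs_by_lineage.values()
    ]
    shared = frozenset.intersection(*map(frozenset, signatures))

    filtered: dict[str, StatusTable] = {}
    log_rows = []
    for lin, st in statuses.items():
        df = st.statuses.copy()
        for r in runs_by_lineage[lin]:
            sig = (r.locus_id, r.direction, r.onset_gen, r.length)
            if sig in shared:
                df.loc[r.locus_id, list(r.measured_covered)] = 0
                log_rows.append(
                    dict(lineage_id=lin, locus_id=r.locus_id, direction=r.direction,
                         onset_gen=r.onset_gen, offset_gen=r.offset_gen, length=r.length)
                )
        filtered[lin] = StatusTable(st.lineage_id, st.assay, df)
    log = pd.DataFrame(
        log_rows,
        columns=["lineage_id", "locus_id", "direction", "onset_gen", "offset_gen", "length"],
    )
    return filtered, log
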