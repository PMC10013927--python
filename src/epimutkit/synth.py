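"""Synthetic multi-lineage, multi-assay count data with a truth ledger.

The generator emulates the mutation-accumulation study design: three
independent lineages sampled at the founder (generation 0) and at even
generations 2-20, with three count channels -- polyA expression and
antisense 22G small RNAs quantified per gene, and chromatin accessibility
quantified per regulatory element (several elements may belong to one gene).

Counts are negative-binomial around a log-normal per-locus baseline with an
RNA-seq-like mean-variance trend ``var = mu + phi(mu) * mu^2`` where
``phi(mu) = a + b/mu``.  Epimutation events arise on the *full* generation
lattice 1-20 (onset Bernoulli(rho) per generation, duration geometric with
continuation probability pi) and multiply the baseline mean by
``2^{+/-delta}`` while active; the pipeline only ever observes the even
measured grid, so the odd-generation imputation logic downstream is
genuinely exercised.  Optional features: expression events coupled to a
partner chromatin/22G event (with a sign-concordance probability), and
"environmental" events injected with identical locus, direction, onset and
duration in every lineage.

Every injected event is recorded in a ledger so recovery (rate, duration,
environmental filtering) can be scored against ground truth.  To keep that
scoring unambiguous, events at one locus are separated by at least two
silent generations (each event then projects to exactly one run on the
measured grid) and environmental loci carry no other events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AnnotationTable, CountTable, StatusTable

DEFAULT_MEASURED = (0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
CHANNELS = ("expression", "atac", "sRNA-22G")


@dataclass
class SimConfig:
    """Study-design and event-process parameters for :func:`simulate`.

    rho is the per-generation, per-locus onset probability of a spontaneous
    epimutation (default 0.01 per channel); pi the per-generation
    continuation probability (default 0.8, i.e. geometric durations with
    median 4 generations, matching the 3-5-generation persistence typical of
    these lineages); delta the log2 fold-change magnitude of an active event.
    """

    n_lineages: int = 3
    measured_gens: tuple[int, ...] = DEFAULT_MEASURED
    n_genes: int = 2000
    n_elements: int = 3000
    channels: tuple[str, ...] = CHANNELS
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    disp_a: float = 0.01
    disp_b: float = 1.0
    rho: float = 0.01
    pi: float = 0.8
    delta: float = 3.0
    coupling_prob: float = 0.25
    concordance_prob: float = 0.5
    environmental_events: int = 5
    depth_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho", "pi", "coupling_prob", "concordance_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if 0 not in self.measured_gens:
            raise ValueError("measured_gens must include the PMA generation 0")


LEDGER_COLUMNS = [
    "event_id",
    "lineage_id",
    "assay",
    "locus_id",
    "direction",
    "onset",
    "offset",
    "environmental",
    "coupled_to",
]


@dataclass
class SimResult:
    counts: dict[tuple[str, str], CountTable]  # (lineage, assay) -> raw counts
    annotation: AnnotationTable
    ledger: pd.DataFrame
    config: SimConfig

    def truth_status(self, lineage_id: str, assay: str) -> StatusTable:
        """Project ledger events of one (lineage, assay) onto the measured grid."""
        ct = self.counts[(lineage_id, assay)]
        gens = [g for g in ct.generations if g != 0]
        mat = pd.DataFrame(0, index=ct.locus_ids, columns=gens, dtype=int)
        sub = self.ledger[
            (self.ledger["lineage_id"] == lineage_id)
            & (self.ledger["assay"] == assay)
        ]
        for _, ev in sub.iterrows():
            cover = [g for g in gens if ev["onset"] <= g <= ev["offset"]]
            if cover:
                mat.loc[ev["locus_id"], cover] = int(ev["direction"])
        return StatusTable(lineage_id, assay, mat)


def _make_annotation(cfg: SimConfig, rng: np.random.Generator) -> AnnotationTable:
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    domains = ("Active", "Regulated", "Border", "X", "piRNA_cluster")
    dom_p = (0.35, 0.35, 0.1, 0.15, 0.05)
    chroms = ("I", "II", "III", "IV", "V", "X")
    rows = []
    pos = {c: 1000 for c in chroms}
    gene_chrom = {}
    for g in genes:
        chrom = chroms[rng.integers(len(chroms))]
        start = pos[chrom]
        pos[chrom] += 2000
        gene_chrom[g] = chrom
        rows.append((chrom, start, start + 1500, g, "gene", g,
                     str(rng.choice(domains, p=dom_p))))
    # every gene gets one element, extras are assigned at random
    owners = genes + [genes[int(i)] for i in
                      rng.integers(cfg.n_genes, size=max(0, cfg.n_elements - cfg.n_genes))]
    for j, owner in enumerate(owners[: cfg.n_elements]):
        chrom = gene_chrom[owner]
        start = pos[chrom]
        pos[chrom] += 600
        rows.append((chrom, start, start + 400, f"re{j:05d}",
                     "regulatory_element", owner, str(rng.choice(domains, p=dom_p))))
    return AnnotationTable(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "locus_id",
                                    "locus_class", "gene_id", "domain"])
    )


def _draw_duration(rng: np.random.Generator, pi: float) -> int:
    if pi >= 1.0:
        return 10**6  # persists past the end of the experiment
    return int(rng.geometric(1.0 - pi))


def _spontaneous_events(
    rng: np.random.Generator, loci: Sequence[str], blocked: set[str],
    rho: float, pi: float, last_gen: int,
) -> list[tuple[str, int, int, int]]:
    """(locus, direction, onset, offset) with >= 2 silent generations between events."""
    out = []
    if rho <= 0:
        return out
    for locus in loci:
        if locus in blocked:
            continue
        t = 1
        while t <= last_gen:
            # generations until next onset ~ geometric(rho)
            gap = int(rng.geometric(rho))
            onset = t + gap - 1
            if onset > last_gen:
                break
            dur = _draw_duration(rng, pi)
            offset = min(onset + dur - 1, last_gen)
            direction = int(rng.integers(0, 2)) * 2 - 1
            out.append((locus, direction, onset, offset))
            t = offset + 3  # enforce a >= 2-generation silent gap
    return out


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate raw count tables for every (lineage, assay) plus a truth ledger."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    annotation = _make_annotation(cfg, rng)
    genes = list(annotation.genes)
    elements = list(annotation.elements)
    loci_by_channel = {
        "expression": genes,
        "sRNA-22G": genes,
        "atac": elements,
    }
    lineages = [chr(ord("A") + i) for i in range(cfg.n_lineages)]
    last_gen = max(cfg.measured_gens)

    # reserved loci for environmental events (no other events placed there)
    env_events: list[dict] = []
    env_loci: dict[str, set[str]] = {ch: set() for ch in cfg.channels}
    for k in range(cfg.environmental_events):
        channel = cfg.channels[k % len(cfg.channels)]
        pool = [l for l in loci_by_channel[channel] if l not in env_loci[channel]]
        locus = pool[int(rng.integers(len(pool)))]
        env_loci[channel].add(locus)
        even_gens = [g for g in cfg.measured_gens if 2 <= g <= last_gen - 4]
        onset = int(even_gens[int(rng.integers(len(even_gens)))])
        offset = min(onset + _draw_duration(rng, cfg.pi) - 1, last_gen)
        direction = int(rng.integers(0, 2)) * 2 - 1
        env_events.append(
            dict(assay=channel, locus_id=locus, direction=direction,
                 onset=onset, offset=offset)
        )

    ledger_rows: list[dict] = []
    events_by_table: dict[tuple[str, str], list[tuple[str, int, int, int]]] = {}
    eid = 0
    for lin in lineages:
        per_channel: dict[str, list[tuple[str, int, int, int]]] = {}
        for channel in cfg.channels:
            blocked = set(env_loci[channel])
            per_channel[channel] = _spontaneous_events(
                rng, loci_by_channel[channel], blocked, cfg.rho, cfg.pi, last_gen
            )
        # coupled partner events for expression events
        coupled: list[tuple[str, str, tuple[str, int, int, int], int]] = []
        if "expression" in cfg.channels and cfg.coupling_prob > 0:
            occupied: dict[str, dict[str, list[tuple[int, int]]]] = {
                ch: {} for ch in cfg.channels
            }
            for ch in cfg.channels:
                for locus, _, onset, offset in per_channel[ch]:
                    occupied[ch].setdefault(locus, []).append((onset, offset))
            partner_channels = [c for c in ("atac", "sRNA-22G") if c in cfg.channels]
            for idx, (gene, direction, onset, offset) in enumerate(
                per_channel["expression"]
            ):
                if not partner_channels or rng.random() >= cfg.coupling_prob:
                    continue
                pch = partner_channels[int(rng.integers(len(partner_channels)))]
                if pch == "atac":
                    elems = annotation.gene_to_elements.get(gene, [])
                    elems = [e for e in elems if e not in env_loci["atac"]]
                    if not elems:
                        continue
                    plocus = elems[int(rng.integers(len(elems)))]
                else:
                    if gene in env_loci["sRNA-22G"]:
                        continue
                    plocus = gene
                p_off = min(onset + _draw_duration(rng, cfg.pi) - 1, last_gen)
                clash = any(
                    s <= p_off + 2 and onset - 2 <= e
                    for s, e in occupied[pch].get(plocus, [])
                )
                if clash:
                    continue
                pdir = direction if rng.random() < cfg.concordance_prob else -direction
                occupied[pch].setdefault(plocus, []).append((onset, p_off))
                coupled.append((pch, plocus, (plocus, pdir, onset, p_off), idx))

        expr_event_ids: dict[int, int] = {}
        for channel in cfg.channels:
            evs = list(per_channel[channel])
            key = (lin, channel)
            events_by_table[key] = []
            for idx, (locus, direction, onset, offset) in enumerate(evs):
                ledger_rows.append(
                    dict(event_id=eid, lineage_id=lin, assay=channel,
                         locus_id=locus, direction=direction, onset=onset,
                         offset=offset, environmental=False, coupled_to=pd.NA)
                )
                if channel == "expression":
                    expr_event_ids[idx] = eid
                events_by_table[key].append((locus, direction, onset, offset))
                eid += 1
        for pch, plocus, (l, d, o, f), expr_idx in coupled:
            ledger_rows.append(
                dict(event_id=eid, lineage_id=lin, assay=pch, locus_id=l,
                     direction=d, onset=o, offset=f, environmental=False,
                     coupled_to=expr_event_ids[expr_idx])
            )
            events_by_table[(lin, pch)].append((l, d, o, f))
            eid += 1
        for ev in env_events:
            ledger_rows.append(
                dict(event_id=eid, lineage_id=lin, assay=ev["assay"],
                     locus_id=ev["locus_id"], direction=ev["direction"],
                     onset=ev["onset"], offset=ev["offset"],
                     environmental=True, coupled_to=pd.NA)
            )
            events_by_table[(lin, ev["assay"])].append(
                (ev["locus_id"], ev["direction"], ev["onset"], ev["offset"])
            )
            eid += 1

    # baselines shared across lineages (same founder population)
    baselines = {
        ch: np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                              size=len(loci_by_channel[ch])))
        for ch in cfg.channels
    }

    counts: dict[tuple[str, str], CountTable] = {}
    gens = list(cfg.measured_gens)
    for lin in lineages:
        for channel in cfg.channels:
            loci = loci_by_channel[channel]
            locus_pos = {l: i for i, l in enumerate(loci)}
            mu = np.tile(baselines[channel][:, None], (1, len(gens)))
            for locus, direction, onset, offset in events_by_table[(lin, channel)]:
                i = locus_pos[locus]
                for j, g in enumerate(gens):
                    if onset <= g <= offset:
                        mu[i, j] *= 2.0 ** (direction * cfg.delta)
            depth = np.exp(rng.normal(0.0, cfg.depth_log_sd, size=len(gens)))
            mu_eff = mu * depth[None, :]
            phi = cfg.disp_a + cfg.disp_b / mu_eff
            size = 1.0 / phi  # NB with var = mu + phi mu^2
            p = size / (size + mu_eff)
            mat = rng.negative_binomial(size, p)
            counts[(lin, channel)] = CountTable(
                lin, channel,
                pd.DataFrame(mat, index=pd.Index(loci, name="locus_id"), columns=gens),
            )
    ledger = pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS)
    return SimResult(counts=counts, annotation=annotation, ledger=ledger, config=cfg)


# ---------------------------------------------------------------------------
# Printed worked examples


def emit_worked_examples() -> dict[str, StatusTable]:
    """The three printed per-locus status vectors used as desk fixtures.

    A germline coding-promoter locus with three separate Down episodes, and
    the ugt-26 expression / regulatory-element pair whose overlap illustrates
    simultaneous, inherited changes.
    """
    gens = list(range(2, 21, 2))

    def one(locus: str, lineage: str, assay: str, vec) -> StatusTable:
        df = pd.DataFrame([vec], index=pd.Index([locus], name="locus_id"), columns=gens)
        return StatusTable(lineage, assay, df)

    return {
        "chromatin_Y65B4BL.7": one(
            "Y65B4BL.7", "A", "atac", [-1, 0, 0, 0, -1, -1, -1, 0, -1, 0]
        ),
        "expression_ugt-26": one(
            "ugt-26", "A", "expression", [0, 1, 0, 1, 1, 1, 1, 1, 1, 1]
        ),
        "chromatin_ugt-26": one(
            "ugt-26_re1", "A", "atac", [0, 0, 0, 1, 1, 0, 0, 0, 1, 0]
        ),
    }
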