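"""End-to-end orchestration: normalize -> zscore -> call -> filter ->
runs -> survival -> classify -> associate (-> enrich).

Configuration is a plain YAML mapping (see :class:`PipelineConfig`);
all intermediate Z-score and status tables are written as CSVs (locus-id
column plus one column per generation), along with a JSON manifest recording
the package version,
a hash of the configuration and every seed used.  Stage failures abort with
the stage name attached so the offending table can be located.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import build_gene_records
from .calling import CallParams, call_epimutations, filter_environmental, ma_zscores, normalize_counts
from .core_io import read_annotation, read_count_table, write_status_table, write_z_table
from .duration_model import em_mixture_crosscheck, estimate_duration_effects, kmeans_longevity
from .inheritance import detect_runs_table, runs_to_frame, survival_analysis

log = logging.getLogger("epimutkit")

STOCHASTIC_STAGES = ("classify",)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, calling parameters and per-stage seeds for a full run.

    YAML layout::

        counts:                      # one entry per (lineage, assay) CSV
          - {path: a_expr.csv, lineage: A, assay: expression}
        annotation: annotation.csv
        out_dir: results/
        call: {z_threshold: 2.25, pseudocount: 1.0, min_mean: 1.0}
        classify: {lam: 0.0, restarts: 25}
        seeds: {classify: 1}
    """

    counts: list[dict]
    annotation: str
    out_dir: str
    call: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    filter_environmental: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for entry in self.counts:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(entry["path"])
        if not Path(self.annotation).exists():
            raise FileNotFoundError(self.annotation)
        for stage in STOCHASTIC_STAGES:
            if stage not in self.seeds:
                raise PipelineError(stage, "no seed configured for stochastic stage")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: getattr(cfg, k) for k in
         ("counts", "annotation", "out_dir", "call", "classify", "seeds",
          "filter_environmental")},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seeds": dict(config.seeds),
        "stages": {},
    }
    params = CallParams(**config.call)
    annotation = read_annotation(config.annotation)

    statuses_by_assay: dict[str, dict[str, object]] = {}
    try:
        for entry in config.counts:
            lin, assay = entry["lineage"], entry["assay"]
            raw = read_count_table(entry["path"], lin, assay,
                                   sep=entry.get("sep", ","))
            norm = normalize_counts(raw)
            zt, _ = ma_zscores(norm, params, annotation)
            write_z_table(zt, out / f"zscores_{lin}_{assay}.csv")
            st = call_epimutations(zt, params)
            write_status_table(st, out / f"status_{lin}_{assay}.csv")
            statuses_by_assay.setdefault(assay, {})[lin] = st
            log.info("called %s/%s: %d loci, %d calls", lin, assay,
                     len(st.locus_ids), int((st.statuses != 0).sum().sum()))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("call", str(exc)) from exc
    manifest["stages"]["call"] = {
        a: {lin: int((st.statuses != 0).sum().sum()) for lin, st in d.items()}
        for a, d in statuses_by_assay.items()
    }

    if config.filter_environmental:
        try:
            for assay, per_lin in statuses_by_assay.items():
                if len(per_lin) < 2:
                    continue
                filtered, removal = filter_environmental(per_lin)
                statuses_by_assay[assay] = filtered
                removal.to_csv(out / f"environmental_removed_{assay}.csv", index=False)
                for lin, st in filtered.items():
                    write_status_table(st, out / f"status_filtered_{lin}_{assay}.csv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("environmental_filter", str(exc)) from exc

    try:
        all_runs = []
        for assay, per_lin in statuses_by_assay.items():
            for st in per_lin.values():
                all_runs.extend(detect_runs_table(st))
        runs_df = runs_to_frame(all_runs)
        runs_df.to_csv(out / "runs.csv", index=False)
        manifest["stages"]["runs"] = {"n_runs": len(runs_df)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("runs", str(exc)) from exc

    try:
        by_assay = {}
        for r in all_runs:
            by_assay.setdefault(r.assay, []).append(r)
        if all(len(v) > 0 for v in by_assay.values()) and by_assay:
            surv = survival_analysis(by_assay)
            curves = pd.concat(
                [df.assign(group=g) for g, df in surv.curves.items()]
            )
            curves.to_csv(out / "survival_curves.csv", index=False)
            manifest["stages"]["survival"] = {
                "medians": surv.medians, "logrank_p": surv.p,
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("survival", str(exc)) from exc

    try:
        classify_cfg = dict(config.classify)
        lam = classify_cfg.get("lam", 0.0)
        restarts = classify_cfg.get("restarts", 25)
        frames = []
        for assay, runs in by_assay.items():
            est = estimate_duration_effects(runs, lam=lam)
            if est["estimate"].nunique() < 2:
                continue
            classes, _ = kmeans_longevity(
                est, restarts=restarts, seed=int(config.seeds["classify"])
            )
            if len(est) >= 10:
                em = em_mixture_crosscheck(
                    est, seed=int(config.seeds["classify"]), kmeans_classes=classes
                )
                classes = classes.assign(em_component=em.assignments)
            frames.append(classes.assign(assay=assay))
        if frames:
            pd.concat(frames).rename_axis("locus_id").to_csv(out / "longevity_classes.csv")
            manifest["stages"]["classify"] = {
                "n_classified": int(sum(len(f) for f in frames))
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", str(exc)) from exc

    try:
        if "expression" in by_assay:
            from .association import stepwise_fisher

            partner_assays = [a for a in by_assay if a != "expression"]
            assoc_rows = []
            for pa in partner_assays:
                records = build_gene_records(
                    by_assay["expression"], by_assay[pa], annotation
                )
                element_genes = (
                    set(annotation.gene_to_elements) if pa == "atac" else None
                )
                for res in stepwise_fisher(records, element_genes=element_genes):
                    a, b, c, d = res.table.ravel()
                    assoc_rows.append(
                        dict(partner=pa, test=res.label, a=a, b=b, c=c, d=d,
                             odds_ratio=res.odds_ratio,
                             odds_ratio_cmle=res.odds_ratio_cmle, p=res.p)
                    )
            if assoc_rows:
                pd.DataFrame(assoc_rows).to_csv(out / "association.csv", index=False)
                manifest["stages"]["associate"] = {"n_tests": len(assoc_rows)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("associate", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
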