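"""Gene-centric integration of expression changes with partner epimutations.

Expression-change runs at a gene are matched with "partner" epimutation runs
in an associated channel: chromatin runs at any regulatory element annotated
to the gene, or antisense small-RNA (22G) runs at the gene itself.  A partner
run is *simultaneous* when it shares at least one measured epimutated
generation with an expression run (durations need not match: an established
epigenetic state may persist after the initiating signal has gone), and
*concordant* when the directions agree at the earliest shared generation.

The stepwise Fisher battery then asks, with progressively narrower
backgrounds, whether expression changes and partner epimutations co-occur
and whether simultaneity predicts inheritance of the expression change.
Domain and ontology enrichment helpers round out the locus-set comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .core_io import AnnotationTable
from .inheritance import Run


@dataclass
class FisherResult:
    label: str
    table: np.ndarray  # 2x2 [[a, b], [c, d]]
    odds_ratio: float  # sample cross-product (a*d)/(b*c)
    odds_ratio_cmle: float  # conditional-MLE estimate (as R's fisher.test prints)
    p: float
    p_corrected: float | None = None

    @property
    def log2_odds_ratio(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.log2(self.odds_ratio))


def fisher_test(table, label: str = "") -> FisherResult:
    """Two-sided Fisher exact test with both odds-ratio conventions."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    a, b, c, d = t.ravel()
    if b * c == 0:
        sample_or = np.inf if a * d > 0 else np.nan
    else:
        sample_or = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    cmle = _cmle_odds_ratio(t, kind="conditional").statistic
    return FisherResult(label, t, float(sample_or), float(cmle), float(p))


# ---------------------------------------------------------------------------
# Gene records


RECORD_COLUMNS = [
    "gene_id",
    "lineage_id",
    "has_expr_change",
    "expr_inherited",
    "has_partner_epimutation",
    "partner_inherited",
    "simultaneous",
    "concordant",
]


def build_gene_records(
    expr_runs: Iterable[Run],
    partner_runs: Iterable[Run],
    annotation: AnnotationTable,
    lineages: Sequence[str] | None = None,
    require_all_concordant: bool = False,
) -> pd.DataFrame:
    """One record per (gene, lineage) with expression/partner overlap flags.

    The gene universe is the annotation's gene set; partner run loci are
    mapped to genes through the annotation (regulatory elements to their
    ``gene_id``; gene-level loci, e.g. antisense 22G runs, to themselves).
    ``concordant`` is NA unless the record is simultaneous; a multi-element
    gene is concordant when any simultaneous pair matches direction (all
    pairs when ``require_all_concordant``).
    """
    expr_runs = list(expr_runs)
    partner_runs = list(partner_runs)
    ann = annotation.table
    genes = list(annotation.genes)
    gene_set = set(genes)
    if lineages is None:
        lineages = sorted(
            {r.lineage_id for r in expr_runs} | {r.lineage_id for r in partner_runs}
        )

    def partner_gene(locus: str) -> str:
        if locus in gene_set:
            return locus
        if locus in ann.index:
            return ann.at[locus, "gene_id"]
        raise ValueError(f"partner run locus {locus!r} has no gene mapping")

    expr_by_key: dict[tuple[str, str], list[Run]] = {}
    for r in expr_runs:
        expr_by_key.setdefault((r.locus_id, r.lineage_id), []).append(r)
    partner_by_key: dict[tuple[str, str], list[Run]] = {}
    for r in partner_runs:
        partner_by_key.setdefault((partner_gene(r.locus_id), r.lineage_id), []).append(r)

    rows = []
    for gene in genes:
        for lin in lineages:
            e_runs = expr_by_key.get((gene, lin), [])
            p_runs = partner_by_key.get((gene, lin), [])
            simultaneous = False
            concordances: list[bool] = []
            for er in e_runs:
                e_cov = set(er.measured_covered)
                for pr in p_runs:
                    overlap = e_cov & set(pr.measured_covered)
                    if overlap:
                        simultaneous = True
                        concordances.append(er.direction == pr.direction)
            if simultaneous:
                concordant = all(concordances) if require_all_concordant else any(concordances)
            else:
                concordant = pd.NA
            rows.append(
                (
                    gene,
                    lin,
                    bool(e_runs),
                    any(r.inherited for r in e_runs),
                    bool(p_runs),
                    any(r.inherited for r in p_runs),
                    simultaneous,
                    concordant,
                )
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _crosstab(records: pd.DataFrame, row_flag: str, col_flag: str) -> np.ndarray:
    r = records[row_flag].astype(bool).to_numpy()
    c = records[col_flag].astype(bool).to_numpy()
    return np.array(
        [[(r & c).sum(), (r & ~c).sum()], [(~r & c).sum(), (~r & ~c).sum()]],
        dtype=np.int64,
    )


def stepwise_fisher(
    records: pd.DataFrame,
    element_genes: set[str] | None = None,
) -> list[FisherResult]:
    """The four-test association battery, with progressively narrower backgrounds.

    1. expression change x partner epimutation, all genes;
    2. inherited expression change x partner epimutation, all genes;
    3. inherited expression change x simultaneous partner, among genes with
       expression changes;
    4. as 3, among genes with both change types.

    ``element_genes`` restricts tests 1-2 to genes with at least one
    annotated regulatory element (the appropriate background when the
    partner channel is chromatin).
    """
    base = records
    if element_genes is not None:
        base = records[records["gene_id"].isin(element_genes)]
    if len(base) == 0:
        raise ValueError("empty background")
    t3_bg = records[records["has_expr_change"]]
    t4_bg = t3_bg[t3_bg["has_partner_epimutation"]]
    specs = [
        ("test1_change_x_partner", base, "has_expr_change", "has_partner_epimutation"),
        ("test2_inherited_x_partner", base, "expr_inherited", "has_partner_epimutation"),
        ("test3_inherited_x_simultaneous", t3_bg, "expr_inherited", "simultaneous"),
        ("test4_inherited_x_simultaneous_both", t4_bg, "expr_inherited", "simultaneous"),
    ]
    results = []
    for label, bg, rf, cf in specs:
        if len(bg) == 0:
            raise ValueError(f"empty background for {label}")
        results.append(fisher_test(_crosstab(bg, rf, cf), label=label))
    return results


def concordance_association(records: pd.DataFrame) -> dict[str, FisherResult | None]:
    """Inheritance odds for concordant vs discordant simultaneous partners.

    Among genes with expression changes, each arm contrasts records whose
    simultaneous partner matches (concordant) or opposes (discordant) the
    expression direction against records with no simultaneous partner at
    all; an arm with no qualifying records is reported as None.
    """
    bg = records[records["has_expr_change"]]
    if not bg["simultaneous"].any():
        raise ValueError("no simultaneous records")
    no_partner = bg[~bg["simultaneous"]]
    out: dict[str, FisherResult | None] = {}
    for label, want in (("concordant", True), ("discordant", False)):
        arm = bg[bg["simultaneous"] & (bg["concordant"].astype("boolean") == want)]
        if len(arm) == 0:
            out[label] = None
            continue
        sub = pd.concat([arm, no_partner])
        flag = np.concatenate(
            [np.ones(len(arm), dtype=bool), np.zeros(len(no_partner), dtype=bool)]
        )
        inh = sub["expr_inherited"].astype(bool).to_numpy()
        table = np.array(
            [
                [(flag & inh).sum(), (flag & ~inh).sum()],
                [(~flag & inh).sum(), (~flag & ~inh).sum()],
            ],
            dtype=np.int64,
        )
        out[label] = fisher_test(table, label=f"{label}_simultaneous_vs_none")
    return out


# ---------------------------------------------------------------------------
# Enrichment


def domain_enrichment(
    classes: pd.DataFrame,
    domains: Mapping[str, str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Fisher grid of longevity class membership versus chromatin domain.

    Each (class, domain) cell gets a 2x2 Fisher exact test over all loci in
    the domain map, Bonferroni-corrected over the grid; ``significant``
    flags corrected p <= ``alpha``.
    """
    missing = [loc for loc in classes.index if loc not in domains]
    if missing:
        raise ValueError(f"loci without a domain label: {missing}")
    universe = list(domains)
    dom_series = pd.Series({loc: domains[loc] for loc in universe})
    class_series = classes["longevity"]
    class_labels = [c for c in ("non_inherited", "short_lived", "long_lived")
                    if (class_series == c).any()]
    domain_labels = sorted(set(dom_series))
    m = len(class_labels) * len(domain_labels)
    rows = []
    for cl in class_labels:
        in_class = pd.Series(False, index=universe)
        in_class[class_series.index[class_series == cl]] = True
        for dom in domain_labels:
            in_dom = dom_series == dom
            a = int((in_class & in_dom).sum())
            b = int((in_class & ~in_dom).sum())
            c = int((~in_class & in_dom).sum())
            d = int((~in_class & ~in_dom).sum())
            res = fisher_test([[a, b], [c, d]], label=f"{cl}|{dom}")
            p_corr = min(1.0, m * res.p)
            rows.append(
                dict(longevity=cl, domain=dom, a=a, b=b, c=c, d=d,
                     odds_ratio=res.odds_ratio, odds_ratio_cmle=res.odds_ratio_cmle,
                     p=res.p, p_bonferroni=p_corr, significant=p_corr <= alpha)
            )
    return pd.DataFrame(rows)


def _pearson_chi2(table: np.ndarray) -> float:
    """Pearson statistic without continuity correction."""
    chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2)


def ontology_enrichment(
    test_genes: Sequence[str],
    background_genes: Sequence[str],
    term_map: Mapping[str, Sequence[str]] | pd.DataFrame,
    n_samples: int = 50,
    sample_size: int = 6000,
    min_genes: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Term enrichment of a test gene set against a background.

    When the background is at least ``sample_size`` genes, repeated samples
    of that size are drawn and each term scored by the mean Pearson
    chi-squared statistic of its 2x2 membership table (test list vs sample);
    otherwise a direct Fisher exact test with Bonferroni correction is used.
    Terms with fewer than ``min_genes`` members in both lists are excluded.
    """
    if isinstance(term_map, pd.DataFrame):
        pairs = term_map.iloc[:, :2].to_numpy()
        mapping: dict[str, set[str]] = {}
        for gene, term in pairs:
            mapping.setdefault(str(gene), set()).add(str(term))
        term_map = mapping
    if not term_map:
        raise ValueError("empty term_map")
    test = [g for g in dict.fromkeys(test_genes)]
    background = [g for g in dict.fromkeys(background_genes)]
    terms = sorted({t for g in term_map for t in term_map[g]})
    test_counts = {
        t: sum(t in term_map.get(g, ()) for g in test) for t in terms
    }
    rng = np.random.default_rng(seed)

    rows = []
    if len(background) >= sample_size:
        samples = [
            rng.choice(background, size=sample_size, replace=False)
            for _ in range(n_samples)
        ]
        for t in terms:
            a = test_counts[t]
            stats_acc, bg_counts = [], []
            for bg_s in samples:
                c = sum(t in term_map.get(g, ()) for g in bg_s)
                if max(a, c) < min_genes:
                    continue
                table = np.array(
                    [[a, len(test) - a], [c, len(bg_s) - c]], dtype=np.int64
                )
                stats_acc.append(_pearson_chi2(table))
                bg_counts.append(c)
            if not stats_acc:
                continue
            mean_bg = float(np.mean(bg_counts))
            rows.append(
                dict(term=t, mode="chi2_sampled", n_test=a,
                     n_background=mean_bg, statistic=float(np.mean(stats_acc)),
                     p=np.nan, p_bonferroni=np.nan,
                     enriched=a / len(test) > mean_bg / sample_size)
            )
    else:
        eligible = []
        for t in terms:
            a = test_counts[t]
            c = sum(t in term_map.get(g, ()) for g in background)
            if max(a, c) < min_genes:
                continue
            eligible.append((t, a, c))
        m = len(eligible)
        for t, a, c in eligible:
            table = [[a, len(test) - a], [c, len(background) - c]]
            res = fisher_test(table, label=t)
            rows.append(
                dict(term=t, mode="fisher_direct", n_test=a, n_background=c,
                     statistic=res.odds_ratio, p=res.p,
                     p_bonferroni=min(1.0, m * res.p),
                     enriched=a / max(len(test), 1) > c / max(len(background), 1))
            )
    return pd.DataFrame(
        rows,
        columns=["term", "mode", "n_test", "n_background", "statistic", "p",
                 "p_bonferroni", "enriched"],
    )
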