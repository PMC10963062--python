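"""Cross-comparison consistency scoring of differential-abundance calls.

A feature tested in several independent case-vs-control comparisons gets

* a consistency score  CS  = (n1 - n2) / denominator, where n1 and n2
  count the comparisons with a statistically significant increase and
  decrease in the case group, and the denominator is by default the
  number of significant comparisons (n1 + n2; the alternative, all
  evaluated comparisons, is available via ``denominator="total"``);
* a weighted consistency score  WCS = sum(log2FC_i) / sum(|log2FC_i|)
  over the significant comparisons, so large fold changes dominate.

Both scores live in [-1, 1]; +1/-1 means unanimous up/down-regulation.
This is vote counting with magnitude weighting, not a formal
meta-analytic effect pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import ComparisonResult, wilcoxon_rank_sum
from .diversity import fb_ratio
from .io import FeatureTable, TaxonomyMap, ValidationError, RANKS

logger = logging.getLogger(__name__)

#: WCS interprets the up/down coefficient as the sign already carried by
#: log2FC; a literal coefficient-times-signed-fold-change product would be
#: identically 1. Exports carry this flag so the convention is explicit.
WCS_CONVENTION = "signed-log2fc-over-abs-sum"


@dataclass
class ConsistencyRecord:
    """Cross-comparison summary for one feature."""

    feature: str
    n1: int  # significant increases in case
    n2: int  # significant decreases in case
    n_total: int  # comparisons in which the feature was evaluated
    cs: float
    wcs: float
    sig_log2fcs: list[float] = field(default_factory=list)

    @property
    def n_sig(self) -> int:
        return self.n1 + self.n2


def consistency_score(n1: int, n2: int, denominator: int) -> float:
    """CS = (n1 - n2) / denominator; undefined when the denominator is 0."""
    if n1 < 0 or n2 < 0:
        raise ValidationError("n1 and n2 must be non-negative")
    if denominator < n1 + n2:
        raise ValidationError("denominator cannot be smaller than n1 + n2")
    if denominator == 0:
        raise ValidationError("consistency score undefined without comparisons")
    return (n1 - n2) / denominator


def weighted_consistency_score(sig_log2fcs) -> float:
    """WCS = sum(signed log2FC) / sum(|log2FC|) over significant comparisons."""
    fcs = np.asarray(list(sig_log2fcs), dtype=float)
    if fcs.size == 0:
        raise ValidationError("WCS undefined without significant comparisons")
    if (fcs == 0).any() or not np.isfinite(fcs).all():
        raise ValidationError("significant log2 fold changes must be nonzero and finite")
    return float(fcs.sum() / np.abs(fcs).sum())


def consistency_table(
    results: list[ComparisonResult], denominator: str = "significant"
) -> list[ConsistencyRecord]:
    """Score every feature significant in at least one comparison.

    Features are aligned by name across comparisons; a feature absent
    from a comparison's table simply was not evaluated there (its
    n_total is lower). Records are ordered by descending |CS|, then
    descending |WCS|, then feature name.
    """
    if not results:
        raise ValidationError("need at least one comparison result")
    if denominator not in ("significant", "total"):
        raise ValidationError(f"unknown denominator convention {denominator!r}")
    features: dict[str, dict] = {}
    for res in results:
        for fid, row in res.stats.iterrows():
            acc = features.setdefault(
                fid, {"n1": 0, "n2": 0, "n_total": 0, "fcs": []}
            )
            acc["n_total"] += 1
            if bool(row["significant"]) and np.isfinite(row["log2fc"]) and row["log2fc"] != 0:
                if row["log2fc"] > 0:
                    acc["n1"] += 1
                else:
                    acc["n2"] += 1
                acc["fcs"].append(float(row["log2fc"]))
    records = []
    for fid, acc in features.items():
        n_sig = acc["n1"] + acc["n2"]
        if n_sig == 0:
            continue
        denom = n_sig if denominator == "significant" else acc["n_total"]
        records.append(
            ConsistencyRecord(
                feature=fid,
                n1=acc["n1"],
                n2=acc["n2"],
                n_total=acc["n_total"],
                cs=consistency_score(acc["n1"], acc["n2"], denom),
                wcs=weighted_consistency_score(acc["fcs"]),
                sig_log2fcs=acc["fcs"],
            )
        )
    records.sort(key=lambda r: (-abs(r.cs), -abs(r.wcs), r.feature))
    return records


def select_consistent(
    records: list[ConsistencyRecord],
    min_projects: int = 3,
    min_abs_cs: float = 0.6,
) -> list[ConsistencyRecord]:
    """Keep features significant in >= ``min_projects`` comparisons with
    |CS| strictly above ``min_abs_cs`` (the consistency-heatmap rule)."""
    if min_projects < 1 or not 0 <= min_abs_cs <= 1:
        raise ValidationError("invalid selection thresholds")
    return [
        r for r in records if r.n_sig >= min_projects and abs(r.cs) > min_abs_cs
    ]


def records_frame(records: list[ConsistencyRecord]) -> pd.DataFrame:
    rows = [
        {
            "feature": r.feature,
            "n1": r.n1,
            "n2": r.n2,
            "n_sig": r.n_sig,
            "n_total": r.n_total,
            "CS": r.cs,
            "WCS": r.wcs,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows, columns=["feature", "n1", "n2", "n_sig", "n_total", "CS", "WCS"]
    )
    return frame.set_index("feature") if len(frame) else frame


def heatmap_matrix(
    results: list[ComparisonResult], features: list[str] | None = None
) -> pd.DataFrame:
    """Features x comparisons matrix of log2FC masked by significance."""
    cols = {}
    for res in results:
        s = res.stats["log2fc"].where(res.stats["significant"])
        cols[res.comparison_id] = s
    frame = pd.DataFrame(cols)
    if features is not None:
        frame = frame.loc[[f for f in features if f in frame.index]]
    return frame


# ---------------------------------------------------------------------------
# cross-project F/B ratio


def fb_ratio_cross_project(
    phylum_tables: dict[str, FeatureTable],
    designs,
    meta_by_comparison,
    firmicutes: str = "Firmicutes",
    bacteroidetes: str = "Bacteroidetes",
) -> pd.DataFrame:
    """Per-comparison fold change of the median F/B ratio (case/control).

    Returns a frame indexed by comparison id with the fold change, the
    Wilcoxon rank-sum p comparing per-sample F/B ratios, and log2(p) for
    display export. Comparisons whose phylum table lacks either phylum
    are skipped with a warning.
    """
    rows = []
    for design in designs:
        table = phylum_tables.get(design.comparison_id)
        meta = meta_by_comparison[design.comparison_id]
        if table is None:
            logger.warning("no phylum table for %s; skipped", design.comparison_id)
            continue
        try:
            ratios = fb_ratio(table, firmicutes, bacteroidetes)
        except ValidationError as exc:
            logger.warning("%s: %s; skipped", design.comparison_id, exc)
            continue
        case_ids = meta.samples_in_group(design.project, design.case_group)
        control_ids = meta.samples_in_group(design.project, design.control_group)
        case_r = ratios.loc[[s for s in case_ids if s in ratios.index]]
        ctrl_r = ratios.loc[[s for s in control_ids if s in ratios.index]]
        if len(case_r) < 2 or len(ctrl_r) < 2:
            logger.warning("%s: too few samples for F/B; skipped", design.comparison_id)
            continue
        fold = float(np.median(case_r) / np.median(ctrl_r))
        _, p = wilcoxon_rank_sum(case_r.to_numpy(), ctrl_r.to_numpy())
        rows.append(
            {
                "comparison_id": design.comparison_id,
                "fold_change": fold,
                "p": p,
                "log2_p": float(np.log2(p)) if p > 0 else -np.inf,
            }
        )
    return pd.DataFrame(
        rows, columns=["comparison_id", "fold_change", "p", "log2_p"]
    ).set_index("comparison_id")


def pathway_consistency(
    results: list[ComparisonResult],
    lda_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathways x comparisons matrix of signed LDA scores.

    An entry survives only when log10(LDA) strictly exceeds the threshold
    AND p < alpha in that comparison; the sign is the direction of change.
    Rows are ordered by how many comparisons pass, descending, then name.
    """
    cols = {}
    for res in results:
        st = res.stats
        mask = (st["lda_log10"] > lda_threshold) & (st["p"] < alpha)
        signed = np.sign(st["log2fc"]) * st["lda_log10"]
        cols[res.comparison_id] = signed.where(mask)
    frame = pd.DataFrame(cols)
    frame = frame.dropna(how="all")
    if len(frame):
        n_pass = frame.notna().sum(axis=1).to_numpy()
        frame = frame.iloc[np.lexsort((frame.index.to_numpy(), -n_pass))]
    return frame


def stratified_consistency(
    results_by_stratum: dict[str, list[ComparisonResult]],
    min_projects: int = 3,
    min_abs_cs: float = 0.6,
    denominator: str = "significant",
) -> pd.DataFrame:
    """CS per stratum (phenotype or intervention) for generalization checks.

    CS is computed independently within each stratum; a feature is
    reported if it passes the selection rule in at least one stratum. The
    ``concordant`` column flags features whose selected strata agree in
    sign.
    """
    strata = {k: v for k, v in results_by_stratum.items() if v}
    dropped = set(results_by_stratum) - set(strata)
    for name in sorted(dropped):
        logger.warning("stratum %r has no comparisons; dropped", name)
    if len(strata) < 2:
        raise ValidationError("stratified consistency needs >=2 nonempty strata")
    per_stratum = {
        name: {r.feature: r for r in consistency_table(res, denominator)}
        for name, res in strata.items()
    }
    selected_any: dict[str, set[str]] = {}
    for name, res in strata.items():
        recs = select_consistent(
            list(per_stratum[name].values()), min_projects, min_abs_cs
        )
        for r in recs:
            selected_any.setdefault(r.feature, set()).add(name)
    rows = []
    for feature in sorted(selected_any):
        row: dict = {"feature": feature}
        signs = []
        for name in sorted(strata):
            rec = per_stratum[name].get(feature)
            row[f"CS_{name}"] = rec.cs if rec is not None else np.nan
            row[f"selected_{name}"] = name in selected_any[feature]
            if name in selected_any[feature] and rec is not None:
                signs.append(np.sign(rec.cs))
        row["concordant"] = bool(signs) and len(set(signs)) == 1
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame()


def sankey_edges(
    selected: list[ConsistencyRecord], tax: TaxonomyMap, to_rank: str = "genus"
) -> pd.DataFrame:
    """Lineage-level edge list (level, parent, child, weight) for the
    selected features, weight = count of selected features under the edge."""
    upto = RANKS.index(to_rank) + 1
    counts: dict[tuple[str, str, str], int] = {}
    for rec in selected:
        lin = tax.get(rec.feature)
        if lin is None:
            continue
        levels = [v for v in lin.levels[:upto]]
        for i in range(1, upto):
            parent, child = levels[i - 1], levels[i]
            if not parent or not child:
                continue
            key = (f"{RANKS[i - 1]}->{RANKS[i]}", parent, child)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"level": k[0], "source": k[1], "target": k[2], "weight": v}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["level", "source", "target", "weight"])
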