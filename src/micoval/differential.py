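"""Per-comparison differential-abundance statistics.

Rank tests (Kruskal-Wallis, Wilcoxon rank-sum), log2 fold changes,
Benjamini-Hochberg correction, and a single-level LEfSe-style bootstrapped
LDA effect size. The same machinery is applied to taxonomic tables and to
functional (KO / pathway) abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import ComparisonDesign, FeatureTable, SampleMetadata, ValidationError, design_samples

# full enumeration of labelings stays cheap up to this combined sample size
_TIE_ENUMERATION_LIMIT = 12


@dataclass
class ComparisonResult:
    """Per-feature statistics for one case-vs-control comparison.

    ``stats`` is indexed by feature with columns mean_case, mean_control,
    log2fc, p, q, significant, direction (up = higher in case) and an
    optional lda_log10 (LEfSe-style effect-size magnitude).
    """

    design: ComparisonDesign
    stats: pd.DataFrame
    method: str = "kw"
    alpha: float = 0.05
    use_fdr: bool = False

    @property
    def comparison_id(self) -> str:
        return self.design.comparison_id

    def significant_features(self) -> list[str]:
        return self.stats.index[self.stats["significant"]].tolist()


def kruskal_wallis_scan(table: FeatureTable, groups) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H and chi-square p per feature.

    Constant features get H = 0, p = 1 and a ``constant`` flag instead of
    an error.
    """
    labels = np.asarray(pd.Series(list(groups)).astype(str))
    if len(labels) != table.n_samples:
        raise ValidationError("group labels must match table samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValidationError("Kruskal-Wallis needs >=2 groups with >=2 samples each")
    masks = [labels == g for g in uniq]
    out = []
    for fid in table.feature_ids:
        row = table.data.loc[fid].to_numpy(dtype=float)
        if np.ptp(row) == 0:
            out.append({"feature": fid, "H": 0.0, "p": 1.0, "constant": True})
            continue
        h, p = stats.kruskal(*[row[m] for m in masks])
        out.append({"feature": fid, "H": float(h), "p": float(p), "constant": False})
    return pd.DataFrame(out).set_index("feature")


def wilcoxon_rank_sum(x, y, exact_threshold: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test -> (U, p).

    Tie-free samples with both sizes <= ``exact_threshold`` use the exact
    null distribution. Tied small samples (combined size <= 12) fall back
    to full enumeration of labelings with the symmetric two-sided
    criterion |U - mn/2| >= |U_obs - mn/2|; anything larger uses the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    m, n = x.size, y.size
    if not has_ties and m <= exact_threshold and n <= exact_threshold:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if has_ties and m + n <= _TIE_ENUMERATION_LIMIT:
        return _enumerated_u_test(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)


def _enumerated_u_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    mu = m * n / 2
    u_obs = _u_statistic(x, y)
    dev_obs = abs(u_obs - mu)
    total = comb(m + n, m)
    extreme = 0
    idx = np.arange(m + n)
    for chosen in combinations(idx, m):
        sel = np.zeros(m + n, dtype=bool)
        sel[list(chosen)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mu) >= dev_obs - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def log2_fold_change(mean_case: float, mean_control: float) -> float:
    """log2(mean_case / mean_control); both means must be positive."""
    if mean_case <= 0 or mean_control <= 0:
        raise ValidationError(
            "fold change needs positive means; run impute_zeros first"
        )
    return float(np.log2(mean_case / mean_control))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# LEfSe-style LDA effect size


def lda_effect_size(
    table: FeatureTable,
    groups,
    case_label: str,
    control_label: str,
    alpha: float = 0.05,
    n_boot: int = 30,
    boot_fraction: float = 2 / 3,
    seed: int = 0,
) -> pd.Series:
    """Single-level LEfSe-style effect sizes for a two-class comparison.

    Relative abundances are scaled to parts-per-million; features passing
    a Kruskal-Wallis gate at ``alpha`` enter ``n_boot`` bootstrapped
    two-class LDAs on ``boot_fraction`` of each group. The per-feature
    effect is the bootstrap mean of (|w_f| * axis separation +
    |mean_case_f - mean_control_f|) / 2 with w the unit LDA direction, and
    the reported score is its log10 (floored at 1 before the log, the
    LEfSe convention). Features failing the gate get no score (NaN).
    """
    labels = np.asarray(pd.Series(list(groups)).astype(str))
    case_mask = labels == case_label
    ctrl_mask = labels == control_label
    if case_mask.sum() < 3 or ctrl_mask.sum() < 3:
        raise ValidationError("LEfSe bootstrap needs >=3 samples per group")
    used = case_mask | ctrl_mask
    sub = table.data.loc[:, table.data.columns[used]]
    labels = labels[used]
    case_mask = labels == case_label

    gate = kruskal_wallis_scan(
        FeatureTable(sub, units=table.units, rank=table.rank), labels
    )
    passing = gate.index[gate["p"] < alpha].tolist()
    scores = pd.Series(np.nan, index=table.data.index, name="lda_log10")
    if not passing:
        return scores

    x = sub.loc[passing].to_numpy(dtype=float).T * 1e6  # samples x features, ppm
    y = case_mask.astype(int)
    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    n_case = max(2, int(round(boot_fraction * idx_case.size)))
    n_ctrl = max(2, int(round(boot_fraction * idx_ctrl.size)))

    effects = np.zeros(len(passing))
    used_boots = 0
    for _ in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_case, size=n_case, replace=False),
                rng.choice(idx_ctrl, size=n_ctrl, replace=False),
            ]
        )
        xb, yb = x[take], y[take]
        try:
            lda = LinearDiscriminantAnalysis(solver="svd", tol=1e-10)
            lda.fit(xb, yb)
        except np.linalg.LinAlgError:  # degenerate bootstrap draw
            continue
        w = lda.coef_.ravel()
        norm = np.linalg.norm(w)
        if norm == 0:
            continue
        w = w / norm
        proj = xb @ w
        separation = abs(proj[yb == 1].mean() - proj[yb == 0].mean())
        mean_diff = np.abs(xb[yb == 1].mean(axis=0) - xb[yb == 0].mean(axis=0))
        effects += (np.abs(w) * separation + mean_diff) / 2
        used_boots += 1
    if used_boots == 0:
        return scores
    effects /= used_boots
    scores.loc[passing] = np.log10(np.maximum(effects, 1.0))
    return scores


# ---------------------------------------------------------------------------
# assembled per-comparison result


def compare_features(
    table: FeatureTable,
    design: ComparisonDesign,
    meta: SampleMetadata,
    method: str = "kw",
    alpha: float = 0.05,
    use_fdr: bool = False,
    lda_threshold: float = 2.0,
    seed: int = 0,
) -> ComparisonResult:
    """Run one two-group comparison over all features of a table.

    ``method`` selects the p-value engine: ``kw`` (Kruskal-Wallis, the
    default), ``wilcoxon`` (rank-sum), or ``lefse`` (Wilcoxon gate plus
    bootstrapped LDA; significance then additionally requires
    log10(LDA) > ``lda_threshold``). Direction is the sign of the log2
    fold change of arithmetic group means; significance uses raw p by
    default, or BH q when ``use_fdr``.
    """
    if method not in ("kw", "wilcoxon", "lefse"):
        raise ValidationError(f"unknown method {method!r}")
    case_ids, control_ids = design_samples(design, meta)
    case = table.data.loc[:, case_ids].to_numpy(dtype=float)
    control = table.data.loc[:, control_ids].to_numpy(dtype=float)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)

    pvals = np.ones(table.n_features)
    for i in range(table.n_features):
        xc, xk = case[i], control[i]
        if np.ptp(np.concatenate([xc, xk])) == 0:
            pvals[i] = 1.0
        elif method == "kw":
            _, pvals[i] = stats.kruskal(xc, xk)
        else:
            _, pvals[i] = wilcoxon_rank_sum(xc, xk)
    qvals = bh_adjust(pvals)

    log2fc = np.full(table.n_features, np.nan)
    ok = (mean_case > 0) & (mean_control > 0)
    log2fc[ok] = np.log2(mean_case[ok] / mean_control[ok])
    direction = np.where(log2fc > 0, "up", "down")

    crit = qvals if use_fdr else pvals
    significant = crit <= alpha

    frame = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "significant": significant,
            "direction": direction,
        },
        index=table.data.index,
    )

    if method == "lefse":
        sub_ids = case_ids + control_ids
        sub = FeatureTable(
            table.data.loc[:, sub_ids], units=table.units, rank=table.rank
        )
        groups = meta.groups_for(sub_ids)
        lda = lda_effect_size(
            sub,
            groups,
            case_label=design.case_group,
            control_label=design.control_group,
            alpha=alpha,
            seed=seed,
        )
        frame["lda_log10"] = lda
        frame["significant"] = (
            frame["significant"] & (lda > lda_threshold).fillna(False)
        )
    else:
        frame["lda_log10"] = np.nan

    # features with a zero-mean side carry no usable fold change
    frame.loc[~np.isfinite(frame["log2fc"]), "significant"] = False

    return ComparisonResult(
        design=design, stats=frame, method=method, alpha=alpha, use_fdr=use_fdr
    )


def write_comparison(result: ComparisonResult, path) -> None:
    out = result.stats.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format="%.8g")
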