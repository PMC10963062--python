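"""Alpha diversity, the Firmicutes/Bacteroidetes ratio, beta diversity,
ordination (PCoA, NMDS) and the ANOSIM permutation test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

from .io import FeatureTable, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    frame: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        m = self.frame.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValidationError("distances must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


# ---------------------------------------------------------------------------
# alpha diversity


def _as_probs(column: np.ndarray) -> np.ndarray:
    p = np.asarray(column, dtype=float)
    if (p < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    return p / total


def shannon_index(column: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (natural log) over positive entries."""
    p = _as_probs(column)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson_index(column: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p^2 (larger = more diverse)."""
    p = _as_probs(column)
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: FeatureTable, base: str = "e") -> pd.DataFrame:
    """Per-sample Shannon and (Gini-)Simpson indices.

    ``base="2"`` reports Shannon in bits instead of nats.
    """
    rows = []
    scale = np.log(2) if base == "2" else 1.0
    for sample in table.sample_ids:
        col = table.data[sample].to_numpy()
        rows.append(
            {
                "sample_id": sample,
                "shannon": shannon_index(col) / scale,
                "simpson": simpson_index(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def fb_ratio(
    table: FeatureTable,
    firmicutes: str = "Firmicutes",
    bacteroidetes: str = "Bacteroidetes",
) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidetes abundance ratio.

    Expects a phylum-rank table whose row ids carry the configured phylum
    names exactly (no synonym matching — "Bacteroidota" is not
    "Bacteroidetes").
    """
    for name in (firmicutes, bacteroidetes):
        if name not in table.data.index:
            raise ValidationError(f"phylum row {name!r} missing from table")
    f = table.data.loc[firmicutes]
    b = table.data.loc[bacteroidetes]
    if (b <= 0).any():
        bad = b.index[b <= 0].tolist()
        raise ValidationError(
            f"zero Bacteroidetes abundance in samples {bad}; impute zeros first"
        )
    return (f / b).rename("fb_ratio")


# ---------------------------------------------------------------------------
# beta diversity


def beta_distance(table: FeatureTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Bray-Curtis (abundance) or Jaccard (presence/absence) distances.

    Jaccard uses presence = abundance > 0 and should therefore be computed
    on the table before zero imputation.
    """
    if table.n_samples < 2:
        raise ValidationError("beta diversity needs at least two samples")
    x = table.data.to_numpy(dtype=float).T  # samples x features
    if metric == "bray_curtis":
        condensed = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        condensed = pdist(x > 0, metric="jaccard")
    else:
        raise ValidationError(f"unknown beta-diversity metric {metric!r}")
    condensed = np.nan_to_num(condensed, nan=0.0)
    frame = pd.DataFrame(
        squareform(condensed), index=table.sample_ids, columns=table.sample_ids
    )
    return DistanceMatrix(frame, metric=metric)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    negative_eigenvalue_magnitude: float | None = None
    stress: float | None = None
    converged: bool = True


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers the squared distance matrix, eigendecomposes it, and
    returns the top-``k`` axes with positive eigenvalues scaled by
    sqrt(eigenvalue). Negative eigenvalues (non-Euclidean distances) are
    dropped; their summed magnitude is reported.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    neg_mag = float(-eigvals[eigvals < -tol].sum())
    n_pos = int(positive.sum())
    k_eff = min(k, n_pos)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    total = eigvals[positive].sum()
    prop = eigvals[:k_eff] / total if total > 0 else np.zeros(k_eff)
    frame = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(k_eff)],
    )
    return OrdinationResult(
        coordinates=frame,
        eigenvalues=eigvals[:k_eff],
        proportion_explained=np.asarray(prop),
        negative_eigenvalue_magnitude=neg_mag,
    )


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 by SMACOF majorization.

    Runs ``restarts`` seeded random initializations and keeps the
    best-stress embedding; stress lies in [0, 1].
    """
    n = dm.values.shape[0]
    if n < k + 1:
        raise ValidationError("NMDS needs at least k+1 samples")
    kwargs = dict(
        n_components=k,
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
    )
    try:  # scikit-learn >= 1.9 signature
        model = MDS(
            metric="precomputed", metric_mds=False, init="random", **kwargs
        )
    except TypeError:  # older signature
        model = MDS(metric=False, dissimilarity="precomputed", **kwargs)
    coords = model.fit_transform(dm.values)
    frame = pd.DataFrame(
        coords, index=dm.sample_ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=frame,
        stress=float(model.stress_),
        converged=model.n_iter_ < max_iter,
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    r: float
    p: float
    permutations: int
    seed: int


def anosim(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2) with M = n(n-1)/2 pairwise distances, ranked with
    average ties. The p-value is the permutation probability
    (1 + #{R_perm >= R_obs}) / (permutations + 1) under random relabeling.
    """
    labels = np.asarray(pd.Series(list(groups)).astype(str))
    n = dm.values.shape[0]
    if len(labels) != n:
        raise ValidationError("group labels must match distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValidationError(f"ANOSIM groups need >=2 samples each: {small}")
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dm.values[iu, ju])
    m = ranks.size

    def _r(lbl: np.ndarray) -> float:
        within = lbl[iu] == lbl[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    r_obs = _r(labels)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(permutations):
        if _r(rng.permutation(labels)) >= r_obs:
            count_ge += 1
    p = (1 + count_ge) / (permutations + 1)
    return AnosimResult(r=float(r_obs), p=float(p), permutations=permutations, seed=seed)
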