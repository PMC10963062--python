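"""Seeded multi-project case/control microbiome simulator.

Emulates the structure of curated multi-study collections: several
projects share a taxon namespace but have project-specific baseline
compositions (batch effects), and selected taxa carry planted
directional fold changes in the case group. Counts follow a
Dirichlet-multinomial: per-sample compositions are Dirichlet draws
around the project baseline and reads are multinomial at negative-
binomial library sizes. The planted truth is returned alongside the
data so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    FeatureTable,
    Lineage,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)

PHYLA = (
    ("Firmicutes", 0.40),
    ("Bacteroidetes", 0.30),
    ("Proteobacteria", 0.15),
    ("Actinobacteria", 0.10),
    ("Verrucomicrobia", 0.05),
)


@dataclass(frozen=True)
class PlantedEffect:
    """One taxon's planted per-project direction pattern.

    ``signs`` has one entry per project: +1 (up in case), -1 (down in
    case) or 0 (no effect in that project); ``log2fc`` is the common
    effect magnitude.
    """

    taxon: str
    signs: tuple[int, ...]
    log2fc: float

    def __post_init__(self) -> None:
        if self.log2fc <= 0:
            raise ValidationError("planted |log2FC| must be positive")
        if any(s not in (-1, 0, 1) for s in self.signs):
            raise ValidationError("signs must be -1, 0 or +1")


@dataclass
class SimulationSpec:
    """Study conditions for a multi-project simulation.

    Defaults emulate a moderate rodent/human cohort collection: 6
    projects of 20 case + 20 control samples, 60 taxa with a skewed
    baseline, ~20k reads per sample with overdispersed library sizes,
    moderate compositional noise (Dirichlet concentration 50 around the
    project baseline) and mild project-to-project baseline variation
    (concentration 200 around the global base).
    """

    n_projects: int = 6
    n_taxa: int = 60
    samples_per_group: int = 20
    depth_mean: float = 20000.0
    depth_dispersion: float = 5.0
    concentration: float = 50.0
    base_concentration: float = 200.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    phenotypes: list[str] = field(default_factory=list)  # one per project
    interventions: list[str] = field(default_factory=list)
    case_group: str = "case"
    control_group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean < 100:
            raise ValidationError("depth_mean below 100 yields degenerate tables")
        if self.n_taxa < 2 or self.n_projects < 1 or self.samples_per_group < 2:
            raise ValidationError("degenerate simulation dimensions")
        taxa = set(self.taxon_names())
        for eff in self.planted_effects:
            if eff.taxon not in taxa:
                raise ValidationError(f"planted taxon {eff.taxon!r} not in namespace")
            if len(eff.signs) != self.n_projects:
                raise ValidationError(
                    f"{eff.taxon}: need one sign per project ({self.n_projects})"
                )

    def taxon_names(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"Taxon_{i + 1:0{width}d}" for i in range(self.n_taxa)]


def global_base(spec: SimulationSpec) -> np.ndarray:
    """Skewed global baseline composition, sorted so Taxon_1 is the most
    abundant (log-normal abundance spectrum)."""
    rng = np.random.default_rng([spec.seed, 101])
    raw = np.exp(rng.normal(0.0, 1.25, size=spec.n_taxa))
    raw = np.sort(raw)[::-1]
    return raw / raw.sum()


def taxonomy_for(spec: SimulationSpec) -> TaxonomyMap:
    """Seeded lineage assignment over five phyla; genus = taxon name."""
    rng = np.random.default_rng([spec.seed, 202])
    names = [p for p, _ in PHYLA]
    probs = np.array([w for _, w in PHYLA])
    tax = TaxonomyMap()
    for i, taxon in enumerate(spec.taxon_names()):
        phylum = names[rng.choice(len(names), p=probs)]
        tax.lineages[taxon] = Lineage(
            (
                "Bacteria",
                phylum,
                f"{phylum}_class",
                f"{phylum}_order",
                f"{phylum}_family_{i % 3 + 1}",
                taxon,
                "",
            )
        )
    return tax


def _sample_block(
    rng: np.random.Generator,
    base: np.ndarray,
    n_samples: int,
    spec: SimulationSpec,
) -> np.ndarray:
    """Dirichlet-multinomial counts (taxa x samples) around ``base``."""
    alpha = np.maximum(spec.concentration * base, 1e-6)
    k = spec.depth_dispersion
    depths = rng.negative_binomial(k, k / (k + spec.depth_mean), size=n_samples)
    depths = np.maximum(depths, 100)
    out = np.zeros((base.size, n_samples))
    for s in range(n_samples):
        comp = rng.dirichlet(alpha)
        out[:, s] = rng.multinomial(depths[s], comp)
    return out


def simulate_project(
    spec: SimulationSpec, project_index: int
) -> tuple[FeatureTable, SampleMetadata]:
    """One project's count table and metadata, deterministic in
    (spec.seed, project_index)."""
    if not 0 <= project_index < spec.n_projects:
        raise ValidationError("project_index out of range")
    rng = np.random.default_rng([spec.seed, 303, project_index])
    base0 = global_base(spec)
    project_base = rng.dirichlet(np.maximum(spec.base_concentration * base0, 1e-6))
    project_base = np.maximum(project_base, 1e-9)
    project_base = project_base / project_base.sum()

    multiplier = np.ones(spec.n_taxa)
    names = spec.taxon_names()
    index_of = {t: i for i, t in enumerate(names)}
    for eff in spec.planted_effects:
        sign = eff.signs[project_index]
        if sign:
            multiplier[index_of[eff.taxon]] = 2.0 ** (sign * eff.log2fc)
    case_base = project_base * multiplier
    case_base = case_base / case_base.sum()

    n = spec.samples_per_group
    control = _sample_block(rng, project_base, n, spec)
    case = _sample_block(rng, case_base, n, spec)
    project = f"P{project_index + 1}"
    case_ids = [f"{project}_case_{s + 1:02d}" for s in range(n)]
    ctrl_ids = [f"{project}_ctrl_{s + 1:02d}" for s in range(n)]
    data = pd.DataFrame(
        np.hstack([case, control]),
        index=pd.Index(names, name="feature_id"),
        columns=case_ids + ctrl_ids,
    )
    phenotype = spec.phenotypes[project_index] if spec.phenotypes else "obesity"
    intervention = spec.interventions[project_index] if spec.interventions else ""
    meta = pd.DataFrame(
        {
            "group": [spec.case_group] * n + [spec.control_group] * n,
            "project": project,
            "phenotype": phenotype,
            "intervention": intervention,
            "role": ["case"] * n + ["control"] * n,
        },
        index=pd.Index(case_ids + ctrl_ids, name="sample_id"),
    )
    return FeatureTable(data, units="counts"), SampleMetadata(meta)


def simulate_multiproject(
    spec: SimulationSpec,
) -> tuple[list[tuple[FeatureTable, SampleMetadata]], pd.DataFrame]:
    """All projects plus the planted-truth table.

    The truth table has one row per (taxon, project) with a nonzero
    planted sign: columns taxon, project, sign, log2fc.
    """
    datasets = [simulate_project(spec, j) for j in range(spec.n_projects)]
    rows = []
    for eff in spec.planted_effects:
        for j, sign in enumerate(eff.signs):
            if sign:
                rows.append(
                    {
                        "taxon": eff.taxon,
                        "project": f"P{j + 1}",
                        "sign": sign,
                        "log2fc": eff.log2fc,
                    }
                )
    truth = pd.DataFrame(rows, columns=["taxon", "project", "sign", "log2fc"])
    return datasets, truth


def mass_balanced_effects(
    seed: int,
    n_taxa: int,
    n_projects: int,
    n_up: int = 4,
    n_down: int = 4,
    log2fc: float = 1.5,
    down_start_rank: int = 2,
) -> list[PlantedEffect]:
    """Consistent up/down effects whose planted mass change cancels.

    Multiplying planted taxa by 2^(sign*log2fc) and renormalizing shifts
    every unplanted taxon by the inverse of the total mass change; if the
    planted sets are not balanced this spillover is directional and
    consistent across projects, making null taxa look like biomarkers.
    Choosing the up set so that up_mass = down_mass / 2^log2fc cancels
    the shift in expectation, so unplanted taxa stay null.

    Down-regulated taxa are taken from abundance ranks starting at
    ``down_start_rank`` (0-based on the sorted baseline); up-regulated
    taxa are then picked greedily from the remaining spectrum to match
    the target mass.
    """
    probe = SimulationSpec(
        n_projects=n_projects, n_taxa=n_taxa, samples_per_group=2, seed=seed
    )
    base = global_base(probe)
    names = probe.taxon_names()
    m = 2.0**log2fc
    down_idx = list(range(down_start_rank, down_start_rank + n_down))
    target = base[down_idx].sum() * (1 - 1 / m) / (m - 1)
    remaining = [i for i in range(n_taxa) if i not in down_idx]
    up_idx: list[int] = []
    for _ in range(n_up):
        slots_left = n_up - len(up_idx)
        want = (target - base[up_idx].sum()) / slots_left
        pick = min(
            (i for i in remaining if i not in up_idx),
            key=lambda i: abs(base[i] - want),
        )
        up_idx.append(pick)
    return consistent_effects(
        [names[i] for i in up_idx], [names[i] for i in down_idx], n_projects, log2fc
    )


def consistent_effects(
    taxa_up: list[str], taxa_down: list[str], n_projects: int, log2fc: float = 1.5
) -> list[PlantedEffect]:
    """Effects planted in every project: up for ``taxa_up``, down for
    ``taxa_down`` (the consistent-biomarker scenario)."""
    ups = [
        PlantedEffect(t, tuple([1] * n_projects), log2fc) for t in taxa_up
    ]
    downs = [
        PlantedEffect(t, tuple([-1] * n_projects), log2fc) for t in taxa_down
    ]
    return ups + downs
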