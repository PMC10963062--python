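import numpy as np
import pandas as pd
import pytest

from micoval.differential import ComparisonResult
from micoval.io import ComparisonDesign, FeatureTable, Lineage, SampleMetadata, TaxonomyMap


@pytest.fixture
def count_table():
    """4 features x 3 samples of integer counts."""
    data = pd.DataFrame(
        [[10, 0, 5], [0, 20, 5], [30, 40, 5], [0, 0, 0]],
        index=["f1", "f2", "f3", "f4"],
        columns=["s1", "s2", "s3"],
        dtype=float,
    )
    return FeatureTable(data, units="counts")


@pytest.fixture
def taxonomy():
    return TaxonomyMap(
        {
            "f1": Lineage(("Bacteria", "Firmicutes", "", "", "", "GenusA", "")),
            "f2": Lineage(("Bacteria", "Firmicutes", "", "", "", "GenusB", "")),
            "f3": Lineage(("Bacteria", "Bacteroidetes", "", "", "", "GenusC", "")),
            # f4 intentionally unannotated
        }
    )


@pytest.fixture
def two_group_meta():
    frame = pd.DataFrame(
        {
            "group": ["case", "case", "case", "control", "control", "control"],
            "project": "P1",
            "phenotype": "obesity",
            "intervention": "",
            "role": ["case"] * 3 + ["control"] * 3,
        },
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
    )
    return SampleMetadata(frame)


def make_design(comparison_id="P1:case_vs_control", project="P1", **kw):
    return ComparisonDesign(
        comparison_id=comparison_id,
        project=project,
        case_group=kw.get("case_group", "case"),
        control_group=kw.get("control_group", "control"),
        phenotype=kw.get("phenotype", ""),
        intervention=kw.get("intervention", ""),
    )


def make_result(comparison_id, entries, project=None, **design_kw):
    """Fabricate a ComparisonResult from {feature: (log2fc, p, significant)}.

    ``lda`` may be appended as a 4th tuple entry.
    """
    project = project or comparison_id.split(":")[0]
    rows = {}
    for feature, entry in entries.items():
        log2fc, p, significant = entry[:3]
        lda = entry[3] if len(entry) > 3 else np.nan
        rows[feature] = {
            "mean_case": 2.0**log2fc,
            "mean_control": 1.0,
            "log2fc": log2fc,
            "p": p,
            "q": p,
            "significant": significant,
            "direction": "up" if log2fc > 0 else "down",
            "lda_log10": lda,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "feature"
    return ComparisonResult(
        design=make_design(comparison_id, project, **design_kw), stats=frame
    )
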