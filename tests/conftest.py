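import numpy as np
import pandas as pd
import pytest

from renomark import biomarker, diffexpr, synthetic


@pytest.fixture(scope="session")
def catalogue() -> biomarker.MarkerCatalogue:
    return biomarker.MarkerCatalogue.load()


@pytest.fixture(scope="session")
def regulator_map() -> biomarker.RegulatorMap:
    return biomarker.RegulatorMap.load()


@pytest.fixture(scope="session")
def geometry() -> synthetic.FrameGeometry:
    return synthetic.FrameGeometry()


@pytest.fixture(scope="session")
def roi_seeds(geometry):
    """Truth seed pixels for the default scene layout."""
    return {
        "kidneys": tuple((int(r), int(c)) for r, c in geometry.kidney_centers),
        "bladder": (int(geometry.bladder_center[0]), int(geometry.bladder_center[1])),
        "syringe": (
            (geometry.syringe_rows[0] + geometry.syringe_rows[1]) // 2,
            (geometry.syringe_cols[0] + geometry.syringe_cols[1]) // 2,
        ),
    }


def make_expression_set(
    gene_values: dict[str, dict[str, list[float]]],
    tissue: str = "cortex",
    timepoint: float = 12.0,
) -> diffexpr.ExpressionSet:
    """Tiny ExpressionSet from {gene: {group_label: replicate values}}.

    Group labels are "control" or an activity in MBq as a string.
    """
    genes = sorted(gene_values)
    groups = sorted({g for v in gene_values.values() for g in v})
    cols, meta = [], []
    for grp in groups:
        act = 0.0 if grp == "control" else float(grp)
        n = len(next(iter(gene_values.values()))[grp])
        for r in range(n):
            cols.append([gene_values[g][grp][r] for g in genes])
            meta.append(
                {
                    "sample_id": f"{grp}_{r}",
                    "tissue": tissue,
                    "timepoint_months": timepoint,
                    "activity_MBq": act,
                    "replicate": r,
                }
            )
    return diffexpr.ExpressionSet(genes, np.array(cols).T, pd.DataFrame(meta))
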