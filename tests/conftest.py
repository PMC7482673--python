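import numpy as np
import pandas as pd
import pytest

from phenoplast.expression_io import ExpressionTable
from phenoplast.features import FeatureSpec, FeatureTable


def make_table(values, proteins, metadata=None, metadata_fields=None) -> ExpressionTable:
    """Build an ExpressionTable from a value matrix and optional metadata dict."""
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(values, columns=proteins)
    fields = []
    if metadata:
        for name, col in metadata.items():
            data.insert(len(fields), name, [str(v) for v in col])
            fields.append(name)
    return ExpressionTable(
        data=data,
        protein_names=list(proteins),
        metadata_fields=metadata_fields or fields,
    )


def make_feature_table(values, names, groups=None, kinds=None) -> FeatureTable:
    """Build a FeatureTable directly from a value matrix (for stage tests)."""
    values = np.asarray(values, dtype=float)
    kinds = kinds or ["sum"] * values.shape[1]
    specs = []
    for j, (name, kind) in enumerate(zip(names, kinds)):
        if kind == "sum":
            specs.append(FeatureSpec(name=name, kind="sum", numerator=(f"p{j}",)))
        else:
            specs.append(
                FeatureSpec(name=name, kind="index", numerator=(f"p{j}a",),
                            denominator=(f"p{j}b",))
            )
    data = pd.DataFrame(values, columns=names)
    fields = []
    if groups is not None:
        data.insert(0, "condition", [str(g) for g in groups])
        fields = ["condition"]
    return FeatureTable(data=data, specs=specs, metadata_fields=fields)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
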