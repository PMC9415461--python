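"""Packaged reference data.

The package ships the published 4-condition (Control, PTX, CLC, VBL)
dominant-Fourier feature table — 11 amplitudes and 11 phases per
condition after the authors' scaling — as a verbatim fixture.  It is the
worked example for condition correlation and mode-of-action clustering.
Note the printed columns are *not* exactly zero-mean/unit-variance under
any single obvious scaling, so the fixture is loaded with
``normalized=False`` and downstream correlation re-standardizes columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fft_profiler import FEATURE_COLUMNS, FeatureMatrix
from .params import LABEL_TO_KEY, PARAM_LABELS

_FIXTURE = "table2_fixture.csv"
_FACTORS = {"amplitude": "amp", "phase": "phase"}


def _fixture_path():
    return resources.files("phenofft.data").joinpath(_FIXTURE)


def load_reference_features() -> FeatureMatrix:
    """The packaged published feature table as a 4 × 22 FeatureMatrix."""
    with resources.as_file(_fixture_path()) as path:
        long = pd.read_csv(path)
    conditions = list(dict.fromkeys(long["sample"]))
    data = pd.DataFrame(index=pd.Index(conditions, name="condition"),
                        columns=list(FEATURE_COLUMNS), dtype=float)
    for _, row in long.iterrows():
        prefix = _FACTORS[row["factor"]]
        for label, key in LABEL_TO_KEY.items():
            data.loc[row["sample"], f"{prefix}_{key}"] = row[label]
    return FeatureMatrix(data=data, normalized=False)


def export_reference_features(matrix: FeatureMatrix) -> str:
    """Re-serialize a feature matrix in the fixture's printed layout.

    Loading the fixture and exporting it reproduces the packaged file
    byte for byte (two-decimal fixed-point, amplitude block first).
    """
    labels = [PARAM_LABELS[k] for k in LABEL_TO_KEY.values()]
    lines = ["factor,sample," + ",".join(labels)]
    for factor, prefix in _FACTORS.items():
        for cond in matrix.conditions:
            vals = [f"{matrix.data.loc[cond, f'{prefix}_{key}']:.2f}"
                    for key in LABEL_TO_KEY.values()]
            lines.append(f"{factor},{cond}," + ",".join(vals))
    return "\n".join(lines) + "\n"


def reference_fixture_text() -> str:
    """Raw text of the packaged fixture file."""
    return _fixture_path().read_text()
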