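"""Registry of the 11 phenotypic parameters.

The pipeline tracks eleven per-cell metrics derived from label-free
quantitative phase images, split into two subtypes: cell morphology
(area, area fraction of the field, perimeter, form factor, extent,
compactness, eccentricity) and cell composition (mean refractive index,
average dry mass density, dry mass, granularity).  Column order below is
canonical everywhere: records tables, condition series, and the
22-column FFT feature matrix (11 amplitudes then 11 phases).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Parameter:
    """One phenotypic parameter: canonical key, short plot label, units,
    calibration range (the population-mean band the simulator is held to),
    and the hard physical domain values are clipped to per cell."""

    key: str
    label: str
    units: str
    range_low: float
    range_high: float
    domain_low: float
    domain_high: float


#: The 11 parameters in canonical order.  Calibration ranges follow the
#: published axis ranges of the per-parameter time-series panels.
PARAMETERS: tuple[Parameter, ...] = (
    Parameter("area", "A", "um^2", 0.0, 1000.0, 1e-6, float("inf")),
    Parameter("area_pct", "A%", "%", 0.4, 2.0, 1e-9, 100.0),
    Parameter("perimeter", "P", "um", 50.0, 400.0, 1e-6, float("inf")),
    Parameter("form_factor", "FF", "", 0.0, 0.8, 1e-6, 1.05),
    Parameter("extent", "EX", "", 0.4, 0.8, 1e-6, 1.0),
    Parameter("compactness", "C", "", 0.0, 15.0, 1e-6, float("inf")),
    Parameter("eccentricity", "EC", "", 0.2, 1.0, 0.0, 1.0),
    Parameter("mean_ri", "RI", "", 1.34, 1.37, 1.0, 1.6),
    Parameter("dry_mass_density", "DMD", "pg/um^3", 0.05, 0.2, 1e-9, float("inf")),
    Parameter("dry_mass", "DM", "pg", 80.0, 250.0, 1e-9, float("inf")),
    Parameter("granularity", "G", "", 5.0, 15.0, 0.0, float("inf")),
)

PARAM_KEYS: tuple[str, ...] = tuple(p.key for p in PARAMETERS)
PARAM_LABELS: dict[str, str] = {p.key: p.label for p in PARAMETERS}
LABEL_TO_KEY: dict[str, str] = {p.label: p.key for p in PARAMETERS}

#: Calibration ranges keyed by parameter, (low, high).
CALIBRATION_RANGES: dict[str, tuple[float, float]] = {
    p.key: (p.range_low, p.range_high) for p in PARAMETERS
}

#: Non-parameter columns of the canonical long records table.
RECORD_META_COLUMNS: tuple[str, ...] = ("condition", "cell_id", "cycle", "alive")
RECORD_COLUMNS: tuple[str, ...] = RECORD_META_COLUMNS + PARAM_KEYS


def parameter(key: str) -> Parameter:
    """Look up a parameter by canonical key or short label."""
    key = LABEL_TO_KEY.get(key, key)
    for p in PARAMETERS:
        if p.key == key:
            return p
    raise KeyError(f"unknown phenotypic parameter: {key!r}")
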