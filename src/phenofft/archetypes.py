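"""Mode-of-action archetypes: parameterized population dynamics.

An archetype encodes how a treatment condition evolves over the imaging
run: a piecewise-linear mean trajectory per phenotypic parameter, the
magnitude of cell-to-cell heterogeneity, the autocorrelated measurement
noise, and the event model (mitotic-arrest onset, death hazard,
division rate).

Three built-in archetypes cover the classes of microtubule-targeting
agents studied with this pipeline:

``control``
    Untreated, proliferating cells: slow growth in area and dry mass,
    occasional divisions, stable shape.
``stabilizer``
    A microtubule stabilizer (paclitaxel-like): cells keep spreading
    until mitotic arrest at ~10 h, then round up — form factor rises,
    eccentricity and perimeter fall; dry mass density declines through
    the first half of the run.
``disruptor``
    A microtubule disruptor (colchicine/vinblastine-like): rapid
    contraction within ~2 h (area down >20%), rising dry mass density
    with a late fall, late-onset necrotic cell loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError
from .params import CALIBRATION_RANGES, PARAM_KEYS

Knots = list[tuple[int, float]]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One mode-of-action archetype.

    ``trajectories`` maps each of the 11 parameter keys to a sorted list
    of (cycle, value) knots; the population mean follows the piecewise
    linear interpolant (held flat beyond the outer knots).  Per-cell
    heterogeneity is a lognormal multiplicative effect of scale
    ``cell_effect_sd``; measurement noise is AR(1) with stationary
    standard deviation ``noise_sd[param]`` and lag-one coefficient
    ``noise_autocorr``.
    """

    name: str
    trajectories: dict[str, Knots]
    cell_effect_sd: float = 0.1
    noise_sd: dict[str, float] = field(default_factory=dict)
    noise_autocorr: float = 0.6
    arrest_onset_h: float | None = None
    death_onset_h: float | None = None
    death_hazard: float | None = None  # per-cycle probability after onset
    division_rate: float | None = None  # per-cell per-hour probability

    def __post_init__(self) -> None:
        missing = [k for k in PARAM_KEYS if k not in self.trajectories]
        if missing:
            raise ConfigurationError(f"trajectories missing parameters: {missing}")
        for key, knots in self.trajectories.items():
            if key not in PARAM_KEYS:
                raise ConfigurationError(f"unknown trajectory parameter: {key!r}")
            cycles = [c for c, _ in knots]
            if cycles != sorted(cycles):
                raise ConfigurationError(f"knots for {key!r} not sorted by cycle")
            low, high = CALIBRATION_RANGES[key]
            for c, v in knots:
                if not (low <= v <= high):
                    raise ConfigurationError(
                        f"knot ({c}, {v}) for {key!r} outside calibration "
                        f"range [{low}, {high}]"
                    )
        if self.cell_effect_sd < 0:
            raise ConfigurationError("cell_effect_sd must be non-negative")
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ConfigurationError("noise_autocorr must lie in [0, 1)")
        for key, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd[{key!r}] must be non-negative")
        for name in ("death_hazard", "division_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")

    def mean_at(self, key: str, cycles: np.ndarray) -> np.ndarray:
        """Piecewise-linear population mean of a parameter at given cycles."""
        knots = self.trajectories[key]
        xp = np.array([c for c, _ in knots], dtype=float)
        fp = np.array([v for _, v in knots], dtype=float)
        return np.interp(np.asarray(cycles, dtype=float), xp, fp)

    def with_noise(self, cell_effect_sd: float | None = None,
                   noise_scale: float | None = None) -> "ArchetypeSpec":
        """Copy with heterogeneity and/or all noise SDs rescaled."""
        from dataclasses import replace
        kwargs = {}
        if cell_effect_sd is not None:
            kwargs["cell_effect_sd"] = cell_effect_sd
        if noise_scale is not None:
            kwargs["noise_sd"] = {k: v * noise_scale for k, v in self.noise_sd.items()}
        return replace(self, **kwargs)


#: Default AR(1) stationary noise SD per parameter (measurement units).
_DEFAULT_NOISE_SD: dict[str, float] = {
    "area": 25.0,
    "area_pct": 0.0,  # derived from area, carries its noise
    "perimeter": 8.0,
    "form_factor": 0.025,
    "extent": 0.02,
    "compactness": 0.3,
    "eccentricity": 0.04,
    "mean_ri": 0.0012,
    "dry_mass_density": 0.006,
    "dry_mass": 7.0,
    "granularity": 0.6,
}

_FIELD_AREA_DEFAULT = 236.0 ** 2


def _with_area_pct(traj: dict[str, Knots]) -> dict[str, Knots]:
    """Fill in area% knots consistent with the area knots (default field)."""
    traj = dict(traj)
    traj["area_pct"] = [
        (c, 100.0 * v / _FIELD_AREA_DEFAULT) for c, v in traj["area"]
    ]
    return traj


def builtin_archetypes() -> dict[str, ArchetypeSpec]:
    """The three calibrated built-in archetypes, keyed by name.

    Knot times follow the phenotype chronology of the emulated study:
    disruptor contraction by ~2 h (cycle 40), stabilizer arrest at ~10 h
    (cycle 200), late necrosis for the disruptor; amplitudes sit inside
    the published per-parameter axis ranges with margin for sampling
    variation of the population mean.
    """
    control = ArchetypeSpec(
        name="control",
        trajectories=_with_area_pct({
            "area": [(1, 520.0), (200, 560.0), (400, 620.0)],
            "perimeter": [(1, 150.0), (400, 170.0)],
            "form_factor": [(1, 0.30), (400, 0.28)],
            "extent": [(1, 0.60), (400, 0.58)],
            "compactness": [(1, 3.3), (400, 3.6)],
            "eccentricity": [(1, 0.80), (400, 0.80)],
            "mean_ri": [(1, 1.352), (400, 1.350)],
            "dry_mass_density": [(1, 0.11), (400, 0.10)],
            "dry_mass": [(1, 140.0), (200, 160.0), (400, 170.0)],
            "granularity": [(1, 9.0), (400, 10.0)],
        }),
        noise_sd=dict(_DEFAULT_NOISE_SD),
        division_rate=0.02,
    )
    stabilizer = ArchetypeSpec(
        name="stabilizer",
        trajectories=_with_area_pct({
            "area": [(1, 540.0), (200, 480.0), (280, 380.0), (400, 360.0)],
            "perimeter": [(1, 150.0), (200, 140.0), (260, 95.0), (400, 90.0)],
            "form_factor": [(1, 0.30), (200, 0.34), (260, 0.55), (400, 0.60)],
            "extent": [(1, 0.58), (200, 0.60), (260, 0.68), (400, 0.70)],
            "compactness": [(1, 3.3), (200, 3.0), (260, 1.9), (400, 1.7)],
            "eccentricity": [(1, 0.80), (200, 0.76), (260, 0.45), (400, 0.40)],
            "mean_ri": [(1, 1.351), (200, 1.355), (400, 1.356)],
            # clear decline through the first half, mild late recovery
            "dry_mass_density": [(1, 0.175), (200, 0.095), (400, 0.105)],
            "dry_mass": [(1, 150.0), (400, 155.0)],
            "granularity": [(1, 9.0), (200, 10.0), (400, 12.0)],
        }),
        noise_sd=dict(_DEFAULT_NOISE_SD),
        arrest_onset_h=10.0,
    )
    disruptor = ArchetypeSpec(
        name="disruptor",
        trajectories=_with_area_pct({
            # >20% contraction by the 2 h mark (cycle 40)
            "area": [(1, 560.0), (40, 430.0), (200, 360.0), (340, 330.0), (400, 320.0)],
            "perimeter": [(1, 155.0), (40, 120.0), (400, 100.0)],
            "form_factor": [(1, 0.30), (40, 0.38), (400, 0.35)],
            "extent": [(1, 0.58), (40, 0.64), (400, 0.62)],
            "compactness": [(1, 3.3), (40, 2.6), (400, 2.9)],
            "eccentricity": [(1, 0.80), (40, 0.65), (400, 0.60)],
            "mean_ri": [(1, 1.350), (340, 1.358), (400, 1.356)],
            # positive slope along the run, slight fall at the end
            "dry_mass_density": [(1, 0.09), (340, 0.165), (400, 0.150)],
            "dry_mass": [(1, 150.0), (400, 145.0)],
            "granularity": [(1, 9.0), (200, 11.0), (400, 13.0)],
        }),
        noise_sd=dict(_DEFAULT_NOISE_SD),
        death_onset_h=12.0,
        death_hazard=0.003,
    )
    return {"control": control, "stabilizer": stabilizer, "disruptor": disruptor}
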