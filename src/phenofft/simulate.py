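"""Synthetic live-cell acquisitions.

Generates per-cell phenotypic trajectories (and optionally full image
frames: label mask, refractive-index map, optical-height map) for a
mode-of-action archetype, emulating a label-free quantitative-phase
time-lapse run: 15–25 starting cells in a 236 µm field imaged every
3 minutes for 20 h.

The statistical model per cell and parameter is

    value(c) = mean_archetype(c) · effect + AR1_noise(c)

with a lognormal per-cell multiplicative effect (unit mean) and
stationary AR(1) Gaussian measurement noise, clipped to the parameter's
physical domain.  Mean refractive index is the one exception: the
multiplicative effect acts on the RI *excess* over the medium index,
because cell-to-cell optical variability lives in the dry-mass-related
excess, not in the absolute index.  Two parameters are derived rather
than drawn so that their defining identities hold exactly: area% =
100·area/field² and volume = dry mass / dry-mass density.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .archetypes import ArchetypeSpec
from .config import AcquisitionConfig, ConfigurationError
from .params import PARAM_KEYS, RECORD_COLUMNS, parameter

#: Refractive index of aqueous culture medium.
N_MEDIUM = 1.333
#: Specific refractive increment relating RI excess to dry-mass
#: concentration, µm³/pg.
ALPHA_RI_INCREMENT = 0.19

_MAX_CELLS = 500
#: Rendering cap on eccentricity (axis ratio ~3).
ECC_RENDER_CAP = 0.94


class GenerationError(RuntimeError):
    """Raised when synthetic frames cannot be generated as requested."""


@dataclass
class FieldFrame:
    """One rendered imaging cycle.

    ``label_mask`` is 0 on background and the cell id elsewhere;
    ``ri_map`` holds the refractive index (medium index on background);
    ``height_map`` the optical height in µm (0 on background).
    """

    cycle: int
    label_mask: np.ndarray
    ri_map: np.ndarray
    height_map: np.ndarray


def _rng_for(config: AcquisitionConfig, archetype: ArchetypeSpec) -> np.random.Generator:
    # Mix the archetype name into the stream so conditions sharing a seed
    # still get independent noise.
    tag = zlib.crc32(archetype.name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([config.seed, tag])


def _event_cycles(rng: np.random.Generator, config: AcquisitionConfig,
                  archetype: ArchetypeSpec) -> list[tuple[int, int, int]]:
    """Lay out the cell population: (cell_id, birth_cycle, end_cycle).

    ``end_cycle`` is the last cycle with a record (inclusive).  Division
    spawns a new track; death truncates one.
    """
    n_cycles = config.n_cycles
    n0 = int(rng.integers(config.initial_cells_min, config.initial_cells_max + 1))
    p_div = 0.0
    if archetype.division_rate:
        p_div = archetype.division_rate * config.interval / 60.0
    death_onset = None
    if archetype.death_hazard and archetype.death_onset_h is not None:
        death_onset = max(1, int(np.ceil(archetype.death_onset_h * 60.0 / config.interval)))

    cells: list[tuple[int, int, int]] = []
    queue: list[tuple[int, int]] = [(i + 1, 1) for i in range(n0)]
    next_id = n0 + 1
    while queue:
        cell_id, birth = queue.pop(0)
        end = n_cycles
        if death_onset is not None:
            start = max(birth, death_onset)
            # geometric waiting time for the necrotic event
            draws = rng.random(n_cycles - start + 1) if start <= n_cycles else np.array([])
            hit = np.nonzero(draws < archetype.death_hazard)[0]
            if hit.size:
                end = start + int(hit[0]) - 1  # last alive cycle before the event
        if p_div > 0.0 and len(cells) + len(queue) < _MAX_CELLS:
            for c in range(birth + 1, end + 1):
                if rng.random() < p_div:
                    queue.append((next_id, c))
                    next_id += 1
        if end >= birth:
            cells.append((cell_id, birth, end))
    cells.sort()
    return cells


def _ar1_noise(rng: np.random.Generator, sds: np.ndarray, phi: float,
               n: int) -> np.ndarray:
    """Stationary AR(1) noise, one row per parameter, shape (len(sds), n)."""
    innov = rng.standard_normal((len(sds), n))
    scale = np.sqrt(1.0 - phi * phi)
    innov *= sds[:, None] * scale
    if scale > 0:
        innov[:, 0] /= scale  # stationary start
    return lfilter([1.0], [1.0, -phi], innov, axis=1)


def simulate_trajectories(config: AcquisitionConfig,
                          archetype: ArchetypeSpec) -> pd.DataFrame:
    """Simulate per-cell phenotypic records for one condition.

    Returns a long-format table with one row per (cell, cycle) while the
    cell is alive: columns ``condition, cell_id, cycle, alive``, the 11
    phenotypic parameters, and the internal ``volume`` (µm³) satisfying
    dry_mass = dry_mass_density · volume exactly.

    Fully reproducible: identical config and archetype give a
    bit-identical table.
    """
    rng = _rng_for(config, archetype)
    cells = _event_cycles(rng, config, archetype)
    drawn_keys = [k for k in PARAM_KEYS if k != "area_pct"]
    sds = np.array([archetype.noise_sd.get(k, 0.0) for k in drawn_keys])

    chunks: list[pd.DataFrame] = []
    for cell_id, birth, end in cells:
        cycles = np.arange(birth, end + 1)
        n = len(cycles)
        mu = -0.5 * archetype.cell_effect_sd ** 2
        effects = np.exp(rng.normal(mu, archetype.cell_effect_sd, size=len(drawn_keys)))
        noise = _ar1_noise(rng, sds, archetype.noise_autocorr, n)
        values: dict[str, np.ndarray] = {}
        for j, key in enumerate(drawn_keys):
            base = archetype.mean_at(key, cycles)
            if key == "mean_ri":
                v = N_MEDIUM + (base - N_MEDIUM) * effects[j] + noise[j]
            else:
                v = base * effects[j] + noise[j]
            p = parameter(key)
            values[key] = np.clip(v, p.domain_low, p.domain_high)
        values["area_pct"] = 100.0 * values["area"] / config.field_area
        volume = values["dry_mass"] / values["dry_mass_density"]
        chunk = pd.DataFrame({
            "condition": archetype.name,
            "cell_id": cell_id,
            "cycle": cycles,
            "alive": True,
            **{k: values[k] for k in PARAM_KEYS},
            "volume": volume,
        })
        chunks.append(chunk)
    if not chunks:
        return pd.DataFrame(columns=list(RECORD_COLUMNS) + ["volume"])
    out = pd.concat(chunks, ignore_index=True)
    assert list(out.columns) == list(RECORD_COLUMNS) + ["volume"]
    return out


# ---------------------------------------------------------------------------
# frame rendering

def _place_cells(rng: np.random.Generator, radii: dict[int, float],
                 field_side: float) -> dict[int, tuple[float, float]]:
    """Place non-overlapping cells on a jittered grid.

    With grid pitch field_side/ceil(sqrt(n)) and jitter bounded by
    0.7·(pitch/2 − r), any two cells with bounding radii below pitch/2
    are guaranteed disjoint and inside the field.
    """
    n = len(radii)
    if n == 0:
        return {}
    grid_n = int(np.ceil(np.sqrt(n)))
    pitch = field_side / grid_n
    too_big = [cid for cid, r in radii.items() if r >= pitch / 2]
    if too_big:
        raise GenerationError(
            f"field too crowded to place {n} cells without overlap "
            f"(cells {too_big[:3]} exceed the {pitch / 2:.1f} µm slot radius); "
            "use a larger field or fewer cells"
        )
    slots = [(i, j) for i in range(grid_n) for j in range(grid_n)]
    order = rng.permutation(len(slots))
    centers: dict[int, tuple[float, float]] = {}
    for idx, (cell_id, r) in enumerate(radii.items()):
        i, j = slots[order[idx]]
        max_jitter = 0.7 * (pitch / 2 - r)
        dx, dy = rng.uniform(-max_jitter, max_jitter, size=2)
        centers[cell_id] = ((j + 0.5) * pitch + dx, (i + 0.5) * pitch + dy)
    return centers


def simulate_field_frames(config: AcquisitionConfig, archetype: ArchetypeSpec,
                          alpha: float = ALPHA_RI_INCREMENT,
                          n_medium: float = N_MEDIUM) -> Iterator[FieldFrame]:
    """Render the trajectory targets of ``simulate_trajectories`` (same
    seed, hence identical targets) as image frames, one per cycle.

    Each cell is a rotated ellipse whose area, axis ratio and mean RI
    follow its trajectory; the optical height is a half-ellipsoid dome
    rescaled so the rasterized dry mass (1/α)·Σ(RI−n_m)·h·px² matches the
    trajectory's dry-mass value.  The rendered eccentricity is capped at
    0.94 (axis ratio ~3): beyond that an ellipse of fixed area grows an
    arbitrarily long major axis, and the area — not the axis ratio — is
    the binding target.  Yields frames lazily.
    """
    records = simulate_trajectories(config, archetype)
    rng = _rng_for(config, archetype).spawn(1)[0]  # independent render stream
    ny, nx = config.grid_shape
    px = config.pixel_size

    if len(records):
        by_cell = dict(tuple(records.groupby("cell_id")))
        radii: dict[int, float] = {}
        angles: dict[int, float] = {}
        for cid, df in by_cell.items():
            ecc = np.clip(df["eccentricity"].to_numpy(), 0.0, ECC_RENDER_CAP)
            q = np.sqrt(1.0 - ecc ** 2)
            a = np.sqrt(df["area"].to_numpy() / (np.pi * q))
            radii[cid] = float(a.max()) * 1.05 + px
            angles[cid] = float(rng.uniform(0, np.pi))
        centers = _place_cells(rng, radii, config.field_side)
        by_cycle = {c: g for c, g in records.groupby("cycle")}
    else:
        by_cycle = {}
        centers = {}
        angles = {}

    yc = (np.arange(ny) + 0.5) * px
    xc = (np.arange(nx) + 0.5) * px

    for cycle in range(1, config.n_cycles + 1):
        mask = np.zeros((ny, nx), dtype=np.int32)
        ri = np.full((ny, nx), n_medium, dtype=float)
        height = np.zeros((ny, nx), dtype=float)
        frame_rng = np.random.default_rng([config.seed, cycle, 0x5EED])
        g = by_cycle.get(cycle)
        if g is not None:
            for row in g.itertuples(index=False):
                cid = int(row.cell_id)
                cx, cy = centers[cid]
                theta = angles[cid]
                ecc = min(max(row.eccentricity, 0.0), ECC_RENDER_CAP)
                q = np.sqrt(1.0 - ecc ** 2)
                a = np.sqrt(row.area / (np.pi * q))
                b = q * a
                # local bounding box in pixels
                r = a + px
                i0 = max(0, int((cy - r) / px)); i1 = min(ny, int((cy + r) / px) + 1)
                j0 = max(0, int((cx - r) / px)); j1 = min(nx, int((cx + r) / px) + 1)
                Y = yc[i0:i1, None] - cy
                X = xc[None, j0:j1] - cx
                xr = X * np.cos(theta) + Y * np.sin(theta)
                yr = -X * np.sin(theta) + Y * np.cos(theta)
                u2 = (xr / a) ** 2 + (yr / b) ** 2
                inside = u2 <= 1.0
                if not inside.any():
                    continue
                mask[i0:i1, j0:j1][inside] = cid
                tex_sd = max(row.granularity - 5.0, 0.0) / 2000.0
                tex = frame_rng.normal(0.0, tex_sd, size=int(inside.sum())) if tex_sd > 0 else 0.0
                if np.ndim(tex):
                    tex = tex - tex.mean()
                cell_ri = np.maximum(row.mean_ri + tex, n_medium)
                ri[i0:i1, j0:j1][inside] = cell_ri
                dome = np.sqrt(np.clip(1.0 - u2[inside], 0.0, None))
                dm_unit = float(np.sum((cell_ri - n_medium) * dome) * px * px / alpha)
                scale = row.dry_mass / dm_unit if dm_unit > 0 else 0.0
                height[i0:i1, j0:j1][inside] = dome * scale
        yield FieldFrame(cycle=cycle, label_mask=mask, ri_map=ri, height_map=height)
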