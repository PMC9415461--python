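"""Simulator: trajectories, events, reproducibility, calibration."""

import numpy as np
import pandas as pd
import pytest

from phenofft import (AcquisitionConfig, ConfigurationError, GenerationError,
                      simulate_field_frames, simulate_trajectories)
from phenofft.archetypes import ArchetypeSpec, builtin_archetypes
from phenofft.params import CALIBRATION_RANGES, PARAM_KEYS


def test_default_acquisition_arithmetic(default_config):
    """3-min cycles over 20 h give exactly 400 cycles on a 236 µm field."""
    assert default_config.n_cycles == 400
    assert default_config.field_side == 236.0
    assert default_config.interval == 3.0
    assert default_config.duration == 20.0


@pytest.mark.parametrize("bad", [
    dict(field_side=-1), dict(pixel_size=0), dict(interval=-3),
    dict(initial_cells_min=10, initial_cells_max=5),
])
def test_invalid_config_names_field(bad):
    with pytest.raises(ConfigurationError):
        AcquisitionConfig(**bad)


def test_noise_free_run_equals_mean_trajectory(archetypes, default_config):
    """With zero heterogeneity and noise every cell rides the archetype mean."""
    quiet = archetypes["control"].with_noise(cell_effect_sd=0.0, noise_scale=0.0)
    rec = simulate_trajectories(default_config, quiet)
    for key in PARAM_KEYS:
        if key == "area_pct":
            continue
        expected = quiet.mean_at(key, rec["cycle"].to_numpy())
        np.testing.assert_allclose(rec[key].to_numpy(), expected, rtol=1e-12)
    np.testing.assert_allclose(
        rec["area_pct"], 100.0 * rec["area"] / default_config.field_area,
        rtol=1e-12)


def test_every_cell_covers_all_400_cycles(archetypes, default_config):
    """Without division or death each track spans cycles 1..400."""
    rec = simulate_trajectories(default_config, archetypes["stabilizer"])
    for _, g in rec.groupby("cell_id"):
        assert g["cycle"].min() == 1
        assert g["cycle"].max() == 400
        assert len(g) == 400


def test_initial_cell_count_in_configured_range(archetypes):
    for seed in range(12):
        rec = simulate_trajectories(AcquisitionConfig(seed=seed),
                                    archetypes["stabilizer"])
        n0 = rec.loc[rec["cycle"] == 1, "cell_id"].nunique()
        assert 15 <= n0 <= 25


def test_reproducible_bit_identical(archetypes, default_config):
    a = simulate_trajectories(default_config, archetypes["disruptor"])
    b = simulate_trajectories(default_config, archetypes["disruptor"])
    pd.testing.assert_frame_equal(a, b)


def test_mass_conservation(archetypes, default_config):
    """DMD · volume equals dry mass at every record."""
    rec = simulate_trajectories(default_config, archetypes["control"])
    err = np.abs(rec["dry_mass"] - rec["dry_mass_density"] * rec["volume"])
    assert (err / rec["dry_mass"]).max() < 1e-9


def test_count_law_without_events(archetypes, default_config):
    rec = simulate_trajectories(default_config, archetypes["stabilizer"])
    assert len(rec) == rec["cell_id"].nunique() * default_config.n_cycles


def test_disruptor_death_truncates_tracks(archetypes, default_config):
    rec = simulate_trajectories(default_config, archetypes["disruptor"])
    onset = int(np.ceil(12.0 * 60.0 / default_config.interval))
    ends = rec.groupby("cell_id")["cycle"].max()
    assert (ends < default_config.n_cycles).any()  # some necrotic losses
    assert (ends[ends < default_config.n_cycles] >= onset - 1).all()


def test_control_division_spawns_tracks(archetypes, default_config):
    rec = simulate_trajectories(default_config, archetypes["control"])
    births = rec.groupby("cell_id")["cycle"].min()
    assert (births > 1).any()  # at least one division in 20 h


def test_builtin_archetype_shapes(archetypes):
    """Trend shapes that define the three modes of action."""
    cyc = np.arange(1, 401)
    dmd_stab = archetypes["stabilizer"].mean_at("dry_mass_density", cyc[:200])
    assert np.all(np.diff(dmd_stab) < 0)  # strict decline over first half
    dmd_dis = archetypes["disruptor"].mean_at("dry_mass_density", cyc)
    peak = int(np.argmax(dmd_dis))
    assert peak > 200  # late peak
    assert np.all(np.diff(dmd_dis[: peak + 1]) >= 0)
    assert dmd_dis[-1] < dmd_dis[peak]  # slight fall at the end
    area = archetypes["disruptor"].mean_at("area", cyc)
    assert area[39] <= 0.8 * area[0]  # ≥20% contraction by the 2 h cycle
    # control knots validated against calibration ranges at construction
    assert set(archetypes["control"].trajectories) == set(PARAM_KEYS)


def test_calibration_population_means_within_ranges(archetypes):
    """Over several seeds the population mean of every parameter stays
    inside its published axis range at every cycle, for every archetype."""
    from phenofft import aggregate
    for name, spec in archetypes.items():
        for seed in (1, 7, 13):
            rec = simulate_trajectories(AcquisitionConfig(seed=seed), spec)
            mean = aggregate(rec)[name].mean
            for key, (lo, hi) in CALIBRATION_RANGES.items():
                assert mean[key].min() >= lo, (name, seed, key)
                assert mean[key].max() <= hi, (name, seed, key)


def test_knot_outside_range_rejected(archetypes):
    traj = dict(archetypes["control"].trajectories)
    traj["mean_ri"] = [(1, 1.50)]
    with pytest.raises(ConfigurationError):
        ArchetypeSpec(name="bad", trajectories=traj)


def test_unsorted_knots_rejected(archetypes):
    traj = dict(archetypes["control"].trajectories)
    traj["area"] = [(200, 500.0), (1, 520.0)]
    with pytest.raises(ConfigurationError):
        ArchetypeSpec(name="bad", trajectories=traj)


# --------------------------------------------------------------------------
# frame rendering


def test_rendered_disk_area_matches_rasterization(small_config):
    """A near-circular cell's mask pixel count reproduces its target area."""
    target = np.pi * 10.0 ** 2
    traj = dict(builtin_archetypes()["stabilizer"].trajectories)
    traj["area"] = [(1, target)]
    traj["area_pct"] = [(1, 100.0 * target / 236.0 ** 2)]
    traj["eccentricity"] = [(1, 0.2)]
    spec = ArchetypeSpec(name="disk", trajectories=traj,
                         cell_effect_sd=0.0, noise_sd={})
    cfg = small_config.with_(initial_cells_min=1, initial_cells_max=1)
    frame = next(iter(simulate_field_frames(cfg, spec)))
    area = (frame.label_mask > 0).sum() * cfg.pixel_size ** 2
    assert abs(area - target) / target < 0.02


def test_empty_field_renders_zero_masks(archetypes, small_config):
    cfg = small_config.with_(initial_cells_min=0, initial_cells_max=0)
    frames = list(simulate_field_frames(cfg, archetypes["stabilizer"]))
    assert len(frames) == cfg.n_cycles
    assert all(not f.label_mask.any() for f in frames)


def test_default_cycle_count_renders_400_frames(archetypes):
    """The default schedule yields one frame per cycle, 400 in total."""
    cfg = AcquisitionConfig(seed=5, pixel_size=4.0, initial_cells_min=15,
                            initial_cells_max=15)
    n = sum(1 for _ in simulate_field_frames(cfg, archetypes["stabilizer"]))
    assert n == 400


def test_frame_invariants(archetypes, small_config):
    from phenofft import N_MEDIUM
    for frame in simulate_field_frames(small_config, archetypes["control"]):
        assert frame.ri_map.min() >= N_MEDIUM - 1e-12
        assert np.all(frame.height_map[frame.label_mask == 0] == 0.0)
        assert frame.label_mask.shape == small_config.grid_shape


def test_overcrowded_field_raises(archetypes):
    cfg = AcquisitionConfig(seed=1, field_side=60.0, pixel_size=1.0,
                            duration=0.1, initial_cells_min=25,
                            initial_cells_max=25)
    with pytest.raises(GenerationError):
        list(simulate_field_frames(cfg, archetypes["control"]))
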