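"""End-to-end orchestration: simulate/read → profile → cluster.

``run_all`` executes the whole pipeline from a flat configuration
mapping and writes every stage output plus a run manifest (config echo,
seed, library versions, per-stage row counts) sufficient to reproduce
the run bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .archetypes import builtin_archetypes
from .cluster import cluster_conditions, condition_correlation
from .config import AcquisitionConfig, ConfigurationError
from .datasets import load_reference_features
from .fft_profiler import build_feature_matrix, spectral_features
from .io import (read_records, write_feature_matrix, write_records,
                 write_series)
from .simulate import simulate_trajectories
from .timeseries import aggregate, center_scale, parameter_correlation

_CONFIG_FIELDS = ("field_side", "pixel_size", "interval", "duration",
                  "initial_cells_min", "initial_cells_max", "seed")


def acquisition_from_mapping(mapping: dict) -> AcquisitionConfig:
    """Build an AcquisitionConfig from a flat key-value mapping."""
    kwargs = {k: mapping[k] for k in _CONFIG_FIELDS if k in mapping}
    return AcquisitionConfig(**kwargs)


def simulate_replicates(archetype_names: list[str], seeds: list[int],
                        base: AcquisitionConfig) -> dict[str, pd.DataFrame]:
    """Simulate one record table per (archetype, seed) replicate."""
    archetypes = builtin_archetypes()
    out: dict[str, pd.DataFrame] = {}
    for name in archetype_names:
        if name not in archetypes:
            raise ConfigurationError(
                f"unknown archetype {name!r}; built-ins: {sorted(archetypes)}")
        for seed in seeds:
            rep = f"{name}#s{seed}"
            records = simulate_trajectories(base.with_(seed=seed),
                                            archetypes[name])
            out[rep] = records.assign(condition=rep)
    return out


def run_all(config: dict, out_dir) -> dict:
    """Run the full pipeline and write the artifact bundle.

    ``config`` is a flat mapping; either ``records`` names an input CSV,
    or ``archetypes`` (list) and ``seeds`` (list) request simulation.
    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    if config.get("records"):
        records = read_records(config["records"])
    elif config.get("archetypes"):
        base = acquisition_from_mapping(config)
        seeds = [int(s) for s in config.get("seeds", [base.seed])]
        replicates = simulate_replicates(list(config["archetypes"]), seeds, base)
        records = pd.concat(replicates.values(), ignore_index=True)
    else:
        raise ConfigurationError(
            "config must name either 'records' or 'archetypes'")
    write_records(records, out / "records.csv")
    stage_counts["records"] = len(records)

    series_by_cond = aggregate(records)
    features = []
    for cond, series in series_by_cond.items():
        safe = cond.replace("#", "_")
        write_series(series, out / f"series_{safe}.csv")
        parameter_correlation(series).to_csv(out / f"paramcorr_{safe}.csv")
        features.extend(spectral_features(center_scale(series)))
    stage_counts["conditions"] = len(series_by_cond)
    stage_counts["spectral_features"] = len(features)

    fft_rows = pd.DataFrame(
        [{"condition": f.condition, "parameter": f.parameter,
          "k_star": f.k_star, "period": f.period,
          "amplitude": f.amplitude, "phase": f.phase} for f in features])
    fft_rows.to_csv(out / "fft_features.csv", index=False)

    if config.get("fixture"):
        matrix = load_reference_features()
    else:
        matrix = build_feature_matrix(features, normalize=True)
    write_feature_matrix(matrix, out / "feature_matrix.csv")

    corr = condition_correlation(matrix)
    corr.to_csv(out / "corr.csv")
    k = int(config.get("k", 2))
    method = str(config.get("linkage", "average"))
    result = cluster_conditions(corr, method=method, k=k)
    clusters = {
        "conditions": result.conditions,
        "labels": result.labels,
        "members": {str(kk): v for kk, v in result.members().items()},
        "linkage": result.linkage_matrix.tolist(),
        "method": method,
        "k": k,
    }
    (out / "clusters.json").write_text(json.dumps(clusters, indent=2) + "\n")

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": config.get("seed", 0),
        "versions": {"phenofft": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "stage_counts": stage_counts,
        "outputs": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
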