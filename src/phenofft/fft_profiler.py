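"""Dominant-Fourier-feature dimension reduction.

Each centered, scaled population time series x_n (n = 0..N−1) is mapped
through the discrete Fourier transform

    X_k = Σ_{n=0}^{N−1} x_n · exp(−i 2π k n / N)

and summarized by the single frequency index k* of maximal amplitude on
k ∈ [1, N/2) — usually the lowest non-trivial frequency, carrying the
main trend — together with that amplitude (scaled 2|X_k*|/N so a unit
cosine reports 1) and its phase angle(X_k*) ∈ (−π, π].  The amplitude
tells how wave-like the series is; the phase encodes which part of the
wave the acquisition captured (rise, fall, trough).  Eleven parameters
× (amplitude, phase) give a 22-dimensional signature per condition; the
feature matrix z-scores each column across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PARAM_KEYS
from .timeseries import CenteredSeries


@dataclass
class Spectrum:
    """DFT coefficients of one centered parameter series."""

    condition: str
    parameter: str
    coefficients: np.ndarray  # complex, length N

    @property
    def n(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class SpectralFeature:
    """Dominant-frequency summary of one (condition, parameter) series."""

    condition: str
    parameter: str
    k_star: int
    amplitude: float
    phase: float

    @property
    def period(self) -> float:
        """Period in cycles, N/k*."""
        return self._n / self.k_star if self.k_star else np.inf

    _n: int = 0


@dataclass
class FeatureMatrix:
    """Conditions × 22 dominant-Fourier features.

    Columns are ``amp_<param>`` for the 11 parameters in canonical
    order, then ``phase_<param>``.  When ``normalized``, each column is
    z-scored (n−1 denominator) across conditions.
    """

    data: pd.DataFrame
    normalized: bool

    @property
    def conditions(self) -> list[str]:
        return list(self.data.index)


AMP_COLUMNS = tuple(f"amp_{k}" for k in PARAM_KEYS)
PHASE_COLUMNS = tuple(f"phase_{k}" for k in PARAM_KEYS)
FEATURE_COLUMNS = AMP_COLUMNS + PHASE_COLUMNS


def dft(series: CenteredSeries) -> dict[str, Spectrum]:
    """Discrete Fourier transform of every parameter series.

    Uses the e^{−i2πkn/N} sign convention; after centering, X_0 is
    numerically zero.  Non-finite input raises with the offending cycle.
    """
    n = len(series.values)
    if n < 4:
        raise ValueError(f"need at least 4 cycles for a spectrum, got {n}")
    out: dict[str, Spectrum] = {}
    for param in series.values.columns:
        x = series.values[param].to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(x))[0]
        if bad.size:
            cyc = series.values.index[bad[0]]
            raise ValueError(f"non-finite value in {series.condition}/{param} "
                             f"at cycle {cyc}")
        out[param] = Spectrum(condition=series.condition, parameter=param,
                              coefficients=np.fft.fft(x))
    return out


def dominant_feature(spectrum: Spectrum) -> SpectralFeature:
    """Frequency index, amplitude and phase of the maximal-amplitude bin.

    The argmax runs over k ∈ [1, ceil(N/2)−1]: the DC bin is meaningless
    after centering and, for even N, the Nyquist bin carries no phase.
    Ties break toward the smallest k (the lower frequency).
    """
    n = spectrum.n
    k_hi = (n + 1) // 2  # exclusive upper bound: excludes Nyquist for even N
    band = np.abs(spectrum.coefficients[1:k_hi])
    if band.size == 0 or not band.any():
        raise ValueError(
            f"all-zero spectrum for {spectrum.condition}/{spectrum.parameter}: "
            "constant series should have been rejected upstream"
        )
    k_star = int(np.argmax(band)) + 1  # argmax returns first (smallest k) tie
    coef = spectrum.coefficients[k_star]
    return SpectralFeature(
        condition=spectrum.condition, parameter=spectrum.parameter,
        k_star=k_star, amplitude=2.0 * float(np.abs(coef)) / n,
        phase=float(np.angle(coef)), _n=n,
    )


def spectral_features(series: CenteredSeries) -> list[SpectralFeature]:
    """Dominant feature of every parameter of one condition."""
    return [dominant_feature(s) for s in dft(series).values()]


def build_feature_matrix(features: list[SpectralFeature],
                         normalize: bool = True) -> FeatureMatrix:
    """Assemble the conditions × 22 feature matrix.

    Every (condition, parameter) pair must appear exactly once.  With
    ``normalize``, each column is z-scored across conditions (requires
    ≥ 3 conditions); amplitude and phase blocks are normalized
    independently, column by column.
    """
    seen: dict[tuple[str, str], SpectralFeature] = {}
    for f in features:
        key = (f.condition, f.parameter)
        if key in seen:
            raise ValueError(f"duplicate feature for {key}")
        seen[key] = f
    conditions = list(dict.fromkeys(f.condition for f in features))
    missing = [(c, p) for c in conditions for p in PARAM_KEYS if (c, p) not in seen]
    if missing:
        raise ValueError(f"missing (condition, parameter) pairs: {missing}")
    rows = {
        c: [seen[(c, p)].amplitude for p in PARAM_KEYS]
        + [seen[(c, p)].phase for p in PARAM_KEYS]
        for c in conditions
    }
    data = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(FEATURE_COLUMNS))
    data.index.name = "condition"
    if normalize:
        if len(conditions) < 3:
            raise ValueError("column z-scoring needs at least 3 conditions")
        sd = data.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(
                f"zero-variance feature column(s): {list(sd[sd == 0].index)}"
            )
        data = (data - data.mean(axis=0)) / sd
    return FeatureMatrix(data=data, normalized=normalize)


def absolute_features(matrix: FeatureMatrix) -> pd.DataFrame:
    """Companion export of absolute values (bar-chart style summary)."""
    return matrix.data.abs()
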