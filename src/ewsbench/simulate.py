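"""Stochastic simulation and data-degradation transforms.

This is the synthetic-data generator of the benchmark: Euler-Maruyama
integration of the mutualistic community model under additive or
multiplicative Gaussian white noise, plus the pure transforms that emulate
common data problems (measurement noise, short records, coarse sampling,
observing only a subset of variables).

All randomness flows through integer seeds or :class:`numpy.random.SeedSequence`;
the same seed reproduces the same sample path bit for bit, and per-step
sub-seeds are derived with spawn keys so different scenarios reuse identical
latent paths wherever the scenario definition allows (paired comparisons
remove a large share of the Monte-Carlo noise between scenario columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import DimensionError, IntegrationError, PreconditionError
from .model import (
    EXTINCTION_THRESHOLD,
    ModelParameters,
    StabilityMetrics,
    SweepStep,
)

__all__ = [
    "TimeSeriesMatrix",
    "NoiseSpec",
    "SweepResult",
    "SweepSeries",
    "integrate",
    "add_measurement_noise",
    "truncate_length",
    "thin_resolution",
    "select_subset",
    "generate_sweep_series",
]

#: Noise chunk length (integration steps) streamed through the kernel.
_CHUNK_STEPS = 2_000_000


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A sampled multivariate time series.

    ``values`` has one row per sample and one column per variable
    (abundance units); ``sampling_interval`` is the time between rows.
    ``meta`` records provenance (seed, sweep step, scenario ...) and is
    carried through transforms.
    """

    values: np.ndarray
    sampling_interval: float
    labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 2:
            raise DimensionError("values must be a T x N matrix with T >= 2")
        if not np.isfinite(v).all():
            raise PreconditionError("values contain non-finite entries")
        if self.sampling_interval <= 0:
            raise PreconditionError("sampling_interval must be positive")
        labels = tuple(self.labels) if self.labels else tuple(
            f"x{j + 1}" for j in range(v.shape[1])
        )
        if len(labels) != v.shape[1]:
            raise DimensionError("labels length does not match column count")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, "time", self.times)
        return df

    def write_csv(self, path) -> None:
        """Delimited text: header row, first column is time."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TimeSeriesMatrix":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise DimensionError("expected a time column plus at least one variable")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dts = np.diff(t)
        if len(dts) == 0 or not np.allclose(dts, dts[0]):
            raise PreconditionError("time column must be uniformly spaced")
        return cls(
            values=df.iloc[:, 1:].to_numpy(dtype=float),
            sampling_interval=float(dts[0]),
            labels=tuple(df.columns[1:]),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """System and observational noise settings.

    ``mode='additive'`` adds ``sigma * dW``; ``'multiplicative'`` scales the
    increment with the current abundance (``sigma * x * dW``).  The default
    ``sigma`` of 0.02 is the benchmark's standard system-noise level.
    ``measurement_sd`` is i.i.d. Gaussian observation noise applied to the
    recorded samples afterwards, not to the dynamics.
    """

    mode: Literal["additive", "multiplicative"] = "additive"
    sigma: float = 0.02
    measurement_sd: float = 0.0

    def __post_init__(self):
        if self.mode not in ("additive", "multiplicative"):
            raise PreconditionError("mode must be 'additive' or 'multiplicative'")
        if np.any(np.asarray(self.sigma) < 0) or self.measurement_sd < 0:
            raise PreconditionError("noise scales must be non-negative")


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def integrate(
    params: ModelParameters,
    start,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.01,
    sampling_interval: float = 0.1,
    burn_in: float = 100.0,
    seed=0,
) -> TimeSeriesMatrix:
    """Euler-Maruyama integration of the community SDE.

    The state is advanced with ``x <- x + f(x) dt + amp * sqrt(dt) * xi``
    where ``amp`` is ``sigma`` (additive) or ``sigma * x`` (multiplicative)
    and ``xi ~ N(0, 1)`` i.i.d. per species and step.  Abundances are
    clipped at zero after each step.  ``burn_in`` time units are integrated
    and discarded before the first sample; thereafter one row is recorded
    every ``sampling_interval`` time units until ``duration`` is covered.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite.
    PreconditionError
        If fewer than two samples are requested or the step sizes are
        inconsistent.
    """
    x0 = np.asarray(start, dtype=float)
    if x0.shape != (params.n_species,):
        raise DimensionError(
            f"start must have shape ({params.n_species},), got {x0.shape}"
        )
    if dt <= 0 or sampling_interval < dt:
        raise PreconditionError("need 0 < dt <= sampling_interval")
    stride = sampling_interval / dt
    if abs(stride - round(stride)) > 1e-9:
        raise PreconditionError("sampling_interval must be an integer multiple of dt")
    stride = int(round(stride))
    n_samples = int(round(duration / sampling_interval))
    if n_samples < 2:
        raise PreconditionError("requested series length must be at least 2 samples")
    burn_steps = int(round(burn_in / dt))

    sigma = np.asarray(noise.sigma, dtype=float)
    if sigma.ndim == 0:
        sigma_A = np.full(params.n_pollinators, float(sigma))
        sigma_P = np.full(params.n_plants, float(sigma))
    else:
        full = np.asarray(sigma, dtype=float)
        if full.shape != (params.n_species,):
            raise DimensionError("per-variable sigma must match species count")
        sigma_A, sigma_P = full[: params.n_pollinators], full[params.n_pollinators :]

    n = params.n_species
    A = x0[: params.n_pollinators].copy()
    P = x0[params.n_pollinators :].copy()
    out = np.empty((n_samples, n))
    clip_count = np.zeros(1, dtype=np.int64)
    rng = np.random.Generator(np.random.PCG64(_seed_sequence(seed)))

    total = burn_steps + n_samples * stride
    step0, rec = 0, 0
    while step0 < total:
        m = min(_CHUNK_STEPS, total - step0)
        noise_chunk = rng.standard_normal((m, n), dtype=np.float32)
        rec = _kernels.em_chunk(
            A,
            P,
            params.r_A,
            params.r_P,
            params.gamma_A,
            params.gamma_P,
            params.c_A,
            params.c_P,
            params.h_A,
            params.h_P,
            sigma_A,
            sigma_P,
            noise.mode == "multiplicative",
            float(dt),
            noise_chunk,
            step0,
            burn_steps,
            stride,
            out,
            rec,
            clip_count,
        )
        step0 += m
        if not (np.isfinite(A).all() and np.isfinite(P).all()):
            raise IntegrationError(
                "integration blew up (non-finite state)", step=step0
            )

    return TimeSeriesMatrix(
        values=out,
        sampling_interval=sampling_interval,
        labels=tuple(params.labels),
        meta={
            "seed": seed if isinstance(seed, int) else "seed-sequence",
            "dt": dt,
            "burn_in": burn_in,
            "noise_mode": noise.mode,
            "sigma": noise.sigma,
            "clip_fraction": float(clip_count[0]) / (total * n),
        },
    )


def add_measurement_noise(ts: TimeSeriesMatrix, sd: float, seed=0) -> TimeSeriesMatrix:
    """Add i.i.d. Gaussian observation noise to every data point.

    Pure transform: the input matrix is left untouched.  ``sd=0`` returns
    an identical copy.
    """
    if sd < 0:
        raise PreconditionError("sd must be non-negative")
    if sd == 0:
        return replace(ts, values=ts.values.copy())
    rng = np.random.Generator(np.random.PCG64(_seed_sequence(seed)))
    noisy = ts.values + rng.normal(0.0, sd, size=ts.values.shape)
    meta = dict(ts.meta, measurement_sd=sd)
    return replace(ts, values=noisy, meta=meta)


def truncate_length(ts: TimeSeriesMatrix, n: int) -> TimeSeriesMatrix:
    """Keep only the first ``n`` samples."""
    if n < 2:
        raise PreconditionError("truncated length must be at least 2")
    if n > ts.n_samples:
        raise PreconditionError(
            f"cannot truncate to {n} samples; series has {ts.n_samples}"
        )
    return replace(ts, values=ts.values[:n].copy())


def thin_resolution(ts: TimeSeriesMatrix, factor: int) -> TimeSeriesMatrix:
    """Keep every ``factor``-th sample, scaling the sampling interval.

    Post-hoc decimation of an existing record.  Note that the benchmark's
    low-resolution scenario is *not* produced this way: it keeps the number
    of samples fixed and integrates a longer window instead.
    """
    if factor < 1:
        raise PreconditionError("factor must be >= 1")
    if factor == 1:
        return replace(ts, values=ts.values.copy())
    vals = ts.values[::factor].copy()
    if vals.shape[0] < 2:
        raise PreconditionError("thinning leaves fewer than 2 samples")
    return replace(
        ts, values=vals, sampling_interval=ts.sampling_interval * factor
    )


def select_subset(ts: TimeSeriesMatrix, indices: Sequence[int]) -> TimeSeriesMatrix:
    """Restrict the series to a subset of variables (columns)."""
    idx = list(indices)
    if len(idx) == 0:
        raise PreconditionError("indices must be non-empty")
    if len(set(idx)) != len(idx):
        raise PreconditionError("indices must be unique")
    if min(idx) < 0 or max(idx) >= ts.n_variables:
        raise PreconditionError("column index out of range")
    return replace(
        ts,
        values=ts.values[:, idx].copy(),
        labels=tuple(ts.labels[j] for j in idx),
    )


@dataclass(frozen=True)
class SweepSeries:
    """One sweep step's stationary series with its true stability metrics."""

    step_index: int
    r_A: np.ndarray
    series: TimeSeriesMatrix
    stability: StabilityMetrics
    flagged: bool = False


@dataclass(frozen=True)
class SweepResult:
    """Stationary time series for every step of a bifurcation sweep."""

    steps: tuple[SweepSeries, ...]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def valid_steps(self) -> list[SweepSeries]:
        return [s for s in self.steps if not s.flagged]

    def map_series(self, f) -> "SweepResult":
        """Apply a pure series transform to every step."""
        return SweepResult(
            steps=tuple(replace(s, series=f(s.series)) for s in self.steps),
            meta=dict(self.meta),
        )


def _sustained_below(values: np.ndarray, threshold: float, window: int) -> bool:
    below = values < threshold
    if not below.any():
        return False
    if window <= 1:
        return True
    # any run of `window` consecutive below-threshold samples in any column
    kernel = np.ones(window)
    for j in range(values.shape[1]):
        if np.convolve(below[:, j].astype(float), kernel, mode="valid").max() >= window:
            return True
    return False


def generate_sweep_series(
    sweep: Sequence[SweepStep],
    noise: NoiseSpec,
    length: int,
    sampling_interval: float = 0.1,
    seed=0,
    dt: float = 0.01,
    burn_in: float = 100.0,
) -> SweepResult:
    """Simulate one stationary series per sweep step.

    Each step is initialised at that step's deterministic equilibrium, the
    burn-in is discarded, and ``length`` samples are recorded.  Per-step
    seeds are spawned from the master seed by step index, so two scenarios
    sharing a master seed see identical latent noise at every step.

    A step whose realised path spends a sustained window (one time unit)
    below the extinction threshold is flagged (kept, but excluded from
    :meth:`SweepResult.valid_steps`) with a warning.
    """
    root = _seed_sequence(seed)
    window = max(1, int(round(1.0 / sampling_interval)))
    out: list[SweepSeries] = []
    for i, step in enumerate(sweep):
        child = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(*root.spawn_key, i)
        )
        ts = integrate(
            step.params,
            step.equilibrium,
            noise,
            duration=length * sampling_interval,
            dt=dt,
            sampling_interval=sampling_interval,
            burn_in=burn_in,
            seed=child,
        )
        ts = replace(ts, meta=dict(ts.meta, sweep_step=i, seed=f"spawn[{i}]"))
        flagged = _sustained_below(ts.values, EXTINCTION_THRESHOLD, window)
        if flagged:
            warnings.warn(
                f"sweep step {i}: realised path crossed the extinction "
                "threshold for a sustained window; step flagged",
                stacklevel=2,
            )
        out.append(
            SweepSeries(
                step_index=i,
                r_A=step.params.r_A.copy(),
                series=ts,
                stability=step.stability,
                flagged=flagged,
            )
        )
    return SweepResult(
        steps=tuple(out),
        meta={
            "seed": seed if isinstance(seed, int) else "seed-sequence",
            "length": length,
            "sampling_interval": sampling_interval,
            "noise_mode": noise.mode,
            "sigma": noise.sigma,
            "dt": dt,
            "burn_in": burn_in,
        },
    )
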