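"""Named experimental scenarios: data-quality regimes for the benchmark.

Each scenario is the basic protocol — a 50-step sweep toward the
bifurcation with a stationary series of 10,000 samples at interval 0.1 and
additive system noise 0.02 per step — with exactly one deviation:

==================== =======================================================
basic                the reference protocol, no deviation
data_length          1,000 samples instead of 10,000
data_resolution      sampling interval 100 instead of 0.1 (length kept at
                     10,000, so the simulated window is much longer)
measurement_noise    i.i.d. Gaussian observation noise, sd 0.08, added to
                     every data point afterwards
multiplicative_noise system noise scales with abundance (sigma 0.02 * x)
subset_variables     only half of the variables are observed; all subsets
                     are scored and summarised by 5%/95% quantiles
reactive             parameters tuned so the equilibrium turns reactive on
                     the way to the tipping point (4-species setting only)
==================== =======================================================

Scenarios apply to three model settings: the 4-species community (``4d``)
and two random 20-species communities, one collapsing fully
(``20d_full``) and one partially (``20d_partial``).  The reactive scenario
exists only for ``4d``: the large community cannot be tuned reactive while
keeping all species present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigError, PreconditionError
from .model import (
    ModelParameters,
    SweepStep,
    default_4d_sweep,
    random_parameter_search,
    sweep_bifurcation_parameter,
)
from .simulate import (
    NoiseSpec,
    SweepResult,
    add_measurement_noise,
    generate_sweep_series,
    select_subset,
)

__all__ = [
    "ScenarioConfig",
    "SCENARIO_NAMES",
    "MODEL_SETTINGS",
    "scenario_presets",
    "model_for_setting",
    "run_scenario",
    "subset_indices",
    "iter_subset_results",
    "sensitivity_grid",
]

SCENARIO_NAMES = (
    "basic",
    "data_length",
    "data_resolution",
    "measurement_noise",
    "multiplicative_noise",
    "subset_variables",
    "reactive",
)

MODEL_SETTINGS = ("4d", "20d_full", "20d_partial")

#: Default sampling grid: 10,000 samples, 0.1 time units apart.
DEFAULT_LENGTH = 10_000
DEFAULT_INTERVAL = 0.1
DEFAULT_SIGMA = 0.02
DEFAULT_SWEEP_STEPS = 50


@dataclass(frozen=True)
class ScenarioConfig:
    """One executable scenario for one model setting."""

    name: str
    model_setting: str = "4d"
    length: int = DEFAULT_LENGTH
    sampling_interval: float = DEFAULT_INTERVAL
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subset_fraction: float | None = None
    n_sweep_steps: int = DEFAULT_SWEEP_STEPS
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ConfigError(
                f"unknown scenario {self.name!r}; valid: {', '.join(SCENARIO_NAMES)}"
            )
        if self.model_setting not in MODEL_SETTINGS:
            raise ConfigError(
                f"unknown model setting {self.model_setting!r}; "
                f"valid: {', '.join(MODEL_SETTINGS)}"
            )
        if self.name == "reactive" and self.model_setting != "4d":
            raise ConfigError(
                "the reactive scenario exists only for the 4d setting"
            )
        if self.length < 2 or self.sampling_interval <= 0 or self.n_sweep_steps < 1:
            raise ConfigError("invalid length / sampling_interval / n_sweep_steps")
        if self.subset_fraction is not None and not (0 < self.subset_fraction < 1):
            raise ConfigError("subset_fraction must lie in (0, 1)")

    def with_scale(self, scale: float) -> "ScenarioConfig":
        """Down-scaled copy: the series length is multiplied by ``scale``."""
        if not (0 < scale <= 1):
            raise ConfigError("scale must lie in (0, 1]")
        return replace(self, length=max(16, int(round(self.length * scale))))


def _preset(name: str, setting: str, seed: int) -> ScenarioConfig:
    base = dict(name=name, model_setting=setting, seed=seed)
    if name == "data_length":
        return ScenarioConfig(**base, length=1_000)
    if name == "data_resolution":
        return ScenarioConfig(**base, sampling_interval=100.0)
    if name == "measurement_noise":
        return ScenarioConfig(
            **base, noise=NoiseSpec(sigma=DEFAULT_SIGMA, measurement_sd=0.08)
        )
    if name == "multiplicative_noise":
        return ScenarioConfig(
            **base, noise=NoiseSpec(mode="multiplicative", sigma=DEFAULT_SIGMA)
        )
    if name == "subset_variables":
        return ScenarioConfig(**base, subset_fraction=0.5)
    return ScenarioConfig(**base)  # basic / reactive


def scenario_presets(seed: int = 0) -> list[ScenarioConfig]:
    """The full benchmark catalogue: 6 scenarios x 3 settings + reactive."""
    presets = [
        _preset(name, setting, seed)
        for setting in MODEL_SETTINGS
        for name in SCENARIO_NAMES
        if name != "reactive"
    ]
    presets.append(_preset("reactive", "4d", seed))
    return presets


_MODEL_CACHE: dict = {}


def model_for_setting(
    model_setting: str,
    reactive: bool = False,
    seed: int = 0,
    search_budget: int = 2000,
) -> tuple[ModelParameters, np.ndarray, np.ndarray]:
    """Parameters and sweep endpoints for a model setting.

    The 4d setting uses the reference community with calibrated endpoints;
    the 20d settings run (and cache) the random parameter search.
    """
    key = (model_setting, reactive, seed)
    if key in _MODEL_CACHE:
        return _MODEL_CACHE[key]
    if model_setting == "4d":
        out = default_4d_sweep(reactive=reactive)
    else:
        if reactive:
            raise ConfigError("the 20d settings cannot be made reactive")
        collapse = "full" if model_setting == "20d_full" else "partial"
        res = random_parameter_search(
            dims=(10, 10), collapse_type=collapse, seed=seed, budget=search_budget
        )
        out = (res.params, res.r_A_start, res.r_A_end)
    _MODEL_CACHE[key] = out
    return out


def run_scenario(
    config: ScenarioConfig,
    sweep_steps: Sequence[SweepStep] | None = None,
    dt: float = 0.01,
    burn_in: float = 100.0,
) -> SweepResult:
    """Execute a scenario: sweep, simulate, apply the scenario transforms.

    Returns the sweep of time series with all variables still present; for
    the subset scenario use :func:`iter_subset_results` on the result.  The
    measurement-noise transform uses sub-seeds spawned from the scenario
    seed, so the latent paths are bit-identical to the basic scenario run
    with the same seed.
    """
    if sweep_steps is None:
        params, r0, r1 = model_for_setting(
            config.model_setting,
            reactive=config.name == "reactive",
            seed=config.seed,
        )
        sweep_steps = sweep_bifurcation_parameter(
            params, r0, r1, config.n_sweep_steps
        )
    result = generate_sweep_series(
        sweep_steps,
        config.noise,
        length=config.length,
        sampling_interval=config.sampling_interval,
        seed=config.seed,
        dt=dt,
        burn_in=burn_in,
    )
    if config.noise.measurement_sd > 0:
        root = np.random.SeedSequence(config.seed)
        steps = tuple(
            replace(
                s,
                series=add_measurement_noise(
                    s.series,
                    config.noise.measurement_sd,
                    seed=np.random.SeedSequence(
                        entropy=root.entropy, spawn_key=(1 << 20, s.step_index)
                    ),
                ),
            )
            for s in result.steps
        )
        result = SweepResult(steps=steps, meta=dict(result.meta, scenario=config.name))
    else:
        result = SweepResult(
            steps=result.steps, meta=dict(result.meta, scenario=config.name)
        )
    return result


def subset_indices(
    n_variables: int,
    fraction: float = 0.5,
    sample: int | None = None,
    seed: int = 0,
) -> Iterator[tuple[int, ...]]:
    """All (or a seeded sample of) variable subsets of the given fraction.

    With ``sample=None`` every combination is enumerated (6 for 4 choose 2;
    184,756 for 20 choose 10 — prefer sampling there).  With ``sample=k``
    a uniform random sample of ``k`` distinct combinations is drawn.
    """
    size = int(round(n_variables * fraction))
    if size < 1 or size >= n_variables:
        raise PreconditionError("subset size must be between 1 and N-1")
    if sample is None:
        yield from combinations(range(n_variables), size)
        return
    rng = np.random.Generator(np.random.PCG64(seed))
    seen = set()
    while len(seen) < sample:
        pick = tuple(sorted(rng.choice(n_variables, size=size, replace=False)))
        if pick not in seen:
            seen.add(pick)
            yield pick


def iter_subset_results(
    result: SweepResult,
    fraction: float = 0.5,
    sample: int | None = None,
    seed: int = 0,
) -> Iterator[tuple[tuple[int, ...], SweepResult]]:
    """Column-sliced sweep results, one per variable subset.

    Subsetting observes fewer variables of the *same* realised system, so
    the slices share the underlying sample paths.
    """
    n = result.steps[0].series.n_variables
    for idx in subset_indices(n, fraction=fraction, sample=sample, seed=seed):
        yield idx, result.map_series(lambda ts, idx=idx: select_subset(ts, idx))


def sensitivity_grid(
    axis: str,
    values: Sequence,
    base: ScenarioConfig,
) -> list[ScenarioConfig]:
    """One config per grid value along a single degradation axis.

    ``axis`` is one of ``length``, ``resolution``, ``measurement_sd``.
    """
    configs = []
    for v in values:
        if axis == "length":
            if v < 2:
                raise ConfigError("length must be >= 2")
            configs.append(replace(base, length=int(v)))
        elif axis == "resolution":
            if v <= 0:
                raise ConfigError("sampling interval must be positive")
            configs.append(replace(base, sampling_interval=float(v)))
        elif axis == "measurement_sd":
            if v < 0:
                raise ConfigError("measurement sd must be >= 0")
            configs.append(
                replace(base, noise=replace(base.noise, measurement_sd=float(v)))
            )
        else:
            raise ConfigError(
                "axis must be one of 'length', 'resolution', 'measurement_sd'"
            )
    return configs
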