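"""Synthetic multi-metric repeated-measures data with known effect structure.

The generator emulates a graded-stress study design: N subjects observed at
T ordered sessions (baseline, stress 1, stress 2, recovery) on M disparate
measures, each with its own native units. The model for subject i, session
j, measure m is

    X_ijm = mu_m + sigma_m * (dir_m * delta_jm + b_im + e_ijm)

with a per-(subject, measure) random intercept b_im ~ N(0, subject_sd^2)
and residual e_ijm ~ N(0, within_sd^2). Effects ``delta_jm`` are injected
on the standardized scale (baseline-SD units), so a simulated measure's
"true sensitivity" is directly comparable across measures regardless of
native units — the precise comparability problem z-scoring addresses. In
variance-normalized mode (default) subject_sd^2 + within_sd^2 = 1, so
``sigma_m`` is the total null SD and the between-session correlation is
subject_sd^2 (compound symmetry; sphericity holds and GG epsilon ~ 1).

Defaults reproduce the canonical study scale: 34 subjects, 4 sessions, 18
measures spanning sustained-attention (PVT), mood inventory (POMS),
short-term spatial memory (match-to-sample) and salivary hormone panels,
with published baseline means/SDs and inverted-U effect trajectories
(0, d, d, d/4): departure from baseline at both stress sessions, near-return
at recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import StudyData, from_cube
from .exceptions import ConfigError

#: default inverted-U trajectory, in units of d: (baseline, stress1, stress2, recovery)
INVERTED_U = (0.0, 1.0, 1.0, 0.25)

#: effect-size classes (baseline-SD units) for the default measure panel
D_MOOD = 0.9
D_TIMING = 0.45
D_PREMATURE = 0.25
D_ACCURACY = 0.15


@dataclass(frozen=True)
class MeasureProfile:
    """Native-unit scale and standardized effect trajectory of one measure."""

    measure: str
    baseline_mean: float
    baseline_sd: float
    effect_profile: tuple[float, ...]  # mean shift per session, baseline-SD units
    direction: int = 1  # +1: stress increases the measure; -1: decreases

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ConfigError(f"{self.measure}: baseline_sd must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Design, variance partition and seed for one simulated study."""

    n_subjects: int
    n_sessions: int
    profiles: tuple[MeasureProfile, ...]
    subject_sd: float = np.sqrt(0.5)
    within_sd: float = np.sqrt(0.5)
    seed: int = 0
    variance_normalized: bool = True
    #: optional per-session residual SD multipliers; breaks sphericity
    session_sd_scale: tuple[float, ...] | None = None
    #: skew parameter for a standardized log-normal residual (0 = Gaussian)
    residual_skew: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 2:
            raise ConfigError("need n_subjects >= 1 and n_sessions >= 2")
        if not self.profiles:
            raise ConfigError("at least one measure profile is required")
        if self.within_sd <= 0 or self.subject_sd < 0:
            raise ConfigError("need within_sd > 0 and subject_sd >= 0")
        if self.variance_normalized:
            total = self.subject_sd**2 + self.within_sd**2
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    "variance-normalized mode requires subject_sd^2 + within_sd^2 = 1 "
                    f"(got {total:.6f})"
                )
        for p in self.profiles:
            if len(p.effect_profile) != self.n_sessions:
                raise ConfigError(
                    f"{p.measure}: effect_profile length {len(p.effect_profile)} "
                    f"!= n_sessions {self.n_sessions}"
                )
        if self.session_sd_scale is not None and len(self.session_sd_scale) != self.n_sessions:
            raise ConfigError("session_sd_scale length must equal n_sessions")


def _scaled_profile(measure, mean, sd, d, direction, shape=INVERTED_U):
    return MeasureProfile(
        measure=measure,
        baseline_mean=mean,
        baseline_sd=sd,
        effect_profile=tuple(d * s for s in shape),
        direction=direction,
    )


def default_profiles() -> tuple[MeasureProfile, ...]:
    """The 18-measure default panel at published baseline scales.

    Baseline means/SDs are the published native-unit values for each
    measure; effect trajectories follow the inverted-U shape (0, d, d, d/4)
    with per-class magnitudes d reflecting the qualitative sensitivity
    ordering the method is expected to recover: mood sub-scales and
    cortisol strongest, response-timing measures and testosterone/NPY
    intermediate, accuracy counts weak, BDNF null. Directions encode the
    expected sign of the stress response (mood disturbance up, vigor down,
    accuracy down, cortisol up, anabolic hormones down).
    """
    return (
        # PVT (sustained attention)
        _scaled_profile("PVT_premature", 10.7, 9.5, D_PREMATURE, +1),
        _scaled_profile("PVT_timeouts", 11.5, 20.6, D_TIMING, +1),
        _scaled_profile("PVT_correct", 114.6, 22.4, D_ACCURACY, -1),
        _scaled_profile("PVT_rt", 0.30, 0.03, D_TIMING, +1),
        # POMS (self-report mood)
        _scaled_profile("POMS_tmd", 20.0, 17.8, D_MOOD, +1),
        _scaled_profile("POMS_tension", 6.6, 3.8, D_MOOD, +1),
        _scaled_profile("POMS_depression", 3.7, 4.4, D_MOOD, +1),
        _scaled_profile("POMS_anger", 7.2, 6.3, D_MOOD, +1),
        _scaled_profile("POMS_vigor", 10.7, 5.7, D_MOOD, -1),
        _scaled_profile("POMS_fatigue", 7.1, 5.0, D_MOOD, +1),
        _scaled_profile("POMS_confusion", 6.2, 3.1, D_MOOD, +1),
        # Match-to-sample (short-term spatial memory)
        _scaled_profile("MTS_correct", 15.4, 3.4, D_ACCURACY, -1),
        _scaled_profile("MTS_timeouts", 0.09, 0.3, D_TIMING, +1),
        _scaled_profile("MTS_rt", 4.5, 1.6, D_TIMING, +1),
        # Salivary hormones
        _scaled_profile("cortisol", 0.2, 0.1, D_MOOD, +1),
        _scaled_profile("testosterone", 56.7, 25.0, D_TIMING, -1),
        _scaled_profile("BDNF", 11.6, 24.8, 0.0, +1),
        _scaled_profile("NPY", 84.5, 29.4, D_TIMING, -1),
    )


def null_profiles(base: tuple[MeasureProfile, ...] | None = None) -> tuple[MeasureProfile, ...]:
    """The same panel with every effect trajectory zeroed (null model)."""
    base = base if base is not None else default_profiles()
    return tuple(
        replace(p, effect_profile=tuple(0.0 for _ in p.effect_profile)) for p in base
    )


def _standardized_lognormal(z: np.ndarray, skew: float) -> np.ndarray:
    """Map standard normals to a mean-0, SD-1 log-normal with shape ``skew``."""
    if skew == 0.0:
        return z
    w = np.exp(skew * z)
    mean = np.exp(skew**2 / 2.0)
    sd = np.sqrt((np.exp(skew**2) - 1.0) * np.exp(skew**2))
    return (w - mean) / sd


def generate_cube(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the raw n_subjects x n_sessions x n_measures value array."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, t = config.n_subjects, config.n_sessions
    m = len(config.profiles)
    b = rng.normal(0.0, config.subject_sd, size=(n, 1, m))
    e = rng.normal(0.0, 1.0, size=(n, t, m))
    e = _standardized_lognormal(e, config.residual_skew) * config.within_sd
    if config.session_sd_scale is not None:
        e = e * np.asarray(config.session_sd_scale, dtype=float)[None, :, None]
    dirs = np.array([p.direction for p in config.profiles], dtype=float)
    delta = np.array([p.effect_profile for p in config.profiles], dtype=float).T
    delta = delta * dirs[None, :]  # t x m, signed standardized shifts
    mu = np.array([p.baseline_mean for p in config.profiles])
    sigma = np.array([p.baseline_sd for p in config.profiles])
    std_scale = delta[None, :, :] + b + e
    return mu[None, None, :] + sigma[None, None, :] * std_scale


def generate_study(config: SimulationConfig) -> StudyData:
    """Simulate a balanced :class:`StudyData` under ``config``.

    Deterministic for a fixed seed; the per-measure population mean at
    session j is ``mu_m + sigma_m * dir_m * delta_jm``.
    """
    cube = generate_cube(config)
    measures = tuple(p.measure for p in config.profiles)
    return from_cube(cube, measures=measures)


def generate_paperlike_study(seed: int = 0) -> StudyData:
    """The canonical end-to-end fixture: 34 subjects x 4 sessions x 18 measures."""
    config = SimulationConfig(
        n_subjects=34, n_sessions=4, profiles=default_profiles(), seed=seed
    )
    return generate_study(config)


def directions(profiles: tuple[MeasureProfile, ...] | None = None) -> dict[str, int]:
    """Expected change direction per measure, for report grouping."""
    profiles = profiles if profiles is not None else default_profiles()
    return {p.measure: p.direction for p in profiles}
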