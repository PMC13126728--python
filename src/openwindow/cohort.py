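"""Synthetic paired-cohort and training-load generation.

Emulates the statistical structure of a 22-athlete paired immune panel
measured before and after a four-week high-intensity training block, and
turns the block's session schedule into the per-tick metabolic stress
input (lactate injection, glucose drain) that drives the simulator.

The marker presets transcribe the published pre/post summary moments for
18 markers: six leukocyte classes (10^9 cells/L), three immunoglobulins
(g/L), four cytokines (pg/mL) and five lymphocyte subsets (cells/uL).
Three post-training leukocyte SDs are printed equal to their means in the
source table (e.g. "0.37 ± 0.37"), a presumed typographical slip; the
presets substitute the pre-training SDs for those rows and flag them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import MarkerPanel

__all__ = [
    "MarkerSpec",
    "TrainingSession",
    "TrainingSchedule",
    "StressSeries",
    "table_marker_presets",
    "table_training_schedule",
    "generate_paired_panel",
    "generate_stress_series",
    "DEFAULT_ZONE_WEIGHTS",
]


@dataclass(frozen=True)
class MarkerSpec:
    """Target marginal moments and dependence for one paired marker."""

    marker: str
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    family: str = "truncated_normal"  # or "lognormal"
    pre_post_correlation: float = 0.85  # intra-subject r; the design assumes > 0.8
    sd_post_imputed: bool = False  # True where the printed post-SD was a typo

    def __post_init__(self) -> None:
        if self.sd_pre < 0 or self.sd_post < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1 < self.pre_post_correlation < 1:
            raise ValueError("pre/post correlation must lie in (-1, 1)")
        if self.family not in ("truncated_normal", "lognormal"):
            raise ValueError(f"unknown marginal family {self.family!r}")


@dataclass(frozen=True)
class TrainingSession:
    """One day-slot of the 4-week schedule."""

    week: int
    day: str
    session_type: str
    zone: str  # Moderate | Heavy | Severe | Extreme | Mixed | Rest
    hr_mean: float | None = None
    hr_sd: float | None = None
    bla_mean: float | None = None
    bla_sd: float | None = None

    @property
    def is_training(self) -> bool:
        """A slot contributes a stress pulse iff it carries a lactate value."""
        return self.zone != "Rest" and self.bla_mean is not None


@dataclass(frozen=True)
class TrainingSchedule:
    sessions: tuple[TrainingSession, ...]

    def __post_init__(self) -> None:
        if len(self.sessions) != 28:
            raise ValueError("a 4-week schedule has 28 day-slots")
        for s in self.sessions:
            if s.zone in ("Severe", "Extreme") and (s.bla_mean is None or s.bla_mean < 6.8):
                raise ValueError(
                    f"severe/extreme session {s.week}/{s.day} must have BLa mean >= 6.8"
                )

    def __len__(self) -> int:
        return len(self.sessions)

    def session(self, week: int, day: str) -> TrainingSession:
        for s in self.sessions:
            if s.week == week and s.day == day:
                return s
        raise KeyError(f"no session W{week} {day}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.week, s.day, s.session_type, s.zone, s.hr_mean, s.hr_sd, s.bla_mean, s.bla_sd)
                for s in self.sessions
            ],
            columns=["week", "day", "session_type", "zone", "hr_mean", "hr_sd", "bla_mean", "bla_sd"],
        )


# ---------------------------------------------------------------------------
# published-table presets

_LEUKOCYTES = [
    # marker, mean_pre, sd_pre, mean_post, sd_post, post_sd_imputed
    ("Leukocyte", 7.32, 0.60, 6.13, 0.50, False),
    ("Neutrophil", 3.70, 0.31, 3.33, 0.28, False),
    ("Lymphocyte", 2.81, 0.32, 2.71, 0.22, False),
    ("Monocyte", 0.42, 0.02, 0.37, 0.02, True),  # printed post-SD 0.37 == mean
    ("Eosinophil", 0.56, 0.03, 0.47, 0.03, True),  # printed post-SD 0.47 == mean
    ("Basophil", 0.06, 0.003, 0.05, 0.003, True),  # printed post-SD 0.05 == mean
]

_IMMUNOGLOBULINS = [
    ("IgA", 1.8905, 0.6521, 2.0234, 0.6664),
    ("IgG", 15.7706, 1.5071, 11.8295, 1.1554),
    ("IgM", 2.0223, 0.6415, 2.2041, 0.6627),
]

_CYTOKINES = [
    ("IL-6", 0.9015, 0.3324, 3.5758, 1.0802),
    ("IL-8", 14.5546, 4.4355, 36.6076, 4.6686),
    ("TNF-a", 2.5108, 1.0542, 9.2420, 0.7456),
    ("IL-10", 15.2823, 3.5390, 2.8291, 1.9216),
]

_LYMPHOCYTE_SUBSETS = [
    ("B cell", 263.19, 19.47, 153.68, 11.37),
    ("NK cells", 698.52, 51.67, 803.63, 59.44),
    ("T cell", 1429.26, 105.71, 1387.96, 102.66),
    ("CD3+CD4+ T cell", 811.92, 60.05, 584.35, 43.22),
    ("CD3+CD8+ T cell", 611.08, 45.20, 625.96, 46.28),
]


def table_marker_presets(correlation: float = 0.85) -> list[MarkerSpec]:
    """The 18 marker specs transcribed from the published summary tables.

    Cell counts and immunoglobulins use truncated-normal marginals;
    cytokines use moment-matched lognormal marginals (physiological
    right-skew).  Values are byte-stable across calls.
    """
    specs: list[MarkerSpec] = []
    for name, mp, sp, mq, sq, imputed in _LEUKOCYTES:
        specs.append(
            MarkerSpec(name, mp, sp, mq, sq, "truncated_normal", correlation, imputed)
        )
    for name, mp, sp, mq, sq in _IMMUNOGLOBULINS:
        specs.append(MarkerSpec(name, mp, sp, mq, sq, "truncated_normal", correlation))
    for name, mp, sp, mq, sq in _CYTOKINES:
        specs.append(MarkerSpec(name, mp, sp, mq, sq, "lognormal", correlation))
    for name, mp, sp, mq, sq in _LYMPHOCYTE_SUBSETS:
        specs.append(MarkerSpec(name, mp, sp, mq, sq, "truncated_normal", correlation))
    return specs


def preset(marker: str, correlation: float = 0.85) -> MarkerSpec:
    """Look up one preset marker spec by name."""
    for s in table_marker_presets(correlation):
        if s.marker == marker:
            return s
    raise KeyError(f"no preset marker {marker!r}")


_SCHEDULE_ROWS: list[tuple] = [
    # week, day, session_type, zone, hr_mean, hr_sd, bla_mean, bla_sd
    (1, "Mon", "Recovery", "Moderate", 142, 8, 1.8, 0.4),
    (1, "Tue", "Intervals", "Severe", 178, 6, 8.2, 1.1),
    (1, "Wed", "Aerobic Base", "Heavy", 162, 5, 3.1, 0.6),
    (1, "Thu", "Special End.", "Severe", 181, 4, 9.5, 1.3),
    (1, "Fri", "Recovery", "Moderate", 135, 9, 1.5, 0.3),
    (1, "Sat", "Long Run", "Heavy", 158, 7, 2.8, 0.8),
    (1, "Sun", "Rest", "Rest", None, None, None, None),  # active recovery / massage
    (2, "Mon", "Recovery", "Moderate", 140, 6, 1.6, 0.3),
    (2, "Tue", "Intervals", "Severe", 176, 5, 7.8, 0.9),
    (2, "Wed", "Aerobic Base", "Heavy", 164, 4, 3.4, 0.5),
    (2, "Thu", "Lactate Tol.", "Extreme", 188, 7, 11.2, 1.5),
    (2, "Fri", "Recovery", "Moderate", 138, 8, 1.4, 0.2),
    (2, "Sat", "Tempo Run", "Mixed", 172, 5, 5.5, 1.0),  # printed zone "Heavy/Severe"
    (2, "Sun", "Rest", "Rest", None, None, None, None),
    (3, "Mon", "Recovery", "Moderate", 141, 7, 1.7, 0.4),
    (3, "Tue", "Intervals", "Severe", 182, 5, 9.1, 1.2),
    (3, "Wed", "Aerobic Base", "Heavy", 155, 6, 2.5, 0.5),
    (3, "Thu", "Special End.", "Severe", 179, 6, 8.5, 1.1),
    (3, "Fri", "Recovery", "Moderate", 136, 5, 1.6, 0.3),
    (3, "Sat", "Fartlek", "Mixed", 168, 9, 4.2, 1.2),
    (3, "Sun", "Rest", "Rest", None, None, None, None),
    (4, "Mon", "Recovery", "Moderate", 135, 6, 1.3, 0.2),
    (4, "Tue", "Taper/Int.", "Severe", 175, 4, 6.8, 0.8),
    (4, "Wed", "Aerobic Base", "Heavy", 150, 5, 2.2, 0.4),
    (4, "Thu", "Activation", "Heavy", 168, 3, 3.8, 0.6),
    (4, "Fri", "Rest", "Rest", None, None, None, None),  # total rest, pre-test
    (4, "Sat", "Rest", "Rest", None, None, None, None),  # total rest, pre-test
    (4, "Sun", "Post-Test", "Rest", None, None, None, None),  # sampling day
]


def table_training_schedule(active_recovery_as_moderate: bool = False) -> TrainingSchedule:
    """The 28-day schedule of the 4-week high-intensity block.

    Six day-slots carry no lactate value (three Sunday rests, the two
    pre-test rest days and the post-test sampling day) and contribute no
    stress pulse; the remaining 22 are training days.  With
    ``active_recovery_as_moderate=True`` the week-1 Sunday
    active-recovery/massage slot is instead treated as an easy Moderate
    session (BLa 1.5 +- 0.3, typical of the block's recovery runs).
    """
    sessions = [TrainingSession(*row) for row in _SCHEDULE_ROWS]
    if active_recovery_as_moderate:
        sessions[6] = TrainingSession(1, "Sun", "Active Recovery", "Moderate", 110, 8, 1.5, 0.3)
    return TrainingSchedule(tuple(sessions))


# ---------------------------------------------------------------------------
# paired-panel generation


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal moment-matched to the given mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal family needs a positive mean")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _draw_pair(spec: MarkerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n, 2) array of (pre, post) values for one marker.

    Dependence is a Gaussian copula with the spec's correlation on the
    latent normals.  Truncated-normal marginals resample any negative draw
    (negligible mass for the preset moments, so moments are preserved);
    lognormal marginals are moment-matched and non-negative by
    construction.
    """
    r = spec.pre_post_correlation
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov)
    out = np.empty((n, 2))
    todo = np.arange(n)
    while todo.size:
        z = rng.standard_normal((todo.size, 2)) @ chol.T
        if spec.family == "lognormal":
            mu_a, sg_a = _lognormal_params(spec.mean_pre, spec.sd_pre)
            mu_b, sg_b = _lognormal_params(spec.mean_post, spec.sd_post)
            vals = np.column_stack(
                [np.exp(mu_a + sg_a * z[:, 0]), np.exp(mu_b + sg_b * z[:, 1])]
            )
        else:
            vals = np.column_stack(
                [
                    spec.mean_pre + spec.sd_pre * z[:, 0],
                    spec.mean_post + spec.sd_post * z[:, 1],
                ]
            )
        ok = (vals >= 0).all(axis=1)
        out[todo[ok]] = vals[ok]
        todo = todo[~ok]
    return out


def generate_paired_panel(
    specs: list[MarkerSpec],
    n: int,
    seed: int,
    add_cd4_cd8_ratio: bool = True,
    cd4_cd8_correlation: float = 0.5,
) -> MarkerPanel:
    """Generate a paired athlete panel matching the specs' moments.

    If both CD4 and CD8 subset specs are present (and
    ``add_cd4_cd8_ratio``), those two markers are drawn *jointly* — the
    within-time-point CD4/CD8 correlation defaults to 0.5 — and a derived
    ``cd4_cd8_ratio`` column is appended per athlete, so the ratio is an
    emergent per-athlete quantity rather than an independently drawn
    marker.  Identical seeds yield identical panels.
    """
    if n < 2:
        raise ValueError("need at least 2 athletes")
    rng = np.random.default_rng(seed)
    names = [s.marker for s in specs]
    cd4_name, cd8_name = "CD3+CD4+ T cell", "CD3+CD8+ T cell"
    joint_ratio = add_cd4_cd8_ratio and cd4_name in names and cd8_name in names

    columns: dict[str, np.ndarray] = {}
    for spec in specs:
        if joint_ratio and spec.marker in (cd4_name, cd8_name):
            continue
        columns[spec.marker] = _draw_pair(spec, n, rng)

    if joint_ratio:
        cd4 = next(s for s in specs if s.marker == cd4_name)
        cd8 = next(s for s in specs if s.marker == cd8_name)
        r, c = cd4.pre_post_correlation, cd4_cd8_correlation
        # latent order: cd4_pre, cd4_post, cd8_pre, cd8_post
        cov = np.array(
            [
                [1.0, r, c, c * r],
                [r, 1.0, c * r, c],
                [c, c * r, 1.0, r],
                [c * r, c, r, 1.0],
            ]
        )
        chol = np.linalg.cholesky(cov)
        means = np.array([cd4.mean_pre, cd4.mean_post, cd8.mean_pre, cd8.mean_post])
        sds = np.array([cd4.sd_pre, cd4.sd_post, cd8.sd_pre, cd8.sd_post])
        out = np.empty((n, 4))
        todo = np.arange(n)
        while todo.size:
            z = rng.standard_normal((todo.size, 4)) @ chol.T
            vals = means + sds * z
            ok = (vals > 0).all(axis=1)
            out[todo[ok]] = vals[ok]
            todo = todo[~ok]
        columns[cd4_name] = out[:, :2]
        columns[cd8_name] = out[:, 2:]
        columns["cd4_cd8_ratio"] = out[:, :2] / out[:, 2:]

    markers = [m for m in names] + (["cd4_cd8_ratio"] if joint_ratio else [])
    athletes = [f"athlete_{i + 1:02d}" for i in range(n)]
    pre = np.column_stack([columns[m][:, 0] for m in markers])
    post = np.column_stack([columns[m][:, 1] for m in markers])
    return MarkerPanel(markers, athletes, pre, post)


# ---------------------------------------------------------------------------
# stress-input series

#: Relative glucose drain per intensity zone (dimensionless multipliers).
DEFAULT_ZONE_WEIGHTS: dict[str, float] = {
    "Moderate": 0.5,
    "Heavy": 1.0,
    "Mixed": 1.0,
    "Severe": 2.0,
    "Extreme": 3.0,
    "Rest": 0.0,
}


@dataclass
class StressSeries:
    """Per-tick metabolic stress input for the simulator.

    ``lactate_injection`` is added to systemic lactate each tick (mmol/L
    equivalents); ``glucose_drain`` is subtracted from every grid patch
    (resource units).  Both carry the pulse-with-decay shape of the
    training days that produced them.
    """

    lactate_injection: np.ndarray
    glucose_drain: np.ndarray
    ticks_per_day: int
    pulse_days: int = 0

    def __post_init__(self) -> None:
        self.lactate_injection = np.asarray(self.lactate_injection, dtype=float)
        self.glucose_drain = np.asarray(self.glucose_drain, dtype=float)
        if self.lactate_injection.shape != self.glucose_drain.shape:
            raise ValueError("series components must have equal length")

    def __len__(self) -> int:
        return self.lactate_injection.size

    def at(self, tick: int) -> tuple[float, float]:
        """(lactate_injection, glucose_drain) at a tick; zero past the end."""
        if tick >= len(self):
            return 0.0, 0.0
        return float(self.lactate_injection[tick]), float(self.glucose_drain[tick])

    def scaled(self, multiplier: float) -> "StressSeries":
        return StressSeries(
            self.lactate_injection * multiplier,
            self.glucose_drain * multiplier,
            self.ticks_per_day,
            self.pulse_days,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tick": np.arange(len(self)),
                "lactate_injection": self.lactate_injection,
                "glucose_drain": self.glucose_drain,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ticks_per_day: int = 10) -> "StressSeries":
        return cls(
            frame["lactate_injection"].to_numpy(float),
            frame["glucose_drain"].to_numpy(float),
            ticks_per_day,
        )


def generate_stress_series(
    schedule: TrainingSchedule,
    ticks_per_day: int = 10,
    seed: int = 0,
    zone_weights: dict[str, float] | None = None,
    drain_scale: float = 1.0,
    pulse_half_life_ticks: float = 3.0,
) -> StressSeries:
    """Convert a training schedule into the simulator's stress input.

    Each training day contributes, at its first tick, a lactate pulse with
    amplitude drawn from Normal(bla_mean, bla_sd) clipped at zero and a
    glucose-drain pulse of amplitude ``zone_weight * drain_scale``; both
    decay geometrically with the given half-life.  Rest slots contribute
    nothing.  Identical seeds give identical series.
    """
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    if ticks_per_day < 1:
        raise ValueError("ticks_per_day must be >= 1")
    weights = dict(DEFAULT_ZONE_WEIGHTS)
    if zone_weights:
        weights.update(zone_weights)
    rng = np.random.default_rng(seed)
    n_ticks = len(schedule) * ticks_per_day
    lactate = np.zeros(n_ticks)
    drain = np.zeros(n_ticks)
    decay = 0.5 ** (1.0 / pulse_half_life_ticks)
    pulse_days = 0
    for d, session in enumerate(schedule.sessions):
        if not session.is_training:
            continue
        pulse_days += 1
        amp_l = max(0.0, rng.normal(session.bla_mean, session.bla_sd))
        amp_g = weights[session.zone] * drain_scale
        start = d * ticks_per_day
        t = np.arange(n_ticks - start)
        kernel = decay**t
        lactate[start:] += amp_l * kernel
        drain[start:] += amp_g * kernel
    # truncate the numerically negligible tail of each pulse
    lactate[lactate < 1e-12] = 0.0
    drain[drain < 1e-12] = 0.0
    return StressSeries(lactate, drain, ticks_per_day, pulse_days)
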