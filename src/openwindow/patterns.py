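"""Pattern-oriented model validation and the tipping-point sweep.

The simulator is judged valid if, under the high-stress training-load
scenario, it qualitatively reproduces three emergent patterns seen in the
empirical post-training data — (1) non-linear decay of the total immune
population, (2) inversion of the CD4/CD8 ratio below 1.0, and (3) failure
of inflammatory resolution (sustained pathogen load while an unstressed
control clears its inoculum) — and a zero-stress control reproduces none
of them.  The detectors are pure functions of traces, so constructed
oracle traces can exercise them without running the simulator.

Each pattern is stated qualitatively by the source model description;
the quantitative operationalizations here (an AIC margin of 2 for
exponential-over-linear decay, the final-10% evaluation window, a 10%
clearance fraction, a 0.8 per-pattern pass fraction) are decided
thresholds, all surfaced in :class:`~openwindow.config.PomParams`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import PomParams, SimulationConfig
from .engine import SimulationTrace, run_simulation

__all__ = [
    "PatternResult",
    "SweepResult",
    "pattern_nonlinear_decay",
    "pattern_ratio_inversion",
    "pattern_resolution_failure",
    "locate_tipping_point",
    "tipping_point_sweep",
    "pom_report",
]


@dataclass
class PatternResult:
    pattern: str
    passes: list[bool]
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def pass_fraction(self) -> float:
        return float(np.mean(self.passes)) if self.passes else 0.0


@dataclass
class SweepResult:
    stress_grid: np.ndarray
    terminal_density: np.ndarray  # median terminal total immune count per multiplier
    critical_lambda: float  # multiplier at the steepest decline
    sharpness: float  # max |d density / d lambda| normalized by the density range
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stress_multiplier": self.stress_grid, "terminal_density": self.terminal_density}
        )


# ---------------------------------------------------------------------------
# pattern detectors (pure functions of traces)


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * k


def pattern_nonlinear_decay(
    trace: SimulationTrace, aic_margin: float = 2.0
) -> tuple[bool, dict]:
    """Does the total immune count decay, and decay non-linearly?

    Fits a straight line and a single exponential ``a * exp(-b t)`` to the
    total immune count by least squares.  Passes iff the terminal count is
    below the initial count and the exponential's AIC beats the linear
    fit's by at least ``aic_margin`` (both fits use two parameters, so the
    margin is purely a goodness-of-fit requirement).
    """
    y = trace.frame["total_immune"].to_numpy(float)
    t = np.arange(y.size, dtype=float)
    if y.size < 20:
        raise ValueError("trace too short to classify decay (need >= 20 ticks)")
    diag: dict = {"initial": float(y[0]), "terminal": float(y[-1])}
    if np.ptp(y) == 0:
        diag["reason"] = "no decay (constant trace)"
        return False, diag
    if y[-1] >= y[0]:
        diag["reason"] = "no decay"
        return False, diag
    slope, intercept = np.polyfit(t, y, 1)
    rss_lin = float(((y - (slope * t + intercept)) ** 2).sum())
    b0 = max(1e-4, -slope / max(y[0], 1.0))

    def model(t, a, b):
        return a * np.exp(-b * t)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(y[0], b0), maxfev=10000, bounds=([0, 0], [np.inf, np.inf])
        )
        rss_exp = float(((y - model(t, *popt)) ** 2).sum())
    except RuntimeError:
        diag["reason"] = "exponential fit failed"
        return False, diag
    aic_lin = _aic(rss_lin, y.size, 2)
    aic_exp = _aic(rss_exp, y.size, 2)
    diag.update(
        {"aic_linear": aic_lin, "aic_exponential": aic_exp, "decay_rate": float(popt[1])}
    )
    return bool(aic_exp <= aic_lin - aic_margin), diag


def pattern_ratio_inversion(
    trace: SimulationTrace,
    baseline_ratio: float | None = None,
    final_window_frac: float = 0.1,
) -> tuple[bool, dict]:
    """Does the CD4/CD8 ratio invert below 1.0 from an initial ratio above it?

    Evaluates the median ratio over the final ``final_window_frac`` of
    ticks.  A trace whose CD8 population hits zero in the window has an
    undefined ratio and fails with a diagnostic.
    """
    frame = trace.frame
    ratio = frame["cd4_cd8_ratio"].to_numpy(float)
    initial = baseline_ratio if baseline_ratio is not None else float(ratio[0])
    window = max(1, int(np.ceil(final_window_frac * len(frame))))
    tail = ratio[-window:]
    diag = {"initial_ratio": initial, "window_ticks": window}
    if np.isnan(tail).any():
        diag["reason"] = "ratio undefined (zero CD8 count in evaluation window)"
        return False, diag
    terminal = float(np.median(tail))
    diag["terminal_median_ratio"] = terminal
    return bool(initial > 1.0 and terminal < 1.0), diag


def pattern_resolution_failure(
    trace_high: SimulationTrace,
    trace_control: SimulationTrace,
    clearance_frac: float = 0.1,
) -> tuple[bool, dict]:
    """Is the pathogen load sustained under stress but cleared in control?

    Passes iff the high-stress terminal pathogen count exceeds
    ``clearance_frac`` of the initial inoculum *and* the control's
    terminal count is at or below that fraction.
    """
    if not 0 < clearance_frac < 1:
        raise ValueError("clearance_frac must lie in (0, 1)")
    p_high = trace_high.frame["pathogen"].to_numpy(float)
    p_ctrl = trace_control.frame["pathogen"].to_numpy(float)
    inoculum = p_high[0]
    if inoculum <= 0:
        raise ValueError("high-stress trace has a zero initial inoculum")
    threshold = clearance_frac * inoculum
    diag = {
        "inoculum": float(inoculum),
        "terminal_high": float(p_high[-1]),
        "terminal_control": float(p_ctrl[-1]),
        "clearance_threshold": float(threshold),
    }
    return bool(p_high[-1] > threshold and p_ctrl[-1] <= threshold), diag


# ---------------------------------------------------------------------------
# tipping-point sweep


def locate_tipping_point(stress_grid, terminal_density) -> SweepResult:
    """Find the steepest decline in a (multiplier, density) response table.

    ``critical_lambda`` is the midpoint of the grid interval with the
    largest magnitude finite-difference slope; ``sharpness`` is that slope
    normalized by the density range per unit multiplier, so a flat
    response has sharpness 0 ("no tipping point").
    """
    lam = np.asarray(stress_grid, dtype=float)
    dens = np.asarray(terminal_density, dtype=float)
    if lam.size < 4:
        raise ValueError("need at least 4 stress-grid points")
    if lam.size != dens.size:
        raise ValueError("grid and density must have equal length")
    slopes = np.diff(dens) / np.diff(lam)
    rng_d = float(np.ptp(dens))
    diag: dict = {}
    if rng_d == 0:
        diag["reason"] = "no tipping point (flat response)"
        return SweepResult(lam, dens, float("nan"), 0.0, diag)
    i = int(np.argmax(np.abs(slopes)))
    critical = float(0.5 * (lam[i] + lam[i + 1]))
    sharpness = float(np.abs(slopes[i]) / rng_d)
    return SweepResult(lam, dens, critical, sharpness, diag)


def tipping_point_sweep(
    base_config: SimulationConfig,
    stress_multipliers=(0.0, 0.5, 1.0, 2.0, 4.0),
    seeds=range(5),
) -> SweepResult:
    """Median terminal immune density across a stress-multiplier grid.

    Runs the simulator for every (multiplier, seed) pair and reduces each
    multiplier to the median terminal total immune count; the tipping
    point is located on that response table.  Deterministic for a fixed
    seed list.
    """
    lam = np.asarray(list(stress_multipliers), dtype=float)
    seeds = list(seeds)
    if lam.size < 4:
        raise ValueError("need at least 4 stress-grid points")
    if len(seeds) < 5:
        raise ValueError("need at least 5 seeds per grid point")
    medians = []
    per_seed = {}
    for mult in lam:
        terminals = []
        for s in seeds:
            cfg = dataclasses.replace(base_config, stress_multiplier=float(mult), seed=int(s))
            trace = run_simulation(cfg)
            terminals.append(float(trace.frame["total_immune"].iloc[-1]))
        per_seed[float(mult)] = terminals
        medians.append(float(np.median(terminals)))
    result = locate_tipping_point(lam, np.array(medians))
    result.diagnostics["per_seed_terminals"] = per_seed
    return result


# ---------------------------------------------------------------------------
# the full validation report


def pom_report(
    high_config: SimulationConfig,
    control_config: SimulationConfig,
    seeds=range(20),
    pom: PomParams | None = None,
) -> dict:
    """Run all three patterns over a seed set and aggregate pass fractions.

    For each seed, one high-stress and one control run are paired: the
    decay and inversion patterns are evaluated on the high-stress trace,
    resolution failure on the pair.  The model passes overall iff every
    pattern's pass fraction reaches the required threshold (psi).
    Returns a JSON-serializable report.
    """
    pom = pom or high_config.pom
    seeds = list(seeds)
    results = {
        "nonlinear_decay": PatternResult("nonlinear_decay", []),
        "ratio_inversion": PatternResult("ratio_inversion", []),
        "resolution_failure": PatternResult("resolution_failure", []),
    }
    for s in seeds:
        hi = run_simulation(dataclasses.replace(high_config, seed=int(s)))
        lo = run_simulation(dataclasses.replace(control_config, seed=int(s)))
        ok, diag = pattern_nonlinear_decay(hi, aic_margin=pom.aic_margin)
        results["nonlinear_decay"].passes.append(ok)
        results["nonlinear_decay"].diagnostics.append(diag)
        ok, diag = pattern_ratio_inversion(hi, final_window_frac=pom.final_window_frac)
        results["ratio_inversion"].passes.append(ok)
        results["ratio_inversion"].diagnostics.append(diag)
        ok, diag = pattern_resolution_failure(hi, lo, clearance_frac=pom.clearance_frac)
        results["resolution_failure"].passes.append(ok)
        results["resolution_failure"].diagnostics.append(diag)
    report = {
        "seeds": [int(s) for s in seeds],
        "pass_fraction_required": pom.pass_fraction_required,
        "patterns": {
            name: {
                "pass_fraction": r.pass_fraction,
                "passes": [bool(b) for b in r.passes],
                "diagnostics": r.diagnostics,
            }
            for name, r in results.items()
        },
    }
    report["overall_pass"] = all(
        r.pass_fraction >= pom.pass_fraction_required for r in results.values()
    )
    return report
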