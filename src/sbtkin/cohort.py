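"""Synthetic crossover-cohort generator for breath-test simulation studies.

Emulates the design of a sucrase-isomaltase (SIM) inhibition crossover
experiment: each participant completes one breath test per dose condition
(no inhibitor, a mild-inhibition dose, a severe-inhibition dose), sampled
every 15 minutes for 4 hours.  A participant owns one baseline parameter
triple (rho, pi, kappa); inhibition acts multiplicatively on rho only, so
pi and kappa are shared across a participant's conditions and the dose
response is monotone by construction.  Observation noise is additive
Gaussian on the PDRr scale with SD 0.555 (the value used by the fitting
likelihood).

The generated ground-truth parameters are retained per curve so downstream
parameter-recovery and classifier-separation checks can compare estimates
against truth.  Dose-effect multipliers and baseline parameter distributions
are synthetic stand-ins chosen to produce realistic curve shapes (peaks
roughly between 0.7 and 2.5 h at baseline, often past the window under
severe inhibition); they are not estimates of any real population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import BreathCurve
from .pk_model import ModelParams, pdr_rate

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "default_schedule",
    "mixed_schedule",
    "draw_participant_params",
    "simulate_breath_curve",
    "generate_cohort",
    "cohort_to_frame",
    "ground_truth_frame",
]


def default_schedule() -> np.ndarray:
    """Sampling every 15 min from 0 to 4 h, in hours (17 samples)."""
    return np.arange(0, 241, 15) / 60.0


def mixed_schedule() -> np.ndarray:
    """Sensitivity schedule: every 15 min for hour 1, every 30 min to 4 h."""
    minutes = np.concatenate([np.arange(0, 61, 15), np.arange(90, 241, 30)])
    return minutes / 60.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic crossover cohort.

    ``dose_effects`` maps condition label -> multiplicative factor on rho
    (1.0 = no inhibition; smaller = stronger inhibition).  Baseline
    parameters are drawn per participant: rho and pi log-normal with the
    given medians and coefficients of variation, kappa uniform on
    ``kappa_range``.  ``spike_rate`` is the per-curve probability, in the
    most-inhibited condition, of injecting a late-time colonic-fermentation
    spike whose samples are pre-flagged as excluded.
    """

    n_participants: int = 16
    dose_effects: tuple[tuple[str, float], ...] = (
        ("0", 1.0),
        ("100", 0.8),
        ("750", 0.35),
    )
    rho_median: float = 1.3  # per hour
    rho_cv: float = 0.25
    pi_median: float = 0.6
    pi_cv: float = 0.30
    kappa_range: tuple[float, float] = (0.5, 0.8)
    schedule: tuple[float, ...] = tuple(default_schedule())
    sigma: float = 0.555
    spike_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if any(m <= 0 for _, m in self.dose_effects):
            raise ValueError("dose-effect multipliers must be > 0")
        if self.rho_median <= 0 or self.pi_median <= 0:
            raise ValueError("parameter medians must be > 0")
        if self.rho_cv <= 0 or self.pi_cv <= 0:
            raise ValueError("parameter CVs must be > 0")
        lo, hi = self.kappa_range
        if not (0 < lo < hi <= 1):
            raise ValueError("kappa_range must satisfy 0 < lo < hi <= 1")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size < 2 or np.any(np.diff(sched) <= 0) or sched[0] < 0:
            raise ValueError("schedule must be strictly increasing and >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike_rate must be in [0, 1]")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.dose_effects)


@dataclass(frozen=True)
class CohortDataset:
    """A generated cohort: curves plus the ground truth that produced them."""

    curves: tuple[BreathCurve, ...]
    true_params: dict  # (participant_id, condition) -> ModelParams
    config: CohortConfig


def _lognormal(median: float, cv: float, rng: np.random.Generator) -> float:
    # median m, CV c  =>  ln X ~ N(ln m, ln(1 + c^2))
    s = np.sqrt(np.log1p(cv**2))
    return float(median * np.exp(rng.normal(0.0, s)))


def draw_participant_params(
    config: CohortConfig, rng: np.random.Generator
) -> dict[str, ModelParams]:
    """Draw one baseline triple and derive the per-condition parameter sets.

    The dose multiplier scales rho only; pi and kappa are shared within the
    participant (crossover structure).
    """
    rho0 = _lognormal(config.rho_median, config.rho_cv, rng)
    pi0 = _lognormal(config.pi_median, config.pi_cv, rng)
    kappa0 = float(rng.uniform(*config.kappa_range))
    return {
        label: ModelParams(rho=rho0 * mult, pi_ratio=pi0, kappa=kappa0)
        for label, mult in config.dose_effects
    }


def simulate_breath_curve(
    params: ModelParams,
    schedule,
    sigma: float,
    rng: np.random.Generator,
    participant_id: str = "sim",
    condition: str = "0",
) -> BreathCurve:
    """One noisy observed curve: y(t_i) + eps_i, eps_i ~ N(0, sigma^2) i.i.d."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    t = np.asarray(schedule, dtype=float)
    clean = pdr_rate(params, t)
    noise = rng.normal(0.0, sigma, size=t.size) if sigma > 0 else 0.0
    return BreathCurve(
        participant_id=participant_id,
        condition=condition,
        times=t,
        values=clean + noise,
        excluded=np.zeros(t.size, dtype=bool),
    )


def _inject_spike(curve: BreathCurve, rng: np.random.Generator) -> BreathCurve:
    """Add a positive late-time bump, pre-flagged excluded."""
    n = curve.times.size
    start = rng.integers(max(n - 4, n // 2), n - 1)
    width = int(rng.integers(1, 3))
    idx = np.arange(start, min(start + width, n))
    values = curve.values.copy()
    values[idx] += rng.uniform(2.0, 5.0, size=idx.size)
    excluded = curve.excluded.copy()
    excluded[idx] = True
    return BreathCurve(
        participant_id=curve.participant_id,
        condition=curve.condition,
        times=curve.times,
        values=values,
        excluded=excluded,
    )


def generate_cohort(
    config: CohortConfig | None = None, rng: np.random.Generator | None = None
) -> CohortDataset:
    """Generate a complete crossover cohort with ground truth retained.

    Defaults produce 16 participants x 3 conditions = 48 curves of 17
    samples each.  Deterministic given ``config.seed`` (or an explicit rng).
    """
    config = config or CohortConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spike_condition = min(config.dose_effects, key=lambda kv: kv[1])[0]
    curves: list[BreathCurve] = []
    truth: dict[tuple[str, str], ModelParams] = {}
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        per_condition = draw_participant_params(config, rng)
        for label, params in per_condition.items():
            curve = simulate_breath_curve(
                params, config.schedule, config.sigma, rng, pid, label
            )
            if (
                label == spike_condition
                and config.spike_rate > 0
                and rng.random() < config.spike_rate
            ):
                curve = _inject_spike(curve, rng)
            curves.append(curve)
            truth[(pid, label)] = params
    return CohortDataset(curves=tuple(curves), true_params=truth, config=config)


def cohort_to_frame(dataset: CohortDataset) -> pd.DataFrame:
    """Long-format observation table matching the breath-curve CSV schema."""
    rows = []
    for c in dataset.curves:
        for t, v, e in zip(c.times, c.values, c.excluded):
            rows.append(
                {
                    "participant_id": c.participant_id,
                    "condition": c.condition,
                    "time_min": t * 60.0,
                    "pdr_pct_per_h": v,
                    "exclude": int(e),
                }
            )
    return pd.DataFrame(rows)


def ground_truth_frame(dataset: CohortDataset) -> pd.DataFrame:
    """Sidecar table of generating parameters, one row per curve."""
    rows = [
        {
            "participant_id": pid,
            "condition": cond,
            "rho_per_h": p.rho,
            "pi_ratio": p.pi_ratio,
            "kappa": p.kappa,
        }
        for (pid, cond), p in dataset.true_params.items()
    ]
    return pd.DataFrame(rows)
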