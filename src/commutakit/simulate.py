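"""Synthetic data generators for every analysis stage.

The generators emulate a material-qualification and proficiency-testing
campaign for blood glucose: native patient samples spanning normo- to
hyperglycaemia measured by a reference method and a meter, candidate
processed materials with optional matrix effects, vial-replicate
homogeneity tables, storage-time stability series and participant
result sets.  Defaults mirror the study designs the analysis modules
expect: 30 native samples over 60-350 mg/dL, reference-method SD of
1 mg/dL, 15 vials x 2 replicates for homogeneity, 5 vials per
checkpoint at days 0/30/60/90/120/150/180 for stability.

All randomness flows through a single integer seed; the same seed
yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (MaterialPoint, PairedSampleSet, PTResultSet,
                        ReplicateTable, StabilitySeries)

__all__ = [
    "MeterModel", "MatrixEffect", "SimulationConfig", "METER_PRESETS",
    "gen_native_pairs", "gen_material", "gen_pt_results",
    "gen_homogeneity", "gen_stability",
]


@dataclass(frozen=True)
class MeterModel:
    """Linear response model of a glucose meter.

    ``reading = slope * truth + intercept + noise`` with noise SD
    ``sqrt(sd_const^2 + (cv_prop * truth)^2)``.
    """

    label: str
    slope: float = 1.0
    intercept: float = 0.0
    cv_prop: float = 0.03
    sd_const: float = 1.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("meter slope must be positive")
        if self.cv_prop < 0 or self.sd_const < 0:
            raise ValueError("noise parameters must be nonnegative")

    def response(self, truth: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(truth, float) + self.intercept

    def noise_sd(self, truth: np.ndarray) -> np.ndarray:
        t = np.asarray(truth, float)
        return np.sqrt(self.sd_const ** 2 + (self.cv_prop * t) ** 2)


#: Illustrative (non-calibrated) meter presets spanning the bias range
#: typically seen across meter chemistries: slightly low, strongly low,
#: high, unbiased, very low.
METER_PRESETS: dict[str, MeterModel] = {
    "meter1": MeterModel("meter1", slope=0.955, cv_prop=0.012),
    "meter2": MeterModel("meter2", slope=0.82, cv_prop=0.025),
    "meter3": MeterModel("meter3", slope=1.16, cv_prop=0.04),
    "meter4": MeterModel("meter4", slope=1.0, cv_prop=0.045),
    "meter5": MeterModel("meter5", slope=0.78, cv_prop=0.025),
}


@dataclass(frozen=True)
class MatrixEffect:
    """Material-specific measurement bias seen only by the field method.

    ``additive`` shifts the meter reading by ``magnitude`` mg/dL;
    ``proportional`` scales it by ``1 + magnitude``.
    """

    mode: str = "additive"
    magnitude: float = 0.0

    def __post_init__(self):
        if self.mode not in ("additive", "proportional"):
            raise ValueError("mode must be 'additive' or 'proportional'")
        if self.mode == "proportional" and self.magnitude <= -1:
            raise ValueError("proportional magnitude must exceed -1")

    def apply(self, reading: np.ndarray) -> np.ndarray:
        r = np.asarray(reading, float)
        if self.mode == "additive":
            return r + self.magnitude
        return r * (1.0 + self.magnitude)


NO_EFFECT = MatrixEffect("additive", 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Campaign-level simulation parameters (all dispersions in mg/dL)."""

    seed: int = 0
    n_native: int = 30
    glucose_range: tuple[float, float] = (60.0, 350.0)
    ref_sd: float = 1.0
    n_participants: int = 300
    participant_cv: float = 0.035
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    sigma_bb: float = 0.5
    sigma_r: float = 1.5
    drift_slope: float = -0.02
    checkpoint_days: tuple[float, ...] = (0, 30, 60, 90, 120, 150, 180)
    n_stability_vials: int = 5

    def __post_init__(self):
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        for name in ("ref_sd", "sigma_bb", "sigma_r", "participant_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if len(self.checkpoint_days) == 0:
            raise ValueError("checkpoint_days must be nonempty")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(stream)]))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def gen_native_pairs(cfg: SimulationConfig,
                     meter: MeterModel) -> PairedSampleSet:
    """Native-sample method pairs: reference x vs meter y."""
    if cfg.n_native < 3:
        raise ValueError("need at least 3 native samples")
    lo, hi = cfg.glucose_range
    if not hi > lo > 0:
        raise ValueError("degenerate glucose range")
    rng = cfg.rng(1)
    truth = rng.uniform(lo, hi, cfg.n_native)
    x = truth + rng.normal(0.0, cfg.ref_sd, cfg.n_native)
    y = (meter.response(truth)
         + rng.normal(0.0, 1.0, cfg.n_native) * meter.noise_sd(truth))
    samples = [(f"s{i+1:03d}", xi, yi) for i, (xi, yi) in
               enumerate(zip(x, y))]
    return PairedSampleSet(samples, x_method="reference",
                           y_method=meter.label)


def gen_material(cfg: SimulationConfig, meter: MeterModel,
                 effect: MatrixEffect, true_level: float,
                 n_rep: int = 10,
                 material_id: str = "M1") -> MaterialPoint:
    """Candidate material characterised by both methods.

    The matrix effect perturbs only the meter readings — the mechanism
    that renders a processed material non-commutable.

    ``n_rep=1`` gives a single-measurement characterisation (SDs
    reported as 0); the commutability band is a band for a single new
    observation, so this is the setting in which its nominal error rate
    applies exactly.  Replicated characterisations average measurement
    noise and are flagged conservatively less often.
    """
    if n_rep < 1:
        raise ValueError("need at least 1 replicate per method")
    rng = cfg.rng(2)
    x_rep = true_level + rng.normal(0.0, cfg.ref_sd, n_rep)
    centre = effect.apply(meter.response(np.array([true_level])))[0]
    y_rep = centre + rng.normal(0.0, 1.0, n_rep) * meter.noise_sd(
        np.array([true_level]))[0]
    sd = (0.0, 0.0) if n_rep == 1 else (float(x_rep.std(ddof=1)),
                                        float(y_rep.std(ddof=1)))
    return MaterialPoint(material_id=material_id,
                         x_mean=float(x_rep.mean()), x_sd=sd[0],
                         y_mean=float(y_rep.mean()), y_sd=sd[1],
                         x_n=n_rep, y_n=n_rep)


def gen_pt_results(cfg: SimulationConfig, meter: MeterModel,
                   true_level: float, scheme_id: str = "scheme1",
                   material_id: str = "M1") -> PTResultSet:
    """Participant results for one meter group on one material."""
    if cfg.n_participants < 3:
        raise ValueError("need at least 3 participants")
    rng = cfg.rng(3)
    centre = float(meter.response(np.array([true_level]))[0])
    sd = float(np.sqrt(meter.sd_const ** 2
                       + (cfg.participant_cv * true_level) ** 2))
    vals = centre + rng.normal(0.0, sd, cfg.n_participants)
    n_out = int(round(cfg.outlier_fraction * cfg.n_participants))
    if n_out:
        idx = rng.choice(cfg.n_participants, n_out, replace=False)
        vals[idx] = cfg.outlier_scale * true_level
    vals = np.maximum(vals, 1.0)  # meters never report nonpositive glucose
    results = [(f"p{i+1:04d}", v) for i, v in enumerate(vals)]
    return PTResultSet(scheme_id, material_id, meter.label, results)


def gen_homogeneity(cfg: SimulationConfig, true_level: float,
                    a: int = 15, n: int = 2,
                    material_id: str = "M1") -> ReplicateTable:
    """Vial-replicate table with between-vial SD sigma_bb and
    repeatability SD sigma_r."""
    if a < 2 or n < 2:
        raise ValueError("need a >= 2 vials and n >= 2 replicates")
    rng = cfg.rng(4)
    vial_means = true_level + rng.normal(0.0, cfg.sigma_bb, a)
    values = vial_means[:, None] + rng.normal(0.0, cfg.sigma_r, (a, n))
    values = np.maximum(values, 1.0)
    rows = [(f"v{i+1:02d}", values[i].tolist()) for i in range(a)]
    return ReplicateTable(material_id, rows)


def gen_stability(cfg: SimulationConfig, true_level: float,
                  material_id: str = "M1") -> StabilitySeries:
    """Stability series: linear drift plus vial and repeatability noise."""
    rng = cfg.rng(5)
    recs = []
    for day in cfg.checkpoint_days:
        centre = true_level + cfg.drift_slope * day
        vals = centre + rng.normal(
            0.0, np.hypot(cfg.sigma_bb, cfg.sigma_r),
            cfg.n_stability_vials)
        vals = np.maximum(vals, 1.0)
        for j, v in enumerate(vals):
            recs.append((float(day), f"v{j+1:02d}", float(v)))
    return StabilitySeries(material_id, recs)
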