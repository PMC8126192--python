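"""Synthetic OhioT1DM-style subjects with known ground truth.

The real dataset is under a data-use agreement, so every pipeline stage is
exercised on simulated subjects instead.  The simulator reproduces the data
*semantics* that matter for the recommendation task, not human physiology:

* glucose follows a linear state-space model: a mean-reverting deviation from
  an equilibrium level, driven by per-step exogenous increments from
  triangular carbohydrate and insulin response kernels (each kernel's
  increments sum to 1 over its support, so a meal of ``c`` grams contributes a
  total accumulated rise of ``c * k_c`` mg/dL before reversion);
* a simulated bolus wizard doses meals from per-time-of-day carb ratios and
  insulin sensitivities, its recommendation overridden for ~20% of boluses;
* pump streams (boluses, basal, CGM) are ground-truth timed, while smartphone
  meal logs are jittered, mis-estimated and sometimes missing - exactly the
  mess the anchoring pre-processing step is meant to clean up;
* CGM has Gaussian noise and day-level dropout gaps.

Because the glucose model is linear in the events, the exact carb amount or
bolus dose needed to hit a target glucose at a given horizon has a closed
form (:func:`oracle_recommendation`), which the learned models can be
compared against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .example_builder import tod_interval
from .timeseries_core import (
    DAY, STEP, BasalSegment, BolusEvent, GlucoseSample, MealEvent,
    SubjectRecord, write_subject,
)

logger = logging.getLogger("bolusrec")

BINS_PER_DAY = DAY // STEP


class InfeasibleError(ValueError):
    """The requested target cannot be reached with a nonnegative dose/carbs."""


@dataclass
class SimConfig:
    seed: int = 0
    days: int = 55
    # per time-of-day window (1..5): carb ratio g/u and insulin sensitivity
    # mg/dL per u.  ISF ~ k_c * CR keeps bolus-wizard meals roughly BG-neutral.
    cr: tuple = (10.0, 8.0, 9.0, 10.0, 11.0)
    isf: tuple = (36.0, 28.0, 32.0, 34.0, 38.0)
    bg_target: float = 110.0
    bg_equilibrium: float = 120.0
    reversion: float = 0.05          # fraction of deviation removed per 5-min step
    carb_peak: int = 45              # min
    carb_support: int = 180          # min
    carb_potency: float = 3.5        # mg/dL per g, total accumulated rise
    insulin_peak: int = 75           # min
    insulin_support: int = 300       # min
    cgm_noise_sd: float = 5.0        # mg/dL
    gap_prob: float = 0.3            # per-day probability of a CGM gap
    gap_len: tuple = (15, 120)       # min
    # meal schedule: (mean wall-clock minute, jitter, mean carbs g, sd)
    meals: tuple = ((450, 45, 45.0, 15.0), (750, 45, 60.0, 20.0),
                    (1110, 60, 70.0, 20.0))
    meal_prob: float = 0.95
    snack_prob: float = 0.4          # unbolused afternoon/evening snack
    snack_carbs: tuple = (15.0, 5.0)
    bedtime_snack_prob: float = 0.3  # unbolused ~22:30 snack
    hypo_threshold: float = 70.0     # BG below this triggers a 16 g correction
    hypo_carbs: float = 16.0
    log_jitter: tuple = (-30, 20)    # smartphone meal timestamp error, min
    log_missing_prob: float = 0.15
    log_carb_error: tuple = (0.8, 1.2)   # smartphone carb misestimation factor
    bw_override_prob: float = 0.2
    bw_override_mult: tuple = (0.8, 1.2)
    dual_prob: float = 0.05
    basal_rate: float = 1.0          # u/h, modulated per segment

    def validate(self) -> "SimConfig":
        for p in (self.gap_prob, self.meal_prob, self.snack_prob,
                  self.bedtime_snack_prob, self.log_missing_prob,
                  self.bw_override_prob, self.dual_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if not 0.0 <= self.reversion < 1.0:
            raise ValueError("reversion must be in [0,1)")
        return self


@dataclass
class SimTruth:
    """Ground truth behind one simulated record."""
    config: SimConfig
    true_meals: list = field(default_factory=list)     # (time, carbs, bolused)
    true_boluses: list = field(default_factory=list)   # (time, delivered, recommended)
    true_bg: np.ndarray = None                         # noise-free, per bin
    n_bins: int = 0


# ---------------------------------------------------------------------------
# Kernels and linear responses
# ---------------------------------------------------------------------------

def triangular_kernel(peak_min: int, support_min: int) -> np.ndarray:
    """Per-bin exogenous increments: triangular in time, zero at lag 0,
    peaking at ``peak_min``, back to zero at ``support_min``; sums to 1."""
    m = np.arange(support_min // STEP + 1) * STEP
    k = np.where(m <= peak_min, m / peak_min,
                 np.clip((support_min - m) / (support_min - peak_min), 0, None))
    k[0] = 0.0
    return k / k.sum()


def unit_response(kernel: np.ndarray, reversion: float, n: int) -> np.ndarray:
    """Cumulative effect at lag l of a unit event: the kernel increments
    convolved with geometric mean-reversion decay."""
    r = np.zeros(n)
    decay = 1.0 - reversion
    prev = 0.0
    for l in range(n):
        prev = decay * prev + (kernel[l] if l < len(kernel) else 0.0)
        r[l] = prev
    return r


def simulate_bg(config: SimConfig, meals, boluses, n_bins: int,
                isf_of=None) -> np.ndarray:
    """Noise-free glucose from given (time, carbs) meals and (time, dose)
    boluses, by the mean-reverting linear recursion."""
    kc = triangular_kernel(config.carb_peak, config.carb_support)
    ki = triangular_kernel(config.insulin_peak, config.insulin_support)
    inp = np.zeros(n_bins + len(ki) + len(kc))
    for t, carbs in meals:
        k0 = int(t) // STEP
        inp[k0:k0 + len(kc)] += carbs * config.carb_potency * kc
    for t, dose in boluses:
        k0 = int(t) // STEP
        isf = isf_of(int(t)) if isf_of else config.isf[tod_interval(int(t) % DAY) - 1]
        inp[k0:k0 + len(ki)] -= dose * isf * ki
    bg = np.empty(n_bins)
    dev = 0.0
    decay = 1.0 - config.reversion
    for k in range(n_bins):
        dev = decay * dev + inp[k]
        bg[k] = config.bg_equilibrium + dev
    return bg


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

def simulate_subject_with_truth(config: SimConfig,
                                subject_id: str | None = None
                                ) -> tuple[SubjectRecord, SimTruth]:
    """Simulate one subject; returns the raw (pre-anchoring) record plus the
    ground truth.  Same seed, same record."""
    config.validate()
    if config.days < 21:
        logger.warning("simulating %d days < 21: chronological split will fail",
                       config.days)
    rng = np.random.default_rng(config.seed)
    n = config.days * BINS_PER_DAY
    kc = triangular_kernel(config.carb_peak, config.carb_support)
    ki = triangular_kernel(config.insulin_peak, config.insulin_support)
    decay = 1.0 - config.reversion

    # plan the meal schedule (times in minutes, on the 5-min grid)
    planned = []    # (bin, carbs, bolused)
    for d in range(config.days):
        for mean_t, jit, mu, sd in config.meals:
            if rng.random() < config.meal_prob:
                t = d * DAY + mean_t + rng.uniform(-jit, jit)
                c = float(np.clip(rng.normal(mu, sd), 10, 150))
                planned.append((int(round(t / STEP)), round(c), True))
        if rng.random() < config.snack_prob:
            t = d * DAY + rng.uniform(840, 1320)
            c = float(np.clip(rng.normal(*config.snack_carbs), 5, 40))
            planned.append((int(round(t / STEP)), round(c), False))
        if rng.random() < config.bedtime_snack_prob:
            t = d * DAY + 1350 + rng.uniform(-20, 20)
            planned.append((int(round(t / STEP)), round(float(np.clip(
                rng.normal(20, 5), 5, 40))), False))
    planned.sort()
    meal_at = {}
    for k, c, bolused in planned:
        if 2 <= k < n - 1 and k not in meal_at:
            meal_at[k] = (c, bolused)

    truth = SimTruth(config=config, n_bins=n)
    inp = np.zeros(n + len(ki) + len(kc) + 1)
    bg = np.empty(n)
    dev = 0.0
    last_hypo = -1000
    last_corr = -1000
    boluses: list[BolusEvent] = []
    true_meal_list = []

    def tod_params(minute):
        k = tod_interval(minute % DAY) - 1
        return config.cr[k], config.isf[k]

    for k in range(n):
        dev = decay * dev + inp[k]
        g = config.bg_equilibrium + dev
        bg[k] = g
        t_min = k * STEP
        # bolus 10 min (2 bins) before each planned, bolused meal
        nxt = meal_at.get(k + 2)
        if nxt is not None and nxt[1]:
            carbs = nxt[0]
            cr, isf = tod_params(t_min)
            rec_dose = carbs / cr + max(0.0, g - config.bg_target) / isf
            dose = rec_dose
            if rng.random() < config.bw_override_prob:
                dose *= rng.uniform(*config.bw_override_mult)
            dose = max(0.1, round(dose, 1))
            kind = "dual" if rng.random() < config.dual_prob else "normal"
            boluses.append(BolusEvent(time=t_min, dose=dose, kind=kind,
                                      bw_carb_input=float(carbs)))
            truth.true_boluses.append((t_min, dose, round(rec_dose, 1)))
            inp[k: k + len(ki)] -= dose * isf * ki
        # correction bolus for marked hyperglycemia (no carbs entered)
        elif g > 240 and k - last_corr > 24 and (k + 2) not in meal_at:
            _, isf = tod_params(t_min)
            dose = max(0.1, round((g - config.bg_target) / isf, 1))
            boluses.append(BolusEvent(time=t_min, dose=dose, kind="normal",
                                      bw_carb_input=None))
            truth.true_boluses.append((t_min, dose, dose))
            inp[k: k + len(ki)] -= dose * isf * ki
            last_corr = k
        if k in meal_at:
            carbs = meal_at[k][0]
            true_meal_list.append((t_min, float(carbs), meal_at[k][1]))
            inp[k: k + len(kc)] += carbs * config.carb_potency * kc
        # hypo correction: fixed carbs, no bolus, 1 h refractory
        if g < config.hypo_threshold and k - last_hypo > 12:
            true_meal_list.append((t_min, config.hypo_carbs, False))
            inp[k: k + len(kc)] += config.hypo_carbs * config.carb_potency * kc
            last_hypo = k

    truth.true_bg = bg
    truth.true_meals = sorted(true_meal_list)

    # CGM stream: noise + day-level gaps
    noise = rng.normal(0.0, config.cgm_noise_sd, size=n) if config.cgm_noise_sd > 0 \
        else np.zeros(n)
    cgm = np.clip(bg + noise, 40.0, None)
    keep = np.ones(n, dtype=bool)
    for d in range(config.days):
        if rng.random() < config.gap_prob:
            length = int(rng.uniform(*config.gap_len)) // STEP
            start = d * BINS_PER_DAY + rng.integers(0, BINS_PER_DAY - length)
            keep[start:start + length] = False
    keep[0] = keep[n - 1] = True    # anchor the record span
    glucose = [GlucoseSample(time=k * STEP, value=float(cgm[k]))
               for k in range(n) if keep[k]]

    # smartphone meal log: jittered, mis-estimated, sometimes missing
    meals = []
    for t, carbs, _ in truth.true_meals:
        if rng.random() < config.log_missing_prob:
            continue
        jt = int(round(t + rng.uniform(*config.log_jitter)))
        jc = max(1.0, round(carbs * rng.uniform(*config.log_carb_error)))
        meals.append(MealEvent(time=max(0, jt), carbs=jc, source="smartphone"))
    meals.sort(key=lambda m: m.time)

    # basal: piecewise-constant profile
    basal = []
    t = 0
    while t < n * STEP:
        seg_len = int(rng.uniform(6, 18)) * 60
        rate = round(config.basal_rate * rng.uniform(0.7, 1.3), 2)
        basal.append(BasalSegment(start=t, end=min(t + seg_len, n * STEP), rate=rate))
        t += seg_len

    record = SubjectRecord(
        subject_id=subject_id or f"sim{config.seed:03d}",
        glucose=glucose, boluses=boluses, meals=meals, basal=basal,
        start_clock=0)
    return record.validate(), truth


def simulate_subject(config: SimConfig) -> SubjectRecord:
    """Simulate one raw subject record (see :func:`simulate_subject_with_truth`)."""
    return simulate_subject_with_truth(config)[0]


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------

def oracle_recommendation(truth: SimTruth, t: int, scenario: str, tau: int,
                          target_bg: float, config: SimConfig | None = None,
                          planned_carbs: float | None = None) -> float:
    """Exact event magnitude at ``t+10`` that drives the noise-free glucose to
    ``target_bg`` at ``t+10+tau``.

    The no-action trajectory keeps all ground-truth events up to ``t`` (their
    kernel tails persist) plus, for ``bolus_p_c``, the planned meal at
    ``t+20``; by linearity the queried event's effect at lag ``tau`` is its
    magnitude times the unit response, so the answer is a single division.
    Raises :class:`InfeasibleError` if a negative amount would be required.
    """
    cfg = config or truth.config
    target_t = t + 10 + tau
    n_bins = target_t // STEP + 1
    meals = [(tt, c) for tt, c, _ in truth.true_meals if tt <= t]
    boluses = [(tt, d) for tt, d, _ in truth.true_boluses if tt <= t]
    if scenario == "bolus_p_c":
        if planned_carbs is None:
            raise ValueError("bolus_p_c oracle needs planned_carbs")
        meals.append((t + 20, planned_carbs))
    base = simulate_bg(cfg, meals, boluses, n_bins)[target_t // STEP]
    lag = tau // STEP
    if scenario in ("bolus_pm_c", "bolus_p_c"):
        resp = unit_response(triangular_kernel(cfg.insulin_peak, cfg.insulin_support),
                             cfg.reversion, lag + 1)[lag]
        isf = cfg.isf[tod_interval((t + 10) % DAY) - 1]
        value = (base - target_bg) / (isf * resp)
    elif scenario in ("carbs_pm_b", "carbs_m_b"):
        resp = unit_response(triangular_kernel(cfg.carb_peak, cfg.carb_support),
                             cfg.reversion, lag + 1)[lag]
        value = (target_bg - base) / (cfg.carb_potency * resp)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if value < 0:
        raise InfeasibleError(
            f"target {target_bg} mg/dL at tau={tau} needs a negative amount "
            f"({value:.2f}); no-action BG is {base:.1f}")
    return float(value)


# ---------------------------------------------------------------------------
# Benchmark generation
# ---------------------------------------------------------------------------

def make_benchmark(n_subjects: int = 12, seed: int = 42, days: int = 55,
                   out=None, force: bool = False, **overrides):
    """Simulate an OhioT1DM-shaped benchmark of ``n_subjects`` subjects.

    Returns ``(records, truths, manifest)``; when ``out`` is given, each
    subject is written in both the XML and CSV dialects together with a
    ground-truth manifest (JSON) of per-subject event counts and parameters.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_subjects) % (2 ** 31)
    records, truths, subjects = [], [], []
    for i in range(n_subjects):
        rng = np.random.default_rng(child_seeds[2 * i])
        f = rng.uniform(0.8, 1.2)
        cfg = SimConfig(seed=int(child_seeds[2 * i + 1]), days=days,
                        cr=tuple(round(c * f, 1) for c in SimConfig.cr),
                        isf=tuple(round(s * f, 1) for s in SimConfig.isf),
                        **overrides)
        rec, truth = simulate_subject_with_truth(cfg, subject_id=f"sim{seed}_{i:02d}")
        records.append(rec)
        truths.append(truth)
        n_bolused = sum(1 for _, _, b in truth.true_meals if b)
        subjects.append({
            "subject_id": rec.subject_id, "days": days,
            "meals_total": len(truth.true_meals),
            "meals_without_bolus": len(truth.true_meals) - n_bolused,
            "boluses_total": len(rec.boluses),
            "boluses_with_meal": n_bolused,
            "logged_meals": len(rec.meals),
            "cgm_samples": len(rec.glucose),
            "config": {k: v for k, v in asdict(cfg).items()},
        })
    manifest = {"seed": seed, "n_subjects": n_subjects, "subjects": subjects}
    if out is not None:
        d = Path(out)
        if d.exists() and any(d.iterdir()) and not force:
            raise FileExistsError(f"{d} exists; pass force=True to overwrite")
        d.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_subject(rec, d / f"{rec.subject_id}.xml", format="ohio_xml")
            write_subject(rec, d / rec.subject_id, format="csv")
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return records, truths, manifest
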