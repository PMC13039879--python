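"""Synthetic pupil recordings and EEG epochs with a known effect structure.

The generator emulates the measurement model the analysis assumes:

* two-eye pupil traces at 300 Hz with a tonic level (subject intercept,
  per-group offsets, within-block drift, optional after-manipulation
  shift per group), a gamma-shaped stimulus-evoked dilation peaking
  around 900 ms, white measurement noise, blink gaps and speed-spike
  artifacts;
* five-channel epochs (Fz, FC1, FC2, FCz, Cz) at 500 Hz over
  [-500, 800] ms with a Gaussian negative deflection in 100-150 ms, a
  Gaussian positive deflection in 150-250 ms, a per-subject DC offset
  and 1/f-plus-white noise.

Ground-truth per-trial feature values are recorded alongside each trial
so downstream stages can be tested for recovery.  Numeric defaults are
generator choices, not empirical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .erp import Epoch
from .pupil_prep import PupilSeries
from .task_design import TaskSchedule, TrialSpec, build_schedule

GROUPS = ("ASD", "CON", "MHC")
EEG_CHANNELS = ("Fz", "FC1", "FC2", "FCz", "Cz")

#: oddball fraction among all 103 trials of a block (20 of 103)
ODDBALL_FRACTION = 20.0 / 103.0


def _zero_groups() -> dict[str, float]:
    return {g: 0.0 for g in GROUPS}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic cohort generator (all units in field names)."""

    pupil_rate_hz: float = 300.0
    eeg_rate_hz: float = 500.0

    # tonic pupil level
    baseline_mm: float = 4.5
    group_baseline_offset_mm: dict[str, float] = field(default_factory=_zero_groups)
    tonic_drift_mm_per_min: float = -0.05
    bps_trial_jitter_mm: float = 0.0  # slow arousal fluctuation, per trial
    subject_bps_sd_mm: float = 0.25
    group_bps_manipulation_shift_mm: dict[str, float] = field(
        default_factory=_zero_groups
    )

    # stimulus-evoked dilation (gamma kernel, peak normalised to 1)
    sepr_amp_mm: float = 0.08
    sepr_oddball_increment_mm: float = 0.04
    sepr_trial_sd_mm: float = 0.03
    sepr_peak_ms: float = 900.0
    sepr_kernel_shape: float = 3.0

    # pupil artifacts / noise
    blink_rate_per_min: float = 6.0
    blink_duration_range_ms: tuple[float, float] = (90.0, 240.0)
    artifact_spike_rate_per_min: float = 2.0
    spike_amp_mm: float = 1.5
    pupil_noise_sd_mm: float = 0.02

    # ERP components (Gaussian shapes)
    mmn_amp_uv: float = 1.0
    mmn_oddball_increment_uv: float = 1.0
    mmn_peak_ms: float = 130.0
    mmn_width_ms: float = 18.0
    mmn_trial_sd_uv: float = 0.3
    p3a_amp_uv: float = 1.5
    p3a_oddball_increment_uv: float = 0.8
    p3a_peak_ms: float = 200.0
    p3a_width_ms: float = 25.0
    p3a_trial_sd_uv: float = 0.3
    subject_erp_sd_uv: float = 1.0
    eeg_noise_uv: float = 3.0
    eeg_pink_fraction: float = 0.6
    epoch_window_ms: tuple[float, float] = (-500.0, 800.0)

    missing_trial_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pupil_rate_hz <= 0 or self.eeg_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        lo, hi = self.blink_duration_range_ms
        if not (40.0 <= lo <= hi <= 600.0):
            raise ValueError("blink_duration_range_ms must lie within [40, 600]")
        for name in (
            "subject_bps_sd_mm", "bps_trial_jitter_mm",
            "sepr_trial_sd_mm", "pupil_noise_sd_mm",
            "mmn_trial_sd_uv", "p3a_trial_sd_uv", "subject_erp_sd_uv",
            "eeg_noise_uv", "blink_rate_per_min", "artifact_spike_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_trial_rate < 1.0:
            raise ValueError("missing_trial_rate must be in [0, 1)")
        if not 0.0 <= self.eeg_pink_fraction <= 1.0:
            raise ValueError("eeg_pink_fraction must be in [0, 1]")


@dataclass
class SubjectEffects:
    """Per-subject random effects."""

    bps_intercept_mm: float = 0.0
    erp_intercept_uv: float = 0.0


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age_years: float
    gender: str
    schedule: TaskSchedule
    trials: list[TrialSpec]
    pupil: list[PupilSeries | None]
    epochs: list[Epoch | None]
    truth: pd.DataFrame  # one row per trial with ground-truth features


def dilation_kernel(t_ms: np.ndarray, peak_ms: float, shape: float) -> np.ndarray:
    """Gamma-shaped dilation kernel, zero before onset, peak value 1 at
    ``peak_ms``."""
    t = np.asarray(t_ms, dtype=float)
    x = np.clip(t / peak_ms, 0.0, None)
    out = np.where(t > 0, x**shape * np.exp(shape * (1.0 - x)), 0.0)
    return out


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


_KERNEL_CACHE: dict[tuple, np.ndarray] = {}
_ERP_SHAPE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _cached_kernel(dt: float, peak_ms: float, shape: float, n: int) -> np.ndarray:
    key = (dt, peak_ms, shape)
    k = _KERNEL_CACHE.get(key)
    if k is None or len(k) < n:
        grid = np.arange(max(n, int(2400.0 / dt))) * dt
        k = dilation_kernel(grid, peak_ms, shape)
        _KERNEL_CACHE[key] = k
    return k[:n]


def _cached_erp_shapes(
    params: "GeneratorParams",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    key = (
        params.eeg_rate_hz, params.epoch_window_ms,
        params.mmn_peak_ms, params.mmn_width_ms,
        params.p3a_peak_ms, params.p3a_width_ms,
    )
    cached = _ERP_SHAPE_CACHE.get(key)
    if cached is None:
        tmin, tmax = params.epoch_window_ms
        dt = 1000.0 / params.eeg_rate_hz
        n = int(round((tmax - tmin) / dt))
        t = tmin + np.arange(n) * dt
        post = (t > 0).astype(float)
        g_mmn = post * _gauss(t, params.mmn_peak_ms, params.mmn_width_ms)
        g_p3a = post * _gauss(t, params.p3a_peak_ms, params.p3a_width_ms)
        cached = (t, g_mmn, g_p3a)
        _ERP_SHAPE_CACHE[key] = cached
    return cached


def simulate_pupil_trial(
    params: GeneratorParams,
    trial: TrialSpec,
    subject_effects: SubjectEffects,
    rng: np.random.Generator,
    *,
    group: str = "CON",
) -> tuple[PupilSeries, dict[str, float]]:
    """Generate one trial's two-eye pupil series plus ground truth.

    Truth values (``true_bps``, ``true_sepr``) are the noise-free signal
    means over the analysis windows on the generated grid.
    """
    dt = 1000.0 / params.pupil_rate_hz
    duration = trial.tone_duration_ms + trial.isi_ms
    t = np.arange(0.0, duration, dt)
    n = len(t)

    level = (
        params.baseline_mm
        + params.group_baseline_offset_mm.get(group, 0.0)
        + subject_effects.bps_intercept_mm
        + params.tonic_drift_mm_per_min * (trial.onset_ms / 60000.0)
    )
    if trial.manipulation_phase == "after":
        level += params.group_bps_manipulation_shift_mm.get(group, 0.0)
    if params.bps_trial_jitter_mm > 0:
        level += rng.normal(0.0, params.bps_trial_jitter_mm)

    amp = params.sepr_amp_mm + rng.normal(0.0, params.sepr_trial_sd_mm)
    if trial.stimulus == "oddball":
        amp += params.sepr_oddball_increment_mm
    kernel = _cached_kernel(dt, params.sepr_peak_ms, params.sepr_kernel_shape, n)
    clean = level + amp * kernel

    base_mask = (t >= 0.0) & (t < 250.0)
    resp_mask = (t >= 500.0) & (t < 1500.0)
    true_bps = float(np.mean(clean[base_mask]))
    true_sepr = float(np.mean(clean[resp_mask]) - true_bps)

    left = clean + rng.normal(0.0, params.pupil_noise_sd_mm, n)
    right = clean + rng.normal(0.0, params.pupil_noise_sd_mm, n)
    valid_l = np.ones(n, dtype=bool)
    valid_r = np.ones(n, dtype=bool)

    # blinks hit both eyes
    dur_min = duration / 60000.0
    for _ in range(rng.poisson(params.blink_rate_per_min * dur_min)):
        length = rng.uniform(*params.blink_duration_range_ms)
        start = rng.uniform(0.0, max(duration - length, 0.0))
        gap = (t >= start) & (t < start + length)
        left[gap] = np.nan
        right[gap] = np.nan
        valid_l[gap] = False
        valid_r[gap] = False

    # isolated speed-spike artifacts, independent per eye
    for vals in (left, right):
        for _ in range(rng.poisson(params.artifact_spike_rate_per_min * dur_min)):
            i = rng.integers(0, n)
            vals[i] += rng.choice((-1.0, 1.0)) * params.spike_amp_mm

    series = PupilSeries(
        t=t, left_mm=left, right_mm=right, valid_l=valid_l, valid_r=valid_r
    )
    return series, {"true_bps": true_bps, "true_sepr": true_sepr}


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def simulate_eeg_epoch(
    params: GeneratorParams,
    trial: TrialSpec,
    subject_effects: SubjectEffects,
    rng: np.random.Generator,
) -> tuple[Epoch, dict[str, float]]:
    """Generate one epoch (channels x time) plus ground-truth amplitudes.

    The negative and positive deflections are identical across channels;
    truth records the underlying component amplitudes in microvolts.
    """
    t, g_mmn, g_p3a = _cached_erp_shapes(params)
    tmin = params.epoch_window_ms[0]
    n = len(t)

    mmn = params.mmn_amp_uv + rng.normal(0.0, params.mmn_trial_sd_uv)
    p3a = params.p3a_amp_uv + rng.normal(0.0, params.p3a_trial_sd_uv)
    if trial.stimulus == "oddball":
        mmn += params.mmn_oddball_increment_uv
        p3a += params.p3a_oddball_increment_uv

    comp = -mmn * g_mmn + p3a * g_p3a

    if params.eeg_noise_uv > 0:
        data = np.empty((len(EEG_CHANNELS), n))
        for c in range(len(EEG_CHANNELS)):
            pink = _pink_noise(n, rng)
            white = rng.standard_normal(n)
            f = params.eeg_pink_fraction
            noise = params.eeg_noise_uv * (
                np.sqrt(f) * pink + np.sqrt(1.0 - f) * white
            )
            data[c] = subject_effects.erp_intercept_uv + comp + noise
    else:
        data = np.empty((len(EEG_CHANNELS), n))
        data[:] = subject_effects.erp_intercept_uv + comp

    epoch = Epoch(EEG_CHANNELS, data, params.eeg_rate_hz, tmin)
    return epoch, {"true_mmn_amp": -mmn, "true_p3a_amp": p3a}


def simulate_cohort(
    params: GeneratorParams,
    n_per_group: tuple[int, int, int] = (52, 55, 43),
    seed: int = 0,
    *,
    blocks: tuple[int, ...] | None = None,
    with_eeg: bool = True,
) -> list[SubjectRecord]:
    """Simulate a full cohort; deterministic under ``seed``.

    ``blocks`` restricts generation to a subset of task blocks (useful
    for reduced-scale simulation studies).
    """
    if any(n < 1 for n in n_per_group):
        raise ValueError("group counts must be >= 1")
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(int(sum(n_per_group)))

    records: list[SubjectRecord] = []
    i = 0
    for group, count in zip(GROUPS, n_per_group):
        for _ in range(count):
            ss = subject_seeds[i]
            rng = np.random.default_rng(ss)
            subject_id = f"S{i + 1:03d}"
            schedule = build_schedule(
                subject_id, int(ss.generate_state(1, np.uint32)[0])
            )
            effects = SubjectEffects(
                bps_intercept_mm=rng.normal(0.0, params.subject_bps_sd_mm),
                erp_intercept_uv=rng.normal(0.0, params.subject_erp_sd_uv),
            )
            age = float(rng.uniform(12.0, 18.0))
            gender = str(rng.choice(("f", "m")))

            trials = [
                tr
                for tr in schedule.trials
                if blocks is None or tr.block in blocks
            ]
            pupil: list[PupilSeries | None] = []
            epochs: list[Epoch | None] = []
            truth_rows = []
            for tr in trials:
                if rng.uniform() < params.missing_trial_rate:
                    pupil.append(None)
                    epochs.append(None)
                    truth_rows.append(
                        {"true_bps": np.nan, "true_sepr": np.nan,
                         "true_mmn_amp": np.nan, "true_p3a_amp": np.nan}
                    )
                    continue
                series, p_truth = simulate_pupil_trial(
                    params, tr, effects, rng, group=group
                )
                pupil.append(series)
                row = dict(p_truth)
                if with_eeg:
                    epoch, e_truth = simulate_eeg_epoch(params, tr, effects, rng)
                    epochs.append(epoch)
                    row.update(e_truth)
                else:
                    epochs.append(None)
                    row.update({"true_mmn_amp": np.nan, "true_p3a_amp": np.nan})
                truth_rows.append(row)

            truth = pd.DataFrame(truth_rows)
            truth.insert(0, "subject_id", subject_id)
            truth.insert(1, "block", [tr.block for tr in trials])
            truth.insert(2, "index_in_block", [tr.index_in_block for tr in trials])
            records.append(
                SubjectRecord(
                    subject_id=subject_id,
                    group=group,
                    age_years=age,
                    gender=gender,
                    schedule=schedule,
                    trials=trials,
                    pupil=pupil,
                    epochs=epochs,
                    truth=truth,
                )
            )
            i += 1
    return records


# ---------------------------------------------------------------------------
# analytic effect-size helpers (for recovery studies)
# ---------------------------------------------------------------------------

def clean_params() -> GeneratorParams:
    """Artifact-free preset under which the analytic effect-size formulas
    of :func:`implied_standardized_effects` are exact (no blinks, spikes,
    drift, missing trials or EEG noise).

    The subject-intercept SD is kept small relative to trial-level noise
    so the grand SD used for standardization is estimated precisely even
    in small cohorts; otherwise the cohort-specific scaling would drift
    away from the population standardized effect and CI coverage of the
    fixed truth would be lost.
    """
    return GeneratorParams(
        tonic_drift_mm_per_min=0.0,
        bps_trial_jitter_mm=0.02,
        subject_bps_sd_mm=0.003,
        blink_rate_per_min=0.0,
        artifact_spike_rate_per_min=0.0,
        pupil_noise_sd_mm=0.015,
        sepr_trial_sd_mm=0.03,
        mmn_trial_sd_uv=0.3,
        p3a_oddball_increment_uv=0.0,
        p3a_trial_sd_uv=0.0,
        eeg_noise_uv=0.0,
        missing_trial_rate=0.0,
    )


def _pupil_window_stats(params: GeneratorParams) -> tuple[float, float, int, int]:
    dt = 1000.0 / params.pupil_rate_hz
    t = np.arange(0.0, 1900.0, dt)
    k = dilation_kernel(t, params.sepr_peak_ms, params.sepr_kernel_shape)
    base = (t >= 0.0) & (t < 250.0)
    resp = (t >= 500.0) & (t < 1500.0)
    k0 = float(k[base].mean())
    kw = float(k[resp].mean())
    return k0, kw, int(base.sum()), int(resp.sum())


def implied_standardized_effects(
    params: GeneratorParams,
    n_per_group: tuple[int, int, int],
    blocks: tuple[int, ...] = (1, 2, 3, 4),
) -> dict[str, object]:
    """Population standardized effect sizes implied by the generator.

    Valid for artifact-free settings (see :func:`clean_params`): zero
    drift, blink/spike/missing rates, EEG noise, and no P3a jitter or
    oddball increment (the P3a tail then cancels in the MMN contrast).
    Returns the standardized oddball-standard contrast on SEPR and MMN
    amplitude, and the after-before BPS contrast per group.
    """
    for name in (
        "tonic_drift_mm_per_min", "blink_rate_per_min",
        "artifact_spike_rate_per_min", "missing_trial_rate",
        "eeg_noise_uv", "p3a_trial_sd_uv", "p3a_oddball_increment_uv",
    ):
        if getattr(params, name) != 0.0:
            raise ValueError(
                f"analytic effects require {name} == 0 (got"
                f" {getattr(params, name)})"
            )

    k0, kw, m_b, m_w = _pupil_window_stats(params)
    gain = kw - k0
    p = ODDBALL_FRACTION
    pq = p * (1.0 - p)
    sn2 = params.pupil_noise_sd_mm**2

    d_s = params.sepr_oddball_increment_mm
    var_sepr = (
        gain**2 * (params.sepr_trial_sd_mm**2 + pq * d_s**2)
        + 0.5 * sn2 * (1.0 / m_w + 1.0 / m_b)
    )
    z_sepr = gain * d_s / np.sqrt(var_sepr)

    d_m = params.mmn_oddball_increment_uv
    z_mmn = -d_m / np.sqrt(params.mmn_trial_sd_uv**2 + pq * d_m**2)

    weights = np.asarray(n_per_group, float) / sum(n_per_group)
    f_after = np.mean([b > 2 for b in blocks])
    shifts = np.array(
        [params.group_bps_manipulation_shift_mm.get(g, 0.0) for g in GROUPS]
    )
    offsets = np.array(
        [params.group_baseline_offset_mm.get(g, 0.0) for g in GROUPS]
    )
    e_s = float(np.sum(weights * shifts) * f_after)
    e_s2 = float(np.sum(weights * shifts**2) * f_after)
    var_shift = e_s2 - e_s**2
    var_off = float(np.sum(weights * offsets**2) - np.sum(weights * offsets) ** 2)
    var_bps = (
        params.subject_bps_sd_mm**2
        + params.bps_trial_jitter_mm**2
        + k0**2 * (params.sepr_trial_sd_mm**2 + pq * d_s**2)
        + var_shift
        + var_off
        + 0.5 * sn2 / m_b
    )
    z_bps = {g: float(s / np.sqrt(var_bps)) for g, s in zip(GROUPS, shifts)}

    return {
        "sepr_stimulus": float(z_sepr),
        "mmn_stimulus": float(z_mmn),
        "bps_manipulation": z_bps,
    }


def params_for_standardized_effects(
    z_sepr: float = 0.3,
    z_mmn: float = -0.25,
    z_bps: float = 0.2,
    *,
    bps_shift_groups: tuple[str, ...] = ("ASD", "MHC"),
    n_per_group: tuple[int, int, int] = (10, 10, 10),
    blocks: tuple[int, ...] = (1, 3),
    base: GeneratorParams | None = None,
) -> GeneratorParams:
    """Solve generator amplitudes so the implied standardized effects hit
    the requested targets (under the clean preset's assumptions)."""
    params = base or clean_params()
    k0, kw, m_b, m_w = _pupil_window_stats(params)
    gain = kw - k0
    p = ODDBALL_FRACTION
    pq = p * (1.0 - p)
    sn2 = params.pupil_noise_sd_mm**2

    # SEPR increment: z^2 = G^2 d^2 / (G^2 (s^2 + pq d^2) + v)
    v = 0.5 * sn2 * (1.0 / m_w + 1.0 / m_b)
    num = z_sepr**2 * (params.sepr_trial_sd_mm**2 + v / gain**2)
    d_s = float(np.sqrt(num / (1.0 - z_sepr**2 * pq)))

    # MMN increment (z_mmn < 0 means more-negative MMN to oddballs)
    num = z_mmn**2 * params.mmn_trial_sd_uv**2
    d_m = float(np.sqrt(num / (1.0 - z_mmn**2 * pq)))

    # BPS shift shared by the listed groups
    weights = {g: n / sum(n_per_group) for g, n in zip(GROUPS, n_per_group)}
    f_after = float(np.mean([b > 2 for b in blocks]))
    a = f_after * sum(weights[g] for g in bps_shift_groups)
    c = (
        params.subject_bps_sd_mm**2
        + params.bps_trial_jitter_mm**2
        + k0**2 * (params.sepr_trial_sd_mm**2 + pq * d_s**2)
        + 0.5 * sn2 / m_b
    )
    s = float(np.sqrt(z_bps**2 * c / (1.0 - z_bps**2 * a * (1.0 - a))))

    shifts = {g: (s if g in bps_shift_groups else 0.0) for g in GROUPS}
    return replace(
        params,
        sepr_oddball_increment_mm=d_s,
        mmn_oddball_increment_uv=d_m,
        group_bps_manipulation_shift_mm=shifts,
    )
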