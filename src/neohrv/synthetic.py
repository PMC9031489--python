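"""Seeded synthetic neonatal ECG cohorts.

The RR process is a sinusoid-plus-noise model: around a per-patient
baseline interval, one low-frequency (0.04–0.3 Hz) and one high-frequency
(0.3–1.3 Hz) oscillation plus white jitter modulate successive beats —
the simplest generator with controllable mean rate, LF/HF band power and
entropy.  During annotated seizure events the mean heart rate is raised by
a multiplicative gain and all variability terms are suppressed by another,
mirroring the ictal tachycardia and loss of variability reported for
neonatal seizures.  ECG waveforms are sums of Gaussian P/R/T templates at
the true beat times plus measurement noise, so the QRS detector can be
scored against exact ground truth.

Everything is driven by one master seed; per-patient streams are spawned
deterministically from it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .io import AnnotationSet, ECGRecord
from .preprocessing import RRSeries


@dataclass
class CohortConfig:
    """Cohort-level simulation parameters.

    Defaults describe a resting neonate: baseline heart rate uniform in
    110–170 bpm (inside the physiological 100–200 bpm), LF/HF modulation
    depths of 15/10 ms on the RR interval, 10 ms white jitter.  Seizures
    multiply heart rate by ``seizure_hr_gain`` (1.15) and scale all
    variability by ``seizure_var_gain`` (0.5), switching instantaneously at
    onset/offset (``ramp_s`` reserved as a hook, default 0).  Event counts
    are 1 + Poisson(3.2) per pathological patient (≈4.2 events on average)
    and durations are log-normal with median ≈72 s, so roughly 40% of
    events last under 60 s and 89% under 180 s.
    """

    n_controls: int = 20
    n_pathological: int = 15
    record_length_s: float = 2700.0
    fs: float = 128.0
    baseline_hr_bpm: tuple = (110.0, 170.0)
    lf_amp_ms: float = 15.0
    hf_amp_ms: float = 10.0
    rr_jitter_ms: float = 10.0
    lf_band_hz: tuple = (0.05, 0.25)
    hf_band_hz: tuple = (0.35, 1.2)
    seizure_hr_gain: float = 1.15
    seizure_var_gain: float = 0.5
    event_count_poisson_mean: float = 3.2
    event_duration_log_mu: float = 4.28
    event_duration_log_sigma: float = 0.74
    event_min_duration_s: float = 10.0
    event_margin_s: float = 30.0
    noise_rms: float = 0.05
    ramp_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seizure_hr_gain <= 0 or self.seizure_var_gain <= 0:
            raise ValueError("gains must be positive")
        if self.fs <= 30:
            raise ValueError("sampling rate below QRS bandwidth")
        if self.n_controls < 0 or self.n_pathological < 0:
            raise ValueError("negative cohort size")


@dataclass
class PatientRecord:
    """One simulated patient: ECG, annotations, group and RR ground truth."""

    record: ECGRecord
    annotations: AnnotationSet
    group: str
    rr_truth: RRSeries


def _draw_events(cfg: CohortConfig, rng) -> list:
    """Draw seizure count and durations, then place events uniformly
    without overlap, keeping a margin from the record edges and between
    events."""
    n = 1 + rng.poisson(cfg.event_count_poisson_mean)
    for _ in range(200):
        durations = np.exp(rng.normal(cfg.event_duration_log_mu,
                                      cfg.event_duration_log_sigma, size=n))
        durations = np.clip(durations, cfg.event_min_duration_s,
                            0.3 * cfg.record_length_s)
        onsets = np.sort(rng.uniform(cfg.event_margin_s,
                                     cfg.record_length_s - cfg.event_margin_s, size=n))
        events = [(float(t), float(min(t + d, cfg.record_length_s - 1.0)))
                  for t, d in zip(onsets, durations)]
        ok = all(events[i + 1][0] - events[i][1] >= cfg.event_margin_s
                 for i in range(len(events) - 1))
        if ok:
            return events
        n = max(n - 1, 1)   # crowded draw: retry with fewer events
    return events[:1]


def generate_rr(cfg: CohortConfig, kind: str, rng=None, events=None):
    """Generate one patient's RR ground truth and annotations.

    Beat-to-beat model:
    ``RR(t) = RR0_eff + aLF sin(2 pi fLF t + p1) + aHF sin(2 pi fHF t + p2)
    + jitter`` with ``RR0_eff = RR0 / hr_gain`` and all amplitude terms
    scaled by ``var_gain`` while ``t`` lies inside an annotated event.
    Controls receive zero events.  Raises if the configured minimum
    possible RR drops below 250 ms (heart rate beyond 240 bpm).
    """
    if kind not in ("control", "pathological"):
        raise ValueError(f"unknown patient kind {kind!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    hr = rng.uniform(*cfg.baseline_hr_bpm)
    rr0 = 60.0 / hr                                   # seconds
    amp = (cfg.lf_amp_ms + cfg.hf_amp_ms) / 1000.0
    if rr0 / cfg.seizure_hr_gain - amp < 0.250:
        raise ValueError(
            "configuration admits RR below 250 ms (non-physiological heart rate)"
        )
    f_lf = rng.uniform(*cfg.lf_band_hz)
    f_hf = rng.uniform(*cfg.hf_band_hz)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    if kind == "control":
        events = []
    elif events is None:
        events = _draw_events(cfg, rng)

    times = []
    t = float(rng.uniform(0, rr0))
    # draw one jitter stream up-front for speed; extend if the loop outruns it
    budget = int(cfg.record_length_s / (rr0 / cfg.seizure_hr_gain)) + 64
    jitter = rng.normal(0.0, cfg.rr_jitter_ms / 1000.0, size=budget)
    i = 0
    while t < cfg.record_length_s:
        times.append(t)
        in_event = any(on <= t < off for on, off in events)
        g = cfg.seizure_var_gain if in_event else 1.0
        rr0_eff = rr0 / cfg.seizure_hr_gain if in_event else rr0
        if i >= jitter.size:
            jitter = np.concatenate([jitter, rng.normal(0.0, cfg.rr_jitter_ms / 1000.0, size=256)])
        rr = (rr0_eff
              + g * (cfg.lf_amp_ms / 1000.0) * np.sin(2 * np.pi * f_lf * t + p1)
              + g * (cfg.hf_amp_ms / 1000.0) * np.sin(2 * np.pi * f_hf * t + p2)
              + g * jitter[i])
        i += 1
        rr = max(rr, 0.250)
        t += rr
    return RRSeries(np.array(times)), AnnotationSet("synthetic", events)


def synthesize_ecg(
    rr: RRSeries,
    fs: float,
    record_length_s: float | None = None,
    noise_rms: float = 0.0,
    r_sigma_s: float = 0.010,
    p_amp: float = 0.1,
    t_amp: float = 0.2,
    rng=None,
    patient_id: str = "synthetic",
    group: str = "CP",
) -> ECGRecord:
    """Render an ECG as Gaussian beat templates at the true R times.

    The R wave is a unit-amplitude Gaussian of ~25 ms width; smaller P and
    T bumps precede/follow each beat at fixed fractions of the local RR.
    White noise of RMS ``noise_rms`` is added when requested.
    """
    if rr.peak_times_s.size == 0:
        raise ValueError("empty RR series")
    if fs < 100:
        raise ValueError("sampling rate too low to render QRS complexes")
    rr_ms = rr.rr_ms
    if rr_ms.size and rr_ms.min() < 6 * r_sigma_s * 1000.0:
        raise ValueError("RR interval shorter than the beat template width")
    if record_length_s is None:
        record_length_s = float(rr.peak_times_s[-1] + 1.0)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = int(round(record_length_s * fs))
    sig = np.zeros(n)
    tt = rr.peak_times_s

    def add_gaussian(center, amp, sigma):
        lo = max(int((center - 4 * sigma) * fs), 0)
        hi = min(int((center + 4 * sigma) * fs) + 1, n)
        if hi <= lo:
            return
        ts = np.arange(lo, hi) / fs
        sig[lo:hi] += amp * np.exp(-0.5 * ((ts - center) / sigma) ** 2)

    for k, tc in enumerate(tt):
        add_gaussian(tc, 1.0, r_sigma_s)
        if p_amp > 0 and k > 0:
            add_gaussian(tc - 0.2 * (tt[k] - tt[k - 1]), p_amp, 0.020)
        if t_amp > 0 and k < tt.size - 1:
            add_gaussian(tc + 0.3 * (tt[k + 1] - tt[k]), t_amp, 0.040)
    if noise_rms > 0:
        sig += rng.normal(0.0, noise_rms, size=n)
    return ECGRecord(patient_id=patient_id, group=group, fs=fs, samples=sig)


def generate_cohort(cfg: CohortConfig) -> list[PatientRecord]:
    """Simulate the full cohort: event-free controls plus pathological
    patients with planted seizures, each from its own spawned seed.

    Pathological patients alternate between the electrographic (EGP) and
    electroclinical (ECP) groups; the distinction does not change the
    generative model, only the metadata tag.
    """
    if cfg.n_controls + cfg.n_pathological == 0:
        raise ValueError("empty cohort")
    master = np.random.SeedSequence(cfg.seed)
    seeds = master.spawn(cfg.n_controls + cfg.n_pathological)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if i < cfg.n_controls:
            pid, group, kind = f"CP{i + 1}", "CP", "control"
        else:
            j = i - cfg.n_controls
            group = "EGP" if j % 2 == 0 else "ECP"
            pid, kind = f"{group}{j // 2 + 1}", "pathological"
        rr, ann = generate_rr(cfg, kind, rng)
        rec = synthesize_ecg(
            rr, cfg.fs, record_length_s=cfg.record_length_s,
            noise_rms=cfg.noise_rms, rng=rng, patient_id=pid, group=group,
        )
        out.append(PatientRecord(rec, AnnotationSet(pid, ann.events), group, rr))
    return out


def config_to_dict(cfg: CohortConfig) -> dict:
    return asdict(cfg)
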