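"""Surrogate recordings mirroring the microexpression-BCI protocol.

Each trial's 4 s task segment is synthesized as a three-population
neural-mass source with class-specific mixing weights (jittered per
subject), projected through the class dipole and the concentric-sphere
forward model to the montage, then degraded with 1/f + white sensor noise
at a configured SNR. Countdown and rest periods are zero placeholders kept
only for timing-faithful EDF export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from mebci import neural_mass as nm
from mebci.forward.analytic import Dipole, ShellModel, analytic_leadfield
from mebci.forward.bem import DIPOLE_TEMPLATES, LeadField, place_dipole
from mebci.forward.montage import CHANNELS_30, standard_montage
from mebci.pipeline import CLASSES, TrialSet

__all__ = [
    "RecordingProtocol",
    "ScenarioConfig",
    "generate_recordings",
    "generate_subject",
    "split_sessions",
    "scenario_leadfield",
]


@dataclass(frozen=True)
class RecordingProtocol:
    n_subjects: int = 8
    classes: tuple[str, ...] = CLASSES
    sessions: int = 4
    trials_per_session: int = 6
    countdown_seconds: float = 3.0
    task_seconds: float = 4.0
    rest_seconds: float = 2.0
    fs: float = 1000.0
    channels: tuple[str, ...] = CHANNELS_30

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.sessions, self.trials_per_session) < 1:
            raise ValueError("protocol counts must be >= 1")
        if min(self.countdown_seconds, self.task_seconds, self.rest_seconds) < 0:
            raise ValueError("trial timing must be nonnegative")

    @property
    def task_samples(self) -> int:
        return int(round(self.task_seconds * self.fs))


@dataclass(frozen=True)
class ScenarioConfig:
    """Statistical structure of the emulated dataset."""

    snr_db: float = 10.0
    jitter: float = 0.1  # multiplicative spread of gains/weights per subject
    seed: int = 0
    amplitude_uv: float = 10.0  # median per-channel RMS of the clean EEG
    burn_in_seconds: float = 2.0
    class_weights: dict[str, nm.PopulationWeights] = field(
        default_factory=lambda: dict(nm.REFERENCE_WEIGHTS)
    )
    noise_one_over_f_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def scenario_leadfield(protocol: RecordingProtocol,
                       shell: ShellModel | None = None) -> LeadField:
    """Analytic-series lead field for the canonical class dipoles."""
    shell = shell or ShellModel()
    montage = standard_montage(scalp_radius=shell.radii[2], center=shell.center)
    keep = [montage.index(ch) for ch in protocol.channels]
    dipoles = [place_dipole(c, shell) for c in sorted(DIPOLE_TEMPLATES)]
    mat = analytic_leadfield(dipoles, montage.positions[keep], shell)
    ref = "CPz" if "CPz" in protocol.channels else None
    if ref is not None:
        ref_row = list(protocol.channels).index(ref)
        mat = mat - mat[ref_row][None, :]
    return LeadField(mat, protocol.channels, "analytic", "scenario")


def _sensor_noise(rng: np.random.Generator, shape, fs: float,
                  one_over_f_fraction: float) -> np.ndarray:
    """Unit-power spatially independent 1/f + white noise, (samples, channels)."""
    n, c = shape
    white = rng.standard_normal((n, c))
    spec = np.fft.rfft(rng.standard_normal((n, c)), axis=0)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    pink = np.fft.irfft(spec * shaping[:, None], n=n, axis=0)
    pink /= pink.std(axis=0, keepdims=True)
    a = np.sqrt(one_over_f_fraction)
    b = np.sqrt(1.0 - one_over_f_fraction)
    mix = a * pink + b * white
    return mix / mix.std(axis=0, keepdims=True)


def generate_subject(
    protocol: RecordingProtocol,
    scenario: ScenarioConfig,
    subject_index: int,
    leadfield: LeadField | None = None,
) -> TrialSet:
    """All trials of one subject; only the task segment is synthesized."""
    for c in protocol.classes:
        if c not in DIPOLE_TEMPLATES or c not in scenario.class_weights:
            raise KeyError(f"no dipole/weights mapping for class {c!r}")
    lf = leadfield if leadfield is not None else scenario_leadfield(protocol)
    rng = np.random.default_rng([scenario.seed, subject_index])
    bands = ("low", "medium", "high")
    gain_jitter = {
        b: 1.0 + scenario.jitter * rng.uniform(-1.0, 1.0) for b in bands
    }
    weight_jitter = {
        c: 1.0 + scenario.jitter * rng.uniform(-1.0, 1.0, size=3)
        for c in protocol.classes
    }
    dipole_order = sorted(DIPOLE_TEMPLATES)

    fs = protocol.fs
    dt = 1.0 / fs
    n_task = protocol.task_samples
    n_steps = n_task + int(round(scenario.burn_in_seconds * fs))
    n_trials = len(protocol.classes) * protocol.sessions * protocol.trials_per_session

    # one batch row per trial and band
    pps, noise_rows, state_rows = [], [], []
    trial_meta = []
    states = {}
    for b in bands:
        pp = nm.BAND_PARAMS[b]
        scaled = nm.PopulationParams(
            b, pp.A * gain_jitter[b], pp.B * gain_jitter[b], pp.G * gain_jitter[b],
            pp.a, pp.b, pp.g,
        )
        states[b] = (scaled, nm.equilibrium_state(scaled).as_array())
    for cls in protocol.classes:
        for ses in range(1, protocol.sessions + 1):
            for tr in range(protocol.trials_per_session):
                trial_meta.append((cls, ses))
                for b in bands:
                    scaled, st = states[b]
                    pps.append(scaled)
                    state_rows.append(st)
                    noise_rows.append(
                        60.0 + 10.0 * rng.standard_normal(n_steps)
                    )
    sources = nm.integrate_populations_batch(
        pps, np.stack(noise_rows), dt, state0=np.stack(state_rows)
    )[:, -n_task:]
    sources = sources.reshape(n_trials, len(bands), n_task)

    analysis_sos = _sig.butter(
        4, (4.0, min(55.0, 0.45 * fs)), btype="bandpass", fs=fs, output="sos"
    )
    data = np.empty((n_trials, n_task, len(protocol.channels)))
    for t, (cls, _ses) in enumerate(trial_meta):
        w = scenario.class_weights[cls].as_array() * weight_jitter[cls]
        # weights are band-energy fractions over the 4-55 Hz analysis band:
        # normalize each band source by its in-analysis-band RMS, then invert
        # the cross-band leakage matrix so the mixed signal's band-energy
        # profile matches the configured weights
        src = sources[t] - sources[t].mean(axis=1, keepdims=True)
        inband = _sig.sosfiltfilt(analysis_sos, src, axis=1)
        src = src / inband.std(axis=1, keepdims=True)
        freqs, psd = _sig.welch(
            src, fs=fs, window="hann",
            nperseg=min(2 * int(fs), src.shape[1]),
        )
        leak = np.empty((3, 3))  # leak[j, k]: band-j share of source k
        total_mask = (freqs >= 4.0) & (freqs <= min(55.0, 0.45 * fs))
        for k in range(3):
            tot = np.trapezoid(psd[k][total_mask], freqs[total_mask])
            for j, (lo, hi) in enumerate(((4.0, 12.0), (12.0, 30.0),
                                          (30.0, min(55.0, 0.45 * fs)))):
                m = (freqs >= lo) & (freqs <= hi)
                leak[j, k] = np.trapezoid(psd[k][m], freqs[m]) / tot
        alpha = np.maximum(np.linalg.solve(leak, w / w.sum()), 0.0)
        mixed = np.sqrt(alpha) @ src
        d_idx = dipole_order.index(cls)
        gains = lf.gains(d_idx, place_dipole(cls).moment)
        clean = mixed[:, None] * gains[None, :]
        rms = np.sqrt(np.mean(clean**2, axis=0))
        med = np.median(rms[rms > 0])
        clean *= scenario.amplitude_uv / med
        noise = _sensor_noise(
            rng, (n_task, len(protocol.channels)), fs,
            scenario.noise_one_over_f_fraction,
        )
        # reference the noise floor to the calibrated amplitude, not the
        # class-dependent mean power, so noise variance carries no class cue
        noise_power = scenario.amplitude_uv**2 / (10.0 ** (scenario.snr_db / 10.0))
        data[t] = clean + np.sqrt(noise_power) * noise

    return TrialSet(
        data,
        tuple(cls for cls, _ in trial_meta),
        fs,
        tuple(ses for _, ses in trial_meta),
        subject=f"S{subject_index + 1}",
        channel_names=protocol.channels,
    )


def generate_recordings(protocol: RecordingProtocol,
                        scenario: ScenarioConfig) -> list[TrialSet]:
    """One TrialSet per subject, fully determined by the scenario seed."""
    lf = scenario_leadfield(protocol)
    return [
        generate_subject(protocol, scenario, s, lf)
        for s in range(protocol.n_subjects)
    ]


def split_sessions(ts: TrialSet) -> tuple[TrialSet, TrialSet]:
    """Session 1 -> template/training, sessions 2+ -> test (disjoint)."""
    sessions = sorted(set(ts.session_ids))
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions to split")
    sid = np.asarray(ts.session_ids)
    template = ts.select(sid == sessions[0])
    test = ts.select(sid != sessions[0])
    return template, test
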