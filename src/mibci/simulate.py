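"""Synthetic multiclass motor-imagery EEG with plantable class structure.

The generator emulates a cue-based four-class imagery paradigm: 7.5 s
trials sampled at 250 Hz, 22 channels, 72 trials per class per session,
two sessions, with the imagery analysis window at 2.5-5 s. Class
structure can be planted through two physiologically motivated, and
independently detectable, mechanisms:

* **ERD** (event-related desynchronization): a fractional reduction of
  band-limited oscillatory amplitude on selected channels during the
  imagery window. Detectable by channel-local spectral features.
* **Phase-lag coupling**: a pair of channels shares one band-limited
  phase process with a fixed lag during the imagery window, so their
  phase difference is nearly constant. Detectable by phase-based
  connectivity metrics (PLI, phase correlation).

Background activity is a sum of white noise, first-order autoregressive
pink-ish noise, and mu/beta oscillations with slowly diffusing phase on
every channel, giving an EEG-like 1/f + alpha-bump spectrum without a
biophysical forward model.

Coupling uses an energy-preserving amplitude mix: each channel always
carries a narrow-band carrier component of constant power; for channels
in a coupling pair of the trial's class, that component is
``sqrt(1-s^2) * independent + s * shared`` with coupling strength ``s``,
so per-channel band power is independent of ``s`` and coupling is
expressed *only* in the phase relation. This is what keeps
channel-local features at chance when class structure is planted purely
in connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 22-channel montage of the standard four-class motor-imagery benchmark
#: (central strip and its fronto-central / centro-parietal neighbours).
MONTAGE_22 = [
    "Fz",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2",
    "POz",
]

DEFAULT_CLASSES = ["LH", "RH", "F", "T"]


class SimulationError(ValueError):
    """Raised for invalid paradigm configurations or class signatures."""


@dataclass
class ParadigmConfig:
    """Timing and size constants of the cue-based imagery paradigm."""

    n_channels: int = 22
    fs: float = 250.0
    trial_duration: float = 7.5
    mi_window: tuple[float, float] = (2.5, 5.0)
    classes: tuple[str, ...] = tuple(DEFAULT_CLASSES)
    trials_per_class: int = 72
    n_sessions: int = 2
    artifact_rate: float = 0.05
    noise_sd: float = 1.0
    montage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.montage:
            if self.n_channels == len(MONTAGE_22):
                self.montage = tuple(MONTAGE_22)
            else:
                self.montage = tuple(f"CH{i:02d}" for i in range(1, self.n_channels + 1))
        self.montage = tuple(self.montage)
        if len(self.montage) != self.n_channels:
            raise SimulationError("montage length must equal n_channels")
        if not (0 <= self.mi_window[0] < self.mi_window[1] <= self.trial_duration):
            raise SimulationError("mi_window must lie inside [0, trial_duration]")
        if not 0 <= self.artifact_rate <= 1:
            raise SimulationError("artifact_rate must be in [0, 1]")
        if self.trials_per_class < 1 or not self.classes:
            raise SimulationError("need at least one class and one trial per class")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))

    @property
    def n_trials(self) -> int:
        return self.trials_per_class * len(self.classes)


@dataclass
class ClassSignature:
    """Plantable class-dependent structure for one imagery class.

    ``coupling_pairs`` entries are ``(channel_i, channel_j, phase_lag,
    coupling_strength)`` with the lag in radians in (-pi, pi] and the
    strength in [0, 1].
    """

    erd_channels: tuple[str, ...] = ()
    erd_band: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.0
    coupling_pairs: tuple[tuple[str, str, float, float], ...] = ()
    carrier_freq: float = 10.0

    def __post_init__(self) -> None:
        self.erd_channels = tuple(self.erd_channels)
        self.coupling_pairs = tuple(tuple(p) for p in self.coupling_pairs)
        if not 0 <= self.erd_depth <= 1:
            raise SimulationError("erd_depth must be in [0, 1]")
        for ci, cj, lag, s in self.coupling_pairs:
            if not 0 <= s <= 1:
                raise SimulationError(f"coupling_strength {s} outside [0, 1]")
            if not -np.pi < lag <= np.pi:
                raise SimulationError(f"phase_lag {lag} outside (-pi, pi]")


def default_signatures() -> dict[str, ClassSignature]:
    """Canonical four-class signatures.

    ERD is placed contralaterally for the hand classes (left hand ->
    right motor cortex C4, right hand -> C3), on the vertex for feet,
    and fronto-centrally for tongue, matching textbook sensorimotor
    somatotopy. Each class additionally couples one characteristic
    channel pair around its ERD site.
    """
    return {
        "LH": ClassSignature(
            erd_channels=("C4",), erd_depth=0.5,
            coupling_pairs=(("C4", "CP2", np.pi / 4, 0.8),),
        ),
        "RH": ClassSignature(
            erd_channels=("C3",), erd_depth=0.5,
            coupling_pairs=(("C3", "CP1", np.pi / 4, 0.8),),
        ),
        "F": ClassSignature(
            erd_channels=("Cz",), erd_depth=0.5,
            coupling_pairs=(("Cz", "FCz", np.pi / 4, 0.8),),
        ),
        "T": ClassSignature(
            erd_channels=("FCz",), erd_depth=0.5,
            coupling_pairs=(("FC1", "FC2", np.pi / 4, 0.8),),
        ),
    }


@dataclass
class SyntheticSession:
    """One generated session: trial tensor plus paradigm metadata."""

    data: np.ndarray  # channels x samples x trials
    labels: np.ndarray
    artifact_flags: np.ndarray
    montage: tuple[str, ...]
    fs: float
    session_id: str
    seed: int


def _window_envelope(n_samples: int, fs: float, window: tuple[float, float],
                     ramp: float = 0.2) -> np.ndarray:
    """Raised-cosine gate: 0 outside the window, 1 inside, smooth ramps."""
    t = np.arange(n_samples) / fs
    env = np.zeros(n_samples)
    t0, t1 = window
    inside = (t >= t0) & (t < t1)
    env[inside] = 1.0
    up = inside & (t < t0 + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp))
    down = inside & (t >= t1 - ramp)
    env[down] = 0.5 * (1 - np.cos(np.pi * (t1 - t[down]) / ramp))
    return env


def _diffusing_phase(n: int, fs: float, freq: float, rng: np.random.Generator,
                     jitter_hz: float = 0.0, diffusion: float = 0.1) -> np.ndarray:
    """Instantaneous phase of a narrow-band process: linear trend at
    ``freq`` (plus a per-call frequency jitter) with a random-walk term."""
    f = freq + (rng.uniform(-jitter_hz, jitter_hz) if jitter_hz > 0 else 0.0)
    walk = np.cumsum(rng.normal(0.0, diffusion, n))
    return 2 * np.pi * f * np.arange(n) / fs + rng.uniform(0, 2 * np.pi) + walk


def _pink_noise_block(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """AR(1) pink-ish noise along the last axis, unit marginal variance."""
    from scipy.signal import lfilter

    w = rng.normal(0.0, 1.0, shape)
    a = 0.95
    out = lfilter([1.0], [1.0, -a], w, axis=-1)
    return out * np.sqrt(1 - a * a)


def generate_trial(
    class_label: str,
    signatures: dict[str, ClassSignature],
    cfg: ParadigmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one trial (channels x samples) for ``class_label``.

    Composition per channel: white + pink background noise scaled by
    ``cfg.noise_sd``, a mu (10 Hz) and beta (20 Hz) oscillation with
    diffusing phase, and a narrow-band carrier component that realizes the
    class's coupling structure. During the imagery window the ERD
    channels' in-band oscillation amplitude is scaled by
    ``1 - erd_depth``.
    """
    if class_label not in signatures:
        raise SimulationError(f"unknown class label {class_label!r}")
    sig = signatures[class_label]
    labels = list(cfg.montage)
    for ch in sig.erd_channels:
        if ch not in labels:
            raise SimulationError(f"ERD channel {ch!r} not in montage")
    for ci, cj, _, _ in sig.coupling_pairs:
        if ci not in labels or cj not in labels:
            raise SimulationError(f"coupling pair ({ci}, {cj}) not in montage")

    n = cfg.n_samples
    nch = cfg.n_channels
    env = _window_envelope(n, cfg.fs, cfg.mi_window)

    # background: white + AR(1) pink
    x = 0.4 * cfg.noise_sd * rng.normal(0.0, 1.0, (nch, n))
    x += cfg.noise_sd * _pink_noise_block((nch, n), rng)

    # ongoing rhythms, identical across classes and channels except for
    # the planted ERD: on ERD channels, the rhythm falling inside
    # erd_band has its amplitude scaled by (1 - erd_depth) during the
    # imagery window
    erd_idx = [labels.index(ch) for ch in sig.erd_channels]
    for c in range(nch):
        for freq, amp in ((10.0, 1.0), (20.0, 0.8)):
            rhythm_env = 1.0
            if (
                c in erd_idx
                and sig.erd_depth > 0
                and sig.erd_band[0] <= freq <= sig.erd_band[1]
            ):
                rhythm_env = 1.0 - sig.erd_depth * env
            phi = _diffusing_phase(n, cfg.fs, freq, rng, diffusion=0.05)
            x[c] += amp * rhythm_env * np.cos(phi)

    # carrier components: every channel gets one at constant power; coupled
    # pairs share a phase process with a fixed lag, energy-preservingly
    # mixed at the coupling strength, and gated to the imagery window.
    # the carrier must dominate the in-band background (rhythms + noise)
    # so that a fully coupled pair's phase difference stays pinned at the lag
    carrier_amp = 6.0
    coupled: dict[int, np.ndarray] = {}
    for ci, cj, lag, s in sig.coupling_pairs:
        i, j = labels.index(ci), labels.index(cj)
        # the shared process has the same jitter/diffusion as the
        # independent carriers, so channel-local (spectral) statistics
        # are identical and only the cross-channel phase relation changes
        shared = _diffusing_phase(n, cfg.fs, sig.carrier_freq, rng,
                                  jitter_hz=1.0, diffusion=0.1)
        own_i = _diffusing_phase(n, cfg.fs, sig.carrier_freq, rng,
                                 jitter_hz=1.0, diffusion=0.1)
        own_j = _diffusing_phase(n, cfg.fs, sig.carrier_freq, rng,
                                 jitter_hz=1.0, diffusion=0.1)
        mix = np.sqrt(max(0.0, 1.0 - s * s))
        coupled[i] = carrier_amp * (mix * np.cos(own_i) + s * np.cos(shared))
        coupled[j] = carrier_amp * (mix * np.cos(own_j) + s * np.cos(shared - lag))
    for c in range(nch):
        if c in coupled:
            comp = coupled[c]
        else:
            own = _diffusing_phase(n, cfg.fs, sig.carrier_freq, rng,
                                   jitter_hz=1.0, diffusion=0.1)
            comp = carrier_amp * np.cos(own)
        x[c] += env * comp

    return x


def generate_session(
    cfg: ParadigmConfig,
    signatures: dict[str, ClassSignature] | None = None,
    seed: int = 0,
    session_id: str = "S1",
) -> SyntheticSession:
    """Generate a full balanced session in randomized trial order.

    Every random draw flows from ``seed``; the same seed reproduces the
    session bit-for-bit.
    """
    if signatures is None:
        signatures = default_signatures()
    for cls in cfg.classes:
        if cls not in signatures:
            raise SimulationError(f"no signature for class {cls!r}")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(cfg.classes)), cfg.trials_per_class)
    rng.shuffle(order)
    labels = np.array([cfg.classes[k] for k in order])
    data = np.empty((cfg.n_channels, cfg.n_samples, cfg.n_trials))
    for t, cls in enumerate(labels):
        data[:, :, t] = generate_trial(cls, signatures, cfg, rng)
    artifact_flags = rng.random(cfg.n_trials) < cfg.artifact_rate
    return SyntheticSession(
        data=data,
        labels=labels,
        artifact_flags=artifact_flags,
        montage=cfg.montage,
        fs=cfg.fs,
        session_id=session_id,
        seed=seed,
    )


def planted_truth(signatures: dict[str, ClassSignature]) -> dict:
    """Machine-readable summary of the planted class structure.

    Returns a dict with, per class, the ERD channels/band/depth and the
    coupled channel pairs, plus ``separable_pairs``: for each unordered
    class pair, whether their signatures differ (identical signatures
    cannot be separated by construction).
    """
    truth: dict = {"classes": {}, "separable_pairs": {}}
    for cls in sorted(signatures):
        sig = signatures[cls]
        truth["classes"][cls] = {
            "erd_channels": tuple(sig.erd_channels) if sig.erd_depth > 0 else (),
            "erd_band": sig.erd_band,
            "erd_depth": sig.erd_depth,
            "coupling_pairs": tuple(
                (ci, cj) for ci, cj, _, s in sig.coupling_pairs if s > 0
            ),
        }
    names = sorted(signatures)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sa, sb = signatures[names[a]], signatures[names[b]]
            truth["separable_pairs"][(names[a], names[b])] = sa != sb
    return truth


def to_trial_set(session: SyntheticSession):
    """View a generated session as a :class:`~mibci.preprocess.TrialSet`."""
    from .preprocess import TrialSet

    return TrialSet(
        data=session.data,
        fs=session.fs,
        montage=list(session.montage),
        labels=session.labels,
        artifact_flags=session.artifact_flags,
        session_id=session.session_id,
        time_zero=0.0,
    )
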