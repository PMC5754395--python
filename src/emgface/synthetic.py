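"""Synthetic sEMG and lip-marker data with known ground truth.

Real recordings of this experiment were never deposited, so every
downstream stage is exercised on synthetic data generated here:

* ground-truth muscle activation patterns per instruction (A–F): smooth
  ramp–hold–release envelopes on exactly the muscles relevant to the
  instruction, with left/right alternation for the asymmetric
  instruction E and the purse–smile–purse phase structure for F;
* surface-EMG emulation: each measured channel is an amplitude-modulated
  band-limited (15–500 Hz) Gaussian carrier at 2048 Hz, mixed through a
  configurable cross-talk matrix plus a noise floor;
* reference ("measured") marker trajectories at 100 frames/s, either
  self-consistent (produced by the finite-element lip model from the
  same truth) or from a fast linear kinematic surrogate.

The per-muscle envelope gains mirror the electrode-to-model transfer
(e.g. the marginal orbicularis at 0.2 of the peripheral), so that a
noise-free pipeline run recovers the truth on the relevant channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .features import EMGRecording
from .fem import LipModel, MeshConfig, TrajectorySet, simulate
from .mapping import ActivationSet
from .muscles import (
    MEASURED_MUSCLES,
    MODEL_MUSCLES,
    ADJACENT_PAIRS,
    RELEVANT_MUSCLES,
    SIDES,
    check_instruction,
    measured_labels,
    model_labels,
)

#: Carrier RMS at full envelope (mV).  Fixed by a one-off design scan so
#: that the Willison-amplitude response at the default 10 mV threshold is
#: close to proportional in the envelope over [0, 1].
CARRIER_RMS_MV = 35.0

ENVELOPE_RATE = 100.0   # Hz, matches the marker frame rate
RAMP_S = 0.3            # raised-cosine ramp/release duration
REST_PAD_S = 0.2        # rest margin inside each repetition segment
REST_BETWEEN_S = 2.0    # rest between repetitions in a concatenated session

#: Relative envelope gain per model muscle, consistent with the
#: measured-to-model composition (OOM = 0.2 OOP, LAO = 0.75 LLSAN,
#: DLI = 0.75 DAO; everything else at unit gain).
TRUTH_GAINS = {"OOM": 0.2, "LAO": 0.75, "DLI": 0.75}


@dataclass
class ActivationTruth:
    """Ground-truth activation traces for the 20 model muscles."""

    values: np.ndarray          # (20, frames) in [0, 1]
    times: np.ndarray
    labels: list[str]
    instruction: str
    repetition: int = 0
    duration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("activation truth must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class CrosstalkModel:
    """Linear leakage between measured channels plus a noise floor.

    ``mixing`` is (14 x 14), nonnegative; the identity reproduces a
    cross-talk-free recording.
    """

    mixing: np.ndarray
    noise_floor: float = 0.5    # mV RMS

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        n = len(measured_labels())
        if self.mixing.shape != (n, n):
            raise ValueError(f"mixing must be {n} x {n}")
        if np.any(self.mixing < 0):
            raise ValueError("mixing must be nonnegative")
        if np.any(self.mixing.sum(axis=1) > 1.0 + 1e-9):
            raise ValueError("mixing rows must sum to at most 1")

    @classmethod
    def identity(cls, noise_floor: float = 0.0) -> "CrosstalkModel":
        n = len(measured_labels())
        return cls(np.eye(n), noise_floor)

    @classmethod
    def default(cls, leakage: float = 0.1,
                noise_floor: float = 0.5) -> "CrosstalkModel":
        """Leakage between anatomically adjacent same-side channel pairs."""
        labels = measured_labels()
        n = len(labels)
        M = np.eye(n)
        for a, b in ADJACENT_PAIRS:
            for s in SIDES:
                ia = labels.index(f"{a}_{s}")
                ib = labels.index(f"{b}_{s}")
                M[ia, ib] = M[ib, ia] = leakage
        M /= M.sum(axis=1, keepdims=True)
        return cls(M, noise_floor)


def _ramp_hold_release(t: np.ndarray, t_on: float, t_off: float,
                       ramp: float = RAMP_S) -> np.ndarray:
    """Raised-cosine ramp up at t_on, hold, release ending at t_off."""
    e = np.zeros_like(t)
    up = (t >= t_on) & (t < t_on + ramp)
    e[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t_on) / ramp))
    e[(t >= t_on + ramp) & (t <= t_off - ramp)] = 1.0
    down = (t > t_off - ramp) & (t <= t_off)
    e[down] = 0.5 * (1 - np.cos(np.pi * (t_off - t[down]) / ramp))
    return e


def gen_activation_truth(
    instruction: str,
    duration: float = 2.0,
    seed: int = 0,
    repetition: int = 0,
    timing_jitter: float = 0.0,
) -> ActivationTruth:
    """Ground-truth activations for one repetition of an instruction.

    Only the instruction's relevant muscles carry nonzero envelopes.
    Symmetric instructions (A–D) activate both sides identically;
    instruction E alternates left/right dominance in three phases; F
    runs purse–smile–purse phases.  ``timing_jitter`` (s, std) perturbs
    the onset/offset to emulate repetition-to-repetition variability.
    """
    check_instruction(instruction)
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, repetition)))
    n = int(round(duration * ENVELOPE_RATE)) + 1
    t = np.arange(n) / ENVELOPE_RATE
    jit = (rng.normal(0.0, timing_jitter) if timing_jitter > 0 else 0.0)
    t_on = np.clip(REST_PAD_S + jit, 0.0, duration / 2)
    t_off = duration - REST_PAD_S

    labels = model_labels()
    values = np.zeros((len(labels), n))
    relevant = RELEVANT_MUSCLES[instruction]

    def gain(m: str) -> float:
        return TRUTH_GAINS.get(m, 1.0)

    if instruction == "E":
        # left-right-left: three sub-phases of alternating dominance
        edges = np.linspace(t_on, t_off, 4)
        phases = [
            _ramp_hold_release(t, edges[i], edges[i + 1] + RAMP_S / 2,
                               ramp=min(RAMP_S, (edges[1] - edges[0]) / 2))
            for i in range(3)
        ]
        env_L = np.clip(phases[0] + phases[2], 0.0, 1.0)
        env_R = phases[1]
        for m in relevant:
            values[labels.index(f"{m}_L")] = gain(m) * env_L
            values[labels.index(f"{m}_R")] = gain(m) * env_R
    elif instruction == "F":
        # purse lips - closed mouth smile - purse lips
        purse = ("OOP", "OOM", "BUC")
        smile = ("LLSAN", "RIS", "ZYG", "LAO")
        edges = np.linspace(t_on, t_off, 4)
        ramp = min(RAMP_S, (edges[1] - edges[0]) / 2)
        ph = [_ramp_hold_release(t, edges[i], edges[i + 1] + ramp / 2,
                                 ramp=ramp) for i in range(3)]
        env = {m: np.clip(ph[0] + ph[2], 0.0, 1.0) for m in purse}
        env.update({m: ph[1] for m in smile})
        for m in relevant:
            for s in SIDES:
                values[labels.index(f"{m}_{s}")] = gain(m) * env[m]
    else:
        env = _ramp_hold_release(t, t_on, t_off)
        for m in relevant:
            for s in SIDES:
                values[labels.index(f"{m}_{s}")] = gain(m) * env

    return ActivationTruth(
        values=values, times=t, labels=labels,
        instruction=instruction, repetition=repetition,
        duration=duration, seed=seed,
    )


def measured_envelopes(truth: ActivationTruth) -> np.ndarray:
    """Project 20-channel model truth onto the 14 measured channels.

    Inverts the measured-to-model composition where possible: the
    orbicularis superior and inferior sites both see the peripheral
    orbicularis envelope, and buccinator activity floods the risorius
    and zygomaticus sites (the leakage the composition rules assume).
    Purely derived muscles (OOM, LAO, DLI) have no site of their own.
    """
    labels = truth.labels
    out = np.zeros((len(measured_labels()), truth.n_frames))
    mlabels = measured_labels()

    def tv(name: str) -> np.ndarray:
        return truth.values[labels.index(name)]

    for s in SIDES:
        for m in MEASURED_MUSCLES:
            row = mlabels.index(f"{m}_{s}")
            if m in ("OOS", "OOI"):
                out[row] = tv(f"OOP_{s}")
            elif m in ("RIS", "ZYG"):
                out[row] = np.maximum(tv(f"{m}_{s}"), tv(f"BUC_{s}"))
            else:
                out[row] = tv(f"{m}_{s}")
    return out


def band_limited_noise(n: int, fs: float, rng: np.random.Generator,
                       lo: float = 15.0, hi: float = 500.0) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz.

    An eighth-order Butterworth keeps >= 95% of the power in band.
    """
    sos = signal.butter(8, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / max(x.std(), 1e-30)


def synth_semg(
    truth: ActivationTruth,
    xtalk: CrosstalkModel | None = None,
    fs: float = 2048.0,
    seed: int = 0,
    carrier_rms: float = CARRIER_RMS_MV,
) -> EMGRecording:
    """Emulate a 14-channel bipolar sEMG recording of the truth.

    Each source channel is ``carrier_rms * envelope(t) * carrier(t)``
    with an independent band-limited unit-RMS carrier; measured channels
    are ``mixing @ sources`` plus band-limited noise at the noise-floor
    RMS.  Bit-identical for identical seeds.
    """
    if fs < 1024.0:
        raise ValueError(
            f"fs={fs} Hz cannot contain the 15-500 Hz band; need >= 1024"
        )
    xtalk = xtalk or CrosstalkModel.identity()
    n = int(round(truth.duration * fs))
    t = np.arange(n) / fs
    env14 = measured_envelopes(truth)
    ss = np.random.SeedSequence((seed, truth.repetition, 7))
    child = ss.spawn(env14.shape[0] + 1)
    sources = np.empty((env14.shape[0], n))
    for c in range(env14.shape[0]):
        rng = np.random.default_rng(child[c])
        env = np.interp(t, truth.times, env14[c])
        sources[c] = carrier_rms * env * band_limited_noise(n, fs, rng)
    measured = xtalk.mixing @ sources
    if xtalk.noise_floor > 0:
        rng = np.random.default_rng(child[-1])
        for c in range(measured.shape[0]):
            measured[c] += xtalk.noise_floor * band_limited_noise(n, fs, rng)
    return EMGRecording(
        samples=measured, fs=fs, labels=measured_labels(),
        instruction=truth.instruction, repetition=truth.repetition,
    )


def truth_to_activation(truth: ActivationTruth,
                        frames: int = 160) -> ActivationSet:
    """Resample truth onto the model frame grid as an ActivationSet."""
    t_new = np.linspace(truth.times[0], truth.times[-1], frames)
    values = np.vstack([
        np.interp(t_new, truth.times, truth.values[c])
        for c in range(truth.values.shape[0])
    ])
    return ActivationSet(
        values=values, times=t_new, labels=list(truth.labels),
        strategy="truth", instruction=truth.instruction,
        repetition=truth.repetition,
    )


# ---------------------------------------------------------------------------
# reference trajectories
# ---------------------------------------------------------------------------

_SURROGATE_SEED = 20481                 # fixed: the synergy map is anatomy
_MARKER_RATE = 100.0                    # frames per second


def kinematic_trajectories(
    truth: ActivationTruth,
    mesh_config: MeshConfig | None = None,
    amplitude: float = 2.0,
) -> TrajectorySet:
    """Fast linear surrogate: markers respond linearly to activations.

    Each marker moves from its rest position by a fixed (seeded,
    anatomy-like) displacement direction per muscle, scaled by the
    activation; mirror symmetry is enforced so symmetric instructions
    produce symmetric motion.  Amplitude is the per-muscle displacement
    scale in mm at full activation.
    """
    from .fem import build_lip_mesh

    cfg = mesh_config or MeshConfig()
    model = build_lip_mesh(cfg)
    rest = model.nodes[model.marker_nodes]              # (10, 3)
    n_mark = rest.shape[0]
    rng = np.random.default_rng(_SURROGATE_SEED)
    n_mus = len(MODEL_MUSCLES)
    # left-muscle displacement field; right side mirrored in x
    D_left = rng.normal(0.0, amplitude / np.sqrt(3), (n_mark, n_mus, 3))
    mirror_marker = [4, 3, 2, 1, 0, 9, 8, 7, 6, 5]
    D_right = D_left[mirror_marker] * np.array([-1.0, 1.0, 1.0])
    D = np.concatenate([D_left, D_right], axis=1)       # (10, 20, 3)

    n = int(round(truth.duration * _MARKER_RATE)) + 1
    t = np.arange(n) / _MARKER_RATE
    act = np.vstack([
        np.interp(t, truth.times, truth.values[c])
        for c in range(truth.values.shape[0])
    ])                                                   # (20, n)
    pos = rest[:, None, :] + np.einsum("kmi,mt->kti", D, act)
    return TrajectorySet(
        positions=pos, frame_rate=_MARKER_RATE, source="measured",
        instruction=truth.instruction, repetition=truth.repetition,
        marker_names=list(model.marker_names),
    )


def fem_trajectories(
    truth: ActivationTruth,
    model: LipModel,
    frames: int = 160,
    **sim_kwargs,
) -> TrajectorySet:
    """Self-consistent reference: simulate the truth with the lip model,
    then resample the marker motion to the 100 frames/s measurement rate.
    """
    act = truth_to_activation(truth, frames)
    sim = simulate(model, act, duration=truth.duration, **sim_kwargs)
    n = int(round(truth.duration * _MARKER_RATE)) + 1
    t_new = np.linspace(0.0, 1.0, n)
    t_old = np.linspace(0.0, 1.0, sim.n_frames)
    pos = np.empty((sim.n_markers, n, 3))
    for m in range(sim.n_markers):
        for k in range(3):
            pos[m, :, k] = np.interp(t_new, t_old, sim.positions[m, :, k])
    return TrajectorySet(
        positions=pos, frame_rate=_MARKER_RATE, source="measured",
        instruction=truth.instruction, repetition=truth.repetition,
        marker_names=sim.marker_names,
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """What to generate: instructions, repetitions, noise, trajectories."""

    instructions: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
    repetitions: int = 4
    duration: float = 2.0
    fs: float = 2048.0
    seed: int = 0
    crosstalk: CrosstalkModel | None = None     # None -> identity, no noise
    timing_jitter: float = 0.0
    trajectory_source: str = "surrogate"        # "surrogate" | "fem"
    model: LipModel | None = None
    frames: int = 160
    sim_kwargs: dict = field(default_factory=dict)


@dataclass
class DatasetRecord:
    """One (instruction, repetition) record with its ground truth."""

    truth: ActivationTruth
    emg: EMGRecording
    trajectories: TrajectorySet


def make_dataset(config: DatasetConfig) -> list[DatasetRecord]:
    """One record per (instruction, repetition), deterministic per seed."""
    for ins in config.instructions:
        check_instruction(ins)
    if config.trajectory_source not in ("surrogate", "fem"):
        raise ValueError("trajectory_source must be 'surrogate' or 'fem'")
    if config.trajectory_source == "fem" and config.model is None:
        raise ValueError(
            "self-consistent (fem) trajectories require a lip model"
        )
    records: list[DatasetRecord] = []
    for i, ins in enumerate(config.instructions):
        for rep in range(config.repetitions):
            rec_seed = int(
                np.random.SeedSequence(
                    (config.seed, i, rep)
                ).generate_state(1)[0] % (2**31)
            )
            truth = gen_activation_truth(
                ins, config.duration, seed=rec_seed, repetition=rep,
                timing_jitter=config.timing_jitter,
            )
            emg = synth_semg(truth, config.crosstalk, config.fs,
                             seed=rec_seed)
            if config.trajectory_source == "fem":
                traj = fem_trajectories(truth, config.model, config.frames,
                                        **config.sim_kwargs)
            else:
                traj = kinematic_trajectories(
                    truth,
                    config.model.mesh_config if config.model else None,
                )
            records.append(DatasetRecord(truth, emg, traj))
    return records


def concatenate_session(records: list[DatasetRecord],
                        rest: float = REST_BETWEEN_S) -> np.ndarray:
    """Join repetition recordings into one stream with rest in between."""
    if not records:
        return np.empty((len(measured_labels()), 0))
    fs = records[0].emg.fs
    pad = np.zeros((records[0].emg.n_channels, int(round(rest * fs))))
    chunks: list[np.ndarray] = []
    for r in records:
        chunks.append(r.emg.samples)
        chunks.append(pad)
    return np.concatenate(chunks[:-1], axis=1)
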