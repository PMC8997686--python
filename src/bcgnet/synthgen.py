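"""Synthetic ballistocardiogram (BCG) generator.

A BCG beat is modelled as a sum of Gaussian deflections, one per lettered
wave (G, H, I, J, K, L, M, N).  The sign convention follows the standard
nomenclature: H, J, L, N are headward (positive) waves, G, I, K, M are
footward (negative), and J is the dominant systolic deflection.  Recordings
concatenate beats at normally distributed inter-beat intervals, apply a
sinusoidal respiratory amplitude modulation and add white Gaussian noise.

The hypertensive (HPT) class differs from healthy controls (HC) through two
documented knobs only: per-beat amplitude jumps (abrupt rises and falls in
amplitude) and inflated heart-rate variability (fast variations in the time
axis).  Everything is driven by a single integer seed, so a configuration
fully determines its dataset.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "WaveComponent",
    "SynthConfig",
    "BCGRecord",
    "DEFAULT_WAVES",
    "InvalidConfigError",
    "make_wave_template",
    "generate_recording",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]

WAVE_ORDER = ("G", "H", "I", "J", "K", "L", "M", "N")
# Headward (positive) deflections; the remainder are footward (negative).
_HEADWARD = frozenset({"H", "J", "L", "N"})

HC_LABEL = "HC"
HPT_LABEL = "HPT"


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class WaveComponent:
    """One lettered BCG deflection, shaped as a Gaussian bump.

    Parameters
    ----------
    name : str
        One of G, H, I, J, K, L, M, N.
    latency : float
        Seconds from beat onset to the bump centre.
    amplitude : float
        Signed amplitude in arbitrary units; positive = headward.
    width : float
        Gaussian standard deviation in seconds.
    """

    name: str
    latency: float
    amplitude: float
    width: float


#: Default beat morphology.  Latencies/amplitudes are not physiological
#: constants from any table; they are chosen to reproduce the canonical
#: lettered-wave shape (small G dip, H-I-J systolic complex with dominant
#: positive J, K trough, decaying L/M/N diastolic ripple).
DEFAULT_WAVES: tuple[WaveComponent, ...] = (
    WaveComponent("G", 0.10, -0.20, 0.015),
    WaveComponent("H", 0.17, +0.50, 0.018),
    WaveComponent("I", 0.22, -0.60, 0.018),
    WaveComponent("J", 0.28, +1.00, 0.020),
    WaveComponent("K", 0.35, -0.50, 0.025),
    WaveComponent("L", 0.45, +0.25, 0.030),
    WaveComponent("M", 0.52, -0.15, 0.030),
    WaveComponent("N", 0.60, +0.12, 0.030),
)


def validate_components(components: Sequence[WaveComponent]) -> None:
    """Check the lettered-wave invariants, raising :class:`InvalidConfigError`.

    Latencies must strictly increase in G..N order, signs must match the
    headward/footward convention, widths must be positive, and J (when
    present) must carry the largest absolute amplitude.
    """
    by_name: dict[str, WaveComponent] = {}
    for c in components:
        if c.name not in WAVE_ORDER:
            raise InvalidConfigError(f"unknown wave name {c.name!r}")
        if c.name in by_name:
            raise InvalidConfigError(f"duplicate wave {c.name!r}")
        if c.width <= 0:
            raise InvalidConfigError(f"wave {c.name}: width must be > 0")
        expected_sign = 1.0 if c.name in _HEADWARD else -1.0
        if c.amplitude * expected_sign < 0:
            side = "headward (positive)" if expected_sign > 0 else "footward (negative)"
            raise InvalidConfigError(f"wave {c.name} must be {side}")
        by_name[c.name] = c
    present = [by_name[n] for n in WAVE_ORDER if n in by_name]
    lats = [c.latency for c in present]
    if any(b <= a for a, b in zip(lats, lats[1:])):
        raise InvalidConfigError("wave latencies must strictly increase in G<H<I<J<K<L<M<N order")
    if "J" in by_name:
        jamp = abs(by_name["J"].amplitude)
        if any(abs(c.amplitude) > jamp for c in components if c.name != "J"):
            raise InvalidConfigError("|J| must be the maximum absolute amplitude")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for synthetic dataset generation."""

    n_hc: int = 67
    n_hpt: int = 61
    duration: float = 120.0  # seconds per recording
    fs: float = 100.0  # Hz
    hr_mean: float = 70.0  # beats/min
    hr_sd: float = 3.0  # beats/min
    resp_freq: float = 0.25  # Hz
    resp_depth: float = 0.2  # fractional amplitude modulation in [0, 1)
    noise_sd: float = 0.1  # arbitrary units
    hpt_amp_jump_prob: float = 0.3  # per-beat probability
    hpt_amp_jump_scale: float = 2.0  # multiplicative factor > 1
    hpt_hr_sd_scale: float = 2.0  # factor >= 1
    seed: int = 0
    waves: tuple[WaveComponent, ...] = field(default=DEFAULT_WAVES)

    def validate(self) -> None:
        if self.n_hc < 0 or self.n_hpt < 0:
            raise InvalidConfigError("subject counts must be >= 0")
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidConfigError("duration and fs must be > 0")
        if self.hr_mean <= 0:
            raise InvalidConfigError("hr_mean must be > 0 (inter-beat interval must be positive)")
        if self.hr_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("hr_sd and noise_sd must be >= 0")
        if not 0.0 <= self.resp_depth < 1.0:
            raise InvalidConfigError("resp_depth must lie in [0, 1)")
        if self.resp_freq <= 0:
            raise InvalidConfigError("resp_freq must be > 0")
        if not 0.0 <= self.hpt_amp_jump_prob <= 1.0:
            raise InvalidConfigError("hpt_amp_jump_prob must lie in [0, 1]")
        if self.hpt_amp_jump_scale <= 1.0:
            raise InvalidConfigError("hpt_amp_jump_scale must be > 1")
        if self.hpt_hr_sd_scale < 1.0:
            raise InvalidConfigError("hpt_hr_sd_scale must be >= 1")
        validate_components(self.waves)


@dataclass
class BCGRecord:
    """One labelled single-channel BCG recording."""

    subject_id: str
    label: str  # HC or HPT
    fs: float
    samples: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def make_wave_template(
    components: Sequence[WaveComponent],
    beat_duration: float,
    fs: float,
) -> np.ndarray:
    """Render one beat as a sum of Gaussian deflections on the sample grid.

    Each component contributes ``a * exp(-(t - latency)^2 / (2 width^2))``.
    An empty component list yields an all-zero beat.
    """
    validate_components(components)
    if components:
        need = max(c.latency for c in components) + 3 * max(c.width for c in components)
        if beat_duration < need:
            raise InvalidConfigError(
                f"beat_duration {beat_duration:g}s too short; needs >= {need:g}s "
                "(max latency + 3 max width)"
            )
    n = int(round(beat_duration * fs))
    t = np.arange(n) / fs
    beat = np.zeros(n)
    for c in components:
        beat += c.amplitude * np.exp(-((t - c.latency) ** 2) / (2.0 * c.width**2))
    return beat


def _default_beat_duration(components: Sequence[WaveComponent]) -> float:
    if not components:
        return 0.7
    return max(c.latency for c in components) + 4 * max(c.width for c in components)


def generate_recording(
    config: SynthConfig,
    label: str,
    subject_id: str,
    rng: np.random.Generator,
) -> BCGRecord:
    """Generate one labelled recording.

    Beats are placed at onsets separated by intervals drawn from
    ``Normal(60/hr_mean, sd_s)`` where ``sd_s`` converts the beats/min
    spread to seconds via the delta method ``60*hr_sd/hr_mean**2``.  For
    the HPT class the interval spread is multiplied by ``hpt_hr_sd_scale``
    and each beat's amplitude is multiplied by ``hpt_amp_jump_scale`` with
    probability ``hpt_amp_jump_prob``.  The assembled beat train is then
    modulated by ``1 + resp_depth*sin(2*pi*resp_freq*t)`` and white
    Gaussian noise of standard deviation ``noise_sd`` is added.
    """
    config.validate()
    if label not in (HC_LABEL, HPT_LABEL):
        raise ValueError(f"label must be {HC_LABEL!r} or {HPT_LABEL!r}, got {label!r}")

    n = int(round(config.duration * config.fs))
    signal = np.zeros(n)
    beat = make_wave_template(config.waves, _default_beat_duration(config.waves), config.fs)

    mean_ibi = 60.0 / config.hr_mean
    sd_ibi = 60.0 * config.hr_sd / config.hr_mean**2
    if label == HPT_LABEL:
        sd_ibi *= config.hpt_hr_sd_scale

    onset = 0.0
    n_beats = 0
    while True:
        idx = int(round(onset * config.fs))
        if idx >= n:
            break
        stop = min(idx + len(beat), n)
        amp = 1.0
        if label == HPT_LABEL and rng.random() < config.hpt_amp_jump_prob:
            amp = config.hpt_amp_jump_scale
        signal[idx:stop] += amp * beat[: stop - idx]
        n_beats += 1
        ibi = rng.normal(mean_ibi, sd_ibi)
        # Guard against pathological draws; intervals cannot collapse or go negative.
        onset += max(ibi, 0.3 * mean_ibi)

    t = np.arange(n) / config.fs
    signal *= 1.0 + config.resp_depth * np.sin(2.0 * np.pi * config.resp_freq * t)
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n)

    return BCGRecord(
        subject_id=subject_id,
        label=label,
        fs=config.fs,
        samples=signal,
        meta={"n_beats": n_beats, "duration": config.duration},
    )


def generate_dataset(config: SynthConfig) -> tuple[list[BCGRecord], dict[str, str]]:
    """Generate ``n_hc`` HC and ``n_hpt`` HPT recordings plus an id->label manifest.

    Per-subject random streams are spawned deterministically from
    ``config.seed`` so the full dataset is a pure function of the config.
    """
    config.validate()
    records: list[BCGRecord] = []
    manifest: dict[str, str] = {}
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_hc + config.n_hpt)
    k = 0
    for i in range(config.n_hc):
        sid = f"HC{i:03d}"
        records.append(generate_recording(config, HC_LABEL, sid, np.random.default_rng(children[k])))
        manifest[sid] = HC_LABEL
        k += 1
    for i in range(config.n_hpt):
        sid = f"HPT{i:03d}"
        records.append(generate_recording(config, HPT_LABEL, sid, np.random.default_rng(children[k])))
        manifest[sid] = HPT_LABEL
        k += 1
    return records, manifest


def write_dataset(records: Sequence[BCGRecord], manifest: dict[str, str],
                  outdir: str | Path, config: SynthConfig | None = None) -> Path:
    """Write recordings as two-column CSVs plus a JSON manifest; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        with open(outdir / f"{rec.subject_id}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "amplitude"])
            for i, v in enumerate(rec.samples):
                w.writerow([f"{i / rec.fs:.4f}", f"{v:.8g}"])
    entries = [
        {
            "subject_id": rec.subject_id,
            "label": rec.label,
            "fs": rec.fs,
            "duration": rec.duration,
        }
        for rec in records
    ]
    payload: dict = {"subjects": entries}
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["waves"] = [dataclasses.asdict(w) for w in config.waves]
        payload["config"] = cfg
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return outdir


def load_dataset(indir: str | Path) -> tuple[list[BCGRecord], dict[str, str]]:
    """Read back a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        payload = json.load(fh)
    records: list[BCGRecord] = []
    manifest: dict[str, str] = {}
    for entry in payload["subjects"]:
        sid = entry["subject_id"]
        path = indir / f"{sid}.csv"
        try:
            data = np.loadtxt(path, delimiter=",", skiprows=1, usecols=1)
        except ValueError as exc:
            raise ValueError(f"corrupt recording CSV: {path}") from exc
        records.append(BCGRecord(sid, entry["label"], float(entry["fs"]), data))
        manifest[sid] = entry["label"]
    return records, manifest
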