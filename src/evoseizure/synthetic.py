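"""Synthetic scalp EEG with plantable pre-ictal signatures.

Every downstream stage is testable without clinical data: the generator
emulates a 19-channel, 256 Hz 10-20 recording regime with annotated seizure
onsets, per-seizure 4-h training segments and a long continuous testing
stretch.

Background model (per channel): coloured ``1/f^gamma`` noise plus a
low-amplitude alpha rhythm generated as 8-12 Hz band-limited (waxing and
waning) noise — the simplest process with a realistic EEG band-power
spectrum.  A band-limited noise component in a chosen analysis band is
present on every channel at baseline amplitude; on the *signature
electrodes* its amplitude gain rises from 1 to ``effect_size`` over the
first ``signature_ramp_fraction`` of the planted window
``[onset - signature_onset, onset]`` and then plateaus — a gradual pre-ictal
drift that settles into an established pre-ictal state — while the channel
is renormalized by its expected total RMS so the signature is a shift of
power into the band rather than a broadband amplitude change.  With
``effect_size = 1`` the record carries no signal at all.  Ictal activity is
not modelled beyond a flagged 60-s placeholder burst at onset; the
prediction method never uses ictal samples.

Identical seeds produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .features import BAND_NAMES, BANDS
from .montage import ELECTRODES_10_20
from .recording import EEGRecording, read_recording, write_recording

ICTAL_PLACEHOLDER_SECONDS = 60.0


@dataclass
class SynthConfig:
    """Generation parameters; defaults emulate the target acquisition setting."""

    n_channels: int = 19
    sampling_rate: float = 256.0
    seizure_onsets: tuple[float, ...] = ()
    signature_electrodes: tuple[str, ...] = ()
    signature_band: str = "theta"
    signature_onset_minutes: float = 60.0
    signature_ramp_fraction: float = 0.5
    effect_size: float = 1.0
    noise_exponent: float = 1.0
    noise_rms_uv: float = 20.0
    alpha_amplitude_uv: float = 5.0
    band_rms_uv: float = 6.0
    segment_variability_sigma: float = 0.0
    modulation_sigma: float = 0.0
    modulation_tau_s: float = 300.0
    duration: float | None = None
    seed: int = 0
    channel_labels: tuple[str, ...] = field(default=ELECTRODES_10_20)

    def __post_init__(self) -> None:
        self.seizure_onsets = tuple(float(o) for o in self.seizure_onsets)
        if any(b <= a for a, b in zip(self.seizure_onsets, self.seizure_onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")
        if self.signature_onset_minutes <= 0:
            raise ValueError("signature_onset_minutes must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.signature_band not in BAND_NAMES:
            raise ValueError(f"unknown band '{self.signature_band}'")
        unknown = set(self.signature_electrodes) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"signature electrodes {sorted(unknown)} not in montage")
        self.channel_labels = tuple(self.channel_labels[: self.n_channels])
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("need one label per channel")
        if self.signature_electrodes and self.effect_size != 1.0:
            window = 60.0 * self.signature_onset_minutes
            for a, b in zip(self.seizure_onsets, self.seizure_onsets[1:]):
                if b - window < a:
                    raise ValueError(
                        f"pre-ictal windows of consecutive seizures at {a:.0f} s and "
                        f"{b:.0f} s overlap (signature onset "
                        f"{self.signature_onset_minutes} min)"
                    )

    @property
    def record_duration(self) -> float:
        if self.duration is not None:
            return float(self.duration)
        return (self.seizure_onsets[-1] if self.seizure_onsets else 0.0) + 600.0

    def to_yaml(self, path: str | Path) -> None:
        record = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(record))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        record = yaml.safe_load(Path(path).read_text())
        for key in ("seizure_onsets", "signature_electrodes", "channel_labels"):
            if key in record and record[key] is not None:
                record[key] = tuple(record[key])
        return cls(**record)


@dataclass(frozen=True)
class GroundTruth:
    """What was actually planted: the reference for recovery tests."""

    pre_ictal_starts: tuple[float, ...]
    seizure_onsets: tuple[float, ...]
    electrodes: tuple[str, ...]
    band: str
    effect_size: float
    ictal_intervals: tuple[tuple[float, float], ...] = ()


#: Spectral shaping is applied in independent blocks of this many seconds;
#: the 1/30 Hz resolution resolves every analysis-band edge and the 0.1 Hz
#: bandpass floor, while keeping the FFTs short and cache-friendly.
_BLOCK_SECONDS = 30.0


def _shaped_noise(shape_fn, n: int, n_channels: int, fs: float,
                  rng: np.random.Generator,
                  block_gain: np.ndarray | None = None,
                  band_mods: list[tuple[np.ndarray, np.ndarray]] | None = None) -> np.ndarray:
    """Unit-RMS Gaussian noise with a one-sided spectral gain, all channels at once.

    The complex spectrum is drawn directly (independent 30-s blocks), which is
    equivalent in law to FFT-shaping white noise and an order of magnitude
    faster than full-length transforms.  Only bins with non-zero gain are
    drawn, so narrow-band components cost almost nothing.

    ``block_gain`` (channels x blocks) applies a per-block amplitude gain to
    the whole component; ``band_mods`` is a list of ``(bin_mask, gains)``
    pairs applying per-block gains to a subset of frequency bins (used for
    independent slow band-power wander).
    """
    from scipy import fft

    block = int(round(_BLOCK_SECONDS * fs))
    n_blocks = -(-n // block)
    n_bins = block // 2 + 1
    gain = shape_fn(np.fft.rfftfreq(block, d=1.0 / fs)).astype(np.float32)
    active = np.nonzero(gain)[0]
    draw = rng.standard_normal(
        (n_channels, n_blocks, 2 * len(active)), dtype=np.float32
    ).view(np.complex64)
    spectrum = np.zeros((n_channels, n_blocks, n_bins), dtype=np.complex64)
    spectrum[..., active] = draw * gain[active]
    if band_mods is not None:
        for mask, gains in band_mods:
            spectrum[..., mask] *= gains[..., None].astype(np.float32)
    if block_gain is not None:
        spectrum *= block_gain[..., None].astype(np.float32)
    x = fft.irfft(spectrum, n=block, axis=-1).reshape(n_channels, n_blocks * block)[:, :n]
    rms = np.sqrt(np.einsum("ij,ij->i", x, x) / n)
    return x / rms[:, None]


def _colored_shape(exponent: float):
    def shape(freqs: np.ndarray) -> np.ndarray:
        out = np.zeros_like(freqs)
        out[1:] = freqs[1:] ** (-exponent / 2.0)
        return out

    return shape


def _band_shape(low: float, high: float):
    def shape(freqs: np.ndarray) -> np.ndarray:
        return ((freqs >= low) & (freqs <= high)).astype(float)

    return shape


def _block_amplitude_drift(n_channels: int, n_blocks: int, sigma: float,
                           tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Per-block slow amplitude gains ``exp(sigma * OU(tau))``, stationary AR(1).

    Emulates vigilance-style slow drifts of band amplitudes.  Every channel
    (and every band it is applied to) gets an independent drift, so spectral
    shape — hence the relative band powers — wanders slowly and independently
    across channels and segments, as real scalp EEG does.
    """
    rho = float(np.exp(-_BLOCK_SECONDS / tau_s))
    shocks = rng.standard_normal((n_channels, n_blocks))
    z = np.empty((n_channels, n_blocks))
    z[:, 0] = shocks[:, 0]
    innov = np.sqrt(1 - rho**2)
    for k in range(1, n_blocks):
        z[:, k] = rho * z[:, k - 1] + innov * shocks[:, k]
    return np.exp(sigma * z)


def _signature_gain(t: np.ndarray, onsets: tuple[float, ...], window_s: float,
                    effect_size: float, ramp_fraction: float = 0.5) -> np.ndarray:
    """Band amplitude gain: 1 outside the planted windows; inside, a linear
    rise from 1 to ``effect_size`` over the first ``ramp_fraction`` of the
    window, then a plateau at ``effect_size`` until onset — a transitional
    drift that settles into an established pre-ictal state.
    """
    gain = np.ones_like(t)
    ramp_s = max(ramp_fraction, 1e-9) * window_s
    for onset in onsets:
        mask = (t >= onset - window_s) & (t <= onset)
        tau = t[mask] - (onset - window_s)
        gain[mask] = 1.0 + (effect_size - 1.0) * np.minimum(tau / ramp_s, 1.0)
    return gain


def generate_recording(config: SynthConfig) -> tuple[EEGRecording, GroundTruth]:
    """One continuous multichannel record with the configured seizure onsets."""
    fs = config.sampling_rate
    n = int(round(config.record_duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    band = next(b for b in BANDS if b[0] == config.signature_band)
    window_s = 60.0 * config.signature_onset_minutes
    gain = _signature_gain(t, config.seizure_onsets, window_s, config.effect_size,
                           config.signature_ramp_fraction)

    n_ch = config.n_channels
    block = int(round(_BLOCK_SECONDS * fs))
    n_blocks = -(-n // block)
    freqs_block = np.fft.rfftfreq(block, d=1.0 / fs)

    # Independent slow power wander per channel per band.  Each dedicated
    # component (alpha rhythm, signature-band component) shares its band's
    # drift so that all content inside one band wanders as one process.
    band_mods = None
    alpha_gain = None
    band_comp_gain = None
    if config.modulation_sigma > 0:
        band_mods = []
        drift = {}
        for name, lo, hi in BANDS:
            mask = (freqs_block >= lo) & (freqs_block <= hi)
            drift[name] = _block_amplitude_drift(
                n_ch, n_blocks, config.modulation_sigma, config.modulation_tau_s, rng
            )
            band_mods.append((mask, drift[name]))
        alpha_gain = drift["alpha"]
        band_comp_gain = drift[config.signature_band]

    # Per-record, per-channel amplitude factors for each component: emulates
    # session-to-session variability (electrode impedance, vigilance state),
    # so absolute amplitudes and band baselines differ between segments while
    # each segment stays stationary.
    sv = config.segment_variability_sigma
    factors = np.exp(sv * rng.standard_normal((3, n_ch))).astype(np.float32)

    samples = config.noise_rms_uv * _shaped_noise(
        _colored_shape(config.noise_exponent), n, n_ch, fs, rng, band_mods=band_mods
    )
    samples *= factors[0][:, None]
    # Alpha rhythm as 8-12 Hz band-limited noise: it waxes and wanes like a
    # physiological alpha instead of holding a metronomic amplitude.
    alpha = _shaped_noise(_band_shape(8.0, 12.0), n, n_ch, fs, rng, block_gain=alpha_gain)
    samples += (config.alpha_amplitude_uv * factors[1])[:, None] * alpha
    del alpha
    band_component = _shaped_noise(
        _band_shape(band[1], band[2]), n, n_ch, fs, rng, block_gain=band_comp_gain
    )
    band_component *= (config.band_rms_uv * factors[2])[:, None]

    # On signature electrodes the band amplitude gain ramps 1 -> effect_size
    # across the planted window and the channel is rescaled by the expected
    # total RMS: the signature is a shift of power *into* the band (what the
    # relative-power features see), not a broadband amplitude change.
    gain32 = gain.astype(np.float32)
    p_rest = config.noise_rms_uv**2 + config.alpha_amplitude_uv**2
    p_band = config.band_rms_uv**2
    scale = np.sqrt((p_rest + p_band * gain32**2) / (p_rest + p_band))
    for c, label in enumerate(config.channel_labels):
        if label in config.signature_electrodes:
            samples[c] = (samples[c] + band_component[c] * gain32) / scale
        else:
            samples[c] += band_component[c]
    del band_component

    ictal: list[tuple[float, float]] = []
    for onset in config.seizure_onsets:
        stop = min(onset + ICTAL_PLACEHOLDER_SECONDS, config.record_duration)
        if stop > onset:
            burst = (t >= onset) & (t < stop)
            samples[:, burst] += (
                3.0 * config.noise_rms_uv * np.sin(2 * np.pi * 3.0 * t[burst])
            ).astype(np.float32)
            ictal.append((float(onset), float(stop)))

    rec = EEGRecording(
        samples=samples,
        sampling_rate=fs,
        channel_labels=config.channel_labels,
        seizure_onsets=np.asarray(config.seizure_onsets),
    )
    truth = GroundTruth(
        pre_ictal_starts=tuple(o - window_s for o in config.seizure_onsets),
        seizure_onsets=config.seizure_onsets,
        electrodes=config.signature_electrodes,
        band=config.signature_band,
        effect_size=config.effect_size,
        ictal_intervals=tuple(ictal),
    )
    return rec, truth


@dataclass
class PatientDataset:
    """Per-seizure training segments plus one continuous testing stretch."""

    train_records: list[EEGRecording]
    test_record: EEGRecording
    train_truths: list[GroundTruth]
    test_truth: GroundTruth
    config: SynthConfig

    def save(self, directory: str | Path) -> Path:
        """Write the dataset in the CSV dialect plus one combined annotation table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, rec in enumerate(self.train_records, start=1):
            name = f"train_{i:02d}"
            write_recording(rec, directory / f"{name}.csv", segment_id=name)
            rows.extend((name, float(o)) for o in rec.seizure_onsets)
        write_recording(self.test_record, directory / "test.csv", segment_id="test")
        rows.extend(("test", float(o)) for o in self.test_record.seizure_onsets)
        import pandas as pd

        pd.DataFrame(rows, columns=["segment_id", "onset_s"]).to_csv(
            directory / "annotations.csv", index=False
        )
        self.config.to_yaml(directory / "synth_config.yaml")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PatientDataset":
        directory = Path(directory)
        config = SynthConfig.from_yaml(directory / "synth_config.yaml")
        train = sorted(directory.glob("train_*.csv"))
        train = [p for p in train if not p.name.endswith(".annotations.csv")]
        records = [read_recording(p, expected_sampling_rate=config.sampling_rate) for p in train]
        test = read_recording(directory / "test.csv", expected_sampling_rate=config.sampling_rate)
        window_s = 60.0 * config.signature_onset_minutes
        truths = [
            GroundTruth(
                pre_ictal_starts=tuple(float(o) - window_s for o in r.seizure_onsets),
                seizure_onsets=tuple(float(o) for o in r.seizure_onsets),
                electrodes=config.signature_electrodes,
                band=config.signature_band,
                effect_size=config.effect_size,
            )
            for r in records + [test]
        ]
        return cls(records, test, truths[:-1], truths[-1], config)


def generate_patient(
    config: SynthConfig,
    n_train_seizures: int,
    n_test_seizures: int,
    train_segment_hours: float = 4.0,
    test_lead_minutes: float = 90.0,
    test_spacing_minutes: float = 150.0,
    test_tail_minutes: float = 30.0,
) -> PatientDataset:
    """Generate one synthetic patient.

    Training seizures come as chronologically indexed segments of exactly
    ``train_segment_hours`` ending at their onset (the last recorded hours
    before each seizure); testing data is one continuous stretch containing
    ``n_test_seizures`` onsets.  Per-segment random streams are spawned from
    ``config.seed`` so the whole patient is reproducible from one integer.
    """
    if n_train_seizures < 2:
        raise ValueError("at least 2 training seizures are required (train/test splits)")
    if n_test_seizures < 1:
        raise ValueError("at least 1 testing seizure is required")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_train_seizures + 1)

    segment_s = 3600.0 * train_segment_hours
    train_records, train_truths = [], []
    for i in range(n_train_seizures):
        seg_config = replace(
            config,
            seizure_onsets=(segment_s,),
            duration=segment_s,
            seed=int(seeds[i] % (2**31)),
        )
        rec, truth = generate_recording(seg_config)
        train_records.append(rec)
        train_truths.append(truth)

    onsets = tuple(
        60.0 * (test_lead_minutes + i * test_spacing_minutes) for i in range(n_test_seizures)
    )
    test_config = replace(
        config,
        seizure_onsets=onsets,
        duration=onsets[-1] + 60.0 * test_tail_minutes,
        seed=int(seeds[-1] % (2**31)),
    )
    test_record, test_truth = generate_recording(test_config)
    return PatientDataset(train_records, test_record, train_truths, test_truth, config)
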