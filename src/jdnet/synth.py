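"""Synthetic epoched EEG cohorts with controllable coupling structure.

The generator emulates the shape of an event-related study — two groups
(13 vs 14 subjects by default), multichannel epoched recordings at 256 Hz
with a pre-stimulus baseline, 23-87 epochs per subject — while giving
analytic control over which channel pairs share variance.

Channels are organized into *local modules* (adjacent pairs by default),
each driven by its own band-limited oscillator at a modest mixing weight.
A single *integration core* oscillator is additionally mixed, at the
between-module weight, into the channels of the first few modules. The two
groups differ only in that weight: a group with a strong core develops a
tightly coupled clique of core channels (clustered, integrated networks),
while a group with a weak core retains only local pairwise synchrony and
its thresholded graphs look random and fragmented — an "integration loss"
phenotype. Sources are stimulus-locked sinusoids inside the pass band:
each has a subject-level phase and frequency, with small per-epoch phase
jitter, so epoch averaging retains the locked component while white channel
noise averages out (the premise of evoked-response analysis). None of the spatial realism of real
EEG (volume conduction, artefacts, 1/f background) is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .preprocess import EpochedRecording

__all__ = [
    "SourceModel",
    "CohortSpec",
    "modular_source_model",
    "generate_subject",
    "generate_cohort",
]


@dataclass
class SourceModel:
    """Linear mixing of band-limited oscillators into channels.

    ``mixing`` is channels x sources with non-negative weights; ``freqs``
    holds one centre frequency (Hz) per source; ``modules`` assigns each
    channel to a local module.
    """

    freqs: np.ndarray
    mixing: np.ndarray
    noise_sd: float
    modules: np.ndarray
    band: tuple[float, float] = (9.0, 34.0)
    freq_jitter_hz: float = 0.5
    phase_jitter_rad: float = 0.5

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.modules = np.asarray(self.modules, dtype=int)
        if self.mixing.ndim != 2 or self.mixing.shape[1] != self.freqs.size:
            raise ConfigError("mixing must be channels x n_sources")
        if (self.mixing < 0).any():
            raise ConfigError("mixing weights must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be non-negative")
        silent = (self.mixing.sum(axis=1) == 0) & (self.noise_sd == 0)
        if silent.any():
            raise ConfigError(
                f"channels {np.flatnonzero(silent).tolist()} have no source "
                "and no noise"
            )

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_sources(self) -> int:
        return self.mixing.shape[1]


@dataclass
class CohortSpec:
    """Study-shape parameters for a two-group synthetic cohort.

    Defaults mirror the emulated study: 13 vs 14 subjects, 256 Hz, 1.40 s
    epochs (358 samples) with a 0.2 s (51 sample) pre-stimulus, epoch counts
    drawn uniformly from 23-87, and 16 channels at test scale (128-channel
    generation is available by setting ``channels``). The group contrast is
    carried by ``between_weights``: integration-core mixing weight for group
    A and group B respectively; equal weights give exchangeable groups.
    """

    n_group_a: int = 13
    n_group_b: int = 14
    channels: int = 16
    fs: float = 256.0
    epoch_len: int = 358
    prestim: int = 51
    epochs_range: tuple[int, int] = (23, 87)
    within_weight: float = 0.25
    between_weights: tuple[float, float] = (0.0, 0.6)
    core_modules: int = 3
    noise_sd: float = 1.0
    band: tuple[float, float] = (9.0, 34.0)
    module_size: int = 2
    freq_jitter_hz: float = 0.5
    phase_jitter_rad: float = 0.5
    seed: int = 0
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_group_a < 3 or self.n_group_b < 3:
            raise ConfigError("group sizes must be >= 3")
        for w in (*self.between_weights, self.within_weight):
            if not 0.0 <= w <= 1.0:
                raise ConfigError("mixing weights must lie in [0, 1]")
        if not (0.0 < self.band[0] < self.band[1] < self.fs / 2):
            raise ConfigError("band must lie inside (0, fs/2)")
        if self.prestim >= self.epoch_len:
            raise ConfigError("prestim must be shorter than the epoch")
        lo, hi = self.epochs_range
        if not 1 <= lo <= hi:
            raise ConfigError("epochs_range must satisfy 1 <= lo <= hi")
        if self.channels < 2 or self.channels % self.module_size:
            raise ConfigError("channels must be a multiple of module_size, >= 2")


def modular_source_model(
    channels: int = 16,
    module_size: int = 2,
    within_weight: float = 0.25,
    between_weight: float = 0.0,
    core_modules: int = 3,
    noise_sd: float = 1.0,
    band: tuple[float, float] = (9.0, 34.0),
    freq_jitter_hz: float = 0.5,
    phase_jitter_rad: float = 0.5,
) -> SourceModel:
    """Build the module + integration-core mixing matrix.

    Consecutive channel blocks of ``module_size`` form local modules, each
    with its own oscillator mixed at ``within_weight``. One extra core
    oscillator is mixed at ``between_weight`` into every channel of the
    first ``core_modules`` modules, creating between-module coupling among
    the core channels. With ``between_weight = 0`` the core is silent and
    only local (within-module) coupling remains.
    """
    if channels % module_size:
        raise ConfigError("channels must be a multiple of module_size")
    n_modules = channels // module_size
    core_modules = min(core_modules, n_modules)
    n_sources = n_modules + 1
    mixing = np.zeros((channels, n_sources))
    modules = np.arange(channels) // module_size
    for c in range(channels):
        mixing[c, modules[c]] = within_weight
        if modules[c] < core_modules:
            mixing[c, n_modules] = between_weight
    lo, hi = band
    margin = 0.1 * (hi - lo)
    freqs = np.empty(n_sources)
    freqs[:n_modules] = np.linspace(lo + margin, hi - margin, n_modules)
    freqs[n_modules] = 0.5 * (lo + hi) + 0.25 * margin  # core sits mid-band
    return SourceModel(
        freqs=freqs,
        mixing=mixing,
        noise_sd=noise_sd,
        modules=modules,
        band=band,
        freq_jitter_hz=freq_jitter_hz,
        phase_jitter_rad=phase_jitter_rad,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_subject(
    model: SourceModel,
    spec: CohortSpec,
    subject_seed,
) -> EpochedRecording:
    """One subject's epoched block: ``A @ sources + noise`` per epoch.

    Each source is a stimulus-locked cosine: its frequency (centre +-
    ``freq_jitter_hz``, uniform) and base phase are drawn once per subject,
    and each epoch adds Gaussian phase jitter of ``phase_jitter_rad``. Epoch
    averaging therefore retains the locked oscillation while the white
    channel noise shrinks. Bit-identical for identical seeds.
    """
    lo, hi = model.band
    if not (0.0 < lo < hi < spec.fs / 2):
        raise ConfigError("source band must lie inside (0, fs/2)")
    rng = _as_rng(subject_seed)
    n_epochs = int(rng.integers(spec.epochs_range[0], spec.epochs_range[1] + 1))
    t = np.arange(spec.epoch_len) / spec.fs
    freqs = model.freqs + model.freq_jitter_hz * rng.uniform(
        -1.0, 1.0, size=model.n_sources
    )
    base_phase = rng.uniform(0.0, 2.0 * np.pi, size=model.n_sources)
    phases = base_phase[None, :] + model.phase_jitter_rad * rng.standard_normal(
        (n_epochs, model.n_sources)
    )
    # sources[e, s, t]
    sources = np.cos(
        2.0 * np.pi * freqs[None, :, None] * t[None, None, :] + phases[:, :, None]
    )
    sig = np.einsum("cs,est->cte", model.mixing, sources)
    if model.noise_sd > 0:
        sig = sig + model.noise_sd * rng.standard_normal(sig.shape)
    return EpochedRecording(data=sig, fs=spec.fs, prestim_samples=spec.prestim)


def generate_cohort(spec: CohortSpec) -> list[tuple[EpochedRecording, str]]:
    """Two labelled groups differing only in bridge mixing weight.

    Group A uses ``between_weights[0]``, group B ``between_weights[1]``.
    Per-subject randomness comes from disjoint substreams spawned from the
    master seed, so the cohort is fully reproducible end to end.
    """
    models = [
        modular_source_model(
            channels=spec.channels,
            module_size=spec.module_size,
            within_weight=spec.within_weight,
            between_weight=w,
            core_modules=spec.core_modules,
            noise_sd=spec.noise_sd,
            band=spec.band,
            freq_jitter_hz=spec.freq_jitter_hz,
            phase_jitter_rad=spec.phase_jitter_rad,
        )
        for w in spec.between_weights
    ]
    n_total = spec.n_group_a + spec.n_group_b
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    cohort: list[tuple[EpochedRecording, str]] = []
    for idx in range(n_total):
        group = 0 if idx < spec.n_group_a else 1
        rec = generate_subject(models[group], spec, np.random.default_rng(streams[idx]))
        rec.subject_id = f"{spec.labels[group]}{idx:02d}"
        rec.group = spec.labels[group]
        cohort.append((rec, spec.labels[group]))
    return cohort
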