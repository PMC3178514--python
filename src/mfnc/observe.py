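"""Observation models: scalp EEG trials and voxel-wise BOLD series.

Noise enters at three independent stages: the innovations driving the
source dynamics (netsim), physiological noise added to each source's time
course, and measurement noise added per channel (EEG) or per voxel (fMRI).
Each stage draws from its own seeded stream, so toggling one stage leaves
the others bit-identical.

SNR throughout is the ratio of signal variance to noise variance;
``snr=inf`` disables a stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .headmodel import LeadField, SourceDisc
from .netsim import SourceSeries

#: source indices feeding each modality (0-based: S1,S2,S3 / S1,S3,S4)
EEG_SOURCES = (0, 1, 2)
FMRI_SOURCES = (0, 2, 3)


@dataclass
class NoiseSpec:
    """Variance-ratio SNRs of the physiological and measurement stages."""

    snr_phys_eeg: float = 5.0
    snr_phys_fmri: float = 5.0
    snr_meas_eeg: float = 1.0
    snr_meas_fmri: float = 0.2

    def __post_init__(self) -> None:
        for name in ("snr_phys_eeg", "snr_phys_fmri", "snr_meas_eeg", "snr_meas_fmri"):
            v = getattr(self, name)
            if not (v > 0 or math.isinf(v)):
                raise ValueError(f"{name} must be positive or inf, got {v}")


@dataclass
class EEGDataset:
    """trials: (n_trials, n_channels, n_samples); average-referenced."""

    trials: np.ndarray
    sample_rate: float
    reference: str = "average"
    source_indices: tuple[int, ...] = EEG_SOURCES


@dataclass
class FMRIDataset:
    """series: (n_voxels, n_volumes); spatial_profiles are the truth maps."""

    series: np.ndarray
    tr_seconds: float
    spatial_profiles: np.ndarray | None = None
    source_indices: tuple[int, ...] = FMRI_SOURCES


@dataclass
class HRFKernel:
    """Sampled gamma hemodynamic impulse response, unit sum."""

    taps: np.ndarray
    spacing: float
    parameters: dict = field(default_factory=dict)


def gamma_hrf(
    l: int = 13,
    tr: float = 1.5,
    neural_dt: float = 0.02,
    mode: str = "default",
    shape: float = 6.0,
    scale: float = 0.9,
) -> HRFKernel:
    """Gamma-density hemodynamic response kernel.

    ``mode="default"`` interprets ``l`` as TR-spaced support points: the
    kernel spans ``l * tr`` seconds sampled densely at ``neural_dt``
    (13 x 1.5 s = 19.5 s at 20 ms steps -> 975 taps).  ``mode="literal"``
    returns exactly ``l`` taps at ``neural_dt`` spacing.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if neural_dt <= 0:
        raise ValueError("neural_dt must be positive")
    if mode == "literal":
        t = np.arange(l) * neural_dt
    elif mode == "default":
        n = int(round(l * tr / neural_dt))
        t = np.arange(n) * neural_dt
        peak = (shape - 1.0) * scale
        if l * tr < peak:
            import logging

            logging.getLogger(__name__).warning(
                "HRF support %.2fs shorter than the gamma peak %.2fs", l * tr, peak
            )
    else:
        raise ValueError(f"unknown HRF mode {mode!r}")
    taps = stats.gamma.pdf(t, a=shape, scale=scale)
    s = taps.sum()
    if s <= 0:
        raise ValueError("degenerate HRF: all taps zero")
    return HRFKernel(
        taps=taps / s,
        spacing=neural_dt,
        parameters={"shape": shape, "scale": scale, "l": l, "tr": tr, "mode": mode},
    )


def _zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    return (x - m) / s


def _noise_std(snr: float) -> float:
    return 0.0 if math.isinf(snr) else 1.0 / math.sqrt(snr)


def _streams(seed, n: int) -> list[np.random.Generator]:
    """n independent generators spawned from an int seed or SeedSequence."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def render_eeg(
    sources: SourceSeries,
    disc: SourceDisc,
    leadfield: LeadField,
    noise: NoiseSpec | None = None,
    n_trials: int = 40,
    trial_len: int = 55,
    seed: int = 0,
    source_indices: tuple[int, ...] = EEG_SOURCES,
) -> EEGDataset:
    """Project the EEG-visible sources to scalp trials.

    The source run is divided equally into ``n_trials`` segments; the first
    ``trial_len`` samples of each segment form one trial.  Each source
    course is z-normalized over the whole run (keeping the forward mixing
    stationary across trials), physiological noise is added, the noisy
    courses are spread uniformly over their dipole patches and projected
    through the lead field; channels are z-normalized over the run,
    measurement noise is added, and the average reference applied.
    """
    noise = noise or NoiseSpec()
    S = sources.values[list(source_indices)]  # (3, T)
    n_src, T = S.shape
    seg = T // n_trials
    if seg < trial_len:
        raise ValueError(
            f"cannot cut {n_trials} trials of {trial_len} samples from {T} samples"
        )
    phys_rng, meas_rng = _streams(seed, 2)

    X = leadfield.gain
    if X.shape[1] != disc.n_dipoles:
        raise ValueError("leadfield inconsistent with disc")
    n_chan = X.shape[0]
    # per-source forward projections of the (uniform) patch profiles
    proj = np.stack(
        [X[:, disc.per_source_masks[i]].sum(axis=1) for i in source_indices]
    )  # (3, n_chan)

    sd_phys = _noise_std(noise.snr_phys_eeg)
    sd_meas = _noise_std(noise.snr_meas_eeg)
    courses = _zscore(S, axis=1)
    courses = courses + sd_phys * phys_rng.standard_normal(courses.shape)
    scalp = proj.T @ courses  # (n_chan, T)
    # renormalize the scalp record globally (root-mean-square over channels
    # and samples); a per-channel rescale would distort the topographies
    # away from the forward model
    scalp = scalp - scalp.mean(axis=1, keepdims=True)
    rms = scalp.std()
    if rms > 0:
        scalp = scalp / rms
    scalp = scalp + sd_meas * meas_rng.standard_normal(scalp.shape)
    scalp = scalp - scalp.mean(axis=0, keepdims=True)  # average reference
    trials = np.empty((n_trials, n_chan, trial_len))
    for tr in range(n_trials):
        trials[tr] = scalp[:, tr * seg : tr * seg + trial_len]
    return EEGDataset(trials=trials, sample_rate=sources.sample_rate, source_indices=tuple(source_indices))


def render_fmri(
    sources: SourceSeries,
    disc: SourceDisc,
    hrf: HRFKernel,
    noise: NoiseSpec | None = None,
    subsample: int = 75,
    seed: int = 0,
    source_indices: tuple[int, ...] = FMRI_SOURCES,
) -> FMRIDataset:
    """Convolve the fMRI-visible sources with the HRF and sample voxel series.

    Per source: convolve with the kernel, z-normalize, add physiological
    noise.  Voxel series are patch-weighted sums of the noisy courses,
    subsampled every ``subsample`` neural steps, z-normalized per voxel, with
    voxel-wise measurement noise added last.
    """
    noise = noise or NoiseSpec()
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    dt = 1.0 / sources.sample_rate
    if abs(hrf.spacing - dt) > 1e-12:
        raise ValueError(
            f"HRF spacing {hrf.spacing}s does not match the neural sampling interval {dt}s"
        )
    S = sources.values[list(source_indices)]
    n_src, T = S.shape
    phys_rng, meas_rng = _streams(seed, 2)

    bold = sp_signal.fftconvolve(S, hrf.taps[None, :], axes=1)[:, :T]
    bold = _zscore(bold, axis=1)
    bold = bold + _noise_std(noise.snr_phys_fmri) * phys_rng.standard_normal(bold.shape)

    # subsample before the (linear) spatial expansion; identical to
    # expanding first but avoids a voxels x T intermediate
    idx = np.arange(subsample - 1, T, subsample)
    bold_sub = bold[:, idx]  # (n_src, n_volumes)

    profiles = np.zeros((n_src, disc.n_dipoles))
    for row, i in enumerate(source_indices):
        profiles[row, disc.per_source_masks[i]] = 1.0
    series = profiles.T @ bold_sub  # (n_voxels, n_volumes)

    active = series.std(axis=1) > 0
    series[active] = _zscore(series[active], axis=1)
    # measurement noise at image-level SNR: variance ratio taken against the
    # mean voxel signal variance (background voxels carry no signal), as a
    # scanner noise floor common to all voxels
    mean_sig_var = float(np.mean(series.var(axis=1)))
    if math.isinf(noise.snr_meas_fmri):
        sd_meas = 0.0
    else:
        sd_meas = math.sqrt(mean_sig_var / noise.snr_meas_fmri) if mean_sig_var > 0 else 0.0
    series = series + sd_meas * meas_rng.standard_normal(series.shape)
    return FMRIDataset(
        series=series,
        tr_seconds=subsample * dt,
        spatial_profiles=profiles,
        source_indices=tuple(source_indices),
    )
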