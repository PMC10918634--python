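"""Per-replicate spectral preprocessing and replicate averaging.

The chain applied to every technical replicate is:

    Savitzky-Golay smoothing -> SNIP baseline subtraction -> TIC
    normalization -> local noise estimation -> peak detection ->
    monoisotopic peak picking

Low-quality replicates are then dropped, the surviving preprocessed
profiles are averaged, and peak picking plus de-isotoping are repeated on
the averaged profile to give the final per-sample peak list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import savgol_filter
from scipy.stats import poisson

from zoomsid.spectra_io import RawSpectrum, ReplicateGroup

logger = logging.getLogger(__name__)

# Expected spacing of isotopic satellites for singly charged peptides (Da).
ISOTOPE_SPACING_DA = 1.00235
# Poisson rate of the aggregated-isotope model per Da of peptide mass
# (averagine-style: dominated by 1.1% 13C at ~0.044 carbons per Da, plus
# smaller 15N/2H/33S contributions).
ISOTOPE_LAMBDA_PER_DA = 5.1e-4
# Floor used when a spectral region is empty/flat so SNR stays finite.
NOISE_FLOOR_FRACTION = 1e-9


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    Window sizes are in grid points of the profile spectrum; masses and
    distances in Da; ``mono_tolerance`` is relative to the peak mass.
    """

    sg_half_window: int = 10
    sg_poly_order: int = 3
    snip_iterations: int = 100
    snr_threshold: float = 3.0
    peak_half_window: int = 20
    mono_min_cor: float = 0.95
    mono_tolerance: float = 1e-4
    mono_distance: float = ISOTOPE_SPACING_DA
    mono_size_range: tuple[int, int] = (2, 10)
    replicate_min_peaks: int = 5
    replicate_median_fraction: float = 0.5
    noise_window: int = 500

    def __post_init__(self) -> None:
        if self.sg_half_window < 1 or self.sg_poly_order < 1:
            raise ValueError("smoothing window and order must be positive")
        if self.sg_poly_order >= 2 * self.sg_half_window + 1:
            raise ValueError("sg_poly_order must be smaller than the smoothing window")
        if self.snip_iterations < 1 or self.peak_half_window < 1 or self.noise_window < 2:
            raise ValueError("window/iteration parameters must be positive")
        if not (0 < self.mono_min_cor <= 1):
            raise ValueError("mono_min_cor must be in (0, 1]")
        if self.snr_threshold <= 0 or self.mono_tolerance <= 0 or self.mono_distance <= 0:
            raise ValueError("thresholds and tolerances must be positive")
        lo, hi = self.mono_size_range
        if lo < 2 or hi < lo:
            raise ValueError("mono_size_range must satisfy 2 <= lo <= hi")
        if self.replicate_min_peaks < 0 or not (0 < self.replicate_median_fraction <= 1):
            raise ValueError("invalid replicate QC thresholds")


@dataclass
class NoiseEstimate:
    """Local noise level per m/z position (same grid as the spectrum)."""

    mz_grid: np.ndarray
    noise_level: np.ndarray

    def at(self, mz: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(mz, float), self.mz_grid, self.noise_level)


@dataclass
class PeakList:
    """Discrete detected peaks of one sample or replicate."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    is_monoisotopic: np.ndarray = field(default=None)  # type: ignore[assignment]
    failed: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if self.is_monoisotopic is None:
            self.is_monoisotopic = np.zeros(self.mz.size, dtype=bool)
        else:
            self.is_monoisotopic = np.asarray(self.is_monoisotopic, dtype=bool)
        if not (self.mz.shape == self.intensity.shape == self.snr.shape == self.is_monoisotopic.shape):
            raise ValueError("peak list arrays must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peak mz must be strictly ascending")

    def __len__(self) -> int:
        return int(self.mz.size)

    def select(self, mask: np.ndarray) -> "PeakList":
        return PeakList(
            sample_id=self.sample_id,
            mz=self.mz[mask],
            intensity=self.intensity[mask],
            snr=self.snr[mask],
            is_monoisotopic=self.is_monoisotopic[mask],
            failed=self.failed,
        )


def smooth(spectrum: RawSpectrum, cfg: PreprocessConfig) -> RawSpectrum:
    """Savitzky-Golay smoothing; negative fit outputs are clamped to zero."""
    window = 2 * cfg.sg_half_window + 1
    if len(spectrum) <= 2 * cfg.sg_half_window:
        raise ValueError(f"spectrum of length {len(spectrum)} shorter than smoothing window {window}")
    smoothed = savgol_filter(spectrum.intensity, window_length=window, polyorder=cfg.sg_poly_order)
    return spectrum.replace_intensity(np.clip(smoothed, 0.0, None))


def snip_baseline(intensity: np.ndarray, iterations: int) -> np.ndarray:
    """Estimate the baseline by iterative peak clipping (SNIP).

    Windows shrink from ``iterations`` points down to 1, which preserves
    the smooth baseline while clipping away features narrower than the
    largest window. Decreasing windows give the smoother variant of the
    algorithm.
    """
    baseline = intensity.astype(float).copy()
    n = baseline.size
    for m in range(min(iterations, n - 1), 0, -1):
        padded = np.pad(baseline, m, mode="edge")
        mean_of_ends = 0.5 * (padded[: -2 * m] + padded[2 * m :])
        baseline = np.minimum(baseline, mean_of_ends)
    return baseline


def remove_baseline(spectrum: RawSpectrum, cfg: PreprocessConfig) -> RawSpectrum:
    """Subtract the SNIP baseline; output intensities are non-negative."""
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    baseline = snip_baseline(spectrum.intensity, cfg.snip_iterations)
    return spectrum.replace_intensity(np.clip(spectrum.intensity - baseline, 0.0, None))


def normalize_tic(spectrum: RawSpectrum) -> RawSpectrum:
    """Total-ion-current calibration: divide intensities by their sum."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ValueError(f"cannot TIC-normalize all-zero spectrum {spectrum.sample_id!r}")
    return spectrum.replace_intensity(spectrum.intensity / total)


def _windowed_mad(mz: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """1.4826 x MAD around the local median, per block, interpolated."""
    n = values.size
    floor = max(float(np.abs(values).max()) * NOISE_FLOOR_FRACTION, np.finfo(float).tiny)
    starts = list(range(0, n, window))
    # a short trailing block gives a meaningless MAD; merge it into the
    # previous block instead
    if len(starts) > 1 and n - starts[-1] < window // 2:
        starts.pop()
    centers = []
    levels = []
    for k, start in enumerate(starts):
        stop = starts[k + 1] if k + 1 < len(starts) else n
        block = values[start:stop]
        med = np.median(block)
        mad = np.median(np.abs(block - med))
        centers.append(float(mz[start:stop].mean()))
        levels.append(max(1.4826 * float(mad), floor))
    if len(centers) == 1:
        return np.full(n, levels[0])
    return np.interp(mz, np.array(centers), np.array(levels))


def estimate_noise(spectrum: RawSpectrum, window: int | None = None, cfg: PreprocessConfig | None = None) -> NoiseEstimate:
    """Windowed robust noise level (MAD around the local median).

    The spectrum is cut into blocks of ``window`` points; within each
    block the noise is 1.4826 x median(|x - median(x)|), which is a
    consistent estimator of the standard deviation for Gaussian noise and
    is insensitive to sparse peaks. Block levels are interpolated back
    onto the full grid, with a small positive floor so SNR stays finite
    over empty regions.
    """
    if window is None:
        window = cfg.noise_window if cfg is not None else 500
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    grid_level = _windowed_mad(spectrum.mz, spectrum.intensity, window)
    return NoiseEstimate(mz_grid=spectrum.mz.copy(), noise_level=grid_level)


def detect_peaks(spectrum: RawSpectrum, noise: NoiseEstimate, cfg: PreprocessConfig) -> PeakList:
    """Local-maximum peak detection with an SNR threshold.

    A point is a peak apex when it equals the running maximum over
    +-``peak_half_window`` points, rises strictly above its left
    neighbour (plateaus keep their first point), and its intensity is at
    least ``snr_threshold`` times the local noise level.
    """
    x = spectrum.intensity
    n = x.size
    if n == 0:
        return PeakList(spectrum.sample_id, np.array([]), np.array([]), np.array([]))
    size = 2 * cfg.peak_half_window + 1
    local_max = maximum_filter1d(x, size=size, mode="nearest")
    is_apex = (x == local_max) & (x > 0)
    # plateau tie-break: keep the first point of a run of equal values;
    # the first grid point has no rising edge and is never an apex
    left = np.empty(n)
    left[0] = x[0]
    left[1:] = x[:-1]
    is_apex &= x > left
    level = noise.at(spectrum.mz)
    snr = x / np.maximum(level, np.finfo(float).tiny)
    keep = is_apex & (snr >= cfg.snr_threshold)
    return PeakList(
        sample_id=spectrum.sample_id,
        mz=spectrum.mz[keep],
        intensity=x[keep],
        snr=snr[keep],
    )


def model_isotope_pattern(mono_mass: float, n_peaks: int) -> np.ndarray:
    """Relative isotopic abundances for a peptide of given monoisotopic mass.

    Aggregated-isotope intensities are approximated by a Poisson
    distribution whose rate grows linearly with mass (averagine-style
    elemental composition); adequate for correlating envelope shapes in
    the 800-4000 Da ZooMS range.
    """
    lam = ISOTOPE_LAMBDA_PER_DA * float(mono_mass)
    pattern = poisson.pmf(np.arange(n_peaks), lam)
    return pattern / pattern.max()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa = a - a.mean()
    sb = b - b.mean()
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return 0.0
    return float((sa * sb).sum() / denom)


def pick_monoisotopic(peaks: PeakList, cfg: PreprocessConfig) -> PeakList:
    """Collapse isotopic envelopes to their monoisotopic (lowest-mass) peak.

    Peaks are clustered greedily along the mass axis using the expected
    isotopic spacing (relative tolerance ``mono_tolerance``); a cluster
    within ``mono_size_range`` is collapsed only when its intensity
    pattern correlates at least ``mono_min_cor`` with the modelled
    envelope, otherwise all members pass through unchanged. Never
    increases the peak count.
    """
    n = len(peaks)
    if n == 0:
        return peaks
    keep = np.ones(n, dtype=bool)
    mono_flag = np.zeros(n, dtype=bool)
    lo_size, hi_size = cfg.mono_size_range
    consumed = np.zeros(n, dtype=bool)
    for i in range(n):
        if consumed[i]:
            continue
        cluster = [i]
        last = i
        while len(cluster) < hi_size:
            target = peaks.mz[last] + cfg.mono_distance
            tol = cfg.mono_tolerance * peaks.mz[last]
            candidates = np.where(
                (~consumed)
                & (np.arange(n) > last)
                & (np.abs(peaks.mz - target) <= tol)
            )[0]
            if candidates.size == 0:
                break
            nxt = candidates[np.argmin(np.abs(peaks.mz[candidates] - target))]
            cluster.append(int(nxt))
            last = int(nxt)
        if len(cluster) >= lo_size:
            observed = peaks.intensity[cluster]
            model = model_isotope_pattern(peaks.mz[cluster[0]], len(cluster))
            if _pearson(observed, model) >= cfg.mono_min_cor:
                keep[cluster[1:]] = False
                mono_flag[cluster[0]] = True
                consumed[cluster] = True
                continue
        # only the maximal chain from each seed is tested; on failure the
        # seed alone is spent, so a stray shoulder peak preceding a true
        # envelope cannot poison the collapse of the envelope itself
        consumed[i] = True
    out = peaks.select(keep)
    out.is_monoisotopic = mono_flag[keep]
    return out


def filter_replicate_quality(
    replicate_peaks: Sequence[PeakList], cfg: PreprocessConfig
) -> list[PeakList]:
    """Drop low-quality replicates by peak count.

    A replicate is dropped when it has fewer than ``replicate_min_peaks``
    peaks or fewer than ``replicate_median_fraction`` times the group's
    median peak count. May return an empty list (sample fails downstream).
    """
    if not replicate_peaks:
        raise ValueError("empty replicate group")
    counts = np.array([len(p) for p in replicate_peaks], dtype=float)
    median = float(np.median(counts))
    kept: list[PeakList] = []
    for peaks, count in zip(replicate_peaks, counts):
        if count < cfg.replicate_min_peaks or count < cfg.replicate_median_fraction * median:
            logger.info(
                "dropping replicate of %s: %d peaks (min %d, median %.1f)",
                peaks.sample_id,
                int(count),
                cfg.replicate_min_peaks,
                median,
            )
            continue
        kept.append(peaks)
    return kept


def average_replicates(replicates: Sequence[RawSpectrum]) -> RawSpectrum:
    """Pointwise mean profile over replicates on their union m/z grid.

    Replicates on different grids are linearly interpolated onto the
    union of all grids first (zero outside a replicate's range).
    """
    if not replicates:
        raise ValueError("cannot average an empty replicate group")
    if len(replicates) == 1:
        return replicates[0]
    grid = replicates[0].mz
    shared = all(np.array_equal(rep.mz, grid) for rep in replicates[1:])
    if not shared:
        grid = np.unique(np.concatenate([rep.mz for rep in replicates]))
    stack = np.empty((len(replicates), grid.size))
    for k, rep in enumerate(replicates):
        if shared:
            stack[k] = rep.intensity
        else:
            stack[k] = np.interp(grid, rep.mz, rep.intensity, left=0.0, right=0.0)
    return RawSpectrum(
        sample_id=replicates[0].sample_id,
        replicate_index=0,
        mz=grid,
        intensity=stack.mean(axis=0),
        source_path="",
    )


def _preprocess_replicate(
    spectrum: RawSpectrum, cfg: PreprocessConfig
) -> tuple[RawSpectrum, np.ndarray, PeakList]:
    """Per-replicate chain; returns (TIC profile, noise level array, peaks).

    The noise level is measured on the high-frequency component of the
    raw signal (raw minus smoothed intensity, windowed MAD): the
    smoothed baseline-subtracted profile itself carries slowly wandering
    correlated residue from clipping through noise, which would both
    bias a MAD taken on the profile and escape it as false apexes. The
    raw-noise level is the conservative yardstick for the SNR test.
    """
    smoothed = smooth(spectrum, cfg)
    baseline = snip_baseline(smoothed.intensity, cfg.snip_iterations)
    clipped = np.clip(smoothed.intensity - baseline, 0.0, None)
    total = float(clipped.sum())
    if total <= 0:
        raise ValueError(f"cannot TIC-normalize all-zero spectrum {spectrum.sample_id!r}")
    profile = smoothed.replace_intensity(clipped / total)
    highfreq = (spectrum.intensity - smoothed.intensity) / total
    noise_level = _windowed_mad(profile.mz, highfreq, cfg.noise_window)
    noise = NoiseEstimate(mz_grid=profile.mz.copy(), noise_level=noise_level)
    peaks = pick_monoisotopic(detect_peaks(profile, noise, cfg), cfg)
    return profile, noise_level, peaks


def preprocess_replicate(spectrum: RawSpectrum, cfg: PreprocessConfig) -> tuple[RawSpectrum, PeakList]:
    """Run the per-replicate chain; returns (processed profile, peak list)."""
    profile, _, peaks = _preprocess_replicate(spectrum, cfg)
    return profile, peaks


def preprocess_sample(group: ReplicateGroup, cfg: PreprocessConfig | None = None) -> PeakList:
    """Full preprocessing of one sample's replicate group.

    Each replicate is smoothed, baseline-subtracted, TIC-normalized and
    peak-picked; low-quality replicates are dropped; the surviving
    processed profiles are averaged; and peak picking plus de-isotoping
    are repeated on the average. If quality control rejects every
    replicate an empty peak list with ``failed=True`` is returned.
    """
    cfg = cfg or PreprocessConfig()
    if len(group) == 0:
        raise ValueError(f"sample {group.sample_id!r} has no replicates")
    profiles: list[RawSpectrum] = []
    noise_levels: list[np.ndarray] = []
    peak_lists: list[PeakList] = []
    for rep in group.replicates:
        try:
            profile, noise_level, peaks = _preprocess_replicate(rep, cfg)
        except ValueError as exc:
            logger.warning("replicate %s/%d unusable: %s", group.sample_id, rep.replicate_index, exc)
            continue
        profiles.append(profile)
        noise_levels.append(noise_level)
        peak_lists.append(peaks)
    if peak_lists:
        kept_ids = {id(p) for p in filter_replicate_quality(peak_lists, cfg)}
        kept = [k for k, pl in enumerate(peak_lists) if id(pl) in kept_ids]
    else:
        kept = []
    if not kept:
        logger.warning("sample %s: no replicate passed quality control", group.sample_id)
        return PeakList(group.sample_id, np.array([]), np.array([]), np.array([]), failed=True)
    averaged = average_replicates([profiles[k] for k in kept])
    if all(np.array_equal(profiles[k].mz, averaged.mz) for k in kept):
        # mean of the per-replicate noise levels: averaging shrinks iid
        # noise but not the systematic clipping residue, so no 1/sqrt(n)
        noise = NoiseEstimate(
            mz_grid=averaged.mz.copy(),
            noise_level=np.mean([noise_levels[k] for k in kept], axis=0),
        )
    else:
        noise = estimate_noise(averaged, cfg=cfg)
    final = pick_monoisotopic(detect_peaks(averaged, noise, cfg), cfg)
    return replace(final, sample_id=group.sample_id)
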