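"""Seeded synthetic ZooMS spectrum generator with known ground truth.

Generates continuous MALDI-like profiles for a chosen reference species:
Gaussian marker peaks (constant resolving power), optional isotopic
envelopes, a random +0.984 Da deamidation shift per marker, a smooth
decaying chemical baseline, iid detector noise, random non-collagenous
decoy peaks and optional contaminant peaks, replicated as technical
triplicates. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from zoomsid.preprocess import ISOTOPE_LAMBDA_PER_DA, ISOTOPE_SPACING_DA
from zoomsid.refdb import ContaminantRecord, ReferenceDB
from zoomsid.spectra_io import RawSpectrum, ReplicateGroup

# Monoisotopic mass shift of Gln/Asn deamidation (Da).
DEAMIDATION_SHIFT_DA = 0.984016
# Decoy peaks keep this margin (Da) clear of the -0.3/+1.3 match window
# around any reference marker, so planted marker counts stay exact.
DECOY_EXCLUSION = (-0.6, 1.6)


@dataclass
class SynthConfig:
    """Generation parameters for one synthetic sample.

    Intensity units are arbitrary (TIC normalization removes them);
    masses in Da. ``resolving_power`` sets peak FWHM = mass / R.
    """

    species: str = "Loxodonta africana"
    n_markers_present: int = 6
    mass_error_sd: float = 0.05
    deamidation_prob: float = 0.1
    isotope_envelope: bool = True
    baseline_amp: float = 20.0
    noise_sd: float = 1.0
    n_noise_peaks: int = 30
    contaminant_names: tuple[str, ...] = ()
    n_replicates: int = 3
    seed: int = 0
    mz_lo: float = 800.0
    mz_hi: float = 3650.0
    mz_step: float = 0.02
    resolving_power: float = 10000.0
    marker_height: float = 60.0
    decoy_height: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.deamidation_prob <= 1):
            raise ValueError("deamidation_prob must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.n_markers_present < 1:
            raise ValueError("need at least one planted marker")


@dataclass
class SampleTruth:
    """Ground truth of one generated sample."""

    sample_id: str
    species: str
    zooms_taxon: str
    family: str
    order: str
    marker_ids: list[str] = field(default_factory=list)
    marker_masses: list[float] = field(default_factory=list)  # reference masses
    planted_masses: list[float] = field(default_factory=list)  # after shifts
    decoy_masses: list[float] = field(default_factory=list)
    contaminant_masses: list[float] = field(default_factory=list)


def _add_peak(grid: np.ndarray, signal: np.ndarray, mass: float, height: float, sigma: float) -> None:
    lo = np.searchsorted(grid, mass - 6 * sigma)
    hi = np.searchsorted(grid, mass + 6 * sigma)
    if hi <= lo:
        return
    window = grid[lo:hi]
    signal[lo:hi] += height * np.exp(-0.5 * ((window - mass) / sigma) ** 2)


def _isotope_heights(mass: float, height: float, n: int = 4) -> np.ndarray:
    """Envelope heights relative to the monoisotopic peak (Poisson model)."""
    lam = ISOTOPE_LAMBDA_PER_DA * mass
    k = np.arange(n)
    pmf = np.exp(-lam) * lam**k / np.array([1, 1, 2, 6][:n])
    return height * pmf / pmf[0]


def _plan_sample(cfg: SynthConfig, db: ReferenceDB, contaminants: Sequence[ContaminantRecord], rng: np.random.Generator) -> SampleTruth:
    records = db.markers_of(cfg.species)
    if not records:
        raise ValueError(f"species {cfg.species!r} not in reference database")
    if cfg.n_markers_present > len(records):
        raise ValueError(f"species {cfg.species!r} has only {len(records)} markers, {cfg.n_markers_present} requested")
    chosen_idx = sorted(rng.choice(len(records), size=cfg.n_markers_present, replace=False))
    chosen = [records[i] for i in chosen_idx]
    planted: list[float] = []
    for rec in chosen:
        mass = rec.mass_da + rng.normal(0.0, cfg.mass_error_sd)
        if rng.random() < cfg.deamidation_prob:
            mass += DEAMIDATION_SHIFT_DA
        planted.append(mass)

    # decoys stay clear of every marker window of the database, so the
    # number of marker-matching peaks equals the number planted
    all_marker_masses = np.array([rec.mass_da for rec in db.records])
    decoys: list[float] = []
    attempts = 0
    while len(decoys) < cfg.n_noise_peaks and attempts < 50 * max(cfg.n_noise_peaks, 1):
        attempts += 1
        mass = rng.uniform(cfg.mz_lo + 20, cfg.mz_hi - 20)
        rel = mass - all_marker_masses
        if np.any((rel >= DECOY_EXCLUSION[0]) & (rel <= DECOY_EXCLUSION[1])):
            continue
        if any(abs(mass - p) < 3.5 for p in planted + decoys):
            continue
        decoys.append(mass)

    contaminant_masses = [
        rec.mass_da
        for rec in contaminants
        if rec.name in cfg.contaminant_names and cfg.mz_lo + 10 < rec.mass_da < cfg.mz_hi - 10
    ]
    first = chosen[0]
    return SampleTruth(
        sample_id=f"{cfg.species.replace(' ', '_')}_{cfg.seed}",
        species=cfg.species,
        zooms_taxon=first.zooms_taxon,
        family=first.family,
        order=first.order,
        marker_ids=[rec.marker_id for rec in chosen],
        marker_masses=[rec.mass_da for rec in chosen],
        planted_masses=planted,
        decoy_masses=decoys,
        contaminant_masses=contaminant_masses,
    )


def _render_replicate(
    cfg: SynthConfig,
    truth: SampleTruth,
    replicate_index: int,
    rng: np.random.Generator,
) -> RawSpectrum:
    grid = cfg.mz_lo + cfg.mz_step * np.arange(int(round((cfg.mz_hi - cfg.mz_lo) / cfg.mz_step)) + 1)
    signal = np.zeros_like(grid)

    def place(mass: float, height: float) -> None:
        sigma = (mass / cfg.resolving_power) / 2.3548
        if cfg.isotope_envelope:
            for k, h in enumerate(_isotope_heights(mass, height)):
                _add_peak(grid, signal, mass + k * ISOTOPE_SPACING_DA, h, sigma)
        else:
            _add_peak(grid, signal, mass, height, sigma)

    for mass in truth.planted_masses:
        place(mass, cfg.marker_height * rng.uniform(0.6, 1.4))
    for mass in truth.decoy_masses:
        place(mass, cfg.decoy_height * rng.uniform(0.4, 1.6))
    for mass in truth.contaminant_masses:
        place(mass, cfg.marker_height * rng.uniform(0.2, 0.8))

    if cfg.baseline_amp > 0:
        signal += cfg.baseline_amp * np.exp(-(grid - cfg.mz_lo) / 700.0)
    if cfg.noise_sd > 0:
        signal += rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return RawSpectrum(
        sample_id=truth.sample_id,
        replicate_index=replicate_index,
        mz=grid,
        intensity=np.clip(signal, 0.0, None),
    )


def synth_replicates(
    cfg: SynthConfig,
    db: ReferenceDB,
    contaminants: Sequence[ContaminantRecord] = (),
) -> tuple[ReplicateGroup, SampleTruth]:
    """Generate one sample's technical replicates plus its ground truth.

    The planted peptide masses (including deamidation shifts and mass
    error) are drawn once per sample — replicates are spots of the same
    digest — while peak heights and noise vary per replicate.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _plan_sample(cfg, db, contaminants, rng)
    reps = [_render_replicate(cfg, truth, r, rng) for r in range(1, cfg.n_replicates + 1)]
    return ReplicateGroup(sample_id=truth.sample_id, replicates=reps), truth


def synth_spectrum(
    cfg: SynthConfig,
    db: ReferenceDB,
    contaminants: Sequence[ContaminantRecord] = (),
) -> tuple[RawSpectrum, SampleTruth]:
    """Generate a single replicate spectrum plus its ground truth."""
    group, truth = synth_replicates(replace(cfg, n_replicates=1), db, contaminants)
    return group.replicates[0], truth


def synth_dataset(
    n_samples: int,
    db: ReferenceDB,
    seed: int = 0,
    contaminants: Sequence[ContaminantRecord] = (),
    out_dir: str | Path | None = None,
    base_cfg: SynthConfig | None = None,
    n_markers_range: tuple[int, int] = (5, 7),
    species_pool: Sequence[str] | None = None,
) -> tuple[list[ReplicateGroup], list[SampleTruth]]:
    """Generate a dataset of samples with random species and marker counts.

    Species are drawn uniformly from ``species_pool`` (default: all
    species of ``db``); the planted marker count is uniform over
    ``n_markers_range`` clipped to each species' availability. With
    ``out_dir`` set, replicate spectra are written as two-column text
    files (``<sample>_<replicate>.txt``) together with ``truth.csv``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    base_cfg = base_cfg or SynthConfig()
    pool = list(species_pool) if species_pool is not None else db.species()
    master = np.random.default_rng(seed)
    groups: list[ReplicateGroup] = []
    truths: list[SampleTruth] = []
    for i in range(n_samples):
        species = pool[int(master.integers(len(pool)))]
        available = len(db.markers_of(species))
        lo = min(n_markers_range[0], available)
        hi = min(n_markers_range[1], available)
        n_markers = int(master.integers(lo, hi + 1))
        cfg = replace(
            base_cfg,
            species=species,
            n_markers_present=n_markers,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        group, truth = synth_replicates(cfg, db, contaminants)
        sample_id = f"S{i:03d}_{truth.species.replace(' ', '_')}"
        truth.sample_id = sample_id
        group = ReplicateGroup(
            sample_id=sample_id,
            replicates=[
                RawSpectrum(sample_id, rep.replicate_index, rep.mz, rep.intensity, rep.source_path)
                for rep in group.replicates
            ],
        )
        groups.append(group)
        truths.append(truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for group in groups:
            for rep in group.replicates:
                path = out_dir / f"{group.sample_id}_{rep.replicate_index}.txt"
                np.savetxt(path, np.column_stack([rep.mz, rep.intensity]), fmt="%.5f %.6f")
        with open(out_dir / "truth.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "manual_label", "species", "family", "order", "n_markers", "planted_masses"])
            for truth in truths:
                writer.writerow(
                    [
                        truth.sample_id,
                        truth.zooms_taxon,
                        truth.species,
                        truth.family,
                        truth.order,
                        len(truth.planted_masses),
                        ";".join(f"{m:.4f}" for m in truth.planted_masses),
                    ]
                )
    return groups, truths
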