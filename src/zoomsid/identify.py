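"""Correlation-based taxonomic identification of peak lists.

The sample's monoisotopic peak list is discretized onto a fixed mass grid
as a binary indicator vector and Gaussian-smoothed; each reference
species is discretized as a binary vector of asymmetric match windows
(-0.3 Da instrument accuracy, +1.3 Da to absorb the +1 deamidation
shift) around its marker masses. Candidates are ranked by the Pearson
correlation between the two vectors; markers are matched peak-by-peak in
exact mass arithmetic within the same window; spectra are scanned for
known contaminant masses; and a status (ok / tentative / fail) is
assigned from the number of matched markers of the best candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from zoomsid.preprocess import PeakList
from zoomsid.refdb import ContaminantRecord, MarkerRecord, ReferenceDB

logger = logging.getLogger(__name__)

# Match window around a reference mass, in Da: [mass + WINDOW_LO, mass + WINDOW_HI].
# -0.3 Da is the instrument mass-accuracy band; +1.3 Da additionally absorbs
# the +1 isotope-distribution shift caused by peptide deamidation.
WINDOW_LO = -0.3
WINDOW_HI = 1.3

RESULTS_COLUMNS = (
    "sample_id",
    "rank",
    "species",
    "zooms_taxon",
    "family",
    "order",
    "correlation",
    "n_matched_markers",
    "matched_markers",
    "status",
)
CONTAMINANTS_COLUMNS = ("sample_id", "contaminant", "ref_mass", "sample_mass")


@dataclass(frozen=True)
class MassGrid:
    """Half-open uniform mass binning of [lo, hi)."""

    lo: float
    hi: float
    bin_width: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("grid requires lo < hi")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.hi - self.lo) / self.bin_width))

    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_of(self, mass: np.ndarray) -> np.ndarray:
        """Bin index for each mass; bins are half-open so a boundary mass
        belongs to the higher bin."""
        return np.floor((np.asarray(mass, float) - self.lo) / self.bin_width).astype(int)


def build_grid(lo: float, hi: float, bin_width: float) -> MassGrid:
    return MassGrid(lo=lo, hi=hi, bin_width=bin_width)


@dataclass(frozen=True)
class MatchedMarker:
    marker_id: str
    ref_mass: float
    sample_mass: float

    @property
    def delta(self) -> float:
        return self.sample_mass - self.ref_mass


@dataclass
class CandidateMatch:
    species: str
    zooms_taxon: str
    family: str
    order: str
    correlation: float
    matched_markers: list[MatchedMarker] = field(default_factory=list)
    rank: int = 0

    @property
    def n_matched(self) -> int:
        return len({m.marker_id for m in self.matched_markers})


@dataclass
class IdentificationResult:
    sample_id: str
    candidates: list[CandidateMatch] = field(default_factory=list)
    status: str = "fail"
    contaminant_hits: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def best(self) -> CandidateMatch | None:
        return self.candidates[0] if self.candidates else None


@dataclass
class IdentificationConfig:
    """Grid, smoothing and reporting parameters of the identification step."""

    grid_lo: float = 800.0
    grid_hi: float = 3700.0
    bin_width: float = 0.1
    sigma_bins: float = 2.0
    n_top: int = 3

    def grid(self) -> MassGrid:
        return build_grid(self.grid_lo, self.grid_hi, self.bin_width)


def vectorize_reference(records: Sequence[MarkerRecord], grid: MassGrid) -> np.ndarray:
    """Binary vector: 1 where a bin center falls inside any marker window."""
    vec = np.zeros(grid.n_bins, dtype=float)
    if not records:
        logger.warning("species with zero markers vectorizes to all-zero")
        return vec
    centers = grid.centers()
    for rec in records:
        vec[(centers >= rec.mass_da + WINDOW_LO) & (centers <= rec.mass_da + WINDOW_HI)] = 1.0
    return vec


def vectorize_sample(peaks: PeakList, grid: MassGrid) -> np.ndarray:
    """Binary vector with a 1 in the bin containing each peak mass."""
    vec = np.zeros(grid.n_bins, dtype=float)
    if len(peaks) == 0:
        return vec
    inside = (peaks.mz >= grid.lo) & (peaks.mz < grid.hi)
    if not np.all(inside):
        logger.warning(
            "%s: %d peak(s) outside grid [%g, %g) dropped",
            peaks.sample_id,
            int((~inside).sum()),
            grid.lo,
            grid.hi,
        )
    vec[grid.bin_of(peaks.mz[inside])] = 1.0
    return vec


def smooth_sample_vector(vec: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Discrete Gaussian smoothing of the indicator vector (mass-preserving)."""
    if sigma_bins < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_bins == 0:
        return np.asarray(vec, float).copy()
    return gaussian_filter1d(np.asarray(vec, float), sigma=sigma_bins, mode="constant", cval=0.0)


def correlate(sample_vec: np.ndarray, ref_vec: np.ndarray) -> float:
    """Pearson correlation; degenerate (zero-variance) vectors score 0."""
    a = np.asarray(sample_vec, float)
    b = np.asarray(ref_vec, float)
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.debug("degenerate vector in correlation; score set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_markers(peaks: PeakList, records: Sequence[MarkerRecord]) -> list[MatchedMarker]:
    """One-to-one marker/peak assignment within the asymmetric window.

    Every (marker, peak) pair with sample - reference mass in
    [-0.3, +1.3] Da is a candidate; pairs are accepted greedily by
    smallest absolute mass difference, each marker and each peak used at
    most once. Exact mass arithmetic, independent of the grid.
    """
    pairs: list[tuple[float, int, int]] = []
    for ri, rec in enumerate(records):
        deltas = peaks.mz - rec.mass_da
        for pi in np.where((deltas >= WINDOW_LO) & (deltas <= WINDOW_HI))[0]:
            pairs.append((abs(float(deltas[pi])), ri, int(pi)))
    pairs.sort(key=lambda t: (t[0], records[t[1]].marker_id, t[2]))
    used_markers: set[int] = set()
    used_peaks: set[int] = set()
    matches: list[MatchedMarker] = []
    for _, ri, pi in pairs:
        if ri in used_markers or pi in used_peaks:
            continue
        used_markers.add(ri)
        used_peaks.add(pi)
        rec = records[ri]
        matches.append(MatchedMarker(marker_id=rec.marker_id, ref_mass=rec.mass_da, sample_mass=float(peaks.mz[pi])))
    matches.sort(key=lambda m: m.ref_mass)
    return matches


def scan_contaminants(
    peaks: PeakList, contaminants: Sequence[ContaminantRecord]
) -> list[tuple[str, float, float]]:
    """All (contaminant, peak) pairs within the match window."""
    hits: list[tuple[str, float, float]] = []
    for rec in contaminants:
        deltas = peaks.mz - rec.mass_da
        for pi in np.where((deltas >= WINDOW_LO) & (deltas <= WINDOW_HI))[0]:
            hits.append((rec.name, rec.mass_da, float(peaks.mz[pi])))
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


def classify_status(best: CandidateMatch | None) -> str:
    """ok with >=5 matched markers, tentative with 1-4, fail with none.

    Identifications resting on four or fewer markers are flagged for
    manual inspection rather than accepted outright.
    """
    if best is None or best.n_matched == 0:
        return "fail"
    if best.n_matched <= 4:
        return "tentative"
    return "ok"


def identify_sample(
    peaks: PeakList,
    db: ReferenceDB,
    contaminants: Sequence[ContaminantRecord] = (),
    cfg: IdentificationConfig | None = None,
) -> IdentificationResult:
    """Score one peak list against every species of a reference database.

    Candidates are sorted by descending Pearson correlation; candidates
    with exactly equal scores share a rank and are all reported even
    beyond ``n_top``. The sample status is derived from the top
    candidate's matched-marker count.
    """
    cfg = cfg or IdentificationConfig()
    if len(db) == 0:
        raise ValueError("reference database is empty")
    grid = cfg.grid()
    sample_vec = smooth_sample_vector(vectorize_sample(peaks, grid), cfg.sigma_bins)

    candidates: list[CandidateMatch] = []
    for species in db.species():
        records = db.markers_of(species)
        ref_vec = vectorize_reference(records, grid)
        score = correlate(sample_vec, ref_vec)
        first = records[0]
        candidates.append(
            CandidateMatch(
                species=species,
                zooms_taxon=first.zooms_taxon,
                family=first.family,
                order=first.order,
                correlation=round(score, 12),
                matched_markers=match_markers(peaks, records),
            )
        )
    candidates.sort(key=lambda c: (-c.correlation, c.species))
    distinct_scores: list[float] = []
    for cand in candidates:
        if not distinct_scores or cand.correlation != distinct_scores[-1]:
            distinct_scores.append(cand.correlation)
        cand.rank = distinct_scores.index(cand.correlation) + 1
    top = [c for c in candidates if c.rank <= cfg.n_top]

    hits = scan_contaminants(peaks, contaminants)
    status = "fail" if (len(peaks) == 0 or peaks.failed) else classify_status(top[0] if top else None)
    if status == "fail":
        # no marker evidence at all: candidate ranking is meaningless
        top = []
    return IdentificationResult(sample_id=peaks.sample_id, candidates=top, status=status, contaminant_hits=hits)


def _format_markers(markers: Sequence[MatchedMarker]) -> str:
    return ";".join(f"{m.marker_id}:{m.ref_mass:.4f}:{m.sample_mass:.4f}" for m in markers)


def results_frame(results: Sequence[IdentificationResult]) -> pd.DataFrame:
    """One row per (sample, candidate); failed samples get one empty row."""
    rows = []
    for res in results:
        if not res.candidates:
            rows.append(
                dict(
                    sample_id=res.sample_id,
                    rank="",
                    species="",
                    zooms_taxon="",
                    family="",
                    order="",
                    correlation="",
                    n_matched_markers=0,
                    matched_markers="",
                    status=res.status,
                )
            )
            continue
        for cand in res.candidates:
            rows.append(
                dict(
                    sample_id=res.sample_id,
                    rank=cand.rank,
                    species=cand.species,
                    zooms_taxon=cand.zooms_taxon,
                    family=cand.family,
                    order=cand.order,
                    correlation=f"{cand.correlation:.6f}",
                    n_matched_markers=cand.n_matched,
                    matched_markers=_format_markers(cand.matched_markers),
                    status=res.status,
                )
            )
    frame = pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))
    return frame.sort_values(["sample_id", "rank", "species"], kind="stable").reset_index(drop=True)


def contaminants_frame(results: Sequence[IdentificationResult]) -> pd.DataFrame:
    rows = [
        dict(sample_id=res.sample_id, contaminant=name, ref_mass=f"{ref:.4f}", sample_mass=f"{obs:.4f}")
        for res in results
        for name, ref, obs in res.contaminant_hits
    ]
    frame = pd.DataFrame(rows, columns=list(CONTAMINANTS_COLUMNS))
    return frame.sort_values(["sample_id", "contaminant", "ref_mass", "sample_mass"], kind="stable").reset_index(drop=True)


def run_batch(
    samples: Sequence[PeakList],
    db: ReferenceDB,
    contaminants: Sequence[ContaminantRecord],
    cfg: IdentificationConfig | None = None,
    out_dir: str | Path = ".",
) -> tuple[Path, Path]:
    """Identify many samples; write results and contaminants CSVs.

    Row order is deterministic (sample_id, rank, species), so repeated
    runs on identical inputs produce byte-identical files.
    """
    if not samples:
        raise ValueError("no samples to identify")
    cfg = cfg or IdentificationConfig()
    results = [identify_sample(peaks, db, contaminants, cfg) for peaks in samples]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "results.csv"
    contaminants_path = out_dir / "contaminants.csv"
    results_frame(results).to_csv(results_path, index=False)
    contaminants_frame(results).to_csv(contaminants_path, index=False)
    logger.info("wrote %s and %s (%d samples)", results_path, contaminants_path, len(samples))
    return results_path, contaminants_path


def plot_identification(result: IdentificationResult, peaks: PeakList, db: ReferenceDB, path: str | Path) -> None:
    """Cosmetic per-sample plot: sample peaks with the best candidate's windows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.vlines(peaks.mz, 0, peaks.intensity, color="k", lw=1, label="sample peaks")
    if result.best is not None:
        top = max(peaks.intensity) if len(peaks) else 1.0
        for rec in db.markers_of(result.best.species):
            ax.axvspan(rec.mass_da + WINDOW_LO, rec.mass_da + WINDOW_HI, color="tab:orange", alpha=0.3)
        ax.set_title(f"{result.sample_id}: {result.best.zooms_taxon} (r={result.best.correlation:.3f}, {result.status})")
        ax.set_ylim(0, top * 1.1)
    ax.set_xlabel("m/z (Da)")
    ax.set_ylabel("intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
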