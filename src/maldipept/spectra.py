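"""Spectral preprocessing for linear-mode MALDI-TOF serum peptidome profiles.

The processing chain turns a set of raw profile spectra into a single
sample-by-peak matrix of zero-level peak areas:

    TIC normalisation -> recalibration against prominent common peaks ->
    top-hat baseline subtraction -> Savitzky-Golay smoothing ->
    S/N-thresholded peak detection -> zero-level integration ->
    cross-sample peak alignment

Each step is exposed as a standalone function operating on :class:`Spectrum`
objects, and :func:`process_spectra` runs the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "Spectrum",
    "Peak",
    "ProcessingConfig",
    "PeakMatrix",
    "tic_normalize",
    "smooth",
    "subtract_baseline_tophat",
    "estimate_noise",
    "detect_peaks",
    "integrate_peak_area",
    "recalibrate_spectra",
    "build_peak_matrix",
    "process_spectra",
    "read_spectrum_txt",
    "write_spectrum_txt",
    "read_spectrum_mzml",
]

RESPONSE = "response"
PROGRESSION = "progression"
UNLABELED = "unlabeled"


@dataclass
class Spectrum:
    """One sample's profile trace: intensity as a function of m/z (Da)."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly ascending")

    def crop(self, mz_min: float, mz_max: float) -> "Spectrum":
        keep = (self.mz >= mz_min) & (self.mz <= mz_max)
        return Spectrum(self.mz[keep], self.intensity[keep], self.sample_id)


@dataclass
class Peak:
    """A detected peak with its zero-level integration bounds."""

    mz_centroid: float
    height: float
    area: float
    snr: float
    left_bound: float
    right_bound: float


@dataclass
class ProcessingConfig:
    """Tunable parameters of the preprocessing chain.

    ``baseline_width_fraction`` is the flat structuring-element span of the
    top-hat filter as a fraction of the processed m/z range (the classic
    "minimum baseline width 10%" setting).  ``alignment_tolerance`` is a
    relative m/z window (0.002 = 2000 ppm) used both for recalibration
    matching and for cross-sample peak clustering.
    """

    mz_min: float = 800.0
    mz_max: float = 10000.0
    snr_threshold: float = 5.0
    baseline_width_fraction: float = 0.10
    smoothing_window: int = 9
    smoothing_polyorder: int = 3
    alignment_tolerance: float = 0.002
    presence_fraction: float = 0.25
    prominent_fraction: float = 0.80
    calibration_top_n: int = 20
    smooth_before_baseline: bool = False
    integrate_raw: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.baseline_width_fraction <= 1):
            raise ValueError("baseline_width_fraction must be in (0, 1]")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be below mz_max")


@dataclass
class PeakMatrix:
    """Samples x aligned reference peaks, holding zero-level areas.

    Missing peaks (not detected in a sample) are recorded as 0.  Group labels
    are ``"response"``, ``"progression"`` or ``"unlabeled"``.
    """

    sample_ids: list[str]
    group_labels: list[str]
    reference_mzs: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.reference_mzs = np.asarray(self.reference_mzs, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.reference_mzs)):
            raise ValueError("areas shape must be (n_samples, n_peaks)")
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        if len(self.reference_mzs) > 1 and np.any(np.diff(self.reference_mzs) <= 0):
            raise ValueError("reference_mzs must be strictly ascending")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.reference_mzs)

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.group_labels, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.areas,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{mz:.2f}" for mz in self.reference_mzs],
        )
        df.insert(0, "group", self.group_labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakMatrix":
        if "group" not in df.columns:
            raise ValueError("peak matrix frame requires a 'group' column")
        mz_cols = [c for c in df.columns if c != "group"]
        return cls(
            sample_ids=[str(s) for s in df.index],
            group_labels=[str(g) for g in df["group"]],
            reference_mzs=np.array([float(c) for c in mz_cols]),
            areas=df[mz_cols].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def subset_columns(self, col_idx: np.ndarray) -> "PeakMatrix":
        return PeakMatrix(
            self.sample_ids,
            self.group_labels,
            self.reference_mzs[col_idx],
            self.areas[:, col_idx],
        )


# ---------------------------------------------------------------------------
# single-spectrum operations
# ---------------------------------------------------------------------------

def tic_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities so they sum to one (total-ion-current normalisation)."""
    total = float(np.sum(s.intensity))
    if total <= 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    return Spectrum(s.mz, s.intensity / total, s.sample_id)


def smooth(s: Spectrum, cfg: ProcessingConfig | None = None) -> Spectrum:
    """Savitzky-Golay smoothing, clipped at zero intensity."""
    cfg = cfg or ProcessingConfig()
    w, p = cfg.smoothing_window, cfg.smoothing_polyorder
    if w % 2 == 0 or w < p + 2:
        raise ValueError("smoothing_window must be odd and >= polyorder + 2")
    if w > len(s.mz):
        raise ValueError("smoothing window longer than spectrum")
    sm = signal.savgol_filter(s.intensity, w, p)
    return Spectrum(s.mz, np.clip(sm, 0.0, None), s.sample_id)


def _tophat_size(s: Spectrum, cfg: ProcessingConfig) -> int:
    """Structuring-element size in grid points for the top-hat filter."""
    span_da = cfg.baseline_width_fraction * (cfg.mz_max - cfg.mz_min)
    step = float(np.median(np.diff(s.mz)))
    size = int(round(span_da / step))
    size += 1 - size % 2  # odd, so the flat element is centred
    return max(size, 3)


def subtract_baseline_tophat(s: Spectrum, cfg: ProcessingConfig | None = None) -> Spectrum:
    """Remove the baseline estimated by a morphological opening.

    The baseline is the grey-scale opening (erosion then dilation) of the
    trace with a flat structuring element spanning ``baseline_width_fraction``
    of the processed m/z range; features narrower than the element survive
    subtraction.  Output is floored at zero.
    """
    cfg = cfg or ProcessingConfig()
    size = _tophat_size(s, cfg)
    if size > len(s.mz):
        raise ValueError("structuring element wider than the spectrum")
    baseline = ndimage.grey_opening(s.intensity, size=size, mode="nearest")
    return Spectrum(s.mz, np.clip(s.intensity - baseline, 0.0, None), s.sample_id)


def estimate_noise(s: Spectrum) -> float:
    """Robust noise scale from successive differences.

    1.4826 * median(|x[i+1] - x[i]|) / sqrt(2): the MAD of first differences
    rescaled to the standard deviation of i.i.d. Gaussian noise.  Peaks
    contribute few large differences, which the median ignores.
    """
    if len(s.mz) < 16:
        raise ValueError("need at least 16 points to estimate noise")
    d = np.diff(s.intensity)
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def _peak_bounds(y: np.ndarray, apex: int, delta: float = 0.0) -> tuple[int, int]:
    """Indices of the nearest flanking local minima or zero crossings.

    ``delta`` is a rise tolerance: fluctuations smaller than it do not count
    as a flanking minimum, so noise ripples on a peak's slope are walked
    through.  With delta=0 the walk stops at the first strict local minimum.
    """

    def walk(step: int) -> int:
        i = best = apex
        n = len(y)
        while 0 <= i + step < n:
            j = i + step
            if y[j] <= y[best]:
                best = j
            elif y[j] - y[best] > delta:
                break
            if y[best] <= 0:
                break
            i = j
        return best

    return walk(-1), walk(+1)


def _centroid(mz: np.ndarray, y: np.ndarray, apex: int) -> float:
    """Intensity-weighted mean m/z over the above-half-height region."""
    half = y[apex] / 2.0
    lo = apex
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] >= half:
        hi += 1
    w = y[lo:hi + 1]
    if w.sum() <= 0:
        return float(mz[apex])
    return float(np.average(mz[lo:hi + 1], weights=w))


def detect_peaks(
    s: Spectrum,
    cfg: ProcessingConfig | None = None,
    noise: float | None = None,
) -> list[Peak]:
    """Local maxima with height >= snr_threshold x robust noise level.

    The input is assumed baseline-subtracted (and normally smoothed).  Peak
    bounds run to the nearest flanking local minimum or zero crossing; the
    centroid is the intensity-weighted mean m/z over the above-half-height
    region; the area is the zero-level trapezoidal integral between bounds.

    ``noise`` should be the noise scale of the trace *before* smoothing
    (smoothing correlates neighbouring points, which deflates the
    successive-difference estimator); when omitted it is estimated from
    ``s`` itself.
    """
    cfg = cfg or ProcessingConfig()
    if noise is None:
        noise = estimate_noise(s)
    if noise <= 0:
        # flat or noiseless trace: any nonzero local max is a peak
        threshold = np.finfo(float).tiny
    else:
        threshold = cfg.snr_threshold * noise
    # prominence filters out noise ripples riding on a peak envelope, which
    # are local maxima above the absolute height threshold but not peaks
    idx, _ = signal.find_peaks(s.intensity, height=threshold, prominence=threshold)
    peaks: list[Peak] = []
    y = s.intensity
    if len(idx):
        widths = signal.peak_widths(y, idx, rel_height=0.5)[0]
    for apex, fwhm_pts in zip(idx, widths if len(idx) else []):
        left, right = _peak_bounds(y, apex, delta=2.0 * noise)
        # zero-level bounds never extend past +/-3.5 sigma (sigma from the
        # measured FWHM): keeps noise-floor stretches and neighbouring tails
        # out of the integral at a 0.05% cost for a Gaussian peak
        cap = max(int(np.ceil(1.486 * fwhm_pts)), 1)
        left = max(left, apex - cap)
        right = min(right, apex + cap)
        if right <= left:
            continue
        cen = _centroid(s.mz, y, apex)
        area = float(np.trapezoid(y[left:right + 1], s.mz[left:right + 1]))
        snr = float(y[apex] / noise) if noise > 0 else np.inf
        peaks.append(Peak(cen, float(y[apex]), area, snr,
                          float(s.mz[left]), float(s.mz[right])))
    return peaks


def integrate_peak_area(s: Spectrum, p: Peak) -> float:
    """Zero-level integration: trapezoid of the trace between the bounds."""
    if p.left_bound >= p.right_bound:
        raise ValueError("inverted peak bounds")
    lo = int(np.searchsorted(s.mz, p.left_bound, side="left"))
    hi = int(np.searchsorted(s.mz, p.right_bound, side="right")) - 1
    if lo >= hi:
        return 0.0
    return float(np.trapezoid(s.intensity[lo:hi + 1], s.mz[lo:hi + 1]))


# ---------------------------------------------------------------------------
# multi-spectrum operations
# ---------------------------------------------------------------------------

def _cluster_centroids(centroids: np.ndarray, tol: float) -> list[np.ndarray]:
    """Single-linkage 1-D clustering: split where the relative gap exceeds tol.

    Returns index arrays into the *sorted* centroid order.
    """
    if len(centroids) == 0:
        return []
    order = np.argsort(centroids)
    sorted_c = centroids[order]
    gaps = np.diff(sorted_c)
    # relative gap against the midpoint mass
    split = gaps > tol * 0.5 * (sorted_c[:-1] + sorted_c[1:])
    boundaries = np.flatnonzero(split) + 1
    return [order[i] for i in np.split(np.arange(len(sorted_c)), boundaries)]


def _floor_correct(s: Spectrum) -> Spectrum:
    """Remove the residual noise floor left by opening under noise.

    A morphological opening of a noisy trace under-estimates the baseline by
    roughly the window minimum of the noise, so the subtracted trace sits a
    few noise-SD above zero.  Peaks occupy a small fraction of the m/z range,
    hence the trace median estimates that floor.
    """
    return Spectrum(s.mz, np.clip(s.intensity - np.median(s.intensity), 0.0, None),
                    s.sample_id)


def _internal_peaklist(s: Spectrum, cfg: ProcessingConfig) -> list[Peak]:
    """Baseline-subtract + smooth a working copy and detect peaks on it."""
    work = subtract_baseline_tophat(s.crop(cfg.mz_min, cfg.mz_max), cfg)
    noise = estimate_noise(work)
    work = _floor_correct(smooth(work, cfg))
    return detect_peaks(work, cfg, noise=noise)


def recalibrate_spectra(
    spectra: list[Spectrum], cfg: ProcessingConfig | None = None
) -> list[Spectrum]:
    """Linear per-spectrum m/z recalibration against prominent common peaks.

    Prominent peaks are clusters, among each spectrum's top peaks by height,
    present in at least ``prominent_fraction`` of spectra.  Each spectrum with
    at least 3 matches gets a least-squares linear map m/z' = a*m/z + b onto
    the consensus (mean) positions; spectra with fewer matches pass through
    unchanged.
    """
    cfg = cfg or ProcessingConfig()
    if len(spectra) < 2:
        return list(spectra)
    top_lists = []
    for s in spectra:
        pks = _internal_peaklist(s, cfg)
        pks.sort(key=lambda p: p.height, reverse=True)
        top_lists.append(pks[: cfg.calibration_top_n])

    all_c = np.array([p.mz_centroid for pks in top_lists for p in pks])
    owner = np.array([i for i, pks in enumerate(top_lists) for _ in pks])
    out = []
    consensus = []
    for members in _cluster_centroids(all_c, cfg.alignment_tolerance):
        if len(np.unique(owner[members])) >= cfg.prominent_fraction * len(spectra):
            consensus.append(float(np.mean(all_c[members])))
    consensus_arr = np.sort(np.array(consensus))

    for s, pks in zip(spectra, top_lists):
        matches = []
        for p in pks:
            if len(consensus_arr) == 0:
                break
            j = int(np.argmin(np.abs(consensus_arr - p.mz_centroid)))
            ref = consensus_arr[j]
            if abs(ref - p.mz_centroid) <= cfg.alignment_tolerance * ref:
                matches.append((p.mz_centroid, ref))
        if len(matches) < 3:
            out.append(s)
            continue
        obs = np.array([m[0] for m in matches])
        ref = np.array([m[1] for m in matches])
        a, b = np.polyfit(obs, ref, 1)
        out.append(Spectrum(a * s.mz + b, s.intensity, s.sample_id))
    return out


def build_peak_matrix(
    peaklists: list[list[Peak]],
    cfg: ProcessingConfig | None = None,
    sample_ids: list[str] | None = None,
    group_labels: list[str] | None = None,
) -> PeakMatrix:
    """Align per-sample peak lists into a common reference frame.

    All centroids are clustered by single linkage with a relative gap
    threshold of ``alignment_tolerance``; clusters present in at least
    ``presence_fraction`` of samples become reference peaks (reference m/z =
    mean member centroid).  Per sample the matrix holds the area of its
    member peak (the largest, if several fall in one cluster), else 0.
    """
    cfg = cfg or ProcessingConfig()
    n = len(peaklists)
    if n < 1:
        raise ValueError("need at least one sample")
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    group_labels = group_labels or [UNLABELED] * n

    all_c = np.array([p.mz_centroid for pks in peaklists for p in pks])
    owner = np.array([i for i, pks in enumerate(peaklists) for _ in pks], dtype=int)
    all_area = np.array([p.area for pks in peaklists for p in pks])

    refs: list[float] = []
    cols: list[np.ndarray] = []
    for members in _cluster_centroids(all_c, cfg.alignment_tolerance):
        present = np.unique(owner[members])
        if len(present) < cfg.presence_fraction * n:
            continue
        col = np.zeros(n)
        for m in members:
            i = owner[m]
            col[i] = max(col[i], all_area[m])
        refs.append(float(np.mean(all_c[members])))
        cols.append(col)

    if refs:
        order = np.argsort(refs)
        areas = np.column_stack([cols[i] for i in order])
        ref_arr = np.array([refs[i] for i in order])
    else:
        areas = np.zeros((n, 0))
        ref_arr = np.array([])
    return PeakMatrix(sample_ids, group_labels, ref_arr, areas)


def process_spectra(
    spectra: list[Spectrum],
    cfg: ProcessingConfig | None = None,
    group_labels: list[str] | None = None,
) -> PeakMatrix:
    """Run the full chain: normalize -> recalibrate -> baseline -> smooth ->
    detect -> integrate -> align."""
    cfg = cfg or ProcessingConfig()
    work = [tic_normalize(s.crop(cfg.mz_min, cfg.mz_max)) for s in spectra]
    if len(work) >= 2:
        work = recalibrate_spectra(work, cfg)
    peaklists = []
    for s in work:
        if cfg.smooth_before_baseline:
            t = subtract_baseline_tophat(smooth(s, cfg), cfg)
            noise = estimate_noise(subtract_baseline_tophat(s, cfg))
        else:
            pre = subtract_baseline_tophat(s, cfg)
            noise = estimate_noise(pre)
            t = smooth(pre, cfg)
        t = _floor_correct(t)
        pks = detect_peaks(t, cfg, noise=noise)
        if cfg.integrate_raw:
            raw = _floor_correct(subtract_baseline_tophat(s, cfg))
            pks = [replace(p, area=integrate_peak_area(raw, p)) for p in pks]
        peaklists.append(pks)
    return build_peak_matrix(
        peaklists, cfg,
        sample_ids=[s.sample_id or f"S{i:03d}" for i, s in enumerate(spectra)],
        group_labels=group_labels,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum_txt(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column whitespace text spectrum (m/z, intensity)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("expected two whitespace-separated columns")
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(arr[:, 0], arr[:, 1], sid)


def write_spectrum_txt(s: Spectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([s.mz, s.intensity]), fmt="%.6f %.8g")


def read_spectrum_mzml(path: str | Path) -> list[Spectrum]:
    """Read all spectra from an mzML file (requires pyteomics)."""
    from pyteomics import mzml  # optional dependency

    out = []
    with mzml.MzML(str(path)) as reader:
        for i, entry in enumerate(reader):
            sid = entry.get("id", f"scan{i}")
            out.append(Spectrum(entry["m/z array"], entry["intensity array"], sid))
    return out
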