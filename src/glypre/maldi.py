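"""Targeted quantification of N-glycans from MALDI-TOF peak lists.

The processing chain mirrors targeted glycomics extraction of permethylated,
sodiated N-glycans: linear recalibration on nine known glycan peaks, rolling
minimum/mean baseline subtraction, and summation of the leading isotopologue
peaks of each panel analyte inside a fixed m/z calculation window (default
0.49 m/z full width, i.e. +-0.245 around each predicted isotopologue),
followed by normalization to the sum of all panel analytes.

Points below 990 m/z are ignored, emulating acquisition ion suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .glycans import (
    DEFAULT_CALIBRANTS,
    ElementalFormula,
    GlycanComposition,
    GlycanPanel,
    elemental_formula,
    mono_mass,
    normalize_profile,
)

__all__ = [
    "MassSpectrum",
    "CalibrationModel",
    "CalibrationError",
    "IsotopeEnvelope",
    "EmptyProfileError",
    "PeaklistError",
    "ISOTOPE_SPACING",
    "ION_SUPPRESSION_LIMIT",
    "read_peaklist",
    "fit_calibration",
    "subtract_baseline",
    "envelope",
    "envelope_from_formula",
    "integrate_analyte",
    "extract_profile",
    "process_spectrum",
]

# Average isotopologue spacing of large organic ions (Da).
ISOTOPE_SPACING = 1.00336
# m/z below which the instrument suppresses ions.
ION_SUPPRESSION_LIMIT = 990.0

# Isotopic abundances per element, indexed by nominal mass shift.
_ISOTOPE_ABUNDANCE = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
}


class PeaklistError(ValueError):
    """A peak-list file could not be parsed."""


class CalibrationError(RuntimeError):
    """Too few calibrant peaks were matched."""


class EmptyProfileError(RuntimeError):
    """No analyte signal was extracted from the spectrum."""


@dataclass
class MassSpectrum:
    """Ordered (m/z, intensity) pairs with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


def read_peaklist(path, sample_id: str | None = None, replicate: int | None = None) -> MassSpectrum:
    """Read a two-column ASCII peak list (whitespace- or comma-delimited).

    Lines starting with '#' are comments.  Unsorted rows are sorted and
    duplicate m/z values merged by intensity sum.  Non-numeric rows raise
    :class:`PeaklistError` with the offending line number.
    """
    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 2:
                raise PeaklistError(f"{path}: line {lineno}: expected two columns, got {s!r}")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError:
                raise PeaklistError(f"{path}: line {lineno}: non-numeric row {s!r}") from None
    if not mzs:
        raise PeaklistError(f"{path}: empty peak list")
    mz = np.asarray(mzs)
    inten = np.asarray(ints)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # merge exact duplicates by intensity sum
    uniq, inverse = np.unique(mz, return_inverse=True)
    if len(uniq) != len(mz):
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, inten)
        mz, inten = uniq, summed
    return MassSpectrum(mz, inten, sample_id=sample_id, replicate=replicate)


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Linear m/z correction mapping observed to theoretical axis."""

    slope: float
    intercept: float
    residuals: dict[str, float] = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.residuals)

    @property
    def max_abs_residual(self) -> float:
        return max((abs(v) for v in self.residuals.values()), default=float("nan"))

    def apply(self, s: MassSpectrum) -> MassSpectrum:
        return MassSpectrum(
            self.slope * s.mz + self.intercept,
            s.intensity.copy(),
            sample_id=s.sample_id,
            replicate=s.replicate,
        )


def _apex_log_parabolic(mz: np.ndarray, inten: np.ndarray, i: int) -> float:
    """Sub-grid apex via log-parabolic interpolation (exact for a Gaussian)."""
    if i <= 0 or i >= len(mz) - 1:
        return float(mz[i])
    y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
    if min(y0, y1, y2) <= 0:
        if y0 - 2 * y1 + y2 >= 0:
            return float(mz[i])
        delta = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    else:
        l0, l1, l2 = math.log(y0), math.log(y1), math.log(y2)
        denom = l0 - 2 * l1 + l2
        if denom >= 0:
            return float(mz[i])
        delta = 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = 0.5 * (mz[i + 1] - mz[i - 1])
    return float(mz[i] + delta * step)


def fit_calibration(
    s: MassSpectrum,
    calibrants: tuple[GlycanComposition, ...] = DEFAULT_CALIBRANTS,
    search_window: float = 1.0,
    reject_threshold: float = 0.2,
) -> CalibrationModel:
    """Least-squares linear recalibration on known glycan peaks.

    For each calibrant, the most intense local maximum inside the
    *search_window* (full width, i.e. +-search_window/2, like the
    calculation window) around its theoretical sodiated permethylated m/z is
    matched, with the apex refined by log-parabolic interpolation; a line
    mapping observed to theoretical m/z is fitted.  Matches whose residual
    exceeds *reject_threshold* (e.g. a +1 isotopologue caught by a wide
    search) are dropped iteratively and the line refitted.  Fewer than three
    surviving matches raise :class:`CalibrationError` naming the unmatched
    calibrants.
    """
    half = search_window / 2.0
    observed, theoretical, matched_labels, unmatched = [], [], [], []
    for c in calibrants:
        # target the predicted tallest isotopologue: for heavy glycans the
        # +1 peak outgrows the monoisotopic one, so "most intense in window"
        # must aim at the envelope maximum to stay self-consistent
        env = envelope(c, k=5)
        j_top = int(np.argmax(env.abundances))
        t = mono_mass(c, adduct="Na", permethylated=True) + env.offsets[j_top]
        lo = np.searchsorted(s.mz, t - half)
        hi = np.searchsorted(s.mz, t + half)
        best = None
        for gi in range(lo, hi):
            left = s.intensity[gi - 1] if gi > 0 else -np.inf
            right = s.intensity[gi + 1] if gi < len(s.mz) - 1 else -np.inf
            if s.intensity[gi] > 0 and s.intensity[gi] >= left and s.intensity[gi] > right:
                if best is None or s.intensity[gi] > s.intensity[best]:
                    best = gi
        if best is None:
            unmatched.append(c.label)
            continue
        observed.append(_apex_log_parabolic(s.mz, s.intensity, best))
        theoretical.append(t)
        matched_labels.append(c.label)

    obs = np.asarray(observed)
    theo = np.asarray(theoretical)
    labels = list(matched_labels)
    while True:
        if len(obs) < 3:
            raise CalibrationError(
                f"calibration failed: only {len(obs)} of {len(calibrants)} calibrants "
                f"usable (unmatched: {', '.join(unmatched)})"
            )
        slope, intercept = np.polyfit(obs, theo, 1)
        resid = slope * obs + intercept - theo
        worst = int(np.argmax(np.abs(resid)))
        if abs(resid[worst]) <= reject_threshold:
            break
        unmatched.append(labels[worst])
        keep = np.arange(len(obs)) != worst
        obs, theo = obs[keep], theo[keep]
        labels = [l for i, l in enumerate(labels) if keep[i]]
    residuals = {lab: float(r) for lab, r in zip(labels, resid)}
    return CalibrationModel(float(slope), float(intercept), residuals)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def subtract_baseline(s: MassSpectrum, half_width: float = 5.0) -> MassSpectrum:
    """Rolling-minimum baseline followed by rolling-mean smoothing.

    The baseline is the moving minimum over +-half_width (in axis units)
    smoothed by a moving average of the same width; output intensities are
    clipped at zero.  Idempotent on isolated peaks narrower than the window.
    """
    if len(s) < 3:
        return MassSpectrum(s.mz.copy(), s.intensity.copy(), s.sample_id, s.replicate)
    step = float(np.median(np.diff(s.mz)))
    size = 2 * max(1, int(round(half_width / step))) + 1
    size = min(size, 2 * len(s) - 1)
    baseline = ndimage.minimum_filter1d(s.intensity, size=size, mode="nearest")
    baseline = ndimage.uniform_filter1d(baseline, size=size, mode="nearest")
    out = np.clip(s.intensity - baseline, 0.0, None)
    return MassSpectrum(s.mz.copy(), out, s.sample_id, s.replicate)


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeEnvelope:
    """First-k isotopologue mass offsets and abundances (sum 1)."""

    offsets: tuple[float, ...]
    abundances: tuple[float, ...]


def _element_power(dist: tuple[float, ...], n: int, k: int) -> np.ndarray:
    """First k coefficients of dist**n (polynomial convolution power)."""
    result = np.zeros(k)
    result[0] = 1.0
    base = np.asarray(dist[:k])
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:k]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:k]
    return result


def envelope_from_formula(f: ElementalFormula, k: int = 3) -> IsotopeEnvelope:
    """Aggregated isotopologue abundances of a formula, truncated to k terms."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = np.zeros(k)
    dist[0] = 1.0
    for sym, count in (("C", f.c), ("H", f.h), ("N", f.n), ("O", f.o)):
        if count:
            dist = np.convolve(dist, _element_power(_ISOTOPE_ABUNDANCE[sym], count, k))[:k]
    dist = dist / dist.sum()
    offsets = tuple(j * ISOTOPE_SPACING for j in range(k))
    return IsotopeEnvelope(offsets, tuple(float(x) for x in dist))


def envelope(c: GlycanComposition, k: int = 3, permethylated: bool = True) -> IsotopeEnvelope:
    """Isotope envelope of a (permethylated) glycan composition."""
    return envelope_from_formula(elemental_formula(c, permethylated=permethylated), k=k)


# ---------------------------------------------------------------------------
# Targeted integration
# ---------------------------------------------------------------------------

def _window_indices(mz: np.ndarray, center: float, half: float) -> slice:
    lo = np.searchsorted(mz, center - half, side="left")
    hi = np.searchsorted(mz, center + half, side="right")
    return slice(lo, hi)


def integrate_analyte(
    s: MassSpectrum, c: GlycanComposition, window: float = 0.49, k: int = 3
) -> float:
    """Summed intensity of the first k isotopologue windows of one analyte.

    *window* is the full calculation width; points are counted once even if
    adjacent isotopologue windows overlap.  Absent analytes integrate to 0.
    """
    base = mono_mass(c, adduct="Na", permethylated=True)
    env = envelope(c, k=k)
    mask = np.zeros(len(s), dtype=bool)
    for off in env.offsets:
        sl = _window_indices(s.mz, base + off, window / 2.0)
        mask[sl] = True
    return float(s.intensity[mask].sum())


def _panel_point_weights(
    s: MassSpectrum, panel: GlycanPanel, window: float, k: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-analyte claimed point indices and envelope weights (max over isos)."""
    idx_list, w_list = [], []
    for c in panel.compositions:
        base = mono_mass(c, adduct="Na", permethylated=True)
        env = envelope(c, k=k)
        weights: dict[int, float] = {}
        for off, ab in zip(env.offsets, env.abundances):
            sl = _window_indices(s.mz, base + off, window / 2.0)
            for gi in range(sl.start, sl.stop):
                weights[gi] = max(weights.get(gi, 0.0), ab)
        idx = np.fromiter(weights.keys(), dtype=int, count=len(weights))
        w = np.fromiter(weights.values(), dtype=float, count=len(weights))
        idx_list.append(idx)
        w_list.append(w)
    return idx_list, w_list


def extract_profile(
    s: MassSpectrum, panel: GlycanPanel | None = None, window: float = 0.49, k: int = 3
) -> pd.Series:
    """Relative intensities of all panel analytes, normalized to sum 1.

    Points claimed by a single analyte contribute fully to it; points inside
    overlapping envelopes are integrated jointly and split in proportion to
    predicted envelope abundance times a preliminary per-analyte area
    estimate, conserving total signal.  Raises :class:`EmptyProfileError`
    when nothing is extracted.
    """
    panel = panel or GlycanPanel.default()
    keep = s.mz >= ION_SUPPRESSION_LIMIT
    s2 = MassSpectrum(s.mz[keep], s.intensity[keep], s.sample_id, s.replicate)
    idx_list, w_list = _panel_point_weights(s2, panel, window, k)

    n_points = len(s2)
    claims = np.zeros(n_points, dtype=int)
    for idx in idx_list:
        claims[idx] += 1

    # preliminary areas from exclusively claimed points
    prelim = np.zeros(len(panel))
    for a, idx in enumerate(idx_list):
        if len(idx):
            excl = idx[claims[idx] == 1]
            prelim[a] = s2.intensity[excl].sum()

    # split shared points proportionally to abundance x preliminary area
    weight_sum = np.zeros(n_points)
    eff_w = []
    for a, (idx, w) in enumerate(zip(idx_list, w_list)):
        we = w * max(prelim[a], 1e-12)
        eff_w.append(we)
        weight_sum[idx] += we

    areas = np.zeros(len(panel))
    for a, (idx, we) in enumerate(zip(idx_list, eff_w)):
        if len(idx):
            share = np.where(claims[idx] > 1, we / weight_sum[idx], 1.0)
            areas[a] = float((s2.intensity[idx] * share).sum())
    areas = np.clip(areas, 0.0, None)
    if areas.sum() <= 0:
        raise EmptyProfileError(
            f"no analyte signal extracted from spectrum {s.sample_id!r}"
        )
    return normalize_profile(pd.Series(areas, index=panel.labels))


def process_spectrum(
    s: MassSpectrum,
    panel: GlycanPanel | None = None,
    window: float = 0.49,
    k: int = 3,
    baseline_half_width: float = 5.0,
    calibration_search_window: float = 1.0,
) -> tuple[pd.Series, CalibrationModel]:
    """Full chain: recalibrate, subtract baseline, extract the profile."""
    model = fit_calibration(s, search_window=calibration_search_window)
    calibrated = model.apply(s)
    cleaned = subtract_baseline(calibrated, half_width=baseline_half_width)
    return extract_profile(cleaned, panel=panel, window=window, k=k), model
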