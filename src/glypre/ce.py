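"""CE-LIF electropherogram processing for APTS-labeled desialylated glycans.

Traces are aligned on the highest peak, smoothed (Savitzky-Golay), baseline
subtracted (rolling minimum + mean, as for mass spectra), integrated by
prominence-based peak detection with boundaries at flanking minima, and
assigned to named glycan bins whose migration windows are expressed relative
to the APTS-maltose internal-standard apex.  Co-migrating structures share a
bin, giving the 23-peak desialylated view of the glycome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

__all__ = [
    "Electropherogram",
    "BinMap",
    "AlignmentError",
    "InternalStandardError",
    "align_traces",
    "smooth",
    "subtract_ce_baseline",
    "detect_and_integrate",
    "assign_bins",
    "bin_profile",
    "process_trace",
]


class AlignmentError(RuntimeError):
    """A trace has no unique global maximum to align on."""


class InternalStandardError(RuntimeError):
    """The internal-standard peak could not be identified."""


@dataclass
class Electropherogram:
    """Uniformly sampled (migration time, fluorescence) trace."""

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if len(self.time) < 3:
            raise ValueError("trace too short")
        d = np.diff(self.time)
        if np.any(d <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.max(np.abs(d - d.mean())) > 1e-9:
            raise ValueError("time axis must be uniformly sampled")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


def _unique_apex_time(t: Electropherogram) -> float:
    m = t.signal.max()
    if m <= t.signal.min():
        raise AlignmentError("flat trace: no unique global maximum")
    hits = np.flatnonzero(t.signal == m)
    if len(hits) > 1:
        raise AlignmentError(f"trace has {len(hits)} tied global maxima")
    return float(t.time[hits[0]])


def align_traces(traces: list[Electropherogram]) -> list[Electropherogram]:
    """Shift every trace so its highest-peak apex matches the first trace's.

    Intensities are unchanged; the applied shift (min) is recorded in
    ``meta['alignment_shift_min']``.  Flat or tied-maximum traces raise
    :class:`AlignmentError`.
    """
    if not traces:
        raise ValueError("no traces to align")
    ref_apex = _unique_apex_time(traces[0])
    out = []
    for t in traces:
        shift = ref_apex - _unique_apex_time(t)
        meta = dict(t.meta, alignment_shift_min=shift)
        out.append(Electropherogram(t.time + shift, t.signal.copy(), meta))
    return out


def smooth(t: Electropherogram, window_points: int = 11, polyorder: int = 3) -> Electropherogram:
    """Savitzky-Golay local-polynomial smoothing (area-preserving for
    well-resolved peaks)."""
    if window_points <= polyorder:
        raise ValueError("window_points must exceed polyorder")
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    sm = signal.savgol_filter(t.signal, window_points, polyorder)
    return Electropherogram(t.time.copy(), sm, dict(t.meta))


def subtract_ce_baseline(t: Electropherogram, half_width_min: float = 1.0) -> Electropherogram:
    """Rolling-minimum + rolling-mean baseline on the time axis, clipped at 0."""
    size = 2 * max(1, int(round(half_width_min / t.step))) + 1
    size = min(size, 2 * len(t) - 1)
    baseline = ndimage.minimum_filter1d(t.signal, size=size, mode="nearest")
    baseline = ndimage.uniform_filter1d(baseline, size=size, mode="nearest")
    return Electropherogram(t.time.copy(), np.clip(t.signal - baseline, 0.0, None), dict(t.meta))


_PEAK_COLUMNS = ["apex_time", "start_time", "end_time", "area", "rel_area", "bin"]


def detect_and_integrate(t: Electropherogram, min_prominence: float = 0.005) -> pd.DataFrame:
    """Detect peaks above a prominence threshold and integrate them.

    *min_prominence* is a fraction of the trace maximum.  Peak boundaries sit
    at the signal minima between adjacent apexes (trace ends for the outer
    flanks); areas are trapezoidal integrals and relative areas are fractions
    of the total integrated peak area.  No peaks found yields an empty table.
    """
    prom = min_prominence * float(t.signal.max()) if t.signal.max() > 0 else np.inf
    peaks, _ = signal.find_peaks(t.signal, prominence=prom)
    if len(peaks) == 0:
        return pd.DataFrame(columns=_PEAK_COLUMNS)
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(t.signal[a:b + 1])))
    bounds.append(len(t) - 1)
    rows = []
    for i, p in enumerate(peaks):
        s_idx, e_idx = bounds[i], bounds[i + 1]
        area = float(np.trapezoid(t.signal[s_idx:e_idx + 1], t.time[s_idx:e_idx + 1]))
        rows.append(
            dict(
                apex_time=float(t.time[p]),
                start_time=float(t.time[s_idx]),
                end_time=float(t.time[e_idx]),
                area=max(area, 0.0),
                bin=None,
            )
        )
    table = pd.DataFrame(rows)
    total = table["area"].sum()
    table["rel_area"] = table["area"] / total if total > 0 else np.nan
    return table[_PEAK_COLUMNS]


class BinMap:
    """Ordered migration windows (relative to the internal standard) with
    their co-migrating desialylated-composition members."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy().reset_index(drop=True)
        required = {"bin_label", "offset_start", "offset_end", "members"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"bin map missing columns: {sorted(missing)}")
        if table["bin_label"].duplicated().any():
            raise ValueError("duplicate bin labels")
        starts = table["offset_start"].to_numpy(float)
        ends = table["offset_end"].to_numpy(float)
        if np.any(ends <= starts):
            raise ValueError("bin windows must have positive width")
        order = np.argsort(starts)
        if np.any(ends[order][:-1] > starts[order][1:]):
            raise ValueError("bin windows overlap")
        self.table = table.iloc[order].reset_index(drop=True)
        self.member_to_bin: dict[str, str] = {}
        for _, row in self.table.iterrows():
            for m in str(row["members"]).split(";"):
                m = m.strip()
                if m in self.member_to_bin:
                    raise ValueError(f"member {m} appears in two bins")
                self.member_to_bin[m] = row["bin_label"]

    @classmethod
    def from_csv(cls, path) -> "BinMap":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "BinMap":
        with resources.files("glypre.data").joinpath("ce_bins.csv").open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    @property
    def labels(self) -> list[str]:
        return list(self.table["bin_label"])

    def __len__(self) -> int:
        return len(self.table)

    def center(self, label: str) -> float:
        row = self.table[self.table["bin_label"] == label].iloc[0]
        return 0.5 * (float(row["offset_start"]) + float(row["offset_end"]))

    def bin_of_offset(self, offset: float) -> str | None:
        hit = self.table[
            (self.table["offset_start"] <= offset) & (offset < self.table["offset_end"])
        ]
        return None if hit.empty else str(hit.iloc[0]["bin_label"])


def _pick_internal_standard(peaks: pd.DataFrame, binmap: BinMap) -> float:
    """Choose the IS apex: the large peak that, used as the time reference,
    places the most detected peaks inside bin windows."""
    best_time, best_key = None, None
    for _, cand in peaks.sort_values("area", ascending=False).iterrows():
        t0 = float(cand["apex_time"])
        filled = {
            binmap.bin_of_offset(float(p) - t0)
            for p in peaks["apex_time"]
        } - {None}
        key = (len(filled), float(cand["area"]))
        if best_key is None or key > best_key:
            best_key, best_time = key, t0
    if best_key is None or best_key[0] == 0:
        raise InternalStandardError("internal standard not found: no reference "
                                    "places any peak inside a bin window")
    return best_time


def assign_bins(
    peaks: pd.DataFrame,
    binmap: BinMap | None = None,
    internal_standard_time: float | None = None,
) -> pd.DataFrame:
    """Label detected peaks with bin names relative to the internal standard.

    At most one peak per bin (largest area wins; conflicts are logged);
    relative areas are recomputed over assigned peaks only, so assigned
    ``rel_area`` sums to 1 and unassigned peaks get NaN.
    """
    binmap = binmap or BinMap.default()
    if peaks.empty:
        raise InternalStandardError("internal standard not found: no peaks detected")
    table = peaks.copy().reset_index(drop=True)
    if internal_standard_time is None:
        internal_standard_time = _pick_internal_standard(table, binmap)
    table["bin"] = [
        binmap.bin_of_offset(t - internal_standard_time) for t in table["apex_time"]
    ]
    # resolve conflicts: largest area keeps the bin
    for label, group in table.groupby("bin"):
        if len(group) > 1:
            keep = group["area"].idxmax()
            losers = group.index.difference([keep])
            logger.warning(
                "bin %s claimed by %d peaks; keeping apex %.3f min",
                label, len(group), table.loc[keep, "apex_time"],
            )
            table.loc[losers, "bin"] = None
    assigned = table["bin"].notna()
    total = table.loc[assigned, "area"].sum()
    table["rel_area"] = np.nan
    if total > 0:
        table.loc[assigned, "rel_area"] = table.loc[assigned, "area"] / total
    table.attrs["internal_standard_time"] = internal_standard_time
    return table


def bin_profile(assigned: pd.DataFrame, binmap: BinMap | None = None) -> pd.Series:
    """Relative areas over the full bin panel (unfilled bins are 0)."""
    binmap = binmap or BinMap.default()
    out = pd.Series(0.0, index=binmap.labels)
    rows = assigned[assigned["bin"].notna()]
    for _, r in rows.iterrows():
        out[r["bin"]] = r["rel_area"]
    return out


def process_trace(
    t: Electropherogram,
    binmap: BinMap | None = None,
    window_points: int = 11,
    polyorder: int = 3,
    baseline_half_width_min: float = 1.0,
    min_prominence: float = 0.005,
    internal_standard_time: float | None = None,
) -> pd.DataFrame:
    """Full chain: smooth, subtract baseline, integrate, assign bins."""
    sm = smooth(t, window_points=window_points, polyorder=polyorder)
    clean = subtract_ce_baseline(sm, half_width_min=baseline_half_width_min)
    peaks = detect_and_integrate(clean, min_prominence=min_prominence)
    return assign_bins(peaks, binmap=binmap, internal_standard_time=internal_standard_time)
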