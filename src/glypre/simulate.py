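"""Desk-scale synthetic study generator with known ground truth.

Emulates the full preanalytics experiment: two collection sets of five
donors, sixteen handling conditions, triplicate MALDI / duplicate CE
preparations, free-hemoglobin levels for the two hemolysis modes, and raw
instrument-like signals (MALDI peak lists with isotope envelopes, linear
calibration drift, a decaying-exponential baseline and detector noise;
CE traces with an internal-standard peak, global migration shift, slow
baseline drift and noise).

Hemolysis acts multiplicatively on the glycome before normalization:
asialylated analytes (oligomannose included) rise log-linearly with free
hemoglobin while sialylated analytes fall, so the GLYCOV score decreases
monotonically with hemoglobin by construction.  Effect sizes are
configuration, not facts: the defaults are chosen so hemolysis-responsive
analytes are detectable at n = 10 under the default technical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .ce import BinMap, Electropherogram
from .glycans import GlycanPanel, mono_mass, normalize_profile
from .maldi import ION_SUPPRESSION_LIMIT, MassSpectrum, envelope

__all__ = [
    "EffectModel",
    "SimulatedStudy",
    "make_design",
    "sample_donor_glycome",
    "apply_condition",
    "synth_hemoglobin",
    "synth_maldi_spectrum",
    "synth_ce_trace",
    "simulate_study",
    "child_rng",
]


def child_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-sample generator derived from the master seed."""
    return np.random.default_rng((int(seed) * 1_000_003 + int(index)) % 2**31)


@dataclass(frozen=True)
class EffectModel:
    """Condition effects, hemolysis response and signal-synthesis parameters."""

    # biology / preanalytics
    donor_sigma: float = 0.15          # lognormal sigma of donor glycomes
    condition_effects: dict = field(default_factory=dict)  # cond id -> per-analyte vector
    hb_slope_asialo: float = 2.0e-3    # log-fold per mg/dl, neuac == 0 (incl. oligomannose)
    hb_slope_mono_sialo: float = -5.0e-4   # neuac == 1
    hb_slope_multi_sialo: float = -1.0e-3  # neuac >= 2
    hb_median_hypotonic: float = 100.0     # mg/dl
    hb_median_shaking: float = 500.0       # mg/dl
    hb_sigma: float = 0.4                  # lognormal sigma of hemoglobin draws
    # technical replicate noise (lognormal CV)
    ms_noise_cv: float = 0.05
    ce_noise_cv: float = 0.05
    # MALDI spectrum synthesis
    mz_min: float = ION_SUPPRESSION_LIMIT
    mz_max: float = 5000.0
    mz_step: float = 0.05
    peak_sigma: float = 0.05           # Da
    total_area: float = 1.0e6          # counts, shared by the whole panel
    n_isotopologues: int = 3
    drift_slope_sd: float = 5.0e-5
    drift_intercept_sd: float = 0.03   # Da
    baseline_amp: float = 2.0e4
    baseline_tau: float = 1000.0       # Da
    maldi_noise_sd: float = 200.0
    # CE trace synthesis
    ce_time_max: float = 20.0          # min
    ce_time_step: float = 0.005        # min
    ce_is_time: float = 3.0            # nominal internal-standard apex, min
    ce_is_area: float = 1.0            # glycan panel area totals 1.0
    ce_peak_sigma: float = 0.04        # min
    ce_shift_sd: float = 0.1           # min, global migration shift
    ce_baseline_amp: float = 0.02
    ce_noise_sd: float = 2.0e-4

    def hemolysis_slopes(self, panel: GlycanPanel) -> np.ndarray:
        """Per-analyte log-fold change per mg/dl free hemoglobin."""
        neuac = panel.table["neuac"].to_numpy(int)
        slopes = np.where(
            neuac == 0,
            self.hb_slope_asialo,
            np.where(neuac == 1, self.hb_slope_mono_sialo, self.hb_slope_multi_sialo),
        )
        return slopes.astype(float)

    def effect_vector(self, condition_id: int, panel: GlycanPanel) -> np.ndarray:
        vec = self.condition_effects.get(condition_id)
        if vec is None:
            return np.ones(len(panel))
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(panel),) or np.any(vec <= 0):
            raise ValueError("condition effect vectors must be strictly positive, panel-length")
        return vec


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def make_design() -> pd.DataFrame:
    """One row per instrument preparation (donor x condition x modality x
    replicate): 465 MALDI and 310 CE rows, 60 of the MALDI rows from the two
    reference tubes."""
    rows = []
    for donor, dset in design.DONORS.items():
        for cond in design.CONDITIONS:
            if cond.set2_only and dset != 2:
                continue
            for modality, n_rep in (("MS", design.MS_REPLICATES), ("CE", design.CE_REPLICATES)):
                for rep in range(1, n_rep + 1):
                    rows.append(
                        dict(
                            donor=donor,
                            set=dset,
                            condition=cond.id,
                            tube=cond.tube,
                            matrix=cond.matrix,
                            is_reference=cond.is_reference,
                            hemolysis_mode=cond.hemolysis_mode,
                            modality=modality,
                            replicate=rep,
                        )
                    )
    df = pd.DataFrame(rows)
    df.index = pd.Index(
        [
            f"{r.donor}_c{r.condition:02d}_{r.modality}{r.replicate}"
            for r in df.itertuples()
        ],
        name="sample_id",
    )
    return df


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def sample_donor_glycome(rng: np.random.Generator, panel: GlycanPanel,
                         sigma: float = 0.15) -> pd.Series:
    """Donor glycome: lognormal perturbation of the reference medians."""
    ref = panel.reference_profile()
    perturbed = ref * np.exp(rng.normal(0.0, sigma, size=len(ref)))
    return normalize_profile(perturbed)


def apply_condition(
    profile: pd.Series,
    condition_id: int,
    hemoglobin: float,
    model: EffectModel,
    panel: GlycanPanel,
) -> pd.Series:
    """Condition effect times the hemolysis response, renormalized."""
    if hemoglobin < 0:
        raise ValueError("hemoglobin must be >= 0")
    eff = model.effect_vector(condition_id, panel)
    hb = np.exp(model.hemolysis_slopes(panel) * hemoglobin)
    return normalize_profile(profile * eff * hb)


def replicate_noise(profile: pd.Series, cv: float, rng: np.random.Generator) -> pd.Series:
    """Multiplicative lognormal technical noise, renormalized."""
    if cv <= 0:
        return profile.copy()
    return normalize_profile(profile * np.exp(rng.normal(0.0, cv, size=len(profile))))


def synth_hemoglobin(condition_id: int, rng: np.random.Generator,
                     model: EffectModel | None = None) -> float:
    """Free hemoglobin (mg/dl): 0 except for the two hemolysis conditions."""
    model = model or EffectModel()
    mode = design.condition(condition_id).hemolysis_mode
    if mode is None:
        return 0.0
    median = model.hb_median_hypotonic if mode == "hypotonic" else model.hb_median_shaking
    return float(median * np.exp(rng.normal(0.0, model.hb_sigma)))


# ---------------------------------------------------------------------------
# Raw-signal synthesis
# ---------------------------------------------------------------------------

def _add_gaussian(axis: np.ndarray, out: np.ndarray, center: float, area: float,
                  sigma: float, step: float) -> None:
    lo = np.searchsorted(axis, center - 6 * sigma)
    hi = np.searchsorted(axis, center + 6 * sigma)
    if hi <= lo:
        return
    x = axis[lo:hi]
    out[lo:hi] += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def synth_maldi_spectrum(
    profile: pd.Series,
    rng: np.random.Generator,
    model: EffectModel | None = None,
    panel: GlycanPanel | None = None,
    sample_id: str | None = None,
    replicate: int | None = None,
) -> tuple[MassSpectrum, dict]:
    """Raw MALDI peak list for a profile, plus generation ground truth.

    Gaussian isotopologue peaks (areas proportional to relative intensity
    times envelope abundance) on a drifted axis, a decaying-exponential
    baseline and additive detector noise, restricted to 990-5000 Da.
    """
    model = model or EffectModel()
    panel = panel or GlycanPanel.default()
    p = normalize_profile(profile).reindex(panel.labels)
    axis = np.arange(model.mz_min, model.mz_max + model.mz_step / 2, model.mz_step)
    clean = np.zeros_like(axis)
    drift_slope = 1.0 + rng.normal(0.0, model.drift_slope_sd)
    drift_intercept = rng.normal(0.0, model.drift_intercept_sd)
    for label, c in zip(panel.labels, panel.compositions):
        area = model.total_area * float(p[label])
        if area <= 0:
            continue
        base_mz = mono_mass(c, adduct="Na", permethylated=True)
        env = envelope(c, k=model.n_isotopologues)
        for off, ab in zip(env.offsets, env.abundances):
            center = drift_slope * (base_mz + off) + drift_intercept
            _add_gaussian(axis, clean, center, area * ab / model.mz_step,
                          model.peak_sigma, model.mz_step)
    # note: areas are expressed in summed-intensity units (area / step)
    baseline = model.baseline_amp * np.exp(-(axis - model.mz_min) / model.baseline_tau)
    noisy = clean + baseline + rng.normal(0.0, model.maldi_noise_sd, size=len(axis))
    spectrum = MassSpectrum(axis, np.clip(noisy, 0.0, None),
                            sample_id=sample_id, replicate=replicate)
    truth = dict(
        profile=p.copy(),
        drift_slope=drift_slope,
        drift_intercept=drift_intercept,
        total_area=model.total_area,
    )
    return spectrum, truth


def project_to_bins(profile: pd.Series, panel: GlycanPanel, binmap: BinMap) -> pd.Series:
    """Desialylated projection: drop sialic acids, merge into CE bins."""
    desial = panel.desialylated_labels()
    out = pd.Series(0.0, index=binmap.labels)
    for label, value in profile.items():
        bin_label = binmap.member_to_bin.get(desial[label])
        if bin_label is None:
            raise ValueError(f"analyte {label} has no CE bin for {desial[label]}")
        out[bin_label] += float(value)
    return out


def synth_ce_trace(
    profile: pd.Series,
    rng: np.random.Generator,
    model: EffectModel | None = None,
    panel: GlycanPanel | None = None,
    binmap: BinMap | None = None,
    sample_id: str | None = None,
    replicate: int | None = None,
) -> tuple[Electropherogram, dict]:
    """Raw CE-LIF trace for a profile, plus generation ground truth.

    The profile is projected to the desialylated 23-bin panel; each bin gets
    a Gaussian at its window center (relative to the internal-standard apex),
    the whole trace receives a global migration shift, a slow baseline drift
    and detector noise.  The 0-20 min time axis matches the separation run.
    """
    model = model or EffectModel()
    panel = panel or GlycanPanel.default()
    binmap = binmap or BinMap.default()
    p = normalize_profile(profile).reindex(panel.labels)
    bins = project_to_bins(p, panel, binmap)
    axis = np.arange(0.0, model.ce_time_max + model.ce_time_step / 2, model.ce_time_step)
    clean = np.zeros_like(axis)
    shift = rng.normal(0.0, model.ce_shift_sd)
    is_time = model.ce_is_time + shift
    _add_gaussian(axis, clean, is_time, model.ce_is_area, model.ce_peak_sigma,
                  model.ce_time_step)
    for label in binmap.labels:
        area = float(bins[label])
        if area <= 0:
            continue
        center = is_time + binmap.center(label)
        _add_gaussian(axis, clean, center, area, model.ce_peak_sigma, model.ce_time_step)
    baseline = model.ce_baseline_amp * (0.5 + 0.5 * axis / model.ce_time_max)
    noisy = clean + baseline + rng.normal(0.0, model.ce_noise_sd, size=len(axis))
    trace = Electropherogram(
        axis, noisy,
        dict(sample_id=sample_id, replicate=replicate, true_shift=shift),
    )
    truth = dict(bin_areas=bins.copy(), shift=shift, internal_standard_time=is_time)
    return trace, truth


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Design, metadata and ground truth of one synthetic study.

    Replicate-level profiles carry the technical noise actually encoded in
    the raw signals; ``true_profiles`` are the per-(donor, condition)
    pre-noise profiles sufficient to compute every recovery metric.
    """

    seed: int
    model: EffectModel
    panel: GlycanPanel
    binmap: BinMap
    meta: pd.DataFrame
    replicate_profiles: pd.DataFrame
    true_profiles: pd.DataFrame

    def maldi_spectrum(self, sample_id: str) -> tuple[MassSpectrum, dict]:
        row = self.meta.loc[sample_id]
        if row["modality"] != "MS":
            raise ValueError(f"{sample_id} is not a MALDI preparation")
        rng = child_rng(self.seed, int(row["signal_seed"]))
        return synth_maldi_spectrum(
            self.replicate_profiles.loc[sample_id], rng, self.model, self.panel,
            sample_id=sample_id, replicate=int(row["replicate"]),
        )

    def ce_trace(self, sample_id: str) -> tuple[Electropherogram, dict]:
        row = self.meta.loc[sample_id]
        if row["modality"] != "CE":
            raise ValueError(f"{sample_id} is not a CE preparation")
        rng = child_rng(self.seed, int(row["signal_seed"]))
        return synth_ce_trace(
            self.replicate_profiles.loc[sample_id], rng, self.model, self.panel,
            self.binmap, sample_id=sample_id, replicate=int(row["replicate"]),
        )


def simulate_study(
    seed: int,
    model: EffectModel | None = None,
    panel: GlycanPanel | None = None,
    binmap: BinMap | None = None,
    donors: dict[str, int] | None = None,
    conditions: tuple[int, ...] | None = None,
) -> SimulatedStudy:
    """Generate the whole study at profile level (signals are lazy).

    One master seed determines everything: donor glycomes, hemoglobin draws,
    replicate noise and the per-sample signal seeds, so a rerun with the same
    seed is byte-identical.  *donors*/*conditions* restrict the design for
    scaled-down runs without changing any default parameter.
    """
    model = model or EffectModel()
    panel = panel or GlycanPanel.default()
    binmap = binmap or BinMap.default()
    meta = make_design()
    if donors is not None:
        meta = meta[meta["donor"].isin(donors)]
        meta = meta[meta.apply(
            lambda r: not design.condition(int(r["condition"])).set2_only
            or donors.get(r["donor"]) == 2, axis=1)]
    if conditions is not None:
        meta = meta[meta["condition"].isin(conditions)]
    meta = meta.copy()

    donor_ids = sorted(meta["donor"].unique())
    donor_profiles = {
        d: sample_donor_glycome(child_rng(seed, 10_000 + i), panel, model.donor_sigma)
        for i, d in enumerate(donor_ids)
    }
    # one hemoglobin draw per (donor, condition) tube
    hb: dict[tuple[str, int], float] = {}
    cells = meta[["donor", "condition"]].drop_duplicates().reset_index(drop=True)
    for i, cell in cells.iterrows():
        hb[(cell["donor"], int(cell["condition"]))] = synth_hemoglobin(
            int(cell["condition"]), child_rng(seed, 20_000 + i), model
        )
    meta["hemoglobin"] = [
        hb[(r.donor, int(r.condition))] for r in meta.itertuples()
    ]

    true_rows, rep_rows, signal_seeds = {}, [], []
    for i, (sample_id, row) in enumerate(meta.iterrows()):
        key = (row["donor"], int(row["condition"]))
        if key not in true_rows:
            true_rows[key] = apply_condition(
                donor_profiles[row["donor"]], int(row["condition"]),
                hb[key], model, panel,
            )
        cv = model.ms_noise_cv if row["modality"] == "MS" else model.ce_noise_cv
        rep = replicate_noise(true_rows[key], cv, child_rng(seed, 30_000 + i))
        rep_rows.append(rep)
        signal_seeds.append(60_000 + i)
    meta["signal_seed"] = signal_seeds
    replicate_profiles = pd.DataFrame(rep_rows, index=meta.index)
    true_profiles = pd.DataFrame(
        {f"{d}_c{c:02d}": v for (d, c), v in true_rows.items()}
    ).T
    true_profiles.index.name = "cell"
    return SimulatedStudy(
        seed=seed, model=model, panel=panel, binmap=binmap, meta=meta,
        replicate_profiles=replicate_profiles, true_profiles=true_profiles,
    )
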