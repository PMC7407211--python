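"""Seeded generators of synthetic all-ion-fragmentation LC-MS runs,
calibration/QC series and cohort feature tables.

The simulator emulates the acquisition the pipeline is built for: a
negative-mode duty cycle of one MS1 scan (m/z 370-700) followed by one
AIF scan, Gaussian chromatographic elution with M+1 isotopologue
satellites, class-diagnostic fragments sharing the precursor's elution
profile, sn-positional isomer pairs for lysophospholipids (minor sn-2
peak ~0.3 min before the sn-1 peak at ~1:10), uniform ppm mass jitter,
and an additive baseline noise floor plus a proportional intensity term.
Every generator returns ground truth alongside its output and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotator import fragments_for_tags, observable_fragment_mzs
from .chemmass import ion_mz, isotope_m1
from .cohortqc import FeatureTable
from .spectra_io import CompoundEntry, Run, SampleSheet, Spectrum

__all__ = [
    "SimCompound",
    "SimConfig",
    "simulate_run",
    "simulate_calibration_series",
    "simulate_cohort_table",
    "DEFAULT_CAL_LEVELS",
]

#: 8-point calibration series spanning the quantified range, µM
DEFAULT_CAL_LEVELS: tuple[float, ...] = tuple(
    float(x) for x in np.geomspace(0.003, 5.0, 8).round(4)
)

#: natural 13C abundance per carbon, drives the M+1 satellite
M1_PER_CARBON = 0.0107

#: baseline noise floor (counts) of the validation noise model: calibrated
#: once so that a 0.003 µM analyte at the default response factor sits
#: about an order of magnitude over the baseline (S/N ~ 10), placing the
#: detection limit near the bottom of the calibrated range as the
#: method's design intends
LOD_NOISE_FLOOR = 1000.0


@dataclass
class SimCompound:
    """A compound to simulate: library entry + true state."""

    entry: CompoundEntry
    concentration: float  # µM
    response_factor: float = 1.0e5  # XIC area counts*min per µM
    apex_rt: float | None = None  # defaults to the library RT
    sigma: float = 0.04  # chromatographic peak sigma, minutes
    fragment_yield: float = 0.2  # fragment intensity as fraction of precursor
    sn2_fraction: float = 0.0  # minor sn-2 isomer share (LPL only)
    sn_offset: float = 0.3  # sn-2 elutes this many minutes earlier

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.sn2_fraction < 1.0:
            raise ValueError("sn2_fraction must be in [0, 1)")
        if self.apex_rt is None:
            self.apex_rt = self.entry.expected_rt
        if self.apex_rt is None:
            raise ValueError(f"{self.entry.name}: no retention time to simulate")


@dataclass
class SimConfig:
    scan_interval: float = 0.5 / 60.0  # minutes per MS level (0.5 s)
    run_length: float = 19.0  # minutes, full gradient
    rt_start: float = 0.0
    ms1_range: tuple[float, float] = (370.0, 700.0)
    ppm_jitter: float = 2.0  # uniform mass jitter, ±ppm
    noise_floor: float = 0.0  # baseline noise scale (half-normal sd), counts
    noise_density: float = 0.1  # fraction of scans carrying a noise centroid
    proportional_noise: float = 0.0  # fractional intensity noise
    intensity_threshold: float = 1.0  # counts; centroids below are not recorded
    precursor_survival: float = 0.3  # precursor intensity left in AIF scans
    seed: int = 0


def _gaussian(t: np.ndarray, apex: float, sigma: float, area: float) -> np.ndarray:
    height = area / (sigma * math.sqrt(2.0 * math.pi))
    return height * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


def simulate_run(
    compounds: list[SimCompound], config: SimConfig | None = None
) -> tuple[Run, dict]:
    """Simulate one AIF run; returns the Run and a ground-truth record.

    Truth maps each compound name to its precursor m/z, the true area and
    apex of every elution component (sn-1/sn-2 for LPL), the spiked
    concentration, and the m/z of each diagnostic fragment channel.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    cycle = 2.0 * config.scan_interval
    n_cycles = int(round((config.run_length - config.rt_start) / cycle))
    ms1_times = config.rt_start + np.arange(n_cycles) * cycle
    aif_times = ms1_times + config.scan_interval

    # channel -> accumulated profile; key (ms_level, round(mz, 6))
    ms1_profiles: dict[float, np.ndarray] = {}
    aif_profiles: dict[float, np.ndarray] = {}
    truth: dict[str, dict] = {}

    def add(profiles: dict, times: np.ndarray, mz: float, profile: np.ndarray):
        key = round(mz, 6)
        if key in profiles:
            profiles[key] = profiles[key] + profile
        else:
            profiles[key] = profile

    lo, hi = config.ms1_range
    for sc in compounds:
        entry = sc.entry
        mz = ion_mz(entry.neutral_formula, entry.adduct).mz
        if not lo <= mz <= hi:
            raise ValueError(
                f"{entry.name}: m/z {mz:.4f} outside simulable MS1 range {config.ms1_range}"
            )
        if sc.sn2_fraction > 0:
            components = [
                (sc.apex_rt, 1.0 - sc.sn2_fraction),
                (sc.apex_rt - sc.sn_offset, sc.sn2_fraction),
            ]
        else:
            components = [(sc.apex_rt, 1.0)]
        total_area = sc.response_factor * sc.concentration
        ms1_profile = np.zeros(n_cycles)
        aif_profile = np.zeros(n_cycles)
        comp_truth = []
        for apex, frac in components:
            area = total_area * frac
            ms1_profile += _gaussian(ms1_times, apex, sc.sigma, area)
            aif_profile += _gaussian(aif_times, apex, sc.sigma, area)
            comp_truth.append({"apex_rt": apex, "fraction": frac, "area": area})

        add(ms1_profiles, ms1_times, mz, ms1_profile)
        n_carbon = entry.neutral_formula.element_counts.get("C", 0)
        add(ms1_profiles, ms1_times, isotope_m1(mz), M1_PER_CARBON * n_carbon * ms1_profile)
        add(aif_profiles, aif_times, mz, config.precursor_survival * aif_profile)

        frag_channels = observable_fragment_mzs(
            fragments_for_tags(entry.class_tag), mz
        )
        for _, fmz in frag_channels:
            add(aif_profiles, aif_times, fmz, sc.fragment_yield * aif_profile)

        truth[entry.name] = {
            "mz": mz,
            "concentration": sc.concentration,
            "total_area": total_area,
            "components": comp_truth,
            "fragments": {name: fmz for name, fmz in frag_channels},
        }

    spectra: list[Spectrum] = []
    for level, times, profiles in (
        (1, ms1_times, ms1_profiles),
        (2, aif_times, aif_profiles),
    ):
        keys = sorted(profiles)
        base = np.array(keys)
        signal = (
            np.vstack([profiles[k] for k in keys])
            if keys
            else np.zeros((0, n_cycles))
        )
        n_ch = base.size
        if config.proportional_noise > 0 and n_ch:
            signal = signal * (
                1.0 + config.proportional_noise * rng.standard_normal(signal.shape)
            )
        if config.noise_floor > 0 and n_ch:
            # centroided baseline noise is sporadic: a noise centroid shows
            # up in a given m/z channel only on a fraction of scans
            present = rng.random(signal.shape) < config.noise_density
            signal = signal + present * np.abs(
                config.noise_floor * rng.standard_normal(signal.shape)
            )
        signal = np.clip(signal, 0.0, None)
        jitter = (
            rng.uniform(-config.ppm_jitter, config.ppm_jitter, size=(n_ch, n_cycles))
            * 1e-6
            if n_ch
            else np.zeros((0, n_cycles))
        )
        mz_obs = base[:, None] * (1.0 + jitter)
        for i, t in enumerate(times):
            if n_ch:
                inten = signal[:, i]
                keep = inten >= config.intensity_threshold
                mzs = mz_obs[keep, i]
                vals = inten[keep]
                order = np.argsort(mzs)
                mzs, vals = mzs[order], vals[order]
                # guard against (vanishingly rare) jitter collisions
                for j in range(1, mzs.size):
                    if mzs[j] <= mzs[j - 1]:
                        mzs[j] = mzs[j - 1] + 1e-9
            else:
                mzs, vals = np.array([]), np.array([])
            spectra.append(
                Spectrum(
                    ms_level=level,
                    rt=float(t),
                    mz_array=mzs,
                    intensity_array=vals,
                    aif=level == 2,
                )
            )
    run = Run(
        spectra=spectra,
        metadata={
            "polarity": "negative",
            "ms1_range": config.ms1_range,
            "seed": config.seed,
            "simulated": True,
        },
    )
    return run, truth


def simulate_calibration_series(
    library: list[CompoundEntry],
    analyte_names: list[str] | None = None,
    levels: tuple[float, ...] = DEFAULT_CAL_LEVELS,
    replicates: int = 3,
    config: SimConfig | None = None,
    suppression: float = 1.0,
) -> tuple[list[Run], SampleSheet]:
    """Simulate a replicated calibration series with internal standards.

    Analytes are spiked at each level; internal standards at their library
    nominal concentration in every run. ``suppression`` models matrix ion
    suppression as a multiplicative factor on the *analyte* response only
    (stable-isotope internal standards co-elute with their analyte and are
    compensated in the area ratio, so a matrix effect manifests as a slope
    change): pass the matrix-curve factor to emulate matrix calibrants.
    """
    if list(levels) != sorted(levels):
        raise ValueError("levels must be ascending")
    config = config or SimConfig()
    by_name = {e.name: e for e in library}
    analytes = [
        e
        for e in library
        if not e.is_internal_standard
        and (analyte_names is None or e.name in analyte_names)
    ]
    if not analytes:
        raise ValueError("no analytes selected")
    standards = list(
        {
            e.internal_standard_ref: by_name[e.internal_standard_ref]
            for e in analytes
            if e.internal_standard_ref
        }.values()
    )
    runs, rows = [], []
    run_index = 0
    for level in levels:
        for rep in range(replicates):
            sim = [
                SimCompound(
                    entry=e,
                    concentration=level,
                    response_factor=1.0e5 * suppression,
                )
                for e in analytes
            ]
            sim += [
                SimCompound(
                    entry=s,
                    concentration=s.nominal_is_concentration or 1.0,
                    response_factor=1.0e5,
                )
                for s in standards
            ]
            run, _ = simulate_run(
                sim, replace(config, seed=config.seed + 7919 * run_index + 1)
            )
            run_id = f"cal_L{level:g}_r{rep}"
            run.metadata["run_id"] = run_id
            runs.append(run)
            rows.append(
                {
                    "run_id": run_id,
                    "role": "calibrant",
                    "level_uM": level,
                    "replicate": rep,
                    "day": 0,
                    "spike_stage": "none",
                }
            )
            run_index += 1
    return runs, SampleSheet(pd.DataFrame(rows))


@dataclass
class CohortSpec:
    """What to plant in a simulated cohort table."""

    n_per_group: int = 50
    n_features: int = 116
    timepoints: tuple[str, ...] = ("CID1", "CID2", "CID3")
    n_missing_violators: int = 6  # features with >10 % missing values
    n_outlier_violators: int = 6  # features with >10 % gross outliers
    violator_missing_fraction: float = 0.15
    violator_outlier_fraction: float = 0.12
    background_missing_fraction: float = 0.02
    effect_features: int = 3  # responder-associated features
    effect_fold: float = 1.5  # responder/non-responder ratio at baseline
    effect_attenuation: tuple[float, ...] = (1.0, 0.3, 0.15)  # per timepoint
    log_sigma: float = 0.3  # within-feature biological spread (log-normal)
    outlier_multiplier: float = 50.0


def simulate_cohort_table(
    spec: CohortSpec | None = None, seed: int = 0
) -> tuple[FeatureTable, dict]:
    """Simulate a responders/non-responders cohort lipid table.

    Log-normal concentrations per feature; the first ``effect_features``
    features carry a multiplicative responder effect at baseline that
    attenuates over the follow-up timepoints. QC violations (missingness,
    gross outliers) are planted in deterministic counts so the truth
    record lists exactly which features a 10 %/10 % filter must discard.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    n_samples = 2 * spec.n_per_group
    n_rows = n_samples * len(spec.timepoints)
    features = [f"lipid_{i + 1:03d}" for i in range(spec.n_features)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = ["responder"] * spec.n_per_group + ["non-responder"] * spec.n_per_group

    # per-feature median concentration, µM (log-normal across features)
    feature_median = np.exp(rng.normal(math.log(0.3), 1.0, size=spec.n_features))
    index = pd.MultiIndex.from_product(
        [sample_ids, spec.timepoints], names=["sample_id", "timepoint"]
    )
    log_values = rng.normal(
        np.log(feature_median)[None, :], spec.log_sigma, size=(n_rows, spec.n_features)
    )
    values = pd.DataFrame(np.exp(log_values), index=index, columns=features)

    effect_names = features[: spec.effect_features]
    for f in effect_names:
        for tp, att in zip(spec.timepoints, spec.effect_attenuation):
            fold = 1.0 + (spec.effect_fold - 1.0) * att
            mask = (
                values.index.get_level_values("timepoint") == tp
            ) & values.index.get_level_values("sample_id").isin(
                sample_ids[: spec.n_per_group]
            )
            values.loc[mask, f] *= fold

    # plant QC violations in the *last* features, away from effect features
    n_viol = spec.n_missing_violators + spec.n_outlier_violators
    violators = features[len(features) - n_viol :] if n_viol else []
    missing_violators = violators[: spec.n_missing_violators]
    outlier_violators = violators[spec.n_missing_violators :]
    for f in missing_violators:
        k = int(math.ceil(spec.violator_missing_fraction * n_rows))
        rows = rng.choice(n_rows, size=k, replace=False)
        values.iloc[rows, values.columns.get_loc(f)] = np.nan
    for f in outlier_violators:
        k = int(math.ceil(spec.violator_outlier_fraction * n_rows))
        rows = rng.choice(n_rows, size=k, replace=False)
        col = values.columns.get_loc(f)
        values.iloc[rows, col] = values.iloc[rows, col] * spec.outlier_multiplier

    # light background missingness on the clean features (well under 10 %)
    clean = [f for f in features if f not in missing_violators + outlier_violators]
    for f in clean:
        k = rng.binomial(n_rows, spec.background_missing_fraction)
        k = min(k, int(0.08 * n_rows))
        if k:
            rows = rng.choice(n_rows, size=k, replace=False)
            values.iloc[rows, values.columns.get_loc(f)] = np.nan

    sample_info = pd.DataFrame({"sample_id": sample_ids, "group": groups}).set_index(
        "sample_id"
    )
    table = FeatureTable(values=values, sample_info=sample_info)
    truth = {
        "violating_features": sorted(missing_violators + outlier_violators),
        "effect_features": effect_names,
        "feature_median": dict(zip(features, feature_median)),
    }
    return table, truth
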