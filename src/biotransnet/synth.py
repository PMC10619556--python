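"""Synthetic-experiment generator with known ground truth.

Emulates the statistical structure of an S9 biotransformation screen so that
every pipeline stage is testable without raw instrument data: a control arm
and a reaction arm (n=3 each) with log-normally noisy peak areas, a parent
compound that is partially depleted by the reaction, planted biotransformant
features at their predicted adduct m/z (within the MS1 gate) whose MS2
spectra are the parent's fragments shifted by the reaction's mass delta,
unrelated decoy features kept >= 20 ppm away from every predicted mass, and
a luciferase plate following a saturating dose-response anchored between the
vehicle and positive controls.

The defaults model the T3 study conditions: n=3 per arm, 20% area CV, the
major reported conjugation/deiodination products planted with strong
increases, a 3% parent metabolic rate, and a phase I+II arm whose top-dose
activity reaches ~309% of the positive control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemcore import (
    ElementalComposition,
    PredictedCompound,
    ReactionPath,
    Transformation,
    adduct_for_polarity,
    default_library,
    delta_mass,
    expected_mz,
    monoisotopic_mass,
    net_delta,
    parse_formula,
)
from .msio import Ms2Spectrum, MsFeature, SampleDesign, write_feature_table, write_mgf

__all__ = ["PlantedPath", "SimConfig", "GroundTruth", "SimulatedExperiment", "simulate_experiment", "write_experiment"]

# 3,3',5-triiodo-L-thyronine
T3_FORMULA = "C15 H12 I3 N O4"

_DEFAULT_PLANTED: tuple[tuple[tuple[str, ...], float], ...] = (
    (("Glucuronide Conjugation",), 10.0),
    (("Oxidation", "Glucuronide Conjugation"), 6.0),
    (("Sulfation",), 5.0),
    (("Deiodination",), 3.0),
    (("Deiodination", "Sulfation"), 4.0),
)


@dataclass(frozen=True)
class PlantedPath:
    """A biotransformant planted into the simulation with a known effect."""

    steps: tuple[str, ...]
    log2fc: float
    detect_prob: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ValueError("detect_prob must be in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    parent_name: str = "T3"
    parent_formula: str = T3_FORMULA
    polarity: str = "pos"
    planted: tuple[PlantedPath, ...] = tuple(
        PlantedPath(steps, fc) for steps, fc in _DEFAULT_PLANTED
    )
    n_replicates: int = 3
    noise_cv: float = 0.2
    parent_base_area: float = 1.0e6
    planted_base_area: float = 3.0e4
    parent_metabolic_rate: float = 3.0  # percent depletion of the parent
    n_decoys: int = 50
    decoy_mz_range: tuple[float, float] = (150.0, 1000.0)
    decoy_min_ppm: float = 20.0
    ms2_peaks_per_spectrum: int = 10
    frag_noise_peaks: int = 3
    ppm_jitter: float = 3.0  # planted m/z error drawn uniform in +/- this
    max_total: int = 5
    max_phase2: int = 1
    # luciferase plate
    doses: tuple[float, ...] = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)
    arm_top_activity: dict = field(
        default_factory=lambda: {
            "parent": 100.0,
            "inactive_s9": 100.0,
            "phase1": 150.0,
            "phase1_2": 309.1,
        }
    )
    ec50: float = 1e-7
    pc_luminescence: float = 10000.0
    vc_luminescence: float = 1000.0
    plate_noise_frac: float = 0.02  # Gaussian SD as a fraction of (PC - VC)


@dataclass
class GroundTruth:
    parent_feature_id: str
    planted: dict[str, dict]  # feature_id -> {steps, log2fc, mz}
    skipped_paths: list[tuple[str, ...]]
    decoy_ids: list[str]
    metabolic_rate_percent: float
    plate_activity: dict[str, dict[float, float]]  # arm -> dose -> true %

    def to_json(self) -> str:
        return json.dumps(
            {
                "parent_feature_id": self.parent_feature_id,
                "planted": {
                    fid: {**info, "steps": list(info["steps"])}
                    for fid, info in self.planted.items()
                },
                "skipped_paths": [list(p) for p in self.skipped_paths],
                "decoy_ids": self.decoy_ids,
                "metabolic_rate_percent": self.metabolic_rate_percent,
                "plate_activity": {
                    arm: {str(d): a for d, a in doses.items()}
                    for arm, doses in self.plate_activity.items()
                },
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimulatedExperiment:
    config: SimConfig
    design: SampleDesign
    features: list[MsFeature]
    spectra: list[Ms2Spectrum]
    plate: pd.DataFrame
    truth: GroundTruth


def _resolve_path(steps: Sequence[str], library: Sequence[Transformation]) -> ReactionPath:
    by_name = {t.name: t for t in library}
    missing = [s for s in steps if s not in by_name]
    if missing:
        raise ValueError(f"planted path names not in library: {missing}")
    return ReactionPath(tuple(by_name[s] for s in steps))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _parent_spectrum(
    rng: np.random.Generator, feature_id: str, precursor_mz: float, n_peaks: int
) -> Ms2Spectrum:
    lo, hi = 150.0, max(200.0, precursor_mz - 50.0)
    mz = np.sort(rng.uniform(lo, hi, size=n_peaks))
    # enforce >0.2 Da spacing so fragment matches are unambiguous
    for i in range(1, mz.size):
        if mz[i] - mz[i - 1] < 0.2:
            mz[i] = mz[i - 1] + 0.2 + rng.uniform(0, 0.1)
    inten = 10 ** rng.uniform(4.0, 6.0, size=n_peaks)
    return Ms2Spectrum(feature_id=feature_id, precursor_mz=precursor_mz, mz=mz, intensity=inten)


def _shifted_spectrum(
    rng: np.random.Generator,
    parent: Ms2Spectrum,
    feature_id: str,
    precursor_mz: float,
    shift: float,
    n_noise: int,
) -> Ms2Spectrum:
    mz = parent.mz + shift
    keep = mz > 50.0
    mz = mz[keep]
    inten = parent.intensity[keep] * _lognormal_factors(rng, 0.1, keep.sum())
    if n_noise > 0:
        noise_mz = rng.uniform(60.0, max(120.0, precursor_mz - 20.0), size=n_noise)
        noise_int = 10 ** rng.uniform(2.0, 3.0, size=n_noise)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    return Ms2Spectrum(feature_id=feature_id, precursor_mz=precursor_mz, mz=mz, intensity=inten)


def simulate_experiment(
    config: SimConfig,
    library: Sequence[Transformation] | None = None,
    predictions: Sequence[PredictedCompound] | None = None,
) -> SimulatedExperiment:
    """Generate one control-vs-reaction experiment with ground truth.

    ``predictions`` (the full enumeration for the parent under the depth
    limits) is recomputed when not supplied; it defines the exclusion zone
    for decoy m/z placement.
    """
    rng = np.random.default_rng(config.seed)
    library = default_library() if library is None else list(library)
    parent = parse_formula(config.parent_formula)
    adduct = adduct_for_polarity(config.polarity)
    design = SampleDesign.three_vs_three() if config.n_replicates == 3 else SampleDesign(
        tuple((f"ctrl_{i}", "control") for i in range(1, config.n_replicates + 1))
        + tuple((f"rxn_{i}", "reaction") for i in range(1, config.n_replicates + 1))
    )

    for pp in config.planted:
        path = _resolve_path(pp.steps, library)
        if path.depth > config.max_total or path.n_phase2 > config.max_phase2:
            raise ValueError(f"planted path {pp.steps} violates depth limits")

    if predictions is None:
        from .chemcore import enumerate_biotransformants

        predictions = enumerate_biotransformants(
            parent, library, max_total=config.max_total, max_phase2=config.max_phase2,
            parent_name=config.parent_name,
        )
    predicted_mz = np.sort(
        np.array([pc.expected_mz(adduct) for pc in predictions]
                 + [expected_mz(monoisotopic_mass(parent), adduct)])
    )

    ctrl_ids = design.ids("control")
    rxn_ids = design.ids("reaction")
    n = config.n_replicates

    features: list[MsFeature] = []
    spectra: list[Ms2Spectrum] = []

    # --- parent feature ---------------------------------------------------
    parent_mass = monoisotopic_mass(parent)
    parent_mz = expected_mz(parent_mass, adduct)
    parent_id = "F0000_parent"
    depletion = 1.0 - config.parent_metabolic_rate / 100.0
    areas = {}
    for sid, f in zip(ctrl_ids, _lognormal_factors(rng, config.noise_cv, n)):
        areas[sid] = config.parent_base_area * f
    for sid, f in zip(rxn_ids, _lognormal_factors(rng, config.noise_cv, n)):
        areas[sid] = config.parent_base_area * depletion * f
    parent_feature = MsFeature(parent_id, parent_mz, rt=8.0, areas=areas, polarity=config.polarity)
    parent_ms2 = _parent_spectrum(
        rng, parent_id, parent_mz, config.ms2_peaks_per_spectrum
    )
    parent_feature.ms2 = parent_ms2
    features.append(parent_feature)
    spectra.append(parent_ms2)

    # --- planted biotransformants ----------------------------------------
    planted_truth: dict[str, dict] = {}
    skipped: list[tuple[str, ...]] = []
    for k, pp in enumerate(config.planted, start=1):
        if rng.uniform() > pp.detect_prob:
            skipped.append(tuple(pp.steps))
            continue
        path = _resolve_path(pp.steps, library)
        delta = net_delta(path)
        product = parent + delta
        if not product.is_nonnegative():
            raise ValueError(f"planted path {pp.steps} yields negative composition")
        theo_mz = expected_mz(monoisotopic_mass(product), adduct)
        ppm = rng.uniform(-config.ppm_jitter, config.ppm_jitter)
        obs_mz = theo_mz * (1.0 + ppm * 1e-6)
        fid = f"F{k:04d}_planted"
        areas = {}
        for sid, f in zip(ctrl_ids, _lognormal_factors(rng, config.noise_cv, n)):
            areas[sid] = config.planted_base_area * f
        for sid, f in zip(rxn_ids, _lognormal_factors(rng, config.noise_cv, n)):
            areas[sid] = config.planted_base_area * 2.0 ** pp.log2fc * f
        feat = MsFeature(fid, obs_mz, rt=float(2.0 + rng.uniform(0, 15)), areas=areas,
                         polarity=config.polarity)
        ms2 = _shifted_spectrum(
            rng, parent_ms2, fid, obs_mz, delta_mass(delta), config.frag_noise_peaks
        )
        feat.ms2 = ms2
        features.append(feat)
        spectra.append(ms2)
        planted_truth[fid] = {"steps": tuple(pp.steps), "log2fc": pp.log2fc, "mz": obs_mz}

    # --- decoy features ----------------------------------------------------
    decoy_ids: list[str] = []
    lo, hi = config.decoy_mz_range
    made = 0
    while made < config.n_decoys:
        mz = rng.uniform(lo, hi)
        idx = np.searchsorted(predicted_mz, mz)
        near = min(
            abs(predicted_mz[j] - mz)
            for j in (idx - 1, idx)
            if 0 <= j < predicted_mz.size
        )
        if near <= config.decoy_min_ppm * 1e-6 * mz:
            continue
        made += 1
        fid = f"D{made:04d}_decoy"
        areas = {}
        base = 10 ** rng.uniform(4.5, 6.0)
        for sid, f in zip(
            design.sample_ids, _lognormal_factors(rng, config.noise_cv, 2 * n)
        ):
            areas[sid] = base * f
        feat = MsFeature(fid, mz, rt=float(rng.uniform(0.5, 20.0)), areas=areas,
                         polarity=config.polarity)
        n_peaks = int(rng.integers(7, 13))
        dmz = np.sort(rng.uniform(60.0, max(150.0, mz - 10.0), size=n_peaks))
        dint = 10 ** rng.uniform(3.5, 5.5, size=n_peaks)
        ms2 = Ms2Spectrum(feature_id=fid, precursor_mz=mz, mz=dmz, intensity=dint)
        feat.ms2 = ms2
        features.append(feat)
        spectra.append(ms2)
        decoy_ids.append(fid)

    plate, plate_truth = _simulate_plate(rng, config)

    truth = GroundTruth(
        parent_feature_id=parent_id,
        planted=planted_truth,
        skipped_paths=skipped,
        decoy_ids=decoy_ids,
        metabolic_rate_percent=config.parent_metabolic_rate,
        plate_activity=plate_truth,
    )
    return SimulatedExperiment(
        config=config, design=design, features=features, spectra=spectra,
        plate=plate, truth=truth,
    )


def _simulate_plate(rng: np.random.Generator, config: SimConfig):
    pc, vc = config.pc_luminescence, config.vc_luminescence
    noise_sd = config.plate_noise_frac * (pc - vc)
    rows = []
    truth: dict[str, dict[float, float]] = {}
    wid = 0

    def well(role, arm, compound, dose, lum, rep):
        nonlocal wid
        wid += 1
        rows.append(
            {
                "well_id": f"W{wid:03d}",
                "role": role,
                "arm": arm,
                "compound": compound,
                "dose_molar": dose,
                "luminescence": max(float(lum), 0.0),
                "replicate": rep,
            }
        )

    nrep = config.n_replicates
    for r in range(1, nrep + 1):
        well("PC", "control", "T3_PC", 1e-7, pc + rng.normal(0, noise_sd), r)
    for r in range(1, nrep + 1):
        well("VC_control", "control", "vehicle", 0.0, vc + rng.normal(0, noise_sd), r)

    top = max(config.doses)
    sat_top = top / (top + config.ec50)
    for arm, top_act in config.arm_top_activity.items():
        truth[arm] = {}
        for r in range(1, nrep + 1):
            well("VC_test", arm, "vehicle", 0.0, vc + rng.normal(0, noise_sd), r)
        for dose in config.doses:
            act = top_act * (dose / (dose + config.ec50)) / sat_top
            truth[arm][dose] = act
            for r in range(1, nrep + 1):
                lum = vc + act / 100.0 * (pc - vc) + rng.normal(0, noise_sd)
                well("test", arm, config.parent_name, dose, lum, r)
    return pd.DataFrame(rows), truth


def write_experiment(exp: SimulatedExperiment, out_dir) -> dict[str, Path]:
    """Write the experiment as the file formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.csv",
        "mgf": out / "spectra.mgf",
        "plate": out / "plate.csv",
        "truth": out / "ground_truth.json",
    }
    write_feature_table(exp.features, paths["features"])
    write_mgf(exp.spectra, paths["mgf"])
    exp.plate.to_csv(paths["plate"], index=False)
    paths["truth"].write_text(exp.truth.to_json())
    return paths
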