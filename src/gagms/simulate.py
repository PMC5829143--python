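"""Ground-truth-labeled synthetic data emulating the discovery study design.

The discovery experiment compared liver extracts of untreated mutant mice
against enzyme-treated mutants: three replicate negative-mode full-scan
runs per group over 370–1500 Da, with a set of GAG-derived analytes
enriched 10³–10⁵-fold in the untreated group riding on thousands of
background features with no group effect.  The generator reproduces that
design with known ground truth so every pipeline stage — alignment,
floor-substituted ratio screening, composition assignment, fragment-based
sulfate localization, calibration — can be scored without any raw data.

Areas follow a multiplicative log-normal noise model (σ of ln-area 0.3,
a conventional LC-MS abundance noise level).  Detection is simulated as
genuine left-censoring at an instrument floor: a sampled area below the
floor produces no feature row at all, which is deliberately distinct
from the analysis-time floor substitution of 100 arbitrary units that
the screen applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import GlycanSequence, MassConstants, mz, neutral_mass
from .fragments import generate_fragments, Spectrum

__all__ = [
    "PlantedAnalyte",
    "SimulationConfig",
    "biomarker_trio",
    "simulate_feature_table",
    "simulate_msms",
    "simulate_calibration",
]


def biomarker_trio() -> tuple[GlycanSequence, ...]:
    """The three proposed biomarker structures (non-reducing end first).

    IdoA-GlcNS-IdoA ([M−H]⁻ 610), IdoA-GlcNAc6S-IdoA (652) and
    IdoA-GlcNAc-IdoA-GlcNS (813); IdoA is modeled as HexA (epimers are
    mass-identical) and GlcNS as HexN with an N-sulfate site.
    """
    return (
        GlycanSequence.parse("HexA-HexN(NS)-HexA"),
        GlycanSequence.parse("HexA-HexNAc(6S)-HexA"),
        GlycanSequence.parse("HexA-HexNAc-HexA-HexN(NS)"),
    )


@dataclass(frozen=True)
class PlantedAnalyte:
    """A ground-truth analyte: structure (or bare m/z), elution, fold."""

    sequence: GlycanSequence | None
    fold: float
    rt: float
    base_area: float = 2.0e6  # mean area in the untreated group
    mz_override: float | None = None

    @property
    def mz(self) -> float:
        if self.mz_override is not None:
            return self.mz_override
        return mz(neutral_mass(self.sequence), -1)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic feature tables.

    Defaults mirror the discovery design: 3 replicate runs per group,
    full scan 370–1500 Da, planted enrichment folds spanning 10³–10⁵.
    """

    seed: int = 0
    n_replicates: int = 3
    n_background: int = 5000
    scan_range: tuple[float, float] = (370.0, 1500.0)
    rt_range: tuple[float, float] = (0.5, 7.5)
    background_median_area: float = 5.0e4
    sigma_log_area: float = 0.3       # σ of ln(area), multiplicative noise
    instrument_floor: float = 500.0   # true censoring threshold (area units)
    mz_noise_ppm: float = 1.5
    rt_jitter_min: float = 0.02
    planted: tuple[PlantedAnalyte, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.scan_range
        for p in self.planted:
            if not (lo <= p.mz <= hi):
                raise ValueError(
                    f"planted analyte m/z {p.mz:.4f} outside scan range"
                )

    def with_default_planted(self, n: int = 10,
                             fold_range=(1e3, 1e5)) -> "SimulationConfig":
        """Plant n analytes with log-uniform folds, cycling the trio's
        structures at staggered retention times."""
        rng = np.random.default_rng(self.seed + 7919)
        trio = biomarker_trio()
        lo, hi = self.rt_range
        planted = tuple(
            PlantedAnalyte(
                sequence=trio[i % len(trio)],
                fold=float(np.exp(rng.uniform(np.log(fold_range[0]),
                                              np.log(fold_range[1])))),
                rt=float(lo + (hi - lo) * (i + 1) / (n + 1)),
            )
            for i in range(n)
        )
        return replace(self, planted=planted)


def _runs(config: SimulationConfig) -> list[tuple[str, str]]:
    return [
        (f"{group}_{r + 1}", group)
        for group in ("untreated", "treated")
        for r in range(config.n_replicates)
    ]


def simulate_feature_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-run feature rows and the ground-truth manifest.

    Returns (features, manifest).  ``features`` has columns run_id,
    group, mz, rt_min, area — the package's feature-table schema; rows
    whose sampled area falls below the instrument floor are censored
    (omitted).  ``manifest`` lists each planted analyte's true m/z, rt,
    fold and label, plus one row per background feature.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    manifest: list[dict] = []
    runs = _runs(config)

    def emit(true_mz: float, true_rt: float, mean_area: float,
             run_id: str) -> None:
        area = mean_area * float(np.exp(rng.normal(0.0, config.sigma_log_area)))
        if area < config.instrument_floor:
            return  # censored: the instrument never reports this feature
        obs_mz = true_mz * (1.0 + rng.normal(0.0, config.mz_noise_ppm) * 1e-6)
        obs_rt = max(0.0, true_rt + rng.normal(0.0, config.rt_jitter_min))
        rows.append(
            {"run_id": run_id, "group": run_id.rsplit("_", 1)[0],
             "mz": obs_mz, "rt_min": obs_rt, "area": area}
        )

    for k, p in enumerate(config.planted):
        manifest.append(
            {"kind": "planted", "label": str(p.sequence) if p.sequence else f"planted_{k}",
             "mz": p.mz, "rt_min": p.rt, "fold": p.fold,
             "base_area": p.base_area}
        )
        for run_id, group in runs:
            mean = p.base_area if group == "untreated" else p.base_area / p.fold
            emit(p.mz, p.rt, mean, run_id)

    lo, hi = config.scan_range
    rlo, rhi = config.rt_range
    for k in range(config.n_background):
        bmz = float(rng.uniform(lo, hi))
        brt = float(rng.uniform(rlo, rhi))
        mean = config.background_median_area * float(
            np.exp(rng.normal(0.0, 0.8))
        )
        manifest.append(
            {"kind": "background", "label": f"bg_{k}", "mz": bmz,
             "rt_min": brt, "fold": 1.0, "base_area": mean}
        )
        for run_id, _ in runs:
            emit(bmz, brt, mean, run_id)

    features = pd.DataFrame(
        rows, columns=["run_id", "group", "mz", "rt_min", "area"]
    )
    return features, pd.DataFrame(manifest)


def simulate_msms(
    sequence: GlycanSequence,
    seed: int = 0,
    dropout: float = 0.0,
    n_noise_peaks: int = 0,
    charge: int = -1,
    max_so3_losses: int = 2,
) -> Spectrum:
    """An MS/MS spectrum of a structure: theoretical fragments, with
    optional per-peak dropout and uniform-m/z noise peaks."""
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frags = generate_fragments(sequence, charge, max_so3_losses)
    peaks = [
        (f.mz, float(rng.lognormal(np.log(1000.0), 0.5)))
        for f in frags
        if rng.random() >= dropout
    ]
    prec = mz(neutral_mass(sequence), charge)
    for _ in range(n_noise_peaks):
        peaks.append(
            (float(rng.uniform(100.0, prec)), float(rng.lognormal(np.log(50.0), 0.5)))
        )
    return Spectrum(
        precursor_mz=prec,
        precursor_charge=charge,
        peaks=tuple(sorted(peaks)),
        title=str(sequence),
    )


def simulate_calibration(
    true_slope: float,
    noise_cv: float = 0.05,
    n_points: int = 8,
    seed: int = 0,
    conc_start: float = 1.0,
    analyte: str = "BM652",
    is_area: float = 5.0e5,
) -> pd.DataFrame:
    """A calibration table with multiplicative response noise.

    Concentrations double from ``conc_start``; responses are
    true_slope × conc × (1 + ε), ε ~ N(0, noise_cv²).  Columns match the
    calibration CSV schema (analyte, conc, analyte_area, is_area).
    """
    if n_points < 2:
        raise ValueError("need at least 2 calibration points")
    rng = np.random.default_rng(seed)
    concs = conc_start * 2.0 ** np.arange(n_points)
    responses = true_slope * concs * (1.0 + rng.normal(0.0, noise_cv, n_points))
    return pd.DataFrame(
        {
            "analyte": analyte,
            "conc": concs,
            "analyte_area": responses * is_area,
            "is_area": is_area,
        }
    )
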