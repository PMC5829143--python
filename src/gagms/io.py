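"""Readers and writers for the package's text formats.

Feature tables and calibration tables are plain CSV with a documented
schema; MS/MS spectra are read from MGF (via pyteomics) or centroided
mzML; results are written as TSV/JSON with stable column order and fixed
float formatting so outputs diff cleanly across runs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .fragments import Spectrum
from .screen import SCAN_RANGE, Feature, ScreenHit

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_feature_table",
    "write_feature_table",
    "read_msms",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "read_calibration_table",
    "read_transition_table",
    "write_hits",
    "write_candidates",
    "write_matches",
    "write_quant",
    "write_json",
]

FEATURE_COLUMNS = ("run_id", "group", "mz", "rt_min", "area")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved run configuration; round-trips through YAML.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    mz_tol_ppm: float = 10.0
    rt_tol_min: float = 0.2
    floor: float = 100.0
    thresholds: tuple[float, float, float] = (1000.0, 10000.0, 20000.0)
    max_residues: int = 6
    allow_dhexa: bool = False
    scan_range: tuple[float, float] = SCAN_RANGE
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("thresholds", "scan_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        logger.info("resolved config: %s", asdict(cfg))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["thresholds"] = list(data["thresholds"])
        data["scan_range"] = list(data["scan_range"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_feature_table(
    path: str | Path,
    scan_range: tuple[float, float] = SCAN_RANGE,
) -> list[Feature]:
    """Read the feature CSV (run_id, group, mz, rt_min, area).

    Empty/NA area marks a not-detected entry.  Features outside the scan
    range are rejected with a warning, mirroring the acquisition window.
    A malformed row raises with its line number.
    """
    df = pd.read_csv(path, dtype={"run_id": str, "group": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    features: list[Feature] = []
    lo, hi = scan_range
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            m = float(row["mz"])
            rt = float(row["rt_min"])
            area = None if pd.isna(row["area"]) else float(row["area"])
            if not (lo <= m <= hi):
                warnings.warn(
                    f"{path} line {line}: m/z {m:.4f} outside scan range "
                    f"{lo}-{hi}; feature rejected",
                    stacklevel=2,
                )
                continue
            features.append(
                Feature(run_id=str(row["run_id"]), group=str(row["group"]),
                        mz=m, rt=rt, area=area)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {line}: malformed row: {exc}") from exc
    return features


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g",
              columns=list(FEATURE_COLUMNS))


def _parse_mgf_charge(raw) -> int:
    # pyteomics may hand back a Charge/ChargeList; "1-" means z = −1
    if raw is None:
        return -1
    if isinstance(raw, (list, tuple)):
        raw = raw[0]
    z = int(raw)
    return -abs(z)  # this package is negative-mode only


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MGF spectra; negative charges ('1-') honored, default z = −1."""
    spectra: list[Spectrum] = []
    p = Path(path)
    if p.stat().st_size == 0:
        warnings.warn(f"{path}: empty file", stacklevel=2)
        return spectra
    with _mgf.read(str(p), use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params.get("pepmass", (0.0,))
            prec = float(pep[0] if isinstance(pep, (list, tuple)) else pep)
            spectra.append(
                Spectrum(
                    precursor_mz=prec,
                    precursor_charge=_parse_mgf_charge(params.get("charge")),
                    peaks=tuple(
                        zip(entry["m/z array"].tolist(),
                            entry["intensity array"].tolist())
                    ),
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": [p[0] for p in s.peaks],
                "intensity array": [p[1] for p in s.peaks],
                "params": {
                    "title": s.title,
                    "pepmass": s.precursor_mz,
                    "charge": f"{abs(s.precursor_charge)}-",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read centroided MS/MS spectra from mzML (profile data unsupported)."""
    from pyteomics import mzml as _mzml

    spectra: list[Spectrum] = []
    with _mzml.read(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level", 2) < 2:
                continue
            if "profile spectrum" in entry:
                raise ValueError(f"{path}: profile-mode mzML is unsupported")
            prec_list = entry.get("precursorList", {}).get("precursor", [])
            prec_mz, charge = 0.0, -1
            if prec_list:
                ion = prec_list[0]["selectedIonList"]["selectedIon"][0]
                prec_mz = float(ion.get("selected ion m/z", 0.0))
                if "charge state" in ion:
                    charge = -abs(int(ion["charge state"]))
            spectra.append(
                Spectrum(
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    peaks=tuple(
                        zip(entry["m/z array"].tolist(),
                            entry["intensity array"].tolist())
                    ),
                    title=str(entry.get("id", "")),
                )
            )
    return spectra


def read_msms(path: str | Path) -> list[Spectrum]:
    """Dispatch on extension: .mgf or .mzml/.mzML."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mgf":
        return read_mgf(path)
    if suffix == ".mzml":
        return read_mzml(path)
    raise ValueError(f"unsupported spectrum format: {suffix!r}")


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"analyte", "conc", "analyte_area", "is_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    return df


def read_transition_table(path: str | Path):
    from .quant import TransitionChannel

    df = pd.read_csv(path)
    required = {"analyte", "precursor_mz", "product_mz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    return {
        str(r.analyte): TransitionChannel(
            str(r.analyte), float(r.precursor_mz), float(r.product_mz)
        )
        for r in df.itertuples()
    }


def write_hits(hits: list[ScreenHit], path: str | Path) -> None:
    """TSV of screen hits: m/z to 4 dp, lower-bounded ratios prefixed '≥'."""
    with open(path, "w") as fh:
        fh.write("mz\trt_min\tn_members\tmean_untreated\tmean_treated\t"
                 "ratio\tfold_class\n")
        for h in hits:
            fh.write(
                f"{h.feature.mz:.4f}\t{h.feature.rt:.2f}\t"
                f"{h.feature.n_members}\t{h.mean_untreated:.6g}\t"
                f"{h.mean_treated:.6g}\t{h.ratio_str()}\t{h.fold_class}\n"
            )


def write_candidates(candidates, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tcomposition\ttheoretical_mz\tppm_error\n")
        for c in candidates:
            fh.write(
                f"{c.rank}\t{c.composition}\t{c.theoretical_mz:.4f}\t"
                f"{c.ppm_error:+.2f}\n"
            )


def write_matches(matches, unmatched, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_mz\tintensity\tion\ttheoretical_mz\n")
        for (pmz, pint), frag in matches:
            fh.write(f"{pmz:.4f}\t{pint:.6g}\t{frag.label}\t{frag.mz:.4f}\n")
        for pmz, pint in unmatched:
            fh.write(f"{pmz:.4f}\t{pint:.6g}\t-\t-\n")


def write_quant(results, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("analyte\tresponse\tconcentration\tunits\tbelow_lloq\n")
        for r in results:
            fh.write(
                f"{r.analyte}\t{r.response:.6g}\t{r.concentration:.6g}\t"
                f"{r.units}\t{str(r.below_lloq).lower()}\n"
            )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
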