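"""Glycosidic fragment prediction, spectrum annotation, sulfate localization.

Fragments follow the Domon–Costello glycosidic nomenclature: B/C ions
retain the non-reducing terminus, Y/Z ions the reducing terminus, with
C = B + H2O and Y = Z + H2O.  Sulfated GAG precursors additionally shed
SO3 readily under collisional activation — often before any glycosidic
bond breaks — so every fragment (and the precursor itself) is also
emitted with 0..k sulfate losses.

Sulfate localization mirrors the diagnostic-ion strategy used to place
the sulfate of the 652 biomarker on the N-acetyl-glucosamine: a sulfated
hexosamine monosaccharide ion (e.g. 300.0394/282.0289 for HexNAc+SO3)
and a sulfated uronate monosaccharide ion (272.9922/254.9817 for
HexA+SO3) are easily distinguishable; whichever set is present, with the
rival set absent, calls the site.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .chem import (
    BUILDING_BLOCKS,
    GlycanComposition,
    GlycanSequence,
    MassConstants,
    mz as ion_mz,
    neutral_mass,
)

__all__ = [
    "FragmentIon",
    "Spectrum",
    "SulfationCall",
    "generate_fragments",
    "annotate_spectrum",
    "localize_sulfate",
    "diagnostic_ions",
    "theoretical_spectrum",
]

_URONATE = frozenset({"HexA", "dHexA"})


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical glycosidic fragment (or precursor) ion.

    ``series`` is B, C, Y, Z, or M for the intact precursor; ``index`` is
    the cleavage index counted from the series' retained terminus (0 for
    M).  ``so3_loss`` counts sulfates lost as neutral SO3.
    """

    series: str
    index: int
    so3_loss: int
    composition: GlycanComposition
    charge: int
    mz: float
    label: str = ""

    def neutral(self) -> float:
        """Neutral mass of the (possibly SO3-stripped) fragment."""
        return self.mz * abs(self.charge) + abs(self.charge) * MassConstants.PROTON


def _segment_neutral(residues, with_water: bool) -> float:
    """Neutral mass of a run of residues with their sulfates.

    B/Z-type fragments are the bare dehydrated segment; C/Y-type (and the
    intact molecule) carry the extra water.
    """
    m = sum(
        BUILDING_BLOCKS[name].residue_mass + len(sites) * MassConstants.SULFATE_SO3
        for name, sites in residues
    )
    return m + (MassConstants.WATER if with_water else 0.0)


def _segment_composition(residues) -> GlycanComposition:
    counts = {"HexA": 0, "dHexA": 0, "HexN": 0, "HexNAc": 0}
    n_so3 = 0
    for name, sites in residues:
        counts[name] += 1
        n_so3 += len(sites)
    return GlycanComposition(
        hexa=counts["HexA"], dhexa=counts["dHexA"],
        hexn=counts["HexN"], hexnac=counts["HexNAc"], so3=n_so3,
    )


def generate_fragments(
    sequence: GlycanSequence,
    charge: int = -1,
    max_so3_losses: int = 2,
    include_internal: bool = True,
) -> list[FragmentIon]:
    """All B/C/Y/Z ions at every glycosidic bond plus SO3-loss ladders.

    Each fragment is emitted with 0..max_so3_losses sulfate losses,
    capped by the sulfates the fragment actually retains; the precursor
    is emitted likewise (series M).  With ``include_internal``,
    double-cleavage ions are generated too — e.g. the C1 ion of the Y2
    disaccharide of the 652 trisaccharide, the sulfated-HexNAc
    monosaccharide observed at 300.0395 after in-source HexA loss.
    Deduplicated by (m/z to 1e-4, series, label).
    """
    if charge not in (-1, -2, -3):
        raise ValueError("unsupported charge: negative-mode only")
    res = sequence.residues
    n = len(res)
    out: list[FragmentIon] = []
    seen: set[tuple[float, str, str]] = set()

    def emit(series: str, index: int, segment, with_water: bool,
             label: str | None = None) -> None:
        base = _segment_neutral(segment, with_water)
        comp = _segment_composition(segment)
        stem = label or f"{series}{index if index else ''}"
        for loss in range(min(max_so3_losses, comp.so3) + 1):
            m = base - loss * MassConstants.SULFATE_SO3
            ion = FragmentIon(
                series=series,
                index=index,
                so3_loss=loss,
                composition=GlycanComposition(
                    comp.hexa, comp.dhexa, comp.hexn, comp.hexnac,
                    comp.so3 - loss,
                ),
                charge=charge,
                mz=ion_mz(m, charge),
                label=stem + (f"-{loss}SO3" if loss else ""),
            )
            key = (round(ion.mz, 4), series, stem)
            if key not in seen:
                seen.add(key)
                out.append(ion)

    emit("M", 0, res, with_water=True)
    for i in range(1, n):  # glycosidic bond i: residues [0:i] | [i:]
        emit("B", i, res[:i], with_water=False)
        emit("C", i, res[:i], with_water=True)
        emit("Y", n - i, res[i:], with_water=True)
        emit("Z", n - i, res[i:], with_water=False)
    if include_internal:
        # segment res[i:j] from B-type cleavage at j inside Y_{n−i}
        for i in range(1, n):
            for j in range(i + 1, n):
                emit("BY", j - i, res[i:j], with_water=False,
                     label=f"B{j - i}/Y{n - i}")
                emit("CY", j - i, res[i:j], with_water=True,
                     label=f"C{j - i}/Y{n - i}")
    out.sort(key=lambda f: (f.mz, f.series, f.index, f.so3_loss))
    return out


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS peak list with precursor metadata."""

    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), ascending m/z
    isolation_window: float | None = None
    title: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        mzs = [p[0] for p in self.peaks]
        if any(m <= 0 for m in mzs):
            raise ValueError("peak m/z must be positive")
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
            )

    @property
    def mzs(self) -> list[float]:
        return [p[0] for p in self.peaks]

    def has_peak(self, target_mz: float, tol_ppm: float | None = 10.0,
                 tol_da: float | None = None) -> bool:
        """Any peak within tolerance of target m/z?"""
        window = tol_da if tol_da is not None else tol_ppm * 1e-6 * target_mz
        mzs = self.mzs
        i = bisect.bisect_left(mzs, target_mz - window)
        return i < len(mzs) and mzs[i] <= target_mz + window


def theoretical_spectrum(
    sequence: GlycanSequence,
    charge: int = -1,
    max_so3_losses: int = 2,
    intensity: float = 100.0,
) -> Spectrum:
    """Noiseless spectrum of every predicted fragment at equal intensity."""
    frags = generate_fragments(sequence, charge, max_so3_losses)
    prec = ion_mz(neutral_mass(sequence), charge)
    return Spectrum(
        precursor_mz=prec,
        precursor_charge=charge,
        peaks=tuple((f.mz, intensity) for f in frags),
        title=str(sequence),
    )


def annotate_spectrum(
    spectrum: Spectrum,
    sequence: GlycanSequence,
    tol_ppm: float | None = 10.0,
    tol_da: float | None = None,
    max_so3_losses: int = 2,
):
    """Match observed peaks to theoretical fragments, greedily by |error|.

    One-to-one assignment: candidate (peak, ion) pairs within tolerance
    are consumed in ascending |m/z error|, each peak and each ion used at
    most once.  Returns (matches, unmatched_peaks); matches are
    (peak, FragmentIon) pairs in ascending peak m/z.
    """
    frags = generate_fragments(
        sequence, spectrum.precursor_charge, max_so3_losses
    )
    pairs = []
    for pi, (pmz, pint) in enumerate(spectrum.peaks):
        for fi, frag in enumerate(frags):
            window = tol_da if tol_da is not None else tol_ppm * 1e-6 * frag.mz
            err = pmz - frag.mz
            if abs(err) <= window:
                pairs.append((abs(err), pi, fi))
    pairs.sort()
    used_p: set[int] = set()
    used_f: set[int] = set()
    matches = []
    for _, pi, fi in pairs:
        if pi in used_p or fi in used_f:
            continue
        used_p.add(pi)
        used_f.add(fi)
        matches.append((spectrum.peaks[pi], frags[fi]))
    matches.sort(key=lambda m: m[0][0])
    unmatched = [p for i, p in enumerate(spectrum.peaks) if i not in used_p]
    return matches, unmatched


def diagnostic_ions(residue_name: str) -> dict[str, float]:
    """Deprotonated sulfated-monosaccharide diagnostic m/z for a residue.

    C-type: residue + water + SO3 − H; B-type: residue + SO3 − H.  For
    HexNAc these are 300.0394 / 282.0289; for HexA 272.9922 / 254.9817.
    """
    r = BUILDING_BLOCKS[residue_name].residue_mass + MassConstants.SULFATE_SO3
    return {
        "C": ion_mz(r + MassConstants.WATER, -1),
        "B": ion_mz(r, -1),
    }


@dataclass(frozen=True)
class SulfationCall:
    """Verdict of the diagnostic-ion sulfate-localization test."""

    verdict: str  # hexosamine-sulfated | uronate-sulfated | ambiguous | unsulfated
    supporting: tuple[tuple[str, float], ...] = ()   # (label, m/z) matched
    contradicting: tuple[tuple[str, float], ...] = ()  # expected-but-absent


def localize_sulfate(
    spectrum: Spectrum,
    candidates: list[GlycanSequence],
    tol_ppm: float | None = 10.0,
    tol_da: float | None = None,
) -> SulfationCall:
    """Call the sulfation site class from diagnostic monosaccharide ions.

    Candidates must share a composition and differ only in sulfate
    placement.  For each placement class present among the candidates
    (hexosamine vs uronate) the sulfated-monosaccharide diagnostic ions
    are computed; the verdict is the class whose diagnostics appear in
    the spectrum while the rival class's do not.  Both or neither →
    ambiguous.  The spectrum may be a pseudo-precursor (an in-source
    fragment) — only the peak list is interrogated.
    """
    comps = {c.composition() for c in candidates}
    if len(comps) != 1:
        raise ValueError("candidates must share one composition")
    comp = comps.pop()
    if comp.so3 == 0:
        return SulfationCall(verdict="unsulfated")

    # residue types bearing sulfate in at least one candidate, by class
    classes: dict[str, set[str]] = {"hexosamine": set(), "uronate": set()}
    for cand in candidates:
        for name, sites in cand.residues:
            if sites:
                cls = "uronate" if name in _URONATE else "hexosamine"
                classes[cls].add(name)
    # default rivals so the test is two-sided even if candidates only
    # cover one class
    if not classes["hexosamine"]:
        classes["hexosamine"].add("HexNAc" if comp.hexnac else "HexN")
    if not classes["uronate"]:
        classes["uronate"].add("HexA")

    found: dict[str, list[tuple[str, float]]] = {"hexosamine": [], "uronate": []}
    absent: dict[str, list[tuple[str, float]]] = {"hexosamine": [], "uronate": []}
    for cls, names in classes.items():
        for name in sorted(names):
            for ion_type, m in diagnostic_ions(name).items():
                label = f"{name}+SO3 {ion_type}-ion"
                if spectrum.has_peak(m, tol_ppm=tol_ppm, tol_da=tol_da):
                    found[cls].append((label, round(m, 4)))
                else:
                    absent[cls].append((label, round(m, 4)))

    hex_hit = bool(found["hexosamine"])
    uro_hit = bool(found["uronate"])
    if hex_hit and not uro_hit:
        verdict = "hexosamine-sulfated"
        supporting, contradicting = found["hexosamine"], absent["uronate"]
    elif uro_hit and not hex_hit:
        verdict = "uronate-sulfated"
        supporting, contradicting = found["uronate"], absent["hexosamine"]
    else:
        verdict = "ambiguous"
        supporting = found["hexosamine"] + found["uronate"]
        contradicting = absent["hexosamine"] + absent["uronate"]
    return SulfationCall(
        verdict=verdict,
        supporting=tuple(supporting),
        contradicting=tuple(contradicting),
    )
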