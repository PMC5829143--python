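"""Exact-mass arithmetic for glycosaminoglycan (GAG) building blocks.

Heparan-sulfate-derived oligosaccharides are alternating chains of hexuronic
acid (HexA: iduronic or glucuronic acid, mass-identical epimers) and
hexosamine (HexN, or its N-acetylated form HexNAc), decorated with O- and
N-sulfate groups.  Everything downstream — composition search, fragment
prediction, sulfate localization — reduces to sums over the monoisotopic
residue masses defined here.

Masses are monoisotopic throughout.  All observed ions are deprotonated
([M−H]⁻ and multiply deprotonated analogues); positive mode is rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "MassConstants",
    "BuildingBlock",
    "BUILDING_BLOCKS",
    "GlycanComposition",
    "GlycanSequence",
    "SULFATION_SITES",
    "neutral_mass",
    "mz",
    "ppm_error",
    "formula_mass",
]

#: CODATA monoisotopic atomic masses (Da).
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an element→count map."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


class MassConstants:
    """Fixed mass constants (Da) used by every m/z computation in the package.

    ``PROTON`` is the mass of a proton; the ~0.0005 Da electron mass is
    absorbed into this constant for deprotonated-ion arithmetic, a
    difference far below every tolerance used here.
    """

    WATER: float = 18.010565          # H2O, the terminal water of a free chain
    SULFATE_SO3: float = 79.95682     # SO3, the sulfation mass increment
    PROTON: float = 1.0072765         # per-charge loss for [M−nH]^n−
    ACETYL_C2H2O: float = 42.01057    # HexN ↔ HexNAc increment


@dataclass(frozen=True)
class BuildingBlock:
    """A dehydrated monosaccharide residue as incorporated in a chain.

    ``residue_mass`` is the monoisotopic mass of ``elemental_formula``;
    a free monosaccharide is residue + one water.  ``terminal_only`` marks
    the Δ4,5-unsaturated uronate (dHexA) produced by heparin lyase
    digestion, which can only occupy the non-reducing terminus.
    """

    name: str
    elemental_formula: Mapping[str, int]
    residue_mass: float
    terminal_only: bool = False

    def __post_init__(self) -> None:
        calc = formula_mass(self.elemental_formula)
        if abs(calc - self.residue_mass) > 1e-6:
            raise ValueError(
                f"{self.name}: residue_mass {self.residue_mass} inconsistent "
                f"with formula mass {calc:.6f}"
            )


BUILDING_BLOCKS: Mapping[str, BuildingBlock] = {
    "HexA": BuildingBlock("HexA", {"C": 6, "H": 8, "O": 6}, 176.032088),
    # dHexA: Δ4,5-unsaturated uronate; free molecule is C6H8O6 (176.03209),
    # the chain-incorporated residue is one water less.
    "dHexA": BuildingBlock("dHexA", {"C": 6, "H": 6, "O": 5}, 158.021523,
                           terminal_only=True),
    "HexN": BuildingBlock("HexN", {"C": 6, "H": 11, "N": 1, "O": 4}, 161.068808),
    "HexNAc": BuildingBlock("HexNAc", {"C": 8, "H": 13, "N": 1, "O": 5}, 203.079373),
}

#: Admissible sulfation-site labels per residue type.  Uronates carry a
#: single O-sulfate position (2S); glucosamine carries N-, 6-O- and 3-O-
#: sulfate; the N-acetylated form has no free amine, so only O-sites.
SULFATION_SITES: Mapping[str, tuple[str, ...]] = {
    "HexA": ("2S",),
    "dHexA": ("2S",),
    "HexN": ("NS", "6S", "3S"),
    "HexNAc": ("6S", "3S"),
}

_URONATE = frozenset({"HexA", "dHexA"})
_HEXOSAMINE = frozenset({"HexN", "HexNAc"})


class InvalidCompositionError(ValueError):
    """Raised for compositions that do not describe a molecule."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue and sulfate counts of a GAG oligosaccharide.

    Counts are non-negative; at most one dHexA (it is terminal-only).
    """

    hexa: int = 0
    dhexa: int = 0
    hexn: int = 0
    hexnac: int = 0
    so3: int = 0

    def __post_init__(self) -> None:
        for f in ("hexa", "dhexa", "hexn", "hexnac", "so3"):
            if getattr(self, f) < 0:
                raise InvalidCompositionError(f"negative count for {f}")
        if self.dhexa > 1:
            raise InvalidCompositionError("at most one terminal dHexA allowed")

    @property
    def n_residues(self) -> int:
        return self.hexa + self.dhexa + self.hexn + self.hexnac

    @property
    def n_uronate(self) -> int:
        return self.hexa + self.dhexa

    @property
    def n_hexosamine(self) -> int:
        return self.hexn + self.hexnac

    def residue_counts(self) -> dict[str, int]:
        return {
            "HexA": self.hexa,
            "dHexA": self.dhexa,
            "HexN": self.hexn,
            "HexNAc": self.hexnac,
        }

    def sulfate_site_budget(self) -> int:
        """Maximum number of distinct sulfation sites this composition offers."""
        return sum(
            len(SULFATION_SITES[name]) * n
            for name, n in self.residue_counts().items()
        )

    def __str__(self) -> str:
        parts = [f"{name}:{n}" for name, n in self.residue_counts().items() if n]
        if self.so3:
            parts.append(f"SO3:{self.so3}")
        return "{" + ", ".join(parts) + "}"


@dataclass(frozen=True)
class GlycanSequence:
    """An ordered GAG chain, non-reducing to reducing end.

    ``residues`` is a tuple of (block name, sulfation sites) pairs, e.g.
    ``(("HexA", ()), ("HexNAc", ("6S",)), ("HexA", ()))`` for the proposed
    trisaccharide biomarker IdoA–GlcNAc6S–IdoA.  Site labels must be legal
    for the residue type; the reducing end is a free (unmodified) hemiacetal.
    ``annotation`` records epimer naming (IdoA vs GlcA), which is
    mass-silent and never enters any computation.
    """

    residues: tuple[tuple[str, tuple[str, ...]], ...]
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidCompositionError("empty sequence is not a molecule")
        for i, (name, sites) in enumerate(self.residues):
            if name not in BUILDING_BLOCKS:
                raise ValueError(f"unknown building block {name!r}")
            if BUILDING_BLOCKS[name].terminal_only and i != 0:
                raise ValueError(f"{name} is restricted to the non-reducing terminus")
            allowed = SULFATION_SITES[name]
            if len(set(sites)) != len(sites):
                raise ValueError(f"duplicate sulfation site on residue {i}")
            for s in sites:
                if s not in allowed:
                    raise ValueError(f"site {s!r} not admissible on {name}")

    @classmethod
    def parse(cls, text: str) -> "GlycanSequence":
        """Parse 'HexA-HexNAc(6S)-HexA'-style notation."""
        residues = []
        for token in text.strip().split("-"):
            token = token.strip()
            if "(" in token:
                name, rest = token.split("(", 1)
                sites = tuple(s.strip() for s in rest.rstrip(")").split(","))
            else:
                name, sites = token, ()
            residues.append((name, sites))
        return cls(tuple(residues))

    def __str__(self) -> str:
        return "-".join(
            name + (f"({','.join(sites)})" if sites else "")
            for name, sites in self.residues
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_so3(self) -> int:
        return sum(len(sites) for _, sites in self.residues)

    def composition(self) -> GlycanComposition:
        counts = {"HexA": 0, "dHexA": 0, "HexN": 0, "HexNAc": 0}
        for name, _ in self.residues:
            counts[name] += 1
        return GlycanComposition(
            hexa=counts["HexA"], dhexa=counts["dHexA"],
            hexn=counts["HexN"], hexnac=counts["HexNAc"], so3=self.n_so3,
        )


def neutral_mass(composition: GlycanComposition | GlycanSequence) -> float:
    """Neutral monoisotopic mass (Da) of a composition or sequence.

    Sum of dehydrated residue masses, one terminal water for the free
    chain, and 79.95682 Da per sulfate.
    """
    if isinstance(composition, GlycanSequence):
        composition = composition.composition()
    if composition.n_residues < 1:
        raise InvalidCompositionError("composition has no residues")
    m = sum(
        BUILDING_BLOCKS[name].residue_mass * n
        for name, n in composition.residue_counts().items()
    )
    return m + MassConstants.WATER + composition.so3 * MassConstants.SULFATE_SO3


def mz(neutral: float, charge: int) -> float:
    """m/z of the deprotonated ion [M−nH]^n− at the given negative charge.

    Only charges −1, −2, −3 are supported: every ion observed in this
    workflow is a negative-mode deprotonated species.
    """
    if charge not in (-1, -2, -3):
        raise ValueError(
            f"unsupported charge {charge}: negative-mode deprotonated ions "
            "only (charge in {-1, -2, -3})"
        )
    z = abs(charge)
    return (neutral - z * MassConstants.PROTON) / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
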