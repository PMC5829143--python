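"""Composition enumeration and structure proposal from accurate mass.

Given an observed deprotonated m/z, enumerate every GAG residue/sulfate
composition whose theoretical ion lies within tolerance, under simple
biosynthetic constraints (an alternating uronate–hexosamine backbone, a
per-residue sulfation-site budget, optional heparin-lyase terminal
unsaturated uronate).  Candidate compositions are then expanded into
ordered chains with explicit sulfate placements, optionally anchored by
the assumption that the chain begins with a uronic acid at the
non-reducing end — the assumption under which the 610/652/813 biomarkers
were assigned as IdoA-GlcNS-IdoA, IdoA-GlcNAc6S-IdoA and
IdoA-GlcNAc-IdoA-GlcNS.

Also provides the mass-ladder grouping that flags families of analytes
related by ±176.032 Da (one hexuronic acid) or ±79.957 Da (one sulfate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .chem import (
    BUILDING_BLOCKS,
    SULFATION_SITES,
    GlycanComposition,
    GlycanSequence,
    MassConstants,
    mz,
    neutral_mass,
    ppm_error,
)

__all__ = [
    "SearchConstraints",
    "CompositionCandidate",
    "enumerate_compositions",
    "propose_structures",
    "mass_ladder_group",
    "ladder_families",
    "LADDER_STEPS",
]

#: Default ladder steps: one HexA residue, one SO3.
LADDER_STEPS: tuple[float, ...] = (
    BUILDING_BLOCKS["HexA"].residue_mass,
    MassConstants.SULFATE_SO3,
)


@dataclass(frozen=True)
class SearchConstraints:
    """Constraint box for the composition search.

    tolerance_ppm applies to the theoretical m/z; set ``tolerance_da``
    instead for unit-resolution (triple-quadrupole) inputs — exactly one
    of the two must be positive.  ``allow_dhexa`` admits one terminal
    Δ4,5-unsaturated uronate (heparin-lyase digestion products).
    The backbone rule |uronates − hexosamines| ≤ 1 enforces the
    alternating GAG chain; the sulfate budget counts admissible sites
    (NS/6S/3S per HexN, 6S/3S per HexNAc, 2S per uronate).
    """

    max_residues: int = 6
    allow_dhexa: bool = False
    tolerance_ppm: float | None = None  # defaults to 10 ppm if neither is set
    tolerance_da: float | None = None

    def __post_init__(self) -> None:
        if self.max_residues < 1:
            raise ValueError("max_residues must be >= 1")
        if self.tolerance_ppm is not None and self.tolerance_da is not None:
            raise ValueError("set at most one of tolerance_ppm / tolerance_da")
        if self.tolerance_ppm is None and self.tolerance_da is None:
            object.__setattr__(self, "tolerance_ppm", 10.0)
        tol = self.tolerance_ppm if self.tolerance_ppm is not None else self.tolerance_da
        if tol <= 0:
            raise ValueError("tolerance must be positive")

    def mz_window(self, theoretical_mz: float) -> float:
        """Half-width of the acceptance window in m/z at this theoretical m/z."""
        if self.tolerance_da is not None:
            return self.tolerance_da
        return self.tolerance_ppm * 1e-6 * theoretical_mz

    def admits(self, comp: GlycanComposition) -> bool:
        """Does the composition satisfy the constraint box (mass aside)?"""
        if comp.n_residues < 1 or comp.n_residues > self.max_residues:
            return False
        if comp.dhexa and not self.allow_dhexa:
            return False
        if abs(comp.n_uronate - comp.n_hexosamine) > 1:
            return False
        if comp.so3 > comp.sulfate_site_budget():
            return False
        return True


@dataclass(frozen=True)
class CompositionCandidate:
    composition: GlycanComposition
    theoretical_mz: float
    ppm_error: float
    rank: int


def _constraint_box(constraints: SearchConstraints):
    """Yield every composition in the constraint box (exhaustive)."""
    R = constraints.max_residues
    for hexa in range(R + 1):
        for dhexa in range(2 if constraints.allow_dhexa else 1):
            for hexn in range(R + 1 - hexa - dhexa):
                for hexnac in range(R + 1 - hexa - dhexa - hexn):
                    comp0 = GlycanComposition(hexa, dhexa, hexn, hexnac, 0)
                    if comp0.n_residues < 1:
                        continue
                    if abs(comp0.n_uronate - comp0.n_hexosamine) > 1:
                        continue
                    for so3 in range(comp0.sulfate_site_budget() + 1):
                        yield GlycanComposition(hexa, dhexa, hexn, hexnac, so3)


def enumerate_compositions(
    observed_mz: float,
    charge: int,
    constraints: SearchConstraints | None = None,
) -> list[CompositionCandidate]:
    """All constraint-box compositions matching an observed m/z, ranked.

    Ranked by |ppm error|, ties broken by fewer sulfates then fewer
    residues (then lexicographically on counts, for determinism).
    Returns an empty list when nothing matches.
    """
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    if constraints is None:
        constraints = SearchConstraints()

    hits: list[tuple[float, int, int, GlycanComposition, float]] = []
    for comp in _constraint_box(constraints):
        theo = mz(neutral_mass(comp), charge)
        if abs(observed_mz - theo) <= constraints.mz_window(theo):
            err = ppm_error(observed_mz, theo)
            hits.append((abs(err), comp.so3, comp.n_residues, comp, theo))

    hits.sort(key=lambda h: (h[0], h[1], h[2], h[3]))
    return [
        CompositionCandidate(
            composition=comp,
            theoretical_mz=theo,
            ppm_error=ppm_error(observed_mz, theo),
            rank=i + 1,
        )
        for i, (_, _, _, comp, theo) in enumerate(hits)
    ]


def _backbone_orderings(comp: GlycanComposition, require_nre_uronate: bool):
    """All alternating orderings of the residue multiset.

    No two uronates and no two hexosamines adjacent; dHexA only at the
    non-reducing terminus; optionally the chain must start with a uronate.
    """
    pool = (
        ["HexA"] * comp.hexa + ["dHexA"] * comp.dhexa
        + ["HexN"] * comp.hexn + ["HexNAc"] * comp.hexnac
    )
    uron = frozenset({"HexA", "dHexA"})
    seen = set()
    for perm in itertools.permutations(pool):
        if perm in seen:
            continue
        seen.add(perm)
        if comp.dhexa and "dHexA" in perm[1:]:
            continue
        classes = ["U" if r in uron else "N" for r in perm]
        if any(a == b for a, b in zip(classes, classes[1:])):
            continue
        if require_nre_uronate and classes[0] != "U" and len(perm) > 1:
            continue
        yield perm


def propose_structures(
    candidate: CompositionCandidate | GlycanComposition,
    assume_nre_hexa: bool = True,
) -> list[GlycanSequence]:
    """Expand a composition into ordered chains with sulfate placements.

    Every alternating-backbone ordering (beginning with a uronate at the
    non-reducing end when ``assume_nre_hexa``) is combined with every way
    of distributing the sulfates over admissible sites, one sulfate per
    site.  Ordering of the output is lexicographic on the residue/site
    notation.  A composition that cannot form an alternating chain yields
    an empty list.
    """
    comp = (
        candidate.composition
        if isinstance(candidate, CompositionCandidate)
        else candidate
    )
    sequences: list[GlycanSequence] = []
    for perm in _backbone_orderings(comp, assume_nre_hexa):
        # all per-residue site choices: choose comp.so3 sites from the
        # disjoint union of each residue's admissible sites
        site_slots = [
            (i, site) for i, name in enumerate(perm)
            for site in SULFATION_SITES[name]
        ]
        for chosen in itertools.combinations(site_slots, comp.so3):
            per_res: list[tuple[str, ...]] = [() for _ in perm]
            for i, site in chosen:
                per_res[i] = per_res[i] + (site,)
            sequences.append(
                GlycanSequence(tuple(zip(perm, map(tuple, per_res))))
            )
    sequences.sort(key=str)
    return sequences


def mass_ladder_group(
    masses: list[float],
    steps: tuple[float, ...] = LADDER_STEPS,
    tol: float = 0.01,
) -> nx.Graph:
    """Graph linking masses that differ by one ladder step within tol (Da).

    Nodes are the input masses (deduplicated); an edge carries the step it
    matched.  Connected components are the ladder families.
    """
    g = nx.Graph()
    uniq = sorted(set(masses))
    g.add_nodes_from(uniq)
    for a, b in itertools.combinations(uniq, 2):
        delta = abs(b - a)
        for step in steps:
            if abs(delta - step) <= tol:
                g.add_edge(a, b, step=step)
                break
    return g


def ladder_families(
    masses: list[float],
    steps: tuple[float, ...] = LADDER_STEPS,
    tol: float = 0.01,
) -> list[list[float]]:
    """Connected components of the ladder graph, each sorted ascending."""
    g = mass_ladder_group(masses, steps, tol)
    return sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
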