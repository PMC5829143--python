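"""Composition enumeration vs brute force; structure proposal; mass ladders."""

import itertools

import numpy as np
import pytest

from gagms.chem import (
    SULFATION_SITES,
    GlycanComposition,
    MassConstants,
    mz,
    neutral_mass,
    ppm_error,
)
from gagms.compositions import (
    SearchConstraints,
    enumerate_compositions,
    ladder_families,
    mass_ladder_group,
    propose_structures,
)


def brute_force_scan(observed_mz, charge, constraints):
    """Independent exhaustive oracle over the full constraint box.

    Enumerates every count vector up to the residue cap by nested loops,
    applies the backbone/sulfate rules directly, and keeps compositions
    whose ion is within tolerance.  Shares no code with the search path.
    """
    R = constraints.max_residues
    found = set()
    for counts in itertools.product(range(R + 1), repeat=4):
        hexa, dhexa, hexn, hexnac = counts
        total = sum(counts)
        if not 1 <= total <= R:
            continue
        if dhexa > (1 if constraints.allow_dhexa else 0):
            continue
        if abs((hexa + dhexa) - (hexn + hexnac)) > 1:
            continue
        budget = (hexa + dhexa) * 1 + hexn * 3 + hexnac * 2
        for so3 in range(budget + 1):
            neutral = (
                hexa * 176.032088 + dhexa * 158.021523
                + hexn * 161.068808 + hexnac * 203.079373
                + so3 * 79.95682 + 18.010565
            )
            z = abs(charge)
            theo = (neutral - z * 1.0072765) / z
            if constraints.tolerance_da is not None:
                ok = abs(observed_mz - theo) <= constraints.tolerance_da
            else:
                ok = abs(observed_mz - theo) <= (
                    constraints.tolerance_ppm * 1e-6 * theo
                )
            if ok:
                found.add((hexa, dhexa, hexn, hexnac, so3))
    return found


class TestEnumerateCompositions:
    @pytest.mark.parametrize(
        "observed, expected_top",
        [
            (652.1036, GlycanComposition(hexa=2, hexnac=1, so3=1)),
            (610.0931, GlycanComposition(hexa=2, hexn=1, so3=1)),
            (813.1723, GlycanComposition(hexa=2, hexnac=1, hexn=1, so3=1)),
        ],
    )
    def test_biomarker_assignments(self, observed, expected_top):
        """The three proposed biomarker compositions rank first."""
        cands = enumerate_compositions(observed, -1)
        assert cands, f"no candidate for {observed}"
        assert cands[0].composition == expected_top
        assert abs(cands[0].ppm_error) < 1.0

    def test_heparinase_disaccharides_with_dhexa(self):
        constraints = SearchConstraints(max_residues=2, allow_dhexa=True)
        top = enumerate_compositions(378.1042, -1, constraints)[0]
        assert top.composition == GlycanComposition(dhexa=1, hexnac=1)
        top = enumerate_compositions(416.0504, -1, constraints)[0]
        assert top.composition == GlycanComposition(dhexa=1, hexn=1, so3=1)

    def test_negative_mz_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compositions(-5.0, -1)

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            SearchConstraints(tolerance_ppm=-1.0)
        with pytest.raises(ValueError):
            SearchConstraints(tolerance_ppm=10.0, tolerance_da=0.5)

    def test_no_match_returns_empty(self):
        assert enumerate_compositions(400.0000, -1,
                                      SearchConstraints(tolerance_ppm=1.0)) == []

    def test_ranks_contiguous_and_sorted(self):
        cands = enumerate_compositions(652.10, -1,
                                       SearchConstraints(tolerance_da=0.5))
        assert [c.rank for c in cands] == list(range(1, len(cands) + 1))
        errs = [abs(c.ppm_error) for c in cands]
        assert errs == sorted(errs)

    def test_matches_brute_force_oracle(self):
        """Exhaustiveness proved against an independent nested-loop scan."""
        rng = np.random.default_rng(42)
        constraints = SearchConstraints(tolerance_ppm=10.0, allow_dhexa=True)
        for target in rng.uniform(300.0, 1500.0, size=60):
            got = {
                (c.composition.hexa, c.composition.dhexa, c.composition.hexn,
                 c.composition.hexnac, c.composition.so3)
                for c in enumerate_compositions(float(target), -1, constraints)
            }
            assert got == brute_force_scan(float(target), -1, constraints)

    def test_soundness_every_candidate_within_tolerance(self):
        cands = enumerate_compositions(813.17, -1,
                                       SearchConstraints(tolerance_da=0.5))
        for c in cands:
            assert abs(813.17 - c.theoretical_mz) <= 0.5
            assert c.ppm_error == pytest.approx(
                ppm_error(813.17, c.theoretical_mz)
            )

    def test_tolerance_monotonicity(self):
        """Enlarging the tolerance never removes a candidate."""
        narrow = enumerate_compositions(
            652.1036, -1, SearchConstraints(tolerance_ppm=5.0))
        wide = enumerate_compositions(
            652.1036, -1, SearchConstraints(tolerance_ppm=20.0))
        assert {c.composition for c in narrow} <= {c.composition for c in wide}


def brute_force_placements(perm, n_so3):
    """Oracle: count sulfate placements by direct site enumeration."""
    slots = [
        (i, s) for i, name in enumerate(perm) for s in SULFATION_SITES[name]
    ]
    return sum(1 for _ in itertools.combinations(slots, n_so3))


class TestProposeStructures:
    def test_652_placements_include_both_hypotheses(self):
        comp = GlycanComposition(hexa=2, hexnac=1, so3=1)
        structures = {str(s) for s in propose_structures(comp)}
        assert "HexA-HexNAc(6S)-HexA" in structures
        assert "HexA(2S)-HexNAc-HexA" in structures

    def test_652_placement_count_matches_site_oracle(self):
        comp = GlycanComposition(hexa=2, hexnac=1, so3=1)
        structures = propose_structures(comp)
        # only one alternating uronate-first ordering: HexA-HexNAc-HexA
        assert len(structures) == brute_force_placements(
            ("HexA", "HexNAc", "HexA"), 1
        )

    def test_single_residue(self):
        assert len(propose_structures(GlycanComposition(hexa=1))) == 1

    def test_backbone_violation_yields_empty(self):
        comp = GlycanComposition(hexnac=3)  # 3 hexosamines, 0 uronates
        assert propose_structures(comp) == []

    def test_nre_flag_constrains_first_residue(self):
        comp = GlycanComposition(hexa=1, hexnac=2)
        with_flag = propose_structures(comp, assume_nre_hexa=True)
        without = propose_structures(comp, assume_nre_hexa=False)
        assert with_flag == []  # 2 hexosamines need the uronate internal
        assert {str(s) for s in without} == {"HexNAc-HexA-HexNAc"}

    def test_sequences_reproduce_composition_and_mass(self):
        comp = GlycanComposition(hexa=2, hexn=1, so3=2)
        for seq in propose_structures(comp):
            assert seq.composition() == comp
            assert neutral_mass(seq) == pytest.approx(
                neutral_mass(comp), abs=1e-9
            )

    def test_deterministic_lexicographic_order(self):
        comp = GlycanComposition(hexa=2, hexnac=1, so3=1)
        a = [str(s) for s in propose_structures(comp)]
        assert a == sorted(a)
        assert a == [str(s) for s in propose_structures(comp)]


class TestMassLadder:
    def test_hexa_and_so3_edges(self):
        g = mass_ladder_group([653.111, 477.079, 573.154], tol=0.01)
        assert g.has_edge(477.079, 653.111)  # Δ = 176.032, HexA step
        assert g.has_edge(573.154, 653.111)  # Δ = 79.957, SO3 step
        assert len(ladder_families([653.111, 477.079, 573.154])) == 1

    def test_unrelated_masses_stay_singletons(self):
        fams = ladder_families([653.111, 1000.0])
        assert fams == [[653.111], [1000.0]]

    def test_acetyl_delta_is_not_a_ladder_step(self):
        # 653.111 − 611.100 = 42.011 (acetyl), not a HexA/SO3 step
        g = mass_ladder_group([611.100, 653.111], tol=0.01)
        assert not g.has_edge(611.100, 653.111)

    def test_empty_input(self):
        assert ladder_families([]) == []
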