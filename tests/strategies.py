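"""Hypothesis strategies for random GAG chains."""

from hypothesis import strategies as st

from gagms.chem import SULFATION_SITES, GlycanSequence


@st.composite
def glycan_sequences(draw, max_residues=6, max_so3=4, allow_dhexa=False):
    """Random alternating uronate/hexosamine chains with sulfate placements."""
    n = draw(st.integers(min_value=1, max_value=max_residues))
    start_uronate = draw(st.booleans())
    residues = []
    for i in range(n):
        is_uronate = (i % 2 == 0) == start_uronate
        if is_uronate:
            name = "dHexA" if (
                i == 0 and allow_dhexa and draw(st.booleans())
            ) else "HexA"
        else:
            name = draw(st.sampled_from(["HexN", "HexNAc"]))
        residues.append(name)
    slots = [
        (i, site) for i, name in enumerate(residues)
        for site in SULFATION_SITES[name]
    ]
    k = draw(st.integers(min_value=0, max_value=min(max_so3, len(slots))))
    chosen = draw(
        st.permutations(slots).map(lambda p: p[:k])
    )
    per_res = [[] for _ in residues]
    for i, site in chosen:
        if site not in per_res[i]:
            per_res[i].append(site)
    return GlycanSequence(
        tuple((name, tuple(sorted(sites)))
              for name, sites in zip(residues, per_res))
    )
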