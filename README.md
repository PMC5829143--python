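# gagms

Mucopolysaccharidosis type I (MPS I, Hurler syndrome) is a lysosomal
storage disease caused by α-L-iduronidase deficiency: heparan sulfate
fragments that the missing enzyme would normally trim accumulate in
tissue and body fluids. Small sulfated oligosaccharides derived from
that accumulation — a trisaccharide observed at [M−H]⁻ 652
(IdoA-GlcNAc6S-IdoA), its N-sulfated counterpart at 610
(IdoA-GlcNS-IdoA) and a tetrasaccharide at 813
(IdoA-GlcNAc-IdoA-GlcNS) — make sensitive biomarkers of disease burden
and of response to enzyme replacement therapy.

`gagms` implements the computational side of discovering and measuring
such biomarkers by negative-mode LC-MS, for mass-spectrometrists and
computational biologists working on glycosaminoglycan (GAG) analytics:

- **Mass model** (`gagms.chem`) — monoisotopic residue masses for the
  GAG building blocks HexA (iduronic/glucuronic acid, C₆H₈O₆ as a
  residue, 176.03209 Da), HexN (161.06881), HexNAc (203.07937) and the
  heparin-lyase terminal Δ4,5-unsaturated uronate ΔUA (C₆H₆O₅,
  158.02152); neutral mass `M = Σ residues + H₂O + n·SO₃`; deprotonated
  ions `m/z = (M − |z|·1.0072765)/|z|`.
- **Composition search** (`gagms.compositions`) — exhaustive enumeration
  of residue/sulfate compositions matching an observed accurate mass
  within a ppm (or Da) tolerance, under an alternating
  uronate–hexosamine backbone constraint; expansion into ordered chains
  with explicit sulfate placements under the iduronic-acid
  non-reducing-end assumption; ±176.032/±79.957 Da mass-ladder family
  grouping.
- **Fragmentation** (`gagms.fragments`) — Domon–Costello B/C/Y/Z
  glycosidic ions, SO₃ neutral-loss ladders and double-cleavage internal
  ions; spectrum annotation; sulfation-site calls from diagnostic
  sulfated-monosaccharide ions (HexNAc+SO₃ at 300.0395/282.0289 vs
  HexA+SO₃ at 272.9922/254.9817).
- **Differential screen** (`gagms.screen`) — cross-run feature
  alignment, 100-unit detection-floor substitution, untreated/treated
  ratio classes (>1000×, >10,000×, >20,000×, mirrored for depletion)
  with lower-bound flags when the denominator was floored.
- **Quantification** (`gagms.quant`) — internal-standard response
  ratios, weighted linear calibration (1/x default), LLOQ flagging, and
  the 8-channel heparan-sulfate disaccharide sum.
- **Synthetic study designs** (`gagms.simulate`) — seeded generators
  for the 3-vs-3 run design with planted enriched analytes, MS/MS
  spectra and calibration sets, each with a ground-truth manifest.

## Worked example

```python
from gagms import (GlycanSequence, enumerate_compositions,
                   generate_fragments, localize_sulfate,
                   simulate_msms)

# 1. Assign a composition to the enriched ion at m/z 652.1036
top = enumerate_compositions(652.1036, charge=-1)[0]
print(top.composition, f"{top.ppm_error:+.2f} ppm")
# {HexA:2, HexNAc:1, SO3:1} -0.09 ppm

# 2. Where is the sulfate? Predict fragments of the 6S placement
bm652 = GlycanSequence.parse("HexA-HexNAc(6S)-HexA")
for f in generate_fragments(bm652):
    if f.label in ("Y2", "C1/Y2", "M-1SO3"):
        print(f.label, round(f.mz, 4))
# Y2 476.0716        (in-source loss of the non-reducing IdoA)
# C1/Y2 300.0395     (sulfated GlcNAc monosaccharide)
# M-1SO3 572.1468    (the 652.3 → 572.1 MRM transition)

# 3. Call the site from a (simulated) HCD spectrum
rival = GlycanSequence.parse("HexA-HexNAc-HexA(2S)")
call = localize_sulfate(simulate_msms(bm652, seed=0), [bm652, rival])
print(call.verdict)
# hexosamine-sulfated
```

The composition search confirms the trisaccharide assignment at
sub-ppm error; the fragment list reproduces the in-source disaccharide
(476.0716), the sulfated-GlcNAc diagnostic (300.0395) and the SO₃-loss
MRM product (572.1); and the diagnostic-ion logic places the sulfate on
the hexosamine, not the uronate.

The same operations are available from the shell:

```sh
gagms assign --mz 652.1036
gagms simulate features --seed 1 --out features.csv --manifest truth.csv
gagms screen --features features.csv --hits-out hits.tsv
gagms fragment --structure 'HexA-HexNAc(6S)-HexA'
gagms localize --mgf spectrum.mgf \
    --candidates 'HexA-HexNAc(6S)-HexA,HexA-HexNAc-HexA(2S)'
gagms quantify --cal cal.csv --samples samples.csv
```

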