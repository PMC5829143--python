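# Methods

## Mass model

GAG oligosaccharides are modeled as chains of dehydrated residues plus
one terminal water, with sulfation as +79.95682 Da (SO₃) per site:

    M = Σᵢ residue_massᵢ + 18.010565 + n_SO3 × 79.95682

Residue masses (monoisotopic, Da) are computed from elemental formulas
and checked against pyteomics in the test suite:

| block  | formula (residue) | mass      | role |
|--------|-------------------|-----------|------|
| HexA   | C₆H₈O₆            | 176.03209 | hexuronic acid (IdoA/GlcA — epimers are mass-identical; epimer names survive only as annotations) |
| dHexA  | C₆H₆O₅            | 158.02152 | Δ4,5-unsaturated uronate, the heparin-lyase product; restricted to the non-reducing terminus |
| HexN   | C₆H₁₁NO₄          | 161.06881 | glucosamine |
| HexNAc | C₈H₁₃NO₅          | 203.07937 | N-acetyl-glucosamine |

Note the dHexA convention: the *free* Δ4,5-unsaturated uronic acid
molecule is C₆H₈O₆ (176.032), but as a chain residue under the
one-terminal-water convention it contributes C₆H₆O₅ (158.022). This is
what makes the unsulfated lyase disaccharide ΔUA-GlcNAc come out at
[M−H]⁻ 378.10 and the N-sulfated ΔUA-GlcNS at 416.05, the precursors
the triple-quadrupole disaccharide assay monitors.

Ions are negative-mode deprotonated species only: m/z =
(M − |z|·1.0072765)/|z| for z ∈ {−1, −2, −3}. The electron mass is
absorbed into the per-charge proton constant; the ~0.0005 Da difference
from the electron-explicit convention is far below every tolerance used
here. Positive mode and adducts are rejected with an error — the
hexylamine ion-pairing agent in these chromatographies shapes retention,
not the detected ion species.

Sulfation sites are per-residue labels: 2S on uronates; NS, 6S, 3S on
HexN; 6S and 3S on HexNAc (its amine is acetylated, so no NS).

## Composition search

`enumerate_compositions` scans the full constraint box — up to
`max_residues` (default 6, reflecting the 550–900 Da, 3–5-block size
range of these analytes), |uronates − hexosamines| ≤ 1 (alternating
backbone), sulfates up to the site budget, at most one terminal dHexA
and only when enabled — and keeps compositions whose deprotonated ion
lies within tolerance. Default tolerance is 10 ppm (high-resolution
Orbitrap discovery data); an absolute-Da mode (e.g. 0.5 Da) serves
unit-resolution triple-quadrupole inputs. Candidates are ranked by
|ppm error| with ties broken toward fewer sulfates, then fewer
residues — a deliberate parsimony rule: structural assignment in
practice leans on prior literature, and this tie-break simply prefers
the least-modified explanation. Exhaustiveness is proven in the tests
against an independent nested-loop brute-force scan.

`propose_structures` expands a composition into every alternating
ordering (optionally anchored by a uronate at the non-reducing end, the
biosynthetic assumption under which the 610/652/813 analytes were
assigned) crossed with every admissible sulfate placement. For the 652
composition {HexA:2, HexNAc:1, SO₃:1} this yields exactly the two
hypotheses the fragmentation work then discriminates: sulfate on the
GlcNAc (6S or 3S) or on a uronate (2S).

GlcNS is handled as HexN + 1 SO₃ at the composition stage; N-sulfation
becomes a site assignment only at the structure stage. This keeps the
mass search one-dimensional in SO₃.

## Fragmentation and sulfate localization

Fragments follow the Domon–Costello glycosidic nomenclature (B/C retain
the non-reducing end, Y/Z the reducing end; C = B + H₂O, Y = Z + H₂O);
cross-ring A/X cleavages are not modeled — the localization logic needs
none. Every fragment and the precursor are also emitted with 0..k SO₃
neutral losses (default k = 2), because sulfate loss precedes
glycosidic cleavage under HCD. Double-cleavage internal ions (B/C of a
Y fragment) are generated as well: the key diagnostic ion of the 652
biomarker — sulfated GlcNAc at 300.0395 — is the C1 ion of the Y2
in-source disaccharide, not a primary cleavage of the trisaccharide.

`localize_sulfate` interrogates a spectrum for the sulfated-
monosaccharide diagnostics of each placement class among the candidate
structures: HexNAc+SO₃ at 300.0394 (C-type) / 282.0289 (B-type),
HexN+SO₃ at 258.0289/240.0183, HexA+SO₃ at 272.9922/254.9817. The call
is presence/absence at a configurable tolerance (default 10 ppm;
intensity is ignored): one class present with the rival absent gives a
verdict, both or neither is `ambiguous`, and a sulfate-free composition
is `unsulfated` by definition. A spectrum whose precursor is itself a
predicted fragment (the 476 pseudo-precursor isolated after in-source
HexA loss) is handled identically — only the peak list matters.

## Differential screen

Per-run features (m/z, retention time, area) are aligned by greedy
single-linkage clustering: seeds in descending area order absorb all
unassigned features within the m/z window (default 10 ppm) and rt
window (default 0.2 min); consensus m/z and rt are member medians. This
is deliberately a simple behavioral stand-in for proprietary vendor
alignment, not a reimplementation of it.

Ratios use group *means* over the replicates (matching the 3-vs-3
triplicate design; configurable). Not-detected replicates are
substituted with the analysis floor of 100 instrument arbitrary units
before averaging, so a feature absent from all treated runs gets a
*lower-bound* ratio (flagged, rendered as "≥"). Class boundaries are
strict: "enriched>1000" means ratio > 1000, so a ratio of exactly
20,000 falls in the >10,000 class. Depletion mirrors the lowest
threshold. Features below detection in every replicate of both groups
are dropped with a log line. Features outside the 370–1500 Da scan
window are rejected at load with a warning, mirroring the acquisition
range.

## Quantification

Responses are analyte area / internal-standard area; scale-invariance
of this ratio is property-tested. Calibration is weighted least squares
(statsmodels WLS) with 1/x default weighting — conventional for LC-MS/MS
calibrations spanning decades of concentration; "none" and 1/x² are
selectable since the regression form is a package choice. LLOQ is the
lowest calibrator (configurable); below-LLOQ results are flagged but
still reported. Total heparan sulfate is the arithmetic sum over the
eight disaccharide channels H1001–H1008, with flagged channels
contributing zero under a warning and missing channels a hard error.
The H100x codes are opaque labels: only the unsulfated (378) and one
mono-sulfated (416) channel are forced by mass, so no further
structural identity is asserted. Concentrations may be reported in
ng/ml (plasma/CSF with an absolute calibration) or left as
response ratios (tissue surveys); both modes are supported.

## Synthetic study design

`simulate_feature_table` emulates the discovery design: two groups
(untreated vs enzyme-treated) × 3 replicate runs, full-scan 370–1500 Da,
5,000 background features by default with no group effect, and planted
GAG analytes enriched 10³–10⁵-fold (log-uniform) in the untreated
group. Numerical choices, each made once:

- **Area noise**: multiplicative log-normal, σ of ln(area) = 0.3 — a
  conventional LC-MS abundance noise level.
- **Censoring**: genuine left-censoring at an instrument floor of 500
  area units (a censored measurement produces *no* row), deliberately
  distinct from the analysis-time floor substitution of 100 units, so
  the floor rule is exercised against real missingness.
- **Planted base area**: 2×10⁶ in the untreated group, so a 10⁴-fold
  analyte falls to ~200 in the treated group — below the instrument
  floor, exactly the censored regime the lower-bound arithmetic exists
  for.
- **m/z accuracy**: σ = 1.5 ppm, the routine lock-mass-corrected
  Orbitrap accuracy at 140k resolving power. This choice is coupled to
  the 10 ppm alignment window: the run-to-run difference of two
  1.5 ppm draws has σ ≈ 2.1 ppm, keeping cluster-splitting (which would
  fabricate floored singletons and hence false enrichment) a ≪1 event
  per simulated experiment. A noise level half the window, e.g. 5 ppm,
  would break any aligner of this kind.
- **rt jitter**: σ = 0.02 min against a 0.2 min window.

What the generator does *not* emulate: chromatographic peak shapes,
correlated (batch/drift) noise, isotope envelopes, charge states beyond
−1, in-source fragments of background ions, and real biological
covariation between analytes. Passing the recovery suite therefore
shows the screening arithmetic and its censoring logic are correct
under the declared noise model — not that the pipeline matches
vendor-software feature detection on raw data, and not the study's own
feature counts (25,777 features / 225 enriched / 90 depleted), which
would require the undeposited raw files.

Problem sizes in the test and acceptance suites — 5,000 background
features, 10 planted analytes, 200 random masses for the search oracle,
100 random sequences for complementarity, 1,000 calibration
repetitions — are chosen so the whole suite completes in seconds while
each check retains statistical force.

## Numerical notes and limitations

- Fragment deduplication is by (m/z rounded to 10⁻⁴, series, label);
  C_i and Y_{n−i} of a symmetric chain can coincide in m/z and are both
  retained, since annotation is one-to-one greedy by |error|.
- At 5% response CV and 8 calibrators, a single fitted slope has a mean
  absolute error of ~2.5% but a tail reaching ~11% across 1,000 seeds;
  recovery claims are therefore Monte-Carlo statements about the
  ensemble, not per-fit guarantees.
- Epimers and sulfate regio-isomers are mass-identical; nothing here
  can distinguish IdoA from GlcA, or 6S from 3S, by mass alone — the
  diagnostic-ion logic resolves only the residue *class* carrying the
  sulfate.
- Fragment charge is fixed at the precursor's charge; multiply
  deprotonated fragment ladders of small (<1000 Da) precursors are not
  generated, matching the singly-charged ions this workflow interprets.
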