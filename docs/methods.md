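# Methods

## Mass arithmetic and the modification registry (`chemdb`)

All arithmetic is monoisotopic (element and residue masses from the NIST
tables shipped with pyteomics; proton 1.00727646677 Da).  The aldehyde
reactive probe (ARP, C₁₂H₂₁N₅O₄S, 331.1314 Da) derivatizes a carbonyl as an
oxime with loss of one water, so every ARP adduct mass shift decomposes as

    delta = base_carbonyl_delta + (m(ARP) − m(H₂O)) = base + 313.1209 Da

The shipped registry derives each entry from explicit base chemistry rather
than storing rounded literature values:

| adduct | residues | base chemistry | Δm (Da) |
|---|---|---|---|
| aminoadipic semialdehyde (allysine) | K | −NH₃ +O | +312.089 |
| radical backbone-cleavage product | A, L | −NH₃ +O | +312.089 |
| glutamic semialdehyde | P | +O | +329.116 |
| glutamic semialdehyde | R | C₆H₁₂N₄O→C₅H₇NO₂ | +270.067 |
| 2-amino-3-ketobutyric acid / Ser keto | T, S | −2H | +311.105 |
| alternative Lys oxidation | K | −CH₅N +O | +298.074 |
| alternative Leu oxidation | L | −CH₄ +O | +313.084 |
| cyclic imide capture | Q, N | −NH +O (+0.984) | +314.105 |
| cyclic isoimide capture | E, D | none | +313.121 |
| glycation (Amadori) | K | +C₆H₁₀O₅ | +475.174 |
| MDA/methylglyoxal Michael adduct | K | +C₃H₄O₂ | +385.142 |
| crotonaldehyde Michael adduct | K | +C₄H₆O | +383.163 |
| acrolein Michael adduct | K, C | +C₃H₄O | +369.147 |
| acetaldehyde aldoamine | K | +C₂H₂O | +355.131 |
| glyoxal adduct | C | +C₂H₂O₂ | +371.126 |
| Met side-chain aldehyde | M | −CH₄S +O | +281.112 |

plus non-ARP carbamidomethyl (+57.0215) and Met sulfoxide (+15.9949).  Each
oxime entry must satisfy `delta = base + oxime` within 1 mDa at load time.
The registry is user-extensible via TSV/JSON files with the same schema.

Reporter profiles: semialdehyde-type oximes (K/P/R) are `FULL_TAG`
(reporters 227.085 / 299.117 / 332.139; tag losses 227.085 and 331.139 Da
from precursor and modified b/y ions); keto-type oximes (T/S) are
`BIOTIN_ONLY` (227.085 plus a 288.126 Da loss from modified y ions); every
other ARP adduct is `BIOTIN_MINIMAL`, since only the biotin reporter is
guaranteed across modification types.  `find_isobaric_conflicts` enumerates
single modifications and unordered pairs and reports total-mass collisions;
the canonical case is glyoxal-Cys ≡ carbamidomethyl-Cys + Gln/Asn imide,
whose elemental sums are identical.

A known literature ambiguity: the Lys semialdehyde shift is sometimes
quoted as 312.125 Da in running text while the derivable value is 312.089;
the registry stores the derived value.  For the Met side-chain aldehyde the
only base chemistry consistent with an MCO carbonyl (−CH₄S +O) gives
+281.112, about 1.4 mDa above the three-decimal value sometimes printed;
the registry stores the formula-derived number.

## Digestion, peptidoforms, decoys (`insilico`)

Trypsin cleaves C-terminal to K/R, not before P; protein termini count as
cleavage sites.  Defaults: ≤3 missed cleavages, peptide length 6–45 (bounds
the search space; typical tryptic identifications fall well inside).
Semi-specific digestion (one ragged terminus) is implemented behind a flag
and off by default: on the bundled panel it multiplies the peptidoform index
roughly thirty-fold for no gain under the synthetic study conditions.

Modification enumeration assigns at most one modification per residue and at
most 3 variable modifications per peptide (higher multiplicities mostly
produce unmatchable spectra; a cap of 10 000 forms per peptide guards the
combinatorics, and the pipeline backs off to fewer variable modifications
for peptides that exceed it).  Under fixed-carbamidomethyl mode a variable
Cys modification *displaces* the fixed one — both alkylate the thiol, so
they are mutually exclusive — which also lets the search propose Cys
adducts (acrolein, glyoxal) without a separate variable-CAM pass.

Decoys are pseudo-reversed proteins: every tryptic segment is reversed in
place with its C-terminal K/R fixed, preserving peptide lengths, composition
and approximate cleavage structure.  Decoy peptides whose sequence collides
with any target peptide are excluded from FDR counting.

## Spectra I/O and lock mass (`spectra_io`)

Spectra are centroided peak lists sorted in m/z (duplicates merged by
summing).  MGF I/O uses pyteomics; mzML is read and written by a small
built-in implementation (plain XML, base64 arrays; the reader resolves
cvParams by accession and accepts 32/64-bit, zlib or uncompressed arrays).
Lock-mass recalibration is multiplicative — every m/z in a block is scaled
by `reference / observed` with the 785.843 reference — matching the
ppm-like error model of a TOF; the correction is refused (with a warning)
when the observed reference deviates by more than 0.5 Da.  Whether the
instrument's own correction is multiplicative or additive is not knowable
from the data; multiplicative is this package's choice and composes cleanly.

## Reporter triage (`triage`)

For each MS/MS spectrum the nearest peak within 20 ppm of 227.085, 299.117
and 332.139 is recorded.  A spectrum is an ARP candidate iff the 227.085 ion
is present at ≥1 % of the base peak.  The 1 % floor is a free parameter (no
canonical value exists); raising it can only shrink the candidate set.
Triage is advisory: it feeds confidence criterion 3, it does not gate the
search.

## Search, scoring, FDR (`psm`)

Theoretical fragmentation covers b/y ions at charges 1–2 plus the
profile-dependent loss variants above.  Matching assigns each observed peak
to at most one fragment, nearest-ppm first, within 20 ppm.  Sequence
coverage is the fraction of the n−1 backbone cleavages observed by any
matched b/y variant; a modification site is *confirmed* when the cleavages
on both sides of the residue are observed (peptide termini count).

The score is `−log10 P(X ≥ k)` for X ~ Binomial(n_theoretical, p) — the
chance of matching k fragments given the spectrum's peak density p
(peaks × mean window width / m/z range) — plus the matched-intensity
fraction as a tie-breaking bonus.  It is deterministic and transparent; it
does not attempt to reproduce any proprietary engine's score scale.

The search runs two passes, emulating a standard-then-PTM strategy: pass 1
against carbamidomethyl/Met-oxidation forms only, pass 2 (full ARP registry)
for scans not confidently assigned in pass 1.  "Assigned" requires both a
minimum score (3.0) and coverage ≥ 0.5; the coverage requirement exists
because a chance isobaric pass-1 hit can clear a pure score bar while
covering a fraction of the backbone, and would otherwise shadow the correct
modified form.  Candidates are taken from a ±3×15 ppm precursor gate (the
strict ±2 SD rule is applied later, with the fitted error model).  At equal
score a target outranks a decoy.

FDR is estimated at the peptide level: best PSM per (sequence, localized
modifications), q = decoys/targets at or above each score, monotonized from
the bottom; peptides with q ≤ 0.05 are retained.  With zero decoy PSMs the
empirical FDR is indistinguishable from zero and the pipeline retains all
best-per-peptide targets at q = 0 (the `fdr_filter` primitive itself treats
zero decoys as a hard error).

## Confidence classification (`validate`)

The precursor error model is robust: median and 1.4826×MAD of the retained
PSMs' ppm errors, with the SD floored at 0.5 ppm so noiseless data do not
collapse the window.  Criterion mapping: all evaluable criteria pass →
confident; failures confined to {site localization, precursor error} →
ambiguous; anything else → rejected.  Criteria 1–2 are `not_evaluable`
without paired enriched/non-enriched quantitation and are then excluded from
the all-pass rule.  A "resolved chromatographic peak" (criterion 1) is
operationalized as area/background ≥ 3 — no numeric definition is standard,
and 3 separates planted peaks from baseline by an order of magnitude in the
synthetic data.  Criterion 2 compares raw areas, per the literal reading of
"relative intensity higher in enriched fractions"; a load-normalized
comparison is available behind the recovery machinery.  Candidate precursors
within 2 m/z units are annotated as possible chimeras.

Isobaric assignment conflicts (e.g. glyoxal-Cys vs CAM + Gln/Asn imide, or
one- vs three-modification readings of the same precursor) are resolved by
rescoring each alternative against the spectrum and requiring the
site-discriminating ions of the winner to be matched; if no alternative has
its sites confirmed, all are recorded as ambiguous.

## Quantitation (`quantify`)

EICs sum the first three isotopes (spacing 1.00335/z) within
±(m/z / 20 000) windows.  Isotope abundances come from a Poisson
approximation to the averagine envelope (rate ≈ carbons × 1.1 %, with the
minor N/H/S contribution folded into a 1.08 factor); only relative
abundances matter, and generator and extractor share the function, so the
approximation cancels in all ratios.

Two manual clean-up steps of targeted integration are automated:

* *Interfered isotopes are removed*: per-isotope traces are normalized by
  their envelope weight; because interference is additive, the elementwise
  minimum of the normalized traces estimates the true profile even with two
  of three isotopes contaminated.  Isotopes whose normalized total exceeds
  1.25× the consensus are dropped and the remainder rescaled to full
  envelope.
* *Integration windows are corrected*: starting from the apex nearest the
  triggering MS/MS scan's retention time (hill-climbed, so a stronger
  neighbour cannot hijack the window), the boundaries walk outward while the
  trace descends or sits below 5 % of apex, and stop at a genuine valley.

Areas are trapezoidal integrals above a baseline interpolated between the
window-edge medians (leading/trailing 10 % of points); the background area
is the baseline integral, and A/B > 10 marks a peptide as quantifiable
before enrichment.  Recovery is the load-normalized area ratio
`100 · (A_enr/A_non) · (L_non/L_enr)`; the load ratio is oriented so that a
lossless enrichment reads exactly 100 % under the default 11 µg / 70 ng
loads.  CV is `100 · SD/mean` over replicate areas (sample SD, n ≥ 2).
The upscale comparison reports per-peptide mean-area ratios between load
conditions and summarizes them as mean, median, and the fraction above 1;
"mean of per-peptide ratios" is the reported statistic (a ratio of means is
the other defensible reading, and differs only at second order here).
Ion-mobility filtering keeps features within a half-window of
drift/(2 × 15) around the predicted drift time; the bundled drift predictor
(0.25·√(m/z)/√z ms) is a monotone surrogate shared with the generator, not
a physical model.

## The synthetic-data generator (`synth`)

The generator is first-class, tested code and defines the study conditions:

* Protein panel: a synthetic assembly of mature-HSA tryptic regions
  (containing the classic carbonylation-hotspot peptides LKCASLQK,
  LCTVATLR, YICENQDSISSKLK, LKECCEKPLLEK), one background protein carrying
  an avidin-binding HPY motif, and three fully synthetic background
  proteins.  No download is ever required.
* Truth: 50 ARP peptidoforms (one randomly chosen eligible site/adduct per
  peptide, distinct forms, fixed CAM elsewhere) and 30 unmodified background
  peptides by default, spread over a 18-min retention axis (Gaussian peaks,
  σ = 0.08 min), charges 2–3 by length, base peak heights lognormal around
  10⁴ counts.
* Abundance model: in a non-enriched fraction a peptide's height is
  `h · L_non/L_enr`; in an enriched fraction `h · retention`, with retention
  1.0 for ARP peptides, 0.01 for background (100-fold depletion) and 0.5 for
  HPY-motif peptides.  True recovery is therefore exactly 100·retention %,
  which is what the quantitation stage must reproduce.
* Rendering: MS1 scans every 0.05 min with three-isotope envelopes; one MS2
  scan per planted peptidoform at its apex containing the full b/y ladder,
  loss variants and profile-mandated reporter ions with uniform(0.2–1)
  intensities; optional lognormal intensity jitter, Gaussian per-peak m/z
  jitter (ppm), exponential baseline peaks, and pure-noise MS2 scans.
  Scenario templates: `baseline` (noiseless), `noisy` (10 ppm jitter, 20 %
  intensity CV, baseline, 20 noise scans), `noise_only` (500 noise scans),
  `recovery`, `upscale` (10× load at 0.73 efficiency → 7.3-fold expected
  gain), `dilution` (9:1/49:1/249:1 matrix ratios).  Everything is
  bit-reproducible from (config, seed).

What the generator does **not** emulate — and hence what green tests do not
show about real data: physical CID intensity patterns (intensities are
uniform× lognormal, not mobile-proton physics), chromatographic tailing and
cross-run retention drift, charge-state mixtures per peptide, in-source
fragmentation, and real matrix complexity (background is sparse and
uncorrelated).  Conclusions supported by the synthetic truth are about the
*bookkeeping* of the pipeline — site localization, FDR control, recovery
arithmetic, criterion logic — not about spectral prediction.

## Problem sizes and known limitations

Default end-to-end runs use 50 planted ARP peptidoforms, 1–3 replicates per
fraction, ~360 MS1 scans per run, and a pass-2 index of ~6×10⁵ peptidoforms
— sizes chosen so a full simulate→search→validate→quantify cycle completes
in well under a minute on one CPU after the index is built.

Known limitations: with ~50 co-planted peptides per run, occasional pairs
land within one EIC window and <0.35 min of each other; such genuinely
unresolved coelutions fail the resolved-peak criterion (about 2 sites in 500
across ten generator seeds), which is the intended behaviour of that
criterion rather than an artifact.  The score has no learned calibration,
so absolute score values are not comparable across spectra with very
different peak densities (q-values are).  Site localization reports a
binary bracketing verdict, not a localization probability.
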