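# Methods

This note documents the models and procedures implemented in `h1ptm`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Mass scales and constants

Two mass scales are maintained throughout. Peptide- and fragment-level
arithmetic is **monoisotopic** (most abundant isotope per element, values
to ≥ 7 decimals: H 1.00782503, C 12 exactly, N 14.00307400, O 15.99491462,
P 30.97376163, S 31.97207100; proton 1.00727647 Da for m/z conversion), as
appropriate for high-resolution Orbitrap-class measurements. Intact-protein
work is **average-mass** (standard atomic weights), matching linear-mode
MALDI-TOF, whose resolution cannot separate isotopologues; its default
relative tolerance is 0.2%. Residue masses on both scales are derived from
a single table of residue elemental compositions, so the two scales cannot
drift apart.

## The modification registry

The default registry carries the classical histone marks (phospho on S/T,
acetyl on K and the protein N-terminus, methyl on K/N, dimethyl, formyl,
crotonyl, propionyl on K), the unusual plant-H1 marks (methylpyrroline
C6H7NO on K/T; phosphoglycerol, assumed composition C3H7O5P ≈ 154.0031 Da,
on S/T — the measured values 154.009/154.002 bracket this and no formula is
established), the K / KV / KH amino-acid adducts, and two chemically
unresolved shifts carried as bare masses (84.020 Da on K; 156.1016 Da on
E/I). The K/KV/KH adducts are modelled as **isopeptide branches**: the
delta is the sum of the bare residue masses with no terminal water,
matching attachment of an amino acid (or dipeptide) through the lysine
side-chain ε-amine. Every consumer of the registry handles both
composition-backed and bare-mass entries. Dimethyl and formyl differ by
0.036 Da and are the registry's canonical near-isobar pair; discriminating
them is a direct test of the mass-refinement machinery.

## Digestion

Cleavage rules: trypsin C-terminal to K/R, Arg-C C-terminal to R (both
suppressed before proline — the standard Keil rule, configurable),
thermolysin N-terminal to L/I/A/F/V/M, pepsin C-terminal to F/L. Pepsin
cleaves only "preferentially" at these residues in reality; the strict
deterministic rule is a documented simplification, as probabilistic
cleavage would not be reproducible. Defaults: ≤ 2 missed cleavages, length
5–40. Digestion is verified against a brute-force enumerator that tests
every substring against the rule.

**Coordinates are Met-inclusive**: position 1 is the initiator methionine
even though the mature histones lack it, so site labels agree with the
standard numbering (the mature chain starts at position 2). All digest
spans, localization outputs and map rows use this frame.

## Fragment ladders

HCD produces b and y ions plus internal (doubly cleaved) fragments; a/c/z
series are not generated. The b series includes the full-chain b_n
(dehydrated protonated molecule) so every residue is covered by the series.
Internal ions are b-type (residue sum + proton), generated for peptides of
≥ 5 residues, windows of 2–12 residues. Single-residue internal fragments
are deliberately excluded: the observable single-residue marker in HCD is
the immonium ion, which lies at a different mass, whereas a b1-type
single-residue "internal" would be isobaric with genuine b1 ions of other
peptides and creates artifactual cross-assignments. Neutral losses are
attached only to phospho-bearing fragments (−H3PO4) and to
phosphoglycerol-mass-bearing fragments (−63.96 Da, annotated "unassigned,
mass matches SO2" — the loss could not be assigned to any part of a
glycerophosphate group, which is why the phosphoglycerol identification
remains putative). Singly charged b/y pairs obey
b_i + y_(n−i) = M + 2·proton exactly; this conservation identity is
asserted across the test suite.

## Open delta-mass search

For each spectrum, the observed neutral precursor mass is compared against
every digest peptide within a delta window (−0.5 to +500 Da). Each
candidate is annotated with its plain ladder plus a copy shifted by the
full delta; which positions fly shifted versus unshifted brackets the
site. Three numerical safeguards matter in practice and are part of the
method:

1. **Isobar pruning.** Theoretical ions whose m/z coincide within the
   matching tolerance but which carry different (series, position,
   shift-state) interpretations are removed before annotation — e.g. a
   shifted y_k coincides with the plain y_(k+1) exactly when the delta
   equals a residue mass (the K-adduct case), and a b_i coincides with an
   internal ion over an anagram of the same residues. A peak at such a
   mass carries no site information; keeping the ions would convert mass
   coincidences into arbitrary assignments and spurious contradictions.
2. **Candidate ranking.** Candidates are ranked first by the fraction of
   observed peaks their (unfiltered) ladder explains — the true peptide
   accounts for essentially the whole spectrum, while sub- and
   super-peptides of it explain only the shared part — then by the
   fraction of b/y ladder positions matched, heavily discounted for
   positions observed in both shift states (a candidate that "explains"
   the spectrum only through contradictory assignments must lose), then by
   more matched ions, fewer missed cleavages, and smaller |delta|.
3. **Localization brackets.** The site interval is the smallest one
   consistent with the clean ladder: unshifted b_i forces the site above
   i, shifted b_i caps it at i, the smallest shifted y_k gives the
   tightest lower bound n−k+1, the largest unshifted y_k the tightest
   upper bound, and shifted internal windows intersect the interval.
   Ladder positions observed in both states are excluded as contradicted
   rather than fatal; the result is flagged ambiguous only when the
   contradictions leave no clean shifted evidence or the bracket empties.
   A site is accepted (site-specific) only when the interval closes to one
   residue with evidence on both flanks, or with a terminal bracket.

The modification mass is then refined as the arithmetic mean of per-ion
shifts over matched shifted fragments with m/z ≤ 800 Da (Orbitrap-type
resolution improves toward low m/z; the cutoff is a package choice — the
preference for low-mass ions is inherent to the instrument model, the
threshold value is not critical), falling back to all ions when none
qualify. The refined mass is matched against the registry at the localized
residue with a 0.01 Da tolerance (the instrument-accuracy figure); all
hits within tolerance are reported, never a silent winner — near-isobars
like dimethyl/formyl are the caller's to adjudicate with the reported
|Δ| values.

## Elemental composition enumeration

Unknown deltas are searched exhaustively over CHNO by default (CHNOPS by
flag) with hydrogen counts solved from the residual mass. Plausibility
filters: ring-and-double-bond equivalents (RDBE = C − H/2 + N/2 + 1) must
be a non-negative integer — half-integer RDBE marks an odd-electron
radical composition, excluded unless `allow_radical` — hydrogen at most
2C + 2 + N, O/C ≤ 1.2, N/C ≤ 1.3, and at most 3 nitrogens (compositions
with four or more N are treated as unrealistic for small adducts).
Phosphorus and sulfur are ignored by the RDBE formula. Candidates are
sorted by |Δmass|, ties toward fewer heteroatoms. The search is verified
against a naive quadruple-loop oracle.

Two documented caveats. Reproducing C8H14O2N as the top candidate for the
156.1016 Da shift requires `allow_radical=True` (its RDBE is 2.5); with
standard isotope masses its distance from 156.1016 is ≈ 0.0009 Da, not the
0.0003 Da sometimes quoted, while the arginine-residue composition
C6H12N4O lies 0.0005 Da away — both are reported. And a plain CHNO search
finds C4H4O2 within ≈ 0.001 Da of the unexplained 84.020 Da shift; the
original analysis nevertheless deemed no combination plausible,
presumably on chemical grounds beyond these filters, so the 84.020 entry
stays classed unknown.

## Intact-mass assignment

Theoretical average masses of candidate variants (Σ average residue
masses + water, + 42.037 for an acetylated N-terminus) are compared to
deconvoluted observations at 0.2% relative tolerance; whether the measured
28.45/28.92 kDa peaks reflect acetylated termini is not resolvable at that
accuracy, and the tolerance absorbs the 42 Da ambiguity. Satellite peaks
(e.g. +190 Da) are screened as multisets of ≤ 3 registry modifications
within ±0.5 Da; monoisotopic deltas are summed, the mono-versus-average
difference for small modifications (< 0.1 Da) being immaterial at that
tolerance.

## Synthetic data: what it emulates, what it does not

`generate_proteome` builds H1-like proteins: an acidic N-terminal segment
(~20% of the length), a globular-like core (~35%), and a C-terminal tail
where each position is lysine with probability `lysine_enrichment` (0.3 by
default). `plant_modifications` draws sites respecting each modification's
residue targets at `mod_density` = 2 per 100 residues. Sites where the
modification mass equals (within 0.02 Da) the mass of one or two
contiguous adjacent residues are **not planted**: a lysine isopeptide
adduct on a lysine that neighbours another lysine, or an arginine-mass
shift next to an arginine, is indistinguishable from a linear-sequence
extension by any mass-spectrometric method, so such sites are outside the
set of assignable modifications the pipeline (like any PTM-discovery
analysis restricted to MS/MS-assignable sites) can claim.

`simulate_digest_spectra` emits one spectrum per planted site — the
smallest tryptic peptide covering it, carrying only that modification,
emulating molecule subpopulations each bearing a single mark — plus three
unmodified peptides per protein. Fragment m/z values receive Gaussian
relative error (σ = 3 ppm), peaks drop out with probability 0.1, and 10
uniform-random noise peaks are added at the 10th percentile of signal
intensity. Intensities follow a rank-based exponential decay with no
physical meaning and are never used for inference, matching the
mass-centric procedure throughout. Identical configuration and seed give
byte-identical output files.

The generator does **not** emulate: chromatographic retention or
co-isolation (chimeric spectra), isotope envelopes and deisotoping
artifacts, charge-state errors from deconvolution, intensity-dependent
peak detection, multiply modified peptides within one spectrum, or decoy
sequences for FDR control. Benchmark results therefore show that the
inference chain is correct and robust to calibrated mass error and peak
loss — not that it would match a search engine's performance on raw
instrument data.

Benchmark problem sizes (package choices): 3 proteins of 200–260 residues,
roughly 9–20 planted sites per seed, ~20–30 spectra per run; the noiseless
benchmark aggregates three seeds, the noisy benchmark five.

## Reference variant stand-ins

The bundled H1.2 / H1.1 / H1.2-splice sequences
(`synthetic_data.reference_variants`) are **synthetic stand-ins**, not
database entries: Met-initiated chains of 273/276/203 residues with the
variants' domain architecture and S/TPxK-bearing lysine-rich tails, tuned
by construction (greedy residue substitutions spanning ~0.04 Da to ~57 Da
per swap) so the mature average masses match the reported intact masses of
28 450, 28 920 and 21 560 Da to well under 0.1%. The splice stand-in is
the H1.2 stand-in with a 70-residue block of the C-terminal domain
removed, mirroring the short splice variant. They exercise the intact-mass
arithmetic and variant-assignment logic; they carry no claim about the
real sequences beyond length, architecture and mass.

## Known limitations

* The open search assumes at most one modification (one delta) per
  spectrum; composite deltas are only handled at the intact-protein level.
* Localization is deterministic bracketing, not probabilistic scoring
  (no Ascore/PTMProphet analogue), and there is no target–decoy FDR.
* Isopeptide adducts adjacent to identical sequence context are
  intrinsically unassignable (see above); the generator excludes them and
  the search will report such spectra as ambiguous or as the parsimonious
  unmodified interpretation.
* Pepsin/thermolysin specificity is idealized; semi-specific cleavage is
  out of scope.
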