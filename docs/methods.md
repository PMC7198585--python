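# Methods

`isoxlink` identifies N^ε^-(γ-glutamyl)-lysine isopeptides between gluten
peptides and human tissue transglutaminase (TG2) peptides from tandem mass
spectrometry data. This note documents the model, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## The crosslink-as-modification model

TG2 transamidation joins a glutamine γ-carboxamide (acyl donor, on the gluten
"α-side") to a lysine ε-amine (acyl acceptor, on the TG2 "β-side") with
release of one NH3. An isopeptide is therefore modelled as a base peptide
carrying a variable modification whose elemental composition is the partner
peptide's composition minus NH3. The seven TG2-side peptides are the
single-lysine tryptic peptides around K205, K265, K429, K468, K590, K600 and
K677 (FLKNAGR, WKNHGCQR, ISTKSVGR, LAEKEETGMAMR, DLYLENPEIKIR, QKR, AVKGFR);
using single-lysine peptides pins the acceptor site on the TG2 side, so all
positional ambiguity lives on the gluten side.

All mass arithmetic is element-count arithmetic over signed composition maps;
monoisotopic masses (NIST atomic masses) are used throughout, and m/z =
(M + z·1.007276466)/z. Cysteine is handled as the free thiol — no
carbamidomethylation — which is what reproduces the WKNHGCQR modification
formula C43H62N16O11S; alkylation is available as an optional modification
but off by default. Deamidation (Q/N → E/D) is the delta −H −N +O
(+0.9840156 Da) and is never placed on the crosslinked Q, which no longer has
a free carboxamide.

Isotope envelopes are computed by exact per-element multinomial convolution
of isotope-offset distributions (binary exponentiation over atom counts),
aggregated by nominal mass offset (A, A+1, …) because that is the binning on
which expected-vs-observed precursor comparisons operate. Returned abundances
are renormalized over the requested number of peaks.

## Digestion

Gluten proteins are digested in silico with the union of pepsin, trypsin and
chymotrypsin sites; TG2 with trypsin alone. Site definitions (the original
search engine's definitions are not recoverable from its configuration):

* trypsin: after K/R, not before P;
* chymotrypsin (high specificity): after F/Y/W, not before P;
* pepsin (pH 1.3–2 convention): after F/L, not before P.

The pepsin rule in particular is a documented default, not an inference —
pepsin's specificity is famously loose, and the rule is configurable via
`CleavageRule`. Missed cleavages (default ≤ 2) are counted against the union
of active sites, matching a single-pass multi-enzyme "specific" search.
Semi-specific digestion (one free terminus) is available for products of
unspecific cleavage. Coordinates are 1-based inclusive. Search candidates are
bounded to 5–30 residues by default (the shortest reference α-side peptide
has 7); the bounds do not apply to TG2 donor selection, which must keep the
tripeptide QKR.

## Fragment calculus

For either side taken as the base sequence, b- and y-ions of every prefix and
suffix are enumerated (a = b − CO), and any fragment covering the crosslink
position carries the full partner mass (partner composition − NH3). Neutral
losses are residue-gated by default — H2O from fragments containing S/T/E/D,
NH3 from fragments containing R/K/N/Q (or carrying the K/R-containing
partner) — and can be switched to "always". Fragment charges go up to 3+
(default 2+ for scoring), precursor charges up to 5+.

"Internal fragments" (double fragmentation) admit two readings, both
implemented and independently switchable: (i) ordinary interior b-type
internal ions of the base sequence (length 2–12 by default), and (ii)
spanning ions in which the attached partner is itself truncated to a b/y
sub-fragment still containing its crosslink residue. The third-party
calculator used for the original annotations does not publish its internal
ion rules, so neither reading is treated as canonical and neither is enabled
in scoring by default.

Fragment-to-peak matching is greedy one-to-one: fragments in m/z order each
take the nearest unclaimed peak within tolerance (default 0.5 Da), distance
ties broken toward higher intensity, then lower peak index — fully
deterministic. Precursor matching uses 4.5 ppm.

## Discovery search and scoring

Candidates for a spectrum are digested gluten peptides whose mass plus the
active crosslink-modification mass plus k deamidation deltas (k = 0…4, at
most 5 modifications total including the crosslink) matches the precursor
within tolerance, found by binary search over a mass-sorted peptide index.
Each candidate is expanded over admissible placements (crosslink on any Q ×
deamidation k-subsets of remaining N/Q). The expansion is exhaustive up to
2000 placements per candidate; beyond that, each crosslink site's deamidation
set is built by greedy forward selection against the spectrum and the best
site's set is surrounded by all single-site swaps, so localization posteriors
keep representing the alternatives that matter. The exhaustive and guided
paths agree on every benchmark case small enough to compare.

The score is an explicit binomial survival score: with t theoretical
fragments, m matched, and per-fragment chance probability p = peak density ×
2·tolerance (clipped to [1e-9, 0.3]), score = −10·log10 P(X ≥ m) for
X ~ Binomial(t, p). The tail is evaluated in log space with log-sum-exp over
pmf terms because the plain survival function underflows near-complete
matches (hundreds of fragments), which would otherwise saturate the score and
erase site discrimination. The score is a transparent surrogate — it is
comparable within a run but is not on any proprietary engine's scale; the
default acceptance threshold for modified peptides (40, i.e. P ≈ 1e-4) was
validated on the synthetic benchmark. A note on resolution: at 0.5 Da
fragment tolerance, charge-2 fragments cannot discriminate single
deamidations (0.492 Th shift); discrimination rests on charge-1 ions, exactly
as in manual annotation practice.

Localization probabilities follow published PTM-score practice: placement
weights are a softmax of 10^(score/10); a site's probability is the summed
weight of placements containing it; sites above 0.75 are "localized". With
fragment sets identical between two placements the posterior is split evenly,
which is the honest answer.

Decoys are shuffled sequences with the C-terminal residue fixed, generated
from the run's seed, competing in the same search when enabled.

## Confirmation and targeted validation

A discovery identification is **confirmed** only if: detected in every sample
replicate (configurable to k-of-n) with retention times within ±0.5 min
(configurable; the source protocol states no number, this is typical nano-LC
reproducibility); absent from every negative control; at least 7 matched b/y
fragments — unique (side, type, index), charge and loss variants collapsed,
internal and a-ions never counted; at least 3 consecutive indices within one
ion ladder (ladders never join b with y, or α with β); precursor isotope dot
product (cosine) > 0.9; and crosslink localization > 0.75, failing which the
verdict is "ambiguous-site" rather than rejected. Every failed criterion
emits a reason code; a verdict is confirmed iff the reason set is empty, and
verdicts are monotone in every evidence value (property-tested).

PRM validation exports an isolation list with both representations of each
isopeptide (gluten-base and TG2-base — the same molecule, same precursor m/z)
at charges 2–3 in a vendor-neutral TSV (m/z, charge, polarity, start, end,
name; 1.7 Th windows). Analysis assigns MS2 scans to targets by isolation
window, sums peak intensity within tolerance of each transition, and picks
elution peaks deterministically: baseline = trace median, peak = maximal
contiguous region above baseline bounded at 5% of apex height (the original
analysis used interactive software; an explicit rule replaces the analyst).
Confirmation requires ≥7 co-eluting b/y transitions (apexes within 0.2 min of
the strongest transition), ≥3 consecutive, retention time consistent with
discovery, no control signal; site-determining transitions detected for
exactly one candidate site assign that site.

## Q-motif bookkeeping

TG2's sequence preference is read from the residues after a glutamine: QXP
and QXXF(Y/W/M/L/I/V) (and the more specific QXPF*) are preferred targets; QP
and QXXP are poor or non-targets; X is any residue but proline.
Classification precedence is fixed: QP → QXPF* → QXP → QXXF* → QXXP → other,
with "insufficient-context" when the peptide ends before any rule can fire.
Context is evaluated within the peptide as printed, not the parent protein.
Because a QXPF* context also satisfies the QXP pattern, summaries report a
"QXP family" rollup (QXP + QXPF*) alongside the fine labels; the reference
set's crosslink counts (12 QXP-family, 5 QP, 3 QXXF*) use the rollup.

## The synthetic benchmark

The generator emulates the statistical structure the analysis assumes:
Q/P-rich gluten-like proteins (defaults Q 0.30, P 0.20, F 0.05, L 0.08, the
remainder spread over a lysine-free alphabet — prolamins are famously
lysine-poor); true isopeptides pairing digested Q-containing peptides with
the seven TG2 donors, crosslink sites drawn with a configurable bias toward
preferred motifs (default 0.7); per-site deamidation probability 0.2 (≤ 3
per peptide); triplicate samples plus triplicate negative controls in which
crosslinked species are absent by construction; fragment subsets drawn per a
coverage fraction with m/z jitter uniform within ±0.15 Da (inside the 0.5 Da
tolerance) and log-normal intensities; uniform retention times over a
10–70 min gradient with 0.1 min replicate jitter; precursor charges 2–4;
observed precursor envelopes = expected envelope with 0.5% multiplicative
noise; PRM transitions as Gaussian elution profiles (σ = 0.08 min, 0.02 min
scan interval) with configurable dropout of site-determining ions. All
randomness flows from one seed; identical seeds give byte-identical outputs.

What the generator does **not** model: chromatographic physics, ionization
efficiency, co-isolation/chimeric spectra, correlated noise, intensity
realism, non-tryptic background, or real sequence homology structure
(repetitiveness is emulated only through residue frequencies). Passing the
round trip therefore demonstrates the internal consistency and calibration
of the pipeline — candidate generation finds the truth, scoring ranks it
first, localization pins the site, confirmation logic is sound — not
instrument-level performance on real hydrolysates.

Benchmark sizes: the perfect-conditions acceptance run injects 50 isopeptides
(coverage 1.0, zero noise) and requires sensitivity = specificity = 1.0; the
noise benchmark uses ≥100 spectra at coverage 0.8 with 50 noise peaks and
requires ≥95% rank-1 accuracy. These sizes exercise every code path while
keeping the default test run fast on one CPU.

## Packaged reference data

The 29-isopeptide reference table (wheat W1–W13, rye R1–R6, barley B1–B10)
ships as TSV with crosslink/deamidation sites, ambiguity flags (crosslink
ambiguous exactly for B4 and B6, deamidation for B6 and B8), provenance
fields and per-record notes. Where the typeset source is internally
inconsistent (W5, W11, B5 bolding vs the motif groupings discussed by id) the
fixture follows the id-level groupings and figure evidence, with a note on
each affected record. Deamidation positions that survive only in figure
annotations were reconstructed from the id-level motif lists; the two
reconstructed records (W2, W8) are marked as such. The TG2 carrier sequence
is a synthetic stand-in (clearly labelled in its FASTA header): 687 residues
reproducing the seven donor peptides in tryptic context at the published
lysine positions, sufficient for digestion and donor selection; its filler
regions are not the native sequence.

## Known limitations

* The binomial score and softmax localization are surrogates; engine scores
  and engine localization percentages from the original study are
  descriptive context, not reproduction targets.
* Only protonated species; no c/z ions, no isotope-resolved fragment
  matching, no intensity prediction, no FDR machinery beyond decoy
  generation.
* mzML is supported on the read side only; synthetic runs are written as MGF
  (with the precursor envelope carried in a header field) because no mzML
  writer is part of the dependency set.
* PRM scan-to-target assignment assumes targets are separated by more than
  the isolation window; co-isolating targets would merge traces.
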