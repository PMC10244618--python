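# Methods

This note documents the models, the simulator, the numerical choices and
the limits of what the test suite demonstrates.

## Coordinate model

Isoform relationships are interval-deletion maps: an alternate isoform is
the reference minus one internal closed interval, with an optional
divergent C-terminal tail of different length. For NF2, isoform 7 lacks
reference residues 39–121 (83 residues of the F1/F2 FERM subdomains) and
carries an exon-16 tail that starts at reference residue 580 and is 5
residues shorter, so its length is 595 − 83 − 5 = 507 and every residue
from 122 to 579 maps with a constant −83 offset. Positions 580–590 map
positionally but are flagged `divergent_sequence`, because the residue
identities differ — callers must decide whether a divergent position is
usable for their purpose (profiles computed here keep them, flagged).
Positions 39–121 and 591–595 have no partner and are `unmapped` rather
than approximated. All coordinates are 1-based, intervals inclusive.
Variant labels use reference (isoform-1) numbering; the library and all
profile coordinates are isoform-7; conversions are always explicit.

## Library catalog

One entry per (codon position, replacement codon) with replacement codons
GCT/AAA/GAA/TTG. Entries identical to the wild-type codon are suppressed
(unobservable in sequencing); protein-synonymous but codon-changing
entries are kept and flagged — they are sequencable internal negative
controls. Oligo design (flanks, melting temperatures) is out of scope;
the catalog is the contract between design, simulation and scoring.

## Screen simulator

The generator emulates the sequencing side of a reverse-Y2H selection on
a single-ORF mutant library. Per molecule: one catalog variant (or none,
with probability `wt_fraction`) drawn proportionally to a log-normal
library abundance, multiplied in the selected pool by the variant's
enrichment factor `f ≥ 1` (selection enriches non-interactors; all
non-perturbing variants keep `f = 1`); a uniformly placed fragment of
normal length; 150 bp reads from both ends; optional secondary codon
change, substitution errors and 1–3 bp indels. Defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| `read_length` | 150 bp | paired-end short-read screen format |
| `fragment_length` | 280 ± 30 bp | typical short-insert library; keeps mates nearly tiling the insert and yields the smooth position-dependent coverage that motivates per-codon models |
| `abundance_sigma` | 0.5 (log-normal) | on-chip oligo pools are fairly even; ~2–3-fold spread between quartile entries |
| `wt_fraction` | 0.05 | residual unmutated template after multi-step mutagenic PCR |
| `secondary_rate` | 0.01 / molecule | spurious extra codon change from PCR/synthesis, drawn uniformly from non-programmed codon changes; these are real molecules, reproducible between pools, and motivate the 0.8 co-occurrence exclusion |
| `error_rate` | 5e-5 / base | residual *consensus-level* substitution miscalls after quality filtering; raw instrument error is an order of magnitude higher but is largely removed upstream of variant counting, and molecule-level artifacts are modelled separately by `secondary_rate` |
| `indel_rate` | 1e-3 / read | rare sequencing/synthesis indels, enough to exercise local indel removal |

A variant is visible in a pair only when the sequenced bases cover its
codon; the ground-truth table records both molecule counts and
covered-molecule counts so calling can be checked for exact equality.
Identical seeds give byte-identical FASTQ. Quality strings are constant;
realistic quality profiles and barcode demultiplexing are out of scope.

What the simulator does **not** emulate: position- or motif-dependent
error profiles, PCR jackpotting (duplicate multiplicities come only from
finite fragment-coordinate space), chimeric reads, and selection acting
on anything but a per-variant multiplicative factor. Passing tests
therefore show that the analysis recovers a planted multiplicative
enrichment under realistic coverage geometry and noise — not that it is
robust to every artifact of real libraries.

## Mutant calling

Counting unit: the unique (seq1, seq2) pair weighted by its multiplicity.
Alignment is seed-and-verify against the single known ORF: exact 25-mer
seeds anchor an offset (final window always probed; a denser 12-mer pass
rescues short reads whose long seeds all straddle a mutation), the
placement is verified by vectorized mismatch counting, and reads below
80% identity fall back to a bounded-gap infix alignment (edlib), whose
insertions are dropped and deletions masked (`indel_corrected`). Both
orientations are tried. Unalignable reads are counted, never fatal.

Calls are per codon: all three bases must be covered by the pair (partial
codons are discarded — conservative, avoids phantom codons), positions
where overlapping mates disagree are voided, and 1–3 nt changes within
one codon are a single call. Co-occurrence of calls on the same pair is
recorded for filtering.

The two confidence rules are interpretations behind named thresholds,
because the exact operand of "maximal signal" is not standardized:

* **secondary exclusion (0.8)** — for a primary call `m`, any other call
  `s` co-occurring on more than `0.8 × count(m)` of its pairs marks those
  joint pairs as artifact-driven; they are removed from `count(m)`.
* **low-confidence removal (0.7)** — a call with any indel-corrected
  support whose total support is below `0.7 ×` the strongest call at that
  position is dropped.

Both directions of "stricter" (lower co-occurrence threshold, higher
low-confidence threshold) can only decrease counts; coverage is never
altered by filtering. Every exclusion is logged with its rule.

## Enrichment model

Per codon identity, ordinary least squares of selected counts on control
counts across positions (statsmodels OLS; an intercept column is always
included, with the pseudoinverse resolving the degenerate constant-count
case). Positions observed in both samples form the residual set; codons
carried by fewer than 3 control positions are marked invalid and skipped.
The control is the pooled no-selection baseline across control runs.
Summaries per codon: slope, intercept, residuals, MAE (mean absolute
residual) and `residual_scale` (median absolute residual — robust to the
very outliers the screen is meant to find).

Scores are `observed / expected` with `expected = a + b·control`; records
with `expected ≤ 0` are excluded with a reason, never scored. The
high-confidence flag is `observed ≥ 50` **and** `observed > expected +
2·residual_scale` (default reading of "twofold variation of the linear
model"); `score ≥ 2` is the alternative reading behind a switch.

Per-position scores default to the **max** over the position's programmed
codons (a position is perturbing if any of its four substitutions is; a
mean mode exists). Missing positions stay missing — they are never
zero-filled, so Z-scores are computed over scored positions only, per
interaction sample, before replicate combination (position-wise mean of
replicate Z, missing ignored per position). With constant scores the Z
denominator is guarded to zero. Hotspots are maximal runs of
centered-window smoothed Z above a threshold (defaults: window 9,
Z ≥ 1.5, run ≥ 5), reported in isoform-7 and mapped isoform-1 coordinates.
Pooled-across-interactions Z normalization can be had by concatenating
records before profiling; per-interaction is the default because
replicate combination is defined on per-sample Z tracks.

## Cell assays

FACS: replicate percent-positive values are averaged per variant within
each (experiment, timepoint) stratum (averaging first is a choice;
the alternative inflates n with replicate noise), then z-scored across
the variant panel (ddof = 1; ≥ 3 variants required). A variant is a hit
in an experiment when its z is beyond ±0.8 *inclusive* with the same sign
on ≥ 2 timepoints — same sign so opposite excursions cannot combine into
a spurious hit. Live imaging: confluency area integrated (trapezoid) over
the configured interval per replicate, variant means normalized by the
median across variants, Welch's unequal-variance two-sided t-test against
the designated reference (scaling by the common median does not change
the test), stars at 0.05/0.01/0.001.

## Structure contacts

Heavy-atom, distance-only criteria — no hydrogens are placed and no
angular terms are evaluated, because reported contact distances of this
kind are plain inter-atom distances and exact geometric criteria vary by
tool. Defaults: hydrogen bond = N/O pair ≤ 3.4 Å; salt bridge =
opposite-charge group N/O ≤ 4.0 Å (Asp/Glu carboxylate vs
Arg/Lys/His nitrogen); hydrophobic = sidechain C–C ≤ 5.6 Å (wide enough
to include weak ~5.5 Å contacts); π–sulfur = aromatic ring centroid to
S ≤ 5.5 Å. Sequence neighbours within ±2 on the same chain are suppressed
to avoid counting covalent geometry as contacts. All cutoffs are
configuration values; a residue pair may satisfy several types and yields
one record per type. Parsing is via gemmi (PDB and mmCIF).

The shipped `contacts_synthetic_mimic.pdb` is a constructed-coordinate
fixture: four residues placed so that the E260↔R588 charged-group minimum
is 2.7 Å and the Y244↔P252 sidechain-carbon minimum is 4.2 Å, mimicking
the closed-conformation FERM / C-terminal-peptide interface. It validates
selectors, classification and distance code against a known geometry; it
is not an experimental structure, and conclusions about the real protein
require real coordinates (in-silico mutagenesis and energy modelling are
out of scope entirely).

## Problem sizes and determinism

The test suite runs the full analysis at a 507-codon, 200,000-pair-per-
sample scale (one selection screen with 10 variants planted at f = 20 and
one all-`f = 1` null screen) — large enough for the MAE contrast,
recovery and calibration properties to be stable, small enough for a
laptop-class run; calling-fidelity checks use a 50-codon ORF across 20
seeds where equality with ground truth is exact, not approximate. All
randomness flows from one integer seed per run; pipeline artifacts carry
the package version, a configuration hash (output location excluded) and
the coordinate convention in their headers, and identical seed +
configuration reproduce byte-identical files.

## Known limitations

* The shipped NF2 sequences are synthetic stand-ins with the correct
  architecture and anchored residue identities, not database entries;
  analyses of real screens should supply the real CDS FASTA.
* The two confidence filters implement one reasonable reading each of
  their cutoff phrases; other readings exist and the thresholds are
  exposed rather than hard-coded.
* Enrichment models are per-codon OLS on counts; no variance
  stabilization or count-model (Poisson/NB) likelihoods. With planted
  outliers the robust `residual_scale` keeps flagging calibrated, but
  extremely deep screens may prefer a count-aware model.
* The aligner is specialized to a single short known ORF; it is not a
  general-purpose spliced or multi-reference aligner, though SAM input
  from an external aligner enters the same calling path.
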