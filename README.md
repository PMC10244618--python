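# nf2scan

Deep mutational **interaction-perturbation scanning** of the NF2 (merlin)
tumor suppressor, as a tested, reusable analysis pipeline.

NF2 switches between open and closed conformations; which protein partners
it binds (KDM1A, EMILIN1, PIK3R3, its own C-terminal half) depends on that
conformation. A reverse yeast two-hybrid (rY2H) screen turns this into a
selection: a mutagenic library of the 507-residue NF2 isoform 7 — every
codon replaced by alanine (GCT), lysine (AAA), glutamic acid (GAA) and
leucine (TTG), the "AKEL" scan — is mated against one wild-type partner,
and *non-interacting* variants grow on selective medium. Sequencing the
selected pool against the unselected library reveals which substitutions
perturb each interaction, and where those residues cluster along — and on
the 3D structure of — the protein.

`nf2scan` implements everything downstream of the sequencer, plus a
generative simulator of the screen itself:

| stage | module | what it does |
|---|---|---|
| coordinates | `nf2scan.isoforms` | residue mapping between isoform-1 (595 aa) and isoform-7 (507 aa) numbering: deletion of residues 39–121, divergent exon-16 C-terminus from residue 580, 5 residues shorter |
| design | `nf2scan.catalog` | the programmed AKEL substitution catalog for any ORF |
| simulation | `nf2scan.simulate` | paired-end FASTQ for control + selected pools with planted enrichment, log-normal library abundances, coverage geometry, secondary mutations, errors, indels, and a ground-truth table |
| calling | `nf2scan.calling` | unique-pair dedup, seed-and-verify alignment to the single known ORF, codon-level mutation calls with co-occurrence records, and the 0.8 (secondary-mutation) / 0.7 (indel-corrected low-support) confidence filters |
| scoring | `nf2scan.enrichment` | per-codon linear models of selected vs control counts, enrichment scores, MAE diagnostics, high-confidence flags, Z-score perturbation profiles, replicate combination, hotspot regions |
| cell assays | `nf2scan.assays` | FACS percent-positive z-scores with the two-timepoint ±0.8 hit rule; median-normalized live-imaging proliferation with Welch t-tests |
| structure | `nf2scan.contacts` | distance-based residue contact classification (hydrogen bond ≤ 3.4 Å, salt bridge ≤ 4.0 Å, hydrophobic C–C ≤ 5.6 Å, π–sulfur ≤ 5.5 Å) on PDB/mmCIF |

## The statistic at the core

For each codon identity `c` (the four programmed codons and every observed
background codon), counts are compared across ORF positions `p` between the
selected pool and the unselected library:

```
selected_count(p, c) = a_c + b_c * control_count(p, c) + e(p, c)
```

fitted by least squares, with `MAE_c = mean |e(p, c)|` as the recall
diagnostic. Selection leaves background codons on the line (small MAE) and
pulls programmed codons off it. One variant's enrichment is

```
score(p, c) = observed selected count / model-expected count
```

High-confidence calls need ≥ 50 selected reads and enrichment above twofold
variation of the linear model (implemented as
`observed > expected + 2 × median|residual|`; a plain `score ≥ 2` mode is a
configuration switch). Per-position scores (max over the four programmed
codons) are normalized to Z-scores per interaction sample, replicates are
combined by position-wise means, and contiguous stretches of elevated
smoothed Z become hotspot regions — reported in both isoform-7 and mapped
isoform-1 coordinates, since variant names (Q147A, S518D, …) use isoform-1
numbering throughout while the library lives on isoform 7.

The shipped NF2 sequences are **synthetic stand-ins** (see
`src/nf2scan/data/*synthetic*`): they reproduce the real isoform
architecture and the residue identities at every position this package
reasons about, but are not the database entries, which keeps the repository
self-contained and network-free. The same applies to the constructed
coordinate fixture used by the structure tests.

## Worked example

```python
from nf2scan.pipeline import PipelineConfig, run_pipeline
from nf2scan.simulate import SimulationConfig

cfg = PipelineConfig(
    outdir="worked", seed=42,
    sim=SimulationConfig(n_pairs_control=50_000, n_pairs_selected=50_000,
                         n_perturbing=10, enrichment_factor=20.0))
out = run_pipeline(cfg)
print((out / "summary.txt").read_text())
```

simulates a 507-codon AKEL screen with 10 planted interaction-perturbing
variants enriched 20-fold, calls mutants, and fits the models. It prints:

```
catalog: 2028 entries over 507 codons
control: 50000 pairs (44416 unique, 0 unaligned); mutant reads 9353 -> 9081 after filters
selected: 50000 pairs (44560 unique, 0 unaligned); mutant reads 9473 -> 9195 after filters
enrichment: 1862 records, 5 high-confidence

Codon-specific enrichment model
  codons fitted: 8 of 64   positions: 507
  scored records: 1862   high-confidence: 5 (cutoff 50 reads, mode residual)

   codon  n_pos     slope  intercept       MAE  resid_scale
     AAA    414     0.452       2.98      2.73         2.14
     GAA    418     0.575       1.83      2.10         1.72
     GCT    416     0.542       2.37      2.21         1.84
     TTG    404     0.443       3.08      2.71         1.96
     ...
```

Reading it: 2028 = 4 × 507 programmed entries; ~89% of read pairs are
unique molecules; the four programmed codons are observed at ~410 positions
each. The top of `enrichment.tsv` is dominated by the planted variants
(e.g. codon 436, AAA: observed 146 vs expected 5.2, score 27.9,
high-confidence) while background codons sit near score 1. At this depth a
planted variant needs a fortunate library abundance to clear the 50-read
cutoff — 5 of the 10 do; the deeper simulations in the test suite recover
10 of 10 in the top ranks.

The command-line interface exposes the same stages
(`nf2scan simulate | call | enrich | hotspots | facs | contacts | run-all`).

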