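# dsrnakit

Design of optimized dsRNA regions for RNA interference (RNAi), with
companion analyses for RISC-bound small-RNA profiles and insect
bioassay survival data.

The library scores every candidate 21-nt siRNA that a target transcript
can yield:

* **efficacy features** — thermodynamic asymmetry of the duplex ends
  (nearest-neighbor stack energies), antisense self-folding energy,
  GC content over antisense positions 9–14, adenine at position 10,
  full-length GC, antisense:target binding energy, target-region label
  (ORF/UTR) and target-site accessibility (equilibrium partition
  function on a local window);
* **off-target safety** — mismatch-tolerant (Hamming ≤ 2) search of
  each siRNA against non-target transcriptomes in both orientations,
  with essential-gene hits weighted 20:1 and the weighted counts
  percent-normalized into a safety score;

blends them with a configurable efficacy/safety priority, and selects
the dsRNA region whose siRNAs have the best mean score by a 1-nt-step
sliding window (default 300 bp, optionally restricted to the longest
ORF). It also builds siRNA-insertion constructs (a 21-nt site placed at
the midpoint of a backbone sequence), maps small-RNA reads strand-
specifically onto dsRNA templates, compares base composition between
abundance extremes (per-position chi-square with Bonferroni
correction), and computes bioassay statistics (observed/expected
log-rank hazard ratios, Cox proportional-hazards fits with Harrell's
C, hazard-ratio multiple regression, paired t-tests).

No external folding engine or aligner is required: folding and
accessibility use an internal reduced stacking/McCaskill model, and
off-target search uses a pigeonhole seed index verified by Hamming
count.

## Layout

| module | role |
| --- | --- |
| `dsrnakit.seqio` | FASTA I/O, coordinate conventions, longest-ORF finder |
| `dsrnakit.energetics` | nearest-neighbor duplex energies, folding MFE, site accessibility |
| `dsrnakit.sirna_features` | candidate enumeration and per-siRNA feature vectors |
| `dsrnakit.offtarget` | mismatch-tolerant transcriptome search and safety scores |
| `dsrnakit.designer` | score normalization, priority blending, sliding-window selection, constructs |
| `dsrnakit.riscseq` | strand-specific read mapping, antisense fraction, composition tests |
| `dsrnakit.biostats` | log-rank hazard ratios, Cox fits, hazard regression, paired t |
| `dsrnakit.fixtures` | deterministic synthetic transcriptomes/reads/survival generators |

## CLI

```sh
# score siRNAs of each transcript and select the best window
dsrnakit design target.fasta \
    --window 300 --orf-only --priority 50 \
    --offtarget-db honeybee.fasta --essential honeybee_essential.txt \
    --mismatches 1 --out-prefix design

# outputs: design.bed (0-based half-open window), design.<id>.fasta
# (selected region), design.<id>.tsv (per-siRNA feature/score table)

# log-rank hazard ratios of every group against a control
dsrnakit survstats bioassay.csv --control-group dsmGFP --one-tailed
```

`bioassay.csv` is delimited text with columns `subject,group,day,event`
(event 1 = death observed on that day, 0 = censored).

## Notes

* Sequences are stored DNA-alphabet internally (U→T on input); all
  internal coordinates are 0-based half-open; positions quoted inside
  an siRNA ("10th nt") are 1-based along the antisense strand 5'→3'.
* The nearest-neighbor stack table ships as a TSV
  (`src/dsrnakit/data/nn_stacks.tsv`) and alternative parameter sets
  can be loaded with `energetics.load_stack_table`.
* Duplex end energies exclude initiation/terminal corrections — the
  asymmetry score is a difference in which those constants cancel.
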