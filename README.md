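# splicegc

Analysis toolkit relating GC content around splice sites to the stability of
local pre-mRNA secondary structure. It classifies splice sites from
transcript models, extracts junction windows, folds them with a simplified
nearest-neighbor energy model, selects decoy splice sites as matched
controls, generates order-preserving permutation nulls, and runs the full
battery of statistical comparisons — all exercisable end-to-end on synthetic
genomes with planted, configurable effects.

## Components

| module | what it does |
| --- | --- |
| `annotation_assembly` | GTF/BED12 transcript models; alternative / constitutive / skipped / first-exon splice-site categorization with minimum-distance filters; exon length classes |
| `windows_gc` | sense-strand junction windows (141 nt default), GC metrics, positional GC profiles, normalized junction GC |
| `folding` | minimum-free-energy prediction (Zuker-style DP, stacking + loop penalties + affine multiloops, temperature via dH/dS), exhaustive enumeration oracle, Nussinov bound |
| `decoy_model` | position log-odds splice-site scorer (donor 9-mer, acceptor 23-mer); nearest qualifying GT/AG decoy 150–300 nt into the flanking intron; paired real-vs-decoy comparisons |
| `shuffling` | mononucleotide permutation and dinucleotide-preserving Euler-path shuffle; nucleotide-order-effect analysis |
| `stats` | rank-sum and signed-rank tests (exact by enumeration for small n), GC–energy regression, GC-matched bin comparisons, distance-controlled pairing, tissue-specificity rule |
| `synthetic_data` | deterministic genomes/annotations/tissue tables with planted categories, GC targets, consensus dinucleotides and decoys |
| `pipeline` | orchestration of all stages behind a CLI, TSV reports, one-page summary |

## CLI

```
splicegc simulate --seed 1 --n-genes 30 --tissue --out sim/
splicegc classify --annotation sim/annotation.gtf --out sites.tsv
splicegc windows --fasta sim/genome.fa --annotation sim/annotation.gtf --out windows.tsv
splicegc fold --sequence GGGGAAAACCCC --temperature 37
splicegc decoys --fasta sim/genome.fa --annotation sim/annotation.gtf --out decoys.tsv
splicegc shuffle ACGUACGUACGU --order dinuc --n 10 --seed 1
splicegc run-all --synthetic --n-genes 30 --seed 11 --out run/
```

`run-all` also accepts `--fasta/--annotation/--tissue-table` for real inputs,
`--flank 30` for the 61-nt window variant, and `--temperature 25`/`24` for
the colder presets. Each stage writes a TSV (units in the header); `run/
summary.txt` collects n's, means, p-values and direction checks per stage.

## Conventions

Coordinates are 0-based half-open internally and 1-based in written reports.
For a donor site, `junction_pos` is the first intronic base (GT begins
there on the sense strand); for an acceptor it is the last intronic base
(AG ends there). Windows are centered on that base; the exonic and intronic
halves are the two flanks, with the center base counted separately.
Energies are kcal/mol; MFE is always ≤ 0 (open chain = 0).
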