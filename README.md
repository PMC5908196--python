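# lgtrecon

Detection of lateral gene transfer (LGT) in gene families by
duplication–transfer–loss (DTL) parsimony reconciliation of gene trees
against a species tree, with an independent Robinson–Foulds/SPR
cross-check, homolog filtering, Tajima's D neutrality screening,
flanking-gene synteny scoring, and CAZome count-matrix analytics — plus
seeded simulators that generate every input with ground-truth event
histories, so the whole pipeline is testable offline.

## Layout

| module | what it does |
|---|---|
| `lgtrecon.trees` | Newick I/O, rooting (midpoint), support-threshold collapsing, RF distance |
| `lgtrecon.reconcile` | undated DTL / DL parsimony reconciliation, optimal rooting, polytomy resolution, brute-force oracle |
| `lgtrecon.lgt_caller` | homolog filters, per-family classification across transfer:duplication cost ratios, SPR/RF cross-check, donor assignment, summary table |
| `lgtrecon.neutrality` | Tajima's D, beta-approximation significance, marker selection filter |
| `lgtrecon.synteny` | ±5-flanking-gene synteny score, cluster conservation test |
| `lgtrecon.profile` | hierarchical clustering (Euclidean/complete), PCA, genome-fraction statistic |
| `lgtrecon.synthetic_data` | seeded generators: species trees, DTL gene families with event logs, neutral coalescent sites, gene-order neighborhoods, hit tables |
| `lgtrecon.validation` | simulation benchmarks: false-positive control and detection power of the LGT caller |
| `lgtrecon.cli` | `lgtrecon` command line and the end-to-end pipeline |

## CLI

```sh
# simulate a project, then classify it
lgtrecon simulate family --seed 3 --out sim/
lgtrecon call --families families/ --species species.nwk \
    --ratios 2,4,6 --threshold 0.9 --focal focal.txt --out run1/

# individual stages
lgtrecon trees rf --t1 a.nwk --t2 b.nwk
lgtrecon trees collapse genetree.nwk --threshold 0.9
lgtrecon reconcile --gene g.nwk --species s.nwk --dup 1 --transfer 2 --loss 1
lgtrecon tajima alignment.fasta
lgtrecon synteny --orders orders.tsv --orthologs pairs.tsv \
    --focal-a geneA --focal-b geneB --genome-a g01 --genome-b g02
lgtrecon profile counts.tsv
lgtrecon run --config run.yaml
```

Gene-tree leaves encode their species as `species|geneid`; a bare label is
its own species. Defaults follow the reference analysis: primary
transfer:duplication ratio 2 (also evaluated at 4 and 6, dup = loss = 1),
support threshold 0.9 (strictly lower collapses), homolog cutoffs
coverage > 0.90 and E-value < 1e-100, ±5 flanking genes, cluster
conservation cutoff 80 % (strict), α = 0.05.

A family is called `lgt` only when the reconciliation at the primary ratio
contains a transfer, the DTL optimum is strictly cheaper than the best
transfer-free (duplication+loss) explanation, and the independent SPR scan
of the midpoint-rooted, one-tip-per-species gene tree finds a conflicting
split implicating the focal clade. Families whose leaves are all focal are
`unresolved`; discordant families failing the tests are `conflicting`;
transfers onto the branch ancestral to the whole focal clade are flagged
`pre_diversification` rather than called.

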