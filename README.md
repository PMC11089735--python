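# topowindow

Sliding-window tree discordance and ancient-introgression analysis for
small multi-species genome alignments, with a
multispecies-coalescent-plus-pulse simulator that makes every stage of the
pipeline verifiable on data with known truth.

## The problem

Genome-scale phylogenies disagree window by window.  Two forces produce
discordant window trees and they leave different footprints:

* **Incomplete lineage sorting (ILS)** — retention of ancestral
  polymorphism across rapid speciations.  For a rooted triple separated by
  an internal branch of `T` coalescent units, each discordant topology
  occurs with probability `(1/3)·e^(-T)`; discordant windows scatter
  almost independently along the genome.
* **Introgression** — hybridization transfers haplotype blocks.
  Introgressed windows share one alternative topology, form *long runs* of
  consecutive windows, show an excess of ABBA over BABA site patterns
  (`D = (ABBA − BABA)/(ABBA + BABA) > 0` with the donor as P3), and have
  *reduced* recipient–donor genetic distances.

`topowindow` implements that contrast as a pipeline over a six-lineage
focal system (outgroup; a two-taxon donor clade; a two-taxon cherry; a
recipient): window splitting and quality filters (gap ratio > 10%,
per-sequence composition chi-square at α = 0.05, a long-branch screen),
neighbor-joining window trees, exhaustive rooted-topology classification
(15 classes when the donor pair is constrained), consecutive-window run
statistics, the D-statistic with a weighted block jackknife, block
permutation tests on MRCA distances (295-tree blocks, 10,000 draws), and a
percentile/run-length region caller (introgressed: runs > 10 of the
introgression topology in the lowest 1% of recipient–donor distances;
resistant: runs > 5 of the species topology in the highest 1%) with gene
overlap.

Because no real genomes ship with the package, the `synthetic` module is a
first-class component: a structured-coalescent simulator with one timed,
unidirectional introgression pulse (donor clade → recipient, proportion γ
of the genome), geometric run-sharing of gene trees across windows, and
Jukes–Cantor sequence evolution, so the whole pipeline closes on data
whose truth is recorded.

## Worked example

```bash
python analysis/01_simulate.py      # 3 chromosomes x 1,500 10-kb windows,
                                    # gamma = 0.3, two planted runs
python analysis/03_topology_runs.py
python analysis/04_introgression.py
python analysis/05_species_tree.py
```

Output from this run (seed 2024 fixed in the scripts):

```
t1: 1405 windows, 91.2% in runs >= 2, 12.2% in runs >= 10
t2: 1351 windows, 95.4% in runs >= 2, 64.9% in runs >= 10
t3:  231 windows, 79.7% in runs >= 2,  0.0% in runs >= 10

D = 0.6831 +- 0.0302  (Z = 22.6, 45 blocks, ABBA 28561 / BABA 5377)
longest t2 run: 66 windows on chr2; observed MRCA distance 2.576 vs null
mean 1.621; permutation p = 9.999e-05 (66-tree blocks, 10,000 draws)
2 introgressed and 0 resistant calls; planted-base recovery 100.0%

winning topology: t1
```

Reading it: `t2` (donor clade grouped with the recipient) is the
introgression topology — it concentrates in long runs (64.9% of its
windows sit in runs of ≥ 10 identical consecutive topologies) while the
ILS topology `t3` never does; the strongly positive D confirms gene flow;
the recipient's MRCA distance to the cherry is *increased* inside the
longest t2 run (permutation p < 10⁻⁴), the signature that the flow ran
donor → recipient; the region caller recovers all planted introgressed
bases; and the exhaustive triplet-score species tree still finds the true
species topology t1 at this γ.  The same commands are available as a CLI
(`topowindow simulate|split|filter|trees|classify|runscan|dstat|permtest|`
`callregions|speciestree|pipeline`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-derives the package's headline combinatorial fact from scratch: it
enumerates every rooted binary topology on the six focal taxa with the
outgroup fixed as root and the donor pair constrained to a clade, audits
the catalogue by classifying one generated tree per class plus 200 random
trees, and reports the class count.

## Layout

```
src/topowindow/     library: treeio, topology, windows, runscan,
                    introgression, speciestree, synthetic, pipeline, cli
analysis/           numbered narrative drivers writing to results/
tests/              pytest suite; test_acceptance.py holds the seeded
                    calibration experiments
docs/methods.md     model assumptions, parameter choices, limitations
```
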