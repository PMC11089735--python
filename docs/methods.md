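# Methods

This note records the models, parameter choices and numerical conventions
behind `topowindow`, and what the synthetic world does and does not
establish.

## Focal system and topology catalogue

All analyses run on a six-taxon focal system with fixed roles: an outgroup
used only for rooting; a two-taxon **donor clade**; a two-taxon
**cherry**; and a **recipient** lineage.  Window trees are reduced to
rooted leaf-labelled topologies by implicit pruning to the focal taxa,
rooting on the outgroup edge, stripping branch lengths, and recursively
sorting children by the smallest leaf label they subtend; the resulting
canonical string is the class identifier.  With the donor pair constrained
to a clade the catalogue has exactly 15 classes (the (2n−3)!! = 15 rooted
shapes on the 4 remaining units); trees that split the constrained pair
are classed `other`, multifurcating trees `unresolved`.  Three classes
carry aliases: `t1` (species topology: cherry with recipient), `t2`
(introgression topology: donor clade with recipient) and `t3` (donor clade
with cherry).  Aliases bind to canonical strings through a YAML config so
other taxon systems can reuse the machinery unchanged.

Rooted-topology enumeration works by stepwise leaf insertion with
constrained clades collapsed to meta-leaves and re-expanded, and is
exercised against the (2n−3)!! closed form for 3–7 free lineages.

## The synthetic world

### Gene trees

Gene trees are drawn from the multispecies coalescent embedded in an
ultrametric species tree in coalescent units.  Default heights: cherry
and donor-pair coalescences at 0.5; recipient joins the cherry at 1.0;
donors join at 2.0 (internal branch `T = 1`, so each discordant rooted
topology at the focal node has ILS probability `(1/3)e^(-1) ≈ 0.1226`);
outgroup at 5.0.  Pairwise coalescence proceeds at rate `C(k,2)/size` per
branch; all branches have relative size 1 except the donor clade
(size 0.1), which keeps the donor pair monophyletic in essentially every
gene tree — emulating donor species whose divergence is deep relative to
their effective sizes, and matching the empirical situation where almost
no window tree splits the donor pair.

The introgression pulse is a single mass-migration event: at time 0.8
(inside both the recipient's terminal branch and the donor stem) the
recipient's still-uncoalesced lineage moves into the donor-stem population
with probability γ.  Gene flow between extant lineages requires both
populations to exist at the pulse time, so the config validator enforces
that the pulse is strictly younger than the recipient's split from its
sister and falls inside the donor clade's stem span; configs outside that
window are rejected.  The simulator is cross-checked against msprime under
the identical demography in the test suite.

### Genome layout and linkage

The downstream analysis consumes *runs* of identical window topologies,
not recombination breakpoints, so linkage is modelled directly at that
level: each run draws one gene tree and a geometric length (memoryless,
mean 2 windows for species-path trees, mean 8 for pulse-derived trees —
introgressed haplotype blocks are longer because the donor haplotype
entered recently relative to the speciations).  Run provenance is drawn
with a length-adjusted probability so that the *window* fraction carrying
pulse history equals γ; trees are then drawn conditioned on provenance
(the reroute Bernoulli is independent of the coalescent, so the
conditional draws are exact mixture components).  Planted runs — used for
end-to-end truth recovery — stamp a forced-pulse tree over a chosen window
range and may shrink all its branch lengths (`tree_scale`, default 0.3 in
the analysis scripts), modelling a low-divergence introgressed haplotype
whose recipient–donor distance is unambiguously in the genome-wide low
tail; every plant is recorded in a truth table.

### Sequences

Sequences evolve by Jukes–Cantor from a uniform random root: substitution
events per branch are Poisson(length × branch × scale) with each event
moving the site to one of the other three bases, so multiple hits saturate
toward p = 3/4 exactly as JC prescribes.  The default scale 0.01
substitutions/site per coalescent unit puts ingroup divergences near 2%
and outgroup divergence near 10% — typical for congeneric birds against a
confamilial outgroup at fourfold-degenerate sites.

### What a green test does not establish

The generator emulates the *statistical structure* the analysis assumes —
ILS at calibrated rates, one pulse, linkage runs, JC sequences.  It does
not emulate recombination-explicit ancestry, rate variation across sites
or lineages, selection, gaps/missing data beyond what the filters are
tested on, or alignment error.  Green calibration tests therefore
establish internal correctness of the estimators under the stated model,
not robustness to real-data pathologies.

## Pipeline conventions and numerical choices

* **Informative column**: ≥ 2 non-gap, non-N characters; windows under 30
  informative columns are dropped at splitting.
* **Gap ratio**: gap characters over all characters (taxa × columns);
  windows fail on strictly > 0.10.
* **Composition test**: per sequence, X² over A/C/G/T against pooled
  frequencies over all sequences (the tested one included, mirroring the
  cited tool's behaviour), df = 3, fail at p < 0.05; expected counts
  floored at 1e-6 of the sequence length.  The whole window is discarded
  if any sequence fails.  The pipeline applies the test to windows
  ≤ 10 kb, matching the workflow it reproduces (larger windows went
  through a different inference path there).
* **4D sites**: a codon column is emitted (third position) when positions
  1–2 are ungapped, strictly conserved across taxa, and form one of the
  eight fourfold-degenerate prefixes of the standard code.  Strict
  conservation is the common concatenated-phylogenomics convention.
* **NJ trees**: JC distances on pairwise-complete columns; saturated pairs
  (p ≥ 3/4) are capped at 5.0 and flag the window; negative NJ branches
  are clamped to zero (scikit-bio backend).  On 50-kb low-rate windows NJ
  recovers the generating topology in ≥ 95% of windows (tested); on 10-kb
  windows agreement drops to ~2/3 (analysis script 02) because short
  coalescent internal edges carry few substitutions — the same reason the
  reproduced workflow used likelihood methods and why topology *frequency*
  summaries, not single windows, carry the inference.
* **Long-branch screen**: a tree is flagged when any taxon's root-to-tip
  length exceeds 5× that taxon's median across trees; with < 20 trees the
  baseline is untrusted and nothing is flagged.  This is a deliberately
  simplified stand-in for published outlier-branch trimmers.
* **Runs**: maximal blocks of equal class over the ordinal sequence of
  retained windows; genomic gaps from filtered windows are ignored, but
  runs never cross chromosomes (linkage cannot).
* **D-statistic**: `D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA)` over blocks;
  the standard error is the weighted delete-one block jackknife (Busing
  et al. 1999 form, block weight = its pattern total), `Z = D/SE`.
  Jackknife calibration was checked against the empirical sd of D on
  i.i.d. blocks.  Because linked sites within a window share one
  genealogy, per-window pattern counts are heavy-tailed; blocks must
  aggregate many windows (the calibration experiments use 40-window
  blocks) for Z to be near-normal.  Default jackknife block: 5 Mb on real
  coordinates.
* **Permutation test**: the observed statistic is a mean over a window
  set; the null is the same mean over uniformly placed *contiguous* blocks
  of background windows (preserving linkage), default 295 trees × 10,000
  draws; `p = (1 + #{null ≥ obs})/(1 + n_perm)` (add-one, never zero;
  with 10,000 draws the minimum is just under 10⁻⁴).  The directional
  "increased" alternative is the default, with `less` and `two-sided`
  options.
* **Region calls**: introgressed = run of `t2` strictly longer than 10
  whose mean recipient–donor distance is strictly below the genome-wide
  1% per-window quantile; resistant = run of `t1` strictly longer than 5
  with mean strictly above the 99% quantile.  Strict inequalities make the
  all-equal degenerate track yield zero calls.  Quantiles are genome-wide
  (not per-chromosome).  Distances are computed per window and averaged
  over the run; both ingredients are exposed so either reading of
  "lowest 1% of average distances" can be audited.  Adjacent qualifying
  runs separated by one non-qualifying window are not merged.
* **Ties in the species-tree search** break by lexicographic canonical
  string.  Triplet (not quartet) agreement is scored because all trees are
  outgroup-rooted; for ranking on rooted data the two are equivalent and
  triplets are simpler.
* Patristic distances are rooting-invariant, so whether distance
  extraction runs on rooted or unrooted trees is immaterial; we compute on
  rooted trees.
* Branch lengths serialise at up to 10 significant digits; length
  comparisons in tests use absolute tolerance 1e-9.

## Design decisions that were genuinely open

* The run-length model is geometric rather than a sequential coalescent:
  the analysis consumes runs, and geometric is the simplest generator with
  a controllable mean.
* One unidirectional pulse only; multiple or bidirectional pulses are out
  of scope.
* The γ = 0 "control" assertion in the end-to-end test checks for zero
  *introgressed* calls; resistant calls can arise by chance in any
  finite ILS genome and are not part of the planted-truth contrast.
* The consecutive-window reference arithmetic uses the printed totals
  as-is; the two slightly different published tree-1 totals (15,606 vs
  15,607) are not reconciled — the run-fraction check uses the 15,607
  denominator and the permutation background convention uses 295-of-15,606.

## Known limitations

* The exhaustive species-tree search is limited to ≤ 8 ingroup taxa
  (catalogue growth is (2n−3)!!).
* MAF input is not parsed; reference-anchored alignments enter as
  per-chromosome or per-window multi-FASTA.
* The composition test, long-branch screen and 4D extraction are
  simplified stand-ins for the external tools they replace; they are
  specified and tested in their own right, not as re-implementations.
* Z calibration of the D-statistic degrades when jackknife blocks contain
  few windows (heavy-tailed per-window counts); keep ≥ ~40 windows per
  block.
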