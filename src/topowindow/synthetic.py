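"""Multispecies-coalescent synthetic genomes with one introgression pulse.

The generator stands in for unavailable real genomes.  It draws per-window
gene trees under the multispecies coalescent (MSC) embedded in a species
tree given in coalescent units, with a single timed, unidirectional
introgression pulse: with probability ``gamma`` the recipient's sampled
lineage is rerouted into the donor-clade population at the pulse time and
coalesces there first, which is what produces the donor-with-recipient
window topology in excess of its incomplete-lineage-sorting expectation.

Linkage is modelled at the level the downstream analysis consumes: adjacent
windows share a gene tree in geometrically distributed runs (memoryless,
with a controllable mean), with a separately configurable — typically
longer — mean for pulse-derived runs, so highly consecutive introgressed
blocks can arise or be planted deliberately.  Sequences evolve on each
window's tree under Jukes–Cantor with Poisson substitution counts per
branch.

Every draw flows through one :class:`numpy.random.Generator`; a fixed seed
reproduces the dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import treeio
from .windows import AlignmentWindow

__all__ = [
    "Pulse",
    "PlantedRun",
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "three_taxon_config",
    "simulate_gene_tree",
    "layout_genome",
    "evolve_sequences",
    "emit_site_patterns",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Pulse:
    """One unidirectional introgression event.

    ``time`` (coalescent units before present) must fall inside the
    recipient's terminal branch and inside the donor clade's stem branch so
    that both populations exist when the lineage is rerouted.
    """

    donor: tuple[str, ...]
    recipient: str
    time: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.time <= 0:
            raise ValueError("pulse time must be positive")


@dataclass(frozen=True)
class PlantedRun:
    """A deliberately placed run of identical pulse-derived windows.

    ``tree_scale`` < 1 shrinks every branch of the planted gene tree,
    modelling a low-divergence introgressed haplotype whose
    recipient–donor distance is unambiguously in the genome-wide low tail.
    """

    chrom: int
    start_window: int
    n_windows: int
    tree_scale: float = 1.0


@dataclass
class SimulationConfig:
    species_newick: str
    pulse: Pulse | None
    n_chromosomes: int = 2
    windows_per_chromosome: int = 500
    window_size: int = 10_000
    mean_run_length: float = 2.0
    pulse_mean_run_length: float = 8.0
    mutation_scale: float = 0.01  # substitutions/site per coalescent unit
    alignment_length: int = 1_000  # evolved columns per window
    genes_per_chromosome: int = 40
    planted_runs: tuple[PlantedRun, ...] = ()
    #: relative effective size per species-tree branch, keyed by the clade's
    #: leaf labels (pairwise coalescence rate is 1/size); unlisted branches
    #: have size 1.  A small donor-clade size keeps the donor pair
    #: monophyletic in gene trees, emulating long-sorted donor species.
    population_sizes: tuple[tuple[tuple[str, ...], float], ...] = ()

    def __post_init__(self) -> None:
        if self.mean_run_length < 1 or self.pulse_mean_run_length < 1:
            raise ValueError("mean run lengths must be >= 1")

    @property
    def taxa(self) -> list[str]:
        tree = treeio.parse_newick(self.species_newick)
        return treeio.leaf_labels(tree)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        """Rehydrate a config written by :meth:`SyntheticDataset.write`."""
        data = json.loads(Path(path).read_text())
        data.pop("seed_state", None)
        if data.get("pulse") is not None:
            p = data["pulse"]
            data["pulse"] = Pulse(
                donor=tuple(p["donor"]), recipient=p["recipient"],
                time=p["time"], gamma=p["gamma"],
            )
        data["planted_runs"] = tuple(
            PlantedRun(**pr) for pr in data.get("planted_runs", ())
        )
        data["population_sizes"] = tuple(
            (tuple(labels), size)
            for labels, size in data.get("population_sizes", ())
        )
        return cls(**data)


def default_config(
    gamma: float = 0.3, internal_branch: float = 1.0, **overrides
) -> SimulationConfig:
    """The six-lineage default world: an outgroup, a two-taxon donor clade,
    two single lineages forming a cherry, and a recipient.

    Heights are in coalescent units; ``internal_branch`` is the branch
    between the (cherry + recipient) ancestor and its join with the donor
    clade.  The default 1.0 is the heavy-ILS regime in which each
    discordant rooted topology has probability (1/3)e^{-1} without gene
    flow; shorter values push discordance toward the anomaly zone.  The
    pulse (donor clade -> recipient, time 0.8) crosses from the donor stem
    into the recipient's terminal branch.
    """
    T = float(internal_branch)
    root = 1.0 + T
    newick = (
        f"(Outgroup:5.0,((DonorA:0.5,DonorB:0.5):{root - 0.5},"
        f"((TealX:0.5,ShovelerX:0.5):0.5,RecipientP:1.0):{T}):{5.0 - root});"
    )
    pulse = Pulse(
        donor=("DonorA", "DonorB"), recipient="RecipientP", time=0.8,
        gamma=gamma,
    )
    overrides.setdefault(
        "population_sizes", ((("DonorA", "DonorB"), 0.1),)
    )
    return SimulationConfig(species_newick=newick, pulse=pulse, **overrides)


def three_taxon_config(T: float = 1.0, **overrides) -> SimulationConfig:
    """Outgroup + rooted triple with internal branch ``T``: the textbook MSC
    calibration system (concordant 1-(2/3)e^{-T}, each discordant
    (1/3)e^{-T})."""
    newick = (
        f"(Outgroup:8.0,((B:1.0,C:1.0):{T},A:{1.0 + T}):{7.0 - T});"
    )
    overrides.setdefault("genes_per_chromosome", 0)
    return SimulationConfig(species_newick=newick, pulse=None, **overrides)


# ---------------------------------------------------------------------------
# Species-tree scaffolding

class _SpeciesModel:
    """Preprocessed species tree: node ages, children, pulse anchors."""

    def __init__(self, cfg: SimulationConfig):
        self.tree = treeio.parse_newick(cfg.species_newick)
        self.ages: dict[int, float] = {}
        self.parent: dict[int, int | None] = {}
        self.children: dict[int, list] = {}
        self.label: dict[int, str | None] = {}
        self.nodes: list = []
        # ages from leaf depths (leaves at 0); require ultrametric input
        depth_to_root: dict[int, float] = {}
        for nd in self.tree.preorder_node_iter():
            up = 0.0 if nd.parent_node is None else (
                depth_to_root[id(nd.parent_node)] + (nd.edge.length or 0.0)
            )
            depth_to_root[id(nd)] = up
        total = max(
            depth_to_root[id(lf)] for lf in self.tree.leaf_node_iter()
        )
        for lf in self.tree.leaf_node_iter():
            if abs(depth_to_root[id(lf)] - total) > 1e-9:
                raise ValueError(
                    "species tree must be ultrametric in coalescent units"
                )
        for nd in self.tree.preorder_node_iter():
            self.nodes.append(nd)
            self.ages[id(nd)] = total - depth_to_root[id(nd)]
            self.parent[id(nd)] = (
                None if nd.parent_node is None else id(nd.parent_node)
            )
            self.children[id(nd)] = [id(c) for c in nd.child_nodes()]
            self.label[id(nd)] = nd.taxon.label if nd.taxon else None
        self.leaf_pop = {
            self.label[id(lf)]: id(lf) for lf in self.tree.leaf_node_iter()
        }
        self.root = id(self.tree.seed_node)
        self.pop_size: dict[int, float] = {}
        clade_of = {
            id(nd): frozenset(
                lf.taxon.label for lf in nd.leaf_iter()
            )
            for nd in self.tree.preorder_node_iter()
        }
        for labels, size in cfg.population_sizes:
            want = frozenset(labels)
            hits = [nid for nid, cl in clade_of.items() if cl == want]
            if not hits:
                raise ValueError(
                    f"{sorted(want)} is not a clade of the species tree"
                )
            if size <= 0:
                raise ValueError("population sizes must be positive")
            self.pop_size[hits[0]] = float(size)

    def clade_node(self, labels: Sequence[str]) -> int:
        node = treeio.mrca_node(self.tree, list(labels))
        below = {
            lf.taxon.label for lf in node.leaf_iter()
        }
        if below != set(labels):
            raise ValueError(
                f"{sorted(labels)} is not a clade of the species tree"
            )
        return id(node)

    def validate_pulse(self, pulse: Pulse) -> tuple[int, int]:
        """Return (recipient population, donor population) at pulse time."""
        rec = self.leaf_pop[pulse.recipient]
        rec_top = self.ages[self.parent[rec]]
        if not pulse.time < rec_top:
            raise ValueError(
                "pulse time must predate the recipient's split from its "
                f"sister (branch ends at {rec_top})"
            )
        don = self.clade_node(pulse.donor)
        don_base = self.ages[don]
        don_top = (
            np.inf if self.parent[don] is None else self.ages[self.parent[don]]
        )
        if not don_base <= pulse.time < don_top:
            raise ValueError(
                "pulse time must fall inside the donor clade's stem branch "
                f"[{don_base}, {don_top})"
            )
        return rec, don


class _GN:
    __slots__ = ("label", "age", "children")

    def __init__(self, label, age, children=()):
        self.label = label
        self.age = age
        self.children = list(children)


def _to_dendropy(root: _GN, taxa: Sequence[str]) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(list(taxa))
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(gn: _GN, parent_age: float | None) -> dendropy.Node:
        node = dendropy.Node()
        if not gn.children:
            node.taxon = ns.get_taxon(gn.label)
        for c in gn.children:
            node.add_child(build(c, gn.age))
        if parent_age is not None:
            node.edge.length = parent_age - gn.age
        return node

    tree.seed_node = build(root, None)
    return tree


def simulate_gene_tree(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    model: _SpeciesModel | None = None,
    force_pulse: bool = False,
    suppress_pulse: bool = False,
) -> tuple[dendropy.Tree, str]:
    """One MSC gene tree (one sample per species) and its provenance.

    Lineages coalesce within species-tree branches at rate C(k,2)/size per
    coalescent unit; at the pulse time the recipient's (still uncoalesced)
    lineage moves to the donor population with probability ``gamma``.
    Provenance is ``"pulse"`` if the rerouting happened, else ``"species"``.
    ``force_pulse`` / ``suppress_pulse`` condition the draw on the reroute
    outcome (the Bernoulli is independent of the coalescent, so the
    conditional distributions are exact mixture components).
    """
    if force_pulse and suppress_pulse:
        raise ValueError("cannot both force and suppress the pulse")
    if model is None:
        model = _SpeciesModel(cfg)
    pops: dict[int, list[_GN]] = {
        pop: [_GN(lab, 0.0)] for lab, pop in model.leaf_pop.items()
    }
    events: list[tuple[float, str, int]] = []
    for nid in model.nodes:
        i = id(nid)
        if model.children[i]:
            events.append((model.ages[i], "join", i))
    provenance = "species"
    pulse_pops = None
    pulse_active = (
        cfg.pulse is not None
        and not suppress_pulse
        and (cfg.pulse.gamma > 0 or force_pulse)
    )
    if pulse_active:
        pulse_pops = model.validate_pulse(cfg.pulse)
        events.append((cfg.pulse.time, "pulse", -1))
    events.sort(key=lambda e: (e[0], e[1] != "pulse"))

    def coalesce_in(pop: int, t_from: float, t_to: float) -> None:
        lineages = pops.get(pop)
        if not lineages:
            return
        size = model.pop_size.get(pop, 1.0)
        t = t_from
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / (2.0 * size)
            t = t + rng.exponential(1.0 / rate)
            if t >= t_to:
                return
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            merged = _GN(None, t, (a, b))
            lineages[:] = [
                x for x in lineages if x is not a and x is not b
            ] + [merged]

    t_now = 0.0
    for t_ev, kind, nid in events:
        for pop in list(pops):
            coalesce_in(pop, t_now, t_ev)
        if kind == "pulse":
            rec_pop, don_pop = pulse_pops
            movers = pops.get(rec_pop, [])
            if movers and (force_pulse or rng.random() < cfg.pulse.gamma):
                pops.setdefault(don_pop, []).extend(movers)
                pops[rec_pop] = []
                provenance = "pulse"
        else:
            gathered: list[_GN] = []
            for child in model.children[nid]:
                gathered.extend(pops.pop(child, []))
            pops.setdefault(nid, []).extend(gathered)
        t_now = t_ev
    root_lineages = pops[model.root]
    coalesce_in(model.root, t_now, np.inf)
    (root,) = root_lineages
    return _to_dendropy(root, cfg.taxa), provenance


# ---------------------------------------------------------------------------
# Genome layout

def _scale_tree(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


@dataclass
class SyntheticDataset:
    """Windows, gene trees, provenance labels and the planted-run truth set."""

    config: SimulationConfig
    windows: pd.DataFrame  # chrom, start, end
    trees: list[dendropy.Tree]
    provenance: list[str]
    truth: pd.DataFrame  # chrom, start, end, kind, n_windows
    genes: pd.DataFrame  # chrom, start, end, name
    seed_state: str = ""

    def __len__(self) -> int:
        return len(self.trees)

    def window_trees(self) -> list[treeio.WindowTree]:
        return [
            treeio.WindowTree(
                chrom=r.chrom, start=int(r.start), end=int(r.end),
                tree=self.trees[i],
            )
            for i, r in enumerate(self.windows.itertuples(index=False))
        ]

    def alignments(
        self, rng: np.random.Generator, length: int | None = None
    ) -> list[AlignmentWindow]:
        """Evolve one alignment per window on that window's gene tree."""
        n = length or self.config.alignment_length
        out = []
        for i, r in enumerate(self.windows.itertuples(index=False)):
            aln = evolve_sequences(
                self.trees[i], n, rng, scale=self.config.mutation_scale
            )
            out.append(
                AlignmentWindow(
                    chrom=r.chrom, start=int(r.start), end=int(r.end),
                    seqs=aln,
                )
            )
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        treeio.write_tree_file(
            self.window_trees(),
            outdir / "window_trees.nwk",
            outdir / "window_trees.bed",
        )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.genes.to_csv(
            outdir / "genes.bed", sep="\t", index=False, header=False
        )
        with open(outdir / "provenance.tsv", "w") as fh:
            fh.write("window\tprovenance\n")
            for i, p in enumerate(self.provenance):
                fh.write(f"{i}\t{p}\n")
        meta = asdict(self.config)
        meta["seed_state"] = self.seed_state
        (outdir / "config.json").write_text(json.dumps(meta, indent=2))


def _random_genes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    chrom_len = cfg.windows_per_chromosome * cfg.window_size
    for c in range(cfg.n_chromosomes):
        n = cfg.genes_per_chromosome
        if n == 0:
            continue
        starts = np.sort(
            rng.choice(max(chrom_len - 20_000, n), size=n, replace=False)
        )
        for g, s in enumerate(starts):
            length = int(rng.integers(2_000, 20_000))
            rows.append(
                (f"chr{c + 1}", int(s), min(int(s) + length, chrom_len),
                 f"gene_c{c + 1}_{g}")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def layout_genome(
    cfg: SimulationConfig, rng: np.random.Generator
) -> SyntheticDataset:
    """Tile chromosomes with windows and assign run-shared gene trees.

    Each run draws one gene tree; its length is geometric with mean
    ``mean_run_length`` (species-path trees) or ``pulse_mean_run_length``
    (pulse-derived trees).  Run provenance is drawn with a length-adjusted
    probability so that the *window* (genome) fraction with pulse history
    equals gamma even though pulse runs are longer; the tree for each run
    is then drawn conditioned on that provenance.  Planted runs are stamped
    on afterwards and recorded in the truth set.
    """
    model = _SpeciesModel(cfg)
    ws = cfg.window_size
    gamma = cfg.pulse.gamma if cfg.pulse is not None else 0.0
    l_b, l_p = cfg.mean_run_length, cfg.pulse_mean_run_length
    q_pulse = (
        gamma * l_b / (gamma * l_b + (1.0 - gamma) * l_p)
        if gamma > 0 else 0.0
    )
    chroms, starts = [], []
    trees: list[dendropy.Tree] = []
    provenance: list[str] = []
    for c in range(cfg.n_chromosomes):
        name = f"chr{c + 1}"
        filled = 0
        while filled < cfg.windows_per_chromosome:
            want_pulse = bool(rng.random() < q_pulse)
            tree, prov = simulate_gene_tree(
                cfg, rng, model=model,
                force_pulse=want_pulse, suppress_pulse=not want_pulse,
            )
            mean = cfg.pulse_mean_run_length if prov == "pulse" \
                else cfg.mean_run_length
            run_len = int(rng.geometric(1.0 / mean))
            run_len = min(run_len, cfg.windows_per_chromosome - filled)
            for _ in range(run_len):
                chroms.append(name)
                starts.append(filled * ws)
                trees.append(tree)
                provenance.append(prov)
                filled += 1
    windows = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": [s + ws for s in starts],
        }
    )
    truth_rows = []
    offsets = {
        f"chr{c + 1}": c * cfg.windows_per_chromosome
        for c in range(cfg.n_chromosomes)
    }
    for planted in cfg.planted_runs:
        name = f"chr{planted.chrom + 1}"
        if planted.start_window + planted.n_windows > cfg.windows_per_chromosome:
            raise ValueError("planted run exceeds chromosome length")
        tree, _ = simulate_gene_tree(cfg, rng, model=model, force_pulse=True)
        if planted.tree_scale != 1.0:
            tree = _scale_tree(tree, planted.tree_scale)
        base = offsets[name] + planted.start_window
        for k in range(planted.n_windows):
            trees[base + k] = tree
            provenance[base + k] = "planted_pulse"
        truth_rows.append(
            (
                name,
                planted.start_window * ws,
                (planted.start_window + planted.n_windows) * ws,
                "planted_pulse",
                planted.n_windows,
            )
        )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "kind", "n_windows"]
    )
    genes = _random_genes(cfg, rng)
    return SyntheticDataset(
        config=cfg,
        windows=windows,
        trees=trees,
        provenance=provenance,
        truth=truth,
        genes=genes,
        seed_state=str(rng.bit_generator.state.get("state", "")),
    )


# ---------------------------------------------------------------------------
# Sequence evolution and site patterns

def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    rng: np.random.Generator,
    scale: float = 0.01,
) -> dict[str, str]:
    """Jukes–Cantor evolution from a uniform random root sequence.

    Substitution events per branch are Poisson(length x branch x scale);
    each event moves the hit site to one of the three other bases, so
    multiple hits saturate toward p = 3/4 exactly as JC prescribes.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
    out: dict[str, str] = {}

    def walk(node: dendropy.Node, seq: np.ndarray) -> None:
        if node.parent_node is not None:
            b = node.edge.length or 0.0
            n_events = rng.poisson(length * b * scale)
            if n_events:
                seq = seq.copy()
                sites = rng.integers(0, length, size=n_events)
                shifts = rng.integers(1, 4, size=n_events, dtype=np.int8)
                for s, sh in zip(sites, shifts):
                    seq[s] = (seq[s] + sh) % 4
        if node.is_leaf():
            out[node.taxon.label] = (
                _BASES[seq].tobytes().decode("ascii")
            )
            return
        for child in node.child_nodes():
            walk(child, seq)

    walk(tree.seed_node, root_seq)
    return out


def count_patterns(
    seqs: dict[str, str], quartet: Sequence[str]
) -> tuple[int, int]:
    """ABBA and BABA column counts for an ordered quartet (P1, P2, P3, Out).

    A column counts when all four states are unambiguous bases, the
    outgroup carries the ancestral state, and the derived state is shared by
    (P2, P3) [ABBA] or (P1, P3) [BABA].
    """
    missing = [q for q in quartet if q not in seqs]
    if missing:
        raise KeyError(f"quartet taxa missing from alignment: {missing}")
    arrs = [
        np.frombuffer(seqs[q].encode("ascii"), dtype="S1") for q in quartet
    ]
    p1, p2, p3, out = arrs
    valid = np.ones(len(p1), dtype=bool)
    for a in arrs:
        valid &= np.isin(a, _BASES)
    abba = valid & (p1 == out) & (p2 == p3) & (p2 != out)
    baba = valid & (p2 == out) & (p1 == p3) & (p1 != out)
    return int(abba.sum()), int(baba.sum())


def emit_site_patterns(
    alignments: Sequence[AlignmentWindow],
    quartet: Sequence[str],
    block: int = 5_000_000,
) -> pd.DataFrame:
    """Per-block ABBA/BABA counts over window alignments.

    Windows are grouped into fixed ``block``-bp genomic blocks per
    chromosome (the jackknife unit downstream).
    """
    rows: dict[tuple[str, int], list[int]] = {}
    for w in alignments:
        key = (w.chrom, (w.start // block) * block)
        a, b = count_patterns(w.seqs, quartet)
        acc = rows.setdefault(key, [0, 0])
        acc[0] += a
        acc[1] += b
    data = [
        (chrom, bstart, bstart + block, ab[0], ab[1])
        for (chrom, bstart), ab in sorted(rows.items())
    ]
    return pd.DataFrame(
        data, columns=["chrom", "start", "end", "n_abba", "n_baba"]
    )
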