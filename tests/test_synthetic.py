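"""The coalescent-with-pulse generator: calibration against closed forms,
layout/linkage behaviour, sequence evolution, and site-pattern emission."""

import math

import numpy as np
import pytest

from topowindow import synthetic as syn
from topowindow import topology as tp
from topowindow import treeio
from topowindow.synthetic import _SpeciesModel
from topowindow.treeio import TaxonSet


def topology_frequencies(cfg, rng, taxa, n):
    model = _SpeciesModel(cfg)
    cat = tp.TopologyCatalogue.build(taxa)
    counts: dict[str, int] = {}
    pulses = 0
    for _ in range(n):
        t, prov = syn.simulate_gene_tree(cfg, rng, model=model)
        k = cat.classify(t).canonical
        counts[k] = counts.get(k, 0) + 1
        pulses += prov == "pulse"
    return {k: v / n for k, v in counts.items()}, pulses / n


class TestGeneTreeSimulation:
    @pytest.mark.parametrize("T", [0.5, 2.0])
    def test_msc_closed_form(self, T):
        """Discordant rooted-triple frequencies match (1/3)e^{-T} within
        3 Monte-Carlo SE (the T=1 case runs at larger n in the acceptance
        suite)."""
        n = 40_000
        rng = np.random.default_rng(1000 + int(10 * T))
        cfg = syn.three_taxon_config(T=T)
        taxa = TaxonSet(labels=("Outgroup", "A", "B", "C"),
                        outgroup="Outgroup")
        freqs, _ = topology_frequencies(cfg, rng, taxa, n)
        p_disc = math.exp(-T) / 3
        se = math.sqrt(p_disc * (1 - p_disc) / n)
        disc = [v for k, v in freqs.items() if "(B,C)" not in k]
        assert len(disc) == 2
        for f in disc:
            assert abs(f - p_disc) < 3 * se

    def test_no_ils_limit(self, rng):
        """A long internal branch gives near-total concordance."""
        cfg = syn.three_taxon_config(T=6.0)
        taxa = TaxonSet(labels=("Outgroup", "A", "B", "C"),
                        outgroup="Outgroup")
        freqs, _ = topology_frequencies(cfg, rng, taxa, 2_000)
        concordant = [v for k, v in freqs.items() if "(B,C)" in k]
        assert sum(concordant) > 0.99

    def test_full_replacement_limit(self, rng, synthetic_taxa):
        """gamma = 1 reroutes every recipient lineage: the pulse topology
        dominates and every tree is pulse-provenanced."""
        cfg = syn.default_config(gamma=1.0)
        freqs, pulse_frac = topology_frequencies(
            cfg, rng, synthetic_taxa, 2_000
        )
        assert pulse_frac == 1.0
        from topowindow.config import alias_bindings

        t2 = alias_bindings()["t2"]
        assert freqs.get(t2, 0.0) > 0.5

    def test_pulse_excess_monotone_in_gamma(self, rng, synthetic_taxa):
        """The pulse-topology frequency exceeds its ILS-only expectation
        and the excess grows with gamma."""
        from topowindow.config import alias_bindings

        t2 = alias_bindings()["t2"]
        n = 4_000
        freqs0, _ = topology_frequencies(
            syn.default_config(gamma=0.0), rng, synthetic_taxa, n
        )
        base = freqs0.get(t2, 0.0)
        excesses = []
        for gamma in (0.1, 0.2, 0.4):
            freqs, pulse_frac = topology_frequencies(
                syn.default_config(gamma=gamma), rng, synthetic_taxa, n
            )
            assert abs(pulse_frac - gamma) < 3 * math.sqrt(gamma / n) + 0.01
            excesses.append(freqs.get(t2, 0.0) - base)
        assert all(e > 0 for e in excesses)
        assert excesses == sorted(excesses)

    def test_pulse_time_validation(self):
        cfg = syn.default_config(gamma=0.2)
        bad = syn.SimulationConfig(
            species_newick=cfg.species_newick,
            pulse=syn.Pulse(
                donor=("DonorA", "DonorB"), recipient="RecipientP",
                time=3.0, gamma=0.2,  # older than the recipient's split
            ),
        )
        with pytest.raises(ValueError, match="pulse time"):
            _SpeciesModel(bad).validate_pulse(bad.pulse)

    def test_matches_msprime_cross_check(self, synthetic_taxa):
        """Independent oracle: msprime under the same species tree and
        pulse gives the same t1/t2 topology frequencies (3 SE)."""
        import msprime

        gamma = 0.3
        n = 4_000
        demography = msprime.Demography()
        for pop in ["Outgroup", "DonorA", "DonorB", "TealX", "ShovelerX",
                    "RecipientP", "DP", "TS", "TSR", "ING", "ROOT"]:
            # ploidy-1 time scale: pairwise coalescence rate 1/initial_size
            demography.add_population(
                name=pop, initial_size=0.1 if pop == "DP" else 1.0
            )
        demography.add_population_split(
            time=0.5, derived=["DonorA", "DonorB"], ancestral="DP")
        demography.add_population_split(
            time=0.5, derived=["TealX", "ShovelerX"], ancestral="TS")
        demography.add_population_split(
            time=1.0, derived=["TS", "RecipientP"], ancestral="TSR")
        demography.add_population_split(
            time=2.0, derived=["DP", "TSR"], ancestral="ING")
        demography.add_population_split(
            time=5.0, derived=["ING", "Outgroup"], ancestral="ROOT")
        demography.add_mass_migration(
            time=0.8, source="RecipientP", dest="DP", proportion=gamma)
        demography.sort_events()
        samples = {
            name: 1 for name in
            ["Outgroup", "DonorA", "DonorB", "TealX", "ShovelerX",
             "RecipientP"]
        }
        ts = msprime.sim_ancestry(
            samples=samples, demography=demography, ploidy=1,
            num_replicates=n, random_seed=7,
        )
        cat = tp.TopologyCatalogue.build(synthetic_taxa)
        id_to_name = None
        counts: dict[str, int] = {}
        for rep in ts:
            if id_to_name is None:
                id_to_name = {}
                for ind in rep.samples():
                    pop = rep.population(rep.node(ind).population)
                    id_to_name[ind] = pop.metadata["name"]
            newick = rep.first().as_newick(
                node_labels={k: v for k, v in id_to_name.items()}
            )
            tree = treeio.parse_newick(newick)
            key = cat.classify(tree).canonical
            counts[key] = counts.get(key, 0) + 1
        ms_freqs = {k: v / n for k, v in counts.items()}

        rng = np.random.default_rng(8)
        ours, _ = topology_frequencies(
            syn.default_config(gamma=gamma), rng, synthetic_taxa, n
        )
        from topowindow.config import alias_bindings

        for alias in ("t1", "t2", "t3"):
            canon = alias_bindings()[alias]
            a, b = ms_freqs.get(canon, 0.0), ours.get(canon, 0.0)
            se = math.sqrt(2 * max(a, b) * (1 - max(a, b)) / n)
            assert abs(a - b) < 3 * se + 0.01


class TestLayout:
    def test_independent_windows_mean_run_length(self, rng, synthetic_taxa):
        """With L = 1 every window draws its own tree; the observed mean
        topology-run length matches the renewal formula 1/(1 - sum f_c^2)."""
        from topowindow import runscan

        cfg = syn.default_config(
            gamma=0.0, n_chromosomes=1, windows_per_chromosome=4_000,
            mean_run_length=1.0, pulse_mean_run_length=1.0,
            genes_per_chromosome=0,
        )
        ds = syn.layout_genome(cfg, rng)
        cat = tp.TopologyCatalogue.build(synthetic_taxa)
        keys = [cat.classify(t).canonical for t in ds.trees]
        df = ds.windows.assign(class_key=keys)
        runs = runscan.detect_runs(df)
        mean_run = np.mean([r.length for r in runs])
        freqs = np.array([
            keys.count(k) for k in set(keys)
        ]) / len(keys)
        expect = 1.0 / (1.0 - (freqs ** 2).sum())
        assert mean_run == pytest.approx(expect, rel=0.05)

    def test_planted_run_recovered(self, rng):
        from topowindow import runscan

        cfg = syn.default_config(
            gamma=0.0, n_chromosomes=1, windows_per_chromosome=400,
            planted_runs=(syn.PlantedRun(chrom=0, start_window=50,
                                         n_windows=300),),
            genes_per_chromosome=0,
        )
        ds = syn.layout_genome(cfg, rng)
        assert list(ds.truth["n_windows"]) == [300]
        labels = [
            "P" if p == "planted_pulse" else f"b{i}"
            for i, p in enumerate(ds.provenance)
        ]
        runs = runscan.detect_runs(ds.windows.assign(class_key=labels))
        planted = [r for r in runs if r.class_key == "P"]
        assert len(planted) == 1 and planted[0].length == 300

    def test_seed_reproducibility(self, tmp_path):
        cfg = syn.default_config(
            gamma=0.2, n_chromosomes=1, windows_per_chromosome=50
        )
        a = syn.layout_genome(cfg, np.random.default_rng(123))
        b = syn.layout_genome(cfg, np.random.default_rng(123))
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        assert syn.SimulationConfig.from_json(
            tmp_path / "a" / "config.json"
        ) == cfg
        for name in ("window_trees.nwk", "window_trees.bed", "truth.tsv",
                     "genes.bed", "provenance.tsv"):
            assert (
                (tmp_path / "a" / name).read_bytes()
                == (tmp_path / "b" / name).read_bytes()
            )


class TestSequenceEvolution:
    def test_zero_branches_identical_sequences(self, rng):
        t = treeio.parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        seqs = syn.evolve_sequences(t, 500, rng)
        assert len(set(seqs.values())) == 1

    def test_saturation_limit(self, rng):
        t = treeio.parse_newick("(A:500,B:500);")
        seqs = syn.evolve_sequences(t, 30_000, rng, scale=1.0)
        p = np.mean([
            a != b for a, b in zip(seqs["A"], seqs["B"])
        ])
        assert p == pytest.approx(0.75, abs=0.01)

    def test_jc_estimates_recover_patristic_distances(self, rng):
        """JC-corrected distances match the generating branch lengths
        within 3 SE at 100-kb sequences."""
        from topowindow import windows as win

        t = treeio.parse_newick(
            "((A:0.02,B:0.03):0.02,(C:0.01,D:0.04):0.02);"
        )
        seqs = syn.evolve_sequences(t, 100_000, rng, scale=1.0)
        w = win.AlignmentWindow(chrom="c", start=0, end=100_000, seqs=seqs)
        d, taxa, _ = win.jc_distance_matrix(w)
        for x, y in [("A", "B"), ("A", "C"), ("B", "D")]:
            truth = treeio.patristic_distance(t, x, y)
            est = d[taxa.index(x), taxa.index(y)]
            # delta-method SE of the JC estimator
            p = 0.75 * (1 - math.exp(-4 * truth / 3))
            se = math.sqrt(p * (1 - p) / 100_000) / (1 - 4 * p / 3)
            assert abs(est - truth) < 3 * se


class TestSitePatterns:
    def test_hand_written_columns(self):
        seqs = {
            "P1": "AAAAG",
            "P2": "CCCAG",
            "P3": "CCCAG",
            "O":  "AAAAG",
        }
        # columns 1-3 are ABBA; column 4 constant; column 5 constant
        a, b = syn.count_patterns(seqs, ("P1", "P2", "P3", "O"))
        assert (a, b) == (3, 0)
        a, b = syn.count_patterns(seqs, ("P2", "P1", "P3", "O"))
        assert (a, b) == (0, 3)

    def test_missing_quartet_taxon_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            syn.count_patterns({"A": "ACGT"}, ("A", "B", "C", "D"))

    def test_column_scan_oracle(self, rng):
        """Vectorised pattern counts equal a per-column classifier."""
        taxa = ("P1", "P2", "P3", "O")
        for _ in range(100):
            n = int(rng.integers(10, 200))
            mat = rng.choice(list("ACGT-N"), size=(4, n),
                             p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04])
            seqs = {t: "".join(row) for t, row in zip(taxa, mat)}
            a, b = syn.count_patterns(seqs, taxa)
            ea = eb = 0
            for j in range(n):
                col = [seqs[t][j] for t in taxa]
                if any(c in "-N" for c in col):
                    continue
                p1, p2, p3, o = col
                if p1 == o and p2 == p3 and p2 != o:
                    ea += 1
                elif p2 == o and p1 == p3 and p1 != o:
                    eb += 1
            assert (a, b) == (ea, eb)

    def test_ils_only_patterns_nearly_symmetric(self, rng):
        """gamma = 0 gives |D| small over a modest genome."""
        cfg = syn.default_config(
            gamma=0.0, n_chromosomes=1, windows_per_chromosome=300,
            mean_run_length=1.0, genes_per_chromosome=0,
        )
        ds = syn.layout_genome(cfg, rng)
        alns = ds.alignments(rng)
        pats = syn.emit_site_patterns(
            alns, ("TealX", "RecipientP", "DonorA", "Outgroup"),
            block=500_000,
        )
        tot_a = pats["n_abba"].sum()
        tot_b = pats["n_baba"].sum()
        d = (tot_a - tot_b) / (tot_a + tot_b)
        assert abs(d) < 0.15
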