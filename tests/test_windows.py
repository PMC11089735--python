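"""Window splitting, quality filters, 4D sites and NJ tree inference."""

import numpy as np
import pytest
from scipy import stats

from topowindow import treeio, windows as win
from topowindow import synthetic as syn
from topowindow.topology import canonical_string
from topowindow.treeio import TaxonSet


def make_window(seqs, chrom="chr1", start=0):
    end = start + len(next(iter(seqs.values())))
    return win.AlignmentWindow(chrom=chrom, start=start, end=end, seqs=seqs)


class TestSplitWindows:
    def test_tiling_coordinates(self):
        aln = {t: "ACGT" * 2500 for t in "AB"}
        wins = win.split_windows(aln, size=1000, min_informative=0)
        assert len(wins) == 10
        assert [(w.start, w.end) for w in wins] == [
            (i * 1000, (i + 1) * 1000) for i in range(10)
        ]

    def test_all_gap_window_dropped(self):
        aln = {"A": "ACGT" * 10 + "-" * 40, "B": "ACGT" * 10 + "-" * 40}
        wins = win.split_windows(aln, size=40, min_informative=30)
        assert len(wins) == 1
        assert wins[0].start == 0

    def test_retained_set_equals_column_scan_oracle(self, rng):
        """Informative-column counting matches a brute-force per-column
        scan on a noisy random alignment."""
        taxa = [f"T{i}" for i in range(5)]
        n = 5000
        mat = rng.choice(list("ACGT-N"), size=(5, n), p=[0.2, 0.2, 0.2, 0.2, 0.15, 0.05])
        aln = {t: "".join(row) for t, row in zip(taxa, mat)}
        size, min_inf = 250, 180
        wins = win.split_windows(aln, size=size, min_informative=min_inf)
        expected_starts = []
        for start in range(0, n, size):
            count = 0
            for j in range(start, min(start + size, n)):
                good = sum(
                    aln[t][j] not in "-N" for t in taxa
                )
                if good >= 2:
                    count += 1
            if count >= min_inf:
                expected_starts.append(start)
        assert [w.start for w in wins] == expected_starts

    def test_empty_alignment(self):
        assert win.split_windows({}, size=100) == []


class TestGapFilter:
    def test_printed_ratio_fails(self):
        seqs = {}
        gaps_left = 660
        for i in range(6):
            g = min(110, gaps_left)
            seqs[f"T{i}"] = "-" * 110 + "A" * 890
        w = make_window(seqs)
        ok, ratio = win.gap_filter(w, threshold=0.10)
        assert ratio == pytest.approx(660 / 6000)
        assert not ok

    def test_gap_free_passes(self):
        w = make_window({"A": "ACGT" * 25, "B": "ACGT" * 25})
        ok, ratio = win.gap_filter(w)
        assert ok and ratio == 0.0

    def test_boundary_exact_threshold_passes(self):
        # exactly 10% gaps: strict "larger than" keeps the window
        seqs = {"A": "-" * 10 + "A" * 90, "B": "-" * 10 + "A" * 90}
        ok, ratio = win.gap_filter(make_window(seqs), threshold=0.10)
        assert ratio == pytest.approx(0.10)
        assert ok


class TestCompositionTest:
    def test_uniform_composition_statistic_zero(self):
        w = make_window({t: "ACGT" * 100 for t in "ABCD"})
        statistics, passed = win.composition_test(w)
        assert all(v == pytest.approx(0.0) for v in statistics.values())
        assert all(passed.values())

    def test_all_g_sequence_fails(self):
        """One all-G sequence among uniform ones exceeds the chi-square
        critical value 7.815 at df=3; statistic checked by hand formula."""
        n = 400
        seqs = {t: "ACGT" * (n // 4) for t in "ABC"}
        seqs["D"] = "G" * n
        w = make_window(seqs)
        statistics, passed = win.composition_test(w, alpha=0.05)
        pooled = np.array([300, 300, 300 + 400, 300], dtype=float)  # A C G T
        freqs = pooled / pooled.sum()
        exp = n * freqs
        obs = np.array([0, 0, 400, 0], dtype=float)
        by_hand = (((obs - exp) ** 2) / exp).sum()
        assert statistics["D"] == pytest.approx(by_hand)
        assert by_hand > stats.chi2.ppf(0.95, df=3) == pytest.approx(7.814727903)
        assert not passed["D"]
        # the outlier drags the pooled mean, so the uniform sequences are
        # deflected too; the outlier must carry by far the largest statistic
        assert statistics["D"] > 4 * max(
            statistics[t] for t in "ABC"
        )

    def test_sequences_at_pooled_mean_pass(self):
        w = make_window({"A": "AACCGGTT" * 50, "B": "AACCGGTT" * 50})
        _, passed = win.composition_test(w)
        assert all(passed.values())


class TestFilterReport:
    def test_report_combines_both_filters(self):
        seqs = {"A": "-" * 30 + "A" * 70, "B": "G" * 100}
        rep = win.filter_report(make_window(seqs), max_gap=0.10, alpha=0.05)
        assert rep.gap_ratio == pytest.approx(0.15)
        assert not rep.gap_pass
        assert not rep.composition_window_pass  # A-only vs G-only sequences
        assert rep.window_id == "chr1:0-100"


class TestExtract4D:
    def test_fourfold_family_emitted(self):
        # Ala codons GCx across taxa: third positions kept
        seqs = {"A": "GCAGCC", "B": "GCCGCG", "C": "GCTGCA"}
        out = win.extract_4d_sites(make_window(seqs))
        assert out.seqs == {"A": "AC", "B": "CG", "C": "TA"}

    def test_non_degenerate_codon_excluded(self):
        seqs = {"A": "ATG", "B": "ATG", "C": "ATG"}
        out = win.extract_4d_sites(make_window(seqs))
        assert out.n_columns == 0

    def test_unconserved_prefix_excluded(self):
        seqs = {"A": "GGA", "B": "GAA", "C": "GGA"}
        out = win.extract_4d_sites(make_window(seqs))
        assert out.n_columns == 0

    def test_frame_required(self):
        with pytest.raises(ValueError, match="frame"):
            win.extract_4d_sites(make_window({"A": "GCA", "B": "GCC"}),
                                 frame=None)

    def test_codon_table_oracle(self, rng):
        """Every emitted column's codon context is fourfold degenerate per
        Biopython's translation table; every skipped conserved-prefix codon
        is not."""
        from Bio.Seq import Seq

        taxa = [f"T{i}" for i in range(4)]
        n_codons = 300
        mat = rng.choice(list("ACGT"), size=(4, 3 * n_codons))
        # force many conserved prefixes
        for k in range(0, n_codons, 2):
            pre = "".join(rng.choice(list("ACGT"), size=2))
            for r in range(4):
                mat[r, 3 * k] = pre[0]
                mat[r, 3 * k + 1] = pre[1]
        aln = {t: "".join(row) for t, row in zip(taxa, mat)}
        out = win.extract_4d_sites(make_window(aln))
        emitted = out.n_columns
        expect = 0
        for k in range(n_codons):
            p1 = {aln[t][3 * k] for t in taxa}
            p2 = {aln[t][3 * k + 1] for t in taxa}
            if len(p1) != 1 or len(p2) != 1:
                continue
            prefix = next(iter(p1)) + next(iter(p2))
            aas = {str(Seq(prefix + b).translate()) for b in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                expect += 1
        assert emitted == expect

    def test_output_at_most_third_of_input(self, rng):
        mat = rng.choice(list("ACGT"), size=(4, 999))
        aln = {f"T{i}": "".join(row) for i, row in enumerate(mat)}
        out = win.extract_4d_sites(make_window(aln))
        assert out.n_columns <= 333


class TestStripGaps:
    def test_gap_free_identity(self):
        w = make_window({"A": "ACGT", "B": "ACGT"})
        assert win.strip_gap_columns(w).seqs == w.seqs

    def test_single_gapped_column_removed(self):
        seqs = {"A": "A" * 49 + "-" + "A" * 50, "B": "C" * 100}
        out = win.strip_gap_columns(make_window(seqs))
        assert out.n_columns == 99

    def test_column_mask_oracle(self, rng):
        taxa = [f"T{i}" for i in range(4)]
        mat = rng.choice(list("ACGT-N"), size=(4, 500),
                         p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06])
        aln = {t: "".join(row) for t, row in zip(taxa, mat)}
        out = win.strip_gap_columns(make_window(aln))
        keep = [
            j for j in range(500)
            if all(aln[t][j] not in "-N" for t in taxa)
        ]
        assert out.seqs == {
            t: "".join(aln[t][j] for j in keep) for t in taxa
        }


class TestNJTree:
    def test_additive_matrix_recovers_split(self):
        """NJ on sequences realising an additive AB|CD metric groups the
        right pairs (four-point condition)."""
        # build sequences with planted divergences via a star-free tree
        rng = np.random.default_rng(5)
        tree = treeio.parse_newick(
            "((A:0.01,B:0.01):0.04,(C:0.01,D:0.01):0.04);"
        )
        seqs = syn.evolve_sequences(tree, 20000, rng, scale=1.0)
        w = make_window(seqs)
        nj = win.nj_tree(w)
        taxa = TaxonSet(labels=("A", "B", "C", "D"), outgroup="A")
        assert canonical_string(nj, taxa) == "(A,(B,(C,D)))"

    def test_identical_sequences_zero_lengths(self):
        w = make_window({t: "ACGT" * 50 for t in "ABCD"})
        nj = win.nj_tree(w)
        for a, b in [("A", "B"), ("A", "C"), ("B", "D")]:
            assert treeio.patristic_distance(nj, a, b) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_saturated_pair_capped_and_flagged(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=400))
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        far = "".join(rot[b] for b in base)  # p-distance exactly 1
        w = make_window({"A": base, "B": base, "C": base, "D": far})
        d, taxa, saturated = win.jc_distance_matrix(w, max_distance=5.0)
        assert saturated
        assert d[taxa.index("A"), taxa.index("D")] == 5.0
        with pytest.warns(UserWarning, match="saturated"):
            win.nj_tree(w)
        assert "saturated" in w.flags

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="4 taxa"):
            win.nj_tree(make_window({"A": "ACGT", "B": "ACGT", "C": "ACGT"}))

    def test_recovers_generating_topology_on_simulated_windows(
        self, rng, synthetic_taxa, synthetic_catalogue
    ):
        """On low-rate simulated 6-taxon windows, the NJ topology matches
        the generating gene tree in >= 95% of windows."""
        cfg = syn.default_config(gamma=0.0, genes_per_chromosome=0)
        from topowindow.synthetic import _SpeciesModel

        model = _SpeciesModel(cfg)
        hits = 0
        n = 60
        for _ in range(n):
            gt, _ = syn.simulate_gene_tree(cfg, rng, model=model)
            seqs = syn.evolve_sequences(gt, 50_000, rng, scale=0.01)
            nj = win.nj_tree(make_window(seqs))
            if (
                canonical_string(nj, synthetic_taxa)
                == canonical_string(gt, synthetic_taxa)
            ):
                hits += 1
        assert hits / n >= 0.95


class TestLongBranchFilter:
    def _tree(self, scale_taxon=None, factor=1.0):
        t = treeio.parse_newick(
            "((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);"
        )
        if scale_taxon:
            node = t.find_node_with_taxon_label(scale_taxon)
            node.edge.length *= factor
        return t

    def test_homogeneous_trees_unflagged(self):
        trees = [self._tree() for _ in range(100)]
        assert win.long_branch_filter(trees, factor=5.0) == [False] * 100

    def test_planted_outlier_flagged(self):
        trees = [self._tree() for _ in range(99)]
        trees.insert(42, self._tree(scale_taxon="C", factor=50.0))
        flags = win.long_branch_filter(trees, factor=5.0)
        assert flags[42] is True or flags[42] == True  # noqa: E712
        assert sum(flags) == 1

    def test_infinite_factor_no_flags(self):
        trees = [self._tree(scale_taxon="A", factor=30.0) for _ in range(25)]
        assert not any(win.long_branch_filter(trees, factor=np.inf))

    def test_few_trees_pass_with_warning(self):
        trees = [self._tree() for _ in range(5)]
        with pytest.warns(UserWarning, match="long-branch"):
            flags = win.long_branch_filter(trees)
        assert flags == [False] * 5
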