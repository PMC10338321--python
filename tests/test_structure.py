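import numpy as np
import pytest

from covet import (
    build_contact_map,
    evaluate_contact_prediction,
    functional_residues,
    hypergeometric_overlap,
    mean_sequence_separation,
    read_pdb,
    scw_w,
    scw_zscore,
    selected_pair_components,
    toy_structure,
    write_pdb,
)
from covet.ranking import CoverageSelection
from covet.scoring import PairScoreTable
from covet.structure import Residue, StructureModel, separation_class

from .oracles import brute_hypergeometric, brute_scw_moments


def residue(pos, name="ALA", ca=(0, 0, 0), cb=None):
    atoms = [("CA", *map(float, ca))]
    if cb is not None:
        atoms.append(("CB", *map(float, cb)))
    return Residue(pos, name, tuple(atoms))


class TestContactMap:
    def test_cb_distance_below_cutoff_is_contact(self):
        st = StructureModel(
            (
                residue(10, ca=(0, 0, 0), cb=(0, 0, 0)),
                residue(16, ca=(99, 0, 0), cb=(7.9, 0, 0)),
            )
        )
        cm = build_contact_map(st)
        assert cm.is_contact(10, 16)
        assert cm.classes[(10, 16)] == "short"

    def test_close_in_sequence_excluded(self):
        st = StructureModel(
            (residue(10, cb=(0, 0, 0)), residue(14, cb=(1, 0, 0)))
        )
        cm = build_contact_map(st)
        assert (10, 14) not in cm.contacts

    def test_glycine_uses_ca(self):
        st = StructureModel(
            (
                residue(3, name="GLY", ca=(0, 0, 0), cb=(50, 0, 0)),
                residue(10, ca=(99, 0, 0), cb=(5, 0, 0)),
            )
        )
        cm = build_contact_map(st)
        assert cm.is_contact(3, 10)  # GLY Ca at origin, 5 A from the Cb

    @pytest.mark.parametrize(
        "sep,cls",
        [(5, "excluded"), (6, "short"), (11, "short"), (12, "medium"),
         (23, "medium"), (24, "long"), (100, "long")],
    )
    def test_separation_classes(self, sep, cls):
        assert separation_class(sep) == cls

    def test_symmetric_and_complete(self, chain_structure):
        cm = build_contact_map(chain_structure)
        pos = chain_structure.positions
        expected_pairs = {
            (i, j) for a, i in enumerate(pos) for j in pos[a + 1:] if j - i >= 6
        }
        assert set(cm.contacts) == expected_pairs

    def test_missing_contact_atom_reported(self):
        st = StructureModel(
            (
                Residue(1, "ALA", (("N", 0.0, 0.0, 0.0),)),
                residue(10, cb=(0, 0, 0)),
                residue(20, cb=(5, 0, 0)),
            )
        )
        cm = build_contact_map(st)
        assert cm.excluded_residues == (1,)


class TestContactEvaluation:
    @staticmethod
    def _table(scores: dict, lower=True):
        positions = tuple(sorted({p for pair in scores for p in pair}))
        idx = {p: k for k, p in enumerate(positions)}
        k = len(positions)
        m = np.zeros((k, k))
        for (i, j), s in scores.items():
            m[idx[min(i, j)], idx[max(i, j)]] = s
        return PairScoreTable(positions, m, "covet", lower, 10)

    def _two_pair_setup(self):
        # contact (1,10); non-contact (1, 20)
        st = StructureModel(
            (
                residue(1, cb=(0, 0, 0)),
                residue(10, cb=(5, 0, 0)),
                residue(20, cb=(50, 0, 0)),
            )
        )
        return build_contact_map(st)

    def test_perfect_ranking(self):
        cm = self._two_pair_setup()
        table = self._table({(1, 10): 1.0, (1, 20): 9.0, (10, 20): 9.0})
        out = evaluate_contact_prediction(table, cm)
        assert out["auroc"] == 1.0

    def test_anti_ranking(self):
        cm = self._two_pair_setup()
        table = self._table({(1, 10): 9.0, (1, 20): 1.0, (10, 20): 1.0})
        assert evaluate_contact_prediction(table, cm)["auroc"] == 0.0

    def test_single_class_raises(self):
        cm = self._two_pair_setup()
        table = self._table({(1, 10): 1.0})
        with pytest.raises(ValueError):
            evaluate_contact_prediction(table, cm, "long")

    def test_random_scores_adjusted_auprc_near_zero(self, rng):
        """Adjusted AUPRC of a random predictor is approximately centered.

        Subtracting the positive rate removes the class-imbalance floor;
        the average-precision estimator retains a small positive bias of
        order 1/#positives at this problem size, so the check is a coarse
        band around zero rather than a standard-error one.
        """
        n_pairs, n_pos = 200, 20
        labels = np.zeros(n_pairs, dtype=bool)
        labels[:n_pos] = True
        from sklearn.metrics import average_precision_score

        vals = []
        for _ in range(1000):
            scores = rng.random(n_pairs)
            vals.append(average_precision_score(labels, scores) - n_pos / n_pairs)
        assert abs(np.mean(vals)) < 0.05
        # and far below any real signal: a perfect predictor scores ~0.9
        assert np.mean(vals) < 0.1 * (1 - n_pos / n_pairs)


class TestScwW:
    adjacency = {(1, 2): True, (3, 4): True, (1, 4): False}

    def test_empty_selection_zero(self):
        assert scw_w(set(), self.adjacency) == 0.0

    def test_unbiased_counts_edges(self):
        assert scw_w({1, 2}, self.adjacency) == 1.0

    def test_biased_weights_by_separation(self):
        assert scw_w({1, 2}, self.adjacency, bias="biased") == 1.0
        assert scw_w({1, 4}, self.adjacency, bias="biased") == 0.0

    def test_unbiased_never_exceeds_biased(self, clustered_structure):
        adj = clustered_structure.adjacency()
        sel = {3, 7, 11, 14, 17, 20}
        assert scw_w(sel, adj) <= scw_w(sel, adj, bias="biased")


class TestScwZscore:
    def test_analytic_moments_match_exhaustive_enumeration(self):
        """Pair-overlap decomposition equals brute-force over all selections."""
        st = toy_structure(8, clusters=[({2, 5, 7}, 1.0)], seed=9)
        from covet.structure import _edge_weights

        for bias in ("unbiased", "biased"):
            weights = _edge_weights(st, bias)
            mean, var = brute_scw_moments(weights, list(st.positions), 4)
            res = scw_zscore({1, 2, 3, 4}, st, bias=bias)
            assert res.expected_w == pytest.approx(mean, abs=1e-9)
            assert res.sd_w**2 == pytest.approx(var, abs=1e-9)

    @pytest.mark.parametrize("bias", ["unbiased", "biased"])
    def test_analytic_agrees_with_montecarlo(self, clustered_structure, bias):
        sel = {3, 7, 11, 14, 17, 20}
        ana = scw_zscore(sel, clustered_structure, bias=bias)
        mc = scw_zscore(
            sel, clustered_structure, bias=bias, null="montecarlo",
            draws=10_000, seed=42,
        )
        se_mean = mc.sd_w / np.sqrt(10_000)
        assert abs(ana.expected_w - mc.expected_w) < 3 * se_mean
        assert ana.sd_w == pytest.approx(mc.sd_w, rel=0.1)

    def test_planted_cluster_is_significant(self, clustered_structure):
        res = scw_zscore({3, 7, 11, 14, 17, 20}, clustered_structure)
        assert res.z is not None and res.z > 2.0

    def test_random_selections_center_on_zero(self, chain_structure, rng):
        zs = []
        pos = np.array(chain_structure.positions)
        for _ in range(300):
            sel = set(rng.choice(pos, size=6, replace=False).tolist())
            res = scw_zscore(sel, chain_structure)
            if res.z is not None:
                zs.append(res.z)
        se = np.std(zs) / np.sqrt(len(zs))
        assert abs(np.mean(zs)) < 3 * se

    def test_selecting_everything_flags_undefined(self, chain_structure):
        res = scw_zscore(set(chain_structure.positions), chain_structure)
        assert res.z is None

    def test_tiny_selection_rejected(self, chain_structure):
        with pytest.raises(ValueError):
            scw_zscore({1}, chain_structure)


class TestFunctionalResidues:
    def test_strict_four_angstrom_boundary(self):
        st = StructureModel(
            (residue(1, ca=(3.9, 0, 0)), residue(9, ca=(4.0, 0, 0)))
        )
        ligand = np.array([[0.0, 0.0, 0.0]])
        assert functional_residues(st, ligand) == {1}

    def test_distant_ligand_empty_set(self, chain_structure):
        assert functional_residues(chain_structure, np.array([[0, 99, 99]])) == set()

    def test_empty_ligand_rejected(self, chain_structure):
        with pytest.raises(ValueError):
            functional_residues(chain_structure, np.empty((0, 3)))


class TestHypergeometricOverlap:
    def test_exact_combinatorial_example(self):
        # universe 10, gold 5, selected 4, overlap 4: C(5,4)/C(10,4)
        p = hypergeometric_overlap({1, 2, 3, 4}, {1, 2, 3, 4, 5}, 10)
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_empty_selection_p_one(self):
        assert hypergeometric_overlap(set(), {1, 2}, 10) == 1.0

    def test_gold_equals_universe_p_one(self):
        assert hypergeometric_overlap({1, 2}, set(range(1, 11)), 10) == pytest.approx(1.0)

    def test_matches_enumeration_on_small_universes(self):
        for universe, n_gold, n_sel, overlap in [
            (8, 3, 4, 2), (10, 5, 4, 4), (12, 6, 6, 3), (7, 2, 5, 1),
        ]:
            gold = set(range(1, n_gold + 1))
            sel = set(range(1, overlap + 1)) | set(
                range(n_gold + 1, n_gold + 1 + n_sel - overlap)
            )
            assert hypergeometric_overlap(sel, gold, universe) == pytest.approx(
                brute_hypergeometric(universe, n_gold, n_sel, overlap), abs=1e-12
            )


class TestSummaries:
    def test_mean_separation_arithmetic(self):
        sel = CoverageSelection(((1, 5), (2, 10)), frozenset({1, 2, 5, 10}), 0.3)
        assert mean_sequence_separation(sel) == 6.0
        assert mean_sequence_separation(sel, 100, normalized=True) == 0.06

    def test_single_pair_separation(self):
        sel = CoverageSelection(((4, 10),), frozenset({4, 10}), 0.1)
        assert mean_sequence_separation(sel) == 6.0

    def test_components_split_and_cycle(self):
        sel = CoverageSelection(
            ((1, 2), (2, 3), (7, 8)), frozenset({1, 2, 3, 7, 8}), 0.3
        )
        assert selected_pair_components(sel) == [[1, 2, 3], [7, 8]]
        cyc = CoverageSelection(((1, 2), (2, 3), (1, 3)), frozenset({1, 2, 3}), 0.3)
        assert selected_pair_components(cyc) == [[1, 2, 3]]


class TestPdbIO:
    def test_write_read_round_trip(self, tmp_path, clustered_structure):
        p = tmp_path / "toy.pdb"
        write_pdb(clustered_structure, p)
        back = read_pdb(p)
        assert back.positions == clustered_structure.positions
        for pos in back.positions:
            np.testing.assert_allclose(
                back.residue(pos).coords(),
                clustered_structure.residue(pos).coords(),
                atol=1e-3,  # PDB fixed-format precision
            )
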