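"""Prediction support filtering, inverse networks and the crossmatch."""

import numpy as np
import pandas as pd
import pytest

from miromics import networks as N
from miromics.simulate import split_transfection

from conftest import make_protein_matrix


def _pred(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene_id", "algorithm"])


def _difftable(ids, fc, sig):
    fc = np.asarray(fc, dtype=float)
    sig = np.asarray(sig, dtype=bool)
    return pd.DataFrame(
        {
            "feature_id": ids,
            "contrast": "d3_vs_native",
            "mean_ref": 10.0,
            "mean_alt": 10.0,
            "log2fc": fc,
            "log2fc_eff": fc,
            "p": np.where(sig, 1e-4, 0.5),
            "q": np.where(sig, 1e-3, 0.7),
            "significant": sig,
            "direction": np.where(~sig, "none", np.where(fc > 0, "up", "down")),
        }
    )


class TestNaming:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("miR-221-5p", "hsa-miR-221-5p"),
            ("HSA-MIR-221-5P", "hsa-miR-221-5p"),
            ("hsa-miR-27a-5p", "hsa-miR-27a-5p"),
            ("let-7i-5p", "hsa-let-7i-5p"),
        ],
    )
    def test_normalize(self, raw, canonical):
        assert N.normalize_mirna(raw) == canonical

    def test_unknown_algorithm_listed(self):
        pred = _pred([("m1", "g1", "PITA"), ("m1", "g2", "DeepSeqMagic")])
        with pytest.raises(ValueError, match="DeepSeqMagic"):
            N.validate_predictions(pred)

    def test_duplicate_triples_collapse(self):
        """Name-case and prefix variants of the same triple count once."""
        sup = N.support_counts(_pred([("miR-9", "g1", "PITA"), ("hsa-miR-9", "g1", "pita")]))
        assert len(sup) == 1 and sup["support"].iloc[0] == 1


class TestSupportFilter:
    def test_full_support_always_retained(self):
        rows = [("m1", "g1", a) for a in N.ALGORITHMS]
        for k in (1, 5, 12):
            assert N.support_filter(_pred(rows), ["m1"], k) == {("hsa-m1", "g1")}

    def test_boundary(self):
        rows = [("m1", "g1", a) for a in N.ALGORITHMS[:4]]
        assert N.support_filter(_pred(rows), ["m1"], 5) == set()
        assert N.support_filter(_pred(rows), ["m1"], 1) == {("hsa-m1", "g1")}

    def test_matches_bruteforce_group_count(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"m{rng.integers(2)}", f"g{rng.integers(4)}", N.ALGORITHMS[rng.integers(12)])
            for _ in range(20)
        ]
        pred = _pred(rows)
        for k in (1, 2, 3):
            got = N.support_filter(pred, ["m0", "m1"], k)
            brute = {}
            for m, g, a in set((N.normalize_mirna(m), g, a.lower()) for m, g, a in rows):
                brute.setdefault((m, g), set()).add(a)
            expected = {pair for pair, algs in brute.items() if len(algs) >= k}
            assert got == expected

    def test_min_support_bounds(self):
        with pytest.raises(ValueError):
            N.support_filter(_pred([]), ["m1"], 0)


class TestInverseNetwork:
    def _inputs(self):
        mirnas = pd.DataFrame({"mirna": ["hsa-miR-1", "hsa-miR-2"],
                               "direction": ["down", "down"]})
        rows = [("hsa-miR-1", "gP", a) for a in N.ALGORITHMS[:6]]
        rows += [("hsa-miR-2", "gP", a) for a in N.ALGORITHMS[:7]]
        rows += [("hsa-miR-1", "gQ", a) for a in N.ALGORITHMS[:4]]  # below support
        proteins = _difftable(["P", "Q"], [2.0, 1.5], [True, True])
        return mirnas, proteins, _pred(rows), {"P": "gP", "Q": "gQ"}

    def test_toy_enumeration(self):
        mirnas, proteins, pred, gene_of = self._inputs()
        nets = N.build_inverse_network(mirnas, proteins, pred, 5, gene_of)
        g = nets["down_up"]
        assert g.nodes["P"]["n_predicting_mirnas"] == 2
        assert g.edges["hsa-miR-1", "P"]["support"] == 6
        assert g.edges["hsa-miR-2", "P"]["support"] == 7
        assert "Q" not in g
        assert nets["up_down"].number_of_edges() == 0

    def test_no_inverse_proteins_empty(self):
        mirnas, _, pred, gene_of = self._inputs()
        proteins = _difftable(["P"], [-2.0], [True])  # same direction as miRNAs
        nets = N.build_inverse_network(mirnas, proteins, pred, 5, gene_of)
        assert nets["down_up"].number_of_edges() == 0

    def test_lowering_min_support_never_removes_edges(self):
        mirnas, proteins, pred, gene_of = self._inputs()
        e5 = set(N.build_inverse_network(mirnas, proteins, pred, 5, gene_of)["down_up"].edges)
        e3 = set(N.build_inverse_network(mirnas, proteins, pred, 3, gene_of)["down_up"].edges)
        assert e5 <= e3

    def test_row_order_permutation_stable(self):
        mirnas, proteins, pred, gene_of = self._inputs()
        shuffled = pred.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = N.build_inverse_network(mirnas, proteins, pred, 5, gene_of)["down_up"]
        b = N.build_inverse_network(mirnas, proteins, shuffled, 5, gene_of)["down_up"]
        assert set(a.edges) == set(b.edges)
        for e in a.edges:
            assert a.edges[e] == b.edges[e]


class TestTransfectionDiff:
    def _matrices(self, a, b):
        na, nb = a.shape[1], b.shape[1]
        trans = make_protein_matrix(a, ["5/03"] * na, ["d3"] * na,
                                    conditions=["mimic:hsa-miR-1"] * na)
        ctrl = make_protein_matrix(b, ["5/03"] * nb, ["d3"] * nb,
                                   conditions=["control_sirna"] * nb)
        return trans, ctrl

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        vals = 2.0 ** rng.normal(20, 1, (50, 3))
        trans, ctrl = self._matrices(vals, vals)
        out = N.transfection_diff(trans, ctrl)
        assert not out["significant"].any()

    def test_antisymmetry_flips_directions(self):
        rng = np.random.default_rng(2)
        a = 2.0 ** rng.normal(20, 1, (50, 3))
        b = a.copy()
        b[:10] *= 2.0 ** 1.5
        t1, c1 = self._matrices(a, b)
        fwd = N.transfection_diff(t1, c1)
        rev = N.transfection_diff(c1, t1)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert [flip[d] for d in fwd["direction"]] == list(rev["direction"])

    def test_single_replicate_rejected(self):
        a = 2.0 ** np.random.default_rng(3).normal(20, 1, (5, 1))
        trans, ctrl = self._matrices(a, np.hstack([a, a]))
        with pytest.raises(ValueError, match="transfected"):
            N.transfection_diff(trans, ctrl)


def crossmatch_bruteforce(diff, pred, mirna, mode, tc_inverse, min_support, gene_of):
    """Independent set-comprehension implementation of the crossmatch."""
    mirna = N.normalize_mirna(mirna)
    support = {}
    for m, g, a in pred[["mirna", "gene_id", "algorithm"]].itertuples(index=False):
        support.setdefault((N.normalize_mirna(m), g), set()).add(a.lower())
    predicted = {g for (m, g), algs in support.items()
                 if m == mirna and len(algs) >= min_support}
    genes = {p: gene_of.get(p, p) for p in diff["feature_id"]}
    quantified = set(genes.values())
    up = {genes[r.feature_id] for r in diff.itertuples(index=False)
          if r.significant and r.direction == "up"}
    down = {genes[r.feature_id] for r in diff.itertuples(index=False)
            if r.significant and r.direction == "down"}
    expected = down if mode == "mimic" else up
    inverse_dir = "up" if mode == "mimic" else "down"
    reg_pred = {g for g in expected if g in predicted and g in quantified}
    tc_pred = {g for g, d in tc_inverse.items() if d == inverse_dir and g in predicted}
    return {
        "n_quantified": len(quantified),
        "n_predicted_of_quantified": len(quantified & predicted),
        "n_regulated_up": len(up),
        "n_regulated_down": len(down),
        "n_regulated_expected_direction_and_predicted": len(reg_pred),
        "n_inverse_regulated_predicted_in_timecourse": len(tc_pred),
        "n_overlap": len(reg_pred & tc_pred),
    }


def random_crossmatch_instance(rng):
    n_prot = int(rng.integers(5, 40))
    prots = [f"p{i}" for i in range(n_prot)]
    genes = {p: f"g{int(rng.integers(0, 30))}" for p in prots}
    fc = rng.normal(0, 1.5, n_prot)
    sig = rng.random(n_prot) < 0.4
    diff = _difftable(prots, fc, sig)
    mirna = "hsa-miR-X"
    rows = [
        (mirna, f"g{g}", N.ALGORITHMS[a])
        for g in range(30)
        for a in range(12)
        if rng.random() < 0.25
    ]
    rows.append((mirna, "g0", "PITA"))
    pred = _pred(rows)
    tc = {f"g{g}": ("up" if rng.random() < 0.5 else "down")
          for g in range(30) if rng.random() < 0.5}
    mode = "mimic" if rng.random() < 0.5 else "inhibitor"
    min_support = int(rng.integers(1, 6))
    return diff, pred, mirna, mode, tc, min_support, genes


class TestCrossmatch:
    def test_empty_significant_set(self):
        diff = _difftable(["p1", "p2"], [0.1, 0.2], [False, False])
        pred = _pred([("hsa-miR-X", "p1", "PITA")])
        rep = N.crossmatch(diff, pred, "hsa-miR-X", "mimic", {})
        assert rep.n_regulated_up == rep.n_regulated_down == rep.n_overlap == 0
        assert rep.n_quantified == 2

    def test_unknown_mirna_rejected(self):
        diff = _difftable(["p1"], [1.0], [True])
        pred = _pred([("hsa-miR-X", "p1", "PITA")])
        with pytest.raises(ValueError, match="absent"):
            N.crossmatch(diff, pred, "hsa-miR-Y", "mimic", {})

    def test_planted_instance_equals_set_algebra(self):
        """10 planted responsive targets, 4 of them inverse in the time
        course: the report equals explicit set algebra."""
        prots = [f"p{i}" for i in range(20)]
        fc = np.array([-1.0] * 10 + [0.0] * 10)
        sig = np.array([True] * 10 + [False] * 10)
        diff = _difftable(prots, fc, sig)
        pred = _pred([("hsa-miR-X", p, a) for p in prots[:12] for a in N.ALGORITHMS[:6]])
        tc = {p: "up" for p in prots[:4]}
        rep = N.crossmatch(diff, pred, "hsa-miR-X", "mimic", tc, "any")
        assert rep.n_quantified == 20
        assert rep.n_predicted_of_quantified == 12
        assert rep.n_regulated_down == 10
        assert rep.n_regulated_expected_direction_and_predicted == 10
        assert rep.n_inverse_regulated_predicted_in_timecourse == 4
        assert rep.n_overlap == 4

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            diff, pred, mirna, mode, tc, k, gene_of = random_crossmatch_instance(rng)
            rep = N.crossmatch(diff, pred, mirna, mode, tc, k, gene_of)
            expected = crossmatch_bruteforce(diff, pred, mirna, mode, tc, k, gene_of)
            got = {k2: v for k2, v in rep.as_dict().items() if k2 in expected}
            assert got == expected

    def test_overlap_invariant_on_random_instances(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            diff, pred, mirna, mode, tc, k, gene_of = random_crossmatch_instance(rng)
            rep = N.crossmatch(diff, pred, mirna, mode, tc, k, gene_of)
            assert rep.n_overlap <= rep.n_regulated_expected_direction_and_predicted
            assert rep.n_overlap <= rep.n_inverse_regulated_predicted_in_timecourse
            assert rep.n_predicted_of_quantified <= rep.n_quantified


class TestTimecourseInverse:
    def _tables(self, d3_dir, d7_dir):
        return {
            "d3": _difftable(["P"], [1.0 if d3_dir == "up" else -1.0], [True]).assign(direction=d3_dir),
            "d7": _difftable(["P"], [1.0 if d7_dir == "up" else -1.0], [True]).assign(direction=d7_dir),
        }

    def test_union_and_agreement(self):
        out = N.timecourse_inverse_set(self._tables("up", "up"))
        assert out == {"P": "up"}

    def test_conflict_policies(self):
        with pytest.raises(ValueError, match="conflict"):
            N.timecourse_inverse_set(self._tables("up", "down"))
        out = N.timecourse_inverse_set(self._tables("up", "down"), on_conflict="drop")
        assert out == {}


class TestPredictedCoverage:
    def test_degenerate_cases(self):
        pred = _pred([("hsa-miR-X", "g1", "PITA"), ("hsa-miR-X", "g2", "RNA22")])
        assert N.predicted_coverage_check({"g1", "g2"}, pred, "hsa-miR-X") == 1.0
        assert N.predicted_coverage_check({"h1"}, pred, "hsa-miR-X") == 0.0
        with pytest.raises(ValueError, match="empty"):
            N.predicted_coverage_check(set(), pred, "hsa-miR-X")

    def test_synthetic_coverage_matches_binomial_complement(self, small_study, small_cfg):
        """With independent algorithms, P(>=1 of 12 fires on a false pair)
        = 1-(1-fp)^12; plus the true-target contribution."""
        mirna = "hsa-miR-S00000"
        quantified = set(small_study.mrna.features)
        frac = N.predicted_coverage_check(quantified, small_study.predictions, mirna)
        fp, sens = small_cfg.pred_fp_rate, small_cfg.pred_sensitivity
        p_true = small_cfg.true_targets_per_mirna / small_cfg.n_mrna
        expected = (1 - p_true) * (1 - (1 - fp) ** 12) + p_true * (1 - (1 - sens) ** 12)
        assert frac == pytest.approx(expected, abs=0.02)


class TestTransfectionPipelinePower:
    def test_mimic_targets_recovered(self, small_study):
        """Planted mimic effect (-1 log2) on quantified targets is recovered
        as significantly lower abundant for >= 80% of targets."""
        key = [k for k in small_study.transfections if k.endswith("mimic")][0]
        trans, ctrl = split_transfection(small_study.transfections[key])
        diff = N.transfection_diff(trans, ctrl)
        gene_of = dict(zip(small_study.gene_map.pairs["protein_id"],
                           small_study.gene_map.pairs["gene_id"]))
        responsive = small_study.proteome_truth.responsive[key]
        sig_down = {
            gene_of.get(p, p)
            for p, s, d in zip(diff["feature_id"], diff["significant"], diff["direction"])
            if s and d == "down"
        }
        assert len(responsive) >= 10
        assert len(sig_down & responsive) / len(responsive) >= 0.8
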