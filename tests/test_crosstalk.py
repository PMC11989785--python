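import numpy as np
import pandas as pd
import pytest

from lrcrosstalk.crosstalk import (
    DirectionRule,
    build_pairs,
    communication_score,
    default_rules,
    rank_pairs,
    run_crosstalk,
    select_lr_candidates,
)
from lrcrosstalk.diffexpr import (
    ContrastResult,
    estimate_dispersion,
    filter_low_counts,
    nb_wald_contrast,
    size_factors,
    study_contrasts,
)
from lrcrosstalk.io_formats import LRDatabase
from lrcrosstalk.simulate import (
    CO_CONTRAST,
    IMADC_CONTRAST,
    SMSC_CONTRAST,
    SimulationConfig,
    generate_counts,
    generate_lr_scenario,
)


def _result(name, genes, lfcs, statuses):
    table = pd.DataFrame(
        {"log2fc": lfcs, "padj": [0.01 if s != "NS" else 0.5 for s in statuses], "status": statuses},
        index=pd.Index(genes, name="gene"),
    )
    return ContrastResult(name, table)


class TestSelectCandidates:
    def test_membership(self):
        db = LRDatabase(frozenset({("GCG", "DPP4")}))
        res = _result("c", ["GCG", "DPP4", "ACTB"], [2.0, 1.5, 1.2], ["UP", "UP", "UP"])
        cand = select_lr_candidates(res, db)
        assert list(cand.ligands.index) == ["GCG"]
        assert list(cand.receptors.index) == ["DPP4"]

    def test_empty_deg_set(self):
        db = LRDatabase(frozenset({("GCG", "DPP4")}))
        res = _result("c", ["GCG"], [0.1], ["NS"])
        cand = select_lr_candidates(res, db)
        assert cand.n_ligands == 0 and cand.n_receptors == 0

    def test_dual_role_gene_in_both_sets(self):
        db = LRDatabase(frozenset({("X", "Y"), ("W", "X")}))
        res = _result("c", ["X"], [2.0], ["UP"])
        cand = select_lr_candidates(res, db)
        assert "X" in cand.ligands.index and "X" in cand.receptors.index


class TestCommunicationScore:
    @pytest.mark.parametrize(
        "l,r,fc_l,fc_r,cs",
        [
            (1.0, 2.0, 2.0, 4.0, 8.0),
            (0.0, 0.0, 1.0, 1.0, 1.0),
            (-1.0, 2.0, 2.0, 4.0, 8.0),  # magnitudes: sign drops out
        ],
    )
    def test_powers_of_two(self, l, r, fc_l, fc_r, cs):
        assert communication_score(l, r) == pytest.approx((fc_l, fc_r, cs))

    def test_reported_magnitudes(self):
        # representative validated magnitudes: 1.0485 up, 0.4761 down
        fc_l, fc_r, cs = communication_score(1.0485, -0.4761)
        assert cs == pytest.approx(2.0**1.5246, abs=1e-9)
        assert cs == pytest.approx(2.877069356, abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            communication_score(float("nan"), 1.0)

    def test_monotone_in_magnitude(self):
        base = communication_score(1.0, 1.0)[2]
        assert communication_score(1.5, 1.0)[2] > base
        assert communication_score(-1.5, 1.0)[2] > base


class TestBuildPairs:
    def _candidates(self):
        lig = _result("L", ["L1", "L2"], [2.0, -2.0], ["UP", "DOWN"])
        rec = _result("R", ["R1", "R2"], [-2.0, -1.5], ["DOWN", "DOWN"])
        db = LRDatabase(frozenset({("L1", "R1"), ("L2", "R2")}))
        cands = {
            "L": select_lr_candidates(lig, db),
            "R": select_lr_candidates(rec, db),
        }
        return cands, db

    def test_direction_rule_filters(self):
        cands, db = self._candidates()
        rule = DirectionRule("paracrine", 1, "L", "UP", "R", "DOWN", "SMSC", "IMAdC")
        pairs = build_pairs(rule, cands, db)
        assert list(zip(pairs["ligand"], pairs["receptor"])) == [("L1", "R1")]

    def test_any_any_emits_all_db_matches(self):
        cands, db = self._candidates()
        rule = DirectionRule("autocrine", 1, "L", "ANY", "R", "ANY", "IMAdC", "IMAdC")
        pairs = build_pairs(rule, cands, db)
        assert len(pairs) == 2

    def test_no_db_overlap_empty(self):
        cands, _ = self._candidates()
        db2 = LRDatabase(frozenset({("ZZ", "QQ")}))
        rule = DirectionRule("autocrine", 1, "L", "ANY", "R", "ANY", "IMAdC", "IMAdC")
        assert build_pairs(rule, cands, db2).empty

    def test_unknown_contrast_rejected(self):
        cands, db = self._candidates()
        rule = DirectionRule("autocrine", 1, "NOPE", "ANY", "R", "ANY", "IMAdC", "IMAdC")
        with pytest.raises(ValueError, match="NOPE"):
            build_pairs(rule, cands, db)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        statuses = np.array(["UP", "DOWN", "NS"])
        for trial in range(100):
            n_genes = int(rng.integers(5, 50))
            genes = [f"G{i}" for i in range(n_genes)]
            st_a = rng.choice(statuses, n_genes)
            st_b = rng.choice(statuses, n_genes)
            lfc = lambda s: {"UP": 2.0, "DOWN": -2.0, "NS": 0.1}[s]
            res_a = _result("A", genes, [lfc(s) for s in st_a], list(st_a))
            res_b = _result("B", genes, [lfc(s) for s in st_b], list(st_b))
            n_pairs = int(rng.integers(1, 20))
            db_pairs = frozenset(
                (genes[rng.integers(n_genes)], genes[rng.integers(n_genes)])
                for _ in range(n_pairs)
            )
            db = LRDatabase(db_pairs)
            req_l, req_r = rng.choice(["UP", "DOWN", "ANY"], 2)
            rule = DirectionRule("paracrine", 1, "A", req_l, "B", req_r, "SMSC", "IMAdC")
            cands = {
                "A": select_lr_candidates(res_a, db),
                "B": select_lr_candidates(res_b, db),
            }
            got = set(zip(*(build_pairs(rule, cands, db)[c] for c in ("ligand", "receptor")))) if len(
                build_pairs(rule, cands, db)
            ) else set()
            # oracle: direct enumeration of db x statuses
            stat_a = dict(zip(genes, st_a))
            stat_b = dict(zip(genes, st_b))
            expected = {
                (l, r)
                for l, r in db_pairs
                if stat_a[l] in (("UP", "DOWN") if req_l == "ANY" else (req_l,))
                and stat_b[r] in (("UP", "DOWN") if req_r == "ANY" else (req_r,))
            }
            assert got == expected, f"trial {trial}"


class TestRankPairs:
    def _pairs(self, cs_values, names):
        rows = [
            {
                "mode": "autocrine",
                "method": 1,
                "source_cell": "IMAdC",
                "target_cell": "IMAdC",
                "ligand": l,
                "receptor": r,
                "ligand_log2fc": 1.0,
                "receptor_log2fc": 1.0,
                "fc_ligand": 2.0,
                "fc_receptor": 2.0,
                "cs": c,
            }
            for (l, r), c in zip(names, cs_values)
        ]
        return pd.DataFrame(rows)

    def test_tie_broken_alphabetically(self):
        pairs = self._pairs([8.0, 2.0, 2.0], [("B", "X"), ("C", "Y"), ("A", "Z")])
        ranked = rank_pairs(pairs)
        assert list(ranked["ligand"]) == ["B", "A", "C"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_single_pair_rank_one(self):
        ranked = rank_pairs(self._pairs([3.0], [("A", "B")]))
        assert list(ranked["rank"]) == [1]

    def test_permutation_invariant(self):
        pairs = self._pairs([5.0, 9.0, 1.0], [("A", "B"), ("C", "D"), ("E", "F")])
        r1 = rank_pairs(pairs)
        r2 = rank_pairs(pairs.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(r1, r2)

    def test_increasing_magnitude_never_worsens_rank(self):
        pairs = self._pairs([4.0, 8.0], [("A", "B"), ("C", "D")])
        before = rank_pairs(pairs)
        boosted = pairs.copy()
        boosted.loc[0, "cs"] = 16.0  # raise |log2fc| of pair (A,B)
        after = rank_pairs(boosted)
        rank_before = before.set_index("ligand")["rank"]["A"]
        rank_after = after.set_index("ligand")["rank"]["A"]
        assert rank_after <= rank_before


class TestRunCrosstalk:
    def _study_results(self, seed):
        planted = tuple(
            [(f"G{i:03d}", SMSC_CONTRAST, 2.0) for i in range(1, 21)]
            + [(f"G{i:03d}", IMADC_CONTRAST, -2.0) for i in range(21, 41)]
        )
        config = SimulationConfig(
            n_genes=300,
            dispersion=0.05,
            baseline_log2_mean=9.0,
            baseline_log2_sd=0.0,
            planted_de=planted,
            seed=seed,
        )
        counts, _ = generate_counts(config)
        db, truth = generate_lr_scenario(config, n_true_pairs=2, n_decoys=5)
        f = filter_low_counts(counts)
        sf = size_factors(f)
        disp = estimate_dispersion(f, sf)
        results = {
            spec.name: nb_wald_contrast(f, spec, disp, sf) for spec in study_contrasts()
        }
        return results, db, truth

    def test_planted_pairs_recovered_in_their_stratum(self):
        results, db, truth = self._study_results(seed=0)
        table = run_crosstalk(results, db)
        stratum = table[
            (table["mode"] == "paracrine")
            & (table["method"] == 1)
            & (table["source_cell"] == "SMSC")
        ]
        got = set(zip(stratum["ligand"], stratum["receptor"]))
        expected = {(p["ligand"], p["receptor"]) for p in truth.true_lr_pairs}
        assert got == expected

    def test_null_data_empty_table(self):
        config = SimulationConfig(n_genes=100, seed=5)
        counts, _ = generate_counts(config)
        f = filter_low_counts(counts)
        sf = size_factors(f)
        disp = estimate_dispersion(f, sf)
        results = {
            spec.name: nb_wald_contrast(f, spec, disp, sf) for spec in study_contrasts()
        }
        db = LRDatabase(frozenset({("G001", "G002"), ("G003", "G004")}))
        assert run_crosstalk(results, db).empty

    def test_missing_contrast_named(self):
        results, db, _ = self._study_results(seed=1)
        del results[CO_CONTRAST]
        with pytest.raises(ValueError, match=CO_CONTRAST):
            run_crosstalk(results, db)

    def test_emitted_pairs_sound(self):
        results, db, _ = self._study_results(seed=2)
        table = run_crosstalk(results, db)
        for row in table.itertuples(index=False):
            assert (row.ligand, row.receptor) in db.pairs
            assert row.cs == pytest.approx(row.fc_ligand * row.fc_receptor)
            if row.mode == "autocrine":
                assert row.source_cell == row.target_cell

    def test_default_rules_cover_both_methods_and_modes(self):
        rules = default_rules()
        assert len(rules) == 8
        combos = {(r.mode, r.method) for r in rules}
        assert combos == {("autocrine", 1), ("autocrine", 2), ("paracrine", 1), ("paracrine", 2)}
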