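"""Differential abundance, SAP classification and signature-set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from senosig import signature_derivation as sig
from conftest import make_records


class TestDifferentialAbundance:
    def test_identical_constant_matrices(self):
        m = pd.DataFrame(np.full((5, 3), 7.0), index=list("abcde"))
        rec = sig.differential_abundance(m, m.copy())
        assert (rec["log2fc"] == 0).all()
        assert (rec["p_adj"] == 1.0).all()

    def test_planted_effect_recovered(self):
        # strong planted effect, tiny noise: estimate within +-0.2, q < 0.05
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pro = pd.DataFrame(rng.normal(8.0, 0.1, (50, 4)))
            sen = pro + rng.normal(0.0, 0.1, (50, 4))
            sen.iloc[:10] += 2.0
            rec = sig.differential_abundance(pro, sen)
            top = rec.iloc[:10]
            ok = (top["log2fc"].sub(2.0).abs() < 0.2) & (top["p_adj"] < 0.05)
            hits += ok.all()
        assert hits >= 9

    def test_bh_monotone_in_rank(self, rng):
        pro = pd.DataFrame(rng.normal(size=(40, 4)))
        sen = pd.DataFrame(rng.normal(size=(40, 4)))
        rec = sig.differential_abundance(pro, sen)
        by_p = rec.sort_values("p_value")
        assert by_p["p_adj"].is_monotonic_increasing

    def test_errors(self):
        m = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="replicates"):
            sig.differential_abundance(m.iloc[:, :1], m)
        other = pd.DataFrame(np.ones((3, 4)), index=[9, 10, 11])
        with pytest.raises(ValueError, match="mismatched"):
            sig.differential_abundance(m, other)


class TestClassification:
    def test_rule_forced_cases(self):
        rec = make_records(
            [
                # elevated in IR + ETO for astrocytes only -> SAP
                ("A", "astrocyte", "IR", 1.0, 0.01),
                ("A", "astrocyte", "ETO", 1.5, 0.01),
                # elevated in IR only -> inconclusive
                ("B", "astrocyte", "IR", 1.0, 0.01),
                ("B", "astrocyte", "ETO", 0.5, 0.80),
                # negative everywhere -> non-SAP
                ("C", "astrocyte", "IR", -1.0, 0.01),
                ("C", "astrocyte", "ETO", -0.5, 0.01),
            ]
        )
        status = sig.classify_senescence_status(rec)
        assert status["A"] == "SAP"
        assert status["B"] == "inconclusive"
        assert status["C"] == "non-SAP"

    def test_exhaustive_two_induction_patterns(self):
        """All elevation patterns over 3 cell types x 2 inductions."""
        cts = ["ct1", "ct2", "ct3"]
        inds = ["IR", "ETO"]
        cells = [(c, i) for c in cts for i in inds]
        rows = []
        expected = {}
        for pattern in range(2 ** len(cells)):
            prot = f"P{pattern:02d}"
            bits = [(pattern >> k) & 1 for k in range(len(cells))]
            for (ct, ind), bit in zip(cells, bits):
                rows.append((prot, ct, ind, 1.0 if bit else -1.0, 0.01))
            per_ct = {
                c: {i for (cc, i), b in zip(cells, bits) if cc == c and b}
                for c in cts
            }
            if any(len(v) == 2 for v in per_ct.values()):
                expected[prot] = "SAP"
            elif any(per_ct.values()):
                expected[prot] = "inconclusive"
            else:
                expected[prot] = "non-SAP"
        status = sig.classify_senescence_status(make_records(rows))
        assert status.to_dict() == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        prots = [f"P{i}" for i in range(rng.integers(3, 15))]
        for p in prots:
            for ct in ["x", "y"]:
                for ind in ["IR", "ETO"]:
                    rows.append(
                        (p, ct, ind, rng.normal(), float(rng.uniform()))
                    )
        status = sig.classify_senescence_status(make_records(rows))
        counts = status.value_counts()
        assert counts.sum() == len(prots)
        assert set(status.unique()) <= {"SAP", "non-SAP", "inconclusive"}

    def test_ir_plus_chemical_vs_any_two(self):
        rec = make_records(
            [
                ("A", "ct", "IR", 0.5, 0.90),
                ("A", "ct", "ETO", 1.0, 0.01),
                ("A", "ct", "DOXO", 1.0, 0.01),
            ]
        )
        assert sig.classify_senescence_status(rec)["A"] == "inconclusive"
        assert sig.classify_senescence_status(rec, rule="any-two")["A"] == "SAP"


class TestSignatureSets:
    def test_mean_qualifying_log2fc(self):
        rec = make_records(
            [
                ("A", "ct", "IR", 1.0, 0.01),
                ("A", "ct", "ETO", 2.0, 0.01),
                ("B", "ct", "IR", 1.0, 0.01),
                ("B", "ct", "ETO", 0.5, 0.90),  # IR only -> non-member
            ]
        )
        out = sig.cell_type_signature(rec, "ct")
        assert out.set_index("protein")["mean_log2fc"].to_dict() == {"A": 1.5}

    def test_unknown_cell_type(self, default_records):
        with pytest.raises(KeyError):
            sig.cell_type_signature(default_records, "hepatocyte")

    def test_exclusive_set_algebra(self):
        sigs = {"a": {"P1", "P2"}, "b": {"P2", "P3"}, "c": {"P4"}}
        assert sig.exclusive_signature(sigs, "a") == {"P1"}
        assert sig.exclusive_signature(sigs, "b") == {"P3"}
        assert sig.exclusive_signature(sigs, "c") == {"P4"}
        # pairwise disjoint
        ex = [sig.exclusive_signature(sigs, k) for k in sigs]
        assert len(set().union(*ex)) == sum(len(e) for e in ex)
        # degenerate one-cell-type universe
        assert sig.exclusive_signature({"a": {"P1", "P2"}}, "a") == {"P1", "P2"}

    def test_core_threshold_and_monotonicity(self):
        sigs = {f"ct{i}": set() for i in range(14)}
        for i in range(9):
            sigs[f"ct{i}"].add("IN9")
        for i in range(8):
            sigs[f"ct{i}"].add("IN8")
        assert sig.core_signature(sigs, 9) == {"IN9"}
        assert "IN8" not in sig.core_signature(sigs, 9)
        assert sig.core_signature(sigs, 1) == {"IN9", "IN8"}
        for k in range(1, 14):
            assert sig.core_signature(sigs, k + 1) <= sig.core_signature(sigs, k)
        with pytest.raises(ValueError):
            sig.core_signature(sigs, 0)


class TestDetectionCrosstab:
    def test_balanced_table_p_one(self):
        assert sig.fisher_exact_rxc(np.array([[5, 5], [5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_identical_panels_p_one(self):
        status = pd.Series(
            ["SAP"] * 5 + ["non-SAP"] * 5 + ["inconclusive"] * 5,
            index=[f"P{i}" for i in range(15)],
        )
        panel = [f"P{i}" for i in range(15)]
        table, pvals = sig.detection_crosstab(status, panel, panel)
        assert pvals["overall"] == pytest.approx(1.0)
        assert (table.iloc[:, 0] == table.iloc[:, 1]).all()

    def test_2x2_matches_hypergeometric_enumeration(self):
        # brute-force oracle: enumerate the hypergeometric distribution
        def oracle(a, b, c, d):
            n = a + b + c + d
            obs = sps.hypergeom.pmf(a, n, a + b, a + c)
            ps = sps.hypergeom.pmf(
                np.arange(0, min(a + b, a + c) + 1), n, a + b, a + c
            )
            return ps[ps <= obs + 1e-9].sum()

        for table in [(8, 2, 1, 5), (3, 0, 2, 7), (4, 4, 4, 4), (0, 6, 6, 0)]:
            a, b, c, d = table
            got = sig.fisher_exact_rxc(np.array([[a, b], [c, d]]))
            assert got == pytest.approx(oracle(a, b, c, d), abs=1e-10)

    def test_empty_panel_rejected(self):
        status = pd.Series({"P1": "SAP"})
        with pytest.raises(ValueError):
            sig.detection_crosstab(status, [], ["P1"])


class TestTissueSupport:
    def test_proportions(self):
        atlas = pd.DataFrame(
            {
                "protein": ["P1", "P2", "P3", "P4"] * 2,
                "section": ["s1"] * 4 + ["s2"] * 4,
                "level": ["high", "medium", "medium", "low"]
                + ["not detected"] * 4,
            }
        )
        prop = sig.tissue_support_proportion({"P1", "P2", "P3", "P4"}, atlas)
        assert prop["s1"] == pytest.approx(0.75)
        assert prop["s2"] == pytest.approx(0.0)
        assert list(prop.index) == ["s1", "s2"]

    def test_disjoint_signature_rejected(self):
        atlas = pd.DataFrame(
            {"protein": ["P1"], "section": ["s"], "level": ["high"]}
        )
        with pytest.raises(ValueError):
            sig.tissue_support_proportion({"QQ"}, atlas)

    def test_planted_enrichment_ranks_matched_first(self):
        from senosig import synthetic_data as syn

        sigs = {"PBMC": {f"P{i}" for i in range(40)}}
        wins = 0
        for s in range(10):
            atlas = syn.simulate_tissue_atlas(sigs, seed=s, enrichment=0.5)
            prop = sig.tissue_support_proportion(sigs["PBMC"], atlas)
            wins += prop.index[0] == "PBMC_matched"
        assert wins >= 9
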