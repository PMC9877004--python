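"""Panel selection and 2^-ddCt qPCR analytics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wbgr import panel_qpcr as pq, synthetic_data as synth
from wbgr.errors import DesignError, EmptyOutputError, InsufficientDataError
from wbgr.types import PanelDefinition, QpcrSheet

from conftest import make_sheet


class TestGbmDxFixture:
    def test_panel_composition(self):
        panel = pq.load_gbm_dx_panel()
        assert len(panel) == 10
        classes = panel.entries["rna_class"].value_counts()
        assert classes["mRNA"] == 7
        assert classes["lncRNA"] == 1
        assert classes["miRNA"] == 2
        dirs = panel.entries.set_index("gene_id")["expected_direction"]
        assert set(dirs[dirs == "up"].index) == {
            "MMP9", "TMEM92", "C1orf226", "CD163", "LINC00482", "miR-3918"
        }
        assert set(dirs[dirs == "down"].index) == {"AK5", "CD200", "MICU3", "miR-760"}


def _gbm_sheet(n_ctrl, n_gbm):
    rows = [(f"c{i}", f"dc{i}", "control", "M", "post", "mRNA") for i in range(n_ctrl)]
    rows += [(f"p{i}", f"dp{i}", "GBM", "F", "post", "mRNA") for i in range(n_gbm)]
    return make_sheet(rows)


class TestSampleFrequency:
    def _centered(self, gbm_values):
        cols = [f"p{i}" for i in range(len(gbm_values))]
        return pd.DataFrame([gbm_values], index=["g"], columns=cols)

    def test_counting_oracle(self):
        centered = self._centered([2.0, 1.5, -0.1, 0.8, 2.2])
        sheet = _gbm_sheet(0, 5)
        freq = pq.compute_sample_frequency(centered, sheet, {"g": "up"}, margin=0.5)
        assert freq["g"] == pytest.approx(0.8)

    def test_flat_samples_have_zero_frequency(self):
        centered = self._centered([0.0, 0.0, 0.0])
        freq = pq.compute_sample_frequency(
            centered, _gbm_sheet(0, 3), {"g": "up"}, margin=0.5
        )
        assert freq["g"] == 0.0

    def test_margin_zero_counts_any_positive_move(self):
        centered = self._centered([0.2, 0.9, 1.4])
        freq = pq.compute_sample_frequency(
            centered, _gbm_sheet(0, 3), {"g": "up"}, margin=0.0
        )
        assert freq["g"] == 1.0

    def test_down_gene_uses_negative_margin(self):
        centered = self._centered([-2.0, -0.2, 0.4])
        freq = pq.compute_sample_frequency(
            centered, _gbm_sheet(0, 3), {"g": "down"}, margin=0.5
        )
        assert freq["g"] == pytest.approx(1 / 3)

    def test_frequency_monotone_in_margin(self, rng):
        centered = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"p{i}" for i in range(6)],
        )
        sheet = _gbm_sheet(0, 6)
        directions = {f"g{i}": ("up" if i % 2 else "down") for i in range(10)}
        prev = None
        for margin in (0.0, 0.25, 0.5, 1.0):
            freq = pq.compute_sample_frequency(centered, sheet, directions, margin)
            if prev is not None:
                assert (freq <= prev + 1e-12).all()
            prev = freq

    def test_no_gbm_samples_is_design_error(self):
        centered = pd.DataFrame([[1.0]], index=["g"], columns=["c0"])
        with pytest.raises(DesignError):
            pq.compute_sample_frequency(
                centered, _gbm_sheet(1, 0), {"g": "up"}, margin=0.5
            )


class TestSelectPanel:
    DIRS = {"A": "up", "B": "up", "C": "down", "D": "down", "E": "down"}

    def test_rule_tracing_example(self):
        freq = pd.Series({"A": 0.8, "B": 0.6, "C": 0.7, "D": 0.55, "E": 0.52})
        panel = pq.select_panel_candidates(freq, self.DIRS, min_frequency=0.5)
        assert set(panel.gene_ids) == {"A", "B", "C"}
        ups = (panel.entries["expected_direction"] == "up").mean()
        assert ups == pytest.approx(2 / 3)

    def test_single_up_gene(self):
        freq = pd.Series({"A": 0.9})
        panel = pq.select_panel_candidates(freq, {"A": "up"})
        assert panel.gene_ids == ["A"]

    def test_boundary_frequency_excluded(self):
        freq = pd.Series({"A": 0.5, "B": 0.7})
        panel = pq.select_panel_candidates(freq, {"A": "up", "B": "up"})
        assert panel.gene_ids == ["B"]

    def test_empty_candidates_is_error(self):
        freq = pd.Series({"A": 0.3})
        with pytest.raises(EmptyOutputError):
            pq.select_panel_candidates(freq, {"A": "up"})

    def test_target_size_with_tie_breaks(self):
        freq = pd.Series({"A": 0.9, "B": 0.9, "C": 0.8, "D": 0.8})
        dirs = {"A": "up", "B": "up", "C": "up", "D": "down"}
        lfc = {"A": 1.0, "B": 3.0, "C": 2.0, "D": 2.0}
        panel = pq.select_panel_candidates(
            freq, dirs, target_size=2, log2fc=lfc
        )
        assert panel.gene_ids == ["B", "A"]  # |lfc| breaks the 0.9 tie

    def test_constraint_invariants_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            genes = [f"g{i}" for i in range(n)]
            freq = pd.Series(rng.uniform(0.3, 1.0, size=n), index=genes)
            dirs = {g: ("up" if rng.random() < 0.4 else "down") for g in genes}
            try:
                panel = pq.select_panel_candidates(freq, dirs, min_frequency=0.5)
            except EmptyOutputError:
                continue
            share = (panel.entries["expected_direction"] == "up").mean()
            assert share >= 0.5
            assert (freq[panel.gene_ids] > 0.5).all()


def _manual_qpcr_sheet():
    # one control, one GBM sample; mRNA target + GAPDH reference
    rows = []
    for sid, grp, target_ct in (("c0", "control", 24.0), ("p0", "GBM", 25.0)):
        for rep in (1, 2, 3):
            rows.append((sid, grp, "GAPDH", "mRNA", rep, 20.0))
            rows.append((sid, grp, "TG1", "mRNA", rep, target_ct))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "gene_id", "rna_class", "replicate_index", "ct_value"],
    )
    return QpcrSheet(df)


class TestDdctAnalysis:
    def test_hand_worked_example(self):
        ddct = pq.ddct_analysis(_manual_qpcr_sheet()).set_index(["sample_id", "gene_id"])
        row = ddct.loc[("p0", "TG1")]
        assert row["ddct"] == pytest.approx(1.0)
        assert row["fold_change"] == pytest.approx(0.5)
        assert row["log2fc"] == pytest.approx(-1.0)

    def test_control_centering_identity(self):
        ddct = pq.ddct_analysis(_manual_qpcr_sheet())
        ctrl = ddct[(ddct["group"] == "control") & (ddct["gene_id"] == "TG1")]
        assert ctrl["log2fc"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_reference_gene_fold_change_is_one(self):
        ddct = pq.ddct_analysis(_manual_qpcr_sheet())
        ref = ddct[ddct["gene_id"] == "GAPDH"]
        np.testing.assert_allclose(ref["fold_change"], 1.0)

    def test_noise_free_generator_inversion(self):
        panel = pq.load_gbm_dx_panel()
        planted = {g: (2.0 if d == "up" else -1.5) for g, d in panel.directions().items()}
        sheet = synth.simulate_qpcr(
            panel, n_control=3, n_gbm=3, planted_log2fc=planted,
            ct_noise_sd=0.0, seed=6,
        )
        ddct = pq.ddct_analysis(sheet)
        gbm = ddct[ddct["group"] == "GBM"].set_index(["sample_id", "gene_id"])
        for g, lfc in planted.items():
            vals = gbm.xs(g, level="gene_id")["log2fc"]
            np.testing.assert_allclose(vals, lfc, atol=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        # planted +1 with 0.2 Ct noise, n=5/group: mean recovered log2fc
        # stays within +-0.3 across seeds
        panel = PanelDefinition(
            pd.DataFrame(
                {"gene_id": ["TG1"], "rna_class": ["mRNA"], "expected_direction": ["up"]}
            )
        )
        recovered = []
        for s in range(100):
            sheet = synth.simulate_qpcr(
                panel, n_control=5, n_gbm=5, planted_log2fc={"TG1": 1.0},
                ct_noise_sd=0.2, seed=9000 + s,
            )
            ddct = pq.ddct_analysis(sheet)
            gbm = ddct[(ddct["group"] == "GBM") & (ddct["gene_id"] == "TG1")]
            recovered.append(gbm["log2fc"].mean())
        assert abs(np.mean(recovered) - 1.0) <= 0.3
        assert np.mean([abs(r - 1.0) <= 0.3 for r in recovered]) >= 0.9


class TestGroupComparison:
    def test_identical_groups_give_half(self):
        ddct = pd.DataFrame(
            {
                "gene_id": ["g"] * 4,
                "group": ["GBM", "GBM", "control", "control"],
                "log2fc": [1.0, 1.0, 1.0, 1.0],
            }
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = pq.compare_groups_onesided(ddct, {"g": "up"})
        assert res.loc["g", "p_value"] == 0.5

    def test_strong_up_gene_is_significant(self):
        ddct = pd.DataFrame(
            {
                "gene_id": ["g"] * 8,
                "group": ["GBM"] * 4 + ["control"] * 4,
                "log2fc": [3.0, 3.2, 2.8, 3.1, 0.0, 0.1, -0.1, 0.05],
            }
        )
        res = pq.compare_groups_onesided(ddct, {"g": "up"})
        assert res.loc["g", "p_value"] < 0.001

    def test_misoriented_direction_gives_large_p(self):
        ddct = pd.DataFrame(
            {
                "gene_id": ["g"] * 8,
                "group": ["GBM"] * 4 + ["control"] * 4,
                "log2fc": [-2.0, -2.1, -1.9, -2.2, 0.0, 0.1, -0.1, 0.05],
            }
        )
        res = pq.compare_groups_onesided(ddct, {"g": "up"})
        assert res.loc["g", "p_value"] > 0.5

    def test_too_few_samples_is_error(self):
        ddct = pd.DataFrame(
            {"gene_id": ["g", "g"], "group": ["GBM", "control"], "log2fc": [1.0, 0.0]}
        )
        with pytest.raises(InsufficientDataError):
            pq.compare_groups_onesided(ddct, {"g": "up"})


class TestPatientProfile:
    def _values(self, blood, tissue, genes):
        rows = []
        for g, v in zip(genes, blood):
            rows.append(("P21", "blood", g, v))
        for g, v in zip(genes, tissue):
            rows.append(("P21", "tissue", g, v))
        return pd.DataFrame(rows, columns=["patient_id", "specimen", "gene_id", "value"])

    def test_identical_specimens_have_equal_sums(self):
        panel = pq.load_gbm_dx_panel()
        vals = [1.0] * 10
        prof = pq.patient_panel_profile(
            self._values(vals, vals, panel.gene_ids), panel
        )
        assert prof.loc[("P21", "blood"), "panel_sum"] == pytest.approx(
            prof.loc[("P21", "tissue"), "panel_sum"]
        )

    def test_shifted_tissue_raises_sum_by_gene_count(self):
        panel = pq.load_gbm_dx_panel()
        blood = list(np.linspace(-1, 2, 10))
        tissue = [v + 1 for v in blood]
        prof = pq.patient_panel_profile(self._values(blood, tissue, panel.gene_ids), panel)
        diff = prof.loc[("P21", "tissue"), "panel_sum"] - prof.loc[("P21", "blood"), "panel_sum"]
        assert diff == pytest.approx(10.0)

    def test_missing_genes_are_gaps_not_zeros(self):
        panel = pq.load_gbm_dx_panel()
        genes = panel.gene_ids[:4]
        prof = pq.patient_panel_profile(
            self._values([1, 2, 3, 4], [1, 2, 3, 4], genes), panel
        )
        assert prof.loc[("P21", "blood"), panel.gene_ids[5]] != prof.loc[
            ("P21", "blood"), panel.gene_ids[5]
        ]  # NaN
        assert prof.loc[("P21", "blood"), "panel_sum"] == pytest.approx(10.0)

    def test_no_panel_genes_is_error(self):
        panel = pq.load_gbm_dx_panel()
        vals = pd.DataFrame(
            [("P1", "blood", "OTHER", 1.0)],
            columns=["patient_id", "specimen", "gene_id", "value"],
        )
        with pytest.raises(InsufficientDataError):
            pq.patient_panel_profile(vals, panel)

    def test_concordant_specimens_rank_correlate(self):
        # blood and tissue qPCR generated from the same planted effects
        # should agree in per-gene ranking
        panel = pq.load_gbm_dx_panel()
        planted = {
            g: (2.0 if d == "up" else -2.0) + 0.2 * i
            for i, (g, d) in enumerate(panel.directions().items())
        }
        profiles = {}
        for specimen, seed in (("blood", 31), ("tissue", 32)):
            sheet = synth.simulate_qpcr(
                panel, n_control=3, n_gbm=1, planted_log2fc=planted,
                ct_noise_sd=0.2, seed=seed,
            )
            ddct = pq.ddct_analysis(sheet)
            gbm = ddct[ddct["group"] == "GBM"].set_index("gene_id")
            profiles[specimen] = gbm.loc[panel.gene_ids, "log2fc"]
        rho = stats.spearmanr(profiles["blood"], profiles["tissue"]).statistic
        assert rho > 0.8
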