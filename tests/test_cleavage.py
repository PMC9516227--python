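"""The terminal-block cleavage detector, against fixtures and oracles."""

import numpy as np
import pandas as pd
import pytest

from sheddex.cleavage import (
    boundary_grid,
    call_substrates,
    detect_substrates,
    peptide_stats,
    site_report,
    sweep_boundaries,
)
from tests._oracles import brute_force_calls
from tests.conftest import make_peptide_table


def stats_frame(pid, midpoints, log2fcs, pvals):
    """Assemble a peptide_stats-shaped frame directly (length 1000)."""
    midpoints = np.asarray(midpoints, dtype=float)
    start = np.maximum((midpoints * 2000 / 2).astype(int) - 4, 1)
    return pd.DataFrame(
        {
            "protein_id": pid,
            "peptide": [f"PEP{i}" for i in range(len(midpoints))],
            "start": start,
            "end": start + 8,
            "midpoint_frac": midpoints,
            "log2fc": np.asarray(log2fcs, dtype=float),
            "t": 0.0,
            "p": np.asarray(pvals, dtype=float),
            "n_case_obs": 10,
            "n_control_obs": 10,
        }
    )


class TestPeptideStats:
    def build(self, case_obs, n_case, ctrl_obs, n_ctrl):
        case = np.ones((1, n_case))
        case[0, case_obs:] = np.nan
        ctrl = np.full((1, n_ctrl), 2.0)
        ctrl[0, ctrl_obs:] = np.nan
        return make_peptide_table([("P1", "AAK", 10, 12)], case, ctrl)

    def test_majority_quantified_peptide_retained(self):
        # 10/18 (56%) and 11/20 (55%) both exceed the 50% rule
        table = self.build(10, 18, 11, 20)
        out = peptide_stats(table, {"P1": 100})
        assert len(out) == 1
        assert out.loc[0, "n_case_obs"] == 10
        assert out.loc[0, "n_control_obs"] == 11

    def test_under_half_quantified_peptide_excluded(self):
        table = self.build(18, 18, 9, 20)  # 9/20 = 45% in control
        assert len(peptide_stats(table, {"P1": 100})) == 0

    def test_exactly_half_is_not_over_half(self):
        table = self.build(9, 18, 20, 20)
        assert len(peptide_stats(table, {"P1": 100})) == 0

    def test_identical_groups_give_null_statistics(self):
        case = np.tile([1.0, 2.0, 3.0], (1, 1))
        table = make_peptide_table([("P1", "AAK", 40, 60)], case, case)
        out = peptide_stats(table, {"P1": 100})
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0
        assert out.loc[0, "log2fc"] == 0.0
        assert out.loc[0, "midpoint_frac"] == pytest.approx(0.5)

    def test_unknown_protein_length_is_error(self):
        table = self.build(10, 18, 11, 20)
        with pytest.raises(KeyError, match="length"):
            peptide_stats(table, {"OTHER": 100})


class TestSweep:
    def test_grid_has_91_boundaries(self):
        assert len(boundary_grid()) == 91
        grid = boundary_grid()
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(0.95)

    def test_flat_protein_has_zero_factor_everywhere(self):
        stats = stats_frame("P1", [0.1, 0.3, 0.6, 0.9], [0, 0, 0, 0],
                            [1, 1, 1, 1])
        sweep = sweep_boundaries(stats)
        valid = sweep[sweep["valid"]]
        assert len(sweep) == 91
        assert (valid["factor"] == 0).all()

    def test_boundary_counts_partition_all_peptides(self):
        stats = stats_frame("P1", [0.1, 0.2, 0.5, 0.7, 0.9],
                            [0, 0, 1, 1, 1], [0.5] * 5)
        sweep = sweep_boundaries(stats)
        assert (sweep["n_block"] + sweep["n_rest"] == 5).all()
        # invalid boundaries are flagged with p_sep 1
        invalid = sweep[~sweep["valid"]]
        assert (invalid["p_sep"] == 1.0).all()

    def test_planted_step_maximizes_separation_at_true_boundary(self):
        mids = [0.10, 0.20, 0.30, 0.38, 0.55, 0.70, 0.85, 0.95]
        lfc = [-1.6, -1.58, -1.62, -1.6, 0.01, -0.02, 0.0, 0.02]
        stats = stats_frame("P1", mids, lfc, [0.001] * 4 + [0.9] * 4)
        sweep = sweep_boundaries(stats)
        valid = sweep[sweep["valid"]]
        best = valid.loc[valid["p_sep"].idxmin()]
        assert 0.38 <= best["boundary"] < 0.55
        assert best["factor"] == pytest.approx(-1.6, abs=0.05)

    def test_fewer_than_four_peptides_rejected(self):
        stats = stats_frame("P1", [0.2, 0.5, 0.8], [0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError, match="4"):
            sweep_boundaries(stats)


class TestCalls:
    def run_calls(self, mids, lfc, pvals, **kw):
        stats = stats_frame("P1", mids, lfc, pvals)
        return call_substrates(sweep_boundaries(stats), **kw)

    def test_uniform_reduction_rejected_by_secretion_guard(self):
        calls = self.run_calls(
            [0.1, 0.25, 0.4, 0.6, 0.75, 0.9], [-1.0] * 6, [0.001] * 6
        )
        assert calls.empty

    def test_n_terminal_block_reduction_called(self):
        calls = self.run_calls(
            [0.1, 0.2, 0.3, 0.55, 0.65, 0.75, 0.85, 0.95],
            [-1.6, -1.6, -1.6, 0.0, 0.05, -0.05, 0.0, 0.02],
            [0.001] * 3 + [0.9] * 5,
        )
        assert len(calls) == 1
        call = calls.iloc[0]
        assert call["side"] == "N_side"
        assert call["direction"] == "reduced_in_case"
        assert call["n_sig_block"] == 3
        assert call["boundary"] < 0.55

    def test_c_terminal_event_called_via_rest_segment(self):
        calls = self.run_calls(
            [0.1, 0.2, 0.3, 0.55, 0.65, 0.75, 0.85, 0.95],
            [0.0, 0.05, -0.05, 0.0, -1.6, -1.7, -1.6, -1.65],
            [0.9] * 4 + [0.001] * 4,
        )
        assert len(calls) == 1
        call = calls.iloc[0]
        assert call["side"] == "C_side"
        assert call["direction"] == "reduced_in_case"
        assert 0.55 <= call["boundary"] < 0.65

    def test_single_significant_peptide_insufficient(self):
        calls = self.run_calls(
            [0.1, 0.2, 0.3, 0.55, 0.65, 0.75, 0.85, 0.95],
            [-1.6, -0.3, -0.3, 0.0, 0.05, -0.05, 0.0, 0.02],
            [0.001] + [0.9] * 7,
        )
        assert calls.empty

    def test_increased_block_gets_increased_direction(self):
        calls = self.run_calls(
            [0.1, 0.2, 0.3, 0.55, 0.65, 0.75, 0.85, 0.95],
            [1.6, 1.6, 1.6, 0.0, 0.05, -0.05, 0.0, 0.02],
            [0.001] * 3 + [0.9] * 5,
        )
        assert len(calls) == 1
        assert calls.iloc[0]["direction"] == "increased_in_case"

    def test_min_sig_below_two_rejected(self):
        stats = stats_frame("P1", [0.1, 0.3, 0.6, 0.9], [0] * 4, [1] * 4)
        with pytest.raises(ValueError):
            call_substrates(sweep_boundaries(stats), min_sig=1)


def random_stats(rng, pid):
    """A random small protein profile; some get a planted terminal step."""
    m = rng.integers(4, 13)
    mids = np.sort(rng.uniform(0.02, 0.98, size=m))
    kind = rng.integers(0, 3)
    if kind == 0:  # null
        lfc = rng.normal(0, 0.2, size=m)
        p = rng.uniform(0.01, 1, size=m)
    elif kind == 1:  # terminal step
        b = rng.uniform(0.2, 0.8)
        side = rng.random() < 0.5
        on = mids <= b if side else mids > b
        lfc = np.where(on, rng.normal(-1.6, 0.1, size=m),
                       rng.normal(0, 0.1, size=m))
        p = np.where(on, rng.uniform(0, 0.05, size=m),
                     rng.uniform(0.1, 1, size=m))
    else:  # uniform shift (secretion-like)
        lfc = rng.normal(1.0, 0.15, size=m)
        p = rng.uniform(0, 0.2, size=m)
    return stats_frame(pid, mids, lfc, p)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_small_proteins(self):
        rng = np.random.default_rng(42)
        frames = [random_stats(rng, f"P{i:03d}") for i in range(200)]
        sweeps = pd.concat(
            [sweep_boundaries(f) for f in frames], ignore_index=True
        )
        calls = call_substrates(sweeps).set_index("protein_id")
        n_called = 0
        for frame in frames:
            pid = frame["protein_id"].iloc[0]
            expected = brute_force_calls(
                list(zip(frame["midpoint_frac"], frame["log2fc"], frame["p"]))
            )
            if expected is None:
                assert pid not in calls.index
                continue
            n_called += 1
            got = calls.loc[pid]
            assert got["boundary"] == pytest.approx(expected["boundary"],
                                                    abs=1e-12)
            assert got["side"] == expected["side"]
            assert got["direction"] == expected["direction"]
            assert got["n_sig_block"] == expected["n_sig"]
            assert got["n_block"] == expected["n_block"]
            assert got["n_rest"] == expected["n_rest"]
            assert got["factor"] == pytest.approx(expected["factor"],
                                                  rel=1e-9)
            assert got["p_sep"] == pytest.approx(expected["p_sep"], rel=1e-9,
                                                 abs=1e-300)
        assert n_called >= 20  # the planted third should mostly be called

    def test_label_swap_antisymmetry(self, small_catalog):
        from sheddex import preprocess, simulate

        truth = simulate.plan_truth(small_catalog, n_shed=4, n_secretion=0,
                                    seed=3)
        design = simulate.SimDesign(n_case=8, n_control=8, cv=0.2,
                                    missing_rate=0.0, seed=4)
        table = simulate.simulate_study(small_catalog, design, truth)
        ratios = preprocess.normalize_peptides_to_reference(table)
        flipped_groups = {
            s: ({"case": "control", "control": "case"}.get(g, g))
            for s, g in ratios.groups.items()
        }
        from sheddex.io import PeptideQuantTable

        flipped = PeptideQuantTable(data=ratios.data, groups=flipped_groups)
        lengths = small_catalog.lengths
        c1, p1 = detect_substrates(ratios, lengths, return_profiles=True)
        c2, p2 = detect_substrates(flipped, lengths, return_profiles=True)
        assert set(c1["protein_id"]) == set(c2["protein_id"])
        merged = c1.merge(c2, on="protein_id", suffixes=("_a", "_b"))
        assert (merged["boundary_a"] == merged["boundary_b"]).all()
        assert (merged["side_a"] == merged["side_b"]).all()
        assert (
            merged["direction_a"] != merged["direction_b"]
        ).all()
        np.testing.assert_allclose(merged["factor_a"], -merged["factor_b"],
                                   rtol=1e-9)
        np.testing.assert_allclose(merged["p_sep_a"], merged["p_sep_b"],
                                   rtol=1e-9)


class TestFoldMonotonicity:
    def test_stronger_planted_folds_never_lose_true_positives(
        self, small_catalog
    ):
        from sheddex import preprocess, simulate

        tp = {}
        for fold in (1 / 2, 1 / 4):
            truth = simulate.plan_truth(
                small_catalog, n_shed=6, n_secretion=0, shed_fold=fold,
                seed=21,
            )
            design = simulate.SimDesign(n_case=8, n_control=8, cv=0.25,
                                        missing_rate=0.1, seed=22)
            table = simulate.simulate_study(small_catalog, design, truth)
            ratios = preprocess.normalize_peptides_to_reference(table)
            calls = detect_substrates(ratios, small_catalog.lengths)
            tp[fold] = sum(
                pid in truth.shed_ids for pid in calls["protein_id"]
            )
        assert tp[1 / 4] >= tp[1 / 2]


class TestSiteReport:
    def make_calls(self, boundary):
        return pd.DataFrame(
            [{"protein_id": "P1", "boundary": boundary, "side": "N_side",
              "direction": "reduced_in_case", "n_sig_block": 3,
              "factor": -1.5, "p_sep": 1e-6, "n_block": 5, "n_rest": 5}]
        )

    def test_distance_to_annotated_site(self):
        rep = site_report(self.make_calls(0.90), {"P1": [688]}, {"P1": 770})
        assert rep.loc[0, "implied_residue"] == 693
        assert rep.loc[0, "distance"] == 5

    def test_no_annotation_gives_empty_report(self):
        rep = site_report(self.make_calls(0.5), {}, {"P1": 770})
        assert rep.empty

    def test_exact_site_gives_zero_distance(self):
        rep = site_report(self.make_calls(0.5), {"P1": [385]}, {"P1": 770})
        assert rep.loc[0, "distance"] == 0
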