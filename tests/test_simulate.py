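"""Tryptic digestion, catalog generation, and study simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheddex import simulate as sim
from sheddex.simulate import (
    C_SIDE,
    N_SIDE,
    DigestError,
    SecretionEvent,
    ShedEvent,
    SimDesign,
    SimTruth,
    digest,
    evaluate_calls,
    generate_catalog,
    plan_truth,
    simulate_study,
)

sequences = st.text(alphabet=sim.AMINO_ACIDS, min_size=1, max_size=120)


class TestDigest:
    def test_no_cleavage_site_yields_whole_protein(self):
        assert digest("AAAAAA", min_len=4, max_len=30) == [("AAAAAA", 1, 6)]

    def test_keil_rule_proline_blocks_cleavage(self):
        # hand-applied rule on AAKRPAAK: cut after K3 (next=R), not after
        # R4 (next=P); trailing K8 is the C terminus
        peps = digest("AAKRPAAK", min_len=1, max_len=30, missed_cleavages=0)
        assert peps == [("AAK", 1, 3), ("RPAAK", 4, 8)]

    def test_positions_match_sequence(self):
        seq = "MKTAYRLKPQWRSTK"
        for pep, start, end in digest(seq, 1, 30, missed_cleavages=2):
            assert seq[start - 1:end] == pep

    @settings(max_examples=50, deadline=None)
    @given(seq=sequences)
    def test_missed_cleavage_output_is_superset(self, seq):
        base = set(digest(seq, 1, 200, missed_cleavages=0))
        more = set(digest(seq, 1, 200, missed_cleavages=1))
        assert base <= more

    @settings(max_examples=50, deadline=None)
    @given(seq=sequences)
    def test_fully_tryptic_fragments_tile_the_sequence(self, seq):
        frags = digest(seq, 1, len(seq), missed_cleavages=0)
        assert "".join(p for p, _, _ in frags) == seq

    def test_length_bounds_respected(self):
        for pep, _, _ in digest("MKTAYRLKPQWRSTKAAAK", 3, 6, 1):
            assert 3 <= len(pep) <= 6

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(DigestError, match="non-standard"):
            digest("AAXKA", 1, 30)
        with pytest.raises(DigestError):
            digest("", 1, 30)


class TestCatalog:
    def test_postconditions(self, small_catalog):
        assert len(small_catalog) == 30
        for prot in small_catalog:
            assert len(prot.peptides) >= 4
            assert 300 <= prot.length <= 600
            for pep, s, e in prot.peptides:
                assert prot.sequence[s - 1:e] == pep

    def test_same_seed_reproduces(self):
        a = generate_catalog(5, (300, 400), seed=3)
        b = generate_catalog(5, (300, 400), seed=3)
        assert a.sequences() == b.sequences()

    def test_different_seed_differs(self):
        a = generate_catalog(5, (300, 400), seed=7)
        b = generate_catalog(5, (300, 400), seed=8)
        assert a.sequences() != b.sequences()

    def test_impossible_constraints_fail(self):
        with pytest.raises((RuntimeError, ValueError)):
            generate_catalog(1, (8, 9), seed=0, min_len=7, max_len=30)


class TestTruth:
    def test_event_validation(self):
        with pytest.raises(ValueError):
            ShedEvent("P1", 1.2, N_SIDE, 0.5)
        with pytest.raises(ValueError):
            ShedEvent("P1", 0.5, "left", 0.5)
        with pytest.raises(ValueError):
            SecretionEvent("P1", -1.0)
        with pytest.raises(ValueError, match="at most one"):
            SimTruth(
                shed_events=[ShedEvent("P1", 0.5, N_SIDE, 0.5)],
                secretion_events=[SecretionEvent("P1", 2.0)],
            )

    def test_plan_truth_events_recoverable(self, small_catalog):
        truth = plan_truth(small_catalog, n_shed=5, n_secretion=5, seed=1)
        assert len(truth.shed_events) == 5
        assert not truth.shed_ids & truth.secretion_ids
        for ev in truth.shed_events:
            prot = small_catalog[ev.protein_id]
            mids = [
                sim.midpoint_fraction(s, e, prot.length)
                for _, s, e in prot.peptides
            ]
            n_n = sum(m <= ev.boundary_fraction for m in mids)
            n_c = len(mids) - n_n
            changed = n_n if ev.changed_side == N_SIDE else n_c
            assert changed >= 3
            assert min(n_n, n_c) >= 2


class TestSimulateStudy:
    def test_no_effect_no_noise_means_equal(self, small_catalog):
        design = SimDesign(n_case=4, n_control=4, cv=1e-9, missing_rate=0.0,
                           seed=5)
        table = simulate_study(small_catalog, design, SimTruth())
        case = table.data[table.samples_in("case")].to_numpy()
        ctrl = table.data[table.samples_in("control")].to_numpy()
        np.testing.assert_allclose(case.mean(axis=1) / ctrl.mean(axis=1),
                                   1.0, rtol=1e-6)

    def test_planted_fold_appears_on_correct_side(self, small_catalog):
        pid = next(iter(small_catalog)).protein_id
        truth = SimTruth(shed_events=[ShedEvent(pid, 0.4, N_SIDE, 1 / 3)])
        design = SimDesign(n_case=4, n_control=4, cv=1e-9, missing_rate=0.0,
                           seed=5)
        table = simulate_study(small_catalog, design, truth)
        sub = table.data[table.data["protein_id"] == pid]
        length = small_catalog[pid].length
        mids = (sub["start"] + sub["end"]) / (2 * length)
        ratio = (
            sub[table.samples_in("case")].mean(axis=1)
            / sub[table.samples_in("control")].mean(axis=1)
        )
        np.testing.assert_allclose(
            ratio[mids <= 0.4], 1 / 3, rtol=1e-6
        )
        np.testing.assert_allclose(ratio[mids > 0.4], 1.0, rtol=1e-6)
        assert (mids <= 0.4).sum() >= 1

    def test_secretion_event_moves_every_peptide(self, small_catalog):
        pid = next(iter(small_catalog)).protein_id
        truth = SimTruth(secretion_events=[SecretionEvent(pid, 2.0)])
        design = SimDesign(n_case=4, n_control=4, cv=1e-9, missing_rate=0.0,
                           seed=5)
        table = simulate_study(small_catalog, design, truth)
        sub = table.data[table.data["protein_id"] == pid]
        ratio = (
            sub[table.samples_in("case")].mean(axis=1)
            / sub[table.samples_in("control")].mean(axis=1)
        )
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-6)

    def test_fixed_seed_is_byte_identical(self, small_catalog):
        design = SimDesign(n_case=3, n_control=3, cv=0.2, missing_rate=0.1,
                           seed=9)
        a = simulate_study(small_catalog, design).data.to_csv()
        b = simulate_study(small_catalog, design).data.to_csv()
        assert a == b

    def test_missing_rate_calibrated(self, small_catalog):
        rate = 0.1
        design = SimDesign(n_case=10, n_control=10, cv=0.2,
                           missing_rate=rate, seed=2)
        table = simulate_study(small_catalog, design)
        cells = table.data[
            table.samples_in("case") + table.samples_in("control")
        ].to_numpy()
        n = cells.size
        assert n >= 10_000
        observed = np.isnan(cells).mean()
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) <= 2 * se

    def test_reference_is_geometric_mean_and_complete(self, small_catalog):
        design = SimDesign(n_case=3, n_control=3, cv=1e-9, missing_rate=0.0,
                           seed=4)
        table = simulate_study(small_catalog, design)
        vals = table.data[
            table.samples_in("case") + table.samples_in("control")
        ].to_numpy()
        ref = table.data["reference"].to_numpy()
        np.testing.assert_allclose(
            ref, np.exp(np.log(vals).mean(axis=1)), rtol=1e-9
        )
        assert not np.isnan(ref).any()

    def test_unknown_truth_protein_rejected(self, small_catalog):
        truth = SimTruth(secretion_events=[SecretionEvent("NOPE", 2.0)])
        with pytest.raises(KeyError):
            simulate_study(small_catalog, SimDesign(seed=0), truth)


class TestEvaluateCalls:
    @staticmethod
    def calls_frame(rows):
        return pd.DataFrame(rows, columns=["protein_id", "boundary"])

    def test_perfect_recovery(self):
        truth = SimTruth(shed_events=[ShedEvent("P1", 0.4, N_SIDE, 0.5),
                                      ShedEvent("P2", 0.6, C_SIDE, 0.5)])
        rep = evaluate_calls(
            self.calls_frame([("P1", 0.4), ("P2", 0.6)]), truth
        )
        assert rep.sensitivity == 1.0
        assert rep.fdr == 0.0
        assert rep.boundary_errors_pp == [0.0, 0.0]

    def test_empty_calls(self):
        truth = SimTruth(shed_events=[ShedEvent("P1", 0.4, N_SIDE, 0.5)])
        rep = evaluate_calls(self.calls_frame([]), truth)
        assert rep.sensitivity == 0.0
        assert rep.fdr == 0.0

    def test_partial_recovery_with_false_positive(self):
        shed = [ShedEvent(f"P{i}", 0.5, N_SIDE, 0.5) for i in range(10)]
        truth = SimTruth(shed_events=shed)
        calls = self.calls_frame(
            [(f"P{i}", 0.5) for i in range(8)] + [("FPX", 0.3)]
        )
        rep = evaluate_calls(calls, truth)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.fdr == pytest.approx(1 / 9)

    def test_secretion_only_protein_counts_as_fp(self):
        truth = SimTruth(
            shed_events=[ShedEvent("P1", 0.4, N_SIDE, 0.5)],
            secretion_events=[SecretionEvent("S1", 2.0)],
        )
        rep = evaluate_calls(self.calls_frame([("S1", 0.5)]), truth)
        assert rep.n_fp == 1
        assert rep.sensitivity == 0.0

    def test_truth_roundtrip_via_frame(self):
        truth = SimTruth(
            shed_events=[ShedEvent("P1", 0.35, C_SIDE, 1 / 3)],
            secretion_events=[SecretionEvent("S1", 2.0)],
        )
        back = sim.truth_from_frame(sim.truth_to_frame(truth))
        assert back.shed_events == truth.shed_events
        assert back.secretion_events == truth.secretion_events
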