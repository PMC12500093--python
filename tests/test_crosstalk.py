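import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptmrhythm import crosstalk as ct
from ptmrhythm import simulate as sim
from ptmrhythm.types import (
    InputError,
    KinaseMotifEntry,
    MotifPattern,
    SiteRecord,
)


class TestPhaseDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (20.0, 8.0, 12.0),   # antiphase glyco/phospho peaks
        (23.0, 1.0, 2.0),    # wraparound
        (5.0, 5.0, 0.0),
        (0.0, 12.0, 12.0),
        (2.0, 21.0, 5.0),
    ])
    def test_values(self, a, b, expected):
        assert ct.phase_difference(a, b) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ct.phase_difference(24.0, 3.0)

    @given(st.floats(0, 23.999), st.floats(0, 23.999), st.floats(0, 23.999))
    @settings(deadline=None, max_examples=200)
    def test_circle_metric(self, a, b, c):
        """Symmetry, identity of indiscernibles (mod 24), triangle."""
        dab = ct.phase_difference(a, b)
        assert dab == pytest.approx(ct.phase_difference(b, a))
        assert 0 <= dab <= 12
        if dab == 0:
            assert a % 24 == pytest.approx(b % 24, abs=1e-9)
        dac = ct.phase_difference(a, c)
        dcb = ct.phase_difference(c, b)
        assert dab <= dac + dcb + 1e-9


class TestPhaseRelation:
    @pytest.mark.parametrize("delta,expected", [
        (1.9, "phase-locked"), (2.0, "phase-locked"), (2.1, "intermediate"),
        (7.9, "intermediate"), (8.0, "phase-shifted"), (8.1, "phase-shifted"),
        (0.0, "phase-locked"), (12.0, "phase-shifted"), (5.0, "intermediate"),
    ])
    def test_boundary_grid(self, delta, expected):
        assert ct.classify_phase_relation(delta) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ct.classify_phase_relation(12.5)


def _site(acc, pos, ptm, fid, residue="S"):
    return SiteRecord(acc, pos, residue, ptm, fid)


class TestProximalPairs:
    def test_distance_nine_included(self):
        # glyco at 450 proximal to a phosphosite at 441
        pairs = ct.proximal_pairs([_site("CLOCK", 450, "O-GlcNAc", "g1")],
                                  [_site("CLOCK", 441, "phospho", "p1")])
        assert len(pairs) == 1 and pairs.loc[0, "distance_aa"] == 9

    def test_distance_eleven_excluded(self):
        pairs = ct.proximal_pairs([_site("A", 100, "O-GlcNAc", "g1")],
                                  [_site("A", 111, "phospho", "p1")])
        assert len(pairs) == 0

    def test_distance_ten_inclusive_and_same_site(self):
        pairs = ct.proximal_pairs(
            [_site("A", 100, "O-GlcNAc", "g1")],
            [_site("A", 110, "phospho", "p1"),
             _site("A", 100, "phospho", "p2")])
        assert len(pairs) == 2
        same = pairs[pairs.phospho_feature == "p2"]
        assert bool(same["same_site"].iloc[0])

    def test_matches_brute_force_on_random_sites(self):
        rng = np.random.default_rng(40)
        accs = [f"P{i}" for i in range(8)]
        glyco = [_site(accs[rng.integers(8)], int(rng.integers(1, 200)),
                       "O-GlcNAc", f"g{i}") for i in range(25)]
        phospho = [_site(accs[rng.integers(8)], int(rng.integers(1, 200)),
                         "phospho", f"p{i}") for i in range(25)]
        got = ct.proximal_pairs(glyco, phospho, 10)
        expected = {(g.feature_id, p.feature_id)
                    for g in glyco for p in phospho
                    if g.accession == p.accession
                    and abs(g.position - p.position) <= 10}
        assert set(zip(got.glyco_feature, got.phospho_feature)) == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(41)
        glyco = [_site("P1", int(p), "O-GlcNAc", f"g{i}")
                 for i, p in enumerate(rng.integers(1, 60, 10))]
        phospho = [_site("P1", int(p), "phospho", f"p{i}")
                   for i, p in enumerate(rng.integers(1, 60, 10))]
        a = ct.proximal_pairs(glyco, phospho)
        b = ct.proximal_pairs(glyco[::-1], phospho[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestMotifScan:
    def test_pattern_semantics_worked_example(self):
        motif = MotifPattern("S.{3}S", 0, 4, "proximal")
        hits = ct.scan_interplay_motifs({"P1": "ASPPQSG"}, [motif])
        assert len(hits) == 1
        row = hits.iloc[0]
        assert row.match_start == 2
        assert row.phospho_position == 2 and row.glyco_position == 6

    def test_absent_motif_no_matches(self):
        motif = MotifPattern("[ST]P", 0, 0, "same-site")
        hits = ct.scan_interplay_motifs({"P1": "AAAGGG"}, [motif])
        assert hits.empty

    def test_observed_site_flagging(self):
        motif = MotifPattern("[ST]P", 0, 0, "same-site")
        sites = [SiteRecord("P1", 2, "S", "phospho", "p1")]
        hits = ct.scan_interplay_motifs({"P1": "ASPAGG"}, [motif], sites)
        assert bool(hits.loc[0, "phospho_observed"])
        assert not bool(hits.loc[0, "glyco_observed"])

    def test_planted_motifs_all_recovered(self):
        seqs, _, _, _, truth = sim.simulate_site_universe(
            n_proteins=10, crosstalk=sim.CrosstalkSpec(n_locked=2, n_shifted=2),
            params=sim.SimParams(seed=42))
        hits = ct.scan_interplay_motifs(seqs, sim.DEFAULT_MOTIFS)
        found = set(zip(hits.accession, hits.pattern, hits.match_start))
        for row in truth["motifs"].itertuples():
            assert (row.accession, row.pattern, row.start) in found

    def test_false_positive_rate_matches_analytic_probability(self):
        """On uniform random sequences the per-position hit rate equals the
        product of class sizes over 20, within 3 binomial SD."""
        rng = np.random.default_rng(43)
        from ptmrhythm.types import AMINO_ACIDS
        aa = np.array(list(AMINO_ACIDS))
        seqs = {f"R{i}": "".join(aa[rng.integers(0, 20, 300)])
                for i in range(60)}
        motif = MotifPattern("[ST]P.A", 0, 0, "same-site")
        hits = ct.scan_interplay_motifs(seqs, [motif])
        n_windows = sum(len(s) - motif.length + 1 for s in seqs.values())
        p = motif.hit_probability()
        assert p == pytest.approx((2 / 20) * (1 / 20) * 1.0 * (1 / 20))
        sd = np.sqrt(n_windows * p * (1 - p))
        assert abs(len(hits) - n_windows * p) < 3 * sd + 1e-9


class TestFlanks:
    SEQS = {"P1": "ABCDEFGHIKLMNPQ".replace("B", "S")}  # pos 2 = S

    def test_left_padding_at_terminus(self):
        seqs = {"P1": "SAAAAAAAAA"}
        site = SiteRecord("P1", 1, "S", "phospho", "f1")
        flank = ct.extract_flank(site, seqs, half_window=7)
        assert flank == "-------SAAAAAAA"
        assert len(flank) == 15

    def test_central_site_exact_substring(self):
        seq = "AAAAAAAASAAAAAAAA"
        site = SiteRecord("P1", 9, "S", "phospho", "f1")
        flank = ct.extract_flank(site, {"P1": seq}, half_window=7)
        assert flank == seq[1:16]

    @pytest.mark.parametrize("pos", [1, 3, 8, 15, 17])
    def test_acceptor_always_centered(self, pos):
        seq = "S" * 17
        site = SiteRecord("P1", pos, "S", "O-GlcNAc", "f1")
        flank = ct.extract_flank(site, {"P1": seq}, half_window=7)
        assert flank[7] == "S" and len(flank) == 15


class TestKinaseIntersection:
    def _rhythms(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "q", "phase"])

    def test_triple_filter_matches_brute_force(self):
        rng = np.random.default_rng(44)
        flanks = ["AAAAAAASPAAAAAA", "RRRAAAASAAAAAAA", "AAAAAAATPAAAAAA"]
        panel = [KinaseMotifEntry(f"K{i}", pat, f"K{i}") for i, pat in
                 enumerate(["...[ST]P..", "R..[ST]...", "E..[ST]..."])]
        rhythms = self._rhythms(
            [[f"K{i}", float(q), float(ph)] for i, (q, ph) in enumerate(
                zip(rng.uniform(0, 0.4, 3), rng.uniform(0, 24, 3)))])
        got = ct.phase_matched_kinases(flanks, panel, rhythms,
                                       substrate_phase=10.0, window_h=4.0)
        expected = sorted({
            e.kinase for e in panel
            if any(e.matches_flank(f) for f in flanks)
            and float(rhythms.set_index("feature_id").loc[
                e.source_feature, "q"]) < 0.2
            and ct.phase_difference(
                float(rhythms.set_index("feature_id").loc[
                    e.source_feature, "phase"]), 10.0) <= 4.0})
        assert got == expected

    def test_arrhythmic_kinase_excluded(self):
        panel = [KinaseMotifEntry("K0", "...[ST]P..", "K0")]
        rhythms = self._rhythms([["K0", 0.9, 10.0]])
        assert ct.phase_matched_kinases(["AAAAAAASPAAAAAA"], panel, rhythms,
                                        10.0) == []

    def test_phase_window_retention(self):
        panel = [KinaseMotifEntry("K0", "...[ST]P..", "K0")]
        rhythms = self._rhythms([["K0", 0.01, 16.0]])
        kept = ct.phase_matched_kinases(["AAAAAAASPAAAAAA"], panel, rhythms,
                                        substrate_phase=18.0, window_h=4.0)
        assert kept == ["K0"]
        dropped = ct.phase_matched_kinases(["AAAAAAASPAAAAAA"], panel, rhythms,
                                           substrate_phase=4.0, window_h=4.0)
        assert dropped == []


class TestRhythmicBoth:
    def _res(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "q", "phase"])

    def test_disjoint_sets_empty(self):
        g = self._res([["P1", 0.01, 20.0]])
        p = self._res([["f1", 0.01, 8.0]])
        accs, pairs = ct.rhythmic_both(g, p, {"f1": "P2"})
        assert accs == set() and pairs.empty

    def test_antiphase_pair_is_shifted(self):
        g = self._res([["P1", 0.01, 20.0]])
        p = self._res([["f1", 0.05, 8.0]])
        accs, pairs = ct.rhythmic_both(g, p, {"f1": "P1"})
        assert accs == {"P1"}
        assert pairs.loc[0, "delta_h"] == pytest.approx(12.0)
        assert pairs.loc[0, "relation"] == "phase-shifted"

    def test_q_gate_strict_on_both_sides(self):
        g = self._res([["P1", 0.2, 20.0]])
        p = self._res([["f1", 0.01, 8.0]])
        accs, _ = ct.rhythmic_both(g, p, {"f1": "P1"})
        assert accs == set()

    def test_planted_relation_proportions(self):
        """Site-universe truth: locked and shifted pair classes recovered in
        the planted proportions from the planted phases."""
        spec = sim.CrosstalkSpec(n_locked=6, n_shifted=9)
        _, _, _, _, truth = sim.simulate_site_universe(
            n_proteins=20, crosstalk=spec, params=sim.SimParams(seed=45))
        pairs = truth["pairs"]
        rel = [ct.classify_phase_relation(d) for d in pairs["delta_h"]]
        assert rel.count("phase-locked") == 6
        assert rel.count("phase-shifted") == 9
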