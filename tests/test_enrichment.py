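"""Composition backgrounds, enrichment ratios, heptad matrices, shuffling."""

import numpy as np
import pandas as pd
import pytest

import ctdkit as ck
from ctdkit.enrichment import (
    composition,
    contact_type_fractions,
    enrichment_table,
    enrichment_with_se,
    expected_pair_fraction,
    heptad_position_matrix,
    shuffle_background,
)
from ctdkit.model import ValidationError
from ctdkit.sequence import annotate_heptads
from ctdkit.synthetic import FixtureFrame, FixtureSpec, make_contact_fixture


class TestComposition:
    def test_consensus_heptad_frequencies(self):
        prof = composition(["YSPTSPS"])
        assert prof == pytest.approx({"Y": 1 / 7, "S": 3 / 7, "P": 2 / 7, "T": 1 / 7})

    def test_homopolymer_and_normalization(self):
        assert composition(["PPPP"]) == {"P": 1.0}
        prof = composition(["YSPTSPS" * 4, "YSTPPSS"])
        assert sum(prof.values()) == pytest.approx(1.0)

    def test_canonical_mask_restricts_residues(self):
        seq = "YSTPPSS"  # canonical at positions 1, 2, 7 -> Y, S, S
        ann = annotate_heptads(seq)
        prof = composition([seq], restrict=[ann.canonical])
        assert prof == pytest.approx({"Y": 1 / 3, "S": 2 / 3})

    def test_empty_after_mask_rejected(self):
        with pytest.raises(ValidationError):
            composition(["YS"], restrict=[np.zeros(2, dtype=bool)])


class TestExpectedPairFraction:
    def test_closed_forms_on_heptad_composition(self):
        prof = composition(["YSPTSPS"])
        assert expected_pair_fraction(prof, "P", "S") == pytest.approx(12 / 49)
        assert expected_pair_fraction(prof, "Y", "Y") == pytest.approx(1 / 49)

    def test_multinomial_identity_sums_to_one(self):
        prof = composition(["YSPTSPS" * 3])
        types = sorted(prof)
        total = sum(
            expected_pair_fraction(prof, a, b)
            for i, a in enumerate(types)
            for b in types[i:]
        )
        assert total == pytest.approx(1.0)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValidationError):
            expected_pair_fraction({"Y": 1.0}, "Y", "W")


def _typed_fixture(pairs_per_frame, sequences=("YP", "YP"), cutoff=3.5):
    """Small two-chain system realizing the requested inter-chain contacts."""
    seqs = list(sequences)
    n_a = len(seqs[0])
    row = lambda res: res[1] - 1 if res[0] == "A" else n_a + res[1] - 1
    frames = []
    for contacts in pairs_per_frame:
        # every residue starts isolated on a widely spaced grid
        n = sum(len(s) for s in seqs)
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 200.0
        for k, (a, b) in enumerate(contacts):
            site = np.array([0.0, 500.0 + k * 300.0, 0.0])
            coords[row(a)] = site
            coords[row(b)] = site + [cutoff - 0.5, 0.0, 0.0]
        frames.append(FixtureFrame(coords=coords, contacts=list(contacts)))
    spec = FixtureSpec(chain_ids=["A", "B"], sequences=seqs, frames=frames,
                       cutoff_A=cutoff)
    return make_contact_fixture(spec)


class TestContactTypeFractions:
    def test_single_type_pair_gets_full_fraction(self):
        traj, table = _typed_fixture([[(("A", 1), ("B", 2))]] * 3)  # Y-P contacts only
        fractions, listing = contact_type_fractions(table, traj.topology)
        assert fractions == {("P", "Y"): 1.0}
        assert listing.iloc[0]["fraction"] == 1.0

    def test_fractions_sum_to_one_and_events_weighted(self):
        traj, table = _typed_fixture(
            [[(("A", 1), ("B", 1))], [(("A", 1), ("B", 1))], [(("A", 2), ("B", 2))]]
        )
        fractions, _ = contact_type_fractions(table, traj.topology)
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert fractions[("Y", "Y")] == pytest.approx(2 / 3)  # pair x frame events

    def test_unique_mode_counts_pairs_once(self):
        traj, table = _typed_fixture(
            [[(("A", 1), ("B", 1))], [(("A", 1), ("B", 1))], [(("A", 2), ("B", 2))]]
        )
        fractions, _ = contact_type_fractions(table, traj.topology, mode="unique")
        assert fractions[("Y", "Y")] == pytest.approx(1 / 2)

    def test_empty_table_rejected(self):
        traj, table = _typed_fixture([[]])
        with pytest.raises(ValidationError):
            contact_type_fractions(table, traj.topology)


class TestEnrichmentTable:
    def test_ratios_one_when_observed_equals_expected(self):
        prof = composition(["YSPTSPS"])
        types = sorted(prof)
        observed = {}
        for i, a in enumerate(types):
            for b in types[i:]:
                observed[(a, b)] = expected_pair_fraction(prof, a, b)
        df = enrichment_table(observed, prof)
        assert np.allclose(df["ratio"], 1.0)

    def test_zero_expected_reported_missing_not_infinite(self):
        df = enrichment_table({("Y", "Y"): 1.0}, {"Y": 1.0, "W": 0.0})
        ww = df[(df.type_a == "W") & (df.type_b == "W")]["ratio"].iloc[0]
        assert np.isnan(ww)


class TestShuffleBackground:
    def _table(self):
        # large system: the permutation background (without replacement)
        # approaches the composition product to O(1/N)
        seq = "YSPTSPS" * 10
        return _typed_fixture(
            [
                [(("A", 1), ("B", 1)), (("A", 3), ("B", 9))],
                [(("A", 1), ("B", 2)), (("A", 4), ("B", 6))],
                [(("A", 2), ("B", 2)), (("A", 10), ("B", 17))],
            ],
            sequences=(seq, seq),
        )

    def test_same_seed_reproducible(self):
        traj, table = self._table()
        a = shuffle_background(table, traj.topology, n_shuffles=50, seed=7)
        b = shuffle_background(table, traj.topology, n_shuffles=50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_fractions_converge_to_analytic_background(self):
        traj, table = self._table()
        df = shuffle_background(table, traj.topology, n_shuffles=1000, seed=3)
        prof = composition([c.sequence for c in traj.topology.chains])
        for row in df.itertuples():
            expected = expected_pair_fraction(prof, row.type_a, row.type_b)
            assert abs(row.mean_fraction - expected) <= max(3 * row.se, 0.02)

    def test_fractions_sum_to_one_each_report(self):
        traj, table = self._table()
        df = shuffle_background(table, traj.topology, n_shuffles=200, seed=5)
        assert df["mean_fraction"].sum() == pytest.approx(1.0)


class TestHeptadMatrix:
    def test_matrix_is_symmetric_and_near_one_for_uniform_contacts(self, rng):
        """Contacts drawn uniformly over canonical residues -> ratios ~ 1."""
        seq = "YSPTSPS" * 4
        n = len(seq)
        frames = []
        for _ in range(40):
            i, j = rng.choice(n, size=2, replace=False)
            coords = np.zeros((2 * n, 3))
            coords[:n, 0] = np.arange(n) * 10.0
            coords[n:, 0] = np.arange(n) * 10.0
            coords[n:, 1] = 500.0
            coords[n + j] = coords[i] + [2.0, 0.0, 0.0]
            frames.append(FixtureFrame(
                coords=coords, contacts=[(("A", int(i) + 1), ("B", int(j) + 1))]))
        spec = FixtureSpec(chain_ids=["A", "B"], sequences=[seq, seq], frames=frames)
        traj, table = make_contact_fixture(spec)
        ann = annotate_heptads(seq)
        hm = heptad_position_matrix(table, traj.topology, ann)
        assert np.allclose(hm.ratios, hm.ratios.T, equal_nan=True)
        iu = np.triu_indices(7)
        assert hm.observed[iu].sum() == pytest.approx(1.0)
        # uniform contacts: no position pair should be wildly enriched
        assert np.nanmean(hm.ratios) == pytest.approx(1.0, abs=0.75)

    def test_non_canonical_residues_do_not_contribute(self):
        seq = "YSPTSPF"  # position 7 non-canonical
        coords = np.zeros((14, 3))
        coords[:7, 0] = np.arange(7) * 10.0
        coords[7:, 0] = np.arange(7) * 10.0
        coords[7:, 1] = 100.0
        coords[13] = coords[6] + [2.0, 0, 0]   # F7-F7 contact: both non-canonical
        coords[7] = coords[0] + [2.0, 0, 0]    # Y1-Y1 contact: canonical
        frames = [FixtureFrame(coords=coords, contacts=[
            (("A", 7), ("B", 7)), (("A", 1), ("B", 1))])]
        traj, table = make_contact_fixture(
            FixtureSpec(chain_ids=["A", "B"], sequences=[seq, seq], frames=frames))
        hm = heptad_position_matrix(table, traj.topology, annotate_heptads(seq))
        assert hm.observed[0, 0] == pytest.approx(1.0)   # only the Y1-Y1 event remains
        assert hm.observed[6, 6] == 0.0


class TestEnrichmentWithSE:
    def test_matches_aggregate_ratio_on_balanced_fixture(self):
        traj, table = _typed_fixture([[(("A", 1), ("B", 2))]] * 4)
        prof = composition([c.sequence for c in traj.topology.chains])
        df = enrichment_with_se(table, traj.topology, prof)
        yp = df[(df.type_a == "P") & (df.type_b == "Y")].iloc[0]
        assert yp["observed"] == pytest.approx(1.0)
        assert yp["ratio"] == pytest.approx(1.0 / expected_pair_fraction(prof, "Y", "P"))
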