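"""Ensemble <r^-6> averaging and relative-NOE prediction."""

import numpy as np
import pytest

from glyconf.ensembles import CoordinateEnsemble
from glyconf.errors import (
    AtomLookupError,
    DegenerateGeometryError,
    PairingError,
    ValidationError,
)
from glyconf.geometry import build_fragment
from glyconf.noe import (
    NoeTable,
    ProtonPair,
    flag_incompatible_noes,
    mean_inv_r6,
    packaged_noe_table,
    relative_noe,
)

from conftest import random_rigid_motion

PAIR = ProtonPair("A", "B")


def two_atom_ensemble(distances):
    coords = np.zeros((len(distances), 2, 3))
    coords[:, 1, 0] = distances
    return CoordinateEnsemble(["A", "B"], coords)


class TestMeanInvR6:
    def test_single_frame_r2(self):
        assert mean_inv_r6(two_atom_ensemble([2.0]), PAIR) == pytest.approx(1 / 64)

    def test_two_frames_equal_weights(self):
        want = (2.0 ** -6 + 3.0 ** -6) / 2
        assert mean_inv_r6(two_atom_ensemble([2.0, 3.0]), PAIR) == pytest.approx(want, rel=1e-15)

    def test_matches_naive_loop_oracle(self, rng):
        coords = rng.normal(size=(1000, 4, 3)) * 4.0
        ens = CoordinateEnsemble(["A", "B", "C", "D"], coords)
        pair = ProtonPair("B", "D")
        acc = 0.0
        for i in range(ens.n_frames):  # brute-force per-frame loop
            fr = ens.frame(i)
            acc += np.linalg.norm(fr["B"] - fr["D"]) ** -6
        want = acc / ens.n_frames
        assert mean_inv_r6(ens, pair) == pytest.approx(want, rel=1e-12)

    def test_rigid_motion_per_frame_invariance(self, rng):
        coords = rng.normal(size=(50, 3, 3)) * 3.0
        ens = CoordinateEnsemble(["A", "B", "C"], coords)
        moved = coords.copy()
        for i in range(50):
            rot, t = random_rigid_motion(rng)
            moved[i] = coords[i] @ rot.T + t
        ens2 = CoordinateEnsemble(["A", "B", "C"], moved)
        assert mean_inv_r6(ens2, PAIR) == pytest.approx(mean_inv_r6(ens, PAIR), rel=1e-10)

    def test_missing_atom_raises(self):
        with pytest.raises(AtomLookupError, match="Z"):
            mean_inv_r6(two_atom_ensemble([2.0]), ProtonPair("A", "Z"))

    def test_zero_distance_raises(self):
        with pytest.raises(DegenerateGeometryError):
            mean_inv_r6(two_atom_ensemble([0.0]), PAIR)

    def test_weights_validated(self):
        with pytest.raises(ValidationError):
            mean_inv_r6(two_atom_ensemble([2.0, 3.0]), PAIR, weights=[1.0, -0.5])


class TestRelativeNoe:
    def three_spin_ensemble(self, r_ab, r_ac, n=1):
        coords = np.zeros((n, 3, 3))
        coords[:, 1, 0] = r_ab
        coords[:, 2, 1] = r_ac
        return CoordinateEnsemble(["A", "B", "C"], coords)

    def test_reference_row_exactly_one(self):
        ens = self.three_spin_ensemble(2.0, 3.0)
        ref = ProtonPair("A", "B")
        table = relative_noe(ens, [ref, ProtonPair("A", "C")], ref)
        assert table.rows.loc[table.rows["pair"] == ref.label, "intensity"].iloc[0] == 1.0

    def test_double_distance_gives_inverse_64(self):
        ens = self.three_spin_ensemble(2.0, 4.0)
        table = relative_noe(ens, [ProtonPair("A", "C")], ProtonPair("A", "B"))
        got = float(table.rows.loc[table.rows["pair"] == "A-C", "intensity"].iloc[0])
        assert got == pytest.approx(2.0 ** -6, rel=1e-12)

    def test_single_conformation_closed_form(self, spec, geom, rng):
        frame = build_fragment(30.0, 40.0, geom, spec)
        ens = CoordinateEnsemble.from_frames([frame])
        ref = ProtonPair("H1", "H3")
        pair = ProtonPair("H1", "H4")
        r_ref = np.linalg.norm(frame["H1"] - frame["H3"])
        r_pair = np.linalg.norm(frame["H1"] - frame["H4"])
        table = relative_noe(ens, [pair], ref)
        got = float(table.rows.loc[table.rows["pair"] == "H1-H4", "intensity"].iloc[0])
        assert got == pytest.approx((r_ref / r_pair) ** 6, rel=1e-12)

    def test_two_state_weighted_closed_form(self, spec, geom):
        """A 0.9/0.1 two-state ensemble built at conformers I and III matches
        the weighted closed form computed from the two rigid geometries."""
        f_i = build_fragment(30.0, 40.0, geom, spec)
        f_iii = build_fragment(30.0, 180.0, geom, spec)
        ens = CoordinateEnsemble.from_frames([f_i, f_iii])
        w = np.array([0.9, 0.1])

        def inv6(frame, a, b):
            return np.linalg.norm(frame[a] - frame[b]) ** -6

        want = (w @ [inv6(f_i, "H1", "H4"), inv6(f_iii, "H1", "H4")]) / (
            w @ [inv6(f_i, "H1", "H3"), inv6(f_iii, "H1", "H3")]
        )
        table = relative_noe(ens, [ProtonPair("H1", "H4")], ProtonPair("H1", "H3"), weights=w)
        got = float(table.rows.loc[table.rows["pair"] == "H1-H4", "intensity"].iloc[0])
        assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_in_pair_distance(self):
        closer = self.three_spin_ensemble(2.0, 3.0)
        farther = self.three_spin_ensemble(2.0, 3.5)
        ref, pair = ProtonPair("A", "B"), ProtonPair("A", "C")
        v_close = float(relative_noe(closer, [pair], ref).rows
                        .query("pair == 'A-C'")["intensity"].iloc[0])
        v_far = float(relative_noe(farther, [pair], ref).rows
                      .query("pair == 'A-C'")["intensity"].iloc[0])
        assert v_close > v_far

    def test_global_rescaling_cancels(self, rng):
        coords = rng.normal(size=(20, 3, 3)) * 3.0
        ens1 = CoordinateEnsemble(["A", "B", "C"], coords)
        ens2 = CoordinateEnsemble(["A", "B", "C"], coords * 1.7)
        ref, pair = ProtonPair("A", "B"), ProtonPair("A", "C")
        v1 = relative_noe(ens1, [pair], ref).rows.set_index("pair")["intensity"]
        v2 = relative_noe(ens2, [pair], ref).rows.set_index("pair")["intensity"]
        assert v1["A-C"] == pytest.approx(v2["A-C"], rel=1e-10)


class TestFlagIncompatible:
    def split(self, table, source):
        rows = table.rows[table.rows["source"] == source].copy()
        return NoeTable(rows)

    def test_sasa_predicted_but_absent_is_flagged(self):
        table = packaged_noe_table()
        flags = flag_incompatible_noes(self.split(table, "SASA"),
                                       self.split(table, "experimental"))
        flagged = {(f.compound, f.pair) for f in flags}
        assert ("1", "H1(Fuc)-H4(GlA)") in flagged  # predicted 0.26, observed 0
        assert all(f.kind == "predicted_but_absent" for f in flags
                   if (f.compound, f.pair) == ("1", "H1(Fuc)-H4(GlA)"))

    def test_water_zero_prediction_not_flagged(self):
        table = packaged_noe_table()
        flags = flag_incompatible_noes(self.split(table, "water"),
                                       self.split(table, "experimental"))
        flagged = {(f.compound, f.pair) for f in flags}
        assert ("4", "H1(Fuc)-H4(GlA)") not in flagged  # predicted 0, observed 0

    def test_water_model_has_fewer_discrepancies_than_sasa(self):
        """The model-selection logic: the explicit-water predictions are
        compatible with the spectra where the continuum ones are not."""
        table = packaged_noe_table()
        exp = self.split(table, "experimental")
        n_sasa = len(flag_incompatible_noes(self.split(table, "SASA"), exp))
        n_water = len(flag_incompatible_noes(self.split(table, "water"), exp))
        assert n_water < n_sasa

    def test_identical_tables_no_flags(self):
        table = packaged_noe_table()
        exp = self.split(table, "experimental")
        assert flag_incompatible_noes(exp, exp) == []

    def test_unmatched_labels_raise(self):
        table = packaged_noe_table()
        exp = self.split(table, "experimental")
        pred = NoeTable(exp.rows.iloc[:-1].copy())
        with pytest.raises(PairingError, match="unmatched"):
            flag_incompatible_noes(pred, exp)


class TestNoeTableInvariants:
    def test_reference_intensity_must_be_one(self):
        import pandas as pd

        rows = pd.DataFrame(
            [{"compound": "1", "pair": "A-B", "source": "synthetic",
              "intensity": 0.9, "reference": "A-B"}]
        )
        with pytest.raises(ValidationError, match="reference"):
            NoeTable(rows)

    def test_negative_intensity_rejected(self):
        import pandas as pd

        rows = pd.DataFrame(
            [{"compound": "1", "pair": "A-B", "source": "synthetic",
              "intensity": -0.1, "reference": "A-C"}]
        )
        with pytest.raises(ValidationError):
            NoeTable(rows)

    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            ProtonPair("H1", "H1")
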