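"""Preprocessing rules: parsing, dichotomization, RT filters, activity coding."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emadiff import data_model as dm


@pytest.fixture
def item_set():
    return dm.ItemSet("affect", ("angry", "lonely", "stressed"), "vas")


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadLongTable:
    HEADER = "person_id,occasion_id,day,item_id,rating,rt_seconds,activities,neuroticism,depression\n"

    def test_well_formed_rows_parse_identically(self, tmp_path, item_set):
        p = _write(
            tmp_path,
            self.HEADER
            + "p1,1,1,angry,55,4,work;eating,0.3,-0.2\n"
            + "p1,1,1,lonely,10,6,work;eating,0.3,-0.2\n"
            + "p2,3,1,stressed,80,3,,,\n",
        )
        recs = dm.read_long_table(p, item_set)
        assert len(recs) == 3
        assert recs[0].person_id == "p1" and recs[0].rating == 55
        assert recs[0].activities == frozenset({"work", "eating"})
        assert recs[2].item_id == "stressed" and math.isnan(recs[2].neuroticism)
        assert [r.item_id for r in recs] == ["angry", "lonely", "stressed"]

    def test_missing_rt_column_names_it(self, tmp_path, item_set):
        p = _write(tmp_path, "person_id,occasion_id,item_id,rating\np1,1,angry,55\n")
        with pytest.raises(dm.SchemaError, match="rt_seconds"):
            dm.read_long_table(p, item_set)

    def test_non_numeric_rt_cites_row(self, tmp_path, item_set):
        p = _write(
            tmp_path,
            self.HEADER
            + "p1,1,1,angry,55,4,,,\n"
            + "p1,1,1,lonely,10,abc,,,\n",
        )
        with pytest.raises(dm.RowParseError, match="row 2") as err:
            dm.read_long_table(p, item_set)
        assert err.value.row == 2

    def test_unknown_item_rejected(self, tmp_path, item_set):
        p = _write(tmp_path, self.HEADER + "p1,1,1,happiness,55,4,,,\n")
        with pytest.raises(dm.SchemaError, match="happiness"):
            dm.read_long_table(p, item_set)

    def test_round_trip_preserves_all_fields(self, tmp_path, item_set):
        recs = [
            dm.EMARecord("p1", 2, 1, "angry", 49, 7.0,
                         frozenset({"leisure", "work"}), 0.25, -1.5),
            dm.EMARecord("p2", 41, 7, "lonely", 100, 30.0, frozenset(), 0.0, 0.0),
        ]
        p = tmp_path / "rt.csv"
        dm.write_long_table(recs, p, header_comment="seed=3")
        back = dm.read_long_table(p, item_set)
        assert back == recs
        assert p.read_text().startswith("# seed=3")


class TestDichotomize:
    @pytest.mark.parametrize(
        "rating,expected",
        [(49, 0), (50, 1), (0, 0), (100, 1)],
    )
    def test_midpoint_split(self, rating, expected):
        assert dm.dichotomize_rating(rating) == expected

    @pytest.mark.parametrize("bad", [-1, 101, 150.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            dm.dichotomize_rating(bad)

    @given(st.integers(0, 99))
    @settings(deadline=None)
    def test_monotone_nondecreasing(self, r):
        assert dm.dichotomize_rating(r) <= dm.dichotomize_rating(r + 1)


class TestRTFilter:
    def _rec(self, rt, item="angry", occ=1):
        return dm.EMARecord("p1", occ, 1, item, 50, rt)

    def test_boundary_strictly_greater(self):
        kept, removed = dm.apply_rt_filter([self._rec(31.0), self._rec(30.0, "lonely")])
        assert removed == 1
        assert [r.rt_seconds for r in kept] == [30.0]

    def test_all_under_cap_unchanged(self):
        recs = [self._rec(3.0), self._rec(29.0, "lonely")]
        kept, removed = dm.apply_rt_filter(recs)
        assert kept == recs and removed == 0

    @given(st.lists(st.floats(0.5, 60.0), max_size=20))
    @settings(deadline=None)
    def test_idempotent(self, rts):
        recs = [self._rec(rt, item=f"i{k}") for k, rt in enumerate(rts)]
        once, n1 = dm.apply_rt_filter(recs)
        twice, n2 = dm.apply_rt_filter(once)
        assert twice == once and n2 == 0


class TestOccasionFilters:
    def _occ(self, rts, occ_id=1):
        return dm.OccasionData("p1", occ_id, 1,
                               {f"i{k}": 1 for k in range(len(rts))},
                               {f"i{k}": v for k, v in enumerate(rts)})

    def test_invariant_rts_removed(self):
        occs = [self._occ([3, 3, 3, 3, 3], 1), self._occ([3, 3, 3, 3, 4], 2)]
        kept, removed = dm.drop_invariant_rt_occasions(occs)
        assert removed == 1 and kept[0].occasion_id == 2

    def test_below_min_items_removed(self):
        kept, removed = dm.drop_invariant_rt_occasions([self._occ([5.0])])
        assert removed == 1 and kept == []

    def test_empty_input(self):
        assert dm.drop_invariant_rt_occasions([]) == ([], 0)

    def test_forced_three_percent_invariant(self):
        # 3% of occasions constructed with constant RTs -> reported removal 3%
        rng = np.random.default_rng(0)
        occs = []
        for i in range(1000):
            if i < 30:
                rts = [4.0] * 5
            else:
                rts = list(rng.integers(2, 9, 5).astype(float))
                if len(set(rts)) == 1:
                    rts[0] += 1.0
            occs.append(self._occ(rts, occ_id=i))
        _, removed = dm.drop_invariant_rt_occasions(occs)
        assert removed == 30


class TestActivities:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ({"work", "eating"}, (1, 0)),
            ({"leisure"}, (0, 1)),
            ({"chores", "drinking"}, (0, 0)),
            ({"work", "on the telephone"}, (1, 1)),
            (set(), (0, 0)),
        ],
    )
    def test_coding(self, labels, expected):
        assert dm.code_activities(labels) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="napping"):
            dm.code_activities({"napping"})


class TestMeanLogRT:
    def test_log_identity(self):
        occ = dm.OccasionData("p", 1, 1, {}, {"a": math.e, "b": math.e})
        assert dm.mean_log_rt(occ) == pytest.approx(1.0)

    def test_natural_log_back_transform(self):
        # 1.86 log-seconds back-transforms to about 6.42 s only under
        # natural logs, anchoring the log convention
        assert math.exp(1.86) == pytest.approx(6.42, abs=0.005)
        assert dm.mean_log_rt([6.42] * 5) == pytest.approx(1.86, abs=1e-3)

    def test_capped_items_excluded(self):
        recs = [
            dm.EMARecord("p", 1, 1, "a", 50, 2.0),
            dm.EMARecord("p", 1, 1, "b", 50, 40.0),
            dm.EMARecord("p", 1, 1, "c", 50, 2.0),
        ]
        filtered, _ = dm.apply_rt_filter(recs, cap=30)
        iset = dm.ItemSet("s", ("a", "b", "c"), "vas")
        occ = dm.assemble_occasions(filtered, iset)[0]
        assert occ.mean_log_rt == pytest.approx(math.log(2.0))

    def test_no_items_gives_nan(self):
        assert math.isnan(dm.mean_log_rt([]))


def test_preprocess_order_and_accounting(synth_medium):
    from emadiff import synthetic

    cfg, records, _ = synth_medium
    occ, acct = dm.preprocess(records, synthetic.affect_item_set(cfg))
    assert acct["occasions_retained"] == len(occ)
    assert (
        acct["occasions_assembled"] - acct["occasions_removed_invariant"]
        == acct["occasions_retained"]
    )
    # every retained occasion has RT variation and enough items
    for o in occ[:200]:
        assert len(o.rts) >= 2 and len(set(o.rts.values())) > 1
        assert max(o.rts.values()) <= 30.0
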