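"""Data model, edge-list I/O and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from mergm.netdata import (
    MultilevelNetwork,
    ValidationError,
    descriptive_summary,
    read_multilevel,
    restrict_to_respondents,
    write_multilevel,
)

from conftest import make_random_mnet, net_from_edges


class TestConstruction:
    def test_rejects_self_loops_in_directed_layers(self):
        A = np.eye(3, dtype=np.int8)
        with pytest.raises(ValidationError, match="self-loops"):
            MultilevelNetwork(("a", "b", "c"), ("v",), A,
                              np.zeros((1, 1), np.int8), np.zeros((3, 1), np.int8))

    def test_rejects_duplicate_ids_and_bad_shapes(self):
        with pytest.raises(ValidationError, match="duplicate"):
            MultilevelNetwork(("a", "a"), ("v",), np.zeros((2, 2), np.int8),
                              np.zeros((1, 1), np.int8), np.zeros((2, 1), np.int8))
        with pytest.raises(ValidationError, match="shape"):
            MultilevelNetwork(("a", "b"), ("v",), np.zeros((3, 3), np.int8),
                              np.zeros((1, 1), np.int8), np.zeros((2, 1), np.int8))

    def test_attribute_table_aligned_to_actors(self):
        y = pd.DataFrame({"id": ["m1", "m0"], "gender": ["female", "male"]})
        net = net_from_edges(2, 1, Y=y)
        # records are re-ordered to the actor registry
        assert list(net.Y.index) == ["m0", "m1"]
        assert list(net.Y["gender"]) == ["male", "female"]
        # unknown actor in table is rejected
        with pytest.raises(ValidationError):
            net_from_edges(2, 1, Y=pd.DataFrame({"id": ["m0", "zz"], "gender": ["female", "male"]}))


class TestReadWrite:
    def test_minimal_instance_one_tie_per_layer(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tm1\tm2\nB\tv1\tv2\nX\tm1\tv1\n")
        net = read_multilevel(p, actors=["m1", "m2"], variables=["v1", "v2"])
        assert net.A.sum() == net.B.sum() == net.X.sum() == 1
        assert net.A[0, 1] == 1 and net.B[0, 1] == 1 and net.X[0, 0] == 1

    def test_empty_edge_file_gives_zero_matrices(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("layer\tsource\ttarget\n")
        net = read_multilevel(p, actors=["a", "b", "c"], variables=["v"])
        assert net.A.shape == (3, 3) and not net.A.any()

    def test_self_loop_record_is_named_in_error(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tm1\tm1\n")
        with pytest.raises(ValidationError, match=r"m1.*m1|self-loop"):
            read_multilevel(p, actors=["m1", "m2"], variables=["v"])

    def test_unknown_variable_in_x_record_rejected(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("X\tm1\tnowhere\n")
        with pytest.raises(ValidationError, match="nowhere"):
            read_multilevel(p, actors=["m1", "m2"], variables=["v"])

    def test_duplicate_records_idempotent_with_warning(self, tmp_path, caplog):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tm1\tm2\nA\tm1\tm2\n")
        with caplog.at_level("WARNING", logger="mergm"):
            net = read_multilevel(p, actors=["m1", "m2"], variables=["v"])
        assert net.A.sum() == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_round_trip_preserves_everything(self, rng, tmp_path):
        net = make_random_mnet(rng, n_a=7, n_b=6)
        write_multilevel(net, tmp_path / "e.tsv", tmp_path / "y.csv", tmp_path / "v.txt")
        back = read_multilevel(tmp_path / "e.tsv", tmp_path / "y.csv",
                               variables=tmp_path / "v.txt")
        assert net.equal_layers(back)


class TestRestrict:
    def test_respondent_restriction_shapes(self, rng):
        net = make_random_mnet(rng, n_a=27, n_b=10, with_attributes=False)
        sub = restrict_to_respondents(net, net.actors[:18])
        assert sub.A.shape == (18, 18)
        assert sub.X.shape == (18, 10)
        assert np.array_equal(sub.B, net.B)  # CLD untouched

    def test_all_respondents_is_identity(self, rng):
        net = make_random_mnet(rng)
        assert net.equal_layers(restrict_to_respondents(net, net.actors))

    def test_idempotent(self, rng):
        net = make_random_mnet(rng, n_a=10)
        once = restrict_to_respondents(net, net.actors[:5])
        twice = restrict_to_respondents(once, once.actors)
        assert once.equal_layers(twice)

    @pytest.mark.parametrize("bad", [[], ["ghost"]])
    def test_invalid_respondent_sets_rejected(self, rng, bad):
        net = make_random_mnet(rng)
        with pytest.raises(ValidationError):
            restrict_to_respondents(net, bad)


class TestDescriptives:
    def test_response_rate_18_of_27_is_67_percent(self, rng):
        net = make_random_mnet(rng, n_a=18, with_attributes=False)
        assert descriptive_summary(net, invited=27)["response_rate_pct"] == 67

    def test_response_rate_20_of_27_is_74_percent(self, rng):
        net = make_random_mnet(rng, n_a=20, with_attributes=False)
        assert descriptive_summary(net, invited=27)["response_rate_pct"] == 74

    def test_out_degree_mean_and_range(self):
        net = net_from_edges(3, 1, a_edges=[(0, 1), (0, 2), (1, 2)])
        s = descriptive_summary(net, invited=3)
        assert s["out_degree"] == {"mean": 1.0, "min": 0, "max": 2}

    def test_female_14_of_18_is_78_percent(self):
        y = pd.DataFrame({
            "id": [f"m{i}" for i in range(18)],
            "gender": ["female"] * 14 + ["male"] * 4,
        })
        net = net_from_edges(18, 1, Y=y)
        s = descriptive_summary(net, invited=27)
        assert s["attributes"]["gender"]["female"] == {"n": 14, "pct": 78}

    def test_invalid_invited_counts(self, rng):
        net = make_random_mnet(rng)
        with pytest.raises(ValidationError):
            descriptive_summary(net, invited=0)
        with pytest.raises(ValidationError):
            descriptive_summary(net, invited=net.n_actors - 1)

    def test_summary_matches_brute_force_recomputation(self, rng):
        net = make_random_mnet(rng, n_a=12, n_b=9)
        s = descriptive_summary(net, invited=15)
        out = [sum(net.A[i, j] for j in range(12)) for i in range(12)]
        acts = [sum(net.X[i, v] for v in range(9)) for i in range(12)]
        assert s["out_degree"]["mean"] == pytest.approx(sum(out) / 12)
        assert (s["out_degree"]["min"], s["out_degree"]["max"]) == (min(out), max(out))
        assert s["actions_per_member"]["mean"] == pytest.approx(sum(acts) / 12)
        assert s["n_cld_variables"] == 9
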