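import io

import numpy as np
import pytest
from scipy.stats import norm

from microcolony.lineage import (
    HIGH,
    LOW,
    LineageError,
    classify,
    fit_gmm_threshold,
    read_lineage_table,
    validate_tree,
    write_lineage_table,
)

from conftest import make_tree, obs

MINIMAL_CSV = """cell_id,parent_id,frame,time_h,x_um,y_um,fluor_405,fluor_488,atp_mM,placeholder
a,,0,0.0,0.0,0.0,,,2.0,0
a,,1,1.0,0.1,0.0,,,2.5,0
a,,2,2.0,0.1,0.1,,,2.2,0
a0,a,3,3.0,1.0,0.0,,,1.0,0
a0,a,4,4.0,1.1,0.0,,,1.2,0
a0,a,5,5.0,1.1,0.1,,,1.1,0
a1,a,3,3.0,-1.0,0.0,,,4.0,0
a1,a,4,4.0,-1.1,0.0,,,4.2,0
a1,a,5,5.0,-1.1,0.1,,,4.1,0
"""


class TestReadWrite:
    def test_minimal_binary_tree(self):
        tree = read_lineage_table(io.StringIO(MINIMAL_CSV))
        assert len(tree.cells) == 3
        assert tree.founders == ["a"]
        assert tree.children_of("a") == ["a0", "a1"]
        assert len(tree.cells["a"].observations) == 3

    def test_orphan_parent_is_structural_error(self):
        bad = MINIMAL_CSV.replace("a1,a,", "a1,ghost,")
        with pytest.raises(LineageError, match="ghost"):
            read_lineage_table(io.StringIO(bad))

    def test_placeholder_excluded_from_stats_but_kept(self):
        csv = MINIMAL_CSV.replace("a,,1,1.0,0.1,0.0,,,2.5,0",
                                  "a,,1,1.0,0.1,0.0,,,2.5,1")
        tree = read_lineage_table(io.StringIO(csv))
        cell = tree.cells["a"]
        assert len(cell.observations) == 3          # retained in structure
        assert len(cell.valid_observations()) == 2  # excluded from statistics
        assert cell.atp_trace().tolist() == [2.0, 2.2]

    def test_round_trip_bit_identical(self):
        tree = read_lineage_table(io.StringIO(MINIMAL_CSV))
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_lineage_table(tree, buf1)
        write_lineage_table(read_lineage_table(io.StringIO(buf1.getvalue())), buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_missing_signal_on_real_frame_is_error(self):
        bad = MINIMAL_CSV.replace("a,,1,1.0,0.1,0.0,,,2.5,0",
                                  "a,,1,1.0,0.1,0.0,,,,0")
        with pytest.raises(LineageError):
            read_lineage_table(io.StringIO(bad))


class TestValidate:
    def test_valid_tree_has_no_violations(self):
        tree = read_lineage_table(io.StringIO(MINIMAL_CSV))
        assert validate_tree(tree) == []

    def test_single_child_flagged_as_non_binary(self):
        tree = make_tree({
            "a": (None, [obs(0, 0.0, atp=1.0), obs(1, 1.0, atp=1.0)]),
            "a0": ("a", [obs(2, 2.0, atp=1.0)]),
        })
        v = validate_tree(tree)
        assert any("non-binary" in s for s in v)

    def test_child_born_before_parent_end(self):
        tree = make_tree({
            "a": (None, [obs(0, 0.0, atp=1.0), obs(3, 3.0, atp=1.0)]),
            "a0": ("a", [obs(1, 1.0, atp=1.0)]),
            "a1": ("a", [obs(4, 4.0, atp=1.0)]),
        })
        v = validate_tree(tree)
        assert any("time ordering" in s for s in v)


class TestGMMThreshold:
    def test_separated_mixture_threshold_near_midpoint(self):
        r = np.random.default_rng(7)
        values = np.concatenate([r.normal(1, 0.1, 500), r.normal(9, 0.1, 500)])
        bc = fit_gmm_threshold(values, seed=7)
        # equal weights and variances: the equal-posterior point is the
        # midpoint of the generating means
        assert 4.9 <= bc.threshold <= 5.1
        w, mu, sd = zip(*bc.gmm_params)
        assert abs(sum(w) - 1) < 1e-9
        assert mu[0] < bc.threshold < mu[1]

    def test_symmetric_data_threshold_is_midpoint_of_fitted_means(self):
        r = np.random.default_rng(3)
        half = r.normal(2, 0.3, 400)
        values = np.concatenate([half, 10.0 - half])  # exactly mirrored
        bc = fit_gmm_threshold(values, seed=0)
        mid = 0.5 * (bc.gmm_params[0][1] + bc.gmm_params[1][1])
        assert abs(bc.threshold - mid) < 1e-7

    def test_multi_restart_makes_threshold_seed_stable(self):
        r = np.random.default_rng(11)
        values = np.concatenate([r.normal(2, 0.4, 300), r.normal(6, 0.6, 300)])
        t1 = fit_gmm_threshold(values, seed=1).threshold
        t2 = fit_gmm_threshold(values, seed=99).threshold
        assert abs(t1 - t2) < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_well_separated_means_recovered_within_5pct(self, seed):
        r = np.random.default_rng(seed)
        m1, m2, sd = 2.0, 7.0, 0.5  # separation 10 sd
        values = np.concatenate([r.normal(m1, sd, 300), r.normal(m2, sd, 300)])
        bc = fit_gmm_threshold(values, seed=seed, n_restarts=10)
        mus = sorted(p[1] for p in bc.gmm_params)
        assert abs(mus[0] - m1) / m1 < 0.05
        assert abs(mus[1] - m2) / m2 < 0.05

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_gmm_threshold([1.0] * 5)
        with pytest.raises(ValueError):
            fit_gmm_threshold([-1.0] + [1.0] * 10)
        with pytest.raises(ValueError):
            fit_gmm_threshold([2.0] * 20)


class TestClassify:
    def tree(self):
        return make_tree({
            "a": (None, [obs(0, 0.0, atp=1.0), obs(1, 1.0, atp=9.0)]),
        })

    def test_observation_and_cell_classes(self):
        cls = classify(self.tree(), threshold=4.0)
        assert cls.per_observation_class[("a", 0)] == LOW
        assert cls.per_observation_class[("a", 1)] == HIGH
        assert cls.per_cell_class["a"] == HIGH  # mean 5 > 4

    def test_threshold_above_max_gives_zero_high(self):
        cls = classify(self.tree(), threshold=100.0)
        assert all(v == LOW for v in cls.per_observation_class.values())
        assert all(v == LOW for v in cls.per_cell_class.values())

    def test_monotone_in_threshold(self, rng):
        tree = make_tree({
            str(i): (None, [obs(k, float(k), atp=float(v))
                            for k, v in enumerate(rng.uniform(0, 10, 5))])
            for i in range(20)
        })
        counts = []
        for thr in np.linspace(0, 10, 21):
            cls = classify(tree, thr)
            counts.append(sum(v == HIGH for v in cls.per_cell_class.values()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_atp_is_error(self):
        tree = make_tree({"a": (None, [obs(0, 0.0, f405=1.0, f488=2.0)])})
        with pytest.raises(LineageError):
            classify(tree, 1.0)
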