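import numpy as np
import pandas as pd
import pytest

from umscan import (
    ChannelIntensities,
    CohortDesign,
    InfiniumType,
    IntensityMatrices,
    ProbeDesign,
    Strand,
    compute_beta,
    compute_mvalue,
    map_channels,
    quantile_normalize,
    read_cohort,
    read_intensity_tables,
    read_manifest,
    write_cohort,
    write_intensity_tables,
    write_manifest,
)


def _intens(u, m, su=None, sm=None):
    u = np.atleast_2d(np.asarray(u, float))
    m = np.atleast_2d(np.asarray(m, float))
    su = np.zeros_like(u) if su is None else np.atleast_2d(np.asarray(su, float))
    sm = np.zeros_like(m) if sm is None else np.atleast_2d(np.asarray(sm, float))
    idx = pd.Index([f"p{i}" for i in range(u.shape[0])], name="probe_id")
    cols = pd.Index([f"s{j}" for j in range(u.shape[1])], name="sample_id")
    mk = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    return IntensityMatrices(U=mk(u), M=mk(m), sigma_U=mk(su), sigma_M=mk(sm))


class TestTransforms:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(0.0, 0.0, 0.0), (100.0, 0.0, 0.5), (450.0, 450.0, 0.45)],
    )
    def test_beta_values(self, m, u, expected):
        assert compute_beta(_intens([[u]], [[m]])).iloc[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "m,u,expected", [(5.0, 5.0, 0.0), (3.0, 1.0, 1.0), (0.0, 0.0, 0.0)]
    )
    def test_mvalue_values(self, m, u, expected):
        assert compute_mvalue(_intens([[u]], [[m]])).iloc[0, 0] == pytest.approx(expected)

    def test_beta_requires_positive_offset(self):
        with pytest.raises(ValueError):
            compute_beta(_intens([[1.0]], [[1.0]]), offset=0.0)

    def test_beta_complement_identity_and_monotonicity(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 5000, (20, 30))
        m = rng.uniform(0, 5000, (20, 30))
        intens = _intens(u, m)
        beta = compute_beta(intens).to_numpy()
        complement = (u + 100.0) / (m + u + 100.0)
        assert np.allclose(beta + complement, 1.0)
        # both scales increase with M at fixed U
        bigger = _intens(u, m + 1.0)
        assert (compute_beta(bigger).to_numpy() > beta).all()
        assert (
            compute_mvalue(bigger).to_numpy() > compute_mvalue(intens).to_numpy()
        ).all()


class TestQuantileNormalize:
    def test_single_column_unchanged(self):
        x = np.array([[3.0], [1.0], [2.0]])
        assert np.allclose(quantile_normalize(x), x)

    def test_two_columns_row_means_of_sorted(self):
        x = np.array([[1.0, 6.0], [2.0, 4.0], [3.0, 5.0]])
        out = quantile_normalize(x)
        assert np.allclose(sorted(out[:, 0]), [2.5, 3.5, 4.5])
        assert np.allclose(sorted(out[:, 1]), [2.5, 3.5, 4.5])

    def test_columns_share_sorted_values_and_preserve_ranks(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 6))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(6):
            assert np.allclose(np.sort(out[:, j]), ref)
            assert (np.argsort(out[:, j]) == np.argsort(x[:, j])).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 5))
        once = quantile_normalize(x)
        assert np.allclose(quantile_normalize(once), once)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 4))
        perm = [2, 0, 3, 1]
        assert np.allclose(quantile_normalize(x[:, perm]), quantile_normalize(x)[:, perm])

    def test_ties_get_average_of_reference(self):
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(x)
        # tied smallest values in column 0 share the mean of the two lowest
        # reference quantiles
        ref = np.sort(np.sort(x, axis=0).mean(axis=1))
        assert out[0, 0] == out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_row_returns_row_mean(self):
        out = quantile_normalize(np.array([[2.0, 4.0]]))
        assert np.allclose(out, 3.0)

    def test_missing_values_stay_missing(self):
        x = np.array([[1.0, 4.0], [np.nan, 5.0], [3.0, 6.0]])
        out = quantile_normalize(x)
        assert np.isnan(out[1, 0]) and np.isfinite(out[[0, 2], 0]).all()
        assert np.isfinite(out[:, 1]).all()


class TestMapChannels:
    def _channels(self):
        addr = pd.Index([101, 102, 103])
        cols = ["s1", "s2"]
        g_mean = pd.DataFrame([[5000.0, 5100.0], [4000.0, 4100.0], [100.0, 110.0]], addr, cols)
        g_sd = pd.DataFrame([[200.0, 210.0], [150.0, 160.0], [20.0, 21.0]], addr, cols)
        r_mean = pd.DataFrame([[300.0, 310.0], [700.0, 710.0], [800.0, 810.0]], addr, cols)
        r_sd = pd.DataFrame([[50.0, 51.0], [60.0, 61.0], [70.0, 71.0]], addr, cols)
        return ChannelIntensities(g_mean, g_sd), ChannelIntensities(r_mean, r_sd)

    def test_type_ii_green_is_m_red_is_u(self):
        green, red = self._channels()
        design = ProbeDesign("cgA", InfiniumType.II, Strand.PLUS)
        out = map_channels(green, red, {"cgA": (101, None)}, [design])
        assert out.M.loc["cgA", "s1"] == 5000 and out.sigma_M.loc["cgA", "s1"] == 200
        assert out.U.loc["cgA", "s1"] == 300 and out.sigma_U.loc["cgA", "s1"] == 50

    def test_type_i_green_reads_both_addresses_in_band(self):
        green, red = self._channels()
        design = ProbeDesign("cgB", InfiniumType.I_GREEN, Strand.PLUS)
        out = map_channels(green, red, {"cgB": (102, 103)}, [design])
        # address A holds the unmethylated design, B the methylated one
        assert out.U.loc["cgB", "s1"] == 4000 and out.M.loc["cgB", "s1"] == 100
        assert out.sigma_U.loc["cgB", "s1"] == 150 and out.sigma_M.loc["cgB", "s1"] == 20

    def test_type_i_red_uses_red_channel(self):
        green, red = self._channels()
        design = ProbeDesign("cgC", InfiniumType.I_RED, Strand.PLUS)
        out = map_channels(green, red, {"cgC": (102, 103)}, [design])
        assert out.U.loc["cgC", "s1"] == 700 and out.M.loc["cgC", "s1"] == 800

    def test_missing_address_drops_probe(self, caplog):
        green, red = self._channels()
        designs = [
            ProbeDesign("cgA", InfiniumType.II, Strand.PLUS),
            ProbeDesign("cgZ", InfiniumType.II, Strand.PLUS),
        ]
        out = map_channels(green, red, {"cgA": (101, None), "cgZ": (999, None)}, designs)
        assert list(out.probe_ids) == ["cgA"]

    def test_unknown_infinium_type_is_hard_error(self):
        with pytest.raises(ValueError):
            ProbeDesign("cgX", "TYPE_III", Strand.PLUS)


class TestIO:
    def test_intensity_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(4)
        intens = _intens(
            rng.uniform(0, 1e4, (5, 3)), rng.uniform(0, 1e4, (5, 3)),
            rng.uniform(0, 500, (5, 3)), rng.uniform(0, 500, (5, 3)),
        )
        paths = write_intensity_tables(intens, tmp_path)
        back = read_intensity_tables(paths["U"], paths["M"], paths["sigma_U"], paths["sigma_M"])
        for name in ("U", "M", "sigma_U", "sigma_M"):
            pd.testing.assert_frame_equal(getattr(back, name), getattr(intens, name))

    def test_sample_order_joined_by_id_not_position(self, tmp_path):
        intens = _intens([[1.0, 2.0]], [[3.0, 4.0]])
        paths = write_intensity_tables(intens, tmp_path)
        shuffled = pd.read_csv(paths["M"], sep="\t", index_col=0)[["s1", "s0"]]
        shuffled.to_csv(paths["M"], sep="\t")
        back = read_intensity_tables(paths["U"], paths["M"], paths["sigma_U"], paths["sigma_M"])
        assert back.M.loc["p0", "s1"] == 4.0 and back.M.loc["p0", "s0"] == 3.0

    def test_mismatched_ids_error_names_file(self, tmp_path):
        intens = _intens([[1.0]], [[2.0]])
        paths = write_intensity_tables(intens, tmp_path)
        bad = pd.DataFrame([[1.0]], index=pd.Index(["other"], name="probe_id"), columns=["s0"])
        bad.to_csv(paths["sigma_U"], sep="\t")
        with pytest.raises(ValueError, match="sigma_U"):
            read_intensity_tables(paths["U"], paths["M"], paths["sigma_U"], paths["sigma_M"])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _intens([[-1.0]], [[2.0]])

    def test_manifest_round_trip(self, tmp_path):
        designs = [
            ProbeDesign("cg1", InfiniumType.II, Strand.PLUS, "chr1", 123, 0),
            ProbeDesign("cg2", InfiniumType.I_RED, Strand.MINUS, "chr2", 456, 3),
        ]
        path = tmp_path / "manifest.tsv"
        write_manifest(designs, path)
        back = read_manifest(path)
        assert back["cg2"].infinium_type is InfiniumType.I_RED
        assert back["cg2"].strand is Strand.MINUS and back["cg2"].cpg_pos == 456

    def test_cohort_round_trip(self, tmp_path):
        cohort = CohortDesign(
            ["a", "b", "c"], {"a": "p1", "b": "p1"}, batch_id={"a": "x", "b": "x", "c": "y"}
        )
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back.twin_pairs() == [("a", "b")]
        assert back.batch_id["c"] == "y"


class TestCohortDesign:
    def test_incomplete_twin_pair_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            CohortDesign(["a", "b", "c"], {"a": "p1"})

    def test_pair_ordering_is_lexicographic(self):
        cohort = CohortDesign(["z9", "a1"], {"z9": "p1", "a1": "p1"})
        assert cohort.twin_pairs() == [("a1", "z9")]


def test_sbe_position_follows_strand():
    plus = ProbeDesign("cg", InfiniumType.I_GREEN, Strand.PLUS, cpg_pos=100)
    minus = ProbeDesign("cg", InfiniumType.I_GREEN, Strand.MINUS, cpg_pos=100)
    type2 = ProbeDesign("cg", InfiniumType.II, Strand.PLUS, cpg_pos=100)
    assert plus.sbe_pos == 99 and minus.sbe_pos == 102 and type2.sbe_pos is None
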