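"""Window tiling, counting against a brute-force oracle, ratios, density."""

import numpy as np
import pandas as pd
import pytest

from alienscan.coverage import (count_present_markers, density_matrix,
                                make_windows, ratio_profile,
                                reference_sample_for)
from alienscan.formats_io import ABSENT, MISSING, PRESENT
from alienscan.synthetic import SimConfig, simulate_panel

from conftest import MB, basic_sheet, make_layout, make_matrix


def classes_for(markers, klass="aegilops_U"):
    return pd.DataFrame({"marker_class": [klass] * len(markers),
                         "reason": [""] * len(markers)},
                        index=pd.Index(markers, name="marker_id"))


class TestMakeWindows:
    def test_remainder_window(self):
        layout = make_layout([("1U", "U", int(3.5 * MB), MB, 1)])
        grid = make_windows(layout, MB)
        starts, ends = grid.bounds("1U")
        assert grid.n_windows("1U") == 4
        assert (starts[-1], ends[-1]) == (3 * MB, int(3.5 * MB))
        # exact non-overlapping tiling
        assert starts[0] == 0 and (starts[1:] == ends[:-1]).all()

    def test_single_window_chromosome(self):
        layout = make_layout([("1U", "U", MB, MB // 2, 1)])
        assert make_windows(layout, MB).n_windows("1U") == 1

    def test_default_window_is_one_mb(self):
        layout = make_layout([("1U", "U", 5 * MB, 2 * MB, 1)])
        assert make_windows(layout).window_size == MB

    def test_nonpositive_window_rejected(self):
        layout = make_layout([("1U", "U", MB, MB // 2, 1)])
        with pytest.raises(ValueError):
            make_windows(layout, 0)


class TestCountPresentMarkers:
    def _setup(self, positions, calls_row):
        layout = make_layout([("1U", "U", 5 * MB, 2 * MB, 1)])
        grid = make_windows(layout, MB)
        markers = [f"m{i}" for i in range(len(positions))]
        G = make_matrix(markers, ["S1"], [[c] for c in calls_row])
        placements = pd.DataFrame({"marker_id": markers, "chromosome": "1U",
                                   "position": positions})
        return G, classes_for(markers), placements, grid

    def test_half_open_window_boundaries(self):
        G, cls, pl, grid = self._setup([0, 999_999, 1_000_000],
                                       [PRESENT, PRESENT, PRESENT])
        prof = count_present_markers(G, cls, pl, grid, "S1", "aegilops_U")
        assert prof.raw["1U"].tolist() == [2, 1, 0, 0, 0]

    def test_missing_and_absent_calls_contribute_nothing(self):
        G, cls, pl, grid = self._setup([0, 10, 20], [PRESENT, ABSENT, MISSING])
        prof = count_present_markers(G, cls, pl, grid, "S1", "aegilops_U")
        assert prof.raw["1U"].sum() == 1

    def test_normalization_by_panel_wide_assignment(self):
        G, cls, pl, grid = self._setup([0, 10, 2_000_000],
                                       [PRESENT, ABSENT, PRESENT])
        prof = count_present_markers(G, cls, pl, grid, "S1", "aegilops_U")
        assert prof.n_assigned["1U"] == 3  # all placed markers, not present ones
        assert prof.normalized["1U"][0] == pytest.approx(1 / 3)

    def test_unknown_sample_rejected(self):
        G, cls, pl, grid = self._setup([0], [PRESENT])
        with pytest.raises(KeyError):
            count_present_markers(G, cls, pl, grid, "nope", "aegilops_U")

    def test_counts_equal_brute_force_oracle(self):
        """200 random markers/calls: per-window counts equal a double loop
        over (marker, window)."""
        rng = np.random.default_rng(11)
        layout = make_layout([("1U", "U", 13 * MB, 5 * MB, 1),
                              ("2U", "U", 7 * MB, 3 * MB, 2)])
        grid = make_windows(layout, MB)
        n = 200
        markers = [f"m{i}" for i in range(n)]
        chroms = rng.choice(["1U", "2U"], n)
        lengths = {"1U": 13 * MB, "2U": 7 * MB}
        pos = np.array([rng.integers(0, lengths[c]) for c in chroms])
        calls = rng.choice([PRESENT, ABSENT, MISSING], n, p=[0.5, 0.3, 0.2])
        G = make_matrix(markers, ["S1"], [[c] for c in calls])
        pl = pd.DataFrame({"marker_id": markers, "chromosome": chroms,
                           "position": pos})
        prof = count_present_markers(G, classes_for(markers), pl, grid,
                                     "S1", "aegilops_U")
        for chrom in ("1U", "2U"):
            starts, ends = grid.bounds(chrom)
            for k, (s, e) in enumerate(zip(starts, ends)):
                expected = sum(
                    1 for i in range(n)
                    if chroms[i] == chrom and s <= pos[i] < e
                    and calls[i] == PRESENT)
                assert prof.raw[chrom][k] == expected
        # conservation: per-chromosome sums equal placed & present counts
        for chrom in ("1U", "2U"):
            present_here = sum(1 for i in range(n)
                               if chroms[i] == chrom and calls[i] == PRESENT)
            assert prof.raw[chrom].sum() == present_here


class TestRatioProfile:
    def _profiles(self, bc_calls, ref_calls, positions):
        layout = make_layout([("1U", "U", 4 * MB, 2 * MB, 1)])
        grid = make_windows(layout, MB)
        markers = [f"m{i}" for i in range(len(positions))]
        G = make_matrix(markers, ["BC", "REF"],
                        list(map(list, zip(bc_calls, ref_calls))))
        pl = pd.DataFrame({"marker_id": markers, "chromosome": "1U",
                           "position": positions})
        cls = classes_for(markers)
        bc = count_present_markers(G, cls, pl, grid, "BC", "aegilops_U")
        ref = count_present_markers(G, cls, pl, grid, "REF", "aegilops_U")
        return bc, ref

    def test_bc_zero_over_ref_positive_is_zero(self):
        bc, ref = self._profiles([ABSENT] * 5, [PRESENT] * 5,
                                 [0, 100, 200, 300, 400])
        r = ratio_profile(bc, ref)
        assert r.ratio["1U"][0] == 0.0 and r.mask["1U"][0]

    def test_self_comparison_is_one_on_informative_windows(self):
        bc, ref = self._profiles([PRESENT, ABSENT, PRESENT],
                                 [PRESENT, ABSENT, PRESENT],
                                 [0, MB, 2 * MB])
        r = ratio_profile(bc, bc)
        informative = r.mask["1U"]
        assert np.allclose(r.ratio["1U"][informative], 1.0)

    def test_reference_zero_window_masked(self):
        bc, ref = self._profiles([PRESENT, PRESENT], [PRESENT, ABSENT],
                                 [0, MB])
        r = ratio_profile(bc, ref)
        assert not r.mask["1U"][1] and np.isnan(r.ratio["1U"][1])

    def test_normalization_cancels_to_raw_count_ratio(self):
        rng = np.random.default_rng(3)
        n = 60
        bc_calls = rng.choice([PRESENT, ABSENT], n)
        ref_calls = rng.choice([PRESENT, ABSENT], n, p=[0.8, 0.2])
        pos = rng.integers(0, 4 * MB, n)
        bc, ref = self._profiles(bc_calls, ref_calls, pos)
        r = ratio_profile(bc, ref)
        informative = r.mask["1U"]
        raw_ratio = bc.raw["1U"][informative] / ref.raw["1U"][informative]
        assert np.abs(r.ratio["1U"][informative] - raw_ratio).max() < 1e-12

    def test_mismatched_marker_sets_rejected(self):
        bc, ref = self._profiles([PRESENT], [PRESENT], [0])
        ref.marker_set = "wheat_specific"
        with pytest.raises(ValueError):
            ratio_profile(bc, ref)


class TestDensityMatrix:
    def test_per_mb_scaling_in_short_terminal_window(self):
        layout = make_layout([("1U", "U", int(2.5 * MB), MB, 1)])
        grid = make_windows(layout, MB)
        markers = [f"m{i}" for i in range(10)]
        # 7 markers in window 0, 3 in the terminal half-window
        pos = [1000 * i for i in range(7)] + [2 * MB + 1000 * i for i in range(3)]
        G = make_matrix(markers, ["S1"], [[PRESENT]] * 10)
        pl = pd.DataFrame({"marker_id": markers, "chromosome": "1U",
                           "position": pos})
        prof = count_present_markers(G, classes_for(markers), pl, grid,
                                     "S1", "aegilops_U")
        dm = density_matrix([prof])
        assert dm.loc["1U:0-1000000", "S1"] == pytest.approx(7.0)
        assert dm.loc["1U:2000000-2500000", "S1"] == pytest.approx(6.0)

    def test_all_zero_profile_gives_zero_column(self):
        layout = make_layout([("1U", "U", 2 * MB, MB, 1)])
        grid = make_windows(layout, MB)
        G = make_matrix(["m0"], ["S1"], [[ABSENT]])
        pl = pd.DataFrame({"marker_id": ["m0"], "chromosome": "1U",
                           "position": [0]})
        prof = count_present_markers(G, classes_for(["m0"]), pl, grid,
                                     "S1", "aegilops_U")
        assert (density_matrix([prof])["S1"] == 0).all()


def test_reference_sample_routing(basic_sheet):
    assert reference_sample_for(basic_sheet, "BC1", "wheat_specific") == "WP"
    assert reference_sample_for(basic_sheet, "BC1", "aegilops_U") == "DA"
    assert reference_sample_for(basic_sheet, "BC1", "aegilops_M") == "DA"


def test_synthetic_marker_density_higher_at_telomeres():
    """Distal 20% of each arm carries a higher markers-per-Mb density than
    the proximal 20% around the centromere (telomere bias 3x)."""
    cfg = SimConfig(seed=5, telomere_bias=3.0)
    panel = simulate_panel(cfg)
    distal_counts, distal_len = 0, 0.0
    proximal_counts, proximal_len = 0, 0.0
    for chrom in panel.layout.chromosomes():
        L = panel.layout.length_of(chrom)
        cen = panel.layout.centromere_of(chrom)
        pos = panel.markers.loc[panel.markers["chromosome"] == chrom,
                                "position"].to_numpy()
        for a0, a1, telo_at_start in ((0, cen, True), (cen, L, False)):
            arm = a1 - a0
            fifth = 0.2 * arm
            if telo_at_start:
                distal = (pos >= a0) & (pos < a0 + fifth)
                proximal = (pos >= a1 - fifth) & (pos < a1)
            else:
                distal = (pos >= a1 - fifth) & (pos < a1)
                proximal = (pos >= a0) & (pos < a0 + fifth)
            distal_counts += distal.sum()
            proximal_counts += proximal.sum()
            distal_len += fifth
            proximal_len += fifth
    assert distal_counts / distal_len > proximal_counts / proximal_len
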