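"""Peak-list parsing, attenuation profiles, binning and motif detection."""

import numpy as np
import pandas as pd
import pytest

from spopbind import (
    BIN_SCHEMES,
    bin_changes,
    compute_intensity_change,
    detect_binding_regions,
    gen_nmr_titration,
    read_peak_list,
)
from spopbind.nmr import (
    PeakListError,
    export_attributes,
    read_attributes,
    write_profile_csv,
    write_sparky_list,
)


def make_profile(changes: dict[int, float], missing: set[int] = frozenset()):
    """Profile fixture from residue -> percent_change (fraction)."""
    residues = sorted(set(changes) | set(missing))
    apo = pd.DataFrame({"residue": residues, "intensity": [100.0] * len(residues)})
    bound = pd.DataFrame(
        {
            "residue": [r for r in residues if r not in missing],
            "intensity": [100.0 * (1 - changes.get(r, 0.0)) for r in residues if r not in missing],
        }
    )
    return compute_intensity_change(apo, bound, normalization="max")


class TestPeakListIO:
    def test_sparky_assignments_parsed(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text(
            "      Assignment         w1         w2   Data Height\n"
            "G220N-H\t118.2\t8.10\t1.5e+06\n"
            "V229N-H\t121.0\t8.32\t9.8e+05\n"
            "S273N-H\t116.4\t8.05\t1.1e+06\n"
        )
        table = read_peak_list(path)
        assert list(table["residue"]) == [220, 229, 273]

    def test_unparseable_rows_skipped_with_warning(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text("G220N-H\t118.2\t8.1\t1e6\n?-?\t0\t0\t2e6\n")
        with pytest.warns(RuntimeWarning, match="skipped 1"):
            table = read_peak_list(path, dialect="sparky_list")
        assert list(table["residue"]) == [220]

    def test_duplicate_residue_is_error_naming_it(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text("V229N-H\t1\t1\t1e6\nV229CA-HA\t1\t1\t2e6\n")
        with pytest.raises(PeakListError, match="229"):
            read_peak_list(path, dialect="sparky_list")

    def test_no_parseable_rows_is_format_error(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text("?-?\t0\t0\tnotanumber\n")
        with pytest.raises(PeakListError):
            read_peak_list(path, dialect="sparky_list")

    def test_generic_csv_and_writer_round_trip(self, tmp_path):
        table = pd.DataFrame({"residue": [204, 205, 206], "intensity": [1.0, 2.0, 3.0]})
        sparky = tmp_path / "out.list"
        write_sparky_list(table, sparky)
        back = read_peak_list(sparky)  # auto-detects dialect
        np.testing.assert_allclose(back["intensity"], table["intensity"], rtol=1e-5)
        csv = tmp_path / "out.csv"
        table.to_csv(csv, index=False)
        back2 = read_peak_list(csv, dialect="generic_csv")
        assert list(back2["residue"]) == [204, 205, 206]


class TestIntensityChange:
    def test_attenuation_arithmetic_on_common_scale(self):
        profile = make_profile({**{r: 0.0 for r in range(204, 215)}, 229: 0.80})
        assert profile.table.loc[229, "percent_change"] == pytest.approx(0.80)

    def test_identical_datasets_give_zero_change(self):
        profile = make_profile({r: 0.0 for r in range(204, 216)})
        assert np.allclose(profile.scored()["percent_change"], 0.0)

    def test_residue_absent_from_bound_is_omitted_and_binned_darkest(self):
        profile = make_profile({r: 0.0 for r in range(204, 215)}, missing={210})
        assert bool(profile.table.loc[210, "missing"])
        assert profile.table.loc[210, "missing_reason"] == "omitted"
        bins = bin_changes(profile, BIN_SCHEMES["sbm1_4bin"])
        assert bins.loc[210, "bin"] == "<70"

    def test_scale_invariance_of_percent_change(self):
        residues = list(range(204, 224))
        apo = pd.DataFrame({"residue": residues, "intensity": np.linspace(50, 150, 20)})
        bound = apo.copy()
        bound.loc[5:9, "intensity"] *= 0.2  # attenuate a block
        ref = compute_intensity_change(apo, bound)
        scaled = bound.copy()
        scaled["intensity"] *= 7.3
        alt = compute_intensity_change(apo, scaled)
        np.testing.assert_allclose(
            ref.scored()["percent_change"], alt.scored()["percent_change"], atol=1e-12
        )

    def test_too_few_shared_residues_rejected(self):
        apo = pd.DataFrame({"residue": [1, 2, 3], "intensity": [1.0, 1.0, 1.0]})
        with pytest.raises(PeakListError, match="shared"):
            compute_intensity_change(apo, apo.copy())


class TestBinning:
    @pytest.mark.parametrize(
        "change, label",
        [(0.95, ">90"), (0.85, "80 to 90"), (0.75, "70 to 80"), (0.50, "<70")],
    )
    def test_four_bin_scheme_thresholds(self, change, label):
        scheme = BIN_SCHEMES["sbm1_4bin"]
        assert scheme.assign(change) == label

    @pytest.mark.parametrize(
        "change, label", [(0.80, ">70"), (0.55, "40 to 70"), (0.20, "<40")]
    )
    def test_three_bin_scheme_thresholds(self, change, label):
        assert BIN_SCHEMES["sbm2_3bin"].assign(change) == label

    def test_binning_partitions_all_residues(self):
        rng = np.random.default_rng(3)
        changes = {204 + i: float(rng.uniform(-0.2, 1.0)) for i in range(40)}
        profile = make_profile(changes, missing={210, 230})
        for scheme in BIN_SCHEMES.values():
            bins = bin_changes(profile, scheme)
            assert len(bins) == len(profile.table)
            counts = bins["bin"].value_counts()
            assert counts.sum() == len(profile.table)
            assert set(counts.index) <= set(scheme.labels)


class TestRegionDetection:
    def test_planted_motifs_recovered_exactly(self):
        changes = {r: 0.0 for r in range(204, 284)}
        changes.update({r: 0.85 for r in range(220, 236)})
        changes.update({r: 0.75 for r in range(265, 276)})
        regions = detect_binding_regions(make_profile(changes))
        assert [r.as_tuple() for r in regions] == [(220, 235), (265, 275)]
        assert regions[0].mean_percent_change == pytest.approx(0.85)

    def test_flat_profile_has_no_regions(self):
        changes = {r: 0.05 for r in range(204, 284)}
        assert detect_binding_regions(make_profile(changes)) == []

    def test_single_attenuated_residue_below_min_run(self):
        changes = {r: 0.0 for r in range(204, 284)}
        changes[229] = 0.95
        assert detect_binding_regions(make_profile(changes), min_run=4) == []

    def test_interior_gap_bridged_up_to_max_gap(self):
        changes = {r: 0.0 for r in range(204, 284)}
        changes.update({r: 0.85 for r in range(220, 236)})
        changes[227] = 0.1  # one scored dip inside the motif
        regions = detect_binding_regions(make_profile(changes), max_gap=1)
        assert [r.as_tuple() for r in regions] == [(220, 235)]
        # with max_gap 0 the dip splits the motif
        split = detect_binding_regions(make_profile(changes), max_gap=0)
        assert [r.as_tuple() for r in split] == [(220, 226), (228, 235)]

    def test_missing_residues_do_not_split_a_motif(self):
        changes = {r: 0.0 for r in range(204, 284)}
        changes.update({r: 0.85 for r in range(220, 236)})
        regions = detect_binding_regions(make_profile(changes, missing={227, 228}))
        assert [r.as_tuple() for r in regions] == [(220, 235)]

    def test_closed_loop_with_generator(self, clean_nmr_config):
        apo, bound, truth = gen_nmr_titration(clean_nmr_config)
        profile = compute_intensity_change(apo, bound)
        regions = detect_binding_regions(profile)
        assert [r.as_tuple() for r in regions] == [tuple(t) for t in truth["regions"]]


class TestAttributeExport:
    def test_round_trip_and_determinism(self, tmp_path):
        changes = {204 + i: 0.1 * (i % 10) for i in range(30)}
        profile = make_profile(changes, missing={212})
        bins = bin_changes(profile, BIN_SCHEMES["sbm2_3bin"])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_attributes(bins, "A", p1)
        export_attributes(bins, "A", p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_attributes(p1)
        assert list(back["rank"]) == list(bins.sort_index()["rank"])
        assert list(back["bin"]) == list(bins.sort_index()["bin"])

    def test_empty_bins_header_only_with_warning(self, tmp_path):
        empty = pd.DataFrame(columns=["bin", "rank"])
        out = tmp_path / "empty.tsv"
        with pytest.warns(RuntimeWarning):
            export_attributes(empty, "A", out)
        assert out.read_text().strip().endswith("residue\trank")

    def test_profile_csv_columns(self, tmp_path):
        profile = make_profile({204: 0.9, 205: 0.1, 206: 0.5, **{r: 0.0 for r in range(207, 215)}})
        bins = bin_changes(profile, BIN_SCHEMES["sbm1_4bin"])
        out = tmp_path / "profile.csv"
        write_profile_csv(profile, bins, out)
        back = pd.read_csv(out)
        assert list(back.columns) == ["residue", "percent_change", "bin", "missing_reason"]
        assert len(back) == len(profile.table)
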