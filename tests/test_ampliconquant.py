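"""Indel quantification: demultiplexing, background subtraction, formulas."""

import numpy as np
import pandas as pd
import pytest

from guideeff import ampliconquant as aq
from guideeff.librarydesign import DEFAULT_SCAFFOLD, SurrogateSite
from guideeff import synthdata as sd
from conftest import random_seq

LINK = aq.LINKER_SIGNATURE


def _libs(rng, n):
    sites = {}
    libs = {}
    for i in range(n):
        s = random_seq(rng, 37)
        s = s[:31] + "GG" + s[33:]
        site = SurrogateSite(s[:10], s[10:30], s[30:33], s[33:])
        gid = f"g{i}"
        sites[gid] = site
        libs[gid] = aq.LibraryDef(gid, site.protospacer, DEFAULT_SCAFFOLD, site.seq37)
    return sites, libs


def _read(lib, window, prefix="AATTC", suffix="ACGG"):
    return f"{prefix}{lib.spacer}{lib.scaffold}{window}{LINK}{suffix}"


class TestDemux:
    def test_constructed_read_assigned_with_window(self, rng):
        _, libs = _libs(rng, 3)
        lib = libs["g0"]
        window = lib.seq37[:20] + lib.seq37[22:]  # 2-bp deletion
        res = aq.demux_and_extract([_read(lib, window)], libs)
        assert res.windows["g0"] == [window]
        assert res.counters["assigned"] == 1

    def test_read_without_linker_excluded(self, rng):
        _, libs = _libs(rng, 2)
        lib = libs["g0"]
        read = f"AATTC{lib.spacer}{lib.scaffold}{lib.seq37}ACGG"
        res = aq.demux_and_extract([read], libs)
        assert res.counters["no_linker"] == 1 and not res.windows["g0"]

    def test_ambiguous_read_dropped(self, rng):
        _, libs = _libs(rng, 2)
        a, b = libs["g0"], libs["g1"]
        read = _read(a, a.seq37) + b.spacer + b.scaffold + b.seq37 + LINK
        res = aq.demux_and_extract([read], libs)
        assert res.counters["ambiguous"] == 1

    def test_duplicate_library_keys_rejected(self, rng):
        _, libs = _libs(rng, 1)
        libs["dup"] = aq.LibraryDef("dup", libs["g0"].spacer, libs["g0"].scaffold, libs["g0"].seq37)
        with pytest.raises(ValueError):
            aq.demux_and_extract([], libs)

    def test_matches_brute_force_on_synthetic_pool(self, rng):
        _, libs = _libs(rng, 10)
        keys = {g: (l.spacer + l.scaffold).upper() for g, l in libs.items()}
        reads = []
        for _ in range(1000):
            gid = f"g{rng.integers(10)}"
            window = random_seq(rng, int(rng.integers(5, 50)))
            reads.append(_read(libs[gid], window, prefix=random_seq(rng, 8)))
        res = aq.demux_and_extract(reads, libs)
        # oracle: exhaustive containment scan
        want = {g: [] for g in libs}
        for read in reads:
            matching = [g for g, k in keys.items() if k in read]
            if len(matching) == 1 and LINK in read:
                g = matching[0]
                tail = read[read.find(keys[g]) + len(keys[g]):]
                want[g].append(tail[:tail.rfind(LINK)])
        assert res.windows == want


class TestBackgroundSubtraction:
    def test_control_variant_removed(self, rng):
        sites, _ = _libs(rng, 1)
        ref = sites["g0"].seq37
        variant = ref[:5] + ref[6:]
        out = aq.subtract_background({"g0": [ref, variant, variant]},
                                     {"g0": [ref, variant]}, {"g0": ref})
        assert out["g0"] == [ref]

    def test_reference_windows_survive_subtraction(self, rng):
        sites, _ = _libs(rng, 1)
        ref = sites["g0"].seq37
        out = aq.subtract_background({"g0": [ref] * 5}, {"g0": [ref] * 5}, {"g0": ref})
        assert out["g0"] == [ref] * 5

    def test_missing_control_library_is_noop(self, rng):
        sites, _ = _libs(rng, 1)
        ref = sites["g0"].seq37
        out = aq.subtract_background({"g0": [ref]}, {}, {"g0": ref})
        assert out["g0"] == [ref]

    def test_planted_background_recovers_truth_exactly(self, rng):
        spec = sd.GeneratorSpec(n_guides=8, seed=9, read_depth=400, background_rate=0.05)
        sites = sd.surrogate_sites(spec, n=8)
        sample_w, control_w, truth = sd.gen_windows(spec, sites)
        clean = aq.subtract_background(sample_w, control_w,
                                       {g: s.seq37 for g, s in sites.items()})
        table, _ = aq.quantify_pool(clean, min_reads=1)
        merged = table.merge(truth, on="guide_id")
        assert np.allclose(merged["efficiency"], merged["true_efficiency"])


class TestProfileAndEfficiency:
    def test_quarter_edited(self):
        prof, rec = aq.profile_and_efficiency(["A" * 37] * 3 + ["A" * 35], min_reads=1)
        assert rec["efficiency"] == 25.0
        assert prof.deletions[1] == 1  # 2-bp deletion

    def test_all_reference_length_is_zero(self):
        _, rec = aq.profile_and_efficiency(["A" * 37] * 10, min_reads=1)
        assert rec["efficiency"] == 0.0

    def test_low_support_flagged_excluded(self):
        _, rec = aq.profile_and_efficiency(["A" * 37] * 199)
        assert rec["excluded"]
        _, rec = aq.profile_and_efficiency(["A" * 37] * 200)
        assert not rec["excluded"]

    def test_empty_windows_error(self):
        with pytest.raises(ValueError):
            aq.profile_and_efficiency([])

    def test_count_conservation_on_random_lengths(self, rng):
        for _ in range(30):
            lengths = rng.integers(1, 80, size=500)
            prof = aq.profile_from_lengths(lengths)
            assert prof.total_reads == (prof.unedited_reads + prof.deletions.sum()
                                        + prof.insertions.sum() + prof.out_of_window)

    def test_out_of_window_lengths_count_as_edited(self):
        _, rec = aq.profile_and_efficiency(["A" * 37, "A" * 3], min_reads=1)
        assert rec["efficiency"] == 50.0
        prof = aq.profile_from_lengths(np.array([37, 3]))
        assert prof.out_of_window == 1 and prof.in_window_indel_reads == 0


class TestPoolFraction:
    def test_matches_planted_pool_fraction_exactly(self, rng):
        spec = sd.GeneratorSpec(n_guides=30, seed=4, read_depth=500, background_rate=0.0)
        sites = sd.surrogate_sites(spec, n=30)
        sample_w, _, truth = sd.gen_windows(spec, sites)
        _, profiles = aq.quantify_pool(sample_w, min_reads=1)
        got = aq.pool_indel_fraction(profiles)
        want = 100.0 * truth["n_edited"].sum() / (truth["depth"].sum())
        assert got == pytest.approx(want, abs=1e-12)


class TestInsertionSpectrum:
    def test_constructed_templated_insertion(self, rng):
        sites, _ = _libs(rng, 1)
        site = sites["g0"]
        ref = site.seq37
        n17 = ref[26]
        window = ref[:27] + n17 + ref[27:]
        table = aq.insertion_base_spectrum([window], site)
        assert table.loc[n17, n17] == 1

    def test_two_bp_insertion_rejected(self, rng):
        sites, _ = _libs(rng, 1)
        with pytest.raises(ValueError):
            aq.insertion_base_spectrum([sites["g0"].seq37 + "AA"], sites["g0"])

    def test_templating_rate_recovered(self, rng):
        spec = sd.GeneratorSpec(n_guides=12, seed=6, read_depth=2000,
                                background_rate=0.0, insertion_templating=0.8)
        sites = sd.surrogate_sites(spec, n=12)
        sample_w, _, truth = sd.gen_windows(spec, sites,
                                            efficiencies={g: 80.0 for g in sites})
        diag = off = 0
        for gid, site in sites.items():
            ins1 = [w for w in sample_w[gid] if len(w) == 38]
            table = aq.insertion_base_spectrum(ins1, site)
            n17 = truth.set_index("guide_id").loc[gid, "n17"]
            diag += table.loc[n17, n17]
            off += table.to_numpy().sum() - table.loc[n17, n17]
        assert diag + off > 4000
        assert diag / (diag + off) == pytest.approx(0.8, abs=0.03)


class TestMergeDays:
    def test_intersection_and_mean(self):
        a = pd.DataFrame({"guide_id": ["x", "y"], "efficiency": [60.0, 10.0]})
        b = pd.DataFrame({"guide_id": ["y", "z"], "efficiency": [40.0, 99.0]})
        merged, _ = aq.merge_days(a, b)
        assert merged["guide_id"].tolist() == ["y"]
        assert merged["efficiency"].iloc[0] == 25.0

    def test_empty_intersection_error(self):
        a = pd.DataFrame({"guide_id": ["x"], "efficiency": [1.0]})
        b = pd.DataFrame({"guide_id": ["y"], "efficiency": [2.0]})
        with pytest.raises(ValueError):
            aq.merge_days(a, b)

    def test_planted_day_correlation_recovered(self):
        df = sd.gen_guides(sd.GeneratorSpec(n_guides=2000, seed=8, day_correlation=0.9))
        a = df[["guide_id", "efficiency_day8"]].rename(columns={"efficiency_day8": "efficiency"})
        b = df[["guide_id", "efficiency_day10"]].rename(columns={"efficiency_day10": "efficiency"})
        merged, r = aq.merge_days(a, b)
        assert len(merged) == 2000
        assert r == pytest.approx(0.9, abs=0.05)
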