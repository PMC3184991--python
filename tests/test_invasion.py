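"""Home/invaded-range attribution and concentration accounting."""

from collections import Counter

import pytest

from haplopars.delimit import delimit_by_clustering
from haplopars.invasion import (
    RangeConfig,
    build_range_table,
    concentration,
    invasion_summary,
)
from haplopars.network import build_networks
from haplopars.sequence_io import collapse_haplotypes
from tests.conftest import make_table


def simple_assignment(table, species="SP"):
    """All haplotypes in one species."""
    import pandas as pd

    from haplopars.delimit import SpeciesAssignment

    frame = pd.DataFrame(
        {"code": table.codes, "species": species, "nearest_reference": species,
         "min_divergence": 0.0}
    ).set_index("code")
    return SpeciesAssignment(frame=frame, threshold=0.035)


HUB = "ACGTACGTACGTACGTACGT"


def leaf(i):
    return HUB[:i] + ("T" if HUB[i] != "T" else "A") + HUB[i + 1 :]


@pytest.fixture
def cfg():
    return RangeConfig(home={"SP": {"Israel", "Syria"}})


class TestRangeConfig:
    def test_classify(self, cfg):
        assert cfg.classify("SP", "Israel") == "home"
        assert cfg.classify("SP", "Japan") == "invaded"
        assert cfg.classify("SP", "unknown") == "unknown"

    def test_alias_normalization(self):
        c = RangeConfig()
        assert c.classify("MED", "Greece: Crete") == "home"
        assert c.classify("MEAM1", "Jordon") == "home"

    def test_unconfigured_species_errors(self, cfg):
        with pytest.raises(ValueError, match="home range"):
            cfg.classify("XX", "Japan")

    def test_yaml_roundtrip(self, tmp_path, cfg):
        p = tmp_path / "ranges.yaml"
        p.write_text("home:\n  SP: [Israel, Syria]\naliases: {}\n")
        loaded = RangeConfig.from_yaml(p)
        assert loaded.home["SP"] == {"Israel", "Syria"}


class TestRangeTable:
    def test_all_home_records(self, cfg):
        table = make_table(
            [HUB, leaf(0)], counts=[3, 2],
            countries=[Counter({"Israel": 3}), Counter({"Syria": 2})],
        )
        rt = build_range_table(table, simple_assignment(table), cfg, "SP")
        assert rt.records_invaded == 0 and rt.fraction_invaded == 0.0
        assert set(rt.detail["range_class"]) == {"home_only"}

    def test_split_counts_and_fractions(self, cfg):
        table = make_table(
            [HUB, leaf(0), leaf(5)], counts=[6, 2, 1],
            countries=[
                Counter({"Israel": 2, "Japan": 4}),
                Counter({"USA": 2}),
                Counter({"Syria": 1}),
            ],
        )
        rt = build_range_table(table, simple_assignment(table), cfg, "SP")
        assert rt.records_home == 3 and rt.records_invaded == 6
        assert rt.fraction_invaded == pytest.approx(0.667, abs=1e-3)
        classes = rt.detail["range_class"]
        assert classes["H001"] == "both"
        assert classes["H002"] == "invaded_only"
        assert classes["H003"] == "home_only"

    def test_class_counts_partition_haplotypes(self, cfg):
        table = make_table(
            [HUB, leaf(0), leaf(5)], counts=[4, 1, 1],
            countries=[
                Counter({"Israel": 2, "USA": 2}),
                Counter({"Japan": 1}),
                Counter({"unknown": 1}),
            ],
        )
        rt = build_range_table(table, simple_assignment(table), cfg, "SP")
        nets = build_networks(table, 5)
        s = invasion_summary(rt, nets, table, k=1)
        classified = (rt.detail["range_class"] != "unknown").sum()
        assert s.n_home_only + s.n_invaded_only + s.n_both == classified

    def test_singletons_aggregated_in_report(self, cfg):
        table = make_table(
            [HUB, leaf(0), leaf(5), leaf(10)], counts=[5, 1, 1, 1],
            countries=[
                Counter({"Israel": 5}), Counter({"USA": 1}),
                Counter({"Japan": 1}), Counter({"Syria": 1}),
            ],
        )
        rt = build_range_table(table, simple_assignment(table), cfg, "SP")
        rep = rt.report()
        assert rep.loc["singleton", "records_total"] == 3
        assert rep.loc["Total", "records_total"] == 8

    def test_totals_conserved(self, cfg):
        table = make_table(
            [HUB, leaf(0)], counts=[3, 2],
            countries=[Counter({"Israel": 1, "USA": 1, "unknown": 1}), Counter({"Japan": 2})],
        )
        rt = build_range_table(table, simple_assignment(table), cfg, "SP")
        assert rt.records_home + rt.records_invaded + rt.records_unknown == 5

    def test_absent_species_errors(self, cfg):
        table = make_table([HUB])
        with pytest.raises(ValueError, match="absent"):
            build_range_table(table, simple_assignment(table), cfg, "OTHER")


class TestConcentration:
    @pytest.fixture
    def rt(self, cfg):
        table = make_table(
            [HUB, leaf(0), leaf(5), leaf(10)], counts=[10, 4, 3, 1],
            countries=[
                Counter({"Japan": 8, "Israel": 2}),
                Counter({"USA": 4}),
                Counter({"France": 3}),
                Counter({"Israel": 1}),
            ],
        )
        return table, build_range_table(table, simple_assignment(table), cfg, "SP")

    def test_non_decreasing_and_reaches_one(self, rt):
        _, r = rt
        vals = [concentration(r, k)[0] for k in range(1, 6)]
        assert vals == sorted(vals)
        assert vals[2] == pytest.approx(1.0)  # 3 invaded-range haplotypes

    def test_top1_is_largest_share(self, rt):
        _, r = rt
        c1, top = concentration(r, 1)
        assert top == ["H001"]
        assert c1 == pytest.approx(8 / 15)

    def test_k_below_one_errors(self, rt):
        _, r = rt
        with pytest.raises(ValueError):
            concentration(r, 0)

    def test_hub_linkage(self, rt, cfg):
        table, r = rt
        nets = build_networks(table, 5)
        s = invasion_summary(r, nets, table, k=2)
        assert s.hub_linked["H001"] is True   # the hub itself
        assert s.hub_linked["H002"] is True   # one step off the hub

    def test_single_country_dataset(self, cfg):
        table = make_table(
            [HUB, leaf(0)], counts=[3, 1],
            countries=[Counter({"Israel": 3}), Counter({"Israel": 1})],
        )
        rt = build_range_table(table, simple_assignment(table), cfg, "SP")
        nets = build_networks(table, 5)
        s = invasion_summary(rt, nets, table, k=1)
        assert s.n_both == 0 and s.concentration == 0.0


class TestGeneratorGroundTruth:
    def test_planted_range_counts_recovered(self, sim_default):
        table = collapse_haplotypes(sim_default.records)
        # assignment from truth: map haplotype sequence -> planted species
        truth = dict(zip(sim_default.truth["seq"], sim_default.truth["species"]))
        import pandas as pd

        from haplopars.delimit import SpeciesAssignment

        frame = pd.DataFrame(
            {
                "code": table.codes,
                "species": [truth[h.seq] for h in table],
                "nearest_reference": "",
                "min_divergence": 0.0,
            }
        ).set_index("code")
        assignment = SpeciesAssignment(frame=frame, threshold=0.035)
        cfg = RangeConfig(
            home={
                sp: {f"{sp}_Home_{i + 1}" for i in range(3)}
                for sp in sim_default.species_names
            }
        )
        for sp in sim_default.species_names:
            rt = build_range_table(table, assignment, cfg, sp)
            expect_home = sum(
                1 for r in sim_default.records
                if r.species_ref == sp and r.range_class == "home"
            )
            expect_inv = sum(
                1 for r in sim_default.records
                if r.species_ref == sp and r.range_class == "invaded"
            )
            assert rt.records_home == expect_home
            assert rt.records_invaded == expect_inv
            assert rt.records_unknown == 0
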