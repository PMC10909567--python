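import numpy as np
import pytest
from scipy.stats import chisquare

from coralipm import data_io, synthetic
from coralipm.data_io import (ColonyObservation, StrategyCatalog,
                              SurveyValidationError, assign_strategies,
                              filter_assemblage, read_survey, write_survey)


def _obs(cid="C1", strategy="weedy", region="AT", survived=True, **kw):
    base = dict(colony_id=cid, region=region, site="S1", taxon="Genus",
                strategy=strategy, year_t=2016, size_t=10.0,
                survived=survived, size_t1=12.0 if survived else None)
    base.update(kw)
    return ColonyObservation(**base)


class TestSurveyIO:
    def test_small_table_round_trip(self, tmp_path):
        obs = [
            _obs("C1"),
            _obs("C2", survived=False),
            _obs("C3", fragmented=True, size_t1=4.0, remnant_sizes=(4.0, 2.0)),
        ]
        path = tmp_path / "survey.csv"
        write_survey(path, obs)
        assert read_survey(path) == obs

    def test_dead_colony_with_final_size_rejected_by_row(self, tmp_path):
        path = tmp_path / "survey.csv"
        write_survey(path, [_obs("C1"), _obs("C2")])
        lines = path.read_text().splitlines()
        bad = lines[2].split(",")
        bad[7], bad[8] = "false", "12.0"   # survived=false but size_t1 set
        lines[2] = ",".join(bad)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SurveyValidationError) as err:
            read_survey(path)
        assert err.value.rows == [3]

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "survey.csv"
        path.write_text("colony_id,region\nC1,AT\n")
        with pytest.raises(data_io.SurveyFormatError):
            read_survey(path)

    def test_large_synthetic_round_trip(self, tmp_path):
        params = synthetic.preset_params("JS", "weedy", n_colonies=250,
                                         n_years=3, seed=5)
        obs, recruits = synthetic.simulate_survey(params)
        fec = synthetic.simulate_fecundity(params, 50)
        spath, rpath, fpath = (tmp_path / n for n in
                               ("s.csv", "r.csv", "f.csv"))
        write_survey(spath, obs)
        data_io.write_recruits(rpath, recruits)
        data_io.write_fecundity(fpath, fec)
        assert read_survey(spath) == obs
        assert data_io.read_recruits(rpath) == recruits
        assert data_io.read_fecundity(fpath) == fec

    def test_catalog_round_trip(self, tmp_path):
        cat = StrategyCatalog({"Acropora": "competitive",
                               "Favia": {"stress_tolerant": 2, "weedy": 1}})
        path = tmp_path / "catalog.csv"
        data_io.write_catalog(path, cat)
        assert data_io.read_catalog(path).mapping == cat.mapping


class TestAssignStrategies:
    def test_single_strategy_genus_is_deterministic(self):
        obs = [_obs(f"C{i}", strategy="mixed") for i in range(20)]
        cat = StrategyCatalog({"Genus": "weedy"})
        out = assign_strategies(obs, cat, seed=0)
        assert all(o.strategy == "weedy" for o in out)

    def test_multi_strategy_proportions(self):
        obs = [_obs(f"C{i}", strategy="mixed") for i in range(4000)]
        cat = StrategyCatalog({"Genus": {"competitive": 3, "weedy": 1}})
        out = assign_strategies(obs, cat, seed=42)
        frac = np.mean([o.strategy == "competitive" for o in out])
        assert abs(frac - 0.75) <= 0.02

    def test_same_seed_reproducible_and_per_colony(self):
        # two rows per colony: both rows must get the same strategy
        obs = [_obs(f"C{i}", strategy="mixed", year_t=y)
               for i in range(300) for y in (2016, 2017)]
        cat = StrategyCatalog({"Genus": {"competitive": 1, "weedy": 1}})
        a = assign_strategies(obs, cat, seed=7)
        b = assign_strategies(obs, cat, seed=7)
        assert [o.strategy for o in a] == [o.strategy for o in b]
        per_colony = {}
        for o in a:
            per_colony.setdefault(o.colony_id, set()).add(o.strategy)
        assert all(len(s) == 1 for s in per_colony.values())

    def test_unknown_taxon_named_in_error(self):
        with pytest.raises(KeyError, match="Unknown"):
            assign_strategies([_obs(taxon="Unknown")],
                              StrategyCatalog({"Genus": "weedy"}), seed=0)

    def test_marginal_frequencies_match_catalog(self):
        # chi-square goodness of fit non-significant at alpha=0.01
        cat = StrategyCatalog({"Genus": {"competitive": 5,
                                         "stress_tolerant": 3, "weedy": 2}})
        obs = [_obs(f"C{i}", strategy="mixed") for i in range(10_000)]
        n_reject = 0
        for seed in range(20):
            out = assign_strategies(obs, cat, seed=seed)
            counts = [sum(o.strategy == s for o in out)
                      for s in ("competitive", "stress_tolerant", "weedy")]
            _, p = chisquare(counts, f_exp=[5000, 3000, 2000])
            n_reject += p < 0.01
        assert n_reject <= 2  # ~0.2 expected rejections under the null


class TestFilterAssemblage:
    def test_generalists_dropped_by_default(self):
        obs = [_obs(f"C{i}", strategy="generalist") for i in range(17)] + \
              [_obs(f"D{i}", strategy="weedy") for i in range(5)]
        out = filter_assemblage(obs)
        assert len(out) == 5
        assert all(o.strategy != "generalist" for o in out)

    def test_absent_region_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no records"):
            out = filter_assemblage([_obs()], region="ZZ")
        assert out == []

    def test_counts_match_linear_scan(self):
        rng = np.random.default_rng(3)
        strategies = ("competitive", "weedy", "generalist")
        regions = ("AS", "AT", "JS", "JT")
        obs = [_obs(f"C{i}", strategy=strategies[rng.integers(3)],
                    region=regions[rng.integers(4)]) for i in range(500)]
        for strat in ("competitive", "weedy"):
            for region in regions:
                expected = sum(1 for o in obs
                               if o.strategy == strat and o.region == region)
                got = filter_assemblage(obs, strat, region) if expected else []
                assert len(got) == expected
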