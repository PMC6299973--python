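"""Synthetic-data generator: limits, calibration, determinism."""

import hashlib
import math
from dataclasses import replace

import pytest

from metanno.benchmark import precision_recall
from metanno.model import filter_complete
from metanno.simulate import (
    SimulationConfig,
    ToolProfile,
    TransporterConfig,
    simulate_annotations,
    simulate_study,
    simulate_transporters,
    write_truth,
)


def small_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_genes=300,
        ec_universe_size=400,
        frac_metabolic=0.5,
        multi_ec_prob=0.1,
        difficulty_sd=0.0,
        tools=(
            ToolProfile("rast", 0.8, 0.05),
            ToolProfile("kegg", 0.7, 0.05),
        ),
        transporters=TransporterConfig(n_transporter_genes=100),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestLimits:
    def test_noiseless_limit_reproduces_gold(self):
        config = small_config(
            tools=(ToolProfile("rast", 1.0, 0.0), ToolProfile("kegg", 1.0, 0.0))
        )
        truth = simulate_annotations(config)
        for aset in truth.tool_sets.values():
            assert aset.pairs == truth.gold.pairs

    def test_zero_sensitivity_empty_sets(self):
        config = small_config(tools=(ToolProfile("rast", 0.0, 0.0), ToolProfile("kegg", 0.0, 0.0)))
        truth = simulate_annotations(config)
        for aset in truth.tool_sets.values():
            assert not aset.pairs

    def test_binomial_recall_calibration(self):
        config = small_config(
            seed=7,
            n_genes=1000,
            frac_metabolic=1.0,
            multi_ec_prob=0.0,
            tools=(ToolProfile("rast", 0.8, 0.0),),
        )
        truth = simulate_annotations(config)
        n = len(truth.gold.pairs)
        assert n == 1000
        recall = len(truth.tool_sets["rast"].pairs & truth.gold.pairs) / n
        assert abs(recall - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / n)

    def test_provenance_labels_every_record(self):
        truth = simulate_annotations(small_config(seed=3))
        labeled = {
            (tool, gene, ec)
            for tool, gene, ec, label in truth.provenance
            if label in ("TP", "FP", "PARTIAL")
        }
        for tool, aset in truth.tool_sets.items():
            for gene, ec in aset.pairs:
                assert (tool, gene, str(ec)) in labeled


class TestValidation:
    def test_bad_fraction_rejected_before_output(self):
        with pytest.raises(ValueError):
            simulate_annotations(small_config(frac_metabolic=1.5))

    def test_rank_distribution_must_sum_to_one(self):
        tc = TransporterConfig(
            coverage={"rast": 0.5},
            rank_distribution={"rast": {1: 0.5, 5: 0.4}},
        )
        with pytest.raises(ValueError, match="sums to"):
            tc.validate()

    def test_duplicate_tool_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            small_config(tools=(ToolProfile("x", 0.5, 0.0), ToolProfile("x", 0.5, 0.0))).validate()


class TestTransporterSim:
    def test_degenerate_rank_distribution(self):
        tc = TransporterConfig(
            n_transporter_genes=50,
            coverage={"rast": 1.0},
            rank_distribution={"rast": {1: 1.0}},
        )
        anns, _ = simulate_transporters(small_config(transporters=tc))
        assert anns["rast"] and all(a.rank == 1 for a in anns["rast"])

    def test_full_coverage_full_overlap(self):
        tools = {"transportdb": 1.0, "rast": 1.0, "kegg": 1.0}
        tc = TransporterConfig(
            n_transporter_genes=40,
            coverage=tools,
            rank_distribution={t: {1: 1.0} for t in tools},
        )
        anns, _ = simulate_transporters(small_config(transporters=tc))
        from metanno.transporters import three_tool_overlap

        flat = [a for per_tool in anns.values() for a in per_tool]
        assert three_tool_overlap(flat).all_tools_genes == 40

    def test_rank_mass_binomial_calibration(self):
        dist = {1: 0.35, 2: 0.24, 3: 0.20, 4: 0.12, 5: 0.09}
        tc = TransporterConfig(
            n_transporter_genes=2000,
            coverage={"transportdb": 1.0},
            rank_distribution={"transportdb": dist},
        )
        anns, _ = simulate_transporters(small_config(seed=11, transporters=tc))
        n = len(anns["transportdb"])
        observed = sum(1 for a in anns["transportdb"] if a.rank <= 2) / n
        p = 0.59
        assert abs(observed - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_simulated_substrates_are_in_vocabulary(self):
        truth = simulate_annotations(small_config(seed=5))
        for per_tool in truth.transporter_annotations.values():
            for a in per_tool:
                if a.substrate is not None:
                    assert a.substrate in truth.vocabulary.entries
                    assert truth.vocabulary.entries[a.substrate] == a.rank


class TestDeterminism:
    @staticmethod
    def _digest(tmpdir):
        h = hashlib.sha256()
        for p in sorted(tmpdir.iterdir()):
            h.update(p.name.encode())
            h.update(p.read_bytes())
        return h.hexdigest()

    def test_identical_seed_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            write_truth(simulate_annotations(small_config(seed=42)), tmp_path / sub)
        assert self._digest(tmp_path / "a") == self._digest(tmp_path / "b")

    def test_different_seed_different_output(self, tmp_path):
        write_truth(simulate_annotations(small_config(seed=1)), tmp_path / "a")
        write_truth(simulate_annotations(small_config(seed=2)), tmp_path / "b")
        assert self._digest(tmp_path / "a") != self._digest(tmp_path / "b")

    def test_adding_a_tool_does_not_perturb_others(self):
        base = small_config(seed=9)
        extended = replace(base, tools=base.tools + (ToolProfile("eficaz", 0.5, 0.01),))
        t1, t2 = simulate_annotations(base), simulate_annotations(extended)
        for tool in ("rast", "kegg"):
            assert t1.tool_sets[tool].pairs == t2.tool_sets[tool].pairs


class TestParameterRecovery:
    def test_recall_and_precision_recover_configured_rates(self):
        sens, rate, n_pairs = 0.8, 0.1, 1000
        config = small_config(
            n_genes=n_pairs,
            frac_metabolic=1.0,
            multi_ec_prob=0.0,
            ec_universe_size=1500,
            tools=(ToolProfile("rast", sens, rate),),
        )
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = simulate_annotations(replace(config, seed=seed))
            pr = precision_recall(truth.tool_sets["rast"].pairs, truth.gold.pairs)
            recall_sd = math.sqrt(sens * (1 - sens) / n_pairs)
            t_mean, f_mean = sens * n_pairs, rate * n_pairs
            p_implied = t_mean / (t_mean + f_mean)
            var_p = (
                f_mean**2 * (n_pairs * sens * (1 - sens)) + t_mean**2 * f_mean
            ) / (t_mean + f_mean) ** 4
            ok_recall = abs(pr.recall - sens) <= 3 * recall_sd
            ok_precision = abs(pr.precision - p_implied) <= 3 * math.sqrt(var_p)
            hits += ok_recall and ok_precision
        assert hits >= n_seeds - 1


class TestStudy:
    def test_difficulty_range_orders_ge3_fraction(self):
        from metanno.consensus import support_distribution

        config = small_config(seed=13, n_genes=500, tools=(
            ToolProfile("rast", 0.75, 0.04),
            ToolProfile("kegg", 0.75, 0.04),
            ToolProfile("eficaz", 0.6, 0.02),
            ToolProfile("brenda", 0.4, 0.06),
        ))
        study = simulate_study(config, n_genomes=6, difficulty_range=(0.0, 3.0))
        fractions = [
            support_distribution({t: filter_complete(s) for t, s in truth.tool_sets.items()}, "ec").ge3_fraction
            for truth in study.values()
        ]
        # easiest third should out-support the hardest third
        assert sum(fractions[:2]) / 2 > sum(fractions[-2:]) / 2

    def test_study_genomes_distinct_and_deterministic(self):
        config = small_config(seed=21)
        a = simulate_study(config, 3)
        b = simulate_study(config, 3)
        assert list(a) == ["SIM01", "SIM02", "SIM03"]
        for g in a:
            assert a[g].gold.pairs == b[g].gold.pairs
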