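"""Shared fixtures: a tiny toy genome and one session-scoped run of the
default synthetic scenario (generate, simulate, call, classify, ATAC)."""

from dataclasses import dataclass

import numpy as np
import pytest

from pioneerbind import synth, events, accessibility
from pioneerbind.core import Genome


@pytest.fixture
def toy_genome():
    return Genome({"c1": "ACGT" * 250, "c2": "A" * 500 + "C" * 500})


def _small_config():
    cfg = synth.default_config(100)
    cfg.chrom_lengths = {"chr1": 700_000, "chr2": 700_000}
    cfg.chip_depth = 120_000
    cfg.atac_depth = 500_000
    cfg.n_extra_domains = 30
    return cfg


@pytest.fixture
def small_config():
    """A fast two-chromosome scenario (100 sites per category)."""
    return _small_config()


@dataclass
class Scenario:
    config: synth.LandscapeConfig
    tf_specs: list
    genome: Genome
    truth: synth.SyntheticTruth
    chip: dict
    input_lib: object
    atac_prior: list
    atac_post_b: list
    called: dict
    categorized: events.CategorizedSites
    domains: object


def _build_scenario(cfg, test_cfg, seed=1):
    specs = synth.default_tf_specs()
    genome = synth.generate_genome(cfg, seed)
    genome, truth = synth.plant_landscape(genome, cfg, specs, seed + 1)
    chip = {s.name: synth.simulate_chip(truth, s, seed=seed + 10 + i)
            for i, s in enumerate(specs)}
    input_lib = synth.simulate_input(truth, seed=seed + 20)[0]
    atac_prior = synth.simulate_atac(truth, mode="prior", seed=seed + 30)
    spec_b = next(s for s in specs if s.name == "B")
    atac_post_b = synth.simulate_atac(truth, [spec_b], mode="post",
                                      seed=seed + 31)
    called = {tf: events.call_events(libs, input_lib, genome, test_cfg)
              for tf, libs in chip.items()}
    top = {tf: events.rank_top(ev, test_cfg.top_n) for tf, ev in called.items()}
    cat = events.classify_multiway(top, chip, input_lib, test_cfg)
    domains = accessibility.call_domains(atac_prior, genome)
    return Scenario(cfg, specs, genome, truth, chip, input_lib, atac_prior,
                    atac_post_b, called, cat, domains)


@pytest.fixture(scope="session")
def default_scenario():
    """The default three-TF scenario: 5 truth categories x 800 sites plus
    800 unbound controls on a 10 Mb genome, seed fixed."""
    return _build_scenario(synth.default_config(), events.TestConfig(), seed=1)


@pytest.fixture(scope="session")
def small_scenario():
    """Session-scoped small scenario; tests must not mutate its tag data."""
    return _build_scenario(_small_config(), events.TestConfig(min_category=50),
                           seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
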