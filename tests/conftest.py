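import warnings

import numpy as np
import pytest

from slrkit import bsa, simdata


@pytest.fixture(scope="session")
def default_config():
    return simdata.ScenarioConfig(seed=0)


@pytest.fixture(scope="session")
def genome(default_config):
    """Reference sequences + truth for the default scenario (shared)."""
    return simdata.simulate_genome(default_config)


@pytest.fixture(scope="session")
def pool_calls(default_config, genome):
    refs, truth = genome
    return simdata.simulate_pools(refs, truth, default_config)


@pytest.fixture(scope="session")
def chrom_lengths(default_config, genome):
    refs, _ = genome
    return {c: len(s)
            for c, s in simdata.male_reference(refs, default_config).items()}


@pytest.fixture(autouse=True)
def _quiet_clip_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="methylation level clipped")
        yield


def scan_toy(calls, chrom_lengths, seed, window=10_000, step=10_000,
             n_perm=1000):
    """Toy-scale scan: tiling windows, genome-wide envelope."""
    sites = bsa.site_snp_index(calls)
    windows = bsa.permutation_envelope(
        sites, window, step, n_perm, 0.95, seed=seed,
        chrom_lengths=chrom_lengths, genome_wide=True)
    return bsa.call_candidates(windows, step=step)
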