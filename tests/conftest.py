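"""Shared fixtures: small synthetic datasets and scenario configs."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from lncnet import expression, network, syndata

# silence expected analysis warnings (zero-variance drops, fallbacks)
warnings.filterwarnings("ignore", module="lncnet")


def small_config(seed: int = 0, **overrides) -> syndata.SyntheticConfig:
    """A fast config for unit tests: 80 transcripts, 6+6 samples."""
    params = dict(
        n_samples_treated=6,
        n_samples_control=6,
        n_mrna=60,
        n_lncrna=20,
        module_sizes=(16, 12, 10),
        n_conserved_pairs=4,
        n_decoys=10,
        seed=seed,
    )
    params.update(overrides)
    return syndata.SyntheticConfig(**params)


def recovery_config(seed: int) -> syndata.SyntheticConfig:
    """The conserved-pair recovery scenario: pinned structural parameters
    (trait_effect 2, within-module correlation 0.8, within-pair 0.95) at
    a sample size where TOM estimation noise is small enough for the
    planted hub pairs to dominate the top-quantile filter."""
    return syndata.SyntheticConfig(
        seed=seed,
        n_samples_treated=100,
        n_samples_control=24,
        n_conserved_pairs=8,
        nb_dispersion=0.05,
        mean_log_expr_mrna=6.5,
        mean_log_expr_lnc=5.0,
        trait_effect=2.0,
        within_module_cor=0.8,
        within_pair_cor=0.95,
    )


def normalized_expression(counts: pd.DataFrame) -> pd.DataFrame:
    return expression.normalize_log(counts, expression.size_factors(counts))


def run_group_networks(counts, samples, powers=range(1, 7), **kw):
    """Per-group network analysis on a syndata dataset."""
    results = {}
    for g, cm in counts.items():
        X = normalized_expression(cm)
        results[g] = network.analyze_group(
            X, samples[g]["trait"].to_numpy(), group=g, powers=powers, **kw
        )
    return results


@pytest.fixture(scope="session")
def small_dataset() -> syndata.Dataset:
    return syndata.generate_dataset(small_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
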