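"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genewas.diffexpr import ExpressionStudy
from genewas.simulate import SimConfig, sim_gwas_sumstats, sim_reference_panel
from genewas.sumstats import VariantSummary


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_genes=60, causal_gene_fraction=0.05, signal_mean_shift=4.0)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return sim_reference_panel(small_cfg)


@pytest.fixture(scope="session")
def small_sumstats(small_cfg, small_panel):
    panel, genes = small_panel
    return sim_gwas_sumstats(panel, genes, small_cfg)


def make_variant(**kw) -> VariantSummary:
    defaults = dict(
        chrom="1",
        pos=100,
        rsid="rs1",
        effect_allele="A",
        other_allele="G",
        odds_ratio=1.1,
        se=0.05,
        pvalue=0.5,
        info=0.95,
    )
    defaults.update(kw)
    return VariantSummary(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant


def random_correlation(m: int, rng: np.random.Generator, n: int = 80) -> np.ndarray:
    """Sample correlation matrix of random Gaussian data (full rank a.s.)."""
    X = rng.standard_normal((max(n, m + 5), m))
    return np.corrcoef(X, rowvar=False)


@pytest.fixture
def tiny_expression_study() -> ExpressionStudy:
    rng = np.random.default_rng(5)
    n = 24
    counts = pd.DataFrame(
        rng.poisson(30.0, size=(4, n)),
        index=[f"G{i}" for i in range(4)],
        columns=[f"S{i}" for i in range(n)],
    )
    samples = pd.DataFrame(
        {
            "diagnosis": ["case"] * (n // 2) + ["control"] * (n // 2),
            "age_at_death": rng.normal(50, 10, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "race": np.where(rng.random(n) < 0.7, "white", "non-white"),
            "pmi": rng.normal(15, 4, n),
        },
        index=counts.columns,
    )
    return ExpressionStudy(counts=counts, samples=samples)
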