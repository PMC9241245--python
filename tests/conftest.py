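import numpy as np
import pandas as pd
import pytest

from prs_transcal import DosageMatrix, SimulationConfig, WeightTable


@pytest.fixture(scope="session")
def small_config():
    """A compact two-population study used across ancestry tests."""
    return SimulationConfig(
        n_populations=2,
        fst=(0.1, 0.1),
        n_variants=600,
        n_causal=120,
        prevalence=(0.10, 0.125),
        n_samples=(400, 400),
        n_reference=(250, 250),
        gwas_n=(100_000, 100_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def two_pop_panel(small_config):
    from prs_transcal import simulate_reference_panel

    return simulate_reference_panel(small_config)


@pytest.fixture(scope="session")
def two_pop_pca(two_pop_panel):
    from prs_transcal import fit_pca

    panel, labels = two_pop_panel
    return fit_pca(panel, k_pc=6, ref_labels=labels)


def make_dosage_matrix(dosages, chrom="1", pos=None, a1=None, a2=None,
                       sample_ids=None):
    """Hand-build a DosageMatrix for toy fixtures."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pos = pos if pos is not None else np.arange(1, m + 1) * 100
    a1 = a1 if a1 is not None else ["A"] * m
    a2 = a2 if a2 is not None else ["G"] * m
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom,
        "pos": pos,
        "a1": a1,
        "a2": a2,
    })
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    return DosageMatrix(dosages, variants, np.asarray(ids))


def make_weight_table(weights, chrom="1", pos=None, effect=None, other=None):
    weights = np.asarray(weights, dtype=float)
    m = len(weights)
    pos = pos if pos is not None else np.arange(1, m + 1) * 100
    effect = effect if effect is not None else ["A"] * m
    other = other if other is not None else ["G"] * m
    return WeightTable(pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom,
        "pos": pos,
        "effect_allele": effect,
        "other_allele": other,
        "weight": weights,
    }))
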