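"""Shared fixtures: small deterministic count matrices built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from permdeg import CountMatrix, SimConfig, simulate_counts


def tmm_fixture_inflated() -> CountMatrix:
    """200 genes x 4 samples, no true effects, 10 genes 8x inflated in the
    last sample — a composition shift TMM must absorb."""
    cm, _ = simulate_counts(
        SimConfig(n_genes=200, n_per_group=(2, 2), de_fraction=0.0, seed=1)
    )
    counts = cm.counts.copy()
    counts[:10, 3] *= 8
    return CountMatrix(cm.gene_ids, cm.sample_ids, counts, cm.groups, cm.control_label)


def tmm_fixture(seed: int, composition_bias: float | None = None) -> CountMatrix:
    """500 genes x 6 samples of exchangeable NB counts, optional bias."""
    cm, _ = simulate_counts(
        SimConfig(
            n_genes=500,
            n_per_group=(3, 3),
            de_fraction=0.0,
            seed=seed,
            composition_bias=composition_bias,
        )
    )
    return cm


@pytest.fixture
def small_matrix() -> CountMatrix:
    """A tiny handwritten 4-gene x 4-sample matrix with a two-group design."""
    return CountMatrix(
        gene_ids=["G1", "G2", "G3", "G4"],
        sample_ids=["C1", "C2", "T1", "T2"],
        counts=np.array(
            [
                [10, 12, 11, 9],
                [100, 90, 110, 95],
                [0, 0, 0, 0],
                [5, 7, 50, 60],
            ]
        ),
        groups={"C1": "CTL", "C2": "CTL", "T1": "SPD", "T2": "SPD"},
        control_label="CTL",
    )


@pytest.fixture
def null_run():
    """A pipeline run on a null (no-effect) simulation, shared across tests."""
    from permdeg import run_from_matrix

    cm, truth = simulate_counts(SimConfig(n_genes=600, seed=7, de_fraction=0.0))
    table, summary, norm = run_from_matrix(cm)
    return cm, truth, table, summary, norm
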