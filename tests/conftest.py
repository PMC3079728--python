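"""Shared fixtures: synthetic datasets at two scales.

``flagship`` is the full study-condition fixture (1000 genes, amplitude 2.0,
noise 0.5, WT + DKO); ``mini`` is a 120-gene dataset for fast unit tests.
Both are generated once per session from fixed seeds.
"""

from __future__ import annotations

import pandas as pd
import pytest

from intragene_marks import (
    build_coverage_table,
    classify_marked_genes,
    flagship_config,
    label_gene_class,
    simulate_dataset,
)

FLAGSHIP_SEED = 11
MINI_SEED = 7


@pytest.fixture(scope="session")
def flagship():
    return simulate_dataset(flagship_config(seed=FLAGSHIP_SEED))


@pytest.fixture(scope="session")
def mini():
    return simulate_dataset(flagship_config(seed=MINI_SEED, n_genes=120))


def marked_frame(dataset, condition="WT", params=None):
    """Genes x marks boolean classification frame for one condition."""
    genes = label_gene_class(dataset.genes)
    tracks = list(dataset.tracks[condition].values())
    table = build_coverage_table(genes, tracks, params, genome=dataset.genome)
    marked = pd.DataFrame(
        {
            m: classify_marked_genes(table, m, params, condition)
            for m in dataset.config.marks
        }
    )
    return table, marked


def recovered_mark_sets(dataset, marked: pd.DataFrame) -> pd.Series:
    """Per-gene frozenset of marks called present (NA treated as absent)."""
    filled = marked.fillna(False).astype(bool)
    return pd.Series(
        [frozenset(filled.columns[row]) for row in filled.to_numpy()],
        index=filled.index,
    )


@pytest.fixture(scope="session")
def flagship_classification(flagship):
    table, marked = marked_frame(flagship)
    return table, marked, recovered_mark_sets(flagship, marked)
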