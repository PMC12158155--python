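import numpy as np
import pytest
import scipy.sparse as sp

from orthomapper import (
    ConversionPolicy,
    ExpressionMatrix,
    HomologyType,
    OrthologPair,
    OrthologTable,
    classify_cardinality,
)

ALL_POLICIES = [
    ConversionPolicy(many_to_one=m, one_to_many=o, unmapped=u)
    for m in ("sum", "max_total", "drop_group")
    for o in ("expand", "drop")
    for u in ("drop", "retain_tagged")
]


def make_matrix(feature_ids, counts, obs_ids=None, **kwargs):
    counts = np.asarray(counts)
    if obs_ids is None:
        obs_ids = [f"c{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(list(feature_ids), list(obs_ids), sp.csr_matrix(counts), **kwargs)


def make_table(mapped_pairs, unmapped_sources=()):
    """Build and classify a table from (source, target) tuples."""
    pairs = [
        OrthologPair(s, t, HomologyType.ONE2ONE) for s, t in mapped_pairs
    ] + [OrthologPair(s, None, HomologyType.UNMAPPED) for s in unmapped_sources]
    return classify_cardinality(OrthologTable(tuple(pairs)))


def random_instance(rng, max_genes=50, max_obs=20):
    """Random integer matrix plus a random table mixing all cardinalities."""
    n_genes = int(rng.integers(5, max_genes + 1))
    n_obs = int(rng.integers(2, max_obs + 1))
    counts = rng.integers(0, 30, size=(n_genes, n_obs)).astype(np.int64)
    counts *= rng.random((n_genes, n_obs)) < 0.6
    feature_ids = [f"Gene{i:03d}" for i in range(n_genes)]

    target_pool = [f"HUM{i:03d}" for i in range(max(3, n_genes // 2))]
    mapped, unmapped = [], []
    for feat in feature_ids:
        r = rng.random()
        if r < 0.15:
            continue  # absent from the table entirely
        if r < 0.30:
            unmapped.append(feat)
            continue
        fanout = int(rng.integers(1, 4))
        targets = rng.choice(len(target_pool), size=min(fanout, len(target_pool)),
                             replace=False)
        mapped.extend((feat, target_pool[t]) for t in targets)
    if not mapped:  # force at least one mapped pair
        mapped.append((feature_ids[0], target_pool[0]))
    table = make_table(mapped, unmapped)
    X = make_matrix(feature_ids, counts)
    return X, table


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
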