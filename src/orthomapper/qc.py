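"""Conversion quality metrics and clustering-concordance diagnostics.

Conversion efficiency is quantified at two resolutions: *pseudobulk*
(total counts surviving conversion, as a percent of the input total) and
*per observation* (the same ratio per cell, nucleus or spatial pixel).
Gene-level companions are the mapping rate (fraction of input features with
at least one ortholog target) and per-biotype retention (how well each gene
class — protein_coding, lncRNA, … — survives the mapping).

The effect of conversion on downstream structure is measured by clustering
the matrix before and after conversion with an identical shared-nearest-
neighbor (SNN) pipeline and fixed seed, then comparing the two partitions
with the Rand index and its chance-adjusted variant. Both are always
reported: the raw index is the classic pair-counting agreement, the adjusted
index corrects it under the permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, rand_score

from ._errors import ConversionWarning, ValidationError
from .expression_io import ExpressionMatrix
from .ortholog_map import OrthologTable

if TYPE_CHECKING:  # pragma: no cover
    from .converter import ConversionPlan, ConversionPolicy, ConversionResult


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class ConversionReport:
    """All conversion QC metrics for one run.

    Percentages are stored at full precision; TSV output rounds to two
    decimals. ``per_obs_efficiency`` holds NaN for observations with zero
    source counts (undefined, not 0 or 100).
    """

    n_source_features: int
    n_mapped_features: int
    n_output_features: int
    gene_mapping_rate: float
    pseudobulk_count_efficiency: float
    per_obs_efficiency: np.ndarray
    obs_ids: list[str]
    biotype_retention: pd.DataFrame
    policy_echo: dict
    is_integer_input: bool
    warnings: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.gene_mapping_rate <= 100.0:
            raise ValidationError("gene_mapping_rate outside [0, 100]")
        if self.pseudobulk_count_efficiency < 0.0:
            raise ValidationError("pseudobulk efficiency negative")
        if (
            self.pseudobulk_count_efficiency > 100.0 + 1e-9
            and self.policy_echo.get("one_to_many") != "expand"
        ):
            raise ValidationError(
                "pseudobulk efficiency above 100% without one_to_many=expand"
            )
        pct = self.biotype_retention["percent"]
        if len(pct) and (pct.min() < 0 or pct.max() > 100 + 1e-9):
            raise ValidationError("biotype retention percent outside [0, 100]")

    def rows(self) -> list[tuple[str, str]]:
        """(metric, value) rows for the two-column TSV report."""
        defined = self.per_obs_efficiency[~np.isnan(self.per_obs_efficiency)]
        rows = [
            ("n_source_features", str(self.n_source_features)),
            ("n_mapped_features", str(self.n_mapped_features)),
            ("n_output_features", str(self.n_output_features)),
            ("gene_mapping_rate_percent", f"{self.gene_mapping_rate:.2f}"),
            ("pseudobulk_count_efficiency_percent",
             f"{self.pseudobulk_count_efficiency:.2f}"),
            ("per_obs_efficiency_mean_percent",
             f"{defined.mean():.2f}" if defined.size else ""),
            ("n_obs_undefined_efficiency",
             str(int(np.isnan(self.per_obs_efficiency).sum()))),
            ("integer_input", str(self.is_integer_input)),
        ]
        for k, v in sorted(self.policy_echo.items()):
            rows.append((f"policy.{k}", str(v)))
        for rec in self.biotype_retention.itertuples(index=False):
            rows.append(
                (f"biotype_retention.{rec.biotype}",
                 f"{rec.n_retained}/{rec.n_in} ({rec.percent:.2f})")
            )
        for k, v in sorted(self.extras.items()):
            rows.append((k, f"{v:.2f}" if isinstance(v, float) else str(v)))
        for i, w in enumerate(self.warnings):
            rows.append((f"warning.{i}", w))
        return rows


# ---------------------------------------------------------------------------
# efficiency metrics
# ---------------------------------------------------------------------------

def _check_obs_match(X: ExpressionMatrix, Y: ExpressionMatrix) -> None:
    if X.obs_ids != Y.obs_ids:
        only_x = sorted(set(X.obs_ids) - set(Y.obs_ids))[:5]
        only_y = sorted(set(Y.obs_ids) - set(X.obs_ids))[:5]
        raise ValidationError(
            "observation ids differ between matrices "
            f"(only in first: {only_x}; only in second: {only_y}; "
            "or same set in a different order)"
        )


def pseudobulk_efficiency(X: ExpressionMatrix, Y: ExpressionMatrix) -> float:
    """Percent of total counts surviving conversion: 100 × total(Y)/total(X)."""
    _check_obs_match(X, Y)
    total_x = X.total()
    if total_x == 0:
        raise ValidationError("empty source matrix: total counts are zero")
    return 100.0 * Y.total() / total_x


def per_observation_efficiency(X: ExpressionMatrix, Y: ExpressionMatrix) -> np.ndarray:
    """Per-observation percent of counts surviving; NaN where the source
    column is empty (reported with a warning, never coerced to 0 or 100)."""
    _check_obs_match(X, Y)
    sx = X.obs_totals().astype(float)
    sy = Y.obs_totals().astype(float)
    out = np.full(len(sx), np.nan)
    ok = sx > 0
    out[ok] = 100.0 * sy[ok] / sx[ok]
    if (~ok).any():
        zero_obs = [X.obs_ids[i] for i in np.flatnonzero(~ok)]
        warnings.warn(
            f"{len(zero_obs)} observation(s) with zero source counts have "
            f"undefined efficiency: {zero_obs[:5]}",
            ConversionWarning,
            stacklevel=2,
        )
    return out


def gene_mapping_rate(
    table: OrthologTable, feature_ids: list[str], case_insensitive: bool = False
) -> float:
    """Percent of features with at least one ortholog target in the table."""
    if not feature_ids:
        raise ValidationError("empty feature list")
    fwd = table.forward_map(case_insensitive)
    n_mapped = sum(
        1
        for f in feature_ids
        if fwd.get(f.upper() if case_insensitive else f)
    )
    return 100.0 * n_mapped / len(feature_ids)


def biotype_retention(
    X: ExpressionMatrix,
    result: "ConversionResult | ConversionPlan",
    feature_meta: Optional[pd.DataFrame | pd.Series] = None,
) -> pd.DataFrame:
    """Per-biotype retention: how many input features of each gene class kept.

    Biotypes come from ``feature_meta`` (a 'biotype'/'gene_biotype' column or
    a Series), falling back to the matrix's own feature metadata; features
    without one are pooled as "unknown". A feature counts as retained when
    its conversion fate is "kept". ``result`` may be a full conversion result
    or just its plan.
    """
    biotypes = _resolve_biotypes(X, feature_meta)
    fates = getattr(result, "plan", result).fates
    records: dict[str, list[int]] = {}
    for feat in X.feature_ids:
        bt = biotypes.get(feat, "unknown")
        rec = records.setdefault(bt, [0, 0])
        rec[0] += 1
        if fates[feat].status == "kept":
            rec[1] += 1
    rows = [
        {
            "biotype": bt,
            "n_in": n_in,
            "n_retained": n_kept,
            "percent": 100.0 * n_kept / n_in,
        }
        for bt, (n_in, n_kept) in sorted(records.items())
    ]
    return pd.DataFrame(rows, columns=["biotype", "n_in", "n_retained", "percent"])


def _resolve_biotypes(
    X: ExpressionMatrix, feature_meta: Optional[pd.DataFrame | pd.Series]
) -> dict[str, str]:
    source = None
    if isinstance(feature_meta, pd.Series):
        source = feature_meta
    elif isinstance(feature_meta, pd.DataFrame):
        for col in ("biotype", "gene_biotype"):
            if col in feature_meta.columns:
                source = feature_meta[col]
                break
    elif feature_meta is None and X.feature_meta is not None:
        for col in ("biotype", "gene_biotype"):
            if col in X.feature_meta.columns:
                source = X.feature_meta[col]
                break
    if source is None:
        return {}
    out = {}
    for feat, value in source.items():
        if pd.notna(value) and str(value):
            out[str(feat)] = str(value)
    return out


def build_conversion_report(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    table: OrthologTable,
    plan: "ConversionPlan",
    policy: "ConversionPolicy",
) -> ConversionReport:
    """Assemble the full report for a realized conversion."""
    report_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        per_obs = per_observation_efficiency(X, Y)
    for w in caught:
        report_warnings.append(str(w.message))

    # biotype source: explicit matrix metadata first, else the table's records
    feature_meta = None
    if X.feature_meta is None or not any(
        c in X.feature_meta.columns for c in ("biotype", "gene_biotype")
    ):
        table_biotypes = {
            p.source_gene: p.source_biotype
            for p in table.pairs
            if p.source_biotype
        }
        if table_biotypes:
            feature_meta = pd.Series(
                {f: table_biotypes.get(f) for f in X.feature_ids}
            ).dropna()

    if X.total() == 0:
        pseudobulk = 0.0
        report_warnings.append(
            "source matrix has zero total counts; pseudobulk efficiency undefined, "
            "reported as 0"
        )
    else:
        pseudobulk = pseudobulk_efficiency(X, Y)
    if pseudobulk > 100.0 + 1e-9:
        report_warnings.append(
            "pseudobulk efficiency exceeds 100% (one_to_many=expand replicates "
            "counts into paralog targets)"
        )
    if not X.is_integer():
        report_warnings.append(
            "input matrix is non-integer (normalized assay); interpret count "
            "efficiencies accordingly"
        )

    retention = biotype_retention(X, plan, feature_meta)

    return ConversionReport(
        n_source_features=X.n_features,
        n_mapped_features=plan.n_mapped(),
        n_output_features=Y.n_features,
        gene_mapping_rate=gene_mapping_rate(
            table, X.feature_ids, policy.case_insensitive
        ),
        pseudobulk_count_efficiency=pseudobulk,
        per_obs_efficiency=per_obs,
        obs_ids=list(X.obs_ids),
        biotype_retention=retention,
        policy_echo=policy.as_dict(),
        is_integer_input=X.is_integer(),
        warnings=report_warnings,
    )


# ---------------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------------

@dataclass
class ClusterLabeling:
    """A categorical label per observation."""

    obs_ids: list[str]
    labels: list

    def __post_init__(self):
        if len(self.obs_ids) != len(self.labels):
            raise ValidationError("one label required per observation id")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise ValidationError("observation ids are not unique")

    @classmethod
    def from_obs_meta(cls, X: ExpressionMatrix, column: str) -> "ClusterLabeling":
        if X.obs_meta is None or column not in X.obs_meta.columns:
            raise ValidationError(f"no obs_meta column {column!r}")
        return cls(list(X.obs_ids), list(X.obs_meta[column]))

    @classmethod
    def from_tsv(cls, path) -> "ClusterLabeling":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("label TSV needs two columns: obs_id, label")
        return cls(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def _aligned_labels(L1: ClusterLabeling, L2: ClusterLabeling):
    if len(L1.obs_ids) < 2:
        raise ValidationError("need at least 2 observations to compare partitions")
    if set(L1.obs_ids) != set(L2.obs_ids):
        only1 = sorted(set(L1.obs_ids) - set(L2.obs_ids))[:5]
        only2 = sorted(set(L2.obs_ids) - set(L1.obs_ids))[:5]
        raise ValidationError(
            f"labelings cover different observations (only in first: {only1}; "
            f"only in second: {only2})"
        )
    pos2 = {o: i for i, o in enumerate(L2.obs_ids)}
    a = pd.factorize(np.asarray(L1.labels, dtype=object))[0]
    l2 = np.asarray(L2.labels, dtype=object)[[pos2[o] for o in L1.obs_ids]]
    b = pd.factorize(l2)[0]
    return a, b


def rand_index(L1: ClusterLabeling, L2: ClusterLabeling) -> float:
    """Raw Rand index: (co-clustered pairs + co-separated pairs) / C(n, 2)."""
    a, b = _aligned_labels(L1, L2)
    return float(rand_score(a, b))


def adjusted_rand_index(L1: ClusterLabeling, L2: ClusterLabeling) -> float:
    """Rand index adjusted for chance under the permutation model."""
    a, b = _aligned_labels(L1, L2)
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# SNN clustering pipeline
# ---------------------------------------------------------------------------

def cluster_observations(
    X: ExpressionMatrix,
    n_top_genes: int = 2000,
    n_components: int = 20,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> ClusterLabeling:
    """Cluster observations with a standard SNN workflow, deterministically.

    Steps: depth-normalize each observation to 10,000 total counts; log1p;
    select the ``n_top_genes`` most dispersed genes (variance/mean on the
    depth-normalized values, ties broken by row order); z-score each gene
    (values clipped at ±10); PCA to ``n_components``; k-nearest-neighbor
    graph in component space (Euclidean, self included in neighbor sets);
    SNN edge weights as Jaccard similarity of neighbor sets; community
    detection by modularity optimization at the given resolution and seed.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    n = X.n_obs
    if n < k_neighbors + 1:
        raise ValidationError(
            f"need at least k_neighbors+1 = {k_neighbors + 1} observations, got {n}"
        )

    counts = X.counts.tocsc().astype(np.float64)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    scale = np.divide(1e4, depth, out=np.zeros_like(depth), where=depth > 0)
    norm = (counts @ sp.diags(scale)).tocsc()

    mean = np.asarray(norm.mean(axis=1)).ravel()
    sq_mean = np.asarray(norm.multiply(norm).mean(axis=1)).ravel()
    var = np.maximum(sq_mean - mean**2, 0.0)
    dispersion = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    n_top = min(n_top_genes, X.n_features)
    top = np.argsort(-dispersion, kind="stable")[:n_top]
    top.sort()

    expr = np.log1p(norm[top, :].toarray()).T  # observations × genes
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0)
    sd[sd == 0] = 1.0
    z = np.clip((expr - mu) / sd, -10.0, 10.0)

    n_comp = max(1, min(n_components, n - 1, z.shape[1]))
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1, algorithm="brute")
    nn.fit(pcs)
    neighbor_idx = nn.kneighbors(return_distance=False)
    neighbor_sets = [set(row) | {i} for i, row in enumerate(neighbor_idx)]

    edges = {}
    for i, row in enumerate(neighbor_idx):
        for j in row:
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            if key in edges:
                continue
            inter = len(neighbor_sets[key[0]] & neighbor_sets[key[1]])
            union = len(neighbor_sets[key[0]] | neighbor_sets[key[1]])
            edges[key] = inter / union
    edge_list = sorted(edges)
    weights = [edges[e] for e in edge_list]

    graph = igraph.Graph(n=n, edges=edge_list)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    membership = partition.membership
    return ClusterLabeling(list(X.obs_ids), [str(m) for m in membership])


def concordance_report(
    X: ExpressionMatrix,
    result: "ConversionResult",
    **cluster_params,
) -> dict:
    """Cluster pre- and post-conversion matrices identically; compare.

    Returns ``{"rand_index", "adjusted_rand_index", "n_clusters_pre",
    "n_clusters_post"}``.
    """
    pre = cluster_observations(X, **cluster_params)
    post = cluster_observations(result.converted, **cluster_params)
    return {
        "rand_index": rand_index(pre, post),
        "adjusted_rand_index": adjusted_rand_index(pre, post),
        "n_clusters_pre": len(set(pre.labels)),
        "n_clusters_post": len(set(post.labels)),
    }
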