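"""Dual-species (xenograft) harmonization.

Expression data from a patient-derived xenograft (PDX) mixes transcripts of
the human graft with those of the non-human host. This module assigns each
feature of a mixed matrix to a species, converts only the non-human portion
into the human ortholog namespace, and merges the result with the native
human counts into a single *humanized* matrix — returned alongside, never in
place of, the untouched original.

Species assignment strategies, in order of reliability:

1. **prefix** — multi-genome references (e.g. CellRanger ``GRCh38_…`` /
   ``mm10_…``) tag every feature; assignment is by the configured literal
   prefixes, with ``_`` and ``-`` both accepted as the trailing separator.
2. **table_membership** — a feature found among the ortholog table's source
   genes is non-human; among its targets, human.
3. **case_heuristic** — fallback for features in both or neither namespace:
   all-uppercase alphabetic symbols read as human, Title-case as non-human
   (mouse/rat convention), anything else is ambiguous.

Ambiguous features are, by default, treated as human with a warning: in a
PDX the human graft is the analyte, so mis-assigning a human gene to the
host would silently delete signal of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from ._errors import ConversionWarning, OrthomapperError, ValidationError
from .converter import (
    ConversionPlan,
    ConversionPolicy,
    ConversionResult,
    FeatureFate,
    convert_matrix,
)
from .expression_io import ExpressionMatrix
from .ortholog_map import OrthologTable


@dataclass
class SpeciesPartition:
    """Disjoint assignment of every feature to human / non-human / ambiguous."""

    human_features: list[str]
    nonhuman_features: list[str]
    ambiguous_features: list[str]
    method: str  # "prefix" | "table_membership" | "case_heuristic"

    def __post_init__(self):
        sets = [
            set(self.human_features),
            set(self.nonhuman_features),
            set(self.ambiguous_features),
        ]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValidationError("species partition lists are not disjoint")


def _strip_prefix(feature: str, prefix: Optional[str]) -> str:
    """Remove a literal prefix, tolerating '_' vs '-' as the separator."""
    if not prefix:
        return feature
    base = prefix.rstrip("_-")
    for sep in ("_", "-"):
        candidate = base + sep
        if feature.startswith(candidate):
            return feature[len(candidate):]
    if not prefix[-1] in "_-" and feature.startswith(prefix):
        return feature[len(prefix):]
    return feature


def _has_prefix(feature: str, prefix: str) -> bool:
    return _strip_prefix(feature, prefix) != feature


def _case_class(symbol: str) -> str:
    letters = [c for c in symbol if c.isalpha()]
    if not letters:
        return "ambiguous"
    if all(c.isupper() for c in letters):
        return "human"
    if letters[0].isupper() and all(c.islower() for c in letters[1:]):
        return "nonhuman"
    return "ambiguous"


def detect_species(
    X: ExpressionMatrix,
    table: OrthologTable,
    human_prefix: Optional[str] = None,
    nonhuman_prefix: Optional[str] = None,
) -> SpeciesPartition:
    """Assign each feature of a mixed matrix to a species.

    With both prefixes configured, assignment is purely by prefix and
    unprefixed features are ambiguous. Otherwise table membership decides,
    with the case heuristic breaking features found in both or neither
    namespace. ``method`` records the strategy that resolved the most
    features. Deterministic and invariant to feature order.
    """
    if X.n_features == 0:
        raise ValidationError("input matrix has no features")

    human, nonhuman, ambiguous = [], [], []
    strategy_counts = {"prefix": 0, "table_membership": 0, "case_heuristic": 0}

    if human_prefix and nonhuman_prefix:
        for prefix, label in ((human_prefix, "human"), (nonhuman_prefix, "nonhuman")):
            if not any(_has_prefix(f, prefix) for f in X.feature_ids):
                warnings.warn(
                    f"configured {label} prefix {prefix!r} matches no feature",
                    ConversionWarning,
                    stacklevel=2,
                )
        for f in X.feature_ids:
            if _has_prefix(f, human_prefix):
                human.append(f)
                strategy_counts["prefix"] += 1
            elif _has_prefix(f, nonhuman_prefix):
                nonhuman.append(f)
                strategy_counts["prefix"] += 1
            else:
                ambiguous.append(f)
        method = "prefix"
    else:
        sources = table.source_genes
        targets = table.target_genes
        for f in X.feature_ids:
            in_src, in_tgt = f in sources, f in targets
            if in_src and not in_tgt:
                nonhuman.append(f)
                strategy_counts["table_membership"] += 1
            elif in_tgt and not in_src:
                human.append(f)
                strategy_counts["table_membership"] += 1
            else:
                cls = _case_class(f)
                strategy_counts["case_heuristic"] += 1
                if cls == "human":
                    human.append(f)
                elif cls == "nonhuman":
                    nonhuman.append(f)
                else:
                    ambiguous.append(f)
        method = max(
            ("table_membership", "case_heuristic"), key=lambda k: strategy_counts[k]
        )

    if len(ambiguous) == X.n_features:
        raise OrthomapperError(
            "species undecidable: every feature is ambiguous under the "
            "configured detection strategy"
        )
    return SpeciesPartition(human, nonhuman, ambiguous, method)


def convert_pdx(
    X: ExpressionMatrix,
    table: OrthologTable,
    policy: ConversionPolicy = ConversionPolicy(),
    human_prefix: Optional[str] = None,
    nonhuman_prefix: Optional[str] = None,
    ambiguous_as: str = "human",
) -> ConversionResult:
    """Humanize a mixed-species matrix.

    The non-human portion is converted through :func:`convert_matrix`
    (prefixes stripped before table lookup); native human features keep
    their original order (prefixes stripped) and converted targets merge
    into them, rows sharing one human symbol being summed; converted-only
    targets are appended in sorted order. The harmonized matrix is returned
    as a distinct named result ("humanized") — the input is never modified.
    Ambiguous features are treated per ``ambiguous_as`` ("human",
    "nonhuman" or "drop"), defaulting to human with a warning.
    """
    if ambiguous_as not in ("human", "nonhuman", "drop"):
        raise ValidationError("ambiguous_as must be 'human', 'nonhuman' or 'drop'")

    part = detect_species(X, table, human_prefix, nonhuman_prefix)
    human_feats = list(part.human_features)
    nonhuman_feats = list(part.nonhuman_features)
    extra_warnings: list[str] = []
    if part.ambiguous_features:
        if ambiguous_as == "human":
            human_feats += part.ambiguous_features
        elif ambiguous_as == "nonhuman":
            nonhuman_feats += part.ambiguous_features
        msg = (
            f"{len(part.ambiguous_features)} feature(s) of undecidable species "
            f"treated as {ambiguous_as} (e.g. {part.ambiguous_features[0]!r})"
        )
        warnings.warn(msg, ConversionWarning, stacklevel=2)
        extra_warnings.append(msg)

    # keep original feature order within each species block
    order = {f: i for i, f in enumerate(X.feature_ids)}
    human_feats.sort(key=order.__getitem__)
    nonhuman_feats.sort(key=order.__getitem__)

    human_part = X.subset_features(human_feats) if human_feats else None
    human_ids = [_strip_prefix(f, human_prefix) for f in human_feats]

    fates: dict[str, FeatureFate] = {}
    converted_part: Optional[ExpressionMatrix] = None
    sub_result: Optional[ConversionResult] = None
    if nonhuman_feats:
        stripped = [_strip_prefix(f, nonhuman_prefix) for f in nonhuman_feats]
        nonhuman_part = ExpressionMatrix(
            stripped, list(X.obs_ids), X.subset_features(nonhuman_feats).counts
        )
        sub_result = convert_matrix(nonhuman_part, table, policy)
        converted_part = sub_result.converted
        for orig, strip_id in zip(nonhuman_feats, stripped):
            fates[orig] = sub_result.plan.fates[strip_id]
    for f in human_feats:
        fates[f] = FeatureFate("kept", (_strip_prefix(f, human_prefix),))
    for f in part.ambiguous_features:
        if ambiguous_as == "drop":
            fates[f] = FeatureFate("dropped_unmapped")

    # merge: human block order first, new converted-only targets appended sorted
    merged_ids: list[str] = []
    seen: dict[str, int] = {}
    blocks: list[tuple[ExpressionMatrix, list[str]]] = []
    if human_part is not None:
        blocks.append((human_part, human_ids))
    if converted_part is not None:
        blocks.append((converted_part, list(converted_part.feature_ids)))

    links: list[tuple[int, int]] = []  # (merged row, stacked source row)
    stacked_rows = 0
    for block, ids in blocks:
        for local_idx, name in enumerate(ids):
            if name not in seen:
                seen[name] = len(merged_ids)
                merged_ids.append(name)
            links.append((seen[name], stacked_rows + local_idx))
        stacked_rows += block.n_features

    # reorder: human-order ids first (as encountered), converted-only sorted
    human_id_set = set(human_ids)
    head = [n for n in merged_ids if n in human_id_set]
    tail = sorted(n for n in merged_ids if n not in human_id_set)
    final_ids = head + tail
    final_pos = {n: i for i, n in enumerate(final_ids)}

    if stacked_rows:
        stacked = sp.vstack([b.counts for b, _ in blocks], format="csr")
        rows = np.array([final_pos[merged_ids[m]] for m, _ in links], dtype=np.int64)
        cols = np.array([s for _, s in links], dtype=np.int64)
        data = np.ones(len(links), dtype=stacked.dtype)
        incidence = sp.csr_matrix(
            (data, (rows, cols)), shape=(len(final_ids), stacked_rows)
        )
        merged_counts = (incidence @ stacked).tocsr()
        merged_counts.eliminate_zeros()
    else:
        merged_counts = sp.csr_matrix((0, X.n_obs), dtype=X.counts.dtype)

    harmonized = ExpressionMatrix(
        final_ids,
        list(X.obs_ids),
        merged_counts,
        obs_meta=None if X.obs_meta is None else X.obs_meta.copy(),
        embeddings={k: v.copy() for k, v in X.embeddings.items()},
    )

    from . import qc

    plan = ConversionPlan(
        fates=fates, kept_links=[], feature_ids=list(X.feature_ids)
    )
    human_total = human_part.total() if human_part is not None else 0
    nonhuman_total = (
        X.subset_features(nonhuman_feats).total() if nonhuman_feats else 0
    )
    converted_total = converted_part.total() if converted_part is not None else 0

    report = qc.ConversionReport(
        n_source_features=X.n_features,
        n_mapped_features=(
            sub_result.report.n_mapped_features if sub_result is not None else 0
        )
        + len(human_feats),
        n_output_features=harmonized.n_features,
        gene_mapping_rate=100.0
        * sum(1 for f in X.feature_ids if fates.get(f, FeatureFate("x")).status == "kept")
        / X.n_features,
        pseudobulk_count_efficiency=(
            100.0 * harmonized.total() / X.total() if X.total() > 0 else 0.0
        ),
        per_obs_efficiency=qc.per_observation_efficiency(X, harmonized),
        obs_ids=list(X.obs_ids),
        biotype_retention=qc.biotype_retention(X, plan),
        policy_echo=policy.as_dict()
        | {"mode": "pdx", "ambiguous_as": ambiguous_as, "detection": part.method},
        is_integer_input=X.is_integer(),
        warnings=(sub_result.report.warnings if sub_result is not None else [])
        + extra_warnings,
        extras={
            "pdx_human_input_total": human_total,
            "pdx_nonhuman_input_total": nonhuman_total,
            "pdx_converted_nonhuman_total": converted_total,
            "pdx_merged_total": harmonized.total(),
        },
    )

    return ConversionResult(
        converted=harmonized,
        report=report,
        unmapped_features=(
            sub_result.unmapped_features if sub_result is not None else []
        ),
        dropped_ambiguous=(
            sub_result.dropped_ambiguous if sub_result is not None else []
        ),
        plan=plan,
        name="humanized",
    )
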