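"""Namespace conversion: collapse/expand counts from a source-species gene
space into the human ortholog space under an explicit, fully disclosed policy.

The three policy axes cover the decisions an ortholog table forces on a count
matrix:

* ``many_to_one`` — several source genes share one human target. ``sum``
  aggregates their rows (pseudo-gene-level semantics for counts);
  ``max_total`` keeps only the source with the largest total count across
  observations (ties broken by lexicographically smallest source id);
  ``drop_group`` removes the whole collision group.
* ``one_to_many`` — a source gene has several human targets. ``expand``
  replicates its row into every target (total counts can inflate, which the
  report flags); ``drop`` discards the source as ambiguous.
* ``unmapped`` — a source gene with no target. ``drop`` discards it;
  ``retain_tagged`` keeps the row under an ``unmapped:`` prefix.

Aggregation is realized as a sparse incidence-matrix product and is
bit-identical to the dense definition for integer inputs. Observations,
per-observation metadata and embeddings pass through untouched, preserving
the dimensional architecture of the input.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from ._errors import ConversionWarning, NoFeaturesMappedError, ValidationError
from .expression_io import ExpressionMatrix
from .ortholog_map import OrthologTable

UNMAPPED_TAG = "unmapped:"

_MANY_TO_ONE = ("sum", "max_total", "drop_group")
_ONE_TO_MANY = ("expand", "drop")
_UNMAPPED = ("drop", "retain_tagged")


@dataclass(frozen=True)
class ConversionPolicy:
    """Explicit rules for the three ambiguous mapping situations."""

    many_to_one: str = "sum"
    one_to_many: str = "expand"
    unmapped: str = "drop"
    case_insensitive: bool = False

    def __post_init__(self):
        if self.many_to_one not in _MANY_TO_ONE:
            raise ValidationError(f"many_to_one must be one of {_MANY_TO_ONE}")
        if self.one_to_many not in _ONE_TO_MANY:
            raise ValidationError(f"one_to_many must be one of {_ONE_TO_MANY}")
        if self.unmapped not in _UNMAPPED:
            raise ValidationError(f"unmapped must be one of {_UNMAPPED}")

    def as_dict(self) -> dict:
        return {
            "many_to_one": self.many_to_one,
            "one_to_many": self.one_to_many,
            "unmapped": self.unmapped,
            "case_insensitive": self.case_insensitive,
        }


@dataclass(frozen=True)
class FeatureFate:
    """What conversion does to one source feature.

    ``status`` is one of ``kept`` (contributes to ``targets``),
    ``dropped_unmapped``, ``retained_unmapped`` (kept under the
    ``unmapped:`` tag) or ``dropped_ambiguous``.
    """

    status: str
    targets: tuple[str, ...] = ()


@dataclass
class ConversionPlan:
    """Dry-run summary: per-feature fate plus the realized link set."""

    fates: dict[str, FeatureFate]
    kept_links: list[tuple[int, str]]  # (feature index, target gene)
    feature_ids: list[str]

    @property
    def output_targets(self) -> list[str]:
        return sorted({t for _, t in self.kept_links})

    def n_mapped(self) -> int:
        return sum(
            1
            for f in self.fates.values()
            if f.status not in ("dropped_unmapped", "retained_unmapped")
        )


def conversion_plan(
    table: OrthologTable,
    feature_ids: list[str],
    policy: ConversionPolicy = ConversionPolicy(),
    counts: Optional[sp.spmatrix] = None,
) -> ConversionPlan:
    """Determine each feature's fate without touching any counts.

    The ``max_total`` policy needs row totals to pick a collision-group
    winner; pass ``counts`` to realize those fates exactly (convert_matrix
    does). Without counts, all members of a ``max_total`` group are reported
    as kept, which is the most a counts-free preview can say.
    """
    fwd = table.forward_map(policy.case_insensitive)
    fates: dict[str, FeatureFate] = {}
    links: list[tuple[int, str]] = []

    for idx, feat in enumerate(feature_ids):
        key = feat.upper() if policy.case_insensitive else feat
        targets = fwd.get(key, ())
        if not targets:
            status = (
                "retained_unmapped"
                if policy.unmapped == "retain_tagged"
                else "dropped_unmapped"
            )
            fates[feat] = FeatureFate(status)
        elif len(targets) > 1 and policy.one_to_many == "drop":
            fates[feat] = FeatureFate("dropped_ambiguous")
        else:
            links.extend((idx, t) for t in targets)

    groups: dict[str, list[int]] = defaultdict(list)
    for idx, target in links:
        groups[target].append(idx)

    row_totals = None
    if counts is not None:
        row_totals = np.asarray(sp.csr_matrix(counts).sum(axis=1)).ravel()

    kept_links: list[tuple[int, str]] = []
    for target in sorted(groups):
        members = groups[target]
        if len(members) >= 2 and policy.many_to_one == "drop_group":
            continue
        if len(members) >= 2 and policy.many_to_one == "max_total" and row_totals is not None:
            # max total count across observations; ties → smallest source id
            members = [
                min(members, key=lambda m: (-row_totals[m], feature_ids[m]))
            ]
        kept_links.extend((m, target) for m in members)

    kept_by_feature: dict[int, list[str]] = defaultdict(list)
    for idx, target in kept_links:
        kept_by_feature[idx].append(target)
    for idx, feat in enumerate(feature_ids):
        if feat in fates:
            continue
        targets = kept_by_feature.get(idx)
        if targets:
            fates[feat] = FeatureFate("kept", tuple(sorted(targets)))
        else:
            fates[feat] = FeatureFate("dropped_ambiguous")

    return ConversionPlan(fates=fates, kept_links=kept_links, feature_ids=list(feature_ids))


@dataclass
class ConversionResult:
    """Converted matrix plus the QC report and bookkeeping lists."""

    converted: ExpressionMatrix
    report: "object"  # qc.ConversionReport; avoids an import cycle
    unmapped_features: list[str]
    dropped_ambiguous: list[str]
    plan: ConversionPlan
    name: str = "converted"


def convert_matrix(
    X: ExpressionMatrix,
    table: OrthologTable,
    policy: ConversionPolicy = ConversionPolicy(),
) -> ConversionResult:
    """Convert a matrix into the human ortholog namespace.

    The output feature set is the set of human targets reachable from the
    input features after policy application (plus tagged unmapped rows when
    requested), sorted lexicographically. Observations, per-observation
    metadata and embeddings are passed through unchanged.

    Raises :class:`NoFeaturesMappedError` when no input feature has any
    target in the table; features merely absent from the table are counted
    as unmapped, never an error.
    """
    from . import qc  # deferred: qc also consumes conversion results

    if X.n_features == 0 or X.n_obs == 0:
        raise ValidationError("input matrix is empty")

    plan = conversion_plan(table, X.feature_ids, policy, counts=X.counts)
    if plan.n_mapped() == 0:
        raise NoFeaturesMappedError(
            "no features mapped: none of the matrix's feature ids has an "
            "ortholog target in the table",
            mapping_rate=0.0,
        )

    out_rows: list[tuple[str, list[int]]] = []
    grouped: dict[str, list[int]] = defaultdict(list)
    for idx, target in plan.kept_links:
        grouped[target].append(idx)
    for target in grouped:
        out_rows.append((target, grouped[target]))
    retained = [
        (UNMAPPED_TAG + feat, [i])
        for i, feat in enumerate(X.feature_ids)
        if plan.fates[feat].status == "retained_unmapped"
    ]
    out_rows.extend(retained)
    out_rows.sort(key=lambda r: r[0])
    # out_rows may legitimately be empty (e.g. drop_group removing every
    # collision group): the converted matrix then has zero features.

    # sparse incidence matrix: output rows × input features
    indptr = [0]
    indices: list[int] = []
    for _, members in out_rows:
        indices.extend(members)
        indptr.append(len(indices))
    incidence = sp.csr_matrix(
        (
            np.ones(len(indices), dtype=X.counts.dtype),
            np.array(indices, dtype=np.int64),
            np.array(indptr, dtype=np.int64),
        ),
        shape=(len(out_rows), X.n_features),
    )
    converted_counts = (incidence @ X.counts).tocsr()
    converted_counts.sum_duplicates()
    converted_counts.eliminate_zeros()

    converted = ExpressionMatrix(
        feature_ids=[name for name, _ in out_rows],
        obs_ids=list(X.obs_ids),
        counts=converted_counts,
        obs_meta=None if X.obs_meta is None else X.obs_meta.copy(),
        embeddings={k: v.copy() for k, v in X.embeddings.items()},
    )

    unmapped = [
        f
        for f in X.feature_ids
        if plan.fates[f].status in ("dropped_unmapped", "retained_unmapped")
    ]
    ambiguous = [f for f in X.feature_ids if plan.fates[f].status == "dropped_ambiguous"]

    report = qc.build_conversion_report(X, converted, table, plan, policy)
    if report.pseudobulk_count_efficiency > 100.0 + 1e-9:
        warnings.warn(
            f"pseudobulk efficiency {report.pseudobulk_count_efficiency:.2f}% exceeds "
            "100% because one_to_many=expand replicates counts into paralog targets",
            ConversionWarning,
            stacklevel=2,
        )

    return ConversionResult(
        converted=converted,
        report=report,
        unmapped_features=unmapped,
        dropped_ambiguous=ambiguous,
        plan=plan,
    )
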