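"""Independent brute-force references used to check the package's fast paths.

Everything here is deliberately naive: dense arrays, dict loops and explicit
pair enumeration, kept free of the sparse/indexed code paths they verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def forward_from_pairs(table, case_insensitive=False):
    """source → set of targets, straight off the pair list."""
    fwd: dict[str, set[str]] = {}
    for p in table.pairs:
        if p.target_gene is None:
            continue
        key = p.source_gene.upper() if case_insensitive else p.source_gene
        fwd.setdefault(key, set()).add(p.target_gene)
    return fwd


def dense_convert(feature_ids, counts, table, policy):
    """Dense realization of the conversion definition.

    Returns (sorted output ids, dense output array, fate dict). ``counts``
    is a dense features × observations integer array.
    """
    counts = np.asarray(counts)
    fwd = forward_from_pairs(table, policy.case_insensitive)
    fates: dict[str, str] = {}
    contributing: dict[str, list[int]] = {}

    for i, feat in enumerate(feature_ids):
        key = feat.upper() if policy.case_insensitive else feat
        targets = sorted(fwd.get(key, ()))
        if not targets:
            fates[feat] = (
                "retained_unmapped"
                if policy.unmapped == "retain_tagged"
                else "dropped_unmapped"
            )
            continue
        if len(targets) > 1 and policy.one_to_many == "drop":
            fates[feat] = "dropped_ambiguous"
            continue
        for t in targets:
            contributing.setdefault(t, []).append(i)

    rows: dict[str, np.ndarray] = {}
    kept_members: dict[int, list[str]] = {}
    for target, members in contributing.items():
        if len(members) >= 2 and policy.many_to_one == "drop_group":
            continue
        if len(members) >= 2 and policy.many_to_one == "max_total":
            ranked = sorted(
                members, key=lambda m: (-int(counts[m].sum()), feature_ids[m])
            )
            members = [ranked[0]]
        rows[target] = counts[members].sum(axis=0)
        for m in members:
            kept_members.setdefault(m, []).append(target)

    for i, feat in enumerate(feature_ids):
        if feat in fates:
            continue
        fates[feat] = "kept" if i in kept_members else "dropped_ambiguous"

    if policy.unmapped == "retain_tagged":
        for i, feat in enumerate(feature_ids):
            if fates[feat] == "retained_unmapped":
                rows["unmapped:" + feat] = counts[i]

    out_ids = sorted(rows)
    out = (
        np.array([rows[t] for t in out_ids])
        if out_ids
        else np.zeros((0, counts.shape[1]), dtype=counts.dtype)
    )
    return out_ids, out, fates


def pair_enumeration_rand(labels1, labels2):
    """Rand index by explicit enumeration of all observation pairs."""
    n = len(labels1)
    assert n == len(labels2) and n >= 2
    a = b = 0
    for i, j in itertools.combinations(range(n), 2):
        together1 = labels1[i] == labels1[j]
        together2 = labels2[i] == labels2[j]
        if together1 and together2:
            a += 1
        elif not together1 and not together2:
            b += 1
    return (a + b) / math.comb(n, 2)


def degree_scan_classes(table):
    """Cardinality class per mapped pair, from raw degree counts."""
    out_deg: dict[str, set[str]] = {}
    in_deg: dict[str, set[str]] = {}
    for p in table.pairs:
        if p.target_gene is None:
            continue
        out_deg.setdefault(p.source_gene, set()).add(p.target_gene)
        in_deg.setdefault(p.target_gene, set()).add(p.source_gene)
    classes = {}
    for p in table.pairs:
        if p.target_gene is None:
            classes[(p.source_gene, p.target_gene)] = "unmapped"
            continue
        o = len(out_deg[p.source_gene])
        i = len(in_deg[p.target_gene])
        if o == 1 and i == 1:
            cls = "one2one"
        elif o > 1 and i > 1:
            cls = "many2many"
        else:
            cls = "one2many"
        classes[(p.source_gene, p.target_gene)] = cls
    return classes
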