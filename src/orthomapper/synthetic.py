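"""Synthetic fixtures with known ground truth for every pipeline stage.

Real conversion benchmarks need public single-cell datasets; everything here
emulates their relevant structure offline instead: negative-binomial grouped
counts (the standard scRNA-seq count model), ortholog tables with a designed
one2one / one2many / many2many / unmapped mix, and stacked human+mouse PDX
mixtures. Every generator is deterministic given its design's seed, and every
designed quantity (group labels, pair cardinalities, species tags) is
returned as ground truth so recovery can be asserted exactly.

The count model: ``counts[g, c] ~ NB(mean = base_g · fc_{g, group(c)} ·
size_c, dispersion θ)`` with variance ``μ + μ²/θ`` (so larger θ means less
overdispersion), log-normal baseline means ``base_g``, multiplicative fold
changes on a ``de_fraction`` subset of genes, and per-cell size factors
drawn uniformly from ``depth_range``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._errors import ValidationError
from .expression_io import ExpressionMatrix
from .ortholog_map import HomologyType, OrthologPair, OrthologTable, classify_cardinality
from .pdx import SpeciesPartition


class CaseStyle(str, Enum):
    MOUSE_TITLE_CASE = "mouse_title_case"
    SHARED_UPPER = "shared_upper"


@dataclass
class SimulationDesign:
    """Parameters of the grouped negative-binomial count generator."""

    n_genes: int = 500
    n_cells: int = 300
    n_groups: int = 3
    de_fraction: float = 0.2
    lfc_scale: float = 2.0
    nb_dispersion: float = 10.0
    depth_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_cells, self.n_groups) <= 0:
            raise ValidationError("n_genes, n_cells, n_groups must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.lfc_scale < 0 or self.nb_dispersion <= 0:
            raise ValidationError("lfc_scale must be >= 0 and nb_dispersion > 0")
        lo, hi = self.depth_range
        if not 0 < lo <= hi:
            raise ValidationError("depth_range bounds must be positive and ordered")
        if self.n_cells < self.n_groups:
            raise ValidationError("need at least one cell per group")


@dataclass
class TableDesign:
    """Composition of a synthetic ortholog table."""

    n_one2one: int = 300
    n_one2many: int = 50
    max_fanout: int = 3
    n_many2many_blocks: int = 10
    block_size: int = 3
    n_unmapped: int = 120
    case_style: CaseStyle = CaseStyle.MOUSE_TITLE_CASE
    seed: int = 0

    def __post_init__(self):
        self.case_style = CaseStyle(self.case_style)
        for name in ("n_one2one", "n_one2many", "n_many2many_blocks",
                     "block_size", "n_unmapped"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_one2many > 0 and self.max_fanout < 2:
            raise ValidationError("max_fanout must be >= 2 when n_one2many > 0")

    @property
    def n_consumed(self) -> int:
        return (
            self.n_one2one
            + self.n_one2many
            + self.n_many2many_blocks * self.block_size
            + self.n_unmapped
        )


def _gene_names(n: int, stem: str = "Gene") -> list[str]:
    return [f"{stem}{i:04d}" for i in range(n)]


def simulate_counts(
    design: SimulationDesign, gene_stem: str = "Gene", cell_stem: str = "cell"
) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate a grouped NB count matrix; returns (matrix, group labels).

    Group labels are balanced and randomly permuted across cells, and are
    also stored in ``obs_meta['group']``. The generator's internal mean
    parameters (baseline mean and per-group fold change of every gene) are
    exposed in ``feature_meta`` so tests can assert on them directly.
    """
    rng = np.random.default_rng(design.seed)
    G, C, K = design.n_genes, design.n_cells, design.n_groups

    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    fc = np.ones((G, K))
    n_de = int(round(design.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    if n_de and design.lfc_scale > 0:
        fc[de_idx, :] = 2.0 ** rng.normal(0.0, design.lfc_scale, size=(n_de, K))

    groups = np.tile(np.arange(K), C // K + 1)[:C]
    groups = rng.permutation(groups)
    sizes = rng.uniform(design.depth_range[0], design.depth_range[1], size=C)

    mu = base[:, None] * fc[:, groups] * sizes[None, :]
    theta = design.nb_dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)

    feature_ids = _gene_names(G, gene_stem)
    obs_ids = [f"{cell_stem}{j:04d}" for j in range(C)]
    labels = [f"grp{k}" for k in groups]

    feature_meta = pd.DataFrame({"base_mean": base}, index=pd.Index(feature_ids))
    for k in range(K):
        feature_meta[f"fc_grp{k}"] = fc[:, k]
    obs_meta = pd.DataFrame(
        {"group": labels, "size_factor": sizes}, index=pd.Index(obs_ids)
    )

    X = ExpressionMatrix(
        feature_ids,
        obs_ids,
        sp.csr_matrix(counts.astype(np.int64)),
        feature_meta=feature_meta,
        obs_meta=obs_meta,
    )
    return X, labels


def simulate_ortholog_table(
    design: TableDesign, feature_ids: list[str]
) -> tuple[OrthologTable, dict[str, str]]:
    """Build a table over the leading features; returns (table, fate map).

    The first ``n_one2one`` features get a single private human target, the
    next ``n_one2many`` each fan out to 2…max_fanout targets, then
    ``n_many2many_blocks`` complete bipartite blocks of ``block_size``
    sources × ``block_size`` targets, then ``n_unmapped`` sources with no
    homolog. Target symbols are collision-free uppercase transforms of their
    sources. The fate map gives each consumed feature's designed cardinality
    class (one2one / one2many / many2many / unmapped).
    """
    if len(feature_ids) < design.n_consumed:
        raise ValidationError(
            f"table design consumes {design.n_consumed} features but only "
            f"{len(feature_ids)} provided"
        )
    rng = np.random.default_rng(design.seed)
    it = iter(feature_ids)
    existing = set(feature_ids)
    used_targets: set[str] = set()

    def target_name(source: str, suffix: str = "") -> str:
        base = source.upper() + suffix
        candidate = base
        n = 0
        while candidate in used_targets or candidate in existing:
            n += 1
            candidate = f"{base}-HS{n}"
        used_targets.add(candidate)
        return candidate

    pairs: list[OrthologPair] = []
    fates: dict[str, str] = {}

    for _ in range(design.n_one2one):
        src = next(it)
        pairs.append(OrthologPair(src, target_name(src), HomologyType.ONE2ONE))
        fates[src] = "one2one"

    for _ in range(design.n_one2many):
        src = next(it)
        fanout = int(rng.integers(2, design.max_fanout + 1))
        for j in range(fanout):
            pairs.append(
                OrthologPair(src, target_name(src, f"-P{j + 1}"), HomologyType.ONE2MANY)
            )
        fates[src] = "one2many"

    for b in range(design.n_many2many_blocks):
        sources = [next(it) for _ in range(design.block_size)]
        targets = [target_name(s, "-MM") for s in sources]
        for s in sources:
            fates[s] = "many2many"
            for t in targets:
                pairs.append(OrthologPair(s, t, HomologyType.MANY2MANY))

    for _ in range(design.n_unmapped):
        src = next(it)
        pairs.append(OrthologPair(src, None, HomologyType.UNMAPPED))
        fates[src] = "unmapped"

    table = classify_cardinality(OrthologTable(tuple(pairs)))
    return table, fates


def simulate_pdx(
    human_design: SimulationDesign,
    mouse_design: SimulationDesign,
    table_design: Optional[TableDesign] = None,
    prefix_mode: bool = False,
    human_prefix: str = "GRCh38_",
    nonhuman_prefix: str = "mm10_",
) -> tuple[ExpressionMatrix, SpeciesPartition, OrthologTable]:
    """Stack a human and a mouse count block over shared observations.

    The mouse block carries Title-case mouse-style symbols and an ortholog
    table generated from them; the human block reuses the table's human
    targets as its feature names (so merging collides where it should),
    padding with human-only symbols when the human design asks for more
    genes than the table provides targets. Returns the mixture, the
    ground-truth species partition and the table.
    """
    if human_design.n_cells != mouse_design.n_cells:
        raise ValidationError("human and mouse designs must share the cell count")
    if table_design is None:
        defaults = TableDesign()
        scale = mouse_design.n_genes / max(1, defaults.n_consumed)
        table_design = TableDesign(
            n_one2one=int(defaults.n_one2one * scale),
            n_one2many=max(1, int(defaults.n_one2many * scale)),
            n_many2many_blocks=max(1, int(defaults.n_many2many_blocks * scale)),
            n_unmapped=max(1, int(defaults.n_unmapped * scale)),
            seed=mouse_design.seed,
        )

    mouse_X, _ = simulate_counts(mouse_design, gene_stem="Mgene", cell_stem="cell")
    table, _ = simulate_ortholog_table(table_design, mouse_X.feature_ids)

    human_X, _ = simulate_counts(human_design, gene_stem="Hplaceholder", cell_stem="cell")
    targets = sorted(table.target_genes)
    human_names = targets[: human_design.n_genes]
    human_names += [
        f"HSONLY{i:04d}" for i in range(human_design.n_genes - len(human_names))
    ]
    human_X = ExpressionMatrix(
        human_names,
        human_X.obs_ids,
        human_X.counts,
        obs_meta=human_X.obs_meta,
    )

    h_ids = [human_prefix + f for f in human_names] if prefix_mode else human_names
    m_ids = (
        [nonhuman_prefix + f for f in mouse_X.feature_ids]
        if prefix_mode
        else list(mouse_X.feature_ids)
    )

    obs_meta = human_X.obs_meta.rename(columns={"group": "group_human"})
    obs_meta["group_mouse"] = list(mouse_X.obs_meta["group"])

    stacked = ExpressionMatrix(
        h_ids + m_ids,
        list(human_X.obs_ids),
        sp.vstack([human_X.counts, mouse_X.counts], format="csr"),
        feature_meta=pd.DataFrame(
            {"species": ["human"] * len(h_ids) + ["mouse"] * len(m_ids)},
            index=pd.Index(h_ids + m_ids),
        ),
        obs_meta=obs_meta,
    )
    truth = SpeciesPartition(
        human_features=h_ids,
        nonhuman_features=m_ids,
        ambiguous_features=[],
        method="prefix" if prefix_mode else "table_membership",
    )
    return stacked, truth, table


def simulate_marker_groups(
    n_base_genes: int = 200,
    n_markers_per_group: int = 30,
    n_groups: int = 3,
    n_cells: int = 240,
    base_mean: float = 2.0,
    marker_mean: float = 40.0,
    nb_dispersion: float = 50.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], dict[str, list[str]]]:
    """Groups separable *only* through exclusive marker blocks.

    Background genes share one NB distribution across all cells; each group
    additionally expresses its own private block of high-mean marker genes,
    so group identity lives entirely in the marker blocks. Removing the
    blocks that distinguish two groups (e.g. by leaving them out of an
    ortholog table under the drop policy) forces those groups to merge,
    which is what the drop-policy concordance fixtures need. Returns
    (matrix, labels, {group → marker gene ids}).
    """
    rng = np.random.default_rng(seed)
    groups = np.tile(np.arange(n_groups), n_cells // n_groups + 1)[:n_cells]
    groups = rng.permutation(groups)
    theta = nb_dispersion

    def nb(mean, shape):
        mu = np.full(shape, mean, dtype=float)
        return rng.negative_binomial(theta, theta / (theta + mu))

    blocks = [nb(base_mean, (n_base_genes, n_cells))]
    feature_ids = [f"Base{i:04d}" for i in range(n_base_genes)]
    markers: dict[str, list[str]] = {}
    for k in range(n_groups):
        block = nb(0.05, (n_markers_per_group, n_cells))
        in_group = groups == k
        block[:, in_group] = nb(marker_mean, (n_markers_per_group, int(in_group.sum())))
        blocks.append(block)
        names = [f"Mk{k}g{i:03d}" for i in range(n_markers_per_group)]
        markers[f"grp{k}"] = names
        feature_ids += names

    counts = np.vstack(blocks).astype(np.int64)
    obs_ids = [f"cell{j:04d}" for j in range(n_cells)]
    labels = [f"grp{k}" for k in groups]
    X = ExpressionMatrix(
        feature_ids,
        obs_ids,
        sp.csr_matrix(counts),
        obs_meta=pd.DataFrame({"group": labels}, index=pd.Index(obs_ids)),
    )
    return X, labels, markers
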