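"""Ortholog mapping tables: loading, de-duplication, cardinality classification.

An :class:`OrthologTable` is a set of (source gene, human gene) pairs together
with the two degree indexes needed to classify each pair's homology cardinality
(one2one / one2many / many2many). Sources with no human homolog are retained
as explicit *unmapped* pairs so that mapping-rate denominators stay computable.

Homology-type strings found in a file are treated as advisory only: subsetted
exports routinely break file-level labels, so the classification recomputed
from the table's own degrees is authoritative.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from ._errors import ConversionWarning, DialectError, OrthomapperError
from ._util import atomic_path


class HomologyType(str, Enum):
    ONE2ONE = "one2one"
    ONE2MANY = "one2many"
    MANY2MANY = "many2many"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class OrthologPair:
    """One (source gene, human gene) mapping record.

    ``target_gene`` is ``None`` exactly when ``homology_type`` is unmapped.
    """

    source_gene: str
    target_gene: Optional[str]
    homology_type: HomologyType
    confidence: Optional[int] = None
    source_biotype: Optional[str] = None

    def __post_init__(self):
        if not self.source_gene:
            raise ValueError("source_gene must be non-empty")
        if (self.target_gene is None) != (self.homology_type is HomologyType.UNMAPPED):
            raise ValueError(
                "target_gene must be absent exactly when homology_type is 'unmapped'"
            )


@dataclass
class OrthologTable:
    """Deduplicated ortholog pairs plus forward/reverse degree indexes."""

    pairs: tuple[OrthologPair, ...]
    source_species: str = "mouse"
    target_species: str = "human"
    load_info: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        self.pairs = tuple(self.pairs)
        seen = set()
        for p in self.pairs:
            key = (p.source_gene, p.target_gene)
            if key in seen:
                raise ValueError(f"duplicate ortholog pair {key}")
            seen.add(key)
        self._rebuild_indexes()

    def _rebuild_indexes(self) -> None:
        fwd: dict[str, set[str]] = defaultdict(set)
        rev: dict[str, set[str]] = defaultdict(set)
        for p in self.pairs:
            if p.target_gene is not None:
                fwd[p.source_gene].add(p.target_gene)
                rev[p.target_gene].add(p.source_gene)
        self.forward_index: dict[str, set[str]] = dict(fwd)
        self.reverse_index: dict[str, set[str]] = dict(rev)

    # -- accessors -------------------------------------------------------

    @property
    def mapped_pairs(self) -> tuple[OrthologPair, ...]:
        return tuple(p for p in self.pairs if p.target_gene is not None)

    @property
    def source_genes(self) -> set[str]:
        """All source genes, including unmapped ones."""
        return {p.source_gene for p in self.pairs}

    @property
    def target_genes(self) -> set[str]:
        return set(self.reverse_index)

    def targets_of(self, source_gene: str) -> set[str]:
        return set(self.forward_index.get(source_gene, ()))

    def forward_map(self, case_insensitive: bool = False) -> dict[str, tuple[str, ...]]:
        """source → sorted tuple of targets; keys upper-cased when requested.

        Case folding can merge distinct sources; their target sets are unioned,
        which is the documented risk of the opt-in case-insensitive mode.
        """
        out: dict[str, set[str]] = defaultdict(set)
        for src, tgts in self.forward_index.items():
            key = src.upper() if case_insensitive else src
            out[key] |= tgts
        return {k: tuple(sorted(v)) for k, v in out.items()}

    def max_fanout(self) -> int:
        return max((len(v) for v in self.forward_index.values()), default=0)


def classify_cardinality(table: OrthologTable) -> OrthologTable:
    """Recompute homology types from forward/reverse degrees.

    For a mapped pair (s, t) with out-degree o = |targets(s)| and in-degree
    i = |sources(t)|: one2one iff o = i = 1; many2many iff o > 1 and i > 1;
    one2many otherwise. Unmapped pairs are untouched. Idempotent.
    """
    new_pairs = []
    for p in table.pairs:
        if p.target_gene is None:
            new_pairs.append(p)
            continue
        o = len(table.forward_index[p.source_gene])
        i = len(table.reverse_index[p.target_gene])
        if o == 1 and i == 1:
            ht = HomologyType.ONE2ONE
        elif o > 1 and i > 1:
            ht = HomologyType.MANY2MANY
        else:
            ht = HomologyType.ONE2MANY
        new_pairs.append(replace(p, homology_type=ht))
    return OrthologTable(
        tuple(new_pairs), table.source_species, table.target_species, table.load_info
    )


def filter_table(
    table: OrthologTable,
    min_confidence: Optional[int] = None,
    allowed_types: Optional[Iterable[HomologyType | str]] = None,
    allowed_biotypes: Optional[Iterable[str]] = None,
) -> OrthologTable:
    """Drop mapped pairs failing any predicate; re-classify the survivors.

    Sources that lose all their targets become unmapped pairs (retained, so
    mapping-rate denominators are unchanged). Removing every mapped pair is a
    warning, not an error.
    """
    if allowed_types is not None:
        allowed_types = {HomologyType(t) for t in allowed_types}
    if allowed_biotypes is not None:
        allowed_biotypes = set(allowed_biotypes)

    kept: list[OrthologPair] = []
    lost_sources: dict[str, OrthologPair] = {}
    had_mapped = False
    for p in table.pairs:
        if p.target_gene is None:
            kept.append(p)
            continue
        had_mapped = True
        ok = True
        if min_confidence is not None:
            ok = ok and (p.confidence is not None and p.confidence >= min_confidence)
        if allowed_types is not None:
            ok = ok and p.homology_type in allowed_types
        if allowed_biotypes is not None:
            ok = ok and p.source_biotype in allowed_biotypes
        if ok:
            kept.append(p)
        else:
            lost_sources.setdefault(p.source_gene, p)

    surviving_sources = {p.source_gene for p in kept}
    for src, proto in lost_sources.items():
        if src not in surviving_sources:
            kept.append(
                OrthologPair(
                    src,
                    None,
                    HomologyType.UNMAPPED,
                    confidence=None,
                    source_biotype=proto.source_biotype,
                )
            )
            surviving_sources.add(src)

    if had_mapped and not any(p.target_gene is not None for p in kept):
        warnings.warn(
            "filter removed every mapped pair from the ortholog table",
            ConversionWarning,
            stacklevel=2,
        )
    return classify_cardinality(
        OrthologTable(tuple(kept), table.source_species, table.target_species,
                      table.load_info)
    )


# ---------------------------------------------------------------------------
# TSV loading / writing
# ---------------------------------------------------------------------------

_BIOMART_SOURCE_COLS = ("external_gene_name", "ensembl_gene_id")
_BIOMART_TARGET_COLS = (
    "hsapiens_homolog_associated_gene_name",
    "hsapiens_homolog_ensembl_gene",
)
_BIOMART_TYPE_COL = "hsapiens_homolog_orthology_type"
_BIOMART_CONF_COL = "hsapiens_homolog_orthology_confidence"
_BIOMART_BIOTYPE_COL = "gene_biotype"


def _pick_column(df: pd.DataFrame, candidates: tuple[str, ...], role: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise DialectError(
        f"biomart_tsv table is missing the {role} column "
        f"(expected one of: {', '.join(candidates)})"
    )


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def load_ortholog_table(
    path: str | Path,
    dialect: str = "biomart_tsv",
    source_species: str = "mouse",
) -> OrthologTable:
    """Load an ortholog table from a tab-delimited export.

    Two dialects are accepted. ``biomart_tsv`` follows the standard homolog
    export layout (gene symbols or Ensembl IDs in the source column, human
    homolog symbol/ID, optional orthology type, confidence and biotype
    columns, any column order). ``generic_two_column`` expects ``source`` and
    ``target`` headers with an optional ``biotype``.

    Rows with an empty human homolog become unmapped pairs; exact duplicate
    (source, target) rows collapse to one; identifiers are whitespace-trimmed;
    rows with an empty source gene are skipped with a warning and counted in
    ``load_info``. Cardinality is re-classified from the loaded table's own
    degrees regardless of any type strings in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ortholog table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DialectError(f"empty ortholog table file: {path}") from None

    if dialect == "biomart_tsv":
        src_col = _pick_column(df, _BIOMART_SOURCE_COLS, "source gene")
        tgt_col = _pick_column(df, _BIOMART_TARGET_COLS, "human homolog")
        conf_col = _BIOMART_CONF_COL if _BIOMART_CONF_COL in df.columns else None
        biot_col = _BIOMART_BIOTYPE_COL if _BIOMART_BIOTYPE_COL in df.columns else None
    elif dialect == "generic_two_column":
        for required in ("source", "target"):
            if required not in df.columns:
                raise DialectError(
                    f"generic_two_column table is missing the '{required}' column"
                )
        src_col, tgt_col = "source", "target"
        conf_col = None
        biot_col = "biotype" if "biotype" in df.columns else None
    else:
        raise DialectError(f"unknown table dialect: {dialect!r}")

    pairs: dict[tuple[str, Optional[str]], OrthologPair] = {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        src = _clean(rec.get(src_col))
        if not src:
            n_skipped += 1
            continue
        tgt = _clean(rec.get(tgt_col)) or None
        conf: Optional[int] = None
        if conf_col:
            raw = _clean(rec.get(conf_col))
            if raw:
                try:
                    conf = int(float(raw))
                except ValueError:
                    conf = None
        biotype = _clean(rec.get(biot_col)) or None if biot_col else None
        key = (src, tgt)
        if key in pairs:
            continue
        ht = HomologyType.UNMAPPED if tgt is None else HomologyType.ONE2ONE
        pairs[key] = OrthologPair(src, tgt, ht, conf, biotype)

    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} row(s) with empty source gene in {path.name}",
            ConversionWarning,
            stacklevel=2,
        )
    if not pairs:
        raise OrthomapperError(f"no mapping rows in ortholog table: {path}")

    table = OrthologTable(
        tuple(pairs.values()),
        source_species=source_species,
        load_info={
            "n_rows": int(len(df)),
            "n_pairs": len(pairs),
            "n_skipped_empty_source": n_skipped,
            "dialect": dialect,
        },
    )
    return classify_cardinality(table)


def write_ortholog_table_tsv(
    table: OrthologTable, path: str | Path, dialect: str = "biomart_tsv"
) -> None:
    """Write a table in a dialect :func:`load_ortholog_table` accepts."""
    rows = []
    for p in table.pairs:
        if dialect == "biomart_tsv":
            rows.append(
                {
                    "external_gene_name": p.source_gene,
                    "hsapiens_homolog_associated_gene_name": p.target_gene or "",
                    "hsapiens_homolog_orthology_type": (
                        f"ortholog_{p.homology_type.value}"
                        if p.target_gene is not None
                        else ""
                    ),
                    "hsapiens_homolog_orthology_confidence": (
                        "" if p.confidence is None else p.confidence
                    ),
                    "gene_biotype": p.source_biotype or "",
                }
            )
        elif dialect == "generic_two_column":
            rows.append(
                {
                    "source": p.source_gene,
                    "target": p.target_gene or "",
                    "biotype": p.source_biotype or "",
                }
            )
        else:
            raise DialectError(f"unknown table dialect: {dialect!r}")
    with atomic_path(path) as tmp:
        pd.DataFrame(rows).to_csv(tmp, sep="\t", index=False)
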