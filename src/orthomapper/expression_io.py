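"""Count-matrix containers and readers/writers for the standard formats.

The canonical in-memory object is :class:`ExpressionMatrix`: a sparse,
non-negative, features × observations matrix with optional per-feature and
per-observation metadata and named embeddings. Supported on-disk forms are
the 10x-style MatrixMarket triplet (matrix.mtx + features.tsv + barcodes.tsv,
optionally gzipped), dense CSV, and the HDF5-backed ``.h5ad`` single-cell
container. R ``.RDS`` files are not parsed; export such objects to an MTX
triplet or ``.h5ad`` first (see the package docs for the recipe).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import ValidationError
from ._util import atomic_path, make_unique


@dataclass
class ExpressionMatrix:
    """Sparse non-negative counts, features × observations, with metadata.

    ``counts`` may be real-valued (normalized assays are allowed); the only
    numeric invariant is non-negativity. ``feature_meta`` / ``obs_meta`` are
    indexed by the corresponding identifier lists; each embedding is an
    observations × dimensions array.
    """

    feature_ids: list[str]
    obs_ids: list[str]
    counts: sp.csr_matrix
    feature_meta: Optional[pd.DataFrame] = None
    obs_meta: Optional[pd.DataFrame] = None
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        n_feat, n_obs = self.counts.shape
        if len(self.feature_ids) != n_feat:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {n_feat} matrix rows"
            )
        if len(self.obs_ids) != n_obs:
            raise ValidationError(
                f"{len(self.obs_ids)} observation ids for {n_obs} matrix columns"
            )
        if len(set(self.feature_ids)) != n_feat:
            raise ValidationError("feature ids are not unique")
        if len(set(self.obs_ids)) != n_obs:
            raise ValidationError("observation ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        for meta_name in ("feature_meta", "obs_meta"):
            meta = getattr(self, meta_name)
            ids = self.feature_ids if meta_name == "feature_meta" else self.obs_ids
            if meta is not None:
                if len(meta) != len(ids):
                    raise ValidationError(
                        f"{meta_name} has {len(meta)} rows for {len(ids)} ids"
                    )
                meta = meta.copy()
                meta.index = pd.Index(ids)
                setattr(self, meta_name, meta)
        for name, emb in self.embeddings.items():
            emb = np.asarray(emb)
            if emb.shape[0] != n_obs:
                raise ValidationError(
                    f"embedding {name!r} has {emb.shape[0]} rows for {n_obs} observations"
                )
            self.embeddings[name] = emb

    # -- basic queries ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_obs(self) -> int:
        return self.counts.shape[1]

    def total(self) -> float:
        t = self.counts.sum()
        return int(t) if np.issubdtype(self.counts.dtype, np.integer) else float(t)

    def obs_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def is_integer(self) -> bool:
        if np.issubdtype(self.counts.dtype, np.integer):
            return True
        data = self.counts.data
        return bool(np.all(data == np.round(data)))

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        """Row-subset (and reorder) by feature id."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in pos]
        if missing:
            raise ValidationError(f"unknown feature id(s): {missing[:5]}")
        idx = [pos[f] for f in keep]
        return ExpressionMatrix(
            feature_ids=list(keep),
            obs_ids=list(self.obs_ids),
            counts=self.counts[idx, :],
            feature_meta=None if self.feature_meta is None else self.feature_meta.iloc[idx],
            obs_meta=None if self.obs_meta is None else self.obs_meta.copy(),
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        """Exact equality of ids, order and stored values (metadata ignored)."""
        return (
            self.feature_ids == other.feature_ids
            and self.obs_ids == other.obs_ids
            and self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            obs_ids=list(self.obs_ids),
            counts=self.counts.copy(),
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
            obs_meta=None if self.obs_meta is None else self.obs_meta.copy(),
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
        )

    # -- container interop ----------------------------------------------

    def to_anndata(self):
        """Observations × features AnnData view of this matrix."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=(self.obs_meta.copy() if self.obs_meta is not None
                 else pd.DataFrame(index=pd.Index(self.obs_ids))),
            var=(self.feature_meta.copy() if self.feature_meta is not None
                 else pd.DataFrame(index=pd.Index(self.feature_ids))),
        )
        adata.obs_names = pd.Index(self.obs_ids)
        adata.var_names = pd.Index(self.feature_ids)
        for name, emb in self.embeddings.items():
            adata.obsm[name] = np.asarray(emb)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionMatrix":
        X = adata.X
        counts = sp.csr_matrix(X).T.tocsr() if not sp.issparse(X) else X.tocsr().T.tocsr()
        return cls(
            feature_ids=list(map(str, adata.var_names)),
            obs_ids=list(map(str, adata.obs_names)),
            counts=counts,
            feature_meta=adata.var.copy() if adata.var.shape[1] else None,
            obs_meta=adata.obs.copy() if adata.obs.shape[1] else None,
            embeddings={k: np.asarray(v) for k, v in adata.obsm.items()},
        )


# ---------------------------------------------------------------------------
# 10x-style MTX triplet
# ---------------------------------------------------------------------------

def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {directory}")


def _read_tsv_lines(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_10x_mtx(directory: str | Path) -> ExpressionMatrix:
    """Read a matrix.mtx / features.tsv / barcodes.tsv triplet (gz allowed).

    features.tsv may carry 1–3 columns (id, optional name, optional type);
    the first column is the feature identifier. Duplicate identifiers are
    resolved by numeric suffixing with a warning.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")

    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(mtx_path)
    mat = sp.csr_matrix(mat)

    feats = _read_tsv_lines(feat_path)
    barcodes = _read_tsv_lines(bc_path)

    if len(feats) != mat.shape[0]:
        raise ValidationError(
            f"matrix declares {mat.shape[0]} features but features.tsv has "
            f"{len(feats)} lines"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValidationError(
            f"matrix declares {mat.shape[1]} observations but barcodes.tsv has "
            f"{len(barcodes)} lines"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("matrix.mtx contains negative entries")

    feature_ids = make_unique([str(v) for v in feats.iloc[:, 0]], "feature")
    obs_ids = make_unique([str(v) for v in barcodes.iloc[:, 0]], "barcode")

    feature_meta = None
    if feats.shape[1] >= 2:
        feature_meta = pd.DataFrame(index=pd.Index(feature_ids))
        feature_meta["name"] = feats.iloc[:, 1].values
        if feats.shape[1] >= 3:
            feature_meta["type"] = feats.iloc[:, 2].values

    return ExpressionMatrix(feature_ids, obs_ids, mat, feature_meta=feature_meta)


def write_10x_mtx(X: ExpressionMatrix, directory: str | Path) -> None:
    """Write the MTX triplet accepted by :func:`read_10x_mtx` (uncompressed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with atomic_path(directory / "matrix.mtx") as tmp:
        with open(tmp, "wb") as fh:
            scipy.io.mmwrite(fh, sp.coo_matrix(X.counts))

    cols = [pd.Series(X.feature_ids)]
    if X.feature_meta is not None:
        if "name" in X.feature_meta.columns:
            cols.append(X.feature_meta["name"].reset_index(drop=True))
            if "type" in X.feature_meta.columns:
                cols.append(X.feature_meta["type"].reset_index(drop=True))
    with atomic_path(directory / "features.tsv") as tmp:
        pd.concat(cols, axis=1).to_csv(tmp, sep="\t", header=False, index=False)
    with atomic_path(directory / "barcodes.tsv") as tmp:
        pd.Series(X.obs_ids).to_csv(tmp, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# dense CSV
# ---------------------------------------------------------------------------

def read_dense_csv(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a dense CSV: first column feature ids, header row observation ids.

    ``transpose=True`` accepts the opposite orientation (observations in
    rows). Non-numeric cells raise an error naming the offending row/column.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    for col in df.columns:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row_label = series.index[bad.argmax()]
            raise ValidationError(
                f"non-numeric cell at row {row_label!r}, column {col!r} in {path.name}"
            )
        df[col] = numeric
    if transpose:
        df = df.T
    values = df.to_numpy()
    if values.size and values.min() < 0:
        raise ValidationError(f"negative entries in {path.name}")
    if np.allclose(values, np.round(values)):
        values = values.astype(np.int64)
    feature_ids = make_unique([str(v) for v in df.index], "feature")
    obs_ids = make_unique([str(v) for v in df.columns], "observation")
    return ExpressionMatrix(feature_ids, obs_ids, sp.csr_matrix(values))


def write_dense_csv(X: ExpressionMatrix, path: str | Path) -> None:
    dense = X.counts.toarray()
    df = pd.DataFrame(dense, index=X.feature_ids, columns=X.obs_ids)
    with atomic_path(path) as tmp:
        df.to_csv(tmp)


# ---------------------------------------------------------------------------
# h5ad container
# ---------------------------------------------------------------------------

def read_h5ad(path: str | Path) -> ExpressionMatrix:
    import anndata as ad

    return ExpressionMatrix.from_anndata(ad.read_h5ad(path))


def write_h5ad(X: ExpressionMatrix, path: str | Path) -> None:
    with atomic_path(path) as tmp:
        X.to_anndata().write_h5ad(tmp)


# ---------------------------------------------------------------------------
# metadata and reports
# ---------------------------------------------------------------------------

def read_obs_meta(path: str | Path) -> pd.DataFrame:
    """Per-observation metadata TSV; first column is the observation id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_report_tsv(report, path: str | Path) -> None:
    """Write a conversion/QC report as a two-column (metric, value) TSV.

    Accepts a :class:`~orthomapper.qc.ConversionReport` (via ``.rows()``) or a
    plain mapping of metric → value.
    """
    rows = report.rows() if hasattr(report, "rows") else list(report.items())
    with atomic_path(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("metric\tvalue\n")
            for name, value in rows:
                fh.write(f"{name}\t{value}\n")


def write_per_observation_tsv(report, path: str | Path) -> None:
    """Per-observation efficiencies, one row per barcode; blanks for undefined."""
    eff = report.per_obs_efficiency
    with atomic_path(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("obs_id\tefficiency_percent\n")
            for obs_id, value in zip(report.obs_ids, eff):
                text = "" if np.isnan(value) else f"{value:.2f}"
                fh.write(f"{obs_id}\t{text}\n")


def load_matrix(path: str | Path, fmt: str = "auto", transpose: bool = False) -> ExpressionMatrix:
    """Dispatch on format: 10x MTX directory, dense CSV, or .h5ad file."""
    path = Path(path)
    if fmt == "auto":
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix == ".h5ad":
            fmt = "h5ad"
        else:
            fmt = "csv"
    if fmt == "mtx":
        return read_10x_mtx(path)
    if fmt == "csv":
        return read_dense_csv(path, transpose=transpose)
    if fmt == "h5ad":
        return read_h5ad(path)
    raise ValidationError(f"unknown matrix format: {fmt!r}")
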