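"""Matrix input/output and the preprocessing pathway.

Dense matrices travel as CSV/TSV with a header row of feature names; sparse
single-cell count matrices as MatrixMarket MTX (features x cells, the
convention of the common expression-matrix exports) with a features sidecar,
transposed on read to observations x features.  CSV output uses 17
significant digits so values round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sp_io

__all__ = ["Dataset", "read_matrix", "write_matrix", "preprocess"]


@dataclass
class Dataset:
    """An observations x features matrix with names and provenance."""

    values: np.ndarray
    feature_names: list[str]
    provenance: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    return {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(suffix, "csv")


def read_matrix(path, fmt: str | None = None, features_path=None) -> Dataset:
    """Read a data matrix.

    CSV/TSV: one observation per row, header row of feature names.
    MTX: features x cells plus a features sidecar (one name per line, or the
    first column of a TSV); transposed so rows are observations.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t",
                         float_precision="round_trip")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as e:
            raise ValueError(f"non-numeric cells in {path}") from e
        return Dataset(values, [str(c) for c in df.columns],
                       [f"read {fmt} {path.name} ({values.shape[0]}x{values.shape[1]})"])
    if fmt == "mtx":
        if features_path is None:
            cand = path.with_name("features.tsv")
            if not cand.exists():
                raise ValueError(
                    f"MTX input {path} needs a features sidecar (features_path or features.tsv)"
                )
            features_path = cand
        M = sp_io.mmread(str(path))
        M = np.asarray(M.todense() if hasattr(M, "todense") else M, dtype=float)
        names = [line.split("\t")[0].strip() for line in
                 Path(features_path).read_text().splitlines() if line.strip()]
        if len(names) != M.shape[0]:
            raise ValueError(
                f"features sidecar has {len(names)} names but matrix has {M.shape[0]} features"
            )
        return Dataset(M.T, names, [f"read mtx {path.name} (transposed to {M.shape[1]}x{M.shape[0]})"])
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(ds: Dataset, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in ("csv", "tsv"):
        raise ValueError("writing supports csv/tsv")
    df = pd.DataFrame(ds.values, columns=ds.feature_names)
    df.to_csv(path, sep="," if fmt == "csv" else "\t", index=False, float_format="%.17g")


def preprocess(
    ds: Dataset,
    *,
    library_size_normalize: bool = False,
    log1p: bool = False,
    standardize: bool = False,
    drop_constant: bool = False,
) -> Dataset:
    """Count-matrix preprocessing, applied in the standard order.

    1. per-row library-size normalization (rows scaled to the median row sum),
    2. log1p,
    3. per-column mean subtraction and unit-variance scaling.

    Standardizing a zero-variance column is an error unless ``drop_constant``
    removes such columns first.
    """
    X = np.asarray(ds.values, dtype=float).copy()
    names = list(ds.feature_names)
    prov = list(ds.provenance)
    if library_size_normalize:
        sums = X.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("library-size normalization needs positive row sums")
        X = X * (np.median(sums) / sums)[:, None]
        prov.append("library_size_normalize")
    if log1p:
        if np.any(X < 0):
            raise ValueError("log1p requires nonnegative values")
        X = np.log1p(X)
        prov.append("log1p")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            if not drop_constant:
                bad = [names[i] for i in zero]
                raise ValueError(f"zero-variance columns under standardize: {bad}")
            keep = np.flatnonzero(sd > 0)
            X = X[:, keep]
            names = [names[i] for i in keep]
            sd = sd[keep]
            prov.append(f"dropped {zero.size} constant columns")
        X = (X - X.mean(axis=0)) / sd
        prov.append("standardize")
    return Dataset(X, names, prov)
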