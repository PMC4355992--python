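"""Readers and writers for expression matrices and sample annotations.

Matrices travel as delimited text (TSV/CSV; first column probe id, header
row of sample ids) or as GCT 1.2 ("#1.2" line, dimensions line, then
Name/Description columns).  Sample annotations are TSV with ``sample_id``
and ``batch`` columns plus optional covariates.  Readers reject rather
than coerce: every error names the offending record.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import BatchDesign, ExpressionMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

DIALECTS = ("tsv", "csv", "gct")


def infer_dialect(path) -> str:
    suffix = Path(path).suffix.lower()
    return {".gct": "gct", ".csv": "csv"}.get(suffix, "tsv")


def _to_numeric(frame: pd.DataFrame, path) -> np.ndarray:
    try:
        values = frame.astype(np.float64)
    except (TypeError, ValueError):
        coerced = frame.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & frame.notna()
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {frame.iat[row, col]!r} at probe "
            f"{frame.index[row]!r}, sample {frame.columns[col]!r}"
        ) from None
    if values.isna().any().any():
        row, col = np.argwhere(values.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at probe {values.index[row]!r}, "
            f"sample {values.columns[col]!r}"
        )
    return values.to_numpy()


def _check_ids(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate {what}: {dups}")


def _check_header_duplicates(header_line: str, sep: str, path) -> None:
    # pandas silently mangles duplicate header fields, so check them raw
    fields = header_line.rstrip("\n").split(sep)[1:]
    index = pd.Index(fields)
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids: {dups}")


def read_matrix(path, dialect: Optional[str] = None) -> ExpressionMatrix:
    """Read and validate an expression matrix (dialect inferred from suffix)."""
    path = Path(path)
    dialect = dialect or infer_dialect(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if dialect == "gct":
        with open(path) as handle:
            version = handle.readline().strip()
            if version != "#1.2":
                raise ValidationError(
                    f"{path}: expected GCT version line '#1.2', got {version!r}"
                )
            dims = handle.readline().split()
            if len(dims) < 2:
                raise ValidationError(f"{path}: malformed GCT dimensions line")
            try:
                n_probes, n_samples = int(dims[0]), int(dims[1])
            except ValueError:
                raise ValidationError(
                    f"{path}: malformed GCT dimensions line {dims!r}"
                ) from None
            header_pos = handle.tell()
            _check_header_duplicates(handle.readline(), "\t", path)
            handle.seek(header_pos)
            body = pd.read_csv(handle, sep="\t", index_col=0, dtype={0: str})
        if body.shape[1] == 0 or body.columns[0] != "Description":
            raise ValidationError(
                f"{path}: GCT body must start with a Description column"
            )
        body = body.drop(columns="Description")
        if body.shape != (n_probes, n_samples):
            raise ValidationError(
                f"{path}: GCT header promises {n_probes} x {n_samples} but the "
                f"body is {body.shape[0]} x {body.shape[1]}"
            )
    else:
        sep = "," if dialect == "csv" else "\t"
        with open(path) as handle:
            _check_header_duplicates(handle.readline(), sep, path)
        body = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    if body.shape[0] == 0 or body.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    body.index = body.index.astype(str)
    _check_ids(body.index, "probe ids", path)
    _check_ids(pd.Index(body.columns), "sample ids", path)
    values = _to_numeric(body, path)
    return ExpressionMatrix(values, tuple(body.index), tuple(body.columns))


def write_matrix(
    Y: ExpressionMatrix,
    path,
    dialect: Optional[str] = None,
    digits: Optional[int] = 6,
) -> None:
    """Write a matrix; ``digits`` significant digits, or full precision if None."""
    if Y.n_probes == 0:
        raise ValidationError("refusing to write an empty matrix")
    path = Path(path)
    dialect = dialect or infer_dialect(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    fmt = None if digits is None else f"%.{int(digits)}g"
    frame = Y.to_frame()
    try:
        if dialect == "gct":
            with open(path, "w") as handle:
                handle.write("#1.2\n")
                handle.write(f"{Y.n_probes}\t{Y.n_samples}\n")
                out = frame.copy()
                out.insert(0, "Description", list(Y.probe_ids))
                out.index.name = "Name"
                out.to_csv(handle, sep="\t", float_format=fmt)
        else:
            sep = "," if dialect == "csv" else "\t"
            frame.to_csv(path, sep=sep, float_format=fmt)
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc


def expand_covariates(
    annot: pd.DataFrame, covariate_names: Sequence[str]
) -> pd.DataFrame:
    """Build the numeric covariate frame; categoricals become indicators.

    The reference level of a categorical covariate is the first by lexical
    order (dropped from the indicators and logged).
    """
    pieces = []
    for name in covariate_names:
        if name not in annot.columns:
            raise ValidationError(f"covariate column {name!r} not in annotation")
        col = annot[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            pieces.append(numeric.astype(float).rename(name))
        else:
            levels = sorted(col.astype(str).unique())
            logger.info(
                "covariate %r treated as categorical; reference level %r",
                name, levels[0],
            )
            for level in levels[1:]:
                pieces.append(
                    (col.astype(str) == level).astype(float).rename(f"{name}[{level}]")
                )
    return pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=annot.index)


def read_design(
    path,
    sample_ids: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
    covariates: Optional[Sequence[str]] = None,
) -> BatchDesign:
    """Read a sample annotation table into a validated BatchDesign.

    Requires columns ``sample_id`` and ``batch``.  When ``sample_ids`` is
    given (the matrix column order), the design is aligned to it and any
    mismatch in either direction is an error listing the ids.
    """
    path = Path(path)
    sep = "," if infer_dialect(path) == "csv" else "\t"
    annot = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "batch"):
        if col not in annot.columns:
            raise ValidationError(f"{path}: annotation needs a {col!r} column")
    annot["sample_id"] = annot["sample_id"].astype(str)
    _check_ids(pd.Index(annot["sample_id"]), "sample ids", path)
    annot = annot.set_index("sample_id", drop=False)

    if sample_ids is not None:
        sample_ids = [str(s) for s in sample_ids]
        only_design = sorted(set(annot.index) - set(sample_ids))
        only_matrix = sorted(set(sample_ids) - set(annot.index))
        if only_design or only_matrix:
            raise ValidationError(
                f"{path}: sample mismatch; matrix-only: {only_matrix}, "
                f"design-only: {only_design}"
            )
        annot = annot.loc[sample_ids]
    else:
        sample_ids = list(annot.index)

    cov = None
    if covariates:
        cov = expand_covariates(annot, covariates)
    return BatchDesign(
        tuple(sample_ids),
        tuple(annot["batch"].astype(str)),
        reference=reference,
        covariates=cov,
    )


def write_design(design: BatchDesign, path) -> None:
    frame = pd.DataFrame(
        {"sample_id": design.sample_ids, "batch": design.batch_labels_per_sample}
    )
    if design.covariates is not None:
        frame = pd.concat([frame, design.covariates.reset_index(drop=True)], axis=1)
    frame.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a CLI run; round-trips through JSON."""

    command: str
    matrix_path: Optional[str] = None
    design_path: Optional[str] = None
    out_path: Optional[str] = None
    mode: str = "combat"
    reference: Optional[str] = None
    covariates: tuple = ()
    tol: float = 1e-4
    max_iter: int = 5000
    zero_variance: str = "passthrough"
    qvalue_threshold: float = 0.01
    pca_top: int = 5000
    pca_components: int = 2
    signature_path: Optional[str] = None
    seed: Optional[int] = None

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["covariates"] = list(self.covariates)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, Path):
            data = json.loads(source.read_text())
        else:
            data = json.loads(source)
        data["covariates"] = tuple(data.get("covariates", ()))
        return cls(**data)
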