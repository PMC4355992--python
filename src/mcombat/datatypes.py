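"""Data containers for batch-effect adjustment.

Expression values are log2-scale intensities laid out probes x samples (the
orientation of microarray probe tables).  Containers validate eagerly on
construction and are treated as immutable; every operation returns a new
object rather than mutating in place.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Variances below this (log2 scale) are treated as numerically zero.
VAR_EPS = 1e-12


def _as_id_tuple(ids: Sequence, what: str) -> tuple:
    ids = tuple(str(x) for x in ids)
    index = pd.Index(ids)
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated probes x samples matrix of log2 expression values."""

    values: np.ndarray
    probe_ids: tuple
    sample_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError(
                f"expression values must be 2-D, got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "probe_ids", _as_id_tuple(self.probe_ids, "probe ids")
        )
        object.__setattr__(
            self, "sample_ids", _as_id_tuple(self.sample_ids, "sample ids")
        )
        g, n = values.shape
        if g < 1:
            raise ValidationError("expression matrix needs at least one probe")
        if n < 2:
            raise ValidationError("expression matrix needs at least two samples")
        if len(self.probe_ids) != g or len(self.sample_ids) != n:
            raise ValidationError(
                f"id lengths ({len(self.probe_ids)} probes, "
                f"{len(self.sample_ids)} samples) do not match matrix shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            probe, sample = bad[0]
            raise ValidationError(
                f"non-finite expression value at probe "
                f"{self.probe_ids[probe]!r}, sample {self.sample_ids[sample]!r} "
                f"({bad.shape[0]} offending cells in total)"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=np.float64), tuple(frame.index), tuple(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=list(self.sample_ids),
        )

    def subset_probes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        ids = tuple(p for p, keep in zip(self.probe_ids, mask) if keep)
        return ExpressionMatrix(self.values[mask], ids, self.sample_ids)


@dataclass(frozen=True)
class BatchDesign:
    """Sample-to-batch assignment plus optional covariates.

    Batch labels are ordered by first appearance in ``sample_ids``.  The
    optional ``reference`` names the gold-standard batch that M-ComBat
    anchors to.  ``covariates`` is an N x p numeric frame aligned to
    ``sample_ids``; jointly with the batch indicators it must form a
    full-rank design (a covariate confounded with batch is not estimable).
    """

    sample_ids: tuple
    batch_labels_per_sample: tuple
    reference: Optional[str] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        object.__setattr__(
            self, "sample_ids", _as_id_tuple(self.sample_ids, "sample ids")
        )
        labels = tuple(str(b) for b in self.batch_labels_per_sample)
        object.__setattr__(self, "batch_labels_per_sample", labels)
        if len(labels) != len(self.sample_ids):
            raise ValidationError(
                "batch labels and sample ids have different lengths"
            )
        sizes = self.batch_sizes
        small = [b for b, n in sizes.items() if n < 2]
        if small:
            raise ValidationError(
                f"every batch needs at least 2 samples; too small: {small}"
            )
        if self.reference is not None:
            ref = str(self.reference)
            object.__setattr__(self, "reference", ref)
            if ref not in sizes:
                raise ValidationError(
                    f"reference batch {ref!r} is not among batches {list(sizes)}"
                )
        if self.covariates is not None:
            cov = self.covariates
            if list(cov.index.astype(str)) != list(self.sample_ids):
                cov = cov.reindex(list(self.sample_ids))
            if cov.isna().any().any():
                missing = cov.index[cov.isna().any(axis=1)].tolist()
                raise ValidationError(
                    f"covariates missing for samples: {missing}"
                )
            try:
                arr = cov.to_numpy(dtype=np.float64)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"covariate columns must be numeric: {exc}"
                ) from exc
            object.__setattr__(self, "covariates", cov)
            self._check_full_rank(arr, list(cov.columns))

    def _check_full_rank(self, cov: np.ndarray, names: list) -> None:
        B = self.indicator_matrix()
        k = B.shape[1]
        full = np.hstack([B, cov])
        if np.linalg.matrix_rank(full) == k + cov.shape[1]:
            return
        confounded = []
        for j, name in enumerate(names):
            if np.linalg.matrix_rank(np.hstack([B, cov[:, [j]]])) == k:
                confounded.append(name)
        detail = (
            f"covariates confounded with batch: {confounded}"
            if confounded
            else f"covariate columns are jointly collinear with the batch design: {names}"
        )
        raise ValidationError(f"design matrix is rank deficient; {detail}")

    @classmethod
    def from_mapping(
        cls,
        batch_of: Mapping,
        sample_ids: Sequence,
        reference=None,
        covariates: Optional[pd.DataFrame] = None,
    ) -> "BatchDesign":
        sample_ids = [str(s) for s in sample_ids]
        batch_of = {str(k): str(v) for k, v in batch_of.items()}
        missing = [s for s in sample_ids if s not in batch_of]
        if missing:
            raise ValidationError(f"samples missing from batch mapping: {missing}")
        labels = tuple(batch_of[s] for s in sample_ids)
        return cls(tuple(sample_ids), labels, reference, covariates)

    @property
    def batch_of(self) -> dict:
        return dict(zip(self.sample_ids, self.batch_labels_per_sample))

    @property
    def batch_labels(self) -> tuple:
        """Unique batch labels in order of first appearance."""
        return tuple(dict.fromkeys(self.batch_labels_per_sample))

    @property
    def batch_sizes(self) -> dict:
        sizes: dict = {}
        for b in self.batch_labels_per_sample:
            sizes[b] = sizes.get(b, 0) + 1
        return sizes

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_batches(self) -> int:
        return len(self.batch_labels)

    def batch_indices(self) -> dict:
        """Map batch label -> integer sample positions, in batch-label order."""
        labels = np.asarray(self.batch_labels_per_sample)
        return {b: np.flatnonzero(labels == b) for b in self.batch_labels}

    def indicator_matrix(self) -> np.ndarray:
        """N x k one-hot batch membership, columns in batch-label order."""
        n = self.n_samples
        out = np.zeros((n, self.n_batches))
        for j, (_, idx) in enumerate(self.batch_indices().items()):
            out[idx, j] = 1.0
        return out

    def covariate_matrix(self) -> Optional[np.ndarray]:
        if self.covariates is None:
            return None
        return self.covariates.to_numpy(dtype=np.float64)

    def model_matrix(self) -> np.ndarray:
        """[batch indicators | covariates], the OLS design for gene-wise fits."""
        B = self.indicator_matrix()
        X = self.covariate_matrix()
        return B if X is None else np.hstack([B, X])

    def with_reference(self, reference) -> "BatchDesign":
        return replace(self, reference=str(reference))

    def check_samples(self, matrix: ExpressionMatrix) -> None:
        if tuple(matrix.sample_ids) != tuple(self.sample_ids):
            only_m = sorted(set(matrix.sample_ids) - set(self.sample_ids))
            only_d = sorted(set(self.sample_ids) - set(matrix.sample_ids))
            if only_m or only_d:
                raise ValidationError(
                    f"sample mismatch between matrix and design; "
                    f"matrix-only: {only_m}, design-only: {only_d}"
                )
            raise ValidationError(
                "matrix and design list the same samples in different order"
            )


@dataclass(frozen=True)
class GeneModelFit:
    """Gene-wise location/scale estimates used for standardization.

    ``mode='pooled'`` carries the batch-size-weighted grand intercept
    alpha_pooled and the pooled residual scale sigma_pooled (classic
    ComBat anchors).  ``mode='batchwise'`` carries per-batch intercepts and
    scales (M-ComBat anchors).  ``beta`` holds covariate coefficients from
    the pooled joint fit and is shared by both modes.
    """

    mode: str
    probe_ids: tuple
    batch_labels: tuple
    beta: Optional[np.ndarray] = None           # (p, G)
    covariate_names: tuple = ()
    alpha_pooled: Optional[np.ndarray] = None   # (G,)
    sigma_pooled: Optional[np.ndarray] = None   # (G,)
    alpha_batch: Optional[np.ndarray] = None    # (B, G)
    sigma_batch: Optional[np.ndarray] = None    # (B, G)

    def __post_init__(self):
        if self.mode not in ("pooled", "batchwise"):
            raise ValidationError(f"unknown fit mode {self.mode!r}")
        if self.mode == "pooled":
            if self.alpha_pooled is None or self.sigma_pooled is None:
                raise ValidationError("pooled fit requires alpha_pooled and sigma_pooled")
            if np.any(self.sigma_pooled <= 0):
                raise ValidationError("pooled scales must be strictly positive")
        else:
            if self.alpha_batch is None or self.sigma_batch is None:
                raise ValidationError("batchwise fit requires alpha_batch and sigma_batch")
            if np.any(self.sigma_batch <= 0):
                raise ValidationError("batch-wise scales must be strictly positive")


@dataclass(frozen=True)
class StandardizedMatrix:
    """Dimensionless standardized expression Z with its provenance fit."""

    values: np.ndarray
    probe_ids: tuple
    sample_ids: tuple
    fit: GeneModelFit

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("standardized matrix contains non-finite values")


@dataclass(frozen=True)
class EBEstimates:
    """Naive batch-effect moments, prior hyperparameters, and EB posteriors.

    All per-gene arrays are (B, G) in ``batch_labels`` order.  The
    ``*_degenerate`` flags record batches where the cross-gene moments
    collapse (e.g. batch-wise standardization with no covariates), in which
    case shrinkage is bypassed: gamma_star == gamma_bar for a
    location-degenerate batch and delta2_star == delta2_hat for a
    scale-degenerate one, exactly.
    """

    batch_labels: tuple
    probe_ids: tuple
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    delta2_zero: np.ndarray = field(default=None)  # (B, G) bool
    gamma_bar: Optional[np.ndarray] = None         # (B,)
    tau2_bar: Optional[np.ndarray] = None
    lambda_bar: Optional[np.ndarray] = None
    theta_bar: Optional[np.ndarray] = None
    location_degenerate: Optional[np.ndarray] = None
    scale_degenerate: Optional[np.ndarray] = None
    gamma_star: Optional[np.ndarray] = None        # (B, G)
    delta2_star: Optional[np.ndarray] = None
    n_iterations: Optional[np.ndarray] = None      # (B,)

    def __post_init__(self):
        if self.delta2_zero is None:
            object.__setattr__(
                self, "delta2_zero", self.delta2_hat <= VAR_EPS
            )

    @property
    def has_hyperparameters(self) -> bool:
        return self.gamma_bar is not None

    @property
    def has_posteriors(self) -> bool:
        return self.gamma_star is not None
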