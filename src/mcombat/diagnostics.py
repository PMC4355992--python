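"""Evaluation battery for batch adjustment.

Probe-wise one-way ANOVA on batch label with q-value FDR control, PCA on
the most variable probes, and generic up/down gene-signature risk scoring.
These are the checks a practitioner runs before and after adjustment to
confirm that batch-driven differences are gone while the anchoring batch
kept its location.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .datatypes import BatchDesign, ExpressionMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Grid for the pi0 smoother, lambda in {0, 0.05, ..., 0.90}.
PI0_LAMBDA_GRID = np.arange(0.0, 0.9001, 0.05)


@dataclass(frozen=True)
class ProbeTestResult:
    """Per-probe one-way ANOVA results, optionally completed with q-values.

    ``flag`` is '' for a regular probe, 'zero_within' when all within-batch
    variance vanished while batch means differ (p forced to 0) and
    'constant' when the probe is constant everywhere (p forced to 1).
    """

    probe_ids: tuple
    f_statistic: np.ndarray
    df_between: int
    df_within: int
    p_values: np.ndarray
    flag: np.ndarray
    q_values: Optional[np.ndarray] = None
    pi0: Optional[float] = None

    def with_qvalues(self, pi0: Optional[float] = None) -> "ProbeTestResult":
        q, pi0 = estimate_qvalues(self.p_values, pi0=pi0)
        return replace(self, q_values=q, pi0=pi0)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "F": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_values,
            "flag": self.flag,
        }
        if self.q_values is not None:
            data["q_value"] = self.q_values
        return pd.DataFrame(data, index=pd.Index(self.probe_ids, name="probe_id"))


def probe_anova(Y: ExpressionMatrix, design: BatchDesign) -> ProbeTestResult:
    """One-way fixed-effects ANOVA of every probe on batch label.

    F = (SSB/(k-1)) / (SSW/(N-k)) with p from the F(k-1, N-k) distribution.
    Degenerate probes are flagged instead of producing NaNs: zero within-
    batch variance with real between-batch spread gives p = 0, a fully
    constant probe gives p = 1.
    """
    design.check_samples(Y)
    k = design.n_batches
    if k < 2:
        raise ValidationError("ANOVA needs at least 2 batches")
    n = design.n_samples
    values = Y.values
    grand = values.mean(axis=1)
    ssb = np.zeros(Y.n_probes)
    ssw = np.zeros(Y.n_probes)
    for label, idx in design.batch_indices().items():
        block = values[:, idx]
        m = block.mean(axis=1)
        ssb += idx.size * (m - grand) ** 2
        ssw += ((block - m[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n - k

    # Floating-point floor: a probe constant within every batch never sums
    # its deviations to exactly 0.0, so compare against a scale-aware tiny.
    tiny = 1e-18 * n * (1.0 + grand**2)
    zero_w = ssw <= tiny
    zero_b = ssb <= tiny
    flag = np.full(Y.n_probes, "", dtype=object)
    flag[zero_w & ~zero_b] = "zero_within"
    flag[zero_w & zero_b] = "constant"

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    F[zero_w & ~zero_b] = np.inf
    p[zero_w & ~zero_b] = 0.0
    F[zero_w & zero_b] = 0.0
    p[zero_w & zero_b] = 1.0
    return ProbeTestResult(
        probe_ids=Y.probe_ids,
        f_statistic=F,
        df_between=dfb,
        df_within=dfw,
        p_values=p,
        flag=flag,
    )


def estimate_pi0(
    p_values: Sequence[float], lambdas: np.ndarray = PI0_LAMBDA_GRID
) -> float:
    """Null-proportion estimate by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the lambda grid, then
    a natural cubic smoothing spline is evaluated at the largest lambda and
    clipped to (0, 1].  Fewer than 100 p-values make the smoother unstable;
    pi0 is then fixed to 1 with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m < 100:
        warnings.warn(
            f"only {m} p-values; pi0 smoother is unstable, using pi0 = 1",
            stacklevel=2,
        )
        return 1.0
    pi0_at = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = interpolate.make_smoothing_spline(lambdas, pi0_at)
    pi0 = float(spline(lambdas[-1]))
    return float(np.clip(pi0, 1e-8, 1.0))


def estimate_qvalues(
    p_values: Sequence[float], *, pi0: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """q-values: q_i = pi0 * min_{p_j >= p_i} m p_j / rank_j, capped at 1.

    With pi0 = 1 this is exactly the Benjamini-Hochberg step-up adjustment.
    Returns (q, pi0).
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValidationError(f"pi0 must lie in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = pi0 * (p[order] / (ranks / m))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def count_significant(q_values: Sequence[float], threshold: float) -> int:
    """Number of probes with q < threshold (strict)."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return int((np.asarray(q_values, dtype=float) < threshold).sum())


def _check_pvalues(p: np.ndarray) -> None:
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class PCAResult:
    """PCA of the top-k most variable probes (centered, unscaled)."""

    probe_ids: tuple                      # k selected probes, variance order
    scores: pd.DataFrame                  # N x c, columns PC1..PCc
    explained_variance_ratio: np.ndarray  # (c,) fractions of total variance
    components: np.ndarray                # (c, k) right singular vectors
    center: np.ndarray                    # (k,) per-probe means removed

    def batch_centroids(self, design: BatchDesign) -> pd.DataFrame:
        rows = {}
        for label, idx in design.batch_indices().items():
            rows[label] = self.scores.iloc[idx].mean(axis=0)
        return pd.DataFrame(rows).T


def top_variable_pca(Y: ExpressionMatrix, k: int, c: int = 2) -> PCAResult:
    """PCA on the k probes with largest cross-sample variance.

    Ties in the variance ranking are broken by input probe order (stable
    sort).  Probes are centered but not scaled; components come from the
    SVD of the centered samples x probes submatrix and are ordered by
    decreasing explained variance.
    """
    if k > Y.n_probes:
        raise ValidationError(f"k={k} exceeds the {Y.n_probes} available probes")
    if k < 1:
        raise ValidationError("k must be at least 1")
    c_max = min(k, Y.n_samples)
    if c > c_max:
        raise ValidationError(f"c={c} exceeds min(k, N) = {c_max}")
    var = Y.values.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:k]
    if k < Y.n_probes and var[order[-1]] == var[np.argsort(-var, kind="stable")[k]]:
        logger.info("variance tie at the top-%d boundary broken by probe order", k)
    sel = Y.values[order]                      # (k, N)
    center = sel.mean(axis=1)
    Xc = (sel - center[:, None]).T             # (N, k)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    scores = U[:, :c] * S[:c]
    ratio = (S[:c] ** 2) / total if total > 0 else np.zeros(c)
    frame = pd.DataFrame(
        scores,
        index=list(Y.sample_ids),
        columns=[f"PC{i + 1}" for i in range(c)],
    )
    return PCAResult(
        probe_ids=tuple(Y.probe_ids[i] for i in order),
        scores=frame,
        explained_variance_ratio=ratio,
        components=Vt[:c],
        center=center,
    )


@dataclass(frozen=True)
class SignatureDefinition:
    """A fixed risk signature: up/down probe lists and a published cutoff.

    Scores are mean(up) - mean(down) per sample in log2 units; high risk is
    a score strictly above ``cutoff``.  The actual probe lists of published
    signatures (e.g. GEP70-style scores) are supplied by the user.
    """

    name: str
    up_probes: tuple
    down_probes: tuple
    cutoff: float = 0.0

    def __post_init__(self):
        up = tuple(str(p) for p in self.up_probes)
        down = tuple(str(p) for p in self.down_probes)
        object.__setattr__(self, "up_probes", up)
        object.__setattr__(self, "down_probes", down)
        if not up and not down:
            raise ValidationError("signature needs at least one probe")
        overlap = set(up) & set(down)
        if overlap:
            raise ValidationError(
                f"signature up/down lists overlap: {sorted(overlap)}"
            )


def signature_score(Y: ExpressionMatrix, sig: SignatureDefinition) -> pd.Series:
    """Per-sample score: mean over up-probes minus mean over down-probes.

    An empty side contributes 0.  All signature probes must be present.
    """
    index = {p: i for i, p in enumerate(Y.probe_ids)}
    missing = [p for p in (*sig.up_probes, *sig.down_probes) if p not in index]
    if missing:
        raise ValidationError(f"signature probes missing from matrix: {missing}")
    up = (
        Y.values[[index[p] for p in sig.up_probes]].mean(axis=0)
        if sig.up_probes
        else 0.0
    )
    down = (
        Y.values[[index[p] for p in sig.down_probes]].mean(axis=0)
        if sig.down_probes
        else 0.0
    )
    return pd.Series(up - down, index=list(Y.sample_ids), name=sig.name)


def high_risk_proportion(scores: Sequence[float], cutoff: float) -> float:
    """Fraction of samples whose score strictly exceeds the cutoff."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValidationError("no scores given")
    return float((s > cutoff).mean())
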