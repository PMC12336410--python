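"""Normalization and covariate correction of exon/intron count matrices.

Exonic and intronic counts are processed independently end to end: TMM
library-composition factors, log2 CPM with a prior count, TPM-based
expressed-gene filtering (exonic TPM only, gene set applied to both
matrices), and least-squares residualization of nuisance covariates with
the diagnosis contrast protected.

Matrices are pandas DataFrames with genes as rows and samples as columns —
the bulk RNA-seq convention.  The sklearn-style transformers
(:class:`TMMLogCPM`, :class:`CovariateResidualizer`) follow the sklearn
orientation (samples × genes) so they compose with pipelines; the
module-level functions keep the genes × samples orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

LOG_CPM_PRIOR = 0.5  # edgeR-convention prior count for log2 CPM


@dataclass
class CountMatrix:
    """Integer gene × sample counts tagged exonic or intronic."""

    counts: pd.DataFrame  # genes × samples, non-negative integers
    feature_class: str  # "exonic" | "intronic"
    lengths: pd.Series | None = None  # per-gene composite-exon bases

    def __post_init__(self) -> None:
        if self.feature_class not in ("exonic", "intronic"):
            raise ValueError(f"feature_class must be exonic/intronic, got "
                             f"{self.feature_class!r}")
        if (self.counts.values < 0).any():
            raise ValueError("counts contain negative entries")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("gene or sample ids are not unique")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths <= 0).any() or self.lengths.isna().any():
                raise ValueError("feature lengths must be positive for all genes")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Real-valued gene × sample matrix on the log2 CPM scale."""

    values: pd.DataFrame
    normalized: bool = False
    residualized: bool = False
    tmm_factors: pd.Series | None = None
    covariates_removed: list[str] = field(default_factory=list)


def tpm(c: CountMatrix) -> pd.DataFrame:
    """Transcripts per million from exonic counts and composite-exon lengths.

    TPM_g = (count_g / length_g) / sum_h(count_h / length_h) * 1e6, per
    sample; columns with any signal sum to 1e6 exactly.
    """
    if c.feature_class != "exonic":
        raise ValueError("TPM is defined on the exonic count matrix")
    if c.lengths is None:
        raise ValueError("TPM requires per-gene feature lengths")
    rate = c.counts.div(c.lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        logger.warning("all-zero sample columns in TPM: %s",
                       list(denom.index[zero_cols]))
        denom = denom.replace(0, np.nan)
    out = rate.div(denom, axis=1) * 1e6
    return out.fillna(0.0)


def filter_expressed(
    tpm_matrix: pd.DataFrame, threshold: float = 1.0, fraction: float = 0.5
) -> pd.Index:
    """Genes with TPM strictly above ``threshold`` in >= ``fraction`` of samples."""
    frac_above = (tpm_matrix > threshold).mean(axis=1)
    return tpm_matrix.index[frac_above >= fraction]


def _uq_reference(counts: np.ndarray, libsize: np.ndarray) -> int:
    """Index of the sample whose upper-quartile CPM is closest to the mean."""
    uq = np.array([
        np.quantile(counts[:, j] / libsize[j], 0.75) for j in range(counts.shape[1])
    ])
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    log_ratio_trim: float = 0.30, abs_expr_trim: float = 0.05,
) -> float:
    """Trimmed, precision-weighted mean of M-values of one sample vs the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M; weights are its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e9)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_expr_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = scipy_stats.rankdata(m)  # average ranks: ties from equal counts
    rank_a = scipy_stats.rankdata(a)
    keep2 = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep2.any() or np.sum(1.0 / v[keep2]) == 0:
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2.0 ** f)


def tmm_factors(c: CountMatrix) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: upper-quartile CPM closest to the mean upper quartile.
    Per sample, the factor is the precision-weighted mean of M-values after
    trimming the most extreme 30% of M and 5% of A; factors are rescaled to
    geometric mean 1.
    """
    counts = c.counts.values
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    libsize = counts.sum(axis=0).astype(float)
    zero = libsize == 0
    if zero.any():
        raise ValueError(
            f"sample(s) with all-zero counts: {list(c.counts.columns[zero])}"
        )
    ref_idx = _uq_reference(counts, libsize)
    ref = counts[:, ref_idx]
    factors = np.array([
        _tmm_pair(counts[:, j], ref, libsize[j], libsize[ref_idx])
        for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=c.counts.columns, name="tmm_factor")


def log2_cpm(
    c: CountMatrix, factors: pd.Series | None = None, prior: float = LOG_CPM_PRIOR
) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-adjusted library sizes.

    log2((count + prior) / (libsize * factor + 2 * prior) * 1e6); the prior
    keeps zero counts finite.
    """
    libsize = c.library_sizes.astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=c.counts.columns)
    eff = libsize * factors.reindex(c.counts.columns)
    vals = np.log2((c.counts + prior).div(eff + 2 * prior, axis=1) * 1e6)
    return ExpressionMatrix(values=vals, normalized=True, tmm_factors=factors)


class TMMLogCPM(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: raw counts to TMM-normalized log2 CPM.

    Follows the sklearn orientation: X is samples × genes.  ``fit`` learns
    per-sample TMM factors (so it must be called on the same samples that
    are transformed, as normalization is per-library, not per-cohort).
    """

    def __init__(self, prior: float = LOG_CPM_PRIOR):
        self.prior = prior

    def fit(self, X, y=None):
        df = pd.DataFrame(X)
        cm = CountMatrix(counts=df.T, feature_class="exonic",
                         lengths=pd.Series(1.0, index=df.columns))
        self.factors_ = tmm_factors(cm)
        self.library_sizes_ = cm.library_sizes
        return self

    def transform(self, X):
        df = pd.DataFrame(X)
        cm = CountMatrix(counts=df.T, feature_class="exonic")
        em = log2_cpm(cm, self.factors_, prior=self.prior)
        return em.values.T.values


def build_design(
    samples: pd.DataFrame,
    covariates: list[str],
    protect: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-hot design matrix with an intercept; returns (X, nuisance_mask, names).

    Categorical covariates are dummy-coded against a reference level.
    ``protect`` columns (default: diagnosis) contribute to the fit but are
    retained in the residualized output; the intercept is always protected.
    Exactly collinear nuisance columns are dropped with a warning; a design
    that stays rank-deficient raises naming the aliased covariates.
    """
    protect = list(protect or ["diagnosis"])
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names: list[str] = ["intercept"]
    nuisance: list[bool] = [False]
    for cov in protect + [c for c in covariates if c not in protect]:
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} not in sample table")
        col = samples[cov]
        is_protected = cov in protect
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
            nuisance.append(not is_protected)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
                nuisance.append(not is_protected)
    X = np.column_stack(cols)

    # prune aliased columns (keep earlier = protected-first ordering)
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        protected_dropped = [names[j] for j in range(X.shape[1])
                             if names[j] in dropped and not nuisance[j]]
        if protected_dropped:
            raise ValueError(
                f"design rank-deficient: protected columns aliased: {protected_dropped}"
            )
        logger.warning("dropping aliased nuisance columns: %s", dropped)
    X = X[:, keep]
    return X, np.array([nuisance[j] for j in keep]), [names[j] for j in keep]


def residualize(
    e: ExpressionMatrix,
    samples: pd.DataFrame,
    covariates: list[str],
    protect: list[str] | None = None,
) -> ExpressionMatrix:
    """Regress nuisance covariates out of every gene, keeping protected terms.

    Per gene, fits value ~ intercept + protected + nuisance by least squares
    and subtracts only the nuisance contribution, so diagnosis group
    differences survive.  Idempotent.
    """
    vals = e.values
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns \
        else samples
    samples = samples.loc[vals.columns]
    X, nuis_mask, names = build_design(samples, covariates, protect)
    Y = vals.values.T  # samples × genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    nuisance_fit = X[:, nuis_mask] @ beta[nuis_mask, :]
    resid = pd.DataFrame((Y - nuisance_fit).T, index=vals.index,
                         columns=vals.columns)
    removed = [n for n, m in zip(names, nuis_mask) if m]
    return ExpressionMatrix(values=resid, normalized=e.normalized,
                            residualized=True, tmm_factors=e.tmm_factors,
                            covariates_removed=removed)


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer removing nuisance covariate effects.

    X is samples × genes; the sample table and covariate lists are estimator
    parameters.  ``fit`` stores the nuisance coefficients; ``transform``
    subtracts the fitted nuisance contribution.
    """

    def __init__(self, samples: pd.DataFrame | None = None,
                 covariates: list[str] | None = None,
                 protect: list[str] | None = None):
        self.samples = samples
        self.covariates = covariates
        self.protect = protect

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        design, nuis_mask, names = build_design(
            self.samples, self.covariates or [], self.protect
        )
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        self.design_ = design
        self.nuisance_mask_ = nuis_mask
        self.column_names_ = names
        self.coef_ = beta
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X - self.design_[:, self.nuisance_mask_] @ \
            self.coef_[self.nuisance_mask_, :]


def prepare_expression(
    exon: CountMatrix,
    intron: CountMatrix,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    protect: list[str] | None = None,
    tpm_threshold: float = 1.0,
    tpm_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Index]:
    """Full counts-prep pipeline on the exon/intron pair.

    Filters genes on exonic TPM, applies the surviving set to both matrices,
    then TMM + log2 CPM + residualization independently per matrix.
    """
    keep = exon.counts.index
    if exon.lengths is not None:
        keep = filter_expressed(tpm(exon), tpm_threshold, tpm_fraction)
    keep = keep.intersection(intron.counts.index)
    out = []
    for cm in (exon, intron):
        sub = CountMatrix(
            counts=cm.counts.loc[keep],
            feature_class=cm.feature_class,
            lengths=None if cm.lengths is None else cm.lengths.loc[keep],
        )
        em = log2_cpm(sub, tmm_factors(sub))
        if covariates:
            em = residualize(em, samples, covariates, protect)
        out.append(em)
    return out[0], out[1], keep
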