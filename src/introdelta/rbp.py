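"""Candidate driver RBP/miRNA inference from 3'UTR binding vectors.

Per-gene ΔPTGR (mRNA stability change) is regressed on the genes x motifs
binding-affinity matrix in one joint OLS fit; regulators whose coefficient
is significant at raw p < alpha are the candidate drivers.  Binding-site
*presence* (boolean) defines each regulator's predicted target genes and
the mean ΔPTGR over those targets summarizes the predicted direction of the
stability effect.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class RegulatorRegression(BaseEstimator, RegressorMixin):
    """OLS of per-gene stability change on standardized motif affinities.

    sklearn-shaped: ``fit(X, y)`` with X the genes x motifs affinity matrix
    (DataFrame or array) and y the per-gene ΔPTGR.  Predictors are
    standardized (mean 0, sd 1); zero-variance and exactly collinear columns
    are dropped with a warning.  Inference is the per-coefficient t-test of
    the joint fit; raw p-values are thresholded (a BH column is emitted for
    information only, mirroring common practice of reporting raw p here).

    Attributes
    ----------
    results_ : pd.DataFrame
        motif_id, beta, se, t, p, p_bh, selected.
    dropped_ : list[str]
        Constant or aliased predictor columns excluded from the fit.
    """

    def __init__(self, alpha: float = 0.05, marginal: bool = False):
        self.alpha = alpha
        self.marginal = marginal

    def fit(self, X, y):
        Xdf = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if Xdf.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of genes")
        if not self.marginal and Xdf.shape[1] >= Xdf.shape[0] - 1:
            raise ValueError(
                "more motifs than genes support: cluster PFMs first or use "
                "marginal=True"
            )
        sd = Xdf.std(axis=0, ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()]
        if len(constant):
            logger.warning("dropping zero-variance predictors: %s",
                           list(constant))
        Xz = Xdf.drop(columns=constant)
        Xz = (Xz - Xz.mean(axis=0)) / Xz.std(axis=0, ddof=1)

        dropped = list(constant)
        if not self.marginal:
            # prune exactly collinear columns, earliest kept
            keep: list[str] = []
            arr = np.ones((len(y), 1))
            for col in Xz.columns:
                trial = np.column_stack([arr, Xz[col].values])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    arr = trial
                    keep.append(col)
                else:
                    dropped.append(col)
            if len(dropped) > len(constant):
                logger.warning("dropping aliased predictors: %s",
                               dropped[len(constant):])
            Xz = Xz[keep]
            model = sm.OLS(y, sm.add_constant(Xz.values)).fit()
            rows = [
                {"motif_id": col, "beta": model.params[j + 1],
                 "se": model.bse[j + 1], "t": model.tvalues[j + 1],
                 "p": model.pvalues[j + 1]}
                for j, col in enumerate(Xz.columns)
            ]
        else:
            rows = []
            for col in Xz.columns:
                m = sm.OLS(y, sm.add_constant(Xz[col].values)).fit()
                rows.append({"motif_id": col, "beta": m.params[1],
                             "se": m.bse[1], "t": m.tvalues[1],
                             "p": m.pvalues[1]})

        res = pd.DataFrame(rows)
        if len(res):
            res["p_bh"] = multipletests(res["p"].values, method="fdr_bh")[1]
            res["selected"] = res["p"] < self.alpha
        self.results_ = res
        self.dropped_ = dropped
        self.n_genes_ = len(y)
        self._mean_ = Xdf.drop(columns=constant).mean(axis=0)
        self._sd_ = Xdf.drop(columns=constant).std(axis=0, ddof=1)
        self._intercept_ = float(np.mean(y))
        return self

    def predict(self, X):
        Xdf = pd.DataFrame(X)
        z = (Xdf[self.results_["motif_id"]] - self._mean_[
            self.results_["motif_id"]]) / self._sd_[self.results_["motif_id"]]
        return self._intercept_ + z.values @ self.results_["beta"].values


def regress_stability(dptgr: pd.Series, binding: pd.DataFrame,
                      alpha: float = 0.05,
                      marginal: bool = False) -> pd.DataFrame:
    """Joint OLS of ΔPTGR on all motif affinity columns; one row per motif."""
    common = dptgr.index.intersection(binding.index)
    if len(common) == 0:
        raise ValueError("no genes shared between dptgr and binding matrix")
    est = RegulatorRegression(alpha=alpha, marginal=marginal)
    est.fit(binding.loc[common], dptgr.loc[common].values)
    return est.results_


def select_regulators(results: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Regulators with raw p < alpha, ranked by |beta| (ties: motif_id)."""
    sel = results[results["p"] < alpha].copy()
    if sel.empty:
        return sel.assign(direction=pd.Series(dtype=str))
    sel["direction"] = np.where(sel["beta"] > 0, "stabilizing",
                                "destabilizing")
    sel["abs_beta"] = sel["beta"].abs()
    sel = sel.sort_values(["abs_beta", "motif_id"],
                          ascending=[False, True]).drop(columns="abs_beta")
    return sel.reset_index(drop=True)


def assign_targets(motif_id: str, presence: pd.DataFrame,
                   dptgr: pd.Series) -> tuple[list[str], float]:
    """Predicted target genes (site present) and their mean ΔPTGR.

    Returns ([], nan) when the motif has no predicted sites.
    """
    if motif_id not in presence.columns:
        raise KeyError(f"motif {motif_id!r} not in binding matrix")
    targets = [g for g in presence.index
               if presence.at[g, motif_id] and g in dptgr.index]
    if not targets:
        logger.warning("motif %s has zero predicted targets", motif_id)
        return [], float("nan")
    return targets, float(dptgr.loc[targets].mean())


def regulator_summary(results: pd.DataFrame, presence: pd.DataFrame,
                      dptgr: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Selected-regulator table with target counts and mean target ΔPTGR."""
    sel = select_regulators(results, alpha)
    rows = []
    for _, r in sel.iterrows():
        targets, mean_dptgr = assign_targets(r["motif_id"], presence, dptgr)
        rows.append({**r.to_dict(), "n_bound": len(targets),
                     "mean_target_dptgr": mean_dptgr})
    return pd.DataFrame(rows)
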