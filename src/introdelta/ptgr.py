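"""ΔPTGR estimation: per-gene slope contrast between disease and control.

The model: intronic reads track pre-mRNA (transcription), exonic reads track
mature mRNA (transcription + post-transcriptional regulation).  After
median-centering each gene's log-expression (Δexon, Δintron), a robust line
of Δexon on Δintron is fitted per gene within each sample group.  The
control slope (A) captures the baseline exon-per-intron relationship; the
disease slope (B) shifts when mRNA stability changes.  Per gene,

    ΔPTGR = slope_Disease − slope_Ctrl
    t = ΔPTGR / sqrt(SE_Disease² + SE_Ctrl²),   df = n_Disease + n_Ctrl
    ratio = |slope_Disease / slope_Ctrl − 1|
    ΔPTGR_in = Δexon_i − Δintron_i × slope_Ctrl     (per disease individual)

ΔPTGR > 0 means the mature mRNA is post-transcriptionally up-regulated in
disease.  Genes with Benjamini–Hochberg FDR below the threshold are called
differentially post-transcriptionally regulated (DPRGs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .robust import DEFAULT_MIN_FIT_N, SlopeFitTable, huber_line_fit

RATIO_EPSILON = 1e-6


def median_center(
    values: pd.DataFrame, reference: list[str] | pd.Index | None = None
) -> pd.DataFrame:
    """Subtract each gene's median over the reference samples from all samples.

    ``reference`` defaults to all samples (the pooled-median convention);
    a control-only reference is the alternative when groups are fitted
    separately.
    """
    if reference is None:
        reference = values.columns
    reference = pd.Index(reference)
    if len(reference) == 0:
        raise ValueError("median_center: empty reference sample set")
    missing = reference.difference(values.columns)
    if len(missing):
        raise KeyError(f"reference samples not in matrix: {list(missing)}")
    med = values[reference].median(axis=1)
    return values.sub(med, axis=0)


def delta_ptgr_test(
    slope_d: float, se_d: float, n_d: int,
    slope_c: float, se_c: float, n_c: int,
) -> tuple[float, int, float, str]:
    """t statistic, df, two-sided p and flag for one gene's slope contrast.

    df = n_Disease + n_Ctrl (the printed convention; a Welch df is available
    through :class:`DeltaPTGREstimator`).
    """
    df = int(n_d + n_c)
    denom = np.sqrt(se_d**2 + se_c**2)
    flag = ""
    if denom == 0:
        if slope_d == slope_c:
            return 0.0, df, 1.0, ""
        return np.sign(slope_d - slope_c) * np.inf, df, 0.0, "exact_separation"
    t = (slope_d - slope_c) / denom
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), flag


def ptgr_ratio(slope_d: float, slope_c: float,
               epsilon: float = RATIO_EPSILON) -> float:
    """|slope_D / slope_C − 1|: PTGR dysregulation relative to TGR.

    Undefined (NaN) when the control slope is within ``epsilon`` of zero —
    never infinity.
    """
    if abs(slope_c) <= epsilon:
        return float("nan")
    return abs(slope_d / slope_c - 1.0)


def individual_ptgr(dx: np.ndarray, dy: np.ndarray,
                    slope_ctrl: float) -> np.ndarray:
    """Per-individual ΔPTGR: Δexon − Δintron × slope_Ctrl."""
    return np.asarray(dy, dtype=float) - np.asarray(dx, dtype=float) * slope_ctrl


def call_dprgs(records: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg adjust p-values and flag significant DPRGs."""
    out = records.copy()
    mask = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if mask.any():
        fdr[mask.values] = multipletests(out.loc[mask, "p"].values,
                                         method="fdr_bh")[1]
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < fdr_threshold
    out["direction"] = np.where(out["delta_ptgr"] > 0, "up", "down")
    return out


def _welch_df(se_d, n_d, se_c, n_c):
    num = (se_d**2 + se_c**2) ** 2
    den = se_d**4 / max(n_d - 2, 1) + se_c**4 / max(n_c - 2, 1)
    return num / den if den > 0 else n_d + n_c


class DeltaPTGREstimator(BaseEstimator):
    """Estimate per-gene ΔPTGR from paired exon/intron expression matrices.

    Estimator-styled (``get_params``/``set_params``, fitted attributes with a
    trailing underscore) but, unlike a plain sklearn regressor, ``fit`` takes
    the paired genes × samples exon and intron matrices plus per-sample group
    labels.

    Parameters
    ----------
    control_label:
        Group label treated as the control set; every other label is a
        disease contrast against it.
    center:
        ``"all"`` (default) medians over all samples pooled; ``"control"``
        medians over control samples only.
    df_mode:
        ``"sum"`` (default): df = n_D + n_C.  ``"welch"``:
        Welch–Satterthwaite df for sensitivity analysis.
    min_fit_n:
        Minimum paired samples for a group fit; smaller groups are skipped
        and listed in ``qc_``.
    fdr_threshold:
        Benjamini–Hochberg threshold for the DPRG call.

    Attributes
    ----------
    results_ : pd.DataFrame
        One row per (gene, disease): slopes, SEs, ns, delta_ptgr, t, df, p,
        fdr, ratio, direction, significant, flags.
    individual_ : dict[str, pd.DataFrame]
        Per disease, genes × disease-samples matrix of ΔPTGR_in.
    qc_ : pd.DataFrame
        Genes excluded from testing and why.
    """

    def __init__(self, control_label: str = "control", center: str = "all",
                 df_mode: str = "sum", min_fit_n: int = DEFAULT_MIN_FIT_N,
                 fdr_threshold: float = 0.05):
        self.control_label = control_label
        self.center = center
        self.df_mode = df_mode
        self.min_fit_n = min_fit_n
        self.fdr_threshold = fdr_threshold

    def _fit_group(self, dx: pd.DataFrame, dy: pd.DataFrame) -> SlopeFitTable:
        return huber_line_fit(dx.values, dy.values, min_fit_n=self.min_fit_n)

    def fit(self, exon: pd.DataFrame, intron: pd.DataFrame,
            groups: pd.Series):
        if self.center not in ("all", "control"):
            raise ValueError("center must be 'all' or 'control'")
        if self.df_mode not in ("sum", "welch"):
            raise ValueError("df_mode must be 'sum' or 'welch'")
        common_genes = exon.index.intersection(intron.index)
        common_samples = exon.columns.intersection(intron.columns)
        exon = exon.loc[common_genes, common_samples]
        intron = intron.loc[common_genes, common_samples]
        groups = pd.Series(groups).reindex(common_samples)
        if groups.isna().any():
            raise ValueError("every sample needs a group label")
        if self.control_label not in set(groups):
            raise ValueError(f"control label {self.control_label!r} absent")

        ctrl_samples = groups.index[groups == self.control_label]
        reference = common_samples if self.center == "all" else ctrl_samples
        dex = median_center(exon, reference)
        din = median_center(intron, reference)

        fits: dict[str, SlopeFitTable] = {}
        for label in groups.unique():
            cols = groups.index[groups == label]
            fits[label] = self._fit_group(din[cols], dex[cols])
        fc = fits[self.control_label]

        frames, indiv, qc_rows = [], {}, []
        for label in groups.unique():
            if label == self.control_label:
                continue
            fd = fits[label]
            rows = []
            for gi, gene in enumerate(common_genes):
                if not (fc.ok[gi] and fd.ok[gi]):
                    qc_rows.append({
                        "gene_id": gene, "disease": label,
                        "reason": fc.skip_reason[gi] or fd.skip_reason[gi]
                        or "fit failed",
                    })
                    continue
                t, df, p, flag = delta_ptgr_test(
                    fd.slope[gi], fd.se[gi], fd.n[gi],
                    fc.slope[gi], fc.se[gi], fc.n[gi],
                )
                if self.df_mode == "welch" and np.isfinite(t):
                    df = _welch_df(fd.se[gi], fd.n[gi], fc.se[gi], fc.n[gi])
                    p = float(2.0 * stats.t.sf(abs(t), df))
                rows.append({
                    "gene_id": gene, "disease": label,
                    "slope_ctrl": fc.slope[gi], "se_ctrl": fc.se[gi],
                    "n_ctrl": int(fc.n[gi]),
                    "slope_dis": fd.slope[gi], "se_dis": fd.se[gi],
                    "n_dis": int(fd.n[gi]),
                    "delta_ptgr": fd.slope[gi] - fc.slope[gi],
                    "t": t, "df": df, "p": p,
                    "ratio": ptgr_ratio(fd.slope[gi], fc.slope[gi]),
                    "flags": flag,
                })
            sub = pd.DataFrame(rows)
            if len(sub):
                sub = call_dprgs(sub, self.fdr_threshold)
            frames.append(sub)

            # per-individual scores for disease samples, genes with a control fit
            cols = groups.index[groups == label]
            ok_genes = common_genes[fc.ok]
            slopes = pd.Series(fc.slope[fc.ok], index=ok_genes)
            indiv[label] = dex.loc[ok_genes, cols].sub(
                din.loc[ok_genes, cols].mul(slopes, axis=0)
            )

        self.genes_ = common_genes
        self.group_fits_ = fits
        self.results_ = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
        self.individual_ = indiv
        self.qc_ = pd.DataFrame(qc_rows,
                                columns=["gene_id", "disease", "reason"])
        return self

    def summary(self) -> pd.DataFrame:
        """Per-disease DPRG counts and mean |ratio| over tested genes."""
        res = self.results_
        if res.empty:
            return pd.DataFrame(
                columns=["disease", "n_tested", "n_dprg", "n_up", "n_down",
                         "mean_abs_ratio"])
        rows = []
        for label, sub in res.groupby("disease"):
            sig = sub[sub["significant"]]
            rows.append({
                "disease": label, "n_tested": len(sub), "n_dprg": len(sig),
                "n_up": int((sig["direction"] == "up").sum()),
                "n_down": int((sig["direction"] == "down").sum()),
                "mean_abs_ratio": float(sub["ratio"].abs().mean()),
            })
        return pd.DataFrame(rows)


def two_condition_delta(exon_change: pd.Series,
                        intron_change: pd.Series) -> pd.Series:
    """ΔPTGR for a two-condition (e.g. knockdown vs control) contrast.

    With too few samples per condition for per-group slope fits, the
    per-gene score is simply Δexon − Δintron (control slope fixed at 1).
    """
    return exon_change - intron_change
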