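"""Synthetic exon/intron cohorts with known ground truth.

The generator mirrors the statistical structure the split pipeline assumes:
per gene g and sample i, a latent intron (pre-mRNA) log2-expression
x_gi ~ Normal(baseline_g, spread) and a latent exon (mature mRNA)
log2-expression y_gi = a_g + slope_{g, group(i)} * x_gi + Normal(0, residual
sd).  Counts are drawn negative-binomially at the count level — mean
2^latent * libsize / 1e6 with a gene-independent dispersion — so TMM,
log-CPM and TPM stages are genuinely exercised, not bypassed.  A configured
fraction of genes gets a control-vs-disease slope shift δ (the true ΔPTGR);
optional batch effects add nuisance structure for the residualization stage.
UTR simulation plants motif consensus sequences into designated genes on a
uniform background.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .motifs import BASES, PFM, UTRSet


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_genes: int = 2000
    n_ctrl: int = 100
    n_disease: int = 100
    baseline_mean: float = 7.0  # log2 CPM-scale intron baseline
    baseline_sd: float = 1.5
    spread: float = 1.5  # inter-individual latent sd (log2)
    intercept_mean: float = 1.0  # exon-over-intron offset a_g
    intercept_sd: float = 0.3
    slope_ctrl: float = 1.0
    perturbed_fraction: float = 0.1
    slope_shift: float = 0.5  # δ added to the disease slope of perturbed genes
    residual_sd: float = 0.3
    dispersion: float = 0.005  # NB: var = mu + dispersion * mu^2
    libsize_range: tuple[float, float] = (5.0e6, 1.0e7)
    batch_effect_sd: float = 0.0  # per-gene batch coefficient sd (0 = off)
    length_range: tuple[int, int] = (500, 5000)  # composite-exon lengths
    disease_label: str = "disease"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_ctrl <= 0 or self.n_disease <= 0:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.perturbed_fraction <= 1.0:
            raise ValueError("perturbed_fraction must be in [0, 1]")
        if self.spread <= 0 or self.residual_sd < 0 or self.dispersion < 0:
            raise ValueError("invalid distribution parameters")
        if self.libsize_range[0] <= 0 or \
                self.libsize_range[0] > self.libsize_range[1]:
            raise ValueError("invalid libsize_range")


@dataclass
class SimTruth:
    """Ground truth serialized alongside the synthetic outputs."""

    slope_ctrl: pd.Series
    slope_disease: pd.Series
    perturbed: pd.Series  # bool per gene
    library_sizes: pd.Series
    planted_motifs: dict[str, str] = field(default_factory=dict)
    config: SimConfig | None = None

    def to_json_dict(self) -> dict:
        return {
            "slope_ctrl": self.slope_ctrl.to_dict(),
            "slope_disease": self.slope_disease.to_dict(),
            "perturbed": {g: bool(v) for g, v in self.perturbed.items()},
            "library_sizes": self.library_sizes.to_dict(),
            "planted_motifs": self.planted_motifs,
            "config": None if self.config is None else asdict(self.config),
        }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    cfg: SimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, SimTruth]:
    """Draw the exon/intron count matrices, sample table and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    n = cfg.n_ctrl + cfg.n_disease
    genes = [f"G{i:05d}" for i in range(G)]
    samples = [f"S{i:04d}" for i in range(n)]
    group = np.array(["control"] * cfg.n_ctrl + [cfg.disease_label] *
                     cfg.n_disease)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, G)
    intercept = rng.normal(cfg.intercept_mean, cfg.intercept_sd, G)
    n_pert = int(round(cfg.perturbed_fraction * G))
    perturbed = np.zeros(G, dtype=bool)
    perturbed[rng.choice(G, size=n_pert, replace=False)] = True
    slope_c = np.full(G, cfg.slope_ctrl)
    slope_d = slope_c + np.where(perturbed, cfg.slope_shift, 0.0)
    libsize = rng.uniform(*cfg.libsize_range, size=n)

    x = rng.normal(baseline[:, None], cfg.spread, (G, n))
    slopes = np.where(group[None, :] == "control", slope_c[:, None],
                      slope_d[:, None])
    y = intercept[:, None] + slopes * x + rng.normal(0, cfg.residual_sd, (G, n))

    batch = None
    if cfg.batch_effect_sd > 0:
        batch = np.array(["b1", "b2"])[np.arange(n) % 2]
        beta_batch = rng.normal(0, cfg.batch_effect_sd, G)
        shift = beta_batch[:, None] * (batch[None, :] == "b2")
        x = x + shift
        y = y + shift

    mu_x = 2.0**x * libsize[None, :] / 1e6
    mu_y = 2.0**y * libsize[None, :] / 1e6
    intron_counts = _nb_draw(rng, mu_x, cfg.dispersion)
    exon_counts = _nb_draw(rng, mu_y, cfg.dispersion)
    lengths = pd.Series(rng.integers(*cfg.length_range, size=G), index=genes,
                        name="length")

    sample_table = pd.DataFrame({
        "sample_id": samples,
        "subject_id": [f"subj{i:04d}" for i in range(n)],
        "diagnosis": group,
    })
    if batch is not None:
        sample_table["batch"] = batch

    exon = CountMatrix(
        counts=pd.DataFrame(exon_counts, index=genes, columns=samples),
        feature_class="exonic", lengths=lengths,
    )
    intron = CountMatrix(
        counts=pd.DataFrame(intron_counts, index=genes, columns=samples),
        feature_class="intronic",
    )
    truth = SimTruth(
        slope_ctrl=pd.Series(slope_c, index=genes),
        slope_disease=pd.Series(slope_d, index=genes),
        perturbed=pd.Series(perturbed, index=genes),
        library_sizes=pd.Series(libsize, index=samples),
        config=cfg,
    )
    return exon, intron, sample_table, truth


def simulate_utrs(
    gene_ids: list[str],
    planted: dict[str, PFM],
    length: int = 200,
    seed: int = 0,
) -> tuple[UTRSet, dict[str, str]]:
    """Uniform-background UTRs with motif consensus planted in chosen genes.

    ``planted`` maps gene_id -> PFM whose consensus is inserted at a random
    position; the insertion map (gene -> motif_id) is returned as truth.
    """
    rng = np.random.default_rng(seed)
    for g, p in planted.items():
        if p.length > length:
            raise ValueError(
                f"motif {p.motif_id} ({p.length} nt) longer than UTR ({length})"
            )
    seqs: dict[str, str] = {}
    motif_map: dict[str, str] = {}
    for g in gene_ids:
        seq = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        if g in planted:
            p = planted[g]
            pos = int(rng.integers(0, length - p.length + 1))
            seq = seq[:pos] + p.consensus + seq[pos + p.length:]
            motif_map[g] = p.motif_id
        seqs[g] = seq
    return UTRSet(sequences=seqs), motif_map


def truth_eval(
    records: pd.DataFrame,
    truth: SimTruth,
    fdr_threshold: float = 0.05,
    selected_motifs: list[str] | None = None,
    planted_motifs: list[str] | None = None,
) -> dict:
    """Recovery metrics of pipeline estimates against the simulation truth.

    ``records`` is the per-gene results table from
    :class:`~introdelta.ptgr.DeltaPTGREstimator` (one disease).  Empty call
    sets give sensitivity 0 and FDP 0 by convention.
    """
    rec = records.set_index("gene_id")
    missing = rec.index.difference(truth.perturbed.index)
    if len(missing):
        raise ValueError(f"genes not in truth: {list(missing)[:5]}")
    true_d = truth.slope_disease.loc[rec.index]
    true_c = truth.slope_ctrl.loc[rec.index]
    perturbed = truth.perturbed.loc[rec.index].astype(bool)

    err_d = rec["slope_dis"] - true_d
    called = rec["fdr"] < fdr_threshold if "fdr" in rec else \
        pd.Series(False, index=rec.index)
    tp = int((called & perturbed).sum())
    fp = int((called & ~perturbed).sum())
    n_pos = int(perturbed.sum())
    sens = tp / n_pos if n_pos else float("nan")
    fdp = fp / (tp + fp) if (tp + fp) else 0.0
    tn = int((~called & ~perturbed).sum())
    spec = tn / int((~perturbed).sum()) if (~perturbed).any() else float("nan")

    true_ratio = (true_d / true_c - 1.0).abs()
    out = {
        "slope_bias": float(err_d.mean()),
        "slope_rmse": float(np.sqrt((err_d**2).mean())),
        "sensitivity": sens,
        "specificity": spec,
        "fdp": fdp,
        "n_called": int(called.sum()),
        "mean_est_ratio": float(rec["ratio"].mean()),
        "mean_true_ratio": float(true_ratio.mean()),
    }
    if called.any():
        up_correct = (rec.loc[called & perturbed, "delta_ptgr"] > 0)
        out["direction_accuracy"] = float(up_correct.mean()) if len(up_correct) \
            else float("nan")
    if selected_motifs is not None and planted_motifs is not None:
        sel, planted = set(selected_motifs), set(planted_motifs)
        out["regulators_recovered"] = len(sel & planted)
        out["regulator_false_selections"] = len(sel - planted)
    return out
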