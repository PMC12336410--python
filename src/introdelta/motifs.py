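"""PFM handling, 3'UTR scanning, seed/ARE matching and enrichment tests.

Position frequency matrices (PFMs) describe an RBP's or miRNA's base
preference per motif position.  This module reads PFMs (MEME minimal format
or a plain column-probability table), clusters near-identical motifs into a
non-redundant set, scores 3'UTR sequences for binding affinity and site
presence, matches miRNA seed sites and AU-rich elements by exact IUPAC
patterns, and tests gene sets for site enrichment with Fisher's exact test.

Sequences may arrive in the RNA or DNA alphabet; internally everything is
normalized to DNA (U -> T).  PFM columns are in fixed A, C, G, T/U order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

BASES = "ACGT"
PFM_PSEUDOCOUNT = 1e-3
DEFAULT_PRESENCE_FRACTION = 0.8
ARE_PENTAMER = "ATTTA"  # AUUUA on the RNA strand

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_seq(seq: str) -> str:
    """Uppercase and map the RNA alphabet onto DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


@dataclass
class PFM:
    """A motif as per-position base probabilities (positions x ACGT)."""

    motif_id: str
    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PFM {self.motif_id}: matrix must be positions x 4")
        if self.matrix.shape[0] < 3:
            raise ValueError(f"PFM {self.motif_id}: length must be >= 3")
        sums = self.matrix.sum(axis=1)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValueError(
                f"PFM {self.motif_id}: position {bad[0] + 1} sums to 0"
            )
        # floor zero cells at the pseudocount, renormalize each position to 1
        m = self.matrix / sums[:, None]
        m = np.where(m < 1e-12, PFM_PSEUDOCOUNT, m)
        self.matrix = m / m.sum(axis=1, keepdims=True)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_window_score(self) -> float:
        return float(np.prod(self.matrix.max(axis=1)))


def read_pfms(content: str, fmt: str = "meme") -> list[PFM]:
    """Parse PFMs from MEME minimal format or a plain column table.

    The column table is blocks of ``>motif_id [name]`` followed by one row of
    four whitespace-separated numbers (A C G T/U) per motif position; counts
    are accepted and normalized to probabilities.
    """
    if fmt == "meme":
        return _read_meme(content)
    if fmt == "table":
        return _read_table(content)
    raise ValueError(f"unknown PFM format {fmt!r}")


def _read_meme(content: str) -> list[PFM]:
    pfms: list[PFM] = []
    lines = content.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            name = parts[2] if len(parts) > 2 else motif_id
            width = None
            j = i + 1
            while j < len(lines):
                hdr = lines[j].strip()
                if hdr.startswith("letter-probability matrix"):
                    m = re.search(r"w=\s*(\d+)", hdr)
                    if m:
                        width = int(m.group(1))
                    j += 1
                    break
                if hdr.startswith("MOTIF"):
                    break
                j += 1
            rows: list[list[float]] = []
            while j < len(lines):
                row = lines[j].strip()
                if not row or row.startswith(("MOTIF", "URL")):
                    break
                vals = row.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
                j += 1
                if width is not None and len(rows) == width:
                    break
            if not rows:
                raise ValueError(f"motif {motif_id}: no probability rows found")
            pfms.append(PFM(motif_id, name, np.array(rows)))
            i = j
        else:
            i += 1
    return pfms


def _read_table(content: str) -> list[PFM]:
    pfms: list[PFM] = []
    motif_id = name = None
    rows: list[list[float]] = []

    def flush():
        if motif_id is not None:
            pfms.append(PFM(motif_id, name, np.array(rows)))

    for line in content.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split()
            motif_id, name = parts[0], (parts[1] if len(parts) > 1 else parts[0])
            rows = []
        else:
            vals = line.split()
            if len(vals) != 4:
                raise ValueError(f"PFM table row needs 4 columns: {line!r}")
            rows.append([float(v) for v in vals])
    flush()
    return pfms


def write_pfms(pfms: Iterable[PFM], fmt: str = "meme") -> str:
    """Serialize PFMs; read_pfms(write_pfms(x)) reproduces matrices to 1e-9."""
    out: list[str] = []
    if fmt == "meme":
        out += ["MEME version 4", "", "ALPHABET= ACGT", "",
                "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25",
                ""]
        for p in pfms:
            out.append(f"MOTIF {p.motif_id} {p.name}")
            out.append(
                f"letter-probability matrix: alength= 4 w= {p.length} "
                f"nsites= 20 E= 0"
            )
            for row in p.matrix:
                out.append(" ".join(f"{v:.9f}" for v in row))
            out.append("")
    elif fmt == "table":
        for p in pfms:
            out.append(f">{p.motif_id} {p.name}")
            for row in p.matrix:
                out.append(" ".join(f"{v:.9f}" for v in row))
    else:
        raise ValueError(f"unknown PFM format {fmt!r}")
    return "\n".join(out) + "\n"


@dataclass
class UTRSet:
    """gene_id -> 3'UTR sequence (DNA alphabet) with an eligibility flag."""

    sequences: dict[str, str]
    eligible: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {g: normalize_seq(s) for g, s in self.sequences.items()}
        if not self.eligible:
            self.eligible = {g: True for g in self.sequences}
        for g, flag in self.eligible.items():
            if flag and not self.sequences.get(g):
                raise ValueError(f"eligible gene {g} has an empty sequence")

    def eligible_items(self) -> list[tuple[str, str]]:
        return [(g, s) for g, s in self.sequences.items() if self.eligible.get(g)]


def load_utrs(fasta_text: str) -> UTRSet:
    """Read 3'UTR sequences from FASTA text keyed by gene_id."""
    from io import StringIO

    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(StringIO(fasta_text),
                                                        "fasta")}
    return UTRSet(sequences=seqs)


class ScanResult(NamedTuple):
    affinity: float
    presence: bool
    best_window: int | None


def _encode(seq: str) -> np.ndarray:
    """Map sequence to 0..3 indices; 4 marks a non-alphabet character."""
    idx = np.full(len(seq), 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def scan_affinity(
    pfm: PFM, seq: str,
    presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> ScanResult:
    """Score one sequence: energy-like affinity plus a binding-site call.

    Each window's score is the product of per-position base probabilities;
    affinity is log2 of the sum of all window scores.  A site is present
    when the best window reaches ``presence_fraction`` of the motif's
    maximum attainable window score.  Sequences shorter than the motif get
    affinity 0 and no site.  Non-alphabet characters zero out the windows
    containing them.
    """
    seq = normalize_seq(seq)
    L = pfm.length
    if len(seq) < L:
        return ScanResult(0.0, False, None)
    idx = _encode(seq)
    if (idx == 4).any():
        logger.warning("non-alphabet characters in sequence; windows containing "
                       "them score 0")
    # base-probability lookup with a 5th zero row for invalid characters
    lut = np.zeros((5, L))
    lut[:4, :] = pfm.matrix.T
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = np.prod(lut[windows, np.arange(L)], axis=1)
    total = float(scores.sum())
    best = int(np.argmax(scores))
    affinity = float(np.log2(total)) if total > 0 else 0.0
    presence = bool(scores[best] >= presence_fraction * pfm.max_window_score)
    return ScanResult(affinity, presence, best)


_PANEL_CACHE: dict[tuple[int, int, int], list[str]] = {}


def _random_panel(k: int = 500, length: int = 100, seed: int = 0) -> list[str]:
    key = (k, length, seed)
    if key not in _PANEL_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 4, size=(k, length))
        _PANEL_CACHE[key] = ["".join(BASES[b] for b in row) for row in draws]
    return _PANEL_CACHE[key]


def _panel_scores(pfm: PFM, panel: list[str]) -> np.ndarray:
    return np.array([scan_affinity(pfm, s).affinity for s in panel])


def pfm_similarity(
    a: PFM, b: PFM, k: int = 500, length: int = 100, seed: int = 0
) -> float:
    """Pearson correlation of the two motifs' affinities over a shared
    random-sequence panel; symmetric, 1 for identical motifs, defined as 0
    for a degenerate (constant-scoring, e.g. uniform) motif."""
    panel = _random_panel(k, length, seed)
    sa, sb = _panel_scores(a, panel), _panel_scores(b, panel)
    if np.std(sa) < 1e-12 or np.std(sb) < 1e-12:
        logger.warning("degenerate motif in similarity (%s vs %s); returning 0",
                       a.motif_id, b.motif_id)
        return 0.0
    return float(np.corrcoef(sa, sb)[0, 1])


def cluster_pfms(
    pfms: list[PFM], threshold: float = 0.75,
    k: int = 500, length: int = 100, seed: int = 0,
) -> tuple[list[PFM], dict[str, str]]:
    """Greedy non-redundant clustering of PFMs by panel-score correlation.

    Motifs are visited in input order; each joins the first existing cluster
    whose representative (first member) correlates at >= ``threshold``, else
    opens a new cluster.  Deterministic given input order.
    Returns (representatives, motif_id -> representative_id map).
    """
    panel = _random_panel(k, length, seed)
    reps: list[PFM] = []
    rep_scores: list[np.ndarray] = []
    assignment: dict[str, str] = {}
    for p in pfms:
        sp = _panel_scores(p, panel)
        placed = False
        if np.std(sp) >= 1e-12:
            for rep, sr in zip(reps, rep_scores):
                if np.std(sr) < 1e-12:
                    continue
                if np.corrcoef(sp, sr)[0, 1] >= threshold:
                    assignment[p.motif_id] = rep.motif_id
                    placed = True
                    break
        if not placed:
            reps.append(p)
            rep_scores.append(sp)
            assignment[p.motif_id] = p.motif_id
    return reps, assignment


def kmer_sites(pattern: str, seq: str) -> tuple[int, list[int]]:
    """All (possibly overlapping) occurrences of an exact IUPAC pattern.

    Returns (count, 0-based start positions).
    """
    if not pattern:
        raise ValueError("empty pattern")
    pattern = normalize_seq(pattern)
    seq = normalize_seq(seq)
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters in pattern: {sorted(bad)}")
    regex = "".join(
        ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]" for ch in pattern
    )
    positions = [m.start() for m in re.finditer(f"(?=({regex}))", seq)]
    return len(positions), positions


def mirna_seed_pattern(mirna_seq: str, site_type: str = "7mer-m8") -> str:
    """3'UTR site pattern for a miRNA seed.

    The seed is miRNA bases 2-8; the canonical 7mer-m8 site is the reverse
    complement of those bases.  The 8mer appends an A opposite position 1;
    the 7mer-A1 uses bases 2-7 plus that A.
    """
    seq = normalize_seq(mirna_seq)
    if len(seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    if site_type == "7mer-m8":
        return reverse_complement(seq[1:8])
    if site_type == "8mer":
        return reverse_complement(seq[1:8]) + "A"
    if site_type == "7mer-A1":
        return reverse_complement(seq[1:7]) + "A"
    raise ValueError(f"unknown seed site type {site_type!r}")


class EnrichmentResult(NamedTuple):
    odds_ratio: float
    p: float
    haldane: bool


def enrichment_test(
    hits_in_set: int, set_size: int, hits_total: int, universe_size: int,
    sided: str = "greater",
) -> EnrichmentResult:
    """Fisher's exact test for over-representation of hits in a gene set.

    The 2x2 table is (hit, not-hit) x (in set, out of set).  The reported
    odds ratio is the sample cross-product ratio, with the Haldane 0.5
    continuity correction applied (and flagged) only when a cell is zero.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if set_size > universe_size or hits_total > universe_size:
        raise ValueError("set or hit count exceeds universe")
    if hits_in_set > set_size or hits_in_set > hits_total:
        raise ValueError("inconsistent hit counts")
    if set_size == 0:
        raise ValueError("empty gene set")
    a = hits_in_set
    b = set_size - a
    c = hits_total - a
    d = universe_size - set_size - c
    if d < 0:
        raise ValueError("inconsistent table: more hits than universe allows")
    alternative = {"greater": "greater", "two": "two-sided"}[sided]
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    haldane = 0 in (a, b, c, d)
    if haldane:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return EnrichmentResult(float(a2 * d2 / (b2 * c2)), float(p), haldane)


class MotifScanner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: 3'UTR sequences -> genes x motifs affinities.

    Analogous to a text vectorizer: ``fit`` stores the motif vocabulary,
    ``transform`` maps sequences to the affinity matrix.  The companion
    ``scan`` method also returns the boolean presence matrix and a site
    table (gene-relative 0-based half-open best-window coordinates).
    """

    def __init__(self, pfms: list[PFM] | None = None,
                 presence_fraction: float = DEFAULT_PRESENCE_FRACTION):
        self.pfms = pfms
        self.presence_fraction = presence_fraction

    def fit(self, X=None, y=None):
        if not self.pfms:
            raise ValueError("MotifScanner needs a non-empty PFM list")
        self.motif_ids_ = [p.motif_id for p in self.pfms]
        return self

    def scan(self, utrs: UTRSet) -> tuple[pd.DataFrame, pd.DataFrame,
                                          pd.DataFrame]:
        if not hasattr(self, "motif_ids_"):
            self.fit()
        items = utrs.eligible_items()
        genes = [g for g, _ in items]
        aff = np.zeros((len(genes), len(self.pfms)))
        pres = np.zeros((len(genes), len(self.pfms)), dtype=bool)
        sites = []
        for j, p in enumerate(self.pfms):
            for i, (g, s) in enumerate(items):
                res = scan_affinity(p, s, self.presence_fraction)
                aff[i, j] = res.affinity
                pres[i, j] = res.presence
                if res.presence and res.best_window is not None:
                    sites.append({"gene_id": g, "motif_id": p.motif_id,
                                  "start": res.best_window,
                                  "end": res.best_window + p.length})
        affinity = pd.DataFrame(aff, index=genes, columns=self.motif_ids_)
        presence = pd.DataFrame(pres, index=genes, columns=self.motif_ids_)
        site_df = pd.DataFrame(sites,
                               columns=["gene_id", "motif_id", "start", "end"])
        return affinity, presence, site_df

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, UTRSet):
            utrs = X
        elif isinstance(X, dict):
            utrs = UTRSet(sequences=X)
        else:
            utrs = UTRSet(sequences={f"seq{i}": s for i, s in enumerate(X)})
        affinity, _, _ = self.scan(utrs)
        return affinity
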