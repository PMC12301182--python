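"""Parametric HGT detection from oligonucleotide typicality (the Wn method).

Each gene is scored for how typical its k-mer composition is of the host
genome; the rank-ordered score curve is smoothed with a Savitzky-Golay
filter whose window length is chosen automatically; and genes below the
point where the curve's second derivative stops being significantly nonzero
— in units of the median absolute deviation (MAD) of the double derivative
around zero — are flagged as putative horizontal acquisitions. The MAD
multiple s is the stringency knob (sweep 4..13; lower s flags more genes).

Typicality here is a length-normalized log-likelihood ratio: the gene's
k-mers scored under the pooled genome composition minus under the gene's own
composition, i.e. the negative KL divergence of the gene's k-mer
distribution from the genome background (in bits per k-mer window). It is 0
for a gene compositionally identical to the background and decreases as the
composition deviates in either direction. The background pools the k-mer
counts of all the taxon's genes and their reverse complements, with a
pseudocount.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .model import GainEvent, GenomeAnnotation, InferenceSet

__all__ = [
    "WnConfig",
    "TypicalityTable",
    "count_kmers",
    "typicality_scores",
    "auto_sg_window",
    "detect_transferred",
    "wn_inference_set",
]

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")
MIN_GENES_PER_TAXON = 30


@dataclass
class WnConfig:
    """Parameters of the detector.

    k: oligonucleotide size (8 in the study; smaller k is statistically
       sounder on short synthetic genes, where 8-mers are undersampled).
    pseudocount: added to every background k-mer count.
    sg_polyorder: Savitzky-Golay polynomial order.
    sg_windows: candidate window lengths (odd, ascending).
    stringencies: MAD-multiple sweep.
    """

    k: int = 8
    pseudocount: float = 0.5
    sg_polyorder: int = 3
    sg_windows: Sequence[int] = field(default_factory=lambda: list(range(5, 102, 2)))
    stringencies: Sequence[float] = field(default_factory=lambda: list(range(4, 14)))

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        windows = list(self.sg_windows)
        if windows != sorted(windows) or any(
            w % 2 == 0 or w <= self.sg_polyorder for w in windows
        ):
            raise ValueError("sg_windows must be ascending odd integers > polyorder")
        if any(s <= 0 for s in self.stringencies):
            raise ValueError("stringencies must be > 0")


def count_kmers(sequence: str, k: int) -> dict[str, int]:
    """Counts of all length-k windows containing no N.

    k longer than the sequence yields an empty map.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_RC)[::-1]


@dataclass
class TypicalityTable:
    """Per-taxon typicality scores and the derived rank curve.

    curve: scores sorted ascending; gene_order: gene ids in curve order;
    smoothed: Savitzky-Golay smoothed curve (window chosen by
    :func:`auto_sg_window`); d1/d2: central finite differences of the
    smoothed curve; mad0: median absolute double derivative of the *raw*
    curve — the noise scale against which smoothed curvature is judged.
    """

    taxon: str
    scores: dict[str, float]
    gene_order: list[str]
    curve: np.ndarray
    smoothed: np.ndarray
    window: int
    d1: np.ndarray
    d2: np.ndarray
    mad0: float


def typicality_scores(
    genes: Mapping[str, str], config: WnConfig | None = None, taxon: str = ""
) -> TypicalityTable:
    """Score every gene of one taxon against the pooled genome background."""
    config = config or WnConfig()
    if not genes:
        raise ValueError("no gene sequences")
    k = config.k
    per_gene: dict[str, dict[str, int]] = {}
    background: dict[str, int] = {}
    for gene_id in sorted(genes):
        seq = genes[gene_id]
        if not seq:
            raise ValueError(f"empty sequence for gene {gene_id!r}")
        counts = count_kmers(seq, k)
        per_gene[gene_id] = counts
        for w, c in counts.items():
            background[w] = background.get(w, 0) + c
        for w, c in count_kmers(reverse_complement(seq), k).items():
            background[w] = background.get(w, 0) + c

    pseudo = config.pseudocount
    total_bg = sum(background.values()) + pseudo * 4**k
    log_bg = {w: math.log2((c + pseudo) / total_bg) for w, c in background.items()}
    default_log_bg = math.log2(pseudo / total_bg)

    scores: dict[str, float] = {}
    for gene_id, counts in per_gene.items():
        W = sum(counts.values())
        if W == 0:
            scores[gene_id] = 0.0
            continue
        s = 0.0
        for w, c in counts.items():
            s += c * (log_bg.get(w, default_log_bg) - math.log2(c / W))
        scores[gene_id] = s / W

    gene_order = sorted(scores, key=lambda g: (scores[g], g))
    curve = np.array([scores[g] for g in gene_order])
    window = auto_sg_window(curve, config)
    if window > config.sg_polyorder:
        smoothed = savgol_filter(curve, window, config.sg_polyorder)
    else:
        smoothed = curve.copy()
    d1 = np.gradient(smoothed) if len(curve) > 1 else np.zeros_like(curve)
    d2 = np.gradient(d1) if len(curve) > 1 else np.zeros_like(curve)
    d2_raw = (
        np.gradient(np.gradient(curve)) if len(curve) > 1 else np.zeros_like(curve)
    )
    mad0 = float(np.median(np.abs(d2_raw)))
    return TypicalityTable(
        taxon=taxon,
        scores=scores,
        gene_order=gene_order,
        curve=curve,
        smoothed=smoothed,
        window=window,
        d1=d1,
        d2=d2,
        mad0=mad0,
    )


def auto_sg_window(curve: np.ndarray, config: WnConfig | None = None) -> int:
    """Longest Savitzky-Golay window before smoothing stops converging.

    Candidate windows are tried in ascending order; for each, the RMSE
    between the current and the previous window's smoothed curve is
    computed. While that RMSE decreases, lengthening the window is still
    removing noise; when it stops decreasing (with a patience of two
    candidates, to ride over sampling bumps), lengthening has started to
    distort the signal, and the last window that achieved a decrease is
    returned. A curve shorter than the smallest candidate gets window 1 (no
    smoothing); a curve the filter reproduces exactly (RMSE at machine
    scale) gets the smallest candidate.
    """
    config = config or WnConfig()
    curve = np.asarray(curve, dtype=float)
    windows = [w for w in config.sg_windows if w <= len(curve)]
    if not windows:
        return 1
    poly = config.sg_polyorder
    scale = float(np.ptp(curve)) or 1.0
    floor = 1e-12 * scale
    prev_sm = savgol_filter(curve, windows[0], poly)
    if float(np.sqrt(np.mean((prev_sm - curve) ** 2))) <= floor:
        return windows[0]
    best = windows[0]
    prev_rmse = None
    patience = 0
    for w in windows[1:]:
        sm = savgol_filter(curve, w, poly)
        rmse = float(np.sqrt(np.mean((sm - prev_sm) ** 2)))
        if rmse <= floor:
            return best
        if prev_rmse is not None and rmse >= prev_rmse:
            patience += 1
            if patience >= 2:
                break
        else:
            patience = 0
            best = w
        prev_rmse = rmse
        prev_sm = sm
    return best


def detect_transferred(table: TypicalityTable, s: float) -> set[str]:
    """Gene ids flagged as atypical at MAD-multiple stringency ``s``.

    The cut index is the largest position in the lower half of the rank
    curve where the smoothed curve's double derivative exceeds s times MAD0;
    all genes ranked below the cut (the low-typicality head) are flagged.
    MAD0 = 0 (perfectly smooth curve) flags nothing. The flag set is
    non-increasing in s by construction.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    n = len(table.curve)
    if n == 0:
        return set()
    if table.mad0 == 0.0:
        logger.info("taxon %s: MAD0 = 0 (smooth curve), nothing flagged", table.taxon)
        return set()
    half = n // 2
    exceed = np.where(np.abs(table.d2[:half]) > s * table.mad0)[0]
    cut = int(exceed[-1]) + 1 if len(exceed) else 0
    return set(table.gene_order[:cut])


def wn_inference_set(
    sequences: Mapping[str, Mapping[str, str]],
    annotations: Sequence[GenomeAnnotation],
    config: WnConfig | None = None,
) -> InferenceSet:
    """Run the detector per taxon and assemble the stringency sweep.

    Flagged genes become gain events on the taxon's terminal branch (family
    looked up from the annotation; parametric methods provide no donor).
    Taxa with fewer than 30 genes are skipped; gene ids in the FASTA with no
    annotated counterpart are logged and skipped.
    """
    config = config or WnConfig()
    family_of: dict[str, dict[str, str]] = {}
    for ann in annotations:
        family_of[ann.taxon] = {
            g.gene_id: g.family for _, genes in ann.chromosomes for g in genes
        }
    levels: dict[float, list[GainEvent]] = {float(s): [] for s in config.stringencies}
    for taxon in sorted(sequences):
        genes = sequences[taxon]
        if len(genes) < MIN_GENES_PER_TAXON:
            logger.warning(
                "taxon %s has %d genes (< %d), skipped",
                taxon,
                len(genes),
                MIN_GENES_PER_TAXON,
            )
            continue
        mapping = family_of.get(taxon, {})
        table = typicality_scores(genes, config, taxon=taxon)
        for s in config.stringencies:
            for gene_id in sorted(detect_transferred(table, float(s))):
                family = mapping.get(gene_id)
                if family is None:
                    logger.warning("gene %s of taxon %s not annotated, skipped", gene_id, taxon)
                    continue
                levels[float(s)].append(GainEvent(family=family, recipient=taxon))
    return InferenceSet(method="wn", levels=levels)
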