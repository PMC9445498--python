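"""Promoter scanning: slide 7-15 bp windows over a promoter, score every
(window, TF) pair with the per-length RP and RW models, and keep consensus
hits — pairs scored at or above the probability threshold by *both* models.

Coordinates are 0-based half-open on the forward strand.  A minus-strand
window covers the same interval but its sequence is the reverse complement
of the forward slice (the site as the TF would read it on that strand).
With the strict threshold tau = 1 this reproduces the selection rule used to
nominate promoter regulators: probability exactly 1 in both models.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .constants import DEFAULT_THRESHOLD, DNA_BASES, TFBS_LENGTHS
from .errors import InvariantError
from .io_tables import InteractionRecord
from .model_training import ModelRegistry, predict_proba
from .motif_tools import reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterWindow:
    """One candidate binding-site window on a promoter."""

    promoter_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InvariantError(f"invalid window [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise InvariantError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise InvariantError("window sequence length must equal end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanHit:
    """A (window, TF) pair with its RP and RW model probabilities."""

    window: PromoterWindow
    tf_id: str
    family: str
    prob_rp: float
    prob_rw: float
    consensus: bool


def expected_window_count(promoter_length: int, lengths=TFBS_LENGTHS, strands: str = "+-") -> int:
    """Closed-form window count: len(strands) * sum over L of (P - L + 1)."""
    return len(strands) * sum(max(0, promoter_length - L + 1) for L in lengths)


def enumerate_windows(
    promoter_id: str, sequence: str, lengths=TFBS_LENGTHS, strands: str = "+-",
) -> list[PromoterWindow]:
    """All sliding windows of the given lengths on the requested strands.

    Windows containing non-ACGT characters (e.g. N) are skipped, with the
    skipped count logged.  Order is deterministic: (length, start, strand)
    with + before -.
    """
    sequence = sequence.upper()
    windows, dropped = [], 0
    for L in sorted(lengths):
        for start in range(len(sequence) - L + 1):
            fwd = sequence[start:start + L]
            if set(fwd) - set(DNA_BASES):
                dropped += len(strands)
                continue
            for strand in strands:
                seq = fwd if strand == "+" else reverse_complement(fwd)
                windows.append(PromoterWindow(promoter_id, start, start + L, strand, seq))
    if dropped:
        logger.warning("%s: skipped %d windows containing non-ACGT bases", promoter_id, dropped)
    if not windows:
        logger.warning("%s: promoter shorter than the minimum window length", promoter_id)
    return windows


def scan_promoter(
    promoter_id: str, sequence: str, tfs, registry: ModelRegistry,
    tau: float = DEFAULT_THRESHOLD, lengths=None, strands: str = "+-",
    keep_all: bool = False,
) -> list[ScanHit]:
    """Score every (window, TF) pair and return consensus hits.

    ``tfs`` is a list of TfRecord-like objects (tf_id, family, dbd_type,
    dbd_sequence).  TFs whose DBD type is unknown to a length's models are
    skipped for that length (logged).  Predictions are made once per unique
    (TF, window sequence) and mapped back to all matching windows; the result
    is deduplicated to unique (tf_id, promoter_id, start, end, strand).
    With ``keep_all`` every evaluable pair is returned, consensus flagged.
    """
    scan_lengths = sorted(set(lengths or registry.lengths) & set(registry.lengths))
    hits: list[ScanHit] = []
    for L in scan_lengths:
        rp_model = registry.get(L, "RP")
        rw_model = registry.get(L, "RW")
        known = set(rp_model.profiles) & set(rw_model.profiles) \
            if rp_model.encoding_mode == "base_preference" else None
        windows = [w for w in enumerate_windows(promoter_id, sequence, [L], strands)]
        if not windows:
            continue
        by_seq = defaultdict(list)
        for w in windows:
            by_seq[w.sequence].append(w)
        unique_seqs = sorted(by_seq)
        for tf in tfs:
            if known is not None and tf.dbd_type not in known:
                logger.info("TF %s skipped at L=%d: DBD type %r not modelled",
                            tf.tf_id, L, tf.dbd_type)
                continue
            pairs = [
                InteractionRecord(
                    tf_id=tf.tf_id, dbd_type=tf.dbd_type, dbd_sequence=tf.dbd_sequence,
                    tfbs_sequence=seq, label=0, source="scan",
                )
                for seq in unique_seqs
            ]
            rp = predict_proba(rp_model, pairs)
            rw = predict_proba(rw_model, pairs)
            for seq, p_rp, p_rw in zip(unique_seqs, rp, rw):
                consensus = p_rp.prob >= tau and p_rw.prob >= tau
                if not (consensus or keep_all):
                    continue
                for w in by_seq[seq]:
                    hits.append(ScanHit(
                        window=w, tf_id=tf.tf_id, family=tf.family,
                        prob_rp=p_rp.prob, prob_rw=p_rw.prob, consensus=consensus,
                    ))
    # deduplicate on (tf_id, promoter_id, start, end, strand); first wins
    seen, unique = set(), []
    for h in hits:
        key = (h.tf_id, h.window.promoter_id, h.window.start, h.window.end, h.window.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    unique.sort(key=lambda h: (h.window.start, h.window.end, h.window.strand, h.tf_id))
    return unique


def summarize_by_family(hits, bin_size: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family distinct-TF counts and a hit-start position histogram.

    Returns ``(families, histogram)``: families has columns family / n_tfs /
    n_hits; histogram has one row per (family, bin_start) with its hit count.
    """
    if not hits:
        empty = pd.DataFrame(columns=["family", "n_tfs", "n_hits"])
        return empty, pd.DataFrame(columns=["family", "bin_start", "n_hits"])
    rows = [
        {"family": h.family, "tf_id": h.tf_id, "start": h.window.start}
        for h in hits
    ]
    df = pd.DataFrame(rows)
    families = (
        df.groupby("family")
        .agg(n_tfs=("tf_id", "nunique"), n_hits=("tf_id", "size"))
        .reset_index()
    )
    df["bin_start"] = (df["start"] // bin_size) * bin_size
    histogram = (
        df.groupby(["family", "bin_start"]).size().rename("n_hits").reset_index()
    )
    return families, histogram
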