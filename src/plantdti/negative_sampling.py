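"""Negative (non-interacting) pair generation.

Two schemes, mirroring the two assumptions one can make about what a
non-interaction looks like:

* **RP** (random pairs) - a DBD is paired with a binding site drawn from
  another interaction of the same length group.  Tests whether the model
  recognises which partner belongs to which.
* **RW** (random within) - the bases of a positive's own binding site are
  randomly permuted.  Tests whether the model recognises the sequence
  pattern itself.  Every RW negative is an anagram of its source site.

Both schemes exclude any pair that is a known positive: a candidate
(dbd_type, sequence) is rejected when any TF of that DBD type is known to
bind that exact sequence.  A site whose negative quota cannot be filled
within ``max_attempts`` draws per needed negative (e.g. a homopolymer under
RW, or a site positive for every DBD type under RP) is excluded and reported.

Per length group the generated count is round(ratio * n_positives) minus any
exclusion shortfall; duplicates of (tf_id, sequence) are never emitted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, NoDataError
from .io_tables import InteractionRecord

DEFAULT_MAX_ATTEMPTS = 1000


@dataclass
class NegativeSet:
    """A generated negative set plus its provenance."""

    scheme: str  # "RP" or "RW"
    records: list[InteractionRecord]
    excluded_tfbs: list[str] = field(default_factory=list)
    seed: int = 0
    ratio: float = 1.0


def _positive_keys(positives) -> set[tuple[str, str]]:
    return {(p.dbd_type, p.tfbs_sequence) for p in positives}


def _by_length(positives) -> dict[int, list[InteractionRecord]]:
    groups = defaultdict(list)
    for p in positives:
        groups[p.length].append(p)
    return dict(groups)


def _quotas(n: int, ratio: float) -> list[int]:
    """Per-positive quotas summing to round(ratio * n), spread as evenly as possible."""
    target = int(round(ratio * n))
    base, extra = divmod(target, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


def _negative_from(p: InteractionRecord, seq: str, scheme: str) -> InteractionRecord:
    return InteractionRecord(
        tf_id=p.tf_id, dbd_type=p.dbd_type, dbd_sequence=p.dbd_sequence,
        tfbs_sequence=seq, label=0, source=scheme,
    )


def generate_rp(
    positives, ratio: float = 1.0, seed: int = 0,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> NegativeSet:
    """Shuffled-pair negatives: each positive's DBD re-paired with another site.

    Sites are drawn uniformly from the positive sequence pool of the same
    length group.  Raises :class:`GenerationError` when a length group holds
    fewer than two distinct sites (no cross pair can exist).
    """
    positives = list(positives)
    if not positives:
        raise NoDataError("cannot generate negatives from an empty positive set")
    rng = np.random.default_rng(seed)
    pos_keys = _positive_keys(positives)
    records, excluded = [], []
    seen: set[tuple[str, str]] = set()

    groups = _by_length(positives)
    for length in sorted(groups):
        group = groups[length]
        pool = sorted({p.tfbs_sequence for p in group})
        if len(pool) < 2:
            raise GenerationError(
                f"RP needs at least 2 distinct TFBSs in length group {length}, got {len(pool)}"
            )
        for p, quota in zip(group, _quotas(len(group), ratio)):
            for _ in range(quota):
                for _attempt in range(max_attempts):
                    cand = pool[rng.integers(len(pool))]
                    if cand == p.tfbs_sequence or (p.dbd_type, cand) in pos_keys:
                        continue
                    if (p.tf_id, cand) in seen:
                        continue
                    seen.add((p.tf_id, cand))
                    records.append(_negative_from(p, cand, "RP"))
                    break
                else:
                    excluded.append(p.tfbs_sequence)
                    break
    return NegativeSet(scheme="RP", records=records,
                       excluded_tfbs=sorted(set(excluded)), seed=seed, ratio=ratio)


def generate_rw(
    positives, ratio: float = 1.0, seed: int = 0,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> NegativeSet:
    """Within-site shuffle negatives: each positive's site with its bases permuted.

    A permutation equal to the original, equal to a known positive of the same
    DBD type, or duplicating an already-generated negative for the same TF is
    rejected and redrawn.  Sites with no admissible permutation (homopolymers
    and near-homopolymers) are excluded and listed in ``excluded_tfbs``.
    """
    positives = list(positives)
    if not positives:
        raise NoDataError("cannot generate negatives from an empty positive set")
    rng = np.random.default_rng(seed)
    pos_keys = _positive_keys(positives)
    records, excluded = [], []
    seen: set[tuple[str, str]] = set()

    groups = _by_length(positives)
    for length in sorted(groups):
        group = groups[length]
        for p, quota in zip(group, _quotas(len(group), ratio)):
            letters = np.array(list(p.tfbs_sequence))
            for _ in range(quota):
                for _attempt in range(max_attempts):
                    cand = "".join(letters[rng.permutation(len(letters))])
                    if cand == p.tfbs_sequence or (p.dbd_type, cand) in pos_keys:
                        continue
                    if (p.tf_id, cand) in seen:
                        continue
                    seen.add((p.tf_id, cand))
                    records.append(_negative_from(p, cand, "RW"))
                    break
                else:
                    excluded.append(p.tfbs_sequence)
                    break
    return NegativeSet(scheme="RW", records=records,
                       excluded_tfbs=sorted(set(excluded)), seed=seed, ratio=ratio)


def generate_negatives(scheme: str, positives, **kwargs) -> NegativeSet:
    """Dispatch to :func:`generate_rp` or :func:`generate_rw` by scheme name."""
    scheme = scheme.upper()
    if scheme == "RP":
        return generate_rp(positives, **kwargs)
    if scheme == "RW":
        return generate_rw(positives, **kwargs)
    raise ValueError(f"unknown negative scheme {scheme!r} (expected RP or RW)")
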