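"""Numeric features for a (DBD, TFBS) pair.

Two binding-site encodings are supported, both 4*L reals in position-major
order with bases ordered A, T, C, G within each position:

* ``binary`` - the classic one-hot code (A=1000, T=0100, C=0010, G=0001), so
  "CAGCCG" becomes 001010000001001000100001;
* ``base_preference`` - the one-hot code scaled by the DBD type's positional
  base probability P_j(X_j), so the feature for the observed base carries how
  strongly that DBD type prefers it and the other three slots stay zero.

The protein side is the amino-acid binding-mode composition of the DBD: the
fractions of hydrogen-bonding (hb), van-der-Waals (dw) and weakly binding
(wb) residues, n_k / l for each class k over the domain length l.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    BASE_INDEX, BASE_ORDER, DNA_BASES, DW_RESIDUES, HB_RESIDUES, STANDARD_AA, WB_RESIDUES,
)
from .errors import AlphabetError, InvariantError, KeyMismatchError, NoDataError

BINARY = "binary"
BASE_PREFERENCE = "base_preference"
ENCODING_MODES = (BINARY, BASE_PREFERENCE)

DBD_FEATURE_NAMES = ("dbd_hb", "dbd_dw", "dbd_wb")


@dataclass(frozen=True)
class DbdFeatures:
    """Binding-mode composition of a DBD amino-acid sequence."""

    hb: float
    dw: float
    wb: float
    length: int

    def as_array(self) -> np.ndarray:
        return np.array([self.hb, self.dw, self.wb])


@dataclass(frozen=True)
class FeatureVector:
    """An encoded pair: optional 3-entry DBD block followed by the 4*L TFBS block."""

    values: np.ndarray
    encoding_mode: str
    length: int
    include_dbd: bool

    def __post_init__(self):
        expected = (3 if self.include_dbd else 0) + 4 * self.length
        if self.values.shape != (expected,):
            raise InvariantError(f"feature vector shape {self.values.shape} != ({expected},)")

    @property
    def column_names(self) -> list[str]:
        names = list(DBD_FEATURE_NAMES) if self.include_dbd else []
        names += [f"p{j + 1}_{b}" for j in range(self.length) for b in BASE_ORDER]
        return names


def encode_binary(seq: str) -> np.ndarray:
    """One-hot encode an A/C/G/T sequence into a 4*L block."""
    block = np.zeros(4 * len(seq))
    for j, base in enumerate(seq):
        if base not in BASE_INDEX:
            raise AlphabetError(f"non-ACGT base {base!r} at position {j + 1}")
        block[4 * j + BASE_INDEX[base]] = 1.0
    return block


def decode_binary(block: np.ndarray) -> str:
    """Inverse of :func:`encode_binary` (each position has exactly one 1)."""
    block = np.asarray(block)
    if block.size % 4:
        raise InvariantError("binary block size must be a multiple of 4")
    out = []
    for j in range(block.size // 4):
        pos = block[4 * j: 4 * j + 4]
        hot = np.flatnonzero(pos == 1.0)
        if hot.size != 1 or pos.sum() != 1.0:
            raise InvariantError(f"position {j + 1} is not one-hot")
        out.append(BASE_ORDER[hot[0]])
    return "".join(out)


def encode_base_preference(seq: str, profile) -> np.ndarray:
    """Encode a sequence as one-hot scaled by the profile's P_j(X_j).

    The slot of the observed base at each position carries its probability
    under the DBD type's profile; the other three slots are zero.  A base the
    profile never saw (P=0) leaves the whole position at zero.
    """
    if len(seq) != profile.length:
        raise KeyMismatchError(f"sequence length {len(seq)} != profile length {profile.length}")
    block = np.zeros(4 * len(seq))
    for j, base in enumerate(seq):
        if base not in BASE_INDEX:
            raise AlphabetError(f"non-ACGT base {base!r} at position {j + 1}")
        block[4 * j + BASE_INDEX[base]] = profile.prob(j, base)
    return block


def encode_dbd(aa_seq: str) -> DbdFeatures:
    """Binding-mode composition features n_k/l of a DBD amino-acid sequence."""
    if not aa_seq:
        raise NoDataError("empty DBD sequence")
    aa_seq = aa_seq.upper()
    bad = set(aa_seq) - set(STANDARD_AA)
    if bad:
        raise AlphabetError(f"non-standard amino-acid letter(s) {sorted(bad)} in DBD sequence")
    l = len(aa_seq)
    hb = sum(c in HB_RESIDUES for c in aa_seq) / l
    dw = sum(c in DW_RESIDUES for c in aa_seq) / l
    wb = sum(c in WB_RESIDUES for c in aa_seq) / l
    return DbdFeatures(hb=hb, dw=dw, wb=wb, length=l)


def build_feature_vector(
    record, profile=None, mode: str = BASE_PREFERENCE, include_dbd: bool = True
) -> FeatureVector:
    """Encode an :class:`~plantdti.io_tables.InteractionRecord` into features.

    In ``base_preference`` mode a profile keyed to (record.dbd_type, record
    length) is required; there is no silent fallback to binary for an unknown
    DBD type.  ``include_dbd=False`` gives the TFBS-only variant used to
    ablate the contribution of the protein features.
    """
    if mode not in ENCODING_MODES:
        raise ValueError(f"unknown encoding mode {mode!r}")
    seq = record.tfbs_sequence
    if mode == BASE_PREFERENCE:
        if profile is None:
            raise KeyMismatchError(
                f"base_preference encoding requires a profile for DBD type {record.dbd_type!r}"
            )
        if profile.dbd_type != record.dbd_type or profile.length != len(seq):
            raise KeyMismatchError(
                f"profile key ({profile.dbd_type}, {profile.length}) does not match "
                f"record ({record.dbd_type}, {len(seq)})"
            )
        tfbs_block = encode_base_preference(seq, profile)
    else:
        tfbs_block = encode_binary(seq)
    if include_dbd:
        values = np.concatenate([encode_dbd(record.dbd_sequence).as_array(), tfbs_block])
    else:
        values = tfbs_block
    return FeatureVector(values=values, encoding_mode=mode, length=len(seq), include_dbd=include_dbd)


def encode_records(
    records, profiles: dict | None, mode: str, include_dbd: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorise a list of records into an (n, p) matrix and label vector.

    ``profiles`` maps dbd_type -> profile (all of one length); only consulted
    in base_preference mode.
    """
    X, y = [], []
    for rec in records:
        profile = None
        if mode == BASE_PREFERENCE:
            if profiles is None or rec.dbd_type not in profiles:
                raise KeyMismatchError(f"no profile for DBD type {rec.dbd_type!r}")
            profile = profiles[rec.dbd_type]
        fv = build_feature_vector(rec, profile=profile, mode=mode, include_dbd=include_dbd)
        X.append(fv.values)
        y.append(rec.label)
    return np.array(X), np.array(y)
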