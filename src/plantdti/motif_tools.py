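"""IUPAC motif expansion, strand arithmetic and base-preference profiles.

The base-preference profile of a DBD type is the positional probability
P_j(X) of observing base X at position j among the known interacting binding
sites of that DBD type, estimated separately for every binding-site length L:

    P_j(X) = (1/N) * sum_i 1[site_i has base X at position j]

with N the number of interactions of that (DBD type, L).  Every column of the
resulting L x 4 matrix sums to one.  No pseudocounts are added by default:
a zero probability is informative to the downstream encoder (it zeroes the
feature of an unseen base).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .constants import BASE_INDEX, BASE_ORDER, COMPLEMENT, DNA_BASES, IUPAC_CODES
from .errors import AlphabetError, CappedExpansionError, InvariantError, NoDataError, ParseError

#: Default ceiling on the number of concrete sequences one motif may expand to.
DEFAULT_EXPANSION_CAP = 65536


@dataclass(frozen=True)
class BasePreferenceProfile:
    """Positional base probabilities for one (DBD type, length) group.

    ``matrix`` has shape (L, 4) with columns in base order A, T, C, G;
    every row sums to 1.  ``n`` is the number of interactions averaged.
    """

    dbd_type: str
    length: int
    matrix: np.ndarray
    n: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.length, 4):
            raise InvariantError(f"profile matrix shape {m.shape} != ({self.length}, 4)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise InvariantError("profile entries must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise InvariantError("profile rows must each sum to 1")
        if self.n < 1:
            raise InvariantError("profile must be estimated from at least one interaction")
        object.__setattr__(self, "matrix", m)

    def prob(self, position: int, base: str) -> float:
        """P_j(X) with 0-based ``position`` and ``base`` in A/T/C/G."""
        return float(self.matrix[position, BASE_INDEX[base]])


def expansion_size(iupac: str) -> int:
    """Number of concrete sequences an IUPAC motif denotes (product of degeneracies)."""
    size = 1
    for c in iupac:
        if c not in IUPAC_CODES:
            raise AlphabetError(f"non-IUPAC character {c!r} in motif {iupac!r}")
        size *= len(IUPAC_CODES[c])
    return size


def expand_iupac(iupac: str, cap: int = DEFAULT_EXPANSION_CAP) -> set[str]:
    """Fully expand an IUPAC motif into its set of concrete A/C/G/T sequences.

    Raises :class:`CappedExpansionError` (carrying the true cardinality) if the
    expansion would exceed ``cap``.
    """
    iupac = iupac.upper()
    size = expansion_size(iupac)
    if size > cap:
        raise CappedExpansionError(
            f"motif {iupac!r} expands to {size} sequences (cap {cap})", cardinality=size
        )
    return {"".join(t) for t in itertools.product(*(IUPAC_CODES[c] for c in iupac))}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    bad = set(seq) - set(DNA_BASES)
    if bad:
        raise AlphabetError(f"non-ACGT character(s) {sorted(bad)} in sequence")
    return seq.translate(COMPLEMENT)[::-1]


def compute_base_preference(
    positives, dbd_type: str, length: int, pseudocount: float = 0.0
) -> BasePreferenceProfile:
    """Estimate the base-preference profile from positive interaction records.

    All ``positives`` must carry the given ``dbd_type``, a concrete sequence of
    the given ``length``, and a positive label.  ``pseudocount`` (alpha) is
    added to every cell of the count matrix before normalising; the default 0
    reproduces the plain empirical frequency.
    """
    records = list(positives)
    if not records:
        raise NoDataError(f"no positive interactions for ({dbd_type}, L={length})")
    counts = np.full((length, 4), float(pseudocount))
    for rec in records:
        if rec.label != 1:
            raise InvariantError("profiles are estimated from positive records only")
        if rec.dbd_type != dbd_type:
            raise InvariantError(f"record DBD type {rec.dbd_type!r} != {dbd_type!r}")
        seq = rec.tfbs_sequence
        if len(seq) != length:
            raise InvariantError(f"mixed lengths: {len(seq)} != {length}")
        for j, base in enumerate(seq):
            if base not in BASE_INDEX:
                raise AlphabetError(f"non-ACGT base {base!r} in {seq!r}")
            counts[j, BASE_INDEX[base]] += 1.0
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return BasePreferenceProfile(dbd_type=dbd_type, length=length, matrix=matrix, n=len(records))


# ---------------------------------------------------------------------------
# Minimal MEME motif text format
# ---------------------------------------------------------------------------

_MEME_HEADER = "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n" \
    "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n"

# MEME letter-probability columns are alphabetical A C G T, not the feature order.
_MEME_ORDER = "ACGT"


def profile_to_meme(profile: BasePreferenceProfile, name: str | None = None) -> str:
    """Serialise a profile as a minimal MEME-format motif block."""
    name = name or f"{profile.dbd_type}_L{profile.length}"
    lines = [_MEME_HEADER, f"\nMOTIF {name}\n",
             f"letter-probability matrix: alength= 4 w= {profile.length} "
             f"nsites= {profile.n} E= 0\n"]
    for j in range(profile.length):
        row = " ".join(f"{profile.prob(j, b):.6f}" for b in _MEME_ORDER)
        lines.append(f" {row}\n")
    return "".join(lines)


def meme_to_profile(text: str, dbd_type: str = "") -> BasePreferenceProfile:
    """Parse a minimal MEME motif block back into a profile.

    Only the first motif block is read.  The motif name is used for
    ``dbd_type`` when none is given (the ``_L<len>`` suffix is stripped).
    """
    lines = text.splitlines()
    name, width, nsites, rows = None, None, 1, []
    it = iter(enumerate(lines, start=1))
    for lineno, line in it:
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"MEME motif line {lineno}: missing motif name")
            name = parts[1]
        elif line.startswith("letter-probability matrix:"):
            tokens = line.replace(":", " ").split()
            for key, val in zip(tokens, tokens[1:]):
                if key == "w=":
                    width = int(val)
                elif key == "nsites=":
                    nsites = int(val)
            if width is None:
                raise ParseError(f"MEME matrix line {lineno}: missing w=")
            for _ in range(width):
                lineno, line = next(it)
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ParseError(f"MEME matrix line {lineno}: expected 4 probabilities")
                rows.append(vals)
            break
    if width is None or len(rows) != width:
        raise ParseError("no letter-probability matrix found in MEME text")
    acgt = np.array(rows)
    # reorder columns from MEME's A C G T to the feature order A T C G
    matrix = acgt[:, [_MEME_ORDER.index(b) for b in BASE_ORDER]]
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    if not dbd_type:
        dbd_type = (name or "motif").rsplit("_L", 1)[0]
    return BasePreferenceProfile(dbd_type=dbd_type, length=width, matrix=matrix, n=nsites)
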