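"""Alphabets and catalogue-wide constants."""

DNA_BASES = "ACGT"

#: Feature-block base order within each TFBS position (A, T, C, G).
BASE_ORDER = "ATCG"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: IUPAC degenerate nucleotide codes mapped to the concrete bases they stand for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Two-base ambiguity codes, keyed by the sorted base pair they merge.
TWO_BASE_CODES = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Amino-acid binding-mode classes: hydrogen bonding, van der Waals, weak binding.
HB_RESIDUES = frozenset("RKHSNQDE")
DW_RESIDUES = frozenset("FPTGAVLIY")
WB_RESIDUES = frozenset("CMW")

#: Binding-site length range modelled (nine per-length groups).
MIN_TFBS_LEN = 7
MAX_TFBS_LEN = 15
TFBS_LENGTHS = tuple(range(MIN_TFBS_LEN, MAX_TFBS_LEN + 1))

#: Default operating probability threshold for calling an interaction.
DEFAULT_THRESHOLD = 0.7
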