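"""Readers and writers for the package's exchange formats.

The canonical interaction-catalogue exchange format is a 7-column TSV with
header ``tf_id  species  family  dbd_type  dbd_sequence  motif_id  iupac``:
one row per TF-motif link, TF attributes repeated on every row.  Exports from
motif databases (e.g. CIS-BP ``TF_Information`` plus consensus motifs) can be
flattened into this shape with one join.

Other formats handled here: FASTA (sequences), predictions TSV, BED6 scan hits.
Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import DNA_BASES, IUPAC_CODES, MAX_TFBS_LEN, MIN_TFBS_LEN, STANDARD_AA
from .errors import InvariantError, ParseError, SchemaError

CATALOGUE_COLUMNS = ["tf_id", "species", "family", "dbd_type", "dbd_sequence", "motif_id", "iupac"]

PREDICTION_COLUMNS = [
    "tf_id", "dbd_type", "tfbs_sequence", "length",
    "prob_rp", "prob_rw", "consensus_label", "threshold",
]


@dataclass(frozen=True)
class TfRecord:
    """A transcription factor: the protein side of an interaction pair.

    ``dbd_type`` is the single DNA-binding-domain type of a monotypic TF;
    ``dbd_sequence`` is the domain's amino-acid sequence in one-letter codes.
    """

    tf_id: str
    species: str
    family: str
    dbd_type: str
    dbd_sequence: str


@dataclass(frozen=True)
class TfbsMotif:
    """A binding-site motif in IUPAC degenerate notation, length 7-15 bp."""

    motif_id: str
    iupac: str

    @property
    def length(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class InteractionRecord:
    """A labelled (DBD, concrete TFBS) pair.

    ``tfbs_sequence`` is a fully expanded A/C/G/T string; ``source`` records
    how the pair arose (experimental positives, RP/RW negatives, or a promoter
    scan query).
    """

    tf_id: str
    dbd_type: str
    dbd_sequence: str
    tfbs_sequence: str
    label: int  # 1 = positive (interacting), 0 = negative
    source: str = "experimental"

    @property
    def length(self) -> int:
        return len(self.tfbs_sequence)


@dataclass
class FilterReport:
    """Counts of catalogue rows dropped per filtering rule."""

    n_input_rows: int = 0
    duplicate_links: int = 0
    polytypic_tfs: int = 0
    length_filtered: int = 0
    invalid_records: int = 0
    n_retained_links: int = 0
    messages: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased with whitespace and gap characters removed.
    Raises :class:`ParseError` (naming the line) on an empty file or content
    before the first header.
    """
    text = Path(path).read_text()
    first_content_line = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            first_content_line = (lineno, line)
            break
    if first_content_line is None:
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    lineno, line = first_content_line
    if not line.startswith(">"):
        raise ParseError(f"{path}: expected FASTA header at line {lineno}, got {line[:30]!r}")

    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        records.append((rec.id, seq))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with ``width``-column wrapping."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Interaction catalogue
# ---------------------------------------------------------------------------

def _validate_row(tf_id, dbd_sequence, iupac, strict: bool, report: FilterReport) -> bool:
    """Return True if the row passes alphabet checks; count/raise otherwise."""
    bad = None
    aa = str(dbd_sequence).upper()
    if not aa or any(c not in STANDARD_AA for c in aa):
        bad = f"TF {tf_id}: non-standard amino-acid letter in DBD sequence"
    motif = str(iupac).upper()
    if bad is None and (not motif or any(c not in IUPAC_CODES for c in motif)):
        bad = f"TF {tf_id}: non-IUPAC character in motif {motif!r}"
    if bad is None:
        return True
    if strict:
        raise ParseError(bad)
    report.invalid_records += 1
    report.messages.append(bad)
    return False


def read_interaction_catalogue(
    path, strict: bool = True
) -> tuple[list[TfRecord], list[TfbsMotif], list[tuple[str, str]], FilterReport]:
    """Load and filter a catalogue TSV.

    Filters applied, in order: alphabet validation (strict mode aborts on a bad
    record, lenient mode drops it), exact (tf_id, motif_id) link de-duplication
    (first occurrence wins), removal of polytypic TFs (more than one DBD type),
    and removal of motifs shorter than 7 or longer than 15 bp.  Returns the
    retained TFs, motifs, links, and a :class:`FilterReport`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing catalogue column(s) {missing}")

    report = FilterReport(n_input_rows=len(df))
    for col in ("dbd_sequence", "iupac"):
        df[col] = df[col].astype(str).str.upper()

    keep = df.apply(
        lambda r: _validate_row(r.tf_id, r.dbd_sequence, r.iupac, strict, report), axis=1
    )
    df = df[keep] if len(df) else df

    n = len(df)
    df = df.drop_duplicates(subset=["tf_id", "motif_id"], keep="first")
    report.duplicate_links = n - len(df)

    types_per_tf = df.groupby("tf_id")["dbd_type"].nunique()
    polytypic = set(types_per_tf[types_per_tf > 1].index)
    report.polytypic_tfs = len(polytypic)
    df = df[~df["tf_id"].isin(polytypic)]

    lengths = df["iupac"].str.len()
    bad_len = (lengths < MIN_TFBS_LEN) | (lengths > MAX_TFBS_LEN)
    report.length_filtered = int(bad_len.sum())
    df = df[~bad_len]

    report.n_retained_links = len(df)

    tfs, seen_tf = [], set()
    motifs, seen_motif = [], set()
    links = []
    for row in df.itertuples(index=False):
        if row.tf_id not in seen_tf:
            seen_tf.add(row.tf_id)
            tfs.append(TfRecord(row.tf_id, row.species, row.family, row.dbd_type, row.dbd_sequence))
        if row.motif_id not in seen_motif:
            seen_motif.add(row.motif_id)
            motifs.append(TfbsMotif(row.motif_id, row.iupac))
        links.append((row.tf_id, row.motif_id))
    return tfs, motifs, links, report


def write_interaction_catalogue(path, df: pd.DataFrame) -> None:
    """Write a catalogue DataFrame (7-column schema) as TSV."""
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write catalogue, missing column(s) {missing}")
    df.to_csv(path, sep="\t", index=False, columns=CATALOGUE_COLUMNS)


def positives_from_catalogue(tfs, motifs, links, cap: int | None = None) -> list[InteractionRecord]:
    """Expand a filtered catalogue into concrete positive interaction records.

    Each linked IUPAC motif is fully expanded; duplicate (tf_id, sequence)
    pairs arising from overlapping expansions are kept once (non-redundant
    interactions).  Records are returned sorted by (tf_id, sequence).
    """
    from .motif_tools import DEFAULT_EXPANSION_CAP, expand_iupac

    tf_by_id = {t.tf_id: t for t in tfs}
    motif_by_id = {m.motif_id: m for m in motifs}
    cap = DEFAULT_EXPANSION_CAP if cap is None else cap
    seen, records = set(), []
    for tf_id, motif_id in links:
        tf, motif = tf_by_id[tf_id], motif_by_id[motif_id]
        for seq in sorted(expand_iupac(motif.iupac, cap=cap)):
            if (tf_id, seq) in seen:
                continue
            seen.add((tf_id, seq))
            records.append(InteractionRecord(
                tf_id=tf_id, dbd_type=tf.dbd_type, dbd_sequence=tf.dbd_sequence,
                tfbs_sequence=seq, label=1, source="experimental",
            ))
    records.sort(key=lambda r: (r.tf_id, r.tfbs_sequence))
    return records


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(path, results: Iterable, threshold: float) -> None:
    """Write paired RP/RW probabilities as a predictions TSV.

    ``results`` items expose ``tf_id, dbd_type, tfbs_sequence, prob_rp,
    prob_rw`` (attributes or mapping keys).  A pair is labelled
    ``interacting`` when both probabilities reach ``threshold``.  Rows are
    sorted by (tf_id, tfbs_sequence) for deterministic output.
    """
    rows = []
    for r in results:
        get = (lambda k, r=r: r[k]) if isinstance(r, dict) else (lambda k, r=r: getattr(r, k))
        prob_rp, prob_rw = float(get("prob_rp")), float(get("prob_rw"))
        label = "interacting" if min(prob_rp, prob_rw) >= threshold else "non-interacting"
        rows.append({
            "tf_id": get("tf_id"), "dbd_type": get("dbd_type"),
            "tfbs_sequence": get("tfbs_sequence"), "length": len(get("tfbs_sequence")),
            "prob_rp": prob_rp, "prob_rw": prob_rw,
            "consensus_label": label, "threshold": threshold,
        })
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df = df.sort_values(["tf_id", "tfbs_sequence"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    """Read back a predictions TSV written by :func:`write_predictions`."""
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "dbd_type": str, "tfbs_sequence": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing prediction column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# BED hits
# ---------------------------------------------------------------------------

def write_hits_bed(path, hits: Sequence) -> None:
    """Write scan hits as BED6.

    chrom = promoter id, interval 0-based half-open on the forward strand,
    name = tf_id, score = round(1000 * min(prob_rp, prob_rw)), strand.
    Hits are sorted by (chrom, start, end, strand, name).
    """
    lines = []
    for h in hits:
        w = getattr(h, "window", h)
        start, end = int(w.start), int(w.end)
        if start >= end or start < 0:
            raise InvariantError(f"invalid BED interval [{start}, {end}) for {w.promoter_id}")
        score = int(round(1000 * min(float(h.prob_rp), float(h.prob_rw))))
        lines.append((w.promoter_id, start, end, h.tf_id, score, w.strand))
    lines.sort(key=lambda t: (t[0], t[1], t[2], t[5], t[3]))
    with open(path, "w") as fh:
        for t in lines:
            fh.write("\t".join(map(str, t)) + "\n")
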