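"""Synthetic catalogues, promoters and ground truth.

The generator emulates the statistical structure the predictor assumes:
each DBD type has a planted positional base preference, its binding sites
are drawn column-wise from that preference, and its TF domain sequences are
biased toward one binding-mode residue class so the protein features carry
type signal too.

``planting_strength`` s interpolates each profile column between a random
one-hot (s = 1, every site of a type/length identical to the consensus) and
the uniform distribution (s = 0, sites carry no type information):

    column = s * one_hot + (1 - s) * 0.25

The default configuration is the package's reference benchmark: 2 DBD types,
50 TFs per type, one motif per TF per length (7-15 bp), s = 1, no IUPAC
degeneracy — every per-length model then trains on ~100 positive and ~100
negative pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    BASE_ORDER, DW_RESIDUES, HB_RESIDUES, TFBS_LENGTHS, TWO_BASE_CODES, WB_RESIDUES,
)
from .errors import ConfigurationError, InvariantError
from .io_tables import CATALOGUE_COLUMNS, write_fasta, write_interaction_catalogue
from .motif_tools import BasePreferenceProfile, reverse_complement

_CLASS_CYCLE = (tuple(sorted(HB_RESIDUES)), tuple(sorted(DW_RESIDUES)), tuple(sorted(WB_RESIDUES)))
_ALL_AA = tuple(sorted(HB_RESIDUES | DW_RESIDUES | WB_RESIDUES))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study conditions."""

    n_dbd_types: int = 2
    tfs_per_type: int = 50
    motifs_per_type: int = 50  # motifs per (DBD type, length) cell
    lengths: tuple = TFBS_LENGTHS
    length_weights: tuple | None = None  # relative motif mass per length; None = uniform
    planting_strength: float = 1.0
    iupac_degeneracy_rate: float = 0.0
    dbd_length: tuple = (40, 80)
    class_bias: float = 0.6  # probability a DBD residue comes from the type's favoured class
    seed: int = 0

    def __post_init__(self):
        if min(self.n_dbd_types, self.tfs_per_type, self.motifs_per_type) < 1:
            raise InvariantError("all synthetic counts must be >= 1")
        for name in ("planting_strength", "iupac_degeneracy_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvariantError(f"{name} must lie in [0, 1], got {v}")
        if self.length_weights is not None and len(self.length_weights) != len(self.lengths):
            raise InvariantError("length_weights must match lengths")

    def motifs_at(self, length: int) -> int:
        """Motif count for one (type, length) cell under the length distribution."""
        if self.length_weights is None:
            return self.motifs_per_type
        w = np.asarray(self.length_weights, dtype=float)
        w = w / w.sum()
        i = list(self.lengths).index(length)
        return int(round(self.motifs_per_type * len(self.lengths) * w[i]))


@dataclass
class SyntheticCatalogue:
    """A generated catalogue plus its ground truth."""

    df: pd.DataFrame
    profiles: dict[tuple[str, int], BasePreferenceProfile]
    config: SyntheticConfig

    def positives(self, cap: int | None = None):
        """Expand the catalogue into positive interaction records."""
        from .io_tables import TfbsMotif, TfRecord, positives_from_catalogue

        tfs, motifs, links = {}, {}, []
        for r in self.df.itertuples(index=False):
            tfs.setdefault(r.tf_id, TfRecord(r.tf_id, r.species, r.family,
                                             r.dbd_type, r.dbd_sequence))
            motifs.setdefault(r.motif_id, TfbsMotif(r.motif_id, r.iupac))
            links.append((r.tf_id, r.motif_id))
        return positives_from_catalogue(tfs.values(), motifs.values(), links, cap=cap)


def _dbd_type_names(n: int) -> list[str]:
    return [f"DBD{i:02d}" for i in range(n)]


def sample_planted_profiles(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[tuple[str, int], BasePreferenceProfile]:
    """One planted profile per (DBD type, length): s * one-hot + (1-s) * uniform."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s = config.planting_strength
    profiles = {}
    for dbd_type in _dbd_type_names(config.n_dbd_types):
        for L in config.lengths:
            hot = rng.integers(0, 4, size=L)
            matrix = np.full((L, 4), (1 - s) / 4)
            matrix[np.arange(L), hot] += s
            profiles[(dbd_type, L)] = BasePreferenceProfile(
                dbd_type=dbd_type, length=L, matrix=matrix, n=1
            )
    return profiles


def _draw_site(profile: BasePreferenceProfile, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=profile.matrix[j]) for j in range(profile.length)]
    return "".join(BASE_ORDER[c] for c in cols)


def _degenerate(seq: str, profile: BasePreferenceProfile, rate: float,
                rng: np.random.Generator) -> str:
    """Merge the drawn base with the profile's strongest other base, per position."""
    if rate == 0:
        return seq
    out = []
    for j, base in enumerate(seq):
        if rng.random() < rate:
            order = np.argsort(-profile.matrix[j], kind="stable")
            partner = next(BASE_ORDER[i] for i in order if BASE_ORDER[i] != base)
            out.append(TWO_BASE_CODES[frozenset((base, partner))])
        else:
            out.append(base)
    return "".join(out)


def _dbd_sequence(favoured: tuple, config: SyntheticConfig, rng: np.random.Generator) -> str:
    lo, hi = config.dbd_length
    length = int(rng.integers(lo, hi + 1))
    letters = []
    for _ in range(length):
        pool = favoured if rng.random() < config.class_bias else _ALL_AA
        letters.append(pool[rng.integers(len(pool))])
    return "".join(letters)


def sample_catalogue(config: SyntheticConfig) -> SyntheticCatalogue:
    """Generate a catalogue TSV-shaped DataFrame with planted structure.

    Per DBD type: ``tfs_per_type`` TFs with class-biased domain sequences;
    per (type, length): ``motifs_at(L)`` motifs drawn from the planted profile
    and assigned round-robin to the type's TFs.  With a nonzero
    ``iupac_degeneracy_rate`` individual motif positions are widened to the
    2-base IUPAC code joining the drawn base and the profile's strongest
    alternative.  The same seed yields a byte-identical catalogue.
    """
    rng = np.random.default_rng(config.seed)
    profiles = sample_planted_profiles(config, rng)
    rows = []
    for t_idx, dbd_type in enumerate(_dbd_type_names(config.n_dbd_types)):
        favoured = _CLASS_CYCLE[t_idx % len(_CLASS_CYCLE)]
        tfs = [
            (f"{dbd_type}_TF{j:03d}", _dbd_sequence(favoured, config, rng))
            for j in range(config.tfs_per_type)
        ]
        for L in config.lengths:
            profile = profiles[(dbd_type, L)]
            for m in range(config.motifs_at(L)):
                site = _draw_site(profile, rng)
                iupac = _degenerate(site, profile, config.iupac_degeneracy_rate, rng)
                tf_id, dbd_seq = tfs[m % config.tfs_per_type]
                rows.append({
                    "tf_id": tf_id, "species": "synthetic", "family": f"FAM_{dbd_type}",
                    "dbd_type": dbd_type, "dbd_sequence": dbd_seq,
                    "motif_id": f"{dbd_type}_L{L}_M{m:03d}", "iupac": iupac,
                })
    df = pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)
    return SyntheticCatalogue(df=df, profiles=profiles, config=config)


@dataclass(frozen=True)
class SpikeTruth:
    """Ground-truth record of one embedded binding site."""

    dbd_type: str
    start: int
    end: int
    strand: str
    sequence: str  # the site as read on its own strand


def sample_promoter_with_spikes(
    length: int,
    spikes,
    config: SyntheticConfig,
    profiles: dict | None = None,
    seed: int | None = None,
) -> tuple[str, list[SpikeTruth]]:
    """A uniform-background promoter with binding sites embedded at known spots.

    ``spikes`` is a list of (dbd_type, site_length, position, strand).  Each
    embedded site is drawn from the type's planted profile; on the minus
    strand the promoter carries its reverse complement.  Overlapping spikes
    raise :class:`ConfigurationError`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    profiles = profiles if profiles is not None else sample_planted_profiles(config)
    seq = list(rng.choice(list(BASE_ORDER), size=length))
    occupied: list[tuple[int, int]] = []
    truths = []
    for dbd_type, site_len, position, strand in spikes:
        start, end = position, position + site_len
        if not (0 <= start < end <= length):
            raise ConfigurationError(f"spike [{start}, {end}) outside promoter of length {length}")
        if any(start < e and s < end for s, e in occupied):
            raise ConfigurationError(f"spike [{start}, {end}) overlaps another spike")
        occupied.append((start, end))
        profile = profiles[(dbd_type, site_len)]
        site = _draw_site(profile, rng)
        forward = site if strand == "+" else reverse_complement(site)
        seq[start:end] = list(forward)
        truths.append(SpikeTruth(dbd_type=dbd_type, start=start, end=end,
                                 strand=strand, sequence=site))
    return "".join(seq), truths


def benchmark_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The reference benchmark conditions (see module docstring)."""
    return replace(SyntheticConfig(), seed=seed, **overrides)


def write_bundle(directory, catalogue: SyntheticCatalogue,
                 promoter: tuple[str, str] | None = None,
                 truths: list[SpikeTruth] | None = None) -> None:
    """Write catalogue TSV (+ optional promoter FASTA / truth BED / manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_interaction_catalogue(directory / "catalogue.tsv", catalogue.df)
    if promoter is not None:
        prom_id, prom_seq = promoter
        write_fasta(directory / "promoter.fa", [(prom_id, prom_seq)])
        if truths:
            with open(directory / "truth.bed", "w") as fh:
                for t in truths:
                    fh.write(f"{prom_id}\t{t.start}\t{t.end}\t{t.dbd_type}\t0\t{t.strand}\n")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(catalogue.config).items()}
    (directory / "manifest.json").write_text(json.dumps(cfg, indent=2))
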