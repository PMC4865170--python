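"""Sequence and matrix I/O, labeled promoter sets, and random-background construction.

DNA fragments are grouped into labeled sets: the positive set of
tumor-specific promoters (``TSP``), the negative set of fragments that
initiate no transcription (``NP``), an independent holdout of weaker
tumor promoters (``lowTSP``), a genomic random background (``RP``) and
engineered products (``designed``).  All coordinates in this package are
0-based, half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_LABELS = ("TSP", "NP", "lowTSP", "RP", "designed")
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single uppercase DNA fragment with a set label."""

    id: str
    sequence: str
    label: str = "designed"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.label not in VALID_LABELS:
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")
        seq = self.sequence.upper()
        for pos, base in enumerate(seq):
            if base not in _ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: invalid character {base!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterSet:
    """An ordered collection of records sharing one label, unique ids."""

    name: str
    records: list[SequenceRecord] = field(default_factory=list)
    label: str = "designed"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in set {self.name!r}")
            seen.add(rec.id)
            if rec.label != self.label:
                raise ValueError(
                    f"record {rec.id!r} has label {rec.label!r}, set expects {self.label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def lengths(self) -> list[int]:
        return [r.length for r in self.records]


def read_fasta(path, label: str = "designed") -> PromoterSet:
    """Read a FASTA file into a PromoterSet with the given label.

    The id is the header token before the first whitespace; sequences are
    uppercased and validated against {A,C,G,T,N}.
    """
    records = []
    with open(path) as handle:
        text = handle.read()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, line in enumerate(text.splitlines()) if line.strip()
        )
        raise ValueError(f"{path}: not FASTA — line {first_bad} does not start a record")
    for bio_rec in _BioSeqIO.parse(io.StringIO(text), "fasta"):
        records.append(SequenceRecord(id=bio_rec.id, sequence=str(bio_rec.seq), label=label))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    import os

    return PromoterSet(name=os.path.basename(str(path)), records=records, label=label)


def write_fasta(pset: PromoterSet, path) -> None:
    """Write a PromoterSet as 60-column wrapped FASTA."""
    if len(pset) == 0:
        raise ValueError("refusing to write an empty set")
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in pset
    ]
    with open(path, "w") as handle:
        _BioSeqIO.write(bio, handle, "fasta")


def read_matrix(path, feature_id: str | None = None):
    """Read a plain-text 4-row count (or probability) matrix.

    Format: four rows labeled ``A:``, ``C:``, ``G:``, ``T:`` with
    whitespace-separated non-negative numbers; equal column counts.
    Columns summing to ~1 are treated as probabilities, otherwise counts.
    Returns a :class:`promdissect.features.WeightMatrix`.
    """
    from .features import WeightMatrix

    rows: dict[str, list[float]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, _, rest = line.partition(":")
            base = head.strip().upper()
            if base not in "ACGT" or len(base) != 1:
                raise ValueError(f"{path}: unrecognized row label {head!r}")
            values = [float(tok) for tok in rest.split()]
            if any(v < 0 for v in values):
                raise ValueError(f"{path}: negative value in row {base}")
            rows[base] = values
    if sorted(rows) != ["A", "C", "G", "T"]:
        raise ValueError(f"{path}: expected rows A, C, G, T, got {sorted(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(widths)}")
    counts = np.array([rows[b] for b in "ACGT"], dtype=float)
    if feature_id is None:
        import os

        feature_id = os.path.splitext(os.path.basename(str(path)))[0]
    col_sums = counts.sum(axis=0)
    if np.allclose(col_sums, 1.0, atol=1e-3):
        return WeightMatrix.from_probabilities(feature_id, counts)
    return WeightMatrix.from_counts(feature_id, counts)


def write_matrix(matrix, path) -> None:
    """Write a WeightMatrix's probability rows in the 4-row text format."""
    with open(path, "w") as handle:
        for i, base in enumerate("ACGT"):
            vals = " ".join(f"{v:.6f}" for v in matrix.probabilities[i])
            handle.write(f"{base}: {vals}\n")


def make_random_promoter_set(
    genome: SequenceRecord,
    length_donor: PromoterSet,
    n: int,
    seed: int,
    name: str = "RP",
) -> PromoterSet:
    """Cut ``n`` random fragments from a genome, lengths drawn from the donor set.

    Fragment lengths are sampled with replacement from the donor's empirical
    length distribution; start positions are uniform over the valid range, so
    fragments may overlap.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    donor_lengths = np.asarray(length_donor.lengths, dtype=int)
    if donor_lengths.max() > genome.length:
        raise ValueError("genome shorter than the longest donor fragment")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(donor_lengths, size=n, replace=True)
    records = []
    for i, length in enumerate(lengths):
        start = int(rng.integers(0, genome.length - int(length) + 1))
        frag = genome.sequence[start : start + int(length)]
        records.append(SequenceRecord(id=f"{name}_{i + 1}", sequence=frag, label="RP"))
    return PromoterSet(name=name, records=records, label="RP")


def write_hits_tsv(hits, path) -> None:
    """Write feature hits as BED-like TSV: seq_id, start, end, feature_id, score, strand."""
    with open(path, "w") as handle:
        handle.write("seq_id\tstart\tend\tfeature_id\tscore\tstrand\n")
        for h in hits:
            handle.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.feature_id}\t{h.score:.4f}\t{h.strand}\n"
            )
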