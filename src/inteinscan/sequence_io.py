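"""Sequence input/output, ORF finding and translation.

All coordinates are 0-based, half-open on the forward strand; human-facing
report writers convert to 1-based inclusive at the last moment.  Reverse-strand
ORFs are reported in forward-strand coordinates with ``strand == '-'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("inteinscan")

DNA_CHARS = set("ACGTUNRYSWKMBDHV")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input."""


class AlphabetError(ValueError):
    """Raised when a record has the wrong alphabet for an operation."""


@dataclass
class SequenceRecord:
    """A single named sequence with a declared alphabet (``dna`` or ``protein``)."""

    id: str
    description: str
    seq: str
    alphabet: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_CHARS if self.alphabet == "dna" else PROTEIN_CHARS
        bad = set(self.seq.upper()) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains characters {sorted(bad)} not in the "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OrfRecord:
    """An open reading frame located on a genome, forward-strand coordinates.

    ``end`` is exclusive and includes the stop codon; ``protein`` excludes it.
    ``has_stop`` is False only for open-ended ORFs (optional, off by default),
    whose span then contains no stop codon.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span not divisible by 3")
        expected = (self.end - self.start) // 3 - (1 if self.has_stop else 0)
        if len(self.protein) != expected:
            raise ValueError("protein length inconsistent with ORF span")


def _infer_alphabet(seq: str) -> str:
    letters = set(seq.upper())
    return "dna" if letters <= DNA_CHARS else "protein"


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file.

    The record id is the first whitespace-delimited token of the header; the
    remainder becomes the description.  Duplicate ids and empty files are
    format errors.  ``alphabet`` may be ``dna``, ``protein`` or ``auto``
    (inferred per record from the character set).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).strip()
        desc = rec.description[len(rec.id):].strip()
        ab = _infer_alphabet(seq) if alphabet == "auto" else alphabet
        records.append(SequenceRecord(id=rec.id, description=desc, seq=seq, alphabet=ab))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank_cds(path: str | Path) -> list[SequenceRecord]:
    """Extract CDS /translation products from a GenBank flat file (read-only).

    Features other than CDS-with-translation are ignored with a logged warning.
    """
    proteins: list[SequenceRecord] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            trans = feat.qualifiers.get("translation")
            if not trans:
                skipped += 1
                continue
            locus = feat.qualifiers.get("locus_tag", [f"{rec.id}_cds{i}"])[0]
            proteins.append(
                SequenceRecord(id=locus, description=rec.id, seq=trans[0], alphabet="protein")
            )
    if skipped:
        logger.warning("read_genbank_cds: skipped %d CDS features lacking /translation", skipped)
    return proteins


MANIFEST_COLUMNS = ["genome_id", "cluster", "genome_length_bp", "cds_count"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated survey manifest.

    Required columns: genome_id, cluster, genome_length_bp, cds_count
    (cds_count may be empty).  Lines starting with '#' are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if df["genome_id"].duplicated().any():
        dupes = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome ids in manifest: {dupes}")
    return df


def _codon_map(table: int) -> dict[str, str]:
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[table]
    m = dict(tab.forward_table)
    for stop in tab.stop_codons:
        m[stop] = "*"
    return m


_CODON_MAPS: dict[int, dict[str, str]] = {}


def translate(dna: str, table: int = 11) -> str:
    """Translate a nucleotide string with the bacterial/plastid code (table 11).

    Codons containing unresolved ambiguity codes translate to 'X'.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not divisible by 3")
    if table not in _CODON_MAPS:
        _CODON_MAPS[table] = _codon_map(table)
    cmap = _CODON_MAPS[table]
    s = dna.upper().replace("U", "T")
    return "".join(cmap.get(s[i : i + 3], "X") for i in range(0, len(s), 3))


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _scan_strand(seq: str, genome_id: str, min_aa: int, start_codons: Sequence[str],
                 strand: str, genome_len: int, include_open: bool) -> list[OrfRecord]:
    """Scan three frames of one strand; ``seq`` is already in reading orientation."""
    orfs: list[OrfRecord] = []
    n = len(seq)
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        for i in range(frame, n - 2, 3):
            if seq[i : i + 3] not in start_codons:
                continue
            stop = next((s for s in stops if s >= i + 3), None)
            if stop is not None:
                s, e, has_stop = i, stop + 3, True
                protein = translate(seq[s:e])[:-1]
            elif include_open:
                s = i
                e = i + ((n - i) // 3) * 3
                has_stop = False
                protein = translate(seq[s:e])
            else:
                continue
            if len(protein) < min_aa:
                continue
            if strand == "+":
                fs, fe = s, e
            else:
                fs, fe = genome_len - e, genome_len - s
            orfs.append(OrfRecord(genome_id=genome_id, start=fs, end=fe,
                                  strand=strand, frame=frame, protein=protein,
                                  has_stop=has_stop))
    return orfs


def find_orfs(genome: SequenceRecord, min_aa: int,
              start_codons: Sequence[str] = DEFAULT_START_CODONS,
              include_open: bool = False) -> list[OrfRecord]:
    """Find all ORFs (every start codon to its nearest in-frame stop), both strands.

    Start codons default to ATG/GTG/TTG.  ORFs without an in-frame stop before
    the sequence end are dropped unless ``include_open`` is set (such records
    have ``has_stop=False``).  Results are sorted by (start, end, strand);
    protein length must be >= ``min_aa``.
    """
    if genome.alphabet != "dna":
        raise AlphabetError("find_orfs requires a DNA record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = genome.seq.upper()
    fwd = _scan_strand(seq, genome.id, min_aa, start_codons, "+", len(seq), include_open)
    rev = _scan_strand(reverse_complement(seq), genome.id, min_aa, start_codons, "-",
                       len(seq), include_open)
    return sorted(fwd + rev, key=lambda o: (o.start, o.end, o.strand))


def orf_protein_records(orfs: Iterable[OrfRecord]) -> list[SequenceRecord]:
    """Wrap ORF proteins as SequenceRecords with ids ``<genome>|<start>-<end><strand>``."""
    out = []
    for o in orfs:
        out.append(SequenceRecord(
            id=f"{o.genome_id}|{o.start}-{o.end}{o.strand}",
            description=f"frame={o.frame}",
            seq=o.protein, alphabet="protein"))
    return out
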