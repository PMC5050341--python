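"""Insertion-site mapping onto reference exteins and functional-category tallies.

An insertion site is expressed in reference-extein coordinates: ``ref_column``
is the 0-based reference position aligned to the last N-extein residue (the
residue immediately preceding the intein).  Two inteins share a site label iff
they map to the same family and the exact same reference column; sites one
residue apart are distinct.  The packaged reference exteins and motif intervals
are synthetic stand-ins that encode the qualitative motif layout of terminase
ATPase domains (Walker A/B, C-motif), the RecB PD-(D/E)xK nuclease, the RDF
metallophosphoesterase and the TdS active site.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .intein_caller import InteinCall
from .sequence_io import SequenceRecord, read_fasta

logger = logging.getLogger("inteinscan")

MOTIF_LABELS = {"walker_A", "walker_B", "c_motif", "pd_dexk", "metallophos",
                "active_site", "other"}

DEFAULT_IDENTITY_FLOOR = 25.0  # percent, over >= MIN_ALIGNED_COLUMNS
MIN_ALIGNED_COLUMNS = 50


@dataclass
class AlignmentParams:
    """Conventional protein alignment scoring (BLOSUM62, affine gaps)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    free_end_gaps: bool = True


@dataclass
class ReferenceExtein:
    family: str
    seq: str
    motifs: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        spans = []
        for label, start, end in self.motifs:
            if not (0 <= start < end <= len(self.seq)):
                raise ValueError(f"motif {label} outside {self.family}")
            if label not in MOTIF_LABELS:
                raise ValueError(f"unknown motif label {label!r}")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping motif intervals in {self.family}")

    def motif_at(self, column: int) -> str:
        for label, start, end in self.motifs:
            if start <= column < end:
                return label
        return "none"


@dataclass
class InsertionSite:
    family: str
    ref_column: int
    label: str = ""
    motif_context: str = "none"


class UnassignableFamilyError(ValueError):
    """Extein does not reach the identity floor against the reference."""

    def __init__(self, family: str, best_identity: float):
        self.family = family
        self.best_identity = best_identity
        super().__init__(
            f"extein aligns to {family} at {best_identity:.1f}% identity, "
            f"below the assignment floor")


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    if params.free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _aligned_strings(alignment) -> tuple[str, str]:
    text = str(alignment).splitlines()
    # Bio.Align pretty-printer: rows "target", "", "query" with coordinates;
    # use the indices API instead for robustness.
    a, b = alignment[0], alignment[1]
    return str(a), str(b)


def _column_map(alignment) -> tuple[str, str]:
    return _aligned_strings(alignment)


def aligned_identity(alignment) -> tuple[float, int]:
    """Percent identity over aligned columns, excluding terminal gap overhangs."""
    a, b = _aligned_strings(alignment)
    n = len(a)
    lo = 0
    while lo < n and (a[lo] == "-" or b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols <= 0:
        return 0.0, 0
    ident = sum(1 for i in range(lo, hi) if a[i] == b[i] and a[i] != "-")
    return 100.0 * ident / cols, cols


def map_insertion(call: InteinCall, host_protein: SequenceRecord,
                  reference: ReferenceExtein,
                  params: AlignmentParams | None = None,
                  identity_floor: float = DEFAULT_IDENTITY_FLOOR) -> InsertionSite:
    """Map an intein call onto reference-extein coordinates.

    The inteinless extein (host protein with [start, end) excised) is globally
    aligned to the reference with free end gaps, so extra residues upstream of
    the host protein do not move the mapped column.  ``ref_column`` is the
    reference position aligned to the last N-extein residue; if that residue
    sits in an insertion relative to the reference, the nearest upstream
    aligned reference column is used.
    """
    params = params or AlignmentParams()
    extein = host_protein.seq[:call.start] + host_protein.seq[call.end:]
    if call.start < 1:
        raise ValueError("call has no N-extein residue to anchor the site")
    aligner = _aligner(params)
    alignment = aligner.align(extein, reference.seq)[0]
    identity, cols = aligned_identity(alignment)
    if cols < MIN_ALIGNED_COLUMNS or identity < identity_floor:
        raise UnassignableFamilyError(reference.family, identity)

    target_pos = call.start - 1  # last N-extein residue, extein coordinates
    a, b = _aligned_strings(alignment)
    qi = ri = -1  # last consumed index of extein (a) and reference (b)
    ref_col = None
    for col in range(len(a)):
        if a[col] != "-":
            qi += 1
        if b[col] != "-":
            ri += 1
        if a[col] != "-" and qi == target_pos:
            ref_col = ri if b[col] != "-" else ri  # ri = nearest upstream ref column
            break
    if ref_col is None or ref_col < 0:
        raise UnassignableFamilyError(reference.family, identity)
    return InsertionSite(family=reference.family, ref_column=ref_col,
                         motif_context=reference.motif_at(ref_col))


def best_reference(call: InteinCall, host_protein: SequenceRecord,
                   references: Iterable[ReferenceExtein],
                   params: AlignmentParams | None = None,
                   identity_floor: float = DEFAULT_IDENTITY_FLOOR,
                   ) -> tuple[InsertionSite, float]:
    """Try every reference family; return the site under the best-identity one.

    Raises ``UnassignableFamilyError`` carrying the best identity found when no
    family reaches the floor.
    """
    params = params or AlignmentParams()
    best: tuple[float, ReferenceExtein] | None = None
    aligner = _aligner(params)
    extein = host_protein.seq[:call.start] + host_protein.seq[call.end:]
    for ref in references:
        alignment = aligner.align(extein, ref.seq)[0]
        identity, cols = aligned_identity(alignment)
        if cols < MIN_ALIGNED_COLUMNS:
            continue
        if best is None or identity > best[0]:
            best = (identity, ref)
    if best is None or best[0] < identity_floor:
        raise UnassignableFamilyError(
            best[1].family if best else "(none)", best[0] if best else 0.0)
    site = map_insertion(call, host_protein, best[1], params, identity_floor)
    return site, best[0]


def _letters() -> list[str]:
    base = list(string.ascii_lowercase)
    return base + [x + y for x in base for y in base]


def assign_site_labels(sites: list[InsertionSite]) -> list[InsertionSite]:
    """Letter the unique columns per family: ascending ref_column -> a, b, c...

    Deterministic across runs.  Re-labelling after a new upstream site shifts
    downstream letters; a warning is logged when input sites already carried
    labels that change.
    """
    letters = _letters()
    by_family: dict[str, list[int]] = {}
    for s in sites:
        by_family.setdefault(s.family, []).append(s.ref_column)
    label_map = {
        fam: {col: letters[i] for i, col in enumerate(sorted(set(cols)))}
        for fam, cols in by_family.items()
    }
    out = []
    for s in sites:
        new = label_map[s.family][s.ref_column]
        if s.label and s.label != new:
            logger.warning("site %s:%d relabelled %s -> %s",
                           s.family, s.ref_column, s.label, new)
        out.append(InsertionSite(family=s.family, ref_column=s.ref_column,
                                 label=new, motif_context=s.motif_context))
    return out


def categorize_exteins(calls: list[InteinCall],
                       mapping: Mapping[str, set[str]]) -> pd.DataFrame:
    """Percentage of intein-containing proteins carrying each category.

    One protein may carry several categories, so percentages may sum past 100.
    Families absent from the mapping are tallied under ``unmapped``.
    """
    if not calls:
        return pd.DataFrame(columns=["category", "n_proteins", "percent"])
    proteins: dict[str, set[str]] = {}
    for c in calls:
        cats = mapping.get(c.family or "", None)
        proteins.setdefault(c.protein_id, set()).update(
            cats if cats else {"unmapped"})
    total = len(proteins)
    counts: dict[str, int] = {}
    for cats in proteins.values():
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
    rows = [{"category": cat, "n_proteins": n, "percent": 100.0 * n / total}
            for cat, n in sorted(counts.items())]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged fixtures

def load_reference_exteins() -> dict[str, ReferenceExtein]:
    """Load the packaged synthetic reference exteins and their motif intervals."""
    data = resources.files("inteinscan.data")
    with resources.as_file(data / "synthetic_reference_exteins.fasta") as p:
        records = read_fasta(p, alphabet="protein")
    with resources.as_file(data / "synthetic_extein_motifs.tsv") as p:
        motif_df = pd.read_csv(p, sep="\t", comment="#",
                               names=["family", "start", "end", "label"])
    motifs: dict[str, list[tuple[str, int, int]]] = {}
    for _, row in motif_df.iterrows():
        motifs.setdefault(row["family"], []).append(
            (row["label"], int(row["start"]), int(row["end"])))
    return {rec.id: ReferenceExtein(family=rec.id, seq=rec.seq,
                                    motifs=motifs.get(rec.id, []))
            for rec in records}


def load_reference_sites() -> pd.DataFrame:
    """Designed insertion columns per family (used by the synthetic generator)."""
    data = resources.files("inteinscan.data")
    with resources.as_file(data / "synthetic_extein_sites.tsv") as p:
        return pd.read_csv(p, sep="\t", comment="#",
                           names=["family", "ref_column", "plus_one", "allowed_classes"])


def load_family_categories() -> dict[str, set[str]]:
    data = resources.files("inteinscan.data")
    with resources.as_file(data / "extein_categories.tsv") as p:
        df = pd.read_csv(p, sep="\t", comment="#", names=["family", "category"])
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["family"], set()).add(row["category"])
    return out


def write_sites_tsv(sites: list[InsertionSite], path: str | Path) -> None:
    rows = [{"family": s.family, "label": s.label, "ref_column_1based": s.ref_column + 1,
             "motif_context": s.motif_context} for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
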