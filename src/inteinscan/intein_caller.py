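"""Chain block hits into intein calls, classify them and detect the HEN.

An intein call is a chain of splicing-block hits (B, F, G required; A optional
because class 3 inteins diverge at block A) whose spacing respects known intein
architecture.  Boundaries follow the block G geometry: the intein ends at the
terminal residue (block G column 7) and the +1 extein nucleophile is block G
column 8.  Classification follows the splicing chemistry: class 3 inteins carry
the Trp-Cys-Thr triplet at B12/F4/G5, class 1 inteins a nucleophilic first
residue (Cys/Ser/Thr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .block_models import (
    DEFAULT_MIN_SCORE,
    BlockHit,
    BlockModel,
    scan_blocks,
)
from .sequence_io import SequenceRecord

logger = logging.getLogger("inteinscan")

#: (min_gap, max_gap) between consecutive blocks, measured from the end of the
#: upstream block to the start of the downstream one.  The B->F allowance spans
#: an embedded homing endonuclease.  Implementation defaults, not literature
#: claims; every value is configurable.
DEFAULT_SPACING: dict[tuple[str, str], tuple[int, int]] = {
    ("A", "B"): (30, 120),
    ("B", "F"): (0, 450),
    ("F", "G"): (5, 60),
}

#: Residues accepted as the class 1 initiating nucleophile at intein position 1.
NUCLEOPHILES = {"C", "S", "T"}

#: Accepted terminal residues (Asn canonical; Gln cyclization is a natural variant).
TERMINAL_RESIDUES = {"N", "Q"}

DEFAULT_MINI_GAP = 50  # residues; B->F linkers shorter than this mark mini-inteins
APPROX_N_OFFSET = 10  # columns upstream of block B when block A is absent

CHAIN_ORDER = ("A", "B", "F", "G")
REQUIRED_BLOCKS = ("B", "F", "G")


class ChainConsistencyError(RuntimeError):
    """Internal invariant violation: chain blocks out of protein order."""


@dataclass
class KeyResidues:
    """Diagnostic residues read off the called intein and its +1 position."""

    a1: str
    b12: str
    f4: str
    g5: str
    penultimate: str
    terminal: str
    plus_one: str


@dataclass
class HenAnnotation:
    """Homing-endonuclease status of the region between blocks B and F."""

    present: bool
    motif_hits: list[BlockHit] = field(default_factory=list)
    mini_intein: bool = False


@dataclass
class InteinCall:
    """One detected intein on a protein (0-based, half-open [start, end))."""

    protein_id: str
    start: int
    end: int
    blocks: dict[str, BlockHit]
    key_residues: KeyResidues
    intein_class: str
    sequence: str
    n_flank: str
    c_flank: str
    hen: HenAnnotation | None = None
    status: str = "ok"
    notes: list[str] = field(default_factory=list)
    approximate_n_terminus: bool = False
    family: str | None = None
    site_label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


Chain = dict[str, BlockHit]


def _chain_span(chain: Chain) -> tuple[int, int]:
    hits = [chain[b] for b in CHAIN_ORDER if b in chain]
    return hits[0].start, hits[-1].end


def _chain_key(chain: Chain) -> tuple:
    """Sort key implementing the tie-break: score desc, leftmost, block set."""
    score = sum(h.score for h in chain.values())
    start, _ = _chain_span(chain)
    return (-score, start, tuple(sorted(chain.keys())))


def _gap_ok(prev: BlockHit, nxt: BlockHit,
            constraints: Mapping[tuple[str, str], tuple[int, int]]) -> bool:
    lo, hi = constraints[(prev.block, nxt.block)]
    return lo <= nxt.start - prev.end <= hi


def _best_chain(hits: list[BlockHit],
                constraints: Mapping[tuple[str, str], tuple[int, int]]) -> Chain | None:
    """Maximum-total-score A?-B-F-G chain by dynamic programming."""
    by_block: dict[str, list[BlockHit]] = {b: [] for b in CHAIN_ORDER}
    for h in hits:
        if h.block in by_block:
            by_block[h.block].append(h)

    # best partial chain ending at each B hit (A optional; scores are
    # positive so attaching a compatible A never hurts)
    best_at: dict[int, Chain] = {}
    partials: list[tuple[BlockHit, Chain]] = []
    for b in by_block["B"]:
        options: list[Chain] = [{"B": b}]
        for a in by_block["A"]:
            if _gap_ok(a, b, constraints):
                options.append({"A": a, "B": b})
        partials.append((b, min(options, key=_chain_key)))

    f_partials: list[tuple[BlockHit, Chain]] = []
    for f in by_block["F"]:
        options = []
        for b, chain in partials:
            if _gap_ok(b, f, constraints):
                options.append({**chain, "F": f})
        if options:
            f_partials.append((f, min(options, key=_chain_key)))

    full: list[Chain] = []
    for g in by_block["G"]:
        options = []
        for f, chain in f_partials:
            if _gap_ok(f, g, constraints):
                options.append({**chain, "G": g})
        if options:
            full.append(min(options, key=_chain_key))

    return min(full, key=_chain_key) if full else None


def chain_blocks(hits: list[BlockHit],
                 constraints: Mapping[tuple[str, str], tuple[int, int]] | None = None,
                 ) -> list[Chain]:
    """Chain block hits into candidate inteins, best chain first.

    Repeatedly extracts the maximum-total-score chain (blocks in protein order
    A? B F G with spacing constraints), then removes every hit overlapping its
    span, so returned chains never overlap.  Ties break by higher score, then
    leftmost start, then lexicographic block set.
    """
    constraints = dict(DEFAULT_SPACING if constraints is None else constraints)
    remaining = sorted(hits, key=lambda h: (h.start, h.block))
    chains: list[Chain] = []
    while True:
        best = _best_chain(remaining, constraints)
        if best is None:
            break
        chains.append(best)
        lo, hi = _chain_span(best)
        remaining = [h for h in remaining if h.end <= lo or h.start >= hi]
    return chains


def _key_col(models: Mapping[str, BlockModel], block: str, role: str) -> int:
    return models[block].key_positions[role]


def call_intein(protein: SequenceRecord, chain: Chain,
                models: list[BlockModel] | Mapping[str, BlockModel]) -> InteinCall:
    """Fix boundaries and key residues of a chained candidate intein.

    Start is block A column 1 when A is present, otherwise a heuristic
    N terminus ``APPROX_N_OFFSET`` columns upstream of block B (flagged
    approximate).  End is one past the terminal residue (block G column 7).
    Calls whose terminal residue is not Asn/Gln are demoted to warning status.
    A chain whose block G window ends at the protein's last position has no +1
    extein residue and is rejected with ``ValueError``.
    """
    model_map = models if isinstance(models, Mapping) else {m.name: m for m in models}
    missing = [b for b in REQUIRED_BLOCKS if b not in chain]
    if missing:
        raise ValueError(f"chain lacks required blocks {missing}")
    ordered = [chain[b] for b in CHAIN_ORDER if b in chain]
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise ChainConsistencyError(
                f"blocks {prev.block} and {nxt.block} out of order on {protein.id}")

    seq = protein.seq
    b_hit, f_hit, g_hit = chain["B"], chain["F"], chain["G"]
    if "A" in chain:
        a_col = _key_col(model_map, "A", "nucleophile")
        start = chain["A"].start + a_col - 1
        approximate = False
    else:
        start = max(0, b_hit.start - APPROX_N_OFFSET)
        approximate = True

    terminal_pos = g_hit.start + _key_col(model_map, "G", "terminal") - 1
    end = terminal_pos + 1
    if end >= len(seq):
        raise ValueError(
            f"block G window ends at the last residue of {protein.id}: no +1 extein residue")

    kr = KeyResidues(
        a1=seq[start],
        b12=seq[b_hit.start + _key_col(model_map, "B", "triplet_W") - 1],
        f4=seq[f_hit.start + _key_col(model_map, "F", "triplet_C") - 1],
        g5=seq[g_hit.start + _key_col(model_map, "G", "triplet_T") - 1],
        penultimate=seq[g_hit.start + _key_col(model_map, "G", "penultimate") - 1],
        terminal=seq[terminal_pos],
        plus_one=seq[end],
    )

    call = InteinCall(
        protein_id=protein.id,
        start=start,
        end=end,
        blocks=dict(chain),
        key_residues=kr,
        intein_class="unknown",
        sequence=seq[start:end],
        n_flank=seq[max(0, start - 10):start],
        c_flank=seq[end:end + 10],
        approximate_n_terminus=approximate,
    )
    if approximate:
        call.notes.append("approximate N-terminus (block A absent)")
    if kr.terminal not in TERMINAL_RESIDUES:
        call.status = "warning"
        call.notes.append(f"noncanonical terminal residue {kr.terminal!r}")
    call.intein_class = assign_class(call)
    return call


def assign_class(call: InteinCall) -> str:
    """Class 3 iff (B12, F4, G5) == (W, C, T); else class 1 iff A1 is a
    nucleophile (C/S/T); else unknown."""
    kr = call.key_residues
    if (kr.b12, kr.f4, kr.g5) == ("W", "C", "T"):
        return "class3"
    if kr.a1 in NUCLEOPHILES:
        return "class1"
    return "unknown"


def detect_hen(protein: SequenceRecord, call: InteinCall,
               hen_models: list[BlockModel], mini_gap: int = DEFAULT_MINI_GAP,
               min_score: float = DEFAULT_MIN_SCORE) -> HenAnnotation:
    """Scan only the region between block B end and block F start for the
    LAGLIDADG blocks C/D/E/H.

    ``present`` requires hits for both C and E with C upstream of E.
    ``mini_intein`` marks HEN-less inteins whose B-F linker is shorter than
    ``mini_gap``.
    """
    b_end = call.blocks["B"].end
    f_start = call.blocks["F"].start
    region = protein.seq[b_end:f_start]
    hits: list[BlockHit] = []
    if region and len(region) >= min(m.length for m in hen_models):
        sub = SequenceRecord(id=protein.id, description="B-F region",
                             seq=region, alphabet="protein")
        for h in scan_blocks(sub, hen_models, min_score=min_score):
            hits.append(BlockHit(block=h.block, protein_id=protein.id,
                                 start=h.start + b_end, score=h.score, length=h.length))
    c_hits = [h for h in hits if h.block == "C"]
    e_hits = [h for h in hits if h.block == "E"]
    present = any(c.start < e.start for c in c_hits for e in e_hits)
    mini = (not present) and (f_start - b_end) < mini_gap
    call.hen = HenAnnotation(present=present, motif_hits=hits, mini_intein=mini)
    return call.hen


def splice(protein: SequenceRecord, call: InteinCall) -> str:
    """Simulate splicing: excise [start, end) and ligate the exteins."""
    return protein.seq[:call.start] + protein.seq[call.end:]


def scan_protein(protein: SequenceRecord, splicing_models: list[BlockModel],
                 hen_models: list[BlockModel] | None = None,
                 min_score: float = DEFAULT_MIN_SCORE,
                 constraints: Mapping[tuple[str, str], tuple[int, int]] | None = None,
                 mini_gap: int = DEFAULT_MINI_GAP,
                 include_warnings: bool = False) -> list[InteinCall]:
    """Full per-protein pipeline: scan, chain, call, annotate HEN.

    Warning-status calls (noncanonical terminal residue) are excluded from the
    default report unless ``include_warnings`` is set.
    """
    hits = scan_blocks(protein, splicing_models, min_score=min_score)
    calls: list[InteinCall] = []
    for chain in chain_blocks(hits, constraints):
        try:
            call = call_intein(protein, chain, splicing_models)
        except ValueError as exc:
            logger.debug("rejected candidate on %s: %s", protein.id, exc)
            continue
        if hen_models is not None:
            detect_hen(protein, call, hen_models, mini_gap=mini_gap, min_score=min_score)
        if call.status == "ok" or include_warnings:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# report writers (1-based inclusive coordinates for human-facing tables)

CALL_COLUMNS = ["protein_id", "start_1based", "end_1based", "length", "class",
                "a1", "b12", "f4", "g5", "penultimate", "terminal", "plus_one",
                "hen_present", "mini_intein", "status", "family", "site_label", "notes"]


def calls_to_rows(calls: Iterable[InteinCall]) -> list[dict]:
    rows = []
    for c in calls:
        kr = c.key_residues
        rows.append({
            "protein_id": c.protein_id,
            "start_1based": c.start + 1,
            "end_1based": c.end,
            "length": c.length,
            "class": c.intein_class,
            "a1": kr.a1, "b12": kr.b12, "f4": kr.f4, "g5": kr.g5,
            "penultimate": kr.penultimate, "terminal": kr.terminal,
            "plus_one": kr.plus_one,
            "hen_present": bool(c.hen.present) if c.hen else False,
            "mini_intein": bool(c.hen.mini_intein) if c.hen else False,
            "status": c.status,
            "family": c.family or "",
            "site_label": c.site_label or "",
            "notes": "; ".join(c.notes),
        })
    return rows


def write_calls_tsv(calls: Iterable[InteinCall], path: str | Path,
                    header_comment: str = "") -> None:
    import pandas as pd

    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(calls_to_rows(calls), columns=CALL_COLUMNS).to_csv(
            fh, sep="\t", index=False)


def write_calls_gff3(calls: Iterable[InteinCall], path: str | Path) -> None:
    """GFF3 on the protein coordinate system, feature type ``intein``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            attrs = (f"ID=intein{i};class={c.intein_class};"
                     f"hen={'yes' if c.hen and c.hen.present else 'no'};status={c.status}")
            fh.write(f"{c.protein_id}\tinteinscan\tintein\t{c.start + 1}\t{c.end}\t"
                     f".\t+\t.\t{attrs}\n")


def intein_records(calls: Iterable[InteinCall]) -> list[SequenceRecord]:
    out = []
    for i, c in enumerate(calls, 1):
        out.append(SequenceRecord(
            id=f"{c.protein_id}|intein_{c.start + 1}-{c.end}",
            description=f"class={c.intein_class}",
            seq=c.sequence, alphabet="protein"))
    return out
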