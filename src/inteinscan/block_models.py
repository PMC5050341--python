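"""Position-specific scoring models for intein splicing and endonuclease blocks.

Inteins carry four conserved splicing blocks (A, B near the N terminus; F, G at
the C terminus) and, when a LAGLIDADG homing endonuclease (HEN) is embedded
between B and F, four further conserved blocks (C, D, E, H).  Each block is
modelled as a gap-free log-odds matrix (PSSM, bits) built from a packaged seed
alignment; proteins are scanned by sliding the matrix over every window.

The packaged seed alignments are synthetic, consensus-anchored stand-ins that
encode the block residue logic (nucleophile at A1, the class 3 Trp-Cys-Thr
triplet at B12/F4/G5, the penultimate His at G6, terminal Asn at G7, the +1
extein nucleophile at G8, and the LAGLIDADG cores of blocks C and E); they are
not sampled from any external intein database.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import SequenceRecord, read_fasta

logger = logging.getLogger("inteinscan")

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP_CHARS = set("-.")

SPLICING_BLOCKS = ("A", "B", "F", "G")
HEN_BLOCKS = ("C", "D", "E", "H")

#: Catalytic / diagnostic columns per block, 1-based within the block.
KEY_POSITIONS: dict[str, dict[str, int]] = {
    "A": {"nucleophile": 1},
    "B": {"triplet_W": 12},
    "F": {"triplet_C": 4},
    "G": {"triplet_T": 5, "penultimate": 6, "terminal": 7, "plus_one": 8},
}

DEFAULT_MIN_SCORE = 8.0  # bits per block


@dataclass
class BlockModel:
    """A gap-free PSSM for one conserved block.

    ``log_odds`` has shape (length, 21): the 20 standard residues plus a final
    column fixed at 0 for 'X'/unknown residues (background-expected score).
    ``key_positions`` are 1-based column roles within the block.
    """

    name: str
    length: int
    log_odds: np.ndarray
    key_positions: dict[str, int]
    background: np.ndarray
    consensus: str = ""

    def __post_init__(self) -> None:
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        for role, col in self.key_positions.items():
            if not 1 <= col <= self.length:
                raise ValueError(f"key position {role}={col} outside block {self.name}")
        if not self.consensus:
            self.consensus = "".join(AA[i] for i in np.argmax(self.log_odds[:, :20], axis=1))

    def score_sequence(self, seq: str, offset: int = 0) -> float:
        """Score ``seq[offset:offset+length]`` under the model (bits)."""
        idx = encode_protein(seq[offset : offset + self.length])
        if len(idx) < self.length:
            raise ValueError("window shorter than the model")
        return float(self.log_odds[np.arange(self.length), idx].sum())

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "length": self.length,
            "key_positions": self.key_positions,
            "background": self.background.tolist(),
            "alphabet": AA,
            "log_odds": [list(map(float, row[:20])) for row in self.log_odds],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BlockModel":
        d = json.loads(text)
        lo = np.zeros((d["length"], 21))
        lo[:, :20] = np.asarray(d["log_odds"], dtype=float)
        return cls(name=d["name"], length=d["length"], log_odds=lo,
                   key_positions={k: int(v) for k, v in d["key_positions"].items()},
                   background=np.asarray(d["background"], dtype=float))


@dataclass
class BlockHit:
    """One scoring window of a block model on a protein (0-based start)."""

    block: str
    protein_id: str
    start: int
    score: float
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


def encode_protein(seq: str) -> np.ndarray:
    """Map residues to 0..19; anything else (X, ambiguity) to index 20."""
    return np.array([AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.int64)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def empirical_background(proteins: list[SequenceRecord], floor: float = 1e-4) -> np.ndarray:
    """Residue frequencies pooled over a proteome, floored and renormalised."""
    counts = np.zeros(20)
    for rec in proteins:
        idx = encode_protein(rec.seq)
        counts += np.bincount(idx[idx < 20], minlength=20)
    freqs = np.maximum(counts / max(counts.sum(), 1.0), floor)
    return freqs / freqs.sum()


def build_pssm(seed_alignment: list[str], pseudocount: float = 1.0,
               background: np.ndarray | None = None, name: str = "?",
               key_positions: dict[str, int] | None = None,
               max_gap_fraction: float = 0.5) -> BlockModel:
    """Build a log-odds PSSM from an aligned set of block sequences.

    ``log_odds[c][a] = log2((count(a,c) + pc*bg[a]) / ((N + pc) * bg[a]))``
    where N counts non-gap residues in column c.  Columns with more than
    ``max_gap_fraction`` gap characters are dropped and key positions are
    re-indexed past them.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    lengths = {len(s) for s in seed_alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged seed alignment (lengths {sorted(lengths)})")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be a positive 20-vector summing to 1")

    ncol = lengths.pop()
    keep: list[int] = []
    columns = []
    for c in range(ncol):
        col = [s[c].upper() for s in seed_alignment]
        gap_frac = sum(ch in GAP_CHARS for ch in col) / len(col)
        if gap_frac > max_gap_fraction:
            continue
        keep.append(c)
        columns.append(col)

    key_src = key_positions if key_positions is not None else KEY_POSITIONS.get(name, {})
    new_keys: dict[str, int] = {}
    for role, col1 in key_src.items():
        if col1 - 1 not in keep:
            raise ValueError(f"key column {role}={col1} of block {name} was gap-removed")
        new_keys[role] = keep.index(col1 - 1) + 1

    length = len(keep)
    log_odds = np.zeros((length, 21))
    for c, col in enumerate(columns):
        counts = np.zeros(20)
        for ch in col:
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
        n = counts.sum()
        log_odds[c, :20] = np.log2((counts + pseudocount * bg) / ((n + pseudocount) * bg))
    # column 20 stays 0: 'X' residues score the background expectation
    return BlockModel(name=name, length=length, log_odds=log_odds,
                      key_positions=new_keys, background=bg)


def scan_blocks(protein: SequenceRecord, models: list[BlockModel],
                min_score: float = DEFAULT_MIN_SCORE) -> list[BlockHit]:
    """Score every window of every model; return hits >= ``min_score`` (bits).

    Hits are sorted by (start, block name).  Proteins shorter than a model
    simply yield no hits for it.
    """
    if protein.alphabet != "protein":
        raise ValueError("scan_blocks requires a protein record")
    if not np.isfinite(min_score):
        raise ValueError("min_score must be finite")
    idx = encode_protein(protein.seq)
    hits: list[BlockHit] = []
    for model in models:
        L = model.length
        if len(idx) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = model.log_odds[np.arange(L), windows].sum(axis=1)
        for start in np.nonzero(scores >= min_score)[0]:
            hits.append(BlockHit(block=model.name, protein_id=protein.id,
                                 start=int(start), score=float(scores[start]), length=L))
    return sorted(hits, key=lambda h: (h.start, h.block))


def _read_seed(name: str) -> list[str]:
    ref = resources.files("inteinscan.data") / f"synthetic_seed_block_{name}.fasta"
    with resources.as_file(ref) as path:
        return [rec.seq for rec in read_fasta(path, alphabet="protein")]


def load_packaged_models(kind: str = "all", pseudocount: float = 1.0,
                         background: np.ndarray | None = None) -> list[BlockModel]:
    """Load PSSMs for the packaged seed alignments.

    ``kind`` is ``splicing`` (A,B,F,G), ``hen`` (C,D,E,H) or ``all``.
    """
    names = {"splicing": SPLICING_BLOCKS, "hen": HEN_BLOCKS,
             "all": SPLICING_BLOCKS + HEN_BLOCKS}[kind]
    return [build_pssm(_read_seed(n), pseudocount=pseudocount,
                       background=background, name=n) for n in names]


def block_consensus(models: list[BlockModel]) -> dict[str, str]:
    return {m.name: m.consensus for m in models}


def save_models(models: list[BlockModel], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in models:
        (directory / f"block_{m.name}.json").write_text(m.to_json())


def load_models(directory: str | Path) -> list[BlockModel]:
    directory = Path(directory)
    models = [BlockModel.from_json(p.read_text()) for p in sorted(directory.glob("block_*.json"))]
    if not models:
        raise FileNotFoundError(f"no block_*.json models under {directory}")
    return models
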