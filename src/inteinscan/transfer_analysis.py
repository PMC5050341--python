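"""Intein relatedness, intein/extein trees and horizontal-transfer flags.

Typical unrelated inteins share no more than ~30% amino acid identity, so a
pair well above that background — especially between a phage intein and a
bacterial one — is a horizontal-transfer candidate.  The second, orthogonal
signal is phylogenetic incongruence: inteins that cluster together while their
host exteins do not imply the intein moved independently of its host gene.
Trees here are neighbor-joining on Poisson-corrected distances (a declared,
desk-scale substitution for maximum-likelihood inference) and topology
comparison uses Robinson-Foulds bipartition counts on unrooted trees.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .intein_caller import InteinCall

logger = logging.getLogger("inteinscan")

DEFAULT_TRANSFER_THRESHOLD = 35.0  # percent identity


@dataclass
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    free_end_gaps: bool = False


@dataclass
class PairwiseAlignment:
    """A computed global alignment: gapped strings plus the DP score."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned strings differ in length")


@dataclass
class IdentityResult:
    id_a: str
    id_b: str
    mode: str  # full | splicing_only | flank_nt
    percent_identity: float
    aligned_columns: int


@dataclass
class TransferFlag:
    pair: tuple[str, str]
    percent_identity: float
    threshold: float
    flagged: bool
    evidence: str = "identity_only"


@dataclass
class TreeTopology:
    """An unrooted tree held as newick text plus its taxon set."""

    newick: str
    taxa: frozenset[str]


@dataclass
class IncongruenceReport:
    focal_taxa: frozenset[str]
    monophyletic_in_intein: bool
    monophyletic_in_extein: bool
    status: str  # incongruent | congruent | no_signal


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
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


def global_align(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring (BLOSUM62 by default).

    Biopython's deterministic first alignment is returned; on equal scores its
    traceback prefers matches over gaps, which fixes the tie-break.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(params or AlignParams())
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(a=str(aln[0]), b=str(aln[1]), score=float(aln.score))


def percent_identity(alignment: PairwiseAlignment) -> tuple[float, int]:
    """100 x identical columns / aligned columns, excluding terminal overhangs."""
    a, b = alignment.a, alignment.b
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


def pairwise_identity(id_a: str, seq_a: str, id_b: str, seq_b: str,
                      mode: str = "full",
                      params: AlignParams | None = None) -> IdentityResult:
    pid, cols = percent_identity(global_align(seq_a, seq_b, params))
    return IdentityResult(id_a=id_a, id_b=id_b, mode=mode,
                          percent_identity=pid, aligned_columns=cols)


def identity_matrix(seqs: Mapping[str, str], mode: str = "full",
                    params: AlignParams | None = None) -> list[IdentityResult]:
    """All unordered pairs; identity(a, a) is 100 by construction and skipped."""
    out = []
    for (na, sa), (nb, sb) in itertools.combinations(seqs.items(), 2):
        out.append(pairwise_identity(na, sa, nb, sb, mode=mode, params=params))
    return out


def aligned_pair_identity(id_a: str, id_b: str, aligned_a: str, aligned_b: str,
                          mode: str = "full") -> IdentityResult:
    """Identity for sequences that are already columns of one alignment."""
    pid, cols = percent_identity(PairwiseAlignment(a=aligned_a, b=aligned_b, score=0.0))
    return IdentityResult(id_a=id_a, id_b=id_b, mode=mode,
                          percent_identity=pid, aligned_columns=cols)


def excise_splicing_domain(call: InteinCall) -> str:
    """Drop the region between block B end and block F start (the HEN or
    linker), keeping the concatenated N- and C-terminal splicing domains."""
    for b in ("B", "F"):
        if b not in call.blocks:
            raise ValueError(f"call lacks located block {b}")
    b_end = call.blocks["B"].end - call.start
    f_start = call.blocks["F"].start - call.start
    if not 0 <= b_end <= f_start <= len(call.sequence):
        raise ValueError("block coordinates inconsistent with intein sequence")
    return call.sequence[:b_end] + call.sequence[f_start:]


def flag_transfer_candidates(results: Sequence[IdentityResult],
                             threshold: float = DEFAULT_TRANSFER_THRESHOLD,
                             ) -> list[TransferFlag]:
    """Flag pairs whose identity exceeds the background-relatedness threshold."""
    modes = {r.mode for r in results}
    if len(modes) > 1:
        raise ValueError(f"mixed identity modes {sorted(modes)}")
    return [TransferFlag(pair=(r.id_a, r.id_b), percent_identity=r.percent_identity,
                         threshold=threshold, flagged=r.percent_identity > threshold)
            for r in results]


# ---------------------------------------------------------------------------
# distances and trees

def poisson_distance(percent_id: float, cap: float = 5.0) -> float:
    """Poisson-corrected distance from percent identity: d = -ln(p_identical)."""
    p = max(percent_id / 100.0, math.exp(-cap))
    return min(-math.log(p), cap)


def distance_matrix_from_identities(results: Sequence[IdentityResult]) -> pd.DataFrame:
    taxa = sorted({t for r in results for t in (r.id_a, r.id_b)})
    dm = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for r in results:
        d = poisson_distance(r.percent_identity)
        dm.loc[r.id_a, r.id_b] = d
        dm.loc[r.id_b, r.id_a] = d
    return dm


def nj_tree(distances: pd.DataFrame | np.ndarray,
            taxa: Sequence[str] | None = None) -> TreeTopology:
    """Neighbor-joining tree from a symmetric, zero-diagonal distance matrix.

    Negative branch lengths (an NJ artifact) are clamped to zero with a
    warning.  At least 3 taxa are required; asymmetry beyond 1e-9 is an error.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        ids = list(taxa) if taxa is not None else [f"t{i}" for i in range(len(mat))]
    if mat.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.abs(mat - mat.T).max() > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    tree = nj(DistanceMatrix(mat, ids))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.warning("nj_tree: clamped %d negative branch lengths to 0", clamped)
    return TreeTopology(newick=str(tree).strip(), taxa=frozenset(ids))


def _bipartitions(tree: TreeTopology) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of an unrooted tree, each as {side, complement}."""
    from skbio import TreeNode

    root = TreeNode.read(io.StringIO(tree.newick))
    taxa = frozenset(tree.taxa)
    splits: set[frozenset[frozenset[str]]] = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(frozenset({side, frozenset(other)}))
    return splits


def rf_distance(t1: TreeTopology, t2: TreeTopology) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees have different taxon sets")
    s1, s2 = _bipartitions(t1), _bipartitions(t2)
    return len(s1 ^ s2)


def is_monophyletic(tree: TreeTopology, focal: frozenset[str]) -> bool:
    """Unrooted monophyly: some edge separates exactly the focal taxa."""
    if not focal <= tree.taxa:
        raise ValueError("focal taxa not all present in tree")
    if len(focal) == len(tree.taxa) - 1 or len(focal) == 1:
        return True  # trivially separated by a pendant edge
    return any(focal in split for split in _bipartitions(tree))


def detect_incongruence(intein_tree: TreeTopology, extein_tree: TreeTopology,
                        focal_taxa: Iterable[str]) -> IncongruenceReport:
    """Compare where the focal taxa sit in the intein vs extein tree.

    Incongruent iff the focal group is monophyletic in exactly one tree;
    monophyletic in both means congruent history; in neither, "no_signal".
    """
    focal = frozenset(focal_taxa)
    if len(focal) < 2:
        raise ValueError("need at least 2 focal taxa")
    m1 = is_monophyletic(intein_tree, focal)
    m2 = is_monophyletic(extein_tree, focal)
    if m1 != m2:
        status = "incongruent"
    elif m1:
        status = "congruent"
    else:
        status = "no_signal"
    return IncongruenceReport(focal_taxa=focal, monophyletic_in_intein=m1,
                              monophyletic_in_extein=m2, status=status)


# ---------------------------------------------------------------------------
# serialization

def write_identity_tsv(results: Sequence[IdentityResult], path: str | Path,
                       header_comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# percent identity over aligned columns, terminal overhangs excluded\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame([r.__dict__ for r in results]).to_csv(fh, sep="\t", index=False)


def write_phylip_matrix(dm: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for name, row in dm.iterrows():
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_newick(path_or_text: str | Path) -> TreeTopology:
    from skbio import TreeNode

    s = str(path_or_text)
    text = s if "(" in s else Path(path_or_text).read_text()
    tree = TreeNode.read(io.StringIO(text))
    taxa = frozenset(t.name for t in tree.tips())
    return TreeTopology(newick=text.strip(), taxa=taxa)
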