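"""End-to-end orchestration: scan, site assignment, survey tables, HGT detection,
and scoring of a run against a synthetic truth manifest."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .block_models import (
    DEFAULT_MIN_SCORE,
    BlockModel,
    load_packaged_models,
)
from .extein_context import (
    AlignmentParams,
    UnassignableFamilyError,
    assign_site_labels,
    best_reference,
    load_reference_exteins,
    InsertionSite,
)
from .intein_caller import (
    DEFAULT_MINI_GAP,
    DEFAULT_SPACING,
    InteinCall,
    scan_protein,
)
from .sequence_io import SequenceRecord, find_orfs, orf_protein_records
from .transfer_analysis import (
    DEFAULT_TRANSFER_THRESHOLD,
    IdentityResult,
    TransferFlag,
    aligned_pair_identity,
    detect_incongruence,
    distance_matrix_from_identities,
    nj_tree,
)

logger = logging.getLogger("inteinscan")


@dataclass
class ScanSettings:
    min_score: float = DEFAULT_MIN_SCORE
    mini_gap: int = DEFAULT_MINI_GAP
    spacing: dict = field(default_factory=lambda: dict(DEFAULT_SPACING))
    min_orf_aa: int = 100
    include_warnings: bool = False
    map_sites: bool = True


def scan_proteins(proteins: Iterable[SequenceRecord],
                  settings: ScanSettings | None = None,
                  splicing_models: list[BlockModel] | None = None,
                  hen_models: list[BlockModel] | None = None) -> list[InteinCall]:
    """Scan a protein set for inteins; optionally map each call to a reference
    extein family and insertion site."""
    settings = settings or ScanSettings()
    proteins = list(proteins)
    splicing_models = splicing_models or load_packaged_models("splicing")
    hen_models = hen_models or load_packaged_models("hen")
    calls: list[InteinCall] = []
    for prot in proteins:
        calls.extend(scan_protein(
            prot, splicing_models, hen_models,
            min_score=settings.min_score, constraints=settings.spacing,
            mini_gap=settings.mini_gap, include_warnings=settings.include_warnings))
    if settings.map_sites and calls:
        refs = load_reference_exteins()
        by_id = {p.id: p for p in proteins}
        sites: list[tuple[InteinCall, InsertionSite]] = []
        for call in calls:
            try:
                site, identity = best_reference(call, by_id[call.protein_id],
                                                refs.values())
            except (UnassignableFamilyError, ValueError) as exc:
                call.notes.append(f"unmapped site: {exc}")
                continue
            call.family = site.family
            sites.append((call, site))
        labelled = assign_site_labels([s for _, s in sites])
        for (call, _), site in zip(sites, labelled):
            call.site_label = site.label
            call.notes.append(f"site {site.family}-{site.label} "
                              f"ref_column={site.ref_column} motif={site.motif_context}")
    return calls


def scan_genomes(genomes: Iterable[SequenceRecord],
                 settings: ScanSettings | None = None,
                 **kw) -> tuple[list[InteinCall], list[SequenceRecord]]:
    """ORF-call every genome, then scan the predicted proteins."""
    settings = settings or ScanSettings()
    proteins: list[SequenceRecord] = []
    for genome in genomes:
        orfs = find_orfs(genome, min_aa=settings.min_orf_aa)
        proteins.extend(orf_protein_records(orfs))
    return scan_proteins(proteins, settings, **kw), proteins


def dedupe_genome_calls(calls: Sequence[InteinCall]) -> list[InteinCall]:
    """Collapse duplicate calls arising from nested ORFs.

    ORF-derived protein ids look like ``<genome>|<start>-<end><strand>``; every
    in-frame start codon upstream of an intein yields the same intein at the
    same genome nucleotide span.  Within each (genome, span) group the call
    from the longest ORF (the most complete precursor) is kept.
    """
    best: dict[tuple[str, int, int], tuple[int, InteinCall]] = {}
    passthrough: list[InteinCall] = []
    for c in calls:
        pid = c.protein_id
        if "|" not in pid or "-" not in pid.rsplit("|", 1)[1]:
            passthrough.append(c)
            continue
        genome, span = pid.rsplit("|", 1)
        strand = span[-1]
        lo, hi = (int(x) for x in span[:-1].split("-"))
        if strand == "+":
            nt = (genome, lo + 3 * c.start, lo + 3 * c.end)
        else:
            nt = (genome, hi - 3 * c.end, hi - 3 * c.start)
        orf_len = hi - lo
        if nt not in best or orf_len > best[nt][0]:
            best[nt] = (orf_len, c)
    return passthrough + [c for _, c in best.values()]


# ---------------------------------------------------------------------------
# scoring against a truth manifest

@dataclass
class RecoveryReport:
    n_truth: int
    n_called: int
    n_boundary_exact: int
    n_class_correct: int
    n_site_exact: int
    n_site_mapped: int
    n_hen_correct: int
    false_positive_calls: int
    n_background_proteins: int

    @property
    def boundary_recall(self) -> float:
        return self.n_boundary_exact / self.n_truth if self.n_truth else float("nan")

    @property
    def class_accuracy(self) -> float:
        return self.n_class_correct / self.n_boundary_exact if self.n_boundary_exact \
            else float("nan")

    @property
    def site_exact_fraction(self) -> float:
        return self.n_site_exact / self.n_boundary_exact if self.n_boundary_exact \
            else float("nan")

    @property
    def hen_accuracy(self) -> float:
        return self.n_hen_correct / self.n_boundary_exact if self.n_boundary_exact \
            else float("nan")

    @property
    def false_positive_rate(self) -> float:
        return self.false_positive_calls / self.n_background_proteins \
            if self.n_background_proteins else 0.0


def evaluate_calls(calls: Sequence[InteinCall], truth: pd.DataFrame,
                   n_background_proteins: int | None = None) -> RecoveryReport:
    """Score calls against a synthetic truth manifest.

    Boundary recall counts truth rows whose protein has a call with exactly
    matching [start, end).  Class, site-column and HEN accuracy are computed
    over the boundary-exact subset.  Calls on proteins absent from the truth
    manifest are false positives.
    """
    truth_by_protein = {row["protein_id"]: row for _, row in truth.iterrows()}
    calls_by_protein: dict[str, list[InteinCall]] = {}
    for c in calls:
        calls_by_protein.setdefault(c.protein_id, []).append(c)

    n_boundary = n_class = n_site = n_site_mapped = n_hen = 0
    for pid, row in truth_by_protein.items():
        matched = None
        for c in calls_by_protein.get(pid, []):
            if c.start == int(row["start"]) and c.end == int(row["end"]):
                matched = c
                break
        if matched is None:
            continue
        n_boundary += 1
        if matched.intein_class == row["class"]:
            n_class += 1
        if matched.hen is not None and matched.hen.present == bool(row["hen"]):
            n_hen += 1
        if matched.family is not None and matched.site_label is not None:
            n_site_mapped += 1
            note = next((n for n in matched.notes if n.startswith("site ")), "")
            if (matched.family == row["family"]
                    and f"ref_column={int(row['ref_column'])} " in note):
                n_site += 1

    fp = sum(len(v) for pid, v in calls_by_protein.items()
             if pid not in truth_by_protein)
    n_bg = n_background_proteins if n_background_proteins is not None else 0
    return RecoveryReport(
        n_truth=len(truth_by_protein), n_called=len(calls),
        n_boundary_exact=n_boundary, n_class_correct=n_class,
        n_site_exact=n_site, n_site_mapped=n_site_mapped, n_hen_correct=n_hen,
        false_positive_calls=fp, n_background_proteins=n_bg)


# ---------------------------------------------------------------------------
# HGT detection on aligned intein/extein sets

@dataclass
class HgtDetection:
    detected: bool
    flagged_pairs: list[TransferFlag]
    incongruent_pairs: list[tuple[str, str]]
    intein_tree_newick: str
    extein_tree_newick: str


def detect_hgt(intein_seqs: Mapping[str, str], extein_seqs: Mapping[str, str],
               threshold: float = DEFAULT_TRANSFER_THRESHOLD,
               skip_sisters_in: Mapping[str, str] | None = None) -> HgtDetection:
    """Joint identity + incongruence screen on aligned intein/extein sets.

    A pair is called a transfer candidate when its intein identity exceeds the
    background threshold AND the pair is monophyletic in the intein tree but
    not in the extein tree (evidence = identity_plus_incongruence).  High
    identity alone (e.g. sister taxa) is not sufficient.
    """
    import itertools

    taxa = sorted(intein_seqs)
    if set(taxa) != set(extein_seqs):
        raise ValueError("intein and extein sets cover different taxa")
    int_ids = [aligned_pair_identity(a, b, intein_seqs[a], intein_seqs[b],
                                     mode="splicing_only")
               for a, b in itertools.combinations(taxa, 2)]
    ext_ids = [aligned_pair_identity(a, b, extein_seqs[a], extein_seqs[b],
                                     mode="full")
               for a, b in itertools.combinations(taxa, 2)]
    intein_tree = nj_tree(distance_matrix_from_identities(int_ids))
    extein_tree = nj_tree(distance_matrix_from_identities(ext_ids))

    flags = []
    incongruent = []
    for res in int_ids:
        flagged = res.percent_identity > threshold
        flag = TransferFlag(pair=(res.id_a, res.id_b),
                            percent_identity=res.percent_identity,
                            threshold=threshold, flagged=flagged)
        if flagged:
            report = detect_incongruence(intein_tree, extein_tree,
                                         {res.id_a, res.id_b})
            if report.status == "incongruent" and report.monophyletic_in_intein:
                flag.evidence = "identity_plus_incongruence"
                incongruent.append((res.id_a, res.id_b))
        flags.append(flag)
    return HgtDetection(
        detected=bool(incongruent), flagged_pairs=flags,
        incongruent_pairs=incongruent,
        intein_tree_newick=intein_tree.newick,
        extein_tree_newick=extein_tree.newick)
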