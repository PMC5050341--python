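"""Survey-level aggregation: prevalence, intein frequency, regression, logos.

Display percentages are rounded half-up to one decimal (so 55/62 prints as
88.7); all statistics retain full precision internally and tests compare the
unrounded values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .block_models import AA, AA_INDEX, GAP_CHARS
from .intein_caller import InteinCall

logger = logging.getLogger("inteinscan")

MAX_INFORMATION = math.log2(20.0)


def round_half_up(x: float, digits: int = 1) -> float:
    """Half-up decimal rounding for display (88.65 -> 88.7)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cluster_prevalence(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster intein prevalence, plus an ALL row aggregating every genome.

    The manifest must carry an ``intein_count`` column (filled by the pipeline
    or by the truth manifest).  ``percent_positive`` is unrounded;
    ``percent_display`` applies the half-up one-decimal display convention.
    """
    if manifest.empty:
        raise ValueError("empty survey manifest")
    if "intein_count" not in manifest.columns:
        raise ValueError("manifest lacks an intein_count column")
    df = manifest.copy()
    df["positive"] = df["intein_count"].fillna(0).astype(int) > 0
    rows = []
    for cluster, grp in df.groupby("cluster", sort=True):
        n_total = len(grp)
        n_pos = int(grp["positive"].sum())
        rows.append({"cluster": cluster, "n_total": n_total, "n_positive": n_pos,
                     "percent_positive": 100.0 * n_pos / n_total})
    n_total = len(df)
    n_pos = int(df["positive"].sum())
    rows.append({"cluster": "ALL", "n_total": n_total, "n_positive": n_pos,
                 "percent_positive": 100.0 * n_pos / n_total})
    out = pd.DataFrame(rows)
    out["percent_display"] = out["percent_positive"].map(round_half_up)
    return out


def intein_frequency(manifest: pd.DataFrame) -> pd.DataFrame:
    """Inteins per 100 protein-coding sequences, per genome.

    Rows lacking ``cds_count`` are skipped (their number is logged, since real
    surveys only have CDS counts for a subset of genomes); a zero ``cds_count``
    is a row error.
    """
    if "intein_count" not in manifest.columns:
        raise ValueError("manifest lacks an intein_count column")
    has_cds = manifest["cds_count"].notna()
    skipped = int((~has_cds).sum())
    if skipped:
        logger.warning("intein_frequency: %d genomes lack cds_count and were skipped",
                       skipped)
    rows = []
    for _, row in manifest[has_cds].iterrows():
        cds = float(row["cds_count"])
        if cds == 0:
            raise ValueError(f"genome {row['genome_id']} has cds_count == 0")
        rows.append({"genome_id": row["genome_id"], "cluster": row["cluster"],
                     "inteins_per_100_cds": 100.0 * float(row["intein_count"]) / cds})
    return pd.DataFrame(rows, columns=["genome_id", "cluster", "inteins_per_100_cds"])


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation (the coefficient of determination of a
    simple linear fit).  Constant input yields NaN with a warning, not 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("linear_r2: constant input, R^2 undefined")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LogoColumn:
    position_label: str
    frequencies: np.ndarray  # 20-vector over AA order
    information: float  # bits
    all_gaps: bool = False


def conservation_logo(aligned_columns: list[str],
                      labels: Sequence[str] | None = None,
                      small_sample_correction: bool = False) -> list[LogoColumn]:
    """Per-column residue frequencies and information content (bits).

    Gaps are excluded from the denominator (not a 21st symbol); information is
    log2(20) minus the Shannon entropy of the residue distribution.  A column
    of only gaps is reported with information 0 and ``all_gaps`` set.  The
    optional Miller-Madow correction subtracts the small-sample entropy bias;
    it is off by default because group sizes vary wildly between sets.
    """
    if len(aligned_columns) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in aligned_columns}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    ncol = lengths.pop()
    out: list[LogoColumn] = []
    for c in range(ncol):
        label = labels[c] if labels is not None else str(c + 1)
        residues = [s[c].upper() for s in aligned_columns if s[c] not in GAP_CHARS]
        freqs = np.zeros(20)
        for ch in residues:
            if ch in AA_INDEX:
                freqs[AA_INDEX[ch]] += 1
        n = freqs.sum()
        if n == 0:
            out.append(LogoColumn(position_label=label, frequencies=freqs,
                                  information=0.0, all_gaps=True))
            continue
        freqs = freqs / n
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        if small_sample_correction:
            entropy += (len(nz) - 1) / (2.0 * math.log(2.0) * n)
        info = max(0.0, min(MAX_INFORMATION, MAX_INFORMATION - entropy))
        out.append(LogoColumn(position_label=label, frequencies=freqs, information=info))
    return out


def logo_table(columns: list[LogoColumn]) -> pd.DataFrame:
    rows = []
    for col in columns:
        row = {"position": col.position_label, "information_bits": col.information,
               "all_gaps": col.all_gaps}
        row.update({aa: col.frequencies[i] for i, aa in enumerate(AA)})
        rows.append(row)
    return pd.DataFrame(rows)


def penultimate_report(calls: Iterable[InteinCall],
                       grouping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Counts and fractions of each residue at the penultimate (G6) position.

    Only class 1 calls are tallied (class 3 chemistry is reported separately);
    ``grouping`` maps protein_id to a group name (default: one ``all`` group).
    """
    rows: dict[tuple[str, str], int] = {}
    for call in calls:
        if call.intein_class != "class1":
            continue
        group = grouping.get(call.protein_id, "other") if grouping else "all"
        key = (group, call.key_residues.penultimate)
        rows[key] = rows.get(key, 0) + 1
    if not rows:
        return pd.DataFrame(columns=["group", "residue", "count", "fraction"])
    records = []
    totals: dict[str, int] = {}
    for (group, _), n in rows.items():
        totals[group] = totals.get(group, 0) + n
    for (group, residue), n in sorted(rows.items()):
        records.append({"group": group, "residue": residue, "count": n,
                        "fraction": n / totals[group]})
    return pd.DataFrame(records)


def write_table(df: pd.DataFrame, path: str | Path, params: Mapping | None = None) -> None:
    """TSV with a header comment recording run parameters."""
    with open(path, "w") as fh:
        if params:
            fh.write("# " + "; ".join(f"{k}={v}" for k, v in params.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False)
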