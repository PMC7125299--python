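"""Read counting: spacer extraction and exact dictionary matching.

Reads are assigned by locating the 5' flanking anchor of the expression
cassette, taking the following bases as the candidate spacer and matching
them exactly against the library (longest match wins for nested spacers
of mixed length). Unmatched reads are tallied, never guessed.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .design import MAX_SPACER_LEN, MIN_SPACER_LEN


def extract_spacer(
    read: str,
    flank5: str,
    flank3: str = "",
    max_len: int = MAX_SPACER_LEN,
) -> Optional[str]:
    """The <=max_len bases after the first occurrence of ``flank5``,
    truncated at ``flank3`` when present; None when the anchor is absent."""
    if not flank5:
        raise ValueError("flank5 anchor must be non-empty")
    i = read.find(flank5)
    if i < 0:
        return None
    remainder = read[i + len(flank5) :]
    if flank3:
        j = remainder.find(flank3)
        if 0 <= j <= max_len:
            return remainder[:j]
    return remainder[:max_len]


@dataclass
class AssignmentStats:
    total: int
    assigned: int
    ambiguous: int
    unassigned: int

    @property
    def assignment_rate(self) -> float:
        return self.assigned / self.total if self.total else 0.0


def count_reads(
    reads_by_sample: Mapping[str, Iterable[str]],
    spacer_to_guide: Mapping[str, str],
    flank5: str,
    flank3: str = "",
    min_len: int = MIN_SPACER_LEN,
    max_len: int = MAX_SPACER_LEN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix (guides x samples) plus per-sample assignment stats.

    A read increments exactly one guide when the window after ``flank5``
    has a library spacer as its longest matching prefix.
    """
    guide_ids = list(dict.fromkeys(spacer_to_guide.values()))
    lengths = sorted({len(s) for s in spacer_to_guide}, reverse=True)

    counts: dict[str, dict[str, int]] = {}
    stats_rows = []
    for sample, reads in reads_by_sample.items():
        col = dict.fromkeys(guide_ids, 0)
        total = assigned = unassigned = 0
        for read in reads:
            total += 1
            i = read.find(flank5)
            if i < 0:
                unassigned += 1
                continue
            window = read[i + len(flank5) : i + len(flank5) + max_len]
            hit = None
            for L in lengths:  # longest match wins for nested spacers
                cand = window[:L]
                if len(cand) < L or len(cand) < min_len:
                    continue
                guide = spacer_to_guide.get(cand)
                if guide is not None:
                    hit = guide
                    break
            if hit is None:
                unassigned += 1
            else:
                col[hit] += 1
                assigned += 1
        counts[sample] = col
        stats_rows.append(
            {
                "sample_id": sample,
                "total": total,
                "assigned": assigned,
                "ambiguous": 0,  # impossible under exact unique matching
                "unassigned": unassigned,
                "assignment_rate": assigned / total if total else 0.0,
            }
        )
    counts_df = pd.DataFrame(counts, index=guide_ids).fillna(0).astype(int)
    stats = pd.DataFrame(stats_rows).set_index("sample_id")
    return counts_df, stats


# ----------------------------------------------------------------- file I/O


def read_fastq(path: str | Path) -> list[str]:
    """Sequences from a FASTQ file (gzip allowed)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("guide_id").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")
    return df.astype(int)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "replicate" in meta and (meta["replicate"] < 1).any():
        raise ValueError("replicate numbers must be >= 1")
    if "n_gen" in meta and (meta["n_gen"] < 0).any():
        raise ValueError("n_gen must be non-negative")
    return meta
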