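"""Genome-wide sgRNA library design for CRISPR interference.

Candidate protospacers are enumerated so that the NGG PAM falls on the
coding strand of the targeted gene (the scanned template strand matches
5'-CCN[20-25 bases]T-3', which guarantees the transcribed spacer starts
with A). Candidates are filtered by a window around the TSS / start codon
and by sequence composition, ranked by a mismatch-bounded off-target count
over both strands and both NGG and NAG PAMs, and the best two guides per
gene are selected with a minimum 10 nt separation when achievable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, Feature, reverse_complement

MIN_SPACER_LEN = 20
MAX_SPACER_LEN = 25
CORE_LEN = 17  # PAM-proximal window that determines off-target specificity
PAM_SECOND_BASES = (ord("G"), ord("A"))  # NGG and NAG


@dataclass(frozen=True)
class WindowConfig:
    """Placement window for candidate guides.

    The PAM-proximal protospacer end must lie within
    ``min(max_tss_dist, ceil(max_gene_fraction * gene_length))`` nt
    downstream of the anchor (TSS when annotated, else start codon).
    """

    max_tss_dist: int = 500
    max_gene_fraction: float = 0.75

    def window_max(self, gene_length: int) -> int:
        return min(self.max_tss_dist, math.ceil(self.max_gene_fraction * gene_length))


@dataclass
class GuideCandidate:
    gene_id: str
    spacer: str
    replicon: str
    pam_strand: str  # strand carrying the NGG PAM (= gene coding strand)
    protospacer_start: int  # forward-strand coords, 0-based half-open
    protospacer_end: int
    offset_nt: int  # anchor -> PAM-proximal protospacer end
    gc_fraction: float
    offtarget_count: Optional[int] = None

    @property
    def core_site(self) -> tuple[str, str, int]:
        """Canonical (replicon, strand, forward start) of the PAM-proximal
        17-mer window, used to exclude the on-target site itself."""
        if self.pam_strand == "+":
            return (self.replicon, "+", self.protospacer_end - CORE_LEN)
        return (self.replicon, "-", self.protospacer_start)


@dataclass
class GuideLibrary:
    guides: list[GuideCandidate]
    status: dict[str, str]  # gene_id -> "two" | "one" | "none"

    def spacer_map(self) -> dict[str, str]:
        """spacer -> guide id; raises on duplicate spacers with distinct ids."""
        mapping: dict[str, str] = {}
        for gid, g in zip(self.guide_ids(), self.guides):
            prev = mapping.get(g.spacer)
            if prev is not None and prev != gid:
                raise ValueError(f"duplicate spacer {g.spacer} for {prev} and {gid}")
            mapping[g.spacer] = gid
        return mapping

    def guide_ids(self) -> list[str]:
        ids, per_gene = [], {}
        for g in self.guides:
            per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + 1
            ids.append(f"{g.gene_id}_{per_gene[g.gene_id]}")
        return ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, g in zip(self.guide_ids(), self.guides):
            rows.append(
                {
                    "guide_id": gid,
                    "gene_id": g.gene_id,
                    "spacer": g.spacer,
                    "replicon": g.replicon,
                    "strand": g.pam_strand,
                    "start": g.protospacer_start + 1,  # 1-based in output
                    "end": g.protospacer_end,
                    "offset": g.offset_nt,
                    "gc": round(g.gc_fraction, 4),
                    "offtargets": g.offtarget_count,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "guide_id",
                "gene_id",
                "spacer",
                "replicon",
                "strand",
                "start",
                "end",
                "offset",
                "gc",
                "offtargets",
            ],
        )


# ---------------------------------------------------------------- enumeration


def enumerate_candidates(
    genome: AnnotatedGenome,
    gene: Feature,
    window_cfg: WindowConfig = WindowConfig(),
) -> list[GuideCandidate]:
    """All pattern matches for one gene inside the placement window.

    Matches at the same PAM for several spacer lengths collapse to the
    shortest spacer. Composition filtering is applied separately.
    """
    seq = genome.replicons[gene.replicon]
    n = len(seq)
    anchor = gene.anchor
    win_max = window_cfg.window_max(gene.length)
    out: list[GuideCandidate] = []

    if gene.strand == "+":
        # protospacer + NGG read directly on the forward strand
        for offset in range(0, win_max + 1):
            e3 = anchor + offset  # forward coord of PAM-proximal protospacer base
            if e3 + 3 >= n and not genome.circular:
                break
            if _base(seq, e3 + 2, n) != "G" or _base(seq, e3 + 3, n) != "G":
                continue
            for L in range(MIN_SPACER_LEN, MAX_SPACER_LEN + 1):
                start = e3 - L + 1
                if start < 0 and not genome.circular:
                    break
                spacer = _segment(seq, start, e3 + 1, n)
                if spacer[0] != "A":
                    continue
                out.append(
                    GuideCandidate(
                        gene_id=gene.feature_id,
                        spacer=spacer,
                        replicon=gene.replicon,
                        pam_strand="+",
                        protospacer_start=start % n,
                        protospacer_end=e3 + 1,
                        offset_nt=offset,
                        gc_fraction=_gc(spacer),
                    )
                )
                break  # shortest spacer at this PAM
    else:
        # protospacer + NGG on the reverse strand: forward shows CCN + revcomp
        for offset in range(0, win_max + 1):
            p = anchor - offset  # forward coord of PAM-proximal protospacer base
            if p - 3 < 0 and not genome.circular:
                break
            if _base(seq, p - 2, n) != "C" or _base(seq, p - 3, n) != "C":
                continue
            for L in range(MIN_SPACER_LEN, MAX_SPACER_LEN + 1):
                if p + L > n and not genome.circular:
                    break
                segment = _segment(seq, p, p + L, n)
                if segment[-1] != "T":
                    continue
                spacer = reverse_complement(segment)
                out.append(
                    GuideCandidate(
                        gene_id=gene.feature_id,
                        spacer=spacer,
                        replicon=gene.replicon,
                        pam_strand="-",
                        protospacer_start=p % n,
                        protospacer_end=(p + L - 1) % n + 1,
                        offset_nt=offset,
                        gc_fraction=_gc(spacer),
                    )
                )
                break
    return out


def _base(seq: str, i: int, n: int) -> str:
    return seq[i % n]


def _segment(seq: str, start: int, end: int, n: int) -> str:
    if 0 <= start and end <= n:
        return seq[start:end]
    return "".join(seq[i % n] for i in range(start, end))


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


# --------------------------------------------------------------- composition


def spacer_composition_ok(spacer: str) -> tuple[bool, str]:
    """Composition filter: no G6 run, no T4 run, GC within [0.25, 0.75]."""
    if set(spacer) - set("ACGT"):
        raise ValueError(f"spacer has non-ACGT characters: {spacer!r}")
    if not (MIN_SPACER_LEN <= len(spacer) <= MAX_SPACER_LEN):
        raise ValueError(f"spacer length {len(spacer)} outside 20-25")
    if "G" * 6 in spacer:
        return False, "G6"
    if "T" * 4 in spacer:
        return False, "T4"
    if not 0.25 <= _gc(spacer) <= 0.75:
        return False, "GC"
    return True, ""


# ---------------------------------------------------------------- off-targets


class OffTargetScanner:
    """Vectorized exhaustive scan for near-matches of a spacer's
    PAM-proximal 17-mer next to an NGG/NAG PAM, on both strands.

    The whole genome is scanned with numpy sliding windows; this is exact
    (proven against a per-position brute-force oracle in the test suite)
    and fast at bacterial genome scale.
    """

    def __init__(self, genome: AnnotatedGenome):
        self.genome = genome
        self._windows: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in genome.replicons.items():
            for strand in ("+", "-"):
                oriented = seq if strand == "+" else reverse_complement(seq)
                ext = oriented + (oriented[: CORE_LEN + 2] if genome.circular else "")
                arr = np.frombuffer(ext.encode(), dtype=np.uint8)
                span = CORE_LEN + 3
                if len(arr) < span:
                    self._windows[(name, strand)] = (
                        np.empty((0, span), dtype=np.uint8),
                        np.empty(0, dtype=np.intp),
                    )
                    continue
                w = np.lib.stride_tricks.sliding_window_view(arr, span)
                n_start = len(seq) if genome.circular else len(seq) - span + 1
                w = w[:n_start]
                pam = np.isin(w[:, CORE_LEN + 1], PAM_SECOND_BASES) & (
                    w[:, CORE_LEN + 2] == ord("G")
                )
                self._windows[(name, strand)] = (
                    np.ascontiguousarray(w[pam, :CORE_LEN]),
                    np.flatnonzero(pam),
                )

    def count(
        self,
        spacer: str,
        on_target: Optional[tuple[str, str, int]] = None,
        max_mismatches: int = 1,
    ) -> int:
        """Number of genomic sites whose PAM-proximal 17-mer is within
        ``max_mismatches`` of the spacer's, excluding the on-target site."""
        if len(spacer) < CORE_LEN:
            raise ValueError(f"spacer shorter than {CORE_LEN} nt")
        core = np.frombuffer(spacer[-CORE_LEN:].encode(), dtype=np.uint8)
        total = 0
        for (name, strand), (wins, starts) in self._windows.items():
            if len(wins) == 0:
                continue
            hits = (wins != core).sum(axis=1) <= max_mismatches
            if not hits.any():
                continue
            n = len(self.genome.replicons[name])
            hit_starts = starts[hits]
            if on_target is not None and on_target[0] == name:
                fwd = (
                    hit_starts
                    if strand == "+"
                    else (n - (hit_starts + CORE_LEN)) % n
                )
                keep = ~((strand == on_target[1]) & (fwd == on_target[2]))
                total += int(keep.sum())
            else:
                total += int(hits.sum())
        return total


def count_offtargets(
    spacer: str,
    genome: AnnotatedGenome,
    on_target: Optional[tuple[str, str, int]] = None,
    scanner: Optional[OffTargetScanner] = None,
) -> int:
    """Off-target count for one spacer; see :class:`OffTargetScanner`.

    ``on_target`` is the canonical (replicon, strand, forward core start)
    of the guide's own site (``GuideCandidate.core_site``).
    """
    scanner = scanner or OffTargetScanner(genome)
    return scanner.count(spacer, on_target=on_target)


# ------------------------------------------------------------------ selection


def select_guides(candidates: Sequence[GuideCandidate]) -> list[GuideCandidate]:
    """Pick up to two guides: fewest off-targets first, then closest to the
    anchor, then leftmost coordinate; the second guide must start >=10 nt
    from the first when any such candidate exists."""
    ranked = sorted(
        candidates,
        key=lambda g: (
            g.offtarget_count if g.offtarget_count is not None else 0,
            g.offset_nt,
            g.replicon,
            g.protospacer_start,
            g.spacer,
        ),
    )
    if not ranked:
        return []
    first = ranked[0]
    rest = ranked[1:]
    if not rest:
        return [first]
    apart = [g for g in rest if abs(g.protospacer_start - first.protospacer_start) >= 10]
    second = apart[0] if apart else rest[0]
    return [first, second]


def design_library(
    genome: AnnotatedGenome,
    window_cfg: WindowConfig = WindowConfig(),
) -> GuideLibrary:
    """Full design: enumerate -> composition filter -> off-target count ->
    per-gene selection. Genes without candidates are recorded, not fatal."""
    scanner = OffTargetScanner(genome)
    guides: list[GuideCandidate] = []
    status: dict[str, str] = {}
    for gene in genome.features:
        cands = enumerate_candidates(genome, gene, window_cfg)
        cands = [c for c in cands if spacer_composition_ok(c.spacer)[0]]
        # drop duplicate spacers within a gene (distinct PAM sites can
        # yield the same sequence); keep the closest-to-anchor copy
        seen: dict[str, GuideCandidate] = {}
        for c in sorted(cands, key=lambda g: (g.offset_nt, g.protospacer_start)):
            seen.setdefault(c.spacer, c)
        cands = list(seen.values())
        for c in cands:
            c.offtarget_count = scanner.count(c.spacer, on_target=c.core_site)
        chosen = select_guides(cands)
        guides.extend(chosen)
        status[gene.feature_id] = {2: "two", 1: "one", 0: "none"}[len(chosen)]
    return GuideLibrary(guides=guides, status=status)


# ------------------------------------------------------------------ summary


def composition_summary(
    two_orf: int, two_ncrna: int, one_orf: int, one_ncrna: int
) -> dict[str, int]:
    """Library accounting from per-class design counts."""
    for v in (two_orf, two_ncrna, one_orf, one_ncrna):
        if v < 0:
            raise ValueError("design counts must be non-negative")
    return {
        "total_sgRNAs": 2 * two_orf + 2 * two_ncrna + one_orf + one_ncrna,
        "ORF_sgRNAs": 2 * two_orf + one_orf,
        "ncRNA_sgRNAs": 2 * two_ncrna + one_ncrna,
    }
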