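"""Synthetic data generation with recorded ground truth.

Everything downstream of the wet lab is testable against this module: it
emits annotated genomes with planted guide binding sites, turbidostat
competition count time courses under the discrete depletion model

    f_i(t) = f_i(0) * (1 - (mu_pop - mu_mut_i))**t      (t in hours)

with multinomial or Dirichlet-multinomial read sampling, raw reads around
library spacers, and paired sorted/unsorted droplet-screen counts with
clone-level productivity truth.

All randomness flows from one master seed; per-sample and per-run
substreams are derived with fixed offsets so outputs are bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, Feature, reverse_complement
from .design import CORE_LEN, GuideLibrary

BASES = np.array(list("ACGT"))
LN2 = math.log(2)


# ------------------------------------------------------------------- configs


@dataclass
class CompetitionSimConfig:
    """Turbidostat competition experiment settings.

    ``depth`` defaults to 75 reads per clone per sample (set when the clone
    number is known); ``overdispersion`` is a Dirichlet concentration scale
    (``inf`` means pure multinomial sampling).
    """

    mu_pop: float = 0.07
    timepoints_h: Sequence[float] = (0.0, 48.0, 96.0, 192.0, 384.0)
    replicates: int = 4
    depth: Optional[int] = None
    overdispersion: Optional[float] = None  # default: 200 * n_clones
    condition: str = "L100"
    seed: int = 0

    def validate(self) -> None:
        t = list(self.timepoints_h)
        if t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints_h must be strictly increasing and start at 0")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class DropletSimConfig:
    """Droplet productivity screen settings.

    Defaults are proportional to a full-scale sort: ~10% droplet occupancy
    and the top 2% most fluorescent cell-containing droplets collected, in
    four sorting runs.
    """

    n_droplets: int = 360_000
    occupancy_lambda: float = 0.105
    noise_cv: float = 0.3
    sort_fraction: float = 0.02
    runs: int = 4
    depth: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.sort_fraction < 1:
            raise ValueError("sort_fraction must be in (0, 1)")
        if self.occupancy_lambda <= 0:
            raise ValueError("occupancy_lambda must be positive")
        if self.runs < 1 or self.n_droplets < 1:
            raise ValueError("runs and n_droplets must be positive")


def make_truth(
    clone_ids: Sequence[str],
    mu_mut: Sequence[float],
    f0: Optional[Sequence[float]] = None,
    productivity: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Assemble and validate a ground-truth table."""
    n = len(clone_ids)
    f0 = np.full(n, 1.0 / n) if f0 is None else np.asarray(f0, dtype=float)
    mu = np.asarray(mu_mut, dtype=float)
    if (mu < 0).any():
        raise ValueError("mu_mut must be non-negative")
    if abs(f0.sum() - 1.0) > 1e-9:
        raise ValueError("initial fractions must sum to 1")
    truth = pd.DataFrame({"clone_id": list(clone_ids), "mu_mut": mu, "f0": f0})
    if productivity is not None:
        prod = np.asarray(productivity, dtype=float)
        if (prod < 0).any():
            raise ValueError("productivity must be non-negative")
        truth["productivity"] = prod
    return truth


# -------------------------------------------------------------------- genome


def make_genome(
    seed: int,
    length_nt: int,
    n_genes: int,
    gc_fraction: float,
    orf_fraction: float = 0.8,
) -> AnnotatedGenome:
    """Random circular replicon with non-overlapping genes on both strands.

    Each gene gets a TSS at or up to 50 nt upstream of its start codon.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_genes * 300 > length_nt:
        raise ValueError(
            f"cannot pack {n_genes} genes of >=300 nt into {length_nt} nt"
        )
    rng = np.random.default_rng([seed, 101])
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(BASES, size=length_nt, p=p))

    margin = 60  # room for an upstream TSS and intergenic spacing
    placed: list[tuple[int, int]] = []
    features: list[Feature] = []
    attempts = 0
    while len(features) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise RuntimeError("could not place genes without overlap; genome too dense")
        glen = int(rng.integers(300, 901))
        start = int(rng.integers(margin, length_nt - glen - margin))
        if any(start - margin < e and s < start + glen + margin for s, e in placed):
            continue
        placed.append((start, start + glen))
        strand = "+" if rng.random() < 0.5 else "-"
        if len(features) < 2:  # guarantee both strands are represented
            strand = "+" if len(features) == 0 else "-"
        kind = "ORF" if rng.random() < orf_fraction else "ncRNA"
        tss_off = int(rng.integers(0, 51))
        tss = start - tss_off if strand == "+" else start + glen - 1 + tss_off
        features.append(
            Feature(
                feature_id=f"g{len(features) + 1:04d}",
                kind=kind,
                replicon="chr",
                strand=strand,
                start=start,
                end=start + glen,
                tss=tss,
            )
        )
    features.sort(key=lambda f: f.start)
    features = [
        Feature(f"g{i + 1:04d}", f.kind, f.replicon, f.strand, f.start, f.end, f.tss)
        for i, f in enumerate(features)
    ]
    return AnnotatedGenome({"chr": seq}, features, circular=True)


@dataclass(frozen=True)
class PlantedSite:
    replicon: str
    strand: str
    core_start: int  # forward coord of the PAM-proximal 17-mer window
    mismatches: int
    pam: str


def plant_site(
    genome: AnnotatedGenome,
    spacer: str,
    mismatches: int,
    pam: str,
    strand: str,
    position: int,
    seed: int,
    max_retries: int = 10,
) -> tuple[AnnotatedGenome, PlantedSite]:
    """Edit the genome so a copy of ``spacer`` (+PAM) with the requested
    number of PAM-proximal mismatches exists at ``position`` (forward coord
    of the site's leftmost base). Edits that accidentally create additional
    near-matching sites elsewhere are re-randomized, then rejected.
    """
    if pam not in ("NGG", "NAG"):
        raise ValueError("pam must be 'NGG' or 'NAG'")
    if mismatches > len(spacer):
        raise ValueError("more mismatches than spacer bases")
    rep = next(iter(genome.replicons))
    seq = genome.replicons[rep]
    site_len = len(spacer) + 3
    if not 0 <= position <= len(seq) - site_len:
        raise ValueError("position leaves no room for site + PAM")

    from .design import OffTargetScanner  # local import to avoid cycle

    before = OffTargetScanner(genome).count(spacer, on_target=None)
    rng = np.random.default_rng([seed, 757])
    for _ in range(max_retries):
        chars = list(spacer)
        core_positions = list(range(len(spacer) - CORE_LEN, len(spacer)))
        for i in rng.choice(core_positions, size=mismatches, replace=False):
            alts = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alts[int(rng.integers(3))]
        n_base = str(rng.choice(BASES))
        site = "".join(chars) + n_base + ("GG" if pam == "NGG" else "AG")
        insert = site if strand == "+" else reverse_complement(site)
        new_seq = seq[:position] + insert + seq[position + site_len :]
        edited = AnnotatedGenome({rep: new_seq}, list(genome.features), genome.circular)
        after = OffTargetScanner(edited).count(spacer, on_target=None)
        expected = before + (1 if mismatches <= 1 else 0)
        if after == expected:
            if strand == "+":
                core_start = position + len(spacer) - CORE_LEN
            else:
                core_start = position + 3
            return edited, PlantedSite(rep, strand, core_start, mismatches, pam)
    raise RuntimeError(
        "planting the site repeatedly created or destroyed other matches"
    )


# --------------------------------------------------------------- competition


@dataclass
class CompetitionSim:
    counts: pd.DataFrame  # clones x samples
    meta: pd.DataFrame  # per-sample metadata, indexed by sample_id
    expected_raw: pd.DataFrame  # clones x timepoints, model fractions
    expected_renorm: pd.DataFrame  # renormalized to sum to 1 per timepoint


def depletion_fractions(
    f0: np.ndarray, mu_mut: np.ndarray, mu_pop: float, times_h: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected clone fractions under the discrete per-hour depletion model,
    raw and renormalized per timepoint."""
    mu_diff = mu_pop - np.asarray(mu_mut, dtype=float)
    if (mu_diff >= 1).any():
        raise ValueError("mu_pop - mu_mut >= 1 leaves no valid clone fraction")
    t = np.asarray(times_h, dtype=float)
    raw = np.asarray(f0, dtype=float)[:, None] * (1.0 - mu_diff[:, None]) ** t[None, :]
    renorm = raw / raw.sum(axis=0, keepdims=True)
    cols = [float(x) for x in t]
    return (
        pd.DataFrame(raw, columns=cols),
        pd.DataFrame(renorm, columns=cols),
    )


def generations(mu_pop: float, t: float) -> float:
    """Cell generations in t hours at growth rate mu_pop (h^-1)."""
    if mu_pop < 0 or t < 0:
        raise ValueError("mu_pop and t must be non-negative")
    return mu_pop * t / LN2


def simulate_competition(
    clone_ids: Sequence[str],
    truth: pd.DataFrame,
    cfg: CompetitionSimConfig,
) -> CompetitionSim:
    """Simulate a pooled turbidostat competition time course.

    ``truth`` must provide mu_mut and f0 for every clone in ``clone_ids``.
    """
    cfg.validate()
    truth = truth.set_index("clone_id").loc[list(clone_ids)]
    n = len(truth)
    depth = cfg.depth if cfg.depth is not None else 75 * n
    conc = cfg.overdispersion if cfg.overdispersion is not None else 200.0 * n

    raw, renorm = depletion_fractions(
        truth["f0"].to_numpy(), truth["mu_mut"].to_numpy(), cfg.mu_pop, cfg.timepoints_h
    )
    raw.index = renorm.index = list(clone_ids)

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for rep in range(1, cfg.replicates + 1):
        for ti, t in enumerate(cfg.timepoints_h):
            rng = np.random.default_rng([cfg.seed, 3001, rep, ti])
            p = renorm.iloc[:, ti].to_numpy()
            if np.isfinite(conc):
                p = rng.dirichlet(conc * p)
            sample_id = f"{cfg.condition}_t{int(t)}_r{rep}"
            counts[sample_id] = rng.multinomial(depth, p)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "condition": cfg.condition,
                    "time_h": float(t),
                    "replicate": rep,
                    "induced": True,
                    "mu_pop": cfg.mu_pop,
                    "n_gen": generations(cfg.mu_pop, float(t)),
                }
            )
    counts_df = pd.DataFrame(counts, index=list(clone_ids))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CompetitionSim(counts_df, meta, raw, renorm)


# --------------------------------------------------------------------- reads


def simulate_reads(
    counts: pd.DataFrame,
    spacers: Mapping[str, str],
    flank5: str,
    flank3: str,
    read_len: int,
    seed: int,
) -> dict[str, list[str]]:
    """One read per counted unit: flank5 + spacer + flank3, truncated to
    ``read_len`` and shuffled deterministically per sample."""
    max_spacer = max(len(s) for s in spacers.values())
    if read_len < len(flank5) + max_spacer:
        raise ValueError("read_len too short to contain flank5 + longest spacer")
    out: dict[str, list[str]] = {}
    for si, sample in enumerate(counts.columns):
        reads: list[str] = []
        for guide_id, c in counts[sample].items():
            if c <= 0:
                continue
            read = (flank5 + spacers[guide_id] + flank3)[:read_len]
            reads.extend([read] * int(c))
        rng = np.random.default_rng([seed, 4001, si])
        rng.shuffle(reads)
        out[sample] = reads
    return out


def write_fastq(reads_by_sample: Mapping[str, list[str]], directory) -> list[str]:
    """Write one FASTQ file per sample; returns the paths written."""
    from pathlib import Path

    paths = []
    for sample, reads in reads_by_sample.items():
        path = Path(directory) / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i, read in enumerate(reads):
                fh.write(f"@{sample}:{i}\n{read}\n+\n{'I' * len(read)}\n")
        paths.append(str(path))
    return paths


# ------------------------------------------------------------- droplet sort


@dataclass
class DropletScreenSim:
    unsorted: pd.DataFrame  # clones x runs, read counts
    sorted: pd.DataFrame  # clones x runs, read counts
    sorted_cells: pd.DataFrame  # clones x runs, cell counts in kept droplets
    n_cell_containing: list[int]
    n_sorted_droplets: list[int]


def simulate_droplet_screen(
    clone_ids: Sequence[str],
    truth: pd.DataFrame,
    cfg: DropletSimConfig,
) -> DropletScreenSim:
    """Poisson droplet occupancy, per-droplet fluorescence proportional to
    the summed productivity of its cells times lognormal noise, sorting of
    the top ``sort_fraction`` of cell-containing droplets, and multinomial
    read sampling of both fractions."""
    cfg.validate()
    truth = truth.set_index("clone_id").loc[list(clone_ids)]
    if "productivity" not in truth:
        raise ValueError("truth table lacks a productivity column")
    f0 = truth["f0"].to_numpy()
    prod = truth["productivity"].to_numpy()
    n_clones = len(truth)
    depth = cfg.depth if cfg.depth is not None else 75 * n_clones

    if cfg.noise_cv > 0:
        sigma = math.sqrt(math.log(1 + cfg.noise_cv**2))
    else:
        sigma = 0.0

    unsorted_cols, sorted_cols, cell_cols = {}, {}, {}
    n_cc, n_sd = [], []
    for run in range(1, cfg.runs + 1):
        rng = np.random.default_rng([cfg.seed, 5001, run])
        occupancy = rng.poisson(cfg.occupancy_lambda, size=cfg.n_droplets)
        total_cells = int(occupancy.sum())
        cell_clone = rng.choice(n_clones, size=total_cells, p=f0)
        droplet_of_cell = np.repeat(np.arange(cfg.n_droplets), occupancy)
        fluor = np.bincount(
            droplet_of_cell, weights=prod[cell_clone], minlength=cfg.n_droplets
        )
        if sigma > 0:
            fluor = fluor * rng.lognormal(-sigma**2 / 2, sigma, size=cfg.n_droplets)
        containing = np.flatnonzero(occupancy > 0)
        n_keep = int(round(cfg.sort_fraction * len(containing)))
        order = containing[np.argsort(fluor[containing], kind="stable")[::-1]]
        kept = set(order[:n_keep].tolist())
        kept_mask = np.fromiter(
            (d in kept for d in droplet_of_cell), dtype=bool, count=total_cells
        )
        cell_counts = np.bincount(cell_clone[kept_mask], minlength=n_clones)

        col = f"run{run}"
        cell_cols[col] = cell_counts
        if cell_counts.sum() > 0:
            sorted_cols[col] = rng.multinomial(depth, cell_counts / cell_counts.sum())
        else:
            sorted_cols[col] = np.zeros(n_clones, dtype=int)
        unsorted_cols[col] = rng.multinomial(depth, f0)
        n_cc.append(len(containing))
        n_sd.append(n_keep)

    idx = list(clone_ids)
    return DropletScreenSim(
        unsorted=pd.DataFrame(unsorted_cols, index=idx),
        sorted=pd.DataFrame(sorted_cols, index=idx),
        sorted_cells=pd.DataFrame(cell_cols, index=idx),
        n_cell_containing=n_cc,
        n_sorted_droplets=n_sd,
    )
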