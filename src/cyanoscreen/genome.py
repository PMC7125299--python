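"""Annotated genome container with FASTA / GFF3 / TSV input-output.

Coordinates are 0-based half-open internally and converted to 1-based
inclusive at the GFF3 boundary. Replicons are circular by default, as in
most bacterial genomes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
FEATURE_KINDS = ("ORF", "ncRNA")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Feature:
    """A gene feature (ORF or ncRNA) on a replicon.

    ``start``/``end`` are 0-based half-open genome coordinates; ``tss`` is
    the transcription start site (0-based position of the first transcribed
    base) when known.
    """

    feature_id: str
    kind: str
    replicon: str
    strand: str
    start: int
    end: int
    tss: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty feature interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Design anchor: the TSS when annotated, else the translation start."""
        if self.tss is not None:
            return self.tss
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class AnnotatedGenome:
    """Replicon sequences plus gene features."""

    replicons: dict[str, str]
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, seq in self.replicons.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"replicon {name!r} has non-ACGT characters {sorted(bad)}")
        for f in self.features:
            if f.replicon not in self.replicons:
                raise ValueError(f"feature {f.feature_id} on unknown replicon {f.replicon!r}")
            n = len(self.replicons[f.replicon])
            if not (0 <= f.start < f.end <= n):
                raise ValueError(f"feature {f.feature_id} outside replicon bounds")

    def copy(self) -> "AnnotatedGenome":
        return AnnotatedGenome(dict(self.replicons), list(self.features), self.circular)

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.replicons.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        """Write features as GFF3 (1-based, inclusive)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.replicons.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for f in self.features:
                gff_type = "gene" if f.kind == "ORF" else "ncRNA"
                attrs = f"ID={f.feature_id};kind={f.kind}"
                if f.tss is not None:
                    attrs += f";tss={f.tss + 1}"
                fh.write(
                    "\t".join(
                        [
                            f.replicon,
                            "cyanoscreen",
                            gff_type,
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    def annotation_frame(self) -> pd.DataFrame:
        """Tab-friendly annotation table (1-based inclusive coordinates)."""
        rows = [
            {
                "gene_id": f.feature_id,
                "kind": f.kind,
                "replicon": f.replicon,
                "strand": f.strand,
                "start": f.start + 1,
                "end": f.end,
                "tss": f.tss + 1 if f.tss is not None else pd.NA,
            }
            for f in self.features
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_fasta_gff3(
        cls, fasta: str | Path, gff3: str | Path, circular: bool = True
    ) -> "AnnotatedGenome":
        replicons = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        features = list(_parse_gff3(gff3))
        return cls(replicons, features, circular)

    @classmethod
    def from_fasta_tsv(
        cls, fasta: str | Path, annotation: str | Path, circular: bool = True
    ) -> "AnnotatedGenome":
        """Read annotation from a tab-delimited table with columns
        gene_id, kind, strand, start, end and optional replicon, tss
        (1-based inclusive)."""
        replicons = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        tab = pd.read_csv(annotation, sep="\t")
        default_rep = next(iter(replicons))
        features = []
        for row in tab.itertuples(index=False):
            tss = getattr(row, "tss", None)
            tss = None if tss is None or pd.isna(tss) else int(tss) - 1
            features.append(
                Feature(
                    feature_id=str(row.gene_id),
                    kind=str(row.kind),
                    replicon=str(getattr(row, "replicon", default_rep)),
                    strand=str(row.strand),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    tss=tss,
                )
            )
        return cls(replicons, features, circular)


def _parse_gff3(path: str | Path) -> Iterable[Feature]:
    kind_by_type = {"gene": "ORF", "ncRNA": "ncRNA"}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            kind = attr.get("kind", kind_by_type.get(ftype, "ORF"))
            tss = attr.get("tss")
            yield Feature(
                feature_id=attr.get("ID", f"{seqid}:{start}-{end}"),
                kind=kind,
                replicon=seqid,
                strand=strand,
                start=int(start) - 1,
                end=int(end),
                tss=int(tss) - 1 if tss is not None else None,
            )
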