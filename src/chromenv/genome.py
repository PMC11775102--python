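"""Coordinate frame for all region operations.

All coordinates are 0-based, half-open ``[start, end)`` internally (the BED
convention). GTF input, which is 1-based inclusive, is converted on read.
Peak strand is ignored throughout: ChIP/CUT&Tag peaks are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class GenomeAssembly:
    """Ordered set of chromosomes with lengths (a chrom-sizes table)."""

    def __init__(self, chromosomes):
        names = [str(n) for n, _ in chromosomes]
        lengths = [int(l) for _, l in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for n, l in zip(names, lengths):
            if l < 1:
                raise ValueError(f"chromosome {n} has non-positive length {l}")
        self._lengths = dict(zip(names, lengths))
        self.names = names

    def __contains__(self, chrom):
        return chrom in self._lengths

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return len(self.names)

    def length(self, chrom):
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly") from None

    def items(self):
        return [(n, self._lengths[n]) for n in self.names]

    def __eq__(self, other):
        return isinstance(other, GenomeAssembly) and self.items() == other.items()

    def __repr__(self):
        return f"GenomeAssembly({len(self.names)} chromosomes, {sum(self._lengths.values()):,} bp)"


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start

    def validate(self, assembly: GenomeAssembly):
        if self.chrom not in assembly:
            raise ValueError(f"chromosome {self.chrom!r} not in assembly")
        if self.end > assembly.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} beyond chromosome end"
            )
        return self

    def clipped(self, assembly: GenomeAssembly) -> "Interval":
        """Clip to chromosome bounds (windows near telomeres)."""
        length = assembly.length(self.chrom)
        return Interval(self.chrom, max(0, self.start), min(self.end, length), self.strand)


class PeakSet:
    """A labelled collection of unstranded intervals, e.g. one mark at one stage.

    Stored as a DataFrame with columns chrom/start/end (+ optional score),
    sorted by (chrom, start, end); duplicate (chrom, start, end) rows rejected.
    """

    def __init__(self, label: str, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"PeakSet frame needs columns {sorted(required)}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"start >= end at {bad['chrom']}:{bad['start']}-{bad['end']}")
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "start", "end"]).any():
            raise ValueError("duplicate (chrom, start, end) in peak set")
        self.label = label
        self.df = df

    @classmethod
    def from_intervals(cls, label, intervals, scores=None):
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in intervals],
                "start": [iv.start for iv in intervals],
                "end": [iv.end for iv in intervals],
            }
        )
        if scores is not None:
            df["score"] = list(scores)
        return cls(label, df)

    def intervals(self):
        return [Interval(c, s, e) for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])]

    def validate(self, assembly: GenomeAssembly):
        for chrom, end_max in self.df.groupby("chrom")["end"].max().items():
            if chrom not in assembly:
                raise ValueError(f"chromosome {chrom!r} not in assembly")
            if end_max > assembly.length(chrom):
                raise ValueError(f"peak beyond end of {chrom}")
        return self

    def __len__(self):
        return len(self.df)

    def __repr__(self):
        return f"PeakSet({self.label!r}, n={len(self.df)})"


# Six-group functional annotation scheme plus the "other" bucket for
# biotypes the scheme does not cover.
BIOTYPE_GROUPS = ("IG-TR", "protein_coding", "pseudogene", "lncRNA", "mtRNA", "snoRNA")

_BIOTYPE_LOOKUP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "bidirectional_promoter_lncRNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "3prime_overlapping_ncRNA": "lncRNA",
    "macro_lncRNA": "lncRNA",
    "Mt_rRNA": "mtRNA",
    "Mt_tRNA": "mtRNA",
    "snoRNA": "snoRNA",
}


def biotype_group(gene_type: str) -> str:
    """Collapse a Gencode gene_type into the six-group scheme, else 'other'."""
    if gene_type in _BIOTYPE_LOOKUP:
        return _BIOTYPE_LOOKUP[gene_type]
    if "pseudogene" in gene_type:
        return "pseudogene"
    if gene_type.startswith(("IG_", "TR_")):
        return "IG-TR"
    return "other"


@dataclass(frozen=True)
class GeneModel:
    """Gene-level model; TSS is the 5' end of the body given the strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: Interval
    length: int
    biotype: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        expect_tss = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expect_tss:
            raise ValueError(f"gene {self.gene_id}: tss inconsistent with strand")
        if self.length != len(self.body):
            raise ValueError(f"gene {self.gene_id}: length inconsistent with body")


def make_gene(gene_id, chrom, start, end, strand, biotype="protein_coding") -> GeneModel:
    body = Interval(chrom, start, end, strand)
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id, chrom, strand, tss, body, end - start, biotype)


def gene_table(genes) -> pd.DataFrame:
    """Vector view of a list of GeneModel, one row per gene."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "start": [g.body.start for g in genes],
            "end": [g.body.end for g in genes],
            "length": [g.length for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    )
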