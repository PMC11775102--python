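"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED5 (tab-separated, no header), Gencode-dialect GTF (gene-level records),
chrom-sizes TSV, per-chromosome binarized/continuous track TSVs, count matrices.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, GeneModel, Interval, PeakSet, biotype_group


class ParseError(ValueError):
    pass


def read_chrom_sizes(path) -> GenomeAssembly:
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{i}: expected 2 tab-separated columns")
            pairs.append((fields[0], int(fields[1])))
    return GenomeAssembly(pairs)


def write_chrom_sizes(assembly: GenomeAssembly, path):
    with open(path, "w") as fh:
        for name, length in assembly.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path, assembly: GenomeAssembly | None = None, label=None, lenient=False) -> PeakSet:
    """Read a 3+ column BED into a PeakSet (no merging, overlaps preserved).

    With ``lenient=True`` lines on chromosomes absent from the assembly are
    skipped (with a count kept on the returned set) instead of rejected.
    """
    rows, skipped = [], 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: BED line has {len(fields)} columns, need >=3")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from None
            if not (0 <= start < end):
                raise ParseError(f"{path}:{i}: invalid interval {chrom}:{start}-{end}")
            if assembly is not None:
                if chrom not in assembly:
                    if lenient:
                        skipped += 1
                        continue
                    raise ParseError(f"{path}:{i}: chromosome {chrom!r} not in assembly")
                if end > assembly.length(chrom):
                    raise ParseError(f"{path}:{i}: interval beyond end of {chrom}")
            score = float(fields[4]) if len(fields) >= 5 else None
            name = fields[3] if len(fields) >= 4 else None
            rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    if df["score"].isna().all():
        df = df.drop(columns="score")
    if df["name"].isna().all():
        df = df.drop(columns="name")
    ps = PeakSet(label or Path(path).stem, df)
    ps.n_skipped = skipped
    return ps


def write_bed(peaks: PeakSet, path):
    """Write BED3 (or BED5 when names/scores are present)."""
    df = peaks.df
    cols = ["chrom", "start", "end"]
    if "score" in df.columns:
        name = df["name"] if "name" in df.columns else pd.Series(["."] * len(df))
        out = df[cols].assign(name=name.values, score=df["score"].values)
    elif "name" in df.columns:
        out = df[cols + ["name"]]
    else:
        out = df[cols]
    out.to_csv(path, sep="\t", header=False, index=False)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models(path, assembly: GenomeAssembly | None = None):
    """Parse gene-level GTF records into GeneModel objects.

    Returns ``(genes, report)`` where report counts biotypes that fell
    outside the six-group annotation scheme (labelled "other").
    """
    genes, seen = [], set()
    other_biotypes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{i}: GTF line has {len(fields)} columns, need 9")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ParseError(f"{path}:{i}: gene record missing gene_id attribute")
            gene_id = attrs["gene_id"]
            if gene_id in seen:
                raise ParseError(f"{path}:{i}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{i}: gene {gene_id} has strand {strand!r}")
            start, end = start1 - 1, end1  # 1-based inclusive -> half-open
            group = biotype_group(attrs.get("gene_type", ""))
            if group == "other":
                raw = attrs.get("gene_type", "")
                other_biotypes[raw] = other_biotypes.get(raw, 0) + 1
            body = Interval(chrom, start, end, strand)
            if assembly is not None:
                body.validate(assembly)
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel(gene_id, chrom, strand, tss, body, end - start, group))
    return genes, {"n_genes": len(genes), "other_biotypes": other_biotypes}


def write_gene_models(genes, path, source="chromenv"):
    """Write gene-level GTF (coordinates converted back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_track(path) -> tuple[list[str], np.ndarray]:
    """Per-chromosome track TSV: header row of mark names, one row per bin."""
    df = pd.read_csv(path, sep="\t")
    return list(df.columns), df.to_numpy()


def write_track(marks, matrix, path, float_format=None):
    pd.DataFrame(matrix, columns=marks).to_csv(
        path, sep="\t", index=False, float_format=float_format
    )


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise ParseError(f"{path}: metadata needs a 'sample' column")
    return meta.set_index("sample")
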