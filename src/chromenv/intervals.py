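"""Interval algebra: pairwise intersection, merging, overlap flags, coverage.

All functions operate on half-open coordinates. The pairwise primitives return
index pairs so callers can join back arbitrary per-interval annotations.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, Interval


def _as_arrays(intervals):
    """Group intervals by chromosome -> (original indices, starts, ends)."""
    by_chrom = defaultdict(list)
    for i, iv in enumerate(intervals):
        by_chrom[iv.chrom].append((i, iv.start, iv.end))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: (r[1], r[2]))
        idx = np.array([r[0] for r in rows], dtype=np.int64)
        starts = np.array([r[1] for r in rows], dtype=np.int64)
        ends = np.array([r[2] for r in rows], dtype=np.int64)
        out[chrom] = (idx, starts, ends)
    return out


def frame_to_intervals(df) -> list[Interval]:
    return [Interval(c, s, e) for c, s, e in zip(df["chrom"], df["start"], df["end"])]


def intersect(a, b, min_overlap: int = 1):
    """All pairs (index_a, index_b, overlap_bp) with overlap >= min_overlap.

    overlap_bp = min(end_a, end_b) - max(start_a, start_b).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a_by = _as_arrays(a)
    b_by = _as_arrays(b)
    pairs = []
    for chrom, (ia, sa, ea) in a_by.items():
        if chrom not in b_by:
            continue
        ib, sb, eb = b_by[chrom]
        for k in range(len(ia)):
            # candidates: b.start <= a.end - min_overlap
            hi = np.searchsorted(sb, ea[k] - min_overlap, side="right")
            if hi == 0:
                continue
            ov = np.minimum(ea[k], eb[:hi]) - np.maximum(sa[k], sb[:hi])
            keep = np.nonzero(ov >= min_overlap)[0]
            for j in keep:
                pairs.append((int(ia[k]), int(ib[j]), int(ov[j])))
    pairs.sort()
    return pairs


def overlaps_any(query_df: pd.DataFrame, subject_df: pd.DataFrame, min_overlap: int = 1) -> np.ndarray:
    """Boolean per query row: does it overlap any subject region by >= min_overlap bp?

    Vectorized on frames with chrom/start/end columns.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    flags = np.zeros(len(query_df), dtype=bool)
    subj = {}
    for chrom, g in subject_df.groupby("chrom"):
        ss = g["start"].to_numpy()
        se = g["end"].to_numpy()
        order = np.argsort(ss, kind="mergesort")
        subj[chrom] = (ss[order], se[order])
    qpos = np.arange(len(query_df))
    qchrom = query_df["chrom"].to_numpy()
    for chrom, g in query_df.groupby("chrom"):
        if chrom not in subj:
            continue
        ss, se = subj[chrom]
        rows = qpos[qchrom == chrom]
        for r, s, e in zip(rows, g["start"].to_numpy(), g["end"].to_numpy()):
            hi = np.searchsorted(ss, e - min_overlap, side="right")
            if hi:
                ov = np.minimum(e, se[:hi]) - np.maximum(s, ss[:hi])
                if (ov >= min_overlap).any():
                    flags[r] = True
    return flags


def merge_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Merge strictly overlapping intervals of a single-chromosome frame.

    Book-ended intervals stay separate, matching an overlap-of->=1-bp merge
    rule. Returns (starts, ends) sorted and disjoint.
    """
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s < out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge a chrom/start/end frame into maximal regions (>=1 bp overlap)."""
    parts = []
    for chrom in sorted(df["chrom"].unique()):
        s, e = merge_frame(df[df["chrom"] == chrom])
        parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(parts, ignore_index=True)


def coverage_by_label(window: Interval, segmentation, assembly: GenomeAssembly | None = None) -> dict:
    """bp of each segmentation state label within the window.

    Uncovered bp are reported under the reserved label "unannotated"; the
    values always sum to the (possibly clipped) window length. Windows
    extending past the chromosome end are clipped.
    """
    if assembly is not None:
        window = window.clipped(assembly)
    out: dict[str, int] = {}
    covered = 0
    for label, s, e in segmentation.query(window.chrom, window.start, window.end):
        out[label] = out.get(label, 0) + (e - s)
        covered += e - s
    gap = len(window) - covered
    if gap > 0:
        out["unannotated"] = out.get("unannotated", 0) + gap
    return out
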