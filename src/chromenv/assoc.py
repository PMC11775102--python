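"""Permutation-based association between region sets.

The statistic is the number of query (A) regions overlapping at least one
subject (B) region. A null distribution is built by randomizing A —
``circular``: one random rotation per chromosome, preserving region count,
lengths and inter-region spacing; ``random_regions``: uniform re-placement of
each region preserving its length (optionally avoiding a mask). The empirical
p uses the +1 permutation correction; z = (obs - mean)/sd of the permuted
statistics, and the normalized z (nz) divides z by sqrt(|A|) so associations
of differently sized query sets are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAssembly, PeakSet


@dataclass
class AssociationResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    nz: float
    p: float
    n_perm: int
    seed: int
    n_regions_a: int
    strategy: str


def _prepare(peaks: PeakSet, assembly: GenomeAssembly):
    out = {}
    for chrom, g in peaks.df.groupby("chrom"):
        if chrom not in assembly:
            raise ValueError(f"chromosome {chrom!r} in peaks but not in assembly")
        out[chrom] = (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
    return out


def _merged(b_by_chrom):
    out = {}
    for chrom, (s, e) in b_by_chrom.items():
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        ms, me = [], []
        for a, b in zip(s, e):
            if ms and a < me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        out[chrom] = (np.array(ms), np.array(me))
    return out


def _count_overlaps(a_starts, a_ends, merged_b):
    """Number of [s,e) in A overlapping >=1 bp of the merged, disjoint B blocks."""
    ms, me = merged_b
    if len(ms) == 0 or len(a_starts) == 0:
        return 0
    lo = np.searchsorted(me, a_starts, side="right")
    hit = (lo < len(ms)) & (ms[np.minimum(lo, len(ms) - 1)] < a_ends)
    return int(hit.sum())


def _circular_shift(starts, ends, length, rng):
    shift = int(rng.integers(0, length))
    s = (starts + shift) % length
    e = s + (ends - starts)
    # regions wrapping past the chromosome end split into two pieces that
    # still count as one region: handled by testing both pieces
    return s, e


def _count_circular(a_by, merged_b, assembly, rng):
    total = 0
    for chrom, (s0, e0) in a_by.items():
        length = assembly.length(chrom)
        mb = merged_b.get(chrom, (np.array([]), np.array([])))
        s, e = _circular_shift(s0, e0, length, rng)
        wrap = e > length
        if wrap.any():
            ms, me = mb
            # non-wrapping part
            total += _count_overlaps(s[~wrap], e[~wrap], mb)
            for ws, we in zip(s[wrap], e[wrap]):
                hit = _count_overlaps(np.array([ws]), np.array([length]), mb) or \
                    _count_overlaps(np.array([0]), np.array([we - length]), mb)
                total += int(bool(hit))
        else:
            total += _count_overlaps(s, e, mb)
    return total


def _place_random(lengths, chrom_len, rng, mask=None, max_tries=100):
    """Uniform placement of region lengths on [0, chrom_len), avoiding mask."""
    starts = rng.integers(0, np.maximum(chrom_len - lengths, 1))
    if mask is None:
        return starts, starts + lengths
    ms, me = mask
    for i in range(len(starts)):
        for _ in range(max_tries):
            s, e = starts[i], starts[i] + lengths[i]
            lo = np.searchsorted(me, s, side="right")
            if lo >= len(ms) or ms[lo] >= e:
                break
            starts[i] = int(rng.integers(0, max(chrom_len - lengths[i], 1)))
        else:
            raise RuntimeError("could not place region outside mask")
    return starts, starts + lengths


def _count_random(a_by, merged_b, assembly, rng, mask_by):
    total = 0
    for chrom, (s0, e0) in a_by.items():
        length = assembly.length(chrom)
        lengths = e0 - s0
        s, e = _place_random(lengths, length, rng, mask=mask_by.get(chrom))
        total += _count_overlaps(s, e, merged_b.get(chrom, (np.array([]), np.array([]))))
    return total


def permutation_association(a: PeakSet, b: PeakSet, assembly: GenomeAssembly,
                            n_perm: int = 10_000, strategy: str = "circular",
                            mask: PeakSet | None = None, seed: int = 0) -> AssociationResult:
    """Permutation test of whether A regions overlap B more than expected."""
    if strategy not in ("circular", "random_regions"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a_by = _prepare(a, assembly)
    merged_b = _merged(_prepare(b, assembly))
    mask_by = _merged(_prepare(mask, assembly)) if mask is not None else {}

    observed = sum(
        _count_overlaps(s, e, merged_b.get(chrom, (np.array([]), np.array([]))))
        for chrom, (s, e) in a_by.items()
    )
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        if strategy == "circular":
            perm[i] = _count_circular(a_by, merged_b, assembly, rng)
        else:
            perm[i] = _count_random(a_by, merged_b, assembly, rng, mask_by)
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    n_a = len(a)
    nz = z / np.sqrt(n_a) if n_a > 0 else float("nan")
    p = (1 + int((perm >= observed).sum())) / (n_perm + 1)
    return AssociationResult(observed, mean, sd, z, nz, p, n_perm, seed, n_a, strategy)


def association_matrix(sets: dict[str, PeakSet], assembly: GenomeAssembly,
                       n_perm: int = 1000, strategy: str = "circular",
                       seed: int = 0, alpha: float = 0.05):
    """Pairwise permutation associations for all ordered pairs of sets.

    Returns (nz matrix, p matrix, BH-significance flags) as DataFrames.
    Diagonal cells are self-associations.
    """
    labels = list(sets)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate set labels")
    if len(labels) < 2:
        raise ValueError("need at least two sets")
    nz = pd.DataFrame(np.nan, index=labels, columns=labels)
    pv = pd.DataFrame(np.nan, index=labels, columns=labels)
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(len(labels) ** 2) % (2**31))
    for la in labels:
        for lb in labels:
            res = permutation_association(sets[la], sets[lb], assembly, n_perm=n_perm,
                                          strategy=strategy, seed=int(next(child_seeds)))
            nz.loc[la, lb] = res.nz
            pv.loc[la, lb] = res.p
    flat = pv.to_numpy().ravel()
    flags = multipletests(flat, alpha=alpha, method="fdr_bh")[0].reshape(pv.shape)
    sig = pd.DataFrame(flags, index=labels, columns=labels)
    return nz, pv, sig
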