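"""Heterologous spike-in scaling for CUT&Tag signal.

Samples receive spike-in nuclei (e.g. Drosophila) at a fixed ratio to target
cells, so reads mapping to the spike genome measure per-cell recovery. Signal
is multiplied by factor_i = reference / spike_reads_i, equalizing the
spike-derived signal across samples; the reference defaults to the minimum
spike count so that factors stay <= 1 and noise is never inflated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import gene_table


def spike_scale_factors(spike_counts: pd.DataFrame, reference: float | None = None) -> pd.DataFrame:
    """Per-sample scale factors from spike-in read counts.

    ``spike_counts`` needs columns ``sample`` and ``spike_reads`` (an optional
    ``target_reads`` column is carried through). Factors computed with
    different references are not comparable.
    """
    df = spike_counts.copy()
    if (df["spike_reads"] <= 0).any():
        bad = df.loc[df["spike_reads"] <= 0, "sample"].tolist()
        raise ValueError(f"zero or negative spike reads for samples {bad}")
    ref = float(reference) if reference is not None else float(df["spike_reads"].min())
    df["factor"] = ref / df["spike_reads"]
    df.attrs["reference"] = ref
    return df


def class_tss_profiles(tracks: dict[str, dict[str, np.ndarray]], signal_bin: int,
                       factors: pd.DataFrame, genotypes: pd.Series, genes,
                       de_status: pd.Series, window: int = 3000) -> pd.DataFrame:
    """Spike-scaled, strand-flipped TSS profiles per genotype x DE class.

    ``tracks`` maps sample -> chromosome -> per-bin signal at ``signal_bin``
    resolution; ``genotypes`` maps sample -> genotype; ``de_status`` maps
    gene_id -> {up, down, not}. Per sample the signal is multiplied by that
    sample's spike factor, profiles are averaged across the samples of a
    genotype, anchored at the TSS and flipped for minus-strand genes.

    Returns a long DataFrame with columns genotype, de_class, position, signal.
    Classes with no scorable genes are omitted (recorded in ``.attrs``).
    """
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    genes_df = genes_df[genes_df["gene_id"].isin(de_status.index)]
    fac = factors.set_index("sample")["factor"]
    n_bins = 2 * (window // signal_bin)
    offsets = (np.arange(n_bins) - n_bins // 2) * signal_bin + signal_bin // 2

    rows = []
    omitted = []
    for de_class in ("up", "down", "not"):
        ids = de_status.index[de_status == de_class]
        sub = genes_df[genes_df["gene_id"].isin(ids)]
        if len(sub) == 0:
            omitted.append(de_class)
            continue
        for genotype in sorted(genotypes.unique()):
            samples = genotypes.index[genotypes == genotype]
            acc = np.zeros(n_bins)
            n_prof = 0
            for sample in samples:
                track = tracks[sample]
                f = fac.loc[sample]
                for g in sub.itertuples():
                    if g.chrom not in track:
                        continue
                    vals = track[g.chrom]
                    pos = g.tss + offsets
                    idx = np.clip(pos // signal_bin, 0, len(vals) - 1).astype(int)
                    prof = vals[idx] * f
                    if g.strand == "-":
                        prof = prof[::-1]
                    acc += prof
                    n_prof += 1
            if n_prof == 0:
                omitted.append(f"{genotype}:{de_class}")
                continue
            mean_prof = acc / n_prof
            for p, v in zip(offsets, mean_prof):
                rows.append((genotype, de_class, int(p), v))
    out = pd.DataFrame(rows, columns=["genotype", "de_class", "position", "signal"])
    out.attrs["omitted"] = omitted
    return out
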