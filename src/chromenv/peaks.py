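"""Peak annotation, per-chromosome densities, cross-stage dynamics, TSS profiles.

Annotation uses the four-category scheme (promoter / intragenic / downstream /
distal intergenic) with an explicit priority order to resolve peaks touching
several features: promoter > intragenic > downstream > distal. The promoter
window is TSS +/- ``tss_window`` bp (strand-aware anchor); the downstream
window extends ``downstream_window`` bp past the 3' gene end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, PeakSet, gene_table
from .intervals import merge_intervals, overlaps_any

CATEGORIES = ("promoter", "intragenic", "downstream", "distal_intergenic")


def _window_frames(genes_df: pd.DataFrame, tss_window: int, downstream_window: int):
    plus = genes_df["strand"] == "+"
    promoter = pd.DataFrame(
        {
            "chrom": genes_df["chrom"],
            # inclusive +/- window around the TSS base
            "start": (genes_df["tss"] - tss_window).clip(lower=0),
            "end": genes_df["tss"] + tss_window + 1,
        }
    )
    body = genes_df[["chrom", "start", "end"]].copy()
    down = pd.DataFrame(
        {
            "chrom": genes_df["chrom"],
            "start": np.where(plus, genes_df["end"], (genes_df["start"] - downstream_window).clip(lower=0)),
            "end": np.where(plus, genes_df["end"] + downstream_window, genes_df["start"]),
        }
    )
    down = down[down["start"] < down["end"]]
    return promoter, body, down


def annotate_peaks(peaks: PeakSet, genes, tss_window: int = 3000,
                   downstream_window: int = 3000) -> pd.DataFrame:
    """Per-peak genomic category with the priority rule above.

    Returns the peak frame with an added ``category`` column.
    """
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    if len(genes_df) == 0:
        raise ValueError("gene annotation is empty")
    out = peaks.df.copy()
    if len(out) == 0:
        out["category"] = pd.Series(dtype=object)
        return out
    promoter, body, down = _window_frames(genes_df, tss_window, downstream_window)
    cat = np.full(len(out), "distal_intergenic", dtype=object)
    is_down = overlaps_any(out, down)
    cat[is_down] = "downstream"
    is_body = overlaps_any(out, body)
    cat[is_body] = "intragenic"
    is_prom = overlaps_any(out, promoter)
    cat[is_prom] = "promoter"
    out["category"] = cat
    return out


def category_fractions(annotated: pd.DataFrame) -> pd.Series:
    counts = annotated["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    return counts / max(counts.sum(), 1)


def compare_category_distributions(annotated_by_stage: dict[str, pd.DataFrame]):
    """Chi-square test of category x stage counts."""
    table = pd.DataFrame(
        {
            stage: df["category"].value_counts().reindex(CATEGORIES, fill_value=0)
            for stage, df in annotated_by_stage.items()
        }
    )
    table = table.loc[table.sum(axis=1) > 0]
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
    return {"chi2": chi2, "p": p, "dof": dof, "table": table}


def chromosome_peak_density(peaks: PeakSet, assembly: GenomeAssembly) -> pd.Series:
    """Peaks per Mb per chromosome (all assembly chromosomes reported)."""
    peaks.validate(assembly)
    counts = peaks.df["chrom"].value_counts()
    dens = {}
    for chrom, length in assembly.items():
        dens[chrom] = counts.get(chrom, 0) / (length / 1e6)
    return pd.Series(dens, name=f"{peaks.label}_per_mb")


def ratio_between_stages(density_a: pd.Series, density_b: pd.Series) -> pd.Series:
    """Per-chromosome fold change density_b / density_a.

    inf where a==0 and b>0; missing (NaN) where both are 0.
    """
    a = density_a.astype(float)
    b = density_b.reindex(a.index).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b / a
    ratio[(a == 0) & (b == 0)] = np.nan
    ratio[(a == 0) & (b > 0)] = np.inf
    return ratio


def _pattern_class(presence: tuple, stages: list[str]) -> str:
    on = [s for s, p in zip(stages, presence) if p]
    if len(on) == len(stages):
        return "common"
    if len(on) == 1:
        return f"{on[0]}-spe"
    return "-".join(on)


def classify_stage_dynamics(peaksets: dict[str, PeakSet], min_overlap: int = 1,
                            min_group: int = 100) -> pd.DataFrame:
    """Cross-stage presence classes on the union-merged peak regions.

    All stage peaks are merged (>=1 bp overlap) into maximal regions; a region
    is present at a stage iff it overlaps any peak of that stage by at least
    ``min_overlap`` bp. Class labels follow the presence pattern: all stages
    -> "common", single stage -> "<stage>-spe", otherwise the joined stage
    names. Classes with <= ``min_group`` regions are flagged ``minor``.
    """
    stages = list(peaksets)
    if len(stages) != len(set(stages)):
        raise ValueError("stage labels must be unique")
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    union = pd.concat([ps.df[["chrom", "start", "end"]] for ps in peaksets.values()],
                      ignore_index=True)
    merged = merge_intervals(union)
    for stage in stages:
        merged[stage] = overlaps_any(merged, peaksets[stage].df, min_overlap).astype(int)
    merged["class"] = [
        _pattern_class(tuple(row), stages)
        for row in merged[stages].itertuples(index=False)
    ]
    sizes = merged["class"].value_counts()
    merged["minor"] = merged["class"].map(sizes) <= min_group
    return merged


def dynamics_class_counts(dynamics: pd.DataFrame, drop_minor: bool = True) -> pd.Series:
    d = dynamics if not drop_minor else dynamics[~dynamics["minor"]]
    return d["class"].value_counts()


def _meta_positions(flank: int, flank_bin: int, n_body_bins: int):
    """Offsets for the profile x-axis: upstream flank, scaled body, downstream flank."""
    up = np.arange(-flank, 0, flank_bin) + flank_bin / 2
    body = np.linspace(0, 1, n_body_bins, endpoint=False) + 0.5 / n_body_bins
    down = np.arange(0, flank, flank_bin) + flank_bin / 2
    return up, body, down


def tss_profile(signal: dict[str, np.ndarray], signal_bin: int, genes, expression: pd.Series,
                n_groups: int = 10, flank: int = 1500, flank_bin: int = 50,
                n_body_bins: int = 100) -> pd.DataFrame:
    """Metagene signal profile by expression percentile group.

    ``signal`` maps chromosome -> per-bin values at ``signal_bin`` bp
    resolution. Genes are split into ``n_groups`` expression percentile groups
    (group 1 = lowest). Minus-strand genes are flipped so positions run 5'->3'.
    Flanks are sampled at ``flank_bin`` native resolution; the gene body is
    rescaled to ``n_body_bins`` meta-bins. Genes shorter than two signal bins
    are excluded (count reported via the ``.attrs['n_excluded']`` field).

    Returns a DataFrame: one row per group, columns = meta-bin positions
    (negative bp = upstream flank, [0, 1) = scaled body, bp >= body end as
    1 + bp offsets downstream).
    """
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    genes_df = genes_df[genes_df["gene_id"].isin(expression.index)].reset_index(drop=True)
    expr = expression.loc[genes_df["gene_id"]].to_numpy()
    ranks = pd.Series(expr).rank(method="first")
    groups = np.ceil(ranks / len(ranks) * n_groups).astype(int).clip(1, n_groups)

    n_up = flank // flank_bin
    n_down = flank // flank_bin
    n_cols = n_up + n_body_bins + n_down
    sums = np.zeros((n_groups, n_cols))
    counts = np.zeros(n_groups)
    n_excluded = 0

    def sample(chrom, positions):
        vals = signal[chrom]
        idx = np.clip((positions // signal_bin).astype(int), 0, len(vals) - 1)
        return vals[idx]

    for row, grp in zip(genes_df.itertuples(), groups):
        if row.chrom not in signal:
            n_excluded += 1
            continue
        if row.end - row.start < 2 * signal_bin:
            n_excluded += 1
            continue
        if row.strand == "+":
            up_pos = row.start + np.arange(-flank, 0, flank_bin) + flank_bin // 2
            body_pos = np.linspace(row.start, row.end, n_body_bins, endpoint=False) + (
                (row.end - row.start) / n_body_bins / 2
            )
            down_pos = row.end + np.arange(0, flank, flank_bin) + flank_bin // 2
            prof = np.concatenate([
                sample(row.chrom, up_pos),
                sample(row.chrom, body_pos.astype(int)),
                sample(row.chrom, down_pos),
            ])
        else:
            up_pos = row.end + np.arange(flank, 0, -flank_bin) - flank_bin // 2
            body_pos = np.linspace(row.end, row.start, n_body_bins, endpoint=False) - (
                (row.end - row.start) / n_body_bins / 2
            )
            down_pos = row.start - np.arange(0, flank, flank_bin) - flank_bin // 2
            prof = np.concatenate([
                sample(row.chrom, np.clip(up_pos, 0, None)),
                sample(row.chrom, np.clip(body_pos.astype(int), 0, None)),
                sample(row.chrom, np.clip(down_pos, 0, None)),
            ])
        sums[grp - 1] += prof
        counts[grp - 1] += 1

    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    up, body, down = _meta_positions(flank, flank_bin, n_body_bins)
    columns = np.concatenate([up, body, 1 + down])
    out = pd.DataFrame(means, index=[f"decile_{g}" for g in range(1, n_groups + 1)],
                       columns=columns)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["group_sizes"] = counts.astype(int).tolist()
    return out
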