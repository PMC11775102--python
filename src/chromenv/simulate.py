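"""Synthetic fixtures with known ground truth for every pipeline stage.

The default scenario mirrors the shape of a stage-resolved male-germ-cell
study at toy scale: two autosomes plus chrX and chrY, genes on both strands,
six histone marks emitted by a 13-state chromatin-state model, three
differentiation stages of peaks with planted presence patterns and a
sex-chromosome density bias, and a 3 KO vs 3 CTL negative-binomial count
matrix with ERCC control rows, a planted unwanted sample factor, and planted
up/down genes tied to promoter chromatin state. Every generator is
deterministic given (config, seed) and returns its ground truth alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, GeneModel, PeakSet, gene_table, make_gene
from .hmm import BinarizedTracks, Segmentation, StateModel

DEFAULT_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "H3K36me3", "H3K9me3")

DEFAULT_CHROMOSOMES = (("chr1", 5_000_000), ("chr2", 5_000_000),
                       ("chrX", 3_000_000), ("chrY", 1_000_000))

DEFAULT_STAGES = ("GSC", "SCI", "RS")


def simulate_genome(n_genes: int = 2000, chromosomes=DEFAULT_CHROMOSOMES,
                    seed: int = 0, mean_log_length: float = np.log(2000.0),
                    sd_log_length: float = 0.8, min_length: int = 200):
    """Non-overlapping genes on random strands with log-normal lengths.

    Gene counts are allocated to chromosomes proportionally to length.
    Raises when the demanded genes cannot fit.
    """
    for name, length in chromosomes:
        if length < 50_000:
            raise ValueError(f"chromosome {name} shorter than 50 kb")
    assembly = GenomeAssembly(list(chromosomes))
    rng = np.random.default_rng(seed)
    total = sum(l for _, l in chromosomes)
    genes: list[GeneModel] = []
    gid = 0
    for name, length in chromosomes:
        n_here = int(round(n_genes * length / total))
        if name == chromosomes[-1][0]:
            n_here = n_genes - gid
        lengths = np.maximum(
            rng.lognormal(mean_log_length, sd_log_length, size=n_here).astype(int),
            min_length,
        )
        if lengths.sum() > 0.8 * length:
            raise ValueError(f"gene demand exceeds capacity of {name}")
        # place by spacing the leftover bp uniformly between genes
        slack = length - lengths.sum()
        gaps = rng.multinomial(slack, np.ones(n_here + 1) / (n_here + 1)) if n_here else []
        pos = 0
        for i in range(n_here):
            pos += gaps[i]
            start = pos
            end = start + int(lengths[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = rng.choice(
                ["protein_coding", "lncRNA", "pseudogene", "snoRNA"],
                p=[0.8, 0.12, 0.06, 0.02],
            )
            genes.append(make_gene(f"gene{gid:05d}", name, start, end, strand, str(biotype)))
            gid += 1
    return assembly, genes


def default_state_model(marks=DEFAULT_MARKS, self_transition: float = 0.95,
                        states=None) -> StateModel:
    """A 13-state product-Bernoulli model with field-typical emission patterns."""
    # emission rows: P(mark present | state) for
    # H3K4me1, H3K4me3, H3K27ac, H3K27me3, H3K36me3, H3K9me3
    patterns = {
        "TSSA":     (0.20, 0.95, 0.80, 0.02, 0.05, 0.02),
        "TSSFlnk":  (0.70, 0.80, 0.50, 0.05, 0.05, 0.02),
        "Tx":       (0.05, 0.05, 0.10, 0.02, 0.90, 0.02),
        "TxWk":     (0.05, 0.02, 0.05, 0.02, 0.40, 0.02),
        "EnhG":     (0.85, 0.05, 0.70, 0.15, 0.75, 0.02),
        "EnhA":     (0.90, 0.10, 0.90, 0.02, 0.05, 0.02),
        "EnhW":     (0.80, 0.05, 0.15, 0.05, 0.05, 0.02),
        "ZNF/Rpts": (0.05, 0.05, 0.05, 0.05, 0.40, 0.70),
        "Het":      (0.02, 0.02, 0.02, 0.05, 0.02, 0.90),
        "TssBiv":   (0.40, 0.85, 0.20, 0.85, 0.02, 0.02),
        "EnhBiv":   (0.85, 0.10, 0.30, 0.85, 0.02, 0.02),
        "ReprPC":   (0.05, 0.05, 0.02, 0.90, 0.02, 0.05),
        "Quies":    (0.02, 0.02, 0.02, 0.02, 0.02, 0.02),
    }
    if states is None:
        states = list(patterns)
    emission = np.array([patterns[s] for s in states])
    n = len(states)
    trans = np.full((n, n), (1 - self_transition) / (n - 1))
    np.fill_diagonal(trans, self_transition)
    model = StateModel(emission, trans, np.full(n, 1 / n), list(marks))
    model.state_labels = list(states)
    return model


def simulate_state_tracks(model: StateModel, assembly: GenomeAssembly, seed: int = 0,
                          bin_size: int = 200, state_labels=None):
    """Sample a state path per chromosome and emit marks; returns tracks + truth."""
    labels = state_labels or getattr(model, "state_labels", None) or [
        f"E{i + 1}" for i in range(model.n_states)
    ]
    rng = np.random.default_rng(seed)
    data = {}
    true_labels = {}
    for chrom, length in assembly.items():
        n_bins = -(-length // bin_size)
        path = np.empty(n_bins, dtype=np.int64)
        path[0] = rng.choice(model.n_states, p=model.initial)
        cum = model.transition.cumsum(axis=1)
        u = rng.random(n_bins)
        for t in range(1, n_bins):
            path[t] = np.searchsorted(cum[path[t - 1]], u[t])
        marks = (rng.random((n_bins, len(model.marks))) < model.emission[path]).astype(np.uint8)
        data[chrom] = marks
        true_labels[chrom] = np.array([labels[s] for s in path], dtype=object)
    tracks = BinarizedTracks(bin_size, model.marks, data,
                             chrom_lengths=dict(assembly.items()))
    truth = Segmentation.from_label_vector(true_labels, bin_size,
                                           chrom_lengths=dict(assembly.items()),
                                           vocabulary=labels)
    return tracks, truth


def simulate_peaks(assembly: GenomeAssembly, stages=DEFAULT_STAGES,
                   rate_per_mb: float = 30.0,
                   chrom_rate_scale: dict | None = None,
                   stage_chrom_scale: dict | None = None,
                   pattern_probs: dict | None = None,
                   mean_length: int = 800, min_gap: int = 100,
                   seed: int = 0):
    """Stage-resolved peak sets with planted presence patterns.

    Base regions follow a Poisson count (rate ``rate_per_mb`` per Mb, scaled
    per chromosome by ``chrom_rate_scale``); lengths geometric around
    ``mean_length``. Each base region draws a presence pattern over stages
    from ``pattern_probs`` (pattern = tuple of 0/1 per stage).
    ``stage_chrom_scale`` plants a stage-specific density bias, e.g.
    ``{"RS": {"chrX": 10.0}}`` makes the total RS-stage rate on chrX 10x the
    RS rate elsewhere, by adding that many extra RS-only regions. All planted
    regions are non-overlapping and separated by >= ``min_gap`` bp, so the
    dynamics classifier can be checked against the planted patterns exactly.
    Returns ({stage: PeakSet}, truth DataFrame).
    """
    stages = list(stages)
    if pattern_probs is None:
        pattern_probs = {
            (1, 1, 1): 0.35,        # common
            (1, 0, 0): 0.10, (0, 1, 0): 0.10, (0, 0, 1): 0.20,
            (1, 1, 0): 0.10, (0, 1, 1): 0.10, (1, 0, 1): 0.05,
        }
    patterns = list(pattern_probs)
    probs = np.array([pattern_probs[p] for p in patterns], dtype=float)
    probs = probs / probs.sum()
    if any(len(p) != len(stages) for p in patterns):
        raise ValueError("pattern length must match number of stages")
    if (probs < 0).any() or rate_per_mb <= 0:
        raise ValueError("rates and pattern probabilities must be positive")
    stage_presence = {
        stage: float(sum(pr for pat, pr in zip(patterns, probs) if pat[i]))
        for i, stage in enumerate(stages)
    }
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in assembly.items():
        scale = (chrom_rate_scale or {}).get(chrom, 1.0)
        n_base = rng.poisson(rate_per_mb * scale * length / 1e6)
        region_patterns = [patterns[j] for j in rng.choice(len(patterns), size=n_base, p=probs)]
        # stage-specific extra regions raise one stage's rate on one chromosome
        for i, stage in enumerate(stages):
            extra_scale = (stage_chrom_scale or {}).get(stage, {}).get(chrom, 1.0)
            if extra_scale > 1.0:
                extra_rate = rate_per_mb * scale * stage_presence[stage] * (extra_scale - 1.0)
                n_extra = rng.poisson(extra_rate * length / 1e6)
                only = tuple(int(k == i) for k in range(len(stages)))
                region_patterns += [only] * n_extra
        n = len(region_patterns)
        if n == 0:
            continue
        order = rng.permutation(n)
        region_patterns = [region_patterns[j] for j in order]
        lengths = np.maximum(rng.geometric(1.0 / mean_length, size=n), 50)
        occupied = lengths.sum() + (n + 1) * min_gap
        if occupied > 0.9 * length:
            raise ValueError(f"peak demand exceeds capacity of {chrom}")
        # exact-count non-overlapping placement: spread the slack uniformly
        slack = length - occupied
        gaps = rng.multinomial(slack, np.ones(n + 1) / (n + 1))
        pos = 0
        for i in range(n):
            pos += gaps[i] + min_gap
            s, e = pos, pos + int(lengths[i])
            pos = e
            rows.append((chrom, int(s), int(e), region_patterns[i]))
    truth = pd.DataFrame(
        [(c, s, e) + tuple(p) for c, s, e, p in rows],
        columns=["chrom", "start", "end"] + list(stages),
    )
    peaksets = {}
    for stage in stages:
        sub = truth.loc[truth[stage] == 1, ["chrom", "start", "end"]]
        peaksets[stage] = PeakSet(stage, sub.reset_index(drop=True))
    return peaksets, truth


@dataclass
class CountsTruth:
    up_genes: list
    down_genes: list
    factor: np.ndarray            # planted unwanted factor per sample
    log2fc: float

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"up_genes": self.up_genes, "down_genes": self.down_genes,
                       "factor": self.factor.tolist(), "log2fc": self.log2fc}, fh, indent=1)


def simulate_counts(genes, n_per_group: int = 3, n_up: int = 100, n_down: int = 100,
                    log2fc: float = 2.0, dispersion: float = 0.1,
                    mean_expression: float = 100.0, ercc_n: int = 92,
                    factor_sd: float = 0.0, seed: int = 0,
                    up_gene_ids=None, down_gene_ids=None):
    """NB count matrix for a KO vs CTL design with ERCC control rows.

    Planted up/down genes get a genotype effect of +/- ``log2fc`` in KO; ERCC
    rows never carry a genotype effect. A planted unwanted per-sample factor
    (log-normal sd ``factor_sd``) multiplies ALL rows including ERCC, which is
    what control-gene normalization is meant to remove. Planted gene sets can
    be pinned (e.g. to promoter-state classes) via ``up_gene_ids``/``down_gene_ids``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    gene_ids = list(genes_df["gene_id"])
    rng = np.random.default_rng(seed)

    if up_gene_ids is None or down_gene_ids is None:
        if n_up + n_down > len(gene_ids):
            raise ValueError(
                f"cannot plant {n_up + n_down} DE genes among {len(gene_ids)} genes")
        chosen = rng.choice(len(gene_ids), size=n_up + n_down, replace=False)
        up_gene_ids = [gene_ids[i] for i in chosen[:n_up]]
        down_gene_ids = [gene_ids[i] for i in chosen[n_up:]]
    up_set, down_set = set(up_gene_ids), set(down_gene_ids)
    if up_set & down_set:
        raise ValueError("up and down gene sets overlap")

    samples = [f"KO_{i + 1}" for i in range(n_per_group)] + [
        f"CTL_{i + 1}" for i in range(n_per_group)
    ]
    genotype = ["KO"] * n_per_group + ["CTL"] * n_per_group
    if factor_sd > 0:
        # unwanted variation is technical, not biological: plant it orthogonal
        # to the genotype contrast (the RUV identifiability assumption) and at
        # exactly the stated magnitude
        raw = rng.normal(0.0, 1.0, size=len(samples))
        g = np.where(np.array(genotype) == "KO", 1.0, -1.0)
        raw -= raw @ g / (g @ g) * g
        raw -= raw.mean()
        factor = raw / raw.std() * factor_sd
    else:
        factor = np.zeros(len(samples))

    base = rng.lognormal(np.log(mean_expression), 1.0, size=len(gene_ids))
    effect = np.zeros(len(gene_ids))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in up_set:
        effect[idx[g]] = log2fc
    for g in down_set:
        effect[idx[g]] = -log2fc

    all_ids = gene_ids + [f"ERCC-{i + 1:05d}" for i in range(ercc_n)]
    ercc_base = rng.lognormal(np.log(mean_expression), 1.0, size=ercc_n)
    mu_gene = base[:, None] * 2.0 ** (effect[:, None] * (np.array(genotype) == "KO"))
    mu = np.vstack([mu_gene, np.tile(ercc_base[:, None], (1, len(samples)))])
    mu = mu * np.exp(factor)[None, :]
    if (mu < 0).any():
        raise ValueError("negative NB means")
    # NB via gamma-Poisson: shape r = 1/phi, mean mu
    r = 1.0 / dispersion
    lam = rng.gamma(r, mu / r)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=all_ids, columns=samples)
    meta = pd.DataFrame({"genotype": genotype, "cell_type": "RS",
                         "replicate": list(range(1, n_per_group + 1)) * 2},
                        index=pd.Index(samples, name="sample"))
    control = pd.Series([False] * len(gene_ids) + [True] * ercc_n, index=all_ids)
    truth = CountsTruth(sorted(up_set), sorted(down_set), factor, log2fc)
    from .rnaseq import CountMatrix

    return CountMatrix(counts_df, meta, control), truth
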