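"""Multi-mark chromatin-state segmentation.

A hidden Markov model with independent Bernoulli emissions per histone mark
over fixed-size bins (200 bp by default): each hidden state s emits mark m
with probability e[s, m], independently across marks given the state. This is
the emission model of the standard chromatin-state segmentation tools. The
model is learned by Baum-Welch EM with scaled forward-backward recursions and
decoded by per-bin posterior argmax (not Viterbi), then run-length encoded.

Chromosomes are independent sequences sharing one initial distribution.
Learned states are numbered ("E1".."En"); mapping numbers to mnemonic labels
(TSSA, TxWk, ...) is a user concern, supplied as a labelling map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

# 18-state mnemonic vocabulary and its pooling into 13 states: TSS-flanking,
# genic-enhancer, polycomb and quiescent sub-states are collapsed.
STATES_18 = (
    "TSSA", "TSSFlnk", "TSSFlnkD", "Tx", "TxWk", "EnhG1", "EnhG2", "EnhA",
    "EnhW", "ZNF/Rpts", "Het", "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk",
    "Quies1", "Quies2", "Quies3",
)

DEFAULT_POOLING_MAP = {
    "TSSFlnkD": "TSSFlnk",
    "EnhG1": "EnhG",
    "EnhG2": "EnhG",
    "ReprPCWk": "ReprPC",
    "Quies1": "Quies",
    "Quies2": "Quies",
    "Quies3": "Quies",
    **{s: s for s in ("TSSA", "TSSFlnk", "Tx", "TxWk", "EnhA", "EnhW",
                      "ZNF/Rpts", "Het", "TssBiv", "EnhBiv", "ReprPC")},
}

STATES_13 = (
    "TSSA", "TSSFlnk", "Tx", "TxWk", "EnhG", "EnhA", "EnhW",
    "ZNF/Rpts", "Het", "TssBiv", "EnhBiv", "ReprPC", "Quies",
)

STATE_CATEGORY = {
    "TSSA": "active", "Tx": "active", "EnhG": "active", "EnhA": "active",
    "TSSFlnk": "weak", "TxWk": "weak", "EnhW": "weak",
    "ZNF/Rpts": "heterochromatin", "Het": "heterochromatin",
    "TssBiv": "bivalent", "EnhBiv": "bivalent",
    "ReprPC": "polycomb",
    "Quies": "quiescent",
}

ENHANCER_STATES = ("EnhA", "EnhG", "EnhW", "EnhBiv")

# Tie-break order for predominant-state assignment: category priority, then
# lexicographic within category.
CATEGORY_PRIORITY = ("active", "bivalent", "polycomb", "weak", "heterochromatin", "quiescent")


def categorize_state(label: str) -> str:
    """Map a 13-state label to its category (active/weak/.../quiescent)."""
    try:
        return STATE_CATEGORY[label]
    except KeyError:
        raise ValueError(f"unknown chromatin state label {label!r}") from None


def state_priority(label: str) -> tuple:
    """Sort key: lower sorts first = wins predominance ties."""
    if label == "unannotated":
        return (len(CATEGORY_PRIORITY) + 1, label)
    try:
        cat = STATE_CATEGORY.get(label)
        rank = CATEGORY_PRIORITY.index(cat) if cat else len(CATEGORY_PRIORITY)
    except ValueError:
        rank = len(CATEGORY_PRIORITY)
    return (rank, label)


def binarize_track(bin_counts, global_rate: float, p_threshold: float = 1e-4) -> np.ndarray:
    """Poisson-background binarization: bin=1 iff P(X >= count | rate) <= threshold."""
    counts = np.asarray(bin_counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.floor(counts)):
            raise ValueError("bin counts must be integers")
        counts = counts.astype(np.int64)
    if np.any(counts < 0):
        raise ValueError("bin counts must be >= 0")
    if global_rate <= 0:
        raise ValueError("global_rate must be > 0")
    # P(X >= k) = sf(k - 1)
    tail = stats.poisson.sf(counts - 1, global_rate)
    return (tail <= p_threshold).astype(np.uint8)


class BinarizedTracks:
    """Per-chromosome bins x marks binary matrices at a fixed bin size."""

    def __init__(self, bin_size: int, marks, data: dict[str, np.ndarray],
                 chrom_lengths: dict[str, int] | None = None):
        self.bin_size = int(bin_size)
        self.marks = list(marks)
        self.data = {}
        for chrom, mat in data.items():
            mat = np.asarray(mat)
            if mat.ndim != 2 or mat.shape[1] != len(self.marks):
                raise ValueError(f"{chrom}: track matrix must be bins x {len(self.marks)} marks")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{chrom}: track values must be binary")
            if chrom_lengths is not None:
                expect = -(-chrom_lengths[chrom] // self.bin_size)
                if mat.shape[0] != expect:
                    raise ValueError(f"{chrom}: expected {expect} bins, got {mat.shape[0]}")
            self.data[chrom] = mat.astype(np.uint8)

    @property
    def n_bins(self):
        return sum(m.shape[0] for m in self.data.values())


@dataclass
class StateModel:
    """Product-Bernoulli HMM parameters."""

    emission: np.ndarray     # states x marks
    transition: np.ndarray   # states x states, rows stochastic
    initial: np.ndarray      # states
    marks: list
    log_likelihoods: list = field(default_factory=list)
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        s = self.emission.shape[0]
        if self.transition.shape != (s, s) or self.initial.shape != (s,):
            raise ValueError("inconsistent StateModel dimensions")
        for arr in (self.emission, self.transition, self.initial):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1) > 1e-8:
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self):
        return self.emission.shape[0]

    def to_file(self, path):
        with open(path, "w") as fh:
            fh.write(f"#states\t{self.n_states}\n#marks\t" + "\t".join(self.marks) + "\n")
            fh.write("#initial\t" + "\t".join(f"{v:.10g}" for v in self.initial) + "\n")
            for i in range(self.n_states):
                fh.write("emission\t" + "\t".join(f"{v:.10g}" for v in self.emission[i]) + "\n")
            for i in range(self.n_states):
                fh.write("transition\t" + "\t".join(f"{v:.10g}" for v in self.transition[i]) + "\n")

    @classmethod
    def from_file(cls, path):
        marks, initial, emis, trans = [], None, [], []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "#marks":
                    marks = fields[1:]
                elif fields[0] == "#initial":
                    initial = [float(v) for v in fields[1:]]
                elif fields[0] == "emission":
                    emis.append([float(v) for v in fields[1:]])
                elif fields[0] == "transition":
                    trans.append([float(v) for v in fields[1:]])
        return cls(np.array(emis), np.array(trans), np.array(initial), marks)


class Segmentation:
    """Run-length encoded state labels tiling each chromosome (bp coordinates)."""

    def __init__(self, runs: dict[str, list[tuple[str, int, int]]], bin_size: int | None = None,
                 vocabulary=None):
        self.bin_size = bin_size
        self.runs = {}
        labels_seen = set()
        for chrom, rr in runs.items():
            rr = sorted(rr, key=lambda r: r[1])
            prev_end = None
            for label, s, e in rr:
                if s >= e:
                    raise ValueError(f"{chrom}: empty run {label} {s}-{e}")
                if prev_end is not None and s != prev_end:
                    raise ValueError(f"{chrom}: runs do not tile (gap/overlap at {s})")
                prev_end = e
                labels_seen.add(label)
            self.runs[chrom] = [(str(l), int(s), int(e)) for l, s, e in rr]
        self.vocabulary = list(vocabulary) if vocabulary is not None else sorted(labels_seen)

    @classmethod
    def from_label_vector(cls, per_chrom_labels: dict[str, np.ndarray], bin_size: int,
                          chrom_lengths: dict[str, int] | None = None, vocabulary=None):
        runs = {}
        for chrom, labels in per_chrom_labels.items():
            labels = np.asarray(labels)
            chrom_runs = []
            boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
            starts_idx = np.concatenate([[0], boundaries])
            ends_idx = np.concatenate([boundaries, [len(labels)]])
            length = chrom_lengths[chrom] if chrom_lengths else len(labels) * bin_size
            for si, ei in zip(starts_idx, ends_idx):
                chrom_runs.append((str(labels[si]), si * bin_size, min(ei * bin_size, length)))
            runs[chrom] = chrom_runs
        return cls(runs, bin_size=bin_size, vocabulary=vocabulary)

    def _index(self, chrom):
        if not hasattr(self, "_idx"):
            self._idx = {}
        if chrom not in self._idx:
            rr = self.runs.get(chrom, [])
            self._idx[chrom] = (
                np.array([r[1] for r in rr], dtype=np.int64),
                np.array([r[2] for r in rr], dtype=np.int64),
                [r[0] for r in rr],
            )
        return self._idx[chrom]

    def query(self, chrom, start, end):
        """Runs overlapping [start, end), clipped to the window."""
        starts, ends, labels = self._index(chrom)
        if len(starts) == 0:
            return []
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [
            (labels[k], max(int(starts[k]), start), min(int(ends[k]), end))
            for k in range(lo, hi)
        ]

    def n_runs(self):
        return sum(len(r) for r in self.runs.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, s, e, label)
            for chrom in self.runs
            for label, s, e in self.runs[chrom]
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def to_bed(self, path):
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, bin_size=None):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "state"])
        runs = {
            chrom: [(r.state, r.start, r.end) for r in g.itertuples()]
            for chrom, g in df.groupby("chrom")
        }
        return cls(runs, bin_size=bin_size)

    def relabel(self, mapping: dict) -> "Segmentation":
        """Apply a label map and merge adjacent runs with equal new labels."""
        missing = {l for l in self.vocabulary if l not in mapping}
        if missing:
            raise ValueError(f"labels missing from map: {sorted(missing)}")
        runs = {}
        for chrom, rr in self.runs.items():
            merged = []
            for label, s, e in rr:
                new = mapping[label]
                if merged and merged[-1][0] == new and merged[-1][2] == s:
                    merged[-1] = (new, merged[-1][1], e)
                else:
                    merged.append((new, s, e))
            runs[chrom] = merged
        return Segmentation(runs, bin_size=self.bin_size,
                            vocabulary=sorted(set(mapping[l] for l in self.vocabulary)))


def pool_states(seg18: Segmentation, pooling_map: dict | None = None) -> Segmentation:
    """Pool the 18 raw states into the 13-state vocabulary (default map)."""
    return seg18.relabel(DEFAULT_POOLING_MAP if pooling_map is None else pooling_map)


# ---------------------------------------------------------------------------
# scaled forward-backward kernels

@njit(cache=True)
def _fb_pass(B, trans, init):
    """Scaled forward-backward. B: T x S emission likelihoods.

    Returns (gamma T x S, xi_sum S x S, first-bin posterior S, loglik).
    """
    T, S = B.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    a = init * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, S))
    beta[T - 1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (trans @ bb) / c[t + 1]
        # xi_t[i,j] ∝ alpha[t,i] trans[i,j] B[t+1,j] beta[t+1,j]
        for i in range(S):
            for j in range(S):
                xi_sum[i, j] += alpha[t, i] * trans[i, j] * bb[j] / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    loglik = np.log(c).sum()
    return gamma, xi_sum, gamma[0].copy(), loglik


def _emission_likelihoods(X, emission):
    """B[t, s] = prod_m e[s,m]^x (1-e[s,m])^(1-x), clipped away from 0/1 in logs."""
    e = np.clip(emission, 1e-10, 1 - 1e-10)
    logB = X @ np.log(e).T + (1 - X) @ np.log(1 - e).T
    # per-row shift keeps scaling in float range; absorbed by c_t normalization
    shift = logB.max(axis=1, keepdims=True)
    return np.exp(logB - shift), shift.sum()


def sequence_log_likelihood(model: StateModel, tracks: BinarizedTracks) -> float:
    """Total log-likelihood of the binarized tracks under the model."""
    total = 0.0
    for chrom in sorted(tracks.data):
        X = tracks.data[chrom].astype(np.float64)
        B, shift = _emission_likelihoods(X, model.emission)
        _, _, _, ll = _fb_pass(B, model.transition, model.initial)
        total += ll + shift
    return total


def _init_emissions(X_all, n_states, rng):
    """k-means-style mark-pattern centroids, randomly perturbed."""
    from sklearn.cluster import KMeans

    n = X_all.shape[0]
    sub = X_all[rng.choice(n, size=min(n, 20000), replace=False)]
    uniq = np.unique(sub, axis=0)
    if len(uniq) >= n_states:
        km = KMeans(n_clusters=n_states, n_init=3, random_state=int(rng.integers(2**31)))
        km.fit(sub)
        centers = km.cluster_centers_
    else:
        centers = np.tile(sub.mean(axis=0), (n_states, 1))
    centers = np.clip(centers, 0.05, 0.95)
    noise = rng.uniform(-0.04, 0.04, size=centers.shape)
    return np.clip(centers + noise, 0.01, 0.99)


def fit_state_model(tracks: BinarizedTracks, n_states: int, seed: int,
                    max_iter: int = 200, tol: float = 1e-4,
                    n_restarts: int = 5) -> StateModel:
    """Baum-Welch EM for the product-Bernoulli HMM.

    Deterministic given ``seed``; keeps the best of ``n_restarts`` random
    initializations. Stops when the relative log-likelihood improvement drops
    below ``tol`` or after ``max_iter`` iterations. The per-iteration
    log-likelihood trace (monotone non-decreasing) is stored on the model.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    chroms = sorted(tracks.data)
    Xs = [tracks.data[c].astype(np.float64) for c in chroms]
    X_all = np.concatenate(Xs, axis=0)
    n_bins, n_marks = X_all.shape
    if n_states >= 2 and n_bins < 10 * n_states:
        raise ValueError(f"need >= {10 * n_states} bins to fit {n_states} states")

    mark_freq = X_all.mean(axis=0)
    degenerate = bool((mark_freq == 0).all() or (mark_freq == 1).all())

    if n_states == 1:
        model = StateModel(mark_freq[None, :], np.ones((1, 1)), np.ones(1), tracks.marks)
        model.fit_report = {"n_bins": n_bins, "degenerate": degenerate, "restarts": 0}
        return model

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        emission = _init_emissions(X_all, n_states, rng)
        trans = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
        np.fill_diagonal(trans, 0.95)
        init = np.full(n_states, 1.0 / n_states)
        lls = []
        for it in range(max_iter):
            gamma_sum = np.zeros(n_states)
            gx_sum = np.zeros((n_states, n_marks))
            xi_tot = np.zeros((n_states, n_states))
            init_post = np.zeros(n_states)
            ll = 0.0
            for X in Xs:
                B, shift = _emission_likelihoods(X, emission)
                gamma, xi_sum, g0, l = _fb_pass(B, trans, init)
                gamma_sum += gamma.sum(axis=0)
                gx_sum += gamma.T @ X
                xi_tot += xi_sum
                init_post += g0
                ll += l + shift
            lls.append(ll)
            # M-step
            emission = gx_sum / gamma_sum[:, None]
            row = xi_tot.sum(axis=1, keepdims=True)
            trans = np.where(row > 0, xi_tot / np.where(row > 0, row, 1.0),
                             1.0 / n_states)
            init = init_post / init_post.sum()
            if it > 0 and abs(lls[-1] - lls[-2]) <= tol * abs(lls[-2]):
                break
        if best is None or lls[-1] > best[0]:
            best = (lls[-1], emission, trans, init, lls, restart)

    _, emission, trans, init, lls, which = best
    trans = trans / trans.sum(axis=1, keepdims=True)
    model = StateModel(np.clip(emission, 0, 1), trans, init / init.sum(), tracks.marks,
                       log_likelihoods=lls)
    model.fit_report = {
        "n_bins": n_bins,
        "degenerate": degenerate,
        "restarts": n_restarts,
        "best_restart": which,
        "n_iter": len(lls),
        "final_log_likelihood": lls[-1],
    }
    return model


def posterior_marginals(model: StateModel, tracks: BinarizedTracks) -> dict[str, np.ndarray]:
    """Per-bin posterior state probabilities (forward-backward) per chromosome."""
    if model.marks != tracks.marks:
        raise ValueError("model and tracks disagree on mark names/order")
    out = {}
    for chrom, mat in tracks.data.items():
        X = mat.astype(np.float64)
        B, _ = _emission_likelihoods(X, model.emission)
        gamma, _, _, _ = _fb_pass(B, model.transition, model.initial)
        out[chrom] = gamma
    return out


def decode_segmentation(model: StateModel, tracks: BinarizedTracks,
                        chrom_lengths: dict[str, int] | None = None,
                        state_labels=None) -> Segmentation:
    """Posterior-argmax decoding, run-length encoded into a Segmentation."""
    labels = list(state_labels) if state_labels is not None else [
        f"E{i + 1}" for i in range(model.n_states)
    ]
    if len(labels) != model.n_states:
        raise ValueError("state_labels length must equal n_states")
    per_chrom = {}
    for chrom, gamma in posterior_marginals(model, tracks).items():
        idx = gamma.argmax(axis=1)
        per_chrom[chrom] = np.array([labels[i] for i in idx], dtype=object)
    return Segmentation.from_label_vector(per_chrom, tracks.bin_size,
                                          chrom_lengths=chrom_lengths,
                                          vocabulary=labels)
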