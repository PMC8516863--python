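"""Three-beat sequence construction and recursive two-way K-means selection.

A record is cut into sliding windows of three consecutive PQRST complexes
(window i spans R_i - 0.25*medRR to R_{i+2} + 0.5*medRR, so the P wave
before the first R and the T wave after the last R are included), each
resampled to a fixed 12 x L matrix so windows of different rhythm are
comparable as vectors.

Representative selection splits the windows into two groups with K-means
(k = 2, k-means++ initialisation, Elkan acceleration) and applies a ratio
rule: with r = |small| / |large|,

* r <= 0.35      → draw (seeded, uniform) from the SMALL group — an episodic
  abnormality contaminates only a minority of windows, so the small group is
  where a disease-specific shape hides;
* r > 0.35       → draw from the LARGE group;
* |A| == |B|     → split each group once more and draw from the smallest of
  the four subgroups (ties: lowest group index, then lowest sequence index).

The selected representative is always one of the input windows, never an
average, and the whole decision is recorded in a trace for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import EcgRecord
from .preprocess import RPeakSeries

#: Fixed per-lead length of a resampled three-beat window (~2 s at 500 Hz).
SEQUENCE_LENGTH = 1000


class InsufficientBeatsError(ValueError):
    """Fewer than three detected R-peaks: no three-beat window exists."""


@dataclass
class BeatSequence:
    """One fixed-length, resampled 12-lead window of three PQRST complexes."""

    source_record_id: str
    start_sample: int
    end_sample: int
    resampled: np.ndarray  # 12 x SEQUENCE_LENGTH
    n_beats: int = 3

    def vector(self) -> np.ndarray:
        return self.resampled.ravel()


@dataclass
class ClusteringParams:
    ratio_threshold: float = 0.35
    k: int = 2
    max_recursion: int = 2
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ratio_threshold < 1:
            raise ValueError(f"ratio_threshold {self.ratio_threshold} outside (0, 1)")
        if self.k != 2:
            raise ValueError("the selection rule is defined for k = 2 only")


@dataclass
class ClusterDecisionTrace:
    """Auditable trace of the recursive selection decisions."""

    levels: list[dict] = field(default_factory=list)
    selected_index: int = -1


def build_sequences(record: EcgRecord, peaks: RPeakSeries,
                    length: int = SEQUENCE_LENGTH,
                    stride_beats: int = 1) -> list[BeatSequence]:
    """Cut sliding three-beat windows and resample each lead to ``length``.

    ``stride_beats`` = 1 slides by one beat (n_peaks - 2 windows);
    ``stride_beats`` = 3 tiles disjoint windows.
    """
    idx = peaks.indices
    if len(idx) < 3:
        raise InsufficientBeatsError(
            f"need >= 3 R-peaks to build a three-beat window, got {len(idx)}"
        )
    med_rr = float(np.median(np.diff(idx)))
    n = record.n_samples
    out: list[BeatSequence] = []
    for i in range(0, len(idx) - 2, stride_beats):
        start = max(0, int(round(idx[i] - 0.25 * med_rr)))
        end = min(n, int(round(idx[i + 2] + 0.5 * med_rr)))
        if end - start < 2:
            continue
        seg = record.signal[:, start:end]
        pos = np.linspace(0.0, seg.shape[1] - 1.0, length)
        base = np.arange(seg.shape[1], dtype=float)
        resampled = np.empty((12, length))
        for lead in range(12):
            resampled[lead] = np.interp(pos, base, seg[lead])
        out.append(BeatSequence(record.record_id, start, end, resampled))
    return out


def sequence_from_window(record: EcgRecord, start: int, end: int,
                         length: int = SEQUENCE_LENGTH) -> BeatSequence:
    """Rebuild the resampled sequence for a known window [start, end)."""
    seg = record.signal[:, start:end]
    pos = np.linspace(0.0, seg.shape[1] - 1.0, length)
    base = np.arange(seg.shape[1], dtype=float)
    resampled = np.stack([np.interp(pos, base, seg[lead]) for lead in range(12)])
    return BeatSequence(record.record_id, start, end, resampled)


def _as_matrix(sequences) -> np.ndarray:
    rows = [np.asarray(getattr(s, "resampled", s), dtype=float).ravel()
            for s in sequences]
    return np.stack(rows)


#: Below this size the optimal 2-way partition is found by enumeration.
EXACT_PARTITION_MAX_N = 12


def _exact_two_partition(X: np.ndarray) -> tuple[list[int], list[int]]:
    """Globally optimal 2-means partition by subset enumeration.

    Works on the Gram matrix: for subset S, SSE(S) = sum_i |x_i|^2 -
    (1/|S|) sum_{i,j in S} G_ij, so each of the 2^(n-1)-1 candidate
    partitions costs O(n^2). Point 0 is pinned to group A, which halves the
    search and makes the result deterministic.
    """
    n = X.shape[0]
    G = X @ X.T
    diag = np.diag(G)
    best, best_mask = np.inf, None
    for mask in range(1, 2 ** (n - 1)):
        in_a = np.array([True] + [(mask >> i) & 1 == 1 for i in range(n - 1)])
        sse = 0.0
        for sel in (in_a, ~in_a):
            k = int(sel.sum())
            if k == 0:
                sse = np.inf
                break
            sse += diag[sel].sum() - G[np.ix_(sel, sel)].sum() / k
        if sse < best - 1e-12:
            best, best_mask = sse, in_a
    a = [i for i in range(n) if best_mask[i]]
    b = [i for i in range(n) if not best_mask[i]]
    return a, b


def kmeans_two(sequences, seed: int = 0,
               n_restarts: int = 10) -> tuple[list[int], list[int]]:
    """Partition sequences (or raw vectors) into two non-empty groups
    minimising the within-cluster sum of squares of the flattened vectors.

    Small instances (n <= 12) are solved exactly by partition enumeration,
    which honours the optimality contract outright. Larger instances use
    Euclidean K-means with k-means++ initialisation and Elkan's triangle-
    inequality acceleration (a pure speed-up: it cannot change the
    converged partition), keeping the lowest-SSE result over seeded
    restarts.
    """
    X = _as_matrix(sequences)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 sequences to split, got {n}")
    if n == 2:
        return [0], [1]
    if np.all(X == X[0]):  # degenerate: all identical, SSE 0 either way
        return [0], list(range(1, n))
    if n <= EXACT_PARTITION_MAX_N:
        return _exact_two_partition(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=2, init="k-means++", n_init=n_restarts,
                    algorithm="elkan", random_state=seed % (2 ** 31))
        labels = km.fit_predict(X)
    a = [i for i in range(n) if labels[i] == 0]
    b = [i for i in range(n) if labels[i] == 1]
    if not a or not b:  # all points coincide with one centroid
        a, b = [0], list(range(1, n))
    return a, b


def select_representative(sequences, params: ClusteringParams | None = None
                          ) -> tuple[BeatSequence, ClusterDecisionTrace]:
    """Apply the recursive ratio rule and return (sequence, decision trace)."""
    params = params or ClusteringParams()
    if len(sequences) == 0:
        raise ValueError("no sequences to select from")
    rng = np.random.default_rng(params.seed)
    trace = ClusterDecisionTrace()

    def draw(pool: list[int]) -> int:
        return int(pool[rng.integers(len(pool))])

    def level(indices: list[int], depth: int) -> int:
        if len(indices) == 1:
            trace.levels.append({"sizes": [1], "ratio": None,
                                 "branch": "single", "pool": list(indices)})
            return indices[0]
        sub = [sequences[i] for i in indices]
        a, b = kmeans_two(sub, seed=int(rng.integers(2 ** 31)),
                          n_restarts=params.n_restarts)
        ga = [indices[i] for i in a]
        gb = [indices[i] for i in b]
        small, large = (ga, gb) if len(ga) < len(gb) else (gb, ga)
        entry = {"sizes": [len(ga), len(gb)], "depth": depth}
        if len(ga) == len(gb) and depth < params.max_recursion:
            subgroups: list[list[int]] = []
            for g in (ga, gb):
                if len(g) >= 2:
                    sa, sb = kmeans_two([sequences[i] for i in g],
                                        seed=int(rng.integers(2 ** 31)),
                                        n_restarts=params.n_restarts)
                    subgroups.append(sorted(g[i] for i in sa))
                    subgroups.append(sorted(g[i] for i in sb))
                else:
                    subgroups.append(list(g))
            # smallest subgroup; ties -> lowest group index, then the
            # uniform draw breaks within-group ties by construction
            best = min(range(len(subgroups)),
                       key=lambda j: (len(subgroups[j]), j))
            entry.update({"ratio": 1.0, "branch": f"tie->subgroup{best}",
                          "subgroup_sizes": [len(g) for g in subgroups],
                          "pool": subgroups[best]})
            trace.levels.append(entry)
            return draw(sorted(subgroups[best]))
        ratio = len(small) / len(large)
        if ratio <= params.ratio_threshold:
            entry.update({"ratio": ratio, "branch": "small", "pool": sorted(small)})
            trace.levels.append(entry)
            return draw(sorted(small))
        entry.update({"ratio": ratio, "branch": "large", "pool": sorted(large)})
        trace.levels.append(entry)
        return draw(sorted(large))

    sel = level(list(range(len(sequences))), depth=1)
    trace.selected_index = sel
    return sequences[sel], trace
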