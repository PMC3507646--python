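"""Assembly-collection summaries, depth histogram and accumulation curve.

Unigene collections are described by per-class statistics (contigs = read
clusters of depth >= 2, singletons = depth 1), a doubling-bin depth
histogram (1; 2; 3-4; 5-8; ...) and a rarefaction/accumulation curve: the
expected number of non-redundant clusters recovered as a function of the
number of sequences sampled.  The clusterer used for rarefaction is
pluggable — the default greedy single-linkage identity clusterer is an
explicit stand-in for assembly software, so results are reproducible
without an external assembler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import SequenceRecord


@dataclass
class ClassStats:
    count: int
    total_bases: int
    mean_length: float
    median_length: float


@dataclass
class AssemblyStats:
    contigs: ClassStats
    singletons: ClassStats
    all: ClassStats


def assembly_stats(cluster_sizes, lengths) -> AssemblyStats:
    """Per-class count / total bases / mean / median for a unigene set.

    One depth per unigene (cluster) and one consensus length per unigene,
    in the same order.  Means are kept at full precision; one-decimal
    rounding is a display convention only.
    """
    sizes = np.asarray(cluster_sizes, dtype=int)
    lens = np.asarray(lengths, dtype=int)
    if sizes.size == 0 or sizes.size != lens.size:
        raise ValueError("need one length per cluster, both non-empty")

    def _cls(mask) -> ClassStats:
        sub = lens[mask]
        if sub.size == 0:
            return ClassStats(0, 0, float("nan"), float("nan"))
        return ClassStats(int(sub.size), int(sub.sum()),
                          float(sub.mean()), float(np.median(sub)))

    return AssemblyStats(
        contigs=_cls(sizes >= 2),
        singletons=_cls(sizes == 1),
        all=_cls(np.ones_like(sizes, dtype=bool)),
    )


def depth_bin_index(size: int) -> int:
    """Doubling-bin index: bin 0 = {1}; bin k covers (2^(k-1), 2^k]."""
    if size < 1:
        raise ValueError("cluster sizes must be >= 1")
    if size == 1:
        return 0
    return int(math.ceil(math.log2(size)))


def depth_bin_label(k: int) -> str:
    if k == 0:
        return "1"
    lo, hi = 2 ** (k - 1) + 1, 2 ** k
    return str(hi) if lo == hi else f"{lo}-{hi}"


def depth_histogram(cluster_sizes) -> pd.DataFrame:
    """Histogram of cluster depths over doubling bins.

    Percentages are over the total cluster count; the cumulative column is
    non-decreasing and ends at 100.
    """
    sizes = [int(s) for s in cluster_sizes]
    if not sizes:
        raise ValueError("empty input")
    idx = [depth_bin_index(s) for s in sizes]
    k_max = max(idx)
    counts = np.bincount(idx, minlength=k_max + 1)
    pct = 100 * counts / counts.sum()
    return pd.DataFrame({
        "depth_bin": [depth_bin_label(k) for k in range(k_max + 1)],
        "count": counts,
        "percent": pct,
        "cumulative_percent": np.cumsum(pct),
    })


def annotation_coverage(annotated_count: int, total_count: int) -> float:
    """Percentage of a collection with an annotation (full precision)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= annotated_count <= total_count:
        raise ValueError("annotated_count must lie in [0, total_count]")
    return 100 * annotated_count / total_count


# ------------------------------------------------------------ clusterers

def make_label_clusterer(est_to_cluster: dict[str, str]):
    """Clusterer that counts distinct planted cluster labels (truth-keyed)."""

    def clusterer(records: list[SequenceRecord]) -> int:
        return len({est_to_cluster[r.id] for r in records})

    return clusterer


def greedy_identity_clusterer(min_identity: float = 0.95,
                              min_overlap: float = 0.80):
    """Greedy single-linkage clustering on sequence identity.

    A sequence joins the first existing cluster whose representative it
    matches at >= min_identity over >= min_overlap of the longer sequence
    (edit-distance based, via edlib); otherwise it founds a new cluster.
    A deliberately simple stand-in for EST assembly software.
    """
    import edlib

    def clusterer(records: list[SequenceRecord]) -> int:
        reps: list[str] = []
        for rec in records:
            placed = False
            for rep in reps:
                short, long_ = sorted((rec.seq, rep), key=len)
                if len(short) < min_overlap * len(long_):
                    continue
                res = edlib.align(short, long_, mode="HW", task="distance")
                if res["editDistance"] <= (1 - min_identity) * len(short):
                    placed = True
                    break
            if not placed:
                reps.append(rec.seq)
        return len(reps)

    return clusterer


# ----------------------------------------------------- accumulation curve

def accumulation_curve(sequences: list[SequenceRecord],
                       sizes_grid: list[int],
                       replicates: int,
                       clusterer,
                       seed: int) -> pd.DataFrame:
    """Rarefaction by repeated subsampling without replacement.

    For every grid size and replicate, a random subset is drawn and the
    pluggable clusterer reports its non-redundant cluster count.  Replicate
    sub-streams derive from the single seed, so the whole curve is
    reproducible.  Returns long-form rows (size, replicate, count).
    """
    n = len(sequences)
    for k in sizes_grid:
        if not 1 <= k <= n:
            raise ValueError(f"grid size {k} outside 1..{n}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        rep_rng = np.random.default_rng(rng.integers(2 ** 31))
        for k in sizes_grid:
            take = rep_rng.choice(n, size=k, replace=False)
            subset = [sequences[t] for t in take]
            rows.append({"size": k, "replicate": rep,
                         "count": int(clusterer(subset))})
    return pd.DataFrame(rows)


def default_sizes_grid(n: int, steps: int = 20) -> list[int]:
    grid = sorted({max(1, round(n * (s + 1) / steps)) for s in range(steps)})
    return grid


def expected_unique_clusters(cluster_sizes, k: int) -> float:
    """Closed-form expectation of the accumulation curve at sample size k.

    Sampling k of N sequences without replacement, a cluster of size s is
    represented unless all k draws avoid it: E = sum_c (1 - C(N-s, k)/C(N, k)).
    """
    sizes = np.asarray(list(cluster_sizes), dtype=int)
    n = int(sizes.sum())
    if not 0 <= k <= n:
        raise ValueError("sample size outside collection")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for s in sizes:
        if n - s < k:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_comb(n - s, k) - log_comb(n, k))
    return total
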