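"""Query construction and database search.

A query is a statistically thresholded gene -> (fold, p) signature.  It
is compared with every database record by Pearson correlation over the
genes present on both sides, and records are ranked by the Fisher-z
score

    s = sqrt(N - 3) * (1/2) * ln((1 + r) / (1 - r))

which measures, in standard deviations of the null, how far the
correlation over ``N`` shared genes sits from zero.  Both tails are
reported: strong anti-correlations are as informative as correlations.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from efdb.ef import (
    EFProfile,
    ExpressionSeries,
    compute_ef_profiles,
    compute_pooled_fold_profile,
)
from efdb.errors import EfdbError, SeriesError
from efdb.store import stream_samples

logger = logging.getLogger(__name__)

#: Mathematically N >= 4 is required by the score; the practical floor
#: avoids meaningless correlations over a handful of genes.
DEFAULT_MIN_SHARED_GENES = 5

#: |r| clamp so self-matches score finite and top-ranked.
_R_CLAMP = 1.0 - 1e-15


@dataclass
class QueryProfile:
    """Thresholded gene -> (fold, p) signature used to search a database."""

    name: str
    entries: dict[str, tuple[float, float]]

    def folds(self) -> dict[str, float]:
        return {gene: fold for gene, (fold, _) in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SearchHit:
    sample_id: str
    series_id: str
    r: float
    N: int
    score: float


def build_query_from_replicates(
    treat: Sequence[str],
    ctrl: Sequence[str],
    series: ExpressionSeries,
    alpha: float = 0.05,
    max_genes: int = 500,
    name: Optional[str] = None,
) -> QueryProfile:
    """Build a query signature from replicated treatment/control samples.

    Genes passing the two-sample t-test at ``p < alpha`` are ranked by
    absolute pooled fold, descending, and truncated to ``max_genes``.
    """
    if len(treat) < 2 or len(ctrl) < 2:
        raise SeriesError("need >= 2 samples per group to assign significance")
    if not 0 < alpha <= 1:
        raise EfdbError(f"alpha must be in (0, 1], got {alpha}")
    if max_genes < 1:
        raise EfdbError(f"max_genes must be positive, got {max_genes}")
    pooled = compute_pooled_fold_profile(treat, ctrl, series)
    passing = [
        (gene, pooled.folds[gene], p)
        for gene, p in pooled.p_values.items()
        if p < alpha
    ]
    if not passing:
        logger.warning("no gene passed p < %g; query is empty", alpha)
    passing.sort(key=lambda item: (-abs(item[1]), item[0]))
    entries = {gene: (fold, p) for gene, fold, p in passing[:max_genes]}
    return QueryProfile(name=name or series.series_id, entries=entries)


def correlate(
    query: QueryProfile,
    target: Mapping[str, float],
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> Optional[tuple[float, int]]:
    """Pearson correlation over genes present in both query and target.

    Target genes zeroed by the cutoff are simply absent and therefore
    excluded.  Returns ``(r, N)`` with N the shared-gene count, or
    ``None`` when N is below ``min_shared_genes`` or either side has
    zero variance over the shared genes.
    """
    shared = [gene for gene in query.entries if gene in target]
    n = len(shared)
    if n < max(min_shared_genes, 2):
        return None
    x = np.array([query.entries[g][0] for g in shared])
    y = np.array([target[g] for g in shared])
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        logger.debug("zero variance over %d shared genes; null result", n)
        return None
    r = float(sx @ sy) / denom
    return max(-1.0, min(1.0, r)), n


def fisher_score(r: float, N: int) -> float:
    """Fisher-z ranking score ``sqrt(N - 3) * atanh(r)``.

    ``|r| = 1`` is clamped just inside the open interval so exact
    self-matches stay finite (and maximal).  Requires ``N >= 4``.
    """
    if N < 4:
        raise EfdbError(f"fisher_score needs N >= 4, got {N}")
    if abs(r) > 1:
        raise EfdbError(f"|r| must be <= 1, got {r}")
    r = max(-_R_CLAMP, min(_R_CLAMP, r))
    return math.sqrt(N - 3) * math.atanh(r)


def search_database(
    query: QueryProfile,
    db_path,
    top: int = 100,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
    rank_by: str = "abs",
) -> tuple[list[SearchHit], list[SearchHit]]:
    """Stream every database record and return the two ranked tails.

    Returns ``(positive, negative)``: the ``top`` highest-score hits and
    the ``top`` lowest-score (anti-correlating) hits, each sorted by
    ``|s|`` descending (``rank_by='signed'`` sorts the tails by signed
    score instead).  Deterministic given the file: ties broken by record
    order.
    """
    if rank_by not in ("abs", "signed"):
        raise EfdbError(f"unknown rank_by {rank_by!r}")
    floor = max(min_shared_genes, 4)
    pos_heap: list[tuple[float, int, SearchHit]] = []
    neg_heap: list[tuple[float, int, SearchHit]] = []
    for order, (sample_id, series_id, folds) in enumerate(stream_samples(db_path)):
        result = correlate(query, folds, min_shared_genes=floor)
        if result is None:
            continue
        r, n = result
        hit = SearchHit(sample_id=sample_id, series_id=series_id, r=r, N=n,
                        score=fisher_score(r, n))
        # min-heaps keep the top `top` by score (resp. by -score);
        # -order breaks ties in favour of earlier records.
        if len(pos_heap) < top:
            heapq.heappush(pos_heap, (hit.score, -order, hit))
        elif (hit.score, -order) > pos_heap[0][:2]:
            heapq.heapreplace(pos_heap, (hit.score, -order, hit))
        if len(neg_heap) < top:
            heapq.heappush(neg_heap, (-hit.score, -order, hit))
        elif (-hit.score, -order) > neg_heap[0][:2]:
            heapq.heapreplace(neg_heap, (-hit.score, -order, hit))
    if rank_by == "abs":
        # |s| primary; sign favours the tail's own direction on ties
        pos_key = lambda h: (-abs(h.score), -h.score)
        neg_key = lambda h: (-abs(h.score), h.score)
    else:
        pos_key = lambda h: -h.score
        neg_key = lambda h: h.score
    positive = sorted((h for _, _, h in pos_heap), key=pos_key)
    negative = sorted((h for _, _, h in neg_heap), key=neg_key)
    return positive, negative


def score_series_groups(
    query: QueryProfile,
    series: ExpressionSeries,
    groups: Mapping[str, str],
    treat_label: str = "treat",
    ctrl_label: str = "ctrl",
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> dict:
    """Score a labelled series against a query.

    ``groups`` maps sample id -> label.  The pooled treatment-vs-control
    fold profile is correlated with the query, and each labelled
    sample's EF profile is correlated individually.
    """
    treat = sorted(s for s, g in groups.items() if g == treat_label)
    ctrl = sorted(s for s, g in groups.items() if g == ctrl_label)
    if not treat or not ctrl:
        raise SeriesError(
            f"labels {treat_label!r}/{ctrl_label!r} must each cover >= 1 sample"
        )
    pooled = compute_pooled_fold_profile(treat, ctrl, series)
    pooled_result = correlate(query, pooled.folds, min_shared_genes)
    per_sample: dict[str, Optional[tuple[float, int]]] = {}
    for profile in compute_ef_profiles(series):
        if profile.sample_id in groups:
            per_sample[profile.sample_id] = correlate(
                query, profile.folds, min_shared_genes
            )
    return {
        "pooled": pooled_result,
        "per_sample": per_sample,
        "treat": treat,
        "ctrl": ctrl,
    }


def read_query_tsv(
    path, alpha: float = 1.0, max_genes: Optional[int] = None,
    name: Optional[str] = None,
) -> QueryProfile:
    """Read a ``gene<TAB>fold<TAB>p`` TSV, optionally re-thresholding.

    Entries with ``p >= alpha`` are dropped; the remainder is ranked by
    ``|fold|`` descending and truncated to ``max_genes`` if given.
    """
    rows: list[tuple[str, float, float]] = []
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene", "fold", "p"]:
            raise EfdbError(
                f"{path}: expected header gene<TAB>fold<TAB>p, got {header[:3]}"
            )
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise EfdbError(f"{path}:{lineno}: expected 3 fields")
            try:
                rows.append((parts[0], float(parts[1]), float(parts[2])))
            except ValueError:
                raise EfdbError(f"{path}:{lineno}: bad numeric value") from None
    rows = [row for row in rows if row[2] < alpha]
    rows.sort(key=lambda row: (-abs(row[1]), row[0]))
    if max_genes is not None:
        rows = rows[:max_genes]
    import os

    return QueryProfile(
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
        entries={gene: (fold, p) for gene, fold, p in rows},
    )


def write_query_tsv(query: QueryProfile, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("gene\tfold\tp\n")
        for gene, (fold, p) in sorted(
            query.entries.items(), key=lambda kv: (-abs(kv[1][0]), kv[0])
        ):
            handle.write(f"{gene}\t{fold:.6g}\t{p:.6g}\n")


def write_hits_tsv(hits: Sequence[SearchHit], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("sample_id\tseries_id\tr\tN\tscore\n")
        for hit in hits:
            handle.write(
                f"{hit.sample_id}\t{hit.series_id}\t{hit.r:.6f}\t{hit.N}"
                f"\t{hit.score:.6f}\n"
            )
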