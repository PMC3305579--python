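"""Phenotype enrichment along a correlation-ranked sample list.

Samples carry a binary phenotype label (+1/-1) and are ordered by their
correlation score with a query.  Enrichment of a phenotype towards
either end of the ranking is quantified three ways: the cumulative
enrichment curve, a one-sided Fisher exact (hypergeometric tail) test on
the top-k counts, and a permutation Kolmogorov-Smirnov test on the
maximum deviation of the enrichment curve from the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

from efdb.errors import EfdbError


@dataclass
class RankedLabels:
    """Samples sorted by score descending, each labelled +1 or -1."""

    sample_ids: list[str]
    scores: list[float]
    labels: list[int]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.scores) == len(self.labels) == n):
            raise EfdbError("sample_ids, scores and labels must align")
        if n == 0:
            raise EfdbError("empty label list")
        if any(l not in (1, -1) for l in self.labels):
            raise EfdbError("labels must be +1 or -1")
        order = sorted(range(n), key=lambda i: -self.scores[i])
        self.sample_ids = [self.sample_ids[i] for i in order]
        self.scores = [self.scores[i] for i in order]
        self.labels = [self.labels[i] for i in order]

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "RankedLabels":
        # already-ordered labels; synthetic scores preserve the order
        n = len(labels)
        return cls(
            sample_ids=[f"s{i}" for i in range(n)],
            scores=[float(n - i) for i in range(n)],
            labels=list(labels),
        )


@dataclass
class EnrichmentResult:
    curve_pos: list[float]
    curve_neg: list[float]
    fisher_p: Optional[float]
    ks_stat: float
    ks_p: float
    n_perm: int
    seed: int


def _curve(flags: np.ndarray) -> np.ndarray:
    total = int(flags.sum())
    if total == 0:
        raise EfdbError("curve requested for a label absent from the input")
    return np.cumsum(flags) / total


def enrichment_curve(labels: RankedLabels) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of each phenotype among the top-k samples.

    ``curve_pos[k-1]`` is the share of all +1 samples found in the top k
    of the ranking, for k = 1..N; likewise ``curve_neg``.  Both curves
    are non-decreasing and end at exactly 1.
    """
    arr = np.asarray(labels.labels)
    return _curve(arr == 1), _curve(arr == -1)


def hypergeometric_tail(
    population: int, successes: int, drawn: int, observed: int,
    strict: bool = False,
) -> float:
    """Upper tail P(X >= observed) of the hypergeometric distribution.

    Evaluated as an exact rational sum (integer binomials) converted to
    float at the end, so the tiny tail probabilities the enrichment
    tests produce carry no floating-point accumulation error.

    ``strict=True`` returns P(X > observed) instead, the convention some
    published enrichment analyses used (equivalent to starting the sum
    one term late); kept so their printed significance levels can be
    reproduced exactly.
    """
    if not (0 <= successes <= population and 0 <= drawn <= population):
        raise EfdbError(
            f"inconsistent counts: population={population}, "
            f"successes={successes}, drawn={drawn}"
        )
    upper = min(successes, drawn)
    if not 0 <= observed <= upper:
        raise EfdbError(
            f"observed={observed} outside [0, min(successes, drawn)={upper}]"
        )
    start = observed + 1 if strict else observed
    numerator = sum(
        comb(successes, x) * comb(population - successes, drawn - x)
        for x in range(start, upper + 1)
    )
    return float(Fraction(numerator, comb(population, drawn)))


def fisher_enrichment_test(labels: RankedLabels, k: int) -> float:
    """One-sided Fisher exact test of +1 enrichment in the top k."""
    n = len(labels)
    if not 1 <= k <= n:
        raise EfdbError(f"k must be in [1, {n}], got {k}")
    arr = np.asarray(labels.labels)
    total_pos = int((arr == 1).sum())
    observed = int((arr[:k] == 1).sum())
    return hypergeometric_tail(n, total_pos, k, observed)


def _ks_stat_int(flags: np.ndarray, signed: bool) -> int:
    """Integer form of the K-S deviation: max_k (n*S_k - k*P), where S_k
    counts +1 labels in the top k and P is their total.

    The true statistic max_k |curve_pos[k] - k/n| equals this divided by
    n*P; working in integers makes >= comparisons between permutations
    exact, so ties at rational mass points are counted correctly.
    """
    n = len(flags)
    total = int(flags.sum())
    cumulative = np.cumsum(flags)
    deviation = n * cumulative - np.arange(1, n + 1) * total
    if signed:
        return int(deviation.max())
    return int(np.abs(deviation).max())


def _ks_stat(flags: np.ndarray, signed: bool) -> float:
    n = len(flags)
    total = int(flags.sum())
    return _ks_stat_int(flags, signed) / (n * total)


def ks_permutation_pvalue(
    labels: RankedLabels,
    n_perm: int,
    seed: int,
    exhaustive_below: int = 10,
    signed: bool = False,
) -> tuple[float, float]:
    """Permutation K-S significance of the enrichment.

    The statistic is ``D = max_k |curve_pos[k] - k/N|`` (``signed=True``
    keeps only positive deviations).  For ``N <= exhaustive_below``
    every distinct arrangement of the labels is enumerated and the
    p-value is exact; otherwise ``n_perm`` seeded random rearrangements
    are scored and ``p = (1 + #{D' >= D}) / (1 + n_perm)``, never zero.
    """
    arr = np.asarray(labels.labels)
    if len(set(arr.tolist())) < 2:
        raise EfdbError("both labels must be present")
    if n_perm < 1:
        raise EfdbError(f"n_perm must be >= 1, got {n_perm}")
    flags = arr == 1
    n = len(flags)
    observed_int = _ks_stat_int(flags, signed)
    observed = _ks_stat(flags, signed)
    if n <= exhaustive_below:
        n_pos = int(flags.sum())
        better = 0
        total = 0
        for positions in combinations(range(n), n_pos):
            perm = np.zeros(n, dtype=bool)
            perm[list(positions)] = True
            total += 1
            if _ks_stat_int(perm, signed) >= observed_int:
                better += 1
        return observed, better / total
    rng = np.random.default_rng(seed)
    better = 0
    work = flags.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if _ks_stat_int(work, signed) >= observed_int:
            better += 1
    return observed, (1 + better) / (1 + n_perm)


def analyse(
    labels: RankedLabels,
    k: Optional[int],
    n_perm: int,
    seed: int,
    exhaustive_below: int = 10,
    signed: bool = False,
) -> EnrichmentResult:
    """Run curves, Fisher test (if ``k`` given) and permutation K-S."""
    curve_pos, curve_neg = enrichment_curve(labels)
    fisher_p = fisher_enrichment_test(labels, k) if k is not None else None
    ks_stat, ks_p = ks_permutation_pvalue(
        labels, n_perm=n_perm, seed=seed,
        exhaustive_below=exhaustive_below, signed=signed,
    )
    return EnrichmentResult(
        curve_pos=curve_pos.tolist(),
        curve_neg=curve_neg.tolist(),
        fisher_p=fisher_p,
        ks_stat=ks_stat,
        ks_p=ks_p,
        n_perm=n_perm,
        seed=seed,
    )


def read_labels_tsv(path) -> RankedLabels:
    """Read a ``sample_id<TAB>score<TAB>label`` TSV."""
    sample_ids: list[str] = []
    scores: list[float] = []
    values: list[int] = []
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "score", "label"]:
            raise EfdbError(
                f"{path}: expected header sample_id<TAB>score<TAB>label"
            )
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise EfdbError(f"{path}:{lineno}: expected 3 fields")
            sample_ids.append(parts[0])
            try:
                scores.append(float(parts[1]))
                values.append(int(parts[2].lstrip("+")))
            except ValueError:
                raise EfdbError(f"{path}:{lineno}: bad numeric value") from None
    return RankedLabels(sample_ids=sample_ids, scores=scores, labels=values)
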