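"""Rank-list tools for perturbagen screens.

Ranked probe/gene lists (one per treatment instance) are converted into
pseudo-fold values on [-1, 1] via the linear map

    f = 1 - 2 * (rank - min) / (max - min)

so the top of the list (rank = min, the most up-regulated gene) maps to
+1 and the bottom to -1.  Replicate instances of one compound are pooled
into a per-gene mean pseudo-fold with a one-sample t-test against zero,
and binary disease signatures are scored against a compound's instances
by per-instance correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from efdb.ef import MACHINE_MIN_P
from efdb.errors import EfdbError
from efdb.signatures import BinarySignature

logger = logging.getLogger(__name__)


@dataclass
class RankedInstance:
    """One treatment instance: gene -> integer rank, 1 = top of the list."""

    instance_id: str
    compound: str
    ranks: dict[str, int]


@dataclass
class CompoundProfile:
    """Pooled pseudo-fold profile for one perturbagen."""

    compound: str
    n_instances: int
    folds: dict[str, float]
    p_values: dict[str, float]


def ranks_to_pseudofolds(
    instance: RankedInstance, flip_ranks: bool = False
) -> dict[str, float]:
    """Linearly rescale an instance's ranks to pseudo-folds in [-1, 1].

    The minimal rank maps to +1, the maximal to -1 (``flip_ranks``
    inverts the convention).  Duplicate ranks are rejected.
    """
    ranks = instance.ranks
    if len(ranks) < 2:
        raise EfdbError(
            f"instance {instance.instance_id}: need >= 2 ranks"
        )
    values = list(ranks.values())
    if len(set(values)) != len(values):
        raise EfdbError(
            f"instance {instance.instance_id}: duplicate ranks"
        )
    lo, hi = min(values), max(values)
    span = hi - lo
    sign = -1.0 if flip_ranks else 1.0
    return {
        gene: sign * (1.0 - 2.0 * (rank - lo) / span)
        for gene, rank in ranks.items()
    }


def pool_compound_instances(
    instances: Sequence[RankedInstance],
    alpha: float = 0.05,
    min_replicates: int = 3,
    flip_ranks: bool = False,
) -> Optional[CompoundProfile]:
    """Pool replicate instances of one compound into a thresholded profile.

    Per gene (over the union of instance gene sets) the mean pseudo-fold
    is computed together with a two-sided one-sample t-test against
    zero; genes with ``p >= alpha`` are dropped.  Compounds with fewer
    than ``min_replicates`` instances are rejected: the function returns
    ``None`` and logs, it does not raise.
    """
    if not instances:
        return None
    compounds = {inst.compound for inst in instances}
    if len(compounds) != 1:
        raise EfdbError(f"instances span several compounds: {sorted(compounds)}")
    compound = instances[0].compound
    if len(instances) < min_replicates:
        logger.warning(
            "compound %s rejected: %d instance(s) < %d required",
            compound, len(instances), min_replicates,
        )
        return None
    per_gene: dict[str, list[float]] = {}
    for inst in instances:
        for gene, fold in ranks_to_pseudofolds(inst, flip_ranks).items():
            per_gene.setdefault(gene, []).append(fold)
    folds: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for gene, observed in per_gene.items():
        mean = float(np.mean(observed))
        if len(observed) < 2:
            continue  # no dispersion estimate, no significance call
        if np.var(observed) == 0.0:
            p = 1.0 if mean == 0.0 else MACHINE_MIN_P
        else:
            p = float(stats.ttest_1samp(observed, 0.0).pvalue)
        if p < alpha:
            folds[gene] = mean
            p_values[gene] = p
    return CompoundProfile(
        compound=compound,
        n_instances=len(instances),
        folds=folds,
        p_values=p_values,
    )


def score_signature_against_compound(
    signature: BinarySignature,
    instances: Sequence[RankedInstance],
    flip_ranks: bool = False,
) -> Optional[tuple[float, float, int]]:
    """Correlate a +/-1 signature with each instance of a compound.

    Per instance, the signature values are Pearson-correlated with the
    instance's pseudo-folds over the signature genes present in that
    instance; instances sharing no usable genes are skipped with a log
    message.  Returns ``(mean_r, prob, N)`` where N is the number of
    instances used and prob is the two-sided one-sample t-test of the
    per-instance correlations against zero (``prob`` is NaN when only
    one usable instance remains).  Returns ``None`` when no instance is
    usable.
    """
    if len(signature.entries) == 0:
        raise EfdbError("empty signature")
    if len(instances) < 2:
        raise EfdbError("need >= 2 instances to score a compound")
    correlations: list[float] = []
    for inst in instances:
        pseudo = ranks_to_pseudofolds(inst, flip_ranks)
        shared = [g for g in signature.entries if g in pseudo]
        if len(shared) < 2:
            logger.info(
                "instance %s skipped: %d shared gene(s)",
                inst.instance_id, len(shared),
            )
            continue
        x = np.array([float(signature.entries[g]) for g in shared])
        y = np.array([pseudo[g] for g in shared])
        if x.std() == 0.0 or y.std() == 0.0:
            logger.info("instance %s skipped: zero variance", inst.instance_id)
            continue
        correlations.append(float(np.corrcoef(x, y)[0, 1]))
    if not correlations:
        return None
    mean_r = float(np.mean(correlations))
    if len(correlations) < 2:
        prob = float("nan")
    elif np.var(correlations) == 0.0:
        prob = 1.0 if mean_r == 0.0 else MACHINE_MIN_P
    else:
        prob = float(stats.ttest_1samp(correlations, 0.0).pvalue)
    return mean_r, prob, len(correlations)


def read_instance_tsv(path, instance_id: str, compound: str) -> RankedInstance:
    """Read a ``gene<TAB>rank`` TSV into a :class:`RankedInstance`."""
    ranks: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "rank"]:
            raise EfdbError(
                f"{path}: expected header gene<TAB>rank, got {header[:2]}"
            )
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise EfdbError(f"{path}:{lineno}: expected 2 fields")
            try:
                ranks[parts[0]] = int(parts[1])
            except ValueError:
                raise EfdbError(f"{path}:{lineno}: bad rank {parts[1]!r}") from None
    return RankedInstance(instance_id=instance_id, compound=compound, ranks=ranks)


def write_instance_tsv(instance: RankedInstance, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("gene\trank\n")
        for gene, rank in sorted(instance.ranks.items(), key=lambda kv: kv[1]):
            handle.write(f"{gene}\t{rank}\n")


def read_manifest_tsv(path) -> list[tuple[str, str, str]]:
    """Read an ``instance_id<TAB>compound<TAB>file`` manifest."""
    rows: list[tuple[str, str, str]] = []
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["instance_id", "compound", "file"]:
            raise EfdbError(
                f"{path}: expected header instance_id<TAB>compound<TAB>file"
            )
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise EfdbError(f"{path}:{lineno}: expected 3 fields")
            rows.append((parts[0], parts[1], parts[2]))
    return rows
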