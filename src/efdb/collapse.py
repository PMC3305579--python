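"""Probe-to-gene collapse.

Array platforms carry several probes per gene.  To make profiles
comparable across platforms each gene is represented by the single probe
with the most robust fold response over the whole corpus, measured as
the root-mean-square deviation of its effective folds from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from efdb.ef import EFProfile
from efdb.errors import EfdbError, PlatformMismatchError

logger = logging.getLogger(__name__)

#: Affymetrix-dialect separator marking probes annotated to several genes.
AMBIGUOUS_SEPARATOR = "///"


@dataclass
class PlatformAnnotation:
    """Unambiguous probe -> gene-symbol map restricted to a gene universe."""

    platform_id: str
    probe_to_gene: dict[str, str]
    gene_universe: list[str]
    drop_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class GeneIndex:
    """Per-platform choice of one representative probe per gene."""

    platform_id: str
    gene_to_probe: dict[str, str]
    rms: dict[str, float]


def parse_annotation(
    path, gene_universe_path, platform_id: str = ""
) -> PlatformAnnotation:
    """Parse a probe annotation TSV against a gene-universe list.

    The TSV must have ``probe_id`` and ``gene_symbol`` columns.  Probes
    with empty, ambiguous (``///``-separated multi-symbol) or
    out-of-universe annotations are dropped; drop counts are logged and
    kept on the returned annotation.
    """
    universe: list[str] = []
    seen: set[str] = set()
    with open(gene_universe_path, "r", encoding="utf-8") as handle:
        for line in handle:
            symbol = line.strip()
            if symbol and symbol not in seen:
                universe.append(symbol)
                seen.add(symbol)
    drops = {"empty": 0, "ambiguous": 0, "out_of_universe": 0}
    probe_to_gene: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        try:
            probe_col = header.index("probe_id")
            gene_col = header.index("gene_symbol")
        except ValueError:
            missing = [c for c in ("probe_id", "gene_symbol") if c not in header]
            raise EfdbError(
                f"{path}: missing required column(s) {missing}"
            ) from None
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(probe_col, gene_col):
                drops["empty"] += 1
                continue
            probe = parts[probe_col].strip()
            symbol = parts[gene_col].strip()
            if not probe or not symbol:
                drops["empty"] += 1
                continue
            if AMBIGUOUS_SEPARATOR in symbol:
                drops["ambiguous"] += 1
                continue
            if symbol not in seen:
                drops["out_of_universe"] += 1
                continue
            probe_to_gene[probe] = symbol
    logger.info(
        "annotation %s: kept %d probes, dropped %s", platform_id,
        len(probe_to_gene), drops,
    )
    return PlatformAnnotation(
        platform_id=platform_id,
        probe_to_gene=probe_to_gene,
        gene_universe=universe,
        drop_counts=drops,
    )


def compute_probe_rms(folds: Sequence[float]) -> float:
    """Root-mean-square deviation from zero over the defined folds.

    An empty list (a probe that never survived the cutoff) scores 0.
    Absent folds are not counted as zeros: that would penalise sparsely
    measured probes twice.
    """
    if not folds:
        return 0.0
    return math.sqrt(sum(f * f for f in folds) / len(folds))


def select_representative_probes(
    annotation: PlatformAnnotation, ef_corpus: Iterable[EFProfile]
) -> GeneIndex:
    """Choose, per gene, the probe maximising corpus-wide fold RMS.

    The RMS statistic of each annotated probe is accumulated across every
    profile in the corpus; for each gene with at least one probe observed
    the probe with the highest RMS is selected, ties broken by the
    lexicographically smallest probe id so selection is deterministic.
    """
    sq_sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_profiles = 0
    for profile in ef_corpus:
        n_profiles += 1
        for probe, fold in profile.folds.items():
            if probe in annotation.probe_to_gene:
                sq_sums[probe] = sq_sums.get(probe, 0.0) + fold * fold
                counts[probe] = counts.get(probe, 0) + 1
    if n_profiles == 0:
        raise EfdbError("empty EF corpus")
    rms = {
        probe: math.sqrt(sq_sums[probe] / counts[probe]) for probe in sq_sums
    }
    best: dict[str, str] = {}
    for probe in sorted(rms):
        gene = annotation.probe_to_gene[probe]
        incumbent = best.get(gene)
        if incumbent is None or rms[probe] > rms[incumbent]:
            best[gene] = probe
    return GeneIndex(
        platform_id=annotation.platform_id,
        gene_to_probe=best,
        rms={best[g]: rms[best[g]] for g in best},
    )


def collapse_profile(profile: EFProfile, index: GeneIndex) -> EFProfile:
    """Reduce a probe-keyed EF profile to a non-redundant gene profile.

    A gene is present exactly when its chosen probe has a fold in the
    input; fold values are copied unchanged.
    """
    if (
        profile.platform_id
        and index.platform_id
        and profile.platform_id != index.platform_id
    ):
        raise PlatformMismatchError(
            f"profile platform {profile.platform_id!r} != "
            f"index platform {index.platform_id!r}"
        )
    folds = {
        gene: profile.folds[probe]
        for gene, probe in index.gene_to_probe.items()
        if probe in profile.folds
    }
    return EFProfile(
        sample_id=profile.sample_id,
        series_id=profile.series_id,
        platform_id=index.platform_id or profile.platform_id,
        folds=folds,
    )
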