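"""Synthetic fixtures with known ground truth.

Generates multi-sample expression series with planted treatment
effects, replicate structure and redundant probe sets; whole databases
built through the full EF -> collapse -> store pipeline; and ranked
perturbagen instance lists concordant with a chosen signature.  All
generation is driven by :class:`numpy.random.Generator` seeded
explicitly, so a fixed seed reproduces byte-identical artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from efdb.collapse import (
    GeneIndex,
    PlatformAnnotation,
    collapse_profile,
    select_representative_probes,
)
from efdb.ef import (
    EFProfile,
    ExpressionSeries,
    apply_cutoff,
    compute_ef_profiles,
    rescale_series,
)
from efdb.errors import EfdbError
from efdb.query import QueryProfile, build_query_from_replicates
from efdb.signatures import BinarySignature
from efdb.cmap import RankedInstance
from efdb.store import FoldDatabase, write_database

logger = logging.getLogger(__name__)

SIM_PLATFORM = "SIMPL1"

#: Median and log-sd of the lognormal baseline intensities; chosen to
#: mimic linear-scale microarray levels (hundreds, heavy right tail).
BASELINE_MEDIAN = 200.0
BASELINE_SIGMA = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic expression series."""

    n_genes: int = 100
    n_probes_per_gene: Union[int, tuple[int, int]] = 2
    n_treat: int = 4
    n_ctrl: int = 4
    effect_genes: int = 10
    effect_size: float = 4.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_treat < 1 or self.n_ctrl < 1:
            raise EfdbError("all counts must be positive")
        if not 0 <= self.effect_genes <= self.n_genes:
            raise EfdbError("effect_genes must be within [0, n_genes]")
        if self.effect_size <= 0:
            raise EfdbError("effect_size must be positive")
        if self.noise_cv <= 0:
            raise EfdbError("noise_cv must be positive")
        if isinstance(self.n_probes_per_gene, tuple):
            lo, hi = self.n_probes_per_gene
            if lo < 1 or hi < lo:
                raise EfdbError("invalid probe-count range")
        elif self.n_probes_per_gene < 1:
            raise EfdbError("n_probes_per_gene must be positive")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # unit-mean multiplicative noise with the requested coefficient of variation
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def make_platform(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> PlatformAnnotation:
    """Build the synthetic platform: genes, redundant probes, annotation."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    probe_to_gene: dict[str, str] = {}
    for gene in genes:
        if isinstance(spec.n_probes_per_gene, tuple):
            lo, hi = spec.n_probes_per_gene
            count = int(rng.integers(lo, hi + 1))
        else:
            count = spec.n_probes_per_gene
        for j in range(count):
            probe_to_gene[f"{gene}_p{j}"] = gene
    return PlatformAnnotation(
        platform_id=SIM_PLATFORM,
        probe_to_gene=probe_to_gene,
        gene_universe=genes,
    )


def simulate_series(
    spec: SimulationSpec,
    series_id: str = "SIM",
    annotation: Optional[PlatformAnnotation] = None,
) -> tuple[ExpressionSeries, dict]:
    """Simulate one raw linear-scale series with a planted effect.

    Control samples are per-gene lognormal baselines times unit-mean
    lognormal noise; treatment samples additionally multiply affected
    genes by ``effect_size`` (half up) or ``1/effect_size`` (half down).
    Probe redundancy replicates gene rows with independent noise.
    Returns the series and a ground-truth record.
    """
    rng = np.random.default_rng(spec.seed)
    if annotation is None:
        annotation = make_platform(spec, rng)
    genes = annotation.gene_universe
    if len(genes) != spec.n_genes:
        raise EfdbError("annotation does not match spec gene count")
    baseline = BASELINE_MEDIAN * rng.lognormal(
        mean=0.0, sigma=BASELINE_SIGMA, size=spec.n_genes
    )
    affected = rng.choice(spec.n_genes, size=spec.effect_genes, replace=False)
    n_up = spec.effect_genes // 2 + spec.effect_genes % 2
    up = set(affected[:n_up].tolist())
    down = set(affected[n_up:].tolist())
    multiplier = np.ones(spec.n_genes)
    for g in up:
        multiplier[g] = spec.effect_size
    for g in down:
        multiplier[g] = 1.0 / spec.effect_size

    n_samples = spec.n_treat + spec.n_ctrl
    treat_ids = [f"{series_id}.T{i}" for i in range(spec.n_treat)]
    ctrl_ids = [f"{series_id}.C{i}" for i in range(spec.n_ctrl)]
    sample_ids = treat_ids + ctrl_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    probe_ids = sorted(annotation.probe_to_gene)
    rows = np.asarray(
        [gene_index[annotation.probe_to_gene[p]] for p in probe_ids]
    )
    signal = baseline[rows, np.newaxis] * np.ones((1, n_samples))
    if spec.effect_size != 1.0:
        signal[:, : spec.n_treat] *= multiplier[rows, np.newaxis]
    values = signal * _lognormal_noise(rng, spec.noise_cv,
                                       (len(probe_ids), n_samples))
    series = ExpressionSeries(
        series_id=series_id,
        platform_id=annotation.platform_id,
        sample_ids=sample_ids,
        probe_ids=probe_ids,
        values=values,
    )
    truth = {
        "series_id": series_id,
        "treat_samples": treat_ids,
        "ctrl_samples": ctrl_ids,
        "up_genes": sorted(genes[g] for g in up),
        "down_genes": sorted(genes[g] for g in down),
        "effect_size": spec.effect_size,
    }
    return series, truth


def _gene_level_series(
    series: ExpressionSeries, index: GeneIndex
) -> ExpressionSeries:
    """Restrict a probe-level series to each gene's chosen probe row."""
    probe_pos = {p: i for i, p in enumerate(series.probe_ids)}
    genes = [g for g, p in sorted(index.gene_to_probe.items()) if p in probe_pos]
    rows = [probe_pos[index.gene_to_probe[g]] for g in genes]
    return ExpressionSeries(
        series_id=series.series_id,
        platform_id=series.platform_id,
        sample_ids=list(series.sample_ids),
        probe_ids=genes,
        values=series.values[rows, :],
    )


def simulate_database(
    n_series: int,
    spec_template: SimulationSpec,
    planted: SimulationSpec,
    out_path,
    cutoff_fraction: float = 0.1,
    alpha: float = 0.05,
    max_genes: int = 500,
    species: str = "synthetic",
) -> dict:
    """Build a flat database of null series plus one planted series.

    ``n_series`` null series (no effect) and one planted series are
    generated on a shared platform, run through the full pipeline
    (rescale -> cutoff -> EF -> representative-probe collapse -> store)
    and written to ``out_path``.  The returned truth record carries the
    planted sample ids, affected genes, and a query profile built from
    the planted series' replicates at the gene level.
    """
    annotation = make_platform(spec_template)
    master = np.random.default_rng(spec_template.seed)
    null_spec = replace(spec_template, effect_genes=0, effect_size=1.0)

    all_series: list[ExpressionSeries] = []
    for i in range(n_series):
        spec_i = replace(null_spec, seed=int(master.integers(2 ** 63)))
        series, _ = simulate_series(spec_i, series_id=f"NULL{i:03d}",
                                    annotation=annotation)
        all_series.append(series)
    planted_spec = replace(planted, seed=int(master.integers(2 ** 63)))
    planted_series, truth = simulate_series(
        planted_spec, series_id="PLANTED", annotation=annotation
    )
    all_series.append(planted_series)

    processed = [
        apply_cutoff(rescale_series(s), cutoff_fraction) for s in all_series
    ]
    corpus: list[list[EFProfile]] = [compute_ef_profiles(s) for s in processed]
    index = select_representative_probes(
        annotation, (p for profiles in corpus for p in profiles)
    )
    db = FoldDatabase(
        platform_id=annotation.platform_id,
        species=species,
        gene_list=sorted(index.gene_to_probe),
    )
    for profiles in corpus:
        for profile in profiles:
            db.add_profile(collapse_profile(profile, index))
    write_database(db, out_path)

    planted_processed = processed[-1]
    query = build_query_from_replicates(
        truth["treat_samples"],
        truth["ctrl_samples"],
        _gene_level_series(planted_processed, index),
        alpha=alpha,
        max_genes=max_genes,
        name="planted-query",
    )
    truth.update(
        {
            "db_path": str(out_path),
            "n_series": n_series + 1,
            "query": query,
            "gene_index": index,
        }
    )
    return truth


def simulate_ranked_instances(
    compound_count: int,
    replicates: int,
    signature: BinarySignature,
    fidelity: float,
    seed: int,
    n_background_genes: int = 200,
) -> list[RankedInstance]:
    """Simulate ranked instance lists, one compound tracking a signature.

    The first compound's instances rank each signature gene concordantly
    with probability ``fidelity`` and discordantly otherwise, so
    fidelity 1 is perfectly concordant, 0 perfectly reversed and 0.5
    indistinguishable from the random background.  All remaining
    compounds rank every gene at random.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise EfdbError(f"fidelity must be in [0, 1], got {fidelity}")
    if compound_count < 1 or replicates < 1:
        raise EfdbError("compound_count and replicates must be positive")
    rng = np.random.default_rng(seed)
    sig_genes = sorted(signature.entries)
    genes = sig_genes + [f"BG{i:05d}" for i in range(n_background_genes)]
    instances: list[RankedInstance] = []
    for c in range(compound_count):
        compound = f"CPD{c:03d}"
        for rep in range(replicates):
            scores = rng.standard_normal(len(genes))
            if c == 0:
                for i, gene in enumerate(sig_genes):
                    concordant = rng.random() < fidelity
                    direction = signature.entries[gene] * (1 if concordant else -1)
                    scores[i] = direction * abs(rng.normal(2.0, 0.5))
            order = np.argsort(-scores, kind="stable")
            ranks = {genes[int(g)]: int(pos) + 1 for pos, g in enumerate(order)}
            instances.append(
                RankedInstance(
                    instance_id=f"{compound}.r{rep}",
                    compound=compound,
                    ranks=ranks,
                )
            )
    return instances
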