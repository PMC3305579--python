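"""Effective-fold (EF) profiles.

An EF profile expresses each measurement relative to the average of its
experimental series through the bounded fold measure

    f = 2 * (s - m) / (s + m)

where ``s`` is the (linear-scale, rescaled, cutoff-filtered) expression
value and ``m`` is the per-probe mean over the samples of the series in
which the probe survived the low-expression cutoff.  The measure lies
strictly inside (-2, 2) for positive operands, is antisymmetric in its
arguments and invariant under global rescaling, which is what makes
profiles from unrelated experiments directly comparable without any
control/treatment assignment.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from efdb.errors import SeriesError

logger = logging.getLogger(__name__)

#: Smallest positive normal float; used as the p-value for genes whose
#: groups have zero variance but unequal means (a "certain" difference).
MACHINE_MIN_P = float(np.finfo(np.float64).tiny)


@dataclass
class ExpressionSeries:
    """A raw probe x sample matrix for one experimental series.

    Values are linear-scale, non-negative intensities after
    preprocessing.  Rows are probes (or genes, after collapsing),
    columns are samples.
    """

    series_id: str
    platform_id: str
    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise SeriesError(f"series {self.series_id}: values must be 2-D")
        n_probes, n_samples = self.values.shape
        if n_probes != len(self.probe_ids):
            raise SeriesError(
                f"series {self.series_id}: {n_probes} rows but "
                f"{len(self.probe_ids)} probe ids"
            )
        if n_samples != len(self.sample_ids):
            raise SeriesError(
                f"series {self.series_id}: {n_samples} columns but "
                f"{len(self.sample_ids)} sample ids"
            )
        if n_samples < 2:
            raise SeriesError(
                f"series {self.series_id}: at least 2 samples required"
            )
        if not np.all(np.isfinite(self.values)):
            raise SeriesError(f"series {self.series_id}: non-finite values")
        if np.any(self.values < 0):
            raise SeriesError(f"series {self.series_id}: negative values")
        if len(set(self.sample_ids)) != n_samples:
            raise SeriesError(f"series {self.series_id}: duplicate sample ids")
        if len(set(self.probe_ids)) != n_probes:
            raise SeriesError(f"series {self.series_id}: duplicate probe ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise SeriesError(
                f"series {self.series_id}: unknown sample {sample_id!r}"
            ) from None


@dataclass
class EFProfile:
    """Per-sample sparse vector of effective folds.

    Keys are probe ids (or gene symbols after collapsing); a missing key
    means the measurement was excluded by the cutoff or absent from the
    platform.  Every stored fold is finite and within [-2, 2].
    """

    sample_id: str
    series_id: str
    folds: dict[str, float]
    platform_id: Optional[str] = None

    def __post_init__(self) -> None:
        for key, value in self.folds.items():
            if not np.isfinite(value) or abs(value) > 2:
                raise ValueError(
                    f"profile {self.sample_id}: fold {value!r} for "
                    f"{key!r} outside [-2, 2]"
                )

    def __len__(self) -> int:
        return len(self.folds)


@dataclass
class PooledFoldProfile:
    """Treatment-vs-control fold vector formed from group averages."""

    folds: dict[str, float]
    p_values: dict[str, float]
    n_treat: int
    n_ctrl: int
    zero_variance_keys: list[str] = field(default_factory=list)


def fold_measure(a, b):
    """Bounded fold ``2*(a - b)/(a + b)``, elementwise.

    Antisymmetric (``f(a, b) == -f(b, a)``) and scale invariant; strictly
    inside (-2, 2) when both operands are positive.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * (a - b) / denom
    return out


def detect_and_delog(values: np.ndarray, log_base: Optional[float] = None) -> np.ndarray:
    """Return ``values`` on a linear scale.

    With an explicit ``log_base`` the matrix is exponentiated
    elementwise.  Without one, a standard microarray heuristic is
    applied: a matrix whose maximum is below 30 with no negative entries
    is taken to be log2-scaled and exponentiated; anything else is
    passed through unchanged.

    Raises :class:`SeriesError` when the result (or a passed-through
    matrix) contains negative or non-finite entries.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise SeriesError("empty matrix")
    if not np.all(np.isfinite(values)):
        raise SeriesError("matrix contains non-finite entries")
    if log_base is not None:
        if log_base <= 0 or log_base == 1:
            raise SeriesError(f"invalid log base {log_base}")
        out = np.power(float(log_base), values)
        if not np.all(np.isfinite(out)):
            raise SeriesError("overflow while exponentiating log-scale values")
        return out
    vmin = float(values.min())
    vmax = float(values.max())
    if vmin < 0:
        raise SeriesError(
            f"matrix has negative entries (min {vmin:g}) on a linear scale; "
            "rejecting series"
        )
    if vmax < 30.0:
        logger.info("delog heuristic: max %.3g < 30, assuming log2 scale", vmax)
        return np.power(2.0, values)
    return values


def rescale_series(series: ExpressionSeries) -> ExpressionSeries:
    """Scale every sample to the common (grand) average expression.

    Each sample column is multiplied by a factor that makes its mean over
    all probes equal to the grand mean of the input matrix; relative
    ordering within a sample is untouched.
    """
    sample_means = series.values.mean(axis=0)
    zero = np.flatnonzero(sample_means <= 0)
    if zero.size:
        bad = series.sample_ids[int(zero[0])]
        raise SeriesError(
            f"series {series.series_id}: sample {bad!r} has no positive values"
        )
    grand_mean = series.values.mean()
    scaled = series.values * (grand_mean / sample_means)[np.newaxis, :]
    return ExpressionSeries(
        series_id=series.series_id,
        platform_id=series.platform_id,
        sample_ids=list(series.sample_ids),
        probe_ids=list(series.probe_ids),
        values=scaled,
    )


def apply_cutoff(
    series: ExpressionSeries, cutoff_fraction: float = 0.1
) -> ExpressionSeries:
    """Zero out low expression values.

    Values below ``cutoff_fraction`` of the series grand mean are set to
    zero; zeroed entries do not contribute to fold profiles downstream.
    The series is expected to be rescaled already, so the grand mean
    equals every sample mean.
    """
    if not 0.0 <= cutoff_fraction < 1.0:
        raise SeriesError(
            f"cutoff_fraction must be in [0, 1), got {cutoff_fraction}"
        )
    threshold = cutoff_fraction * series.values.mean()
    mask = series.values < threshold
    out = series.values.copy()
    out[mask] = 0.0
    n_zeroed = int(mask.sum())
    logger.info(
        "series %s: cutoff %.4g zeroed %d of %d entries",
        series.series_id, threshold, n_zeroed, series.values.size,
    )
    return ExpressionSeries(
        series_id=series.series_id,
        platform_id=series.platform_id,
        sample_ids=list(series.sample_ids),
        probe_ids=list(series.probe_ids),
        values=out,
    )


def compute_ef_profiles(series: ExpressionSeries) -> list[EFProfile]:
    """Convert a rescaled, cutoff-filtered series into per-sample EF profiles.

    For probe ``k`` and sample ``j`` with surviving value ``s > 0`` the
    fold is ``2*(s - m)/(s + m)``, where ``m`` is the probe's mean over
    the samples in which it survived the cutoff.  Probes surviving in
    fewer than 2 samples are dropped for the whole series (a mean over a
    single sample carries no information).  Zeroed entries are absent
    from the sample's profile.
    """
    if series.n_samples < 2:
        raise SeriesError(
            f"series {series.series_id}: need >= 2 samples for a series average"
        )
    values = series.values
    surviving = values > 0
    n_surviving = surviving.sum(axis=1)
    keep = n_surviving >= 2
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "series %s: dropped %d probes surviving in < 2 samples",
            series.series_id, n_dropped,
        )
    with np.errstate(invalid="ignore"):
        probe_means = np.where(
            keep, values.sum(axis=1) / np.maximum(n_surviving, 1), 0.0
        )
    folds = fold_measure(values, probe_means[:, np.newaxis])
    defined = surviving & keep[:, np.newaxis] & (probe_means > 0)[:, np.newaxis]
    probe_ids = np.asarray(series.probe_ids, dtype=object)
    profiles = []
    for j, sample_id in enumerate(series.sample_ids):
        col = defined[:, j]
        profiles.append(
            EFProfile(
                sample_id=sample_id,
                series_id=series.series_id,
                platform_id=series.platform_id,
                folds=dict(zip(probe_ids[col], folds[col, j].tolist())),
            )
        )
    return profiles


def _group_indices(series: ExpressionSeries, sample_ids: Sequence[str]) -> np.ndarray:
    return np.asarray([series.sample_index(s) for s in sample_ids], dtype=np.intp)


def compute_pooled_fold_profile(
    treat: Sequence[str],
    ctrl: Sequence[str],
    series: ExpressionSeries,
    measure: str = "fold",
) -> PooledFoldProfile:
    """Pool treatment and control samples into one fold profile.

    Per row, group means are taken over values that survived the cutoff
    (zeros excluded); the pooled fold is the bounded measure
    ``2*(T - C)/(T + C)`` of the two means, or the raw ratio ``T/C``
    when ``measure='ratio'``.  Rows where both group means are zero are
    excluded.  p-values come from an equal-variance two-sample Student's
    t-test on the surviving values and are reported for rows with at
    least 2 surviving values per group.  Rows where both groups have
    zero variance get p = 1 when the means agree and the machine-minimum
    p otherwise, and are listed in ``zero_variance_keys``.
    """
    if not treat or not ctrl:
        raise SeriesError("both sample groups must be non-empty")
    overlap = set(treat) & set(ctrl)
    if overlap:
        raise SeriesError(f"samples in both groups: {sorted(overlap)}")
    if measure not in ("fold", "ratio"):
        raise SeriesError(f"unknown pooled measure {measure!r}")
    ti = _group_indices(series, treat)
    ci = _group_indices(series, ctrl)
    tvals = series.values[:, ti]
    cvals = series.values[:, ci]
    tmask = tvals > 0
    cmask = cvals > 0
    tn = tmask.sum(axis=1)
    cn = cmask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tmean = np.where(tn > 0, tvals.sum(axis=1) / np.maximum(tn, 1), 0.0)
        cmean = np.where(cn > 0, cvals.sum(axis=1) / np.maximum(cn, 1), 0.0)

    folds: dict[str, float] = {}
    p_values: dict[str, float] = {}
    zero_var: list[str] = []
    for k, key in enumerate(series.probe_ids):
        T, C = tmean[k], cmean[k]
        if T + C == 0:
            continue
        if measure == "fold":
            folds[key] = float(2.0 * (T - C) / (T + C))
        else:
            folds[key] = float(np.inf) if C == 0 else float(T / C)
        if tn[k] >= 2 and cn[k] >= 2:
            x = tvals[k, tmask[k]]
            y = cvals[k, cmask[k]]
            if x.var() == 0 and y.var() == 0:
                p = 1.0 if T == C else MACHINE_MIN_P
                zero_var.append(key)
            else:
                p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
            p_values[key] = p
    if zero_var:
        logger.warning(
            "%d rows had zero variance in both groups; p set degenerately",
            len(zero_var),
        )
    return PooledFoldProfile(
        folds=folds,
        p_values=p_values,
        n_treat=len(treat),
        n_ctrl=len(ctrl),
        zero_variance_keys=zero_var,
    )


def read_expression_tsv(
    path, series_id: Optional[str] = None, platform_id: str = ""
) -> ExpressionSeries:
    """Read a probe x sample TSV (first column ``PROBE_ID``, header row
    of sample ids) into an :class:`ExpressionSeries`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    first = frame.columns[0]
    if first.upper() != "PROBE_ID":
        raise SeriesError(
            f"{path}: first column must be PROBE_ID, got {first!r}"
        )
    frame = frame.set_index(first)
    if series_id is None:
        import os

        series_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ExpressionSeries(
        series_id=series_id,
        platform_id=platform_id,
        sample_ids=[str(c) for c in frame.columns],
        probe_ids=[str(p) for p in frame.index],
        values=frame.to_numpy(dtype=np.float64),
    )


def read_group_sidecar(path) -> dict[str, str]:
    """Read a ``sample_id<TAB>group`` sidecar into a mapping."""
    groups: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SeriesError(
                    f"{path}:{lineno}: expected sample_id<TAB>group"
                )
            groups[parts[0]] = parts[1]
    return groups
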