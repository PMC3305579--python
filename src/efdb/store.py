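"""Flat-file fold database.

Collapsed EF profiles are serialised in a line-oriented text format that
can be searched record by record, in the spirit of FASTA sequence
databases: a header, the gene list, then one line per sample profile.

Layout (UTF-8, Unix newlines, one file per platform)::

    #EFDB<TAB>1<TAB>platform=<ID><TAB>species=<NAME><TAB>genes=<M><TAB>samples=<S>
    GENES<TAB>g1<TAB>...<TAB>gM
    <sample_id><TAB><series_id><TAB>v1<TAB>...<TAB>vM

Fold slots are fixed 4-decimal strings (round-half-even) or ``NA`` for
a gene excluded by the cutoff; 4 decimals comfortably exceed the
precision of any correlation computed from the data.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from efdb.collapse import GeneIndex
from efdb.ef import EFProfile
from efdb.errors import FormatError, PlatformMismatchError

logger = logging.getLogger(__name__)

MAGIC = "#EFDB"
FORMAT_VERSION = "1"


@dataclass
class FoldDatabase:
    """In-memory form of a fold database.

    ``records`` holds ``(sample_id, series_id, vector)`` tuples whose
    vectors are aligned to ``gene_list`` with NaN marking missing genes.
    """

    platform_id: str
    species: str
    gene_list: list[str]
    records: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sample_id, series_id, vector in self.records:
            if len(vector) != len(self.gene_list):
                raise FormatError(
                    f"record {sample_id!r}: vector length {len(vector)} != "
                    f"gene list length {len(self.gene_list)}"
                )

    def add_profile(self, profile: EFProfile) -> None:
        vector = np.full(len(self.gene_list), np.nan)
        unknown = 0
        positions = {g: i for i, g in enumerate(self.gene_list)}
        for gene, fold in profile.folds.items():
            pos = positions.get(gene)
            if pos is None:
                unknown += 1
            else:
                vector[pos] = fold
        if unknown:
            logger.info(
                "profile %s: dropped %d genes absent from the gene list",
                profile.sample_id, unknown,
            )
        self.records.append((profile.sample_id, profile.series_id, vector))


def _format_fold(value: float) -> str:
    if math.isnan(value):
        return "NA"
    return format(value, ".4f")


def _check_token(token: str, what: str) -> str:
    if "\t" in token or "\n" in token:
        raise FormatError(f"{what} {token!r} contains a tab or newline")
    return token


def write_database(db: FoldDatabase, path) -> None:
    """Serialise ``db`` to ``path`` in the flat format above.

    Folds are rounded half-even to 4 decimals, so
    ``read -> write -> read`` is the identity up to that quantisation.
    """
    for gene in db.gene_list:
        _check_token(gene, "gene symbol")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(_header_line(db.platform_id, db.species,
                                  len(db.gene_list), len(db.records)))
        handle.write("GENES\t" + "\t".join(db.gene_list) + "\n")
        for sample_id, series_id, vector in db.records:
            _check_token(sample_id, "sample id")
            _check_token(series_id, "series id")
            handle.write(
                sample_id + "\t" + series_id + "\t"
                + "\t".join(_format_fold(v) for v in vector) + "\n"
            )


def _header_line(platform: str, species: str, n_genes: int, n_samples: int) -> str:
    return (
        f"{MAGIC}\t{FORMAT_VERSION}\tplatform={platform}\tspecies={species}"
        f"\tgenes={n_genes}\tsamples={n_samples}\n"
    )


def _parse_header(line: str, path) -> dict[str, str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 2 or parts[0] != MAGIC or parts[1] != FORMAT_VERSION:
        raise FormatError(f"{path}:1: not a version-{FORMAT_VERSION} fold database")
    fields: dict[str, str] = {}
    for token in parts[2:]:
        if "=" not in token:
            raise FormatError(f"{path}:1: malformed header token {token!r}")
        key, _, value = token.partition("=")
        fields[key] = value
    for required in ("platform", "species", "genes", "samples"):
        if required not in fields:
            raise FormatError(f"{path}:1: header missing {required!r}")
    return fields


def read_header(path) -> dict[str, str]:
    with open(path, "r", encoding="utf-8") as handle:
        return _parse_header(handle.readline(), path)


def read_gene_list(path) -> list[str]:
    with open(path, "r", encoding="utf-8") as handle:
        header = _parse_header(handle.readline(), path)
        genes = _parse_genes_line(handle.readline(), header, path)
    return genes


def _parse_genes_line(line: str, header: dict[str, str], path) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if not parts or parts[0] != "GENES":
        raise FormatError(f"{path}:2: expected GENES line")
    genes = parts[1:]
    if len(genes) != int(header["genes"]):
        raise FormatError(
            f"{path}:2: header declares {header['genes']} genes but "
            f"GENES line has {len(genes)}"
        )
    return genes


def stream_samples(path) -> Iterator[tuple[str, str, dict[str, float]]]:
    """Yield ``(sample_id, series_id, sparse fold map)`` records in file
    order, holding at most one record plus the gene list in memory."""
    with open(path, "r", encoding="utf-8") as handle:
        header = _parse_header(handle.readline(), path)
        genes = _parse_genes_line(handle.readline(), header, path)
        n_slots = len(genes)
        n_records = 0
        for lineno, line in enumerate(handle, 3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_slots + 2:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_slots + 2} fields, "
                    f"got {len(parts)}"
                )
            sample_id, series_id = parts[0], parts[1]
            folds: dict[str, float] = {}
            for gene, token in zip(genes, parts[2:]):
                if token == "NA":
                    continue
                try:
                    folds[gene] = float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: bad fold value {token!r}"
                    ) from None
            n_records += 1
            yield sample_id, series_id, folds
        declared = int(header["samples"])
        if n_records != declared:
            raise FormatError(
                f"{path}: header declares {declared} samples but file has "
                f"{n_records} records"
            )


def read_database(path) -> FoldDatabase:
    """Load a whole database into memory (convenience; searching should
    prefer :func:`stream_samples`)."""
    header = read_header(path)
    genes = read_gene_list(path)
    db = FoldDatabase(
        platform_id=header["platform"],
        species=header["species"],
        gene_list=genes,
    )
    positions = {g: i for i, g in enumerate(genes)}
    for sample_id, series_id, folds in stream_samples(path):
        vector = np.full(len(genes), np.nan)
        for gene, fold in folds.items():
            vector[positions[gene]] = fold
        db.records.append((sample_id, series_id, vector))
    return db


def append_series(
    path,
    profiles: Sequence[EFProfile],
    index: Optional[GeneIndex] = None,
) -> None:
    """Append collapsed profiles to an existing database file.

    Profiles must be gene-keyed on the same platform as the file header;
    genes outside the file's closed gene list are dropped with a log
    message.  The header's sample count is updated.  An empty profile
    list leaves the file unchanged.
    """
    if not profiles:
        return
    header = read_header(path)
    platform = header["platform"]
    if index is not None and index.platform_id and index.platform_id != platform:
        raise PlatformMismatchError(
            f"index platform {index.platform_id!r} != database platform "
            f"{platform!r}"
        )
    for profile in profiles:
        if profile.platform_id and profile.platform_id != platform:
            raise PlatformMismatchError(
                f"profile {profile.sample_id!r} platform "
                f"{profile.platform_id!r} != database platform {platform!r}"
            )
    genes = read_gene_list(path)
    positions = {g: i for i, g in enumerate(genes)}
    new_total = int(header["samples"]) + len(profiles)
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp_path = tempfile.mkstemp(dir=directory, suffix=".tmp", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as out:
            out.write(_header_line(platform, header["species"],
                                   len(genes), new_total))
            with open(path, "r", encoding="utf-8") as src:
                src.readline()  # old header
                for line in src:
                    out.write(line)
            for profile in profiles:
                vector = np.full(len(genes), np.nan)
                unknown = 0
                for gene, fold in profile.folds.items():
                    pos = positions.get(gene)
                    if pos is None:
                        unknown += 1
                    else:
                        vector[pos] = fold
                if unknown:
                    logger.info(
                        "append %s: dropped %d genes outside the gene list",
                        profile.sample_id, unknown,
                    )
                out.write(
                    _check_token(profile.sample_id, "sample id") + "\t"
                    + _check_token(profile.series_id, "series id") + "\t"
                    + "\t".join(_format_fold(v) for v in vector) + "\n"
                )
        os.replace(tmp_path, path)
    except BaseException:
        if os.path.exists(tmp_path):
            os.unlink(tmp_path)
        raise
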