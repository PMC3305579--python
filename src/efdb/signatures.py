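"""Sense-conserved binary signatures.

A robust cross-study signature keeps only the genes whose fold-change
direction is unanimous across every input profile, assigning +1 to
consistently up-regulated genes and -1 to consistently down-regulated
ones.  Strict unanimity: a gene missing from any profile, with a zero
fold anywhere, or with conflicting signs is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from efdb.errors import EfdbError


@dataclass
class BinarySignature:
    """Gene -> +/-1 signature with the names of its source profiles."""

    entries: dict[str, int]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.entries.items() if v not in (1, -1)}
        if bad:
            raise EfdbError(f"signature values must be +/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_up(self) -> int:
        return sum(1 for v in self.entries.values() if v == 1)

    @property
    def n_down(self) -> int:
        return sum(1 for v in self.entries.values() if v == -1)


def sense_conserved_signature(
    profiles: Sequence[Mapping[str, float]],
    names: Optional[Sequence[str]] = None,
) -> BinarySignature:
    """Build the unanimous-sign binary signature of several fold profiles.

    A gene is included iff it is present with a nonzero fold in every
    profile and all its folds share one sign; its value is that sign.
    """
    if len(profiles) < 2:
        raise EfdbError("need >= 2 profiles to define a conserved signature")
    common = set(profiles[0])
    for profile in profiles[1:]:
        common &= set(profile)
    entries: dict[str, int] = {}
    for gene in sorted(common):
        signs = set()
        for profile in profiles:
            fold = profile[gene]
            if fold > 0:
                signs.add(1)
            elif fold < 0:
                signs.add(-1)
            else:
                signs.add(0)
        if len(signs) == 1:
            sign = signs.pop()
            if sign != 0:
                entries[gene] = sign
    return BinarySignature(
        entries=entries,
        provenance=list(names) if names is not None else [],
    )


def read_fold_tsv(path) -> dict[str, float]:
    """Read a ``gene<TAB>fold`` TSV (extra columns ignored)."""
    folds: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "fold"]:
            raise EfdbError(
                f"{path}: expected header gene<TAB>fold, got {header[:2]}"
            )
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise EfdbError(f"{path}:{lineno}: expected 2 fields")
            try:
                folds[parts[0]] = float(parts[1])
            except ValueError:
                raise EfdbError(f"{path}:{lineno}: bad fold {parts[1]!r}") from None
    return folds


def read_signature_tsv(path) -> BinarySignature:
    entries: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "value"]:
            raise EfdbError(
                f"{path}: expected header gene<TAB>value, got {header[:2]}"
            )
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise EfdbError(f"{path}:{lineno}: expected 2 fields")
            token = parts[1].lstrip("+")
            try:
                entries[parts[0]] = int(token)
            except ValueError:
                raise EfdbError(
                    f"{path}:{lineno}: bad value {parts[1]!r}"
                ) from None
    return BinarySignature(entries=entries)


def write_signature_tsv(signature: BinarySignature, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("gene\tvalue\n")
        for gene in sorted(signature.entries):
            value = signature.entries[gene]
            handle.write(f"{gene}\t{'+1' if value > 0 else '-1'}\n")
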