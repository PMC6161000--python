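"""InChIKey handling and spectral-library merging.

A mass spectral library is represented by the set of InChIKeys of the
compounds it holds spectra for.  All downstream matching between libraries
and metabolic networks is done on the 14-character *first block* of the
InChIKey, which hashes molecular connectivity only: two stereoisomers, or
the acid and base form of the same compound, share a first block and are
indistinguishable in a typical MS experiment.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "StructureKey",
    "SpectralLibrary",
    "MergedLibrary",
    "InChIKeyError",
    "parse_key",
    "load_library",
    "merge_libraries",
    "write_merged_tsv",
    "library_summary",
]

# 14 connectivity chars, 10 stereo/charge/version chars, 1 protonation char.
_KEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class InChIKeyError(ValueError):
    """Raised for strings that do not match the InChIKey layout."""


@dataclass(frozen=True, order=True)
class StructureKey:
    """A full InChIKey plus its connectivity-only first block."""

    full_key: str
    first_block: str = field(init=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "first_block", self.full_key.split("-", 1)[0])


def parse_key(raw: str) -> StructureKey:
    """Validate ``raw`` as an InChIKey and return its :class:`StructureKey`.

    Case is normalized to upper before validation; lowercase keys found in
    real-world exports are treated as typos rather than distinct identifiers.

    Raises
    ------
    InChIKeyError
        If the string does not match the ``14-10-1`` uppercase-letter layout.
        The offending value is included in the message.
    """
    cleaned = raw.strip().upper()
    if not cleaned:
        raise InChIKeyError("empty string is not an InChIKey")
    if not _KEY_RE.match(cleaned):
        raise InChIKeyError(f"malformed InChIKey: {raw!r}")
    return StructureKey(cleaned)


@dataclass
class SpectralLibrary:
    """One spectral library as a de-duplicated set of structure keys."""

    name: str
    keys: frozenset[StructureKey]
    n_malformed: int = 0

    @property
    def n_full(self) -> int:
        """Number of non-redundant full InChIKeys."""
        return len(self.keys)

    @property
    def n_blocks(self) -> int:
        """Number of non-redundant first blocks (always ``<= n_full``)."""
        return len(self.blocks)

    @property
    def blocks(self) -> frozenset[str]:
        return frozenset(k.first_block for k in self.keys)


@dataclass
class MergedLibrary:
    """Union of several libraries, indexed by first block.

    ``provenance`` records, for every block, which source libraries
    contributed it; every block has at least one source.
    """

    blocks: frozenset[str]
    provenance: dict[str, frozenset[str]]

    def __contains__(self, first_block: str) -> bool:
        return first_block in self.blocks

    def __len__(self) -> int:
        return len(self.blocks)


def load_library(path: str | Path, name: str | None = None) -> SpectralLibrary:
    """Read a one-key-per-line text file into a :class:`SpectralLibrary`.

    Blank lines and ``#`` comment lines are ignored.  Duplicate keys are
    collapsed (set semantics).  Lines that fail InChIKey validation are
    counted in ``n_malformed`` and skipped — real library exports frequently
    contain header junk — but a file yielding *no* valid key is an error.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    keys: set[StructureKey] = set()
    n_malformed = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                keys.add(parse_key(line))
            except InChIKeyError:
                n_malformed += 1
    if not keys:
        raise InChIKeyError(
            f"library file {path} contains no valid InChIKey "
            f"({n_malformed} malformed line(s))"
        )
    return SpectralLibrary(name=name, keys=frozenset(keys), n_malformed=n_malformed)


def merge_libraries(libs: Iterable[SpectralLibrary]) -> MergedLibrary:
    """Union all libraries into one first-block index with provenance.

    The merge is order-invariant and idempotent; ``|blocks|`` is bounded by
    the sum of the per-library block counts.
    """
    libs = list(libs)
    if not libs:
        raise ValueError("merge_libraries requires at least one library")
    prov: dict[str, set[str]] = defaultdict(set)
    for lib in libs:
        for block in lib.blocks:
            prov[block].add(lib.name)
    frozen = {b: frozenset(s) for b, s in prov.items()}
    return MergedLibrary(blocks=frozenset(frozen), provenance=frozen)


def write_merged_tsv(merged: MergedLibrary, path: str | Path) -> None:
    """Write the merged index as TSV (first_block, n_sources, source_names)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("first_block\tn_sources\tsource_names\n")
        for block in sorted(merged.blocks):
            sources = sorted(merged.provenance[block])
            fh.write(f"{block}\t{len(sources)}\t{','.join(sources)}\n")


def library_summary(
    libs: Iterable[SpectralLibrary], merged: MergedLibrary
) -> Mapping[str, object]:
    """JSON-ready summary: per-library and merged non-redundant counts."""
    libs = list(libs)
    per_lib = {
        lib.name: {
            "n_full": lib.n_full,
            "n_blocks": lib.n_blocks,
            "n_malformed": lib.n_malformed,
        }
        for lib in libs
    }
    n_full_union = len({k for lib in libs for k in lib.keys})
    return {
        "libraries": per_lib,
        "merged": {"n_full": n_full_union, "n_blocks": len(merged)},
    }


def write_summary_json(summary: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True))
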