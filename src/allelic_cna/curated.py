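"""Curated per-cell-line mutation / copy-status annotations.

The packaged fixture transcribes the study's curated table of 49 urothelial
bladder cancer (UBC) cell lines: for each line and each major UBC gene
(FGFR3, PIK3CA, HRAS, KRAS, NRAS, TERT, INK4A, PTEN, TP53) the reported
point-mutation status and copy-number status, each tagged with its source.
Conflicting reports from different sources are preserved verbatim, never
resolved at load time; resolution policies are parameters of the counting
operations (:mod:`allelic_cna.instability`).

Source tags: ``1`` COSMIC, ``2`` CCLE, ``3`` IARC, ``4`` the study's own
assays, ``0`` a table entry whose source annotation is not legible; other
integers are literature references of the original table.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

GENES = ("FGFR3", "PIK3CA", "HRAS", "KRAS", "NRAS", "TERT", "INK4A", "PTEN", "TP53")

#: source tag for the study's own assay data
OWN_SOURCE = "4"

#: copy-number status vocabulary
CN_STATUSES = ("WT", "N", "LOH", "HD", "Amp")


@dataclass(frozen=True)
class StatusEntry:
    """One reported status with its sources, e.g. ('R248C', ('2',))."""
    status: str
    sources: tuple[str, ...]

    @property
    def is_own_data(self) -> bool:
        return OWN_SOURCE in self.sources

    @property
    def is_point_mutation(self) -> bool:
        """True for point/indel mutation reports; wild-type, copy-status and
        structural (fusion/amplification) entries are excluded."""
        s = self.status
        if s in ("WT",) or s in CN_STATUSES:
            return False
        if "fusion" in s.lower() or "Amp" in s:
            return False
        return True


class LineNotFound(KeyError):
    """Raised when a cell line name is absent from the curated table."""


class CuratedLineTable:
    """The curated cell-line table with per-gene multi-source entries."""

    def __init__(self, frame: pd.DataFrame):
        if frame["name"].duplicated().any():
            raise ValueError("duplicate cell line names in curated table")
        self._frame = frame.set_index("name", drop=False)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return list(self._frame.index)

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, name: str) -> bool:
        return name in self._frame.index

    def _cell(self, name: str, column: str) -> list[StatusEntry]:
        if name not in self._frame.index:
            raise LineNotFound(name)
        return parse_entries(self._frame.at[name, column])

    def mutation_status(self, name: str, gene: str) -> list[StatusEntry]:
        return self._cell(name, f"{gene}_mut")

    def cn_status(self, name: str, gene: str) -> list[StatusEntry]:
        return self._cell(name, f"{gene}_cn")

    def sex(self, name: str) -> str:
        if name not in self._frame.index:
            raise LineNotFound(name)
        v = self._frame.at[name, "sex"]
        return v if v in ("M", "F") else "unknown"

    def instability_group(self, name: str) -> str | None:
        if name not in self._frame.index:
            raise LineNotFound(name)
        v = self._frame.at[name, "instability_group"]
        return None if v == "." else v


def parse_entries(cell: str) -> list[StatusEntry]:
    """Parse a fixture cell like ``"WT:1,4;R248C:2"`` into entries."""
    if not isinstance(cell, str) or cell in (".", ""):
        return []
    out = []
    for part in cell.split(";"):
        status, _, src = part.partition(":")
        if not src:
            raise ValueError(f"fixture entry without source tag: {part!r}")
        out.append(StatusEntry(status, tuple(src.split(","))))
    return out


def resolve(entries: list[StatusEntry], policy: str) -> list[StatusEntry]:
    """Resolve multi-source entries under a counting policy.

    ``any_source`` keeps everything; ``own_data_precedence`` keeps only the
    study's own-assay entries when any exist, else all external entries.
    """
    if policy == "any_source":
        return list(entries)
    if policy == "own_data_precedence":
        own = [e for e in entries if e.is_own_data]
        return own if own else list(entries)
    raise ValueError(f"unknown policy: {policy!r}")


def load_table1_fixture() -> CuratedLineTable:
    """Load the packaged curated cell-line table (49 lines)."""
    path = resources.files("allelic_cna.data") / "ubc40_table1.tsv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, sep="\t", dtype=str).fillna(".")
    return CuratedLineTable(frame)
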