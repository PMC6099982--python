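"""The published atom-group parameter set and the validity rule.

The embedded table holds the 221 fitted entries (one ``Const`` entry, 218
atom groups and the three special groups) with their contributions in
dyn/cm, the number of occurrences over the 1893-compound training set and
the number of distinct training molecules containing each group.  A group
is *valid* for prediction only when at least three independent compounds
backed its parameterisation; invalid entries are retained for reference
but gate predictions.

``PUBLISHED_STATISTICS`` carries the training/cross-validation summary
block printed alongside the table.  Note that applying the >=3-molecules
rule to the embedded "molecules" column marks 170 entries valid whereas
the published summary states 165; both numbers are exposed and the
discrepancy is documented in the methods note.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

CONST = "Const"
MIN_MOLECULES_FOR_VALIDITY = 3

#: summary statistics printed with the published table (training set of
#: 1893 compounds; statistics over the 1833 compounds whose groups are all
#: valid; 10-fold cross-validation pooled over 1769 predictable compounds)
PUBLISHED_STATISTICS: dict[str, float] = {
    "n_valid_groups": 165,
    "n_training": 1893,
    "r_squared": 0.9039,
    "n_fit": 1833,
    "average_deviation": 1.53,
    "standard_deviation": 1.99,
    "k": 10,
    "q_squared": 0.8823,
    "average_deviation_cv": 1.66,
    "standard_deviation_cv": 2.16,
    "n_cv": 1769,
    "regression_intercept": 2.8653,
    "regression_slope": 0.9049,
}


@dataclass
class ParameterEntry:
    """One fitted group parameter."""

    signature: str  # canonical "atom type/neighbours", special name, or Const
    contribution: float  # dyn/cm
    occurrences: int
    molecule_count: int

    @property
    def valid(self) -> bool:
        if self.signature == CONST:
            return True
        return self.molecule_count >= MIN_MOLECULES_FOR_VALIDITY


class DimensionMismatchError(ValueError):
    """Count-matrix columns do not align with the parameter table."""


@dataclass
class ParameterTable:
    """A set of group contributions plus the constant term."""

    entries: list[ParameterEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        self._index: dict[str, ParameterEntry] = {}
        n_const = 0
        for e in self.entries:
            if e.signature == CONST:
                n_const += 1
            if e.signature in self._index:
                raise ValueError(f"duplicate parameter entry {e.signature!r}")
            self._index[e.signature] = e
        if n_const != 1:
            raise ValueError(f"expected exactly one Const entry, found {n_const}")

    # -- access ---------------------------------------------------------------

    @property
    def constant(self) -> float:
        return self._index[CONST].contribution

    def lookup(self, signature: str) -> Optional[ParameterEntry]:
        """Exact-text lookup of a canonical signature; None when absent."""
        return self._index.get(signature)

    def __contains__(self, signature: str) -> bool:
        return signature in self._index

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_valid(self) -> int:
        return sum(1 for e in self.entries if e.signature != CONST and e.valid)

    def signatures(self, include_const: bool = False) -> list[str]:
        return [
            e.signature
            for e in self.entries
            if include_const or e.signature != CONST
        ]

    # -- serialization --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.entries, start=1):
            if e.signature == CONST:
                atom_type, neighbours = CONST, ""
            elif "/" in e.signature:
                atom_type, neighbours = e.signature.split("/", 1)
            else:  # special groups carry no neighbour field
                atom_type, neighbours = e.signature, ""
            rows.append(
                {
                    "entry": i,
                    "atom_type": atom_type,
                    "neighbours": neighbours,
                    "contribution": e.contribution,
                    "occurrences": e.occurrences,
                    "molecules": e.molecule_count,
                    "valid": e.valid,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], provenance: str = "") -> "ParameterTable":
        return cls._from_rows(
            csv.DictReader(Path(path).open()), provenance or str(path)
        )

    @classmethod
    def _from_rows(cls, rows: Iterable[Mapping[str, str]], provenance: str) -> "ParameterTable":
        entries = []
        for row in rows:
            atom_type = row["atom_type"].strip()
            neighbours = (row.get("neighbours") or "").strip()
            if atom_type == CONST or not neighbours:
                signature = atom_type
            else:
                signature = f"{atom_type}/{neighbours}"
            entries.append(
                ParameterEntry(
                    signature=signature,
                    contribution=float(row["contribution"]),
                    occurrences=int(row["occurrences"] or 0),
                    molecule_count=int(row["molecules"] or 0),
                )
            )
        return cls(entries=entries, provenance=provenance)


_SPECIAL_SPELLINGS = {
    # the printed special-group rows describe their counting rule in the
    # neighbours column; the signature is the name alone
    "(COH)n": "(COH)n",
    "Alkane": "Alkane",
    "Unsaturated HC": "Unsaturated HC",
}

_published_cache: Optional[ParameterTable] = None


def load_published_table() -> ParameterTable:
    """The embedded published 221-entry parameter table (dyn/cm, 293.15 K)."""
    global _published_cache
    if _published_cache is None:
        with resources.files("grouptension.data").joinpath("table2.csv").open() as fh:
            rows = []
            for row in csv.DictReader(fh):
                if row["atom_type"] in _SPECIAL_SPELLINGS:
                    row = dict(row, neighbours="")
                rows.append(row)
            _published_cache = ParameterTable._from_rows(rows, "published")
    return _published_cache


def recompute_validity(
    table: ParameterTable, counts: pd.DataFrame
) -> ParameterTable:
    """Refresh occurrence/molecule counts (hence validity) from a dataset.

    ``counts`` is a group-count matrix: one row per molecule, one column per
    group signature.  Columns must be a subset of the table's entries (plus
    an optional Const column, ignored); a column the table does not know is
    a dimension mismatch.
    """
    unknown = [c for c in counts.columns if c != CONST and c not in table]
    if unknown:
        raise DimensionMismatchError(
            f"count matrix columns not in parameter table: {unknown}"
        )
    entries = []
    for e in table.entries:
        if e.signature == CONST:
            entries.append(
                replace(e, occurrences=len(counts), molecule_count=len(counts))
            )
        elif e.signature in counts.columns:
            col = counts[e.signature]
            entries.append(
                replace(
                    e,
                    occurrences=int(col.sum()),
                    molecule_count=int((col > 0).sum()),
                )
            )
        else:
            entries.append(replace(e, occurrences=0, molecule_count=0))
    return ParameterTable(entries=entries, provenance=table.provenance)
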