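"""Surface-tension prediction: evaluate the additivity sum for a molecule.

The predicted surface tension of a compound record is the sum over its
atom groups of (count x contribution), plus the special-group terms, plus
one constant per record — also for two-component ionic-liquid records.
Groups that are unknown to the parameter table, or known but backed by
fewer than three training compounds, make the prediction invalid; in
strict mode they raise :class:`CoverageError` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chem import Dataset, Molecule
from .params import ParameterTable, load_published_table
from .perception import GroupCountVector, decompose


class CoverageError(ValueError):
    """The molecule contains groups the parameter table cannot cover."""

    def __init__(self, identifier: str, unknown: list[str], invalid: list[str]):
        self.unknown_groups = unknown
        self.invalid_groups = invalid
        parts = []
        if unknown:
            parts.append(f"unknown group(s): {', '.join(unknown)}")
        if invalid:
            parts.append(
                "group(s) below the 3-compound validity threshold: "
                + ", ".join(invalid)
            )
        super().__init__(f"cannot predict {identifier!r}: " + "; ".join(parts))


@dataclass
class PredictionResult:
    """Itemised additivity sum for one compound record."""

    identifier: str
    st_predicted: float  # dyn/cm at 293.15 K
    terms: list[tuple[str, int, float, float]]  # (signature, count, a_i, product)
    constant: float
    invalid_groups: list[str] = field(default_factory=list)
    unknown_groups: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.invalid_groups and not self.unknown_groups


def predict(
    vector: GroupCountVector,
    table: Optional[ParameterTable] = None,
    strict: bool = False,
    identifier: str = "",
) -> PredictionResult:
    """Evaluate the additivity equation for one group-count vector."""
    if table is None:
        table = load_published_table()
    terms: list[tuple[str, int, float, float]] = []
    invalid: list[str] = []
    unknown: list[str] = []
    total = 0.0
    for signature, count in {
        **vector.atom_group_counts,
        **vector.special_group_counts,
    }.items():
        entry = table.lookup(signature)
        if entry is None:
            unknown.append(signature)
            continue
        if not entry.valid:
            invalid.append(signature)
        product = count * entry.contribution
        terms.append((signature, count, entry.contribution, product))
        total += product
    total += table.constant
    if strict and (unknown or invalid):
        raise CoverageError(identifier, sorted(unknown), sorted(invalid))
    return PredictionResult(
        identifier=identifier,
        st_predicted=total,
        terms=terms,
        constant=table.constant,
        invalid_groups=sorted(invalid),
        unknown_groups=sorted(unknown),
    )


def predict_molecule(
    molecule: Molecule,
    table: Optional[ParameterTable] = None,
    strict: bool = False,
) -> PredictionResult:
    """Decompose and predict in one step."""
    if table is None:
        table = load_published_table()
    vector = decompose(molecule, table)
    return predict(vector, table, strict=strict, identifier=molecule.identifier)


@dataclass
class BatchSummary:
    n_predicted: int
    n_skipped: int


def predict_batch(
    dataset: Dataset | Sequence[Molecule] | Iterable[Molecule],
    table: Optional[ParameterTable] = None,
    strict: bool = False,
) -> tuple[list[Optional[PredictionResult]], BatchSummary]:
    """Order-preserving batch prediction.

    In strict mode, records whose groups are not covered yield ``None`` in
    the result list (with the skip counted) instead of aborting the batch.
    """
    if table is None:
        table = load_published_table()
    molecules = dataset.molecules if isinstance(dataset, Dataset) else list(dataset)
    results: list[Optional[PredictionResult]] = []
    n_ok = n_skip = 0
    for mol in molecules:
        try:
            res = predict_molecule(mol, table, strict=strict)
        except CoverageError:
            results.append(None)
            n_skip += 1
            continue
        results.append(res)
        n_ok += 1
    return results, BatchSummary(n_predicted=n_ok, n_skipped=n_skip)
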