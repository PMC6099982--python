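"""Synthetic datasets and curated fixture molecules.

Two kinds of test substrate live here:

* :func:`generate_synthetic` draws group-count matrices with known linear
  coefficients and Gaussian observation noise — a stand-in for a training
  set at the level the linear model actually sees (counts, not structures).
  Every group is guaranteed to occur in at least three molecules so the
  validity rule never bites by construction.
* :func:`load_fixtures` returns the curated molecules (ordinary organics
  and ionic-liquid pairs) whose group decompositions were derived by hand
  from the group definitions; they are the perception oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .params import CONST
from .perception import GroupCountVector


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic group-count dataset.

    Defaults mirror the scale of the real parameterisation problem scaled
    down: 30 groups over 300 molecules, counts up to 4 per group, and a
    noise standard deviation of 2.0 dyn/cm matching the magnitude of the
    published training-set residual spread.
    """

    n_groups: int = 30
    n_molecules: int = 300
    max_count: int = 4
    noise_sd: float = 2.0
    constant: float = 24.0
    coefficient_range: tuple[float, float] = (-5.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < self.n_groups + 1:
            raise ValueError(
                "need n_molecules >= n_groups + 1 for identifiability"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame  # n_molecules x n_groups (no Const column)
    response: np.ndarray  # dyn/cm, with noise
    true_coefficients: pd.Series  # per group, plus "Const"
    noise_sd: float

    @property
    def noiseless_response(self) -> np.ndarray:
        coef = self.true_coefficients
        return (
            self.counts.to_numpy() @ coef.drop(CONST).to_numpy()
            + coef[CONST]
        )


def generate_synthetic(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a reproducible synthetic dataset from a spec.

    Counts are uniform integers in ``[0, max_count]``; the response is
    ``counts @ coefficients + constant + N(0, noise_sd)``.  The count
    matrix is redrawn (bounded retries) until every group occurs in at
    least three molecules.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"G{i + 1:03d}" for i in range(spec.n_groups)]
    counts = None
    for _ in range(100):
        draw = rng.integers(0, spec.max_count + 1, size=(spec.n_molecules, spec.n_groups))
        if ((draw > 0).sum(axis=0) >= 3).all():
            counts = draw
            break
    if counts is None:
        raise ValueError(
            f"cannot satisfy the 3-molecule rule for spec {spec} "
            "after 100 redraws"
        )
    lo, hi = spec.coefficient_range
    coef = rng.uniform(lo, hi, size=spec.n_groups)
    y = counts @ coef + spec.constant
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_molecules)
    return SyntheticDataset(
        counts=pd.DataFrame(counts, columns=names, dtype=float),
        response=y.astype(float),
        true_coefficients=pd.Series(
            np.append(coef, spec.constant), index=names + [CONST]
        ),
        noise_sd=spec.noise_sd,
    )


# -- curated fixture molecules -------------------------------------------------


@dataclass
class FixtureMolecule:
    """A molecule with its hand-derived group decomposition."""

    identifier: str
    smiles: str
    expected_vector: GroupCountVector
    expected_st: Optional[float] = None  # predicted value, dyn/cm
    experimental_st: Optional[float] = None  # literature value, dyn/cm
    tags: list[str] = field(default_factory=list)


_fixture_cache: Optional[list[FixtureMolecule]] = None


def load_fixtures() -> list[FixtureMolecule]:
    """The curated fixture set with hand-derived decompositions."""
    global _fixture_cache
    if _fixture_cache is None:
        raw = json.loads(
            resources.files("grouptension.data")
            .joinpath("fixtures.json")
            .read_text()
        )
        _fixture_cache = [
            FixtureMolecule(
                identifier=r["id"],
                smiles=r["smiles"],
                expected_vector=GroupCountVector(
                    atom_group_counts=dict(r["atom_groups"]),
                    special_group_counts=dict(r.get("special_groups", {})),
                ),
                expected_st=r.get("st_pred"),
                experimental_st=r.get("st_exp"),
                tags=list(r.get("tags", [])),
            )
            for r in raw
        ]
    return _fixture_cache
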