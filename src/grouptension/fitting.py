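"""Parameter fitting and cross-validation for the additivity model.

The group contributions solve an ordinary least-squares problem: the
design matrix holds one row per training compound and one column per group
signature present in the training set plus an all-ones ``Const`` column;
the response is the observed surface tension in dyn/cm.  The normal
equations are solved by Gauss-Seidel iteration (one coefficient updated at
a time until the largest coefficient change drops below a tolerance); a
dense direct solve is used only as an independent oracle in the tests.

Goodness of fit follows the conventions of the original parameterisation:
R-squared is the squared Pearson correlation of predicted versus
experimental values, the average deviation is the mean absolute residual,
and the standard deviation uses an N-1 denominator.  Statistics are
computed over the compounds whose groups are all valid (backed by at least
three training compounds); k-fold cross-validation refits on each training
split, re-derives validity from that split alone, and pools the held-out
predictions for Q-squared and S.

The statsmodels-style front door is :class:`GroupContributionModel` /
:class:`GroupContributionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Dataset, Molecule
from .params import (
    CONST,
    MIN_MOLECULES_FOR_VALIDITY,
    ParameterEntry,
    ParameterTable,
)
from .perception import decompose

__all__ = [
    "DesignMatrix",
    "FitStatistics",
    "CVResult",
    "build_design_matrix",
    "gauss_seidel_normal_equations",
    "fit_gauss_seidel",
    "compute_statistics",
    "cross_validate",
    "GroupContributionModel",
    "GroupContributionResults",
    "SingularityError",
    "ConvergenceError",
    "StatisticsError",
]


class SingularityError(np.linalg.LinAlgError):
    """The least-squares system is rank deficient (underdetermined)."""


class ConvergenceError(RuntimeError):
    """Gauss-Seidel failed to converge within the iteration budget."""

    def __init__(self, iterations: int, last_delta: float, tol: float):
        self.iterations = iterations
        self.last_delta = last_delta
        self.tol = tol
        super().__init__(
            f"Gauss-Seidel did not converge in {iterations} iterations "
            f"(last max coefficient change {last_delta:.3e}, tol {tol:.1e})"
        )


class StatisticsError(ValueError):
    """Too few paired values for N-1 statistics."""


# -- design matrix -------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Count matrix + response for fitting.

    ``counts`` has one row per compound and one column per group signature,
    with a trailing all-ones ``Const`` column; ``response`` is the observed
    surface tension (dyn/cm).  ``identifiers`` preserves record order.
    """

    counts: pd.DataFrame
    response: np.ndarray
    identifiers: list[str]
    n_dropped: int = 0

    @property
    def n_molecules(self) -> int:
        return len(self.counts)

    @property
    def columns(self) -> list[str]:
        return list(self.counts.columns)


def _sorted_columns(signatures: set[str]) -> list[str]:
    """Canonical, reproducible column order: atom groups, specials, Const."""
    from .perception import SPECIAL_GROUPS

    atom_groups = sorted(s for s in signatures if s not in SPECIAL_GROUPS)
    specials = [s for s in SPECIAL_GROUPS if s in signatures]
    return atom_groups + specials + [CONST]


def build_design_matrix(
    dataset: Dataset | Sequence[tuple[Molecule, Optional[float]]],
) -> DesignMatrix:
    """Decompose every observed compound into a row of group counts.

    Records without an observed value are dropped (counted in
    ``n_dropped``).  Unknown signatures become columns like any other:
    fitting is what creates new parameters.
    """
    if isinstance(dataset, Dataset):
        pairs = [(r.molecule, r.st_exp) for r in dataset.records]
    else:
        pairs = list(dataset)
    rows: list[dict[str, int]] = []
    response: list[float] = []
    identifiers: list[str] = []
    n_dropped = 0
    empty_table = _EMPTY_TABLE
    for mol, st in pairs:
        if st is None or (isinstance(st, float) and np.isnan(st)):
            n_dropped += 1
            continue
        vec = decompose(mol, empty_table)
        rows.append(vec.all_counts())
        response.append(float(st))
        identifiers.append(mol.identifier)
    if not rows:
        raise ValueError("empty dataset: no compounds with observed values")
    signatures = set().union(*rows)
    columns = _sorted_columns(signatures)
    counts = pd.DataFrame(0, index=range(len(rows)), columns=columns, dtype=float)
    for i, row in enumerate(rows):
        for sig, count in row.items():
            counts.at[i, sig] = count
    counts[CONST] = 1.0
    return DesignMatrix(
        counts=counts,
        response=np.asarray(response, dtype=float),
        identifiers=identifiers,
        n_dropped=n_dropped,
    )


#: table with only a Const entry: marks every atom group "unknown", which
#: is what design-matrix construction wants (new parameters are fit, not
#: looked up)
_EMPTY_TABLE = ParameterTable(
    entries=[ParameterEntry(CONST, 0.0, 0, 0)], provenance="empty"
)


# -- solver --------------------------------------------------------------------


def gauss_seidel_normal_equations(
    a: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    x0: Optional[np.ndarray] = None,
    check_rank: bool = True,
) -> tuple[np.ndarray, int]:
    """Least squares via Gauss-Seidel iteration on AtA x = At y.

    The normal-equation matrix of a full-column-rank design is symmetric
    positive definite, for which Gauss-Seidel is guaranteed to converge.
    Returns the coefficient vector and the number of sweeps used.

    With ``check_rank=False`` a rank-deficient design is tolerated: the
    sweep is coordinate descent on the least-squares objective, which still
    converges on the (always consistent) normal equations and returns one
    of the minimisers — the behaviour cross-validation relies on when a
    training split loses the compounds that made a group identifiable.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = a.shape
    if check_rank and np.linalg.matrix_rank(a) < p:
        raise SingularityError(
            f"design matrix is rank deficient ({n} rows, {p} columns, "
            f"rank {np.linalg.matrix_rank(a)})"
        )
    m = a.T @ a
    b = a.T @ y
    diag = np.diag(m)
    if np.any(diag == 0):
        raise SingularityError("zero diagonal in normal equations")
    x = np.zeros(p) if x0 is None else np.array(x0, dtype=float)
    delta = np.inf
    for sweep in range(1, max_iter + 1):
        delta = 0.0
        for i in range(p):
            new = (b[i] - m[i] @ x + m[i, i] * x[i]) / diag[i]
            delta = max(delta, abs(new - x[i]))
            x[i] = new
        if delta < tol:
            return x, sweep
    raise ConvergenceError(max_iter, delta, tol)


def fit_gauss_seidel(
    matrix: DesignMatrix, tol: float = 1e-6, max_iter: int = 10_000
) -> ParameterTable:
    """Fit group contributions and package them as a parameter table.

    Occurrence and molecule counts (hence validity flags) are recomputed
    from the design matrix itself.
    """
    coef, _ = gauss_seidel_normal_equations(
        matrix.counts.to_numpy(), matrix.response, tol=tol, max_iter=max_iter
    )
    entries = []
    for sig, c in zip(matrix.columns, coef):
        col = matrix.counts[sig]
        if sig == CONST:
            occ = mols = matrix.n_molecules
        else:
            occ = int(col.sum())
            mols = int((col > 0).sum())
        entries.append(
            ParameterEntry(
                signature=sig, contribution=float(c), occurrences=occ,
                molecule_count=mols,
            )
        )
    return ParameterTable(entries=entries, provenance="fitted")


# -- statistics ----------------------------------------------------------------


@dataclass
class FitStatistics:
    """Goodness-of-fit summary (all deviations in dyn/cm)."""

    n_used: int
    n_excluded: int
    r_squared: float  # squared Pearson correlation, predicted vs experimental
    r_squared_determination: float  # 1 - SSres/SStot, reported alongside
    average_deviation: float  # mean |x - x_hat|
    standard_deviation: float  # sqrt(sum (x - x_hat)^2 / (N - 1))
    regression_slope: float  # predicted regressed on experimental
    regression_intercept: float


def compute_statistics(
    predictions: Sequence[float],
    observations: Sequence[float],
    exclude: Optional[Sequence[bool]] = None,
) -> FitStatistics:
    """Deviation and correlation statistics for paired predictions.

    ``exclude`` marks compounds to leave out (those containing invalid or
    unknown groups); at least two pairs must remain since the standard
    deviation uses an N-1 denominator.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations differ in length")
    n_total = pred.size
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        pred, obs = pred[keep], obs[keep]
    n = pred.size
    if n < 2:
        raise StatisticsError(
            f"need at least 2 paired values for N-1 statistics, got {n}"
        )
    resid = obs - pred
    avg_dev = float(np.mean(np.abs(resid)))
    sd = float(np.sqrt(np.sum(resid**2) / (n - 1)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r2 = 1.0 if np.allclose(pred, obs) else 0.0
        slope, intercept = 0.0, float(np.mean(pred))
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
        r2 = r * r
        slope, intercept = (float(v) for v in np.polyfit(obs, pred, 1))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2_det = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return FitStatistics(
        n_used=n,
        n_excluded=n_total - n,
        r_squared=r2,
        r_squared_determination=r2_det,
        average_deviation=avg_dev,
        standard_deviation=sd,
        regression_slope=slope,
        regression_intercept=intercept,
    )


# -- model / results (statsmodels-style front door) ---------------------------


class GroupContributionModel:
    """Linear group-additivity model of surface tension.

    Built either from decomposed molecules (:meth:`from_dataset`,
    :meth:`from_dataframe`) or directly from a group-count matrix
    (synthetic studies).  ``fit`` solves for the contributions and returns
    a :class:`GroupContributionResults`.
    """

    def __init__(self, design: DesignMatrix):
        self.design = design

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "GroupContributionModel":
        return cls(build_design_matrix(dataset))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroupContributionModel":
        """From a frame with ``id``, ``smiles`` and ``st_exp`` columns."""
        from .chem import read_smiles

        pairs = [
            (read_smiles(str(r["smiles"]), str(r["id"])), float(r["st_exp"]))
            for _, r in df.iterrows()
        ]
        return cls(build_design_matrix(pairs))

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        response: Sequence[float],
        identifiers: Optional[Sequence[str]] = None,
    ) -> "GroupContributionModel":
        """From a ready-made group-count matrix (no Const column needed)."""
        counts = counts.copy().astype(float)
        if CONST not in counts.columns:
            counts[CONST] = 1.0
        ids = list(identifiers) if identifiers is not None else [
            str(i) for i in range(len(counts))
        ]
        return cls(DesignMatrix(counts, np.asarray(response, float), ids))

    def fit(
        self, tol: float = 1e-6, max_iter: int = 10_000
    ) -> "GroupContributionResults":
        table = fit_gauss_seidel(self.design, tol=tol, max_iter=max_iter)
        return GroupContributionResults(self, table)


class GroupContributionResults:
    """Fitted contributions plus diagnostics for a training set."""

    def __init__(self, model: GroupContributionModel, table: ParameterTable):
        self.model = model
        self.table = table
        design = model.design
        coef = np.array(
            [table.lookup(c).contribution for c in design.columns]
        )
        self.params = pd.Series(coef, index=design.columns)
        self.fittedvalues = design.counts.to_numpy() @ coef
        self.resid = design.response - self.fittedvalues
        self._exclude = self._invalid_mask()

    def _invalid_mask(self) -> np.ndarray:
        """Compounds containing any group below the validity threshold."""
        design = self.model.design
        invalid_cols = [
            c
            for c in design.columns
            if c != CONST and not self.table.lookup(c).valid
        ]
        if not invalid_cols:
            return np.zeros(design.n_molecules, dtype=bool)
        return (design.counts[invalid_cols].to_numpy() > 0).any(axis=1)

    @property
    def statistics(self) -> FitStatistics:
        """Training statistics over compounds whose groups are all valid."""
        return compute_statistics(
            self.fittedvalues, self.model.design.response, exclude=self._exclude
        )

    def cross_validate(self, k: int = 10, seed: int = 0) -> "CVResult":
        return cross_validate(self.model.design, k=k, seed=seed)

    def summary(self) -> str:
        stats = self.statistics
        design = self.model.design
        lines = [
            "Group-additivity surface-tension fit (dyn/cm, 293.15 K)",
            "=" * 58,
            f"compounds: {design.n_molecules}   parameters: {len(design.columns)}"
            f"   valid groups: {self.table.n_valid}",
            f"statistics over {stats.n_used} compounds "
            f"({stats.n_excluded} with invalid groups excluded)",
            f"R^2 (Pearson^2)     {stats.r_squared:10.4f}",
            f"R^2 (determination) {stats.r_squared_determination:10.4f}",
            f"average deviation   {stats.average_deviation:10.2f}",
            f"standard deviation  {stats.standard_deviation:10.2f}",
            f"pred = {stats.regression_slope:.4f} * exp "
            f"+ {stats.regression_intercept:.4f}",
            "-" * 58,
            f"{'group':<28}{'contrib':>10}{'occurr':>8}{'mols':>6}{'valid':>6}",
        ]
        for e in self.table.entries:
            lines.append(
                f"{e.signature:<28}{e.contribution:>10.2f}"
                f"{e.occurrences:>8d}{e.molecule_count:>6d}"
                f"{'yes' if e.valid else 'NO':>6}"
            )
        return "\n".join(lines)


# -- cross-validation ----------------------------------------------------------


@dataclass
class CVResult:
    """Pooled k-fold cross-validation outcome."""

    k: int
    seed: int
    fold_assignments: dict[str, int]  # identifier -> fold
    q_squared: float  # pooled squared Pearson correlation on held-out data
    s: float  # pooled N-1 standard deviation of held-out residuals, dyn/cm
    average_deviation: float
    n_test_used: int
    n_test_skipped: int  # held-out compounds with unknown/invalid groups
    per_fold_stats: list[FitStatistics] = field(default_factory=list)


def cross_validate(
    design: DesignMatrix,
    k: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> CVResult:
    """Seeded k-fold cross-validation of the additivity fit.

    Each compound is held out exactly once.  For every fold, the model is
    refit on the remaining folds only, validity is re-derived from that
    training split, and held-out compounds containing groups that are
    absent from — or invalid in — the split are skipped.  Q-squared and S
    are computed over the pooled held-out predictions.
    """
    n = design.n_molecules
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(folds):
        assignment[idx] = f

    pooled_pred: list[float] = []
    pooled_obs: list[float] = []
    per_fold: list[FitStatistics] = []
    n_skipped = 0
    full = design.counts
    y = design.response
    for f, test_idx in enumerate(folds):
        train_mask = assignment != f
        train = full.loc[train_mask]
        # drop all-zero columns: those groups do not exist in this split
        present = [
            c for c in train.columns if c == CONST or (train[c] > 0).any()
        ]
        train = train[present]
        coef, _ = gauss_seidel_normal_equations(
            train.to_numpy(), y[train_mask], tol=tol, max_iter=max_iter,
            check_rank=False,
        )
        mols_per_group = {
            c: int((train[c] > 0).sum()) for c in present if c != CONST
        }
        valid = {
            c for c, m in mols_per_group.items()
            if m >= MIN_MOLECULES_FOR_VALIDITY
        }
        coef_s = pd.Series(coef, index=present)
        fold_pred: list[float] = []
        fold_obs: list[float] = []
        for i in test_idx:
            row = full.iloc[i]
            used = [c for c in full.columns if c != CONST and row[c] > 0]
            if any(c not in present or c not in valid for c in used):
                n_skipped += 1
                continue
            pred = float(sum(row[c] * coef_s[c] for c in used) + coef_s[CONST])
            fold_pred.append(pred)
            fold_obs.append(y[i])
        pooled_pred.extend(fold_pred)
        pooled_obs.extend(fold_obs)
        if len(fold_pred) >= 2:
            per_fold.append(compute_statistics(fold_pred, fold_obs))

    if len(pooled_pred) < 2:
        raise StatisticsError(
            "fewer than 2 predictable held-out compounds across all folds"
        )
    pooled = compute_statistics(pooled_pred, pooled_obs)
    return CVResult(
        k=k,
        seed=seed,
        fold_assignments={
            design.identifiers[i]: int(assignment[i]) for i in range(n)
        },
        q_squared=pooled.r_squared,
        s=pooled.standard_deviation,
        average_deviation=pooled.average_deviation,
        n_test_used=len(pooled_pred),
        n_test_skipped=n_skipped,
        per_fold_stats=per_fold,
    )
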