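"""Recovery of per-residue descriptor tables from sequence-level values.

Both aggregation rules are linear in the residue composition of a
sequence: a SUM descriptor satisfies  C v = s  and a MEAN descriptor
satisfies  C v = s * N, where C is the (sequences x residues) count
matrix, v the unknown per-residue values, s the sequence-level values
and N the per-sequence denominator. Minimum-norm least squares therefore
recovers the per-residue table whenever the composition matrix has full
column rank; rank deficiency is reported, not fatal.

Recovered values are calibration constants for the scoring model, not
chemically interpretable quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import (
    DESCRIPTORS,
    DISTINCT,
    INTEGER_DESCRIPTORS,
    LENGTH,
    MEAN,
    RULES,
    SUM,
    ResidueParamTable,
    sequence_denominator,
)


@dataclass(frozen=True)
class CompositionMatrix:
    """Residue-occurrence counts, one row per sequence."""

    matrix: np.ndarray          # shape (n_sequences, n_residues)
    residues: tuple[str, ...]   # column order
    row_labels: tuple[str, ...]


@dataclass(frozen=True)
class InferenceResult:
    table: ResidueParamTable
    residuals: np.ndarray        # per-sequence, from the returned table
    max_abs_residual: float
    rank: int
    n_observed_residues: int
    denominator_mode_selected: str | None  # set for MEAN descriptors only


def build_design_matrix(sequences: list[str]) -> CompositionMatrix:
    """Count residue occurrences per sequence; columns are the observed letters."""
    if not sequences:
        raise ValueError("no sequences given")
    residues = tuple(sorted(set("".join(sequences))))
    index = {ch: j for j, ch in enumerate(residues)}
    mat = np.zeros((len(sequences), len(residues)), dtype=float)
    for i, seq in enumerate(sequences):
        for ch in seq:
            mat[i, index[ch]] += 1
    return CompositionMatrix(matrix=mat, residues=residues, row_labels=tuple(sequences))


def _solve(mat: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, int]:
    sol, _, rank, _ = np.linalg.lstsq(mat, target, rcond=None)
    return sol, int(rank)


def infer_sum_table(
    sequences: list[str], sp_values, descriptor: str
) -> InferenceResult:
    """Fit per-residue values of a SUM descriptor by minimum-norm least squares.

    For the integer-count descriptors (AM, AC, ROT, NON) the solution is
    rounded to the nearest integer and residuals are reported for the
    rounded table, so exact recovery shows up as zero residuals.
    """
    if RULES.get(descriptor, SUM) != SUM:
        raise ValueError(f"{descriptor} is not a SUM descriptor")
    design = build_design_matrix(sequences)
    target = np.asarray(sp_values, dtype=float)
    sol, rank = _solve(design.matrix, target)
    if descriptor in INTEGER_DESCRIPTORS:
        sol = np.round(sol)
    residuals = design.matrix @ sol - target
    table = ResidueParamTable(
        descriptor=descriptor, rule=SUM,
        values={ch: float(v) for ch, v in zip(design.residues, sol)},
    )
    return InferenceResult(
        table=table, residuals=residuals,
        max_abs_residual=float(np.abs(residuals).max()),
        rank=rank, n_observed_residues=len(design.residues),
        denominator_mode_selected=None,
    )


def infer_mean_table(
    sequences: list[str], sp_values, descriptor: str
) -> InferenceResult:
    """Fit a MEAN descriptor under both denominator hypotheses and keep the
    better one.

    The linear system is  C v = s * N  with N the distinct-residue count
    (DISTINCT) or the sequence length (LENGTH); the hypothesis with the
    smaller residual norm (on the mean scale) is selected and recorded.
    """
    if RULES.get(descriptor, MEAN) != MEAN:
        raise ValueError(f"{descriptor} is not a MEAN descriptor")
    design = build_design_matrix(sequences)
    target = np.asarray(sp_values, dtype=float)
    best = None
    for mode in (DISTINCT, LENGTH):
        denom = np.array(
            [sequence_denominator(s, mode) for s in sequences], dtype=float
        )
        sol, rank = _solve(design.matrix, target * denom)
        residuals = (design.matrix @ sol) / denom - target
        norm = float(np.linalg.norm(residuals))
        if best is None or norm < best[0]:
            best = (norm, mode, sol, residuals, rank)
    _, mode, sol, residuals, rank = best
    table = ResidueParamTable(
        descriptor=descriptor, rule=MEAN,
        values={ch: float(v) for ch, v in zip(design.residues, sol)},
    )
    return InferenceResult(
        table=table, residuals=residuals,
        max_abs_residual=float(np.abs(residuals).max()),
        rank=rank, n_observed_residues=len(design.residues),
        denominator_mode_selected=mode,
    )


def infer_all_tables(records) -> dict[str, InferenceResult]:
    """Fit all eight descriptor tables from a list of reference records."""
    sequences = [r.sequence for r in records]
    out: dict[str, InferenceResult] = {}
    for desc in DESCRIPTORS:
        values = [r.descriptor_values()[desc] for r in records]
        if RULES[desc] == SUM:
            out[desc] = infer_sum_table(sequences, values, desc)
        else:
            out[desc] = infer_mean_table(sequences, values, desc)
    return out
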