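"""Constrained least-squares fitting of atomic point charges to grid potentials.

The fit minimizes the squared misfit between the Coulomb potential of the
candidate charges and the target potential over a grid, optionally plus a
harmonic restraint toward zero, subject to hard linear equality constraints:
total charge, per-group sums (e.g. group neutrality) and equal-charge
equivalence sets.  Constraints are enforced exactly through the KKT system
rather than by penalty weights.

Units are e and Å with a dimensionless Coulomb constant (k = 1), so
potentials are in e/Å; the fit itself is invariant to any consistent unit
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hemelink.errors import (
    IllPosedFitError,
    InfeasibleConstraintsError,
    SingularityError,
    ValidationError,
)

MIN_ATOM_GRID_SEPARATION = 1e-6  # Å


@dataclass
class ESPFitProblem:
    """Data and constraints for one charge fit.

    ``neutral_groups`` is a list of (atom-index tuple, target total charge);
    ``equivalence_sets`` lists index tuples constrained to a common charge.
    """

    atom_positions: np.ndarray  # (N, 3) Å
    grid_points: np.ndarray  # (M, 3) Å
    grid_esp: np.ndarray  # (M,) potential values
    total_charge: float = 0.0
    neutral_groups: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    equivalence_sets: list[tuple[int, ...]] = field(default_factory=list)
    restraint_weight: float = 0.0

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        self.grid_points = np.asarray(self.grid_points, dtype=float)
        self.grid_esp = np.asarray(self.grid_esp, dtype=float)
        n = self.n_atoms
        if self.atom_positions.ndim != 2 or self.atom_positions.shape[1] != 3:
            raise ValidationError("atom_positions must be (N, 3)")
        if self.grid_points.ndim != 2 or self.grid_points.shape[1] != 3:
            raise ValidationError("grid_points must be (M, 3)")
        if len(self.grid_esp) != len(self.grid_points):
            raise ValidationError("grid_esp length must match grid_points")
        if self.restraint_weight < 0:
            raise ValidationError("restraint_weight must be >= 0")
        self.neutral_groups = [
            (tuple(int(i) for i in idx), float(target))
            for idx, target in self.neutral_groups
        ]
        self.equivalence_sets = [
            tuple(int(i) for i in idx) for idx in self.equivalence_sets
        ]
        for idx, _ in self.neutral_groups:
            if any(i < 0 or i >= n for i in idx):
                raise ValidationError(f"group indices {idx} out of range")
        for idx in self.equivalence_sets:
            if any(i < 0 or i >= n for i in idx):
                raise ValidationError(f"equivalence indices {idx} out of range")
            if len(idx) < 2:
                raise ValidationError("equivalence sets need >= 2 atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_positions)

    def constraint_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack all equality constraints as C q = d."""
        n = self.n_atoms
        rows = [np.ones(n)]
        rhs = [self.total_charge]
        for idx, target in self.neutral_groups:
            row = np.zeros(n)
            row[list(idx)] = 1.0
            rows.append(row)
            rhs.append(target)
        for idx in self.equivalence_sets:
            first = idx[0]
            for other in idx[1:]:
                row = np.zeros(n)
                row[first] = 1.0
                row[other] = -1.0
                rows.append(row)
                rhs.append(0.0)
        return np.array(rows), np.array(rhs)


@dataclass
class ChargeSet:
    charges: np.ndarray  # (N,) e
    residual_rms: float
    constraint_violation_max: float

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)


def predict_esp(
    positions: np.ndarray, charges: np.ndarray, grid_points: np.ndarray
) -> np.ndarray:
    """Coulomb potential V(r) = sum_i q_i / |r - r_i| with k = 1."""
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    grid_points = np.asarray(grid_points, dtype=float)
    inv_r = _inverse_distances(positions, grid_points)
    return inv_r @ charges


def _inverse_distances(positions: np.ndarray, grid_points: np.ndarray) -> np.ndarray:
    diff = grid_points[:, None, :] - positions[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < MIN_ATOM_GRID_SEPARATION):
        m, i = np.unravel_index(int(np.argmin(r)), r.shape)
        raise SingularityError(
            f"grid point {m} within {MIN_ATOM_GRID_SEPARATION} Å of atom {i}"
        )
    return 1.0 / r


def fit_charges(problem: ESPFitProblem) -> ChargeSet:
    """Solve the linearly-constrained linear least-squares charge fit.

    The KKT system of the quadratic objective is solved exactly; inconsistent
    constraints raise :class:`InfeasibleConstraintsError` and a rank-deficient
    reduced problem raises :class:`IllPosedFitError` naming a null direction.
    """
    A = _inverse_distances(problem.atom_positions, problem.grid_points)
    v = problem.grid_esp
    n = problem.n_atoms
    C, d = problem.constraint_matrix()

    # consistency of C q = d
    rank_c = np.linalg.matrix_rank(C, tol=1e-10)
    rank_aug = np.linalg.matrix_rank(np.column_stack([C, d]), tol=1e-10)
    if rank_aug > rank_c:
        raise InfeasibleConstraintsError(
            "equality constraints are mutually inconsistent"
        )
    if len(v) < max(0, n - rank_c):
        raise ValidationError(
            f"{len(v)} grid points cannot determine {n - rank_c} free parameters"
        )

    H = 2.0 * (A.T @ A + problem.restraint_weight * np.eye(n))
    g = 2.0 * (A.T @ v)

    # eliminate redundant constraint rows to keep the KKT system nonsingular
    if rank_c < len(C):
        q_fac, r_fac, piv = _qr_pivot(C.T)
        keep = piv[:rank_c]
        C, d = C[keep], d[keep]

    m = len(C)
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = H
    kkt[:n, n:] = C.T
    kkt[n:, :n] = C
    rhs = np.concatenate([g, d])

    # detect rank deficiency of the reduced Hessian (null direction of the fit)
    Z = _nullspace(C)
    if Z.shape[1] > 0:
        reduced = Z.T @ H @ Z
        w, vecs = np.linalg.eigh(reduced)
        if w.min() < 1e-10 * max(w.max(), 1.0):
            null_dir = Z @ vecs[:, int(np.argmin(w))]
            raise IllPosedFitError(
                "fit is rank deficient along charge direction "
                + np.array2string(null_dir, precision=3)
            )

    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise IllPosedFitError(f"singular KKT system: {exc}") from exc
    q = sol[:n]

    residual = A @ q - v
    violation = np.abs(C @ q - d).max() if m else 0.0
    return ChargeSet(
        charges=q,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        constraint_violation_max=float(violation),
    )


def _qr_pivot(mat: np.ndarray):
    from scipy.linalg import qr

    q_fac, r_fac, piv = qr(mat, pivoting=True)
    return q_fac, r_fac, piv


def _nullspace(C: np.ndarray) -> np.ndarray:
    from scipy.linalg import null_space

    return null_space(C)


def split_transferable_charges(
    charges: ChargeSet,
    groups: Sequence[tuple[tuple[int, ...], float]],
    boundary_atoms: Sequence[tuple[int, ...]] = (),
) -> ChargeSet:
    """Force each group's total charge to its declared target exactly.

    The per-group excess is removed uniformly from the group's non-boundary
    atoms (boundary/link atoms keep their fitted values so they remain
    transferable).  Any grand-total drift introduced by the group targets is
    spread over atoms outside all groups; if no such atoms exist a nonzero
    drift means the targets are inconsistent and raises.
    """
    q = charges.charges.copy()
    n = len(q)
    in_any_group = np.zeros(n, dtype=bool)
    boundary_by_group = list(boundary_atoms) + [()] * (
        len(groups) - len(boundary_atoms)
    )
    old_total = q.sum()
    for (idx, target), boundary in zip(groups, boundary_by_group):
        idx = tuple(int(i) for i in idx)
        in_any_group[list(idx)] = True
        free = [i for i in idx if i not in set(boundary)]
        if not free:
            raise ValidationError(
                f"group {idx} has no non-boundary atoms to redistribute over"
            )
        excess = q[list(idx)].sum() - target
        q[free] -= excess / len(free)
    drift = q.sum() - old_total
    if abs(drift) > 1e-12:
        outside = np.where(~in_any_group)[0]
        if len(outside) == 0:
            raise ValidationError(
                "group targets change the grand total and no atoms remain "
                "to absorb the difference"
            )
        q[outside] -= drift / len(outside)
    return ChargeSet(
        charges=q,
        residual_rms=charges.residual_rms,
        constraint_violation_max=0.0,
    )
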