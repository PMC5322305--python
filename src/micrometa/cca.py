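"""Canonical correspondence analysis with Monte-Carlo forward selection.

CCA relates a chi-square-standardized taxa table to explanatory host
variables: with relative table P = F / f (row weights r, column weights c),

    Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j),

the total inertia is ||Q||^2 (the table's chi-square statistic divided by its
grand total). The constrained solution projects Q onto the span of the
row-weighted, standardized explanatory variables (columns of
Z = diag(sqrt(r)) X_std); the canonical eigenvalues are the squared singular
values of that projection and sum to the constrained inertia.

Forward selection repeatedly adds the candidate variable with the largest
*additional* constrained inertia, admitting it only if a Monte-Carlo
permutation of its values (with already-selected variables held fixed) gives
P < alpha. Percentages of variation are reported against total inertia, with
the unexplained remainder as "undetermined".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CCA", "CCAResults", "forward_select", "ForwardSelectionResult", "encode_variables"]

_RANK_TOL = 1e-9


def encode_variables(metadata: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric coding of explanatory variables.

    Numeric columns pass through; two-level categorical columns become 0/1
    indicators (levels in sorted order). More than two levels is an error —
    expand such variables to indicators explicitly.
    """
    out = {}
    for col in columns:
        s = metadata[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = sorted(s.dropna().unique())
            if len(levels) != 2:
                raise ValueError(f"column {col!r} has {len(levels)} levels; expected 2 or numeric")
            out[col] = (s == levels[1]).astype(float)
    return pd.DataFrame(out, index=metadata.index)


def _chi_square_standardize(table: pd.DataFrame):
    """Q matrix (samples x taxa), row weights r, for a taxa x samples table."""
    F = table.to_numpy(float).T  # samples x taxa
    keep = F.sum(axis=0) > 0
    F = F[:, keep]
    if (F.sum(axis=1) == 0).any():
        raise ValueError("every sample needs a non-zero total count")
    f = F.sum()
    P = F / f
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r


def _weighted_z(x, r):
    """Row-weighted centered/standardized variable scaled by sqrt(r)."""
    x = np.asarray(x, float)
    mu = float(r @ x)
    xc = x - mu
    sd = float(np.sqrt(r @ xc**2))
    if sd < _RANK_TOL:
        return np.zeros_like(x)
    return np.sqrt(r) * xc / sd


@dataclass
class CCAResults:
    """Constrained ordination results.

    ``eigenvalues`` are the canonical (constrained) eigenvalues, non-negative
    and non-increasing; their sum is ``constrained_inertia``.
    """

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    rank: int
    n_samples: int
    n_taxa: int
    n_variables: int
    collinear: bool
    variables: list = field(default_factory=list)

    @property
    def proportion_explained(self) -> float:
        return self.constrained_inertia / self.total_inertia

    def summary(self) -> str:
        lines = [
            "Canonical correspondence analysis",
            f"  samples: {self.n_samples}   taxa: {self.n_taxa}   variables: {self.n_variables}"
            + ("   [rank-deficient design]" if self.collinear else ""),
            f"  total inertia:       {self.total_inertia:.6f}",
            f"  constrained inertia: {self.constrained_inertia:.6f} "
            f"({100 * self.proportion_explained:.2f}% of total)",
            "  canonical eigenvalues: " + ", ".join(f"{e:.6f}" for e in self.eigenvalues),
        ]
        return "\n".join(lines)


class CCA:
    """Canonical correspondence analysis of a taxa x samples count table.

    Parameters
    ----------
    table : DataFrame, taxa x samples, non-negative counts or abundances.
    variables : DataFrame, samples x explanatory variables, numerically coded
        (see :func:`encode_variables`); index must match the table's columns.
    """

    def __init__(self, table: pd.DataFrame, variables: pd.DataFrame):
        if list(variables.index) != list(table.columns):
            variables = variables.loc[table.columns]
        n, p = variables.shape
        if table.shape[1] != n:
            raise ValueError("table and variables disagree on samples")
        if n <= p + 1:
            raise ValueError("need n_samples > n_variables + 1")
        self.table = table
        self.variables = variables

    def fit(self) -> CCAResults:
        Q, r = _chi_square_standardize(self.table)
        total = float((Q**2).sum())
        X = self.variables.to_numpy(float)
        Z = np.column_stack([_weighted_z(X[:, j], r) for j in range(X.shape[1])])
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        rank = int((s > _RANK_TOL * max(1.0, s[0] if s.size else 1.0)).sum())
        B = U[:, :rank]
        Qhat = B @ (B.T @ Q)
        sv = np.linalg.svd(Qhat, compute_uv=False)
        eig = (sv**2)[:rank]
        return CCAResults(
            eigenvalues=eig,
            total_inertia=total,
            constrained_inertia=float(eig.sum()),
            rank=rank,
            n_samples=Q.shape[0],
            n_taxa=Q.shape[1],
            n_variables=X.shape[1],
            collinear=rank < X.shape[1],
            variables=list(self.variables.columns),
        )


def _added_inertia(z, B, Q):
    """Additional constrained inertia from adding direction z to basis B."""
    u = z - B @ (B.T @ z) if B.shape[1] else z.copy()
    nu = np.linalg.norm(u)
    if nu < _RANK_TOL:
        return 0.0, None
    u /= nu
    return float(((u @ Q) ** 2).sum()), u


def _perm_added_inertia(x_perms, r, B, Q):
    """Vectorized added inertia for permuted variable values (rows of x_perms)."""
    sq = np.sqrt(r)
    mu = x_perms @ r
    xc = x_perms - mu[:, None]
    sd = np.sqrt((xc**2) @ r)
    sd[sd < _RANK_TOL] = np.inf
    Zp = xc * sq[None, :] / sd[:, None]
    if B.shape[1]:
        Zp = Zp - (Zp @ B) @ B.T
    norms = np.linalg.norm(Zp, axis=1)
    norms[norms < _RANK_TOL] = np.inf
    Zp = Zp / norms[:, None]
    return ((Zp @ Q) ** 2).sum(axis=1)


@dataclass
class ForwardSelectionResult:
    """Forward-selection CCA report.

    ``selected`` rows carry each admitted variable in selection order with its
    conditional (added-at-selection-step) inertia and permutation P;
    ``marginal_pct`` gives each candidate's variable-alone percentage.
    Selected percentages plus ``undetermined_pct`` sum to 100.
    """

    selected: pd.DataFrame
    marginal_pct: pd.Series
    undetermined_pct: float
    total_inertia: float
    alpha: float
    n_permutations: int
    seed: object

    def summary(self) -> str:
        lines = [
            f"CCA forward selection ({self.n_permutations} permutations, alpha = {self.alpha})",
            f"  total inertia: {self.total_inertia:.6f}",
        ]
        if self.selected.empty:
            lines.append("  no variable admitted")
        for _, row in self.selected.iterrows():
            lines.append(
                f"  {int(row['order'])}. {row['variable']}: "
                f"{row['pct_of_total']:.1f}% of variation (P = {row['P']:.4g})"
            )
        lines.append(f"  undetermined: {self.undetermined_pct:.1f}%")
        return "\n".join(lines)


def forward_select(
    table: pd.DataFrame,
    candidates: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> ForwardSelectionResult:
    """Monte-Carlo forward selection of explanatory variables for CCA.

    At each step the remaining candidate with the largest additional
    constrained inertia is permutation-tested (its values shuffled across
    samples, selected variables held fixed, add-one P); it enters if P < alpha,
    otherwise selection stops. Collinear candidates (no added rank) are never
    admitted.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need >= 1 candidate variable")
    if list(candidates.index) != list(table.columns):
        candidates = candidates.loc[table.columns]
    Q, r = _chi_square_standardize(table)
    total = float((Q**2).sum())
    n = Q.shape[0]
    rng = np.random.default_rng(seed)

    X = candidates.to_numpy(float)
    names = list(candidates.columns)
    z_all = {v: _weighted_z(X[:, j], r) for j, v in enumerate(names)}

    # marginal (variable-alone) percentages
    empty = np.zeros((n, 0))
    marginal = pd.Series(
        {v: 100.0 * _added_inertia(z_all[v], empty, Q)[0] / total for v in names},
        name="marginal_pct",
    )

    B = np.zeros((n, 0))
    remaining = list(names)
    rows = []
    while remaining:
        best_v, best_added, best_u = None, -1.0, None
        for v in remaining:
            added, u = _added_inertia(z_all[v], B, Q)
            if u is not None and added > best_added:
                best_v, best_added, best_u = v, added, u
        if best_v is None:
            break
        xv = X[:, names.index(best_v)]
        perms = np.stack([rng.permutation(xv) for _ in range(n_perm)])
        added_perm = _perm_added_inertia(perms, r, B, Q)
        p = (1 + int((added_perm >= best_added - 1e-12).sum())) / (1 + n_perm)
        if p >= alpha:
            break
        rows.append(
            {
                "order": len(rows) + 1,
                "variable": best_v,
                "added_inertia": best_added,
                "pct_of_total": 100.0 * best_added / total,
                "P": p,
            }
        )
        B = np.column_stack([B, best_u])
        remaining.remove(best_v)

    selected = pd.DataFrame(rows, columns=["order", "variable", "added_inertia", "pct_of_total", "P"])
    undetermined = 100.0 - float(selected["pct_of_total"].sum()) if len(rows) else 100.0
    return ForwardSelectionResult(
        selected=selected,
        marginal_pct=marginal,
        undetermined_pct=undetermined,
        total_inertia=total,
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
    )
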