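"""Multi-contrast gene set enrichment via a rank-MANOVA test.

The model
---------
Given a genes x contrasts matrix of centred ranks, each gene set splits the
genes into two groups: members and non-members.  The null hypothesis is that
the two groups share the same mean rank vector.  With ``k`` contrasts this is
a one-way MANOVA with two groups, tested with the Pillai-Bartlett trace

    V = tr( H (H + E)^-1 )

where ``H`` and ``E`` are the between- and within-group sums-of-squares-and-
cross-products matrices.  Because there are only two groups, the hypothesis
has one degree of freedom, ``H`` has rank one, and the test is exactly
Hotelling's T^2:

    F = (n - k - 1)/k * V / (1 - V)     on (k, n - k - 1) df.

For a two-group split, ``H + E`` equals the total SSCP matrix ``T`` about the
grand mean, which does not depend on the set.  With ``d`` the difference of
group mean vectors and ``c = m (n - m) / n`` (m = set size), ``H = c d d'``
and

    V = c * d' T^-1 d,

so a single Cholesky factorisation of ``T`` serves every gene set tested on
the same ranked matrix.  Testing a library of a thousand sets is then a batch
of small triangular solves.

Alongside the test, each set gets a per-contrast enrichment score

    s = 2 (R1 - R2) / n       in [-1, 1],

where R1 / R2 are the mean centred ranks of members / non-members, and the
multidimensional effect size S = ||s||_2 (the Euclidean distance from the
origin of the s vector).  p-values are adjusted with the Benjamini-Hochberg
step-up FDR across exactly the sets tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateTestError, ValidationError
from .geneset import GeneSet, GeneSetLibrary, filter_sets

__all__ = [
    "enrichment_score",
    "manova_test",
    "anova_test",
    "effect_size",
    "adjust_bh",
    "run_enrichment",
    "ResultTable",
]

_TINY = np.finfo(float).tiny

PRIORITIES = ("significance", "effect", "SD")


def _as_matrix(ranked: pd.DataFrame) -> np.ndarray:
    mat = ranked.to_numpy(float)
    if mat.ndim != 2 or mat.shape[0] < 4:
        raise ValidationError("ranked matrix needs at least 4 genes")
    return mat


def _member_indices(ranked: pd.DataFrame, members: Iterable[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(ranked.index)}
    idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=np.intp)
    return idx


def _check_total_sscp(ranked: pd.DataFrame, T: np.ndarray) -> None:
    diag = np.diag(T)
    if (diag <= 0).any():
        col = ranked.columns[int(np.argmin(diag))]
        raise DegenerateTestError(
            f"contrast {col!r} has zero rank variance; the test is degenerate"
        )


class _MatrixContext:
    """Per-ranked-matrix precomputation shared by every set tested on it."""

    def __init__(self, ranked: pd.DataFrame):
        self.R = _as_matrix(ranked)
        self.n, self.k = self.R.shape
        self.col_sums = self.R.sum(axis=0)
        grand_mean = self.col_sums / self.n
        Rc = self.R - grand_mean
        self.T = Rc.T @ Rc
        _check_total_sscp(ranked, self.T)
        try:
            self._chol = cho_factor(self.T, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise DegenerateTestError(f"singular total SSCP matrix: {exc}") from exc

    def stats_for(self, idx: np.ndarray) -> tuple[np.ndarray, float, float, float]:
        """Return (s, S, pillai V, p) for the member index array *idx*."""
        n, k = self.n, self.k
        m = idx.size
        if m < 1 or m >= n:
            raise DegenerateTestError(
                f"set overlaps {m} of {n} profile genes; complement undefined"
            )
        sum_in = self.R[idx].sum(axis=0)
        mean_in = sum_in / m
        mean_out = (self.col_sums - sum_in) / (n - m)
        d = mean_in - mean_out
        s = 2.0 * d / n
        S = float(np.sqrt((s * s).sum()))
        c = m * (n - m) / n
        V = float(c * d @ cho_solve(self._chol, d))
        V = min(V, 1.0)
        err_df = n - k - 1
        if err_df < 1 or m < 2 or m > n - 2:
            raise DegenerateTestError(
                f"test not well posed: n={n}, k={k}, set size m={m}"
            )
        if V >= 1.0:
            p = _TINY
        else:
            F = (err_df / k) * V / (1.0 - V)
            p = float(stats.f.sf(F, k, err_df))
        return s, S, V, max(p, _TINY)


def enrichment_score(ranked: pd.DataFrame, members: Iterable[str]) -> np.ndarray:
    """Per-contrast enrichment score s = 2(R1 - R2)/n on centred ranks."""
    idx = _member_indices(ranked, members)
    R = _as_matrix(ranked)
    n = R.shape[0]
    m = idx.size
    if m < 1 or m >= n:
        raise DegenerateTestError(
            f"set overlaps {m} of {n} profile genes; enrichment score undefined"
        )
    sum_in = R[idx].sum(axis=0)
    d = sum_in / m - (R.sum(axis=0) - sum_in) / (n - m)
    return 2.0 * d / n


def manova_test(ranked: pd.DataFrame, members: Iterable[str]) -> tuple[float, float]:
    """Rank-MANOVA of one gene set: returns ``(p_value, pillai_V)``.

    Two-group Pillai-Bartlett trace with an exact F transform (equivalently
    Hotelling's T^2); see the module docstring for the reduction used.
    """
    ctx = _MatrixContext(ranked)
    idx = _member_indices(ranked, members)
    _, _, V, p = ctx.stats_for(idx)
    return p, V


def anova_test(ranked: pd.DataFrame, members: Iterable[str]) -> float:
    """One-way two-group ANOVA on centred ranks of a single contrast.

    Equals the squared pooled-variance two-sample t-test.  Used in place of
    the MANOVA when only one contrast is supplied.
    """
    if ranked.shape[1] != 1:
        raise ValidationError(f"anova_test expects one contrast, got {ranked.shape[1]}")
    idx = _member_indices(ranked, members)
    x = _as_matrix(ranked)[:, 0]
    n = x.size
    if idx.size < 2 or idx.size > n - 2:
        raise DegenerateTestError(f"set size {idx.size} outside [2, n-2] for n={n}")
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    inside, outside = x[mask], x[~mask]
    ss_within = ((inside - inside.mean()) ** 2).sum() + ((outside - outside.mean()) ** 2).sum()
    if ss_within == 0.0:
        if inside.mean() == outside.mean():
            return 1.0
        warnings.warn("zero within-group variance; p clamped", stacklevel=2)
        return _TINY
    F, p = stats.f_oneway(inside, outside)
    return float(max(p, _TINY))


def effect_size(s: np.ndarray) -> float:
    """Multidimensional effect size S: Euclidean norm of the s vector."""
    s = np.asarray(s, dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("s vector must be finite")
    return float(np.sqrt((s * s).sum()))


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ResultTable:
    """Enrichment results for one analysis, ordered by the chosen priority.

    ``table`` columns: ``set``, ``setSize``, one ``s.<contrast>`` column per
    contrast, ``S``, ``sSD``, ``p.manova``, ``p.manovaFDR``.
    """

    table: pd.DataFrame
    contrasts: list[str]
    n_genes: int
    min_size: int
    priority: str
    top_n: int
    n_sets_excluded: int

    @property
    def detailed_sets(self) -> list[str]:
        """Names of the sets selected for detailed reporting (top N by priority)."""
        return self.table["set"].head(self.top_n).tolist()

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p.manovaFDR"] < fdr]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def __repr__(self) -> str:
        return (
            f"ResultTable({len(self.table)} sets, contrasts={self.contrasts}, "
            f"priority={self.priority!r})"
        )


def _sort_results(table: pd.DataFrame, priority: str) -> pd.DataFrame:
    if priority == "significance":
        keys, ascending = ["p.manova", "set"], [True, True]
    elif priority == "effect":
        keys, ascending = ["S", "set"], [False, True]
    elif priority == "SD":
        keys, ascending = ["sSD", "set"], [False, True]
    else:
        raise ValidationError(f"priority must be one of {PRIORITIES}, got {priority!r}")
    return table.sort_values(keys, ascending=ascending, kind="mergesort").reset_index(drop=True)


def _compute_chunk(ctx: _MatrixContext, idx_list: list[np.ndarray]) -> list[tuple]:
    return [ctx.stats_for(idx) for idx in idx_list]


def run_enrichment(
    ranked: pd.DataFrame,
    library: GeneSetLibrary,
    min_size: int = 10,
    priority: str = "significance",
    top_n: int = 50,
    n_jobs: int = 1,
) -> ResultTable:
    """Test every sufficiently large gene set for joint enrichment.

    Sets are size-filtered against the profile, each retained set is tested
    with the rank-MANOVA (plain ANOVA when there is a single contrast), and
    p-values are BH-adjusted across exactly the tested sets.  Rows are
    ordered by *priority*: ``significance`` (ascending p), ``effect``
    (descending S) or ``SD`` (descending standard deviation of s across
    contrasts, useful for discordant regulation); ties broken by set name so
    output is deterministic.  Per-set computations are independent, so
    ``n_jobs > 1`` distributes them without changing the result.
    """
    k = ranked.shape[1]
    if k > 20:
        warnings.warn(
            f"{k} contrasts: results are fine but plots refuse more than 20",
            stacklevel=2,
        )
    if priority == "SD" and k == 1:
        raise ValidationError("SD prioritisation needs at least two contrasts")
    filtered, excluded = filter_sets(library, ranked, min_size=min_size)
    n = len(ranked)
    kept: list[GeneSet] = []
    full_overlap = 0
    for gs in filtered:
        if len(gs) >= n:
            full_overlap += 1
        else:
            kept.append(gs)
    if full_overlap:
        warnings.warn(
            f"excluded {full_overlap} sets covering the whole profile "
            "(empty complement)",
            stacklevel=2,
        )
        excluded += full_overlap
    if not kept:
        raise ValidationError(
            "no gene sets left after size filtering; check identifiers and min_size"
        )

    ctx = _MatrixContext(ranked)
    pos = {g: i for i, g in enumerate(ranked.index)}
    idx_list = [
        np.fromiter((pos[g] for g in gs.members), dtype=np.intp, count=len(gs.members))
        for gs in kept
    ]
    for idx in idx_list:
        idx.sort()

    if n_jobs > 1:
        from joblib import Parallel, delayed

        chunks = np.array_split(np.arange(len(kept)), n_jobs)
        pieces = Parallel(n_jobs=n_jobs)(
            delayed(_compute_chunk)(ctx, [idx_list[i] for i in chunk])
            for chunk in chunks
            if len(chunk)
        )
        stats_out = [row for piece in pieces for row in piece]
    else:
        stats_out = _compute_chunk(ctx, idx_list)

    s_mat = np.vstack([row[0] for row in stats_out])
    S = np.array([row[1] for row in stats_out])
    p = np.array([row[3] for row in stats_out])
    q = adjust_bh(p)
    s_sd = s_mat.std(axis=1, ddof=1) if k > 1 else np.full(len(kept), np.nan)

    data = {"set": [gs.name for gs in kept], "setSize": [len(gs) for gs in kept]}
    for j, col in enumerate(ranked.columns):
        data[f"s.{col}"] = s_mat[:, j]
    data["S"] = S
    data["sSD"] = s_sd
    data["p.manova"] = p
    data["p.manovaFDR"] = q
    table = _sort_results(pd.DataFrame(data), priority)

    return ResultTable(
        table=table,
        contrasts=[str(c) for c in ranked.columns],
        n_genes=n,
        min_size=min_size,
        priority=priority,
        top_n=top_n,
        n_sets_excluded=excluded,
    )
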