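"""Import differential-expression tables and turn them into centred rank profiles.

Each upstream DE tool writes a table with its own column dialect.  This module
recognises the common dialects, reduces every gene to one signed score per
contrast, joins contrasts into a single profile, optionally translates gene
identifiers, and finally converts scores to centred ranks -- the response
variable of all downstream enrichment tests.

Scoring convention
------------------
Where a tool reports a signed test statistic (DESeq2 ``stat``, limma ``t``,
...), that statistic is used directly.  Where it reports an (effect, p-value)
pair, the directional significance score is computed::

    D = -log10(nominal p-value) * sign(log2 fold change)

Ranks are ascending (most down-regulated gene lowest) with ties averaged, and
are centred so that a score of exactly zero maps to centred rank 0: the offset
subtracted from the raw rank is ``N_neg + (N_zero + 1) / 2``, where ``N_neg``
and ``N_zero`` count strictly negative and exactly zero scores in the
contrast.  Consequently sign(centred rank) == sign(score) away from ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import AmbiguousFormatError, UnrecognisedFormatError, ValidationError

__all__ = [
    "FormatSpec",
    "FORMATS",
    "detect_format",
    "read_de_table",
    "read_id_map",
    "score_genes",
    "import_profile",
    "join_profiles",
    "map_identifiers",
    "rank_and_center",
]


@dataclass(frozen=True)
class FormatSpec:
    """How to extract a per-gene ranking metric from one tool's output table.

    Either ``stat`` is set (the tool reports a signed statistic that is used
    directly) or both ``effect`` and ``pvalue`` are set (the directional
    significance score D is computed from the pair).
    """

    tool: str
    stat: str | None = None
    effect: str | None = None
    pvalue: str | None = None
    #: columns that must all be present for autodetection to pick this spec
    requires: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if (self.stat is None) == (self.effect is None or self.pvalue is None):
            raise ValueError("FormatSpec needs either stat or (effect, pvalue)")
        if not self.requires:
            cols = (self.stat,) if self.stat else (self.effect, self.pvalue)
            object.__setattr__(self, "requires", tuple(cols))

    @property
    def is_pair(self) -> bool:
        return self.stat is None

    @property
    def score_columns(self) -> tuple[str, ...]:
        return (self.stat,) if self.stat else (self.effect, self.pvalue)


#: Registry of recognised upstream-tool dialects, most specific first.
FORMATS: tuple[FormatSpec, ...] = (
    FormatSpec("deseq2", stat="stat", requires=("log2FoldChange", "stat", "pvalue")),
    FormatSpec("edger", effect="logFC", pvalue="PValue"),
    FormatSpec("limma", stat="t", requires=("t", "P.Value")),
    FormatSpec("absseq", effect="foldChange", pvalue="pvalue"),
    FormatSpec("topconfects", stat="confect"),
    FormatSpec("swish", stat="stat"),
    FormatSpec("noiseq", stat="ranking"),
    FormatSpec("ballgown", effect="fc", pvalue="pval"),
    FormatSpec("tcc", effect="m.value", pvalue="p.value"),
    FormatSpec("sleuth", effect="b", pvalue="pval"),
    FormatSpec("cuffdiff", stat="test_stat"),
    FormatSpec("seurat", effect="avg_logFC", pvalue="p_val"),
    FormatSpec("seurat_v4", effect="avg_log2FC", pvalue="p_val"),
    FormatSpec("muscat", effect="logFC", pvalue="p_val"),
    FormatSpec("scde", stat="Z"),
    FormatSpec("mast", effect="Coef", pvalue="Pr(>Chisq)"),
    FormatSpec("desingle", effect="foldchange", pvalue="pvalue"),
    FormatSpec("missmethyl", stat="t"),
    FormatSpec("dmrcate", effect="meanbetafc", pvalue="Stouffer"),
    FormatSpec("dep", effect="ratio", pvalue="p.val"),
    FormatSpec("msmstests", effect="LogFC", pvalue="p.value"),
    FormatSpec("plgem", effect="PLGEM.STN", pvalue="p.value"),
    FormatSpec("sdams", effect="beta", pvalue="pv_2part"),
    FormatSpec("deqms", stat="t"),
    FormatSpec("diffbind", effect="Fold", pvalue="p.value"),
)

_BY_TOOL = {f.tool: f for f in FORMATS}


def detect_format(table: pd.DataFrame, hint: str | None = None) -> FormatSpec:
    """Work out which columns supply the ranking metric for *table*.

    An explicit *hint* (a tool name from :data:`FORMATS`, or ``"prescored"``)
    overrides autodetection.  Without a hint, every registered dialect whose
    required columns are all present is a candidate; the most specific match
    (largest required-column signature) wins.  If the best matches disagree
    about which columns to use, an :class:`AmbiguousFormatError` is raised.
    A table with exactly one numeric column falls back to a generic
    "prescored" format using that column directly.
    """
    cols = set(map(str, table.columns))
    if hint is not None:
        key = hint.lower()
        if key in ("prescored", "generic"):
            return _prescored_spec(table)
        if key not in _BY_TOOL:
            raise UnrecognisedFormatError(
                f"unknown format hint {hint!r}; known: "
                + ", ".join(sorted(_BY_TOOL)) + ", prescored"
            )
        spec = _BY_TOOL[key]
        missing = [c for c in spec.score_columns if c not in cols]
        if missing:
            raise UnrecognisedFormatError(
                f"format {hint!r} needs columns {missing}, table has {sorted(cols)}"
            )
        return spec

    candidates = [f for f in FORMATS if set(f.requires) <= cols]
    if not candidates:
        try:
            return _prescored_spec(table)
        except UnrecognisedFormatError:
            raise UnrecognisedFormatError(
                "no recognised DE-table format among columns "
                f"{sorted(cols)}; pass an explicit format hint"
            ) from None
    best = max(len(f.requires) for f in candidates)
    top = [f for f in candidates if len(f.requires) == best]
    configs = {f.score_columns for f in top}
    if len(configs) > 1:
        raise AmbiguousFormatError(
            "columns match several formats with different ranking metrics: "
            + ", ".join(f"{f.tool}={f.score_columns}" for f in top)
            + "; pass an explicit format hint"
        )
    return top[0]


def _prescored_spec(table: pd.DataFrame) -> FormatSpec:
    numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(numeric) != 1:
        raise UnrecognisedFormatError(
            "a prescored table must have exactly one numeric score column, "
            f"found {numeric or 'none'}"
        )
    return FormatSpec("prescored", stat=str(numeric[0]), requires=(str(numeric[0]),))


def read_de_table(
    path,
    sep: str | None = None,
    gene_col: str | None = None,
) -> pd.DataFrame:
    """Read a delimited DE table, indexed by gene identifier.

    The delimiter is sniffed when *sep* is None (tab and comma both work).
    Gene identifiers are taken from the first column unless *gene_col* names
    another one.
    """
    if sep is None:
        table = pd.read_csv(path, sep=None, engine="python")
    else:
        table = pd.read_csv(path, sep=sep)
    if gene_col is not None:
        if gene_col not in table.columns:
            raise ValidationError(f"gene column {gene_col!r} not in {list(table.columns)}")
        table = table.set_index(gene_col)
    else:
        table = table.set_index(table.columns[0])
    table.index = table.index.astype(str)
    if (table.index == "") .any() or table.index.isna().any():
        raise ValidationError(f"empty gene identifiers in {path}")
    return table


def score_genes(
    table: pd.DataFrame,
    fmt: FormatSpec | None = None,
    contrast: str | None = None,
    on_duplicate: str = "error",
) -> pd.Series:
    """Reduce a DE table to one signed score per gene for one contrast.

    Direct-statistic formats copy the statistic column; pair formats compute
    the directional significance score D = -log10(p) * sign(effect).  A
    p-value of exactly 0 is clamped to the smallest positive normal double
    before the log so D stays finite but extreme.  Rows with missing scores
    (e.g. DESeq2 NA statistics from independent filtering) are dropped with a
    warning.

    Duplicate gene identifiers raise a :class:`ValidationError` unless
    ``on_duplicate="max_abs"``, which keeps the row with the largest absolute
    score.
    """
    if fmt is None:
        fmt = detect_format(table)
    if fmt.is_pair:
        effect = pd.to_numeric(table[fmt.effect], errors="coerce")
        pval = pd.to_numeric(table[fmt.pvalue], errors="coerce")
        ok = effect.notna() & pval.notna()
        bad_p = pval[ok][(pval[ok] < 0) | (pval[ok] > 1)]
        if len(bad_p):
            raise ValidationError(
                f"p-values outside [0, 1] for genes {list(bad_p.index[:5])}"
            )
        if not np.isfinite(effect[ok]).all():
            raise ValidationError("non-finite effect sizes in table")
        p = pval[ok].to_numpy(float)
        p = np.clip(p, np.finfo(float).tiny, None)
        score = pd.Series(
            -np.log10(p) * np.sign(effect[ok].to_numpy(float)),
            index=table.index[ok],
        )
    else:
        stat = pd.to_numeric(table[fmt.stat], errors="coerce")
        ok = stat.notna()
        score = stat[ok].astype(float)
    dropped = len(table) - int(ok.sum())
    if dropped:
        warnings.warn(f"dropped {dropped} genes with missing scores", stacklevel=2)

    if score.index.duplicated().any():
        dups = sorted(set(score.index[score.index.duplicated()]))
        if on_duplicate == "max_abs":
            score = score.iloc[np.argsort(-score.abs().to_numpy(), kind="stable")]
            score = score[~score.index.duplicated(keep="first")]
        else:
            raise ValidationError(
                f"duplicate gene identifiers: {dups[:10]}"
                f"{'...' if len(dups) > 10 else ''}; "
                'pass on_duplicate="max_abs" to keep the strongest row'
            )
    score.name = contrast
    return score


def import_profile(
    path,
    format: str | None = None,
    contrast: str | None = None,
    sep: str | None = None,
    gene_col: str | None = None,
    on_duplicate: str = "error",
) -> pd.Series:
    """Read one DE table from disk and score it: convenience wrapper."""
    table = read_de_table(path, sep=sep, gene_col=gene_col)
    fmt = detect_format(table, hint=format)
    return score_genes(table, fmt, contrast=contrast, on_duplicate=on_duplicate)


def join_profiles(
    profiles: Sequence[pd.Series] | Mapping[str, pd.Series],
    mode: str = "intersect",
) -> pd.DataFrame:
    """Join single-contrast score series into one genes x contrasts profile.

    ``intersect`` keeps only genes detected in every contrast; ``union``
    keeps all genes and fills missing scores with 0 (the least informative
    placement, mapping to a centred rank near zero), which suits sparse data
    such as single-cell contrasts.
    """
    if isinstance(profiles, Mapping):
        series = [s.rename(name) for name, s in profiles.items()]
    else:
        series = list(profiles)
    if not series:
        raise ValidationError("need at least one profile")
    names = [s.name for s in series]
    if len(set(names)) != len(names) or any(n is None for n in names):
        raise ValidationError(f"contrast names must be unique and non-null, got {names}")
    if mode not in ("intersect", "union"):
        raise ValidationError(f"join mode must be 'intersect' or 'union', got {mode!r}")
    how = "inner" if mode == "intersect" else "outer"
    joined = pd.concat(series, axis=1, join=how)
    if mode == "union":
        joined = joined.fillna(0.0)
    if joined.empty and mode == "intersect":
        raise ValidationError(
            "no genes shared by all contrasts; consider mode='union'"
        )
    return joined


def read_id_map(path, sep: str | None = None) -> pd.DataFrame:
    """Read a two-column (source, target) identifier mapping table."""
    table = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if table.shape[1] < 2:
        raise ValidationError("identifier map needs two columns (source, target)")
    table = table.iloc[:, :2].astype(str)
    if (table == "").any().any():
        raise ValidationError("empty identifiers in map")
    return table


def map_identifiers(profile: pd.Series | pd.DataFrame, idmap: pd.DataFrame):
    """Translate a profile's gene identifiers using a (source, target) map.

    Genes without a mapping are dropped.  When several source identifiers map
    to one target, the row with the largest absolute score (largest across
    contrasts, for a multi-contrast profile) is kept.
    """
    if len(idmap) == 0:
        raise ValidationError("identifier map is empty")
    src, tgt = idmap.columns[:2]
    lookup = dict(zip(idmap[src].astype(str), idmap[tgt].astype(str)))
    frame = profile.to_frame() if isinstance(profile, pd.Series) else profile
    keep = frame.index.map(lambda g: g in lookup)
    mapped = frame[keep].copy()
    if mapped.empty:
        warnings.warn("no profile genes found in identifier map", stacklevel=2)
    mapped.index = pd.Index([lookup[g] for g in mapped.index], name=frame.index.name)
    if mapped.index.duplicated().any():
        magnitude = mapped.abs().max(axis=1).to_numpy()
        order = np.argsort(-magnitude, kind="stable")
        mapped = mapped.iloc[order]
        mapped = mapped[~mapped.index.duplicated(keep="first")]
    if isinstance(profile, pd.Series):
        return mapped.iloc[:, 0].rename(profile.name)
    return mapped


def rank_and_center(profile: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Convert scores to centred ranks, per contrast.

    Ascending average ranks (most down-regulated lowest), shifted by
    ``N_neg + (N_zero + 1)/2`` so that a zero score lands exactly on centred
    rank 0 and the sign of the centred rank matches the sign of the score.
    """
    frame = profile.to_frame() if isinstance(profile, pd.Series) else profile
    if frame.empty:
        raise ValidationError("cannot rank an empty profile")
    out = {}
    for col in frame.columns:
        x = frame[col].to_numpy(float)
        bad = ~np.isfinite(x)
        if bad.any():
            gene = frame.index[bad][0]
            raise ValidationError(
                f"non-finite score for gene {gene!r} in contrast {col!r}"
            )
        ranks = rankdata(x, method="average")
        offset = (x < 0).sum() + ((x == 0).sum() + 1) / 2.0
        out[col] = ranks - offset
    return pd.DataFrame(out, index=frame.index)
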