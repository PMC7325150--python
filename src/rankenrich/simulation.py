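"""Synthetic data generators and accuracy benchmarks.

Three families of machinery live here:

* **Fixture generators** -- random centred-rank profiles (independent rank
  shuffles per contrast), random gene set libraries, and targeted rank-shift
  injection that realises a prespecified per-contrast enrichment score ``s*``
  by displacing member centred ranks by ``delta = n * s* / 2``.  Shifted
  values are deliberately *not* re-ranked: the additive shift changes the
  set-vs-complement mean rank difference by exactly ``n s*/2``, so the
  measured ``s`` of the shifted set equals its pre-shift value plus ``s*``,
  and ``E[s] = s*`` over random base profiles.  Re-ranking would attenuate
  the injected signal.

* **Null randomisations** -- the three procedures used to check type-I error
  control on a fixed profile: (i) shuffle gene names jointly across
  contrasts (keeps the inter-contrast correlation structure), (ii) shuffle
  each contrast's values independently (destroys it), (iii) keep the profile
  and draw fresh random gene sets with a prescribed size distribution.

* **Benchmarks** -- the five-contrast rank-shift power simulation
  (per-contrast ``s*`` drawn from Normal(0, sd) for a fixed number of
  designated DE sets, enrichment run, sets called at an FDR cutoff, and
  precision / recall / F1 computed against ground truth), plus a synthetic
  count-matrix generator emulating a sequencing experiment for
  single/dual-contrast harnesses.

Every operation is a pure function of its inputs and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ResultTable, run_enrichment
from .exceptions import ValidationError
from .geneset import GeneSet, GeneSetLibrary

__all__ = [
    "SimConfig",
    "SimTruth",
    "random_profile",
    "random_library",
    "inject_enrichment",
    "shuffle_names",
    "shuffle_values",
    "random_sets_like",
    "simulate_counts",
    "score_counts",
    "confusion_metrics",
    "run_power_benchmark",
    "run_null_benchmark",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the five-contrast rank-shift power simulation.

    Defaults are the reference conditions of the benchmark: a profile of
    15,240 genes (the size of a typical bulk RNA-seq contrast after
    expression filtering) in five contrasts, a library of 1000 random sets
    of 50 members of which 20 carry injected enrichment, per-contrast s
    values drawn from Normal(0, ``s_sd``), and calls made at a 5% FDR.
    """

    n_genes: int = 15240
    n_contrasts: int = 5
    n_sets: int = 1000
    set_size: int = 50
    n_de_sets: int = 20
    s_sd: float = 0.1
    fdr_cutoff: float = 0.05
    replications: int = 1000
    seed: int = 0
    min_size: int = 10

    def __post_init__(self) -> None:
        if self.n_de_sets > self.n_sets:
            raise ValidationError("n_de_sets cannot exceed n_sets")
        if self.set_size < 2:
            raise ValidationError("set_size must be >= 2")
        if self.s_sd < 0:
            raise ValidationError("s_sd must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated library: DE flags and injected s values."""

    flags: pd.Series  # bool per set name
    injected_s: pd.DataFrame  # set name x contrast, zero for non-DE sets

    @property
    def de_names(self) -> frozenset[str]:
        return frozenset(self.flags.index[self.flags])

    def __post_init__(self) -> None:
        nonde = self.injected_s.loc[~self.flags]
        if len(nonde) and (nonde.to_numpy() != 0).any():
            raise ValidationError("non-DE sets must have zero injected s")


def gene_names(n_genes: int) -> pd.Index:
    """Deterministic synthetic gene identifiers g000001..g<n>."""
    width = max(6, len(str(n_genes)))
    return pd.Index([f"g{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene")


def centred_rank_values(n: int) -> np.ndarray:
    """The centred ranks of n untied genes: {1..n} - (n+1)/2."""
    return np.arange(1, n + 1, dtype=float) - (n + 1) / 2.0


def random_profile(n_genes: int, n_contrasts: int, seed=None) -> pd.DataFrame:
    """A null multi-contrast profile: independent rank shuffles per contrast.

    Each column is a uniform random permutation of the centred ranks
    ``{1..n} - (n+1)/2``, so column means are exactly zero and contrasts are
    independent.
    """
    if n_genes < 10:
        raise ValidationError("n_genes must be >= 10")
    rng = _rng(seed)
    base = centred_rank_values(n_genes)
    cols = {f"C{j + 1}": rng.permutation(base) for j in range(n_contrasts)}
    return pd.DataFrame(cols, index=gene_names(n_genes))


def random_library(
    gene_ids: Sequence[str],
    n_sets: int,
    set_size: int,
    seed=None,
) -> GeneSetLibrary:
    """Random gene sets: each samples ``set_size`` distinct genes uniformly."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    if set_size > gene_ids.size:
        raise ValidationError(
            f"set_size {set_size} exceeds number of genes {gene_ids.size}"
        )
    rng = _rng(seed)
    width = max(4, len(str(n_sets)))
    sets = []
    for i in range(n_sets):
        members = rng.choice(gene_ids, size=set_size, replace=False)
        sets.append(GeneSet(f"set{i + 1:0{width}d}", frozenset(members), "random"))
    return GeneSetLibrary(sets)


def inject_enrichment(
    ranked: pd.DataFrame,
    library: GeneSetLibrary,
    n_de_sets: int,
    s_sd: float,
    seed=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Shift member ranks of randomly chosen sets to inject known enrichment.

    For each selected set and contrast, ``s* ~ Normal(0, s_sd)`` is drawn and
    ``n * s* / 2`` is added to the centred rank of every member in that
    contrast, without re-ranking.  Genes belonging to several selected sets
    accumulate the sum of the shifts.  ``s_sd = 0`` leaves the matrix
    untouched.
    """
    if s_sd < 0:
        raise ValidationError("s_sd must be >= 0")
    if n_de_sets > len(library):
        raise ValidationError("n_de_sets exceeds library size")
    rng = _rng(seed)
    names = library.names
    de_names = list(rng.choice(np.asarray(names, dtype=object), size=n_de_sets, replace=False))
    n = len(ranked)
    contrasts = list(ranked.columns)
    flags = pd.Series(False, index=pd.Index(names, name="set"))
    flags.loc[de_names] = True
    injected = pd.DataFrame(0.0, index=flags.index, columns=contrasts)
    shifted = ranked.copy()
    pos = {g: i for i, g in enumerate(ranked.index)}
    mat = shifted.to_numpy(float)
    for name in de_names:
        s_star = rng.normal(0.0, s_sd, size=len(contrasts)) if s_sd > 0 else np.zeros(len(contrasts))
        injected.loc[name] = s_star
        idx = np.fromiter(
            (pos[g] for g in library[name].members if g in pos), dtype=np.intp
        )
        mat[idx] += n * s_star / 2.0
    shifted.iloc[:, :] = mat
    return shifted, SimTruth(flags=flags, injected_s=injected)


def shuffle_names(profile: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Permute gene labels jointly across contrasts (correlation preserved)."""
    rng = _rng(seed)
    out = profile.copy()
    out.index = profile.index[rng.permutation(len(profile))]
    return out


def shuffle_values(profile: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Permute each contrast's values independently (correlation destroyed)."""
    rng = _rng(seed)
    out = profile.copy()
    for col in out.columns:
        out[col] = rng.permutation(out[col].to_numpy())
    return out


def random_sets_like(
    gene_ids: Sequence[str],
    size_template: Sequence[int],
    seed=None,
) -> GeneSetLibrary:
    """Random sets whose sizes follow a given template (e.g. a real library)."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    rng = _rng(seed)
    width = max(4, len(str(len(size_template))))
    sets = []
    for i, size in enumerate(size_template):
        size = int(size)
        if size < 1 or size > gene_ids.size:
            raise ValidationError(
                f"template size {size} impossible with {gene_ids.size} genes"
            )
        members = rng.choice(gene_ids, size=size, replace=False)
        sets.append(GeneSet(f"rand{i + 1:0{width}d}", frozenset(members), "random"))
    return GeneSetLibrary(sets)


def confusion_metrics(
    truth_de: Iterable[str],
    called: Iterable[str],
) -> tuple[float, float, float]:
    """Precision, recall and F1 of a called set list against ground truth.

    Precision is defined as 1 when nothing is called (no opportunity for a
    false positive); F1 is 0 when precision and recall are both 0.
    """
    truth_de = frozenset(truth_de)
    called = frozenset(called)
    tp = len(called & truth_de)
    fp = len(called - truth_de)
    fn = len(truth_de - called)
    precision = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
    recall = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def run_power_benchmark(
    s_sd_grid: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25),
    fdr_cutoffs: Sequence[float] = (0.05, 0.01),
    replications: int = 1000,
    *,
    n_genes: int = 15240,
    n_contrasts: int = 5,
    n_sets: int = 1000,
    set_size: int = 50,
    n_de_sets: int = 20,
    min_size: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank-shift power benchmark over a grid of enrichment strengths.

    For each value of ``s_sd`` and each replication: draw a random profile,
    a random library, inject enrichment into ``n_de_sets`` sets, run the
    full enrichment analysis, call sets below each FDR cutoff, and score
    precision / recall / F1 against the injected truth.  Returns one row per
    (s_sd, fdr_cutoff) with metric means and the mean false-positive count.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rows = []
    for s_sd in s_sd_grid:
        acc = {c: {"precision": [], "recall": [], "f1": [], "fp": []} for c in fdr_cutoffs}
        children = ss.spawn(replications)
        for child in children:
            rng = np.random.default_rng(child)
            ranked = random_profile(n_genes, n_contrasts, rng)
            library = random_library(ranked.index, n_sets, set_size, rng)
            shifted, truth = inject_enrichment(ranked, library, n_de_sets, s_sd, rng)
            result = run_enrichment(shifted, library, min_size=min_size)
            tab = result.table
            for cutoff in fdr_cutoffs:
                called = tab.loc[tab["p.manovaFDR"] < cutoff, "set"]
                precision, recall, f1 = confusion_metrics(truth.de_names, called)
                acc[cutoff]["precision"].append(precision)
                acc[cutoff]["recall"].append(recall)
                acc[cutoff]["f1"].append(f1)
                acc[cutoff]["fp"].append(len(frozenset(called) - truth.de_names))
        for cutoff in fdr_cutoffs:
            rows.append(
                {
                    "s_sd": s_sd,
                    "fdr_cutoff": cutoff,
                    "precision": float(np.mean(acc[cutoff]["precision"])),
                    "recall": float(np.mean(acc[cutoff]["recall"])),
                    "f1": float(np.mean(acc[cutoff]["f1"])),
                    "mean_fp": float(np.mean(acc[cutoff]["fp"])),
                    "total_fp": int(np.sum(acc[cutoff]["fp"])),
                    "replications": replications,
                }
            )
    return pd.DataFrame(rows)


def _reactome_like_sizes(n_sets: int, rng: np.random.Generator) -> np.ndarray:
    """Set sizes emulating a curated pathway library: log-normal, >= 10."""
    sizes = np.round(np.exp(rng.normal(np.log(40.0), 0.9, size=n_sets))).astype(int)
    return np.clip(sizes, 10, 400)


def run_null_benchmark(
    procedure: str,
    replications: int = 1000,
    *,
    n_genes: int = 15240,
    n_contrasts: int = 2,
    n_sets: int = 1000,
    fdr_cutoffs: Sequence[float] = (0.05, 0.01),
    min_size: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """False-positive counts per run under one of three null randomisations.

    A fixed synthetic profile (independent standard-normal DE scores per
    contrast) and a fixed library with a curated-library-like size
    distribution are generated once; each replication then applies the
    chosen randomisation -- ``"names"`` (shuffle gene labels jointly),
    ``"values"`` (shuffle each contrast independently) or ``"sets"`` (fresh
    random sets of the same sizes) -- and counts sets called at each FDR
    cutoff.  Any call is a false positive since no signal is present.
    """
    if procedure not in ("names", "values", "sets"):
        raise ValidationError("procedure must be 'names', 'values' or 'sets'")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    genes = gene_names(n_genes)
    profile = pd.DataFrame(
        base_rng.standard_normal((n_genes, n_contrasts)),
        index=genes,
        columns=[f"C{j + 1}" for j in range(n_contrasts)],
    )
    sizes = _reactome_like_sizes(n_sets, base_rng)
    base_library = random_sets_like(genes, sizes, base_rng)

    from .profile_import import rank_and_center

    rows = []
    for rep, child in enumerate(ss.spawn(replications)):
        rng = np.random.default_rng(child)
        if procedure == "names":
            perturbed, library = shuffle_names(profile, rng), base_library
        elif procedure == "values":
            perturbed, library = shuffle_values(profile, rng), base_library
        else:
            perturbed, library = profile, random_sets_like(genes, sizes, rng)
        ranked = rank_and_center(perturbed)
        result = run_enrichment(ranked, library, min_size=min_size)
        q = result.table["p.manovaFDR"]
        row = {"procedure": procedure, "replication": rep}
        for cutoff in fdr_cutoffs:
            row[f"fp_at_{cutoff:g}"] = int((q < cutoff).sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CountSim:
    """Synthetic case/control count matrices with per-gene fold-change truth."""

    control: pd.DataFrame
    case: pd.DataFrame
    gene_fc: pd.Series


def simulate_counts(
    n_genes: int = 20000,
    depth: int = 10_000_000,
    noise_sd: float = 0.3,
    fold_changes: Mapping[str, float] | None = None,
    library: GeneSetLibrary | None = None,
    n_reps: int = 3,
    seed=None,
) -> CountSim:
    """Synthetic sequencing counts for single/dual-contrast harnesses.

    Baseline gene abundances are drawn once from a long-tailed log-normal
    distribution (a synthetic stand-in for a deeply sequenced real library).
    Per replicate, counts are a multinomial downsample to *depth*, then each
    gene's count is multiplied by a noise factor
    ``f = log2(max(eps, Normal(2, noise_sd)))`` -- exactly 1 when
    ``noise_sd = 0``.  *fold_changes* maps gene set names (members looked up
    in *library*) to multiplicative case fold changes; a gene recruited in
    both directions (factors above and below 1) receives no fold change.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if not 0 <= noise_sd <= 0.6:
        raise ValidationError("noise_sd must be in [0, 0.6]")
    rng = _rng(seed)
    genes = gene_names(n_genes)
    abundance = rng.lognormal(mean=0.0, sigma=2.0, size=n_genes)

    gene_fc = pd.Series(1.0, index=genes)
    if fold_changes:
        if library is None:
            raise ValidationError("fold_changes given but no library to resolve members")
        per_gene: dict[str, list[float]] = {}
        for set_name, fc in fold_changes.items():
            for g in library[set_name].members:
                if g in gene_fc.index:
                    per_gene.setdefault(g, []).append(float(fc))
        for g, fcs in per_gene.items():
            up = any(f > 1 for f in fcs)
            down = any(f < 1 for f in fcs)
            if up and down:
                gene_fc[g] = 1.0
            elif up:
                gene_fc[g] = max(fcs)
            else:
                gene_fc[g] = min(fcs)

    def _matrix(base: np.ndarray) -> pd.DataFrame:
        p = base / base.sum()
        cols = {}
        for r in range(n_reps):
            counts = rng.multinomial(depth, p).astype(float)
            if noise_sd > 0:
                factors = np.log2(np.maximum(1e-9, rng.normal(2.0, noise_sd, size=n_genes)))
                counts = counts * factors
            cols[f"rep{r + 1}"] = np.round(counts)
        return pd.DataFrame(cols, index=genes)

    control = _matrix(abundance)
    case = _matrix(abundance * gene_fc.to_numpy())
    return CountSim(control=control, case=case, gene_fc=gene_fc)


def score_counts(case: pd.DataFrame, control: pd.DataFrame, contrast: str = "case_vs_control") -> pd.Series:
    """Per-gene Welch t statistic on log2 counts-per-million, as a DE score.

    A lightweight internal scorer producing ranking statistics for the
    simulation harness (case minus control on the log scale, so positive
    means up in case).
    """

    def _logcpm(mat: pd.DataFrame) -> np.ndarray:
        counts = mat.to_numpy(float)
        cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
        return np.log2(cpm + 0.5)

    a, b = _logcpm(case), _logcpm(control)
    t, _ = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    return pd.Series(t, index=case.index, name=contrast)
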