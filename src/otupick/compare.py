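"""Concordance statistics between OTU picking runs.

Two OTU picking protocols are judged concordant when, on the same samples,
they produce (i) highly correlated per-sample alpha diversities, (ii)
highly correlated beta-diversity distance matrices (Mantel test), and
(iii) matching per-sample taxonomic profiles. This module computes those
three families of statistics for a pair of runs after rarefying both OTU
tables to a common depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .diversity import beta_diversity_matrix, faith_pd, observed_otus
from .tables import collapse_taxonomy, rarefy

__all__ = [
    "UndefinedCorrelationError",
    "pearson_r",
    "mantel_test",
    "ConcordanceReport",
    "compare_runs",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance, n < 3)."""


def pearson_r(x, y) -> float:
    """Product-moment correlation of two paired value sequences.

    Requires at least 3 pairs and non-zero variance in each sequence;
    otherwise the correlation is undefined and an explicit error is raised
    rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 pairs for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: an input has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    mat = np.asarray(dm.data, dtype=float)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
                permutations: int = 1000, seed=None):
    """One-tailed Mantel test of positive association between matrices.

    r is the Pearson correlation over the strictly-upper-triangle entries.
    The null distribution jointly permutes rows and columns of the second
    matrix; the p-value uses the add-one rule
    ``p = (1 + #{r_perm >= r_obs}) / (1 + permutations)`` (ties count as
    exceeding, and p can never be 0). Both matrices must carry identical
    sample ids in identical order.
    """
    if list(dm_a.ids) != list(dm_b.ids):
        raise ValueError("distance matrices must have the same sample ids "
                         "in the same order")
    n = len(dm_a.ids)
    if n < 3:
        raise ValueError("Mantel test requires at least 3 samples")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    xa = _condensed(dm_a)
    mat_b = np.asarray(dm_b.data, dtype=float)
    iu = np.triu_indices(n, k=1)
    xb = mat_b[iu]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedCorrelationError(
            "Mantel r undefined: a distance matrix has zero variance "
            "off-diagonal")
    r_obs = float(np.corrcoef(xa, xb)[0, 1])

    rng = np.random.default_rng(seed)
    xa_c = xa - xa.mean()
    xa_norm = np.sqrt((xa_c ** 2).sum())
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = mat_b[np.ix_(perm, perm)][iu]
        xp_c = xp - xp.mean()
        denom = xa_norm * np.sqrt((xp_c ** 2).sum())
        r_perm = float(xa_c @ xp_c / denom) if denom > 0 else 1.0
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return r_obs, p


@dataclass
class ConcordanceReport:
    """Correlation summary of two OTU picking runs.

    ``alpha_r`` maps alpha metric name -> Pearson r across samples;
    ``beta`` maps beta metric name -> (Mantel r, p); ``taxa_r`` maps
    taxonomic rank depth -> Pearson r over pooled (sample, taxon) relative
    abundances.
    """

    alpha_r: dict[str, float]
    beta: dict[str, tuple[float, float]]
    taxa_r: dict[int, float]
    labels: tuple[str, str] = ("run_a", "run_b")
    depth: int = 0
    seed: int | None = None
    sample_ids: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for metric, r in self.alpha_r.items():
            rows.append(("alpha", metric, r, np.nan))
        for metric, (r, p) in self.beta.items():
            rows.append(("beta", metric, r, p))
        for level, r in self.taxa_r.items():
            rows.append(("taxa", f"rank_{level}", r, np.nan))
        return pd.DataFrame(rows, columns=["family", "metric", "r", "p"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")


def _taxa_concordance(table_a, table_b, level):
    prof_a = collapse_taxonomy(table_a, level)
    prof_b = collapse_taxonomy(table_b, level)
    taxa = sorted(set(prof_a.index) | set(prof_b.index))
    samples = list(prof_a.columns)
    va = prof_a.reindex(taxa).fillna(0.0)[samples].to_numpy().ravel()
    vb = prof_b.reindex(taxa).fillna(0.0)[samples].to_numpy().ravel()
    return pearson_r(va, vb)


def compare_runs(result_a, result_b, tree_a, tree_b, depth: int, seed,
                 permutations: int = 1000, levels=(2, 6),
                 labels=("run_a", "run_b"),
                 rarefaction_seeds=None) -> ConcordanceReport:
    """Full concordance report between two OTU picking results.

    Both runs' filtered tables are rarefied to ``depth`` reads per sample
    (samples below depth are dropped; only the shared surviving samples are
    compared, and at least 3 are required). Alpha diversity (observed OTUs
    and Faith's PD) is correlated per sample; weighted and unweighted
    UniFrac matrices are compared with the one-tailed Mantel test; taxa
    profiles are correlated at each requested rank depth over the union of
    taxa, absent taxa counting as 0.

    By default both tables are rarefied with the same derived seed, so a
    result compared against itself reports r = 1 for every statistic;
    ``rarefaction_seeds=(sa, sb)`` forces distinct draws to expose pure
    rarefaction noise.
    """
    ss = np.random.SeedSequence(seed)
    seed_r, seed_mantel = [int(c.generate_state(1)[0] % (2**31))
                           for c in ss.spawn(2)]
    seed_a, seed_b = (rarefaction_seeds if rarefaction_seeds is not None
                      else (seed_r, seed_r))
    rt_a = rarefy(result_a.table_filtered, depth, seed_a)
    rt_b = rarefy(result_b.table_filtered, depth, seed_b)
    shared = [s for s in rt_a.sample_ids if s in set(rt_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared samples above depth {depth}, got {len(shared)}")
    rt_a = rt_a.select_samples(shared)
    rt_b = rt_b.select_samples(shared)

    def _defined(func, *fargs, **fkwargs):
        # degenerate inputs (zero variance) are reported as undefined (None)
        # rather than aborting the whole report or propagating NaN
        try:
            return func(*fargs, **fkwargs)
        except UndefinedCorrelationError:
            return None

    alpha_r = {}
    obs_a = [observed_otus(rt_a.sample_counts(s)) for s in shared]
    obs_b = [observed_otus(rt_b.sample_counts(s)) for s in shared]
    alpha_r["observed_otus"] = _defined(pearson_r, obs_a, obs_b)
    pd_a = [_sample_pd(rt_a, tree_a, s) for s in shared]
    pd_b = [_sample_pd(rt_b, tree_b, s) for s in shared]
    alpha_r["faith_pd"] = _defined(pearson_r, pd_a, pd_b)

    beta = {}
    for metric in ("unweighted_unifrac", "weighted_unifrac"):
        dm_a = beta_diversity_matrix(rt_a, tree_a, metric)
        dm_b = beta_diversity_matrix(rt_b, tree_b, metric)
        beta[metric] = _defined(mantel_test, dm_a, dm_b,
                                permutations=permutations,
                                seed=seed_mantel) or (None, None)

    taxa_r = {level: _defined(_taxa_concordance, rt_a, rt_b, level)
              for level in levels}

    return ConcordanceReport(alpha_r=alpha_r, beta=beta, taxa_r=taxa_r,
                             labels=tuple(labels), depth=depth, seed=seed,
                             sample_ids=shared)


def _sample_pd(table, tree, sample_id):
    counts = table.sample_counts(sample_id)
    present = [o for o, v in counts.items() if v > 0]
    return faith_pd(tree, present)
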