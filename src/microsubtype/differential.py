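"""Differential-abundance screening and clinical-covariate association.

Two-stage LEfSe-style screen: a Kruskal-Wallis test per genus keeps taxa
with p below alpha, then each survivor gets a linear-discriminant effect
size — the bootstrap-averaged largest between-group difference of mean
abundance after rescaling relative abundances to [0, 1e6] — reported on a
log10 scale, so the conventional cutoff of 2 means a mean shift of at
least one part in ten thousand of the community.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, SampleMetadata, metadata_frame, normalize_tss
from .subtypes import contingency_chi2

LEFSE_SCALE = 1e6


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence,
    method: str = "chi2",
) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p by chi-square or permutation.

    ``method='permutation'`` enumerates every distinct assignment of the
    pooled values to the observed group sizes (feasible for n <= 12) and
    returns the exact tail probability P(H >= H_obs).  All-equal values are
    a defined degenerate case: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    if method == "chi2":
        return float(H), float(p)
    if method != "permutation":
        raise ValueError(f"method must be chi2|permutation, got {method!r}")
    n = values.size
    if n > 12:
        raise ValueError("exact permutation p limited to n <= 12")
    sizes = [len(s) for s in samples]
    hits = total = 0
    for assignment in _multiset_assignments(n, sizes):
        perm_samples = [values[list(ix)] for ix in assignment]
        h = _h_statistic(perm_samples)
        total += 1
        if h >= H - 1e-12:
            hits += 1
    return float(H), hits / total


def _h_statistic(samples: list[np.ndarray]) -> float:
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0
    ranks = stats.rankdata(pooled)
    n = pooled.size
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start:start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _multiset_assignments(n: int, sizes: list[int]) -> Iterable[tuple[tuple[int, ...], ...]]:
    """All ways to split indices 0..n-1 into ordered groups of given sizes."""

    def rec(remaining: frozenset, sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(sorted(remaining), k):
            for rest in rec(remaining - set(combo), sizes_left[1:]):
                yield (combo,) + rest

    yield from rec(frozenset(range(n)), sizes)


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment; order-preserving, monotone for BH."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if method == "none":
        return p.copy()
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"method must be BH|bonferroni|none, got {method!r}")
    return multipletests(p, method=key)[1]


def lda_effect_size(
    table: AbundanceTable,
    groups: Sequence,
    alpha: float = 0.05,
    lda_cutoff: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Two-stage differential screen: KW filter, then LDA-style effect size.

    Returns a frame (taxon, H, p, q, lda_score, enriched_group) containing
    the taxa passing both the KW alpha and the log10 effect cutoff, sorted
    by descending score.  Groups with fewer than ``min_group_size`` samples
    are excluded with a warning.
    """
    rel = table if table.is_relative else normalize_tss(table)
    groups = pd.Series(list(groups), index=rel.data.index)
    sizes = groups.value_counts()
    small = sizes[sizes < min_group_size].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < {min_group_size} samples: {small}",
                      stacklevel=2)
        keep = ~groups.isin(small)
        rel_data = rel.data.loc[keep]
        groups = groups.loc[keep]
    else:
        rel_data = rel.data
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups after size filtering")

    scaled = rel_data.to_numpy() * LEFSE_SCALE
    labels = groups.to_numpy()
    group_idx = {g: np.flatnonzero(labels == g) for g in uniq}

    records = []
    pvals = {}
    for j, taxon in enumerate(rel_data.columns):
        col = scaled[:, j]
        if np.all(col == col[0]):
            pvals[taxon] = (0.0, 1.0)
        else:
            pvals[taxon] = stats.kruskal(*[col[ix] for ix in group_idx.values()])
    qvals = adjust_pvalues([pvals[t][1] for t in rel_data.columns])
    qmap = dict(zip(rel_data.columns, qvals))

    rng = np.random.default_rng(seed)
    for j, taxon in enumerate(rel_data.columns):
        H, p = pvals[taxon]
        if alpha <= 0 or p >= alpha:
            continue
        col = scaled[:, j]
        effects = []
        for _ in range(n_boot):
            means = []
            for g in uniq:
                ix = group_idx[g]  # resample within group, with replacement
                means.append(col[ix[rng.integers(0, ix.size, ix.size)]].mean())
            means = np.asarray(means)
            effects.append(means.max() - means.min())
        effect = float(np.mean(effects))
        score = math.log10(max(abs(effect), 1.0))
        if score < lda_cutoff:
            continue
        group_means = {g: col[group_idx[g]].mean() for g in uniq}
        enriched = max(sorted(group_means), key=lambda g: group_means[g])
        records.append(
            {"taxon": taxon, "H": float(H), "p": float(p), "q": float(qmap[taxon]),
             "lda_score": score, "enriched_group": enriched}
        )
    frame = pd.DataFrame.from_records(
        records, columns=["taxon", "H", "p", "q", "lda_score", "enriched_group"]
    )
    return frame.sort_values(["lda_score", "taxon"], ascending=[False, True]).reset_index(drop=True)


def kw_screen(
    table: AbundanceTable, groups: Sequence, alpha: float = 0.05
) -> pd.DataFrame:
    """Plain per-taxon Kruskal-Wallis screen (no effect-size stage).

    Returns all taxa with H, p, q and a boolean ``significant`` at alpha.
    """
    rel = table if table.is_relative else normalize_tss(table)
    labels = np.asarray(list(groups))
    uniq = pd.unique(labels)
    idx = [np.flatnonzero(labels == g) for g in uniq]
    X = rel.data.to_numpy()
    rows = []
    for j, taxon in enumerate(rel.data.columns):
        col = X[:, j]
        if np.all(col == col[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*[col[ix] for ix in idx])
        rows.append({"taxon": taxon, "H": float(h), "p": float(p)})
    frame = pd.DataFrame(rows)
    frame["q"] = adjust_pvalues(frame["p"].to_numpy())
    frame["significant"] = frame["p"] < alpha
    return frame


def clinical_association(
    meta: Sequence[SampleMetadata] | pd.DataFrame, strata: Sequence
) -> pd.DataFrame:
    """Test each clinical covariate against the strata.

    Numeric covariates use Kruskal-Wallis across strata; categorical ones a
    Pearson chi-square on the covariate x stratum contingency table.
    Missing values drop pairwise per covariate; constant covariates are
    skipped with a note.
    """
    frame = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    strata = pd.Series(list(strata), index=frame.index)
    if strata.nunique() < 2:
        raise ValueError("need at least two strata")
    rows = []
    for cov in frame.columns:
        if cov == "disease":
            continue
        col = frame[cov]
        mask = col.notna()
        sub, st = col[mask], strata[mask]
        note = ""
        if sub.nunique() <= 1:
            rows.append({"covariate": cov, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "constant covariate"})
            continue
        if pd.api.types.is_numeric_dtype(sub):
            h, p = kruskal_wallis(sub.to_numpy(dtype=float), st.to_numpy())
            rows.append({"covariate": cov, "test": "kruskal-wallis",
                         "statistic": h, "p": p, "note": note})
        else:
            tab = pd.crosstab(sub, st).to_numpy()
            stat, _, p = contingency_chi2(tab)
            rows.append({"covariate": cov, "test": "chi-square",
                         "statistic": stat, "p": p, "note": note})
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p", "note"])


def common_differential(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[set[str], dict[str, int], float]:
    """Overlap of two differential-taxa sets; percentage is of the union."""
    a, b = set(set_a), set(set_b)
    inter, union = a & b, a | b
    counts = {"a": len(a), "b": len(b), "common": len(inter), "union": len(union)}
    pct = 0.0 if not union else round(100.0 * len(inter) / len(union), 2)
    return inter, counts, pct
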