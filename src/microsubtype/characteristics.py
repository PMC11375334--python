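"""Spearman correlation screens and per-sample gut microbial characteristics.

Correlation with a disease or subtype is computed as the Spearman rank
correlation between a quantity (taxon relative abundance or a
characteristic score) and the 0/1 membership indicator of the group — the
rank-biserial-direction construct commonly plotted as correlation heat
maps in microbiome studies.

Fifteen per-sample community characteristics summarize the gut profile:
richness, enterotype (dominant marker genus among Prevotella, Bacteroides,
Ruminococcus), Firmicutes/Bacteroidetes ratio, obligate-anaerobe and
facultative-anaerobe content, counts and summed content of beneficial,
harmful and gram-positive taxa, a beneficial/harmful log-ratio balance
score, Shannon diversity (natural log), oxidative-stress tolerance
(content of aerotolerant taxa) and biofilm formation (content of
biofilm-forming taxa).  Balance, oxidative tolerance and biofilm scores
are declared annotation-driven surrogates — they are simple functionals of
the supplied trait table, not literature-fitted indices.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, TaxonTraitTable, normalize_tss

ENTEROTYPE_MARKERS = ("Prevotella", "Bacteroides", "Ruminococcus")
BALANCE_EPS = 1e-6

CHARACTERISTIC_COLUMNS = [
    "richness", "enterotype", "fb_ratio", "anaerobe_content",
    "facultative_content", "beneficial_count", "beneficial_content",
    "harmful_count", "harmful_content", "balance_score", "diversity_index",
    "grampos_count", "grampos_content", "oxidative_tolerance", "biofilm_score",
]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman rho and its t-approximation p-value.

    Zero variance in either vector leaves the correlation undefined:
    (nan, nan) is returned rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def significance_tier(p: float) -> str:
    """Star annotation used on the correlation heat maps."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def membership_indicators(labels: Sequence) -> pd.DataFrame:
    """One 0/1 indicator column per distinct group label."""
    s = pd.Series(list(labels))
    return pd.get_dummies(s).astype(int)


def correlation_screen(
    features: pd.DataFrame | AbundanceTable,
    indicators: pd.DataFrame,
    threshold: float = 0.14,
) -> pd.DataFrame:
    """Spearman r/p of every feature against every group indicator.

    Returns a tidy frame (feature, group, r, p, tier, shown); ``shown``
    applies the display mask |r| > threshold without touching stored
    values.  Row order of features and indicators must align.
    """
    if isinstance(features, AbundanceTable):
        feat = (features if features.is_relative else normalize_tss(features)).data
    else:
        feat = features
    if len(feat) != len(indicators):
        raise ValueError("features and indicators must have equal row counts")
    ind = indicators.to_numpy(dtype=float)
    rows = []
    for name in feat.columns:
        col = feat[name]
        if not pd.api.types.is_numeric_dtype(col):
            col = pd.Series(pd.factorize(col, sort=True)[0], index=col.index)
        x = col.to_numpy(dtype=float)
        for g, grp in enumerate(indicators.columns):
            r, p = spearman(x, ind[:, g])
            rows.append(
                {
                    "feature": name,
                    "group": grp,
                    "r": r,
                    "p": p,
                    "tier": significance_tier(p),
                    "shown": bool(np.isfinite(r) and abs(r) > threshold),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# characteristics


def _phylum_mass(rel: AbundanceTable, names: set[str]) -> np.ndarray:
    cols = [t for t in rel.taxon_ids if rel.phylum_of(t) in names]
    if not cols:
        return np.zeros(rel.shape[0])
    return rel.data[cols].to_numpy().sum(axis=1)


def enterotype_labels(
    rel: AbundanceTable, method: str = "dominant", seed: int = 0
) -> pd.Series:
    """Per-sample enterotype among the three classical marker regimes.

    ``dominant`` (default): the marker genus with the highest relative
    abundance in the sample, ties broken alphabetically; samples where all
    three markers are absent get ``unknown``.  ``jsd``: cohort-level
    partitioning around medoids (k=3) on Jensen-Shannon distances, each
    medoid cluster named after its most abundant marker.
    """
    markers = [m for m in ENTEROTYPE_MARKERS if m in rel.taxon_ids]
    if method == "dominant":
        out = []
        for _, row in rel.data.iterrows():
            vals = {m: row.get(m, 0.0) for m in markers}
            if not vals or max(vals.values()) <= 0:
                out.append("unknown")
            else:
                out.append(min(sorted(vals), key=lambda m: (-vals[m], m)))
        return pd.Series(out, index=rel.data.index, name="enterotype")
    if method != "jsd":
        raise ValueError(f"method must be dominant|jsd, got {method!r}")
    X = rel.values()
    n = X.shape[0]
    P = X / np.maximum(X.sum(axis=1, keepdims=True), 1e-12)

    def jsd(a, b):
        m = (a + b) / 2
        def kl(p, q):
            mask = p > 0
            return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], 1e-12))))
        return (kl(a, m) + kl(b, m)) / 2

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jsd(P[i], P[j])
    # deterministic farthest-point seeding: most central sample first, then
    # greedily the sample farthest from its nearest chosen medoid
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < min(3, n):
        nearest = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(nearest)))
    for _ in range(25):  # PAM-style alternation
        assign = np.argmin(D[:, medoids], axis=1)
        new = []
        for k in range(len(medoids)):
            members = np.flatnonzero(assign == k)
            if members.size == 0:
                new.append(medoids[k])
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new.append(int(members[np.argmin(costs)]))
        if new == medoids:
            break
        medoids = new
    assign = np.argmin(D[:, medoids], axis=1)
    names = []
    for k in range(len(medoids)):
        members = np.flatnonzero(assign == k)
        means = {m: rel.data[m].iloc[members].mean() if m in rel.taxon_ids else 0.0
                 for m in ENTEROTYPE_MARKERS}
        names.append(min(sorted(means), key=lambda m: (-means[m], m)))
    return pd.Series([names[k] for k in assign], index=rel.data.index, name="enterotype")


def characteristics(
    table: AbundanceTable,
    traits: TaxonTraitTable,
    enterotype_method: str = "dominant",
) -> pd.DataFrame:
    """Compute the fifteen per-sample gut microbial characteristics."""
    rel = table if table.is_relative else normalize_tss(table)
    counts_present = table.values() > 0
    taxa = rel.taxon_ids
    trait_of = {t: traits.lookup(t) for t in taxa}

    def mask(field: str, values: set[str]) -> np.ndarray:
        return np.array([trait_of[t][field] in values for t in taxa])

    rel_values = rel.values()
    beneficial = mask("role", {"beneficial"})
    harmful = mask("role", {"harmful"})
    grampos = mask("gram", {"positive"})
    anaerobe = mask("oxygen", {"obligate_anaerobe"})
    facultative = mask("oxygen", {"facultative_anaerobe"})
    aerotolerant = mask("oxygen", {"aerobe", "facultative_anaerobe"})
    biofilm = mask("biofilm", {"yes"})

    def content(m: np.ndarray) -> np.ndarray:
        return rel_values[:, m].sum(axis=1) if m.any() else np.zeros(rel.shape[0])

    def present_count(m: np.ndarray) -> np.ndarray:
        return counts_present[:, m].sum(axis=1) if m.any() else np.zeros(rel.shape[0], dtype=int)

    firmicutes = _phylum_mass(rel, {"Firmicutes", "Bacillota"})
    bacteroidetes = _phylum_mass(rel, {"Bacteroidetes", "Bacteroidota"})
    have_phyla = any(rel.phylum_of(t) for t in taxa)
    if not have_phyla:
        warnings.warn("no phylum annotations; fb_ratio reported missing", stacklevel=2)
        fb = np.full(rel.shape[0], np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fb = np.where(
                bacteroidetes > 0,
                firmicutes / np.maximum(bacteroidetes, 1e-300),
                np.where(firmicutes > 0, np.inf, np.nan),
            )

    p = rel_values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)

    ben_c, harm_c = content(beneficial), content(harmful)
    frame = pd.DataFrame(
        {
            "richness": counts_present.sum(axis=1),
            "enterotype": enterotype_labels(rel, method=enterotype_method),
            "fb_ratio": fb,
            "anaerobe_content": content(anaerobe),
            "facultative_content": content(facultative),
            "beneficial_count": present_count(beneficial),
            "beneficial_content": ben_c,
            "harmful_count": present_count(harmful),
            "harmful_content": harm_c,
            "balance_score": np.log10((ben_c + BALANCE_EPS) / (harm_c + BALANCE_EPS)),
            "diversity_index": shannon,
            "grampos_count": present_count(grampos),
            "grampos_content": content(grampos),
            "oxidative_tolerance": content(aerotolerant),
            "biofilm_score": content(biofilm),
        },
        index=rel.data.index,
    )
    return frame[CHARACTERISTIC_COLUMNS]
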