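"""Disease-ratio tables and the merging of clusters into risk subtypes.

Each consensus cluster gets exact integer disease counts (CRC, AA, NC) and
ratio columns AA/NC, CRC/NC and (CRC+AA)/NC kept as exact rationals; the
2-decimal display values round half-away-from-zero so printed tables are
reproduced digit-for-digit.  Clusters are then binned into lettered
subtypes either by explicit ratio breakpoints or by exact 1-D
dynamic-programming clustering of log-ratios into a requested number of
groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .tables import DISEASE_LABELS, SampleMetadata, metadata_frame


def round_half_away(value: Fraction | float, digits: int = 2) -> float:
    """Round to ``digits`` decimals, halves away from zero, exactly.

    Uses integer arithmetic on Fractions so 8.235 -> 8.24 and 2.0357 -> 2.04
    without binary-float surprises.
    """
    frac = Fraction(value) if not isinstance(value, Fraction) else value
    scaled = frac * 10**digits
    if scaled >= 0:
        q = (scaled.numerator * 2 + scaled.denominator) // (2 * scaled.denominator)
    else:
        q = -((-scaled.numerator * 2 + scaled.denominator) // (2 * scaled.denominator))
    return q / 10**digits


@dataclass
class ClusterRatioTable:
    """Per-cluster disease counts with exact and display ratios."""

    frame: pd.DataFrame  # index: cluster id; columns below
    exact: dict[str, dict[str, Fraction | float]]  # cluster -> ratio name -> exact value

    COUNT_COLS = ["CRC", "AA", "NC", "Sum", "CRC+NC", "CRC+AA", "AA+NC"]
    RATIO_COLS = ["AA/NC", "CRC/NC", "CRC+AA/NC"]

    def ratio(self, cluster: str, name: str = "CRC+AA/NC"):
        return self.exact[cluster][name]

    def margins(self) -> tuple[int, int, int, int]:
        f = self.frame.drop(index="Sum", errors="ignore")
        return (
            int(f["CRC"].sum()),
            int(f["AA"].sum()),
            int(f["NC"].sum()),
            int(f["Sum"].sum()),
        )

    @property
    def clusters(self) -> list[str]:
        return [c for c in self.frame.index if c != "Sum"]


def _ratios_from_counts(crc: int, aa: int, nc: int) -> dict[str, Fraction | float]:
    def ratio(num: int) -> Fraction | float:
        if nc > 0:
            return Fraction(num, nc)
        return math.inf if num > 0 else Fraction(0)

    return {"AA/NC": ratio(aa), "CRC/NC": ratio(crc), "CRC+AA/NC": ratio(crc + aa)}


def ratio_table_from_counts(counts: dict[str, tuple[int, int, int]]) -> ClusterRatioTable:
    """Build the ratio table from explicit per-cluster (CRC, AA, NC) counts."""
    rows, exact = [], {}
    for cluster, (crc, aa, nc) in counts.items():
        if min(crc, aa, nc) < 0:
            raise ValueError(f"negative count for cluster {cluster}")
        ratios = _ratios_from_counts(crc, aa, nc)
        exact[cluster] = ratios
        display = {
            name: (math.inf if val == math.inf else round_half_away(val))
            for name, val in ratios.items()
        }
        rows.append(
            {
                "cluster": cluster,
                "CRC": crc,
                "AA": aa,
                "NC": nc,
                "Sum": crc + aa + nc,
                "CRC+NC": crc + nc,
                "CRC+AA": crc + aa,
                "AA+NC": aa + nc,
                **display,
            }
        )
    frame = pd.DataFrame(rows).set_index("cluster")
    total = {
        "CRC": frame["CRC"].sum(),
        "AA": frame["AA"].sum(),
        "NC": frame["NC"].sum(),
        "Sum": frame["Sum"].sum(),
    }
    frame.loc["Sum", list(total)] = list(total.values())
    count_cols = ["CRC", "AA", "NC", "Sum", "CRC+NC", "CRC+AA", "AA+NC"]
    frame[count_cols] = frame[count_cols].astype("Int64")
    return ClusterRatioTable(frame=frame, exact=exact)


def disease_ratio_table(
    labels: Sequence, meta: Sequence[SampleMetadata] | pd.DataFrame,
    cluster_prefix: str = "C",
) -> ClusterRatioTable:
    """Cross-tabulate cluster labels against disease and derive ratios.

    ``labels`` aligns positionally with ``meta`` (or with the frame's rows).
    Integer cluster ids are displayed as C1, C2, ...
    """
    frame = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    labels = list(labels)
    if len(labels) != len(frame):
        raise ValueError(
            f"{len(labels)} labels for {len(frame)} samples"
        )
    diseases = frame["disease"].tolist()
    bad = sorted({d for d in diseases if d not in DISEASE_LABELS})
    if bad:
        raise ValueError(f"unknown disease labels: {bad}")

    def name(c) -> str:
        return c if isinstance(c, str) else f"{cluster_prefix}{int(c)}"

    counts: dict[str, list[int]] = {}
    for lab, dis in zip(labels, diseases):
        row = counts.setdefault(name(lab), [0, 0, 0])
        row[DISEASE_LABELS.index(dis)] += 1

    def sort_key(c: str):
        tail = c[len(cluster_prefix):] if c.startswith(cluster_prefix) else c
        return (0, int(tail)) if tail.isdigit() else (1, c)

    ordered = {c: tuple(counts[c]) for c in sorted(counts, key=sort_key)}
    return ratio_table_from_counts(ordered)


# ---------------------------------------------------------------------------
# subtype merging


@dataclass
class SubtypeMap:
    """Total partition of clusters into lettered subtypes."""

    assignment: dict[str, str]  # cluster id -> subtype letter
    breakpoints: tuple[float, ...]

    def members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cluster, subtype in self.assignment.items():
            out.setdefault(subtype, set()).add(cluster)
        return out

    def sample_subtypes(self, cluster_labels: Sequence) -> list[str]:
        def name(c) -> str:
            return c if isinstance(c, str) else f"C{int(c)}"

        return [self.assignment[name(c)] for c in cluster_labels]


def _dp_breakpoints(values: list[float], groups: int) -> tuple[float, ...]:
    """Optimal 1-D grouping of sorted values into ``groups`` contiguous bins.

    Exact dynamic program minimizing within-group sum of squared deviations
    (Fisher/ckmeans style); returns breakpoints placed halfway between
    adjacent groups.  Ties in cost resolve toward earlier splits, making the
    result deterministic.
    """
    xs = sorted(values)
    n = len(xs)
    groups = min(groups, n)
    prefix = np.concatenate([[0.0], np.cumsum(xs)])
    prefix2 = np.concatenate([[0.0], np.cumsum(np.square(xs))])

    def sse(i: int, j: int) -> float:  # cost of xs[i:j]
        s, s2, m = prefix[j] - prefix[i], prefix2[j] - prefix2[i], j - i
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    cost = np.full((groups + 1, n + 1), INF)
    split = np.zeros((groups + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, groups + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                c = cost[g - 1, i] + sse(i, j)
                if c < cost[g, j] - 1e-12:
                    cost[g, j] = c
                    split[g, j] = i
    bounds = []
    j = n
    for g in range(groups, 0, -1):
        i = split[g, j]
        bounds.append(i)
        j = i
    cuts = sorted(b for b in bounds if 0 < b < n)
    return tuple((xs[c - 1] + xs[c]) / 2.0 for c in cuts)


def merge_clusters(
    table: ClusterRatioTable,
    breakpoints: Sequence[float] | None = None,
    target_groups: int | None = None,
    band_labels: Sequence[str] | None = None,
) -> SubtypeMap:
    """Bin clusters into subtypes by their (CRC+AA)/NC disease ratio.

    With explicit ``breakpoints`` each cluster joins the band its ratio
    falls in; a ratio exactly equal to a breakpoint joins the upper band
    (half-open bins, closed below on the upper side).  With
    ``target_groups`` the breakpoints come from exact 1-D DP clustering of
    log10-ratios (clusters with infinite ratio are forced into the top
    band).  Subtype letters default to A, B, C, ... walking bands from the
    highest ratio down; ``band_labels`` overrides that lettering — the
    published preset uses (B, C, A, D).
    """
    if (breakpoints is None) == (target_groups is None):
        raise ValueError("supply exactly one of breakpoints or target_groups")
    clusters = table.clusters
    ratios = {c: table.ratio(c) for c in clusters}

    if breakpoints is not None:
        bp = tuple(float(b) for b in breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError(f"breakpoints must be strictly increasing: {bp}")
    else:
        if not 1 <= target_groups <= len(clusters):
            raise ValueError(
                f"target_groups must be in [1, {len(clusters)}], got {target_groups}"
            )
        finite = {c: r for c, r in ratios.items() if r != math.inf}
        infinite = [c for c in clusters if ratios[c] == math.inf]
        logs = [math.log10(float(r)) if r > 0 else math.log10(1e-6) for r in finite.values()]
        g = target_groups - (1 if infinite and target_groups > 1 else 0)
        log_bp = _dp_breakpoints(logs, max(g, 1))
        bp = tuple(10.0**b for b in log_bp)
        if infinite and target_groups > 1:
            top = max((float(r) for r in finite.values()), default=0.0)
            bp = bp + (top * 10 + 1,)

    # band index: 0 = below first breakpoint ... len(bp) = top band
    def band(r) -> int:
        if r == math.inf:
            return len(bp)
        x = float(r)
        b = 0
        for cut in bp:
            if x >= cut:  # equal to a breakpoint -> upper band
                b += 1
        return b

    bands = {c: band(r) for c, r in ratios.items()}
    occupied = sorted(set(bands.values()), reverse=True)  # descending ratio
    if band_labels is not None:
        if len(band_labels) < len(occupied):
            raise ValueError(
                f"{len(occupied)} occupied bands but only {len(band_labels)} labels"
            )
        letters = list(band_labels)
    else:
        letters = [chr(ord("A") + i) for i in range(len(occupied))]
    label_of = {b: letters[i] for i, b in enumerate(occupied)}
    return SubtypeMap(
        assignment={c: label_of[bands[c]] for c in clusters}, breakpoints=bp
    )


# ---------------------------------------------------------------------------
# chi-square on contingency tables


def contingency_chi2(table: Sequence[Sequence[float]] | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of an R x C count table: (statistic, df, p).

    Zero-margin rows/columns carry no information for the test and are
    dropped with a warning before computing expected counts.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            "dropping zero-margin rows/columns before chi-square", stacklevel=2
        )
        arr = arr[row_ok][:, col_ok]
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")
    stat, p, df, _ = chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)
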