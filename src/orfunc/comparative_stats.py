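"""Sequence-vs-function statistics for receptor ortholog/paralog sets.

Functional distance between two receptors is 1 - R, the complement of the
Pearson correlation of their odor-panel response profiles; receptors
responding to too few odors are excluded (their profile carries little
signal). Sequence metrics (Jukes-Cantor, Grantham, dN/dS) are then related
to functional distance by Spearman rank correlation, common-ligand response
rates are tabulated per stratum, and Grantham distributions of orthologs vs
paralogs are compared by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FunctionalDistanceRecord:
    id_a: str
    id_b: str
    r: float
    distance: float          # 1 - R; NaN when excluded or undefined
    n_responsive_a: int
    n_responsive_b: int
    included: bool
    undefined: bool = False  # zero-variance profile


def functional_distance(
    resp_a: np.ndarray,
    resp_b: np.ndarray,
    min_responsive: int = 3,
    id_a: str = "a",
    id_b: str = "b",
) -> FunctionalDistanceRecord:
    """1 - Pearson R over two aligned odor-response vectors.

    Vectors are expected to be the display copies (non-significant responses
    zeroed); responsiveness per member is the count of nonzero entries, and a
    pair is excluded when either member responds to fewer than
    ``min_responsive`` odors (default >= 3; the stricter > 3 reading is
    min_responsive=4).
    """
    a = np.asarray(resp_a, dtype=float)
    b = np.asarray(resp_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("response vectors must have identical length and odor order")
    n_a = int(np.count_nonzero(a))
    n_b = int(np.count_nonzero(b))
    included = n_a >= min_responsive and n_b >= min_responsive
    if a.std() == 0 or b.std() == 0:
        return FunctionalDistanceRecord(id_a, id_b, float("nan"), float("nan"),
                                        n_a, n_b, included, undefined=True)
    r = float(stats.pearsonr(a, b).statistic)
    dist = 1.0 - r if included else float("nan")
    return FunctionalDistanceRecord(id_a, id_b, r, dist, n_a, n_b, included)


@dataclass(frozen=True)
class RankCorrelation:
    rs: float
    p: float
    n: int
    defined: bool


def rank_correlation(x, y) -> RankCorrelation:
    """Spearman rank correlation (mid-rank ties, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return RankCorrelation(float("nan"), float("nan"), x.size, False)
    res = stats.spearmanr(x, y)
    return RankCorrelation(float(res.statistic), float(res.pvalue), x.size, True)


@dataclass(frozen=True)
class CommonLigandRate:
    responders: int
    total: int

    @property
    def fraction(self) -> float:
        return self.responders / self.total

    @property
    def percent(self) -> int:
        """Whole-percent display rounding; exact counts are always carried."""
        return round(100.0 * self.fraction)


def common_ligand_rate(table: pd.DataFrame, **stratum) -> CommonLigandRate:
    """Fraction of comparison receptors responding to the group's common ligand.

    ``table`` needs a boolean ``responded`` column; keyword filters select a
    stratum by equality on any other column (e.g. relationship="ortholog",
    species_pair="human-chimp").
    """
    sub = table
    for col, val in stratum.items():
        sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError(f"empty stratum {stratum!r}")
    return CommonLigandRate(int(sub["responded"].sum()), int(len(sub)))


@dataclass(frozen=True)
class RankSumResult:
    z: float
    p: float
    defined: bool


def ranksum_compare(group_a, group_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum with normal approximation and tie correction.

    Sign convention: z < 0 when group_a is stochastically smaller than
    group_b. No continuity correction, so identical groups give exactly
    z = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return RankSumResult(float("nan"), float("nan"), False)
    z = (w - mean_w) / np.sqrt(var_w)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(float(z), float(p), True)


def summarize_distribution(values) -> dict[str, float]:
    """Box-plot order statistics: extremes, 10/25/50/75/90% quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need >= 1 value")
    qs = np.quantile(v, [0.10, 0.25, 0.50, 0.75, 0.90])
    return {
        "min": float(v.min()),
        "q10": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q90": float(qs[4]),
        "max": float(v.max()),
    }


def seq_func_table(
    seq_metrics: pd.DataFrame,
    screen,
    min_responsive: int = 3,
) -> pd.DataFrame:
    """Join per-pair sequence metrics with screen-derived functional distance.

    ``seq_metrics`` is the pairwise-metric table (id_a, id_b, jc,
    grantham_orf, grantham_22aa, omega, ...); ``screen`` is an
    agonist-called ScreenMatrix whose receptors include both pair members.
    Adds columns r, functional_distance, included.
    """
    rows = []
    for _, row in seq_metrics.iterrows():
        ra = screen.responses(row["id_a"])
        rb = screen.responses(row["id_b"]).reindex(ra.index)
        rec = functional_distance(ra.to_numpy(), rb.to_numpy(),
                                  min_responsive=min_responsive,
                                  id_a=row["id_a"], id_b=row["id_b"])
        out = dict(row)
        out.update(
            r=rec.r,
            functional_distance=rec.distance,
            n_responsive_a=rec.n_responsive_a,
            n_responsive_b=rec.n_responsive_b,
            included=rec.included,
        )
        rows.append(out)
    return pd.DataFrame(rows)
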