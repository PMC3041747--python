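"""Statistical comparisons: rank tests, GC-energy regression, GC-matched
bins, distance-controlled pairing, and the tissue-specificity rule.

Rank tests switch to exact enumeration for small samples (total n <= 12 for
the rank-sum test, <= 12 non-zero diffs for the signed-rank test) and to the
tie-corrected normal approximation via scipy otherwise.  No multiple-testing
correction is applied anywhere; raw p-values are reported with their n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 12


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group or paired comparison with its sizes, means and p-value."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    paired: bool

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary (slope in kcal/mol per GC unit)."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Wilcoxon rank-sum / Mann-Whitney test.

    Exact enumeration of all group assignments when n_a + n_b <= 12
    (mid-ranks, so ties are handled identically in both modes); otherwise
    the tie-corrected normal approximation.  Alternatives are with respect
    to ``a`` vs ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0
        stat = float(len(a) * (len(a) + len(b) + 1) / 2)
    elif len(pooled) <= EXACT_LIMIT:
        stat, p = _exact_rank_sum(a, b, alternative)
    else:
        res = sps.mannwhitneyu(a, b, alternative=_scipy_alt(alternative), method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        label_a, label_b, len(a), len(b),
        float(a.mean()), float(b.mean()), stat, min(p, 1.0), paired=False,
    )


def _scipy_alt(alternative: str) -> str:
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return alternative


def _exact_rank_sum(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    _scipy_alt(alternative)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    mean_w = na * (n + 1) / 2.0
    ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), na)])
    eps = 1e-9
    if alternative == "greater":
        p = np.mean(ws >= w_obs - eps)
    elif alternative == "less":
        p = np.mean(ws <= w_obs + eps)
    else:
        p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - eps)
    return float(w_obs), float(p)


def signed_rank_test(
    diffs: Sequence[float],
    alternative: str = "two-sided",
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired differences (zeros dropped).

    Exact sign enumeration (2^m assignments, mid-ranks on |diffs|) when the
    number of non-zero differences m <= 12; scipy's implementation
    otherwise.  ``alternative='greater'`` tests for positive location.
    """
    _scipy_alt(alternative)
    diffs = np.asarray(diffs, dtype=float)
    n_all = len(diffs)
    if n_all < 1:
        raise ValueError("no differences supplied")
    mean_d = float(diffs.mean())
    nz = diffs[diffs != 0]
    m = len(nz)
    if m == 0:
        return ComparisonResult(label_a, label_b, n_all, n_all, mean_d, 0.0, 0.0, 1.0, True)
    if m <= EXACT_LIMIT:
        ranks = _midranks(np.abs(nz))
        w_obs = ranks[nz > 0].sum()
        total = ranks.sum()
        eps = 1e-9
        # enumerate all sign assignments
        ws = np.zeros(1)
        for r in ranks:
            ws = np.concatenate([ws, ws + r])
        if alternative == "greater":
            p = np.mean(ws >= w_obs - eps)
        elif alternative == "less":
            p = np.mean(ws <= w_obs + eps)
        else:
            center = total / 2.0
            p = np.mean(np.abs(ws - center) >= abs(w_obs - center) - eps)
        stat = float(w_obs)
    else:
        if m < 6:
            raise ValueError("need >= 6 non-zero differences for the approximation")
        res = sps.wilcoxon(nz, alternative=alternative, method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        label_a, label_b, n_all, n_all, mean_d, 0.0, stat, min(float(p), 1.0), True
    )


def gc_energy_regression(points: Iterable[tuple[float, float]]) -> RegressionResult:
    """OLS of MFE on GC plus Pearson correlation."""
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    gc, mfe = pts[:, 0], pts[:, 1]
    if np.all(gc == gc[0]):
        raise ValueError("GC values are constant; regression undefined")
    res = sps.linregress(gc, mfe)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(pts),
    )


DEFAULT_GC_BINS = tuple((c - 2, c + 2) for c in (50, 60, 70, 80))


def gc_matched_compare(
    groups: dict[str, Sequence[tuple[int, float]]],
    bins: Sequence[tuple[int, int]] = DEFAULT_GC_BINS,
    pair: tuple[str, str] | None = None,
) -> list[tuple[tuple[int, int], ComparisonResult | None]]:
    """Compare group energies within GC-number bins.

    ``groups`` maps a label to (gc_number, mfe) tuples.  Within each bin
    (inclusive bounds) the two labels of ``pair`` (default: the first two)
    are compared with a rank-sum test; bins with fewer than 2 windows in
    either group are reported as skipped (result ``None``).
    """
    labels = list(groups)
    if pair is None:
        if len(labels) < 2:
            raise ValueError("need at least two groups")
        pair = (labels[0], labels[1])
    la, lb = pair
    out: list[tuple[tuple[int, int], ComparisonResult | None]] = []
    any_tested = False
    for lo, hi in bins:
        sel_a = [m for g, m in groups[la] if lo <= g <= hi]
        sel_b = [m for g, m in groups[lb] if lo <= g <= hi]
        if len(sel_a) < 2 or len(sel_b) < 2:
            out.append(((lo, hi), None))
            continue
        any_tested = True
        out.append(((lo, hi), rank_sum_test(sel_a, sel_b, label_a=la, label_b=lb)))
    if not any_tested:
        raise ValueError("no GC bin had >= 2 windows in both groups")
    return out


def distance_controlled_pairs(
    alt_sites: Sequence[tuple[object, float]],
    ref_sites: Sequence[tuple[object, float]],
    max_dist: int = 3000,
) -> tuple[list[tuple[object, object]], ComparisonResult]:
    """Pair each alternative site with its nearest reference within max_dist.

    Sites are (record, mfe) tuples where the record has ``seq_name``,
    ``strand`` and ``junction_pos``.  Distance ties are broken toward the
    upstream (smaller coordinate) reference.  Returns the pairs plus a
    paired signed-rank test of alt minus reference energies.
    """
    by_loc: dict[tuple[str, str], list[tuple[object, float]]] = {}
    for rec, mfe in ref_sites:
        by_loc.setdefault((rec.seq_name, rec.strand), []).append((rec, mfe))
    pairs = []
    diffs = []
    for rec, mfe in alt_sites:
        candidates = by_loc.get((rec.seq_name, rec.strand), [])
        best = None
        for ref, ref_mfe in candidates:
            d = abs(ref.junction_pos - rec.junction_pos)
            if d > max_dist:
                continue
            key = (d, ref.junction_pos)
            if best is None or key < best[0]:
                best = (key, ref, ref_mfe)
        if best is not None:
            pairs.append((rec, best[1]))
            diffs.append(mfe - best[2])
    if not pairs:
        raise ValueError(f"no alternative site had a reference within {max_dist} nt")
    cmp = signed_rank_test(diffs, label_a="alternative", label_b="reference")
    return pairs, cmp


@dataclass(frozen=True)
class TissueEvent:
    """Per-tissue isoform-proportion changes and p-values for one event."""

    event_id: str
    site_id: str
    tissues: tuple[tuple[str, float, float], ...]  # (tissue, delta, p)

    def __post_init__(self):
        if not self.tissues:
            raise ValueError("event needs at least one tissue entry")


def classify_tissue_specific(
    event: TissueEvent,
    delta_hi: float = 0.10,
    delta_lo: float = 0.05,
    p_cut: float = 0.3,
) -> str:
    """Three-way tissue-specificity call.

    ``tissue_specific`` if any tissue has delta >= delta_hi and p < p_cut;
    ``non_tissue_specific`` if every tissue has delta < delta_lo or
    p > p_cut; ``unclassified`` otherwise (the rule as stated leaves a gap
    between the two thresholds).
    """
    for t in (delta_hi, delta_lo, p_cut):
        if not 0.0 < t < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
    deltas = np.array([abs(d) for _, d, _ in event.tissues])
    ps = np.array([p for _, _, p in event.tissues])
    if np.any((deltas >= delta_hi) & (ps < p_cut)):
        return "tissue_specific"
    if np.all((deltas < delta_lo) | (ps > p_cut)):
        return "non_tissue_specific"
    return "unclassified"


def comparison_table(results: dict[str, ComparisonResult]):
    """Flatten labelled comparisons into a pandas DataFrame for reporting."""
    import pandas as pd

    rows = []
    for key, r in results.items():
        rows.append(
            dict(
                comparison=key, group_a=r.label_a, group_b=r.label_b,
                n_a=r.n_a, n_b=r.n_b, mean_a=r.mean_a, mean_b=r.mean_b,
                statistic=r.statistic, p_value=r.p_value, paired=r.paired,
            )
        )
    return pd.DataFrame(rows)
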