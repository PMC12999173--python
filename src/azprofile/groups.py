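"""Group-level statistics: rank tests, BH-FDR, compartment comparisons.

The analysis conventions are nonparametric throughout: Welch's t only where
explicitly requested, Mann-Whitney U (exact null distribution for small
samples without ties) for two groups, Kruskal-Wallis for three or more with
pairwise Mann-Whitney post hoc, and Benjamini-Hochberg step-up control of
the false discovery rate (default q = 0.05) across families of comparisons.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_FDR_Q = 0.05


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values, q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejected flags).

    Rejects every p <= p(k*) where k* is the largest k with
    p(k) <= k q / m over the sorted p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, rejected


# ---------------------------------------------------------------------------
# two- and multi-group tests


def two_group_test(a, b, method: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided two-group test: (statistic, p).

    ``welch_t``: unequal-variance t with Welch-Satterthwaite df (needs >= 2
    values per group).  ``mann_whitney``: exact null distribution when the
    combined sample is <= 20 without ties, otherwise the normal
    approximation with tie correction.  Two identical constant samples give
    p = 1 by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if method == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("Welch's t needs >= 2 values per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("Mann-Whitney needs >= 1 value per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            return float(len(a) * len(b) / 2.0), 1.0
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        exact = (len(a) + len(b) <= 20) and not has_ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        return float(res.statistic), float(min(res.pvalue, 1.0))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class MultiGroupResult:
    omnibus_statistic: float
    omnibus_p: float
    pairs: list[tuple[str, str]]
    pairwise_p: np.ndarray
    pairwise_adjusted: np.ndarray
    pairwise_rejected: np.ndarray
    letters: dict[str, str]
    excluded: list[str] = field(default_factory=list)


def multi_group_test(groups: dict[str, np.ndarray],
                     q: float = DEFAULT_FDR_Q) -> MultiGroupResult:
    """Kruskal-Wallis omnibus (tie corrected) plus BH-adjusted pairwise
    Mann-Whitney post hoc and a compact-letter display.

    Groups with fewer than 2 values are excluded (logged).  Two groups share
    a letter iff their pairwise comparison is not rejected at FDR q.
    """
    usable = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    excluded = [k for k, v in usable.items() if len(v) < 2]
    for k in excluded:
        log.info("multi_group_test: group %s has <2 values; excluded", k)
        usable.pop(k)
    if len(usable) < 3:
        raise ValueError("multi_group_test needs >= 3 usable groups")

    names = list(usable)
    samples = [usable[k] for k in names]
    if np.ptp(np.concatenate(samples)) == 0:
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = stats.kruskal(*samples)

    pairs = list(itertools.combinations(names, 2))
    raw = np.array([two_group_test(usable[x], usable[y], "mann_whitney")[1]
                    for x, y in pairs])
    adjusted, rejected = bh_fdr(raw, q)
    letters = compact_letters(names, pairs, rejected)
    return MultiGroupResult(float(h), float(p_omni), pairs, raw, adjusted,
                            rejected, letters, excluded)


def compact_letters(names, pairs, rejected) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a rejection graph:
    two groups share a letter iff their comparison is not rejected."""
    sets: list[set] = [set(names)]
    for (x, y), rej in zip(pairs, rejected):
        if not rej:
            continue
        nxt = []
        for s in sets:
            if x in s and y in s:
                nxt.append(s - {x})
                nxt.append(s - {y})
            else:
                nxt.append(s)
        # absorb subsets
        nxt.sort(key=len, reverse=True)
        sets = []
        for s in nxt:
            if s and not any(s <= t for t in sets):
                sets.append(s)
    # stable letter order: by best (earliest) member
    order = {n: i for i, n in enumerate(names)}
    sets.sort(key=lambda s: min(order[m] for m in s))
    alphabet = string.ascii_lowercase
    out = {n: "" for n in names}
    for i, s in enumerate(sets):
        for n in s:
            out[n] += alphabet[i % len(alphabet)]
    return {n: "".join(sorted(v)) for n, v in out.items()}


# ---------------------------------------------------------------------------
# condition x compartment comparison


@dataclass
class GroupComparisonResult:
    table: pd.DataFrame    # compartment, diff, p, p_adj, rejected, n_a, n_b
    q: float

    def rejected_compartments(self) -> list[str]:
        return list(self.table.loc[self.table["rejected"], "compartment"])


def condition_compartment_comparison(group_a: list[dict], group_b: list[dict],
                                     compartments: list[str],
                                     q: float = DEFAULT_FDR_Q,
                                     fisher_z: bool = False) -> GroupComparisonResult:
    """Compare per-sample, per-compartment correlation coefficients between
    two conditions.

    ``group_a`` / ``group_b`` are lists of per-sample mappings
    {compartment: R}; a sample missing a compartment is dropped for that
    compartment (logged).  Per compartment: difference of group means of R,
    two-sided Mann-Whitney across samples, BH correction across the
    compartment family at FDR q.  ``fisher_z`` applies the Fisher
    z-transform (atanh) before testing and differencing.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each condition needs >= 3 samples")
    rows = []
    for comp in compartments:
        va = np.array([s[comp] for s in group_a if comp in s and np.isfinite(s[comp])])
        vb = np.array([s[comp] for s in group_b if comp in s and np.isfinite(s[comp])])
        dropped = (len(group_a) - len(va)) + (len(group_b) - len(vb))
        if dropped:
            log.info("compartment %s: %d sample(s) without a value dropped", comp, dropped)
        if fisher_z:
            va, vb = np.arctanh(va), np.arctanh(vb)
        if len(va) < 2 or len(vb) < 2:
            rows.append((comp, np.nan, np.nan, len(va), len(vb)))
            continue
        diff = float(va.mean() - vb.mean())
        _, p = two_group_test(va, vb, "mann_whitney")
        rows.append((comp, diff, p, len(va), len(vb)))

    df = pd.DataFrame(rows, columns=["compartment", "diff", "p", "n_a", "n_b"])
    testable = df["p"].notna()
    adj = np.full(len(df), np.nan)
    rej = np.zeros(len(df), dtype=bool)
    if testable.any():
        a, r = bh_fdr(df.loc[testable, "p"].to_numpy(), q)
        adj[testable.to_numpy()] = a
        rej[testable.to_numpy()] = r
    df["p_adj"] = adj
    df["rejected"] = rej
    return GroupComparisonResult(df[["compartment", "diff", "p", "p_adj",
                                     "rejected", "n_a", "n_b"]], q)


# ---------------------------------------------------------------------------
# behaviour


def performance_index(n_cs_minus: float, n_cs_plus: float) -> float:
    """Avoidance score PI = (#CS- − #CS+) / (#CS- + #CS+), in [-1, 1]."""
    total = n_cs_minus + n_cs_plus
    if total <= 0:
        raise ValueError("performance index needs at least one scored fly")
    return (n_cs_minus - n_cs_plus) / total
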