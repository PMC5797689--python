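"""The heterosis-association test for sRNAs (and sRNA clusters).

Hybrids are ranked by their mid-parent heterosis (MPH) and split into
equal-size low (L) and high (H) trait classes.  For each sRNA the number of
hybrids whose inbred parents are differentially expressed is counted per class
(``o_L``, ``o_H``).  Under the null hypothesis that parental differential
expression is equally probable in both classes, the skew is scored with a
binomial tail probability::

    P = sum_{k=k_min}^{n} C(n, k) * 0.5**n,   n = o_L + o_H,  k_min = max(o_L, o_H)

Benjamini-Hochberg FDR control at alpha = 0.05 yields the set of
heterosis-associated sRNAs (ha-sRNAs): positive when DE concentrates in
high-MPH hybrids (o_H > o_L), negative when it concentrates in low-MPH
hybrids.  Permutation runs (shuffled trait values or parent labels) calibrate
the procedure against spurious associations; the binary distance over a called
subset, correlated with MPH across hybrids, summarizes direction and strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, MatingDesign
from .distances import DEMatrix, DEParams, all_parent_pairs, de_matrix

Direction = Literal["positive", "negative", "none"]


@dataclass
class TraitClasses:
    """Assignment of hybrids to low (L) and high (H) trait classes."""

    low: list[str]
    high: list[str]
    dropped: list[str]

    def __post_init__(self) -> None:
        if set(self.low) & set(self.high):
            raise ValueError("a hybrid cannot be in both classes")


def split_classes(design: MatingDesign, trait: pd.Series | None = None) -> TraitClasses:
    """Rank hybrids by trait value and split into equal-size L and H classes.

    With an odd hybrid count the median hybrid is dropped.  Exact ties are
    broken by hybrid id for a stable, reproducible split.
    """
    mph = design.mph if trait is None else trait
    if mph.isna().any():
        raise ValueError("missing trait values")
    if len(mph) < 2:
        raise ValueError("need at least 2 hybrids")
    order = sorted(mph.index, key=lambda h: (mph[h], h))
    n = len(order)
    half = n // 2
    if n % 2 == 0:
        low, high, dropped = order[:half], order[half:], []
    else:
        low, high, dropped = order[:half], order[half + 1 :], [order[half]]
    return TraitClasses(low=low, high=high, dropped=dropped)


def count_de_by_class(
    dem: DEMatrix, classes: TraitClasses, design: MatingDesign
) -> pd.DataFrame:
    """Per-sRNA counts of DE hybrids in each trait class.

    Each hybrid contributes through its own parent pair; a parent pair shared
    by several hybrids contributes once per hybrid.
    """
    pairs = design.hybrid_pairs()
    cols_l = [dem.pair_index(*pairs[h]) for h in classes.low]
    cols_h = [dem.pair_index(*pairs[h]) for h in classes.high]
    o_l = dem.values[:, cols_l].sum(axis=1).astype(int)
    o_h = dem.values[:, cols_h].sum(axis=1).astype(int)
    return pd.DataFrame({"o_L": o_l, "o_H": o_h}, index=dem.srnas)


def binomial_p(o_L: int, o_H: int) -> tuple[float, Direction, bool]:
    """Exact binomial tail probability and association direction.

    Returns ``(P, direction, tie)`` where ``P = sum_{k>=max(o_L,o_H)}
    C(n,k)/2^n`` with ``n = o_L + o_H``.  Direction is ``negative`` when DE
    concentrates in the low class (``o_L > o_H``), ``positive`` when in the
    high class; a tie is assigned the negative branch and flagged (it can
    never be significant for n >= 1).
    """
    if o_L < 0 or o_H < 0:
        raise ValueError("counts must be nonnegative")
    n = o_L + o_H
    if n < 1:
        raise ValueError("n = o_L + o_H must be >= 1")
    k_min = max(o_L, o_H)
    num = sum(math.comb(n, k) for k in range(k_min, n + 1))
    p = num / (2**n)
    tie = o_L == o_H
    direction: Direction = "positive" if o_H > o_L else "negative"
    return p, direction, tie


def binomial_p_vec(o_L: np.ndarray, o_H: np.ndarray) -> np.ndarray:
    """Vectorized binomial tail probability (scipy survival function)."""
    o_L = np.asarray(o_L, dtype=np.int64)
    o_H = np.asarray(o_H, dtype=np.int64)
    n = o_L + o_H
    k_min = np.maximum(o_L, o_H)
    p = np.ones(len(n), dtype=float)
    pos = n >= 1
    p[pos] = stats.binom.sf(k_min[pos] - 1, n[pos], 0.5)
    return np.minimum(p, 1.0)


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def association_table(
    dem: DEMatrix,
    design: MatingDesign,
    trait: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-sRNA association table: o_L, o_H, n, p, q, direction.

    sRNAs with n = 0 (never DE in any hybrid's parents) are excluded from
    testing so they do not dilute the FDR correction; they appear with
    direction ``none`` and NaN p/q.
    """
    classes = split_classes(design, trait)
    counts = count_de_by_class(dem, classes, design)
    n = counts["o_L"] + counts["o_H"]
    tested = n > 0
    p = np.full(len(counts), np.nan)
    p[tested.to_numpy()] = binomial_p_vec(
        counts.loc[tested, "o_L"].to_numpy(), counts.loc[tested, "o_H"].to_numpy()
    )
    q = np.full(len(counts), np.nan)
    reject = np.zeros(len(counts), dtype=bool)
    if tested.any():
        rej, qq = bh_fdr(p[tested.to_numpy()], alpha)
        q[tested.to_numpy()] = qq
        reject[tested.to_numpy()] = rej
    direction = np.where(
        reject & (counts["o_H"] > counts["o_L"]),
        "positive",
        np.where(reject & (counts["o_L"] >= counts["o_H"]), "negative", "none"),
    )
    table = counts.copy()
    table["n"] = n
    table["p"] = p
    table["q"] = q
    table["direction"] = direction
    table["tie"] = (counts["o_L"] == counts["o_H"]) & tested
    return table


def associate(
    matrix: CountMatrix | pd.DataFrame,
    design: MatingDesign,
    params: DEParams = DEParams(),
    trait: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Convenience pipeline: DE states over hybrid parent pairs, then the
    class-count binomial test with BH-FDR."""
    dem = de_matrix(matrix, design.hybrid_pairs().values(), params)
    return association_table(dem, design, trait, alpha)


def call_ha_srnas(table: pd.DataFrame, alpha: float = 0.05) -> tuple[list, list]:
    """Partition significant records into (positive, negative) ha-sRNA id lists."""
    sig = table["q"].notna() & (table["q"] <= alpha) & (table["direction"] != "none")
    if alpha == 0:
        return [], []
    pos = list(table.index[sig & (table["direction"] == "positive")])
    neg = list(table.index[sig & (table["direction"] == "negative")])
    return pos, neg


def negative_share(n_positive: int, n_negative: int) -> float:
    """Percentage of negatively associated records among all calls."""
    total = n_positive + n_negative
    if total == 0:
        raise ValueError("no calls")
    return 100.0 * n_negative / total


def length_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-length counts and shares of positive/negative ha-sRNAs.

    The table index must be sRNA sequences (length = sequence length).
    """
    pos, neg = call_ha_srnas(table, alpha)
    rows = {}
    for ids, direction in ((pos, "positive"), (neg, "negative")):
        for srna in ids:
            length = len(str(srna))
            rows.setdefault(length, {"positive": 0, "negative": 0})
            rows[length][direction] += 1
    out = []
    for length in sorted(rows):
        p, m = rows[length]["positive"], rows[length]["negative"]
        out.append(
            {
                "length": length,
                "positive": p,
                "negative": m,
                "negative_share_pct": negative_share(p, m),
            }
        )
    return pd.DataFrame(out)


def permutation_null(
    dem: DEMatrix,
    design: MatingDesign,
    n_runs: int = 100,
    mode: Literal["shuffle_trait", "shuffle_parent_labels"] = "shuffle_trait",
    alpha: float = 0.05,
    seed: int = 0,
    trait: pd.Series | None = None,
) -> pd.DataFrame:
    """Permutation null: re-run split/count/test/FDR on permuted data.

    ``shuffle_trait`` permutes hybrid trait values; ``shuffle_parent_labels``
    permutes parent identities within each heterotic group (so every permuted
    hybrid still maps onto an inter-group parent pair present in ``dem``).
    Returns one row per run with the minimum p-value and the number of
    FDR-significant sRNAs; a run "reaches significance" when that number is
    positive.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    mph = design.mph if trait is None else trait
    rows = []
    for run in range(n_runs):
        if mode == "shuffle_trait":
            perm = pd.Series(
                rng.permutation(mph.to_numpy()), index=mph.index, name="mph"
            )
            table = association_table(dem, design, perm, alpha)
        elif mode == "shuffle_parent_labels":
            relabel = {}
            for g in ("A", "B"):
                ids = design.group_parents(g)
                relabel.update(dict(zip(ids, rng.permutation(ids))))
            permuted = MatingDesign(
                parents=list(design.parents),
                hybrids=[
                    type(h)(h.hybrid_id, relabel[h.mother_id], relabel[h.father_id], h.mph)
                    for h in design.hybrids
                ],
            )
            table = association_table(dem, permuted, mph, alpha)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tested = table["p"].notna()
        rows.append(
            {
                "run": run,
                "min_p": float(table.loc[tested, "p"].min()) if tested.any() else np.nan,
                "n_rejected": int((table["direction"] != "none").sum()),
            }
        )
    return pd.DataFrame(rows)


def correlate_binary_distance_with_trait(
    dem: DEMatrix,
    srna_subset: Iterable,
    design: MatingDesign,
    trait: pd.Series | None = None,
) -> tuple[float, float]:
    """Pearson correlation of the per-hybrid binary distance (over an sRNA
    subset) with the hybrid trait.  Returns (r, two-sided p)."""
    subset = pd.Index(list(srna_subset))
    if subset.empty:
        raise ValueError("empty sRNA subset")
    mask = dem.srnas.isin(subset)
    if not mask.any():
        raise ValueError("subset not present in DE matrix")
    mph = design.mph if trait is None else trait
    pairs = design.hybrid_pairs()
    bd = np.array(
        [dem.column(*pairs[h])[mask].mean() for h in mph.index], dtype=float
    )
    if np.allclose(bd, bd[0]) or np.allclose(mph.to_numpy(), mph.iloc[0]):
        raise ValueError("zero-variance input for correlation")
    r, p = stats.pearsonr(bd, mph.to_numpy())
    return float(r), float(p)


@dataclass
class DAScore:
    """Dominance/additivity of hybrid expression relative to its parents.

    ``a`` is half the parental difference, ``d`` the hybrid's deviation from
    the mid-parent; ``d/a`` is 0 for additive, +1 for high-parent-like and -1
    for low-parent-like expression.  Undefined when the parents are equal.
    """

    a: float
    d: float
    ratio: float
    defined: bool


def dominance_additivity(p1: float, p2: float, f1: float) -> DAScore:
    """d/a score for one (parent1, parent2, hybrid) expression triplet."""
    a = abs(p1 - p2) / 2.0
    d = f1 - (p1 + p2) / 2.0
    if a == 0:
        return DAScore(a=a, d=d, ratio=float("nan"), defined=False)
    return DAScore(a=a, d=d, ratio=d / a, defined=True)
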