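"""Pairwise differential-expression states and parent-parent distances.

The central primitive is the differential-expression (DE) state of one sRNA
between two inbred parents with rpmqn counts ``c_i``, ``c_j``
(``c_h = max``, ``c_l = min``)::

    x_s = 1  if (c_l > c_min and c_h >= c_l * f_c)
             or (c_l == 0 and c_h >= c_min * f_c)
    x_s = 0  otherwise

with minimal expression ``c_min = 0.5`` rpmqn and fold-change ``f_c = 2``
throughout.  The binary distance between two parents is the fraction of sRNAs
in DE state 1; Euclidean distances serve sRNA/mRNA expression profiles and SNP
genotypes alike.  Population overlap and principal-coordinate grouping
summarize how sharply the heterotic groups differ in their sRNA populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, MatingDesign


@dataclass(frozen=True)
class DEParams:
    """Minimal expression and fold-change thresholds for the DE state."""

    c_min: float = 0.5
    f_c: float = 2.0

    def __post_init__(self) -> None:
        if self.c_min < 0:
            raise ValueError("c_min must be >= 0")
        if self.f_c <= 1:
            raise ValueError("f_c must be > 1")


def de_state(c_i: float, c_j: float, params: DEParams = DEParams()) -> int:
    """Differential-expression state of one sRNA between two parents."""
    if c_i < 0 or c_j < 0:
        raise ValueError("expression values must be nonnegative")
    c_h, c_l = max(c_i, c_j), min(c_i, c_j)
    if c_l > params.c_min and c_h >= c_l * params.f_c:
        return 1
    if c_l == 0 and c_h >= params.c_min * params.f_c:
        return 1
    return 0


def de_states(
    c_i: np.ndarray, c_j: np.ndarray, params: DEParams = DEParams()
) -> np.ndarray:
    """Vectorized :func:`de_state` over aligned expression vectors."""
    c_i = np.asarray(c_i, dtype=float)
    c_j = np.asarray(c_j, dtype=float)
    if (c_i < 0).any() or (c_j < 0).any():
        raise ValueError("expression values must be nonnegative")
    c_h = np.maximum(c_i, c_j)
    c_l = np.minimum(c_i, c_j)
    hit = ((c_l > params.c_min) & (c_h >= c_l * params.f_c)) | (
        (c_l == 0) & (c_h >= params.c_min * params.f_c)
    )
    return hit.astype(np.uint8)


@dataclass
class DEMatrix:
    """Binary DE states: sRNAs (rows) x unordered parent pairs (columns)."""

    values: np.ndarray
    srnas: pd.Index
    pairs: list[tuple[str, str]]
    params: DEParams = field(default_factory=DEParams)

    def __post_init__(self) -> None:
        self._pair_pos = {p: k for k, p in enumerate(self.pairs)}

    def column(self, parent_a: str, parent_b: str) -> np.ndarray:
        key = tuple(sorted((parent_a, parent_b)))
        return self.values[:, self._pair_pos[key]]

    def pair_index(self, parent_a: str, parent_b: str) -> int:
        return self._pair_pos[tuple(sorted((parent_a, parent_b)))]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a}|{b}" for a, b in self.pairs]
        return pd.DataFrame(self.values, index=self.srnas, columns=cols)


def de_matrix(
    matrix: CountMatrix | pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    params: DEParams = DEParams(),
) -> DEMatrix:
    """DE states of every sRNA for each requested parent pair.

    ``matrix`` is an rpmqn CountMatrix (or any expression DataFrame whose
    columns are parent library ids, e.g. repeat-normalized cluster expression).
    """
    data = matrix.data if isinstance(matrix, CountMatrix) else matrix
    pair_list = sorted({tuple(sorted(p)) for p in pairs})
    X = data.to_numpy(dtype=float)
    cols = {c: k for k, c in enumerate(data.columns)}
    out = np.empty((X.shape[0], len(pair_list)), dtype=np.uint8)
    for k, (a, b) in enumerate(pair_list):
        out[:, k] = de_states(X[:, cols[a]], X[:, cols[b]], params)
    return DEMatrix(values=out, srnas=data.index, pairs=pair_list, params=params)


def all_parent_pairs(design: MatingDesign) -> list[tuple[str, str]]:
    ids = design.parent_ids
    return [
        tuple(sorted((ids[i], ids[j])))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]


def binary_distance(states: np.ndarray) -> float:
    """Mean DE state over an sRNA set: the binary distance D_b in [0, 1]."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("binary distance of an empty sRNA set is undefined")
    return float(states.mean())


def binary_distance_matrix(dem: DEMatrix, parents: Sequence[str]) -> pd.DataFrame:
    """Symmetric parent x parent binary-distance matrix."""
    n = len(parents)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = binary_distance(dem.column(parents[i], parents[j]))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=list(parents), columns=list(parents))


def euclidean_distance(
    profile_i: np.ndarray, profile_j: np.ndarray, cityblock: bool = False
) -> float:
    """Euclidean (or, optionally, city-block) distance between expression profiles."""
    x = np.asarray(profile_i, dtype=float)
    y = np.asarray(profile_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if cityblock:
        return float(np.abs(x - y).sum())
    return float(np.sqrt(((x - y) ** 2).sum()))


def snp_distance(genotypes_i: Sequence, genotypes_j: Sequence) -> float:
    """Distance over SNP calls: per-locus difference 1 when calls differ, 0 when
    equal, combined as the Euclidean form; loci missing in either line are
    excluded pairwise.  Missing calls are ``None``/NaN."""
    gi = pd.Series(list(genotypes_i))
    gj = pd.Series(list(genotypes_j))
    if len(gi) != len(gj):
        raise ValueError("genotype vectors must have equal length")
    ok = gi.notna() & gj.notna()
    if not ok.any():
        raise ValueError("no shared non-missing loci")
    diff = (gi[ok].to_numpy() != gj[ok].to_numpy()).astype(float)
    return float(np.sqrt(diff.sum()))


@dataclass
class PopulationOverlap:
    """Group-specificity of the expressed sRNA population at threshold c_min."""

    per_pair: pd.DataFrame  # one row per inter-group pair: fractions
    specific_a: float  # summary fractions over consistently labelled sRNAs
    specific_b: float
    shared: float
    excluded: int  # sRNAs with inconsistent labels across pairs


def population_overlap(
    matrix: CountMatrix, design: MatingDesign, c_min: float = 0.5
) -> PopulationOverlap:
    """Fractions of group-A-specific, group-B-specific and shared sRNAs.

    For every inter-group parent pair, each sRNA expressed (>= c_min) in at
    least one of the two parents is labelled specific-A / specific-B / shared.
    The summary counts each sRNA once, using its label when it is consistent
    across all pairs in which it is expressed; inconsistently labelled sRNAs
    are reported as excluded.
    """
    a_parents = design.group_parents("A")
    b_parents = design.group_parents("B")
    if not a_parents or not b_parents:
        raise ValueError("both heterotic groups must be non-empty")
    expressed = matrix.data.to_numpy(dtype=float) >= c_min
    cols = {c: k for k, c in enumerate(matrix.data.columns)}

    n = expressed.shape[0]
    # Label codes per sRNA per pair: 0 absent, 1 specific-A, 2 specific-B, 3 shared
    label_seen = np.zeros((n, 4), dtype=bool)
    rows = []
    for pa in a_parents:
        ea = expressed[:, cols[pa]]
        for pb in b_parents:
            eb = expressed[:, cols[pb]]
            code = ea.astype(np.uint8) + 2 * eb.astype(np.uint8)
            for c in range(4):
                label_seen[code == c, c] = True
            tot = int((code > 0).sum())
            if tot:
                rows.append(
                    {
                        "parent_a": pa,
                        "parent_b": pb,
                        "specific_a": float((code == 1).sum() / tot),
                        "specific_b": float((code == 2).sum() / tot),
                        "shared": float((code == 3).sum() / tot),
                        "n_expressed": tot,
                    }
                )
    per_pair = pd.DataFrame(rows)

    labelled = label_seen[:, 1:]  # ignore pairs where the sRNA is absent
    n_labels = labelled.sum(axis=1)
    consistent = n_labels == 1
    excluded = int((n_labels > 1).sum())
    denom = int((n_labels >= 1).sum())
    if denom == 0:
        frac = (0.0, 0.0, 0.0)
    else:
        frac = tuple(
            float((labelled[:, k] & consistent).sum() / denom) for k in range(3)
        )
    return PopulationOverlap(
        per_pair=per_pair,
        specific_a=frac[0],
        specific_b=frac[1],
        shared=frac[2],
        excluded=excluded,
    )


@dataclass
class OrdinationReport:
    coordinates: pd.DataFrame  # parents x components
    proportion_explained: pd.Series
    silhouette: float
    separable: bool


def ordination_grouping(
    distances: pd.DataFrame,
    groups: dict[str, str],
    n_components: int = 3,
) -> OrdinationReport:
    """Principal-coordinate (classical scaling) ordination of a distance matrix,
    with a report on heterotic-group separation in the leading components."""
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa
    from sklearn.metrics import silhouette_score
    from sklearn.svm import SVC

    if distances.shape[0] < 3:
        raise ValueError("need at least 3 parents for ordination")
    arr = distances.to_numpy(dtype=float)
    if not np.any(arr):
        raise ValueError("degenerate (all-zero) distance matrix")
    ids = list(distances.index)
    res = pcoa(DistanceMatrix(arr, ids), method="eigh")
    coords = res.samples.iloc[:, : max(n_components, 1)]
    coords.index = pd.Index(ids)
    labels = np.array([groups[i] for i in ids])
    X = coords.to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("need two groups for a separation report")
    sil = float(silhouette_score(X, labels))
    svm = SVC(kernel="linear", C=1e6).fit(X, labels)
    separable = bool((svm.predict(X) == labels).all())
    return OrdinationReport(
        coordinates=coords,
        proportion_explained=res.proportion_explained[: coords.shape[1]],
        silhouette=sil,
        separable=separable,
    )
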