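"""Genomic context of heterosis-associated sRNAs.

Covers exact-match mapping intake, attribution to gene/repeat/intergenic
annotation, siRNA cluster building (merge within 200 bp, >= 5 member sRNAs,
repeat-normalized expression) and cluster-level association, windowed genome
tracks, bootstrap enrichment tests (size class, repeat superfamily, 1-Mbp
spatial windows, proximity to differentially expressed genes), windowed
recombination rates from a genetic map, and nucleotide-composition profiles.

Coordinates are BED-style 0-based half-open everywhere inside the package;
GFF3 (1-based closed) is converted on read and write.  All bootstrap
p-values use the add-one estimator ``(#extreme + 1) / (runs + 1)`` and are
therefore in (0, 1].
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.sparse import csr_matrix

from .core import CountMatrix, MatingDesign
from .distances import DEParams

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Mapping table
# ---------------------------------------------------------------------------


@dataclass
class MappingTable:
    """sRNA id -> genomic intervals (chrom, start, end, strand), 0-based half-open."""

    entries: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for srna, positions in self.entries.items():
            for chrom, start, end, strand in positions:
                if end <= start:
                    raise ValueError(f"{srna}: end must exceed start")

    @property
    def n_positions(self) -> dict[str, int]:
        return {s: len(p) for s, p in self.entries.items()}

    def subset(self, ids: Iterable[str]) -> "MappingTable":
        ids = set(ids)
        return MappingTable({s: p for s, p in self.entries.items() if s in ids})

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for srna in sorted(self.entries):
                for chrom, start, end, strand in self.entries[srna]:
                    fh.write(f"{chrom}\t{start}\t{end}\t{srna}\t0\t{strand}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "MappingTable":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            comment="#",
        )
        entries: dict[str, list] = defaultdict(list)
        for r in df.itertuples():
            entries[str(r.name)].append((str(r.chrom), int(r.start), int(r.end), str(r.strand)))
        return cls(dict(entries))


def exact_map(
    srnas: Mapping[str, str] | Iterable[str],
    genome: Mapping[str, str],
) -> MappingTable:
    """All exact occurrences of each sRNA on both genome strands.

    ``srnas`` maps ids to sequences (or is an iterable of sequences, used as
    their own ids); ``genome`` maps chromosome names to sequences.  Minus-
    strand hits are found by scanning for the reverse complement.  Unmapped
    sRNAs are absent from the result.
    """
    if not isinstance(srnas, Mapping):
        srnas = {s: s for s in srnas}
    entries: dict[str, list] = defaultdict(list)
    for chrom, seq in genome.items():
        seq = seq.upper()
        for srna_id, query in srnas.items():
            query = query.upper()
            if set(query) - set("ACGT"):
                raise ValueError(f"{srna_id}: sequence must be over ACGT")
            for probe, strand in ((query, "+"), (reverse_complement(query), "-")):
                if strand == "-" and probe == query:
                    continue  # palindromic: avoid double-reporting the same locus
                start = seq.find(probe)
                while start != -1:
                    entries[srna_id].append((chrom, start, start + len(probe), strand))
                    start = seq.find(probe, start + 1)
    return MappingTable(dict(entries))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Gene and repeat intervals; anything else is intergenic by definition."""

    genes: pd.DataFrame  # chrom, start, end, strand, gene_id  (0-based half-open)
    repeats: pd.DataFrame  # chrom, start, end, strand, family, repeat_id

    def __post_init__(self) -> None:
        self._gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._repeat_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for r in self.genes.itertuples():
            self._gene_trees[r.chrom].addi(int(r.start), int(r.end), r.gene_id)
        for r in self.repeats.itertuples():
            self._repeat_trees[r.chrom].addi(int(r.start), int(r.end), r.family)

    @classmethod
    def from_gff3(cls, path: str | Path, gene_types=("gene",)) -> "AnnotationSet":
        """Read genes and repeats from a GFF3 file (1-based closed -> half-open).

        Features typed ``gene`` populate the gene set; features typed
        ``repeat``/``repeat_region``/``transposable_element`` populate the
        repeat set, with the superfamily taken from a ``family=`` attribute
        when present (else the source column).
        """
        cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"]
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#", dtype=str)
        genes, repeats = [], []
        for r in df.itertuples():
            attrs = dict(
                kv.split("=", 1) for kv in str(r.attrs).split(";") if "=" in kv
            )
            start, end = int(r.start) - 1, int(r.end)
            if r.type in gene_types:
                genes.append(
                    (r.chrom, start, end, r.strand, attrs.get("ID", f"gene{len(genes)}"))
                )
            elif r.type in ("repeat", "repeat_region", "transposable_element"):
                repeats.append(
                    (
                        r.chrom,
                        start,
                        end,
                        r.strand,
                        attrs.get("family", r.source),
                        attrs.get("ID", f"repeat{len(repeats)}"),
                    )
                )
        return cls(
            genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"]),
            repeats=pd.DataFrame(
                repeats, columns=["chrom", "start", "end", "strand", "family", "repeat_id"]
            ),
        )

    def repeat_families_at(self, chrom: str, start: int, end: int) -> set[str]:
        return {iv.data for iv in self._repeat_trees[chrom].overlap(start, end)}

    def labels_at(self, chrom: str, start: int, end: int) -> set[str]:
        labels = set()
        if self._gene_trees[chrom].overlaps(start, end):
            labels.add("gene")
        if self._repeat_trees[chrom].overlaps(start, end):
            labels.add("repeat")
        if not labels:
            labels.add("intergenic")
        return labels


def attribute_annotation(
    mapping: MappingTable, ann: AnnotationSet, chrom_names: Iterable[str] | None = None
) -> dict[str, frozenset[str]]:
    """Label every mapped sRNA with the union of annotation categories
    ({gene, repeat, intergenic}) overlapped by its positions.

    A position overlapping no annotation contributes ``intergenic``; a
    multi-position sRNA carries the conjunction of all its positions' labels.
    """
    known = set(chrom_names) if chrom_names is not None else None
    out: dict[str, frozenset[str]] = {}
    for srna, positions in mapping.entries.items():
        labels: set[str] = set()
        for chrom, start, end, _ in positions:
            if known is not None and chrom not in known:
                raise ValueError(f"unknown chromosome {chrom!r}")
            labels |= ann.labels_at(chrom, start, end)
        out[srna] = frozenset(labels)
    return out


def srna_repeat_families(mapping: MappingTable, ann: AnnotationSet) -> dict[str, set[str]]:
    """Repeat superfamilies overlapped by each sRNA's positions (may be empty)."""
    return {
        srna: set().union(
            *(ann.repeat_families_at(chrom, s, e) for chrom, s, e, _ in pos)
        )
        for srna, pos in mapping.entries.items()
    }


# ---------------------------------------------------------------------------
# siRNA clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterRecord:
    """Merged genomic interval with member sRNAs and repeat-normalized expression."""

    chrom: str
    start: int
    end: int
    members: set[str]
    expression: pd.Series  # per library, repnorm rpmqn

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def build_clusters(
    mapping: MappingTable,
    rpmqn: CountMatrix | pd.DataFrame,
    gap: int = 200,
    min_members: int = 5,
) -> list[ClusterRecord]:
    """Single-linkage merge of mapping positions within ``gap`` bp on the same
    chromosome; clusters with fewer than ``min_members`` distinct member sRNAs
    are discarded.

    Cluster expression per library is the sum over member positions of the
    member sRNA's rpmqn divided by its total number of mapping positions
    (repeat-normalization: expression is spread equally over all loci).
    """
    data = rpmqn.data if isinstance(rpmqn, CountMatrix) else rpmqn
    n_pos = mapping.n_positions
    by_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for srna, positions in mapping.entries.items():
        for chrom, start, end, _ in positions:
            by_chrom[chrom].append((start, end, srna))

    clusters: list[ClusterRecord] = []
    zero = pd.Series(0.0, index=data.columns)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        cur: list[tuple[int, int, str]] = []
        cur_end = None
        for start, end, srna in positions:
            if cur and start - cur_end > gap:
                clusters.extend(_finish_cluster(chrom, cur, data, n_pos, min_members, zero))
                cur, cur_end = [], None
            cur.append((start, end, srna))
            cur_end = end if cur_end is None else max(cur_end, end)
        if cur:
            clusters.extend(_finish_cluster(chrom, cur, data, n_pos, min_members, zero))
    return clusters


def _finish_cluster(chrom, positions, data, n_pos, min_members, zero):
    members = {srna for _, _, srna in positions}
    if len(members) < min_members:
        return []
    expr = zero.copy()
    for _, _, srna in positions:
        if srna in data.index:
            expr = expr + data.loc[srna] / n_pos[srna]
    start = min(s for s, _, _ in positions)
    end = max(e for _, e, _ in positions)
    return [ClusterRecord(chrom=chrom, start=start, end=end, members=members, expression=expr)]


def cluster_expression_matrix(clusters: Sequence[ClusterRecord]) -> pd.DataFrame:
    """Cluster x library repeat-normalized expression matrix."""
    if not clusters:
        return pd.DataFrame()
    return pd.DataFrame(
        {c.cluster_id: c.expression for c in clusters}
    ).T.rename_axis("cluster")


def cluster_association(
    clusters: Sequence[ClusterRecord],
    design: MatingDesign,
    trait: pd.Series | None = None,
    alpha: float = 0.05,
    params: DEParams = DEParams(c_min=5.0, f_c=2.0),
) -> pd.DataFrame:
    """Heterosis association of sRNA clusters: same machinery as for single
    sRNAs, on repeat-normalized cluster expression with c_min = 5 repnorm
    rpmqn and f_c = 2."""
    from .association import associate

    expr = cluster_expression_matrix(clusters)
    if expr.empty:
        return pd.DataFrame(
            columns=["o_L", "o_H", "n", "p", "q", "direction", "tie"]
        )
    return associate(expr, design, params=params, trait=trait, alpha=alpha)


def clusters_to_bed(clusters: Sequence[ClusterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{len(c.members)}\t.\n")


# ---------------------------------------------------------------------------
# Windowed tracks and bootstrap enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    unit: str
    observed: float
    bootstrap_mean: float
    factor: float
    p_enriched: float
    p_depleted: float
    runs: int
    flagged: bool = False


def _windows(chrom_lengths: Mapping[str, int], window: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), window):
            rows.append((chrom, start, min(start + window, int(length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def windowed_counts(
    mapping: MappingTable,
    subset: Iterable[str],
    chrom_lengths: Mapping[str, int],
    window: int,
) -> pd.DataFrame:
    """Mapping-position counts per sequential genome window.

    Every position of a multi-mapping sRNA is counted, in the window
    containing its start coordinate.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    win = _windows(chrom_lengths, window)
    key = {(r.chrom, r.start): i for i, r in enumerate(win.itertuples())}
    counts = np.zeros(len(win), dtype=float)
    for srna in subset:
        for chrom, start, _, _ in mapping.entries.get(srna, []):
            counts[key[(chrom, (start // window) * window)]] += 1
    win["count"] = counts
    return win


def _position_window_matrix(
    mapping: MappingTable,
    universe: Sequence[str],
    chrom_lengths: Mapping[str, int],
    window: int,
) -> tuple[csr_matrix, pd.DataFrame]:
    """Sparse sRNA x window matrix of position counts, plus the window table."""
    win = _windows(chrom_lengths, window)
    key = {(r.chrom, r.start): i for i, r in enumerate(win.itertuples())}
    rows, cols, vals = [], [], []
    for i, srna in enumerate(universe):
        for chrom, start, _, _ in mapping.entries.get(srna, []):
            rows.append(i)
            cols.append(key[(chrom, (start // window) * window)])
            vals.append(1.0)
    M = csr_matrix((vals, (rows, cols)), shape=(len(universe), len(win)))
    return M, win


def spatial_enrichment(
    ha_subset: Sequence[str],
    universe: Sequence[str],
    mapping: MappingTable,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
    runs: int = 10_000,
    fold: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap spatial enrichment of an sRNA subset in sequential genome windows.

    Random universe subsets of equal size are drawn ``runs`` times; a window is
    flagged when the observed position count reaches ``fold`` times the
    bootstrap mean and the add-one empirical p-value is below ``alpha``.
    """
    universe = list(universe)
    subset = set(ha_subset)
    if not subset <= set(universe):
        raise ValueError("subset must be contained in the universe")
    M, win = _position_window_matrix(mapping, universe, chrom_lengths, window)
    idx = [i for i, s in enumerate(universe) if s in subset]
    observed = np.asarray(M[idx].sum(axis=0)).ravel()

    rng = np.random.default_rng(seed)
    n_win = M.shape[1]
    boot_sum = np.zeros(n_win)
    n_extreme = np.zeros(n_win)
    k = len(idx)
    for _ in range(runs):
        draw = rng.choice(len(universe), size=k, replace=False)
        counts = np.asarray(M[draw].sum(axis=0)).ravel()
        boot_sum += counts
        n_extreme += counts >= observed
    boot_mean = boot_sum / runs
    p = (n_extreme + 1.0) / (runs + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(boot_mean > 0, observed / boot_mean, np.where(observed > 0, np.inf, 0.0))
    win = win.copy()
    win["observed"] = observed
    win["bootstrap_mean"] = boot_mean
    win["factor"] = factor
    win["p"] = p
    win["flagged"] = (observed > 0) & (observed >= fold * boot_mean) & (p < alpha)
    return win


def _bootstrap_counts(
    membership: np.ndarray, draws: np.ndarray
) -> np.ndarray:  # pragma: no cover - trivial helper
    return membership[draws].sum(axis=1)


def size_class_enrichment(
    ha_subset: Sequence[str],
    universe: Sequence[str],
    lengths: Mapping[str, int] | None = None,
    runs: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per-length bootstrap enrichment/depletion of an sRNA subset.

    ``lengths`` maps sRNA ids to lengths; by default ids are sequences and
    their own length is used.  Bootstrap sets are equal-size random draws from
    the universe; both one-sided add-one p-values are reported.
    """
    universe = list(universe)
    subset = set(ha_subset)
    if not subset <= set(universe):
        raise ValueError("subset must be contained in the universe")
    get_len = (lambda s: lengths[s]) if lengths is not None else (lambda s: len(str(s)))
    ulen = np.array([get_len(s) for s in universe])
    all_lengths = np.unique(ulen)
    sub_idx = np.array([i for i, s in enumerate(universe) if s in subset])
    observed = {L: int((ulen[sub_idx] == L).sum()) for L in all_lengths}

    rng = np.random.default_rng(seed)
    k = len(sub_idx)
    boot = np.zeros((runs, len(all_lengths)))
    onehot = ulen[:, None] == all_lengths[None, :]
    for r in range(runs):
        draw = rng.choice(len(universe), size=k, replace=False)
        boot[r] = onehot[draw].sum(axis=0)
    results = []
    for j, L in enumerate(all_lengths):
        obs = observed[L]
        mean = float(boot[:, j].mean())
        results.append(
            EnrichmentResult(
                unit=str(L),
                observed=obs,
                bootstrap_mean=mean,
                factor=(obs / mean) if mean > 0 else (0.0 if obs == 0 else float("inf")),
                p_enriched=float(((boot[:, j] >= obs).sum() + 1) / (runs + 1)),
                p_depleted=float(((boot[:, j] <= obs).sum() + 1) / (runs + 1)),
                runs=runs,
            )
        )
    return results


def _length_matched_draw(
    rng: np.random.Generator,
    lengths: np.ndarray,
    target_hist: dict[int, int],
    by_length: dict[int, np.ndarray],
) -> np.ndarray:
    parts = [
        rng.choice(by_length[L], size=n, replace=False) for L, n in target_hist.items() if n
    ]
    return np.concatenate(parts) if parts else np.array([], dtype=int)


def family_enrichment(
    ha_subset: Sequence[str],
    universe: Sequence[str],
    families: Mapping[str, Iterable[str]],
    lengths: Mapping[str, int] | None = None,
    runs: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Repeat-superfamily enrichment with length-matched bootstrap draws.

    The universe should be restricted to repeat-mapping sRNAs; ``families``
    maps each sRNA to the repeat superfamilies it overlaps.  Every bootstrap
    draw has exactly the subset's length histogram.
    """
    universe = list(universe)
    subset = set(ha_subset)
    if not subset <= set(universe):
        raise ValueError("subset must be contained in the universe")
    get_len = (lambda s: lengths[s]) if lengths is not None else (lambda s: len(str(s)))
    ulen = np.array([get_len(s) for s in universe])
    by_length = {int(L): np.flatnonzero(ulen == L) for L in np.unique(ulen)}
    sub_idx = np.array([i for i, s in enumerate(universe) if s in subset])
    target_hist: dict[int, int] = defaultdict(int)
    for i in sub_idx:
        target_hist[int(ulen[i])] += 1
    for L, n in target_hist.items():
        if n > len(by_length.get(L, ())):
            raise ValueError(f"cannot length-match: not enough {L}-nt sRNAs in universe")

    fam_list = sorted({f for s in universe for f in families.get(s, ())})
    fam_pos = {f: j for j, f in enumerate(fam_list)}
    member = np.zeros((len(universe), len(fam_list)), dtype=np.int32)
    for i, s in enumerate(universe):
        for f in families.get(s, ()):
            member[i, fam_pos[f]] = 1
    observed = member[sub_idx].sum(axis=0)

    rng = np.random.default_rng(seed)
    boot = np.zeros((runs, len(fam_list)))
    for r in range(runs):
        draw = _length_matched_draw(rng, ulen, target_hist, by_length)
        boot[r] = member[draw].sum(axis=0)
    results = []
    for j, f in enumerate(fam_list):
        obs = int(observed[j])
        mean = float(boot[:, j].mean())
        results.append(
            EnrichmentResult(
                unit=f,
                observed=obs,
                bootstrap_mean=mean,
                factor=(obs / mean) if mean > 0 else (0.0 if obs == 0 else float("inf")),
                p_enriched=float(((boot[:, j] >= obs).sum() + 1) / (runs + 1)),
                p_depleted=float(((boot[:, j] <= obs).sum() + 1) / (runs + 1)),
                runs=runs,
            )
        )
    return results


def gene_proximity_enrichment(
    ha_subset: Sequence[str],
    universe: Sequence[str],
    mapping: MappingTable,
    de_genes: pd.DataFrame,
    flank: int = 1000,
    lengths: Mapping[str, int] | None = None,
    runs: int = 1000,
    seed: int = 0,
) -> tuple[EnrichmentResult, int, pd.DataFrame]:
    """Bootstrap enrichment of an sRNA subset near differentially expressed genes.

    A subset sRNA counts as a hit when any of its positions falls within the
    closed flank [gene start - flank, gene end + flank] of any DE gene
    (``de_genes``: chrom, start, end, strand, gene_id; 0-based half-open).
    Bootstrap draws are length-matched to the subset.  Returns the enrichment
    result, the number of DE genes with at least one subset sRNA position in
    their flank, and a per-strand (sense/antisense) breakdown of subset hits.
    """
    universe = list(universe)
    subset = set(ha_subset)
    if not subset <= set(universe):
        raise ValueError("subset must be contained in the universe")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in de_genes.itertuples():
        trees[r.chrom].addi(max(0, int(r.start) - flank), int(r.end) + flank, (r.gene_id, r.strand))

    def hits(srna: str) -> list[tuple[str, str, str]]:
        found = []
        for chrom, start, end, strand in mapping.entries.get(srna, []):
            for iv in trees[chrom].overlap(start, end):
                gene_id, gstrand = iv.data
                found.append((gene_id, strand, gstrand))
        return found

    hit_flags = np.array([bool(hits(s)) for s in universe])
    sub_idx = np.array([i for i, s in enumerate(universe) if s in subset])
    observed = int(hit_flags[sub_idx].sum())

    genes_hit = set()
    sense = antisense = 0
    for i in sub_idx:
        for gene_id, strand, gstrand in hits(universe[i]):
            genes_hit.add(gene_id)
            if gstrand in "+-" and strand in "+-":
                if strand == gstrand:
                    sense += 1
                else:
                    antisense += 1
    strand_breakdown = pd.DataFrame(
        {"orientation": ["sense", "antisense"], "positions": [sense, antisense]}
    )

    get_len = (lambda s: lengths[s]) if lengths is not None else (lambda s: len(str(s)))
    ulen = np.array([get_len(s) for s in universe])
    by_length = {int(L): np.flatnonzero(ulen == L) for L in np.unique(ulen)}
    target_hist: dict[int, int] = defaultdict(int)
    for i in sub_idx:
        target_hist[int(ulen[i])] += 1
    for L, n in target_hist.items():
        if n > len(by_length.get(L, ())):
            raise ValueError(f"cannot length-match: not enough {L}-nt sRNAs in universe")

    rng = np.random.default_rng(seed)
    boot = np.empty(runs)
    for r in range(runs):
        draw = _length_matched_draw(rng, ulen, target_hist, by_length)
        boot[r] = hit_flags[draw].sum()
    mean = float(boot.mean())
    result = EnrichmentResult(
        unit=f"within_{flank}bp_of_de_genes",
        observed=observed,
        bootstrap_mean=mean,
        factor=(observed / mean) if mean > 0 else (0.0 if observed == 0 else float("inf")),
        p_enriched=float(((boot >= observed).sum() + 1) / (runs + 1)),
        p_depleted=float(((boot <= observed).sum() + 1) / (runs + 1)),
        runs=runs,
    )
    return result, len(genes_hit), strand_breakdown


# ---------------------------------------------------------------------------
# Recombination rate and correlations
# ---------------------------------------------------------------------------


def recombination_rate(
    genetic_map: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Windowed recombination rates (cM/Mb) from a genetic map.

    ``genetic_map`` has columns chrom, bp, cM with cM non-decreasing along
    each chromosome.  cM positions are linearly interpolated to window
    boundaries; windows entirely outside the marker span get rate 0 and are
    flagged ``outside_span``.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = genetic_map[genetic_map["chrom"] == chrom].sort_values("bp")
        if len(sub) < 2:
            raise ValueError(f"{chrom}: need at least 2 markers")
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        if (np.diff(cm) < 0).any():
            raise ValueError(f"{chrom}: cM must be non-decreasing with bp")
        for start in range(0, int(length), window):
            end = min(start + window, int(length))
            c0, c1 = np.interp([start, end], bp, cm)
            outside = end <= bp[0] or start >= bp[-1]
            rate = 0.0 if outside else (c1 - c0) / ((end - start) / 1e6)
            rows.append((chrom, start, end, rate, bool(outside)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cm_per_mb", "outside_span"])


def correlate_with_recombination(
    window_counts: pd.DataFrame,
    rates: pd.DataFrame,
    per_chromosome: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of windowed sRNA counts with cM/Mb.

    Returns one row per chromosome (when ``per_chromosome``) plus a
    genome-wide row.  Chromosomes where either track is constant yield NaN.
    """
    merged = window_counts.merge(rates, on=["chrom", "start", "end"])
    if merged.empty:
        raise ValueError("no aligned windows")

    def _corr(df: pd.DataFrame) -> float:
        x = df["count"].to_numpy(dtype=float)
        y = df["cm_per_mb"].to_numpy(dtype=float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    rows = []
    if per_chromosome:
        for chrom, df in merged.groupby("chrom", sort=True):
            rows.append((str(chrom), _corr(df), len(df)))
    genome_r = _corr(merged)
    if np.isnan(genome_r) and merged["count"].nunique() <= 1:
        raise ValueError("zero-variance window counts")
    rows.append(("genome", genome_r, len(merged)))
    return pd.DataFrame(rows, columns=["chrom", "r", "n_windows"])


def nucleotide_composition(sequences: Iterable[str], length: int) -> pd.DataFrame:
    """Per-position base frequencies for sRNAs of one length.

    Returns a 4 x length DataFrame (rows A, C, G, T; columns 1-based
    positions).  Position 1 is the 5' end, whose base bias determines
    Argonaute sorting of plant sRNAs.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("empty sRNA subset")
    if any(len(s) != length for s in seqs):
        raise ValueError(f"all sequences must have length {length}")
    counts = np.zeros((4, length))
    bases = "ACGT"
    idx = {b: i for i, b in enumerate(bases)}
    for s in seqs:
        for j, b in enumerate(s):
            counts[idx[b], j] += 1
    freq = counts / len(seqs)
    return pd.DataFrame(freq, index=list(bases), columns=range(1, length + 1))
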