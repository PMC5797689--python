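"""Synthetic factorial mating data with planted heterosis-associated sRNAs.

The generators emulate the structure of a two-pool maize breeding factorial:
two heterotic groups of inbred parents (defaults 7 + 14), one hybrid per
inter-group cross (98) with a mid-parent heterosis (MPH) trait value, sparse
unique-sRNA count matrices with group-specific presence/absence structure, and
a toy multi-chromosome genome with gene/repeat/centromere annotation and a
genetic map with pericentromeric recombination suppression.  Every generator
is a pure function of its arguments including the seed.

Trait model.  MPH is drawn as ``mph_mean + g_mother + g_father + eps`` with
independent normal components whose variances are fixed shares of
``mph_sd**2`` (group A 0.6, group B 0.2, residual 0.2), i.e. a normal marginal
with dominant group-A general combining ability.  Planting operates on
per-parent expression states, so the differential-expression pattern of a
planted sRNA is necessarily a "rectangle" (a parent subset crossed with the
whole other group); a trait dominated by one pool's parental effects is the
simplest condition under which such rectangles concentrate in one trait class,
which is what a strong planted association means here.

Planting.  A planted negative sRNA is expressed (negative-binomial counts
around a high mean) in a few group-A parents whose hybrids have the lowest
mean MPH, and has zero counts everywhere else; every hybrid of an expressing
parent is then differentially expressed via the presence/absence branch of the
DE rule, and those hybrids fall mostly in the low-MPH class.  Positive
planting mirrors this at the top of the ranking.  Realized class counts
(o_L/o_H), recomputed from the emitted matrix with the package's own
normalization and DE machinery, are recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, Hybrid, MatingDesign
from .distances import DEParams, de_matrix
from .genomic import MappingTable
from .normalize import rpmqn

# Variance shares of mph_sd**2 for the trait model (group A GCA, group B GCA,
# residual).  See the module docstring for why group A dominates.
MPH_VARIANCE_SHARES = (0.7, 0.15, 0.15)

# How many parents of group A express a planted sRNA, and how sharply their
# choice concentrates on the extreme of the mean-MPH ranking.
PLANT_K_PARENTS = 3
PLANT_RANK_DECAY = 2.5

DEFAULT_LENGTH_WEIGHTS = {20: 0.10, 21: 0.15, 22: 0.25, 23: 0.05, 24: 0.45}
REPEAT_FAMILIES = ("LTR_Gypsy", "LTR_Copia", "DNA_hAT", "DNA_CACTA", "LINE_L1")
REPEAT_FAMILY_WEIGHTS = (0.40, 0.20, 0.15, 0.15, 0.10)


# ---------------------------------------------------------------------------
# Mating design
# ---------------------------------------------------------------------------


def _stratified_effects(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Parental effects as normal scores on a quantile grid, randomly assigned.

    With only a handful of parents per pool, i.i.d. draws occasionally produce
    a near-degenerate (all-similar) effect set; real breeding pools are
    curated to span their diversity.  Stratified scores keep every simulated
    pool representative of the stated effect variance while the assignment of
    effects to parents stays random.
    """
    from scipy.stats import norm

    scores = norm.ppf((np.arange(n) + 0.5) / n) * sd
    return rng.permutation(scores)


def simulate_design(
    n_group_a: int = 7,
    n_group_b: int = 14,
    mph_mean: float = 90.0,
    mph_sd: float = 15.0,
    seed: int = 0,
) -> MatingDesign:
    """Full-factorial mating design with normally distributed MPH values.

    Defaults mirror a 7 x 14 two-pool factorial (98 hybrids) with MPH for
    grain yield around 90% of the mid-parent and a 15-point spread.
    """
    if n_group_a < 2 or n_group_b < 2:
        raise ValueError("each heterotic group needs at least 2 parents")
    rng = np.random.default_rng(seed)
    a_ids = [f"A{i + 1:02d}" for i in range(n_group_a)]
    b_ids = [f"B{i + 1:02d}" for i in range(n_group_b)]
    parents = [(p, "A") for p in a_ids] + [(p, "B") for p in b_ids]

    sh_a, sh_b, sh_e = MPH_VARIANCE_SHARES
    g_a = _stratified_effects(rng, n_group_a, mph_sd * np.sqrt(sh_a))
    g_b = _stratified_effects(rng, n_group_b, mph_sd * np.sqrt(sh_b))
    hybrids = []
    for i, a in enumerate(a_ids):
        for j, b in enumerate(b_ids):
            mph = mph_mean + g_a[i] + g_b[j] + rng.normal(0.0, mph_sd * np.sqrt(sh_e))
            hybrids.append(Hybrid(f"{a}x{b}", a, b, float(mph)))
    return MatingDesign(parents=parents, hybrids=hybrids)


# ---------------------------------------------------------------------------
# Count matrices with planted associations
# ---------------------------------------------------------------------------


@dataclass
class PlantedSrna:
    srna_id: str
    direction: str  # "positive" | "negative"
    realized_oL: int
    realized_oH: int


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated count matrix, for recovery tests."""

    planted: list[PlantedSrna] = field(default_factory=list)
    group_specific: list[tuple[str, str]] = field(default_factory=list)

    @property
    def planted_ids(self) -> dict[str, str]:
        return {p.srna_id: p.direction for p in self.planted}

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            (p.srna_id, p.direction, p.realized_oL, p.realized_oH) for p in self.planted
        ]
        pd.DataFrame(
            rows, columns=["srna_id", "direction", "realized_oL", "realized_oH"]
        ).to_csv(path, sep="\t", index=False)


def _random_sequences(rng: np.random.Generator, lengths: Sequence[int]) -> list[str]:
    """Distinct random ACGT sequences of the requested lengths."""
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out = []
    for L in lengths:
        while True:
            seq = "".join(bases[rng.integers(0, 4, int(L))])
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                break
    return out


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (Poisson when dispersion = 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _mean_mph_rank(design: MatingDesign, group: str) -> list[str]:
    """Group parents ordered by the mean MPH of their hybrids, ascending."""
    mph = design.mph
    pairs = design.hybrid_pairs()
    means = {}
    for p in design.group_parents(group):
        vals = [mph[h] for h, pair in pairs.items() if p in pair]
        means[p] = float(np.mean(vals)) if vals else 0.0
    return sorted(means, key=lambda p: (means[p], p))


def simulate_srna_counts(
    design: MatingDesign,
    n_srnas: int = 5000,
    n_planted_pos: int = 100,
    n_planted_neg: int = 200,
    shared_fraction: float = 0.35,
    lib_size: int = 200_000,
    dispersion: float = 0.3,
    seed: int = 0,
    planted_neg_length: int = 22,
    planted_pos_length: int = 24,
    length_weights: Mapping[int, float] = None,
    presence_prob: float = 0.95,
    params: DEParams = DEParams(),
) -> tuple[CountMatrix, SyntheticTruth]:
    """Sparse raw sRNA count matrix for the parents, with planted associations.

    Non-planted sRNAs have expression states (shared between or specific to the
    heterotic groups, with per-parent presence noise) independent of MPH.
    Planted sRNAs are expressed only in a few extreme-ranked group-A parents
    (see module docstring), of the stated lengths (negative 22 nt, positive
    24 nt by default).  Returns the raw CountMatrix (rows: sRNA sequences,
    columns: parent library ids) and the ground truth with realized o_L/o_H.
    """
    if n_planted_pos + n_planted_neg > n_srnas:
        raise ValueError("planted sRNAs cannot exceed n_srnas")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    n_planted = n_planted_pos + n_planted_neg
    if n_planted and len(design.hybrids) < 2:
        raise ValueError(
            "planted associations are unattainable for a degenerate design "
            "(need at least 2 hybrids)"
        )
    rng = np.random.default_rng(seed)
    if length_weights is None:
        length_weights = DEFAULT_LENGTH_WEIGHTS

    parents = design.parent_ids
    groups = design.group_of
    n_par = len(parents)
    a_mask = np.array([groups[p] == "A" for p in parents])

    # Row layout: negatives, positives, then background sRNAs.
    lens = np.empty(n_srnas, dtype=int)
    lens[:n_planted_neg] = planted_neg_length
    lens[n_planted_neg:n_planted] = planted_pos_length
    lw_keys = np.array(sorted(length_weights))
    lw_p = np.array([length_weights[k] for k in lw_keys], dtype=float)
    lw_p = lw_p / lw_p.sum()
    lens[n_planted:] = rng.choice(lw_keys, size=n_srnas - n_planted, p=lw_p)
    sequences = _random_sequences(rng, lens)

    means = np.zeros((n_srnas, n_par))
    truth = SyntheticTruth()

    # Planted rows: expressed in a few extreme-ranked group-A parents only.
    ranked_a = _mean_mph_rank(design, "A")
    k_sel = max(1, min(PLANT_K_PARENTS, len(ranked_a) - 1))
    rank_w = np.exp(-PLANT_RANK_DECAY * np.arange(len(ranked_a)))
    rank_w /= rank_w.sum()
    col = {p: j for j, p in enumerate(parents)}
    planted_dirs = ["negative"] * n_planted_neg + ["positive"] * n_planted_pos
    for i, direction in enumerate(planted_dirs):
        order = ranked_a if direction == "negative" else ranked_a[::-1]
        chosen = rng.choice(len(order), size=k_sel, replace=False, p=rank_w)
        mu = rng.lognormal(np.log(60.0), 0.3)
        for c in chosen:
            means[i, col[order[c]]] = mu

    # Background rows: group-shared or group-specific, independent of MPH.
    n_bg = n_srnas - n_planted
    if n_bg:
        base_mu = rng.lognormal(np.log(15.0), 1.0, n_bg)
        shared = rng.random(n_bg) < shared_fraction
        spec_a = ~shared & (rng.random(n_bg) < 0.5)
        spec_b = ~shared & ~spec_a
        present = rng.random((n_bg, n_par)) < presence_prob
        bg = base_mu[:, None] * present
        bg[np.ix_(spec_a, ~a_mask)] = 0.0
        bg[np.ix_(spec_b, a_mask)] = 0.0
        means[n_planted:] = bg
        for k in np.flatnonzero(spec_a):
            truth.group_specific.append((sequences[n_planted + k], "A"))
        for k in np.flatnonzero(spec_b):
            truth.group_specific.append((sequences[n_planted + k], "B"))

    # Scale means so library totals land near lib_size, then sample counts.
    col_totals = means.sum(axis=0)
    scale = lib_size / max(col_totals.mean(), 1e-12)
    counts = _negative_binomial(rng, means * scale, dispersion)

    data = pd.DataFrame(
        counts.astype(float), index=pd.Index(sequences, name="srna"), columns=parents
    )
    matrix = CountMatrix(data=data, stage="raw")

    if n_planted:
        realized = _realized_class_counts(matrix, design, params)
        for i, direction in enumerate(planted_dirs):
            o_l, o_h = realized[sequences[i]]
            truth.planted.append(PlantedSrna(sequences[i], direction, o_l, o_h))
    return matrix, truth


def _realized_class_counts(
    matrix: CountMatrix, design: MatingDesign, params: DEParams
) -> dict[str, tuple[int, int]]:
    """o_L/o_H per sRNA, recomputed from the emitted matrix via the pipeline."""
    from .association import count_de_by_class, split_classes

    dem = de_matrix(rpmqn(matrix), design.hybrid_pairs().values(), params)
    counts = count_de_by_class(dem, split_classes(design), design)
    return {
        s: (int(r.o_L), int(r.o_H)) for s, r in counts.iterrows()
    }


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


@dataclass
class Chromosome:
    name: str
    length: int
    centromere: tuple[int, int]
    sequence: str | None = None


@dataclass
class SyntheticGenome:
    """Toy genome: chromosomes with centromeres, gene/repeat annotation and a
    genetic map with pericentromeric recombination suppression."""

    chromosomes: list[Chromosome]
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id (0-based half-open)
    repeats: pd.DataFrame  # chrom, start, end, strand, family, repeat_id
    genetic_map: pd.DataFrame  # chrom, bp, cM

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    @property
    def centromeres(self) -> dict[str, tuple[int, int]]:
        return {c.name: c.centromere for c in self.chromosomes}

    def sequences(self) -> dict[str, str]:
        if any(c.sequence is None for c in self.chromosomes):
            raise ValueError("genome was simulated without sequence")
        return {c.name: c.sequence for c in self.chromosomes}

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        seqs = self.sequences()
        with open(path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        """Genes and repeats as GFF3 (1-based closed coordinates)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in self.genes.itertuples():
                fh.write(
                    f"{r.chrom}\tsynthetic\tgene\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene_id}\n"
                )
            for r in self.repeats.itertuples():
                fh.write(
                    f"{r.chrom}\tsynthetic\trepeat_region\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.repeat_id};family={r.family}\n"
                )

    def write_map_tsv(self, path: str | Path) -> None:
        self.genetic_map.to_csv(path, sep="\t", index=False)


def _place_intervals(
    rng: np.random.Generator, chrom_len: int, lengths: np.ndarray
) -> list[tuple[int, int]]:
    """Non-overlapping intervals with Dirichlet-distributed gaps."""
    total = int(lengths.sum())
    free = chrom_len - total
    if free < 0.1 * chrom_len:
        raise ValueError(
            "annotation density exceeds chromosome capacity "
            f"(requested {total} bp of {chrom_len})"
        )
    gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * free
    out = []
    pos = 0.0
    for gap, length in zip(gaps, lengths):
        pos += gap
        start = int(pos)
        out.append((start, start + int(length)))
        pos += length
    return out


def simulate_genome(
    n_chrom: int = 10,
    chrom_len: int = 10_000_000,
    gene_density: float = 30.0,
    repeat_density: float = 80.0,
    seed: int = 0,
    with_sequence: bool = True,
    marker_spacing: int = 200_000,
    arm_rate: float = 1.5,
    centromere_rate: float = 0.05,
) -> SyntheticGenome:
    """Toy genome with centromeres, annotations and a genetic map.

    Densities are per Mbp.  The centromere occupies the middle 10% of each
    chromosome; the genetic map accrues ``arm_rate`` cM/Mb on the arms and
    ``centromere_rate`` cM/Mb across the centromeric third, emulating strong
    pericentromeric recombination suppression while keeping cM strictly
    increasing.
    """
    if chrom_len < 1_000_000:
        raise ValueError("chrom_len must be at least 1 Mbp")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    chroms, gene_rows, repeat_rows, map_rows = [], [], [], []
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        seq = None
        if with_sequence:
            seq = bases[rng.integers(0, 4, chrom_len)].tobytes().decode()
        cen = (int(0.45 * chrom_len), int(0.55 * chrom_len))
        chroms.append(Chromosome(name=name, length=chrom_len, centromere=cen, sequence=seq))

        n_genes = int(round(gene_density * chrom_len / 1e6))
        n_repeats = int(round(repeat_density * chrom_len / 1e6))
        gene_lens = np.clip(rng.lognormal(np.log(3000), 0.5, n_genes), 200, None).astype(int)
        rep_lens = np.clip(rng.lognormal(np.log(800), 0.7, n_repeats), 50, None).astype(int)
        for k, (s, e) in enumerate(_place_intervals(rng, chrom_len, gene_lens)):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((name, s, e, strand, f"{name}_g{k + 1}"))
        fams = rng.choice(REPEAT_FAMILIES, size=n_repeats, p=REPEAT_FAMILY_WEIGHTS)
        for k, (s, e) in enumerate(_place_intervals(rng, chrom_len, rep_lens)):
            strand = "+" if rng.random() < 0.5 else "-"
            repeat_rows.append((name, s, e, strand, fams[k], f"{name}_r{k + 1}"))

        positions = list(range(0, chrom_len, marker_spacing))
        if positions[-1] != chrom_len:
            positions.append(chrom_len)
        cm = 0.0
        map_rows.append((name, 0, 0.0))
        for a, b in zip(positions[:-1], positions[1:]):
            mid = (a + b) / 2
            rate = centromere_rate if chrom_len / 3 <= mid < 2 * chrom_len / 3 else arm_rate
            cm += rate * (b - a) / 1e6
            map_rows.append((name, b, cm))

    return SyntheticGenome(
        chromosomes=chroms,
        genes=pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"]),
        repeats=pd.DataFrame(
            repeat_rows, columns=["chrom", "start", "end", "strand", "family", "repeat_id"]
        ),
        genetic_map=pd.DataFrame(map_rows, columns=["chrom", "bp", "cM"]),
    )


# ---------------------------------------------------------------------------
# Mapping assignment
# ---------------------------------------------------------------------------


def assign_mappings(
    srnas: Mapping[str, int] | Iterable[str],
    genome: SyntheticGenome,
    multimap_profile: Mapping[int, float],
    seed: int = 0,
    pericentromeric_bias: float = 0.0,
    bias_ids: Iterable[str] | None = None,
) -> MappingTable:
    """Random genomic positions per sRNA with a stated multi-mapping profile.

    ``srnas`` maps ids to lengths (or is an iterable of sequences used as
    their own ids).  ``multimap_profile`` is a distribution over position
    counts (0 = unmapped).  With ``pericentromeric_bias`` p > 0, positions of
    sRNAs in ``bias_ids`` (default: all) are drawn, with probability p, from a
    normal centered on a centromere instead of uniformly — the hook for
    spatial-enrichment tests.
    """
    if not isinstance(srnas, Mapping):
        srnas = {s: len(s) for s in srnas}
    ks = sorted(multimap_profile)
    probs = np.array([multimap_profile[k] for k in ks], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("multimap_profile must be a probability distribution")
    if min(ks) < 0:
        raise ValueError("position counts must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    chrom_w = np.array([c.length for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    biased = set(bias_ids) if bias_ids is not None else set(srnas)

    entries: dict[str, list] = {}
    for srna_id in srnas:
        length = int(srnas[srna_id])
        k = int(rng.choice(ks, p=probs))
        if k == 0:
            continue
        positions = []
        for _ in range(k):
            ci = int(rng.choice(len(chroms), p=chrom_w))
            chrom = chroms[ci]
            hi = chrom.length - length
            if pericentromeric_bias > 0 and srna_id in biased and rng.random() < pericentromeric_bias:
                center = (chrom.centromere[0] + chrom.centromere[1]) / 2
                start = int(np.clip(rng.normal(center, chrom.length / 12), 0, hi))
            else:
                start = int(rng.integers(0, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            positions.append((chrom.name, start, start + length, strand))
        entries[srna_id] = positions
    return MappingTable(entries)


# ---------------------------------------------------------------------------
# Raw reads
# ---------------------------------------------------------------------------


def simulate_reads(
    counts: CountMatrix,
    adapter: str,
    per_base_error: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[str, str, str]]]:
    """FASTQ records per library: each sRNA emitted ``count`` times with the 3'
    adapter appended.

    With ``per_base_error`` = 0 every base is Phred 40 and
    collapse(preprocess(reads)) reproduces the counts exactly; with e > 0
    bases are substituted uniformly among the three alternatives and all
    qualities are set to the Phred score matching e.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    rng = np.random.default_rng(seed)
    q = 40 if per_base_error <= 0 else int(round(-10 * np.log10(per_base_error)))
    qchar = chr(33 + q)
    alternatives = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

    out: dict[str, list[tuple[str, str, str]]] = {}
    for lib in counts.libraries:
        records = []
        col = counts.data[lib]
        for srna in counts.data.index[col.to_numpy() > 0]:
            n = int(col[srna])
            for rep in range(n):
                read = str(srna) + adapter
                if per_base_error > 0:
                    chars = list(read)
                    errs = np.flatnonzero(rng.random(len(chars)) < per_base_error)
                    for i in errs:
                        chars[i] = alternatives[chars[i]][rng.integers(0, 3)]
                    read = "".join(chars)
                records.append((f"{lib}:{srna}:{rep}", read, qchar * len(read)))
        out[lib] = records
    return out


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
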