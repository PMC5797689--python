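"""Shared containers for the sRNA-heterosis pipeline.

The pipeline relates expression variation of small RNAs between inbred
parents of a factorial mating scheme to mid-parent heterosis (MPH) of the
resulting hybrids.  Two containers are shared by every stage:

* :class:`MatingDesign` — the parents of two heterotic groups, the hybrids
  (one per inter-group parent pair) and their MPH trait values.
* :class:`CountMatrix` — a unique-sRNA-sequence x library expression matrix
  tagged with its normalization stage (``raw`` -> ``quantile`` -> ``rpmqn``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

STAGES = ("raw", "quantile", "rpmqn")


@dataclass(frozen=True)
class Hybrid:
    hybrid_id: str
    mother_id: str
    father_id: str
    mph: float

    @property
    def pair(self) -> tuple[str, str]:
        """Parent pair as a canonical (sorted) tuple."""
        return tuple(sorted((self.mother_id, self.father_id)))


@dataclass
class MatingDesign:
    """Factorial mating design: parents in two heterotic groups, hybrids with MPH.

    Parameters
    ----------
    parents
        ``(parent_id, group)`` tuples; ``group`` is ``"A"`` or ``"B"``.
    hybrids
        :class:`Hybrid` records, one per inter-group cross.
    """

    parents: list[tuple[str, str]]
    hybrids: list[Hybrid]

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.parents]
        if len(set(ids)) != len(ids):
            raise ValueError("parent ids must be unique")
        hids = [h.hybrid_id for h in self.hybrids]
        if len(set(hids)) != len(hids):
            raise ValueError("hybrid ids must be unique")
        group = dict(self.parents)
        for h in self.hybrids:
            if h.mother_id not in group or h.father_id not in group:
                raise ValueError(f"hybrid {h.hybrid_id} references unknown parent")
            if group[h.mother_id] == group[h.father_id]:
                raise ValueError(
                    f"hybrid {h.hybrid_id}: parents must come from different groups"
                )

    @property
    def group_of(self) -> dict[str, str]:
        return dict(self.parents)

    def group_parents(self, group: str) -> list[str]:
        return [p for p, g in self.parents if g == group]

    @property
    def parent_ids(self) -> list[str]:
        return [p for p, _ in self.parents]

    @property
    def mph(self) -> pd.Series:
        return pd.Series(
            {h.hybrid_id: h.mph for h in self.hybrids}, name="mph", dtype=float
        )

    def hybrid_pairs(self) -> dict[str, tuple[str, str]]:
        return {h.hybrid_id: h.pair for h in self.hybrids}

    # --- TSV round trip (hybrid_id, parent1, parent2, mph + parent table) ---

    def write_tsv(self, hybrids_path: str | Path, parents_path: str | Path) -> None:
        pd.DataFrame(self.parents, columns=["parent_id", "group"]).to_csv(
            parents_path, sep="\t", index=False
        )
        rows = [(h.hybrid_id, h.mother_id, h.father_id, h.mph) for h in self.hybrids]
        pd.DataFrame(rows, columns=["hybrid_id", "parent1", "parent2", "mph"]).to_csv(
            hybrids_path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, hybrids_path: str | Path, parents_path: str | Path) -> "MatingDesign":
        par = pd.read_csv(parents_path, sep="\t")
        hyb = pd.read_csv(hybrids_path, sep="\t")
        parents = list(zip(par["parent_id"].astype(str), par["group"].astype(str)))
        hybrids = [
            Hybrid(str(r.hybrid_id), str(r.parent1), str(r.parent2), float(r.mph))
            for r in hyb.itertuples()
        ]
        return cls(parents, hybrids)


@dataclass
class CountMatrix:
    """sRNA x library expression matrix with a normalization-stage tag."""

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("count matrix must be nonnegative")

    @property
    def libraries(self) -> list[str]:
        return list(self.data.columns)

    @property
    def srnas(self) -> pd.Index:
        return self.data.index

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# stage: {self.stage}\n")
            self.data.to_csv(fh, sep="\t", index_label="srna")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        stage = "raw"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# stage:"):
                stage = first.split(":", 1)[1].strip()
                data = pd.read_csv(fh, sep="\t", index_col="srna")
            else:
                fh.seek(0)
                data = pd.read_csv(fh, sep="\t", index_col="srna")
        return cls(data=data, stage=stage)


def counts_to_matrix(per_library: dict[str, dict[str, int]]) -> CountMatrix:
    """Combine per-library ``sequence -> count`` maps into a raw CountMatrix."""
    df = pd.DataFrame(per_library).fillna(0.0)
    df = df.sort_index()
    df.index.name = "srna"
    return CountMatrix(data=df.astype(float), stage="raw")
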