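"""Core data containers shared across the pipeline.

The pipeline operates on a fully crossed factorial RNA-seq design:
``cultivar x tissue x stage x soil`` with a fixed number of biological
replicates per condition.  :class:`SampleDesign` holds the sample sheet and
the ordered factor levels; :class:`CountMatrix` binds a gene x sample
integer count table to its design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The four experimental factors, in nesting order used for sample and
#: condition ordering (replicate nests innermost).
FACTORS: tuple[str, ...] = ("cultivar", "tissue", "stage", "soil")

#: Default level names used when a design is specified by level counts only.
DEFAULT_LEVELS: dict[str, tuple[str, ...]] = {
    "cultivar": ("Corvina", "Glera"),
    "tissue": ("pulp", "skin"),
    "stage": ("S", "CV", "R"),
    "soil": ("F", "VV", "L"),
}


def _auto_levels(factor: str, n: int) -> tuple[str, ...]:
    named = DEFAULT_LEVELS.get(factor, ())
    if n <= len(named):
        return named[:n]
    return tuple(f"{factor}{i + 1}" for i in range(n))


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet of a complete-crossing factorial design.

    Parameters
    ----------
    table:
        One row per sample, indexed by ``sample_id``, with columns
        ``cultivar, tissue, stage, soil, replicate``.
    levels:
        Ordered levels of each factor; column order of condition profiles
        and nesting order of samples follow this.
    """

    table: pd.DataFrame
    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = [c for c in (*FACTORS, "replicate") if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        # complete-crossing invariant
        counts = self.table.groupby(list(FACTORS), observed=False).size()
        expected = int(np.prod([len(self.levels[f]) for f in FACTORS]))
        if len(counts) != expected or counts.nunique() != 1:
            raise ValueError("design is not a complete crossing with equal replication")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def n_replicates(self) -> int:
        return int(self.table.groupby(list(FACTORS), observed=False).size().iloc[0])

    @property
    def conditions(self) -> list[tuple[str, ...]]:
        """All factor-level combinations in nesting order."""
        out: list[tuple[str, ...]] = []
        for c in self.levels["cultivar"]:
            for t in self.levels["tissue"]:
                for s in self.levels["stage"]:
                    for o in self.levels["soil"]:
                        out.append((c, t, s, o))
        return out

    @property
    def condition_ids(self) -> list[str]:
        return [".".join(c) for c in self.conditions]

    def condition_of_samples(self) -> pd.Series:
        """Condition id of every sample (sample_id -> condition id)."""
        return self.table[list(FACTORS)].astype(str).agg(".".join, axis=1)

    def samples_of_condition(self) -> dict[str, list[str]]:
        cond = self.condition_of_samples()
        return {cid: list(cond.index[cond == cid]) for cid in self.condition_ids}


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer read counts bound to a design."""

    counts: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.counts.columns) != self.design.sample_ids:
            raise ValueError("count matrix columns do not match design sample ids")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.design)


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset, the oracle for downstream tests.

    Fields are filled incrementally by the generator stages; ``merge``
    combines partial truths.  Inadequate-profile labels override archetype
    membership for genes that were overwritten by planting.
    """

    seed: int | None = None
    archetype_of: dict[str, str] = field(default_factory=dict)
    inadequate: dict[str, str] = field(default_factory=dict)  # gene -> label
    motifs: dict[str, dict] = field(default_factory=dict)  # gene -> {offset, strand}
    terms: dict[str, dict] = field(default_factory=dict)  # term -> planting record

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        arch = dict(self.archetype_of)
        arch.update(other.archetype_of)
        inad = dict(self.inadequate)
        inad.update(other.inadequate)
        for g in inad:
            arch.pop(g, None)
        motifs = {**self.motifs, **other.motifs}
        terms = {**self.terms, **other.terms}
        return SyntheticTruth(self.seed if self.seed is not None else other.seed,
                              arch, inad, motifs, terms)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "archetype_of": self.archetype_of,
            "inadequate": self.inadequate,
            "motifs": self.motifs,
            "terms": self.terms,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            seed=d.get("seed"),
            archetype_of=dict(d.get("archetype_of", {})),
            inadequate=dict(d.get("inadequate", {})),
            motifs={g: dict(v) for g, v in d.get("motifs", {}).items()},
            terms={t: dict(v) for t, v in d.get("terms", {}).items()},
        )
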