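"""Bin quality from single-copy essential-gene statistics.

A bin drawn from a single microbial population should contain each
essential single-copy gene at most once; multiple copies signal
contamination (mixed populations), while the fraction of the gene
universe recovered measures completeness. Gene detection itself (HMM
search against the marker models) is consumed as a precomputed
contig → gene occurrence table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._essential_genes_synthetic import ESSENTIAL_GENES_SYNTHETIC
from .io_formats import SequenceRecord

__all__ = [
    "MarkerTable",
    "BinStats",
    "PartitionComparison",
    "default_gene_universe",
    "read_marker_table",
    "assess_bin",
    "compare_partitions",
]


def default_gene_universe() -> tuple[str, ...]:
    """The shipped 107-gene single-copy universe (synthetic stand-in names)."""
    return ESSENTIAL_GENES_SYNTHETIC


@dataclass
class MarkerTable:
    """Contig id → multiset of essential genes detected on that contig.

    Multiplicities count occurrences: a gene found twice on one contig
    has copy number 2. Every gene must belong to ``gene_universe``.
    """

    assignments: dict[str, Counter]
    gene_universe: tuple[str, ...] = field(default_factory=default_gene_universe)

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        if len(universe) != len(self.gene_universe):
            raise ValueError("gene universe contains duplicates")
        for contig, genes in self.assignments.items():
            unknown = set(genes) - universe
            if unknown:
                raise ValueError(
                    f"contig {contig!r} carries genes outside the universe: {sorted(unknown)}"
                )
            if any(m < 1 for m in genes.values()):
                raise ValueError(f"contig {contig!r} has non-positive multiplicities")

    def genes_on(self, contig_id: str) -> Counter:
        return self.assignments.get(contig_id, Counter())


def read_marker_table(
    path: str | Path, gene_universe: Sequence[str] | None = None
) -> MarkerTable:
    """Read a (contig_id, gene_id) table, one row per gene occurrence.

    Comma- or tab-separated, with or without a header row.
    """
    sep = "\t" if "\t" in Path(path).read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str, header=None)
    if df.shape[1] != 2:
        raise ValueError("marker table must have exactly 2 columns: contig_id, gene_id")
    first = df.iloc[0]
    if {first[0].lower(), first[1].lower()} & {"contig_id", "contig", "gene_id", "gene"}:
        df = df.iloc[1:]
    assignments: dict[str, Counter] = {}
    for contig, gene in zip(df[0], df[1]):
        assignments.setdefault(str(contig), Counter())[str(gene)] += 1
    universe = tuple(gene_universe) if gene_universe is not None else default_gene_universe()
    return MarkerTable(assignments=assignments, gene_universe=universe)


@dataclass
class BinStats:
    """One report row: contig count, size, and essential-gene copy numbers.

    ``single_copy`` counts genes present exactly once across the bin,
    ``multiple_copies`` genes present at least twice; completeness is the
    fraction of the gene universe present at all.
    """

    name: str
    n_contigs: int
    total_bp: int
    single_copy: int
    multiple_copies: int
    universe_size: int

    @property
    def total_mbp(self) -> float:
        """Total size in Mbp, rounded half-even to 2 decimals for display."""
        return float(round(self.total_bp / 1e6, 2))

    @property
    def completeness(self) -> float:
        return (self.single_copy + self.multiple_copies) / self.universe_size


def assess_bin(
    bin_ids: Sequence[str],
    records: Sequence[SequenceRecord] | Mapping[str, int],
    markers: MarkerTable,
    name: str = "bin",
) -> BinStats:
    """Aggregate essential-gene copy numbers over the contigs of one bin.

    ``records`` supplies contig lengths (as SequenceRecords or an
    id → length mapping); every bin id must be present there. Genes
    absent from all bin contigs count toward neither single_copy nor
    multiple_copies. Order of bin ids is irrelevant.
    """
    if isinstance(records, Mapping):
        lengths = records
    else:
        lengths = {r.id: r.length for r in records}
    missing = [i for i in bin_ids if i not in lengths]
    if missing:
        raise KeyError(f"bin contigs absent from records: {missing[:5]}")
    if len(set(bin_ids)) != len(bin_ids):
        raise ValueError("duplicate contig ids in bin")
    copy_numbers: Counter = Counter()
    for contig in bin_ids:
        copy_numbers.update(markers.genes_on(contig))
    single = sum(1 for c in copy_numbers.values() if c == 1)
    multiple = sum(1 for c in copy_numbers.values() if c >= 2)
    return BinStats(
        name=name,
        n_contigs=len(bin_ids),
        total_bp=sum(lengths[i] for i in bin_ids),
        single_copy=single,
        multiple_copies=multiple,
        universe_size=len(markers.gene_universe),
    )


@dataclass
class PartitionComparison:
    """Parent bin vs its refined subclusters, with quality deltas.

    Subclusters need not partition the parent: reselection on the
    embedding may recruit contigs the automatic binning missed, so a
    subcluster's completeness can exceed the parent's.
    """

    parent: BinStats
    subclusters: list[BinStats]

    @property
    def delta_multiple_copies(self) -> list[int]:
        return [s.multiple_copies - self.parent.multiple_copies for s in self.subclusters]

    @property
    def delta_completeness(self) -> list[float]:
        return [s.completeness - self.parent.completeness for s in self.subclusters]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stats, d_mult, d_comp in zip(
            [self.parent] + self.subclusters,
            [0] + self.delta_multiple_copies,
            [0.0] + self.delta_completeness,
        ):
            rows.append(
                {
                    "bin": stats.name,
                    "n_contigs": stats.n_contigs,
                    "mbp": stats.total_mbp,
                    "single_copy": stats.single_copy,
                    "multiple_copies": stats.multiple_copies,
                    "completeness": stats.completeness,
                    "delta_multiple_copies": d_mult,
                    "delta_completeness": d_comp,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_partitions(
    parent_bin: Sequence[str],
    subclusters: Sequence[Sequence[str]],
    records: Sequence[SequenceRecord] | Mapping[str, int],
    markers: MarkerTable,
    names: Sequence[str] | None = None,
) -> PartitionComparison:
    """Score a parent bin against refined subclusters drawn on the embedding."""
    if names is None:
        names = [f"sub{i + 1:03d}" for i in range(len(subclusters))]
    parent = assess_bin(list(parent_bin), records, markers, name="parent")
    subs = [
        assess_bin(list(ids), records, markers, name=str(n))
        for ids, n in zip(subclusters, names)
    ]
    return PartitionComparison(parent=parent, subclusters=subs)
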