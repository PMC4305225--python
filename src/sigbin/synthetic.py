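"""Mock metagenomic communities with population-specific k-mer composition.

Each population is an order-m Markov source over {A, C, G, T} whose
transition rows are Dirichlet draws; the Dirichlet concentration is
controlled by a ``divergence`` knob (0 → exactly uniform rows, i.e. all
populations identical i.i.d. sequence; near 1 → strongly skewed,
well-separated oligonucleotide signatures). One genome is simulated per
population and cut into fragments at uniform random positions, so every
pipeline stage — signatures, embedding, polygon selection, bin
assessment — can be exercised with known ground truth and no downloads.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .assessment import MarkerTable, default_gene_universe
from .io_formats import SequenceRecord, write_fasta

__all__ = [
    "PopulationModel",
    "SyntheticCommunity",
    "generate_population_model",
    "sample_sequence",
    "generate_community",
    "knn_label_purity",
]

_BASES = "ACGT"


@dataclass
class PopulationModel:
    """Stationary order-m Markov source over nucleotides."""

    order: int
    transitions: np.ndarray  # (4^order, 4), rows sum to 1
    divergence: float
    seed: int

    def __post_init__(self) -> None:
        if self.transitions.shape != (4**self.order, 4):
            raise ValueError("transition matrix shape does not match order")


def generate_population_model(order: int, divergence: float, seed: int) -> PopulationModel:
    """Draw an order-m transition model with composition skew ``divergence``.

    divergence = 0 gives exactly uniform rows (featureless composition);
    rows are otherwise Dirichlet(c, c, c, c) with c = 10 (1 − d) / d
    (clamped at 0.05), so higher divergence yields more idiosyncratic,
    hence more separable, k-mer composition. Deterministic per seed.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must be in [0, 1]")
    n_states = 4**order
    if divergence == 0.0:
        transitions = np.full((n_states, 4), 0.25)
    else:
        conc = max(10.0 * (1.0 - divergence) / divergence, 0.05)
        rng = np.random.default_rng(seed)
        transitions = rng.dirichlet(np.full(4, conc), size=n_states)
    return PopulationModel(order=order, transitions=transitions, divergence=divergence, seed=seed)


def sample_sequence(model: PopulationModel, length: int, rng: np.random.Generator) -> str:
    """Simulate ``length`` nt from the Markov source (first m bases uniform)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    m = model.order
    cum = np.cumsum(model.transitions, axis=1)
    out = np.empty(length, dtype=np.int64)
    head = min(m, length)
    out[:head] = rng.integers(0, 4, size=head)
    state = 0
    for i in range(head):
        state = (state * 4 + out[i]) % (4**m if m else 1)
    u = rng.random(length)
    mask = 4**m - 1 if m else 0
    for i in range(head, length):
        b = int(np.searchsorted(cum[state], u[i], side="right"))
        b = min(b, 3)
        out[i] = b
        state = ((state << 2) | b) & mask
    return "".join(_BASES[b] for b in out)


@dataclass
class SyntheticCommunity:
    """Ground-truthed mock community: fragments, labels, coverage, markers."""

    populations: list[PopulationModel]
    fragments: list[SequenceRecord]
    labels: list[str]
    coverages: list[float]
    markers: MarkerTable

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.fragments]

    def write_fixture(self, outdir: str | Path) -> dict[str, Path]:
        """Materialize FASTA + annotation file + marker table + truth labels."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "community.fasta",
            "annotations": outdir / "annotations.csv",
            "markers": outdir / "markers.csv",
            "labels": outdir / "labels.csv",
        }
        write_fasta(self.fragments, paths["fasta"])
        with open(paths["annotations"], "w") as fh:
            fh.write("length,coverage,gc,label,isMarker\n")
            for frag, label, cov in zip(self.fragments, self.labels, self.coverages):
                seq = frag.sequence
                gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
                is_marker = 1 if self.markers.genes_on(frag.id) else 0
                fh.write(f"{frag.length},{cov:.4f},{gc:.4f},{label},{is_marker}\n")
        with open(paths["markers"], "w") as fh:
            for contig in self.ids:
                for gene, mult in sorted(self.markers.genes_on(contig).items()):
                    for _ in range(mult):
                        fh.write(f"{contig},{gene}\n")
        with open(paths["labels"], "w") as fh:
            fh.write("id,label\n")
            for frag, label in zip(self.fragments, self.labels):
                fh.write(f"{frag.id},{label}\n")
        return paths


def generate_community(
    n_pops: int = 5,
    genome_length: int = 100_000,
    frag_length_dist: tuple[int, int] = (1000, 1200),
    n_frags_per_pop: int = 200,
    divergence: float = 0.8,
    seed: int = 0,
    order: int = 4,
    marker_genes: Sequence[str] | None = None,
) -> SyntheticCommunity:
    """Simulate a community: one genome per population, cut into fragments.

    ``frag_length_dist`` is (min, mean): lengths are min + Exponential
    (mean − min), truncated at the genome length. Each population gets a
    log-normal coverage value shared by its fragments, and each gene of
    ``marker_genes`` (default: the full 107-gene universe) is planted
    exactly once per genome on a uniformly chosen fragment. Byte-identical
    output per seed.
    """
    frag_min, frag_mean = frag_length_dist
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    if frag_min < 1 or frag_mean < frag_min:
        raise ValueError("need 1 <= min fragment length <= mean fragment length")
    if genome_length < frag_min:
        raise ValueError("genome shorter than the minimum fragment length")
    universe = default_gene_universe()
    if marker_genes is None:
        marker_genes = universe
    else:
        marker_genes = tuple(marker_genes)

    populations: list[PopulationModel] = []
    fragments: list[SequenceRecord] = []
    labels: list[str] = []
    coverages: list[float] = []
    assignments: dict[str, Counter] = {}
    for p in range(n_pops):
        pop_id = f"pop{p:02d}"
        model_seed = int((seed * 1009 + 7919 * p) % (2**31))
        model = generate_population_model(order, divergence, model_seed)
        populations.append(model)
        rng = np.random.default_rng([seed, p])
        genome = sample_sequence(model, genome_length, rng)
        coverage = float(rng.lognormal(mean=math.log(10.0), sigma=1.0))
        frag_ids = []
        for i in range(n_frags_per_pop):
            extra = 0.0 if frag_mean == frag_min else rng.exponential(frag_mean - frag_min)
            length = min(frag_min + int(extra), genome_length)
            start = int(rng.integers(0, genome_length - length + 1))
            frag_id = f"{pop_id}_frag{i:04d}"
            fragments.append(SequenceRecord(frag_id, genome[start : start + length]))
            labels.append(pop_id)
            coverages.append(coverage)
            frag_ids.append(frag_id)
        for gene in marker_genes:
            carrier = frag_ids[int(rng.integers(0, len(frag_ids)))]
            assignments.setdefault(carrier, Counter())[gene] += 1
    markers = MarkerTable(assignments=assignments, gene_universe=universe)
    return SyntheticCommunity(
        populations=populations,
        fragments=fragments,
        labels=labels,
        coverages=coverages,
        markers=markers,
    )


def knn_label_purity(embedding, labels: Sequence[str], k: int = 5) -> float:
    """Fraction of points whose k nearest embedded neighbors vote their label.

    A point counts as pure only if its own label is the STRICT majority
    among its k nearest neighbors (ties count as disagreement). Neighbor
    ties in distance break by row index.
    """
    from .embedding import EmbeddingResult

    coords = embedding.coords if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    n = len(coords)
    if not (0 < k < n):
        raise ValueError("need 0 < k < n")
    if len(labels) != n:
        raise ValueError("labels not aligned to embedding")
    sq = np.einsum("ij,ij->i", coords, coords)
    D2 = sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T
    np.fill_diagonal(D2, np.inf)
    order = np.argsort(D2, axis=1, kind="stable")[:, :k]
    pure = 0
    labels = list(labels)
    for i in range(n):
        votes = Counter(labels[j] for j in order[i])
        own = votes.get(labels[i], 0)
        if own > 0 and all(c < own for lab, c in votes.items() if lab != labels[i]):
            pure += 1
    return pure / n
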