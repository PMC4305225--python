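"""Oligonucleotide (k-mer) genomic signatures.

A fragment's signature is the vector of its overlapping k-mer frequencies,
which is characteristic of the genome of origin. Counts over the 4^k
k-mers are smoothed with a pseudocount, normalized to frequencies, and
mapped out of the simplex with the centered log-ratio (CLR) transform
ln(x_i) − mean_j ln(x_j). Optionally the CLR matrix is pre-reduced by PCA
before nonlinear embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "SignatureOptions",
    "SignatureMatrix",
    "KmerCounts",
    "kmer_index",
    "count_kmers",
    "to_frequencies",
    "clr_transform",
    "compute_signature_matrix",
]

_BASES = "ACGT"
# byte -> 2-bit code, -1 for anything not A/C/G/T (upper or lower case)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class SignatureOptions:
    """Parameters of signature computation.

    k: k-mer length (4^k dimensions without reverse-complement merging;
    the default k=5 gives 1,024). merge_revcomp: count each window toward
    the lexicographically smaller of {k-mer, reverse complement}.
    pseudocount: additive smoothing applied before normalization so the
    CLR is defined at zero counts. pca_dims: if set, project the CLR
    matrix onto this many principal components before embedding.
    """

    k: int = 5
    merge_revcomp: bool = False
    pseudocount: float = 1.0
    pca_dims: int | None = 50

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.pca_dims is not None and self.pca_dims < 1:
            raise ValueError("pca_dims must be >= 1 or None")


@dataclass
class SignatureMatrix:
    """n × d signature matrix with its k-mer column order.

    ``stage`` records how far the pipeline has run: raw ``counts``,
    ``frequencies`` (rows sum to 1), ``clr`` (rows sum to 0), or ``pca``
    (columns are principal components, kmer_index no longer applies
    columnwise).
    """

    ids: list[str]
    kmer_index: list[str]
    values: np.ndarray
    stage: str

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Export as a comma-separated table (id column + feature columns)."""
        cols = (
            self.kmer_index
            if self.stage != "pca"
            else [f"PC{i + 1}" for i in range(self.values.shape[1])]
        )
        with open(path, "w") as fh:
            fh.write("id," + ",".join(cols) + "\n")
            for rec_id, row in zip(self.ids, self.values):
                fh.write(rec_id + "," + ",".join(f"{float(v)!r}" for v in row) + "\n")


class KmerCounts(NamedTuple):
    counts: np.ndarray
    valid_windows: int


def _revcomp(kmer: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(kmer))


@lru_cache(maxsize=None)
def _canonical_map(k: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map every 2-bit-encoded k-mer id to its canonical index.

    Canonical k-mer = lexicographic min of {k-mer, reverse complement}
    over A<C<G<T (which coincides with numeric order of the encoding).
    """
    d = 4**k
    ids = np.arange(d, dtype=np.int64)
    rc = np.zeros(d, dtype=np.int64)
    tmp = ids.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    canon_id = np.minimum(ids, rc)
    canon_ids_sorted = np.unique(canon_id)
    position = np.full(d, -1, dtype=np.int64)
    position[canon_ids_sorted] = np.arange(len(canon_ids_sorted))
    index_of = position[canon_id]
    canon_strings = tuple(_decode(i, k) for i in canon_ids_sorted)
    return index_of, canon_strings


def _decode(kmer_id: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[kmer_id % 4])
        kmer_id //= 4
    return "".join(reversed(out))


@lru_cache(maxsize=None)
def kmer_index(k: int, merge_revcomp: bool = False) -> tuple[str, ...]:
    """Ordered k-mer column labels: lexicographic, canonical if merging."""
    if merge_revcomp:
        return _canonical_map(k)[1]
    return tuple(_decode(i, k) for i in range(4**k))


def count_kmers(sequence: str, k: int, merge_revcomp: bool = False) -> KmerCounts:
    """Count overlapping k-mers consisting solely of A/C/G/T.

    Windows containing any other symbol (N, ambiguity codes, ...) are
    skipped. A sequence shorter than k yields the zero vector with
    ``valid_windows == 0``. Case-insensitive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = len(kmer_index(k, merge_revcomp))
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return KmerCounts(np.zeros(d, dtype=np.int64), 0)
    # encode every window as a base-4 integer; windows touching a non-ACGT
    # symbol are poisoned via the -1 code check
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    enc = win[valid] @ powers
    if merge_revcomp:
        enc = _canonical_map(k)[0][enc]
    counts = np.bincount(enc, minlength=d).astype(np.int64)
    return KmerCounts(counts, int(valid.sum()))


def to_frequencies(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Pseudocount-smoothed relative frequencies; strictly positive, sums to 1."""
    counts = np.asarray(counts, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    smoothed = counts + pseudocount
    return smoothed / smoothed.sum(axis=-1, keepdims=True)


def clr_transform(freqs: np.ndarray) -> np.ndarray:
    """Centered log-ratio: ln(x_i) − mean_j ln(x_j). Rows sum to zero.

    Raises on any non-positive component, which signals a missing
    pseudocount upstream.
    """
    freqs = np.asarray(freqs, dtype=float)
    if (freqs <= 0).any():
        raise ValueError("clr_transform requires strictly positive frequencies")
    logs = np.log(freqs)
    return logs - logs.mean(axis=-1, keepdims=True)


def _pca_project(X: np.ndarray, n_components: int) -> np.ndarray:
    """Column-center and project onto the top principal components.

    Sign convention: within each component, the loading with the largest
    magnitude is made positive, so the projection is deterministic.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:n_components]
    flip = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    return Xc @ comps.T


def compute_signature_matrix(
    records: Sequence[SequenceRecord], options: SignatureOptions | None = None
) -> SignatureMatrix:
    """Count → smooth → normalize → CLR each record; optionally PCA-reduce.

    Records are processed in input order under a fixed k-mer column
    order, so the result is a deterministic function of the sequences.
    """
    if options is None:
        options = SignatureOptions()
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a signature matrix")
    index = list(kmer_index(options.k, options.merge_revcomp))
    d = len(index)
    counts = np.empty((len(records), d), dtype=np.int64)
    for i, rec in enumerate(records):
        counts[i] = count_kmers(rec.sequence, options.k, options.merge_revcomp).counts
    clr = clr_transform(to_frequencies(counts, options.pseudocount))
    ids = [r.id for r in records]
    if options.pca_dims is None:
        return SignatureMatrix(ids, index, clr, "clr")
    p = options.pca_dims
    if p >= len(records):
        raise ValueError(f"pca_dims={p} must be < n={len(records)}")
    if p > d:
        raise ValueError(f"pca_dims={p} exceeds signature dimensionality {d}")
    return SignatureMatrix(ids, index, _pca_project(clr, p), "pca")
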