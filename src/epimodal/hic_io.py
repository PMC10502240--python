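"""Whole-genome chromatin interaction matrices.

A Hi-C experiment at a fixed resolution (100 kb typically; scaled down for
tests) yields a symmetric, nonnegative interaction-frequency matrix over all
genome bins.  This module provides the genome<->bin index bridge
(:class:`BinGrid`), readers/writers for dense and COO triplet text formats,
the normalisation schemes used by the structure encoders, and the 1D
ablation featurisations (row-sum accessibility and the sequential
within-chromosome chain graph).

Matrices are stored sparse-first (CSR): real Hi-C maps are mostly empty
(<10% nonzero), and the graph encoders exploit that sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .genome_io import GenomeAssembly


@dataclass(frozen=True)
class BinGrid:
    """Fixed-resolution binning of a genome with global bin indices.

    Bins are numbered chromosome by chromosome in assembly order:
    ``global index = offset(chrom) + floor(position / resolution)``.
    """

    resolution: int
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    @classmethod
    def from_assembly(cls, assembly: GenomeAssembly, resolution: int = 100_000) -> "BinGrid":
        lengths = assembly.chrom_lengths
        return cls(
            resolution=resolution,
            chrom_names=tuple(assembly.chrom_names),
            chrom_lengths=tuple(lengths[c] for c in assembly.chrom_names),
        )

    @property
    def bins_per_chrom(self) -> dict[str, int]:
        return {
            c: -(-length // self.resolution)  # ceil division
            for c, length in zip(self.chrom_names, self.chrom_lengths)
        }

    @property
    def offsets(self) -> dict[str, int]:
        out, acc = {}, 0
        for c, n in self.bins_per_chrom.items():
            out[c] = acc
            acc += n
        return out

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom.values())

    def bin_of(self, chrom: str, position: int) -> int:
        """Global bin index containing ``position`` (0-based)."""
        if chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = dict(zip(self.chrom_names, self.chrom_lengths))[chrom]
        if not (0 <= position < length):
            raise ValueError(f"position {position} outside {chrom} (length {length})")
        return self.offsets[chrom] + position // self.resolution

    def bin_of_interval(self, chrom: str, start: int, end: int) -> int:
        """Assign an interval to the bin containing its centre."""
        return self.bin_of(chrom, (start + end) // 2)

    def chrom_of_bin(self, index: int) -> str:
        if not (0 <= index < self.n_bins):
            raise IndexError(f"bin index {index} out of range")
        for c, off in reversed(self.offsets.items()):
            if index >= off:
                return c
        raise AssertionError("unreachable")


@dataclass
class InteractionMatrix:
    """Symmetric nonnegative contact matrix over a grid's global bins."""

    grid: BinGrid
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match grid ({n} bins)"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("interaction frequencies must be nonnegative")

    @property
    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def entry(self, i: int, j: int) -> float:
        return float(self.values[i, j])


@dataclass
class NormalizedMatrix:
    """A normalised view of an interaction matrix.

    ``row``      — each nonzero row rescaled to sum to 1 (MLP featurisation).
    ``sym_loop`` — D^(-1/2) (log1p(A) + I) D^(-1/2), the symmetric
                   self-loop normalisation used as the GCN propagation
                   operator.
    """

    scheme: str
    values: sp.csr_matrix


def _symmetrize_max(m: sp.spmatrix) -> sp.csr_matrix:
    m = m.tocsr()
    return m.maximum(m.T).tocsr()


def read_contacts(path, grid: BinGrid, format: str = "coo") -> InteractionMatrix:
    """Read a contact matrix from text.

    ``coo`` format: whitespace-separated ``chromA startA chromB startB count``
    lines, coordinates being bin start positions (multiples of the
    resolution).  ``dense`` format: an n_bins x n_bins whitespace-separated
    matrix.  Asymmetric input is symmetrised by the elementwise maximum,
    which tolerates upper-triangle-only files.
    """
    n = grid.n_bins
    if format == "dense":
        arr = np.loadtxt(path, ndmin=2)
        if arr.size == 0:
            arr = np.zeros((n, n))
        if arr.shape != (n, n):
            raise ValueError(f"dense matrix shape {arr.shape}, expected ({n},{n})")
        if arr.min() < 0:
            raise ValueError("negative count in dense contact matrix")
        return InteractionMatrix(grid, _symmetrize_max(sp.csr_matrix(arr)))
    if format != "coo":
        raise ValueError(f"unknown contact format {format!r}")
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            ca, sa, cb, sb, count = parts[0], int(parts[1]), parts[2], int(parts[3]), float(parts[4])
            if sa % grid.resolution or sb % grid.resolution:
                raise ValueError(
                    f"{path}: line {lineno}: coordinate not a multiple of "
                    f"resolution {grid.resolution}"
                )
            if count < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            rows.append(grid.bin_of(ca, sa))
            cols.append(grid.bin_of(cb, sb))
            vals.append(count)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return InteractionMatrix(grid, _symmetrize_max(m))


def write_contacts(matrix: InteractionMatrix, path, format: str = "coo") -> None:
    """Write a contact matrix; COO output emits the upper triangle only
    (including the diagonal) in row-major order, round-tripping bit-exactly."""
    if format == "dense":
        np.savetxt(path, matrix.dense, fmt="%.17g", delimiter="\t")
        return
    grid = matrix.grid
    names = list(grid.chrom_names)
    starts = {}
    for c in names:
        off = grid.offsets[c]
        for b in range(grid.bins_per_chrom[c]):
            starts[off + b] = (c, b * grid.resolution)
    coo = sp.triu(matrix.values).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for k in order:
            i, j, v = int(coo.row[k]), int(coo.col[k]), coo.data[k]
            ca, sa = starts[i]
            cb, sb = starts[j]
            fh.write(f"{ca}\t{sa}\t{cb}\t{sb}\t{v:.17g}\n")


def normalize(matrix: InteractionMatrix, scheme: str = "row") -> NormalizedMatrix:
    """Normalise an interaction matrix for encoding.

    Zero rows stay zero under ``row``; under ``sym_loop`` an isolated bin
    contributes only its self-loop.
    """
    a = matrix.values
    if scheme == "row":
        sums = np.asarray(a.sum(axis=1)).ravel()
        inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
        return NormalizedMatrix("row", sp.diags(inv).dot(a).tocsr())
    if scheme == "sym_loop":
        logged = a.copy()
        logged.data = np.log1p(logged.data)
        with_loops = (logged + sp.identity(a.shape[0], format="csr")).tocsr()
        deg = np.asarray(with_loops.sum(axis=1)).ravel()
        dinv = 1.0 / np.sqrt(deg)
        d = sp.diags(dinv)
        return NormalizedMatrix("sym_loop", d.dot(with_loops).dot(d).tocsr())
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def accessibility(matrix: InteractionMatrix) -> np.ndarray:
    """1D chromatin accessibility proxy: per-bin row sums of the raw matrix."""
    return np.asarray(matrix.values.sum(axis=1)).ravel()


def sequential_graph(grid: BinGrid) -> InteractionMatrix:
    """Unit-weight chain over consecutive bins within each chromosome.

    The 1D regional-order ablation: same encoder input shape as Hi-C but
    carrying only sequential adjacency, no long-range contacts.
    """
    rows, cols = [], []
    for c in grid.chrom_names:
        off = grid.offsets[c]
        for b in range(grid.bins_per_chrom[c] - 1):
            rows.append(off + b)
            cols.append(off + b + 1)
    n = grid.n_bins
    m = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    return InteractionMatrix(grid, _symmetrize_max(m))
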