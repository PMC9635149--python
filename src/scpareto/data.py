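"""Expression-count containers and text/HDF5 input-output.

The central object is :class:`ExpressionDataset`: an integer cell-by-gene
count matrix with per-cell batch labels, optional cell-type annotations and
a train/test split.  Readers accept dense CSV/TSV, MatrixMarket triplets, or
an AnnData ``.h5ad`` file with ``obs['batch']`` (and optionally
``obs['cell_type']``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["ExpressionDataset", "load_dataset", "save_dataset_csv"]


@dataclasses.dataclass
class ExpressionDataset:
    counts: np.ndarray            # (n, G) non-negative integers
    batch: np.ndarray             # (n,) integer batch codes in {0..B-1}
    gene_names: np.ndarray        # (G,) strings
    cell_type: np.ndarray | None = None   # (n,) integer type codes
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cell-by-gene matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            flt = np.asarray(self.counts, dtype=np.float64)
            if not np.all(np.isfinite(flt)) or np.any(flt != np.round(flt)):
                raise ValueError("counts must be finite integers")
            self.counts = flt.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.batch = np.asarray(self.batch, dtype=np.int64)
        if self.batch.shape != (self.counts.shape[0],):
            raise ValueError("batch must have one label per cell")
        if self.batch.min(initial=0) < 0:
            raise ValueError("batch codes must be non-negative integers")
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.gene_names.shape != (self.counts.shape[1],):
            raise ValueError("gene_names must have one entry per gene")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=np.int64)
            if self.cell_type.shape != (self.counts.shape[0],):
                raise ValueError("cell_type must have one label per cell")
        if (self.train_idx is None) != (self.test_idx is None):
            raise ValueError("provide both train_idx and test_idx or neither")
        if self.train_idx is not None:
            self._check_split()

    def _check_split(self):
        tr = np.asarray(self.train_idx, dtype=np.int64)
        te = np.asarray(self.test_idx, dtype=np.int64)
        combined = np.sort(np.concatenate([tr, te]))
        if not np.array_equal(combined, np.arange(self.n_cells)):
            raise ValueError("train/test indices must partition the cells")
        self.train_idx, self.test_idx = tr, te

    # -- basic views ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_batches(self) -> int:
        return int(self.batch.max()) + 1

    def subset(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=np.int64)
        return ExpressionDataset(
            counts=self.counts[idx],
            batch=self.batch[idx],
            gene_names=self.gene_names,
            cell_type=None if self.cell_type is None else self.cell_type[idx],
        )

    def train_subset(self) -> "ExpressionDataset":
        if self.train_idx is None:
            raise ValueError("dataset has no split")
        return self.subset(self.train_idx)

    def test_subset(self) -> "ExpressionDataset":
        if self.test_idx is None:
            raise ValueError("dataset has no split")
        return self.subset(self.test_idx)

    def make_split(self, train_fraction: float, seed: int) -> "ExpressionDataset":
        """Return a copy with a fresh random train/test partition."""
        if not 0.0 < train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n_cells)
        n_train = int(round(train_fraction * self.n_cells))
        n_train = min(max(n_train, 1), self.n_cells - 1)
        return dataclasses.replace(
            self, train_idx=np.sort(perm[:n_train]), test_idx=np.sort(perm[n_train:])
        )


def _read_lines(path: Path) -> np.ndarray:
    return np.asarray(
        [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()],
        dtype=object,
    )


def load_dataset(
    counts_path: str | Path,
    batch_path: str | Path | None = None,
    cell_type_path: str | Path | None = None,
    gene_names_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a dataset from disk.

    ``counts_path`` may be ``.h5ad`` (batch/cell_type taken from ``obs``),
    ``.mtx`` (cells-by-genes; gene names from ``gene_names_path``, batch from
    ``batch_path``, one label per line), or delimited text with a header row
    of gene names.  Batch/cell-type label files contain one label per cell;
    arbitrary strings are encoded to integer codes in sorted order.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".h5ad":
        import anndata

        ad = anndata.read_h5ad(counts_path)
        mat = ad.X
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        if "batch" not in ad.obs:
            raise ValueError("h5ad input requires obs['batch']")
        batch = pd.Categorical(ad.obs["batch"]).codes.astype(np.int64)
        cell_type = None
        if "cell_type" in ad.obs:
            cell_type = pd.Categorical(ad.obs["cell_type"]).codes.astype(np.int64)
        return ExpressionDataset(
            counts=np.asarray(mat),
            batch=batch,
            gene_names=np.asarray(ad.var_names, dtype=object),
            cell_type=cell_type,
        )

    if counts_path.suffix == ".mtx":
        counts = np.asarray(scipy.io.mmread(counts_path).todense())
        if gene_names_path is None:
            raise ValueError(".mtx input requires gene_names_path")
        gene_names = _read_lines(Path(gene_names_path))
    else:
        df = pd.read_csv(counts_path, sep=None, engine="python")
        gene_names = np.asarray(df.columns, dtype=object)
        counts = df.to_numpy()

    if batch_path is None:
        raise ValueError("text input requires batch_path")
    batch = pd.Categorical(_read_lines(Path(batch_path))).codes.astype(np.int64)
    cell_type = None
    if cell_type_path is not None:
        cell_type = pd.Categorical(
            _read_lines(Path(cell_type_path))
        ).codes.astype(np.int64)
    return ExpressionDataset(
        counts=counts, batch=batch, gene_names=gene_names, cell_type=cell_type
    )


def save_dataset_csv(ds: ExpressionDataset, outdir: str | Path, prefix: str = "data"):
    """Write counts (CSV with gene-name header) plus label sidecar files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.counts, columns=ds.gene_names).to_csv(
        outdir / f"{prefix}_counts.csv", index=False
    )
    (outdir / f"{prefix}_batch.txt").write_text(
        "\n".join(str(b) for b in ds.batch) + "\n"
    )
    if ds.cell_type is not None:
        (outdir / f"{prefix}_cell_type.txt").write_text(
            "\n".join(str(t) for t in ds.cell_type) + "\n"
        )
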