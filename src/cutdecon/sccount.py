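"""Single-cell layer: pseudo-bulk, per-cell peak counts, TF-IDF and LSI.

Barcoded fragments are pooled into a pseudo-bulk set for deconvolution
and peak calling; fragments are then counted per cell in the called
peaks (a fragment counts for every peak its half-open interval
intersects by at least 1 bp; overlap-class peaks are excluded).  The
cell-by-peak matrix is binarized and TF-IDF normalised separately per
target::

    TF_ij  = b_ij / sum_j b_ij
    IDF_j  = log(1 + n_cells / (1 + n_cells_with_peak_j))
    X_ij   = log(TF_ij * IDF_j * 1e4 + 1)

followed by a 30-component truncated SVD.  Components among the first
two whose cell coordinates correlate strongly (|r| > 0.9) with log
library size are excluded from the embedding, since sequencing depth
dominates them despite the normalisation.  The most variable peaks are
ranked by absolute loading on the first retained component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from cutdecon.fragio import FRAGMENT_COLUMNS

logger = logging.getLogger(__name__)


def pseudobulk(frags: pd.DataFrame) -> pd.DataFrame:
    """Pool barcoded fragments: drop the barcode, collapse duplicates."""
    if frags.empty or (frags["barcode"] == "").all():
        raise ValueError("no barcoded fragments")
    out = frags.copy()
    out["barcode"] = ""
    out = out.groupby(["chrom", "start", "end", "barcode"], as_index=False)["count"].sum()
    out = out[FRAGMENT_COLUMNS].sort_values(["chrom", "start", "end"], kind="mergesort")
    return out.reset_index(drop=True)


@dataclass
class CellPeakMatrix:
    cells: np.ndarray  # barcodes, sorted
    peaks: pd.DataFrame  # chrom, start, end, target (no overlap class)
    counts: sparse.csr_matrix  # cells x peaks, nonnegative integers
    library_size: np.ndarray  # total fragments per cell (in peaks or not)

    def target_columns(self, target: str) -> np.ndarray:
        return np.flatnonzero(self.peaks["target"].to_numpy() == target)


def count_matrix(frags: pd.DataFrame, peaks) -> CellPeakMatrix:
    """Count fragments per cell and peak.

    ``peaks`` is an iterable of :class:`cutdecon.peakcall.Peak` or a
    DataFrame with columns ``chrom, start, end, target``.  Overlap-class
    peaks are dropped (they are not used downstream).  Within each target
    class peaks must be non-overlapping.
    """
    if not isinstance(peaks, pd.DataFrame):
        peaks = pd.DataFrame(
            [(p.chrom, p.start, p.end, p.target) for p in peaks],
            columns=["chrom", "start", "end", "target"],
        )
    n_overlap = int((peaks["target"] == "overlap").sum())
    if n_overlap:
        logger.info("excluding %d overlap-class peaks from counting", n_overlap)
        peaks = peaks[peaks["target"] != "overlap"]
    peaks = peaks.sort_values(["target", "chrom", "start"]).reset_index(drop=True)
    if peaks.empty:
        raise ValueError("empty peak set")

    cells = np.sort(frags.loc[frags["barcode"] != "", "barcode"].unique())
    if cells.size == 0:
        raise ValueError("no barcoded fragments")
    cell_idx = pd.Series(np.arange(cells.size), index=cells)
    fcell = cell_idx.reindex(frags["barcode"]).to_numpy()
    fcount = frags["count"].to_numpy().astype(float)
    library_size = np.bincount(fcell[~np.isnan(fcell)].astype(int),
                               weights=fcount[~np.isnan(fcell)],
                               minlength=cells.size)

    rows, cols, vals = [np.empty(0, int)], [np.empty(0, int)], [np.empty(0)]
    for (target, chrom), pk in peaks.groupby(["target", "chrom"]):
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{target} peaks on {chrom} overlap each other")
        col0 = pk.index.to_numpy()
        sel = (frags["chrom"] == chrom).to_numpy() & (frags["barcode"] != "").to_numpy()
        fs = frags["start"].to_numpy()[sel]
        fe = frags["end"].to_numpy()[sel]
        fc = fcell[sel].astype(int)
        fw = fcount[sel]
        lo = np.searchsorted(ends, fs, side="right")
        hi = np.searchsorted(starts, fe, side="left")
        one = hi == lo + 1
        rows.append(fc[one])
        cols.append(col0[lo[one]])
        vals.append(fw[one])
        for j in np.flatnonzero(hi > lo + 1):  # fragment spanning several peaks
            span = np.arange(lo[j], hi[j])
            rows.append(np.full(span.size, fc[j]))
            cols.append(col0[span])
            vals.append(np.full(span.size, fw[j]))
    counts = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(cells.size, len(peaks)),
    )
    return CellPeakMatrix(cells=cells, peaks=peaks, counts=counts,
                          library_size=library_size)


def tfidf(matrix: CellPeakMatrix, target: str) -> np.ndarray:
    """ArchR-style TF-IDF of the binarized counts of one target.

    Returns a dense ``cells x peaks(target)`` array; invariant to count
    scaling because the matrix is binarized first.
    """
    cols = matrix.target_columns(target)
    if cols.size == 0:
        raise ValueError(f"no peaks for target {target}")
    b = (matrix.counts[:, cols] > 0).astype(float).toarray()
    if b.sum() == 0:
        raise ValueError("all-zero matrix")
    row_sum = b.sum(axis=1, keepdims=True)
    tf = np.divide(b, row_sum, out=np.zeros_like(b), where=row_sum > 0)
    n_cells = b.shape[0]
    idf = np.log(1.0 + n_cells / (1.0 + b.sum(axis=0)))
    return np.log(tf * idf[None, :] * 1e4 + 1.0)


def tfidf_combined(matrix: CellPeakMatrix):
    """TF-IDF per target, concatenated column-wise.

    Returns ``(X, targets)`` where ``targets`` labels each column.
    """
    blocks, labels = [], []
    for target in pd.unique(matrix.peaks["target"]):
        x = tfidf(matrix, target)
        blocks.append(x)
        labels.extend([target] * x.shape[1])
    return np.hstack(blocks), np.asarray(labels)


@dataclass
class Embedding:
    singular_values: np.ndarray  # (n_components,)
    loadings: np.ndarray  # (n_components, n_peaks)
    coords_all: np.ndarray  # (n_cells, n_components), U * S
    excluded_components: list
    n_components: int = 30

    @property
    def cell_coords(self) -> np.ndarray:
        keep = [i for i in range(self.n_components) if i not in self.excluded_components]
        return self.coords_all[:, keep]

    @property
    def retained_components(self) -> list:
        return [i for i in range(self.n_components) if i not in self.excluded_components]


def lsi_embed(norm: np.ndarray, library_size, n_components: int = 30,
              depth_corr_limit: float = 0.9) -> Embedding:
    """Truncated SVD of the normalised matrix with depth-component
    exclusion.

    Among the first two components, any whose cell coordinates have
    absolute Pearson correlation above ``depth_corr_limit`` with log
    library size is excluded from the returned coordinates.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    norm = np.asarray(norm, dtype=float)
    if min(norm.shape) < n_components + 1:
        raise ValueError(
            f"need more than {n_components} cells and peaks, got {norm.shape}"
        )
    u, s, vt = np.linalg.svd(norm, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    for i in range(n_components):  # deterministic sign convention
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u * s[None, :]
    logdepth = np.log(np.asarray(library_size, dtype=float) + 1.0)
    excluded = []
    for i in range(min(2, n_components)):
        r = np.corrcoef(coords[:, i], logdepth)[0, 1]
        if abs(r) > depth_corr_limit:
            excluded.append(i)
    return Embedding(
        singular_values=s,
        loadings=vt,
        coords_all=coords,
        excluded_components=excluded,
        n_components=n_components,
    )


def variable_peaks(embedding: Embedding, k: int = 400,
                   targets: Optional[np.ndarray] = None):
    """Rank peaks by absolute loading on the first retained component.

    With ``targets`` given (one label per column of the normalised
    matrix) the top ``k`` per target are returned as a dict; otherwise a
    single ranked index array of length ``k``.  If ``k`` exceeds the
    available peaks, all are returned with a warning.
    """
    comp = embedding.retained_components[0]
    score = np.abs(embedding.loadings[comp])
    order = np.argsort(-score, kind="mergesort")
    if targets is None:
        if k > order.size:
            logger.warning("k=%d exceeds peak count %d", k, order.size)
            k = order.size
        return order[:k]
    targets = np.asarray(targets)
    out = {}
    for t in pd.unique(targets):
        sub = order[targets[order] == t]
        kk = min(k, sub.size)
        if k > sub.size:
            logger.warning("k=%d exceeds %s peak count %d", k, t, sub.size)
        out[t] = sub[:kk]
    return out
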