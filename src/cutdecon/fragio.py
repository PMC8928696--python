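"""Genomic file I/O: fragment BED, chrom.sizes, bedGraph and peak BED.

All coordinates are BED-style 0-based half-open throughout the package.
Fragment files are tab-separated with at least three columns
(chrom, start, end); column 4, when present, is a cell barcode and
column 5 a positive integer multiplicity.  Files may be gzip-compressed
(detected from the ``.gz`` suffix).

Fragments are held in a :class:`pandas.DataFrame` with columns
``chrom, start, end, barcode, count``; cut sites in a DataFrame with
columns ``chrom, pos, fraglen, weight``.  Each fragment contributes two
cut sites, one per endpoint, both carrying the fragment length.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]
CUT_COLUMNS = ["chrom", "pos", "fraglen", "weight"]


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple
    chrom_lengths: dict = field(compare=False)

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"non-positive length for {name}")

    @classmethod
    def from_dict(cls, lengths: dict) -> "GenomeIndex":
        return cls(tuple(lengths), dict(lengths))

    @classmethod
    def read_chrom_sizes(cls, path) -> "GenomeIndex":
        """Read a two-column ``chrom<TAB>length`` table."""
        names, lengths = [], {}
        with _open_text(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {i}: expected 2 columns")
                names.append(parts[0])
                lengths[parts[0]] = int(parts[1])
        return cls(tuple(names), lengths)

    def __contains__(self, chrom) -> bool:
        return chrom in self.chrom_lengths


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path, genome: GenomeIndex, collapse: bool = True) -> pd.DataFrame:
    """Read a fragment BED file, validate, sort and (optionally) deduplicate.

    Parameters
    ----------
    path
        Tab-separated BED-style file with >= 3 columns.
    genome
        Fragments on chromosomes absent from the genome are dropped
        (a count is logged).
    collapse
        Collapse identical ``(chrom, start, end, barcode)`` records into one
        row with summed count.  Deconvolution then operates on weighted
        unique cut sites.

    Raises
    ------
    ValueError
        On non-integer coordinates or ``start >= end``; the message names
        the offending line number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative start")
            barcode = parts[3] if len(parts) >= 4 and parts[3] != "." else ""
            count = 1
            if len(parts) >= 5:
                try:
                    count = int(parts[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-integer count"
                    ) from exc
                if count <= 0:
                    raise ValueError(f"{path}: line {lineno}: non-positive count")
            rows.append((chrom, start, end, barcode, count))

    frags = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if frags.empty:
        return frags
    keep = frags["chrom"].isin(genome.chrom_names)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d fragments on chromosomes absent from genome", n_dropped)
        frags = frags[keep]
    for chrom, sub in frags.groupby("chrom"):
        limit = genome.chrom_lengths[chrom]
        if (sub["end"] > limit).any():
            raise ValueError(f"fragment end exceeds length of {chrom}")
    if collapse:
        frags = (
            frags.groupby(["chrom", "start", "end", "barcode"], as_index=False)["count"]
            .sum()
        )
        frags = frags[FRAGMENT_COLUMNS]
    frags = frags.sort_values(["chrom", "start", "end"], kind="mergesort")
    return frags.reset_index(drop=True)


def write_fragments(frags: pd.DataFrame, path) -> None:
    """Write fragments as a 5-column BED (barcode '.' when absent)."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end, barcode, count in frags[FRAGMENT_COLUMNS].itertuples(
            index=False
        ):
            bc = barcode if barcode else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{bc}\t{count}\n")


def fragments_to_cuts(frags: pd.DataFrame) -> pd.DataFrame:
    """Turn fragments into weighted cut sites (two per fragment).

    Each fragment emits one cut at ``start`` and one at ``end``, both with
    ``fraglen = end - start`` and the fragment's count as weight.  Cuts that
    coincide in ``(chrom, pos, fraglen)`` are collapsed with summed weight;
    output is sorted by ``(chrom, pos)``.
    """
    if frags.empty:
        return pd.DataFrame(columns=CUT_COLUMNS)
    length = (frags["end"] - frags["start"]).to_numpy()
    cuts = pd.DataFrame(
        {
            "chrom": np.concatenate([frags["chrom"], frags["chrom"]]),
            "pos": np.concatenate([frags["start"], frags["end"]]),
            "fraglen": np.concatenate([length, length]),
            "weight": np.concatenate([frags["count"], frags["count"]]).astype(float),
        }
    )
    cuts = cuts.groupby(["chrom", "pos", "fraglen"], as_index=False)["weight"].sum()
    cuts = cuts.sort_values(["chrom", "pos", "fraglen"], kind="mergesort")
    return cuts[CUT_COLUMNS].reset_index(drop=True)


def write_bedgraph(tracks, path, target: str = "pol") -> None:
    """Write deconvolved density tracks as bedGraph (0-based half-open).

    ``tracks`` is an iterable of objects exposing ``chrom``, ``grid_pos``
    (sorted bp positions), ``grid_step`` and natural-scale density arrays
    ``dens_pol`` / ``dens_k27``.  Values must be finite.
    """
    tracks = list(tracks)
    for tr in tracks:
        values = tr.dens_pol if target == "pol" else tr.dens_k27
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite density values in track on {tr.chrom}")
    with _open_text(path, "wt") as fh:
        for tr in tracks:
            values = tr.dens_pol if target == "pol" else tr.dens_k27
            step = tr.grid_step
            for p, v in zip(tr.grid_pos, values):
                fh.write(f"{tr.chrom}\t{p}\t{p + step}\t{v:.6g}\n")


def write_peaks(peaks, path) -> None:
    """Write peaks as BED6+1: the name field carries the class label
    (``Pol2S5p`` / ``H3K27me3`` / ``overlap``) and column 7 the summit
    offset from the peak start (-1 for domains, which have no summit)."""
    with _open_text(path, "wt") as fh:
        for pk in peaks:
            offset = pk.summit - pk.start if pk.summit is not None else -1
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.target}\t"
                f"{pk.score:.6g}\t.\t{offset}\n"
            )


def read_peaks(path) -> pd.DataFrame:
    """Read a BED3+ interval file into a DataFrame (chrom, start, end, name)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            name = parts[3] if len(parts) >= 4 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
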