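"""Synthetic two-target fragment generator.

Generates fragment data with the statistical structure the deconvolution
model assumes: two latent targets ("pol" = narrow, sharp features with
short fragments; "k27" = broad, diffuse features with longer fragments),
each emitting fragments whose centre positions follow a sum of Gaussian
bumps plus a uniform background and whose lengths follow a four-mode
log-normal mixture (modes 70/200/400/600 bp).

Defaults encode the study conditions the model is calibrated for:

* a 200-kb chromosome with 8 narrow (sd 150 bp) and 3 broad (sd 1,250 bp)
  features placed without overlap, every feature at least 10-fold above
  the background density at its centre;
* distinct but overlapping length-mode weights per target (predominantly
  subnucleosomal for "pol", mono-/oligo-nucleosomal for "k27");
* per-target background fractions (0.50 / 0.56) derived from the peak
  caller's calibration identity: the expected fraction of cut weight
  falling within the ±2 sd feature intervals of a target matches the
  fraction r = (1 + 2 lambda)/8 that the quantile threshold calls, which
  encodes the assumption that about half of a target's cuts fall into
  reproducible peaks (the broad target needs a slightly larger background
  share because its wide footprint also captures background cuts);
* equal overall target abundance.

Ground-truth feature intervals are ``centre +/- 2 sd`` — the span holding
95% of a feature's fragment centres.

With ``n_cells > 0`` fragments are barcoded: cells belong to one of two
types, features are shared or type-specific, and per-cell sequencing depth
follows a configurable geometric gradient (independent of cell type).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cutdecon.fragio import FRAGMENT_COLUMNS, GenomeIndex
from cutdecon.lengthmodel import MODES

# Default generative length-mode weights.  The accessible-chromatin target
# releases predominantly subnucleosomal fragments (mode 70), the
# repressive mark predominantly mono- and oligo-nucleosomal ones; the two
# mixtures are distinct but overlapping, as in the assays.  They
# deliberately differ from the inference model's Dirichlet prior means:
# recovered weights should be data-driven, not prior echoes.
_POL_TRUE_W = (0.90, 0.10, 0.00, 0.00)
_K27_TRUE_W = (0.10, 0.60, 0.25, 0.05)


def _default_genome() -> GenomeIndex:
    return GenomeIndex.from_dict({"chrS": 200_000})


@dataclass(frozen=True)
class SimConfig:
    genome: GenomeIndex = field(default_factory=_default_genome)
    n_pol_features: int = 8
    n_k27_features: int = 3
    pol_feature_width: float = 150.0  # Gaussian sd, bp
    k27_feature_width: float = 1250.0
    pol_length_weights: tuple = _POL_TRUE_W
    k27_length_weights: tuple = _K27_TRUE_W
    length_log_sd: float = 0.35  # generative mode spread (sharp ladder)
    n_fragments: int = 25_000
    n_cells: int = 0
    pol_fraction: float = 0.5  # share of fragments from the pol target
    background: float = 0.50  # pol-target background mass fraction
    background_k27: float = 0.56  # k27-target background mass fraction
    frac_type_specific: float = 0.5  # single-cell mode: non-shared features
    depth_gradient: float = 5.0  # max/min per-cell depth ratio
    seed: int = 0

    def __post_init__(self):
        for w in (self.pol_length_weights, self.k27_length_weights):
            w = np.asarray(w)
            if abs(w.sum() - 1) > 1e-9 or np.any(w < 0):
                raise ValueError("length weights must lie on the simplex")
        if self.pol_feature_width <= 0 or self.k27_feature_width <= 0:
            raise ValueError("feature widths must be positive")
        if self.pol_feature_width >= self.k27_feature_width:
            raise ValueError("pol features must be narrower than k27 features")
        if not (0 <= self.background < 1 and 0 <= self.background_k27 < 1):
            raise ValueError("background fractions must be in [0, 1)")

    def bg_fraction(self, target: str) -> float:
        return self.background if target == "pol" else self.background_k27


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: feature table plus the generative densities."""

    config: SimConfig
    features: pd.DataFrame  # feature_id, target, chrom, center, width, start, end, group

    def intervals(self, target: str) -> pd.DataFrame:
        sub = self.features[self.features["target"] == target]
        return sub[["chrom", "start", "end"]].reset_index(drop=True)

    def density(self, target: str, positions, cell_type=None) -> np.ndarray:
        """Per-bp fragment-centre density of one target (integrates to 1
        over the genome for that target, bulk mode)."""
        cfg = self.config
        positions = np.asarray(positions, dtype=float)
        chrom = cfg.genome.chrom_names[0]
        length = cfg.genome.chrom_lengths[chrom]
        feats = self.features[self.features["target"] == target]
        if cell_type is not None:
            feats = feats[feats["group"].isin(["shared", f"type{cell_type}"])]
        bg = cfg.bg_fraction(target)
        dens = np.full(positions.shape, bg / length)
        if len(feats):
            share = (1.0 - bg) / len(feats)
            for _, f in feats.iterrows():
                z = (positions - f["center"]) / f["width"]
                dens += share * np.exp(-0.5 * z**2) / (f["width"] * math.sqrt(2 * math.pi))
        return dens


TRUTH_SD = 2.0  # ground-truth interval halfwidth in units of feature sd


def feature_contrast(cfg: SimConfig, target: str) -> float:
    """Feature centre density relative to the target's background level."""
    n = cfg.n_pol_features if target == "pol" else cfg.n_k27_features
    width = cfg.pol_feature_width if target == "pol" else cfg.k27_feature_width
    bg = cfg.bg_fraction(target)
    length = cfg.genome.chrom_lengths[cfg.genome.chrom_names[0]]
    amp = (1.0 - bg) / n / (width * math.sqrt(2 * math.pi))
    return amp / (bg / length)


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Place features at random without overlap and record ground truth."""
    rng = np.random.default_rng(cfg.seed)
    chrom = cfg.genome.chrom_names[0]
    length = cfg.genome.chrom_lengths[chrom]

    specs = []
    for target, n, width in (
        ("pol", cfg.n_pol_features, cfg.pol_feature_width),
        ("k27", cfg.n_k27_features, cfg.k27_feature_width),
    ):
        for _ in range(n):
            specs.append((target, width, TRUTH_SD * width))
    # place broad features first so narrow ones can fill the gaps
    specs.sort(key=lambda s: -s[2])

    placed = []  # (start, end) occupied truth intervals
    rows = []
    for target, width, half in specs:
        lo, hi = math.ceil(half), length - math.ceil(half)
        if lo >= hi:
            raise ValueError("feature cannot be placed within chromosome bounds")
        for _ in range(10_000):
            center = float(rng.integers(lo, hi))
            start, end = center - half, center + half
            if all(end <= s or start >= e for s, e in placed):
                placed.append((start, end))
                rows.append((target, chrom, center, width, int(start), int(math.ceil(end))))
                break
        else:
            raise ValueError("could not place features without overlap")

    features = pd.DataFrame(
        rows, columns=["target", "chrom", "center", "width", "start", "end"]
    )
    features = features.sort_values(["target", "center"]).reset_index(drop=True)
    features.insert(0, "feature_id", np.arange(len(features)))

    # single-cell mode: assign features to shared / type-specific groups
    groups = np.full(len(features), "shared", dtype=object)
    if cfg.n_cells > 0:
        for target in ("pol", "k27"):
            idx = features.index[features["target"] == target].to_numpy()
            n_spec = int(round(cfg.frac_type_specific * len(idx)))
            spec_idx = rng.choice(idx, size=n_spec, replace=False)
            half = len(spec_idx) // 2
            perm = rng.permutation(spec_idx)
            groups[perm[:half]] = "type0"
            groups[perm[half:]] = "type1"
    features["group"] = groups
    return SimTruth(config=cfg, features=features)


def _sample_batch(rng, cfg: SimConfig, truth: SimTruth, n: int, active_groups):
    """Sample n fragments from the (possibly type-restricted) densities."""
    chrom = cfg.genome.chrom_names[0]
    length = cfg.genome.chrom_lengths[chrom]
    sigma = cfg.length_log_sd
    mu = np.log(MODES) + sigma**2

    is_pol = rng.random(n) < cfg.pol_fraction
    targets = np.where(is_pol, "pol", "k27")
    centers = np.empty(n)
    feat_ids = np.full(n, -1)
    for target in ("pol", "k27"):
        sel = np.flatnonzero(targets == target)
        feats = truth.features[
            (truth.features["target"] == target)
            & truth.features["group"].isin(active_groups)
        ]
        is_bg = rng.random(sel.size) < cfg.bg_fraction(target)
        if len(feats) == 0:
            is_bg[:] = True
        centers[sel[is_bg]] = rng.uniform(0, length, int(is_bg.sum()))
        n_feat = int((~is_bg).sum())
        if n_feat:
            pick = rng.integers(0, len(feats), n_feat)
            c = feats["center"].to_numpy()[pick]
            w = feats["width"].to_numpy()[pick]
            centers[sel[~is_bg]] = rng.normal(c, w)
            feat_ids[sel[~is_bg]] = feats["feature_id"].to_numpy()[pick]

    weights = np.where(
        is_pol[:, None],
        np.asarray(cfg.pol_length_weights),
        np.asarray(cfg.k27_length_weights),
    )
    comp = (rng.random(n)[:, None] > np.cumsum(weights, axis=1)).sum(axis=1)
    lengths = np.rint(np.exp(rng.normal(mu[comp], sigma))).astype(int)
    lengths = np.clip(lengths, 1, None)

    start = np.rint(centers).astype(int) - lengths // 2
    end = start + lengths
    start = np.clip(start, 0, length - 1)
    end = np.clip(end, start + 1, length)
    return targets, start, end, feat_ids


def sample_fragments(cfg: SimConfig, truth: SimTruth):
    """Draw fragments from the generative model.

    Returns
    -------
    frags : DataFrame
        ``chrom, start, end, barcode, count`` (barcode empty in bulk mode).
    truth_table : DataFrame
        One row per fragment: ``frag_id, chrom, start, end, barcode,
        target, feature_id, cell_type`` — the acceptance surface for
        classification accuracy.
    """
    if cfg.n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(cfg.seed + 1)
    chrom = cfg.genome.chrom_names[0]

    if cfg.n_cells == 0:
        targets, start, end, feat_ids = _sample_batch(
            rng, cfg, truth, cfg.n_fragments, {"shared"}
        )
        barcodes = np.full(cfg.n_fragments, "", dtype=object)
        cell_types = np.full(cfg.n_fragments, -1)
    else:
        n_cells = cfg.n_cells
        width = len(str(n_cells - 1))
        cell_ids = np.array([f"cell{i:0{width}d}" for i in range(n_cells)])
        types = rng.permutation(np.arange(n_cells) % 2)
        depth = np.geomspace(1.0, cfg.depth_gradient, n_cells)
        depth = rng.permutation(depth)
        per_cell = rng.multinomial(cfg.n_fragments, depth / depth.sum())
        parts = []
        for ci in range(n_cells):
            if per_cell[ci] == 0:
                continue
            t, s, e, f = _sample_batch(
                rng, cfg, truth, int(per_cell[ci]), {"shared", f"type{types[ci]}"}
            )
            parts.append((t, s, e, f, np.full(t.size, cell_ids[ci]),
                          np.full(t.size, types[ci])))
        targets = np.concatenate([p[0] for p in parts])
        start = np.concatenate([p[1] for p in parts])
        end = np.concatenate([p[2] for p in parts])
        feat_ids = np.concatenate([p[3] for p in parts])
        barcodes = np.concatenate([p[4] for p in parts])
        cell_types = np.concatenate([p[5] for p in parts])

    frags = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "barcode": barcodes,
            "count": 1,
        }
    )[FRAGMENT_COLUMNS]
    truth_table = pd.DataFrame(
        {
            "frag_id": np.arange(len(frags)),
            "chrom": chrom,
            "start": start,
            "end": end,
            "barcode": barcodes,
            "target": targets,
            "feature_id": feat_ids,
            "cell_type": cell_types,
        }
    )
    return frags, truth_table


def subsample_fragments(frags: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Random fragment subsample (without replacement), order preserved."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frags)) < fraction
    return frags[keep].reset_index(drop=True)


def write_truth_table(truth_table: pd.DataFrame, path) -> None:
    truth_table.to_csv(path, sep="\t", index=False)


def single_cell_config(seed: int = 0, **overrides) -> SimConfig:
    """Default single-cell study conditions: a 2.4-Mb chromosome with 120
    narrow and 120 broad features (enough peak columns for a 30-component
    embedding with structure to spare), 100 cells of two types with a 5x
    depth gradient, and half of the features type-specific."""
    base = SimConfig(
        genome=GenomeIndex.from_dict({"chrS": 2_400_000}),
        n_pol_features=120,
        n_k27_features=120,
        k27_feature_width=600.0,
        n_fragments=60_000,
        n_cells=100,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
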