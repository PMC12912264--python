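"""Synthetic-data generators emulating every input class the pipeline consumes.

Each generator is a pure function of its parameters and a seed, so every
downstream stage can be exercised end-to-end without any external download:

* :func:`gen_frap_traces` — biexponential recovery curves with additive
  Gaussian read noise, sampled on the acquisition grid used for junction
  FRAP (every 10 s for 10 min by default).
* :func:`gen_intensity_table` — a 6-vs-6 bait/control log-normal intensity
  table with a spiked enriched subset, the structure a proximity-labeling
  volcano analysis assumes.
* :func:`gen_network` — a layered interaction graph with a designated bait
  hub and a planted tier structure that breadth-first layering must recover.
* :func:`gen_two_channel_image` — junction-like images: bright curvilinear
  contact segments over a dim cytoplasm, with the between-channel
  correlation of segment intensities set exactly to ``coloc_level``.

The packaged :data:`FRAP_PRESETS` carry the mobile fractions and slow-pool
halftimes measured for the five desmosomal constructs (DSG2, DSC2a, DSC2b,
PKP2, DSP); the fast pool is a minor component for all of them, so the
preset default puts 10% of the mobile pool in a fast phase with a 20 s
halftime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk

from .frap import FrapTrace, two_phase_model
from .io_core import EdgeList, IntensityTable, ValidationError
from .tiers import TierAssignment

import pandas as pd

__all__ = [
    "FrapPreset",
    "FRAP_PRESETS",
    "SpikeDesign",
    "gen_frap_traces",
    "gen_intensity_table",
    "gen_network",
    "gen_two_channel_image",
]


@dataclass(frozen=True)
class FrapPreset:
    """Ground-truth kinetic parameters for one FRAP construct."""

    name: str
    mobile_fraction: float
    slow_halftime: float  # seconds
    fast_halftime: float = 20.0  # seconds
    fast_share: float = 0.10  # fraction of the mobile pool in the fast phase

    def __post_init__(self) -> None:
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValidationError("mobile_fraction must be in [0, 1]")
        if not (0.0 <= self.fast_share <= 1.0):
            raise ValidationError("fast_share must be in [0, 1]")
        if self.slow_halftime <= 0 or self.fast_halftime <= 0:
            raise ValidationError("halftimes must be > 0")
        if self.fast_halftime >= self.slow_halftime:
            raise ValidationError("fast_halftime must be < slow_halftime")

    @property
    def k_fast(self) -> float:
        return float(np.log(2.0) / self.fast_halftime)

    @property
    def k_slow(self) -> float:
        return float(np.log(2.0) / self.slow_halftime)


#: Measured cohort kinetics for the five desmosomal constructs.
FRAP_PRESETS: dict[str, FrapPreset] = {
    "DSG2": FrapPreset("DSG2", 0.269, 231.0),
    "DSC2A": FrapPreset("DSC2A", 0.33, 189.5),
    "DSC2B": FrapPreset("DSC2B", 0.463, 256.5),
    "PKP2": FrapPreset("PKP2", 0.533, 213.5),
    "DSP": FrapPreset("DSP", 0.288, 288.3),
}


def gen_frap_traces(preset: FrapPreset, n_traces: int, noise_sd: float = 0.02,
                    duration_s: float = 600.0, dt_s: float = 10.0,
                    seed: int = 0) -> list[FrapTrace]:
    """Simulate noisy recovery traces from a kinetic preset.

    Times run 0, dt, ..., duration inclusive; the noiseless value at t=0 is
    exactly 0 (the bleach-point constraint the fit imposes).
    """
    if dt_s <= 0 or duration_s < dt_s:
        raise ValidationError("need dt_s > 0 and duration_s >= dt_s")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    clean = two_phase_model(t, preset.mobile_fraction, preset.fast_share,
                            preset.k_fast, preset.k_slow)
    traces = []
    for i in range(n_traces):
        noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0
        traces.append(FrapTrace(t, clean + noise, label=preset.name,
                                replicate=f"{preset.name}_{i:03d}"))
    return traces


@dataclass
class SpikeDesign:
    """Design of a spiked bait-vs-control intensity table.

    Background proteins are i.i.d. log-normal with equal condition means;
    enriched proteins have their bait-condition mean multiplied by
    ``enriched_fold_change``.  ``replicate_cv`` is the within-condition
    coefficient of variation on the linear scale.  A ``singleton_fraction``
    of proteins is assigned a single unique peptide (and is therefore
    removed by the single-peptide exclusion downstream).
    """

    n_proteins: int = 1000
    n_enriched: int = 50
    enriched_fold_change: float = 20.0
    replicate_cv: float = 0.2
    n_replicates: int = 6
    singleton_fraction: float = 0.0
    mean_peptides: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ValidationError("n_enriched must be <= n_proteins")
        if self.enriched_fold_change < 1.0:
            raise ValidationError("enriched fold change must be >= 1 "
                                  "(1.0 gives a null spike)")
        if self.replicate_cv <= 0 or self.n_replicates < 2:
            raise ValidationError("need replicate_cv > 0 and >= 2 replicates")


def gen_intensity_table(design: SpikeDesign) -> tuple[IntensityTable, set[str]]:
    """Generate a spiked intensity table plus the ground-truth enriched set.

    Returns the table and the set of enriched ``protein_id`` values.
    """
    rng = np.random.default_rng(design.seed)
    n, r = design.n_proteins, design.n_replicates
    # per-protein baseline log2 abundance spanning a realistic dynamic range
    base_log2 = rng.uniform(20.0, 27.0, size=n)
    # multiplicative CV -> log2-domain standard deviation
    sd_log2 = np.sqrt(np.log(1.0 + design.replicate_cv ** 2)) / np.log(2.0)
    enriched_idx = rng.choice(n, size=design.n_enriched, replace=False)
    shift = np.zeros(n)
    shift[enriched_idx] = np.log2(design.enriched_fold_change)
    bait = 2.0 ** (base_log2[:, None] + shift[:, None]
                   + rng.normal(0.0, sd_log2, size=(n, r)))
    ctrl = 2.0 ** (base_log2[:, None] + rng.normal(0.0, sd_log2, size=(n, r)))
    peptides = 2 + rng.poisson(max(design.mean_peptides - 2.0, 0.0), size=n)
    if design.singleton_fraction > 0:
        n_single = int(round(design.singleton_fraction * n))
        singles = rng.choice(n, size=n_single, replace=False)
        peptides[singles] = 1
    ids = [f"P{i:05d}" for i in range(n)]
    df = pd.DataFrame({"protein_id": ids,
                       "gene": [f"Gene{i:05d}" for i in range(n)],
                       "unique_peptides": peptides})
    for j in range(r):
        df[f"bait_{j + 1}"] = bait[:, j]
    for j in range(r):
        df[f"ctrl_{j + 1}"] = ctrl[:, j]
    truth = {ids[i] for i in enriched_idx}
    return IntensityTable(df=df, n_replicates_per_condition=r), truth


def gen_network(n_nodes: int, root: str, tier_sizes: list[int],
                n_isolated: int, extra_edge_rate: float = 0.0,
                seed: int = 0) -> tuple[EdgeList, TierAssignment]:
    """Generate a layered interaction graph with a planted tier structure.

    Every tier-k node gets at least one edge to a tier-(k-1) node (tier 0 is
    the root); optional extra edges are added within a layer or between
    adjacent layers only, so no shortcut can shorten any node's distance to
    the root.  Isolated nodes get no edges.  Returns the edge list and the
    planted :class:`~desmokit.tiers.TierAssignment` as ground truth.
    """
    if sum(tier_sizes) + n_isolated + 1 != n_nodes:
        raise ValidationError(
            "tier sizes + isolated + root must total n_nodes exactly")
    if any(s < 0 for s in tier_sizes) or n_isolated < 0:
        raise ValidationError("tier sizes and n_isolated must be >= 0")
    if tier_sizes and tier_sizes[0] == 0 and any(s > 0 for s in tier_sizes[1:]):
        raise ValidationError("cannot plant a deeper tier on an empty one")
    rng = np.random.default_rng(seed)
    names = iter(f"N{i:04d}" for i in range(n_nodes))
    layers: list[list[str]] = [[root]]
    for size in tier_sizes:
        layers.append([next(names) for _ in range(size)])
    isolated = [next(names) for _ in range(n_isolated)]

    edges = EdgeList()
    for k in range(1, len(layers)):
        parents = layers[k - 1]
        for node in layers[k]:
            edges.add(node, parents[int(rng.integers(len(parents)))],
                      "planted")
    if extra_edge_rate > 0:
        for k in range(1, len(layers)):
            layer = layers[k]
            # within-layer candidates
            for i in range(len(layer)):
                for j in range(i + 1, len(layer)):
                    if rng.random() < extra_edge_rate:
                        edges.add(layer[i], layer[j], "extra")
            # adjacent-layer candidates (never shortens a root distance)
            if k + 1 < len(layers):
                for a in layer:
                    for b in layers[k + 1]:
                        if rng.random() < extra_edge_rate:
                            edges.add(a, b, "extra")
    max_tier = len(tier_sizes)
    truth = TierAssignment(
        root=root,
        tiers=[set(layer) for layer in layers[1:]] + [set()] * (4 - max_tier)
        if max_tier <= 4 else [set(layer) for layer in layers[1:]],
        unconnected=set(isolated),
        reasons={n: "isolated" for n in isolated})
    return edges, truth


def _draw_segments(size: tuple[int, int], n_segments: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Rasterize curvilinear 'contact' segments into a boolean mask."""
    h, w = size
    mask = np.zeros(size, dtype=bool)
    for _ in range(n_segments):
        y = rng.uniform(0.15 * h, 0.85 * h)
        x = rng.uniform(0.1 * w, 0.3 * w)
        theta = rng.uniform(-0.4, 0.4)
        length = rng.uniform(0.35, 0.6) * w
        n_steps = int(length)
        for _ in range(n_steps):
            yi, xi = int(round(y)), int(round(x))
            if 0 <= yi < h and 0 <= xi < w:
                mask[yi, xi] = True
            theta += rng.normal(0.0, 0.03)  # gentle curvature
            x += np.cos(theta)
            y += np.sin(theta)
    return dilation(mask, disk(1)).astype(bool)


def gen_two_channel_image(size: tuple[int, int] = (256, 256),
                          n_junction_segments: int = 6,
                          coloc_level: float = 1.0,
                          noise_sd: float = 0.0,
                          seed: int = 0,
                          contact_mean: float = 1000.0,
                          cytoplasm_mean: float = 100.0,
                          segment_cv: float = 0.05,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a correlated two-channel junction image pair.

    Returns ``(ch1, ch2, contact_mask)`` as float64 arrays.  Contact-pixel
    intensities vary around ``contact_mean`` with coefficient of variation
    ``segment_cv``; the channel-2 variates are constructed by exact
    Gram-Schmidt so that, before read noise, the Pearson correlation of the
    two channels over the contact mask equals ``coloc_level`` exactly and
    the contact means equal ``contact_mean`` exactly.
    """
    if not (-1.0 <= coloc_level <= 1.0):
        raise ValidationError("coloc_level must be in [-1, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mask = _draw_segments(size, n_junction_segments, rng)
    n_px = int(mask.sum())
    if n_px < 3:
        raise ValidationError("degenerate geometry: too few contact pixels")

    def _standardize(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / v.std()

    z1 = _standardize(rng.standard_normal(n_px))
    z2 = rng.standard_normal(n_px)
    z2 = z2 - (z2 @ z1) / (z1 @ z1) * z1  # exact orthogonalization
    z2 = _standardize(z2)
    rho = coloc_level
    w = rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z2
    if abs(rho) < 1.0:
        w = _standardize(w)

    ch1 = np.full(size, cytoplasm_mean, dtype=float)
    ch2 = np.full(size, cytoplasm_mean, dtype=float)
    ch1[mask] = contact_mean * (1.0 + segment_cv * z1)
    ch2[mask] = contact_mean * (1.0 + segment_cv * w)
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, size=size)
        ch2 = ch2 + rng.normal(0.0, noise_sd, size=size)
    return ch1, ch2, mask
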