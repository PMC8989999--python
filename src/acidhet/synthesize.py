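"""Synthetic data with the statistical structure the analysis assumes.

Every generator is seeded and deterministic, and returns ground truth
alongside the observable data so that downstream estimators (noise,
crosstalk factor, correlations, ON fractions, tree distances) can be
validated against known parameters.

The population generator models a three-color reporter experiment: each
cell is independently ON or OFF per channel; ON intensities follow either
a normal (symmetric, Gaussian-like) or a lognormal (right-skewed) marginal;
latent inter-channel correlation is imposed through a Gaussian copula so
the stated marginals are preserved; measured intensities add linear
bleed-through from donor channels and a per-field background.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ChannelSpec",
    "PopulationSpec",
    "ImageSpec",
    "CooccurSpec",
    "TreeSimSpec",
    "PROTEIN_ALPHABET",
    "NUCLEOTIDE_ALPHABET",
    "simulate_population",
    "simulate_images",
    "simulate_presence_table",
    "evolve_alignment",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = "ACGT"


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel of the simulated population.

    Parameters
    ----------
    name : channel label, e.g. ``"gfp"`` for a GadC:eGFP reporter.
    on_fraction : probability in [0, 1] that a cell is ON in this channel.
    family : ``"normal"`` (symmetric ON distribution, Gad/Adi-like) or
        ``"lognormal"`` (right-skewed, Cad-like).
    loc : normal mean in intensity units, or log-space mean for lognormal.
    scale : normal standard deviation, or log-space sd for lognormal.
    off_level : mean emission of OFF cells (intensity units).
    """

    name: str
    on_fraction: float = 1.0
    family: str = "normal"
    loc: float = 100.0
    scale: float = 10.0
    off_level: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValueError(f"on_fraction must be in [0, 1], got {self.on_fraction}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.off_level < 0:
            raise ValueError("off_level must be >= 0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of copula uniforms to the ON marginal."""
        if self.scale == 0.0:
            base = np.exp(self.loc) if self.family == "lognormal" else self.loc
            return np.full_like(u, base, dtype=float)
        if self.family == "normal":
            return stats.norm.ppf(u, loc=self.loc, scale=self.scale)
        return stats.lognorm.ppf(u, s=self.scale, scale=np.exp(self.loc))


@dataclass
class PopulationSpec:
    """Specification of a multi-channel cell population.

    ``correlation`` is the latent (copula) inter-channel correlation matrix;
    ``bleed[i, j]`` is the fraction of channel *j*'s true signal added to
    the measured signal of channel *i* (off-diagonal only). Background is
    drawn once per field of view and channel.
    """

    channels: Sequence[ChannelSpec]
    correlation: np.ndarray | None = None
    bleed: np.ndarray | None = None
    background_mean: float = 0.0
    background_sd: float = 0.0
    n_fields: int = 1
    cells_per_field: int = 100
    seed: int = 0
    condition: str = "pH 7.6"
    time_min: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.channels)
        if k == 0:
            raise ValueError("at least one channel required")
        if self.n_fields < 1 or self.cells_per_field < 1:
            raise ValueError("n_fields and cells_per_field must be >= 1")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.correlation is None:
            self.correlation = np.eye(k)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (k, k):
            raise ValueError("correlation must be k x k")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.correlation).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        if self.bleed is None:
            self.bleed = np.zeros((k, k))
        self.bleed = np.asarray(self.bleed, dtype=float)
        if self.bleed.shape != (k, k):
            raise ValueError("bleed must be k x k")
        if np.any(np.diag(self.bleed) != 0):
            raise ValueError("bleed diagonal must be zero (self-bleed is excluded)")
        if np.any(self.bleed < 0):
            raise ValueError("bleed fractions must be >= 0")


def _copula_uniforms(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    """Draw n rows of correlated uniforms via a Gaussian copula."""
    # eigh-based factor tolerates semi-definite matrices (e.g. r = 1)
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, corr.shape[0])) @ factor.T
    return stats.norm.cdf(z)


def simulate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Simulate per-cell intensity records for a multi-channel population.

    Returns a table with one row per cell and, per channel ``c``, the
    columns ``{c}_true`` (latent background-free intensity), ``{c}_raw``
    (measured: true + bleed-through + field background) and ``{c}_on``.
    Shape-descriptor columns emulate what a segmentation tool reports.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.channels)
    n_total = spec.n_fields * spec.cells_per_field
    names = [c.name for c in spec.channels]
    if len(set(names)) != k:
        raise ValueError("channel names must be unique")

    backgrounds = rng.normal(spec.background_mean, spec.background_sd,
                             size=(spec.n_fields, k))
    u = _copula_uniforms(rng, spec.correlation, n_total)
    true = np.empty((n_total, k))
    on = np.empty((n_total, k), dtype=bool)
    for j, ch in enumerate(spec.channels):
        on[:, j] = rng.random(n_total) < ch.on_fraction
        on_vals = ch.ppf(u[:, j])
        true[:, j] = np.where(on[:, j], np.clip(on_vals, 0.0, None), ch.off_level)

    field_idx = np.repeat(np.arange(spec.n_fields), spec.cells_per_field)
    measured = true + true @ spec.bleed.T + backgrounds[field_idx]

    # plausible rod shapes so downstream gates have something to act on
    length = rng.uniform(2.0, 4.0, n_total)
    width = rng.uniform(0.7, 0.95, n_total)

    data: dict[str, object] = {
        "cell_id": np.arange(n_total),
        "field": field_idx,
    }
    for j, name in enumerate(names):
        data[f"{name}_raw"] = measured[:, j]
        data[f"{name}_true"] = true[:, j]
        data[f"{name}_on"] = on[:, j]
    data["area_um2"] = length * width
    data["length_um"] = length
    data["width_um"] = width
    data["curvature"] = rng.uniform(0.0, 0.1, n_total)
    data["angularity"] = rng.uniform(0.0, 0.2, n_total)
    data["condition"] = spec.condition
    data["time_min"] = spec.time_min
    return pd.DataFrame(data)


@dataclass
class ImageSpec:
    """Specification of a synthetic micrograph of rod-shaped cells.

    Cells are spherocylinders with uniform interior intensity, placed
    without overlap, convolved with a Gaussian PSF and optionally
    corrupted by Gaussian or Poisson noise.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # µm per pixel
    n_cells: int = 20
    cell_length_range: tuple[float, float] = (2.0, 4.0)  # µm
    cell_width_range: tuple[float, float] = (0.7, 0.9)  # µm
    cell_intensity: float = 1000.0
    background_intensity: float = 100.0
    psf_sigma: float = 1.0  # pixels
    noise_model: str = "none"  # none | gaussian | poisson
    noise_sd: float = 20.0  # gaussian noise only
    seed: int = 0
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for rng_ in (self.cell_length_range, self.cell_width_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("cell size ranges must be positive and ordered")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _rod_mask(shape: tuple[int, int], cx: float, cy: float, length_px: float,
              width_px: float, theta: float) -> np.ndarray:
    """Boolean mask of a spherocylinder: points within width/2 of the axis segment."""
    half = max(length_px - width_px, 0.0) / 2.0  # axis segment half-length
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dx, dy = xx - cx, yy - cy
    ax, ay = np.cos(theta), np.sin(theta)
    t = np.clip(dx * ax + dy * ay, -half, half)
    dist2 = (dx - t * ax) ** 2 + (dy - t * ay) ** 2
    return dist2 <= (width_px / 2.0) ** 2


def simulate_images(spec: ImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic micrograph and its ground-truth cell table.

    Returns ``(image, truth)`` where ``truth`` lists each planted cell's
    centroid (px), length and width (µm), and orientation (rad). Raises
    ``RuntimeError`` if the requested number of non-overlapping cells
    cannot be placed within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    occupied = np.zeros((h, w), dtype=bool)
    image = np.full((h, w), spec.background_intensity, dtype=float)
    rows = []
    for i in range(spec.n_cells):
        placed = False
        for _ in range(spec.max_placement_tries):
            length_um = rng.uniform(*spec.cell_length_range)
            width_um = rng.uniform(*spec.cell_width_range)
            length_px = length_um / spec.pixel_size
            width_px = width_um / spec.pixel_size
            margin = length_px / 2 + width_px
            if 2 * margin >= min(h, w):
                continue
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            theta = rng.uniform(0, np.pi)
            mask = _rod_mask((h, w), cx, cy, length_px, width_px, theta)
            # forbid touching: dilate by 2 px before the overlap check
            dilated = ndimage.binary_dilation(mask, iterations=2)
            if not (dilated & occupied).any():
                occupied |= dilated
                image[mask] = spec.cell_intensity
                rows.append({"cell_id": i, "cx": cx, "cy": cy,
                             "length_um": length_um, "width_um": width_um,
                             "orientation": theta})
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{spec.n_cells} without overlap "
                f"after {spec.max_placement_tries} tries")
    if spec.psf_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.psf_sigma)
    if spec.noise_model == "gaussian":
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    elif spec.noise_model == "poisson":
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    return image, pd.DataFrame(rows)


@dataclass
class CooccurSpec:
    """Specification of a synthetic regulator presence/absence table.

    Every species carries the anchor component (e.g. CadB); each regulator
    flag is an independent Bernoulli draw with its conditional presence
    probability given the anchor.
    """

    n_species: int = 1000
    anchor_component: str = "CadB"
    regulator_probs: Mapping[str, float] = dc_field(
        default_factory=lambda: {"CadA": 0.943, "CadC": 0.955, "LysP": 0.669})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for reg, p in self.regulator_probs.items():
            if not reg or not isinstance(reg, str):
                raise ValueError(f"invalid regulator name {reg!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {reg} must be in [0, 1]")


def simulate_presence_table(spec: CooccurSpec) -> pd.DataFrame:
    """Simulate a species x component presence/absence matrix (anchor all 1)."""
    rng = np.random.default_rng(spec.seed)
    data: dict[str, object] = {
        "species_id": [f"sp{i:05d}" for i in range(spec.n_species)],
        spec.anchor_component: np.ones(spec.n_species, dtype=int),
    }
    for reg, p in spec.regulator_probs.items():
        data[reg] = (rng.random(spec.n_species) < p).astype(int)
    return pd.DataFrame(data).set_index("species_id")


@dataclass
class TreeSimSpec:
    """Specification for evolving an ungapped alignment along a known tree.

    ``tree`` is a Newick string or dendropy Tree with branch lengths in
    expected substitutions per site. Columns evolve i.i.d. under the
    equal-rates (Jukes-Cantor type) model for the chosen alphabet.
    """

    tree: object  # newick str or dendropy.Tree
    seq_length: int = 1000
    alphabet: str = NUCLEOTIDE_ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet needs at least 2 states")


def _substitution_prob(d: float, a: int) -> float:
    """Total substitution probability along a branch of length d (a states)."""
    if d < 0:
        raise ValueError("branch lengths must be >= 0")
    return (a - 1) / a * (1.0 - np.exp(-a / (a - 1) * d))


def evolve_alignment(spec: TreeSimSpec) -> dict[str, str]:
    """Evolve sequences down a tree under the a-state equal-rates model.

    Returns ``{leaf_label: sequence}`` with all sequences of equal length
    and no gaps. The root sequence is uniform over the alphabet; along each
    branch every site substitutes with probability
    ``((a-1)/a) * (1 - exp(-(a/(a-1)) d))``, to a uniformly chosen
    different state.
    """
    import dendropy

    if isinstance(spec.tree, dendropy.Tree):
        tree = spec.tree
    else:
        tree = dendropy.Tree.get(data=str(spec.tree), schema="newick")
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")

    rng = np.random.default_rng(spec.seed)
    a = len(spec.alphabet)
    states = np.frombuffer(spec.alphabet.encode(), dtype=np.uint8)
    L = spec.seq_length

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, a, size=L)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        d = node.edge.length or 0.0
        p = _substitution_prob(d, a)
        parent_seq = seqs[id(node.parent_node)]
        seq = parent_seq.copy()
        mut = rng.random(L) < p
        n_mut = int(mut.sum())
        if n_mut:
            # uniform over the a-1 states different from the current one
            offset = rng.integers(1, a, size=n_mut)
            seq[mut] = (seq[mut] + offset) % a
        seqs[id(node)] = seq
    out = {}
    for leaf in leaves:
        label = leaf.taxon.label if leaf.taxon else str(leaf)
        out[label] = states[seqs[id(leaf)]].tobytes().decode()
    return out
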