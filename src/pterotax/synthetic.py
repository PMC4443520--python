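"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators emulate the three data streams of the study design:

* shell outlines — a parametric ventral shell profile spanning
  cylindrical to bottle-shaped morphotypes, with per-individual size and
  shape draws and per-point digitization noise;
* aligned sequence sets — a star-like two-level divergence model
  (deme ancestors diverge from a common ancestor, individuals diverge
  from their deme ancestor) under a Jukes-Cantor substitution scheme;
* environmental grids — smooth per-layer gradients plus noise, with
  presence points drawn from a known Gaussian niche and a fixed set of
  candidate sampling locations for the null model.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .morphometrics import Outline
from .niche import EnvGrid, OccurrenceSet
from .popgen import PopulationPartition, SequenceAlignment

__all__ = [
    "MorphotypeSpec",
    "SeqSimConfig",
    "EnvSimConfig",
    "generate_outlines",
    "generate_repeat_series",
    "simulate_sequence_set",
    "generate_environment",
]

_ALPHABET = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# shells


@dataclass
class MorphotypeSpec:
    """Generative parameters for one shell morphotype.

    Width parameters are fractions of shell length; ``max_width_pos``
    runs from 0 (septum, the closed bottom) to 1 (aperture, the open
    top). ``roundness`` controls how peaked the width bump is; the
    cylindrical extreme is approached as ``max_width`` tends to the
    baseline widths, the bottle shape by a pronounced bump low on the
    shell.
    """

    name: str
    length_mean: float = 8.0  # mm; adult shells are roughly 6-11 mm
    length_sd: float = 0.5
    aperture_width: float = 0.28
    max_width: float = 0.34
    max_width_pos: float = 0.45
    septum_width: float = 0.12
    roundness: float = 4.0
    digitization_noise_sd: float = 0.02  # mm
    shape_jitter_sd: float = 0.0  # relative sd of per-individual width jitter

    def validate(self) -> None:
        fracs = {
            "aperture_width": self.aperture_width,
            "max_width": self.max_width,
            "max_width_pos": self.max_width_pos,
            "septum_width": self.septum_width,
        }
        for k, v in fracs.items():
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{k} must be in (0, 1), got {v}")
        if self.length_mean <= 0:
            raise ConfigurationError("length_mean must be positive")
        if self.septum_width > self.max_width:
            raise ConfigurationError("septum_width must not exceed max_width")
        if self.digitization_noise_sd < 0 or self.length_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.roundness <= 0:
            raise ConfigurationError("roundness must be positive")


def _bump(t: np.ndarray, pos: float, roundness: float) -> np.ndarray:
    """Beta-like bump on [0,1] with mode at ``pos``, normalized to max 1."""
    a = 1.0 + roundness * pos
    b = 1.0 + roundness * (1.0 - pos)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = t**(a - 1.0) * (1.0 - t) ** (b - 1.0)
        peak = pos ** (a - 1.0) * (1.0 - pos) ** (b - 1.0)
    return np.where(peak > 0, val / peak, 0.0)


def _half_width(t: np.ndarray, spec_vals: dict) -> np.ndarray:
    """Half-width profile at axial fraction t (0 = septum, 1 = aperture)."""
    base = spec_vals["septum_width"] + (
        spec_vals["aperture_width"] - spec_vals["septum_width"]
    ) * t
    base_at_peak = spec_vals["septum_width"] + (
        spec_vals["aperture_width"] - spec_vals["septum_width"]
    ) * spec_vals["max_width_pos"]
    bump = _bump(t, spec_vals["max_width_pos"], spec_vals["roundness"])
    return 0.5 * (base + (spec_vals["max_width"] - base_at_peak) * bump)


def _shell_outline(length: float, spec_vals: dict, n_side: int = 120, n_cap: int = 24) -> np.ndarray:
    """Open outline: right aperture edge -> septum cap -> left aperture edge."""
    t = np.linspace(1.0, 0.0, n_side)
    w = _half_width(t, spec_vals) * length
    right = np.column_stack([w, t * length])
    # rounded septum: semicircular cap below y = 0
    r_cap = 0.5 * spec_vals["septum_width"] * length
    theta = np.linspace(0.0, np.pi, n_cap + 2)[1:-1]
    cap = np.column_stack([r_cap * np.cos(theta), -r_cap * np.sin(theta)])
    left = np.column_stack([-w[::-1], t[::-1] * length])
    return np.vstack([right, cap, left])


def generate_outlines(
    spec: MorphotypeSpec, n: int, seed: int | None = None
) -> list[tuple[Outline, str]]:
    """Draw ``n`` individual shell outlines for one morphotype.

    Each individual gets a length draw, optional multiplicative jitter
    of the width parameters, and per-point Gaussian digitization noise.
    The outline is an open polyline whose endpoints are the two
    aperture-edge anchors.
    """
    spec.validate()
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    jitter_keys = ("aperture_width", "max_width", "septum_width")
    for _ in range(n):
        length = max(rng.normal(spec.length_mean, spec.length_sd), 0.1 * spec.length_mean)
        vals = {
            k: getattr(spec, k)
            for k in ("aperture_width", "max_width", "max_width_pos",
                      "septum_width", "roundness")
        }
        if spec.shape_jitter_sd > 0:
            for k in jitter_keys:
                vals[k] = float(np.clip(
                    vals[k] * rng.normal(1.0, spec.shape_jitter_sd), 1e-3, 0.999
                ))
            vals["max_width"] = max(vals["max_width"], vals["septum_width"] + 1e-6)
        pts = _shell_outline(length, vals)
        if spec.digitization_noise_sd > 0:
            pts = pts + rng.normal(0.0, spec.digitization_noise_sd, pts.shape)
        outline = Outline(points=pts, is_closed=False,
                          anchor_indices=(0, len(pts) - 1))
        out.append((outline, spec.name))
    return out


def generate_repeat_series(
    outlines: list[Outline],
    noise_sd: float,
    seed: int | None = None,
    max_rotation_deg: float = 2.0,
    max_translation: float = 0.1,
) -> list[Outline]:
    """Second digitization of each outline: fresh noise plus a small
    random re-rotation and re-translation, preserving order."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    series2 = []
    for o in outlines:
        pts = o.points.copy()
        if max_rotation_deg > 0:
            ang = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
            c, s = np.cos(ang), np.sin(ang)
            pts = pts @ np.array([[c, -s], [s, c]]).T
        if max_translation > 0:
            pts = pts + rng.uniform(-max_translation, max_translation, 2)
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd, pts.shape)
        series2.append(Outline(points=pts, is_closed=o.is_closed,
                               anchor_indices=o.anchor_indices))
    return series2


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SeqSimConfig:
    """Two-level divergence model for aligned haplotype sets."""

    n_demes: int = 2
    n_per_deme: int = 20
    seq_length: int = 658  # bp, COI barcode fragment length
    within_divergence: float = 0.01  # expected substitutions/site
    between_divergence: float = 0.05
    substitution_model: str = "JC"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_demes < 1 or self.n_per_deme < 1:
            raise ConfigurationError("n_demes and n_per_deme must be >= 1")
        if self.seq_length <= 0:
            raise ConfigurationError("seq_length must be positive")
        if self.within_divergence < 0 or self.between_divergence < 0:
            raise ConfigurationError("divergences must be non-negative")
        if self.substitution_model != "JC":
            raise ConfigurationError("only the Jukes-Cantor model is implemented")


def _mutate(seq: np.ndarray, expected_subs: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson number of substitutions at uniform sites (multiple hits allowed)."""
    out = seq.copy()
    n_mut = rng.poisson(expected_subs)
    for site in rng.integers(0, len(seq), n_mut):
        current = out[site]
        choices = [b for b in range(4) if b != current]
        out[site] = choices[rng.integers(0, 3)]
    return out


def simulate_sequence_set(cfg: SeqSimConfig) -> tuple[SequenceAlignment, PopulationPartition]:
    """Simulate aligned sequences with nested within/between-deme divergence."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    ancestor = rng.integers(0, 4, L)
    ids, seqs, mapping = [], [], {}
    for d in range(cfg.n_demes):
        deme_anc = _mutate(ancestor, cfg.between_divergence * L, rng)
        deme = f"deme{d}"
        for i in range(cfg.n_per_deme):
            indiv = _mutate(deme_anc, cfg.within_divergence * L, rng)
            sid = f"{deme}_ind{i}"
            ids.append(sid)
            seqs.append("".join(_ALPHABET[indiv]))
            mapping[sid] = deme
    aln = SequenceAlignment(ids=ids, seqs=seqs, locus="COI-sim")
    return aln, PopulationPartition(mapping=mapping)


# ---------------------------------------------------------------------------
# environments


@dataclass
class EnvSimConfig:
    """Gridded environment with a known Gaussian niche.

    ``layer_gradients`` holds one (angle_degrees, low, high) tuple per
    layer: the layer increases linearly from ``low`` to ``high`` along
    the compass direction given by the angle, plus Gaussian noise.
    """

    grid_shape: tuple[int, int] = (40, 60)
    n_layers: int = 3
    layer_gradients: list[tuple[float, float, float]] | None = None
    noise_sd: float = 0.05
    niche_optimum: list[float] | None = None
    niche_breadth: list[float] | None = None
    n_presences: int = 60
    n_sampling_locations: int = 200
    land_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.layer_gradients is None:
            # spread directions over a half-turn so no two default layers
            # are collinear (the analyses assume weakly correlated layers)
            self.layer_gradients = [
                (180.0 * i / max(self.n_layers, 1), 0.0, 1.0)
                for i in range(self.n_layers)
            ]
        if self.niche_optimum is None:
            self.niche_optimum = [0.5] * self.n_layers
        if self.niche_breadth is None:
            self.niche_breadth = [0.15] * self.n_layers

    def validate(self) -> None:
        if min(self.grid_shape) < 1:
            raise ConfigurationError("grid_shape must be positive")
        if self.n_layers < 1:
            raise ConfigurationError("need at least one layer")
        if len(self.layer_gradients) != self.n_layers:
            raise ConfigurationError("one gradient spec per layer required")
        if any(b <= 0 for b in self.niche_breadth):
            raise ConfigurationError("niche_breadth must be positive")
        if not 0.0 <= self.land_fraction < 1.0:
            raise ConfigurationError("land_fraction must be in [0, 1)")


def generate_environment(
    cfg: EnvSimConfig,
) -> tuple[EnvGrid, OccurrenceSet, OccurrenceSet]:
    """Build layers, draw presences from the true niche, fix sampling sites.

    The true suitability is ``exp(-sum_j (x_j - optimum_j)^2 /
    (2 breadth_j^2))`` normalized to sum 1 over ocean cells; presences
    are cells drawn with that probability (with replacement, as repeat
    collection records); sampling locations are drawn uniformly without
    replacement from ocean cells.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nrows, ncols = cfg.grid_shape
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")

    mask = np.ones((nrows, ncols), dtype=bool)
    if cfg.land_fraction > 0:
        n_land = int(round(cfg.land_fraction * mask.size))
        land_ix = rng.choice(mask.size, size=n_land, replace=False)
        mask.ravel()[land_ix] = False

    layers = {}
    for j, (angle, low, high) in enumerate(cfg.layer_gradients):
        theta = np.deg2rad(angle)
        proj = np.cos(theta) * cc / max(ncols - 1, 1) + np.sin(theta) * rr / max(nrows - 1, 1)
        pmin, pmax = proj.min(), proj.max()
        unit = (proj - pmin) / (pmax - pmin) if pmax > pmin else np.zeros_like(proj)
        layer = low + (high - low) * unit
        if cfg.noise_sd > 0:
            layer = layer + rng.normal(0.0, cfg.noise_sd, layer.shape)
        layers[f"layer{j}"] = layer

    grid = EnvGrid(layers=layers, mask=mask, xll=0.0, yll=0.0, cellsize=1.0)

    ocean_flat = np.flatnonzero(mask.ravel())
    if cfg.n_presences > len(ocean_flat):
        raise ConfigurationError("n_presences exceeds the number of ocean cells")
    if cfg.n_sampling_locations > len(ocean_flat):
        raise ConfigurationError("n_sampling_locations exceeds the number of ocean cells")

    log_suit = np.zeros(len(ocean_flat))
    for j, name in enumerate(grid.layer_names):
        x = grid.layers[name].ravel()[ocean_flat]
        log_suit -= (x - cfg.niche_optimum[j]) ** 2 / (2.0 * cfg.niche_breadth[j] ** 2)
    suit = np.exp(log_suit - log_suit.max())
    suit /= suit.sum()

    pres_flat = rng.choice(ocean_flat, size=cfg.n_presences, replace=True, p=suit)
    pr, pc = np.divmod(pres_flat, ncols)
    plon, plat = grid.cell_center(pr, pc)
    occ = OccurrenceSet(lon=plon, lat=plat, label="sim")

    samp_flat = rng.choice(ocean_flat, size=cfg.n_sampling_locations, replace=False)
    sr, sc = np.divmod(samp_flat, ncols)
    slon, slat = grid.cell_center(sr, sc)
    sampling = OccurrenceSet(lon=slon, lat=slat, label="sampling")
    return grid, occ, sampling


def true_suitability(cfg: EnvSimConfig, grid: EnvGrid) -> np.ndarray:
    """The generating niche's normalized suitability over the full grid."""
    values = np.full(grid.shape, np.nan)
    log_suit = np.zeros(int(grid.mask.sum()))
    for j, name in enumerate(grid.layer_names):
        x = grid.layers[name][grid.mask]
        log_suit -= (x - cfg.niche_optimum[j]) ** 2 / (2.0 * cfg.niche_breadth[j] ** 2)
    suit = np.exp(log_suit - log_suit.max())
    values[grid.mask] = suit / suit.sum()
    return values
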