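"""End-to-end orchestration: synthetic data -> morphometrics -> popgen -> niche.

A single master seed deterministically derives one child seed per stage
(counter-based spawning of numpy SeedSequences), so a stage rerun with
the same configuration reproduces its output byte-for-byte regardless of
which other stages are enabled.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics as mm
from . import niche as nc
from . import popgen as pg
from . import synthetic as syn
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "run_pipeline", "default_morphotype_specs"]

log = logging.getLogger("pterotax")

_STAGES = ("morpho", "popgen", "niche")


@dataclass
class PipelineConfig:
    """Toggles and per-stage parameters for one reproducible run."""

    seed: int = 0
    out_dir: str | None = None
    run_morpho: bool = True
    run_popgen: bool = True
    run_niche: bool = True
    # morphometrics stage
    n_per_morphotype: int = 30
    k_ventral: int = 75
    icc_threshold: float = 0.80
    n_repeat_specimens: int = 44
    repeat_noise_sd: float = 0.02
    n_perm_permanova: int = 999
    # popgen stage
    n_demes_atlantic: int = 2
    n_per_deme: int = 20
    seq_length: int = 658
    within_divergence: float = 0.01
    between_deme_divergence: float = 0.004
    between_clade_divergence: float = 0.05
    n_perm_phist: int = 1000
    clade_threshold: float = 0.03
    # niche stage
    grid_shape: tuple[int, int] = (30, 40)
    n_layers: int = 3
    n_presences: int = 40
    n_sampling_locations: int = 150
    n_rand_null: int = 19
    niche_optima: tuple[float, ...] = (0.3, 0.5, 0.7)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown pipeline options: {sorted(bad)}")
        cfg = cls(**d)
        if "grid_shape" in d:
            cfg.grid_shape = tuple(d["grid_shape"])
        if "niche_optima" in d:
            cfg.niche_optima = tuple(d["niche_optima"])
        return cfg


def default_morphotype_specs(shape_jitter_sd: float = 0.02) -> list[syn.MorphotypeSpec]:
    """Six morphotype specs spanning the cylindrical-to-bottle continuum.

    The contrasts emulate the field situation: two Atlantic forms (a
    long cylindrical shell and a broad bottle), an Indo-Pacific bottle
    form, and three intermediate/columnar forms differing in size and
    in where the maximum width sits along the shell axis.
    """
    base = dict(length_sd=0.4, digitization_noise_sd=0.02,
                shape_jitter_sd=shape_jitter_sd)
    return [
        syn.MorphotypeSpec(name="cylindrical_large", length_mean=10.0,
                           aperture_width=0.27, max_width=0.30,
                           max_width_pos=0.55, septum_width=0.12,
                           roundness=3.0, **base),
        syn.MorphotypeSpec(name="bottle_equatorial", length_mean=7.0,
                           aperture_width=0.30, max_width=0.45,
                           max_width_pos=0.25, septum_width=0.16,
                           roundness=6.0, **base),
        syn.MorphotypeSpec(name="bottle_small", length_mean=6.0,
                           aperture_width=0.32, max_width=0.47,
                           max_width_pos=0.30, septum_width=0.18,
                           roundness=6.0, **base),
        syn.MorphotypeSpec(name="columnar_indian", length_mean=9.0,
                           aperture_width=0.28, max_width=0.34,
                           max_width_pos=0.50, septum_width=0.13,
                           roundness=4.0, **base),
        syn.MorphotypeSpec(name="columnar_north", length_mean=8.2,
                           aperture_width=0.29, max_width=0.37,
                           max_width_pos=0.40, septum_width=0.11,
                           roundness=4.0, **base),
        syn.MorphotypeSpec(name="narrow_south", length_mean=8.5,
                           aperture_width=0.26, max_width=0.33,
                           max_width_pos=0.45, septum_width=0.08,
                           roundness=5.0, **base),
    ]


def stage_seed(master_seed: int, stage: str) -> int:
    """Counter-based derivation of a per-stage child seed (< 2**31)."""
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    child = np.random.SeedSequence(master_seed, spawn_key=(_STAGES.index(stage),))
    return int(child.generate_state(1, np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# stages


def _morpho_stage(cfg: PipelineConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    specs = default_morphotype_specs()
    outlines, labels = [], []
    for spec in specs:
        for o, lab in syn.generate_outlines(spec, cfg.n_per_morphotype,
                                            seed=int(rng.integers(2**31))):
            outlines.append(o)
            labels.append(lab)
    configs = [mm.resample_outline(o, cfg.k_ventral) for o in outlines]
    # extra fixed landmark at the top (middle) of the aperture opening
    for c, o in zip(configs, outlines):
        c.extra_points = 0.5 * (o.points[0] + o.points[-1])[None, :]
    pr = mm.gpa(configs)
    rw = mm.relative_warps(pr)

    # repeatability from a duplicate digitization of a specimen subset
    n_rep = min(cfg.n_repeat_specimens, len(outlines))
    rep_ix = rng.choice(len(outlines), size=n_rep, replace=False)
    series2 = syn.generate_repeat_series(
        [outlines[i] for i in rep_ix], cfg.repeat_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    cfg2 = [mm.resample_outline(o, cfg.k_ventral) for o in series2]
    for c, o in zip(cfg2, series2):
        c.extra_points = 0.5 * (o.points[0] + o.points[-1])[None, :]
    both = [configs[i] for i in rep_ix] + cfg2
    pr2 = mm.gpa(both)
    rw2 = mm.relative_warps(pr2)
    n_axes = min(10, rw2.scores.shape[1])
    f1 = pd.DataFrame(rw2.scores[:n_rep, :n_axes],
                      columns=[f"RW{i+1}" for i in range(n_axes)])
    f2 = pd.DataFrame(rw2.scores[n_rep:, :n_axes], columns=f1.columns)
    f1["CS"] = pr2.centroid_sizes[:n_rep]
    f2["CS"] = pr2.centroid_sizes[n_rep:]
    report = mm.repeatability_report(f1, f2, threshold=cfg.icc_threshold)

    n_axes_all = min(10, rw.scores.shape[1])
    features = pd.DataFrame(rw.scores[:, :n_axes_all],
                            columns=[f"RW{i+1}" for i in range(n_axes_all)])
    features["CS"] = pr.centroid_sizes
    features = mm.select_repeatable(report, features)

    confusion = mm.jackknife_confusion(features, labels)
    perm = mm.permanova(features, labels, n_perm=cfg.n_perm_permanova,
                        seed=int(rng.integers(2**31)), standardize=True)
    return {
        "n_specimens": len(outlines),
        "rw_variance_fraction": [round(float(v), 6) for v in rw.variance_fraction[:10]],
        "icc": {k: round(float(v), 6)
                for k, v in zip(report.feature_names, report.icc_values)},
        "selected_features": list(features.columns),
        "jackknife_percent_correct": round(confusion.percent_correct, 4),
        "confusion_matrix": confusion.to_frame().to_dict(),
        "permanova": {"F": round(perm.F, 6), "p": perm.p, "n_perm": perm.n_perm},
    }


def _popgen_stage(cfg: PipelineConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    # Atlantic analog: one clade with two demes (north/south) plus two
    # further clades at deep divergence, mirroring the three-clade setup.
    atl_cfg = syn.SeqSimConfig(
        n_demes=cfg.n_demes_atlantic, n_per_deme=cfg.n_per_deme,
        seq_length=cfg.seq_length, within_divergence=cfg.within_divergence,
        between_divergence=cfg.between_deme_divergence,
        seed=int(rng.integers(2**31)),
    )
    atl_aln, atl_part = syn.simulate_sequence_set(atl_cfg)

    clade_cfg = syn.SeqSimConfig(
        n_demes=3, n_per_deme=cfg.n_per_deme, seq_length=cfg.seq_length,
        within_divergence=cfg.within_divergence,
        between_divergence=cfg.between_clade_divergence,
        seed=int(rng.integers(2**31)),
    )
    clade_aln, clade_part = syn.simulate_sequence_set(clade_cfg)

    stats = pg.haplotype_stats(atl_aln)
    phi = pg.phi_st(atl_aln, atl_part, n_perm=cfg.n_perm_phist,
                    seed=int(rng.integers(2**31)))
    dm = pg.p_distance_matrix(clade_aln)
    clades = pg.clade_partition(dm, threshold=cfg.clade_threshold)
    truth = clade_part.groups_for(clade_aln)
    agree = pd.crosstab(truth, clades.to_numpy()).max(axis=1).sum() / clade_aln.n
    tree = pg.nj_tree(dm) if clade_aln.n <= 30 else None
    return {
        "diversity": {"n": stats.n, "n_haplotypes": stats.n_haplotypes,
                      "S": stats.S, "H": round(stats.H, 6), "pi": round(stats.pi, 6)},
        "phi_st": {"value": round(phi.phi_st, 6), "p": phi.p, "n_perm": phi.n_perm},
        "n_clades_found": int(clades.nunique()),
        "clade_agreement": round(float(agree), 6),
        "nj_tree_taxa": clade_aln.n if tree else None,
    }


def _niche_stage(cfg: PipelineConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    surfaces = {}
    aucs, null_p = {}, {}
    grid = None
    for i, opt in enumerate(cfg.niche_optima):
        env_cfg = syn.EnvSimConfig(
            grid_shape=cfg.grid_shape, n_layers=cfg.n_layers,
            niche_optimum=[opt] * cfg.n_layers,
            niche_breadth=[0.15] * cfg.n_layers,
            n_presences=cfg.n_presences,
            n_sampling_locations=cfg.n_sampling_locations,
            seed=seed,  # same environment for every morphotype
        )
        g, occ, sampling = syn.generate_environment(env_cfg)
        if grid is None:
            grid = g
        name = f"morph{i}"
        occ.label = name
        # re-draw this morphotype's presences from its own niche
        suit = syn.true_suitability(env_cfg, grid)[grid.mask]
        ocean_flat = np.flatnonzero(grid.mask.ravel())
        pres = rng.choice(ocean_flat, size=cfg.n_presences, replace=True,
                          p=suit / suit.sum())
        prow, pcol = np.divmod(pres, grid.shape[1])
        lon, lat = grid.cell_center(prow, pcol)
        occ = nc.OccurrenceSet(lon=lon, lat=lat, label=name)
        model = nc.fit_maxent(occ, grid)
        surfaces[name] = model
        aucs[name] = round(nc.surface_auc(model), 6)
        res = nc.null_model_test(occ, grid, sampling, n_rand=cfg.n_rand_null,
                                 seed=int(rng.integers(2**31)))
        null_p[name] = res.p
    names = list(surfaces)
    d_matrix = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                d = nc.schoener_d(surfaces[a], surfaces[b]).D
                d_matrix.loc[a, b] = d_matrix.loc[b, a] = round(d, 6)
    return {
        "auc": aucs,
        "null_model_p": null_p,
        "schoener_d": d_matrix.round(6).to_dict(),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run report.

    The report is a plain JSON-serializable dict, regenerated
    byte-identically from the same configuration and master seed. Stage
    timings go to the logger (stderr), never into the report.
    """
    from . import __version__

    report: dict = {
        "software": {"name": "pterotax", "version": __version__},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "stage_seeds": {},
        "stages": {},
    }
    runners = {
        "morpho": (cfg.run_morpho, _morpho_stage),
        "popgen": (cfg.run_popgen, _popgen_stage),
        "niche": (cfg.run_niche, _niche_stage),
    }
    for stage, (enabled, fn) in runners.items():
        if not enabled:
            continue
        s = stage_seed(cfg.seed, stage)
        report["stage_seeds"][stage] = s
        t0 = time.perf_counter()
        try:
            report["stages"][stage] = fn(cfg, s)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
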