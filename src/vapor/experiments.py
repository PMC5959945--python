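"""Cooling trials: warm vs cold scalp, parameter sweeps, Pennes baseline.

A cooling trial builds the head domain (phantom by default), grows the
arterial and venous trees from their seeds, solves flow once per
replicate, then solves the energy balance at a warm scalp (33.5 degC)
and a cooled scalp (10 degC) with identical trees and flows. Metrics
are volume-weighted means over the brain and core masks; replicate
spread is reported as the standard error over the tree seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import PhantomSpec, make_phantom_head, make_seed_trees
from .flow import INLET_SPLIT, OUTLET_SPLIT, solve_flow
from .geometry import apply_neonatal_scaling, build_domain
from .params import PhysicalParams
from .thermal import (
    T_SCALP_COLD,
    T_SCALP_WARM,
    pbe_steady_solve,
    vapor_steady_solve,
)
from .vasculature import rrt_expand

METRICS = ("brain_warm", "brain_cold", "core_warm", "core_cold",
           "brain_drop", "core_drop")


@dataclass
class TrialConfig:
    """Configuration of one cooling trial on the phantom head."""

    grid_shape: tuple = (40, 48, 40)
    voxel_edge: float = 3e-3  # m
    blend: bool = False
    mode: str = "vapor"  # "vapor" | "pbe"
    rrt_iterations: int = 2500
    flow_reversal: float = 1.0  # C_R
    step_cap: float = 3e-3  # m
    seeds: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    t_scalp_warm: float = T_SCALP_WARM
    t_scalp_cold: float = T_SCALP_COLD
    total_flow: float = None  # kg/s; None -> integral of brain perfusion
    inlet_split: tuple = INLET_SPLIT
    outlet_split: tuple = OUTLET_SPLIT
    neonatal: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "seeds", "inlet_split", "outlet_split"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrialResult:
    """Replicate metrics, their aggregate, and the mean cooling map."""

    replicates: pd.DataFrame
    summary: dict  # metric -> {"mean": ..., "se": ...}
    drop_map: np.ndarray  # warm - cold, degC, averaged over replicates
    config: dict
    core_mask: np.ndarray = None
    brain_mask: np.ndarray = None

    def mean(self, metric: str) -> float:
        return self.summary[metric]["mean"]

    def se(self, metric: str) -> float:
        return self.summary[metric]["se"]


def _build_model(config: TrialConfig):
    """Phantom domain, seed trees, parameters and total flow for a trial."""
    spec = PhantomSpec(
        grid_shape=tuple(config.grid_shape),
        voxel_edge=config.voxel_edge,
        blend=config.blend,
    )
    tmap = make_phantom_head(spec)
    params = PhysicalParams(flow_reversal=config.flow_reversal)
    if config.neonatal:
        tmap, params = apply_neonatal_scaling(tmap, params)
        spec = dataclasses.replace(spec, voxel_edge=tmap.voxel_edge)
    domain = build_domain(tmap, params)
    arterial, venous = make_seed_trees(spec)
    total_flow = config.total_flow
    if total_flow is None:
        # the physiological closure: total inflow equals the perfusion
        # integral over the brain
        total_flow = float(
            (domain.perfusion_vol[domain.brain_mask] * domain.voxel_volume).sum()
        )
    return domain, arterial, venous, params, total_flow


def _summarize(rows: list) -> dict:
    df = pd.DataFrame(rows)
    out = {}
    for m in METRICS:
        vals = df[m].to_numpy(dtype=float)
        se = (
            float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            if len(vals) >= 2
            else float("nan")
        )
        out[m] = {"mean": float(np.mean(vals)), "se": se}
    return out


def run_cooling_trial(config: TrialConfig) -> TrialResult:
    """Solve both scalp settings with identical trees/flows per replicate.

    In ``"pbe"`` mode there is no vasculature and the trial is a single
    deterministic Pennes solve per scalp setting.
    """
    domain, seed_art, seed_ven, params, total_flow = _build_model(config)
    rows = []
    drop_maps = []

    if config.mode == "pbe":
        warm = pbe_steady_solve(domain, params, config.t_scalp_warm)
        cold = pbe_steady_solve(domain, params, config.t_scalp_cold)
        rows.append(_metrics_row(None, warm, cold, domain))
        drop_maps.append(warm.tissue - cold.tissue)
    elif config.mode == "vapor":
        for seed in config.seeds:
            ss = np.random.SeedSequence(seed)
            s_art, s_ven = ss.spawn(2)
            art = rrt_expand(
                seed_art, domain, config.rrt_iterations,
                step_cap=config.step_cap, rng_seed=s_art,
            )
            ven = rrt_expand(
                seed_ven, domain, config.rrt_iterations,
                step_cap=config.step_cap, rng_seed=s_ven,
            )
            art, ven, flow = solve_flow(
                art, ven, domain, params,
                total_flow=total_flow,
                inlet_split=config.inlet_split,
                outlet_split=config.outlet_split,
            )
            try:
                warm = vapor_steady_solve(
                    domain, art, ven, flow, params, config.t_scalp_warm
                )
                cold = vapor_steady_solve(
                    domain, art, ven, flow, params, config.t_scalp_cold
                )
            except Exception as exc:  # annotate with the replicate id
                raise type(exc)(f"replicate seed {seed}: {exc}") from exc
            rows.append(_metrics_row(seed, warm, cold, domain))
            drop_maps.append(warm.tissue - cold.tissue)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    return TrialResult(
        replicates=pd.DataFrame(rows),
        summary=_summarize(rows),
        drop_map=np.mean(drop_maps, axis=0),
        config=config.to_dict(),
        core_mask=domain.core_mask,
        brain_mask=domain.brain_mask,
    )


def _metrics_row(seed, warm, cold, domain) -> dict:
    bw = warm.mean_over(domain.brain_mask)
    bc = cold.mean_over(domain.brain_mask)
    cw = warm.mean_over(domain.core_mask)
    cc = cold.mean_over(domain.core_mask)
    return {
        "seed": seed,
        "brain_warm": bw,
        "brain_cold": bc,
        "core_warm": cw,
        "core_cold": cc,
        "brain_drop": bw - bc,
        "core_drop": cw - cc,
    }


def sweep(config: TrialConfig, variable: str, values, seeds=None) -> pd.DataFrame:
    """Run one trial per value of ``variable``; aggregate over seeds.

    ``variable`` is ``"flow_reversal"`` (C_R) or ``"rrt_iterations"``
    (vessel count). Failures are recorded per cell and the sweep
    continues. Returns one row per value with mean +/- SE per metric.
    """
    if variable not in ("flow_reversal", "rrt_iterations"):
        raise ValueError("variable must be 'flow_reversal' or 'rrt_iterations'")
    if seeds is not None and len(seeds) == 0:
        raise ValueError("empty seed list")
    rows = []
    for v in values:
        cfg = dataclasses.replace(
            config, **{variable: v}, seeds=tuple(seeds or config.seeds)
        )
        row = {variable: v}
        try:
            res = run_cooling_trial(cfg)
            for m in METRICS:
                row[m] = res.mean(m)
                row[m + "_se"] = res.se(m)
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_mesh_refinement(
    config: TrialConfig,
    refine: float = 4.0 / 3.0,
    seed: int = 1,
) -> dict:
    """Voxel-size dependency check with matched trees.

    Solves the warm and cold scalp settings on the configured grid and on
    a grid refined by ``refine`` (3 mm -> 2.25 mm by default) covering
    the identical world extent, using the *same* vessel tree (grown once
    on the coarse domain). The fine tissue temperatures are interpolated
    to the coarse voxel centers and compared inside the coarse brain
    mask. Returns the mean absolute relative difference in percent,
    averaged over both scalp settings.
    """
    from scipy.ndimage import map_coordinates

    coarse_shape = tuple(config.grid_shape)
    fine_shape = tuple(int(round(n * refine)) for n in coarse_shape)
    if any(abs(n * refine - f) > 1e-9 for n, f in zip(coarse_shape, fine_shape)):
        raise ValueError("grid_shape must refine to integer voxel counts")

    fields = {}
    trees = {}
    for label, shape, edge in (
        ("coarse", coarse_shape, config.voxel_edge),
        ("fine", fine_shape, config.voxel_edge / refine),
    ):
        spec = PhantomSpec(grid_shape=shape, voxel_edge=edge, blend=config.blend)
        params = PhysicalParams(flow_reversal=config.flow_reversal)
        domain = build_domain(make_phantom_head(spec), params)
        if label == "coarse":
            seed_art, seed_ven = make_seed_trees(spec)
            ss = np.random.SeedSequence(seed)
            s_art, s_ven = ss.spawn(2)
            trees["art"] = rrt_expand(
                seed_art, domain, config.rrt_iterations,
                step_cap=config.step_cap, rng_seed=s_art,
            )
            trees["ven"] = rrt_expand(
                seed_ven, domain, config.rrt_iterations,
                step_cap=config.step_cap, rng_seed=s_ven,
            )
            trees["total_flow"] = config.total_flow or float(
                (domain.perfusion_vol[domain.brain_mask] * domain.voxel_volume).sum()
            )
        art, ven, flow = solve_flow(
            trees["art"], trees["ven"], domain, params,
            total_flow=trees["total_flow"],
            inlet_split=config.inlet_split,
            outlet_split=config.outlet_split,
        )
        fields[label] = {
            "domain": domain,
            "warm": vapor_steady_solve(domain, art, ven, flow, params,
                                       config.t_scalp_warm),
            "cold": vapor_steady_solve(domain, art, ven, flow, params,
                                       config.t_scalp_cold),
        }

    coarse_dom = fields["coarse"]["domain"]
    fine_edge = config.voxel_edge / refine
    centers = coarse_dom.voxel_centers()[coarse_dom.brain_mask]  # world, m
    fine_idx = (centers / fine_edge - 0.5).T
    diffs = []
    for setting in ("warm", "cold"):
        tc = fields["coarse"][setting].tissue[coarse_dom.brain_mask]
        tf = map_coordinates(
            fields["fine"][setting].tissue, fine_idx, order=1, mode="nearest"
        )
        diffs.append(np.abs(tf - tc) / np.abs(tc))
    return {
        "mean_abs_rel_diff_percent": float(np.mean(np.concatenate(diffs)) * 100.0),
        "n_compared": int(sum(d.size for d in diffs)),
        "max_abs_diff_C": float(
            max(
                np.max(np.abs(d * np.abs(tc)))
                for d, tc in zip(
                    diffs,
                    [
                        fields["coarse"][s].tissue[coarse_dom.brain_mask]
                        for s in ("warm", "cold")
                    ],
                )
            )
        ),
    }


def compare_with_pbe(trial: TrialResult, pbe: TrialResult) -> dict:
    """Side-by-side cooling of the vascular model and the Pennes baseline.

    Returns whole-brain and core temperature drops for both, plus the
    voxelwise difference of the cooling maps (vascular minus Pennes).
    """
    if trial.drop_map.shape != pbe.drop_map.shape:
        raise ValueError("trials were run on different grids")
    return {
        "brain_drop_vapor": trial.mean("brain_drop"),
        "brain_drop_pbe": pbe.mean("brain_drop"),
        "core_drop_vapor": trial.mean("core_drop"),
        "core_drop_pbe": pbe.mean("core_drop"),
        "difference_map": trial.drop_map - pbe.drop_map,
    }
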