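"""End-to-end analysis protocols over the simulator and the landscape stack.

Each protocol writes (optionally) a manifest — the full configuration plus
all seeds and the package version — sufficient to reproduce its outputs
bit-for-bit, and returns an in-memory result bundle.  The protocols accept
pre-computed rate trajectories in place of network simulation, so the whole
analysis chain can be exercised on surrogate data.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .params import NetworkConfig, StimulusSpec, POP_NAMES
from .network import Network, run_trial, _seed_numba
from .raster import SpikeRaster
from .rates import RateTrajectory, compute_population_rates, pool_trajectories
from .landscape import (LandscapeGrid, AttractorSet, estimate_pss,
                        convergence_sigma, find_minima, barrier_metrics,
                        make_edges, BarrierMetrics)
from .flux import FluxField, pooled_flux, make_coarse_grid
from .transitions import (define_regions, pooled_first_passage_times,
                          FPTResult, AttractorRegion)


@dataclass
class AnalysisOptions:
    """Shared analysis knobs for all protocols."""

    bins: int = 40                 # landscape grid resolution per axis
    flux_boxes: int = 20           # coarse boxes per axis for flux
    window: float = 50.0           # ms, rate counting window
    stride: float = 5.0            # ms, rate window step
    discard_ms: float = 500.0      # transient dropped per trial
    smooth: int = 1                # boxcar passes before minima search
    depth_threshold: float = 0.5   # minimum basin depth (U units)
    rate_threshold: float = 10.0   # spikes/s, SS/DU mean-rate split
    asym_threshold: float = 5.0    # spikes/s, |r1-r2| defining DS
                                   # states (~half their separation)
    region_semi_axes: float = 5.0  # spikes/s, attractor ellipse radius
    sigma_threshold: float = 0.0006  # convergence target (0.06%)
    min_bin_width: float = 0.0     # spikes/s; 0 = derive from the rate
                                   # quantum 1/(N_pop * window) when a
                                   # network config is available


def _manifest(protocol: str, outdir: Optional[Path], **payload) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"unserializable {type(obj)}")

    man = {"protocol": protocol, "package_version": __version__, **payload}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(man, fh, indent=2, default=enc, sort_keys=True)
    return man


def simulate_rate_trials(config: NetworkConfig, stimulus: StimulusSpec,
                         n_trials: int, trial_ms: float, seed: int,
                         window: float = 50.0, stride: float = 5.0
                         ) -> list[RateTrajectory]:
    """Independent trials -> rate trajectories (seed k uses seed*1000+k)."""
    net = Network(config)
    out = []
    for k in range(n_trials):
        raster = run_trial(config, stimulus, duration=trial_ms,
                           seed=seed * 1000 + k, network=net)
        out.append(compute_population_rates(raster, window, stride))
    return out


@dataclass
class StationaryLandscapeResult:
    grid: LandscapeGrid
    attractors: AttractorSet
    flux: FluxField
    trajectories: list[RateTrajectory]
    sigma_history: list[float]
    converged: bool
    manifest: dict

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)


def run_stationary_landscape(config: Optional[NetworkConfig] = None,
                             stimulus: Optional[StimulusSpec] = None,
                             seed: int = 0,
                             trajectories: Optional[Sequence[RateTrajectory]] = None,
                             batch_trials: int = 3,
                             trial_ms: float = 10_000.0,
                             max_batches: int = 4,
                             options: AnalysisOptions = AnalysisOptions(),
                             outdir=None) -> StationaryLandscapeResult:
    """Stationary landscape + flux + attractor census at fixed parameters.

    Simulates batches of trials (or consumes the given trajectories as one
    batch), accumulating the occupancy histogram until the relative change
    sigma between successive accumulations falls below the configured
    threshold or the trial budget is exhausted; the result is flagged
    non-converged in the latter case.
    """
    opt = options
    sigma_history: list[float] = []
    if trajectories is not None:
        trajs = list(trajectories)
        batches = [trajs]
    else:
        if config is None or stimulus is None:
            raise ValueError("need config+stimulus or trajectories")
        trajs = []
        batches = []
        for b in range(max_batches):
            batch = simulate_rate_trials(
                config, stimulus, batch_trials, trial_ms,
                seed=seed * 100 + b, window=opt.window, stride=opt.stride)
            trajs.extend(batch)
            batches.append(batch)

    # fixed grid over everything observed, then incremental convergence
    all_pts = pool_trajectories(trajs, discard_ms=opt.discard_ms)
    min_w = opt.min_bin_width
    if min_w == 0.0 and config is not None:
        # 1.5x the spike-count rate quantum of the selective populations
        min_w = 1.5 * 1000.0 / (config.N_S1 * opt.window)
    edges = make_edges(all_pts, bins=opt.bins, min_width=min_w)
    converged = len(batches) == 1
    acc: list[RateTrajectory] = []
    prev_grid = None
    for batch in batches:
        acc.extend(batch)
        pts = pool_trajectories(acc, discard_ms=opt.discard_ms)
        grid = estimate_pss(pts, edges=edges)
        if prev_grid is not None:
            sigma_history.append(convergence_sigma(prev_grid, grid))
            if sigma_history[-1] < opt.sigma_threshold:
                converged = True
        prev_grid = grid
    grid = prev_grid

    attractors = find_minima(grid, smooth=opt.smooth,
                             depth_threshold=opt.depth_threshold,
                             rate_threshold=opt.rate_threshold,
                             asym_threshold=opt.asym_threshold)
    domain = (edges[0][0], edges[0][-1], edges[1][0], edges[1][-1])
    fgrid = make_coarse_grid(all_pts, opt.flux_boxes, opt.flux_boxes, domain)
    flux = pooled_flux(trajs, grid=fgrid)

    man = _manifest("stationary_landscape", outdir,
                    config=config, stimulus=stimulus, seed=seed,
                    batch_trials=batch_trials, trial_ms=trial_ms,
                    max_batches=max_batches, options=opt,
                    external_trajectories=trajectories is not None,
                    converged=converged, sigma_history=sigma_history,
                    n_attractors=len(attractors),
                    attractor_labels=[m.label for m in attractors])
    if outdir is not None:
        grid.to_hdf5(Path(outdir) / "landscape.h5")
        flux.to_hdf5(Path(outdir) / "flux.h5")
    return StationaryLandscapeResult(grid, attractors, flux, trajs,
                                     sigma_history, converged, man)


# -- phased trials (staircases, decision pulses) -----------------------------


def run_phased_trial(config: NetworkConfig,
                     phases: Sequence[tuple[Optional[StimulusSpec], float]],
                     seed: int, window: float = 50.0, stride: float = 5.0,
                     network: Optional[Network] = None) -> RateTrajectory:
    """One continuous trial through a sequence of (stimulus, dwell_ms)
    phases; the network state carries over between phases."""
    net = network if network is not None else Network(config)
    _seed_numba(np.uint32(seed))
    state = net.init_state()
    ids, times = [], []
    total_ms = 0.0
    for stim, dwell_ms in phases:
        lam = net.external_rates(stim, state.t)
        steps = int(round(dwell_ms / config.dt))
        done = 0
        chunk = int(round(100.0 / config.dt))
        while done < steps:
            n = min(chunk, steps - done)
            t_base = state.t
            flags = net.step(state, n, lam=lam)
            st, nid = np.nonzero(flags)
            times.append(t_base + (st + 1) * config.dt)
            ids.append(nid)
            done += n
        total_ms += dwell_ms
    times = np.concatenate(times)
    ids = np.concatenate(ids)
    order = np.argsort(times, kind="stable")
    raster = SpikeRaster(ids[order].astype(np.int64), times[order],
                         net.pop.copy(), duration=total_ms)
    return compute_population_rates(raster, window, stride)


def run_staircase_trial(config: NetworkConfig, mu_levels: Sequence[float],
                        dwell_ms: float, seed: int, c: float = 0.0,
                        window: float = 50.0, stride: float = 5.0
                        ) -> tuple[RateTrajectory, np.ndarray]:
    """One continuous trial whose stimulus steps through mu_levels.

    Returns the rate trajectory and the per-sample level index.  The network
    state carries over between levels (that is the point: hysteresis).
    """
    traj = run_phased_trial(
        config, [(StimulusSpec(mu=mu, c=c), dwell_ms) for mu in mu_levels],
        seed, window, stride)
    level_idx = np.minimum((traj.t - 1e-9) // dwell_ms,
                           len(mu_levels) - 1).astype(int)
    return traj, level_idx


@dataclass
class PulsedCensusResult:
    attractors: AttractorSet
    grid: LandscapeGrid
    trajectories: list[RateTrajectory]


def pulsed_attractor_census(config: NetworkConfig, stimulus: StimulusSpec,
                            seed: int = 0, n_pulsed: int = 4,
                            n_rest: int = 2, trial_ms: float = 6000.0,
                            pulse_ms: float = 400.0, pulse_mu: float = 58.0,
                            pulse_c: float = 0.8,
                            settle_ms: float = 1500.0,
                            rest_settle_ms: float = 3000.0,
                            options: AnalysisOptions = AnalysisOptions()
                            ) -> PulsedCensusResult:
    """Attractor census by multi-initial-condition trials.

    Each trial is steered into a candidate state before the target stimulus
    is applied: half the pulsed trials get a brief strong stimulus biased
    toward S1 (coherence +pulse_c), half toward S2; the rest trials hold the
    unstimulated network at the spontaneous state first.  After the pulse
    the target stimulus runs for the remainder of the trial, and only
    samples past a settling period are pooled.  States that are not true
    attractors of the target stimulus decay and leave no basin; stable
    states accumulate occupancy.  The pooled landscape's minima are the
    census.
    """
    net = Network(config)
    trajs = []
    kept = []
    opt = options
    for k in range(n_pulsed + n_rest):
        if k < n_pulsed:
            sign = 1 if k % 2 == 0 else -1
            pulse = StimulusSpec(mu=pulse_mu, c=sign * pulse_c)
            discard = pulse_ms + settle_ms
        else:
            pulse = None
            discard = pulse_ms + rest_settle_ms
        traj = run_phased_trial(
            config, [(pulse, pulse_ms), (stimulus, trial_ms - pulse_ms)],
            seed=seed * 1000 + k, window=opt.window, stride=opt.stride,
            network=net)
        trajs.append(traj)
        kept.append(traj.points[traj.t >= discard])
    pts = np.vstack(kept)
    min_w = opt.min_bin_width or 1.5 * 1000.0 / (config.N_S1 * opt.window)
    edges = make_edges(pts, bins=opt.bins, min_width=min_w)
    grid = estimate_pss(pts, edges=edges)
    att = find_minima(grid, smooth=opt.smooth,
                      depth_threshold=opt.depth_threshold,
                      rate_threshold=opt.rate_threshold,
                      asym_threshold=opt.asym_threshold)
    return PulsedCensusResult(att, grid, trajs)


@dataclass
class RampResult:
    mu_levels: tuple
    up_path: pd.DataFrame      # per level: mean r1, r2 across trials
    down_path: pd.DataFrame
    layer_grids: dict          # (direction, mu) -> LandscapeGrid
    hysteresis: float          # mean |up - down| state distance per level
    manifest: dict


def run_ramp_hysteresis(config: NetworkConfig,
                        mu_levels: Sequence[float] = (5, 16, 40, 76, 90),
                        dwell_ms: float = 3000.0, n_trials: int = 4,
                        seed: int = 0, c: float = 0.0,
                        options: AnalysisOptions = AnalysisOptions(),
                        outdir=None) -> RampResult:
    """Staircase up-ramp and down-ramp with per-level landscapes.

    The 'continuously varied' stimulus is discretized as a staircase over
    mu_levels with a fixed dwell per level; the down-ramp traverses the same
    levels in reverse.  The averaged (r1, r2) state per level, compared
    between directions, is the hysteresis indicator.
    """
    mu_levels = tuple(mu_levels)
    paths = {}
    grids: dict = {}
    per_dir_level_means = {}
    for direction, levels in (("up", mu_levels), ("down", mu_levels[::-1])):
        rows = []
        level_samples = {mu: [] for mu in levels}
        for k in range(n_trials):
            traj, lidx = run_staircase_trial(
                config, levels, dwell_ms, seed=seed * 100 + k, c=c,
                window=options.window, stride=options.stride)
            for li, mu in enumerate(levels):
                m = (lidx == li) & (traj.t % dwell_ms >= options.discard_ms)
                level_samples[mu].append(traj.points[m])
        for mu in levels:
            pts = np.vstack(level_samples[mu])
            rows.append({"mu": mu, "r1": pts[:, 0].mean(),
                         "r2": pts[:, 1].mean(), "n": len(pts)})
            grids[(direction, mu)] = estimate_pss(pts, bins=options.bins)
        paths[direction] = pd.DataFrame(rows)
        per_dir_level_means[direction] = {
            row["mu"]: (row["r1"], row["r2"]) for row in rows}

    hyst = float(np.mean([
        np.hypot(per_dir_level_means["up"][mu][0] - per_dir_level_means["down"][mu][0],
                 per_dir_level_means["up"][mu][1] - per_dir_level_means["down"][mu][1])
        for mu in mu_levels]))
    man = _manifest("ramp_hysteresis", outdir, config=config,
                    mu_levels=mu_levels, dwell_ms=dwell_ms,
                    n_trials=n_trials, seed=seed, c=c, options=options,
                    hysteresis=hyst)
    if outdir is not None:
        paths["up"].to_csv(Path(outdir) / "ramp_up_path.csv", index=False)
        paths["down"].to_csv(Path(outdir) / "ramp_down_path.csv", index=False)
    return RampResult(mu_levels, paths["up"], paths["down"], grids, hyst, man)


def decision_regions(attractors: AttractorSet,
                     semi_axes: float = 5.0) -> dict[str, AttractorRegion]:
    """Elliptic regions for DS1 and DS2, mirroring across the diagonal when
    only one decision state was resolved as a landscape minimum.

    The circuit is symmetric under S1<->S2 at zero coherence (and nearly so
    at the few-percent coherences studied), so the unresolved decision
    state sits at the reflection of the resolved one.
    """
    regions: dict[str, AttractorRegion] = {}
    for label in ("DS1", "DS2"):
        try:
            m = attractors.get(label)
            regions[label] = AttractorRegion(label, m.position,
                                             (semi_axes, semi_axes))
        except KeyError:
            pass
    if "DS1" in regions and "DS2" not in regions:
        c = regions["DS1"].center
        regions["DS2"] = AttractorRegion("DS2", (c[1], c[0]),
                                         (semi_axes, semi_axes))
    elif "DS2" in regions and "DS1" not in regions:
        c = regions["DS2"].center
        regions["DS1"] = AttractorRegion("DS1", (c[1], c[0]),
                                         (semi_axes, semi_axes))
    if not regions:
        raise ValueError("no decision-state minimum resolved")
    return regions


def relative_barrier_ds(attractors: AttractorSet) -> float:
    """RB1 = BH1 - BH2 = U(DS2) - U(DS1) for the decision pair.

    The saddle cancels in the difference, so only the two minima enter.
    When one decision state is not resolved as a minimum, its potential is
    read off the (smoothed) landscape at the mirror position of the other
    (diagonal symmetry of the circuit); NaN if that bin was never visited.
    """
    grid = attractors.grid

    def u_at(label):
        try:
            return attractors.get(label).U, attractors.get(label).position
        except KeyError:
            return None, None

    u1, p1 = u_at("DS1")
    u2, p2 = u_at("DS2")
    if u1 is None and u2 is None:
        return np.nan
    if u1 is None or u2 is None:
        present_u, present_p = (u2, p2) if u1 is None else (u1, p1)
        mirror = (present_p[1], present_p[0])
        i = int(np.clip(np.searchsorted(grid.edges1, mirror[0]) - 1,
                        0, grid.shape[0] - 1))
        j = int(np.clip(np.searchsorted(grid.edges2, mirror[1]) - 1,
                        0, grid.shape[1] - 1))
        mirror_u = grid.U[i, j]
        if not np.isfinite(mirror_u):
            return np.nan
        if u1 is None:
            u1, u2 = mirror_u, present_u
        else:
            u2 = mirror_u
    return float(u2 - u1)


# -- coherence sweep ---------------------------------------------------------


@dataclass
class CoherenceSweepResult:
    table: pd.DataFrame            # per c: RB, MFPT, K, converged
    rb_monotone: bool
    spearman_rb_logmfpt: float
    manifest: dict


def run_coherence_sweep(config: NetworkConfig, mu: float,
                        c_values: Sequence[float],
                        pair: tuple[str, str] = ("DS1", "DS2"),
                        seed: int = 0, n_trials: int = 4,
                        trial_ms: float = 10_000.0,
                        options: AnalysisOptions = AnalysisOptions(),
                        outdir=None) -> CoherenceSweepResult:
    """Relative barrier height and MFPT as the coherence c varies.

    For each c the stationary landscape is estimated from pooled trials, the
    relative barrier RB = BH(pair[0]) - BH(pair[1]) is measured on it, and
    first-passage times pair[0] -> pair[1] are pooled over the trials.
    """
    rows = []
    for ci, c in enumerate(c_values):
        trajs = simulate_rate_trials(config, StimulusSpec(mu=mu, c=c),
                                     n_trials, trial_ms,
                                     seed=seed * 100 + ci,
                                     window=options.window,
                                     stride=options.stride)
        res = run_stationary_landscape(trajectories=trajs, options=options)
        row = {"c": c, "n_attractors": res.n_attractors,
               "converged": res.converged,
               "RB": np.nan, "mfpt_s": np.nan, "K": 0}
        try:
            bm = barrier_metrics(res.attractors.grid, res.attractors, pair)
            row["RB"] = bm.RB
            regions = {r.label: r for r in define_regions(
                res.attractors, options.region_semi_axes)}
            fpt = pooled_first_passage_times(trajs, regions[pair[0]],
                                             regions[pair[1]])
            row["mfpt_s"] = fpt.mfpt
            row["K"] = fpt.K
        except (KeyError, ValueError) as err:
            row["error"] = str(err)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["RB", "mfpt_s"])
    rb_monotone = bool(np.all(np.diff(table["RB"].to_numpy()) > 0)) \
        if table["RB"].notna().all() else False
    if len(ok) >= 3:
        rho = float(stats.spearmanr(ok["RB"], np.log(ok["mfpt_s"])).statistic)
    else:
        rho = np.nan
    man = _manifest("coherence_sweep", outdir, config=config, mu=mu,
                    c_values=list(c_values), pair=pair, seed=seed,
                    n_trials=n_trials, trial_ms=trial_ms, options=options,
                    rb_monotone=rb_monotone, spearman=rho)
    if outdir is not None:
        table.to_csv(Path(outdir) / "coherence_sweep.csv", index=False)
    return CoherenceSweepResult(table, rb_monotone, rho, man)


# -- parameter census --------------------------------------------------------


@dataclass
class CensusResult:
    table: pd.DataFrame            # per (w_plus, mu): attractor count, labels
    count_vs_wplus_spearman: float
    max_attractors: int
    manifest: dict


def run_parameter_census(base_config: NetworkConfig,
                         w_plus_values: Sequence[float],
                         mu_values: Sequence[float],
                         seed: int = 0, n_trials: int = 4,
                         trial_ms: float = 8000.0,
                         options: AnalysisOptions = AnalysisOptions(),
                         outdir=None) -> CensusResult:
    """Attractor count over the (w_plus, mu) plane.

    Each cell pools `n_trials` independent trials (different initial Poisson
    realizations double as different initial conditions, since every trial
    starts at rest and decides stochastically) and counts landscape minima.
    The summary statistic is the Spearman correlation between w_plus and the
    attractor count at fixed mu, averaged over mu values.
    """
    rows = []
    for wi, w in enumerate(w_plus_values):
        for mi, mu in enumerate(mu_values):
            cfg = base_config.with_(w_plus=w)
            trajs = simulate_rate_trials(cfg, StimulusSpec(mu=mu),
                                         n_trials, trial_ms,
                                         seed=seed * 1000 + wi * 29 + mi,
                                         window=options.window,
                                         stride=options.stride)
            res = run_stationary_landscape(trajectories=trajs,
                                           options=options)
            rows.append({"w_plus": w, "mu": mu,
                         "n_attractors": res.n_attractors,
                         "labels": ",".join(str(m.label)
                                            for m in res.attractors)})
    table = pd.DataFrame(rows)
    rhos = []
    for mu in mu_values:
        sub = table[table["mu"] == mu]
        if sub["n_attractors"].nunique() > 1:
            rhos.append(stats.spearmanr(sub["w_plus"],
                                        sub["n_attractors"]).statistic)
    rho = float(np.mean(rhos)) if rhos else np.nan
    man = _manifest("parameter_census", outdir, config=base_config,
                    w_plus_values=list(w_plus_values),
                    mu_values=list(mu_values), seed=seed,
                    n_trials=n_trials, trial_ms=trial_ms, options=options,
                    spearman=rho)
    if outdir is not None:
        table.to_csv(Path(outdir) / "census.csv", index=False)
    return CensusResult(table, rho, int(table["n_attractors"].max()), man)
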