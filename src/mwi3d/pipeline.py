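"""End-to-end orchestration: generate -> simulate -> invert -> train -> evaluate.

Two compute profiles are provided.  The ``full`` profile mirrors the
reference study conditions (600 phantoms, 3-D 64^3 volumes, 500 CSI
iterations per frequency, a depth-4/32-filter U-Net trained for 200
epochs) and is intended for long batch runs.  The ``scaled`` profile is
the desk-scale configuration used by the test-suite and the worked
examples: a 2-D TM slice of the same geometry (32^2 inversion grid, 64^2
forward grid, 100 CSI iterations, a depth-2/8-filter U-Net, 20 epochs,
~60 phantoms), chosen so a complete study runs in minutes on one CPU.

Robustness scenarios regenerate only test data (off-band frequencies,
smaller fibroglandular region, imperfect prior permittivity, tumor-free
phantom) and reuse the baseline-trained network.

Forward data is always simulated on a grid twice as fine as the
inversion grid, so the inversion never sees data produced by its own
discretization (inverse-crime avoidance).  Because all phantoms of a run
share the tumor-free breast geometry, the background part of each
forward system is factorized once per frequency and each phantom is
solved with an exact low-rank (Woodbury) update over its tumor voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .csi import DistortedOperators, ReconstructionStack, csi_run
from .detection import compare_methods, threshold_detect, intersection_score
from .forward import (AIR_EPS, DEFAULT_FREQUENCIES, FieldDataSet, ProbeArray,
                      ScatteringOperators, add_noise, default_probes)
from .grids import VoxelGrid
from .phantoms import (TUMOR, PermittivityVolume, PhantomSpec, TissueTable,
                       generate_dataset)
from .unet import (NetworkConfig, TrainConfig, crossvalidate, predict,
                   stack_channels)

__all__ = [
    "Profile",
    "SCALED",
    "FULL",
    "RunConfig",
    "SCENARIOS",
    "ForwardCache",
    "simulate_phantom_data",
    "make_fixture_suite",
    "run_scenario",
]


@dataclass(frozen=True)
class Profile:
    """Compute-scale parameters shared by every stage of a run."""

    name: str
    ndim: int
    grid_shape: tuple
    spacing: float
    fine_factor: int
    probe_radius: float
    csi_iterations: int
    csi_dtype: str
    net: NetworkConfig
    train: TrainConfig
    n_phantoms: int


SCALED = Profile(
    name="scaled", ndim=2, grid_shape=(32, 32), spacing=3.3e-3,
    fine_factor=2, probe_radius=0.06, csi_iterations=100,
    csi_dtype="complex64",
    net=NetworkConfig(depth=2, kernel=3, base_filters=8, in_channels=10),
    train=TrainConfig(batch_size=10, epochs=20, folds=4),
    n_phantoms=60)

FULL = Profile(
    name="full", ndim=3, grid_shape=(64, 64, 64), spacing=3.3e-3,
    fine_factor=2, probe_radius=0.06, csi_iterations=500,
    csi_dtype="complex128",
    net=NetworkConfig(depth=4, kernel=3, base_filters=32, in_channels=10),
    train=TrainConfig(batch_size=10, epochs=200, folds=4),
    n_phantoms=600)

_PROFILES = {"scaled": SCALED, "full": FULL}

# scenario tag -> overrides applied on top of the baseline run
SCENARIOS = {
    "baseline": {},
    "offband_freqs": {
        "frequencies": tuple(f * 1e9 for f in (1.05, 1.15, 1.25, 1.35, 1.45))},
    "highband_freqs": {
        "frequencies": tuple(f * 1e9 for f in (2.5, 2.6, 2.7, 2.8, 2.9))},
    "small_fibro": {"fibro_height_delta": 0.009},
    "prior_error_10": {"fibro_error_frac": 0.10},
    "no_tumor_prior_error_5": {"fibro_error_frac": 0.05, "n_tumors": 0},
}


@dataclass(frozen=True)
class RunConfig:
    """One run: a profile, a scenario tag, and the master seed."""

    profile: str = "scaled"
    scenario: str = "baseline"
    seed: int = 0
    n_phantoms: int | None = None
    noise_level: float = 0.05
    frequencies: tuple = DEFAULT_FREQUENCIES
    fibro_error_frac: float = 0.0
    fibro_height_delta: float = 0.0
    n_tumors: int | None = None
    threshold_frac: float = 0.85

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"known: {sorted(SCENARIOS)}")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    def resolved(self) -> "RunConfig":
        """Apply the scenario's documented parameter overrides."""
        return replace(self, **SCENARIOS[self.scenario])

    @property
    def prof(self) -> Profile:
        return _PROFILES[self.profile]


def _upsample(values: np.ndarray, factor: int) -> np.ndarray:
    out = values
    for ax in range(values.ndim):
        out = np.repeat(out, factor, axis=ax)
    return out


class ForwardCache:
    """Shared-background forward solver for one frequency.

    Factorizes the volume-integral system of the tumor-free breast once;
    each phantom differs from it only at its tumor voxels, so its total
    fields follow from an exact rank-t Woodbury update.  Masks too large
    to factorize densely (the 3-D full profile) fall back to an
    FFT-accelerated iterative solve per phantom.
    """

    def __init__(self, background: PermittivityVolume, probes: ProbeArray,
                 freq: float, embedding_eps: complex = AIR_EPS,
                 dense_limit: int = 12000):
        grid = background.grid
        eps_b = complex(embedding_eps)
        self.eps_b = eps_b
        self.grid = grid
        self.ops = ScatteringOperators(grid, probes, freq, eps_b)
        chi_n_full = (background.values - eps_b) / eps_b
        self.mask = np.abs(chi_n_full) > 1e-12
        n = int(self.mask.sum())
        self.dense = n <= dense_limit
        self.chi_n = chi_n_full[self.mask]
        self._flat = np.flatnonzero(self.mask.ravel())
        self.gs = self.ops.gs_matrix(self.mask)
        if self.dense:
            self.a = self.ops.dense_gd(self.mask)
            b0 = np.eye(n, dtype=np.complex128) - self.a * self.chi_n[None, :]
            self.lu = lu_factor(b0, overwrite_a=True)
            self.e0 = lu_solve(self.lu, self.ops.incident(self.mask))

    def phantom_data(self, eps: PermittivityVolume) -> FieldDataSet:
        """Noiseless scattered data (relative to air) for one phantom."""
        chi_full = ((eps.values - self.eps_b) / self.eps_b)
        chi = chi_full.ravel()[self._flat]
        if self.dense:
            delta = chi - self.chi_n
            tcols = np.flatnonzero(np.abs(delta) > 1e-12)
            if len(tcols) == 0:
                x = self.e0
            else:
                u = self.a[:, tcols] * delta[tcols][None, :]
                y = lu_solve(self.lu, u)
                s = np.eye(len(tcols), dtype=np.complex128) - y[tcols]
                w = np.linalg.solve(s, self.e0[tcols])
                x = self.e0 + y @ w
        else:
            from .forward import _solve_masked
            e_inc = self.ops.incident(self.mask)
            x = _solve_masked(self.ops, chi, self.mask, e_inc,
                              tol=1e-6, maxiter=2000, dense_limit=0)
        d = (self.gs @ (chi[:, None] * x)).T
        np.fill_diagonal(d, 0.0)
        return FieldDataSet(frequency=self.ops.freq, matrix=d)


def simulate_phantom_data(eps_fine: PermittivityVolume, caches: dict,
                          noise_level: float, rng: np.random.Generator):
    """Noisy multistatic data at every cached frequency for one phantom."""
    out = []
    for freq in sorted(caches):
        d = caches[freq].phantom_data(eps_fine)
        out.append(add_noise(d, noise_level, rng) if noise_level > 0 else d)
    return out


def make_fixture_suite(config: RunConfig | None = None,
                       progress: bool = False) -> dict:
    """Generate phantoms, simulate data, and run CSI for a whole run.

    Returns a dict with parallel lists over phantoms (``tissues``,
    ``stacks`` as complex (F, spatial...) arrays, ``targets`` as real
    ground-truth permittivity), the shared breast-interior ``region``,
    the stacked network inputs ``x`` / targets ``y``, and the manifest.
    Deterministic given the config (one master seed drives phantom
    geometry and measurement noise).
    """
    cfg = (config or RunConfig()).resolved()
    prof = cfg.prof
    grid = VoxelGrid(prof.grid_shape, prof.spacing)
    fine = grid.refine(prof.fine_factor)
    probes = default_probes(prof.ndim, prof.probe_radius)
    n = cfg.n_phantoms or prof.n_phantoms
    table = TissueTable()

    ss = np.random.SeedSequence(cfg.seed)
    seed_phantoms, seed_noise = (int(s.generate_state(1)[0] % 2**31)
                                 for s in ss.spawn(2))
    spec = PhantomSpec(grid=grid, fibro_height_delta=cfg.fibro_height_delta)
    items, manifest = generate_dataset(n, spec, seed_phantoms, table,
                                       cfg.fibro_error_frac,
                                       n_tumors=cfg.n_tumors)
    background = items[0]["background"]  # tumor-free prior, shared by all

    # forward simulation on the refined grid, one frequency at a time
    air_fine = complex(AIR_EPS)
    noise_rngs = [np.random.default_rng(s) for s in
                  np.random.SeedSequence(seed_noise).spawn(n)]
    data_per_phantom = [[] for _ in range(n)]
    for freq in cfg.frequencies:
        bg_fine = PermittivityVolume(
            fine, _upsample(background.values, prof.fine_factor))
        cache = ForwardCache(bg_fine, probes, freq, air_fine)
        for i, item in enumerate(items):
            eps_fine = PermittivityVolume(
                fine, _upsample(item["eps"].values, prof.fine_factor))
            d = cache.phantom_data(eps_fine)
            if cfg.noise_level > 0:
                d = add_noise(d, cfg.noise_level, noise_rngs[i])
            data_per_phantom[i].append(d)
        del cache
        if progress:
            print(f"simulated {freq / 1e9:.2f} GHz")

    # CSI per frequency with operators shared across phantoms
    dtype = np.dtype(prof.csi_dtype)
    stacks = [np.empty((len(cfg.frequencies), *grid.shape), dtype=complex)
              for _ in range(n)]
    for fi, freq in enumerate(cfg.frequencies):
        ops = DistortedOperators(background, probes, freq, dtype=dtype)
        for i in range(n):
            res = csi_run(data_per_phantom[i][fi], background, probes,
                          prof.csi_iterations, operators=ops, dtype=dtype)
            stacks[i][fi] = res.eps.values
        del ops
        if progress:
            print(f"inverted {freq / 1e9:.2f} GHz")

    region = items[0]["tissue"].interior_mask()
    targets = [item["eps"].values.real for item in items]
    x = np.stack([
        stack_channels(ReconstructionStack(grid=grid,
                                           frequencies=tuple(cfg.frequencies),
                                           volumes=st))
        for st in stacks])
    y = np.stack(targets)[:, None]
    manifest = {"config": {
        "profile": prof.name, "scenario": cfg.scenario, "seed": cfg.seed,
        "n_phantoms": n, "noise_level": cfg.noise_level,
        "frequencies_hz": list(cfg.frequencies),
        "fibro_error_frac": cfg.fibro_error_frac,
        "fibro_height_delta": cfg.fibro_height_delta,
        "csi_iterations": prof.csi_iterations,
    }, "phantoms": manifest["phantoms"]}
    return {"grid": grid, "probes": probes, "items": items,
            "tissues": [it["tissue"] for it in items],
            "background": background, "stacks": stacks, "targets": targets,
            "region": region, "x": x, "y": y,
            "frequencies": tuple(cfg.frequencies), "manifest": manifest}


def run_scenario(config: RunConfig, baseline: dict | None = None,
                 progress: bool = False) -> dict:
    """Execute one scenario end to end and evaluate detection.

    The baseline scenario trains the network by cross validation and
    evaluates the pooled out-of-fold predictions.  Robustness scenarios
    reuse the baseline-trained models (pass the baseline result, or it is
    recomputed) and only regenerate test data under the scenario's
    overrides; each test phantom is predicted by the first fold's model.
    """
    cfg = config.resolved()
    prof = cfg.prof
    if cfg.scenario == "baseline":
        suite = baseline or make_fixture_suite(cfg, progress)
        train_cfg = replace(prof.train, seed=cfg.seed)
        cv = crossvalidate(suite["x"], suite["y"], prof.net, train_cfg,
                           ndim=prof.ndim)
        preds = [_mask_to_air(p[0], suite["region"])
                 for p in cv["predictions"]]
        report = _evaluate(suite, preds, cfg)
        return {"scenario": cfg.scenario, "suite": suite, "cv": cv,
                "predictions": preds, "report": report,
                "manifest": {**suite["manifest"], "cv": cv["manifest"]}}

    if baseline is None:
        baseline = run_scenario(replace(cfg, scenario="baseline"),
                                progress=progress)
    n_test = cfg.n_phantoms or max(6, prof.n_phantoms // 10)
    test_cfg = replace(cfg, n_phantoms=n_test,
                       seed=cfg.seed + 104729)  # fresh phantoms, same law
    suite = make_fixture_suite(test_cfg, progress)
    model = baseline["cv"]["models"][0]
    preds = [_mask_to_air(predict(model, xi)[0], suite["region"])
             for xi in suite["x"]]
    report = _evaluate(suite, preds, cfg)
    return {"scenario": cfg.scenario, "suite": suite, "predictions": preds,
            "report": report,
            "manifest": {**suite["manifest"],
                         "baseline_cv": baseline["cv"]["manifest"]}}


def _mask_to_air(pred: np.ndarray, region: np.ndarray,
                 air_re: float = 1.0) -> np.ndarray:
    """Fix predictions to the air permittivity outside the imaging mask.

    The breast-interior mask is prior knowledge used identically by the
    inversion; the network output is only meaningful inside it.
    """
    out = np.asarray(pred).copy()
    out[~region] = air_re
    return out


def _evaluate(suite: dict, preds, cfg: RunConfig):
    """Detection report, or a false-positive summary for tumor-free runs."""
    labels = [t.labels for t in suite["tissues"]]
    region = [suite["region"]] * len(labels)
    has_tumor = any((lab == TUMOR).any() for lab in labels)
    if has_tumor:
        return compare_methods(suite["stacks"], preds, labels, TUMOR,
                               region, suite["frequencies"],
                               cfg.threshold_frac)
    # no ground-truth tumor: every detected voxel is a false positive
    fp = {"cnn": [], "csi_intersection": []}
    for st, p in zip(suite["stacks"], preds):
        inter = intersection_score([st[fi].real for fi in range(st.shape[0])],
                                   suite["region"])
        fp["csi_intersection"].append(
            threshold_detect(inter, cfg.threshold_frac, suite["region"]).count)
        fp["cnn"].append(
            threshold_detect(np.asarray(p), cfg.threshold_frac,
                             suite["region"]).count)
    return {"false_positive_voxels": fp}
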