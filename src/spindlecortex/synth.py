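"""Synthetic fluorescence "experiments" with known ground truth.

Every generator runs the forward model, samples it at a realistic frame
interval (the live imaging used 2, 3 or 5 min), applies a simple
fluorescence noise model (multiplicative Gaussian on the signal plus an
additive Gaussian background, clamped at zero) and returns the noisy data
together with a ground-truth manifest. Quantification stages consume only
the data, never the manifest, so parameter-recovery tests are honest.

All randomness derives deterministically from the seeds given: the same
seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from . import io
from .containers import Kymograph, Trajectory
from .cortex import LgnKinetics
from .geometry import DnaRegion, Domain1D
from .orientation import OrientationResult, RoundingSchedule, SpindleState2D, \
    run_orientation
from .spindle1d import MicrotubuleModel, MonopolarSpindle, SimulationResult1D, \
    simulate_monopolar, simulate_on_line


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative + additive Gaussian fluorescence noise, clamped at 0."""

    mult_sd: float = 0.1       # fraction of the signal
    background_mean: float = 0.05
    background_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.mult_sd, self.background_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = (signal * (1.0 + self.mult_sd * rng.standard_normal(signal.shape))
                 + self.background_mean
                 + self.background_sd * rng.standard_normal(signal.shape))
        return np.maximum(noisy, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Population of synthetic cells with per-cell parameter jitter."""

    n_cells: int = 12
    v0_mean: float = 6.7        # μm/min, population mean
    v0_sd: float = 6.7          # μm/min, population SD (draws truncated at 0)
    length_range: tuple[float, float] = (60.0, 100.0)
    frame_intervals: tuple[float, ...] = (2.0, 3.0, 5.0)
    T: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if any(f not in (2.0, 3.0, 5.0) for f in self.frame_intervals):
            raise ValueError("frame intervals must be from {2, 3, 5} min")


@dataclass
class Dataset:
    """A synthetic acquisition: noisy kymograph, DNA track, ground truth."""

    kymograph: Kymograph
    trajectory: Trajectory
    truth: dict = field(default_factory=dict)
    result: SimulationResult1D | None = None

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        io.write_kymograph(self.kymograph, d / "kymograph.tsv")
        io.write_track(self.trajectory, d / "dna_track.tsv")
        io.write_manifest(self.truth, d / "truth.yaml")


@dataclass
class RoundingDataset:
    """A synthetic rounding cell: contour kymograph, shape series, angle track."""

    contour_kymograph: np.ndarray   # (n_nodes, n_frames), noisy
    t: np.ndarray
    axes: np.ndarray                # (n_frames, 2)
    angle_track: Trajectory
    truth: dict = field(default_factory=dict)
    result: OrientationResult | None = None

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        kymo = pd.DataFrame(self.contour_kymograph, columns=self.t)
        kymo.index.name = "node"
        kymo.to_csv(d / "contour_kymograph.tsv", sep="\t",
                    float_format=io.FLOAT_FMT)
        io.write_table(
            pd.DataFrame({"t_min": self.t, "a_long_um": self.axes[:, 0],
                          "b_short_um": self.axes[:, 1]}),
            d / "shape.tsv")
        io.write_track(self.angle_track, d / "angle_track.tsv",
                       columns=("phi_rad",))
        io.write_manifest(self.truth, d / "truth.yaml")


def _simulate_and_corrupt(result: SimulationResult1D, noise: NoiseModel,
                          seed: int, truth: dict) -> Dataset:
    rng = np.random.default_rng(seed)
    clean = result.kymograph
    noisy = noise.apply(clean.intensity, rng)
    kymo = Kymograph(clean.x, clean.t, noisy, clean.dna_center,
                     clean.dna_half_extent, "raw")
    traj = Trajectory(result.t, result.xn)
    truth = dict(truth, seed=seed, noise_mult_sd=noise.mult_sd,
                 noise_bg_mean=noise.background_mean,
                 noise_bg_sd=noise.background_sd,
                 asymptotic_speed=result.asymptotic_speed,
                 regime=result.regime, n_reversals=result.n_reversals)
    return Dataset(kymo, traj, truth, result)


def make_monopolar_dataset(
    kinetics: LgnKinetics | None = None,
    spindle: MonopolarSpindle | None = None,
    mt: MicrotubuleModel | None = None,
    domain: Domain1D | None = None,
    noise: NoiseModel | None = None,
    frame_interval: float = 3.0,
    T: float = 120.0,
    dt: float = 0.05,
    seed: int = 0,
    dna: DnaRegion | None = None,
) -> Dataset:
    """Synthetic monopolar acquisition (flat-cell, periodic path)."""
    kinetics = kinetics or LgnKinetics()
    domain = domain or Domain1D(80.0, periodic=True)
    spindle = spindle or MonopolarSpindle(dna_center=domain.length / 2)
    mt = mt or MicrotubuleModel.exponential()
    noise = noise or NoiseModel()
    result = simulate_monopolar(
        kinetics, spindle, mt, domain, T=T, dt=dt, seed=seed, dna=dna,
        sample_interval=frame_interval,
    )
    truth = dict(result.params, model="monopolar", v0=spindle.v0,
                 D=kinetics.D, koff_near=kinetics.koff_near,
                 koff_far=kinetics.koff_far, frame_interval=frame_interval,
                 domain_length=domain.length)
    return _simulate_and_corrupt(result, noise, seed, truth)


def make_line_dataset(
    line_length: float = 60.0,
    kinetics: LgnKinetics | None = None,
    spindle: MonopolarSpindle | None = None,
    mt: MicrotubuleModel | None = None,
    noise: NoiseModel | None = None,
    frame_interval: float = 3.0,
    T: float = 450.0,
    dt: float = 0.05,
    seed: int = 0,
    dna: DnaRegion | None = None,
) -> Dataset:
    """Synthetic acquisition of a cell on a micropatterned line."""
    kinetics = kinetics or LgnKinetics()
    domain = Domain1D(line_length, periodic=False)
    spindle = spindle or MonopolarSpindle(dna_center=line_length / 2)
    mt = mt or MicrotubuleModel.exponential()
    noise = noise or NoiseModel()
    result = simulate_on_line(
        kinetics, spindle, mt, domain, T=T, dt=dt, seed=seed, dna=dna,
        sample_interval=frame_interval,
    )
    truth = dict(result.params, model="line", v0=spindle.v0,
                 line_length=line_length, frame_interval=frame_interval)
    return _simulate_and_corrupt(result, noise, seed, truth)


def make_rounding_dataset(
    schedule: RoundingSchedule | None = None,
    kinetics: LgnKinetics | None = None,
    mt: MicrotubuleModel | None = None,
    spindle_template: SpindleState2D | None = None,
    noise: NoiseModel | None = None,
    phi0_list: tuple[float, ...] = (0.0,),
    lgn_scale: float = 1.0,
    frame_interval: float = 1.0,
    T: float = 49.0,
    seed: int = 0,
    **run_kwargs,
) -> list[RoundingDataset]:
    """Synthetic rounding cells: one orientation run per initial spindle angle.

    Noise is applied to the contour intensities only; the shape series and
    angle track are reported noise-free (they come from segmentation and
    manual tracking in the real pipeline, with errors of a different kind).
    """
    schedule = schedule or RoundingSchedule()
    kinetics = kinetics or LgnKinetics()
    mt = mt or MicrotubuleModel.exponential()
    noise = noise or NoiseModel()
    seeds = np.random.SeedSequence(seed).spawn(len(phi0_list))
    out = []
    for phi0, child in zip(phi0_list, seeds):
        template = spindle_template or SpindleState2D(phi=0.0)
        from dataclasses import replace
        state0 = replace(template, phi=float(phi0))
        res = run_orientation(schedule, state0, kinetics, mt,
                              lgn_scale=lgn_scale, T=T,
                              sample_interval=frame_interval, **run_kwargs)
        rng = np.random.default_rng(child)
        noisy = noise.apply(res.kymograph, rng)
        out.append(RoundingDataset(
            contour_kymograph=noisy, t=res.t, axes=res.axes,
            angle_track=Trajectory(res.t, res.phi),
            truth=dict(res.params, phi0=float(phi0), model="rounding",
                       regime=res.regime,
                       seed_entropy=int(child.entropy),
                       final_alignment=float(res.a[-1])),
            result=res,
        ))
    return out


@dataclass
class Cohort:
    """A set of per-cell synthetic acquisitions plus the cohort manifest."""

    cells: list[Dataset]
    manifest: list[dict]

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        for i, cell in enumerate(self.cells):
            cell.write(d / f"cell_{i:03d}")
        io.write_table(pd.DataFrame(self.manifest), d / "cohort_index.tsv")


def draw_cohort_parameters(spec: CohortSpec):
    """Per-cell parameter draws for a cohort (deterministic in the seed).

    v0 comes from a normal with the spec's mean and SD truncated at 0 (the
    population SD equals the mean, so negatives must be excluded); domain
    lengths are uniform over the spec's range; frame intervals are drawn
    from the allowed set; per-cell seeds derive from the master seed.
    """
    master = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    a = (0.0 - spec.v0_mean) / spec.v0_sd
    v0s = truncnorm.rvs(a, np.inf, loc=spec.v0_mean, scale=spec.v0_sd,
                        size=spec.n_cells, random_state=rng)
    lengths = rng.uniform(*spec.length_range, size=spec.n_cells)
    intervals = rng.choice(spec.frame_intervals, size=spec.n_cells)
    cell_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in master.spawn(spec.n_cells + 1)[1:]]
    return v0s, lengths, intervals, cell_seeds


def make_cohort(
    spec: CohortSpec | None = None,
    kinetics: LgnKinetics | None = None,
    mt: MicrotubuleModel | None = None,
    noise: NoiseModel | None = None,
    dt: float = 0.05,
) -> Cohort:
    """Population of monopolar cells with per-cell v0 and geometry jitter."""
    spec = spec or CohortSpec()
    kinetics = kinetics or LgnKinetics()
    mt = mt or MicrotubuleModel.exponential()
    noise = noise or NoiseModel()
    v0s, lengths, intervals, cell_seeds = draw_cohort_parameters(spec)
    cells, manifest = [], []
    for i in range(spec.n_cells):
        domain = Domain1D(float(lengths[i]), periodic=True)
        spindle = MonopolarSpindle(dna_center=domain.length / 2,
                                   v0=float(v0s[i]))
        ds = make_monopolar_dataset(
            kinetics, spindle, mt, domain, noise,
            frame_interval=float(intervals[i]), T=spec.T, dt=dt,
            seed=cell_seeds[i],
        )
        cells.append(ds)
        manifest.append({"cell": i, "v0": float(v0s[i]),
                         "domain_length": float(lengths[i]),
                         "frame_interval": float(intervals[i]),
                         "seed": cell_seeds[i]})
    return Cohort(cells, manifest)
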