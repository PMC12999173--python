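"""End-to-end benchmark scenarios built entirely from the synthetic generator.

These functions wire the full pipeline together for self-contained
evaluation runs: simulate a bead stack and extract the PSF from it, render
a spot field blurred by that PSF with shot noise, deconvolve, and sweep the
detection parameters against the known ground truth.  The dense scenario
emulates a Kenyon-cell-like density regime (~0.13 clusters/um^3, hard-core
0.35 um, peak SNR ~ 10); the sparse scenario a DPM/APL-like regime of
well-separated puncta.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .benchmark import SweepResult, parameter_sweep
from .core import PointSpreadFunction, VolumetricImage
from .psf import DEFAULT_RL_ITERATIONS, extract_psf, richardson_lucy
from .synthetic import Layout, SyntheticSpec, dense_spec, render_stack, simulate, sparse_spec

#: optical blur assumed by the simulated microscope (um)
MICROSCOPE_SIGMA_XY = 0.08
MICROSCOPE_SIGMA_Z = 0.35


@dataclass
class BenchmarkRun:
    sweep: SweepResult
    n_truth: int
    noise_floor: float
    median_peak: float
    psf: PointSpreadFunction


def simulated_psf(spacing, seed: int, n_beads: int = 4) -> PointSpreadFunction:
    """Extract a PSF from a simulated bead stack (beads are sub-resolution,
    so their image is the optical blur itself)."""
    shape = (48, 128, 128)
    spec = SyntheticSpec(shape=shape, spacing=spacing, noise_model="none",
                         background=0.0, layout=Layout(names=("roi",)), seed=seed)
    dz, dy, dx = spacing
    rng = np.random.default_rng([seed, 91])
    # beads on a coarse grid, jittered by whole voxels: all isolated
    positions = []
    for i in range(n_beads):
        ix = 24 + (i % 2) * 64 + int(rng.integers(-4, 5))
        iy = 32 + (i // 2) * 64 + int(rng.integers(-4, 5))
        iz = 24 + int(rng.integers(-2, 3))
        positions.append((ix * dx, iy * dy, iz * dz))
    marks = pd.DataFrame({
        "intensity": [50000.0] * n_beads,
        "sigma_xy_um": [MICROSCOPE_SIGMA_XY] * n_beads,
        "sigma_z_um": [MICROSCOPE_SIGMA_Z] * n_beads,
        "compartment": ["roi"] * n_beads,
    })
    stack, _ = render_stack(np.asarray(positions), marks, spec, quantize=False)
    return extract_psf(VolumetricImage(stack.data, spacing),
                       crop_size=(21, 32, 32), isolation_radius_um=2.0,
                       min_peak=100.0)


def _detection_grid(deconvolved: np.ndarray, truth: pd.DataFrame, spacing,
                    n: int) -> tuple[np.ndarray, float, float]:
    """n sweep levels spanning the noise floor (median + 5 MAD of the
    deconvolved stack) to the median ground-truth peak height."""
    med = float(np.median(deconvolved))
    mad = float(np.median(np.abs(deconvolved - med)))
    floor = med + 5.0 * mad
    dz, dy, dx = spacing
    iz = np.clip(np.rint(truth["z_um"] / dz).astype(int), 0, deconvolved.shape[0] - 1)
    iy = np.clip(np.rint(truth["y_um"] / dy).astype(int), 0, deconvolved.shape[1] - 1)
    ix = np.clip(np.rint(truth["x_um"] / dx).astype(int), 0, deconvolved.shape[2] - 1)
    median_peak = float(np.median(deconvolved[iz, iy, ix]))
    return np.linspace(floor, median_peak, n), floor, median_peak


def detection_benchmark(spec: SyntheticSpec, seed: int, grid_size: int = 6,
                        rl_iterations: int = DEFAULT_RL_ITERATIONS,
                        match_tolerance_um: float = 0.3) -> BenchmarkRun:
    """Simulate -> extract PSF -> blur + noise -> deconvolve -> sweep.

    The sweep covers a ``grid_size x grid_size`` grid of (threshold, noise
    tolerance) levels spanning the noise floor to the median peak height of
    the deconvolved stack, and scores detected maxima against ground truth
    one-to-one within ``match_tolerance_um``.
    """
    spec = replace(spec, seed=seed)
    psf = simulated_psf(spec.spacing, seed)
    stack, truth, _ = simulate(spec, psf=psf)
    deconvolved = richardson_lucy(
        VolumetricImage(stack.data.astype(float), stack.spacing), psf,
        rl_iterations)
    grid, floor, median_peak = _detection_grid(deconvolved.data, truth,
                                               spec.spacing, grid_size)
    sweep = parameter_sweep(deconvolved, truth[["x_um", "y_um", "z_um"]].to_numpy(),
                            grid, grid, match_tolerance=match_tolerance_um)
    return BenchmarkRun(sweep=sweep, n_truth=len(truth), noise_floor=floor,
                        median_peak=median_peak, psf=psf)


def dense_benchmark(seed: int = 1, **kw) -> BenchmarkRun:
    return detection_benchmark(dense_spec(), seed, **kw)


def sparse_benchmark(seed: int = 1, **kw) -> BenchmarkRun:
    return detection_benchmark(sparse_spec(), seed, **kw)
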