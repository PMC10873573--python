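"""Seeded end-to-end benchmark experiments.

Scaled-down versions of the three simulation studies the method is
validated on: the sparseness-target (spH) sweep, the intensity-ratio
robustness sweep, and the fluorophore-count sweep, each on strip-phantom
datasets in the determined system (as many channels as fluorophores).
Every experiment is a pure function of its seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, evaluate
from .solver import FactorizationResult, SolverConfig, bingo_unmix, random_nmf
from .synthetic import Phantom, default_config, make_dataset, strip_phantom

__all__ = [
    "run_once",
    "sph_sweep",
    "intensity_sweep",
    "count_sweep",
]

DEFAULT_SIZE = 60  # phantom side length (pixels) for the 3-color studies


def run_once(
    r: int,
    seed: int,
    *,
    size: int = DEFAULT_SIZE,
    noise_sigma: float = 0.02,
    shift_nm: float = 3.0,
    intensity_scales: tuple[float, ...] | None = None,
    solver: SolverConfig | None = None,
    algorithm: str = "bingo",
) -> tuple[FactorizationResult, MetricsReport]:
    """Simulate one strip dataset and unmix it with the chosen algorithm
    ("bingo" or the random-init no-penalty "nnmf" comparator)."""
    config = default_config(
        r,
        rng_seed=seed,
        noise_sigma=noise_sigma,
        shift_nm=shift_nm,
        intensity_scales=intensity_scales,
    )
    phantom = strip_phantom(r, size, size)
    stack, mixing = make_dataset(config, phantom)
    if algorithm == "bingo":
        result = bingo_unmix(stack, r, solver or SolverConfig())
    elif algorithm == "nnmf":
        result = random_nmf(stack, r, seed=seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return result, evaluate(result, phantom, mixing)


def sph_sweep(
    sp_values: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1)),
    seed: int = 0,
    *,
    r: int = 3,
    size: int = DEFAULT_SIZE,
    noise_sigma: float = 0.02,
    shift_nm: float = 3.0,
) -> pd.DataFrame:
    """RMSE / SAD / SSIM / Dice of the solver as the sparseness target spH
    varies on one 3-color high-overlap dataset."""
    rows = []
    for sp in sp_values:
        _, report = run_once(
            r,
            seed,
            size=size,
            noise_sigma=noise_sigma,
            shift_nm=shift_nm,
            solver=SolverConfig(sp_h=float(sp)),
        )
        rows.append(
            {
                "sp_h": float(sp),
                "rmse": report.rmse,
                "sad_mean": float(np.nanmean(report.sad_per_component)),
                "ssim_mean": report.ssim_mean,
                "dice_mean": report.dice_mean,
            }
        )
    return pd.DataFrame(rows)


def intensity_sweep(
    ratios: Sequence[float] = (0.1, 0.5, 1.0, 2.0, 10.0),
    seed: int = 0,
    *,
    r: int = 3,
    size: int = DEFAULT_SIZE,
    noise_sigma: float = 0.0,
    shift_nm: float = 0.0,
    algorithms: Sequence[str] = ("bingo", "nnmf"),
) -> pd.DataFrame:
    """SSIM/Dice as fluorophore 0's relative brightness sweeps 0.1x-10x,
    for the solver and the random-init NMF comparator.

    Noise is off by default so the sweep isolates the intensity factor:
    because the generator scales noise with the *global* signal maximum, a
    brighter fluorophore would raise every other fluorophore's noise floor
    and the sweep would measure noise robustness instead (even
    reference-aided linear unmixing degrades heavily there). The noisy
    variant is available via ``noise_sigma``/``shift_nm``.
    """
    rows = []
    for ratio in ratios:
        scales = (float(ratio),) + (1.0,) * (r - 1)
        for algo in algorithms:
            _, report = run_once(
                r,
                seed,
                size=size,
                noise_sigma=noise_sigma,
                shift_nm=shift_nm,
                intensity_scales=scales,
                algorithm=algo,
            )
            rows.append(
                {
                    "ratio": float(ratio),
                    "algorithm": algo,
                    "ssim_mean": report.ssim_mean,
                    "dice_mean": report.dice_mean,
                    "sad_mean": float(np.nanmean(report.sad_per_component)),
                }
            )
    return pd.DataFrame(rows)


def count_sweep(
    counts: Sequence[int] = (3, 5, 7, 9, 11),
    seeds: Sequence[int] = (0,),
    *,
    size: int = 96,
    noise_sigma: float = 0.02,
    shift_nm: float = 3.0,
    algorithms: Sequence[str] = ("bingo", "nnmf"),
) -> pd.DataFrame:
    """SSIM/Dice while the number of fluorophores (and channels with it)
    grows, per seed and algorithm."""
    rows = []
    for r in counts:
        for seed in seeds:
            for algo in algorithms:
                _, report = run_once(
                    r,
                    seed,
                    size=size,
                    noise_sigma=noise_sigma,
                    shift_nm=shift_nm,
                    algorithm=algo,
                )
                rows.append(
                    {
                        "r": int(r),
                        "seed": int(seed),
                        "algorithm": algo,
                        "ssim_mean": report.ssim_mean,
                        "dice_mean": report.dice_mean,
                    }
                )
    return pd.DataFrame(rows)
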