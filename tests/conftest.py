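"""Shared fixtures: tiny handmade datasets and the 20-seed recovery study."""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pytest

from skinmsi.cli import RunConfig, run_workflow
from skinmsi.io import MSIDataset
from skinmsi.profiles import depth_of_detection
from skinmsi.synthetic import SectionSpec, generate_section, true_profile

N_RECOVERY_SEEDS = 20
RECOVERY_N_LAYERS = 10  # 100 um layers on the default 1 mm band


@pytest.fixture
def two_pixel_dataset() -> MSIDataset:
    return MSIDataset(
        {
            (0, 0): (np.array([104.107, 292.207]), np.array([500.0, 900.0])),
            (1, 0): (np.array([104.107, 760.585]), np.array([450.0, 800.0])),
        },
        pixel_size_um=50.0,
    )


def random_dataset(rng: np.random.Generator, n_cols=4, n_rows=3, max_peaks=6) -> MSIDataset:
    """Random small dataset; every pixel has at least one peak."""
    pixels = {}
    for c in range(n_cols):
        for r in range(n_rows):
            n = rng.integers(1, max_peaks + 1)
            mz = np.sort(rng.uniform(100, 900, n))
            while np.any(np.diff(mz) == 0):  # pragma: no cover
                mz = np.sort(rng.uniform(100, 900, n))
            inten = rng.uniform(0.5, 1000, n)
            pixels[(c, r)] = (mz, inten)
    return MSIDataset(pixels, pixel_size_um=50.0)


@pytest.fixture(scope="session")
def small_section():
    """One compact synthetic section + ground truth for fast unit tests."""
    spec = SectionSpec(n_cols=40, n_rows=40, band_center_row=20.0, seed=7)
    dataset, gt = generate_section(spec)
    return spec, dataset, gt


@dataclass
class RecoveryResult:
    seed: int
    f1: float
    pearson_r: float
    spearman_depth: float
    dod_error_um: float
    layer_width_um: float
    fraction_sum: float
    elapsed_s: float


@pytest.fixture(scope="session")
def recovery_study() -> list[RecoveryResult]:
    """Full-pipeline recovery on 20 default synthetic sections.

    Shared by the property tests (mask F1, depth monotonicity) and the
    parameter-recovery acceptance test so the heavy computation runs
    once per session.
    """
    from scipy.stats import spearmanr

    out: list[RecoveryResult] = []
    for seed in range(N_RECOVERY_SEEDS):
        spec = SectionSpec(seed=seed)
        dataset, gt = generate_section(spec)
        t0 = time.perf_counter()
        res = run_workflow(dataset, RunConfig(n_layers=RECOVERY_N_LAYERS, seed=seed))
        elapsed = time.perf_counter() - t0
        profile = res["profile"]
        expected = true_profile(gt, RECOVERY_N_LAYERS)

        mask = res["mask"].pixels
        tp = len(mask & gt.tissue)
        f1 = 2 * tp / (len(mask) + len(gt.tissue))
        r = float(np.corrcoef(profile.fraction, expected.fraction)[0, 1])
        assignment = res["assignment"]
        true_depth = np.array([gt.depth_um.get(p, np.nan) for p in assignment.pixels])
        ok = ~np.isnan(true_depth)
        rho = float(spearmanr(assignment.layer_index[ok], true_depth[ok]).statistic)
        dod_err = abs(depth_of_detection(profile) - depth_of_detection(expected))
        out.append(
            RecoveryResult(
                seed=seed, f1=f1, pearson_r=r, spearman_depth=rho,
                dod_error_um=dod_err,
                layer_width_um=float(np.mean(assignment.widths_um)),
                fraction_sum=float(profile.fraction.sum()),
                elapsed_s=elapsed,
            )
        )
    return out
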