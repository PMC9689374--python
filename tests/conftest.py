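"""Shared fixtures: phantom cases, fused LR volumes, short trainings.

Everything is generated programmatically and seeded. The short-training
fixture is session-scoped because it is the single expensive item in
the suite (it trains all four architectures for three seeds each) and
is consumed by several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import orthosr as o
from orthosr.pipeline import _desk_train_config


@pytest.fixture(scope="session")
def phantom_triplet():
    """A mid-size phantom case: (hr, thick_axial, thick_coronal)."""
    return o.make_triplet(o.PhantomSpec(size=(48, 48, 40), seed=7))


@pytest.fixture(scope="session")
def fused_case(phantom_triplet):
    """(hr, lr) with the LR volume fused on the thin-axial grid."""
    hr, ta, tc = phantom_triplet
    return hr, o.fuse(ta, tc, hr.geometry).lr


@pytest.fixture(scope="session")
def small_triplet():
    """A tiny phantom triplet for brute-force (per-voxel) oracles."""
    return o.make_triplet(o.PhantomSpec(size=(24, 24, 20), seed=3))


@pytest.fixture(scope="session")
def phantom_cases():
    """Five fused phantom cases: 3 train, 1 eval, 1 test."""
    cases = []
    for s in range(5):
        hr, ta, tc = o.make_triplet(o.PhantomSpec(size=(48, 48, 40), seed=100 + s))
        lr = o.fuse(ta, tc, hr.geometry).lr
        cases.append((hr, lr))
    return {"train": cases[:3], "eval": cases[3:4], "test": cases[4]}


@pytest.fixture(scope="session")
def short_training_results(phantom_cases):
    """Held-out PSNR of short sagittal trainings vs the LR baseline.

    Trains every architecture (width 8, desk-scale schedule) for three
    seeds on the same phantom cases and records the test-case PSNR of
    the super-resolved volume next to the fused-LR baseline.
    """
    test_hr, test_lr = phantom_cases["test"]
    lr_psnr = o.psnr(test_hr.intensities, test_lr.intensities)
    results: dict[str, list[dict]] = {}
    for arch in o.ARCHITECTURES:
        runs = []
        for seed in (1, 2, 3):
            cfg = _desk_train_config(arch, "sagittal", seed=seed)
            net = o.build_model(o.ArchitectureSpec(arch, width=8), rng=seed)
            model = o.train(net, phantom_cases["train"], phantom_cases["eval"], cfg)
            sr = o.infer_volume(model, test_lr)
            runs.append(
                {
                    "seed": seed,
                    "sr_psnr": o.psnr(test_hr.intensities, sr.intensities),
                    "model": model,
                }
            )
        results[arch] = runs
    return {"lr_psnr": lr_psnr, "runs": results}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
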