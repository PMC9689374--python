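"""End-to-end experiment orchestration on phantom cases.

One run generates a set of synthetic cases, fuses each thick pair into
an LR volume, trains the requested architectures on the requested
planes, super-resolves the test cases, scores every condition over the
three ROIs and produces the pairwise comparison matrices. Artifacts
(LR DICOM, checkpoints, CSV tables, manifest) are written under one
output root and are reproducible given the global seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

import orthosr

from .admission import validate_triplet
from .dicom_io import write_series
from .fusion import fuse
from .geometry import CTVolume
from .metrics import ROI_LABELS, evaluate_case
from .models import ArchitectureSpec, build_model
from .phantom import PhantomSpec, make_triplet
from .stats import comparison_matrix, plane_conditions, roi_conditions
from .training import TrainConfig, infer_volume, train

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    n_train: int = 4
    n_eval: int = 1
    n_test: int = 3
    architectures: tuple[str, ...] = ("EDSR",)
    planes: tuple[str, ...] = ("sagittal",)
    width: int = 8
    train_config: TrainConfig | None = None
    phantom_size: tuple[int, int, int] = (48, 48, 40)
    seed: int = 0
    out_dir: str | Path = "run"
    write_dicom: bool = True

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_eval, self.n_test) < 1:
            raise ValueError("each split needs at least one case")

    def case_splits(self) -> dict[str, list[int]]:
        """Disjoint case indices per split (train, eval, test)."""
        n = self.n_train + self.n_eval + self.n_test
        idx = list(range(n))
        return {
            "train": idx[: self.n_train],
            "eval": idx[self.n_train : self.n_train + self.n_eval],
            "test": idx[self.n_train + self.n_eval :],
        }


def _desk_train_config(arch: str, plane: str, seed: int) -> TrainConfig:
    """Desk-scale profile: published structure, shrunk schedule.

    Loss types and gradient clipping follow the per-architecture
    published settings; batches per epoch and epochs are reduced for
    single-CPU runs and the learning rate raised to 1e-3 to suit the
    short schedule.
    """
    full = TrainConfig.published(arch, plane=plane, seed=seed)
    steps = {"SRCNN": (40, 8), "VDSR": (12, 4), "SRResNet": (12, 4), "EDSR": (12, 4)}
    bpe, epochs = steps[arch]
    full.patch_size = 32
    full.batch_size = 8
    full.batches_per_epoch = bpe
    full.total_epochs = epochs
    full.learning_rate = 1e-3
    return full


def _check_splits(splits: dict[str, list[int]]) -> None:
    seen: set[int] = set()
    for name, ids in splits.items():
        overlap = seen & set(ids)
        if overlap:
            raise ValueError(f"overlapping splits: cases {sorted(overlap)} in {name}")
        seen |= set(ids)


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the full phantom experiment; return the report bundle.

    The bundle contains the records DataFrame, the comparison matrices
    for both modes and metrics, and the manifest. Everything is also
    written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    splits = cfg.case_splits()
    _check_splits(splits)
    rng = np.random.default_rng(cfg.seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=sum(len(v) for v in splits.values()))

    # --- phantom generation + fusion ------------------------------------
    cases: dict[int, dict] = {}
    for split, ids in splits.items():
        for cid in ids:
            spec = PhantomSpec(size=cfg.phantom_size, seed=int(case_seeds[cid]))
            hr, thick_ax, thick_co = make_triplet(spec)
            verdict = validate_triplet(hr, thick_ax, thick_co)
            if not verdict:
                raise RuntimeError(
                    f"stage fusion, case {cid}: triplet rejected: {verdict.reasons}"
                )
            lr = fuse(thick_ax, thick_co, hr.geometry).lr
            cases[cid] = {"split": split, "hr": hr, "lr": lr}
            if cfg.write_dicom:
                write_series(lr, out / f"case_{cid:02d}" / "lr",
                             description="fused low-resolution volume")

    pairs = {
        split: [(cases[c]["hr"], cases[c]["lr"]) for c in ids]
        for split, ids in splits.items()
    }

    # --- training per architecture and plane ----------------------------
    models: dict[tuple[str, str], object] = {}
    for arch in cfg.architectures:
        for plane in cfg.planes:
            if cfg.train_config is not None:
                tc = replace(cfg.train_config, plane=plane)
            else:
                tc = _desk_train_config(arch, plane, cfg.seed)
            net = build_model(ArchitectureSpec(arch, width=cfg.width), rng=cfg.seed)
            try:
                model = train(net, pairs["train"], pairs["eval"], tc)
            except Exception as exc:  # annotate failing stage
                raise RuntimeError(f"stage train, {arch}/{plane}: {exc}") from exc
            models[(arch, plane)] = model
            ckpt = out / "checkpoints" / f"{arch}_{plane}.npz"
            ckpt.parent.mkdir(parents=True, exist_ok=True)
            np.savez(ckpt, *[p.value for p in model.network.params()])

    # --- inference + evaluation on test cases ---------------------------
    records = []
    for cid in splits["test"]:
        hr, lr = cases[cid]["hr"], cases[cid]["lr"]
        rec = evaluate_case(hr, lr, case_id=f"case_{cid:02d}", condition="LR")
        records.append(rec)
        for (arch, plane), model in models.items():
            sr = infer_volume(model, lr, plane)
            if cfg.write_dicom:
                write_series(sr, out / f"case_{cid:02d}" / f"sr_{arch}_{plane}",
                             description=f"{arch} super-resolution ({plane})")
            records.append(
                evaluate_case(hr, sr, case_id=f"case_{cid:02d}",
                              condition=f"{arch}-{plane}")
            )

    rows = [
        {"case": r.case_id, "condition": r.condition, "roi": roi,
         "psnr": r.psnr[roi], "ssim": r.ssim[roi]}
        for r in records
        for roi in ROI_LABELS
    ]
    df = pd.DataFrame(rows).sort_values(["condition", "case", "roi"]).reset_index(drop=True)
    df.to_csv(out / "quality_records.csv", index=False)

    # --- comparison matrices --------------------------------------------
    matrices = {}
    conds_plane = plane_conditions(cfg.architectures, cfg.planes)
    whole = df[df.roi == "whole-DICOM"].sort_values("case")
    for metric in ("psnr", "ssim"):
        vals = {c: whole[whole.condition == c][metric].to_numpy() for c in conds_plane}
        mat = comparison_matrix(vals, conds_plane, mode="plane")
        matrices[f"plane_{metric}"] = mat
        pd.DataFrame(mat.p, index=mat.conditions, columns=mat.conditions).to_csv(
            out / f"comparisons_plane_{metric}.csv"
        )
    methods = ["LR"] + [f"{a}-{p}" for a in cfg.architectures for p in cfg.planes]
    conds_roi = roi_conditions(tuple(methods), ROI_LABELS)
    for metric in ("psnr", "ssim"):
        vals = {}
        for m in methods:
            for roi in ROI_LABELS:
                sub = df[(df.condition == m) & (df.roi == roi)].sort_values("case")
                vals[f"{m}|{roi}"] = sub[metric].to_numpy()
        mat = comparison_matrix(vals, conds_roi, mode="roi")
        matrices[f"roi_{metric}"] = mat
        pd.DataFrame(mat.p, index=mat.conditions, columns=mat.conditions).to_csv(
            out / f"comparisons_roi_{metric}.csv"
        )

    manifest = {
        "seed": cfg.seed,
        "case_seeds": [int(s) for s in case_seeds],
        "splits": splits,
        "architectures": list(cfg.architectures),
        "planes": list(cfg.planes),
        "width": cfg.width,
        "phantom_size": list(cfg.phantom_size),
        "train_log": {
            f"{a}_{p}": m.train_log for (a, p), m in models.items()
        },
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
        "software": {
            "orthosr": orthosr.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"records": df, "matrices": matrices, "manifest": manifest,
            "models": models}
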