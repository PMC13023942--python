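"""End-to-end orchestration: training, inference, ablations, manifests.

Training follows the self-supervised recipe: each step draws a batch of
noisy patches, splits every patch into its fixed complementary sub-image
pair, denoises, and minimises the four-term objective with Adam
(beta = (0.9, 0.999)); the learning rate is halved every
``lr_halving_period`` epochs and the parameters with the best validation
SSIM (pseudo-clean protocol) are retained.

Two presets are provided: the ``paper`` preset (100 epochs, batch 4,
lr 1e-4 halved every 20 epochs) and a ``desk`` preset sized for a single
CPU (25 epochs over 64x64 patches, lr 1e-3, float32 arithmetic).  Every
random choice — split, patch order, initialisation — derives from the run
seed, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import autodiff as ad
from .autodiff import Adam
from .bscan import BScan
from .fenet import FEUNet, NetConfig, build_network
from .losses import LossBreakdown, LossWeights, total_loss
from .metrics import evaluate_pseudo_clean, evaluate_true_clean
from .phantom import PhantomConfig, default_roi_masks, make_dataset
from .sampler import PATTERNS

__all__ = [
    "TrainConfig",
    "RunManifest",
    "desk_preset",
    "paper_preset",
    "lr_at_epoch",
    "split_dataset",
    "train",
    "denoise",
    "run_ablation_suite",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = ("full", "no_wspm", "no_ferfb", "n2n_baseline")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-4
    lr_halving_period: int = 20
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    patch_size: int = 64
    ablation: str = "full"
    steps_per_epoch: int | None = None
    pattern_id: str = "A"
    weights: LossWeights = field(default_factory=LossWeights)
    dtype: str = "float32"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patch_size % 16:
            raise ValueError("patch_size must be divisible by 16")
        if self.ablation not in ABLATION_VARIANTS:
            raise ValueError(f"ablation must be one of {ABLATION_VARIANTS}")
        if self.pattern_id not in PATTERNS:
            raise ValueError(f"unknown pattern_id {self.pattern_id!r}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32|float64")


def paper_preset(**overrides) -> TrainConfig:
    """The published training schedule (GPU-scale)."""
    return TrainConfig(**overrides)


def desk_preset(**overrides) -> TrainConfig:
    """A single-CPU schedule: 25 epochs, lr 1e-3 halved every 10 epochs."""
    base = dict(epochs=25, learning_rate=1e-3, lr_halving_period=10)
    base.update(overrides)
    return TrainConfig(**base)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate at a given epoch: halved every lr_halving_period."""
    return cfg.learning_rate * 0.5 ** (epoch // cfg.lr_halving_period)


def split_dataset(items: Sequence, seed: int,
                  ratios: tuple[int, int, int] = (8, 1, 1)) -> tuple[list, list, list]:
    """Random overlap-free 8:1:1 split covering every item."""
    n = len(items)
    total = sum(ratios)
    n_val = max(1, int(round(n * ratios[1] / total))) if n >= 3 else 0
    n_test = max(1, int(round(n * ratios[2] / total))) if n >= 3 else 0
    order = np.random.default_rng(seed).permutation(n)
    test_idx = order[:n_test]
    val_idx = order[n_test:n_test + n_val]
    train_idx = order[n_test + n_val:]
    pick = lambda idx: [items[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


@dataclass
class RunManifest:
    """Everything needed to re-launch a bit-reproducible run."""

    train_config: dict
    net_config: dict
    seed: int
    code_version: str
    config_hash: str
    epoch_table: list[dict] = field(default_factory=list)
    wall_clock_s: float = 0.0
    best_epoch: int = -1
    best_val_ssim: float = math.nan
    n_parameters: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def _variant_net_config(cfg: NetConfig, ablation: str) -> NetConfig:
    if ablation == "full":
        return cfg
    if ablation == "no_wspm":
        return replace(cfg, use_wspm=False)
    if ablation == "no_ferfb":
        return replace(cfg, use_ferfb=False)
    if ablation == "n2n_baseline":
        return replace(cfg, use_wspm=False, use_ferfb=False)
    raise ValueError(ablation)


def _crop(rng: np.random.Generator, px: np.ndarray, size: int) -> np.ndarray:
    h, w = px.shape
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than patch size {size}")
    # even offsets keep the 2x2 subsampling cells aligned with the source
    r = 2 * rng.integers(0, (h - size) // 2 + 1)
    c = 2 * rng.integers(0, (w - size) // 2 + 1)
    return px[r:r + size, c:c + size]


def _half_model(net: FEUNet, value_range, dtype):
    def model(b: BScan) -> BScan:
        out = net.forward_array(b.pixels[None, None].astype(dtype))[0, 0]
        return BScan.clipped(out.astype(np.float64), value_range)

    return model


def _step_losses(net: FEUNet, y: np.ndarray, cfg: TrainConfig) -> LossBreakdown:
    """Forward passes and the four-term objective for one batch (N,1,H,W)."""
    (r1, c1), (r2, c2) = PATTERNS[cfg.pattern_id]
    ty = ad.tensor(y)
    g1 = ad.strided_sub(ty, r1, c1)
    g2 = ad.strided_sub(ty, r2, c2)
    f_g1 = net(g1)

    if cfg.ablation == "n2n_baseline":
        # original neighbour-subsampling objective: L2 reconstruction + reg
        rec = ad.mean_square(f_g1, g2)
        f_y = net(ty)
        res = (f_g1 - g2) - (ad.strided_sub(f_y, r1, c1) - ad.strided_sub(f_y, r2, c2))
        reg = res.square().mean()
        w = LossWeights(lambda1=1.0, lambda2=0.0, lambda3=0.0,
                        gamma=cfg.weights.gamma)
        return total_loss([rec, 0.0, 0.0, reg], w)

    f_g2 = net(g2)
    f_y = net(ty)
    l1 = ad.mean_abs(f_g1, g2)
    l2 = ad.mean_square(f_g1, f_g2)
    avg = 0.5 * (g1.data + g2.data)
    x_pseudo = np.repeat(np.repeat(avg, 2, axis=-2), 2, axis=-1)
    l_freq = ad.freq_mse(f_y, ad.tensor(x_pseudo))
    res = (f_g1 - g2) - (ad.strided_sub(f_y, r1, c1) - ad.strided_sub(f_y, r2, c2))
    reg = res.square().mean()
    return total_loss([l1, l2, l_freq, reg], cfg.weights)


def train(train_set: Sequence[BScan], val_set: Sequence[BScan],
          net_cfg: NetConfig, train_cfg: TrainConfig,
          log_csv: str | Path | None = None) -> tuple[FEUNet, RunManifest]:
    """Train the network on noisy B-scans only; returns the best-validation
    parameters and the run manifest."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    dtype = np.float32 if train_cfg.dtype == "float32" else np.float64
    vcfg = _variant_net_config(net_cfg, train_cfg.ablation)
    net = build_network(vcfg, seed=train_cfg.seed, dtype=dtype)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate,
               betas=train_cfg.adam_betas)
    rng = np.random.default_rng(train_cfg.seed + 1)
    value_range = train_set[0].value_range
    cfg_json = json.dumps({"train": _cfg_dict(train_cfg), "net": vcfg.to_dict()},
                          sort_keys=True)
    manifest = RunManifest(
        train_config=_cfg_dict(train_cfg), net_config=vcfg.to_dict(),
        seed=train_cfg.seed, code_version=_pkg_version,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        n_parameters=net.n_parameters(),
    )
    steps = train_cfg.steps_per_epoch or max(1, math.ceil(len(train_set) / train_cfg.batch_size))
    writer = None
    csv_file = None
    if log_csv is not None:
        csv_file = open(log_csv, "w", newline="")
        writer = csv.DictWriter(csv_file, fieldnames=[
            "epoch", "step", "l1_pred", "l2_consistency", "l_freq", "l_reg", "total"])
        writer.writeheader()

    best_state = net.state_dict()
    best_ssim = -math.inf
    t0 = time.perf_counter()
    try:
        for epoch in range(train_cfg.epochs):
            opt.lr = lr_at_epoch(train_cfg, epoch)
            totals = []
            for step in range(steps):
                idx = rng.integers(0, len(train_set), size=train_cfg.batch_size)
                batch = np.stack([
                    _crop(rng, train_set[i].pixels, train_cfg.patch_size)
                    for i in idx
                ])[:, None].astype(dtype)
                bd = _step_losses(net, batch, train_cfg)
                if not math.isfinite(bd.total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: {bd.as_row()}"
                    )
                opt.zero_grad()
                bd.total_tensor.backward()
                opt.step()
                # keep only the float row: the tensor holds the whole tape
                totals.append(bd.as_row())
                del bd
                if writer is not None:
                    writer.writerow({"epoch": epoch, "step": step, **totals[-1]})
            report = evaluate_pseudo_clean(
                _half_model(net, value_range, dtype), val_set,
                pattern_id=train_cfg.pattern_id)
            if report.ssim > best_ssim:
                best_ssim = report.ssim
                best_state = net.state_dict()
                manifest.best_epoch = epoch
            manifest.epoch_table.append({
                "epoch": epoch, "lr": opt.lr,
                **{f"mean_{k}": float(np.mean([row[k] for row in totals]))
                   for k in ("total", "l1_pred", "l2_consistency", "l_freq", "l_reg")},
                "val_ssim": report.ssim,
                "val_psnr": report.psnr_db,
            })
    finally:
        if csv_file is not None:
            csv_file.close()
    net.load_state_dict(best_state)
    manifest.best_val_ssim = best_ssim if math.isfinite(best_ssim) else math.nan
    manifest.wall_clock_s = time.perf_counter() - t0
    return net, manifest


def _cfg_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["adam_betas"] = list(cfg.adam_betas)
    return d


def denoise(net: FEUNet, img: BScan) -> BScan:
    """Denoise a full B-scan of any size: reflect-pad to a multiple of 16,
    forward, crop back, clip to the declared range."""
    dtype = net.parameters()[0].data.dtype
    h, w = img.pixels.shape
    ph = (-h) % 16
    pw = (-w) % 16
    px = np.pad(img.pixels, ((0, ph), (0, pw)), mode="reflect") if ph or pw else img.pixels
    out = net.forward_array(px[None, None].astype(dtype))[0, 0]
    return BScan.clipped(out[:h, :w].astype(np.float64), img.value_range)


def run_ablation_suite(phantom_cfg: PhantomConfig, net_cfg: NetConfig,
                       train_cfg: TrainConfig, n_train: int = 48,
                       n_val: int = 8, n_test: int = 8,
                       out_csv: str | Path | None = None) -> pd.DataFrame:
    """Train all four variants under identical seeds and data and evaluate
    them on held-out phantoms with both reference kinds.

    Returns a table with one row per variant (stable order: full, no_wspm,
    no_ferfb, n2n_baseline) and SNR/PSNR/SSIM columns per reference kind.
    """
    truths = make_dataset(phantom_cfg, n_train + n_val + n_test)
    train_n = [t.noisy for t in truths[:n_train]]
    val_n = [t.noisy for t in truths[n_train:n_train + n_val]]
    test_t = truths[n_train + n_val:]
    roi = default_roi_masks(phantom_cfg) if phantom_cfg.air_fraction > 0 else None
    rows = []
    for variant in ABLATION_VARIANTS:
        vcfg = replace(train_cfg, ablation=variant)
        net, _manifest = train(train_n, val_n, net_cfg, vcfg)
        dtype = np.float32 if vcfg.dtype == "float32" else np.float64
        pseudo = evaluate_pseudo_clean(
            _half_model(net, test_t[0].noisy.value_range, dtype),
            [t.noisy for t in test_t], pattern_id=vcfg.pattern_id)
        true = evaluate_true_clean(
            lambda b: denoise(net, b),
            [(t.noisy, t.clean) for t in test_t], roi=roi)
        rows.append({
            "variant": variant,
            "pseudo_snr_db": pseudo.snr_db, "pseudo_psnr_db": pseudo.psnr_db,
            "pseudo_ssim": pseudo.ssim,
            "true_snr_db": true.snr_db, "true_psnr_db": true.psnr_db,
            "true_ssim": true.ssim,
        })
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
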