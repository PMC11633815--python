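"""Content-noise CycleGAN for unpaired low-dose CT enhancement.

Two generators translate between the low-dose domain A and the
normal-dose domain B (``G_A: A -> B`` enhances, ``G_B: B -> A``
re-degrades); each is trained adversarially against a patch
discriminator on its target domain.  The total objective is the weighted
sum

    L = L_adv(G_A, D_B) + L_adv(G_B, D_A)
        + lambda_cyc * L_cyc(G_A, G_B) + lambda_iden * L_iden(G_A, G_B)

with vanilla (log/BCE) adversarial terms, mean-L1 cycle consistency
``|I_A - G_B(G_A(I_A))| + |I_B - G_A(G_B(I_B))|`` and mean-L1 identity
terms ``|I_B - G_A(I_B)| + |I_A - G_B(I_A)|``.  Defaults:
lambda_cyc = 20, lambda_iden = 0.5, Adam at lr 2e-4 held for the first
150 of 250 epochs then decayed linearly to zero, batch size 4, Gaussian
N(0, 0.02^2) weight initialization.

"Content-noise" means the generators predict a noise map that is
subtracted from their input (a residual skip), so an untrained or
zero-output generator is exactly the identity and the network only has
to learn the noise component.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .phantom import CTImage, ParameterError
from .preprocess import (
    AugmentationPolicy,
    NormalizationSpec,
    denormalize,
    extract_patches,
    fit_normalizer,
    normalize,
)

EPS = 1e-7


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------

def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """Vanilla GAN losses from discriminator probabilities.

    Returns ``(d_loss, g_loss)`` where ``d_loss`` is the negated
    discriminator objective ``mean log D(real) + mean log(1 - D(fake))``
    (so minimizing ``d_loss`` maximizes the objective) and ``g_loss`` is
    the non-saturating generator loss ``-mean log D(fake)``.  Values at
    exactly 0 or 1 are clamped by 1e-7 before the logarithm.
    """
    pr = np.clip(np.asarray(d_real, dtype=np.float64), EPS, 1.0 - EPS)
    pf = np.clip(np.asarray(d_fake, dtype=np.float64), EPS, 1.0 - EPS)
    d_loss = -(float(np.mean(np.log(pr))) + float(np.mean(np.log(1.0 - pf))))
    g_loss = -float(np.mean(np.log(pf)))
    return d_loss, g_loss


def _mean_l1(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def cycle_loss(i_a, recon_a, i_b, recon_b) -> float:
    """Mean-L1 cycle consistency: ``|I_A - G_B(G_A(I_A))| + |I_B - G_A(G_B(I_B))|``."""
    return _mean_l1(i_a, recon_a) + _mean_l1(i_b, recon_b)


def identity_loss(i_a, g_b_of_i_a, i_b, g_a_of_i_b) -> float:
    """Mean-L1 identity terms: ``|I_B - G_A(I_B)| + |I_A - G_B(I_A)|``."""
    return _mean_l1(i_b, g_a_of_i_b) + _mean_l1(i_a, g_b_of_i_a)


@dataclass(frozen=True)
class LossWeights:
    lambda_cyc: float = 20.0
    lambda_iden: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_cyc < 0 or self.lambda_iden < 0:
            raise ParameterError("loss weights must be >= 0")


@dataclass
class LossReport:
    """Per-step (or per-epoch mean) loss decomposition.

    ``d_real_*`` / ``d_fake_*`` are mean discriminator probabilities,
    recorded for training diagnostics; they do not enter ``total``.
    """

    adv_A: float
    adv_B: float
    cyc: float
    iden: float
    total: float = field(default=0.0)
    d_real_A: float = 0.0
    d_fake_A: float = 0.0
    d_real_B: float = 0.0
    d_fake_B: float = 0.0

    @classmethod
    def assemble(cls, adv_a: float, adv_b: float, cyc: float, iden: float,
                 weights: LossWeights) -> "LossReport":
        return cls(adv_a, adv_b, cyc, iden,
                   total_loss(adv_a, adv_b, cyc, iden, weights))


def total_loss(adv_a: float, adv_b: float, cyc: float, iden: float,
               weights: LossWeights = LossWeights()) -> float:
    """Weighted total: ``adv_A + adv_B + lambda_cyc*cyc + lambda_iden*iden``."""
    return adv_a + adv_b + weights.lambda_cyc * cyc + weights.lambda_iden * iden


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainSchedule:
    epochs_total: int = 250
    epochs_constant_lr: int = 150
    lr_initial: float = 2e-4
    batch_size: int = 4
    betas: tuple[float, float] = (0.5, 0.999)
    init_std: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_constant_lr > self.epochs_total:
            raise ParameterError("epochs_constant_lr must be <= epochs_total")
        if self.lr_initial <= 0:
            raise ParameterError("lr_initial must be > 0")


def lr_at_epoch(schedule: TrainSchedule, epoch: int) -> float:
    """Learning rate: constant for the first ``epochs_constant_lr`` epochs,
    then linear descent reaching exactly zero at ``epochs_total``."""
    if epoch < 0 or epoch > schedule.epochs_total:
        raise ParameterError(f"epoch {epoch} outside [0, {schedule.epochs_total}]")
    if epoch < schedule.epochs_constant_lr:
        return schedule.lr_initial
    span = schedule.epochs_total - schedule.epochs_constant_lr
    if span == 0:
        return 0.0
    return schedule.lr_initial * (schedule.epochs_total - epoch) / span


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """The four networks plus everything needed to run them on HU images."""

    G_A: nn.Network  # low-dose -> normal-dose (the enhancer)
    G_B: nn.Network  # normal-dose -> low-dose
    D_A: nn.Network  # realism of domain-A (low-dose) images
    D_B: nn.Network  # realism of domain-B (normal-dose) images
    weights: LossWeights
    normalizer: NormalizationSpec
    residual: bool = True
    arch: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for name, net in self.nets().items():
            for i, p in enumerate(net.params):
                arrays[f"{name}_{i}"] = p.data
        meta = {
            "weights": asdict(self.weights),
            "normalizer": json.loads(self.normalizer.to_json()),
            "residual": self.residual,
            "arch": self.arch,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                     else path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arch = meta["arch"]
            bundle = build_bundle(
                normalizer=NormalizationSpec(
                    hu_floor=meta["normalizer"]["hu_floor"],
                    hu_ceiling=meta["normalizer"]["hu_ceiling"],
                    out_range=tuple(meta["normalizer"]["out_range"]),
                ),
                weights=LossWeights(**meta["weights"]),
                residual=meta["residual"],
                seed=0,
                **arch,
            )
            for name, net in bundle.nets().items():
                net.load_state([data[f"{name}_{i}"] for i in range(len(net.params))])
        return bundle

    def nets(self) -> dict[str, nn.Network]:
        return {"G_A": self.G_A, "G_B": self.G_B, "D_A": self.D_A, "D_B": self.D_B}


def build_bundle(
    normalizer: NormalizationSpec,
    weights: LossWeights = LossWeights(),
    seed: int = 0,
    base_channels: int = 32,
    width_multiplier: float = 1.0,
    n_res_blocks: int = 4,
    residual: bool = True,
    d_width_multiplier: float | None = None,
) -> ModelBundle:
    """Construct untrained networks with Gaussian N(0, 0.02^2) weights.

    ``d_width_multiplier`` scales the discriminators independently of the
    generators; at reduced generator widths the discriminators keep full
    width by default so the adversary stays strong enough to matter.
    """
    rng = np.random.default_rng(seed)
    if d_width_multiplier is None:
        d_width_multiplier = 1.0
    mk_g = lambda: nn.build_generator(rng, base_channels, n_res_blocks, width_multiplier)
    mk_d = lambda: nn.build_discriminator(rng, base_channels, d_width_multiplier)
    return ModelBundle(
        G_A=mk_g(), G_B=mk_g(), D_A=mk_d(), D_B=mk_d(),
        weights=weights, normalizer=normalizer, residual=residual,
        arch={
            "base_channels": base_channels,
            "width_multiplier": width_multiplier,
            "n_res_blocks": n_res_blocks,
            "d_width_multiplier": d_width_multiplier,
        },
    )


# ---------------------------------------------------------------------------
# Generator application
# ---------------------------------------------------------------------------

def _g_forward(net: nn.Network, x: np.ndarray, residual: bool):
    y, cache = net.forward(x)
    return (x - y, cache) if residual else (y, cache)


def _g_backward(net: nn.Network, dy: np.ndarray, cache, residual: bool) -> np.ndarray:
    if residual:
        return dy + net.backward(-dy, cache)
    return net.backward(dy, cache)


def _pad_to_multiple(x: np.ndarray, m: int = 4):
    h, w = x.shape[-2:]
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        x = np.pad(x, [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)], mode="reflect")
    return x, (h, w)


def generate(bundle: ModelBundle, ldct: CTImage) -> CTImage:
    """Enhance a low-dose image: normalize, apply G_A, denormalize to HU.

    The output is clipped to the normalizer window, so it never leaves
    ``[hu_floor, hu_ceiling]`` — the reason very dense (bone-like) values
    above the ceiling cannot be recovered exactly.
    """
    norm = normalize(ldct, bundle.normalizer)
    x = norm.pixels[None, None, :, :]
    x, (h, w) = _pad_to_multiple(x, 4)
    y, _ = _g_forward(bundle.G_A, x, bundle.residual)
    lo, hi = bundle.normalizer.out_range
    out = norm.copy()
    out.pixels = np.clip(y[0, 0, :h, :w], lo, hi)
    return denormalize(out, bundle.normalizer)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sign_grad(x: np.ndarray, target: np.ndarray, weight: float) -> np.ndarray:
    return weight * np.sign(x - target) / x.size


def _log_grad(p: np.ndarray, sign: float) -> np.ndarray:
    """Gradient of ``sign * mean log p`` w.r.t. p, with clamping."""
    pc = np.clip(p, EPS, 1.0 - EPS)
    g = sign / (pc * p.size)
    g[(p <= EPS) | (p >= 1.0 - EPS)] = 0.0
    return g


def _log1m_grad(p: np.ndarray, sign: float) -> np.ndarray:
    """Gradient of ``sign * mean log(1 - p)`` w.r.t. p, with clamping."""
    pc = np.clip(p, EPS, 1.0 - EPS)
    g = -sign / ((1.0 - pc) * p.size)
    g[(p <= EPS) | (p >= 1.0 - EPS)] = 0.0
    return g


class TrainingDiverged(RuntimeError):
    pass


class ImagePool:
    """Replay buffer of generated images for discriminator updates.

    Discriminators train against a history of fakes rather than only the
    newest batch, which stops the generators from exploiting the current
    discriminator state with transient adversarial perturbations (the
    standard CycleGAN stabilization).
    """

    def __init__(self, capacity: int, rng: np.random.Generator):
        self.capacity = capacity
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.capacity == 0:
            return batch
        out = []
        for img in batch:
            if len(self.images) < self.capacity:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                k = int(self.rng.integers(len(self.images)))
                out.append(self.images[k].copy())
                self.images[k] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


def train(
    domain_a: Sequence[CTImage],
    domain_b: Sequence[CTImage],
    schedule: TrainSchedule = TrainSchedule(),
    weights: LossWeights = LossWeights(),
    normalizer: NormalizationSpec | None = None,
    patch_size: int = 256,
    patches_per_image: int = 4,
    augmentation: AugmentationPolicy | None = AugmentationPolicy(),
    base_channels: int = 32,
    width_multiplier: float = 1.0,
    n_res_blocks: int = 4,
    residual: bool = True,
    d_width_multiplier: float | None = None,
    g_updates: int = 1,
    d_updates: int = 1,
    d_warmup_steps: int = 0,
    pool_size: int = 50,
    checkpoint_dir: str | Path | None = None,
    checkpoint_every: int = 0,
    initial_bundle: ModelBundle | None = None,
    start_epoch: int = 0,
    log_fn=None,
) -> tuple[ModelBundle, list[LossReport]]:
    """Alternating adversarial training on unpaired corpora.

    Per batch: one joint update of both generators (adversarial +
    cycle + identity terms), then one update each of D_A and D_B on
    real-vs-generated batches.  The learning rate follows
    :func:`lr_at_epoch`.  Deterministic given ``schedule.seed``.

    Returns the trained bundle and one mean :class:`LossReport` per epoch.
    """
    if not domain_a or not domain_b:
        raise ParameterError("both training domains must be non-empty")
    if normalizer is None:
        normalizer = fit_normalizer(list(domain_a) + list(domain_b))
    rng = np.random.default_rng(schedule.seed)
    if initial_bundle is not None:
        bundle = initial_bundle
        normalizer = bundle.normalizer
        rng.integers(0, 2**31 - 1)  # keep the stream aligned with a fresh run
    else:
        bundle = build_bundle(
            normalizer, weights,
            seed=int(rng.integers(0, 2**31 - 1)),
            base_channels=base_channels,
            width_multiplier=width_multiplier,
            n_res_blocks=n_res_blocks,
            residual=residual,
            d_width_multiplier=d_width_multiplier,
        )
    norm_a = [normalize(img, normalizer) for img in domain_a]
    norm_b = [normalize(img, normalizer) for img in domain_b]
    g_params = bundle.G_A.params + bundle.G_B.params
    opt_g = nn.Adam(g_params, lr=schedule.lr_initial, betas=schedule.betas)
    opt_da = nn.Adam(bundle.D_A.params, lr=schedule.lr_initial, betas=schedule.betas)
    opt_db = nn.Adam(bundle.D_B.params, lr=schedule.lr_initial, betas=schedule.betas)
    pool_a = ImagePool(pool_size, np.random.default_rng(rng.integers(2**31 - 1)))
    pool_b = ImagePool(pool_size, np.random.default_rng(rng.integers(2**31 - 1)))

    lam_c, lam_i = weights.lambda_cyc, weights.lambda_iden

    # Discriminator warmup: with small Gaussian init the discriminators
    # output ~0.5 everywhere and supply no useful gradient; training them
    # alone first (against the untrained, near-identity generators) means
    # the generators face an informative adversary from the first
    # alternating epoch of the short smoke schedule.
    if d_warmup_steps > 0:
        wa = extract_patches(norm_a, patch_size, rng, augmentation,
                             patches_per_image)
        wb = extract_patches(norm_b, patch_size, rng, augmentation,
                             patches_per_image)
        res = bundle.residual
        for step in range(d_warmup_steps):
            ia = rng.choice(len(wa), size=schedule.batch_size, replace=True)
            ib = rng.choice(len(wb), size=schedule.batch_size, replace=True)
            a = np.stack([wa[i].pixels for i in ia])[:, None, :, :]
            b = np.stack([wb[i].pixels for i in ib])[:, None, :, :]
            fake_b, _ = _g_forward(bundle.G_A, a, res)
            fake_a, _ = _g_forward(bundle.G_B, b, res)
            for disc, opt, real, fake, pool in (
                (bundle.D_B, opt_db, b, fake_b, pool_b),
                (bundle.D_A, opt_da, a, fake_a, pool_a),
            ):
                fake_hist = pool.query(fake)
                for _ in range(d_updates):
                    disc.zero_grad()
                    p_real, c_r = disc.forward(real)
                    disc.backward(_log_grad(p_real, -1.0), c_r)
                    p_fake, c_f = disc.forward(fake_hist)
                    disc.backward(_log1m_grad(p_fake, -1.0), c_f)
                    opt.step()

    history: list[LossReport] = []
    for epoch in range(start_epoch, schedule.epochs_total):
        lr = lr_at_epoch(schedule, epoch)
        opt_g.lr = opt_da.lr = opt_db.lr = lr
        pa = extract_patches(norm_a, patch_size, rng, augmentation, patches_per_image)
        pb = extract_patches(norm_b, patch_size, rng, augmentation, patches_per_image)
        rng.shuffle(pa)
        rng.shuffle(pb)
        n_batches = max(1, min(len(pa), len(pb)) // schedule.batch_size)
        acc = np.zeros(8)
        for bi in range(n_batches):
            sl = slice(bi * schedule.batch_size, (bi + 1) * schedule.batch_size)
            a = np.stack([p.pixels for p in pa[sl]])[:, None, :, :]
            b = np.stack([p.pixels for p in pb[sl]])[:, None, :, :]
            step = _train_step(bundle, a, b, lam_c, lam_i,
                               opt_g, opt_da, opt_db, g_updates, d_updates,
                               pool_a, pool_b)
            if not all(math.isfinite(v) for v in step[:4]):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} batch {bi}: {step}"
                )
            acc += np.asarray(step)
        acc /= n_batches
        report = LossReport.assemble(acc[0], acc[1], acc[2], acc[3], weights)
        report.d_real_A, report.d_fake_A = acc[4], acc[5]
        report.d_real_B, report.d_fake_B = acc[6], acc[7]
        history.append(report)
        if log_fn is not None:
            log_fn(epoch, lr, report)
        if checkpoint_dir and checkpoint_every and (epoch + 1) % checkpoint_every == 0:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            bundle.save(Path(checkpoint_dir) / f"checkpoint_epoch{epoch + 1:04d}.npz")
    return bundle, history


def _train_step(bundle, a, b, lam_c, lam_i, opt_g, opt_da, opt_db,
                g_updates, d_updates, pool_a=None, pool_b=None):
    """One alternating update; returns the loss components plus mean
    discriminator probabilities for diagnostics."""
    res = bundle.residual
    G_A, G_B, D_A, D_B = bundle.G_A, bundle.G_B, bundle.D_A, bundle.D_B

    # forward passes (always needed for loss reporting)
    fake_b, c_fb = _g_forward(G_A, a, res)
    fake_a, c_fa = _g_forward(G_B, b, res)
    rec_a, c_ra = _g_forward(G_B, fake_b, res)
    rec_b, c_rb = _g_forward(G_A, fake_a, res)
    idt_b, c_ib = _g_forward(G_A, b, res)
    idt_a, c_ia = _g_forward(G_B, a, res)
    p_fb, c_dfb = D_B.forward(fake_b)
    p_fa, c_dfa = D_A.forward(fake_a)

    g_adv_a = -float(np.mean(np.log(np.clip(p_fb, EPS, 1.0 - EPS))))
    g_adv_b = -float(np.mean(np.log(np.clip(p_fa, EPS, 1.0 - EPS))))
    cyc = cycle_loss(a, rec_a, b, rec_b)
    iden = identity_loss(a, idt_a, b, idt_b)

    if g_updates > 0:
        for net in (G_A, G_B, D_A, D_B):
            net.zero_grad()
        # adversarial branches (gradients flow through the discriminators
        # into the generators; discriminator grads are discarded below)
        d_fake_b = D_B.backward(_log_grad(p_fb, -1.0), c_dfb)
        d_fake_a = D_A.backward(_log_grad(p_fa, -1.0), c_dfa)
        # cycle branches
        d_rec_a = _sign_grad(rec_a, a, lam_c)
        d_fake_b = d_fake_b + _g_backward(G_B, d_rec_a, c_ra, res)
        d_rec_b = _sign_grad(rec_b, b, lam_c)
        d_fake_a = d_fake_a + _g_backward(G_A, d_rec_b, c_rb, res)
        # into the first generators
        _g_backward(G_A, d_fake_b, c_fb, res)
        _g_backward(G_B, d_fake_a, c_fa, res)
        # identity branches
        _g_backward(G_A, _sign_grad(idt_b, b, lam_i), c_ib, res)
        _g_backward(G_B, _sign_grad(idt_a, a, lam_i), c_ia, res)
        opt_g.step()

    d_stats = {"A": (0.5, 0.5), "B": (0.5, 0.5)}
    if d_updates > 0:
        for key, disc, opt, real, fake, pool in (
            ("B", D_B, opt_db, b, fake_b, pool_b),
            ("A", D_A, opt_da, a, fake_a, pool_a),
        ):
            fake_hist = pool.query(fake) if pool is not None else fake
            for _ in range(d_updates):
                disc.zero_grad()
                p_real, c_r = disc.forward(real)
                disc.backward(_log_grad(p_real, -1.0), c_r)
                p_fake, c_f = disc.forward(fake_hist)
                disc.backward(_log1m_grad(p_fake, -1.0), c_f)
                opt.step()
            d_stats[key] = (float(p_real.mean()), float(p_fake.mean()))

    return (g_adv_a, g_adv_b, cyc, iden,
            d_stats["A"][0], d_stats["A"][1], d_stats["B"][0], d_stats["B"][1])


def history_to_csv(history: list[LossReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "adv_A", "adv_B", "cyc", "iden", "total"])
        for i, r in enumerate(history):
            writer.writerow([i, r.adv_A, r.adv_B, r.cyc, r.iden, r.total])
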