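"""Cycle-consistent adversarial domain translation (standard → pocus).

Two ResNet-style generators and two patch discriminators are trained
with least-squares adversarial losses, an L1 cycle-consistency loss
(weight ``lambda_cycle``) and an L1 identity loss (weight
``lambda_identity * lambda_cycle``), with a replay buffer for
discriminator updates and optional linear learning-rate decay over the
second half of training.

Two regimes are supported: ``cyclegan1`` trains a single model on all
classes; ``cyclegan3`` trains one model per class. Translation conserves
the class label and patient id of the source record — the labelling
assumption under which translated images enter classifier training.

Images are single-channel; internally they are normalised to [-1, 1]
and the generators end in tanh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .records import CLASSES, CohortManifest

__all__ = ["CycleGANConfig", "TranslatorPair", "adversarial_loss", "cycle_loss",
           "train_cyclegan", "train_regime", "translate_cohort"]

REGIMES = ("cyclegan1", "cyclegan3")


@dataclass(frozen=True)
class CycleGANConfig:
    generator_width: int = 64          # base filter count (ngf)
    n_residual_blocks: int = 6
    discriminator_depth: int = 3       # strided conv stages in the patch critic
    lambda_cycle: float = 10.0
    lambda_identity: float = 0.5       # multiplier on lambda_cycle
    learning_rate: float = 2e-4
    epochs: int = 200
    image_side: int = 180
    batch_size: int = 1
    replay_buffer: int = 50
    lr_decay: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lambda_cycle <= 0:
            raise ValueError("lambda_cycle must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def desk_cyclegan_config(**overrides) -> CycleGANConfig:
    """Reduced preset (small width, 32 px, raised lr) for CPU-scale runs."""
    defaults = dict(generator_width=8, n_residual_blocks=2, discriminator_depth=2,
                    epochs=20, image_side=32, batch_size=4, learning_rate=8e-4)
    defaults.update(overrides)
    return CycleGANConfig(**defaults)


def _build_generator(cfg: CycleGANConfig, rng) -> _nn.Sequential:
    w = cfg.generator_width
    layers: list[_nn.Layer] = [
        _nn.Conv2d(1, w, 3, stride=1, rng=rng), _nn.InstanceNorm2d(w), _nn.ReLU(),
        _nn.Conv2d(w, 2 * w, 3, stride=2, pad=1, rng=rng), _nn.InstanceNorm2d(2 * w), _nn.ReLU(),
    ]
    for _ in range(cfg.n_residual_blocks):
        layers.append(_nn.Residual(_nn.Sequential(
            _nn.Conv2d(2 * w, 2 * w, 3, rng=rng), _nn.InstanceNorm2d(2 * w), _nn.ReLU(),
            _nn.Conv2d(2 * w, 2 * w, 3, rng=rng), _nn.InstanceNorm2d(2 * w))))
    layers += [
        _nn.UpsampleNearest2(),
        _nn.Conv2d(2 * w, w, 3, rng=rng), _nn.InstanceNorm2d(w), _nn.ReLU(),
        _nn.Conv2d(w, 1, 3, rng=rng, gain=1.0), _nn.Tanh(),
    ]
    return _nn.Sequential(*layers)


def _build_discriminator(cfg: CycleGANConfig, rng) -> _nn.Sequential:
    w = cfg.generator_width
    layers: list[_nn.Layer] = [_nn.Conv2d(1, w, 4, stride=2, pad=1, rng=rng), _nn.LeakyReLU(0.2)]
    cin = w
    for _ in range(cfg.discriminator_depth - 1):
        layers += [_nn.Conv2d(cin, 2 * cin, 4, stride=2, pad=1, rng=rng),
                   _nn.InstanceNorm2d(2 * cin), _nn.LeakyReLU(0.2)]
        cin *= 2
    layers.append(_nn.Conv2d(cin, 1, 4, stride=1, pad=1, rng=rng, gain=1.0))
    return _nn.Sequential(*layers)


@dataclass
class TranslatorPair:
    """The trained generator/discriminator quartet of one model."""

    g_st: _nn.Sequential   # standard -> pocus
    g_ts: _nn.Sequential   # pocus -> standard
    d_s: _nn.Sequential
    d_t: _nn.Sequential
    config: CycleGANConfig
    history: list[dict] = field(default_factory=list)

    def translate(self, pixels: np.ndarray) -> np.ndarray:
        """Map one or more uint8 images standard → pocus."""
        single = pixels.ndim == 2
        batch = pixels[None] if single else pixels
        x = batch.astype(np.float64) / 127.5 - 1.0
        y, _ = self.g_st.forward(x[:, None, :, :], train=False)
        out = np.clip(np.round((y[:, 0] + 1.0) * 127.5), 0, 255).astype(np.uint8)
        return out[0] if single else out

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for name, net in (("g_st", self.g_st), ("g_ts", self.g_ts),
                          ("d_s", self.d_s), ("d_t", self.d_t)):
            for i, p in enumerate(net.params()):
                arrays[f"{name}_{i}"] = p.value
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": asdict(self.config), "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TranslatorPair":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = CycleGANConfig(**sidecar["config"])
        pair = _init_pair(config)
        with np.load(path.with_suffix(".npz")) as data:
            for name, net in (("g_st", pair.g_st), ("g_ts", pair.g_ts),
                              ("d_s", pair.d_s), ("d_t", pair.d_t)):
                for i, p in enumerate(net.params()):
                    p.value[...] = data[f"{name}_{i}"]
        pair.history = sidecar["history"]
        return pair


def _init_pair(config: CycleGANConfig) -> TranslatorPair:
    rng = np.random.default_rng(config.seed)
    return TranslatorPair(_build_generator(config, rng), _build_generator(config, rng),
                          _build_discriminator(config, rng), _build_discriminator(config, rng),
                          config)


# ---------------------------------------------------------------------------
# losses


def adversarial_loss(discriminator_outputs: np.ndarray, is_real: bool) -> float:
    """Least-squares GAN loss: mean squared deviation from the target label."""
    out = np.asarray(discriminator_outputs, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("discriminator outputs must be finite")
    target = 1.0 if is_real else 0.0
    return float(np.mean((out - target) ** 2))


def cycle_loss(original: np.ndarray, reconstructed: np.ndarray,
               lambda_cycle: float) -> float:
    """lambda_cycle times the mean absolute reconstruction error."""
    original = np.asarray(original, dtype=np.float64)
    reconstructed = np.asarray(reconstructed, dtype=np.float64)
    if original.shape != reconstructed.shape:
        raise ValueError(f"shape mismatch {original.shape} vs {reconstructed.shape}")
    return float(lambda_cycle * np.mean(np.abs(original - reconstructed)))


def _mse_grad(out, target):
    return float(np.mean((out - target) ** 2)), 2.0 * (out - target) / out.size


def _l1_grad(a, b, weight):
    diff = a - b
    return float(weight * np.mean(np.abs(diff))), weight * np.sign(diff) / diff.size


class _ReplayBuffer:
    """Image pool that feeds discriminators a mix of current and past fakes."""

    def __init__(self, capacity: int, rng):
        self.capacity = capacity
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.capacity == 0:
            return batch
        out = []
        for img in batch:
            if len(self.items) < self.capacity:
                self.items.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                j = int(self.rng.integers(len(self.items)))
                out.append(self.items[j].copy())
                self.items[j] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


# ---------------------------------------------------------------------------
# training


def _to_net_scale(manifest: CohortManifest, side: int) -> np.ndarray:
    imgs = []
    for r in manifest:
        if r.pixels.shape != (side, side):
            raise ValueError(f"image shape {r.pixels.shape} does not match "
                             f"configured side {side}; preprocess first")
        imgs.append(r.pixels.astype(np.float64) / 127.5 - 1.0)
    return np.stack(imgs)[:, None, :, :]


def train_cyclegan(source_images: CohortManifest, target_images: CohortManifest,
                   config: CycleGANConfig) -> TranslatorPair:
    """Train one translator pair on unpaired source/target cohorts."""
    if len(source_images) == 0 or len(target_images) == 0:
        raise ValueError("both domains must be non-empty")
    a = _to_net_scale(source_images, config.image_side)
    b = _to_net_scale(target_images, config.image_side)
    pair = _init_pair(config)
    rng = np.random.default_rng(config.seed + 101)
    g_params = pair.g_st.params() + pair.g_ts.params()
    d_params = pair.d_s.params() + pair.d_t.params()
    opt_g = _nn.Adam(g_params, lr=config.learning_rate, beta1=0.5)
    opt_d = _nn.Adam(d_params, lr=config.learning_rate, beta1=0.5)
    pool_s = _ReplayBuffer(config.replay_buffer, rng)
    pool_t = _ReplayBuffer(config.replay_buffer, rng)
    lam = config.lambda_cycle
    lam_id = config.lambda_identity * config.lambda_cycle
    probe = a[: min(8, len(a))]
    bs = config.batch_size
    steps = max(len(a), len(b)) // bs or 1

    for epoch in range(config.epochs):
        if config.lr_decay:
            frac = max(0.0, (epoch - config.epochs / 2) / max(1.0, config.epochs / 2))
            lr = config.learning_rate * (1.0 - frac)
            opt_g.lr = opt_d.lr = lr
        ia = rng.permutation(len(a))
        ib = rng.permutation(len(b))
        tot = {"g_adv": 0.0, "cycle": 0.0, "identity": 0.0, "d": 0.0}
        for step in range(steps):
            real_a = a[np.take(ia, np.arange(step * bs, (step + 1) * bs), mode="wrap")]
            real_b = b[np.take(ib, np.arange(step * bs, (step + 1) * bs), mode="wrap")]

            # ---- generator update ----
            opt_g.zero_grad()
            opt_d.zero_grad()
            fake_b, c_gab = pair.g_st.forward(real_a, train=True)
            fake_a, c_gba = pair.g_ts.forward(real_b, train=True)
            rec_a, c_rec_a = pair.g_ts.forward(fake_b, train=True)
            rec_b, c_rec_b = pair.g_st.forward(fake_a, train=True)
            id_b, c_id_b = pair.g_st.forward(real_b, train=True)
            id_a, c_id_a = pair.g_ts.forward(real_a, train=True)
            dt_fake, c_dt = pair.d_t.forward(fake_b, train=True)
            ds_fake, c_ds = pair.d_s.forward(fake_a, train=True)

            l_adv_t, g_adv_t = _mse_grad(dt_fake, 1.0)
            l_adv_s, g_adv_s = _mse_grad(ds_fake, 1.0)
            l_cyc_a, g_cyc_a = _l1_grad(rec_a, real_a, lam)
            l_cyc_b, g_cyc_b = _l1_grad(rec_b, real_b, lam)
            l_id_b, g_id_b = _l1_grad(id_b, real_b, lam_id)
            l_id_a, g_id_a = _l1_grad(id_a, real_a, lam_id)

            d_fake_b = pair.d_t.backward(g_adv_t, c_dt)       # adversarial pull
            d_fake_b += pair.g_ts.backward(g_cyc_a, c_rec_a)  # cycle pull
            pair.g_st.backward(d_fake_b, c_gab)
            d_fake_a = pair.d_s.backward(g_adv_s, c_ds)
            d_fake_a += pair.g_st.backward(g_cyc_b, c_rec_b)
            pair.g_ts.backward(d_fake_a, c_gba)
            pair.g_st.backward(g_id_b, c_id_b)
            pair.g_ts.backward(g_id_a, c_id_a)
            opt_g.step()

            # ---- discriminator update (replay-buffered fakes) ----
            opt_g.zero_grad()
            opt_d.zero_grad()
            l_d = 0.0
            for disc, real, fake, pool in ((pair.d_t, real_b, fake_b, pool_t),
                                           (pair.d_s, real_a, fake_a, pool_s)):
                out_r, c_r = disc.forward(real, train=True)
                lr_, gr = _mse_grad(out_r, 1.0)
                disc.backward(0.5 * gr, c_r)
                out_f, c_f = disc.forward(pool.query(fake), train=True)
                lf_, gf = _mse_grad(out_f, 0.0)
                disc.backward(0.5 * gf, c_f)
                l_d += 0.5 * (lr_ + lf_)
            opt_d.step()

            tot["g_adv"] += l_adv_t + l_adv_s
            tot["cycle"] += l_cyc_a + l_cyc_b
            tot["identity"] += l_id_b + l_id_a
            tot["d"] += l_d
        record = {k: v / steps for k, v in tot.items()}
        if not all(np.isfinite(v) for v in record.values()):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}: "
                                     f"history={pair.history + [record]}")
        fb, _ = pair.g_st.forward(probe, train=False)
        ra, _ = pair.g_ts.forward(fb, train=False)
        record["probe_cycle_l1"] = float(np.mean(np.abs(ra - probe)))
        record["probe_mean_darkening"] = float(np.mean(probe) - np.mean(fb))
        record["epoch"] = epoch
        pair.history.append(record)
    return pair


def train_regime(manifest: CohortManifest, config: CycleGANConfig,
                 regime: str) -> dict[str, TranslatorPair]:
    """Train translators under a regime; returns a class → pair map.

    cyclegan1: one pair on all classes, shared by every class key.
    cyclegan3: one independently seeded pair per class.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    source = manifest.filter(domain="standard")
    target = manifest.filter(domain="pocus")
    if regime == "cyclegan1":
        pair = train_cyclegan(source, target, config)
        return {c: pair for c in CLASSES}
    out = {}
    for i, c in enumerate(CLASSES):
        src_c = source.filter(class_label=c)
        tgt_c = target.filter(class_label=c)
        if len(src_c) == 0 or len(tgt_c) == 0:
            raise ValueError(f"class {c!r} missing from a domain; cyclegan3 "
                             "requires every class in both domains")
        cfg_c = CycleGANConfig(**{**asdict(config), "seed": config.seed + 7 * (i + 1)})
        out[c] = train_cyclegan(src_c, tgt_c, cfg_c)
    return out


def translate_cohort(manifest: CohortManifest, translators: dict[str, TranslatorPair],
                     regime_tag: str = "cyclegan1", batch_size: int = 16) -> CohortManifest:
    """Translate every standard-domain record, conserving label and patient id."""
    standard = [r for r in manifest if r.domain == "standard"]
    missing = {r.class_label for r in standard} - set(translators)
    if missing:
        raise ValueError(f"no translator for class(es) {sorted(missing)}")
    from dataclasses import replace

    out: list = [None] * len(standard)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(standard):
        by_class.setdefault(r.class_label, []).append(i)
    for c, indices in by_class.items():
        pair = translators[c]
        for start in range(0, len(indices), batch_size):
            chunk = indices[start: start + batch_size]
            batch = np.stack([standard[i].pixels for i in chunk])
            translated = pair.translate(batch)
            for i, px in zip(chunk, translated):
                out[i] = replace(standard[i], pixels=px, domain="translated",
                                 provenance=regime_tag)
    return CohortManifest(out)
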