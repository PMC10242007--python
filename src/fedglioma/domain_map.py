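"""Unpaired two-domain intensity mapping between imaging sites (toy scale).

Different scanners shift image intensity statistics between sites; an
unpaired cycle-consistent pair of generators learns to map one site's
preprocessed 2D slices into the intensity domain of a chosen target site
while the discriminators tell mapped from real target images apart.  The
objective is

    L = L_GAN(to_target, D_target) + L_GAN(to_source, D_source)
        + lambda * L_cyc(to_source, to_target)

with least-squares GAN terms and an L1 cycle-consistency loss; the round-trip
constraint keeps the mapping invertible, hence label-preserving.  Generators
are residual 3-layer 3x3 conv nets (output = input + learned correction),
discriminators are small conv nets with a scalar score head; both are trained
with Adam.  Only the source site is mapped; the target site passes through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _layers as L
from .params import ParameterSet
from .preprocess import SliceDataset

__all__ = [
    "MapperConfig", "MapperPair", "cycle_loss", "gan_losses",
    "total_objective", "train_mapper", "map_dataset", "DomainMapper",
    "intensity_histogram_distance",
]


@dataclass(frozen=True)
class MapperConfig:
    lambda_cyc: float = 10.0
    hidden_channels: int = 8
    epochs: int = 20
    learning_rate: float = 2e-3
    batch_size: int = 16
    target_site: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lambda_cyc < 0:
            raise ValueError("lambda_cyc must be nonnegative")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid mapper training configuration")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _init_generator(rng, channels: int, hidden: int) -> ParameterSet:
    return ParameterSet({
        "conv1_W": L.he_conv(rng, hidden, channels),
        "conv1_b": np.zeros(hidden),
        "conv2_W": L.he_conv(rng, hidden, hidden),
        "conv2_b": np.zeros(hidden),
        # last layer starts near zero so the initial map is near-identity
        "conv3_W": 0.01 * L.he_conv(rng, channels, hidden),
        "conv3_b": np.zeros(channels),
    })


def _init_discriminator(rng, channels: int, hidden: int) -> ParameterSet:
    return ParameterSet({
        "conv1_W": L.he_conv(rng, hidden, channels),
        "conv1_b": np.zeros(hidden),
        "conv2_W": L.he_conv(rng, hidden, hidden),
        "conv2_b": np.zeros(hidden),
        "head_W": L.he_dense(rng, hidden, 1),
        "head_b": np.zeros(1),
    })


def generator_forward(p: ParameterSet, x: np.ndarray):
    """Residual generator: y = x + conv3(relu(conv2(relu(conv1(x)))))."""
    h1, c1 = L.conv2d(x, p["conv1_W"], p["conv1_b"])
    r1, m1 = L.relu(h1)
    h2, c2 = L.conv2d(r1, p["conv2_W"], p["conv2_b"])
    r2, m2 = L.relu(h2)
    t, c3 = L.conv2d(r2, p["conv3_W"], p["conv3_b"])
    return x + t, (c1, m1, c2, m2, c3)


def generator_backward(cache, dy):
    c1, m1, c2, m2, c3 = cache
    dr2, dW3, db3 = L.conv2d_backward(c3, dy)
    dh2 = L.relu_backward(m2, dr2)
    dr1, dW2, db2 = L.conv2d_backward(c2, dh2)
    dh1 = L.relu_backward(m1, dr1)
    dx_conv, dW1, db1 = L.conv2d_backward(c1, dh1)
    grads = ParameterSet({"conv1_W": dW1, "conv1_b": db1,
                          "conv2_W": dW2, "conv2_b": db2,
                          "conv3_W": dW3, "conv3_b": db3})
    return grads, dy + dx_conv


def discriminator_forward(p: ParameterSet, x: np.ndarray):
    """Scalar realness score per image."""
    h1, c1 = L.conv2d(x, p["conv1_W"], p["conv1_b"])
    r1, m1 = L.relu(h1)
    pooled, cp = L.avgpool2(r1)
    h2, c2 = L.conv2d(pooled, p["conv2_W"], p["conv2_b"])
    r2, m2 = L.relu(h2)
    feat, cg = L.global_avg_pool(r2)
    score, cd = L.dense(feat, p["head_W"], p["head_b"])
    return score[:, 0], (c1, m1, cp, c2, m2, cg, cd)


def discriminator_backward(cache, dscore):
    c1, m1, cp, c2, m2, cg, cd = cache
    dfeat, dWh, dbh = L.dense_backward(cd, dscore[:, None])
    dr2 = L.global_avg_pool_backward(cg, dfeat)
    dh2 = L.relu_backward(m2, dr2)
    dpool, dW2, db2 = L.conv2d_backward(c2, dh2)
    dr1 = L.avgpool2_backward(cp, dpool)
    dh1 = L.relu_backward(m1, dr1)
    dx, dW1, db1 = L.conv2d_backward(c1, dh1)
    grads = ParameterSet({"conv1_W": dW1, "conv1_b": db1,
                          "conv2_W": dW2, "conv2_b": db2,
                          "head_W": dWh, "head_b": dbh})
    return grads, dx


@dataclass
class MapperPair:
    """Two generators and two discriminators tying the domains together."""

    to_target: ParameterSet      # maps source-domain images toward the target
    to_source: ParameterSet      # maps target-domain images back
    disc_source: ParameterSet
    disc_target: ParameterSet
    config: MapperConfig = field(default_factory=MapperConfig)

    def map_to_target(self, x: np.ndarray) -> np.ndarray:
        y, _ = generator_forward(
            self.to_target, np.asarray(x, dtype=self.to_target.dtype))
        return y

    def map_to_source(self, x: np.ndarray) -> np.ndarray:
        y, _ = generator_forward(
            self.to_source, np.asarray(x, dtype=self.to_source.dtype))
        return y


def init_mapper(channels: int = 2, cfg: MapperConfig = MapperConfig(),
                dtype=np.float64) -> MapperPair:
    rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden_channels
    return MapperPair(
        to_target=_init_generator(rng, channels, h).astype(dtype),
        to_source=_init_generator(rng, channels, h).astype(dtype),
        disc_source=_init_discriminator(rng, channels, h).astype(dtype),
        disc_target=_init_discriminator(rng, channels, h).astype(dtype),
        config=cfg)


# ---------------------------------------------------------------------------
# objective pieces (generator/discriminator arguments are plain callables so
# the pieces can be checked against hand arithmetic)
# ---------------------------------------------------------------------------

def cycle_loss(g_to_source, g_to_target, batch_src: np.ndarray,
               batch_tgt: np.ndarray) -> float:
    """Mean L1 round-trip error: source -> target -> source plus
    target -> source -> target."""
    if len(batch_src) == 0 or len(batch_tgt) == 0:
        raise ValueError("cycle_loss requires nonempty batches")
    rec_src = g_to_source(g_to_target(batch_src))
    rec_tgt = g_to_target(g_to_source(batch_tgt))
    return float(np.mean(np.abs(batch_src - rec_src))
                 + np.mean(np.abs(batch_tgt - rec_tgt)))


def gan_losses(d, real_batch: np.ndarray, fake_batch: np.ndarray):
    """Least-squares GAN terms.

    L_D = mean((D(real) - 1)^2) + mean(D(fake)^2);
    L_G = mean((D(fake) - 1)^2).
    """
    d_real = np.asarray(d(real_batch), dtype=float)
    d_fake = np.asarray(d(fake_batch), dtype=float)
    l_d = float(np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2))
    l_g = float(np.mean((d_fake - 1.0) ** 2))
    return l_d, l_g


def total_objective(pair: MapperPair, batch_src: np.ndarray,
                    batch_tgt: np.ndarray,
                    cfg: MapperConfig | None = None) -> float:
    """Full mapping objective: both generator GAN terms plus the weighted
    cycle term."""
    cfg = pair.config if cfg is None else cfg
    g_st, g_ts = pair.map_to_target, pair.map_to_source

    def d_src(x):
        return discriminator_forward(pair.disc_source, x)[0]

    def d_tgt(x):
        return discriminator_forward(pair.disc_target, x)[0]

    _, l_g_tgt = gan_losses(d_tgt, batch_tgt, g_st(batch_src))
    _, l_g_src = gan_losses(d_src, batch_src, g_ts(batch_tgt))
    return l_g_tgt + l_g_src + cfg.lambda_cyc * cycle_loss(
        g_ts, g_st, batch_src, batch_tgt)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_images(data) -> np.ndarray:
    if isinstance(data, SliceDataset):
        return data.images
    return np.asarray(data, dtype=np.float64)


def train_mapper(source, target, cfg: MapperConfig = MapperConfig()):
    """Alternate discriminator/generator Adam updates for cfg.epochs.

    ``source`` / ``target`` are SliceDatasets or (N, C, H, W) arrays.
    Deterministic for a given cfg.seed.  Returns the trained MapperPair.
    """
    xs, xt = _as_images(source), _as_images(target)
    if len(xs) < cfg.batch_size or len(xt) < cfg.batch_size:
        raise ValueError("each domain needs at least batch_size images")
    xs = xs.astype(np.float32)
    xt = xt.astype(np.float32)
    pair = init_mapper(channels=xs.shape[1], cfg=cfg, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    opt = {k: L.Adam(getattr(pair, k), lr=cfg.learning_rate)
           for k in ("to_target", "to_source", "disc_source", "disc_target")}
    steps_per_epoch = max(len(xs) // cfg.batch_size, 1)
    for _ in range(cfg.epochs):
        src_order = rng.permutation(len(xs))
        tgt_order = rng.permutation(len(xt))
        for step in range(steps_per_epoch):
            bs = cfg.batch_size
            take = np.arange(step * bs, (step + 1) * bs)
            x = xs[src_order[take % len(xs)]]
            y = xt[tgt_order[take % len(xt)]]
            _train_step(pair, opt, x, y, cfg)
    return pair


def _lsgan_d_grads(d_params, real, fake):
    """Discriminator LSGAN gradient: push D(real) to 1 and D(fake) to 0."""
    s_r, cache_r = discriminator_forward(d_params, real)
    s_f, cache_f = discriminator_forward(d_params, fake)
    g_r, _ = discriminator_backward(cache_r, 2.0 * (s_r - 1.0) / len(s_r))
    g_f, _ = discriminator_backward(cache_f, 2.0 * s_f / len(s_f))
    return g_r + g_f


def _train_step(pair: MapperPair, opt, x, y, cfg: MapperConfig):
    # --- discriminators (generators detached) ---
    fake_t, _ = generator_forward(pair.to_target, x)
    fake_s, _ = generator_forward(pair.to_source, y)
    pair.disc_target = opt["disc_target"].step(
        pair.disc_target, _lsgan_d_grads(pair.disc_target, y, fake_t))
    pair.disc_source = opt["disc_source"].step(
        pair.disc_source, _lsgan_d_grads(pair.disc_source, x, fake_s))

    # --- generators (discriminators frozen) ---
    fake_t, cache_st = generator_forward(pair.to_target, x)
    fake_s, cache_ts = generator_forward(pair.to_source, y)
    rec_s, cache_rec_s = generator_forward(pair.to_source, fake_t)
    rec_t, cache_rec_t = generator_forward(pair.to_target, fake_s)

    g_st = pair.to_target.zeros_like()
    g_ts = pair.to_source.zeros_like()

    # GAN terms: mean((D(fake) - 1)^2)
    s_t, dc_t = discriminator_forward(pair.disc_target, fake_t)
    _, dfake_t = discriminator_backward(dc_t, 2.0 * (s_t - 1.0) / len(s_t))
    s_s, dc_s = discriminator_forward(pair.disc_source, fake_s)
    _, dfake_s = discriminator_backward(dc_s, 2.0 * (s_s - 1.0) / len(s_s))

    # cycle terms: lambda * mean |x - rec|
    drec_s = cfg.lambda_cyc * np.sign(rec_s - x) / rec_s.size
    drec_t = cfg.lambda_cyc * np.sign(rec_t - y) / rec_t.size
    grads_ts_rec, dfake_t_cyc = generator_backward(cache_rec_s, drec_s)
    grads_st_rec, dfake_s_cyc = generator_backward(cache_rec_t, drec_t)
    g_ts = g_ts + grads_ts_rec
    g_st = g_st + grads_st_rec

    grads_st, _ = generator_backward(cache_st, dfake_t + dfake_t_cyc)
    grads_ts, _ = generator_backward(cache_ts, dfake_s + dfake_s_cyc)
    g_st = g_st + grads_st
    g_ts = g_ts + grads_ts

    pair.to_target = opt["to_target"].step(pair.to_target, g_st)
    pair.to_source = opt["to_source"].step(pair.to_source, g_ts)


def map_dataset(mapper, dataset: SliceDataset,
                batch_size: int = 128) -> SliceDataset:
    """Map a site's slices toward the target domain.

    ``mapper`` is a MapperPair (its ``to_target`` generator is used) or any
    callable on image stacks.  Outputs are clipped to [0, 1]; labels, patient
    ids, views and slice indices are untouched.
    """
    fn = mapper.map_to_target if isinstance(mapper, MapperPair) else mapper
    mapped = np.concatenate([
        np.asarray(fn(dataset.images[i:i + batch_size]), dtype=np.float64)
        for i in range(0, len(dataset), batch_size)])
    return dataset.replace_images(np.clip(mapped, 0.0, 1.0))


def intensity_histogram_distance(a: np.ndarray, b: np.ndarray,
                                 bins: int = 32) -> float:
    """L1 distance between normalized pixel-intensity histograms on [0, 1]."""
    ha, _ = np.histogram(np.ravel(a), bins=bins, range=(0.0, 1.0))
    hb, _ = np.histogram(np.ravel(b), bins=bins, range=(0.0, 1.0))
    ha = ha / max(ha.sum(), 1)
    hb = hb / max(hb.sum(), 1)
    return float(np.abs(ha - hb).sum())


# ---------------------------------------------------------------------------
# Model / Results front door
# ---------------------------------------------------------------------------

@dataclass
class MapperResults:
    pair: MapperPair
    config: MapperConfig

    def transform(self, dataset: SliceDataset) -> SliceDataset:
        return map_dataset(self.pair, dataset)

    def summary(self) -> str:
        return "\n".join([
            "Domain mapper fit", "=" * 40,
            f"lambda_cyc       : {self.config.lambda_cyc}",
            f"epochs           : {self.config.epochs}",
            f"generator params : {self.pair.to_target.n_parameters} x 2",
            f"discrim. params  : {self.pair.disc_target.n_parameters} x 2",
        ])


class DomainMapper:
    """Unpaired source->target intensity harmonizer for slice datasets."""

    def __init__(self, source: SliceDataset, target: SliceDataset,
                 config: MapperConfig = MapperConfig()):
        self.source = source
        self.target = target
        self.config = config

    def fit(self) -> MapperResults:
        pair = train_mapper(self.source, self.target, self.config)
        return MapperResults(pair=pair, config=self.config)
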