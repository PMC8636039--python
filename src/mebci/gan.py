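"""Conditional GAN converting simulated scalp EEG into "practical" EEG.

The generator receives a whole simulated trial (timestamps x channels) plus
a one-hot class label embedded as an extra channel, and outputs a converted
trial of the same shape bounded by tanh. The discriminator judges short
(100 ms) windows, also label-conditioned. Training alternates: (1) the
discriminator learns to separate real template windows from sliced
generator outputs; (2) the discriminator is frozen and the stacked
generator->slicer->discriminator is trained against the "real" target.

Everything is plain numpy (see :mod:`mebci.nn`), deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mebci.nn import (
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    RMSprop,
    Sequential,
    Sigmoid,
    Tanh,
    bce_grad,
    binary_cross_entropy,
)
from mebci.pipeline import CLASSES, TrialSet, WindowBatch

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "ConditionalNet",
    "build_generator",
    "build_discriminator",
    "embed_label",
    "slice_trialset",
    "train_gan",
    "convert",
    "TrainedConverter",
    "MinMaxNorm",
]


@dataclass(frozen=True)
class GeneratorSpec:
    timestamps: int
    channels: int
    n_classes: int = 4
    filters: tuple[int, ...] = (64, 52, 42, 36, -1)  # -1 -> channels
    kernels: tuple[int, ...] = (64, 32, 16, 6, 2)
    leaky_alpha: float = 0.2

    def resolved_filters(self) -> tuple[int, ...]:
        return tuple(self.channels if f == -1 else f for f in self.filters)

    def validate(self) -> None:
        if len(self.filters) != 5 or len(self.kernels) != 5:
            raise ValueError("generator requires five 1-D convolutions")
        if self.resolved_filters()[-1] != self.channels:
            raise ValueError("final filter count must equal channel count")
        if self.timestamps < max(self.kernels):
            raise ValueError("timestamps shorter than the largest kernel")


@dataclass(frozen=True)
class DiscriminatorSpec:
    window: int
    channels: int
    n_classes: int = 4
    filters: tuple[int, ...] = (16, 8, 4, 2)
    kernels: tuple[int, ...] = (32, 16, 8, 4)
    dropout: float = 0.4
    leaky_alpha: float = 0.2

    def validate(self) -> None:
        if len(self.filters) != 4 or len(self.kernels) != 4:
            raise ValueError("discriminator requires four 1-D convolutions")
        if self.window <= sum(k - 1 for k in self.kernels):
            raise ValueError("window too short for the valid-padding stack")


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 200
    d_learning_rate: float = 0.0008
    g_learning_rate: float = 0.0004
    clip_value: float = 1.0
    decay: float = 1e-8
    batch_size: int = 64  # discriminator windows per update (half real/half fake)
    gen_batch: int = 8  # trials per stacked-generator update
    window_len: int = 100
    seed: int = 0
    # update pacing (how many updates each network receives per iteration is
    # not fixed by the published tables): the discriminator trains on
    # iterations divisible by d_interval, the generator on iterations
    # divisible by g_interval
    d_interval: int = 1
    g_interval: int = 1
    # fraction of the fake half-batch drawn from raw (unconverted) simulated
    # windows; anchoring the discriminator on the source domain keeps it from
    # merely fingerprinting generator artifacts and gives the generator a
    # consistent sim-to-real direction to move along
    sim_negatives: float = 0.5

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.d_learning_rate <= 0 or self.g_learning_rate <= 0:
            raise ValueError("learning rates must be > 0")


class ConditionalNet:
    """Label-conditioned network: Dense label embedding as an extra channel.

    The label branch (Dense -> LeakyReLU -> reshape to (length, 1)) is
    concatenated with the signal along the channel axis and fed to the
    convolutional trunk.
    """

    def __init__(self, n_classes: int, length: int, trunk: Sequential,
                 rng: np.random.Generator, alpha: float = 0.2,
                 dtype=np.float64) -> None:
        self.length = length
        self.n_classes = n_classes
        self.dtype = dtype
        self.label_dense = Dense(n_classes, length, rng, dtype=dtype)
        self.label_act = LeakyReLU(alpha)
        self.trunk = trunk

    def embed_label(self, one_hot: np.ndarray) -> np.ndarray:
        one_hot = np.asarray(one_hot, dtype=float)
        if one_hot.ndim == 1:
            one_hot = one_hot[None, :]
        row_sums = one_hot.sum(axis=1)
        if not (
            np.allclose(row_sums, 1.0)
            and np.all((one_hot == 0) | (one_hot == 1))
        ):
            raise ValueError("labels must be one-hot")
        h = self.label_act.forward(self.label_dense.forward(one_hot))
        return h[:, :, None]  # (batch, length, 1)

    def forward(self, signal: np.ndarray, one_hot: np.ndarray,
                training: bool = False) -> np.ndarray:
        emb = self.embed_label(one_hot)
        x = np.concatenate([emb, signal], axis=2)
        return self.trunk.forward(x, training=training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop; returns gradient w.r.t. the signal input."""
        dx = self.trunk.backward(dout)
        demb, dsignal = dx[:, :, :1], dx[:, :, 1:]
        dlab = self.label_act.backward(demb[:, :, 0])
        self.label_dense.backward(dlab)
        return dsignal

    def zero_grad(self) -> None:
        self.label_dense.zero_grad()
        self.trunk.zero_grad()

    def parameters(self):
        out = [
            ("label:W", self.label_dense.params["W"], self.label_dense.grads["W"]),
            ("label:b", self.label_dense.params["b"], self.label_dense.grads["b"]),
        ]
        out += [("trunk:" + n, p, g) for n, p, g in self.trunk.parameters()]
        return out

    def state_dict(self):
        return {n: p.copy() for n, p, _ in self.parameters()}

    def load_state_dict(self, state):
        for n, p, _ in self.parameters():
            p[...] = state[n]


def embed_label(net: ConditionalNet, one_hot: np.ndarray) -> np.ndarray:
    """Embedded label channel of shape (batch, length, 1)."""
    return net.embed_label(one_hot)


def build_generator(spec: GeneratorSpec, seed: int = 0,
                    dtype=np.float64, init: str = "passthrough") -> ConditionalNet:
    """Construct the conditional generator.

    ``init="passthrough"`` biases every convolution toward copying its first
    ``channels`` input channels at the central tap (damped random weights
    elsewhere), so an untrained converter starts close to the identity on the
    signal channels and adversarial training only has to learn the
    *adjustment* toward the template statistics. This keeps the class
    structure of the simulated input intact at desk-scale training budgets.
    ``init="glorot"`` is the plain random initialization.
    """
    spec.validate()
    if init not in ("passthrough", "glorot"):
        raise ValueError("init must be 'passthrough' or 'glorot'")
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = spec.channels + 1
    filters = spec.resolved_filters()
    for i, (f, k) in enumerate(zip(filters, spec.kernels)):
        conv = Conv1D(c_in, f, k, rng, padding="same", dtype=dtype)
        if init == "passthrough":
            conv.params["W"] *= 0.003
            center = (k - 1) // 2
            last = i == len(filters) - 1
            for j in range(min(f, spec.channels)):
                src = j + 1 if i == 0 else j  # skip the label channel once
                if src < c_in:
                    conv.params["W"][center * c_in + src, j] += 1.0
                    # keep passthrough channels in LeakyReLU's linear
                    # (positive) region: shift up at entry, remove at exit
                    if i == 0:
                        conv.params["b"][j] += 1.5
                    if last:
                        conv.params["b"][j] -= 1.5
        layers.append(conv)
        layers.append(Tanh() if i == len(filters) - 1 else LeakyReLU(spec.leaky_alpha))
        c_in = f
    return ConditionalNet(
        spec.n_classes, spec.timestamps, Sequential(layers), rng,
        spec.leaky_alpha, dtype,
    )


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0,
                        dtype=np.float64) -> ConditionalNet:
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = spec.channels + 1
    length = spec.window
    for f, k in zip(spec.filters, spec.kernels):
        layers.append(Conv1D(c_in, f, k, rng, padding="valid", dtype=dtype))
        layers.append(LeakyReLU(spec.leaky_alpha))
        c_in = f
        length = length - k + 1
    layers.append(Flatten())
    layers.append(Dropout(spec.dropout, rng))
    layers.append(Dense(length * c_in, 1, rng, dtype=dtype))
    layers.append(Sigmoid())
    return ConditionalNet(
        spec.n_classes, spec.window, Sequential(layers), rng,
        spec.leaky_alpha, dtype,
    )


@dataclass(frozen=True)
class MinMaxNorm:
    """Min-max map onto (-1, 1).

    Global (scalar) by default: a single lo/hi over all channels, so the
    relative channel amplitudes — the spatial signature the classifier
    relies on — survive the round trip sim-scale -> (-1,1) -> real-scale.
    Per-channel scaling is available but rescales every channel onto every
    other channel's range, which erases exactly that structure whenever the
    simulated and real channel ranges differ.
    """

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, data: np.ndarray, per_channel: bool = False) -> "MinMaxNorm":
        if per_channel:
            lo = data.min(axis=(0, 1))
            hi = data.max(axis=(0, 1))
            span = hi - lo
            span[span == 0] = 1.0
            return cls(lo, lo + span)
        lo = np.asarray(data.min())
        hi = np.asarray(data.max())
        if hi == lo:
            hi = lo + 1.0
        return cls(lo, hi)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return (x + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


def slice_trialset(ts: TrialSet, window_len: int = 100,
                   stride: int | None = None, source: str = "real") -> WindowBatch:
    """Non-overlapping (by default) windows inheriting their trial's label."""
    from mebci.pipeline import slice_windows

    return slice_windows(ts, window_len, stride, source=source)


def _one_hot(labels, classes=CLASSES) -> np.ndarray:
    idx = np.array([classes.index(l) for l in labels])
    out = np.zeros((len(idx), len(classes)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


@dataclass
class TrainedConverter:
    generator: ConditionalNet
    discriminator: ConditionalNet
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    config: TrainConfig
    norm_real: MinMaxNorm
    norm_sim: MinMaxNorm
    classes: tuple[str, ...] = CLASSES
    loss_history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, path) -> None:
        import json

        import h5py

        meta = {
            "gen_spec": vars(self.gen_spec) | {"filters": list(self.gen_spec.filters),
                                               "kernels": list(self.gen_spec.kernels)},
            "disc_spec": vars(self.disc_spec) | {
                "filters": list(self.disc_spec.filters),
                "kernels": list(self.disc_spec.kernels),
            },
            "config": vars(self.config),
            "classes": list(self.classes),
        }
        with h5py.File(path, "w") as f:
            f.attrs["meta"] = json.dumps(meta)
            for group, net in (("generator", self.generator),
                               ("discriminator", self.discriminator)):
                g = f.create_group(group)
                for name, arr in net.state_dict().items():
                    g.create_dataset(name.replace("/", "_"), data=arr)
            n = f.create_group("norm")
            n.create_dataset("real_lo", data=self.norm_real.lo)
            n.create_dataset("real_hi", data=self.norm_real.hi)
            n.create_dataset("sim_lo", data=self.norm_sim.lo)
            n.create_dataset("sim_hi", data=self.norm_sim.hi)
            h = f.create_group("loss")
            for k, v in self.loss_history.items():
                h.create_dataset(k, data=np.asarray(v))

    @classmethod
    def load(cls, path) -> "TrainedConverter":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            gen_spec = GeneratorSpec(**{
                **meta["gen_spec"],
                "filters": tuple(meta["gen_spec"]["filters"]),
                "kernels": tuple(meta["gen_spec"]["kernels"]),
            })
            disc_spec = DiscriminatorSpec(**{
                **meta["disc_spec"],
                "filters": tuple(meta["disc_spec"]["filters"]),
                "kernels": tuple(meta["disc_spec"]["kernels"]),
            })
            cfg = TrainConfig(**meta["config"])
            gen = build_generator(gen_spec, cfg.seed)
            disc = build_discriminator(disc_spec, cfg.seed + 1)
            gen.load_state_dict({k: f["generator"][k][...] for k in f["generator"]})
            disc.load_state_dict(
                {k: f["discriminator"][k][...] for k in f["discriminator"]}
            )
            norm_real = MinMaxNorm(f["norm"]["real_lo"][...], f["norm"]["real_hi"][...])
            norm_sim = MinMaxNorm(f["norm"]["sim_lo"][...], f["norm"]["sim_hi"][...])
            loss = {k: list(f["loss"][k][...]) for k in f["loss"]}
        return cls(gen, disc, gen_spec, disc_spec, cfg, norm_real, norm_sim,
                   tuple(meta["classes"]), loss)

    def export_loss_history(self, path) -> None:
        keys = sorted(self.loss_history)
        rows = zip(*(self.loss_history[k] for k in keys))
        lines = ["iteration\t" + "\t".join(keys)]
        lines += [
            f"{i}\t" + "\t".join(f"{v:.6f}" for v in row)
            for i, row in enumerate(rows)
        ]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def train_gan(
    simulated: TrialSet,
    real_templates: TrialSet,
    cfg: TrainConfig = TrainConfig(),
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    classes=CLASSES,
) -> TrainedConverter:
    """Adversarial training of the converter; see module docstring.

    Raises on NaN losses. Deterministic for a fixed config seed.
    """
    if simulated.n_channels != real_templates.n_channels:
        raise ValueError("simulated and real template channel counts differ")
    if simulated.fs != real_templates.fs:
        raise ValueError("sampling rates differ")
    timestamps = simulated.data.shape[1]
    channels = simulated.n_channels
    if gen_spec is None:
        gen_spec = GeneratorSpec(timestamps, channels, len(classes))
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(cfg.window_len, channels, len(classes))
    gen = build_generator(gen_spec, cfg.seed, dtype=np.float32)
    disc = build_discriminator(disc_spec, cfg.seed + 1, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed + 2)

    norm_real = MinMaxNorm.fit(real_templates.data)
    norm_sim = MinMaxNorm.fit(simulated.data)
    sim_scaled = norm_sim.transform(simulated.data).astype(np.float32)
    sim_onehot = _one_hot(simulated.labels, classes)
    real_wb = slice_trialset(real_templates, cfg.window_len)
    real_windows = norm_real.transform(real_wb.windows).astype(np.float32)
    real_onehot = _one_hot(real_wb.labels, classes)

    opt_d = RMSprop(cfg.d_learning_rate, clipvalue=cfg.clip_value, decay=cfg.decay)
    opt_g = RMSprop(cfg.g_learning_rate, clipvalue=cfg.clip_value, decay=cfg.decay)
    w = cfg.window_len
    half = max(1, cfg.batch_size // 2)
    history: dict[str, list[float]] = {"d_loss": [], "g_loss": []}

    for it in range(cfg.iterations):
        # --- discriminator update on half real / half fake windows
        # fakes come from a few generated trials, several windows each,
        # to keep the full-trial generator passes affordable
        ri = rng.integers(0, len(real_windows), size=half)
        n_sim_neg = int(round(cfg.sim_negatives * half))
        n_fake = half - n_sim_neg
        n_gen = min(max(1, cfg.gen_batch), simulated.n_trials, max(n_fake, 1))
        gi_d = rng.integers(0, simulated.n_trials, size=n_gen)
        fake_full = gen.forward(sim_scaled[gi_d], sim_onehot[gi_d])
        src = rng.integers(0, n_gen, size=n_fake)
        offs = rng.integers(0, timestamps - w + 1, size=n_fake)
        fake_windows = np.stack(
            [fake_full[s, o: o + w, :] for s, o in zip(src, offs)]
        ) if n_fake else np.empty((0, w, fake_full.shape[2]), dtype=np.float32)
        # raw simulated windows as additional negatives
        si = rng.integers(0, simulated.n_trials, size=n_sim_neg)
        soffs = rng.integers(0, timestamps - w + 1, size=n_sim_neg)
        sim_neg = np.stack(
            [sim_scaled[t, o: o + w, :] for t, o in zip(si, soffs)]
        ) if n_sim_neg else np.empty((0, w, sim_scaled.shape[2]),
                                     dtype=np.float32)
        x = np.concatenate([real_windows[ri], fake_windows, sim_neg], axis=0)
        oh = np.concatenate(
            [real_onehot[ri], sim_onehot[gi_d[src]], sim_onehot[si]], axis=0
        )
        target = np.concatenate(
            [np.ones((half, 1)), np.zeros((half, 1))], axis=0
        )
        disc.zero_grad()
        pred = disc.forward(x, oh, training=True)
        d_loss = binary_cross_entropy(pred, target)
        if it % cfg.d_interval == 0:
            disc.backward(bce_grad(pred, target))
            opt_d.step(disc.parameters())

        # --- stacked generator update (discriminator frozen)
        gi = rng.integers(0, simulated.n_trials, size=min(cfg.gen_batch,
                                                          simulated.n_trials))
        gen.zero_grad()
        disc.zero_grad()
        fake_full = gen.forward(sim_scaled[gi], sim_onehot[gi], training=True)
        offs = rng.integers(0, timestamps - w + 1, size=len(gi))
        fake_windows = np.stack(
            [fake_full[i, o: o + w, :] for i, o in enumerate(offs)]
        )
        ones = np.ones((len(gi), 1))
        pred = disc.forward(fake_windows, sim_onehot[gi], training=True)
        g_loss = binary_cross_entropy(pred, ones)
        if it % cfg.g_interval == 0:
            dwin = disc.backward(bce_grad(pred, ones))
            dfull = np.zeros_like(fake_full)
            for i, o in enumerate(offs):
                dfull[i, o: o + w, :] = dwin[i]
            gen.backward(dfull)
            opt_g.step(gen.parameters())

        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise RuntimeError(
                f"non-finite loss at iteration {len(history['d_loss'])}: "
                f"d={d_loss} g={g_loss}"
            )
        history["d_loss"].append(d_loss)
        history["g_loss"].append(g_loss)

    return TrainedConverter(gen, disc, gen_spec, disc_spec, cfg, norm_real,
                            norm_sim, tuple(classes), history)


def convert(trained: TrainedConverter, simulated: TrialSet,
            batch: int = 8) -> TrialSet:
    """Generator inference on whole trials, rescaled to template amplitude."""
    if simulated.n_channels != trained.gen_spec.channels:
        raise ValueError("channel count does not match the trained converter")
    unknown = set(simulated.labels) - set(trained.classes)
    if unknown:
        raise ValueError(f"labels outside trained classes: {sorted(unknown)}")
    x = trained.norm_sim.transform(simulated.data)
    oh = _one_hot(simulated.labels, trained.classes)
    outs = []
    for i in range(0, len(x), batch):
        outs.append(trained.generator.forward(x[i: i + batch], oh[i: i + batch]))
    y = trained.norm_real.inverse(np.concatenate(outs, axis=0))
    return replace(simulated, data=y)
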