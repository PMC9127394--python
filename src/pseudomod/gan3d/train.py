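"""CycleGAN training loop, losses, and inference for T1w→T2w translation.

Two generators (T1→T2 and T2→T1) and two least-squares patch discriminators
are trained simultaneously from *unpaired* volume sets. The adversarial terms
are mean squared error between discriminator scores and real/fake labels;
the cycle-consistency term is the mean absolute error between each volume and
its round-trip reconstruction, weighted by ``lambda_cycle``. Training is a
pure function of (data, config, seed) on CPU: repeated runs give identical
loss histories.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..volume import ScalarVolume
from .layers import Adam, F32
from .networks import GanConfig, build_discriminator, build_generator

INTENSITY_SCALE = 1000.0  # x/1000 − 1 maps the 0–2000 working scale to (−1, 1)


def to_tanh_scale(data):
    return (np.asarray(data, dtype=F32) / F32(INTENSITY_SCALE)) - F32(1.0)


def from_tanh_scale(data):
    return (np.asarray(data, dtype=np.float64) + 1.0) * INTENSITY_SCALE


@dataclass
class CycleGanNets:
    g_ab: object  # T1 → T2 generator
    g_ba: object  # T2 → T1 generator
    d_a: object   # discriminator on domain A (T1w)
    d_b: object   # discriminator on domain B (T2w)


@dataclass
class TrainState:
    nets: CycleGanNets
    config: GanConfig
    loss_history: list = field(default_factory=list)  # dicts per step
    epochs_done: int = 0
    seed: int = 0

    def history_column(self, key):
        return np.array([h[key] for h in self.loss_history])

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name in ("g_ab", "g_ba", "d_a", "d_b"):
            for i, p in enumerate(getattr(self.nets, name).params()):
                arrays[f"{name}_{i:03d}"] = p.value
        np.savez(out / "weights.npz", **arrays)
        meta = {"config": {**self.config.__dict__,
                           "input_shape": list(self.config.input_shape),
                           "channel_mult": list(self.config.channel_mult)},
                "epochs_done": self.epochs_done, "seed": self.seed}
        (out / "state.json").write_text(json.dumps(meta, indent=2))
        with open(out / "loss_history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["adv_g", "adv_d", "cycle"])
            writer.writeheader()
            writer.writerows(self.loss_history)

    @classmethod
    def load(cls, out_dir):
        out = Path(out_dir)
        meta = json.loads((out / "state.json").read_text())
        cfg = GanConfig(**meta["config"])
        state = init_state(cfg)
        data = np.load(out / "weights.npz")
        for name in ("g_ab", "g_ba", "d_a", "d_b"):
            for i, p in enumerate(getattr(state.nets, name).params()):
                p.value[...] = data[f"{name}_{i:03d}"]
        hist_path = out / "loss_history.csv"
        if hist_path.exists():
            with open(hist_path) as fh:
                state.loss_history = [
                    {k: float(v) for k, v in row.items()}
                    for row in csv.DictReader(fh)]
        state.epochs_done = meta["epochs_done"]
        return state


def init_state(config):
    rng = np.random.default_rng(config.seed)
    seeds = [int(rng.integers(0, 2 ** 31 - 1)) for _ in range(4)]
    nets = CycleGanNets(
        g_ab=build_generator(config, seeds[0]),
        g_ba=build_generator(config, seeds[1]),
        d_a=build_discriminator(config, seeds[2]),
        d_b=build_discriminator(config, seeds[3]),
    )
    return TrainState(nets, config, [], 0, config.seed)


def _check_scaled(x, name):
    if np.abs(x).max() > 1.5:
        raise ValueError(f"{name} appears unscaled: values outside [-1.5, 1.5] "
                         "(expected tanh-range inputs)")


def cycle_losses(real_a, real_b, nets, lambda_cycle=10.0):
    """Forward-only loss components for one unpaired (a, b) sample.

    Returns a dict with ``adv_g`` (generator-side least-squares adversarial
    loss), ``adv_d`` (discriminator loss on real/fake), ``cycle_raw``
    (unweighted round-trip MAE) and ``cycle`` (= lambda_cycle × cycle_raw).
    """
    a = np.asarray(real_a, dtype=F32)
    b = np.asarray(real_b, dtype=F32)
    _check_scaled(a, "real_a")
    _check_scaled(b, "real_b")
    if a.ndim == 3:
        a = a[None]
    if b.ndim == 3:
        b = b[None]
    fake_b = nets.g_ab.forward(a)
    rec_a = nets.g_ba.forward(fake_b)
    fake_a = nets.g_ba.forward(b)
    rec_b = nets.g_ab.forward(fake_a)
    score_fb = nets.d_b.forward(fake_b)
    score_fa = nets.d_a.forward(fake_a)
    score_b = nets.d_b.forward(b)
    score_a = nets.d_a.forward(a)
    adv_g = float(np.mean((score_fb - 1) ** 2) + np.mean((score_fa - 1) ** 2))
    adv_d = float(0.5 * (np.mean((score_b - 1) ** 2) + np.mean(score_fb ** 2)
                         + np.mean((score_a - 1) ** 2) + np.mean(score_fa ** 2)))
    cycle_raw = float(np.mean(np.abs(rec_a - a)) + np.mean(np.abs(rec_b - b)))
    return {"adv_g": adv_g, "adv_d": adv_d,
            "cycle_raw": cycle_raw, "cycle": lambda_cycle * cycle_raw}


def _generator_direction_step(g_fwd, g_bwd, d, x, lam):
    """One cycle direction: x →(g_fwd)→ fake →(g_bwd)→ rec.

    Accumulates gradients into both generators (discriminator gradients are
    also touched but zeroed before the discriminator step). Returns
    (adv_loss, cycle_raw, fake) for bookkeeping.
    """
    fake = g_fwd.forward(x)
    score = d.forward(fake)
    adv = float(np.mean((score - 1) ** 2))
    d_score = (2.0 / score.size) * (score - 1)
    g_adv = d.backward(d_score.astype(F32))
    rec = g_bwd.forward(fake)
    cyc = float(np.mean(np.abs(rec - x)))
    d_rec = (lam / rec.size) * np.sign(rec - x)
    g_cyc = g_bwd.backward(d_rec.astype(F32))
    g_fwd.backward((g_adv + g_cyc).astype(F32))
    return adv, cyc, fake


def _discriminator_step(d, real, fake):
    score_r = d.forward(real)
    loss_r = float(np.mean((score_r - 1) ** 2))
    d.backward(((1.0 / score_r.size) * (score_r - 1)).astype(F32))  # ×0.5·2
    score_f = d.forward(fake)
    loss_f = float(np.mean(score_f ** 2))
    d.backward(((1.0 / score_f.size) * score_f).astype(F32))
    return 0.5 * (loss_r + loss_f)


def train_cyclegan(set_a, set_b, config, state=None, progress=None):
    """Train the CycleGAN on unpaired tanh-scaled volume sets.

    ``set_a`` / ``set_b`` are lists of ScalarVolumes or arrays already mapped
    to [−1, 1] with shape ``config.input_shape``. Returns a TrainState whose
    loss history has one entry per optimization step.
    """
    def _as_arrays(vols, name):
        out = []
        for v in vols:
            x = np.asarray(v.data if isinstance(v, ScalarVolume) else v, dtype=F32)
            if x.shape != config.input_shape:
                raise ValueError(f"{name} volume shape {x.shape} does not match "
                                 f"config input_shape {config.input_shape}")
            _check_scaled(x, name)
            out.append(x[None])  # add channel axis
        return out

    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both training sets must be nonempty")
    A = _as_arrays(set_a, "set_a")
    B = _as_arrays(set_b, "set_b")
    if state is None:
        state = init_state(config)
    nets = state.nets
    gen_params = nets.g_ab.params() + nets.g_ba.params()
    dis_params = nets.d_a.params() + nets.d_b.params()
    opt_g = Adam(gen_params, lr=config.learning_rate)
    opt_d = Adam(dis_params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    lam = config.lambda_cycle

    def _zero_all():
        for net in (nets.g_ab, nets.g_ba, nets.d_a, nets.d_b):
            net.zero_grad()

    for epoch in range(config.epochs):
        order_a = rng.permutation(len(A))
        order_b = rng.permutation(len(B))
        n_steps = max(len(A), len(B))
        for step in range(n_steps):
            a = A[order_a[step % len(A)]]
            b = B[order_b[step % len(B)]]
            # generator update (both cycle directions)
            _zero_all()
            adv_ab, cyc_a, fake_b = _generator_direction_step(
                nets.g_ab, nets.g_ba, nets.d_b, a, lam)
            adv_ba, cyc_b, fake_a = _generator_direction_step(
                nets.g_ba, nets.g_ab, nets.d_a, b, lam)
            for p in dis_params:
                p.grad[...] = 0  # discriminators are frozen in the G step
            opt_g.step()
            # discriminator update (fakes detached by construction)
            _zero_all()
            loss_db = _discriminator_step(nets.d_b, b, fake_b)
            loss_da = _discriminator_step(nets.d_a, a, fake_a)
            for p in gen_params:
                p.grad[...] = 0
            opt_d.step()
            state.loss_history.append({
                "adv_g": adv_ab + adv_ba,
                "adv_d": loss_da + loss_db,
                "cycle": lam * (cyc_a + cyc_b),
            })
        state.epochs_done += 1
        if progress is not None:
            progress(epoch, state.loss_history[-1])
    return state


def synthesize_gan_t2w(target_t1, state, mask):
    """One forward pass of the T1→T2 generator.

    The input must be on the 0–2000 working scale; it is mapped to the tanh
    range, translated, and mapped back (clipped to [0, 2000]) and masked.
    """
    x = to_tanh_scale(target_t1.data)
    if x.shape != state.config.input_shape:
        raise ValueError(f"input shape {x.shape} incompatible with trained "
                         f"network {state.config.input_shape}")
    y = state.nets.g_ab.forward(x[None])[0]
    out = np.clip(from_tanh_scale(y), 0.0, 2000.0)
    out[~mask.data] = 0.0
    return ScalarVolume(out, target_t1.spacing, target_t1.affine, "pseudoT2w")
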