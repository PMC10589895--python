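"""Path-integration recurrent network trained on place-cell targets.

Architecture (no biases anywhere):

    g_0 = We p_0                      linear encoder of the initial place code
    g_t = ReLU(Wg g_{t-1} + Wv v_t)   recurrent state driven by 2-d velocity
    phat_t = softmax(Wd g_t)          decoded place-cell distribution

trained by cross-entropy between predicted and true place-cell activity,
time-averaged over the trajectory, plus an L2 penalty on the recurrent
weights:

    L = -(1/T) sum_t sum_i p_i(x_t) ln phat_it  +  lambda ||Wg||_F^2.

The implementation is plain numpy with hand-derived backpropagation through
time (T is small, so full BPTT) and an Adam optimizer; the analytic gradient
is validated against finite differences in the test suite.

Two training schedules are supported: ``multi_env`` (every minibatch holds an
equal share of trajectories from each environment) and ``continual`` (one
environment's data is exhausted before the next is presented).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .placecode import PlaceCellEnsemble, decode_position, encode_position
from .trajectories import ArenaSpec, MotionParams, generate_batch_fast

__all__ = [
    "ModelParams",
    "TrainConfig",
    "TrainingLog",
    "init_model",
    "forward",
    "loss",
    "kl_divergence",
    "decoding_error",
    "train",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class ModelParams:
    """The four weight matrices of the network."""

    We: np.ndarray  # (Ng, Np)
    Wg: np.ndarray  # (Ng, Ng)
    Wv: np.ndarray  # (Ng, 2)
    Wd: np.ndarray  # (Np, Ng)
    relu_initial_state: bool = False

    @property
    def n_units(self) -> int:
        return self.We.shape[0]

    @property
    def n_place(self) -> int:
        return self.We.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(self.We.copy(), self.Wg.copy(), self.Wv.copy(),
                           self.Wd.copy(), self.relu_initial_state)


@dataclass
class TrainConfig:
    l2_weight: float = 1e-4
    learning_rate: float = 1e-4
    batch_size: int = 200
    n_steps: int = 20
    minibatches_per_env: int = 100_000
    schedule: str = "multi_env"      # or "continual"
    n_envs: int = 3
    seed: int = 0
    log_every: int = 50
    eval_batch_size: int = 200

    def __post_init__(self) -> None:
        if self.l2_weight < 0 or self.batch_size < 1:
            raise ValueError("l2_weight >= 0 and batch_size >= 1 required")
        if self.schedule not in ("multi_env", "continual"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class TrainingLog:
    steps: list = field(default_factory=list)
    kl: list = field(default_factory=list)          # mean over T, batch
    l2: list = field(default_factory=list)          # ||Wg||_F^2
    decode_err: list = field(default_factory=list)  # per familiar env, at t=T
    decode_err_novel: list = field(default_factory=list)
    env_schedule: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            n_env = len(self.decode_err[0]) if self.decode_err else 0
            w.writerow(["step", "kl", "l2"]
                       + [f"decode_err_env{e}" for e in range(n_env)]
                       + ["decode_err_novel"])
            for i, s in enumerate(self.steps):
                w.writerow([s, self.kl[i], self.l2[i], *self.decode_err[i],
                            self.decode_err_novel[i]])


def xavier_uniform(shape: tuple[int, int], rng: np.random.Generator,
                   gain: float = 1.0) -> np.ndarray:
    fan_out, fan_in = shape
    bound = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def init_model(n_place: int, n_units: int, seed: int = 0,
               relu_initial_state: bool = False) -> ModelParams:
    """Xavier-uniform (unity gain) initialisation of all four matrices."""
    rng = np.random.default_rng(seed)
    return ModelParams(
        We=xavier_uniform((n_units, n_place), rng),
        Wg=xavier_uniform((n_units, n_units), rng),
        Wv=xavier_uniform((n_units, 2), rng),
        Wd=xavier_uniform((n_place, n_units), rng),
        relu_initial_state=relu_initial_state,
    )


def forward(model: ModelParams, p0: np.ndarray, velocities: np.ndarray,
            return_states: bool = False):
    """Run the recurrence.

    p0 : (B, Np) initial place activity; velocities : (B, T, 2).
    Returns predictions (B, T, Np); with ``return_states`` also the unit
    activities g (B, T+1, Ng) including the initial state, and the
    pre-activation cache used by the backward pass.
    """
    p0 = np.atleast_2d(p0)
    velocities = np.asarray(velocities)
    if velocities.ndim == 2:
        velocities = velocities[None]
    B, T, _ = velocities.shape
    Ng = model.n_units

    g = np.empty((B, T + 1, Ng))
    pre = np.empty((B, T, Ng))
    g0 = p0 @ model.We.T
    if model.relu_initial_state:
        g0 = np.maximum(g0, 0.0)
    g[:, 0] = g0
    for t in range(T):
        a = g[:, t] @ model.Wg.T + velocities[:, t] @ model.Wv.T
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(
                f"non-finite recurrent state at step {t + 1}")
        pre[:, t] = a
        g[:, t + 1] = np.maximum(a, 0.0)
    logits = g[:, 1:] @ model.Wd.T
    preds = softmax(logits, axis=-1)
    if return_states:
        return preds, g, pre
    return preds


def loss(predictions: np.ndarray, labels: np.ndarray, Wg: np.ndarray,
         l2_weight: float) -> float:
    """Time-averaged cross-entropy plus the (added) L2 recurrent penalty."""
    preds = np.clip(predictions, _EPS, None)
    T = preds.shape[-2]
    ce = -(labels * np.log(preds)).sum(axis=-1).sum(axis=-1) / T
    return float(np.mean(ce) + l2_weight * np.sum(Wg ** 2))


def kl_divergence(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean KL(p || phat) over batch and time; >= 0, zero iff equal."""
    p = np.asarray(labels)
    q = np.clip(predictions, _EPS, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return float(np.mean(terms.sum(axis=-1)))


def _gradients(model: ModelParams, p0, velocities, labels, l2_weight):
    """Analytic BPTT gradients of :func:`loss`; returns (loss, grads dict)."""
    preds, g, pre = forward(model, p0, velocities, return_states=True)
    B, T, _ = preds.shape
    L = loss(preds, labels, model.Wg, l2_weight)

    dlogits = (preds - labels) / (T * B)            # (B, T, Np)
    Np, Ng = model.Wd.shape
    dWd = dlogits.reshape(-1, Np).T @ g[:, 1:].reshape(-1, Ng)
    dWg = 2.0 * l2_weight * model.Wg
    dWv = np.zeros_like(model.Wv)
    dg_next = np.zeros((B, model.n_units))
    dg_all = dlogits.reshape(-1, Np) @ model.Wd     # (B*T, Ng)
    dg_all = dg_all.reshape(B, T, Ng)
    for t in range(T - 1, -1, -1):
        da = (dg_all[:, t] + dg_next) * (pre[:, t] > 0)
        dWg += da.T @ g[:, t]
        dWv += da.T @ velocities[:, t]
        dg_next = da @ model.Wg
    dg0 = dg_next
    if model.relu_initial_state:
        dg0 = dg0 * (g[:, 0] > 0)
    dWe = dg0.T @ np.atleast_2d(p0)
    return L, {"We": dWe, "Wg": dWg, "Wv": dWv, "Wd": dWd}, preds


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_batch(arena, motion, ensembles, counts, rng):
    """Fresh trajectories encoded per environment; returns (p0, v, labels, pos)."""
    p0s, vs, labels, poss = [], [], [], []
    for ens, cnt in zip(ensembles, counts):
        if cnt == 0:
            continue
        walk = generate_batch_fast(arena, motion, cnt, rng)
        p0s.append(encode_position(walk.x0, ens))
        labels.append(encode_position(walk.positions, ens))
        vs.append(walk.velocities)
        poss.append(walk.positions)
    return (np.concatenate(p0s), np.concatenate(vs), np.concatenate(labels),
            np.concatenate(poss))


def decoding_error(model: ModelParams, p0, velocities, labels,
                   ensemble: PlaceCellEnsemble) -> np.ndarray:
    """Per-timestep mean distance between decoded prediction and decoded label."""
    preds = forward(model, p0, velocities)
    xhat = decode_position(preds, ensemble)
    xref = decode_position(labels, ensemble)
    return np.linalg.norm(xhat - xref, axis=-1).mean(axis=0)


def _split_counts(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def train(model: ModelParams, config: TrainConfig,
          ensembles: list[PlaceCellEnsemble],
          arena: ArenaSpec | None = None,
          motion: MotionParams | None = None,
          novel_ensemble: PlaceCellEnsemble | None = None,
          progress: bool = False) -> tuple[ModelParams, TrainingLog]:
    """Train in-place on fresh simulated data; returns (model, log).

    Total steps = minibatches_per_env * n_envs.  ``multi_env`` splits every
    minibatch equally across environments; ``continual`` presents
    ``minibatches_per_env`` consecutive minibatches per environment.
    """
    if not ensembles:
        raise ValueError("at least one environment required")
    arena = arena or ensembles[0].arena
    motion = motion or MotionParams(n_steps=config.n_steps)
    rng = np.random.default_rng(config.seed)
    eval_rng = np.random.default_rng(np.random.default_rng(config.seed + 1).integers(2**31))
    n_env = len(ensembles)
    total_steps = config.minibatches_per_env * n_env

    params = {"We": model.We, "Wg": model.Wg, "Wv": model.Wv, "Wd": model.Wd}
    opt = _Adam(params, config.learning_rate)
    log = TrainingLog()

    # fixed evaluation batches (one per familiar env, one novel)
    eval_batches = []
    for ens in ensembles:
        walk = generate_batch_fast(arena, motion, config.eval_batch_size, eval_rng)
        eval_batches.append((encode_position(walk.x0, ens), walk.velocities,
                             encode_position(walk.positions, ens), ens))
    if novel_ensemble is not None:
        walk = generate_batch_fast(arena, motion, config.eval_batch_size, eval_rng)
        novel_batch = (encode_position(walk.x0, novel_ensemble), walk.velocities,
                       encode_position(walk.positions, novel_ensemble),
                       novel_ensemble)

    def log_point(step: int) -> None:
        kls, errs = [], []
        for p0, v, lab, ens in eval_batches:
            preds = forward(model, p0, v)
            kls.append(kl_divergence(lab, preds))
            errs.append(float(decoding_error(model, p0, v, lab, ens)[-1]))
        log.steps.append(step)
        log.kl.append(float(np.mean(kls)))
        log.l2.append(float(np.sum(model.Wg ** 2)))
        log.decode_err.append(errs)
        if novel_ensemble is not None:
            p0, v, lab, ens = novel_batch
            log.decode_err_novel.append(
                float(decoding_error(model, p0, v, lab, ens)[-1]))
        else:
            log.decode_err_novel.append(np.nan)

    log_point(0)
    iterator = range(total_steps)
    if progress:
        iterator = _maybe_tqdm(iterator)
    for step in iterator:
        if config.schedule == "multi_env":
            counts = _split_counts(config.batch_size, n_env)
            env_label = -1
        else:
            env = min(step // config.minibatches_per_env, n_env - 1)
            counts = [config.batch_size if i == env else 0 for i in range(n_env)]
            env_label = env
        p0, v, labels, _ = _make_batch(arena, motion, ensembles, counts, rng)
        L, grads, _ = _gradients(model, p0, v, labels, config.l2_weight)
        if not np.isfinite(L):
            raise FloatingPointError(f"training diverged at step {step}")
        opt.step(params, grads)
        log.env_schedule.append(env_label)
        if (step + 1) % config.log_every == 0 or step + 1 == total_steps:
            log_point(step + 1)
    return model, log


def _maybe_tqdm(it):
    try:
        from tqdm import tqdm

        return tqdm(it)
    except ImportError:  # pragma: no cover
        return it


def save_model(path, model: ModelParams, config: TrainConfig | None = None) -> None:
    cfg = json.dumps(vars(config)) if config is not None else ""
    np.savez(path, We=model.We, Wg=model.Wg, Wv=model.Wv, Wd=model.Wd,
             relu_initial_state=model.relu_initial_state, config=cfg)


def load_model(path) -> ModelParams:
    with np.load(path, allow_pickle=False) as f:
        return ModelParams(f["We"], f["Wg"], f["Wv"], f["Wd"],
                           bool(f["relu_initial_state"]))
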