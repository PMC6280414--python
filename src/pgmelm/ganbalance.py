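"""Dynamic-GAN minority oversampling, plus SMOTE as the comparison method.

The balancing rule is driven by the training-set class counts alone.  With
N+ minority and N- majority samples the GAN execution count is

    num = floor(N- / N+),

after which the minority class holds num * N+ rows (the N+ originals plus
(num - 1) * N+ generated ones), the training set grows to
N' = num * N+ + N-, and the imbalance ratio moves from IR = N+/N- to
IR' = num * N+ / N-, a change of

    dIR = IR' - IR = (num - 1) * N+ / N-  in [0, 1).

The majority class is never touched, so no majority information is lost.

The GAN itself is a small fully-connected pair trained by alternating
full-batch gradient steps on the classic minimax objective: the generator
uses ReLU then sigmoid (so it emits values in (0,1); features are min-max
scaled before training and inverse-scaled after sampling), the discriminator
uses a two-piece maxout layer then sigmoid.  Training stops early once the
discriminator's mean output on a mixed real+generated batch has settled at
1/2 — the theoretical optimum D*(x) = p_data/(p_data + p_g) = 1/2 when the
generator has matched the data distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

_LOG_EPS = 1e-8


class EmptyMinorityError(ValueError):
    """No minority samples: balancing undefined."""


class GANDivergenceError(RuntimeError):
    """Non-finite loss during adversarial training."""


# ---------------------------------------------------------------------------
# balancing arithmetic
# ---------------------------------------------------------------------------

def num_gan_runs(n_min: int, n_maj: int) -> int:
    """GAN execution count num = floor(N-/N+)."""
    if n_min < 1:
        raise EmptyMinorityError("minority class is empty")
    if n_maj < n_min:
        raise ValueError(
            f"majority count {n_maj} < minority count {n_min}; "
            "labels 1/0 must mark minority/majority"
        )
    return n_maj // n_min


def delta_ir(n_min: int, n_maj: int) -> float:
    """Change of imbalance ratio dIR = (floor(N-/N+) - 1) * N+ / N-."""
    return (num_gan_runs(n_min, n_maj) - 1) * n_min / n_maj


# ---------------------------------------------------------------------------
# GAN
# ---------------------------------------------------------------------------

@dataclass
class GANConfig:
    """Hyper-parameters of the minority-class GAN.

    ``dropout_d`` / ``dropout_g`` are keep-probabilities applied to the
    hidden layer of the discriminator / generator during training.
    ``noise_dim=None`` means "same dimension as the data" (standard-normal
    prior).  ``early_stop_tol``/``early_stop_patience`` implement the
    D = 1/2 convergence stop.
    """

    hidden_nodes: int = 100
    learning_rate: float = 0.01
    dropout_d: float = 0.9
    dropout_g: float = 0.1
    epochs: int = 2000
    noise_dim: int | None = None
    seed: int = 0
    momentum: float = 0.0
    early_stop_tol: float = 0.05
    early_stop_patience: int = 10
    min_epochs: int = 50
    uniform_prior: bool = False

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if not (0.0 < self.dropout_d <= 1.0 and 0.0 < self.dropout_g <= 1.0):
            raise ValueError("dropout keep-probabilities must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class GANModel:
    """Trained generator/discriminator parameter sets with training trace."""

    config: GANConfig
    # generator: noise -> hidden (ReLU) -> data dim (sigmoid)
    W1: np.ndarray = None
    b1: np.ndarray = None
    W2: np.ndarray = None
    b2: np.ndarray = None
    # discriminator: data -> maxout(2 pieces) hidden -> sigmoid scalar
    A1: np.ndarray = None
    c1: np.ndarray = None
    A2: np.ndarray = None
    c2: np.ndarray = None
    V: np.ndarray = None
    v0: np.ndarray = None
    # min-max scaling of the training chunk
    x_min: np.ndarray = None
    x_max: np.ndarray = None
    trace: dict = field(default_factory=dict)
    trained: bool = False

    @property
    def data_dim(self) -> int:
        return self.W2.shape[1]

    # -- forward passes -------------------------------------------------
    def _gen_forward(self, z: np.ndarray, rng=None, keep: float = 1.0):
        t1 = z @ self.W1 + self.b1
        h = np.maximum(t1, 0.0)
        if rng is not None and keep < 1.0:
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
        else:
            mask = None
        t2 = h @ self.W2 + self.b2
        x = 1.0 / (1.0 + np.exp(-t2))
        return x, (z, t1, h, mask, t2)

    def _disc_forward(self, x: np.ndarray, rng=None, keep: float = 1.0):
        u1 = x @ self.A1 + self.c1
        u2 = x @ self.A2 + self.c2
        m = np.maximum(u1, u2)
        piece1 = u1 >= u2
        if rng is not None and keep < 1.0:
            mask = (rng.random(m.shape) < keep) / keep
            md = m * mask
        else:
            mask = None
            md = m
        s = md @ self.V + self.v0
        p = 1.0 / (1.0 + np.exp(-s))
        return p, (x, piece1, mask, md)

    def discriminate(self, X: np.ndarray) -> np.ndarray:
        """Discriminator outputs in (0,1) on scaled-space rows."""
        p, _ = self._disc_forward(np.atleast_2d(X))
        return p.ravel()


def _init_gan(d: int, cfg: GANConfig, rng: np.random.Generator) -> GANModel:
    nz = cfg.noise_dim if cfg.noise_dim is not None else d
    h = cfg.hidden_nodes

    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    return GANModel(
        config=cfg,
        W1=glorot(nz, h), b1=np.zeros(h),
        W2=glorot(h, d), b2=np.zeros(d),
        A1=glorot(d, h), c1=rng.uniform(-0.01, 0.01, h),
        A2=glorot(d, h), c2=rng.uniform(-0.01, 0.01, h),
        V=glorot(h, 1), v0=np.zeros(1),
    )


def _sample_noise(rng: np.random.Generator, n: int, nz: int, uniform: bool) -> np.ndarray:
    if uniform:
        return rng.uniform(-1.0, 1.0, size=(n, nz))
    return rng.standard_normal((n, nz))


def train_dynamic_gan(X_min: np.ndarray, config: GANConfig | None = None) -> GANModel:
    """Adversarially fit a generator to the minority-class chunk.

    The whole minority segment is used as one batch per step (the chunk is
    small by construction).  Discriminator ascends
    mean[log D(x) + log(1 - D(G(z)))]; generator descends
    mean[log(1 - D(G(z)))].  Raises :class:`GANDivergenceError` (with the
    epoch index) if a loss goes non-finite.
    """
    cfg = config or GANConfig()
    X_min = np.asarray(X_min, dtype=float)
    if X_min.ndim != 2 or X_min.shape[0] < 2:
        raise ValueError("GAN training needs a 2-D minority matrix with >= 2 rows")
    rng = np.random.default_rng(cfg.seed)
    d = X_min.shape[1]
    model = _init_gan(d, cfg, rng)

    # scale features into the sigmoid output range
    model.x_min = X_min.min(axis=0)
    model.x_max = X_min.max(axis=0)
    span = np.where(model.x_max - model.x_min < 1e-12, 1.0, model.x_max - model.x_min)
    Xs = (X_min - model.x_min) / span

    n = Xs.shape[0]
    nz = cfg.noise_dim if cfg.noise_dim is not None else d
    lr, mom = cfg.learning_rate, cfg.momentum
    vel: dict[str, np.ndarray] = {}

    def step(name: str, grad: np.ndarray, sign: float) -> None:
        # sign=+1 ascends (D), sign=-1 descends (G)
        v = vel.get(name)
        v = mom * v + grad if v is not None and mom > 0 else grad
        vel[name] = v
        setattr(model, name, getattr(model, name) + sign * lr * v)

    d_losses, g_losses, d_means = [], [], []
    settled = 0
    ever_unsettled = False
    for epoch in range(cfg.epochs):
        # ---- discriminator step ----
        z = _sample_noise(rng, n, nz, cfg.uniform_prior)
        x_fake, _ = model._gen_forward(z, rng, cfg.dropout_g)
        p_r, (xr, pc_r, mk_r, md_r) = model._disc_forward(Xs, rng, cfg.dropout_d)
        p_f, (xf, pc_f, mk_f, md_f) = model._disc_forward(x_fake, rng, cfg.dropout_d)
        d_loss = float(np.mean(np.log(p_r + _LOG_EPS)) +
                       np.mean(np.log(1.0 - p_f + _LOG_EPS)))
        if not np.isfinite(d_loss):
            raise GANDivergenceError(f"discriminator loss non-finite at epoch {epoch}")

        ds_r = (1.0 - p_r) / n          # d/ds of mean log sigmoid(s)
        ds_f = -p_f / n                 # d/ds of mean log(1 - sigmoid(s))
        gV = md_r.T @ ds_r + md_f.T @ ds_f
        gv0 = ds_r.sum(0) + ds_f.sum(0)
        dm_r = (ds_r @ model.V.T)
        dm_f = (ds_f @ model.V.T)
        if mk_r is not None:
            dm_r, dm_f = dm_r * mk_r, dm_f * mk_f
        gA1 = xr.T @ (dm_r * pc_r) + xf.T @ (dm_f * pc_f)
        gc1 = (dm_r * pc_r).sum(0) + (dm_f * pc_f).sum(0)
        gA2 = xr.T @ (dm_r * ~pc_r) + xf.T @ (dm_f * ~pc_f)
        gc2 = (dm_r * ~pc_r).sum(0) + (dm_f * ~pc_f).sum(0)
        for name, g in (("V", gV), ("v0", gv0), ("A1", gA1), ("c1", gc1),
                        ("A2", gA2), ("c2", gc2)):
            step(name, g, +1.0)

        # ---- generator step ----
        z = _sample_noise(rng, n, nz, cfg.uniform_prior)
        x_fake, (zg, t1, hdrop, gmask, _t2) = model._gen_forward(z, rng, cfg.dropout_g)
        p_f, (xf, pc_f, mk_f, md_f) = model._disc_forward(x_fake, rng, cfg.dropout_d)
        g_loss = float(np.mean(np.log(1.0 - p_f + _LOG_EPS)))
        if not np.isfinite(g_loss):
            raise GANDivergenceError(f"generator loss non-finite at epoch {epoch}")

        ds = -p_f / n                   # d/ds of the generator objective
        dmd = ds @ model.V.T
        if mk_f is not None:
            dmd = dmd * mk_f
        dx = (dmd * pc_f) @ model.A1.T + (dmd * ~pc_f) @ model.A2.T
        dt2 = dx * x_fake * (1.0 - x_fake)
        gW2 = hdrop.T @ dt2
        gb2 = dt2.sum(0)
        dh = dt2 @ model.W2.T
        if gmask is not None:
            dh = dh * gmask
        dh = dh * (t1 > 0)
        gW1 = zg.T @ dh
        gb1 = dh.sum(0)
        for name, g in (("W2", gW2), ("b2", gb2), ("W1", gW1), ("b1", gb1)):
            step(name, g, -1.0)

        # ---- convergence monitor: mean D output on mixed real+fake ----
        z = _sample_noise(rng, n, nz, cfg.uniform_prior)
        x_eval, _ = model._gen_forward(z)
        d_mean = float(np.mean(np.concatenate([
            model.discriminate(Xs), model.discriminate(x_eval)])))
        d_losses.append(d_loss)
        g_losses.append(g_loss)
        d_means.append(d_mean)
        in_band = abs(d_mean - 0.5) < cfg.early_stop_tol
        settled = settled + 1 if in_band else 0
        ever_unsettled = ever_unsettled or not in_band
        # an untrained D also sits near 1/2, so "converged back to 1/2"
        # only counts after the game has produced a real signal once
        if (ever_unsettled and epoch + 1 >= cfg.min_epochs
                and settled >= cfg.early_stop_patience):
            break

    model.trace = {"d_loss": d_losses, "g_loss": g_losses, "d_mean": d_means,
                   "epochs_run": len(d_losses)}
    model.trained = True
    return model


def generate_minority(model: GANModel, count: int, seed: int) -> np.ndarray:
    """Draw ``count`` synthetic minority rows in the original feature scale."""
    if not model.trained:
        raise RuntimeError("GAN model is untrained; call train_dynamic_gan first")
    if count < 0:
        raise ValueError("count must be >= 0")
    cfg = model.config
    nz = cfg.noise_dim if cfg.noise_dim is not None else model.data_dim
    rng = np.random.default_rng(seed)
    if count == 0:
        return np.empty((0, model.data_dim))
    z = _sample_noise(rng, count, nz, cfg.uniform_prior)
    x, _ = model._gen_forward(z)
    span = np.where(model.x_max - model.x_min < 1e-12, 1.0,
                    model.x_max - model.x_min)
    return x * span + model.x_min


# ---------------------------------------------------------------------------
# balanced dataset
# ---------------------------------------------------------------------------

@dataclass
class BalancedDataset:
    """Original + generated rows after class balancing.

    ``generated_mask`` is True on synthetic rows.  ``num`` is the GAN
    execution count floor(N-/N+); ``ir_before``/``ir_after``/``delta_ir``
    record the ratio change.
    """

    Z: np.ndarray
    y: np.ndarray
    generated_mask: np.ndarray
    num: int
    ir_before: float
    ir_after: float
    delta_ir: float
    gan: GANModel | None = None

    @property
    def n(self) -> int:
        return self.Z.shape[0]


def balance_dataset(Z: np.ndarray, y: np.ndarray,
                    config: GANConfig | None = None) -> BalancedDataset:
    """Grow the minority class to num * N+ rows with GAN samples.

    The N+ original minority rows are kept; (num - 1) * N+ synthetic rows
    are appended; majority rows pass through bit-identical.  With num = 1
    (already near-balanced) the data is returned unchanged and no GAN is
    trained.
    """
    cfg = config or GANConfig()
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    n_min = int(np.sum(y == 1))
    n_maj = int(np.sum(y == 0))
    num = num_gan_runs(n_min, n_maj)
    ir0 = n_min / n_maj
    d_ir = delta_ir(n_min, n_maj)
    if num == 1:
        return BalancedDataset(Z=Z.copy(), y=y.copy(),
                               generated_mask=np.zeros(len(y), bool),
                               num=1, ir_before=ir0, ir_after=ir0, delta_ir=0.0)
    if n_min < 2:
        raise ValueError("GAN balancing needs >= 2 minority samples")
    X_min = Z[y == 1]
    gan = train_dynamic_gan(X_min, cfg)
    n_new = (num - 1) * n_min
    X_new = generate_minority(gan, n_new, seed=cfg.seed + 1)
    Z_out = np.vstack([Z, X_new])
    y_out = np.concatenate([y, np.ones(n_new, int)])
    mask = np.concatenate([np.zeros(len(y), bool), np.ones(n_new, bool)])
    return BalancedDataset(Z=Z_out, y=y_out, generated_mask=mask, num=num,
                           ir_before=ir0, ir_after=num * n_min / n_maj,
                           delta_ir=d_ir, gan=gan)


# ---------------------------------------------------------------------------
# SMOTE baseline
# ---------------------------------------------------------------------------

def smote_oversample(Z: np.ndarray, y: np.ndarray, k: int = 5,
                     target_count: int | None = None,
                     seed: int = 0) -> BalancedDataset:
    """Synthetic minority oversampling by k-NN segment interpolation.

    Each synthetic row is x_i + t * (x_nn - x_i) with t ~ U[0,1), x_nn one
    of the k minority nearest neighbours of minority row x_i.
    ``target_count`` is the number of synthetic rows to add (default:
    N- - N+, balancing to parity).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    X_min = Z[y == 1]
    n_min, n_maj = X_min.shape[0], int(np.sum(y == 0))
    if n_min == 0:
        raise EmptyMinorityError("minority class is empty")
    if k < 1 or k >= n_min:
        raise ValueError(
            f"k must satisfy 1 <= k < minority count ({n_min}), got {k}"
        )
    if target_count is None:
        target_count = max(0, n_maj - n_min)
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    # first neighbour is the point itself
    idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=target_count)
    pick = idx[base, rng.integers(0, k, size=target_count)]
    t = rng.random((target_count, 1))
    X_new = X_min[base] + t * (X_min[pick] - X_min[base])
    Z_out = np.vstack([Z, X_new])
    y_out = np.concatenate([y, np.ones(target_count, int)])
    mask = np.concatenate([np.zeros(len(y), bool), np.ones(target_count, bool)])
    n_min2 = n_min + target_count
    return BalancedDataset(Z=Z_out, y=y_out, generated_mask=mask,
                           num=1, ir_before=n_min / n_maj,
                           ir_after=n_min2 / n_maj,
                           delta_ir=n_min2 / n_maj - n_min / n_maj)
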