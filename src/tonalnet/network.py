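"""The key-identification multilayer perceptron.

Three affine layers (2232 -> 45 -> 30 -> 24), each followed by the hyperbolic
tangent sigmoid, trained by online stochastic gradient descent on the squared
error between raw outputs and {0, 1} one-hot teacher signals. Output
binarization (1 for positive activation, 0 otherwise) is a readout used only
when interpreting outputs, never inside the gradient.

The training loop exploits the sparsity of the positional one-hot input: a
melody of L tones activates exactly L of the 2232 input units, so the first
layer touches only those L weight columns. The per-item update loop is
compiled with numba; a pure-numpy single-item path (:func:`loss_and_gradients`)
exists for gradient verification and agrees with the compiled path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .corpus import Corpus, EmptyCorpusError
from .encoding import INPUT_SIZE, N_KEYS, active_indices

HIDDEN1 = 45
HIDDEN2 = 30
LAYER_SIZES = (INPUT_SIZE, HIDDEN1, HIDDEN2, N_KEYS)

CHECKPOINT_FORMAT_VERSION = 1


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def activation(x):
    """Hyperbolic tangent sigmoid, (e^x - e^-x) / (e^x + e^-x), range (-1, 1).

    Evaluated through the numerically stable library tanh, which agrees with
    the exponential form to machine precision and does not overflow.
    """
    return np.tanh(x)


def binarize(outputs: np.ndarray) -> np.ndarray:
    """Binarized readout of raw outputs: 1 where strictly positive, else 0."""
    outputs = np.asarray(outputs, dtype=float)
    if np.any(outputs <= -1.0) or np.any(outputs >= 1.0):
        raise ValueError("raw outputs must lie strictly inside (-1, 1)")
    return (outputs > 0.0).astype(np.int64)


@dataclass(eq=False)
class NetworkState:
    """Weights and biases of the three affine layers, plus bookkeeping.

    ``w1`` has shape (n_in, n_h1) and so on; the column convention keeps the
    sparse first-layer update a plain row gather.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray
    seed: int = 0
    epoch: int = 0

    def __post_init__(self) -> None:
        n_in, n_h1 = self.w1.shape
        n_h1b, n_h2 = self.w2.shape
        n_h2b, n_out = self.w3.shape
        if n_h1 != n_h1b or n_h2 != n_h2b:
            raise ValueError("inconsistent layer shapes")
        if (self.b1.shape, self.b2.shape, self.b3.shape) != ((n_h1,), (n_h2,), (n_out,)):
            raise ValueError("bias shapes do not match weight shapes")
        for arr in (self.w1, self.b1, self.w2, self.b2, self.w3, self.b3):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        return (self.w1.shape[0], self.w1.shape[1], self.w2.shape[1], self.w3.shape[1])

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy(),
            self.w3.copy(), self.b3.copy(), seed=self.seed, epoch=self.epoch,
        )

    def parameter_hash(self) -> int:
        """Order-stable hash of all parameters (read-only evaluation checks)."""
        return hash(tuple(arr.tobytes() for arr in
                          (self.w1, self.b1, self.w2, self.b2, self.w3, self.b3)))


def init_network(
    seed: int,
    init_scale: float = 0.1,
    layer_sizes: tuple[int, int, int, int] = LAYER_SIZES,
) -> NetworkState:
    """Fresh network with parameters i.i.d. uniform on [-init_scale, +init_scale].

    ``layer_sizes`` defaults to the full architecture; smaller sizes are
    accepted for miniature instances used in gradient verification.
    """
    if init_scale <= 0:
        raise ValueError("init_scale must be positive")
    rng = np.random.default_rng(seed)
    n_in, n_h1, n_h2, n_out = layer_sizes
    return NetworkState(
        w1=rng.uniform(-init_scale, init_scale, size=(n_in, n_h1)),
        b1=rng.uniform(-init_scale, init_scale, size=n_h1),
        w2=rng.uniform(-init_scale, init_scale, size=(n_h1, n_h2)),
        b2=rng.uniform(-init_scale, init_scale, size=n_h2),
        w3=rng.uniform(-init_scale, init_scale, size=(n_h2, n_out)),
        b3=rng.uniform(-init_scale, init_scale, size=n_out),
        seed=seed,
        epoch=0,
    )


def forward(state: NetworkState, x: np.ndarray) -> np.ndarray:
    """Raw output activations for a dense input vector; all in (-1, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (state.w1.shape[0],):
        raise ValueError(f"input must have shape ({state.w1.shape[0]},), got {x.shape}")
    h1 = activation(x @ state.w1 + state.b1)
    h2 = activation(h1 @ state.w2 + state.b2)
    return activation(h2 @ state.w3 + state.b3)


def forward_indices(state: NetworkState, idx: np.ndarray) -> np.ndarray:
    """Raw outputs for a sparse input given by its active flat indices."""
    h1 = activation(state.w1[idx].sum(axis=0) + state.b1)
    h2 = activation(h1 @ state.w2 + state.b2)
    return activation(h2 @ state.w3 + state.b3)


def loss_and_gradients(state: NetworkState, x: np.ndarray, target: np.ndarray):
    """Squared-error loss and its analytic gradients for one item.

    Returns ``(loss, grads)`` where ``grads`` maps 'w1', 'b1', ..., 'b3' and
    'x' (the input gradient) to arrays matching their parameter shapes. This
    is the reference backpropagation path used to verify the compiled
    training loop.
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    a1 = x @ state.w1 + state.b1
    h1 = activation(a1)
    a2 = h1 @ state.w2 + state.b2
    h2 = activation(a2)
    a3 = h2 @ state.w3 + state.b3
    out = activation(a3)
    err = out - target
    loss = float(np.sum(err**2))
    d3 = 2.0 * err * (1.0 - out**2)
    d2 = (state.w3 @ d3) * (1.0 - h2**2)
    d1 = (state.w2 @ d2) * (1.0 - h1**2)
    grads = {
        "w3": np.outer(h2, d3), "b3": d3,
        "w2": np.outer(h1, d2), "b2": d2,
        "w1": np.outer(x, d1), "b1": d1,
        "x": state.w1 @ d1,
    }
    return loss, grads


@dataclass
class TrainingConfig:
    """Hyperparameters of a training run.

    ``learning_rate`` applies to plain online (per-item) gradient descent on
    the squared error; the presentation order is reshuffled every epoch from
    ``seed`` when ``shuffle`` is set. ``target_coding`` selects the teacher
    levels: ``"binary"`` keeps the {0, 1} code, ``"symmetric"`` substitutes
    {-0.9, +0.9}, which sits symmetrically in the tanh output range.
    """

    n_epochs: int = 50_000
    learning_rate: float = 0.01
    checkpoint_interval: int = 5_000
    shuffle: bool = True
    seed: int = 0
    loss: str = "squared_error"
    target_coding: str = "binary"
    include_baseline: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1 or self.checkpoint_interval < 1:
            raise ValueError("n_epochs and checkpoint_interval must be >= 1")
        if self.loss != "squared_error":
            raise ValueError("only squared_error loss is supported")
        if self.target_coding not in ("binary", "symmetric"):
            raise ValueError("target_coding must be 'binary' or 'symmetric'")

    @property
    def target_levels(self) -> tuple[float, float]:
        """(off, on) teacher values."""
        return (0.0, 1.0) if self.target_coding == "binary" else (-0.9, 0.9)


@dataclass(eq=False)
class Checkpoint:
    """A snapshot of the network at a test time."""

    epoch: int
    state: NetworkState
    training_loss: float


def checkpoint_epochs(
    n_epochs: int, interval: int, include_baseline: bool = False
) -> list[int]:
    """Epochs at which checkpoints are taken.

    Every ``interval`` epochs; a final checkpoint is forced at ``n_epochs``
    when the interval does not divide it. The untrained epoch-0 baseline is
    prepended on request.
    """
    epochs = list(range(interval, n_epochs + 1, interval))
    if not epochs or epochs[-1] != n_epochs:
        epochs.append(n_epochs)
    if include_baseline:
        epochs = [0] + epochs
    return epochs


@njit(cache=True)
def _sgd_epochs(w1, b1, w2, b2, w3, b3, idx_mat, lengths, targets, perms,
                lr, t_off, t_on):  # pragma: no cover - exercised via train()
    n_h1 = b1.shape[0]
    n_h2 = b2.shape[0]
    n_out = b3.shape[0]
    n_epochs = perms.shape[0]
    n_items = perms.shape[1]
    h1 = np.empty(n_h1)
    h2 = np.empty(n_h2)
    out = np.empty(n_out)
    d3 = np.empty(n_out)
    d2 = np.empty(n_h2)
    d1 = np.empty(n_h1)
    losses = np.empty(n_epochs)
    for e in range(n_epochs):
        total = 0.0
        for ii in range(n_items):
            m = perms[e, ii]
            L = lengths[m]
            # forward
            for j in range(n_h1):
                s = b1[j]
                for k in range(L):
                    s += w1[idx_mat[m, k], j]
                h1[j] = np.tanh(s)
            for j in range(n_h2):
                s = b2[j]
                for k in range(n_h1):
                    s += w2[k, j] * h1[k]
                h2[j] = np.tanh(s)
            for j in range(n_out):
                s = b3[j]
                for k in range(n_h2):
                    s += w3[k, j] * h2[k]
                out[j] = np.tanh(s)
            # output delta
            t_idx = targets[m]
            for j in range(n_out):
                t = t_on if j == t_idx else t_off
                err = out[j] - t
                total += err * err
                d3[j] = 2.0 * err * (1.0 - out[j] * out[j])
            # backpropagate through the (pre-update) weights
            for k in range(n_h2):
                s = 0.0
                for j in range(n_out):
                    s += w3[k, j] * d3[j]
                d2[k] = s * (1.0 - h2[k] * h2[k])
            for k in range(n_h1):
                s = 0.0
                for j in range(n_h2):
                    s += w2[k, j] * d2[j]
                d1[k] = s * (1.0 - h1[k] * h1[k])
            # parameter updates
            for k in range(n_h2):
                for j in range(n_out):
                    w3[k, j] -= lr * d3[j] * h2[k]
            for j in range(n_out):
                b3[j] -= lr * d3[j]
            for k in range(n_h1):
                for j in range(n_h2):
                    w2[k, j] -= lr * d2[j] * h1[k]
            for j in range(n_h2):
                b2[j] -= lr * d2[j]
            for k in range(L):
                row = idx_mat[m, k]
                for j in range(n_h1):
                    w1[row, j] -= lr * d1[j]
            for j in range(n_h1):
                b1[j] -= lr * d1[j]
        losses[e] = total / n_items
    return losses


def _pack_corpus(corpus: Corpus):
    """Sparse index matrix, lengths and target key indices for the kernel."""
    n = len(corpus)
    lengths = np.array([m.length for m in corpus], dtype=np.int64)
    idx_mat = np.zeros((n, int(lengths.max())), dtype=np.int64)
    for i, m in enumerate(corpus):
        idx_mat[i, : m.length] = active_indices(m)
    targets = np.array([m.key.index for m in corpus], dtype=np.int64)
    return idx_mat, lengths, targets


def train(state: NetworkState, corpus: Corpus, cfg: TrainingConfig) -> list[Checkpoint]:
    """Train in place by online backpropagation; return periodic checkpoints.

    Each epoch presents every corpus item exactly once (shuffled order when
    ``cfg.shuffle``). Checkpoints carry deep parameter copies, so later
    evaluation can never disturb training. Raises :class:`DivergenceError` if
    the epoch loss stops being finite.
    """
    if not corpus.augmented:
        raise ValueError("training expects a transposition-augmented corpus")
    if len(corpus) == 0:
        raise EmptyCorpusError("cannot train on an empty corpus")
    if state.layer_sizes[0] != INPUT_SIZE and any(
        m.length * 12 > state.layer_sizes[0] for m in corpus
    ):
        raise ValueError("corpus melodies exceed the network's input capacity")

    idx_mat, lengths, targets = _pack_corpus(corpus)
    n = len(corpus)
    rng = np.random.default_rng(cfg.seed)
    t_off, t_on = cfg.target_levels

    checkpoints: list[Checkpoint] = []
    if cfg.include_baseline:
        checkpoints.append(Checkpoint(0, state.copy(), float("nan")))

    cp_epochs = checkpoint_epochs(cfg.n_epochs, cfg.checkpoint_interval)
    done = 0
    for cp_epoch in cp_epochs:
        n_seg = cp_epoch - done
        if cfg.shuffle:
            perms = np.stack([rng.permutation(n) for _ in range(n_seg)])
        else:
            perms = np.tile(np.arange(n), (n_seg, 1))
        losses = _sgd_epochs(
            state.w1, state.b1, state.w2, state.b2, state.w3, state.b3,
            idx_mat, lengths, targets, perms.astype(np.int64),
            float(cfg.learning_rate), float(t_off), float(t_on),
        )
        if not np.all(np.isfinite(losses)):
            bad = int(np.flatnonzero(~np.isfinite(losses))[0])
            raise DivergenceError(done + bad + 1)
        done = cp_epoch
        state.epoch = done
        checkpoints.append(Checkpoint(done, state.copy(), float(losses[-1])))
    return checkpoints


# ---------------------------------------------------------------------------
# Checkpoint serialization (versioned npz archives)
# ---------------------------------------------------------------------------

def save_checkpoint(checkpoint: Checkpoint, path: str | Path) -> None:
    s = checkpoint.state
    np.savez(
        path,
        format_version=CHECKPOINT_FORMAT_VERSION,
        epoch=checkpoint.epoch,
        training_loss=checkpoint.training_loss,
        seed=s.seed,
        w1=s.w1, b1=s.b1, w2=s.w2, b2=s.b2, w3=s.w3, b3=s.b3,
    )


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format version {version}")
        state = NetworkState(
            w1=data["w1"], b1=data["b1"], w2=data["w2"], b2=data["b2"],
            w3=data["w3"], b3=data["b3"],
            seed=int(data["seed"]), epoch=int(data["epoch"]),
        )
        return Checkpoint(int(data["epoch"]), state, float(data["training_loss"]))
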