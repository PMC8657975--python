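"""The sparsely connected autoencoder (SCA).

A single-hidden-layer autoencoder in which each hidden node corresponds to
an interpretable metafeature (a transcription factor, a miRNA, or a cell
cluster) and both encoder and decoder weights are zeroed outside the known
metafeature -> target-feature relationships:

    h    = act((M . W_e) x + b_e)
    xhat = (M^T . W_d) h + b_d

with M the binary connectivity mask (metafeatures x features) and ``.`` the
elementwise product. Masking is enforced by multiplying the weights by the
mask in the forward pass, so gradient flows only through unmasked entries
and masked positions are exactly zero at every step.

Training minimises mean squared reconstruction error with Adam. Runs are
deterministic given a seed; the multi-run driver ("permutations" — here,
independent re-initialization + retraining) gives run ``r`` the seed
``base_seed + r`` so runs are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import RelationshipTable


class TrainingDivergedError(RuntimeError):
    """Raised when the reconstruction loss becomes non-finite."""


@dataclass
class ConnectivityMask:
    """Binary metafeatures x features matrix of allowed connections."""

    values: np.ndarray
    metafeature_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if self.values.shape != (len(self.metafeature_ids), len(self.feature_ids)):
            raise ValueError("mask shape does not match ID lists")
        if self.values.size and (self.values.sum(axis=1) == 0).any():
            raise ValueError("mask has an all-zero metafeature row")
        self.values = self.values.astype(np.float64)

    @property
    def n_metafeatures(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def build_mask(
    rel: RelationshipTable,
    feature_ids: Sequence[str],
    drop_unconnected: bool = True,
) -> ConnectivityMask:
    """Binarize a relationship table against the features of a matrix.

    ``mask[k, j] = 1`` iff feature ``j`` is a target of metafeature ``k``.
    Metafeatures with no surviving target are dropped; with
    ``drop_unconnected`` features connected to no metafeature are removed
    as well (and should be removed from the model input downstream).
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValueError("feature_ids is empty")
    col = {g: j for j, g in enumerate(feature_ids)}
    kept_mf: list[str] = []
    rows: list[np.ndarray] = []
    for mf, targets in rel.entries.items():
        row = np.zeros(len(feature_ids))
        hits = [col[g] for g in targets if g in col]
        if not hits:
            continue
        row[hits] = 1.0
        kept_mf.append(mf)
        rows.append(row)
    if not kept_mf:
        raise ValueError("no metafeature has any target among the given features")
    values = np.vstack(rows)
    if drop_unconnected:
        connected = values.sum(axis=0) > 0
        values = values[:, connected]
        feature_ids = [g for g, c in zip(feature_ids, connected) if c]
    return ConnectivityMask(values, kept_mf, feature_ids)


@dataclass
class SCAConfig:
    """Training hyperparameters.

    n_epochs
        Full passes over the data (default 1000, matching the toolkit's
        pseudo-bulk and metagene defaults).
    learning_rate
        Adam step size.
    hidden_activation
        ``relu`` (default; keeps hidden activations nonnegative so they can
        be treated as pseudo-counts) or ``sigmoid``.
    batch_size
        ``None`` = full batch when n_samples <= 2048, else minibatches of
        128 with per-epoch shuffling seeded by the run seed.
    base_seed
        Seed of run 0 in a multi-run driver; run r uses base_seed + r.
    """

    n_epochs: int = 1000
    learning_rate: float = 1e-3
    hidden_activation: str = "relu"
    batch_size: int | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.hidden_activation not in ("relu", "sigmoid"):
            raise ValueError("hidden_activation must be 'relu' or 'sigmoid'")


def scale_input(x: np.ndarray, counts: bool = True) -> np.ndarray:
    """Standard input preparation: log1p (for counts) then per-feature
    min-max scaling to [0, 1]. Constant features map to 0."""
    x = np.asarray(x, dtype=np.float64)
    if counts:
        x = np.log1p(x)
    lo = x.min(axis=0, keepdims=True)
    span = x.max(axis=0, keepdims=True) - lo
    span[span == 0] = 1.0
    return (x - lo) / span


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return 1.0 / (1.0 + np.exp(-z))


def _activate_grad(z: np.ndarray, h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(np.float64)
    return h * (1.0 - h)


class SparseAutoencoder:
    """Masked autoencoder model over a samples x features data matrix.

    Parameters
    ----------
    data
        samples x features array, columns aligned to ``mask.feature_ids``.
        Expected to be scaled to [0, 1] per feature (see
        :func:`scale_input`); pass ``prescaled=False`` to have the model
        apply the standard count scaling itself.
    mask
        The metafeature -> feature connectivity mask; the hidden layer has
        one node per metafeature.
    config
        Training hyperparameters (:class:`SCAConfig`).
    """

    def __init__(
        self,
        data: np.ndarray,
        mask: ConnectivityMask,
        config: SCAConfig | None = None,
        prescaled: bool = True,
    ) -> None:
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2 or data.shape[1] != mask.n_features:
            raise ValueError(
                f"data has {data.shape} but mask expects {mask.n_features} feature columns"
            )
        self.data = data if prescaled else scale_input(data)
        self.mask = mask
        self.config = config or SCAConfig()

    # -- internals -----------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        k, f = self.mask.values.shape
        lim_e = np.sqrt(6.0 / (f + k))
        lim_d = np.sqrt(6.0 / (k + f))
        return {
            "We": rng.uniform(-lim_e, lim_e, size=(k, f)) * self.mask.values,
            "be": np.zeros(k),
            "Wd": rng.uniform(-lim_d, lim_d, size=(f, k)) * self.mask.values.T,
            "bd": np.zeros(f),
        }

    def _forward(self, x: np.ndarray, p: dict[str, np.ndarray]):
        me = p["We"] * self.mask.values
        md = p["Wd"] * self.mask.values.T
        z = x @ me.T + p["be"]
        h = _activate(z, self.config.hidden_activation)
        xhat = h @ md.T + p["bd"]
        return z, h, xhat

    def _loss_and_grads(self, x: np.ndarray, p: dict[str, np.ndarray]):
        n, f = x.shape
        z, h, xhat = self._forward(x, p)
        resid = xhat - x
        loss = float(np.mean(resid**2))
        g = 2.0 * resid / (n * f)
        md = p["Wd"] * self.mask.values.T
        grads = {
            "Wd": (g.T @ h) * self.mask.values.T,
            "bd": g.sum(axis=0),
        }
        dh = g @ md
        dz = dh * _activate_grad(z, h, self.config.hidden_activation)
        grads["We"] = (dz.T @ x) * self.mask.values
        grads["be"] = dz.sum(axis=0)
        return loss, grads

    def fit(self, seed: int | None = None, run_index: int = 0) -> "SCAResults":
        """Train for exactly ``config.n_epochs`` epochs (no early stopping).

        Deterministic given ``seed`` (full-batch mode is bitwise
        reproducible). Raises :class:`TrainingDivergedError` naming the
        epoch if the loss becomes non-finite.
        """
        cfg = self.config
        if seed is None:
            seed = cfg.base_seed
        rng = np.random.default_rng(seed)
        params = self._init_params(rng)
        n = self.data.shape[0]
        batch_size = cfg.batch_size
        if batch_size is None and n > 2048:
            batch_size = 128

        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        loss_history = np.empty(cfg.n_epochs)

        for epoch in range(cfg.n_epochs):
            if batch_size is None:
                batches = [self.data]
            else:
                order = rng.permutation(n)
                batches = [
                    self.data[order[i : i + batch_size]] for i in range(0, n, batch_size)
                ]
            epoch_loss = 0.0
            for xb in batches:
                loss, grads = self._loss_and_grads(xb, params)
                epoch_loss += loss * xb.shape[0]
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} (run {run_index})"
                    )
                t += 1
                for key in params:
                    adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * grads[key]
                    adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * grads[key] ** 2
                    mhat = adam_m[key] / (1 - beta1**t)
                    vhat = adam_v[key] / (1 - beta2**t)
                    params[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            loss_history[epoch] = epoch_loss / n

        # hard-mask for exact zeros in the stored parameters
        params["We"] *= self.mask.values
        params["Wd"] *= self.mask.values.T
        _, hidden, xhat = self._forward(self.data, params)
        final_loss = float(np.mean((xhat - self.data) ** 2))
        return SCAResults(
            model=self,
            params=params,
            hidden=hidden,
            loss_history=loss_history,
            final_loss=final_loss,
            seed=seed,
            run_index=run_index,
        )


@dataclass
class SCAResults:
    """Fitted SCA: trained weights, hidden activations and diagnostics."""

    model: SparseAutoencoder
    params: dict[str, np.ndarray]
    hidden: np.ndarray
    loss_history: np.ndarray
    final_loss: float
    seed: int
    run_index: int = 0

    @property
    def metafeature_ids(self) -> list[str]:
        return self.model.mask.metafeature_ids

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Hidden activations for new samples (columns as in training)."""
        _, h, _ = self.model._forward(np.asarray(x, dtype=np.float64), self.params)
        return h

    def reconstruct(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.model.data if x is None else np.asarray(x, dtype=np.float64)
        return self.model._forward(x, self.params)[2]

    def summary(self) -> str:
        cfg = self.model.config
        mask = self.model.mask
        lines = [
            "Sparsely Connected Autoencoder Results",
            "=" * 46,
            f"samples:              {self.model.data.shape[0]}",
            f"features:             {mask.n_features}",
            f"metafeatures (hidden): {mask.n_metafeatures}",
            f"mask density:         {mask.values.mean():.4f}",
            f"activation:           {cfg.hidden_activation}",
            f"epochs:               {cfg.n_epochs}",
            f"learning rate:        {cfg.learning_rate:g}",
            f"seed / run:           {self.seed} / {self.run_index}",
            f"initial MSE:          {self.loss_history[0]:.6g}",
            f"final MSE:            {self.final_loss:.6g}",
            "-" * 46,
            "metafeature   mean activation",
        ]
        means = self.hidden.mean(axis=0)
        for mf, mu in zip(self.metafeature_ids, means):
            lines.append(f"{mf:<14s}{mu:.6g}")
        return "\n".join(lines)


def train_sca(
    data: np.ndarray,
    mask: ConnectivityMask,
    config: SCAConfig | None = None,
    seed: int | None = None,
) -> SCAResults:
    """Convenience wrapper: build the model and fit one run."""
    return SparseAutoencoder(data, mask, config).fit(seed=seed)


def run_permutations(
    data: np.ndarray,
    mask: ConnectivityMask,
    config: SCAConfig | None = None,
    n_runs: int = 20,
) -> list[SCAResults]:
    """Independent re-initialization + retraining, ``n_runs`` times.

    Run ``r`` uses seed ``config.base_seed + r``, so each run's output
    depends only on its own seed and runs are order-independent.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or SCAConfig()
    model = SparseAutoencoder(data, mask, config)
    out: list[SCAResults] = []
    for r in range(n_runs):
        try:
            res = model.fit(seed=config.base_seed + r, run_index=r)
        except TrainingDivergedError as exc:
            raise TrainingDivergedError(f"run {r}: {exc}") from exc
        out.append(res)
    return out
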