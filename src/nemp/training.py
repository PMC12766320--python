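"""Loss, optimizer loop, metrics and checkpointing for fitting the
potential to labeled datasets.

The loss is a weighted sum of per-atom-normalised squared energy residuals
and per-component squared force residuals; normalising energies per atom
keeps mixed-size batches balanced.  Optimisation is Adam with an
exponentially decaying learning rate; training gradients flow through the
force computation (mixed second derivatives of the energy) on the autodiff
tape.  Training runs in float32 by default — the working precision the
model is meant to be deployed at — and is bit-reproducible for a fixed
seed and thread count at either precision; set ``precision='float64'``
for strict-tolerance work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .model import NempModel
from .systems_io import Dataset

__all__ = ["TrainConfig", "Metrics", "weighted_loss", "fit", "evaluate"]


@dataclass
class TrainConfig:
    energy_weight: float = 1.0       # on mean((ΔE/N_atom)²), eV²
    force_weight: float = 10.0       # on mean(ΔF²) over components, (eV/Å)²
    batch_size: int = 100
    lr: float = 0.01
    lr_final: float = 1.0e-3         # reached at max_epochs (exponential decay)
    max_epochs: int = 500
    patience: int = 200              # epochs without validation improvement
    seed: int = 0
    precision: str = "float32"       # "float32" | "float64"
    validation_fraction: float = 0.1
    eval_every: int = 1              # validate every k epochs

    def __post_init__(self):
        if self.energy_weight < 0 or self.force_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.energy_weight == 0 and self.force_weight == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")

    @property
    def dtype(self):
        return np.float32 if self.precision == "float32" else np.float64


@dataclass
class Metrics:
    """Prediction errors; energies in meV, forces in meV Å⁻¹."""

    rmse_energy: float
    mae_energy: float
    rmse_energy_per_atom: float
    rmse_force: float
    mae_force: float
    n_structures: int
    rmse_energy_per_unit: float | None = None   # e.g. per molecule

    def __post_init__(self):
        for name in ("rmse_energy", "mae_energy", "rmse_energy_per_atom",
                     "rmse_force", "mae_force"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"metric {name} must be finite and nonnegative")


def weighted_loss(e_pred, f_pred, e_ref, f_ref, n_atoms, cfg: TrainConfig) -> float:
    """w_E · mean(((E−E_ref)/N_atom)²) + w_F · mean((F−F_ref)²).

    The force mean runs over all 3N Cartesian components of the batch.
    """
    e_pred, e_ref = np.asarray(e_pred, float), np.asarray(e_ref, float)
    f_pred, f_ref = np.asarray(f_pred, float), np.asarray(f_ref, float)
    n_atoms = np.asarray(n_atoms, float)
    if e_pred.shape != e_ref.shape or f_pred.shape != f_ref.shape:
        raise ValueError("prediction/reference shape mismatch")
    de = (e_pred - e_ref) / n_atoms
    loss = cfg.energy_weight * float(np.mean(de * de))
    if f_pred.size:
        loss += cfg.force_weight * float(np.mean((f_pred - f_ref) ** 2))
    return loss


def _labeled_batch(model: NempModel, systems: list) -> dict:
    batch = model.assemble(systems)
    batch["E_ref"] = np.array([s.energy for s in systems], dtype=float)
    batch["F_ref"] = np.concatenate([s.forces for s in systems], axis=0)
    return batch


def _batch_loss(model, batch, params, cfg: TrainConfig):
    pos = ad.tensor(batch["positions"], requires_grad=True)
    res = model.forward(batch, pos, params)
    e = res["E_struct"]
    gpos, = ad.grad(ad.sum_(e), [pos], create_graph=True)
    n_at = ad.constant(batch["n_atoms_per_struct"].astype(float))
    de = (e - ad.constant(batch["E_ref"])) / n_at
    loss = ad.sum_(de * de) * (cfg.energy_weight / len(batch["E_ref"]))
    # F_pred − F_ref = −gpos − F_ref
    df = gpos + ad.constant(batch["F_ref"])
    loss = loss + ad.sum_(df * df) * (cfg.force_weight / df.data.size)
    return loss


def _predict(model, batch, params) -> tuple[np.ndarray, np.ndarray]:
    pos = ad.tensor(batch["positions"], requires_grad=True)
    res = model.forward(batch, pos, params)
    gpos, = ad.grad(ad.sum_(res["E_struct"]), [pos])
    return res["E_struct"].data.astype(float), -gpos.data.astype(float)


def _split_train_valid(data: Dataset, cfg: TrainConfig, rng) -> tuple[list, list]:
    if data.split_labels is not None and "valid" in data.split_labels:
        tr = [s for s, lab in zip(data.systems, data.split_labels) if lab == "train"]
        va = [s for s, lab in zip(data.systems, data.split_labels) if lab == "valid"]
        return tr, va
    idx = rng.permutation(len(data))
    if cfg.validation_fraction <= 0 or len(data) < 2:
        n_valid = 0
    else:
        n_valid = max(1, int(round(cfg.validation_fraction * len(data))))
    va = [data.systems[i] for i in idx[:n_valid]]
    tr = [data.systems[i] for i in idx[n_valid:]]
    return tr, va


def _e0_least_squares(model: NempModel, systems: list) -> np.ndarray:
    """Least-squares per-element reference energies from train compositions."""
    n_el = len(model.config.elements)
    z_index = {z: k for k, z in enumerate(model.config.elements)}
    A = np.zeros((len(systems), n_el))
    b = np.array([s.energy for s in systems], dtype=float)
    for r, s in enumerate(systems):
        for z in s.elements:
            A[r, z_index[int(z)]] += 1.0
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol


def fit(model: NempModel, data: Dataset, cfg: TrainConfig) -> tuple[NempModel, list[dict]]:
    """Train and return (best-validation model, per-epoch history).

    The history rows record epoch, learning rate, mean train loss,
    validation energy/force RMSE (meV, meV Å⁻¹) and the running best
    validation loss (non-increasing by construction).
    """
    for s in data:
        if s.energy is None or s.forces is None:
            raise ValueError("every system must carry energy and forces")
    rng = np.random.default_rng(cfg.seed)
    train_sys, valid_sys = _split_train_valid(data, cfg, rng)
    if cfg.max_epochs == 0:
        return NempModel(model.config, {k: v.copy() for k, v in model.params.items()}), []
    start = {k: v.copy() for k, v in model.params.items()}
    start["e0"] = start["e0"] + _e0_least_squares(model, train_sys)
    order = rng.permutation(len(train_sys))
    batches = [_labeled_batch(model, [train_sys[i] for i in order[k:k + cfg.batch_size]])
               for k in range(0, len(train_sys), cfg.batch_size)]
    vbatch = _labeled_batch(model, valid_sys) if valid_sys else None

    dtype = cfg.dtype
    master = {k: v.astype(dtype) for k, v in start.items()}
    adam_m = {k: np.zeros_like(v) for k, v in master.items()}
    adam_v = {k: np.zeros_like(v) for k, v in master.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best = np.inf
    best_params = {k: v.copy() for k, v in master.items()}
    best_epoch = 0
    history: list[dict] = []

    with ad.default_dtype(dtype):
        for epoch in range(1, cfg.max_epochs + 1):
            lr = cfg.lr * (cfg.lr_final / cfg.lr) ** ((epoch - 1) / max(cfg.max_epochs - 1, 1))
            # batch losses are measured before their update, so the matching
            # parameter snapshot is the one from the top of the epoch
            pre = {k: v.copy() for k, v in master.items()} if vbatch is None else None
            ep_loss = 0.0
            for bi, batch in enumerate(batches):
                params = {k: ad.tensor(v, requires_grad=True) for k, v in master.items()}
                loss = _batch_loss(model, batch, params, cfg)
                lval = float(loss.data)
                if not np.isfinite(lval):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {bi}, lr {lr:.2e}")
                grads = ad.grad(loss, list(params.values()))
                step += 1
                corr = np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
                for k, g in zip(master, grads):
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * g.data
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * g.data * g.data
                    master[k] = master[k] - (lr * corr) * adam_m[k] / \
                        (np.sqrt(adam_v[k]) + eps)
                ep_loss += lval
            row = {"epoch": epoch, "lr": lr, "train_loss": ep_loss / len(batches),
                   "valid_e_rmse": np.nan, "valid_f_rmse": np.nan}
            if vbatch is not None and (epoch % cfg.eval_every == 0
                                       or epoch == cfg.max_epochs):
                params = {k: ad.tensor(v) for k, v in master.items()}
                e_pred, f_pred = _predict(model, vbatch, params)
                vloss = weighted_loss(e_pred, f_pred, vbatch["E_ref"], vbatch["F_ref"],
                                      vbatch["n_atoms_per_struct"], cfg)
                row["valid_e_rmse"] = 1e3 * float(np.sqrt(np.mean(
                    (e_pred - vbatch["E_ref"]) ** 2)))
                row["valid_f_rmse"] = 1e3 * float(np.sqrt(np.mean(
                    (f_pred - vbatch["F_ref"]) ** 2)))
                if vloss < best:
                    best = vloss
                    best_params = {k: v.copy() for k, v in master.items()}
                    best_epoch = epoch
            elif vbatch is None:
                if ep_loss < best:
                    best = ep_loss
                    best_params = pre
                    best_epoch = epoch
            row["best_valid"] = best
            history.append(row)
            if epoch - best_epoch > cfg.patience:
                break

    best64 = {k: v.astype(np.float64) for k, v in best_params.items()}
    return NempModel(model.config, best64), history


def evaluate(model: NempModel, data: Dataset, batch_size: int = 50,
             atoms_per_unit: int | None = None) -> Metrics:
    """Prediction errors in meV / meV Å⁻¹.

    ``atoms_per_unit`` reports an additional energy RMSE normalised per
    chemical unit of that many atoms (e.g. 3 for 'per H₂O' reporting).
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    e_pred, e_ref, f_pred, f_ref, n_at = [], [], [], [], []
    params = model.params_tensors(False)
    for k in range(0, len(data), batch_size):
        systems = data.systems[k:k + batch_size]
        batch = _labeled_batch(model, systems)
        ep, fp = _predict(model, batch, params)
        e_pred.append(ep)
        f_pred.append(fp)
        e_ref.append(batch["E_ref"])
        f_ref.append(batch["F_ref"])
        n_at.append(batch["n_atoms_per_struct"])
    e_pred, e_ref = np.concatenate(e_pred), np.concatenate(e_ref)
    f_pred, f_ref = np.concatenate(f_pred), np.concatenate(f_ref)
    n_at = np.concatenate(n_at).astype(float)
    de = e_pred - e_ref
    df = (f_pred - f_ref).ravel()
    per_unit = None
    if atoms_per_unit is not None:
        per_unit = 1e3 * float(np.sqrt(np.mean((de / (n_at / atoms_per_unit)) ** 2)))
    return Metrics(
        rmse_energy=1e3 * float(np.sqrt(np.mean(de * de))),
        mae_energy=1e3 * float(np.mean(np.abs(de))),
        rmse_energy_per_atom=1e3 * float(np.sqrt(np.mean((de / n_at) ** 2))),
        rmse_force=1e3 * float(np.sqrt(np.mean(df * df))) if df.size else 0.0,
        mae_force=1e3 * float(np.mean(np.abs(df))) if df.size else 0.0,
        n_structures=len(e_pred),
        rmse_energy_per_unit=per_unit,
    )
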