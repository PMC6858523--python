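"""Scikit-learn-style estimator facade over the network and its training loop.

``SchNOrbRegressor`` follows the sklearn estimator contract: constructor takes
hyperparameters only, ``fit`` consumes a list of electronic records,
fitted state lives in trailing-underscore attributes, and
``get_params``/``set_params`` come from :class:`sklearn.base.BaseEstimator`,
so the model composes with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .chem import BasisSet, Molecule, build_orbital_index
from .model import (ElectronicPrediction, Forward, ModelConfig, init_params,
                    load_checkpoint, predict as _predict, save_checkpoint)
from .training import TrainConfig, TrainHistory, evaluate_loss, train


class SchNOrbRegressor(BaseEstimator):
    """Predicts (H, S, E, F) for molecular geometries after training.

    Parameters mirror the architecture (B, D, T, r_c, delta_mu, gamma,
    n_hidden) and the optimizer schedule (rho, lr0, decay, patience, lr_min,
    batch_size, max_epochs, augment, val_fraction); ``basis`` fixes the
    atomic-orbital layout and the maximal angular momentum L.
    """

    def __init__(self, basis: BasisSet = None, B: int = 64, D: int = 4, T: int = 3,
                 r_c: float = 5.0, delta_mu: float = 0.25, gamma: float = 10.0,
                 n_hidden: int = 64, rho: float = 0.1, lr0: float = 1e-3,
                 decay: float = 0.8, patience: int = 15, lr_min: float = 5e-6,
                 batch_size: int = 8, max_epochs: int = 100, augment: bool = True,
                 val_fraction: float = 0.1, seed: int = 0):
        self.basis = basis
        self.B, self.D, self.T = B, D, T
        self.r_c, self.delta_mu, self.gamma = r_c, delta_mu, gamma
        self.n_hidden = n_hidden
        self.rho, self.lr0, self.decay = rho, lr0, decay
        self.patience, self.lr_min = patience, lr_min
        self.batch_size, self.max_epochs = batch_size, max_epochs
        self.augment, self.val_fraction, self.seed = augment, val_fraction, seed

    # -- sklearn API ----------------------------------------------------
    def _build_config(self) -> ModelConfig:
        if self.basis is None:
            raise ValueError("a BasisSet is required to build the model")
        return ModelConfig.from_basis(
            self.basis, B=self.B, D=self.D, T=self.T, r_c=self.r_c,
            delta_mu=self.delta_mu, gamma=self.gamma, n_hidden=self.n_hidden)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(rho=self.rho, lr0=self.lr0, decay=self.decay,
                           patience=self.patience, lr_min=self.lr_min,
                           batch_size=self.batch_size, max_epochs=self.max_epochs,
                           seed=self.seed, augment=self.augment,
                           val_fraction=self.val_fraction)

    def fit(self, X, y=None, val_records=None):
        """Train on a list of :class:`ElectronicRecord`; ``y`` is unused."""
        self.config_ = self._build_config()
        self.params_ = init_params(self.config_, seed=self.seed)
        self.params_, self.history_ = train(self.params_, self.config_, list(X),
                                            self._train_config(), basis=self.basis,
                                            val_records=val_records)
        return self

    def predict(self, X):
        """Predictions for a molecule or a list of molecules."""
        self._check_fitted()
        single = isinstance(X, Molecule)
        mols = [X] if single else list(X)
        out = [_predict(self.params_, self.config_, m,
                        build_orbital_index(m, self.basis)) for m in mols]
        return out[0] if single else out

    def score(self, X, y=None):
        """Negative mean combined loss (higher is better, sklearn convention)."""
        self._check_fitted()
        index = build_orbital_index(X[0].molecule, self.basis)
        return -evaluate_loss(self.params_, self.config_, list(X), self.rho, index)["total"]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit() or load()")

    # -- interoperation --------------------------------------------------
    def provider(self) -> "ModelProvider":
        self._check_fitted()
        return ModelProvider(self.params_, self.config_, self.basis)

    def save(self, path, extra: dict = None) -> None:
        self._check_fitted()
        save_checkpoint(path, self.params_, self.config_, self.basis, extra)

    @classmethod
    def load(cls, path) -> "SchNOrbRegressor":
        params, config, basis, meta = load_checkpoint(path)
        est = cls(basis=basis, B=config.B, D=config.D, T=config.T, r_c=config.r_c,
                  delta_mu=config.delta_mu, gamma=config.gamma,
                  n_hidden=config.n_hidden)
        est.config_, est.params_ = config, params
        est.meta_ = meta
        return est


class ModelProvider:
    """Force/matrix provider facade over a parameter set (for MD, properties)."""

    def __init__(self, params: dict, config: ModelConfig, basis: BasisSet = None):
        self.params, self.config, self.basis = params, config, basis

    def _index(self, mol: Molecule):
        return build_orbital_index(mol, self.basis) if self.basis is not None else None

    def matrices(self, mol: Molecule):
        fwd = Forward(self.params, self.config, mol, self._index(mol))
        return fwd.H.value.copy(), fwd.S.value.copy()

    def matrices_forward(self, mol: Molecule) -> Forward:
        return Forward(self.params, self.config, mol, self._index(mol))

    def energy(self, mol: Molecule) -> float:
        fwd = Forward(self.params, self.config, mol, self._index(mol))
        return float(fwd.E.value)

    def energy_forces(self, mol: Molecule):
        pred = _predict(self.params, self.config, mol, self._index(mol))
        return pred.E, pred.F

    def predict(self, mol: Molecule) -> ElectronicPrediction:
        return _predict(self.params, self.config, mol, self._index(mol))
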