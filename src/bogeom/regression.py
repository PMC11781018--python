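"""Gaussian-process regression surrogate with an RBF kernel.

The surrogate is trained on standardized inputs and outputs: every
explanatory column and the objective are shifted/scaled to zero mean and
unit variance before fitting, and predictions are mapped back to objective
units.  Hyperparameters (length-scale, signal variance, observation-noise
variance) are obtained by maximizing the log marginal likelihood with the
Adam optimizer in log-parameter space, full-batch, for a fixed number of
epochs (default 100 at learning rate 0.2).  An observation-noise term is
always present (floor 1e-6 in standardized units) so the model remains
well-conditioned and can absorb deliberately noisy energies.

The class follows the scikit-learn estimator protocol (constructor
parameters only, fitted attributes with a trailing underscore,
``get_params``/``set_params`` inherited from ``BaseEstimator``).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["TrainingSet", "GaussianProcessSurrogate", "ConditioningError"]


class ConditioningError(np.linalg.LinAlgError):
    """Kernel matrix remained singular after jitter escalation."""


class TrainingSet:
    """Plain container pairing an (n, d) input matrix with an n-vector of
    objective values (maximization convention)."""

    def __init__(self, X, y):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of rows")

    @property
    def n(self) -> int:
        return self.y.size


def _standardize_columns(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)  # constant-column fallback
    return mean, scale


def _sq_dists(A, B):
    """Pairwise squared Euclidean distances, (nA, nB)."""
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


class GaussianProcessSurrogate(BaseEstimator, RegressorMixin):
    """GP regressor with isotropic RBF kernel and Adam-fitted hyperparameters.

    Parameters
    ----------
    epochs : int
        Number of full-batch Adam steps on the log marginal likelihood.
    learning_rate : float
        Adam step size.
    lengthscale_init, signal_variance_init, noise_variance_init : float
        Hyperparameter initialization in standardized units.
    noise_floor : float
        Lower bound on the observation-noise variance (standardized units).
    random_state : int or None
        Accepted for interface uniformity; the fit is deterministic.
    """

    def __init__(
        self,
        epochs: int = 100,
        learning_rate: float = 0.2,
        lengthscale_init: float = 1.0,
        signal_variance_init: float = 1.0,
        noise_variance_init: float = 1e-2,
        noise_floor: float = 1e-6,
        random_state=None,
    ):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.lengthscale_init = lengthscale_init
        self.signal_variance_init = signal_variance_init
        self.noise_variance_init = noise_variance_init
        self.noise_floor = noise_floor
        self.random_state = random_state

    # -- kernel helpers (standardized units) --------------------------------

    def _kernel(self, A, B, lengthscale, signal_var):
        return signal_var * np.exp(-0.5 * _sq_dists(A, B) / lengthscale**2)

    def _factorize(self, K):
        """Cholesky with jitter escalation; raises ConditioningError."""
        jitter = 0.0
        scale = np.mean(np.diag(K))
        for _ in range(8):
            try:
                L = np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
                return L, jitter
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-10 * scale)
        raise ConditioningError("kernel matrix is numerically singular")

    def _lml_and_grad(self, theta, Xs, ys):
        """Log marginal likelihood and gradient w.r.t. log-hyperparameters
        theta = (log lengthscale, log signal_var, log noise_var)."""
        ell = np.exp(theta[0])
        sf2 = np.exp(theta[1])
        sn2 = np.exp(theta[2]) + self.noise_floor
        n = ys.size
        D2 = _sq_dists(Xs, Xs)
        Kf = sf2 * np.exp(-0.5 * D2 / ell**2)
        K = Kf + sn2 * np.eye(n)
        L, jitter = self._factorize(K)
        alpha = cho_solve((L, True), ys)
        Kinv = cho_solve((L, True), np.eye(n))
        lml = (
            -0.5 * ys @ alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        M = np.outer(alpha, alpha) - Kinv  # dLML/dK = M/2
        grad = np.empty(3)
        grad[0] = 0.5 * np.sum(M * (Kf * D2 / ell**2))
        grad[1] = 0.5 * np.sum(M * Kf)
        # chain rule through the +noise_floor offset: d sn2/d theta2 = exp(theta2)
        grad[2] = 0.5 * np.trace(M) * np.exp(theta[2])
        return lml, grad

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of rows")
        if y.size < 2:
            raise ValueError("need at least two training points")
        self.X_mean_, self.X_scale_ = _standardize_columns(X)
        self.y_mean_ = y.mean()
        y_scale = y.std()
        self.y_scale_ = 1.0 if y_scale < 1e-12 else y_scale
        Xs = (X - self.X_mean_) / self.X_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        theta = np.log(
            [
                self.lengthscale_init,
                self.signal_variance_init,
                max(self.noise_variance_init - self.noise_floor, 1e-12),
            ]
        )
        lml0, _ = self._lml_and_grad(theta, Xs, ys)
        # Adam ascent, full batch, fixed epoch count
        m = np.zeros(3)
        v = np.zeros(3)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for t in range(1, self.epochs + 1):
            _, g = self._lml_and_grad(theta, Xs, ys)
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            theta = theta + self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            theta = np.clip(theta, -15.0, 15.0)

        self.lengthscale_ = float(np.exp(theta[0]))
        self.signal_variance_ = float(np.exp(theta[1]))
        self.noise_variance_ = float(np.exp(theta[2]) + self.noise_floor)
        lml1, _ = self._lml_and_grad(theta, Xs, ys)
        self.log_marginal_likelihood_path_ = (float(lml0), float(lml1))

        self.X_train_ = Xs
        K = self._kernel(Xs, Xs, self.lengthscale_, self.signal_variance_)
        K += self.noise_variance_ * np.eye(ys.size)
        L, jitter = self._factorize(K)
        self.L_ = L
        self.jitter_ = jitter
        self.alpha_ = cho_solve((L, True), ys)
        # explicit inverse cached for the many cheap gradient queries made
        # during acquisition maximization (one O(n^3) solve per fit)
        self.K_inv_ = cho_solve((L, True), np.eye(ys.size))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, return_std: bool = False):
        """Posterior mean (and latent standard deviation) in objective units."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query dimensionality {X.shape[1]} != training "
                f"dimensionality {self.n_features_in_}"
            )
        Xs = (X - self.X_mean_) / self.X_scale_
        Ks = self._kernel(Xs, self.X_train_, self.lengthscale_, self.signal_variance_)
        mu = Ks @ self.alpha_ * self.y_scale_ + self.y_mean_
        if not return_std:
            return mu
        V = solve_triangular(self.L_, Ks.T, lower=True)
        var = self.signal_variance_ - np.sum(V**2, axis=0)
        sigma = np.sqrt(np.maximum(var, 0.0)) * self.y_scale_
        return mu, sigma

    def predict_gradient(self, x):
        """Mean, std and their gradients w.r.t. the raw coordinates at a
        single point.  Returns (mu, sigma, dmu_dx, dsigma_dx)."""
        x = np.asarray(x, dtype=float).ravel()
        xs = (x - self.X_mean_) / self.X_scale_
        diff = self.X_train_ - xs  # (n, d), standardized
        d2 = np.einsum("ij,ij->i", diff, diff)
        k = self.signal_variance_ * np.exp(-0.5 * d2 / self.lengthscale_**2)
        mu_s = k @ self.alpha_
        v = self.K_inv_ @ k
        var = self.signal_variance_ - k @ v
        var = max(var, 0.0)
        sigma_s = np.sqrt(var)
        # dk_i/dx_s = k_i * (X_i - x_s) / ell^2
        dk = (k[:, None] * diff) / self.lengthscale_**2  # (n, d)
        dmu_s = dk.T @ self.alpha_
        dvar_s = -2.0 * dk.T @ v
        if sigma_s > 1e-12:
            dsigma_s = dvar_s / (2.0 * sigma_s)
        else:
            dsigma_s = np.zeros_like(dvar_s)
        # chain rule through input standardization, then de-standardize y
        scale = self.y_scale_ / self.X_scale_
        mu = mu_s * self.y_scale_ + self.y_mean_
        sigma = sigma_s * self.y_scale_
        return float(mu), float(sigma), dmu_s * scale, dsigma_s * scale

    # -- plain-text checkpointing ------------------------------------------

    def to_text(self, path):
        """Serialize hyperparameters and standardizers to key=value lines."""
        fields = {
            "lengthscale": self.lengthscale_,
            "signal_variance": self.signal_variance_,
            "noise_variance": self.noise_variance_,
            "y_mean": self.y_mean_,
            "y_scale": self.y_scale_,
            "X_mean": ",".join(repr(float(v)) for v in self.X_mean_),
            "X_scale": ",".join(repr(float(v)) for v in self.X_scale_),
        }
        with open(path, "w") as fh:
            for key, value in fields.items():
                fh.write(f"{key}={value}\n")

    @staticmethod
    def read_text(path) -> dict:
        out = {}
        with open(path) as fh:
            for line in fh:
                key, _, value = line.strip().partition("=")
                if "," in value or key in ("X_mean", "X_scale"):
                    out[key] = np.array([float(p) for p in value.split(",")])
                else:
                    out[key] = float(value)
        return out
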