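"""Core learners: random Fourier feature maps, incremental ridge regression,
and exact batch baselines (linear ridge, kernel ridge).

The central object is :class:`IncrementalRidge`, an online multi-output ridge
regressor that maintains the inverse covariance matrix ``A^-1`` with
Sherman--Morrison rank-1 updates, so that each update and each prediction
costs a constant amount of time and memory regardless of how many samples
have been absorbed.  Combined with :class:`RFFMap` -- a frozen randomized
cosine projection whose inner products approximate the RBF (Gaussian)
kernel -- it forms the iRFFRR learner used for proportional myoelectric
control: a non-linear regressor that can be updated on the fly as the
sEMG signal drifts.

Exact kernel ridge regression (:class:`KernelRidgeModel`) is provided as the
accuracy oracle that the random-feature approximation converges to, and plain
linear ridge (:func:`fit_batch_linear`) as the capacity baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "RFFMap",
    "RidgeConfig",
    "IncrementalRidge",
    "KernelRidgeModel",
    "sample_rff",
    "fit_batch_linear",
    "fit_krr",
    "save_model",
    "load_model",
    "LinearRidgeLearner",
    "RFFRidgeLearner",
    "KRRLearner",
    "make_learner",
    "IncrementalUnsupportedError",
]

#: inv_cov is re-symmetrized every this many rank-1 updates to bound float drift
RESYMMETRIZE_EVERY = 1000

MODEL_FORMAT_VERSION = 1


class IncrementalUnsupportedError(TypeError):
    """Raised when an incremental update is requested from a learner that
    cannot be updated in constant time (exact kernel ridge regression)."""


# ---------------------------------------------------------------------------
# Random Fourier features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RFFMap:
    """A frozen random cosine projection approximating the RBF kernel.

    The map sends an input ``x`` of dimension ``n_inputs`` to

        z(x) = sqrt(2 / D) * cos(Omega @ x + b)

    with ``Omega`` (shape ``D x n``) drawn i.i.d. from ``Normal(0, 2*gamma)``
    and phases ``b`` drawn from ``Uniform[0, 2*pi)``.  Inner products
    ``z(x) . z(y)`` are unbiased Monte-Carlo estimates of the RBF kernel
    ``exp(-gamma * ||x - y||^2)``; the approximation sharpens as the number of
    features ``D`` grows.

    Instances are deterministic functions of ``(n_inputs, n_features,
    bandwidth, seed)`` and are never mutated after construction.
    """

    n_inputs: int
    n_features: int
    bandwidth: float
    frequencies: np.ndarray
    phases: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.frequencies.shape != (self.n_features, self.n_inputs):
            raise ValueError(
                f"frequencies must have shape {(self.n_features, self.n_inputs)}, "
                f"got {self.frequencies.shape}"
            )
        if self.phases.shape != (self.n_features,):
            raise ValueError(
                f"phases must have shape {(self.n_features,)}, got {self.phases.shape}"
            )

    @classmethod
    def sample(
        cls, n_inputs: int, n_features: int, bandwidth: float, seed: int
    ) -> "RFFMap":
        """Draw a fresh map; bit-identical for identical arguments."""
        if n_inputs <= 0:
            raise ValueError(f"n_inputs must be positive, got {n_inputs}")
        if n_features <= 0:
            raise ValueError(f"n_features must be positive, got {n_features}")
        if bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {bandwidth}")
        rng = np.random.default_rng(seed)
        # frequency distribution for the RBF kernel: Normal with variance 2*gamma
        freqs = rng.normal(
            0.0, np.sqrt(2.0 * bandwidth), size=(n_features, n_inputs)
        )
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
        return cls(
            n_inputs=n_inputs,
            n_features=n_features,
            bandwidth=bandwidth,
            frequencies=freqs,
            phases=phases,
            seed=seed,
        )

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Map one sample (shape ``(n,)``) or a batch (shape ``(m, n)``) to
        random feature space; every component has magnitude <= sqrt(2/D)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected inputs of dimension {self.n_inputs}, got {X.shape[1]}"
            )
        Z = np.cos(X @ self.frequencies.T + self.phases)
        Z *= np.sqrt(2.0 / self.n_features)
        return Z[0] if single else Z

    __call__ = transform


def sample_rff(
    n_inputs: int, n_features: int, bandwidth: float, seed: int
) -> RFFMap:
    """Functional alias for :meth:`RFFMap.sample`."""
    return RFFMap.sample(n_inputs, n_features, bandwidth, seed)


def rbf_kernel(X: np.ndarray, Y: np.ndarray, bandwidth: float) -> np.ndarray:
    """Exact RBF Gram matrix ``K_ij = exp(-gamma * ||x_i - y_j||^2)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return np.exp(-bandwidth * cdist(X, Y, "sqeuclidean"))


# ---------------------------------------------------------------------------
# Incremental ridge regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RidgeConfig:
    """Ridge regression hyper-parameters: the regularizer ``lambda`` trading
    data fit against weight shrinkage, and the number of jointly learned
    outputs ``p`` (the five finger-force channels in the target application).
    """

    regularizer: float
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if self.regularizer <= 0:
            raise ValueError(f"regularizer must be positive, got {self.regularizer}")
        if self.n_outputs <= 0:
            raise ValueError(f"n_outputs must be positive, got {self.n_outputs}")


class IncrementalRidge:
    """Streaming multi-output ridge regression with constant-cost updates.

    The learner maintains the quantities of the closed-form ridge solution
    ``w = (lambda*I + Z^T Z)^{-1} Z^T Y = A^{-1} beta`` directly:

    - ``inv_cov``      -- ``A^{-1}``, a ``D x D`` symmetric matrix, updated by
      the Sherman--Morrison rank-1 formula when a sample arrives;
    - ``accumulator``  -- ``beta = Z^T Y``, a ``D x p`` matrix;
    - ``weights``      -- ``w = A^{-1} beta``, a ``D x p`` matrix.

    Because the inverse covariance does not depend on the outputs, any number
    of output channels share it: multi-output learning costs one extra
    accumulator column per channel.  After ``m`` updates the state equals the
    batch ridge solution on the same ``m`` samples, in any arrival order.

    Parameters
    ----------
    config
        Regularizer and output count.
    n_features
        Dimensionality ``D`` of the (already mapped) inputs.
    weight_mode
        ``"literal"`` recomputes ``w = A^{-1} beta`` after every single
        update, an ``O(D^2 p)`` matrix product; ``"lazy"`` defers the product
        to the next prediction, which is cheaper on long update streams and
        produces identical results.
    """

    def __init__(
        self,
        config: RidgeConfig,
        n_features: int,
        weight_mode: str = "literal",
    ) -> None:
        if n_features <= 0:
            raise ValueError(f"n_features must be positive, got {n_features}")
        if weight_mode not in ("literal", "lazy"):
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        self.config = config
        self.n_features = int(n_features)
        self.weight_mode = weight_mode
        D, p = self.n_features, config.n_outputs
        self.inv_cov = np.eye(D) / config.regularizer
        self.accumulator = np.zeros((D, p))
        self._weights = np.zeros((D, p))
        self._weights_stale = False
        self.n_updates = 0

    # -- state ------------------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        """Current ridge weights ``w = A^{-1} beta`` (shape ``D x p``)."""
        if self._weights_stale:
            self._weights = self.inv_cov @ self.accumulator
            self._weights_stale = False
        return self._weights

    @property
    def n_outputs(self) -> int:
        return self.config.n_outputs

    # -- learning ---------------------------------------------------------

    def update(self, z: np.ndarray, y: np.ndarray) -> "IncrementalRidge":
        """Absorb one sample ``(z, y)`` via a Sherman--Morrison rank-1 update.

        Time and memory depend only on ``(D, p)``, never on ``n_updates``.
        Returns ``self`` for chaining.
        """
        z = np.asarray(z, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if z.shape[0] != self.n_features:
            raise ValueError(
                f"feature vector has length {z.shape[0]}, expected {self.n_features}"
            )
        if y.shape[0] != self.config.n_outputs:
            raise ValueError(
                f"target vector has length {y.shape[0]}, expected {self.config.n_outputs}"
            )
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite entries in update sample")

        self.accumulator += z[:, None] * y[None, :]
        Az = self.inv_cov @ z
        denom = 1.0 + z @ Az
        self.inv_cov -= np.outer(Az, Az) / denom
        self.n_updates += 1
        if self.n_updates % RESYMMETRIZE_EVERY == 0:
            self.inv_cov = 0.5 * (self.inv_cov + self.inv_cov.T)
        if self.weight_mode == "literal":
            self._weights = self.inv_cov @ self.accumulator
            self._weights_stale = False
        else:
            self._weights_stale = True
        return self

    def update_many(self, Z: np.ndarray, Y: np.ndarray) -> "IncrementalRidge":
        """Absorb a block of ``k`` samples at once.

        Uses the Woodbury identity -- the block generalization of the rank-1
        Sherman--Morrison step -- so the result is numerically equivalent to
        ``k`` sequential calls to :meth:`update`, at vectorized cost.
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        k = Z.shape[0]
        if Z.shape[1] != self.n_features or Y.shape != (k, self.config.n_outputs):
            raise ValueError(
                f"block shapes {Z.shape} / {Y.shape} incompatible with "
                f"(D={self.n_features}, p={self.config.n_outputs})"
            )
        if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite entries in update block")
        if k == 0:
            return self

        self.accumulator += Z.T @ Y
        U = self.inv_cov @ Z.T                      # D x k
        S = np.eye(k) + Z @ U                       # k x k, SPD
        self.inv_cov -= U @ cho_solve(cho_factor(S), U.T)
        self.inv_cov = 0.5 * (self.inv_cov + self.inv_cov.T)
        self.n_updates += k
        if self.weight_mode == "literal":
            self._weights = self.inv_cov @ self.accumulator
            self._weights_stale = False
        else:
            self._weights_stale = True
        return self

    # -- prediction -------------------------------------------------------

    def predict(self, z: np.ndarray) -> np.ndarray:
        """Predict outputs for one feature vector or a batch; pure."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        Z = z[None, :] if single else z
        if Z.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {Z.shape[1]} does not match D={self.n_features}"
            )
        out = Z @ self.weights
        return out[0] if single else out


def init_incremental(
    config: RidgeConfig, n_features: int, weight_mode: str = "literal"
) -> IncrementalRidge:
    """Create a fresh incremental ridge state: ``A^-1 = I/lambda``, zero
    accumulator and weights."""
    return IncrementalRidge(config, n_features, weight_mode=weight_mode)


# ---------------------------------------------------------------------------
# Exact batch baselines
# ---------------------------------------------------------------------------


def fit_batch_linear(
    X: np.ndarray, Y: np.ndarray, regularizer: float
) -> np.ndarray:
    """Closed-form ridge solution ``(lambda*I + X^T X)^{-1} X^T Y``.

    Returns the ``n x p`` weight matrix, one column per output.
    """
    if regularizer <= 0:
        raise ValueError(f"regularizer must be positive, got {regularizer}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in training data")
    n = X.shape[1]
    A = regularizer * np.eye(n) + X.T @ X
    return cho_solve(cho_factor(A), X.T @ Y)


@dataclass
class KernelRidgeModel:
    """Exact RBF kernel ridge regression in dual form.

    Predicts ``f(x) = sum_i c_i k(x, x_i)`` with dual coefficients solving
    ``(K + lambda*I) C = Y`` on the Gram matrix of the stored training
    inputs.  Cost of predictions and (hypothetical) updates grows with the
    training set size, which is why the streaming learner approximates it
    with random features instead.
    """

    dual_coeffs: np.ndarray
    train_inputs: np.ndarray
    bandwidth: float
    regularizer: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        K = rbf_kernel(np.atleast_2d(X), self.train_inputs, self.bandwidth)
        out = K @ self.dual_coeffs
        return out[0] if single else out


def fit_krr(
    X: np.ndarray, Y: np.ndarray, regularizer: float, bandwidth: float
) -> KernelRidgeModel:
    """Fit exact kernel ridge regression with the RBF kernel."""
    if regularizer <= 0:
        raise ValueError(f"regularizer must be positive, got {regularizer}")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    K = rbf_kernel(X, X, bandwidth)
    K[np.diag_indices_from(K)] += regularizer
    C = cho_solve(cho_factor(K), Y)
    return KernelRidgeModel(
        dual_coeffs=C, train_inputs=X, bandwidth=bandwidth, regularizer=regularizer
    )


# ---------------------------------------------------------------------------
# Uniform learner adapters used by the evaluation harness
# ---------------------------------------------------------------------------


class LinearRidgeLearner:
    """Linear ridge baseline with incremental support (identity feature map)."""

    supports_update = True
    name = "rr"

    def __init__(self, n_inputs: int, n_outputs: int, regularizer: float,
                 **_ignored) -> None:
        self.state = IncrementalRidge(
            RidgeConfig(regularizer=regularizer, n_outputs=n_outputs),
            n_features=n_inputs,
            weight_mode="lazy",
        )

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "LinearRidgeLearner":
        self.state.update_many(X, Y)
        return self

    def update(self, X: np.ndarray, Y: np.ndarray) -> "LinearRidgeLearner":
        self.state.update_many(X, Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.state.predict(X)


class RFFRidgeLearner:
    """iRFFRR: incremental ridge regression on random Fourier features."""

    supports_update = True
    name = "irffrr"

    def __init__(
        self,
        n_inputs: int,
        n_outputs: int,
        regularizer: float,
        bandwidth: float,
        n_features: int = 1000,
        seed: int = 0,
    ) -> None:
        self.map = RFFMap.sample(n_inputs, n_features, bandwidth, seed)
        self.state = IncrementalRidge(
            RidgeConfig(regularizer=regularizer, n_outputs=n_outputs),
            n_features=n_features,
            weight_mode="lazy",
        )

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RFFRidgeLearner":
        self.state.update_many(self.map.transform(X), Y)
        return self

    def update(self, X: np.ndarray, Y: np.ndarray) -> "RFFRidgeLearner":
        self.state.update_many(self.map.transform(X), Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.state.predict(self.map.transform(X))


class KRRLearner:
    """Exact kernel ridge oracle; batch only, refuses incremental updates."""

    supports_update = False
    name = "krr"

    def __init__(self, n_inputs: int, n_outputs: int, regularizer: float,
                 bandwidth: float, **_ignored) -> None:
        self.regularizer = regularizer
        self.bandwidth = bandwidth
        self.model: KernelRidgeModel | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "KRRLearner":
        self.model = fit_krr(X, Y, self.regularizer, self.bandwidth)
        return self

    def update(self, X: np.ndarray, Y: np.ndarray) -> "KRRLearner":
        raise IncrementalUnsupportedError(
            "exact kernel ridge regression cannot be updated incrementally; "
            "use the 'rr' or 'irffrr' learners for incremental settings"
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("learner has not been fitted")
        return self.model.predict(X)


_LEARNERS = {
    "rr": LinearRidgeLearner,
    "irffrr": RFFRidgeLearner,
    "krr": KRRLearner,
}


def make_learner(kind: str, n_inputs: int, n_outputs: int, **kwargs):
    """Construct a learner adapter by name (``rr``, ``irffrr`` or ``krr``)."""
    try:
        cls = _LEARNERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown learner {kind!r}; choose from {sorted(_LEARNERS)}"
        ) from None
    return cls(n_inputs=n_inputs, n_outputs=n_outputs, **kwargs)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(path: str | Path, learner: RFFRidgeLearner) -> None:
    """Persist an iRFFRR learner (feature map + ridge state) to one archive.

    The stored arrays round-trip bit-exactly through :func:`load_model`.
    """
    m, s = learner.map, learner.state
    np.savez(
        path,
        format_version=np.int64(MODEL_FORMAT_VERSION),
        n_inputs=np.int64(m.n_inputs),
        n_features=np.int64(m.n_features),
        bandwidth=np.float64(m.bandwidth),
        frequencies=m.frequencies,
        phases=m.phases,
        map_seed=np.int64(m.seed),
        regularizer=np.float64(s.config.regularizer),
        n_outputs=np.int64(s.config.n_outputs),
        inv_cov=s.inv_cov,
        accumulator=s.accumulator,
        weights=s.weights,
        n_updates=np.int64(s.n_updates),
    )


def load_model(path: str | Path) -> RFFRidgeLearner:
    """Restore an iRFFRR learner saved by :func:`save_model`."""
    with np.load(path) as arc:
        version = int(arc["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {version} "
                f"(this build reads version {MODEL_FORMAT_VERSION})"
            )
        learner = RFFRidgeLearner.__new__(RFFRidgeLearner)
        learner.map = RFFMap(
            n_inputs=int(arc["n_inputs"]),
            n_features=int(arc["n_features"]),
            bandwidth=float(arc["bandwidth"]),
            frequencies=arc["frequencies"].copy(),
            phases=arc["phases"].copy(),
            seed=int(arc["map_seed"]),
        )
        state = IncrementalRidge(
            RidgeConfig(
                regularizer=float(arc["regularizer"]),
                n_outputs=int(arc["n_outputs"]),
            ),
            n_features=int(arc["n_features"]),
            weight_mode="lazy",
        )
        state.inv_cov = arc["inv_cov"].copy()
        state.accumulator = arc["accumulator"].copy()
        state._weights = arc["weights"].copy()
        state._weights_stale = False
        state.n_updates = int(arc["n_updates"])
        learner.state = state
    return learner
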