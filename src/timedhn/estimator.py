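"""Scikit-learn style estimator front-end for timed hazard networks.

``TimedHazardNetwork`` wraps the constrained maximum-likelihood machinery
of :mod:`timedhn.inference` behind the familiar ``fit`` / ``predict`` /
``score`` surface so it composes with sklearn pipelines and model
selection.  ``fit`` consumes a (samples x events) binary matrix, ``predict``
returns the model-based pseudo-time ``E(t|x)`` per sample, and ``score``
reports the mean per-sample profile log-likelihood (each sample's
likelihood maximized over its observation time).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ctmc import (
    DEFAULT_K_MAX,
    ExpectedTimeUndefinedError,
    expected_time,
    likelihood,
)
from .inference import Dataset, FitConfig, FitResult, fit as _fit, threshold_network

__all__ = ["TimedHazardNetwork"]


class TimedHazardNetwork(BaseEstimator):
    """Hazard-network MLE over cross-sectional binary event profiles.

    Parameters mirror :class:`timedhn.inference.FitConfig`; see its
    docstring for the estimation problem and constraint handling.

    Attributes (after ``fit``)
    --------------------------
    rates_ : (n, n) ndarray
        Estimated hazard matrix.
    times_ : (n_samples,) ndarray
        Estimated (or rescaled fixed) progression times of the training
        samples.
    adjacency_ : (n, n) int8 ndarray
        Thresholded binary inter-event edges (``threshold_frac * max(R)``).
    objective_trace_, n_iter_, converged_ :
        Optimization diagnostics.
    """

    def __init__(
        self,
        lam: float = 1e-2,
        learning_rate: float = 1e-3,
        max_iter: int = 5000,
        tol: float = 1e-7,
        time_budget: float | None = None,
        times_mode: str = "joint",
        threshold_frac: float = 0.1,
        optimizer: str = "gd",
        step_halving: bool = True,
        rescale_fixed_times: bool = True,
        k_max: int = DEFAULT_K_MAX,
        random_state: int = 0,
    ):
        self.lam = lam
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.time_budget = time_budget
        self.times_mode = times_mode
        self.threshold_frac = threshold_frac
        self.optimizer = optimizer
        self.step_halving = step_halving
        self.rescale_fixed_times = rescale_fixed_times
        self.k_max = k_max
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            lam=self.lam,
            learning_rate=self.learning_rate,
            max_iter=self.max_iter,
            tol=self.tol,
            time_budget=self.time_budget,
            times_mode=self.times_mode,
            threshold_frac=self.threshold_frac,
            seed=self.random_state,
            k_max=self.k_max,
            optimizer=self.optimizer,
            step_halving=self.step_halving,
            rescale_fixed_times=self.rescale_fixed_times,
        )

    def _as_dataset(self, X, times=None) -> Dataset:
        if isinstance(X, Dataset):
            return X
        if hasattr(X, "columns"):  # DataFrame: keep event names
            names = [str(c) for c in X.columns]
            ids = [str(i) for i in X.index]
            return Dataset.from_matrix(
                np.asarray(X), sample_ids=ids, times=times, event_names=names
            )
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (samples x events) matrix")
        return Dataset.from_matrix(X, times=times)

    def fit(self, X, y=None, times=None):
        """Estimate the hazard network (and, in joint mode, the times).

        Parameters
        ----------
        X : (n_samples, n_events) binary array-like or Dataset
        times : (n_samples,) array-like, optional
            Pseudo-times for ``times_mode="fixed"``.
        """
        dataset = self._as_dataset(X, times=times)
        result: FitResult = _fit(dataset, self._config())
        self.result_ = result
        self.rates_ = result.network.rates
        self.network_ = result.network
        self.event_names_ = list(result.network.event_names)
        self.times_ = result.times
        self.objective_trace_ = result.objective_trace
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.n_features_in_ = dataset.n
        self.adjacency_, self.thresholded_network_ = threshold_network(
            result.network, self.threshold_frac
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Pseudo-time ``E(t|x)`` per sample (NaN where undefined)."""
        check_is_fitted(self, "network_")
        dataset = self._as_dataset(X)
        cache: dict = {}
        out = np.empty(len(dataset))
        for i, profile in enumerate(dataset.profiles):
            key = profile.active
            if key not in cache:
                try:
                    cache[key] = expected_time(self.network_, profile, k_max=self.k_max)
                except ExpectedTimeUndefinedError:
                    cache[key] = np.nan
            out[i] = cache[key]
        return out

    def score(self, X, y=None) -> float:
        """Mean per-sample profile log-likelihood, max over observation time."""
        check_is_fitted(self, "network_")
        dataset = self._as_dataset(X)
        cache: dict = {}
        total = 0.0
        for profile in dataset.profiles:
            key = profile.active
            if key not in cache:
                res = minimize_scalar(
                    lambda logt: -np.log(
                        max(
                            likelihood(
                                self.network_,
                                profile,
                                float(np.exp(logt)),
                                k_max=self.k_max,
                            ),
                            1e-300,
                        )
                    ),
                    bounds=(-10.0, 10.0),
                    method="bounded",
                )
                cache[key] = -res.fun
            total += cache[key]
        return total / len(dataset)
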