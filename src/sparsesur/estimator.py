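"""scikit-learn style front end for the sparse SUR sampler.

``SparseSUR`` is a multi-output Bayesian regression with per-cell variable
selection and residual covariance selection. ``fit(X, Y)`` runs the MCMC;
the posterior summaries live in trailing-underscore attributes and
``predict`` uses the posterior-mean coefficients.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .engine import RunConfig, run_chain
from .selection import Dataset
from .summaries import bayes_fdr

__all__ = ["SparseSUR"]


class SparseSUR(RegressorMixin, BaseEstimator):
    """Bayesian seemingly-unrelated-regressions with covariance selection.

    Each of the s responses gets its own sparse regression on a shared
    predictor matrix; residuals are correlated across responses with either a
    dense inverse-Wishart covariance or a sparse hyper inverse-Wishart
    covariance on a decomposable graph sampled by junction-tree MCMC. The
    inclusion prior is the hotspot prior γ_kj ~ Ber(o_k π_j) (or its
    beta-binomial simplification with π ≡ 1).

    Parameters
    ----------
    n_iter, burnin, thin : chain length controls (burnin defaults to 20%).
    covariance : 'sparse' or 'dense' residual covariance model.
    variant : 'hotspot' or 'betabinomial' inclusion prior.
    n_chains : size of the tempered ensemble (1 disables tempering).
    standardize : centre and scale X and Y before sampling (default True;
        the model carries no intercept, matching standardised data).
    a_o, b_o, nu, ... : prior hyperparameters; None means the documented
        data-dependent default.

    Attributes
    ----------
    mpip_ : (s, p) marginal posterior inclusion probabilities.
    mepip_ : (s, s) marginal posterior edge inclusion probabilities.
    coef_ : (s, p) posterior-mean coefficients on the original data scale.
    pi_mean_, o_mean_ : posterior means of the hotspot parameters.
    summary_ : the full PosteriorSummary.
    """

    def __init__(self, n_iter=10000, burnin=None, thin=10, covariance="sparse",
                 variant="hotspot", n_chains=2, graph_moves_per_sweep=5,
                 standardize=True, a_o=None, b_o=None, a_pi=0.5, b_pi=0.5,
                 a_w=0.1, b_w=0.1, a_tau=0.1, b_tau=0.1, a_eta=1.0, b_eta=1.0,
                 nu=None, temperature=2.0, full_trace=False, random_state=0):
        self.n_iter = n_iter
        self.burnin = burnin
        self.thin = thin
        self.covariance = covariance
        self.variant = variant
        self.n_chains = n_chains
        self.graph_moves_per_sweep = graph_moves_per_sweep
        self.standardize = standardize
        self.a_o = a_o
        self.b_o = b_o
        self.a_pi = a_pi
        self.b_pi = b_pi
        self.a_w = a_w
        self.b_w = b_w
        self.a_tau = a_tau
        self.b_tau = b_tau
        self.a_eta = a_eta
        self.b_eta = b_eta
        self.nu = nu
        self.temperature = temperature
        self.full_trace = full_trace
        self.random_state = random_state

    def fit(self, X, Y):
        X = check_array(X, dtype=float)
        Y = check_array(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of samples")
        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            self.x_scale_ = np.clip(X.std(axis=0), 1e-12, None)
            self.y_mean_ = Y.mean(axis=0)
            self.y_scale_ = np.clip(Y.std(axis=0), 1e-12, None)
            Xs = (X - self.x_mean_) / self.x_scale_
            Ys = (Y - self.y_mean_) / self.y_scale_
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1])
            self.y_scale_ = np.ones(Y.shape[1])
            Xs, Ys = X, Y
        config = RunConfig(
            n_iter=self.n_iter, burnin=self.burnin, thin=self.thin,
            covariance=self.covariance, n_chains=self.n_chains,
            variant=self.variant,
            graph_moves_per_sweep=self.graph_moves_per_sweep,
            seed=self.random_state if self.random_state is not None else 0,
            a_o=self.a_o, b_o=self.b_o, a_pi=self.a_pi, b_pi=self.b_pi,
            a_w=self.a_w, b_w=self.b_w, a_tau=self.a_tau, b_tau=self.b_tau,
            a_eta=self.a_eta, b_eta=self.b_eta, nu=self.nu,
            temperature=self.temperature, full_trace=self.full_trace,
        )
        summary, extras = run_chain(Dataset(Ys, Xs), config)
        self.summary_ = summary
        self.extras_ = extras
        self.mpip_ = summary.mpip
        self.mepip_ = summary.mepip
        self.pi_mean_ = summary.pi_mean
        self.o_mean_ = summary.o_mean
        # back-transform standardised coefficients to the original scale
        self.coef_ = summary.beta_mean * self.y_scale_[:, None] / self.x_scale_[None, :]
        self.intercept_ = self.y_mean_ - self.coef_ @ self.x_mean_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def select(self, threshold=0.5):
        """Thresholded associations and their Bayesian FDR."""
        check_is_fitted(self, "mpip_")
        return bayes_fdr(self.mpip_, threshold)
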