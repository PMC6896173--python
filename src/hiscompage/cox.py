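"""Breslow partial likelihood for the Cox model, in linear-predictor space.

Everything here is parametrized by the per-sample linear predictor eta rather
than by regression coefficients: the hierarchical model alternates weighted
least-squares updates on an IRLS working response built from the gradient u
and the full negative Hessian A of the partial log-likelihood with respect
to eta. Tied event times share a common risk-set denominator (Breslow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import pinvh


class AllCensoredWarning(UserWarning):
    """Emitted when a likelihood is requested for data without any event."""


class CoxTimes:
    """Precomputed ordering structures for one (time, event) configuration.

    Caches the sort order, the distinct event times with multiplicities, and
    the index maps needed to evaluate the log-likelihood, score and Hessian
    at any eta in O(I log I) / O(I^2) without re-sorting. Reused across the
    many evaluations of an alternating-least-squares fit.
    """

    def __init__(self, time, event):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be equal-length 1-D arrays")
        self.n = self.time.size
        self.order = np.argsort(self.time, kind="stable")
        self._t_sorted = self.time[self.order]
        ev_times = self.time[self.event == 1]
        self.d_times, self.d_mult = np.unique(ev_times, return_counts=True)
        # first sorted position with y >= t_d  (start of each risk set)
        self._risk_start = np.searchsorted(self._t_sorted, self.d_times, side="left")
        # number of distinct event times <= y_i, per sample (original order)
        self._n_le = np.searchsorted(self.d_times, self.time, side="right")
        self.n_events = int(self.event.sum())
        self._event_mask = self.event == 1

    def _risk_sums(self, eta):
        """exp-shift-stabilized risk-set sums S0_d and the shifted weights."""
        shift = eta.max() if eta.size else 0.0
        w = np.exp(eta - shift)
        ws = w[self.order]
        rev = np.cumsum(ws[::-1])[::-1]
        s0 = rev[self._risk_start]
        return w, s0, shift

    def loglik(self, eta) -> float:
        if self.n_events == 0:
            return 0.0
        eta = np.asarray(eta, dtype=float)
        _, s0, shift = self._risk_sums(eta)
        # s0 may underflow to 0 for extreme eta; the resulting -inf is a
        # legitimate objective value handled by callers (step-halving)
        with np.errstate(divide="ignore"):
            return float(
                eta[self._event_mask].sum() - (self.d_mult * (np.log(s0) + shift)).sum()
            )

    def score(self, eta) -> np.ndarray:
        eta = np.asarray(eta, dtype=float)
        if self.n_events == 0:
            return np.zeros(self.n)
        w, s0, _ = self._risk_sums(eta)
        cum1 = np.concatenate(([0.0], np.cumsum(self.d_mult / s0)))
        return self.event - w * cum1[self._n_le]

    def score_info(self, eta):
        """Gradient u and full negative Hessian A of the partial log-likelihood.

        A = diag(w * c) - (w w^T) * Qmin where c and Qmin accumulate 1/S0 and
        1/S0^2 over event times inside both samples' risk membership.
        """
        eta = np.asarray(eta, dtype=float)
        if self.n_events == 0:
            return np.zeros(self.n), np.zeros((self.n, self.n))
        w, s0, _ = self._risk_sums(eta)
        # extreme eta can underflow s0; the resulting inf/nan propagate to
        # the caller, whose step-halving rejects the non-finite proposal
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            v1 = self.d_mult / s0
            v2 = self.d_mult / (s0 * s0)
            cum1 = np.concatenate(([0.0], np.cumsum(v1)))
            cum2 = np.concatenate(([0.0], np.cumsum(v2)))
            c = cum1[self._n_le]
            u = self.event - w * c
            qmin = cum2[np.minimum.outer(self._n_le, self._n_le)]
            A = np.diag(w * c) - np.outer(w, w) * qmin
        return u, A


def cox_partial_loglik(time, event, eta) -> float:
    """Breslow-tie Cox partial log-likelihood at linear predictor ``eta``.

    Risk set R(y_i) = {l : y_l >= y_i}. With no events the likelihood is
    constant; 0 is returned with an :class:`AllCensoredWarning`.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    if not (time.shape == event.shape == eta.shape):
        raise ValueError("time, event and eta must have equal length")
    if np.any(time <= 0):
        raise ValueError("all times must be > 0")
    ct = CoxTimes(time, event)
    if ct.n_events == 0:
        warnings.warn("no events observed; partial likelihood is constant (0 returned)",
                      AllCensoredWarning, stacklevel=2)
        return 0.0
    return ct.loglik(eta)


@dataclass
class CoxWorking:
    """IRLS working quantities at a given linear predictor.

    eta — linear predictor; u — score dphi/deta; A — negative Hessian
    (symmetric PSD, null space contains the constant vector); z — working
    response solving A z = A eta + u (pseudo-inverse when A is singular).
    """

    eta: np.ndarray
    u: np.ndarray
    A: np.ndarray
    z: np.ndarray


def cox_working_response(time, event, eta) -> CoxWorking:
    """Compute the IRLS working response for one Newton step in eta-space."""
    ct = CoxTimes(time, event)
    if ct.n_events == 0:
        raise ValueError("working response requires at least one event")
    eta = np.asarray(eta, dtype=float)
    u, A = ct.score_info(eta)
    # A is singular (A 1 = 0); u lies in range(A), so the pseudo-inverse
    # solve is exact for the Newton step.
    z = eta + pinvh(A, rtol=1e-12) @ u
    return CoxWorking(eta=eta, u=u, A=A, z=z)
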