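"""Temporal filtering, CompCor-style nuisance removal, Fisher transform.

The two workhorses are scikit-learn style transformers operating on a
single subject's (n_timepoints, n_signals) array:

* :class:`BandpassFilter` — zero-phase band-pass (forward-backward
  Butterworth by default, FIR window method selectable);
* :class:`CompCor` — principal components of detrended, z-scored noise
  region signals, regressed out of every node signal.

Panel-level helpers apply them subject by subject, so permuting subjects
permutes outputs identically.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .panel import TimeSeriesPanel

__all__ = [
    "FilterSpec",
    "BandpassFilter",
    "CompCor",
    "NuisanceModel",
    "bandpass",
    "fit_compcor",
    "regress_nuisance",
    "preprocess_panel",
    "fisher_z",
    "fisher_z_inverse",
]

CLIP_R = 1.0 - 1e-7


def fisher_z(r, clip: bool = False):
    """Fisher r-to-z transform, ``z = arctanh(r)``.

    With ``clip=True`` correlations at or beyond +/-1 are clipped to
    +/-(1 - 1e-7) instead of raising; use this for degenerate noiseless
    inputs where perfect correlations legitimately occur.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -CLIP_R, CLIP_R)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError(
            "|r| >= 1 has infinite Fisher z; pass clip=True to clip to "
            "+/-(1 - 1e-7)"
        )
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z):
    """Inverse Fisher transform, ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class FilterSpec:
    """Band-pass specification: pass frequencies in Hz, filter family, order."""

    low_hz: float = 0.008
    high_hz: float = 0.08
    method: str = "butter"  # "butter" (zero-phase IIR) or "fir" (window method)
    order: int = 4          # IIR order; FIR taps = order if method == "fir"

    def validate(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= nyquist:
            raise ValueError(
                f"high edge {self.high_hz} Hz is not below the Nyquist "
                f"frequency {nyquist:.4g} Hz for TR {tr_seconds} s"
            )
        if self.method not in ("butter", "fir"):
            raise ValueError(f"unknown filter method {self.method!r}")


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase temporal band-pass filter.

    Parameters
    ----------
    low_hz, high_hz : float
        Pass-band edges in Hz.
    tr_seconds : float
        Sampling interval of the input in seconds.
    method : {"butter", "fir"}
        Forward-backward Butterworth (default) or linear-phase FIR
        (Hamming window) with the delay compensated.
    order : int
        Butterworth order (applied twice by filtfilt), or FIR tap count.

    ``transform`` expects ``X`` of shape (n_timepoints, n_signals) and
    returns the filtered array of the same shape.
    """

    def __init__(self, low_hz: float = 0.008, high_hz: float = 0.08,
                 tr_seconds: float = 3.0, method: str = "butter",
                 order: int = 4):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.tr_seconds = tr_seconds
        self.method = method
        self.order = order

    def _spec(self) -> FilterSpec:
        return FilterSpec(self.low_hz, self.high_hz, self.method, self.order)

    def fit(self, X, y=None):
        self._spec().validate(self.tr_seconds)
        fs = 1.0 / self.tr_seconds
        if self.method == "butter":
            self.sos_ = scipy.signal.butter(
                self.order, [self.low_hz, self.high_hz],
                btype="bandpass", fs=fs, output="sos",
            )
        else:
            taps = self.order if self.order % 2 == 1 else self.order + 1
            self.taps_ = scipy.signal.firwin(
                taps, [self.low_hz, self.high_hz],
                pass_zero=False, fs=fs, window="hamming",
            )
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else None
        return self

    def transform(self, X):
        check_is_fitted(self, ["sos_"] if self.method == "butter" else ["taps_"])
        X = np.asarray(X, dtype=float)
        if self.method == "butter":
            return scipy.signal.sosfiltfilt(self.sos_, X, axis=0)
        return scipy.signal.filtfilt(self.taps_, [1.0], X, axis=0)


class CompCor(TransformerMixin, BaseEstimator):
    """Component-based nuisance correction for one subject.

    ``fit`` takes the (n_timepoints, n_noise_signals) array of designated
    noise-region signals, removes a polynomial trend of order
    ``detrend_order``, z-scores each signal, and extracts the top
    ``n_components`` principal components (deterministic sign: the
    largest-magnitude loading of each component is positive).
    ``transform`` projects node signals onto the orthogonal complement of
    [polynomial trend basis, components] — i.e. returns regression
    residuals.
    """

    def __init__(self, n_components: int = 5, detrend_order: int = 1):
        self.n_components = n_components
        self.detrend_order = detrend_order

    @staticmethod
    def _poly_basis(n_timepoints: int, order: int) -> np.ndarray:
        # orthonormal Legendre-style basis incl. intercept
        t = np.linspace(-1, 1, n_timepoints)
        cols = [t**k for k in range(order + 1)]
        q, _ = np.linalg.qr(np.stack(cols, axis=1))
        return q

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_timepoints, n_noise_signals)")
        T, m = X.shape
        self.n_timepoints_ = T
        basis = self._poly_basis(T, self.detrend_order)
        resid = X - basis @ (basis.T @ X)
        sd = resid.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = resid / sd
        rank = np.linalg.matrix_rank(Z)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank {rank} "
                f"of the {m} noise-region signals"
            )
        if self.n_components == 0:
            self.components_ = np.empty((T, 0))
            self.explained_variance_ratio_ = np.empty(0)
        else:
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            comp = U[:, : self.n_components]
            # sign convention: largest-|loading| entry of each right vector > 0
            for k in range(self.n_components):
                lead = np.argmax(np.abs(Vt[k]))
                if Vt[k, lead] < 0:
                    comp[:, k] = -comp[:, k]
            self.components_ = comp
            self.explained_variance_ratio_ = (s[: self.n_components] ** 2) / (
                s**2
            ).sum()
        self._regressors_ = np.hstack([basis, self.components_])
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n_timepoints_:
            raise ValueError(
                f"time axis mismatch: fitted on {self.n_timepoints_} "
                f"timepoints, got {X.shape[0]}"
            )
        R = self._regressors_
        return X - R @ np.linalg.lstsq(R, X, rcond=None)[0]


@dataclasses.dataclass
class NuisanceModel:
    """Per-subject fitted CompCor models plus their settings."""

    n_components: int
    detrend_order: int
    models: list[CompCor]

    @property
    def component_timeseries(self) -> list[np.ndarray]:
        return [m.components_ for m in self.models]


def bandpass(panel: TimeSeriesPanel, spec: FilterSpec | None = None) -> TimeSeriesPanel:
    """Zero-phase band-pass filter every node signal of every subject."""
    spec = spec or FilterSpec()
    spec.validate(panel.tr_seconds)
    filt = BandpassFilter(spec.low_hz, spec.high_hz, panel.tr_seconds,
                          spec.method, spec.order)
    filt.fit(panel.data[0].T)
    out = np.empty_like(panel.data)
    for s in range(panel.n_subjects):
        out[s] = filt.transform(panel.data[s].T).T
    return panel.copy_with(out)


def fit_compcor(
    panel: TimeSeriesPanel, n_components: int = 5, detrend_order: int = 1
) -> NuisanceModel:
    """Fit one CompCor model per subject on the panel's noise regions."""
    if not panel.noise_region_ids:
        raise ValueError("panel has no designated noise regions")
    idx = [panel.node_index(n) for n in panel.noise_region_ids]
    models = []
    for s in range(panel.n_subjects):
        cc = CompCor(n_components=n_components, detrend_order=detrend_order)
        cc.fit(panel.data[s][idx].T)
        models.append(cc)
    return NuisanceModel(n_components, detrend_order, models)


def regress_nuisance(panel: TimeSeriesPanel, model: NuisanceModel) -> TimeSeriesPanel:
    """Residualize every node signal against the fitted nuisance model."""
    if len(model.models) != panel.n_subjects:
        raise ValueError(
            f"model fitted on {len(model.models)} subjects, panel has "
            f"{panel.n_subjects}"
        )
    out = np.empty_like(panel.data)
    for s in range(panel.n_subjects):
        out[s] = model.models[s].transform(panel.data[s].T).T
    return panel.copy_with(out)


def preprocess_panel(
    panel: TimeSeriesPanel,
    filter_spec: FilterSpec | None = None,
    n_components: int = 5,
    detrend_order: int = 1,
    order: str = "regress_then_filter",
) -> TimeSeriesPanel:
    """Full preprocessing: nuisance regression and band-pass filtering.

    ``order`` is either ``"regress_then_filter"`` (default: removing
    nuisance first avoids re-introducing stop-band energy) or
    ``"filter_then_regress"``.  With no noise regions or
    ``n_components=0`` plus ``detrend_order=0`` the nuisance step reduces
    to mean removal of each signal.
    """
    if order not in ("regress_then_filter", "filter_then_regress"):
        raise ValueError(f"unknown preprocessing order {order!r}")
    steps = []
    if panel.noise_region_ids and n_components > 0:
        def _regress(p: TimeSeriesPanel) -> TimeSeriesPanel:
            return regress_nuisance(
                p, fit_compcor(p, n_components, detrend_order)
            )
        steps.append(_regress)
    steps.append(lambda p: bandpass(p, filter_spec))
    if order == "filter_then_regress":
        steps = steps[::-1]
    for step in steps:
        panel = step(panel)
    return panel
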