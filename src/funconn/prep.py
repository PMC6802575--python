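"""Quality gating and conditioning of ROI time series.

Operates on parcellated resting-state signals (one column per region of
interest): temporal signal-to-noise gating, zero-phase band-pass
filtering, and nuisance regression against named confound regressors
(typically global signal, white matter, CSF and six motion parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "NuisanceSet",
    "TsnrReport",
    "temporal_snr",
    "apply_tsnr_gate",
    "bandpass",
    "regress_nuisance",
    "condition_series",
]

#: Repetition time of a typical resting-state EPI sequence, in seconds.
DEFAULT_SAMPLING_INTERVAL = 2.009


@dataclass
class RoiTimeSeries:
    """One subject's ROI signal matrix (timepoints x regions).

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (T, n)
        One column per ROI, one row per acquired volume.
    roi_labels : list of str
        Unique region labels, aligned with the columns of ``data``.
    sampling_interval : float
        Time between consecutive rows, in seconds.
    """

    subject_id: str
    data: np.ndarray
    roi_labels: list[str]
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D timepoints x ROI matrix")
        self.roi_labels = [str(l) for l in self.roi_labels]
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_labels)} labels"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains missing/non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with a header row of ROI labels."""
        df = pd.DataFrame(self.data, columns=self.roi_labels)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        subject_id: str | None = None,
        sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    ) -> "RoiTimeSeries":
        """Load a timepoints x ROI TSV; rejects files with missing values."""
        df = pd.read_csv(path, sep="\t")
        if df.isna().any().any():
            raise ValueError(f"{path}: missing values in time-series table")
        if subject_id is None:
            subject_id = Path(path).stem
        return cls(subject_id, df.to_numpy(dtype=float), list(df.columns),
                   sampling_interval)


@dataclass
class NuisanceSet:
    """Named confound regressors sharing the series' time axis."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2-D (timepoints x q)")
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("number of names must match regressor columns")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NuisanceSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), list(df.columns))


@dataclass
class TsnrReport:
    """Per-ROI temporal SNR and its subject-level mean."""

    subject_id: str
    per_roi: np.ndarray
    mean: float

    def passes(self, threshold: float = 100.0) -> bool:
        return self.mean > threshold


def temporal_snr(series: RoiTimeSeries) -> TsnrReport:
    """Temporal SNR of each ROI column: temporal mean / temporal SD.

    The SD uses the n-1 denominator.  A constant column has undefined
    (infinite) tSNR; it is reported as ``+inf`` with a warning rather
    than raising, since a flat channel is a data-quality observation,
    not a programming error.
    """
    if series.n_timepoints < 2:
        raise ValueError("temporal SNR needs at least 2 timepoints")
    mu = series.data.mean(axis=0)
    sd = series.data.std(axis=0, ddof=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant ROI column(s); tSNR reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        tsnr = np.where(flat, np.inf, mu / np.where(flat, 1.0, sd))
    return TsnrReport(series.subject_id, tsnr, float(np.mean(tsnr)))


def apply_tsnr_gate(
    series_list: Sequence[RoiTimeSeries], threshold: float = 100.0
) -> tuple[list[RoiTimeSeries], list[dict]]:
    """Split subjects into kept / excluded by mean tSNR.

    Subjects with mean tSNR <= ``threshold`` are excluded, mirroring the
    conventional resting-state quality gate.  Returns the kept series and
    an exclusion log (one record per subject, kept or not).
    """
    kept: list[RoiTimeSeries] = []
    log: list[dict] = []
    for s in series_list:
        rep = temporal_snr(s)
        ok = rep.passes(threshold)
        log.append(
            {
                "subject_id": s.subject_id,
                "mean_tsnr": rep.mean,
                "threshold": threshold,
                "decision": "keep" if ok else "exclude",
            }
        )
        if ok:
            kept.append(s)
    return kept, log


def bandpass(
    series: RoiTimeSeries,
    low_cut_hz: float = 0.005,
    high_cut_hz: float = 0.1,
    order: int = 4,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass along the time axis.

    A forward-backward (filtfilt) order-``order`` Butterworth filter, so
    the effective attenuation is doubled and the phase response is flat —
    filtering cannot shift one region's signal relative to another, which
    would otherwise bias inter-regional correlations.

    ``low_cut_hz = 0`` degenerates to a pure low-pass; ``high_cut_hz``
    equal to the Nyquist frequency degenerates to a pure high-pass.
    """
    fs = 1.0 / series.sampling_interval
    nyq = fs / 2.0
    if not 0 <= low_cut_hz < high_cut_hz:
        raise ValueError("need 0 <= low_cut_hz < high_cut_hz")
    if high_cut_hz > nyq + 1e-12:
        raise ValueError(
            f"high_cut_hz={high_cut_hz} exceeds the Nyquist frequency "
            f"{nyq:.6g} Hz for sampling_interval={series.sampling_interval}"
        )
    if low_cut_hz == 0:
        sos = signal.butter(order, high_cut_hz, btype="lowpass", fs=fs,
                            output="sos")
    elif high_cut_hz >= nyq - 1e-12:
        sos = signal.butter(order, low_cut_hz, btype="highpass", fs=fs,
                            output="sos")
    else:
        sos = signal.butter(order, [low_cut_hz, high_cut_hz], btype="bandpass",
                            fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return replace(series, data=filtered)


def regress_nuisance(
    series: RoiTimeSeries, nuisance: NuisanceSet
) -> RoiTimeSeries:
    """Remove nuisance structure by multiple regression.

    Each ROI column is regressed on an intercept plus all nuisance
    regressors; the residuals replace the signal.  The intercept makes
    residuals exactly zero-mean, and the least-squares projection makes
    them orthogonal to every regressor.
    """
    R = nuisance.regressors
    T = series.n_timepoints
    if R.shape[0] != T:
        raise ValueError(
            f"nuisance has {R.shape[0]} timepoints, series has {T}"
        )
    design = np.column_stack([np.ones(T), R])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _collinear_names(design, nuisance.names)
        raise ValueError(
            "nuisance regressors are rank-deficient after adding an "
            f"intercept; collinear: {collinear}"
        )
    beta, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    residuals = series.data - design @ beta
    return replace(series, data=residuals)


def _collinear_names(design: np.ndarray, names: list[str]) -> list[str]:
    """Regressors whose removal does not reduce the design rank."""
    full_rank = np.linalg.matrix_rank(design)
    redundant = []
    for j, name in enumerate(names):
        reduced = np.delete(design, j + 1, axis=1)  # column 0 is the intercept
        if np.linalg.matrix_rank(reduced) == full_rank:
            redundant.append(name)
    return redundant


def condition_series(
    series: RoiTimeSeries,
    nuisance: NuisanceSet | None = None,
    low_cut_hz: float | None = 0.005,
    high_cut_hz: float | None = 0.1,
    order: str = "regress_then_filter",
) -> RoiTimeSeries:
    """Full conditioning stage: nuisance regression and band-pass.

    The default order regresses first and filters second; the alternative
    ``"filter_then_regress"`` is available since the two do not commute
    exactly.  Filtering is skipped when both cutoffs are None.
    """
    if order not in ("regress_then_filter", "filter_then_regress"):
        raise ValueError(f"unknown stage order {order!r}")

    def _filter(s: RoiTimeSeries) -> RoiTimeSeries:
        if low_cut_hz is None and high_cut_hz is None:
            return s
        nyq = 0.5 / s.sampling_interval
        return bandpass(s, low_cut_hz or 0.0,
                        high_cut_hz if high_cut_hz is not None else nyq)

    def _regress(s: RoiTimeSeries) -> RoiTimeSeries:
        return regress_nuisance(s, nuisance) if nuisance is not None else s

    if order == "regress_then_filter":
        return _filter(_regress(series))
    return _regress(_filter(series))
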