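"""Per-trial VAR fitting and directed-transfer-function connectivity.

A single joint VAR model is fitted per trial over all channels (ordinary
least squares, order selected by Schwarz's Bayesian criterion).  The model
is evaluated on a frequency grid to obtain the transfer matrix H(f), the
row-normalized squared transfer magnitudes (DTF^2), and band-averaged
connectivity matrices with entry (i, j) = mean influence of source j on
target i over the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import TrialRecording, spectral_radius
from .defs import BANDS

__all__ = [
    "VARFit",
    "TransferSpectrum",
    "BandConnectivity",
    "SingularFitError",
    "fit_var",
    "transfer_spectrum",
    "dtf_squared",
    "band_average",
    "default_frequency_grid",
    "trial_band_connectivity",
    "write_band_connectivity_hdf5",
    "read_band_connectivity_hdf5",
]


class SingularFitError(ValueError):
    """Regressor matrix is rank deficient (e.g. a constant channel)."""


@dataclass
class VARFit:
    """Estimated VAR model: coefficient stack A(m) (order x k x k), noise
    covariance, selected order, and the SBC trace over candidate orders."""

    coefficients: np.ndarray
    noise_cov: np.ndarray
    order: int
    sbc_trace: np.ndarray
    n_samples_used: int
    sampling_rate: float
    stable: bool = True


@dataclass
class TransferSpectrum:
    freqs: np.ndarray
    H: np.ndarray  # (n_freqs, k, k) complex
    A_of_f: np.ndarray  # (n_freqs, k, k) complex
    sampling_rate: float = 0.0


@dataclass
class BandConnectivity:
    """Band-averaged DTF^2 matrix; C[i, j] = influence of source j on
    target i.  The diagonal is stored but is not a graph edge."""

    band: str
    C: np.ndarray
    low: float = 0.0
    high: float = 0.0


def _lag_matrix(x: np.ndarray, p: int, offset: int) -> np.ndarray:
    """Stack lagged samples: row t has [x(t-1), ..., x(t-p)] flattened.

    ``x`` is samples x channels; rows start at ``offset`` (>= p).
    """
    n, k = x.shape
    cols = [x[offset - m : n - m] for m in range(1, p + 1)]
    return np.concatenate(cols, axis=1)


def fit_var(
    trial: TrialRecording | np.ndarray,
    max_order: int = 15,
    sampling_rate: float | None = None,
) -> VARFit:
    """Fit a VAR by OLS, selecting the order that minimizes SBC over
    1..max_order.  Channels are mean-centered first; all candidate orders
    are scored on the same effective sample (last n - max_order rows).
    """
    if isinstance(trial, TrialRecording):
        data = trial.data
        fs = trial.sampling_rate
    else:
        data = np.asarray(trial, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required when passing a raw array")
        fs = float(sampling_rate)
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains NaN/Inf")
    k, n = data.shape
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    # cap the order so the regression stays overdetermined by a margin
    max_order = min(max_order, max(1, n // (3 * k)))
    if n <= k * max_order + k:
        raise ValueError(
            f"too few samples ({n}) for k={k}, max_order={max_order}"
        )
    x = (data - data.mean(axis=1, keepdims=True)).T  # samples x channels
    n_eff = n - max_order
    y = x[max_order:]
    lagged_full = _lag_matrix(x, max_order, max_order)

    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    sbc_trace = np.full(max_order, np.nan)
    for p in range(1, max_order + 1):
        regressors = lagged_full[:, : p * k]
        coef, _, rank, _ = np.linalg.lstsq(regressors, y, rcond=None)
        if rank < p * k:
            raise SingularFitError(
                f"rank-deficient regressor matrix at order {p} "
                f"(rank {rank} < {p * k}); constant or duplicate channel?"
            )
        resid = y - regressors @ coef
        sigma = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf  # perfect fit; SBC penalty decides
        sbc = logdet + (np.log(n_eff) * p * k * k) / n_eff
        sbc_trace[p - 1] = sbc
        if best is None or sbc < best[0]:
            best = (sbc, p, coef, sigma)
    assert best is not None
    _, order, coef, sigma = best
    # coef rows are [lag1 block; lag2 block; ...], each k x k mapping
    coeffs = np.stack(
        [coef[m * k : (m + 1) * k].T for m in range(order)], axis=0
    )
    return VARFit(
        coefficients=coeffs,
        noise_cov=(sigma + sigma.T) / 2.0,
        order=order,
        sbc_trace=sbc_trace,
        n_samples_used=n_eff,
        sampling_rate=fs,
        stable=spectral_radius(coeffs) < 1.0,
    )


def default_frequency_grid(fs: float) -> np.ndarray:
    """1-Hz grid from 1 Hz to the Nyquist frequency inclusive."""
    return np.arange(1.0, fs / 2.0 + 0.5, 1.0)


def transfer_spectrum(fit: VARFit, freqs: np.ndarray | None = None) -> TransferSpectrum:
    """Evaluate A(f) = I - sum_m A(m) exp(-i 2 pi f m / fs) and H(f) = A(f)^-1
    on a frequency grid."""
    fs = fit.sampling_rate
    if freqs is None:
        freqs = default_frequency_grid(fs)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size and (freqs.min() <= 0 or freqs.max() > fs / 2 + 1e-9):
        raise ValueError("frequencies must lie in (0, fs/2]")
    p, k, _ = fit.coefficients.shape
    # A(0) = I, A(m>=1) = -(fitted coefficients)
    phase = np.exp(
        -2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs
    )  # (n_freqs, p)
    A_of_f = np.eye(k)[None, :, :] - np.einsum(
        "fp,pij->fij", phase, fit.coefficients
    )
    H = np.empty_like(A_of_f)
    for idx, f in enumerate(freqs):
        try:
            H[idx] = np.linalg.inv(A_of_f[idx])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"A(f) singular at f={f} Hz") from exc
    return TransferSpectrum(freqs=freqs, H=H, A_of_f=A_of_f, sampling_rate=fs)


def dtf_squared(ts: TransferSpectrum) -> np.ndarray:
    """Row-normalized squared transfer magnitudes, shape (n_freqs, k, k).

    Entry (f, i, j) = |H_ij(f)|^2 / sum_m |H_im(f)|^2, so each target row
    sums to 1 at every frequency.
    """
    power = np.abs(ts.H) ** 2
    row_sums = power.sum(axis=2, keepdims=True)
    if np.any(row_sums == 0):
        f_idx, i_idx = np.argwhere(row_sums[:, :, 0] == 0)[0]
        raise ValueError(
            f"all-zero transfer row for target {i_idx} at "
            f"f={ts.freqs[f_idx]} Hz; cannot normalize"
        )
    return power / row_sums


def band_average(
    dtf: np.ndarray,
    freqs: np.ndarray,
    band: str | tuple[float, float],
    sampling_rate: float | None = None,
) -> BandConnectivity:
    """Arithmetic mean of DTF^2 over grid frequencies in [low, high)."""
    if isinstance(band, str):
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}")
        low, high = BANDS[band]
        name = band
    else:
        low, high = band
        name = f"{low}-{high}Hz"
    if sampling_rate is not None and high > sampling_rate / 2 + 1e-9:
        raise ValueError(
            f"band {name} upper edge {high} Hz exceeds Nyquist "
            f"{sampling_rate / 2} Hz"
        )
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        raise ValueError(f"no grid frequencies in band {name} [{low}, {high})")
    return BandConnectivity(
        band=name, C=dtf[mask].mean(axis=0), low=low, high=high
    )


def trial_band_connectivity(
    trial: TrialRecording,
    bands: list[str] | None = None,
    max_order: int = 15,
    skip_above_nyquist: bool = False,
) -> dict[str, BandConnectivity]:
    """Fit one VAR on a trial and band-average its DTF^2 for each band.

    With ``skip_above_nyquist`` bands that do not fit under fs/2 are
    silently dropped instead of raising.
    """
    names = list(bands) if bands is not None else list(BANDS)
    fs = trial.sampling_rate
    fit = fit_var(trial, max_order=max_order)
    ts = transfer_spectrum(fit)
    dtf = dtf_squared(ts)
    out: dict[str, BandConnectivity] = {}
    for name in names:
        low, high = BANDS[name] if name in BANDS else (np.nan, np.nan)
        if high > fs / 2 + 1e-9:
            if skip_above_nyquist:
                continue
            raise ValueError(
                f"band {name} ({low}-{high} Hz) above Nyquist {fs / 2} Hz; "
                "raise the sampling rate or drop the band"
            )
        out[name] = band_average(dtf, ts.freqs, name, sampling_rate=fs)
    return out


def write_band_connectivity_hdf5(
    path,
    matrices: dict[tuple[int, int], dict[str, BandConnectivity]],
) -> None:
    """Write band matrices as /subject_<id>/trial_<n>/<band> k x k datasets.

    ``matrices`` maps (subject_id, trial_index) -> {band: BandConnectivity}.
    """
    import h5py

    with h5py.File(path, "w") as f:
        for (subject, trial), bands in matrices.items():
            grp = f.require_group(f"subject_{subject}/trial_{trial}")
            for band, conn in bands.items():
                ds = grp.create_dataset(band, data=conn.C)
                ds.attrs["low"] = conn.low
                ds.attrs["high"] = conn.high


def read_band_connectivity_hdf5(
    path,
) -> dict[tuple[int, int], dict[str, BandConnectivity]]:
    import h5py

    out: dict[tuple[int, int], dict[str, BandConnectivity]] = {}
    with h5py.File(path, "r") as f:
        for subj_name, subj_grp in f.items():
            subject = int(subj_name.split("_")[1])
            for trial_name, trial_grp in subj_grp.items():
                trial = int(trial_name.split("_")[1])
                out[(subject, trial)] = {
                    band: BandConnectivity(
                        band=band,
                        C=ds[()],
                        low=float(ds.attrs["low"]),
                        high=float(ds.attrs["high"]),
                    )
                    for band, ds in trial_grp.items()
                }
    return out
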