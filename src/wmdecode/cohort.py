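"""Synthetic multi-subject cohort generator.

Trials are simulated from stable multivariate autoregressive (VAR) models.
Every channel carries a damped-oscillator AR(2) core tuned to its region's
node frequency; directed couplings between channels are planted as
off-diagonal VAR coefficients that are active only in chosen conditions.
Reaction times are drawn from a linear model tied to the planted couplings,
so condition and RT contrasts both have a known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .defs import CONDITIONS, REGION_ORDER

__all__ = [
    "PlantedCoupling",
    "CohortSpec",
    "TrialRecording",
    "ar2_coefficients",
    "build_generative_var",
    "generate_cohort",
    "companion_matrix",
    "spectral_radius",
    "write_cohort_hdf5",
    "read_cohort_hdf5",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Samples discarded at the start of every simulated trial so the zero
#: initial state has washed out.
BURN_IN_SAMPLES = 500

#: Reaction times are truncated below at this value (ms).
RT_FLOOR_MS = 100.0


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of a VAR coefficient stack ``coeffs`` of shape (p, k, k)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[k:, : (p - 1) * k] = np.eye((p - 1) * k)
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix; < 1 means a stable process."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


def ar2_coefficients(f0: float, r: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients placing complex-conjugate poles at radius ``r``
    and angle ``2*pi*f0/fs``, i.e. a damped oscillator resonant near ``f0``.

    Returns ``(a1, a2) = (2 r cos(2 pi f0 / fs), -r**2)``.
    """
    if not 0 < f0 < fs / 2:
        raise ValueError(
            f"resonance f0={f0} Hz must lie in (0, fs/2)={fs / 2} Hz (aliasing)"
        )
    if not 0 < r < 1:
        raise ValueError(f"pole radius r={r} must lie in (0, 1) for stability")
    a1 = 2.0 * r * math.cos(2.0 * math.pi * f0 / fs)
    a2 = -r * r
    return a1, a2


@dataclass(frozen=True)
class PlantedCoupling:
    """A known directed influence ``source_channel -> target_channel``.

    The coupling is inserted as a VAR coefficient of size ``gain`` at the
    given lag, but only when generating trials of the listed conditions.
    """

    source_channel: int
    target_channel: int
    lag: int = 1
    gain: float = 0.5
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.source_channel == self.target_channel:
            raise ValueError("coupling source and target must differ")
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 sample")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the single source of truth
    for reproducibility (everything downstream derives from spec + seed)."""

    n_subjects: int = 8
    channels_per_region: dict[str, int] = field(
        default_factory=lambda: {"MTL": 4, "PFC": 12, "OFC": 10}
    )
    trials_per_condition: int = 34
    trial_count_jitter: int = 3
    sampling_rate: float = 250.0
    window_length: float = 0.6
    node_frequencies: dict[str, float] = field(
        default_factory=lambda: {"MTL": 6.0, "PFC": 6.0, "OFC": 6.0}
    )
    damping: float = 0.95
    coupling_edges: list[PlantedCoupling] = field(default_factory=list)
    rt_model: tuple[float, float, float] = (1500.0, 200.0, 150.0)
    p_correct: float = 1.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return sum(self.channels_per_region.values())

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.window_length))

    @property
    def channel_regions(self) -> list[str]:
        """Per-channel region labels, channels grouped in REGION_ORDER."""
        labels: list[str] = []
        for region in REGION_ORDER:
            labels.extend([region] * self.channels_per_region.get(region, 0))
        return labels

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie in (0, 1)")
        missing = [r for r in REGION_ORDER if self.channels_per_region.get(r, 0) < 1]
        if missing:
            raise ValueError(f"every region needs >= 1 channel; missing {missing}")
        for region, f0 in self.node_frequencies.items():
            if not 0 < f0 < self.sampling_rate / 2:
                raise ValueError(
                    f"node frequency {f0} Hz for {region} exceeds Nyquist"
                )
        if self.n_samples < 50 * self.n_channels:
            raise ValueError(
                f"window too short: {self.n_samples} samples < 50 x "
                f"{self.n_channels} channels (VAR fit would be unreliable)"
            )
        k = self.n_channels
        for edge in self.coupling_edges:
            if not (0 <= edge.source_channel < k and 0 <= edge.target_channel < k):
                raise ValueError(f"coupling {edge} references a channel >= {k}")
        if not 0 <= self.p_correct <= 1:
            raise ValueError("p_correct must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling_edges"] = [dataclasses.asdict(e) for e in self.coupling_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["coupling_edges"] = [
            PlantedCoupling(**{**e, "conditions": tuple(e["conditions"])})
            for e in d.get("coupling_edges", [])
        ]
        d["rt_model"] = tuple(d["rt_model"])
        return cls(**d)


@dataclass
class TrialRecording:
    """One trial: a channels x samples matrix with its labels."""

    data: np.ndarray
    condition: str
    rt: float
    correct: bool
    subject_id: int
    channel_regions: list[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains NaN/Inf")
        if self.data.shape[0] != len(self.channel_regions):
            raise ValueError("channel_regions length must match channel count")


def build_generative_var(
    spec: CohortSpec, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Generative VAR for one condition: (coefficient stack (p,k,k), noise cov).

    Each channel gets a diagonal AR(2) core at its region's node frequency;
    couplings active in ``condition`` add one off-diagonal coefficient each.
    Raises if any coupling makes the process unstable, naming the edge.
    """
    spec.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    k = spec.n_channels
    regions = spec.channel_regions
    p = max([2] + [e.lag for e in spec.coupling_edges])
    coeffs = np.zeros((p, k, k))
    for ch, region in enumerate(regions):
        a1, a2 = ar2_coefficients(
            spec.node_frequencies[region], spec.damping, spec.sampling_rate
        )
        coeffs[0, ch, ch] = a1
        coeffs[1, ch, ch] = a2
    if spectral_radius(coeffs) >= 1.0:
        raise ValueError("diagonal AR(2) cores are unstable (check damping)")
    for edge in spec.coupling_edges:
        if condition not in edge.conditions:
            continue
        coeffs[edge.lag - 1, edge.target_channel, edge.source_channel] += edge.gain
        rho = spectral_radius(coeffs)
        if rho >= 1.0:
            raise ValueError(
                f"coupling {edge.source_channel}->{edge.target_channel} "
                f"(gain {edge.gain}, lag {edge.lag}) destabilizes the model "
                f"(spectral radius {rho:.3f})"
            )
    return coeffs, np.eye(k)


def simulate_var(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = BURN_IN_SAMPLES,
) -> np.ndarray:
    """Simulate a VAR realization, discarding ``burn_in`` initial samples.

    Returns a channels x samples array.
    """
    p, k, _ = coeffs.shape
    total = n_samples + burn_in + p
    noise = rng.multivariate_normal(
        np.zeros(k), noise_cov, size=total, method="cholesky"
    )
    x = np.zeros((total, k))
    for t in range(p, total):
        acc = noise[t].copy()
        for m in range(p):
            acc += coeffs[m] @ x[t - m - 1]
        x[t] = acc
    return x[p + burn_in :].T.copy()


def _draw_rt(
    spec: CohortSpec, condition: str, rng: np.random.Generator
) -> float:
    base_ms, effect_ms, noise_sd_ms = spec.rt_model
    active = any(condition in e.conditions for e in spec.coupling_edges)
    rt = base_ms - effect_ms * float(active) + rng.normal(0.0, noise_sd_ms)
    return max(rt, RT_FLOOR_MS)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[TrialRecording], list[PlantedCoupling]]:
    """Generate all trials of a cohort plus the ground-truth coupling list.

    Fully deterministic given ``spec`` (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    models = {c: build_generative_var(spec, c) for c in CONDITIONS}
    regions = spec.channel_regions
    trials: list[TrialRecording] = []
    for subject in range(spec.n_subjects):
        for condition in CONDITIONS:
            jitter = spec.trial_count_jitter
            n_trials = spec.trials_per_condition + int(
                rng.integers(-jitter, jitter + 1)
            )
            n_trials = max(n_trials, 1)
            coeffs, noise_cov = models[condition]
            for _ in range(n_trials):
                data = simulate_var(coeffs, noise_cov, spec.n_samples, rng)
                rt = _draw_rt(spec, condition, rng)
                correct = bool(rng.random() < spec.p_correct)
                trials.append(
                    TrialRecording(
                        data=data,
                        condition=condition,
                        rt=rt,
                        correct=correct,
                        subject_id=subject,
                        channel_regions=regions,
                        sampling_rate=spec.sampling_rate,
                    )
                )
    return trials, list(spec.coupling_edges)


# ---------------------------------------------------------------------------
# I/O: HDF5 layout /subject_<id>/trial_<n>/data, JSON sidecar with the spec;
# CSV fallback writes one matrix file per trial plus a manifest.
# ---------------------------------------------------------------------------

def write_cohort_hdf5(
    path: str | Path,
    trials: list[TrialRecording],
    spec: CohortSpec | None = None,
    ground_truth: list[PlantedCoupling] | None = None,
) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        if trials:
            f.attrs["channel_regions"] = [
                r.encode() for r in trials[0].channel_regions
            ]
        counters: dict[int, int] = {}
        for trial in trials:
            n = counters.get(trial.subject_id, 0)
            counters[trial.subject_id] = n + 1
            grp = f.require_group(f"subject_{trial.subject_id}")
            ds = grp.create_dataset(f"trial_{n}", data=trial.data)
            ds.attrs["condition"] = trial.condition
            ds.attrs["rt_ms"] = trial.rt
            ds.attrs["correct"] = trial.correct
            ds.attrs["fs"] = trial.sampling_rate
    if spec is not None:
        sidecar = {
            "spec": spec.to_dict(),
            "ground_truth": [
                dataclasses.asdict(e) for e in (ground_truth or [])
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )
    return path


def read_cohort_hdf5(path: str | Path) -> list[TrialRecording]:
    import h5py

    path = Path(path)
    trials: list[TrialRecording] = []
    with h5py.File(path, "r") as f:
        regions = [
            r.decode() if isinstance(r, bytes) else str(r)
            for r in f.attrs["channel_regions"]
        ]
        for subj_name in sorted(f, key=lambda s: int(s.split("_")[1])):
            subject = int(subj_name.split("_")[1])
            grp = f[subj_name]
            for trial_name in sorted(grp, key=lambda s: int(s.split("_")[1])):
                ds = grp[trial_name]
                trials.append(
                    TrialRecording(
                        data=ds[()],
                        condition=str(ds.attrs["condition"]),
                        rt=float(ds.attrs["rt_ms"]),
                        correct=bool(ds.attrs["correct"]),
                        subject_id=subject,
                        channel_regions=regions,
                        sampling_rate=float(ds.attrs["fs"]),
                    )
                )
    return trials


def write_cohort_csv(directory: str | Path, trials: list[TrialRecording]) -> Path:
    """Portable fallback: one CSV matrix per trial + manifest.csv."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for n, trial in enumerate(trials):
        fname = f"trial_{n:05d}.csv"
        np.savetxt(directory / fname, trial.data, delimiter=",")
        rows.append(
            {
                "file": fname,
                "subject_id": trial.subject_id,
                "condition": trial.condition,
                "rt_ms": trial.rt,
                "correct": trial.correct,
                "fs": trial.sampling_rate,
                "channel_regions": "|".join(trial.channel_regions),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_cohort_csv(directory: str | Path) -> list[TrialRecording]:
    import pandas as pd

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    trials = []
    for row in manifest.itertuples():
        data = np.loadtxt(directory / row.file, delimiter=",")
        trials.append(
            TrialRecording(
                data=np.atleast_2d(data),
                condition=row.condition,
                rt=float(row.rt_ms),
                correct=bool(row.correct),
                subject_id=int(row.subject_id),
                channel_regions=row.channel_regions.split("|"),
                sampling_rate=float(row.fs),
            )
        )
    return trials
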