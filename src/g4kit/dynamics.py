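"""Diffusion and distance dynamics: MSD, diffusion constants, end-to-end
distances and FRET efficiency <-> distance conversion.

For free diffusion the mean squared displacement grows linearly,
``MSD(t) = 2 * dim * D * t``, so a 3-D point estimate is ``D = MSD(t)/(6 t)``
and the 2-D single-particle-tracking analogue uses ``4 t``.  Dimensionality
is always an explicit argument.  Tracks carry positions in µm and times in
seconds; trajectory input (Å, declared time unit) is converted here at the
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import Frame, Trajectory

__all__ = [
    "Track",
    "MSDProfile",
    "DiffusionEstimate",
    "read_tracks_csv",
    "write_tracks_csv",
    "compute_msd",
    "diffusion_from_msd",
    "per_track_diffusion",
    "end_to_end_distance",
    "fret_efficiency",
    "fret_distance",
]

_ANGSTROM_TO_UM = 1e-4


@dataclass
class Track:
    """A single-particle track: uniformly spaced times (s), positions (µm)."""

    track_id: int
    times: np.ndarray
    positions: np.ndarray  # (n, dim), dim in {2, 3}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions length mismatch")
        if self.positions.shape[1] not in (2, 3):
            raise ValueError("tracks must be 2- or 3-dimensional")
        dts = np.diff(self.times)
        if len(dts):
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(dts) > 1e-6:
                raise ValueError("track sampling must be uniform (tolerance 1e-6 s)")

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class MSDProfile:
    """Mean squared displacement versus lag time.

    ``msd`` is in µm² over lags in seconds; ``n_pairs`` counts the
    (overlapping) displacement pairs averaged at each lag — successive lags
    therefore share data and are statistically dependent.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    dim: int

    def at(self, lag: float) -> float:
        idx = np.nonzero(np.isclose(self.lags, lag, rtol=1e-9, atol=1e-12))[0]
        if not len(idx):
            raise ValueError(f"lag {lag} not present in profile")
        return float(self.msd[idx[0]])


@dataclass
class DiffusionEstimate:
    D: float
    method: str  # "point" or "slope"
    fit_range: tuple[float, float]
    stderr: float | None = None
    track_id: int | None = None


def read_tracks_csv(path: str | Path) -> list[Track]:
    """Read tracks from CSV ``track_id,t,x,y[,z]`` (units: s, µm)."""
    df = pd.read_csv(path, comment="#")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        tracks.append(Track(int(tid), sub["t"].to_numpy(), sub[cols].to_numpy()))
    return tracks


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, p in zip(tr.times, tr.positions):
            rows.append([tr.track_id, t, *p])
    cols = ["track_id", "t", "x", "y", "z"][: 2 + tracks[0].dim]
    with open(path, "w") as fh:
        fh.write("# units: s, um\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, index=False)


def _msd_single(positions: np.ndarray, lag_steps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over overlapping windows for one position series."""
    n = positions.shape[0]
    msd = np.empty(len(lag_steps))
    npairs = np.empty(len(lag_steps), dtype=int)
    for i, ell in enumerate(lag_steps):
        disp = positions[ell:] - positions[:-ell] if ell else np.zeros_like(positions)
        msd[i] = float(np.mean(np.sum(disp**2, axis=1))) if ell else 0.0
        npairs[i] = n - ell if ell else n
    return msd, npairs


def _trajectory_centroid_tracks(traj: Trajectory, molecule_kind: str) -> list[Track]:
    """Per-molecule centroid tracks (µm, s) for one molecule kind."""
    frame0 = traj.frames[0]
    mols = [m for m in frame0.molecule_ids()
            if frame0.atoms_of_molecule(m)[0].molecule_kind == molecule_kind]
    idx_by_mol = {
        m: [i for i, a in enumerate(frame0.atoms) if a.molecule_id == m] for m in mols
    }
    dt_s = traj.dt_seconds()
    times = np.arange(len(traj)) * dt_s
    coords = np.array([f.coords for f in traj.frames])  # (F, N, 3)
    tracks = []
    for m in mols:
        cent = coords[:, idx_by_mol[m], :].mean(axis=1) * _ANGSTROM_TO_UM
        tracks.append(Track(m, times, cent))
    return tracks


def compute_msd(
    data: Trajectory | Sequence[Track],
    lags: Sequence[int] | None = None,
    averaging: str = "time_and_ensemble",
    molecule_kind: str = "protein",
) -> MSDProfile | list[MSDProfile]:
    """Mean squared displacement from tracks or per-molecule trajectory centroids.

    ``lags`` are integer multiples of the sampling step (default: all
    available); lags at or beyond the series length are omitted with a
    warning.  ``averaging='time_and_ensemble'`` pools displacement pairs over
    overlapping windows and all particles into a single profile;
    ``'per_track'`` returns one profile per particle.
    """
    if isinstance(data, Trajectory):
        tracks = _trajectory_centroid_tracks(data, molecule_kind)
    else:
        tracks = list(data)
    if not tracks:
        raise ValueError("no tracks to analyze")
    n_min = min(tr.positions.shape[0] for tr in tracks)
    if n_min < 2:
        raise ValueError("need at least 2 time points")
    dt = tracks[0].dt
    dim = tracks[0].dim
    if lags is None:
        lag_steps = np.arange(0, n_min)
    else:
        lag_steps = np.asarray(sorted(set(int(l) for l in lags)))
        dropped = lag_steps[lag_steps >= n_min]
        if len(dropped):
            warnings.warn(f"lags {dropped.tolist()} >= series length; omitted")
            lag_steps = lag_steps[lag_steps < n_min]

    if averaging == "per_track":
        out = []
        for tr in tracks:
            msd, npairs = _msd_single(tr.positions, lag_steps)
            out.append(MSDProfile(lag_steps * dt, msd, npairs, dim))
        return out
    if averaging != "time_and_ensemble":
        raise ValueError(f"unknown averaging {averaging!r}")

    total = np.zeros(len(lag_steps))
    pairs = np.zeros(len(lag_steps), dtype=int)
    for tr in tracks:
        msd, npairs = _msd_single(tr.positions[:n_min], lag_steps)
        total += msd * npairs
        pairs += npairs
    return MSDProfile(lag_steps * dt, total / pairs, pairs, dim)


def diffusion_from_msd(
    profile: MSDProfile,
    method: str = "slope",
    at_lag: float | None = None,
    fit_range: tuple[float, float] | None = None,
    through_origin: bool = True,
) -> DiffusionEstimate:
    """Diffusion constant from an MSD profile.

    ``point``: D = MSD(at_lag) / (2 * dim * at_lag).
    ``slope``: least-squares line over ``fit_range`` (default: all nonzero
    lags), through the origin unless ``through_origin=False`` (then an
    intercept absorbs static localization offsets), D = slope / (2 * dim).
    """
    d2 = 2.0 * profile.dim
    if method == "point":
        if at_lag is None or at_lag == 0:
            raise ValueError("point estimate needs a nonzero at_lag")
        return DiffusionEstimate(profile.at(at_lag) / (d2 * at_lag), "point",
                                 (at_lag, at_lag))
    if method != "slope":
        raise ValueError(f"unknown method {method!r}")
    mask = profile.lags > 0
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (profile.lags >= lo) & (profile.lags <= hi)
    x = profile.lags[mask]
    y = profile.msd[mask]
    if len(x) < 2:
        raise ValueError("slope fit needs at least 2 lags in range")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        resid = y - slope * x
        se = float(np.sqrt(np.sum(resid**2) / max(len(x) - 1, 1) / np.dot(x, x)))
    else:
        (slope, _), cov = np.polyfit(x, y, 1, cov=True) if len(x) > 2 else (
            np.polyfit(x, y, 1), None)
        slope = float(slope)
        se = float(np.sqrt(cov[0, 0])) if cov is not None else None
    return DiffusionEstimate(slope / d2, "slope", (float(x[0]), float(x[-1])),
                             stderr=None if se is None else se / d2)


def per_track_diffusion(
    tracks: Sequence[Track],
    fit_fraction: float = 0.25,
    bins: int | Sequence[float] = 20,
) -> tuple[list[DiffusionEstimate], pd.DataFrame]:
    """One slope-method diffusion estimate per track, plus a histogram summary.

    Each track's time-averaged MSD is fit through the origin over the first
    ``fit_fraction`` of its lags (at least 2).  Tracks shorter than 4 points
    are skipped with a warning; the histogram table reports bin edges, counts
    and the number of skipped tracks in ``DataFrame.attrs``.
    """
    if not tracks:
        raise ValueError("no tracks provided")
    estimates: list[DiffusionEstimate] = []
    skipped = 0
    for tr in tracks:
        if tr.positions.shape[0] < 4:
            skipped += 1
            continue
        profile = compute_msd([tr], averaging="per_track")[0]
        n_fit = max(2, int(np.ceil(fit_fraction * (len(profile.lags) - 1))))
        est = diffusion_from_msd(
            profile, "slope",
            fit_range=(profile.lags[1], profile.lags[min(n_fit, len(profile.lags) - 1)]),
        )
        estimates.append(DiffusionEstimate(est.D, "slope", est.fit_range,
                                           est.stderr, tr.track_id))
    if skipped:
        warnings.warn(f"skipped {skipped} tracks shorter than 4 points")
    if not estimates:
        raise ValueError("no track was long enough to fit")
    values = np.array([e.D for e in estimates])
    counts, edges = np.histogram(values, bins=bins)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    hist.attrs["n_tracks"] = len(estimates)
    hist.attrs["n_skipped"] = skipped
    hist.attrs["mean_D"] = float(values.mean())
    return estimates, hist


def end_to_end_distance(
    traj: Trajectory,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
    molecule_id: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-frame distance (Å) between two ``(residue_id, atom_name)`` selectors.

    Returns ``(distances, mean, sd)`` with the population standard deviation
    over frames.  A selector matching no atom raises, naming the selector.
    """
    def locate(frame: Frame, sel: tuple[int, str]) -> np.ndarray:
        rid, name = sel
        for a in frame.atoms:
            if a.residue_id == rid and a.atom_name == name and (
                molecule_id is None or a.molecule_id == molecule_id
            ):
                return a.position
        raise ValueError(f"no atom matches selector (residue {rid}, atom {name!r})")

    d = np.array([
        float(np.linalg.norm(locate(f, atom_a) - locate(f, atom_b)))
        for f in traj.frames
    ])
    return d, float(d.mean()), float(d.std())


def fret_efficiency(r: float | np.ndarray, R0: float = 5.4):
    """Förster efficiency E = 1 / (1 + (r/R0)^6) for distance r (nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or R0 <= 0:
        raise ValueError("r and R0 must be positive")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return float(out) if out.ndim == 0 else out


def fret_distance(E: float | np.ndarray, R0: float = 5.4):
    """Donor-acceptor distance r = R0 * (1/E - 1)^(1/6) (nm) for E in (0, 1).

    The Förster radius default (5.4 nm) is a typical cyanine donor/acceptor
    value and is configurable.
    """
    E = np.asarray(E, dtype=float)
    if np.any((E <= 0) | (E >= 1)):
        raise ValueError("FRET efficiency must lie strictly in (0, 1)")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    out = R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out
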