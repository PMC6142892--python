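"""Single-particle tracking reference pipeline.

Detection uses a Laplacian-of-Gaussian (LoG) blob filter matched to the
expected spot radius, with sub-pixel localization by quadratic interpolation
of the response peak.  Linking solves a frame-to-frame linear assignment
problem (squared-displacement cost, non-link cost at the maximum link
distance) with optional gap closing; full segment merging/splitting is out
of scope — for sparse organelle fields frame-to-frame optimal assignment is
an internally consistent reference.  Trajectories shorter than a duration
threshold (default 12 s, strict inequality) are discarded before MSD
analysis; the MSD of each trajectory is time-averaged over all sample pairs
at each frame separation, and the ensemble curve is the unweighted mean of
the per-trajectory curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .io import ImageStack

__all__ = [
    "SpotDetection",
    "Trajectory",
    "MSDCurve",
    "detect_spots",
    "detect_stack",
    "link_trajectories",
    "filter_by_duration",
    "compute_msd",
    "ensemble_msd",
    "fit_diffusivity",
    "track",
    "trajectories_to_dataframe",
    "plot_trajectories",
]


@dataclass(frozen=True)
class SpotDetection:
    frame: int
    x_um: float
    y_um: float
    quality: float


@dataclass
class Trajectory:
    """Linked particle positions: strictly increasing frames, (x, y) in um."""

    particle_id: int
    frames: np.ndarray
    xy: np.ndarray
    frame_time_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")
        if self.xy.shape != (len(self.frames), 2):
            raise ValueError("xy must have shape (n_samples, 2)")

    @property
    def n_samples(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.frame_time_s)

    @property
    def t_s(self) -> np.ndarray:
        return self.frames * self.frame_time_s


@dataclass
class MSDCurve:
    """Time-averaged MSD: tau in s (multiples of the frame time), msd in um^2."""

    tau: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    frame_time_s: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"tau_s": self.tau, "msd_um2": self.msd, "n_pairs": self.n_pairs})


def _log_response(image: np.ndarray, sigma_px: float) -> np.ndarray:
    # scale-normalized negative LoG: positive at bright blobs
    return -(sigma_px**2) * ndimage.gaussian_laplace(
        np.asarray(image, dtype=np.float64), sigma_px
    )


def detect_spots(
    image: np.ndarray,
    expected_radius_px: float,
    quality_threshold: float | None = None,
    pixel_size_nm: float = 1000.0,
    frame: int = 0,
) -> list[SpotDetection]:
    """LoG spot detection on one frame with sub-pixel refinement.

    The LoG scale is matched to the expected blob radius (sigma = r/sqrt(2)).
    ``quality_threshold`` is in response units; when None a robust automatic
    threshold (median + 8 * MAD of the response) is used.  Sub-pixel offsets
    come from a per-axis quadratic fit of the response around each maximum.
    """
    if expected_radius_px < 1:
        raise ValueError("expected_radius_px must be >= 1")
    resp = _log_response(image, expected_radius_px / np.sqrt(2.0))
    if quality_threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med))
        quality_threshold = float(med + 8.0 * 1.4826 * mad)
    peaks = peak_local_max(
        resp,
        min_distance=max(int(np.ceil(expected_radius_px)), 1),
        threshold_abs=quality_threshold,
        exclude_border=1,
    )
    px_um = pixel_size_nm / 1000.0
    out = []
    for r, c in peaks:
        dr = _quad_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
        dc = _quad_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
        out.append(
            SpotDetection(
                frame=frame,
                x_um=(c + dc) * px_um,
                y_um=(r + dr) * px_um,
                quality=float(resp[r, c]),
            )
        )
    return out


def _quad_offset(m1: float, c0: float, p1: float) -> float:
    denom = m1 - 2.0 * c0 + p1
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))


def detect_stack(
    stack: ImageStack,
    expected_radius_px: float,
    quality_threshold: float | None = None,
) -> list[list[SpotDetection]]:
    """Run :func:`detect_spots` on every frame of a stack."""
    return [
        detect_spots(
            frame_data,
            expected_radius_px,
            quality_threshold,
            pixel_size_nm=stack.meta.pixel_size_nm,
            frame=t,
        )
        for t, frame_data in enumerate(stack.data)
    ]


_BIG = 1e12


def link_trajectories(
    detections_per_frame: Sequence[Sequence[SpotDetection]],
    max_link_distance_um: float,
    max_gap: int = 0,
    frame_time_s: float = 1.0,
) -> list[Trajectory]:
    """Frame-to-frame optimal assignment linking with gap closing.

    At each frame the active track ends (tracks last seen within
    ``max_gap + 1`` frames) and the new detections are matched by solving a
    padded linear assignment problem: real links cost squared distance and
    are forbidden beyond ``max_link_distance_um``; the alternative (track
    skips a frame / detection starts a new track) costs the squared maximum
    link distance.  Each detection is used at most once.
    """
    tracks: list[dict] = []
    active: list[dict] = []
    for f, dets in enumerate(detections_per_frame):
        dets = list(dets)
        candidates = [tr for tr in active if f - tr["frames"][-1] <= max_gap + 1]
        links: dict[int, dict] = {}
        if candidates and dets:
            R, C = len(candidates), len(dets)
            pos_t = np.array([tr["xy"][-1] for tr in candidates])
            pos_d = np.array([[d.x_um, d.y_um] for d in dets])
            d2 = np.sum((pos_t[:, None, :] - pos_d[None, :, :]) ** 2, axis=-1)
            alt = max_link_distance_um**2
            cost = np.full((R + C, R + C), _BIG)
            cost[:R, :C] = np.where(d2 <= alt, d2, _BIG)
            cost[:R, C:] = np.where(np.eye(R, dtype=bool), alt, _BIG)
            cost[R:, :C] = np.where(np.eye(C, dtype=bool), alt, _BIG)
            cost[R:, C:] = 0.0
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if r < R and c < C and cost[r, c] < alt:
                    links[c] = candidates[r]
        for c, det in enumerate(dets):
            if c in links:
                tr = links[c]
                tr["frames"].append(f)
                tr["xy"].append([det.x_um, det.y_um])
            else:
                tr = {"frames": [f], "xy": [[det.x_um, det.y_um]]}
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active if f - tr["frames"][-1] <= max_gap]
    return [
        Trajectory(
            particle_id=i,
            frames=np.array(tr["frames"]),
            xy=np.array(tr["xy"]),
            frame_time_s=frame_time_s,
        )
        for i, tr in enumerate(tracks)
    ]


def filter_by_duration(
    trajectories: Sequence[Trajectory], min_duration_s: float = 12.0
) -> list[Trajectory]:
    """Keep trajectories strictly longer than ``min_duration_s`` seconds."""
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    return [t for t in trajectories if t.duration_s > min_duration_s]


def compute_msd(traj: Trajectory) -> MSDCurve:
    """Time-averaged MSD over all sample pairs at each true frame separation.

    Gap frames are handled by pairing on the real frame separation, not the
    sample index, so a closed gap never contaminates neighbouring lags.
    """
    if traj.n_samples < 2:
        raise ValueError("need at least 2 samples to compute an MSD")
    span = traj.frames - traj.frames[0]
    dense = np.full((span[-1] + 1, 2), np.nan)
    dense[span] = traj.xy
    taus = [0.0]
    msds = [0.0]
    n_pairs = [traj.n_samples]
    for k in range(1, span[-1] + 1):
        d = dense[k:] - dense[:-k]
        sq = np.sum(d * d, axis=1)
        good = ~np.isnan(sq)
        if not np.any(good):
            continue
        taus.append(k * traj.frame_time_s)
        msds.append(float(np.mean(sq[good])))
        n_pairs.append(int(np.sum(good)))
    return MSDCurve(
        tau=np.array(taus),
        msd=np.array(msds),
        n_pairs=np.array(n_pairs),
        frame_time_s=traj.frame_time_s,
    )


def ensemble_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Unweighted mean of per-trajectory MSDs at each common lag.

    ``n_pairs`` records how many trajectories contribute at each lag.
    """
    if not curves:
        raise ValueError("need at least one MSD curve")
    dt = curves[0].frame_time_s
    acc: dict[int, list[float]] = {}
    for cv in curves:
        for t, m in zip(cv.tau, cv.msd):
            acc.setdefault(int(round(t / dt)), []).append(m)
    if not acc:
        raise ValueError("no common lags across curves")
    ks = sorted(acc)
    return MSDCurve(
        tau=np.array([k * dt for k in ks]),
        msd=np.array([np.mean(acc[k]) for k in ks]),
        n_pairs=np.array([len(acc[k]) for k in ks]),
        frame_time_s=dt,
    )


def fit_diffusivity(
    curve: MSDCurve, n_lags: int | None = None, with_offset: bool = True
) -> tuple[float, float, float]:
    """Diffusivity from a linear fit msd = offset + 4 D tau over early lags.

    Default window: the first max(4, 10% of available) nonzero lags,
    mirroring the iMSD default fit window.  Returns (D, offset, r_squared).
    """
    nz = curve.tau > 0
    tau = curve.tau[nz]
    msd = curve.msd[nz]
    if n_lags is None:
        n_lags = max(4, int(round(0.1 * len(tau))))
    tau, msd = tau[:n_lags], msd[:n_lags]
    if len(tau) < 2:
        raise ValueError("need at least 2 nonzero lags for a diffusivity fit")
    if with_offset:
        A = np.vstack([np.ones_like(tau), 4.0 * tau]).T
    else:
        A = (4.0 * tau)[:, None]
    coef, *_ = np.linalg.lstsq(A, msd, rcond=None)
    pred = A @ coef
    ss_tot = np.sum((msd - msd.mean()) ** 2)
    r2 = 1.0 - np.sum((msd - pred) ** 2) / ss_tot if ss_tot > 0 else np.nan
    D = float(coef[-1])
    offset = float(coef[0]) if with_offset else 0.0
    return D, offset, float(r2)


def track(
    stack: ImageStack,
    expected_radius_px: float = 3.0,
    quality_threshold: float | None = None,
    max_link_distance_um: float = 0.5,
    max_gap: int = 2,
    min_duration_s: float = 12.0,
) -> list[Trajectory]:
    """Full SPT pipeline: detect -> link -> duration filter."""
    dets = detect_stack(stack, expected_radius_px, quality_threshold)
    trajs = link_trajectories(
        dets, max_link_distance_um, max_gap=max_gap, frame_time_s=stack.meta.frame_time_s
    )
    return filter_by_duration(trajs, min_duration_s)


def trajectories_to_dataframe(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for f, (x, y) in zip(tr.frames, tr.xy):
            rows.append(
                {
                    "particle_id": tr.particle_id,
                    "frame": int(f),
                    "t_s": f * tr.frame_time_s,
                    "x_um": x,
                    "y_um": y,
                }
            )
    return pd.DataFrame(rows, columns=["particle_id", "frame", "t_s", "x_um", "y_um"])


def plot_trajectories(
    stack: ImageStack, trajectories: Sequence[Trajectory], path: str | Path
) -> None:
    """Overlay trajectories on the first frame and save as PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    px_um = stack.meta.pixel_size_um
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(stack.data[0], cmap="gray", origin="upper")
    for tr in trajectories:
        ax.plot(tr.xy[:, 0] / px_um, tr.xy[:, 1] / px_um, lw=0.8)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{len(trajectories)} trajectories")
    fig.savefig(path, dpi=150)
    plt.close(fig)
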