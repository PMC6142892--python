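"""Reading calibrated TIFF stacks and writing spreadsheet-style results.

Time-lapse confocal acquisitions are stored either as a directory of
single-frame TIFFs named ``<prefix>_<xxxx>.tif`` (a 4-digit zero-padded
frame counter) or as a single multi-page TIFF (the common ImageJ export).
TIFF calibration tags are deliberately ignored: pixel size and frame time
come from user-supplied :class:`AcquisitionMeta`, because the calibration
of typical deposited datasets lives in the accompanying documentation, not
reliably in the files.

Analysis results are exported both as plain CSV files (the canonical,
round-trippable form) and as a multi-sheet ``.xlsx`` workbook mirroring the
per-acquisition spreadsheet layout used in the field: correlation-function
evolution, iMSD curve, fitted curves with determination coefficients, and
the fitted dynamic parameters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionMeta",
    "ImageStack",
    "ResultsTable",
    "ORGANELLE_DEFAULTS",
    "meta_for_label",
    "read_stack",
    "write_stack",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition calibration: pixel size (nm), frame time (s), frame count.

    ``n_frames`` may be ``None`` when the count is to be taken from the
    files themselves (``read_stack`` fills it in).
    """

    pixel_size_nm: float
    frame_time_s: float
    n_frames: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if not self.frame_time_s > 0:
            raise ValueError(f"frame_time_s must be > 0, got {self.frame_time_s}")
        if self.n_frames is not None and self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


#: Per-organelle acquisition defaults: early/late endosomes were imaged at
#: 129 ms per frame (1000 frames), lysosomes at 65 ms (460 frames), all at
#: 69 nm pixel size.
ORGANELLE_DEFAULTS: Mapping[str, AcquisitionMeta] = {
    "ee": AcquisitionMeta(69.0, 0.129, 1000, "ee"),
    "le": AcquisitionMeta(69.0, 0.129, 1000, "le"),
    "ly": AcquisitionMeta(69.0, 0.065, 460, "ly"),
}


def meta_for_label(label: str, n_frames: int | None = None) -> AcquisitionMeta:
    """Default :class:`AcquisitionMeta` for an organelle label (ee/le/ly)."""
    try:
        meta = ORGANELLE_DEFAULTS[label]
    except KeyError:
        raise KeyError(
            f"unknown organelle label {label!r}; known: {sorted(ORGANELLE_DEFAULTS)}"
        ) from None
    if n_frames is not None:
        meta = replace(meta, n_frames=n_frames)
    return meta


@dataclass
class ImageStack:
    """A calibrated intensity record indexed (frame, row, column).

    ``data`` is floating point (promoted once at read time); the original
    integer array, when the stack came from integer TIFFs, is retained in
    ``raw`` so that write/read round trips can be checked bit-exactly.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if self.raw is None and np.issubdtype(arr.dtype, np.integer):
            self.raw = arr.copy()
        self.data = arr.astype(np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (frame, row, col), got {self.data.ndim}D")
        if self.data.shape[0] < 2:
            raise ValueError("stack must contain at least 2 frames")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")
        if self.meta.n_frames is None:
            self.meta = replace(self.meta, n_frames=self.data.shape[0])
        elif self.meta.n_frames != self.data.shape[0]:
            raise ValueError(
                f"meta.n_frames={self.meta.n_frames} but stack has "
                f"{self.data.shape[0]} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


_FRAME_RE = re.compile(r"^(?P<prefix>.+)_(?P<idx>\d+)\.tiff?$", re.IGNORECASE)


def _collect_frame_files(directory: Path) -> list[tuple[int, Path]]:
    found: dict[str, list[tuple[int, Path]]] = {}
    for p in directory.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            found.setdefault(m.group("prefix"), []).append((int(m.group("idx")), p))
    if not found:
        raise FileNotFoundError(
            f"no files matching '<prefix>_<index>.tif' in {directory}"
        )
    if len(found) > 1:
        raise ValueError(
            f"multiple frame-series prefixes in {directory}: {sorted(found)}; "
            "point read_stack at a single series"
        )
    (_, files), = found.items()
    files.sort(key=lambda t: t[0])
    return files


def read_stack(source: str | Path, meta: AcquisitionMeta) -> ImageStack:
    """Read a TIFF frame series (or a multi-page TIFF) into an ImageStack.

    Frames are ordered by the numeric index embedded in the filenames, never
    by filesystem listing order; the index run must be contiguous.  Pixel
    values are preserved bit-exactly in ``raw`` and promoted to float64 in
    ``data``.
    """
    source = Path(source)
    if source.is_file():
        raw = tifffile.imread(source)
        if raw.ndim == 2:
            raise ValueError(f"{source} holds a single frame; a stack needs >= 2")
        if raw.ndim != 3:
            raise ValueError(f"{source}: expected a 2D-frame series, got shape {raw.shape}")
    else:
        files = _collect_frame_files(source)
        if len(files) < 2:
            raise ValueError(
                f"{source}: found {len(files)} frame(s); a stack needs at least 2"
            )
        indices = [i for i, _ in files]
        expect = range(indices[0], indices[0] + len(indices))
        if indices != list(expect):
            missing = sorted(set(expect) - set(indices))
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            detail = f"missing frame index(es) {missing}" if missing else f"duplicate index(es) {dupes}"
            raise ValueError(f"{source}: frame index run is not contiguous: {detail}")
        frames = [tifffile.imread(p) for _, p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"{source}: mixed frame shapes {sorted(shapes)}")
        raw = np.stack(frames, axis=0)

    meta = replace(meta, n_frames=raw.shape[0]) if meta.n_frames is None else meta
    keep_raw = raw if np.issubdtype(raw.dtype, np.integer) else None
    return ImageStack(data=raw.astype(np.float64), meta=meta, raw=keep_raw)


def write_stack(
    stack: ImageStack | np.ndarray,
    directory: str | Path,
    prefix: str = "sim",
    start_index: int = 1,
    digits: int = 4,
) -> list[Path]:
    """Write a stack as a 16-bit single-frame TIFF series ``<prefix>_<xxxx>.tif``.

    Float data are rounded and clipped into the uint16 range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.uint16)
    else:
        out = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    paths = []
    for k, frame in enumerate(out):
        p = directory / f"{prefix}_{start_index + k:0{digits}d}.tif"
        tifffile.imwrite(p, frame)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

#: block name -> canonical CSV file name
_BLOCKS = {
    "correlation_evolution": "correlation_evolution.csv",
    "imsd": "imsd.csv",
    "fitted_curves": "fitted_curves.csv",
    "fits": "fits.csv",
}


@dataclass
class ResultsTable:
    """The spreadsheet-style output of one acquisition's iMSD analysis.

    Blocks: the time evolution of the correlation function (zero-lag
    amplitude vs temporal lag), the iMSD curve sigma^2(tau), the fitted
    model curves, and the fitted parameters (D_M, alpha, sigma0^2, size)
    each with its determination coefficient.
    """

    correlation_evolution: pd.DataFrame = field(default_factory=pd.DataFrame)
    imsd: pd.DataFrame = field(default_factory=pd.DataFrame)
    fitted_curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    fits: pd.DataFrame = field(default_factory=pd.DataFrame)
    label: str = ""

    def _validate(self) -> None:
        for name in ("correlation_evolution", "imsd", "fitted_curves"):
            df = getattr(self, name)
            if len(df) and "tau_s" in df.columns:
                tau = df["tau_s"].to_numpy(float)
                if np.any(np.diff(tau) <= 0):
                    raise ValueError(f"{name}: tau_s column must be strictly increasing")
        if len(self.fits) and "r_squared" not in self.fits.columns:
            raise ValueError("fits block must carry a determination coefficient column")


def write_results(results: ResultsTable, out_dir: str | Path) -> Path:
    """Write all blocks as CSVs plus a multi-sheet workbook ``results.xlsx``.

    CSV is the canonical form: a round trip through :func:`read_results`
    recovers every numeric value at full written precision.
    """
    results._validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for block, fname in _BLOCKS.items():
        df: pd.DataFrame = getattr(results, block)
        if df.empty:
            logger.warning("results block %r is empty; writing header-only file", block)
        df.to_csv(out_dir / fname, index=False, float_format="%.17g")
    with pd.ExcelWriter(out_dir / "results.xlsx") as xl:
        for block in _BLOCKS:
            getattr(results, block).to_excel(xl, sheet_name=block, index=False)
    return out_dir


def read_results(out_dir: str | Path) -> ResultsTable:
    """Read back a :class:`ResultsTable` written by :func:`write_results`."""
    out_dir = Path(out_dir)
    kwargs = {}
    for block, fname in _BLOCKS.items():
        p = out_dir / fname
        if not p.exists():
            raise FileNotFoundError(f"missing results block file {p}")
        try:
            kwargs[block] = pd.read_csv(p, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            kwargs[block] = pd.DataFrame()
    return ResultsTable(**kwargs)
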