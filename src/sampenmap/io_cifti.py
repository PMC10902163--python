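"""File I/O: CIFTI-2 time series and scalar maps, plus a plain TSV dialect.

CIFTI-2 (read and written through nibabel) is the only imaging dialect.
The TSV dialect — tab-delimited, UTF-8, rows = grayordinates, missing =
empty field — is normative for tests, so the whole pipeline can run on
plain text.  Multi-run series are supplied as separate files plus a small
YAML/JSON manifest; run boundaries are never inferred from a single
concatenated file.  No operation reorders grayordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .signal_model import BoldMatrix, MotionTrace

__all__ = [
    "GrayordinateSpace",
    "read_timeseries",
    "write_timeseries",
    "read_scalar_map",
    "write_scalar_map",
    "read_fd",
    "load_manifest",
    "write_fixture",
    "make_dense_space",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


@dataclass
class GrayordinateSpace:
    """Structure layout of a dense or parcellated axis.

    ``structures`` is an ordered tuple of (name, start, stop) half-open
    index ranges partitioning [0, total); ``axis`` retains the underlying
    nibabel CIFTI-2 axis (BrainModelAxis or ParcelsAxis) so output files
    carry the input geometry bit-exactly.  A plain space has one structure
    and no axis.
    """

    structures: tuple[tuple[str, int, int], ...]
    total: int
    axis: object | None = None

    def __post_init__(self) -> None:
        pos = 0
        for name, a, b in self.structures:
            if a != pos or b <= a:
                raise ValueError("structure ranges must partition [0, total)")
            pos = b
        if pos != self.total:
            raise ValueError("structure ranges must cover the whole space")

    @classmethod
    def plain(cls, total: int) -> "GrayordinateSpace":
        return cls((("plain", 0, total),), total)

    @classmethod
    def from_axis(cls, axis) -> "GrayordinateSpace":
        import nibabel.cifti2.cifti2_axes as axes

        if isinstance(axis, axes.BrainModelAxis):
            structures = tuple(
                (
                    str(name),
                    int(sl.start or 0),
                    len(axis) if sl.stop is None else int(sl.stop),
                )
                for name, sl, _ in axis.iter_structures()
            )
            return cls(structures, len(axis), axis)
        if isinstance(axis, axes.ParcelsAxis):
            structures = tuple((name, i, i + 1) for i, name in enumerate(axis.name))
            return cls(structures, len(axis), axis)
        raise FormatError(f"unsupported grayordinate axis type {type(axis).__name__}")

    def region_masks(self) -> dict[str, np.ndarray]:
        masks = {}
        for name, a, b in self.structures:
            mask = np.zeros(self.total, dtype=bool)
            mask[a:b] = True
            masks[name] = mask
        return masks


def _infer_format(path: Path) -> str:
    name = path.name
    if name.endswith(".dtseries.nii"):
        return "dtseries"
    if name.endswith(".ptseries.nii"):
        return "ptseries"
    if name.endswith(".dscalar.nii"):
        return "dscalar"
    if name.endswith(".pscalar.nii"):
        return "pscalar"
    if name.endswith((".tsv", ".txt")):
        return "tsv"
    raise FormatError(f"cannot infer format from file name {name!r}")


def _load_cifti(path: Path, want_first: str):
    import nibabel as nib
    import nibabel.cifti2.cifti2_axes as axes

    img = nib.load(str(path))
    try:
        ax0 = img.header.get_axis(0)
        ax1 = img.header.get_axis(1)
    except Exception as exc:  # malformed header
        raise FormatError(f"{path}: malformed CIFTI-2 header ({exc})") from exc
    wanted = {"series": axes.SeriesAxis, "scalar": axes.ScalarAxis}[want_first]
    if not isinstance(ax0, wanted):
        raise FormatError(
            f"{path}: expected a {want_first} axis along rows, found "
            f"{type(ax0).__name__}"
        )
    return np.asarray(img.get_fdata()), ax0, ax1


def read_timeseries(
    path: str | Path, fmt: str | None = None
) -> tuple[BoldMatrix, GrayordinateSpace]:
    """Read a single-run time series file.

    Formats: ``dtseries`` / ``ptseries`` (CIFTI-2) or ``tsv`` (rows =
    grayordinates, columns = volumes).  Returns the grayordinates x volumes
    matrix with an all-False censor mask, one run, and the space.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", header=None, float_precision="round_trip")
        data = frame.to_numpy(dtype=float)
        bold = BoldMatrix(data, space="plain")
        return bold, GrayordinateSpace.plain(data.shape[0])
    if fmt not in ("dtseries", "ptseries"):
        raise FormatError(f"unknown time-series format {fmt!r}")
    data, series, ax1 = _load_cifti(path, "series")
    space = GrayordinateSpace.from_axis(ax1)
    tr = float(series.step) if series.unit == "SECOND" else None
    bold = BoldMatrix(
        data.T, space="dense" if fmt == "dtseries" else "parcellated", tr=tr
    )
    return bold, space


def write_timeseries(
    bold: BoldMatrix,
    space: GrayordinateSpace,
    path: str | Path,
    fmt: str | None = None,
) -> Path:
    """Write a time series as TSV or CIFTI-2 dtseries/ptseries."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if bold.n_grayordinates != space.total:
        raise ValueError(
            f"matrix has {bold.n_grayordinates} grayordinates, space expects {space.total}"
        )
    if fmt == "tsv":
        np.savetxt(path, bold.data, delimiter="\t", fmt=_FLOAT_FMT)
        return path
    if fmt not in ("dtseries", "ptseries"):
        raise FormatError(f"unknown time-series format {fmt!r}")
    import nibabel as nib
    from nibabel.cifti2.cifti2_axes import SeriesAxis

    if space.axis is None:
        raise ValueError("a CIFTI-2 axis is required to write imaging formats")
    series = SeriesAxis(start=0.0, step=bold.tr or 1.0, size=bold.n_volumes)
    header = nib.cifti2.Cifti2Header.from_axes((series, space.axis))
    img = nib.cifti2.Cifti2Image(bold.data.T, header)
    img.nifti_header.set_data_dtype(np.float64)
    img.to_filename(str(path))
    return path


def write_scalar_map(
    values: np.ndarray,
    space: GrayordinateSpace,
    path: str | Path,
    fmt: str | None = None,
    name: str = "sampen",
) -> Path:
    """Write one per-grayordinate scalar map (entropy, ICC, ...).

    Undefined sentinels (NaN) are stored as the format's missing-value
    convention: NaN in CIFTI-2, an empty field in TSV.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != space.total:
        raise ValueError(f"expected {space.total} values, got {values.size}")
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        pd.DataFrame({name: values}).to_csv(
            path, sep="\t", index=False, na_rep="", float_format=_FLOAT_FMT
        )
        return path
    if fmt not in ("dscalar", "pscalar"):
        raise FormatError(f"unknown scalar format {fmt!r}")
    import nibabel as nib
    from nibabel.cifti2.cifti2_axes import ScalarAxis

    if space.axis is None:
        raise ValueError("a CIFTI-2 axis is required to write imaging formats")
    header = nib.cifti2.Cifti2Header.from_axes((ScalarAxis([name]), space.axis))
    img = nib.cifti2.Cifti2Image(values[None, :], header)
    img.nifti_header.set_data_dtype(np.float64)
    img.to_filename(str(path))
    return path


def read_scalar_map(
    path: str | Path, fmt: str | None = None
) -> tuple[np.ndarray, GrayordinateSpace]:
    """Read a scalar map written by :func:`write_scalar_map`."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        col = pd.read_csv(path, sep="\t").iloc[:, 0].to_numpy(dtype=float)
        return col, GrayordinateSpace.plain(col.size)
    if fmt not in ("dscalar", "pscalar"):
        raise FormatError(f"unknown scalar format {fmt!r}")
    data, _, ax1 = _load_cifti(path, "scalar")
    return data[0], GrayordinateSpace.from_axis(ax1)


def read_fd(path: str | Path, column: str | None = None) -> np.ndarray:
    """Read one run's FD trace: a single-column text file, or a delimited
    table with a named FD column (``column`` overrides the default
    candidates 'fd' / 'framewise_displacement')."""
    path = Path(path)
    try:
        return np.loadtxt(path, ndmin=1, dtype=float)
    except ValueError:
        pass
    table = pd.read_csv(path, sep=None, engine="python")
    candidates = [column] if column else ["fd", "framewise_displacement"]
    for cand in candidates:
        for col in table.columns:
            if col.strip().lower() == cand.lower():
                return table[col].to_numpy(dtype=float)
    raise FormatError(f"{path}: no FD column found among {list(table.columns)}")


def load_manifest(path: str | Path) -> tuple[BoldMatrix, MotionTrace, GrayordinateSpace]:
    """Load a multi-run dataset described by a YAML/JSON run manifest.

    Schema::

        tr: 0.8            # optional, seconds
        runs:
          - {bold: run1_bold.tsv, fd: run1_fd.txt}
          - {bold: run2_bold.tsv, fd: run2_fd.txt}

    Paths are resolved relative to the manifest.  Run boundaries follow
    file lengths in manifest order.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        manifest = yaml.safe_load(path.read_text())
    elif path.suffix == ".json":
        manifest = json.loads(path.read_text())
    else:
        raise FormatError(f"manifest must be YAML or JSON, got {path.name!r}")
    runs = manifest.get("runs")
    if not runs:
        raise FormatError(f"{path}: manifest lists no runs")
    blocks: list[np.ndarray] = []
    fds: list[np.ndarray] = []
    space: GrayordinateSpace | None = None
    space_kind = "plain"
    tr = manifest.get("tr")
    for entry in runs:
        bold, run_space = read_timeseries(path.parent / entry["bold"])
        if space is None:
            space = run_space
            space_kind = bold.space
        elif run_space.total != space.total:
            raise FormatError(
                f"{entry['bold']}: {run_space.total} grayordinates, expected {space.total}"
            )
        tr = tr if tr is not None else bold.tr
        blocks.append(bold.data)
        fds.append(read_fd(path.parent / entry["fd"]))
    lengths = [b.shape[1] for b in blocks]
    boundaries = []
    pos = 0
    for n in lengths:
        boundaries.append((pos, pos + n))
        pos += n
    combined = BoldMatrix(
        np.concatenate(blocks, axis=1),
        run_boundaries=tuple(boundaries),
        space=space_kind,
        tr=tr,
    )
    trace = MotionTrace(tuple(fds))
    trace.check_paired(combined)
    return combined, trace, space


def write_fixture(
    bold: BoldMatrix, trace: MotionTrace, directory: str | Path, stem: str = "run"
) -> Path:
    """Serialize a generated fixture as per-run TSV matrices, single-column
    FD text files and a YAML manifest; returns the manifest path."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trace.check_paired(bold)
    entries = []
    for i, (a, b) in enumerate(bold.run_boundaries):
        bold_name = f"{stem}{i + 1}_bold.tsv"
        fd_name = f"{stem}{i + 1}_fd.txt"
        np.savetxt(directory / bold_name, bold.data[:, a:b], delimiter="\t", fmt=_FLOAT_FMT)
        np.savetxt(directory / fd_name, trace.fd[i], fmt=_FLOAT_FMT)
        entries.append({"bold": bold_name, "fd": fd_name})
    manifest_path = directory / "manifest.yaml"
    manifest = {"tr": bold.tr, "runs": entries}
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def make_dense_space(
    n_left: int = 8, n_right: int = 8, volume_shape: tuple[int, int, int] = (4, 4, 4), n_voxels: int = 8
) -> GrayordinateSpace:
    """Build a small synthetic dense grayordinate space (two surface
    structures plus one subcortical block) for tests and examples."""
    import nibabel.cifti2.cifti2_axes as axes

    left = axes.BrainModelAxis.from_surface(
        np.arange(n_left), n_left, name="CIFTI_STRUCTURE_CORTEX_LEFT"
    )
    right = axes.BrainModelAxis.from_surface(
        np.arange(n_right), n_right, name="CIFTI_STRUCTURE_CORTEX_RIGHT"
    )
    mask = np.zeros(volume_shape, dtype=bool)
    mask.ravel()[:n_voxels] = True
    sub = axes.BrainModelAxis.from_mask(
        mask, name="thalamus_right", affine=np.eye(4)
    )
    return GrayordinateSpace.from_axis(left + right + sub)
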