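"""On-disk formats: EDF, plain matrix + JSON sidecar, cohort manifests.

Two interchangeable per-subject formats are supported:

* ``matrix`` — a delimited text file of channels x samples next to a
  JSON sidecar holding the sampling rate, channel names and labels
  (lossless, diff-able; the default);
* ``edf`` — 16-bit European Data Format. Writing uses a minimal
  header/int16 encoder implemented here; reading goes through MNE's
  EDF reader, so the writer is always exercised against an independent
  parser.

A cohort lives in one directory with a ``manifest.csv`` mapping
``subject_id, group, dataset_id, file``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_cohort",
    "write_edf",
    "read_edf",
]


class FormatError(ValueError):
    """Corrupt or unsupported file content."""


# ---------------------------------------------------------------- matrix

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_matrix(rec: Recording, path: Path) -> None:
    np.savetxt(path, rec.data, delimiter="\t")
    meta = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "dataset_id": rec.dataset_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_matrix(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = {"fs", "channel_names", "subject_id", "group", "dataset_id"} - set(meta)
    if missing:
        raise FormatError(f"sidecar {sidecar} missing fields {sorted(missing)}")
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        dataset_id=meta["dataset_id"],
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        data=data,
    )


# ------------------------------------------------------------------- EDF

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.encode("ascii").ljust(width)


def _fmt8(v: float, width: int = 7) -> str:
    """Shortest %g rendering of ``v`` that fits a ``width``-char field
    (7 by default, leaving room for a leading minus sign)."""
    for prec in range(7, -1, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    raise FormatError(f"cannot encode {v!r} in a {width}-character EDF field")


def write_edf(rec: Recording, path: Path) -> None:
    """Write a 16-bit EDF file with 1 s data records.

    Per-channel physical ranges are symmetric around zero, so the
    quantization step is ``2 * max|x| / 65534``. The sampling rate must
    be a positive integer; trailing samples that do not fill a whole
    record are dropped.
    """
    path = Path(path)
    fs = rec.fs
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF data record")
    ns = rec.n_channels
    data = rec.data[:, : n_rec * spr]
    dig_max = 32767
    # symmetric physical range, rounded to its 8-char header rendering so
    # the digital -> physical scaling is exactly what a reader recovers
    phys_str = [_fmt8(m) for m in np.maximum(np.abs(data).max(axis=1), 1e-12)]
    phys_max = np.array([float(s) for s in phys_str])
    phys_max = np.where(
        phys_max < np.abs(data).max(axis=1),
        np.array([float(_fmt8(m * (1 + 1e-5))) for m in np.abs(data).max(axis=1)]),
        phys_max,
    )
    phys_str = [_fmt8(m) for m in phys_max]
    phys_max = np.array([float(s) for s in phys_str])
    header = b"".join([
        _ascii(0, 8),
        _ascii(f"{rec.subject_id} {rec.group} {rec.dataset_id}", 80),
        _ascii("synthetic cohort", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ])
    fields = [
        [_ascii(name, 16) for name in rec.channel_names],
        [_ascii("", 80)] * ns,                       # transducer
        [_ascii("uV", 8)] * ns,                      # physical dimension
        [_ascii(f"-{s}"[:8], 8) for s in phys_str],
        [_ascii(s, 8) for s in phys_str],
        [_ascii(-dig_max, 8)] * ns,
        [_ascii(dig_max, 8)] * ns,
        [_ascii("", 80)] * ns,                       # prefiltering
        [_ascii(spr, 8)] * ns,
        [_ascii("", 32)] * ns,
    ]
    header += b"".join(b"".join(f) for f in fields)
    scale = phys_max / dig_max
    digital = np.clip(
        np.round(data / scale[:, None]), -dig_max, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(
    path: Path,
    subject_id: str | None = None,
    group: str = "",
    dataset_id: str = "",
) -> Recording:
    """Read an EDF file via MNE; metadata not stored in EDF is supplied
    by the caller (normally from the cohort manifest)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts for uV channels
    return Recording(
        subject_id=subject_id or Path(path).stem,
        group=group,
        dataset_id=dataset_id,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        data=data,
    )


# ---------------------------------------------------------------- fronts

def write_recording(rec: Recording, path, format: str = "matrix") -> None:
    if format == "matrix":
        _write_matrix(rec, Path(path))
    elif format == "edf":
        write_edf(rec, Path(path))
    else:
        raise FormatError(f"unknown format {format!r}")


def read_recording(
    path,
    format: str = "matrix",
    montage: list[str] | None = None,
    **meta,
) -> Recording:
    """Read one recording; optionally subset/reorder to ``montage``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix":
        rec = _read_matrix(path)
    elif format == "edf":
        rec = read_edf(path, **meta)
    else:
        raise FormatError(f"unknown format {format!r}")
    if montage is not None:
        rec = rec.subset(montage)
    return rec


def write_cohort(recs: list[Recording], out_dir, format: str = "matrix") -> Path:
    """Write one file per subject plus ``manifest.csv``; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"matrix": ".tsv", "edf": ".edf"}[format]
    rows = []
    for rec in recs:
        fname = f"{rec.subject_id}{ext}"
        write_recording(rec, out_dir / fname, format=format)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "dataset_id": rec.dataset_id,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_cohort(in_dir, montage: list[str] | None = None) -> list[Recording]:
    """Read every subject listed in a cohort directory's manifest."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    recs = []
    for row in manifest.itertuples():
        fname = Path(str(row.file))
        fmt = "edf" if fname.suffix == ".edf" else "matrix"
        rec = read_recording(
            in_dir / fname,
            format=fmt,
            montage=montage,
            **(
                dict(
                    subject_id=row.subject_id,
                    group=row.group,
                    dataset_id=row.dataset_id,
                )
                if fmt == "edf"
                else {}
            ),
        )
        if fmt == "matrix":
            rec.subject_id = str(row.subject_id)
            rec.group = str(row.group)
            rec.dataset_id = str(row.dataset_id)
        recs.append(rec)
    return recs
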