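"""Reading and writing 12-lead ECG records and derived feature tensors.

Three record formats are supported:

* ``csv`` — one header row of lead names, one row per sample, values in mV.
  An optional JSON sidecar (same stem, ``.json`` extension) carries sampling
  frequency, labels and record id.
* ``cpsc-matrix`` — a ``.npy`` file holding the raw 12xN sample matrix plus a
  mandatory JSON sidecar with metadata (mirrors the corpus layout of one
  matrix per record without committing to a proprietary container).
* ``wfdb`` — a minimal WFDB implementation (format 16, interleaved int16
  little-endian ``.dat`` with a text ``.hea`` header; ``#Dx:`` comment lines
  carry labels).

All readers normalise to :class:`EcgRecord` with the canonical lead order,
so downstream code may assume row 0 is lead I.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

#: Canonical 12-lead ordering enforced at the I/O boundary.
LEAD_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6"]

#: The nine rhythm classes, in fixed index order.
CLASSES = ["NSR", "AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC", "STD", "STE"]

#: Sentinel label for records whose annotation is missing.
UNKNOWN_LABEL = "UNKNOWN"

DEFAULT_FS = 500.0


class ParseError(ValueError):
    """A file did not parse in the stated format."""


class DimensionError(ValueError):
    """A record does not have the expected channel count / shape."""


@dataclass
class EcgRecord:
    """A 12-lead ECG record: 12 x N sample matrix in mV plus metadata.

    ``labels`` is ordered; ``labels[0]`` is THE class used for training and
    evaluation (multi-label records keep their remaining labels but are
    represented by the first diagnosis).
    """

    signal: np.ndarray
    fs: float = DEFAULT_FS
    lead_names: list[str] = field(default_factory=lambda: list(LEAD_NAMES))
    labels: list[str] = field(default_factory=lambda: [UNKNOWN_LABEL])
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise DimensionError(
                f"expected a 12 x N signal matrix, got shape {self.signal.shape}"
            )
        if not self.fs > 0:
            raise ParseError(f"sampling frequency must be positive, got {self.fs}")
        if len(self.lead_names) != 12:
            raise DimensionError(f"expected 12 lead names, got {len(self.lead_names)}")
        if not self.labels:
            self.labels = [UNKNOWN_LABEL]
        if self.n_samples < 6 * self.fs:
            warnings.warn(
                f"record {self.record_id!r} is shorter than 6 s "
                f"({self.n_samples / self.fs:.2f} s)",
                stacklevel=2,
            )
        if list(self.lead_names) != LEAD_NAMES:
            self._reorder_leads()

    def _reorder_leads(self) -> None:
        canon = {name.upper(): i for i, name in enumerate(LEAD_NAMES)}
        try:
            order = [canon[name.upper()] for name in self.lead_names]
        except KeyError as exc:
            raise ParseError(f"unknown lead name {exc.args[0]!r}") from exc
        if sorted(order) != list(range(12)):
            raise ParseError(f"lead names are not a permutation of {LEAD_NAMES}")
        permuted = np.empty_like(self.signal)
        permuted[order] = self.signal
        self.signal = permuted
        self.lead_names = list(LEAD_NAMES)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def label(self) -> str:
        """The representative class (first diagnosis)."""
        return self.labels[0]

    @property
    def has_labels(self) -> bool:
        return self.labels[0] != UNKNOWN_LABEL

    def lead(self, name: str) -> np.ndarray:
        return self.signal[LEAD_NAMES.index(name)]


# ---------------------------------------------------------------------------
# record readers / writers


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path, required: bool) -> dict:
    side = _sidecar_path(path)
    if not side.exists():
        if required:
            raise ParseError(f"missing metadata sidecar {side}")
        return {}
    try:
        return json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed sidecar {side}: {exc}") from exc


def read_record(path: str | Path, format: str | None = None) -> EcgRecord:
    """Read an ECG record, normalising to the canonical lead order.

    ``format`` is one of ``csv``, ``cpsc-matrix``, ``wfdb``; when omitted it
    is inferred from the file extension (.csv / .npy / .hea).
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".npy": "cpsc-matrix", ".hea": "wfdb",
                  ".dat": "wfdb"}.get(path.suffix.lower())
        if format is None:
            raise ParseError(f"cannot infer format from {path.name!r}")
    if format == "csv":
        return _read_csv(path)
    if format == "cpsc-matrix":
        return _read_cpsc(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ParseError(f"unknown format {format!r}")


def write_record(record: EcgRecord, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".npy": "cpsc-matrix", ".hea": "wfdb",
                  ".dat": "wfdb"}.get(path.suffix.lower())
        if format is None:
            raise ParseError(f"cannot infer format from {path.name!r}")
    if format == "csv":
        _write_csv(record, path)
    elif format == "cpsc-matrix":
        _write_cpsc(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ParseError(f"unknown format {format!r}")


def _read_csv(path: Path) -> EcgRecord:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        raise ParseError(f"{path}: empty file (field: header)")
    names = [c.strip() for c in header.split(",")]
    if len(names) != 12:
        raise DimensionError(f"{path}: expected 12 lead columns, got {len(names)}")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed sample row ({exc})") from exc
    meta = _read_sidecar(path, required=False)
    return EcgRecord(
        signal=data.T,
        fs=float(meta.get("fs", DEFAULT_FS)),
        lead_names=names,
        labels=list(meta.get("labels", [])) or [UNKNOWN_LABEL],
        record_id=str(meta.get("record_id", path.stem)),
    )


def _write_csv(record: EcgRecord, path: Path) -> None:
    header = ",".join(record.lead_names)
    np.savetxt(path, record.signal.T, delimiter=",", header=header, comments="",
               fmt="%.6f")
    _sidecar_path(path).write_text(json.dumps({
        "fs": record.fs, "labels": record.labels, "record_id": record.record_id,
    }))


def _read_cpsc(path: Path) -> EcgRecord:
    arr = np.load(path)
    if arr.ndim != 2:
        raise DimensionError(f"{path}: expected a 2-D matrix, got ndim={arr.ndim}")
    if arr.shape[0] != 12:
        if arr.shape[1] == 12:  # stored samples x leads
            arr = arr.T
        else:
            raise DimensionError(f"{path}: expected 12 channels, got {arr.shape[0]}")
    meta = _read_sidecar(path, required=True)
    if "fs" not in meta:
        raise ParseError(f"{path}: sidecar missing field 'fs'")
    return EcgRecord(
        signal=arr,
        fs=float(meta["fs"]),
        lead_names=list(meta.get("lead_names", LEAD_NAMES)),
        labels=list(meta.get("labels", [])) or [UNKNOWN_LABEL],
        record_id=str(meta.get("record_id", path.stem)),
    )


def _write_cpsc(record: EcgRecord, path: Path) -> None:
    np.save(path, record.signal)
    _sidecar_path(path).write_text(json.dumps({
        "fs": record.fs, "lead_names": record.lead_names,
        "labels": record.labels, "record_id": record.record_id,
    }))


# --- minimal WFDB (format 16) ----------------------------------------------

_WFDB_GAIN = 1000.0  # ADC units per mV


def _read_wfdb(path: Path) -> EcgRecord:
    hea = path.with_suffix(".hea")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    head = [ln for ln in lines if not ln.startswith("#")]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    try:
        fields = head[0].split()
        name, n_sig, fs = fields[0], int(fields[1]), float(fields[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{hea}: malformed record line (field: header)") from exc
    if n_sig != 12:
        raise DimensionError(f"{hea}: expected 12 signals, got {n_sig}")
    lead_names, gains, baselines, dat_file = [], [], [], None
    for ln in head[1:1 + n_sig]:
        parts = ln.split()
        try:
            dat_file = parts[0]
            if parts[1] not in ("16", "16+0"):
                raise ParseError(f"{hea}: unsupported sample format {parts[1]!r}")
            gain_spec = parts[2]
            gain_str = gain_spec.split("/")[0]
            if "(" in gain_str:
                g, b = gain_str.split("(")
                gains.append(float(g))
                baselines.append(float(b.rstrip(")")))
            else:
                gains.append(float(gain_str))
                baselines.append(0.0)
            lead_names.append(parts[-1])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{hea}: malformed signal line {ln!r}") from exc
    raw = np.fromfile(path.parent / dat_file, dtype="<i2")
    if raw.size % n_sig:
        raise ParseError(f"{dat_file}: sample count not divisible by {n_sig}")
    adc = raw.reshape(-1, n_sig).T.astype(float)
    signal = (adc - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    labels = []
    for c in comments:
        if c.lower().startswith("dx:"):
            labels = [s.strip() for s in c[3:].split(",") if s.strip()]
    return EcgRecord(signal=signal, fs=fs, lead_names=lead_names,
                     labels=labels or [UNKNOWN_LABEL], record_id=name)


def _write_wfdb(record: EcgRecord, path: Path) -> None:
    stem = path.with_suffix("")
    dat_name = stem.name + ".dat"
    adc = np.round(record.signal * _WFDB_GAIN).astype("<i2")
    adc.T.reshape(-1).tofile(stem.with_suffix(".dat"))
    lines = [f"{stem.name} 12 {record.fs:g} {record.n_samples}"]
    for lead in record.lead_names:
        lines.append(f"{dat_name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 0 0 0 {lead}")
    lines.append("#Dx: " + ",".join(record.labels))
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature tensors (HDF5)


def write_feature_tensor(maps, labels, path: str | Path) -> None:
    """Write a stack of 120x120 feature maps plus integer labels to HDF5.

    ``maps`` may be :class:`~ecgtfmap.features.TimeFrequencyMap` objects or
    raw 120x120 arrays; ``labels`` are class names from :data:`CLASSES`.
    """
    if len(maps) == 0:
        raise ValueError("nothing to write: empty map list")
    if len(maps) != len(labels):
        raise ValueError(f"{len(maps)} maps but {len(labels)} labels")
    arrays = [np.asarray(getattr(m, "values", m)) for m in maps]
    for a in arrays:
        if a.shape != (120, 120):
            raise DimensionError(f"expected 120x120 maps, got {a.shape}")
    y = np.array([CLASSES.index(lab) for lab in labels], dtype=np.int64)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("maps", data=np.stack(arrays))
        fh.create_dataset("labels", data=y)
        fh.attrs["class_names"] = CLASSES


def read_feature_tensor(path: str | Path):
    """Inverse of :func:`write_feature_tensor` → (maps array, label names)."""
    with h5py.File(path, "r") as fh:
        maps = fh["maps"][()]
        y = fh["labels"][()]
        class_names = [str(c) for c in fh.attrs["class_names"]]
    return maps, [class_names[i] for i in y]
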