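"""Reading and writing intrapartum cardiotocography (CTG) records.

A CTG record pairs a fetal heart rate (FHR) trace in beats per minute with a
uterine contraction (UC) trace in arbitrary units, both sampled at 4 Hz in the
CTU-UHB database layout. Two on-disk dialects are supported:

* ``wfdb`` -- the PhysioNet WFDB header/signal pair used by the CTU-UHB
  accession (two format-16 channels, pH carried in ``#`` header comments).
* ``csv``  -- a plain-text dialect ``time_s,fhr_bpm,uc_au`` with one row per
  4 Hz sample, plus an optional ``meta.csv`` sidecar (``record_id,ph``).

Missing FHR samples are zero-coded on read; downstream signal-loss handling
relies on that convention.
"""

from __future__ import annotations

import csv
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CTGRecord",
    "Label",
    "FormatError",
    "read_record",
    "write_record",
    "assign_label",
    "load_cohort",
    "read_meta_sidecar",
    "write_meta_sidecar",
]

COMPROMISE_PH = 7.05
INTERMEDIATE_UPPER_PH = 7.15


class FormatError(ValueError):
    """Raised when an on-disk record violates the expected layout."""


class Label(enum.Enum):
    """Outcome class from umbilical-artery pH.

    ``INTERMEDIATE`` is a sub-category of the normal class: for binary
    scoring only ``COMPROMISED`` counts as positive.
    """

    NORMAL = "normal"
    INTERMEDIATE = "intermediate"
    COMPROMISED = "compromised"

    @property
    def is_compromised(self) -> bool:
        return self is Label.COMPROMISED


@dataclass
class CTGRecord:
    """Raw paired FHR/UC series at a common sample rate plus metadata."""

    record_id: str
    fhr_raw: np.ndarray
    uc_raw: np.ndarray
    sample_rate: float = 4.0
    ph: float | None = None
    extra_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fhr_raw = np.asarray(self.fhr_raw, dtype=float)
        self.uc_raw = np.asarray(self.uc_raw, dtype=float)
        if self.fhr_raw.shape != self.uc_raw.shape:
            raise FormatError(
                f"record {self.record_id!r}: FHR length {self.fhr_raw.size} "
                f"!= UC length {self.uc_raw.size}"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.ph is not None:
            if not math.isfinite(self.ph):
                raise ValueError("pH must be finite")
            if not (6.5 < self.ph < 7.6):
                raise ValueError(f"pH {self.ph} outside plausible range (6.5, 7.6)")

    @property
    def duration_min(self) -> float:
        return self.fhr_raw.size / self.sample_rate / 60.0

    @property
    def label(self) -> Label | None:
        return None if self.ph is None else assign_label(self.ph)


def assign_label(
    ph: float,
    compromise_threshold: float = COMPROMISE_PH,
    intermediate_upper: float = INTERMEDIATE_UPPER_PH,
) -> Label:
    """Classify a record by umbilical-artery pH.

    pH < 7.05 is compromised; 7.05 <= pH < 7.15 is the intermediate
    sub-category of normal; pH >= 7.15 is plain normal. Comparisons are
    strict at both cut points.
    """
    if not math.isfinite(ph):
        raise ValueError(f"pH must be finite, got {ph}")
    if ph < compromise_threshold:
        return Label.COMPROMISED
    if ph < intermediate_upper:
        return Label.INTERMEDIATE
    return Label.NORMAL


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_CSV_HEADER = ["time_s", "fhr_bpm", "uc_au"]


def _read_csv(path: Path) -> CTGRecord:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _CSV_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(_CSV_HEADER)}, got {','.join(header)}"
            )
        t, fhr, uc = [], [], []
        for row in reader:
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}: malformed row {row!r}")
            t.append(float(row[0]))
            fhr.append(float(row[1]))
            uc.append(float(row[2]))
    if len(t) >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], atol=1e-6):
            raise FormatError(f"{path}: non-uniform time column")
        rate = 1.0 / dt[0]
    else:
        rate = 4.0
    return CTGRecord(
        record_id=path.stem,
        fhr_raw=np.array(fhr),
        uc_raw=np.array(uc),
        sample_rate=round(rate, 6),
    )


def _write_csv(record: CTGRecord, path: Path) -> None:
    dt = 1.0 / record.sample_rate
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for i, (f, u) in enumerate(zip(record.fhr_raw, record.uc_raw)):
            writer.writerow([repr(i * dt), repr(float(f)), repr(float(u))])


# ---------------------------------------------------------------------------
# WFDB dialect (CTU-UHB layout: two format-16 channels, FHR then UC)
# ---------------------------------------------------------------------------

_HEA_RECORD_RE = re.compile(r"^(\S+)\s+(\d+)\s+([\d.]+)(?:/\S+)?\s+(\d+)")


def _read_wfdb(path: Path) -> CTGRecord:
    """Read a WFDB header/signal pair (format 16, single .dat file).

    Covers the subset of the WFDB spec the CTU-UHB accession uses: an ASCII
    ``.hea`` header whose first line gives record name, channel count,
    sampling frequency and sample count, one line per channel with
    ``file format gain(baseline)/units ...``, and 16-bit little-endian
    interleaved samples in the ``.dat`` file. Physical values are recovered
    as ``(raw - baseline) / gain``. ``#`` comment lines of the form
    ``#key value`` (e.g. ``#pH 7.12``) become metadata.
    """
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    m = _HEA_RECORD_RE.match(lines[0])
    if m is None:
        raise FormatError(f"{hea}: unparseable record line {lines[0]!r}")
    name, n_sig, fs, n_samp = m.group(1), int(m.group(2)), float(m.group(3)), int(m.group(4))
    if n_sig != 2:
        raise FormatError(f"{hea}: expected 2 channels (FHR, UC), got {n_sig}")

    sig_lines = [ln for ln in lines[1:] if not ln.startswith("#")][:n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError(f"{hea}: missing signal specification lines")
    gains, baselines, dat_names = [], [], []
    for ln in sig_lines:
        parts = ln.split()
        dat_names.append(parts[0])
        if parts[1] not in ("16", "16+0"):
            raise FormatError(f"{hea}: unsupported signal format {parts[1]!r}")
        gm = re.match(r"([-\d.]+)(?:\(([-\d]+)\))?(?:/\S+)?", parts[2])
        if gm is None:
            raise FormatError(f"{hea}: unparseable gain field {parts[2]!r}")
        gains.append(float(gm.group(1)) or 200.0)  # WFDB default gain when 0
        baselines.append(int(gm.group(2)) if gm.group(2) else 0)
    if len(set(dat_names)) != 1:
        raise FormatError(f"{hea}: multi-file records not supported")

    dat = hea.with_name(dat_names[0])
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < n_samp * n_sig:
        raise FormatError(
            f"{dat}: expected {n_samp * n_sig} samples, found {raw.size}"
        )
    raw = raw[: n_samp * n_sig].reshape(n_samp, n_sig).astype(float)
    phys = (raw - np.array(baselines)) / np.array(gains)

    meta: dict[str, str] = {}
    ph: float | None = None
    for ln in lines[1:]:
        if ln.startswith("#"):
            fields = ln[1:].strip().split(None, 1)
            if len(fields) == 2:
                key, val = fields
                meta[key] = val
                if key.lower() == "ph":
                    try:
                        ph = float(val)
                    except ValueError:
                        pass
    return CTGRecord(
        record_id=name,
        fhr_raw=phys[:, 0],
        uc_raw=phys[:, 1],
        sample_rate=fs,
        ph=ph,
        extra_meta=meta,
    )


def _write_wfdb(record: CTGRecord, path: Path, gain: float = 4.0) -> None:
    # Used by the synthetic generator and tests to materialise cohorts in the
    # same layout as the public accession; quantises to 1/gain units.
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    dat = hea.with_suffix(".dat")
    n = record.fhr_raw.size
    sig = np.column_stack(
        [np.rint(record.fhr_raw * gain), np.rint(record.uc_raw * gain)]
    ).astype("<i2")
    sig.tofile(dat)
    lines = [
        f"{hea.stem} 2 {record.sample_rate:g} {n}",
        f"{dat.name} 16 {gain:g}(0)/bpm 16 0 0 0 0 FHR",
        f"{dat.name} 16 {gain:g}(0)/au 16 0 0 0 0 UC",
    ]
    if record.ph is not None:
        lines.append(f"#pH {record.ph:.3f}")
    for key, val in record.extra_meta.items():
        if key.lower() != "ph":
            lines.append(f"#{key} {val}")
    hea.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def read_record(path: str | Path, dialect: str = "csv") -> CTGRecord:
    """Read one CTG record from ``path`` in the given dialect."""
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'wfdb')")


def write_record(record: CTGRecord, path: str | Path, dialect: str = "csv") -> None:
    """Write ``record`` to ``path``; ``csv`` is the supported output dialect."""
    path = Path(path)
    if dialect == "csv":
        _write_csv(record, path)
    elif dialect == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_meta_sidecar(path: str | Path) -> dict[str, float | None]:
    """Read ``meta.csv`` (columns ``record_id,ph``; empty pH allowed)."""
    out: dict[str, float | None] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "record_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing record_id column")
        for row in reader:
            raw = (row.get("ph") or "").strip()
            out[row["record_id"]] = float(raw) if raw else None
    return out


def write_meta_sidecar(records: Iterable[CTGRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "ph"])
        for rec in records:
            writer.writerow([rec.record_id, "" if rec.ph is None else repr(rec.ph)])


def load_cohort(directory: str | Path, dialect: str = "csv") -> list[CTGRecord]:
    """Load every record in a directory, attaching pH from ``meta.csv`` if present.

    For the csv dialect each ``*.csv`` file except ``meta.csv`` is one record;
    for wfdb each ``*.hea``/``*.dat`` pair is one record. Records are returned
    sorted by record_id.
    """
    directory = Path(directory)
    meta: Mapping[str, float | None] = {}
    meta_path = directory / "meta.csv"
    if meta_path.exists():
        meta = read_meta_sidecar(meta_path)
    if dialect == "csv":
        paths = sorted(p for p in directory.glob("*.csv") if p.name != "meta.csv")
    elif dialect == "wfdb":
        paths = sorted(directory.glob("*.hea"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    for p in paths:
        rec = read_record(p, dialect=dialect)
        if rec.ph is None and rec.record_id in meta:
            rec.ph = meta[rec.record_id]
            rec.__post_init__()
        records.append(rec)
    return records
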