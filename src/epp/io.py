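"""Event-table input: FCS and delimited files, censoring, dimension metadata.

Events are assumed already compensated/unmixed and pre-gated to live single
cells.  After the per-dimension transform, any event with a value outside
the closed interval [0, 1] in any declared dimension — or any non-finite
value — is censored (dropped and counted), so downstream stages never
bounds-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .transforms import TransformSpec, apply_transform

__all__ = ["DimensionConfig", "EventMatrix", "read_events", "write_fcs"]


@dataclass(frozen=True)
class DimensionConfig:
    name: str
    phenotyping: bool = True
    transform: TransformSpec = field(default_factory=TransformSpec)


@dataclass
class EventMatrix:
    """Unit-scaled events x dimensions table with dimension metadata."""

    values: np.ndarray                # (n_events, n_dims), all in [0, 1]
    dim_names: list
    phenotyping_flags: np.ndarray     # bool per dimension
    n_censored: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.phenotyping_flags = np.asarray(self.phenotyping_flags, dtype=bool)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be 2-D (events x dimensions)")
        if self.values.shape[1] != len(self.dim_names):
            raise ConfigurationError("dim_names length mismatch")
        if self.phenotyping_flags.size != len(self.dim_names):
            raise ConfigurationError("phenotyping_flags length mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ConfigurationError("EventMatrix values must lie in [0, 1]")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def phenotyping_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phenotyping_flags)

    def subset(self, rows: np.ndarray) -> "EventMatrix":
        return EventMatrix(self.values[rows], self.dim_names,
                           self.phenotyping_flags, 0, self.provenance)


def _censor(values: np.ndarray) -> tuple[np.ndarray, int]:
    finite = np.isfinite(values).all(axis=1)
    safe = np.where(np.isfinite(values), values, -1.0)
    inside = finite & (safe >= 0.0).all(axis=1) & (safe <= 1.0).all(axis=1)
    return values[inside], int(values.shape[0] - inside.sum())


def read_events(path, format: str | None = None,
                dim_config: list[DimensionConfig] | None = None) -> EventMatrix:
    """Read an FCS or delimited event file, transform and censor.

    ``dim_config`` declares which columns are used, whether each is a
    phenotyping dimension, and its transform.  With ``format=None`` the
    format is inferred from the extension (.fcs vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if format == "fcs":
        raw, names = _read_fcs(path)
        frame = pd.DataFrame(raw, columns=names)
    elif format == "delimited":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        frame = pd.read_csv(path, sep=sep)
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    if dim_config is None:
        dim_config = [DimensionConfig(c, True, TransformSpec(kind="none"))
                      for c in frame.columns]
    missing = [d.name for d in dim_config if d.name not in frame.columns]
    if missing:
        raise ConfigurationError(f"dimensions not present in file: {missing}")

    cols = []
    for d in dim_config:
        cols.append(apply_transform(frame[d.name].to_numpy(dtype=float),
                                    d.transform))
    values = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    values, n_censored = _censor(values)
    return EventMatrix(
        values=values,
        dim_names=[d.name for d in dim_config],
        phenotyping_flags=np.array([d.phenotyping for d in dim_config]),
        n_censored=n_censored,
        provenance={"path": str(path), "format": format,
                    "transforms": [d.transform.kind for d in dim_config]},
    )


# --- minimal FCS 3.0/3.1 support (float data) -------------------------------
# Covers list-mode files with $DATATYPE F or D, the overwhelmingly common
# layout for post-acquisition analysis exports.

def _read_fcs(path: Path) -> tuple[np.ndarray, list]:
    with open(path, "rb") as fh:
        header = fh.read(58)
        version = header[:6].decode("ascii", "replace")
        if not version.startswith("FCS3"):
            raise IOError(f"unsupported FCS version {version!r}")
        t0, t1 = int(header[10:18]), int(header[18:26])
        fh.seek(t0)
        text = fh.read(t1 - t0 + 1).decode("latin-1")
        delim = text[0]
        parts = text[1:].split(delim)
        kw = {parts[i].strip().upper(): parts[i + 1]
              for i in range(0, len(parts) - 1, 2)}
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        dtype_code = kw["$DATATYPE"].strip().upper()
        if dtype_code not in ("F", "D"):
            raise IOError(f"unsupported $DATATYPE {dtype_code!r}")
        byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
        little = byteord.startswith("1")
        base = "<" if little else ">"
        dt = np.dtype(base + ("f4" if dtype_code == "F" else "f8"))
        names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
        d0 = int(kw.get("$BEGINDATA", "0") or 0)
        d1 = int(kw.get("$ENDDATA", "0") or 0)
        if d0 == 0:
            d0, d1 = int(header[26:34]), int(header[34:42])
        fh.seek(d0)
        buf = fh.read(d1 - d0 + 1)
        data = np.frombuffer(buf[: n_tot * n_par * dt.itemsize], dtype=dt)
        return data.reshape(n_tot, n_par).astype(float), names


def write_fcs(path, values: np.ndarray, names: list) -> None:
    """Write a minimal FCS 3.1 float list-mode file (used for fixtures)."""
    values = np.asarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    data = values.tobytes()
    kw = {"$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
          "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0"}
    for i, name in enumerate(names, 1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    # two-pass assembly so BEGIN/ENDDATA are self-consistent
    for _ in range(3):
        text = "/" + "/".join(f"{k}/{v}" for k, v in kw.items()) + "/"
        t0 = 58
        t1 = t0 + len(text) - 1
        d0 = t1 + 1
        d1 = d0 + len(data) - 1
        kw["$BEGINDATA"], kw["$ENDDATA"] = str(d0), str(d1)
    header = f"FCS3.1    {t0:8d}{t1:8d}{d0:8d}{d1:8d}{0:8d}{0:8d}"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("latin-1"))
        fh.write(data)
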