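"""Event-level cytometry I/O: FCS 3.0/3.1 reading, FCS 3.1 writing, CSV export.

The central container is :class:`EventMatrix`, an events x channels matrix of
fluorescence (or scatter) values with per-channel metadata.  Values are stored
exactly as read -- no transform is ever applied on ingestion.  Derived
parameters (for example 2-D embedding coordinates) can be appended as new
``derived`` channels and written back to an FCS 3.1 file, so that downstream
viewers see them as ordinary parameters.

FCS files are written as version 3.1, list mode, 32-bit float (``$DATATYPE F``),
little endian -- the convention of modern spectral instruments.  ``$PnN`` holds
the detector/fluorophore token and ``$PnS`` the marker token (e.g. ``CD3``), so
gating configurations can refer to markers independently of the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_KINDS",
    "ChannelMetadata",
    "EventMatrix",
    "FcsFormatError",
    "read_fcs",
    "write_fcs",
    "export_csv",
    "import_csv",
    "append_parameters",
]

#: Valid per-channel tags.
CHANNEL_KINDS = ("detector", "marker", "scatter", "viability", "derived")

#: Laser lines of the four-laser instrument model (nm).
LASER_LINES = (405, 488, 561, 640)


class FcsFormatError(ValueError):
    """Raised for malformed, truncated, or unsupported FCS content."""


@dataclass(frozen=True)
class ChannelMetadata:
    """Static description of one acquisition channel.

    ``detector_index`` is present iff the channel is a raw spectral detector;
    ``laser`` is one of the instrument's excitation lines when known.
    """

    name: str
    detector_index: Optional[int] = None
    laser: Optional[int] = None
    display_transform: str = "linear"

    def __post_init__(self) -> None:
        if self.laser is not None and self.laser not in LASER_LINES:
            raise ValueError(f"unknown laser line {self.laser}; expected one of {LASER_LINES}")


@dataclass
class EventMatrix:
    """Events x channels measurement matrix with channel metadata.

    Parameters
    ----------
    values
        2-D float array, one row per event, one column per channel.
    channel_names
        Unique channel identifiers, one per column.
    channel_kinds
        Per-channel tag from :data:`CHANNEL_KINDS`.
    sample_id, batch_id
        Sample bookkeeping; ``batch_id`` may be absent.
    truth_labels
        Optional per-event ground-truth population label (simulated data).
    """

    values: np.ndarray
    channel_names: list[str]
    channel_kinds: list[str]
    sample_id: str = "sample"
    batch_id: Optional[str] = None
    truth_labels: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels array")
        self.channel_names = list(self.channel_names)
        self.channel_kinds = list(self.channel_kinds)
        n_ch = self.values.shape[1]
        if len(self.channel_names) != n_ch or len(self.channel_kinds) != n_ch:
            raise ValueError(
                f"channel metadata length mismatch: {n_ch} columns, "
                f"{len(self.channel_names)} names, {len(self.channel_kinds)} kinds"
            )
        if len(set(self.channel_names)) != n_ch:
            dupes = {c for c in self.channel_names if self.channel_names.count(c) > 1}
            raise ValueError(f"duplicate channel names: {sorted(dupes)}")
        bad = [k for k in self.channel_kinds if k not in CHANNEL_KINDS]
        if bad:
            raise ValueError(f"unknown channel kinds {sorted(set(bad))}; expected {CHANNEL_KINDS}")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=object)
            if self.truth_labels.shape[0] != self.values.shape[0]:
                raise ValueError("truth_labels must have exactly one entry per event")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def index_of(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not present; have {self.channel_names}") from None

    def channel(self, name: str) -> np.ndarray:
        """Column vector for one channel."""
        return self.values[:, self.index_of(name)]

    def channels_of_kind(self, kind: str) -> list[str]:
        return [n for n, k in zip(self.channel_names, self.channel_kinds) if k == kind]

    def select_channels(self, names: Sequence[str]) -> "EventMatrix":
        idx = [self.index_of(n) for n in names]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            channel_names=[self.channel_names[i] for i in idx],
            channel_kinds=[self.channel_kinds[i] for i in idx],
        )

    def select_events(self, mask: np.ndarray) -> "EventMatrix":
        mask = np.asarray(mask)
        truth = self.truth_labels[mask] if self.truth_labels is not None else None
        return replace(self, values=self.values[mask].copy(), truth_labels=truth)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are rare; handle by split/rejoin of empties.
    parts = body.split(delim)
    # Re-join empty tokens produced by doubled delimiters.
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok += delim.decode("latin-1") + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2 == 1:
        tokens = tokens[:-1]
    keys = [t.decode("latin-1") if isinstance(t, bytes) else t for t in tokens[0::2]]
    vals = [t.decode("latin-1") if isinstance(t, bytes) else t for t in tokens[1::2]]
    return {k.strip().upper(): v for k, v in zip(keys, vals)}


def _infer_kind(name: str, marker: str) -> str:
    upper = name.upper()
    if upper.startswith(("FSC", "SSC")) or upper == "TIME":
        return "scatter"
    if "VIA" in upper or "VIA" in marker.upper():
        return "viability"
    if upper.startswith(("UMAP", "PC", "TSNE")):
        return "derived"
    return "marker"


def read_fcs(path: str | Path) -> EventMatrix:
    """Read an FCS 3.0 / 3.1 file into an :class:`EventMatrix`.

    Channel names are taken from ``$PnN`` with ``$PnS`` (marker token)
    preferred when present; raw values are returned unmodified.  Nonstandard
    ``CSKINDn`` keywords written by :func:`write_fcs` restore channel kinds
    exactly; otherwise kinds are inferred from the names.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FcsFormatError(f"{path}: file too short for an FCS header")
    version = blob[0:6].decode("latin-1")
    if version not in _SUPPORTED_VERSIONS:
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        txt = blob[lo:hi].decode("latin-1").strip()
        if not txt:
            return 0
        try:
            return int(txt)
        except ValueError:
            raise FcsFormatError(f"{path}: malformed header offset {txt!r}") from None

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    if text_beg <= 0 or text_end <= text_beg:
        raise FcsFormatError(f"{path}: malformed TEXT segment offsets")
    keywords = _parse_text_segment(blob[text_beg : text_end + 1])

    if data_beg == 0 and "$BEGINDATA" in keywords:
        data_beg = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])

    n_par = int(keywords.get("$PAR", 0))
    n_tot = int(keywords.get("$TOT", 0))
    datatype = keywords.get("$DATATYPE", "F").upper()
    mode = keywords.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list-mode ($MODE L) files are supported, got {mode}")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) > 1:
            raise FcsFormatError(f"{path}: mixed-width integer data not supported")
        width = bits.pop() // 8
        dtype = np.dtype(f"{order}u{width}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    data = blob[data_beg : data_end + 1][:expected] if n_tot else b""
    if len(data) < expected:
        raise FcsFormatError(
            f"{path}: truncated data segment (expected {expected} bytes, got {len(data)})"
        )
    if n_tot:
        values = np.frombuffer(data, dtype=dtype).reshape(n_tot, n_par).astype(float)
    else:
        values = np.empty((0, n_par), dtype=float)

    names, kinds = [], []
    for i in range(1, n_par + 1):
        pnn = keywords.get(f"$P{i}N", f"P{i}")
        pns = keywords.get(f"$P{i}S", "")
        name = pns or pnn
        names.append(name)
        kinds.append(keywords.get(f"CSKIND{i}", _infer_kind(pnn, pns)))

    return EventMatrix(
        values=values,
        channel_names=names,
        channel_kinds=kinds,
        sample_id=keywords.get("CSSAMPLEID", path.stem),
        batch_id=keywords.get("CSBATCHID") or None,
        metadata={"fcs_version": version, "keywords": keywords},
    )


# ---------------------------------------------------------------------------
# FCS writing
# ---------------------------------------------------------------------------


def write_fcs(events: EventMatrix, path: str | Path) -> Path:
    """Write ``events`` to ``path`` as FCS 3.1, float list mode.

    Raises ``ValueError`` naming the offending channel if any value is
    non-finite.  Channel order is preserved exactly.
    """
    path = Path(path)
    finite = np.isfinite(events.values)
    if not finite.all():
        bad_cols = np.flatnonzero(~finite.all(axis=0))
        bad = [events.channel_names[i] for i in bad_cols]
        raise ValueError(f"non-finite values in channel(s) {bad}; cannot write FCS")

    n_tot, n_par = events.values.shape
    data = events.values.astype("<f4").tobytes()

    delim = "/"
    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("CSSAMPLEID", events.sample_id or "sample"),
    ]
    if events.batch_id:
        kw.append(("CSBATCHID", events.batch_id))
    for i, (name, kind) in enumerate(zip(events.channel_names, events.channel_kinds), start=1):
        col = events.values[:, i - 1]
        rng = float(np.max(col)) if n_tot else 0.0
        kw += [
            (f"$P{i}N", name),
            (f"$P{i}S", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(rng, 1)) + 1)),
            (f"CSKIND{i}", kind),
        ]

    # Two-pass offset computation: data offsets depend on TEXT length, which
    # depends on the offset digits themselves.
    def render(text_beg: int) -> tuple[bytes, int, int]:
        body = "".join(f"{delim}{k}{delim}{v}" for k, v in kw_full) + delim
        text = body.encode("latin-1")
        data_beg = text_beg + len(text)
        return text, data_beg, data_beg + max(len(data) - 1, 0)

    text_beg = 58
    data_beg = data_end = 0
    for _ in range(4):
        kw_full = kw + [("$BEGINDATA", str(data_beg)), ("$ENDDATA", str(data_end))]
        text, new_beg, new_end = render(text_beg)
        if (new_beg, new_end) == (data_beg, data_end):
            break
        data_beg, data_end = new_beg, new_end
    kw_full = kw + [("$BEGINDATA", str(data_beg)), ("$ENDDATA", str(data_end))]
    text, data_beg, data_end = render(text_beg)
    text_end = text_beg + len(text) - 1

    def fmt(n: int) -> bytes:
        s = str(n) if n <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_beg) + fmt(text_end) + fmt(data_beg) + fmt(data_end)
    header += fmt(0) + fmt(0)  # no ANALYSIS segment
    path.write_bytes(header + text + data)
    return path


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def export_csv(events: EventMatrix, path: str | Path) -> Path:
    """Export events as CSV: header of channel names, one row per event.

    Values are written in full float precision so a re-import reproduces the
    matrix; names containing commas are quoted per the CSV dialect.
    """
    path = Path(path)
    events.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def import_csv(
    path: str | Path,
    channel_kinds: Optional[Sequence[str]] = None,
    sample_id: Optional[str] = None,
) -> EventMatrix:
    """Read a CSV event export (one row per cell, one column per channel)."""
    path = Path(path)
    df = pd.read_csv(path)
    names = [str(c) for c in df.columns]
    kinds = list(channel_kinds) if channel_kinds else [_infer_kind(n, n) for n in names]
    return EventMatrix(
        values=df.to_numpy(dtype=float),
        channel_names=names,
        channel_kinds=kinds,
        sample_id=sample_id or path.stem,
    )


def append_parameters(
    events: EventMatrix, new_values: np.ndarray, names: Sequence[str]
) -> EventMatrix:
    """Widen ``events`` with derived channels (e.g. UMAP coordinates).

    The new columns are tagged ``derived``.  Row counts must match and names
    must not collide with existing channels.
    """
    new_values = np.atleast_2d(np.asarray(new_values, dtype=float))
    if new_values.shape[0] != events.n_events:
        raise ValueError(
            f"row mismatch: {events.n_events} events but {new_values.shape[0]} new rows"
        )
    names = list(names)
    if new_values.shape[1] != len(names):
        raise ValueError("one name required per new column")
    clash = set(names) & set(events.channel_names)
    if clash:
        raise ValueError(f"channel name(s) already present: {sorted(clash)}")
    return replace(
        events,
        values=np.hstack([events.values, new_values]),
        channel_names=events.channel_names + names,
        channel_kinds=events.channel_kinds + ["derived"] * len(names),
    )
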