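"""Reading SEEG recordings and assembling shank-ordered contact chains.

The ingestion contract is an EDF/EDF+ file plus a delimited channel-metadata
table with columns::

    channel  shank  contact_index  in_brain  excluded  label

``channel`` must match an EDF channel name; ``contact_index`` counts from 0
at the deepest contact (the shank tip) and increases toward the periphery —
this orientation is fixed package-wide.  ``in_brain`` and ``excluded`` are
0/1 flags; ``label`` is the optional clinician ground truth, ``-1``/``gray``
for gray matter, ``1``/``white`` for white matter, empty when unknown.

Bipolar referencing subtracts, for every usable contact, the signal of the
adjacent usable contact closer to the tip; the deepest usable contact
instead has its peripheral neighbour subtracted so that every contact gets
a trace.  Excluded (noisy) channels are skipped when choosing the
reference partner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SAMPLING_RATE_HZ = 1000.0  # inclusion criterion; lower rates only warn

METADATA_COLUMNS = ["channel", "shank", "contact_index",
                    "in_brain", "excluded", "label"]


class MetadataError(ValueError):
    """Inconsistent or duplicate channel-metadata rows."""


class DegenerateShankError(ValueError):
    """Shank has too few usable contacts for bipolar referencing."""


@dataclass
class RecordingSet:
    """Multi-channel recording with one shared sampling rate.

    ``data`` is (n_channels, n_samples) in microvolts.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows and channel names differ in length")
        if self.sfreq < MIN_SAMPLING_RATE_HZ:
            warnings.warn(
                f"sampling rate {self.sfreq:g} Hz is below the "
                f"{MIN_SAMPLING_RATE_HZ:g} Hz inclusion criterion",
                stacklevel=2)

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


@dataclass
class ShankLayout:
    """Ordered chain of contacts on one electrode shank.

    ``contacts`` runs from the tip (index 0, deepest) toward the periphery.
    ``labels`` uses -1 = gray, +1 = white, NaN = unlabeled.  ``gaps_mm``
    optionally gives the N-1 physical gaps between consecutive contacts
    (tip to periphery) for irregularly spaced electrodes; otherwise the
    uniform ``spacing_mm`` applies.
    """

    shank: str
    contacts: list[str]
    in_brain: np.ndarray
    excluded: np.ndarray
    spacing_mm: float = 5.0
    gaps_mm: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.contacts)
        self.in_brain = np.asarray(self.in_brain, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.in_brain.shape != (n,) or self.excluded.shape != (n,):
            raise ValueError("flag arrays must match contact count")
        if self.gaps_mm is not None:
            self.gaps_mm = np.asarray(self.gaps_mm, dtype=float)
            if self.gaps_mm.shape != (max(n - 1, 0),):
                raise ValueError("gaps_mm must have length N-1")
            if np.any(self.gaps_mm <= 0):
                raise ValueError("gaps must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape != (n,):
                raise ValueError("labels must match contact count")
            known = self.labels[~np.isnan(self.labels)]
            if not np.all(np.isin(known, (-1.0, 1.0))):
                raise ValueError("labels must be -1 (gray) or +1 (white)")

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def usable(self) -> np.ndarray:
        """Contacts that enter the classifier: in brain and not excluded."""
        return self.in_brain & ~self.excluded


def read_metadata(path_or_frame) -> pd.DataFrame:
    """Read and validate a channel-metadata table (TSV/CSV or DataFrame)."""
    if isinstance(path_or_frame, pd.DataFrame):
        meta = path_or_frame.copy()
    else:
        sep = "," if str(path_or_frame).endswith(".csv") else "\t"
        meta = pd.read_csv(path_or_frame, sep=sep)
    missing = set(METADATA_COLUMNS[:-1]) - set(meta.columns)
    if missing:
        raise MetadataError(f"metadata table lacks columns: {sorted(missing)}")
    if "label" not in meta.columns:
        meta["label"] = np.nan
    meta["label"] = meta["label"].map(_parse_label)
    dup = meta.duplicated(subset=["shank", "contact_index"])
    if dup.any():
        rows = meta.loc[dup, ["shank", "contact_index"]].to_records(index=False)
        raise MetadataError(f"duplicate (shank, contact_index): {list(rows)}")
    if meta["channel"].duplicated().any():
        raise MetadataError("duplicate channel names in metadata")
    return meta


def _parse_label(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip().lower()
    if text in ("", "nan", "none"):
        return np.nan
    if text in ("-1", "-1.0", "gray", "grey", "gm"):
        return -1.0
    if text in ("1", "+1", "1.0", "white", "wm"):
        return 1.0
    raise MetadataError(f"unparseable label {value!r}")


def layouts_from_metadata(meta: pd.DataFrame,
                          spacing_mm: float = 5.0) -> list[ShankLayout]:
    """Group metadata rows into tip-to-periphery ordered shank layouts."""
    layouts = []
    for shank, grp in meta.groupby("shank", sort=True):
        grp = grp.sort_values("contact_index")
        idx = grp["contact_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise MetadataError(f"contact order on shank {shank} not monotone")
        layouts.append(ShankLayout(
            shank=str(shank),
            contacts=list(grp["channel"]),
            in_brain=grp["in_brain"].to_numpy().astype(bool),
            excluded=grp["excluded"].to_numpy().astype(bool),
            spacing_mm=spacing_mm,
            labels=grp["label"].to_numpy(dtype=float),
        ))
    return layouts


def load_edf(path, metadata,
             spacing_mm: float = 5.0) -> tuple[RecordingSet, list[ShankLayout]]:
    """Load an EDF recording together with its shank layouts.

    Channels listed in the metadata but absent from the file are reported
    via a logged warning and marked excluded in the layout; channels in the
    file but not in the metadata (scalp EEG, EKG, ...) are dropped.
    """
    import mne

    meta = read_metadata(metadata)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # mne raises various types on malformed files
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    present = set(raw.ch_names)
    absent = [c for c in meta["channel"] if c not in present]
    if absent:
        logger.warning("channels in metadata but not in EDF, marked "
                       "excluded: %s", absent)
        meta = meta.copy()
        meta.loc[meta["channel"].isin(absent), "excluded"] = 1
    keep = [c for c in meta["channel"] if c in present]
    if not keep:
        raise MetadataError("no metadata channel found in the EDF file")
    raw.pick(keep)
    data_uv = raw.get_data() * 1e6  # MNE honours header units; SI volts out
    rec = RecordingSet(data=data_uv, sfreq=float(raw.info["sfreq"]),
                       ch_names=list(raw.ch_names))
    # pad missing channels with zeros so layout indices stay aligned
    if absent:
        pad = np.zeros((len(absent), rec.data.shape[1]))
        rec = RecordingSet(data=np.vstack([rec.data, pad]),
                           sfreq=rec.sfreq,
                           ch_names=rec.ch_names + absent)
    return rec, layouts_from_metadata(meta, spacing_mm=spacing_mm)


def bipolar_reference(recording: RecordingSet,
                      layout: ShankLayout) -> tuple[list[str], np.ndarray]:
    """Bipolar-reference the usable contacts of one shank.

    Returns the usable contact names (tip to periphery) and the matching
    (n_usable, n_samples) array of difference traces.  Each contact has the
    adjacent usable contact toward the tip subtracted; the deepest usable
    contact has its peripheral usable neighbour subtracted instead.
    """
    usable_idx = np.flatnonzero(layout.usable)
    if usable_idx.size < 2:
        raise DegenerateShankError(
            f"shank {layout.shank} has {usable_idx.size} usable contact(s); "
            "bipolar referencing needs at least 2")
    names = [layout.contacts[i] for i in usable_idx]
    sig = np.stack([recording.channel(n) for n in names])
    out = np.empty_like(sig)
    out[0] = sig[0] - sig[1]          # end-contact rule at the tip
    out[1:] = sig[1:] - sig[:-1]      # neighbour toward the tip, skipping
    return names, out                 # excluded channels implicitly


# ---------------------------------------------------------------------------
# Minimal EDF writing (16-bit), used by the synthetic generator and for
# round-trip tests.  Only plain continuous EDF is produced: one data record
# per second, all channels at the recording's sampling rate, physical unit
# microvolts.
# ---------------------------------------------------------------------------

def _field(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(path, recording: RecordingSet) -> None:
    """Write a RecordingSet as a plain 16-bit EDF file (unit uV)."""
    fs = recording.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(recording.ch_names)
    n_rec = recording.data.shape[1] // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one 1 s data record")
    data = recording.data[:, :n_rec * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_max = 32767
    scale = phys_max / dig_max
    digital = np.round(data / scale[:, None]).astype("<i2")

    header = b"".join([
        _field("0", 8), _field("X X X X", 80), _field("Startdate X", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8), _field("", 44),
        _field(str(n_rec), 8), _field("1", 8), _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(n, 16) for n in recording.ch_names),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_field(str(-dig_max), 8) for _ in range(n_ch)),
        b"".join(_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def write_metadata(path, layouts: list[ShankLayout]) -> None:
    """Write the channel-metadata table for a set of layouts (TSV)."""
    rows = []
    for lay in layouts:
        for i, ch in enumerate(lay.contacts):
            lab = ""
            if lay.labels is not None and not np.isnan(lay.labels[i]):
                lab = int(lay.labels[i])
            rows.append(dict(channel=ch, shank=lay.shank, contact_index=i,
                             in_brain=int(lay.in_brain[i]),
                             excluded=int(lay.excluded[i]), label=lab))
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False)
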