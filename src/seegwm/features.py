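"""Per-contact features: relative log-power shift and contact depth.

Two numbers summarise each SEEG contact for classification:

* ``s`` — the vertical shift of the contact's bipolar log power spectrum
  relative to the patient-average spectrum, averaged over 1-150 Hz with a
  4 Hz band around 60 and 120 Hz masked out (line noise).  White-matter
  contacts sit lower (less power at all frequencies below 150 Hz).
  Patient-centering makes the mean of ``s`` across a patient's usable
  contacts exactly zero, removing across-patient gain differences.
* ``d`` — contact depth along the shank, zero at the most peripheral
  in-brain contact and increasing toward the tip, in inter-contact spacing
  units (or millimetres for irregularly spaced electrodes).

Spectra are estimated by Welch's method inside 10 equally spaced 10 s
windows and averaged across windows in the power domain before taking the
natural log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import RecordingSet, ShankLayout, bipolar_reference

logger = logging.getLogger(__name__)

# analysis band and line-noise exclusions (Hz)
BAND_HZ = (1.0, 150.0)
NOTCH_CENTERS_HZ = (60.0, 120.0)
NOTCH_HALFWIDTH_HZ = 2.0   # "4 Hz band around" = +/- 2 Hz


@dataclass
class PowerSpectrum:
    """Log-scale Welch PSD of one contact with line-noise bins masked."""

    freqs: np.ndarray
    log_psd: np.ndarray        # natural log of power spectral density
    excluded: np.ndarray       # True where the bin is inside a notch band

    def __post_init__(self) -> None:
        if not (self.freqs.shape == self.log_psd.shape == self.excluded.shape):
            raise ValueError("frequency grid and PSD shapes differ")


@dataclass
class ShankRecord:
    """Feature chain of one shank: inputs to the Bayesian model.

    Contacts are ordered tip to periphery (depth strictly decreasing).
    ``labels`` are -1 gray / +1 white, or None when unlabeled.
    """

    patient: str
    shank: str
    contacts: list[str]
    s: np.ndarray
    depth: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.s.shape != self.depth.shape:
            raise ValueError("s and depth must have equal length")
        if self.depth.size > 1 and np.any(np.diff(self.depth) >= 0):
            raise ValueError("depth must strictly decrease tip->periphery")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape != self.s.shape:
                raise ValueError("labels length mismatch")
            if not np.all(np.isin(self.labels, (-1.0, 1.0))):
                raise ValueError("labels must be -1 or +1")

    def __len__(self) -> int:
        return self.s.size

    @property
    def depth_intervals(self) -> np.ndarray:
        """(N, 2) integration limits [lo, hi] in the depth dimension.

        Midpoints between neighbouring contact positions; at shank ends the
        open side extends half the local spacing outward.
        """
        return depth_intervals(self.depth)


def depth_intervals(depth: np.ndarray,
                    default_halfwidth: float = 0.5) -> np.ndarray:
    """Likelihood integration limits around each contact position."""
    d = np.asarray(depth, dtype=float)
    n = d.size
    out = np.empty((n, 2))
    if n == 1:
        out[0] = (d[0] - default_halfwidth, d[0] + default_halfwidth)
        return out
    mid = (d[:-1] + d[1:]) / 2.0        # depth decreases with index
    hi_end = d[0] + (d[0] - d[1]) / 2.0
    lo_end = d[-1] - (d[-2] - d[-1]) / 2.0
    out[:, 1] = np.r_[hi_end, mid]      # toward the tip
    out[:, 0] = np.r_[mid, lo_end]      # toward the periphery
    return out


def welch_psd(x: np.ndarray, sfreq: float, n_windows: int = 10,
              window_length_s: float = 10.0, seg_length_s: float = 1.0,
              seg_overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD averaged over equally spaced windows, in natural log.

    ``n_windows`` windows of ``window_length_s`` seconds are placed with
    equal spacing across the recording; a recording shorter than their
    total length makes the windows overlap, with a logged warning.  Inside
    each window the PSD is a standard Welch estimate (Hann segments of
    ``seg_length_s`` seconds, fractional overlap ``seg_overlap``), and the
    window PSDs are averaged in the power domain.
    """
    x = np.asarray(x, dtype=float)
    win_len = int(round(window_length_s * sfreq))
    if x.size < win_len:
        raise ValueError("recording shorter than one analysis window")
    if n_windows == 1:
        starts = np.array([0])
    else:
        starts = np.round(
            np.linspace(0, x.size - win_len, n_windows)).astype(int)
        if x.size < n_windows * win_len:
            warnings.warn(
                "recording shorter than the requested windows; placing "
                f"{n_windows} overlapping windows with maximal spacing",
                stacklevel=2)
    nperseg = int(round(seg_length_s * sfreq))
    noverlap = int(round(seg_overlap * nperseg))
    psds = []
    for s0 in starts:
        f, pxx = sps.welch(x[s0:s0 + win_len], fs=sfreq, window="hann",
                           nperseg=nperseg, noverlap=noverlap)
        psds.append(pxx)
    mean_psd = np.mean(psds, axis=0)
    with np.errstate(divide="ignore"):
        log_psd = np.log(mean_psd)
    excluded = np.zeros_like(f, dtype=bool)
    for c in NOTCH_CENTERS_HZ:
        excluded |= np.abs(f - c) <= NOTCH_HALFWIDTH_HZ
    return PowerSpectrum(freqs=f, log_psd=log_psd, excluded=excluded)


def relative_power_shift(spectra: list[PowerSpectrum],
                         band_hz: tuple[float, float] = BAND_HZ,
                         average: str = "log") -> np.ndarray:
    """Per-contact mean log-power shift relative to the patient average.

    ``average`` selects how the patient-reference spectrum is formed:
    ``"log"`` (default) averages the log-PSDs across contacts (geometric
    mean spectrum); ``"power"`` averages in the power domain first.  Either
    way the returned shifts are re-centered so their mean over the
    patient's contacts is exactly zero.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 usable contacts per patient")
    f = spectra[0].freqs
    for ps in spectra[1:]:
        if not np.array_equal(ps.freqs, f):
            raise ValueError("spectra must share one frequency grid")
    keep = (f >= band_hz[0]) & (f <= band_hz[1]) & ~spectra[0].excluded
    if not keep.any():
        raise ValueError("no unmasked frequency bins in the analysis band")
    logp = np.stack([ps.log_psd[keep] for ps in spectra])
    if average == "log":
        ref = logp.mean(axis=0)
    elif average == "power":
        ref = np.log(np.mean(np.exp(logp), axis=0))
    else:
        raise ValueError("average must be 'log' or 'power'")
    s = (logp - ref).mean(axis=1)
    return s - s.mean()


def depth_feature(layout: ShankLayout, units: str = "spacing") -> np.ndarray:
    """Contact depth per layout contact; NaN for out-of-brain contacts.

    The most peripheral in-brain contact gets depth 0; depth increases
    toward the tip by 1 per contact (``units="spacing"``) or by the actual
    gap in millimetres (``units="mm"``, honouring ``layout.gaps_mm``).
    """
    n = len(layout)
    in_brain = layout.in_brain
    if not in_brain.any():
        raise ValueError(f"shank {layout.shank} has no in-brain contact")
    if units == "spacing":
        gaps = np.ones(max(n - 1, 0))
    elif units == "mm":
        gaps = (layout.gaps_mm if layout.gaps_mm is not None
                else np.full(max(n - 1, 0), layout.spacing_mm))
    else:
        raise ValueError("units must be 'spacing' or 'mm'")
    # position measured from the tip; depth = pos(peripheral ref) - pos(i)
    pos = np.r_[0.0, np.cumsum(gaps)]
    ref = np.flatnonzero(in_brain).max()
    depth = pos[ref] - pos
    depth[~in_brain] = np.nan
    return depth


def extract_features(recording: RecordingSet, layouts: list[ShankLayout],
                     patient: str = "patient", n_windows: int = 10,
                     window_length_s: float = 10.0,
                     depth_units: str = "spacing",
                     reference: str = "bipolar") -> list[ShankRecord]:
    """Full feature pipeline for one patient: recording -> ShankRecords.

    ``reference="common"`` skips bipolar referencing and computes the power
    feature on the raw (common-reference) traces; used for the feature
    comparison analyses, not for classification.
    """
    per_shank: list[tuple[ShankLayout, list[str], np.ndarray]] = []
    for lay in layouts:
        try:
            if reference == "bipolar":
                names, sig = bipolar_reference(recording, lay)
            elif reference == "common":
                idx = np.flatnonzero(lay.usable)
                names = [lay.contacts[i] for i in idx]
                sig = np.stack([recording.channel(nm) for nm in names])
            else:
                raise ValueError("reference must be 'bipolar' or 'common'")
        except Exception as exc:
            if reference == "bipolar" and "usable contact" in str(exc):
                logger.warning("dropping shank %s: %s", lay.shank, exc)
                continue
            raise
        per_shank.append((lay, names, sig))

    spectra = []
    for lay, names, sig in per_shank:
        for row in sig:
            spectra.append(welch_psd(row, recording.sfreq,
                                     n_windows=n_windows,
                                     window_length_s=window_length_s))
    shifts = relative_power_shift(spectra)

    records, k = [], 0
    for lay, names, sig in per_shank:
        s = shifts[k:k + len(names)]
        k += len(names)
        depth_all = depth_feature(lay, units=depth_units)
        usable_idx = [lay.contacts.index(nm) for nm in names]
        depth = depth_all[usable_idx]
        ok = ~np.isnan(depth)
        labels = None
        if lay.labels is not None:
            lab = lay.labels[usable_idx][ok]
            labels = None if np.isnan(lab).any() else lab
        records.append(ShankRecord(
            patient=patient, shank=lay.shank,
            contacts=[nm for nm, good in zip(names, ok) if good],
            s=s[ok], depth=depth[ok], labels=labels))
    return records


# ---------------------------------------------------------------------------
# Feature-table round trip: lets the model run from pre-extracted features
# without touching the signal modules.
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["patient", "shank", "contact", "s", "d", "label"]


def records_to_table(records: list[ShankRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for i in range(len(rec)):
            lab = "" if rec.labels is None else int(rec.labels[i])
            rows.append(dict(patient=rec.patient, shank=rec.shank,
                             contact=rec.contacts[i], s=rec.s[i],
                             d=rec.depth[i], label=lab))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def records_from_table(table) -> list[ShankRecord]:
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    records = []
    for (pat, shank), grp in table.groupby(["patient", "shank"], sort=True):
        grp = grp.sort_values("d", ascending=False)
        labels = None
        lab = pd.to_numeric(grp["label"], errors="coerce").to_numpy(float)
        if not np.isnan(lab).any():
            labels = lab
        records.append(ShankRecord(
            patient=str(pat), shank=str(shank),
            contacts=list(grp["contact"].astype(str)),
            s=grp["s"].to_numpy(float), depth=grp["d"].to_numpy(float),
            labels=labels))
    return records


def write_feature_table(path, records: list[ShankRecord]) -> None:
    records_to_table(records).to_csv(path, sep="\t", index=False)
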