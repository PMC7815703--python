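"""Seeded synthetic SEEG cohorts with the statistical structure the
classifier assumes, so the whole pipeline is testable without clinical data.

Three levels of realism are generated from one config:

* **labelings** — gray/white chains drawn exactly from the Ising chain
  distribution at ``beta_true`` (forward sampling from transfer-matrix
  conditionals).  A depth-dependent external field, applied during
  generation only, makes both shank ends gray-rich and sets the overall
  white-matter fraction (default 0.3); the inference prior never sees this
  field.
* **features** — the relative power shift ``s`` is drawn from
  class-conditional Gaussians with the white class shifted downward
  (less power below 150 Hz), then patient-centered; depth comes from the
  layout.
* **time series** — each contact records a shared per-shank pink-noise
  source whose amplitude decays with distance from gray matter, plus an
  independent local pink-noise source that is weaker on white-matter
  contacts (both effects of white matter lying farther from the neural
  sources).  Under bipolar referencing the shared component cancels,
  which is what makes the power feature separate the classes more than a
  common reference does.  Recordings round-trip through EDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chain import chain_marginals, chain_sample
from .features import ShankRecord
from .signal_io import RecordingSet, ShankLayout, write_edf, write_metadata


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the clinical setting the model targets: 12-contact
    shanks (real shanks carry 10+), ~30% of contacts in white matter,
    blocky labelings with one or two gray/white transitions per shank
    (beta_true = 1 plus the depth field), class-mean separation of the
    power-shift feature of 1.2 natural-log units with SD 0.6 (clearly
    separated but overlapping class clouds), 1 kHz sampling.
    """

    n_patients: int = 8
    shanks_per_patient: int = 6
    contacts_per_shank: int = 12
    beta_true: float = 1.0
    white_fraction: float = 0.3
    field_amplitude: float = 2.0     # depth profile strength; 0 = pure Ising
    mean_separation: float = 1.2     # gray-minus-white gap in s (log units)
    feature_sd: float = 0.6          # class-conditional SD of s
    spacing_mm: float = 5.0
    sfreq: float = 1000.0
    duration_s: float = 120.0
    shared_amp_uv: float = 100.0     # shared pink-noise source amplitude
    shared_decay: float = 0.05       # per-contact amplitude decay rate
    local_amp_uv: float = 25.0       # local source amplitude on gray contacts
    local_atten: float = 1.0         # local amplitude attenuation into white
    pink_slope: float = 1.0          # PSD ~ 1/f^slope
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.shanks_per_patient,
               self.contacts_per_shank) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.white_fraction < 1.0:
            raise ValueError("white_fraction must be in (0, 1)")
        if self.beta_true < 0:
            raise ValueError("beta_true must be >= 0")


def _depth_field(config: GeneratorConfig) -> np.ndarray:
    """External field h_i: gray-pulling at both shank ends, calibrated
    offset so the exact mean marginal P(white) equals white_fraction."""
    n = config.contacts_per_shank
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    profile = config.field_amplitude * (0.5 - 4.0 * (t - 0.5) ** 2 / 2.0)

    def white_mean(h0: float) -> float:
        marg = chain_marginals(config.beta_true, np.zeros((n, 2)),
                               field=profile + h0)
        return float(marg.mean())

    lo, hi = -10.0, 10.0
    if config.field_amplitude == 0.0 and config.white_fraction == 0.5:
        return np.zeros(n)
    for _ in range(60):               # bisection; white_mean is monotone
        mid = 0.5 * (lo + hi)
        if white_mean(mid) < config.white_fraction:
            lo = mid
        else:
            hi = mid
    return profile + 0.5 * (lo + hi)


def sample_labelings(config: GeneratorConfig,
                     rng: np.random.Generator | None = None,
                     n_shanks: int | None = None) -> list[np.ndarray]:
    """Draw shank labelings from the chain distribution at ``beta_true``.

    With ``field_amplitude = 0`` and ``white_fraction = 0.5`` the draws
    follow the bare Ising chain exactly; otherwise the depth field biases
    shank ends toward gray and fixes the expected white fraction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_shanks is None:
        n_shanks = config.n_patients * config.shanks_per_patient
    h = _depth_field(config)
    n = config.contacts_per_shank
    return [chain_sample(config.beta_true, n, rng, field=h)
            for _ in range(n_shanks)]


def sample_features(labelings: list[np.ndarray], config: GeneratorConfig,
                    rng: np.random.Generator | None = None,
                    patient: str = "synthetic",
                    overlap_scale: float = 1.0) -> list[ShankRecord]:
    """Class-conditional feature draws for one patient's labeled shanks.

    ``s`` is Gaussian per class, white shifted ``mean_separation`` below
    gray (scaled by ``overlap_scale``: 0 gives identical classes), then
    re-centered so the patient mean is zero.  Depth is 0 at the periphery
    and counts up toward the tip in spacing units.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sep = config.mean_separation * overlap_scale
    raw = []
    for z in labelings:
        mu = np.where(z > 0, -sep, 0.0)
        raw.append(mu + config.feature_sd * rng.standard_normal(z.size))
    center = np.mean(np.concatenate(raw))
    records = []
    for i, (z, s) in enumerate(zip(labelings, raw)):
        depth = np.arange(z.size - 1, -1, -1, dtype=float)
        records.append(ShankRecord(
            patient=patient, shank=f"S{i:02d}",
            contacts=[f"S{i:02d}-{j + 1}" for j in range(z.size)],
            s=s - center, depth=depth, labels=z.astype(float)))
    return records


def simulate_cohort(config: GeneratorConfig) -> dict[str, list[ShankRecord]]:
    """Feature-level cohort: patient id -> labeled ShankRecords.

    Deterministic given the config (labels and features both derive from
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    cohort = {}
    for p in range(config.n_patients):
        pat = f"P{p:02d}"
        labelings = sample_labelings(config, rng,
                                     n_shanks=config.shanks_per_patient)
        cohort[pat] = sample_features(labelings, config, rng, patient=pat)
    return cohort


# ---------------------------------------------------------------------------
# Raw time series
# ---------------------------------------------------------------------------

def pink_noise(n: int, rng: np.random.Generator,
               slope: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^slope noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size))
    with np.errstate(divide="ignore"):
        gain = np.where(freqs > 0, freqs ** (-slope / 2.0), 0.0)
    x = np.fft.irfft(spec * gain, n=n)
    return x / x.std()


def _gray_distance(z: np.ndarray) -> np.ndarray:
    """Per contact, chain distance to the nearest gray-matter contact."""
    gray = np.flatnonzero(z < 0)
    idx = np.arange(z.size)
    if gray.size == 0:
        return np.full(z.size, float(z.size))
    return np.min(np.abs(idx[:, None] - gray[None, :]), axis=1).astype(float)


def sample_timeseries(labelings: list[np.ndarray], config: GeneratorConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[RecordingSet, list[ShankLayout]]:
    """Raw recordings for one patient's labeled shanks.

    Contact i on a shank records
    ``shared_amp / (1 + shared_decay * dist_i) * shared(t)
    + local_amp_i * local_i(t)`` where ``dist_i`` is the chain distance to
    the nearest gray contact and local amplitude falls off into white
    matter.  With ``shared_decay = 0`` and ``local_amp_uv = 0`` every
    contact carries the identical signal and all bipolar traces vanish.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_samp = int(round(config.sfreq * config.duration_s))
    data, names, layouts = [], [], []
    for k, z in enumerate(labelings):
        shank = chr(ord("A") + k)
        shared = pink_noise(n_samp, rng, config.pink_slope)
        dist = _gray_distance(z)
        for i in range(z.size):
            amp_shared = config.shared_amp_uv / (1.0
                                                 + config.shared_decay * dist[i])
            amp_local = config.local_amp_uv / (1.0
                                               + config.local_atten * dist[i])
            local = (amp_local * pink_noise(n_samp, rng, config.pink_slope)
                     if config.local_amp_uv > 0 else 0.0)
            data.append(amp_shared * shared + local)
            names.append(f"{shank}{i + 1}")
        layouts.append(ShankLayout(
            shank=shank, contacts=[f"{shank}{i + 1}" for i in range(z.size)],
            in_brain=np.ones(z.size, bool), excluded=np.zeros(z.size, bool),
            spacing_mm=config.spacing_mm, labels=z.astype(float)))
    rec = RecordingSet(data=np.array(data), sfreq=config.sfreq,
                       ch_names=names)
    return rec, layouts


def write_patient_edf(directory, patient: str, recording: RecordingSet,
                      layouts: list[ShankLayout]) -> tuple[Path, Path]:
    """Write one patient's EDF + metadata table; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edf = directory / f"{patient}.edf"
    meta = directory / f"{patient}_channels.tsv"
    write_edf(edf, recording)
    write_metadata(meta, layouts)
    return edf, meta


def simulate_signal_cohort(config: GeneratorConfig, directory
                           ) -> list[tuple[Path, Path]]:
    """Signal-level cohort written to disk as per-patient EDF + metadata."""
    rng = np.random.default_rng(config.seed)
    paths = []
    for p in range(config.n_patients):
        pat = f"P{p:02d}"
        labelings = sample_labelings(config, rng,
                                     n_shanks=config.shanks_per_patient)
        rec, layouts = sample_timeseries(labelings, config, rng)
        paths.append(write_patient_edf(directory, pat, rec, layouts))
    return paths
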