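"""Synthetic tri-modal cohort generator with planted class signal.

Generates cohorts of AD / PD / HC subjects carrying three modalities:

* **Volumes** — a smooth blob ("brain") with two fixed ellipsoidal
  regions. AD subjects lose intensity mass in the first (a stand-in for
  hippocampal atrophy), PD subjects in the second ("motor" region). A
  smooth multiplicative polynomial bias field emulates scanner intensity
  inhomogeneity.
* **Recordings** — multichannel band-limited sinusoid mixtures plus pink
  noise; per-class offsets (in dB) raise delta/theta power for AD and
  alpha/beta power for PD.
* **Genotypes** — independent biallelic loci with minor-allele counts
  0/1/2; designated risk loci are drawn with class-specific allele
  frequencies (AD-associated and PD-associated blocks).

An optional cross-modal interaction plants a signal that no single
modality carries: a latent SNP bit (homozygous-alt vs homozygous-ref at
a dedicated locus) and a latent EEG bit (an extra alpha-power bump)
agree for AD subjects, disagree for PD subjects, and are independent
for controls, so each bit is marginally uninformative (present with
probability 1/2 in every class) while their parity separates AD from PD.

Class counts follow deterministic largest-remainder rounding (ties
broken in class order AD, PD, HC), and a configurable fraction of
subjects carries all three modalities; the rest drop modalities
uniformly at random with at least one retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .config import CLASSES, BANDS

__all__ = [
    "CohortSpec", "CohortSample", "generate_cohort", "plant_bias_field",
    "write_fixtures", "largest_remainder_counts",
    "ATROPHY_REGION", "MOTOR_REGION", "ellipsoid_mask",
]

#: Fixed ellipsoidal regions in fractional volume coordinates
#: (center, semi-axes). Not anatomical; chosen once and documented.
ATROPHY_REGION = ((0.38, 0.38, 0.42), (0.16, 0.16, 0.16))
MOTOR_REGION = ((0.62, 0.62, 0.55), (0.16, 0.16, 0.16))

_DEFAULT_N_RISK = 12  # 6 AD-associated + 6 PD-associated loci


def _default_risk_freqs() -> dict[str, tuple[float, ...]]:
    """Per-class risk-allele frequencies at the designated risk loci."""
    base, enriched = 0.15, 0.45
    ad = tuple([enriched] * 6 + [base] * 6)
    pd = tuple([base] * 6 + [enriched] * 6)
    hc = tuple([base] * 12)
    return {"AD": ad, "PD": pd, "HC": hc}


def _default_band_shifts() -> dict[str, tuple[float, float, float, float]]:
    """Per-class band-power offsets in dB (delta, theta, alpha, beta)."""
    return {"AD": (3.0, 3.0, 0.0, 0.0),
            "PD": (0.0, 0.0, 3.0, 3.0),
            "HC": (0.0, 0.0, 0.0, 0.0)}


@dataclass
class CohortSpec:
    n_subjects: int = 1000
    class_proportions: tuple[float, float, float] = (0.34, 0.33, 0.33)
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    n_channels: int = 4
    n_timesteps: int = 2048
    sample_rate: float = 128.0
    n_snps: int = 300
    atrophy_effect: float = 0.15
    motor_effect: float = 0.15
    band_shift_db: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_band_shifts)
    risk_allele_freqs: dict[str, tuple[float, ...]] = field(
        default_factory=_default_risk_freqs)
    frac_complete: float = 0.6
    bias_amplitude: float = 0.2
    noise_sd: float = 0.05
    band_jitter_db: float = 2.0      # per-subject band-power heterogeneity
    effect_jitter: float = 0.4       # per-subject severity spread (fraction)
    scans_per_subject: int = 1
    interaction_effect_db: float = 0.0
    #: when set, AD and PD share the same volume effect region, so
    #: volumes separate diseased-vs-healthy but not AD-vs-PD (used with
    #: symmetric band shifts / allele tables to plant a cohort whose
    #: AD/PD distinction lives in the SNP x EEG interaction alone)
    shared_disease_volume: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be nonnegative")
        for name in ("n_channels", "n_timesteps", "n_snps", "scans_per_subject"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be >= 1")
        if not 0.0 <= self.frac_complete <= 1.0:
            raise ValueError("frac_complete must be in [0, 1]")
        for name in ("atrophy_effect", "motor_effect"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.band_jitter_db < 0:
            raise ValueError("band_jitter_db must be >= 0")
        if self.effect_jitter < 0:
            raise ValueError("effect_jitter must be >= 0")
        for cls, freqs in self.risk_allele_freqs.items():
            if cls not in CLASSES:
                raise ValueError(f"risk_allele_freqs has unknown class {cls!r}")
            if any(not 0.0 <= f <= 1.0 for f in freqs):
                raise ValueError("risk_allele_freqs entries must be in [0, 1]")
        n_risk = len(next(iter(self.risk_allele_freqs.values())))
        reserved = n_risk + (1 if self.interaction_effect_db else 0)
        if self.n_snps < reserved:
            raise ValueError(
                f"n_snps must be >= {reserved} to hold the designated loci")

    @property
    def n_risk_loci(self) -> int:
        return len(next(iter(self.risk_allele_freqs.values())))

    @property
    def interaction_locus(self) -> int:
        """Index of the SNP carrying the cross-modal interaction bit."""
        return self.n_risk_loci


@dataclass
class CohortSample:
    subject_id: str
    label: str
    genotypes: np.ndarray          # (p,) minor-allele counts in {0,1,2}
    volume: np.ndarray             # (h, w, d)
    recording: np.ndarray          # (T_sig, c)
    modality_mask: tuple[bool, bool, bool]   # (SNP, MRI, EEG) present
    extra_volumes: list[np.ndarray] = field(default_factory=list)

    @property
    def all_volumes(self) -> list[np.ndarray]:
        return [self.volume] + self.extra_volumes


def largest_remainder_counts(n: int, proportions) -> list[int]:
    """Integer class counts by largest-remainder rounding, ties by order."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    shortfall = n - sum(counts)
    remainders = [r - c for r, c in zip(raw, counts)]
    # stable sort: ties broken by original (class) order
    order = sorted(range(len(proportions)), key=lambda i: (-remainders[i], i))
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def ellipsoid_mask(shape: tuple[int, int, int],
                   region: tuple[tuple, tuple]) -> np.ndarray:
    center, axes = region
    grids = np.meshgrid(*[np.arange(s) / max(s - 1, 1) for s in shape],
                        indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def plant_bias_field(volume: np.ndarray, amplitude: float,
                     seed: int) -> np.ndarray:
    """Multiply a volume by a smooth quadratic bias field.

    The field has mean exactly 1 over the voxel grid and peak deviation
    at most ``amplitude``. Amplitude 0 returns the input unchanged.
    """
    if amplitude < 0:
        raise ValueError("bias amplitude must be >= 0")
    if amplitude == 0:
        return volume
    field_ = bias_field(volume.shape, amplitude, seed)
    return volume * field_


def bias_field(shape: tuple[int, int, int], amplitude: float,
               seed: int) -> np.ndarray:
    """The quadratic polynomial field used by :func:`plant_bias_field`."""
    rng = np.random.default_rng(seed)
    coords = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape],
                         indexing="ij")
    x, y, z = coords
    basis = [x, y, z, x * y, x * z, y * z, x ** 2, y ** 2, z ** 2]
    coeffs = rng.uniform(-1, 1, size=len(basis))
    f = sum(c * b for c, b in zip(coeffs, basis))
    f = f - f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f = f * (amplitude / peak)
    return 1.0 + f


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec = spec / np.sqrt(freqs)
    pink = np.fft.irfft(spec, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


# baseline band amplitudes (dB relative to 1) before class shifts: a
# gently decaying spectrum, lower-frequency bands carrying more power
_BASE_BAND_DB = {"delta": 0.0, "theta": -1.0, "alpha": -2.0, "beta": -3.0}


#: Episodic-burst geometry for the cross-modal interaction channel:
#: bursts are BURST_LEN_S-second alpha-power elevations aligned to the
#: burst grid; a positive EEG bit plants N_BURSTS of them.
BURST_LEN_S = 2.0
N_BURSTS = 2


def _synth_recording(rng: np.random.Generator, spec: CohortSpec, label: str,
                     eeg_bit: int) -> np.ndarray:
    from .config import BAND_EDGES
    t = np.arange(spec.n_timesteps) / spec.sample_rate
    shifts = spec.band_shift_db[label]
    # subject-level spectral heterogeneity, shared across channels
    jitter = rng.normal(0.0, spec.band_jitter_db, size=len(BANDS))
    # episodic alpha bursts (the EEG half of the interaction channel):
    # a gain envelope over a few burst-grid slots, shared across channels
    envelope = np.ones_like(t)
    if eeg_bit and spec.interaction_effect_db:
        slot = int(round(BURST_LEN_S * spec.sample_rate))
        n_slots = max(1, spec.n_timesteps // slot)
        chosen = rng.choice(n_slots, size=min(N_BURSTS, n_slots),
                            replace=False)
        gain = 10.0 ** (spec.interaction_effect_db / 20.0)
        for s in chosen:
            envelope[s * slot:(s + 1) * slot] = gain
    rec = np.empty((spec.n_timesteps, spec.n_channels))
    nyq = spec.sample_rate / 2
    for ch in range(spec.n_channels):
        sig = np.zeros_like(t)
        for b, band in enumerate(BANDS):
            lo, hi = BAND_EDGES[band]
            hi = min(hi, 0.9 * nyq)
            db = _BASE_BAND_DB[band] + shifts[b] + jitter[b]
            amp = 10.0 ** (db / 20.0)
            # three incoherent tones spread across the band
            band_sig = np.zeros_like(t)
            for f in rng.uniform(lo, hi, size=3):
                phase = rng.uniform(0, 2 * np.pi)
                band_sig += (amp / np.sqrt(3)) * np.sin(
                    2 * np.pi * f * t + phase)
            if band == "alpha":
                band_sig = band_sig * envelope
            sig += band_sig
        sig += 0.5 * _pink_noise(rng, spec.n_timesteps)
        rec[:, ch] = sig
    return rec


def _synth_volume(rng: np.random.Generator, spec: CohortSpec, label: str,
                  base: np.ndarray, atrophy: np.ndarray,
                  motor: np.ndarray) -> np.ndarray:
    vol = base.copy()
    severity = float(np.clip(1.0 + spec.effect_jitter * rng.normal(),
                             0.0, 2.0))
    if label == "AD" and spec.atrophy_effect > 0:
        vol[atrophy] *= np.clip(1.0 - severity * spec.atrophy_effect, 0, 1)
    elif label == "PD":
        if spec.shared_disease_volume and spec.atrophy_effect > 0:
            vol[atrophy] *= np.clip(1.0 - severity * spec.atrophy_effect,
                                    0, 1)
        elif spec.motor_effect > 0:
            vol[motor] *= np.clip(1.0 - severity * spec.motor_effect, 0, 1)
    vol = vol + spec.noise_sd * rng.normal(size=vol.shape)
    vol = plant_bias_field(vol, spec.bias_amplitude,
                           int(rng.integers(0, 2 ** 31 - 1)))
    return np.clip(vol, 0.0, None)


def _synth_genotypes(rng: np.random.Generator, spec: CohortSpec, label: str,
                     background_maf: np.ndarray, snp_bit: int) -> np.ndarray:
    freqs = background_maf.copy()
    risk = np.asarray(spec.risk_allele_freqs[label], dtype=float)
    freqs[:len(risk)] = risk
    g = rng.binomial(2, freqs).astype(np.int64)
    if spec.interaction_effect_db:
        g[spec.interaction_locus] = 2 * snp_bit
    return g


def _partial_mask(rng: np.random.Generator) -> tuple[bool, bool, bool]:
    # uniformly among the 6 proper nonempty subsets of {SNP, MRI, EEG}
    options = [(True, False, False), (False, True, False), (False, False, True),
               (True, True, False), (True, False, True), (False, True, True)]
    return options[int(rng.integers(0, len(options)))]


def _interaction_bits(rng: np.random.Generator, label: str) -> tuple[int, int]:
    b_snp = int(rng.integers(0, 2))
    if label == "AD":
        return b_snp, b_snp            # parity 0
    if label == "PD":
        return b_snp, 1 - b_snp        # parity 1
    return b_snp, int(rng.integers(0, 2))


def interaction_cohort_spec(seed: int, n_subjects: int = 300) -> CohortSpec:
    """Study conditions for cross-modal signal recovery at desk scale.

    A complete tri-modal cohort with moderate marginal class effects in
    every modality (so each branch is informative but insufficient) and
    the SNP x EEG interaction channel switched on: episodic alpha bursts
    whose parity with a dedicated genotype bit separates AD from PD.
    Volumes are generated at 16^3 and recordings at 64 s so ten repeats
    of the full ablation fit in a CPU-scale run.
    """
    shifts = {"AD": (2.5, 2.5, 0.5, 0.5), "PD": (0.5, 0.5, 2.5, 2.5),
              "HC": (0.0, 0.0, 0.0, 0.0)}
    base, enriched = 0.15, 0.40
    freqs = {"AD": (enriched,) * 6 + (base,) * 6,
             "PD": (base,) * 6 + (enriched,) * 6,
             "HC": (base,) * 12}
    return CohortSpec(
        n_subjects=n_subjects, volume_shape=(16, 16, 16), n_channels=4,
        n_timesteps=8192, sample_rate=128.0, n_snps=120,
        atrophy_effect=0.12, motor_effect=0.12, band_shift_db=shifts,
        risk_allele_freqs=freqs, frac_complete=1.0,
        interaction_effect_db=10.0, seed=seed)


def generate_cohort(spec: CohortSpec) -> list[CohortSample]:
    """Generate the cohort; bit-identical for identical spec and seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    counts = largest_remainder_counts(spec.n_subjects, spec.class_proportions)
    labels = [c for c, k in zip(CLASSES, counts) for _ in range(k)]

    n_complete = int(round(spec.frac_complete * spec.n_subjects))
    complete = np.zeros(spec.n_subjects, dtype=bool)
    complete[rng.choice(spec.n_subjects, size=n_complete, replace=False)] = True

    base = _base_volume(spec.volume_shape)
    atrophy = ellipsoid_mask(spec.volume_shape, ATROPHY_REGION)
    motor = ellipsoid_mask(spec.volume_shape, MOTOR_REGION)
    background_maf = rng.uniform(0.05, 0.5, size=spec.n_snps)

    samples = []
    width = len(str(spec.n_subjects))
    for i, label in enumerate(labels):
        b_snp, b_eeg = _interaction_bits(rng, label)
        genotypes = _synth_genotypes(rng, spec, label, background_maf, b_snp)
        volume = _synth_volume(rng, spec, label, base, atrophy, motor)
        extra = [_synth_volume(rng, spec, label, base, atrophy, motor)
                 for _ in range(spec.scans_per_subject - 1)]
        recording = _synth_recording(rng, spec, label, b_eeg)
        mask = (True, True, True) if complete[i] else _partial_mask(rng)
        samples.append(CohortSample(
            subject_id=f"sub-{i + 1:0{width}d}", label=label,
            genotypes=genotypes, volume=volume, recording=recording,
            modality_mask=mask, extra_volumes=extra))
    return samples


def _base_volume(shape: tuple[int, int, int]) -> np.ndarray:
    """Plateau "tissue" volume with mild texture, intensities in [0, 1].

    Tissue intensity is roughly constant (as in real tissue classes)
    rather than smoothly varying, so that a low-order polynomial fit to
    log-intensity captures a planted bias field and not the anatomy.
    The texture is a fixed pseudo-random pattern shared by all subjects.
    """
    from scipy.ndimage import gaussian_filter
    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    r = np.sqrt(sum(g ** 2 for g in grids))
    tissue = 1.0 / (1.0 + np.exp((r - 0.82) / 0.05))
    texture_rng = np.random.default_rng(1234567)  # anatomy, not per-subject
    texture = gaussian_filter(texture_rng.normal(size=shape), sigma=1.0)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd
    return np.clip(0.75 * tissue * (1.0 + 0.06 * texture) + 0.02, 0.0, 1.0)


# -- fixture writing ---------------------------------------------------------

MANIFEST_COLUMNS = ("subject_id", "label", "snp_path", "mri_path",
                    "eeg_path", "mask")


def write_fixtures(cohort: list[CohortSample], out_dir: str | os.PathLike,
                   sample_rate: float = 128.0) -> str:
    """Write a cohort to disk (NIfTI + EDF + VCF + genotype table + manifest).

    Returns the manifest path. Genotypes of all SNP-carrying subjects go
    into one shared VCF and one CSV count table; the manifest's
    ``snp_path`` points at the VCF. ``mask`` is a three-character 0/1
    string in (SNP, MRI, EEG) order.
    """
    import pandas as pd
    import nibabel as nib
    from .io_formats import write_edf, write_vcf, write_genotype_table

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    snp_subjects = [s for s in cohort if s.modality_mask[0]]
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    table_path = os.path.join(out_dir, "genotypes.csv")
    if snp_subjects:
        G = np.stack([s.genotypes for s in snp_subjects])
        ids = [s.subject_id for s in snp_subjects]
        snp_ids = [f"rs{j + 1:06d}" for j in range(G.shape[1])]
        write_vcf(vcf_path, G, ids, snp_ids)
        write_genotype_table(table_path, G, ids, snp_ids)

    rows = []
    for s in cohort:
        has_snp, has_mri, has_eeg = s.modality_mask
        mri_path = eeg_path = ""
        if has_mri:
            mri_path = os.path.join(out_dir, f"{s.subject_id}_T1w.nii")
            nib.save(nib.Nifti1Image(s.volume.astype(np.float32), np.eye(4)),
                     mri_path)
        if has_eeg:
            eeg_path = os.path.join(out_dir, f"{s.subject_id}_eeg.edf")
            write_edf(eeg_path, s.recording, sample_rate)
        rows.append({
            "subject_id": s.subject_id, "label": s.label,
            "snp_path": vcf_path if has_snp else "",
            "mri_path": mri_path, "eeg_path": eeg_path,
            "mask": "".join(str(int(b)) for b in s.modality_mask),
        })
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False)
    return manifest_path
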