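"""Read and write the on-disk formats the pipeline touches.

Volumes are NIfTI (read/written through nibabel), recordings are EDF
(read through mne; written by a minimal single-record EDF writer since
the physical-unit scaling is all the generator needs), genotypes are
either VCF v4.2 (read through cyvcf2) or a plain CSV count table
(rows = subjects, columns = SNP IDs, values 0/1/2). A cohort manifest
CSV maps subject IDs to labels, file paths and modality availability.

Genotype convention: minor (alternate) allele count, so AA -> 0,
AG -> 1, GG -> 2 when G is the alternate allele. Missing genotypes are
coded as -1 and preserved at read time; imputation is a preprocessing
step, not a reading concern.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .config import CLASSES

__all__ = [
    "FormatError", "DimensionalityError", "UnsupportedFormatError",
    "read_volume", "read_recording", "read_genotypes",
    "write_edf", "write_vcf", "write_genotype_table", "load_manifest",
    "MISSING",
]

MISSING = -1  # missing-genotype code


class FormatError(ValueError):
    """File exists but cannot be interpreted as the expected format."""


class DimensionalityError(FormatError):
    """Image is not a 3-D volume."""


class UnsupportedFormatError(FormatError):
    """Parseable file with features the pipeline does not support."""


# -- NIfTI -------------------------------------------------------------------


def read_volume(path: str | os.PathLike):
    """Load a NIfTI volume. Returns ``(array, voxel_sizes)``."""
    import nibabel as nib
    try:
        img = nib.load(os.fspath(path))
        data = np.asarray(img.get_fdata())
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot parse NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, got {data.ndim}-D image in {path}")
    if not np.all(np.isfinite(data)):
        raise FormatError(f"non-finite voxel values in {path}")
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


# -- EDF ---------------------------------------------------------------------


def _edf_num(value: float, width: int = 8) -> bytes:
    text = f"{value:.5g}"
    if len(text) > width:
        text = f"{value:.3g}"
    if len(text) > width:
        raise ValueError(f"cannot encode {value} in {width} EDF characters")
    return text.ljust(width).encode("ascii")


def _edf_str(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(path: str | os.PathLike, recording: np.ndarray,
              sample_rate: float, channel_names: list[str] | None = None
              ) -> None:
    """Write a ``(T, c)`` recording as a single-record EDF file.

    Values are interpreted as microvolts and quantised to 16 bits over
    each channel's observed physical range.
    """
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2:
        raise ValueError("recording must be a (T, c) array")
    n_samples, n_ch = recording.shape
    if channel_names is None:
        channel_names = [f"EEG{i + 1:03d}" for i in range(n_ch)]
    duration = n_samples / sample_rate

    dig_min, dig_max = -32768, 32767
    header = b""
    header += _edf_str("0", 8)                    # version
    header += _edf_str("X X X X", 80)             # patient id
    header += _edf_str("Startdate 01-JAN-2000 X X X", 80)
    header += _edf_str("01.01.00", 8)             # start date
    header += _edf_str("00.00.00", 8)             # start time
    header += _edf_num(256 * (n_ch + 1))          # header bytes
    header += _edf_str("", 44)                    # reserved
    header += _edf_num(1)                         # number of records
    header += _edf_num(duration)                  # record duration (s)
    header += _edf_num(n_ch, 4)                   # number of signals

    phys_mins, phys_maxs = [], []
    for ch in range(n_ch):
        x = recording[:, ch]
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        # round the range outward to values that encode exactly in 8 chars
        span = hi - lo
        lo = float(f"{lo - 0.01 * span:.5g}")
        hi = float(f"{hi + 0.01 * span:.5g}")
        phys_mins.append(lo)
        phys_maxs.append(hi)

    fields = [
        [_edf_str(name, 16) for name in channel_names],
        [_edf_str("", 80)] * n_ch,                      # transducer
        [_edf_str("uV", 8)] * n_ch,                     # physical dimension
        [_edf_num(v) for v in phys_mins],
        [_edf_num(v) for v in phys_maxs],
        [_edf_num(dig_min)] * n_ch,
        [_edf_num(dig_max)] * n_ch,
        [_edf_str("", 80)] * n_ch,                      # prefiltering
        [_edf_num(n_samples)] * n_ch,
        [_edf_str("", 32)] * n_ch,                      # reserved
    ]
    for group in fields:
        header += b"".join(group)

    body = b""
    for ch in range(n_ch):
        lo, hi = phys_mins[ch], phys_maxs[ch]
        scaled = (recording[:, ch] - lo) / (hi - lo)
        digital = np.round(scaled * (dig_max - dig_min) + dig_min)
        body += digital.astype("<i2").tobytes()

    with open(os.fspath(path), "wb") as fh:
        fh.write(header + body)


def _edf_samples_per_record(path: str) -> list[int]:
    """Parse per-signal sample counts straight from the EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"truncated EDF header in {path}")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"bad EDF signal count in {path}") from exc
        sig = fh.read(256 * n_ch)
    offset = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_ch
    counts = []
    for ch in range(n_ch):
        raw = sig[offset + 8 * ch: offset + 8 * (ch + 1)]
        counts.append(int(raw.decode("ascii").strip()))
    return counts


def read_recording(path: str | os.PathLike):
    """Load an EDF recording.

    Returns ``(array, sample_rate, channel_names)`` with the array in the
    file's physical units (microvolts), shaped ``(T, c)``. Recordings with
    differing per-channel sample rates are rejected.
    """
    import mne

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    counts = _edf_samples_per_record(path)
    if len(set(counts)) > 1:
        raise UnsupportedFormatError(
            f"mixed per-channel sample rates in {path}: {sorted(set(counts))}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV").T  # (T, c)
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


# -- genotypes ---------------------------------------------------------------


def write_vcf(path: str | os.PathLike, genotypes: np.ndarray,
              subject_ids: list[str], snp_ids: list[str]) -> None:
    """Write an (n_subjects, p) count matrix as a biallelic VCF v4.2.

    REF is A and ALT is G at every site, so counts 0/1/2 correspond to
    the AA / AG / GG genotype classes.
    """
    genotypes = np.asarray(genotypes)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(subject_ids),
    ]
    for j, snp in enumerate(snp_ids):
        calls = "\t".join(gt_strings[int(g)] for g in genotypes[:, j])
        lines.append(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{calls}")
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_genotype_table(path: str | os.PathLike, genotypes: np.ndarray,
                         subject_ids: list[str], snp_ids: list[str]) -> None:
    df = pd.DataFrame(np.asarray(genotypes), index=subject_ids,
                      columns=snp_ids)
    df.index.name = "subject_id"
    df.to_csv(os.fspath(path))


def _read_genotypes_vcf(path: str, strict: bool):
    from cyvcf2 import VCF

    vcf = VCF(path)
    subject_ids = list(vcf.samples)
    columns, snp_ids = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            msg = (f"multiallelic site {variant.ID or variant.POS} "
                   f"in {path}")
            if strict:
                raise UnsupportedFormatError(msg)
            warnings.warn(f"skipping {msg}")
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        mapping = np.array([0, 1, MISSING, 2])
        columns.append(mapping[variant.gt_types])
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    matrix = (np.stack(columns, axis=1) if columns
              else np.empty((len(subject_ids), 0), dtype=int))
    return matrix.astype(np.int64), snp_ids, subject_ids


def _read_genotypes_table(path: str, strict: bool):
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    matrix = np.full(values.shape, MISSING, dtype=np.int64)
    valid = np.isin(values, (0, 1, 2))
    matrix[valid] = values[valid].astype(np.int64)
    bad = ~valid & ~np.isnan(values)
    if bad.any():
        pos = np.argwhere(bad)[0]
        msg = (f"non-{{0,1,2}} genotype {values[tuple(pos)]!r} at subject "
               f"{df.index[pos[0]]!r}, locus {df.columns[pos[1]]!r}")
        if strict:
            raise FormatError(msg)
        warnings.warn(msg + "; coded as missing")
    return matrix, list(df.columns), list(df.index)


def read_genotypes(path: str | os.PathLike, format: str = "vcf",
                   strict: bool = True):
    """Load genotypes as an (n_subjects, p) minor-allele count matrix.

    Returns ``(matrix, snp_ids, subject_ids)``; missing calls are coded
    as :data:`MISSING` (-1).
    """
    path = os.fspath(path)
    if format == "vcf":
        return _read_genotypes_vcf(path, strict)
    if format == "table":
        return _read_genotypes_table(path, strict)
    raise ValueError(f"unknown genotype format {format!r}")


# -- manifest ----------------------------------------------------------------


def load_manifest(path: str | os.PathLike,
                  check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV."""
    df = pd.read_csv(os.fspath(path), dtype=str).fillna("")
    required = {"subject_id", "label", "snp_path", "mri_path", "eeg_path",
                "mask"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"manifest missing columns {sorted(missing_cols)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"duplicate subject_id {dup!r} in manifest")
    bad = ~df["label"].isin(CLASSES)
    if bad.any():
        raise FormatError(
            f"label {df.loc[bad, 'label'].iloc[0]!r} not in {CLASSES}")
    if not df["mask"].str.fullmatch("[01]{3}").all():
        raise FormatError("mask must be a 3-character 0/1 string (SNP,MRI,EEG)")
    if check_paths:
        base = os.path.dirname(os.fspath(path))
        for col in ("snp_path", "mri_path", "eeg_path"):
            for p in df[col]:
                if p and not os.path.exists(p) and not os.path.exists(
                        os.path.join(base, p)):
                    raise FileNotFoundError(f"manifest references missing "
                                            f"file {p}")
    return df
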