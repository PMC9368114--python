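"""Reading and writing centroided DART spectra and feature matrices.

The canonical interchange format is a long-format peak CSV with columns
sample_id, species, extraction, polarity, replicate, mz, intensity — one
row per centroided peak. mzML is supported as an ingestion path for data
converted with standard proteomics tooling. Feature matrices travel as
TSV with replicate rows and m/z-bin columns.

I/O is lossless with respect to the acquisition range: peaks outside
75-1125 Da are flagged in a range report, never dropped here (range
enforcement belongs to preprocessing).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BLOCK_OF, MZ_MAX, MZ_MIN, SPECIES

__all__ = [
    "Peak",
    "Spectrum",
    "SampleRecord",
    "read_peak_csv",
    "write_peak_csv",
    "read_mzml",
    "range_check",
    "write_feature_matrix",
    "read_feature_matrix",
]

PEAK_CSV_COLUMNS = [
    "sample_id",
    "species",
    "extraction",
    "polarity",
    "replicate",
    "mz",
    "intensity",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One replicate's centroided peak list with its block metadata."""

    sample_id: str
    extraction: str  # "A" (H2O:MeOH 20:80) or "B" (ethyl acetate)
    polarity: str  # "pos" or "neg"
    replicate: int  # 1..3
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError(
                    f"duplicate m/z in spectrum {self.key}: centroided peak "
                    "lists must have strictly increasing m/z"
                )
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in spectrum {self.key}")
        if self.replicate not in (1, 2, 3):
            raise ValueError(f"replicate must be 1..3, got {self.replicate}")
        if self.extraction not in ("A", "B"):
            raise ValueError(f"extraction must be 'A' or 'B', got {self.extraction!r}")
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be 'pos' or 'neg', got {self.polarity!r}")

    @property
    def block(self) -> str:
        return BLOCK_OF[(self.extraction, self.polarity)]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sample_id, self.block, self.replicate)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: str
    role: str = "unassigned"  # train | test | unassigned

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; expected one of {list(SPECIES)}"
            )
        if self.role not in ("train", "test", "unassigned"):
            raise ValueError(f"invalid role {self.role!r}")


def _sorted_spectra(spectra: list[Spectrum]) -> list[Spectrum]:
    return sorted(spectra, key=lambda s: s.key)


def read_peak_csv(path) -> tuple[list[SampleRecord], list[Spectrum]]:
    """Read a long-format peak CSV into sample records and spectra.

    Output spectra are ordered lexicographically by (sample_id, block,
    replicate); the total row count is conserved as the total peak count.
    Malformed rows raise with the offending 1-based data row number.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in PEAK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak CSV {path} is missing columns: {missing}")

    bad = df.index[~df["species"].isin(SPECIES)]
    if len(bad):
        raise ValueError(
            f"row {bad[0] + 1}: unknown species {df.loc[bad[0], 'species']!r}; "
            f"expected one of {list(SPECIES)}"
        )
    for col in ("mz", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"row {bad[0] + 1}: non-numeric {col} {df.loc[bad[0], col]!r}")
        df[col] = vals
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad = df.index[~rep.isin([1, 2, 3])]
    if len(bad):
        raise ValueError(f"row {bad[0] + 1}: replicate must be 1..3, got {df.loc[bad[0], 'replicate']!r}")
    df["replicate"] = rep.astype(int)

    samples: dict[str, SampleRecord] = {}
    spectra: list[Spectrum] = []
    for (sid, species, extraction, polarity, replicate), grp in df.groupby(
        ["sample_id", "species", "extraction", "polarity", "replicate"], sort=True
    ):
        if sid in samples and samples[sid].species != species:
            raise ValueError(f"sample {sid!r} has inconsistent species labels")
        samples.setdefault(sid, SampleRecord(sample_id=sid, species=species))
        grp = grp.sort_values("mz")
        spectra.append(
            Spectrum(
                sample_id=sid,
                extraction=extraction,
                polarity=polarity,
                replicate=int(replicate),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return sorted(samples.values(), key=lambda s: s.sample_id), _sorted_spectra(spectra)


def write_peak_csv(path, samples: list[SampleRecord], spectra: list[Spectrum]) -> None:
    """Write spectra to the long-format peak CSV (inverse of read_peak_csv)."""
    species_of = {s.sample_id: s.species for s in samples}
    rows = []
    for spec in _sorted_spectra(spectra):
        for m, i in zip(spec.mz, spec.intensity):
            rows.append(
                (
                    spec.sample_id,
                    species_of[spec.sample_id],
                    spec.extraction,
                    spec.polarity,
                    spec.replicate,
                    f"{m:.6f}",
                    f"{i:.6g}",
                )
            )
    pd.DataFrame(rows, columns=PEAK_CSV_COLUMNS).to_csv(path, index=False)


def range_check(
    spectra: list[Spectrum], mz_min: float = MZ_MIN, mz_max: float = MZ_MAX
) -> dict[tuple[str, str, int], int]:
    """Count peaks outside the acquisition range, per spectrum.

    Returns only spectra with at least one out-of-range peak; peaks are
    flagged, never removed.
    """
    report = {}
    for spec in spectra:
        n = int(np.sum((spec.mz < mz_min) | (spec.mz > mz_max)))
        if n:
            report[spec.key] = n
    return report


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# mzML controlled-vocabulary accessions used by the reader
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_NEGATIVE = "MS:1000129"
_CV_POSITIVE = "MS:1000130"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _decode_binary_array(elem) -> np.ndarray:
    import base64
    import zlib as _zlib

    accessions = {cv.get("accession") for cv in elem.iter(f"{_MZML_NS}cvParam")}
    node = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(node.text or "")
    if _CV_ZLIB in accessions:
        raw = _zlib.decompress(raw)
    dtype = "<f4" if _CV_FLOAT32 in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, sample_id: str, extraction: str, replicate: int) -> list[Spectrum]:
    """Read centroided spectra from an mzML file.

    Polarity is taken from each spectrum's scan polarity term; profile-mode
    spectra raise with advice to centroid first (DART data are expected to
    be centroided at conversion). The reader is a compact lxml-based mzML
    parser covering centroided peak lists (64/32-bit floats, optional zlib
    compression).
    """
    from lxml import etree

    tree = etree.parse(str(path))
    out = []
    for spec_elem in tree.iter(f"{_MZML_NS}spectrum"):
        accessions = {
            cv.get("accession") for cv in spec_elem.iter(f"{_MZML_NS}cvParam")
        }
        if _CV_PROFILE in accessions:
            raise ValueError(
                f"{path}: profile-mode spectrum found; centroid the data "
                "(e.g. at Proteowizard conversion) before reading"
            )
        if _CV_NEGATIVE in accessions:
            polarity = "neg"
        elif _CV_POSITIVE in accessions:
            polarity = "pos"
        else:
            raise ValueError(f"{path}: spectrum without a scan polarity term")
        mz = intensity = None
        for arr in spec_elem.iter(f"{_MZML_NS}binaryDataArray"):
            arr_acc = {cv.get("accession") for cv in arr.iter(f"{_MZML_NS}cvParam")}
            if _CV_MZ_ARRAY in arr_acc:
                mz = _decode_binary_array(arr)
            elif _CV_INT_ARRAY in arr_acc:
                intensity = _decode_binary_array(arr)
        if mz is None or intensity is None:
            raise ValueError(f"{path}: spectrum without m/z or intensity arrays")
        out.append(
            Spectrum(
                sample_id=sample_id,
                extraction=extraction,
                polarity=polarity,
                replicate=replicate,
                mz=mz,
                intensity=intensity,
            )
        )
    if not out:
        raise ValueError(f"{path}: no spectra found")
    return out


def write_feature_matrix(matrix, path) -> None:
    """Write a FeatureMatrix as TSV (sample_id, replicate, block + bin columns)."""
    df = matrix.values
    out = df.copy()
    out.columns = [f"{mz:.4f}" for mz in df.columns]
    if len(set(out.columns)) != len(out.columns):
        raise ValueError("duplicate bin headers at 4-decimal precision")
    out.insert(0, "block", matrix.block)
    out = out.reset_index()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scaling_state={matrix.scaling_state}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path):
    """Read a feature-matrix TSV written by write_feature_matrix."""
    from .preprocessing import FeatureMatrix

    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        state = "raw"
        if first.startswith("# scaling_state="):
            state = first.split("=", 1)[1].strip()
        else:
            fh.seek(0)
        header_pos = fh.tell()
        header = fh.readline().rstrip("\n").split("\t")
        bins = [c for c in header if c not in ("sample_id", "replicate", "block")]
        if len(set(bins)) != len(bins):
            raise ValueError(f"{path}: duplicate bin headers")
        fh.seek(header_pos)
        df = pd.read_csv(fh, sep="\t", dtype={"sample_id": str})
    if df.empty:
        raise ValueError(f"{path}: empty feature matrix")
    blocks = df.pop("block").unique()
    if len(blocks) != 1:
        raise ValueError(f"{path}: expected a single block, found {list(blocks)}")
    df = df.set_index(["sample_id", "replicate"])
    bin_cols = [float(c) for c in df.columns]
    if len(set(bin_cols)) != len(bin_cols):
        raise ValueError(f"{path}: duplicate bin headers")
    df.columns = bin_cols
    return FeatureMatrix(block=str(blocks[0]), values=df, scaling_state=state)


def file_checksum(path) -> str:
    """SHA-256 of a file, for manifest/reproducibility audits."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
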