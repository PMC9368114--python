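"""Replicate spectra -> aligned, filtered, imputed, scaled block matrices.

The fixed preprocessing order for each measurement block is:

1. isotope removal (M+1/M+2 peaks 1.00336 Da above a more intense peak),
2. m/z alignment across spectra by single-linkage grouping in ppm space,
3. removal of bins missing in more than 75% of replicate rows,
4. imputation of remaining missing cells with 1/5 of the bin's lowest
   observed intensity,
5. row-wise sum normalization (each spectrum becomes a composition), and
6. Pareto scaling, (x - mean)/sqrt(sd), with parameters learned on
   training rows and applied unchanged to held-out rows.

Each stage is idempotent on its own output and the scaling state of a
matrix only moves forward (raw -> imputed -> normalized -> pareto).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import C13_C12_DELTA
from .spectra_io import Spectrum

__all__ = [
    "FeatureMatrix",
    "ScalingParams",
    "remove_isotopes",
    "align_features",
    "filter_missing",
    "impute_missing",
    "normalize_sum",
    "pareto_scale",
    "preprocess_block",
]

_STATES = ("raw", "imputed", "normalized", "pareto")


@dataclass
class FeatureMatrix:
    """Samples-x-bins intensity table for one block.

    ``values`` is a DataFrame indexed by (sample_id, replicate) with one
    float column per aligned m/z bin (column label = representative m/z);
    NaN marks a missing cell.
    """

    block: str
    values: pd.DataFrame
    scaling_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scaling_state not in _STATES:
            raise ValueError(f"unknown scaling_state {self.scaling_state!r}")
        cols = np.asarray(self.values.columns, dtype=float)
        if cols.size and np.any(np.diff(cols) <= 0):
            raise ValueError("bin m/z values must be strictly increasing")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate (sample_id, replicate) rows: {dup}")

    @property
    def bin_mz(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def _advance(self, state: str) -> None:
        if _STATES.index(state) < _STATES.index(self.scaling_state):
            raise ValueError(
                f"scaling_state may only move forward ({self.scaling_state} -> {state})"
            )

    def rows_for(self, sample_ids) -> "FeatureMatrix":
        """Subset to the given sample ids (all replicates), preserving order."""
        keep = self.values.index.get_level_values("sample_id").isin(set(sample_ids))
        return replace(self, values=self.values.loc[keep])


@dataclass
class ScalingParams:
    """Per-bin mean and sample standard deviation from training rows."""

    bin_mz: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.bin_mz) == len(self.mean) == len(self.sd)):
            raise ValueError("bin_mz, mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be non-negative")


def remove_isotopes(spectrum: Spectrum, ppm_tol: float = 10.0) -> Spectrum:
    """Strip isotopologue peaks from a centroided spectrum.

    A peak P is removed iff some peak Q sits one 13C-12C spacing
    (1.00336 Da) below it within ``ppm_tol`` (evaluated at P's m/z) with
    strictly higher intensity. The test runs against the original peak
    list, so an M+2 peak is removed through its (also removed) M+1
    neighbour; monoisotopic peaks have no lighter partner and survive.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size == 0:
        return spectrum
    keep = np.ones(mz.size, dtype=bool)
    for i in range(mz.size):
        target = mz[i] - C13_C12_DELTA
        tol = mz[i] * ppm_tol * 1e-6
        j = np.searchsorted(mz, target - tol)
        while j < mz.size and mz[j] <= target + tol:
            if inten[j] > inten[i]:
                keep[i] = False
                break
            j += 1
    return replace(spectrum, mz=mz[keep], intensity=inten[keep])


def align_features(spectra: list[Spectrum], ppm_tol: float = 5.0) -> FeatureMatrix:
    """Group peaks across one block's spectra into m/z bins.

    Peaks from all spectra are pooled, sorted, and split wherever the gap
    between consecutive m/z values exceeds ``ppm_tol`` (single-linkage
    clustering with chain breaking). Within a bin each spectrum
    contributes at most one peak (most intense wins); the representative
    m/z is the intensity-weighted mean of the contributing peaks.
    """
    if not spectra:
        raise ValueError("no spectra to align")
    blocks = {s.block for s in spectra}
    if len(blocks) != 1:
        raise ValueError(f"spectra from multiple blocks passed to align_features: {sorted(blocks)}")
    block = blocks.pop()

    spec_keys = [(s.sample_id, s.replicate) for s in spectra]
    all_mz = np.concatenate([s.mz for s in spectra]) if spectra else np.array([])
    all_int = np.concatenate([s.intensity for s in spectra])
    all_src = np.concatenate(
        [np.full(s.mz.size, k, dtype=int) for k, s in enumerate(spectra)]
    )
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_src = all_mz[order], all_int[order], all_src[order]

    if all_mz.size == 0:
        raise ValueError("all spectra are empty")
    gaps = np.diff(all_mz) / all_mz[:-1] * 1e6
    breaks = np.flatnonzero(gaps > ppm_tol) + 1
    starts = np.concatenate([[0], breaks])
    stops = np.concatenate([breaks, [all_mz.size]])

    n_rows = len(spectra)
    cols: list[np.ndarray] = []
    reps: list[float] = []
    for a, b in zip(starts, stops):
        mzs, ints, srcs = all_mz[a:b], all_int[a:b], all_src[a:b]
        col = np.full(n_rows, np.nan)
        best = np.full(n_rows, -np.inf)
        used = np.zeros(b - a, dtype=bool)
        for i in range(b - a):
            s = srcs[i]
            if ints[i] > best[s]:
                best[s] = ints[i]
        for i in range(b - a):
            s = srcs[i]
            if ints[i] == best[s] and np.isnan(col[s]):
                col[s] = ints[i]
                used[i] = True
        w = ints[used]
        reps.append(float(np.average(mzs[used], weights=w)) if w.sum() > 0 else float(mzs[used].mean()))
        cols.append(col)

    rep_arr = np.array(reps)
    order = np.argsort(rep_arr, kind="stable")
    index = pd.MultiIndex.from_tuples(spec_keys, names=["sample_id", "replicate"])
    values = pd.DataFrame(
        np.column_stack([cols[i] for i in order]), index=index, columns=rep_arr[order]
    )
    values = values.sort_index()
    return FeatureMatrix(block=block, values=values, scaling_state="raw")


def filter_missing(matrix: FeatureMatrix, threshold: float = 0.75) -> FeatureMatrix:
    """Drop bins whose missing fraction over all rows strictly exceeds threshold.

    A bin missing in exactly 75% of rows is retained ("more than 75%"
    reads as a strict inequality); a bin every row contributed to is
    never dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    frac = matrix.values.isna().mean(axis=0)
    keep = frac.values <= threshold
    return replace(matrix, values=matrix.values.loc[:, keep])


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing cell with 1/5 of its bin's lowest observed intensity."""
    values = matrix.values.copy()
    for col in values.columns:
        x = values[col]
        if x.isna().any():
            observed = x[x > 0]
            if observed.empty:
                raise RuntimeError(
                    f"bin {col} has no positive observations; filter_missing "
                    "must run before imputation"
                )
            values[col] = x.fillna(observed.min() / 5.0)
    return replace(matrix, values=values, scaling_state="imputed")


def normalize_sum(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each row by its total so every spectrum sums to one."""
    matrix._advance("normalized")
    totals = matrix.values.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero rows cannot be sum-normalized: {zero}")
    return replace(
        matrix, values=matrix.values.div(totals, axis=0), scaling_state="normalized"
    )


def pareto_scale(
    matrix: FeatureMatrix, params: ScalingParams | None = None
) -> tuple[FeatureMatrix, ScalingParams]:
    """Pareto-scale each bin: (x - mean)/sqrt(sd).

    With ``params`` given (learned on training rows) they are applied as
    is, keeping held-out rows leakage-free; otherwise mean and sample
    standard deviation (n-1 divisor, the convention of the common
    metabolomics suites) are learned from the supplied rows. Bins with
    zero sd map to zero.
    """
    matrix._advance("pareto")
    X = matrix.values.to_numpy(dtype=float)
    if params is None:
        params = ScalingParams(
            bin_mz=matrix.bin_mz, mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1)
        )
    else:
        if len(params.bin_mz) != matrix.n_bins or not np.allclose(
            params.bin_mz, matrix.bin_mz
        ):
            raise ValueError("scaling parameters do not match the matrix bins")
    denom = np.sqrt(params.sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(params.sd > 0, (X - params.mean) / denom, 0.0)
    values = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values, scaling_state="pareto"), params


def preprocess_block(
    spectra: list[Spectrum],
    ppm_isotope: float = 10.0,
    ppm_align: float = 5.0,
    missing_threshold: float = 0.75,
) -> FeatureMatrix:
    """Run stages 1-5 (up to sum normalization) on one block's spectra.

    Pareto scaling is applied separately so its parameters can be learned
    on the training partition only.
    """
    cleaned = [remove_isotopes(s, ppm_isotope) for s in spectra]
    matrix = align_features(cleaned, ppm_align)
    matrix = filter_missing(matrix, missing_threshold)
    matrix = impute_missing(matrix)
    return normalize_sum(matrix)
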