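"""Synthetic DART-HRMS cohort generator.

The study cohort this package targets (33 powdered-insect samples: 12
*Acheta domesticus*, 11 *Bombyx mori*, 5 *Hermetia illucens*, 5 *Tenebrio
molitor*; two extractions x two polarities, each in triplicate) has no
publicly deposited raw spectra, so every downstream stage is exercised on
a generated stand-in that reproduces the cohort's design and the known
marker chemistry:

* per block, a set of background ions shared by all samples (uniform over
  the 75-1125 Da acquisition window, lognormal base abundances),
* every marker ion of the bundled compound table, elevated ``marker_fold``
  times in samples of its own species,
* a carbon-count-proportional M+1 isotopologue 1.00336 Da above every
  peak (1.1% per carbon),
* ppm-scale multiplicative mass jitter, lognormal intensity noise, and
  Bernoulli dropout of non-marker peaks.

One global seed feeds independent substreams (background layout, jitter,
intensity noise, dropout) so changing one noise knob does not reshuffle
the rest; generation is bit-reproducible for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import CompoundRecord, load_marker_table
from .constants import BLOCK_META, BLOCK_ORDER, C13_C12_DELTA, MZ_MAX, MZ_MIN, SPECIES
from .spectra_io import SampleRecord, Spectrum

__all__ = ["SyntheticConfig", "generate_cohort", "split_train_test"]

#: Study cohort composition.
DEFAULT_SPECIES_COUNTS = {
    "Acheta domesticus": 12,
    "Bombyx mori": 11,
    "Hermetia illucens": 5,
    "Tenebrio molitor": 5,
}


@dataclass
class SyntheticConfig:
    """Generative settings; the defaults emulate the study conditions."""

    species_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_COUNTS)
    )
    n_replicates: int = 3
    blocks: tuple[str, ...] = BLOCK_ORDER
    marker_table: list[CompoundRecord] | None = None  # None -> bundled table
    n_background: int = 60  # shared background ions per block
    mz_jitter_ppm: float = 2.0  # sd of multiplicative mass error
    intensity_cv: float = 0.25  # lognormal coefficient of variation
    dropout_prob: float = 0.15  # per-replicate absence of non-marker peaks
    marker_fold: float = 10.0  # own-species elevation of marker ions
    background_median: float = 1.0e5  # median background base intensity
    background_sigma: float = 1.0  # lognormal sigma of base intensities
    marker_median: float = 3.0e5  # median off-species marker intensity
    seed: int = 42

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.species_counts.values()):
            raise ValueError("species counts must be positive")
        if unknown := set(self.species_counts) - set(SPECIES):
            raise ValueError(f"unknown species in config: {sorted(unknown)}")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")
        if self.n_background < 0 or self.n_replicates < 1:
            raise ValueError("n_background >= 0 and n_replicates >= 1 required")

    @property
    def n_samples(self) -> int:
        return sum(self.species_counts.values())

    def resolved_markers(self) -> list[CompoundRecord]:
        table = self.marker_table if self.marker_table is not None else load_marker_table()
        for rec in table:
            if not MZ_MIN <= rec.theoretical_mz <= MZ_MAX:
                raise ValueError(
                    f"marker {rec.name!r} at m/z {rec.theoretical_mz} lies outside "
                    f"the acquisition range {MZ_MIN}-{MZ_MAX}"
                )
        return table


def _lognormal_sigma(cv: float) -> float:
    # cv of a lognormal: sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv**2)))


def _carbon_count(rec: CompoundRecord) -> int:
    return rec.formula.get("C", 0)


def _plan_block(
    block: str, markers: list[CompoundRecord], cfg: SyntheticConfig, rng: np.random.Generator
) -> dict:
    """Lay out one block's true peak set (shared across all samples)."""
    block_markers = [m for m in markers if m.block == block]
    marker_mz = np.array([m.theoretical_mz for m in block_markers])
    # background ions: uniform over the window, kept >= 0.1 Da from every
    # planted feature and its M+1 so alignment bins never collide
    taken = list(marker_mz) + [m + C13_C12_DELTA for m in marker_mz]
    bg_mz: list[float] = []
    while len(bg_mz) < cfg.n_background:
        cand = float(rng.uniform(MZ_MIN, MZ_MAX - C13_C12_DELTA - 0.2))
        if all(abs(cand - t) > 0.1 and abs(cand + C13_C12_DELTA - t) > 0.1 for t in taken):
            bg_mz.append(cand)
            taken += [cand, cand + C13_C12_DELTA]
    bg_mz = sorted(bg_mz)
    bg_base = cfg.background_median * np.exp(
        rng.normal(0.0, cfg.background_sigma, size=len(bg_mz))
    )
    # plausible organic carbon counts for background ions (~1 C per 15-25 Da)
    bg_carbons = np.maximum(
        1, np.round(np.array(bg_mz) / rng.uniform(15.0, 25.0, size=len(bg_mz)))
    ).astype(int)
    return {
        "markers": block_markers,
        "marker_carbons": np.array([_carbon_count(m) for m in block_markers]),
        "bg_mz": np.array(bg_mz),
        "bg_base": bg_base,
        "bg_carbons": bg_carbons,
    }


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[list[SampleRecord], list[Spectrum]]:
    """Generate the synthetic cohort: one spectrum per sample x block x replicate.

    Returns sample records (roles unassigned; see :func:`split_train_test`)
    and spectra sorted by (sample_id, block, replicate).
    """
    cfg = config or SyntheticConfig()
    markers = cfg.resolved_markers()

    root = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_jitter, ss_noise, ss_dropout = root.spawn(4)
    rng_layout = np.random.default_rng(ss_layout)
    rng_jitter = np.random.default_rng(ss_jitter)
    rng_noise = np.random.default_rng(ss_noise)
    rng_dropout = np.random.default_rng(ss_dropout)

    plans = {b: _plan_block(b, markers, cfg, rng_layout) for b in cfg.blocks}

    samples: list[SampleRecord] = []
    idx = 1
    for species in SPECIES:
        for _ in range(cfg.species_counts.get(species, 0)):
            samples.append(SampleRecord(sample_id=f"S{idx:02d}", species=species))
            idx += 1

    sigma = _lognormal_sigma(cfg.intensity_cv)
    spectra: list[Spectrum] = []
    for sample in samples:
        for block in cfg.blocks:
            plan = plans[block]
            extraction, polarity = BLOCK_META[block]
            fold = np.array(
                [
                    cfg.marker_fold if m.species == sample.species else 1.0
                    for m in plan["markers"]
                ]
            )
            # one ion can mark several species (e.g. palmitic acid); take
            # the max fold over duplicate rows sharing an m/z
            for replicate in range(1, cfg.n_replicates + 1):
                mz_parts, int_parts = [], []
                # marker peaks: always present
                n_m = len(plan["markers"])
                if n_m:
                    base = cfg.marker_median * fold
                    noisy = base * np.exp(rng_noise.normal(0.0, sigma, size=n_m)) if sigma > 0 else base
                    true_mz = np.array([m.theoretical_mz for m in plan["markers"]])
                    mz_parts.append(true_mz)
                    int_parts.append(noisy)
                    # M+1 isotopologues (carbon-only model)
                    has_c = plan["marker_carbons"] > 0
                    if has_c.any():
                        mz_parts.append(true_mz[has_c] + C13_C12_DELTA)
                        int_parts.append(noisy[has_c] * 0.011 * plan["marker_carbons"][has_c])
                # background peaks: subject to dropout
                n_b = len(plan["bg_mz"])
                if n_b:
                    present = (
                        rng_dropout.random(n_b) >= cfg.dropout_prob
                        if cfg.dropout_prob > 0
                        else np.ones(n_b, dtype=bool)
                    )
                    base = plan["bg_base"][present]
                    noisy = base * np.exp(rng_noise.normal(0.0, sigma, size=base.size)) if sigma > 0 else base
                    mz_parts.append(plan["bg_mz"][present])
                    int_parts.append(noisy)
                    carbons = plan["bg_carbons"][present]
                    mz_parts.append(plan["bg_mz"][present] + C13_C12_DELTA)
                    int_parts.append(noisy * 0.011 * carbons)
                mz = np.concatenate(mz_parts)
                inten = np.concatenate(int_parts)
                # collapse duplicate rows sharing an m/z (same ion marking
                # two species appears once, at its strongest intensity)
                mz, inv = np.unique(mz, return_inverse=True)
                collapsed = np.zeros(mz.size)
                np.maximum.at(collapsed, inv, inten)
                inten = collapsed
                if cfg.mz_jitter_ppm > 0:
                    mz = mz * (1.0 + rng_jitter.normal(0.0, cfg.mz_jitter_ppm * 1e-6, mz.size))
                order = np.argsort(mz, kind="stable")
                spectra.append(
                    Spectrum(
                        sample_id=sample.sample_id,
                        extraction=extraction,
                        polarity=polarity,
                        replicate=replicate,
                        mz=mz[order],
                        intensity=inten[order],
                    )
                )
    spectra.sort(key=lambda s: s.key)
    return samples, spectra


def split_train_test(
    samples: list[SampleRecord], n_test: int = 8, seed: int = 42
) -> list[SampleRecord]:
    """Stratified sample-level train/test split.

    Test slots are apportioned proportionally to species prevalence with a
    floor of one test sample per species (largest-remainder rounding), so
    the default 33-sample cohort splits 25 train / 8 test with test
    composition 3 *A. domesticus* / 3 *B. mori* / 1 *H. illucens* /
    1 *T. molitor*. All replicates of a sample share its role.
    """
    if n_test >= len(samples):
        raise ValueError("n_test must be smaller than the number of samples")
    by_species: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)
    if n_test == 0:
        return [SampleRecord(s.sample_id, s.species, "train") for s in samples]
    if n_test < len(by_species):
        raise ValueError(
            f"n_test={n_test} cannot cover one test sample per each of "
            f"{len(by_species)} species"
        )
    if any(len(v) < 2 for v in by_species.values()):
        raise ValueError("every species needs >= 2 samples to split")

    total = len(samples)
    quota = {sp: n_test * len(v) / total for sp, v in by_species.items()}
    alloc = {sp: max(1, int(np.floor(q))) for sp, q in quota.items()}
    # largest-remainder top-up, deterministic species order
    while sum(alloc.values()) < n_test:
        rem = {sp: quota[sp] - alloc[sp] for sp in alloc if alloc[sp] < len(by_species[sp]) - 1}
        sp = max(sorted(rem), key=lambda k: rem[k])
        alloc[sp] += 1
    while sum(alloc.values()) > n_test:
        rem = {sp: quota[sp] - alloc[sp] for sp in alloc if alloc[sp] > 1}
        sp = min(sorted(rem), key=lambda k: rem[k])
        alloc[sp] -= 1

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = []
    test_ids = set()
    for sp in sorted(by_species):
        ids = sorted(s.sample_id for s in by_species[sp])
        chosen = rng.choice(len(ids), size=alloc[sp], replace=False)
        test_ids.update(ids[i] for i in chosen)
    for s in samples:
        role = "test" if s.sample_id in test_ids else "train"
        out.append(SampleRecord(s.sample_id, s.species, role))
    return out
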