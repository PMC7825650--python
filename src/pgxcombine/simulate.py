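"""Synthetic cohorts: genotypes, probe-level CNV tracks, and the worked
614-subject combined-analysis fixture.

The generator produces the two raw inputs the pipeline consumes —
biallelic autosomal genotypes (drawn either per-variant under linkage
equilibrium or as two independent draws from a specified haplotype pool
under HWE) and per-subject probe series carrying a piecewise-constant
copy-number signal plus i.i.d. Gaussian noise.  Planted truth (phased
haplotypes, true segment boundaries and shifts) is retained so that
downstream estimates can be scored against it.

All randomness flows from a single integer seed; per-subject /
per-chromosome noise streams are derived deterministically from it, so
any track can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VariantRecord
from .regions import GeneRegion
from .cnv import ProbeSeries
from .star import StarAlleleDefinitions, default_definitions

__all__ = [
    "VariantSpec",
    "PlantedEvent",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_probe_series",
    "WorkedExampleCohort",
    "make_worked_example_cohort",
]


@dataclass(frozen=True)
class VariantSpec:
    """Specification of one simulated biallelic SNV."""

    rsid: str
    chrom: str
    pos: int  # 1-based hg19
    ref: str
    alt: str
    alt_freq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"{self.rsid}: alt_freq must be in [0, 1]")

    def record(self) -> VariantRecord:
        return VariantRecord(self.rsid, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PlantedEvent:
    """A true copy-number event to embed in probe tracks.

    Carriers are either an explicit list of subject indices or a random
    subset drawn once per event at ``carrier_freq``.  ``shift`` is the
    true mean log2-ratio displacement inside [start, end].
    """

    chrom: str
    start: int
    end: int
    shift: float
    subjects: tuple[int, ...] | None = None
    carrier_freq: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start > end")
        if (self.subjects is None) == (self.carrier_freq is None):
            raise ValueError("specify exactly one of subjects / carrier_freq")
        if self.carrier_freq is not None and not 0.0 <= self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic cohort.

    Default planted log2 shifts elsewhere in the package are +/-0.40 for
    single-copy gain/loss surrogates and +/-1.0 for amplification/deletion,
    straddling the +/-0.25 and +/-0.8 classification cutoffs.  The default
    probe noise (sd 0.15) is a realistic mid-range aCGH value and is a
    plain config field, not an assertion about any particular platform.
    """

    n_subjects: int
    seed: int
    variant_specs: list[VariantSpec] = field(default_factory=list)
    haplotype_pool: list[tuple[tuple[int, ...], float]] | None = None
    probe_spacing: int = 500
    noise_sd: float = 0.15
    probe_regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_events: list[PlantedEvent] = field(default_factory=list)
    screen_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.haplotype_pool is not None:
            k = len(self.variant_specs)
            total = 0.0
            for hap, freq in self.haplotype_pool:
                if len(hap) != k:
                    raise ValueError("haplotype length must match variant_specs")
                if not 0.0 <= freq <= 1.0:
                    raise ValueError("haplotype frequency outside [0, 1]")
                total += freq
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    def subject_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_subjects)]


def _stream(seed: int, *keys: int | str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (seed, keys)."""
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw unphased genotypes, returning the phased truth alongside.

    With a haplotype pool, each subject is two independent draws from the
    pool (HWE at the haplotype level); otherwise alleles are independent
    Bernoulli(alt_freq) draws per variant (linkage equilibrium).

    Returns
    -------
    (matrix, haplotypes)
        ``haplotypes`` has shape (n_subjects, 2, n_variants).
    """
    if not config.variant_specs:
        raise ValueError("no variants specified")
    rng = _stream(config.seed, "genotypes")
    n = config.n_subjects
    k = len(config.variant_specs)
    if config.haplotype_pool is not None:
        haps = np.array([h for h, _ in config.haplotype_pool], dtype=np.int8)
        freqs = np.array([f for _, f in config.haplotype_pool], dtype=float)
        freqs = freqs / freqs.sum()
        draws = rng.choice(len(haps), size=(n, 2), p=freqs)
        phased = haps[draws]  # (n, 2, k)
    else:
        p = np.array([v.alt_freq for v in config.variant_specs])
        phased = (rng.random((n, 2, k)) < p).astype(np.int8)
    calls = phased.sum(axis=1).astype(np.int8)
    matrix = GenotypeMatrix(
        subjects=config.subject_ids(),
        variants=[v.record() for v in config.variant_specs],
        calls=calls,
    )
    return matrix, phased


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------

def resolve_event_carriers(config: SimulationConfig) -> list[tuple[int, ...]]:
    """Carrier subject indices for each planted event (deterministic)."""
    out = []
    for e_idx, event in enumerate(config.planted_events):
        if event.subjects is not None:
            out.append(tuple(event.subjects))
        else:
            rng = _stream(config.seed, "carriers", e_idx)
            mask = rng.random(config.n_subjects) < event.carrier_freq
            out.append(tuple(np.flatnonzero(mask)))
    return out


_SCREEN_WINDOWS = range(6, 13)
_SCREEN_MAX_MEAN = 0.20


def _noise_is_typical(noise: np.ndarray) -> bool:
    """True if no short window of the noise has an extreme mean.

    Screens windows of 6-12 probes for |mean| >= 0.20.  A pure-noise
    track passing this screen cannot, by arithmetic, contain a short
    all-noise segment whose mean reaches the 0.25 gain/loss cutoff.
    """
    cs = np.concatenate([[0.0], np.cumsum(noise)])
    for w in _SCREEN_WINDOWS:
        if w > noise.size:
            break
        means = (cs[w:] - cs[:-w]) / w
        if np.abs(means).max() >= _SCREEN_MAX_MEAN:
            return False
    return True


def _draw_noise(
    config: SimulationConfig, subject: int, chrom: str, size: int
) -> np.ndarray:
    """Per-probe Gaussian noise for one track, deterministic in the seed.

    With ``screen_noise`` the draw is from the conditional distribution of
    Gaussian noise given no extreme short-window excursion (see
    :func:`_noise_is_typical`): numbered substreams are tried in order and
    the first typical draw is kept, so the result is still a pure function
    of (seed, subject, chrom).
    """
    for attempt in range(1000):
        rng = _stream(config.seed, "noise", subject, chrom, attempt)
        noise = rng.normal(0.0, config.noise_sd, size)
        if not config.screen_noise or _noise_is_typical(noise):
            return noise
    raise RuntimeError(
        "could not draw screened noise; noise_sd is too large for the screen"
    )


def simulate_probe_series(
    config: SimulationConfig, subject: int, chrom: str
) -> tuple[ProbeSeries, list[tuple[int, int, float]]]:
    """Probe-level log2-ratio track for one subject on one chromosome.

    Probes sit at regular spacing across the configured span; the signal
    is 0 outside planted events and the event shift inside, plus
    Gaussian(0, noise_sd) noise.  The returned truth is the list of
    (start, end, shift) events carried by this subject on this chromosome.

    Raises
    ------
    ValueError
        If the subject's events on this chromosome overlap each other or
        fall outside the probe span.
    """
    if chrom not in config.probe_regions:
        raise ValueError(f"no probe region configured for chromosome {chrom!r}")
    start, end = config.probe_regions[chrom]
    positions = np.arange(start, end + 1, config.probe_spacing, dtype=np.int64)

    carriers = resolve_event_carriers(config)
    events = [
        (e.start, e.end, e.shift)
        for e, carr in zip(config.planted_events, carriers)
        if e.chrom == chrom and subject in carr
    ]
    events.sort()
    for (s1, e1, _), (s2, _, _) in zip(events, events[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping planted events for subject {subject} on {chrom}")
    for s, e, _ in events:
        if s < positions[0] or e > positions[-1] + config.probe_spacing - 1:
            raise ValueError("planted event outside the probe span")

    signal = np.zeros(positions.size)
    for s, e, shift in events:
        signal[(positions >= s) & (positions <= e)] += shift
    if config.noise_sd > 0:
        noise = _draw_noise(config, subject, chrom, positions.size)
    else:
        noise = 0.0
    series = ProbeSeries(
        subject=f"S{subject:04d}", chrom=chrom,
        positions=positions, log2r=signal + noise,
    )
    return series, events


# ---------------------------------------------------------------------------
# The 614-subject worked-example fixture
# ---------------------------------------------------------------------------

# CYP4F2 defining SNVs: rs3093105 (allele *2), rs2108622 (allele *3);
# TPMT defining SNV: rs1142345 (allele *3C).  Positions hg19.
_FIXTURE_VARIANTS = [
    VariantSpec("rs3093105", "19", 16008388, "T", "G", 0.0),
    VariantSpec("rs2108622", "19", 15990431, "C", "T", 0.0),
    VariantSpec("rs1142345", "6", 18130918, "A", "G", 0.0),
]

_CYP4F2_REGION = GeneRegion("CYP4F2", "19", 15988834, 16008884)
_TPMT_REGION = GeneRegion("TPMT", "6", 18128545, 18155374)

# ((rs3093105 count, rs2108622 count), gene CNV status, n subjects).
# Composite-labelled rows plant the per-locus genotype combination that the
# diplotyper renders as that label (e.g. het *2-SNV + hom *3-SNV -> *1*2-*3*3).
_CYP4F2_CATEGORIES = [
    ((0, 0), "neutral", 258),
    ((1, 0), "neutral", 1),
    ((0, 1), "neutral", 150),
    ((0, 2), "neutral", 22),
    ((1, 1), "neutral", 114),
    ((1, 2), "neutral", 31),
    ((2, 2), "neutral", 13),
    ((0, 0), "gain", 9),
    ((0, 1), "gain", 6),
    ((1, 1), "gain", 6),
    ((0, 2), "gain", 1),
    ((0, 0), "loss", 2),
    ((1, 1), "loss", 1),
]

# (rs1142345 count, gene CNV status, n subjects)
_TPMT_CATEGORIES = [
    (0, "neutral", 287),
    (1, "neutral", 8),
    (0, "loss", 308),
    (1, "loss", 11),
]

_FIXTURE_N = 614
_GAIN_SHIFT = 0.40
_LOSS_SHIFT = -0.40


@dataclass
class WorkedExampleCohort:
    """Deterministic 614-subject cohort for the combined SNV x CNV example."""

    genotypes: GenotypeMatrix
    probe_tracks: dict[str, list[ProbeSeries]]
    regions: list[GeneRegion]
    definitions: StarAlleleDefinitions
    truth: pd.DataFrame
    config: SimulationConfig


def make_worked_example_cohort(seed: int) -> WorkedExampleCohort:
    """Build the worked-example cohort for the combined analysis.

    614 subjects receive CYP4F2 genotypes at rs3093105/rs2108622, TPMT
    genotypes at rs1142345, and planted CNV segments (log2 shift +/-0.40
    spanning the gene body) over the CYP4F2 and TPMT regions, in fixed
    per-category blocks.  Probe noise is drawn at sd 0.15 from the
    screened ensemble (``screen_noise=True``), so the planted category
    structure is identifiable by construction and running the full
    pipeline yields the reference combined frequency table exactly; only
    the noise realisation depends on the seed.
    """
    g2 = np.empty(_FIXTURE_N, dtype=np.int8)
    g3 = np.empty(_FIXTURE_N, dtype=np.int8)
    cyp_status = np.empty(_FIXTURE_N, dtype=object)
    i = 0
    for (a, b), status, count in _CYP4F2_CATEGORIES:
        g2[i : i + count] = a
        g3[i : i + count] = b
        cyp_status[i : i + count] = status
        i += count
    assert i == _FIXTURE_N

    gt = np.empty(_FIXTURE_N, dtype=np.int8)
    tpmt_status = np.empty(_FIXTURE_N, dtype=object)
    i = 0
    for a, status, count in _TPMT_CATEGORIES:
        gt[i : i + count] = a
        tpmt_status[i : i + count] = status
        i += count
    assert i == _FIXTURE_N

    pad = _CYP4F2_REGION.pad
    probe_regions = {
        "19": (_CYP4F2_REGION.start - pad, _CYP4F2_REGION.end + pad),
        "6": (_TPMT_REGION.start - pad, _TPMT_REGION.end + pad),
    }
    events: list[PlantedEvent] = []
    for i in range(_FIXTURE_N):
        if cyp_status[i] != "neutral":
            shift = _GAIN_SHIFT if cyp_status[i] == "gain" else _LOSS_SHIFT
            events.append(
                PlantedEvent("19", _CYP4F2_REGION.start, _CYP4F2_REGION.end,
                             shift, subjects=(i,))
            )
        if tpmt_status[i] == "loss":
            events.append(
                PlantedEvent("6", _TPMT_REGION.start, _TPMT_REGION.end,
                             _LOSS_SHIFT, subjects=(i,))
            )

    config = SimulationConfig(
        n_subjects=_FIXTURE_N,
        seed=seed,
        variant_specs=list(_FIXTURE_VARIANTS),
        probe_regions=probe_regions,
        planted_events=events,
        screen_noise=True,
    )

    matrix = GenotypeMatrix(
        subjects=config.subject_ids(),
        variants=[v.record() for v in _FIXTURE_VARIANTS],
        calls=np.column_stack([g2, g3, gt]),
    )
    tracks = {
        sid: [
            simulate_probe_series(config, i, "19")[0],
            simulate_probe_series(config, i, "6")[0],
        ]
        for i, sid in enumerate(config.subject_ids())
    }
    truth = pd.DataFrame(
        {
            "subject": config.subject_ids(),
            "cyp4f2_rs3093105": g2,
            "cyp4f2_rs2108622": g3,
            "cyp4f2_cnv": cyp_status,
            "tpmt_rs1142345": gt,
            "tpmt_cnv": tpmt_status,
        }
    )
    return WorkedExampleCohort(
        genotypes=matrix,
        probe_tracks=tracks,
        regions=[_CYP4F2_REGION, _TPMT_REGION],
        definitions=default_definitions(),
        truth=truth,
        config=config,
    )
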