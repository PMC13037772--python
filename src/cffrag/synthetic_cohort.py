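"""Synthetic cfDNA cohorts with known truth for every downstream stage.

The generator emulates the statistical structure of plasma cfDNA at desk
scale:

* a nucleosomal fragment-length ladder — mono-, di-, and polynucleosome peaks
  plus a sub-mononucleosomal tail carrying the ~10 bp helical-pitch comb;
* species presets capturing the contrasts between human plasma (modal ~166 bp,
  dominant mononucleosome), healthy canine plasma (modal ~153 bp, depleted
  mononucleosome, dinucleosome shifted ~+100 bp, heavier polynucleosomal
  tail), and tumor-derived canine cfDNA (modal ~144 bp, enriched short
  fragments);
* copy-number-modulated sequencing depth at a chosen tumor fraction, so an
  ichorCNA-style estimator has identifiable signal;
* position-specific base bias at 5' fragment ends, planted by placing
  fragments preferentially where the reference matches a weight matrix;
* paired short/long-amplicon qPCR read-outs with a configurable standard
  curve and Cq noise.

Every random draw flows through one seeded :class:`numpy.random.Generator`,
so identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .core_io import (
    MAX_FRAGMENT_LENGTH,
    Fragment,
    Genome,
    write_fragment_tsv,
    write_sample_sheet,
)
from .qpcr_quant import StandardCurve

__all__ = [
    "LadderModel",
    "SpeciesPreset",
    "CnaSegment",
    "SubjectTruth",
    "HUMAN",
    "CANINE_HEALTHY",
    "CANINE_TUMOR",
    "build_reference",
    "sample_fragments",
    "simulate_qpcr",
    "generate_cohort",
    "simulate_feature_cohort",
    "fragments_to_bam",
    "DEFAULT_CURVE",
    "FeatureCalibration",
]

BIN_SIZE = 500_000

#: Default in-silico assay calibration: perfect efficiency (slope -log2(10)^-1
#: per log10), Cq 24 at 1 ng — typical for a repeat-family qPCR target.
DEFAULT_CURVE = StandardCurve(slope=-3.3219280948873623, intercept=24.0)


# ---------------------------------------------------------------------------
# Fragment-length ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LadderModel:
    """Mixture model of a cfDNA fragment-length distribution.

    Components: a sub-mononucleosomal tail (exponential approach to the
    mononucleosome peak, modulated by a cosine comb of period ``comb_period``
    and amplitude ``comb_amplitude``), Gaussian mono- and dinucleosome peaks,
    and a geometric polynucleosomal ladder with inter-nucleosome spacing
    ``di_mean - mono_mean``.  ``weights`` are the mixture weights over
    (sub_mono, mono, di, poly) and must sum to 1.
    """

    mono_mean: float = 153.0
    mono_sd: float = 9.0
    di_mean: float = 440.0
    di_sd: float = 30.0
    ladder_decay: float = 0.55
    sub_mono_rate: float = 0.02
    comb_amplitude: float = 0.45
    comb_period: float = 10.0
    weights: tuple[float, float, float, float] = (0.12, 0.62, 0.16, 0.10)
    sub_mono_min: int = 50
    max_poly_units: int = 12

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be 4 nonnegative values summing to 1")
        if not (0 <= self.comb_amplitude < 1):
            raise ValueError("comb_amplitude must lie in [0, 1)")
        for name in ("mono_mean", "mono_sd", "di_mean", "di_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def length_pmf(self, max_length: int = MAX_FRAGMENT_LENGTH) -> np.ndarray:
        """Probability of each fragment length 1..max_length (index = length - 1)."""
        ell = np.arange(1, max_length + 1, dtype=float)
        w_sub, w_mono, w_di, w_poly = self.weights

        # sub-mononucleosomal: exponential decay away from the mono peak going
        # shorter, times the 10 bp helical-pitch comb; support ends one sd
        # below the peak so the modal length stays at mono_mean
        sub = np.zeros_like(ell)
        hi = int(round(self.mono_mean - self.mono_sd))
        mask = (ell >= self.sub_mono_min) & (ell <= hi)
        sub[mask] = np.exp(-self.sub_mono_rate * (self.mono_mean - ell[mask]))
        sub[mask] *= 1.0 + self.comb_amplitude * np.cos(
            2 * np.pi * ell[mask] / self.comb_period
        )
        if sub.sum() > 0:
            sub /= sub.sum()

        mono = stats.norm.pdf(ell, self.mono_mean, self.mono_sd)
        mono[ell < self.sub_mono_min] = 0.0
        mono /= mono.sum()

        di = stats.norm.pdf(ell, self.di_mean, self.di_sd)
        di /= di.sum()

        # polynucleosome ladder: k = 3.. nucleosome units, geometric weights,
        # unit spacing = di_mean - mono_mean
        unit = self.di_mean - self.mono_mean
        poly = np.zeros_like(ell)
        geo = self.ladder_decay ** np.arange(self.max_poly_units - 2)
        geo /= geo.sum()
        for i, k in enumerate(range(3, self.max_poly_units + 1)):
            mean_k = self.mono_mean + (k - 1) * unit
            if mean_k > max_length + 4 * self.di_sd:
                break
            poly += geo[i] * stats.norm.pdf(ell, mean_k, self.di_sd * np.sqrt(k - 1))
        if poly.sum() > 0:
            poly /= poly.sum()

        pmf = w_sub * sub + w_mono * mono + w_di * di + w_poly * poly
        return pmf / pmf.sum()

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pmf = self.length_pmf()
        return rng.choice(np.arange(1, pmf.size + 1), size=n, p=pmf)


# Position weight matrices over positions -2..+2 relative to the 5' end
# (negative = upstream of the fragment, +0 = first fragment base); rows are
# positions, columns A, C, G, T.
PWM_POSITIONS = np.arange(-2, 3)

_HUMAN_PWM = np.array([
    [0.20, 0.20, 0.20, 0.40],   # -2: T up
    [0.18, 0.22, 0.18, 0.42],   # -1: T up
    [0.15, 0.45, 0.20, 0.20],   # +0: strong C preference at the terminus
    [0.22, 0.30, 0.24, 0.24],   # +1
    [0.25, 0.25, 0.25, 0.25],   # +2
])
_CANINE_PWM = np.array([
    [0.20, 0.21, 0.19, 0.40],   # -2: T up
    [0.19, 0.21, 0.20, 0.40],   # -1: T up
    [0.24, 0.27, 0.25, 0.24],   # +0: near-uniform downstream of the end
    [0.25, 0.25, 0.25, 0.25],   # +1
    [0.25, 0.25, 0.25, 0.25],   # +2
])
_CANINE_TUMOR_PWM = np.array([
    [0.22, 0.23, 0.22, 0.33],   # reduced bias in cancer
    [0.22, 0.23, 0.22, 0.33],
    [0.24, 0.26, 0.25, 0.25],
    [0.25, 0.25, 0.25, 0.25],
    [0.25, 0.25, 0.25, 0.25],
])


@dataclass(frozen=True)
class SpeciesPreset:
    """A named ladder + fragment-end base-bias matrix."""

    name: str
    ladder: LadderModel
    end_bias: np.ndarray | None = None  # shape (5, 4), rows = positions -2..+2

    def __post_init__(self):
        if self.end_bias is not None:
            pwm = np.asarray(self.end_bias, dtype=float)
            if pwm.shape != (len(PWM_POSITIONS), 4):
                raise ValueError(f"end_bias must have shape {(len(PWM_POSITIONS), 4)}")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("end_bias rows must each sum to 1")


HUMAN = SpeciesPreset(
    "HUMAN",
    LadderModel(mono_mean=166, mono_sd=8, di_mean=340, di_sd=25,
                sub_mono_rate=0.03, comb_amplitude=0.35,
                weights=(0.08, 0.72, 0.14, 0.06)),
    _HUMAN_PWM,
)
CANINE_HEALTHY = SpeciesPreset(
    "CANINE_HEALTHY",
    LadderModel(mono_mean=153, mono_sd=9, di_mean=440, di_sd=30,
                sub_mono_rate=0.02, comb_amplitude=0.45,
                weights=(0.10, 0.40, 0.16, 0.34),
                ladder_decay=0.85, max_poly_units=30),
    _CANINE_PWM,
)
CANINE_TUMOR = SpeciesPreset(
    "CANINE_TUMOR",
    LadderModel(mono_mean=144, mono_sd=10, di_mean=440, di_sd=30,
                sub_mono_rate=0.02, comb_amplitude=0.45,
                weights=(0.30, 0.58, 0.06, 0.06), ladder_decay=0.55),
    _CANINE_TUMOR_PWM,
)


# ---------------------------------------------------------------------------
# Subjects, CNA truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnaSegment:
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self):
        if self.copy_number < 0 or self.end <= self.start:
            raise ValueError("invalid CNA segment")


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    tumor_fraction: float = 0.0
    cna_segments: list[CnaSegment] = field(default_factory=list)
    true_short_index: float = float("nan")
    n_samples: int = 1

    def __post_init__(self):
        if self.group == "healthy" and self.tumor_fraction != 0:
            raise ValueError("healthy subjects must have tumor_fraction 0")
        if not (0 <= self.tumor_fraction <= 1):
            raise ValueError("tumor_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Reference genomes
# ---------------------------------------------------------------------------

def build_reference(
    n_contigs: int = 2,
    contig_length: int = 5_000_000,
    gc_profile: float | Sequence[float] | None = None,
    seed: int = 0,
    gc_range: tuple[float, float] = (0.35, 0.55),
) -> Genome:
    """Random reference whose per-500kb-bin GC varies smoothly.

    ``gc_profile`` may be a constant GC fraction, an explicit per-bin sequence,
    or None for a smooth sinusoidal sweep across ``gc_range`` (so GC
    correction downstream has signal to work with).  Deterministic given
    ``seed``.
    """
    if contig_length < BIN_SIZE:
        raise ValueError(f"contig_length must be >= bin width ({BIN_SIZE})")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    n_bins = contig_length // BIN_SIZE + (contig_length % BIN_SIZE > 0)
    for ci in range(n_contigs):
        if gc_profile is None:
            # smooth sinusoidal sweep with a ~4 Mb period so per-bin GC spans
            # the range several times per contig and stays decorrelated from
            # any multi-bin copy-number segment
            lo, hi = gc_range
            phase = 2 * np.pi * (np.arange(n_bins) / 8.0 + ci / n_contigs)
            bin_gc = (lo + hi) / 2 + (hi - lo) / 2 * np.sin(phase)
        elif np.isscalar(gc_profile):
            bin_gc = np.full(n_bins, float(gc_profile))
        else:
            bin_gc = np.asarray(gc_profile, dtype=float)
            if bin_gc.size != n_bins:
                raise ValueError(f"gc_profile needs {n_bins} per-bin values")
        parts = []
        for bi in range(n_bins):
            size = min(BIN_SIZE, contig_length - bi * BIN_SIZE)
            gc = bin_gc[bi]
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            codes = rng.choice(4, size=size, p=p)
            parts.append(codes.astype(np.uint8))
        seq = np.concatenate(parts)
        contigs[f"chr{ci + 1}"] = (
            np.frombuffer(b"ACGT", dtype=np.uint8)[seq].tobytes().decode("ascii")
        )
    return Genome(contigs)


# ---------------------------------------------------------------------------
# Fragment sampling
# ---------------------------------------------------------------------------

def _pwm_accept_prob(
    genome: Genome, chrom: str, starts: np.ndarray, ends: np.ndarray, pwm: np.ndarray
) -> np.ndarray:
    """Acceptance probability of each candidate placement under the end PWM.

    Score = product over PWM positions of pwm[pos, base] / max(pwm[pos]) for
    the left 5' end window (read forward) times the same for the right 5' end
    window (read on the reverse strand), so both molecule ends carry bias.
    """
    enc = genome.encoded(chrom)
    norm = pwm / pwm.max(axis=1, keepdims=True)
    comp = np.array([3, 2, 1, 0], dtype=np.int64)
    prob = np.ones(starts.size)
    for i, off in enumerate(PWM_POSITIONS):
        left = enc[starts + off]
        ok = left < 4
        prob[ok] *= norm[i, left[ok]]
        # right end: position +off on the reverse strand is end-1-off forward,
        # complemented
        right = enc[ends - 1 - off]
        ok = right < 4
        prob[ok] *= norm[i, comp[right[ok]]]
    return prob


def _place_fragments(
    genome: Genome,
    chrom: str,
    bin_start: int,
    bin_end: int,
    lengths: np.ndarray,
    pwm: np.ndarray | None,
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> np.ndarray:
    """Uniform starts within a bin, optionally PWM-biased by rejection sampling."""
    contig_len = genome.lengths[chrom]
    margin = PWM_POSITIONS.max() + 1
    lo = max(bin_start, margin)
    hi_for = np.minimum(bin_end, contig_len - margin - lengths)
    hi_for = np.maximum(hi_for, lo + 1)
    starts = rng.integers(lo, hi_for)
    if pwm is None:
        return starts
    pending = np.arange(lengths.size)
    for _ in range(max_attempts - 1):
        p = _pwm_accept_prob(genome, chrom, starts[pending], starts[pending] + lengths[pending], pwm)
        keep = rng.random(pending.size) < p
        pending = pending[~keep]
        if pending.size == 0:
            break
        starts[pending] = rng.integers(lo, hi_for[pending])
    return starts


def sample_fragments(
    subject: SubjectTruth,
    healthy_preset: SpeciesPreset,
    tumor_preset: SpeciesPreset,
    depth: float,
    genome: Genome,
    seed: int,
    apply_end_bias: bool = True,
) -> tuple[list[Fragment], np.ndarray]:
    """Draw one sample's fragments for a subject.

    Depth model: in a bin with tumor copy number ``c`` the expected fragment
    count is depth * ((1-tf)*2 + tf*c) / 2; within the bin each fragment is
    tumor-derived with probability tf*c / (tf*c + (1-tf)*2), drawing its
    length from the tumor ladder, otherwise from the healthy ladder.  Starts
    are uniform within the bin (rejection-biased toward PWM-matching end
    contexts when ``apply_end_bias``).

    Returns the fragments and a parallel array of origin labels
    ('healthy'/'tumor').
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    tf = subject.tumor_fraction
    if tf > 0 and not subject.cna_segments:
        import warnings

        warnings.warn("tumor_fraction > 0 with no CNA segments: fragmentation-only signal",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    h_pmf = healthy_preset.ladder.length_pmf()
    t_pmf = tumor_preset.ladder.length_pmf()
    ell_grid = np.arange(1, h_pmf.size + 1)

    frags: list[Fragment] = []
    origins: list[np.ndarray] = []
    for chrom, clen in genome.lengths.items():
        n_bins = clen // BIN_SIZE + (clen % BIN_SIZE > 0)
        for bi in range(n_bins):
            b0, b1 = bi * BIN_SIZE, min((bi + 1) * BIN_SIZE, clen)
            c = 2
            for seg in subject.cna_segments:
                if seg.chrom == chrom and seg.start < b1 and b0 < seg.end:
                    c = seg.copy_number
                    break
            local = tf * c + (1 - tf) * 2
            n = rng.poisson(depth * (b1 - b0) / BIN_SIZE * local / 2.0)
            if n == 0:
                continue
            tf_local = tf * c / local if local > 0 else 0.0
            is_tumor = rng.random(n) < tf_local
            lengths = np.empty(n, dtype=np.int64)
            n_t = int(is_tumor.sum())
            if n - n_t:
                lengths[~is_tumor] = rng.choice(ell_grid, size=n - n_t, p=h_pmf)
            if n_t:
                lengths[is_tumor] = rng.choice(ell_grid, size=n_t, p=t_pmf)
            pwm_h = healthy_preset.end_bias if apply_end_bias else None
            pwm_t = tumor_preset.end_bias if apply_end_bias else None
            starts = np.empty(n, dtype=np.int64)
            for mask, pwm in ((~is_tumor, pwm_h), (is_tumor, pwm_t)):
                if mask.any():
                    starts[mask] = _place_fragments(
                        genome, chrom, b0, b1, lengths[mask], pwm, rng
                    )
            for s, l in zip(starts.tolist(), lengths.tolist()):
                frags.append(Fragment(chrom, s, s + l))
            origins.append(np.where(is_tumor, "tumor", "healthy"))
    labels = np.concatenate(origins) if origins else np.empty(0, dtype="<U7")
    return frags, labels


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def _amplifiable_weight(lengths: np.ndarray, amplicon: int) -> float:
    """Total amplifiable templates: each fragment of length l contributes
    max(0, l - L + 1) start positions for an amplicon of length L."""
    return float(np.maximum(0, lengths - amplicon + 1).sum())


def expected_short_index(
    ladder: LadderModel | np.ndarray,
    assay_short_len: int = 99,
    assay_long_len: int = 598,
) -> float:
    """Closed-form short index implied by a length distribution.

    Accepts a :class:`LadderModel` or an explicit length pmf (index =
    length - 1), e.g. a healthy/tumor mixture at some tumor fraction.
    """
    pmf = ladder.length_pmf() if isinstance(ladder, LadderModel) else np.asarray(ladder)
    ell = np.arange(1, pmf.size + 1)
    q_s = float((pmf * np.maximum(0, ell - assay_short_len + 1)).sum())
    q_l = float((pmf * np.maximum(0, ell - assay_long_len + 1)).sum())
    return (q_s - q_l) / q_s


def simulate_qpcr(
    source: np.ndarray | LadderModel,
    assay_short_len: int = 99,
    assay_long_len: int = 598,
    curve: StandardCurve = DEFAULT_CURVE,
    replicates: int = 3,
    noise_sd_cq: float = 0.05,
    seed: int = 0,
    sample_id: str = "S1",
    ng_per_template: float = 1e-8,
    n_molecules: float = 1e6,
) -> tuple[pd.DataFrame, float]:
    """Cq read-outs for a short/long assay pair on one sample.

    ``source`` is either an integer array of fragment lengths (quantities are
    the amplicon-spanning template counts of those molecules) or a
    :class:`LadderModel` / length pmf (float array over lengths 1..N summing
    to 1), in which case expected quantities for ``n_molecules`` plasma
    molecules are used — appropriate when the assay interrogates far more
    molecules than were sequenced.  Cq is drawn from the standard curve with
    Normal(0, noise_sd_cq) noise.  Returns the replicate-level Cq table and
    the noise-free truth short index.
    """
    if assay_short_len >= assay_long_len:
        raise ValueError("short amplicon must be shorter than the long amplicon")
    if isinstance(source, LadderModel):
        source = source.length_pmf()
    source = np.asarray(source)
    is_pmf = np.issubdtype(source.dtype, np.floating) and abs(source.sum() - 1.0) < 1e-6
    rng = np.random.default_rng(seed)
    rows = []
    q = {}
    for assay, amplicon in (("short", assay_short_len), ("long", assay_long_len)):
        if is_pmf:
            ell = np.arange(1, source.size + 1)
            weight = float((source * np.maximum(0, ell - amplicon + 1)).sum()) * n_molecules
        else:
            weight = _amplifiable_weight(source, amplicon)
        ng = weight * ng_per_template
        q[assay] = ng
        for rep in range(1, replicates + 1):
            if ng <= 0:
                cq = np.nan  # no amplification within 40 cycles
            else:
                cq = curve.cq(ng) + rng.normal(0, noise_sd_cq)
            rows.append({"sample_id": sample_id, "assay": assay, "replicate": rep, "cq": cq})
    truth = (q["short"] - q["long"]) / q["short"] if q["short"] > 0 else np.nan
    return pd.DataFrame(rows), truth


def make_dilution_series(
    curve: StandardCurve = DEFAULT_CURVE,
    ngs: Sequence[float] = (0.002, 0.02, 0.2, 2.0, 20.0),
    replicates: int = 3,
    noise_sd_cq: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standard-curve dilution series table (columns ng, cq)."""
    rng = np.random.default_rng(seed)
    rows = [
        {"ng": ng, "cq": curve.cq(ng) + rng.normal(0, noise_sd_cq)}
        for ng in ngs
        for _ in range(replicates)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BAM round-trip writer
# ---------------------------------------------------------------------------

def fragments_to_bam(
    fragments: Sequence[Fragment],
    genome: Genome,
    path: str | Path,
    read_len: int = 60,
    mapq: int = 60,
) -> Path:
    """Write fragments as a coordinate-sorted paired-end BAM.

    Each fragment becomes one properly-paired read pair whose template span
    equals the fragment exactly, so alignment-based fragment extraction can be
    validated against the generator truth.
    """
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.lengths.items()],
    }
    tid = {name: i for i, name in enumerate(genome.lengths)}
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        for i, frag in enumerate(fragments):
            rl = min(read_len, frag.length)
            for first in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.reference_id = tid[frag.chrom]
                a.mapping_quality = mapq
                a.is_paired = True
                a.is_proper_pair = True
                a.set_tag("MQ", mapq)
                if first:
                    a.reference_start = frag.start
                    a.next_reference_start = frag.end - rl
                    a.template_length = frag.length
                    a.is_read1 = True
                    a.mate_is_reverse = True
                else:
                    a.reference_start = frag.end - rl
                    a.next_reference_start = frag.start
                    a.template_length = -frag.length
                    a.is_read2 = True
                    a.is_reverse = True
                a.next_reference_id = a.reference_id
                a.query_sequence = genome.slice(
                    frag.chrom, a.reference_start, a.reference_start + rl
                ).replace("N", "A")
                a.cigarstring = f"{rl}M"
                out.write(a)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    return path


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------

def _default_cna_segments(genome: Genome, fraction: float = 0.2) -> list[CnaSegment]:
    """One loss (c=1) and one gain (c=3) together covering ``fraction`` of the genome."""
    chroms = list(genome.lengths)
    total = sum(genome.lengths.values())
    span = max(BIN_SIZE, (int(total * fraction / 2) // BIN_SIZE) * BIN_SIZE)
    segs = []
    for chrom, cn in zip(chroms[:2] if len(chroms) > 1 else chroms * 2, (1, 3)):
        clen = genome.lengths[chrom]
        seg_span = min(span, (clen // BIN_SIZE) * BIN_SIZE // 2)
        start = 0 if cn == 1 else clen - seg_span
        segs.append(CnaSegment(chrom, start, start + seg_span, cn))
    return segs


def _perturb_ladder(ladder: LadderModel, rng: np.random.Generator, sd: float) -> LadderModel:
    """Per-subject biological variability in long-fragment burden.

    One lognormal factor scales the di- and polynucleosome weights jointly
    (the dominant axis along which individual plasma profiles differ), so a
    subject's qPCR short index and its long-fragment proportion move together
    as they do in real cohorts.
    """
    if sd <= 0:
        return ladder
    z = rng.normal()
    # polynucleosome tail extent: jitter the geometric decay on the logit scale
    logit = np.log(ladder.ladder_decay / (1 - ladder.ladder_decay)) + sd * z
    decay = float(1 / (1 + np.exp(-logit)))
    # long-fragment weight moves with the same latent burden factor
    g = float(np.exp(0.5 * sd * z))
    w = np.asarray(ladder.weights) * np.array([1.0, 1.0, g, g])
    w /= w.sum()
    return replace(ladder, weights=tuple(w), ladder_decay=decay)


def generate_cohort(
    outdir: str | Path,
    n_healthy: int = 10,
    n_cancer: int = 10,
    samples_per_subject: int = 1,
    depth: float = 400.0,
    seed: int = 0,
    healthy_preset: SpeciesPreset = CANINE_HEALTHY,
    tumor_preset: SpeciesPreset = CANINE_TUMOR,
    n_contigs: int = 2,
    contig_length: int = 6_000_000,
    tf_range: tuple[float, float] = (0.05, 0.5),
    apply_end_bias: bool = True,
    noise_sd_cq: float = 0.05,
    subject_variability: float = 0.5,
    write_bam: bool = False,
) -> dict:
    """Generate a complete synthetic cohort on disk.

    Writes reference.fa, fragments/<sample>.tsv (optionally .bam), qpcr.csv,
    dilutions.csv, samples.csv, truth.csv and segments.tsv under ``outdir``.
    Healthy subjects have tumor fraction 0; cancer subjects draw a tumor
    fraction uniformly from ``tf_range`` and carry the default loss+gain CNA
    profile.  Every subject gets an individually perturbed fragment ladder
    (``subject_variability`` is the lognormal sd on the mixture weights),
    emulating the marked between-individual variability of real plasma.
    Deterministic given ``seed``.
    """
    if n_healthy < 1 or n_cancer < 1:
        raise ValueError("need at least one subject per group")
    outdir = Path(outdir)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genome = build_reference(n_contigs, contig_length, seed=int(rng.integers(2**31)))
    genome.to_fasta(outdir / "reference.fa")
    cna = _default_cna_segments(genome)

    t_pmf = tumor_preset.ladder.length_pmf()
    subjects: list[SubjectTruth] = []
    subject_presets: dict[str, SpeciesPreset] = {}
    for i in range(n_healthy):
        ladder = _perturb_ladder(healthy_preset.ladder, rng, subject_variability)
        sid = f"H{i + 1:03d}"
        subject_presets[sid] = replace(healthy_preset, ladder=ladder)
        subjects.append(SubjectTruth(sid, "healthy", 0.0, [],
                                     expected_short_index(ladder.length_pmf()),
                                     samples_per_subject))
    for i in range(n_cancer):
        ladder = _perturb_ladder(healthy_preset.ladder, rng, subject_variability)
        sid = f"C{i + 1:03d}"
        subject_presets[sid] = replace(healthy_preset, ladder=ladder)
        tf = float(rng.uniform(*tf_range))
        mix_idx = expected_short_index((1 - tf) * ladder.length_pmf() + tf * t_pmf)
        subjects.append(SubjectTruth(sid, "cancer", tf, list(cna),
                                     mix_idx, samples_per_subject))

    sheet_rows, qpcr_frames, truth_rows, seg_rows = [], [], [], []
    for subj in subjects:
        # plasma-level length distribution: the qPCR assay sees the whole
        # tube, not just the sequenced fragments
        subj_pmf = (1 - subj.tumor_fraction) * subject_presets[subj.subject_id].ladder.length_pmf() \
            + subj.tumor_fraction * t_pmf
        for rep in range(1, subj.n_samples + 1):
            sample_id = f"{subj.subject_id}_s{rep}"
            s_seed = int(rng.integers(2**31))
            frags, _ = sample_fragments(
                subj, subject_presets[subj.subject_id], tumor_preset, depth,
                genome, s_seed, apply_end_bias=apply_end_bias,
            )
            write_fragment_tsv(frags, outdir / "fragments" / f"{sample_id}.tsv")
            if write_bam:
                fragments_to_bam(frags, genome, outdir / "fragments" / f"{sample_id}.bam")
            q_seed = int(rng.integers(2**31))
            cq_df, _ = simulate_qpcr(subj_pmf, seed=q_seed, sample_id=sample_id,
                                     noise_sd_cq=noise_sd_cq)
            qpcr_frames.append(cq_df)
            timepoint = "na" if subj.group == "healthy" else (
                "pretreatment" if rep == 1 else "posttreatment"
            )
            sheet_rows.append({"sample_id": sample_id, "subject_id": subj.subject_id,
                               "group": subj.group, "timepoint": timepoint,
                               "species": "canine"})
        truth_rows.append({"subject_id": subj.subject_id, "group": subj.group,
                           "tumor_fraction": subj.tumor_fraction,
                           "true_short_index": subj.true_short_index,
                           "n_samples": subj.n_samples})
        for seg in subj.cna_segments:
            seg_rows.append({"subject_id": subj.subject_id, "chrom": seg.chrom,
                             "start": seg.start, "end": seg.end,
                             "copy_number": seg.copy_number})

    samples = pd.DataFrame(sheet_rows)
    write_sample_sheet(samples, outdir / "samples.csv")
    qpcr = pd.concat(qpcr_frames, ignore_index=True)
    qpcr.to_csv(outdir / "qpcr.csv", index=False)
    make_dilution_series(noise_sd_cq=0.02, seed=seed).to_csv(
        outdir / "dilutions.csv", index=False
    )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(seg_rows).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    return {"outdir": outdir, "genome": genome, "samples": samples,
            "truth": truth, "qpcr": qpcr}


# ---------------------------------------------------------------------------
# Calibrated feature-level cohort (classifier study conditions)
# ---------------------------------------------------------------------------

def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and interquartile range."""
    mu = np.log(median)
    # IQR = median * (e^{z75 s} - e^{-z75 s}) with z75 = Phi^-1(0.75)
    z75 = stats.norm.ppf(0.75)
    sigma = np.arcsinh(iqr / (2 * median)) / z75
    return mu, float(sigma)


@dataclass(frozen=True)
class FeatureCalibration:
    """Median/IQR pairs defining the per-group feature distributions.

    Defaults reproduce the cohort-level contrasts reported for canine plasma:
    qPCR short index 0.196 (IQR 0.095) in healthy dogs vs 0.47 (IQR 0.33) in
    dogs with sarcoma; WGS short-fragment proportion (100-155 bp) 0.31 (0.07)
    vs 0.42 (0.17); long-fragment proportion (250 bp+) 0.194 vs 0.121 (spread
    unreported; sigma 0.30 on the log scale for both).  Tumor fraction is
    detected (> 0.03) in ~55% of cancer samples with detected median 0.184.
    """

    short_index_healthy: tuple[float, float] = (0.196, 0.095)
    short_index_cancer: tuple[float, float] = (0.47, 0.33)
    prop_short_healthy: tuple[float, float] = (0.31, 0.07)
    prop_short_cancer: tuple[float, float] = (0.42, 0.17)
    prop_long_healthy_median: float = 0.194
    prop_long_cancer_median: float = 0.121
    prop_long_sigma: float = 0.30
    tf_detect_rate: float = 0.55
    tf_detected_median: float = 0.184
    tf_detected_sigma: float = 0.80
    tf_noise_max: float = 0.03
    latent_corr: float = 0.6


def simulate_feature_cohort(
    n_healthy: int = 54,
    n_cancer: int = 54,
    samples_per_subject: int = 1,
    seed: int = 0,
    calibration: FeatureCalibration = FeatureCalibration(),
) -> pd.DataFrame:
    """Feature table drawn directly from the calibrated group distributions.

    Each subject carries a latent disease-burden factor shared across its
    features (and its repeat samples), inducing realistic cross-feature
    correlation while preserving the marginal median/IQR calibration.
    Returns a classification-ready table with columns sample_id, subject_id,
    group, timepoint and the four fragmentomic features.
    """
    cal = calibration
    rng = np.random.default_rng(seed)
    rho = cal.latent_corr
    rows = []
    for group, n_subj in (("healthy", n_healthy), ("cancer", n_cancer)):
        si_mu, si_s = _lognormal_params(*(cal.short_index_cancer if group == "cancer"
                                          else cal.short_index_healthy))
        ps_mu, ps_s = _lognormal_params(*(cal.prop_short_cancer if group == "cancer"
                                          else cal.prop_short_healthy))
        pl_med = cal.prop_long_cancer_median if group == "cancer" else cal.prop_long_healthy_median
        for i in range(n_subj):
            sid = f"{group[0].upper()}{i + 1:03d}"
            z = rng.normal()  # subject-level disease-burden latent
            for rep in range(1, samples_per_subject + 1):
                def draw(mu, s):
                    eps = rng.normal()
                    return float(np.exp(mu + s * (rho * z + np.sqrt(1 - rho**2) * eps)))

                short_idx = min(draw(si_mu, si_s), 0.999)
                p_short = min(draw(ps_mu, ps_s), 0.95)
                # long-fragment proportion falls with disease burden
                p_long = min(float(np.exp(np.log(pl_med) + cal.prop_long_sigma *
                                          (-rho * z + np.sqrt(1 - rho**2) * rng.normal()))), 0.95)
                if group == "cancer" and rng.random() < cal.tf_detect_rate:
                    tf = float(np.exp(np.log(cal.tf_detected_median)
                                      + cal.tf_detected_sigma *
                                      (rho * z + np.sqrt(1 - rho**2) * rng.normal())))
                    tf = min(tf, 0.9)
                else:
                    tf = float(rng.uniform(0, cal.tf_noise_max))
                timepoint = "na" if group == "healthy" else (
                    "pretreatment" if rep == 1 else "posttreatment"
                )
                rows.append({"sample_id": f"{sid}_s{rep}", "subject_id": sid,
                             "group": group, "timepoint": timepoint,
                             "short_index_qpcr": short_idx, "tf_ichor": tf,
                             "prop_short_wgs": p_short, "prop_long_wgs": p_long})
    return pd.DataFrame(rows)
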