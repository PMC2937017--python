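"""Synthetic tumour/normal cohorts with planted structure.

The generator plants region aberrations through a latent-factor logistic
model (shared factors with same-sign loadings induce co-occurrence, opposite
signs induce exclusivity), emits copy-number polymorphisms in tumours and
normals alike, fills the background genome with near-neutral segments split
at Poisson breakpoints, and can couple expression and survival to the
planted events.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import CopyNumberProfile, GenomeBuild, Region, Segment


@dataclass(frozen=True)
class SimRegionSpec:
    region: Region
    base_freq: float
    # distribution over log2 levels as (level, weight) pairs
    amplitude_mix: tuple[tuple[float, float], ...]
    factor_loadings: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.base_freq < 1):
            raise ValueError(f"{self.region.label}: base_freq must be in (0, 1)")
        sign = 1.0 if self.region.aber_type == "gain" else -1.0
        for level, weight in self.amplitude_mix:
            if level * sign <= 0:
                raise ValueError(
                    f"{self.region.label}: amplitude {level} inconsistent with "
                    f"{self.region.aber_type}"
                )
            if weight < 0:
                raise ValueError("amplitude weights must be non-negative")


@dataclass(frozen=True)
class CnpSpec:
    region: Region  # provenance should be cnp
    pop_freq: float
    log2: float = 0.55

    def __post_init__(self):
        if not (0 < self.pop_freq < 1):
            raise ValueError("CNP pop_freq must be in (0, 1)")


@dataclass
class SimConfig:
    n_tumours: int
    n_normals: int
    genome: GenomeBuild
    region_specs: list[SimRegionSpec] = field(default_factory=list)
    cnp_specs: list[CnpSpec] = field(default_factory=list)
    n_latent_factors: int = 0
    segment_noise_sd: float = 0.1
    probes_per_mb: float = 100.0
    breakpoint_rate_per_mb: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_tumours < 0 or self.n_normals < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.segment_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        self._validate_planted()

    def _validate_planted(self):
        planted = [s.region for s in self.region_specs] + [
            c.region for c in self.cnp_specs
        ]
        for r in planted:
            if r.chrom not in self.genome:
                raise ValueError(f"planted region {r.label} on unknown {r.chrom}")
            if r.end > self.genome.length(r.chrom):
                raise ValueError(f"planted region {r.label} exceeds chromosome")
        # any overlap among planted intervals would make the truth ambiguous
        # (and same-type overlaps doubly so), so all overlaps are rejected
        by_chrom: dict[str, list[Region]] = {}
        for r in planted:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"planted intervals overlap on {chrom}: "
                        f"{a.label} and {b.label}"
                    )


def _probes(length: int, probes_per_mb: float) -> int:
    return max(1, round(length / 1e6 * probes_per_mb))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_amplitude(
    mix: tuple[tuple[float, float], ...], rng: np.random.Generator
) -> float:
    levels = np.array([m[0] for m in mix])
    weights = np.array([m[1] for m in mix], dtype=float)
    return float(rng.choice(levels, p=weights / weights.sum()))


def _build_profile(
    sample_id: str,
    genome: GenomeBuild,
    events: list[tuple[Region, float]],
    noise_sd: float,
    probes_per_mb: float,
    breakpoint_rate_per_mb: float,
    rng: np.random.Generator,
) -> CopyNumberProfile:
    segments: list[Segment] = []
    by_chrom: dict[str, list[tuple[Region, float]]] = {}
    for region, log2 in events:
        by_chrom.setdefault(region.chrom, []).append((region, log2))
    for chrom in genome.names:
        length = genome.length(chrom)
        chrom_events = sorted(by_chrom.get(chrom, []), key=lambda e: e[0].start)
        pos = 0
        gaps: list[tuple[int, int]] = []
        for region, log2 in chrom_events:
            if region.start > pos:
                gaps.append((pos, region.start))
            segments.append(
                Segment(
                    sample_id, chrom, region.start, region.end,
                    _probes(region.length, probes_per_mb),
                    log2 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                )
            )
            pos = region.end
        if pos < length:
            gaps.append((pos, length))
        for g_start, g_end in gaps:
            span = g_end - g_start
            if noise_sd > 0 and breakpoint_rate_per_mb > 0:
                n_breaks = rng.poisson(breakpoint_rate_per_mb * span / 1e6)
            else:
                n_breaks = 0
            cuts = np.sort(rng.integers(g_start + 1, g_end, size=n_breaks)) if (
                n_breaks and span > 1
            ) else np.array([], dtype=int)
            bounds = [g_start, *np.unique(cuts).tolist(), g_end]
            for b_start, b_end in zip(bounds, bounds[1:]):
                segments.append(
                    Segment(
                        sample_id, chrom, b_start, b_end,
                        _probes(b_end - b_start, probes_per_mb),
                        rng.normal(0.0, noise_sd) if noise_sd else 0.0,
                    )
                )
    return CopyNumberProfile(sample_id, segments)


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[CopyNumberProfile], list[CopyNumberProfile], pd.DataFrame]:
    """Generate (tumour profiles, normal profiles, truth table).

    Region indicators are drawn from
    logit(p) = logit(base_freq) + sum(loading * latent factor); CNPs appear in
    tumours and normals at their population frequency.  The truth table holds
    every planted indicator (regions and CNPs) per sample.
    """
    rng = np.random.default_rng(config.seed)
    tumours: list[CopyNumberProfile] = []
    normals: list[CopyNumberProfile] = []
    truth_rows: list[dict] = []
    region_cols = [s.region.label for s in config.region_specs]
    cnp_cols = [c.region.label for c in config.cnp_specs]

    for t in range(config.n_tumours):
        sample_id = f"T{t + 1:04d}"
        factors = rng.normal(size=config.n_latent_factors)
        events: list[tuple[Region, float]] = []
        row = {"sample_id": sample_id, "kind": "tumour"}
        for spec in config.region_specs:
            eta = math.log(spec.base_freq / (1 - spec.base_freq))
            for f_idx, loading in spec.factor_loadings.items():
                eta += loading * factors[f_idx]
            aberrant = rng.random() < _sigmoid(np.array(eta))
            row[spec.region.label] = int(aberrant)
            if aberrant:
                events.append(
                    (spec.region, _sample_amplitude(spec.amplitude_mix, rng))
                )
        for cnp in config.cnp_specs:
            present = rng.random() < cnp.pop_freq
            row[cnp.region.label] = int(present)
            if present:
                events.append((cnp.region, cnp.log2))
        truth_rows.append(row)
        tumours.append(
            _build_profile(
                sample_id, config.genome, events, config.segment_noise_sd,
                config.probes_per_mb, config.breakpoint_rate_per_mb, rng,
            )
        )

    for t in range(config.n_normals):
        sample_id = f"N{t + 1:04d}"
        events = []
        row = {"sample_id": sample_id, "kind": "normal"}
        for label in region_cols:
            row[label] = 0
        for cnp in config.cnp_specs:
            present = rng.random() < cnp.pop_freq
            row[cnp.region.label] = int(present)
            if present:
                events.append((cnp.region, cnp.log2))
        truth_rows.append(row)
        normals.append(
            _build_profile(
                sample_id, config.genome, events, config.segment_noise_sd,
                config.probes_per_mb, config.breakpoint_rate_per_mb, rng,
            )
        )

    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "kind", *region_cols, *cnp_cols]
    ).set_index("sample_id")
    return tumours, normals, truth


# ---------------------------------------------------------------------------
# expression

@dataclass(frozen=True)
class SimGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    region_label: str | None = None  # None -> background gene


def simulate_expression(
    profiles: Sequence[CopyNumberProfile],
    genes: Sequence[SimGene],
    region_labels: Sequence[str],
    coupling: float,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Genes-by-samples expression: region genes get coupling * gene-level CN
    log2 plus standard-normal noise; background genes are pure noise."""
    from .exprlink import gene_level_cn

    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    known = set(region_labels)
    for g in genes:
        if g.region_label is not None and g.region_label not in known:
            raise ValueError(
                f"gene {g.gene_id} mapped to unknown region {g.region_label!r}"
            )
    rng = np.random.default_rng(seed)
    data = np.zeros((len(genes), len(profiles)))
    for gi, gene in enumerate(genes):
        for si, profile in enumerate(profiles):
            if gene.region_label is None:
                signal = 0.0
            else:
                cn = gene_level_cn(profile, gene.chrom, gene.start, gene.end)
                signal = coupling * (cn if cn is not None else 0.0)
            data[gi, si] = signal + rng.normal(0.0, noise_sd)
    return pd.DataFrame(
        data,
        index=[g.gene_id for g in genes],
        columns=[p.sample_id for p in profiles],
    )


# ---------------------------------------------------------------------------
# survival

def simulate_survival(
    covariate: Sequence[float],
    log_hr: float,
    baseline_rate: float = 0.002,
    censor_max: float | None = 3000.0,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exponential survival with per-sample hazard baseline * exp(log_hr * x)
    and independent uniform censoring; censor_max None disables censoring."""
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    x = np.asarray(covariate, dtype=float)
    rng = np.random.default_rng(seed)
    rates = baseline_rate * np.exp(log_hr * x)
    event_times = rng.exponential(1.0 / rates)
    if censor_max is None:
        times, events = event_times, np.ones(x.size, dtype=int)
    else:
        censor_times = rng.uniform(0.0, censor_max, size=x.size)
        times = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    index = (
        list(sample_ids)
        if sample_ids is not None
        else [f"S{i + 1:04d}" for i in range(x.size)]
    )
    return pd.DataFrame({"time": times, "event": events}, index=index)


# ---------------------------------------------------------------------------
# direct planted-odds-ratio binary matrices (for association benchmarking)

def joint_prob_from_or(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(both) for given marginals and odds ratio (Plackett construction)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1.0:
        return p_a * p_b
    th = odds_ratio
    a = th - 1.0
    b = -((th - 1.0) * (p_a + p_b) + 1.0)
    c = th * p_a * p_b
    disc = b * b - 4 * a * c
    p11 = (-b - math.sqrt(disc)) / (2 * a)
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        p11 = (-b + math.sqrt(disc)) / (2 * a)
    return min(max(p11, lo), hi)


def simulate_planted_matrix(
    n_samples: int,
    n_regions: int,
    planted_pairs: Sequence[tuple[int, int, float]],
    base_freqs: Sequence[float],
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Binary matrix with given per-column frequencies where each planted
    (i, j, odds_ratio) pair is drawn jointly at that odds ratio and all other
    columns are independent.  Planted pairs must be column-disjoint."""
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.size != n_regions:
        raise ValueError("one base frequency per region required")
    used: set[int] = set()
    for i, j, _ in planted_pairs:
        if i in used or j in used or i == j:
            raise ValueError("planted pairs must be column-disjoint")
        used.update((i, j))
    rng = np.random.default_rng(seed)
    X = np.zeros((n_samples, n_regions), dtype=np.int8)
    for i, j, odds_ratio in planted_pairs:
        p11 = joint_prob_from_or(freqs[i], freqs[j], odds_ratio)
        p10 = freqs[i] - p11
        p01 = freqs[j] - p11
        p00 = 1.0 - p11 - p10 - p01
        draws = rng.choice(4, size=n_samples, p=[p11, p10, p01, p00])
        X[:, i] = np.isin(draws, (0, 1))
        X[:, j] = np.isin(draws, (0, 2))
    for c in range(n_regions):
        if c not in used:
            X[:, c] = rng.random(n_samples) < freqs[c]
    return X, [(i, j) for i, j, _ in planted_pairs]


# ---------------------------------------------------------------------------
# config-file bridge

def config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML).

    Expected keys: n_tumours, n_normals, seed, genome {chrom: length},
    regions [{label, chrom, start, end, type, base_freq, amplitudes
    [[log2, weight], ...], loadings {factor: weight}}], cnps [{label, chrom,
    start, end, pop_freq, log2}], n_latent_factors, segment_noise_sd,
    probes_per_mb, breakpoint_rate_per_mb.
    """
    genome = GenomeBuild.from_dict(
        {str(k): int(v) for k, v in raw["genome"].items()}
    )
    specs = []
    for r in raw.get("regions", []):
        region = Region(
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            aber_type=str(r["type"]),
            label=str(r["label"]),
            provenance="tier",
        )
        specs.append(
            SimRegionSpec(
                region=region,
                base_freq=float(r["base_freq"]),
                amplitude_mix=tuple(
                    (float(a), float(w)) for a, w in r["amplitudes"]
                ),
                factor_loadings={
                    int(k): float(v) for k, v in r.get("loadings", {}).items()
                },
            )
        )
    cnps = []
    for c in raw.get("cnps", []):
        cnps.append(
            CnpSpec(
                region=Region(
                    chrom=str(c["chrom"]),
                    start=int(c["start"]),
                    end=int(c["end"]),
                    aber_type="gain",
                    label=str(c["label"]),
                    provenance="cnp",
                ),
                pop_freq=float(c["pop_freq"]),
                log2=float(c.get("log2", 0.55)),
            )
        )
    return SimConfig(
        n_tumours=int(raw["n_tumours"]),
        n_normals=int(raw.get("n_normals", 0)),
        genome=genome,
        region_specs=specs,
        cnp_specs=cnps,
        n_latent_factors=int(raw.get("n_latent_factors", 0)),
        segment_noise_sd=float(raw.get("segment_noise_sd", 0.1)),
        probes_per_mb=float(raw.get("probes_per_mb", 100.0)),
        breakpoint_rate_per_mb=float(raw.get("breakpoint_rate_per_mb", 0.02)),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# an example configuration usable out of the box

def example_genome() -> GenomeBuild:
    return GenomeBuild.from_dict(
        {
            "chr3": 199_000_000,
            "chr8": 146_000_000,
            "chr17": 79_000_000,
            "chr19": 64_000_000,
            "chr20": 62_000_000,
            "chrX": 155_000_000,
        }
    )


def example_config(
    n_tumours: int = 200, n_normals: int = 50, seed: int = 0
) -> SimConfig:
    """A compact cohort with frequent gains, a co-occurring pair (chr19/chr20
    gains on a shared factor), an anti-occurring pair, and two CNPs."""
    gain_mix = ((0.4, 0.5), (0.7, 0.25), (0.9, 0.15), (1.2, 0.1))
    loss_mix = ((-0.5, 0.85), (-1.3, 0.15))

    def gain(label, chrom, start, end):
        return Region(chrom, int(start), int(end), "gain", label, "tier")

    def loss(label, chrom, start, end):
        return Region(chrom, int(start), int(end), "loss", label, "tier")

    specs = [
        SimRegionSpec(gain("gain_3q", "chr3", 160e6, 190e6), 0.63, gain_mix),
        SimRegionSpec(gain("gain_8q", "chr8", 100e6, 140e6), 0.62, gain_mix),
        SimRegionSpec(
            gain("gain_20q11", "chr20", 29e6, 35e6), 0.37, gain_mix, {0: 1.4}
        ),
        SimRegionSpec(
            gain("gain_19q12", "chr19", 34e6, 36e6), 0.33, gain_mix, {0: 1.4}
        ),
        SimRegionSpec(
            loss("loss_Xq", "chrX", 80e6, 150e6), 0.45, loss_mix, {1: 1.2}
        ),
        SimRegionSpec(
            loss("loss_17q", "chr17", 25e6, 40e6), 0.40, loss_mix, {1: -1.2}
        ),
    ]
    cnps = [
        CnpSpec(
            Region("chr8", 7_000_000, 8_200_000, "gain", "cnp_8p", "cnp"), 0.30
        ),
        CnpSpec(
            Region("chr19", 20_000_000, 20_800_000, "gain", "cnp_19p", "cnp"), 0.25
        ),
    ]
    return SimConfig(
        n_tumours=n_tumours,
        n_normals=n_normals,
        genome=example_genome(),
        region_specs=specs,
        cnp_specs=cnps,
        n_latent_factors=2,
        segment_noise_sd=0.08,
        probes_per_mb=30.0,
        breakpoint_rate_per_mb=0.02,
        seed=seed,
    )
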