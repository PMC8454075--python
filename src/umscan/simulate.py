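"""Synthetic fluorescence cohorts with twin structure and artifact patterns.

The generator emulates the cluster geometries that raw two-channel
methylation arrays actually display, so that every statistic, clustering
routine and classifier in this package can be exercised at desk scale with
known truth:

* fully methylated / unmethylated probes arrange as vertical / horizontal
  lines in the U/M plane, elongated by per-array (lognormal) variation in
  total fluorescence intensity;
* intermediate methylation spreads along the diagonal;
* probe failure clumps near the origin at background fluorescence;
* genotype-dependent patterns (CpG-SNPs disguising as an epiallele, SNPs
  causing failure, channel switches, two-SNP haplotype systems, triallelic
  sites) draw genotypes from Hardy-Weinberg proportions with monozygotic
  co-twins sharing every draw;
* Y probes fail in females ("exclamation mark"), X-inactivation splits the
  sexes into V-shaped clusters, X-hypermethylation halves male intensity on
  the methylated axis.

Bead-level channel SDs are emitted with shot-noise-like sqrt(mean) scaling
and a background floor, jittered as if estimated from a finite bead pool, so
the noise statistics computed downstream are informative.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .intensity import (
    CohortDesign,
    InfiniumType,
    IntensityMatrices,
    ProbeDesign,
    Sex,
    Strand,
    write_cohort,
    write_intensity_tables,
    write_manifest,
)

__all__ = [
    "Pattern",
    "ProbePatternSpec",
    "CohortSpec",
    "SimulatedProbe",
    "SimulatedDataset",
    "simulate_cohort",
    "simulate_probe",
    "simulate_dataset",
    "simulate_region",
    "simulate_chromosome",
    "write_fixture",
    "load_fixture_config",
    "EXPECTED_K",
]


class Pattern(str, Enum):
    CONSTANT_U = "CONSTANT_U"
    CONSTANT_M = "CONSTANT_M"
    INTERMEDIATE = "INTERMEDIATE"
    SNP_3CLUSTER = "SNP_3CLUSTER"
    SNP_EQ_U = "SNP_EQ_U"
    SNP_EQ_M = "SNP_EQ_M"
    SNP_EQ_PF = "SNP_EQ_PF"
    CHANNEL_SWITCH = "CHANNEL_SWITCH"
    TWO_SNP_4CLUSTER = "TWO_SNP_4CLUSTER"
    TRIALLELIC = "TRIALLELIC"
    Y_PROBE = "Y_PROBE"
    X_INACTIVATION = "X_INACTIVATION"
    X_HYPERMETH = "X_HYPERMETH"
    MEQTL_BLOCK = "MEQTL_BLOCK"


#: Number of U/M clusters each pattern is built to display in a large cohort.
EXPECTED_K: dict[Pattern, int] = {
    Pattern.CONSTANT_U: 1,
    Pattern.CONSTANT_M: 1,
    Pattern.INTERMEDIATE: 1,
    Pattern.SNP_3CLUSTER: 3,
    Pattern.SNP_EQ_U: 3,  # within a methylated region
    Pattern.SNP_EQ_M: 3,  # within an unmethylated region
    Pattern.SNP_EQ_PF: 2,
    Pattern.CHANNEL_SWITCH: 3,
    Pattern.TWO_SNP_4CLUSTER: 4,
    Pattern.TRIALLELIC: 3,
    Pattern.Y_PROBE: 2,
    Pattern.X_INACTIVATION: 2,
    Pattern.X_HYPERMETH: 1,
    Pattern.MEQTL_BLOCK: 3,
}


@dataclass(frozen=True)
class ProbePatternSpec:
    """Geometry and genetics of a single simulated probe.

    ``intensity_scale`` is the mean total fluorescence of a fully detecting
    sample (arbitrary scanner units); ``noise_sd`` the within-cluster channel
    SD at full intensity; ``sample_scale_sd`` the log-sd of a per-sample,
    per-probe multiplicative brightness jitter shared by both channels (DNA
    input / amplification variation, which blurs points along rays from the
    origin); ``background`` the (mean, sd) of the near-origin signal every
    channel acquires.  ``maf`` drives Hardy-Weinberg genotype
    draws; ``hap_freqs`` the four haplotype frequencies of the two-SNP
    pattern.  For meQTL blocks, ``meth_levels`` are the per-genotype beta
    levels and ``n_neighbors``/``window_bp`` place co-methylated neighbors.
    """

    pattern: Pattern
    maf: float = 0.5
    hap_freqs: tuple[float, float, float, float] = (0.6, 0.13, 0.27, 0.0)
    intensity_scale: float = 4000.0
    noise_sd: float = 300.0
    sample_scale_sd: float = 0.13
    background: tuple[float, float] = (250.0, 60.0)
    meth_levels: tuple[float, float, float] = (0.1, 0.5, 0.9)
    n_neighbors: int = 5
    window_bp: int = 800

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        if abs(sum(self.hap_freqs) - 1.0) > 1e-9 or min(self.hap_freqs) < 0:
            raise ValueError("hap_freqs must lie on the simplex")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if self.noise_sd < 0 or min(self.background) < 0 or self.sample_scale_sd < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Twin-cohort layout: 2*n_pairs samples on lognormal-intensity arrays."""

    n_pairs: int = 426
    female_fraction: float = 0.5
    n_batches: int = 8
    batch_scale_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.batch_scale_sd < 0:
            raise ValueError("batch_scale_sd must be >= 0")


def simulate_cohort(spec: CohortSpec) -> tuple[CohortDesign, pd.Series]:
    """Draw a twin cohort and per-sample multiplicative intensity factors.

    Twins share sex and pair id; every sample sits on its own array, so batch
    factors (lognormal with log-sd ``batch_scale_sd``) are independent even
    within a pair.
    """
    rng = np.random.default_rng(spec.seed)
    ids, pair_id, sex, batch = [], {}, {}, {}
    for p in range(spec.n_pairs):
        s = Sex.F if rng.random() < spec.female_fraction else Sex.M
        pid = f"pair{p:04d}"
        for suffix in "ab":
            sid = f"tw{p:04d}{suffix}"
            ids.append(sid)
            pair_id[sid] = pid
            sex[sid] = s
            batch[sid] = f"batch{rng.integers(spec.n_batches):02d}"
    factors = pd.Series(
        np.exp(rng.normal(0.0, spec.batch_scale_sd, size=len(ids))), index=ids
    )
    return CohortDesign(ids, pair_id, sex, batch), factors


@dataclass
class SimulatedProbe:
    """One probe row plus the generating truth for oracle tests."""

    probe_id: str
    u: np.ndarray
    m: np.ndarray
    sigma_u: np.ndarray
    sigma_m: np.ndarray
    genotype: np.ndarray  # alt-allele dose, haplotype-pair code, or -1
    expected_k: int
    pattern: Pattern


def _hwe_genotypes(maf: float, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Per-pair genotype (alt dose 0/1/2) from HWE, duplicated onto co-twins."""
    q = maf
    per_pair = rng.choice(3, size=n_pairs, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])
    return np.repeat(per_pair, 2)


def _diplotypes(freqs: np.ndarray, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Per-pair unordered haplotype pairs, duplicated onto co-twins; (n, 2)."""
    h = rng.choice(len(freqs), size=(n_pairs, 2), p=freqs)
    h.sort(axis=1)
    return np.repeat(h, 2, axis=0)


# per-allele readout classes: fraction of half-scale landing on (U, M)
_READOUT = {"U": (1.0, 0.0), "M": (0.0, 1.0), "PF": (0.0, 0.0)}


def _emit_signals(
    u: np.ndarray,
    m: np.ndarray,
    pattern: ProbePatternSpec,
    factors: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Turn clean cluster centers into observed means and bead SDs."""
    n = len(factors)
    bright = factors
    if pattern.sample_scale_sd > 0:
        # bounded (log-uniform) jitter with log-sd sample_scale_sd: brightness
        # variation within an array run has limited range, unlike the
        # between-array lognormal factor
        half_width = pattern.sample_scale_sd * np.sqrt(3.0)
        bright = factors * np.exp(rng.uniform(-half_width, half_width, size=n))
    bg_mean, bg_sd = pattern.background
    scale = pattern.intensity_scale
    mean_u = (u + bg_mean) * bright
    mean_m = (m + bg_mean) * bright
    # across-bead SD per channel: shot-noise-like sqrt(mean) scaling with a
    # background floor; the reported channel value is a mean over ~14 beads,
    # so its sampling noise is the bead SD shrunk by sqrt(n_beads)
    n_beads = 14.0
    sd_u = np.maximum(pattern.noise_sd * np.sqrt(mean_u / scale), bg_sd)
    sd_m = np.maximum(pattern.noise_sd * np.sqrt(mean_m / scale), bg_sd)
    obs_u = np.maximum(rng.normal(mean_u, sd_u / np.sqrt(n_beads)), 0.0)
    obs_m = np.maximum(rng.normal(mean_m, sd_m / np.sqrt(n_beads)), 0.0)
    # stored SDs carry the chi-type estimation jitter of a finite bead pool
    nu = n_beads - 1.0
    sigma_u = sd_u * np.sqrt(rng.chisquare(nu, size=n) / nu)
    sigma_m = sd_m * np.sqrt(rng.chisquare(nu, size=n) / nu)
    return obs_u, obs_m, sigma_u, sigma_m

# allele readouts of the two-SNP pattern: reference haplotype reads methylated,
# the CpG-C SNP haplotype disguises as U, haplotypes carrying the CpG-G SNP
# fail; the double-mutant haplotype exists but is typically near-absent for
# adjacent cis variants
_TWO_SNP_READOUTS = ("M", "U", "PF", "PF")


def _genotype_centers(readout_a: str, readout_b: str, dose: np.ndarray, scale: float):
    """Cluster centers for a biallelic readout pair given alt dose 0/1/2."""
    ua, ma = _READOUT[readout_a]
    ub, mb = _READOUT[readout_b]
    w = dose / 2.0
    u = scale * ((1 - w) * ua + w * ub)
    m = scale * ((1 - w) * ma + w * mb)
    return u, m


def simulate_probe(
    pattern: ProbePatternSpec,
    cohort: CohortDesign,
    batch_factors: pd.Series,
    rng: np.random.Generator,
    probe_id: str = "cg_sim",
) -> SimulatedProbe:
    """Simulate one probe row across the cohort.

    Genotypes are drawn per pair (twins share them), mapped to cluster
    centers by the pattern, multiplied by each sample's array factor, and
    jittered with truncated Gaussian within-cluster noise.  Emitted channel
    SDs scale as noise_sd * sqrt(mean/intensity_scale) with a background
    floor, multiplied by a chi-based estimation jitter (bead pool of 14).
    """
    n = len(cohort.sample_ids)
    n_pairs = n // 2
    scale = pattern.intensity_scale
    bg_mean, bg_sd = pattern.background
    p = pattern.pattern
    genotype = np.full(n, -1, dtype=int)

    if p is Pattern.CONSTANT_U:
        u, m = np.full(n, scale), np.zeros(n)
        genotype[:] = 0
    elif p is Pattern.CONSTANT_M:
        u, m = np.zeros(n), np.full(n, scale)
        genotype[:] = 0
    elif p is Pattern.INTERMEDIATE:
        u, m = np.full(n, scale / 2), np.full(n, scale / 2)
        genotype[:] = 0
    elif p in (
        Pattern.SNP_3CLUSTER,
        Pattern.SNP_EQ_U,
        Pattern.CHANNEL_SWITCH,
        Pattern.TRIALLELIC,
    ):
        # reference allele reads methylated; the artifact allele reads U
        # (for the triallelic pattern two alt alleles collapse onto U)
        genotype = _hwe_genotypes(pattern.maf, n_pairs, rng)
        u, m = _genotype_centers("M", "U", genotype, scale)
    elif p is Pattern.SNP_EQ_M:
        genotype = _hwe_genotypes(pattern.maf, n_pairs, rng)
        u, m = _genotype_centers("U", "M", genotype, scale)
    elif p is Pattern.SNP_EQ_PF:
        genotype = _hwe_genotypes(pattern.maf, n_pairs, rng)
        u, m = _genotype_centers("M", "PF", genotype, scale)
    elif p is Pattern.TWO_SNP_4CLUSTER:
        dip = _diplotypes(np.asarray(pattern.hap_freqs), n_pairs, rng)
        genotype = dip[:, 0] * 4 + dip[:, 1]  # packed unordered pair code
        u = np.zeros(n)
        m = np.zeros(n)
        for hap in range(4):
            uh, mh = _READOUT[_TWO_SNP_READOUTS[hap]]
            dose = (dip == hap).sum(axis=1)
            u += scale / 2 * uh * dose
            m += scale / 2 * mh * dose
    elif p is Pattern.Y_PROBE:
        female = np.array([cohort.sex[s] is Sex.F for s in cohort.sample_ids])
        genotype = (~female).astype(int)
        u = np.zeros(n)
        m = np.where(female, 0.0, scale)  # males read fully methylated
    elif p is Pattern.X_INACTIVATION:
        female = np.array([cohort.sex[s] is Sex.F for s in cohort.sample_ids])
        genotype = female.astype(int)
        # females: one X silenced at random -> intermediate; males: one
        # active unmethylated X
        u = np.where(female, scale / 2, scale)
        m = np.where(female, scale / 2, 0.0)
    elif p is Pattern.X_HYPERMETH:
        female = np.array([cohort.sex[s] is Sex.F for s in cohort.sample_ids])
        genotype = female.astype(int)
        u = np.zeros(n)
        m = np.where(female, scale, scale / 2)  # copy-number halves male signal
    elif p is Pattern.MEQTL_BLOCK:
        genotype = _hwe_genotypes(pattern.maf, n_pairs, rng)
        beta = np.asarray(pattern.meth_levels)[genotype]
        u, m = scale * (1 - beta), scale * beta
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {p!r}")

    factors = batch_factors.loc[list(cohort.sample_ids)].to_numpy()
    obs_u, obs_m, sigma_u, sigma_m = _emit_signals(u, m, pattern, factors, rng)
    return SimulatedProbe(
        probe_id=probe_id,
        u=obs_u,
        m=obs_m,
        sigma_u=sigma_u,
        sigma_m=sigma_m,
        genotype=genotype,
        expected_k=EXPECTED_K[p],
        pattern=p,
    )


@dataclass
class SimulatedDataset:
    """A complete synthetic dataset: matrices, designs, cohort, truth, config."""

    intensities: IntensityMatrices
    cohort: CohortDesign
    designs: dict[str, ProbeDesign]
    truth: pd.DataFrame  # per probe: pattern, expected_k; genotypes separate
    genotypes: pd.DataFrame  # probes x samples
    batch_factors: pd.Series
    config: dict

    def points(self, probe_id: str) -> np.ndarray:
        return self.intensities.points(probe_id)


def _assemble(
    probes: list[SimulatedProbe],
    cohort: CohortDesign,
    designs: dict[str, ProbeDesign],
    batch_factors: pd.Series,
    config: dict,
) -> SimulatedDataset:
    idx = pd.Index([p.probe_id for p in probes], name="probe_id")
    cols = pd.Index(cohort.sample_ids, name="sample_id")
    stack = lambda attr: pd.DataFrame(
        np.vstack([getattr(p, attr) for p in probes]), index=idx, columns=cols
    )
    intens = IntensityMatrices(
        U=stack("u"), M=stack("m"), sigma_U=stack("sigma_u"), sigma_M=stack("sigma_m")
    )
    truth = pd.DataFrame(
        {
            "pattern": [p.pattern.value for p in probes],
            "expected_k": [p.expected_k for p in probes],
        },
        index=idx,
    )
    genotypes = stack("genotype").astype(int)
    return SimulatedDataset(intens, cohort, designs, truth, genotypes, batch_factors, config)


def simulate_dataset(
    cohort_spec: CohortSpec,
    patterns: Mapping[str, ProbePatternSpec],
    designs: Mapping[str, ProbeDesign] | None = None,
) -> SimulatedDataset:
    """Simulate a named set of probes over one cohort (seed from the spec)."""
    cohort, factors = simulate_cohort(cohort_spec)
    rng = np.random.default_rng(cohort_spec.seed + 1)
    probes = [
        simulate_probe(ps, cohort, factors, rng, probe_id=pid)
        for pid, ps in patterns.items()
    ]
    if designs is None:
        designs = {
            pid: ProbeDesign(
                pid, InfiniumType.II, Strand.PLUS, chrom="chrS", cpg_pos=1000 + 100 * i
            )
            for i, pid in enumerate(patterns)
        }
    config = {
        "cohort": asdict(cohort_spec),
        "patterns": {
            pid: {**asdict(ps), "pattern": ps.pattern.value}
            for pid, ps in patterns.items()
        },
    }
    return _assemble(probes, cohort, dict(designs), factors, config)


def simulate_region(
    pattern: ProbePatternSpec,
    cohort: CohortDesign,
    batch_factors: pd.Series,
    rng: np.random.Generator,
    chrom: str = "chrS",
    start_pos: int = 10_000,
    prefix: str = "cg_region",
    ld_genotype: np.ndarray | None = None,
) -> tuple[list[SimulatedProbe], dict[str, ProbeDesign]]:
    """Simulate a genomic neighborhood around one focal probe.

    For ``MEQTL_BLOCK`` the focal probe and its ``n_neighbors`` neighbors all
    read the *same* per-individual genotype (co-methylation); for artifact
    patterns the focal probe draws its own genotype while neighbors are
    genuine invariant probes, so co-methylation is absent.  ``ld_genotype``
    forces the focal genotype (used to correlate genotypes of nearby
    artifact probes, emulating linkage disequilibrium).
    """
    n_pairs = len(cohort.sample_ids) // 2
    probes: list[SimulatedProbe] = []
    designs: dict[str, ProbeDesign] = {}
    n_flank = pattern.n_neighbors
    positions = np.linspace(0, pattern.window_bp, n_flank + 1).astype(int) + start_pos

    if pattern.pattern is Pattern.MEQTL_BLOCK:
        genotype = (
            ld_genotype
            if ld_genotype is not None
            else _hwe_genotypes(pattern.maf, n_pairs, rng)
        )
        for i, pos in enumerate(positions):
            pid = f"{prefix}_{i:02d}"
            beta = np.asarray(pattern.meth_levels)[genotype]
            sim = simulate_probe(
                replace(pattern, pattern=Pattern.INTERMEDIATE),
                cohort, batch_factors, rng, probe_id=pid,
            )
            # overwrite the geometry with the shared genotype effect
            scale = pattern.intensity_scale
            factors = batch_factors.loc[list(cohort.sample_ids)].to_numpy()
            sim.u, sim.m, sim.sigma_u, sim.sigma_m = _emit_signals(
                scale * (1 - beta), scale * beta, pattern, factors, rng
            )
            sim.genotype = genotype
            sim.expected_k = EXPECTED_K[Pattern.MEQTL_BLOCK]
            sim.pattern = Pattern.MEQTL_BLOCK
            probes.append(sim)
            designs[pid] = ProbeDesign(
                pid, InfiniumType.II, Strand.PLUS, chrom=chrom, cpg_pos=int(pos)
            )
    else:
        focal = simulate_probe(pattern, cohort, batch_factors, rng, probe_id=f"{prefix}_00")
        if ld_genotype is not None:
            # replay with the forced genotype: regenerate centers deterministically
            forced = replace(pattern)
            focal = _forced_genotype_probe(forced, cohort, batch_factors, rng,
                                           f"{prefix}_00", ld_genotype)
        probes.append(focal)
        designs[focal.probe_id] = ProbeDesign(
            focal.probe_id, InfiniumType.II, Strand.PLUS, chrom=chrom, cpg_pos=int(positions[0])
        )
        flank_patterns = [Pattern.CONSTANT_M, Pattern.CONSTANT_U, Pattern.INTERMEDIATE]
        for i, pos in enumerate(positions[1:], start=1):
            pid = f"{prefix}_{i:02d}"
            fp = replace(pattern, pattern=flank_patterns[i % 3])
            probes.append(simulate_probe(fp, cohort, batch_factors, rng, probe_id=pid))
            designs[pid] = ProbeDesign(
                pid, InfiniumType.II, Strand.PLUS, chrom=chrom, cpg_pos=int(pos)
            )
    return probes, designs


def _forced_genotype_probe(pattern, cohort, batch_factors, rng, probe_id, genotype):
    sim = simulate_probe(pattern, cohort, batch_factors, rng, probe_id=probe_id)
    scale = pattern.intensity_scale
    readouts = {
        Pattern.SNP_EQ_U: ("M", "U"),
        Pattern.SNP_3CLUSTER: ("M", "U"),
        Pattern.SNP_EQ_M: ("U", "M"),
        Pattern.SNP_EQ_PF: ("M", "PF"),
        Pattern.CHANNEL_SWITCH: ("M", "U"),
    }[pattern.pattern]
    u, m = _genotype_centers(*readouts, genotype, scale)
    factors = batch_factors.loc[list(cohort.sample_ids)].to_numpy()
    sim.u, sim.m, sim.sigma_u, sim.sigma_m = _emit_signals(u, m, pattern, factors, rng)
    sim.genotype = genotype
    return sim


def simulate_chromosome(
    cohort_spec: CohortSpec,
    n_meqtl: int = 50,
    n_artifact: int = 50,
    meqtl_pattern: ProbePatternSpec | None = None,
    artifact_pattern: ProbePatternSpec | None = None,
    ld_mode: bool = False,
    ld_copy_prob: float = 0.9,
    region_spacing_bp: int = 10_000,
) -> SimulatedDataset:
    """A synthetic chromosome interleaving meQTL blocks and artifact probes.

    meQTL blocks are co-methylated neighborhoods driven by a shared genotype;
    artifact probes (a CpG-SNP disguising as the unmethylated epiallele in a
    methylated background) sit among unrelated invariant neighbors.  With
    ``ld_mode`` the genotypes of consecutive artifact probes are copied with
    probability ``ld_copy_prob`` and the artifact probes are placed within
    each other's co-methylation window, reproducing the linkage-
    disequilibrium failure mode of co-methylation-based discrimination.
    """
    cohort, factors = simulate_cohort(cohort_spec)
    rng = np.random.default_rng(cohort_spec.seed + 2)
    n_pairs = cohort_spec.n_pairs
    meqtl_pattern = meqtl_pattern or ProbePatternSpec(Pattern.MEQTL_BLOCK)
    artifact_pattern = artifact_pattern or ProbePatternSpec(Pattern.SNP_EQ_U)
    probes: list[SimulatedProbe] = []
    designs: dict[str, ProbeDesign] = {}
    pos = 100_000
    for i in range(n_meqtl):
        ps, ds = simulate_region(
            meqtl_pattern, cohort, factors, rng,
            start_pos=pos, prefix=f"cg_meqtl{i:03d}",
        )
        probes += ps
        designs.update(ds)
        pos += region_spacing_bp

    prev_genotype: np.ndarray | None = None
    for i in range(n_artifact):
        if ld_mode and prev_genotype is not None and rng.random() < ld_copy_prob:
            genotype = prev_genotype
        else:
            genotype = _hwe_genotypes(artifact_pattern.maf, n_pairs, rng)
        prev_genotype = genotype
        if ld_mode:
            # pack artifact probes close together so they fall inside each
            # other's window and become each other's neighbors
            pid = f"cg_artif{i:03d}_00"
            probes.append(
                _forced_genotype_probe(
                    artifact_pattern, cohort, factors, rng, pid, genotype
                )
            )
            designs[pid] = ProbeDesign(
                pid, InfiniumType.II, Strand.PLUS, chrom="chrS",
                cpg_pos=pos + i * 300,
            )
        else:
            ps, ds = simulate_region(
                artifact_pattern, cohort, factors, rng,
                start_pos=pos, prefix=f"cg_artif{i:03d}", ld_genotype=genotype,
            )
            probes += ps
            designs.update(ds)
            pos += region_spacing_bp

    config = {
        "cohort": asdict(cohort_spec),
        "chromosome": {
            "n_meqtl": n_meqtl,
            "n_artifact": n_artifact,
            "ld_mode": ld_mode,
            "ld_copy_prob": ld_copy_prob,
        },
    }
    return _assemble(probes, cohort, designs, factors, config)


# ---------------------------------------------------------------------------
# fixture round trip


def write_fixture(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as re-readable plain-text files.

    Emits the four intensity TSVs, the manifest, the cohort table, the truth
    table (pattern labels and per-sample genotypes) and the generating
    configuration (YAML); everything reads back through the intensity module
    and the config replays the dataset bit-identically through
    ``simulate_dataset``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_intensity_tables(dataset.intensities, directory)
    paths["manifest"] = directory / "manifest.tsv"
    write_manifest(dataset.designs.values(), paths["manifest"])
    paths["cohort"] = directory / "cohort.tsv"
    write_cohort(dataset.cohort, paths["cohort"])
    paths["truth"] = directory / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t")
    paths["genotypes"] = directory / "genotypes.tsv"
    dataset.genotypes.to_csv(paths["genotypes"], sep="\t")
    paths["config"] = directory / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config, fh, sort_keys=True)
    return paths


def load_fixture_config(path: str | Path) -> SimulatedDataset:
    """Replay a dataset from its generating config (seed contract)."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    cohort_spec = CohortSpec(**config["cohort"])
    if "patterns" not in config:
        raise ValueError("only pattern-map configs can be replayed")
    patterns = {
        pid: ProbePatternSpec(
            **{**cfg, "pattern": Pattern(cfg["pattern"]),
               "hap_freqs": tuple(cfg["hap_freqs"]),
               "background": tuple(cfg["background"]),
               "meth_levels": tuple(cfg["meth_levels"])}
        )
        for pid, cfg in config["patterns"].items()
    }
    return simulate_dataset(cohort_spec, patterns)
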