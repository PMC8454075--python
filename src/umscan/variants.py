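"""Genetic interpretation of U/M clusters and mechanistic SNP classification.

Once clusters in the U/M plane are mapped to genotypes, minor allele
frequencies follow from cluster counts -- with monozygotic twins as a
genetic control, only pairs assigned concordantly are counted, one genotype
per pair.  For a CpG flanked by two SNPs, the ten diplotypes of four
haplotypes map onto U/M clusters and haplotype frequencies are recovered by
maximizing a multinomial likelihood over the frequency simplex.

The mechanistic classifier predicts how a variant at the CpG C, the CpG G or
the type I single-base-extension (SBE) site manifests, by simulating
bisulfite conversion of both alleles on the targeted strand and asking
whether the resulting template mimics the converted unmethylated sequence
(``SNP_EQ_U``), the protected methylated sequence (``SNP_EQ_M``), abolishes
probe extension (``SNP_EQ_PF``), or -- at type I SBE sites -- moves the
extended base between the red (A/T) and green (C/G) fluorophore groups
(``CHANNEL_SWITCH`` vs ``NO_CHANNEL_CHANGE``).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax

from .intensity import CohortDesign, InfiniumType, ProbeDesign, Strand

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "Site",
    "ArtifactCategory",
    "ArtifactCall",
    "MafEstimate",
    "HaplotypeFreqs",
    "estimate_maf",
    "hwe_proportions",
    "estimate_haplotype_freqs",
    "classify_cpg_sbe_snp",
    "classify_multiallelic",
    "predict_probe_body_snp",
    "internal_cpg_failure_adjustment",
    "enumerate_categories",
    "read_vcf_variants",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VariantRecord:
    """A variant in plus-strand coordinates (1-based) with per-population MAF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    maf_by_pop: Mapping[str, float] = field(default_factory=dict)
    variant_id: str | None = None

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"alleles must be non-empty over ACGT, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for pop, maf in self.maf_by_pop.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"MAF for {pop} outside [0, 0.5]: {maf}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1

    @property
    def span(self) -> tuple[int, int]:
        """1-based closed interval of reference bases replaced."""
        return self.pos, self.pos + len(self.ref) - 1


class Site(str, Enum):
    CPG_C = "CPG_C"
    CPG_G = "CPG_G"
    SBE = "SBE"
    NONE = "NONE"


class ArtifactCategory(str, Enum):
    SNP_EQ_U = "SNP_EQ_U"
    SNP_EQ_M = "SNP_EQ_M"
    SNP_EQ_PF = "SNP_EQ_PF"
    CHANNEL_SWITCH = "CHANNEL_SWITCH"
    NO_CHANNEL_CHANGE = "NO_CHANNEL_CHANGE"
    NOT_AFFECTED = "NOT_AFFECTED"
    UNRESOLVED_INDEL = "UNRESOLVED_INDEL"


# expected number of U/M clusters per category for a common biallelic variant;
# None marks the context rule (1 in a region matching the mimicked epiallele,
# 3 otherwise)
_EXPECTED_K = {
    ArtifactCategory.SNP_EQ_U: None,
    ArtifactCategory.SNP_EQ_M: None,
    ArtifactCategory.SNP_EQ_PF: 2,
    ArtifactCategory.CHANNEL_SWITCH: 3,
    ArtifactCategory.NO_CHANNEL_CHANGE: 1,
    ArtifactCategory.NOT_AFFECTED: 1,
    ArtifactCategory.UNRESOLVED_INDEL: None,
}


@dataclass(frozen=True)
class ArtifactCall:
    """Classification outcome for one (probe, variant) pair."""

    category: ArtifactCategory
    site: Site
    expected_k: int | None  # None = context-dependent (see expected_k_in_context)
    flags: frozenset[str] = frozenset()

    def expected_k_in_context(self, region_methylated: bool | None = None) -> int | None:
        """Resolve the context rule for epiallele-mimicking categories.

        A variant disguising as the unmethylated epiallele is invisible in an
        unmethylated region (K=1) and forms three genotype clusters in a
        methylated one; symmetrically for ``SNP_EQ_M``.
        """
        if self.expected_k is not None:
            return self.expected_k
        if region_methylated is None:
            return None
        if self.category is ArtifactCategory.SNP_EQ_U:
            return 3 if region_methylated else 1
        if self.category is ArtifactCategory.SNP_EQ_M:
            return 1 if region_methylated else 3
        return None


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _site_of(design: ProbeDesign, pos: int) -> Site:
    """Which sensitive site a plus-strand position hits for this probe."""
    plus = design.strand is Strand.PLUS
    if pos == (design.cpg_pos if plus else design.cpg_pos + 1):
        return Site.CPG_C
    if pos == (design.cpg_pos + 1 if plus else design.cpg_pos):
        return Site.CPG_G
    if design.is_type_i and pos == design.sbe_pos:
        return Site.SBE
    return Site.NONE


def _bisulfite(base: str) -> str:
    """Post-conversion identity of an unmethylated, non-CpG-protected base."""
    return "T" if base == "C" else base


def _sbe_channel(template_base: str) -> str:
    """Fluorophore group of the base extended against a converted template.

    ddATP/ddTTP carry the red label, ddCTP/ddGTP the green one; the extended
    base is the complement of the template base, so templates A/T read red
    and G/C read green.  On a converted template a C only survives inside a
    protected CpG, which cannot occur at the SBE site, so conversion is
    applied before grouping.
    """
    b = _bisulfite(template_base)
    return "GRN" if b in "CG" else "RED"


def classify_cpg_sbe_snp(design: ProbeDesign, variant: VariantRecord) -> ArtifactCall:
    """Mechanistic category of a variant at the CpG C, CpG G or SBE site.

    The variant is given on the plus strand; for minus-strand probes alleles
    are reverse-complemented onto the targeted strand first.  The category is
    a pure function of (infinium_type, strand, site, ref, alt).  Variants
    outside the three sites return ``NOT_AFFECTED``; indels are resolved only
    as probe-failure candidates when they delete the CpG, otherwise
    ``UNRESOLVED_INDEL``.
    """
    if variant.is_indel:
        return _classify_indel(design, variant)
    site = _site_of(design, variant.pos)
    if site is Site.NONE:
        cat = ArtifactCategory.NOT_AFFECTED
        return ArtifactCall(cat, site, _EXPECTED_K[cat])
    minus = design.strand is Strand.MINUS
    ref = _revcomp(variant.ref) if minus else variant.ref
    alt = _revcomp(variant.alt) if minus else variant.alt
    flags: set[str] = set()

    if site is Site.CPG_C:
        if ref != "C":
            raise ValueError(
                f"probe {design.probe_id}: targeted-strand CpG C expected as "
                f"reference, got {ref!r}"
            )
        # the alt allele destroys the CpG, so the alt chromosome carries no
        # methylation at this site and any C it contributes converts
        if design.infinium_type is InfiniumType.II:
            # SBE happens at this very position: T/A templates read red (= U),
            # G templates read green (= M); hybridization is untouched
            cat = (
                ArtifactCategory.SNP_EQ_M if alt == "G" else ArtifactCategory.SNP_EQ_U
            )
        else:
            # type I probes terminate on this base: T matches the
            # unmethylated-design probe, G pairs with the methylated-design
            # probe's terminal C, A matches neither and kills extension
            cat = {
                "T": ArtifactCategory.SNP_EQ_U,
                "G": ArtifactCategory.SNP_EQ_M,
                "A": ArtifactCategory.SNP_EQ_PF,
            }[alt]
    elif site is Site.CPG_G:
        # destroying the G removes the CpG: the C converts and reads U
        if ref != "G":
            raise ValueError(
                f"probe {design.probe_id}: targeted-strand CpG G expected as "
                f"reference, got {ref!r}"
            )
        if design.infinium_type is InfiniumType.II:
            # the G pairs the type II probe's 3'-terminal base: any alt is a
            # terminal mismatch and abolishes extension
            cat = ArtifactCategory.SNP_EQ_PF
        else:
            # for type I the G sits one base in from the 3' terminus; the
            # converted alt template still matches the unmethylated-design
            # probe at 49/50 positions including the terminus
            cat = ArtifactCategory.SNP_EQ_U
            flags.add("near_3prime_mismatch")
    else:  # SBE site, type I only; beyond the probe, hybridization untouched
        if _bisulfite(ref) == _bisulfite(alt):
            # e.g. C/T: bisulfite renders the alleles identical
            cat = ArtifactCategory.NO_CHANNEL_CHANGE
            flags.add("bisulfite_indistinguishable")
        elif _sbe_channel(ref) != _sbe_channel(alt):
            cat = ArtifactCategory.CHANNEL_SWITCH
        else:
            cat = ArtifactCategory.NO_CHANNEL_CHANGE
    return ArtifactCall(cat, site, _EXPECTED_K[cat], frozenset(flags))


def _classify_indel(design: ProbeDesign, variant: VariantRecord) -> ArtifactCall:
    lo, hi = variant.span
    cpg_span = (design.cpg_pos, design.cpg_pos + 1)
    deletes = len(variant.ref) > len(variant.alt)
    overlaps_cpg = lo <= cpg_span[1] and hi >= cpg_span[0]
    if deletes and overlaps_cpg:
        return ArtifactCall(
            ArtifactCategory.SNP_EQ_PF, Site.CPG_C, 2, frozenset({"indel"})
        )
    return ArtifactCall(
        ArtifactCategory.UNRESOLVED_INDEL, Site.NONE, None, frozenset({"indel"})
    )


def classify_multiallelic(
    design: ProbeDesign, chrom: str, pos: int, ref: str, alts: Sequence[str]
) -> list[ArtifactCall]:
    """Classify a multi-allelic (e.g. triallelic) site.

    Each alt is classified against the reference; alts that the assay cannot
    tell apart (same category at the same site, e.g. two alleles that both
    read as the unmethylated epiallele) are flagged ``triallelic_collapsed``,
    since post-bisulfite the detection chemistry sees them as one allele.
    """
    calls = [
        classify_cpg_sbe_snp(design, VariantRecord(chrom, pos, ref, alt))
        for alt in alts
    ]
    keys = [(c.category, c.site) for c in calls]
    dup = {k for k in keys if keys.count(k) > 1}
    return [
        ArtifactCall(
            c.category,
            c.site,
            c.expected_k,
            frozenset(set(c.flags) | {"triallelic_collapsed"}),
        )
        if (c.category, c.site) in dup
        else c
        for c in calls
    ]


@dataclass(frozen=True)
class ProbeBodyEffect:
    failure_risk: bool
    bisulfite_masked: bool


def predict_probe_body_snp(
    design: ProbeDesign, variant: VariantRecord, dist_3prime: int
) -> ProbeBodyEffect:
    """Effect of a SNP in the probe body (outside CpG/SBE sites).

    ``dist_3prime`` counts bases from the probe 3'-end (0 = terminal base).
    C/T alleles on plus-strand probes and G/A alleles on minus-strand probes
    are masked by bisulfite conversion (outside CpG context both alleles read
    T on the targeted strand) and cause no failure at any distance; unmasked
    SNPs carry failure risk only within 15 bp of the 3'-end, beyond which
    their effect is diluted by the 50-mer's hybridization energy.
    """
    if dist_3prime < 0:
        raise ValueError("dist_3prime must be non-negative")
    alleles = frozenset((variant.ref, variant.alt))
    masked = (design.strand is Strand.PLUS and alleles == frozenset("CT")) or (
        design.strand is Strand.MINUS and alleles == frozenset("GA")
    )
    return ProbeBodyEffect(
        failure_risk=(not masked) and dist_3prime <= 15, bisulfite_masked=masked
    )


def internal_cpg_failure_adjustment(
    call: ArtifactCall, design: ProbeDesign, region_methylated: bool
) -> ArtifactCall:
    """Override SNP_EQ_U to probe failure for type I probes with internal CpGs.

    A type I probe spans neighboring ("internal") CpGs whose degenerate bases
    assume the probe-wide methylation state.  When a CpG-destroying variant
    reads as the unmethylated epiallele inside a methylated region, the alt
    chromosome presents a mixed template (converted at the target, protected
    at the internal CpGs) that neither the fully-methylated nor the
    fully-unmethylated probe design can bind, so the probe fails instead and
    two clusters are expected.
    """
    if (
        call.category is ArtifactCategory.SNP_EQ_U
        and design.is_type_i
        and region_methylated
        and design.n_internal_cpgs >= 1
    ):
        return ArtifactCall(
            ArtifactCategory.SNP_EQ_PF,
            call.site,
            2,
            frozenset(set(call.flags) | {"internal_cpg_failure"}),
        )
    return call


def enumerate_categories() -> pd.DataFrame:
    """Exhaustive (type, strand, site, ref, alt) -> category table.

    The classifier is a pure function, so this finite enumeration fully
    specifies it; tests freeze the table for regression.
    """
    rows = []
    for itype, strand in itertools.product(InfiniumType, Strand):
        design = ProbeDesign("cg_enum", itype, strand, chrom="chr1", cpg_pos=100)
        plus = strand is Strand.PLUS
        sites = {
            Site.CPG_C: 100 if plus else 101,
            Site.CPG_G: 101 if plus else 100,
        }
        if design.sbe_pos is not None:
            sites[Site.SBE] = design.sbe_pos
        for site, pos in sites.items():
            if site is Site.CPG_C:
                refs = ["C" if plus else "G"]
            elif site is Site.CPG_G:
                refs = ["G" if plus else "C"]
            else:
                refs = list("ACGT")
            for ref in refs:
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    call = classify_cpg_sbe_snp(
                        design, VariantRecord("chr1", pos, ref, alt)
                    )
                    rows.append(
                        {
                            "infinium_type": itype.value,
                            "strand": strand.value,
                            "site": site.value,
                            "ref": ref,
                            "alt": alt,
                            "category": call.category.value,
                            "flags": ",".join(sorted(call.flags)),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele and haplotype frequencies


@dataclass
class MafEstimate:
    maf: float
    concordance: pd.DataFrame  # twin-A label x twin-B label pair counts
    n_pairs_used: int
    flipped: bool  # True when the raw frequency exceeded 0.5 and was mirrored
    genotype_counts: dict[str, int]


_GENO_ALT_DOSE = {"AA": 0, "AB": 1, "BB": 2}


def estimate_maf(
    assignments: Mapping[str, int] | pd.Series,
    gmap: Mapping[int, str],
    cohort: CohortDesign,
) -> MafEstimate:
    """Allele frequency from twin-concordant cluster counts.

    ``assignments`` maps sample id -> cluster label; ``gmap`` maps every
    non-noise cluster label to a genotype in {AA, AB, BB}.  Twin pairs are
    cross-tabulated by their two labels and only concordant (diagonal) pairs
    contribute, one genotype per pair:

        MAF = (2 n_BB + n_AB) / (2 (n_AA + n_AB + n_BB))

    A result above 0.5 is mirrored to the minor allele and flagged, since the
    cluster-genotype map may have been specified with either allele as
    reference.
    """
    assignments = dict(assignments)
    labels_present = {
        assignments[s] for s in assignments if assignments[s] >= 0
    }
    missing = labels_present - set(gmap)
    if missing:
        raise ValueError(f"gmap does not cover cluster labels {sorted(missing)}")
    pairs = [
        p
        for p in cohort.twin_pairs()
        if p[0] in assignments and p[1] in assignments
        and assignments[p[0]] >= 0 and assignments[p[1]] >= 0
    ]
    if not pairs:
        raise ValueError("no twin pairs with assignments")
    all_labels = sorted(set(gmap))
    table = pd.DataFrame(0, index=all_labels, columns=all_labels)
    counts = {"AA": 0, "AB": 0, "BB": 0}
    for a, b in pairs:
        la, lb = assignments[a], assignments[b]
        table.loc[la, lb] += 1
        if la == lb:
            counts[gmap[la]] += 1
    n_used = sum(counts.values())
    if n_used == 0:
        raise ValueError("zero concordant twin pairs")
    freq = (2 * counts["BB"] + counts["AB"]) / (2 * n_used)
    flipped = freq > 0.5
    if flipped:
        logger.warning("estimate_maf: frequency %.3f > 0.5; minor allele flipped", freq)
        freq = 1.0 - freq
    return MafEstimate(
        maf=freq,
        concordance=table,
        n_pairs_used=n_used,
        flipped=flipped,
        genotype_counts=counts,
    )


def hwe_proportions(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype proportions ((1-q)^2, 2q(1-q), q^2) for q = maf."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    q = maf
    return ((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2)


@dataclass
class HaplotypeFreqs:
    freqs: np.ndarray  # (4,) on the simplex
    loglik: float
    non_identifiable: tuple[int, ...] = ()


def _cluster_probs(p: np.ndarray, dmap: Mapping[tuple[int, int], int], n_clusters: int) -> np.ndarray:
    """Cluster probabilities under HWE of diplotypes: sum (2-delta_ij) p_i p_j."""
    probs = np.zeros(p.shape[:-1] + (n_clusters,))
    for (i, j), c in dmap.items():
        w = (1.0 if i == j else 2.0) * p[..., i] * p[..., j]
        probs[..., c] += w
    return probs


def estimate_haplotype_freqs(
    cluster_counts: Sequence[float],
    dmap: Mapping[tuple[int, int], int],
    n_starts: int = 10,
    seed: int | np.random.Generator | None = 0,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies from U/M cluster counts.

    The ten unordered diplotypes (i <= j) of four haplotypes map onto
    clusters via ``dmap``; cluster probabilities are the Hardy-Weinberg sums
    sum_{(i,j)->c} (2 - delta_ij) p_i p_j and the multinomial log-likelihood
    of the observed counts is maximized over the 4-simplex via a softmax
    reparameterization with multiple starts.  Haplotypes whose every
    informative cluster is empty are reported as non-identifiable with a
    warning.
    """
    counts = np.asarray(cluster_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("cluster counts must be non-negative")
    need = {(i, j) for i in range(4) for j in range(i, 4)}
    got = {tuple(sorted(k)) for k in dmap}
    if got != need:
        raise ValueError("dmap must cover all 10 unordered diplotypes of 4 haplotypes")
    dmap = {tuple(sorted(k)): v for k, v in dmap.items()}
    n_clusters = len(counts)
    if any(c < 0 or c >= n_clusters for c in dmap.values()):
        raise ValueError("dmap cluster indices out of range")

    non_ident = tuple(
        h
        for h in range(4)
        if all(
            counts[c] == 0
            for (i, j), c in dmap.items()
            if h in (i, j)
        )
    )
    if non_ident:
        warnings.warn(
            f"haplotypes {non_ident} appear only in empty clusters; "
            "their frequencies are not identifiable",
            stacklevel=2,
        )

    observed = counts > 0

    def nll(theta: np.ndarray) -> float:
        p = softmax(theta)
        probs = _cluster_probs(p, dmap, n_clusters)[observed]
        with np.errstate(divide="ignore"):
            return -float((counts[observed] * np.log(probs)).sum())

    rng = np.random.default_rng(seed)
    best_theta, best_val = None, np.inf
    starts = [np.zeros(4)] + [rng.normal(scale=1.5, size=4) for _ in range(n_starts - 1)]
    for theta0 in starts:
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    p = softmax(best_theta)
    if non_ident:
        # spread the unidentifiable mass flat across the affected haplotypes
        mass = p[list(non_ident)].sum()
        p[list(non_ident)] = mass / len(non_ident)
    return HaplotypeFreqs(freqs=p, loglik=-best_val, non_identifiable=non_ident)


# ---------------------------------------------------------------------------
# VCF ingestion


def read_vcf_variants(
    path: str, populations: Sequence[str] = ("EUR", "AFR")
) -> list[VariantRecord]:
    """Read variants from a VCF; per-population allele frequencies are taken
    from INFO keys ``<POP>_AF`` (or ``<POP>``) and folded to MAF."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(path):
        mafs = {}
        for pop in populations:
            af = rec.INFO.get(f"{pop}_AF", rec.INFO.get(pop))
            if af is not None:
                af = float(af)
                mafs[pop] = min(af, 1.0 - af)
        for alt in rec.ALT:
            if set(rec.REF) - set("ACGT") or set(alt) - set("ACGT"):
                logger.warning("skipping non-ACGT variant at %s:%d", rec.CHROM, rec.POS)
                continue
            out.append(
                VariantRecord(
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                    ref=rec.REF,
                    alt=alt,
                    maf_by_pop=mafs,
                    variant_id=rec.ID,
                )
            )
    return out
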