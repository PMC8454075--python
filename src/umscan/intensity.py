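"""Core data model for raw two-channel fluorescence intensities.

Illumina Infinium methylation arrays quantify CpG methylation from two
fluorescence signals per probe and sample: M (methylated epiallele) and U
(unmethylated epiallele).  Type II probes read both epialleles from a single
bead address (green channel = M, red channel = U); type I probes use two bead
addresses (A = unmethylated design, B = methylated design) read in a single
channel determined at design time (green or red).  Alongside the per-bead-pool
mean intensities, the raw files store the across-bead standard deviations of
each channel, which this package uses as a per-entry noise measurement.

This module holds the domain types (probe designs, intensity matrices, cohort
metadata), the channel -> U/M mapping, the elementary methylation transforms
(beta, M-value), quantile normalization, and plain-text (TSV) matrix I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InfiniumType",
    "Strand",
    "Sex",
    "ProbeDesign",
    "ChannelIntensities",
    "IntensityMatrices",
    "CohortDesign",
    "MethylationMatrices",
    "map_channels",
    "compute_beta",
    "compute_mvalue",
    "compute_total",
    "compute_methylation",
    "quantile_normalize",
    "read_intensity_tables",
    "write_intensity_tables",
    "read_manifest",
    "write_manifest",
    "read_cohort",
    "write_cohort",
]


class InfiniumType(str, Enum):
    """Probe chemistry: type I read in red, type I read in green, or type II."""

    I_RED = "I_RED"
    I_GREEN = "I_GREEN"
    II = "II"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


class Sex(str, Enum):
    F = "F"
    M = "M"


@dataclass(frozen=True)
class ProbeDesign:
    """Assay description of a single probe.

    ``cpg_pos`` is always the 1-based plus-strand coordinate of the CpG's C,
    regardless of which strand the probe targets.  ``probe_seq``, when given,
    is the 50-mer probe sequence over {A,C,G,T,R,Y} (R/Y mark degenerate
    positions covering internal CpGs).
    """

    probe_id: str
    infinium_type: InfiniumType
    strand: Strand
    chrom: str = "chr0"
    cpg_pos: int = 1
    n_internal_cpgs: int = 0
    probe_seq: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.infinium_type, InfiniumType):
            raise ValueError(f"unknown Infinium type: {self.infinium_type!r}")
        if not isinstance(self.strand, Strand):
            raise ValueError(f"unknown strand: {self.strand!r}")
        if self.cpg_pos < 1:
            raise ValueError("cpg_pos is 1-based and must be >= 1")
        if self.n_internal_cpgs < 0:
            raise ValueError("n_internal_cpgs must be non-negative")
        if self.probe_seq is not None:
            if len(self.probe_seq) != 50:
                raise ValueError("probe_seq must be 50 bases long")
            if set(self.probe_seq) - set("ACGTRY"):
                raise ValueError("probe_seq may only contain A,C,G,T,R,Y")

    @property
    def is_type_i(self) -> bool:
        return self.infinium_type in (InfiniumType.I_RED, InfiniumType.I_GREEN)

    @property
    def sbe_pos(self) -> int | None:
        """Plus-strand coordinate of the single-base-extension site.

        Type I probes terminate on the CpG C itself so extension reads the
        template base adjacent to the CpG on the extension side: position
        ``cpg_pos - 1`` for plus-strand probes and ``cpg_pos + 2`` for
        minus-strand probes.  Type II probes extend at the C itself and have
        no separate SBE site (returns None).
        """
        if not self.is_type_i:
            return None
        return self.cpg_pos - 1 if self.strand is Strand.PLUS else self.cpg_pos + 2


@dataclass
class ChannelIntensities:
    """Per-bead-address mean and across-bead SD for one fluorescence channel."""

    mean: pd.DataFrame
    sd: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index) or not self.mean.columns.equals(
            self.sd.columns
        ):
            raise ValueError("channel mean and sd matrices must be aligned")


def _check_aligned(name: str, ref: pd.DataFrame, other: pd.DataFrame) -> None:
    if other.shape != ref.shape:
        raise ValueError(f"{name}: shape {other.shape} != {ref.shape}")
    if not other.index.equals(ref.index) or not other.columns.equals(ref.columns):
        raise ValueError(f"{name}: probe/sample ids differ from U matrix")


@dataclass
class IntensityMatrices:
    """Probes x samples matrices of U/M fluorescence means and bead-level SDs."""

    U: pd.DataFrame
    M: pd.DataFrame
    sigma_U: pd.DataFrame
    sigma_M: pd.DataFrame
    n_beads: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("M", "sigma_U", "sigma_M"):
            _check_aligned(name, self.U, getattr(self, name))
        if self.n_beads is not None:
            _check_aligned("n_beads", self.U, self.n_beads)
            if (self.n_beads.to_numpy() < 1).any():
                raise ValueError("n_beads must be positive")
        for name in ("U", "M", "sigma_U", "sigma_M"):
            arr = getattr(self, name).to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError(f"negative entries in {name}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.U.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.U.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.U.shape

    def points(self, probe_id: str) -> np.ndarray:
        """(n_samples, 2) array of (U, M) coordinates for one probe."""
        return np.column_stack(
            [self.U.loc[probe_id].to_numpy(float), self.M.loc[probe_id].to_numpy(float)]
        )


@dataclass
class CohortDesign:
    """Sample metadata: monozygotic twin pairing, sex and batch.

    MZ twins share their genotype and act as a genetic control: a statistic
    driven by genetics must agree within pairs.  Every declared pair id must
    appear on exactly two samples.
    """

    sample_ids: list[str]
    twin_pair_id: dict[str, str] = field(default_factory=dict)
    sex: dict[str, Sex] = field(default_factory=dict)
    batch_id: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        known = set(self.sample_ids)
        counts: dict[str, list[str]] = {}
        for sid, pid in self.twin_pair_id.items():
            if sid not in known:
                raise ValueError(f"twin metadata for unknown sample {sid!r}")
            counts.setdefault(pid, []).append(sid)
        for pid, members in counts.items():
            if len(members) != 2:
                raise ValueError(
                    f"twin pair {pid!r} has {len(members)} members; exactly 2 required"
                )

    def twin_pairs(self) -> list[tuple[str, str]]:
        """Pairs as (twin_a, twin_b), ordered lexicographically within a pair.

        The within-pair ordering is arbitrary biologically but must be
        deterministic for correlation-based statistics; sample-id sort fixes it.
        """
        by_pair: dict[str, list[str]] = {}
        for sid, pid in self.twin_pair_id.items():
            by_pair.setdefault(pid, []).append(sid)
        return [tuple(sorted(v)) for _, v in sorted(by_pair.items())]


@dataclass
class MethylationMatrices:
    """Derived methylation scales: beta in [0,1), unbounded M-values, total T."""

    beta: pd.DataFrame
    mvalue: pd.DataFrame
    total: pd.DataFrame


# ---------------------------------------------------------------------------
# channel mapping


def map_channels(
    raw_green: ChannelIntensities,
    raw_red: ChannelIntensities,
    address_map: Mapping[str, tuple[object, object | None]],
    designs: Iterable[ProbeDesign],
) -> IntensityMatrices:
    """Map per-address channel intensities to per-probe U/M matrices.

    Type II probes have a single address read in both channels: green is the
    methylated signal, red the unmethylated one.  Type I probes have two
    addresses (A = unmethylated design, B = methylated design) and are read in
    the channel fixed by their design; the out-of-band channel is discarded.
    Probes whose addresses are missing from a channel matrix are dropped with
    a warning; an unknown Infinium type is a hard error.
    """
    u_rows, m_rows, su_rows, sm_rows, kept = [], [], [], [], []
    g_mean, g_sd = raw_green.mean, raw_green.sd
    r_mean, r_sd = raw_red.mean, raw_red.sd
    for design in designs:
        pid = design.probe_id
        if pid not in address_map:
            logger.warning("probe %s missing from address map; dropped", pid)
            continue
        addr_a, addr_b = address_map[pid]
        if design.infinium_type is InfiniumType.II:
            if addr_a not in g_mean.index or addr_a not in r_mean.index:
                logger.warning("probe %s: address %r missing; dropped", pid, addr_a)
                continue
            m, u = g_mean.loc[addr_a], r_mean.loc[addr_a]
            sm, su = g_sd.loc[addr_a], r_sd.loc[addr_a]
        elif design.is_type_i:
            mean, sd = (
                (g_mean, g_sd)
                if design.infinium_type is InfiniumType.I_GREEN
                else (r_mean, r_sd)
            )
            if addr_b is None or addr_a not in mean.index or addr_b not in mean.index:
                logger.warning("probe %s: type I address missing; dropped", pid)
                continue
            u, m = mean.loc[addr_a], mean.loc[addr_b]
            su, sm = sd.loc[addr_a], sd.loc[addr_b]
        else:  # pragma: no cover - ProbeDesign validates the enum
            raise ValueError(f"unknown Infinium type: {design.infinium_type!r}")
        kept.append(pid)
        u_rows.append(u)
        m_rows.append(m)
        su_rows.append(su)
        sm_rows.append(sm)
    cols = g_mean.columns
    build = lambda rows: pd.DataFrame(rows, index=pd.Index(kept, name="probe_id"))[cols]
    return IntensityMatrices(
        U=build(u_rows), M=build(m_rows), sigma_U=build(su_rows), sigma_M=build(sm_rows)
    )


# ---------------------------------------------------------------------------
# methylation transforms


def compute_beta(intens: IntensityMatrices, offset: float = 100.0) -> pd.DataFrame:
    """Methylation ratio beta = M / (M + U + offset), entrywise in [0, 1).

    The additive offset (default 100, matching common practice) forbids
    division by zero and shrinks background-only entries toward 0.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    return intens.M / (intens.M + intens.U + offset)


def compute_mvalue(intens: IntensityMatrices) -> pd.DataFrame:
    """M-value = log2((M + 1) / (U + 1)); unbounded, better for correlations."""
    return np.log2((intens.M + 1.0) / (intens.U + 1.0))


def compute_total(intens: IntensityMatrices, offset: float = 100.0) -> pd.DataFrame:
    """Total signal T = U + M + offset."""
    return intens.U + intens.M + offset


def compute_methylation(
    intens: IntensityMatrices, offset: float = 100.0
) -> MethylationMatrices:
    return MethylationMatrices(
        beta=compute_beta(intens, offset),
        mvalue=compute_mvalue(intens),
        total=compute_total(intens, offset),
    )


# ---------------------------------------------------------------------------
# quantile normalization


def _qn_reference(x: np.ndarray) -> np.ndarray:
    """Across-column mean of order statistics, from complete rows only."""
    complete = x[~np.isnan(x).any(axis=1)]
    if complete.shape[0] == 0:
        raise ValueError("quantile normalization needs at least one complete row")
    return np.sort(complete, axis=0).mean(axis=1)


def quantile_normalize(x: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Quantile-normalize columns against the mean order-statistic reference.

    After normalization every column has the same sorted value vector while
    within-column ranks are preserved.  Ties receive the mean of the reference
    values at their tied ranks (average-tie convention).  Missing values are
    left missing; they are excluded from ranking and the reference
    distribution is built on complete rows only.
    """
    from scipy.stats import rankdata

    df = isinstance(x, pd.DataFrame)
    arr = x.to_numpy(dtype=float) if df else np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if arr.shape[0] == 1:  # degenerate: a single row normalizes to its mean
        out = np.full_like(arr, np.nanmean(arr))
    else:
        ref = _qn_reference(arr)
        out = np.full_like(arr, np.nan)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            ok = ~np.isnan(col)
            m = ok.sum()
            if m == 0:
                continue
            ranks = rankdata(col[ok], method="average")  # 1..m, ties averaged
            # map rank r to a (possibly fractional) position in the reference
            pos = (ranks - 1.0) * (len(ref) - 1.0) / max(m - 1.0, 1.0)
            lo = np.floor(pos).astype(int)
            hi = np.ceil(pos).astype(int)
            out[ok, j] = ref[lo] + (pos - lo) * (ref[hi] - ref[lo])
    return pd.DataFrame(out, index=x.index, columns=x.columns) if df else out


# ---------------------------------------------------------------------------
# TSV I/O


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = "probe_id"
    df.columns = df.columns.astype(str)
    df.columns.name = "sample_id"
    return df


def read_intensity_tables(
    path_u: str | Path,
    path_m: str | Path,
    path_sigma_u: str | Path,
    path_sigma_m: str | Path,
) -> IntensityMatrices:
    """Read the four intensity TSVs (probe_id column, sample-id header).

    Matrices are aligned by probe and sample *id* (not position); an id-set
    or shape mismatch raises an error naming the offending file.
    """
    ref = _read_table(path_u)
    mats = {"U": ref}
    for name, path in (
        ("M", path_m),
        ("sigma_U", path_sigma_u),
        ("sigma_M", path_sigma_m),
    ):
        df = _read_table(path)
        if set(df.index) != set(ref.index) or set(df.columns) != set(ref.columns):
            raise ValueError(f"probe/sample ids in {path} do not match {path_u}")
        mats[name] = df.loc[ref.index, ref.columns]
    return IntensityMatrices(**mats)


def write_intensity_tables(intens: IntensityMatrices, directory: str | Path) -> dict[str, Path]:
    """Write U/M/sigma_U/sigma_M as TSVs into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("U", "M", "sigma_U", "sigma_M"):
        p = directory / f"{name}.tsv"
        getattr(intens, name).to_csv(p, sep="\t", na_rep="NA")
        paths[name] = p
    return paths


_MANIFEST_COLS = ["chrom", "pos", "probe_id", "type", "strand", "n_internal_cpgs"]


def write_manifest(designs: Iterable[ProbeDesign], path: str | Path) -> None:
    """Write a BED-like TSV manifest (chrom, 1-based pos, id, type, strand, nCpG)."""
    rows = [
        {
            "chrom": d.chrom,
            "pos": d.cpg_pos,
            "probe_id": d.probe_id,
            "type": d.infinium_type.value,
            "strand": d.strand.value,
            "n_internal_cpgs": d.n_internal_cpgs,
        }
        for d in designs
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> dict[str, ProbeDesign]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.probe_id] = ProbeDesign(
            probe_id=row.probe_id,
            infinium_type=InfiniumType(row.type),
            strand=Strand(row.strand),
            chrom=str(row.chrom),
            cpg_pos=int(row.pos),
            n_internal_cpgs=int(row.n_internal_cpgs),
        )
    return out


def write_cohort(cohort: CohortDesign, path: str | Path) -> None:
    rows = [
        {
            "sample_id": sid,
            "twin_pair_id": cohort.twin_pair_id.get(sid, "NA"),
            "sex": cohort.sex[sid].value if sid in cohort.sex else "NA",
            "batch_id": cohort.batch_id.get(sid, "NA"),
        }
        for sid in cohort.sample_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ids = list(df["sample_id"])
    pick = lambda col: {
        s: v for s, v in zip(ids, df[col]) if col in df and v not in ("", "NA")
    }
    return CohortDesign(
        sample_ids=ids,
        twin_pair_id=pick("twin_pair_id"),
        sex={s: Sex(v) for s, v in pick("sex").items()},
        batch_id=pick("batch_id"),
    )
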