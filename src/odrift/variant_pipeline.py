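"""Organelle variant filtering, distances, substitution rates, copy numbers.

This stage consumes per-sample, per-position coverage/allele-count tables for
the two organelle genomes (the pysamstats-style dialect documented in the
README: ``sample  organelle  pos  ref  coverage  A  C  G  T`` with 1-based
positions) together with annotation channels (BED intervals per channel).

The analysis mirrors a short-read organelle resequencing workflow in which
the main false-positive sources are cross-mapping from DNA shared between
genomes (NUMTs, NUPTs, mtptDNA) and repeat-induced misalignment.  Neutral
position masks, a coverage-proportion metric (per-position coverage over the
median coverage of its genome segment, shared regions excluded), clustered-
candidate and reference-allele-coverage filters remove those artifact
classes before fixed and heteroplasmic SNPs are called.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "VariantCall",
    "QCLog",
    "load_records",
    "write_records",
    "summarize_alleles",
    "segment_medians",
    "coverage_proportion",
    "neutral_mask",
    "sample_and_position_qc",
    "call_fixed",
    "call_heteroplasmic",
    "genetic_distance",
    "substitution_rate",
    "SubstitutionRate",
    "estimate_copy_number",
    "write_vcf",
]

BASES = ("A", "C", "G", "T")

# QC thresholds of the empirical stage
MIN_SAMPLE_MEDIAN_MT = 50
MIN_POSITION_COVERAGE_MT = 150
COVPROP_BOUNDS_MT = (0.3, 1.5)
COVPROP_MIN_PT = 0.3
FIXED_AF = 0.75
HET_AF_RANGE = (0.05, 0.95)
CLUSTER_DISTANCE = 2
REPEAT_MIN_LEN = 9   # mononucleotide repeats longer than eight base pairs
REPEAT_HALO = 2      # +/- bp excluded around such repeats


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _as_intervals(iv) -> np.ndarray:
    a = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(a) and (a[:, 0] >= a[:, 1]).any():
        raise ValueError("intervals must be non-empty half-open [start, end)")
    return a


@dataclass
class GenomeAnnotation:
    """Feature channels of one organelle genome.

    All intervals are 0-based half-open (BED convention); reported positions
    are 1-based.  ``segments`` must partition the genome (they define the
    per-segment coverage medians); ``repeats`` are mononucleotide runs longer
    than eight base pairs, masked with a +/-2 bp halo.  ``numt``/``nupt``/
    ``mtpt`` are the DNA regions shared with the nuclear or the other
    organelle genome; ``inverted_repeats`` only applies to plastid genomes.
    ``imperfect_repeats`` is a user-supplied channel (curated, not detected).
    """

    genome_length: int
    coding: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    repeats: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    numt: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    nupt: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    mtpt: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    segments: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    inverted_repeats: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    imperfect_repeats: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for name in ("coding", "repeats", "numt", "nupt", "mtpt",
                     "segments", "inverted_repeats", "imperfect_repeats"):
            iv = _as_intervals(getattr(self, name))
            if len(iv) and (iv.min() < 0 or iv.max() > self.genome_length):
                raise ValueError(f"{name} intervals fall outside the genome")
            setattr(self, name, iv)
        if len(self.segments) == 0:
            self.segments = np.array([[0, self.genome_length]], dtype=np.int64)
        seg = self.segments[np.argsort(self.segments[:, 0])]
        if seg[0, 0] != 0 or seg[-1, 1] != self.genome_length or \
                (seg[1:, 0] != seg[:-1, 1]).any():
            raise ValueError("segments must partition the genome")
        self.segments = seg

    # -- masks -------------------------------------------------------------

    def channel_mask(self, name: str, halo: int = 0) -> np.ndarray:
        """Boolean mask (0-based) of the positions covered by a channel."""
        mask = np.zeros(self.genome_length, dtype=bool)
        for s, e in getattr(self, name):
            mask[max(0, s - halo):min(self.genome_length, e + halo)] = True
        return mask

    def shared_mask(self) -> np.ndarray:
        return (self.channel_mask("numt") | self.channel_mask("nupt")
                | self.channel_mask("mtpt"))

    def segment_of(self, pos0: np.ndarray) -> np.ndarray:
        """Segment index of each 0-based position."""
        return np.searchsorted(self.segments[:, 1], pos0, side="right")

    # -- BED round trip ----------------------------------------------------

    def to_bed_dir(self, directory, chrom: str = "genome") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("coding", "repeats", "numt", "nupt", "mtpt",
                     "segments", "inverted_repeats", "imperfect_repeats"):
            iv = getattr(self, name)
            df = pd.DataFrame({"chrom": chrom, "start": iv[:, 0], "end": iv[:, 1]})
            df.to_csv(directory / f"{name}.bed", sep="\t", header=False, index=False)

    @classmethod
    def from_bed_dir(cls, directory, genome_length: int) -> "GenomeAnnotation":
        directory = Path(directory)
        kw = {}
        for name in ("coding", "repeats", "numt", "nupt", "mtpt",
                     "segments", "inverted_repeats", "imperfect_repeats"):
            path = directory / f"{name}.bed"
            if path.exists() and path.stat().st_size:
                df = pd.read_csv(path, sep="\t", header=None,
                                 names=["chrom", "start", "end"],
                                 usecols=[0, 1, 2])
                kw[name] = df[["start", "end"]].to_numpy(np.int64)
        return cls(genome_length=genome_length, **kw)


# ---------------------------------------------------------------------------
# Position records
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["sample", "organelle", "pos", "ref", "coverage", "A", "C", "G", "T"]


def load_records(path) -> pd.DataFrame:
    """Read a per-position table in the documented TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "organelle": str,
                                            "ref": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records table misses columns {sorted(missing)}")
    return df


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def summarize_alleles(records: pd.DataFrame) -> pd.DataFrame:
    """Add variant-allele summaries to a records table.

    The variant allele of a position is the highest-count non-reference base;
    allele frequencies are computed over the four base counts.  Positions
    where a second non-reference base also passes the heteroplasmy floor are
    flagged ``triallelic`` (they are reported but never called).
    """
    df = records.copy()
    counts = df[list(BASES)].to_numpy(np.int64)
    depth = counts.sum(axis=1)
    ref_idx = pd.Categorical(df["ref"], categories=BASES).codes
    if (ref_idx < 0).any():
        raise ValueError("ref column contains non-ACGT bases")
    rows = np.arange(len(df))
    ref_count = counts[rows, ref_idx]
    nonref = counts.copy()
    nonref[rows, ref_idx] = -1
    var_idx = nonref.argmax(axis=1)
    var_count = counts[rows, var_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_af = np.where(depth > 0, ref_count / np.maximum(depth, 1), 0.0)
        var_af = np.where(depth > 0, var_count / np.maximum(depth, 1), 0.0)
    # second-best non-reference allele for the tri-allelic flag
    nonref2 = nonref.copy()
    nonref2[rows, var_idx] = -1
    second = nonref2.max(axis=1)
    df["depth_used"] = depth
    df["ref_count"] = ref_count
    df["variant_base"] = np.array(BASES)[var_idx]
    df["variant_count"] = var_count
    df["ref_af"] = ref_af
    df["variant_af"] = var_af
    df["triallelic"] = (second / np.maximum(depth, 1)) >= HET_AF_RANGE[0]
    return df


def segment_medians(
    records: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Median coverage per (sample, segment), excluding shared-DNA positions."""
    shared = annotation.shared_mask()
    pos0 = records["pos"].to_numpy(np.int64) - 1
    keep = ~shared[pos0]
    seg = annotation.segment_of(pos0)
    sub = records.loc[keep, ["sample", "coverage"]].copy()
    sub["segment"] = seg[keep]
    med = (sub.groupby(["sample", "segment"])["coverage"]
           .median().rename("segment_median").reset_index())
    return med


def coverage_proportion(cov: float, segment_median: float) -> float:
    """Per-position coverage over its segment's (shared-excluded) median."""
    if segment_median <= 0:
        raise ValueError("segment median coverage must be positive")
    return cov / segment_median


def _with_coverage_proportion(
    records: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    med = segment_medians(records, annotation)
    df = records.copy()
    df["segment"] = annotation.segment_of(df["pos"].to_numpy(np.int64) - 1)
    df = df.merge(med, on=["sample", "segment"], how="left")
    if df["segment_median"].isna().any() or (df["segment_median"] <= 0).any():
        raise ValueError("a genome segment has no usable coverage median")
    df["cov_prop"] = df["coverage"] / df["segment_median"]
    return df


# ---------------------------------------------------------------------------
# Neutral masks
# ---------------------------------------------------------------------------

def neutral_mask(
    annotation: GenomeAnnotation, organelle: str, mode: str
) -> np.ndarray:
    """Boolean mask (0-based) of neutral positions for an analysis mode.

    Both modes exclude coding regions and mononucleotide repeats (>8 bp, with
    a 2 bp halo).  Fixed-mutation mode additionally excludes mtptDNA in the
    mitochondrial genome (plastids out-number mitochondria, so cross-mapped
    reads would swamp mt variants there).  Heteroplasmy mode excludes every
    shared-DNA class in both genomes, the plastid inverted repeats, and any
    curated imperfect-repeat intervals.
    """
    if organelle not in ("mt", "pt"):
        raise ValueError("organelle must be 'mt' or 'pt'")
    if mode not in ("fixed", "heteroplasmy"):
        raise ValueError("mode must be 'fixed' or 'heteroplasmy'")
    excl = annotation.channel_mask("coding")
    excl |= annotation.channel_mask("repeats", halo=REPEAT_HALO)
    if mode == "fixed":
        if organelle == "mt":
            excl |= annotation.channel_mask("mtpt")
    else:
        excl |= annotation.shared_mask()
        excl |= annotation.channel_mask("imperfect_repeats")
        if organelle == "pt":
            excl |= annotation.channel_mask("inverted_repeats")
    return ~excl


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCLog:
    """Tallies of what sample/position QC removed (mirrored to the logs)."""

    organelle: str
    n_samples_in: int = 0
    samples_dropped_low_median: list[str] = field(default_factory=list)
    n_positions_in: int = 0
    n_dropped_low_coverage: int = 0
    n_dropped_cov_prop: int = 0

    def summary(self) -> str:
        return (f"[{self.organelle}] excluded {len(self.samples_dropped_low_median)} "
                f"of {self.n_samples_in} samples with median coverage < "
                f"{MIN_SAMPLE_MEDIAN_MT}; dropped {self.n_dropped_low_coverage} "
                f"low-coverage and {self.n_dropped_cov_prop} coverage-proportion "
                f"outlier positions of {self.n_positions_in}")


def sample_and_position_qc(
    records: pd.DataFrame,
    annotation: GenomeAnnotation,
    organelle: str,
) -> tuple[pd.DataFrame, QCLog]:
    """Apply the per-sample and per-position coverage filters.

    Mitochondrial genome: samples with median coverage below 50 are removed
    entirely; positions need coverage >= 150 and a coverage proportion inside
    [0.3, 1.5].  Plastid genome: positions with coverage proportion below 0.3
    are removed (the boundary passes).  Returns the surviving records with a
    ``cov_prop`` column attached, plus the removal tallies.
    """
    log = QCLog(organelle=organelle)
    df = records[records["organelle"] == organelle]
    log.n_samples_in = df["sample"].nunique()
    log.n_positions_in = len(df)
    if organelle == "mt":
        med = df.groupby("sample")["coverage"].median()
        bad = med[med < MIN_SAMPLE_MEDIAN_MT].index.tolist()
        log.samples_dropped_low_median = sorted(bad)
        df = df[~df["sample"].isin(bad)]
    df = _with_coverage_proportion(df, annotation)
    if organelle == "mt":
        low = df["coverage"] < MIN_POSITION_COVERAGE_MT
        log.n_dropped_low_coverage = int(low.sum())
        df = df[~low]
        lo, hi = COVPROP_BOUNDS_MT
        out = (df["cov_prop"] < lo) | (df["cov_prop"] > hi)
        log.n_dropped_cov_prop = int(out.sum())
        df = df[~out]
    else:
        out = df["cov_prop"] < COVPROP_MIN_PT
        log.n_dropped_cov_prop = int(out.sum())
        df = df[~out]
    return df.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    sample: str
    organelle: str
    position: int  # 1-based
    base: str
    af: float
    kind: str  # "fixed" | "heteroplasmic"
    filters_failed: list[str] = field(default_factory=list)


def _apply_mask(records: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    pos0 = records["pos"].to_numpy(np.int64) - 1
    return records[mask[pos0]]


def call_fixed(records: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Fixed SNPs: variant allele frequency >= 0.75 at masked positions.

    The fixation threshold is deliberately permissive so that genuine fixed
    variants diluted by reads from shared genome regions are not missed; AFs
    up to 0.95 also fall in the heteroplasmic range, and both memberships are
    reported (``also_heteroplasmic_range``) for downstream consumers to pick.
    """
    df = summarize_alleles(_apply_mask(records, mask))
    df = df[(df["variant_af"] >= FIXED_AF) & ~df["triallelic"]]
    calls = df[["sample", "organelle", "pos", "variant_base", "variant_af"]].copy()
    calls.columns = ["sample", "organelle", "pos", "base", "af"]
    calls["kind"] = "fixed"
    calls["also_heteroplasmic_range"] = calls["af"] <= HET_AF_RANGE[1]
    return calls.reset_index(drop=True)


def call_heteroplasmic(
    records: pd.DataFrame,
    mask: np.ndarray,
    annotation: GenomeAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heteroplasmic sites: 0.05 <= AF <= 0.95 surviving the artifact filters.

    Filters applied to the candidate set (each removal recorded):
      * ``cluster``: more than one candidate within two nucleotides of each
        other in the same sample removes all members of the cluster;
      * ``ref_cov_prop``: the position is removed cohort-wide when in any
        sample carrying the candidate the reference-allele coverage alone
        exceeds the segment median — the apparent heteroplasmy then sits on
        top of full reference coverage and is explained by extra reads
        cross-mapped from another region;
      * ``triallelic``: a second non-reference allele above the floor flags
        the position, which is reported but not called.

    Returns ``(calls, rejected)``; ``records`` must already be QC-passed
    (with ``cov_prop``/``segment_median`` columns attached).
    """
    if "segment_median" not in records.columns:
        records = _with_coverage_proportion(records, annotation)
    df = summarize_alleles(_apply_mask(records, mask))
    lo, hi = HET_AF_RANGE
    cand = df[(df["variant_af"] >= lo) & (df["variant_af"] <= hi)].copy()
    if cand.empty:
        empty = pd.DataFrame(columns=["sample", "organelle", "pos", "base",
                                      "af", "kind", "filters_failed"])
        return empty, empty.copy()
    cand["filters_failed"] = [[] for _ in range(len(cand))]

    # (i) clustered candidates, per sample
    for sample, sub in cand.groupby("sample"):
        pos = np.sort(sub["pos"].to_numpy())
        if len(pos) < 2:
            continue
        close = np.zeros(len(pos), dtype=bool)
        gaps = np.diff(pos) <= CLUSTER_DISTANCE
        close[:-1] |= gaps
        close[1:] |= gaps
        bad_pos = set(pos[close].tolist())
        idx = cand.index[(cand["sample"] == sample) & cand["pos"].isin(bad_pos)]
        for i in idx:
            cand.at[i, "filters_failed"].append("cluster")

    # (ii) reference-allele coverage proportion above 1 in a candidate sample
    ref_prop = cand["ref_count"] / cand["segment_median"]
    bad_positions = set(cand.loc[ref_prop > 1.0, "pos"].tolist())
    for i in cand.index[cand["pos"].isin(bad_positions)]:
        cand.at[i, "filters_failed"].append("ref_cov_prop")

    for i in cand.index[cand["triallelic"]]:
        cand.at[i, "filters_failed"].append("triallelic")

    cand["kind"] = "heteroplasmic"
    keep_cols = ["sample", "organelle", "pos", "variant_base", "variant_af",
                 "kind", "filters_failed"]
    out = cand[keep_cols].rename(columns={"variant_base": "base",
                                          "variant_af": "af"})
    passed = out[out["filters_failed"].str.len() == 0].reset_index(drop=True)
    rejected = out[out["filters_failed"].str.len() > 0].reset_index(drop=True)
    return passed, rejected


# ---------------------------------------------------------------------------
# Distances and rates
# ---------------------------------------------------------------------------

def _fixed_genotypes(
    records: pd.DataFrame, mask: np.ndarray, samples: Iterable[str]
) -> dict[str, dict[int, str]]:
    """Per-sample genotype (variant base where fixed, else ref) at passing positions."""
    genotypes: dict[str, dict[int, str]] = {}
    df = summarize_alleles(_apply_mask(records, mask))
    for sample in samples:
        sub = df[df["sample"] == sample]
        geno = dict(zip(sub["pos"], sub["ref"]))
        fixed = sub[(sub["variant_af"] >= FIXED_AF) & ~sub["triallelic"]]
        geno.update(zip(fixed["pos"], fixed["variant_base"]))
        genotypes[sample] = geno
    return genotypes


def genetic_distance(
    records: pd.DataFrame,
    mask: np.ndarray,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[float, float]:
    """Average pairwise fixed-genotype distance between two sample groups.

    For every cross-group pair, genotypes are compared at the intersection of
    positions passing QC in both samples; the distance is the count of
    differing genotypes.  Returns ``(mean, standard deviation)`` over the
    pairs.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    genos = _fixed_genotypes(records, mask, set(group_a) | set(group_b))
    dists = []
    for a in group_a:
        ga = genos[a]
        for b in group_b:
            gb = genos[b]
            common = ga.keys() & gb.keys()
            dists.append(sum(ga[p] != gb[p] for p in common))
    d = np.asarray(dists, dtype=float)
    return float(d.mean()), float(d.std(ddof=1)) if len(d) > 1 else 0.0


@dataclass(frozen=True)
class SubstitutionRate:
    rate: float               # substitutions per bp per year
    accumulated_per_bp: float  # mutations accumulated per bp since divergence
    accumulated: float         # mutations accumulated per genome (distance / 2)


def substitution_rate(
    distance: float, n_neutral: float, t_divergence: float
) -> SubstitutionRate:
    """Neutral substitution rate from a pairwise distance.

    ``distance / 2`` mutations accumulated along each of the two lineages
    since their split, normalised by the neutral positions per genome and the
    divergence time: ``rate = distance / (2 * n_neutral * t_divergence)``.
    """
    if n_neutral <= 0 or t_divergence <= 0:
        raise ValueError("n_neutral and t_divergence must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return SubstitutionRate(
        rate=distance / (2.0 * n_neutral * t_divergence),
        accumulated_per_bp=distance / (2.0 * n_neutral),
        accumulated=distance / 2.0,
    )


def estimate_copy_number(mean_organelle_coverage: float, nuclear_target: float) -> float:
    """Organelle replicons per cell from coverage normalised to the nuclear depth."""
    if nuclear_target <= 0:
        raise ValueError("nuclear target coverage must be positive")
    if mean_organelle_coverage < 0:
        raise ValueError("coverage must be non-negative")
    return mean_organelle_coverage / nuclear_target


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_vcf(calls: pd.DataFrame, path, reference_name: str = "organelle") -> None:
    """Write calls as a minimal single-sample-per-record VCF text file."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference_name}",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=KIND,Number=1,Type=String,Description="fixed or heteroplasmic">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, row in calls.iterrows():
        ref = row.get("ref", "N")
        info = f"AF={row['af']:.4f};KIND={row['kind']};SAMPLE={row['sample']}"
        lines.append(f"{row['organelle']}\t{row['pos']}\t.\t{ref}\t{row['base']}"
                     f"\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
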