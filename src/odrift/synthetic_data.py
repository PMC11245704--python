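"""Synthetic organelle resequencing cohorts with known ground truth.

The generator emulates the tabular shape of a short-read organelle
resequencing study: per-sample, per-position coverage and allele counts for a
mitochondrial and a plastid genome, two diverged sample groups separated by a
configurable number of fixed divergence SNPs, a handful of genuine
heteroplasmic sites, and — optionally — the artifact classes the filtering
stage exists to remove (coverage inflation over shared DNA, repeat-associated
candidates, clustered candidate pairs, and positions whose reference-allele
coverage betrays cross-mapped reads).

Coverage is drawn from an overdispersed negative-binomial model around each
sample's median; allele counts are binomial around the true allele frequency
with a symmetric per-base sequencing-error rate.  Every planted feature is
recorded in a :class:`GroundTruth` registry so that pipeline output can be
scored feature by feature and filter by filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variant_pipeline import (
    BASES,
    GenomeAnnotation,
    RECORD_COLUMNS,
)

__all__ = ["CohortConfig", "GroundTruth", "generate_annotation",
           "generate_cohort", "evaluate_calls"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-shaped defaults for one synthetic cohort.

    Genome lengths, coverage medians, divergence SNP counts and heteroplasmy
    allele frequencies default to the eelgrass study conditions (187,048 /
    143,968 bp genomes, median coverages around 985x mt and 6,966x pt, 57 mt
    and 23 pt divergence SNPs, observed heteroplasmy AFs); the default group
    sizes are a compact two-groups-of-five cohort (tests and examples pass
    smaller explicit configs).
    """

    mt_length: int = 187_048
    pt_length: int = 143_968
    group_sizes: tuple[int, int] = (5, 5)
    # annotation densities
    coding_fraction: float = 0.30
    n_repeats: int = 40
    repeat_length: tuple[int, int] = (9, 14)
    n_shared: int = 12
    shared_length: tuple[int, int] = (200, 2000)
    n_segments_mt: int = 4
    # divergence and heteroplasmy truth
    divergence_snps_mt: int = 57
    divergence_snps_pt: int = 23
    het_af_mt: tuple[float, ...] = (0.91,)
    het_af_pt: tuple[float, ...] = (0.75, 0.44, 0.82, 0.78, 0.50, 0.94)
    # coverage model
    median_coverage_mt: float = 985.0
    median_coverage_pt: float = 6966.0
    coverage_dispersion: float = 100.0  # negative-binomial shape; larger = tighter
    shared_inflation: float = 3.0       # coverage multiplier over shared DNA
    error_rate: float = 1e-3           # symmetric per-base misread rate
    # planted artifacts (0 disables the class)
    n_clustered_pairs: int = 1
    n_repeat_candidates: int = 1
    n_ref_covprop_artifacts: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.mt_length, self.pt_length) < 2000:
            raise ValueError("genome lengths must be at least 2 kb")
        if min(self.group_sizes) < 1:
            raise ValueError("both groups need at least one sample")
        if not 0.0 <= self.coding_fraction < 0.9:
            raise ValueError("coding_fraction must be in [0, 0.9)")
        if not 0.0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must stay below the heteroplasmy floor")
        for af in self.het_af_mt + self.het_af_pt:
            if not 0.05 <= af <= 0.95:
                raise ValueError("planted heteroplasmy AFs must lie in [0.05, 0.95]")

    def evolve(self, **overrides) -> "CohortConfig":
        return replace(self, **overrides)


@dataclass
class GroundTruth:
    """Registry of planted features and the filter expected to remove each artifact."""

    divergence: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    heteroplasmies: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)
    samples: dict[str, list[str]] = field(default_factory=dict)
    annotations: dict[str, GenomeAnnotation] = field(default_factory=dict)

    def heteroplasmy_index(self) -> set[tuple[str, str, int]]:
        return {(h["organelle"], h["sample"], h["pos"]) for h in self.heteroplasmies}


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def _random_intervals(rng, genome_length, n, len_range, forbidden=None) -> np.ndarray:
    """Place n non-overlapping intervals, avoiding a forbidden mask if given."""
    out = []
    occupied = np.zeros(genome_length, dtype=bool)
    if forbidden is not None:
        occupied |= forbidden
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError("could not place the requested annotation density")
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(0, genome_length - length))
        if occupied[start:start + length].any():
            continue
        occupied[start:start + length] = True
        out.append((start, start + length))
    return np.array(sorted(out), dtype=np.int64).reshape(-1, 2)


def generate_annotation(
    config: CohortConfig, rng: np.random.Generator, organelle: str
) -> GenomeAnnotation:
    """Random feature channels for one organelle genome.

    The mitochondrial genome gets ``n_segments_mt`` rearrangement segments
    and mtptDNA/NUMT shared regions; the plastid genome gets the quadripartite
    structure (LSC - IRa - SSC - IRb, the IRs each ~1/6 of the genome) whose
    four parts double as the coverage segments, plus NUPT/mtptDNA shared
    regions.  Inverted repeats on a mitochondrial genome are rejected.
    """
    if organelle not in ("mt", "pt"):
        raise ValueError("organelle must be 'mt' or 'pt' (IRs are pt-only)")
    L = config.mt_length if organelle == "mt" else config.pt_length

    if organelle == "pt":
        ir = L // 6
        lsc = (L - 2 * ir) * 2 // 3
        ssc = L - 2 * ir - lsc
        segments = np.array([
            [0, lsc], [lsc, lsc + ir],
            [lsc + ir, lsc + ir + ssc], [lsc + ir + ssc, L],
        ], dtype=np.int64)
        inverted = np.array([[lsc, lsc + ir], [lsc + ir + ssc, L]], dtype=np.int64)
    else:
        cuts = np.linspace(0, L, config.n_segments_mt + 1).astype(np.int64)
        segments = np.stack([cuts[:-1], cuts[1:]], axis=1)
        inverted = np.empty((0, 2), dtype=np.int64)

    # coding blocks: gene-sized intervals until the requested fraction is met
    coding = []
    occupied = np.zeros(L, dtype=bool)
    target = int(config.coding_fraction * L)
    covered = 0
    while covered < target:
        length = int(rng.integers(300, 2000))
        start = int(rng.integers(0, L - length))
        if occupied[start:start + length].any():
            continue
        occupied[start:start + length] = True
        coding.append((start, start + length))
        covered += length
    coding = (np.array(sorted(coding), dtype=np.int64).reshape(-1, 2)
              if coding else np.empty((0, 2), np.int64))

    repeats = _random_intervals(rng, L, config.n_repeats, config.repeat_length,
                                forbidden=occupied) \
        if config.n_repeats else np.empty((0, 2), np.int64)
    shared = _random_intervals(rng, L, config.n_shared, config.shared_length) \
        if config.n_shared else np.empty((0, 2), np.int64)
    half = len(shared) // 2
    kw = dict(
        genome_length=L, coding=coding, repeats=repeats,
        segments=segments, inverted_repeats=inverted,
    )
    if organelle == "mt":
        kw["numt"], kw["mtpt"] = shared[:half], shared[half:]
    else:
        kw["nupt"], kw["mtpt"] = shared[:half], shared[half:]
    return GenomeAnnotation(**kw)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _nb_coverage(rng, mean, dispersion, size):
    """Overdispersed coverage: negative binomial with the given mean/shape."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _pick_positions(rng, mask0, k, taken: set[int]) -> list[int]:
    """k distinct 1-based positions uniformly from a 0-based boolean mask."""
    avail = np.flatnonzero(mask0) + 1
    avail = np.array([p for p in avail if p not in taken])
    if len(avail) < k:
        raise ValueError("not enough neutral positions to plant the features")
    picked = rng.choice(avail, size=k, replace=False)
    taken.update(int(p) for p in picked)
    return [int(p) for p in picked]


def generate_cohort(
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    annotations: Optional[dict[str, GenomeAnnotation]] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the per-position tables of one cohort plus its ground truth.

    Returns a single records DataFrame in the pipeline's TSV dialect covering
    both organelles and all samples, and the :class:`GroundTruth` registry
    (which also carries the annotations used).
    """
    from .variant_pipeline import neutral_mask  # local to avoid cycle at import

    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    na, nb = config.group_sizes
    groups = {
        "A": [f"A{i:02d}" for i in range(1, na + 1)],
        "B": [f"B{i:02d}" for i in range(1, nb + 1)],
    }
    truth.samples = groups
    all_samples = groups["A"] + groups["B"]

    frames = []
    for organelle in ("mt", "pt"):
        ann = (annotations or {}).get(organelle) or \
            generate_annotation(config, rng, organelle)
        truth.annotations[organelle] = ann
        L = ann.genome_length
        ref = rng.integers(0, 4, size=L)

        het_mask = neutral_mask(ann, organelle, "heteroplasmy")
        fix_mask = neutral_mask(ann, organelle, "fixed")
        taken: set[int] = set()

        # divergence SNPs: fixed variant alleles in group B, neutral positions
        n_div = (config.divergence_snps_mt if organelle == "mt"
                 else config.divergence_snps_pt)
        div_pos = _pick_positions(rng, fix_mask & het_mask, n_div, taken)
        div_alt = {}
        for p in div_pos:
            alt = (ref[p - 1] + int(rng.integers(1, 4))) % 4
            div_alt[p] = alt
        truth.divergence[organelle] = [(p, BASES[div_alt[p]]) for p in div_pos]

        # genuine heteroplasmies: one random sample each, neutral positions
        het_afs = config.het_af_mt if organelle == "mt" else config.het_af_pt
        het_pos = _pick_positions(rng, het_mask, len(het_afs), taken)
        het_plan: dict[tuple[str, int], tuple[int, float]] = {}
        for p, af in zip(het_pos, het_afs):
            sample = all_samples[rng.integers(len(all_samples))]
            alt = (ref[p - 1] + int(rng.integers(1, 4))) % 4
            het_plan[(sample, p)] = (alt, af)
            truth.heteroplasmies.append({
                "organelle": organelle, "sample": sample, "pos": p,
                "base": BASES[alt], "af": af,
            })

        # artifact classes -------------------------------------------------
        artifact_het: dict[tuple[str, int], tuple[int, float]] = {}
        for _ in range(config.n_clustered_pairs):
            # both members of the pair must themselves be neutral positions
            pair_ok = het_mask[:-2] & het_mask[2:]
            base_pos = _pick_positions(rng, pair_ok, 1, taken)[0]
            pair = (base_pos, base_pos + 2)
            taken.add(base_pos + 2)
            sample = all_samples[rng.integers(len(all_samples))]
            for p in pair:
                alt = (ref[p - 1] + int(rng.integers(1, 4))) % 4
                artifact_het[(sample, p)] = (alt, 0.4)
                truth.artifacts.append({
                    "organelle": organelle, "sample": sample, "pos": p,
                    "class": "clustered", "expected_filter": "cluster",
                })
        repeat_halo_mask = ann.channel_mask("repeats", halo=2)
        for _ in range(config.n_repeat_candidates):
            if not repeat_halo_mask.any():
                break
            p = _pick_positions(rng, repeat_halo_mask, 1, taken)[0]
            sample = all_samples[rng.integers(len(all_samples))]
            alt = (ref[p - 1] + int(rng.integers(1, 4))) % 4
            artifact_het[(sample, p)] = (alt, 0.3)
            truth.artifacts.append({
                "organelle": organelle, "sample": sample, "pos": p,
                "class": "repeat", "expected_filter": "neutral_mask",
            })
        ref_inflated: dict[int, float] = {}
        for _ in range(config.n_ref_covprop_artifacts):
            p = _pick_positions(rng, het_mask, 1, taken)[0]
            sample = all_samples[rng.integers(len(all_samples))]
            alt = (ref[p - 1] + int(rng.integers(1, 4))) % 4
            # modest total inflation (usually inside the mt coverage-proportion
            # QC window) whose reference share alone exceeds the median
            artifact_het[(sample, p)] = (alt, 0.12)
            ref_inflated[p] = 1.42
            truth.artifacts.append({
                "organelle": organelle, "sample": sample, "pos": p,
                "class": "ref_cov_prop", "expected_filter": "ref_cov_prop",
            })

        # per-sample tables ------------------------------------------------
        median = (config.median_coverage_mt if organelle == "mt"
                  else config.median_coverage_pt)
        shared0 = ann.shared_mask()
        pos = np.arange(1, L + 1)
        for group, samples in groups.items():
            for sample in samples:
                sample_median = median * float(rng.lognormal(0.0, 0.25))
                mean_cov = np.full(L, sample_median)
                mean_cov[shared0] *= config.shared_inflation
                for p, factor in ref_inflated.items():
                    mean_cov[p - 1] *= factor
                cov = _nb_coverage(rng, mean_cov, config.coverage_dispersion, L)
                af = np.zeros(L)
                var_idx = ref.copy()
                if group == "B":
                    for p, alt in div_alt.items():
                        af[p - 1] = 1.0
                        var_idx[p - 1] = alt
                for (s, p), (alt, f) in {**het_plan, **artifact_het}.items():
                    if s == sample:
                        af[p - 1] = f
                        var_idx[p - 1] = alt
                counts = _sample_counts(rng, cov, ref, var_idx, af,
                                        config.error_rate)
                frames.append(pd.DataFrame({
                    "sample": sample, "organelle": organelle, "pos": pos,
                    "ref": np.array(BASES)[ref],
                    "coverage": cov,
                    "A": counts[:, 0], "C": counts[:, 1],
                    "G": counts[:, 2], "T": counts[:, 3],
                }))
    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    return records, truth


def _sample_counts(rng, cov, ref_idx, var_idx, af, error_rate):
    """Draw per-base read counts: true-allele binomials plus scattered misreads."""
    L = len(cov)
    counts = np.zeros((L, 4), dtype=np.int64)
    var_reads = rng.binomial(cov, af)
    ref_reads = cov - var_reads
    rows = np.arange(L)
    if error_rate > 0:
        err = rng.binomial(ref_reads, error_rate)
        ref_reads = ref_reads - err
        # scatter misreads over the three non-reference bases
        split = rng.multinomial(err, [1 / 3] * 3)
        other = np.array([[b for b in range(4) if b != r] for r in ref_idx])
        for j in range(3):
            np.add.at(counts, (rows, other[:, j]), split[:, j])
    counts[rows, ref_idx] += ref_reads
    np.add.at(counts, (rows, var_idx), var_reads)
    return counts


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def evaluate_calls(
    het_calls: pd.DataFrame,
    fixed_calls: pd.DataFrame,
    truth: GroundTruth,
    rejected: Optional[pd.DataFrame] = None,
) -> dict:
    """Precision/recall of the calls against the planted truth.

    The call tables may cover one or both organelles; the truth is restricted
    to the organelles present.  Fixed-call recall counts each planted
    divergence SNP as recovered when every group-B sample carries the fixed
    call; a fixed call at a planted heteroplasmy whose AF lies in the
    fixed/heteroplasmic overlap range (>= 0.75) is not counted as spurious.
    Heteroplasmy precision/recall are per (organelle, sample, position).
    When the ``rejected`` table from :func:`call_heteroplasmic` is supplied,
    each planted artifact is looked up there and scored against its intended
    filter (a mismatch is reported, not raised).
    """
    orgs = set(het_calls.get("organelle", pd.Series(dtype=str))) \
        | set(fixed_calls.get("organelle", pd.Series(dtype=str)))
    if not orgs:
        orgs = set(truth.annotations)
    truth_het = {k for k in truth.heteroplasmy_index() if k[0] in orgs}
    called_het = {(r.organelle, r.sample, int(r.pos))
                  for r in het_calls.itertuples()}
    tp = len(truth_het & called_het)
    het_precision = tp / len(called_het) if called_het else 1.0
    het_recall = tp / len(truth_het) if truth_het else 1.0

    fixed_index: dict[str, set[tuple[str, int]]] = {}
    for r in fixed_calls.itertuples():
        fixed_index.setdefault(r.organelle, set()).add((r.sample, int(r.pos)))
    b_samples = truth.samples.get("B", [])
    div_total = div_found = 0
    spurious = 0
    truth_div_pos = {org: {p for p, _ in sites}
                     for org, sites in truth.divergence.items()}
    overlap_het = {(h["organelle"], h["sample"], h["pos"])
                   for h in truth.heteroplasmies if h["af"] >= 0.75}
    for org, sites in truth.divergence.items():
        if org not in orgs:
            continue
        for p, _ in sites:
            div_total += 1
            hits = {s for s, q in fixed_index.get(org, set()) if q == p}
            if b_samples and set(b_samples) <= hits:
                div_found += 1
    for org, calls in fixed_index.items():
        spurious += sum(
            1 for s, p in calls
            if p not in truth_div_pos.get(org, set())
            and (org, s, p) not in overlap_het)
    fixed_recall = div_found / div_total if div_total else 1.0
    n_fixed_calls = sum(len(v) for v in fixed_index.values())
    fixed_precision = (n_fixed_calls - spurious) / n_fixed_calls if n_fixed_calls else 1.0

    artifact_report = []
    if rejected is not None:
        rej_index = {(r.organelle, r.sample, int(r.pos)): list(r.filters_failed)
                     for r in rejected.itertuples()}
        for art in truth.artifacts:
            key = (art["organelle"], art["sample"], art["pos"])
            expected = art["expected_filter"]
            if expected == "neutral_mask":
                # masked positions never reach the candidate stage
                caught = key not in called_het and key not in rej_index
                by = "neutral_mask" if caught else "none"
            elif key in rej_index:
                caught = True
                by = ";".join(rej_index[key])
            else:
                caught = key not in called_het
                by = "absent" if caught else "none"
            artifact_report.append({**art, "caught": caught,
                                    "caught_by": by,
                                    "as_intended": expected in by})
    return {
        "heteroplasmy": {"precision": het_precision, "recall": het_recall,
                         "n_true": len(truth_het), "n_called": len(called_het)},
        "fixed": {"precision": fixed_precision, "recall": fixed_recall,
                  "n_planted": div_total},
        "artifacts": artifact_report,
    }
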