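"""CDR3 spectratype analysis: clonality classes and repertoire perturbation.

A polyclonal T-cell population yields, for each of 23 TRBV subgroups, a
roughly Gaussian distribution of CDR3 fragment lengths on a 3-nt in-frame
ladder.  Clonal expansions distort that picture.  This module

1. parses GeneMapper-style fragment peak tables,
2. normalizes each subgroup's peak areas into a relative CDR3-length
   distribution,
3. classifies each distribution into four clonality categories —
   *normal* (>=7 peaks, Gaussian), *shifted* (>=7 peaks, non-Gaussian),
   *restricted* (<7 peaks) and *mono/oligoclonal* (one or two dominant
   peaks),
4. scores perturbation with the generalized Hamming distance
   ``D = 1/2 * sum_i |p_i - r_i| * 100`` against the mean distribution of a
   reference group of healthy controls (12 by default) — 0 % means
   identical to the reference, 100 % disjoint support, and
5. flags subgroups whose D exceeds the healthy-control mean + 2 SD or
   mean + 3 SD for that subgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import UndetectedSubgroupError, ValidationError
from .trbv import TRBV_SUBGROUPS

logger = logging.getLogger(__name__)

CLONALITY_CLASSES = ("normal", "shifted", "restricted", "mono_oligoclonal")

#: default minimum relative area for a peak to count as detectable
MIN_PEAK_FRAC = 0.02
#: subgroups whose total area (rfu*nt) is below this are treated as
#: undetected; instrument-dependent, deliberately permissive by default
AREA_FLOOR = 1.0


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds of the four-category clonality classifier.

    Decision order: dominance first (so a 7-peak profile with one towering
    peak is still called mono/oligoclonal), then peak count, then the
    Gaussian shape test.
    """

    top1_dominance: float = 0.40  # top-1 area share for mono/oligoclonal
    top2_dominance: float = 0.60  # top-2 area share for mono/oligoclonal
    min_normal_peaks: int = 7  # fewer detectable peaks => restricted
    gaussian_r2_threshold: float = 0.90  # fit score below => shifted
    min_peak_frac: float = MIN_PEAK_FRAC
    area_floor: float = AREA_FLOOR


@dataclass(frozen=True)
class PeakRecord:
    sample_id: str
    trbv: str
    fragment_size: float  # nt
    height: float  # rfu
    area: float  # rfu*nt

    def __post_init__(self) -> None:
        if self.trbv not in TRBV_SUBGROUPS:
            raise ValidationError(
                f"unknown TRBV subgroup {self.trbv!r}; valid names: {', '.join(TRBV_SUBGROUPS)}"
            )
        if self.area < 0:
            raise ValidationError(f"negative peak area for {self.sample_id}/{self.trbv}")


@dataclass(frozen=True)
class TRBVDistribution:
    """Relative CDR3-length distribution of one TRBV subgroup."""

    trbv: str
    lengths: tuple[float, ...]  # strictly increasing fragment sizes (nt)
    rel_area: np.ndarray  # fractions summing to 1 (if detected)
    detected: bool = True

    def as_mapping(self) -> dict[float, float]:
        return dict(zip(self.lengths, self.rel_area.tolist()))


@dataclass(frozen=True)
class ProfileClass:
    label: str
    peak_count: int
    gaussian_fit_score: float
    top1_share: float
    top2_share: float


@dataclass(frozen=True)
class ReferenceRepertoire:
    """Healthy-control reference: per-TRBV mean distribution and D statistics."""

    mean_distributions: dict[str, TRBVDistribution]
    perturbation_mean: dict[str, float]  # % over the full HC pool
    perturbation_sd: dict[str, float]
    reference_ids: tuple[str, ...]


@dataclass(frozen=True)
class PerturbationResult:
    sample_id: str
    per_trbv: dict[str, float]  # D in %
    global_perturbation: float  # mean D over evaluated subgroups, %
    flags: dict[str, str]  # none | over2sd | over3sd
    n_overperturbed: int  # subgroups flagged at >= 2 SD
    n_evaluated: int = 0


# ---------------------------------------------------------------------------
# parsing and normalization
# ---------------------------------------------------------------------------

PEAK_TABLE_COLUMNS = ("sample_id", "trbv", "fragment_size", "height", "area")


def parse_peak_table(path_or_frame: str | Path | pd.DataFrame) -> dict[str, list[PeakRecord]]:
    """Read a fragment peak table (TSV) into per-sample peak records.

    Columns required: sample_id, trbv, fragment_size, height, area.
    Subgroup names are validated against the 23-name IMGT vocabulary.
    Within each (sample, trbv) the peaks are sorted by fragment size;
    duplicate sizes are rejected.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, sep="\t")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"peak table missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("peak table is empty")
        return {}
    unknown = sorted(set(df["trbv"].astype(str)) - set(TRBV_SUBGROUPS))
    if unknown:
        raise ValidationError(
            f"unknown TRBV subgroup(s) {unknown}; valid names: {', '.join(TRBV_SUBGROUPS)}"
        )
    out: dict[str, list[PeakRecord]] = {}
    for (sid, trbv), grp in df.groupby(["sample_id", "trbv"], sort=False):
        grp = grp.sort_values("fragment_size")
        sizes = grp["fragment_size"].to_numpy(dtype=float)
        if np.any(np.diff(sizes) <= 0):
            raise ValidationError(f"duplicate fragment size in {sid}/{trbv}")
        out.setdefault(str(sid), []).extend(
            PeakRecord(str(sid), str(trbv), float(r.fragment_size), float(r.height), float(r.area))
            for r in grp.itertuples()
        )
    return out


def normalize_distribution(
    peaks: Sequence[PeakRecord],
    min_peak_frac: float = MIN_PEAK_FRAC,
    area_floor: float = AREA_FLOOR,
) -> TRBVDistribution:
    """Turn one subgroup's peak areas into a relative distribution.

    Peaks below ``min_peak_frac`` of the subgroup total are zeroed (they do
    not count as detectable); the rest is renormalized to sum to 1.  A
    subgroup whose total area is below ``area_floor`` is marked undetected.
    """
    if not peaks:
        raise ValidationError("normalize_distribution needs at least one peak record")
    trbvs = {p.trbv for p in peaks}
    if len(trbvs) != 1:
        raise ValidationError(f"peaks span multiple subgroups: {sorted(trbvs)}")
    trbv = peaks[0].trbv
    ordered = sorted(peaks, key=lambda p: p.fragment_size)
    lengths = tuple(p.fragment_size for p in ordered)
    area = np.array([p.area for p in ordered], dtype=float)
    total = float(area.sum())
    if total < area_floor:
        return TRBVDistribution(trbv, lengths, np.zeros_like(area), detected=False)
    rel = area / total
    rel[rel < min_peak_frac] = 0.0
    rel = rel / rel.sum()
    return TRBVDistribution(trbv, lengths, rel, detected=True)


def profiles_from_peaks(
    records: Mapping[str, Sequence[PeakRecord]],
    min_peak_frac: float = MIN_PEAK_FRAC,
    area_floor: float = AREA_FLOOR,
) -> dict[str, dict[str, TRBVDistribution]]:
    """Group parsed peak records into per-sample, per-TRBV distributions."""
    out: dict[str, dict[str, TRBVDistribution]] = {}
    for sid, peaks in records.items():
        by_trbv: dict[str, list[PeakRecord]] = {}
        for p in peaks:
            by_trbv.setdefault(p.trbv, []).append(p)
        out[sid] = {
            trbv: normalize_distribution(plist, min_peak_frac, area_floor)
            for trbv, plist in by_trbv.items()
        }
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def count_peaks(dist: TRBVDistribution) -> int:
    """Number of ladder positions with positive relative area."""
    if not dist.detected:
        raise UndetectedSubgroupError(f"{dist.trbv}: peak count undefined for undetected subgroup")
    return int(np.count_nonzero(dist.rel_area > 0))


_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gaussian_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed unit-amplitude Gaussian shapes over n ladder positions.

    Grid over mean (0..n-1, fine) and width (geometric); amplitude is solved
    in closed form per shape, so scoring one profile is a single matmul.
    """
    if n not in _GRID_CACHE:
        x = np.arange(n, dtype=float)
        means = np.linspace(0.0, n - 1.0, 8 * (n - 1) + 1)
        sigmas = np.geomspace(0.4, max(4.0, n / 2.0), 48)
        mu, sg = np.meshgrid(means, sigmas, indexing="ij")
        shapes = np.exp(-((x[None, None, :] - mu[..., None]) ** 2) / (2.0 * sg[..., None] ** 2))
        shapes = shapes.reshape(-1, n)
        _GRID_CACHE[n] = (shapes, np.einsum("ij,ij->i", shapes, shapes))
    return _GRID_CACHE[n]


def gaussian_fit_score(rel_area: np.ndarray) -> float:
    """R² of the best least-squares discrete Gaussian (amplitude, mean, width).

    The fit is over the ladder index axis; amplitude is profiled out
    analytically and (mean, width) searched on a fine deterministic grid.
    Returns 0 for flat profiles (zero variance: no Gaussian shape evidence).
    """
    y = np.asarray(rel_area, dtype=float)
    n = y.size
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-14:
        return 0.0
    shapes, gg = _gaussian_grid(n)
    gy = shapes @ y
    amp = np.where(gg > 0, gy / gg, 0.0)
    ss_res = float(np.min(np.sum(y * y) - 2 * amp * gy + amp**2 * gg))
    return max(0.0, 1.0 - max(ss_res, 0.0) / ss_tot)


def classify_profile(
    dist: TRBVDistribution, config: ClassifierConfig = ClassifierConfig()
) -> ProfileClass:
    """Assign one of the four clonality categories to a detected subgroup.

    Order: (1) mono/oligoclonal on dominance, (2) restricted on peak count,
    (3) normal vs shifted on the Gaussian shape score.
    """
    if not dist.detected:
        raise UndetectedSubgroupError(f"{dist.trbv}: cannot classify undetected subgroup")
    rel = dist.rel_area
    srt = np.sort(rel)[::-1]
    top1 = float(srt[0])
    top2 = float(srt[0] + (srt[1] if srt.size > 1 else 0.0))
    npk = int(np.count_nonzero(rel > 0))
    score = gaussian_fit_score(rel)
    if top1 >= config.top1_dominance or top2 >= config.top2_dominance:
        label = "mono_oligoclonal"
    elif npk < config.min_normal_peaks:
        label = "restricted"
    elif score >= config.gaussian_r2_threshold:
        label = "normal"
    else:
        label = "shifted"
    return ProfileClass(label, npk, score, top1, top2)


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


def _aligned(p: TRBVDistribution, r: TRBVDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Align two distributions on the union ladder (absent position = 0)."""
    union = sorted(set(p.lengths) | set(r.lengths))
    pm, rm = p.as_mapping(), r.as_mapping()
    pv = np.array([pm.get(s, 0.0) for s in union])
    rv = np.array([rm.get(s, 0.0) for s in union])
    return pv, rv


def perturbation_score(dist: TRBVDistribution, ref_mean: TRBVDistribution) -> float:
    """Generalized Hamming distance ``D = 1/2 * sum |p - r| * 100`` in percent.

    Equivalent to the total-variation distance between the two relative-area
    vectors, scaled to [0, 100]; symmetric, 0 iff identical on the shared
    ladder, 100 on disjoint supports.
    """
    if not dist.detected:
        raise UndetectedSubgroupError(f"{dist.trbv}: no perturbation score for undetected subgroup")
    pv, rv = _aligned(dist, ref_mean)
    return float(0.5 * np.abs(pv - rv).sum() * 100.0)


def build_reference(
    hc_profiles: Mapping[str, Mapping[str, TRBVDistribution]],
    n_ref: int = 12,
    seed: int | np.random.Generator = 0,
) -> ReferenceRepertoire:
    """Build the healthy-control reference repertoire.

    ``n_ref`` subjects (default 12) are drawn from the HC pool with a seeded
    generator; the per-TRBV mean of their relative-area vectors is the
    reference distribution.  Per-TRBV perturbation mean/SD are then computed
    by scoring *every* HC subject (reference members included) against that
    mean.
    """
    ids = sorted(hc_profiles)
    if len(ids) < n_ref:
        raise ValidationError(f"need >= {n_ref} healthy controls, got {len(ids)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref_ids = tuple(sorted(rng.choice(ids, size=n_ref, replace=False).tolist()))

    mean_dists: dict[str, TRBVDistribution] = {}
    for trbv in TRBV_SUBGROUPS:
        members = [
            hc_profiles[sid][trbv]
            for sid in ref_ids
            if trbv in hc_profiles[sid] and hc_profiles[sid][trbv].detected
        ]
        if not members:
            continue
        union = sorted({s for d in members for s in d.lengths})
        acc = np.zeros(len(union))
        for d in members:
            dm = d.as_mapping()
            acc += np.array([dm.get(s, 0.0) for s in union])
        acc /= len(members)
        mean_dists[trbv] = TRBVDistribution(trbv, tuple(union), acc, detected=True)

    pert_mean: dict[str, float] = {}
    pert_sd: dict[str, float] = {}
    for trbv, ref in mean_dists.items():
        scores = [
            perturbation_score(hc_profiles[sid][trbv], ref)
            for sid in ids
            if trbv in hc_profiles[sid] and hc_profiles[sid][trbv].detected
        ]
        pert_mean[trbv] = float(np.mean(scores))
        pert_sd[trbv] = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0

    return ReferenceRepertoire(mean_dists, pert_mean, pert_sd, ref_ids)


def flag_overperturbed(
    sample_id: str, per_trbv_d: Mapping[str, float], ref: ReferenceRepertoire
) -> PerturbationResult:
    """Flag subgroups whose D exceeds the HC mean + 2 SD / + 3 SD (strictly).

    D exactly at the bound is not flagged ("higher than" is strict); a 3-SD
    flag always implies the 2-SD bound is also exceeded.
    """
    flags: dict[str, str] = {}
    for trbv, d in per_trbv_d.items():
        if trbv not in ref.perturbation_mean:
            raise ValidationError(f"reference has no entry for scored subgroup {trbv}")
        m, s = ref.perturbation_mean[trbv], ref.perturbation_sd[trbv]
        if d > m + 3 * s:
            flags[trbv] = "over3sd"
        elif d > m + 2 * s:
            flags[trbv] = "over2sd"
        else:
            flags[trbv] = "none"
    n_over = sum(1 for f in flags.values() if f != "none")
    vals = list(per_trbv_d.values())
    return PerturbationResult(
        sample_id=sample_id,
        per_trbv=dict(per_trbv_d),
        global_perturbation=float(np.mean(vals)) if vals else float("nan"),
        flags=flags,
        n_overperturbed=n_over,
        n_evaluated=len(vals),
    )


def score_subject(
    sample_id: str,
    profiles: Mapping[str, TRBVDistribution],
    ref: ReferenceRepertoire,
) -> PerturbationResult:
    """Per-TRBV D and flags for one subject against the reference."""
    per_trbv = {
        trbv: perturbation_score(dist, ref.mean_distributions[trbv])
        for trbv, dist in profiles.items()
        if dist.detected and trbv in ref.mean_distributions
    }
    return flag_overperturbed(sample_id, per_trbv, ref)


def perturbed_counts_per_trbv(results: Iterable[PerturbationResult]) -> dict[str, int]:
    """Across subjects, how many are flagged (>=2 SD) in each TRBV subgroup."""
    counts = {t: 0 for t in TRBV_SUBGROUPS}
    for res in results:
        for trbv, flag in res.flags.items():
            if flag != "none":
                counts[trbv] += 1
    return counts


# ---------------------------------------------------------------------------
# cohort-level summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySummary:
    """Per-group clonality-class proportions and perturbation descriptives."""

    pooled_proportions: dict[str, dict[str, float]]  # group -> class -> fraction
    per_subject_fraction_nonnormal: dict[str, float]  # subject -> fraction
    per_subject_global_perturbation: dict[str, float]  # subject -> %
    group_perturbation_median_iqr: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )


def summarize_categories(
    classifications: Mapping[str, Mapping[str, ProfileClass]],
    perturbations: Mapping[str, PerturbationResult],
    groups: Mapping[str, str],
) -> CategorySummary:
    """Cohort summary over (subject x detected TRBV) units.

    Pooled class proportions are computed per group over all detected
    subgroups of all its subjects; per-subject values (fraction of
    non-normal subgroups, global perturbation) are reported alongside so
    subject-averaged summaries can be derived too.
    """
    pooled: dict[str, dict[str, int]] = {}
    frac_nonnormal: dict[str, float] = {}
    for sid, per_trbv in classifications.items():
        grp = groups[sid]
        counts = pooled.setdefault(grp, {c: 0 for c in CLONALITY_CLASSES})
        labels = [pc.label for pc in per_trbv.values()]
        for lab in labels:
            counts[lab] += 1
        if labels:
            frac_nonnormal[sid] = sum(1 for l in labels if l != "normal") / len(labels)
    proportions = {
        grp: {c: counts[c] / max(1, sum(counts.values())) for c in CLONALITY_CLASSES}
        for grp, counts in pooled.items()
    }
    global_pert = {sid: res.global_perturbation for sid, res in perturbations.items()}
    med_iqr: dict[str, tuple[float, float, float]] = {}
    for grp in proportions:
        vals = np.array([v for sid, v in global_pert.items() if groups[sid] == grp])
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            med_iqr[grp] = (float(med), float(q1), float(q3))
    return CategorySummary(proportions, frac_nonnormal, global_pert, med_iqr)


def trbv_usage(
    profiles_or_areas: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subject share of total area per TRBV, with optional group medians.

    Accepts either a mapping subject -> {trbv: total area} or a peak-table
    DataFrame; returns a tidy frame (sample_id, trbv, share[, group]).
    """
    if isinstance(profiles_or_areas, pd.DataFrame):
        totals = (
            profiles_or_areas.groupby(["sample_id", "trbv"])["area"].sum().unstack(fill_value=0.0)
        )
    else:
        totals = pd.DataFrame(profiles_or_areas).T.fillna(0.0)
        totals.index.name = "sample_id"
    shares = totals.div(totals.sum(axis=1), axis=0)
    tidy = shares.reset_index().melt(id_vars="sample_id", var_name="trbv", value_name="share")
    if groups is not None:
        tidy["group"] = tidy["sample_id"].map(dict(groups))
    return tidy


def flag_matrix(results: Mapping[str, PerturbationResult]) -> pd.DataFrame:
    """Subjects x 23 TRBV matrix of flags with row/column overperturbed sums."""
    rows = {}
    for sid, res in results.items():
        rows[sid] = {t: res.flags.get(t, "nd") for t in TRBV_SUBGROUPS}
    df = pd.DataFrame.from_dict(rows, orient="index")[list(TRBV_SUBGROUPS)]
    df["n_overperturbed"] = [results[sid].n_overperturbed for sid in df.index]
    col_counts = perturbed_counts_per_trbv(results.values())
    df.loc["n_patients_perturbed"] = [col_counts[t] for t in TRBV_SUBGROUPS] + [
        sum(col_counts.values())
    ]
    return df
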