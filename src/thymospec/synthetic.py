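"""Synthetic cohort generator with known ground truth.

The real study cohorts (21 perinatally HIV-infected young adults, 19
non-perinatally infected young adults, 40 healthy controls) are not public,
so every downstream stage is exercised on simulated data that emulates the
cohort's statistical structure:

* Table-1-style clinical metadata (age, gender, CD4/CD8 counts and
  percentages) with group-specific medians and IQRs,
* configured Pearson correlations between clinical and laboratory
  variables, induced by a Gaussian copula on per-subject latent normals
  (rank-preserving, so the marginal medians/IQRs survive; the induced
  Pearson r is approximate and verified by Monte-Carlo in the tests),
* per-subject, per-TRBV clonality class labels drawn from group-level
  category mixes, and CDR3 spectratype peak tables realising those classes,
* qPCR plates (telomere T/S and duplex TREC/KREC) whose Cq values follow
  the configured standard curves plus Gaussian noise.

Seeding is counter-based: every subject derives its own generator from
``(seed, group index, subject index)``, so adding subjects or groups never
perturbs previously generated subjects' data, and a fixed seed reproduces
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .qpcr import BloodNormalization, QpcrPlate, Well
from .trbv import DEFAULT_N_LENGTHS, LADDER_SPACING_NT, TRBV_SUBGROUPS, ladder_offset

GROUPS = ("pHIVy", "npHIVy", "HC")
CLASSES = ("normal", "shifted", "restricted", "mono_oligoclonal")

#: IQR -> SD for a normal distribution (Q3 - Q1 = 1.349 sigma)
_IQR_TO_SD = 1.3489795


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_group_sizes() -> dict[str, int]:
    return {"pHIVy": 21, "npHIVy": 19, "HC": 40}


def _default_age() -> dict[str, tuple[float, float, float]]:
    # median, Q1, Q3 (years)
    return {"pHIVy": (27, 24, 29), "npHIVy": (27, 24, 29), "HC": (28, 24, 31)}


def _default_cd4() -> dict[str, tuple[float, float, float]]:
    return {"pHIVy": (803, 526, 1052), "npHIVy": (818, 688, 1024), "HC": (851, 643, 1099)}


def _default_cd4_pct() -> dict[str, tuple[float, float, float]]:
    return {"pHIVy": (33.8, 28.7, 38.8), "npHIVy": (38.1, 31.9, 42.0), "HC": (42.9, 39.7, 49.4)}


def _default_ratio() -> dict[str, tuple[float, float, float]]:
    return {"pHIVy": (0.8, 0.6, 1.2), "npHIVy": (1.2, 0.8, 1.4), "HC": (2.0, 2.0, 2.5)}


def _default_cd8_pct() -> dict[str, tuple[float, float, float]]:
    return {"pHIVy": (42.8, 32.7, 51.0), "npHIVy": (32.3, 28.0, 40.3), "HC": (22.2, 22.0, 22.6)}


def _default_male_frac() -> dict[str, float]:
    return {"pHIVy": 7 / 21, "npHIVy": 12 / 19, "HC": 19 / 40}


def _default_category_mix() -> dict[str, dict[str, float]]:
    # normal / restricted / mono-oligoclonal anchored to the reported pooled
    # proportions; the unreported shifted (and pHIVy mono) shares close each
    # mix to 1.
    return {
        "pHIVy": {"normal": 0.168, "shifted": 0.287, "restricted": 0.495, "mono_oligoclonal": 0.050},
        "npHIVy": {"normal": 0.188, "shifted": 0.338, "restricted": 0.360, "mono_oligoclonal": 0.114},
        "HC": {"normal": 0.275, "shifted": 0.341, "restricted": 0.355, "mono_oligoclonal": 0.029},
    }


def _default_ts_median() -> dict[str, float]:
    # HIV groups carry shorter telomeres than controls; levels are not
    # published, these are realistic relative T/S levels.
    return {"pHIVy": 0.85, "npHIVy": 0.87, "HC": 1.05}


def _default_trec_krec() -> dict[str, dict[str, tuple[float, float]]]:
    # log10 copies/ml (mean, sd); identical across groups: thymic and
    # bone-marrow output did not differ between groups in the study design
    # this emulates.
    per_group = {"TREC": (3.6, 0.45), "KREC": (3.8, 0.45)}
    return {g: dict(per_group) for g in GROUPS}


def _default_perturbation_median() -> dict[str, float]:
    # subject-level severity medians (%): HIV groups more perturbed than HC
    return {"pHIVy": 14.4, "npHIVy": 15.1, "HC": 10.4}


def _default_correlations() -> list[tuple[str, str, str, float]]:
    # (variable a, variable b, group, target Pearson r); the trec-ts and
    # ratio-cd4 entries keep the target matrix positive definite and are
    # themselves biologically sensible couplings.
    return [
        ("trec", "cd4_abs", "pHIVy", 0.75),
        ("ts", "cd4_abs", "pHIVy", 0.75),
        ("trec", "ts", "pHIVy", 0.70),
        ("cd4_cd8_ratio", "cd4_abs", "pHIVy", 0.18),
        ("perturbation", "cd4_cd8_ratio", "pHIVy", -0.81),
    ]


#: latent variables jointly sampled per subject (cd8_abs is derived as
#: cd4_abs / cd4_cd8_ratio so the ratio invariant holds exactly)
COPULA_VARIABLES = (
    "age",
    "cd4_abs",
    "cd4_pct",
    "cd4_cd8_ratio",
    "cd8_pct",
    "trec",
    "krec",
    "ts",
    "perturbation",
)

_VARIABLE_ALIASES = {
    "cd4": "cd4_abs",
    "cd4+": "cd4_abs",
    "ratio": "cd4_cd8_ratio",
    "cd4/cd8": "cd4_cd8_ratio",
    "t/s": "ts",
    "tl": "ts",
}


def canonical_variable(name: str) -> str:
    key = name.strip().lower()
    key = _VARIABLE_ALIASES.get(key, key)
    if key not in COPULA_VARIABLES:
        raise ConfigurationError(
            f"unknown correlation variable {name!r}; valid: {', '.join(COPULA_VARIABLES)}"
        )
    return key


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    age_median_iqr: dict = field(default_factory=_default_age)
    cd4_median_iqr: dict = field(default_factory=_default_cd4)
    cd4_pct_median_iqr: dict = field(default_factory=_default_cd4_pct)
    ratio_median_iqr: dict = field(default_factory=_default_ratio)
    cd8_pct_median_iqr: dict = field(default_factory=_default_cd8_pct)
    male_fraction: dict = field(default_factory=_default_male_frac)
    correlation_targets: list = field(default_factory=_default_correlations)
    category_mix: dict = field(default_factory=_default_category_mix)
    tl_ts_median: dict = field(default_factory=_default_ts_median)
    ts_sd: float = 0.18
    trec_krec_log10_mean_sd: dict = field(default_factory=_default_trec_krec)
    perturbation_median: dict = field(default_factory=_default_perturbation_median)
    perturbation_sd: float = 4.0
    qpcr_noise_sd: float = 0.05  # Cq units
    n_lengths: int = DEFAULT_N_LENGTHS
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"invalid group name {g!r}; valid: {GROUPS}")
            if n <= 0:
                raise ConfigurationError(f"group size for {g} must be > 0, got {n}")
        for g, mix in self.category_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"category mix for {g} sums to {total}, expected 1")
            if set(mix) != set(CLASSES):
                raise ConfigurationError(f"category mix for {g} must cover {CLASSES}")
        for a, b, g, r in self.correlation_targets:
            if g not in GROUPS:
                raise ConfigurationError(f"correlation target names invalid group {g!r}")
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"correlation target |r|<=1 violated for ({a}, {b})")
            canonical_variable(a), canonical_variable(b)
        if self.qpcr_noise_sd < 0:
            raise ConfigurationError("qpcr_noise_sd must be >= 0")
        if self.n_lengths < 3:
            raise ConfigurationError("n_lengths must be >= 3")


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: int
    gender: str  # M | F
    cd4_abs: float
    cd4_pct: float
    cd8_abs: float
    cd8_pct: float
    cd4_cd8_ratio: float


@dataclass(frozen=True)
class SubjectTruth:
    ts: float
    trec_copies_per_ml: float
    krec_copies_per_ml: float
    severity: float  # subject-level perturbation severity target, %
    classes: dict[str, str]  # trbv -> clonality class
    perturbation_target: dict[str, float]  # trbv -> nominal D target, %


@dataclass(frozen=True)
class GroundTruth:
    subjects: dict[str, SubjectTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            sid: {
                "ts": t.ts,
                "trec_copies_per_ml": t.trec_copies_per_ml,
                "krec_copies_per_ml": t.krec_copies_per_ml,
                "severity": t.severity,
                "classes": t.classes,
                "perturbation_target": t.perturbation_target,
            }
            for sid, t in self.subjects.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# copula machinery
# ---------------------------------------------------------------------------


def _margin_spec(config: CohortConfig, group: str, var: str) -> tuple:
    """Hashable description of one variable's marginal transform."""
    if var == "age":
        return ("age", *config.age_median_iqr[group])
    if var == "cd4_abs":
        return ("lognorm", *config.cd4_median_iqr[group])
    if var == "cd4_pct":
        return ("normclip", *config.cd4_pct_median_iqr[group], 1.0, 99.0)
    if var == "cd4_cd8_ratio":
        return ("lognorm", *config.ratio_median_iqr[group])
    if var == "cd8_pct":
        return ("normclip", *config.cd8_pct_median_iqr[group], 1.0, 99.0)
    if var == "trec":
        return ("log10norm", *config.trec_krec_log10_mean_sd[group]["TREC"])
    if var == "krec":
        return ("log10norm", *config.trec_krec_log10_mean_sd[group]["KREC"])
    if var == "ts":
        return ("meansd_clip", config.tl_ts_median[group], config.ts_sd, 0.2, math.inf)
    if var == "perturbation":
        return ("meansd_clip", config.perturbation_median[group], config.perturbation_sd, 2.0, 60.0)
    raise ConfigurationError(f"no marginal defined for variable {var!r}")


def _transform(spec: tuple, z: np.ndarray) -> np.ndarray:
    """Apply a marginal transform to latent standard normals (vectorized)."""
    kind = spec[0]
    if kind == "age":
        _, med, q1, q3 = spec
        return np.clip(np.round(med + z * (q3 - q1) / _IQR_TO_SD), 18, 45)
    if kind == "lognorm":
        _, med, q1, q3 = spec
        sigma = (math.log(q3) - math.log(q1)) / _IQR_TO_SD
        return np.exp(math.log(med) + sigma * z)
    if kind == "normclip":
        _, med, q1, q3, lo, hi = spec
        return np.clip(med + z * (q3 - q1) / _IQR_TO_SD, lo, hi)
    if kind == "log10norm":
        _, mean, sd = spec
        return 10.0 ** (mean + sd * z)
    if kind == "meansd_clip":
        _, mean, sd, lo, hi = spec
        return np.clip(mean + sd * z, lo, hi)
    raise ConfigurationError(f"unknown margin kind {kind!r}")


# fixed quadrature sample for latent-correlation calibration (independent of
# the cohort seed so calibration never consumes study randomness)
_CALIB_N = 200_000
_CALIB_SEED = 987_654_321


@lru_cache(maxsize=256)
def _latent_correlation(r_target: float, spec_a: tuple, spec_b: tuple) -> float:
    """Latent normal correlation that realises ``r_target`` Pearson r after
    the two marginal transforms (solved by bisection on a fixed sample).

    The Gaussian copula preserves rank correlation but nonlinear margins
    attenuate Pearson r; this inverts that attenuation.
    """
    if r_target == 0.0:
        return 0.0
    rng = np.random.default_rng(_CALIB_SEED)
    z1 = rng.standard_normal(_CALIB_N)
    z2 = rng.standard_normal(_CALIB_N)
    xa = _transform(spec_a, z1)
    xa = (xa - xa.mean()) / xa.std()

    def realized(rho: float) -> float:
        xb = _transform(spec_b, rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
        sb = xb.std()
        if sb == 0:
            return 0.0
        return float(np.mean(xa * (xb - xb.mean()) / sb))

    lo, hi = (0.0, 0.9999) if r_target > 0 else (-0.9999, 0.0)
    if abs(realized(hi if r_target > 0 else lo)) < abs(r_target):
        raise ConfigurationError(
            f"Pearson target {r_target} unattainable under the configured margins"
        )
    for _ in range(40):  # realized r is monotone increasing in rho
        mid = 0.5 * (lo + hi)
        if realized(mid) < r_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _correlation_matrix(config: CohortConfig, group: str) -> np.ndarray:
    """Latent correlation matrix for one group.

    Each configured Pearson target is mapped to its margin-calibrated latent
    correlation before assembly; joint infeasibility (a non-positive-definite
    matrix) is a configuration error naming the offending pairs.
    """
    k = len(COPULA_VARIABLES)
    idx = {v: i for i, v in enumerate(COPULA_VARIABLES)}
    r_mat = np.eye(k)
    pairs = []
    for a, b, g, r in config.correlation_targets:
        if g != group:
            continue
        ca, cb = canonical_variable(a), canonical_variable(b)
        ia, ib = idx[ca], idx[cb]
        if ia == ib:
            raise ConfigurationError(f"correlation target pairs a variable with itself: {a}")
        try:
            latent = _latent_correlation(
                float(r), _margin_spec(config, group, ca), _margin_spec(config, group, cb)
            )
        except ConfigurationError as exc:
            raise ConfigurationError(f"pair ({a}, {b}) in group {group}: {exc}") from None
        r_mat[ia, ib] = r_mat[ib, ia] = latent
        pairs.append((a, b))
    eigvals = np.linalg.eigvalsh(r_mat)
    if eigvals.min() < 1e-10:
        raise ConfigurationError(
            f"correlation targets for group {group} are jointly unattainable "
            f"(latent matrix not positive definite); offending pairs: {pairs}"
        )
    return r_mat


def _subject_rng(seed: int, group_index: int, subject_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_index, subject_index, stream))
    return np.random.default_rng(ss)


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Sample the cohort metadata and the hidden per-subject truth.

    Deterministic for a fixed ``config.seed``; group sizes are exactly as
    configured; configured correlations are induced within each group by a
    Gaussian copula on the latent normals behind each variable's marginal.
    """
    config.validate()
    chol = {g: np.linalg.cholesky(_correlation_matrix(config, g)) for g in config.group_sizes}
    subjects: list[SubjectRecord] = []
    truths: dict[str, SubjectTruth] = {}
    vidx = {v: i for i, v in enumerate(COPULA_VARIABLES)}

    for g, n in config.group_sizes.items():
        gi = GROUPS.index(g)
        specs = {v: _margin_spec(config, g, v) for v in COPULA_VARIABLES}

        def margin(var: str, z: np.ndarray) -> float:
            return float(_transform(specs[var], np.asarray([z[vidx[var]]]))[0])

        for j in range(n):
            rng = _subject_rng(config.seed, gi, j, 0)
            z = chol[g] @ rng.standard_normal(len(COPULA_VARIABLES))
            age = int(margin("age", z))
            cd4 = margin("cd4_abs", z)
            cd4_pct = margin("cd4_pct", z)
            ratio = margin("cd4_cd8_ratio", z)
            cd8 = cd4 / ratio
            cd8_pct = margin("cd8_pct", z)
            trec = margin("trec", z)
            krec = margin("krec", z)
            ts = margin("ts", z)
            severity = margin("perturbation", z)
            gender = "M" if rng.random() < config.male_fraction[g] else "F"

            sid = f"{g}-{j + 1:03d}"
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=g,
                    age=age,
                    gender=gender,
                    cd4_abs=round(cd4, 1),
                    cd4_pct=round(cd4_pct, 1),
                    cd8_abs=round(cd8, 1),
                    cd8_pct=round(cd8_pct, 1),
                    cd4_cd8_ratio=round(cd4, 1) / round(cd8, 1),
                )
            )

            class_rng = _subject_rng(config.seed, gi, j, 1)
            mix = config.category_mix[g]
            probs = np.array([mix[c] for c in CLASSES])
            draws = class_rng.choice(len(CLASSES), size=len(TRBV_SUBGROUPS), p=probs)
            classes = {t: CLASSES[d] for t, d in zip(TRBV_SUBGROUPS, draws)}
            factor = {"normal": 0.6, "shifted": 1.0, "restricted": 1.4, "mono_oligoclonal": 2.2}
            pert_target = {
                t: float(np.clip(severity * factor[c], 0.0, 100.0)) for t, c in classes.items()
            }
            truths[sid] = SubjectTruth(
                ts=ts,
                trec_copies_per_ml=trec,
                krec_copies_per_ml=krec,
                severity=severity,
                classes=classes,
                perturbation_target=pert_target,
            )
    return subjects, GroundTruth(truths)


def cohort_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in subjects])


# ---------------------------------------------------------------------------
# spectratype profiles
# ---------------------------------------------------------------------------


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _archetype_weights(
    class_label: str, n: int, rng: np.random.Generator, noise_scale: float
) -> np.ndarray:
    """Relative peak weights realising one clonality class archetype."""
    x = np.arange(n, dtype=float)
    centre = (n - 1) / 2.0
    if class_label == "normal":
        mu = rng.uniform(centre - 0.5, centre + 0.5)
        sigma = rng.uniform(1.7, 2.2) * n / 8.0
        w = _gauss(x, mu, sigma)
    elif class_label == "shifted":
        # deep bimodal: >=7 peaks but clearly non-Gaussian
        mu = rng.uniform(centre - 0.5, centre + 0.5)
        sep = rng.uniform(1.9, 2.5) * n / 8.0
        sigma = rng.uniform(0.9, 1.2) * n / 8.0
        mix = rng.uniform(0.45, 0.55)
        w = mix * _gauss(x, mu - sep, sigma) + (1 - mix) * _gauss(x, mu + sep, sigma)
    elif class_label == "restricted":
        n_peaks = int(rng.integers(5, min(7, n)))
        start = int(rng.integers(0, n - n_peaks + 1))
        sub = rng.dirichlet(np.full(n_peaks, 8.0))
        # blend toward uniform so no peak dominates (keeps the profile well
        # away from the mono/oligoclonal thresholds even after noise)
        u = 1.0 / n_peaks
        cap = 0.26
        if sub.max() > cap:
            lam = (cap - u) / (sub.max() - u)
            sub = u + lam * (sub - u)
        floor = 0.06
        if sub.min() < floor:
            lam = (u - floor) / (u - sub.min())
            sub = u + lam * (sub - u)
        w = np.zeros(n)
        w[start : start + n_peaks] = sub
    elif class_label == "mono_oligoclonal":
        w = np.full(n, 1.0)
        if rng.random() < 0.5:  # monoclonal: one dominant peak
            dom = rng.uniform(0.55, 0.80)
            pos = int(rng.integers(0, n))
            w = w / w.sum() * (1 - dom)
            w[pos] += dom
        else:  # oligoclonal: two dominant peaks
            total = rng.uniform(0.70, 0.82)
            split = rng.uniform(0.48, 0.52)
            p1 = int(rng.integers(0, n - 1))
            p2 = p1 + 1 + int(rng.integers(0, n - 1 - p1))
            w = w / w.sum() * (1 - total)
            w[p1] += total * split
            w[p2] += total * (1 - split)
    else:
        raise ConfigurationError(f"unknown clonality class {class_label!r}; valid: {CLASSES}")
    w = w * np.exp(rng.normal(0.0, 0.08 * noise_scale, n))
    return w / w.sum()


def generate_spectratype_profile(
    class_label: str,
    n_lengths: int = DEFAULT_N_LENGTHS,
    seed: int | np.random.Generator = 0,
    base_size: int = 130,
    noise_scale: float = 1.0,
    total_area: float | None = None,
) -> list[tuple[int, float]]:
    """One subgroup's (fragment size, area) peaks for a given clonality class.

    The ladder is in-frame (3-nt spacing) starting at ``base_size``.  Areas
    are positive where a peak exists; downstream detectability (the 2 %
    floor) is applied by the analysis side, not here.
    """
    if n_lengths < 3:
        raise ConfigurationError("n_lengths must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = _archetype_weights(class_label, n_lengths, rng, noise_scale)
    if total_area is None:
        total_area = float(rng.lognormal(math.log(5e4), 0.3))
    sizes = [base_size + LADDER_SPACING_NT * k for k in range(n_lengths)]
    return [(s, float(total_area * wk)) for s, wk in zip(sizes, w)]


def generate_peak_table(
    subjects: Sequence[SubjectRecord], truth: GroundTruth, config: CohortConfig
) -> pd.DataFrame:
    """Cohort-wide GeneMapper-style peak table (one row per peak).

    Per-subject profile noise is scaled by the subject's severity relative
    to its group median, which couples measured perturbation to the latent
    severity without changing the expected class mixes.
    """
    rows = []
    for s in subjects:
        gi = GROUPS.index(s.group)
        j = int(s.subject_id.rsplit("-", 1)[1]) - 1
        rng = _subject_rng(config.seed, gi, j, 2)
        t = truth.subjects[s.subject_id]
        noise_scale = float(np.clip(t.severity / config.perturbation_median[s.group], 0.5, 2.0))
        for trbv in TRBV_SUBGROUPS:
            peaks = generate_spectratype_profile(
                t.classes[trbv],
                n_lengths=config.n_lengths,
                seed=rng,
                base_size=ladder_offset(trbv),
                noise_scale=noise_scale,
            )
            for size, area in peaks:
                rows.append(
                    {
                        "sample_id": s.subject_id,
                        "trbv": trbv,
                        "fragment_size": size,
                        "height": round(area / 2.5, 2),
                        "area": round(area, 2),
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "trbv", "fragment_size", "height", "area"])


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveParams:
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ConfigurationError(f"standard-curve slope must be < 0, got {self.slope}")

    def cq_of(self, quantity: float) -> float:
        return self.intercept + self.slope * math.log10(quantity)


#: telomere assay defaults: slopes as observed for the telomere and
#: beta-globin curves; intercepts give plausible Cq ranges
DEFAULT_TELOMERE_CURVES = {"TEL": CurveParams(-3.05, 25.0), "BG": CurveParams(-3.22, 28.0)}
DEFAULT_EXCISION_CURVES = {"TREC": CurveParams(-3.40, 38.0), "KREC": CurveParams(-3.45, 38.5)}

#: 8-point 1:2 reference ladder (ng/well), 21 ng halved seven times
TELOMERE_LADDER_NG = tuple(21.0 / 2**k for k in range(8))
#: copy-number ladder for the duplex assay
EXCISION_LADDER_COPIES = tuple(10.0**k for k in range(6, 0, -1))

DEFAULT_BLOOD_NORM = BloodNormalization(cells_per_ml=2.0e6, cells_per_reaction=1.25e5)


def generate_qpcr_plate(
    truth_quantities: Mapping[str, Mapping[str, float]],
    curve_params: Mapping[str, CurveParams],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    standard_ladder: Mapping[str, Sequence[float]] | None = None,
    n_replicates: int = 3,
) -> QpcrPlate:
    """Simulate a plate: standards, triplicate samples, one NTC per target.

    ``truth_quantities`` maps sample id -> {target: true quantity per
    reaction}.  Cq = intercept + slope*log10(quantity) + N(0, noise_sd).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ladders = standard_ladder or {}
    wells: list[Well] = []
    wid = 0

    def next_id() -> str:
        nonlocal wid
        wid += 1
        return f"W{wid:03d}"

    for target, params in curve_params.items():
        ladder = ladders.get(
            target, TELOMERE_LADDER_NG if target in ("TEL", "BG") else EXCISION_LADDER_COPIES
        )
        for q in ladder:
            cq = params.cq_of(q) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            wells.append(Well(next_id(), target, "standard", f"std:{target}:{q:g}", float(q), cq))
        for sid, quantities in truth_quantities.items():
            if target not in quantities:
                continue
            q = quantities[target]
            if not q > 0:
                raise ConfigurationError(f"true quantity for {sid}/{target} must be > 0")
            for _ in range(n_replicates):
                cq = params.cq_of(q) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                wells.append(Well(next_id(), target, "sample", sid, None, cq))
        wells.append(Well(next_id(), target, "ntc", f"ntc:{target}", None, math.nan))
    return QpcrPlate(wells)


def telomere_plate(
    ts_by_sample: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    sample_input_ng: float = 10.0,
    curve_params: Mapping[str, CurveParams] = None,
) -> QpcrPlate:
    """Telomere assay plate: TEL quantity = T/S x input ng, BG = input ng."""
    curves = curve_params or DEFAULT_TELOMERE_CURVES
    truths = {
        sid: {"TEL": ts * sample_input_ng, "BG": sample_input_ng}
        for sid, ts in ts_by_sample.items()
    }
    return generate_qpcr_plate(truths, curves, noise_sd, seed)


def excision_plate(
    copies_per_ml: Mapping[str, tuple[float, float]],
    blood_norm: BloodNormalization = DEFAULT_BLOOD_NORM,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    curve_params: Mapping[str, CurveParams] = None,
) -> QpcrPlate:
    """Duplex TREC/KREC plate from true copies/ml of blood per sample."""
    curves = curve_params or DEFAULT_EXCISION_CURVES
    truths = {
        sid: {"TREC": trec / blood_norm.factor, "KREC": krec / blood_norm.factor}
        for sid, (trec, krec) in copies_per_ml.items()
    }
    return generate_qpcr_plate(truths, curves, noise_sd, seed)


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: CohortConfig
    subjects: list[SubjectRecord]
    truth: GroundTruth
    metadata: pd.DataFrame
    peak_table: pd.DataFrame
    telomere: QpcrPlate
    excision: QpcrPlate
    blood_norm: BloodNormalization

    def write(self, outdir: str | Path) -> None:
        """Write all study files (CSV/TSV/JSON) into ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out / "cohort.csv", index=False)
        self.peak_table.to_csv(out / "peaks.tsv", sep="\t", index=False)
        self.telomere.to_csv(out / "telomere_plate.csv")
        self.excision.to_csv(out / "excision_plate.csv")
        self.truth.to_json(out / "ground_truth.json")


def simulate_study(
    config: CohortConfig | None = None, blood_norm: BloodNormalization = DEFAULT_BLOOD_NORM
) -> SimulatedStudy:
    """Generate a full synthetic study: cohort, peak table, both plates."""
    config = config or CohortConfig()
    subjects, truth = generate_cohort(config)
    peaks = generate_peak_table(subjects, truth, config)
    plate_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(99, 0, 0))
    )
    tel = telomere_plate(
        {sid: t.ts for sid, t in truth.subjects.items()}, config.qpcr_noise_sd, plate_rng
    )
    exc = excision_plate(
        {
            sid: (t.trec_copies_per_ml, t.krec_copies_per_ml)
            for sid, t in truth.subjects.items()
        },
        blood_norm,
        config.qpcr_noise_sd,
        plate_rng,
    )
    return SimulatedStudy(
        config=config,
        subjects=subjects,
        truth=truth,
        metadata=cohort_frame(subjects),
        peak_table=peaks,
        telomere=tel,
        excision=exc,
        blood_norm=blood_norm,
    )
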