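"""Synthetic patient-cohort generator.

Real multimodal MR grading cohorts are rarely public, so the package ships a
generator that emulates the statistical shape of a mixed-grade glioma cohort:
grade-conditional moments for each continuous feature, a grade-conditional
three-state enhancement category, and modality-level (block) missingness —
every patient has the enhancement reading, while perfusion and MRSI are each
present for only a subset of patients, with a smaller overlap having both.

Continuous features are drawn independently given grade, either as plain
Gaussians or as moment-matched log-normals for nonnegative heavy-tailed
ratios whose standard deviation rivals or exceeds the mean (e.g. lactate and
lipid ratios). The log-normal is parameterized so its analytic mean and SD
equal the requested ones exactly.
"""

from __future__ import annotations

import io
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    CONTINUOUS_FEATURES,
    GRADE_COL,
    GRADE_STATES,
    ID_COL,
    MODALITY_GROUPS,
    T1WC_COL,
    T1WC_STATES,
    TABLE_COLUMNS,
)

__all__ = [
    "GroupFeatureSpec",
    "EnhancementSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "write_table",
    "read_table",
    "validate_table",
    "lognormal_params",
    "spec_to_dict",
    "spec_from_dict",
]

_FAMILIES = ("gaussian", "lognormal_moment_matched")


@dataclass(frozen=True)
class GroupFeatureSpec:
    """Grade-conditional moments for one continuous feature.

    ``family`` selects the sampling distribution; for
    ``lognormal_moment_matched`` the log-normal parameters are solved so the
    distribution's mean and SD equal (mean, sd) exactly in each group.
    """

    feature_name: str
    mean_high: float
    sd_high: float
    mean_low: float
    sd_low: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sd_high <= 0 or self.sd_low <= 0:
            raise ValueError(
                f"{self.feature_name}: group SDs must be strictly positive"
            )
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.feature_name}: unknown family {self.family!r}")
        if self.family == "lognormal_moment_matched" and (
            self.mean_high <= 0 or self.mean_low <= 0
        ):
            raise ValueError(
                f"{self.feature_name}: log-normal family requires positive means"
            )

    def params(self, grade: str) -> tuple[float, float]:
        if grade == "high":
            return self.mean_high, self.sd_high
        if grade == "low":
            return self.mean_low, self.sd_low
        raise ValueError(f"unknown grade {grade!r}")


@dataclass(frozen=True)
class EnhancementSpec:
    """Grade-conditional distribution over the three enhancement states.

    Ordered (negative, slight, apparent). These frequencies are a modelling
    choice of the generator, not measured quantities; override them to probe
    other regimes.
    """

    p_states_high: tuple[float, float, float] = (0.10, 0.17, 0.73)
    p_states_low: tuple[float, float, float] = (0.62, 0.23, 0.15)

    def __post_init__(self) -> None:
        for name, p in (("high", self.p_states_high), ("low", self.p_states_low)):
            if len(p) != 3 or any(x < 0 for x in p):
                raise ValueError(f"p_states_{name}: need 3 nonnegative entries")
            if abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"p_states_{name} must sum to 1 (got {sum(p)!r})")

    def probs(self, grade: str) -> tuple[float, float, float]:
        return self.p_states_high if grade == "high" else self.p_states_low


@dataclass(frozen=True)
class CohortSpec:
    """Complete recipe for one synthetic cohort (counts, moments, seed)."""

    n_high: int
    n_low: int
    n_pwi: int
    n_mrsi: int
    n_both: int
    seed: int = 20160414
    features: tuple[GroupFeatureSpec, ...] = ()
    enhancement: EnhancementSpec = field(default_factory=EnhancementSpec)

    def __post_init__(self) -> None:
        n = self.n_high + self.n_low
        if min(self.n_high, self.n_low, self.n_pwi, self.n_mrsi, self.n_both) < 0:
            raise ValueError("all counts must be nonnegative")
        if self.n_both > min(self.n_pwi, self.n_mrsi):
            raise ValueError(
                f"n_both={self.n_both} exceeds min(n_pwi={self.n_pwi}, "
                f"n_mrsi={self.n_mrsi})"
            )
        if self.n_pwi > n or self.n_mrsi > n:
            raise ValueError("n_pwi and n_mrsi cannot exceed the cohort size")

    @property
    def n_total(self) -> int:
        return self.n_high + self.n_low

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


#: default grade-conditional (mean, sd) per feature; heavy-tailed nonnegative
#: ratios use the moment-matched log-normal family.
_DEFAULT_FEATURES = (
    GroupFeatureSpec("nrCBV", 3.762, 2.234, 1.482, 0.624),
    GroupFeatureSpec("nMTT", 1.483, 0.779, 1.007, 0.115),
    GroupFeatureSpec("nrCBF", 2.653, 1.514, 1.571, 0.895),
    GroupFeatureSpec("nT0", 1.048, 0.212, 1.030, 0.120),
    GroupFeatureSpec("nTTP", 1.088, 0.168, 1.007, 0.051),
    GroupFeatureSpec("Cho/Cr", 1.169, 0.522, 0.565, 0.179),
    GroupFeatureSpec("NAA/Cr", 0.357, 0.186, 0.680, 0.340),
    GroupFeatureSpec("Lac/Cr", 109.598, 206.765, 1.462, 2.919,
                     family="lognormal_moment_matched"),
    GroupFeatureSpec("Lip13/Cr", 37.762, 34.745, 1.795, 2.680,
                     family="lognormal_moment_matched"),
)


def default_cohort_spec(seed: int = 20160414) -> CohortSpec:
    """Spec of the reference study cohort: 30 high / 26 low grade patients,
    51 with perfusion, 26 with MRSI and 21 with both modalities."""
    return CohortSpec(
        n_high=30, n_low=26, n_pwi=51, n_mrsi=26, n_both=21,
        seed=seed, features=_DEFAULT_FEATURES,
    )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given analytic mean and SD."""
    if mean <= 0:
        raise ValueError("log-normal moment matching requires mean > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _stream(seed: int, name: str) -> np.random.Generator:
    # per-name sub-stream: stable under edits to the feature list
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table from *spec*.

    The table has one row per patient with columns ``patient_id``, ``grade``,
    ``t1wc`` and the continuous features; missing modalities are NaN.
    Identical spec (including seed) gives an identical table.
    """
    n = spec.n_total
    n_pwi_only = spec.n_pwi - spec.n_both
    n_mrsi_only = spec.n_mrsi - spec.n_both
    if spec.n_both + n_pwi_only + n_mrsi_only > n:
        raise ValueError(
            "infeasible missingness allocation: n_pwi + n_mrsi - n_both = "
            f"{spec.n_pwi + spec.n_mrsi - spec.n_both} exceeds cohort size {n}"
        )

    grade = np.array(["high"] * spec.n_high + ["low"] * spec.n_low)
    table = pd.DataFrame({
        ID_COL: [f"pt{i + 1:04d}" for i in range(n)],
        GRADE_COL: grade,
    })

    t1wc_rng = _stream(spec.seed, "t1wc")
    t1wc = np.empty(n, dtype=object)
    for g in GRADE_STATES:
        mask = grade == g
        t1wc[mask] = t1wc_rng.choice(
            T1WC_STATES, size=int(mask.sum()), p=spec.enhancement.probs(g)
        )
    table[T1WC_COL] = t1wc

    for fs in spec.features:
        rng = _stream(spec.seed, f"feature:{fs.feature_name}")
        col = np.empty(n)
        for g in GRADE_STATES:
            mask = grade == g
            mean, sd = fs.params(g)
            if fs.family == "gaussian":
                col[mask] = rng.normal(mean, sd, size=int(mask.sum()))
            else:
                mu, sigma = lognormal_params(mean, sd)
                col[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
        table[fs.feature_name] = col

    # modality allocation: shuffled, independent of grade
    alloc_rng = _stream(spec.seed, "missingness")
    perm = alloc_rng.permutation(n)
    has_pwi = np.zeros(n, dtype=bool)
    has_mrsi = np.zeros(n, dtype=bool)
    both_idx = perm[: spec.n_both]
    pwi_idx = perm[spec.n_both: spec.n_both + n_pwi_only]
    mrsi_idx = perm[spec.n_both + n_pwi_only:
                    spec.n_both + n_pwi_only + n_mrsi_only]
    has_pwi[both_idx] = has_pwi[pwi_idx] = True
    has_mrsi[both_idx] = has_mrsi[mrsi_idx] = True

    present = {f: fs for fs in spec.features for f in [fs.feature_name]}
    for feat in MODALITY_GROUPS["perfusion"]:
        if feat in present:
            table.loc[~has_pwi, feat] = np.nan
    for feat in MODALITY_GROUPS["MRSI"]:
        if feat in present:
            table.loc[~has_mrsi, feat] = np.nan

    missing_cols = [c for c in TABLE_COLUMNS if c not in table.columns]
    for c in missing_cols:
        table[c] = np.nan
    return table[list(TABLE_COLUMNS)]


def validate_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a patient table.

    Raises ``ValueError`` naming the first offending row/column: every row
    needs a valid grade and enhancement state, and each modality's features
    must be jointly present or jointly absent (block missingness).
    """
    for col in (ID_COL, GRADE_COL, T1WC_COL):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    for i, (_, row) in enumerate(table.iterrows()):
        if row[GRADE_COL] not in GRADE_STATES:
            raise ValueError(
                f"row {i}: column 'grade' has invalid value {row[GRADE_COL]!r}"
            )
        if row[T1WC_COL] not in T1WC_STATES:
            raise ValueError(
                f"row {i}: column 't1wc' has invalid value {row[T1WC_COL]!r}"
            )
        for modality in ("perfusion", "MRSI"):
            members = [f for f in MODALITY_GROUPS[modality]
                       if f in table.columns]
            if not members:
                continue
            observed = [not pd.isna(row[f]) for f in members]
            if any(observed) and not all(observed):
                missing = members[observed.index(False)]
                raise ValueError(
                    f"row {i}: column {missing!r} missing while other "
                    f"{modality} features are present (block missingness)"
                )


def write_table(table: pd.DataFrame, path) -> None:
    """Write the cohort CSV (missing cells as empty fields)."""
    table.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; "" and "NA" both mean missing."""
    if isinstance(path, io.TextIOBase):
        raw = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    else:
        raw = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    validate_table(raw)
    for col in raw.columns:
        if col in CONTINUOUS_FEATURES:
            raw[col] = pd.to_numeric(raw[col], errors="raise")
    return raw


# ---------------------------------------------------------------------------
# config (YAML/JSON-style dict) mirror of CohortSpec

def spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_high": spec.n_high, "n_low": spec.n_low,
        "n_pwi": spec.n_pwi, "n_mrsi": spec.n_mrsi, "n_both": spec.n_both,
        "seed": spec.seed,
        "enhancement": {
            "p_states_high": list(spec.enhancement.p_states_high),
            "p_states_low": list(spec.enhancement.p_states_low),
        },
        "features": [
            {
                "feature_name": fs.feature_name,
                "mean_high": fs.mean_high, "sd_high": fs.sd_high,
                "mean_low": fs.mean_low, "sd_low": fs.sd_low,
                "family": fs.family,
            }
            for fs in spec.features
        ],
    }


def spec_from_dict(d: dict) -> CohortSpec:
    enh = d.get("enhancement")
    enhancement = (
        EnhancementSpec(
            tuple(enh["p_states_high"]), tuple(enh["p_states_low"])
        )
        if enh else EnhancementSpec()
    )
    features = tuple(
        GroupFeatureSpec(**f) for f in d.get("features", [])
    ) or _DEFAULT_FEATURES
    return CohortSpec(
        n_high=d["n_high"], n_low=d["n_low"],
        n_pwi=d["n_pwi"], n_mrsi=d["n_mrsi"], n_both=d["n_both"],
        seed=d.get("seed", 20160414),
        features=features, enhancement=enhancement,
    )
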