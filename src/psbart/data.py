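"""Trial data containers, validation, delimited I/O and fixture generation.

The central object is :class:`TrialDataset`, one row per participant of a
two-arm cluster-randomized trial whose non-mortality outcome is truncated by
death.  Truncation is *not* missingness: a participant observed to have died
has an outcome that is undefined (written as the sentinel ``TRUNC`` in files),
while a participant whose survival status was never recorded has a genuinely
missing outcome (empty cell or ``NA``).  Every row must fall into exactly one
of four observation patterns:

====  ====  ====  ==============================
R_S   S     R_Y   pattern
====  ====  ====  ==============================
1     1     1     complete_survivor
1     0     --    death_truncation (Y undefined)
1     1     0     survivor_outcome_missing
0     --    --    status_outcome_missing
====  ====  ====  ==============================
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ObservationPattern",
    "StratumLabel",
    "TrialDataset",
    "CovariateTransform",
    "classify_pattern",
    "load_trial_data",
    "write_trial_data",
    "validation_report",
    "generate_wsd_like",
    "impute_baseline_covariates",
    "G00",
    "G10",
    "G11",
]

# Integer codes for principal strata used throughout the samplers:
# never-survivor (0,0), protected (1,0), always-survivor (1,1).
G00, G10, G11 = 0, 1, 2

#: sentinel written for an outcome undefined by observed death
TRUNC_SENTINEL = "TRUNC"
#: cell contents treated as missing on input
NA_SENTINELS = {"", "NA", "NaN", "nan"}


class ObservationPattern(str, Enum):
    COMPLETE_SURVIVOR = "complete_survivor"
    DEATH_TRUNCATION = "death_truncation"
    SURVIVOR_OUTCOME_MISSING = "survivor_outcome_missing"
    STATUS_OUTCOME_MISSING = "status_outcome_missing"


class StratumLabel(Enum):
    """Principal stratum under monotonicity; the harmed stratum (0,1) is
    unrepresentable by construction."""

    NEVER_SURVIVOR = G00
    PROTECTED = G10
    ALWAYS_SURVIVOR = G11

    @property
    def code(self) -> int:
        return self.value

    @property
    def pair(self) -> tuple[int, int]:
        """(S(1), S(0)) potential survival pair."""
        return {G00: (0, 0), G10: (1, 0), G11: (1, 1)}[self.value]


def classify_pattern(r_s: int, s_obs, r_y) -> ObservationPattern:
    """Map an (R_S, S_obs, R_Y) triple to its observation pattern.

    ``s_obs`` and ``r_y`` may be ``None``/NaN where the pattern leaves them
    undefined.  Inconsistent triples raise ``ValueError``.
    """
    def _isna(v):
        return v is None or (isinstance(v, float) and np.isnan(v))

    if r_s not in (0, 1):
        raise ValueError(f"R_S must be 0 or 1, got {r_s!r}")
    if r_s == 0:
        if not _isna(s_obs):
            raise ValueError("R_S=0 requires survival status to be missing")
        return ObservationPattern.STATUS_OUTCOME_MISSING
    if _isna(s_obs) or s_obs not in (0, 1):
        raise ValueError("R_S=1 requires an observed survival status in {0,1}")
    if s_obs == 0:
        # outcome undefined by death; R_Y carries no information
        return ObservationPattern.DEATH_TRUNCATION
    if _isna(r_y) or r_y not in (0, 1):
        raise ValueError("observed survivors need R_Y in {0,1}")
    return (
        ObservationPattern.COMPLETE_SURVIVOR
        if r_y == 1
        else ObservationPattern.SURVIVOR_OUTCOME_MISSING
    )


@dataclass
class TrialDataset:
    """Observed data of a two-arm CRT with truncation by death.

    Arrays are aligned, one entry per participant.  ``cluster`` holds dense
    0-based cluster indices; ``z`` the (cluster-constant) arm; ``x`` the
    numeric covariate matrix.  ``s_obs`` is NaN where survival was not
    recorded; ``y_obs`` is NaN where the outcome is missing *or* undefined —
    the ``truncated`` flag distinguishes the undefined case.
    """

    cluster: np.ndarray
    z: np.ndarray
    x: np.ndarray
    covariate_names: list[str]
    s_obs: np.ndarray
    r_s: np.ndarray
    r_y: np.ndarray
    y_obs: np.ndarray
    truncated: np.ndarray
    imputed_covariate_mask: np.ndarray | None = None

    def __post_init__(self):
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        self.z = np.asarray(self.z, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.s_obs = np.asarray(self.s_obs, dtype=np.float64)
        self.r_s = np.asarray(self.r_s, dtype=np.int64)
        self.r_y = np.asarray(self.r_y, dtype=np.int64)
        self.y_obs = np.asarray(self.y_obs, dtype=np.float64)
        self.truncated = np.asarray(self.truncated, dtype=bool)
        self.validate()

    # -- basic structure -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.cluster)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1 if self.n else 0

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def cluster_z(self) -> np.ndarray:
        """Arm per cluster (length ``n_clusters``)."""
        out = np.zeros(self.n_clusters, dtype=np.int64)
        out[self.cluster] = self.z
        return out

    def patterns(self) -> np.ndarray:
        """Observation pattern of every row (array of ObservationPattern)."""
        out = np.empty(self.n, dtype=object)
        out[self.r_s == 0] = ObservationPattern.STATUS_OUTCOME_MISSING
        dead = (self.r_s == 1) & (self.s_obs == 0)
        out[dead] = ObservationPattern.DEATH_TRUNCATION
        alive = (self.r_s == 1) & (self.s_obs == 1)
        out[alive & (self.r_y == 1)] = ObservationPattern.COMPLETE_SURVIVOR
        out[alive & (self.r_y == 0)] = ObservationPattern.SURVIVOR_OUTCOME_MISSING
        return out

    def pattern_codes(self) -> np.ndarray:
        """Patterns as integer codes (0 complete survivor, 1 death
        truncation, 2 survivor-outcome-missing, 3 status-and-outcome
        missing) for vectorized tallies."""
        out = np.full(self.n, 3, dtype=np.int8)
        dead = (self.r_s == 1) & (self.s_obs == 0)
        out[dead] = 1
        alive = (self.r_s == 1) & (self.s_obs == 1)
        out[alive & (self.r_y == 1)] = 0
        out[alive & (self.r_y == 0)] = 2
        return out

    def pattern_counts(self) -> dict[str, int]:
        codes = self.pattern_codes()
        order = [ObservationPattern.COMPLETE_SURVIVOR,
                 ObservationPattern.DEATH_TRUNCATION,
                 ObservationPattern.SURVIVOR_OUTCOME_MISSING,
                 ObservationPattern.STATUS_OUTCOME_MISSING]
        return {p.value: int((codes == i).sum()) for i, p in enumerate(order)}

    def validate(self) -> None:
        n = self.n
        for name in ("z", "s_obs", "r_s", "r_y", "y_obs", "truncated"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has wrong length")
        if self.x.shape[0] != n:
            raise ValueError("covariate matrix has wrong number of rows")
        if n == 0:
            return
        # dense cluster ids
        uniq = np.unique(self.cluster)
        if uniq[0] != 0 or uniq[-1] != len(uniq) - 1:
            raise ValueError("cluster ids must be dense 0-based integers")
        # arm constant within cluster
        for c in uniq:
            zc = self.z[self.cluster == c]
            if not (zc == zc[0]).all():
                raise ValueError(f"arm varies within cluster {c}")
        # pattern consistency
        if ((self.r_s == 0) & ~np.isnan(self.s_obs)).any():
            raise ValueError("R_S=0 rows must have missing survival status")
        if ((self.r_s == 1) & np.isnan(self.s_obs)).any():
            raise ValueError("R_S=1 rows must have observed survival status")
        dead = (self.r_s == 1) & (self.s_obs == 0)
        if (self.truncated != dead).any():
            raise ValueError("Y is undefined (truncated) iff survival observed 0")
        if (~np.isnan(self.y_obs) & dead).any():
            raise ValueError("outcome value present for an observed non-survivor")
        if (~np.isnan(self.y_obs) & (self.r_s == 0)).any():
            raise ValueError("outcome value present while survival status missing")
        alive = (self.r_s == 1) & (self.s_obs == 1)
        if (np.isnan(self.y_obs) & alive & (self.r_y == 1)).any():
            raise ValueError("R_Y=1 survivor without outcome value")
        if (~np.isnan(self.y_obs) & alive & (self.r_y == 0)).any():
            raise ValueError("R_Y=0 survivor with outcome value")

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.cluster, "arm": self.z})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.x[:, j]
        surv = np.where(np.isnan(self.s_obs), "", self.s_obs.astype("object"))
        surv = [("" if s == "" else str(int(s))) for s in surv]
        df["survival"] = surv
        out = []
        for i in range(self.n):
            if self.truncated[i]:
                out.append(TRUNC_SENTINEL)
            elif np.isnan(self.y_obs[i]):
                out.append("")
            else:
                out.append(repr(float(self.y_obs[i])))
        df["outcome"] = out
        return df

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def write_trial_data(data: TrialDataset, path: str | Path, sep: str = ",") -> None:
    data.write(path, sep=sep)


DEFAULT_SCHEMA = {
    "cluster": "cluster",
    "arm": "arm",
    "survival": "survival",
    "outcome": "outcome",
    "covariates": None,  # None -> all remaining columns
}


def load_trial_data(path: str | Path, schema: dict | None = None,
                    sep: str = ",") -> TrialDataset:
    """Read a delimited trial table and derive missingness indicators.

    ``schema`` maps roles (cluster, arm, survival, outcome, covariates) to
    column names; missing cells are empty or ``NA``; outcomes undefined by
    death are written ``TRUNC``.  Violations of the four-pattern structure
    raise with the offending row index.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for role in ("cluster", "arm", "survival", "outcome"):
        if schema[role] not in df.columns:
            raise ValueError(f"column {schema[role]!r} (role {role}) not in file")
    covs = schema["covariates"]
    if covs is None:
        used = {schema[r] for r in ("cluster", "arm", "survival", "outcome")}
        covs = [c for c in df.columns if c not in used]
    n = len(df)

    raw_cluster = df[schema["cluster"]].to_numpy()
    _, cluster = np.unique(raw_cluster, return_inverse=True)
    z = df[schema["arm"]].astype(int).to_numpy()
    for c in np.unique(cluster):
        zc = z[cluster == c]
        if not (zc == zc[0]).all():
            raise ValueError(
                f"arm varies within cluster {raw_cluster[cluster == c][0]!r}"
            )

    def _cell(v: str) -> str:
        return v.strip()

    x = np.full((n, len(covs)), np.nan)
    for j, name in enumerate(covs):
        col = df[name].map(_cell)
        ok = ~col.isin(NA_SENTINELS)
        x[ok.to_numpy(), j] = col[ok].astype(float).to_numpy()

    s_obs = np.full(n, np.nan)
    r_s = np.zeros(n, dtype=int)
    r_y = np.zeros(n, dtype=int)
    y_obs = np.full(n, np.nan)
    truncated = np.zeros(n, dtype=bool)

    for i in range(n):
        sv = _cell(df[schema["survival"]].iloc[i])
        yv = _cell(df[schema["outcome"]].iloc[i])
        if sv in NA_SENTINELS:
            if yv not in NA_SENTINELS:
                raise ValueError(
                    f"row {i}: outcome cell present but survival status missing"
                )
            continue  # status_outcome_missing
        s = int(float(sv))
        if s not in (0, 1):
            raise ValueError(f"row {i}: survival must be 0/1, got {sv!r}")
        r_s[i] = 1
        s_obs[i] = s
        if s == 0:
            if yv not in NA_SENTINELS and yv != TRUNC_SENTINEL:
                raise ValueError(
                    f"row {i}: outcome value present for a non-survivor"
                )
            truncated[i] = True
        else:
            if yv == TRUNC_SENTINEL:
                raise ValueError(f"row {i}: TRUNC outcome for a survivor")
            if yv in NA_SENTINELS:
                r_y[i] = 0
            else:
                r_y[i] = 1
                y_obs[i] = float(yv)

    return TrialDataset(
        cluster=cluster, z=z, x=x, covariate_names=list(covs),
        s_obs=s_obs, r_s=r_s, r_y=r_y, y_obs=y_obs, truncated=truncated,
    )


def validation_report(data: TrialDataset) -> dict:
    """JSON-serializable summary: pattern counts and per-column missingness."""
    miss = {
        name: float(np.isnan(data.x[:, j]).mean())
        for j, name in enumerate(data.covariate_names)
    }
    return {
        "n": data.n,
        "n_clusters": data.n_clusters,
        "n_treated_clusters": int(data.cluster_z.sum()),
        "pattern_counts": data.pattern_counts(),
        "covariate_missingness": miss,
    }


# ---------------------------------------------------------------------------
# covariate imputation and standardization
# ---------------------------------------------------------------------------

def impute_baseline_covariates(data: TrialDataset,
                               method: str = "mean_mode") -> TrialDataset:
    """Fill missing baseline covariates (continuous: mean, discrete: mode).

    A single completed dataset is produced; the imputation mask is retained on
    the result.  Outcome/survival missingness is untouched (it is handled by
    the sampler's data augmentation, not here).
    """
    if method != "mean_mode":
        raise ValueError(f"unknown imputation method {method!r}")
    x = data.x.copy()
    mask = np.isnan(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(
                f"covariate {data.covariate_names[j]!r} is entirely missing"
            )
        obs = col[~miss]
        if len(np.unique(obs)) <= 2:  # binary/indicator column -> mode
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]  # ties -> smallest value
        else:
            fill = obs.mean()
        col[miss] = fill
    return TrialDataset(
        cluster=data.cluster, z=data.z, x=x,
        covariate_names=list(data.covariate_names),
        s_obs=data.s_obs, r_s=data.r_s, r_y=data.r_y,
        y_obs=data.y_obs, truncated=data.truncated,
        imputed_covariate_mask=mask,
    )


@dataclass
class CovariateTransform:
    """Z-scoring of continuous covariates; binary 0/1 columns pass through."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "CovariateTransform":
        center = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
        for j in range(x.shape[1]):
            vals = np.unique(x[~np.isnan(x[:, j]), j])
            if set(vals.tolist()) <= {0.0, 1.0}:
                continue
            center[j] = np.nanmean(x[:, j])
            sd = np.nanstd(x[:, j])
            scale[j] = sd if sd > 0 else 1.0
        return cls(center=center, scale=scale)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale

    def invert(self, x_std: np.ndarray) -> np.ndarray:
        return x_std * self.scale + self.center


# ---------------------------------------------------------------------------
# fixture generator emulating the WSD telecare trial
# ---------------------------------------------------------------------------

def generate_wsd_like(
    n_clusters: int = 204,
    size_range: tuple[int, int] = (1, 26),
    seed: int = 0,
    rate_both_missing: float = 0.199,
    rate_death: float = 0.107,
    rate_survivor_missing: float = 0.052,
) -> TrialDataset:
    """Synthetic trial table with the WSD telecare study's shape.

    Emulates the published covariate marginals (age 74.13 (13.94); deprivation
    28.13 (15.04) on [1.89, 66.49]; mental health 33.05 (7.87); baseline
    EQ-5D-VAS 53.04 (22.02) on [0, 100]; binary/categorical frequencies) and
    the observed missingness pattern rates (defaults 19.9% status-and-outcome
    missing, 10.7% death truncation, 5.2% survivor-outcome missing).  Strata
    are generated from a nested-Probit model on standardized age, deprivation
    and mental health so the fixture exercises the same code paths as the
    confidential trial data at matching dimensions.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    lo, hi = size_range
    if not (1 <= lo <= hi <= 50):
        raise ValueError(f"size_range must be within [1, 50], got {size_range}")
    for r in (rate_both_missing, rate_death, rate_survivor_missing):
        if not 0 <= r < 1:
            raise ValueError("missingness rates must be in [0, 1)")

    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=n_clusters)
    n = int(sizes.sum())
    cluster = np.repeat(np.arange(n_clusters), sizes)

    # 1:1 cluster randomization
    n_treat = n_clusters // 2
    arm_c = np.zeros(n_clusters, dtype=int)
    arm_c[rng.permutation(n_clusters)[:n_treat]] = 1
    z = arm_c[cluster]

    def _tnorm(mean, sd, lo_, hi_, size):
        from scipy.stats import truncnorm
        a, b = (lo_ - mean) / sd, (hi_ - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)

    age = rng.normal(74.13, 13.94, n)
    deprivation = _tnorm(28.13, 15.04, 1.89, 66.49, n)
    mental = rng.normal(33.05, 7.87, n)
    physical = rng.normal(28.09, 8.62, n)
    eqvas0 = _tnorm(53.04, 22.02, 0.0, 100.0, n)
    # comorbid count: negative binomial matched to mean 1.09, sd 1.45
    nb_r = 1.09**2 / (1.45**2 - 1.09)
    comorbid = rng.negative_binomial(nb_r, nb_r / (nb_r + 1.09), n).astype(float)
    white = rng.binomial(1, 0.8856, n).astype(float)
    male = rng.binomial(1, 0.6434, n).astype(float)
    edu_p = np.array([0.6552, 0.1884, 0.0606, 0.0345, 0.0614])
    education = rng.choice(5, size=n, p=edu_p / edu_p.sum()).astype(float)
    living_alone = rng.binomial(1, 0.529, n).astype(float)

    x = np.column_stack([age, deprivation, comorbid, physical, mental,
                         eqvas0, white, male, education, living_alone])
    names = ["age", "deprivation", "comorbid", "physical", "mental",
             "eqvas0", "white", "male", "education", "living_alone"]

    # -- latent strata: calibrated so the death-truncation pattern lands near
    #    its configured rate among recorded-status rows
    from scipy.special import ndtr, ndtri

    p_dead = min(rate_death / max(1 - rate_both_missing, 1e-12), 0.95)
    p10_target = min(0.03, p_dead / 2)
    p00_target = max(p_dead - p10_target / 2, 1e-4)
    z_age = (age - 74.13) / 13.94
    z_dep = (deprivation - 28.13) / 15.04
    z_mh = (mental - 33.05) / 7.87
    mq = ndtri(1 - p00_target) - 0.25 * z_age - 0.10 * z_dep + 0.10 * z_mh
    mw = ndtri(1 - p10_target / max(1 - p00_target, 1e-12)) - 0.20 * z_age
    b_q = rng.normal(0, 0.15, n_clusters)[cluster]
    b_w = rng.normal(0, 0.15, n_clusters)[cluster]
    q = mq + b_q + rng.standard_normal(n)
    w = mw + b_w + rng.standard_normal(n)
    g = np.where(q <= 0, G00, np.where(w <= 0, G10, G11))
    s_true = ((g == G11) | ((g == G10) & (z == 1))).astype(int)

    # -- 12-month EQ-5D-VAS outcome for survivors
    b_y = rng.normal(0, 3.0, n_clusters)[cluster]
    base = (30.0 + 0.45 * eqvas0 + 2.0 * z_mh - 1.5 * z_age
            - 2.0 * (g == G10))
    tau = 1.5 - 1.0 * z_dep - 1.0 * living_alone
    y_true = base + tau * z + b_y + rng.normal(0, 12.0, n)
    y_true = np.clip(y_true, 0.0, 100.0)

    # -- missingness
    r_s = rng.binomial(1, 1 - rate_both_missing, n)
    p_surv_obs = (1 - rate_both_missing) * (1 - p_dead)
    p_ry0 = (min(rate_survivor_missing / p_surv_obs, 0.95)
             if p_surv_obs > 0 else 0.0)
    r_y = np.zeros(n, dtype=int)
    alive_obs = (r_s == 1) & (s_true == 1)
    r_y[alive_obs] = rng.binomial(1, 1 - p_ry0, int(alive_obs.sum()))

    s_obs = np.where(r_s == 1, s_true.astype(float), np.nan)
    truncated = (r_s == 1) & (s_true == 0)
    y_obs = np.full(n, np.nan)
    keep = alive_obs & (r_y == 1)
    y_obs[keep] = y_true[keep]

    return TrialDataset(
        cluster=cluster, z=z, x=x, covariate_names=names,
        s_obs=s_obs, r_s=r_s, r_y=r_y, y_obs=y_obs, truncated=truncated,
    )
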