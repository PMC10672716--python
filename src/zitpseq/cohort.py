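"""Synthetic trial cohorts: biomarkers, MCAR missingness, randomization,
outcome generation, and subset bookkeeping.

Cohorts are plain :class:`pandas.DataFrame` objects with one row per
patient and columns ``id``, ``x1`` ... ``xm`` (1.0 positive / 0.0
negative / NaN missing), ``arm`` (1 = experimental) and ``outcome``
(integer days in [0, G]).  All randomness flows through
:class:`numpy.random.Generator` seed-specs so every cohort is exactly
reproducible.

Missingness emulates inconsistent biomarker measurement in intensive
care: patients split completely at random into equal groups — one with
every biomarker measured, and one group per biomarker with only that
biomarker measured (for m = 2: terciles "both", "only x1", "only x2") —
so every patient has at least one measured biomarker.

Outcome generation follows the censored mechanism: a Poisson draw with
subject-specific mean ``lambda_i`` from the log-linear model (missing
biomarkers contributing zero), censored at G, then zeroed with
probability phi by an independent uniform coin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenarios import ScenarioSpec
from .zitp import linear_predictor

__all__ = [
    "count_subsets",
    "generate_biomarkers",
    "apply_mcar_terciles",
    "randomize",
    "generate_cohort",
    "biomarker_columns",
    "joint_subset_labels",
    "assign_subsets",
    "marginal_subsets",
    "missingness_strata",
    "write_cohort_csv",
    "read_cohort_csv",
]


def count_subsets(m: int) -> int:
    """Number of nonempty biomarker-defined partitions, ``3**m - 1``.

    Each biomarker can be positive, negative, or missing; the all-missing
    cell is excluded because every enrolled patient has at least one
    measurement.
    """
    if int(m) != m or m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    return 3 ** int(m) - 1


def generate_biomarkers(n: int, prevalence, seed=None) -> np.ndarray:
    """Independent Bernoulli biomarker matrix (n x m), 1 = positive."""
    prevalence = np.asarray(prevalence, dtype=float)
    if np.any((prevalence <= 0) | (prevalence >= 1)):
        raise ValueError("prevalences must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    return (rng.uniform(size=(n, prevalence.size)) < prevalence).astype(float)


def apply_mcar_terciles(n: int, seed=None, m: int = 2) -> np.ndarray:
    """MCAR missingness patterns: equal random groups of size ~ n/(m+1).

    Returns an integer vector: 0 = all biomarkers measured, j >= 1 = only
    biomarker j measured.  Group sizes differ by at most one.  The m = 2
    default gives the three terciles (both / only x1 / only x2).
    """
    if n < m + 1:
        raise ValueError(f"need n >= {m + 1} to populate every missingness group")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    pattern = np.empty(n, dtype=np.int64)
    for g, chunk in enumerate(np.array_split(perm, m + 1)):
        pattern[chunk] = g
    return pattern


def randomize(n: int, allocation: float = 0.5, seed=None) -> np.ndarray:
    """Independent Bernoulli treatment assignment, 1 = experimental."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return (rng.uniform(size=n) < allocation).astype(np.int64)


def _mask_biomarkers(x: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Hide biomarkers per the missingness pattern (NaN = missing)."""
    m = x.shape[1]
    out = x.copy()
    for j in range(m):
        # group 0 keeps everything; group j+1 keeps only biomarker j
        hide = (pattern != 0) & (pattern != j + 1)
        out[hide, j] = np.nan
    return out


def generate_cohort(spec: ScenarioSpec, n: int, seed=None) -> pd.DataFrame:
    """Generate ``n`` patients under a scenario.

    Missing biomarkers are masked *before* outcome generation, so a
    hidden biomarker's main effect and treatment interaction genuinely do
    not influence the generated outcome (they are zeroed in the linear
    predictor).
    """
    m = spec.m
    cols = [f"x{j + 1}" for j in range(m)]
    if n == 0:
        return pd.DataFrame(
            {"id": pd.Series([], dtype=np.int64)}
            | {c: pd.Series([], dtype=float) for c in cols}
            | {"arm": pd.Series([], dtype=np.int64), "outcome": pd.Series([], dtype=np.int64)}
        )
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_bio, s_miss, s_arm, s_out = ss.spawn(4)
    x = generate_biomarkers(n, spec.prevalence, np.random.default_rng(s_bio))
    pattern = apply_mcar_terciles(n, np.random.default_rng(s_miss), m=m)
    arm = randomize(n, spec.allocation, np.random.default_rng(s_arm))
    x_obs = _mask_biomarkers(x, pattern)
    lam = linear_predictor(spec.coef, x_obs, arm)
    rng = np.random.default_rng(s_out)
    w = rng.poisson(lam)
    r = np.minimum(w, spec.G)
    u = rng.uniform(size=n)
    outcome = np.where(u < spec.phi, 0, r).astype(np.int64)
    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64)})
    for j, c in enumerate(cols):
        df[c] = x_obs[:, j]
    df["arm"] = arm
    df["outcome"] = outcome
    return df


def biomarker_columns(records: pd.DataFrame) -> list[str]:
    """Biomarker column names present in a cohort table."""
    return [c for c in records.columns if c.startswith("x") and c[1:].isdigit()]


def _label_char(v: float) -> str:
    if np.isnan(v):
        return "?"
    return "+" if v == 1.0 else "-"


def joint_subset_labels(records: pd.DataFrame) -> pd.Series:
    """Per-patient joint subset label, e.g. "++", "+?", "?-" for m = 2."""
    cols = biomarker_columns(records)
    vals = records[cols].to_numpy(dtype=float)
    labels = ["".join(_label_char(v) for v in row) for row in vals]
    return pd.Series(labels, index=records.index, name="subset")


def assign_subsets(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map each joint subset label to the patient ids it contains.

    Every patient lands in exactly one of the ``3**m - 1`` joint labels
    (the all-missing label cannot occur by construction).
    """
    labels = joint_subset_labels(records)
    return {
        lab: records.loc[labels == lab, "id"].to_numpy()
        for lab in sorted(labels.unique())
    }


def marginal_subsets(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Overlapping marginal subsets: for each biomarker, its +/- groups
    among patients with that biomarker measured (e.g. "x1+", "x1-")."""
    out: dict[str, np.ndarray] = {}
    for j, col in enumerate(biomarker_columns(records)):
        v = records[col]
        out[f"{col}+"] = records.loc[v == 1.0, "id"].to_numpy()
        out[f"{col}-"] = records.loc[v == 0.0, "id"].to_numpy()
    return out


def missingness_strata(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a cohort by missingness pattern.

    Keys are "both" (all biomarkers measured; for general m, "all") and
    "only-xj" for single-measured groups.  Only patterns actually present
    are returned.
    """
    cols = biomarker_columns(records)
    measured = records[cols].notna()
    out: dict[str, pd.DataFrame] = {}
    all_key = "both" if len(cols) == 2 else "all"
    mask_all = measured.all(axis=1)
    if mask_all.any():
        out[all_key] = records.loc[mask_all]
    for col in cols:
        only = measured[col] & ~measured.drop(columns=col).any(axis=1)
        if only.any():
            out[f"only-{col}"] = records.loc[only]
    return out


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    """Write a patient table as CSV (missing biomarkers as NA)."""
    records.to_csv(path, index=False, na_rep="NA")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a patient table written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path, na_values=["NA"])
    df["id"] = df["id"].astype(np.int64)
    df["arm"] = df["arm"].astype(np.int64)
    if df["outcome"].notna().all():
        df["outcome"] = df["outcome"].astype(np.int64)
    for c in biomarker_columns(df):
        df[c] = df[c].astype(float)
    return df
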