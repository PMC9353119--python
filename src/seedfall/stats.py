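"""Intraspecific variability and repeatability of terminal-velocity estimates.

Works on tidy replicated measurement tables with columns
(species, seed, replicate, Vt): each seed measured several times, several
seeds per species.  All analyses run on natural-log-transformed Vt (the
choice of base does not affect any variance ratio).

Three complementary summaries:

* a nested variance decomposition — how much of the variance in log Vt sits
  between species, between seeds within species, and between repeated drops
  of the same seed (random-effects model, REML, with a method-of-moments
  estimator from the balanced-design expected mean squares as cross-check);
* the coefficient of determination of seed identity within one species
  (one-way ANOVA R^2);
* the intraclass correlation coefficient (one-way ANOVA ICC with the
  standard k0 group-size adjustment for unbalanced data), the repeatability
  of a single measurement, computed either across all seeds pooled or
  per-species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "validate_vt_dataset",
    "variance_decomposition",
    "per_seed_r_squared",
    "icc",
]

VT_COLUMNS = ["species", "seed", "replicate", "Vt"]


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of log Vt and their fractions of the total."""

    var_species: float
    var_seed: float
    var_resid: float
    method: str  # "reml" | "moments"

    @property
    def total(self) -> float:
        return self.var_species + self.var_seed + self.var_resid

    @property
    def fractions(self) -> dict:
        tot = self.total
        return {
            "species": self.var_species / tot,
            "seed": self.var_seed / tot,
            "resid": self.var_resid / tot,
        }


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_among: float
    ms_within: float
    n_groups: int
    k: float  # (adjusted) group size
    note: str = ""


def validate_vt_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy Vt table (species, seed, replicate, Vt) and return it."""
    missing = [c for c in VT_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"Vt dataset is missing columns {missing}")
    if not (data["Vt"] > 0).all():
        raise ValueError("all Vt values must be positive")
    return data


def _is_balanced(data: pd.DataFrame) -> bool:
    seeds_per_species = data.groupby("species")["seed"].nunique()
    reps_per_seed = data.groupby(["species", "seed"]).size()
    return seeds_per_species.nunique() == 1 and reps_per_seed.nunique() == 1


def _moments_components(data: pd.DataFrame) -> VarianceComponents:
    """Expected-mean-squares estimator for the balanced nested design.

    With s species x m seeds x r replicates:
    E[MS_resid]   = s2_e
    E[MS_seed]    = s2_e + r s2_seed
    E[MS_species] = s2_e + r s2_seed + m r s2_species
    """
    if not _is_balanced(data):
        raise ValueError(
            "method-of-moments variance decomposition requires a balanced "
            "design (equal seeds per species and replicates per seed); use "
            "method='reml' for unbalanced data"
        )
    y = np.log(data["Vt"].to_numpy(float))
    df = data.assign(logv=y)
    s = df["species"].nunique()
    m = df.groupby("species")["seed"].nunique().iloc[0]
    r = df.groupby(["species", "seed"]).size().iloc[0]

    grand = df["logv"].mean()
    sp_mean = df.groupby("species")["logv"].transform("mean")
    seed_mean = df.groupby(["species", "seed"])["logv"].transform("mean")

    ms_species = float(((sp_mean - grand) ** 2).sum() / (s - 1))
    ms_seed = float(((seed_mean - sp_mean) ** 2).sum() / (s * (m - 1)))
    ms_resid = float(((df["logv"] - seed_mean) ** 2).sum() / (s * m * (r - 1)))

    var_e = ms_resid
    var_seed = (ms_seed - ms_resid) / r
    var_sp = (ms_species - ms_seed) / (m * r)
    for name, v in (("seed", var_seed), ("species", var_sp)):
        if v < 0:
            warnings.warn(f"negative {name}-level moment estimate clamped to zero", stacklevel=3)
    return VarianceComponents(
        var_species=max(var_sp, 0.0),
        var_seed=max(var_seed, 0.0),
        var_resid=var_e,
        method="moments",
    )


def _reml_components(data: pd.DataFrame) -> VarianceComponents:
    df = pd.DataFrame(
        {
            "logv": np.log(data["Vt"].to_numpy(float)),
            "species": data["species"].astype(str).to_numpy(),
            "seed_id": (
                data["species"].astype(str) + ":" + data["seed"].astype(str)
            ).to_numpy(),
        }
    )
    model = smf.mixedlm(
        "logv ~ 1",
        data=df,
        groups="species",
        re_formula="1",
        vc_formula={"seed": "0 + C(seed_id)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    var_sp = float(fit.cov_re.iloc[0, 0])
    var_seed = float(np.asarray(fit.vcomp).ravel()[0])
    var_e = float(fit.scale)
    for name, v in (("species", var_sp), ("seed", var_seed)):
        if v <= 0:
            warnings.warn(
                f"singular REML fit: {name}-level variance estimated at the "
                f"zero boundary",
                stacklevel=3,
            )
    return VarianceComponents(
        var_species=max(var_sp, 0.0),
        var_seed=max(var_seed, 0.0),
        var_resid=var_e,
        method="reml",
    )


def variance_decomposition(data: pd.DataFrame, method: str = "reml") -> VarianceComponents:
    """Decompose variance in log Vt across species / seed / residual levels.

    Fits the nested two-level random-effects model
    log Vt = mu + species + seed(species) + error by REML (default) or by
    the balanced-design method of moments (``method="moments"``, also the
    standard cross-check: the two agree on balanced data).
    """
    data = validate_vt_dataset(data)
    if data["species"].nunique() < 2:
        raise ValueError("variance decomposition needs at least 2 species")
    if (data.groupby("species")["seed"].nunique() < 2).any():
        raise ValueError("each species needs at least 2 seeds")
    if (data.groupby(["species", "seed"]).size() < 2).any():
        raise ValueError("each seed needs at least 2 replicates")
    if method == "moments":
        return _moments_components(data)
    if method == "reml":
        return _reml_components(data)
    raise ValueError(f"unknown method {method!r}; choose 'reml' or 'moments'")


def per_seed_r_squared(data: pd.DataFrame) -> float:
    """R^2 of seed identity for log Vt within a single species (one-way ANOVA)."""
    data = validate_vt_dataset(data)
    if data["species"].nunique() != 1:
        raise ValueError("per-seed R^2 is defined within one species; got several")
    if data["seed"].nunique() < 2:
        raise ValueError("need at least 2 seeds")
    if (data.groupby("seed").size() < 2).any():
        raise ValueError("each seed needs at least 2 replicates")
    y = np.log(data["Vt"].to_numpy(float))
    groups = data["seed"].to_numpy()
    grand = y.mean()
    seed_mean = pd.Series(y).groupby(pd.Series(groups)).transform("mean").to_numpy()
    ss_between = float(((seed_mean - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        return 1.0
    return ss_between / ss_total


def icc(data: pd.DataFrame, grouping: str = "seed") -> ICCResult:
    """One-way ANOVA intraclass correlation coefficient of log Vt.

    ``grouping="seed"`` treats each individual seed (across all species) as a
    group — the repeatability of a single drop measurement;
    ``grouping="species"`` pools all seeds of a species into one group.
    Unbalanced group sizes use the standard k0 adjustment
    k0 = (N - sum(n_i^2)/N) / (G - 1).  A negative ICC (within-group spread
    exceeding the between-group signal) is reported as computed.
    """
    data = validate_vt_dataset(data)
    if grouping == "seed":
        labels = data["species"].astype(str) + ":" + data["seed"].astype(str)
    elif grouping == "species":
        labels = data["species"].astype(str)
    else:
        raise ValueError(f"grouping must be 'seed' or 'species', got {grouping!r}")

    y = np.log(data["Vt"].to_numpy(float))
    groups = labels.to_numpy()
    uniq, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    G, N = len(uniq), len(y)
    if G < 2:
        raise ValueError("ICC needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 observations")

    grand = y.mean()
    group_means = np.bincount(inverse, weights=y) / counts
    ss_among = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((y - group_means[inverse]) ** 2))
    ms_among = ss_among / (G - 1)
    ms_within = ss_within / (N - G)
    k0 = (N - np.sum(counts**2) / N) / (G - 1)

    if ms_within == 0:
        value, note = 1.0, "zero within-group variance"
    else:
        value = (ms_among - ms_within) / (ms_among + (k0 - 1) * ms_within)
        note = "negative ICC: within-group variance exceeds among-group signal" if value < 0 else ""
    return ICCResult(
        icc=float(value),
        ms_among=ms_among,
        ms_within=ms_within,
        n_groups=G,
        k=float(k0),
        note=note,
    )
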