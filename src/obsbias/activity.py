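"""Diel activity patterns and observation-time alignment.

Trait databases describe when a mammal is active with three binary flags
(diurnal, nocturnal, crepuscular); their eight combinations map onto eight
categorical activity patterns (e.g. flags (1,1,0) = cathemeral: active day
and night but not specifically at twilight). Each timestamped observation
falls in a diel period — diurnal 6:00-18:00, nocturnal 18:00-6:00,
crepuscular 5:00-7:00 and 17:00-19:00 — and is "aligned" when its period
matches the species' declared pattern. Because the literal windows overlap
at 5-7 h and 17-19 h, two policies are offered:

* ``crepuscular_priority`` (default): twilight hours count as crepuscular
  only, which turns the three windows into a partition of the 24-h clock —
  diurnal [7,17), crepuscular [5,7) u [17,19), nocturnal [19,5).
* ``overlapping``: every window keeps its literal bounds and an hour may
  belong to more than one period.

The per-pattern alignment proportions are summarized with a logistic
regression of the aligned/not-aligned outcome on the activity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ACTIVITY_PATTERNS",
    "derive_pattern",
    "classify_period",
    "is_aligned",
    "alignment_summary",
    "fit_alignment_glm",
    "AlignmentSummary",
]

# (diurnal, nocturnal, crepuscular) flags -> pattern
ACTIVITY_PATTERNS = {
    (1, 0, 0): "diurnal",
    (0, 1, 0): "nocturnal",
    (0, 0, 1): "crepuscular",
    (1, 1, 0): "cathemeral",
    (1, 0, 1): "diurnal_crepuscular",
    (0, 1, 1): "nocturnal_crepuscular",
    (1, 1, 1): "flexible",
    (0, 0, 0): "unknown",
}

POLICIES = ("crepuscular_priority", "overlapping")


def derive_pattern(diurnal: int, nocturnal: int, crepuscular: int) -> str:
    """Categorical activity pattern from the three activity flags."""
    key = (diurnal, nocturnal, crepuscular)
    if any(v not in (0, 1) for v in key):
        raise ValueError(f"activity flags must be 0/1, got {key}")
    return ACTIVITY_PATTERNS[key]


def _in_crepuscular(hour: float) -> bool:
    return 5.0 <= hour < 7.0 or 17.0 <= hour < 19.0


def classify_period(hour: float, policy: str = "crepuscular_priority") -> frozenset[str]:
    """Diel period(s) of a clock hour in [0, 24).

    Returns a frozenset of period names: a singleton under
    ``crepuscular_priority`` (the windows partition the clock), possibly
    two elements under ``overlapping``. Interval bounds are half-open so
    every instant maps deterministically.
    """
    if not (0.0 <= hour < 24.0):
        raise ValueError(f"hour must be in [0, 24), got {hour}")
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy == "crepuscular_priority":
        if _in_crepuscular(hour):
            return frozenset({"crepuscular"})
        if 7.0 <= hour < 17.0:
            return frozenset({"diurnal"})
        return frozenset({"nocturnal"})
    periods = set()
    if 6.0 <= hour < 18.0:
        periods.add("diurnal")
    else:
        periods.add("nocturnal")
    if _in_crepuscular(hour):
        periods.add("crepuscular")
    return frozenset(periods)


# periods in which each pattern counts as active
_ALIGNED_PERIODS = {
    "diurnal": {"diurnal"},
    "nocturnal": {"nocturnal"},
    "crepuscular": {"crepuscular"},
    "cathemeral": {"diurnal", "nocturnal"},
    "diurnal_crepuscular": {"diurnal", "crepuscular"},
    "nocturnal_crepuscular": {"nocturnal", "crepuscular"},
    "flexible": {"diurnal", "nocturnal", "crepuscular"},
}


def is_aligned(pattern: str, periods) -> bool:
    """Whether an observation in ``periods`` matches a declared pattern.

    Combined patterns align on any of their declared periods; flexible
    aligns always; cathemeral aligns by day or night but an hour falling
    in a crepuscular window vetoes it (cathemeral excludes twilight).
    ``unknown`` must be filtered by the caller.
    """
    if pattern == "unknown":
        raise ValueError("alignment undefined for pattern 'unknown'; filter upstream")
    if pattern not in _ALIGNED_PERIODS:
        raise ValueError(f"unrecognized pattern {pattern!r}")
    if isinstance(periods, str):
        periods = frozenset({periods})
    else:
        periods = frozenset(periods)
    if pattern == "flexible":
        return True
    if pattern == "cathemeral" and "crepuscular" in periods:
        return False
    return bool(periods & _ALIGNED_PERIODS[pattern])


@dataclass
class AlignmentSummary:
    policy: str
    per_pattern: pd.DataFrame  # index pattern; columns n_obs, n_aligned, prop_aligned
    n_no_time: int
    n_unknown_pattern: int
    glm: dict | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "per_pattern": self.per_pattern.reset_index().to_dict(orient="records"),
            "n_no_time": self.n_no_time,
            "n_unknown_pattern": self.n_unknown_pattern,
            "glm": self.glm,
        }


def alignment_table(
    hours,
    patterns,
    policy: str = "crepuscular_priority",
) -> tuple[pd.DataFrame, int, int]:
    """Per-observation alignment flags.

    ``hours`` may contain NaN for date-only records; those rows and rows
    with pattern ``unknown`` are excluded and counted. Returns
    (dataframe with columns pattern/aligned, n_no_time, n_unknown).
    """
    hours = np.asarray(hours, dtype=float)
    patterns = np.asarray(patterns, dtype=object)
    if hours.shape != patterns.shape:
        raise ValueError("hours and patterns must have equal length")
    has_time = ~np.isnan(hours)
    known = patterns != "unknown"
    keep = has_time & known
    n_no_time = int((~has_time).sum())
    n_unknown = int((has_time & ~known).sum())
    aligned = [
        is_aligned(p, classify_period(h, policy))
        for h, p in zip(hours[keep], patterns[keep])
    ]
    df = pd.DataFrame({"pattern": patterns[keep], "aligned": np.asarray(aligned, dtype=bool)})
    return df, n_no_time, n_unknown


def alignment_summary(
    hours,
    patterns,
    policy: str = "crepuscular_priority",
    fit_glm: bool = True,
    reference: str = "cathemeral",
) -> AlignmentSummary:
    """Per-pattern alignment proportions, optionally with a logistic fit."""
    df, n_no_time, n_unknown = alignment_table(hours, patterns, policy)
    if df.empty:
        raise ValueError("no usable records: every row lacks a time or has pattern 'unknown'")
    per = df.groupby("pattern")["aligned"].agg(n_obs="size", n_aligned="sum")
    per["prop_aligned"] = per["n_aligned"] / per["n_obs"]
    glm = None
    if fit_glm and df["pattern"].nunique() >= 2 and df["aligned"].nunique() == 2:
        glm = fit_alignment_glm(df, reference=reference)
    return AlignmentSummary(
        policy=policy,
        per_pattern=per,
        n_no_time=n_no_time,
        n_unknown_pattern=n_unknown,
        glm=glm,
    )


def fit_alignment_glm(df: pd.DataFrame, reference: str = "cathemeral") -> dict:
    """Logistic regression of alignment on activity pattern.

    One-factor binomial GLM with a treatment-coded pattern effect; the
    reference level defaults to ``cathemeral`` (alphabetically first) and
    falls back to the alphabetically first level actually present.
    Reports coefficients, Wald p-values, null/residual deviance and AIC,
    and flags quasi-complete separation (a level with all-0 or all-1
    outcomes) rather than failing.
    """
    levels = sorted(df["pattern"].unique())
    if reference not in levels:
        reference = levels[0]
    rates = df.groupby("pattern")["aligned"].mean()
    separation = [lvl for lvl in levels if rates[lvl] in (0.0, 1.0)]

    data = df.assign(aligned=df["aligned"].astype(float))
    model = smf.glm(
        f"aligned ~ C(pattern, Treatment(reference='{reference}'))",
        data=data,
        family=sm.families.Binomial(),
    )
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=200)
    names = []
    for name in res.params.index:
        if name == "Intercept":
            names.append("Intercept")
        else:
            names.append(name.split("[T.")[-1].rstrip("]"))
    return {
        "reference": reference,
        "coefficients": dict(zip(names, (float(v) for v in res.params))),
        "std_errors": dict(zip(names, (float(v) for v in res.bse))),
        "p_values": dict(zip(names, (float(v) for v in res.pvalues))),
        "null_deviance": float(res.null_deviance),
        "residual_deviance": float(res.deviance),
        "aic": float(res.aic),
        "separation_levels": separation,
        "converged": bool(res.converged),
    }
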