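"""Brain-response maturity classification and behavioural discrimination.

Each infant's EEG yields three booleans: noxious-specific activity (heel
lance, Cz), a sensory-evoked potential (to either the lance or the control
lance), and an evoked delta brush (any electrode, either stimulus). A fixed
decision tree maps these to an ordinal maturity level — split first on
noxious-specific activity, then on the sensory-evoked potential, finally on
delta brushes:

====== ============================================ =========================
level  profile                                      label
====== ============================================ =========================
4      noxious-specific AND sensory potential       most mature
3      noxious-specific only                        intermediate (noxious)
2      sensory potential only                       intermediate (sensory)
1      delta brushes only                           least mature
====== ============================================ =========================

An all-false profile is *unclassifiable* (such infants are excluded from
group analyses); a profile with an unknown field (e.g. Cz rejected) is
*unknown*, counted separately. The two anchored extremes (level 4 and
level 1) follow the source analysis; the relative order of the two
intermediate leaves is a documented package choice (noxious-specific above
sensory-only) and can be overridden via ``level_map``.

Behavioural discrimination is a facial response to the noxious but not the
innocuous stimulus. The association between maturity level (numeric
ordinal) and discrimination is assessed with a logit-link binomial GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "EEGResponseProfile",
    "MaturityClass",
    "DiscriminationFlag",
    "UNCLASSIFIABLE",
    "UNKNOWN",
    "MATURITY_LABELS",
    "classify",
    "discrimination_flag",
    "maturity_association",
    "MaturityTreeClassifier",
    "GLMResult",
]

UNCLASSIFIABLE = "unclassifiable"
UNKNOWN = "unknown"

MATURITY_LABELS = {
    1: "delta brushes only",
    2: "sensory-evoked potential only",
    3: "noxious-specific only",
    4: "noxious-specific and sensory-evoked",
}

#: Default tree leaves: (noxious_specific, sensory_potential) -> level.
#: The brush-only leaf (level 1) applies when both are False and a brush
#: was seen; both-False without a brush is unclassifiable.
DEFAULT_LEVEL_MAP = {(True, True): 4, (True, False): 3, (False, True): 2}


@dataclass(frozen=True)
class EEGResponseProfile:
    """Per-infant EEG occurrence flags; ``None`` marks an unknown field."""

    noxious_specific: bool | None
    sensory_potential: bool | None
    delta_brush: bool | None


@dataclass(frozen=True)
class MaturityClass:
    level: int
    label: str

    def __lt__(self, other: "MaturityClass") -> bool:
        return self.level < other.level


@dataclass(frozen=True)
class DiscriminationFlag:
    value: bool


def classify(
    profile: EEGResponseProfile,
    level_map: dict[tuple[bool, bool], int] | None = None,
):
    """Map one EEG response profile to its maturity class.

    Returns a :class:`MaturityClass`, or the string sentinels
    ``UNCLASSIFIABLE`` (no evoked response of any type) or ``UNKNOWN``
    (some field could not be assessed).
    """
    if (
        profile.noxious_specific is None
        or profile.sensory_potential is None
        or profile.delta_brush is None
    ):
        return UNKNOWN
    lm = DEFAULT_LEVEL_MAP if level_map is None else level_map
    nox, sep, brush = (
        bool(profile.noxious_specific),
        bool(profile.sensory_potential),
        bool(profile.delta_brush),
    )
    if not nox and not sep:
        if not brush:
            return UNCLASSIFIABLE
        level = 1
    else:
        level = lm[(nox, sep)]
    return MaturityClass(level=level, label=MATURITY_LABELS.get(level, f"level {level}"))


def discrimination_flag(nox_facial: bool, innoc_facial: bool) -> DiscriminationFlag:
    """Discriminative = facial response to noxious AND none to innocuous."""
    return DiscriminationFlag(value=bool(nox_facial) and not bool(innoc_facial))


class MaturityTreeClassifier(BaseEstimator, ClassifierMixin):
    """Fixed decision-tree classifier over EEG response profiles.

    ``predict`` accepts a DataFrame with boolean columns
    ``noxious_specific``, ``sensory_potential``, ``delta_brush`` (NaN =
    unknown) or an (n, 3) array in that column order, and returns integer
    levels with 0 for unclassifiable and -1 for unknown. ``fit`` is a no-op
    (the tree is hand-specified, not learned)."""

    def __init__(self, level_map: dict[tuple[bool, bool], int] | None = None):
        self.level_map = level_map

    def fit(self, X=None, y=None):
        return self

    @staticmethod
    def _to_profiles(X) -> list[EEGResponseProfile]:
        if isinstance(X, pd.DataFrame):
            cols = ["noxious_specific", "sensory_potential", "delta_brush"]
            arr = X[cols].to_numpy(dtype=object)
        else:
            arr = np.asarray(X, dtype=object)
        profiles = []
        for row in arr:
            vals = [None if (v is None or (isinstance(v, float) and np.isnan(v))) else bool(v) for v in row]
            profiles.append(EEGResponseProfile(*vals))
        return profiles

    def predict(self, X) -> np.ndarray:
        out = []
        for p in self._to_profiles(X):
            res = classify(p, self.level_map)
            if res == UNCLASSIFIABLE:
                out.append(0)
            elif res == UNKNOWN:
                out.append(-1)
            else:
                out.append(res.level)
        return np.asarray(out, dtype=int)

    def classify_profiles(self, X) -> list:
        """Like predict, but returns MaturityClass objects / sentinels."""
        return [classify(p, self.level_map) for p in self._to_profiles(X)]


@dataclass
class GLMResult:
    """Logit-link binomial regression summary (linear-predictor scale)."""

    slope: float
    ci: tuple[float, float]
    pvalue: float
    intercept: float
    link: str = "logit"
    separation: bool = False


def _binary_logit_fit(x: np.ndarray, y: np.ndarray) -> GLMResult:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    X = sm.add_constant(np.asarray(x, dtype=float))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.GLM(np.asarray(y, dtype=float), X, family=sm.families.Binomial()).fit()
        except Exception:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    np.asarray(y, dtype=float), X, family=sm.families.Binomial()
                ).fit(maxiter=25)
    if not separation and np.abs(fit.params).max() > 1e2:
        separation = True
    ci = fit.conf_int()
    return GLMResult(
        slope=float(fit.params[1]),
        ci=(float(ci[1][0]), float(ci[1][1])),
        pvalue=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        separation=separation,
    )


def maturity_association(levels, flags) -> GLMResult:
    """Regress per-infant discrimination (Bernoulli) on numeric maturity level.

    Perfect separation is reported via ``GLMResult.separation`` rather than
    allowed to masquerade as a huge finite slope.
    """
    levels = np.asarray(levels, dtype=float)
    flags = np.asarray(
        [f.value if isinstance(f, DiscriminationFlag) else bool(f) for f in flags],
        dtype=float,
    )
    if levels.size != flags.size:
        raise ValueError("levels and flags must be paired per infant")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct maturity levels")
    return _binary_logit_fit(levels, flags)
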